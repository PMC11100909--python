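import numpy as np
import pytest

from ptmrot.config import RunConfig
from ptmrot.geometry import circular_distance
from ptmrot.library_build import (
    BDLibrary,
    BILibrary,
    LibraryFormatError,
    RotamerEntry,
    RotamerLibraryModel,
    bin_center,
    bin_of,
    build_bd,
    build_bi,
    read_library,
    sample_rotamer,
    write_library,
)
from ptmrot.rotamer_binning import assign_state, build_scheme
from ptmrot.structures_io import TorsionRecord
from ptmrot.synthetic_fixtures import (
    default_spec,
    gen_torsion_dataset,
    region_dominant_state,
    two_region_spec,
)


def _record(resname, phi, psi, chis):
    return TorsionRecord("X", "A", 1, resname, phi, psi, np.asarray(chis, float))


class TestBinGrid:
    @pytest.mark.parametrize(
        "phi,psi,expected",
        [(-180, -180, (0, 0)), (0, 0, (6, 6)), (179.9, -0.1, (11, 5)),
         (-165, 165, (0, 11))],
    )
    def test_bin_of(self, phi, psi, expected):
        assert bin_of(phi, psi) == expected

    def test_bin_center_round_trip(self):
        for row in range(12):
            for col in range(12):
                assert bin_of(*bin_center(row, col)) == (row, col)


class TestBuildBI:
    def test_single_state_probability_one(self):
        scheme = build_scheme("M3L")
        records = [_record("M3L", -60, -40, (-60, 180, 180, 180, 30))] * 100
        lib = build_bi(records, scheme)
        assert len(lib.entries) == 1
        assert lib.entries[0].probability == 1.0
        assert lib.entries[0].count == 100

    def test_sixty_forty_split(self):
        scheme = build_scheme("M3L")
        records = [_record("M3L", -60, -40, (-60, 180, 180, 180, 30))] * 60
        records += [_record("M3L", -60, -40, (60, 180, 180, 180, 30))] * 40
        lib = build_bi(records, scheme)
        probs = sorted(e.probability for e in lib.entries)
        assert probs == [pytest.approx(0.4), pytest.approx(0.6)]

    def test_probabilities_normalized(self, sep_bi):
        assert sum(e.probability for e in sep_bi.entries) == pytest.approx(1.0, abs=1e-9)

    def test_mixture_means_recovered(self, sep_bi):
        spec = default_spec("SEP")
        recovered = 0
        for state_spec in spec.states:
            target = np.asarray(state_spec.chi_means[:2])
            for entry in sep_bi.entries:
                if np.all(circular_distance(entry.chi_means[:2], target) < 3.0):
                    assert abs(entry.probability - state_spec.weight) < 0.03
                    recovered += 1
                    break
        assert recovered == len(spec.states)

    def test_terminal_chi_folded_into_120_domain(self, sep_bi):
        for entry in sep_bi.entries:
            assert -60.0 <= entry.chi_means[-1] < 60.0

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            build_bi([], build_scheme("M3L"))


class TestBuildBD:
    def test_backfilled_bins_equal_bi_exactly(self, sep_bd_coupled):
        _, _, model, bd = sep_bd_coupled
        bi_sorted = sorted(bd.bi.entries, key=lambda e: (-e.probability, e.state))
        assert bd.backfilled
        for key in bd.backfilled:
            for entry, ref in zip(bd.grid[key], bi_sorted):
                assert entry.state == ref.state
                assert entry.probability == ref.probability
                assert np.array_equal(entry.chi_means, ref.chi_means)
                assert np.array_equal(entry.chi_stds, ref.chi_stds)

    def test_bin_probabilities_normalized(self, sep_bd_coupled):
        _, _, _, bd = sep_bd_coupled
        for entries in bd.grid.values():
            assert sum(e.probability for e in entries) == pytest.approx(1.0, abs=1e-9)

    def test_supported_plus_backfilled_is_144(self, sep_bd_coupled):
        _, _, _, bd = sep_bd_coupled
        assert len(bd.grid) == 144
        assert len(bd.backfilled) + (144 - len(bd.backfilled)) == 144

    def test_single_rotamer_state_everywhere(self):
        scheme = build_scheme("M3L")
        rng = np.random.default_rng(0)
        records = [
            _record("M3L", rng.uniform(-170, 170), rng.uniform(-170, 170),
                    (-60, 180, 180, 180, 30))
            for _ in range(50)
        ]
        bd = build_bd(records, scheme)
        for entries in bd.grid.values():
            assert len(entries) == 1
            assert entries[0].probability == pytest.approx(1.0)

    def test_locally_dominant_state_ranks_first(self, sep_bd_coupled):
        spec, _, model, bd = sep_bd_coupled
        truth = [assign_state(np.asarray(s.chi_means), model.scheme) for s in spec.states]
        hits = total = 0
        for row in range(12):
            for col in range(12):
                if (row, col) in bd.backfilled:
                    continue
                total += 1
                dominant = truth[region_dominant_state(spec, *bin_center(row, col))]
                hits += bd.grid[(row, col)][0].state == dominant
        assert hits / total >= 0.95

    def test_marginal_over_bins_matches_bi_when_uncoupled(self, sep_records, sep_model):
        bd = sep_model.fit()
        occupancy = np.zeros((12, 12))
        for r in sep_records:
            occupancy[bin_of(r.phi, r.psi)] += 1
        occupancy /= occupancy.sum()
        marginal = {}
        for (row, col), entries in bd.grid.items():
            for e in entries:
                marginal[e.state] = marginal.get(e.state, 0.0) + occupancy[row, col] * e.probability
        for e in bd.bi.entries:
            assert abs(marginal[e.state] - e.probability) < 0.05


class TestSerialization:
    def test_bd_round_trip(self, sep_bd_coupled):
        _, _, _, bd = sep_bd_coupled
        text = write_library(bd)
        again = read_library(text)
        assert isinstance(again, BDLibrary)
        assert again.resname == bd.resname
        assert again.backfilled == bd.backfilled
        for key, entries in bd.grid.items():
            for e1, e2 in zip(entries, again.grid[key]):
                assert e1.state == e2.state
                assert e1.count == e2.count
                assert abs(e1.probability - e2.probability) < 1e-9
                assert np.all(np.abs(e1.chi_means - e2.chi_means) < 1e-9)
                assert np.all(np.abs(e1.chi_stds - e2.chi_stds) < 1e-9)

    def test_bi_round_trip(self, sep_bi):
        again = read_library(write_library(sep_bi))
        assert isinstance(again, BILibrary)
        for e1, e2 in zip(sep_bi.entries, again.entries):
            assert e1.state == e2.state
            assert abs(e1.probability - e2.probability) < 1e-9

    def test_hand_written_bi_file(self):
        text = (
            "# resname: M3L\n"
            "# mode: BI\n"
            "# n_records: 10\n"
            "M3L . . G-,T,T,T 6 0.6 -60 180 180 180 30 5 5 5 5 10 0\n"
            "M3L . . T,T,T,T 4 0.4 -175 180 180 180 30 5 5 5 5 10 0\n"
        )
        lib = read_library(text)
        assert [e.count for e in lib.entries] == [6, 4]
        assert lib.entries[0].state == ("G-", "T", "T", "T")

    def test_unnormalized_probabilities_rejected(self):
        text = (
            "# resname: M3L\n"
            "# mode: BI\n"
            "M3L . . G-,T,T,T 6 0.5 -60 180 180 180 30 5 5 5 5 10 0\n"
            "M3L . . T,T,T,T 4 0.4 -175 180 180 180 30 5 5 5 5 10 0\n"
        )
        with pytest.raises(LibraryFormatError, match="sum"):
            read_library(text)

    def test_malformed_row_names_line(self):
        text = (
            "# resname: M3L\n"
            "# mode: BI\n"
            "M3L . . G-,T,T,T 6 1.0 -60 180 180\n"
        )
        with pytest.raises(LibraryFormatError, match="line 3"):
            read_library(text)


class TestSampling:
    def _toy_bi(self, probabilities, means, stds):
        entries = [
            RotamerEntry(state, p, np.asarray(m, float), np.asarray(s, float),
                         count=int(p * 100))
            for state, p, m, s in zip((("G-",), ("G+",)), probabilities, means, stds)
        ]
        scheme = build_scheme("M3L")
        lib = BILibrary(resname="M3L", entries=entries[: len(probabilities)],
                        n_records=100, scheme=scheme)
        return lib

    def test_single_state_floor_std_stays_near_mean(self):
        scheme = build_scheme("M3L")
        entry = RotamerEntry(("G-", "T", "T", "T"), 1.0,
                             np.array([-60.0, 180.0, 180.0, 180.0, 30.0]),
                             np.full(5, 3.0), 100)
        lib = BILibrary("M3L", [entry], 100, RunConfig(), scheme)
        rng = np.random.default_rng(5)
        for _ in range(200):
            chis = sample_rotamer(lib, rng=rng)
            assert np.all(circular_distance(chis[:4], entry.chi_means[:4]) <= 15.0)

    def test_state_frequencies_match_probabilities(self, sep_bi):
        rng = np.random.default_rng(42)
        scheme = sep_bi.scheme
        counts = {}
        n = 100_000
        for _ in range(n):
            state = assign_state(sample_rotamer(sep_bi, rng=rng), scheme)
            counts[state] = counts.get(state, 0) + 1
        for e in sep_bi.entries:
            assert abs(counts.get(e.state, 0) / n - e.probability) < 0.01

    def test_terminal_symmetry_images_uniform(self, sep_bi):
        rng = np.random.default_rng(7)
        n = 30_000
        image_counts = np.zeros(3)
        for _ in range(n):
            chi3 = sample_rotamer(sep_bi, rng=rng)[-1]
            image_counts[int((chi3 + 180.0) // 120.0)] += 1
        assert np.all(np.abs(image_counts / n - 1 / 3) < 0.02)

    def test_sample_and_rebuild_recovers_library(self, sep_bi):
        rng = np.random.default_rng(11)
        scheme = sep_bi.scheme
        records = [
            TorsionRecord("S", "A", i, "SEP", 0.0, 0.0, sample_rotamer(sep_bi, rng=rng))
            for i in range(100_000)
        ]
        rebuilt = build_bi(records, scheme)
        by_state = {e.state: e for e in rebuilt.entries}
        for e in sep_bi.entries:
            r = by_state[e.state]
            assert abs(r.probability - e.probability) < 0.01
            assert np.all(circular_distance(r.chi_means, e.chi_means) < 1.0)

    def test_bd_sampling_requires_backbone(self, sep_bd_coupled):
        _, _, _, bd = sep_bd_coupled
        with pytest.raises(ValueError):
            sample_rotamer(bd, None, None, np.random.default_rng(0))


class TestModelSurface:
    def test_from_dataframe_matches_records(self, sep_records):
        import pandas as pd

        df = pd.DataFrame(
            {
                "resname": [r.resname for r in sep_records],
                "phi": [r.phi for r in sep_records],
                "psi": [r.psi for r in sep_records],
                "chi1": [r.chis[0] for r in sep_records],
                "chi2": [r.chis[1] for r in sep_records],
                "chi3": [r.chis[2] for r in sep_records],
            }
        )
        model = RotamerLibraryModel.from_dataframe(df, resname="SEP")
        bi = model.fit(backbone_dependent=False)
        probs = sorted(e.probability for e in bi.entries)
        direct = RotamerLibraryModel(sep_records).fit(backbone_dependent=False)
        assert probs == pytest.approx(sorted(e.probability for e in direct.entries))

    def test_summary_mentions_states_and_counts(self, sep_bi):
        text = sep_bi.summary()
        assert "SEP" in text
        assert "2000" in text

    def test_mixed_residues_rejected_without_resname(self):
        a = gen_torsion_dataset(default_spec("SEP"), 5, 0)
        b = gen_torsion_dataset(default_spec("TPO"), 5, 0)
        with pytest.raises(ValueError, match="resname"):
            RotamerLibraryModel(a + b)

    def test_to_dataframe_has_all_bins(self, sep_bd_coupled):
        _, _, _, bd = sep_bd_coupled
        df = bd.to_dataframe()
        assert set(zip(df.phi, df.psi)).__len__() == 144
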