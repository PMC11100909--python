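import numpy as np
import pytest

from ptmrot.geometry import circular_distance
from ptmrot.structures_io import (
    Atom,
    PDBParseError,
    Residue,
    StructureModel,
    build_sidechain,
    contact_map,
    contact_map_diff,
    detect_hbonds,
    extract_torsions,
    parse_pdb,
    sidechain_rmsd,
    write_pdb,
)
from ptmrot.synthetic_fixtures import gen_hbond_fixture, gen_toy_model, gen_toy_pdb
from ptmrot.templates import CHI_COUNTS, get_template

CHI_EXAMPLES = {
    "SEP": (-60.0, 120.0, 30.0),
    "TPO": (-60.0, 120.0, 30.0),
    "PTR": (-65.0, 85.0, -40.0, 20.0),
    "M3L": (-60.0, 180.0, 180.0, 180.0, 45.0),
    "ALY": (-60.0, 180.0, 180.0, 178.0, 60.0),
}


class TestParsePDB:
    def test_toy_fixture_round_trip(self):
        text = gen_toy_pdb("SEP", -60, -45, CHI_EXAMPLES["SEP"])
        model = parse_pdb(text)
        resnames = [r.resname for r in model.residues()]
        assert resnames == ["ALA", "SEP", "ALA"]
        assert model.resolution == pytest.approx(1.5)

    def test_altloc_highest_occupancy_wins(self):
        text = (
            "ATOM      1  N  AALA A   1       0.000   0.000   0.000  0.60 10.00           N\n"
            "ATOM      2  N  BALA A   1       1.000   0.000   0.000  0.40 10.00           N\n"
            "ATOM      3  CA  ALA A   1       1.400   0.000   0.000  1.00 10.00           C\n"
            "END\n"
        )
        model = parse_pdb(text)
        res = next(model.residues())
        assert res.atom("N").position[0] == pytest.approx(0.0)
        assert res.atom("N").occupancy == pytest.approx(0.6)

    def test_remark_2_resolution(self):
        text = (
            "REMARK   2\n"
            "REMARK   2 RESOLUTION.    1.50 ANGSTROMS.\n"
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "END\n"
        )
        assert parse_pdb(text).resolution == pytest.approx(1.5)

    def test_malformed_coordinate_names_line(self):
        text = (
            "ATOM      1  CA  ALA A   1       0.000   0.000   0.000  1.00 10.00           C\n"
            "ATOM      2  CB  ALA A   1       xx.xxx   0.000   0.000  1.00 10.00           C\n"
        )
        with pytest.raises(PDBParseError, match="line 2"):
            parse_pdb(text)

    def test_empty_input_raises(self):
        with pytest.raises(PDBParseError):
            parse_pdb("")

    def test_writer_preserves_resolution_and_atoms(self):
        model = gen_toy_model("TPO", -60, -45, CHI_EXAMPLES["TPO"])
        again = parse_pdb(write_pdb(model))
        assert again.resolution == pytest.approx(1.5)
        orig = {a.name for r in model.residues() for a in r.atoms}
        back = {a.name for r in again.residues() for a in r.atoms}
        assert orig == back


class TestExtractTorsions:
    def test_single_residue_chain_has_no_torsions(self):
        res = Residue("SEP", "A", 1, atoms=[
            Atom("N", "N", (0, 0, 0)), Atom("CA", "C", (1.5, 0, 0)),
            Atom("C", "C", (2, 1, 0)),
        ])
        model = StructureModel(chains={"A": [res]})
        assert extract_torsions(model, {"SEP"}) == []

    @pytest.mark.parametrize("resname", sorted(CHI_EXAMPLES))
    def test_in_memory_round_trip_exact(self, resname):
        model = gen_toy_model(resname, -60, -45, CHI_EXAMPLES[resname])
        (rec,) = extract_torsions(model, {resname})
        assert circular_distance(rec.phi, -60) < 1e-6
        assert circular_distance(rec.psi, -45) < 1e-6
        assert np.all(circular_distance(rec.chis, CHI_EXAMPLES[resname]) < 1e-6)

    def test_missing_chi_atom_skips_record(self, caplog):
        model = gen_toy_model("SEP", -60, -45, CHI_EXAMPLES["SEP"])
        res = model.chains["A"][1]
        res.atoms = [a for a in res.atoms if a.name != "OG"]
        with caplog.at_level("INFO", logger="ptmrot.structures_io"):
            records = extract_torsions(model, {"SEP"})
        assert records == []
        assert any("OG" in message for message in caplog.messages)


class TestBuildSidechain:
    @pytest.mark.parametrize("resname", sorted(CHI_EXAMPLES))
    def test_chi_round_trip_identity(self, resname, rng):
        template = get_template(resname)
        for _ in range(5):
            chis = rng.uniform(-180, 180, size=CHI_COUNTS[resname])
            model = gen_toy_model(resname, -60, -45, chis)
            (rec,) = extract_torsions(model, {resname})
            assert np.all(circular_distance(rec.chis, chis) < 1e-6)

    def test_perturbing_chi_moves_only_downstream_atoms(self):
        base = gen_toy_model("SEP", -60, -45, (-60, 120, 30)).chains["A"][1]
        bumped = gen_toy_model("SEP", -60, -45, (-50, 120, 30)).chains["A"][1]
        moved = {
            a.name
            for a in base.atoms
            if np.linalg.norm(a.position - bumped.atom(a.name).position) > 1e-9
        }
        assert moved == {"OG", "P", "O1P", "O2P", "O3P"}

    def test_aly_extended_chain_has_no_atom_overlap(self):
        res = gen_toy_model("ALY", -60, -45, (-177, 180, 180, 180, 60)).chains["A"][1]
        coords = np.array([a.position for a in res.atoms])
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        assert d.min() > 1.0

    def test_chi_count_mismatch_raises(self):
        bb = gen_toy_model("SEP", -60, -45, (-60, 120, 30)).chains["A"][1]
        with pytest.raises(ValueError, match="chi"):
            build_sidechain(bb, "SEP", (-60, 120))

    def test_unknown_resname_raises(self):
        bb = gen_toy_model("SEP", -60, -45, (-60, 120, 30)).chains["A"][1]
        with pytest.raises(KeyError):
            build_sidechain(bb, "XXX", (0,))


class TestSidechainRMSD:
    def test_identical_residues_zero(self):
        res = gen_toy_model("SEP", -60, -45, (-60, 120, 30)).chains["A"][1]
        assert sidechain_rmsd(res, res) == 0.0

    def test_single_displaced_atom_closed_form(self):
        a = gen_toy_model("SEP", -60, -45, (-60, 120, 30)).chains["A"][1]
        import copy

        b = copy.deepcopy(a)
        b.atom("P").position = b.atom("P").position + np.array([1.0, 0, 0])
        n = 6  # CB OG P O1P O2P O3P
        assert sidechain_rmsd(a, b) == pytest.approx(1 / np.sqrt(n))

    def test_matches_direct_formula(self):
        a = gen_toy_model("SEP", -60, -45, (-60, 120, 30)).chains["A"][1]
        b = gen_toy_model("SEP", -60, -45, (-60, -60, 30)).chains["A"][1]
        names = ["CB", "OG", "P", "O1P", "O2P", "O3P"]
        direct = np.sqrt(
            np.mean(
                [np.sum((a.atom(n).position - b.atom(n).position) ** 2) for n in names]
            )
        )
        assert sidechain_rmsd(a, b, symmetry_aware=False) == pytest.approx(direct, abs=1e-12)
        # relabeling equivalent phosphate oxygens can only reduce the value
        assert sidechain_rmsd(a, b) <= direct + 1e-12

    def test_symmetry_aware_matches_rotor_images(self):
        a = gen_toy_model("SEP", -60, -45, (-60, 120, 30)).chains["A"][1]
        b = gen_toy_model("SEP", -60, -45, (-60, 120, 150)).chains["A"][1]
        # 120-degree image of the terminal rotor: equivalent oxygens permuted
        assert sidechain_rmsd(a, b) < 0.2
        assert sidechain_rmsd(a, b, symmetry_aware=False) > 1.0

    def test_metric_properties_on_random_triples(self, rng):
        conformers = [
            gen_toy_model("SEP", -60, -45, rng.uniform(-180, 180, 3)).chains["A"][1]
            for _ in range(3)
        ]
        a, b, c = conformers
        ab, bc, ac = (sidechain_rmsd(x, y) for x, y in ((a, b), (b, c), (a, c)))
        assert ab == pytest.approx(sidechain_rmsd(b, a))
        assert ac <= ab + bc + 1e-12

    def test_atom_mismatch_error_lists_names(self):
        a = gen_toy_model("SEP", -60, -45, (-60, 120, 30)).chains["A"][1]
        import copy

        b = copy.deepcopy(a)
        b.atoms = [at for at in b.atoms if at.name != "O3P"]
        with pytest.raises(ValueError, match="O3P"):
            sidechain_rmsd(a, b)


class TestDetectHbonds:
    def _model_with_pair(self, distance):
        sep = gen_toy_model("SEP", -60, -45, (-60, 120, 30))
        donor = sep.chains["A"][2].atom("N")
        o1p = sep.chains["A"][1].atom("O1P")
        # translate residue 3 so its N sits exactly `distance` from O1P
        direction = donor.position - o1p.position
        direction /= np.linalg.norm(direction)
        shift = o1p.position + direction * distance - donor.position
        for atom in sep.chains["A"][2].atoms:
            atom.position = atom.position + shift
        return sep

    def test_pair_inside_cutoff_reported(self):
        model = self._model_with_pair(3.4)
        pairs = {(d[1].name, a[1].name) for d, a, _ in detect_hbonds(model)}
        assert ("N", "O1P") in pairs

    def test_pair_outside_cutoff_not_reported(self):
        model = self._model_with_pair(3.6)
        found = [
            (dres.seqnum, aatom.name)
            for (dres, datom), (ares, aatom), dist in detect_hbonds(model)
            if dres.seqnum == 3 and aatom.name == "O1P"
        ]
        assert found == []

    def test_internal_phosphate_amide_contact(self):
        for name in ("TPO_internal", "SEP_internal"):
            model = gen_hbond_fixture(name)
            contacts = {
                (dres.seqnum, aatom.name)
                for (dres, datom), (ares, aatom), dist in detect_hbonds(model)
            }
            assert any(seq == 2 and acc.endswith("P") for seq, acc in contacts)

    def test_adjacent_residue_phosphate_contact(self):
        model = gen_hbond_fixture("SEP_adjacent")
        contacts = {
            (dres.seqnum, aatom.name)
            for (dres, datom), (ares, aatom), dist in detect_hbonds(model)
        }
        assert any(seq == 3 and acc.endswith("P") for seq, acc in contacts)


def _ca_model(positions):
    residues = [
        Residue("ALA", "A", i + 1, atoms=[Atom("CA", "C", p)])
        for i, p in enumerate(positions)
    ]
    return StructureModel(chains={"A": residues})


class TestContactMap:
    def test_pair_inside_and_outside_cutoff(self):
        near = _ca_model([(0, 0, 0), (7.9, 0, 0)])
        far = _ca_model([(0, 0, 0), (8.1, 0, 0)])
        assert contact_map([near])[0, 1] == 1.0
        assert contact_map([far])[0, 1] == 0.0

    def test_fraction_counts_conformers(self):
        ensemble = [_ca_model([(0, 0, 0), (5, 0, 0)]) for _ in range(3)]
        ensemble += [_ca_model([(0, 0, 0), (12, 0, 0)]) for _ in range(7)]
        m = contact_map(ensemble)
        assert m[0, 1] == pytest.approx(0.3)
        assert m[1, 0] == pytest.approx(0.3)
        assert np.all(np.diag(m) == 1.0)

    def test_monotone_in_cutoff(self, rng):
        ensemble = [_ca_model(rng.uniform(0, 15, size=(5, 3))) for _ in range(4)]
        m8 = contact_map(ensemble, cutoff=8.0)
        m10 = contact_map(ensemble, cutoff=10.0)
        assert np.all(m10 >= m8)

    def test_diff_identities(self):
        a = np.array([[1.0, 0.4], [0.4, 1.0]])
        assert np.all(contact_map_diff(a, a) == 0.0)
        b = np.zeros((2, 2))
        assert contact_map_diff(a, b)[0, 1] == pytest.approx(0.4)
        with pytest.raises(ValueError):
            contact_map_diff(a, np.zeros((3, 3)))

    def test_missing_ca_raises(self):
        model = _ca_model([(0, 0, 0), (5, 0, 0)])
        model.chains["A"][1].atoms = []
        with pytest.raises(ValueError, match="CA"):
            contact_map([model])
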