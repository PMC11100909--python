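"""Rotamer library assembly, serialization and sampling.

Two library flavors are built from torsion records of one PTM residue type:

* backbone-independent (BI): rotamer state probabilities and per-chi
  circular means/standard deviations marginal over the backbone;
* backbone-dependent (BD): the same quantities on a 12 x 12 grid of 30
  degree phi/psi bins.  Per-bin probabilities come from Bayes' rule with the
  BI probabilities as priors and per-state adaptive von Mises KDE densities
  evaluated at the bin center; chi means/stds come from Nadaraya-Watson
  circular regression at the bin center.  Bins with no observations within
  the kernel's effective reach are backfilled with the BI values and flagged.

The public estimation surface follows the model/results convention:
:class:`RotamerLibraryModel` is constructed from data and ``fit()`` returns
a :class:`BILibrary` or :class:`BDLibrary` results object carrying the
estimates, their dispersions, a ``summary()`` table and a ``sample()``
method.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .circular_stats import (
    AdaptiveKDEModel,
    adaptive_lambdas,
    circular_mean_std,
    kde_density,
    nw_regress_circular,
    rotamer_posterior,
    von_mises_density,
)
from .config import RunConfig
from .geometry import circular_distance, wrap_angle
from .rotamer_binning import ConformerScheme, assign_state, build_scheme, fold_symmetric
from .templates import CHI_COUNTS

BIN_SIZE = 30.0
N_BINS = 12

__all__ = [
    "RotamerEntry",
    "BILibrary",
    "BDLibrary",
    "RotamerLibraryModel",
    "bin_of",
    "bin_center",
    "build_bi",
    "build_bd",
    "write_library",
    "read_library",
    "sample_rotamer",
]


def bin_of(phi: float, psi: float):
    """(row, col) of the 30-degree phi/psi bin containing the point."""
    phi = float(wrap_angle(phi))
    psi = float(wrap_angle(psi))
    return int((phi + 180.0) // BIN_SIZE), int((psi + 180.0) // BIN_SIZE)


def bin_center(row: int, col: int):
    """Center (phi, psi) of a grid bin: -165, -135, ..., 165."""
    return (-180.0 + BIN_SIZE * row + BIN_SIZE / 2.0,
            -180.0 + BIN_SIZE * col + BIN_SIZE / 2.0)


@dataclass
class RotamerEntry:
    """One rotamer state: probability, chi circular means/stds, support count."""

    state: tuple  # wedge labels for the non-terminal chis
    probability: float
    chi_means: np.ndarray  # degrees, terminal chi folded into [-60, 60)
    chi_stds: np.ndarray  # degrees, floored
    count: int

    def __post_init__(self):
        self.chi_means = np.asarray(self.chi_means, dtype=float)
        self.chi_stds = np.asarray(self.chi_stds, dtype=float)

    def copy(self) -> "RotamerEntry":
        return RotamerEntry(self.state, self.probability,
                            self.chi_means.copy(), self.chi_stds.copy(), self.count)


class _LibraryBase:
    """Shared results-object behavior for BI and BD libraries."""

    def sample(self, phi: float | None = None, psi: float | None = None,
               size: int = 1, seed=None):
        """Draw chi vectors from the library; see :func:`sample_rotamer`."""
        rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
        out = [sample_rotamer(self, phi, psi, rng) for _ in range(size)]
        return out[0] if size == 1 else np.array(out)

    def save(self, path) -> None:
        Path(path).write_text(write_library(self))

    def to_dataframe(self):
        """Flat per-entry table (pandas)."""
        import pandas as pd

        rows = []
        if isinstance(self, BDLibrary):
            for (r, c), entries in sorted(self.grid.items()):
                phi, psi = bin_center(r, c)
                for e in entries:
                    rows.append(self._row(e, phi, psi, (r, c) in self.backfilled))
        else:
            for e in self.entries:
                rows.append(self._row(e, None, None, False))
        return pd.DataFrame(rows)

    def _row(self, e, phi, psi, backfilled):
        row = {"resname": self.resname, "phi": phi, "psi": psi,
               "state": ",".join(e.state), "count": e.count,
               "probability": e.probability, "backfilled": backfilled}
        for i, (m, s) in enumerate(zip(e.chi_means, e.chi_stds), start=1):
            row[f"chi{i}_mean"] = m
            row[f"chi{i}_std"] = s
        return row


@dataclass
class BILibrary(_LibraryBase):
    """Backbone-independent rotamer library (results object)."""

    resname: str
    entries: list
    n_records: int = 0
    config: RunConfig = field(default_factory=RunConfig)
    scheme: ConformerScheme | None = None

    @property
    def mode(self) -> str:
        return "BI"

    def probability_of(self, state) -> float:
        for e in self.entries:
            if e.state == tuple(state):
                return e.probability
        return 0.0

    def summary(self) -> str:
        buf = io.StringIO()
        n_chi = CHI_COUNTS[self.resname]
        buf.write(f"Backbone-independent rotamer library: {self.resname}\n")
        buf.write("=" * 72 + "\n")
        buf.write(f"No. observations: {self.n_records}    rotamer states: {len(self.entries)}\n")
        buf.write("-" * 72 + "\n")
        head = f"{'state':<14}{'prob':>8}{'count':>7}"
        head += "".join(f"{f'chi{i}':>16}" for i in range(1, n_chi + 1))
        buf.write(head + "\n")
        for e in sorted(self.entries, key=lambda e: -e.probability):
            line = f"{','.join(e.state):<14}{e.probability:>8.3f}{e.count:>7d}"
            for m, s in zip(e.chi_means, e.chi_stds):
                line += f"{f'{m:7.1f} ({s:4.1f})':>16}"
            buf.write(line + "\n")
        buf.write("=" * 72 + "\n")
        return buf.getvalue()


@dataclass
class BDLibrary(_LibraryBase):
    """Backbone-dependent rotamer library on a 12 x 12 phi/psi grid."""

    resname: str
    grid: dict  # (row, col) -> list[RotamerEntry]
    backfilled: set
    bi: BILibrary | None = None
    n_records: int = 0
    config: RunConfig = field(default_factory=RunConfig)
    scheme: ConformerScheme | None = None

    @property
    def mode(self) -> str:
        return "BD"

    def entries_at(self, phi: float, psi: float):
        return self.grid[bin_of(phi, psi)]

    def summary(self) -> str:
        buf = io.StringIO()
        buf.write(f"Backbone-dependent rotamer library: {self.resname}\n")
        buf.write("=" * 72 + "\n")
        buf.write(
            f"No. observations: {self.n_records}    grid: {N_BINS}x{N_BINS} bins of "
            f"{BIN_SIZE:.0f} deg\n"
        )
        buf.write(
            f"data-supported bins: {N_BINS * N_BINS - len(self.backfilled)}    "
            f"backfilled from BI: {len(self.backfilled)}\n"
        )
        if self.bi is not None:
            buf.write("-" * 72 + "\n")
            buf.write("Marginal (BI) states:\n")
            for e in sorted(self.bi.entries, key=lambda e: -e.probability):
                buf.write(f"  {','.join(e.state):<14}{e.probability:>8.3f}{e.count:>7d}\n")
        buf.write("=" * 72 + "\n")
        return buf.getvalue()


def _state_chi_stats(records_chis, scheme, config) -> tuple:
    """Circular mean/std per chi over one state's records (terminal folded)."""
    means, stds = [], []
    terminal = scheme.terminal_index
    for i in range(scheme.n_chi):
        values = records_chis[:, i]
        if i == terminal:
            m, s = circular_mean_std(fold_symmetric(values, 120.0), period=120.0,
                                     std_floor=config.std_floor_deg)
        else:
            m, s = circular_mean_std(values, std_floor=config.std_floor_deg)
        means.append(m)
        stds.append(s)
    return np.array(means), np.array(stds)


def _group_by_state(records, scheme):
    groups: dict = {}
    for rec in records:
        state = assign_state(rec.chis, scheme)
        groups.setdefault(state, []).append(rec)
    return groups


def build_bi(records, scheme: ConformerScheme,
             config: RunConfig | None = None) -> BILibrary:
    """Backbone-independent library: state count fractions and chi statistics."""
    if not records:
        raise ValueError("cannot build a library from zero records")
    config = config or RunConfig()
    n = len(records)
    entries = []
    for state, members in sorted(_group_by_state(records, scheme).items()):
        chis = np.array([m.chis for m in members])
        means, stds = _state_chi_stats(chis, scheme, config)
        entries.append(
            RotamerEntry(state=state, probability=len(members) / n,
                         chi_means=means, chi_stds=stds, count=len(members))
        )
    entries.sort(key=lambda e: (-e.probability, e.state))
    return BILibrary(resname=scheme.resname, entries=entries, n_records=n,
                     config=config, scheme=scheme)


def build_bd(records, scheme: ConformerScheme, bi: BILibrary | None = None,
             config: RunConfig | None = None) -> BDLibrary:
    """Backbone-dependent library via Bayes posteriors at 30-degree bin centers.

    For each bin center, state probabilities are the Bayes posterior of the
    BI priors under each state's adaptive-KDE phi/psi density; chi means and
    stds are Nadaraya-Watson regressions over that state's records.  Bins
    with no record within ``config.support_radius_deg`` of the center on
    both axes take the BI entries verbatim and are flagged as backfilled.
    """
    config = config or RunConfig()
    if bi is None:
        bi = build_bi(records, scheme, config)
    groups = _group_by_state(records, scheme)
    states = [e.state for e in bi.entries]
    priors = np.array([e.probability for e in bi.entries])
    bi_by_state = {e.state: e for e in bi.entries}

    all_points = np.array([[r.phi, r.psi] for r in records])
    centers = np.array([bin_center(r, c) for r in range(N_BINS) for c in range(N_BINS)])

    # Per-state KDE densities at every bin center.  Bandwidth factors come
    # from the POOLED backbone sample: the kernel width at a data point
    # reflects how densely the backbone torus is populated there overall, so
    # a state's stray observations inside another state's dense region keep
    # narrow kernels and cannot dominate distant bins through tail overlap.
    densities = np.zeros((len(states), centers.shape[0]))
    pooled_lambdas, g = adaptive_lambdas(all_points, kappa0=config.kappa0,
                                         alpha=config.alpha)
    rec_index = {id(r): i for i, r in enumerate(records)}
    state_points = {}
    state_chis = {}
    for si, state in enumerate(states):
        members = groups[state]
        pts = np.array([[m.phi, m.psi] for m in members])
        state_points[state] = pts
        state_chis[state] = np.array([m.chis for m in members])
        lambdas = pooled_lambdas[[rec_index[id(m)] for m in members]]
        model = AdaptiveKDEModel(points=pts, kappa0=config.kappa0,
                                 alpha=config.alpha, lambdas=lambdas,
                                 geometric_mean_pilot=g)
        densities[si] = np.atleast_1d(kde_density(model, centers))

    grid: dict = {}
    backfilled: set = set()
    for flat, (row, col) in enumerate(
        (r, c) for r in range(N_BINS) for c in range(N_BINS)
    ):
        phi_c, psi_c = centers[flat]
        supported = bool(
            np.any(
                (circular_distance(all_points[:, 0], phi_c) <= config.support_radius_deg)
                & (circular_distance(all_points[:, 1], psi_c) <= config.support_radius_deg)
            )
        )
        if not supported:
            grid[(row, col)] = [bi_by_state[s].copy() for s in states]
            backfilled.add((row, col))
            continue
        post = rotamer_posterior(priors, densities[:, flat])
        entries = []
        for si, state in enumerate(states):
            pts = state_points[state]
            chis = state_chis[state]
            in_bin = int(
                np.sum(
                    (np.floor((wrap_angle(pts[:, 0]) + 180.0) / BIN_SIZE) == row)
                    & (np.floor((wrap_angle(pts[:, 1]) + 180.0) / BIN_SIZE) == col)
                )
            )
            means, stds = [], []
            terminal = scheme.terminal_index
            for i in range(scheme.n_chi):
                values = chis[:, i]
                period = 360.0
                if i == terminal:
                    values = fold_symmetric(values, 120.0)
                    period = 120.0
                est = nw_regress_circular(
                    pts, values, (phi_c, psi_c), kappa_reg=config.kappa_reg,
                    std_floor=config.std_floor_deg, period=period,
                )
                means.append(est.circ_mean)
                stds.append(est.circ_std)
            entries.append(
                RotamerEntry(state=state, probability=float(post[si]),
                             chi_means=np.array(means), chi_stds=np.array(stds),
                             count=in_bin)
            )
        entries.sort(key=lambda e: (-e.probability, e.state))
        grid[(row, col)] = entries
    return BDLibrary(resname=scheme.resname, grid=grid, backfilled=backfilled,
                     bi=bi, n_records=len(records), config=config, scheme=scheme)


# ---------------------------------------------------------------------------
# serialization

_SENTINEL = "."


def _fmt(x: float) -> str:
    return f"{x:.12g}"


def write_library(lib) -> str:
    """Serialize a library to its text format.

    Header lines are ``#``-prefixed (resname, mode, counts, config); each row
    holds one (bin, state) pair: resname, bin-center phi/psi (``.`` for BI
    rows), comma-joined state labels, support count, probability, chi means,
    chi stds, backfilled flag.
    """
    n_chi = CHI_COUNTS[lib.resname]
    lines = [
        "# ptmrot rotamer library",
        f"# resname: {lib.resname}",
        f"# mode: {lib.mode}",
        f"# n_records: {lib.n_records}",
        f"# config: {lib.config.to_header()}",
        "# columns: resname phi psi state count probability "
        + " ".join(f"chi{i}_mean" for i in range(1, n_chi + 1))
        + " " + " ".join(f"chi{i}_std" for i in range(1, n_chi + 1))
        + " backfilled",
    ]

    def row(e, phi, psi, flag):
        fields = [lib.resname,
                  _SENTINEL if phi is None else _fmt(phi),
                  _SENTINEL if psi is None else _fmt(psi),
                  ",".join(e.state), str(e.count), _fmt(e.probability)]
        fields += [_fmt(m) for m in e.chi_means]
        fields += [_fmt(s) for s in e.chi_stds]
        fields.append("1" if flag else "0")
        return " ".join(fields)

    if isinstance(lib, BDLibrary):
        for (r, c) in sorted(lib.grid):
            phi, psi = bin_center(r, c)
            for e in lib.grid[(r, c)]:
                lines.append(row(e, phi, psi, (r, c) in lib.backfilled))
    else:
        for e in lib.entries:
            lines.append(row(e, None, None, False))
    return "\n".join(lines) + "\n"


class LibraryFormatError(ValueError):
    pass


def read_library(path_or_text):
    """Parse a library file; validates per-bin probability normalization."""
    if isinstance(path_or_text, (str, Path)) and "\n" not in str(path_or_text):
        text = Path(path_or_text).read_text()
    else:
        text = str(path_or_text)
    header: dict = {}
    rows = []
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                header[key.strip()] = val.strip()
            continue
        rows.append((lineno, line.split()))
    for key in ("resname", "mode"):
        if key not in header:
            raise LibraryFormatError(f"missing '{key}' header line")
    resname = header["resname"]
    mode = header["mode"]
    n_chi = CHI_COUNTS[resname]
    config = RunConfig.from_header(header["config"]) if "config" in header else RunConfig()
    n_records = int(header.get("n_records", 0))
    expected = 6 + 2 * n_chi + 1

    def parse_row(lineno, fields):
        if len(fields) != expected:
            raise LibraryFormatError(
                f"line {lineno}: expected {expected} fields, found {len(fields)}"
            )
        try:
            phi = None if fields[1] == _SENTINEL else float(fields[1])
            psi = None if fields[2] == _SENTINEL else float(fields[2])
            state = tuple(fields[3].split(","))
            count = int(fields[4])
            prob = float(fields[5])
            means = np.array([float(x) for x in fields[6:6 + n_chi]])
            stds = np.array([float(x) for x in fields[6 + n_chi:6 + 2 * n_chi]])
            flag = fields[-1] == "1"
        except ValueError as exc:
            raise LibraryFormatError(f"line {lineno}: {exc}") from exc
        return phi, psi, RotamerEntry(state, prob, means, stds, count), flag

    if mode == "BI":
        entries = [parse_row(ln, f)[2] for ln, f in rows]
        total = sum(e.probability for e in entries)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise LibraryFormatError(f"BI probabilities sum to {total}, not 1")
        return BILibrary(resname=resname, entries=entries, n_records=n_records,
                         config=config)
    grid: dict = {}
    backfilled: set = set()
    for ln, f in rows:
        phi, psi, entry, flag = parse_row(ln, f)
        if phi is None or psi is None:
            raise LibraryFormatError(f"line {ln}: BD row lacks bin center")
        key = bin_of(phi, psi)
        grid.setdefault(key, []).append(entry)
        if flag:
            backfilled.add(key)
    for key, entries in grid.items():
        total = sum(e.probability for e in entries)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise LibraryFormatError(
                f"bin {key}: probabilities sum to {total}, not 1"
            )
    return BDLibrary(resname=resname, grid=grid, backfilled=backfilled,
                     n_records=n_records, config=config)


# ---------------------------------------------------------------------------
# sampling


def _kappa_from_std(std_deg: float) -> float:
    """Small-angle concentration matching a circular std in degrees."""
    sigma = np.radians(max(std_deg, 1e-3))
    return 1.0 / sigma**2


def sample_rotamer(lib, phi=None, psi=None, rng=None) -> np.ndarray:
    """Draw one chi vector (degrees) from a library.

    A rotamer state is drawn from the (per-bin, for BD) probabilities; each
    chi is drawn from a von Mises centered on the state's mean with
    concentration matched to its standard deviation.  The terminal 3-fold
    rotor is drawn in its folded 120-degree domain and lifted by a uniformly
    random symmetry copy.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    if isinstance(lib, BDLibrary):
        if phi is None or psi is None:
            raise ValueError("BD sampling needs phi and psi")
        entries = lib.grid[bin_of(phi, psi)]
    else:
        entries = lib.entries
    probs = np.array([e.probability for e in entries])
    probs = probs / probs.sum()
    entry = entries[rng.choice(len(entries), p=probs)]
    terminal = None
    if lib.scheme is not None:
        terminal = lib.scheme.terminal_index
    else:
        from .templates import TERMINAL_CHI

        t = TERMINAL_CHI[lib.resname]
        terminal = None if t is None else t - 1
    chis = []
    for i, (mean, std) in enumerate(zip(entry.chi_means, entry.chi_stds)):
        if i == terminal:
            # sample on the folded circle (period 120 -> scale 3x)
            theta = rng.vonmises(np.radians(mean * 3.0), _kappa_from_std(std * 3.0))
            value = np.degrees(theta) / 3.0
            value += 120.0 * rng.integers(0, 3)
        else:
            theta = rng.vonmises(np.radians(mean), _kappa_from_std(std))
            value = np.degrees(theta)
        chis.append(float(wrap_angle(value)))
    return np.array(chis)


# ---------------------------------------------------------------------------
# model / results surface


class RotamerLibraryModel:
    """Rotamer-library estimator for one PTM residue type.

    Parameters
    ----------
    records : sequence of TorsionRecord
        Observed phi/psi/chi torsions, typically from
        :func:`ptmrot.structures_io.extract_torsions`.
    resname : str, optional
        Residue type; inferred when the records are homogeneous.
    scheme : ConformerScheme, optional
        Pre-built conformer scheme; by default it is fit from the records
        (including any DBSCAN wedge splitting).
    config : RunConfig, optional
        Estimation tunables.

    Examples
    --------
    >>> model = RotamerLibraryModel(records)       # doctest: +SKIP
    >>> bd = model.fit()                            # backbone-dependent
    >>> bi = model.fit(backbone_dependent=False)
    >>> print(bi.summary())                         # doctest: +SKIP
    """

    def __init__(self, records, resname: str | None = None,
                 scheme: ConformerScheme | None = None,
                 config: RunConfig | None = None):
        records = list(records)
        if not records:
            raise ValueError("no torsion records")
        if resname is None:
            names = {r.resname for r in records}
            if len(names) != 1:
                raise ValueError(
                    f"records mix residue types {sorted(names)}; pass resname="
                )
            resname = names.pop()
        self.records = [r for r in records if r.resname == resname]
        if not self.records:
            raise ValueError(f"no records for residue {resname}")
        self.resname = resname
        self.config = config or RunConfig()
        eff_min = max(self.config.dbscan_min_samples, len(self.records) // 50)
        self.scheme = scheme or build_scheme(
            resname, self.records, eps=self.config.dbscan_eps_deg,
            min_samples=eff_min,
        )

    @classmethod
    def from_dataframe(cls, df, resname: str | None = None, **kwargs):
        """Build from a table with columns phi, psi, chi1..chiK (and
        optionally resname, entry_id, chain, seqnum, resolution)."""
        from .structures_io import TorsionRecord

        records = []
        for _, row in df.iterrows():
            name = str(row.get("resname", resname))
            n_chi = CHI_COUNTS[name]
            chis = [float(row[f"chi{i}"]) for i in range(1, n_chi + 1)]
            records.append(
                TorsionRecord(
                    entry_id=str(row.get("entry_id", "")),
                    chain_id=str(row.get("chain", "")),
                    seqnum=int(row.get("seqnum", 0)),
                    resname=name,
                    phi=float(row["phi"]),
                    psi=float(row["psi"]),
                    chis=np.array(chis),
                    resolution=float(row["resolution"]) if "resolution" in row else None,
                )
            )
        return cls(records, resname=resname, **kwargs)

    def fit(self, backbone_dependent: bool = True):
        """Estimate the library; returns a results object."""
        bi = build_bi(self.records, self.scheme, self.config)
        if not backbone_dependent:
            return bi
        return build_bd(self.records, self.scheme, bi=bi, config=self.config)
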