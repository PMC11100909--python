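"""Side-chain repacking on fixed backbones and its statistical evaluation.

The repack protocol removes a PTM residue's side chain, redraws chi vectors
from a rotamer library at the residue's backbone phi/psi, rebuilds the side
chain in place, and rejects draws that clash with the (unchanged) rest of
the structure.  Accuracy against reference structures is summarized by
side-chain heavy-atom RMSD distributions (box statistics with 1.5 IQR
whiskers) and paired library-vs-library comparisons use the one-sided
Wilcoxon signed-rank test, exact by enumeration at small n.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from .geometry import compute_dihedral
from .library_build import sample_rotamer
from .structures_io import BACKBONE_ATOMS, Residue, StructureModel, build_sidechain, sidechain_rmsd

#: van der Waals radii (A) used by the clash criterion.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "P": 1.80, "S": 1.80}
_DEFAULT_RADIUS = 1.70


@dataclass
class RepackResult:
    residue_id: tuple  # (chain_id, seqnum)
    chis: np.ndarray
    residue: Residue
    clash_free: bool
    n_trials_used: int
    rmsd_to_reference: float | None = None


@dataclass
class PairedComparison:
    """Wilcoxon signed-rank comparison of paired RMSDs (A vs B)."""

    pairs: list
    statistic: float  # W: the smaller of the two signed-rank sums
    p_value: float  # one-sided, alternative: A < B
    n_used: int  # pairs after dropping zero differences
    degenerate: bool = False


def _backbone_phi_psi(model: StructureModel, res: Residue):
    residues = model.chains[res.chain_id]
    idx = residues.index(res)
    prev_res = residues[idx - 1] if idx > 0 else None
    next_res = residues[idx + 1] if idx + 1 < len(residues) else None
    phi = psi = None
    n, ca, c = (res.atom(x) for x in ("N", "CA", "C"))
    if n is None or ca is None or c is None:
        raise ValueError(f"missing backbone atom in {res.chain_id}:{res.seqnum}")
    if prev_res is not None and prev_res.atom("C") is not None:
        phi = compute_dihedral(prev_res.atom("C").position, n.position,
                               ca.position, c.position)
    if next_res is not None and next_res.atom("N") is not None:
        psi = compute_dihedral(n.position, ca.position, c.position,
                               next_res.atom("N").position)
    return phi, psi


def _count_clashes(candidate: Residue, env_positions, env_radii,
                   clash_factor: float) -> int:
    """Number of rebuilt side-chain atoms violating the vdW criterion."""
    if len(env_positions) == 0:
        return 0
    clashes = 0
    for atom in candidate.atoms:
        if atom.name in BACKBONE_ATOMS:
            continue
        r_self = VDW_RADII.get(atom.element, _DEFAULT_RADIUS)
        limit = clash_factor * (r_self + env_radii)
        d = np.linalg.norm(env_positions - atom.position, axis=1)
        clashes += int(np.sum(d < limit))
    return clashes


def repack_residue(model: StructureModel, site, lib, n_trials: int = 200,
                   clash_factor: float = 0.7, rng=None) -> RepackResult:
    """Resample one PTM side chain on the fixed backbone.

    Draws up to ``n_trials`` chi vectors from the library at the site's
    phi/psi; the first draw whose rebuilt side chain has no atom within
    ``clash_factor`` times the summed van der Waals radii of any atom
    outside the residue is accepted.  If none is clash-free the
    least-clashing draw is returned with ``clash_free=False``.
    """
    if rng is None or isinstance(rng, int):
        rng = np.random.default_rng(rng)
    chain_id, seqnum = site
    res = model.find_residue(chain_id, seqnum)
    if res is None:
        raise ValueError(f"no residue at {chain_id}:{seqnum}")
    phi, psi = _backbone_phi_psi(model, res)
    from .library_build import BDLibrary

    if isinstance(lib, BDLibrary) and (phi is None or psi is None):
        raise ValueError("BD repacking needs defined phi and psi at the site")

    env_positions = []
    env_radii = []
    for other in model.residues():
        if other is res:
            continue
        for atom in other.atoms:
            if atom.element == "H":
                continue
            env_positions.append(atom.position)
            env_radii.append(VDW_RADII.get(atom.element, _DEFAULT_RADIUS))
    env_positions = np.array(env_positions) if env_positions else np.empty((0, 3))
    env_radii = np.array(env_radii)

    best = None
    for trial in range(1, n_trials + 1):
        chis = sample_rotamer(lib, phi, psi, rng)
        candidate = build_sidechain(res, res.resname, chis)
        clashes = _count_clashes(candidate, env_positions, env_radii, clash_factor)
        if best is None or clashes < best[0]:
            best = (clashes, chis, candidate, trial)
        if clashes == 0:
            break
    clashes, chis, candidate, trial = best
    return RepackResult(
        residue_id=(chain_id, seqnum), chis=chis, residue=candidate,
        clash_free=(clashes == 0), n_trials_used=trial,
    )


def box_summary(values) -> dict:
    """Box-plot statistics: quartiles, 1.5 IQR whiskers and outliers."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return {"n": 0, "q1": None, "median": None, "q3": None,
                "whisker_low": None, "whisker_high": None, "outliers": []}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_limit, hi_limit = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inliers = values[(values >= lo_limit) & (values <= hi_limit)]
    return {
        "n": int(values.size),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_low": float(inliers.min()),
        "whisker_high": float(inliers.max()),
        "outliers": sorted(float(v) for v in values[(values < lo_limit) | (values > hi_limit)]),
    }


def evaluate_repacking(cases, lib, n_trials: int = 200, clash_factor: float = 0.7,
                       seed: int = 0):
    """Repack every case and measure side-chain RMSD to its reference.

    ``cases`` is a list of (model, site, reference residue).  Returns
    (rmsd list, box summary dict).
    """
    rng = np.random.default_rng(seed)
    rmsds = []
    for model, site, reference in cases:
        result = repack_residue(model, site, lib, n_trials=n_trials,
                                clash_factor=clash_factor, rng=rng)
        rmsds.append(sidechain_rmsd(result.residue, reference))
    return rmsds, box_summary(rmsds)


def wilcoxon_signed_rank(pairs, max_exact_n: int = 12) -> PairedComparison:
    """One-sided Wilcoxon signed-rank test for paired RMSDs.

    Differences d = A - B; zero differences are dropped.  W is the
    smaller of the positive- and negative-rank sums.  The one-sided p-value
    (alternative: A < B, i.e. negative differences dominate) is
    P(W+ <= observed) under the null — computed by full enumeration of all
    2^n sign assignments (tied ranks included) for n <= ``max_exact_n``,
    otherwise by normal approximation with tie correction and continuity
    correction.
    """
    pairs = [(float(a), float(b)) for a, b in pairs]
    d = np.array([a - b for a, b in pairs])
    nonzero = d[d != 0.0]
    n = nonzero.size
    if n == 0:
        return PairedComparison(pairs=pairs, statistic=0.0, p_value=1.0,
                                n_used=0, degenerate=True)
    ranks = rankdata(np.abs(nonzero))
    w_plus = float(ranks[nonzero > 0].sum())
    w_minus = float(ranks[nonzero < 0].sum())
    w = min(w_plus, w_minus)
    if n <= max_exact_n:
        count = 0
        for signs in itertools.product((0.0, 1.0), repeat=n):
            if float(np.dot(signs, ranks)) <= w_plus + 1e-9:
                count += 1
        p = count / 2.0**n
    else:
        mean = n * (n + 1) / 4.0
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = float(np.sum(tie_counts**3 - tie_counts)) / 48.0
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
        z = (w_plus + 0.5 - mean) / math.sqrt(var)
        p = float(norm.cdf(z))
    return PairedComparison(pairs=pairs, statistic=w, p_value=min(p, 1.0),
                            n_used=int(n), degenerate=False)
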