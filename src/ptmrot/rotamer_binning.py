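"""Conformer wedge schemes: discretizing chi angles into named rotamer states.

Each chi angle of each residue type is partitioned into named angular wedges
(conformers).  sp3-sp3 torsions use the classical trans/gauche wedges; the
acetyllysine chi5 (sp3-sp2 amide) and phosphotyrosine chi2 (phenyl ring,
2-fold symmetric) have their own printed ranges; the chi2 of phosphoserine/
phosphothreonine and chi3 of phosphotyrosine have non-standard distributions
and get data-driven wedges from DBSCAN clustering with a circular metric.
Terminal 3-fold rotors (phosphate, trimethylammonium) are folded onto a 120
degree period and excluded from the rotamer state tuple; their circular
statistics are kept per state.

All wedges are lower-inclusive half-open so every scheme tiles the circle
exactly: each angle belongs to exactly one wedge.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import DBSCAN

from .geometry import circular_distance, wrap_angle
from .templates import CHI_COUNTS, TERMINAL_CHI

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Wedge:
    """A named conformer: a union of half-open degree intervals on [-180, 180)."""

    label: str
    intervals: tuple  # of (lo, hi) with lo <= angle < hi

    def contains(self, angle: float) -> bool:
        a = float(wrap_angle(angle))
        return any(lo <= a < hi for lo, hi in self.intervals)

    def center(self) -> float:
        """Circular mean of interval midpoints weighted by width."""
        mids = []
        widths = []
        for lo, hi in self.intervals:
            mids.append((lo + hi) / 2.0)
            widths.append(hi - lo)
        theta = np.radians(np.asarray(mids))
        w = np.asarray(widths)
        return float(
            wrap_angle(
                np.degrees(
                    np.arctan2((w * np.sin(theta)).sum(), (w * np.cos(theta)).sum())
                )
            )
        )


# trans/gauche wedges for sp3-sp3 torsions (peaks near 180, +60, -60)
SP3_WEDGES = (
    Wedge("T", ((120.0, 180.0), (-180.0, -120.0))),
    Wedge("G+", ((0.0, 120.0),)),
    Wedge("G-", ((-120.0, 0.0),)),
)

# acetyllysine chi5 (sp3-sp2): printed ranges, overlaps resolved in favor of
# T so the wedges tile the circle
ALY_CHI5_WEDGES = (
    Wedge("G+", ((30.0, 90.0), (-135.0, -90.0))),
    Wedge("G-", ((-90.0, -30.0), (90.0, 135.0))),
    Wedge("T", ((-30.0, 30.0), (135.0, 180.0), (-180.0, -135.0))),
)

# phosphotyrosine ring chi2: 2-fold symmetric (phenyl ring)
PTR_CHI2_WEDGES = (
    Wedge("G", ((45.0, 135.0), (-135.0, -45.0))),
    Wedge("T", ((-45.0, 45.0), (135.0, 180.0), (-180.0, -135.0))),
)


def _classify(angle: float, wedges) -> str:
    a = float(wrap_angle(angle))
    for wedge in wedges:
        if wedge.contains(a):
            return wedge.label
    raise RuntimeError(f"angle {a} not covered by wedges {wedges}")  # pragma: no cover


def classify_sp3(angle: float) -> str:
    """T on [120,180) u [-180,-120); G+ on [0,120); G- on [-120,0)."""
    return _classify(angle, SP3_WEDGES)


def classify_aly_chi5(angle: float) -> str:
    return _classify(angle, ALY_CHI5_WEDGES)


def classify_ptr_chi2(angle: float) -> str:
    """Ring-symmetric gauche/trans; equal for angles 180 degrees apart."""
    return _classify(angle, PTR_CHI2_WEDGES)


def fold_symmetric(angle, period: float):
    """Canonical representative in [-period/2, period/2) under n-fold symmetry."""
    if 360.0 % period != 0:
        raise ValueError("period must divide 360")
    a = np.asarray(angle, dtype=float)
    folded = (a + period / 2.0) % period - period / 2.0
    return float(folded) if np.isscalar(angle) else folded


def dbscan_split(angles, eps: float = 20.0, min_samples: int = 5):
    """Density-based splitting of a 1-D circular torsion distribution.

    Clusters are found by DBSCAN under the circular metric
    min(|d|, 360 - |d|); they are ordered by descending population and
    labeled C1..Ck.  Noise points are assigned to the nearest cluster by
    circular distance to the cluster circular mean, so every observation
    contributes to the library.  Returns ``(clusters, noise)`` where
    ``clusters`` is a list of index arrays and ``noise`` the indices that
    were re-assigned.
    """
    angles = np.asarray(wrap_angle(np.asarray(angles, dtype=float)))
    n = angles.shape[0]
    dist = circular_distance(angles[:, None], angles[None, :])
    labels = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(dist).labels_
    cluster_ids = [c for c in sorted(set(labels)) if c != -1]
    if not cluster_ids:
        logger.info("DBSCAN found no cluster (n=%d); using a single full-circle wedge", n)
        return [np.arange(n)], np.array([], dtype=int)
    clusters = [np.flatnonzero(labels == c) for c in cluster_ids]
    clusters.sort(key=lambda idx: (-idx.size, float(np.min(idx))))
    noise = np.flatnonzero(labels == -1)
    if noise.size:
        from .circular_stats import circular_mean_std

        means = np.array([circular_mean_std(angles[idx])[0] for idx in clusters])
        assigned = [list(idx) for idx in clusters]
        for i in noise:
            j = int(np.argmin(circular_distance(angles[i], means)))
            assigned[j].append(int(i))
        clusters = [np.array(sorted(idx)) for idx in assigned]
        clusters.sort(key=lambda idx: (-idx.size, float(np.min(idx))))
    return clusters, noise


def wedges_from_clusters(angles, clusters) -> tuple:
    """Convert DBSCAN clusters into wedges that tile the circle.

    Wedge boundaries are the circular midpoints between adjacent cluster
    means; labels C1..Ck follow descending cluster population.
    """
    from .circular_stats import circular_mean_std

    angles = np.asarray(wrap_angle(np.asarray(angles, dtype=float)))
    if len(clusters) == 1:
        return (Wedge("C1", ((-180.0, 180.0),)),)
    means = [circular_mean_std(angles[idx])[0] for idx in clusters]
    order = np.argsort(means)  # position on the circle
    k = len(clusters)
    bounds = {}
    for pos in range(k):
        i = order[pos]
        j = order[(pos + 1) % k]
        lo, hi = means[i], means[j]
        gap = (hi - lo) % 360.0
        bounds[(i, j)] = wrap_angle(lo + gap / 2.0)
    wedges = []
    for pos in range(k):
        i = order[pos]
        prev = order[(pos - 1) % k]
        nxt = order[(pos + 1) % k]
        lo = float(bounds[(prev, i)])
        hi = float(bounds[(i, nxt)])
        if lo < hi:
            intervals = ((lo, hi),)
        else:  # wraps through +/-180
            intervals = ((lo, 180.0), (-180.0, hi))
        wedges.append((i, intervals))
    # label by population rank (clusters are already sorted by size)
    out = [None] * k
    for i, intervals in wedges:
        out[i] = Wedge(f"C{i + 1}", intervals)
    return tuple(out)


@dataclass
class ConformerScheme:
    """Per-residue wedge schemes and symmetry periods for every chi.

    ``wedges[i]`` is the wedge tuple for chi i+1 (None for the terminal
    symmetric rotor, which is not part of the rotamer state);
    ``symmetry_period[i]`` is 360, 180 (ring) or 120 (3-fold terminal).
    """

    resname: str
    wedges: list
    symmetry_period: list
    dbscan_provenance: dict = field(default_factory=dict)

    @property
    def n_chi(self) -> int:
        return len(self.wedges)

    @property
    def terminal_index(self):
        """0-based index of the terminal symmetric rotor, or None."""
        t = TERMINAL_CHI[self.resname]
        return None if t is None else t - 1

    def state_chi_indices(self):
        """0-based chi indices that participate in the rotamer state tuple."""
        return [i for i in range(self.n_chi) if i != self.terminal_index]

    def classify_chi(self, i: int, angle: float) -> str:
        wedges = self.wedges[i]
        if wedges is None:
            raise ValueError(f"chi{i + 1} of {self.resname} is a terminal rotor")
        # ring-symmetric wedge sets (period 180) already tile both half-circles
        return _classify(angle, wedges)

    def to_json(self) -> str:
        payload = {
            "resname": self.resname,
            "chis": [
                {
                    "symmetry_period": self.symmetry_period[i],
                    "wedges": None
                    if self.wedges[i] is None
                    else [
                        {"label": w.label, "intervals": [list(iv) for iv in w.intervals]}
                        for w in self.wedges[i]
                    ],
                }
                for i in range(self.n_chi)
            ],
            "dbscan": self.dbscan_provenance,
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "ConformerScheme":
        payload = json.loads(text)
        wedges = []
        periods = []
        for chi in payload["chis"]:
            periods.append(float(chi["symmetry_period"]))
            if chi["wedges"] is None:
                wedges.append(None)
            else:
                wedges.append(
                    tuple(
                        Wedge(w["label"], tuple(tuple(iv) for iv in w["intervals"]))
                        for w in chi["wedges"]
                    )
                )
        return cls(
            resname=payload["resname"],
            wedges=wedges,
            symmetry_period=periods,
            dbscan_provenance=payload.get("dbscan", {}),
        )


#: chi indices (1-based) that get data-driven DBSCAN wedges, per residue.
DBSCAN_CHIS = {"SEP": (2,), "TPO": (2,), "PTR": (3,), "M3L": (), "ALY": ()}


def build_scheme(resname: str, records=None, eps: float = 20.0,
                 min_samples: int = 5) -> ConformerScheme:
    """Assemble the conformer scheme for a residue type.

    Fixed wedges (sp3, ALY chi5, PTR chi2) are filled immediately; chi
    angles flagged for density-based splitting need ``records`` (torsion
    records for this residue) to fit their DBSCAN wedges.  The effective
    DBSCAN ``min_samples`` is max(min_samples, n // 50).
    """
    n_chi = CHI_COUNTS[resname]
    terminal = TERMINAL_CHI[resname]
    wedges: list = []
    periods: list = []
    provenance: dict = {}
    for k in range(1, n_chi + 1):
        if k == terminal:
            wedges.append(None)
            periods.append(120.0)
        elif resname == "PTR" and k == 2:
            wedges.append(PTR_CHI2_WEDGES)
            periods.append(180.0)
        elif resname == "ALY" and k == 5:
            wedges.append(ALY_CHI5_WEDGES)
            periods.append(360.0)
        elif k in DBSCAN_CHIS[resname]:
            if records is None:
                raise ValueError(
                    f"chi{k} of {resname} needs torsion records to fit DBSCAN wedges"
                )
            angles = np.array([r.chis[k - 1] for r in records])
            eff_min = max(min_samples, angles.shape[0] // 50)
            clusters, _ = dbscan_split(angles, eps=eps, min_samples=eff_min)
            wedges.append(wedges_from_clusters(angles, clusters))
            periods.append(360.0)
            provenance[f"chi{k}"] = {
                "eps": eps,
                "min_samples": eff_min,
                "n": int(angles.shape[0]),
                "k": len(clusters),
            }
        else:
            wedges.append(SP3_WEDGES)
            periods.append(360.0)
    return ConformerScheme(
        resname=resname,
        wedges=wedges,
        symmetry_period=periods,
        dbscan_provenance=provenance,
    )


def assign_state(chis, scheme: ConformerScheme) -> tuple:
    """Rotamer state tuple: one wedge label per non-terminal chi.

    The terminal symmetric rotor keeps its statistics but does not index
    rotamer states.
    """
    chis = np.asarray(chis, dtype=float)
    if chis.shape[0] != scheme.n_chi:
        raise ValueError(
            f"{scheme.resname} takes {scheme.n_chi} chi angles, got {chis.shape[0]}"
        )
    return tuple(scheme.classify_chi(i, chis[i]) for i in scheme.state_chi_indices())
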