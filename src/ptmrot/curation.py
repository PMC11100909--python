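"""Dataset curation: the rules that turn raw structure entries into the set
a library is built from.

Resolution filtering (3.5 A cutoff by default), sequence-redundancy
clustering at 90% identity with single linkage, best-resolution
representative selection, exclusion of entries with incomplete PTM sites,
and the minimum-count gate (40 contributing entries per residue type).

Sequence identity is the global-alignment identity fraction
(match = 1, mismatch = 0, gap open -10, gap extend -0.5), computed with
Biopython's pairwise aligner.  Entries may carry several chains; two entries
are linked when any chain pair reaches the threshold.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

from Bio import Align

logger = logging.getLogger(__name__)


@dataclass
class DatasetEntry:
    """One candidate structure entry."""

    entry_id: str
    sequences: dict  # chain_id -> one-letter sequence (PTMs mapped to parent)
    resolution: float | None
    ptm_sites: list = field(default_factory=list)  # (chain, seqnum, resname)
    complete: bool = True


@dataclass
class ClusterAssignment:
    cluster_id: int
    members: list  # entry_ids
    representative: str


def filter_resolution(entries, cutoff: float = 3.5):
    """Keep entries with resolution at or below the cutoff (A).

    Entries without a resolution (e.g. NMR) are dropped and logged.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    kept = []
    for e in entries:
        if e.resolution is None:
            logger.info("%s: no resolution; dropped", e.entry_id)
        elif e.resolution <= cutoff:
            kept.append(e)
    return kept


@lru_cache(maxsize=1)
def _aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = 0.0
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def pairwise_identity(seq_a: str, seq_b: str) -> float:
    """Global-alignment identity fraction: matches / alignment length."""
    if not seq_a or not seq_b:
        raise ValueError("empty sequence")
    if seq_a == seq_b:
        return 1.0
    alignment = _aligner().align(seq_a, seq_b)[0]
    counts = alignment.counts()
    return counts.identities / alignment.length


def cluster_sequences(entries, threshold: float = 0.90):
    """Single-linkage clustering of entries by sequence identity.

    Two entries are linked when any chain pair reaches the identity
    threshold; clusters are the connected components.  The representative is
    the member with the best (lowest A) resolution, ties broken by
    lexicographic entry id.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    entries = list(entries)
    n = len(entries)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        for j in range(i + 1, n):
            linked = False
            for sa in entries[i].sequences.values():
                for sb in entries[j].sequences.values():
                    if pairwise_identity(sa, sb) >= threshold:
                        linked = True
                        break
                if linked:
                    break
            if linked:
                union(i, j)
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(i)
    clusters = []
    for cid, idxs in enumerate(sorted(groups.values(), key=lambda g: entries[g[0]].entry_id)):
        members = [entries[i] for i in idxs]
        rep = min(
            members,
            key=lambda e: (e.resolution if e.resolution is not None else float("inf"),
                           e.entry_id),
        )
        clusters.append(
            ClusterAssignment(
                cluster_id=cid,
                members=sorted(e.entry_id for e in members),
                representative=rep.entry_id,
            )
        )
    return clusters


def select_representatives(clusters, entries):
    """One entry per cluster: its best-resolution representative."""
    by_id = {e.entry_id: e for e in entries}
    reps = []
    for cluster in clusters:
        if cluster.representative not in cluster.members:
            raise ValueError(
                f"cluster {cluster.cluster_id}: representative not a member"
            )
        reps.append(by_id[cluster.representative])
    return reps


def exclude_incomplete(entries):
    """Drop entries whose every PTM site lacks chi-defining atoms.

    The ``complete`` flag is set upstream (an entry counts as complete when
    at least one PTM site has all chi-defining atoms present).
    """
    kept = []
    for e in entries:
        if e.complete:
            kept.append(e)
        else:
            logger.info("%s: incomplete structural data; excluded", e.entry_id)
    return kept


def gate_min_count(counts_by_resname: dict, minimum: int = 40) -> set:
    """Residue types with at least ``minimum`` contributing PDB entries.

    ``counts_by_resname`` maps resname to either an integer count or a
    collection of contributing entry ids.
    """
    if minimum < 1:
        raise ValueError("minimum must be >= 1")
    eligible = set()
    for resname, value in counts_by_resname.items():
        count = value if isinstance(value, int) else len(set(value))
        if count >= minimum:
            eligible.add(resname)
    return eligible


def curate(entries, identity_threshold: float = 0.90, max_resolution: float = 3.5,
           min_count: int = 40):
    """Full curation chain; returns (kept entries, eligible resnames).

    Order: resolution filter, completeness exclusion, redundancy clustering,
    representative selection, then the per-residue-type minimum-count gate
    over the representatives' PTM sites.
    """
    entries = filter_resolution(entries, cutoff=max_resolution)
    entries = exclude_incomplete(entries)
    clusters = cluster_sequences(entries, threshold=identity_threshold)
    reps = select_representatives(clusters, entries)
    contributing: dict = {}
    for e in reps:
        for _, _, resname in e.ptm_sites:
            contributing.setdefault(resname, set()).add(e.entry_id)
    eligible = gate_min_count(contributing, minimum=min_count)
    return reps, eligible
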