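"""Synthetic test-data generators.

Everything the test suite consumes is generated here: torsion datasets drawn
from known von Mises mixtures (optionally with backbone-region-dependent
state weights), toy tripeptide PDB files with prescribed phi/psi/chi,
redundant sequence sets with controlled pairwise identity, and paired RMSD
samples.  All generators are bit-reproducible given a seed.

The default mixture specs mirror the qualitative structure reported for the
real curated data — a dominant -60/120 chi1/chi2 state for phosphothreonine,
a mixed chi2 population spanning 60 to -120 degrees for phosphoserine (with
the -180/60 state whose phosphate accepts a hydrogen bond from the next
residue's amide), and broad 3-fold terminal rotors — so that desk-scale
tests exercise the same code paths as real data: DBSCAN wedge splitting,
ring symmetry, and terminal folding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import place_atom, wrap_angle
from .structures_io import Atom, Residue, StructureModel, TorsionRecord, build_sidechain, write_pdb
from .templates import CHI_COUNTS, TERMINAL_CHI, get_template

# Engh-Huber-style ideal backbone geometry
_BB = {
    "N_CA": 1.458, "CA_C": 1.525, "C_N": 1.329, "C_O": 1.231,
    "N_CA_C": 111.2, "CA_C_N": 116.2, "C_N_CA": 121.7, "CA_C_O": 120.8,
    "OMEGA": 180.0,
}


@dataclass
class StateSpec:
    """One mixture component: a rotamer state's weight and per-chi law."""

    weight: float
    chi_means: tuple
    chi_kappas: tuple


@dataclass
class RegionSpec:
    """A backbone region: phi/psi center, spread, and its state weights."""

    name: str
    phi: float
    psi: float
    kappa: float
    weight: float
    state_weights: tuple | None = None  # None -> use global weights


@dataclass
class MixtureSpec:
    """Generating model for synthetic torsion datasets."""

    resname: str
    states: list
    regions: list = field(default_factory=list)
    terminal_kappa: float = 8.0

    def __post_init__(self):
        total = sum(s.weight for s in self.states)
        if not np.isclose(total, 1.0):
            raise ValueError(f"state weights sum to {total}, not 1")
        for s in self.states:
            if any(k <= 0 for k in s.chi_kappas):
                raise ValueError("concentrations must be positive")
        if self.regions:
            rt = sum(r.weight for r in self.regions)
            if not np.isclose(rt, 1.0):
                raise ValueError(f"region weights sum to {rt}, not 1")


def _regions_uniform():
    return [
        RegionSpec("helix", -65.0, -40.0, 40.0, 0.4),
        RegionSpec("sheet", -120.0, 135.0, 40.0, 0.35),
        RegionSpec("ppII", -65.0, 145.0, 40.0, 0.25),
    ]


def default_spec(resname: str, backbone_dependent: bool = False) -> MixtureSpec:
    """Reference mixture spec per residue type.

    With ``backbone_dependent=True`` the state weights differ per backbone
    region (the structure a BD library is supposed to recover); otherwise
    regions only shape the phi/psi distribution.
    """
    if resname == "SEP":
        states = [
            StateSpec(0.40, (-63.0, 118.0, 20.0), (20.0, 20.0, 8.0)),
            StateSpec(0.35, (-178.0, 62.0, 20.0), (20.0, 20.0, 8.0)),
            StateSpec(0.25, (-60.0, -120.0, 20.0), (20.0, 20.0, 8.0)),
        ]
        bd = [(0.70, 0.15, 0.15), (0.10, 0.75, 0.15), (0.30, 0.30, 0.40)]
    elif resname == "TPO":
        states = [
            StateSpec(0.70, (-60.0, 120.0, 20.0), (20.0, 20.0, 8.0)),
            StateSpec(0.30, (-65.0, -118.0, 20.0), (20.0, 20.0, 8.0)),
        ]
        bd = [(0.85, 0.15), (0.35, 0.65), (0.60, 0.40)]
    elif resname == "PTR":
        states = [
            StateSpec(0.45, (-65.0, 90.0, -40.0, 20.0), (20.0, 30.0, 20.0, 8.0)),
            StateSpec(0.35, (178.0, 85.0, 60.0, 20.0), (20.0, 30.0, 20.0, 8.0)),
            StateSpec(0.20, (62.0, 0.0, -40.0, 20.0), (20.0, 30.0, 20.0, 8.0)),
        ]
        bd = [(0.70, 0.15, 0.15), (0.15, 0.70, 0.15), (0.25, 0.35, 0.40)]
    elif resname == "M3L":
        states = [
            StateSpec(0.50, (-60.0, 180.0, 180.0, 180.0, 30.0),
                      (20.0, 20.0, 20.0, 20.0, 8.0)),
            StateSpec(0.30, (-175.0, 178.0, 175.0, 180.0, 30.0),
                      (20.0, 20.0, 20.0, 20.0, 8.0)),
            StateSpec(0.20, (-60.0, -65.0, 178.0, 180.0, 30.0),
                      (20.0, 20.0, 20.0, 20.0, 8.0)),
        ]
        bd = [(0.70, 0.20, 0.10), (0.15, 0.65, 0.20), (0.30, 0.25, 0.45)]
    elif resname == "ALY":
        states = [
            StateSpec(0.45, (-60.0, 180.0, 180.0, 178.0, 60.0),
                      (20.0, 20.0, 20.0, 20.0, 25.0)),
            StateSpec(0.35, (-178.0, 178.0, 180.0, 180.0, 0.0),
                      (20.0, 20.0, 20.0, 20.0, 25.0)),
            StateSpec(0.20, (-60.0, -60.0, 180.0, 180.0, -60.0),
                      (20.0, 20.0, 20.0, 20.0, 25.0)),
        ]
        bd = [(0.70, 0.20, 0.10), (0.10, 0.70, 0.20), (0.30, 0.30, 0.40)]
    else:
        raise ValueError(f"no default spec for residue {resname!r}")
    regions = _regions_uniform()
    if backbone_dependent:
        for region, weights in zip(regions, bd):
            region.state_weights = weights
    return MixtureSpec(resname=resname, states=states, regions=regions)


def _sample_vm(rng, mean_deg, kappa):
    return float(wrap_angle(np.degrees(rng.vonmises(np.radians(mean_deg), kappa))))


def gen_torsion_dataset(spec: MixtureSpec, n: int, seed: int) -> list:
    """Draw ``n`` torsion records from a mixture spec, reproducibly.

    Backbone phi/psi come from the spec's region mixture; the rotamer state
    is drawn from the region's state weights (or the global weights); each
    chi from its von Mises; the terminal 3-fold rotor is drawn in the folded
    domain and lifted to a uniformly random symmetry image, as raw
    crystallographic torsions would appear.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    terminal = TERMINAL_CHI[spec.resname]
    global_weights = np.array([s.weight for s in spec.states])
    regions = spec.regions or _regions_uniform()
    region_weights = np.array([r.weight for r in regions])
    records = []
    for i in range(n):
        region = regions[rng.choice(len(regions), p=region_weights)]
        phi = _sample_vm(rng, region.phi, region.kappa)
        psi = _sample_vm(rng, region.psi, region.kappa)
        weights = (np.array(region.state_weights)
                   if region.state_weights is not None else global_weights)
        state = spec.states[rng.choice(len(spec.states), p=weights)]
        chis = []
        for k, (mean, kappa) in enumerate(zip(state.chi_means, state.chi_kappas), start=1):
            value = _sample_vm(rng, mean, kappa)
            if k == terminal:
                # fold to [-60, 60) then place on a random symmetry image
                value = (value + 60.0) % 120.0 - 60.0 + 120.0 * rng.integers(0, 3)
            chis.append(float(wrap_angle(value)))
        records.append(
            TorsionRecord(
                entry_id=f"SYN{i:05d}", chain_id="A", seqnum=i + 1,
                resname=spec.resname, phi=phi, psi=psi,
                chis=np.array(chis), resolution=1.5,
            )
        )
    return records


def _build_backbone(phi: float, psi: float):
    """Ideal ALA-X-ALA tripeptide backbone with the central phi/psi."""
    g = _BB
    n1 = np.array([0.0, 0.0, 0.0])
    ca1 = np.array([g["N_CA"], 0.0, 0.0])
    theta = np.radians(g["N_CA_C"])
    c1 = ca1 + g["CA_C"] * np.array([-np.cos(theta), np.sin(theta), 0.0])
    psi1 = 150.0  # arbitrary: residue 1 has no phi
    n2 = place_atom(n1, ca1, c1, g["C_N"], g["CA_C_N"], psi1)
    o1 = place_atom(n1, ca1, c1, g["C_O"], g["CA_C_O"], psi1 + 180.0)
    ca2 = place_atom(ca1, c1, n2, g["N_CA"], g["C_N_CA"], g["OMEGA"])
    c2 = place_atom(c1, n2, ca2, g["CA_C"], g["N_CA_C"], phi)
    n3 = place_atom(n2, ca2, c2, g["C_N"], g["CA_C_N"], psi)
    o2 = place_atom(n2, ca2, c2, g["C_O"], g["CA_C_O"], psi + 180.0)
    ca3 = place_atom(ca2, c2, n3, g["N_CA"], g["C_N_CA"], g["OMEGA"])
    c3 = place_atom(c2, n3, ca3, g["CA_C"], g["N_CA_C"], -70.0)
    o3 = place_atom(n3, ca3, c3, g["C_O"], g["CA_C_O"], 60.0)
    return {
        1: {"N": n1, "CA": ca1, "C": c1, "O": o1},
        2: {"N": n2, "CA": ca2, "C": c2, "O": o2},
        3: {"N": n3, "CA": ca3, "C": c3, "O": o3},
    }


def gen_toy_model(resname: str, phi: float, psi: float, chis,
                  environment=None, entry_id: str = "TOY",
                  resolution: float = 1.5) -> StructureModel:
    """In-memory ALA-X-ALA tripeptide whose center reproduces the torsions."""
    template = get_template(resname)
    chis = np.asarray(chis, dtype=float)
    if chis.shape[0] != CHI_COUNTS[resname]:
        raise ValueError(
            f"{resname} takes {CHI_COUNTS[resname]} chi angles, got {chis.shape[0]}"
        )
    backbone = _build_backbone(phi, psi)
    residues = []
    for seq, resn in ((1, "ALA"), (2, resname), (3, "ALA")):
        res = Residue(resname=resn, chain_id="A", seqnum=seq)
        for name, pos in backbone[seq].items():
            res.atoms.append(Atom(name, name[0], pos))
        if resn == "ALA":
            cb = place_atom(backbone[seq]["C"], backbone[seq]["N"],
                            backbone[seq]["CA"], 1.53, 109.5, 120.0)
            res.atoms.append(Atom("CB", "C", cb))
            residues.append(res)
        else:
            built = build_sidechain(res, resname, chis, template)
            residues.append(built)
    model = StructureModel(entry_id=entry_id, resolution=resolution,
                           chains={"A": residues})
    if environment:
        env = Residue(resname="LIG", chain_id="Z", seqnum=1)
        for j, item in enumerate(environment, start=1):
            name, element, pos = item
            env.atoms.append(Atom(name, element, np.asarray(pos, float)))
        model.chains["Z"] = [env]
    return model


def gen_toy_pdb(resname: str, phi: float, psi: float, chis,
                environment=None, entry_id: str = "TOY",
                resolution: float = 1.5) -> str:
    """PDB text for an ideal tripeptide with prescribed central torsions."""
    return write_pdb(
        gen_toy_model(resname, phi, psi, chis, environment=environment,
                      entry_id=entry_id, resolution=resolution)
    )


def two_region_spec(resname: str = "SEP") -> MixtureSpec:
    """Strongly backbone-coupled fixture: two well-separated backbone
    regions with contrasting rotamer preferences (first state dominant in
    the helix region, second in the sheet region).  This is the reference
    input for checking that a backbone-dependent library ranks the locally
    dominant rotamer first."""
    base = default_spec(resname)
    k = len(base.states)
    w_a = tuple(0.8 if i == 0 else 0.2 / (k - 1) for i in range(k))
    w_b = tuple(0.8 if i == 1 else 0.2 / (k - 1) for i in range(k))
    regions = [
        RegionSpec("helix", -65.0, -40.0, 40.0, 0.5, w_a),
        RegionSpec("sheet", -120.0, 135.0, 40.0, 0.5, w_b),
    ]
    return MixtureSpec(resname=resname, states=base.states, regions=regions)


def region_dominant_state(spec: MixtureSpec, phi: float, psi: float) -> int:
    """Index of the generating mixture's dominant state at a backbone point
    (the large-sample truth a backbone-dependent library should recover)."""
    from .circular_stats import von_mises_density

    posts = []
    for region in spec.regions:
        w = region.weight
        w *= von_mises_density(phi, region.phi, region.kappa)
        w *= von_mises_density(psi, region.psi, region.kappa)
        posts.append(w)
    posts = np.asarray(posts)
    posts = posts / posts.sum()
    weights = np.zeros(len(spec.states))
    for region, p in zip(spec.regions, posts):
        rw = (np.array(region.state_weights) if region.state_weights is not None
              else np.array([s.weight for s in spec.states]))
        weights += p * rw
    return int(np.argmax(weights))


# Named hydrogen-bond fixtures.  The -60/120 chi1/chi2 well of the
# phosphorylated residues places a phosphate oxygen within donor-acceptor
# range of the residue's own amide nitrogen (the internal P-O/N-H bond);
# the trans/gauche chi1/chi2 well around -180/60-90 places one within range
# of the NEXT residue's amide.  Exact angles chosen so the idealized
# tripeptide geometry keeps every non-bonded pair at physical distances
# (in strict ideal geometry the literature configuration at exactly
# -180/60 presses the phosphate against the backbone; deposited structures
# relieve this with small angle distortions, which the fixture emulates by
# sitting 30 degrees away within the same rotamer well).
HBOND_FIXTURES = {
    "TPO_internal": {"resname": "TPO", "phi": -60.0, "psi": -45.0,
                     "chis": (-60.0, 120.0, -45.0)},
    "SEP_internal": {"resname": "SEP", "phi": -60.0, "psi": -45.0,
                     "chis": (-60.0, 120.0, -45.0)},
    "SEP_adjacent": {"resname": "SEP", "phi": -75.0, "psi": -145.0,
                     "chis": (-180.0, 90.0, -10.0)},
}


def gen_hbond_fixture(name: str) -> StructureModel:
    """One of the named hydrogen-bond fixture tripeptides."""
    spec = HBOND_FIXTURES[name]
    return gen_toy_model(spec["resname"], spec["phi"], spec["psi"], spec["chis"],
                         entry_id=name)


_AA = "ACDEFGHIKLMNPQRSTVWY"


def gen_redundant_entries(n_clusters: int, members_per_cluster: int,
                          identity_within: float, seed: int,
                          seq_length: int = 100) -> list:
    """Dataset entries whose within-cluster pairwise identity is exact.

    All members of a cluster mutate the same ``round((1 - identity) * L)``
    positions of a cluster-specific base sequence, each member to a
    member-specific letter, so every within-cluster pair differs at exactly
    those positions (no gaps) and pairwise identity hits the target exactly.
    Base sequences of different clusters are independent random strings,
    far below any clustering threshold.
    """
    from .curation import DatasetEntry

    rng = np.random.default_rng(seed)
    n_mut = int(round((1.0 - identity_within) * seq_length))
    entries = []
    for c in range(n_clusters):
        base = "".join(rng.choice(list(_AA), size=seq_length))
        positions = rng.choice(seq_length, size=n_mut, replace=False) if n_mut else []
        for m in range(members_per_cluster):
            seq = list(base)
            if m > 0:
                for p in positions:
                    choices = [a for a in _AA if a != base[p]]
                    seq[p] = choices[(m - 1) % len(choices)]
            entries.append(
                DatasetEntry(
                    entry_id=f"C{c:02d}M{m:02d}",
                    sequences={"A": "".join(seq)},
                    resolution=float(np.round(1.0 + 0.1 * m + 0.01 * c, 3)),
                    ptm_sites=[("A", 10, "SEP")],
                    complete=True,
                )
            )
    return entries


def gen_paired_rmsd_samples(n: int, shift: float, noise: float, seed: int):
    """Paired positive samples (method A, method B) with B = A + shift + noise."""
    rng = np.random.default_rng(seed)
    a = np.abs(rng.normal(1.0, 0.4, size=n))
    b = np.abs(a + shift + rng.normal(0.0, noise, size=n))
    return list(zip(a.tolist(), b.tolist()))
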