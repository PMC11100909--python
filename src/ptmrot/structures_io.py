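"""Structure I/O and geometric observables.

Reads and writes PDB-format coordinate files (via gemmi), extracts backbone
phi/psi and side-chain chi torsions for post-translationally modified
residues, rebuilds side chains from chi values by sequential
internal-coordinate (natural extension) construction, and computes the
geometric observables used downstream: side-chain RMSD, donor-acceptor
hydrogen-bond contacts, and fractional C-alpha contact maps.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import gemmi
import numpy as np

from .geometry import compute_dihedral, place_atom, wrap_angle
from .templates import CHI_COUNTS, PTM_RESNAMES, SidechainTemplate, get_template

logger = logging.getLogger(__name__)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

#: Hydrogen-bond donor/acceptor roles (heavy atoms only; deposited PTM
#: structures rarely carry hydrogens, so the criterion is distance-only).
HBOND_DONORS = ("N",)
HBOND_ACCEPTORS = ("O1P", "O2P", "O3P", "OG", "OG1", "OH")


class PDBParseError(ValueError):
    """Raised on malformed PDB input, naming the offending line."""


@dataclass
class Atom:
    name: str
    element: str
    position: np.ndarray
    altloc: str = ""
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.position = np.asarray(self.position, dtype=float)


@dataclass
class Residue:
    resname: str
    chain_id: str
    seqnum: int
    icode: str = ""
    atoms: list = field(default_factory=list)

    def atom(self, name: str):
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_atoms(self, names) -> bool:
        present = {a.name for a in self.atoms}
        return all(n in present for n in names)

    @property
    def key(self):
        return (self.chain_id, self.seqnum, self.icode)


@dataclass
class StructureModel:
    entry_id: str = ""
    resolution: float | None = None
    chains: dict = field(default_factory=dict)  # chain_id -> list[Residue]

    def residues(self):
        for chain in self.chains.values():
            yield from chain

    def find_residue(self, chain_id: str, seqnum: int):
        for res in self.chains.get(chain_id, []):
            if res.seqnum == seqnum:
                return res
        return None

    def all_atoms(self):
        for res in self.residues():
            for a in res.atoms:
                yield res, a


@dataclass
class TorsionRecord:
    """One observed PTM residue: identifiers, backbone and side-chain torsions."""

    entry_id: str
    chain_id: str
    seqnum: int
    resname: str
    phi: float
    psi: float
    chis: np.ndarray
    resolution: float | None = None

    def __post_init__(self):
        self.phi = float(wrap_angle(self.phi))
        self.psi = float(wrap_angle(self.psi))
        self.chis = np.asarray(wrap_angle(np.asarray(self.chis, dtype=float)))


def _validate_coordinate_lines(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(("ATOM  ", "HETATM")) and len(line) >= 54:
            for lo, hi in ((30, 38), (38, 46), (46, 54)):
                fieldtxt = line[lo:hi].strip()
                try:
                    float(fieldtxt)
                except ValueError:
                    raise PDBParseError(
                        f"malformed coordinate field {fieldtxt!r} on line {lineno}"
                    ) from None


def parse_pdb(text: str, entry_id: str = "") -> StructureModel:
    """Parse PDB-format text into a :class:`StructureModel` (first model only).

    Alternate locations are resolved to the highest-occupancy copy (ties go
    to the first occurrence in the file); resolution is taken from REMARK 2
    when present.
    """
    if not text.strip():
        raise PDBParseError("empty PDB input")
    _validate_coordinate_lines(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBParseError(str(exc)) from exc
    if len(st) == 0:
        raise PDBParseError("PDB input contains no coordinate model")
    model = StructureModel(
        entry_id=entry_id or st.name.strip(),
        resolution=float(st.resolution) if st.resolution > 0 else None,
    )
    gmodel = st[0]
    for gchain in gmodel:
        residues = []
        for gres in gchain:
            res = Residue(
                resname=gres.name,
                chain_id=gchain.name,
                seqnum=gres.seqid.num,
                icode=(gres.seqid.icode or "").strip(),
            )
            # altloc resolution: highest occupancy wins, ties -> first in file
            best: dict[str, Atom] = {}
            for ga in gres:
                atom = Atom(
                    name=ga.name,
                    element=ga.element.name,
                    position=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                    altloc=(ga.altloc or "").strip("\x00"),
                    occupancy=float(ga.occ),
                    b_factor=float(ga.b_iso),
                )
                prev = best.get(ga.name)
                if prev is None or atom.occupancy > prev.occupancy:
                    best[ga.name] = atom
            res.atoms = list(best.values())
            residues.append(res)
        residues.sort(key=lambda r: (r.seqnum, r.icode))
        model.chains[gchain.name] = residues
    return model


def write_pdb(model: StructureModel) -> str:
    """Serialize a :class:`StructureModel` to PDB-format text."""
    st = gemmi.Structure()
    st.name = model.entry_id or "XXXX"
    if model.resolution is not None:
        st.resolution = model.resolution
    gmodel = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gchain = gemmi.Chain(chain_id)
        for res in residues:
            gres = gemmi.Residue()
            gres.name = res.resname
            gres.seqid = gemmi.SeqId(res.seqnum, res.icode or " ")
            gres.het_flag = "H" if res.resname in PTM_RESNAMES else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.position)
                ga.occ = a.occupancy
                ga.b_iso = a.b_factor
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    header = ""
    if model.resolution is not None:
        header = (
            "REMARK   2\n"
            f"REMARK   2 RESOLUTION. {model.resolution:7.2f} ANGSTROMS.\n"
        )
    return header + st.make_pdb_string()


def extract_torsions(model: StructureModel, targets=None, templates=None) -> list:
    """Extract phi/psi/chi torsion records for all target residues.

    phi is C(i-1)-N-CA-C and psi is N-CA-C-N(i+1); residues at chain termini
    (either backbone dihedral undefined) are skipped, as are residues missing
    any chi-defining atom.  Skips are logged, never raised.
    """
    if targets is None:
        targets = set(PTM_RESNAMES)
    records = []
    for chain_id, residues in model.chains.items():
        for idx, res in enumerate(residues):
            if res.resname not in targets:
                continue
            template = (templates or {}).get(res.resname) if templates else None
            if template is None:
                try:
                    template = get_template(res.resname)
                except KeyError:
                    logger.info("no template for %s; skipping", res.resname)
                    continue
            prev_res = residues[idx - 1] if idx > 0 else None
            next_res = residues[idx + 1] if idx + 1 < len(residues) else None
            if prev_res is None or next_res is None:
                logger.info(
                    "%s %s%d: chain terminus, phi/psi undefined; skipped",
                    res.resname, chain_id, res.seqnum,
                )
                continue
            if prev_res.seqnum + 1 != res.seqnum or next_res.seqnum != res.seqnum + 1:
                logger.info(
                    "%s %s%d: neighbors not sequential; skipped",
                    res.resname, chain_id, res.seqnum,
                )
                continue
            needed = [prev_res.atom("C"), res.atom("N"), res.atom("CA"), res.atom("C"),
                      next_res.atom("N")]
            if any(a is None for a in needed):
                logger.info(
                    "%s %s%d: missing backbone atom; skipped",
                    res.resname, chain_id, res.seqnum,
                )
                continue
            c_prev, n, ca, c, n_next = needed
            chis = []
            ok = True
            for quad in template.chi_defs:
                atoms = [res.atom(name) for name in quad]
                if any(a is None for a in atoms):
                    missing = [name for name, a in zip(quad, atoms) if a is None]
                    logger.info(
                        "%s %s%d: missing chi-defining atom(s) %s; skipped",
                        res.resname, chain_id, res.seqnum, ",".join(missing),
                    )
                    ok = False
                    break
                chis.append(compute_dihedral(*(a.position for a in atoms)))
            if not ok:
                continue
            records.append(
                TorsionRecord(
                    entry_id=model.entry_id,
                    chain_id=chain_id,
                    seqnum=res.seqnum,
                    resname=res.resname,
                    phi=compute_dihedral(c_prev.position, n.position, ca.position, c.position),
                    psi=compute_dihedral(n.position, ca.position, c.position, n_next.position),
                    chis=np.array(chis),
                    resolution=model.resolution,
                )
            )
    return records


_ELEMENT_OF = {
    "N": "N", "CA": "C", "C": "C", "O": "O", "CB": "C", "OG": "O", "OG1": "O",
    "CG": "C", "CG2": "C", "CD": "C", "CD1": "C", "CD2": "C", "CE": "C",
    "CE1": "C", "CE2": "C", "CZ": "C", "OH": "O", "P": "P", "O1P": "O",
    "O2P": "O", "O3P": "O", "NZ": "N", "CM1": "C", "CM2": "C", "CM3": "C",
    "CH": "C", "CH3": "C",
}


def build_sidechain(backbone: Residue, resname: str, chis,
                    template: SidechainTemplate | None = None) -> Residue:
    """Rebuild a full side chain from backbone atoms and chi values.

    Atoms are placed sequentially from internal coordinates; re-extracting
    chi from the built coordinates recovers the input to numerical precision.
    """
    if template is None:
        template = get_template(resname)
    if template.resname != resname:
        raise ValueError(f"template is for {template.resname}, not {resname}")
    chis = np.asarray(chis, dtype=float)
    if chis.shape[0] != template.n_chi:
        raise ValueError(
            f"{resname} takes {template.n_chi} chi angles, got {chis.shape[0]}"
        )
    for name in ("N", "CA", "C"):
        if backbone.atom(name) is None:
            raise ValueError(f"backbone atom {name} missing")
    out = Residue(
        resname=resname,
        chain_id=backbone.chain_id,
        seqnum=backbone.seqnum,
        icode=backbone.icode,
        atoms=[Atom(a.name, a.element, a.position.copy(), a.altloc, a.occupancy,
                    a.b_factor)
               for a in backbone.atoms if a.name in BACKBONE_ATOMS],
    )
    positions = {a.name: a.position for a in out.atoms}
    for row in template.ic_table:
        ref_positions = []
        for ref in row.refs:
            if ref not in positions:
                raise ValueError(f"reference atom {ref} not yet placed for {row.atom}")
            ref_positions.append(positions[ref])
        if row.torsion_rule[0] == "fixed":
            torsion = row.torsion_rule[1]
        else:
            _, k, offset = row.torsion_rule
            torsion = float(wrap_angle(chis[k - 1] + offset))
        pos = place_atom(*ref_positions, row.bond, row.angle, torsion)
        positions[row.atom] = pos
        out.atoms.append(Atom(row.atom, _ELEMENT_OF.get(row.atom, "C"), pos))
    return out


#: Atom-name permutations induced by chemical symmetry: the 3-fold terminal
#: rotors (phosphate oxygens, trimethylammonium methyls) and the 2-fold
#: phenyl ring flip.  Deposited structures name these equivalent atoms
#: arbitrarily, so RMSD is minimized over the group.
_SYMMETRY_CYCLES = {
    "SEP": [[("O1P", "O2P", "O3P")]],
    "TPO": [[("O1P", "O2P", "O3P")]],
    "PTR": [[("O1P", "O2P", "O3P")], [("CD1", "CD2"), ("CE1", "CE2")]],
    "M3L": [[("CM1", "CM2", "CM3")]],
    "ALY": [],
}


def _symmetry_mappings(resname: str):
    """All atom-name relabelings generated by the residue's symmetry groups."""
    mappings = [{}]
    for cycles in _SYMMETRY_CYCLES.get(resname, []):
        order = len(cycles[0])
        new = []
        for base in mappings:
            for shift in range(order):
                m = dict(base)
                for cycle in cycles:
                    for i, name in enumerate(cycle):
                        m[name] = cycle[(i + shift) % len(cycle)]
                new.append(m)
        mappings = new
    return mappings


def sidechain_rmsd(a: Residue, b: Residue, atom_selection=None,
                   symmetry_aware: bool = True) -> float:
    """Side-chain heavy-atom RMSD in the common frame (no superposition).

    Backbones are shared during repacking, so deviations are measured
    directly in the fixed laboratory frame.  With ``symmetry_aware`` the
    value is minimized over relabelings of chemically equivalent atoms
    (phosphate oxygens, trimethyl rotors, ring flips), whose names in
    deposited files are arbitrary.
    """
    if a.resname != b.resname:
        raise ValueError(f"residue mismatch: {a.resname} vs {b.resname}")
    if atom_selection is None:
        atom_selection = [
            name for name in (at.name for at in a.atoms)
            if name not in BACKBONE_ATOMS and not name.startswith("H")
        ]
    missing_a = [n for n in atom_selection if a.atom(n) is None]
    missing_b = [n for n in atom_selection if b.atom(n) is None]
    if missing_a or missing_b:
        raise ValueError(
            f"atom selection mismatch; missing in a: {missing_a}, in b: {missing_b}"
        )
    pa = np.array([a.atom(n).position for n in atom_selection])
    mappings = _symmetry_mappings(a.resname) if symmetry_aware else [{}]
    best = np.inf
    for mapping in mappings:
        pb = np.array(
            [b.atom(mapping.get(n, n)).position for n in atom_selection]
        )
        best = min(best, float(np.sqrt(np.mean(np.sum((pa - pb) ** 2, axis=1)))))
    return best


def _bond_graph(model: StructureModel, bond_cutoff: float = 1.95):
    """Distance-based covalent bond adjacency over all heavy atoms."""
    entries = [(res, a) for res, a in model.all_atoms() if a.element != "H"]
    coords = np.array([a.position for _, a in entries])
    adj = [set() for _ in entries]
    if len(entries) > 1:
        d2 = np.sum((coords[:, None, :] - coords[None, :, :]) ** 2, axis=-1)
        ii, jj = np.where((d2 > 0) & (d2 <= bond_cutoff**2))
        for i, j in zip(ii, jj):
            adj[i].add(int(j))
    return entries, adj


def detect_hbonds(model: StructureModel, cutoff: float = 3.5) -> list:
    """Backbone-N to phosphate/hydroxyl-oxygen contacts within ``cutoff`` A.

    Heavy-atom donor-acceptor distance criterion only; pairs separated by
    two or fewer covalent bonds are excluded.
    """
    entries, adj = _bond_graph(model)
    index = {id(a): i for i, (_, a) in enumerate(entries)}
    donors = [(res, a) for res, a in entries if a.name in HBOND_DONORS]
    acceptors = [
        (res, a) for res, a in entries
        if a.name in HBOND_ACCEPTORS and res.resname in PTM_RESNAMES
    ]
    out = []
    for dres, datom in donors:
        di = index[id(datom)]
        near = set(adj[di])
        for j in list(near):
            near |= adj[j]
        for ares, aatom in acceptors:
            ai = index[id(aatom)]
            if ai == di or ai in near:
                continue
            dist = float(np.linalg.norm(datom.position - aatom.position))
            if dist <= cutoff:
                out.append(((dres, datom), (ares, aatom), dist))
    return out


def contact_map(ensemble, region=None, cutoff: float = 8.0) -> np.ndarray:
    """Fractional C-alpha contact map over an ensemble of conformers.

    Entry (i, j) is the fraction of conformers in which residues i and j have
    C-alpha atoms within ``cutoff`` A.  ``region`` is an optional ordered list
    of (chain_id, seqnum) keys; by default all residues of the first conformer
    are used in order.
    """
    if not ensemble:
        raise ValueError("empty ensemble")
    if region is None:
        region = [(r.chain_id, r.seqnum) for r in ensemble[0].residues()]
    n = len(region)
    counts = np.zeros((n, n))
    for model in ensemble:
        coords = []
        for chain_id, seqnum in region:
            res = model.find_residue(chain_id, seqnum)
            ca = res.atom("CA") if res is not None else None
            if ca is None:
                raise ValueError(f"missing CA for residue {chain_id}:{seqnum}")
            coords.append(ca.position)
        coords = np.array(coords)
        d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=-1)
        counts += (d <= cutoff).astype(float)
    return counts / len(ensemble)


def contact_map_diff(map_ptm: np.ndarray, map_unmodified: np.ndarray) -> np.ndarray:
    """Elementwise contact-fraction difference (modified minus unmodified)."""
    map_ptm = np.asarray(map_ptm)
    map_unmodified = np.asarray(map_unmodified)
    if map_ptm.shape != map_unmodified.shape:
        raise ValueError(
            f"shape mismatch: {map_ptm.shape} vs {map_unmodified.shape}"
        )
    return map_ptm - map_unmodified
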