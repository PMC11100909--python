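"""Internal-coordinate side-chain templates for the five supported PTMs.

Each template lists, for every side-chain heavy atom, the three reference
atoms, the bond length (A), the bond angle (degrees) and a torsion rule:
either a fixed value (ring closure, planar amide, chirality improper) or a
chi index with an additive offset (branch atoms riding on the same rotor,
e.g. the three phosphate oxygens at chi +/- 120).

Geometry constants are idealized values measured from the PDB chemical
component dictionary's ideal coordinates for each residue; torsion offsets
for symmetric branches are rounded to exact multiples of 120/180 degrees so
that symmetry folding is exact.

Chi definitions:

=======  ====================================================================
residue  chi atom quadruples
=======  ====================================================================
SEP      N-CA-CB-OG, CA-CB-OG-P, CB-OG-P-O1P (terminal phosphate rotor)
TPO      N-CA-CB-OG1, CA-CB-OG1-P, CB-OG1-P-O1P (terminal)
PTR      N-CA-CB-CG, CA-CB-CG-CD1 (ring), CE1-CZ-OH-P, CZ-OH-P-O1P (terminal)
M3L      lysine chi1-chi4, then CD-CE-NZ-CM1 (terminal trimethyl rotor)
ALY      lysine chi1-chi4, then CD-CE-NZ-CH (sp3-sp2 amide bond)
=======  ====================================================================

The terminal rotors (SEP/TPO chi3, PTR chi4, M3L chi5) have 3-fold
symmetry (120 degree period); the PTR ring torsion chi2 has 2-fold (180
degree) symmetry.  ALY's chi5 crosses onto an sp2 nitrogen and is a full
library degree of freedom; the amide geometry beyond it is fixed planar.
"""

from __future__ import annotations

from dataclasses import dataclass, field

PTM_RESNAMES = ("SEP", "TPO", "PTR", "M3L", "ALY")

#: Number of chi angles per supported residue.
CHI_COUNTS = {"SEP": 3, "TPO": 3, "PTR": 4, "M3L": 5, "ALY": 5}

#: 1-based index of the 3-fold symmetric terminal rotor, or None (ALY).
TERMINAL_CHI = {"SEP": 3, "TPO": 3, "PTR": 4, "M3L": 5, "ALY": None}


@dataclass(frozen=True)
class ICRow:
    """One internal-coordinate row: place ``atom`` from reference atoms.

    ``torsion_rule`` is ``("fixed", value_deg)`` or ``("chi", k, offset_deg)``
    with k 1-based.
    """

    atom: str
    refs: tuple  # (a, b, c); torsion a-b-c-atom, angle b-c-atom, bond c-atom
    bond: float
    angle: float
    torsion_rule: tuple


@dataclass(frozen=True)
class SidechainTemplate:
    resname: str
    chi_defs: tuple  # atom-name quadruples, one per chi
    ic_table: tuple  # ICRow, topologically ordered

    @property
    def n_chi(self) -> int:
        return len(self.chi_defs)

    @property
    def terminal_chi(self):
        return TERMINAL_CHI[self.resname]

    @property
    def sidechain_atoms(self) -> tuple:
        return tuple(row.atom for row in self.ic_table)

    def chi_atoms(self) -> set:
        """All atom names any chi definition touches (completeness check)."""
        names = set()
        for quad in self.chi_defs:
            names.update(quad)
        return names


def _rows(raw):
    return tuple(ICRow(atom, refs, bond, angle, rule) for atom, refs, bond, angle, rule in raw)


_LYS_STEM = [
    ("CB", ("C", "N", "CA"), 1.530, 110.4, ("fixed", 122.5)),
    ("CG", ("N", "CA", "CB"), 1.530, 109.5, ("chi", 1, 0.0)),
    ("CD", ("CA", "CB", "CG"), 1.530, 109.5, ("chi", 2, 0.0)),
    ("CE", ("CB", "CG", "CD"), 1.530, 109.5, ("chi", 3, 0.0)),
    ("NZ", ("CG", "CD", "CE"), 1.468, 109.5, ("chi", 4, 0.0)),
]

TEMPLATES = {
    "SEP": SidechainTemplate(
        resname="SEP",
        chi_defs=(
            ("N", "CA", "CB", "OG"),
            ("CA", "CB", "OG", "P"),
            ("CB", "OG", "P", "O1P"),
        ),
        ic_table=_rows(
            [
                ("CB", ("C", "N", "CA"), 1.529, 110.4, ("fixed", 122.5)),
                ("OG", ("N", "CA", "CB"), 1.428, 109.5, ("chi", 1, 0.0)),
                ("P", ("CA", "CB", "OG"), 1.609, 118.0, ("chi", 2, 0.0)),
                ("O1P", ("CB", "OG", "P"), 1.480, 109.5, ("chi", 3, 0.0)),
                ("O2P", ("CB", "OG", "P"), 1.610, 109.5, ("chi", 3, -120.0)),
                ("O3P", ("CB", "OG", "P"), 1.609, 109.5, ("chi", 3, 120.0)),
            ]
        ),
    ),
    "TPO": SidechainTemplate(
        resname="TPO",
        chi_defs=(
            ("N", "CA", "CB", "OG1"),
            ("CA", "CB", "OG1", "P"),
            ("CB", "OG1", "P", "O1P"),
        ),
        ic_table=_rows(
            [
                ("CB", ("C", "N", "CA"), 1.530, 110.4, ("fixed", 122.5)),
                ("OG1", ("N", "CA", "CB"), 1.428, 109.5, ("chi", 1, 0.0)),
                ("CG2", ("N", "CA", "CB"), 1.529, 109.5, ("chi", 1, 120.0)),
                ("P", ("CA", "CB", "OG1"), 1.609, 118.0, ("chi", 2, 0.0)),
                ("O1P", ("CB", "OG1", "P"), 1.480, 109.5, ("chi", 3, 0.0)),
                ("O2P", ("CB", "OG1", "P"), 1.610, 109.5, ("chi", 3, -120.0)),
                ("O3P", ("CB", "OG1", "P"), 1.610, 109.5, ("chi", 3, 120.0)),
            ]
        ),
    ),
    "PTR": SidechainTemplate(
        resname="PTR",
        chi_defs=(
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "CD1"),
            ("CE1", "CZ", "OH", "P"),
            ("CZ", "OH", "P", "O1P"),
        ),
        ic_table=_rows(
            [
                ("CB", ("C", "N", "CA"), 1.529, 110.4, ("fixed", 122.5)),
                ("CG", ("N", "CA", "CB"), 1.507, 113.9, ("chi", 1, 0.0)),
                ("CD1", ("CA", "CB", "CG"), 1.382, 120.0, ("chi", 2, 0.0)),
                ("CD2", ("CA", "CB", "CG"), 1.382, 120.0, ("chi", 2, 180.0)),
                ("CE1", ("CB", "CG", "CD1"), 1.381, 120.0, ("fixed", 180.0)),
                ("CE2", ("CB", "CG", "CD2"), 1.381, 120.0, ("fixed", 180.0)),
                ("CZ", ("CG", "CD1", "CE1"), 1.387, 120.0, ("fixed", 0.0)),
                ("OH", ("CD1", "CE1", "CZ"), 1.359, 120.0, ("fixed", 180.0)),
                ("P", ("CE1", "CZ", "OH"), 1.609, 120.0, ("chi", 3, 0.0)),
                ("O1P", ("CZ", "OH", "P"), 1.481, 109.5, ("chi", 4, 0.0)),
                ("O2P", ("CZ", "OH", "P"), 1.610, 109.5, ("chi", 4, -120.0)),
                ("O3P", ("CZ", "OH", "P"), 1.608, 109.5, ("chi", 4, 120.0)),
            ]
        ),
    ),
    "M3L": SidechainTemplate(
        resname="M3L",
        chi_defs=(
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"),
            ("CG", "CD", "CE", "NZ"),
            ("CD", "CE", "NZ", "CM1"),
        ),
        ic_table=_rows(
            _LYS_STEM
            + [
                ("CM1", ("CD", "CE", "NZ"), 1.469, 109.5, ("chi", 5, 0.0)),
                ("CM2", ("CD", "CE", "NZ"), 1.469, 109.5, ("chi", 5, 120.0)),
                ("CM3", ("CD", "CE", "NZ"), 1.470, 109.5, ("chi", 5, -120.0)),
            ]
        ),
    ),
    "ALY": SidechainTemplate(
        resname="ALY",
        chi_defs=(
            ("N", "CA", "CB", "CG"),
            ("CA", "CB", "CG", "CD"),
            ("CB", "CG", "CD", "CE"),
            ("CG", "CD", "CE", "NZ"),
            ("CD", "CE", "NZ", "CH"),
        ),
        ic_table=_rows(
            _LYS_STEM
            + [
                ("CH", ("CD", "CE", "NZ"), 1.347, 120.0, ("chi", 5, 0.0)),
                # sp2 amide kept planar: carbonyl O cis to CE, methyl trans
                ("OH", ("CE", "NZ", "CH"), 1.211, 120.0, ("fixed", 0.0)),
                ("CH3", ("CE", "NZ", "CH"), 1.507, 120.0, ("fixed", 180.0)),
            ]
        ),
    ),
}


def get_template(resname: str) -> SidechainTemplate:
    try:
        return TEMPLATES[resname]
    except KeyError:
        raise KeyError(f"no side-chain template for residue {resname!r}") from None
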