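"""Run configuration shared across the pipeline.

Every tunable that affects library construction or evaluation lives here so
that a single object can be serialized into output headers and round-tripped
from a config file, making library builds reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path


@dataclass
class RunConfig:
    """All pipeline tunables with their pinned defaults.

    Parameters
    ----------
    kappa0 : float
        Pilot concentration of the adaptive von Mises KDE on the phi/psi
        torus (dimensionless; 50 corresponds to a kernel circular standard
        deviation of roughly 8 degrees).
    alpha : float
        Local-bandwidth sensitivity exponent of the adaptive KDE, in [0, 1].
        0 disables adaptivity; 0.5 is the classical Abramson choice.
    kappa_reg : float
        Concentration of the Nadaraya-Watson regression kernel used to smooth
        chi means and standard deviations over the backbone torus.
    std_floor_deg : float
        Lower bound on reported circular standard deviations, in degrees.
        Prevents zero-width sampling distributions from quantized data.
    grid_step_deg : float
        Quadrature step used when checking density normalization.
    support_radius_deg : float
        A phi/psi bin counts as data-supported when at least one observation
        lies within this circular distance of the bin center on both axes;
        otherwise the bin is backfilled from the backbone-independent library.
    dbscan_eps_deg : float
        DBSCAN neighborhood radius (circular distance, degrees) used when
        splitting non-standard torsion distributions.
    dbscan_min_samples : int
        Minimum DBSCAN neighborhood size; the effective value is
        ``max(dbscan_min_samples, n // 50)``.
    clash_factor : float
        A rebuilt atom clashes when closer than ``clash_factor`` times the sum
        of van der Waals radii to any atom outside its residue.
    identity_threshold : float
        Sequence identity at or above which two entries join a cluster.
    max_resolution : float
        Resolution cutoff in Angstrom; entries above it are dropped.
    min_count : int
        Minimum number of contributing PDB entries for a residue type to be
        eligible for library construction.
    hbond_cutoff : float
        Donor-acceptor heavy-atom distance cutoff for hydrogen bonds (A).
    contact_cutoff : float
        C-alpha contact distance cutoff (A).
    seed : int
        Base seed for all stochastic steps.
    """

    kappa0: float = 50.0
    alpha: float = 0.5
    kappa_reg: float = 50.0
    std_floor_deg: float = 3.0
    grid_step_deg: float = 5.0
    support_radius_deg: float = 30.0
    dbscan_eps_deg: float = 20.0
    dbscan_min_samples: int = 5
    clash_factor: float = 0.7
    identity_threshold: float = 0.90
    max_resolution: float = 3.5
    min_count: int = 40
    hbond_cutoff: float = 3.5
    contact_cutoff: float = 8.0
    seed: int = 0

    def to_header(self) -> str:
        """Serialize as a single ``key=value;...`` provenance string."""
        parts = []
        for f in dataclasses.fields(self):
            parts.append(f"{f.name}={getattr(self, f.name)}")
        return ";".join(parts)

    @classmethod
    def from_header(cls, header: str) -> "RunConfig":
        kwargs = {}
        field_types = {f.name: f.type for f in dataclasses.fields(cls)}
        for part in header.split(";"):
            if not part.strip():
                continue
            key, _, val = part.partition("=")
            key = key.strip()
            if key not in field_types:
                raise ValueError(f"unknown config key: {key!r}")
            typ = field_types[key]
            kwargs[key] = int(val) if typ in ("int", int) else float(val)
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a key-value config file (one ``key = value`` per line,
        ``#`` comments allowed)."""
        lines = []
        for raw in Path(path).read_text().splitlines():
            line = raw.split("#", 1)[0].strip()
            if line:
                lines.append(line.replace(" ", ""))
        return cls.from_header(";".join(lines))

    def write(self, path: str | Path) -> None:
        out = []
        for f in dataclasses.fields(self):
            out.append(f"{f.name} = {getattr(self, f.name)}")
        Path(path).write_text("\n".join(out) + "\n")

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
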