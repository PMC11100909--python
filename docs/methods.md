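# Methods

`ptmrot` builds side-chain rotamer libraries for five post-translationally
modified residues — phosphoserine (SEP), phosphothreonine (TPO),
phosphotyrosine (PTR), trimethyllysine (M3L) and acetyllysine (ALY) — from
protein coordinate files, and uses those libraries to resample ("repack")
PTM side chains on fixed backbones. This note records the statistical
model, the geometry conventions, every tunable that matters, and the design
choices made where more than one defensible option existed.

## The estimation problem

A rotamer library summarizes the conditional distribution of side-chain
torsions chi = (chi1, ..., chiK) given the backbone torsions (phi, psi).
The estimator has two layers:

1. **Discrete layer.** Each chi axis is partitioned into named angular
   wedges (conformers). The tuple of wedge labels over the non-terminal
   chis is the rotamer *state* r. A library stores P(r) (backbone
   independent, BI) or P(r | phi, psi) on a 12 x 12 grid of 30-degree
   backbone bins (backbone dependent, BD).
2. **Continuous layer.** Within each state, per-chi circular means and
   standard deviations describe the torsion distribution; sampling draws a
   state and then each chi from a von Mises matched to those moments.

### Conformer wedges

* sp3–sp3 torsions use the classical staggered wedges, lower-inclusive
  half-open so they tile the circle exactly: T on [120, 180) u [-180,
  -120), G+ on [0, 120), G- on [-120, 0).
* ALY chi5 crosses an sp3–sp2 amide bond and uses its own six-arc wedge set
  (G+ on [30, 90) u [-135, -90); G- on [-90, -30) u [90, 135); T on
  [-30, 30) u [135, 180) u [-180, -135)). The printed literature ranges
  overlap on two arcs; overlaps are resolved in favor of T so that the
  wedges partition the circle — a measure-zero bookkeeping decision.
* PTR chi2 rotates a phenyl ring, a 2-fold symmetric torsion: G on
  [45, 135) u [-135, -45), T elsewhere. Classification is invariant under
  a 180-degree shift.
* SEP/TPO chi2 and PTR chi3 have distributions that do not match staggered
  hybridization wedges (they are shaped by hydrogen bonding to the
  phosphate). Their wedges are data driven: DBSCAN with a circular metric
  min(|d|, 360 - |d|) splits the observed 1-D distribution into clusters;
  cluster circular means define wedge boundaries at the circular midpoints
  between adjacent means; labels C1..Ck follow descending population.
  Noise points are assigned to the nearest cluster so every observation
  counts. Defaults: eps = 20 degrees, min_samples = max(5, n/50). When no
  cluster forms, a single full-circle wedge is used (logged).
* Terminal 3-fold rotors — the phosphate of SEP/TPO (chi3) and PTR (chi4),
  and the trimethylammonium of M3L (chi5) — are physically symmetric under
  120-degree rotation. They are excluded from the state tuple; their
  statistics are computed on the folded domain [-60, 60), and sampling
  lifts a folded draw onto a uniformly random symmetry image.

### BI estimation

P(r) is the count fraction of records assigned to each state. Per-state
chi moments are weighted circular statistics: mean from the resultant
direction, standard deviation sqrt(-2 ln Rbar) in degrees, on a 120-degree
circle for terminal rotors. Standard deviations are floored at 3 degrees
(`std_floor_deg`) because finite, quantized crystallographic torsions can
collapse to zero spread, which would make sampling degenerate.

### BD estimation

At each of the 144 bin centers (-165, -135, ..., 165 on both axes):

* **Probabilities** come from Bayes' rule,
  P(r | phi, psi) ∝ P(r) f_r(phi, psi), with the BI probabilities as
  priors and f_r an adaptive von Mises kernel density estimate of the
  state's backbone distribution. The kernel is a product of von Mises
  densities on phi and psi (the simplest torus kernel); the pilot
  concentration is kappa0 = 50 (kernel circular std of roughly 8 degrees)
  and per-point bandwidth factors follow the Abramson rule
  lambda_i = (g / f_pilot(x_i))^alpha with alpha = 0.5 and g the geometric
  mean of pilot values, mapped to concentrations kappa_i = kappa0 /
  lambda_i^2 (the small-angle correspondence between a linear kernel's
  variance scaling and the von Mises concentration; the von Mises family
  has no exact bandwidth-scaling identity).

  One deliberate refinement: the bandwidth factors are computed from the
  pilot density of the **pooled** backbone sample and then applied to each
  state's kernels, rather than from per-state pilots. With per-state
  pilots, a state's few stray observations inside another state's dense
  region receive very large lambdas (near-uniform kernels) whose tails
  dominate distant bins and can invert the posterior ranking; pooled
  bandwidths make kernel width a property of how densely the backbone
  torus is populated at a location, which is what local adaptivity is
  meant to capture. On two-region synthetic data this changes rank-1
  agreement with the generating model from well under 90% to 100%.
* **Chi moments** come from Nadaraya–Watson circular kernel regression:
  observations are weighted by a product von Mises kernel centered on the
  bin center (kappa_reg = 50), and weighted circular mean/std are computed
  per chi (folded domain for terminal rotors). The Kish effective sample
  size of the weights is recorded.
* **Backfill.** A bin is data supported when at least one record lies
  within `support_radius_deg` = 30 degrees of its center on both axes
  (about four kernel standard deviations). Unsupported bins copy the BI
  entries verbatim and carry a backfill flag, so the library degrades
  gracefully to the marginal where data run out. States absent from the
  data entirely get probability zero everywhere — rotamers are never
  invented by smoothing.

Probabilities are evaluated at bin centers, not bin averages; with
30-degree bins and kernels of ~8-degree width the difference is second
order.

## Geometry

* All torsions are degrees on the half-open interval [-180, 180); every
  wrap goes through one function so bin boundaries behave identically
  everywhere. Dihedrals follow the IUPAC sign convention (verified
  against cis = 0 and trans = -180 anchors); reversing the four atoms
  preserves the sign.
* Side chains are rebuilt from chi values by sequential natural-extension
  placement: each atom is placed from a parent triple by bond length, bond
  angle and torsion. Templates carry idealized geometry measured from the
  chemical component dictionary's ideal coordinates, with branch atoms of
  symmetric rotors at exact +/-120 or 180-degree offsets and the
  L-chirality improper C-N-CA-CB at 122.5 degrees (the standard peptide
  value). Rebuilding then re-extracting chi is the identity to better than
  1e-6 degrees. The chi atom quadruples are: SEP N-CA-CB-OG /
  CA-CB-OG-P / CB-OG-P-O1P; TPO the same through OG1; PTR N-CA-CB-CG /
  CA-CB-CG-CD1 / CE1-CZ-OH-P / CZ-OH-P-O1P; M3L lysine chi1–chi4 then
  CD-CE-NZ-CM1; ALY lysine chi1–chi4 then CD-CE-NZ-CH, with the amide
  beyond chi5 fixed planar (carbonyl O cis to CE, methyl trans).
* Side-chain RMSD is computed over heavy atoms in the fixed laboratory
  frame (no superposition — backbones are shared during repacking) and is
  by default minimized over relabelings of chemically equivalent atoms:
  the three phosphate oxygens, the three N-methyl carbons, and the PTR
  ring flip. Those atom names are arbitrary in deposited files, and a
  terminal rotor drawn on a different symmetry image is the same
  conformation. The plain named-atom variant is available
  (`symmetry_aware=False`).
* Hydrogen bonds are heavy-atom donor–acceptor contacts: backbone N to
  phosphate/hydroxyl oxygens within 3.5 A, excluding pairs within two
  covalent bonds. Deposited PTM structures rarely carry hydrogens, so no
  angle term is used.
* Contact maps are fractions of conformers with C-alpha pairs within 8 A.

## Curation

Raw entries pass through: resolution filter (keep <= 3.5 A; entries
without a resolution are dropped and logged), completeness exclusion (an
entry counts when at least one PTM site has all chi-defining atoms),
single-linkage clustering of entries at >= 90% global-alignment identity
(match 1, mismatch 0, gap open -10, gap extend -0.5; an entry joins a
cluster when any chain pair crosses the threshold), best-resolution
representative per cluster (ties broken by lexicographic entry id), and a
minimum of 40 contributing entries per residue type before a library is
built. Single linkage and the alignment dialect are pinned choices — the
operative publication route uses an external alignment tool whose exact
scoring is not part of this package's contract.

## Repacking and evaluation

Repacking removes a PTM side chain, draws chi vectors from a library at
the site's phi/psi, rebuilds the side chain, and rejects draws with any
rebuilt atom closer than 0.7 x (sum of van der Waals radii; C 1.70,
N 1.55, O 1.52, P 1.80, S 1.80 A) to an atom outside the residue. The
first clash-free draw is returned (one conformer per case — no energy
ranking, which is the job of downstream packing engines); if none passes,
the least-clashing draw is returned and flagged. Accuracy is the
side-chain RMSD distribution versus reference structures, summarized with
quartiles and 1.5 IQR whiskers. Paired method comparisons use the
one-sided Wilcoxon signed-rank test (alternative: first method's RMSDs are
smaller), zero differences dropped, W = the smaller signed-rank sum, exact
p by enumeration over all 2^n sign assignments (tied ranks included) for
n <= 12 and a tie-corrected, continuity-corrected normal approximation
beyond.

## Synthetic data

The generator draws torsion records from known von Mises mixtures:
backbone (phi, psi) from a mixture of helix/sheet/polyproline-like
regions, a rotamer state from region-specific or global weights, and each
chi from its von Mises component; terminal rotors are drawn folded and
lifted to a random symmetry image, as raw crystallographic torsions
appear. Default specs mirror the qualitative structure reported for real
phospho-residues: TPO dominated by the -60/120 chi1/chi2 well whose
phosphate accepts an internal amide hydrogen bond, SEP with a mixed chi2
population spanning 60 to -120, broad terminal rotors. The two-region
spec (first state dominant in the helix region, second in the sheet
region, weights 0.8 vs 0.1) is the reference input for checking that a BD
library ranks the locally dominant state first.

Toy structures are ideal ALA–X–ALA tripeptides built by natural extension
with Engh–Huber-like backbone geometry; the central residue reproduces any
requested phi/psi/chi exactly in memory. Two caveats about what these
fixtures can and cannot show:

* Writing to PDB text quantizes coordinates to 0.001 A, which perturbs
  re-extracted torsions by up to ~0.05 degrees; the exact round trip is a
  property of the in-memory structure, and the text round trip is checked
  at a 0.2-degree format bound.
* At exactly chi1/chi2 = -180/60 the idealized geometry presses a
  phosphate oxygen into the residue's own backbone; deposited structures
  showing the adjacent-residue phosphate hydrogen bond relieve this with
  small angle distortions. The named fixture for that interaction
  therefore sits at (-180, 90) with psi = -145 — the same trans/gauche
  well — giving the i+1 amide–phosphate contact at 2.74 A with all
  non-bonded pairs at physical distances.

The generator makes no attempt to imitate crystallographic noise,
B-factor statistics, missing-atom patterns or sequence biases, so green
tests demonstrate correctness of the estimator and pipeline mechanics,
not performance on real deposited data.

## Tunables

| name | default | units | role |
|---|---|---|---|
| `kappa0` | 50 | — | pilot KDE concentration (~8 deg kernel std) |
| `alpha` | 0.5 | — | adaptive bandwidth exponent (Abramson) |
| `kappa_reg` | 50 | — | regression kernel concentration |
| `std_floor_deg` | 3 | deg | lower bound on reported chi stds |
| `support_radius_deg` | 30 | deg | data-support radius for BD bins |
| `dbscan_eps_deg` | 20 | deg | DBSCAN neighborhood radius |
| `dbscan_min_samples` | 5 | — | DBSCAN core threshold (>= n/50) |
| `clash_factor` | 0.7 | — | vdW overlap fraction counted as clash |
| `identity_threshold` | 0.90 | — | redundancy clustering threshold |
| `max_resolution` | 3.5 | A | resolution cutoff |
| `min_count` | 40 | entries | per-residue library eligibility |
| `hbond_cutoff` | 3.5 | A | donor–acceptor distance |
| `contact_cutoff` | 8 | A | C-alpha contact distance |

All are fields of `RunConfig`, serialized into every output header, so a
library file records exactly how it was built.

## Problem sizes

Tests and the acceptance script run at desk scale: 2000-record mixtures
for parameter recovery, 3000 records for backbone-dependence recovery,
300–1000 records per residue for scheme and normalization checks, 40-file
pipelines for reproducibility, and 20-case repacking batches. These sizes
put empirical weights within ~0.02 of truth and circular means within
~1 degree, comfortably inside the stated tolerances, while the whole suite
builds dozens of libraries in under a minute.

## Known limitations

* No mmCIF input; first NMR model only; no hydrogen placement.
* The BD estimator assumes the state partition from the BI step is
  correct; wedge boundaries are global, not backbone dependent.
* DBSCAN wedge splitting operates on one chi at a time; genuinely joint
  multi-chi structure is captured only through the state tuple.
* The clash criterion is a fixed-radius overlap test, not an energy; it
  cannot rank two clash-free conformers.
* Curation identity uses one global-alignment dialect; proteins whose
  similarity is only detectable through local alignment may escape
  clustering.
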