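# Methods

This note records the models implemented in cnbdkit, the defaults and why
they were chosen, what the synthetic-data generators do and do not emulate,
and the numerical conventions that matter for reproducing its output.

## Coordinate model and I/O

Structures are read through gemmi (PDB and mmCIF dialects) into a minimal
chain → residue → atom hierarchy. Author-assigned residue numbers are kept
verbatim — pocket residues are referred to by those numbers (Thr193,
Leu172/Cys173, Cys133/Cys211 in the 92–227 PKG Iβ construct numbering) and
renumbering would silently break every site annotation. Alternate locations
are retained on read; all geometry uses the preferred conformer (highest
occupancy, ties broken by alphabetical alt-loc) so results are deterministic.
Ribose atom-name spelling variants (`O2*`, `O2'`, `O2′`) collapse to one key,
since deposited files and published tables mix the dialects. Ligand residue
names are matched against configurable sets (`PCG/CGM/35G/CGP` for cGMP,
`CMP/CAM/1CA` for cAMP) because chemical-component naming has drifted across
depositions.

Space-group multiplicities are resolved from gemmi's symmetry tables rather
than a hand-maintained list; the groups relevant here are P6₂22 (12
operators) and P4₃ (4).

## Contact classification

A contact is any protein-heavy-atom/ligand-heavy-atom pair within the VDW
cutoff, default 4.0 Å (the largest distance such studies tabulate as a VDW
contact is ~3.9 Å). A hydrogen bond requires both atoms in {N, O} and
distance ≤ 3.5 Å. No angular criterion is applied: the models contain no
hydrogens, and published pocket tables report distances only. Sulfur is
handled specially: an S⋯(N/O) pair within 3.5 Å keeps VDW class but carries
an `extended` flag — this reproduces how the Cys173 thiol-to-N7 interaction
is conventionally grouped (listed among VDW contacts, described as an
extended hydrogen bond).

Leucine δ-carbon contacts can be reported collapsed to a single
`CD(min)` row (the shorter of CD1/CD2 per ligand atom), because published
tables sometimes print a bare "CD" that leucine does not possess.

Site labels follow the three-part pocket decomposition: site 1 =
{182, 183, 184, 185, 192} (P-helix backbone amides + Arg gripping the cyclic
phosphate), site 2 = {193} (the bridging threonine), site 3 = {172, 173}
(the cis-peptide purine dock), with {165, 175} annotated `near_site3`.

## Torsion conventions

Dihedrals use the signed atan2 construction, range (−180°, +180°], invariant
under rigid motion and negated by mirror reflection. Omega is
CA(i)–C(i)–N(i+1)–CA(i+1): cis ⇔ |ω| ≤ 30°, trans ⇔ |ω − 180°| ≤ 30°
(wrapped), otherwise *ambiguous* — the standard crystallographic windows.
The purine glycosidic torsion χ is O4′–C1′–N9–C4; syn is the closed interval
[−90°, +90°] (so χ = ±90° is syn, ±90.0001° is anti; the boundary is tested
explicitly). Residue pairs missing backbone atoms are skipped with a log
message, not an error, because partial models are normal at low resolution.

Disulfide candidates are cysteine SG–SG pairs within 4.5 Å, deliberately
wider than the 2.05 Å bonded distance: reduced thiols poised to form a bond
on oxidation sit apart in the crystal.

## Superposition and restraint selection

The Kabsch solution (SVD of the centered covariance with determinant
correction) gives the optimal rotation; an independent closed-form
quaternion-eigenvalue oracle checks it in the test suite to 1e-9. Residues
are paired by author number by default (all comparisons here are within one
construct); a global-sequence-alignment mode handles renumbered chains.
Outlier rejection iterates fit → drop pairs deviating > 2.0 Å → refit, at
most 5 cycles. The 2.0 Å cutoff and cycle cap were chosen to emulate the
behaviour of standard structure-comparison tools that report "N equivalent
Cα atoms"; those counts are protocol-dependent, which is why comparisons
against published counts carry ±10-atom tolerances.

Restraint selection compares every φ, ψ and side-chain χ computable in both
models and selects a torsion iff the wrapped circular deviation is within
the threshold (default 15°). Chi torsions with two-fold-symmetric termini
(Asp χ2, Glu χ3, Phe/Tyr χ2) are compared modulo 180° so chemically
equivalent flips do not defeat selection.

## One-site ITC model

Forward model: after injection i the total cell concentrations follow the
discrete perfusion dilution M_i = M₀(1 − ΔV/2V₀)/(1 + ΔV/2V₀),
X_i = X_syr(ΔV/V₀)/(1 + ΔV/2V₀) (ΔV = cumulative injected volume); the
cumulative heat is the Wiseman single-site closed form, and per-injection
heats add the trapezoidal displacement correction
q_i = Q_i − Q_{i−1} + (dV_i/V₀)(Q_i + Q_{i−1})/2. Units are cal/mol
internally, µcal per injection and kcal/mol-of-injectant in reports.
R = 1.987 cal mol⁻¹ K⁻¹; 30 °C = 303.15 K.

Defaults mirror the reference protocol: 15 µM macromolecule in a 1.43 mL
cell (the standard VP-ITC cell volume, configurable), 250 µM syringe,
28 × 5 µL injections (giving a final molar ratio ≈ 1.6), 303.15 K. The
first injection is fit by default; a discard-first option exists because
many practitioners drop it.

Fitting minimizes per-injection heat residuals over (n, log₁₀Kₐ, ΔH) by
Levenberg–Marquardt (lmfit); log-Kₐ parameterization keeps the problem well
scaled across twelve decades of affinity. The automatic initializer is
deterministic: n = 1, ΔH from the first normalized heat, and log₁₀Kₐ from a
coarse fixed grid scan (3.0–13.0 in 0.5 steps) of residual norms — so a fit
on the same data always returns the same result. Non-convergence sets a
flag on the result instead of raising. Parameter uncertainties come from
the scaled covariance; the c-value n·Kₐ·[M]₀ is always reported because it
governs conditioning: at the reference design a 12 nM ligand gives
c ≈ 1250, where the isotherm is nearly a step and K_d is weakly determined
under noise. The test suite verifies that the reported relative Kₐ
uncertainty grows between c = 10 and c = 1250 at equal noise.

A numerical note on derived entropies: ΔS = (ΔH − ΔG)/T is sensitive to
rounding of the inputs. For K_d = 12 nM and ΔH = −12.5 kcal/mol at
303.15 K the identity gives ΔS = −5.0 cal mol⁻¹ K⁻¹; quoting the same
system as K_d ≈ 10.4 nM gives −4.7. Rounded (K_d, ΔH, ΔS) triples taken
from fits are therefore rarely mutually consistent to better than ~0.3
cal mol⁻¹ K⁻¹, and this package always reports the entropy derived from
its own fitted Kₐ and ΔH.

## Synthetic-data generators

Structural fixtures are built from internal coordinates by the NeRF
construction, so requested torsions are exact to float precision (tested at
1e-6°). The dipeptide and poly-alanine builders use standard backbone
geometry (N–CA 1.458 Å, CA–C 1.525 Å, C–N 1.329 Å, τ(N-CA-C) 111°). The
purine-nucleotide template carries correctly named ribose, base and
3′,5′-cyclic-phosphate atoms with a controllable glycosidic χ; its ribose
is an *open* idealized template (ring closure approximate), which is
irrelevant for torsion and contact tests but means the fixture is not a
chemically exact nucleotide. Chain-copy fixtures apply seeded isotropic
Gaussian noise then a seeded random rigid motion. Titration fixtures add
i.i.d. Gaussian noise (µcal) to the forward model. Every fixture is
byte-reproducible from its spec and seed.

What the generators do **not** emulate: the CNBD fold itself, real
crystallographic noise models (anisotropy, disorder, alt-locs), ligand
strain, or instrument baselines and heats of dilution. Passing synthetic
tests therefore demonstrates the correctness of the computations, not
agreement with any particular deposited structure; checks against deposited
coordinates run only when the files are present under `data/pdb/`.

Stochastic-recovery conditions: the noisy-fit study uses c = 10
(10 µM cell, Kₐ = 10⁶ M⁻¹, ΔH = −12 kcal/mol, σ = 0.1 µcal, 200 seeded
replicates) — a well-conditioned design with µM-scale protein giving
instrument-realistic µcal heats. The stoichiometric-limit check uses a
sharp design (1.25 mM syringe, 10 injections) so that saturation occurs
before significant volume displacement, keeping the analytic limit
n·ΔH·M₀·V₀ applicable to 2%.

## Crystal-level quantities

Cell volume uses the general triclinic formula; the Matthews coefficient is
V_M = V_cell/(Z·n_mol·MW) and solvent fraction 1 − 1.23/V_M. The molecular
weight of the 136-residue construct is estimated as residue count × 110 Da
(+18 for termini) ≈ 15.0 kDa, since the exact construct sequence is not
bundled; the ±few-percent MW uncertainty moves the solvent fraction by
roughly ∓1 percentage point, which is why the hexagonal-form check asserts
a band (≥ 0.70) rather than a point value.

## Known limitations

- Hydrogen-bond calls are distance-only; no donor/acceptor geometry or
  angular screening.
- The outlier-rejection protocol is one reasonable choice among several;
  matched-atom counts are comparable to other tools only within a few
  residues.
- The ITC model is strictly single-site: no competitive, sequential or
  multi-site schemes, no baseline drift, no heat-of-dilution blank beyond
  what a constant offset would absorb.
- B-factor region means use fixed default spans for the secondary-structure
  elements (β4/β5 161–176 and the helical elements); deposited structures
  may warrant adjusting these via configuration.
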