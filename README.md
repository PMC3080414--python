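# cnbdkit

Quantitative structural and thermodynamic analysis of cyclic-nucleotide-binding
domains (CNBDs): protein–ligand contact geometry, least-squares superposition
with outlier rejection, cis-peptide and glycosidic torsion classification,
per-residue B-factor profiles, crystal solvent content, reference-model
dihedral-restraint selection, and one-site isothermal titration calorimetry
(ITC) fitting.

The package is aimed at structural biologists characterizing how cyclic
nucleotides (cGMP, cAMP) engage CNBDs such as the amino-terminal domain of
cGMP-dependent protein kinase (PKG I). Its analyses answer the questions such a
study asks of its coordinates and calorimetry: which pocket residues contact
the ligand and at what distances; whether the nucleotide is bound *syn* or
*anti*; whether unusual backbone features (non-proline cis peptides, poised
cysteine pairs) are present; how similar two copies of the domain are; and what
affinity and thermodynamic signature the binding isotherm implies.

## Core methods

**Contact geometry.** All protein-atom/ligand-atom pairs within a
van-der-Waals cutoff (4.0 Å) are tabulated; pairs of N/O atoms within 3.5 Å
are classed as hydrogen bonds (distance-only criterion — crystallographic
models carry no hydrogens). A sulfur within 3.5 Å of N/O stays in the VDW
class but is flagged as an *extended* hydrogen bond. Contacts are annotated
with the three-part pocket decomposition (phosphate-gripping P-helix + Arg,
the bridging Thr, and the cis-peptide purine dock).

**Superposition.** The Kabsch closed-form solution (SVD with determinant
correction) minimizes Cα RMSD, inside an iterative loop that drops pairs
deviating by more than 2.0 Å and refits — yielding the "RMSD over N
equivalent Cα atoms" numbers used to compare domain copies.

**Torsions.** ω = CA(i)–C(i)–N(i+1)–CA(i+1); cis ⇔ |ω| ≤ 30°. Glycosidic
χ = O4′–C1′–N9–C4; syn ⇔ χ ∈ [−90°, +90°]. Reference-model restraint
selection keeps a torsion iff the circular deviation between working and
reference models is ≤ 15°.

**ITC.** The one-site (Wiseman) isotherm expresses cumulative heat Q as a
function of total concentrations, stoichiometry n, association constant Kₐ
and enthalpy ΔH; injection heats include the displacement-dilution
correction. (n, Kₐ, ΔH) are fit by damped least squares, and
ΔG = −RT ln Kₐ, ΔS = (ΔH − ΔG)/T, K_d = 1/Kₐ, c = n·Kₐ·[M]₀ are derived.

**Crystal solvent content.** Matthews coefficient V_M = V_cell /
(Z·n_mol·MW) and solvent fraction 1 − 1.23/V_M.

## Worked example

```python
from cnbdkit import OneSiteParams, fit_one_site, simulate_titration, vp_itc_design

design = vp_itc_design()   # 15 uM cell, 250 uM syringe, 28 x 5 uL, 303.15 K
truth = OneSiteParams(n=1.0, Ka=1.0 / 12e-9, dH=-12500.0)
fit = fit_one_site(simulate_titration(truth, design), design)
print(f"Kd = {fit.Kd * 1e9:.2f} nM, dH = {fit.params.dH / 1000:.2f} kcal/mol, "
      f"dS = {fit.dS:.2f} cal/(mol K), c = {fit.c_value:.0f}")
```

prints

```
Kd = 12.00 nM, dH = -12.50 kcal/mol, dS = -4.99 cal/(mol K), c = 1250
```

— the fitter recovers the generating affinity and enthalpy exactly from a
noiseless isotherm; the derived entropy is negative (binding is
enthalpy-driven with an entropic penalty), and the c-value of 1250 warns
that with real noise K_d would be weakly determined at this design. The
`examples/` directory holds one short script per capability (cis-peptide
detection, syn/anti classification, contact tables, superposition,
ITC fitting, solvent content, restraint selection), each printing annotated
output.

A command-line interface mirrors the library:

```sh
cnbdkit itc-sim --kd 12 --dh -12.5 --out curve.tsv
cnbdkit itc-fit curve.tsv
cnbdkit contacts structure.pdb --ligand PCG
cnbdkit superpose a.pdb A b.pdb B
```

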