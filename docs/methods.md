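# Methods

## Graph representation of the complexes

A complex is a simple undirected graph over heavy atoms. Conventions,
each of which matters for the index value:

- **Coordination number.** The metal is tetracoordinate in MB (amino N,
  one carboxylate O, two water O) and hexacoordinate in MB₂ (two
  bidentate ligands plus two waters). Each bound ligand closes a
  five-membered chelate ring M–N–Cα–C–O.
- **Carboxylate.** Only one oxygen coordinates; the other is a pendant
  carbonyl vertex. Bond orders are ignored — C=O is one edge, and
  coordination bonds are indistinguishable from covalent ones, because
  connectivity indices are defined on the simple graph.
- **Hydrogens** never appear as vertices; each vertex carries an
  attached-H count (amine N: 2, water O: 2, carboxylate oxygens: 0,
  carbons per structure). Formal charges (M²⁺, carboxylate⁻) are
  ignored: neutral-atom electron counts are used throughout.
- **Determinism.** Vertices are created in a fixed canonical order
  (metal, then each ligand backbone-to-side-chain, waters last), so path
  listings and file outputs are byte-for-byte reproducible.

Graph topology depends only on the ligand and species; metals differ
solely in the vertex weight of M (tested by isomorphism across metals).

## Valence deltas and the index

δᵛ = (Zᵛ − H)/(Z − Zᵛ − 1), with the denominator equal to 1 for
second-row atoms. For the metals the neutral-atom d+s electron count is
used (Mn 7 … Cu 11) with a core of 17, giving δᵛ(Ni) = 10/17 ≈ 0.588.
No oxidation-state correction is applied; the reproduction checks
confirm this convention against all thirty published index values.

³χᵛ is computed by exhaustive depth-first enumeration of simple paths
(all vertices distinct), each undirected path counted once in canonical
orientation. The graphs have at most 21 vertices, so exhaustive
enumeration is instantaneous; orders 1–10 are supported though only
n = 3 is used. An independent brute-force oracle (testing every
(n+1)-tuple of vertices for path-ness) backs the enumeration in the
test suite on random graphs.

**Delta precision.** Vertex weights are truncated to three decimal
places by default (`delta_decimals=3`). Descriptor programs carry
fixed-precision weights, and this convention reproduces all thirty
published reference indices to half a unit in the last printed digit
(worst deviation 0.0048), whereas exact rational deltas leave three
bis-complex values 0.0001–0.0006 outside that band. The difference
between the two conventions is below 1.5×10⁻³ on every complex and has
no visible effect on the regression (coefficients move by well under
one standard error). Exact deltas are available with
`delta_decimals=None`.

## The simultaneous regression model

For metals {Mn, Fe, Co, Ni} and ligands {glycine, alanine, valine,
leucine}:

    log K = a₁x² + a₂x + a₃·χ_Ni + b,   x = χ(MB) − χ(NiB)

with mono-complex indices for log K₁ and bis-complex indices for
log β₂. The x-normalization places Ni at x = 0, so the quadratic pair
(a₁, a₂) carries the metal trend and the χ_Ni term the (linear) ligand
trend. The Ni index of a ligand is the reference even where Ni itself
has no measured constant (valine). Cu is hard-excluded from fitting
with a descriptive error: its complexes sit far above the quadratic
trend of the other four metals, which the per-ligand quadratic
diagnostic quantifies (deviation of observed Cu from the extrapolated
parabola, positive for every ligand). Per-metal linear fits of the
constants against χ (negative slope for every metal, Cu included) are
the other diagnostic.

- **Estimation** is ordinary least squares on the full-rank 4-column
  design (x², x, χ_Ni, 1); a rank-deficient design raises, it is never
  regularized silently. 12 records enter the log K₁ fit and 14 the
  log β₂ fit.
- **Quality statistics.** r is the Pearson correlation of observed vs
  fitted. The standard error of estimate uses the N−1 denominator,
  S.E. = √(Σr²/(N−1)); this convention, rather than N−p, matches the
  published summary statistics and is applied identically to the
  cross-validation residuals: S.E._cv = √(ΣΔX²_cv/(N−1)).
- **Leave-one-out** refits on N−1 records and predicts the held-out
  one; the maximum absolute cv residual is reported alongside S.E._cv.

The published per-complex estimates are matched (to ±0.05) by both the
in-sample fitted values and the LOO predictions; the reproduction
report accepts whichever of the two flavors is closer, since the two
are numerically near-identical at these sample sizes.

## Experimental data

The packaged table holds the 18 literature records (metal, ligand,
log K₁, log β₂) selected for consistent conditions (25 °C, I = 0.01
mol L⁻¹ or I → 0; the three Fe entries at 20 °C). Missing measurements
(Fe/alanine and Fe/valine log K₁; the entire Ni/valine and Fe/leucine
pairs) are explicit absences, never sentinels, and all rows are
weighted equally in fitting. Zn has no usable data and is excluded.

## Numerical and testing notes

- Path sums are accumulated in canonical path order in double
  precision; reproduction tolerance against printed values is half a
  unit in the last printed decimal (±0.005 on indices).
- The synthetic parameter-recovery test generates responses from known
  coefficients on the real χ design with Gaussian noise σ = 0.05 (about
  the experimental scatter of the constants) under a fixed seed, and
  requires recovery within three standard errors. It exercises the
  estimator, not the chemistry: passing it says nothing about model
  adequacy on new ligand classes.
- Everything is deterministic end to end; two identical runs of
  `chelstab reproduce` produce byte-identical CSVs.

## Limitations

- The graph model ignores 3D geometry, cis/trans isomerism of the bis
  complex, protonation equilibria and solvent structure beyond the two
  explicit waters; it cannot distinguish stereoisomers.
- The model is calibrated on four aliphatic α-amino acids and four
  metals; extrapolation to functionalized side chains, other donor
  sets, or Cu/Zn is outside its validated domain.
- With 12–14 points and 4 parameters the coefficient standard errors
  are wide; the model's strength is interpolation within the series,
  not mechanistic inference.
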