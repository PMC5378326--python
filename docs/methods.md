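# Methods

This note records how `deltol` computes what it computes, the defaults and
why, and what the synthetic benchmarks do and do not demonstrate.

## Structural features

**Structure model.** PDB text is parsed (via gemmi) into an ordered
residue/atom model keyed by author chain, residue number and insertion
code; mutant positions use the same author numbering.  Hydrogens are
dropped (crystal structures typically lack them, and standard WCN/ASA
practice is heavy-atom only).  Alternate locations keep the
highest-occupancy copy, ties broken by file order.  HETATM groups are
excluded by default; `include_het={"CRO"}` treats a named het group (such
as a mature GFP chromophore) as a pseudo-residue when one wants its atoms
to contribute contacts and occlusion.  Whether to include it is a genuine
modelling choice — a chromophore is covalently part of the chain but
chemically nonstandard — and the default here is exclusion.

**Side-chain centers.** The reference point of a residue is the arithmetic
mean of its side-chain heavy atoms, defined as all heavy atoms except the
backbone set {N, CA, C, O, OXT}.  Glycine has no side chain and uses Cα;
any other residue with no modeled side-chain atoms falls back to Cα with
the method flagged, so downstream tables can report how often the fallback
fired.

**WCN.** `WCN_i = Σ_{j≠i} r_ij⁻²` over the side-chain centers, in Å⁻².
Computed from the full pairwise distance matrix; coincident centers are an
error naming the offending pair rather than a silent infinity.  The
implementation is checked against an independent O(N²) double-loop oracle
to machine precision, and satisfies the exact scale law WCN → WCN/c² when
coordinates are multiplied by c.

**ASA and RSA.** Solvent-accessible surface area uses the Shrake–Rupley
construction: each atom's sphere of radius r_vdw + probe (probe 1.4 Å, the
water radius) is sampled at `n_sphere_points` lattice points, a point
counts as accessible if it lies outside every other atom's expanded
sphere, and a residue's ASA sums its atoms.  Two numerical choices matter:

- the quadrature lattice is a deterministic Fibonacci (golden-angle)
  spiral, so ASA is bit-for-bit reproducible for a fixed point count;
  at the default 960 points the isolated-sphere case is exact and
  multi-atom values are rotation-stable to a few percent (per-atom
  binomial quadrature noise ≈ √(p(1−p)/960) of the sphere area);
- van der Waals radii are packaged constants (C 1.70, N 1.55, O 1.52,
  S 1.80, P 1.80, Se 1.90 Å); an unknown element is a hard error rather
  than a guessed radius.

RSA divides a residue's ASA by the maximum ASA of that amino-acid type in
an extended Gly-X-Gly tripeptide (the theoretical normalization constants
of Tien et al. 2013, packaged as data).  RSA > 1 is possible (crystal
contacts, conformational strain) and is retained but logged, not clipped.
A dedicated test cross-checks the ASA implementation against Biopython's
independent Shrake–Rupley on the same structure, radii and probe.

ASA from sphere-sampling differs numerically from DSSP-style algorithms by
a few percent per residue; RSA rank order, which is what the classifiers
consume, is insensitive to this at the accuracy the pipeline needs.

## Design scores

A deletion mutant's design predictor is the plain arithmetic mean of its
model total scores (nominally 100 models per mutant; Rosetta-style, lower
= better).  No trimming or best-of selection: the mean is what downstream
models use, and a count other than the nominal one warns rather than
fails, since modelling pipelines occasionally drop a few structures.
Score tables are accepted in whitespace-delimited and CSV dialects,
auto-detected from the header.

## Classification and evaluation

**Encoding.** Continuous predictors enter as-is.  SS expands to indicator
columns; the logistic design drops the reference level (helix,
alphabetically first) for identifiability, while the SVM and the PCA keep
all three indicators (the kernel and the correlation decomposition are
happy with the redundancy, and keeping all three makes the loadings
directly interpretable).

**Logistic regression** is a maximum-likelihood logit fit (statsmodels).
Small, strongly separated training folds can separate perfectly; the fit
detects this, logs it, and returns the iteration-capped coefficients —
their predicted ranking is still well defined, which is all ROC pooling
needs.  A singular Hessian (e.g. a constant indicator column inside a
small training fold) triggers a BFGS refit.  Logistic features are not
standardized: the MLE is equivariant to affine rescaling.

**SVM** is a soft-margin RBF-kernel classifier (scikit-learn) with cost
C = 1 and γ = 1/d, d the number of encoded columns — the classical e1071
defaults.  Features are standardized with training-fold statistics before
fitting (mirroring that tooling's default scaling); the ranking score is
the signed decision value, not a calibrated probability.

**Pooled repeated CV.** One round draws a random partition into k = 10
folds (sizes differing by at most one; plain, not stratified — the
procedure being emulated says only "10-fold").  Each fold is scored by a
model trained on its complement, the n out-of-fold scores are pooled into
one ROC curve, and the trapezoidal AUC — equal to the tie-corrected
Mann–Whitney statistic P(s⁺>s⁻) + ½P(s⁺=s⁻), an identity the tests assert
exactly — is the round's summary.  Rounds repeat with independent
partitions (repetition r seeds its generator with seed + r); a partition
whose training complement is single-class is re-drawn and logged.  The
reported quantity is mean ± SE of the per-round AUCs, with SE = sd/√R.
Model pairs are compared by a Welch t-test on their repetition-AUC lists
(a paired variant exists for runs sharing partition seeds; unpaired is the
default since the emulated analysis does not state pairing).

**A calibration caveat that matters.** The repetition SE measures only
partition noise.  Conditional on one dataset, the mean pooled CV AUC can
sit several partition-SEs away from its over-datasets expectation, because
all repetitions share the same rows; and under a true null the pooled
statistic is additionally pessimistically biased (≈ −0.02 to −0.04 at
n = 100 here): a training fold's class balance anti-correlates with its
held-out fold's, which systematically distorts pooled ranks.  The null
calibration test therefore spreads its repetitions over 25 independent
null tables and takes the SE across table-level means — the honest error
bar for the claim "no signal ⇒ AUC ≈ 0.5" — and can certify calibration
only to the ≈0.04 resolution that dataset noise allows.  Practical
consequence for users: the ± SE printed next to a mean CV AUC quantifies
partition noise only, not how the number would move on a fresh dataset.

## Group statistics and PCA

Group contrasts use Welch (unequal-variance) two-sided t-tests, the common
default of the statistical environments this analysis style comes from.
The SS composition test is Pearson's χ² on the 2×3
{tolerated, non-tolerated} × {loop, helix, sheet} table, no continuity
correction, df = (r−1)(c−1); a zero marginal is an error, not a silent
NaN.

The PCA operates on the correlation matrix: every encoded column (RSA,
WCN, mean score, three SS indicators) is centered and scaled to unit
sample variance before eigendecomposition, which is forced by the wildly
heterogeneous units (0–1 fractions, Å⁻² packing densities, design-energy
totals in the hundreds).  Eigenvalues therefore sum to the number of
retained columns.  Zero-variance columns are dropped with a log entry.
Component signs are fixed by making each axis's largest-magnitude loading
positive, so rotations, scores and plots are deterministic.

## Synthetic data: what it emulates, what it does not

The generator produces three substrates with known ground truth:

- **point clouds / pseudo-structures** — rejection-sampled separated
  points, and compact self-avoiding Cα walks (step 3.8 Å, ≥3.5 Å
  separation, confined to a sphere of radius 2.8·n^⅓ + 3 Å) carrying 1–4
  carbon side-chain pseudo-atoms, ~10% glycines with none.  These exercise
  parsing, centers, WCN and ASA geometry (interior vs surface exposure),
  but are not protein decoys: no realistic torsions, elements, or packing.
- **feature tables** — the defaults encode the study conditions: 72
  mutants, 34 tolerated / 38 non-tolerated, tolerated class with higher
  RSA (0.45 ± 0.20 vs 0.22 ± 0.15), lower WCN (0.10 ± 0.030 vs
  0.16 ± 0.035 Å⁻²), more negative mean scores (−510 ± 8 vs −494 ± 10) and
  loop-enriched SS (loop/helix/sheet 0.55/0.20/0.25 vs 0.18/0.10/0.72).
  The class contrasts are qualitative emulations chosen once for realism
  (moderate overlap, comparable spreads), not measured values.  A second
  mode draws features first and labels from a configured logistic model,
  giving the exact ground truth needed for coefficient-recovery tests.
- **score sets** — class-conditional normal draws, 100 per mutant, and a
  binormal score generator whose theoretical AUC Φ(Δ/√(σ₀²+σ₁²)) anchors
  the AUC recovery tests.

Passing tests on these substrates demonstrates the *machinery* — feature
geometry, encoding, CV bookkeeping, rank statistics, recovery of known
generating parameters.  They do not demonstrate that the predictors carry
the same signal in real proteins, where features are correlated in ways
the class-conditional generator does not model (the real RSA–WCN
anticorrelation arises from shared geometry, not from the label), and
where label noise is experimental, not Bernoulli.

## Problem sizes and defaults

Cross-validation defaults to k = 10 with 100 repetitions.  The bundled
property checks use the sizes at which their guarantees are sharp: WCN
oracle clouds up to N = 200; ASA at 960 quadrature points; null
calibration 25 tables × 4 repetitions at n = 100; coefficient recovery 20
seeds × n = 2000; ranking-by-signal n = 200 × 100 repetitions; the
study-shaped run n = 72 × 100 repetitions — all chosen so each statistical
bound has comfortable power on a single CPU.

## Known limitations

- ASA is Shrake–Rupley quadrature, not an analytic surface; per-residue
  values carry ~1–3% quadrature noise at 960 points.
- SS is an input annotation; the package does not assign secondary
  structure from coordinates.
- No stratified CV, hyperparameter tuning, or probability calibration;
  the SVM's ranking uses raw decision values.
- The pooled CV AUC's pessimistic null bias (above) is inherent to
  pooling, not removed by this implementation.
- mmCIF input, structure repair and biological-assembly reconstruction
  are out of scope; one chain of one PDB file is the unit of analysis.
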