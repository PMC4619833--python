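# Methods

This note documents the statistical and geometric conventions behind each
step of the pipeline, the defaults and why they were chosen, what the
synthetic generator does and does not emulate, and the known limitations.

## Cleavage entropy

Specificity of substrate position Pn is the Shannon entropy of the observed
residue frequencies normalised by ln 20, so the value is 0 exactly when a
single residue type occurs and 1 exactly when all twenty standard residues
are equally frequent. Conventions:

* `0·ln 0 = 0` (standard information-theoretic limit).
* Unknown residues (`"X"`, including empty cells) are excluded from both
  numerator and denominator. Spreading them uniformly would inflate entropy
  for sparsely annotated positions; exclusion keeps the estimate a plug-in
  estimate of the conditional distribution given a known residue. Positions
  where *every* record is unknown are an error, not a zero.
* Rows are unweighted: a substrate reported several times counts several
  times, once per row. No smoothing is applied by default; an additive
  pseudocount is exposed for users with very small tables (default 0).
* Prime-side positions (P1′…) are parsed but excluded from the default
  profile; for serine proteases the non-prime side carries the specificity
  signal and the sub-pocket mapping used here is non-prime only.

The plug-in estimator's bias at the table sizes involved (hundreds to a
thousand rows against a 20-letter alphabet) is below ~0.005 entropy units,
well under the pocket-to-pocket differences the correlation step consumes.

## Ensembles, residues, sub-pockets

Ensembles are multi-model PDB files; frames must agree atom-for-atom.
Residues are always identified by the `(chain, number, insertion_code)`
triple — serine-protease (chymotrypsinogen) numbering contains insertion
codes (60A-loop etc.), so a bare residue number is ambiguous. Alternate
locations other than blank/'A' are dropped on reading.

Pocket Sn is the set of protease residues with **any** atom (hydrogens
included) within 3.5 Å of any atom of the peptide residue bound at Pn,
evaluated on a single structure (the first frame by default). Pockets may
overlap and may be empty; empty pockets are flagged, never silently
dropped. Definitions from different complexes are merged by per-pocket set
union with concatenated provenance.

Pocket aggregation of any residue-wise metric is the unweighted arithmetic
mean over the pocket's residues; a residue assigned to two pockets
contributes to both. Pockets with no covered residue yield NaN and are
excluded pairwise from correlations, with the effective n reported.

## Global Cα B-factors

All frames are rigid-body aligned onto one reference (first frame by
default, or an external structure) by the Kabsch algorithm over a chosen
selection; the SVD determinant correction forbids improper rotations, so a
mirror image can never masquerade as a fit. After this **single global
alignment** the per-residue mean-square fluctuation of the Cα atom about
its ensemble mean is converted as B = (8π²/3)·MSF (Å²). B-factors are
per-Cα, not residue-averaged over all atoms. A strictly static trajectory
returns exactly 0 (the degenerate case is short-circuited before any
floating-point averaging).

The choice of alignment selection matters: fitting on atoms that themselves
fluctuate absorbs part of the motion into the rigid-body fit (6 degrees of
freedom distributed over 3N coordinates) and deflates B. Recovery tests
therefore align on a rigid scaffold; for real proteins the practical
equivalent is aligning on the stable core rather than on the loops under
study.

## Backbone torsions and dihedral entropy

φ(i) = C(i−1)–N(i)–Cα(i)–C(i) and ψ(i) = N(i)–Cα(i)–C(i)–N(i+1), IUPAC
sign convention, values in [−180°, 180°). Chain termini lack φ/ψ
respectively; those series are absent, not padded. A C(i−1)–N(i) distance
above 2.5 Å (first frame) is treated as a chain break.

The torsion distribution is estimated by Gaussian KDE treated periodically
on the circle and integrated as S = −R ∫ p ln p dα with R = 8.314 J/(mol·K)
and **degree measure**. On this convention a uniform box of width w has
entropy R·ln w: ≈ 0 for a 1°-wide peak (the "rigid" anchor) and
R·ln 360 ≈ 48.94 J/(mol·K) for full disorder. Values are therefore directly
comparable across residues and systems, but the absolute numbers depend on
the measure convention; rank structure is the robust comparand.

Numerical choices:

* **Bandwidth**: Silverman's rule on the circular standard deviation,
  h = (4/3)^{1/5}·σ_circ·n^{−1/5} (degrees) with σ_circ = √(−2 ln R̄).
  Zero-spread samples fall back to a 1° bandwidth with a warning; a 0.01°
  numerical floor matches the finest internal grid.
* **Periodicity**: the estimate is computed by binned circular convolution
  with a wrapped-Gaussian kernel (FFT), which is the exact limit of
  duplicating the data at ±360° and renormalising over one period; the
  returned density integrates to 1 over the period to 1e−6.
* **Grid**: the public `grid_points` (default 720) sets the returned
  density grid; internally the grid is refined in powers of two until there
  are ≥ 8 bins per bandwidth (capped at 1024× the public grid), so narrow
  peaks remain resolved. Quadrature is the rectangle rule on the uniform
  circular grid (identical to the trapezoid rule under periodicity);
  doubling the grid moves entropies by < 0.05 J/(mol·K).
* `p ln p` is taken as 0 wherever the density underflows (p < 1e−300).

Estimator quality under the defaults: for von Mises torsion distributions
with κ ∈ {0.5, 2, 8} the KDE entropy is within 0.3% of the closed form
R·[ln(2π·I0(κ)) − κ·I1(κ)/I0(κ)] + R·ln(180/π) at n = 50,000 samples, and
the error decreases monotonically through n = 500 → 5,000 → 50,000.

One-dimensional torsion entropies ignore correlation between angles, so
summed values upper-bound the true backbone conformational entropy; no
mutual-information correction is attempted, and side-chain χ torsions are
out of scope.

## Hydrogen-bond occupancy

A bond is counted in a frame when the donor–acceptor heavy-atom distance is
≤ 3.0 Å **and** the D–H···A angle is within 45° of linearity (i.e.
≥ 135°) — the deviation-from-linearity reading of the angle criterion,
matching common trajectory-analysis tools. Donors are N/O atoms with a
hydrogen within 1.2 Å (first frame); acceptors are all N/O atoms; only
protease↔peptide pairs are tested. Inputs must be protonated — the angle
criterion needs explicit hydrogens, and their absence is a hard error
rather than a silently distance-only fallback.

Pocket occupancy is the ensemble-mean *number* of bonds per frame
attributed to the pocket via its protease residue (a bond is credited to
every pocket containing that residue). Values above 1 mean multiple
simultaneous bonds. Occupancy is non-increasing under stricter criteria by
construction.

## Rank correlation and convergence

Spearman ρ uses midranks for ties and is computed as the Pearson
correlation of the rank vectors, which reduces to 1 − 6Σd²/(n(n²−1))
without ties. Zero rank variance makes ρ undefined; it is reported as such,
never coerced to 0. With only six pockets, large-sample p-values are
meaningless, so an exact permutation p-value (all 720 permutations at
n = 6) is offered instead. Pockets missing a metric are dropped pairwise
and the effective n is part of the result. Correlations are computed on
pocket-level aggregates (typically n = 6), not on residue-level values.

Difference maps report complex-minus-unbound metric values on the residues
shared by both profiles; negative values mean rigidification upon binding.

Block convergence splits the trajectory into k contiguous, equally sized
blocks (remainder to the last block; default k = 10), recomputes the
chosen metric per block, and reports for every pocket pair the fraction of
blocks reproducing the full-trajectory rank order. One failing block is
logged and skipped without aborting the rest.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *statistical* structure the estimators
consume, with analytic ground truth stored alongside (never recomputed
from the estimator under test):

* substrate tables: i.i.d. draws from planted positional distributions;
  truth is the distribution's normalised Shannon entropy;
* torsion ensembles: i.i.d. von Mises (mixture) samples per residue,
  realised as Cartesian backbones by internal-coordinate chain building
  with ideal bond lengths/angles and trans peptide bonds, so torsions
  recomputed from coordinates round-trip exactly; truth from the closed
  form or 1e6-point quadrature of the analytic mixture density;
* Cα ensembles: isotropic per-residue Gaussian displacements
  (truth B = (8π²/3)·3σ²) on probe residues embedded in a rigid helical
  anchor scaffold, with optional global rigid-body jitter that a correct
  alignment must remove;
* toy complexes: hexapeptide plus planted contact/distant/donor protease
  residues; each planted bond is in ideal geometry (N···O 2.9 Å,
  collinear) with per-frame probability q, displaced to 3.9 Å otherwise —
  failing the 3.0 Å criterion while remaining inside the 3.5 Å contact
  shell, so pocket membership is state-independent.

Frames are i.i.d. by default; an AR(1) mode exists solely to stress the
convergence diagnostics. There is no force field, no solvent, no
autocorrelated collective motion, no real protein geometry beyond ideal
backbone parameters. Passing recovery tests therefore demonstrates
estimator correctness and the pipeline's plumbing — not that any real
protease behaves like the scenario.

### The thrombin-like scenario

Defaults (the scenario's study conditions): 6 pockets × 3 binding-site
residues, 20,000 frames for the flexibility ensembles, 5,000 frames for
the complex, 1,000 substrates. Planted values mirror the specificity
pattern reported for thrombin — cleavage entropy < 0.2 at P1 (strong Arg
preference), < 0.7 at P2, and 0.89–0.97 at P3–P6 — via point-mass/uniform
mixtures, with torsion concentration (κ = 64 → 0.8) and Cα σ
(0.15 → 0.90 Å) decreasing and increasing respectively in the same pocket
order. The hydrogen-bond plan copies the qualitative published occupancy
pattern (≈3.4 bonds in S1, ≈1 in S6, none in S2/S4): it is deliberately
*not* rank-concordant with specificity, so the scenario reproduces both
the strong flexibility correlations (ρ = 1 under the planted monotone
design) and the near-zero hydrogen-bond correlation. Mixing weights were
set from the target entropy values analytically, before any estimator ran.

## Other numerical conventions

* Coordinates are Å throughout; frames 0-indexed in the API, 1-indexed in
  reports; PDB round-trips preserve coordinates to the format's 3-decimal
  precision.
* Superposition requires ≥ 3 non-collinear fit atoms; collinear selections
  are a hard error (the rotation is underdetermined).
* 2D-RMSD entries are minimal pairwise RMSDs (fresh Kabsch fit per pair),
  symmetric with an exactly zero diagonal.
* All generator randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; identical (spec, seed) pairs are
  bit-reproducible.

## Known limitations

* Absolute Sφ/Sψ values depend on the KDE bandwidth/grid convention;
  published per-residue entropy tables computed with other settings will
  not be bit-reproducible. Comparisons should use ranks, as the
  correlation step does.
* The cleavage-entropy estimator is unweighted and smoothing-free; very
  small substrate tables (n ≲ 50) carry visible plug-in bias.
* Hydrogen-bond chemistry is element-based (N/O only); sulfur donors or
  acceptors and water-mediated bridges are not considered.
* No periodic-boundary handling: inputs are assumed whole molecules after
  imaging, as is standard for extracted snapshot ensembles.
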