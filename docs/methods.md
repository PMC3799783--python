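# Methods

## Model and procedure

The pipeline analyses a probe-by-sample intensity matrix **X** (m × l,
m ≫ l) with a two-class labelling of the samples (n controls, d cases,
n + d = l). Four phases:

1. **Gram-trick projection.** The Gram matrix **S** = **X**ᵀ**X** is
   eigendecomposed; the left directions **X**·EIV_S span the column
   space of **X**, and the data are re-expressed in those ≤ l
   coordinates. Directions whose Gram eigenvalue falls below 1e-10 of
   the largest are treated as numerically null and dropped (exact
   duplicate columns are removed beforehand, so this cutoff only guards
   against numerical deficiency).
2. **Class-weighted covariance.** In projected coordinates, the
   class-conditional covariances Cₙ and C_d (maximum-likelihood
   divisors n and d, not n−1) and the between-class scatter C_B are
   combined as C = a·Cₙ + (1−a)·C_d + b·C_B.
3. **Eigendecomposition.** Eigenpairs of C sorted by descending
   eigenvalue; proportions are eigenvalue/trace. The second eigenvector
   is the discriminant component: with b large, the leading eigenvector
   absorbs the class-mean difference together with the shared profile,
   so the second concentrates the dominant within-class contrast.
4. **Scoring and calling.** The discriminant eigenvector is
   back-projected to gene space; each probe's coefficient is its signed
   score S. The threshold is θ = ⌊|S|ₘₐₓ/2⌋ and calls are strict
   (|S| > θ). Probe calls aggregate to genes on the verbatim symbol
   string, so a composite locus ("HBA1 /// HBA2") is one gene.

Identity used for the PCA baseline: with a = n/l and b = 1 the combined
matrix equals the total covariance about the global mean. The baseline
is implemented exactly that way, so APCA-vs-PCA comparisons differ only
in the weights.

## Parameters

| parameter | default | meaning |
|---|---|---|
| a | 0.3 | weight of the control-class covariance; 1−a weights the cases, so a < 0.5 emphasises the minority class |
| b | 20 | weight of the between-class matrix; "large" by design so the class means load on the first component |
| k | 2 | index of the discriminant component |
| θ | ⌊\|S\|ₘₐₓ/2⌋ | integer DEG-calling threshold on the score scale |
| τ | 0.9 | within-class Pearson threshold for network edges (inclusive) |
| tol | 1e-10 | relative Gram-eigenvalue cutoff |

(a, b) can also be selected by grid search: a candidate is feasible
when cases and controls are strictly linearly separable in the plane of
the first two factor loadings. Separability is decided by convex-hull
disjointness; the reported margin is half the hull distance divided by
the pooled RMS point spread (scale-free). Ties break to smaller b, then
smaller a.

## Basis conventions and the score scale

The back-projection matrix **X**·EIV_S is not column-normalised; its
column norms are the square roots of the Gram eigenvalues. Two
conventions are provided:

* **orthonormal** (default of the core functions): columns normalised
  to unit length. This makes the basis an orthonormal frame, gives
  unit-norm score vectors, and is required for the exact equivalences
  with full-space PCA that the property tests assert.
* **raw** (default of the pipeline): the literal product, columns left
  unnormalised. Scores then live on the intensity scale of the data.

The pipeline calls DEGs in raw mode because the integer floor threshold
is only meaningful on a data-scale score: unit-norm scores have
|S|ₘₐₓ < 1 for realistic m, making θ = 0 and the rule vacuous. On
simulated intensity data of the target design, raw-mode runs produce
maximum scores near 10, thresholds of 4–5, and a first-component
proportion around 0.999 — the same regime as published analyses of this
kind — which is why raw is the convention the calling rule is paired
with. Note the floor-based θ is consequently not covariant under
rescaling of the input intensities; the threshold is defined on the
scale the data are loaded at (no log transform or renormalisation is
applied by default).

Eigenvector signs are arbitrary, so every gene-space component is
oriented to make its maximum-absolute coefficient positive; this is
applied consistently to the component and its sample-space eigenvector.

## Evaluation conventions

* AUC is the Mann–Whitney statistic U/(n_pos·n_neg) with ties counted
  half; cases are positives. The p-value is the two-sided
  normal-approximation rank test with tie correction; values below
  1e-15 are floored and displayed as "< 1e-15", never as 0. With all
  values tied the test is uninformative and p = 1.
* The combination score of a network component is the mean over member
  probes of the z-scored expression, each multiplied by the sign of the
  member's discriminant score. This rule is a convention of this
  package: it is parameter-free, monotone in each member, and uses only
  quantities the pipeline already computes.
* Network edges use the inclusive comparison CC ≥ τ; components are
  maximal connected sets (connectivity is transitive even though high
  correlation is not).

## Synthetic data

The generator emulates the unbalanced-microarray regime: per-probe
baseline intensities (Normal(8, 2), an arbitrary positive intensity
scale), a per-sample multiplicative array effect (sd 0.15) acting on the
baseline, optional correlated probe blocks driven by shared latent
factors, i.i.d. Gaussian noise (sd 1), optional exact technical
replicates of the first control column, and planted differential probes.
Defaults mirror the target design: 2000 probes, 19 controls + 10 cases,
30 planted probes at a 3-sd mean shift.

The array effect is what makes the leading component a "commonality"
axis, as in unnormalised array data. It is drawn with equal class means
so that class differences come only from the planted signal; without
this, sampling noise in the array-scale class means would be amplified
b-fold into a spurious component.

Two planted-signal modes:

* **mean**: a ±(effect·sd) shift of the case-class mean per planted
  probe.
* **case-variance**: a case-only latent factor (centred, so class means
  stay exactly equal) loading on the planted probes, together with a
  control-only distractor factor of matching strength on a disjoint
  probe set. This is the regime where asymmetric weighting matters:
  sample-fraction PCA weights the majority-class structure by
  n/l ≈ 0.66 and hands the minor component to the distractor, while
  weighting the cases by 1−a = 0.7 keeps the minority signal on the
  discriminant component.

For the case-variance scenario the effect size must clear a visibility
floor that the mean-dominance weighting itself creates: the
between-class matrix amplifies pure noise class-mean differences to an
eigenvalue of about b·(nd/l²)·m·σ²(1/n + 1/d) ≈ 1.4 × 10³ at the default
design, so the planted case variance (1−a)·n_de·effect²·(d−1)/d must
exceed it, i.e. effect ≳ 9 sd. The scenario uses effect = 10 sd. This
floor is a real property of the method — with b large, weak
minority-class variance structure is masked by mean-difference noise —
and is worth knowing when choosing b on real data.

What the generator does **not** emulate: Affymetrix probe-level physics
(MAS5/RMA summarisation, probe affinity), heavy-tailed or
intensity-dependent noise, batch structure beyond a scalar array
effect, and biological co-regulation beyond block factors. Passing
tests therefore demonstrate the algebra, the conventions and the
qualitative weighting behaviour, not performance on any particular real
dataset.

## Numerical choices and degenerate inputs

* Duplicate samples are detected by exact bitwise equality (no
  tolerance): technical replicates are exact copies, and a tolerance
  would silently merge near-replicates. The first column in file order
  represents its group; a group spanning both classes is an error.
* Eigendecompositions use symmetric solvers; exact eigenvalue ties keep
  index order (stable sort).
* Zero-variance columns make factor loadings undefined and raise;
  zero-variance probes are excluded (with a warning) from correlation
  networks and combination scores rather than propagating NaNs.
* A zero input matrix, an empty class, an empty score table and
  non-finite entries are rejected with named errors; an all-zero score
  table yields θ = 0 with a warning that nothing can be called.
* Scores are exactly scale-equivariant (raw mode) or scale-invariant
  (orthonormal mode); eigenvalues scale as c², proportions and factor
  loadings are scale-free.

## Known limitations

* The (a, b) selection criterion is in-sample separability of ≈30
  points in a plane derived from an (l−1)-dimensional supervised
  decomposition; it can be satisfied by a lucky random labelling
  (roughly 1 in 8 label shuffles on the strong-signal test fixture).
  The feasible-set margins, not bare feasibility, are the informative
  output; there is no cross-validation by design.
* The integer floor threshold couples the DEG list to the intensity
  scale of the input; data on a log scale will produce very different
  calls than linear-scale data.
* Only two-class designs, dense matrices, and complete data (no
  missing-value imputation) are supported.
* The b-amplified noise floor described above masks weak
  minority-variance signal; b = 20 is a convention, not an optimum.
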