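# Methods

This note documents the model implemented by `ncfger`, the choices made
where the method description leaves room, and what the synthetic fixtures
do and do not establish.

## Model and assumptions

The predictor treats a cell-line × drug response matrix (log IC50 or
activity area) as a partially observed table with three layers of
structure:

1. additive global effects — an overall level, per-cell-line offsets
   (generally sensitive or resistant lines), and per-drug offsets
   (generally potent or weak drugs);
2. a residual interaction signal that is locally low-dimensional, so a
   missing residual is well approximated by a non-negative linear
   combination of the residuals of a few similar drugs (or similar cell
   lines); and
3. unstructured measurement noise.

The method assumes responses are comparable across the panel (a shared
assay and normalisation), that similarity is informative of response —
molecularly similar entities respond similarly — and, for the evaluation,
that entries are missing at random.

## Estimation pipeline

**Global effects.**  Effects are estimated sequentially, each on the
residuals of the previous step, under `r = θ·x + ε` with x ≡ 1; the
per-entity estimate `θ̂_u = (Σ r·x / Σ x²)` is multiplied by
`n_u/(n_u + α₁)`, an empirical-Bayes shrinkage toward 0 that discounts
entities with few observations.  Removal then restoration is exactly
invertible, which the tests assert to 1e-12.  Entities with no data (or a
degenerate covariate) get θ̂ = 0.  The chain is the three named effects
only; the `EffectSpec` list keeps it extensible but cross-effects with
centered covariates are not implemented.

**Similarity.**  `COEF` uses molecular features only (expression Pearson
correlation for cell lines; fingerprint-bit Jaccard for drugs), `RPCC`
correlates response profiles over commonly observed entries, and `MRPCC`
is their elementwise product, the default because response-derived
similarity captures information molecular features miss.  Undefined
correlations (zero variance, overlap below `min_overlap`) become 0 rather
than NaN so neighbor ranking stays total.  The ranking similarity is
shrunk by `|U|/(|U| + α₂)` after the MRPCC product; for the COEF variant
the response-overlap counts are attached so all variants are shrunk on the
same footing.

**Weights.**  For target (u, i) with drug neighbors N, the normal
equations use mean co-products over co-observed cell lines, always
excluding the target cell line (also from the `b̄` terms and the `avg`
baseline) so cross-validation cannot leak the held-out entry.  Zero-support
pairs keep the system K×K by shrinking fully to `avg`, the mean of the
positive-support `Ā` entries among the K×K neighbor pairs (diagonal
included) — a local scope that keeps the system cheap.  The printed form of
the `b̂` shrinkage is implemented as the symmetric analog of the `Â` form,
`(|U(i,j)|·b̄_j + β·avg)/(|U(i,j)| + β)`.

**Hybrid.**  The hybrid prediction is the arithmetic mean of the two
orientation predictions on the residual scale.  Both orientations share one
global-effects model, so averaging before or after restoration coincides;
a test asserts this.  If one orientation has no candidates the other is
used alone; with none, the prediction falls back to global effects only
and is flagged.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| α₁ | 3 | counts | effect shrinkage; overall mean uses 0 (a global scalar needs none) |
| α₂ | 1 | counts | similarity support shrinkage |
| K | 10 | neighbors | neighborhood size per orientation |
| β | 500 | counts | normal-equation shrinkage toward the mean co-product |
| min_overlap | 3 | counts | below this, response correlations are set to 0 — a PCC over fewer than 3 points is ±1 noise and support shrinkage alone cannot zero it |

α₁, α₂ and K are the published operating point.  β has no published value;
500 is the convention of the neighborhood-interpolation literature this
solver follows and should be treated as a free parameter (it matters most
on sparse panels, where supports are small and the equations would
otherwise be dominated by noisy co-products).  Whether α₁ = 3 applies to
the drug effect as well as the cell-line effect is not specified; both
default to 3 and are configurable separately.  Response correlations are
computed on post-removal residuals by default (`rpcc_on="residuals"`) —
neighbor relations are measured on the same scale the model predicts in —
with `"raw"` available for comparison experiments.

## Numerical choices

- **Non-negative solve.**  `w = argmin_{w≥0} wᵀÂw − 2b̂ᵀw` is solved by
  symmetrising Â, eigendecomposing, discarding eigenvalues below
  `1e-8·λ_max` (including any negative spectrum), and running Lawson-Hanson
  NNLS on the retained square-root factor.  Â is not positive definite by
  construction: shrinkage pulls it toward `avg·J` and `avg` can be
  negative, and near-singular systems arise routinely (duplicated or
  strongly correlated neighbors).  An additive ridge was tried first and
  rejected: it leaves a near-null direction whose tiny eigenvalue amplifies
  the off-range component of b̂ by up to 1e8, which produced exploding
  predictions in cell-line-oriented cross-validation.  Spectral truncation
  leaves well-conditioned systems bit-unchanged (the oracle-equivalence
  tests check objectives to 1e-9) and gives bounded, sensible solutions on
  degenerate ones.  KKT conditions on the retained system are verified to
  1e-8 after every solve.
- **Ties and determinism.**  Neighbor ties are broken by ascending entity
  index; the predictor contains no randomness, so fixed inputs give
  bit-identical outputs.  The only RNG streams are the fold generator and
  the simulator, both seeded.
- **Degenerate inputs.**  0/0 situations (no observations, zero variance,
  zero support, empty neighbor sets) all resolve to 0 or to the
  global-effects fallback rather than NaN; every such branch has a test.
- **Quartile labels.**  Sensitive/resistant labels use linear-interpolation
  quartiles of each drug's observed responses; boundary ties join the
  extreme group, values qualifying for both extremes (degenerate spread)
  and drugs with fewer than 4 responses are labeled neither and excluded
  from the S/R averages.

## Evaluation design

Folds partition observed *entries* (not rows or columns), sizes differing
by at most one; every entry is hidden exactly once per repetition.  All
refitting — effects, similarities, weight systems — sees only training
entries, asserted by a test that poisons held-out values and checks
predictions are bit-identical.  Per-drug metrics are pooled across the
folds of a repetition rather than averaged per fold, giving each drug one
well-supported estimate; drug averages are unweighted means over drugs
with at least 2 test entries.  Reports carry both spreads — across drugs
and across repetitions — explicitly labeled, since a "±" on a drug-averaged
metric is ambiguous between the two.

Default problem sizes: the study panel is 100 cell lines × 30 drugs at 30%
missingness with 10-fold CV repeated 5 times; the full-scale 100-repetition
protocol is available through the `repeats` config.

## Synthetic data: what it emulates, what it does not

The generator produces `r_ui = μ + a_u + b_i + Σ_f λ_f p_uf q_if + ε` with
Gaussian effects and noise and a missing-at-random mask (with a logged
guard that rescues all-missing rows/columns).  Defaults: μ = 2,
σ_row = 0.5, σ_col = 1.0 (drug potency varies more than cell-line
sensitivity, as in log-IC50 panels), rank 3 with λ = 0.5 (interaction
magnitude comparable to the main effects), σ_noise = 0.3.

Molecular features are deliberately *imperfect* proxies: expression is a
noisy linear read-out of `P + distortion` and fingerprint bits are random
halfspace indicators of `Q + distortion`, with distortion s.d. 0.5.  In
real panels molecular similarity explains response-relevant similarity
only partially — that is precisely why response-derived similarity adds
information — and with no distortion the feature similarities would be
oracles for the latent structure, a regime the method does not target.  At
the default settings the expression-correlation matrix rank-correlates
with the true latent cosine similarity at Spearman ≈ 0.7 (a test enforces
> 0.5 at 500 genes).

What passing on this fixture does **not** show: robustness to structured
(non-random) missingness, to tissue-driven expression covariance unrelated
to response, to heavy-tailed or censored IC50 noise, or to batch effects
between screens.  Real-panel missingness in particular is structured by
screening design; structured masks can be passed explicitly but are not
generated.

## Known limitations

- The neighborhood model is local and cannot extrapolate for a cell line
  or drug with no observed responses at all (such entries fall back to
  global effects, or to 0 when even those are unavailable).
- Fingerprints are consumed, never computed: there is no SDF/SMILES
  parsing.
- Only expression feeds cell-line similarity; mutation, methylation or
  pathway information would enter through the same `COEF` slot but is out
  of scope.
- Duplicate entity labels are rejected rather than merged; resolving
  duplicate cell-line names across dataset releases is left to the user.
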