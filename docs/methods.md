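# Methods

This note documents the models, parameter choices, numerical conventions
and known limitations of `dyadgrid`.

## Task model

The task is a 65-trial dyadic punishment game: four interactive blocks of
15 trials (B1, B2, B3, B4) with a five-trial scripted "fake" block between
B2 and B3 (trials 31–35). Selections lie on the 10-level scale 0, 10, …, 90
cents. Trial outcomes are scheduled, identical for every dyad, and balanced
within each interactive block (five wins for each member and five ties).
The published order of scheduled outcomes is not public, so the package
ships one fixed, balanced default pattern per block; any user-supplied
pattern of the correct composition is accepted. The winner of a trial gains
50 cents and the loser loses the winner's selection.

Conventions where the task description is silent:

* **Ties** transfer nothing (no gain, no loss) — the minimal rule
  consistent with a winner-gain/loser-loss scheme.
* **Fake-block outcomes** cannot split 5 trials evenly three ways; the
  default pattern is WIN_A, WIN_B, TIE, WIN_A, WIN_B (config-overridable).
* **Non-response** costs the non-responder 100 cents and the trial,
  regardless of the schedule; the opponent wins the fixed gain. If both
  members fail to respond, both are penalized and the trial is recorded as
  a tie.

## Synthetic cohort generator

Each member i follows, with displayed punishment $d_i(t)$ and own outcome
$o_i(t)$:

```
s_i(1)   = q(b_i + eps)
s_i(t+1) = q((1 - rho_i)(b_i - delta_i * max(0, t - 35))
            + rho_i d_i(t) + gamma_i [o_i(t) = LOSS] + eps),   eps ~ N(0, sigma_i)
```

where `q` clips to [0, 90] and rounds half-up to the nearest multiple
of 10. Parameters (units: cents unless noted): baseline `b`; reciprocity
weight `rho` in [0, 1] (1 = pure tit-for-tat); loss reactivity `gamma`;
de-escalation rate `delta` (cents/trial, active only after the fake block
ends at trial 35, where the empirical decline is located); noise SD
`sigma`. This linear reciprocity rule is the simplest mechanism producing
the phenomena the task is designed to elicit — tit-for-tat convergence,
escalation under the scripted provocation, and a final-block decline — and
is fully parametrized for power and robustness studies.

The default cohort plants three dyad types matching the empirically
observed subtypes, 28 dyads in total:

| type      | n  | member baselines | rho | gamma | delta | sigma |
|-----------|----|------------------|-----|-------|-------|-------|
| both_low  | 10 | 10 / 10          | 0.3 | 5     | 0.2   | 5     |
| both_high | 10 | 75 / 75          | 0.4 | 5     | 0.5   | 5     |
| mixed     | 8  | 70 / 20          | 0.2 | 5     | 0.4 / 0.1 | 5 |

The mixed type uses a weak reciprocity weight so the two members stay
apart instead of converging. Baselines 10/75/(70, 20) put the three types
in distinct grid regions at a realistic noise level; `sigma = 5` produces
mostly ±1-level trial-to-trial scatter. Pair gender (13/28 male pairs) and
member ages (mean 23.4, SD 3.4 years, within-pair gap below 5) mirror the
study cohort's composition and are assigned independently of type. A
non-response probability is exposed (default 0 — the empirical record
reports none).

What the generator does *not* emulate: within-session learning beyond the
stated rule, cognitive or physiological processes, serial correlation in
the noise, and member-specific response styles (e.g. rounding habits).
Passing recovery tests on this generator therefore demonstrates that the
pipeline recovers types that differ in grid location and dispersion; it
does not guarantee recovery of subtler empirical structure.

## Grid sequence analysis

* **Encoding.** Interactive trials map to canonical sorted cells
  ((min, max) of the two level indices; 55-cell alphabet), making sibling
  roles interchangeable end-to-end. Fake trials map each member separately
  to (member level, scripted level) cells in scripted order. Trials with a
  missing selection are dropped from the sequence (OM tolerates unequal
  lengths) and logged.
* **Costs.** Substitution is the Manhattan distance between cells
  (maximum 18 on the grid); indel is 1 by default. On canonical cells the
  Manhattan distance equals the minimum over the two diagonal reflections
  (verified exhaustively over all 55 × 55 pairs in the tests). Both costs
  are configurable because the common sequence-analysis convention
  (indel = max substitution / 2) differs materially from indel = 1; with
  indel = 1 the effective substitution cost is capped at 2 by
  delete + insert, so dissimilarities are dominated by how often — not by
  how far — two trajectories disagree.
* **Optimal matching.** Standard edit-distance dynamic programming; the
  implementation vectorizes each row with a prefix-minimum fold and is
  checked exactly against an exhaustive edit-script enumerator.
* **Ward clustering.** Lance–Williams agglomeration directly on the OM
  dissimilarities. `ward_d` (default) updates raw dissimilarities — the
  historical "ward" behavior of the R ecosystem — and `ward_d2` updates
  squared ones, reporting square-root heights; `ward_d2` reproduces
  scipy's ward linkage exactly on Euclidean data (cross-checked in the
  tests). Minimal-pair ties break deterministically toward the lowest pair
  index. Cluster labels are numbered by first appearance.
* **Choosing k.** The advisory `select_k` inspects dendrogram gap ratios:
  successive Ward merge heights grow smoothly (ratios ≈ 1–2) in
  homogeneous data but jump by an order of magnitude when a cut crosses
  real group structure. The recommendation is the feasible k (all clusters
  ≥ `min_size`, default 3) with the largest height ratio above 2.5,
  falling back to 1. It is advisory only; k remains user-settable, and the
  threshold was fixed from the contrast between homogeneous and planted
  cohorts before being frozen.

## Scoring

Per member: five block means (the fake block counts as its own block), the
interactive mean over 60 trials, zero-selection counts over interactive
and fake trials, the pre–post difference (mean of the 30 trials before the
fake block minus the 30 after), and selection means conditioned on the
member's own previous-trial outcome (the first trial, having no
predecessor, is excluded; group sizes sum to 64). Per dyad: per-block mean
and *absolute* difference of the two members' block means — members are
treated as indistinguishable, so a signed difference would be arbitrary.
The seven dyad-level scores used for cluster characterization are the
mean/difference over interactive trials, over fake trials, of the
zero-selection count, and the dyad-mean pre–post difference.

Questionnaire subscales are sum-scored with item polarity applied
(x → min + max − x) and within-respondent mean imputation of missing
items; Cronbach's α uses listwise deletion (imputation applies to sum
scores only). Undefined quantities (all-missing blocks or respondents,
zero total variance) are returned as NaN with an explicit flag, never
silently zeroed.

One ambiguity: "total" block scores are implemented as cohort averages per
block (for plotting/export); the alternative reading — averaging across
blocks per dyad — is available as the `total_mean`/`total_diff` fields.

## Inference

* **GEE manipulation check.** `dv ~ block * gender`, Gaussian identity
  link, exchangeable working correlation (independence and AR1 exposed),
  dyads as clusters, robust sandwich covariance. Term tests are Wald χ²
  on marginal contrasts — block effects averaged over the gender factor
  and vice versa — with df 4 / 1 / 4. Because a 4-df sandwich Wald test on
  28 clusters is badly anti-conservative against the asymptotic χ²
  (simulated type-I error ≈ 0.2), the default p value refers
  W(K − q)/(q(K − 1)) to F(q, K − q) — exact for a Hotelling T² of
  cluster-averaged contrasts and asymptotically identical to the χ²
  reference (`small_sample="chi2"` restores the latter). Post-hoc block
  contrasts are model-based marginal-mean differences: Wald z with robust
  SE, two-sided, Bonferroni m = 10.
* **Rank tests.** Kruskal–Wallis uses midranks with tie correction (H is
  undefined and flagged when all values coincide). Dunn's post hoc uses
  the tie-corrected pooled variance and Bonferroni multiplication (chosen
  because it exactly reproduces the published pairwise p values from their
  z statistics); Spearman p values use the t approximation
  t = ρ √((n − 2)/(1 − ρ²)). All tests are two-sided.
* **Cluster comparison.** Kruskal–Wallis per variable across clusters with
  α\* = α/7 for the seven task scores (0.007 at α = 0.05) and plain α
  otherwise; Dunn post hoc only where KW clears its α; gender balance by
  Pearson χ² (with a small-expected-count warning below 5). Radar panels
  z-normalize each variable over the cohort (ddof = 1) before averaging
  within cluster. The outcome-conditioned KW treats each member's three
  conditional means as independent observations; the within-member
  dependence this ignores is a documented property of the analysis, not
  corrected here.

## Problem sizes and determinism

The validation studies run at the study's own scale: 28-dyad cohorts,
500 null replicates for the GEE type-I estimate, 200 replicates for power
(20-cent fake-block elevation, σ = 5, tested at α = .001), 20 seeds for
the recovery median, 400 random sequence pairs (length ≤ 4 on a 3 × 3
sub-grid) for the OM oracle and 1,000 random triples for the triangle
inequality. All randomness flows from a single seed through spawned
per-stage substreams, so every stage is independently re-runnable and a
manifest (seed + config hash + version) reproduces any pipeline run
bit-identically.

## Limitations

* OM distances are not length-normalized (sequences are equal-length
  unless selections are missing); heavily missing data would need
  normalization.
* The distinguishable fake-block alphabet is restricted by the script to
  40 feasible cells; costs are coordinate-based, so the restriction does
  not change any distance.
* GEE post-hoc contrasts are model-based; running separate tests per pair
  is a defensible alternative the package does not implement.
* Cronbach's α and subscale scoring are generic; instrument-specific
  content, norms and validity are out of scope.
* With fewer than ~3 dyads per planted type, Ward clustering and the
  advisory k criterion become unstable (minimum enforced by the cohort
  spec).
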