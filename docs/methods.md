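# Methods

## Screen model

The package scores colony-array induction screens: a deletion library
arrayed in 384 format (16 rows × 24 columns) is pinned in quadruplicate to
1536-format plates (each parent position feeding a 2×2 block), one plate
pair (induced / uninduced) per query construct. Colony area is the fitness
proxy. The scoring model is multiplicative: the expected induced area of
mutant *x* under query *q* is baseline × W<sub>j,x</sub> × W<sub>i,q</sub>,
and a genetic interaction is a departure of the observed induction ratio
W<sub>ij</sub> from the product W<sub>i</sub>·W<sub>j</sub>, summarized by
S = W<sub>ij</sub> − W<sub>i</sub>·W<sub>j</sub>. All three W statistics
are ratios of medians, so the analysis is invariant to global rescaling of
areas and robust to heavy effect tails.

Medians are numpy medians (the mean of the two central values at even
counts); this convention, together with the n−1 sample variance in the
jackknife, fixes the statistics bit-for-bit.

## Normalization

Two median-based passes, both missing-aware and both rescaled to preserve
the plate median (keeping areas in their original units for the low-area
filter):

1. **Spatial**: each cell is divided by the median of its window×window
   neighborhood (default window 9, truncated at edges, missing cells
   ignored). This removes smooth multiplicative artifacts — nutrient or
   humidity gradients — while leaving isolated strain effects alone,
   because a median over ~20 strains is insensitive to a minority of true
   effects.
2. **Row/column**: each row is divided by (row median / plate median),
   then, on the result, each column likewise. Fully-missing lines are left
   unscaled.

Plate normalization (forcing all plates to a common median) is available
as an option but off by default: it assumes colony-size changes are rare,
which is wrong for induction screens where the query construct shifts the
entire distribution. The window size and the surface algorithm are this
package's own choices; median-based operators were chosen over mean-based
smoothing for robustness to the same heavy tails.

## Replicate filters

* **Jackknife**: within each quadruplicate set, replicate *i* is flagged
  when (Var(all) − Var(all∖i)) / Var(all) > 0.9 (n−1 variances). At most
  one replicate — the maximal contributor — can be flagged: two replicates
  cannot each contribute more than 90% of the variance under this
  definition, and the cap prevents cascades on small sets. Sets with
  fewer than 3 usable replicates or zero variance are left alone.
* **Low-area**: a strain whose induced+uninduced median-area sum falls
  below 400 (in the area units of the quantifier) in *any* screen of the
  set is dropped from *all* screens, so every query is scored over the
  identical strain set.

## Threshold testing

Per-strain induction responses are paired log2 differentials
d<sub>r</sub> = log2(induced<sub>r</sub>) − log2(uninduced<sub>r</sub>),
paired positionally by quadruplicate slot (slots share pinning position
and local plate context). Log areas are used for variance stabilization.
The null hypothesis centers effects on the median over strains of the
per-strain median differential — "this strain responds like the screen at
large" — and significance additionally requires the centered effect to
exceed τ = log2(1.3).

Variance moderation follows the standard empirical-Bayes construction: the
per-strain sample variances are modeled as s² ~ s0²·F(df, d0); (d0, s0²)
are fitted by matching the mean and variance of the adjusted log variances
(digamma/trigamma moments, Newton inversion of the trigamma function), and
each strain's variance is replaced by the posterior
(d0·s0² + df·s²)/(d0 + df). The composite-tail p-value is

p = P(T<sub>df</sub> ≥ (|Δ|−τ)/se) + P(T<sub>df</sub> ≥ (|Δ|+τ)/se),
df = n − 1 + d0,

which reduces exactly to the two-sided moderated t-test at τ = 0 and to
the unmoderated test at d0 = 0 (both retained as limits and used in
tests). Degenerate inputs: se = 0 gives p = 0 when |Δ| > τ and p = 1
otherwise; an all-equal variance distribution gives d0 = ∞ with s0² the
common variance. q-values are Benjamini–Hochberg within each query's
testable strains (the per-query presentation is the natural unit here;
pooling across queries would mix different null centers).

Calls: a strain is eligible only when its control-query W<sub>ij</sub>
lies in the closed window [0.7, 1.3]; eligible strains are positive when
q ≤ 0.05 and S > 0.3, negative when q ≤ 0.05 and S < −0.3. The sign
convention for "positive" follows the score direction (S > 0.3), the only
reading consistent with positive = alleviating.

## Compound mode

For screens where a second perturbation (petite [rho−] background,
hydroxyurea) replaces the arrayed mutation, the three ratios are
conditional: W<sub>i</sub> = variant baseline effect, W<sub>j</sub> =
parent's induction response, W<sub>ij</sub> = induction response *within*
the variant. Because W<sub>ij</sub> is already conditional on the variant,
independence corresponds to W<sub>ij</sub> = W<sub>j</sub>, and the score
is computed as the conditional contrast S = W<sub>ij</sub> − W<sub>j</sub>
(W<sub>i</sub> is reported alongside). The literal product form
W<sub>ij</sub> − W<sub>i</sub>·W<sub>j</sub> with these conditional
definitions would not vanish for independent multiplicative effects, which
is what "no synergy" must mean. S < −0.1 is called synthetic sick.

## Fitness-defect profiles and correlation

FD = −log2(W<sub>ij</sub>), so a fitness *defect* on induction is
positive; the opposite sign is a configuration switch since reference
matrices differ in convention (correlations flip sign coherently either
way). Profiles are correlated against each experiment of a reference
strains × experiments FD matrix by pairwise-complete Pearson correlation
(the reference is sparse across experiments); p-values use the exact
t-transform with n−2 df, BH adjustment runs across reported experiments,
and q ≤ 0.01 is significant. Experiments sharing fewer than 30 strains are
skipped — t-transform p-values are unreliable at small n — as are
zero-variance vectors. Only strains passing the screen filters enter the
profile.

## Synthetic screens

The generator produces the same plate/layout/manifest artifacts the reader
consumes, with planted truth: per-strain log-normal baselines (default
median 500 area units, log-sd 0.15, placing typical colonies comfortably
above the low-area threshold), a per-query induction effect W<sub>i</sub>,
planted interaction factors I drawn from configurable ranges (none on the
control query), a smooth multiplicative plate surface (random quadratic in
normalized coordinates, exponent-scaled so max/min = 1 + amplitude),
log-normal replicate noise with median 1 and configurable CV, optional
single-replicate outlier shocks (exactly the case the jackknife targets),
and missing colonies recorded as absent (area 0 is a legitimate dead-spot
measurement and is produced instead via I ≈ 0). The planted score is
W<sub>i</sub>·(I − W<sub>j</sub>) with W<sub>j</sub> = 1 by default; a
slow-grower option exercises the W<sub>j</sub> term. Identical config and
seed give bit-identical output.

What the generator does *not* emulate: pinning-order spatial
autocorrelation beyond the smooth surface, agar-edge growth advantage,
competition between neighboring colonies, batch effects across plates of
one condition, and the artifact structure of any particular scanner.
Passing tests therefore demonstrate correctness of the statistics and
calibration under the stated noise model, not robustness to every real
plate pathology.

## Default study conditions in the checks

The acceptance checks run at sizes chosen to exercise the full plate
geometry while staying desk-scale: oracle agreement on a 4-query ×
500-strain screen; null calibration and recovery on 2,000-strain screens
(noise CV 0.1, 4 replicate pairs, 3 seeds); variance-prior recovery at
5,000 strains (d0 = 4, s0² = 0.04); correlation null at 1,000 shared
strains × 200 experiments (10 seeds). Recovery screens plant 5%
interactions with factors in (0.2, 0.4) ∪ (2.0, 2.5) against
W<sub>i</sub> = 0.9, giving every planted |S| ≥ 0.5.

## Known limitations

* The spatial surface division is exactly transparent only where the local
  median equals the plate median; on plates where a majority of colonies
  in some window carry true effects, normalization will absorb part of the
  effect. This mirrors the assumption of every local-surface normalizer.
* The jackknife's one-flag cap means a replicate set with two gross
  outliers keeps both; such sets are usually removed later by the q-value
  or the low-area filter.
* Compound-mode inputs are summary medians; no variance is propagated, so
  the S < −0.1 call carries no p-value.
* The moderated test assumes approximately log-normal replicate noise;
  gross departures inflate the prior's d0 estimate rather than breaking
  the test, but calibration is only verified under the generator's model.
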