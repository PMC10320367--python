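# Methods

## The indices

**SEMA-CD.** Two bowel regions are graded on an ordinal 0–4 scale (0
endoscopic remission … 4 severe disease, or "not assessed"): the terminal
ileum and the colon as a whole, the latter graded by its most severe
segment. The reader also flags which of the four colonic segments
(ascending, transverse, descending, rectum) show any active disease. The
total is `ileum + colon × n_involved`, range 0–20. Conventions implemented:

* `colon = 0 ⇔ involved set empty` is enforced at validation (the overall
  colon grade is that of the worst involved segment, so a nonzero grade
  requires a flagged segment and vice versa).
* A not-assessed region contributes nothing; the total is computed from the
  assessed region alone and flagged *partial*. Partial totals are allowed
  into downstream analyses as recorded, and the flag is propagated into the
  scored table and counted in the report. Severity classification of partial
  totals is permitted. (Whether such videos should enter the correlation
  analyses at all is a judgement call; keeping them with a flag preserves
  auditability and the complete-case alternative is one filter away.)
* Ileocecal-valve strictures are represented as an elevated ileum grade by
  the data generator; the calculator has no special case.
* Severity bands are realised as half-open real intervals [0,1) inactive,
  [1,2) minimal, [2,5) mild, [5,10) moderate, [10,20] severe. On integers
  these reproduce the candidate cutoffs (0 / 1 / 2–4 / 5–9 / ≥10) exactly
  and give a total, deterministic rule for the half-integer medians that
  two-read videos produce.

**SES-CD (comparator).** Five segments (ileum, right colon, transverse
colon, left colon, rectum), four items each (ulcer size, ulcerated surface,
affected surface, narrowing; 0–3), summed over assessed segments with no
renormalisation for missing segments. Severity strata on integers: 0–2
inactive, 3–6 mild, 7–15 moderate, ≥16 severe.

## Reading workflow

Each video receives two blinded primary reads; if the totals differ by
**strictly more than 5 points** a standby adjudicator provides a third read
(a difference of exactly 5 does not adjudicate). The final score is the
median of the available totals — mean of two, middle of three. Re-reads
(default 15% of videos, round-half-up, reassigned to one of the original
readers after a ≥14-day gap; 22 days by default) are used for intra-rater
analysis only and never enter the final score or trigger adjudication.
Primary pairs rotate round-robin over the unordered reader pairs (max−min
pair load ≤ 1); no assignment scheme is prescribed by the study design, so
balance is best-effort. When one read is partial and the other full, the
adjudication trigger compares the totals as recorded and a data-quality
warning is logged.

## Statistics

* **Spearman ρ** (average ranks, via `scipy.stats.spearmanr`) with a
  Fisher-z interval using the Bonett–Wright standard error
  `sqrt((1+ρ²/2)/(n−3))`; a Fieller–Hartley–Pearson variant
  (`sqrt(1.06/(n−3))`) is available behind a flag. ρ ≥ 0.6 is flagged as the
  meaningfulness threshold. Requires n ≥ 4 complete pairs and non-degenerate
  vectors.
* **ICC**: one-way random effects with video as the random effect. A fully
  crossed video×reader design does not exist when pairs rotate over a
  4-reader pool, so the reader factor is absorbed into the residual. Point
  estimate by ANOVA method of moments on balanced tables and REML
  (`statsmodels` MixedLM) on unbalanced ones (adjudicated videos contribute
  three reads), truncated at 0. Interval: exact F for balanced data,
  Satterthwaite-style via the effective group size n0 otherwise. Bands:
  <0.50 poor, [0.50,0.75) moderate, [0.75,0.90] good, >0.90 excellent (the
  0.90 boundary is assigned to "good" since the printed scale says
  ">0.90 excellent"). Intra-rater ICC applies the same estimator to the
  (initial read, re-read) pairs.
* **Weighted Cohen kappa** on the 5-band severity scale for each of the 6
  reader pairs, linear disagreement weights `|i−j|/(k−1)` by default
  (quadratic behind a flag; no scheme is canonical for this design), with
  the Fleiss–Cohen–Everitt large-sample variance and a normal interval.
  Bands: <0.41 below-moderate, 0.41–0.60 moderate, 0.61–0.80 good,
  >0.80 very good. The overall kappa is the inverse-variance-weighted mean
  of the pairwise kappas — mirroring the pooling used for mean
  differences — with variance `1/Σwᵢ`.
* **Mean differences**: per-stratum mean and variance of the mean, pooled by
  inverse variance (strata = reader pairs for inter-rater, readers for
  intra-rater; fixed sign convention: id-sorted first reader minus second).
  Strata with n < 2 are dropped with a warning. Zero-variance strata
  (identical reads throughout, e.g. the noiseless limit) carry infinite
  weight, and the pool degenerates to the mean of those exact strata.
* Missing data are complete-case per analysis; no imputation and no
  multiplicity adjustment anywhere.

Degenerate inputs raise typed errors rather than returning NaN: correlations
with zero variance, kappa with expected agreement 1, ICC with no replicated
videos. The pipeline report catches these per stratum and records the reason
(small severity strata of near-constant scores genuinely produce undefined
correlations).

## Synthetic study generator

The generator emulates the *layout* of a two-trial validation study:
110 patients (configurable), ~33% pediatric, one pre- and one
post-treatment video each, a 4-reader pool, double reads with >5-point
adjudication, 15% re-reads, and a video-quality label ("optimal" with
probability 0.482).

* **Latent severity.** One scalar θ per video drives all five segments
  through a cumulative-ordinal link: segment grade = number of thresholds
  (2, 4, 6, 8) exceeded by θ + jitter, with segment-specific shifts
  (distal colon shifted up, i.e. less frequently involved) and
  N(0, 1) jitter. This is the simplest structure that yields ileum-only,
  colon-only and mixed involvement patterns.
* **Baseline severity mix.** A band (inactive/mild/moderate/severe on the
  baseline SES-CD scale) is drawn per patient from the configured mix
  (defaults 4.5/19.1/40.9/35.5%, matching the trial population the layout
  emulates); θ and the segment grades are then rejection-sampled until the
  realised SES-CD total falls in the drawn band, so the realised marginal
  matches the mix up to multinomial noise exactly.
* **Treatment effect.** θ_post = θ_pre − Δ with Δ ~ N(1.5, 1.5²), clipped to
  the latent support [−2, 10]. The default produces modest median
  improvements comparable to an effective-therapy trial arm.
* **Ground-truth scores.** SES-CD items are a fixed monotone map of the
  segment grade — grade g ↦ (ulcer size, ulcerated surface, affected
  surface, narrowing) = (0,0,0,0), (1,1,1,0), (2,1,1,1), (2,2,2,2),
  (3,3,3,3) — chosen so grade 0 is all-normal and grade 4 saturates ulcer
  size and narrowing. The true SEMA-CD rating is the ileum grade plus the
  max colonic grade with involvement flags. Comparator SES-CD totals are
  taken noiselessly from this ground truth: the trial's SES-CD readings came
  from a separate reader pool whose error process is uncharacterised, so no
  defensible noise model exists for them.
* **Reader noise.** Region-level ordinal misclassification: each region
  grade is kept with probability `p_exact` (default 0.8 per reader, no
  bias), else moved one step (direction biased by the reader's bias
  parameter), clipped to 0–4. Involvement flags stay consistent with the
  perturbed colon grade (a 0 empties them; a false-positive colon grade
  flags one random segment). NOT_ASSESSED is never perturbed. Ileum
  non-intubation (without stricture) occurs with probability 0.02 per video
  and emits NOT_ASSESSED.
* **Usability.** The 7-point ease-of-scoring rating is a categorical draw
  per reading (majority "easier", ~0.4% "slightly more difficult") and is
  only tallied, never analysed inferentially.
* Everything is driven by `numpy` Generators spawned from the single config
  seed; identical seeds give byte-identical CSV and JSON outputs. Report
  provenance records the config hash and seed (no wall-clock timestamp, to
  keep reports reproducible byte for byte).

**What the generator does not emulate** — and hence what green tests do not
show about real data: correlated errors between readers viewing the same
video, segment-level reader disagreement (noise is region-level), drift or
learning effects across reads, SES-CD reader noise, dependence of video
quality on disease severity, and any pediatric/adult difference beyond the
cohort label. Statistics computed on synthetic data characterise the
pipeline under a known noise model, not the measurement properties of the
index in the clinic.

## Problem sizes and tolerances in the test suite

Simulation-based checks use sizes where Monte-Carlo error is comfortably
inside the asserted tolerance: 2,000 videos for inter-rater ICC recovery
(±0.05 against a noise-model oracle with 200 replicate reads per video),
10⁵ draws for the adjudication-probability law (3 combined standard errors),
500 replicates at n = 50 (Spearman) and 30×2 (ICC) for ≥90% empirical
coverage of the nominal 95% intervals, and 1,000 random tables for the
weighted-kappa brute-force oracle. The default study (n = 110) runs in well
under a second.

## Known limitations

* The one-way ICC treats reader identity as exchangeable noise; systematic
  reader bias inflates σ²_w rather than appearing as a reader effect.
* The Satterthwaite-style interval for unbalanced ICC designs is
  approximate; with the tiny adjudication rate the imbalance is negligible.
* Kappa pooling by inverse variance has no finite-sample optimality
  guarantee; it matches the pooling used for the mean differences.
* Partial (colon-only) totals are classified on the same severity bands as
  full totals, which understates severity when the unassessed ileum was
  diseased.
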