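# Methods

This note documents the models, rules, defaults, and numerical choices
behind the pipeline, and what the synthetic world does and does not
establish.

## The synthetic EMR world

Real EMR subtyping studies run on hospital databases that cannot be
shipped. The generator (`nafld_subtypes.synthetic`) therefore states a
world explicitly and every downstream claim is relative to it.

**Model.** Each patient is drawn from a mixture of subtypes. A
`SubtypeSpec` holds: a mixing proportion; independent Bernoulli
prevalences per feature concept (diagnoses, medications, abnormal labs,
procedures, abnormal vitals); constant hazards (events per person-year)
for death, cirrhosis, HCC, CKD, CVD and MI; and a distribution over how
the steatosis evidence appears in text (positive / negated /
family-history / absent mention). Event times are exponential
(constant hazard) and administratively censored at 2019-01-31; death
truncates the observation of other events. Exponential times were
chosen because their closed forms (`P(observed) = 1 − e^{−λh}`) make
the generator verifiable by hand.

**Defaults.** The default world has five subtypes with mixing
(0.50, 0.06, 0.37, 0.04, 0.03): two large, relatively healthy subtypes
covering 87% of patients and three small, sicker subtypes with higher
comorbidity prevalences and death hazards (0.004 to 0.30 /person-year),
mirroring the qualitative narrative of published NAFLD subtyping
(large mild clusters; a small cluster with severe liver disease, high
MELD/FIB-4, and sharply elevated mortality). Demographics: age means
47–65 (sd ~13), female fraction 0.35–0.62, Hispanic fraction 0.10–0.26
by subtype; cohort-level values approximate a diverse urban hospital
population (mean age ~53, ~51% female, ~17% Hispanic). Patients
qualify for the cohort via an ALT pair (probability 0.8), an inclusion
code (0.5), or both; 3% carry a random exclusion trigger; steatosis
notes are positive/negated/family/absent with probabilities
(0.88, 0.05, 0.03, 0.04). None of these values is fit to data; they
are a stated, plausible world.

**What it omits.** Independence across concepts (no comorbidity
correlation structure), flat event rates (no ageing, no care-pattern
seasonality), template note language, day-resolution dates, and a
vocabulary of ~60 concepts instead of thousands. A green test on this
world shows the *pipeline machinery* is correct, not that five subtypes
exist in any real population. Because the fixture vocabulary is small
(~79 features at n=500), mutually exclusive demographic indicators
carry more of the Manhattan distance than they would in a 1,145-feature
matrix; default-world clusters are therefore demographics-heavy and
only moderately stable (ARI ≈ 0.4) — reported as is. The
well-separated world (`separated_cohort_config`: each concept 0.95 in
one subtype, 0.05 elsewhere) and the pure-noise world
(`noise_cohort_config`) bracket the recovery behavior: ARI ≥ 0.9 and
|ARI| < 0.05 respectively at n=1000.

## Phenotype rules

* ALT persistence: two ambulatory results ≥ 40 IU/mL (men) / 31 (women),
  strictly more than 183 days apart ("more than 6 months", read
  conservatively in day arithmetic). The qualifying date is the second
  date of the earliest qualifying pair. Unknown sex falls back to the
  stricter male threshold and is flagged in the trace.
* Inclusion codes: ICD-9 571.5/571.8/571.9, ICD-10 K75.81/K76.0/K76.9.
  ALT **or** code suffices by default (`require_both_channels` switches
  to AND; the source description is ambiguous and OR is the natural
  reading of "based on persistent ALT elevation or ICD codes").
* Exclusions are evaluated over the entire record, any time: exclusion
  codes (fixture list standing in for the eMerge enumerations), positive
  HBsAg / detected HCV RNA, any steatogenic medication order.
* Steatosis evidence: at least one positive mention (below).
* NAFLD diagnosis date = max over criteria of each criterion's earliest
  satisfaction date ("the earliest date the patient met *the criteria*"
  requires all of them); must lie in (2012-12-31, 2019-01-31].

## Text mining

Deterministic NegEx-style scanning: case-insensitive longest-first term
matching over a fixed synonym lexicon (steatosis, steatohepatitis,
fatty liver, hepatic steatosis, NASH, NAFLD); a negation cue (no, not,
absence of, without, negative for, denies, free of) within 6 tokens
before the term inside the same sentence negates it; a kinship noun in
the sentence marks family/false-positive; sentences end at periods or
newlines. The 6-token window and cue list are implementation choices —
the source method names only example patterns — and are constants in
`textmining.py`. MELD scores are extracted (first integer 6–40
following the token "MELD"), not computed from labs, matching how the
scores were collected. The same machinery drives cirrhosis and death
mentions.

## Featurization

Binary indicators only. Age bins [18–20], [21–30], …, [101+] at the
diagnosis date (integer ages make the bins exhaustive). Race categories
plus Hispanic ethnicity; Hispanic ethnicity also sets the Hispanic race
indicator. Diagnoses map ICD→phecode and keep columns with prevalence
≥ 0.001 (no rounding); procedures map CPT codes into second-level group
ranges; medications map names→ingredients and count only chronic use
(two orders ≥ 183 days apart). A lab is abnormal if its free text
matches an abnormal term (abnormal, low, below average, reactive, …) or
its numeric value falls **strictly** outside the reference range —
boundary values are normal ("outside the normal range" read strictly);
low and high are deliberately pooled into one feature per test. Vitals:
temperature > 39 °C / 102 °F (threshold applied in the recorded unit),
SBP > 130 **or** DBP > 80 (the OR reading of "> 130/80"), HR > 130,
RR > 40, pain ≥ 9; a single occurrence flags the feature.

## Clustering

Manhattan distance on the binary matrix (= Hamming count), then Ward's
criterion in the **D2** convention: the Lance–Williams recurrence with
Ward coefficients applied to squared dissimilarities, heights reported
as square roots. Ward on a non-Euclidean metric is mathematically
heterodox but is exactly the published procedure (R `hclust`,
`ward.D2`); this implementation reproduces it rather than correcting
it, and was verified against R's output during development and against
a naive O(n³) closed-form re-scanning oracle in the tests (agreement to
1e−9 on 50 random datasets). Tied merge costs — common with integer
distances — are broken by the smallest (left, right) cluster-id pair,
with a 1e−9 relative tolerance so both computation paths resolve ties
identically; under exact ties the merge order is deterministic but
depends on input order. The k-cut undoes the last k−1 merges and labels
clusters 1..k by decreasing size (ties by smallest leaf id) so subtype
1 is always the largest and serves as the regression reference. k = 5
follows the published choice; no automatic model selection is offered.

## Subtype profiling

Each subtype vs all remaining patients: Pearson chi-squared without
continuity correction on the 2×2 table per binary feature (constant
features excluded and logged; zero-margin tables return NaN and are
flagged). One-way ANOVA and the tie-corrected normal-approximation
rank-sum test are provided for continuous summaries. All p-values of a
run are adjusted together with Benjamini–Hochberg — the standard
default when a study specifies only "false discovery rate" — and
significance is q < 0.001.

## Survival analysis

Time runs from the NAFLD diagnosis date. Evidence on/before day 183
(inclusive, "prior to or within 6 months") marks a prevalent case,
excluded from fitting. Death before the outcome is a competing event
(code 2). Censoring is administrative at 2019-01-31 by default;
last-contact censoring is available (`censor_at_last_contact`) but off,
because in the synthetic world absence of events genuinely means
event-free follow-up.

* **Kaplan–Meier** product-limit for overall survival (events before
  censorings at tied times).
* **Aalen–Johansen** CIFs: `CIF_k(t) = Σ_{t_i≤t} S(t_i−) d_{k,i}/n_i`
  with S the all-cause KM; reduces to 1−KM without competing events and
  conserves `ΣCIF + S = 1` on complete data.
* **Cox**: Newton–Raphson on the partial likelihood with step-halving;
  Efron tie correction by default (Breslow available); SEs from the
  inverse observed information; 95% CI = exp(β ± 1.96·SE). Convergence
  requires both a < 1e−10 log-likelihood step and gradient sup-norm
  < 1e−6; separation/monotone likelihoods surface as `converged=False`
  with infinite CIs rather than an error.
* **Fine–Gray**: subdistribution-hazard partial likelihood where
  competing-event subjects remain at risk after their event with IPCW
  weight `G(t−)/G(T_i−)`, G the KM of the censoring distribution;
  Breslow ties; same Newton engine. With no competing events (weights
  all 1) it reduces to Cox exactly, which the tests assert to 1e−6.
  Variance is model-based (inverse weighted information); the robust
  IPCW-corrected sandwich variance is not implemented, so SEs are
  mildly anti-conservative in heavy-censoring regimes.
* **FIB-4** = age·AST / (platelets·√ALT), categories < 1.3 low,
  1.3–2.67 indeterminate (bounds inclusive), > 2.67 high, any missing
  or non-positive input → missing. The formula and cut-offs are the
  standard literature values because the source uses the category
  without defining it; labs are taken from the closest result within
  ±365 days of diagnosis. Covariates: subtype indicators (reference =
  subtype 1), age in decades, female sex, race with Hispanic-ethnicity
  precedence (reference White), FIB-4 category indicators (reference
  low, plus an explicit missing indicator).

No installed package fits Fine–Gray regression, so the Cox/Fine–Gray
engine is implemented here; lifelines (Cox) and brute-force likelihood
maximization serve as independent cross-checks in the test suite.

## Stability validation

10 repeats × 90% subsamples without replacement; distances, linkage,
k-cut and profiles are recomputed per repeat. Agreement with the
full-cohort partition is the adjusted Rand index on shared patients;
repeat clusters are matched to full-run clusters by maximum-overlap
linear assignment, and matched pairs are compared by Jaccard overlap of
their q < 0.001 enriched-feature sets. ARI + Jaccard is this package's
quantitative surrogate for the published protocol's qualitative
"similar enriched features" claim, which names no metric. Repeat seeds
derive from one master seed, so reports are reproducible bit-for-bit.

## Determinism and seeds

Every randomized stage consumes `stage_seed(master_seed, stage_name)` =
first 4 bytes of SHA-256, mod 2³¹−1. Identical config + seed reproduce
byte-identical bundles, assignments, and stability reports.

## Known limitations

* Independence of feature concepts in the generator; no planted
  correlation between comorbidities and outcomes beyond subtype
  membership.
* Template-based note text; the NLP's ≥ 99% recovery on it says nothing
  about clinical prose.
* Fixture vocabularies (phecode, CPT groups, ingredients, exclusions)
  are small stand-ins for the real terminologies.
* Model-based (not robust) Fine–Gray variance; no time-varying
  covariates; no proportional-hazards diagnostics.
* At demo scale (n = 500) rare outcomes (HCC, cirrhosis) have a handful
  of events and their fits are frequently flagged non-converged; this
  is faithfully reported, and parameter-recovery guarantees are only
  asserted at the sizes the tests use (n = 2000–3000).
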