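# Methods

## Problem and model

Blastoid high-grade B-cell lymphoma (HGBL) and B-lymphoblastic
leukemia/lymphoma (B-ALL) can be morphologically indistinguishable. The
package implements two additive scoring systems over binary
immunophenotype criteria and a rule-based decision procedure combining
them. Each criterion contributes 0 or 1 point; the total is compared with
a fixed threshold. No weights are fitted and no probabilities are
estimated — the systems are deliberately simple deterministic rules, so
the whole pipeline is exactly reproducible.

Six-point system (flow-cytometry-focused): CD45 intensity above
granulocytes, CD10 below hematogone brightness (outright negativity
counts, being below hematogone level), CD20 at or above mature-B
intensity, CD38 at hematogone brightness, TdT negativity, and MYC
activity (IHC ≥ 40% and/or rearrangement). Threshold: total ≥ 3 favors
HGBL. Three-point system (IHC-focused): BCL6 ≥ 30%, TdT negativity, the
same MYC criterion; total ≥ 2 favors HGBL, and a total of 0 — not covered
explicitly by the published rule text, which mentions scores 1–3 — is
treated as favoring B-ALL, consistent with 0 being described as definitive
for that side. "Definitive bands" are ≥ 4 / ≤ 2 (six-point) and 3 / 0
(three-point).

All percent cutoffs are inclusive (≥), and IHC percents are compared as
plain floats — inputs are whole-percent estimates in practice, so no
tolerance is applied at the boundary.

### TdT consolidation

TdT may be assessed by flow cytometry and/or IHC. The scoring call pools
the modalities: flow if known, else IHC. In dual-tested discordant cases
(observed pattern: weak partial IHC positivity with negative flow) the
flow call therefore wins; the completeness report flags such cases. The
modality-agreement statistic (`tdt_modality_concordance`) counts
dual-tested cases only.

### Combined algorithm

Step order: (1) cyclin D1 / *CCND1* exclusion (mantle cell lymphoma is a
separate, easier differential, so it is removed up front); (2) CD34
positivity — definitive for B-ALL regardless of any score; (3) score both
systems where inputs allow; (4) a single scoreable system decides only
inside its definitive band; (5) concordant favored calls decide; (6)
discordant calls are resolved by an unweighted signed tally over eight
ancillary features (NHL history, *MYC*-R, complex karyotype, *TP53*
mutation vs myeloid markers, *KRAS*, *NRAS*, B-ALL-type translocation);
unknown features contribute 0 and ties stay indeterminate. The tally is
unweighted because no weighting is published; directions follow the
reported group contrasts. The discordant-case branch structure is not
fully specified in prose anywhere, so the step order above is this
package's reading; it is configurable only by editing
`ANCILLARY_FEATURES`.

## Missing data

"Unknown" is first-class (enum token / `None`) and is never coerced to
negative. Real panels are incomplete in different ways per case — the
validation cohort's per-marker denominators differ for exactly this
reason — so scoreability is decided per case and per system
(`validate_for_system`), and unscoreable cases are reported, never
dropped. Group-comparison denominators include only assessed cases.

## Performance statistics

HGBL is the positive class. Sensitivity tp/(tp+fn), specificity
tn/(tn+fp), PPV tp/(tp+fp), NPV tn/(tn+fn), accuracy (tp+tn)/n; zero
denominators yield "not available" (None), never 0. Printed percents use
round-half-away-from-zero to the nearest integer (40/46 → 87, 33/39 → 85),
while JSON output carries full-precision fractions. Site-subgroup
evaluation restricts the positive group to one site while keeping the
whole comparison group, mirroring how the validation study reports
bone-marrow and extramedullary subgroups. Two-system concordance is
computed over cases scoreable in both systems; a case is *misleading* when
either system's favored call contradicts the gold label. The Fisher exact
test is the two-sided point-probability convention (sum of same-margin
tables with point probability ≤ observed), delegated to
`scipy.stats.fisher_exact`; the test suite checks it against an
independent exhaustive hypergeometric enumeration for every non-degenerate
table with n ≤ 30. Degenerate margins return p = 1 by convention. No
confidence intervals and no multiplicity correction are produced, matching
the scope of the statistics being reproduced.

## Fixture cohort

`build_fixture_cohort()` reconstructs, without randomness, a cohort whose
score-level structure equals the validation study's published counts: 121
HGBL (92 six-point-scoreable: 69 at ≥ 4, 23 at 3; 33 bone marrow / 59
extramedullary; 64 also three-point-scoreable, 59 at ≥ 2 and 5 misleading
at 1) and 47 B-ALL (46 scoreable: 6 at 3, 40 at 1–2; 37 jointly scoreable
partitioned 5/1/2/29 over the score cross-tabulation, with the single
doubly-misleading case CD34-positive), plus the TdT dual-modality
subtable (23 + 17 cases, 38 concordant).

Criterion-level patterns are under-determined by published totals. Each
block of cases therefore carries a fixed hand-specified pattern, chosen so
that the marker margins the downstream statistics consume are matched
exactly (CD45 72/96 vs 11/47, CD10 83/96 vs 27/47, CD38 67/96 vs 18/47,
CD34 0/96 vs 22/47, myeloid markers 0/30 vs 19/46, MYC IHC 78/93 vs 9/37,
MYC-R 87/121 vs 0/44, BCL6 6/37 in B-ALL, complex karyotype 53/57 vs
19/41, B-ALL translocations 0/57 vs 27/47, TP53 11/25 vs 6/41, KRAS 0/25
vs 7/41, NRAS 0/25 vs 9/41). Three margins cannot coexist with the
scoreable-subset sizes and are matched in proportion instead: the combined
TdT denominator (published 87/45, here 92/46, since every
six-point-scoreable case needs a TdT call), the HGBL BCL6 denominator
(published 109, here 93: any six-point-scoreable case with BCL6 assessed
would be three-point-scoreable, capping the count), and CD20 (published
denominator 65 with 72% positive, here 92 with 67%). The flow-only TdT
count (5 positive of 30 flow-tested HGBL) is exact. Within blocks,
remaining free choices (which cases are bone-marrow, dual-tested, or
mutation-panel members) are assigned by fixed position, so rebuilds are
byte-identical; `verify=True` re-checks every invariant after
construction.

Cases outside the scoreable subsets are emitted with the relevant fields
unknown, so subset sizes emerge from `validate_for_system` rather than
being hard-coded. The 64-case joint subset is nested inside the 92-case
six-point subset (the overlap structure is only partially published; full
nesting is the simplest consistent reading).

## Synthetic cohorts

`generate(CohortSpec)` draws each case by independent Bernoulli variables,
one per feature, at its group's prevalence. Defaults are the validation
cohort's marginal frequencies (bundled, with per-value provenance
comments, in `data/default_cohort_spec.yaml`); the MYC criterion
prevalence is set to the MYC-IHC marginal (0.84 HGBL / 0.20 B-ALL) because
the composite criterion is not published as a single number. Published
tables constrain only marginals, so independence is the honest default;
correlation enters solely through the atypical-mixture mechanism
(`atypical_fraction`, default 0): an atypical case draws its
`swap_features` (default: the seven criterion-level features) from the
*opposite* group's prevalences, emulating aberrant immunophenotypes
without inventing a correlation matrix. The MYC rearrangement flag is
drawn conditionally on the criterion bit (probability p_R/p_crit, valid
whenever p_R ≤ p_crit, true for both groups), preserving both marginals
while keeping rearrangement a subset of MYC-criterion-positive cases.

Seeding: `default_rng([seed, group, index])` per case, so growing a cohort
never reshuffles existing cases. Synthetic cases have no missing fields;
they exercise scoring and evaluation, not missingness handling. What
passing simulator tests show is marginal and score-distribution fidelity
under independence — not the dependence structure, site mixture or
missingness patterns of real cohorts, which only the fixture (partially)
and real data (fully) carry. `analytic_score_distribution` provides the
exact enumeration (2^6 or 2^3 patterns) used as the simulator's
closed-form cross-check (chi-square at α = 0.01; sparse tail bins pooled
to expected counts ≥ 5; Monte-Carlo sizes 4000–5000, which keep the full
suite under half a minute).

## Known limitations

- The two scoring systems are reproduced as published rules, not
  re-derived or re-optimized; no alternative thresholds are explored.
- "Extra copies of MYC" (gain without rearrangement) does not satisfy the
  MYC criterion; only rearrangement or IHC ≥ 40% counts.
- TdT IHC positivity is any reported positivity; no percent cutoff is
  applied (none is published; expression in lymphoma is typically a weak
  subset).
- The ancillary tally is unweighted and ignores narrative-only features
  (surface-light-chain status, CD45 dimness).
- The fixture reproduces published counts, not patients: within-block
  cases are exchangeable and carry identical patterns.
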