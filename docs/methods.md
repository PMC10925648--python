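# Methods

`movscreen` implements a two-stage strategy for nominating candidate
monogenic obesity variants (MOVs) in an exome-sequenced bariatric-surgery
cohort: a genotype-side triage that reduces thousands of called variants to
a handful of rare, case-private, predicted-deleterious candidates, and a
phenotype-side validation that asks whether carriers of each candidate lose
less weight after surgery — the behaviour expected of a true MOV — and show
attenuated metabolic improvement.

## The triage cascade

A variant survives triage iff all of the following hold (the conjunction is
order-invariant; the audit trail uses the order below):

1. **Consequence class.** Synonymous SNVs and unclassified consequences are
   removed. Frameshift insertions/deletions, stop-gains and stop-losses are
   kept and treated as damaging outright.
2. **Population rarity.** Every *present* allele frequency (1000 Genomes,
   ExAC) must be `< 0.05`; a value at the threshold fails. A variant absent
   from both panels passes — absence from panels of that size is itself
   evidence of rarity, and mapping "missing" to 0 would be indistinguishable
   from an observed frequency of zero.
3. **Control exclusion.** Zero carriers among the late-onset controls,
   strictly: with only 9 controls, a single control carrier is strong
   evidence against a high-penetrance early-onset variant.
4. **Deleteriousness.** Truncating classes pass automatically. A
   nonsynonymous SNV passes by consensus vote over 13 prediction tools
   (SIFT, Polyphen2 HDIV/HVAR, LRT, MutationTaster, MutationAssessor,
   FATHMM, PROVEAN, MetaSVM, MetaLR, M-CAP, CADD, fathmm-MKL): damaging iff
   `n_damaging >= ½ · n_available`, where missing calls are excluded from
   both sides. The tie at exactly half counts as damaging ("half or more").
   A variant with no available score is *indeterminate* — reported as such,
   and removed (it cannot positively qualify).
5. **Cohort carrier fraction.** At least 5% of cases must carry the variant
   (the smallest qualifying count at n = 62 is 4). This selects variants
   common enough within the case group to be screenable downstream.
6. **Gene allow-list** (optional). The literature-driven candidate-gene
   selection step, mechanized as a configurable set; no text mining.

ACMG classification is reporting-only and never filters: variants of
uncertain significance are legitimate candidates at this stage.

## ACMG evidence combination

Evidence tags (PVS1, PS1–4, PM1–6, PP1–5, BA1, BS1–4, BP1–7) come from an
external classifier and are combined, never inferred. Two engines:

* **Rules**: the literal 2015 ACMG/AMP combining table. Neither-side and
  both-side (conflict) tag sets give VUS.
* **Points** (pipeline default): very strong 8, strong 4, moderate 2,
  supporting 1; benign side −1 (supporting), −4 (strong), −8 (stand-alone);
  thresholds ≥10 pathogenic, 6–9 LP, 0–5 VUS, −6…−1 LB, ≤−7 benign. This is
  the additive heuristic used by automated classifiers, and it reproduces
  more of the externally reported classes on the bundled candidate table.

Per-tag strength overrides are accepted as *input* (an override moves a tag
between buckets in the rules engine and changes its points). They are never
guessed. Consequence of this honesty: the bundled table's two
`PM4, PM2, BP4 → LP` rows (AIM2, SNX16) are **not** reproducible at default
strengths — 2+2−1 = 3 points is VUS, and no combining rule fires. The
external classifier evidently applied a modified strength (e.g. PM4 at
strong, which under the rules engine gives 1 PS + 1 PM → LP). The default
output is VUS for these rows; `analysis/03_classify_candidates.py` reports
the mismatch explicitly. PP5/BS2 are accepted despite the later deprecation
of reputable-source criteria, because classifier output still carries them.

## Protein-consequence arithmetic

HGVS `fs*N` counts the altered residue as position 1 of the shifted frame,
so the new stop is codon `pos + N − 1` and the mutant protein has
`pos + N − 2` residues (stop never counted). `ext*N` appends N codons past
the former stop at `pos`: `(pos − 1) + N` residues. For the flagship
frameshift `p.Gly539Argfs*3` on a 556-residue kinase this gives 540.

The arithmetic is cross-checked by construction: `build_dup_fixture`
engineers a CDS of any length in which duplicating the last base of codon
`r − 1` turns Gly at `r` into Arg and terminates the shifted frame exactly
`N` codons on; `apply_single_base_dup` performs the duplication and
translates (standard nuclear code, Biopython). A property test runs this
loop over random lengths/positions/offsets; translation length must always
equal the notation arithmetic. A shifted frame that reaches the sequence
end without a stop is reported as a read-through outcome, not silently
truncated.

**NMD.** `predict_nmd` implements the canonical 50-nt rule on an exon
model in CDS coordinates: degraded iff the PTC starts more than 50 nt
upstream of the last exon–exon junction; at or within 50 nt — or with no
junction at all — it escapes (the boundary is inclusive for escape, the
common convention; configurable). The engine returns whatever the rule
dictates for the supplied transcript model. Notably, for a PTC 16 codons
(48 nt) from the wild-type terminus, no junction placement *within the CDS*
can exceed the 50-nt distance, so the rule as implemented always predicts
escape for such a variant; a degradation claim for it must rest on
junctions beyond the CDS (3′ UTR) or on non-canonical NMD, which this model
deliberately does not speculate about.

## The outcome screen

Percent total weight loss: `%TWL = 100 · (w₀ − w_t)/w₀`; negative values
(regain) are allowed. For each candidate, case carriers vs case
non-carriers are compared at months 1, 3, 6, 12 by independent t test;
controls never enter. The default is the pooled-variance Student test: on
the cohort's printed BMI summary (33.52 ± 3.54, n = 9 vs 40.13 ± 5.95,
n = 62) pooled gives p = 0.0019 (prints as 0.002) where Welch gives
0.00025, identifying pooled as the test behind the published table. Welch
is available by configuration.

The BH family is the four time points of one variant — matching per-
comparison significance marking — and is never pooled across variants. The
flag rule is `q < 0.05` at ≥ 1 time point (the threshold count is
configurable). Variants with fewer than two carriers or two non-carriers
with data at every time point are returned as *unevaluable*, never
dropped. Degenerate inputs: two zero-variance samples with equal means give
t = 0, p = 1; with unequal means p = 0.

**Lipids.** Subjects contribute to a lipid's cells only with both baseline
and month-12 values. Paired t tests compare the two visits within carriers
and within non-carriers; TC and TG are log10-transformed first (they are
right-skewed; the base is immaterial to the t statistic and log10 is the
plotting convention the analysis mirrors). Per-subject percentage change is
always computed on the raw scale; between-group independent t tests compare
those changes. Each analysis family (4 lipids) is BH-adjusted separately —
per group for the paired tests, once for the between-group tests; the
grouping of the paired-test family is a documented choice, since families
spanning groups would couple carrier and non-carrier inference. Reported q
values are the computed numbers; nothing is rounded to zero.

**Intersection check.** For a flagged variant, the set of other variants
carried by *every* one of its carriers. An empty set rules out a single
shared confounding mutation explaining the carrier group's poorer outcome.

## The synthetic cohort

The generator emulates the study conditions so every stage is testable
without any external data: 62 early-onset cases, 9 late-onset controls, one
planted rare truncating variant with exactly 8 case carriers and no control
carriers, and 30 null background variants whose genotypes are drawn
independently of all phenotypes (null association by construction).
Anthropometry is drawn per group from the published summary locations/
scales (case BMI 40.13 ± 5.95, control 33.52 ± 3.54, etc.); baseline weight
is BMI × height² with height ~ N(1.66, 0.08) m.

Weight trajectories: subject i at time t has
`%TWL_it = μ_t + u_i + ε_it − δ_t·carrier_i`, with non-carrier means
μ = (10, 18, 25, 30) percentage points at months (1, 3, 6, 12) — a typical
post-sleeve-gastrectomy curve saturating by a year — between-subject SD 3
pp, residual SD 1.5 pp, and planted carrier deficit δ = (3, 5, 7, 8) pp.
The deficit is a free parameter (the source analysis shows its effect only
graphically); the default was fixed once from a design power calculation
(≈ 8 carriers vs ≈ 54 non-carriers at d ≳ 2 for the later time points)
so that a real MOV-sized effect is recovered with high power while month 1
remains borderline, as in real cohorts. Weights are
`w₀ · (1 − %TWL/100)`.

Lipids: baselines HDL 1.15 (non-carriers) / 1.17 (carriers), LDL 3.0, TC
5.0, TG 2.0 mmol/L; month-12 per-subject percentage changes are normal with
non-carrier means HDL +27.3, LDL −15, TC −3, TG −29.5 and carrier
attenuation factors 11.5/27.3 (HDL) and 14/29.5 (TG) — the printed group
means of the study design being emulated — with change SDs (12, 12, 10, 18)
pp. Follow-up loss is missing-completely-at-random at 19% (50 of 62 cases
with complete month-12 data), erasing month-12 weight and lipids together.

Everything flows from a single integer seed (`numpy.random.default_rng`);
the same config and seed give byte-identical cohorts and pipeline outputs.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: linkage disequilibrium and relatedness, realistic
genome-wide variant counts (tens of thousands, not 31), informative
dropout, measurement error correlated across visits, non-normal %TWL tails,
and annotation errors beyond independent per-tool miscalls (rate 0.10) and
missing scores (rate 0.15). Null calibration and power results are
statements about this generative model, not about any particular cohort.

## Numerical and testing choices

* t tests come from `scipy.stats` (`ttest_ind`, `ttest_ind_from_stats`,
  `ttest_rel`); BH from `statsmodels` `multipletests("fdr_bh")`. Tests
  verify both against independent oracles: a from-definition step-up BH, a
  10⁵-permutation p for the pooled t (monotone-equivalent statistic:
  absolute mean difference), the summary/sample algebraic identity, and an
  exhaustive truth-table transcription of the ACMG combining rules.
* Null calibration: with the planted deficit at zero, the flag rate over
  500 seeded replicates must stay within 0.05 + 3·SE — the per-variant flag
  event is "any of 4 BH-adjusted q < 0.05", bounded at the nominal level by
  the Simes inequality under the positively correlated per-timepoint tests.
* Power: with the default deficit, the planted variant must be flagged in
  ≥ 90% of 200 replicates. Replicates use single-variant cohorts (the
  screen is per-variant, so background variants are irrelevant) to keep the
  full suite around twenty seconds.
* Carrier sets parsed from VCF genotypes are checked against an
  independent reader (pysam) on generated fixtures.

## Known limitations

* Zygosity is recorded but unused; the screen treats het and hom-alt
  carriers identically, as the carrier-count framing dictates.
* No covariate adjustment or longitudinal modelling — the screen is a
  deliberate reimplementation of a t-test-per-timepoint design; with 8
  carriers, mixed models would be underpowered anyway.
* The triage thresholds (5% MAF, 5% carrier fraction) are design constants
  of the screening strategy, not estimated quantities.
* Wild-type protein lengths are inputs; the bundled table fills them only
  where authoritative (printed, or implied by a stop-loss position).
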