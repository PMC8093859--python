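# Methods

## Haplotype model and scoring

A CYP2D6 haplotype is an ordered list of (core allele, copy count)
components, parsed from labels of the grammar

```
label     := component ("+" component)*
component := "*" core ("x" N)?        N >= 2, copies default to 1
```

The core identifier may not contain `*`, `+`, `/` or `x`. Parsing and
formatting are exact inverses, and the canonical label is the property
all counting keys off.

Activity values follow the CPIC activity-score system. Each core allele
is assigned a base value in {0, 0.25, 0.5, 1.0} by the allele-definition
table; the table also records the derived function class (0 → none,
0.25/0.5 → decreased, 1.0 → normal) and rejects any inconsistent pair.
A haplotype's value is Σ base × copies over components. The published
per-haplotype values state only the duplication doubling rule
explicitly; summation over components is the unique simple extension
that also reproduces the tandem arrangements (`*36+*10 → 0.25`,
`*36x2+*10 → 0 × 2 + 0.25 = 0.25`), so it is the rule implemented.
Undefined core alleles are hard lookup errors — a cohort containing an
allele missing from the definition table does not silently score.

The diplotype activity score is the sum of the two haplotype values.
Phenotype translation is defined by CPIC on a grid of attainable scores
(PM: 0; IM: 0.25–1.0; NM: 1.25–2.25; UM: > 2.25); we implement the
half-open intervals PM = {0}, IM = (0, 1], NM = (1, 2.25],
UM = (2.25, ∞), which agree with every grid value and classify
arbitrary simulated scores. The classes are ordered PM < IM < NM < UM
and the mapping is monotone in the score.

Haplotype function classes are assigned from the summed haplotype value
(0 → none, 0.25/0.5 → decreased, 1.0 → normal, ≥ 2.0 → increased,
covering duplications of normal-function alleles). Values outside that
set (e.g. a hypothetical `*1+*10` tandem at 1.25) raise rather than
guess, since no published class exists for them.

## Counting and frequency estimation

Each diploid subject contributes exactly two haplotype units; a tandem
arrangement is one atomic unit under its full label and is never split
into its gene copies. With N subjects the frequency denominator is
n = 2N.

Confidence intervals are the normal approximation
p ± z·√(p(1−p)/n), truncated to [0, 1]. The default multiplier is
z = 2 rather than 1.96: the two-sigma convention reproduces the
reference cohort's printed bounds (e.g. *10 at 72/422 gives
[13.40, 20.72] with z = 2 but [13.47, 20.65] with 1.96; the *41 and *5
rows confirm the same choice). `z` is configurable (`ci_z`).

Percentages are reported rounded half-away-from-zero to 2 decimals;
stored values keep full precision and rounding happens only at
serialisation. Class-level "rounded-sum" percentages add per-haplotype
percentages *after* rounding each to 2 decimals, because that is how
aggregate prevalences quoted from printed tables are formed (the
decreased-function total 50.48 = 17.06 + 10.90 + 6.64 + 12.09 + 0.24 +
3.55); the raw percentage is reported alongside.

The predicted poor-metabolizer fraction is the random-mating
expectation q², with q the proportion of haplotype units whose activity
value is 0.

## Hardy–Weinberg comparison

Expected genotype counts come from exact haplotype count ratios
(e.g. 151/422), not pre-rounded percentages, removing a hidden rounding
dependency: homozygote i/i → pᵢ²N, heterozygote i/j → 2pᵢpⱼN. The
statistic is Σ (O−E)²/E over the genotypes supplied — the pipeline
restricts to the genotypes observed in the cohort, so the expected
total can fall below N (189.0 of 211 on the reference cohort; the
shortfall is the probability mass of unobserved genotype cells).
Per-genotype contributions above 3.841 (the 1-d.f. critical value at
α = 0.05) are flagged.

Two degrees-of-freedom rules are provided:

- `paper` (default): df = G − 1 − k, with G the number of genotypes
  compared and k the number of distinct haplotypes (41 − 1 − 17 = 23 on
  the reference cohort) — one d.f. for the finite sample and k for the
  estimated allele frequencies.
- `conventional`: df = k(k−1)/2, the standard multi-allelic
  goodness-of-fit count when all k(k+1)/2 genotype cells enter the
  statistic.

P-values are the chi-square survival function (scipy); the test suite
cross-checks it against an independent series/continued-fraction
evaluation of the regularized incomplete gamma function to 1e-8.

When a cohort is too degenerate for the chosen rule (df < 1, e.g. a
single-genotype cohort), the summary still completes and its `hwe`
field is `None`.

## Synthetic cohorts

`sample_cohort` draws each subject's two haplotypes from a categorical
frequency vector with one seeded numpy generator threaded explicitly
(no global state). With `inbreeding_f = f > 0` the second haplotype
copies the first with probability f, the standard one-parameter
homozygosity-excess model; f = 0 is exactly the Hardy–Weinberg null the
chi-square test assumes. The default frequency vector is the bundled
cohort's 17-haplotype spectrum, so simulations exercise duplications
and tandem labels. Frequency labels must be valid star-allele labels,
since simulated cohorts flow through the same typed pipeline as real
ones.

`hwe_calibration_run` replays the full analysis per replicate —
counting, frequency estimation from the replicate itself, restriction
to the genotypes observed in that replicate — and summarises the
chi-square distribution. Calibration p-values default to the
`conventional` df rule: with a handful of common alleles essentially
every genotype cell is observed, and k(k−1)/2 is the df for which the
statistic is asymptotically calibrated (mean χ² ≈ df, rejection rate
≈ α under the null). The `paper` rule subtracts one d.f. more than the
classical count and is kept as the default only for the cohort report,
where it reproduces the published 23 d.f. Test problem sizes (3
equifrequent alleles, 500 subjects, 1000 replicates) keep Monte-Carlo
error small while the whole suite stays fast.

What the simulator does **not** emulate: genotyping error, allele
dropout or default-to-`*1` assignment, population substructure beyond
the single f parameter, and linkage between markers. Passing
calibration therefore shows the statistics are correct under the
sampling model, not that real genotyping pipelines are unbiased.

## Known limitations

- The allele-definition fixture covers the 13 core alleles observed in
  the bundled cohort, not the full PharmVar catalogue; cohorts with
  other alleles need an extended definition table.
- Increased-function single-copy alleles are not represented in the
  definition grid (no base value above 1.0); duplications are the only
  route to the increased class.
- The chi-square comparison is asymptotic; many cells in the reference
  cohort have small expected counts, which is why per-genotype flags
  and the exact-rational test oracle exist. No exact HWE test is
  provided.
- The pipeline predicts phenotype from genotype; it does not model
  drug-specific activity (for primaquine specifically, in-vitro data
  suggest some decreased-function alleles may behave as nonfunctional).
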