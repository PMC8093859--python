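"""End-to-end cohort summarisation.

``summarize_cohort`` runs the whole analysis on a genotyped cohort:
allele frequency table with confidence intervals, genotype table with
activity scores and phenotypes, phenotype and activity-score group
distributions, function-class aggregates, predicted poor-metabolizer
fraction, and the Hardy-Weinberg observed-vs-expected chi-square report.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .alleles import (
    AlleleDefinitionTable,
    PhenotypeClass,
    diplotype_activity_score,
    parse_haplotype_label,
    phenotype_from_score,
)
from .popgen import (
    Cohort,
    FrequencyRecord,
    FunctionClassSummary,
    HWEResult,
    allele_frequency_table,
    count_genotypes,
    count_haplotypes,
    expected_genotype_counts,
    function_class_frequencies,
    hwe_chi_square,
    predicted_pm_fraction,
    round_half_away,
)

__all__ = [
    "CohortSummary",
    "GenotypeRow",
    "SummaryConfig",
    "as_group_breakdown",
    "null_allele_carrier_share",
    "summarize_cohort",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SummaryConfig:
    """Tunables of the summary pipeline.

    ci_z: CI half-width multiplier on the frequency standard error.
    df_rule: "paper" (df = G - 1 - k) or "conventional" (df = k(k-1)/2).
    reported_rounding: decimals for the rounded-sum percent aggregates.
    """

    ci_z: float = 2.0
    df_rule: str = "paper"
    reported_rounding: int = 2


@dataclass(frozen=True)
class GenotypeRow:
    label: str
    subjects: int
    percent: float
    activity_score: float
    phenotype: PhenotypeClass


@dataclass(frozen=True)
class CohortSummary:
    """All cohort-level results; full precision, rounding happens at output."""

    n_subjects: int
    frequency_table: tuple[FrequencyRecord, ...]
    genotype_table: tuple[GenotypeRow, ...]
    phenotype_distribution: dict[PhenotypeClass, tuple[int, float]]
    as_group_breakdown: dict[float, tuple[int, int, float]]
    function_classes: dict[str, FunctionClassSummary]
    hwe: HWEResult | None  # None when the cohort is too degenerate to test
    predicted_pm: float
    config: SummaryConfig = field(default_factory=SummaryConfig)

    @property
    def n_genotypes(self) -> int:
        return len(self.genotype_table)


def summarize_cohort(
    cohort: Cohort,
    defs: AlleleDefinitionTable,
    config: SummaryConfig | None = None,
) -> CohortSummary:
    """Run the full analysis; deterministic and invariant to subject order."""
    cfg = config or SummaryConfig()
    n = cohort.n_subjects
    logger.info("summarising cohort: %d subjects (ci_z=%g, df_rule=%s)", n, cfg.ci_z, cfg.df_rule)

    hap_counts = count_haplotypes(cohort)
    freq_table = allele_frequency_table(hap_counts, z=cfg.ci_z)
    logger.info("haplotype units: %d distinct labels, %d units", len(hap_counts), 2 * n)

    geno_counts = count_genotypes(cohort)
    rows = []
    for label, count in geno_counts.items():
        d = _parse_canonical(label)
        score = diplotype_activity_score(d, defs)
        rows.append(
            GenotypeRow(
                label=label,
                subjects=count,
                percent=100.0 * count / n,
                activity_score=score,
                phenotype=phenotype_from_score(score),
            )
        )
    rows.sort(key=lambda r: (r.activity_score, -r.subjects, r.label))
    logger.info("genotypes: %d distinct", len(rows))

    pheno: dict[PhenotypeClass, tuple[int, float]] = {}
    for r in rows:
        cnt, _ = pheno.get(r.phenotype, (0, 0.0))
        cnt += r.subjects
        pheno[r.phenotype] = (cnt, 100.0 * cnt / n)

    groups = as_group_breakdown(rows, n)

    total_units = sum(hap_counts.values())
    freqs_exact = {lab: c / total_units for lab, c in hap_counts.items()}
    expected = expected_genotype_counts(freqs_exact, n, list(geno_counts))
    try:
        hwe = hwe_chi_square(geno_counts, expected, num_alleles=len(hap_counts), df_rule=cfg.df_rule)
    except ValueError as exc:
        # degenerate cohorts (too few distinct genotypes for the df rule)
        # still get the rest of the summary
        logger.warning("HWE test not computable: %s", exc)
        hwe = None
    else:
        logger.info(
            "HWE: chi2=%.2f df=%d p=%.3g total_expected=%.1f",
            hwe.cumulative_chi2, hwe.df, hwe.p_value, hwe.total_expected,
        )

    return CohortSummary(
        n_subjects=n,
        frequency_table=tuple(freq_table),
        genotype_table=tuple(rows),
        phenotype_distribution=pheno,
        as_group_breakdown=groups,
        function_classes=function_class_frequencies(hap_counts, defs, cfg.reported_rounding),
        hwe=hwe,
        predicted_pm=predicted_pm_fraction(hap_counts, defs),
        config=cfg,
    )


def _parse_canonical(label: str):
    from .alleles import parse_diplotype_label

    return parse_diplotype_label(label)


def as_group_breakdown(
    genotype_rows: Sequence[GenotypeRow], n_subjects: int
) -> dict[float, tuple[int, int, float]]:
    """Group genotypes by exact activity score.

    Returns AS -> (distinct genotype count, subject count, percent of N);
    scores with no subjects are simply absent.
    """
    groups: dict[float, tuple[int, int]] = {}
    for r in genotype_rows:
        g, s = groups.get(r.activity_score, (0, 0))
        groups[r.activity_score] = (g + 1, s + r.subjects)
    return {
        score: (g, s, 100.0 * s / n_subjects)
        for score, (g, s) in sorted(groups.items())
    }


def null_allele_carrier_share(
    cohort: Cohort,
    defs: AlleleDefinitionTable,
    score_set: set[float],
    null_labels: set[str],
) -> tuple[int, float]:
    """Among subjects whose AS falls in ``score_set``, the number and percent
    whose diplotype carries any haplotype in ``null_labels`` (matched by
    canonical haplotype label, so ``*4`` does not match ``*4x2``)."""
    if not score_set:
        raise ValueError("score_set must be nonempty")
    targets = {parse_haplotype_label(lab).label for lab in null_labels}
    denom = 0
    carriers = 0
    for _, d in cohort.subjects:
        if diplotype_activity_score(d, defs) in score_set:
            denom += 1
            if any(h.label in targets for h in d.haplotypes()):
                carriers += 1
    if denom == 0:
        raise ValueError(f"no subjects have an activity score in {sorted(score_set)}")
    return carriers, 100.0 * carriers / denom
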