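"""Cohort-level allele statistics and Hardy-Weinberg goodness of fit.

Counting convention: each diploid subject contributes exactly two
haplotype units, and a tandem arrangement such as ``*36+*10`` is one
atomic unit under its full label — it is never split into its gene-copy
components.  With N subjects the denominator for allele frequencies is
therefore 2N.

Confidence intervals on allele frequencies use the normal approximation
p +/- z * sqrt(p(1-p)/n) truncated to [0, 1]; the default multiplier is
z = 2 (the two-sigma convention of the population-genetics teaching
literature), configurable to 1.96 or anything else.

The Hardy-Weinberg test compares observed genotype counts with the
random-mating expectations p_i^2 N (homozygotes) and 2 p_i p_j N
(heterozygotes) computed from exact haplotype count ratios, accumulating
(O - E)^2 / E per genotype.  Degrees of freedom follow the
"restrict-to-observed" convention df = G - 1 - k (G observed genotypes,
k distinct haplotypes); the conventional multi-allelic rule
df = k(k-1)/2 is available as an alternative.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .alleles import (
    AlleleDefinitionTable,
    AlleleModelError,
    Diplotype,
    canonical_diplotype_label,
    haplotype_activity_value,
    haplotype_function_class,
    parse_diplotype_label,
    parse_haplotype_label,
)

__all__ = [
    "Cohort",
    "FrequencyRecord",
    "FunctionClassSummary",
    "HWEResult",
    "allele_frequency_table",
    "chi_square_upper_tail",
    "count_genotypes",
    "count_haplotypes",
    "expected_genotype_counts",
    "function_class_frequencies",
    "hwe_chi_square",
    "predicted_pm_fraction",
    "round_half_away",
]

#: Critical chi-square value at 1 d.f. and alpha = 0.05; per-genotype
#: contributions above it are flagged as individually significant.
CHI2_CRIT_1DF = 3.841


def round_half_away(x: float, ndigits: int = 2) -> float:
    """Round with ties going away from zero (the convention of printed tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class Cohort:
    """A genotyped cohort: one (subject_id, diplotype) pair per subject."""

    subjects: tuple[tuple[str, Diplotype], ...]

    def __post_init__(self) -> None:
        if not self.subjects:
            raise ValueError("a cohort needs at least one subject")
        ids = [sid for sid, _ in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({s for s in ids if ids.count(s) > 1})
            raise ValueError(f"duplicate subject ids: {dupes}")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, Diplotype]]) -> "Cohort":
        return cls(tuple(pairs))

    @classmethod
    def from_labels(cls, labels: Iterable[tuple[str, str]]) -> "Cohort":
        """Build from (subject_id, "hapA/hapB") label pairs."""
        return cls(tuple((sid, parse_diplotype_label(lab)) for sid, lab in labels))

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def diplotypes(self) -> tuple[Diplotype, ...]:
        return tuple(d for _, d in self.subjects)


@dataclass(frozen=True)
class FrequencyRecord:
    """One row of an allele-frequency table."""

    haplotype_label: str
    count: int
    frequency: float
    ci_low: float
    ci_high: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.ci_low <= self.frequency <= self.ci_high <= 1.0):
            raise ValueError(
                f"inconsistent frequency record for {self.haplotype_label}: "
                f"{self.ci_low}, {self.frequency}, {self.ci_high}"
            )


def count_haplotypes(cohort: Cohort) -> dict[str, int]:
    """Count haplotype units by canonical label; every subject adds two units."""
    counts: dict[str, int] = {}
    for _, d in cohort.subjects:
        for h in d.haplotypes():
            counts[h.label] = counts.get(h.label, 0) + 1
    return counts


def count_genotypes(cohort: Cohort) -> dict[str, int]:
    """Count subjects by canonical diplotype label."""
    counts: dict[str, int] = {}
    for _, d in cohort.subjects:
        lab = canonical_diplotype_label(d)
        counts[lab] = counts.get(lab, 0) + 1
    return counts


def _haplotype_sort_key(label: str):
    # labels are opaque at this layer; star-allele labels sort by their
    # numeric structure, anything else lexicographically after them
    try:
        return (0, parse_haplotype_label(label).sort_key(), "")
    except AlleleModelError:
        return (1, (), label)


def allele_frequency_table(counts: Mapping[str, int], z: float = 2.0) -> list[FrequencyRecord]:
    """Frequencies with normal-approximation CIs from haplotype unit counts.

    p = count / n with n the total unit count; CI = p +/- z * sqrt(p(1-p)/n),
    truncated to [0, 1].  Records are sorted canonically by label.
    """
    if not counts:
        raise ValueError("empty haplotype count table")
    if z <= 0:
        raise ValueError(f"CI multiplier must be positive, got {z}")
    n = sum(counts.values())
    if n <= 0:
        raise ValueError("total haplotype count must be positive")
    records = []
    for label in sorted(counts, key=_haplotype_sort_key):
        c = counts[label]
        p = c / n
        half = z * math.sqrt(p * (1.0 - p) / n)
        records.append(
            FrequencyRecord(
                haplotype_label=label,
                count=c,
                frequency=p,
                ci_low=max(0.0, p - half),
                ci_high=min(1.0, p + half),
            )
        )
    return records


def expected_genotype_counts(
    freqs: Mapping[str, float],
    n_subjects: int,
    genotypes: Sequence[str],
) -> dict[str, float]:
    """Hardy-Weinberg expected subject counts for the given diplotype labels.

    Homozygote i/i -> p_i^2 N; heterozygote i/j -> 2 p_i p_j N.  Labels must
    be canonical and reference only haplotypes present in ``freqs``.
    """
    total = sum(freqs.values())
    if not math.isclose(total, 1.0, abs_tol=1e-9):
        raise ValueError(f"haplotype frequencies must sum to 1, got {total!r}")
    expected: dict[str, float] = {}
    for label in genotypes:
        parts = label.split("/")
        if len(parts) != 2:
            raise ValueError(f"not a diplotype label: {label!r}")
        a, b = parts
        for hap in (a, b):
            if hap not in freqs:
                raise KeyError(f"genotype {label!r} references unknown haplotype {hap!r}")
        if label in expected:
            raise ValueError(f"duplicate genotype label {label!r}")
        if a == b:
            expected[label] = freqs[a] ** 2 * n_subjects
        else:
            expected[label] = 2.0 * freqs[a] * freqs[b] * n_subjects
    return expected


@dataclass(frozen=True)
class HWEResult:
    """Observed-vs-expected genotype comparison under Hardy-Weinberg.

    ``rows`` holds per-genotype (label, observed, expected, chi2
    contribution, flagged) tuples; ``flagged`` marks contributions above
    the 1-d.f. alpha=0.05 critical value 3.841.
    """

    rows: tuple[tuple[str, int, float, float, bool], ...]
    cumulative_chi2: float
    df: int
    p_value: float
    total_observed: int
    total_expected: float
    df_rule: str = field(default="paper")

    def flagged_genotypes(self) -> tuple[str, ...]:
        return tuple(label for label, _, _, _, flag in self.rows if flag)


def chi_square_upper_tail(x: float, df: int) -> float:
    """Upper-tail probability P(X >= x) for X ~ chi-square(df)."""
    if df < 1 or int(df) != df:
        raise ValueError(f"degrees of freedom must be a positive integer, got {df}")
    if x < 0:
        raise ValueError(f"chi-square statistic must be >= 0, got {x}")
    return float(stats.chi2.sf(x, df))


def hwe_chi_square(
    observed: Mapping[str, int],
    expected: Mapping[str, float],
    num_alleles: int,
    df_rule: str = "paper",
) -> HWEResult:
    """Cumulative chi-square over genotypes with per-genotype contributions.

    ``df_rule="paper"`` uses df = G - 1 - k (G genotype labels compared,
    k distinct haplotypes: one d.f. lost to the finite sample and k to
    the allele frequencies); ``"conventional"`` uses the multi-allelic
    goodness-of-fit rule df = k(k-1)/2, appropriate when all k(k+1)/2
    genotype cells are compared.
    """
    if set(observed) != set(expected):
        missing = set(observed) ^ set(expected)
        raise ValueError(f"observed and expected key sets differ: {sorted(missing)}")
    if not observed:
        raise ValueError("no genotypes to compare")
    rows = []
    cumulative = 0.0
    for label in sorted(observed, key=lambda g: [_haplotype_sort_key(h) for h in g.split("/")]):
        o = observed[label]
        e = expected[label]
        if e <= 0:
            raise ValueError(
                f"expected count for {label!r} is {e}; exclude or pool genotypes with zero expectation"
            )
        contrib = (o - e) ** 2 / e
        cumulative += contrib
        rows.append((label, o, e, contrib, contrib > CHI2_CRIT_1DF))
    k = num_alleles
    if k < 1:
        raise ValueError(f"number of alleles must be >= 1, got {k}")
    if df_rule == "paper":
        df = len(rows) - 1 - k
    elif df_rule == "conventional":
        df = k * (k - 1) // 2
    else:
        raise ValueError(f"unknown df rule {df_rule!r}")
    if df < 1:
        raise ValueError(f"nonpositive degrees of freedom ({df}) under rule {df_rule!r}")
    return HWEResult(
        rows=tuple(rows),
        cumulative_chi2=cumulative,
        df=df,
        p_value=chi_square_upper_tail(cumulative, df),
        total_observed=sum(observed.values()),
        total_expected=sum(expected.values()),
        df_rule=df_rule,
    )


@dataclass(frozen=True)
class FunctionClassSummary:
    """Per function class: haplotype units, raw percent, and the sum of
    per-haplotype percentages each pre-rounded (the reporting convention
    of printed frequency tables)."""

    unit_count: int
    raw_percent: float
    rounded_sum_percent: float


def function_class_frequencies(
    counts: Mapping[str, int],
    defs: AlleleDefinitionTable,
    reported_rounding: int = 2,
) -> dict[str, FunctionClassSummary]:
    """Aggregate haplotype units into function classes (none / decreased /
    normal / increased).

    ``rounded_sum_percent`` adds per-haplotype percentages after rounding
    each to ``reported_rounding`` decimals, reproducing aggregates quoted
    from tables that print rounded frequencies.
    """
    if not counts:
        raise ValueError("empty haplotype count table")
    n = sum(counts.values())
    per_class_units: dict[str, int] = {}
    per_class_rounded: dict[str, float] = {}
    for label, c in counts.items():
        h = parse_haplotype_label(label)
        fclass = haplotype_function_class(h, defs)
        per_class_units[fclass] = per_class_units.get(fclass, 0) + c
        per_class_rounded[fclass] = per_class_rounded.get(fclass, 0.0) + round_half_away(
            100.0 * c / n, reported_rounding
        )
    return {
        fclass: FunctionClassSummary(
            unit_count=units,
            raw_percent=100.0 * units / n,
            rounded_sum_percent=round_half_away(per_class_rounded[fclass], reported_rounding),
        )
        for fclass, units in per_class_units.items()
    }


def predicted_pm_fraction(counts: Mapping[str, int], defs: AlleleDefinitionTable) -> float:
    """Random-mating expectation of the poor-metabolizer fraction: q^2,
    with q the proportion of haplotype units whose activity value is 0."""
    if not counts:
        raise ValueError("empty haplotype count table")
    n = sum(counts.values())
    null_units = 0
    for label, c in counts.items():
        h = parse_haplotype_label(label)
        if haplotype_activity_value(h, defs) == 0.0:
            null_units += c
    q = null_units / n
    return q * q
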