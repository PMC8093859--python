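"""Reading and writing the pipeline's TSV/JSON formats.

Cohort tables are TSV with header ``sample_id  haplotype_1  haplotype_2``
(star-allele labels without the gene-name prefix).  Allele-definition
tables are TSV with header ``core_allele  activity_value  function_class``.
All files are UTF-8.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path
from typing import Any

from .alleles import (
    AlleleDefinitionTable,
    AlleleModelError,
    LabelParseError,
    parse_haplotype_label,
    Diplotype,
)
from .pipeline import CohortSummary
from .popgen import Cohort, HWEResult, round_half_away

__all__ = [
    "CohortFileError",
    "read_allele_definitions",
    "read_cohort",
    "summary_to_dict",
    "write_cohort",
    "write_frequency_table_tsv",
    "write_genotype_table_tsv",
    "write_hwe_tsv",
    "write_summary_json",
]

COHORT_HEADER = ["sample_id", "haplotype_1", "haplotype_2"]
ALLELE_HEADER = ["core_allele", "activity_value", "function_class"]


class CohortFileError(ValueError):
    """A cohort or allele-definition file is malformed; messages carry row numbers."""


def read_cohort(path: str | Path) -> Cohort:
    """Read a cohort TSV; errors name the offending row and token."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFileError(f"{path}: empty file") from None
        if header != COHORT_HEADER:
            raise CohortFileError(
                f"{path}: bad header {header!r}, expected {COHORT_HEADER!r}"
            )
        pairs = []
        seen: set[str] = set()
        for rownum, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise CohortFileError(f"{path}: row {rownum}: expected 3 columns, got {len(row)}")
            sid, hap1, hap2 = (c.strip() for c in row)
            if not sid:
                raise CohortFileError(f"{path}: row {rownum}: empty sample_id")
            if sid in seen:
                raise CohortFileError(f"{path}: row {rownum}: duplicate sample_id {sid!r}")
            seen.add(sid)
            try:
                d = Diplotype(parse_haplotype_label(hap1), parse_haplotype_label(hap2))
            except LabelParseError as exc:
                raise CohortFileError(f"{path}: row {rownum}: {exc}") from exc
            pairs.append((sid, d))
        if not pairs:
            raise CohortFileError(f"{path}: no subject rows")
    return Cohort.from_pairs(pairs)


def write_cohort(cohort: Cohort, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(COHORT_HEADER)
        for sid, d in cohort.subjects:
            h1, h2 = d.haplotypes()
            writer.writerow([sid, h1.label, h2.label])


def read_allele_definitions(path: str | Path) -> AlleleDefinitionTable:
    """Read an allele-definition TSV; value/class consistency is enforced."""
    path = Path(path)
    entries: dict[str, tuple[float, str]] = {}
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise CohortFileError(f"{path}: empty file") from None
        if header != ALLELE_HEADER:
            raise CohortFileError(f"{path}: bad header {header!r}, expected {ALLELE_HEADER!r}")
        for rownum, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != 3:
                raise CohortFileError(f"{path}: row {rownum}: expected 3 columns, got {len(row)}")
            core, value_s, fclass = (c.strip() for c in row)
            try:
                value = float(value_s)
            except ValueError:
                raise CohortFileError(f"{path}: row {rownum}: bad activity value {value_s!r}") from None
            if core in entries:
                raise CohortFileError(f"{path}: row {rownum}: duplicate core allele {core!r}")
            entries[core] = (value, fclass)
    try:
        return AlleleDefinitionTable(entries)
    except AlleleModelError as exc:
        raise CohortFileError(f"{path}: {exc}") from exc


def write_frequency_table_tsv(summary: CohortSummary, path: str | Path, ndigits: int = 2) -> None:
    """Allele-frequency table (label, count, percent, CI bounds) as TSV."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["haplotype", "count", "frequency_pct", "ci_low_pct", "ci_high_pct"])
        for rec in summary.frequency_table:
            writer.writerow(
                [
                    rec.haplotype_label,
                    rec.count,
                    _fmt_pct(rec.frequency, ndigits),
                    _fmt_pct(rec.ci_low, ndigits),
                    _fmt_pct(rec.ci_high, ndigits),
                ]
            )


def write_genotype_table_tsv(summary: CohortSummary, path: str | Path, ndigits: int = 2) -> None:
    """Genotype table (label, subjects, percent, AS, phenotype) as TSV."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["genotype", "subjects", "frequency_pct", "activity_score", "phenotype"])
        for row in summary.genotype_table:
            writer.writerow(
                [row.label, row.subjects, _fmt_pct(row.percent / 100.0, ndigits),
                 _fmt_score(row.activity_score), str(row.phenotype)]
            )


def write_hwe_tsv(hwe: HWEResult, path: str | Path) -> None:
    """Per-genotype observed/expected/chi-square table as TSV."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["genotype", "observed", "expected", "chi2_contribution", "flagged"])
        for label, o, e, contrib, flag in hwe.rows:
            writer.writerow([label, o, f"{e:.4f}", f"{contrib:.4f}", "yes" if flag else "no"])


def _fmt_pct(proportion: float, ndigits: int) -> str:
    return f"{round_half_away(100.0 * proportion, ndigits):.{ndigits}f}"


def _fmt_score(score: float) -> str:
    return f"{score:g}"


def summary_to_dict(summary: CohortSummary, ndigits: int = 2) -> dict[str, Any]:
    """JSON-ready representation of a :class:`CohortSummary`.

    Percentages are rounded here, at serialisation; the dataclass itself
    keeps full precision.
    """
    return {
        "n_subjects": summary.n_subjects,
        "n_genotypes": summary.n_genotypes,
        "frequency_table": [
            {
                "haplotype": rec.haplotype_label,
                "count": rec.count,
                "frequency_pct": round_half_away(100 * rec.frequency, ndigits),
                "ci_low_pct": round_half_away(100 * rec.ci_low, ndigits),
                "ci_high_pct": round_half_away(100 * rec.ci_high, ndigits),
            }
            for rec in summary.frequency_table
        ],
        "genotype_table": [
            {
                "genotype": row.label,
                "subjects": row.subjects,
                "frequency_pct": round_half_away(row.percent, ndigits),
                "activity_score": row.activity_score,
                "phenotype": str(row.phenotype),
            }
            for row in summary.genotype_table
        ],
        "phenotype_distribution": {
            str(cls): {"subjects": cnt, "percent": round_half_away(pct, ndigits)}
            for cls, (cnt, pct) in summary.phenotype_distribution.items()
        },
        "as_group_breakdown": {
            f"{score:g}": {
                "genotypes": g,
                "subjects": s,
                "percent": round_half_away(pct, ndigits),
            }
            for score, (g, s, pct) in summary.as_group_breakdown.items()
        },
        "function_classes": {
            fclass: {
                "units": fc.unit_count,
                "percent": round_half_away(fc.raw_percent, ndigits),
                "rounded_sum_percent": fc.rounded_sum_percent,
            }
            for fclass, fc in summary.function_classes.items()
        },
        "predicted_pm_pct": round_half_away(100 * summary.predicted_pm, ndigits),
        "hwe": None
        if summary.hwe is None
        else {
            "cumulative_chi2": round(summary.hwe.cumulative_chi2, 4),
            "df": summary.hwe.df,
            "df_rule": summary.hwe.df_rule,
            "p_value": summary.hwe.p_value,
            "total_observed": summary.hwe.total_observed,
            "total_expected": round(summary.hwe.total_expected, 4),
            "flagged_genotypes": list(summary.hwe.flagged_genotypes()),
        },
    }


def write_summary_json(summary: CohortSummary, path: str | Path, ndigits: int = 2) -> None:
    path = Path(path)
    path.write_text(json.dumps(summary_to_dict(summary, ndigits), indent=2) + "\n", encoding="utf-8")
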