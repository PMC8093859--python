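"""Bundled fixture data: the 211-subject Madagascar cohort and its
CYP2D6 allele-definition table.

The cohort table lists each subject's two star-allele haplotypes as
genotyped in the Madagascar study population (211 subjects, 41 distinct
diplotypes over 17 haplotype labels).  The allele-definition table maps
the 13 core alleles involved to their CPIC activity values.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

from .alleles import AlleleDefinitionTable
from .popgen import Cohort

__all__ = [
    "load_allele_definitions",
    "load_madagascar_cohort",
    "madagascar_cohort_path",
    "allele_definitions_path",
]


def _data_path(name: str) -> Path:
    return Path(resources.files("cyp2d6pop.data").joinpath(name))  # type: ignore[arg-type]


def madagascar_cohort_path() -> Path:
    return _data_path("madagascar_cohort.tsv")


def allele_definitions_path() -> Path:
    return _data_path("table1_alleles.tsv")


def load_madagascar_cohort() -> Cohort:
    """The 211-subject Madagascar cohort."""
    from .io import read_cohort

    return read_cohort(madagascar_cohort_path())


def load_allele_definitions() -> AlleleDefinitionTable:
    """Activity values for the 13 core alleles observed in the cohort."""
    from .io import read_allele_definitions

    return read_allele_definitions(allele_definitions_path())
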