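"""Shared fixtures: the bundled Madagascar cohort and the published
per-allele / per-genotype reference values it must reproduce."""

from __future__ import annotations

import pytest

from cyp2d6pop import load_allele_definitions, load_madagascar_cohort


@pytest.fixture(scope="session")
def defs():
    return load_allele_definitions()


@pytest.fixture(scope="session")
def cohort():
    return load_madagascar_cohort()


# Published allele-frequency table for the 211-subject cohort:
# label -> (unit count, frequency %, CI low %, CI high %, activity value).
TABLE1 = {
    "*1": (151, 35.78, 31.12, 40.45, 1.0),
    "*1x2": (1, 0.24, 0.00, 0.71, 2.0),
    "*2": (27, 6.40, 4.02, 8.78, 1.0),
    "*2x2": (2, 0.47, 0.00, 1.14, 2.0),
    "*4": (9, 2.13, 0.73, 3.54, 0.0),
    "*4x2": (6, 1.42, 0.27, 2.57, 0.0),
    "*5": (7, 1.66, 0.42, 2.90, 0.0),
    "*10": (72, 17.06, 13.40, 20.72, 0.25),
    "*17": (46, 10.90, 7.87, 13.93, 0.5),
    "*29": (28, 6.64, 4.21, 9.06, 0.5),
    "*35x2": (1, 0.24, 0.00, 0.71, 2.0),
    "*36+*10": (51, 12.09, 8.91, 15.26, 0.25),
    "*36x2+*10": (1, 0.24, 0.00, 0.71, 0.25),
    "*40": (1, 0.24, 0.00, 0.71, 0.0),
    "*41": (15, 3.55, 1.75, 5.36, 0.5),
    "*45": (3, 0.71, 0.00, 1.53, 1.0),
    "*100": (1, 0.24, 0.00, 0.71, 0.0),
}

# Published genotype table: label -> (subjects, frequency %, AS, phenotype).
TABLE2 = {
    "*1/*2x2": (1, 0.47, 3.0, "UM"),
    "*1/*35x2": (1, 0.47, 3.0, "UM"),
    "*1/*10": (30, 14.22, 1.25, "NM"),
    "*1/*36+*10": (19, 9.00, 1.25, "NM"),
    "*1/*36x2+*10": (1, 0.47, 1.25, "NM"),
    "*2/*10": (4, 1.90, 1.25, "NM"),
    "*2/*36+*10": (2, 0.95, 1.25, "NM"),
    "*36+*10/*45": (1, 0.47, 1.25, "NM"),
    "*1/*17": (21, 9.95, 1.5, "NM"),
    "*1/*29": (12, 5.69, 1.5, "NM"),
    "*1/*41": (4, 1.90, 1.5, "NM"),
    "*2/*17": (3, 1.42, 1.5, "NM"),
    "*2/*29": (3, 1.42, 1.5, "NM"),
    "*2/*41": (1, 0.47, 1.5, "NM"),
    "*1/*1": (18, 8.53, 2.0, "NM"),
    "*1/*2": (13, 6.16, 2.0, "NM"),
    "*1/*45": (1, 0.47, 2.0, "NM"),
    "*2/*45": (1, 0.47, 2.0, "NM"),
    "*2x2/*5": (1, 0.47, 2.0, "NM"),
    "*1x2/*10": (1, 0.47, 2.25, "NM"),
    "*4/*36+*10": (2, 0.95, 0.25, "IM"),
    "*4x2/*36+*10": (1, 0.47, 0.25, "IM"),
    "*5/*10": (3, 1.42, 0.25, "IM"),
    "*10/*40": (1, 0.47, 0.25, "IM"),
    "*36+*10/*100": (1, 0.47, 0.25, "IM"),
    "*4/*29": (2, 0.95, 0.5, "IM"),
    "*4x2/*41": (1, 0.47, 0.5, "IM"),
    "*10/*10": (7, 3.32, 0.5, "IM"),
    "*10/*36+*10": (6, 2.84, 0.5, "IM"),
    "*36+*10/*36+*10": (3, 1.42, 0.5, "IM"),
    "*10/*17": (5, 2.37, 0.75, "IM"),
    "*10/*29": (6, 2.84, 0.75, "IM"),
    "*10/*41": (2, 0.95, 0.75, "IM"),
    "*17/*36+*10": (7, 3.32, 0.75, "IM"),
    "*36+*10/*41": (6, 2.84, 0.75, "IM"),
    "*1/*4": (5, 2.37, 1.0, "IM"),
    "*1/*4x2": (4, 1.90, 1.0, "IM"),
    "*1/*5": (3, 1.42, 1.0, "IM"),
    "*17/*17": (2, 0.95, 1.0, "IM"),
    "*17/*29": (5, 2.37, 1.0, "IM"),
    "*17/*41": (1, 0.47, 1.0, "IM"),
}
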