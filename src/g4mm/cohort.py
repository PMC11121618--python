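"""Cohort-level germline analyses and summary statistics.

Covers the discovery of germline SNPs carried by every member of a sample
group and by no one outside it (with a population-allele-frequency filter
to exclude variants common enough to co-occur by chance) and simple
cohort descriptives (median age, age range, sex split).

A published 11-patient multiple myeloma exome cohort is bundled as the
worked example: per-patient sex, age, paraprotein, R-ISS stage, ECOG
performance status, somatic mutation count, and the G4-enrichment label of
each tumor.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd

from .genome_io import Variant

__all__ = [
    "VariantKey",
    "group_exclusive_snps",
    "filter_by_population_frequency",
    "cohort_summary",
    "myeloma_cohort",
]

VariantKey = tuple[str, int, str, str]

# Bundled example cohort (11 newly diagnosed multiple myeloma patients):
# sample, sex, age, paraprotein, R-ISS stage, ECOG status, somatic mutation
# count in the tumor exome, G4 context enrichment label.
_MM_COHORT_ROWS = [
    ("S7", "M", 81, "IgG k", "I", "ECOG II", 115, "No"),
    ("S12", "F", 61, "IgG l", "II", "ECOG II", 63, "G4 strong"),
    ("P1", "F", 74, "IgG k", "II", "ECOG II", 87, "No"),
    ("P14", "F", 58, "IgA k", "I", "ECOG I", 234, "No"),
    ("P20", "M", 74, "IgG k", "III", "ECOG III", 182, "No"),
    ("P22", "F", 71, "IgA l", "I", "ECOG I", 191, "No"),
    ("P23", "F", 73, "IgG k", "I", "ECOG I", 119, "G4 strong"),
    ("P30", "M", 69, "IgG k", "III", "ECOG II", 662, "No"),
    ("P34", "M", 83, "IgG k", "II", "ECOG II", 267, "No"),
    ("P37", "M", 64, "IgA l", "II", "ECOG III", 82, "G4 strong"),
    ("P48", "F", 56, "IgG k", "III", "ECOG III", 227, "G4 weak + G4 strong"),
]


def myeloma_cohort() -> pd.DataFrame:
    """The bundled 11-patient multiple myeloma cohort table."""
    return pd.DataFrame(
        _MM_COHORT_ROWS,
        columns=[
            "sample",
            "sex",
            "age",
            "paraprotein",
            "stage",
            "performance",
            "n_somatic",
            "enrichment",
        ],
    )


def group_exclusive_snps(
    germline: Mapping[str, Iterable[VariantKey]],
    group: Iterable[str],
) -> set[VariantKey]:
    """SNPs carried by every group member and absent from every other sample.

    Variant identity is the (chrom, pos, ref, alt) key, so variants without
    an rsid participate; zygosity is ignored (presence/absence only).
    """
    group = set(group)
    if not group:
        raise ValueError("group must be non-empty")
    unknown = group - set(germline)
    if unknown:
        raise ValueError(f"group samples not in cohort: {sorted(unknown)}")
    others = set(germline) - group
    if not others:
        raise ValueError("group equals the whole cohort: complement is empty")
    sets = {s: set(keys) for s, keys in germline.items()}
    shared = set.intersection(*(sets[s] for s in group))
    for s in others:
        shared -= sets[s]
    return shared


def filter_by_population_frequency(
    snps: Iterable[Variant],
    max_af: float = 0.1,
) -> tuple[set[VariantKey], set[VariantKey]]:
    """Keep SNPs with population allele frequency strictly below max_af.

    Returns (kept keys, unknown-AF keys); variants lacking an AF
    annotation cannot be filtered and are reported separately.
    """
    kept: set[VariantKey] = set()
    unknown: set[VariantKey] = set()
    for v in snps:
        if v.af_pop is None:
            unknown.add(v.key)
        elif v.af_pop < max_af:
            kept.add(v.key)
    return kept, unknown


def cohort_summary(table: pd.DataFrame) -> dict:
    """Median age, age range, and sex split for a cohort table.

    Expects at least ``sample``, ``sex`` and ``age`` columns.  Sex
    percentages are rounded to 1 decimal place.
    """
    if table.empty:
        raise ValueError("empty cohort table")
    ages = table["age"]
    sexes = table["sex"].value_counts()
    n = len(table)
    return {
        "n": n,
        "median_age": float(ages.median()),
        "age_min": int(ages.min()),
        "age_max": int(ages.max()),
        "n_female": int(sexes.get("F", 0)),
        "n_male": int(sexes.get("M", 0)),
        "pct_female": round(100.0 * sexes.get("F", 0) / n, 1),
        "pct_male": round(100.0 * sexes.get("M", 0) / n, 1),
    }
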