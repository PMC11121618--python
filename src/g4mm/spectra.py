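"""Mutation spectra stratified by G4 context and enrichment group.

Substitutions are kept strand-specific (12 types, e.g. C>A and G>T are NOT
collapsed onto one pyrimidine-centred class) because the G4 context itself
is strand-asymmetric: a G-run on the reference strand is a C-run on the
other.  Each (enrichment group, G4 stratum) cell gets per-type counts,
proportions, and the binomial standard deviation of each proportion,
sd = sqrt(p*(1-p)/n), used as error bars.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Mapping

import pandas as pd

from .g4scan import G4Category
from .genome_io import Variant, VariantClass

__all__ = [
    "SpectrumGroup",
    "SUBSTITUTION_TYPES",
    "SpectrumTable",
    "classify_substitution",
    "build_spectra",
    "spectra_long_table",
    "consequence_by_g4",
]


class SpectrumGroup(enum.Enum):
    ENRICHED = "ENRICHED"
    NOT_ENRICHED = "NOT_ENRICHED"


_BASES = "ACGT"
SUBSTITUTION_TYPES: tuple[str, ...] = tuple(
    f"{r}>{a}" for r in _BASES for a in _BASES if r != a
)


def classify_substitution(ref: str, alt: str) -> str:
    """Strand-specific substitution type of a single-base change."""
    if ref not in _BASES or alt not in _BASES:
        raise ValueError(f"not a classifiable substitution: {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError("ref and alt are identical")
    return f"{ref}>{alt}"


@dataclass(frozen=True)
class SpectrumTable:
    """Per-type counts and proportions for one (group, stratum) cell."""

    group: SpectrumGroup
    stratum: G4Category
    counts: Mapping[str, int]
    total: int

    @property
    def proportions(self) -> dict[str, float]:
        if self.total == 0:
            return {t: math.nan for t in SUBSTITUTION_TYPES}
        return {t: self.counts[t] / self.total for t in SUBSTITUTION_TYPES}

    @property
    def sd(self) -> dict[str, float]:
        if self.total == 0:
            return {t: math.nan for t in SUBSTITUTION_TYPES}
        return {
            t: math.sqrt(p * (1.0 - p) / self.total)
            for t, p in self.proportions.items()
        }


def build_spectra(
    classified: Iterable[tuple[Variant, G4Category]],
    group_of: Callable[[str], SpectrumGroup] | Mapping[str, SpectrumGroup],
) -> tuple[list[SpectrumTable], int]:
    """Count substitution types per (enrichment group, G4 stratum) cell.

    Non-SNV variants are not classifiable and are excluded; their number is
    returned alongside.  All six cells are always present (empty cells have
    zero counts).
    """
    if isinstance(group_of, Mapping):
        mapping = group_of
        group_of = lambda s: mapping[s]  # noqa: E731
    counts: dict[tuple[SpectrumGroup, G4Category], dict[str, int]] = {
        (g, c): {t: 0 for t in SUBSTITUTION_TYPES}
        for g in SpectrumGroup
        for c in G4Category
    }
    excluded = 0
    for variant, category in classified:
        if variant.vclass is not VariantClass.SNV:
            excluded += 1
            continue
        cell = counts[(group_of(variant.sample), category)]
        cell[classify_substitution(variant.ref, variant.alt)] += 1
    tables = [
        SpectrumTable(group=g, stratum=c, counts=cell, total=sum(cell.values()))
        for (g, c), cell in counts.items()
    ]
    return tables, excluded


def spectra_long_table(tables: Iterable[SpectrumTable]) -> pd.DataFrame:
    """Long-format (group, stratum, type, count, proportion, sd) table."""
    rows = []
    for tab in tables:
        props, sds = tab.proportions, tab.sd
        for t in SUBSTITUTION_TYPES:
            rows.append(
                {
                    "group": tab.group.value,
                    "stratum": tab.stratum.value,
                    "type": t,
                    "count": tab.counts[t],
                    "proportion": props[t],
                    "sd": sds[t],
                }
            )
    return pd.DataFrame(rows)


def consequence_by_g4(
    classified: Iterable[tuple[Variant, G4Category]],
) -> pd.DataFrame:
    """Contingency report of consequence label x G4 category.

    Labels are passed through verbatim; variants without a label fall into
    an "unannotated" bucket.  Proportions are within-category.
    """
    cells: dict[tuple[str, str], int] = {}
    cat_totals: dict[str, int] = {}
    for variant, category in classified:
        label = variant.consequence if variant.consequence else "unannotated"
        key = (label, category.value)
        cells[key] = cells.get(key, 0) + 1
        cat_totals[category.value] = cat_totals.get(category.value, 0) + 1
    rows = [
        {
            "consequence": label,
            "category": cat,
            "count": n,
            "proportion_within_category": n / cat_totals[cat],
        }
        for (label, cat), n in sorted(cells.items())
    ]
    return pd.DataFrame(rows, columns=["consequence", "category", "count", "proportion_within_category"])
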