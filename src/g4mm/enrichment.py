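"""Enrichment of G4 context around somatic mutation sites vs. a random null.

The null model is a set of windows (default 2000, matching the tumor
window length) anchored at positions drawn uniformly over the bases of the
sample's capture panel.  Each tumor sample is compared to its panel's
control set for two contexts — STRONG alone, and WEAK-plus-STRONG combined
— with a Pearson chi-square test of independence on the 2x2 table and a
pooled two-proportion z-test, plus Wilson score confidence intervals for
the per-set proportions.

A sample is labelled G4_STRONG when the strong context is significantly
enriched (one-sided, tumor above control) by both tests at level alpha;
failing that, G4_WEAK_PLUS_STRONG when the combined context passes the same
rule; otherwise NONE.  Two-sided statistics are reported alongside, but the
label uses one-sided p-values so that the type-I rate of the G4_STRONG call
is alpha rather than alpha/2: enrichment is a directional hypothesis.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint, proportions_ztest

from .g4scan import G4Category, classify_window
from .genome_io import GenomicInterval, SequenceWindow, extract_site_window

__all__ = [
    "Context",
    "SampleLabel",
    "ContingencyTable",
    "EnrichmentResult",
    "sample_random_windows",
    "wilson_interval",
    "chi_square_independence",
    "two_proportion_z",
    "evaluate_sample",
    "summarize_groups",
]


class Context(enum.Enum):
    STRONG = "STRONG"
    WEAK_PLUS_STRONG = "WEAK_PLUS_STRONG"


class SampleLabel(enum.Enum):
    G4_STRONG = "G4_STRONG"
    G4_WEAK_PLUS_STRONG = "G4_WEAK_PLUS_STRONG"
    NONE = "NONE"


@dataclass(frozen=True)
class ContingencyTable:
    """Counts of context-positive windows in tumor and control sets."""

    k_tumor: int
    n_tumor: int
    k_control: int
    n_control: int

    def __post_init__(self) -> None:
        if not (0 <= self.k_tumor <= self.n_tumor and 0 <= self.k_control <= self.n_control):
            raise ValueError("require 0 <= k <= n on both rows")
        if self.n_tumor == 0 or self.n_control == 0:
            raise ValueError("empty tumor or control set")

    def as_2x2(self) -> list[list[int]]:
        return [
            [self.k_tumor, self.n_tumor - self.k_tumor],
            [self.k_control, self.n_control - self.k_control],
        ]


@dataclass(frozen=True)
class EnrichmentResult:
    sample: str
    context: Context
    table: ContingencyTable
    prop_tumor: float
    prop_control: float
    wilson_tumor: tuple[float, float]
    wilson_control: tuple[float, float]
    chi2_stat: float
    chi2_p: float
    z_stat: float
    z_p: float
    degenerate: bool
    significant_enrichment: bool


def sample_random_windows(
    reference: Mapping[str, str],
    panel: Sequence[GenomicInterval],
    n: int = 2000,
    flank: int = 70,
    rng: np.random.Generator | int | None = None,
) -> list[SequenceWindow]:
    """Draw n control windows anchored uniformly over the panel's bases.

    An interval is chosen with probability proportional to its length and
    an anchor base uniformly within it (equivalently, uniform over the
    union of panel bases), with replacement; each anchor is expanded to a
    nominal 2*flank+1 window clipped at contig edges.  Deterministic for a
    fixed seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    if not panel:
        raise ValueError("empty panel")
    rng = np.random.default_rng(rng)
    lengths = np.array([len(iv) for iv in panel], dtype=np.int64)
    total = int(lengths.sum())
    if total < 1:
        raise ValueError("panel has zero total length")
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    draws = rng.integers(0, total, size=n)
    out: list[SequenceWindow] = []
    for d in draws:
        idx = int(np.searchsorted(offsets, d, side="right") - 1)
        iv = panel[idx]
        pos0 = iv.start + int(d - offsets[idx])
        out.append(extract_site_window(reference, iv.chrom, pos0, flank))
    return out


def wilson_interval(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Wilson score confidence interval for a binomial proportion."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    lo, hi = proportion_confint(k, n, alpha=1.0 - conf, method="wilson")
    lo = 0.0 if k == 0 else max(0.0, float(lo))
    hi = 1.0 if k == n else min(1.0, float(hi))
    return lo, hi


def chi_square_independence(
    table: ContingencyTable, continuity: bool = False
) -> tuple[float, float, int]:
    """Pearson chi-square test of independence on the 2x2 context table."""
    arr = np.asarray(table.as_2x2(), dtype=float)
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("degenerate 2x2 table: zero marginal")
    res = stats.chi2_contingency(arr, correction=continuity)
    return float(res.statistic), float(res.pvalue), 1


def two_proportion_z(
    k1: int, n1: int, k2: int, n2: int
) -> tuple[float, float, bool]:
    """Pooled two-proportion z-test; positive z when p1 > p2.

    Returns (z, two-sided p, degenerate).  When the pooled proportion is 0
    or 1 the statistic is undefined; (0.0, 1.0, True) is returned.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("n1 and n2 must be positive")
    pooled = (k1 + k2) / (n1 + n2)
    if pooled <= 0.0 or pooled >= 1.0:
        return 0.0, 1.0, True
    z, p = proportions_ztest([k1, k2], [n1, n2], alternative="two-sided")
    return float(z), float(p), False


def _one_sided_greater_p(z: float, p_two: float, degenerate: bool) -> float:
    if degenerate:
        return 1.0
    return p_two / 2.0 if z > 0 else 1.0 - p_two / 2.0


def _context_count(categories: Sequence[G4Category], context: Context) -> int:
    if context is Context.STRONG:
        return sum(c is G4Category.STRONG for c in categories)
    return sum(c in (G4Category.WEAK, G4Category.STRONG) for c in categories)


def evaluate_sample(
    tumor_windows: Sequence[SequenceWindow],
    control_windows: Sequence[SequenceWindow],
    alpha: float = 0.05,
    *,
    sample: str = "",
    strict_loops: bool = False,
    continuity: bool = False,
    conf: float = 0.95,
) -> tuple[list[EnrichmentResult], SampleLabel]:
    """Test one tumor's windows against its panel control and label the sample.

    Both the STRONG and the combined WEAK_PLUS_STRONG contexts are tested.
    The G4_STRONG label requires one-sided significance (tumor above
    control) from both the chi-square and the z test at level alpha for the
    STRONG context; the combined context decides G4_WEAK_PLUS_STRONG under
    the same rule; otherwise NONE.
    """
    if not tumor_windows or not control_windows:
        raise ValueError("tumor and control window sets must be non-empty")
    tumor_cats = [classify_window(w.seq, strict_loops=strict_loops) for w in tumor_windows]
    control_cats = [classify_window(w.seq, strict_loops=strict_loops) for w in control_windows]
    return evaluate_sample_categories(
        tumor_cats, control_cats, alpha, sample=sample, continuity=continuity, conf=conf
    )


def evaluate_sample_categories(
    tumor_cats: Sequence[G4Category],
    control_cats: Sequence[G4Category],
    alpha: float = 0.05,
    *,
    sample: str = "",
    continuity: bool = False,
    conf: float = 0.95,
) -> tuple[list[EnrichmentResult], SampleLabel]:
    """As :func:`evaluate_sample` but on pre-computed window categories."""
    results: list[EnrichmentResult] = []
    significant: dict[Context, bool] = {}
    for context in (Context.STRONG, Context.WEAK_PLUS_STRONG):
        table = ContingencyTable(
            k_tumor=_context_count(tumor_cats, context),
            n_tumor=len(tumor_cats),
            k_control=_context_count(control_cats, context),
            n_control=len(control_cats),
        )
        prop_t = table.k_tumor / table.n_tumor
        prop_c = table.k_control / table.n_control
        z, z_p, degenerate = two_proportion_z(
            table.k_tumor, table.n_tumor, table.k_control, table.n_control
        )
        try:
            chi2, chi2_p, _ = chi_square_independence(table, continuity=continuity)
        except ValueError:  # zero marginal <=> pooled proportion 0 or 1
            chi2, chi2_p = 0.0, 1.0
        enriched = (
            not degenerate
            and prop_t > prop_c
            and _one_sided_greater_p(z, z_p, degenerate) < alpha
            and chi2_p / 2.0 < alpha  # one-sided via z^2 = chi^2, direction checked
        )
        significant[context] = enriched
        results.append(
            EnrichmentResult(
                sample=sample,
                context=context,
                table=table,
                prop_tumor=prop_t,
                prop_control=prop_c,
                wilson_tumor=wilson_interval(table.k_tumor, table.n_tumor, conf),
                wilson_control=wilson_interval(table.k_control, table.n_control, conf),
                chi2_stat=chi2,
                chi2_p=chi2_p,
                z_stat=z,
                z_p=z_p,
                degenerate=degenerate,
                significant_enrichment=enriched,
            )
        )
    if significant[Context.STRONG]:
        label = SampleLabel.G4_STRONG
    elif significant[Context.WEAK_PLUS_STRONG]:
        label = SampleLabel.G4_WEAK_PLUS_STRONG
    else:
        label = SampleLabel.NONE
    return results, label


def summarize_groups(
    labels: Mapping[str, SampleLabel],
    mutation_counts: Mapping[str, int],
) -> pd.DataFrame:
    """Mean somatic mutation count per enrichment group.

    Samples labelled G4_STRONG form one group; everything else (NONE and
    the combined weak-plus-strong label) is pooled as "without G4 strong
    enrichment".  Returns a two-row table with group sizes and means (NA
    for an empty group).
    """
    missing = set(labels) ^ set(mutation_counts)
    if missing:
        raise ValueError(f"samples without both label and count: {sorted(missing)}")
    strong = [s for s, lab in labels.items() if lab is SampleLabel.G4_STRONG]
    other = [s for s in labels if s not in strong]
    rows = []
    for name, members in (
        ("G4_strong_enriched", strong),
        ("without_G4_strong_enrichment", other),
    ):
        counts = [mutation_counts[s] for s in members]
        rows.append(
            {
                "group": name,
                "n_samples": len(members),
                "samples": ",".join(sorted(members)),
                "mean_mutations": float(np.mean(counts)) if counts else math.nan,
            }
        )
    return pd.DataFrame(rows)
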