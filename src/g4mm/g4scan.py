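"""Detection of weak and strong G-quadruplex-forming motifs.

A putative quadruplex motif is four guanine runs separated by three loops
of 1-10 nt.  Two classes are scanned: *weak* motifs built from runs of
exactly two G's and *strong* motifs from runs of three to four G's; the
mirror C-run patterns capture quadruplex potential on the complementary
strand.  The loop element deliberately matches ANY character (the regex
``\\D``, i.e. non-digit, which on a nucleotide string is unrestricted):
loops may therefore contain G, C and N.  This permissive semantics is part
of the motif definition and the enrichment counts depend on it; a strict
mode restricting loops to non-run bases is available for sensitivity
analysis.

Window classification is three-level: STRONG if any strong motif matches,
else WEAK if any weak motif matches, else NONE.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Iterable

from .genome_io import SequenceWindow, Variant, apply_variants

__all__ = [
    "G4Strength",
    "StrandPattern",
    "G4Category",
    "G4Motif",
    "G4Change",
    "find_g4_motifs",
    "classify_window",
    "g4_change_on_mutation",
    "oracle_find_g4",
]


class G4Strength(enum.Enum):
    WEAK = "WEAK"
    STRONG = "STRONG"


class StrandPattern(enum.Enum):
    G_PATTERN = "G_PATTERN"
    C_PATTERN = "C_PATTERN"


class G4Category(enum.Enum):
    NONE = "NONE"
    WEAK = "WEAK"
    STRONG = "STRONG"


@dataclass(frozen=True)
class G4Motif:
    start: int
    end: int
    strength: G4Strength
    strand_pattern: StrandPattern


@dataclass(frozen=True)
class G4Change:
    """G4 classification of a window before and after a somatic mutation."""

    before: G4Category
    after: G4Category

    @property
    def changed(self) -> bool:
        return self.before != self.after

    @property
    def transition(self) -> str:
        return f"{self.before.value}->{self.after.value}"


def _quad_pattern(run: str, base: str, loop: str) -> re.Pattern[str]:
    return re.compile((base + run + loop) * 3 + base + run)

# Loop element \D{1,10}: any 1-10 characters on a nucleotide string.
_PATTERNS: dict[tuple[G4Strength, StrandPattern, bool], re.Pattern[str]] = {}
for _strict in (False, True):
    for _strength, _run in ((G4Strength.WEAK, "{2}"), (G4Strength.STRONG, "{3,4}")):
        for _sp, _base in ((StrandPattern.G_PATTERN, "G"), (StrandPattern.C_PATTERN, "C")):
            _loop = f"[^{_base}]{{1,10}}" if _strict else r"\D{1,10}"
            _PATTERNS[(_strength, _sp, _strict)] = _quad_pattern(_run, _base, _loop)

_VALID_SEQ = re.compile(r"[ACGTN]*\Z")


def _check_seq(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    if not _VALID_SEQ.match(seq):
        raise ValueError("sequence must be uppercase over {A,C,G,T,N}")


def find_g4_motifs(
    seq: str,
    strength: G4Strength,
    *,
    strict_loops: bool = False,
) -> list[G4Motif]:
    """Scan both the G-run and C-run patterns for motifs of one strength.

    Matches are the standard non-overlapping leftmost-earliest regex scan,
    reported per strand pattern and merged in positional order.  With
    ``strict_loops`` the loop element excludes the run base instead of
    matching any character.
    """
    _check_seq(seq)
    motifs: list[G4Motif] = []
    for sp in (StrandPattern.G_PATTERN, StrandPattern.C_PATTERN):
        pat = _PATTERNS[(strength, sp, strict_loops)]
        for m in pat.finditer(seq):
            motifs.append(G4Motif(m.start(), m.end(), strength, sp))
    motifs.sort(key=lambda mo: (mo.start, mo.end, mo.strand_pattern.value))
    return motifs


def _has_motif(seq: str, strength: G4Strength, strict_loops: bool) -> bool:
    for sp in (StrandPattern.G_PATTERN, StrandPattern.C_PATTERN):
        if _PATTERNS[(strength, sp, strict_loops)].search(seq):
            return True
    return False


def classify_window(seq: str, *, strict_loops: bool = False) -> G4Category:
    """Three-level G4 context label; STRONG dominates WEAK dominates NONE."""
    _check_seq(seq)
    if _has_motif(seq, G4Strength.STRONG, strict_loops):
        return G4Category.STRONG
    if _has_motif(seq, G4Strength.WEAK, strict_loops):
        return G4Category.WEAK
    return G4Category.NONE


def g4_change_on_mutation(
    window: SequenceWindow,
    somatic: Variant,
    *,
    strict_loops: bool = False,
) -> G4Change:
    """Reclassify a window after introducing a somatic mutation.

    The window is expected to already carry the sample's germline edits;
    the somatic edit is applied on top (coordinate shifts from germline
    indels are handled) and both haplotypes are classified.
    """
    before = classify_window(window.seq, strict_loops=strict_loops)
    mutated = apply_variants(window, [somatic])
    if not mutated.applied_edits or mutated.applied_edits[-1] is not somatic:
        raise ValueError(
            f"somatic variant {somatic.chrom}:{somatic.pos} lies outside the window"
        )
    after = classify_window(mutated.seq, strict_loops=strict_loops)
    return G4Change(before=before, after=after)


# ---------------------------------------------------------------------------
# Brute-force oracle (test-time verification)

_RUN_LENGTHS = {G4Strength.WEAK: (2,), G4Strength.STRONG: (3, 4)}


def oracle_find_g4(seq: str, strength: G4Strength) -> list[tuple[int, int]]:
    """Exhaustively enumerate run1-loop1-...-run4 decompositions.

    Independent of the regex engine: explicitly iterates every placement of
    four runs (lengths per strength) separated by loops of 1-10 arbitrary
    characters, for both the G-run and C-run forms, and returns the (start,
    end) spans found.  Intended to certify the scanning engine's
    presence/absence calls on short sequences.
    """
    _check_seq(seq)
    if len(seq) > 300:
        raise ValueError("oracle guard: sequence longer than 300 nt")
    spans: set[tuple[int, int]] = set()
    for base in "GC":
        spans.update(_oracle_one_strand(seq, base, _RUN_LENGTHS[strength]))
    return sorted(spans)


def _oracle_one_strand(
    seq: str, base: str, run_lengths: Iterable[int]
) -> set[tuple[int, int]]:
    n = len(seq)
    run_lengths = tuple(run_lengths)

    def is_run(start: int, length: int) -> bool:
        return start + length <= n and all(
            seq[start + j] == base for j in range(length)
        )

    # ends reachable from `pos` with `remaining` run+loop stages still to place
    cache: dict[tuple[int, int], frozenset[int]] = {}

    def ends_from(pos: int, remaining: int) -> frozenset[int]:
        if remaining == 0:
            return frozenset((pos,))
        key = (pos, remaining)
        if key not in cache:
            ends: set[int] = set()
            for loop in range(1, 11):
                nxt = pos + loop
                for r in run_lengths:
                    if is_run(nxt, r):
                        ends.update(ends_from(nxt + r, remaining - 1))
            cache[key] = frozenset(ends)
        return cache[key]

    found: set[tuple[int, int]] = set()
    for s in range(n):
        for r in run_lengths:
            if is_run(s, r):
                for e in ends_from(s + r, 3):
                    found.add((s, e))
    return found
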