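"""Reference, panel and variant I/O with explicit coordinate conventions.

All internal coordinates are 0-based half-open.  VCF positions (1-based)
are converted on ingest; BED intervals are taken as-is.  Sequence windows
around variant sites are extracted from the reference and germline /
somatic edits are applied to them with correct coordinate shifting, so the
scanned haplotype is the one the patient actually carries.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

__all__ = [
    "GenomicInterval",
    "Variant",
    "VariantClass",
    "VariantOrigin",
    "SequenceWindow",
    "GermlineFilterReport",
    "load_reference",
    "read_panel",
    "write_panel",
    "read_variants",
    "filter_germline",
    "extract_window",
    "apply_variants",
    "reverse_complement",
]

# IUPAC nucleotide one-letter codes accepted in a reference sequence.
_IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")

_RC = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def reverse_complement(seq: str) -> str:
    """Reverse complement of an uppercase IUPAC DNA string."""
    return seq.translate(_RC)[::-1]


class VariantClass(enum.Enum):
    SNV = "SNV"
    MNV = "MNV"
    INS = "INS"
    DEL = "DEL"


class VariantOrigin(enum.Enum):
    SOMATIC = "SOMATIC"
    GERMLINE = "GERMLINE"


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open region ``[start, end)`` on a named contig (0-based)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def contains(self, chrom: str, pos0: int) -> bool:
        return chrom == self.chrom and self.start <= pos0 < self.end


@dataclass(frozen=True)
class Variant:
    """One normalized VCF record (single alt allele) with sample attribution.

    ``pos`` is the 1-based VCF anchor position.  ``vclass`` is derived from
    the allele lengths when not given explicitly.
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str = ""
    origin: VariantOrigin = VariantOrigin.SOMATIC
    vclass: VariantClass = None  # type: ignore[assignment]
    dp: int | None = None
    ad_alt: int | None = None
    af_pop: float | None = None
    consequence: str | None = None
    rsid: str | None = None

    def __post_init__(self) -> None:
        if not self.ref or not self.alt or self.ref == self.alt:
            raise ValueError(
                f"ref/alt must be non-empty and differ, got {self.ref!r}>{self.alt!r}"
            )
        if self.vclass is None:
            object.__setattr__(self, "vclass", _derive_class(self.ref, self.alt))

    @property
    def pos0(self) -> int:
        """0-based anchor offset."""
        return self.pos - 1

    @property
    def ref_span(self) -> tuple[int, int]:
        """0-based half-open span of the reference bases replaced."""
        return (self.pos0, self.pos0 + len(self.ref))

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity key used for cross-sample presence/absence."""
        return (self.chrom, self.pos, self.ref, self.alt)


def _derive_class(ref: str, alt: str) -> VariantClass:
    if len(ref) == len(alt):
        return VariantClass.SNV if len(ref) == 1 else VariantClass.MNV
    return VariantClass.INS if len(alt) > len(ref) else VariantClass.DEL


@dataclass(frozen=True)
class SequenceWindow:
    """Sequence around a variant site, with provenance of applied edits.

    The nominal interval spans ``flank`` nt either side of the anchor span;
    ``clipped_left``/``clipped_right`` record bases lost at contig edges.
    ``seq`` reflects all ``applied_edits`` (length may differ from the
    interval by their net indel length).
    """

    interval: GenomicInterval
    seq: str
    flank: int = 70
    source_variant: Variant | None = None
    clipped_left: int = 0
    clipped_right: int = 0
    applied_edits: tuple[Variant, ...] = ()
    skipped_edits: tuple[Variant, ...] = ()


# ---------------------------------------------------------------------------
# FASTA


def load_reference(fasta_path: str | Path) -> dict[str, str]:
    """Load a FASTA into a contig-name -> uppercase-sequence mapping.

    Duplicate contig names, an empty file, and non-IUPAC characters are
    errors; soft-masked (lowercase) bases are uppercased, N is preserved.
    """
    fasta_path = Path(fasta_path)
    if not fasta_path.exists():
        raise FileNotFoundError(fasta_path)
    store: dict[str, str] = {}
    for record in SeqIO.parse(str(fasta_path), "fasta"):
        if record.id in store:
            raise ValueError(f"duplicate contig name {record.id!r} in {fasta_path}")
        seq = str(record.seq).upper()
        bad = next((i for i, c in enumerate(seq) if c not in _IUPAC_DNA), None)
        if bad is not None:
            raise ValueError(
                f"non-IUPAC character {seq[bad]!r} at {record.id}:{bad + 1}"
            )
        store[record.id] = seq
    if not store:
        raise ValueError(f"empty FASTA: {fasta_path}")
    return store


# ---------------------------------------------------------------------------
# BED


def read_panel(bed_path: str | Path) -> list[GenomicInterval]:
    """Read a BED3+ capture panel; sort and merge overlapping/adjacent rows."""
    bed_path = Path(bed_path)
    raw: list[GenomicInterval] = []
    with open(bed_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise ValueError(f"{bed_path}:{lineno}: fewer than 3 BED columns")
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise ValueError(f"{bed_path}:{lineno}: non-integer coordinates") from exc
            if start >= end or start < 0:
                raise ValueError(
                    f"{bed_path}:{lineno}: invalid interval {chrom}:{start}-{end}"
                )
            raw.append(GenomicInterval(chrom, start, end))
    return merge_intervals(raw)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Sort by (chrom, start) and merge overlapping or adjacent intervals."""
    merged: list[GenomicInterval] = []
    for iv in sorted(intervals, key=lambda iv: (iv.chrom, iv.start, iv.end)):
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            last = merged[-1]
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end)
        else:
            merged.append(iv)
    return merged


def write_panel(intervals: Sequence[GenomicInterval], bed_path: str | Path) -> None:
    with open(bed_path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\n")


def panel_length(intervals: Sequence[GenomicInterval]) -> int:
    return sum(len(iv) for iv in intervals)


# ---------------------------------------------------------------------------
# VCF


def read_variants(
    vcf_path: str | Path,
    sample: str,
    origin: VariantOrigin,
    *,
    keep_nonpass: bool = False,
    af_field: str = "AF",
    consequence_field: str = "CSQ",
) -> list[Variant]:
    """Read one sample's variants from a VCF, splitting multiallelic records.

    Records whose FILTER is neither PASS nor "." are excluded unless
    ``keep_nonpass``.  DP and alternate-allele AD are taken from the named
    sample's FORMAT fields when the VCF carries sample columns, otherwise
    from INFO.  The population allele frequency is read from the
    ``af_field`` INFO key and the consequence label from ``consequence_field``.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(vcf_path))
    sample_idx = vcf.samples.index(sample) if sample in vcf.samples else None
    out: list[Variant] = []
    for rec in vcf:
        if rec.FILTER is not None and not keep_nonpass:
            continue
        dp = _sample_int(rec, "DP", sample_idx)
        af_raw = rec.INFO.get(af_field)
        csq = rec.INFO.get(consequence_field)
        rsid = rec.ID if rec.ID not in (None, ".") else None
        for i, alt in enumerate(rec.ALT):
            if alt in ("*", "<NON_REF>") or not alt:
                continue
            ad_alt = _sample_ad(rec, sample_idx, i)
            af = _alt_value(af_raw, i)
            out.append(
                Variant(
                    chrom=rec.CHROM,
                    pos=rec.POS,
                    ref=rec.REF,
                    alt=alt,
                    sample=sample,
                    origin=origin,
                    dp=dp,
                    ad_alt=ad_alt,
                    af_pop=af,
                    consequence=str(csq) if csq is not None else None,
                    rsid=rsid,
                )
            )
    return out


def _sample_int(rec, key: str, sample_idx: int | None) -> int | None:
    if sample_idx is not None:
        try:
            arr = rec.format(key)
        except KeyError:
            arr = None
        if arr is not None:
            val = int(arr[sample_idx][0])
            return val if val >= 0 else None
    val = rec.INFO.get(key)
    return int(val) if val is not None else None


def _sample_ad(rec, sample_idx: int | None, alt_index: int) -> int | None:
    if sample_idx is None:
        return None
    try:
        arr = rec.format("AD")
    except KeyError:
        return None
    if arr is None:
        return None
    row = arr[sample_idx]
    if len(row) <= alt_index + 1:
        return None
    val = int(row[alt_index + 1])
    return val if val >= 0 else None


def _alt_value(raw, alt_index: int) -> float | None:
    if raw is None:
        return None
    if isinstance(raw, (tuple, list)):
        raw = raw[alt_index] if alt_index < len(raw) else None
        if raw is None:
            return None
    return float(raw)


# ---------------------------------------------------------------------------
# Germline depth filter


@dataclass
class GermlineFilterReport:
    total: int = 0
    kept: int = 0
    dropped: int = 0
    unscored: int = 0


def filter_germline(
    variants: Iterable[Variant],
    min_dp: int = 10,
    min_ad: int = 5,
) -> tuple[list[Variant], GermlineFilterReport]:
    """Depth filter for germline calls: keep DP > min_dp and alt AD > min_ad.

    Both inequalities are strict.  Variants missing either field cannot be
    scored; they are dropped and tallied separately in the report.
    """
    if min_dp < 0 or min_ad < 0:
        raise ValueError("thresholds must be >= 0")
    kept: list[Variant] = []
    report = GermlineFilterReport()
    for v in variants:
        report.total += 1
        if v.dp is None or v.ad_alt is None:
            report.unscored += 1
        elif v.dp > min_dp and v.ad_alt > min_ad:
            report.kept += 1
            kept.append(v)
        else:
            report.dropped += 1
    return kept, report


# ---------------------------------------------------------------------------
# Windows


def extract_window(
    reference: Mapping[str, str],
    variant: Variant,
    flank: int = 70,
) -> SequenceWindow:
    """Extract the +/-flank nt window around a variant's anchor span.

    For an SNV at 1-based position p the interval is [p-1-flank, p+flank),
    nominal length 2*flank+1; indel anchors span len(ref) bases.  Windows
    crossing contig ends are clipped and flagged, never discarded.
    """
    if variant.chrom not in reference:
        raise KeyError(f"contig {variant.chrom!r} absent from reference")
    contig = reference[variant.chrom]
    anchor_start, anchor_end = variant.ref_span
    if not (0 <= anchor_start and anchor_end <= len(contig)):
        raise ValueError(
            f"variant anchor {variant.chrom}:{variant.pos} (+{len(variant.ref)} nt) "
            f"outside contig of length {len(contig)}"
        )
    if contig[anchor_start:anchor_end] != variant.ref:
        raise ValueError(
            f"reference mismatch at {variant.chrom}:{variant.pos}: "
            f"expected {variant.ref!r}, found {contig[anchor_start:anchor_end]!r}"
        )
    nominal_start = anchor_start - flank
    nominal_end = anchor_end + flank
    start = max(0, nominal_start)
    end = min(len(contig), nominal_end)
    return SequenceWindow(
        interval=GenomicInterval(variant.chrom, start, end),
        seq=contig[start:end],
        flank=flank,
        source_variant=variant,
        clipped_left=start - nominal_start,
        clipped_right=nominal_end - end,
    )


def extract_site_window(
    reference: Mapping[str, str], chrom: str, pos0: int, flank: int = 70
) -> SequenceWindow:
    """Window of nominal length 2*flank+1 around a bare genomic position."""
    contig = reference[chrom]
    if not (0 <= pos0 < len(contig)):
        raise ValueError(f"position {chrom}:{pos0} outside contig")
    start = max(0, pos0 - flank)
    end = min(len(contig), pos0 + flank + 1)
    return SequenceWindow(
        interval=GenomicInterval(chrom, start, end),
        seq=contig[start:end],
        flank=flank,
        clipped_left=start - (pos0 - flank),
        clipped_right=(pos0 + flank + 1) - end,
    )


def apply_variants(window: SequenceWindow, edits: Sequence[Variant]) -> SequenceWindow:
    """Apply edits (reference coordinates) to a window's sequence.

    Edits are applied right-to-left so earlier splices never shift later
    offsets; edits already applied to the window are accounted for by
    shifting incoming offsets by their net indel length.  Mutually
    overlapping edits or a ref mismatch raise; edits not fully inside the
    window interval are skipped and recorded.
    """
    iv = window.interval
    inside: list[Variant] = []
    skipped = list(window.skipped_edits)
    for e in edits:
        s, t = e.ref_span
        if e.chrom == iv.chrom and s >= iv.start and t <= iv.end:
            inside.append(e)
        else:
            skipped.append(e)

    spans = [e.ref_span for e in inside] + [p.ref_span for p in window.applied_edits]
    spans.sort()
    for (s1, t1), (s2, t2) in zip(spans, spans[1:]):
        if s2 < t1:
            raise ValueError(
                f"overlapping edits at {iv.chrom}:{s1 + 1}-{t1} and {s2 + 1}-{t2}"
            )

    seq = window.seq
    for e in sorted(inside, key=lambda e: e.pos0, reverse=True):
        # net length change of previously applied edits left of this one
        shift = sum(
            len(p.alt) - len(p.ref)
            for p in window.applied_edits
            if p.ref_span[1] <= e.pos0
        )
        off = e.pos0 - iv.start + shift
        found = seq[off : off + len(e.ref)]
        if found != e.ref:
            raise ValueError(
                f"edit ref mismatch at {e.chrom}:{e.pos}: "
                f"expected {e.ref!r}, window has {found!r}"
            )
        seq = seq[:off] + e.alt + seq[off + len(e.ref) :]

    return replace(
        window,
        seq=seq,
        applied_edits=window.applied_edits + tuple(inside),
        skipped_edits=tuple(skipped),
    )
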