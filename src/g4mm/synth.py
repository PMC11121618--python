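"""Fully synthetic exome-like study generator.

Emulates the study design every pipeline stage needs: reference contigs
with planted weak/strong quadruplex motifs at known coordinates, a capture
panel, per-sample somatic VCFs in which a controllable fraction of
mutation sites is forced within one window-flank of a planted strong
motif, and per-sample germline VCFs with DP/AD depth fields, a population
allele-frequency annotation, and SNPs carried exclusively by a designated
sample group.

All randomness flows from one config seed through independent per-stage
substreams, so regenerating one sample never shifts another; identical
config and seed give byte-identical files.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .g4scan import G4Category, G4Strength, classify_window
from .genome_io import GenomicInterval, Variant, VariantOrigin, write_panel

__all__ = [
    "SampleSpec",
    "GroupSnpSpec",
    "SynthConfig",
    "PlantedMotif",
    "SynthStudy",
    "generate_reference",
    "generate_somatic",
    "generate_germline",
    "build_study",
    "write_study",
    "study_like_cohort",
]

_CONSEQUENCES = (
    "5_prime_UTR_variant",
    "3_prime_UTR_variant",
    "intron_variant",
    "missense_variant",
    "synonymous_variant",
)


@dataclass(frozen=True)
class SampleSpec:
    """One synthetic tumor-normal pair.

    ``g4_enrichment`` is the fraction of somatic sites forced within one
    flank length of a planted strong motif; the rest are background sites
    kept away from every planted motif.
    """

    id: str
    n_somatic: int
    g4_enrichment: float = 0.0
    indel_fraction: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.g4_enrichment <= 1.0:
            raise ValueError("g4_enrichment must lie in [0, 1]")


@dataclass(frozen=True)
class GroupSnpSpec:
    """A germline SNP planted for the designated sample group."""

    af_pop: float
    group_only: bool = True


def _default_samples() -> tuple[SampleSpec, ...]:
    # Mirrors the 11-tumor study scale: per-sample somatic mutation counts
    # as printed in the source cohort, enrichment planted for the three
    # samples labelled G4-strong there.
    counts = {
        "S7": 115, "S12": 63, "P1": 87, "P14": 234, "P20": 182, "P22": 191,
        "P23": 119, "P30": 662, "P34": 267, "P37": 82, "P48": 227,
    }
    strong = {"S12", "P23", "P37"}
    return tuple(
        SampleSpec(sid, n, 0.6 if sid in strong else 0.0)
        for sid, n in counts.items()
    )


def _default_group_snps() -> tuple[GroupSnpSpec, ...]:
    # 15 group-exclusive SNPs of which 8 are rare (population AF < 0.1),
    # matching the cohort the generator emulates.
    rare = [0.02, 0.03, 0.04, 0.05, 0.06, 0.07, 0.08, 0.09]
    common = [0.15, 0.2, 0.25, 0.3, 0.35, 0.4, 0.45]
    return tuple(GroupSnpSpec(af_pop=a, group_only=True) for a in rare + common)


@dataclass(frozen=True)
class SynthConfig:
    n_contigs: int = 2
    contig_length: int = 100_000
    gc_background: float = 0.45
    n_strong_motifs: int = 30
    n_weak_motifs: int = 30
    panel_fraction: float = 0.6
    flank: int = 70
    samples: tuple[SampleSpec, ...] = field(default_factory=_default_samples)
    snp_group: tuple[str, ...] = ("S12", "P23", "P37")
    group_snps: tuple[GroupSnpSpec, ...] = field(default_factory=_default_group_snps)
    n_background_germline: int = 60
    germline_carrier_prob: float = 0.5
    dp_range: tuple[int, int] = (5, 30)
    background_exclusion_nt: int = 200
    seed: int = 0


@dataclass(frozen=True)
class PlantedMotif:
    interval: GenomicInterval
    strength: G4Strength


class _PanelIndex:
    """Membership and distance queries over merged panel intervals."""

    def __init__(self, panel: Sequence[GenomicInterval]):
        self._starts: dict[str, list[int]] = {}
        self._ends: dict[str, list[int]] = {}
        for iv in panel:
            self._starts.setdefault(iv.chrom, []).append(iv.start)
            self._ends.setdefault(iv.chrom, []).append(iv.end)

    def contains(self, chrom: str, pos0: int) -> bool:
        starts = self._starts.get(chrom)
        if not starts:
            return False
        i = bisect.bisect_right(starts, pos0) - 1
        return i >= 0 and pos0 < self._ends[chrom][i]


class _MotifIndex:
    """Nearest-motif distance via sorted motif spans per contig."""

    def __init__(self, motifs: Sequence[PlantedMotif]):
        self._spans: dict[str, list[tuple[int, int]]] = {}
        for m in motifs:
            self._spans.setdefault(m.interval.chrom, []).append(
                (m.interval.start, m.interval.end)
            )
        for spans in self._spans.values():
            spans.sort()

    def min_distance(self, chrom: str, pos0: int) -> int:
        spans = self._spans.get(chrom)
        if not spans:
            return 1 << 30
        i = bisect.bisect_left(spans, (pos0, pos0))
        best = 1 << 30
        for j in (i - 1, i):
            if 0 <= j < len(spans):
                s, e = spans[j]
                if s <= pos0 < e:
                    return 0
                best = min(best, abs(pos0 - s), abs(pos0 - (e - 1)))
        return best


def _substream(seed: int, *tags: int) -> np.random.Generator:
    return np.random.default_rng([seed, *tags])


def _motif_string(rng: np.random.Generator, strength: G4Strength) -> str:
    """Four base runs separated by 1-10 nt A/T loops (no stray G/C runs)."""
    base = "G" if rng.integers(2) == 0 else "C"
    run_lo, run_hi = (3, 4) if strength is G4Strength.STRONG else (2, 2)
    parts = []
    for i in range(4):
        parts.append(base * int(rng.integers(run_lo, run_hi + 1)))
        if i < 3:
            loop_len = int(rng.integers(1, 11))
            parts.append("".join("AT"[b] for b in rng.integers(0, 2, size=loop_len)))
    return "".join(parts)


# ---------------------------------------------------------------------------
# Reference + panel


def _build_panel(config: SynthConfig) -> list[GenomicInterval]:
    """Alternating on/off tiling covering ~panel_fraction of each contig."""
    block = 2000
    on = max(1, round(block * config.panel_fraction))
    panel = []
    for c in range(config.n_contigs):
        chrom = f"chr{c + 1}"
        pos = 0
        while pos < config.contig_length:
            end = min(pos + on, config.contig_length)
            if end > pos:
                panel.append(GenomicInterval(chrom, pos, end))
            pos += block
    return panel


def generate_reference(
    config: SynthConfig,
) -> tuple[dict[str, str], list[GenomicInterval], list[PlantedMotif]]:
    """Random background contigs with non-overlapping planted motifs.

    Background bases are i.i.d. at the configured GC fraction; motifs are
    planted inside panel intervals, separated by at least 300 nt and kept
    one flank length from contig ends.  Every planted locus is verified by
    ``classify_window`` on its own span before being accepted.
    """
    min_footprint = 4 * 2 + 3  # smallest weak motif
    if config.contig_length < 10 * min_footprint:
        raise ValueError("contig_length too small for motif planting")
    rng = _substream(config.seed, 0)
    panel = _build_panel(config)
    panel_by_chrom: dict[str, list[GenomicInterval]] = {}
    for iv in panel:
        panel_by_chrom.setdefault(iv.chrom, []).append(iv)

    gc = config.gc_background
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    reference: dict[str, str] = {}
    motifs: list[PlantedMotif] = []
    for c in range(config.n_contigs):
        chrom = f"chr{c + 1}"
        bases = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=config.contig_length, p=probs)
        seq = bytearray(bases.tobytes())
        placed: list[tuple[int, int]] = []
        plan = [(G4Strength.STRONG, config.n_strong_motifs), (G4Strength.WEAK, config.n_weak_motifs)]
        for strength, count in plan:
            for _ in range(count):
                motif = _motif_string(rng, strength)
                for _attempt in range(1000):
                    iv = panel_by_chrom[chrom][int(rng.integers(len(panel_by_chrom[chrom])))]
                    lo = max(iv.start, config.flank)
                    hi = min(iv.end, config.contig_length - config.flank) - len(motif)
                    if hi <= lo:
                        continue
                    start = int(rng.integers(lo, hi))
                    end = start + len(motif)
                    if all(end + 300 <= s or e + 300 <= start for s, e in placed):
                        break
                else:
                    raise RuntimeError("could not place motif without overlap")
                expected = (
                    G4Category.STRONG if strength is G4Strength.STRONG else G4Category.WEAK
                )
                if classify_window(motif) is not expected:
                    raise AssertionError("planted motif failed self-verification")
                seq[start:end] = motif.encode()
                placed.append((start, end))
                motifs.append(PlantedMotif(GenomicInterval(chrom, start, end), strength))
        reference[chrom] = seq.decode()
    motifs.sort(key=lambda m: (m.interval.chrom, m.interval.start))
    return reference, panel, motifs


# ---------------------------------------------------------------------------
# Somatic variants


@dataclass(frozen=True)
class SomaticTruth:
    sample: str
    chrom: str
    pos: int
    near_motif: bool


def generate_somatic(
    config: SynthConfig,
    sample: SampleSpec,
    reference: Mapping[str, str],
    panel: Sequence[GenomicInterval],
    motifs: Sequence[PlantedMotif],
    *,
    background_exclusion_nt: int | None = None,
) -> tuple[list[Variant], list[SomaticTruth]]:
    """Somatic variants with a planted fraction of near-strong-motif sites.

    round(f * n) sites are placed so their window fully contains a
    uniformly chosen planted strong motif (site within one flank of the
    motif, intersected with the panel); the remainder are uniform over
    panel bases at least ``background_exclusion_nt`` from any planted
    motif (0 makes the background distribution identical to the control
    sampler's).  SNV alt alleles are uniform over the three non-reference
    bases; a configurable fraction of sites become 1-nt indels.
    """
    excl = (
        config.background_exclusion_nt
        if background_exclusion_nt is None
        else background_exclusion_nt
    )
    rng = _substream(config.seed, 1, _sample_tag(config, sample.id))
    panel_idx = _PanelIndex(panel)
    motif_idx = _MotifIndex(motifs)
    strong = [m for m in motifs if m.strength is G4Strength.STRONG]
    n_near = round(sample.g4_enrichment * sample.n_somatic)
    if sample.g4_enrichment > 0 and not strong:
        raise ValueError("no planted strong motifs to enrich around")

    lengths = np.array([len(iv) for iv in panel], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(lengths.sum())
    if total < 10 * sample.n_somatic:
        raise ValueError("panel too small for requested somatic count")

    used: set[tuple[str, int]] = set()
    sites: list[tuple[str, int, bool]] = []
    for _ in range(n_near):
        for _attempt in range(10_000):
            m = strong[int(rng.integers(len(strong)))]
            iv = m.interval
            lo = iv.end - 1 - config.flank
            hi = iv.start + config.flank  # inclusive; window then contains the motif
            pos0 = int(rng.integers(lo, hi + 1))
            chrom = iv.chrom
            if (
                panel_idx.contains(chrom, pos0)
                and (chrom, pos0) not in used
                and reference[chrom][pos0] != "N"
            ):
                break
        else:
            raise RuntimeError("could not place near-motif somatic site")
        used.add((chrom, pos0))
        sites.append((chrom, pos0, True))
    for _ in range(sample.n_somatic - n_near):
        for _attempt in range(100_000):
            d = int(rng.integers(total))
            idx = int(np.searchsorted(offsets, d, side="right") - 1)
            iv = panel[idx]
            pos0 = iv.start + (d - int(offsets[idx]))
            chrom = iv.chrom
            if (
                motif_idx.min_distance(chrom, pos0) >= excl
                and (chrom, pos0) not in used
                and reference[chrom][pos0] != "N"
            ):
                break
        else:
            raise RuntimeError("could not place background somatic site")
        used.add((chrom, pos0))
        sites.append((chrom, pos0, False))

    variants: list[Variant] = []
    truth: list[SomaticTruth] = []
    for chrom, pos0, near in sites:
        ref_base = reference[chrom][pos0]
        r = rng.random()
        if r < sample.indel_fraction and pos0 + 1 < len(reference[chrom]):
            if rng.random() < 0.5:  # 1-nt deletion anchored at pos0
                ref = reference[chrom][pos0 : pos0 + 2]
                alt = ref_base
            else:  # 1-nt insertion after pos0
                ref = ref_base
                alt = ref_base + "ACGT"[int(rng.integers(4))]
        else:
            others = [b for b in "ACGT" if b != ref_base]
            ref = ref_base
            alt = others[int(rng.integers(3))]
        variants.append(
            Variant(
                chrom=chrom,
                pos=pos0 + 1,
                ref=ref,
                alt=alt,
                sample=sample.id,
                origin=VariantOrigin.SOMATIC,
                consequence=_CONSEQUENCES[int(rng.integers(len(_CONSEQUENCES)))],
            )
        )
        truth.append(SomaticTruth(sample.id, chrom, pos0 + 1, near))
    order = sorted(range(len(variants)), key=lambda i: (variants[i].chrom, variants[i].pos))
    return [variants[i] for i in order], [truth[i] for i in order]


def _sample_tag(config: SynthConfig, sample_id: str) -> int:
    return next(i for i, s in enumerate(config.samples) if s.id == sample_id)


# ---------------------------------------------------------------------------
# Germline variants


def generate_germline(
    config: SynthConfig,
    reference: Mapping[str, str],
    panel: Sequence[GenomicInterval],
) -> tuple[dict[str, list[Variant]], list[tuple[str, int, str, str]]]:
    """Per-sample germline SNVs with DP/AD and population AF annotations.

    Group SNPs are written to exactly the configured group samples (plus
    one outside carrier when not group-only); background SNPs go to random
    sample subsets (never exactly the group, so the planted exclusive set
    stays unambiguous).  Returns (variants per sample, group-exclusive
    truth keys).
    """
    rng = _substream(config.seed, 2)
    sample_ids = [s.id for s in config.samples]
    group = [s for s in sample_ids if s in config.snp_group]
    others = [s for s in sample_ids if s not in config.snp_group]
    if config.group_snps and (not group or not others):
        raise ValueError("snp_group must be a non-empty strict subset of samples")

    lengths = np.array([len(iv) for iv in panel], dtype=np.int64)
    offsets = np.concatenate([[0], np.cumsum(lengths)])
    total = int(lengths.sum())
    used: set[tuple[str, int]] = set()

    def draw_site() -> tuple[str, int, str]:
        while True:
            d = int(rng.integers(total))
            idx = int(np.searchsorted(offsets, d, side="right") - 1)
            iv = panel[idx]
            pos0 = iv.start + (d - int(offsets[idx]))
            base = reference[iv.chrom][pos0]
            if base != "N" and (iv.chrom, pos0) not in used:
                used.add((iv.chrom, pos0))
                return iv.chrom, pos0, base

    per_sample: dict[str, list[Variant]] = {s: [] for s in sample_ids}
    truth_keys: list[tuple[str, int, str, str]] = []

    def emit(chrom: str, pos0: int, ref: str, alt: str, af: float, carriers: Sequence[str]) -> None:
        for sid in carriers:
            dp = int(rng.integers(config.dp_range[0], config.dp_range[1] + 1))
            ad = int(rng.binomial(dp, 0.5))
            per_sample[sid].append(
                Variant(
                    chrom=chrom,
                    pos=pos0 + 1,
                    ref=ref,
                    alt=alt,
                    sample=sid,
                    origin=VariantOrigin.GERMLINE,
                    dp=dp,
                    ad_alt=ad,
                    af_pop=af,
                )
            )

    for spec in config.group_snps:
        chrom, pos0, ref = draw_site()
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
        carriers = list(group)
        if not spec.group_only:
            carriers.append(others[int(rng.integers(len(others)))])
        emit(chrom, pos0, ref, alt, spec.af_pop, carriers)
        if spec.group_only:
            truth_keys.append((chrom, pos0 + 1, ref, alt))

    group_set = set(group)
    for _ in range(config.n_background_germline):
        chrom, pos0, ref = draw_site()
        alt = [b for b in "ACGT" if b != ref][int(rng.integers(3))]
        af = round(float(rng.uniform(0.01, 0.6)), 3)
        for _attempt in range(1000):
            mask = rng.random(len(sample_ids)) < config.germline_carrier_prob
            carriers = [sid for sid, m in zip(sample_ids, mask) if m]
            if carriers and set(carriers) != group_set:
                break
        emit(chrom, pos0, ref, alt, af, carriers)

    for sid in per_sample:
        per_sample[sid].sort(key=lambda v: (v.chrom, v.pos))
    return per_sample, sorted(truth_keys)


# ---------------------------------------------------------------------------
# Whole-study assembly and file output


@dataclass
class SynthStudy:
    config: SynthConfig
    reference: dict[str, str]
    panel: list[GenomicInterval]
    motifs: list[PlantedMotif]
    somatic: dict[str, list[Variant]]
    somatic_truth: dict[str, list[SomaticTruth]]
    germline: dict[str, list[Variant]]
    exclusive_truth: list[tuple[str, int, str, str]]


def build_study(config: SynthConfig) -> SynthStudy:
    """Generate the full synthetic study in memory."""
    reference, panel, motifs = generate_reference(config)
    somatic: dict[str, list[Variant]] = {}
    somatic_truth: dict[str, list[SomaticTruth]] = {}
    for spec in config.samples:
        variants, truth = generate_somatic(config, spec, reference, panel, motifs)
        somatic[spec.id] = variants
        somatic_truth[spec.id] = truth
    germline, exclusive_truth = generate_germline(config, reference, panel)
    return SynthStudy(
        config=config,
        reference=reference,
        panel=panel,
        motifs=motifs,
        somatic=somatic,
        somatic_truth=somatic_truth,
        germline=germline,
        exclusive_truth=exclusive_truth,
    )


def _write_fasta(reference: Mapping[str, str], path: Path) -> None:
    with open(path, "w") as fh:
        for name in reference:
            fh.write(f">{name}\n")
            seq = reference[name]
            for i in range(0, len(seq), 60):
                fh.write(seq[i : i + 60] + "\n")


def _vcf_header(reference: Mapping[str, str], sample: str) -> str:
    lines = ["##fileformat=VCFv4.2"]
    for name, seq in reference.items():
        lines.append(f"##contig=<ID={name},length={len(seq)}>")
    lines += [
        '##INFO=<ID=AF,Number=A,Type=Float,Description="Population allele frequency">',
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence label">',
        '##FILTER=<ID=PASS,Description="All filters passed">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">',
        f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}",
    ]
    return "\n".join(lines) + "\n"


def write_vcf(variants: Sequence[Variant], reference: Mapping[str, str], sample: str, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(_vcf_header(reference, sample))
        for v in variants:
            info_parts = []
            if v.af_pop is not None:
                info_parts.append(f"AF={v.af_pop:g}")
            if v.consequence:
                info_parts.append(f"CSQ={v.consequence}")
            info = ";".join(info_parts) if info_parts else "."
            if v.dp is not None and v.ad_alt is not None:
                fmt, gt = "GT:DP:AD", f"0/1:{v.dp}:{v.dp - v.ad_alt},{v.ad_alt}"
            else:
                fmt, gt = "GT", "0/1"
            rsid = v.rsid or "."
            fh.write(
                f"{v.chrom}\t{v.pos}\t{rsid}\t{v.ref}\t{v.alt}\t.\tPASS\t{info}\t{fmt}\t{gt}\n"
            )


def write_study(study: SynthStudy, out_dir: str | Path) -> dict[str, Path]:
    """Write the study to disk: FASTA, panel/truth BEDs, truth TSV, VCFs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    paths["reference"] = out / "reference.fa"
    _write_fasta(study.reference, paths["reference"])
    paths["panel"] = out / "panel.bed"
    write_panel(study.panel, paths["panel"])
    paths["truth_motifs"] = out / "truth_motifs.bed"
    with open(paths["truth_motifs"], "w") as fh:
        for m in study.motifs:
            fh.write(
                f"{m.interval.chrom}\t{m.interval.start}\t{m.interval.end}\t{m.strength.value}\n"
            )
    paths["truth_somatic"] = out / "truth_somatic.tsv"
    with open(paths["truth_somatic"], "w") as fh:
        fh.write("sample\tchrom\tpos\tnear_motif\n")
        for sid in study.somatic_truth:
            for t in study.somatic_truth[sid]:
                fh.write(f"{t.sample}\t{t.chrom}\t{t.pos}\t{int(t.near_motif)}\n")
    paths["truth_exclusive"] = out / "truth_exclusive_snps.tsv"
    with open(paths["truth_exclusive"], "w") as fh:
        fh.write("chrom\tpos\tref\talt\n")
        for chrom, pos, ref, alt in study.exclusive_truth:
            fh.write(f"{chrom}\t{pos}\t{ref}\t{alt}\n")
    for sid in study.somatic:
        p = out / f"{sid}.somatic.vcf"
        write_vcf(study.somatic[sid], study.reference, sid, p)
        paths[f"somatic:{sid}"] = p
    for sid in study.germline:
        p = out / f"{sid}.germline.vcf"
        write_vcf(study.germline[sid], study.reference, sid, p)
        paths[f"germline:{sid}"] = p
    return paths


def signal_recovery_rates(
    base_config: SynthConfig | None = None,
    *,
    enrichment_fractions: Sequence[float] = (0.0, 0.3, 0.6),
    n_replicates: int = 50,
    n_somatic: int = 100,
    n_controls: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
    null_background_exclusion: int = 0,
) -> dict[float, float]:
    """G4_STRONG detection rate vs. planted enrichment fraction.

    For each fraction f, n_replicates independent tumors of ``n_somatic``
    mutations are generated on one fixed synthetic genome and each is
    tested against a freshly drawn control set of ``n_controls`` windows.
    At f=0 the background exclusion defaults to 0 nt so null somatic sites
    are placed uniformly over the panel — the same distribution the
    control sampler draws from — making the observed label rate a direct
    estimate of the procedure's type-I error; at f>0 the generator's
    configured exclusion keeps truth labels unambiguous and the rate
    estimates power.
    """
    from dataclasses import replace

    from .enrichment import SampleLabel, evaluate_sample_categories, sample_random_windows
    from .genome_io import extract_window

    config = base_config if base_config is not None else SynthConfig(seed=seed)
    reference, panel, motifs = generate_reference(config)
    rates: dict[float, float] = {}
    for fi, f in enumerate(enrichment_fractions):
        detected = 0
        for rep in range(n_replicates):
            rep_seed = (seed * 1_000_003 + fi * 100_000 + rep) % (2**31)
            cfg = replace(config, seed=rep_seed, samples=(SampleSpec("SIM", n_somatic, f),))
            excl = null_background_exclusion if f == 0 else None
            variants, _ = generate_somatic(
                cfg, cfg.samples[0], reference, panel, motifs,
                background_exclusion_nt=excl,
            )
            tumor = [
                classify_window(extract_window(reference, v, config.flank).seq)
                for v in variants
            ]
            controls = sample_random_windows(
                reference, panel, n=n_controls, flank=config.flank,
                rng=np.random.default_rng([seed, 6, fi, rep]),
            )
            control = [classify_window(w.seq) for w in controls]
            _, label = evaluate_sample_categories(tumor, control, alpha)
            detected += label is SampleLabel.G4_STRONG
        rates[f] = detected / n_replicates
    return rates


def study_like_cohort(seed: int = 0, **overrides) -> SynthConfig:
    """Convenience: the default study-scale config with a chosen seed."""
    return SynthConfig(seed=seed, **overrides)
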