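"""End-to-end orchestration from one declarative run config.

Stages: ingest reference/panels/VCFs -> per-variant windows -> germline
edit application -> G4 classification -> per-sample enrichment vs. the
panel-matched random control -> group summary -> mutation spectra ->
G4-change records -> consequence tabulation -> cohort germline analyses.
Every output is a plain TSV (plot-ready) plus a machine-readable JSON
manifest; a rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import enrichment as enrich_mod
from . import genome_io as gio
from . import spectra as spectra_mod
from .g4scan import G4Category, classify_window, g4_change_on_mutation

__all__ = ["SampleEntry", "RunConfig", "run"]


@dataclass(frozen=True)
class SampleEntry:
    id: str
    somatic_vcf: str
    panel: str
    germline_vcf: str | None = None


@dataclass(frozen=True)
class RunConfig:
    reference: str
    panels: dict[str, str]
    samples: tuple[SampleEntry, ...]
    n_controls: int = 2000
    flank: int = 70
    seed: int = 0
    alpha: float = 0.05
    continuity: bool = False
    strict_loops: bool = False
    keep_nonpass: bool = False
    bh_correction: bool = False
    min_dp: int = 10
    min_ad: int = 5
    max_af: float = 0.1
    af_field: str = "AF"
    consequence_field: str = "CSQ"
    snp_group: tuple[str, ...] = ()  # empty = use the labelled G4_STRONG samples
    patient_metadata: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        samples = tuple(SampleEntry(**entry) for entry in raw.pop("samples"))
        raw["samples"] = samples
        if "snp_group" in raw:
            raw["snp_group"] = tuple(raw["snp_group"])
        return cls(**raw)

    def validate(self) -> None:
        if not Path(self.reference).exists():
            raise FileNotFoundError(f"reference not found: {self.reference}")
        for pid, ppath in self.panels.items():
            if not Path(ppath).exists():
                raise FileNotFoundError(f"panel {pid!r} not found: {ppath}")
        ids = [s.id for s in self.samples]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate sample ids in config")
        for s in self.samples:
            if s.panel not in self.panels:
                raise ValueError(f"sample {s.id}: unknown panel id {s.panel!r}")
            if not Path(s.somatic_vcf).exists():
                raise FileNotFoundError(f"sample {s.id}: {s.somatic_vcf}")
            if s.germline_vcf is not None and not Path(s.germline_vcf).exists():
                raise FileNotFoundError(f"sample {s.id}: {s.germline_vcf}")
        if self.patient_metadata is not None and not Path(self.patient_metadata).exists():
            raise FileNotFoundError(self.patient_metadata)

    def content_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()


def _overlapping_edits(
    edits: Sequence[gio.Variant], window: gio.SequenceWindow, somatic: gio.Variant
) -> list[gio.Variant]:
    """Germline edits fully inside the window and clear of the somatic anchor."""
    iv = window.interval
    s_lo, s_hi = somatic.ref_span
    out = []
    for e in edits:
        lo, hi = e.ref_span
        if e.chrom == iv.chrom and lo >= iv.start and hi <= iv.end:
            if hi <= s_lo or lo >= s_hi:
                out.append(e)
    return out


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def run(config: RunConfig, out_dir: str | Path) -> Path:
    """Execute the full analysis and write the report directory."""
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reference = gio.load_reference(config.reference)
    panels = {pid: gio.read_panel(p) for pid, p in config.panels.items()}

    # one control window set per panel, classified once on reference sequence
    control_cats: dict[str, list[G4Category]] = {}
    control_counts: dict[str, dict[str, int]] = {}
    for i, pid in enumerate(sorted(panels)):
        rng = np.random.default_rng([config.seed, 3, i])
        windows = enrich_mod.sample_random_windows(
            reference, panels[pid], n=config.n_controls, flank=config.flank, rng=rng
        )
        cats = [classify_window(w.seq, strict_loops=config.strict_loops) for w in windows]
        control_cats[pid] = cats
        control_counts[pid] = {
            "STRONG": sum(c is G4Category.STRONG for c in cats),
            "WEAK_PLUS_STRONG": sum(c is not G4Category.NONE for c in cats),
            "n": len(cats),
        }

    per_sample_rows: list[dict] = []
    change_rows: list[dict] = []
    category_rows: list[dict] = []
    classified_pairs: list[tuple[gio.Variant, G4Category]] = []
    labels: dict[str, enrich_mod.SampleLabel] = {}
    results_by_sample: dict[str, list[enrich_mod.EnrichmentResult]] = {}
    mutation_counts: dict[str, int] = {}
    germline_reports: list[dict] = []
    germline_keys: dict[str, set] = {}
    germline_variants: dict[str, list[gio.Variant]] = {}
    stage_counts: dict[str, dict] = {}

    for entry in config.samples:
        try:
            somatic = gio.read_variants(
                entry.somatic_vcf,
                entry.id,
                gio.VariantOrigin.SOMATIC,
                keep_nonpass=config.keep_nonpass,
                af_field=config.af_field,
                consequence_field=config.consequence_field,
            )
            germline: list[gio.Variant] = []
            if entry.germline_vcf is not None:
                raw = gio.read_variants(
                    entry.germline_vcf,
                    entry.id,
                    gio.VariantOrigin.GERMLINE,
                    keep_nonpass=config.keep_nonpass,
                    af_field=config.af_field,
                    consequence_field=config.consequence_field,
                )
                germline, report = gio.filter_germline(raw, config.min_dp, config.min_ad)
                germline_reports.append({"sample": entry.id, **vars(report)})
                germline_keys[entry.id] = {v.key for v in germline}
                germline_variants[entry.id] = germline

            tumor_cats: list[G4Category] = []
            for v in somatic:
                window = gio.extract_window(reference, v, config.flank)
                edits = _overlapping_edits(germline, window, v)
                if edits:
                    window = gio.apply_variants(window, edits)
                cat = classify_window(window.seq, strict_loops=config.strict_loops)
                tumor_cats.append(cat)
                classified_pairs.append((v, cat))
                category_rows.append(
                    {
                        "sample": entry.id,
                        "chrom": v.chrom,
                        "pos": v.pos,
                        "ref": v.ref,
                        "alt": v.alt,
                        "vclass": v.vclass.value,
                        "category": cat.value,
                        "consequence": v.consequence or "unannotated",
                    }
                )
                change = g4_change_on_mutation(window, v, strict_loops=config.strict_loops)
                if change.changed:
                    change_rows.append(
                        {
                            "sample": entry.id,
                            "chrom": v.chrom,
                            "pos": v.pos,
                            "ref": v.ref,
                            "alt": v.alt,
                            "before": change.before.value,
                            "after": change.after.value,
                            "transition": change.transition,
                            "consequence": v.consequence or "unannotated",
                        }
                    )

            results, label = enrich_mod.evaluate_sample_categories(
                tumor_cats,
                control_cats[entry.panel],
                config.alpha,
                sample=entry.id,
                continuity=config.continuity,
            )
            labels[entry.id] = label
            results_by_sample[entry.id] = results
            mutation_counts[entry.id] = len(somatic)
            stage_counts[entry.id] = {
                "somatic_in": len(somatic),
                "windows_analyzed": len(tumor_cats),
                "excluded": 0,
            }
        except Exception as exc:
            raise RuntimeError(f"sample {entry.id}: stage failed: {exc}") from exc

    if config.bh_correction:
        labels = _bh_relabel(results_by_sample, config.alpha)

    for entry in config.samples:
        for res in results_by_sample[entry.id]:
            per_sample_rows.append(
                {
                    "sample": res.sample,
                    "panel": entry.panel,
                    "context": res.context.value,
                    "k_tumor": res.table.k_tumor,
                    "n_tumor": res.table.n_tumor,
                    "k_control": res.table.k_control,
                    "n_control": res.table.n_control,
                    "prop_tumor": res.prop_tumor,
                    "prop_control": res.prop_control,
                    "wilson_tumor_lo": res.wilson_tumor[0],
                    "wilson_tumor_hi": res.wilson_tumor[1],
                    "wilson_control_lo": res.wilson_control[0],
                    "wilson_control_hi": res.wilson_control[1],
                    "chi2_stat": res.chi2_stat,
                    "chi2_p": res.chi2_p,
                    "z_stat": res.z_stat,
                    "z_p": res.z_p,
                    "significant_enrichment": res.significant_enrichment,
                    "label": labels[res.sample].value,
                }
            )
    _write_tsv(pd.DataFrame(per_sample_rows), out / "enrichment_per_sample.tsv")
    _write_tsv(pd.DataFrame(category_rows), out / "variant_categories.tsv")

    summary = enrich_mod.summarize_groups(labels, mutation_counts)
    _write_tsv(summary, out / "summary_groups.tsv")

    # bar-plot-ready percentages with Wilson CIs: samples then controls
    fig_rows = []
    for entry in config.samples:
        res = next(
            r
            for r in results_by_sample[entry.id]
            if r.context is enrich_mod.Context.STRONG
        )
        fig_rows.append(
            {
                "set": entry.id,
                "kind": "tumor",
                "percent": 100.0 * res.prop_tumor,
                "ci_lo": 100.0 * res.wilson_tumor[0],
                "ci_hi": 100.0 * res.wilson_tumor[1],
                "significant": res.significant_enrichment,
            }
        )
    for pid in sorted(panels):
        cc = control_counts[pid]
        lo, hi = enrich_mod.wilson_interval(cc["STRONG"], cc["n"])
        fig_rows.append(
            {
                "set": f"random_{pid}",
                "kind": "control",
                "percent": 100.0 * cc["STRONG"] / cc["n"],
                "ci_lo": 100.0 * lo,
                "ci_hi": 100.0 * hi,
                "significant": False,
            }
        )
    _write_tsv(pd.DataFrame(fig_rows), out / "strong_context_percentages.tsv")

    group_of = {
        entry.id: (
            spectra_mod.SpectrumGroup.ENRICHED
            if labels[entry.id] is enrich_mod.SampleLabel.G4_STRONG
            else spectra_mod.SpectrumGroup.NOT_ENRICHED
        )
        for entry in config.samples
    }
    tables, non_snv = spectra_mod.build_spectra(classified_pairs, group_of)
    _write_tsv(spectra_mod.spectra_long_table(tables), out / "spectra.tsv")

    _write_tsv(
        pd.DataFrame(
            change_rows,
            columns=[
                "sample", "chrom", "pos", "ref", "alt",
                "before", "after", "transition", "consequence",
            ],
        ),
        out / "g4_changes.tsv",
    )
    _write_tsv(spectra_mod.consequence_by_g4(classified_pairs), out / "consequence_by_g4.tsv")

    if germline_reports:
        _write_tsv(pd.DataFrame(germline_reports), out / "germline_filter_report.tsv")

    exclusive_rows: list[dict] = []
    group = tuple(config.snp_group) or tuple(
        s for s, lab in labels.items() if lab is enrich_mod.SampleLabel.G4_STRONG
    )
    have_all_germline = set(germline_keys) == {s.id for s in config.samples}
    if group and have_all_germline and set(group) != set(germline_keys):
        exclusive = cohort_mod.group_exclusive_snps(germline_keys, group)
        af_by_key = {
            v.key: v.af_pop
            for vs in germline_variants.values()
            for v in vs
            if v.key in exclusive
        }
        variants = [
            gio.Variant(chrom=k[0], pos=k[1], ref=k[2], alt=k[3], af_pop=af_by_key.get(k))
            for k in sorted(exclusive)
        ]
        kept, unknown = cohort_mod.filter_by_population_frequency(variants, config.max_af)
        for k in sorted(exclusive):
            exclusive_rows.append(
                {
                    "chrom": k[0],
                    "pos": k[1],
                    "ref": k[2],
                    "alt": k[3],
                    "af_pop": af_by_key.get(k),
                    "low_af": k in kept,
                    "af_unknown": k in unknown,
                }
            )
    _write_tsv(
        pd.DataFrame(
            exclusive_rows,
            columns=["chrom", "pos", "ref", "alt", "af_pop", "low_af", "af_unknown"],
        ),
        out / "group_exclusive_snps.tsv",
    )

    if config.patient_metadata is not None:
        meta = pd.read_csv(config.patient_metadata, sep="\t")
        summary_dict = cohort_mod.cohort_summary(meta)
        _write_tsv(pd.DataFrame([summary_dict]), out / "cohort_summary.tsv")

    from . import __version__

    manifest = {
        "package_version": __version__,
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "alpha": config.alpha,
        "n_controls": config.n_controls,
        "flank": config.flank,
        "labels": {s: labels[s].value for s in sorted(labels)},
        "mutation_counts": {s: mutation_counts[s] for s in sorted(mutation_counts)},
        "control_counts": control_counts,
        "stage_counts": stage_counts,
        "spectra_excluded_non_snv": non_snv,
        "n_g4_change_cases": len(change_rows),
        "snp_group_used": list(group),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out


def _bh_relabel(
    results_by_sample: dict[str, list[enrich_mod.EnrichmentResult]],
    alpha: float,
) -> dict[str, enrich_mod.SampleLabel]:
    """Benjamini-Hochberg adjustment of one-sided p-values across samples."""
    from statsmodels.stats.multitest import multipletests

    labels: dict[str, enrich_mod.SampleLabel] = {}
    adjusted: dict[enrich_mod.Context, dict[str, bool]] = {}
    for context in (enrich_mod.Context.STRONG, enrich_mod.Context.WEAK_PLUS_STRONG):
        entries = []
        for sid, results in results_by_sample.items():
            res = next(r for r in results if r.context is context)
            if res.degenerate or res.z_stat <= 0:
                p_one = 1.0
            else:
                p_one = res.z_p / 2.0
            entries.append((sid, p_one, res.prop_tumor > res.prop_control))
        reject, *_ = multipletests([p for _, p, _ in entries], alpha=alpha, method="fdr_bh")
        adjusted[context] = {
            sid: bool(rej and positive)
            for (sid, _, positive), rej in zip(entries, reject)
        }
    for sid in results_by_sample:
        if adjusted[enrich_mod.Context.STRONG][sid]:
            labels[sid] = enrich_mod.SampleLabel.G4_STRONG
        elif adjusted[enrich_mod.Context.WEAK_PLUS_STRONG][sid]:
            labels[sid] = enrich_mod.SampleLabel.G4_WEAK_PLUS_STRONG
        else:
            labels[sid] = enrich_mod.SampleLabel.NONE
    return labels
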