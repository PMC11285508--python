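"""End-to-end orchestration: peak merging and annotation, filters,
differential initiation and expression, intersection, enhancer pairing and
TFBS enrichment, with a machine-readable report.

Results go to files; structured log lines go to stderr only, so stdout
stays pipe-safe.
"""

from __future__ import annotations

import dataclasses
import glob
import json
import logging
import sys
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .counts_differential import (
    CountMatrix,
    SampleSheet,
    filter_min_cpm,
    filter_min_initiation,
    fit_differential,
    pca_top_features,
    read_counts_tsv,
)
from .enhancer_pairing import pair_enhancers
from .genome_annotation import (
    annotate_peaks,
    extract_fasta_windows,
    merge_peaks,
    read_bed,
    read_gtf,
    write_bed,
    write_peak_table,
)
from .intersection_analysis import (
    candidate_enrichment,
    category_gtest,
    join_di_de,
    read_candidate_list,
)
from .motif_enrichment import (
    build_enhancer_background,
    build_promoter_background,
    enrich,
    enrichment_frame,
    read_jaspar,
    tf_expression_support,
)
from .peak_classification import (
    classify_stability,
    filter_input_contamination,
    flag_putative_enhancers,
    read_window_coverage,
)

__all__ = ["PipelineConfig", "run_all"]

logger = logging.getLogger("nascentreg")


def _setup_logging():
    if not logger.handlers:
        handler = logging.StreamHandler(sys.stderr)
        handler.setFormatter(
            logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
        )
        logger.addHandler(handler)
        logger.setLevel(logging.INFO)


@dataclass
class PipelineConfig:
    """Paths and thresholds for a full run.  Every analysis parameter is
    surfaced here; none are hard-coded in the stages."""

    data_dir: str = "."
    csrna_counts: str = "csrna_counts.tsv"
    input_counts: str = "input_counts.tsv"
    mrna_counts: str = "mrna_counts.tsv"
    window_coverage: str = "mrna_window_coverage.tsv"
    samples: str = "samples.tsv"
    gtf: str = "genes.gtf"
    fasta: str = "genome.fa"
    motifs: str = "motifs.jaspar"
    candidates: str = "candidates.txt"
    peaks_glob: str = "peaks_cs_*.bed"

    fdr: float = 0.05
    motif_alpha: float = 0.01
    max_deficit: float = 0.15
    min_cpm: float = 5.0
    min_nonzero: int = 5
    min_initiation_reads_per_1e7: float = 7.0
    min_input_fold: float = 2.0
    min_stability_reads: float = 5.0
    enhancer_distal_bp: float = 500.0
    pairing_window: int = 500_000
    residual_cut: float = 1.0
    bg_n: int = 1000
    test: str = "lrt"
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.fdr < 1.0) or not (0.0 < self.motif_alpha < 1.0):
            raise ValueError("fdr and motif_alpha must lie in (0, 1)")
        for name in ("max_deficit", "min_cpm", "min_initiation_reads_per_1e7",
                     "enhancer_distal_bp", "pairing_window", "residual_cut", "bg_n"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")

    def path(self, attr: str) -> Path:
        return Path(self.data_dir) / getattr(self, attr)

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)


def _stage(report: dict, name: str):
    logger.info("stage %s", name)
    report["stages"].append(name)


def run_all(config: PipelineConfig, out_dir) -> dict:
    """Run every stage in dependency order and write stage outputs plus
    report.json to ``out_dir``.  Returns the report dict."""
    _setup_logging()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": {
            k: getattr(config, k)
            for k in (
                "fdr", "motif_alpha", "max_deficit", "min_cpm", "min_nonzero",
                "min_initiation_reads_per_1e7", "min_input_fold",
                "min_stability_reads", "enhancer_distal_bp", "pairing_window",
                "residual_cut", "bg_n", "test",
            )
        },
        "stages": [],
        "counts": {},
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    C = report["counts"]

    # ---- merge + annotate ----------------------------------------------
    _stage(report, "merge_peaks")
    bed_paths = sorted(glob.glob(str(Path(config.data_dir) / config.peaks_glob)))
    if not bed_paths:
        raise FileNotFoundError(f"no peak BED files match {config.peaks_glob}")
    per_sample = [read_bed(p) for p in bed_paths]
    merged = merge_peaks(per_sample)
    C["peaks_input"] = sum(len(s) for s in per_sample)
    C["peaks_merged"] = len(merged)
    write_bed(merged, out / "merged_peaks.bed")

    _stage(report, "annotate")
    genes = read_gtf(config.path("gtf"))
    merged = annotate_peaks(merged, genes)
    C["genes"] = len(genes)

    # ---- csRNA filters ---------------------------------------------------
    _stage(report, "filters")
    sheet = SampleSheet.read_tsv(config.path("samples"))
    cs_counts = read_counts_tsv(config.path("csrna_counts"))
    missing = set(cs_counts.feature_ids) ^ {p.peak_id for p in merged}
    if missing:
        raise ValueError(
            f"csRNA count matrix and merged peaks disagree on {len(missing)} peak ids"
        )
    keep_init = filter_min_initiation(cs_counts, config.min_initiation_reads_per_1e7)
    in_counts = read_counts_tsv(config.path("input_counts"))
    cs_cpm_mean = cs_counts.cpm().mean(axis=1)
    in_cpm_mean = (
        in_counts.subset_features(cs_counts.feature_ids).cpm().mean(axis=1)
    )
    keep_input = filter_input_contamination(
        cs_cpm_mean, in_cpm_mean, min_fold=config.min_input_fold
    )
    keep = keep_init & keep_input
    C["peaks_failed_initiation"] = int((~keep_init).sum())
    C["peaks_failed_input_filter"] = int((~keep_input).sum())
    C["peaks_kept"] = int(keep.sum())
    cs_counts = cs_counts.subset_features(keep)
    kept_ids = set(cs_counts.feature_ids)
    peaks = [p for p in merged if p.peak_id in kept_ids]

    _stage(report, "stability")
    coverage = read_window_coverage(config.path("window_coverage"))
    calls = classify_stability(
        coverage.reindex([p.peak_id for p in peaks]).fillna(0.0),
        config.min_stability_reads,
    )
    for p in peaks:
        p.stability = calls[p.peak_id]
    C["peaks_stable"] = int((calls == "stable").sum())
    C["peaks_unstable"] = int((calls == "unstable").sum())
    write_peak_table(peaks, out / "annotated_peaks.tsv")

    # ---- differential initiation / expression ---------------------------
    _stage(report, "differential_csrna")
    cs_sheet = sheet.for_assay("csrna")
    di = fit_differential(cs_counts, cs_sheet, test=config.test)
    di.to_csv(out / "differential_initiation.tsv", sep="\t", index=False)
    di_sig = di[di["fdr"] < config.fdr]
    C["di_peaks"] = int(len(di_sig))
    C["di_peaks_up"] = int((di_sig["log2fc"] > 0).sum())
    C["di_peaks_down"] = int((di_sig["log2fc"] < 0).sum())
    pca = pca_top_features(cs_counts)
    pca.to_csv(out / "pca_csrna.tsv", sep="\t", index_label="sample_id")

    _stage(report, "differential_mrna")
    mr_counts = read_counts_tsv(config.path("mrna_counts"))
    keep_genes = filter_min_cpm(mr_counts, config.min_cpm, config.min_nonzero)
    C["genes_failed_cpm_filter"] = int((~keep_genes).sum())
    mr_counts = mr_counts.subset_features(keep_genes)
    de = fit_differential(mr_counts, sheet.for_assay("mrna"), test="qlf")
    de.to_csv(out / "differential_expression.tsv", sep="\t", index=False)
    de_sig = de[de["fdr"] < config.fdr]
    C["de_genes"] = int(len(de_sig))
    C["de_genes_up"] = int((de_sig["log2fc"] > 0).sum())
    C["de_genes_down"] = int((de_sig["log2fc"] < 0).sum())

    # ---- intersection ----------------------------------------------------
    _stage(report, "intersect")
    joins = join_di_de(di, de, peaks, config.fdr)
    joins.to_csv(out / "di_de_joins.tsv", sep="\t", index=False)
    C["joins"] = int(len(joins))
    for cls in ("parallel_up", "parallel_down", "divergent", "not_de"):
        C[f"joins_{cls}"] = int((joins["direction_class"] == cls).sum())
    C["joins_no_gene"] = joins.attrs["n_no_gene"]

    categories = ["promoter-TSS", "TTS", "exon", "intron", "intergenic"]
    all_cat = pd.Series([p.category for p in peaks]).value_counts()
    all_props = np.array([all_cat.get(c, 0) for c in categories], dtype=float)
    all_props = all_props / all_props.sum()
    gtests = {}
    di_ids = set(di_sig["feature_id"])
    subsets = {
        "di": [p for p in peaks if p.peak_id in di_ids],
        "parallel_up": set(joins.loc[joins["direction_class"] == "parallel_up", "peak_id"]),
        "parallel_down": set(joins.loc[joins["direction_class"] == "parallel_down", "peak_id"]),
    }
    for name, members in subsets.items():
        ids = members if isinstance(members, set) else {p.peak_id for p in members}
        sub = pd.Series([p.category for p in peaks if p.peak_id in ids]).value_counts()
        obs = np.array([sub.get(c, 0) for c in categories], dtype=float)
        if obs.sum() > 0 and (all_props > 0).all():
            G, df, pval = category_gtest(obs, all_props)
            gtests[name] = {"G": G, "df": df, "p": pval, "n": int(obs.sum())}
    with open(out / "category_gtests.json", "w") as fh:
        json.dump(gtests, fh, indent=1, sort_keys=True)

    _stage(report, "candidate_enrichment")
    candidates = {g.lower() for g in read_candidate_list(config.path("candidates"))}
    if not candidates:
        raise ValueError("candidate gene list is empty")
    peak_index = pd.Index([p.peak_id for p in peaks])
    di_flags = pd.Series(
        [pid in di_ids for pid in peak_index], index=peak_index
    )
    cand_flags = pd.Series(
        [
            (p.nearest_gene or "").lower() in candidates
            for p in peaks
        ],
        index=peak_index,
    )
    table, fisher = candidate_enrichment(di_flags, cand_flags)
    C["candidate_linked_peaks"] = int(cand_flags.sum())
    enrichment_payload = {
        "table": {"a": table.a, "b": table.b, "c": table.c, "d": table.d},
        "odds_ratio_cmle": fisher.odds_ratio_cmle,
        "odds_ratio_sample": fisher.odds_ratio_sample,
        "ci95": list(fisher.ci95),
        "p_two_sided": fisher.p_two_sided,
    }
    with open(out / "candidate_enrichment.json", "w") as fh:
        json.dump(enrichment_payload, fh, indent=1, sort_keys=True)
    report["candidate_enrichment"] = enrichment_payload

    # ---- enhancers and pairing ------------------------------------------
    _stage(report, "enhancers")
    enhancer_ids = flag_putative_enhancers(peaks, genes, config.enhancer_distal_bp)
    C["putative_enhancers"] = len(enhancer_ids)
    di_idx = di.set_index("feature_id")
    di_enhancers = sorted(
        pid for pid in enhancer_ids if pid in di_ids
    )
    C["di_enhancers"] = len(di_enhancers)

    _stage(report, "pairing")
    peak_by_id = {p.peak_id: p for p in peaks}
    gene_by_id = {g.gene_id: g for g in genes}
    enh_frame = pd.DataFrame(
        {
            "peak_id": di_enhancers,
            "chrom": [peak_by_id[i].chrom for i in di_enhancers],
            "center": [peak_by_id[i].center for i in di_enhancers],
            "log2fc": [float(di_idx.loc[i, "log2fc"]) for i in di_enhancers],
        }
    )
    de_frame = pd.DataFrame(
        {
            "gene_id": de_sig["feature_id"],
            "chrom": [gene_by_id[g].interval.chrom for g in de_sig["feature_id"]],
            "tss": [gene_by_id[g].tss for g in de_sig["feature_id"]],
            "log2fc": de_sig["log2fc"].to_numpy(),
        }
    )
    if len(enh_frame) and len(de_frame):
        pairs, pair_summary = pair_enhancers(
            enh_frame, de_frame, config.pairing_window, config.residual_cut
        )
    else:
        pairs = pd.DataFrame(
            columns=["peak_id", "gene_id", "distance", "enhancer_log2fc",
                     "gene_log2fc", "direction", "std_residual", "retained"]
        )
        pair_summary = {"n_candidates": 0, "n_same_direction": 0}
    pairs.to_csv(out / "enhancer_gene_pairs.tsv", sep="\t", index=False)
    with open(out / "pair_regression.json", "w") as fh:
        json.dump(pair_summary, fh, indent=1, sort_keys=True)
    retained = pairs[pairs.get("retained", pd.Series(dtype=bool)) == True]  # noqa: E712
    C["pairs_candidates"] = pair_summary.get("n_candidates", 0)
    C["pairs_same_direction"] = pair_summary.get("n_same_direction", 0)
    C["pairs_retained"] = int(len(retained))
    C["pairs_retained_up"] = int((retained["direction"] == "up").sum()) if len(retained) else 0
    C["pairs_retained_down"] = int((retained["direction"] == "down").sum()) if len(retained) else 0

    # ---- motif enrichment ------------------------------------------------
    _stage(report, "motifs")
    motifs = read_jaspar(config.path("motifs"))
    de_gene_set = set(de_sig["feature_id"])
    windows = extract_fasta_windows(peaks, str(config.path("fasta")))

    def _enrich_set(name: str, target_ids, bg_ids):
        target = {i: windows[i] for i in sorted(target_ids) if i in windows}
        bg = {i: windows[i] for i in sorted(bg_ids) if i in windows}
        if not target or not bg:
            C[f"motifs_significant_{name}"] = 0
            return None
        results = enrich(target, bg, motifs, config.max_deficit, config.motif_alpha)
        results = tf_expression_support(results, de, config.fdr)
        frame = enrichment_frame(results)
        frame.to_csv(out / f"motif_enrichment_{name}.tsv", sep="\t", index=False)
        C[f"motifs_significant_{name}"] = int(frame["significant"].sum())
        return frame

    promoter_bg = build_promoter_background(peaks, di, de_gene_set, config.fdr)
    C["promoter_background"] = len(promoter_bg)
    up_ids = set(joins.loc[joins["direction_class"] == "parallel_up", "peak_id"])
    down_ids = set(joins.loc[joins["direction_class"] == "parallel_down", "peak_id"])
    _enrich_set("promoter_up", up_ids, promoter_bg)
    _enrich_set("promoter_down", down_ids, promoter_bg)

    if enhancer_ids:
        enh_bg = build_enhancer_background(
            enhancer_ids, di, n=config.bg_n, seed=config.seed
        )
        C["enhancer_background"] = len(enh_bg)
        ret_up = set(retained.loc[retained["direction"] == "up", "peak_id"]) if len(retained) else set()
        ret_down = set(retained.loc[retained["direction"] == "down", "peak_id"]) if len(retained) else set()
        _enrich_set("enhancer_up", ret_up, enh_bg)
        _enrich_set("enhancer_down", ret_down, enh_bg)

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    logger.info("pipeline complete: %d stages", len(report["stages"]))
    return report
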