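"""Transcript-stability calls, input-library contamination filter, and
putative-enhancer designation.

A csRNA-seq peak is *stable* when pooled mRNA reads map within the -100..+500
window around its center (in peak orientation): nascent transcripts that are
processed into stable mRNAs leave steady-state coverage there, while eRNAs
and other unstable species do not.  Unstable peaks lying more than 500 bp
from every promoter-TSS window are flagged as putative enhancers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome_annotation import GeneModel, Peak

__all__ = [
    "StabilityEvidence",
    "STABILITY_WINDOW",
    "classify_stability",
    "filter_input_contamination",
    "flag_putative_enhancers",
    "read_window_coverage",
]

#: strand-oriented window around the peak center used for the stability call
STABILITY_WINDOW = (-100, 500)


@dataclass
class StabilityEvidence:
    peak_id: str
    mrna_reads_in_window: float
    csrna_cpm: float = 0.0
    input_cpm: float = 0.0


def read_window_coverage(path) -> pd.Series:
    """Read pooled mRNA window coverage: TSV with columns peak_id, mrna_reads."""
    df = pd.read_csv(path, sep="\t")
    return df.set_index("peak_id")["mrna_reads"]


def classify_stability(evidence, min_mrna_reads: float = 5.0):
    """'stable' iff pooled mRNA window coverage >= ``min_mrna_reads``.

    Accepts a single StabilityEvidence (returns a string) or a pandas Series
    of per-peak coverage (returns a Series of calls).
    """
    if isinstance(evidence, StabilityEvidence):
        return "stable" if evidence.mrna_reads_in_window >= min_mrna_reads else "unstable"
    cov = pd.Series(evidence, dtype=float)
    return pd.Series(
        np.where(cov.to_numpy() >= min_mrna_reads, "stable", "unstable"),
        index=cov.index,
    )


def filter_input_contamination(
    csrna_cpm, input_cpm, min_fold: float = 2.0, floor: float = 0.1
) -> np.ndarray:
    """Keep a peak iff csRNA signal exceeds ``min_fold`` times the input-library
    signal (both per-million), with the input floored at ``floor``/M so that
    zero-input peaks are judged against a small constant rather than zero.

    A deliberately simple surrogate for the read-level exonic-contamination
    control of csRNA peak callers.
    """
    cs = np.asarray(csrna_cpm, dtype=float)
    inp = np.asarray(input_cpm, dtype=float)
    return cs >= min_fold * np.maximum(inp, floor)


def _promoter_edge_distance(center: int, chrom: str, genes_by_chrom) -> float:
    """bp from a position to the nearest promoter-window edge (0 if inside)."""
    windows = genes_by_chrom.get(chrom)
    if windows is None or len(windows) == 0:
        return np.inf
    lo, hi = windows[:, 0], windows[:, 1]
    d = np.where(center < lo, lo - center, np.where(center > hi, center - hi, 0))
    return float(d.min())


def flag_putative_enhancers(
    peaks: list[Peak],
    genes: list[GeneModel],
    min_distance: float = 500.0,
) -> set[str]:
    """Peak ids of putative enhancers: unstable peaks whose center lies
    strictly more than ``min_distance`` bp from every promoter-TSS window
    ([TSS-1000, TSS+100] in gene orientation, any gene)."""
    genes_by_chrom: dict[str, np.ndarray] = {}
    per_chrom: dict[str, list[tuple[int, int]]] = {}
    for g in genes:
        per_chrom.setdefault(g.interval.chrom, []).append(g.promoter_window())
    for chrom, wins in per_chrom.items():
        genes_by_chrom[chrom] = np.asarray(wins, dtype=np.int64)
    out = set()
    for p in peaks:
        if p.stability != "unstable":
            continue
        if _promoter_edge_distance(p.center, p.chrom, genes_by_chrom) > min_distance:
            out.add(p.peak_id)
    return out
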