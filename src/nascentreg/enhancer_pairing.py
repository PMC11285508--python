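"""Pairing of differentially active putative enhancers with nearby
differentially expressed genes.

eRNA abundance tends to track the expression of an enhancer's target genes,
so candidate targets are all DE genes whose TSS lies within 500 kbp of a
DI putative-enhancer peak center on the same scaffold.  Pairs are filtered
to the same fold-change direction, regressed (enhancer log2FC on gene
log2FC, one regression over all same-direction pairs), and retained when
they fall within one internally studentized residual of the fit.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "find_candidate_pairs",
    "direction_filter",
    "residual_filter",
    "pair_enhancers",
]

PAIRING_WINDOW = 500_000


def find_candidate_pairs(
    enhancers: pd.DataFrame,
    genes: pd.DataFrame,
    max_distance: int = PAIRING_WINDOW,
) -> pd.DataFrame:
    """All (enhancer peak, DE gene) pairs with |TSS - center| strictly less
    than ``max_distance`` on the same chromosome/scaffold; strand is ignored.

    ``enhancers``: columns peak_id, chrom, center, log2fc.
    ``genes``: columns gene_id, chrom, tss, log2fc.
    A peak may pair with several genes and vice versa.
    """
    rows = []
    for chrom, esub in enhancers.groupby("chrom", sort=True):
        gsub = genes[genes["chrom"] == chrom]
        if gsub.empty:
            continue
        tss = gsub["tss"].to_numpy(dtype=np.int64)
        for _, e in esub.iterrows():
            dist = np.abs(tss - int(e["center"]))
            hit = dist < max_distance
            for gi in np.flatnonzero(hit):
                g = gsub.iloc[gi]
                rows.append(
                    {
                        "peak_id": e["peak_id"],
                        "gene_id": g["gene_id"],
                        "distance": int(dist[gi]),
                        "enhancer_log2fc": float(e["log2fc"]),
                        "gene_log2fc": float(g["log2fc"]),
                    }
                )
    out = pd.DataFrame(
        rows,
        columns=["peak_id", "gene_id", "distance", "enhancer_log2fc", "gene_log2fc"],
    )
    return out.sort_values(["peak_id", "gene_id"], kind="stable").reset_index(drop=True)


def direction_filter(pairs: pd.DataFrame) -> pd.DataFrame:
    """Keep pairs whose enhancer and gene fold-changes are both strictly
    positive (direction 'up') or both strictly negative ('down'); a zero
    fold-change on either side drops the pair."""
    e = pairs["enhancer_log2fc"].to_numpy()
    g = pairs["gene_log2fc"].to_numpy()
    keep = ((e > 0) & (g > 0)) | ((e < 0) & (g < 0))
    out = pairs.loc[keep].copy()
    out["direction"] = np.where(out["enhancer_log2fc"] > 0, "up", "down")
    return out.reset_index(drop=True)


def residual_filter(
    pairs: pd.DataFrame,
    residual_cut: float = 1.0,
    per_direction: bool = False,
    studentized: bool = True,
) -> tuple[pd.DataFrame, dict]:
    """OLS of enhancer log2FC on gene log2FC over the same-direction pairs;
    pairs within ``residual_cut`` standardized residuals of the line
    (|r| <= cut, inclusive) are retained.

    Residuals are internally studentized (leverage-corrected,
    e_i / (s * sqrt(1 - h_ii))) by default; ``studentized=False`` falls back
    to raw residual / RMSE for sensitivity checks.  ``per_direction=True``
    fits one regression per direction instead of a single pooled fit.
    Returns (pairs with std_residual and retained columns, regression summary).
    """
    if len(pairs) < 3:
        raise ValueError("need at least 3 same-direction pairs for the regression")

    def _fit(sub: pd.DataFrame):
        x = sub["gene_log2fc"].to_numpy(dtype=float)
        y = sub["enhancer_log2fc"].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError("zero variance in gene log2fc (regression predictor)")
        model = sm.OLS(y, sm.add_constant(x)).fit()
        scale = max(np.var(y), 1.0)
        if model.ssr <= 1e-12 * scale:
            # (near-)perfect fit: all residuals are zero by convention
            resid = np.zeros(len(sub))
        elif studentized:
            resid = model.get_influence().resid_studentized_internal
        else:
            s = np.sqrt(np.maximum(model.ssr / max(model.df_resid, 1), 1e-300))
            resid = model.resid / s
        if not np.all(np.isfinite(resid)):
            resid = np.where(np.isfinite(resid), resid, 0.0)
        summary = {
            "slope": float(model.params[1]),
            "intercept": float(model.params[0]),
            "r": float(np.sign(model.params[1]) * np.sqrt(max(model.rsquared, 0.0))),
            "n": int(len(sub)),
        }
        return resid, summary

    out = pairs.copy()
    if per_direction:
        out["std_residual"] = np.nan
        summaries = {}
        for direction, sub in out.groupby("direction", sort=True):
            resid, summ = _fit(sub)
            out.loc[sub.index, "std_residual"] = resid
            summaries[direction] = summ
        summary = {"per_direction": summaries}
    else:
        resid, summary = _fit(out)
        out["std_residual"] = resid
    out["retained"] = np.abs(out["std_residual"]) <= residual_cut
    return out.reset_index(drop=True), summary


def pair_enhancers(
    enhancers: pd.DataFrame,
    genes: pd.DataFrame,
    max_distance: int = PAIRING_WINDOW,
    residual_cut: float = 1.0,
) -> tuple[pd.DataFrame, dict]:
    """Full pairing stage: distance candidates -> direction filter ->
    standardized-residual retention.  Returns the annotated pair table (all
    same-direction pairs, with retained flags) and the regression summary."""
    candidates = find_candidate_pairs(enhancers, genes, max_distance)
    same_dir = direction_filter(candidates)
    if len(same_dir) < 3:
        same_dir["std_residual"] = np.nan
        same_dir["retained"] = False
        return same_dir, {"n_candidates": int(len(candidates)), "n_same_direction": int(len(same_dir))}
    filtered, summary = residual_filter(same_dir, residual_cut=residual_cut)
    summary["n_candidates"] = int(len(candidates))
    summary["n_same_direction"] = int(len(same_dir))
    return filtered, summary
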