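"""Intersection of differential initiation with differential expression,
annotation-category G-tests, and candidate-gene Fisher enrichment.

Differentially initiated (DI) peaks are joined to their nearest gene's
differential-expression (DE) result and classed as parallel (same
fold-change sign, up or down), divergent (opposite signs) or not_de.  A
curated candidate-gene list is tested for overrepresentation among DI peaks
with a two-sided Fisher's exact test (R convention: two-sided p is the sum
of hypergeometric point probabilities no larger than the observed table's;
the odds ratio is the conditional MLE).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cmle_odds_ratio

__all__ = [
    "ContingencyTable2x2",
    "FisherResult",
    "join_di_de",
    "category_gtest",
    "fisher_exact",
    "candidate_enrichment",
    "read_candidate_list",
]

DIRECTION_CLASSES = ("parallel_up", "parallel_down", "divergent", "not_de")


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Rows: DI vs not-DI; columns: candidate-linked vs not."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("negative cell in 2x2 table")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=np.int64)

    @property
    def margins_positive(self) -> bool:
        t = self.as_array()
        return bool(t.sum(0).min() > 0 and t.sum(1).min() > 0)


@dataclass
class FisherResult:
    p_two_sided: float
    odds_ratio_cmle: float
    odds_ratio_sample: float
    ci95: tuple[float, float]


def fisher_exact(table: ContingencyTable2x2, full: bool = True) -> FisherResult:
    """Two-sided Fisher's exact test with conditional-MLE odds ratio and
    exact 95% CI; the sample odds ratio (ad/bc) is reported alongside.

    ``full=False`` skips the (comparatively expensive) CMLE odds ratio and
    CI, returning NaN for them; used where only the p-value matters.
    """
    t = table.as_array()
    p = float(stats.fisher_exact(t, alternative="two-sided")[1])
    a, b, c, d = table.a, table.b, table.c, table.d
    if b * c == 0:
        sample_or = np.inf if a * d > 0 else np.nan
    else:
        sample_or = a * d / (b * c)
    if not full:
        return FisherResult(min(p, 1.0), np.nan, float(sample_or), (np.nan, np.nan))
    res = _cmle_odds_ratio(t, kind="conditional")
    ci = res.confidence_interval(confidence_level=0.95)
    return FisherResult(
        p_two_sided=min(p, 1.0),
        odds_ratio_cmle=float(res.statistic),
        odds_ratio_sample=float(sample_or),
        ci95=(float(ci.low), float(ci.high)),
    )


def _direction_class(peak_lfc, peak_fdr, gene_lfc, gene_fdr, alpha=0.05) -> str:
    if gene_lfc is None or gene_fdr is None or not (gene_fdr < alpha):
        return "not_de"
    if peak_lfc > 0 and gene_lfc > 0:
        return "parallel_up"
    if peak_lfc < 0 and gene_lfc < 0:
        return "parallel_down"
    return "divergent"


def join_di_de(
    di: pd.DataFrame,
    de: pd.DataFrame,
    peaks,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """One row per significantly DI peak (FDR < threshold) that has a nearest
    gene, with its gene's DE statistics and a direction class.

    ``peaks`` is the annotated peak list; DI/DE are DiffResult frames indexed
    by feature_id.  Genes absent from the DE table (not tested) yield
    direction_class 'not_de' and gene_tested = False; peaks without a nearest
    gene are excluded and counted in ``result.attrs['n_no_gene']``.
    """
    di_idx = di.set_index("feature_id")
    de_idx = de.set_index("feature_id")
    rows = []
    n_no_gene = 0
    by_id = {p.peak_id: p for p in peaks}
    sig = di_idx[di_idx["fdr"] < fdr_threshold]
    for peak_id, drow in sig.iterrows():
        peak = by_id.get(peak_id)
        if peak is None:
            continue
        if peak.nearest_gene is None:
            n_no_gene += 1
            continue
        gene = peak.nearest_gene
        if gene in de_idx.index:
            grow = de_idx.loc[gene]
            gene_lfc, gene_fdr, tested = float(grow["log2fc"]), float(grow["fdr"]), True
        else:
            gene_lfc, gene_fdr, tested = np.nan, np.nan, False
        rows.append(
            {
                "peak_id": peak_id,
                "gene_id": gene,
                "category": peak.category,
                "peak_log2fc": float(drow["log2fc"]),
                "peak_fdr": float(drow["fdr"]),
                "gene_log2fc": gene_lfc,
                "gene_fdr": gene_fdr,
                "gene_tested": tested,
                "direction_class": _direction_class(
                    float(drow["log2fc"]), float(drow["fdr"]),
                    None if not tested else gene_lfc,
                    None if not tested else gene_fdr,
                    fdr_threshold,
                ),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "peak_id", "gene_id", "category", "peak_log2fc", "peak_fdr",
            "gene_log2fc", "gene_fdr", "gene_tested", "direction_class",
        ],
    )
    out.attrs["n_no_gene"] = n_no_gene
    out.attrs["n_gene_untested"] = int((~out["gene_tested"]).sum()) if len(out) else 0
    return out


def category_gtest(observed_counts, expected_props, williams: bool = False):
    """G-test goodness of fit of a subset's annotation-category counts
    against the category proportions of all peaks.

    G = 2 * sum O_i * ln(O_i / E_i) with E_i = N * p_i; empty observed cells
    contribute zero.  Returns (G, df, p) with p from the chi-square upper
    tail on k-1 df.  Williams' correction is available but off by default.
    """
    O = np.asarray(list(observed_counts.values) if isinstance(observed_counts, pd.Series)
                   else observed_counts, dtype=float)
    p = np.asarray(list(expected_props.values) if isinstance(expected_props, pd.Series)
                   else expected_props, dtype=float)
    if O.shape != p.shape:
        raise ValueError("observed and expected category vectors differ in length")
    if not np.isclose(p.sum(), 1.0, atol=1e-8):
        raise ValueError("expected proportions must sum to 1")
    N = O.sum()
    E = N * p
    if np.any((E == 0) & (O > 0)):
        raise ValueError("observed count in a category with zero expectation")
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(O > 0, O * np.log(O / np.maximum(E, 1e-300)), 0.0)
    G = 2.0 * terms.sum()
    k = O.size
    df = k - 1
    if williams and N > 0 and df > 0:
        G /= 1.0 + (k + 1.0) / (6.0 * N)
    pval = float(stats.chi2.sf(G, df)) if df > 0 else 1.0
    return float(G), df, pval


def read_candidate_list(path) -> set[str]:
    """One gene id per line; matched case-insensitively downstream."""
    with open(path) as fh:
        genes = {line.strip() for line in fh if line.strip()}
    return genes


def candidate_enrichment(
    di_flags: pd.Series,
    candidate_flags: pd.Series,
) -> tuple[ContingencyTable2x2, FisherResult]:
    """Fisher enrichment of candidate-gene-linked peaks among DI peaks.

    Both inputs are boolean Series indexed by peak_id over the same peak set.
    """
    di = di_flags.astype(bool)
    cand = candidate_flags.reindex(di.index).fillna(False).astype(bool)
    if not cand.any() or cand.all():
        raise ValueError("degenerate candidate column margin (all or none linked)")
    table = ContingencyTable2x2(
        a=int((di & cand).sum()),
        b=int((di & ~cand).sum()),
        c=int((~di & cand).sum()),
        d=int((~di & ~cand).sum()),
    )
    return table, fisher_exact(table)
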