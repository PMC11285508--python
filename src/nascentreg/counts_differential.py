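"""Normalization, filtering and per-feature differential testing.

Shared by the csRNA-seq (differential initiation) and mRNA-seq (differential
expression) arms: TMM library normalization, CPM/initiation filters, a
negative-binomial log-linear model with moderated tagwise dispersion fitted
by IRLS, likelihood-ratio (default) or quasi-likelihood F tests on the
ecotype coefficient, and Benjamini-Hochberg FDR control.

The fold-change sign convention throughout is sulfidic minus non-sulfidic:
positive log2fc means higher in the sulfidic ecotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, special, stats

__all__ = [
    "SampleSheet",
    "CountMatrix",
    "read_counts_tsv",
    "tmm_factors",
    "filter_min_cpm",
    "filter_min_initiation",
    "fit_differential",
    "bh_fdr",
    "pca_top_features",
]

ECOTYPES = ("sulfidic", "nonsulfidic")
ASSAYS = ("csrna", "input", "mrna")


@dataclass
class SampleSheet:
    """Sample metadata: assay, ecotype, drainage and species per sample."""

    table: pd.DataFrame

    REQUIRED = ("sample_id", "assay", "ecotype", "drainage", "species")

    def __post_init__(self):
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValueError(f"sample sheet missing columns: {missing}")
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample_id in sample sheet")
        bad = set(self.table["ecotype"]) - set(ECOTYPES)
        if bad:
            raise ValueError(f"unknown ecotype values: {sorted(bad)}")
        self.table = self.table.set_index("sample_id", drop=False)

    @classmethod
    def read_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def subset(self, sample_ids) -> "SampleSheet":
        return SampleSheet(self.table.loc[list(sample_ids)].reset_index(drop=True))

    def for_assay(self, assay: str) -> "SampleSheet":
        return SampleSheet(
            self.table[self.table["assay"] == assay].reset_index(drop=True)
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])


class CountMatrix:
    """Nonnegative integer features x samples count matrix.

    Library sizes are always recomputed from the counts, never trusted from
    input files.
    """

    def __init__(self, counts: np.ndarray, feature_ids, sample_ids):
        counts = np.asarray(counts)
        if counts.ndim != 2:
            raise ValueError("counts must be 2-D")
        if (counts < 0).any():
            raise ValueError("negative counts")
        self.counts = counts.astype(np.int64)
        self.feature_ids = np.asarray(feature_ids, dtype=object)
        self.sample_ids = np.asarray(sample_ids, dtype=object)
        if len(self.feature_ids) != counts.shape[0]:
            raise ValueError("feature_ids length mismatch")
        if len(self.sample_ids) != counts.shape[1]:
            raise ValueError("sample_ids length mismatch")

    @property
    def lib_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def shape(self):
        return self.counts.shape

    def cpm(self) -> np.ndarray:
        lib = self.lib_sizes.astype(float)
        if (lib == 0).any():
            raise ValueError("sample with all-zero counts")
        return self.counts / lib * 1e6

    def subset_features(self, keep) -> "CountMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            idx = np.flatnonzero(keep)
        else:
            pos = {f: i for i, f in enumerate(self.feature_ids)}
            idx = np.array([pos[f] for f in keep], dtype=int)
        return CountMatrix(self.counts[idx], self.feature_ids[idx], self.sample_ids)

    def subset_samples(self, sample_ids) -> "CountMatrix":
        pos = {s: i for i, s in enumerate(self.sample_ids)}
        idx = np.array([pos[s] for s in sample_ids], dtype=int)
        return CountMatrix(self.counts[:, idx], self.feature_ids, np.asarray(sample_ids, dtype=object))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def write_tsv(self, path, index_label: str = "feature_id") -> None:
        self.to_frame().to_csv(path, sep="\t", index_label=index_label)


def read_counts_tsv(path) -> CountMatrix:
    """Read a counts TSV: first column feature_id, header row of sample ids."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return CountMatrix(df.to_numpy(), df.index.to_numpy(), df.columns.to_numpy())


# ---------------------------------------------------------------------------
# TMM normalization
# ---------------------------------------------------------------------------

def _tmm_pair(obs, obs_lib, ref, ref_lib, logratio_trim=0.3, sum_trim=0.05):
    keep = (obs > 0) & (ref > 0)
    if not keep.any():
        return 1.0
    obs, ref = obs[keep].astype(float), ref[keep].astype(float)
    p_obs, p_ref = obs / obs_lib, ref / ref_lib
    m = np.log2(p_obs / p_ref)
    a = 0.5 * np.log2(p_obs * p_ref)
    # asymptotic (delta-method) variance of M
    v = (obs_lib - obs) / (obs_lib * obs) + (ref_lib - ref) / (ref_lib * ref)
    finite = np.isfinite(m) & np.isfinite(a)
    m, a, v = m[finite], a[finite], v[finite]
    if m.size == 0 or np.max(np.abs(m)) < 1e-10:
        return 1.0
    n = m.size
    lo_m, hi_m = np.floor(n * logratio_trim) + 1, n + 1 - (np.floor(n * logratio_trim) + 1)
    lo_a, hi_a = np.floor(n * sum_trim) + 1, n + 1 - (np.floor(n * sum_trim) + 1)
    rank_m = stats.rankdata(m, method="average")
    rank_a = stats.rankdata(a, method="average")
    keep2 = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep2.any():
        return 1.0
    f = np.sum(m[keep2] / v[keep2]) / np.sum(1.0 / v[keep2])
    if not np.isfinite(f):
        return 1.0
    return float(2.0 ** f)


def tmm_factors(counts: CountMatrix, ref: str | None = None) -> pd.Series:
    """Trimmed-mean-of-M-values scaling factors, one per sample.

    30% two-sided trimming on M-values and 5% on A-values before the
    precision-weighted mean; the reference sample, when not given, is the one
    whose upper-quartile CPM is closest to the mean upper-quartile.  Factors
    are renormalized so that their product is 1.
    """
    lib = counts.lib_sizes.astype(float)
    if (lib == 0).any():
        zero = counts.sample_ids[lib == 0]
        raise ValueError(f"sample(s) with all-zero counts: {list(zero)}")
    cpm = counts.cpm()
    if ref is None:
        uq = np.array([np.quantile(cpm[:, j][cpm[:, j] > 0], 0.75) if (cpm[:, j] > 0).any() else 0.0
                       for j in range(cpm.shape[1])])
        ref_idx = int(np.argmin(np.abs(uq - uq.mean())))
    else:
        ref_idx = int(np.where(counts.sample_ids == ref)[0][0])
    refcol = counts.counts[:, ref_idx]
    factors = np.array(
        [
            1.0 if j == ref_idx else _tmm_pair(counts.counts[:, j], lib[j], refcol, lib[ref_idx])
            for j in range(counts.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return pd.Series(factors, index=counts.sample_ids, name="tmm_factor")


# ---------------------------------------------------------------------------
# filters
# ---------------------------------------------------------------------------

def filter_min_cpm(counts: CountMatrix, min_cpm: float = 5.0, min_nonzero_samples: int = 5) -> np.ndarray:
    """Keep features with CPM >= min_cpm in the smallest library AND nonzero
    counts in at least ``min_nonzero_samples`` samples.  Returns a boolean mask."""
    lib = counts.lib_sizes
    smallest = int(np.argmin(lib))
    cpm_small = counts.counts[:, smallest] / lib[smallest] * 1e6
    nonzero = (counts.counts > 0).sum(axis=1)
    return (cpm_small >= min_cpm) & (nonzero >= min_nonzero_samples)


def filter_min_initiation(counts: CountMatrix, min_reads_per_1e7: float = 7.0) -> np.ndarray:
    """Keep peaks with at least ``min_reads_per_1e7`` reads per 10 million in
    at least one sample (i.e. normalized count >= 0.7 per million by default)."""
    cpm = counts.cpm()
    threshold = min_reads_per_1e7 / 10.0  # per million
    return (cpm >= threshold - 1e-12).any(axis=1)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values), capped at 1."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# NB GLM differential testing
# ---------------------------------------------------------------------------

def build_design(sheet: SampleSheet, covariates=("drainage", "species")) -> tuple[np.ndarray, list[str]]:
    """Design matrix: intercept, ecotype (sulfidic = 1), then treatment-coded
    covariates.  Rank-deficient (aliased) columns are dropped with a warning."""
    tab = sheet.table
    cols = [np.ones(len(tab))]
    names = ["intercept"]
    cols.append((tab["ecotype"].to_numpy() == "sulfidic").astype(float))
    names.append("ecotype_sulfidic")
    for cov in covariates:
        if cov not in tab.columns:
            continue
        levels = sorted(tab[cov].dropna().unique())
        for lev in levels[1:]:
            cols.append((tab[cov].to_numpy() == lev).astype(float))
            names.append(f"{cov}_{lev}")
    X = np.column_stack(cols)
    # drop aliased columns (keep earliest) via incremental rank checks
    keep = [0, 1]
    for j in range(2, X.shape[1]):
        trial = X[:, keep + [j]]
        if np.linalg.matrix_rank(trial) == len(keep) + 1:
            keep.append(j)
        else:
            warnings.warn(
                f"design column {names[j]!r} is aliased with earlier columns; dropped"
            )
    X = X[:, keep]
    names = [names[j] for j in keep]
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix not full rank after aliasing removal")
    return X, names


def _nb_deviance(y, mu, phi):
    """Negative-binomial residual deviance, elementwise-summed over samples."""
    y = np.asarray(y, dtype=float)
    mu = np.maximum(mu, 1e-10)
    phi = np.maximum(phi, 1e-10)[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        term1 = np.where(y > 0, y * np.log(np.maximum(y, 1e-300) / mu), 0.0)
        term2 = (y + 1.0 / phi) * np.log((1.0 + phi * mu) / (1.0 + phi * y))
    return 2.0 * np.sum(term1 + term2, axis=-1)


def _irls_nb(Y, X, offset, phi, max_iter=60, tol=1e-10):
    """Batched IRLS for NB log-linear models with per-feature dispersion.

    Y: (F, S); X: (S, P); offset: (S,) or (F, S); phi: (F,).
    Returns (beta (F, P), mu (F, S)).
    """
    F, S = Y.shape
    P = X.shape[1]
    offset = np.broadcast_to(np.asarray(offset, dtype=float), (F, S))
    phi = np.asarray(phi, dtype=float)[:, None]
    mu = np.maximum(Y, 0.5) * np.exp(offset - offset.mean(axis=1, keepdims=True)) ** 0
    eta = np.log(mu)
    beta = np.zeros((F, P))
    ridge = 1e-8 * np.eye(P)
    for _ in range(max_iter):
        mu = np.exp(np.clip(eta, -30.0, 30.0))
        w = mu / (1.0 + phi * mu)
        z = (eta - offset) + (Y - mu) / mu
        A = np.einsum("fs,sp,sq->fpq", w, X, X, optimize=True) + ridge
        b = np.einsum("fs,fs,sp->fp", w, z, X, optimize=True)
        new_beta = np.linalg.solve(A, b[..., None])[..., 0]
        delta = np.max(np.abs(new_beta - beta))
        beta = new_beta
        eta = beta @ X.T + offset
        if delta < tol:
            break
    mu = np.exp(np.clip(eta, -30.0, 30.0))
    return beta, mu


def _moment_dispersion(Y, mu, n_params):
    """Method-of-moments dispersion; the squared-residual term is scaled by
    n/(n-p) to compensate for fitted-mean shrinkage."""
    n = Y.shape[1]
    dfc = n / max(n - n_params, 1)
    num = dfc * np.sum((Y - mu) ** 2, axis=1) - np.sum(mu, axis=1)
    den = np.sum(mu**2, axis=1)
    phi = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(phi, 1e-8, 20.0)


def _nb_loglik(Y, mu, phi):
    r = 1.0 / max(phi, 1e-12)
    mu = np.maximum(mu, 1e-10)
    return np.sum(
        special.gammaln(Y + r) - special.gammaln(r) - special.gammaln(Y + 1)
        + r * np.log(r / (r + mu)) + Y * np.log(mu / (r + mu)),
        axis=1,
    )


def _common_dispersion_cr(Y, X, offset, lo=1e-4, hi=5.0):
    """Common NB dispersion by maximizing the Cox-Reid adjusted profile
    likelihood (total over features), a 1-D bounded search on log phi."""

    def neg_adj_ll(log_phi: float) -> float:
        phi = float(np.exp(log_phi))
        _, mu = _irls_nb(Y, X, offset, np.full(Y.shape[0], phi))
        w = mu / (1.0 + phi * mu)
        A = np.einsum("fs,sp,sq->fpq", w, X, X, optimize=True)
        _, logdet = np.linalg.slogdet(A)
        return -float(np.sum(_nb_loglik(Y, mu, phi) - 0.5 * logdet))

    res = optimize.minimize_scalar(
        neg_adj_ll, bounds=(np.log(lo), np.log(hi)), method="bounded",
        options={"xatol": 1e-3},
    )
    return float(np.exp(res.x))


def fit_differential(
    counts: CountMatrix,
    sheet: SampleSheet,
    covariates=("drainage", "species"),
    coef: str = "ecotype_sulfidic",
    shrink_weight: float = 0.5,
    test: str = "lrt",
    norm_factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature NB differential test of sulfidic vs non-sulfidic ecotype.

    Fits a log-linear negative-binomial model with offsets
    ``log(lib_size * tmm_factor)`` by IRLS, moderates the method-of-moments
    tagwise dispersion toward the common dispersion with weight
    ``shrink_weight``, and tests the ecotype coefficient by likelihood-ratio
    chi-square (``test='lrt'``, default) or a quasi-likelihood-style F test
    (``test='qlf'``).  Returns a DataFrame with columns feature_id, log2fc,
    pvalue, fdr, ave_log_cpm, sorted by feature_id order of the input.
    """
    if test not in ("lrt", "qlf"):
        raise ValueError("test must be 'lrt' or 'qlf'")
    sheet = sheet.subset(counts.sample_ids)
    X, names = build_design(sheet, covariates)
    if coef not in names:
        raise ValueError(f"coefficient {coef!r} not in design: {names}")
    ci = names.index(coef)
    Y = counts.counts.astype(float)
    lib = counts.lib_sizes.astype(float)
    if norm_factors is None:
        norm_factors = tmm_factors(counts)
    tmm = norm_factors.loc[list(counts.sample_ids)].to_numpy(dtype=float)
    offset = np.log(lib * tmm)

    # common dispersion by Cox-Reid adjusted profile likelihood; tagwise
    # method-of-moments estimates are shrunk toward it
    phi_common = _common_dispersion_cr(Y, X, offset)
    _, mu0 = _irls_nb(Y, X, offset, np.full(Y.shape[0], phi_common))
    phi_tag = _moment_dispersion(Y, mu0, X.shape[1])
    phi = np.clip(shrink_weight * phi_common + (1.0 - shrink_weight) * phi_tag, 1e-8, 20.0)

    X_red = np.delete(X, ci, axis=1)
    beta_full, mu_full = _irls_nb(Y, X, offset, phi)
    _, mu_red = _irls_nb(Y, X_red, offset, phi)
    dev_full = _nb_deviance(Y, mu_full, phi)
    dev_red = _nb_deviance(Y, mu_red, phi)
    lr = np.maximum(dev_red - dev_full, 0.0)
    if test == "lrt":
        pvals = stats.chi2.sf(lr, df=1)
    else:
        df_resid = max(Y.shape[1] - X.shape[1], 1)
        s2 = np.maximum(dev_full / df_resid, 1e-12)
        pvals = stats.f.sf(lr / s2, 1, df_resid)
    # exact-null identity: identical fits give p = 1
    pvals = np.where(lr <= 1e-12, 1.0, pvals)
    log2fc = beta_full[:, ci] / np.log(2.0)
    ave_log_cpm = np.log2(counts.cpm() + 1.0).mean(axis=1)
    return pd.DataFrame(
        {
            "feature_id": counts.feature_ids,
            "log2fc": log2fc,
            "pvalue": np.clip(pvals, 0.0, 1.0),
            "fdr": bh_fdr(np.clip(pvals, 0.0, 1.0)),
            "ave_log_cpm": ave_log_cpm,
        }
    )


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------

def pca_top_features(counts: CountMatrix, n_top: int = 500) -> pd.DataFrame:
    """Sample coordinates on PCs 1-2 from the ``n_top`` features with highest
    mean log2(CPM + 1) signal.  Sign is fixed by making each PC's
    largest-magnitude loading positive, so coordinates are deterministic."""
    if counts.shape[1] < 3:
        raise ValueError("need at least 3 samples for a PCA")
    log_cpm = np.log2(counts.cpm() + 1.0)
    if n_top > counts.shape[0]:
        warnings.warn(
            f"n_top={n_top} exceeds feature count {counts.shape[0]}; using all features"
        )
        n_top = counts.shape[0]
    rank = np.argsort(-log_cpm.mean(axis=1), kind="stable")[:n_top]
    M = log_cpm[rank]
    M = M - M.mean(axis=1, keepdims=True)
    # samples as rows for the decomposition
    U, s, Vt = np.linalg.svd(M.T, full_matrices=False)
    coords = U[:, :2] * s[:2]
    var = s**2 / max(np.sum(s**2), 1e-300)
    for k in range(min(2, Vt.shape[0])):
        j = int(np.argmax(np.abs(Vt[k])))
        if Vt[k, j] < 0:
            coords[:, k] *= -1.0
    out = pd.DataFrame(coords, index=counts.sample_ids, columns=["PC1", "PC2"])
    out.attrs["explained_variance_ratio"] = var[:2].tolist()
    return out
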