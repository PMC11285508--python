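"""JASPAR motif parsing, deficit-thresholded PWM scanning and target-vs-
background TFBS enrichment.

Position frequency matrices are converted to log-odds weight matrices
against a background (uniform by default) with a pseudocount; a window's
*deficit* is its score shortfall from the best attainable score, normalized
to the best-worst range: deficit = (s_max - score) / (s_max - s_min).  Hits
are emitted when deficit <= 0.15 (by default) on either strand.  Enrichment
is sequence-level: per motif, the number of target vs background sequences
carrying at least one hit is tested with a two-sided Fisher's exact test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intersection_analysis import ContingencyTable2x2, fisher_exact

__all__ = [
    "MotifMatrix",
    "MotifHit",
    "EnrichmentResult",
    "read_jaspar",
    "write_jaspar",
    "pfm_to_pwm",
    "scan",
    "scan_sequences",
    "enrich",
    "build_promoter_background",
    "build_enhancer_background",
    "tf_expression_support",
]

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


@dataclass
class MotifMatrix:
    """A position frequency matrix with derived log-odds scores.

    ``pfm`` is 4 x L (rows A, C, G, T, nonnegative counts); ``pwm`` is the
    log2-odds matrix vs background, never -inf thanks to the pseudocount.
    """

    motif_id: str
    name: str
    pfm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    pseudocount: float = 0.8

    def __post_init__(self):
        self.pfm = np.asarray(self.pfm, dtype=float)
        if self.pfm.shape[0] != 4 or self.pfm.shape[1] < 1:
            raise ValueError(f"motif {self.motif_id}: PFM must be 4 x L")
        if (self.pfm < 0).any():
            raise ValueError(f"motif {self.motif_id}: negative PFM counts")
        self.pwm, self.s_max, self.s_min = pfm_to_pwm(
            self.pfm, self.background, self.pseudocount
        )

    @property
    def length(self) -> int:
        return self.pfm.shape[1]

    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.pwm, axis=0))


@dataclass(frozen=True)
class MotifHit:
    motif_id: str
    sequence_id: str
    offset: int
    strand: str
    score: float
    deficit: float


@dataclass
class EnrichmentResult:
    motif_id: str
    name: str
    n_target_with: int
    n_target: int
    n_bg_with: int
    n_bg: int
    prop_target: float
    prop_bg: float
    log2_enrichment: float
    pvalue: float
    significant: bool
    support: str = "none"


# ---------------------------------------------------------------------------
# JASPAR I/O
# ---------------------------------------------------------------------------

def read_jaspar(path) -> list[MotifMatrix]:
    """Parse JASPAR text format: ``>ID NAME`` then four bracketed,
    base-labelled count rows.  Rows are mapped by their base label, not by
    order, so files listing rows as e.g. C,A,T,G parse correctly."""
    motifs = []
    header = None
    rows: dict[str, list[float]] = {}

    def _flush():
        nonlocal header, rows
        if header is None:
            return
        motif_id, name = header
        missing = [b for b in BASES if b not in rows]
        if missing:
            raise ValueError(f"motif {motif_id}: missing rows for {missing}")
        lengths = {len(rows[b]) for b in BASES}
        if len(lengths) != 1:
            raise ValueError(f"motif {motif_id}: row length mismatch {sorted(lengths)}")
        motifs.append(MotifMatrix(motif_id, name, np.array([rows[b] for b in BASES])))
        header, rows = None, {}

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1] if len(parts) > 1 else parts[0])
            else:
                base = line[0].upper()
                if base not in _BASE_INDEX:
                    raise ValueError(f"unrecognized PFM row label {line[0]!r}")
                body = line[1:].strip().lstrip("[").rstrip("]").strip(" []")
                rows[base] = [float(x) for x in body.split()]
    _flush()
    if not motifs:
        warnings.warn(f"{path}: no motifs parsed")
    return motifs


def write_jaspar(motifs: list[MotifMatrix], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.name}\n")
            for i, b in enumerate(BASES):
                vals = " ".join(f"{v:6.0f}" for v in m.pfm[i])
                fh.write(f"{b} [{vals} ]\n")


def pfm_to_pwm(pfm, background=None, pseudocount: float = 0.8):
    """Counts -> log2-odds weights with a background-split pseudocount:
    p[b,j] = (count[b,j] + pc * bg_b) / (colsum_j + pc);
    pwm[b,j] = log2(p[b,j] / bg_b).  Returns (pwm, s_max, s_min)."""
    pfm = np.asarray(pfm, dtype=float)
    bg = np.full(4, 0.25) if background is None else np.asarray(background, dtype=float)
    colsum = pfm.sum(axis=0)
    if (colsum <= 0).any():
        raise ValueError("PFM column with zero total count")
    p = (pfm + pseudocount * bg[:, None]) / (colsum + pseudocount)
    pwm = np.log2(p / bg[:, None])
    s_max = float(pwm.max(axis=0).sum())
    s_min = float(pwm.min(axis=0).sum())
    return pwm, s_max, s_min


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def _encode(seq: str) -> np.ndarray:
    """A,C,G,T -> 0..3; anything else (incl. N) -> 4."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.size, 4, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def _window_scores(encoded: np.ndarray, pwm: np.ndarray) -> np.ndarray:
    """Score every offset of a forward scan; N positions score the per-column
    minimum (worst case)."""
    L = pwm.shape[1]
    n = encoded.size
    if n < L:
        return np.empty(0)
    # 5th row: worst score per column, used for N
    table = np.vstack([pwm, pwm.min(axis=0)])
    # score[k] = sum_j table[encoded[k+j], j]
    idx = np.arange(n - L + 1)[:, None] + np.arange(L)[None, :]
    return table[encoded[idx], np.arange(L)[None, :]].sum(axis=1)


_RC = np.array([3, 2, 1, 0, 4], dtype=np.int8)


def scan(seq: str, motif: MotifMatrix, max_deficit: float = 0.15,
         sequence_id: str = "") -> list[MotifHit]:
    """Scan both strands of ``seq``; emit hits with deficit <= max_deficit.

    Offsets are 0-based window starts on the forward sequence for both
    strands; minus-strand scores are computed on the reverse complement.
    """
    L = motif.length
    enc = _encode(seq)
    n = enc.size
    if n < L:
        return []
    rng = motif.s_max - motif.s_min
    hits = []
    fwd = _window_scores(enc, motif.pwm)
    rev = _window_scores(_RC[enc][::-1], motif.pwm)
    for strand, scores in (("+", fwd), ("-", rev)):
        if rng <= 0:
            deficits = np.zeros_like(scores)
        else:
            deficits = (motif.s_max - scores) / rng
        ok = np.flatnonzero(deficits <= max_deficit + 1e-12)
        for k in ok:
            offset = int(k) if strand == "+" else n - L - int(k)
            hits.append(
                MotifHit(motif.motif_id, sequence_id, offset, strand,
                         float(scores[k]), float(max(deficits[k], 0.0)))
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def scan_sequences(seqs: dict[str, str], motifs: list[MotifMatrix],
                   max_deficit: float = 0.15) -> pd.DataFrame:
    """Hit table over a keyed sequence set (one row per hit)."""
    rows = []
    for seq_id in seqs:
        for m in motifs:
            for h in scan(seqs[seq_id], m, max_deficit, sequence_id=seq_id):
                rows.append(
                    (h.motif_id, h.sequence_id, h.offset, h.strand, h.score, h.deficit)
                )
    return pd.DataFrame(
        rows, columns=["motif_id", "sequence_id", "offset", "strand", "score", "deficit"]
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrich(
    target_seqs: dict[str, str],
    background_seqs: dict[str, str],
    motifs: list[MotifMatrix],
    max_deficit: float = 0.15,
    alpha: float = 0.01,
) -> list[EnrichmentResult]:
    """Per-motif sequence-level enrichment of targets over background.

    Counts sequences with >= 1 hit in each set, tests the 2x2 with a
    two-sided Fisher's exact test, and reports a Haldane-smoothed log2
    enrichment ratio (epsilon = 0.5/n of the respective set).  Results are
    sorted by p-value.
    """
    if not target_seqs or not background_seqs:
        raise ValueError("target and background sequence sets must be nonempty")
    n_t, n_b = len(target_seqs), len(background_seqs)
    results = []
    for m in motifs:
        with_t = sum(
            1 for s in target_seqs.values() if scan(s, m, max_deficit)
        )
        with_b = sum(
            1 for s in background_seqs.values() if scan(s, m, max_deficit)
        )
        table = ContingencyTable2x2(with_t, n_t - with_t, with_b, n_b - with_b)
        fisher = fisher_exact(table, full=False)
        prop_t, prop_b = with_t / n_t, with_b / n_b
        log2_ratio = float(
            np.log2((prop_t + 0.5 / n_t) / (prop_b + 0.5 / n_b))
        )
        results.append(
            EnrichmentResult(
                motif_id=m.motif_id,
                name=m.name,
                n_target_with=with_t,
                n_target=n_t,
                n_bg_with=with_b,
                n_bg=n_b,
                prop_target=prop_t,
                prop_bg=prop_b,
                log2_enrichment=log2_ratio,
                pvalue=fisher.p_two_sided,
                significant=fisher.p_two_sided < alpha,
            )
        )
    results.sort(key=lambda r: (r.pvalue, r.motif_id))
    return results


def enrichment_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


# ---------------------------------------------------------------------------
# background construction
# ---------------------------------------------------------------------------

def build_promoter_background(
    peaks,
    di_results: pd.DataFrame,
    de_genes: set[str],
    fdr_threshold: float = 0.05,
    max_abs_log2fc: float = 0.5,
) -> list[str]:
    """Promoter-TSS peaks that are not differentially initiated
    (FDR > threshold and |log2FC| < 0.5) and whose nearest gene is not DE.
    The whole set is used, not a sample."""
    di_idx = di_results.set_index("feature_id")
    out = []
    for p in peaks:
        if p.category != "promoter-TSS" or p.peak_id not in di_idx.index:
            continue
        row = di_idx.loc[p.peak_id]
        if row["fdr"] <= fdr_threshold or abs(row["log2fc"]) >= max_abs_log2fc:
            continue
        if p.nearest_gene is not None and p.nearest_gene in de_genes:
            continue
        out.append(p.peak_id)
    if not out:
        raise ValueError("empty promoter background set")
    return out


def build_enhancer_background(
    enhancer_peak_ids,
    di_results: pd.DataFrame,
    n: int = 1000,
    seed: int = 0,
    fdr_threshold: float = 0.05,
) -> list[str]:
    """Uniform seeded sample (without replacement) of up to ``n`` putative
    enhancer peaks that are not differentially initiated (FDR > threshold)."""
    di_idx = di_results.set_index("feature_id")
    pool = sorted(
        pid
        for pid in enhancer_peak_ids
        if pid in di_idx.index and di_idx.loc[pid, "fdr"] > fdr_threshold
    )
    if not pool:
        raise ValueError("empty non-DI enhancer pool for background sampling")
    if len(pool) <= n:
        if len(pool) < n:
            warnings.warn(
                f"enhancer background pool ({len(pool)}) smaller than requested n={n}"
            )
        return pool
    rng = np.random.default_rng(seed)
    picked = rng.choice(len(pool), size=n, replace=False)
    return [pool[i] for i in sorted(picked)]


# ---------------------------------------------------------------------------
# TF expression support
# ---------------------------------------------------------------------------

def tf_expression_support(
    results: list[EnrichmentResult],
    de: pd.DataFrame,
    fdr_threshold: float = 0.05,
) -> list[EnrichmentResult]:
    """Annotate each motif with whether the gene(s) encoding the TF are DE.

    Dimer names are split on '::'; each component is matched
    case-insensitively against DE gene ids/symbols.  Support is 'up' if any
    component is significantly upregulated, 'down' if downregulated,
    'up/down' on conflict, else 'none'.
    """
    sig = de[de["fdr"] < fdr_threshold]
    lookup = {
        str(g).lower(): float(lfc)
        for g, lfc in zip(sig["feature_id"], sig["log2fc"])
    }
    for r in results:
        calls = set()
        for component in r.name.split("::"):
            lfc = lookup.get(component.strip().lower())
            if lfc is not None:
                calls.add("up" if lfc > 0 else "down")
        r.support = "/".join(sorted(calls)) if calls else "none"
    return results
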