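"""Seeded synthetic dataset generator with known ground truth.

Emulates the study design of a two-ecotype (sulfidic vs non-sulfidic),
three-drainage comparison of transcription initiation (csRNA-seq, 2 fish
per site = 12 samples, with matched input libraries) and steady-state
expression (mRNA-seq, 17 sulfidic + 18 non-sulfidic samples):

* a toy genome partitioned into fixed-size gene slots, each holding one
  gene (promoter peak at its TSS) and optionally one distal "enhancer"
  peak, one intronic peak, and one input-heavy contaminant peak;
* negative-binomial counts with log-linear ecotype and drainage effects
  and lognormal library-depth factors;
* differentially initiated (DI) peaks drawn per peak, with a configurable
  odds multiplier for peaks linked to candidate genes;
* differentially expressed (DE) genes derived from DI promoter peaks
  (matching fold-change sign with probability ``parallel_sign_prob``) and
  from DI enhancer peaks, whose (peak, gene) log2 fold-changes are drawn
  bivariate-normal with correlation ``enhancer_gene_corr``;
* motif consensus sequences substituted into the scan windows of regulated
  peaks at ``motif_plant_rate_target`` and elsewhere at
  ``motif_plant_rate_background``;
* stable peaks given fixed mRNA window coverage, unstable (enhancer) peaks
  zero coverage.

All randomness derives from one seed through fixed substream indices, so
the same seed reproduces every file byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .counts_differential import CountMatrix
from .genome_annotation import (
    GeneModel,
    GenomicInterval,
    Peak,
    merge_peaks,
    reverse_complement,
    scan_window_bounds,
    write_bed,
)
from .motif_enrichment import MotifMatrix, write_jaspar

__all__ = ["SimConfig", "GroundTruth", "simulate_dataset", "simulate_null_counts"]

DRAINAGES = ("Pichucalco", "Puyacatengo", "Tacotalpa")

# substream indices for the per-stage RNGs
_STREAMS = {
    "geometry": 1, "effects": 2, "csrna": 3, "input": 4,
    "mrna": 5, "motifs": 6, "genome": 7, "jitter": 8,
}

# gene-slot layout (bp offsets within a slot of SLOT_LEN)
SLOT_LEN = 7000
_GENE_OFFSET = 2000
_GENE_LEN = 3000
_ENHANCER_CENTER = 300
_INTRONIC_CENTER = 3800
_CONTAMINANT_CENTER = 700


@dataclass
class SimConfig:
    seed: int = 0
    n_chrom: int = 10
    chrom_len: int = 1_750_000
    n_genes: int = 2500
    n_promoter_peaks: int = 2500
    n_enhancer_peaks: int = 1500
    n_intronic_peaks: int = 1000
    n_contaminant_peaks: int = 100
    n_csrna_samples_per_site: int = 2
    drainages: tuple = DRAINAGES
    n_mrna_sulfidic: int = 17
    n_mrna_nonsulfidic: int = 18
    frac_di: float = 0.15
    lfc_magnitude: float = 2.0
    dispersion: float = 0.1
    mean_count: float = 100.0
    frac_candidate_genes: float = 0.1
    candidate_di_odds: float = 3.0
    enhancer_gene_corr: float = 0.9
    enhancer_lfc_sd: float = 0.5
    motif_plant_rate_target: float = 0.6
    motif_plant_rate_background: float = 0.05
    de_given_promoter_di: float = 0.7
    frac_independent_de: float = 0.05
    parallel_sign_prob: float = 0.9
    drainage_effect_sd: float = 0.25
    libsize_sd: float = 0.2
    stable_coverage: float = 20.0

    def __post_init__(self):
        for name in ("frac_di", "frac_candidate_genes", "enhancer_gene_corr",
                     "motif_plant_rate_target", "motif_plant_rate_background",
                     "de_given_promoter_di", "frac_independent_de",
                     "parallel_sign_prob"):
            v = getattr(self, name)
            if not (0.0 <= abs(v) <= 1.0):
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be > 0")
        if self.lfc_magnitude < 0:
            raise ValueError("lfc_magnitude must be >= 0")
        genes_per_chrom = -(-self.n_genes // self.n_chrom)
        if genes_per_chrom * SLOT_LEN > self.chrom_len:
            raise ValueError(
                f"infeasible geometry: {genes_per_chrom} gene slots of {SLOT_LEN} bp "
                f"do not fit in chrom_len={self.chrom_len}"
            )
        if self.n_promoter_peaks > self.n_genes:
            raise ValueError("n_promoter_peaks exceeds n_genes")
        for name in ("n_enhancer_peaks", "n_intronic_peaks", "n_contaminant_peaks"):
            if getattr(self, name) > self.n_genes:
                raise ValueError(f"{name} exceeds the number of gene slots")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([_STREAMS[stream], self.seed])


@dataclass
class GroundTruth:
    """True generating state, keyed by the merged peak ids the pipeline sees."""

    di_peaks: dict[str, float] = field(default_factory=dict)
    de_genes: dict[str, float] = field(default_factory=dict)
    enhancer_peaks: list[str] = field(default_factory=list)
    enhancer_target_pairs: list[tuple[str, str]] = field(default_factory=list)
    planted_motifs: dict[str, list[dict]] = field(default_factory=dict)
    candidate_genes: list[str] = field(default_factory=list)
    contaminant_peaks: list[str] = field(default_factory=list)
    peak_roles: dict[str, str] = field(default_factory=dict)
    peak_gene: dict[str, str] = field(default_factory=dict)

    def to_json(self, path) -> None:
        payload = asdict(self)
        payload["enhancer_target_pairs"] = [list(t) for t in self.enhancer_target_pairs]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
            fh.write("\n")

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        payload["enhancer_target_pairs"] = [tuple(t) for t in payload["enhancer_target_pairs"]]
        return cls(**payload)


def nb_draws(rng: np.random.Generator, mean, dispersion: float) -> np.ndarray:
    """Negative-binomial draws via the gamma-Poisson mixture;
    var = mean + dispersion * mean^2.  dispersion below 1e-8 is Poisson."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 1e-8:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, dispersion * mean)
    return rng.poisson(lam)


def simulate_null_counts(
    n_features: int, n_samples: int, mean: float, dispersion: float, seed: int
) -> CountMatrix:
    """NB counts with no group effect (type-I-error harness)."""
    if mean <= 0 or dispersion < 0:
        raise ValueError("mean must be positive and dispersion nonnegative")
    rng = np.random.default_rng(seed)
    counts = nb_draws(rng, np.full((n_features, n_samples), mean), max(dispersion, 0.0))
    return CountMatrix(
        counts,
        [f"f{i:05d}" for i in range(n_features)],
        [f"s{j:03d}" for j in range(n_samples)],
    )


# ---------------------------------------------------------------------------
# built-in toy motif database
# ---------------------------------------------------------------------------

_MOTIF_SPECS = [
    ("MA9001.1", "SYNTF1", "TGACGTCATC"),
    ("MA9002.1", "SYNTF2", "CCGGAAGTGA"),
    ("MA9003.1", "FOXQ9", "ATGCAAATGG"),
    ("MA9004.1", "MEF2X", "CTATTTATAG"),
    ("MA9005.1", "NR4X1::NR4X2", "TTTCACGCAA"),
    ("MA9006.1", "TBX99", "CAGCTGTTGA"),
]
#: indices of the motifs planted in regulated windows
TARGET_MOTIF_INDICES = (0, 1)


def default_motifs() -> list[MotifMatrix]:
    """Six sharply-peaked 10-bp motifs (85 counts on the consensus base, 5 on
    each alternative); the first two are the 'regulatory' motifs the
    generator plants preferentially."""
    motifs = []
    for motif_id, name, consensus in _MOTIF_SPECS:
        pfm = np.full((4, len(consensus)), 5.0)
        for j, base in enumerate(consensus):
            pfm["ACGT".index(base), j] = 85.0
        motifs.append(MotifMatrix(motif_id, name, pfm))
    return motifs


# ---------------------------------------------------------------------------
# dataset generation
# ---------------------------------------------------------------------------

def _sample_sheet_rows(config: SimConfig):
    rows = []
    for eco in ("sulfidic", "nonsulfidic"):
        for drain in config.drainages:
            species = "sulphuraria" if (eco == "sulfidic" and drain == "Pichucalco") else "mexicana"
            for rep in range(1, config.n_csrna_samples_per_site + 1):
                rows.append((f"cs_{eco}_{drain}_{rep}", "csrna", eco, drain, species))
                rows.append((f"in_{eco}_{drain}_{rep}", "input", eco, drain, species))
    n_per_site = {
        "sulfidic": _split(config.n_mrna_sulfidic, len(config.drainages)),
        "nonsulfidic": _split(config.n_mrna_nonsulfidic, len(config.drainages)),
    }
    for eco in ("sulfidic", "nonsulfidic"):
        for drain, n in zip(config.drainages, n_per_site[eco]):
            species = "sulphuraria" if (eco == "sulfidic" and drain == "Pichucalco") else "mexicana"
            for rep in range(1, n + 1):
                rows.append((f"mr_{eco}_{drain}_{rep}", "mrna", eco, drain, species))
    return rows


def _split(total: int, k: int) -> list[int]:
    base = total // k
    out = [base] * k
    for i in range(total - base * k):
        out[i] += 1
    return out


def _random_genome(config: SimConfig) -> dict[str, bytearray]:
    rng = config.rng("genome")
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = {}
    for c in range(config.n_chrom):
        idx = rng.integers(0, 4, size=config.chrom_len)
        genome[f"chr{c + 1}"] = bytearray(bases[idx].tobytes())
    return genome


def _write_fasta(genome: dict[str, bytearray], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom in genome:
            fh.write(f">{chrom}\n")
            seq = genome[chrom].decode()
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _build_genes(config: SimConfig, rng) -> list[GeneModel]:
    genes = []
    genes_per_chrom = -(-config.n_genes // config.n_chrom)
    for i in range(config.n_genes):
        chrom = f"chr{i // genes_per_chrom + 1}"
        slot = (i % genes_per_chrom) * SLOT_LEN
        gs = slot + _GENE_OFFSET
        strand = "+" if rng.random() < 0.5 else "-"
        interval = GenomicInterval(chrom, gs, gs + _GENE_LEN, strand)
        exons = [
            GenomicInterval(chrom, gs, gs + 500, strand),
            GenomicInterval(chrom, gs + 1000, gs + 1500, strand),
            GenomicInterval(chrom, gs + 2500, gs + _GENE_LEN, strand),
        ]
        genes.append(GeneModel(f"g{i + 1:04d}", interval, exons))
    return genes


def _write_gtf(genes: list[GeneModel], path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            iv = g.interval
            attrs = f'gene_id "{g.gene_id}";'
            fh.write(
                f"{iv.chrom}\tsim\tgene\t{iv.start + 1}\t{iv.end}\t.\t{iv.strand}\t.\t{attrs}\n"
            )
            for e in g.exons:
                fh.write(
                    f"{e.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t{attrs}\n"
                )


def _make_truth_peaks(config: SimConfig, genes: list[GeneModel], rng):
    """Place peaks in gene slots.  Returns (peaks, roles, host_gene) lists."""
    n = config.n_genes
    peaks, roles, hosts = [], [], []

    def _slot_origin(i: int) -> tuple[str, int]:
        g = genes[i]
        return g.interval.chrom, g.interval.start - _GENE_OFFSET

    for i in range(config.n_promoter_peaks):
        g = genes[i]
        center = g.tss + 25 if g.strand == "+" else g.tss - 25
        peaks.append(
            Peak(f"t_prom_{i}", GenomicInterval(g.interval.chrom, center - 75, center + 75, g.strand), center=center)
        )
        roles.append("promoter")
        hosts.append(g.gene_id)

    for role, count, center_off, width in (
        ("enhancer", config.n_enhancer_peaks, _ENHANCER_CENTER, 100),
        ("intronic", config.n_intronic_peaks, _INTRONIC_CENTER, 100),
        ("contaminant", config.n_contaminant_peaks, _CONTAMINANT_CENTER, 100),
    ):
        slots = np.sort(rng.choice(n, size=count, replace=False))
        for i in slots:
            chrom, origin = _slot_origin(int(i))
            center = origin + center_off
            strand = "+" if rng.random() < 0.5 else "-"
            peaks.append(
                Peak(
                    f"t_{role[:4]}_{i}",
                    GenomicInterval(chrom, center - width // 2, center + width // 2, strand),
                    center=center,
                )
            )
            roles.append(role)
            hosts.append(genes[int(i)].gene_id)
    return peaks, roles, hosts


def simulate_dataset(config: SimConfig, out_dir) -> GroundTruth:
    """Write the full synthetic dataset to ``out_dir`` and return the ground
    truth.  Files: genome.fa, genes.gtf, peaks_<sample>.bed (csRNA samples),
    csrna_counts.tsv, input_counts.tsv, mrna_counts.tsv,
    mrna_window_coverage.tsv, motifs.jaspar, samples.tsv, candidates.txt,
    ground_truth.json."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    geom_rng = config.rng("geometry")
    eff_rng = config.rng("effects")
    jitter_rng = config.rng("jitter")
    motif_rng = config.rng("motifs")

    genes = _build_genes(config, geom_rng)
    truth_peaks, roles, hosts = _make_truth_peaks(config, genes, geom_rng)

    # ---- per-sample jittered peak lists and the merged non-redundant list
    sheet_rows = _sample_sheet_rows(config)
    csrna_samples = [r[0] for r in sheet_rows if r[1] == "csrna"]
    input_samples = [r[0] for r in sheet_rows if r[1] == "input"]
    mrna_samples = [r[0] for r in sheet_rows if r[1] == "mrna"]

    per_sample: list[list[Peak]] = []
    for _ in csrna_samples:
        sample_peaks = []
        for p in truth_peaks:
            j1 = int(jitter_rng.integers(0, 11))
            j2 = int(jitter_rng.integers(0, 11))
            iv = GenomicInterval(
                p.chrom, max(p.interval.start - j1, 0), p.interval.end + j2, p.strand
            )
            sample_peaks.append(Peak(p.peak_id, iv, center=p.center))
        per_sample.append(sample_peaks)
    merged = merge_peaks(per_sample)

    # map truth peaks -> merged ids (same chrom/strand, truth center inside)
    truth_to_merged = {}
    by_key = sorted(merged, key=lambda m: (m.chrom, m.strand, m.interval.start))
    starts: dict[tuple[str, str], tuple[list[int], list[Peak]]] = {}
    for m in by_key:
        key = (m.chrom, m.strand)
        starts.setdefault(key, ([], []))
        starts[key][0].append(m.interval.start)
        starts[key][1].append(m)
    import bisect as _bisect

    for p in truth_peaks:
        key = (p.chrom, p.strand)
        pos, plist = starts[key]
        i = _bisect.bisect_right(pos, p.center) - 1
        m = plist[i]
        if not (m.interval.start <= p.center < m.interval.end):
            raise RuntimeError(f"truth peak {p.peak_id} not contained in a merged peak")
        truth_to_merged[p.peak_id] = m.peak_id

    merged_ids = [truth_to_merged[p.peak_id] for p in truth_peaks]
    if len(set(merged_ids)) != len(merged_ids):
        raise RuntimeError("distinct truth peaks merged together; geometry too dense")

    # ---- ground-truth effects -------------------------------------------
    truth = GroundTruth()
    truth.peak_roles = dict(zip(merged_ids, roles))
    truth.peak_gene = dict(zip(merged_ids, hosts))

    n_cand = int(round(config.frac_candidate_genes * config.n_genes))
    cand_idx = np.sort(eff_rng.choice(config.n_genes, size=n_cand, replace=False))
    candidate_genes = {genes[int(i)].gene_id for i in cand_idx}
    truth.candidate_genes = sorted(candidate_genes)

    p0 = config.frac_di
    odds0 = p0 / (1.0 - p0) if p0 < 1 else np.inf
    p_cand = (odds0 * config.candidate_di_odds) / (1.0 + odds0 * config.candidate_di_odds)

    di_sign: dict[str, int] = {}
    for mid, role, host in zip(merged_ids, roles, hosts):
        if role == "contaminant":
            continue
        p_di = p_cand if host in candidate_genes else p0
        if eff_rng.random() < p_di:
            di_sign[mid] = 1 if eff_rng.random() < 0.5 else -1

    # enhancer channel: DI enhancers get a bivariate (peak, gene) effect
    rho = config.enhancer_gene_corr
    sd = config.enhancer_lfc_sd
    cov = np.array([[sd**2, rho * sd**2], [rho * sd**2, sd**2]])
    for mid, role, host in zip(merged_ids, roles, hosts):
        if role != "enhancer" or mid not in di_sign:
            continue
        s = di_sign[mid]
        mean = np.array([s * config.lfc_magnitude, s * config.lfc_magnitude])
        peak_lfc, gene_lfc = eff_rng.multivariate_normal(mean, cov)
        truth.di_peaks[mid] = float(peak_lfc)
        truth.enhancer_peaks.append(mid)
        if host not in truth.de_genes:
            truth.de_genes[host] = float(gene_lfc)
            truth.enhancer_target_pairs.append((mid, host))
    # non-DI enhancer peaks are still true (unstable, distal) enhancers
    for mid, role in zip(merged_ids, roles):
        if role == "enhancer" and mid not in truth.enhancer_peaks:
            truth.enhancer_peaks.append(mid)
    truth.enhancer_peaks.sort()

    # promoter/intronic channel: fixed-magnitude DI effects; DE derives from
    # DI promoter peaks with matching sign w.p. parallel_sign_prob
    for mid, role, host in zip(merged_ids, roles, hosts):
        if role not in ("promoter", "intronic") or mid not in di_sign:
            continue
        s = di_sign[mid]
        if role == "promoter":
            if host in truth.de_genes:
                # gene already DE (enhancer target): align the peak sign instead
                gsign = 1 if truth.de_genes[host] > 0 else -1
                s = gsign if eff_rng.random() < config.parallel_sign_prob else -gsign
            elif eff_rng.random() < config.de_given_promoter_di:
                gsign = s if eff_rng.random() < config.parallel_sign_prob else -s
                truth.de_genes[host] = float(gsign * config.lfc_magnitude)
        truth.di_peaks[mid] = float(s * config.lfc_magnitude)
    # independent background DE genes
    for g in genes:
        if g.gene_id in truth.de_genes:
            continue
        if eff_rng.random() < config.frac_independent_de:
            s = 1 if eff_rng.random() < 0.5 else -1
            truth.de_genes[g.gene_id] = float(
                eff_rng.normal(s * config.lfc_magnitude, 0.5)
            )
    truth.contaminant_peaks = sorted(
        mid for mid, role in zip(merged_ids, roles) if role == "contaminant"
    )

    # ---- counts ----------------------------------------------------------
    n_peaks = len(truth_peaks)
    base_cs = config.mean_count * np.exp(eff_rng.normal(0.0, 0.5, size=n_peaks))
    drain_eff = eff_rng.normal(0.0, config.drainage_effect_sd, size=(n_peaks, len(config.drainages)))
    cs_meta = [r for r in sheet_rows if r[1] == "csrna"]
    depth_cs = np.exp(config.rng("csrna").normal(0.0, config.libsize_sd, size=len(cs_meta)))

    lfc_vec = np.array([truth.di_peaks.get(mid, 0.0) for mid in merged_ids])
    contaminant_mask = np.array([r == "contaminant" for r in roles])

    drain_index = {d: k for k, d in enumerate(config.drainages)}
    cs_rng = config.rng("csrna")
    cs_counts = np.zeros((n_peaks, len(cs_meta)), dtype=np.int64)
    for j, (sid, _a, eco, drain, _sp) in enumerate(cs_meta):
        eco_sign = 1.0 if eco == "sulfidic" else -1.0
        log2_mu = (
            np.log2(base_cs)
            + 0.5 * lfc_vec * eco_sign
            + drain_eff[:, drain_index[drain]]
        )
        mu = (2.0**log2_mu) * depth_cs[j]
        cs_counts[:, j] = nb_draws(cs_rng, mu, config.dispersion)

    in_rng = config.rng("input")
    input_mean = np.where(contaminant_mask, config.mean_count, 0.2)
    in_counts = np.zeros((n_peaks, len(input_samples)), dtype=np.int64)
    depth_in = np.exp(in_rng.normal(0.0, config.libsize_sd, size=len(input_samples)))
    for j in range(len(input_samples)):
        in_counts[:, j] = nb_draws(in_rng, input_mean * depth_in[j], config.dispersion)

    mr_meta = [r for r in sheet_rows if r[1] == "mrna"]
    mr_rng = config.rng("mrna")
    base_mr = config.mean_count * np.exp(eff_rng.normal(0.0, 0.5, size=config.n_genes))
    gene_drain_eff = eff_rng.normal(0.0, config.drainage_effect_sd, size=(config.n_genes, len(config.drainages)))
    gene_lfc_vec = np.array([truth.de_genes.get(g.gene_id, 0.0) for g in genes])
    depth_mr = np.exp(mr_rng.normal(0.0, config.libsize_sd, size=len(mr_meta)))
    mr_counts = np.zeros((config.n_genes, len(mr_meta)), dtype=np.int64)
    for j, (sid, _a, eco, drain, _sp) in enumerate(mr_meta):
        eco_sign = 1.0 if eco == "sulfidic" else -1.0
        log2_mu = (
            np.log2(base_mr)
            + 0.5 * gene_lfc_vec * eco_sign
            + gene_drain_eff[:, drain_index[drain]]
        )
        mu = (2.0**log2_mu) * depth_mr[j]
        mr_counts[:, j] = nb_draws(mr_rng, mu, config.dispersion)

    # ---- stability / coverage -------------------------------------------
    coverage = {
        mid: (0.0 if role == "enhancer" else config.stable_coverage)
        for mid, role in zip(merged_ids, roles)
    }

    # ---- motif planting --------------------------------------------------
    motifs = default_motifs()
    genome = _random_genome(config)
    target_motifs = [motifs[i] for i in TARGET_MOTIF_INDICES]
    merged_by_id = {m.peak_id: m for m in merged}
    for mid, role in zip(merged_ids, roles):
        if role not in ("promoter", "enhancer"):
            continue
        # plant relative to the merged peak's center so that rescanning the
        # merged peak window finds the motif at the recorded offset
        peak = merged_by_id[mid]
        regulated = mid in truth.di_peaks
        rate = (
            config.motif_plant_rate_target if regulated
            else config.motif_plant_rate_background
        )
        planted = []
        for k, motif in enumerate(target_motifs):
            if motif_rng.random() >= rate:
                continue
            woff = 30 + 40 * k
            lo, hi = scan_window_bounds(peak.center, peak.strand, 150, 50)
            consensus = motif.consensus()
            if peak.strand == "-":
                gstart = hi - woff - motif.length
                insert = reverse_complement(consensus)
            else:
                gstart = lo + woff
                insert = consensus
            genome[peak.chrom][gstart : gstart + motif.length] = insert.encode()
            planted.append({"motif_id": motif.motif_id, "name": motif.name, "offset": woff})
        if planted:
            truth.planted_motifs[mid] = planted

    # ---- write everything ------------------------------------------------
    _write_fasta(genome, out / "genome.fa")
    _write_gtf(genes, out / "genes.gtf")
    for sid, sample_peaks in zip(csrna_samples, per_sample):
        write_bed(sample_peaks, out / f"peaks_{sid}.bed")

    order = np.argsort(np.asarray(merged_ids, dtype=object))
    CountMatrix(cs_counts[order], np.asarray(merged_ids, dtype=object)[order], csrna_samples).write_tsv(
        out / "csrna_counts.tsv", index_label="peak_id"
    )
    CountMatrix(in_counts[order], np.asarray(merged_ids, dtype=object)[order], input_samples).write_tsv(
        out / "input_counts.tsv", index_label="peak_id"
    )
    CountMatrix(mr_counts, [g.gene_id for g in genes], mrna_samples).write_tsv(
        out / "mrna_counts.tsv", index_label="gene_id"
    )

    with open(out / "mrna_window_coverage.tsv", "w") as fh:
        fh.write("peak_id\tmrna_reads\n")
        for mid in sorted(coverage):
            fh.write(f"{mid}\t{coverage[mid]:.1f}\n")

    write_jaspar(motifs, out / "motifs.jaspar")

    with open(out / "samples.tsv", "w") as fh:
        fh.write("sample_id\tassay\tecotype\tdrainage\tspecies\n")
        for row in sheet_rows:
            fh.write("\t".join(row) + "\n")

    with open(out / "candidates.txt", "w") as fh:
        for g in truth.candidate_genes:
            fh.write(g + "\n")

    truth.enhancer_target_pairs.sort()
    truth.to_json(out / "ground_truth.json")
    return truth
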