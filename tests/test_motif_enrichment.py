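import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nascentreg.genome_annotation import GenomicInterval, Peak, reverse_complement
from nascentreg.intersection_analysis import ContingencyTable2x2, fisher_exact
from nascentreg.motif_enrichment import (
    MotifMatrix,
    build_enhancer_background,
    build_promoter_background,
    enrich,
    pfm_to_pwm,
    read_jaspar,
    scan,
    tf_expression_support,
    write_jaspar,
)
from nascentreg.synthetic_data import default_motifs


JASPAR_TEXT = """\
>MA0001.1 TFA
A [ 10  0 30 ]
C [  0 40  0 ]
G [ 20  0  0 ]
T [  0  0  0 ]
>MA0002.1 TFB::TFC
C [ 1 2 3 4 ]
A [ 4 3 2 1 ]
T [ 0 1 0 1 ]
G [ 5 4 5 4 ]
"""


class TestReadJaspar:
    def test_parses_two_motifs(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_TEXT)
        motifs = read_jaspar(path)
        assert [m.motif_id for m in motifs] == ["MA0001.1", "MA0002.1"]
        assert motifs[0].length == 3 and motifs[1].length == 4

    def test_row_labels_drive_mapping(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(JASPAR_TEXT)
        m = read_jaspar(path)[1]
        # rows listed C,A,T,G must land on canonical A,C,G,T order
        assert list(m.pfm[0]) == [4, 3, 2, 1]  # A row
        assert list(m.pfm[2]) == [5, 4, 5, 4]  # G row

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.jaspar"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert read_jaspar(path) == []

    def test_row_length_mismatch_names_motif(self, tmp_path):
        path = tmp_path / "bad.jaspar"
        path.write_text(">MX BAD\nA [1 2 3]\nC [1 2]\nG [1 2 3]\nT [1 2 3]\n")
        with pytest.raises(ValueError, match="MX"):
            read_jaspar(path)

    def test_round_trip(self, tmp_path):
        motifs = default_motifs()
        path = tmp_path / "rt.jaspar"
        write_jaspar(motifs, path)
        back = read_jaspar(path)
        assert [m.motif_id for m in back] == [m.motif_id for m in motifs]
        for a, b in zip(motifs, back):
            assert np.allclose(a.pfm, b.pfm)


class TestPfmToPwm:
    def test_uniform_column_scores_zero(self):
        pwm, s_max, s_min = pfm_to_pwm(np.full((4, 2), 25.0))
        assert np.allclose(pwm, 0.0, atol=1e-12)
        assert s_max == pytest.approx(s_min)

    def test_one_hot_column_weight(self):
        pfm = np.array([[100.0], [0.0], [0.0], [0.0]])
        pwm, s_max, s_min = pfm_to_pwm(pfm, pseudocount=0.8)
        expected = math.log2((100.2 / 100.8) / 0.25)
        assert pwm[0, 0] == pytest.approx(expected, abs=1e-6)
        assert pwm[0, 0] == pytest.approx(1.991, abs=1e-3)

    def test_smax_bounds_smin(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            pfm = rng.integers(0, 50, size=(4, 6)).astype(float) + 0.1
            _, s_max, s_min = pfm_to_pwm(pfm)
            assert s_max >= s_min

    def test_zero_column_errors(self):
        with pytest.raises(ValueError):
            pfm_to_pwm(np.zeros((4, 2)))


def _flanked(consensus, rng, left=60, right=60):
    flank = lambda n: "".join(rng.choice(list("ACGT"), size=n))
    return flank(left) + consensus + flank(right), left


class TestScan:
    def test_consensus_hit_deficit_zero(self):
        m = default_motifs()[0]
        rng = np.random.default_rng(4)
        seq, offset = _flanked(m.consensus(), rng)
        hits = [h for h in scan(seq, m) if h.offset == offset and h.strand == "+"]
        assert hits and hits[0].deficit == pytest.approx(0.0, abs=1e-12)

    def test_strict_zero_deficit_rejects_mismatch(self):
        m = default_motifs()[0]
        rng = np.random.default_rng(4)
        cons = list(m.consensus())
        cons[3] = "A" if cons[3] != "A" else "C"
        seq, offset = _flanked("".join(cons), rng)
        assert not [h for h in scan(seq, m, max_deficit=0.0) if h.offset == offset]

    def test_sequence_shorter_than_motif(self):
        assert scan("ACG", default_motifs()[0]) == []

    def test_deficit_range_and_anticonsensus(self):
        m = default_motifs()[0]
        anti = "".join("ACGT"[int(np.argmin(m.pwm[:, j]))] for j in range(m.length))
        hits = scan(anti, m, max_deficit=1.0)
        fwd = [h for h in hits if h.strand == "+" and h.offset == 0]
        assert fwd and fwd[0].deficit == pytest.approx(1.0, abs=1e-12)
        assert all(0.0 <= h.deficit <= 1.0 for h in hits)

    @given(st.integers(0, 2 ** 16))
    @settings(max_examples=30, deadline=None)
    def test_strand_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        m = default_motifs()[seed % 6]
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04], size=80))
        fwd = {(h.offset, h.strand, round(h.score, 9)) for h in scan(seq, m, 0.4)}
        rc = {(h.offset, h.strand, round(h.score, 9)) for h in scan(reverse_complement(seq), m, 0.4)}
        L = m.length
        mirrored = {(len(seq) - L - o, "+" if s == "-" else "-", sc) for o, s, sc in rc}
        assert fwd == mirrored


class TestEnrich:
    def test_planted_motif_detected(self):
        rng = np.random.default_rng(10)
        m = default_motifs()[0]
        targets, background = {}, {}
        for i in range(100):
            seq, _ = _flanked(m.consensus() if i < 60 else "", rng, 95, 95)
            targets[f"t{i}"] = seq
        for i in range(1000):
            seq, _ = _flanked(m.consensus() if i < 50 else "", rng, 95, 95)
            background[f"b{i}"] = seq
        res = enrich(targets, background, [m])
        assert res[0].significant and res[0].pvalue < 0.01
        assert res[0].log2_enrichment > 3

    def test_identical_sets_are_null(self):
        rng = np.random.default_rng(11)
        seqs = {f"s{i}": "".join(rng.choice(list("ACGT"), size=200)) for i in range(50)}
        res = enrich(seqs, dict(seqs), default_motifs())
        for r in res:
            assert r.log2_enrichment == pytest.approx(0.0, abs=1e-12)
            assert r.pvalue == pytest.approx(1.0)

    def test_pvalue_agrees_with_fisher_oracle(self):
        rng = np.random.default_rng(12)
        m = default_motifs()[1]
        targets = {f"t{i}": _flanked(m.consensus() if i % 3 == 0 else "", rng, 40, 40)[0]
                   for i in range(30)}
        background = {f"b{i}": _flanked(m.consensus() if i % 7 == 0 else "", rng, 40, 40)[0]
                      for i in range(60)}
        r = enrich(targets, background, [m])[0]
        oracle = fisher_exact(
            ContingencyTable2x2(
                r.n_target_with, r.n_target - r.n_target_with,
                r.n_bg_with, r.n_bg - r.n_bg_with,
            )
        )
        assert r.pvalue == pytest.approx(oracle.p_two_sided, rel=1e-9)

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            enrich({}, {"a": "ACGT"}, default_motifs())


def _promoter_peak(pid, gene):
    p = Peak(pid, GenomicInterval("chr1", 100, 200, "+"))
    p.category = "promoter-TSS"
    p.nearest_gene = gene
    return p


class TestBackgrounds:
    def test_promoter_background_rules(self):
        peaks = [_promoter_peak("p1", "g1"), _promoter_peak("p2", "g2"),
                 _promoter_peak("p3", "g3"), _promoter_peak("p4", "g4")]
        di = pd.DataFrame(
            {
                "feature_id": ["p1", "p2", "p3", "p4"],
                "log2fc": [0.3, 0.6, 0.3, -0.3],
                "pvalue": [0.5, 0.5, 0.001, 0.5],
                "fdr": [0.2, 0.2, 0.01, 0.2],
                "ave_log_cpm": 5.0,
            }
        )
        bg = build_promoter_background(peaks, di, de_genes={"g4"})
        # p1 passes; p2 fails |lfc| < 0.5; p3 fails fdr; p4's gene is DE
        assert bg == ["p1"]

    def test_promoter_background_empty_errors(self):
        peaks = [_promoter_peak("p1", "g1")]
        di = pd.DataFrame(
            {"feature_id": ["p1"], "log2fc": [2.0], "pvalue": [0.001],
             "fdr": [0.01], "ave_log_cpm": 5.0}
        )
        with pytest.raises(ValueError, match="empty"):
            build_promoter_background(peaks, di, de_genes=set())

    def test_enhancer_background_sampling(self):
        ids = [f"e{i:04d}" for i in range(500)]
        di = pd.DataFrame(
            {"feature_id": ids, "log2fc": 0.0, "pvalue": 1.0, "fdr": 1.0,
             "ave_log_cpm": 5.0}
        )
        a = build_enhancer_background(ids, di, n=100, seed=1)
        b = build_enhancer_background(ids, di, n=100, seed=1)
        c = build_enhancer_background(ids, di, n=100, seed=2)
        assert a == b and len(a) == 100
        assert a != c
        with pytest.warns(UserWarning, match="smaller"):
            clamped = build_enhancer_background(ids[:50], di, n=100, seed=1)
        assert len(clamped) == 50

    def test_enhancer_background_excludes_di(self):
        ids = ["e1", "e2"]
        di = pd.DataFrame(
            {"feature_id": ids, "log2fc": [2.0, 0.1], "pvalue": [0.001, 0.9],
             "fdr": [0.01, 0.9], "ave_log_cpm": 5.0}
        )
        assert build_enhancer_background(ids, di, n=10, seed=0) == ["e2"]


class TestTfExpressionSupport:
    def _de(self, rows):
        return pd.DataFrame(rows, columns=["feature_id", "log2fc", "pvalue", "fdr", "ave_log_cpm"])

    def _result(self, name):
        from nascentreg.motif_enrichment import EnrichmentResult

        return EnrichmentResult(
            motif_id="M1", name=name, n_target_with=1, n_target=2, n_bg_with=1,
            n_bg=2, prop_target=0.5, prop_bg=0.5, log2_enrichment=0.0,
            pvalue=1.0, significant=False,
        )

    def test_case_insensitive_match(self):
        de = self._de([("gata2", 1.2, 0.001, 0.01, 5.0)])
        (r,) = tf_expression_support([self._result("GATA2")], de)
        assert r.support == "up"

    def test_dimer_components_split_on_double_colon(self):
        de = self._de([("fosb", 1.2, 0.001, 0.01, 5.0), ("junb", 0.5, 0.5, 0.6, 5.0)])
        (r,) = tf_expression_support([self._result("FOSB::JUNB")], de)
        assert r.support == "up"

    def test_conflicting_components_report_both(self):
        de = self._de([("a1", 1.0, 0.001, 0.01, 5.0), ("b1", -1.0, 0.001, 0.01, 5.0)])
        (r,) = tf_expression_support([self._result("A1::B1")], de)
        assert r.support == "down/up"

    def test_no_match_is_none(self):
        (r,) = tf_expression_support([self._result("NOSUCH")], self._de([]))
        assert r.support == "none"
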