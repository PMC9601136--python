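"""Mapper, union counting, TPM, depth, per-cell and differential rules."""

import numpy as np
import pandas as pd
import pytest

from metamerge import quant
from metamerge.types import (
    AlignmentRecord,
    AnnotationRecord,
    GeneFeature,
    ParameterError,
    ReadPair,
    SeqRecord,
    revcomp,
)


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def make_pair(rid, template, off, frag, read_len=100):
    rl = min(read_len, frag)
    return ReadPair(
        id=rid,
        seq1=template[off : off + rl],
        seq2=revcomp(template[off + frag - rl : off + frag]),
        qual1="I" * rl,
        qual2="I" * rl,
    )


class TestMapper:
    def test_error_free_read_maps_to_truth(self, rng):
        ref = SeqRecord(id="s", sequence=rand_seq(rng, 5000))
        pair = make_pair("r1", ref.sequence, 1234, 400)
        a, b = quant.ReadMapper([ref]).map_pair(pair)
        assert a.target_start == 1234 and a.strand == "+"
        assert b.target_start == 1534 - 100 + 100 and b.strand == "-"
        assert a.properly_paired and a.fragment_len == 400

    def test_exhaustive_hamming_oracle_with_mismatches(self, rng):
        ref_seq = rand_seq(rng, 4000)
        ref = SeqRecord(id="s", sequence=ref_seq)
        read = list(ref_seq[700:850])  # 150 nt
        for p in (10, 80, 140):
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        read = "".join(read)
        hit = quant.ReadMapper([ref])._map_single(read)
        # sliding-window Hamming oracle
        best = min(
            range(len(ref_seq) - 150 + 1),
            key=lambda i: sum(a != b for a, b in zip(ref_seq[i : i + 150], read)),
        )
        assert hit is not None and hit[1] == best == 700 and hit[3] == 3

    def test_repeat_locus_read_unmapped(self, rng):
        unit = rand_seq(rng, 500)
        ref = SeqRecord(id="s", sequence=unit + rand_seq(rng, 1000) + unit)
        read = unit[100:300]
        assert quant.ReadMapper([ref])._map_single(read) is None

    def test_too_many_mismatches_unmapped(self, rng):
        ref_seq = rand_seq(rng, 3000)
        read = list(ref_seq[500:600])
        for p in rng.choice(100, size=10, replace=False):  # 10% > 5%
            read[p] = {"A": "C", "C": "G", "G": "T", "T": "A"}[read[p]]
        hit = quant.ReadMapper([SeqRecord(id="s", sequence=ref_seq)])._map_single("".join(read))
        assert hit is None

    def test_empty_reference_rejected(self):
        with pytest.raises(ParameterError):
            quant.ReadMapper([])


def _aln(query, target, start, end, mate1=True, proper=True):
    return AlignmentRecord(
        query_id=query,
        target_id=target,
        target_start=start,
        strand="+",
        cigar=f"{end - start}M",
        mapq=60,
        is_mate1=mate1,
        properly_paired=proper,
        fragment_len=end - start,
    )


class TestCountReads:
    FEATS = [
        GeneFeature(gene_id="gA", scaffold_id="s", start=1000, end=2000, strand="+"),
        GeneFeature(gene_id="gB", scaffold_id="s", start=3000, end=4000, strand="+"),
    ]

    def test_pair_inside_one_gene(self):
        alns = [_aln("r1", "s", 1100, 1200), _aln("r1", "s", 1400, 1500, mate1=False)]
        counts = quant.count_reads(alns, self.FEATS)
        assert counts["gA"] == 1 and counts["gB"] == 0

    def test_mates_in_different_genes_ambiguous(self):
        alns = [_aln("r1", "s", 1100, 1200), _aln("r1", "s", 3100, 3200, mate1=False)]
        counts = quant.count_reads(alns, self.FEATS)
        assert counts.sum() == 0

    def test_no_feature_uncounted(self):
        alns = [_aln("r1", "s", 2100, 2200), _aln("r1", "s", 2400, 2500, mate1=False)]
        assert quant.count_reads(alns, self.FEATS).sum() == 0

    def test_matches_bruteforce_interval_oracle_on_random_fixtures(self, rng):
        for _ in range(25):
            n_genes = rng.integers(2, 6)
            starts = np.sort(rng.choice(np.arange(0, 9000, 100), size=n_genes, replace=False))
            feats = [
                GeneFeature(
                    gene_id=f"g{i}",
                    scaffold_id="s",
                    start=int(s),
                    end=int(s) + int(rng.integers(200, 800)),
                    strand="+",
                )
                for i, s in enumerate(starts)
            ]
            alns = []
            for r in range(40):
                a = int(rng.integers(0, 9500))
                b = int(rng.integers(0, 9500))
                alns.append(_aln(f"r{r}", "s", a, a + 100))
                alns.append(_aln(f"r{r}", "s", b, b + 100, mate1=False))
            counts = quant.count_reads(alns, feats)
            # brute-force union oracle
            expected = {f.gene_id: 0 for f in feats}
            for r in range(40):
                touched = set()
                for aln in alns:
                    if aln.query_id != f"r{r}":
                        continue
                    for f in feats:
                        if aln.target_start < f.end and f.start < aln.target_end:
                            touched.add(f.gene_id)
                if len(touched) == 1:
                    expected[next(iter(touched))] += 1
            assert counts.to_dict() == {k: float(v) for k, v in expected.items()}

    def test_unknown_scaffold_rejected(self):
        with pytest.raises(ParameterError):
            quant.count_reads([_aln("r1", "zzz", 0, 100)], self.FEATS)


class TestTpm:
    def test_single_gene_gets_all(self):
        tpm = quant.compute_tpm(pd.Series({"g": 5.0}), pd.Series({"g": 700.0}))
        assert tpm["g"] == pytest.approx(1e6)

    def test_hand_computed_two_genes(self):
        # c=(10,10), l=(1kb,2kb): rates (10,5) -> tpm (2/3, 1/3) * 1e6
        tpm = quant.compute_tpm(
            pd.Series({"a": 10.0, "b": 10.0}), pd.Series({"a": 1000.0, "b": 2000.0})
        )
        assert tpm["a"] == pytest.approx(666_666.6667, rel=1e-6)
        assert tpm["b"] == pytest.approx(333_333.3333, rel=1e-6)

    def test_sum_conservation_random(self, rng):
        for _ in range(20):
            n = int(rng.integers(2, 50))
            counts = pd.Series(rng.integers(0, 1000, n).astype(float))
            lengths = pd.Series(rng.integers(300, 3000, n).astype(float))
            if counts.sum() == 0:
                continue
            assert quant.compute_tpm(counts, lengths).sum() == pytest.approx(1e6, rel=1e-6)

    def test_permutation_equivariance(self, rng):
        counts = pd.Series({"a": 5.0, "b": 9.0, "c": 2.0})
        lengths = pd.Series({"a": 400.0, "b": 1200.0, "c": 900.0})
        t1 = quant.compute_tpm(counts, lengths)
        order = ["c", "a", "b"]
        t2 = quant.compute_tpm(counts[order], lengths[order])
        assert t1.sort_index().equals(t2.sort_index())

    def test_all_zero_sample_stays_zero(self):
        tpm = quant.compute_tpm(pd.Series({"a": 0.0}), pd.Series({"a": 500.0}))
        assert (tpm == 0).all()


class TestDepthAndPerCell:
    def test_ten_reads_fully_inside_gives_depth_one(self):
        feats = [GeneFeature(gene_id="g", scaffold_id="s", start=0, end=1000, strand="+")]
        alns = [_aln(f"r{i}", "s", i * 50, i * 50 + 100) for i in range(10)]
        depth = quant.compute_depth(alns, feats)
        assert depth["g"] == pytest.approx(1.0)

    def test_depth_linearity(self):
        feats = [GeneFeature(gene_id="g", scaffold_id="s", start=0, end=1000, strand="+")]
        alns = [_aln(f"r{i}", "s", 100, 300) for i in range(5)]
        d1 = quant.compute_depth(alns, feats)["g"]
        d2 = quant.compute_depth(alns + [_aln(f"q{i}", "s", 100, 300) for i in range(5)], feats)["g"]
        assert d2 == pytest.approx(2 * d1)

    def test_per_cell_direct_formula(self):
        pc = quant.compute_per_cell(
            pd.Series({"g": 100.0}), pd.Series({"g": 1000.0}), pd.Series({"g": 10.0})
        )
        assert pc["g"] == pytest.approx(10.0)

    def test_per_cell_abundance_cancellation(self):
        # 10x abundance -> 10x counts and 10x depth -> identical per-cell
        counts = pd.Series({"a": 10.0, "b": 100.0})
        lengths = pd.Series({"a": 1000.0, "b": 1000.0})
        depth = pd.Series({"a": 1.0, "b": 10.0})
        pc = quant.compute_per_cell(counts, lengths, depth)
        assert pc["a"] == pytest.approx(pc["b"])

    def test_zero_depth_masked_not_zero(self):
        pc = quant.compute_per_cell(
            pd.Series({"g": 5.0}), pd.Series({"g": 1000.0}), pd.Series({"g": 0.0})
        )
        assert np.isnan(pc["g"])


class TestDifferential:
    def _matrix(self, vals):
        cols = pd.MultiIndex.from_tuples(
            [("ind1", "cecum"), ("ind1", "feces"), ("ind2", "cecum"), ("ind2", "feces")]
        )
        # second KO with a tiny positive value keeps the adaptive
        # pseudocount (min positive / 2) negligible for the KO under test
        return pd.DataFrame(
            [vals, [1e-4] * 4], index=["K00001", "K99999"], columns=cols
        )

    def test_same_direction_twofold_significant(self):
        m = self._matrix([2.9, 1.0, 2.4, 1.0])  # +1.5, +1.2 log2
        call = next(c for c in quant.flag_differential(m, ("cecum", "feces")) if c.ko_id == "K00001")
        assert call.significant

    def test_direction_clash_not_significant(self):
        m = self._matrix([2.9, 1.0, 1.0, 2.4])  # +1.5, -1.2
        call = next(c for c in quant.flag_differential(m, ("cecum", "feces")) if c.ko_id == "K00001")
        assert not call.significant

    def test_twofold_not_met_in_both(self):
        m = self._matrix([1.8, 1.0, 4.1, 1.0])  # +0.9, +2.0
        call = next(c for c in quant.flag_differential(m, ("cecum", "feces")) if c.ko_id == "K00001")
        assert not call.significant

    def test_ko_aggregation_sums_members(self):
        ann = {
            "g1": AnnotationRecord(gene_id="g1", ko="K1"),
            "g2": AnnotationRecord(gene_id="g2", ko="K1"),
            "g3": AnnotationRecord(gene_id="g3", ko="K2"),
            "g4": AnnotationRecord(gene_id="g4"),
        }
        cols = pd.MultiIndex.from_tuples([("ind1", "cecum")])
        m = pd.DataFrame([[1.0], [2.0], [4.0], [8.0]], index=["g1", "g2", "g3", "g4"], columns=cols)
        agg = quant.aggregate_by_ko(m, ann)
        assert agg.loc["K1"].iloc[0] == 3.0 and agg.loc["K2"].iloc[0] == 4.0
        assert "g4" not in agg.index and len(agg) == 2
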