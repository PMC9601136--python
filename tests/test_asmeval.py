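"""Assembly metrics: N-statistics, chimera index, nonchimeric rate, CPM."""

import itertools

import numpy as np
import pytest

from metamerge import asmeval
from metamerge.merge import merge_pair
from metamerge.types import ParameterError, ReadPair, SeqRecord


def rand_seq(rng, n):
    return "".join("ACGT"[i] for i in rng.integers(0, 4, n))


def bruteforce_nx(lengths, x):
    """Cumulative-scan oracle for the Nx statistic."""
    lens = sorted(lengths, reverse=True)
    total = sum(lens)
    cum = 0
    for ln in lens:
        cum += ln
        if cum >= x / 100 * total:
            return ln
    return lens[-1]


class TestNStatistics:
    def test_worked_example(self):
        curve = asmeval.n_statistics([8, 5, 3])
        assert curve[10] == 8 and curve[50] == 8 and curve[60] == 5 and curve[100] == 3

    def test_single_scaffold_flat_curve(self):
        curve = asmeval.n_statistics([42])
        assert all(v == 42 for v in curve.values())

    def test_matches_bruteforce_on_random_sets(self, rng):
        for _ in range(50):
            lengths = rng.integers(1, 10_000, size=int(rng.integers(1, 30))).tolist()
            curve = asmeval.n_statistics(lengths)
            for x in range(10, 101, 10):
                assert curve[x] == bruteforce_nx(lengths, x)
            assert curve[100] == min(lengths)
            # non-increasing in percentile
            vals = [curve[x] for x in range(10, 101, 10)]
            assert vals == sorted(vals, reverse=True)

    def test_merged_dominates_fragments(self):
        whole = asmeval.n_statistics([12])
        for parts in ([8, 5], [5, 3]):
            frag = asmeval.n_statistics(parts)
            assert asmeval.curve_dominates(whole, frag)

    def test_empty_rejected(self):
        with pytest.raises(ParameterError):
            asmeval.n_statistics([])


@pytest.fixture
def truth_genomes(rng):
    return [
        SeqRecord(id="spA", sequence=rand_seq(rng, 20_000)),
        SeqRecord(id="spB", sequence=rand_seq(rng, 20_000)),
    ]


class TestAlignToTruth:
    def test_exact_segment_single_block(self, truth_genomes):
        scaf = SeqRecord(id="c1", sequence=truth_genomes[0].sequence[2000:8000])
        aligned = asmeval.align_to_truth([scaf], truth_genomes)
        (blk,) = aligned.blocks["c1"]
        assert blk.ref_id == "spA" and blk.identity == 100.0
        assert blk.q_start == 0 and blk.q_end == 6000

    def test_spliced_chimera_two_blocks(self, truth_genomes):
        a, b = truth_genomes
        scaf = SeqRecord(id="x", sequence=a.sequence[:5000] + b.sequence[:5000])
        aligned = asmeval.align_to_truth([scaf], truth_genomes)
        assert aligned.species_of("x") == {"spA", "spB"}

    def test_random_sequence_no_blocks(self, truth_genomes, rng):
        scaf = SeqRecord(id="r", sequence=rand_seq(rng, 5000))
        aligned = asmeval.align_to_truth([scaf], truth_genomes)
        assert aligned.blocks["r"] == []


class TestChimeraIndex:
    def _aligned(self, truth_genomes, scaffolds):
        return asmeval.align_to_truth(scaffolds, truth_genomes)

    def test_all_clean_ci_zero(self, truth_genomes):
        scafs = [
            SeqRecord(id="c1", sequence=truth_genomes[0].sequence[:8000]),
            SeqRecord(id="c2", sequence=truth_genomes[1].sequence[:8000]),
        ]
        assert asmeval.chimera_index(self._aligned(truth_genomes, scafs)) == 0.0

    def test_single_half_half_chimera_ci_one(self, truth_genomes):
        a, b = truth_genomes
        scafs = [SeqRecord(id="x", sequence=a.sequence[:5000] + b.sequence[:5000])]
        assert asmeval.chimera_index(self._aligned(truth_genomes, scafs)) == 1.0

    def test_chimera_plus_clean_ci_half(self, truth_genomes):
        a, b = truth_genomes
        scafs = [
            SeqRecord(id="x", sequence=a.sequence[:5000] + b.sequence[:5000]),
            SeqRecord(id="c", sequence=a.sequence[5000:15000]),
        ]
        assert asmeval.chimera_index(self._aligned(truth_genomes, scafs)) == pytest.approx(0.5)

    def test_no_aligned_scaffolds_undefined(self, truth_genomes, rng):
        scafs = [SeqRecord(id="r", sequence=rand_seq(rng, 5000))]
        with pytest.raises(ParameterError):
            asmeval.chimera_index(self._aligned(truth_genomes, scafs))


class TestNonchimericRate:
    def test_correct_merge_is_100(self, rng):
        genome = rand_seq(rng, 12_000)
        m = merge_pair(
            [SeqRecord(id="r1", sequence=genome[:7000])],
            [SeqRecord(id="q1", sequence=genome[5000:])],
            ref_site="a",
            query_site="b",
        )
        rate = asmeval.nonchimeric_rate(m, {("a", "r1"): "sp1", ("b", "q1"): "sp1"})
        assert rate == 100.0

    def test_cross_species_join_counts_clean_fraction(self, rng):
        # engineered shared overlap sequence forces a chimeric join
        shared = rand_seq(rng, 2000)
        ga = rand_seq(rng, 8000) + shared
        gb = shared + rand_seq(rng, 8000)
        m = merge_pair(
            [SeqRecord(id="r1", sequence=ga), SeqRecord(id="r2", sequence=rand_seq(rng, 5000))],
            [SeqRecord(id="q1", sequence=gb)],
            ref_site="a",
            query_site="b",
        )
        labels = {("a", "r1"): "spA", ("a", "r2"): "spC", ("b", "q1"): "spB"}
        rate = asmeval.nonchimeric_rate(m, labels)
        total = m.total_bp()
        chimera_len = next(
            len(s) for s in m.scaffolds if len({labels[(p.site, p.source_id)] for p in m.provenance[s.id]}) > 1
        )
        assert rate == pytest.approx(100.0 * (total - chimera_len) / total)

    def test_missing_labels_rejected(self, rng):
        genome = rand_seq(rng, 5000)
        m = merge_pair([SeqRecord(id="r1", sequence=genome)], [], ref_site="a")
        with pytest.raises(ParameterError):
            asmeval.nonchimeric_rate(m, {})


class TestCompositeMetric:
    def test_perfect_assembly_cpm_is_n50(self, truth_genomes):
        scafs = [SeqRecord(id=g.id + "_c", sequence=g.sequence) for g in truth_genomes]
        ev = asmeval.composite_metric(scafs, asmeval.align_to_truth(scafs, truth_genomes))
        assert ev.ci == 0.0
        assert ev.tal == sum(len(s) for s in scafs)
        assert ev.cpm == pytest.approx(ev.n50)
        assert ev.mal == 20_000

    def test_fully_chimeric_cpm_zero(self, truth_genomes):
        a, b = truth_genomes
        scafs = [SeqRecord(id="x", sequence=a.sequence[:5000] + b.sequence[:5000])]
        ev = asmeval.composite_metric(scafs, asmeval.align_to_truth(scafs, truth_genomes))
        assert ev.ci == 1.0 and ev.cpm == 0.0

    def test_cpm_strictly_decreases_under_chimera_injection(self, rng):
        genomes = [SeqRecord(id=f"sp{i}", sequence=rand_seq(rng, 10_000)) for i in range(4)]
        cpms = []
        for n_chim in range(3):
            scafs = []
            for i, g in enumerate(genomes):
                if i < n_chim:
                    partner = genomes[(i + 1) % 4]
                    scafs.append(
                        SeqRecord(id=f"x{i}", sequence=g.sequence[:5000] + partner.sequence[5000:])
                    )
                else:
                    scafs.append(SeqRecord(id=f"c{i}", sequence=g.sequence))
            ev = asmeval.composite_metric(scafs, asmeval.align_to_truth(scafs, genomes))
            cpms.append(ev.cpm)
        assert cpms[0] > cpms[1] > cpms[2]

    def test_ci_and_nonchimeric_move_oppositely(self, rng):
        genomes = [SeqRecord(id=f"sp{i}", sequence=rand_seq(rng, 10_000)) for i in range(4)]
        cis, ncrs = [], []
        for n_chim in range(3):
            scafs = []
            for i, g in enumerate(genomes):
                if i < n_chim:
                    partner = genomes[(i + 1) % 4]
                    scafs.append(
                        SeqRecord(id=f"x{i}", sequence=g.sequence[:5000] + partner.sequence[5000:])
                    )
                else:
                    scafs.append(SeqRecord(id=f"c{i}", sequence=g.sequence))
            aligned = asmeval.align_to_truth(scafs, genomes)
            cis.append(asmeval.chimera_index(aligned))
            ncrs.append(asmeval.nonchimeric_rate(aligned=aligned))
        assert cis == sorted(cis) and ncrs == sorted(ncrs, reverse=True)
        assert cis[0] < cis[-1] and ncrs[0] > ncrs[-1]


class TestMappingRate:
    def test_reads_from_reference_all_map(self, rng):
        ref = SeqRecord(id="s", sequence=rand_seq(rng, 6000))
        pairs = []
        for i in range(20):
            off = int(rng.integers(0, 5600))
            frag = 300
            from metamerge.types import revcomp

            pairs.append(
                ReadPair(
                    id=f"r{i}",
                    seq1=ref.sequence[off : off + 100],
                    seq2=revcomp(ref.sequence[off + frag - 100 : off + frag]),
                    qual1="I" * 100,
                    qual2="I" * 100,
                )
            )
        assert asmeval.mapping_rate(pairs, [ref]) == 100.0

    def test_foreign_reads_do_not_map(self, rng):
        ref = SeqRecord(id="s", sequence=rand_seq(rng, 6000))
        other = rand_seq(rng, 6000)
        pairs = [
            ReadPair(id=f"r{i}", seq1=other[i * 100 : i * 100 + 100], seq2=other[i * 100 : i * 100 + 100], qual1="I" * 100, qual2="I" * 100)
            for i in range(10)
        ]
        assert asmeval.mapping_rate(pairs, [ref]) == 0.0
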