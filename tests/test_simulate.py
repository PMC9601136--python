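"""Generator contracts: determinism, ORF validity, designed structure."""

import numpy as np
import pytest

from metamerge import simulate
from metamerge.spatial import build_weights, lee_L
from metamerge.types import ParameterError, PipelineConfig, revcomp

STOPS = {"TAA", "TAG", "TGA"}


def orf_is_valid(seq: str) -> bool:
    """Independent ORF checker: ATG start, stop end, no internal stop."""
    if len(seq) % 3 != 0 or not seq.startswith("ATG"):
        return False
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    return codons[-1] in STOPS and not any(c in STOPS for c in codons[:-1])


class TestSimulateGenomes:
    def test_gene_count_and_orf_validity(self):
        c = simulate.simulate_genomes(1, (50_000, 50_001), gc=0.5, gene_density=1 / 5000, seed=7)
        genes = c.genes
        assert len(genes) == 10
        for g in genes:
            assert orf_is_valid(c.gene_sequence(g))
            assert 300 <= len(g) <= 3000 and len(g) % 3 == 0

    def test_genes_non_overlapping(self):
        c = simulate.simulate_genomes(2, (30_000, 40_000), seed=3)
        for sp, _rec in c.genomes:
            spans = sorted((g.start, g.end) for g in c.genes_of(sp))
            for (s1, e1), (s2, _e2) in zip(spans, spans[1:]):
                assert e1 <= s2

    def test_same_seed_identical(self):
        a = simulate.simulate_genomes(2, (30_000, 40_000), seed=11)
        b = simulate.simulate_genomes(2, (30_000, 40_000), seed=11)
        assert [r.sequence for _s, r in a.genomes] == [r.sequence for _s, r in b.genomes]

    def test_infeasible_density_rejected(self):
        with pytest.raises(ParameterError):
            simulate.simulate_genomes(1, (10_000, 10_001), gene_density=1 / 500, seed=0)


class TestExpression:
    def test_null_effect_indistinguishable(self, site_order, weights):
        """effect 0: designed-pair L distribution overlaps the null."""
        c = simulate.gene_panel(400)
        simulate.assign_expression(c, site_order, n_covariant_pairs=50, effect_size=0.0, noise_sd=0.5, seed=5)
        expr = np.log2(1 + c.expression)
        prof = {g: expr.loc[g].to_numpy() for g in expr.index}
        pair_L = [lee_L(prof[a], prof[b], weights) for a, b in c.covariant_pairs]
        others = sorted(set(expr.index) - {g for p in c.covariant_pairs for g in p})
        null_L = [lee_L(prof[a], prof[b], weights) for a, b in zip(others[::2], others[1::2])]
        assert abs(np.mean(pair_L) - np.mean(null_L)) < 0.15

    def test_zero_noise_strong_effect_near_perfect_ranking(self, site_order, weights):
        """noise 0, strong effect: designed pairs outrank non-pairs almost surely.

        An identical pair's L equals its spatial smoothing scalar (< 1 for
        non-block-constant shapes), so exact AUC 1 is not guaranteed with 6
        observations; near-perfect ranking is.
        """
        c = simulate.gene_panel(30)
        simulate.assign_expression(c, site_order, n_covariant_pairs=5, effect_size=3.0, noise_sd=0.0, seed=2)
        expr = np.log2(1 + c.expression)
        prof = {g: expr.loc[g].to_numpy() for g in expr.index}
        pair_ids = set(map(frozenset, c.covariant_pairs))
        ids = sorted(prof)
        pair_L, non_L = [], []
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                L = lee_L(prof[a], prof[b], weights)
                (pair_L if frozenset((a, b)) in pair_ids else non_L).append(L)
        auc = np.mean([p > q for p in pair_L for q in non_L])
        assert auc >= 0.95
        assert np.median(pair_L) > np.quantile(non_L, 0.95)

    def test_pair_members_share_reaction(self, site_order):
        c = simulate.gene_panel(100)
        simulate.assign_expression(c, site_order, n_covariant_pairs=10, seed=1)
        for a, b in c.covariant_pairs:
            assert c.annotations[a].reactions & c.annotations[b].reactions

    def test_same_seed_identical_matrix(self, site_order):
        kw = dict(n_covariant_pairs=10, effect_size=2.0, noise_sd=0.3, seed=9)
        a = simulate.gene_panel(100)
        simulate.assign_expression(a, site_order, **kw)
        b = simulate.gene_panel(100)
        simulate.assign_expression(b, site_order, **kw)
        assert a.expression.equals(b.expression)


class TestFragmentation:
    def test_cross_site_overlaps_at_least_mL(self, site_order):
        c = simulate.simulate_genomes(2, (40_000, 60_000), seed=4)
        sets = simulate.fragment_per_site(c, site_order["ind1"], mL=1000, seed=8)
        # fragments from different sites covering adjacent regions overlap >= mL
        for sp, rec in c.genomes:
            intervals = sorted(
                (int(r.tags()["start"]), int(r.tags()["end"]))
                for recs in sets.values()
                for r in recs
                if r.tags()["species"] == sp
            )
            # the union must tile the genome with pairwise chaining overlaps
            cover_end = intervals[0][1]
            assert intervals[0][0] == 0
            for s, e in intervals[1:]:
                if e <= cover_end:
                    continue  # contained
                assert cover_end - s >= 1000
                cover_end = e
            assert cover_end == len(rec.sequence)

    def test_min_frag_guard(self, site_order):
        c = simulate.simulate_genomes(1, (30_000, 30_001), seed=0)
        with pytest.raises(ParameterError):
            simulate.fragment_per_site(c, site_order["ind1"], min_frag=500, seed=0)

    def test_overlap_below_mL_rejected(self, site_order):
        c = simulate.simulate_genomes(1, (30_000, 30_001), seed=0)
        with pytest.raises(ParameterError):
            simulate.fragment_per_site(
                c, site_order["ind1"], overlap_range=(500, 800), mL=1000, seed=0
            )

    def test_fragments_at_least_1kb(self, site_order):
        c = simulate.simulate_genomes(3, (30_000, 50_000), seed=6)
        sets = simulate.fragment_per_site(c, site_order["ind1"], seed=6)
        for recs in sets.values():
            assert all(len(r) >= 1000 for r in recs)


def small_config(seed=0, **overrides):
    config = PipelineConfig()
    config.simulation.n_species = 2
    config.simulation.length_range = (25_000, 35_000)
    config.simulation.gene_density = 1 / 3000.0
    config.simulation.dna_depth = 2.0
    config.simulation.rna_depth = 2.0
    config.simulation.n_covariant_pairs = 4
    config.simulation.seed = seed
    for k, v in overrides.items():
        setattr(config.simulation, k, v)
    return config


class TestReads:
    def test_error_free_reads_substring_of_genome(self, site_order):
        config = small_config()
        community, _sets, dna, _rna, truth = simulate.simulate_community(config)
        genomes = dict(community.genomes)
        sample = ("ind1", "cecum")
        for pair in dna[sample][:50]:
            kind, smp, sp, off, strand, _g = truth.read_origin[pair.id]
            genome = genomes[sp].sequence
            fwd, rev = (pair.seq1, pair.seq2) if strand == "+" else (pair.seq2, pair.seq1)
            assert genome[off : off + len(fwd)] == fwd
            assert revcomp(rev) in genome

    def test_rna_reads_confined_to_gene_bodies(self, site_order):
        config = small_config()
        community, _sets, _dna, rna, truth = simulate.simulate_community(config)
        genes = {g.gene_id: g for g in community.genes}
        for pair in rna[("ind1", "feces")][:50]:
            _k, _s, sp, off, _strand, gid = truth.read_origin[pair.id]
            g = genes[gid]
            assert g.start <= off and off + len(pair.seq1) <= g.end + len(g)

    def test_expression_ratio_recovered_in_read_counts(self, site_order):
        """4:1 designed expression ratio appears as ~4:1 read counts."""
        c = simulate.simulate_genomes(1, (40_000, 40_001), gene_density=1 / 5000, seed=3)
        simulate.assign_abundance(c, site_order, seed=1)
        simulate.assign_expression(c, site_order, n_covariant_pairs=0, effect_size=0, noise_sd=0, seed=1)
        genes = sorted(c.annotations)
        same_len = [g for g in genes if len_of(c, g) == len_of(c, genes[0])]
        ga = genes[0]
        gb = next(g for g in genes if g != ga)
        c.expression.loc[:, :] = 1.0
        c.expression.loc[ga] = 4.0
        c.expression.loc[gb] = 1.0
        _dna, rna, truth = simulate.simulate_reads(c, dna_depth=1.0, rna_depth=30.0, seed=7)
        counts = {ga: 0, gb: 0}
        for sample, pairs in rna.items():
            for p in pairs:
                gid = truth.read_origin[p.id][5]
                if gid in counts:
                    counts[gid] += 1
        la, lb = len_of(c, ga), len_of(c, gb)
        ratio = (counts[ga] / la) / (counts[gb] / lb)
        assert 3.5 < ratio < 4.5

    def test_same_seed_identical_fastq(self, site_order, tmp_path):
        from metamerge import io

        config = small_config(seed=2)
        outs = []
        for rep in range(2):
            _c, _s, dna, _r, _t = simulate.simulate_community(config)
            p1 = tmp_path / f"r{rep}_R1.fastq"
            p2 = tmp_path / f"r{rep}_R2.fastq"
            io.write_fastq_pairs(dna[("ind2", "feces")], p1, p2)
            outs.append(p1.read_bytes() + p2.read_bytes())
        assert outs[0] == outs[1]

    def test_error_rate_introduces_mismatches(self, site_order):
        config = small_config(error_rate=0.02)
        community, _sets, dna, _rna, truth = simulate.simulate_community(config)
        genomes = dict(community.genomes)
        mism = total = 0
        for pair in dna[("ind1", "cecum")][:200]:
            _k, _s, sp, off, strand, _g = truth.read_origin[pair.id]
            fwd = pair.seq1 if strand == "+" else pair.seq2
            ref = genomes[sp].sequence[off : off + len(fwd)]
            mism += sum(a != b for a, b in zip(ref, fwd))
            total += len(fwd)
        assert 0.01 < mism / total < 0.03


def len_of(c, gid):
    return next(len(g) for g in c.genes if g.gene_id == gid)
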