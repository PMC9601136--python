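"""Synthetic multi-site, multi-individual microbial communities.

The generator emulates the statistical structure the downstream analysis
assumes: several bacterial genomes with non-overlapping ORF-valid genes;
per-species abundance gradients over an ordered site chain within each
individual; per-gene expression with designed covariant pairs that share a
latent site profile (and a reaction label); per-site genome fragmentations
whose fragments overlap across sites by at least the merge length cutoff;
and paired-end DNA/mRNA reads with configurable substitution error.  All
outputs are pure functions of (parameters, seed), and full truth tables
(read origins, scaffold intervals, expression, covariant pairs) are kept.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .types import (
    AnnotationRecord,
    GeneFeature,
    ParameterError,
    PipelineConfig,
    ReadPair,
    SeqRecord,
    revcomp,
)

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
STOPS = ("TAA", "TAG", "TGA")
NONSTOP_CODONS = [
    "".join(c) for c in itertools.product("ACGT", repeat=3) if "".join(c) not in STOPS
]


@dataclass
class SyntheticCommunity:
    genomes: list[tuple[str, SeqRecord]]
    genes: list[GeneFeature]  # scaffold_id == genome record id == species id
    annotations: dict[str, AnnotationRecord]
    covariant_pairs: list[tuple[str, str]] = field(default_factory=list)
    samples: list[tuple[str, str]] = field(default_factory=list)
    abundance: pd.DataFrame | None = None  # species x samples
    expression: pd.DataFrame | None = None  # gene x samples
    # (individual, site) -> list of (species, start, end, scaffold_id)
    fragmentation: dict[tuple[str, str], list[tuple[str, int, int, str]]] = field(
        default_factory=dict
    )

    def genome_of(self, species: str) -> str:
        for sp, rec in self.genomes:
            if sp == species:
                return rec.sequence
        raise KeyError(species)

    def genes_of(self, species: str) -> list[GeneFeature]:
        return [g for g in self.genes if g.scaffold_id == species]

    def gene_sequence(self, gene: GeneFeature) -> str:
        seq = self.genome_of(gene.scaffold_id)[gene.start : gene.end]
        return seq if gene.strand == "+" else revcomp(seq)


@dataclass
class TruthTables:
    # read id -> (kind 'dna'|'rna', sample, species, fragment start, strand, gene_id|None)
    read_origin: dict[str, tuple[str, tuple[str, str], str, int, str, str | None]]
    # (individual, site, scaffold_id) -> (species, genome start, genome end)
    scaffold_intervals: dict[tuple[str, str, str], tuple[str, int, int]]
    expression: pd.DataFrame
    covariant_pairs: list[tuple[str, str]]


# ---------------------------------------------------------------------------
# genomes and genes


def _random_intergenic(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return bytes(BASES[rng.choice(4, size=n, p=p)]).decode()


def _random_orf(rng: np.random.Generator, length_nt: int) -> str:
    """ATG, (length/3 - 2) sense codons, one stop; no internal stop."""
    assert length_nt % 3 == 0 and length_nt >= 9
    n_internal = length_nt // 3 - 2
    body = "".join(
        NONSTOP_CODONS[i] for i in rng.integers(0, len(NONSTOP_CODONS), n_internal)
    )
    stop = STOPS[rng.integers(0, 3)]
    return "ATG" + body + stop


def simulate_genomes(
    n_species: int,
    length_range: tuple[int, int],
    gc: float = 0.45,
    gene_density: float = 1 / 2500.0,
    seed: int = 0,
) -> SyntheticCommunity:
    """Genomes with non-overlapping, ORF-valid genes on both strands.

    Gene lengths are multiples of 3 in [300, 3000] nt; each gene starts with
    ATG, ends with a stop, and has no internal in-frame stop.  A
    ``gene_density`` that requests more gene bp than the genome can hold
    raises :class:`ParameterError`.
    """
    if n_species < 1:
        raise ParameterError("need at least one species")
    if length_range[0] < 10_000:
        raise ParameterError("genome lengths must be >= 10 kb")
    rng = np.random.default_rng(seed)
    genomes: list[tuple[str, SeqRecord]] = []
    genes: list[GeneFeature] = []
    annotations: dict[str, AnnotationRecord] = {}
    label_counter = 1
    for si in range(n_species):
        species = f"sp{si + 1:02d}"
        glen = int(rng.integers(length_range[0], length_range[1] + 1))
        n_genes = int(round(glen * gene_density))
        lengths = 3 * rng.integers(100, 1001, size=n_genes)
        if lengths.sum() > 0.9 * glen:
            raise ParameterError(
                f"gene density {gene_density} infeasible for genome of {glen} bp"
            )
        # distribute the non-gene bp into n_genes+1 gaps
        free = glen - int(lengths.sum())
        cuts = np.sort(rng.integers(0, free + 1, size=n_genes))
        gaps = np.diff(np.concatenate([[0], cuts, [free]]))
        parts: list[str] = []
        pos = 0
        for gi in range(n_genes):
            parts.append(_random_intergenic(rng, int(gaps[gi]), gc))
            pos += int(gaps[gi])
            orf = _random_orf(rng, int(lengths[gi]))
            strand = "+" if rng.random() < 0.5 else "-"
            parts.append(orf if strand == "+" else revcomp(orf))
            gene_id = f"{species}_g{gi + 1:04d}"
            genes.append(
                GeneFeature(
                    gene_id=gene_id,
                    scaffold_id=species,
                    start=pos,
                    end=pos + int(lengths[gi]),
                    strand=strand,
                )
            )
            annotations[gene_id] = AnnotationRecord(
                gene_id=gene_id,
                ko=f"K{label_counter:05d}",
                cog=f"COG{label_counter:04d}",
                reactions=frozenset({f"R{label_counter:05d}"}),
            )
            label_counter += 1
            pos += int(lengths[gi])
        parts.append(_random_intergenic(rng, int(gaps[-1]), gc))
        sequence = "".join(parts)
        assert len(sequence) == glen
        genomes.append((species, SeqRecord(id=species, sequence=sequence)))
    return SyntheticCommunity(genomes=genomes, genes=genes, annotations=annotations)


def gene_panel(n_genes: int) -> SyntheticCommunity:
    """A sequence-free community skeleton: genes and annotations only.

    Useful for expression-level studies (covariation power/calibration)
    where genome sequences are irrelevant.
    """
    annotations = {
        f"g{i + 1:05d}": AnnotationRecord(
            gene_id=f"g{i + 1:05d}",
            ko=f"K{i + 1:05d}",
            cog=f"COG{i + 1:04d}",
            reactions=frozenset({f"R{i + 1:05d}"}),
        )
        for i in range(n_genes)
    }
    return SyntheticCommunity(genomes=[], genes=[], annotations=annotations)


def designate_unknown(
    community: SyntheticCommunity, fraction: float = 0.30, seed: int = 0
) -> None:
    """Strip KO/COG labels from a fraction of genes.

    The hidden reaction labels are retained so label transfer can be scored
    against truth.  When covariant pairs have been designated, the pair
    composition is stratified so a small community still yields both
    known-known benchmark positives and known-unknown transfer truth:
    pair categories (both known / one unknown / both unknown) follow the
    binomial proportions but with at least two known-known and, where the
    pair count allows, one known-unknown pair.
    """
    rng = np.random.default_rng(seed)
    gene_ids = sorted(community.annotations)
    budget = int(round(fraction * len(gene_ids)))
    unknown: set[str] = set()
    pairs = list(community.covariant_pairs)
    if pairs and fraction > 0:
        n_p = len(pairs)
        n_kk = max(min(2, n_p), int(round(n_p * (1 - fraction) ** 2)))
        n_ku = max(1 if n_p - n_kk >= 1 else 0, int(round(n_p * 2 * fraction * (1 - fraction))))
        n_ku = min(n_ku, n_p - n_kk)
        order = rng.permutation(n_p)
        for idx in order[n_kk : n_kk + n_ku]:
            a, b = pairs[idx]
            unknown.add((a, b)[int(rng.integers(0, 2))])
        for idx in order[n_kk + n_ku :]:
            unknown.update(pairs[idx])
    in_pair = {g for p in pairs for g in p}
    free = [g for g in gene_ids if g not in in_pair]
    remaining = max(0, budget - len(unknown))
    if free and remaining:
        chosen = rng.choice(len(free), size=min(remaining, len(free)), replace=False)
        unknown.update(free[i] for i in chosen)
    for g in unknown:
        a = community.annotations[g]
        a.ko = None
        a.cog = None


# ---------------------------------------------------------------------------
# abundance and expression


def _site_basis(n_sites: int) -> np.ndarray:
    """Orthonormal linear + quadratic contrasts over the ordered site chain."""
    t = np.linspace(0.0, 1.0, n_sites)
    z1 = t - t.mean()
    z1 /= np.linalg.norm(z1)
    z2 = (t - 0.5) ** 2
    z2 -= z2.mean()
    z2 -= (z2 @ z1) * z1
    nrm = np.linalg.norm(z2)
    if nrm > 0:
        z2 /= nrm
    return np.vstack([z1, z2])


def assign_abundance(
    community: SyntheticCommunity,
    site_order: dict[str, tuple[str, ...]],
    gradient_sd: float = 0.8,
    seed: int = 0,
) -> None:
    """Per-species log-normal abundance with a smooth per-site gradient."""
    rng = np.random.default_rng(seed)
    samples = [(ind, s) for ind in sorted(site_order) for s in site_order[ind]]
    rows = []
    species = [sp for sp, _ in community.genomes]
    for sp in species:
        base = rng.normal(0.0, 0.5)
        slope = rng.normal(0.0, gradient_sd)
        vals = []
        for ind in sorted(site_order):
            sites = site_order[ind]
            t = np.linspace(0.0, 1.0, len(sites))
            ind_off = rng.normal(0.0, 0.2)
            vals.extend(np.exp(base + ind_off + slope * (t - 0.5)))
        rows.append(vals)
    community.samples = samples
    community.abundance = pd.DataFrame(
        rows, index=species, columns=pd.MultiIndex.from_tuples(samples)
    )


def assign_expression(
    community: SyntheticCommunity,
    site_order: dict[str, tuple[str, ...]],
    n_covariant_pairs: int = 20,
    effect_size: float = 2.0,
    noise_sd: float = 0.25,
    seed: int = 0,
    individual_sd_frac: float = 0.3,
) -> None:
    """Expression truth with designed covariant pairs.

    Each covariant pair shares a latent site profile — a per-individual mean
    activity plus smooth linear/quadratic gradients over the ordered site
    chain, common to both genes and across individuals up to
    individual-level coefficient noise — so spatial *shape* is shared while
    per-gene magnitudes differ.  Non-covariant genes draw independent,
    spatially unstructured profiles (i.i.d. per sample) of matching scale:
    functional covariation is spatially coherent, background variation is
    not, which is the premise the L statistic exploits.  Expression =
    exp(baseline + latent + Normal(0, noise_sd)).  The designed pair members
    get a shared reaction label added to their annotations.  With
    ``effect_size=0`` all profiles are pure noise and designed pairs are
    statistically indistinguishable from non-pairs.
    """
    rng = np.random.default_rng(seed)
    gene_ids = sorted(community.annotations)
    if 2 * n_covariant_pairs > len(gene_ids):
        raise ParameterError("not enough genes for the requested covariant pairs")
    perm = rng.permutation(len(gene_ids))
    pairs = [
        (gene_ids[perm[2 * i]], gene_ids[perm[2 * i + 1]])
        for i in range(n_covariant_pairs)
    ]
    group_of: dict[str, int] = {}
    for gi, (a, b) in enumerate(pairs):
        group_of[a] = gi
        group_of[b] = gi
        shared = f"RSHARED{gi + 1:04d}"
        for g in (a, b):
            ann = community.annotations[g]
            ann.reactions = ann.reactions | {shared}
    next_group = n_covariant_pairs
    for g in gene_ids:
        if g not in group_of:
            group_of[g] = next_group
            next_group += 1

    inds = sorted(site_order)
    samples = [(ind, s) for ind in inds for s in site_order[ind]]
    # Latent profile per group (shared by both genes of a covariant pair):
    # a per-individual mean activity plus linear/quadratic site gradients
    # (quadratic down-weighted so typical profiles are smooth over the
    # chain), with individual-level coefficient noise.
    coef = rng.normal(0.0, 1.0, size=(next_group, 2)) * np.array(
        [effect_size, 0.4 * effect_size]
    )
    ind_coef = {
        ind: rng.normal(0.0, individual_sd_frac * effect_size, size=(next_group, 2))
        for ind in inds
    }
    # Per-group individual activity levels: a random permutation of
    # equispaced levels scaled by effect_size, plus jitter — effect_size is
    # the guaranteed between-individual contrast of a covariant group.
    levels = (
        np.linspace(-1.0, 1.0, len(inds)) if len(inds) > 1 else np.zeros(1)
    )
    ind_mean = {ind: np.empty(next_group) for ind in inds}
    for gi in range(next_group):
        perm = rng.permutation(len(inds))
        for k, ind in enumerate(inds):
            ind_mean[ind][gi] = effect_size * levels[perm[k]] + rng.normal(
                0.0, 0.2 * effect_size
            )
    baseline = rng.normal(0.0, 1.0, size=len(gene_ids))
    in_pair = {g for p in pairs for g in p}
    rows = np.empty((len(gene_ids), len(samples)))
    col = 0
    for ind in inds:
        sites = site_order[ind]
        basis = _site_basis(len(sites))  # 2 x n_sites
        latent = (coef + ind_coef[ind]) @ basis + ind_mean[ind][:, None]
        for si in range(len(sites)):
            for gi, g in enumerate(gene_ids):
                rows[gi, col] = latent[group_of[g], si]
            col += 1
    # non-covariant genes: spatially unstructured latents of matching scale
    solo = [gi for gi, g in enumerate(gene_ids) if g not in in_pair]
    if solo:
        rows[solo, :] = rng.normal(0.0, effect_size, size=(len(solo), len(samples)))
    noise = rng.normal(0.0, noise_sd, size=rows.shape) if noise_sd > 0 else 0.0
    values = np.exp(baseline[:, None] + rows + noise)
    community.samples = samples
    community.expression = pd.DataFrame(
        values, index=gene_ids, columns=pd.MultiIndex.from_tuples(samples)
    )
    community.covariant_pairs = pairs


# ---------------------------------------------------------------------------
# fragmentation


def fragment_per_site(
    community: SyntheticCommunity,
    sites: tuple[str, ...],
    individual: str = "ind1",
    min_frag: int = 6000,
    overlap_range: tuple[int, int] = (1500, 2500),
    mL: int = 1000,
    seed: int = 0,
) -> dict[str, list[SeqRecord]]:
    """Cut each genome into per-site fragments with designed cross-site overlaps.

    Each genome is chopped into consecutive chunks of ~[min_frag, 2*min_frag)
    bp; chunk *i* is given to sites ``i % S`` and ``(i+1) % S`` and extended
    rightward by an overlap drawn from ``overlap_range``, so consecutive
    chunks — and hence the union of any two sites — tile the genome with
    pairwise overlaps of at least ``mL``.  Fragments shorter than 1,000 bp
    are discarded.
    """
    if min_frag < 1000:
        raise ParameterError("min_frag must be >= 1000 bp")
    if overlap_range[0] < mL:
        raise ParameterError(f"overlap lower bound {overlap_range[0]} < mL {mL}")
    rng = np.random.default_rng(seed)
    n_sites = len(sites)
    out: dict[str, list[SeqRecord]] = {s: [] for s in sites}
    counter = {s: 0 for s in sites}
    for species, rec in community.genomes:
        glen = len(rec.sequence)
        # chunk boundaries
        bounds = [0]
        while glen - bounds[-1] > 3 * min_frag:
            bounds.append(bounds[-1] + int(rng.integers(min_frag, 2 * min_frag)))
        bounds.append(glen)  # last chunk length in (min_frag, 3*min_frag]
        n_chunks = len(bounds) - 1
        # chunk i belongs to sites i%S and (i+1)%S (just i%S for 2 sites);
        # consecutive same-site chunks coalesce into one fragment, so
        # fragments are disjoint within a site but overlap across sites
        chunk_sites: list[set[int]] = []
        for ci in range(n_chunks):
            if n_sites == 2:
                chunk_sites.append({ci % 2})
            else:
                chunk_sites.append({ci % n_sites, (ci + 1) % n_sites})
        for s_idx, site in enumerate(sites):
            runs: list[list[int]] = []
            for ci in range(n_chunks):
                if s_idx not in chunk_sites[ci]:
                    continue
                if runs and runs[-1][-1] == ci - 1:
                    runs[-1].append(ci)
                else:
                    runs.append([ci])
            for run in runs:
                start = bounds[run[0]]
                end = bounds[run[-1] + 1]
                if run[-1] + 1 < n_chunks:
                    end = min(glen, end + int(rng.integers(*overlap_range)))
                if end - start < 1000:
                    continue
                counter[site] += 1
                sid = f"{site}_{species}_c{counter[site]:03d}"
                out[site].append(
                    SeqRecord(
                        id=sid,
                        sequence=rec.sequence[start:end],
                        description=f"species={species} site={site} "
                        f"individual={individual} start={start} end={end}",
                    )
                )
                community.fragmentation.setdefault((individual, site), []).append(
                    (species, start, end, sid)
                )
    return out


# ---------------------------------------------------------------------------
# reads


def _mutate(rng: np.random.Generator, seq: str, error_rate: float) -> str:
    if error_rate <= 0:
        return seq
    n = len(seq)
    k = rng.binomial(n, error_rate)
    if k == 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    pos = rng.choice(n, size=k, replace=False)
    shift = rng.integers(1, 4, size=k)
    lut = {65: 0, 67: 1, 71: 2, 84: 3, 78: 0}
    for p, s in zip(pos, shift):
        arr[p] = BASES[(lut[arr[p]] + s) % 4]
    return bytes(arr).decode()


def _emit_pair(
    rng: np.random.Generator,
    template: str,
    offset: int,
    frag: int,
    read_len: int,
    error_rate: float,
    rid: str,
) -> tuple[ReadPair, str]:
    """One FR pair from template[offset:offset+frag]; returns (pair, strand)."""
    rl = min(read_len, frag)
    fwd = template[offset : offset + rl]
    rev = revcomp(template[offset + frag - rl : offset + frag])
    if rng.random() < 0.5:
        s1, s2, strand = fwd, rev, "+"
    else:
        s1, s2, strand = rev, fwd, "-"
    s1 = _mutate(rng, s1, error_rate)
    s2 = _mutate(rng, s2, error_rate)
    return (
        ReadPair(id=rid, seq1=s1, seq2=s2, qual1="I" * len(s1), qual2="I" * len(s2)),
        strand,
    )


def simulate_reads(
    community: SyntheticCommunity,
    dna_depth: float = 3.0,
    rna_depth: float = 3.0,
    read_len: int = 150,
    fragment_mean: int = 400,
    error_rate: float = 0.0,
    seed: int = 0,
) -> tuple[
    dict[tuple[str, str], list[ReadPair]],
    dict[tuple[str, str], list[ReadPair]],
    TruthTables,
]:
    """Paired-end DNA and mRNA reads per sample, with truth tables.

    DNA pairs are drawn uniformly within each genome at a per-species depth
    proportional to abundance (mean depth = ``dna_depth``); mRNA pairs are
    drawn within gene bodies at a rate proportional to abundance x
    expression (mean per-gene depth = ``rna_depth``).  Substitution errors
    are i.i.d. at ``error_rate``; qualities are constant Q40.
    """
    if dna_depth <= 0 or rna_depth <= 0:
        raise ParameterError("depths must be positive")
    if community.abundance is None or community.expression is None:
        raise ParameterError("assign abundance and expression first")
    rng = np.random.default_rng(seed)
    dna: dict[tuple[str, str], list[ReadPair]] = {}
    rna: dict[tuple[str, str], list[ReadPair]] = {}
    origin: dict[str, tuple] = {}
    species_list = [sp for sp, _ in community.genomes]
    genomes = dict(community.genomes)
    frag_sd = 0.1 * fragment_mean

    for sample in community.samples:
        ind, site = sample
        label = f"{ind}-{site}"
        dna_pairs: list[ReadPair] = []
        rna_pairs: list[ReadPair] = []
        ab = community.abundance[sample]
        rel = ab / ab.mean()
        ridx = 0
        for sp in species_list:
            genome = genomes[sp].sequence
            glen = len(genome)
            depth = dna_depth * float(rel[sp])
            n_pairs = int(round(depth * glen / (2 * read_len)))
            for _ in range(n_pairs):
                frag = int(np.clip(round(rng.normal(fragment_mean, frag_sd)), read_len, min(2000, glen)))
                off = int(rng.integers(0, glen - frag + 1))
                rid = f"{label}_dna_{ridx:07d}"
                ridx += 1
                pair, strand = _emit_pair(
                    rng, genome, off, frag, read_len, error_rate, rid
                )
                dna_pairs.append(pair)
                origin[rid] = ("dna", sample, sp, off, strand, None)
        expr = community.expression[sample]
        weights = {}
        for gene in community.genes:
            weights[gene.gene_id] = float(rel[gene.scaffold_id] * expr[gene.gene_id])
        mean_w = np.mean(list(weights.values()))
        ridx = 0
        for gene in community.genes:
            genome = genomes[gene.scaffold_id].sequence
            gene_len = len(gene)
            depth = rna_depth * weights[gene.gene_id] / mean_w
            n_pairs = int(round(depth * gene_len / (2 * read_len)))
            for _ in range(n_pairs):
                frag = int(
                    np.clip(
                        round(rng.normal(fragment_mean, frag_sd)),
                        min(read_len, gene_len),
                        gene_len,
                    )
                )
                off = gene.start + int(rng.integers(0, gene_len - frag + 1))
                rid = f"{label}_rna_{ridx:07d}"
                ridx += 1
                pair, strand = _emit_pair(
                    rng, genome, off, frag, read_len, error_rate, rid
                )
                rna_pairs.append(pair)
                origin[rid] = ("rna", sample, gene.scaffold_id, off, strand, gene.gene_id)
        dna[sample] = dna_pairs
        rna[sample] = rna_pairs

    scaffold_intervals = {
        (ind, site, sid): (sp, start, end)
        for (ind, site), entries in community.fragmentation.items()
        for (sp, start, end, sid) in entries
    }
    truth = TruthTables(
        read_origin=origin,
        scaffold_intervals=scaffold_intervals,
        expression=community.expression,
        covariant_pairs=list(community.covariant_pairs),
    )
    return dna, rna, truth


# ---------------------------------------------------------------------------
# orchestration


def simulate_community(config: PipelineConfig):
    """Build a full synthetic study: genomes, truth, per-site scaffolds, reads.

    Returns ``(community, scaffold_sets, dna_reads, rna_reads, truth)`` where
    ``scaffold_sets`` maps (individual, site) to its scaffold records.
    Deterministic given ``config.simulation.seed``.
    """
    p = config.simulation
    community = simulate_genomes(
        p.n_species, p.length_range, p.gc, p.gene_density, seed=p.seed
    )
    assign_abundance(community, config.site_order, seed=p.seed + 2)
    assign_expression(
        community,
        config.site_order,
        n_covariant_pairs=p.n_covariant_pairs,
        effect_size=p.effect_size,
        noise_sd=p.noise_sd,
        seed=p.seed + 3,
    )
    # after expression so the covariant-pair composition can be stratified
    designate_unknown(community, p.unknown_fraction, seed=p.seed + 1)
    scaffold_sets: dict[tuple[str, str], list[SeqRecord]] = {}
    for k, ind in enumerate(sorted(config.site_order)):
        sets = fragment_per_site(
            community,
            config.site_order[ind],
            individual=ind,
            min_frag=p.min_frag,
            overlap_range=p.overlap_range,
            mL=config.merge.mL,
            seed=p.seed + 10 + k,
        )
        for site, recs in sets.items():
            scaffold_sets[(ind, site)] = recs
    dna, rna, truth = simulate_reads(
        community,
        dna_depth=p.dna_depth,
        rna_depth=p.rna_depth,
        read_len=p.read_len,
        fragment_mean=p.fragment_mean,
        error_rate=p.error_rate,
        seed=p.seed + 20,
    )
    return community, scaffold_sets, dna, rna, truth
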