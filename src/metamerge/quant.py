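"""Read mapping, per-gene counting, and expression quantification.

Two expression layers are produced: whole-community expression (TPM of
mRNA counts) and per-cell expression (mRNA reads-per-kilobase divided by
the gene's mean DNA depth, which cancels species abundance and so
approximates expression per bacterium).  The mapper is a deterministic
k-mer seed / gapless-extend stand-in for a production short-read aligner;
externally produced SAM is accepted interchangeably.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .types import (
    AlignmentRecord,
    AnnotationRecord,
    GeneFeature,
    MapperParams,
    ParameterError,
    ReadPair,
    SeqRecord,
)


# ---------------------------------------------------------------------------
# mapping


class ReadMapper:
    """Exact k-mer seeded, gapless, unique-best-hit read mapper."""

    def __init__(self, reference: list[SeqRecord], params: MapperParams | None = None):
        if not reference:
            raise ParameterError("reference is empty")
        self.params = params or MapperParams()
        self.names = [r.id for r in reference]
        self.arrays = {
            r.id: np.frombuffer(r.sequence.encode(), dtype=np.uint8)
            for r in reference
        }
        k = self.params.k
        index: dict[str, list[tuple[str, int]]] = {}
        for r in reference:
            seq = r.sequence
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" not in kmer:
                    index.setdefault(kmer, []).append((r.id, i))
        self.index = index

    def _map_single(self, seq: str) -> tuple[str, int, str, int] | None:
        """Best unique locus for one mate: (target, start, strand, mismatches)."""
        from .types import revcomp

        k = self.params.k
        n = len(seq)
        if n < k:
            return None
        max_mm = int(self.params.max_mismatch_rate * n)
        candidates: set[tuple[str, int, str]] = set()
        for strand, s in (("+", seq), ("-", revcomp(seq))):
            # disjoint seeds guarantee a clean k-mer for reads with up to
            # (number of seeds - 1) substitutions (pigeonhole)
            offsets = set(range(0, n - k + 1, k)) | {n - k}
            for off in offsets:
                for name, pos in self.index.get(s[off : off + k], ()):
                    start = pos - off
                    if start >= 0 and start + n <= len(self.arrays[name]):
                        candidates.add((name, start, strand))
        if not candidates:
            return None
        best: tuple[str, int, str] | None = None
        best_mm = max_mm + 1
        tie = False
        qarr = {
            "+": np.frombuffer(seq.encode(), dtype=np.uint8),
            "-": np.frombuffer(revcomp(seq).encode(), dtype=np.uint8),
        }
        for name, start, strand in sorted(candidates):
            mm = int(
                np.count_nonzero(self.arrays[name][start : start + n] != qarr[strand])
            )
            if mm < best_mm:
                best, best_mm, tie = (name, start, strand), mm, False
            elif mm == best_mm and best is not None and (name, start) != best[:2]:
                tie = True
        if best is None or tie or best_mm > max_mm:
            return None
        return (*best, best_mm)

    def map_pair(self, pair: ReadPair) -> tuple[AlignmentRecord, AlignmentRecord]:
        hits = [self._map_single(pair.seq1), self._map_single(pair.seq2)]
        seqs = [pair.seq1, pair.seq2]
        quals = [pair.qual1, pair.qual2]
        proper = False
        frag = 0
        if hits[0] and hits[1]:
            (t1, s1, st1, _), (t2, s2, st2, _) = hits
            if t1 == t2 and st1 != st2:
                lo = min(s1, s2)
                hi = max(s1 + len(pair.seq1), s2 + len(pair.seq2))
                if hi - lo <= self.params.max_fragment_len:
                    proper = True
                    frag = hi - lo
        records = []
        for i, hit in enumerate(hits):
            if hit is None:
                records.append(
                    AlignmentRecord(
                        query_id=pair.id,
                        target_id=None,
                        target_start=0,
                        strand="+",
                        cigar="",
                        mapq=0,
                        is_mate1=(i == 0),
                        properly_paired=False,
                        fragment_len=0,
                        seq=seqs[i],
                        qual=quals[i],
                    )
                )
            else:
                name, start, strand, _mm = hit
                sign = 1 if (proper and start == min(h[1] for h in hits if h)) else -1
                records.append(
                    AlignmentRecord(
                        query_id=pair.id,
                        target_id=name,
                        target_start=start,
                        strand=strand,
                        cigar=f"{len(seqs[i])}M",
                        mapq=60,
                        is_mate1=(i == 0),
                        properly_paired=proper,
                        fragment_len=sign * frag if proper else 0,
                        seq=seqs[i],
                        qual=quals[i],
                    )
                )
        return records[0], records[1]


def map_reads(
    reference: list[SeqRecord],
    read_pairs: list[ReadPair],
    params: MapperParams | None = None,
    mapper: ReadMapper | None = None,
) -> list[AlignmentRecord]:
    """Map pairs against the reference; two records (one per mate) per pair."""
    mapper = mapper or ReadMapper(reference, params)
    out: list[AlignmentRecord] = []
    for pair in read_pairs:
        out.extend(mapper.map_pair(pair))
    return out


# ---------------------------------------------------------------------------
# counting (union mode)


def _feature_trees(features: list[GeneFeature]) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for f in features:
        trees.setdefault(f.scaffold_id, IntervalTree()).addi(f.start, f.end, f.gene_id)
    return trees


def count_reads(
    alignments: list[AlignmentRecord],
    features: list[GeneFeature],
    mode: str = "union",
) -> pd.Series:
    """Union-mode fragment counting.

    A read pair is assigned to gene *g* iff the union of genes overlapped by
    either mapped mate equals {g}; pairs overlapping no gene (``no_feature``)
    or several distinct genes (``ambiguous``) are uncounted.  Strand-agnostic.
    """
    if mode != "union":
        raise ParameterError(f"unsupported count mode {mode!r}")
    trees = _feature_trees(features)
    known_scaffolds = {f.scaffold_id for f in features}
    counts = {f.gene_id: 0 for f in features}
    by_query: dict[str, set[str]] = {}
    mapped_any: set[str] = set()
    for aln in alignments:
        if not aln.mapped:
            continue
        if aln.target_id not in known_scaffolds and aln.target_id not in trees:
            raise ParameterError(f"alignment to unknown scaffold {aln.target_id!r}")
        mapped_any.add(aln.query_id)
        tree = trees.get(aln.target_id)
        if tree is None:
            continue
        genes = {iv.data for iv in tree.overlap(aln.target_start, aln.target_end)}
        by_query.setdefault(aln.query_id, set()).update(genes)
    for _q, genes in by_query.items():
        if len(genes) == 1:
            counts[next(iter(genes))] += 1
    return pd.Series(counts, dtype=float).sort_index()


# ---------------------------------------------------------------------------
# normalisation


def compute_tpm(counts: pd.Series, lengths_bp: pd.Series) -> pd.Series:
    """Transcripts per million: rate_g = c_g / l_g(kb), scaled to sum 1e6."""
    if (counts < 0).any():
        raise ParameterError("negative counts")
    if (lengths_bp <= 0).any():
        raise ParameterError("gene lengths must be positive")
    rate = counts / (lengths_bp / 1000.0)
    total = rate.sum()
    if total == 0:
        return rate * 0.0  # all-zero sample, flagged by being all zero
    return 1e6 * rate / total


def compute_depth(
    dna_alignments: list[AlignmentRecord], features: list[GeneFeature]
) -> pd.Series:
    """Mean per-base DNA depth per gene: aligned bases overlapping / length."""
    trees = _feature_trees(features)
    lengths = {f.gene_id: len(f) for f in features}
    acc = {f.gene_id: 0.0 for f in features}
    for aln in dna_alignments:
        if not aln.mapped or not aln.properly_paired:
            continue
        tree = trees.get(aln.target_id)
        if tree is None:
            continue
        for iv in tree.overlap(aln.target_start, aln.target_end):
            ov = min(aln.target_end, iv.end) - max(aln.target_start, iv.begin)
            acc[iv.data] += ov
    return pd.Series(
        {g: acc[g] / lengths[g] for g in acc}, dtype=float
    ).sort_index()


def compute_per_cell(
    counts: pd.Series,
    lengths_bp: pd.Series,
    depth: pd.Series,
    pseudodepth: float = 0.0,
) -> pd.Series:
    """Per-cell expression: (c_g / l_g(kb)) / (d_g + pseudodepth).

    Genes with zero effective depth are masked (NaN), not zero: without DNA
    evidence the per-bacterium rate is undefined.
    """
    rate = counts / (lengths_bp / 1000.0)
    denom = depth + pseudodepth
    out = rate / denom.where(denom > 0)
    return out


@dataclass
class ExpressionMatrix:
    """Gene x sample expression with count/tpm/per_cell/depth layers."""

    counts: pd.DataFrame
    tpm: pd.DataFrame
    per_cell: pd.DataFrame
    depth: pd.DataFrame
    lengths_bp: pd.Series

    @property
    def samples(self) -> list[tuple[str, str]]:
        return list(self.counts.columns)


def build_expression_matrix(
    per_sample_counts: dict[tuple[str, str], pd.Series],
    per_sample_depth: dict[tuple[str, str], pd.Series],
    lengths_bp: pd.Series,
    pseudodepth: float = 0.0,
) -> ExpressionMatrix:
    samples = sorted(per_sample_counts)
    counts = pd.DataFrame({s: per_sample_counts[s] for s in samples})
    counts.columns = pd.MultiIndex.from_tuples(samples)
    depth = pd.DataFrame({s: per_sample_depth[s] for s in samples})
    depth.columns = pd.MultiIndex.from_tuples(samples)
    tpm = counts.apply(lambda col: compute_tpm(col, lengths_bp))
    per_cell = pd.DataFrame(
        {
            s: compute_per_cell(counts[s], lengths_bp, depth[s], pseudodepth)
            for s in samples
        }
    )
    per_cell.columns = pd.MultiIndex.from_tuples(samples)
    return ExpressionMatrix(
        counts=counts, tpm=tpm, per_cell=per_cell, depth=depth, lengths_bp=lengths_bp
    )


# ---------------------------------------------------------------------------
# KO aggregation and differential calls


@dataclass
class DifferentialCall:
    ko_id: str
    site_pair: tuple[str, str]
    log2_diff: dict[str, float]  # per individual
    significant: bool

    @property
    def max_abs_diff(self) -> float:
        return max(abs(v) for v in self.log2_diff.values())


def aggregate_by_ko(
    matrix: pd.DataFrame, annotations: dict[str, AnnotationRecord]
) -> pd.DataFrame:
    """Sum member-gene values per KO for one expression layer."""
    ko_of = {
        g: a.ko for g, a in annotations.items() if a.ko is not None
    }
    sub = matrix.loc[[g for g in matrix.index if g in ko_of]]
    return sub.groupby([ko_of[g] for g in sub.index]).sum()


def flag_differential(
    ko_matrix: pd.DataFrame, site_pair: tuple[str, str]
) -> list[DifferentialCall]:
    """Two-fold same-direction rule between a site pair across individuals.

    A KO is significant iff, in every individual sharing both sites, the
    log2 difference exceeds 1 in magnitude with the same sign.  A pseudocount
    of half the smallest positive value in the layer avoids infinities.
    Results are ranked by the maximum |log2 difference|.
    """
    a, b = site_pair
    inds = sorted(
        {
            ind
            for ind, site in ko_matrix.columns
            if site == a and (ind, b) in ko_matrix.columns
        }
    )
    if len(inds) < 2:
        raise ParameterError(f"fewer than 2 individuals share sites {site_pair}")
    positive = ko_matrix.values[ko_matrix.values > 0]
    eps = positive.min() / 2 if positive.size else 1.0
    calls = []
    for ko in ko_matrix.index:
        diffs = {}
        for ind in inds:
            va = ko_matrix.loc[ko, (ind, a)]
            vb = ko_matrix.loc[ko, (ind, b)]
            if np.isnan(va) or np.isnan(vb):
                continue
            diffs[ind] = float(np.log2((va + eps) / (vb + eps)))
        if len(diffs) < len(inds):
            continue  # site value missing for an individual: skipped
        vals = list(diffs.values())
        significant = all(abs(v) > 1 for v in vals) and (
            all(v > 0 for v in vals) or all(v < 0 for v in vals)
        )
        calls.append(
            DifferentialCall(
                ko_id=ko, site_pair=site_pair, log2_diff=diffs, significant=significant
            )
        )
    calls.sort(key=lambda c: (-c.max_abs_diff, c.ko_id))
    return calls
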