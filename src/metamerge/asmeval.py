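"""Assembly evaluation: N-statistics, chimera metrics, composite score.

Assemblies are graded against labeled truth genomes: generalized
N-statistics (N10..N100) measure contiguity; the chimera index (CI) and
nonchimeric rate measure whether scaffolds mix species; MAL/TAL measure
aligned completeness; and a composite performance metric (CPM) — this
package's own composite, monotone in contiguity, accuracy and completeness —
summarises them as N50_broken x (1 - CI) x (TAL / assembly bp), where
N50_broken is the N50 after splitting scaffolds at species-switch points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._align import Block, KmerIndex
from .merge import MergedReference
from .quant import ReadMapper
from .types import MapperParams, ParameterError, ReadPair, SeqRecord


# ---------------------------------------------------------------------------
# N-statistics


def n_statistics(lengths: list[int]) -> dict[int, int]:
    """Nx for x in 10..100: the scaffold length at which the descending
    cumulative sum first reaches x% of the total."""
    lens = sorted((int(x) for x in lengths), reverse=True)
    if not lens or lens[-1] <= 0:
        raise ParameterError("need at least one positive scaffold length")
    total = sum(lens)
    curve: dict[int, int] = {}
    cum = 0
    i = 0
    for x in range(10, 101, 10):
        need = x / 100.0 * total
        while cum < need:
            cum += lens[i]
            i += 1
        curve[x] = lens[i - 1]
    return curve


def n50(lengths: list[int]) -> int:
    return n_statistics(lengths)[50]


# ---------------------------------------------------------------------------
# alignment to truth


@dataclass
class LabeledAlignmentSet:
    """Per-scaffold alignment blocks against labeled truth genomes."""

    blocks: dict[str, list[Block]]  # scaffold id -> accepted blocks (species in ref_id)
    scaffold_lengths: dict[str, int]

    def species_of(self, scaffold_id: str) -> set[str]:
        return {b.ref_id for b in self.blocks.get(scaffold_id, [])}


def align_to_truth(
    assembly: list[SeqRecord],
    truth_genomes: list[SeqRecord],
    min_block: int = 1000,
    min_identity: float = 95.0,
    anchor_k: int = 21,
) -> LabeledAlignmentSet:
    """Anchored gapless blocks of each scaffold against the truth genomes.

    Overlapping blocks on a scaffold are resolved best-identity-first (then
    longest); a surviving block may overlap accepted ones by at most 100 bp.
    """
    index = KmerIndex({g.id: g.sequence for g in truth_genomes}, k=anchor_k)
    out: dict[str, list[Block]] = {}
    for rec in assembly:
        raw = [
            b
            for b in index.find_blocks(rec.sequence, min_len=min_block)
            if b.identity >= min_identity
        ]
        accepted: list[Block] = []
        for b in sorted(raw, key=lambda b: (-b.identity, -b.length, b.ref_id)):
            if all(
                min(b.q_end, a.q_end) - max(b.q_start, a.q_start) <= 100
                for a in accepted
            ):
                accepted.append(b)
        out[rec.id] = sorted(accepted, key=lambda b: b.q_start)
    return LabeledAlignmentSet(
        blocks=out, scaffold_lengths={r.id: len(r) for r in assembly}
    )


# ---------------------------------------------------------------------------
# chimera metrics


def chimera_index(aligned: LabeledAlignmentSet) -> float:
    """Length-weighted fraction of aligned scaffolds spanning >= 2 species."""
    total = chimeric = 0
    for sid, blocks in aligned.blocks.items():
        if not blocks:
            continue
        length = aligned.scaffold_lengths[sid]
        total += length
        if len({b.ref_id for b in blocks}) >= 2:
            chimeric += length
    if total == 0:
        raise ParameterError("chimera index undefined: no aligned scaffolds")
    return chimeric / total


def nonchimeric_rate(
    merged: MergedReference | None = None,
    species_of_source: dict[tuple[str, str], str] | None = None,
    aligned: LabeledAlignmentSet | None = None,
) -> float:
    """Percent of assembled length attributable to a single species.

    Uses merge provenance plus the simulator's species-of-origin labels when
    available; otherwise alignment labels against truth genomes.
    """
    if merged is not None and species_of_source is not None:
        total = clean = 0
        for rec in merged.scaffolds:
            segs = merged.provenance[rec.id]
            species = {
                species_of_source[(s.site, s.source_id)]
                for s in segs
                if (s.site, s.source_id) in species_of_source
            }
            if not species:
                raise ParameterError(f"no species label for scaffold {rec.id}")
            total += len(rec.sequence)
            if len(species) == 1:
                clean += len(rec.sequence)
        return 100.0 * clean / total
    if aligned is not None:
        total = clean = 0
        for sid, blocks in aligned.blocks.items():
            if not blocks:
                continue
            length = aligned.scaffold_lengths[sid]
            total += length
            if len({b.ref_id for b in blocks}) == 1:
                clean += length
        if total == 0:
            raise ParameterError("nonchimeric rate undefined: no aligned scaffolds")
        return 100.0 * clean / total
    raise ParameterError("need provenance labels or an alignment set")


# ---------------------------------------------------------------------------
# composite metric


@dataclass
class AssemblyEvaluation:
    n50: int
    nstats: dict[int, int]
    ci: float
    nonchimeric_rate: float
    mal: int
    tal: int
    cpm: float
    n50_broken: int = 0
    per_scaffold: dict[str, list[Block]] = field(default_factory=dict)


def _broken_lengths(aligned: LabeledAlignmentSet) -> list[int]:
    """Scaffold lengths after splitting at species-switch points."""
    out = []
    for sid, length in aligned.scaffold_lengths.items():
        blocks = aligned.blocks.get(sid, [])
        if len({b.ref_id for b in blocks}) < 2:
            out.append(length)
            continue
        pieces = []
        piece_start = 0
        prev = blocks[0]
        for b in blocks[1:]:
            if b.ref_id != prev.ref_id:
                cut = (prev.q_end + b.q_start) // 2
                pieces.append(cut - piece_start)
                piece_start = cut
            prev = b
        pieces.append(length - piece_start)
        out.extend(p for p in pieces if p > 0)
    return out


def composite_metric(
    assembly: list[SeqRecord], aligned: LabeledAlignmentSet
) -> AssemblyEvaluation:
    """Full evaluation: N-curve, CI, nonchimeric rate, MAL, TAL, CPM."""
    lengths = [len(r) for r in assembly]
    nstats = n_statistics(lengths)
    all_blocks = [b for blocks in aligned.blocks.values() for b in blocks]
    mal = max((b.length for b in all_blocks), default=0)
    tal = sum(b.length for b in all_blocks)
    ci = chimera_index(aligned)
    ncr = nonchimeric_rate(aligned=aligned)
    total_bp = sum(lengths)
    n50_broken = n50(_broken_lengths(aligned))
    cpm = n50_broken * (1.0 - ci) * (tal / total_bp)
    return AssemblyEvaluation(
        n50=nstats[50],
        nstats=nstats,
        ci=ci,
        nonchimeric_rate=ncr,
        mal=mal,
        tal=tal,
        cpm=cpm,
        n50_broken=n50_broken,
        per_scaffold=aligned.blocks,
    )


# ---------------------------------------------------------------------------
# mapping rate


def mapping_rate(
    read_pairs: list[ReadPair],
    reference: list[SeqRecord],
    params: MapperParams | None = None,
    mapper: ReadMapper | None = None,
) -> float:
    """Percent of read pairs with at least one mapped mate."""
    if not read_pairs:
        return 0.0
    mapper = mapper or ReadMapper(reference, params)
    mapped = 0
    for pair in read_pairs:
        a, b = mapper.map_pair(pair)
        if a.mapped or b.mapped:
            mapped += 1
    return 100.0 * mapped / len(read_pairs)


def curve_dominates(a: dict[int, int], b: dict[int, int]) -> bool:
    """Point-wise dominance of N-statistic curve a over b."""
    return all(a[x] >= b[x] for x in range(10, 101, 10))
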