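"""Gapless seed-and-extend alignment shared by the merger and the evaluator.

The pipeline's sequences differ only by substitutions (scaffolds from the
same community, simulated reads), so alignments live on exact diagonals:
anchors are shared k-mers, co-diagonal anchors are grouped, and each
diagonal's match profile is trimmed to the maximal block not interrupted by
a long mismatch run.  Indel-tolerant alignment is deliberately out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import revcomp

# A mismatch run of this length terminates a block: genuine overlaps at the
# identity levels the merger accepts (>= 90%) essentially never contain one,
# while unrelated sequence (75% mismatch) produces one almost immediately.
MAX_MISMATCH_RUN = 20


@dataclass
class Block:
    """One gapless alignment block between a reference and a query sequence.

    Coordinates are 0-based half-open in the *original* (forward) frame of
    both sequences; ``strand`` is '-' when the query aligns reverse
    complemented.
    """

    ref_id: str
    ref_start: int
    ref_end: int
    q_start: int
    q_end: int
    strand: str
    n_match: int

    @property
    def length(self) -> int:
        return self.ref_end - self.ref_start

    @property
    def identity(self) -> float:
        return 100.0 * self.n_match / self.length if self.length else 0.0


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode("ascii"), dtype=np.uint8)


class KmerIndex:
    """Exact k-mer index over a set of named reference sequences."""

    def __init__(self, sequences: dict[str, str], k: int = 21):
        self.k = k
        self.sequences = sequences
        self.arrays = {name: _encode(s) for name, s in sequences.items()}
        index: dict[str, list[tuple[str, int]]] = {}
        for name, seq in sequences.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if "N" in kmer:
                    continue
                index.setdefault(kmer, []).append((name, i))
        self.index = index

    def _diagonal_hits(
        self, query: str, stride: int
    ) -> dict[tuple[str, int], list[int]]:
        """Group query k-mer hits by (ref name, diagonal)."""
        k = self.k
        hits: dict[tuple[str, int], list[int]] = {}
        n = len(query) - k + 1
        positions = list(range(0, n, stride))
        if positions and positions[-1] != n - 1:
            positions.append(n - 1)
        for qpos in positions:
            kmer = query[qpos : qpos + k]
            for name, rpos in self.index.get(kmer, ()):
                hits.setdefault((name, rpos - qpos), []).append(qpos)
        return hits

    def _blocks_on_diagonal(
        self, name: str, diag: int, qarr: np.ndarray, seed_positions: list[int]
    ) -> list[Block]:
        """Trim the full diagonal intersection into well-matching blocks."""
        rarr = self.arrays[name]
        q_lo = max(0, -diag)
        q_hi = min(len(qarr), len(rarr) - diag)
        if q_hi - q_lo < self.k:
            return []
        match = rarr[q_lo + diag : q_hi + diag] == qarr[q_lo:q_hi]
        # split at mismatch runs >= MAX_MISMATCH_RUN
        mism = np.flatnonzero(~match)
        boundaries = [0]
        if mism.size:
            run_start = mism[0]
            prev = mism[0]
            for m in mism[1:]:
                if m == prev + 1:
                    prev = m
                else:
                    if prev - run_start + 1 >= MAX_MISMATCH_RUN:
                        boundaries.append((run_start, prev + 1))
                    run_start = prev = m
            if prev - run_start + 1 >= MAX_MISMATCH_RUN:
                boundaries.append((run_start, prev + 1))
        segments = []
        cursor = 0
        for b in boundaries[1:]:
            segments.append((cursor, b[0]))
            cursor = b[1]
        segments.append((cursor, q_hi - q_lo))
        seeds = set(seed_positions)
        blocks = []
        for s, e in segments:
            if e - s < self.k:
                continue
            # trim to the max-scoring run (+1 match / -3 mismatch): related
            # sequence scores positive, flanking junk (75% mismatch) negative
            seg = match[s:e]
            scores = np.where(seg, 1.0, -3.0)
            best = run_start = cur = 0
            s2 = e2 = 0
            cur_start = 0
            for i, v in enumerate(scores):
                cur += v
                if cur <= 0:
                    cur = 0.0
                    cur_start = i + 1
                elif cur > best:
                    best = cur
                    s2, e2 = s + cur_start, s + i + 1
            if best <= 0:
                continue
            # keep only blocks supported by at least one anchor
            if not any(s2 <= sp - q_lo < e2 for sp in seeds):
                continue
            n_match = int(match[s2:e2].sum())
            blocks.append(
                Block(
                    ref_id=name,
                    ref_start=q_lo + s2 + diag,
                    ref_end=q_lo + e2 + diag,
                    q_start=q_lo + s2,
                    q_end=q_lo + e2,
                    strand="+",
                    n_match=n_match,
                )
            )
        return blocks

    def find_blocks(
        self, query: str, min_len: int = 1, stride: int = 8, both_strands: bool = True
    ) -> list[Block]:
        """All gapless blocks of ``query`` against the index, both strands."""
        out: list[Block] = []
        frames = [("+", query)]
        if both_strands:
            frames.append(("-", revcomp(query)))
        qlen = len(query)
        for strand, qseq in frames:
            qarr = _encode(qseq)
            for (name, diag), seeds in self._diagonal_hits(qseq, stride).items():
                for blk in self._blocks_on_diagonal(name, diag, qarr, seeds):
                    if blk.length < min_len:
                        continue
                    if strand == "-":
                        # map query coords back to the forward frame
                        blk = Block(
                            ref_id=blk.ref_id,
                            ref_start=blk.ref_start,
                            ref_end=blk.ref_end,
                            q_start=qlen - blk.q_end,
                            q_end=qlen - blk.q_start,
                            strand="-",
                            n_match=blk.n_match,
                        )
                    out.append(blk)
        # dedupe identical spans found on overlapping seed sets
        seen = set()
        uniq = []
        for b in sorted(
            out, key=lambda b: (-b.length, -b.n_match, b.ref_id, b.ref_start)
        ):
            key = (b.ref_id, b.ref_start, b.ref_end, b.q_start, b.q_end, b.strand)
            if key not in seen:
                seen.add(key)
                uniq.append(b)
        return uniq
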