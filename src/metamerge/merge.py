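"""Cross-site scaffold merging into a single common reference metagenome.

Per-site assemblies of the same community fragment each genome differently;
scaffolds from different sites therefore overlap at their ends.  This module
detects those overlaps (shared-k-mer seeding, diagonal grouping, gapless
extension), accepts them greedily in a deterministic order (each scaffold
end used at most once, no cycles), splices chains keeping the reference-side
bases inside each overlap, drops contained scaffolds, and carries everything
else through unchanged.  Every merged base is traceable to exactly one input
scaffold base via the provenance tiling.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from ._align import KmerIndex
from .io import logger
from .types import MergeParams, ParameterError, SeqRecord, revcomp

MIN_SCAFFOLD_LEN = 1000  # contigs shorter than 1,000 bp are discarded
N_SPLIT_RUN = 10  # split scaffolds at runs of >= 10 N before overlap search


@dataclass(frozen=True)
class ProvSegment:
    """One source interval tiling part of a merged scaffold."""

    site: str
    source_id: str
    merged_start: int
    merged_end: int
    src_start: int
    src_end: int
    orientation: str  # '+' or '-'


@dataclass
class OverlapCandidate:
    ref_id: str
    query_id: str
    orientation: str  # 'same' or 'rc'
    ref_span: tuple[int, int]
    query_span: tuple[int, int]  # forward frame of the query
    aln_len: int
    identity: float
    junction: str  # 'ref_then_query', 'query_then_ref', 'containment'
    ref_overhang: int
    query_overhang: int


@dataclass
class MergedReference:
    scaffolds: list[SeqRecord]
    provenance: dict[str, list[ProvSegment]]
    # (site, scaffold_id) -> 'merged' | 'contained' | 'carried'
    accounting: dict[tuple[str, str], str] = field(default_factory=dict)

    def total_bp(self) -> int:
        return sum(len(s) for s in self.scaffolds)

    def validate(self) -> None:
        """Provenance must tile each scaffold exactly (internal consistency)."""
        for rec in self.scaffolds:
            segs = self.provenance[rec.id]
            pos = 0
            for s in segs:
                assert s.merged_start == pos, f"{rec.id}: provenance gap at {pos}"
                assert s.merged_end - s.merged_start == s.src_end - s.src_start
                pos = s.merged_end
            assert pos == len(rec.sequence), f"{rec.id}: provenance short at {pos}"


# ---------------------------------------------------------------------------
# working scaffolds with provenance arithmetic


@dataclass
class _Work:
    key: str  # unique working key
    id: str  # display id
    seq: str
    segs: list[ProvSegment]

    @classmethod
    def from_record(cls, key: str, site: str, rec: SeqRecord) -> _Work:
        seg = ProvSegment(site, rec.id, 0, len(rec.sequence), 0, len(rec.sequence), "+")
        return cls(key=key, id=rec.id, seq=rec.sequence, segs=[seg])

    def slice(self, a: int, b: int) -> _Work:
        segs = []
        for s in self.segs:
            lo, hi = max(s.merged_start, a), min(s.merged_end, b)
            if lo >= hi:
                continue
            dl, dr = lo - s.merged_start, s.merged_end - hi
            if s.orientation == "+":
                src = (s.src_start + dl, s.src_end - dr)
            else:
                src = (s.src_start + dr, s.src_end - dl)
            segs.append(
                ProvSegment(s.site, s.source_id, lo - a, hi - a, src[0], src[1], s.orientation)
            )
        return _Work(self.key, self.id, self.seq[a:b], segs)

    def revcomp(self) -> _Work:
        n = len(self.seq)
        segs = [
            ProvSegment(
                s.site,
                s.source_id,
                n - s.merged_end,
                n - s.merged_start,
                s.src_start,
                s.src_end,
                "-" if s.orientation == "+" else "+",
            )
            for s in reversed(self.segs)
        ]
        return _Work(self.key, self.id, revcomp(self.seq), segs)

    def concat(self, other: _Work) -> _Work:
        off = len(self.seq)
        segs = self.segs + [
            replace(s, merged_start=s.merged_start + off, merged_end=s.merged_end + off)
            for s in other.segs
        ]
        return _Work(self.key, self.id, self.seq + other.seq, segs)


def _prepare(
    records_or_ref: list[SeqRecord] | MergedReference, site: str, prefix: str
) -> tuple[list[_Work], dict[tuple[str, str], str]]:
    """Convert inputs to working scaffolds: N-run split, length filter."""
    works: list[_Work] = []
    accounting: dict[tuple[str, str], str] = {}
    if isinstance(records_or_ref, MergedReference):
        items = [
            (_Work(f"{prefix}:{i}", r.id, r.sequence, records_or_ref.provenance[r.id]), None)
            for i, r in enumerate(records_or_ref.scaffolds)
        ]
        accounting.update(records_or_ref.accounting)
    else:
        items = [
            (_Work.from_record(f"{prefix}:{i}", site, r), (site, r.id))
            for i, r in enumerate(records_or_ref)
        ]
    out: list[_Work] = []
    counter = 0
    for w, acct_key in items:
        pieces = _split_n_runs(w)
        kept = []
        for p in pieces:
            if len(p.seq) < MIN_SCAFFOLD_LEN:
                logger.debug("dropping short scaffold piece %s (%d bp)", p.id, len(p.seq))
                continue
            kept.append(p)
        if not kept and acct_key is not None:
            accounting[acct_key] = "carried"  # fully discarded as short
        for j, p in enumerate(kept):
            key = f"{prefix}:{counter}"
            counter += 1
            pid = p.id if len(pieces) == 1 else f"{p.id}/{j + 1}"
            out.append(_Work(key, pid, p.seq, p.segs))
    works = out
    return works, accounting


def _split_n_runs(w: _Work) -> list[_Work]:
    pieces = []
    start = 0
    i = 0
    seq = w.seq
    n = len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            if j - i >= N_SPLIT_RUN:
                if i > start:
                    pieces.append(w.slice(start, i))
                start = j
            i = j
        else:
            i += 1
    if start < n:
        pieces.append(w.slice(start, n))
    return pieces or [w]


# ---------------------------------------------------------------------------
# overlap detection


def _candidates(
    refs: list[_Work], queries: list[_Work], params: MergeParams
) -> list[OverlapCandidate]:
    index = KmerIndex({w.key: w.seq for w in refs}, k=params.anchor_k)
    ref_by_key = {w.key: w for w in refs}
    cands: list[OverlapCandidate] = []
    for q in queries:
        min_needed = min(params.mL, max(1, int(params.containment_cov * len(q.seq))))
        for blk in index.find_blocks(q.seq, min_len=min_needed):
            if blk.identity < params.c:
                continue
            r = ref_by_key[blk.ref_id]
            len_r, len_q = len(r.seq), len(q.seq)
            # query span in its oriented frame (flipped if rc)
            if blk.strand == "+":
                oq_lo, oq_hi = blk.q_start, blk.q_end
            else:
                oq_lo, oq_hi = len_q - blk.q_end, len_q - blk.q_start
            q_cov = (blk.q_end - blk.q_start) / len_q
            if q_cov >= params.containment_cov:
                junction = "containment"
                r_over = q_over = 0
            else:
                r_left, r_right = blk.ref_start, len_r - blk.ref_end
                q_left, q_right = oq_lo, len_q - oq_hi
                fwd_ok = r_right <= params.hco and q_left <= params.hco
                rev_ok = q_right <= params.hco and r_left <= params.hco
                if blk.length < params.mL or not (fwd_ok or rev_ok):
                    continue
                if fwd_ok and (not rev_ok or r_right + q_left <= q_right + r_left):
                    junction, r_over, q_over = "ref_then_query", r_right, q_left
                else:
                    junction, r_over, q_over = "query_then_ref", r_left, q_right
            cands.append(
                OverlapCandidate(
                    ref_id=blk.ref_id,
                    query_id=q.key,
                    orientation="same" if blk.strand == "+" else "rc",
                    ref_span=(blk.ref_start, blk.ref_end),
                    query_span=(blk.q_start, blk.q_end),
                    aln_len=blk.length,
                    identity=blk.identity,
                    junction=junction,
                    ref_overhang=r_over,
                    query_overhang=q_over,
                )
            )
    cands.sort(key=lambda c: (-c.aln_len, -c.identity, c.ref_id, c.query_id))
    return cands


def find_overlaps(
    set_R: list[SeqRecord], set_Q: list[SeqRecord], params: MergeParams | None = None
) -> list[OverlapCandidate]:
    """End-anchored and containment overlap candidates between two scaffold sets.

    Candidate ids refer to working keys ``R:<i>`` / ``Q:<i>`` by input order
    (stable across N-splitting only when no scaffold is split).
    """
    params = params or MergeParams()
    refs, _ = _prepare(set_R, "R", "R")
    queries, _ = _prepare(set_Q, "Q", "Q")
    return _candidates(refs, queries, params)


# ---------------------------------------------------------------------------
# greedy merge


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: str, b: str) -> None:
        self.parent[self.find(a)] = self.find(b)


@dataclass
class _Join:
    left_key: str  # scaffold whose (oriented) right end is consumed
    right_key: str
    # overlap interval on the left scaffold's oriented frame
    left_span: tuple[int, int]
    right_span: tuple[int, int]
    keep: str  # 'left' or 'right' — which side's bases win in the overlap


def merge_pair(
    set_R: list[SeqRecord] | MergedReference,
    set_Q: list[SeqRecord] | MergedReference,
    params: MergeParams | None = None,
    ref_site: str = "R",
    query_site: str = "Q",
) -> MergedReference:
    """Merge a query scaffold set into a reference scaffold set.

    Candidates are accepted greedily in (aln_len desc, identity desc, ids)
    order; each scaffold end joins at most once and joins never close a
    cycle.  Inside an accepted overlap the reference-side bases are kept.
    Query scaffolds contained in a reference scaffold are dropped; all other
    scaffolds are carried through unchanged.
    """
    params = params or MergeParams()
    refs, acct_r = _prepare(set_R, ref_site, "R")
    queries, acct_q = _prepare(set_Q, query_site, "Q")
    accounting = {**acct_r, **acct_q}
    cands = _candidates(refs, queries, params)
    by_key = {w.key: w for w in refs + queries}
    is_ref = {w.key: True for w in refs} | {w.key: False for w in queries}

    contained: set[str] = set()
    for c in cands:
        if c.junction == "containment" and c.query_id not in contained:
            contained.add(c.query_id)

    orientation: dict[str, str] = {w.key: "+" for w in refs}
    used_ends: set[tuple[str, str]] = set()
    uf = _UnionFind()
    joins: list[_Join] = []
    for c in cands:
        if c.junction == "containment":
            continue
        if c.query_id in contained:
            continue
        want = "+" if c.orientation == "same" else "-"
        if c.query_id in orientation and orientation[c.query_id] != want:
            continue
        q = by_key[c.query_id]
        len_q = len(q.seq)
        if c.orientation == "same":
            oq = c.query_span
        else:
            oq = (len_q - c.query_span[1], len_q - c.query_span[0])
        if c.junction == "ref_then_query":
            left, right = c.ref_id, c.query_id
            left_span, right_span = c.ref_span, oq
        else:
            left, right = c.query_id, c.ref_id
            left_span, right_span = oq, c.ref_span
        ends = ((left, "right"), (right, "left"))
        if any(e in used_ends for e in ends):
            continue
        if uf.find(left) == uf.find(right):
            continue  # would close a cycle
        used_ends.update(ends)
        uf.union(left, right)
        orientation.setdefault(c.query_id, want)
        joins.append(
            _Join(
                left_key=left,
                right_key=right,
                left_span=left_span,
                right_span=right_span,
                keep="left" if is_ref[left] else "right",
            )
        )

    oriented: dict[str, _Work] = {}
    for key, w in by_key.items():
        if key in contained:
            continue
        o = orientation.get(key, "+")
        oriented[key] = w if o == "+" else w.revcomp()

    succ = {j.left_key: j for j in joins}
    has_pred = {j.right_key for j in joins}
    in_chain = {j.left_key for j in joins} | has_pred

    merged_scaffolds: list[SeqRecord] = []
    provenance: dict[str, list[ProvSegment]] = {}
    used_ids: set[str] = set()

    def emit(work: _Work, member_keys: list[str]) -> None:
        # display id: first reference-set member, else first member
        ref_members = [k for k in member_keys if is_ref[k]]
        display = by_key[(ref_members or member_keys)[0]].id
        if display in used_ids:
            i = 2
            while f"{display}.{i}" in used_ids:
                i += 1
            display = f"{display}.{i}"
        used_ids.add(display)
        merged_scaffolds.append(SeqRecord(id=display, sequence=work.seq))
        provenance[display] = work.segs
        status = "merged" if len(member_keys) > 1 else "carried"
        for k in member_keys:
            for s in by_key[k].segs:
                accounting[(s.site, s.source_id)] = status

    # chains first (heads = chain members without a predecessor)
    for w in refs + queries:
        if w.key in contained or w.key not in in_chain or w.key in has_pred:
            continue
        cur = oriented[w.key]
        members = [w.key]
        # offset of the current tail scaffold inside `cur`, and how much of
        # its oriented left side was dropped at the previous junction
        tail_off, tail_drop = 0, 0
        key = w.key
        while key in succ:
            j = succ[key]
            nxt = oriented[j.right_key]
            if j.keep == "left":
                cut = j.right_span[1]
                assert cut >= 0
                cur = cur.concat(nxt.slice(cut, len(nxt.seq)))
                tail_off = len(cur.seq) - (len(nxt.seq) - cut)
                tail_drop = cut
            else:
                cut_in_tail = j.left_span[0] - tail_drop
                assert cut_in_tail >= 0, "junction before previous splice point"
                cur = cur.slice(0, tail_off + cut_in_tail).concat(nxt)
                tail_off = len(cur.seq) - len(nxt.seq)
                tail_drop = 0
            members.append(j.right_key)
            key = j.right_key
        emit(cur, members)

    # untouched scaffolds carried through
    for w in refs + queries:
        if w.key in contained or w.key in in_chain:
            continue
        emit(oriented[w.key], [w.key])

    for key in contained:
        for s in by_key[key].segs:
            accounting[(s.site, s.source_id)] = "contained"

    result = MergedReference(
        scaffolds=merged_scaffolds, provenance=provenance, accounting=accounting
    )
    result.validate()
    return result


def merge_sites(
    scaffold_sets: dict[str, list[SeqRecord]],
    params: MergeParams | None = None,
) -> MergedReference:
    """Left-fold pairwise merging over per-site scaffold sets.

    Sets are processed in descending order of total assembly size (the
    largest set is the backbone), ties broken by site name.
    """
    params = params or MergeParams()
    if len(scaffold_sets) < 2:
        raise ParameterError("merge_sites needs at least 2 scaffold sets")
    order = sorted(
        scaffold_sets, key=lambda s: (-sum(len(r) for r in scaffold_sets[s]), s)
    )
    first = order[0]
    refs, acct = _prepare(scaffold_sets[first], first, "R")
    current = MergedReference(
        scaffolds=[SeqRecord(id=w.id, sequence=w.seq) for w in refs],
        provenance={w.id: w.segs for w in refs},
        accounting={
            **acct,
            **{
                (s.site, s.source_id): "carried"
                for w in refs
                for s in w.segs
            },
        },
    )
    for site in order[1:]:
        current = merge_pair(
            current, scaffold_sets[site], params, ref_site="merged", query_site=site
        )
    return current
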