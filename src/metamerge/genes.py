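"""Gene catalogue construction on the merged reference.

ORF-based gene calling (a stand-in for a statistical gene finder — external
GFF3 gene models are accepted interchangeably), cross-assembly gene-identity
matching at a small edit-distance budget, COG grouping of known genes, and
greedy centroid clustering of unknown proteins by sequence similarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib
from Bio.Seq import Seq

from .types import AnnotationRecord, GeneFeature, SeqRecord, revcomp

STOPS = {"TAA", "TAG", "TGA"}


@dataclass
class GeneCatalogue:
    features: list[GeneFeature]
    annotations: dict[str, AnnotationRecord] = field(default_factory=dict)
    proteins: dict[str, str] = field(default_factory=dict)
    nucleotides: dict[str, str] = field(default_factory=dict)


@dataclass
class GeneCluster:
    cluster_id: str
    members: list[str]
    centroid: str
    kind: str  # 'known' or 'unknown'
    label: str | None = None  # COG label for known clusters
    multi_member_genes: frozenset[str] = frozenset()


@dataclass
class GeneMatchReport:
    n_common_genes: int
    n_matched: int

    @property
    def percent_matched(self) -> float | None:
        if self.n_common_genes == 0:
            return None  # undefined, flagged by None
        return 100.0 * self.n_matched / self.n_common_genes


# ---------------------------------------------------------------------------
# ORF calling


def _orfs_one_strand(seq: str) -> list[tuple[int, int, int]]:
    """Maximal ORFs (start, end, frame) on the forward strand of ``seq``."""
    n = len(seq)
    out = []
    for frame in range(3):
        first_atg: int | None = None
        for pos in range(frame, n - 2, 3):
            codon = seq[pos : pos + 3]
            if codon in STOPS:
                if first_atg is not None:
                    out.append((first_atg, pos + 3, frame))
                first_atg = None
            elif codon == "ATG" and first_atg is None:
                first_atg = pos
    return out


def call_orfs(
    reference: list[SeqRecord], min_len_nt: int = 300
) -> list[GeneFeature]:
    """All maximal ORFs (ATG -> stop, both strands, 3 frames) >= min_len_nt.

    Overlapping ORFs on the same strand are resolved longest-first; opposite
    strands may overlap freely.
    """
    features: list[GeneFeature] = []
    for rec in reference:
        seq = rec.sequence
        n = len(seq)
        raw: list[tuple[int, int, str, int]] = []
        for s, e, frame in _orfs_one_strand(seq):
            raw.append((s, e, "+", frame))
        for s, e, frame in _orfs_one_strand(revcomp(seq)):
            raw.append((n - e, n - s, "-", frame))
        raw = [r for r in raw if r[1] - r[0] >= min_len_nt]
        # longest-first per strand
        kept: dict[str, list[tuple[int, int]]] = {"+": [], "-": []}
        chosen = []
        for s, e, strand, frame in sorted(raw, key=lambda r: (-(r[1] - r[0]), r[0])):
            if any(s < ke and ks < e for ks, ke in kept[strand]):
                continue
            kept[strand].append((s, e))
            chosen.append((s, e, strand, frame))
        for i, (s, e, strand, frame) in enumerate(sorted(chosen), start=1):
            features.append(
                GeneFeature(
                    gene_id=f"{rec.id}_orf{i:04d}",
                    scaffold_id=rec.id,
                    start=s,
                    end=e,
                    strand=strand,
                    frame=0,
                )
            )
    return features


def extract_gene_sequences(
    features: list[GeneFeature], reference: list[SeqRecord]
) -> dict[str, str]:
    """Nucleotide sequence per gene; minus-strand genes reverse-complemented."""
    scaffolds = {r.id: r.sequence for r in reference}
    out = {}
    for f in features:
        seq = scaffolds[f.scaffold_id][f.start : f.end]
        out[f.gene_id] = seq if f.strand == "+" else revcomp(seq)
    return out


def translate(nt: str) -> str:
    """Translate a CDS; trailing stop is dropped, ambiguous codons become X."""
    prot = str(Seq(nt[: len(nt) - len(nt) % 3]).translate())
    return prot[:-1] if prot.endswith("*") else prot


def build_catalogue(
    reference: list[SeqRecord],
    features: list[GeneFeature] | None = None,
    annotations: dict[str, AnnotationRecord] | None = None,
    min_len_nt: int = 300,
) -> GeneCatalogue:
    if features is None:
        features = call_orfs(reference, min_len_nt=min_len_nt)
    nts = extract_gene_sequences(features, reference)
    proteins = {g: translate(s) for g, s in nts.items()}
    return GeneCatalogue(
        features=features,
        annotations=annotations or {},
        proteins=proteins,
        nucleotides=nts,
    )


# ---------------------------------------------------------------------------
# cross-assembly gene-identity matching


def _banded_edit(a: str, b: str, max_edit: int) -> int | None:
    if abs(len(a) - len(b)) > max_edit:
        return None
    res = edlib.align(a, b, mode="NW", task="distance", k=max_edit)
    d = res["editDistance"]
    return None if d < 0 else d


def _greedy_match(
    seqs_a: list[str], seqs_b: list[str], max_edit: int
) -> dict[int, int]:
    """Greedy one-to-one matching on the globally sorted candidate list."""
    candidates = []
    by_len_b: list[tuple[int, int]] = sorted(
        (len(s), i) for i, s in enumerate(seqs_b)
    )
    for ia, sa in enumerate(seqs_a):
        la = len(sa)
        for lb, ib in by_len_b:
            if lb < la - max_edit:
                continue
            if lb > la + max_edit:
                break
            d = _banded_edit(sa, seqs_b[ib], max_edit)
            if d is not None:
                candidates.append((d, ia, ib))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    match: dict[int, int] = {}
    for _d, ia, ib in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        match[ia] = ib
    return match


def match_genes_across(
    site_genes: dict[str, list[str]],
    merged_genes: list[str],
    max_edit: int = 3,
) -> GeneMatchReport:
    """How many genes common to all sites match the merged catalogue.

    A gene (anchored in the first site by sorted name) is *common* if a
    counterpart within ``max_edit`` edits exists in every other site's gene
    set under greedy one-to-one matching; it *matches* if such a counterpart
    also exists in the merged catalogue.  Distances are banded edit
    distances (substitutions + indels).
    """
    sites = sorted(site_genes)
    if not sites or not merged_genes:
        return GeneMatchReport(n_common_genes=0, n_matched=0)
    anchor = site_genes[sites[0]]
    common = set(range(len(anchor)))
    for other in sites[1:]:
        match = _greedy_match(anchor, site_genes[other], max_edit)
        common &= set(match)
    common_seqs = [anchor[i] for i in sorted(common)]
    merged_match = _greedy_match(common_seqs, merged_genes, max_edit)
    return GeneMatchReport(n_common_genes=len(common), n_matched=len(merged_match))


# ---------------------------------------------------------------------------
# clustering


def group_known_by_cog(catalogue: GeneCatalogue) -> list[GeneCluster]:
    """One cluster per COG label; genes carrying several labels join each."""
    by_cog: dict[str, list[str]] = {}
    counts: dict[str, int] = {}
    for gid, ann in sorted(catalogue.annotations.items()):
        if ann.cog is None:
            continue
        labels = [c for c in ann.cog.split(";") if c]
        counts[gid] = len(labels)
        for label in labels:
            by_cog.setdefault(label, []).append(gid)
    clusters = []
    multi = frozenset(g for g, c in counts.items() if c > 1)
    for label in sorted(by_cog):
        members = by_cog[label]
        clusters.append(
            GeneCluster(
                cluster_id=f"known:{label}",
                members=members,
                centroid=members[0],
                kind="known",
                label=label,
                multi_member_genes=multi & set(members),
            )
        )
    return clusters


def _protein_identity(shorter: str, longer: str) -> float:
    """Identity of the shorter protein aligned as an infix of the longer."""
    res = edlib.align(shorter, longer, mode="HW", task="distance")
    d = res["editDistance"]
    return 1.0 - d / len(shorter) if d >= 0 else 0.0


def _kmer_set(seq: str, k: int = 5) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def cluster_unknown_proteins(
    catalogue: GeneCatalogue,
    min_identity: float = 0.90,
    min_coverage: float = 0.85,
) -> list[GeneCluster]:
    """Greedy centroid clustering of unknown proteins.

    Proteins are visited longest-first; each joins the first centroid with
    identity >= ``min_identity`` over the shorter sequence, provided the
    shorter covers >= ``min_coverage`` of itself in the alignment (infix
    alignment covers the shorter fully, so the operative constraint is the
    length ratio and identity).  Otherwise it founds a new cluster.
    """
    unknown = [
        (gid, catalogue.proteins[gid])
        for gid, ann in sorted(catalogue.annotations.items())
        if not ann.is_known and gid in catalogue.proteins
    ]
    unknown.sort(key=lambda t: (-len(t[1]), t[0]))
    centroids: list[tuple[str, str, set[str]]] = []  # (gene_id, protein, kmers)
    members: dict[str, list[str]] = {}
    for gid, prot in unknown:
        joined = False
        kmers = _kmer_set(prot)
        for cid, cprot, ckmers in centroids:
            # shorter must cover min_coverage of the longer-vs-shorter ratio
            if len(prot) < min_coverage * len(cprot):
                continue
            if not (kmers & ckmers):
                continue
            if _protein_identity(prot, cprot) >= min_identity:
                members[cid].append(gid)
                joined = True
                break
        if not joined:
            centroids.append((gid, prot, kmers))
            members[gid] = [gid]
    return [
        GeneCluster(
            cluster_id=f"unknown:{cid}",
            members=members[cid],
            centroid=cid,
            kind="unknown",
        )
        for cid, _p, _k in centroids
    ]
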