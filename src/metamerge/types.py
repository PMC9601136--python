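"""Core domain types shared across the pipeline.

All coordinates are 0-based half-open throughout the package; the SAM and
GFF3 converters in :mod:`metamerge.io` are the only places where 1-based
arithmetic occurs.  A *sample* is always the ordered pair
``(individual, site)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

VALID_BASES = frozenset("ACGTN")

DEFAULT_SITE_ORDER = ("cecum", "transverse_colon", "feces")


class FormatError(ValueError):
    """A file violated the expected on-disk format."""


class PairingError(ValueError):
    """Mate files could not be paired record-for-record."""


class ReferenceError_(ValueError):
    """An alignment referred to an unknown target sequence."""


class ParameterError(ValueError):
    """A configuration value is outside its documented range."""


@dataclass
class SeqRecord:
    """A named nucleotide sequence with free-text provenance.

    ``description`` may carry ``key=value`` tags (site, individual, truth
    species) used by the simulator and the evaluation stages.
    """

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("sequence record with empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: invalid characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)

    def tags(self) -> dict[str, str]:
        """Parse ``key=value`` tokens out of the description."""
        out: dict[str, str] = {}
        for token in self.description.split():
            if "=" in token:
                k, _, v = token.partition("=")
                out[k] = v
        return out


@dataclass
class ReadPair:
    """A paired-end read; ``truth_origin`` is set for simulated reads."""

    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str
    # (species_id, genome_position, strand) of the sequenced fragment
    truth_origin: tuple[str, int, str] | None = None

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise FormatError(
                f"read {self.id!r}: sequence/quality length mismatch"
            )


@dataclass
class AlignmentRecord:
    """One aligned (or unmapped) mate against a reference scaffold."""

    query_id: str
    target_id: str | None  # None for unmapped
    target_start: int  # 0-based
    strand: str  # '+' or '-'
    cigar: str
    mapq: int
    is_mate1: bool
    properly_paired: bool
    fragment_len: int
    seq: str = ""
    qual: str = ""

    @property
    def mapped(self) -> bool:
        return self.target_id is not None

    def aligned_ref_length(self) -> int:
        """Reference bases consumed by the CIGAR (M and D ops)."""
        n, total = 0, 0
        for ch in self.cigar:
            if ch.isdigit():
                n = n * 10 + int(ch)
            else:
                if ch in "MD=X":
                    total += n
                n = 0
        return total

    @property
    def target_end(self) -> int:
        return self.target_start + self.aligned_ref_length()


@dataclass(frozen=True)
class GeneFeature:
    """A located gene, 0-based half-open on its scaffold."""

    gene_id: str
    scaffold_id: str
    start: int
    end: int
    strand: str
    frame: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise FormatError(
                f"gene {self.gene_id!r}: invalid interval [{self.start},{self.end})"
            )
        if self.strand not in "+-":
            raise FormatError(f"gene {self.gene_id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AnnotationRecord:
    """Functional labels for one gene; a gene is *known* iff it has a KO or COG."""

    gene_id: str
    ko: str | None = None
    cog: str | None = None
    reactions: frozenset[str] = frozenset()

    @property
    def is_known(self) -> bool:
        return self.ko is not None or self.cog is not None


@dataclass
class MergeParams:
    """Knobs of the scaffold overlap-merge step.

    ``mL`` is the minimum overlap alignment length in bp; ``c`` the minimum
    percent identity over the overlap; ``hco`` the maximum inner overhang at
    a junction in bp.  These names mirror the roles of an external merger's
    length cutoff / alignment confidence / overlap confidence but carry this
    package's own, precisely testable semantics (see docs/methods.md).
    """

    mL: int = 1000
    c: float = 95.0
    hco: int = 100
    containment_cov: float = 0.90
    anchor_k: int = 21

    def __post_init__(self) -> None:
        if self.mL < 1:
            raise ParameterError("mL must be >= 1")
        if not (0 < self.c <= 100):
            raise ParameterError("c must be in (0, 100]")
        if self.hco < 0:
            raise ParameterError("hco must be >= 0")
        if not (0 < self.containment_cov <= 1):
            raise ParameterError("containment_cov must be in (0, 1]")


@dataclass
class MapperParams:
    k: int = 31
    max_mismatch_rate: float = 0.05
    max_fragment_len: int = 2000  # maximum DNA fragment accepted as a proper pair


@dataclass
class QuantParams:
    count_mode: str = "union"
    pseudodepth: float = 0.0
    stranded: bool = False


@dataclass
class CovariationParams:
    target_fpr: float = 0.05
    # Documented reference threshold; used only when benchmarking is bypassed.
    L_threshold_override: float | None = None
    cluster_identity: float = 0.90
    cluster_coverage: float = 0.85
    log_transform: bool = True
    profile_agg: str = "sum"


@dataclass
class SimulationParams:
    seed: int = 0
    n_species: int = 6
    length_range: tuple[int, int] = (80_000, 120_000)
    gc: float = 0.45
    gene_density: float = 1 / 2500.0
    unknown_fraction: float = 0.30
    n_covariant_pairs: int = 20
    effect_size: float = 2.0
    noise_sd: float = 0.25
    min_frag: int = 6000
    overlap_range: tuple[int, int] = (1500, 2500)
    dna_depth: float = 3.0
    rna_depth: float = 3.0
    read_len: int = 150
    fragment_mean: int = 400
    error_rate: float = 0.0


@dataclass
class PipelineConfig:
    """All stage parameters plus the per-individual ordered site chains."""

    merge: MergeParams = field(default_factory=MergeParams)
    mapper: MapperParams = field(default_factory=MapperParams)
    quant: QuantParams = field(default_factory=QuantParams)
    covariation: CovariationParams = field(default_factory=CovariationParams)
    simulation: SimulationParams = field(default_factory=SimulationParams)
    site_order: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {
            "ind1": DEFAULT_SITE_ORDER,
            "ind2": DEFAULT_SITE_ORDER,
        }
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for ind, sites in self.site_order.items():
            if len(sites) < 2:
                raise ParameterError(
                    f"individual {ind!r} lists {len(sites)} site(s); need >= 2"
                )

    @property
    def samples(self) -> list[tuple[str, str]]:
        """All (individual, site) pairs in canonical order."""
        return [
            (ind, site)
            for ind in sorted(self.site_order)
            for site in self.site_order[ind]
        ]


COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]
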