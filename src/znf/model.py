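"""Shared domain types for the KZNF toolkit.

Coordinate convention: all genomic intervals are 0-based, half-open, on the
forward strand.  Minus-strand features store their forward-strand interval
plus a strand flag; 5'->3' order for minus-strand features is descending
genomic coordinates.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

DNA_ALPHABET = frozenset("ACGTN")
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: canonical 28-residue C2H2 zinc-finger unit (84 nt) used for the default
#: family profile and the synthetic-data generator.  C2H2 core: cysteines at
#: offsets 2 and 5, histidines at 18 and 22; TGEKP-style linker at the tail.
ZNF_UNIT_LENGTH = 28
ZNF_CONSENSUS = "YKCGECGKAFNRSSNLTRHQRTHTGEKP"
ZNF_CYS_OFFSETS = (2, 5)
ZNF_HIS_OFFSETS = (18, 22)

#: recognition-helix offsets of the four DNA-contacting residues (helix
#: positions -1, 2, 3, 6) measured from the first histidine of the C2H2 core.
CONTACT_OFFSETS_FROM_HIS = (-7, -5, -4, -1)
#: the same positions within the canonical 28-aa unit
CONTACT_POSITIONS = tuple(ZNF_HIS_OFFSETS[0] + o for o in CONTACT_OFFSETS_FROM_HIS)


class FormatError(ValueError):
    """Raised when an external file violates its format contract."""


class ConfigurationError(ValueError):
    """Raised when a component is used before it is fully configured."""


@dataclass
class GenomeSequence:
    """A DNA sequence with an id and (optionally) a species label."""

    id: str
    seq: str
    species: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("genome sequence id must be non-empty")
        bad = set(self.seq) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"illegal character(s) {sorted(bad)} in sequence {self.id!r}"
            )

    def __len__(self) -> int:
        return len(self.seq)


class SubstitutionMatrix:
    """Symmetric integer amino-acid substitution matrix.

    Backed by a dense numpy array over an explicit alphabet; ``score`` raises
    for residues outside the alphabet.
    """

    def __init__(self, alphabet: str, scores: np.ndarray, name: str = ""):
        scores = np.asarray(scores)
        if scores.shape != (len(alphabet), len(alphabet)):
            raise FormatError("score matrix shape does not match alphabet")
        if not (scores == scores.T).all():
            raise FormatError("substitution matrix is not symmetric")
        self.alphabet = alphabet
        self.name = name
        self._index = {a: i for i, a in enumerate(alphabet)}
        self._scores = scores

    def score(self, a: str, b: str) -> float:
        try:
            return float(self._scores[self._index[a], self._index[b]])
        except KeyError as exc:
            raise KeyError(f"residue {exc.args[0]!r} not in matrix alphabet") from None

    __call__ = score

    def __contains__(self, residue: str) -> bool:
        return residue in self._index


@dataclass
class IntervalRecord:
    """A genomic interval with free-form attributes (internal convention)."""

    seqid: str
    start: int
    end: int
    strand: str = "+"
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 <= self.start <= self.end):
            raise FormatError(
                f"coordinate inversion: [{self.start}, {self.end}) on {self.seqid}"
            )
        if self.strand not in ("+", "-"):
            raise FormatError(f"strand must be + or -, got {self.strand!r}")

    def overlaps(self, other: "IntervalRecord") -> bool:
        return self.seqid == other.seqid and self.start < other.end and other.start < self.end


@dataclass
class MappingRow:
    """One row of a liftover-style cross-genome coordinate mapping table."""

    src_seq: str
    src_start: int
    src_end: int
    src_strand: str
    dst_seq: str
    dst_start: int
    dst_end: int
    dst_strand: str


@dataclass
class DomainHit:
    """A scored match of a domain profile on one strand/frame of a genome."""

    profile: str
    genome_id: str
    start: int
    end: int
    strand: str
    frame: int
    aa_seq: str
    bit_score: float
    e_score: float

    def __post_init__(self) -> None:
        if self.e_score < 0:
            raise FormatError("E-score must be non-negative")
        if self.end - self.start != 3 * len(self.aa_seq):
            raise ValueError("interval length must equal 3 x aa length")

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


EFFECTOR_DOMAINS = frozenset(
    {"KRAB-A", "KRAB-B", "KRAB-b", "KRAB-BL", "KRAB-C", "SCAN", "BTB"}
)


@dataclass
class OrfBlock:
    """A stop-to-stop extension of one same-frame block of domain hits."""

    start: int
    end: int
    frame: int
    aa_seq: str


@dataclass
class Locus:
    """An assembled KZNF gene model."""

    id: str
    species: str
    genome_id: str
    strand: str
    hits: list  # DomainHit, ordered 5'->3'
    orf_blocks: list = field(default_factory=list)
    orf_aa: str = ""
    cds_aa: str = ""  # annotated coding-region translation, may contain '*'
    classification: str = ""  # gene | pseudogene
    cluster_id: Optional[str] = None
    seq: str = ""  # nucleotide sequence of the annotated coding span

    @property
    def start(self) -> int:
        return min(h.start for h in self.hits)

    @property
    def end(self) -> int:
        return max(h.end for h in self.hits)

    @property
    def znf_hits(self) -> list:
        return [h for h in self.hits if h.profile == "ZNF"]

    @property
    def span(self) -> tuple[int, int]:
        if self.orf_blocks:
            return (
                min(b.start for b in self.orf_blocks),
                max(b.end for b in self.orf_blocks),
            )
        return (self.start, self.end)


@dataclass
class ZnfMotif:
    """One 28-aa zinc-finger unit of an array."""

    seq: str
    index: int  # 1-based, 5'->3' within the array
    functional: bool = True
    contacts: Optional[str] = None  # 4 residues, helix positions -1,2,3,6

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValueError("motif index is 1-based")


@dataclass
class MotifSequence:
    """The ordered zinc-finger units of one protein/locus."""

    id: str
    motifs: list  # list[ZnfMotif], indices strictly increasing

    def __post_init__(self) -> None:
        indices = [m.index for m in self.motifs]
        if any(b <= a for a, b in zip(indices, indices[1:])):
            raise ValueError("motif indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.motifs)


@dataclass
class AlignerParams:
    """Parameters of the motif-level global aligner.

    The gap penalties follow the published parameterisation: opening costs
    motif_length**-1 and extension motif_length**-0.9 with motif_length the
    84-nt finger unit.  Both are tiny relative to substitution-matrix sums and
    act mainly as deterministic tie-breakers.
    """

    matrix: SubstitutionMatrix
    motif_length: int = 84
    gap_open: float = None  # type: ignore[assignment]
    gap_extend: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.motif_length <= 0:
            raise ValueError("motif_length must be positive")
        if self.gap_open is None:
            self.gap_open = self.motif_length ** -1.0
        if self.gap_extend is None:
            self.gap_extend = self.motif_length ** -0.9
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive")


@dataclass
class AlignColumn:
    """One column of a motif alignment.

    kind 'pair' carries both indices; 'gap_a' a motif of B unmatched in A;
    'gap_b' a motif of A unmatched in B.  Indices are 1-based motif indices.
    """

    kind: str  # pair | gap_a | gap_b
    i: Optional[int] = None  # index in A
    j: Optional[int] = None  # index in B
    score: float = 0.0


@dataclass
class MotifAlignment:
    columns: list  # list[AlignColumn]
    score: float
    params: AlignerParams
    a_id: str = ""
    b_id: str = ""

    def paired(self) -> list:
        return [c for c in self.columns if c.kind == "pair"]


@dataclass
class SimilarityEdge:
    """A scored (possibly cross-species) locus pair with best-hit flags."""

    a: str
    b: str
    score: float
    best_ab: bool = False  # b is a's unique best hit
    best_ba: bool = False

    def __post_init__(self) -> None:
        if self.score < 0:
            raise ValueError("similarity score must be non-negative")


@dataclass
class Orthogroup:
    id: str
    members: dict  # species -> list of locus ids
    tier: str  # step0_high_confidence | step1 | step2 | step3

    def species_counts(self) -> dict:
        return {sp: len(ids) for sp, ids in self.members.items() if ids}

    def all_loci(self) -> list:
        return [lid for ids in self.members.values() for lid in ids]


# -- species tree -----------------------------------------------------------

SPECIES = ("H", "C", "O", "R")
BRANCHES = ("H", "C", "O", "R", "HC", "HCO")
#: leaf descendants of every branch of the fixed tree (((H,C)HC,O)HCO,R)
BRANCH_DESCENDANTS = {
    "H": frozenset("H"),
    "C": frozenset("C"),
    "O": frozenset("O"),
    "R": frozenset("R"),
    "HC": frozenset("HC"),
    "HCO": frozenset("HCO"),
}
#: divergence-time ranges (My) used to convert branch event counts to rates:
#: terminal H/C branches span the human-chimpanzee split (4.5-6 My), the HC
#: branch and the orangutan branch the human-orangutan split (12-16 My), and
#: the HCO/rhesus branches the human-macaque split (25-33 My).
DIVERGENCE_MY = {
    "H": (4.5, 6.0),
    "C": (4.5, 6.0),
    "O": (12.0, 16.0),
    "HC": (12.0, 16.0),
    "R": (25.0, 33.0),
    "HCO": (25.0, 33.0),
}


@dataclass(frozen=True)
class SpeciesTree:
    """The fixed rooted 4-taxon primate tree (((H,C)HC,O)HCO,R)."""

    species: tuple = SPECIES
    branches: tuple = BRANCHES
    divergence_my: dict = field(default_factory=lambda: dict(DIVERGENCE_MY))

    def descendants(self, branch: str) -> frozenset:
        return BRANCH_DESCENDANTS[branch]


@dataclass
class LineageEvent:
    """A polarized lineage-specific event on the species tree."""

    kind: str  # locus_gain | locus_loss | pseudogenization | finger_gain |
    #           finger_loss | finger_seq_change | contact_change
    branch: str
    orthogroup: Optional[str] = None
    locus: Optional[str] = None
    motif_index: Optional[int] = None
    count: int = 1
    ambiguous_with: Optional[str] = None  # e.g. "R" on an HCO event (R=HCO)

    @property
    def candidate_branches(self) -> frozenset:
        if self.ambiguous_with is None:
            return frozenset({self.branch})
        return frozenset({self.branch, *self.ambiguous_with.split(",")})


@dataclass
class RateEstimate:
    """An event count converted to a per-My rate range."""

    count: int
    my_low: float
    my_high: float
    rate_low: float
    rate_high: float

    def __post_init__(self) -> None:
        if self.rate_low > self.rate_high:
            raise ValueError("rate_low must not exceed rate_high")


@dataclass
class KaKsResult:
    ka: float
    ks: float
    ratio: Optional[float]  # None when Ka = Ks = 0; 99 sentinel when Ks = 0
    syn_sites: float
    nonsyn_sites: float
    syn_diffs: float
    nonsyn_diffs: float


IUPAC_BASES = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGTN"),  # motif N matches anything, including assembly N
}


@dataclass
class BindingMotif:
    """A predicted IUPAC binding motif with per-position provenance."""

    iupac: str
    provenance: list = field(default_factory=list)  # finger index or "linker"

    def __post_init__(self) -> None:
        bad = set(self.iupac) - set(IUPAC_BASES)
        if bad:
            raise ValueError(f"invalid IUPAC symbol(s): {sorted(bad)}")
        if self.provenance and len(self.provenance) != len(self.iupac):
            raise ValueError("provenance must cover every motif position")

    def __len__(self) -> int:
        return len(self.iupac)


@dataclass
class MotifMatch:
    genome_id: str
    start: int
    end: int
    strand: str


@dataclass
class CoexpressionResult:
    gene: str
    rho: Optional[float]
    p: Optional[float]
    p_adjusted: Optional[float]
    n: int
    testable: bool = True
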