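"""Six-frame translation and position-specific domain scanning.

Detection uses additive position-specific scores (PSSM) with an extreme-value
(Gumbel) tail fitted on shuffled sequence for E-values.  External HMMER hits
(ingested through :func:`znf.io.read_domtblout`) remain the recommended
production path; the internal scanner exists so the downstream locus rules
are fully testable without external binaries.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from Bio.Seq import Seq
from scipy.stats import gumbel_r

from .model import (
    AMINO_ACIDS,
    ConfigurationError,
    DomainHit,
    GenomeSequence,
)

# scanner alphabet: 20 amino acids + X (ambiguous) + * (stop)
SCAN_ALPHABET = AMINO_ACIDS + "X*"
_AA_INDEX = {a: i for i, a in enumerate(SCAN_ALPHABET)}

#: default E-value thresholds; only the KRAB annotation threshold (1e-6) is a
#: published rule, the rest are configurable defaults.
DEFAULT_E_THRESHOLDS = {
    "KRAB-A": 1e-6,
    "KRAB-B": 1e-3,
    "KRAB-b": 1e-3,
    "KRAB-BL": 1e-3,
    "KRAB-C": 1e-3,
    "SCAN": 1e-3,
    "BTB": 1e-3,
    "ZNF": 1e-3,
}


@dataclass
class Frame:
    """One of the six translation frames of a genome."""

    number: int  # 1..6; 4..6 are reverse-complement frames
    aa: str
    genome_id: str
    genome_length: int

    @property
    def offset(self) -> int:
        return (self.number - 1) % 3

    @property
    def strand(self) -> str:
        return "+" if self.number <= 3 else "-"

    def to_genome(self, aa_start: int, aa_end: int) -> tuple[int, int]:
        """Forward-strand nt interval of a half-open aa window."""
        if self.number <= 3:
            return self.offset + 3 * aa_start, self.offset + 3 * aa_end
        return (
            self.genome_length - (self.offset + 3 * aa_end),
            self.genome_length - (self.offset + 3 * aa_start),
        )


def _translate(dna: str) -> str:
    n = len(dna) - len(dna) % 3
    if n == 0:
        return ""
    aa = list(str(Seq(dna[:n]).translate()))
    # contract: any codon containing N renders X (biopython would resolve
    # family-degenerate codons like GTN to their amino acid)
    for i in range(len(aa)):
        if "N" in dna[3 * i : 3 * i + 3]:
            aa[i] = "X"
    return "".join(aa)


def six_frame_translate(genome: GenomeSequence) -> list[Frame]:
    """Translate a genome into all six frames.

    Frames 1-3 read the forward strand at offsets 0-2, frames 4-6 the reverse
    complement at offsets 0-2.  Stop codons render '*', codons containing N
    render 'X'.  Each frame maps aa windows back to forward-strand intervals.
    """
    fwd = genome.seq
    rev = str(Seq(fwd).reverse_complement())
    frames = []
    for number in range(1, 7):
        src = fwd if number <= 3 else rev
        offset = (number - 1) % 3
        frames.append(
            Frame(
                number=number,
                aa=_translate(src[offset:]),
                genome_id=genome.id,
                genome_length=len(fwd),
            )
        )
    return frames


@dataclass
class DomainProfile:
    """Additive position-specific log-odds profile with Gumbel calibration.

    ``weights`` has shape (length, len(SCAN_ALPHABET)).  The default family
    profiles score conserved positions +match/-mismatch and family-variable
    positions (e.g. the DNA-contacting residues of a finger) zero, so family
    members diverged at variable positions keep their full margin over the
    E-value threshold.
    """

    name: str
    weights: np.ndarray
    loc: Optional[float] = None  # Gumbel location
    scale: Optional[float] = None  # Gumbel scale
    consensus: str = ""

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 2 or self.weights.shape[1] != len(SCAN_ALPHABET):
            raise ValueError("weights must be (length, alphabet) shaped")
        if self.length == 0:
            raise ValueError("profile length must be positive")
        if not np.isfinite(self.weights).all():
            raise ValueError("profile weights must be finite")

    @property
    def length(self) -> int:
        return self.weights.shape[0]

    @property
    def calibrated(self) -> bool:
        return self.loc is not None and self.scale is not None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_family(
        cls,
        name: str,
        consensus: str,
        variable_positions: Iterable[int] = (),
        match: float = 4.0,
        mismatch: float = -3.0,
        stop: float = -8.0,
    ) -> "DomainProfile":
        """Family-style profile: conserved positions reward the consensus
        residue and penalise others; variable positions are uninformative."""
        variable = set(variable_positions)
        L = len(consensus)
        w = np.zeros((L, len(SCAN_ALPHABET)))
        for j, c in enumerate(consensus):
            if j in variable:
                w[j, :] = 0.0
            else:
                w[j, :] = mismatch
                w[j, _AA_INDEX[c]] = match
            w[j, _AA_INDEX["X"]] = 0.0
            w[j, _AA_INDEX["*"]] = stop
        return cls(name=name, weights=w, consensus=consensus)

    @classmethod
    def from_consensus(cls, name: str, consensus: str, matrix) -> "DomainProfile":
        """Generic profile from substitution-matrix rows of a consensus."""
        L = len(consensus)
        w = np.zeros((L, len(SCAN_ALPHABET)))
        for j, c in enumerate(consensus):
            for a in AMINO_ACIDS:
                w[j, _AA_INDEX[a]] = matrix.score(c, a)
            w[j, _AA_INDEX["X"]] = 0.0
            w[j, _AA_INDEX["*"]] = -8.0
        return cls(name=name, weights=w, consensus=consensus)

    # -- scoring -----------------------------------------------------------

    def window_scores(self, aa: str) -> np.ndarray:
        """Scores of every length-L window of *aa* (vectorised)."""
        L = self.length
        if len(aa) < L:
            return np.empty(0)
        idx = np.fromiter(
            (_AA_INDEX.get(c, _AA_INDEX["X"]) for c in aa), dtype=np.int64, count=len(aa)
        )
        n = len(aa) - L + 1
        scores = np.zeros(n)
        for j in range(L):
            scores += self.weights[j, idx[j : j + n]]
        return scores

    def calibrate(self, n_windows: int = 10_000, seed: int = 99) -> "DomainProfile":
        """Fit the Gumbel tail on uniformly shuffled amino-acid sequence."""
        rng = np.random.default_rng(seed)
        aa = "".join(rng.choice(list(AMINO_ACIDS), size=n_windows + self.length - 1))
        scores = self.window_scores(aa)
        self.loc, self.scale = gumbel_r.fit(scores)
        return self

    def evalue(self, score, n_searched: int):
        """E-value of a score given the number of windows searched."""
        if not self.calibrated:
            raise ConfigurationError(
                f"profile {self.name!r} is not calibrated (no Gumbel parameters)"
            )
        return n_searched * gumbel_r.sf(score, loc=self.loc, scale=self.scale)


# --------------------------------------------------------------------------
# default family profiles (synthetic stand-ins for HMM matrices)

from .model import (  # noqa: E402  (constants shared with the simulator)
    CONTACT_POSITIONS,
    ZNF_CONSENSUS,
)

#: family-variable positions of the canonical finger: the four DNA-contacting
#: residues plus four additional surface positions.
ZNF_VARIABLE_POSITIONS = tuple(sorted(set(CONTACT_POSITIONS) | {3, 7, 21, 25}))

KRAB_A_CONSENSUS = "VTFEDVAVYFSQEEWGLLDEAQRLLYRDVMLENYSNLVSLG"
KRAB_A_VARIABLE_POSITIONS = (2, 6, 10, 14, 18, 22, 26, 30, 34, 38)
KRAB_B_CONSENSUS = "EGLVSFKDVFVDFTREEWQLLDTAQQIVYRNVMLEN"
KRAB_B_VARIABLE_POSITIONS = (2, 6, 10, 14, 18, 22, 26, 30, 34)
SCAN_CONSENSUS = "AEAVTFRDVAVLFSEDEWKLLSPSQKELYKEVMLENARNL"
SCAN_VARIABLE_POSITIONS = (2, 6, 10, 14, 18, 22, 26, 30, 34, 38)
BTB_CONSENSUS = "MSQQFCLRWNNHQSNLLSVFEELLQSESFVDVTLACE"
BTB_VARIABLE_POSITIONS = (2, 6, 10, 14, 18, 22, 26, 30, 34)


def default_profiles(calibrate: bool = True, seed: int = 99) -> dict:
    """The shipped profile set (ZNF + effector domains), calibrated."""
    specs = {
        "ZNF": (ZNF_CONSENSUS, ZNF_VARIABLE_POSITIONS),
        "KRAB-A": (KRAB_A_CONSENSUS, KRAB_A_VARIABLE_POSITIONS),
        "KRAB-B": (KRAB_B_CONSENSUS, KRAB_B_VARIABLE_POSITIONS),
        "SCAN": (SCAN_CONSENSUS, SCAN_VARIABLE_POSITIONS),
        "BTB": (BTB_CONSENSUS, BTB_VARIABLE_POSITIONS),
    }
    profiles = {}
    for name, (consensus, variable) in specs.items():
        p = DomainProfile.from_family(name, consensus, variable)
        if calibrate:
            p.calibrate(seed=seed)
        profiles[name] = p
    return profiles


# --------------------------------------------------------------------------
# scanning


def scan_profiles(
    frames: list[Frame],
    profiles: Iterable[DomainProfile],
    e_thresholds: Optional[dict] = None,
) -> list[DomainHit]:
    """Scan translation frames with calibrated profiles.

    Every window with E <= threshold yields a hit; overlapping same-profile
    hits on one frame are reduced to the best bit score (ties: leftmost
    start).  Hit coordinates are forward-strand genomic.
    """
    thresholds = dict(DEFAULT_E_THRESHOLDS)
    if e_thresholds:
        thresholds.update(e_thresholds)
    hits: list[DomainHit] = []
    for profile in profiles:
        if not profile.calibrated:
            raise ConfigurationError(f"profile {profile.name!r} is not calibrated")
        threshold = thresholds.get(profile.name, 1e-3)
        n_searched = sum(
            max(0, len(f.aa) - profile.length + 1) for f in frames
        )
        if n_searched == 0:
            continue
        for frame in frames:
            scores = profile.window_scores(frame.aa)
            if scores.size == 0:
                continue
            evalues = profile.evalue(scores, n_searched)
            candidates = np.nonzero(evalues <= threshold)[0]
            # overlap reduction: best bit score wins, ties leftmost
            kept: list[int] = []
            for i in sorted(candidates, key=lambda i: (-scores[i], i)):
                if all(abs(i - k) >= profile.length for k in kept):
                    kept.append(i)
            for i in sorted(kept):
                start, end = frame.to_genome(i, i + profile.length)
                hits.append(
                    DomainHit(
                        profile=profile.name,
                        genome_id=frame.genome_id,
                        start=start,
                        end=end,
                        strand=frame.strand,
                        frame=frame.number,
                        aa_seq=frame.aa[i : i + profile.length],
                        bit_score=float(scores[i]),
                        e_score=float(evalues[i]),
                    )
                )
    hits.sort(key=lambda h: (h.genome_id, h.start, h.profile))
    return hits


def scan_genome_for_domains(
    genome: GenomeSequence,
    profiles: Iterable[DomainProfile],
    e_thresholds: Optional[dict] = None,
) -> list[DomainHit]:
    """Convenience wrapper: six-frame translate then scan."""
    return scan_profiles(six_frame_translate(genome), profiles, e_thresholds)


def merge_hit_sources(
    internal: Iterable[DomainHit], external: Iterable[DomainHit]
) -> list[DomainHit]:
    """Deduplicate internal + external hit lists.

    Hits identical in (profile, genome, interval, strand) appear once with
    the lower E (and higher bit score); output is sorted by (genome, start).
    """
    best: dict = {}
    for h in list(internal) + list(external):
        key = (h.genome_id, h.profile, h.start, h.end, h.strand)
        prev = best.get(key)
        if prev is None or h.e_score < prev.e_score:
            best[key] = h
    merged = sorted(best.values(), key=lambda h: (h.genome_id, h.start, h.profile))
    return merged
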