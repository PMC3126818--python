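"""Zinc-finger DNA-binding motif prediction, degenerate genome scanning,
nearest-gene assignment and co-expression testing.

Each functional finger contacts three adjacent nucleotides through the four
recognition-helix residues (positions -1, 2, 3, 6).  The default model is a
transparent deterministic recognition code (Zif268-style): helix position 6
specifies the 5' base of the finger's triplet, position 3 the middle base
and position -1 the 3' base; position 2 contacts the opposite strand of the
neighbouring subsite and contributes no base here.  Residues without a
preference in the code emit N.  Any learned contact->triplet model can be
plugged in instead via the same interface.
"""
from __future__ import annotations

import itertools
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .model import (
    BindingMotif,
    CoexpressionResult,
    GenomeSequence,
    IntervalRecord,
    IUPAC_BASES,
    MotifMatch,
    MotifSequence,
)

#: per-residue base preferences of the default recognition code
DEFAULT_RESIDUE_CODE = {
    "R": "G",  # arginine - guanine (bidentate H-bond)
    "K": "G",
    "H": "G",
    "N": "A",  # asparagine - adenine
    "Q": "A",
    "D": "C",
    "E": "C",
    "S": "T",
    "T": "T",
}


class RecognitionCode:
    """Deterministic contact-signature -> triplet model.

    ``signature`` is the 4-residue contact string ordered by helix positions
    (-1, 2, 3, 6).  The triplet is emitted 5'->3' from positions (6, 3, -1).
    Unknown residues fall back to N; a fully unknown signature yields 'NNN'.
    """

    def __init__(self, residue_code: Optional[dict] = None):
        self.residue_code = dict(DEFAULT_RESIDUE_CODE if residue_code is None
                                 else residue_code)

    def triplet(self, signature: str) -> str:
        if len(signature) != 4:
            return "NNN"
        pos_m1, _, pos3, pos6 = signature
        return "".join(
            self.residue_code.get(res, "N") for res in (pos6, pos3, pos_m1)
        )


class SignatureTable:
    """Explicit signature -> triplet lookup (e.g. from a trained model)."""

    def __init__(self, table: dict):
        self.table = dict(table)

    def triplet(self, signature: str) -> str:
        return self.table.get(signature, "NNN")


def predict_binding_motif(
    fingers: MotifSequence, model=None
) -> BindingMotif:
    """Predicted IUPAC binding motif of a finger array.

    Only functional fingers contribute.  Fingers emit their triplets
    C-terminal-finger-first, so the protein's last functional finger
    specifies the 5' end of the motif (fingers bind DNA antiparallel to the
    motif orientation).  An empty/non-functional array yields an empty
    motif.
    """
    model = model or RecognitionCode()
    functional = [m for m in fingers.motifs if m.functional]
    iupac = []
    provenance = []
    for m in reversed(functional):
        trip = model.triplet(m.contacts) if m.contacts else "NNN"
        iupac.append(trip)
        provenance.extend([m.index] * len(trip))
    return BindingMotif(iupac="".join(iupac), provenance=provenance)


# --------------------------------------------------------------------------
# degenerate genome scanning

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")

#: bitmask encoding: A=1, C=2, G=4, T=8, genome-N=16.  Motif N matches
#: everything (incl. assembly gaps); A/C/G/T classes never match genome N.
_BASE_BIT = {"A": 1, "C": 2, "G": 4, "T": 8, "N": 16}


def _motif_masks(motif: str) -> np.ndarray:
    masks = []
    for sym in motif:
        bases = IUPAC_BASES[sym]
        bit = 0
        for b in bases:
            bit |= _BASE_BIT[b]
        if sym == "N":
            bit |= 16
        masks.append(bit)
    return np.array(masks, dtype=np.uint8)


def reverse_complement_motif(motif: str) -> str:
    return motif.translate(_COMPLEMENT)[::-1]


def scan_genome(
    genome: GenomeSequence,
    motif: BindingMotif | str,
    both_strands: bool = True,
) -> list[MotifMatch]:
    """All matches of a degenerate IUPAC motif in a genome.

    Matches on the minus strand (of the reverse-complement motif) are
    reported in forward-strand coordinates.  The scan of both strands is a
    setting (default on).
    """
    pattern = motif.iupac if isinstance(motif, BindingMotif) else motif
    if not pattern:
        return []
    L = len(pattern)
    seq = genome.seq
    if len(seq) < L:
        return []
    codes = np.frombuffer(seq.encode(), dtype=np.uint8)
    bits = np.zeros(len(seq), dtype=np.uint8)
    for base, bit in _BASE_BIT.items():
        bits[codes == ord(base)] = bit

    def positions(masks: np.ndarray) -> np.ndarray:
        n = len(seq) - L + 1
        ok = np.ones(n, dtype=bool)
        for j in range(L):
            ok &= (bits[j : j + n] & masks[j]) != 0
        return np.nonzero(ok)[0]

    matches = [
        MotifMatch(genome_id=genome.id, start=int(p), end=int(p) + L, strand="+")
        for p in positions(_motif_masks(pattern))
    ]
    if both_strands:
        rc = reverse_complement_motif(pattern)
        matches += [
            MotifMatch(genome_id=genome.id, start=int(p), end=int(p) + L, strand="-")
            for p in positions(_motif_masks(rc))
        ]
    matches.sort(key=lambda m: (m.start, m.strand))
    return matches


# --------------------------------------------------------------------------
# nearest-gene assignment


def _tss(gene: IntervalRecord) -> int:
    return gene.start if gene.strand == "+" else gene.end - 1


def assign_nearest_gene(
    matches: Iterable[MotifMatch], genes: Sequence[IntervalRecord]
) -> dict:
    """Assign each match to the closest gene.

    Distance is 0 for a match overlapping the gene body, otherwise the
    absolute distance from the match midpoint to the gene TSS.  Ties are
    broken by distance to the gene body, then by lexicographic gene id.
    Returns match index -> gene id (misses absent when no genes given).
    """
    genes = list(genes)
    out: dict = {}
    for mi, m in enumerate(matches):
        best = None
        mid = (m.start + m.end) // 2
        for g in genes:
            if g.seqid != m.genome_id:
                continue
            gid = g.attributes.get("ID", g.attributes.get("name", f"{g.seqid}:{g.start}"))
            overlapping = m.start < g.end and g.start < m.end
            tss_dist = 0 if overlapping else abs(mid - _tss(g))
            body_dist = 0 if overlapping else max(g.start - m.end + 1, m.start - g.end + 1, 0)
            key = (tss_dist, body_dist, gid)
            if best is None or key < best:
                best = key
        if best is not None:
            out[mi] = best[2]
    return out


# --------------------------------------------------------------------------
# co-expression


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _rank_rho(x: np.ndarray, y: np.ndarray) -> Optional[float]:
    rx, ry = _midranks(x), _midranks(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return None
    return float(np.corrcoef(rx, ry)[0, 1])


def spearman_midrank(
    x: Sequence[float], y: Sequence[float], exact_max_n: int = 8
) -> tuple:
    """Spearman rho via Pearson on mid-ranks; exact permutation p for small n.

    Returns (rho, p); rho is None (p None) for constant input.  For
    n <= exact_max_n the two-sided p enumerates all permutations of one
    vector; larger n uses the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("vectors must be the same length")
    n = len(x)
    if n < 3:
        raise ValueError("need at least three shared samples")
    rho = _rank_rho(x, y)
    if rho is None:
        return None, None
    if n <= exact_max_n:
        ry = _midranks(y)
        count = 0
        total = 0
        observed = abs(rho)
        for perm in itertools.permutations(range(n)):
            r = _rank_rho(x, ry[list(perm)])
            total += 1
            if r is not None and abs(r) >= observed - 1e-12:
                count += 1
        p = count / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


def bonferroni(p: float, n_tests: int) -> float:
    return min(1.0, p * n_tests)


def coexpression(
    expr, focal: str, candidates: Sequence[str], exact_max_n: int = 8
) -> list[CoexpressionResult]:
    """Spearman co-expression of *focal* with each candidate gene.

    *expr* is a DataFrame (genes x samples).  Samples missing in either gene
    are dropped; fewer than three shared samples or a constant vector makes
    a candidate not-testable.  P-values are Bonferroni-adjusted over the
    candidate list.
    """
    results = []
    n_tests = len(candidates)
    fx = expr.loc[focal]
    for gene in candidates:
        gy = expr.loc[gene]
        mask = fx.notna() & gy.notna()
        n = int(mask.sum())
        if n < 3:
            results.append(CoexpressionResult(gene, None, None, None, n, False))
            continue
        rho, p = spearman_midrank(fx[mask].values, gy[mask].values, exact_max_n)
        if rho is None:
            results.append(CoexpressionResult(gene, None, None, None, n, False))
        else:
            results.append(
                CoexpressionResult(gene, rho, p, bonferroni(p, n_tests), n, True)
            )
    return results
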