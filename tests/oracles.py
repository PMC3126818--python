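"""Independent oracles for the test suite.

Everything here is deliberately written without reference to the package's
own dynamic programs / vectorised scanners, so tests compare two independent
routes to the same quantity.
"""
from __future__ import annotations

import math
import re

#: the standard genetic code, written out so translation checks do not share
#: a code path with the implementation
CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L", "TCT": "S", "TCC": "S",
    "TCA": "S", "TCG": "S", "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W", "CTT": "L", "CTC": "L",
    "CTA": "L", "CTG": "L", "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q", "CGT": "R", "CGC": "R",
    "CGA": "R", "CGG": "R", "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T", "AAT": "N", "AAC": "N",
    "AAA": "K", "AAG": "K", "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V", "GCT": "A", "GCC": "A",
    "GCA": "A", "GCG": "A", "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def translate_frame(dna: str, frame: int) -> str:
    """Translate one of the six frames (1-3 forward, 4-6 reverse)."""
    if frame >= 4:
        dna = "".join(_COMP[b] for b in reversed(dna))
    offset = (frame - 1) % 3
    out = []
    for i in range(offset, len(dna) - 2, 3):
        codon = dna[i : i + 3]
        out.append(CODON_TABLE.get(codon, "X") if "N" not in codon else "X")
    return "".join(out)


def brute_force_align_score(seq_a, seq_b, params) -> float:
    """Exhaustive enumeration over all monotone affine-gap alignments.

    A gap run of length L costs open + (L-1) * extend; paired columns score
    the motif similarity sum.  Exponential: only for short sequences.
    """
    from znf.aligner import motif_similarity

    n, m = len(seq_a.motifs), len(seq_b.motifs)
    S = [
        [motif_similarity(a, b, params.matrix) for b in seq_b.motifs]
        for a in seq_a.motifs
    ]
    open_, ext = params.gap_open, params.gap_extend
    best = [-math.inf]

    def walk(i: int, j: int, last: str, acc: float) -> None:
        if i == n and j == m:
            if acc > best[0]:
                best[0] = acc
            return
        if i < n and j < m:
            walk(i + 1, j + 1, "M", acc + S[i][j])
        if i < n:
            cost = ext if last == "A" else open_
            walk(i + 1, j, "A", acc - cost)
        if j < m:
            cost = ext if last == "B" else open_
            walk(i, j + 1, "B", acc - cost)

    walk(0, 0, "M", 0.0)
    return best[0]


def fisher_exact_enumeration(table) -> float:
    """Two-sided Fisher exact p by full hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def log_fact(k):
        return math.lgamma(k + 1)

    def log_prob(x):
        # P(table with margins fixed and top-left = x)
        y, z, w = r1 - x, c1 - x, r2 - (c1 - x)
        if min(y, z, w) < 0:
            return None
        return (
            log_fact(r1) + log_fact(r2) + log_fact(c1) + log_fact(n - c1)
            - log_fact(n) - log_fact(x) - log_fact(y) - log_fact(z) - log_fact(w)
        )

    obs = log_prob(a)
    total = 0.0
    for x in range(0, min(r1, c1) + 1):
        lp = log_prob(x)
        if lp is not None and lp <= obs + 1e-9:
            total += math.exp(lp)
    return min(1.0, total)


IUPAC_REGEX = {
    "A": "A", "C": "C", "G": "G", "T": "T", "R": "[AG]", "Y": "[CT]",
    "S": "[CG]", "W": "[AT]", "K": "[GT]", "M": "[AC]", "B": "[CGT]",
    "D": "[AGT]", "H": "[ACT]", "V": "[ACG]", "N": "[ACGTN]",
}

_MOTIF_COMP = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def regex_match_positions(seq: str, motif: str) -> list:
    pattern = "".join(IUPAC_REGEX[s] for s in motif)
    return [m.start() for m in re.finditer(f"(?=({pattern}))", seq)]


def regex_scan_both_strands(seq: str, motif: str) -> int:
    fwd = regex_match_positions(seq, motif)
    rc_motif = motif.translate(_MOTIF_COMP)[::-1]
    rev = regex_match_positions(seq, rc_motif)
    return len(fwd) + len(rev)


def single_linkage_intervals(intervals, max_gap: int) -> list:
    """Brute-force single-linkage grouping of (start, end) intervals."""
    order = sorted(range(len(intervals)), key=lambda i: intervals[i])
    groups = []
    for idx in order:
        placed = False
        for g in groups:
            if any(
                intervals[idx][0] - intervals[j][1] <= max_gap
                and intervals[j][0] - intervals[idx][1] <= max_gap
                for j in g
            ):
                g.append(idx)
                placed = True
                break
        if not placed:
            groups.append([idx])
    # merge transitively
    merged = True
    while merged:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                if any(
                    intervals[x][0] - intervals[y][1] <= max_gap
                    and intervals[y][0] - intervals[x][1] <= max_gap
                    for x in groups[i]
                    for y in groups[j]
                ):
                    groups[i] += groups[j]
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
    return [sorted(g) for g in groups]
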