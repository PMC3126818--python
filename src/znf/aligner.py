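"""Motif-level global alignment of zinc-finger arrays.

The alignment unit is a whole 28-aa finger, not a single residue: pairwise
motif similarity S(a, b) is the positionwise sum of substitution-matrix
values over the two motifs, and a Needleman-Wunsch dynamic program with
affine gap costs (opening 84**-1, extension 84**-0.9, with 84 the
nucleotide length of a finger unit) finds the maximum-score monotone
alignment.  The outcome depends only on the motif protein sequences.

The published penalties are tiny relative to substitution-matrix sums and
extension exceeds opening; they are implemented literally as printed and act
mainly as deterministic tie-breakers.
"""
from __future__ import annotations

from typing import Optional

from .model import (
    AlignColumn,
    AlignerParams,
    MotifAlignment,
    MotifSequence,
    SubstitutionMatrix,
    ZnfMotif,
)

NEG_INF = float("-inf")


def motif_similarity(a: ZnfMotif, b: ZnfMotif, matrix: SubstitutionMatrix) -> float:
    """S(a, b) = sum over aligned positions of the substitution score.

    Positions absent in a degenerate (short) motif contribute 0; the score
    is symmetric.  Residues outside the matrix alphabet raise KeyError.
    """
    n = min(len(a.seq), len(b.seq))
    return float(sum(matrix.score(a.seq[p], b.seq[p]) for p in range(n)))


def _gap_cost(run_length: int, params: AlignerParams) -> float:
    """Affine cost of one maximal gap run: open + (len-1) * extend."""
    if run_length <= 0:
        return 0.0
    return params.gap_open + (run_length - 1) * params.gap_extend


def align_motif_sequences(
    a: MotifSequence, b: MotifSequence, params: AlignerParams
) -> MotifAlignment:
    """Global maximum-score monotone alignment of two motif sequences.

    Ties in the dynamic program are broken by preferring a paired column
    over a gap-in-B ('gap_b', motif of A unmatched) over a gap-in-A
    ('gap_a'), which makes the traceback deterministic.  Empty sequences
    yield an all-gap alignment.
    """
    n, m = len(a.motifs), len(b.motifs)
    S = [
        [motif_similarity(ai, bj, params.matrix) for bj in b.motifs]
        for ai in a.motifs
    ]
    open_, ext = params.gap_open, params.gap_extend

    # Gotoh three-state DP: M ends in a pair, X ends in a gap consuming a
    # motif of A (gap-in-B), Y ends in a gap consuming a motif of B.
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    # traceback: which predecessor state fed each cell
    ptrM = [[None] * (m + 1) for _ in range(n + 1)]
    ptrX = [[None] * (m + 1) for _ in range(n + 1)]
    ptrY = [[None] * (m + 1) for _ in range(n + 1)]

    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -_gap_cost(i, params)
        ptrX[i][0] = "X" if i > 1 else "M"
    for j in range(1, m + 1):
        Y[0][j] = -_gap_cost(j, params)
        ptrY[0][j] = "Y" if j > 1 else "M"

    def best(options):
        # options: list of (score, state_label) in preference order
        top = max(s for s, _ in options)
        for s, label in options:
            if s == top:
                return s, label
        raise AssertionError

    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s, lab = best(
                [
                    (M[i - 1][j - 1], "M"),
                    (X[i - 1][j - 1], "X"),
                    (Y[i - 1][j - 1], "Y"),
                ]
            )
            M[i][j] = s + S[i - 1][j - 1]
            ptrM[i][j] = lab
            s, lab = best(
                [(M[i - 1][j] - open_, "M"), (X[i - 1][j] - ext, "X"),
                 (Y[i - 1][j] - open_, "Y")]
            )
            X[i][j] = s
            ptrX[i][j] = lab
            s, lab = best(
                [(M[i][j - 1] - open_, "M"), (X[i][j - 1] - open_, "X"),
                 (Y[i][j - 1] - ext, "Y")]
            )
            Y[i][j] = s
            ptrY[i][j] = lab
    if n == 0 and m == 0:
        return MotifAlignment(columns=[], score=0.0, params=params,
                              a_id=a.id, b_id=b.id)

    score, state = best([(M[n][m], "M"), (X[n][m], "X"), (Y[n][m], "Y")])
    columns: list[AlignColumn] = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == "M":
            columns.append(
                AlignColumn(kind="pair", i=i, j=j, score=S[i - 1][j - 1])
            )
            state = ptrM[i][j]
            i, j = i - 1, j - 1
        elif state == "X":
            columns.append(AlignColumn(kind="gap_b", i=i))
            state = ptrX[i][j]
            i -= 1
        else:
            columns.append(AlignColumn(kind="gap_a", j=j))
            state = ptrY[i][j]
            j -= 1
    columns.reverse()
    return MotifAlignment(
        columns=columns, score=float(score), params=params, a_id=a.id, b_id=b.id
    )


def call_finger_events(
    alignment: MotifAlignment,
    a: Optional[MotifSequence] = None,
    b: Optional[MotifSequence] = None,
) -> dict:
    """Summarise an alignment into candidate finger gains/losses/changes.

    Returns a dict with 'only_in_a'/'only_in_b' (1-based motif indices in
    gap columns) and 'changed' (list of (i, j, sequence_changed,
    contact_changed) for paired columns; the change flags require the motif
    sequences to be supplied).
    """
    only_in_a = [c.i for c in alignment.columns if c.kind == "gap_b"]
    only_in_b = [c.j for c in alignment.columns if c.kind == "gap_a"]
    changed = []
    if a is not None and b is not None:
        for c in alignment.columns:
            if c.kind != "pair":
                continue
            ma, mb = a.motifs[c.i - 1], b.motifs[c.j - 1]
            seq_changed = ma.seq != mb.seq
            contact_changed = (
                ma.contacts is not None
                and mb.contacts is not None
                and ma.contacts != mb.contacts
            )
            if seq_changed or contact_changed:
                changed.append((c.i, c.j, seq_changed, contact_changed))
    return {"only_in_a": only_in_a, "only_in_b": only_in_b, "changed": changed}
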