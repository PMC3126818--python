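"""Readers and writers for the external formats the toolkit touches.

Everything is converted to the internal convention (0-based, half-open,
forward strand) on read and back to the on-disk convention on write:
GFF3 is 1-based inclusive on disk, BED and mapping tables are 0-based
half-open.
"""
from __future__ import annotations

from typing import Iterable, Optional

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices

from .model import (
    DNA_ALPHABET,
    DomainHit,
    FormatError,
    GenomeSequence,
    IntervalRecord,
    MappingRow,
    SubstitutionMatrix,
)

# --------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list[GenomeSequence]:
    """Read a DNA FASTA file.

    Sequences are uppercased; any character outside {A,C,G,T,N} (including U:
    this is a DNA-only reader) is a format error naming the record and offset.
    Species labels are taken from an id prefix "<species>_" when present.
    """
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - DNA_ALPHABET
        if bad:
            pos = min(seq.index(b) for b in bad)
            raise FormatError(
                f"illegal character {seq[pos]!r} at position {pos + 1} of "
                f"record {rec.id!r}"
            )
        species = rec.id.split("_", 1)[0] if "_" in rec.id else ""
        records.append(GenomeSequence(id=rec.id, seq=seq, species=species))
    return records


def write_fasta(seqs: Iterable[GenomeSequence], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n")
            for i in range(0, len(s.seq), width):
                fh.write(s.seq[i : i + width] + "\n")
            if not s.seq:
                fh.write("\n")


# --------------------------------------------------------------------------
# substitution matrices


def _wrap_matrix(arr, name: str) -> SubstitutionMatrix:
    alphabet = "".join(arr.alphabet)
    return SubstitutionMatrix(alphabet, np.asarray(arr), name=name)


def read_matrix(path) -> SubstitutionMatrix:
    """Read an NCBI-format substitution matrix (e.g. a BLOSUM85 file).

    The matrix must be square, complete over its alphabet and symmetric.
    """
    try:
        arr = substitution_matrices.read(str(path))
    except Exception as exc:  # malformed/incomplete file
        raise FormatError(f"cannot parse substitution matrix: {exc}") from exc
    m = _wrap_matrix(arr, name=str(path))
    missing = [a for a in "ACDEFGHIKLMNPQRSTVWY" if a not in m]
    if missing:
        raise FormatError(f"matrix is missing amino acid(s) {missing}")
    return m


def write_matrix(matrix: SubstitutionMatrix, path) -> None:
    """Write a matrix in NCBI square-matrix text format."""
    alphabet = matrix.alphabet
    with open(path, "w") as fh:
        fh.write("   " + "  ".join(alphabet) + "\n")
        for a in alphabet:
            row = " ".join(f"{int(matrix.score(a, b)):3d}" for b in alphabet)
            fh.write(f"{a} {row}\n")


def blosum85() -> SubstitutionMatrix:
    """The default BLOSUM85 matrix (loaded from biotite's distributed file)."""
    import biotite.sequence as _bseq
    import biotite.sequence.align as _balign

    m = _balign.SubstitutionMatrix(
        _bseq.ProteinSequence.alphabet, _bseq.ProteinSequence.alphabet, "BLOSUM85"
    )
    alphabet = "".join(m.get_alphabet1())
    return SubstitutionMatrix(alphabet, m.score_matrix(), name="BLOSUM85")


# --------------------------------------------------------------------------
# HMMER domtblout

#: columns of a domtblout row we rely on (whitespace-delimited)
_DOMTBL_MIN_COLUMNS = 23


def _parse_frame_target(target: str) -> tuple[str, int]:
    if "|frame" not in target:
        raise FormatError(
            f"target id {target!r} does not follow the '<seqid>|frame<1..6>' scheme"
        )
    seqid, _, frame_s = target.rpartition("|frame")
    try:
        frame = int(frame_s)
    except ValueError:
        raise FormatError(f"bad frame in target id {target!r}") from None
    if not 1 <= frame <= 6:
        raise FormatError(f"frame must be 1..6 in target id {target!r}")
    return seqid, frame


def aa_window_to_genome(
    aa_start: int, aa_end: int, frame: int, genome_length: int
) -> tuple[int, int]:
    """Map a half-open aa window of a translation frame to forward-strand nt.

    Frames 1-3 are forward with offsets 0-2, frames 4-6 the reverse
    complement with offsets 0-2.
    """
    offset = (frame - 1) % 3
    if frame <= 3:
        return offset + 3 * aa_start, offset + 3 * aa_end
    return (
        genome_length - (offset + 3 * aa_end),
        genome_length - (offset + 3 * aa_start),
    )


def read_domtblout(
    path, genome_lengths: Optional[dict] = None
) -> list[DomainHit]:
    """Ingest HMMER domtblout-dialect hits.

    Target ids must encode the frame as ``<seqid>|frame<1..6>``.  Alignment
    coordinates (1-based inclusive residues on the frame) are converted to
    0-based half-open forward-strand genome coordinates.  For reverse frames
    the genome length is taken from *genome_lengths* when provided, else
    reconstructed as ``offset + 3 * tlen`` (exact up to the frame remainder).
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < _DOMTBL_MIN_COLUMNS:
                raise FormatError(
                    f"line {lineno}: expected >= {_DOMTBL_MIN_COLUMNS} columns, "
                    f"got {len(parts)}"
                )
            target, query = parts[0], parts[3]
            try:
                tlen = int(parts[2])
                i_evalue = float(parts[12])
                score = float(parts[13])
                ali_from, ali_to = int(parts[17]), int(parts[18])
            except ValueError as exc:
                raise FormatError(f"line {lineno}: {exc}") from None
            if i_evalue < 0:
                raise FormatError(f"line {lineno}: negative E-value")
            seqid, frame = _parse_frame_target(target)
            offset = (frame - 1) % 3
            if genome_lengths and seqid in genome_lengths:
                glen = genome_lengths[seqid]
            else:
                glen = offset + 3 * tlen
            start, end = aa_window_to_genome(ali_from - 1, ali_to, frame, glen)
            hits.append(
                DomainHit(
                    profile=query,
                    genome_id=seqid,
                    start=start,
                    end=end,
                    strand="+" if frame <= 3 else "-",
                    frame=frame,
                    aa_seq="X" * (ali_to - ali_from + 1),
                    bit_score=score,
                    e_score=i_evalue,
                )
            )
    return hits


# --------------------------------------------------------------------------
# GFF3 / BED

_GFF_COLUMNS = ("source", "type", "score", "phase")


def read_gff3(path) -> list[IntervalRecord]:
    """Read GFF3 features; on-disk 1-based inclusive -> internal [start, end).

    The source/type/score/phase columns are preserved under reserved
    attribute keys; column-9 attribute keys are preserved verbatim.
    """
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise FormatError(f"line {lineno}: expected 9 columns")
            seqid, source, ftype, start_s, end_s, score, strand, phase, attrs = parts
            try:
                start1, end1 = int(start_s), int(end_s)
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            if start1 < 1 or end1 < start1:
                raise FormatError(f"line {lineno}: coordinate inversion")
            attributes = {"source": source, "type": ftype, "score": score, "phase": phase}
            if attrs and attrs != ".":
                for item in attrs.split(";"):
                    if not item:
                        continue
                    key, _, value = item.partition("=")
                    attributes[key] = value
            strand = strand if strand in ("+", "-") else "+"
            records.append(
                IntervalRecord(seqid, start1 - 1, end1, strand, attributes)
            )
    return records


def write_gff3(records: Iterable[IntervalRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = {k: v for k, v in r.attributes.items() if k not in _GFF_COLUMNS}
            col9 = ";".join(f"{k}={v}" for k, v in attrs.items()) or "."
            fh.write(
                "\t".join(
                    [
                        r.seqid,
                        r.attributes.get("source", "znf"),
                        r.attributes.get("type", "region"),
                        str(r.start + 1),
                        str(r.end),
                        r.attributes.get("score", "."),
                        r.strand,
                        r.attributes.get("phase", "."),
                        col9,
                    ]
                )
                + "\n"
            )


def read_bed(path) -> list[IntervalRecord]:
    """Read BED (already 0-based half-open on disk)."""
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"line {lineno}: expected >= 3 BED columns")
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            if start > end:
                raise FormatError(f"line {lineno}: coordinate inversion")
            attributes = {}
            if len(parts) > 3:
                attributes["name"] = parts[3]
            if len(parts) > 4:
                attributes["score"] = parts[4]
            strand = parts[5] if len(parts) > 5 and parts[5] in ("+", "-") else "+"
            records.append(IntervalRecord(parts[0], start, end, strand, attributes))
    return records


def write_bed(records: Iterable[IntervalRecord], path) -> None:
    with open(path, "w") as fh:
        for r in records:
            name = r.attributes.get("name", ".")
            score = r.attributes.get("score", "0")
            fh.write(f"{r.seqid}\t{r.start}\t{r.end}\t{name}\t{score}\t{r.strand}\n")


# --------------------------------------------------------------------------
# TSV tables


def read_tsv_matrix(path) -> pd.DataFrame:
    """Read a TSV expression matrix (rows = genes, columns = samples)."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_mapping_table(path) -> list[MappingRow]:
    """Read a liftover-style mapping table.

    Columns: source seq, start, end, strand, target seq, start, end, strand
    (0-based half-open).  A header line starting with 'src' is allowed.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#") or line.startswith("src"):
                continue
            parts = line.split("\t")
            if len(parts) != 8:
                raise FormatError(f"line {lineno}: expected 8 columns")
            try:
                row = MappingRow(
                    parts[0], int(parts[1]), int(parts[2]), parts[3],
                    parts[4], int(parts[5]), int(parts[6]), parts[7],
                )
            except ValueError:
                raise FormatError(f"line {lineno}: non-integer coordinates") from None
            if row.src_start > row.src_end or row.dst_start > row.dst_end:
                raise FormatError(f"line {lineno}: coordinate inversion")
            rows.append(row)
    return rows


def write_mapping_table(rows: Iterable[MappingRow], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "src_seq\tsrc_start\tsrc_end\tsrc_strand\t"
            "dst_seq\tdst_start\tdst_end\tdst_strand\n"
        )
        for r in rows:
            fh.write(
                f"{r.src_seq}\t{r.src_start}\t{r.src_end}\t{r.src_strand}\t"
                f"{r.dst_seq}\t{r.dst_start}\t{r.dst_end}\t{r.dst_strand}\n"
            )
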