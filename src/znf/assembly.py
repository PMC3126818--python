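"""Assembly of domain hits into KZNF loci, ORF determination and
gene/pseudogene classification.

The annotation rules are: a same-strand chain of domain hits becomes a locus
iff it contains a KRAB-A hit below the E threshold (1e-6) or a tandem array
of >= 3 zinc fingers with < 100 bp adjacent gaps; SCAN/BTB effectors never
qualify a chain on their own.  Modular architecture (effector exons 5' of the
single ZNF-array exon) is enforced by splitting chains where an effector hit
lies 3' of a zinc-finger run.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

from Bio.Seq import Seq

from .model import (
    CONTACT_OFFSETS_FROM_HIS,
    EFFECTOR_DOMAINS,
    DomainHit,
    GenomeSequence,
    Locus,
    MotifSequence,
    OrfBlock,
    ZNF_CYS_OFFSETS,
    ZNF_HIS_OFFSETS,
    ZNF_UNIT_LENGTH,
    ZnfMotif,
)

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


@dataclass
class PipelineConfig:
    """Thresholds of the annotation pipeline.

    ``krab_e_threshold``, ``znf_adjacent_max_gap``, ``min_znf_count``,
    ``gene_min_orf``, ``pseudo_max_len`` and ``pseudo_stop_window`` are the
    published annotation rules; the chaining gaps are configurable defaults.
    """

    krab_e_threshold: float = 1e-6
    znf_adjacent_max_gap: int = 100  # bp, gap end->start between fingers
    min_znf_count: int = 3
    gene_min_orf: int = 200  # aa
    pseudo_max_len: int = 150  # aa
    pseudo_stop_window: int = 600  # nt of the annotated coding region
    intra_locus_max_gap: int = 40_000  # bp
    cluster_max_gap: int = 500_000  # bp

    def __post_init__(self) -> None:
        for name in (
            "krab_e_threshold",
            "znf_adjacent_max_gap",
            "min_znf_count",
            "gene_min_orf",
            "pseudo_max_len",
            "pseudo_stop_window",
            "intra_locus_max_gap",
            "cluster_max_gap",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.pseudo_max_len >= self.gene_min_orf:
            raise ValueError("pseudo_max_len must be below gene_min_orf")


def _transcript_order(hits: list[DomainHit], strand: str) -> list[DomainHit]:
    """Hits in 5'->3' transcript order."""
    return sorted(hits, key=lambda h: h.start, reverse=(strand == "-"))


def _genomic_gap(a: DomainHit, b: DomainHit) -> int:
    """Gap (bp) between two hits in genomic coordinates (half-open)."""
    lo, hi = (a, b) if a.start <= b.start else (b, a)
    return max(0, hi.start - lo.end)


def _znf_runs(ordered: list[DomainHit], cfg: PipelineConfig) -> list[list[DomainHit]]:
    """Maximal runs of adjacent ZNF hits (gap < znf_adjacent_max_gap)."""
    runs: list[list[DomainHit]] = []
    current: list[DomainHit] = []
    for h in ordered:
        if h.profile != "ZNF":
            continue
        if current and _genomic_gap(current[-1], h) >= cfg.znf_adjacent_max_gap:
            runs.append(current)
            current = []
        current.append(h)
    if current:
        runs.append(current)
    return runs


def _qualifying_arrays(ordered, cfg):
    return [r for r in _znf_runs(ordered, cfg) if len(r) >= cfg.min_znf_count]


def _split_on_order(ordered: list[DomainHit]) -> list[list[DomainHit]]:
    """Enforce the modular-architecture rule.

    Walking 5'->3', an effector hit after a zinc finger starts a new chain
    (ZNF arrays are 3' of all effector exons); similarly a KRAB-A after
    another KRAB-type exon starts a new chain (KRAB-A is the 5'-most KRAB
    exon).
    """
    segments: list[list[DomainHit]] = []
    current: list[DomainHit] = []
    seen_znf = False
    seen_other_krab = False
    for h in ordered:
        is_effector = h.profile in EFFECTOR_DOMAINS
        violation = current and (
            (is_effector and seen_znf)
            or (h.profile == "KRAB-A" and seen_other_krab)
        )
        if violation:
            segments.append(current)
            current = []
            seen_znf = False
            seen_other_krab = False
        current.append(h)
        if h.profile == "ZNF":
            seen_znf = True
        elif h.profile.startswith("KRAB") and h.profile != "KRAB-A":
            seen_other_krab = True
    if current:
        segments.append(current)
    return segments


def assemble_loci(
    hits: Iterable[DomainHit], cfg: Optional[PipelineConfig] = None
) -> list[Locus]:
    """Assemble deduplicated domain hits into loci.

    Same-strand hits within ``intra_locus_max_gap`` are chained; chains are
    split at domain-order violations; a chain becomes a locus iff it has a
    strong KRAB-A hit or a qualifying ZNF array.
    """
    cfg = cfg or PipelineConfig()
    groups: dict = {}
    for h in hits:
        groups.setdefault((h.genome_id, h.strand), []).append(h)
    loci = []
    counter: dict = {}
    for (genome_id, strand), group in sorted(groups.items()):
        group.sort(key=lambda h: h.start)
        # chain by genomic proximity
        chains: list[list[DomainHit]] = []
        for h in group:
            if chains and h.start - chains[-1][-1].end <= cfg.intra_locus_max_gap:
                chains[-1].append(h)
            else:
                chains.append([h])
        for chain in chains:
            ordered = _transcript_order(chain, strand)
            for segment in _split_on_order(ordered):
                strong_krab = any(
                    h.profile == "KRAB-A" and h.e_score < cfg.krab_e_threshold
                    for h in segment
                )
                arrays = _qualifying_arrays(segment, cfg)
                if not strong_krab and not arrays:
                    continue
                n = counter.get(genome_id, 0) + 1
                counter[genome_id] = n
                species = genome_id.split("_", 1)[0] if "_" in genome_id else genome_id
                loci.append(
                    Locus(
                        id=f"{genome_id}:{n:03d}",
                        species=species,
                        genome_id=genome_id,
                        strand=strand,
                        hits=segment,
                    )
                )
    loci.sort(key=lambda l: (l.genome_id, l.start))
    return loci


# --------------------------------------------------------------------------
# ORF extension


def _extend_block_forward(seq: str, start: int, end: int, offset: int) -> tuple[int, int]:
    """Extend [start, end) 5' and 3' in frame *offset* up to (excluding) the
    first stop codon or the sequence boundary (forward strand)."""
    # snap to codon boundaries of this frame
    start -= (start - offset) % 3
    rem = (end - offset) % 3
    if rem:
        end += 3 - rem
        end = min(end, offset + 3 * ((len(seq) - offset) // 3))
    p = start - 3
    while p >= offset and seq[p : p + 3] not in STOP_CODONS:
        start = p
        p -= 3
    p = end
    while p + 3 <= len(seq) and seq[p : p + 3] not in STOP_CODONS:
        end = p + 3
        p += 3
    return start, end


def _revcomp(s: str) -> str:
    return str(Seq(s).reverse_complement())


def extend_orf(locus: Locus, genome: GenomeSequence) -> Locus:
    """Extend the domain-coding blocks to the flanking stop codons.

    Hits are grouped into consecutive same-frame blocks (5'->3'); each block
    is extended 5' and 3' until the next in-frame stop (or sequence end) and
    the block translations are concatenated 5'->3'.  ``cds_aa`` is the
    translation of the full annotated coding span of each block chain (it may
    contain internal stops between blocks), ``orf_aa`` its longest stop-free
    stretch.
    """
    if locus.end > len(genome.seq) or locus.start < 0:
        raise ValueError(f"locus {locus.id} outside genome bounds")
    ordered = _transcript_order(locus.hits, locus.strand)
    blocks: list[list[DomainHit]] = []
    for h in ordered:
        if blocks and blocks[-1][-1].frame == h.frame:
            blocks[-1].append(h)
        else:
            blocks.append([h])

    seq = genome.seq
    L = len(seq)
    orf_blocks = []
    for block in blocks:
        frame = block[0].frame
        offset = (frame - 1) % 3
        b_start = min(h.start for h in block)
        b_end = max(h.end for h in block)
        if frame <= 3:
            s, e = _extend_block_forward(seq, b_start, b_end, offset)
            aa = _translate_span(seq, s, e)
            orf_blocks.append(OrfBlock(start=s, end=e, frame=frame, aa_seq=aa))
        else:
            rc = _revcomp(seq)
            rs, re_ = L - b_end, L - b_start
            s, e = _extend_block_forward(rc, rs, re_, offset)
            aa = _translate_span(rc, s, e)
            orf_blocks.append(OrfBlock(start=L - e, end=L - s, frame=frame, aa_seq=aa))

    locus.orf_blocks = orf_blocks
    # annotated coding region: when all blocks share a frame, translate the
    # contiguous span so stops *between* blocks stay visible to
    # classification; otherwise concatenate the block translations 5'->3'
    if len({b.frame for b in orf_blocks}) == 1:
        frame = orf_blocks[0].frame
        lo = min(b.start for b in orf_blocks)
        hi = max(b.end for b in orf_blocks)
        if frame <= 3:
            locus.cds_aa = _translate_span(seq, lo, hi)
            locus.seq = seq[lo:hi]
        else:
            rc = _revcomp(seq)
            locus.cds_aa = _translate_span(rc, L - hi, L - lo)
            locus.seq = rc[L - hi : L - lo]
    else:
        locus.cds_aa = "".join(b.aa_seq for b in orf_blocks)
        locus.seq = "".join(
            seq[b.start : b.end] if b.frame <= 3 else _revcomp(seq[b.start : b.end])
            for b in orf_blocks
        )
    locus.orf_aa = max(locus.cds_aa.split("*"), key=len) if locus.cds_aa else ""
    return locus


def _translate_span(seq: str, start: int, end: int) -> str:
    n = (end - start) - (end - start) % 3
    if n <= 0:
        return ""
    return str(Seq(seq[start : start + n]).translate())


def classify_locus(locus: Locus, cfg: Optional[PipelineConfig] = None) -> str:
    """Classify a locus with a determined ORF as gene or pseudogene.

    Gene: ORF >= 200 aa and no stop codon within the first 600 nt of the
    annotated coding region.  Everything else (including stop-free loci of
    150-199 aa) is a pseudogene, matching the published equivalence that the
    pseudogene rules "essentially mean" ORFs shorter than 200 aa.
    """
    cfg = cfg or PipelineConfig()
    window_aa = cfg.pseudo_stop_window // 3
    premature_stop = "*" in locus.cds_aa[:window_aa]
    is_gene = len(locus.orf_aa) >= cfg.gene_min_orf and not premature_stop
    locus.classification = "gene" if is_gene else "pseudogene"
    return locus.classification


# --------------------------------------------------------------------------
# finger extraction


def _functional(unit: str) -> bool:
    """A finger is functional iff both cysteines and both histidines of the
    C2H2 core are present at the canonical offsets."""
    if len(unit) < ZNF_HIS_OFFSETS[1] + 1:
        return False
    return all(unit[i] == "C" for i in ZNF_CYS_OFFSETS) and all(
        unit[i] == "H" for i in ZNF_HIS_OFFSETS
    )


def _contacts(unit: str) -> Optional[str]:
    his = ZNF_HIS_OFFSETS[0]
    positions = [his + o for o in CONTACT_OFFSETS_FROM_HIS]
    if any(p < 0 or p >= len(unit) for p in positions):
        return None
    return "".join(unit[p] for p in positions)


def extract_motif_sequence(
    locus: Locus, genome: Optional[GenomeSequence] = None
) -> MotifSequence:
    """Extract the ordered 28-aa finger units of a locus's ZNF array.

    The array span (first to last ZNF hit, transcript orientation) is
    partitioned into consecutive 84-nt units anchored on the first hit, so
    units between detected hits (e.g. fingers degenerated by a stop or point
    mutations) are retained with their sequence.
    """
    znf = _transcript_order(locus.znf_hits, locus.strand)
    if not znf:
        return MotifSequence(id=locus.id, motifs=[])
    # runs of adjacent fingers: use the largest run as the array
    cfg = PipelineConfig()
    runs = _znf_runs(znf, cfg)
    array = max(runs, key=len)
    first = array[0]
    frame = first.frame

    if genome is not None:
        seq = genome.seq if frame <= 3 else _revcomp(genome.seq)
        L = len(genome.seq)
        if frame <= 3:
            a_start = min(h.start for h in array)
            a_end = max(h.end for h in array)
        else:
            a_start = L - max(h.end for h in array)
            a_end = L - min(h.start for h in array)
        n_units = max(1, round((a_end - a_start) / (3 * ZNF_UNIT_LENGTH)))
        units = [
            _translate_span(seq, a_start + 3 * ZNF_UNIT_LENGTH * k,
                            a_start + 3 * ZNF_UNIT_LENGTH * (k + 1))
            for k in range(n_units)
        ]
    else:
        units = [h.aa_seq for h in array]

    motifs = [
        ZnfMotif(
            seq=u,
            index=k + 1,
            functional=_functional(u),
            contacts=_contacts(u),
        )
        for k, u in enumerate(units)
        if u
    ]
    return MotifSequence(id=locus.id, motifs=motifs)


# --------------------------------------------------------------------------
# chromosomal clustering


def cluster_loci(
    loci: Iterable[Locus], cfg: Optional[PipelineConfig] = None
) -> dict:
    """Single-linkage grouping of loci on one genome within cluster_max_gap.

    Returns locus id -> cluster id ("<genome>_cl<ordinal>") and stamps each
    locus's ``cluster_id``.
    """
    cfg = cfg or PipelineConfig()
    by_genome: dict = {}
    for l in loci:
        by_genome.setdefault(l.genome_id, []).append(l)
    assignment = {}
    for genome_id, group in sorted(by_genome.items()):
        group.sort(key=lambda l: l.start)
        ordinal = 0
        prev_end = None
        for l in group:
            if prev_end is None or l.start - prev_end > cfg.cluster_max_gap:
                ordinal += 1
            prev_end = max(prev_end or 0, l.end)
            cid = f"{genome_id}_cl{ordinal}"
            l.cluster_id = cid
            assignment[l.id] = cid
    return assignment


def annotate_genome(
    genome: GenomeSequence,
    hits: Iterable[DomainHit],
    cfg: Optional[PipelineConfig] = None,
) -> list[Locus]:
    """Hits -> assembled, ORF-extended, classified, clustered loci."""
    cfg = cfg or PipelineConfig()
    loci = assemble_loci(hits, cfg)
    for l in loci:
        extend_orf(l, genome)
        classify_locus(l, cfg)
    cluster_loci(loci, cfg)
    return loci
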