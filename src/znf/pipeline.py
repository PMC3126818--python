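"""End-to-end orchestration: genomes -> loci -> orthogroups -> events.

This is the glue used by the CLI and by simulation-recovery scoring; each
step is the corresponding module's public API.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .aligner import AlignerParams
from .assembly import PipelineConfig, annotate_genome, extract_motif_sequence
from .io import blosum85
from .lineage import (
    call_gain_loss,
    call_pseudogenization,
    polarize_domain_changes,
)
from .model import GenomeSequence, SpeciesTree
from .orthology import (
    build_orthogroups,
    high_confidence,
    markov_cluster,
    pairwise_similarity,
    reciprocal_best_hits,
    synteny_orthologs,
    synteny_overlaps,
    within_species_similarity,
)
from .scan import default_profiles, scan_genome_for_domains


@dataclass
class PipelineResult:
    loci: dict  # species -> list[Locus]
    orthogroups: list
    high_confidence: list
    events: list
    motif_sequences: dict = field(default_factory=dict)  # locus id -> MotifSequence


def annotate_all(
    genomes: dict,
    cfg: Optional[PipelineConfig] = None,
    profiles: Optional[dict] = None,
) -> dict:
    """Scan + assemble + classify every genome; returns species -> loci."""
    cfg = cfg or PipelineConfig()
    profiles = profiles or default_profiles()
    loci = {}
    for sp, genome in genomes.items():
        hits = scan_genome_for_domains(genome, profiles.values())
        loci[sp] = annotate_genome(genome, hits, cfg)
    return loci


def run_pipeline(
    genomes: dict,
    mappings: Optional[dict] = None,
    cfg: Optional[PipelineConfig] = None,
    profiles: Optional[dict] = None,
    tree: Optional[SpeciesTree] = None,
    aligner_params: Optional[AlignerParams] = None,
) -> PipelineResult:
    """Full comparative analysis of a set of species genomes.

    *genomes* maps species label -> GenomeSequence; *mappings* maps ordered
    species pairs (x, y) -> liftover-style MappingRow lists (optional;
    without them synteny contributes nothing and orthogroups rest on RBH +
    clustering).
    """
    cfg = cfg or PipelineConfig()
    tree = tree or SpeciesTree()
    mappings = mappings or {}
    aligner_params = aligner_params or AlignerParams(matrix=blosum85())

    loci_by_sp = annotate_all(genomes, cfg, profiles)
    species = sorted(loci_by_sp)

    cross_edges = []
    rbh_pairs = []
    syn_pairs = []
    syn_any = []
    for i, x in enumerate(species):
        for y in species[i + 1 :]:
            edges = pairwise_similarity(loci_by_sp[x], loci_by_sp[y])
            cross_edges.extend(edges)
            rbh_pairs.extend(reciprocal_best_hits(edges))
            if (x, y) in mappings:
                syn_pairs.extend(
                    synteny_orthologs(loci_by_sp[x], loci_by_sp[y], mappings[(x, y)])
                )
                syn_any.extend(
                    synteny_overlaps(loci_by_sp[x], loci_by_sp[y], mappings[(x, y)])
                )
    within_edges = []
    for sp in species:
        within_edges.extend(within_species_similarity(loci_by_sp[sp]))

    clusters = markov_cluster(cross_edges + within_edges)
    all_loci = [l for ls in loci_by_sp.values() for l in ls]
    groups = build_orthogroups(
        all_loci,
        rbh_pairs,
        syn_pairs,
        clusters,
        edges=cross_edges,
        within_species_edges=within_edges,
        synteny_any=syn_any,
    )
    hc = high_confidence(groups)

    events = list(call_gain_loss(groups, hc, tree))
    classifications = {l.id: l.classification for l in all_loci}
    events.extend(call_pseudogenization(hc, classifications, tree))

    locus_by_id = {l.id: l for l in all_loci}
    genome_by_sp = dict(genomes)
    motif_seqs_cache = {}
    for g in hc:
        present = {sp for sp, ids in g.members.items() if len(ids) == 1}
        if len(present) < 3:
            continue
        seqs = {}
        for sp in present:
            lid = g.members[sp][0]
            if lid not in motif_seqs_cache:
                motif_seqs_cache[lid] = extract_motif_sequence(
                    locus_by_id[lid], genome_by_sp[sp]
                )
            seqs[sp] = motif_seqs_cache[lid]
        if any(len(s) == 0 for s in seqs.values()):
            continue
        events.extend(
            polarize_domain_changes(seqs, aligner_params, tree, orthogroup=g.id)
        )

    return PipelineResult(
        loci=loci_by_sp,
        orthogroups=groups,
        high_confidence=hc,
        events=events,
        motif_sequences=motif_seqs_cache,
    )


# --------------------------------------------------------------------------
# truth matching helpers (simulation studies)


def match_loci_to_truth(loci_by_sp: dict, truth) -> dict:
    """Map recovered locus id -> TruthLocus by same-genome overlap."""
    out = {}
    for sp, loci in loci_by_sp.items():
        rows = truth.loci.get(sp, [])
        for l in loci:
            best = None
            for t in rows:
                lo, hi = max(l.start, t.start), min(l.end, t.end)
                overlap = max(0, hi - lo)
                if overlap > 0 and (best is None or overlap > best[0]):
                    best = (overlap, t)
            if best is not None:
                out[l.id] = best[1]
    return out


def group_ancestral_ids(groups: list, locus_truth: dict) -> dict:
    """Majority ancestral locus id of every orthogroup."""
    out = {}
    for g in groups:
        votes: dict = {}
        for lid in g.all_loci():
            t = locus_truth.get(lid)
            if t is not None:
                votes[t.ancestral_id] = votes.get(t.ancestral_id, 0) + 1
        if votes:
            out[g.id] = max(sorted(votes), key=lambda k: votes[k])
    return out
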