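"""Cross-species ortholog assignment.

Three independent signals — reciprocal best hits on locus sequences, synteny
through liftover-style coordinate mappings, and Markov clustering of the
similarity graph — are combined by a 4-step orthogroup construction:

* step 0: pairs on which all three methods agree ("high-confidence" set);
* step 1: RBH or unique synteny pairs not contradicted by clustering;
* step 2: one-directional best hits or any synteny overlap, cluster-compatible;
* step 3: within-species best hits; every remaining locus becomes a singleton.

After step 3 every locus belongs to exactly one orthogroup (the
"all-inclusive" set).
"""
from __future__ import annotations

import logging
from typing import Callable, Iterable, Optional

import numpy as np

from .model import Locus, MappingRow, Orthogroup, SimilarityEdge

logger = logging.getLogger(__name__)

DEFAULT_KMER = 12
DEFAULT_SCORE_FLOOR = 0.05


# --------------------------------------------------------------------------
# similarity


def kmer_set(seq: str, k: int = DEFAULT_KMER) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_similarity(a: str, b: str, k: int = DEFAULT_KMER) -> float:
    """Shared k-mer count normalised by the shorter sequence's k-mer count."""
    if len(a) < k or len(b) < k:
        return 0.0
    ka, kb = kmer_set(a, k), kmer_set(b, k)
    denom = min(len(a), len(b)) - k + 1
    return len(ka & kb) / denom if denom > 0 else 0.0


def pairwise_similarity(
    loci_x: Iterable[Locus],
    loci_y: Iterable[Locus],
    scorer: Optional[Callable[[str, str], float]] = None,
    floor: float = DEFAULT_SCORE_FLOOR,
) -> list[SimilarityEdge]:
    """All above-floor edges between two locus sets, with best-hit flags.

    A locus's best hit in a direction is flagged only when it is a *unique*
    maximum (ties leave the flag unset, so they can never become RBHs).
    """
    scorer = scorer or kmer_similarity
    xs, ys = list(loci_x), list(loci_y)
    edges: list[SimilarityEdge] = []
    score_of: dict = {}
    for x in xs:
        for y in ys:
            s = scorer(x.seq, y.seq)
            if s >= floor:
                edges.append(SimilarityEdge(a=x.id, b=y.id, score=s))
                score_of[(x.id, y.id)] = s
    _flag_unique_best(edges, forward=True)
    _flag_unique_best(edges, forward=False)
    return edges


def _flag_unique_best(edges: list[SimilarityEdge], forward: bool) -> None:
    by_node: dict = {}
    for e in edges:
        key = e.a if forward else e.b
        by_node.setdefault(key, []).append(e)
    for key, node_edges in by_node.items():
        top = max(e.score for e in node_edges)
        winners = [e for e in node_edges if e.score == top]
        if len(winners) == 1:
            if forward:
                winners[0].best_ab = True
            else:
                winners[0].best_ba = True


def within_species_similarity(
    loci: Iterable[Locus],
    scorer: Optional[Callable[[str, str], float]] = None,
    floor: float = DEFAULT_SCORE_FLOOR,
) -> list[SimilarityEdge]:
    """Above-floor edges inside one species (self-pairs excluded)."""
    scorer = scorer or kmer_similarity
    ls = sorted(loci, key=lambda l: l.id)
    edges = []
    for i, x in enumerate(ls):
        for y in ls[i + 1 :]:
            s = scorer(x.seq, y.seq)
            if s >= floor:
                edges.append(SimilarityEdge(a=x.id, b=y.id, score=s))
    _flag_unique_best(edges, forward=True)
    _flag_unique_best(edges, forward=False)
    return edges


def reciprocal_best_hits(edges: Iterable[SimilarityEdge]) -> list[tuple]:
    """Pairs in which each locus is the other's unique best hit."""
    return sorted((e.a, e.b) for e in edges if e.best_ab and e.best_ba)


# --------------------------------------------------------------------------
# synteny


def _map_interval(
    start: int, end: int, rows: list[MappingRow], seqid: str
) -> Optional[tuple[str, int, int]]:
    """Liftover of [start, end) on seqid through the mapping rows.

    Overlapping rows are interpolated linearly; disjoint images (a split
    mapping) make the interval unmappable.
    """
    pieces = []
    for r in rows:
        if r.src_seq != seqid or r.src_end <= start or end <= r.src_start:
            continue
        lo, hi = max(start, r.src_start), min(end, r.src_end)
        span_src = r.src_end - r.src_start
        span_dst = r.dst_end - r.dst_start
        scale = span_dst / span_src if span_src else 1.0
        d_lo = r.dst_start + round((lo - r.src_start) * scale)
        d_hi = r.dst_start + round((hi - r.src_start) * scale)
        pieces.append((r.dst_seq, d_lo, d_hi))
    if not pieces:
        return None
    seqs = {p[0] for p in pieces}
    if len(seqs) > 1:
        return None
    return (pieces[0][0], min(p[1] for p in pieces), max(p[2] for p in pieces))


def _reciprocal_overlap(a: tuple, b: tuple) -> float:
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    inter = max(0, hi - lo)
    if inter == 0:
        return 0.0
    return min(inter / (a[1] - a[0]), inter / (b[1] - b[0]))


def synteny_orthologs(
    loci_x: Iterable[Locus],
    loci_y: Iterable[Locus],
    mapping: list[MappingRow],
    min_reciprocal_overlap: float = 0.5,
) -> list[tuple]:
    """1:1 positional pairs through a coordinate mapping.

    x pairs with y iff the lifted interval of x reciprocally overlaps y by at
    least *min_reciprocal_overlap* and the pairing is unique both ways.
    Unmappable loci are simply unpaired.
    """
    xs, ys = list(loci_x), list(loci_y)
    candidates: list[tuple] = []
    for x in xs:
        image = _map_interval(x.start, x.end, mapping, x.genome_id)
        if image is None:
            continue
        dst_seq, lo, hi = image
        for y in ys:
            if y.genome_id != dst_seq:
                continue
            if _reciprocal_overlap((lo, hi), (y.start, y.end)) >= min_reciprocal_overlap:
                candidates.append((x.id, y.id))
    x_count: dict = {}
    y_count: dict = {}
    for xid, yid in candidates:
        x_count[xid] = x_count.get(xid, 0) + 1
        y_count[yid] = y_count.get(yid, 0) + 1
    return sorted(
        (xid, yid)
        for xid, yid in candidates
        if x_count[xid] == 1 and y_count[yid] == 1
    )


def synteny_overlaps(
    loci_x: Iterable[Locus],
    loci_y: Iterable[Locus],
    mapping: list[MappingRow],
) -> list[tuple]:
    """Any-overlap (non-unique) positional support, used by step 2."""
    xs, ys = list(loci_x), list(loci_y)
    out = []
    for x in xs:
        image = _map_interval(x.start, x.end, mapping, x.genome_id)
        if image is None:
            continue
        dst_seq, lo, hi = image
        for y in ys:
            if y.genome_id == dst_seq and lo < y.end and y.start < hi:
                out.append((x.id, y.id))
    return sorted(out)


# --------------------------------------------------------------------------
# Markov clustering


def markov_cluster(
    edges: Iterable[SimilarityEdge],
    inflation: float = 2.0,
    max_iterations: int = 200,
    tolerance: float = 1e-6,
) -> list[set]:
    """In-repo MCL on the normalised similarity graph.

    Edge weights are symmetrised by averaging the two directions; self-loops
    are added with the node's maximum incident weight.  Expansion is matrix
    squaring, inflation elementwise power + column renormalisation.  Clusters
    are the attractor sets of the converged matrix; only clusters of size
    >= 2 are returned (singletons count as "not grouped").
    """
    weight: dict = {}
    nodes: set = set()
    for e in edges:
        nodes.update((e.a, e.b))
        key = tuple(sorted((e.a, e.b)))
        weight.setdefault(key, []).append(e.score)
    order = sorted(nodes)
    index = {n: i for i, n in enumerate(order)}
    n = len(order)
    if n == 0:
        return []
    A = np.zeros((n, n))
    for (a, b), scores in weight.items():
        w = float(np.mean(scores))
        i, j = index[a], index[b]
        A[i, j] = A[j, i] = max(A[i, j], w)
    np.fill_diagonal(A, 0.0)
    diag = A.max(axis=0)
    diag[diag == 0] = 1.0
    np.fill_diagonal(A, diag)
    col = A.sum(axis=0)
    col[col == 0] = 1.0
    M = A / col

    converged = False
    for _ in range(max_iterations):
        expanded = M @ M
        inflated = np.power(expanded, inflation)
        col = inflated.sum(axis=0)
        col[col == 0] = 1.0
        new = inflated / col
        if np.abs(new - M).max() < tolerance:
            M = new
            converged = True
            break
        M = new
    if not converged:
        logger.warning("MCL did not converge in %d iterations", max_iterations)

    # attractors: rows with positive diagonal mass; their support = cluster
    eps = 1e-8
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[rj] = ri

    for i in range(n):
        if M[i, i] > eps:
            for j in np.nonzero(M[i] > eps)[0]:
                union(i, int(j))
    groups: dict = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(order[i])
    return sorted(
        (g for g in groups.values() if len(g) >= 2),
        key=lambda g: sorted(g)[0],
    )


# --------------------------------------------------------------------------
# orthogroup construction


class _GroupBuilder:
    def __init__(self) -> None:
        self.assignment: dict = {}  # locus id -> group index
        self.groups: list[dict] = []  # group index -> {"members": set, "tier": str}

    def new_group(self, tier: str, members: Iterable[str]) -> int:
        gi = len(self.groups)
        self.groups.append({"members": set(), "tier": tier})
        for m in members:
            self.add(gi, m)
        return gi

    def add(self, gi: int, locus_id: str) -> None:
        if locus_id in self.assignment:
            return
        self.groups[gi]["members"].add(locus_id)
        self.assignment[locus_id] = gi

    def merge(self, gi: int, gj: int) -> int:
        if gi == gj:
            return gi
        keep, drop = sorted((gi, gj))
        for m in self.groups[drop]["members"]:
            self.assignment[m] = keep
        self.groups[keep]["members"] |= self.groups[drop]["members"]
        self.groups[drop]["members"] = set()
        return keep


def build_orthogroups(
    loci: Iterable[Locus],
    rbh_pairs: Iterable[tuple],
    synteny_pairs: Iterable[tuple],
    clusters: Iterable[set],
    edges: Iterable[SimilarityEdge] = (),
    within_species_edges: Iterable[SimilarityEdge] = (),
    synteny_any: Iterable[tuple] = (),
) -> list[Orthogroup]:
    """The 4-step tiered orthogroup construction.

    *rbh_pairs* / *synteny_pairs* are cross-species 1:1 pairs pooled over all
    species pairs; *clusters* the MCL clusters; *edges* all cross-species
    similarity edges (for one-directional best flags and conflict
    resolution); *within_species_edges* similarity edges inside one species;
    *synteny_any* non-unique positional support.  Returns all orthogroups;
    the high-confidence set is the tier ``step0_high_confidence`` subset.
    """
    loci = list(loci)
    species_of = {l.id: l.species for l in loci}
    edges = list(edges)
    within = list(within_species_edges)

    cluster_of: dict = {}
    for ci, members in enumerate(clusters):
        for m in members:
            cluster_of[m] = ci

    def same_cluster(a: str, b: str) -> bool:
        return (
            a in cluster_of and b in cluster_of and cluster_of[a] == cluster_of[b]
        )

    def cluster_compatible(a: str, b: str) -> bool:
        # same group, or at least one of the two not grouped at all
        if a not in cluster_of or b not in cluster_of:
            return True
        return cluster_of[a] == cluster_of[b]

    rbh = {tuple(sorted(p)) for p in rbh_pairs}
    syn = {tuple(sorted(p)) for p in synteny_pairs}
    syn_any = {tuple(sorted(p)) for p in synteny_any} | syn
    score_of = {tuple(sorted((e.a, e.b))): e.score for e in edges}

    builder = _GroupBuilder()

    # ---- step 0: all three methods agree
    step0_edges = sorted(rbh & syn)
    for a, b in step0_edges:
        if not same_cluster(a, b):
            continue
        ga, gb = builder.assignment.get(a), builder.assignment.get(b)
        if ga is None and gb is None:
            builder.new_group("step0_high_confidence", (a, b))
        elif ga is None:
            builder.add(gb, a)
        elif gb is None:
            builder.add(ga, b)
        else:
            builder.merge(ga, gb)

    # ---- steps 1 and 2: attach by weakening evidence
    def attach(pairs: list[tuple], tier: str) -> None:
        # deterministic: strongest similarity first, then ids
        pairs = sorted(
            pairs, key=lambda p: (-score_of.get(tuple(sorted(p)), 0.0), p)
        )
        for a, b in pairs:
            ga, gb = builder.assignment.get(a), builder.assignment.get(b)
            if ga is not None and gb is not None:
                continue  # both already placed; tiers never merge groups
            if ga is None and gb is None:
                builder.new_group(tier, (a, b))
            elif ga is None:
                builder.add(gb, a)
            else:
                builder.add(ga, b)

    step1_pairs = [
        (a, b)
        for a, b in sorted(rbh | syn)
        if cluster_compatible(a, b)
        and (a not in builder.assignment or b not in builder.assignment)
    ]
    attach(step1_pairs, "step1")

    one_way_best = {
        tuple(sorted((e.a, e.b)))
        for e in edges
        if (e.best_ab or e.best_ba) and species_of[e.a] != species_of[e.b]
    }
    step2_pairs = [
        (a, b)
        for a, b in sorted(one_way_best | syn_any)
        if cluster_compatible(a, b)
        and (a not in builder.assignment or b not in builder.assignment)
    ]
    attach(step2_pairs, "step2")

    # ---- step 3: within-species 1:1 best hits, then singletons
    within_best = {
        tuple(sorted((e.a, e.b)))
        for e in within
        if e.best_ab and e.best_ba
    }
    step3_pairs = [
        (a, b)
        for a, b in sorted(within_best)
        if cluster_compatible(a, b)
        and (a not in builder.assignment or b not in builder.assignment)
    ]
    attach(step3_pairs, "step3")
    for l in sorted(loci, key=lambda l: l.id):
        if l.id not in builder.assignment:
            builder.new_group("step3", (l.id,))

    out = []
    ordinal = 0
    for g in builder.groups:
        if not g["members"]:
            continue
        ordinal += 1
        members: dict = {}
        for lid in sorted(g["members"]):
            members.setdefault(species_of[lid], []).append(lid)
        out.append(
            Orthogroup(id=f"OG{ordinal:04d}", members=members, tier=g["tier"])
        )
    return out


def high_confidence(groups: Iterable[Orthogroup]) -> list[Orthogroup]:
    return [g for g in groups if g.tier == "step0_high_confidence"]


def relation_classes(group: Orthogroup) -> dict:
    """1:1 / 1:many / many:many per represented species pair."""
    counts = group.species_counts()
    species = sorted(counts)
    out = {}
    for i, x in enumerate(species):
        for y in species[i + 1 :]:
            cx, cy = counts[x], counts[y]
            if cx == 1 and cy == 1:
                rel = "1:1"
            elif cx == 1 or cy == 1:
                rel = "1:many"
            else:
                rel = "many:many"
            out[(x, y)] = rel
    return out
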