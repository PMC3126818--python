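"""Polarization of orthogroup composition and finger alignments onto the
primate tree (((H,C),O),R), per-My rates, Ka/Ks and supporting statistics.

Branch labels: H, C, O, R for the terminal branches, HC for the homininae
(human-chimpanzee ancestor) branch and HCO for the hominid branch.  Locus
gains on HCO are indistinguishable from losses on R (and vice versa); such
events carry an ambiguity flag listing both candidate branches.
"""
from __future__ import annotations

import itertools
import logging
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .aligner import align_motif_sequences
from .model import (
    BRANCHES,
    DIVERGENCE_MY,
    SPECIES,
    IntervalRecord,
    KaKsResult,
    LineageEvent,
    MotifSequence,
    Orthogroup,
    RateEstimate,
    SpeciesTree,
)

logger = logging.getLogger(__name__)

#: species priority used when choosing alignment references
_SPECIES_ORDER = {sp: i for i, sp in enumerate(SPECIES)}


# --------------------------------------------------------------------------
# locus gain / loss (copy-number parsimony)


def _parsimony_labelings(counts: dict) -> list[dict]:
    """All minimum-cost integer count labelings of the internal nodes.

    The tree is (((H,C)hc,O)hco,root=(hco,R)); edge cost is |parent - child|
    (each copy gained or lost is one event).  Returns the internal labelings
    {hc, hco, root} achieving the minimum total cost.
    """
    leaf = {sp: counts.get(sp, 0) for sp in SPECIES}
    max_c = max(leaf.values()) if leaf else 0
    best_cost = None
    best: list[dict] = []
    rng = range(0, max_c + 1)
    for hc, hco, root in itertools.product(rng, rng, rng):
        cost = (
            abs(hc - leaf["H"])
            + abs(hc - leaf["C"])
            + abs(hco - hc)
            + abs(hco - leaf["O"])
            + abs(root - hco)
            + abs(root - leaf["R"])
        )
        if best_cost is None or cost < best_cost:
            best_cost = cost
            best = [{"hc": hc, "hco": hco, "root": root}]
        elif cost == best_cost:
            best.append({"hc": hc, "hco": hco, "root": root})
    return best


def _events_from_labeling(counts: dict, lab: dict) -> list[tuple]:
    """(kind, branch, copies) tuples for one internal labeling."""
    deltas = [
        ("H", counts.get("H", 0) - lab["hc"]),
        ("C", counts.get("C", 0) - lab["hc"]),
        ("HC", lab["hc"] - lab["hco"]),
        ("O", counts.get("O", 0) - lab["hco"]),
        ("HCO", lab["hco"] - lab["root"]),
        ("R", counts.get("R", 0) - lab["root"]),
    ]
    events = []
    for branch, d in deltas:
        if d > 0:
            events.append(("locus_gain", branch, d))
        elif d < 0:
            events.append(("locus_loss", branch, -d))
    return events


def call_gain_loss(
    groups: Iterable[Orthogroup],
    hc_groups: Iterable[Orthogroup],
    tree: Optional[SpeciesTree] = None,
) -> list[LineageEvent]:
    """Minimal single-branch gain/loss events per orthogroup.

    Copy-number parsimony on the fixed tree explains each species count
    profile; when an HCO-gain and an R-loss (or the mirror case) are equally
    parsimonious, one event is emitted with both candidate branches.  Extra
    copies that have a 1:1 high-confidence partner are not counted as gained.
    """
    # a locus is "partnered" when its species is 1:1 within a high-confidence
    # group spanning >= 2 species; extra copies are never partnered
    hc_partnered: set = set()
    for g in hc_groups:
        if len(g.species_counts()) < 2:
            continue
        for ids in g.members.values():
            if len(ids) == 1:
                hc_partnered.update(ids)

    events: list[LineageEvent] = []
    for g in groups:
        counts = g.species_counts()
        if not counts:
            raise ValueError(f"orthogroup {g.id} is empty")
        labelings = _parsimony_labelings(counts)
        event_sets = []
        seen = set()
        for lab in labelings:
            ev = tuple(sorted(_events_from_labeling(counts, lab)))
            if ev not in seen:
                seen.add(ev)
                event_sets.append(ev)
        chosen, ambiguity = _resolve_event_sets(event_sets)
        for kind, branch, copies in chosen:
            if kind == "locus_gain" and branch in SPECIES:
                unpartnered = [
                    lid for lid in g.members.get(branch, []) if lid not in hc_partnered
                ]
                copies = min(copies, len(unpartnered))
                if copies == 0:
                    continue
            events.append(
                LineageEvent(
                    kind=kind,
                    branch=branch,
                    orthogroup=g.id,
                    count=copies,
                    ambiguous_with=ambiguity.get((kind, branch)),
                )
            )
    return events


def _resolve_event_sets(event_sets: list) -> tuple:
    """Pick the reported event set and derive R=HCO ambiguity flags.

    Two equally parsimonious sets that differ only by swapping an HCO event
    for the mirror R event collapse to the HCO version flagged 'R'.  Any
    other multi-optimum is resolved deterministically (fewest events, then
    lexicographically) — the published analysis resolved these manually.
    """
    if len(event_sets) == 1:
        return list(event_sets[0]), {}
    event_sets = sorted(event_sets, key=lambda s: (len(s), s))
    mirror = {"locus_gain": "locus_loss", "locus_loss": "locus_gain"}
    for s1, s2 in itertools.combinations(event_sets, 2):
        diff1 = set(s1) - set(s2)
        diff2 = set(s2) - set(s1)
        if len(diff1) == 1 and len(diff2) == 1:
            (k1, b1, c1), (k2, b2, c2) = next(iter(diff1)), next(iter(diff2))
            if (
                c1 == c2
                and {b1, b2} == {"HCO", "R"}
                and mirror[k1] == k2
            ):
                keep = (k1, "HCO", c1) if b1 == "HCO" else (k2, "HCO", c2)
                base = [e for e in s1 if e != (k1, b1, c1)]
                base.append(keep)
                return sorted(base), {(keep[0], "HCO"): "R"}
    return list(event_sets[0]), {}


# --------------------------------------------------------------------------
# pseudogenization


def call_pseudogenization(
    hc_groups: Iterable[Orthogroup],
    classifications: dict,
    tree: Optional[SpeciesTree] = None,
) -> list[LineageEvent]:
    """Lineage-specific pseudogenization from the high-confidence set.

    *classifications* maps locus id -> 'gene' | 'pseudogene'.  A branch event
    is called when the pseudogene state is confined to the branch's
    descendants and every other member is a gene; groups with fewer than
    three species, or unpolarizable patterns, are skipped with a log entry.
    """
    tree = tree or SpeciesTree()
    events: list[LineageEvent] = []
    for g in hc_groups:
        present = {sp for sp, ids in g.members.items() if ids}
        if len(present) < 3:
            logger.debug("orthogroup %s: <3 species, pseudogenization skipped", g.id)
            continue
        state = {}
        for sp in present:
            members = g.members[sp]
            state[sp] = (
                "pseudogene"
                if all(classifications.get(l) == "pseudogene" for l in members)
                else "gene"
            )
        pseudo = {sp for sp in present if state[sp] == "pseudogene"}
        if not pseudo or pseudo == present:
            continue
        called = False
        for branch in BRANCHES:
            desc = tree.descendants(branch) & present
            if desc and pseudo == desc:
                events.append(
                    LineageEvent(kind="pseudogenization", branch=branch,
                                 orthogroup=g.id)
                )
                called = True
                break
        if not called:
            logger.debug(
                "orthogroup %s: pseudogene pattern %s not single-branch", g.id, pseudo
            )
    return events


# --------------------------------------------------------------------------
# finger-level polarization


def _progressive_columns(seqs: dict, params) -> list[dict]:
    """Multiple alignment of per-species motif sequences as columns.

    Sequences are added in tree order (H, C, O, R restricted to the present
    species) by aligning a column-representative profile with the next
    sequence using the motif aligner.  Each column maps species -> motif.
    """
    order = [sp for sp in SPECIES if sp in seqs]
    first = order[0]
    columns = [{first: m} for m in seqs[first].motifs]
    for sp in order[1:]:
        reps = []
        for ci, col in enumerate(columns):
            for ref in order:
                if ref in col:
                    m = col[ref]
                    break
            reps.append((ci, m))
        profile = MotifSequence(
            id="profile",
            motifs=[
                type(m)(seq=m.seq, index=k + 1, functional=m.functional,
                        contacts=m.contacts)
                for k, (_, m) in enumerate(reps)
            ],
        )
        aln = align_motif_sequences(profile, seqs[sp], params)
        new_columns = []
        for c in aln.columns:
            if c.kind == "pair":
                col = columns[reps[c.i - 1][0]]
                col[sp] = seqs[sp].motifs[c.j - 1]
                new_columns.append(col)
            elif c.kind == "gap_b":
                new_columns.append(columns[reps[c.i - 1][0]])
            else:  # gap_a: motif only in the new species
                new_columns.append({sp: seqs[sp].motifs[c.j - 1]})
        columns = new_columns
    return columns


#: tree edges as (parent node, child node/leaf, branch label)
_TREE_EDGES = (
    ("hc", "H", "H"),
    ("hc", "C", "C"),
    ("hco", "hc", "HC"),
    ("hco", "O", "O"),
    ("root", "hco", "HCO"),
    ("root", "R", "R"),
)
_INTERNAL_BRANCHES = {"HC", "HCO"}


def _sankoff_changes(leaf_states: dict) -> list[tuple]:
    """Minimum-change polarization of one character on the fixed tree.

    *leaf_states* maps present species to a hashable state (absent species
    are unconstrained).  Internal-node states are enumerated over the
    observed states; among minimum-cost labelings those with the fewest
    internal-branch changes are preferred (changes are pushed towards the
    tips, matching outgroup-consensus polarization).  Returns
    [(branch, parent_state, child_state, ambiguous_with)]; the classic
    rhesus-vs-hominid indeterminacy is collapsed to one HCO event flagged
    'R', other residual ambiguity is flagged with the alternative branches.
    """
    states = sorted(set(leaf_states.values()), key=repr)
    if len(states) == 1:
        return []

    def node_state(lab: dict, node: str):
        return leaf_states.get(node, None) if node in SPECIES else lab[node]

    labelings = []
    best_cost = None
    for hc in states:
        for hco in states:
            for root in states:
                lab = {"hc": hc, "hco": hco, "root": root}
                changes = []
                for parent, child, branch in _TREE_EDGES:
                    ps = lab[parent]
                    cs = node_state(lab, child)
                    if cs is None:
                        continue  # absent leaf: unconstrained
                    if ps != cs:
                        changes.append((branch, ps, cs))
                cost = len(changes)
                if best_cost is None or cost < best_cost:
                    best_cost = cost
                    labelings = [changes]
                elif cost == best_cost:
                    labelings.append(changes)

    branch_sets = [frozenset(b for b, *_ in ch) for ch in labelings]
    certain = frozenset.intersection(*branch_sets)
    residual = frozenset().union(*branch_sets) - certain

    out = []
    if residual <= {"HCO", "R"} and residual:
        # the classic rhesus-vs-hominid indeterminacy: report as HCO, flag R
        source = next(
            ch for ch in labelings if any(b == "HCO" for b, *_ in ch)
        )
        for branch, ps, cs in source:
            if branch in certain:
                out.append((branch, ps, cs, None))
            elif branch == "HCO":
                out.append(("HCO", ps, cs, "R"))
    else:
        # prefer labelings pushing changes towards the tips
        # (outgroup-consensus polarization), then deterministic order
        preferred = min(
            labelings,
            key=lambda ch: (
                sum(1 for b, *_ in ch if b in _INTERNAL_BRANCHES),
                repr(ch),
            ),
        )
        for branch, ps, cs in preferred:
            if branch in certain:
                out.append((branch, ps, cs, None))
            else:
                others = ",".join(sorted(residual - {branch}))
                out.append((branch, ps, cs, others or None))
    out.sort(key=lambda t: BRANCHES.index(t[0]))
    return out


def polarize_domain_changes(
    motif_seqs: dict,
    params,
    tree: Optional[SpeciesTree] = None,
    orthogroup: Optional[str] = None,
) -> list[LineageEvent]:
    """Finger gain/loss and sequence/contact changes polarized onto branches.

    *motif_seqs* maps species -> MotifSequence for one orthogroup; at least
    three species are required.  For every alignment column, presence and
    state patterns confined to a single branch's descendants become events;
    rhesus-vs-hominid indistinguishable cases are flagged 'R=HCO' (branch
    HCO, ambiguous_with R).
    """
    tree = tree or SpeciesTree()
    present = {sp for sp in motif_seqs if len(motif_seqs[sp])}
    if len(present) < 3:
        raise ValueError("unpolarizable: fewer than three species present")
    seqs = {sp: motif_seqs[sp] for sp in present}
    columns = _progressive_columns(seqs, params)
    events: list[LineageEvent] = []
    for ci, col in enumerate(columns, 1):
        # finger presence/absence
        presence = {sp: sp in col for sp in present}
        for branch, ancestral, derived, ambig in _sankoff_changes(presence):
            kind = "finger_gain" if derived else "finger_loss"
            events.append(
                LineageEvent(kind=kind, branch=branch, orthogroup=orthogroup,
                             motif_index=ci, ambiguous_with=ambig)
            )
        covered = set(col)
        if len(covered) < 3:
            continue  # a 2-species column cannot polarize a state change
        # sequence / contact changes (species absent from the column are
        # unconstrained in the parsimony, mirroring the >= 3 species rule)
        for attr, kind in (("seq", "finger_seq_change"), ("contacts", "contact_change")):
            values = {sp: getattr(col[sp], attr) for sp in covered}
            if any(v is None for v in values.values()):
                continue
            for branch, _ps, _cs, ambig in _sankoff_changes(values):
                events.append(
                    LineageEvent(kind=kind, branch=branch, orthogroup=orthogroup,
                                 motif_index=ci, ambiguous_with=ambig)
                )
    return events


# --------------------------------------------------------------------------
# rates


def _round_half_up(x: float, decimals: int = 1) -> float:
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def gain_loss_rates(
    count: int, divergence_range: tuple, decimals: int = 1
) -> RateEstimate:
    """Convert an event count to a per-My rate range.

    rate range = (count/upper, count/lower), each rounded half-up.
    """
    low, high = divergence_range
    if low <= 0 or high <= 0 or low > high:
        raise ValueError("divergence range must be positive with low <= high")
    if count < 0:
        raise ValueError("count must be non-negative")
    return RateEstimate(
        count=count,
        my_low=low,
        my_high=high,
        rate_low=_round_half_up(count / high, decimals),
        rate_high=_round_half_up(count / low, decimals),
    )


def branch_rate(count: int, branch: str, decimals: int = 1) -> RateEstimate:
    return gain_loss_rates(count, DIVERGENCE_MY[branch], decimals)


def percentage(numerator: float, denominator: float, decimals: int = 1) -> float:
    """Half-up rounded percentage (e.g. 4/28 -> 14 at 0 decimals)."""
    if denominator == 0:
        raise ValueError("denominator must be non-zero")
    return _round_half_up(100.0 * numerator / denominator, decimals)


# --------------------------------------------------------------------------
# Ka/Ks (Nei-Gojobori 1986 with Jukes-Cantor correction)

_BASES = "TCAG"
_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
_STOPS = {"TAA", "TAG", "TGA"}

_STANDARD_CODE = {}


def _codon_table() -> dict:
    global _STANDARD_CODE
    if not _STANDARD_CODE:
        from Bio.Seq import Seq

        _STANDARD_CODE = {c: str(Seq(c).translate()) for c in _CODONS}
    return _STANDARD_CODE


def _syn_sites(codon: str) -> tuple:
    """(synonymous, nonsynonymous) site counts of one codon.

    Each position contributes fractionally by the share of its three
    possible changes that are synonymous; changes to stop codons count as
    nonsynonymous.
    """
    code = _codon_table()
    aa = code[codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        for b in _BASES:
            if b == codon[pos]:
                continue
            alt = codon[:pos] + b + codon[pos + 1 :]
            if alt not in _STOPS and code[alt] == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def _pathway_diffs(c1: str, c2: str) -> tuple:
    """Average (syn, nonsyn) differences over all mutational pathways.

    Pathways passing through stop codons are excluded unless every pathway
    does.
    """
    code = _codon_table()
    positions = [i for i in range(3) if c1[i] != c2[i]]
    if not positions:
        return 0.0, 0.0
    pathways = []
    for order in itertools.permutations(positions):
        cur = c1
        syn = nonsyn = 0
        through_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in _STOPS:
                through_stop = True
            if code.get(cur) == code.get(nxt) and nxt not in _STOPS and cur not in _STOPS:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        pathways.append((syn, nonsyn, through_stop))
    valid = [p for p in pathways if not p[2]] or pathways
    syn = float(np.mean([p[0] for p in valid]))
    nonsyn = float(np.mean([p[1] for p in valid]))
    return syn, nonsyn


def _jukes_cantor(p: float) -> float:
    if p <= 0:
        return 0.0
    if p >= 0.75:
        raise ValueError("proportion of differences saturates the JC correction")
    return -0.75 * np.log(1 - 4.0 * p / 3.0)


KAKS_SATURATION_SENTINEL = 99.0


def ka_ks(cds_a: str, cds_b: str) -> KaKsResult:
    """NG86 Ka/Ks on a gap-free in-frame codon alignment.

    Ks = 0 with Ka > 0 yields the saturation sentinel ratio 99; Ka = Ks = 0
    yields an undefined (None) ratio.
    """
    a, b = cds_a.upper(), cds_b.upper()
    if len(a) != len(b):
        raise ValueError("sequences must be equal length")
    if len(a) % 3:
        raise ValueError("length must be a multiple of 3")
    if "-" in a or "-" in b:
        raise ValueError("gap-free alignment required")
    code = _codon_table()
    S = N = Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        if ca in _STOPS or cb in _STOPS:
            if i + 3 == len(a):
                continue  # terminal stop codon allowed
            raise ValueError(f"internal stop codon at nt {i}")
        sa, na = _syn_sites(ca)
        sb, nb = _syn_sites(cb)
        S += (sa + sb) / 2.0
        N += (na + nb) / 2.0
        ds, dn = _pathway_diffs(ca, cb)
        Sd += ds
        Nd += dn
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    ks = _jukes_cantor(ps)
    ka = _jukes_cantor(pn)
    if ka == 0 and ks == 0:
        ratio = None
    elif ks == 0:
        ratio = KAKS_SATURATION_SENTINEL
    else:
        ratio = ka / ks
    return KaKsResult(
        ka=ka, ks=ks, ratio=ratio, syn_sites=S, nonsyn_sites=N,
        syn_diffs=Sd, nonsyn_diffs=Nd,
    )


# --------------------------------------------------------------------------
# enrichment / CNV support


def fisher_gene_pseudogene(table) -> float:
    """Two-sided Fisher exact p for a 2x2 gene-vs-pseudogene count table."""
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("expected a 2x2 table")
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def cnv_overlap(
    loci: Iterable, regions: Iterable[IntervalRecord]
) -> dict:
    """Annotate loci with copy-number-variant regions they intersect.

    Any overlap (>= 1 bp, half-open arithmetic) counts; touching intervals do
    not.  Returns locus id -> list of overlapping region records.
    """
    regions = list(regions)
    out: dict = {}
    for l in loci:
        hits = [
            r
            for r in regions
            if r.seqid == l.genome_id and l.start < r.end and r.start < l.end
        ]
        if hits:
            out[l.id] = hits
    return out
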