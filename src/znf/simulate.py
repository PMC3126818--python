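"""Synthetic 4-species KZNF cluster genomes with a full event history.

The generator emulates the processes that reshape tandem zinc-finger
clusters: an ancestral genome of modular loci (a KRAB-A effector region 5'
of a tandem array of 84-nt finger units, all in one reading frame, flanked
by in-frame stop codons), evolved along the fixed tree (((H,C),O),R) by

* whole-locus tandem duplications and deletions,
* insertions/deletions of single 84-nt finger units,
* pseudogenizing stop codons planted within the first 600 coding nt,
* point substitutions (with rejection of changes that would create new
  in-frame stops in coding sequence — purifying selection against nonsense
  changes keeps the truth bookkeeping exact).

Every event is logged with its branch so pipeline recovery can be scored.
Variable family positions of each ancestral locus (finger contact residues
plus a few surface positions, and every fourth KRAB position) are
randomized so paralogous loci are distinguishable by sequence while still
matching the family profiles.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .model import (
    AMINO_ACIDS,
    CONTACT_POSITIONS,
    GenomeSequence,
    LineageEvent,
    MappingRow,
    SPECIES,
    ZNF_CONSENSUS,
    ZNF_UNIT_LENGTH,
)
from .scan import (
    KRAB_A_CONSENSUS,
    KRAB_A_VARIABLE_POSITIONS,
    ZNF_VARIABLE_POSITIONS,
)

#: deterministic codon per amino acid (the generator's encoding)
AA_TO_CODON = {
    "A": "GCT", "R": "CGT", "N": "AAT", "D": "GAT", "C": "TGT",
    "Q": "CAA", "E": "GAA", "G": "GGT", "H": "CAT", "I": "ATT",
    "L": "CTG", "K": "AAA", "M": "ATG", "F": "TTT", "P": "CCT",
    "S": "TCT", "T": "ACT", "W": "TGG", "Y": "TAT", "V": "GTT",
}
STOP = "TAA"
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_BASES = "ACGT"

#: branch evolution order (parent genome -> child genome)
BRANCH_TOPOLOGY = [
    ("root", "HCO"),
    ("HCO", "HC"),
    ("HC", "H"),
    ("HC", "C"),
    ("HCO", "O"),
    ("root", "R"),
]
LEAVES = set(SPECIES)


def encode(aa: str) -> str:
    return "".join(AA_TO_CODON[a] for a in aa)


def random_finger(rng: np.random.Generator, index: int = 1):
    """A canonical-scaffold finger with randomized family-variable positions."""
    from .assembly import _contacts, _functional
    from .model import ZnfMotif

    seq = _randomized(ZNF_CONSENSUS, ZNF_VARIABLE_POSITIONS, rng)
    return ZnfMotif(seq=seq, index=index, functional=_functional(seq),
                    contacts=_contacts(seq))


def random_motif_sequence(rng: np.random.Generator, n: int, id: str = "seq"):
    """An n-finger synthetic motif sequence (for aligner studies/tests)."""
    from .model import MotifSequence

    return MotifSequence(id=id, motifs=[random_finger(rng, i + 1) for i in range(n)])


@dataclass
class SimParams:
    """Study conditions for the synthetic clusters.

    Rates are per locus per branch (structural events) or per site per
    branch (substitutions); they are deliberately low so most orthogroups
    carry at most one structural event and polarization is well-posed.
    """

    seed: int = 0
    clusters: int = 2
    loci_per_cluster: int = 4
    fingers_min: int = 6
    fingers_max: int = 10
    dup_rate: float = 0.015
    del_rate: float = 0.015
    finger_ins_rate: float = 0.02
    finger_del_rate: float = 0.02
    pseudo_rate: float = 0.02
    subst_rate: float = 0.004
    intergenic_min: int = 200
    intergenic_max: int = 600
    cluster_gap: int = 5_000
    pseudo_orf_remainder: int = 150  # aa left downstream of a planted stop

    def __post_init__(self) -> None:
        for name in ("dup_rate", "del_rate", "finger_ins_rate",
                     "finger_del_rate", "pseudo_rate", "subst_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability")
        if self.loci_per_cluster < 1 or self.clusters < 1:
            raise ValueError("need at least one locus")
        if self.fingers_min < 4 or self.fingers_max < self.fingers_min:
            raise ValueError("finger count range invalid (need >= 4)")


@dataclass
class SimLocus:
    """One locus: KRAB + linker + finger units, all nucleotide-level."""

    ancestral_id: str
    uid: str
    krab_nt: str
    linker_nt: str
    fingers_nt: list  # list[str], 84 nt each (may contain a planted stop)
    finger_uids: list  # parallel ancestral finger identifiers
    primary: bool = True  # descends without duplication
    pseudo: bool = False
    born_branch: str = "root"

    def coding_nt(self) -> str:
        return self.krab_nt + self.linker_nt + "".join(self.fingers_nt)

    def render(self) -> str:
        return STOP + self.coding_nt() + STOP

    def n_codons(self) -> int:
        return len(self.coding_nt()) // 3

    def finger_aa(self) -> list:
        from Bio.Seq import Seq

        return [str(Seq(f).translate()) for f in self.fingers_nt]

    def clone(self, uid: str, primary: bool, branch: str) -> "SimLocus":
        return SimLocus(
            ancestral_id=self.ancestral_id,
            uid=uid,
            krab_nt=self.krab_nt,
            linker_nt=self.linker_nt,
            fingers_nt=list(self.fingers_nt),
            finger_uids=list(self.finger_uids),
            primary=primary,
            pseudo=self.pseudo,
            born_branch=branch,
        )


@dataclass
class TruthLocus:
    species: str
    uid: str
    ancestral_id: str
    primary: bool
    pseudo: bool
    start: int  # coding start (after the upstream stop codon)
    end: int  # coding end (before the downstream stop codon)
    array_start: int  # first finger unit start
    array_end: int  # last finger unit end
    n_fingers: int


@dataclass
class SimTruth:
    loci: dict  # species -> list[TruthLocus]
    events: list  # list[LineageEvent]; .locus = ancestral id
    mappings: dict  # (species_x, species_y) -> list[MappingRow]
    genome_ids: dict  # species -> genome id


def _random_aa(rng: np.random.Generator) -> str:
    return AMINO_ACIDS[rng.integers(len(AMINO_ACIDS))]


def _randomized(consensus: str, variable: tuple, rng: np.random.Generator) -> str:
    out = list(consensus)
    for p in variable:
        out[p] = _random_aa(rng)
    return "".join(out)


def _random_dna(n: int, rng: np.random.Generator) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, size=n))


def _intergenic(params: SimParams, rng: np.random.Generator) -> str:
    n = int(rng.integers(params.intergenic_min, params.intergenic_max + 1))
    return _random_dna(n, rng)


# --------------------------------------------------------------------------
# ancestor


def generate_ancestor(
    params: SimParams, rng: Optional[np.random.Generator] = None
) -> list:
    """The ancestral genome as an ordered element list.

    Elements are ("ig", nt) intergenic stretches or ("locus", SimLocus);
    clusters are separated by a long intergenic gap.
    """
    rng = rng or np.random.default_rng(params.seed)
    elements: list = []
    counter = 0
    finger_counter = 0
    for ci in range(params.clusters):
        if ci:
            elements.append(("ig", _random_dna(params.cluster_gap, rng)))
        elements.append(("ig", _intergenic(params, rng)))
        for _ in range(params.loci_per_cluster):
            counter += 1
            n_fingers = int(rng.integers(params.fingers_min, params.fingers_max + 1))
            fingers = []
            finger_uids = []
            for _ in range(n_fingers):
                finger_counter += 1
                fingers.append(
                    encode(_randomized(ZNF_CONSENSUS, ZNF_VARIABLE_POSITIONS, rng))
                )
                finger_uids.append(f"f{finger_counter:04d}")
            locus = SimLocus(
                ancestral_id=f"anc{counter:03d}",
                uid=f"anc{counter:03d}.0",
                krab_nt=encode(
                    _randomized(KRAB_A_CONSENSUS, KRAB_A_VARIABLE_POSITIONS, rng)
                ),
                linker_nt=encode("".join(_random_aa(rng) for _ in range(10))),
                fingers_nt=fingers,
                finger_uids=finger_uids,
            )
            elements.append(("locus", locus))
            elements.append(("ig", _intergenic(params, rng)))
    return elements


# --------------------------------------------------------------------------
# branch evolution


def _substitute_coding(
    nt: str,
    rng: np.random.Generator,
    rate: float,
    protected: set,
) -> str:
    """Point substitutions with rejection of new in-frame stop codons."""
    seq = list(nt)
    n = len(seq)
    k = rng.binomial(n, rate)
    if k == 0:
        return nt
    positions = rng.choice(n, size=k, replace=False)
    for pos in positions:
        pos = int(pos)
        codon_i = pos // 3
        if codon_i in protected:
            continue
        old = seq[pos]
        new = _BASES[rng.integers(0, 4)]
        if new == old:
            continue
        c0 = 3 * codon_i
        codon = seq[c0], seq[c0 + 1], seq[c0 + 2]
        trial = list(codon)
        trial[pos - c0] = new
        if "".join(trial) in STOP_CODONS:
            continue  # nonsense changes are purged
        if "".join(codon) in STOP_CODONS:
            continue  # planted stops stay in place
        seq[pos] = new
    return "".join(seq)


def _substitute_neutral(nt: str, rng: np.random.Generator, rate: float) -> str:
    seq = list(nt)
    k = rng.binomial(len(seq), rate)
    for pos in rng.choice(len(seq), size=k, replace=False) if k else []:
        seq[int(pos)] = _BASES[rng.integers(0, 4)]
    return "".join(seq)


def _contacts_of(aa_unit: str) -> str:
    return "".join(
        aa_unit[p] if p < len(aa_unit) else "X" for p in CONTACT_POSITIONS
    )


def _evolve_branch(
    elements: list,
    branch: str,
    params: SimParams,
    rng: np.random.Generator,
    uid_counter: list,
) -> tuple:
    """One branch: structural events then substitutions.  Returns the new
    element list and the branch's truth events."""
    elements = [
        (kind, payload.clone(payload.uid, payload.primary, payload.born_branch)
         if kind == "locus" else payload)
        for kind, payload in elements
    ]
    events: list[LineageEvent] = []
    out: list = []
    for kind, payload in elements:
        if kind != "locus":
            out.append((kind, payload))
            continue
        locus: SimLocus = payload
        # deletion
        if locus.born_branch != branch and rng.poisson(params.del_rate) > 0:
            events.append(
                LineageEvent(kind="locus_loss", branch=branch,
                             locus=locus.ancestral_id)
            )
            continue  # locus (and its element) removed
        out.append((kind, locus))
        # duplication
        for _ in range(rng.poisson(params.dup_rate)):
            uid_counter[0] += 1
            dup = locus.clone(
                uid=f"{locus.ancestral_id}.{uid_counter[0]}",
                primary=False,
                branch=branch,
            )
            out.append(("ig", _intergenic(params, rng)))
            out.append(("locus", dup))
            events.append(
                LineageEvent(kind="locus_gain", branch=branch,
                             locus=locus.ancestral_id)
            )
        # finger insertion (tandem unit duplication)
        if rng.poisson(params.finger_ins_rate) > 0:
            i = int(rng.integers(len(locus.fingers_nt)))
            uid_counter[0] += 1
            locus.fingers_nt.insert(i + 1, locus.fingers_nt[i])
            locus.finger_uids.insert(i + 1, f"f_new{uid_counter[0]:04d}")
            events.append(
                LineageEvent(kind="finger_gain", branch=branch,
                             locus=locus.ancestral_id, motif_index=i + 2)
            )
        # finger deletion
        if (
            rng.poisson(params.finger_del_rate) > 0
            and len(locus.fingers_nt) >= 5
        ):
            i = int(rng.integers(len(locus.fingers_nt)))
            del locus.fingers_nt[i]
            del locus.finger_uids[i]
            events.append(
                LineageEvent(kind="finger_loss", branch=branch,
                             locus=locus.ancestral_id, motif_index=i + 1)
            )
        # pseudogenization
        if not locus.pseudo and rng.poisson(params.pseudo_rate) > 0:
            _plant_stop(locus, params)
            events.append(
                LineageEvent(kind="pseudogenization", branch=branch,
                             locus=locus.ancestral_id)
            )

    # substitutions + per-finger change bookkeeping
    final: list = []
    for kind, payload in out:
        if kind == "ig":
            final.append(("ig", _substitute_neutral(payload, rng, params.subst_rate)))
            continue
        locus = payload
        before_aa = dict(zip(locus.finger_uids, locus.finger_aa()))
        coding = locus.coding_nt()
        protected = {
            ci for ci in range(len(coding) // 3)
            if coding[3 * ci : 3 * ci + 3] in STOP_CODONS
        }
        mutated = _substitute_coding(coding, rng, params.subst_rate, protected)
        _write_back(locus, mutated)
        after_aa = dict(zip(locus.finger_uids, locus.finger_aa()))
        for idx, fuid in enumerate(locus.finger_uids, 1):
            old, new = before_aa.get(fuid), after_aa[fuid]
            if old is None or old == new:
                continue
            events.append(
                LineageEvent(kind="finger_seq_change", branch=branch,
                             locus=locus.ancestral_id, motif_index=idx)
            )
            if _contacts_of(old) != _contacts_of(new):
                events.append(
                    LineageEvent(kind="contact_change", branch=branch,
                                 locus=locus.ancestral_id, motif_index=idx)
                )
        final.append(("locus", locus))
    return final, events


def _plant_stop(locus: SimLocus, params: SimParams) -> None:
    """Plant an in-frame stop leaving ~pseudo_orf_remainder codons downstream
    (inside the first 600 coding nt by construction of the defaults)."""
    total = locus.n_codons()
    target = max(total - params.pseudo_orf_remainder, 1)
    n_krab = len(locus.krab_nt) // 3
    n_linker = len(locus.linker_nt) // 3
    first_finger_codon = n_krab + n_linker
    # keep the stop inside the finger region, sparing the first finger
    target = max(target, first_finger_codon + ZNF_UNIT_LENGTH)
    fi, within = divmod(target - first_finger_codon, ZNF_UNIT_LENGTH)
    fi = min(fi, len(locus.fingers_nt) - 4)  # >= 3 intact fingers downstream
    fnt = locus.fingers_nt[fi]
    locus.fingers_nt[fi] = fnt[: 3 * within] + STOP + fnt[3 * (within + 1) :]
    locus.pseudo = True


def _write_back(locus: SimLocus, coding: str) -> None:
    pos = 0
    locus.krab_nt = coding[pos : pos + len(locus.krab_nt)]
    pos += len(locus.krab_nt)
    locus.linker_nt = coding[pos : pos + len(locus.linker_nt)]
    pos += len(locus.linker_nt)
    fingers = []
    for f in locus.fingers_nt:
        fingers.append(coding[pos : pos + len(f)])
        pos += len(f)
    locus.fingers_nt = fingers


# --------------------------------------------------------------------------
# whole-tree simulation


def evolve_along_tree(
    ancestor: list, params: SimParams, rng: Optional[np.random.Generator] = None
) -> tuple:
    """Evolve the ancestor into the four leaf genomes.

    Returns ({species: GenomeSequence}, SimTruth).  With all rates zero the
    four genomes are identical to the ancestor and the event list is empty.
    """
    rng = rng or np.random.default_rng(params.seed + 1)
    uid_counter = [0]
    states = {"root": ancestor}
    events: list[LineageEvent] = []
    for parent, child in BRANCH_TOPOLOGY:
        state, branch_events = _evolve_branch(
            states[parent], child, params, rng, uid_counter
        )
        states[child] = state
        events.extend(branch_events)

    genomes: dict = {}
    truth_loci: dict = {}
    genome_ids = {sp: f"{sp}_1" for sp in SPECIES}
    for sp in SPECIES:
        seq_parts = []
        loci_rows = []
        offset = 0
        for kind, payload in states[sp]:
            if kind == "ig":
                seq_parts.append(payload)
                offset += len(payload)
                continue
            locus: SimLocus = payload
            rendered = locus.render()
            coding_start = offset + 3
            coding_end = offset + len(rendered) - 3
            array_start = coding_start + len(locus.krab_nt) + len(locus.linker_nt)
            loci_rows.append(
                TruthLocus(
                    species=sp,
                    uid=locus.uid,
                    ancestral_id=locus.ancestral_id,
                    primary=locus.primary,
                    pseudo=locus.pseudo,
                    start=coding_start,
                    end=coding_end,
                    array_start=array_start,
                    array_end=array_start + sum(len(f) for f in locus.fingers_nt),
                    n_fingers=len(locus.fingers_nt),
                )
            )
            seq_parts.append(rendered)
            offset += len(rendered)
        genomes[sp] = GenomeSequence(
            id=genome_ids[sp], seq="".join(seq_parts), species=sp
        )
        truth_loci[sp] = loci_rows

    mappings: dict = {}
    for x in SPECIES:
        for y in SPECIES:
            if x == y:
                continue
            rows = []
            primary_y = {
                t.ancestral_id: t for t in truth_loci[y] if t.primary
            }
            for t in truth_loci[x]:
                ty = primary_y.get(t.ancestral_id)
                if ty is None:
                    continue
                rows.append(
                    MappingRow(
                        genome_ids[x], t.start, t.end, "+",
                        genome_ids[y], ty.start, ty.end, "+",
                    )
                )
            mappings[(x, y)] = rows

    truth = SimTruth(
        loci=truth_loci, events=events, mappings=mappings, genome_ids=genome_ids
    )
    return genomes, truth


def simulate(params: SimParams) -> tuple:
    """Ancestor + tree evolution with one seeded generator."""
    rng = np.random.default_rng(params.seed)
    ancestor = generate_ancestor(params, rng)
    return evolve_along_tree(ancestor, params, rng)


# --------------------------------------------------------------------------
# recovery scoring


_MIRROR = {
    "locus_gain": "locus_loss",
    "locus_loss": "locus_gain",
    "finger_gain": "finger_loss",
    "finger_loss": "finger_gain",
}


def observable_events(truth: SimTruth) -> list:
    """Planted events the pipeline can in principle recover.

    Excluded: events on orthogroups hit by more than one structural event
    (parsimony is only well-posed for unique events), finger-level events on
    orthogroups with any structural event (polarization needs 1:1 groups),
    and finger-level events on groups retaining fewer than three species.
    """
    structural = ("locus_gain", "locus_loss")
    struct_count: dict = {}
    for e in truth.events:
        if e.kind in structural:
            struct_count[e.locus] = struct_count.get(e.locus, 0) + 1
    species_with: dict = {}
    for sp, rows in truth.loci.items():
        for t in rows:
            species_with.setdefault(t.ancestral_id, set()).add(sp)

    # fingers changed on both R and HCO collapse to a single parsimony
    # pattern (x,x,x,y): the two planted events are jointly unidentifiable
    finger_branches: dict = {}
    for e in truth.events:
        if e.kind in ("finger_seq_change", "contact_change"):
            key = (e.locus, e.kind, e.motif_index)
            finger_branches.setdefault(key, set()).add(e.branch)

    out = []
    for e in truth.events:
        n_struct = struct_count.get(e.locus, 0)
        present = species_with.get(e.locus, set())
        if e.kind in structural:
            if n_struct > 1:
                continue
            out.append(e)
        elif e.kind == "pseudogenization":
            if n_struct > 0 or len(present) < 3:
                continue
            out.append(e)
        else:  # finger-level
            if n_struct > 0 or len(present) < 3:
                continue
            if e.kind in ("finger_seq_change", "contact_change"):
                branches = finger_branches[(e.locus, e.kind, e.motif_index)]
                if {"R", "HCO"} <= branches:
                    continue
            out.append(e)
    return out


def _compatible(truth_event: LineageEvent, r: LineageEvent) -> bool:
    kinds_ok = truth_event.kind == r.kind or (
        r.ambiguous_with is not None
        and _MIRROR.get(truth_event.kind) == r.kind
    )
    return kinds_ok and truth_event.branch in r.candidate_branches


def _max_bipartite_match(truth_events: list, recovered: list) -> int:
    """Maximum matching between truth events and compatible recovered events
    (augmenting-path search; pools are small)."""
    adj = [
        [j for j, r in enumerate(recovered) if _compatible(e, r)]
        for e in truth_events
    ]
    match_r = [-1] * len(recovered)

    def augment(i: int, seen: set) -> bool:
        for j in adj[i]:
            if j in seen:
                continue
            seen.add(j)
            if match_r[j] == -1 or augment(match_r[j], seen):
                match_r[j] = i
                return True
        return False

    matched = 0
    for i in range(len(truth_events)):
        if augment(i, set()):
            matched += 1
    return matched


def score_event_recovery(
    truth: SimTruth, recovered: list, group_ancestral: dict
) -> dict:
    """Fraction of observable planted events recovered on the right branch.

    *recovered* are pipeline LineageEvents (``orthogroup`` set);
    *group_ancestral* maps orthogroup id -> ancestral locus id.  Truth
    events on R or HCO match recovered events flagged with the R=HCO
    ambiguity (including the mirrored kind).
    """
    observable = observable_events(truth)
    pools: dict = {}
    for r in recovered:
        anc = group_ancestral.get(r.orthogroup)
        if anc is None:
            continue
        expanded = [r] * max(1, r.count)
        pools.setdefault(anc, []).extend(expanded)
    truth_by_locus: dict = {}
    for e in observable:
        truth_by_locus.setdefault(e.locus, []).append(e)
    matched = sum(
        _max_bipartite_match(events, pools.get(locus, []))
        for locus, events in truth_by_locus.items()
    )
    return {
        "observable": len(observable),
        "matched": matched,
        "recall": matched / len(observable) if observable else 1.0,
    }
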