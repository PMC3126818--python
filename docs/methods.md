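# Methods

## The annotation model

KZNF genes are modular: one or more effector exons (KRAB-A/B, SCAN, BTB) 5′
of a single exon encoding a tandem array of 28-aa (84-nt) C2H2 fingers.
The annotation pipeline mirrors this structure. Same-strand domain hits
within `intra_locus_max_gap` (default 40 kb) are chained; walking 5′→3′, an
effector hit after a finger starts a new chain, and a KRAB-A after another
KRAB-type exon does the same — this is what separates tandem loci that sit
within chaining distance of each other. A chain is annotated as a locus iff
it contains a KRAB-A hit with E < 10⁻⁶ (the family's published annotation
threshold) or a run of ≥ 3 fingers with adjacent gaps < 100 bp; SCAN/BTB
effectors alone never qualify a chain. Finger adjacency is measured
half-open, hit end to next hit start.

ORFs follow the "crude locus" convention: each same-frame block of domain
hits is extended 5′ and 3′ to (excluding) the first in-frame stop codon or
the sequence boundary. When all blocks share one frame the annotated coding
region is the translation of the contiguous span, so stops *between* blocks
remain visible; multi-frame loci concatenate block translations 5′→3′.
Classification: *gene* iff the longest stop-free stretch is ≥ 200 aa **and**
no stop occurs in the first 600 nt of the annotated coding region;
everything else, including stop-free 150–199 aa loci, is a *pseudogene*
(the two published rules do not formally partition that band; the ≥ 200 aa
gene requirement is taken as primary, consistent with the stated
equivalence of the two formulations).

Finger extraction partitions the array span (first to last finger hit) into
consecutive 84-nt units anchored on the first hit, so units whose
individual score fell below threshold (degenerate fingers, fingers broken
by a stop) are retained between detected neighbours. A unit is *functional*
iff both cysteines (offsets 2, 5) and both histidines (offsets 18, 22) of
the C2H2 core are intact. The four DNA-contacting residues sit at helix
positions −1, 2, 3, 6, located at offsets −7, −5, −4, −1 from the first
core histidine; the offset table is configuration with this default.

## Domain detection

Profiles are additive position-specific scores over the 20 amino acids plus
X (scored 0) and stop (−8). The shipped profiles are family-style: each
conserved consensus position scores +4 for the consensus residue and −3
otherwise, while family-variable positions — the four contact residues plus
four surface positions of the finger, and every fourth KRAB position —
score 0 for any residue. This mirrors how family HMMs treat
hypervariable columns and keeps genuinely diverged family members far above
threshold: detection degrades only with substitutions at structurally
conserved positions. E-values come from a Gumbel tail fitted to the score
distribution of 10 000 windows of uniformly random residues (fixed
calibration seed), scaled by the number of windows searched. Overlapping
same-profile hits in one frame are reduced to the best bit score, ties to
the leftmost. External HMMER `domtblout` hits are the recommended
production path; they carry frame-encoded target ids
(`<seqid>|frame<1..6>`, frames 4–6 reverse-complement) and merge with
internal hits by keeping the lower E per identical interval.

Six-frame translation renders stop codons `*` and any codon containing N as
`X` (even where the genetic code would be unambiguous, e.g. GTN): assembly
and ORF logic must never depend on bases that are not actually present.

## MotifAligner

The alignment unit is a whole finger. Pairwise similarity is the
positionwise substitution-matrix sum over the two 28-aa units (BLOSUM85 by
default, loaded from biotite's distributed matrix file; any NCBI-format
matrix can be supplied); positions absent from a degenerate short unit
contribute 0. A Gotoh three-state dynamic program maximises the summed
similarity minus affine gap costs of `open + (len−1)·extend` per maximal
gap run, with the published parameterisation open = 84⁻¹ ≈ 0.0119 and
extend = 84⁻⁰·⁹ ≈ 0.0186 implemented literally — note extension exceeds
opening; both are tiny against BLOSUM sums and act mostly as deterministic
tie-breakers. DP ties prefer pair over gap-in-B over gap-in-A, making the
traceback deterministic. The alignment depends only on the motif protein
sequences. Correctness is guarded by an exhaustive-enumeration oracle over
all monotone affine-gap alignments for short sequences.

## Orthology

Three independent signals are computed per species pair: (i) reciprocal
best hits on locus nucleotide sequences, scored by default as shared
12-mers normalised by the shorter sequence's k-mer count (any scorer is
pluggable; score ties yield no best hit, hence no RBH); (ii) synteny
through liftover-style mapping tables, pairing loci with ≥ 50 % reciprocal
overlap of the lifted interval, unique both ways; (iii) Markov clustering
(inflation 2.0, self-loops at the maximum incident weight, convergence at
max column change < 10⁻⁶) of the full similarity graph, where clusters of
size ≥ 2 count as "grouped".

Orthogroups build in four tiers: tier 0 components of edges on which all
three methods agree (the high-confidence set; 1:1 per species pair by
construction); tier 1 attaches loci with RBH or unique synteny support not
contradicted by clustering ("same cluster or not clustered at all" is
implemented literally); tier 2 weakens to one-directional best hits or any
synteny overlap; tier 3 uses within-species 1:1 best hits and finally
leaves singletons. Tiers attach loci to existing groups but never merge two
existing groups; attachment order is by descending similarity, then
lexicographic ids. After tier 3 the all-inclusive set partitions the locus
universe.

## Lineage events and rates

Locus gain/loss uses copy-number parsimony on (((H,C)HC,O)HCO,R): internal
nodes take integer copy counts, edge cost |parent − child|, and the
minimum-cost labelings define per-branch events. Profiles explained equally
by an HCO event or the mirrored R event emit one event labelled HCO with an
`R` ambiguity flag. Extra copies whose species is already 1:1 within a
high-confidence group are not counted as gained. Pseudogenization is called
on high-confidence groups with ≥ 3 species when the pseudogene state is
confined to one branch's descendants; the (gene,gene,gene,pseudo) pattern
is assigned to R without an ambiguity flag, since re-activation of an
ancestrally dead locus is not a considered state.

Finger-level polarization aligns the per-species finger arrays
progressively along the tree (H+C, then O, then R) with the MotifAligner,
yielding columns of homologous fingers. Presence/absence and sequence /
contact-signature states are polarized per column by small-parsimony
enumeration over the observed states, with absent species unconstrained.
Among equally parsimonious labelings, the classic R-vs-HCO indeterminacy
collapses to a flagged HCO event; any other residual ambiguity prefers
labelings with the fewest internal-branch changes (outgroup-consensus
behaviour: changes are pushed to the tips) and flags the alternatives.
Columns covering ≥ 3 species are polarized even when a species is gapped,
matching the ≥ 3-species requirement of the analysis.

Rates: a count over a divergence range (low, high) My becomes the range
(count/high, count/low), rounded half-up to one decimal. The divergence
ranges are 4.5–6 My for the terminal human/chimpanzee branches, 12–16 My
for orangutan and the homininae stem, 25–33 My for rhesus and the hominid
stem.

Ka/Ks is Nei–Gojobori (1986): fractional synonymous site counts per codon
(changes to stop codons count as nonsynonymous), pathway averaging over
multi-hit codons excluding pathways through stops when possible, and
Jukes–Cantor correction. Ks = 0 with Ka > 0 reports the saturation sentinel
99 (matching how such entries are conventionally printed); Ka = Ks = 0 is
undefined. Fisher's exact test (two-sided) is delegated to scipy and
checked against a hypergeometric enumeration oracle. CNV support is plain
≥ 1 bp interval intersection in half-open arithmetic.

## Binding prediction

Only functional fingers contribute. Each emits a 3-nt subsite from its
contact residues through a pluggable model; fingers emit C-terminal-first,
so the protein's last functional finger specifies the motif's 5′ end
(zinc-finger proteins run antiparallel to their site). The default model is
a transparent deterministic code: position 6 → 5′ base, position 3 →
middle, position −1 → 3′ base, using R/K/H → G, N/Q → A, D/E → C, S/T → T
and N otherwise; position 2 contacts the complementary strand of the
neighbouring subsite and emits nothing. This default is *not* a trained
binding model — learned contact→triplet tables plug in via the same
interface, and published motifs can always be scanned directly. IUPAC
scanning checks both strands by default (a setting), reports forward-strand
coordinates, and treats genome N as matching only motif N. Nearest-gene
assignment is by TSS distance (0 when overlapping the gene body), ties by
body distance then lexicographic id. Co-expression is Spearman's rho as
Pearson on mid-ranks, with an exact permutation p for n ≤ 8 and the t
approximation above, Bonferroni-corrected over the candidate list.

## The synthetic-data generator

`znf.simulate` emulates a pair of tandem KZNF clusters in four species:
8 ancestral loci (2 clusters × 4), each a KRAB-A region (41 aa), a random
10-aa linker and 6–10 finger units in a single reading frame flanked by
in-frame stops, separated by 200–600 nt of random intergenic sequence
(clusters by 5 kb). Family-variable positions are randomized per locus so
paralogs are sequence-distinguishable while matching the family profiles;
the fixed codon-per-amino-acid encoding keeps conserved runs short enough
that distinct loci share essentially no 12-mers.

Along (((H,C),O),R), each branch draws Poisson event counts per locus:
tandem locus duplication (0.015), locus deletion (0.015), single-unit
finger insertion and deletion (0.02 each, deletions keeping ≥ 4 units),
pseudogenizing stop placement (0.02; the stop lands in the finger region
within the first 600 coding nt, leaving ~150 codons downstream so the
resulting ORF is unambiguously sub-200 aa), and per-site substitutions
(0.004 per branch, giving ≈ 5 % human–rhesus divergence, in the range of
real primate genomes). Substitutions that would create a new in-frame stop
in coding sequence are rejected — purifying selection against nonsense
changes — so pseudogenization remains an explicit, logged event class and
the truth bookkeeping stays exact. Every event is logged with its branch;
per-finger amino-acid changes are recorded by diffing each finger before
and after a branch (with contact-signature changes logged additionally).
Liftover-style mapping tables are emitted by mapping each locus to the
primary (unduplicated-lineage) copy of its ancestral locus in the other
species, which reproduces the characteristic ambiguity liftover shows over
fresh tandem duplicates.

What the generator does *not* emulate: minus-strand loci (strand handling
is unit-tested separately), spliced multi-exon structure beyond the
single-frame modular layout, inversions and larger rearrangements,
assembly gaps/errors, rate heterogeneity along branches, and realistic
substitution models (uniform base choice rather than HKY/GTR). Passing
recovery tests therefore demonstrates the correctness of the rule logic
and polarization machinery under the stated processes, not performance on
draft genome assemblies.

## Recovery scoring

Pipeline output is compared to the simulation truth by matching recovered
loci to planted loci via coordinate overlap, mapping orthogroups to
ancestral loci by member majority, and finding a maximum bipartite matching
between observable planted events and recovered events (compatible when
kinds agree — or mirror under an R=HCO flag — and the planted branch is
among the recovered event's candidate branches). *Observable* events
exclude patterns that are unidentifiable in principle: orthogroups hit by
more than one structural event (copy-number parsimony is only well-posed
for unique events), finger-level events on orthogroups with any structural
event (polarization requires 1:1 groups) or retaining < 3 species, and
fingers hit on both R and HCO for the same change class (the two events
collapse to a single parsimony step).

## Numerical and determinism notes

All randomness flows through seeded `numpy` generators; profile calibration
uses a fixed internal seed; MCL iterates over a sorted node order; DP and
event resolution tie-breaks are documented preference orders. Rounding of
rates and percentages is decimal half-up (via `decimal.Decimal`), matching
how the reference rate tables print. Simulation sizes (8 loci × 4 species,
~15 kb per genome, 20 replicates in the recovery studies) were chosen so a
full study runs in seconds on one CPU while still yielding on the order of
a thousand planted events per 20-replicate study.

## Known limitations

- The internal PSSM scanner is a stand-in for profile HMM search; it is not
  expected to reproduce genome-wide hit counts on real assemblies, where
  HMMER hits should be ingested instead.
- Tier 1–3 orthogroup construction approximates what was originally a
  semi-manual curation; tiers attach but never merge, which can leave a
  truly orthologous pair separate when clustering contradicts it.
- Progressive finger alignment can misplace a fresh tandem finger duplicate
  (the copy, not the source, pairs with the other species), which shifts
  sequence changes on the source finger into a gapped column; partial-column
  polarization recovers most but not all of these.
- Parsimony cannot see homoplasy: the same state arising on two branches,
  or nested R+HCO changes of one finger, undercount by construction.
- Ka/Ks saturates (JC undefined) at p ≥ 0.75 within a site class; intended
  for the closely related sequences this family analysis targets.
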