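# Methods

This note documents the models, parameters and numerical choices behind
`nanomatch`, and what the synthetic-data experiments do and do not show
about real data.

## Amplicon processing

**Read merging.** Pairs are merged on the longest ungapped
suffix/prefix overlap of R1 against the reverse complement of R2 whose
mismatch fraction is at most `max_overlap_mismatch_frac` (default 0.05)
and whose length is at least `min_overlap` (default 20). Conflicting
overlap positions take the base with the higher Phred quality; an exact
quality tie keeps R1's base, and every disagreement is counted in
`conflict_count`. The merged length always equals
`len(R1) + len(R2) − overlap`. The overlap scan is vectorized (one
sliding-window comparison per pair) but is exactly equivalent to the
exhaustive offset scan, which the tests assert.

**Primer search.** Matching is substitution-only (Hamming). Degenerate
IUPAC codes in a primer match by set membership (Y matches C or T at no
cost). The mismatch budget for a primer of annealing length L at
fractional tolerance f is `ceil(f·L)` — the only rounding consistent
with a 23-base primer tolerating 5 mismatches at 20%. The best hit has
the fewest mismatches, ties broken by the smallest plus-strand
position; reverse primers are searched on the reverse complement and
reported in plus-strand coordinates. 5′ diversity tails (the `NNNNNN`
hexamer) are declared as `tail_len` and never matched. Indels are not
modeled: substitution-only matching keeps the operation exactly
checkable against a brute-force oracle, and primer-length indels are
rare relative to substitutions at these read qualities.

**ORF selection.** The coding region runs from the end of the forward
primer's annealing site (plus a configurable `frame_offset`, default 0:
the leader-style forward primer ends in frame) to the start of the
reverse primer's site, truncated to whole codons. The identity of the
matching reverse primer assigns the hinge class (long hinge → IgG2,
short hinge → IgG3); a configurable fallback anchor yields
`hinge=unknown`. Sequences with internal stops or translated length
outside [90, 180] residues (a VHH domain plus hinge stub; the window is
config-exposed) are rejected with a tallied reason.

**Deduplication.** Identical protein strings collapse; read support is
summed (total support is conserved exactly), the representative DNA is
the most frequent exact DNA variant (tie: lexicographically smallest),
and the output is sorted by count descending, then protein. Collapsing
at the protein level (not DNA) was chosen because counts exist to
support a candidate *protein*; synonymous variants are evidence for the
same candidate.

**Primer coverage survey.** For each target the best within-tolerance
annealing-site variant is extracted and tallied. The `top_n` (default
10) most abundant variants are selected; every less abundant variant is
then merged into the most abundant selected variant within Hamming
distance `merge_radius` (default 1, absorbing sequencing errors and
point mutations), or dropped. Coverage is the kept abundance divided by
the number of targets with any within-tolerance site. Selecting first
and merging second makes coverage provably monotone in both `top_n` and
`merge_radius`.

## Annotation

Four conserved landmarks anchor the variable-domain architecture: the
FR1 cysteine (IMGT 23), the tryptophan after CDR1 (IMGT 41), the second
cysteine at the end of FR3 (IMGT 104, sought first in its Y-x-C
context), and the FR4 W-G-x-G tryptophan (IMGT 118). Default search
windows are 18–30, 31–48 and 85–112 (0-based anchor positions), and the
final 15 residues for the FR4 motif; all patterns and windows are
config-overridable. The windows are wider than the canonical positions
alone would need so that the full range of CDR1 (5–12) and CDR2 (4–10)
lengths keeps the anchors inside them. An anchor must match its
pattern's anchor residue exactly; multi-residue patterns tolerate one
mismatch elsewhere, and exact matches are preferred, then leftmost.
Anchors found out of order are discarded wholesale rather than
guessed at.

Boundaries follow from the anchors: FR1 ends three residues after
Cys-23, FR2 spans Trp-41 ± (2, 14), FR3 is pinned backwards 39 residues
from Cys-104, CDR3 is strictly between Cys-104 and the FR4 tryptophan,
and FR4 runs to the C-terminus (any hinge stub rides with it). A
missing anchor leaves its dependent regions unresolved (`None`) and
degrades confidence (`full` → `partial` → `failed`); downstream scoring
gives unresolved regions zero weight.

IMGT-style numbering is pinned linearly at the four anchors. CDR loops
are numbered by the bidirectional convention: residues fill the slot
range (27–38, 56–65, 105–117) from both ends toward the middle, the
extra residue of an odd-length loop sitting N-terminal. Loops longer
than the slot count receive fractional insertion codes ascending from
the middle slot — a simplification of the full IMGT insertion scheme
chosen to keep the map strictly monotone, which the GLEW lookup and the
cleavage histogram rely on. Externally computed numberings can be
imported and take precedence; boundaries are then derived from the IMGT
region definitions.

The GLEW check is position-specific: it is true only when IMGT 49–52
map exactly to G, L, E, W. If any of those positions is unmapped the
check is *indeterminate* (None), which deliberately does **not** remove
a candidate — the filter exists to strike known VH contaminants, not
sequences that merely failed annotation.

## Digestion

Cleavage rules are the simple Expasy-style site definitions: trypsin
cleaves after K/R, chymotrypsin (high specificity) after F/Y/W,
chymotrypsin (low specificity) after F/Y/W/M/L/H, all blocked before
proline. The extended Keil context exceptions are deliberately not
applied; the tests cross-check fragments against an independent
cleavage engine driven by these same rules and against a quadratic
reference. With zero missed cleavages the fragments tile the protein
exactly; `missed_cleavages=k` additionally emits every union of up to
k+1 adjacent fragments (default 0 for the emitted peptide lists, max 2,
because real PSM lists contain missed cleavages). I/L ambiguity is
*not* applied at digestion time — digestion is sequence-exact; isobaric
matching is a concern of the matching stage.

## Matching, scoring and selection

Peptide-to-sequence matching is substring containment with leucine and
isoleucine collapsed onto one symbol (they are isobaric and
indistinguishable by standard CID fragmentation); the flag is exposed
because it changes uniqueness denominators. Unmatched peptides are kept
and reported, never dropped.

The coverage score of a sequence is
`100 · Σ_r w_r·c_r / Σ_r w_r·n_r` over resolved regions, with default
per-residue weights FR=1, CDR1=3, CDR2=3, CDR3=10 (config-exposed; the
requirement is only that CDR3 carries the most weight). Unresolved
regions carry zero weight; a failed annotation falls back to uniform
weights and is flagged. Adding a match can never lower a score.

Clonotype groups are keyed by the I/L-collapsed CDR3 string (exact
mode, the default). Cluster mode single-linkage-merges exact groups
whose CDR3s have ungapped identity ≥ 0.8 at length difference ≤ 1.
Unresolved-CDR3 sequences become flagged singletons. Groups are ranked
by their top-scoring member (ties: total group read count, then group
id); members within a group by read count (ties: score, then id) —
higher-count sequences are likelier to be bona fide transcripts than
PCR/sequencing-error variants.

The uniqueness score of a peptide with respect to a group is 100 × the
group members containing it divided by the database sequences
containing it, the same containment relation as matching. Selection of
a member requires (i) at least one matched peptide with uniqueness
*strictly* above the threshold (default 80 — the bound is exclusive, so
exactly 80 does not qualify), (ii) no cross-antigen hit, and (iii) no
GLEW hallmark. The cross-antigen filter flags a member when any of its
CDR3-covering, above-threshold peptides also appears (I/L-equivalent)
in an unrelated antigen's observed peptide set — peptide-level
comparison, because MS samples contain peptides, not sequences. The
post-elimination candidate list (`CandidateReport.candidate_shortlist`)
drops groups in which every member was flagged; the flags themselves
are always serialized. Selected candidates get an evidence table of
their CDR3-spanning peptides, ordered for manual inspection of MS/MS
fragmentation within CDR3 — no automatic spectral validation is
attempted.

## The synthetic experiment

The generator emulates the study conditions end to end. Clones share a
fixed framework scaffold (FR1 26 aa with Cys at index 22; FR2 17 aa
with the anchor Trp and a VHH-type E-R-E at IMGT 49–51, or the G-L-E-W
VH hallmark for a configurable fraction; FR3 39 aa ending Y-Y-C; FR4
W-G-Q-G…, 11 aa) with CDR loops drawn uniformly over configurable
length ranges (CDR1 6–10, CDR2 5–9, CDR3 5–22) from an 18-letter
alphabet excluding Cys and Trp, which are reserved as anchor landmarks.
Each clone gets a random codon assignment, a hinge class, and an
amplicon consisting of the printed leader-primer annealing site
(degenerate position instantiated per clone), the coding region, and
the reverse complement of the matching hinge primer site. Abundances
are log-normal (σ = 1), producing the count regime the ranking relies
on.

Reads are the first/last 300 bases of the amplicon flanked by fresh 6N
tails, with i.i.d. substitution errors (default 0.3% per base) and flat
qualities at the Phred equivalent of the error rate. Binders (default
5) and a disjoint decoy binder set are drawn with probability
proportional to abundance: serum antibodies recovered by affinity
purification come from expanded clones, and rare clones are not
required for recovery. Peptide observations digest the binder proteins
with trypsin and with chymotrypsin under both specificity rules, expose
peptides with up to 2 missed cleavages (enzymatic digestion of real
samples is incomplete, and search engines routinely allow missed
cleavages), and observe each distinct peptide with probability 0.6.
Contaminants are added at 5% of the observation count: half are
peptides of random non-binder clones — nonspecifically co-purifying
VHH background, which is therefore also written into the
unrelated-antigen decoy sample where the cross-antigen filter can see
it — and half are random strings, which stay sample-specific.

What passing the simulated experiments shows: the pipeline's bookkeeping
is exact (conservation laws, oracle equivalence), the noiseless limit
reconstructs and selects the binders perfectly, and under the default
noisy conditions all binder clonotypes reach the top 5 of the
post-elimination candidate list in ≥ 95% of seeded runs. What it does
not show: robustness to real somatic-hypermutation framework diversity
(the simulator uses one scaffold), indel sequencing errors, chimeric
amplicons, retention-time or spectrum-level effects, or search-engine
FDR behavior — peptide observations here are sampled from the true
digest rather than inferred from spectra.

## Problem sizes and runtime

The default recovery experiment uses 500 clones, 5 binders, 20,000 read
pairs and 20 seeds (~13 s per seed, ~5 min total); the noiseless check
runs one default-size experiment; oracle-equivalence suites use 1000
randomized cases per operation and the conservation suites 500
instances each. These sizes were chosen to give the statistics meaning
(binomial noise on a 20-seed success rate resolves the 95% criterion)
while keeping a full run on one CPU inside a coffee break.

## Known limitations

- The anchor motifs approximate profile-HMM numbering; unusual
  frameworks (mutated anchors, atypical FR3 lengths) degrade to partial
  annotations rather than being force-numbered. External numberings can
  be imported instead.
- IMGT insertion codes for very long CDR3s are monotone fractional
  positions, not the official alternating insertion letters.
- Hamming-only primer matching misses indel-containing primer sites.
- Per-member selection can mark many error variants of a strong binder
  as selected (they genuinely carry clonotype-unique peptides); the
  candidate taken forward is the top-count member of each shortlisted
  group, and the report preserves that ordering.
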