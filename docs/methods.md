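# Methods

This note documents the models, parameter choices and numerical
conventions behind `ureidoscan`, and what the synthetic benchmark does and
does not establish.

## Active-site model and classification rule

The unit of analysis is the 8-residue condensation-domain active-site
window M1..M8. Two exact patterns are distinguished:

| label | pattern | fixed positions |
|---|---|---|
| `C_urea` | EHHXXHDG | M1=E, M2=H, M3=H, M6=H, M7=D, M8=G |
| `canonical_C` | XHHXXXDG | M2=H, M3=H, M7=D, M8=G |

Anything matching neither is `noncanonical`. The ureido pattern is a
strict specialization of the canonical core; classification is pure
string matching with no substitution tolerance (no D-for-E credit), and
the unknown residue X never satisfies a constrained position. We chose
exact matching because the claim under test is that the exact octamer
separates ureido-forming from all other condensation domains; a fuzzy
rule would make that claim untestable. Condensation-domain subtypes other
than the ureido variant (epimerizing, heterocyclizing, X-domains) are not
distinguished — they fall into `canonical_C` or `noncanonical`.

Coordinates are 0-based half-open internally and 1-based inclusive in all
user-facing output, matching enzymological residue numbering (E744, H746,
H749, S753 in SnaA coordinates; M1 at alignment position 144 and the
conserved serine at 153 of the domain register).

## Anchoring and profile scoring

Candidate anchors are found by scanning for the four fixed core positions
only (M2=H, M3=H, M7=D, M8=G) — an exact, exhaustively auditable
operation. A *relaxed* scan additionally admits windows matching 3 of the
4 fixed positions; relaxed anchors model degraded domains, are flagged,
and are never classified `C_urea`.

Discrimination between candidate anchors is delegated to a
position-specific scoring matrix built from an alignment of active-site
regions: per column, `freq = (count + α) / (n_ungapped + 20α)` with
Jeffreys-style pseudocount α = 0.5 (configurable), gaps and X excluded
from counts, and log-odds in bits against a uniform 1/20 background (no
composition is assumed; a composition-based background is a config
option). The scoring window spans 30 columns upstream and 10 downstream
of M1 — conservation is concentrated around the active site, and a short
window keeps decoy noise out. Score ties prefer exact-core anchors over
relaxed ones, then the leftmost anchor (determinism). Positions clipped
off the sequence and X residues contribute 0 bits.

Domain excision around an anchor uses ±150/+300 residues by default
(bracketing a typical ~450-residue condensation domain); the analysis
scripts use ±60 for alignment/tree work, which keeps the conserved region
and makes the all-pairs alignment step fast. These bounds are artifact
choices — the boundary convention used for the original alignments is not
recorded in the literature the signature comes from.

## Alignment, distances, trees

Pairwise alignment is global Needleman–Wunsch with affine gaps under the
three-state Gotoh recurrence; a gap run of length k costs
`open + (k−1)·extend`, BLOSUM62 with open 11 / extend 1 by default
(the values shipped with Biopython). Traceback is deterministic with tie
order diagonal > up > left. An empty sequence aligns all-gap with score
`−(open + extend·(n−1))`.

Distances are `1 − identities / aligned-columns` (dual-gap columns
excluded) — the simplest auditable choice; model-corrected distances are
deliberately not implemented. Trees are built by neighbor joining
(Saitou–Nei Q-criterion), with exact Q ties broken by the
lexicographically smallest pair of node ids (an internal node is keyed by
the smallest leaf label beneath it) and negative branch lengths clamped
to zero with a log entry. Trees are unrooted; monophyly of a label set is
defined by edge bipartitions. Progressive multiple alignment merges
profiles in guide-tree postorder with the same affine scheme
(profile–profile column scores are count-weighted average substitution
scores); gaps once introduced are never removed.

Column conservation is `IC = log2(20) − H(column)` in bits with gaps and
X excluded and no small-sample correction (so an invariant column scores
exactly 4.3219 bits and a uniform column 0).

## Signature screening and the neighborhood rule

`evaluate_signature` treats `urea` labels as the positive class and pools
`amide`/`other` as negative, mirroring the binary form of the claim;
sensitivity and specificity are reported as NA when their denominator is
empty. Every labeled protein must have a classified call; the pipeline
guarantees one by scanning strictly first and falling back to relaxed
candidates (at best `noncanonical`) for motif-free proteins.

The genome-neighborhood rule marks a gene carrying the glutamylation
family PF04738 as dehydratase-like when the elimination family PF14028
occurs anywhere in the same cluster record — not just on the same gene —
because the underlying observation concerns the genome neighborhood, and
as PEARL-like otherwise. Family annotations are taken as given in the
BGC record; no HMM annotation is performed.

## The synthetic generator

The generator emulates a family of condensation domains as seen through a
sequence alignment: a random consensus per function class (ureido and
canonical classes get independent consensi, mimicking distinct
subfamilies) over a **column-wise conservation profile**. Each non-motif
column is conserved with probability `identity`; in a variable column
every member draws an independent uniformly random non-consensus residue.
The mean pairwise per-site match probability is therefore
`identity + (1 − identity)/19` (two variable-column draws coincide with
probability 1/19), which the tests check by simulation. Defaults: domain
length 450, M1 at domain position 300, identity 0.7, benchmark of
5 ureido + 20 amide + 5 decoy-only proteins — the conditions used
throughout the analysis scripts and acceptance checks.

Motif columns are exempt from mutation: ureido members get `EHH??HDG`
(?? uniform), canonical members `?HH???DG` with (M1=E ∧ M6=H) excluded,
so labels and octamer classification agree by construction. Both classes
conserve a serine two residues downstream of M8 (the conserved serine is
also present in amide-forming domains). Domains are embedded between
uniform-random flanks carrying planted decoys (exactly 3 of 4 fixed core
positions); accidental windows matching ≥3 core positions are scrubbed by
overwriting one matching position with alanine, and a drawn octamer whose
free positions would recreate an unremovable overlapping near-motif is
redrawn. Consequently a strict scan finds exactly the embedded motif and
a relaxed scan exactly the motif plus the planted decoys, deterministically.
Substitutions are i.i.d. per column with no indels by default, keeping
coordinate truth exact.

**What this shows and does not show.** Because motif positions are exempt
from mutation, perfect sensitivity/specificity on the benchmark asserts
end-to-end label fidelity of the pipeline (plumbing), not biological
discovery power. Detection power is exercised separately by the
anchor-ranking experiment: at 60% conservation with 3 decoys per protein,
the top profile-scored anchor must equal the embedded truth in ≥99% of
500 proteins. The generator does not model indel-rich real alignments,
phylogenetic (tree-structured) correlation between family members, or
realistic amino-acid composition; conclusions about real proteomes
require real inputs through the same interfaces.

The SnaA-register construct (`snaa_like_benchmark`) is a synthetic
stand-in: it reproduces only the register geometry of SnaA's
ureido-forming domain (octamer EHHLVHDG with M1 at protein residue 744
and the conserved serine at 753, via a 300-residue domain with M1 at
domain position 144 embedded after a 600-residue upstream flank). No real
SnaA sequence is used; running the real ADD43706.1 entry through
`ureidoscan scan`/`classify` is the corresponding real-data check when
the sequence is available.

## Problem sizes and numerical conventions

The analysis and acceptance runs use 25 labeled domains for the
tree/monophyly stage (±60-residue active-site regions), 500 + 50 proteins
for the ranking experiment, and 30 proteins for the screen — sizes chosen
so the whole study re-runs from scratch in well under a minute on one
CPU while every stage still operates at family scale. Profile columns
sum to 1 within 1e-9 after pseudocount normalization; Newick round trips
preserve branch lengths to 1e-9 (12 significant digits written); NJ on
additive matrices recovers generating trees to 1e-9. All randomness
derives from a single integer seed per run.

## Known limitations

* Exact-match classification will miss natural ureido-forming variants
  that deviate from EHHXXHDG, should any exist beyond current examples;
  the package deliberately does not guess.
* The profile scanner is a PSSM, not a profile HMM: no insert/delete
  states, so it assumes an ungapped active-site region.
* Neighbor joining with identity distances is a reconstruction heuristic;
  no bootstrap support or likelihood model is provided, and topology-level
  agreement with any particular published tree is not claimed.
* GenBank parsing, database (MiBiG) access and nucleotide-level analysis
  are out of scope; inputs are FASTA, the JSON BGC record schema, and TSV
  label tables.
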