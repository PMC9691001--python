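# Methods

## The model

A germline SINE insertion is a presence/absence character on a rooted
species tree. Integration by target-primed reverse transcription duplicates
the target-site bases into flanking TSDs and is effectively irreversible,
so absence is the ancestral state of every locus. Under Dollo parsimony
("Dollo.up") a character may be gained exactly once — at the most recent
common ancestor of its carriers — and lost any number of times; the step
count for a column is 1 (the gain) plus the minimum number of 1→0 losses
below the gain node, with missing states resolved to minimize steps. A gain
placed at the root node itself is allowed and counted as one step (the root
*state* is still ancestral absence conceptually; the whole-tree gain is the
single permitted origination). An all-absent column costs 0 steps.

`dollo_steps` computes this by a post-order dynamic program: for each node
`v`, `loss[v]` is the minimum number of losses in the subtree given the
state above `v` is 1 (a subtree with no definite carrier can be shut off
with a single loss on its stem), and the step count is `1 + loss[MRCA of
definite carriers]`. The vectorized form scores all matrix columns in one
pass per tree. Tests verify equivalence with a brute-force enumeration over
all ancestral assignments with ≤ 1 gain, for every topology with up to six
taxa and every binary character.

Tree statistics follow the standard parsimony conventions: per variable
character the minimum conceivable length is mᵢ = 1 and the maximum gᵢ is
the Dollo length on the completely unresolved star tree; CI = Σmᵢ/Σsᵢ,
HI = 1 − CI, RI = (Σgᵢ−Σsᵢ)/(Σgᵢ−Σmᵢ). Constant characters are excluded
throughout; parsimony-uninformative characters (gᵢ = mᵢ) are excluded from
the RI sums. Because conventions differ on whether CI also excludes
uninformative characters, both variants are computed (`ci` and
`ci_informative_only`).

## Tree search and bootstrap

Exhaustive search enumerates all unrooted topologies (limited to ≤ 9
distinct taxa; (2n−5)!! shapes), rooted on the outgroup edge, and returns
every co-optimal tree. The heuristic is random-order stepwise addition
followed by nearest-neighbor-interchange and subtree-pruning-regrafting
hill climbing, with configurable restarts (default 10); the outgroup
attachment is never disturbed, which keeps Dollo rooting valid throughout.
The SPR neighborhood excludes regrafts adjacent to the root; NNI plus
restarts compensates. On random 5-taxon matrices the heuristic matches the
exhaustive optimum in ≥ 29/30 seeded trials.

The bootstrap resamples characters with replacement, re-runs a cheaper
heuristic (NNI only, 2 restarts by default), and reports for every internal
clade of the reference tree the percentage of replicate optima containing
it; the full clade-frequency table feeds a greedy majority-rule consensus.

## The synthetic panel

The generator is the package's study condition, not a convenience fixture.
Defaults emulate a multi-specimen owl-monkey-style panel:

- **Species tree**: four ingroup taxa — `vociferans` basal, then
  `trivirgatus`, then sister species `nancymaae` (the reference) +
  `azarae` — plus one outgroup; 9/4/6/3 ingroup individuals and one
  outgroup individual (22 + 1 genotyped samples).
- **Subfamilies**: consensuses ≥ 267 bp derived from one root sequence with
  an A-rich linker; each subfamily carries private diagnostic substitutions
  (default 3 subfamilies × 4 diagnostics), so inter-subfamily Hamming
  distance is ≥ 2 × 4 and assignment by minimum alignment mismatch is
  unambiguous for young copies.
- **Events**: Poisson with mean rate × total branch length, branch chosen
  proportional to length. Non-ILS events are fixed (frequency 1) in all
  descendants of their branch and absent elsewhere. TSD length is uniform
  on [5, 20] bp and the A-tail uniform on [8, 30] bp — typical
  L1-machinery ranges; neither is part of the element length used by the
  full-length filter, but the annotated element interval *includes* the
  tail (as repeat masking does), so
  filled − empty = element + tail + TSD exactly.
- **Divergence**: each event's copy is mutated once at
  substitution_rate × (age = branch midpoint to tips), shared by all
  carriers — modelling common ancestry and the RepeatMasker divergence d
  (default 0.002/site/unit gives ~0.2–1.2% for the default tree, i.e.
  "young" copies). Per-taxon backbones additionally drift at
  `flank_divergence` (default 0.5%) so flank anchoring is exercised
  non-trivially. This is far below real between-genus divergence: the
  anchor-based orthology caller is a desk-scale stand-in for a full
  aligner, and the simulation keeps it in its operating range.
- **ILS**: phenomenological, not coalescent — an ILS event receives a
  carrier set rejection-sampled to be a non-clade, with per-carrier allele
  frequency drawn from {0.5, 1.0}; ILS events are therefore also the only
  default source of within-species polymorphism. This suffices to exercise
  category classification, homoplasy indices and topology-recovery
  behavior, but says nothing about coalescent branch-length expectations.
- **Near-parallels**: with small probability an event is planted 50–260 bp
  5′ of an earlier target, carried by a tip that lacks the target —
  reproducing the confounding same-size-band scenario.
- **Individuals**: two haplotypes per individual, each allele an
  independent Bernoulli draw from the taxon frequency (Hardy–Weinberg).
  Per-taxon *assemblies* carry an event iff its frequency is ≥ 0.5.

Coordinates are 0-based half-open internally; RepeatMasker `.out` files are
read/written in the native 1-based inclusive dialect including the reversed
repeat-coordinate convention for C-strand hits.

## Orthology calls by gap size

For a candidate with 600 bp flanks, both flanks are anchored in a
comparison assembly by exact k-mer seeds (k = 25, stepping away from the
element junction by 7 bp up to 40 times until a uniquely-mapping seed is
found). The TSD is estimated as the longest left-flank-suffix /
right-flank-prefix overlap (≤ 30 bp); adding it to the anchored junction
gap makes the empty configuration read ≈ 0 and the filled configuration
read ≈ element span + TSD. With the default tolerance of 15 bp the call is
`unique` (absent in the target) for |g| ≤ 15, `shared` for
|g − (element+TSD)| ≤ 15, otherwise `unresolved` — including anchoring
failure, which is a data state, not an error. The 15 bp default is a
repository decision (the tolerance is not dictated by the underlying gap
statistic); it comfortably absorbs TSD over-detection by chance overlap
(geometric, ~1/4 per extra base).

## Primer design

Candidate windows of 18–27 nt within 300 bp of each junction are screened
by GC ≥ 40%, homopolymer runs ≤ 3 ("Max Poly X = 3" read as maximum run
length 3, runs of 4 fail), and nearest-neighbor Tm within 57–62 °C
(Biopython `Tm_NN`, 50 mM monovalent salt, 200 nM oligo, matching the PCR
recipe the constraint block accompanies; Primer3's exact internal Tm
variant is not reproduced and the conditions are configurable). Pairs must
differ by ≤ 2 °C, amplify the empty allele within the product limits, and
give filled > empty; ranking is |ΔTm| then closeness of the empty product
to a 250 bp optimum — a repository convention, not Primer3's scoring.
Specificity is "one exact match in the assembly over both strands"; a
palindromic primer occurring once counts on both strands. Amplicon size is
measured 5′-end to 5′-end inclusive, and a missing or duplicated primer
site yields no product (modelling PCR failure / null alleles).

## Genotyping, categories and sequence review

Fragments within ±20 bp (gel-resolution scale; band sizes are only ever
approximate) of the expected filled/empty sizes give (1,1)/(1,0)/(0,0);
no product is missing data; an off-size fragment flags the locus for
sequence review. Review aligns the amplicon against the reconstructed
empty reference with affine gap penalties (Biopython `PairwiseAligner`;
unit-cost alignment fragments a long insertion into micro-matches), takes
the largest inserted block, and classifies it against the subfamily
consensus set: ≤ 25% divergence → near-parallel insertion (with signed
offset, 5′ negative, and orientation relative to the target); otherwise a
non-repeat artifact/structural finding. Carriers are re-coded
target-absent, unresolved evidence becomes missing, and every change is
logged; adjustment is idempotent and conflicting findings are an error.

Categories are assigned in fixed precedence: fixed present → fixed absent
→ restricted to the reference species (homozygous-present vs polymorphic)
→ shared by exactly two species → by three → residual ILS. Sharing
categories additionally require the element present in *every* genotyped
individual of each carrier species; presence segregating across several
species is exactly the erratic pattern attributed to ILS, and lands in the
residual class. Single-specimen taxa can be passed as auxiliary species:
they are reported but never anchor a category alone. The three-way
partition (fixed present / fixed absent / polymorphic) always sums to the
classified locus count.

## Character encoding

(1,1) and (1,0) encode as 1, (0,0) as 0, missing as `?`. Outgroup taxa
absent from the genotype table are appended with state 0 at every locus —
they are ascertained-absent by construction, which is the directional
ascertainment bias inherent to reference-genome ascertainment (the matrix
records it honestly rather than correcting it). NEXUS output is a standard
DATA block plus a PAUP block with `ctype Dollo.up: all;`.

## Problem sizes and numerical choices

The default pipeline demo uses ~130 events on a 0.6 Mb backbone with 23
genotyped individuals, 50 bootstrap replicates and 5 search restarts —
minutes of CPU. The acceptance script scales the ascertainment check to
> 500 insertions (~1.5 Mb backbone) and topology recovery to 100 simulated
panels; both sizes were chosen so the measured rates are stable to a few
tenths of a percent while the whole script stays in the minutes range.
All randomness flows from a single integer seed through
`numpy.random.default_rng`; identical seeds give byte-identical FASTA,
CSV and tree outputs.

Degenerate inputs are handled explicitly: all-constant matrices raise an
"indices undefined" error rather than returning NaN silently; all-missing
loci cannot be classified; expected filled/empty sizes closer than twice
the size tolerance are rejected; backbone overflow on placement raises a
placement error naming the colliding loci; subfamily assignment ties break
to the lexicographically smallest name.

## What passing tests do and do not show

The simulator's flanks drift at ~0.5% between taxa and elements at ≤ ~2%
from their consensus; real cross-genus comparisons are an order of
magnitude more diverged, with indels, segmental duplications, assembly
gaps and repeat-dense flanks that defeat exact k-mer anchoring. Truth
recovery rates reported here therefore validate the *logic* of the chain
(gap arithmetic, TSD handling, category precedence, Dollo scoring), not
its robustness to real assembly noise — a production run would substitute
a full aligner for the anchor-based caller behind the same interface.
Likewise the phenomenological ILS model exercises discordance handling but
does not calibrate expected discordance rates, and Sanger chemistry
(chromatogram quality, weak amplicons) is out of scope: sequence review
operates on the in-silico amplicon sequences directly.
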