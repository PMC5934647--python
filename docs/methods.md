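# Methods

## The system being modelled

IS608 (an IS200/IS605-family insertion sequence from *Helicobacter pylori*)
transposes through single-stranded top-strand DNA intermediates
("peel-and-paste").  The transposase is a HUH endonuclease that cleaves DNA
with a catalytic tyrosine, forming a 5'-phosphotyrosine covalent intermediate
with the segment 3' of the cut.  Cleavage sites are 4-nt motifs read not by
protein but by DNA base pairing: a guide tetranucleotide (G_L = AAAG at left
end positions +16..+19) pairs with the integration target core (C_T = TTAC),
and a pair of base triplets — extension bases +42/+43 stacked onto the
G_L:C_T pairs — stabilizes the target capture complex.  Integration occurs
immediately 3' of C_T and strongly prefers a cytosine at the next position
(+1); the +1 pocket of the enzyme is tight and disfavors purines.

The retargeting strategy implemented by this package extends the G_L/C_T
pairing: an 8–13 nt sequence installed at LE positions +44..+(43+L) is made
reverse-complementary to the target window lying a 3-nt linker upstream of
C_T, so the transposon recognizes a 12–17 nt site (4 + L).  Two
structural obstacles must be removed for the extension to engage: the
triplet-forming purine at +42 (mutated to T, which maintains the triplet as
the more stable T·A:T form and relieves steric strain) and, in the wild-type
element, a second stem-loop over +46..+60 that buries the extension window
in the folded ssDNA intermediate (opened by point mutations confined to
+55..+60).

## Coordinates

* Transposon ends: 1-based on the top strand, 5'->3' (prose uses the "+"
  prefix).  On a junction oligo, left-end coordinates start at the `LE`
  feature (offset 50 in the canonical layout).
* Targets: cleavage-relative; C_T occupies -4..-1, the cut falls between -1
  and +1.  With the default 3-nt linker, the 8-nt design window is -15..-8
  and the register pairs +44 with -8 antiparallel through +51 with -15.
* Genome output (BED6) is 0-based half-open.

## Secondary-structure model

The fold is a weighted Nussinov maximum-pairing dynamic program, not a
nearest-neighbour thermodynamic model: the biological questions here —
"does the IP_L stem-loop form?", "is the extension window buried?" — are
binary and topological, and a free-energy model would add parameters the
analysis never exploits.  Choices:

* Pair weights AT = 2, GC = 3, GT = 1; G:T wobble disabled by default (the
  relevant hairpins are canonical).
* `min_loop = 3`: a hairpin-closing pair (i, j) requires j - i > 3.
* `min_helix = 3`: pairs count only inside runs of at least three stacked
  pairs.  Unconstrained pair maximization pairs essentially every position
  of a 100-nt oligo, which would make every window look occluded; 1–2 bp
  duplexes are not stable at assay temperature, and requiring 3-stacks
  restores a meaningful notion of "single-stranded" while leaving every
  planted stem (IP_L: 9 bp; second hairpin: 6 bp) detectable.
* Deterministic traceback: when structures tie, the one pairing the 5'-most
  position first is returned, with a fixed candidate iteration order.
* Exactness is property-tested against exhaustive enumeration of all nested,
  helix-constrained structures for lengths <= 12.

Accessibility of a window is its unpaired fraction under the optimal fold.
A design is considered retargeting-competent when the extension window is at
least 90% unpaired — an all-or-nothing cutoff mirroring the all-or-nothing
effect of planting or opening the second hairpin in the competition data.
The +42/+43 triplet-forming bases fold freely in the free ssDNA (their
triplet partners exist only in the synaptic complex).

## Synthetic fixtures

Wild-type end sequences are not reproduced; fixtures are synthetic oligos
that pin the functionally characterized anchors: G_L = AAAG at +16..+19, a
perfect 9-bp/4-nt-loop palindrome at +20..+41, A+42/T+43, the extension
window from +44, and optionally a second hairpin whose 3' arm (+55..+60)
pairs +46..+51.  Random filler is drawn deterministically from the seed and
redrawn until the fold exhibits exactly the intended architecture (and, for
planted hairpins, until opening the +55..+60 arm provably frees the
extension).  The canonical junction prepends a 46-nt RE-derived segment plus
the joint motif TCAA, so the 5' segment up to the cleavage position is 50 nt.
Target pools follow the competition-assay layout: a fully complementary
target with a 38-nt 3' segment, a random competitor with a 30-nt 3' segment
(distinguishable product length), and scrambled-window competitors whose
windows are redrawn until they share fewer than 5 contiguous
register-correct bases with the extension — 5 bp being the complementarity
length shown not to confer selection.  All fixture members carry the
preferred C at +1 so competition isolates the pairing effect.

A design-grade extension is dictated by the user's target, so a scaffold
with a perfectly unpaired window may not exist (e.g. self-complementary
windows, or T-rich windows that pair the A-rich G_L).  Junction generation
then returns the most accessible scaffold found and validation reports the
residual structure honestly; the bundled demonstration locus screens its
planted window against these failure modes (no TTT/CTT in the extension, no
self-fold), exactly as a user would screen candidate sites.

These fixtures emulate the *architecture* of the in vitro substrates, not
real genomic context: no chromatin, no replication-dependent ssDNA exposure,
no bottom-strand events, and sequence composition is uniform-random.
Passing tests therefore demonstrate correctness of the design logic and
bookkeeping, not in vivo retargeting efficiency.

## Competition model

Selectivity is encoded as a cooperative (Hill-type) function of the longest
run of consecutive register-correct Watson-Crick pairs between extension and
target window:

    weight = rel_conc x plus1_weight x coop(m)
    coop(m) = floor + (amp - floor) * m^h / (m^h + K^h)

with defaults floor = 1, amp = 60, K = 6.8, h = 12.  The parameters are not
fits to densitometry (the source data are gels); they are the simplest curve
satisfying the two ordinal outcomes the assays establish, re-checked
numerically whenever parameters are constructed:

* coop(8)/coop(0) >= 40 — an 8-match target keeps the majority of
  integration against >= 20-fold molar excess of zero-match competitors
  (with the defaults the model sustains majority selection up to 52-fold);
* coop(5)/coop(0) <= 3 — 5 matches give no efficient selection.

A per-base multiplicative bonus cannot satisfy both constraints at once,
which is why the curve is sigmoidal; the contiguous-run statistic reflects
duplex nucleation (non-contiguous partial complementarity is not modelled,
as it was never tested).  +1 weights are ordinal encodings of the cleavage
gel classes: C = 1.0, T = 0.5, A = G = 0.15.  Off-target scans bin sites by
match length; "high risk" means a full 8-match register with C at +1.

## Design procedure

1. `design_extension` — extension := reverse complement of the window at
   -(linker+4+L)..-(linker+5); registers, features and the 4+L recognized
   length are recorded.  Lengths 8–13 are supported (13 is the longest
   demonstrated); 5–7 emit a selectivity warning; linkers 2–5 are accepted
   with a warning away from the optimal 3.
2. `apply_structural_unlocking` — set +42 to T; while the extension window
   is < 90% accessible, substitute one base at a time within +55..+60
   (5'->3', transversions before the transition, keeping the substitution
   that most improves accessibility after refolding).  G_L, IP_L, +43 and
   the extension are never edited; failure returns the best design found,
   marked failed, rather than raising.
3. `reset_ct` — alternative core sites are programmed by rewriting the guide
   base that reads each changed C_T position (defaults -4 -> +17,
   -3 -> +16, the two structure-characterized pairs).  Positions -2/-1 have
   no named guide partner and are not resettable unless the user extends the
   map explicitly.
4. `validate_design` — accessibility, self-complementarity (no >= 6-nt
   reverse complement of the extension elsewhere in the junction),
   unintended-C_T creation, register complementarity, and optionally a
   genome off-target summary.

## Transposition bookkeeping

All steps are pure sequence accounting with conservation invariants: cuts
fall immediately 3' of a 4-nt cleavage motif located by sequence/feature
analysis at run time; excision retains C_L (TTAC) in the sealed donor's left
flank and circularizes the element at the RE-LE joint; linear junction
integration yields the labeled 5'-segment + target-3'-segment species seen
on denaturing gels; circular junction integration inserts the element
scarlessly 3' of C_T.  The virtual gel lists labeled species by descending
length with competition fractions as intensities.  Bottom-strand chemistry,
kinetics and divalent-metal effects are out of scope.

## Structure validation

`struct_validate` (gemmi-backed) resolves named atom selections in a
user-supplied PDB/mmCIF coordinate file of the target capture complex and
recomputes the linker-gap distance (target-terminus O5' to the +44
phosphorus) and the catalytic-competence distance (tyrosine hydroxyl to the
scissile phosphorus at +1), selecting the active complex copy among the
several in an asymmetric unit by the latter distance itself.  The module is
exercised in tests on small synthetic coordinate fixtures only; the
`checkstruct` CLI subcommand runs the same computation on a locally
downloaded deposition.

## Problem sizes and determinism

Everything is seeded and deterministic: fixture generators consume a single
integer seed, folding tie-breaks are fixed, and repeated runs are
byte-identical.  Default demonstration sizes — a 400-nt locus, 70-nt left
ends, 120-nt junctions, pools of six targets, 200-donor conservation sweeps
and 500-sequence fold-oracle sweeps — were chosen to exercise every code
path at interactive speed.

## Known limitations

* The fold is qualitative; it cannot rank near-isoenergetic structures or
  capture temperature/ion dependence.
* coop parameters encode ordinal outcomes, not measured intensities;
  predicted fractions are relative preferences, not absolute rates.
* Only top-strand events are modelled; a genomic target is treated as
  available ssDNA.
* The guide/core pairing network beyond the two structure-named pairs is
  deliberately not guessed (exposed via `GlCtMap`).
* Wild-type end sequences are synthetic stand-ins anchored at the
  characterized positions.
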