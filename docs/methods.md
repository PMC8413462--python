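# Methods

`snokturn` annotates the conserved sequence motifs of box C/D
methylation-guide snoRNAs, classifies whether their internal box C'/D'
elements can form the kink-turn (k-turn) structure recognised by the
eukaryotic protein Snu13 and its archaeal orthologue L7Ae, predicts
2'-O-methylation sites on substrate RNAs, and checks ribonucleoprotein
(RNP) stoichiometry hypotheses against observed particle masses. This note
records the model, the parameters that matter, the numerical conventions,
and what the synthetic benchmark does and does not establish.

## The k-turn model

A box C/D k-turn is described by a coordinate frame over two windows on the
same strand: a 7-mer box C-like window (consensus 5'-RUGAUGA, R ∈ {A, G})
and a 4-mer box D-like window (consensus 5'-CUGA). Structural roles map
onto the consensus as

```
box C window :  L2  L3  1b  2b  3b  4b  5b      (R   U   G   A   U   G   A)
box D window :  4n  3n  2n  1n                  (C   U   G   A)
```

with the two strands antiparallel: stem-II pairs are (1b,1n)…(4b,4n), and
stem-I pairs −1 and −2 sit just outside the windows (−1 pairs the
nucleotide two positions 5' of the C-like window with the one immediately
3' of the D-like window; −2 one step further out). L1–L3 are the bulged
loop nucleotides. The kink-proximal stem-II pairs are the tandem sheared
pairs: 1b•1n = G•A and 2b•2n = A•G. For the terminal box C/D motif the
C window lies near the 5' end and the D window near the 3' end; for the
internal box C'/D' motif the D' window lies 5' of the C' window and stem I
closes over the intervening spacer.

Feature evaluation is sequence-level, not structural prediction:

- the sheared-pair flags are strict identity checks (exactly G with A);
- an "intact" stem-I pair admits Watson–Crick and G•U wobble geometries,
  because genuine k-turn stems can open with a wobble pair;
- a k-loop is declared only when both the −1 and −2 pairs fail or are
  absent; a broken −1 with intact −2 is reported as a broken stem I, not a
  k-loop (the conservative reading);
- the stem-II score counts how many of the four pairs have the canonical
  identities (G•A, A•G, U•U, G•C), giving 0–4; only the four pairs whose
  partners lie inside the D-like window are scored (the 5b partner falls
  outside it);
- any pair involving N or an out-of-sequence position evaluates false.

## Box annotation rules

- **Box C**: best RUGAUGA match starting within 5 nt of the 5' end, at most
  one mismatch by default (`max_mismatch`, configurable); fewer mismatches
  win, ties go to the smaller start.
- **Box D / D'**: exact CUGA matches (the D boxes are treated as strictly
  conserved). When the guide position paired with a known methylation
  target is supplied, the box must start exactly five nucleotides
  downstream of it. Box D without target information is the 3'-most CUGA
  in the final 15 nt.
- **Box C'**: among all 7-mer windows between box D' (leaving its two
  stem-I slots free, start ≥ D'.end + 3) and the guide upstream of box D
  (end ≤ D.start − `min_gap_to_d`, default 6 nt — a minimal guide
  reservation, configurable), the window maximising the stem-II score
  against the D' window is selected; ties are broken by fewer mismatches
  to RUGAUGA, then by smaller start. If no window scores ≥ 1 the snoRNA is
  reported as having no credible box C'/D' rather than forcing a window.
- **Joint D'/C' selection**: generic inputs lack target anchors for D', so
  every CUGA between box C and box D is kept as a D' candidate and the
  (D', C') pair with the maximal stem-II score wins; ties go to the
  5'-most D'. Where a curated database placement disagrees, the database
  placement can be imposed by passing the known guide position.

`window_offset` measures the shift between two same-length candidate
windows that tile one region (smallest positive s with
`a[s:] == b[:len−s]`); it reproduces the 3-nt re-annotation shifts of the
documented worked examples. The identity that holds generally is symmetry
under region reversal, `offset(a, b) == offset(reverse(b), reverse(a))`;
plain argument swapping is not symmetric for self-overlapping windows.

## Functional classification

Snu13 recognition of a box C'/D' element requires all three of: the 1b•1n
G•A pair, the 2b•2n A•G pair, and an intact −1 stem-I pair. The five
mutually exclusive categories are: CANONICAL (both windows match
consensus), FUNCTIONAL_NONCANONICAL (all three required features without
full consensus), TANDEM_NO_STEM1 (tandem sheared pairs, −1 broken),
MISSING_SHEARED (at least one sheared pair absent), NO_MOTIF (annotation
failed). "Functional" means the first two categories; the census reports
category counts and the percentage non-functional, with NO_MOTIF counted
as non-functional.

Binding predicates are qualitative tiers, not affinities:

- **Snu13**: BINDER when all three required features hold and the stem-II
  score is the canonical maximum of 4; WEAK when the three features hold
  at score < 4 (the observed weak, smearing complex of one construct shows
  the features are necessary but not sufficient for a strong complex);
  NONBINDER otherwise.
- **L7Ae**: BINDER when 1b•1n G•A is present together with either an
  intact −1 pair or the 2b•2n pair; WEAK for a k-loop carrying only the
  first sheared pair (fast-dissociating, smeared bands); NONBINDER
  otherwise.

Known limitation: one construct in the published EMSA panel (snR41-kl2)
carries all three required features yet showed no Snu13 binding; the
feature-level predicate necessarily over-calls it, and the panel table
records its Snu13 outcome as "not asserted". Sequence determinants beyond
these features (and beyond the stem-II score) evidently modulate Snu13
affinity.

K_D bounds from EMSA titrations use only the order-of-magnitude rule for
saturating lanes: complete displacement at a 1:1 protein:RNA ratio bounds
K_D ≤ [RNA]_total / 10 (2 µM RNA → ≤ 200 nM). Lower bounds from
non-binding lanes are reported descriptively only, because the published
non-binding bounds use inconsistent factors.

## Methylation-site prediction

The guide region immediately 5' of box D (or D') must form a contiguous
antiparallel duplex with a substrate window, ending flush at the box
(internal gaps are not modelled; the guide–substrate helices are drawn
contiguous). The search maximises duplex length; ties prefer more
Watson–Crick (fewer wobble) pairs, then the 5'-most substrate window;
duplexes shorter than `min_len` (default 8 nt) are rejected. The predicted
site is the substrate nucleotide paired with the fifth guide nucleotide
upstream of the box — guide position box_start − 5 in 1-based coordinates,
counting the C of CUGA as box_start. This off-by-one-prone convention is
pinned by a worked example in the tests. Wobble pairs are accepted inside
the duplex by default but rejected at the target-paired position
(configurable); the original reports are silent on both points, so the
permissive-duplex/strict-target combination was chosen as the conservative
default.

## RNP masses

Average (not monoisotopic) residue masses from the IUPAC 2021 atomic
weights are embedded as versioned constants; a polymer weighs the sum of
its residue masses plus one water. The RNA residue table uses
nucleoside-monophosphate residues, so the base formula corresponds to a
5'-phosphorylated chain; the `triphosphate` option adds the two extra
phosphates of a T7 transcript (+159.96 Da, below SEC-MALS reporting
precision). Assembly masses are stoichiometric sums (exactly linear in
copy numbers); candidate stoichiometries are ranked by |mass − observed|
with stable ties. Agreement with published theoretical masses is asserted
to 1% relative, not exactly: the mass convention used there is unstated,
and affinity-tag remnants after TEV cleavage are unspecified.

## Synthetic benchmark

The generator plants the full architecture
tail–boxC–guide–boxD'–stemI/loop–boxC'–guide–boxD–tail with uniform random
background, 12-nt guides (the optimal archaeal spacer/guide length), a
2-bp stem-I extension beyond the −1/−2 core closed by a 4-nt loop, and
0–3-nt random tails. Category proportions default to the yeast census
(2/6/18/17 of 43); benchmarks pass explicit mixes. Largest-remainder
apportionment converts proportions to deterministic integer counts.
Substrates are exact reverse complements of the guides with 2-nt random
flanks, so the planted target is always substrate position 7.

Category construction: non-consensus windows vary L2/L3 while keeping the
b-side GAUGA; stem-I pairs are broken by copying the n-side nucleotide
onto the b side (never WC nor wobble); a missing sheared pair is made by
mutating 1b or 2b. The 2b mutation (rather than the n-side 2n) realises
the same feature set while keeping box D' an exact CUGA — an n-side
mutation would make the record unannotatable under the exact-match D'
rule and collapse it into NO_MOTIF. The excluded L2L3 = (C, U) and
2b = C choices would spell a spurious CUGA inside the C' window.

Every record is rejection-sampled until unambiguous: exactly the planted
CUGA occurrences exist; no window in the C' search interval ties or beats
the planted stem-II score; no earlier 5'-window ties the planted box C;
and each substrate has a unique best duplex anchor. Construct-style edits
(introduce the 2b•2n pair, break −1, turn stem I into a loop, or the
combined edit) make minimal substitutions at frame positions, recompute
the truth labels, and are revertible from the recorded substitutions.

What a green benchmark establishes: the annotation, classification and
target-prediction code inverts the generative model exactly on sequences
where the truth is unambiguous. What it does not establish: performance on
real snoRNAs, whose boxes drift from consensus, whose guides contain
mismatches and wobbles, whose backgrounds are not uniform, and whose D'
boxes occasionally deviate from CUGA (such motifs are reported as
NO_MOTIF here). The census of real yeast snoRNAs therefore remains an
external check requiring the database sequences.

## Determinism and reporting

All randomness flows from a single integer seed through one NumPy
generator; identical inputs, configuration and seed give byte-identical
outputs. Internal coordinates are 0-based half-open; every user-facing
table is 1-based inclusive and says so in its header, alongside the tool
version and a hash of the effective configuration. BED output stays
0-based half-open per the format.
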