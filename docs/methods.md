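# Methods

This note documents the models, parameters and design choices behind
`haloterm`, in the order the pipeline runs.

## Hairpin folding

A terminator window is decomposed into
`5' tail — A-tract — 5' stem — loop(s) — 3' stem — U-tract — 3' tail`.
The folder enumerates every single stem-loop decomposition of the window —
a terminal loop of 3–12 nt closed by a helix of Watson-Crick and G:U wobble
pairs, with at most one interruption (bulge or internal loop) of up to 8
unpaired nt in total — and returns the minimum-free-energy one. Pseudoknots,
multi-branch structures, suboptimal ensembles and co-transcriptional
kinetics are out of scope: the working assumption is that a terminator's
functional structure is a single hairpin, so a constrained search is both
faster and better matched to the decomposition the downstream features need.

Free energies are Turner-style RNA nearest-neighbor parameters at 37 °C
(the folding element is the nascent transcript; sequences are handled in the
DNA alphabet with T standing for U). Watson-Crick stack energies follow
Xia et al. (1998); hairpin/bulge/internal-loop initiation terms follow the
Turner 1999/2004 rule set with Jacobson–Stockmayer log extrapolation beyond
tabulated sizes; internal-loop asymmetry costs 0.5 kcal/mol per unit. The
G:U wobble stack set is approximate (Turner-style constants), and terminal
AU/GU helix-end penalties and loop first-mismatch bonuses are not modeled.
This coarseness is deliberate: the package's quantitative surface is the
*structures* (stem lengths, loop sizes, tract lengths), which are governed
by the dominant Watson-Crick stacks, not by sub-kcal refinements. Energies
(ΔG_H, ΔG_W, ΔG_B) are reported for feature computation and should be read
as model-internal quantities, comparable across sequences folded with the
same table but not against other folding engines.

Two structural constraints beyond the obvious ones, both exposed in
`FoldParams`:

* **Watson-Crick closing pair** (`wc_closing=True`). The loop-closing pair
  must be WC; wobbles remain legal elsewhere in the stem. A G:U pair is too
  weak to nucleate the hairpin against the entropic cost of a tight loop;
  without this constraint the folder shaves annotated 5-nt loops down to
  3 nt by closing them with a wobble.
* **Interruption cap of 8 nt** (`max_interruption_total=8`). One bulge or
  internal loop is allowed (enough for the characterized double-loop part),
  but large internal loops would let spurious flank helices attach to the
  hairpin.

Ties in energy are broken deterministically: longer stem, then smaller
terminal loop, then leftmost 5' stem start.

The MFE search is verified in the test suite against an independent
brute-force enumeration of all legal decompositions on random windows of up
to 30 nt (agreement to 1e-6 kcal/mol over 1,000 windows).

## Tract trimming

In the untrimmed MFE fold, the upstream A-tract pairs with the downstream
U-tract and extends the helix below the genuine stem. That pairing is the
substrate of the `match_pattern` feature, not stem structure, so it is
reassigned to the tracts:

1. bottom pairs of *tract type* (A paired with T, in either orientation)
   are peeled iteratively;
2. a short residual block (< `min_stem` non-tract pairs) at the helix
   bottom is discarded together with the contiguous run of tract pairs
   directly above it, provided the run contains at least one A:T pair
   (5' partner A) and the remaining stem stays ≥ `min_stem`. This covers
   flank-to-flank pairs that close *over* the tracts: once the tract pairs
   are reassigned, such a pair would enclose unpaired tracts, which is not a
   stem-loop.

Trimming never touches the terminal loop and never increases the stem
length. ΔG_H and ΔG_B are recomputed on the trimmed stem; ΔG_W keeps the
untrimmed whole-window value. On the 19 characterized parts this
fold-and-trim procedure reproduces 16 of the 19 annotated stem/loop
decompositions. The three exceptions are annotation-method artifacts, not
tunable cases: two parts admit a much longer wobble-rich MFE helix than
their annotation (which derives from a scanning annotator, not a
whole-window fold), and one part's annotated stem length *includes* the
bottom A:T tract pairs that the same trimming rule must remove to reproduce
the others. They are excluded from the reproduction test with comments.

## Features

* **Uscore** ∈ [0, 1]: positionally weighted U-content of the `L = 15` nt
  immediately 3' of the trimmed stem, weight `0.9^(i−1)` at position *i*
  (position 1 adjacent to the stem), normalized by the full-T maximum.
  Records shorter than 15 nt are padded with non-T. The geometric decay
  encodes that proximal U's, where the polymerase pauses, dominate
  termination. Both `L` and the decay are configurable; the functional form
  is this package's concretization (the concept has several conventions in
  the literature) and is validated against ordering/qualitative claims, not
  absolute values.
* **match_pattern** ∈ {0..8}: count of positions *i* ≤ `W = 8` at which the
  A-tract (read 3'→5' from the stem base) offers A and the U-tract (read
  5'→3') offers T — the canonical ~8-nt tract window. Tract segments are
  the maximal A-run/T-run adjacent to the trimmed stem; they come from the
  folding decomposition, not from independent regex scanning (single source
  of truth).
* **ΔG_H/n_H**: hairpin energy per base pair — the stem-quality regressor;
  total ΔG_H correlates poorly with efficiency, normalized ΔG_H/n_H is the
  informative form.
* **ΔG_B**: stacking free energy of the `k = 3` bottom-most pair-steps of
  the trimmed stem (the pairs the polymerase must melt last). How many
  steps enter this quantity is not standardized; `k` is a config knob, and
  stems with fewer available contiguous steps use what they have, flagged.
* Auxiliary: stem GC fraction, loop count/sizes, tract lengths.

## Linear TE model

`TE = 4.0458·Uscore + 2.1789·(−ΔG_H/n_H) + 2.524·match_pattern
+ 0.2526·ΔG_B + 55.5843` (percent). The energy term enters as the *negated*
normalized hairpin energy, positive for stable stems, so stability raises
TE; ΔG_B enters with its raw negative sign. The default coefficients are
the published fit on an external 582-terminator library and are applied
as-is under this package's feature conventions; only the analytic fixed
points (e.g. intercept 55.5843 at the zero vector) are guaranteed
quantitatively. Predictions are unclamped by default (measured TEs can be
negative); a display clamp to [−100, 100] is optional. Predictions below
50% carry a low-confidence flag: the model's reliable regime is strong
terminators.

`fit_ols` refits the same functional form by ordinary least squares
(statsmodels) with a condition-number guard against collinear designs and
reports R², residual SD and n. On a noise-free synthetic table the refit
recovers the generating coefficients to 1e-8 (exact interpolation). On the
standard noisy recovery setting (n = 500, TE noise SD 5, regressors uniform
over the cohort ranges) the per-coefficient standard errors are ~0.09–0.2
for match_pattern, ΔG_B and the energy term, but ~0.77 for the Uscore
coefficient, whose regressor spans only [0, 1]; single-draw estimates of
that coefficient therefore scatter well beyond ±0.2, and the unit test
asserts recovery within three standard errors rather than a fixed band.

## Rating (mining)

`rating = 0.6·Uscore + 0.4·hairpin_score`, the 60/40 split between poly-U
signal and hairpin structure. `hairpin_score` is the equal-weight mean of
min-max-normalized −ΔG_W and stem GC — the smallest formula consistent with
the three declared ingredients (window energy, stem GC, poly-U). −ΔG_W is
normalized cohort-relative by default (per mining run), mirroring how a
genome-wide candidate set spans a wide energy range (the characterized
cohort spanned roughly −3 to −35 kcal/mol); fixed bounds can be supplied.
Candidates that do not fold rate 0. One window (60 nt, configurable) per
gene; no operon merging.

## Reporter assay

Blank subtraction precedes OD600 normalization (the order is a convention
of this package; published protocols are typically silent on it). Negative
normalized fluorescence is floored at 0 and flagged rather than propagated,
keeping TE defined. TE is computed per replicate and aggregated as
mean ± SD, matching per-culture error bars; aggregating fluorescence first
would shrink the SD. TE is scale-invariant under any common rescaling of
all fluorescence values, and the noise-free simulator round-trips
programmed TEs exactly.

## Design operators

Every operator edits exactly one segment of the decomposition and validates
its product by refolding — flanking context can create alternative
structures, which is also the accepted explanation for why measured
efficiencies of truncated parts can differ from their parents (the linear
model has no flank term, so such orderings are not model properties).
Random stem sampling is seeded and the seed recorded in the record
description. The de novo constructor retries a bounded number of stem
samples and reports constructive failure for unsatisfiable blueprints
(e.g. an all-A:T 4-bp stem, which cannot survive as a hairpin under the
energy model).

## Synthetic data

* **Genomes**: i.i.d. background at configurable GC, non-overlapping genes
  on both strands, terminators planted verbatim at their gene's
  stop-codon end (reverse-complemented on minus-strand genes). Default
  study condition for planted-recovery: 100 genes, GC 0.5, five strong
  parts planted, seed fixed.
* **Plates**: multiplicative Gaussian noise on normalized GFP and RFP
  (CV-parameterized, floored at 0) back-transformed to raw readings —
  plate-reader-like behavior; NC generated at TE 0, blanks included.
* **Training libraries**: regressors uniform over ranges bracketing the
  characterized cohort (Uscore [0,1], −ΔG_H/n_H [0,4] kcal/mol/bp,
  match_pattern {0..8}, ΔG_B [−6,0] kcal/mol), TE from the linear model
  plus Gaussian noise.

All generators are pure functions of (config, seed). What they deliberately
do **not** emulate: real intergenic base composition and repeats, operon
structure, expression-dependent annotation quality, spectral overlap and
plate-position effects, or correlated feature distributions of real
terminator cohorts. Passing tests therefore demonstrate internal
correctness and statistical behavior of the methods, not genome-scale
precision/recall on real annotation.

## Degenerate inputs and numerical conventions

Windows shorter than `2·min_stem + min_loop` return no hairpin (not an
error); IUPAC degeneracy codes are rejected; U is accepted and stored as T.
Folds with non-negative free energy, or whose trimmed stem falls below
`min_stem`, return no hairpin. Energy ties are resolved by the
deterministic tie-break above; energy comparisons use a 1e-6 kcal/mol
quantum. OLS refits require ≥ 10 rows. All internal coordinates are
0-based half-open; GFF3 converts at the boundary; report tables print
1-based inclusive coordinates.

## Known limitations

* Thermodynamic, not kinetic: co-transcriptional folding effects (the
  reason one characterized part shows a double loop in kinetic folders) are
  approximated by the one-interruption allowance.
* The published model coefficients were trained under unknown feature
  scalings; absolute TE predictions with this package's feature conventions
  are indicative, class-level quantities — the strong/weak ordering claims
  are tested, absolute agreement with measured TEs is not.
* The wobble stack constants are approximate; energies should not be
  compared against other engines.
* Mining reproduces the procedure, not the historical candidate list, which
  depended on an expression-derived annotation.
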