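# Methods

## Model

A triacylglycerol (TG) is treated as an unordered multiset of exactly three
fatty acyl (FA) chains on a glycerol backbone; a chain is the pair
(carbons, double bonds), written `C:D`, with the carboxyl carbon counted.
*sn*-positions, double-bond positions and branching are outside the model:
the package identifies chain compositions and distinguishes
chromatographically separated positional isomers by suffix, nothing finer.

Monoisotopic masses are assembled from molecular formulas via pyteomics: the
free acid is C\_c H\_{2c−2d} O\_2; the neutral TG is the three acids plus the
glycerol backbone residue C\_3H\_2 (glycerol minus three waters); the
monitored precursor is the ammonium adduct [M+NH₄]⁺ and the neutral loss is
the acid's ammonium salt (acid + NH₃). The electron mass of the singly
charged cation is ignored (< 0.0006 Da), consistent with unit-resolution
triple-quadrupole reporting; masses are rounded to a configurable precision,
default 1 decimal place, which is also the transition-deduplication
identity. The TG mass depends only on the brutto totals, so all chain splits
of one brutto share a precursor channel, and equal losses within a brutto
collapse to a single transition — increasing the precision can only split
such merged channels, never merge them (tested as a monotone-refinement
property).

## Acquisition design

Enumeration produces all chain multisets of size 3 from the user list:
(n³+3n²+2n)/6 for n chains. The *reappearance* restriction models the
practice of letting only designated abundant chains occupy more than one of
the three positions: a structure may contain at most one chain position
(counted with multiplicity) filled from the non-repeatable set. For a
repeatable chains and r non-repeatable ones this leaves
multiset(a,3) + multiset(a,2)·r structures — 56 + 252 = 308 at the 18/6
split typical of a milk-fat acquisition list. The naive alternative reading
("non-repeatable chains simply may not repeat") was rejected because it
admits structures with two or three distinct rare chains and yields 924
structures at the same split, defeating the purpose of shrinking the method;
both readings are distinguished by the package's own brute-force property
test.

## Identification and prediction

Peak tables come from an upstream peak-picking/deconvolution tool: one row
per chromatographic peak of one transition, with brutto label, Q1 channel
key, loss chain, peak letter (distinguishing separated peaks of one
channel), retention-time borders, and intensity (area, height or
concentration — only ratios are used). Validation enforces
rt\_left < rt\_right, non-negative intensity and uniqueness of
(q1, loss chain, letter), reporting offending line numbers.

Within a brutto group, a candidate triple of detected chains (each present
in the user FA list) is accepted when:

1. its carbon and double-bond sums equal the brutto totals exactly
   (integer subtraction, no tolerance);
2. one supporting peak is chosen per distinct chain — a repeated chain is
   served by a single physical peak, since both losses of a repeated chain
   co-elute by construction;
3. the supporting intervals share a segment of **positive** length
   (touching endpoints do not co-elute — this hard gate applies even at a
   0% overlap threshold);
4. that segment covers at least the overlap threshold % of the ID peak's
   span, the ID peak being the lowest-intensity distinct supporting peak
   (ties broken by earlier left border, then letter);
5. the ID peak's relative abundance — 100·intensity/max over its Q1 channel
   group, 0 throughout for an all-zero group — meets the abundance
   threshold.

Defaults are 0% abundance and 75% overlap. The assignment string carries one
character per chain in canonical (C, D) order: the supporting peak's letter,
capitalized at every position the ID peak serves (hence `AA#` when a
repeated chain's single peak is the ID peak), `#` for a predicted chain.
The reported intensity/abundance of an assignment is that of its ID peak and
is an upper bound on the species' true abundance, because an ID peak can
serve several structures.

Prediction considers every pair of detected chains with co-eluting support
(one peak may serve both positions of a repeated pair) and completes the
third chain by subtraction from the brutto. A prediction is emitted only if
the completed chain has positive carbons, non-negative double bonds, and is
a member of the user FA list; it is suppressed when an acquired peak of that
chain overlaps the pair's common segment in the same brutto group, since
that triple is then a three-peak identification — without suppression every
identified species would be double-reported as a prediction. Predictions
are deduplicated on (name, assignment string), so one completed structure
reachable via two pair orderings appears once.

Regioisomer labeling groups assignments by bare chain multiset (pooling
identified and predicted variants) and numbers groups of ≥ 2 by ascending
ID-peak left border, then letter, then assignment string, making the
numbering invariant under input row order; a multiset seen once keeps
suffix 0 (printed without suffix). The regioisomer summary is the histogram
of variants per multiset.

## Synthetic data

The generator emulates the deconvolution export of a targeted TG run. Per
true TG and chromatographic variant it draws a retention center uniformly in
the gradient window and a width of 0.30 ± 0.05 min (typical lipid RP-LC
peaks), then gives each distinct chain one peak whose borders are jittered
by up to 4% of the width per side — enough that borders differ as real
deconvolution output does, little enough that co-eluting channels stay well
above the 75% overlap gate. Intensities are a per-TG base level, log-uniform
over 10⁴–10⁶ (AUC-like dynamic range), times a per-channel response
multiplier uniform in 0.2–1.0; channels drop out independently with a
configurable probability (default 0). Letters are assigned a, b, c per
channel in retention order. One integer seed fixes every draw; equal seeds
give byte-identical tables.

What the generator does *not* emulate — partially merged adjacent peaks,
peak tailing, chemical noise, in-source fragmentation, isotope interference
— bounds what passing tests show: they validate the matching logic against
its own rules and ground truth, not robustness to imperfect chromatography,
which in practice is handled by lowering the overlap threshold.

The prediction-recovery benchmark removes ⌊fraction·N⌋ peak rows uniformly
at random (fixed count, not per-row Bernoulli), never touching protected
chains (e.g. 16:0, 18:0, 18:1, which a targeted method would not miss),
re-identifies on the subset, and reports per repeat the percentage of
species (compared as chain multisets, since removal reshuffles letters)
lost from the full-table identification that the subset's prediction
recovers; a repeat losing no species is reported as NaN and skipped.
Per-repeat RNG streams are spawned from the single seed.

## Numerical and interface choices

- Integer chain arithmetic throughout identification; floating point enters
  only via retention times and masses.
- Delimiters are auto-detected (comma/tab) on read, comma on write;
  percentages are 0–100 numbers everywhere, never fractions.
- All writers are atomic (write to a temporary file, rename), so a failed
  run leaves no partial output.
- Test and benchmark problem sizes — a dozen peaks in the worked example,
  ~100 randomized tables of ≤ 30 peaks for the brute-force cross-check,
  five-TG simulations — were chosen as the smallest sizes that exercise
  every rule (multiple bruttos, repeated chains, merged/separated variants,
  all threshold branches); the algorithms are polynomial in peaks per brutto
  group and handle the hundreds-of-peaks tables of a real run in seconds.

## Known limitations

- No peak picking, smoothing or merged-peak splitting; the package trusts
  the upstream tool's borders.
- Prediction is inclusive: a predicted species is a hypothesis whose
  abundance is bounded by one observed channel, and confirming it requires
  re-acquiring with the missing transition.
- A single ID peak shared by several structures means their reported
  abundances are not additive.
- Chains absent from the user FA list are invisible to both halves, as in
  any targeted method.
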