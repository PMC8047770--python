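# tgmrm

Targeted LC-MS/MS triacylglycerol (TG) profiling toolkit: design of MRM
acquisition lists covering every fatty-acyl combination a user chain list can
form, and automated determination and prediction of the three acyl chains
constituting each detected TG species from processed peak tables, including
labeling of chromatographically separated regioisomers.

## The problem

A TG is a glycerol backbone esterified with three fatty acyl (FA) chains, so
*n* candidate chains give rise to (*n*³ + 3*n*² + 2*n*)/6 distinct chain
multisets — 220 species from only 10 chains. On a triple quadrupole, TGs are
monitored as ammonium adducts [M+NH₄]⁺ (Q1) fragmenting by neutral loss of
one chain as its ammonium salt RCOONH₄ to a diacylglycerol-like ion (Q3). One
product ion only reveals one constituent chain, so deciphering full
structures means matching two or three co-eluting neutral-loss peaks per
precursor by retention time and abundance — laborious and error-prone by
hand for complex fats such as bovine milk.

`tgmrm` automates both halves:

- **Acquisition design** (`generate-mrm`): enumerate all TG compositions
  from a chain list, optionally applying a *reappearance* restriction (only
  designated abundant chains may occupy more than one of the three
  positions), and emit the deduplicated MRM transition list plus the TG
  structure table it can confirm. With 18 chains of which 6 are repeatable,
  the restricted design covers exactly 308 structures.
- **Identification** (`identify`): within each brutto group (shared total
  carbons:double bonds, e.g. `TG(48:3)`), a chain multiset is *identified*
  when the brutto totals minus the three detected neutral losses are exactly
  zero in both carbons and double bonds and the supporting peaks co-elute;
  with only two losses, the third chain is *predicted* by subtraction and
  checked against the user chain list (marked `#`). Two user thresholds
  filter the output: minimum % relative abundance of the ID peak (the
  lowest-abundance supporting peak, capitalized in the assignment string)
  versus the strongest peak of its Q1 channel, and minimum % retention-time
  overlap of the peaks' common segment versus the ID peak's span (defaults
  0% and 75%). Chromatographically separated variants of one chain multiset
  — positional (regio)isomers — receive numeric suffixes in retention order.

A synthetic-data module generates peak tables with known ground truth
(co-eluting loss peaks per TG variant, intensity spread, jittered borders,
random channel dropout) and implements a subset-removal benchmark of the
prediction function.

## Worked example

`fas.csv` lists the acquisition chains (`fa_carbons,fa_double_bonds,repeatable`);
`peaks.csv` is a processed peak table for one brutto group, `TG(48:3)`, with
three chromatographic windows (peak letters a, b, c):

```sh
$ tgmrm identify --peaks peaks.csv --fa-list fas.csv --out assignments.csv
INFO tgmrm: read 12 peaks, 9 FA groups; thresholds: 0.0% abundance, 75.0% RT overlap
INFO tgmrm: identified 4 and predicted 6 TG structures -> assignments.csv
```

```
tg_name,status,assignment,regio_suffix,id_peak_q3_fa,id_peak_letter,rt_left,rt_right,relative_abundance_pct,intensity
TG(12:0_14:0_22:3#),predicted,aA#,0,14:0,a,1.0,2.0,40.00,40.0
TG(12:0_16:0_20:3#),predicted,aA#,0,16:0,a,1.0,2.0,50.00,50.0
TG(12:0_18:1_18:2),identified,aAa,0,18:1,a,1.0,2.0,30.00,30.0
TG(14:0_14:0_20:3#),predicted,AA#,1,14:0,a,1.0,2.0,40.00,40.0
TG(14:0_14:0_20:3#),predicted,BB#,2,14:0,b,3.0,4.0,70.00,70.0
TG(14:0_14:0_20:3#),predicted,CC#,3,14:0,c,5.0,6.0,90.00,90.0
TG(14:0_16:0_18:3),identified,aaA,1,18:3,a,1.0,2.0,20.00,20.0
TG(14:0_16:0_18:3),identified,bbB,2,18:3,b,3.0,4.0,35.00,35.0
TG(14:0_16:0_18:3),identified,cCc,3,16:0,c,5.0,6.0,25.00,25.0
TG(14:0_16:1#_18:2),predicted,A#a,0,14:0,a,1.0,2.0,40.00,40.0
```

Reading the output: `TG(12:0_18:1_18:2) aAa` is a confirmed structure — all
three loss peaks (letter *a* of their channels) co-elute, and the 18:1 peak,
being the weakest (30% of the Q1 maximum), is the ID peak whose abundance
bounds the species' abundance from above. `TG(14:0_16:0_18:3)` appears in
all three windows, so its variants are regioisomer-suffixed 1–3 in retention
order. `TG(14:0_14:0_20:3#) AA#` is a prediction: a single 14:0 loss peak
serves both observed positions and the 20:3 chain is completed
arithmetically from the chain list (no 20:3 channel was acquired).

The design half, from the same chain list:

```sh
$ tgmrm generate-mrm --fa-list fas.csv --policy unrestricted --out-prefix design
INFO tgmrm: read 9 FA groups; unrestricted policy -> 165 TG structures, 270 transitions
$ head -3 design_mrm_list.csv
q1_mz,q3_mz,loss_fa,compound_group
656.6,439.4,12:0,TG 656.6 loss 12:0
684.6,439.4,14:0,TG 684.6 loss 14:0
```

165 = (9³ + 3·9² + 2·9)/6 compositions; isobaric losses collapse the naive
3-per-composition transition count to 270 unique (Q1, Q3) channels at one
decimal place.

`tgmrm simulate` and `tgmrm benchmark` drive the synthetic generator and the
subset-removal prediction benchmark; see `tgmrm <cmd> --help`.

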