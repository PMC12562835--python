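# Methods

## Model and assumptions

A Y-STR haplotype is a per-marker multiset of repeat-count alleles on
the non-recombining Y, inherited patrilineally; the only between-
generation change is mutation. For a pedigree pair — two men joined by a
known patrilineal path of `m` meioses — the package infers the minimum
number of mutational events consistent with the observed per-marker
differences, then aggregates events and meioses across pairs into
per-marker rates.

Three assumptions underlie the counting:

1. **Zero difference ⇒ zero events.** When the two haplotypes match at a
   marker, no mutation is inferred along the unobserved path. Parallel
   and back mutations are therefore knowingly uncounted, and every
   inferred count is a lower bound on the true event count (per marker:
   the net repeat displacement cannot exceed the number of ±1 steps).
2. **Multi-step differences decompose.** Because no father–son links are
   typed, a k-repeat difference is interpreted as k single-step
   mutations distributed along the connecting lineage. Where along the
   lineage they fell is never modelled — only counts enter the rate and
   differentiation estimates.
3. **Parsimony everywhere.** Among all explanations of a difference, the
   one with the fewest mutations wins.

### Per-marker counting rules

* Single-copy markers: same nomenclature → |Δrepeats| single-step
  events; exactly one `NEG` → one deletion; both `NEG` → shared state,
  zero events; different fractional nomenclature (16 vs 16.2) → one
  "complex" event. Steps cannot interconvert nomenclatures, so no step
  decomposition of a microvariant mismatch is defined; a single event is
  the parsimony-minimal reading, and microvariants in real panels are
  almost always shared inherited states anyway.
* Multi-copy markers (expected two copies): with equal observed copy
  numbers, the event list is the minimum-cost bijection between the two
  multisets (cost of a matched pair = its single-copy event list). With
  unequal copy numbers, each unit of copy-number difference costs
  exactly one duplication (above the expected count) or deletion (below
  it), with the gained/lost copy chosen to minimise the residual
  matching cost. A single displayed allele at a two-copy marker may hide
  a homoallelic pair; both readings are costed and the cheaper wins.
* Tie-breaks, in order: fewer total events; fewer copy-number events
  (so an equal-cost homoallelic reading beats a deletion reading, and a
  single step beats a copy-number change); fewer complex events (step
  decompositions are the biological default); smaller gained/lost
  allele; lexicographically smallest event list. These make the counter
  deterministic and symmetric in the pair's order.
* More than four observed copies at a marker is outside panel biology
  and raises an error.

All multisets involved have at most four elements, so the minimum-cost
bijection is found by direct enumeration of assignments rather than a
general assignment solver; the test suite checks it against an
independent recursive minimum-mutation search over every reading.

Pairs with more than 15 total inferred mutations are excluded from
estimation (configurable): at panel-wide rates such counts are
implausible for a true patrilineal pair and indicate misattributed
ancestry. The boundary count (exactly 15) is kept.

## Rate estimation

Per marker, μ̂ = x/N with x the summed event count (each decomposed step
and each duplication/deletion/complex event is one mutation) and N the
summed meioses of the retained pairs. Because each pedigree contributes
exactly two men, pairwise and actual meioses coincide and no
transmission is double-counted.

Intervals (default α = 0.05):

* **Clopper–Pearson (exact)**: beta quantiles,
  `[B(α/2; x, N−x+1), B(1−α/2; x+1, N−x)]`, with the lower bound pinned
  to 0 at x = 0 and the upper to 1 at x = N. Guaranteed ≥ nominal
  coverage; conservative.
* **Wilson score**: the closed-form score interval; narrower, always
  inside [0, 1], containing x/N.

Cross-study comparison uses the two-sided Fisher's exact test on
`[[x1, N1−x1], [x2, N2−x2]]` under the standard "sum of hypergeometric
probabilities ≤ observed" convention (other two-sided conventions
exist; this is the one scipy implements and the enumeration oracle in
the tests reproduces). Published comparison tables often print only the
reference study's *rate*; `reconstruct_count` recovers x₂ =
round(rate·N₂) and comparisons built that way are flagged approximate,
because the unprinted true counts can differ by ±1 and shift the
p-value.

Report tables round rates and bounds half-up to three decimals
(percentages to one decimal), alongside full-precision values.

## The simulator

`simulate_pairs` emulates a deep-pedigree study design: each pedigree
has a founder at the apex and two branches of lengths m₁ + m₂ = m
(uniform over compositions; the counting statistics are split-invariant,
so the split only matters for the truth log). Founders draw integer
alleles uniformly from approximate published Yfiler Plus allele ranges
(two independent copies at two-copy markers); microvariant and null
founders are off by default.

Per meiosis and marker, a mutation occurs with probability μ and moves
one uniformly chosen copy ±1 repeat with equal probability — the
symmetric single-step model; deep-pedigree data cannot resolve gain/loss
asymmetry, so 50/50 is the default with `p_multistep`/`step_size_p`
knobs for geometric multi-step events. Two-copy markers additionally
gain (copy an existing allele, offset 0 or ±1) or lose a uniformly
chosen copy with per-meiosis probability `p_dupdel` (default 2/1576,
matching the handful of copy-number events seen per ~1576 meioses in
panels of this size; capped at four copies, never below one). A walk
below one repeat reflects at one. Every event is logged with pair,
marker, branch, meiosis index and signed size.

`study_like_config()` fixes the study conditions: 183 pairs with the
meioses multiset {4:13, 5:14, 6:19, 7:23, 8:25, 9:24, 10:19, 11:15,
12:12, 13:9, 14:5, 15:3, 16:2} — the published per-meioses breakdown is
not available as numbers, so this right-skewed unimodal multiset was
fixed once to satisfy the two published constraints (183 pairs over
4–16 meioses, 1576 meioses total, mean 8.61) — and per-marker μ equal
to the bundled reference rates x/1576. The reference counts include
copy-number events, so at the two-copy markers the stepwise component
is reduced by `p_dupdel` to keep each marker's total event rate at the
reference value.

### What the simulator does and does not emulate

It reproduces the study *design* (pair counts, meioses spread, rates,
event-type mix) but not population structure: founders are uniform
rather than drawn from real haplotype frequencies, mutation rates are
allele-length-independent, there is no primer-binding-site null-allele
process, and no misreported kinship. Tests passing on simulated data
therefore validate the inference machinery under the stated model, not
robustness to genotyping artefacts or pedigree errors.

### Parsimony bias, quantified

Under the stepwise model, parsimony recovers the per-copy *net*
displacement, not the event count: two same-marker mutations in
opposite directions cancel and are invisible. The test suite compares
replicate-mean estimates against the closed-form expectation
E[x̂]/N = Σ_pairs Σ_k P(K=k) E|W_k| / N (K ~ Binomial(m, μ), W the ±1
walk; events split binomially across copies at two-copy markers, plus
the copy-number rate), computed independently of the simulator. At
study-scale rates (μ ≤ 0.013, m ≤ 16) the bias is below 6% of μ at the
hottest markers and negligible elsewhere; estimates are additionally
asserted never to *exceed* truth beyond Monte-Carlo noise. Exact-interval
coverage of the true rate stays at or above the nominal 95% within
Monte-Carlo tolerance for markers with μ ≥ 0.003.

## Numerical and design choices

* Alleles store integer repeat units and a microvariant digit
  separately, so 15 and 15.0 are identical, and no floating-point
  comparison enters allele arithmetic.
* Multisets are stored canonically sorted; DYS385's two copies are
  treated as an unordered multiset (electrophoresis does not reveal
  which physical copy is which).
* The "more than 15 mutations" exclusion is a strict inequality.
* Known published rate tables occasionally contain interval cells
  inconsistent with their stated exact method (e.g. Wald-style or
  double-rounded values); the package always computes the stated
  method and never special-cases individual markers.
* `x = N` and `x = 0` interval boundaries, empty strata (rate reported
  as missing, not 0), and duplicate-sample or sub-1 meioses inputs are
  all explicit edge cases with tests.

## Limitations

Event placement along the lineage is not modelled; rates are not
allele-length- or direction-resolved; no likelihood-ratio kinship
framework is included (the estimated rates are inputs to such
frameworks, not a replacement); and the discrimination-capacity summary
is a plain unique-haplotype count, not a population-database frequency
analysis.
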