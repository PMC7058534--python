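# Methods

## The detection model

Chromothripsis is modelled as single-event shattering of a chromosomal
region on one chromatid followed by random religation of a subset of the
fragments. The observable consequences, each measured by one statistic:

1. **Interleaved rearrangements.** Random religation joins fragments that
   are far apart in reference coordinates, so the intervals bridged by two
   junctions typically overlap without either containing the other. Two SVs
   are *interleaved* exactly when their intervals overlap and neither is
   nested in the other; clusters are connected components of the
   interleaving graph. Nested SVs never connect — nesting is the signature
   of sequential, not simultaneous, rearrangement. The component floor is
   `min_cluster_svs = 6` intrachromosomal SVs.
2. **Oscillating copy number.** Fragments are retained (background CN) or
   lost (background − 1), so the merged segment profile alternates between
   two states; aneuploid backgrounds motivate the relaxed three-state
   variant. `max_alternating_run(states, k)` is the longest contiguous run
   with ≤ k distinct levels in which every adjacent pair differs. High
   confidence requires a two-state run ≥ 7 adjacent segments; low
   confidence 4–6. An event is *canonical* when > 60% of region segments
   participate in the dominant two-state oscillation (strictly greater).
3. **Interspersed LOH.** Losses from a single chromatid drive minor-allele
   CN to zero on the lost fragments only. "Interspersed" is operationalised
   as ≥ `min_loh_switches = 4` transitions between minor CN 0 and ≥ 1
   across the region; a single arm-level transition does not qualify. The
   verdict requires minor CN on ≥ 50% of the region length, else missing.
4. **Equal join proportions.** Under random religation the four junction
   classes (deletion-like, duplication-like, head-to-head, tail-to-tail
   inversion) are equally likely. The test is exact multinomial for totals
   ≤ `exact_cutoff = 15` — outcomes ordered by their own probability under
   Multinomial(n, ¼), summed where ≤ the observed vector's (log-space tie
   tolerance 1e−9) — and Pearson chi-square (3 df) above. The two branches
   track each other within ~0.02 on average at n = 40; individual vectors
   can differ by more because the exact p-value is a step function.
5. **Breakpoint randomness.** Within the region, breakpoints of a
   single-event process are uniform, hence their adjacent spacings follow
   the exponential law with rate n / region length. Raw spacings are
   sum-constrained (they are gaps of uniform order statistics), which makes
   a naive Kolmogorov–Smirnov test conservative (~1% rejection at nominal
   5%); the ordered spacings are therefore passed through the Sukhatme
   transformation, whose normalised cumulative sums are exact uniform order
   statistics under the null. The resulting test holds its 5% size and
   rejects both clumping (power ≈ 1 when 80% of 40 breakpoints fall in 10%
   of the region) and zero-variance periodic spacing. Complementarily, a
   one-sided binomial tail tests whether the region holds more of the
   chromosome's breakpoints than its length share predicts. The randomness
   criterion passes when either the enrichment test rejects (breakpoints
   chromosomally concentrated) or the spacing test does not reject
   (uniform within the region): genuine events concentrated on one
   chromosome always satisfy the first clause, even when paired cut-point
   breakpoints (1-bp spacings) trip the second.
6. **Mimic exclusion.** BFB cycles are flagged by the fraction of short
   inversions (span ≤ `foldback_span = 30 kb`); events with
   `foldback_fraction ≥ 0.5` are rejected. Junctions repaired by
   end-joining carry short microhomology (0–6 bp); a fraction ≥ 0.5 of
   junctions with homology > `long_homology_bp = 10` likewise rejects.

## Gate order and confidence tiers

Gates are evaluated in a fixed order — cluster size → oscillation →
fragment joins → randomness → fold-backs → homology — and a rejection
records the first failure on the chromosome that got furthest, so
diagnostics are reproducible. Multi-chromosome events qualify through a
translocation route: ≥ `min_inter_link = 3` interchromosomal SVs bridging
the regions, with the per-chromosome oscillation floor relaxed to 4. Every
component, including sub-floor ones, may serve as a link anchor (a
breakpoint-dense region without its own qualifying cluster can still be
part of a multi-chromosome event); the SV floor is re-imposed on the
linked event.

The fragment-join gate is two-level. An extreme imbalance
(p < `alpha_joins_strict = 0.001`, e.g. a pure tandem-duplication shower at
p ≈ 1e−13) rejects the cluster outright. A marginal imbalance
(`alpha_joins_strict` ≤ p < `alpha_joins = 0.05`) demotes the call to low
confidence instead: the test is exactly calibrated on genuine events, so a
hard gate at α on both tiers would, by construction, discard a fraction α
of real events; demotion preserves sensitivity while flagging the unusual
spectrum. A consequence is that a low-confidence call may carry an
oscillation run ≥ 7 together with a marginal join imbalance.

Tiering is monotone: relaxing any gate threshold never demotes a call.

## Downstream annotations

* **WGD timing** (polyploid samples, ploidy ≥ 2.5, canonical events with a
  run ≥ 7 only). With dominant oscillation levels (lo, hi): lo = hi/2 with
  hi even means the losses were doubled along with the genome —
  chromothripsis before WGD (2↔4); lo = hi − 1 means single-copy losses on
  a doubled background — WGD first (3↔4). The (1, 2) pair satisfies both
  patterns and is left undetermined, as is everything else. Levels come
  from the longest two-state run, ties broken toward the level pair
  covering more segments.
* **APOBEC kataegis.** A mutation is APOBEC-associated when it is C→G/T in
  a tCw context or G→C/A in a wGa context (w ∈ {A, T}); the two clauses are
  reverse-complement images, so classification is strand-symmetric.
  Classified mutations inside the event region are chained while
  consecutive distances stay ≤ `kataegis_imd = 1000 bp` (the field-standard
  kataegis scale; the count thresholds, ≥ 5 for co-occurrence and > 20 for
  kataegis, are the cited ones). Chain size is monotone in the distance
  parameter.
* **Double minutes / focal amplification / gene loss.** A double-minute
  signature is an alternating run ≥ 4 between a level ≤ 4 and a level
  ≥ 10. Focal amplifications are maximal contiguous runs with CN ≥ 4
  spanning < 6 Mb, annotated with overlapping genes. Lost genes must lie
  fully inside the event region and be gap-free covered by segments with
  total CN ≤ 1 or minor CN 0; genes straddling a loss boundary are not
  reported.
* **Repair signature.** With homology and insertion annotations on ≥ 50%
  of junctions: median homology ≤ 6 bp with < 2 templated insertions
  (10–500 bp) reads as end-joining (NHEJ/alt-EJ); ≥ 2 microhomology
  junctions plus ≥ 2 templated insertions as MMBIR-like; otherwise mixed.
  Insertion length in 10–500 bp stands in for "maps to a distant template",
  which would need read-level data.

## The simulator

`simulate_chromothripsis` implements the generative model directly: cut
points uniform in the region, each fragment lost independently with
`p_loss` (resampled until ≥ 1 lost and ≥ 2 retained), retained fragments
religated in uniform random order and orientation, anchored to the flanking
arms. Junction strand pairs follow mechanically from the religation
orientation, so interior junctions are exchangeable across the four
classes; the two flank-anchored joins are tied to forward-oriented arms and
can never be duplication-like — a small, structural asymmetry that real
flank junctions share. CN derives from the losses (background 2/1, lost
1/0). WGD after shattering doubles everything (4/2 vs 2/0 → 2↔4 with LOH);
WGD before yields single-copy losses on a 4/2 background (3↔4, no LOH).
Junction homology is geometric with mean 2 bp and 10% of junctions carry a
10–500 bp insertion, so the repair-signature summary is exercisable.
Multi-chromosome events pool fragments from several chromosomes into one
derivative (micronucleus-style), making inter-fragment junctions between
chromosomes translocations.

Default study conditions are 30 fragments over a 30-Mb region of a 100-Mb
chromosome with `p_loss = 0.3`; benchmark and acceptance runs use 100
seeded replicates per scenario and 50 per WGD mode — sizes at which every
rate estimate has a standard error below 0.05 while the whole suite runs in
seconds.

Confounder generators: overlapping tandem duplications (all
duplication-like, stepwise CN staircase, no LOH), strictly nested deletion
cascades (no interleaving, so no cluster), BFB series (alternating
fold-back inversions, CN staircase rising toward the fused end), stepwise
aneuploidy without SVs, and Poisson background SVs on flat diploid CN.

What the simulator does **not** emulate: breakpoint-position uncertainty
and caller noise (positions are exact), purity/subclonality effects on CN
(segments are integer and clonal), replication-based chromoanasynthesis
(no generator), chained mimic combinations, and realistic genome-wide SV
background rates. Passing tests therefore demonstrate correctness of the
statistics and gates under the generative model, not performance on noisy
real call sets.

## Numerical and degenerate-input choices

* Coordinates are 1-based inclusive internally; BEDPE is read 0-based
  half-open with each breakpoint collapsed to the end of its interval.
  The strand dialect (+,− = deletion-like; −,+ = duplication-like; +,+ =
  head-to-head; −,− = tail-to-tail) is isolated in one function and
  overridable per call.
* Equal-state CN neighbours are merged on load (oscillation is defined on
  state changes; merging is idempotent); overlapping segments are a
  validation error; coverage gaps are permitted and ignored. Segments
  shorter than `min_segment_bp` (default 0 = off) can be dropped first.
* Region statistics need CN on ≥ 50% of the region, else the chromosome is
  unevaluable and the call is rejected with "insufficient CN coverage".
* The spacing test needs ≥ 4 breakpoints (else missing, not an error);
  coincident breakpoints give p = 0; single-point regions skip the
  positional tests entirely.
* The enrichment test's chromosome length comes from declared lengths when
  available, else the extent of CN/SV coverage.
* All simulation randomness flows through one `numpy` generator per call,
  seeded explicitly: identical seeds give byte-identical output files.

## Known limitations

* Interchromosomal linking (the ≥ 3-translocation rule and the
  anchor-attachment of singly-anchored translocations) is a design choice;
  field practice varies and no single published rule exists to match.
* The fragment-join demotion tier trades a small specificity risk (a
  mimic failing *only* the joins gate marginally would be called low) for
  calibrated sensitivity; in the simulated confounder classes this does
  not occur because earlier gates fail first.
* Derivative-chromosome reconstruction, chromoplexy, cohort-level
  statistics and read-level evidence are out of scope.
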