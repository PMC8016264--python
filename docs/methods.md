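# Methods

## Genotype model and coordinates

Markers live on a single chromosome with 1-based bp positions, strictly
increasing, and are informative by construction (the two parental alleles
differ at every marker).  Genotype states are defined relative to the named
parents (N = 93-11-like homozygote, P = PA64s-like homozygote, H =
heterozygote, NA = missing) so the same pipeline applies to any cross
genotyped with the same marker panel.  Spans are closed intervals in bp and
lengths are `end − start`.

A missing call at either intragenic diagnostic marker excludes the
individual from restored-haplotype screening (`FocalMarkerMissing`), because
the restored/nonrecombinant decision is made exactly there.  Missing calls
elsewhere are bridged: segmentation skips them, a block may span interior
missing markers, and any called tract containing a missing marker is flagged
`low_confidence`.

## Event classification

The classifier operates on the maximal state blocks of a vector.  Rules, in
order:

1. a single block is no event (all-H is the nonrecombinant F1; uniform
   homozygosity offers no transition to call);
2. a lone terminal homozygous block is one CO — terminal homozygosity cannot
   be distinguished from a conversion tract running off the surveyed region,
   so end-abutting tracts are deliberately absorbed into the CO class;
3. a lone internal homozygous block is one NCO-GC (Type1/Type2 by donor); a
   vector consisting solely of two or more disjoint such tracts is the
   double-conversion pattern (Type3);
4. terminal homozygous blocks at both ends with heterozygosity between are
   two COs (Type6);
5. in a run of adjacent homozygous blocks, a minority block whose midpoint
   length is **strictly below** `long_threshold` (default 100 kb, exposed as
   a flag) is a conversion tract associated with the CO that made the
   surrounding region homozygous: one CO-GC event (embedded = Type7,
   abutting = Type8).  At or above the threshold the block is read as two
   adjacent COs — crossover interference makes two independent COs within
   <100 kb very unlikely, which is why short minority blocks are read as
   conversions; ties at exactly 100 kb resolve to the two-CO reading.
6. anything else gets a minimal decomposition (terminal blocks → CO,
   internal blocks → conversion tracts) recorded with pattern `OTHER` and a
   `complex_decomposition` flag.

Two refinements of rule 5 were forced by geometry.  When one block of an
adjacent pair is terminal and the other internal, only the internal block
can be the tract (a terminal tract is indistinguishable from a CO by rule
2), so the threshold is applied to the internal block regardless of which
is smaller.  When a short block is embedded in homozygosity that never
reaches an end (H on both outer flanks), no single CO can explain the
surroundings; the minimal reading is a nested pair of conversions (outer
tract plus inner re-conversion), emitted as two NCO-GC events flagged
`nested` with pattern `OTHER`.

Type9 — the judgment call of a long CO-associated tract — is never assigned
automatically; its geometry is not decidable from the block sequence alone,
and the fallback is the recorded `OTHER` decomposition.

The classifier is deterministic, depends only on the block sequence and the
marker positions, and is verified exhaustively against an independent naive
implementation of the same rules on every genotype vector of length ≤ 6 on
both a dense (1 kb) and a sparse (150 kb) map.

## Midpoint tract estimation

Each tract boundary is the midpoint between the outermost converted marker
and the nearest flanking non-converted marker.  If a true boundary is
uniformly distributed within the flanking interval the estimator is
unbiased, and its absolute error is bounded by half the flanking gap —
both properties are simulation-tested.  Edge tracts anchor the censored
boundary at the outermost converted marker itself: conservative (shortens
the tract) and flagged.  Tract exclusions (e.g. a tract called long purely
because of low local marker density) go through an explicit exclusion list
rather than hard-coded ids.  Single-marker tracts, whose called length is
an artifact of local marker spacing, can be replaced by a fixed nominal
length (e.g. 6.4 kb, a typical single-marker meiotic call) before
averaging.  With M tracts summing to S bp over N event-bearing plants, the
per-tract mean is S/M and the per-event mean S/N ≥ S/M.

## Rate inference

All rate operations are plain quotients, exact to floating point.  The
truncation correction uses the scipy normal CDF (erf-based, ≥1e-10
absolute accuracy; no table lookups).  Note the two-step arithmetic used
when quoting a corrected count at whole-percent resolution: the exact tail
at Z = −1.83 is 3.36%, giving 24/0.9664 = 24.83, whereas quantising to 3%
first gives 24/0.97 = 24.74; the package returns the exact value and the
tests document both.

The mutation/conversion discriminator compares the per-site probability of
the specific base change, μ/3, with the observed reversion frequency
`(n_obs − expected_mutants)/n_plants`.  `expected_mutants` defaults to the
recomputed `μ/3 · n_plants` but accepts an override for reproducing
published arithmetic that used a slightly different constant.  With the
observed frequency recomputed at each n_obs, the joint "none are mutations"
probability is essentially flat in n_obs (the per-event posterior scales as
1/n); the meaningful monotonicity — tested — is in the mutation-rate prior.

Amplicon mosaic fractions are binomial: the recombinant-cell fraction is
the fraction of reads carrying the recombinant-type base at the diagnostic
site.  Upstream read error correction is replaced by a minimum-depth filter
plus an optional symmetric base-error deconvolution `f = (p − e)/(1 − 2e)`,
clipped to [0, 1].

The Wilcoxon paired test uses the exact null distribution for n ≤ 25;
identical samples return p = 1 rather than an error.  The 1:2:1 segregation
test is the standard df-2 Pearson chi-square; for counts (12, 23, 8) this
gives χ² ≈ 0.953, p ≈ 0.62.  Published analyses of such counts sometimes
quote other p-values from unstated procedures; this package does not imitate
them.

## Ontogeny model

The early-development reconstruction: the zygote grows as a binary tree; at
each division every cell acquires an event with the per-division probability
and the event enters exactly one daughter (conversion resolves on one
chromatid), while daughters of a recombinant cell both inherit the changed
genotype.  At the root/shoot split the RM and SAM founder pools are drawn
uniformly at random without replacement from the cells then present;
`split_division` defaults to the earliest division with enough cells (the
4-cell stage for 2+2 founders).  Detection requires at least the configured
minimum of recombinant founders in each pool, so only pre-split events are
detectable — which is the biological observation (recombinant roots) the
founder configurations encode.  Four configurations are preloaded:
RM 2 (≥1)/SAM 2 (≥1), 3 (≥2)/2 (≥1), 4 (≥2)/4 (≥1), 4 (≥3)/4 (≥1).  No
cell-lineage competition is modelled, and the observed fixation of
recombinant cells in late flag leaves is deliberately out of scope.

Calibration inverts the Monte-Carlo detection probability against an
observed per-plant frequency: geometric bisection on the rate, then a
linear-regime refinement (for small rates detection probability is linear
in rate; e.g. for the 2+2 configuration a single zygote-division event
splits across the pools with probability 2/3, so p ≈ (2/3)r).  The
returned CI combines the Clopper-Pearson interval of the final Monte-Carlo
evaluation with the binomial uncertainty of the observed frequency when
the screened population size is supplied; a 50-trial round-trip test
requires ≥90% CI coverage of a planted rate at 10⁵ replicates per
evaluation — sizes chosen to make the check sharp at ~100 expected
detections per simulated screen.

## Impact model

Constant per-division rates are assumed (the homogeneity assumption); the
API also accepts a per-division rate vector so the assumption is relaxable
without change.  Parity is defined at integer division counts:
`n_cross = ceil(E_me / (½ R_mi L_mi))` is the first n with E_mi ≥ E_me and
`n_below = n_cross − 1` the last below; the closed form is cross-checked
against a brute-force curve scan.  The meiotic conversion rate defaults to
the exact quotient 24/18000/2/(1/4) rather than a rounded constant; preset
parameterisations cover the marker-based tract means (50,297.08 / 9,755.5
bp), the refined means (28.5 / 3.121 kb), yeast tract sizes under rice
rates, and the all-yeast setting (rate 1.3×10⁻⁶ per division, tract
30,790 bp, 2% of markers converted per meiosis at 227 bp spacing).  The
four calibrated per-mitosis rates consumed by the presets
(GC: 4.63×10⁻⁶…1.68×10⁻⁵; CO: 1.46×10⁻⁵…5.32×10⁻⁵) are inputs to this
module, not outputs of the calibrator.

## Synthetic data

The generator's defaults are the study conditions: a 15-marker map over
445 kb with the intragenic pair 2.3 kb apart near the centre; per-plant
event rates equal to the screen frequencies (18 CO, 3 NCO-GC, 3 CO-GC per
1.1×10⁶ plants); 1:2:1 F2 segregation.  Uniform spacing is the default;
"field-like" spacing draws log-normal gaps and forces one <2 kb and one
>90 kb interval to exercise classifier edge cases.  Tract lengths come
from a two-component log-normal mixture, 0.7·LogN(ln 8000, 0.5) +
0.3·LogN(ln 60000, 0.6), chosen to span the ~8–250 kb range of called
tracts; the real tract-length distribution is known only through a few
dozen events, so this is a documented stand-in and fully configurable.
CO breakpoints are uniform over the surveyed span and donor direction is
Bernoulli(½).  Planted CO-GC events use the embedded geometry (opposite-
state tract strictly inside the CO region) with the tract shrunk until its
midpoint length stays below the two-CO threshold.

What the generator does *not* emulate: sequence-level reads, plant height
as a quantitative trait, marker-density variation of the real panel
(positions are synthetic), intra-plant selection, or tract-length/event
correlations.  Passing recovery tests therefore demonstrate correctness of
the calling and estimation machinery under the stated geometry, not
robustness to every property of real field data.

## Problem sizes in the test suite

Exhaustive classifier checks run over all 3⁶ vectors on two maps; the
synthetic screen check uses 2×10⁵ plants at field-like rates (plus a
2×10⁴-plant tract-rich setting for tract-mean recovery); ontogeny
calibration coverage uses 50 trials at 10⁵ Monte-Carlo replicates; the F2
type-I calibration uses 3,000 simulated families of 43.  These sizes give
stable statistics while keeping the default suite fast.

## Known limitations

* Tract boundaries are interval-censored by the marker grid; absolute tract
  means inherit marker-density artifacts that the single-marker correction
  only partially removes.
* The ontogeny reconstruction is one of many plausible early-development
  models; calibrated per-division rates are order-of-magnitude estimates
  whose assumptions (founder counts, split timing, no competition) are all
  exposed as parameters.
* Pattern types 7–9 are geometric judgment calls in the source taxonomy;
  the classifier assigns Type7/Type8 for the two decidable geometries and
  falls back to recorded OTHER decompositions otherwise.
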