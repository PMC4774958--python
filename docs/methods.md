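# Methods

## Shape parameters and the serration concept

A feather is described in a frame whose y-axis runs from the beginning of
the calamus to the tip of the rachis and whose x-axis points toward the
outer vane; sampling positions along the outer vane are normalized to
[0, 1] (vane start = 0, vane tip = 1).  All measurements are taken on the
2D ventral projection of this plane.  Left-wing data are mirrored about the
y-axis on the fly, so "away from the rachis" is always +x and the sign
convention of the tip-displacement angle is handedness-independent.  The
out-of-plane (upward) bending and twisting of serration tips is not
quantified; it is a known additional component of serration geometry that
a 2D projection cannot capture.

Three parameters summarise one barb/serration:

* **Inclination angle α** — unsigned angle in [0, 90]° between the rachis
  axis and the straight barb base (origin at the rachis → point of
  separation).
* **Tip-displacement angle β** — signed angle between the base direction
  and the chord from the point of separation to the tip; positive away
  from the rachis.
* **Serration length** — arc length (mm) of the digitised path from the
  point of separation to the tip, computed by piecewise-linear summation.
  Curve acquisition (e.g. Bezier tracing) happens upstream; a supplied
  path of ≥ 50 points keeps the polyline error of a smooth arc below
  10⁻⁴ relative.

An edge element is classified as **smooth** when the barb tip is attached
to the adjoining barb, **denticulation** when detached but with β at or
below the away-threshold, and **serration** when detached with β above it.
The defining criterion of a serration is the combination of detachment and
away-bending — detachment alone (denticulate edges, as in frogmouths or
the kakapo) is not sufficient.  The away-threshold defaults to 2°; it has
no biological meaning and only guards against digitisation noise in
near-straight tips.  Classification is invariant to uniform scaling and
rigid rotation of the landmark set.

The synthetic landmark generator builds a barb whose base leaves the rachis
at α and whose tip follows a discretised circular arc turning 2β in total,
so by the tangent-chord relation the chord sits at exactly β from the base
direction and the polyline length equals the requested length exactly;
measurement of synthesized landmarks therefore round-trips (α, β, length)
to floating-point precision, which the property tests exploit.

## Hierarchical generator

The study design is 7 species × 4 vane positions × 5 feathers × 5
serrations (25 measurements per species-position cell per parameter).  The
raw measurements behind the published study are not deposited, so the
package generates data with the correlation structure that motivates the
resampling procedure.  A measured value is modelled as

    x = μ(species, position, parameter) + f + e,
    f ~ N(0, σ_feather²),
    e: equicorrelated within a feather-position, Corr(e_i, e_j) = ρ,
       marginal SD σ_serration,

implemented as `e = σ_serration(√ρ·z₀ + √(1-ρ)·z_i)` with one shared z₀
per feather-position block.  Defaults: σ_feather = 1.5°, σ_serration = 2°
for both angles (visible error bars, clear species separation), ρ = 0.5;
lengths use a total CV of 10% split equally between the two levels, so
short and long serrations are equally variable in relative terms.  Draws
violating the record invariants (angles in (0, 90)°, α + β ≤ 90°, positive
length) trigger a whole-block resample (at most 100 attempts) rather than
clipping, which avoids truncation bias at these noise levels.  One RNG
stream is consumed in (species, feather, position, serration) order, so a
seed fixes the table byte-for-byte.

### Calibration of the default mean table

Published species-level anchors are held exactly: inclination means
A. noctua@0.4 = 12°, B. scandiacus@0.2 = 17.3° (the diurnal range),
A. funereus@0.2 = 19.9° (the nocturnal minimum), B. bubo@0.2 = 33° (the
maximum); B. bubo serration length in [5, 7] mm at positions 0.2/0.4 and
A. noctua length ≈ 1 mm.  Unprinted cells are package choices constrained
by the published qualitative structure:

* diurnal inclination means stay within [12, 17.3]°; nocturnal means at
  0.2/0.4 stay above 19.9°, declining mildly toward the feather tip;
* tip-displacement means are position-independent per species, lie in
  [10, 33]°, and every nocturnal mean exceeds every diurnal mean by at
  least 47% at every position; a flat positional profile also keeps the
  within-species position comparisons null for this parameter;
* lengths at 0.6/0.8 are reduced by 30%/60% relative to the 0.4 column,
  reflecting the distal reduction of serrations while preserving the
  between-species ratios, so the position-0.6 dendrogram behaves like the
  0.4 one;
* the free angle cells were chosen, before any statistics were run on
  them, by a power analysis of the Monte-Carlo procedure under the default
  noise scales: nocturnal-diurnal inclination gaps of ≳10° are needed for
  a comparison to exceed 99% significant runs, whereas the anchored pair
  A. funereus/B. scandiacus at 0.2 (gap 2.6°) can never reach that level —
  reproducing the published pattern in which 20 of the 24 cross-activity
  comparisons are maximal;
* two unprinted length cells (A. otus@0.2 = 2.8 mm, B. bubo@0.4 = 5.6 mm)
  are set so that the dendrogram topology requirements hold with margin
  under the default noise (verified on 200 seeds: B. bubo isolates first
  at position 0.2 in ~98% of seeds; the root split at 0.4 separates
  activities in ~100%).

What passing tests on this generator do **not** show: real measurement
error is not Gaussian or homoscedastic, feather effects need not be
additive, and the within-feather correlation of real serrations is
unknown; the generator demonstrates that the *pipeline* recovers the
published structure under the stated model, not that the model describes
owl feathers.

## Resampling statistics

Five serrations per feather-position are interdependent, so each
Monte-Carlo run selects one value per feather per group, yielding two
samples of five, and applies a two-sided Mann-Whitney U test that is exact
by full enumeration of all C(10, 5) = 252 group assignments of the pooled
values; ties are midranked inside the enumeration, which keeps the test an
exact permutation test for rounded data.  The two-sided p-value is the
proportion of assignments with |U − n_a·n_b/2| at least as large as
observed.  Consequences used as test oracles: complete separation gives
p = 2/252 ≈ 0.0079; the exact size of the nominal-0.05 test is 8/252 ≈
0.0317, which is also the expected fraction of significant runs under the
null.  Whether the original analysis used exact or normal-approximation
p-values is not documented; this implementation is exact, and the null
calibration above assumes exactness.  A two-sided test is used because
directionality is a conclusion of the analysis, not a premise.

The summary of a comparison is the fraction of n_runs = 5000 runs with
p < α = 0.05, banded `***` / `**` / `*` / ns at the strict thresholds
0.99 / 0.95 / 0.67 (a fraction exactly at an edge falls in the lower
band).  Each comparison draws from its own RNG substream derived from
(seed, CRC32 of the pair identity), so adding or reordering comparisons
never changes existing results.  Note that the 5000 runs of one comparison
resample the same 50 measured values, so the fraction is itself a random
variable of the dataset with an SD of roughly 0.017 under the null —
calibration checks therefore average over independent datasets.

Comparison schemes enumerate unordered species pairs crossed with the
well-developed positions {0.2, 0.4}: activity-only contrasts (4 nocturnal
× 3 diurnal × 2 = 24), cross-activity contrasts restricted to unequal size
classes (8 pairs × 2 = 16), within-nocturnal (6 × 2 = 12), within-diurnal
(3 × 2 = 6), and within-species position contrasts (7).  The source
narrative refers to the within-nocturnal set once as "12 comparisons" and
once as "3 of 10 comparisons"; the enumeration here yields 12, and the
discrepancy is left as documented.

## Clustering

For each vane position the species × parameter table of means is
normalized column-wise to its maximum (the species with the highest value
of a parameter sits at exactly 1), pairwise Euclidean distances are taken
over the normalized 3-vectors, and UPGMA builds the dendrogram: at each
step the cluster pair with the smallest unweighted average of the original
leaf-leaf distances merges, and that average is stored as the merge
height (not halved).  Ties are broken by the lexicographically smallest
pair of sorted leaf-name tuples and the lexicographically smaller cluster
becomes the left child, so trees are identical across platforms and input
orderings.  Newick branch lengths are parent-child height differences;
cophenetic distances equal merge heights, so ultrametric inputs are
reproduced exactly and the implementation is cross-checked against an
independent average-linkage oracle in the tests.  Dendrograms are computed
independently at positions 0.2, 0.4 and 0.6 (position 0.8 serrations are
too reduced to classify reliably), and each tree is checked for an
activity bipartition at the root.

## Pipeline, sizes and budgets

The full pipeline (generate/ingest → summarise → 195 Monte-Carlo
comparisons at 5000 runs → 3 dendrograms → report) is vectorised over runs
(rank matrix × assignment matrix product) and completes in a few seconds
on one CPU.  The acceptance script averages each species-position cell
over 20 replicate synthetic studies (SE ≈ 0.2° per angle cell against the
±1° reporting tolerance); single-study cell means have an SD of ≈ 0.96°
under the default noise, which is why replicate averaging is the package's
reporting convention for recovered means.

## Known limitations

* 2D only: upward bending/twist of serration tips is out of scope.
* The generator's parameter triples are drawn independently per parameter;
  real α, β and length are likely correlated within a serration.
* The occurrence matrix (which feathers of which species carry serrations)
  is a packaged fixture, not a computed result.
* Exact Mann-Whitney enumeration is limited to ≤ 10 values per side; the
  design never needs more (5 feathers per group).
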