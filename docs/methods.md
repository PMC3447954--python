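# Methods

This note documents the models, parameter choices and numerical conventions
behind `cnvstress`, and what the synthetic data do and do not establish.

## Coordinate and data conventions

All intervals are 0-based half-open internally; table writers can emit
1-based inclusive coordinates for publication-style output. A CNV's size is
`end − start`. Junction records carry the numeric homology length as
authoritative; homology strings with ambiguity codes (e.g. `T(T/C)CTGC`)
are stored verbatim and not length-checked. A junction is an `insertion`
iff its inserted-bases field is non-empty, `blunt` iff it has neither
homology nor insertion, else `microhomology`. The bundled junction catalog
is treated as positions on the declared genome without validating against
any particular reference build.

## Poisson rates and the E-test

Counts of CNVs per clone are modelled as Poisson — appropriate for rare,
independently arising events in independently expanded clones. Arm rates
are `k/n` with the exact Garwood CI on the total (`χ²` form), divided by
`n`. Treated and untreated arms are compared with the one-sided
unconditional E-test for two Poisson means: the standardized difference

    T = (λ̂₂ − λ̂₁) / sqrt(λ̂₂/n₂ + λ̂₁/n₁)      (T = 0 when both rates are 0)

is referred to its exact null distribution, summing
`P(X₁=x₁; n₁λ̃) P(X₂=x₂; n₂λ̃)` over all `(x₁, x₂)` with
`T(x₁,x₂) ≥ T(k₁,k₂)`, where `λ̃ = (k₁+k₂)/(n₁+n₂)` is the restricted
estimate under the null. Ties are counted in the rejection region
(conservative). The double sum is truncated where each marginal Poisson
tail falls below `tail_eps` (default 1e-9) and the truncated mass is
reported on the result. **Numerical caveat:** a reported p-value is only
meaningful down to roughly the truncated mass; analyses that need to
resolve p ≈ 1e-14 (the study-scale rate separation) must pass
`tail_eps=1e-18`, for which a Chernoff-style support bound replaces scipy's
extreme-tail quantiles. Simulated type-I error at α = 0.05 (λ = 1, 20 vs 20
units, 10,000 replicates) lands near nominal, as this test is known to do.
The test is one-sided by design; no two-sided variant or overdispersion
handling is provided.

## Hotspots and the Monte Carlo null

Hotspots are defined operationally: tile each chromosome in non-overlapping
10 kb windows, count distinct CNVs intersecting each window (half-open
intersection), and merge maximal runs of consecutive windows with count ≥5
into regions. A region's `cnv_count` is the number of distinct CNVs
overlapping the merged region; `clone_frequency` is the fraction of a
supplied treated-clone roster carrying at least one overlapping CNV, and
`cnvs_per_treated_clone` is `cnv_count` over the roster size (the two
differ when one clone carries several CNVs in the same region). How the
original hotspot tables drew exact region limits is not documented
anywhere we can consult, so no claim is made of reproducing published
region boundaries — only the windowed-run core, counts and frequencies.

The null asks: if the same interval sizes were placed uniformly at random —
chromosome chosen with probability proportional to length among
chromosomes long enough, start uniform over valid positions — how often
does any ≥5-overlap window arise? The per-iteration statistic is computed
by an endpoint sweep over window-snapped interval ranges (closings ordered
before openings at ties), vectorised over iterations in chunks of 2,000;
10,000 iterations take about a second at cohort scale. A
`per_chromosome` option keeps each interval on its observed chromosome
instead. The default "any qualifying region" statistic is the most literal
reading of the published method; the count-of-regions alternative can be
derived from `find_hotspots` directly.

## Junction calling

A junction read is anchored by its maximal exact common prefix with the
left flank window and maximal exact common suffix with the right flank
window; both anchors must be ≥20 bp and unique within their windows. If
the extensions overlap by `k`, the junction has `k` bp of microhomology
(the deletion placement is ambiguous over that tract; the leftmost
placement is reported, i.e. the breakpoint at the left edge of the tract).
A gap is an untemplated insertion; exact abutment is blunt. No probabilistic
realignment or gapped alignment is attempted — the synthetic generator
guarantees reads for which exact extension is the correct model, and real
Sanger-confirmed junctions satisfy it in practice.

## Microhomology null model

Under random sequence, exact extension from the junction point is
geometric on either side with per-base match probability `m = Σ pᵢ²`
(`p` the base composition), and the two directions are independent:

    P(K = k) = (k + 1) (1 − m)² mᵏ,   E[K] = 2m / (1 − m)

the `k+1` factor counting the ways `k` matched bases split around the
junction point. For uniform composition, `P(0) = 9/16` and the mean is
2/3 bp. The model is cross-validated in the tests by direct Monte Carlo
(simulated bidirectional extension over a million junction points). Base
composition defaults to uniform; a genome-estimated composition can be
passed. The comparison report flags the observed distribution as
right-shifted when its mean exceeds the null mean — the qualitative
signature distinguishing microhomology-mediated joining from
sequence-indifferent joining.

Mean/median homology statistics exclude insertion junctions by default:
an insertion junction's homology is 0 by definition and mixing the two
classes makes the homology statistics depend on the insertion rate. With
this convention the bundled catalog gives means of 2.0 bp (wild-type) and
2.1 bp (Xrcc4-null), medians 2.0 bp; including insertions gives 1.76/1.92.
The flag is exposed (`exclude_insertions`).

## Complex events

Junctions from the same clone and chromosome are single-linkage clustered
with a 5 Mb gap limit — wide enough to capture both ~0.2 Mb multi-junction
events and ~2.5 Mb shattered regions, and far below the distance between
independent events in practice. Clusters of ≥2 junctions are complex
events; clusters with ≥8 deletion-type junctions are flagged
chromothripsis-like (the threshold sits below the ~10 discrete deletions of
a full chromothripsis event so that desk-scale simulations can trip it;
both knobs are arguments).

## Flank homology scan

Each CNV contributes two 10 kb windows centred on its breakpoints (clipped
at chromosome bounds with a warning). Windows are compared by k-mer seeded
(k = 16), ungapped extension in both orientations. Per seeded diagonal the
maximum-scoring segment is reported (match +1, mismatch
−min_ident/(1−min_ident), so a positive score implies identity strictly
above the threshold); if that segment is shorter than `min_len` the longest
positive-score stretch is used instead, so detection never depends on the
scoring variant. Ungapped alignment is deliberate: the criterion is percent
identity over a contiguous stretch, and a gapped variant would import an
arbitrary gap-penalty convention. The fraction of CNVs with a qualifying
hit carries an exact (Clopper–Pearson) binomial CI. Genome-wide fractions
on a real reference are out of scope; synthetic genomes with planted
repeats substitute in the tests.

## Segmentation and CNV calling

Probe tracks are segmented by penalised least-squares binary segmentation:
recursively split at the change point with the largest residual-sum-of-
squares reduction, keep a split iff the reduction exceeds the penalty and
both children hold ≥2 probes, then polish every internal boundary by
re-optimising it between its neighbouring boundaries (this removes
off-by-one boundary placements that top-level splits inherit from fitting
a mixture of baseline and event as one segment). The default penalty is
`2σ̂² ln n` with σ̂ estimated from the median absolute successive
difference — robust to the (few) change points. Segment boundaries fall
midway between adjacent probes; segment means are thresholded at −0.5
(loss) and +0.3 (gain), adjacent same-state segments merged, and calls
below `min_size` (default 1 kb) dropped. At the default synthetic
conditions (3.6 kb spacing, noise sd 0.2, shift −1) a 50-probe deletion's
boundaries are recovered within one probe spacing in ≥95% of replicates
and flat tracks of 10⁴ probes produce no calls. The vendor segmentation
used for the original arrays is proprietary and unpublished;
equivalence to its exact call set is not claimed, only the stated
detection contract (routine detection of events ≥20 kb at this probe
density).

## Synthetic data

The stochastic generator (`SimulationConfig`) emulates the study design:
Poisson clone counts per arm with default rates 0.43/5.19 (wild-type
untreated/treated) and 1.31/7.34 (Xrcc4-null), 20 clones per arm by
default (per-arm clone counts were never published; 20 is one experiment's
scale); log-normal sizes with 60 kb median and log-sd 1.0 (reproducing the
published median ~60 kb and range ~10 kb–Mb); a hotspot mixture routing
35% of CNVs through the observed 13-region catalog weighted by observed
counts, the rest uniform; deletion probabilities 0.909/0.833 per genotype;
probe tracks at 3.6 kb spacing (≈720k probes genome-wide) with shifts −1
(hemizygous loss, log2(1/2)) and +0.585 (single-copy gain, log2(3/2)) and
Gaussian noise sd 0.2 — the shifts are modelling choices, not published
values. Junction reads are created by locally editing the reference so the
two breakpoint flanks share exactly the requested homology and mismatch
immediately beyond it in both directions (edits prefer bases inside the
deleted interval), which guarantees exact truth labels rather than relying
on naturally occurring homology.

The deterministic reference cohort (`synthetic_cohort`) stands in for the
study's unpublished per-CNV supplementary list. It is *constructed*, not
sampled: per (genotype × hotspot-status) cell, sizes are geometric grids
within intervals bounded by the four published median pivots (46.3 kb
non-hotspot, 59 kb wild-type, 63 kb Xrcc4-null, 89.8 kb hotspot), with
per-interval counts chosen so that all four cohort medians land exactly on
their pivot order statistics simultaneously; hotspot members all overlap a
region-core 10 kb window with staggered offsets (distinct boundaries);
non-hotspot CNVs are placed isolated, ≥0.5 Mb apart and ≥2 Mb from any
hotspot. It therefore reproduces the published *cohort-level* numbers
exactly (counts, deletion fractions, hotspot per-region counts, medians,
ranges) while its per-CNV coordinates, clone assignments and
within-stratum size spacing are artificial. Consequences: tests passing on
this cohort validate the statistics and interval machinery, not CNV
calling from real array data; its spatial regularity (isolated non-hotspot
placements) makes the hotspot null slightly cleaner than real data would
be; and clone-level frequencies are round-robin artefacts. Real-data
features deliberately not emulated anywhere: array waviness and dye bias,
mosaicism, breakage-fusion-bridge dynamics, and sequence-driven hotspot
mechanisms.

## Known limitations

* The E-test p-value resolution is bounded by the truncation threshold;
  callers comparing astronomically small p-values must lower `tail_eps`.
* Hotspot region boundaries are window-quantised (10 kb); sub-window
  precision is not attempted.
* The junction caller requires unique ≥20 bp anchors and exact flank
  matches; sequencing errors or SNVs in flanks are not modelled.
* The homology scan is ungapped; a diverged repeat with indels registers
  as multiple shorter diagonals and may fall below `min_len`.
* `group_complex_events` clusters within a chromosome only; inter-
  chromosomal complex events (translocation-coupled) are out of scope.
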