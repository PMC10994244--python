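# Methods

## Copy number from off-target reads

### Model

A targeted capture panel sequences its baits deeply, but a sizeable
fraction of reads falls outside the baited regions and samples the
genome approximately uniformly. Binning these off-target reads gives a
shallow whole-genome coverage track. For a tumour sample with purity ρ
(fraction of tumour cells) mixed with diploid normal cells, a genomic
segment at tumour copy number n_T contributes coverage proportional to
n_T·ρ + 2(1 − ρ). Because the track is normalized by its own mean
(r = count / mean count), the normalizing constant is the average copy
number of the sequenced mixture,

    ψ = ρ·ψ_tumour + 2(1 − ρ),   ψ_tumour = length-weighted mean n_T,

so that

    r = (n_T·ρ + 2(1 − ρ)) / ψ      and      n_T = (ψ·r − 2(1 − ρ)) / ρ.

ψ here is deliberately the mixture-average copy number, not the tumour
ploidy: the two coincide only at ρ = 1 or ψ_tumour = 2, and the
normalized ratio track can only identify the mixture-scale quantity.
The synthetic generator's truth record carries both (`psi_tumour`,
`psi_sample`) so simulation studies compare against the estimable one.

### Pipeline steps and parameters

* **Target masking** — baited intervals are padded by 1000 bp on both
  sides (bait shoulders still capture on-target fragments) and merged;
  reads starting inside the padded union are discarded and bins wholly
  inside it are masked.
* **Binning** — fixed 30-kb bins; a read is assigned to the bin
  containing its leftmost aligned position. Reads must be mapped,
  primary, non-duplicate and have MAPQ strictly greater than 30
  (31 passes, 30 fails). Zero-count bins are masked rather than given
  −∞ log-ratio; the ratio mean over retained bins is exactly 1.
* **Segmentation** — circular binary segmentation on log2(r). At each
  recursion the arc (i, j] maximizing the two-sample t-like statistic
  against its complement is tested by permutation (1000 label
  permutations, α = 0.01, seeded RNG; early stop once the exceedance
  count rules significance out); accepted cuts recurse. Minimum
  segment width is 2 bins and there is no post-hoc undo-splits
  pruning. After the recursion, every breakpoint is re-optimized
  between its two neighbours until the set is stable ("refinement"):
  the recursive search alone can freeze a misplaced arc edge tens of
  bins from the true changepoint, and the resulting blended segments
  bias the downstream fit far more than their size suggests. Segment
  means are computed on the linear ratio scale because the copy-number
  equations are written in r, not log r.
* **Grid fit** — for every (ψ, ρ) on the 351 × 81 grid
  (ψ ∈ [1.5, 5], ρ ∈ [0.2, 1], step 0.01) the per-segment n_T is
  computed and the distance Σ w·|n_T − round(n_T)| accumulated, with
  the nearest integer floored at zero: copy numbers cannot be
  negative, and without the floor the grid admits spurious exact
  solutions whose implied copies are negative (e.g. ratios (0.5, 1,
  1.5) are "explained" by n_T = (−3, 0, 3) at ψ = 1.5, ρ = 0.25).
  Weights are 1 per segment by default; `weight_by_length` switches to
  bin counts, useful when small spurious segments are present. Ties
  break to the lowest ψ, then the highest ρ — the most parsimonious
  genome. The surface is accumulated segment-by-segment with
  element-wise operations, so it is bit-identical to a scalar triple
  loop in the same order.
* **Degeneracy** — when ≥ 2 grid points within 1e-12 of the minimum
  differ in ψ by more than 0.1, the fit is flagged unidentifiable.
  A genome with a single copy-number state always triggers this (one
  equation, two unknowns: the zero set is a ridge).

### Identifiability

Integer-snap fitting has intrinsic ambiguities beyond the flat-genome
ridge: any affine relabelling of the copies that lands on non-negative
integers is an equally exact solution. A profile with states
(1, 2, 3, 4) is exactly re-explained as (0, 1, 2, 3) at
(ψ = 1.74, ρ = 0.52), and every profile has a genome-doubled
counterpart. A homozygous-deletion state anchors the fit (a downward
shift would require −1 copies, which the non-negative floor penalizes
heavily), and the doubled solution both amplifies noise-to-integer
distances (slope ψ/ρ doubles) and loses the lowest-ψ tie-break. The
simulation studies therefore use a deletion-anchored profile — also
the realistic choice for this tumour type, where homozygous *CDKN2A*
deletion is the most frequent lesion.

### Exon-level ratios

On-target copy ratios divide the MAPQ-filtered read depth at each exon
target's centre base by the depth of a user-supplied diploid reference
sample at the same base, normalizing for per-bait capture efficiency.
The reference sample is a required input; exons with zero reference
depth are masked with a warning.

## Expected splicing ratio

For a single gene, exons are the union of its annotated exon records
(GTF, 1-based inclusive; converted internally to 0-based half-open),
merged per overlapping cluster and ordered 5′→3′ by strand; introns are
the inter-exon gaps. A 200-nt promoter pseudo-exon ("upstream anchor")
precedes exon 1.

For exon k, the expected set contains every upstream exon j whose
sequence can appear in a canonically spliced read of length L (default
97 nt) ending in exon k: j is reachable iff the exonic length strictly
between j and k is < L − 1 (the limiting read ends on exon k's first
base and extends L − 1 nt upstream in spliced coordinates). The sets
are suffix-contiguous by construction; the boundary convention is
isolated in one function (`_reachable`) for easy revision. The anchor
joins the set under the same rule.

A read is **informative** for exon k when one of its aligned reference
blocks overlaps the exon by ≥ 1 base (N gaps do not count as
coverage), and **expected** when its transcription-wise 5′ start base
lies inside an exon of k's expected set or the anchor. The ratio is
expected / informative; cells with fewer than 10 informative reads are
reported as not informative (NA; black in the heatmap). On fully
canonical data every informative cell is exactly 1.0; exon skipping
depresses the exon immediately downstream of a skipped exon that is
long enough (≥ L − 1 exonic nt) to break upstream reachability —
skipping shorter exons is invisible to this statistic by design of its
reachability bound.

The noncanonical-junction screen classifies every CIGAR `N` gap as
canonical iff both boundaries coincide with an annotated intron and
reports the noncanonical fraction per sample. Mate-pair information is
not used in either statistic.

## CDK4 profile classification

The spot3/spot2 background-subtracted volume ratio from 2D-gel
immunoblots maps to: A (ratio < 0.025), L (0.025 ≤ r ≤ 0.5),
H (r > 0.5). The L interval is closed at both ends; 0.025 and 0.5 are
L. The three intervals partition [0, ∞); a zero spot-2 volume leaves
the ratio undefined and the record flagged rather than classified.

The CCP proliferation score is the per-sample median of the signature
genes' CP20M values, on the linear scale (a `log2` switch exists,
default off). The signature is supplied as a plain gene list — the
31-gene CCP set belongs to its original publication and is not
hard-coded. Correlation between ratio and score uses Spearman's rank
test with mid-rank ties, by default restricted to H and L samples (the
classes with detectable phosphorylation); the raw ratio is used, not
its log, as rank correlation is invariant to monotone transforms.

## Expression, strata and survival

* **CP20M**: count · 2×10⁷ / library size, library defaulting to the
  column sum, so normalized columns sum to 2×10⁷ exactly.
* **Gene filter**: keep genes with ≥ 100 raw counts in ≥ 1 sample
  (boundary inclusive). **Virus detection**: a viral genome (one "gene"
  per genome) is detected at ≥ 20 counts.
* **Strata** (CP20M scale): public-cohort schemes — *CDKN2A*
  low < 100, intermediate 100–1000 (both ends included; "high" is
  defined by > 1000), high > 1000; *CCNE1* high ≥ 200; *RB1* low
  < 400. Own-cohort schemes: *CDKN2A* high ≥ 600; *CCNE1* high ≥ 100;
  *RB1* low < 900. "From X" / "set at X" thresholds are read as ≥ X,
  "below X" as < X; every scheme's exact inequalities are printed in
  the CLI help and the output header.
* **Survival**: Kaplan–Meier product-limit curves per group; the
  Mantel–Cox log-rank test from observed/expected event tallies over
  pooled event times, χ² = (O₁ − E₁)²/V for two groups (V the
  hypergeometric variance) and Σ(O − E)²/E for more. The two-group
  hazard ratio is the O/E construction (O₁/E₁)/(O₂/E₂) with
  se(log HR) = √(1/E₁ + 1/E₂) — not a Cox fit. This estimator is known
  to be biased toward the null for hazard ratios far from 1 in large
  balanced designs; in the unbalanced small-vs-large contrasts it is
  used for here its CI is wide and coverage is conservative. No
  multiple-testing correction is applied to survival contrasts.
* **Fisher**: two-sided exact p (hypergeometric tail sum) with the
  conditional-MLE odds ratio; a zero margin gives p = 1 and an
  undefined odds ratio.

## Synthetic data

The generator produces every input with known ground truth; all
generators are pure functions of their inputs and seed.

* **Off-target counts** — negative-binomial bin counts with mean
  mean_depth · r. `dispersion` d is the relative extra-Poisson
  variance: variance = (1 + d)·mean, realized as gamma-Poisson with
  NB size = mean/d; d = 0 degrades to Poisson. d = 0.05 emulates
  clean shallow off-target coverage (variance 5% above Poisson);
  real panels show d up to ~1 from GC and mappability structure,
  which this generator does not model (no GC correction exists in
  the pipeline either). Defaults: depth 200 per 30-kb bin, purity
  0.7, a five-state profile (copies 2, 1, 0, 3, 4) over 500 bins.
* **Spliced reads** — reads placed uniformly along each isoform's
  spliced sequence, converted to genomic start + CIGAR with N gaps
  spanning skipped introns/exons. The ground truth enumerates every
  placement of every isoform exhaustively and tallies
  expected/informative weight per exon with exactly the reader's
  counting rules, so generator and reader agree to binomial noise by
  construction. No sequencing errors, soft clips or coverage bias are
  modelled — passing tests validate the counting logic, not robustness
  to alignment artefacts.
* **Spot tables** — true ratios drawn strictly inside each class
  interval (A: 0.002–0.023, L: 0.05–0.45, H: 0.6–3.0), spot-2 volumes
  log-uniform over a plausible densitometry range.
* **Cohorts** — exponential survival per group hazard with independent
  exponential censoring; expression counts Poisson around group means
  at a fixed 2×10⁷ library (a filler gene absorbs the remainder, so
  CP20M equals the raw count). The default scenario mirrors a merged
  public MPM cohort: short-survival hazard ln 2 / 7.88 ≈ 0.088 per
  month, hazard ratio 0.31, censoring 0.02 per month (≈ two-thirds of
  patients reach the event), and the unbalanced 17-vs-124 group sizes
  of the high-vs-intermediate *CDKN2A* contrast.

## Problem sizes

Simulation studies use 500-bin tracks (20 seeds for recovery),
100/50 seeded runs for breakpoint accuracy,
2000 reads for the splicing mixture, 1000 null cohorts for the
log-rank level and 200 cohorts for hazard-ratio coverage. These sizes
give Monte-Carlo standard errors comfortably below the tolerances they
are checked against while keeping a full run in the tens of seconds.

## Known limitations

* No GC or mappability correction; no allele-specific copy number; no
  subclonal (non-integer) states. Whole-genome-doubled solutions are
  suppressed only by noise amplification and the lowest-ψ tie-break,
  not by orthogonal evidence (e.g. SNP allele frequencies).
* CBS p-values use plain max-statistic permutation; for very long
  tracks a hybrid tail approximation would be faster and slightly more
  accurate.
* The splicing detector tests read starts against genomic exon
  intervals only (it does not verify that a spliced read's path is
  consistent with the canonical chain), counts a read once per
  overlapped exon, and cannot see skipping of exons shorter than the
  reachability bound.
* The O/E hazard ratio inherits the Mantel–Haenszel bias for extreme
  effects in balanced designs; a Cox model is deliberately out of
  scope.
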