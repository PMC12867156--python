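# Methods

This note documents the models, procedures, parameter choices and numerical
conventions behind `cfties`, and what the synthetic-data tests do and do not
establish.

## Coordinates and interval semantics

All coordinates are 0-based half-open (BED convention). Two intervals
*overlap* iff they share at least one base pair; a shared boundary
(`a.end == b.start`) is not an overlap. `overlap_intersect` and
`subtract_overlapping` are asymmetric filters that return members of the
query set with their coordinates unmodified, and they partition the query
set exactly. *Merging* (`extend_and_merge`, `consensus_peaks`) follows the
union of covered bases on the integer line, so book-ended intervals
coalesce — the bedtools-merge default. The centre of an even-width interval
is the floor midpoint, keeping all arithmetic in integers. Exact duplicate
`(chrom, start, end)` records are dropped at `SiteSet` construction and
zero-length records are rejected, since peak callers should emit neither.

## Signature derivation

The scoring bundle holds three site sets: promoter-mark (H3K4me3) tumor-up
peaks, enhancer-mark (H3K27ac) tumor-up peaks, and fusion-occupied TFBSs
(catalogue sites retained because a fusion ChIP peak overlaps them ≥1 bp;
output coordinates are the catalogue's). TFBSs overlapping the H3K27ac-up
set are discarded before scoring so a locus never contributes twice;
`assemble_bundle` enforces this invariant and is idempotent.

### Differential test

Tumor-up peaks come from a per-peak test over the consensus peak set of a
mark, with selection at BH FDR q < 0.01 and |log2FC| above a mark-specific
threshold (2 for H3K4me3, 1 for H3K27ac). Full negative-binomial GLM
machinery is deliberately out of scope; the in-repo test is designed to
preserve that pipeline's two load-bearing properties — cross-peak
information sharing and threshold-aware selection — with fully specified
arithmetic:

* **Normalization.** Counts are scaled by median-of-ratios size factors
  (per sample, the median across peaks of the ratio to the per-peak
  geometric mean, rescaled to a CPM-like magnitude), then log2-transformed
  with a 0.5 pseudocount. Total-count scaling is available as an option
  but is composition-biased: when differential peaks hold a nontrivial
  share of the reads, the enriched group's library total inflates and
  every log2FC shrinks by the log of the library ratio. The log2 fold
  change reported per peak is the log-ratio of group mean normalized
  counts; positive means tumor-enriched.
* **Test.** The default is an empirical-Bayes moderated pooled-variance
  t-test: per-peak variances are squeezed toward a prior `(s0², d0)`
  estimated from all peaks of the mark by method of moments on log
  variances (Smyth 2004), and the statistic has `d + d0` degrees of
  freedom. With 4–6 samples per group an unmoderated Welch t has ~6 df and
  essentially no power at q < 0.01; sharing variance across peaks is what
  small ChIP-seq designs require. When a fold-change threshold `lfc_min`
  is in force, the moderated test is computed against the interval null
  |Δ| ≤ `lfc_min` (the TREAT construction of McCarthy & Smyth 2009):
  significance then requires the fold change to significantly *exceed*
  the threshold rather than merely be nonzero with a point estimate past
  it. This is what makes "recover all spiked peaks with no chance false
  positives" an achievable property — a plain zero-null test with a
  post-hoc fold-change filter admits ~`q × discoveries` chance false
  discoveries per analysis by design. `lfc_min = 0` reduces to the
  ordinary two-sided moderated test. Plain Welch (`method="welch"`) and
  exact rank-sum (`method="ranksum"`) are available; groups with <3
  samples always fall back to the exact rank-sum.
* **FDR family** is all consensus peaks of the given mark.

## Plasma quantification

Fragments are collapsed to 1-bp floor midpoints so each fragment can count
at most once per site window. Each site is re-centred to a `window` of
3000 bp, binned at `bin_width` 40 bp (75 bins), and midpoint counts are
aggregated across all sites of the set; a midpoint inside two overlapping
re-centred windows counts once per window (rare for well-spaced sites).

Shoulder normalization estimates flat background as the mean bin count
over the outermost 20% of bins on each side (bins 0–14 and 60–74) and sums
`max(bin − shoulder, 0)` over the central third (bins 25–49, ±500 bp).
Consequences used as exact test oracles: an additive flat background
cancels exactly; a central spike of height *h* in *k* bins yields exactly
*k·h*. Negative post-subtraction bins are floored per bin before summing
to stop noise-driven negative signals; the floor makes healthy-sample
central signals small positive numbers rather than zero-mean noise, which
is harmless because every contrast is rank-based. Whether the upstream
convention subtracts or divides background is not fixed by any public
description; subtraction with explicit geometry was chosen because it is
exactly testable. Normalizing the aggregate (rather than each bin) by the
housekeeping signal is equivalent for the ratio-of-sums summary used.

The housekeeping reference is the same shoulder-corrected central signal
over a DNase-hypersensitivity site set expected active across tissues
(an input BED in real use; a fabricated stand-in set in the generator).
It must be positive — a sample whose reference is ≤ 0 is *unquantifiable*
and raises an error rather than silently scoring 0. `site_signal` =
central signal over the site set ÷ reference; duplicating a sample's
fragments changes neither (depth invariance, exact).

## The integrated score and classification

`TIES = log(max(w·(s_K4, s_K27, s_TFBS), ε))` with unweighted components
by default, natural log, and floor ε = 1e−6 (shoulder subtraction can
yield an exact 0). The log base is configurable and immaterial to every
downstream decision — AUC, Youden ordering and rank tests are invariant
under strictly increasing transforms (tested) — only the absolute cutoff
value depends on base and scale. H3K4me3 fragments are scored on the
promoter-mark set only; H3K27ac fragments on the enhancer-mark set and on
the deduplicated TFBSs. A sample missing an assay fails loudly unless
partial scoring is explicitly allowed, in which case missing components
contribute zero and are recorded.

ROC/AUC is rank-based with ties counted one half (scikit-learn backend,
oracle-checked against explicit pair counting). The operating threshold
maximizes Youden's J = TPR − FPR under `score > threshold`; candidates are
midpoints between consecutive distinct scores plus sentinels beyond the
extremes, and ties in J break toward the largest threshold (maximal
specificity — the operating point favouring precision). LOO-CV refits the
threshold on each n−1 fold, classifies the held-out sample, pools
precision/recall/specificity over held-out predictions, and reports the
mean per-fold threshold. The positive class is the tumor label.

Monitoring: draws are ordered by date within patient; each adjacent pair
yields `Δ% = 100·(TIES₁ − TIES₀)/|TIES₀|`, labelled with the status of the
interval ending at the later draw. Because the score is on a log scale and
can cross zero, pairs whose baseline magnitude is below 10·ε are excluded
and logged. Progression pairs are compared against pooled response/stable
pairs with the two-sided rank-sum test (exact for ≤25 per group without
ties, tie-corrected normal approximation otherwise).

## In silico dilution

For a tumor/healthy pair the read budget is `N = min(|tumor|, |healthy|)`;
`round(N·DL)` fragments are drawn without replacement from the tumor
sample and `round(N·(1−DL))` from the healthy one, per mark, one draw per
(pair, level). `DL` is defined as the tumor fraction *of reads*: that is
the only reading under which the expected tumor fraction of the mixture,
`TF_tumor × DL`, is coherent, and it respects the read budget regardless
of which sample is smaller. The default grid is the 11 levels
0.9…0.1, 0.05, 0.01. Mixtures are binned by expected TF into 0.4%-wide
bins with open terminal bins (<0.4% and ≥3.2%); each populated bin's
scores are compared against the undiluted healthy samples' scores by the
rank-sum test. The limit of detection is reported as a bin interval: the
lowest-TF populated bin significant at α = 0.05 with every higher
populated bin also significant.

## Synthetic data generator

The generator defines the study conditions; its defaults are fixed, not
tuning knobs.

* **Genome**: one 10-Mb chromosome. Site sets (60 promoter-up, 80
  enhancer-up, 100 TFBS, 150 DHS, 60 rival-subtype-up) of width
  200–1000 bp placed uniformly with ≥3 kb separation, so each site's
  3-kb aggregate window sees only flat background from its neighbours —
  the shoulder-normalization assumption. Exactly
  `round(0.13 × n_tfbs)` TFBSs are placed overlapping enhancer-up sites
  (the 13% default mirrors the observed shared fraction in the motivating
  dataset) to exercise deduplication; DHS sites are disjoint from all
  signature sets.
* **Fragments**: per sample, 100,000 fragments; each is tumor-derived with
  probability equal to the tumor fraction. Tumor midpoints fall at the
  label's signature sites with relative rate λ = 20 per site bp over
  background; all other midpoints follow the shared housekeeping
  enrichment (rate 30) at DHS sites or uniform background. Lengths are
  truncated-normal 167 ± 20 bp (bounds 50–400) — standard mononucleosomal
  cfDNA; no public quantitative value exists for the plasma enrichment
  magnitude, so λ is a fixed generator choice, and every enrichment-
  dependent result below is a property of the synthetic conditions, not an
  inferred biological value.
* **Tumor fractions**: tRCC and ccRCC samples draw log-uniformly from
  0.005–0.30 (ccRCC carries its own enrichment site set so that the
  tRCC-vs-ccRCC contrast is nontrivial rather than a relabelled healthy
  contrast); healthy samples are 0. Longitudinal trajectories multiply TF
  by U(1.8, 2.8) across progression intervals, U(0.9, 1.1) across stable
  and U(0.25, 0.55) across response, capped at 0.5, with draws 90 days
  apart.
* **Cell-line counts**: negative binomial with dispersion 0.1 and
  log-normal baseline means (ln 300 ± 0.8); the tumor group's mean is
  multiplied by 2^log2fc at true-up peaks (divided at true-down). The
  pipeline's cell-line stage uses log2fc = 4 with 360 background decoy
  peaks per mark, making true peaks a 12–14% share of the consensus with
  ≥2 log2 units of margin over each mark's selection threshold — matching
  the real setting, where differential peaks are a ~9–18% share and
  cell-line effects sit far above threshold. (At a 33% share with only
  1 unit of margin, residual normalization shrinkage of ~0.6 log2 units
  makes threshold-aware selection powerless; the generator avoids that
  regime because the data it emulates is not in it.)
* **Reproducibility**: all randomness flows from one master seed through
  named substreams (per sample, per mark, per stage); identical
  configuration and seed reproduce byte-identical fragment files
  (hash-checked in tests).

What the generator does **not** emulate: GC and mappability bias,
copy-number structure, fragment-level sequence, immunoprecipitation
efficiency variation, or biological heterogeneity of signature strength
between patients. Passing tests therefore demonstrate that the machinery —
interval algebra, quantification, normalization, scoring, thresholding,
dilution and monitoring statistics — is correct and discriminates when the
assumed signal structure is present; they say nothing about clinical
sensitivity or specificity on real plasma.

## Numerical choices and degenerate inputs

* BH adjustment via `statsmodels`; q ≥ p always holds within a family.
* Rank tests via `scipy.stats.mannwhitneyu`: exact when both groups ≤25
  without ties, otherwise tie/continuity-corrected normal approximation.
* Trigamma inversion for the variance-prior df uses Newton iteration
  (limma's scheme); when log-variances show no excess spread the prior df
  is effectively infinite and the common-variance z-limit is used.
* Empty site sets, single-class label vectors, zero-fragment samples,
  zero-length or reversed BED intervals, single-class LOO folds, and
  dilution levels outside (0, 1) all raise typed errors naming the
  problem; nothing degrades silently.
* Youden candidates include sentinels below the minimum and above the
  maximum score, so "classify everything negative" is always available;
  with inverted labels the best J under the fixed `>` rule is 0 at the
  upper sentinel.
* The pipeline exchanges only plain-text artifacts (BED/TSV/JSON) between
  stages, and the manifest records config, versions, per-stage row counts
  and output hashes, so reruns are bit-exact diffs.

## Scales used by the shipped analyses

The test suite and `scripts/acceptance.py` run at desk scale on one CPU:
cohorts of 15/15/9 samples (and 10 tumors × 9 healthy for the dilution
design, its full 90-pair × 11-level grid), 100k fragments per sample and
mark, 200-peak differential simulations over 10 seeds, and 1,000 randomized
interval instances against brute-force oracles. These sizes were chosen so
every statistical check retains comfortable power while the whole suite
completes in a few minutes.
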