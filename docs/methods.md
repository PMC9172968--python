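# Methods

This note documents the models, numerical choices and limitations behind
`seizmap`. Parameter defaults restate the analysis conventions of the
larval zebrafish *sv2a* loss-of-function study design the package models;
where that design leaves a choice open, the decision and its rationale are
given here.

## LFP quantification

**Conditioning.** Traces are zero-phase filtered: 4th-order Butterworth
band-pass at 3–300 Hz and an IIR notch (Q = 30) at 50 Hz, matching the
hardware filtering of the recording protocol (2 kHz digitization, 10-min
traces). Zero-phase filtering (`filtfilt`) keeps event timing unbiased.

**Baseline measure.** The discharge rule is "amplitude ≥ 3× baseline for
≥ 100 ms", but the baseline statistic itself is a design choice: we use
1.4826 × the median absolute deviation of the full conditioned trace, a
robust SD estimate that is insensitive to the discharges themselves and
needs no hand-picked quiet segment.

**Envelope and detection.** The instantaneous amplitude is estimated by a
10 ms moving RMS, noise-floor corrected and scaled:
amplitude ≈ sqrt(2·RMS² − 2·baseline²). For a sinusoidal burst of
amplitude A on noise of SD σ the raw mean square is A²/2 + σ², so the
correction makes the envelope an approximately unbiased estimate of A
itself; the 3× rule then compares burst amplitude, not
amplitude-plus-noise (a burst at 2.5× baseline must not cross a 3×
threshold just because the noise adds ~8% to the envelope). Suprathreshold
runs separated by < 20 ms are merged before the 100 ms duration rule,
because polyspiking bursts dip between spikes; the merge gap is
configurable. Events are reported as half-open intervals with their peak
amplitude factor.

**Spectral analysis.** Welch's method with Hamming tapers, 100 ms windows,
80% overlap, per-segment constant detrend, one-sided density scaling and
the final partial segment dropped — at 2 kHz this is 200-sample segments
with 160-sample overlap and a 10 Hz bin spacing. Band averages use
frequency-bin centers in half-open [low, high) bands of width 10 Hz up to
150 Hz (15 bands); the 20–50 Hz summary is the arithmetic mean of the
three bands inside that range. Note that at the default window a pure tone
midway between bins (e.g. 35 Hz) splits its power across the 30 and 40 Hz
bins; analyses that need to resolve single tones should pass a longer
window (1 s gives a 1 Hz grid). Group summaries are normalized to the
reference (wildtype) group mean as 100%; means rather than medians match
the "normalized to … as 100%" plotting convention.

## Differential expression (NB Wald surrogate)

The published analysis used a full NB GLM framework with dispersion
shrinkage; reproducing that machinery is out of scope. The surrogate here
is deliberately desk-scale and deterministic:

- library-size factors by median-of-ratios over genes with all-positive
  counts (fallback: total-count scaling normalized to mean 1);
- expression filter: mean CPM ≥ 1 in at least one condition;
- per-gene method-of-moments dispersion pooled across the two contrast
  groups under Var(q) = μ·mean(1/s) + αμ², floored at 1e-8, no shrinkage —
  the main divergence from the published tool;
- delta-method standard error of the log fold change;
- p-values from a **t reference with residual df (n_a + n_b − 2)** rather
  than a normal reference: with quadruplicate samples the variance
  estimate has ~6 df, and the normal reference would roughly double the
  nominal type-I error. With the t reference the null rate on simulated
  data is ~0.05 (the test suite asserts 0.03–0.07);
- genes with zero counts throughout both groups are excluded (logged);
  when exactly one group mean is zero a 0.5 continuity correction is
  applied to both means, keeping fold changes finite and signs consistent.

"Absolute fold change > 2" is interpreted on the linear scale
(fold_change ≥ 2 up, ≤ 0.5 down), consistent with down-regulated fold
changes being printed below 1. Ortholog mapping precedes top-k selection
(matching the workflow's stated order); one-to-many sources contribute to
each target once, many-to-one conflicts resolve to the largest |Wald|
(ties: smaller p, then lexicographic id). Signature selection takes the k
largest positive and k most-negative Wald statistics with the same
deterministic tie-break.

## Connectivity scoring

The reference service queried in the original workflow does not publish
its per-query scoring pipeline in reproducible form, so the package adopts
the canonical rank-based connectivity statistic: the unweighted two-sided
KS enrichment of each signature side in the compound's ranked profile,
combined as raw = (es_up − es_down)/2 when the enrichments disagree in
sign and 0 otherwise (null connectivity). Two points are deliberate
choices:

- **Normalization** is max-|raw| scaling onto [−100, 100] rather than a
  percentile scheme against a historical query corpus (which a single
  reference matrix cannot supply). The score range and the −90/+90/0
  selection semantics are preserved.
- **Asymmetry of the statistic**: the a and b terms are offset by one rank
  step, so a query at the exact bottom of a list scores slightly larger in
  magnitude than the same query mirrored to the top (e.g. ranks {9,10} of
  10 give −0.9 while {1,2} give +0.8). This is a property of the classic
  statistic, not a bug; tests pin it against a term-by-term brute-force
  evaluator exhaustively for query sizes ≤ 4 over profiles of length ≤ 12.

Ranking ties break lexicographically by gene id for cross-platform
determinism. Candidate selection excludes mechanism classes targeting
master regulators of cellular homeostasis ("DNA synthesis", "RNA
synthesis", "tRNA synthetase", "RNA polymerase", "protein synthesis" by
default; case-insensitive exact match, configurable, since the published
exclusion list is open-ended). "Score = 0" controls are identified within
1e-9.

## Statistics

- **One-way ANOVA**: classical fixed-effects F; degenerate all-zero
  within-group variance raises rather than returning infinity.
- **Dunnett**: many-to-one t statistics on the pooled within-group
  variance; the family-wise adjustment samples the null of max|T| by
  Monte-Carlo (default 1e5 draws, adjusted p accurate to ~±0.005).
  Group-mean draws use one substream per group and the pooled SD comes
  from a uniform stream mapped through the chi-square quantile, so
  repeated calls on the same design reuse cached draws and adding a group
  leaves the others' draws unchanged. Equal variances are assumed (no
  Welch variant), as in standard usage.
- **Two-way ANOVA** (type-II) with Šidák-adjusted cell-mean contrasts,
  p_adj = 1 − (1 − p)^m; requires a complete factorial layout.
- **Log-rank**: Mantel-Cox chi-square with 1 df via `lifelines`; the test
  suite checks it against a hand-tabulated hypergeometric worked example.
- **ROUT-like screen** (constant model only, hence "ROUT-like"): residuals
  from the median, robust scale = 68.27th percentile of |residuals| with
  an n/(n−1) small-sample correction, two-sided t(n−1) p-values screened
  by BH at Q = 1%. The study applies outlier removal to group scalars
  only, so the full robust-nonlinear-regression form is not implemented.

## Synthetic data: what it emulates, and what it does not

Generators are pure functions of their configs (single explicit seed,
default 0).

**LFP**: white or 1/f ("pink", by deterministic spectral shaping) Gaussian
noise plus sinusoidal bursts under a flat-top raised-cosine (Tukey,
taper 0.25) envelope whose peak is `event_amplitude_factor` × baseline SD.
The flat top is deliberate: the detection rule measures the time the
envelope stays above threshold, and a fully tapered (Hann) envelope of a
nominal 150 ms burst exceeds a 3× threshold for only ~70 ms, which would
make nominal-duration events undetectable by construction. Carriers are
drawn uniformly from the configured band shrunk by a spectral-leakage
margin of 1.5/T Hz per edge (capped at 45% of the band width), keeping
≥ 80% of burst power inside the nominal band even for 150 ms events.
Events are placed by rejection sampling with a 0.5 s minimum gap. Real
polyspiking morphology (sharp spike trains, after-discharges, amplitude
drift) is not modeled; passing detection tests demonstrates correctness of
the stated amplitude/duration rule, not robustness to every real-world
waveform. Baseline noise statistics of real recordings are unreported;
defaults are chosen for testability.

**Counts**: NB(μ, α) via the gamma-Poisson mixture, variance = μ + αμ²,
default dispersion 0.05, three genotypes × 4 replicates, library sizes
uniform in [0.8M, 1.2M] so that 2000 genes average ~500 counts. Planted
genes (fraction `frac_de`, alternating signs, default |log2FC| = 2) scale
the last group's means; means are renormalized to the library size, which
reproduces the compositional bias real library-size normalization must
absorb. Gene-gene correlation and sample-level batch effects are not
simulated.

**Reference**: planted opposing compounds shift the signature's up-genes
by −3 (z-score-like units) and down-genes by +3 (matching compounds the
reverse) on top of N(0, noise_sd) noise; other compounds are pure noise.
Mechanism labels cycle through realistic classes, with blocklisted
classes landing on neutral compounds so exclusion logic is exercised.

**Survival**: deaths uniform on integer days within a group's window,
otherwise censored alive at follow-up (default 10 days, mirroring the
homozygous-death-at-8–10-dpf design).

## Problem sizes

Default test and acceptance runs use 20–120 s traces, 1500–2000 genes,
50-compound references and 90-subject survival arms — sizes at which every
planted effect is comfortably recoverable while the full suite runs in
seconds. The pipeline itself has no size-dependent logic; production runs
simply pass larger configs.

## Known limitations

- The DE surrogate does not reproduce shrinkage-based effect estimates;
  its fold changes are raw group-ratio estimates and its padj ordering can
  differ from the published tool's near the significance boundary.
- Connectivity scores are comparable within one reference matrix only;
  the max-|raw| normalization makes cross-run score comparisons
  meaningless without a fixed corpus.
- The Dunnett adjustment is Monte-Carlo: adjusted p-values carry ~±0.005
  noise (seeded, hence reproducible).
- GCT support covers the v1.3 text layout with genes as rows; row-metadata
  columns are skipped on read and not written.
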