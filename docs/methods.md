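# Methods

This note documents the statistical models behind `dmhprep`, the
defaults and why they were chosen, what the synthetic-data generator
does and does not emulate, and the numerical decisions that a user
re-implementing or auditing the package would want spelled out.

## 1. Internal control probes from restriction logic

The DMH protocol digests fragments at the HpaII/HinP1I sites `CCGG` and
`CGCG`; a fragment is retained for hybridization iff every site it
carries is methylated (vacuously for site-free fragments).  A probe
whose surrounding window contains no recognition site therefore
receives the same material in test and reference channels, making its
theoretical log-ratio M = 0 — a protocol-intrinsic negative control.

Decisions:

* **Window L = 900 bases** centered on the probe (L/2 each side),
  reflecting 400–500 bp sonication fragments reaching the probe from
  either side.  `L` is a parameter; the package does not attempt to
  derive it from other fragment-length protocols.
* **Single-strand scan.** Both default motifs are reverse-complement
  palindromes, so scanning one strand is complete.  Users configuring
  other enzymes must supply both strands' motifs (documented on
  `find_recognition_sites`).
* **Overlapping occurrences all count** — any unmethylated occurrence
  can be cut.
* **Boundary rule:** a motif counts only if all four bases lie inside
  the window; windows truncated at chromosome ends are scanned over
  their available extent.
* **Probe center** = `floor((start + end) / 2)` in 0-based half-open
  coordinates, deterministic for odd-length probes.
* **N bases never match**, so an N-rich window can still qualify as a
  control; this is the permissive choice and is configurable.

## 2. Background correction

Five methods: `none`, `subtract`, `edwards`, `normexp`,
`normexp_offset`.

* **Edwards.** `f − b` when `f − b > d`, else the smooth positive
  completion `d·exp(1 − (b + d)/f)` — the unique monotone completion
  continuous at the threshold.  The threshold `d` defaults to the 10th
  percentile of the channel's positive `f − b` differences
  (data-adaptive, strictly positive, user-overridable).  Where the
  exponential underflows (b ≫ f) the result is clamped to the smallest
  positive float rather than 0, preserving positivity.
* **Normexp.** `X = S + B`, `S ~ Exponential(mean α)` independent of
  `B ~ N(μ, σ²)`, fitted to `x = f − b` per channel per array (channels
  never pooled) by direct maximum likelihood over
  `(μ, log σ, log α)` (Nelder–Mead), initialized by method of moments
  (`E X = μ + α`, `Var X = σ² + α²`, third central moment `2α³`).  The
  returned likelihood is never below the initializer's.  The corrected
  intensity is the conditional mean
  `E(S | X = x) = m + σ·φ(m/σ)/Φ(m/σ)`, `m = x − μ − σ²/α`, with the
  Mills-type ratio evaluated in the log domain (`log_ndtr`), so the
  result stays finite and positive for arbitrarily negative `m/σ`.
  The fit agrees with the R/limma reference implementation to seven
  significant digits on shared data; at `σ/α = 0.05` the σ estimate is
  the weakly identified one, with median |relative error| ≈ 3.5% at
  n = 10,000 — an identifiability property of the model, not an
  optimizer artifact.
* **Offset.** `normexp_offset` adds `k = 50` to both channels,
  damping low-intensity log-ratio variance.

## 3. M/A values and normalization

`M = log2 R − log2 G`, `A = (log2 R + log2 G)/2`; cells with `R ≤ 0` or
`G ≤ 0` are missing (relevant after plain subtraction) and are excluded
from all fits, passing through as missing.

Normalizations (all within-array): `none`; `global`
(`M − f_all(A)`); `control` (`M − f_ctrl(A)`, curve fitted on the
internal control probes only); `composite`
(`M − [a·f_ctrl + (1 − a)·f_all](A)` with `a(A)` the proportion of
biological-probe A values **strictly** below `A` — ties go to the
smaller weight).  The composite curve therefore tracks the control
curve at low intensity and the global curve at high intensity, and is
always pointwise between the two.

LOESS details:

* span 0.3, local degree 1, tricube weights, 3 bisquare robustness
  iterations — common two-color practice; all exposed as parameters.
* Degree 1 delegates to the compiled `statsmodels` lowess (with a small
  `delta` interpolation step, 0.5% of the A range); other degrees use a
  plain numpy local-polynomial implementation that also serves as an
  independent cross-check in the tests.
* The fitted curve is a linear interpolant between fitted points,
  extended **by its boundary value** outside the training domain.
  Control probes may not span the full A range and polynomial
  extrapolation is unstable, so constant extension is the conservative
  choice.
* Control/composite normalization requires ≥ 30 control probes with
  observed M on the array; fewer is an error naming the count.
* "Biological probes" for the global curve means every probe on the
  array, including the identified control probes.
* LOESS is not a projection: re-normalizing an already-normalized
  array moves each M by O(σ/√(span·n)) (≈ 4·10⁻³ at σ = 0.3,
  n = 2000), because the second pass re-smooths noise.  Exact
  idempotence is impossible for any linear smoother on noisy data; the
  test suite checks that the second-pass change is an order of
  magnitude below the first-pass change.

## 4. Island-level quantile-regression scoring

Per CpG island, at quantile level τ = 0.75,

    M_ap = array_a + probe_p + ε_ap ,

array and probe fixed effects, errors independent and distribution-free
with τ-quantile zero.  Identifiability: no intercept, free array
coefficients, probe effects constrained to sum to zero — so `array_a`
*is* the island-level 75%-quantile methylation signal of array `a`.
The check loss `Σ ρ_τ` is minimized **exactly** via the standard LP
formulation (HiGHS); exactness makes the brute-force loss-minimality
tests meaningful.  Islands with fewer than 3 probes, fewer than 2
arrays, or more than 20% missing cells are skipped and reported;
an all-missing array receives p-value 1.

**P-values.** One-sided Wald test of `H1: array_a > 0` (a flag gives
two-sided): `Cov(β) = τ(1−τ) s² (XᵀX)⁻¹` with the sparsity
`s = 1/f(F⁻¹(τ))` estimated by the Hall–Sheather difference quotient on
the residual quantile function, after dropping the residuals the LP
drives to exact zero (they sit at the fitted hyperplane and carry no
density information).  The reference distribution is Student-t with a
Satterthwaite-style effective df for the sparsity estimate: from
binomial quantile asymptotics of the difference quotient,
`cv² = [hi(1−hi) + lo(1−lo) − 2·lo(1−hi)] / (n (hi−lo)²)` and
`df = 1/(2·cv²)`.  This accounts for the sparsity-estimation error
that a plain normal reference ignores; without it the t statistic's
null variance is visibly inflated (≈ 1.06) and one-sided rejection
rates drift.  With it, the empirical type-I error at nominal 0.05 on
model-null islands drawn from the generator's own noise distribution
is 0.051–0.055 (6 probes × 26 arrays, 500 islands, several seeds).

Two caveats, both finite-sample properties of quantile regression with
~6 observations per array coefficient rather than implementation
choices: (i) calibration is error-shape dependent (pure Gaussian noise
is mildly conservative, strongly skewed noise mildly anticonservative,
both at the ±0.015 level); (ii) the "null" of this test is *zero 75th
percentile*, not zero mean — noise that is symmetric about zero has a
positive 75th percentile and genuinely triggers the one-sided test.
Consequently unmethylated islands accumulate nonzero scores on real and
simulated data alike; the housekeeping-gene selection rule
(score ≤ N/2 under every method) exists precisely because of this.

**Scores.** `n(island, p0) = #{a : p_a < p0}` over
`p0 ∈ {0.05, 0.04, 0.03, 0.02, 0.01}`, so `0 ≤ n ≤ N` and `n` is
non-decreasing in `p0`.

**Control-gene filters.** Housekeeping (negative-control) genes must
have exactly one associated island, ≥ 3 probes with ≥ 1 in the
promoter, and score ≤ N/2 under every supplied method/dataset.
Candidate methylated genes are excluded for: no island, < 3 probes,
no promoter/first-exon coverage, or multiple islands with none
designated primary.  Exclusions carry machine-readable reason codes.

## 5. Evaluation statistics

* `T.stat` is the Welch two-sample form
  `(mean_m − mean_hk)/√(var_m/N_m + var_hk/N_hk)` (sample variances,
  n − 1); a flag offers the pooled-variance alternative.
* `AUC`: ROC points at cutoffs `C0 = 0..N` ("methylated" ⇔ score ≥ C0)
  plus an appended (0, 0) point; trapezoidal area over points ordered
  by increasing FPR with ties broken by increasing TPR (deterministic
  area for tied points).  On integer scores this equals the
  Mann–Whitney U statistic normalized by `N_m·N_HK` with 0.5 tie
  weight, which the tests verify independently.
* The grid runner evaluates all 5 × 4 method combinations, scoring only
  the islands of the two control-gene groups; background corrections
  are computed once per background method (the offset variant reuses
  the normexp fit), a failing cell is logged and skipped without
  aborting the grid, and per-factor means (each normalization averaged
  over backgrounds and vice versa) are provided.

## 6. Synthetic data generator

The generator is the package's test bed; its defaults are the study
conditions everything else is verified under.

Layout: one synthetic chromosome; probe units (islands of
`probes_per_island` consecutive probes, and single control probes) are
interleaved in random order at 1000-base spacing, so the 900-base
windows of adjacent probes never overlap.  Control windows are scrubbed
of motifs (a motif base is replaced by `A`, which can participate in
neither motif); every island probe gets a `CCGG` planted 20 bases from
its center.  By construction `identify_control_probes` must recover the
planted control set exactly — a recovery the tests assert for many
seeds.  Each island's first probe is promoter-flagged.

Intensities, per probe and array:

* true signals are exponential with mean α = 1000, coupled across
  channels by a Gaussian copula with ρ = 0.95 — marginals stay exactly
  exponential (so background-subtracted intensities follow the normexp
  convolution, which a KS test verifies) while the log-ratio carries
  realistic heavy-tailed, intensity-dependent noise (M sd ≈ 0.6,
  wider at low A);
* methylated islands multiply the red-channel signal by `2^delta`
  (default delta = 1, a two-fold effect) on a
  Bernoulli(prevalence = 0.7) subset of arrays (at least one);
* per-probe dye affinity (sd 0.08 in log2, split ± between channels)
  gives island probes stable probe effects; control probes get exactly
  zero, honoring their defining property;
* foreground = signal + `N(100, 50²)` noise; the separate background
  columns are `N(50, 10²)`; negatives are redrawn, keeping
  distributions clean near zero;
* dye bias is applied to the *measured* fluorescence: half to each
  channel in log space as a smooth polynomial
  `c(A) = 0.4 − 0.1(A−10) + 0.02(A−10)²` of the measured A, so A is
  preserved exactly while M picks up the curve.  Magnitude (~0.4–1
  across the A range) is a typical two-color bias; nothing in the
  emulated study quantifies its real shape.

Preset scales mirror the emulated study designs: 26 arrays / 32
methylated genes ("ovarian") or 40 / 30 ("breast"), 47 housekeeping
genes, 199 control probes, plus 40 unlabelled islands; genes map 1:1 to
islands.  Everything is a pure function of (config, seed).

What the generator does **not** emulate — and what passing tests
therefore cannot show about real data: spatial artifacts and print-tip
structure, copy-number variation (which can shift control-probe ratios),
probe-sequence effects (GC/affinity correlated with genomic context),
island-size heterogeneity, and between-array batch structure.  At the
default effect size the method grid separates the two gene groups
almost perfectly (AUC ≈ 0.95 even unnormalized); the grid comparisons
here are qualitative orderings, not quantitative performance claims.

Null islands for calibration testing are *not* raw delta = 0 output:
the test's null is a zero 75th percentile, so
`simulate_null_island_blocks` draws errors from the generator's M-noise
distribution recentred at its 75th percentile and adds centred probe
effects — data that satisfy the scoring model's H0 exactly while
keeping the realistic noise shape.

## 7. Interface notes

* Feature-table column names default to
  `{ProbeName, rMeanSignal, gMeanSignal, rBGMeanSignal, gBGMeanSignal}`
  and are fully remappable (`dialect=`), since scanner exports vary;
  whether mean or median per-probe summaries are used is the caller's
  choice via the same mapping.
* Coordinates are 0-based half-open (BED) everywhere internally.
* Negative or missing raw intensities are rejected at read time rather
  than clamped — the background methods define their own handling of
  small values.
* Method-id vocabulary on the CLI matches the comparison grid:
  `--bg {none, sub, edwards, normexp, normexp50}`,
  `--norm {none, loess, control, composite}`.
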