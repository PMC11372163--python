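# Methods

This note documents the models and estimators implemented in `biqpc`, the
defaults and why they were chosen, the numerical choices that matter, and the
limits of what the synthetic benchmark can show.

## The three-channel multiplier model

Channels are generated per epoch ν of duration `epoch_duration` seconds at
sampling rate `fs`:

    X1(t, ν) = I1(t, ν) + ξ1(t, ν)          I1 = 2·asin(sin(2π F1 t + ω1(ν)))
    X2(t, ν) = I2(t, ν) + ξ2(t, ν)          I2 = ±1 square wave at F2
    X3(t, ν) = W·X1·X2 + I3(t, ν) + ξ3(t, ν)   I3 = cos(2π F3 t + ω3(ν))

with each phase ω_i(ν) drawn independently per epoch from Uniform[0, 2π) and
ξ_i i.i.d. N(0, 1). The triangular wave ranges over [−π, π] (variance π²/3),
the rectangular over {−1, +1} (variance 1), the cosine over [−1, 1]
(variance ½); triangular and rectangular carriers hold only odd harmonics
(power ∝ n⁻⁴ and n⁻² respectively), giving the inputs a spread spectrum
closer to physiological signals than pure tones. The instantaneous product
`W·X1·X2` injects quadratic phase coupling at the bifrequency (F1, F2): the
sum- and difference-frequency lines of the product carry the summed phases.

Defaults are the study conditions: `fs = 100 Hz`, 5-s epochs, 128 epochs
(64 000 samples), `noise_sd = 1`, carrier set
{70/2π, 80/2π, 120/2π, 150/2π, 230/2π, 50 − 10/2π} Hz and couplings
W ∈ {0.025, 0.05, 0.075, 0.15, 0.3, 0.75}. `F3` must differ from F1, F2 and
F1 + F2 so the output carrier does not mask the interaction products
(overridable for exploration). Seeding: a master `SeedSequence` spawns one
child per epoch, so records are bit-reproducible and any epoch's realization
is independent of `n_epochs`.

### Analytic and empirical SNR

The signal-to-noise ratios of the channels have closed forms:
`SNR_X1 = π²/3`, `SNR_X2 = 1`, `SNR_X3 = (2π²/3 + 2)·W² + ½` (all of the
product term counts as signal in the analytic expression). The empirical
estimator works per epoch by **harmonic regression**: each epoch is
least-squares-projected onto sine/cosine pairs at the channel's declared
harmonic frequencies — odd harmonics of the carrier folded (aliased) into
(0, Nyquist), truncated at order 19 (triangular) / 199 (rectangular), plus
the `n F1 ± m F2` product lines for the output channel when W > 0; lines
closer than half the epoch's Rayleigh resolution are merged. Noise power is
the residual variance corrected for the regression degrees of freedom; signal
power is the fitted power minus the noise absorbed by the fitted parameters.
This construction is free of the leakage bias that a periodogram-bin
estimator suffers when dense aliased harmonics sit between grid bins, and it
reaches the analytic limits of the input channels within Monte-Carlo error.

Because the estimator books the *broadband* part of `W·X1·X2` (carrier×noise
and noise×noise cross terms) as noise while the analytic value counts it as
signal, the empirical SNR of X3 falls below its analytic value as W grows.
The ratio of the two — the **SNR efficiency** — is below 1 in ≈97 % of the
grid conditions and decreases with W; this is a property of the estimation
problem, not an estimator defect, and makes the specificity indices
conservative.

## Spectral estimation

Welch segmentation slides 50 %-overlapping windows of one epoch length
(500 samples) across the merged record: 255 segments for the defaults
(`(64000 − 500)/250 + 1`), optionally confined within epochs. Each segment
is standardized (mean 0, variance 1) and transformed **without a taper**;
the per-epoch phase randomization already decorrelates segments, and the
estimator stack is deliberately the simplest consistent one.

The bispectral grid spacing is the fractional power of two closest to the
experimental resolution `fs/segment_length` (0.2 Hz → **Δf = 0.25 Hz**, ties
toward the smaller power), realized by truncating each segment to
`dft_length = fs/Δf = 400` samples. Frequencies are bin centers at integer
multiples of Δf; sum frequencies beyond the Nyquist bin use the
conjugate-symmetric (aliased) DFT coefficients.

Cross-spectrum, cross-bispectrum and cross-bicoherence are segment averages:

    C_ij(f)        = ⟨X̃_i(f) X̃_j*(f)⟩
    B_ijk(f1, f2)  = ⟨X̃_i(f1) X̃_j(f2) X̃_k*(f1+f2)⟩
    b²_ijk(f1,f2)  = |⟨X̃_i(f1) X̃_j(f2) X̃_k*(f1+f2)⟩|²
                     / (⟨|X̃_i(f1) X̃_j(f2)|²⟩ ⟨|X̃_k(f1+f2)|²⟩)

The normalization places the sample average inside the squared magnitude of
the numerator and leaves plain second-moment averages in the denominator;
Cauchy–Schwarz then bounds b² in [0, 1], and under a linear Gaussian null
`2L·b²` is asymptotically χ² with 2 degrees of freedom for L *independent*
segments (null mean 1/L). (Putting the average of |B|² in the numerator
instead would break the unit bound — a two-segment counterexample reaches 2.)
With 50 %-overlapping segments the nominal-L null is inflated by ≈10 %
(fitted null mean ≈2.2 on the 2L scale instead of 2), which is exactly what
the empirical-null fit below absorbs.

The bifrequency square (0, f_Nyq]² is partitioned into sectors
Q_I (f1+f2 ≤ f_Nyq, boundary included), Q_II (above, f1 > f2) and Q_III
(above, f1 ≤ f2); interactions whose sum frequency exceeds Nyquist alias
into Q_II/Q_III. The single corner bin whose sum folds onto DC is excluded
from the usable domain.

## Significance: empirical-Bayes FDR

The grid's b² values are modeled as a two-class mixture
`F = p0·F0 + (1 − p0)·F_A` on the χ²-scale statistic `x = 2L·b²`, with the
null F0 a scaled χ²₂ (exponential). The statistic is histogrammed at bin
width Δ = 0.001; for the fit the histogram is aggregated into blocks such
that the bulk spans ≈150 blocks (stable Poisson counts), the mode is located
on 3-block smoothed counts (ties to the smaller statistic), the null scale
is initialized from the mode's half-maximum width and refined by iteratively
reweighted log-linear regression over the modal bulk `[mode, mode + 2.5·m̂]`,
and p0 follows from the regression intercept, constrained to [0, 0.9]. A
mode at the histogram's right edge falls back to the theoretical χ²₂ null
with a warning. Right-tail FDR q-values compare the fitted null survival to
the empirical survival (`q(x) = min over thresholds ≤ x of
p0·n·S0(t)/#{x ≥ t}`), enforced monotone non-increasing in the statistic;
the significance map keeps b² at bins with q < 0.05 (threshold exposed) and
zeros elsewhere. The p0 recovery was validated on synthetic mixtures
(±0.02 at true p0 ∈ {0.5, 0.7, 0.9}); pure-null maps yield essentially no
discoveries.

For bootstrap p-values (the Granger arm) the package provides Storey-type
q-values with `π0 = #{p > 0.5}/(0.5·n)` and the pFDR variant (conditioning
on at least one discovery by dividing by `1 − (1−p)^n`; a p of exactly 0 has
q = 0, the limit value). When the p-value sample variance falls below 1e−10
the Benjamini–Hochberg procedure (π0 = 1) is used as the conservative
fallback.

## R_BQPC

The neighborhood of interest `G(f1, f2; d)` holds grid bins whose centers lie
in `[f1−d, f1+d] × [f2−d, f2+d]`, clipped to the sector of (f1, f2) (so
G ⊆ Q by construction; the sector-wide denominator includes G's own bins);
`d = 0` selects the single nearest bin. Default `d = 0.5 Hz` — at
Δf = 0.25 Hz a 5×5-bin box when the carriers sit on bin centers — matching
the tolerance a real recording's frequency drift requires. R_BQPC is the
ratio of the significant-b² sums over G and over Q; a 0/0 case is reported
as a distinct *undefined* flag (never coerced to 0), and exact 0 or 1 ratios
are flagged so aggregation can exclude boundary outcomes.

## Bivariate spectral Granger causality and R_GQPC

The driver is the point-wise product `U(t) = X_i(t)·X_j(t)`; the target is
`X_k`. The VAR order is selected once on the full standardized record by the
Schwarz criterion with `lag_max = 50`, relaxed against overfitting: the
smallest order whose SC lies within 5 % of the minimum on the |SC| scale
(`SC(l) ≤ SC_min + 0.05·|SC_min|`, well defined for either sign and never
exceeding the argmin). On every Welch segment (500 samples, standardized) a
bivariate VAR of that order is fitted by OLS (tiny ridge 1e−10 for
conditioning; singular segments are skipped, more than half skipped is an
error) and Geweke's decomposition evaluated on the Fourier grid of the
*experimental* resolution (0.2 Hz, 249 frequencies in the open band): with
transfer function H = (I − ΣA_m e^{−iωm})⁻¹ and residual covariance Σ,

    f_{U→Y}(ω) = ln( S_yy(ω) / (|H̃_yy(ω)|² Σ_yy) ),
    H̃_yy = H_yy + (Σ_yx/Σ_yy)·H_yx,

non-negative by construction. The **median across segments** is the BGCS.
For one-directional systems the band-average of the spectrum equals the
time-domain log-variance-ratio statistic (verified to 0.3 % on VAR(2)
systems; with feedback the integral is a lower bound, which is Geweke's
inequality, not an implementation error).

**Bootstrap significance.** The default null is a *prominence* test in the
spirit of the method's reference implementation: the full bivariate VAR
fitted to the whole record is resimulated `nboots` times from jointly
resampled residual pairs (coefficients shrunk to spectral radius < 0.999 if
needed; 20·lag burn-in), the median BGCS is recomputed per draw, and the
p-value at f is the fraction of draws in which BGCS(f) does not exceed the
draw's spectrum-wide median — small p means f carries consistently prominent
causal mass. p-values are raw proportions (0 attainable), q-values Storey
pFDR as above. `θ` — the smallest median-BGCS value among q < 0.05
frequencies — is then applied as an **amplitude threshold to the whole
spectrum**: every frequency with BGCS ≥ θ carries significant mass (the
"dashed line" reading: the significant region is the part of the curve above
θ). With no q < 0.05 frequency, θ and the index are undefined (flagged). A
global no-causality null (target resimulated from its own reduced
autoregression, point-wise comparison with the observed spectrum) is
available as `null_model="reduced"`; it is far more conservative — isolated
causal peaks spanning fewer than ~15 of the 249 frequencies cannot survive
the FDR step at any attainable bootstrap p-value — and is kept for
sensitivity analysis rather than as the default.

`nboots` follows the resolution rule `round(√Δf_exp × 1000)` (447 at
0.2 Hz); fewer than 100 draws triggers a reduced-precision warning. The
bootstrap is calibrated on independent channels (no discoveries across
replicate null runs) and detects planted coupling at W = 0.3 in ≥ 90 % of
replicates at a fraction of the full scale (16 epochs, 200 draws).

The spectral interval of interest is centered at f1 + f2 when the sum is
below Nyquist and at the fold-back `fs − (f1 + f2)` otherwise (the aliased
image; a literal `f_Nyq − (f1+f2)` would be negative for typical above-band
sums), with half-width 2d, clipped to (0, f_Nyq). R_GQPC is the ratio of the
significant-BGCS sums over the interval and over the full band, with the
same undefined/0/1 flagging as R_BQPC. Note the product process also carries
the *difference* frequency |f1 − f2|; its causal peak is genuine but lies
outside the interval of interest, which is one reason R_GQPC sits below
R_BQPC even at weak coupling.

## The batch study

Conditions enumerate unordered carrier pairs ordered F1 ≥ F2 (so above-band
interactions land in Q_II) with every admissible F3; for the default carrier
set this yields **58 conditions per coupling** (two pairs, 70/2π + 80/2π =
150/2π and 80/2π + 150/2π = 230/2π, have their sum inside the set and lose
one F3 choice). Per-condition seeds derive from one master seed at
enumeration time, so results are identical for any execution order or worker
count (verified). Aggregation takes per-coupling medians of R_BQPC, R_GQPC
and the SNR efficiency after excluding flagged (undefined/0/1) rows.

Observed behavior on the defaults: the R_BQPC median at W = 0.05 is ≈0.50
and falls monotonically for stronger coupling (≈0.2 at W = 0.3, ≈0.1 at
W = 0.75) as incidental discoveries spread along the carrier axes; R_GQPC
medians decrease with W and sit below R_BQPC at every coupling; the SNR
efficiency is below 1 in ≈97 % of conditions and decreases with W. At the
weakest coupling (W = 0.025) the bicoherence arm leaves ~40 % of conditions
undefined or at the ratio-1 boundary; the median over the *surviving*
conditions is high, so the rising branch of the median-vs-W curve depends
strongly on the exclusion rule and is not a robust feature of the reduced
reproduction.

## Problem sizes used in the shipped checks

The test suite and acceptance script run on one CPU in minutes by scaling
down where the full protocol is expensive while keeping the estimator
structure intact: the SNR recovery uses 20 replicates of the full 128-epoch
record; the bicoherence-arm medians use the full 58-condition grid at full
record length; the Granger-arm medians use every 5th condition pair, three
couplings (0.025, 0.150, 0.750), 64 epochs and 200 bootstrap draws (the full
grid at the 447-draw rule is a multi-day computation); calibration and power
checks use 16–50 epoch records. The methods themselves carry no
scale-dependent switches. One caveat of the reduced Granger scale: bootstrap
granularity (p-values no finer than 1/200) raises the significance threshold
θ and narrows the significant set, which inflates R_GQPC — most strongly at
couplings whose causal structure is only borderline prominent — so the
reduced median-vs-coupling curve need not be monotone even though the
full-scale curve is.

## What the benchmark does and does not show

The generator provides ground truth with stationary carriers, i.i.d.
Gaussian noise, exactly per-epoch-randomized phases and a purely
instantaneous quadratic interaction. Passing these checks shows the
estimator stack is correct and well calibrated under those assumptions. It
does not establish performance under colored or non-Gaussian noise,
drifting carriers, non-stationary coupling, volume conduction/mixing between
channels, or interactions with transmission delays — all present in real
electrophysiological data. The indices also inherit the resolution limits of
the segmentation: carriers closer than Δf to each other or to a sector
boundary are not resolvable, and the sector clipping of G can asymmetrize
the neighborhood for bifrequencies near a boundary.

## Known limitations

- The two-class mixture constrains p0 ≤ 0.9; on maps that are almost purely
  null the cap makes q-values mildly anti-conservative relative to p0 = 1
  (discoveries remain essentially absent in null calibration runs).
- The prominence bootstrap tests "consistently above the spectrum's typical
  level", not "nonzero causality"; a spectrum with genuinely uniform causal
  mass would show nothing prominent. That is the intended reading of the
  threshold-θ construction, but it differs from a pure no-causality test
  (available as `null_model="reduced"`).
- `θ` is computed from the median spectrum's bootstrap, not as a median of
  per-segment thresholds; a per-segment bootstrap would multiply the cost by
  the segment count without changing the thresholded statistic.
- VAR orders selected on the multiplier model's records are large (≈20–30);
  the SC relaxation keeps them below the argmin but the per-segment fits at
  500 samples then estimate 4·lag parameters from ~470 rows — the regularity
  limit of the per-segment framing, mitigated by the median across segments.
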