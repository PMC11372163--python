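# biqpc

Detection of **specific quadratic phase coupling (QPC)** in trivariate time
series, by cross-bicoherence with empirical-Bayes FDR significance and by
bivariate spectral Granger causality with bootstrap significance.

## The problem

When two oscillatory signals at frequencies f1 and f2 interact through a
quadratic (multiplicative) nonlinearity, the output carries a component at the
sum frequency whose *phase* equals the sum of the constituent phases. Such
quadratic phase coupling is a hallmark of nonlinear interaction in neural
recordings (EEG/MEG/LFP), but estimators of it also light up at incidental
bifrequencies — noise components, carrier harmonics, aliased products — and
the stronger the coupling, the more spurious detections appear. The question
this package addresses is therefore not merely "is there QPC?" but **"how
specific is the detected QPC to the bifrequency where the physics puts
it?"**

Two specificity indices answer that, each in [0, 1]:

- **R_BQPC** — the fraction of significant cross-bicoherence
  `b²(f1, f2)` that falls inside a small neighborhood `G(f1, f2; d)` of the
  carrier bifrequency, relative to all significant bins in the containing
  sector `Q(f1, f2)` of the bifrequency plane:

  `R_BQPC = Σ_{G} b̄²(g1, g2) / Σ_{Q} b̄²(g1, g2)`

- **R_GQPC** — the fraction of significant bivariate Granger-causal mass
  `BGCS(f)` (from the product process `X1·X2` to `X3`, Geweke's
  frequency-domain decomposition) that falls inside the spectral interval
  `[(f1+f2) − 2d, (f1+f2) + 2d]` around the (possibly aliased) sum frequency:

  `R_GQPC = Σ_{interval} BGCS̄(f) / Σ_{(0, f_Nyq)} BGCS̄(f)`

Values near 1 mean the detected coupling is exactly where it should be.

The package ships the three-channel benchmark generator used to score the two
estimators: a triangular carrier (X1) and a rectangular carrier (X2), each in
unit Gaussian noise, feeding a noisy multiplier channel
`X3 = W·X1·X2 + cos-carrier + noise`, with per-epoch uniform random phases.
The analytic signal-to-noise ratios of the three channels
(`π²/3`, `1`, `(2π²/3 + 2)W² + ½`) give an exact yardstick for the empirical
SNR estimator and the *SNR efficiency* of the output channel.

## Worked example

```python
import numpy as np
import biqpc as bq

F1, F2, F3 = 120/(2*np.pi), 70/(2*np.pi), 80/(2*np.pi)   # ~19.1, 11.1, 12.7 Hz
cond = bq.ConditionSpec(F1=F1, F2=F2, F3=F3, W=0.05, n_epochs=128, seed=3)
series = bq.simulate_condition(cond)                      # 3 x 128 x 500 samples

plan = bq.SegmentPlan(fs=100.0, segment_length=500)       # delta_f = 0.25 Hz
spectra = bq.segment_series(series, plan)                 # 255 Welch segments
bmap = bq.cross_bicoherence(spectra, 0, 1, 2)
fit = bq.fit_null_mixture(bmap.values_in_domain(), bmap.n_segments)
sig = bq.significance_map(bmap, fit)                      # q < 0.05 mask
nbhd = bq.neighborhood_bins(F1, F2, 0.5, bmap.grid)
res = bq.r_bqpc(sig, nbhd)
print(f"R_BQPC = {res.ratio:.4f} ({res.numerator:.3f} / {res.denominator:.3f})")
```

prints

```
R_BQPC = 0.4994 (0.861 / 1.724)
```

i.e. at weak coupling (W = 0.05) roughly half of the significant bicoherence
mass in sector Q_I sits inside the ±0.5 Hz neighborhood of the true carrier
bifrequency — the remainder is incidental detections along the carrier axes.
The same condition run through the Granger arm (`bq.bgcs`,
`bq.bootstrap_significance`, `bq.r_gqpc`) yields a smaller ratio: the
bispectral index is consistently the more specific detector, which is the
central comparative finding the batch study (`bq.run_study`) reproduces
across the full condition grid.

A command-line interface mirrors the library:

```
biqpc simulate  --f1 19.1 --f2 11.1 --f3 36.6 -w 0.05 --seed 3 --out run/
biqpc qpc       --f1 19.1 --f2 11.1 --f3 36.6 -w 0.05 --seed 3 --out run/
biqpc granger   --f1 19.1 --f2 11.1 --f3 36.6 -w 0.05 --seed 3 --out run/
biqpc study     --couplings 0.05 --no-gc --out study/
```

All outputs are plain TSV with a YAML manifest, reproducible bit-for-bit
from the recorded seed.

## Layout

| module | contents |
| --- | --- |
| `biqpc.signal_model` | three-channel simulator, analytic + empirical SNR |
| `biqpc.spectral` | Welch segmentation, cross-spectra, cross-bispectra, cross-bicoherence, sector geometry |
| `biqpc.fdr` | empirical-Bayes two-class mixture fit, q-values (Storey pFDR / BH) |
| `biqpc.qpc_bispec` | neighborhood of interest, R_BQPC |
| `biqpc.gc_spectral` | VAR lag selection, Geweke spectra, bootstrap significance, R_GQPC |
| `biqpc.study` | condition-grid enumeration, batch runs, per-coupling medians |
| `biqpc.config` / `biqpc.io` / `biqpc.cli` | YAML config, TSV round-trips, `biqpc` CLI |

See `docs/methods.md` for the estimation details, numerical choices and known
limitations.
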