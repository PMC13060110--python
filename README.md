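# swcapacity

Time-resolved **directed effective connectivity** for multi-ROI neural time
series, measured as the **information channel capacity** of a fitted
communication channel between two regions.

Functional connectivity (sliding-window correlation) tells you whether two
brain regions fluctuate together; it says nothing about direction.
`swcapacity` instead models the influence of a sender region *x* on a
receiver region *y*, within each sliding window, as a finite-impulse-response
(FIR) channel with additive white Gaussian noise:

```
y_t = a_0 x_t + a_1 x_{t-1} + ... + a_{k-1} x_{t-k+1} + w_t ,   a_j >= 0
```

Signals are standardized to zero mean and unit RMS, the nonnegative taps
`a` are the NNLS maximum-likelihood estimate, the noise power is the mean
squared residual, and the channel memory `k` is chosen per window by an
information criterion (AIC / BIC / AICc).  The connectivity measure is the
channel's **water-filling capacity**: with equivalent-input-noise spectrum
`S_EIN(f) = sigma^2 / |H(f)|^2` and a unit sender-power budget,

```
C = ∫ over [0, 1/2] of  [ log( lambda / S_EIN(f) ) ]_+  df ,
1/2 = ∫ over [0, 1/2] of  [ lambda - S_EIN(f) ]_+  df ,
```

evaluated on an N-point DFT grid by sorting the EIN values and growing the
active set until the water level `lambda` falls below the next bin.
Alongside capacity, every window also yields the prediction-correlation
(SWpC, `corr(y, X a)`), the plain sliding-window correlation (SWC), and the
connection duration (`k` in TRs — the effective channel memory).

The package is for researchers analyzing ROI-level fMRI, LFP band-limited
power, or wide-field calcium time series who want a directed, dynamic,
information-theoretic connectivity measure plus the statistical machinery
to vet it: task-sensitivity testing (CV filter, right-tailed paired t-tests,
BH-FDR), resting-state directionality-specificity testing (directional
asymmetry vs scan-to-scan variability, left-tailed Wilcoxon signed-rank),
bootstrap cross-modal correspondence, and k-means brain-state clustering
with WCSS-elbow model selection and permutation centroid alignment.

## Worked example

```python
import numpy as np
from swcapacity import (OrderSelectionConfig, plan_windows, sliding_capacity)
from swcapacity.simulate import ChannelSimSpec, simulate_pair

# ground truth: y receives x through taps (0.8, 0.4) with unit noise
ts = simulate_pair(ChannelSimSpec(taps=(0.8, 0.4), noise_sd=1.0,
                                  length=600, seed=7))
plan = plan_windows(ts.n_samples, length_samples=50, step_samples=10)
cfg = OrderSelectionConfig(criterion="BIC", k_max=4)

fwd = sliding_capacity(ts.values[0], ts.values[1], plan, cfg, grid_size=1024)
bwd = sliding_capacity(ts.values[1], ts.values[0], plan, cfg, grid_size=1024)
print(f"windows: {plan.n_windows}")
print(f"capacity x->y: {np.nanmean(fwd.capacity):.3f} nats")
print(f"capacity y->x: {np.nanmean(bwd.capacity):.3f} nats")
print(f"median duration x->y: {np.nanmedian(fwd.duration_trs):.0f} TR")
print(f"mean SWpC x->y: {np.nanmean(fwd.pcorr):.3f}")
```

prints

```
windows: 56
capacity x->y: 0.279 nats
capacity y->x: 0.201 nats
median duration x->y: 2 TR
mean SWpC x->y: 0.624
```

The forward direction carries a clearly higher information rate than the
reverse one, and the selected memory matches the planted two-tap coupling:
the directed structure of the simulation is recovered.  (The reverse
direction is not zero because a one-lag channel can always exploit the
instantaneous correlation; genuine asymmetry appears through the memory.)

The same pipeline is available from the shell:

```bash
swcapacity simulate pair --taps 0.8,0.4 --length 600 --seed 7 --out data/
swcapacity connectivity data/pair-seed7.csv --tr 1.0 --out results/
swcapacity validate specificity results/*.windows.csv \
    --sender sender --receiver receiver --out reports/
```

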