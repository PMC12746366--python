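# downfield-mrs

Quantification of magnetization exchange between brain water and downfield
¹H-MRS resonances — the tryptophan (TRP) indole NH at 10.1 ppm and the NAD⁺
nicotinamide H2/H6/H4 protons at 9.3/9.1/8.9 ppm — from paired selective and
broadband saturation-recovery experiments at 7 T.

Downfield metabolite protons exchange magnetization with water, through
chemical exchange (labile TRP NH) or cross-relaxation (non-labile NAD⁺ ring
protons).  When water is saturated together with the metabolites (broadband
saturation), the metabolite longitudinal recovery is dramatically slowed
relative to metabolite-only (selective) saturation; the contrast between the
two recoveries quantifies the exchange.

## Models

**Apparent T₁ (Model 1).**  Each experiment's peak-amplitude recovery is fit
with the three-parameter law

    S(TS) = M₀ (1 − k e^(−TS/T₁,app))

where `k ∈ [0, 1]` is the saturation efficiency and `T₁,app` folds in the
exchange.

**Two-spin exchange (Model 2).**  Both experiments are fit simultaneously
with the Solomon/Bloch equations for metabolite (A) and water (B):

    dM_z,A/dt = −(M_z,A − M₀,A)/T₁,A − σ_AB (M_z,A − M₀,A) + σ_BA (M_z,B − M₀,B)
    dM_z,B/dt = −(M_z,B − M₀,B)/T₁,B − σ_BA (M_z,B − M₀,B) + σ_AB (M_z,A − M₀,A)

with `σ_BA = σ_AB · M₀,A/M₀,B`, water T₁ fixed at 1800 ms and
`M₀,B/M₀,A = (2·55 M)/(0.3 mM)`.  Selective saturation starts at
`(M₀,A(1−k_sel), M₀,B)`, broadband at `(M₀,A(1−k_b), M₀,B(1−k_b))`, with the
`k`s fixed from the Model-1 fits.  Free parameters `(T₁,A, σ_AB, M₀,A)` are
found by basin-hopping over bounded least squares.

Upstream of the models: multi-channel FIDs are apodized (5 Hz), aligned,
coil-combined with water-reference weights, and peak amplitudes are read out
by HSVD (Hankel SVD, 60 components) of the no-saturation scan followed by
fixed-basis complex linear regression of every saturation scan.  A synthetic
cohort generator emulates the whole acquisition so that every stage is
testable without scanner data.

## Worked example

```python
import numpy as np
from downfield_mrs import TwoSpinParams, two_spin_solve, fit_model1, fit_model2

# a tryptophan-like subject: corrected T1 = 600 ms, exchange rate 12 Hz
p = TwoSpinParams(t1_a_ms=600.0, sigma_ab_hz=12.0, k_sel=0.85, k_broad=0.85)
sel_ts = np.array([25., 50., 300., 600., 10000.])
broad_ts = np.array([500., 1000., 2000., 4000., 10000.])
sel = two_spin_solve(p, "selective", sel_ts)
broad = two_spin_solve(p, "broadband", broad_ts)

m1_sel = fit_model1(sel_ts, sel, "selective")
m1_broad = fit_model1(broad_ts, broad, "broadband")
print(round(m1_sel.t1_ms, 1), round(m1_broad.t1_ms, 1))
# 73.2 1799.7   <- apparent T1 (ms): exchange slows the broadband recovery ~25x

m2 = fit_model2(sel_ts, sel, broad_ts, broad, m1_sel.k, m1_broad.k, seed=0)
print(m2.summary())
# Two-spin exchange fit (selective + broadband)
# T1_A (corrected):     600.0 ms ...
# sigma_AB:             12.00 Hz ...
```

The selective recovery is governed by `1/T₁,A + σ_AB` (fast), the broadband
recovery is pinned to the water recovery (slow), and the simultaneous
two-spin fit recovers the generating parameters exactly on noiseless data.

A full synthetic cohort analysis:

```bash
downfield-mrs run --out results/ --seed 1       # simulate + process + fit + stats
```

writes tidy CSVs (`amplitudes.csv`, `model1.csv`, `model2.csv`,
`summary.csv`, `stats.csv`) with per-subject apparent T₁s, corrected T₁s and
exchange rates, cohort mean ± SD summaries, paired t-tests, and ANOVA/Tukey
comparisons across resonances.

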