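# stprf — spatiotemporal population receptive field modeling

`stprf` implements image-computable forward models of how visual-cortex
fMRI voxels respond to stimuli over *space and time*, together with the
machinery to validate them: stimulus rendering, BOLD synthesis with
calibrated noise, and a coarse-to-fine parameter solver. It is aimed at
visual-neuroscience researchers who want to simulate, fit, or
sanity-check spatiotemporal pRF analyses without a GPU.

A population receptive field (pRF) summarizes the region of visual space
driving a voxel's response. Classical pRF mapping fits a 2D Gaussian
(center x, y; size σ) to responses evoked by a bar sweeping the visual
field. `stprf` extends this with two models of *temporal* integration at
10 ms resolution, both sharing the Gaussian spatial stage
`spatialRF(X,Y) = exp(−((X−x)² + (Y−y)²)/2σ²)`:

- **CST** (compressive spatiotemporal): three channels — sustained
  (gamma impulse response, time constant τ), on- and off-transient
  (biphasic difference of gammas) — each rectified and compressed,
  `p_i(t) = [ReLU(h_i ⊛ drive)]^n` with n ∈ [0.1, 1]. BOLD is
  `β_sus (p₁ ⊛ HRF) + β_tran ((p₂+p₃) ⊛ HRF)`, downsampled to 1 s.
- **DN-ST** (delayed divisive normalization):
  `p(t) = |r|^n / (σ_DN^n + (|r| ⊛ e^{−t/τ₂})^n)` with
  `r = (t·e^{−t/τ₁}) ⊛ drive` — an onset transient that is divisively
  normalized by a delayed copy of its own drive.
- **Spatial**: the purely linear baseline.

The **synthesizer** generates ground-truth voxel populations and noisy
BOLD (white + physiological + drift noise calibrated to a target SNR in
dB), and the **solver** recovers parameters per voxel via grid search
plus bounded derivative-free refinement with GLM-estimated gains,
scored by `R² = 1 − Σ(model−data)²/Σdata²`. Closed-loop recovery — can
the solver get back what the synthesizer put in, at realistic noise? —
is the package's headline validation.

## Worked example

Simulate five CST voxels under the nine-run spatiotemporal mapping
design, solve the noiseless series, and score recovery (~1.5 min on one
CPU, most of it the grid bank):

```python
import stprf

seq   = stprf.spatiotemporal_sequence(n_runs=9, seed=0)
gt    = stprf.sample_ground_truth("cst", n=5, seed=3)
clean = stprf.synthesize_bold(gt, seq)                 # (1620, 5) at 1 s
fits  = stprf.solve_voxels(clean, seq, "cst", seed=0)
print(stprf.recovery_report(fits, gt).table.round(4))
```

```
       mape_pct  pearson_r  n_undefined
x        0.0001        1.0          0.0
y        0.0001        1.0          0.0
sigma    0.0000        1.0          0.0
tau      0.0001        1.0          0.0
n_exp    0.0001        1.0          0.0
```

`mape_pct` is the median absolute percentage error between estimated and
generating parameters, `pearson_r` the correlation between estimates and
ground truth across voxels: the solver recovers the generating
parameters essentially exactly from noiseless data (all five voxels at
R² = 1.0). Add noise before solving —

```python
noisy = stprf.add_noise(clean, stprf.NoiseSpec(target_snr_db=0.1),
                        seq.run_breaks // 100, seed=0)
```

— and at the validation scale (50 voxels per model) median errors rise
to ~4–7% for pRF centers and size and ~3% for the CST time constant
(the numbers `scripts/acceptance.py` recomputes; medians over only a
handful of voxels are much less stable, since percentage errors explode
for pRFs with near-zero coordinates).

The same pipeline is scriptable from the shell:

```bash
stprf synthesize --model cst --n 50 --snr-db 0.1 --seed 1 --out sim/
stprf solve --model cst --data sim/bold_noisy.tsv --seed 1 --out fits.tsv
stprf validate --model cst --n 50 --snr-db 0.1 --seed 1
```

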