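# scanfcs

Scanning fluorescence correlation spectroscopy (scanning FCS) analyses for
confocal raster and line scans, built around the question of how the
*Arabidopsis* transcription factor SHORTROOT (SHR) moves from the
vasculature into the endodermis, how its oligomeric state changes there,
and how its interaction with SCARECROW (SCR) shapes root patterning.

The package implements, as tested library code:

* **RICS** (raster image correlation spectroscopy): the spatial
  autocorrelation `G_S(ξ,ψ) = S(ξ,ψ)·G(ξ,ψ)` of a raster time series,
  fitted with the one-component 3D Gaussian scanning/diffusion model to
  extract diffusion coefficients; immobile-fraction removal by a 10-frame
  moving average; PSF calibration on dye solutions with D clamped to the
  free-EGFP value (78 µm²/s).
* **pCF** (pair correlation function): carpets
  `G(τ,δr) = ⟨F(t,0)F(t+τ,δr)⟩/(⟨F(t,0)⟩⟨F(t,δr)⟩) − 1` from 32-pixel
  line scans, an automated "arch" call (delayed cross-wall correlation vs
  a circular-shift null), and the binary Movement Index (MI) over pixel
  distances {5, 7, 9} and replicates.
* **N&B / cross-N&B** (number & brightness): per-pixel moment analysis
  `B = σ²/⟨k⟩`, `N = ⟨k⟩²/σ²`, S-factor background calibration (B = 1),
  monomer/homodimer cursor classification, and two-colour cross-variance
  `B_cc = σ_cc²/(⟨G⟩⟨R⟩)` with 1:1 vs 2:1 complex stoichiometry.
* **A six-variable ODE model** of SHR/SCR dynamics (vascular SHR,
  endodermal monomer/homodimer, SCR, 1:1 and 2:1 complexes) with
  measured transport rates `a = D/A`, a logistic SCR-dependent
  dimerisation switch `k2(C) = L/(1+e^{−k(C−C0)})`, Sobol total-effect
  sensitivity analysis (radial design, Jansen estimator), and calibration
  of {d2, K2D, L} against the imaging-derived compositions.
* **A Brownian-dynamics scan simulator** (3D Gaussian PSF, Poisson
  detection, cell-wall barriers with directional permeability, confined
  species, two-colour complexes) providing ground truth for every stage.

Everything runs on synthetic data generated in-package; no microscope
files are required. See `docs/methods.md` for models, estimators, study
designs and their limitations.

## Worked example

Recover a diffusion coefficient from a simulated raster series and
calibrate molecular brightness:

```python
from scanfcs import rics, nandb
from scanfcs.studies import rics_study, solution_scan_study

psf = rics.calibrate_psf(solution_scan_study(seed=0), fixed_D=78.0)
series = rics_study(D=2.45, seed=0)           # SHR-like mobility
filtered = rics.subtract_moving_average(series)
fit = rics.fit_diffusion(rics.compute_acf(filtered), psf, series.config)
print(f"w0 = {psf.w0:.3f} um, D = {fit.D:.2f} um^2/s, qc = {fit.qc_pass}")
```

prints (seed 0):

```
w0 = 0.250 um, D = 2.39 um^2/s, qc = True
```

i.e. the beam waist is recovered to three digits against the simulated
0.25 µm and the diffusion coefficient within ~2.5% of the simulated 2.45 µm²/s, with
the fit passing the residual QC rule (ACF peak ≥ 3× largest residual).

Calibrating the model against the imaging-derived compositions:

```python
from scanfcs import model, calibrate
fitted = calibrate.estimate_parameters(model.default_params())
print(fitted.achieved["homodimer_pct"], fitted.achieved["complex21_pct"])
```

```
7.500193438917231 15.199801401834973
```

— the calibrated wild-type steady state carries 7.5% SHR homodimer (of
endodermal SHR entities) and 15.2% 2:1 complexes (of all SHR-SCR
complexes), and settles between 18 and 24 h while SHR itself equilibrates
in under a minute.

The numbered drivers under `analysis/` run each stage end to end
(`01_simulate_scans.py` … `08_model_dynamics.py`) and write their tables
under `results/`.

## Command line

```bash
scanfcs simulate --out scan.tif --seed 1 -d 2.45
scanfcs rics scan.tif
scanfcs model --mode wildtype --tend 48
scanfcs calibrate --targets 7.5,15.2
```

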