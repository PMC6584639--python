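# kifquant

Quantitative analyses for single-molecule and cell-biological studies of
the kinesin-3 motor **KIF1C**, an autoinhibited, plus-end-directed organelle
transporter. Experiments on such a motor span several very different
measurement modalities — hydrodynamics, photobleaching, TIRF motility,
binding titrations and fluorescence-image quantification — and each needs
a small amount of bespoke numerics. This package implements those analyses
as a tested library, with seeded synthetic-data generators so every
estimator can be validated closed-loop against known ground truth.

It is written for motor-protein biophysicists and cell biologists who want
the quantification steps of such a study to be reproducible and testable
rather than buried in ad hoc scripts.

## What it computes

**Hydrodynamic sizing** (`kifquant.hydro`). Stokes radius from size-exclusion
chromatography via the calibration log₁₀ R_s = a·(V_e − V₀) + b, sedimentation
coefficient from glycerol gradients via S = a·v + b, combined through the
Siegel–Monty relation

    M = 4205 · R_s[nm] · S[Svedberg]   (Da)

and the frictional ratio f/f_min = S_max/S with S_max = 0.00361·M^(2/3),
which reports molecular shape (1 ≈ sphere, larger ≈ elongated). Errors
propagate from the calibration-fit standard errors and a half-fraction
peak-location uncertainty.

**Photobleaching stoichiometry** (`kifquant.bleachsteps`). Bleach steps are
counted by penalized change-point segmentation, and the step-count
histogram is fitted by maximum likelihood to a dimer/tetramer mixed
binomial

    P(k) = C(2,k) p^k (1−p)^(2−k) (1−x) + C(4,k) p^k (1−p)^(4−k) x

with x the tetramer fraction and p the fraction of active GFPs; fits are
conditioned on detection (k ≥ 1) by default because dark spots are
invisible in TIRF.

**Single-molecule motility** (`kifquant.motility`). Kymographs are traced
automatically (binarise → connected structures → per-frame blob assignment
to split crossing tracks → robust Theil–Sen line fits), events are
classified running (>25 nm/s) vs static, and per-microtubule statistics are
pooled: landing rate (events·µm⁻¹·min⁻¹), running frequency, mean speed,
and run length, including a censoring-corrected run-length estimate for
runs cut short by the microtubule plus end or the movie end. Vesicle-level
operations classify tracks as stationary below 1.5 µm total displacement
and count anterograde/retrograde flux through a location.

**Binding affinity** (`kifquant.binding`). Dissociation constants from
titration series via the quadratic (ligand-depletion) isotherm, with the
hyperbolic limit for vanishing receptor; plus microtubule-decoration
intensity with local background subtraction.

**Cell-image quantification** (`kifquant.cellimage`). Podosome counting
(threshold → 16-px minimal size filter → actin-coincidence check → optional
watershed cluster splitting) and tail-enrichment ratios
(I_tail − I_bg)/(I_cyto − I_bg) per channel, which are exactly invariant to
affine intensity rescaling.

**Synthetic data** (`kifquant.synthgen`) generates every input with known
ground truth: mixed-binomial bleach counts, noisy bleach traces, Poisson
motor landings rendered into kymographs through a Gaussian PSF, elution
peaks placed exactly on the calibration lines, quadratic-isotherm
titrations built with the standard twofold-dilution/4:1-mixing scheme, and
two-channel cell/podosome images. `kifquant.pipeline` and the `kifquant`
CLI orchestrate config-driven runs; `kifquant.stats` wraps the standard
group comparisons (t, Mann–Whitney, KS, ANOVA+Tukey; Bonferroni /
Holm–Šídák).

## Worked example

Fit the oligomeric state of a simulated population of 108 motors that is
88% dimer / 12% tetramer with 80% active GFP:

```python
from kifquant.synthgen import sim_bleach_counts
from kifquant.bleachsteps import fit_oligomer

hist = sim_bleach_counts(x=0.12, p=0.8, n_motors=108, seed=0)
print(hist.counts)
fit = fit_oligomer(hist)
print(round(fit.x_hat, 3), round(fit.p_hat, 3))
```

```
{1: 41, 2: 57, 3: 5, 4: 5}
0.121 0.736
```

Most spots show one or two steps (a dimer with partially active GFP), and
the 3- and 4-step tail pins the tetramer fraction: the fit recovers
x ≈ 0.12. A single histogram of 108 motors determines p less sharply
(here 0.74); over 250 replicate simulations the median estimates are
x = 0.119 and p = 0.797 (see `analysis/02_bleach_stoichiometry.py`).

The numbered scripts under `analysis/` run each analysis end to end on
synthetic data and write tables under `results/`:

```sh
python analysis/01_hydrodynamics.py      # Rs, S -> MW ~268 kDa, f/fmin 1.5 -> 1.9
python analysis/02_bleach_stoichiometry.py
python analysis/03_motility_roundtrip.py # kymograph round trip + landing-rate contrasts
python analysis/04_binding_kd.py         # Kd = 1 µM recovery
python analysis/05_cell_quantification.py
```

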