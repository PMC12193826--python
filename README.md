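# uteqmt

Quantitative ultrashort-echo-time (UTE) MRI biomarkers of the
**osteochondral junction (OCJ)** — the thin, collagen-rich interface between
deep articular cartilage and subchondral bone that is invisible on
conventional knee MRI because its T2/T2* relaxation times are far below
ordinary echo times. Degeneration of this layer is an early event in knee
osteoarthritis (OA), and short-TE quantitative imaging can measure it.

The package implements the full biomarker chain for a UTE knee exam and the
cohort analysis around it:

* **Macromolecular fraction (MMF)** from two-pool magnetization-transfer
  (MT) modeling of a 15-point saturation grid (3 MT flip angles × 5
  frequency offsets), with a super-Lorentzian semisolid lineshape,
  continuous-wave power-equivalent (CWPE) saturation, and the measured T1
  map as a fixed input.
* **Magnetization transfer ratio (MTR)** = 100·(S_off − S_on)/S_off from
  the MT-off / 1500°-at-2 kHz pair.
* **UTE-T2\*** by single-component fitting of six-echo magnitudes
  (TE = 0.032–22 ms).
* **T1** by variable-flip-angle (VFA) SPGR fitting with actual-flip-angle
  (AFI) B1 correction.
* **ROI pipeline**: four OCJ regions per knee (anterior/inferior/posterior
  femoral condyle and tibial plateau); the whole-knee biomarker is the
  unweighted mean of the four region means.
* **Cohort statistics**: Lilliefors normality, Welch t / Mann–Whitney group
  comparison, Spearman/Pearson correlation with the Kellgren–Lawrence (KL)
  grade, empirical ROC with Youden-index cut-offs, inter-reader ICC(2,1).

Because in vivo patient data of this kind are not public, the package ships
first-class **synthetic generators**: a layered digital OCJ phantom whose
simulated acquisitions close the loop through the fitting pipeline, and a
KL-stratified two-group cohort model (n = 21 normal/subtle KL 0–1 vs n = 24
mild-to-moderate KL 2–3) with group means/SDs of MMF 15.8 ± 1.4 vs
13.6 ± 1.2 %, MTR 42.5 ± 2.5 vs 38.3 ± 2.9 %, T2* 19.7 ± 2.6 vs
21.6 ± 3.8 ms.

## The core model

Two proton pools — free water (a) and semisolid macromolecules (b) with
bound fraction f — exchange longitudinal magnetization at fundamental rate
R (k_ab = R·M0b, k_ba = R·M0a) while an off-resonance pulse of CW-equivalent
amplitude ω₁ at offset Δ saturates them at

    W_b = π ω₁² g(Δ, T2mm)          (super-Lorentzian absorption g)
    W_a = ω₁² / ((2πΔ)² T2w)        (far-offset Lorentzian direct saturation)

The steady-state water magnetization solves the coupled rate equations

    0 = R1a (M0a − Mza) − k_ab Mza + k_ba Mzb − W_a Mza
    0 = R1b (M0b − Mzb) − k_ba Mzb + k_ab Mza − W_b Mzb

in closed form; fitting {f, R, T2mm, M0} to the 15 measured signals (with
R1a = 1/T1 from the VFA/AFI map and R1b pinned at 1 s⁻¹) yields the MMF map.
ω₁ follows from the nominal MT flip θ through the pulse-shape factors:
ω₁max = θ/(p₁τp), ω₁ = ω₁max·sqrt(p₂τp/TR).

## Worked example

Simulate the 45-subject cohort, add a synthetic second reader at ICC 0.94,
and run the statistics layer:

```python
from uteqmt import synthetic_data as sd
from uteqmt.cohort_statistics import run_study

cohort = sd.add_reader_noise(sd.draw_cohort(seed=7), icc_target=0.94, seed=7)
report = run_study(cohort)
```

For seed 7 this prints (via the snippet in `uteqmt stats --help` style
formatting):

```
mmf_percent  ns 16.1±1.6  mm 13.7±1.2  welch_t p=1.9e-06  r=-0.55  AUC=0.88  thr=14.4  sens=70.8 spec=95.2  icc=0.96
mtr_percent  ns 41.4±2.7  mm 37.9±2.7  welch_t p=0.00011  r=-0.45  AUC=0.82  thr=39.8  sens=79.2 spec=81.0  icc=0.95
t2star_ms    ns 20.0±2.2  mm 21.5±4.3  welch_t p=0.15     r=0.20   AUC=0.61  thr=22.7  sens=41.7 spec=95.2  icc=0.93
```

Reading: in this draw the MT biomarkers separate the groups strongly (MMF
AUC 0.88 with a cut-off near 14.4 %, below which a knee is called diseased),
T2* separates weakly (AUC 0.61, non-significant comparison), and the
simulated second reader reproduces the target reliability. Because the
generator draws normal deviates, the normality gate usually selects the
Welch t-test here; on real in vivo MMF/MTR distributions the gate falls
back to Mann–Whitney.

The same pipeline runs from the shell:

```bash
uteqmt simulate demo --seed 3 --shape 16,16,4      # phantom NIfTI stacks + cohort.csv
uteqmt fit --mt demo/mt.nii.gz --multiecho demo/multiecho.nii.gz \
           --vfa demo/vfa.nii.gz --afi demo/afi.nii.gz \
           --regions demo/regions.nii.gz --kl-grade 0
uteqmt stats demo/cohort.csv --out demo/report.json --figures demo/figs
```

The `fit` verb on the zero-noise phantom returns whole-knee
MMF = 16.000 %, T2* = 17.000 ms — exactly the OCJ truth-layer values — and
the phantom's model-implied MTR.

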