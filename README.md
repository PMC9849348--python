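# pmihub

AI-based locoregional markers of the brain **peritumoral microenvironment**
from diffusion-MRI free-water volume-fraction maps.

## The problem

In high-grade gliomas, tumor cells infiltrate the peritumoral edema — the
T2-hyperintense zone around the enhancing core — where biopsy is hazardous
and treatment rarely reaches. Free-water volume-fraction maps from DTI
distinguish *vasogenic* edema (pure vascular leakage, high free water,
typical of metastases) from *infiltrative* edema (tumor cells restricting
water movement, locally lowered free water, typical of glioblastoma).

`pmihub` implements a pipeline that turns this contrast into per-patient
imaging markers:

1. **PMI map** — a 2-class CNN (six 3×3 convolutions, one 2×2 max-pool, a
   fully connected softmax head; SGD with momentum 0.9, weight decay 5·10⁻⁵,
   learning rate 10⁻⁴) is trained on 16×16 free-water patches sampled in the
   three cardinal planes inside edema: patches from metastasis-like edema
   are labeled *high free water*, patches from glioblastoma-like edema *low
   free water*, with shift augmentation allowing ≤ 20% overlap with healthy
   brain. At inference the three cardinal patches centered at every edema
   voxel are averaged into the voxel-wise **peritumoral microenvironment
   index** PMI ∈ [0, 1] (high = infiltrative-looking).
2. **Locoregional hubs** — 26-connected components of `PMI ≥ τ` inside
   edema; components with diameter < 2 voxels are discarded. The threshold τ
   is chosen on a labeled validation set by sweeping τ = 0.0, 0.1, …, 1.0
   and maximizing marker-wise group separation.
3. **Five markers** per patient: number of hubs and mean hub size (each
   normalized by edema voxel count), shape heterogeneity
   ⟨(s₁−s₂)/s₁⟩ of each hub's sorted coordinate-SD vector (*sdvec*),
   directional heterogeneity (max–min pairwise cosine distance between hub
   sdvecs), and spatial heterogeneity (mean pairwise centroid distance over
   the edema diameter).
4. **Cohort statistics** — median-survival split, t/Wilcoxon rank-sum tests
   with Bonferroni correction over the five markers, age/sex-adjusted OLS,
   K-means over z-scored markers with Calinski–Harabasz selection of
   k ∈ 1..9, Kaplan–Meier curves, logrank test and a Cox proportional-hazards
   hazard ratio between the low- and high-PMI clusters.

Clinical DTI cohorts of this kind are not public, so the package ships a
**phantom generator**: ellipsoidal tumor core + edema shell on a 2 mm grid,
with vasogenic (smooth high free water) and infiltrative (low-free-water
pocket-bearing) phenotypes, and synthetic cohorts whose survival hazard
depends on the planted infiltration burden through an exponential
proportional-hazards model. Every pipeline stage is tested against these
phantoms.

## Worked example

```python
from pmihub.pipeline import train_default_model, choose_threshold, run_phantom_cohort

model = train_default_model(seed=0)          # ~2000 phantom patches/class
print(model.report.summary())
# PMI patch classifier: train acc 0.950 (n=1600), held-out acc 0.943 (n=400), final loss 0.2080

threshold, sweep = choose_threshold(model, seed=1)
print(threshold)
# 0.8

res = run_phantom_cohort(model, threshold, cohort_seed=100)   # 40 subjects
print(f"HR(high vs low PMI) = {res.hr_high_vs_low:.2f}, logrank p = {res.logrank_p:.3f}")
# HR(high vs low PMI) = 3.75, logrank p = 0.001
```

The held-out accuracy says the patch classifier separates the two edema
phenotypes; the threshold is the PMI level at which hub markers best
discriminate the validation classes; the hazard ratio shows that patients
clustered as high-PMI by the five markers die faster — as planted by the
phantom's burden-linked hazard.

A thin CLI mirrors the stages: `pmihub phantom`, `pmihub train`,
`pmihub pmi`, `pmihub hubs`, `pmihub markers`, `pmihub analyze`.

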