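"""Synthetic subjects and cohorts for the PMI pipeline.

Clinical free-water data for this problem is not public, so phantoms stand
in: an ellipsoidal tumor core surrounded by an edema shell on an isotropic
grid.  Two edema phenotypes are emulated:

* ``vasogenic`` — spatially smooth, uniformly high free-water edema, the
  metastasis-like pattern of pure vascular leakage;
* ``infiltrative`` — the same background edema containing blob-like pockets
  of *restricted* (low) free water, the glioblastoma-like signature of
  tumor-cell infiltration.

The pockets are the only systematic difference between phenotypes, so they
are exactly what a patch classifier must learn.  Cohorts attach survival
times whose hazard depends on the planted infiltration burden (pocket voxels
per edema voxel) through an exponential proportional-hazards model, giving
cohort-level statistics a known recovery target.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, optimize

from .nifti_io import FreeWaterVolume, SubjectMasks, save_volume

logger = logging.getLogger(__name__)

_PHENOTYPES = ("vasogenic", "infiltrative")

#: canonical pocket load of the infiltrative *training* condition: with the
#: default geometry this covers roughly 15-20% of the edema, emulating
#: pervasively infiltrated glioblastoma-like edema so that diagnosis-labeled
#: patches carry class signal almost everywhere
DEFAULT_POCKET_COUNT = 150

#: pocket load and interior margin of the *analysis* (validation/test)
#: condition: fewer pockets, kept clear of the edema boundaries by roughly
#: the patch half-width, so each pocket resolves into its own locoregional
#: hub instead of merging with the boundary zone
ANALYSIS_POCKET_COUNT = 12
ANALYSIS_POCKET_MARGIN = 5.0


def training_spec(phenotype: str, seed: int, **overrides) -> "PhantomSpec":
    """Study conditions for CNN training subjects: dense, unconstrained pockets."""
    kw = dict(
        phenotype=phenotype,
        pocket_count=DEFAULT_POCKET_COUNT if phenotype == "infiltrative" else 0,
        noise_sd=0.05,
        seed=seed,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


def analysis_spec(phenotype: str, seed: int, **overrides) -> "PhantomSpec":
    """Study conditions for hub/marker analysis subjects: sparse interior pockets."""
    kw = dict(
        phenotype=phenotype,
        pocket_count=ANALYSIS_POCKET_COUNT if phenotype == "infiltrative" else 0,
        pocket_margin_vox=ANALYSIS_POCKET_MARGIN,
        noise_sd=0.05,
        seed=seed,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Free-water levels: ``fw_high`` is the vasogenic edema mean, ``fw_low``
    the level inside restricted pockets; healthy background sits near
    ``fw_background``.  Noise is white Gaussian smoothed with a 1-voxel
    Gaussian kernel, so phenotypes cannot be told apart from pixel-level
    noise statistics alone.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 64)
    spacing_mm: tuple[float, float, float] = (2.0, 2.0, 2.0)
    core_radius_vox: float = 5.0
    edema_thickness_vox: float = 20.0
    phenotype: str = "vasogenic"
    pocket_count: int = 0
    pocket_radius_vox: float = 2.5
    pocket_margin_vox: float = 0.0
    fw_high: float = 0.8
    fw_low: float = 0.3
    fw_background: float = 0.15
    noise_sd: float = 0.05
    center_jitter_vox: float = 2.0
    core_axis_ratio: float = 1.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.phenotype not in _PHENOTYPES:
            raise ValueError(f"phenotype must be one of {_PHENOTYPES}")
        if not (0.0 < self.fw_low < self.fw_high <= 1.0):
            raise ValueError("need 0 < fw_low < fw_high <= 1")
        if self.pocket_count and self.phenotype != "infiltrative":
            raise ValueError("pockets only make sense for the infiltrative phenotype")
        if self.pocket_count < 0 or self.pocket_radius_vox <= 0:
            raise ValueError("pocket parameters must be non-negative / positive")
        outer = self.core_radius_vox * self.core_axis_ratio + self.edema_thickness_vox
        if any(outer + self.center_jitter_vox >= n / 2 for n in self.grid_shape):
            raise ValueError("grid too small to contain core + edema (+ jitter)")


def _smooth_noise(shape, sd: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    smooth = ndimage.gaussian_filter(white, sigma=1.0)
    # restore unit variance lost to smoothing, then scale to sd
    smooth /= smooth.std()
    return sd * smooth


def make_phantom(spec: PhantomSpec) -> tuple[FreeWaterVolume, SubjectMasks, np.ndarray]:
    """Build one phantom subject.

    Returns the free-water volume, the masks, and ``truth``: a boolean array
    marking planted pocket voxels (all False for vasogenic subjects).
    Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    shape = tuple(spec.grid_shape)
    center = np.array(shape) / 2.0 - 0.5
    center = center + rng.uniform(-spec.center_jitter_vox, spec.center_jitter_vox, size=3)

    # ellipsoidal core: per-axis radii jittered around core_radius_vox
    radii = spec.core_radius_vox * rng.uniform(1.0, spec.core_axis_ratio, size=3)
    ii, jj, kk = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    d2_core = sum(((g - c) / r) ** 2 for g, c, r in zip((ii, jj, kk), center, radii))
    core = d2_core <= 1.0
    d2_outer = sum(
        ((g - c) / (r + spec.edema_thickness_vox)) ** 2
        for g, c, r in zip((ii, jj, kk), center, radii)
    )
    edema = (d2_outer <= 1.0) & ~core

    fw = np.full(shape, spec.fw_background)
    fw[core] = 0.5  # necrotic/enhancing core; never sampled by the pipeline
    fw[edema] = spec.fw_high

    truth = np.zeros(shape, dtype=bool)
    if spec.phenotype == "infiltrative" and spec.pocket_count > 0:
        # pockets must lie fully inside edema, optionally with an extra
        # interior margin keeping them clear of the edema boundaries
        depth = ndimage.distance_transform_edt(edema)
        min_depth = spec.pocket_radius_vox + spec.pocket_margin_vox
        r = spec.pocket_radius_vox
        ri = int(np.ceil(r))
        placed = 0
        rejections = 0
        candidate_idx = np.argwhere(edema)
        while placed < spec.pocket_count:
            if rejections > 1000:
                raise RuntimeError(
                    f"could not place {spec.pocket_count} pockets of radius "
                    f"{spec.pocket_radius_vox} inside edema after 1000 rejections"
                )
            c = candidate_idx[rng.integers(len(candidate_idx))]
            if depth[tuple(c)] <= min_depth:
                rejections += 1
                continue
            box = tuple(
                slice(max(0, int(ci) - ri), min(n, int(ci) + ri + 1))
                for ci, n in zip(c, shape)
            )
            bg = np.meshgrid(*[np.arange(sl.start, sl.stop) for sl in box], indexing="ij")
            pocket = sum((g - ci) ** 2 for g, ci in zip(bg, c)) <= r**2
            truth[box] |= pocket
            placed += 1
            rejections = 0
        fw[truth] = spec.fw_low

    fw = fw + _smooth_noise(shape, spec.noise_sd, rng)
    fw = np.clip(fw, 0.0, 1.0)

    vol = FreeWaterVolume(fw, spec.spacing_mm, np.diag(list(spec.spacing_mm) + [1.0]))
    masks = SubjectMasks(tumor_core=core, edema=edema)
    return vol, masks, truth


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort with burden-linked survival.

    Survival times follow an exponential proportional-hazards model: subject
    hazard per month is ``baseline_hazard * exp(log_hr_per_sd * z)`` where
    ``z`` is the within-cohort standardized infiltration burden.  Censoring
    is an independent exponential whose rate is solved so the expected
    censored fraction equals ``censoring_rate``.
    """

    n_subjects: int = 40
    phenotype_mix: float = 0.5
    baseline_hazard: float = 1.0 / 14.0  # per month; median survival ~10 months
    log_hr_per_sd: float = float(np.log(2.0))
    censoring_rate: float = 0.3
    age_range: tuple[float, float] = (40.0, 80.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.phenotype_mix <= 1.0):
            raise ValueError("phenotype_mix must be in [0, 1]")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.n_subjects < 2:
            raise ValueError("need at least 2 subjects")


@dataclass
class CohortSubject:
    """One generated subject held in memory (see :func:`generate_cohort`)."""

    subject_id: str
    volume: FreeWaterVolume
    masks: SubjectMasks
    truth: np.ndarray
    phenotype: str
    burden: float
    row: dict = field(default_factory=dict)


def _censoring_rate_for(hazards: np.ndarray, target: float) -> float:
    """Exponential censoring rate mu with mean_i mu/(lambda_i+mu) = target."""
    if target <= 0:
        return 0.0

    def f(mu):
        return float(np.mean(mu / (hazards + mu)) - target)

    lo, hi = 1e-12, float(hazards.max())
    while f(hi) < 0:
        hi *= 10
    return float(optimize.brentq(f, lo, hi))


def generate_cohort(
    cspec: CohortSpec, pspec_template: PhantomSpec
) -> tuple[list[CohortSubject], pd.DataFrame]:
    """Generate a cohort in memory; see :func:`make_cohort` for the on-disk form.

    Infiltrative subjects get the template's pocket settings (falling back to
    3 pockets if the template requests none); vasogenic subjects get zero
    pockets.  Returns the subjects and the cohort table.
    """
    rng = np.random.default_rng(cspec.seed)
    n = cspec.n_subjects
    n_inf = int(round(cspec.phenotype_mix * n))
    phenotypes = np.array(["infiltrative"] * n_inf + ["vasogenic"] * (n - n_inf))
    rng.shuffle(phenotypes)

    subjects: list[CohortSubject] = []
    burdens = np.zeros(n)
    for i, phen in enumerate(phenotypes):
        pocket_count = 0
        if phen == "infiltrative":
            base = pspec_template.pocket_count or DEFAULT_POCKET_COUNT
            # vary the planted burden so it is a graded, not binary, signal
            pocket_count = int(rng.integers(max(1, base // 2), base + base // 2 + 1))
        pspec = replace(
            pspec_template,
            phenotype=phen,
            pocket_count=pocket_count,
            seed=int(rng.integers(2**31 - 1)),
        )
        vol, masks, truth = make_phantom(pspec)
        burden = float(truth.sum() / masks.edema.sum())
        burdens[i] = burden
        subjects.append(
            CohortSubject(
                subject_id=f"sub-{i:03d}",
                volume=vol,
                masks=masks,
                truth=truth,
                phenotype=phen,
                burden=burden,
            )
        )

    sd = burdens.std()
    z = (burdens - burdens.mean()) / sd if sd > 0 else np.zeros(n)
    hazards = cspec.baseline_hazard * np.exp(cspec.log_hr_per_sd * z)
    event_times = rng.exponential(1.0 / hazards)
    mu = _censoring_rate_for(hazards, cspec.censoring_rate)
    if mu > 0:
        censor_times = rng.exponential(1.0 / mu, size=n)
    else:
        censor_times = np.full(n, np.inf)
    observed = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)

    ages = rng.uniform(*cspec.age_range, size=n)
    sexes = rng.choice(["M", "F"], size=n)
    rows = []
    for i, s in enumerate(subjects):
        row = {
            "subject_id": s.subject_id,
            "age_years": round(float(ages[i]), 1),
            "sex": sexes[i],
            "survival_months": float(observed[i]),
            "event": int(event[i]),
            # infiltrative phantoms emulate IDH1-wildtype glioblastoma edema,
            # vasogenic ones the metastasis-like (here: mutant-labeled) pattern
            "idh1_status": "wildtype" if s.phenotype == "infiltrative" else "mutant",
            "phenotype": s.phenotype,
            "burden": s.burden,
        }
        s.row = row
        rows.append(row)
    return subjects, pd.DataFrame(rows)


def make_cohort(
    cspec: CohortSpec, pspec_template: PhantomSpec, out_dir: str | Path
) -> pd.DataFrame:
    """Write a cohort to ``out_dir``: per-subject NIfTI files + cohort.csv.

    Layout per subject: ``<id>_fw.nii.gz``, ``<id>_tumor.nii.gz``,
    ``<id>_edema.nii.gz`` and the truth pocket mask ``<id>_truth.nii.gz``.
    Fully reproducible given ``cspec.seed``.
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
        probe = out / ".write_probe"
        probe.touch()
        probe.unlink()
    except OSError as exc:
        raise OSError(f"cohort output directory {out} is not writable: {exc}") from exc

    subjects, table = generate_cohort(cspec, pspec_template)
    for s in subjects:
        sp = s.volume.spacing
        aff = s.volume.affine
        save_volume(out / f"{s.subject_id}_fw.nii.gz", s.volume.data, sp, aff)
        save_volume(out / f"{s.subject_id}_tumor.nii.gz", s.masks.tumor_core, sp, aff)
        save_volume(out / f"{s.subject_id}_edema.nii.gz", s.masks.edema, sp, aff)
        save_volume(out / f"{s.subject_id}_truth.nii.gz", s.truth, sp, aff)
    table.to_csv(out / "cohort.csv", index=False)
    return table
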