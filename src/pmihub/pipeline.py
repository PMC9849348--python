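"""Canonical end-to-end pipeline over phantom cohorts.

Bundles the stages — training-patch sampling (with shift augmentation),
CNN training, PMI mapping, hub extraction, markers, exclusions, clustering
and the survival contrast — in the configuration the package uses as its
study conditions.  Tests, the acceptance script and the CLI all route
through these helpers so there is a single definition of "the pipeline".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort_stats import cluster_markers, survival_compare
from .hubs import extract_hubs, select_threshold
from .markers import apply_exclusions, compute_markers, markers_table
from .patches import Patch, augment_shift, sample_training_patches
from .phantom import (
    CohortSpec,
    analysis_spec,
    generate_cohort,
    make_phantom,
    training_spec,
)
from .pmi_model import PMIModel, TrainConfig, pmi_map

logger = logging.getLogger(__name__)

#: training patches sampled per subject (augmented copies on top)
PATCHES_PER_SUBJECT = 150
#: every AUGMENT_EVERY-th base patch receives one shifted copy
AUGMENT_EVERY = 3


def training_patch_set(
    seed: int,
    n_subjects_per_class: int = 5,
    patches_per_subject: int = PATCHES_PER_SUBJECT,
) -> list[Patch]:
    """Sample labeled, shift-augmented patches from training phantoms.

    Vasogenic subjects contribute ``high_fw`` patches, infiltrative subjects
    (dense-pocket training condition) ``low_fw`` ones.
    """
    patches: list[Patch] = []
    for i in range(n_subjects_per_class):
        for phenotype, label, off in (
            ("vasogenic", "high_fw", 0),
            ("infiltrative", "low_fw", 500),
        ):
            vol, masks, _ = make_phantom(training_spec(phenotype, seed * 1000 + off + i))
            base = sample_training_patches(
                vol, masks, patches_per_subject, label, seed=seed * 7 + off + i,
                subject_id=f"train-{phenotype[:4]}-{i}",
            )
            patches.extend(base)
            for j, p in enumerate(base[::AUGMENT_EVERY]):
                patches.extend(
                    augment_shift(p, vol, masks, n_aug=1, seed=(seed * 7 + off + i) * 997 + j)
                )
    return patches


def train_default_model(seed: int = 0, epochs: int = 8, **patch_kw) -> PMIModel:
    """Train the patch CNN under the package's standard phantom conditions."""
    model = PMIModel(cfg=TrainConfig(epochs=epochs, seed=seed))
    model.fit(training_patch_set(seed, **patch_kw))
    return model


def validation_inputs(model: PMIModel, seed: int, n_per_class: int = 10):
    """PMI maps + masks for a labeled analysis-condition validation set.

    Returns ``(inputs, labels)`` suitable for
    :func:`pmihub.hubs.select_threshold` (label 0 = vasogenic /
    metastasis-like, 1 = infiltrative / glioblastoma-like).
    """
    inputs, labels = [], []
    for i in range(n_per_class):
        for cls, phenotype in ((0, "vasogenic"), (1, "infiltrative")):
            vol, masks, _ = make_phantom(
                analysis_spec(phenotype, seed * 10_000 + cls * 5000 + i)
            )
            inputs.append((pmi_map(model, vol, masks), masks))
            labels.append(cls)
    return inputs, labels


def choose_threshold(model: PMIModel, seed: int = 1, n_per_class: int = 10):
    """Validation-set threshold selection under standard conditions."""
    inputs, labels = validation_inputs(model, seed, n_per_class)
    return select_threshold(inputs, labels)


def cohort_markers_table(
    model: PMIModel, subjects, threshold: float
) -> pd.DataFrame:
    """PMI -> hubs -> markers for a list of :class:`CohortSubject`."""
    ids, vecs = [], []
    for s in subjects:
        pm = pmi_map(model, s.volume, s.masks)
        hs = extract_hubs(pm, s.masks, threshold)
        ids.append(s.subject_id)
        vecs.append(compute_markers(hs, s.masks))
    return markers_table(ids, vecs)


@dataclass
class CohortRunResult:
    """End-to-end result for one phantom cohort."""

    markers: pd.DataFrame  # merged markers + cohort table, post exclusion
    excluded: pd.DataFrame
    chosen_k: int
    hr_high_vs_low: float
    logrank_p: float
    cluster_labels: np.ndarray


def run_phantom_cohort(
    model: PMIModel,
    threshold: float,
    cohort_seed: int,
    n_subjects: int = 40,
    cluster_seed: int = 0,
) -> CohortRunResult:
    """Full pipeline on one analysis-condition phantom cohort.

    Generates the cohort (survival hazard tied to planted burden), computes
    markers at ``threshold``, applies exclusions, clusters, and returns the
    Cox hazard ratio of the high- versus low-PMI cluster.
    """
    cspec = CohortSpec(n_subjects=n_subjects, seed=cohort_seed)
    subjects, table = generate_cohort(cspec, analysis_spec("infiltrative", 0))
    mt = cohort_markers_table(model, subjects, threshold).merge(table, on="subject_id")
    kept, excl = apply_exclusions(mt)
    clus = cluster_markers(kept, seed=cluster_seed)
    kept = kept.assign(cluster=clus.named_labels())
    sr = survival_compare(kept, "cluster")
    # survival_compare codes the second sorted level as 1; orient to high-PMI
    hr = sr.hazard_ratio if sr.levels[1] == "high-PMI" else 1.0 / sr.hazard_ratio
    return CohortRunResult(
        markers=kept,
        excluded=excl,
        chosen_k=clus.chosen_k,
        hr_high_vs_low=hr,
        logrank_p=sr.logrank_p,
        cluster_labels=clus.named_labels(),
    )
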