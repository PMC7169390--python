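"""Cohort-level recovery experiments.

Each function sets the generator's ground truth to a published cohort-level
readout (a growth fold change, a metastasis incidence, a dead-cell label
retention, a pooled dispersion variance), runs the full render → segment →
quantify pipeline, and returns the recovered quantity. They are the basis
of the package's reproducibility checks and are deliberately thin wrappers
over the public API so every number they report is produced by the same
code a user would run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from zeonco.config import RunConfig
from zeonco.io import VoxelStack
from zeonco.pipeline import quantify_records
from zeonco.quantification import call_metastasis, x_variance
from zeonco.segmentation import segment_larva
from zeonco.stats import rout_outliers
from zeonco.synthetic import (
    CohortConfig,
    GroundTruth,
    GroupSpec,
    LabelingModel,
    apply_labeling_model,
    dispersion_config,
    render_larva,
    sample_cohort,
)


@dataclass
class GrowthRecovery:
    mean_ratio: float
    sd_ratio: float
    se: float
    n: int
    true_mean: float


def recover_growth_mean(
    g_mean: float,
    n_larvae: int = 24,
    sd_frac: float = 0.1,
    seed: int = 0,
    rout_q: float = 1.0,
) -> GrowthRecovery:
    """Recover a cohort mean volume ratio from rendered stacks.

    True per-larva growth factors are Normal(g_mean, sd_frac*g_mean); the
    cohort mean of pipeline-recovered ratios is reported after ROUT outlier
    removal at rate ``rout_q``.
    """
    cfg = CohortConfig(
        groups=(
            GroupSpec(
                n_larvae=n_larvae, g_mean=g_mean, g_sd=sd_frac * g_mean
            ),
        ),
        seed=seed,
    )
    records = sample_cohort(cfg)
    result = quantify_records(records, RunConfig(rout_q=rout_q))
    ratios = np.array([q.growth_ratio for q in result.quants])
    kept, _ = rout_outliers(ratios, q=rout_q)
    return GrowthRecovery(
        mean_ratio=float(np.mean(kept)),
        sd_ratio=float(np.std(kept, ddof=1)),
        se=float(np.std(kept, ddof=1) / np.sqrt(len(kept))),
        n=int(len(kept)),
        true_mean=float(np.mean([r.truth.g for r in records])),
    )


def metastasis_incidence(
    dissemination_p: float = 0.762,
    n_larvae: int = 200,
    seed: int = 0,
) -> tuple[float, int]:
    """Percentage of larvae with a metastasis call at the second time point.

    Per-larva dissemination is Bernoulli(``dissemination_p``) with 1–3
    foci; only the second time point is rendered and segmented, since the
    call depends on tp2 masses alone.
    """
    cfg = CohortConfig(
        groups=(
            GroupSpec(
                n_larvae=n_larvae,
                g_mean=3.7,
                g_sd=0.37,
                dissemination_p=dissemination_p,
                n_foci_min=1,
                n_foci_max=3,
            ),
        ),
        seed=seed,
    )
    records = sample_cohort(cfg)
    calls = []
    for rec in records:
        s2 = render_larva(rec.spec, "tp2")
        seg2 = segment_larva(s2, eye_annotation_um=rec.spec.eye_center)
        calls.append(call_metastasis(seg2))
    return float(100.0 * np.mean(calls)), n_larvae


def label_retention_pct(
    kind: str,
    n_dead: int = 10_000,
    seed: int = 0,
) -> float:
    """Percent of dead tumor voxels still label-positive under a model.

    Builds a stack containing exactly ``n_dead`` foreground tumor voxels,
    declares all of them dead, applies the labeling model and counts the
    voxels that kept foreground intensity.
    """
    model = (
        LabelingModel.dye(dead_fraction_tp2=1.0)
        if kind == "dye"
        else LabelingModel.reporter(dead_fraction_tp2=1.0)
    )
    bg, fg, eye = 10.0, 100.0, 200.0
    side = int(np.ceil(n_dead ** (1 / 3))) + 2
    arr = np.full((side, side, side), bg, dtype=np.float32)
    arr.ravel()[:n_dead] = fg
    stack = VoxelStack(arr, (1.0, 1.0, 1.0), timepoint_tag="tp2")
    truth = GroundTruth(
        larva_id="dead-cells",
        v1_um3=float(n_dead),
        v2_um3=float(n_dead),
        g=1.0,
        disseminated=False,
        n_foci=0,
        foci_rel_x=(),
        model_kind=model.kind,
        p_retain=model.p_signal_retained_dead,
        dead_fraction=model.dead_fraction_tp2,
        seed=seed,
        background_level=bg,
        foreground_level=fg,
        eye_level=eye,
    )
    out = apply_labeling_model(stack, truth, model, seed)
    retained = int(np.sum(out.intensities > 0.5 * (bg + fg)))
    return 100.0 * retained / n_dead


def pooled_dispersion_variance(
    true_variance_um2: float = 2.5e5,
    n_larvae: int = 200,
    n_foci: int = 10,
    seed: int = 0,
) -> tuple[float, int]:
    """Pooled x-variance (µm²) of all segmented secondary foci in a cohort.

    Focus x-positions are drawn Normal with the requested true variance in
    a whole-larva field of view; every focus position is re-measured by
    segmentation and referenced to the eye landmark before pooling.
    """
    cfg = dispersion_config(
        groups=(
            GroupSpec(
                n_larvae=n_larvae,
                g_mean=3.7,
                g_sd=0.37,
                dissemination_p=1.0,
                n_foci_min=n_foci,
                n_foci_max=n_foci,
            ),
        ),
        foci_x_spread=float(np.sqrt(true_variance_um2)),
        seed=seed,
    )
    records = sample_cohort(cfg)
    pooled: list[float] = []
    for rec in records:
        s2 = render_larva(rec.spec, "tp2")
        seg2 = segment_larva(s2, eye_annotation_um=rec.spec.eye_center)
        pooled.extend(seg2.foci_rel_x)
    return x_variance(pooled), len(pooled)
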