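"""Run configuration and cohort presets.

Every knob of the pipeline — segmentation method, threshold, component size
filter, eye exclusion radius, metastasis distance, outlier-removal rate,
significance level, post hoc choice, seed — lives here, loadable from a
flat YAML file; nothing is hard-coded in the analysis path.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path
from typing import Optional

import yaml

from zeonco.synthetic import (
    CohortConfig,
    GroupSpec,
    LabelingModel,
    dispersion_config,
)


@dataclass(frozen=True)
class RunConfig:
    """Analysis-side configuration (segmentation, metrics, statistics)."""

    segmentation_method: str = "otsu"  # "otsu" | "fixed"
    fixed_threshold: Optional[float] = None
    min_voxels: int = 30
    connectivity: int = 26  # only 26-connectivity is implemented
    eye_exclusion_radius_um: float = 40.0
    metastasis_min_distance_um: float = 100.0
    rout_q: float = 1.0
    alpha: float = 0.05
    posthoc: str = "tukey"  # "tukey" | "sidak"
    seed: int = 0
    voxel_size_override: Optional[tuple[float, float, float]] = None

    def __post_init__(self) -> None:
        if self.segmentation_method not in ("otsu", "fixed"):
            raise ValueError(
                f"segmentation_method must be 'otsu' or 'fixed', "
                f"got {self.segmentation_method!r}"
            )
        if self.segmentation_method == "fixed" and self.fixed_threshold is None:
            raise ValueError("fixed segmentation requires fixed_threshold")
        if self.connectivity != 26:
            raise ValueError("only 26-connectivity is supported")
        if self.posthoc not in ("tukey", "sidak"):
            raise ValueError(f"posthoc must be 'tukey' or 'sidak', got {self.posthoc!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = sorted(set(raw) - known)
        if unknown:
            raise ValueError(f"unknown config keys: {unknown}")
        if "voxel_size_override" in raw and raw["voxel_size_override"] is not None:
            raw["voxel_size_override"] = tuple(raw["voxel_size_override"])
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# Cohort presets named after the screening scenarios they emulate. Growth
# means are the published cohort fold changes of the corresponding
# conditions; per-larva SD defaults to 10% of the mean.
# ---------------------------------------------------------------------------


def _preset_mda_pvs_dmso(seed: int) -> CohortConfig:
    """MDA-MB-231 in the perivitelline space, DMSO control vs ROCK-inhibitor
    (RKI-1447)-like treatment: growth 3.7 vs 2.0, frequent dissemination."""
    return CohortConfig(
        groups=(
            GroupSpec(
                treatment="DMSO",
                cell_line="MDA-MB-231",
                n_larvae=16,
                g_mean=3.7,
                g_sd=0.37,
                dissemination_p=0.762,
            ),
            GroupSpec(
                treatment="RKI-1447",
                cell_line="MDA-MB-231",
                n_larvae=16,
                g_mean=2.0,
                g_sd=0.2,
                dissemination_p=0.3,
            ),
        ),
        seed=seed,
    )


def _preset_hct116_docetaxel(seed: int) -> CohortConfig:
    """HCT116 at the late second time point: DMSO control grows (1.9),
    docetaxel regresses (0.3)."""
    return CohortConfig(
        groups=(
            GroupSpec(
                treatment="DMSO",
                cell_line="HCT116",
                n_larvae=16,
                g_mean=1.9,
                g_sd=0.19,
                dissemination_p=0.545,
            ),
            GroupSpec(
                treatment="Docetaxel",
                cell_line="HCT116",
                n_larvae=16,
                g_mean=0.3,
                g_sd=0.03,
                dissemination_p=0.1,
            ),
        ),
        seed=seed,
        timepoint_tag_tp2="ltp2",
    )


def _preset_dye_vs_reporter(seed: int) -> CohortConfig:
    """Equal true growth, half the tumor cells dead at tp2: membrane-dye
    labeling retains dead-cell signal, degradable reporter loses it."""
    return CohortConfig(
        groups=(
            GroupSpec(
                treatment="dye",
                cell_line="MDA-MB-231",
                n_larvae=16,
                g_mean=1.5,
                g_sd=0.15,
                labeling=LabelingModel.dye(dead_fraction_tp2=0.5),
            ),
            GroupSpec(
                treatment="reporter",
                cell_line="MDA-MB-231",
                n_larvae=16,
                g_mean=1.5,
                g_sd=0.15,
                labeling=LabelingModel.reporter(dead_fraction_tp2=0.5),
            ),
        ),
        seed=seed,
    )


def _preset_dispersion_dmso(seed: int) -> CohortConfig:
    """Whole-larva field of view, heavy caudal dissemination: the scenario
    behind the pooled x-variance readout."""
    return dispersion_config(
        groups=(
            GroupSpec(
                treatment="DMSO",
                cell_line="MDA-MB-231",
                n_larvae=24,
                g_mean=3.7,
                g_sd=0.37,
                dissemination_p=1.0,
                n_foci_min=3,
                n_foci_max=6,
            ),
        ),
        seed=seed,
    )


COHORT_PRESETS = {
    "mda_pvs_dmso": _preset_mda_pvs_dmso,
    "hct116_docetaxel": _preset_hct116_docetaxel,
    "dye_vs_reporter": _preset_dye_vs_reporter,
    "dispersion_dmso": _preset_dispersion_dmso,
}


def cohort_preset(name: str, seed: int = 0) -> CohortConfig:
    try:
        factory = COHORT_PRESETS[name]
    except KeyError:
        raise ValueError(
            f"unknown preset {name!r}; available: {sorted(COHORT_PRESETS)}"
        ) from None
    return factory(seed)
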