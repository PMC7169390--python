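"""End-to-end orchestration: plate → per-larva quantification → cohort table.

Two entry points: :func:`quantify_plate` consumes a plate directory written
by the generator (or by a microscope export following the same plate-map
contract), reading stacks from disk; :func:`quantify_records` runs the same
segmentation/quantification on in-memory synthetic larvae, which is how the
recovery experiments avoid TIFF round-trip cost. A larva that cannot be
quantified is flagged with a reason and skipped, never fatal for the plate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from zeonco.config import RunConfig
from zeonco.io import PlateMap, load_plate_map, read_stack
from zeonco.quantification import (
    LarvaQuant,
    QuantificationError,
    aggregate_cohort,
    quantify_larva,
)
from zeonco.segmentation import LarvaSegmentation, segment_larva
from zeonco.synthetic import LarvaRecord, apply_labeling_model, render_larva

log = logging.getLogger("zeonco")


@dataclass
class PlateQuantResult:
    per_larva: pd.DataFrame
    cohort: pd.DataFrame
    flagged: dict[str, str] = field(default_factory=dict)
    quants: list[LarvaQuant] = field(default_factory=list)
    group_labels: list[str] = field(default_factory=list)


def _segment_pair(
    stack1,
    stack2,
    eye_annotation,
    config: RunConfig,
) -> tuple[LarvaSegmentation, LarvaSegmentation]:
    kwargs = dict(
        eye_annotation_um=eye_annotation,
        method=config.segmentation_method,
        fixed_threshold=config.fixed_threshold,
        min_voxels=config.min_voxels,
        eye_exclusion_radius_um=config.eye_exclusion_radius_um,
    )
    return segment_larva(stack1, **kwargs), segment_larva(stack2, **kwargs)


def _per_larva_frame(
    quants: Sequence[LarvaQuant], labels: Sequence[str]
) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "larva_id": q.larva_id,
                "group": g,
                "v_tp1_um3": q.v_tp1_um3,
                "v_tp2_um3": q.v_tp2_um3,
                "growth_ratio": q.growth_ratio,
                "n_secondary_tp2": q.n_secondary_tp2,
                "x_variance_um2": q.x_variance_um2,
                "metastasis": q.metastasis,
                "foci_rel_x_csv": ";".join(f"{x:.3f}" for x in q.foci_rel_x_tp2),
            }
            for q, g in zip(quants, labels)
        ]
    )


def quantify_records(
    records: Sequence[LarvaRecord],
    config: Optional[RunConfig] = None,
    tp2_tag: str = "tp2",
) -> PlateQuantResult:
    """Render and quantify in-memory synthetic larvae (no disk I/O)."""
    config = config or RunConfig()
    quants: list[LarvaQuant] = []
    labels: list[str] = []
    flagged: dict[str, str] = {}
    for rec in records:
        try:
            s1 = render_larva(rec.spec, "tp1")
            s2 = render_larva(rec.spec, tp2_tag)
            if rec.group.labeling is not None:
                s2 = apply_labeling_model(
                    s2, rec.truth, rec.group.labeling, rec.spec.seed
                )
            seg1, seg2 = _segment_pair(s1, s2, rec.spec.eye_center, config)
            quants.append(
                quantify_larva(seg1, seg2, config.metastasis_min_distance_um)
            )
            labels.append(rec.group.treatment)
        except (QuantificationError, ValueError) as exc:
            flagged[rec.spec.larva_id] = str(exc)
            log.warning("larva %s flagged: %s", rec.spec.larva_id, exc)
    cohort = aggregate_cohort(quants, labels, rout_q=config.rout_q) if quants else pd.DataFrame()
    return PlateQuantResult(
        per_larva=_per_larva_frame(quants, labels),
        cohort=cohort,
        flagged=flagged,
        quants=quants,
        group_labels=labels,
    )


def quantify_plate(
    plate_dir: str | Path,
    config: Optional[RunConfig] = None,
    plate_map: Optional[PlateMap] = None,
) -> PlateQuantResult:
    """Quantify every included larva of a plate directory.

    Stacks referenced by the plate map are read relative to the plate
    directory; eye annotations from the map are used when present,
    otherwise the eye is auto-detected.
    """
    plate_dir = Path(plate_dir)
    config = config or RunConfig()
    plate = plate_map or load_plate_map(plate_dir / "plate_map.csv")
    quants: list[LarvaQuant] = []
    labels: list[str] = []
    flagged: dict[str, str] = {}
    for _, row in plate.included.iterrows():
        larva_id = row["larva_id"]
        try:
            eye = plate.eye_annotation(larva_id)
            s1 = read_stack(
                plate_dir / row["stack_tp1"],
                voxel_size=config.voxel_size_override,
                timepoint_tag="tp1",
                larva_id=larva_id,
                well=row["well"],
            )
            s2 = read_stack(
                plate_dir / row["stack_tp2"],
                voxel_size=config.voxel_size_override,
                timepoint_tag="tp2",
                larva_id=larva_id,
                well=row["well"],
            )
            seg1, seg2 = _segment_pair(s1, s2, eye, config)
            quants.append(
                quantify_larva(seg1, seg2, config.metastasis_min_distance_um)
            )
            labels.append(str(row["treatment"]))
            log.info(
                "larva %s: threshold tp1=%.3g tp2=%.3g ratio=%.3g",
                larva_id,
                seg1.threshold_used,
                seg2.threshold_used,
                quants[-1].growth_ratio,
            )
        except (QuantificationError, ValueError, OSError) as exc:
            flagged[larva_id] = str(exc)
            log.warning("larva %s flagged: %s", larva_id, exc)
    cohort = aggregate_cohort(quants, labels, rout_q=config.rout_q) if quants else pd.DataFrame()
    return PlateQuantResult(
        per_larva=_per_larva_frame(quants, labels),
        cohort=cohort,
        flagged=flagged,
        quants=quants,
        group_labels=labels,
    )
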