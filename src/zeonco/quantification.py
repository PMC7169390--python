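"""Per-larva growth and dispersion readouts and their cohort aggregation.

Tumor growth is the per-larva ratio of primary-mass volumes between the two
imaging time points (tp2/tp1) — ratios, not absolute volumes, absorb
per-larva differences in injected cell number. Dissemination is summarised
by the sample variance of secondary-focus x-positions relative to the eye,
and by a per-larva metastasis call (any focus sufficiently caudal of the
primary tumor).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from zeonco.segmentation import LarvaSegmentation
from zeonco.stats import rout_outliers


class QuantificationError(ValueError):
    """Raised when a larva cannot be quantified (flagged, not fatal)."""


@dataclass
class LarvaQuant:
    """Paired-time-point quantification of one larva."""

    larva_id: str
    v_tp1_um3: float
    v_tp2_um3: float
    growth_ratio: float
    foci_rel_x_tp2: tuple[float, ...]
    x_variance_um2: float
    n_secondary_tp2: int
    metastasis: bool


def growth_ratio(v_tp1: float, v_tp2: float) -> float:
    """Volume fold change tp2/tp1 for one larva."""
    if v_tp1 <= 0:
        raise QuantificationError(
            f"tp1 primary volume must be > 0 to form a ratio (got {v_tp1})"
        )
    if v_tp2 < 0:
        raise QuantificationError(f"tp2 volume must be >= 0 (got {v_tp2})")
    return float(v_tp2) / float(v_tp1)


def x_variance(foci_rel_x: Sequence[float]) -> float:
    """Sample variance (n−1 divisor) of focus positions along x, µm².

    Zero when fewer than two foci: larvae without dissemination contribute
    zero dispersion rather than an undefined value.
    """
    x = np.asarray(list(foci_rel_x), dtype=float)
    if x.size <= 1:
        return 0.0
    return float(np.var(x, ddof=1))


def call_metastasis(
    seg_tp2: LarvaSegmentation, min_distance_um: float = 100.0
) -> bool:
    """True iff at least one secondary mass lies more than ``min_distance_um``
    caudal (along +x) of the primary-mass centroid at the second time point."""
    primary = seg_tp2.primary
    if primary is None:
        return False
    px = primary.centroid_um[2]
    return any(
        (m.centroid_um[2] - px) > min_distance_um for m in seg_tp2.secondaries
    )


def quantify_larva(
    seg_tp1: LarvaSegmentation,
    seg_tp2: LarvaSegmentation,
    metastasis_min_distance_um: float = 100.0,
) -> LarvaQuant:
    """Combine the two time-point segmentations of one larva."""
    if seg_tp1.larva_id != seg_tp2.larva_id:
        raise QuantificationError(
            f"time points belong to different larvae: "
            f"{seg_tp1.larva_id!r} vs {seg_tp2.larva_id!r}"
        )
    p1 = seg_tp1.primary
    if p1 is None:
        raise QuantificationError(
            f"{seg_tp1.larva_id}: no primary mass at tp1; cannot form ratio"
        )
    p2 = seg_tp2.primary
    v1 = p1.volume_um3
    v2 = p2.volume_um3 if p2 is not None else 0.0
    foci = tuple(seg_tp2.foci_rel_x)
    return LarvaQuant(
        larva_id=seg_tp1.larva_id,
        v_tp1_um3=v1,
        v_tp2_um3=v2,
        growth_ratio=growth_ratio(v1, v2),
        foci_rel_x_tp2=foci,
        x_variance_um2=x_variance(foci),
        n_secondary_tp2=len(foci),
        metastasis=call_metastasis(seg_tp2, metastasis_min_distance_um),
    )


def aggregate_cohort(
    quants: Sequence[LarvaQuant],
    group_labels: Sequence[str],
    rout_q: float = 1.0,
) -> pd.DataFrame:
    """Per-group summaries of growth and dissemination.

    Growth ratios pass through robust outlier removal (ROUT, FDR ``rout_q``
    %) before the mean/SD; metastasis incidence is the percentage of larvae
    in the group called metastatic; the pooled x-variance is the sample
    variance over all secondary foci of all larvae in the group combined.
    """
    if len(quants) != len(group_labels):
        raise ValueError("quants and group_labels must have equal length")
    if not quants:
        raise ValueError("no larvae to aggregate")
    df = pd.DataFrame(
        {
            "group": list(group_labels),
            "ratio": [q.growth_ratio for q in quants],
            "metastasis": [q.metastasis for q in quants],
        }
    )
    foci_by_group: dict[str, list[float]] = {}
    for q, g in zip(quants, group_labels):
        foci_by_group.setdefault(g, []).extend(q.foci_rel_x_tp2)
    rows = []
    for group, sub in df.groupby("group", sort=False):
        ratios = sub["ratio"].to_numpy()
        kept, flags = rout_outliers(ratios, q=rout_q)
        rows.append(
            {
                "group": group,
                "n": int(len(sub)),
                "n_outliers_removed": int(flags.sum()),
                "mean_ratio": float(np.mean(kept)),
                "sd_ratio": float(np.std(kept, ddof=1)) if len(kept) > 1 else 0.0,
                "incidence_pct": float(100.0 * sub["metastasis"].mean()),
                "pooled_x_variance_um2": x_variance(foci_by_group[group]),
            }
        )
    return pd.DataFrame(rows)
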