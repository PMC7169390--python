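"""Acute-toxicity endpoint scoring and NOEC determination.

Larvae are exposed individually to a dilution series of a compound and
scored for mortality and six teratogenic endpoints (body deformity,
scoliosis, yolk size, heart edema, heartbeat, movement) at 24 and 144 hours
post incubation. The NOEC — the concentration then used to dose efficacy
experiments — is the highest tested concentration at which both the
mortality and the teratogenicity score are strictly below 20% at 144 hpi.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

ENDPOINTS = (
    "body_deformity",
    "scoliosis",
    "yolk_size",
    "heart_edema",
    "heartbeat",
    "movement",
)

TIMEPOINTS_HPI = (24, 144)


@dataclass(frozen=True)
class ToxRecord:
    """One larva at one scoring time point."""

    larva_id: str
    concentration_uM: float
    timepoint_hpi: int
    dead: bool = False
    body_deformity: bool = False
    scoliosis: bool = False
    yolk_size: bool = False
    heart_edema: bool = False
    heartbeat: bool = False
    movement: bool = False

    def __post_init__(self) -> None:
        if self.concentration_uM <= 0:
            raise ValueError("concentration must be > 0 µM")
        if self.timepoint_hpi not in TIMEPOINTS_HPI:
            raise ValueError(
                f"timepoint must be one of {TIMEPOINTS_HPI} hpi, "
                f"got {self.timepoint_hpi}"
            )
        if self.dead and any(getattr(self, e) for e in ENDPOINTS):
            raise ValueError(
                f"{self.larva_id}: teratogenic endpoints are not evaluated on "
                "dead larvae"
            )

    @property
    def any_endpoint_affected(self) -> bool:
        return any(getattr(self, e) for e in ENDPOINTS)


@dataclass
class NOECResult:
    """NOEC and the per-concentration score table it was derived from."""

    compound: str
    noec_uM: Optional[float]  # None => below the lowest tested concentration
    scores: pd.DataFrame  # columns: concentration_uM, n, mortality_pct, teratogenicity_pct

    @property
    def label(self) -> str:
        return f"{self.noec_uM:g} µM" if self.noec_uM is not None else "below lowest tested"

    def to_dict(self) -> dict:
        return {
            "compound": self.compound,
            "noec_uM": self.noec_uM,
            "noec": self.label,
            "per_concentration_144hpi": self.scores.to_dict(orient="records"),
        }


def concentration_scores(
    records: Sequence[ToxRecord], concentration_uM: float, timepoint_hpi: int = 144
) -> tuple[float, float]:
    """(mortality %, teratogenicity %) at one concentration/time point.

    Mortality is dead/n; teratogenicity is survivors-with-≥1-affected-
    endpoint over n (the full group, not just survivors), each ×100.
    """
    slice_ = [
        r
        for r in records
        if r.concentration_uM == concentration_uM and r.timepoint_hpi == timepoint_hpi
    ]
    if not slice_:
        raise ValueError(
            f"no records at {concentration_uM} µM / {timepoint_hpi} hpi"
        )
    n = len(slice_)
    dead = sum(r.dead for r in slice_)
    terato = sum((not r.dead) and r.any_endpoint_affected for r in slice_)
    return 100.0 * dead / n, 100.0 * terato / n


def compute_noec(
    records: Sequence[ToxRecord], compound: str = ""
) -> NOECResult:
    """NOEC: highest concentration with mortality < 20% AND teratogenicity
    < 20% at 144 hpi (both strict). Returns ``noec_uM=None`` when no tested
    concentration qualifies."""
    concs = sorted({r.concentration_uM for r in records if r.timepoint_hpi == 144})
    if len(concs) < 2:
        raise ValueError(
            "NOEC requires >= 2 distinct concentrations scored at 144 hpi"
        )
    rows = []
    noec: Optional[float] = None
    for c in concs:
        mort, ter = concentration_scores(records, c, 144)
        rows.append(
            {
                "concentration_uM": c,
                "n": sum(
                    1
                    for r in records
                    if r.concentration_uM == c and r.timepoint_hpi == 144
                ),
                "mortality_pct": mort,
                "teratogenicity_pct": ter,
            }
        )
        if mort < 20.0 and ter < 20.0:
            noec = c  # concs ascending: ends at the highest qualifying one
    return NOECResult(compound=compound, noec_uM=noec, scores=pd.DataFrame(rows))


TOX_CSV_COLUMNS = [
    "larva_id",
    "concentration_uM",
    "timepoint_hpi",
    "dead",
    *ENDPOINTS,
]


def load_tox_table(path: str | Path) -> list[ToxRecord]:
    """Read a toxicity score CSV (one row per larva/time point)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"toxicity table not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in TOX_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"toxicity table missing columns: {missing}")
    if df.empty:
        raise ValueError(f"toxicity table is empty: {path}")
    records = []
    for _, row in df.iterrows():
        records.append(
            ToxRecord(
                larva_id=str(row["larva_id"]),
                concentration_uM=float(row["concentration_uM"]),
                timepoint_hpi=int(row["timepoint_hpi"]),
                dead=bool(row["dead"]),
                **{e: bool(row[e]) for e in ENDPOINTS},
            )
        )
    return records
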