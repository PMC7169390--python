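"""Stack and plate-map I/O.

Stacks are single-channel 3D grids in (z, y, x) axis order with physical
voxel sizes in micrometres; x is the rostro-caudal axis. Larvae are kept
individualized in 96-well plates, so every stack carries the larva identity
and well it came from, and a plate map (CSV) links wells to larva IDs,
treatments and the stack files of both imaging time points.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

TIMEPOINT_TAGS = ("tp1", "etp2", "ltp2", "tp2")
STATUS_VALUES = ("included", "excluded_dead", "excluded_misinjected")

PLATE_MAP_COLUMNS = [
    "well",
    "larva_id",
    "cell_line",
    "treatment",
    "stack_tp1",
    "stack_tp2",
    "eye_z_um",
    "eye_y_um",
    "eye_x_um",
    "status",
]

_WELL_RE = re.compile(r"^[A-H](0[1-9]|1[0-2])$")


@dataclass
class VoxelStack:
    """A single larva/time-point 3D intensity grid with physical voxel sizes.

    Parameters
    ----------
    intensities
        3D array in (z, y, x) order; finite and non-negative.
    voxel_size
        (dz, dy, dx) in µm, all strictly positive.
    channel_name, timepoint_tag, larva_id, well
        Identity metadata; ``timepoint_tag`` is one of tp1/etp2/ltp2/tp2.
    """

    intensities: np.ndarray
    voxel_size: tuple[float, float, float]
    channel_name: str = "GFP"
    timepoint_tag: str = "tp1"
    larva_id: str = ""
    well: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise ValueError(f"stack must be 3D (z, y, x); got ndim={arr.ndim}")
        if arr.size == 0 or min(arr.shape) < 1:
            raise ValueError("stack must have at least one voxel per axis")
        if not np.all(np.isfinite(arr)):
            raise ValueError("stack intensities must be finite")
        if arr.min() < 0:
            raise ValueError("stack intensities must be non-negative")
        vs = tuple(float(v) for v in self.voxel_size)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size must be three positive values; got {self.voxel_size}")
        if self.timepoint_tag not in TIMEPOINT_TAGS:
            raise ValueError(
                f"timepoint_tag {self.timepoint_tag!r} not in {TIMEPOINT_TAGS}"
            )
        self.intensities = arr
        self.voxel_size = vs  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    @property
    def voxel_volume_um3(self) -> float:
        dz, dy, dx = self.voxel_size
        return dz * dy * dx

    def with_intensities(self, intensities: np.ndarray) -> "VoxelStack":
        return replace(self, intensities=intensities)


def write_stack(stack: VoxelStack, path: str | Path) -> Path:
    """Write a :class:`VoxelStack` as an OME-TIFF with voxel-size metadata.

    Round-trips bit-exactly through :func:`read_stack`.
    """
    path = Path(path)
    if not path.parent.exists():
        raise FileNotFoundError(f"parent directory does not exist: {path.parent}")
    dz, dy, dx = stack.voxel_size
    tifffile.imwrite(
        path,
        stack.intensities,
        ome=True,
        photometric="minisblack",
        metadata={
            "axes": "ZYX",
            "PhysicalSizeZ": dz,
            "PhysicalSizeZUnit": "µm",
            "PhysicalSizeY": dy,
            "PhysicalSizeYUnit": "µm",
            "PhysicalSizeX": dx,
            "PhysicalSizeXUnit": "µm",
            "Name": stack.larva_id or path.stem,
        },
    )
    return path


def _voxel_size_from_ome(tif: tifffile.TiffFile) -> Optional[tuple[float, float, float]]:
    try:
        import xml.etree.ElementTree as ET

        root = ET.fromstring(tif.ome_metadata or "")
    except Exception:
        return None
    for pixels in root.iter():
        if pixels.tag.endswith("Pixels"):
            try:
                dz = float(pixels.attrib["PhysicalSizeZ"])
                dy = float(pixels.attrib["PhysicalSizeY"])
                dx = float(pixels.attrib["PhysicalSizeX"])
            except KeyError:
                return None
            return (dz, dy, dx)
    return None


def read_stack(
    path: str | Path,
    voxel_size: Optional[tuple[float, float, float]] = None,
    channel_name: str = "GFP",
    timepoint_tag: str = "tp1",
    larva_id: str = "",
    well: str = "",
) -> VoxelStack:
    """Read a single-channel TIFF/OME-TIFF z-stack.

    The voxel size comes from OME metadata when present; an explicit
    ``voxel_size`` override takes precedence. If neither is available the
    call fails rather than assuming a size.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"stack file not found: {path}")
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        meta_vs = _voxel_size_from_ome(tif) if tif.is_ome else None
    if arr.ndim == 2:
        arr = arr[np.newaxis, ...]
    if arr.ndim == 4:
        # OME writers may add a singleton channel/time axis
        squeezable = [i for i, s in enumerate(arr.shape) if s == 1]
        if not squeezable:
            raise ValueError(
                f"{path} is multi-channel/multi-series; select a channel upstream"
            )
        arr = np.squeeze(arr, axis=squeezable[0])
    if arr.ndim != 3:
        raise ValueError(f"{path}: cannot interpret array of shape {arr.shape} as z-stack")
    vs = voxel_size if voxel_size is not None else meta_vs
    if vs is None:
        raise ValueError(
            f"{path}: no voxel-size metadata and no override provided"
        )
    return VoxelStack(
        intensities=arr,
        voxel_size=tuple(float(v) for v in vs),  # type: ignore[arg-type]
        channel_name=channel_name,
        timepoint_tag=timepoint_tag,
        larva_id=larva_id,
        well=well,
    )


@dataclass
class PlateMap:
    """Validated plate map: one row per individualized larva.

    Excluded larvae (dead or mis-injected at screening) are retained and
    flagged, never silently dropped; only ``included`` rows are quantified.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        df = self.table
        missing = [c for c in PLATE_MAP_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"plate map missing columns: {missing}")
        dupes = df["larva_id"][df["larva_id"].duplicated()].tolist()
        if dupes:
            raise ValueError(f"duplicate larva_id values: {sorted(set(dupes))}")
        bad_status = sorted(set(df["status"]) - set(STATUS_VALUES))
        if bad_status:
            raise ValueError(f"unknown status values: {bad_status}")
        bad_wells = [w for w in df["well"] if not _WELL_RE.match(str(w))]
        if bad_wells:
            raise ValueError(f"malformed well names (expect A01–H12): {bad_wells}")
        inc = df[df["status"] == "included"]
        for col in ("stack_tp1", "stack_tp2"):
            empty = inc[inc[col].isna() | (inc[col].astype(str).str.strip() == "")]
            if len(empty):
                raise ValueError(
                    f"included larvae missing {col}: {empty['larva_id'].tolist()}"
                )
        self.table = df.reset_index(drop=True)

    @property
    def included(self) -> pd.DataFrame:
        return self.table[self.table["status"] == "included"]

    @property
    def excluded(self) -> pd.DataFrame:
        return self.table[self.table["status"] != "included"]

    def __len__(self) -> int:
        return len(self.table)

    def eye_annotation(self, larva_id: str) -> Optional[tuple[float, float, float]]:
        """Eye landmark (z, y, x) in µm for a larva, or None when unannotated."""
        row = self.table[self.table["larva_id"] == larva_id]
        if row.empty:
            raise KeyError(f"larva_id {larva_id!r} not in plate map")
        vals = row.iloc[0][["eye_z_um", "eye_y_um", "eye_x_um"]]
        if vals.isna().any():
            return None
        return (float(vals.iloc[0]), float(vals.iloc[1]), float(vals.iloc[2]))


def load_plate_map(path: str | Path) -> PlateMap:
    """Load and validate a plate-map CSV (see :data:`PLATE_MAP_COLUMNS`)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"plate map not found: {path}")
    df = pd.read_csv(path, dtype={"well": str, "larva_id": str, "status": str})
    return PlateMap(df)


def save_plate_map(plate: PlateMap, path: str | Path) -> Path:
    path = Path(path)
    plate.table.to_csv(path, index=False)
    return path
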