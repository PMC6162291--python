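"""Observational data containers, assay-to-volume-fraction conversions, and I/O.

Two kinds of observations drive the calibration stages:

* daily cell-viability readouts per well, converted to viable tumor volume
  fractions ``phi_V`` and stored long-format in delimited text, and
* short time series of 2D viable-tumor volume-fraction grids (every 30
  minutes for 12 hours in the mobility experiments), stored as multi-page
  TIFF stacks with a YAML sidecar carrying grid metadata.

Viability assays report fluorescence intensity proportional to the number of
metabolically active cells; the conversion to a volume fraction is a linear
map through the origin anchored at the day-0 cell count.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

__all__ = [
    "ScenarioMeta",
    "TimeCourseDataset",
    "FieldSeries",
    "DEFAULT_ANCHOR",
    "seeding_density_to_volume_fraction",
    "fluorescence_to_volume_fraction",
    "footprint_volume_fraction",
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_field_series",
    "write_field_series",
    "FormatError",
]

#: Anchor pair (seeding density in cells/ml, viable volume fraction) for the
#: linear density -> volume-fraction conversion: 5,000 cells/ml corresponds
#: to an initial viable volume fraction of 4.22e-3.
DEFAULT_ANCHOR: tuple[float, float] = (5_000.0, 4.22e-3)

#: Allowed FBS percentages and their nutrient volume-fraction images.
FBS_LEVELS: tuple[float, ...] = (0.0, 2.5, 5.0, 7.5, 10.0)


class FormatError(ValueError):
    """A file does not conform to the documented on-disk format."""


@dataclass(frozen=True)
class ScenarioMeta:
    """Design metadata for one experimental scenario (one well-plate condition).

    ``nutrient_fraction`` is the dimensionless nutrient volume fraction
    ``phi_sigma = fbs_percent / 10`` (10% FBS, the vendor-optimal level, maps
    to 1). ``treatment`` is ``"MMC"`` for Mitomycin-C-treated wells (cell
    proliferation inhibited) or ``"none"``.
    """

    scenario_id: str
    seeding_density: float  # cells/ml
    fbs_percent: float
    treatment: str = "none"  # {"MMC", "none"}
    duration: float = 7.0  # days
    sampling_interval: float = 1.0  # days

    def __post_init__(self) -> None:
        if self.seeding_density <= 0:
            raise ValueError(f"seeding_density must be > 0, got {self.seeding_density}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if self.fbs_percent not in FBS_LEVELS:
            raise ValueError(
                f"fbs_percent must be one of {FBS_LEVELS}, got {self.fbs_percent}"
            )
        if self.treatment not in ("MMC", "none"):
            raise ValueError(f"treatment must be 'MMC' or 'none', got {self.treatment!r}")

    @property
    def nutrient_fraction(self) -> float:
        """Nutrient volume fraction phi_sigma = FBS% / 10, in [0, 1]."""
        return self.fbs_percent / 10.0


@dataclass
class TimeCourseDataset:
    """Per-scenario replicate measurements of viable volume fraction.

    ``values[j, i]`` is replicate ``i``'s measurement on day ``times[j]``;
    the study design uses four biological replicates per day.
    """

    meta: ScenarioMeta
    times: np.ndarray  # (N_t,) measurement days, strictly increasing
    values: np.ndarray  # (N_t, N_r) viable volume fractions, >= 0
    floored: np.ndarray | None = None  # optional (N_t, N_r) bool: obs floored at 0

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("times must be 1-D")
        if self.values.shape[0] != self.times.size or self.values.ndim != 2:
            raise ValueError(
                f"values must be (N_t, N_r) with N_t={self.times.size}, "
                f"got shape {self.values.shape}"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("viable volume fractions must be >= 0")
        if self.values.shape[1] < 1:
            raise ValueError("need at least one replicate")

    @property
    def n_times(self) -> int:
        return self.times.size

    @property
    def n_replicates(self) -> int:
        return self.values.shape[1]

    def drop_replicate(self, i: int) -> "TimeCourseDataset":
        """Dataset without replicate ``i`` (used by cross-validation)."""
        keep = [k for k in range(self.n_replicates) if k != i]
        if not keep:
            raise ValueError("cannot drop the only replicate")
        fl = self.floored[:, keep] if self.floored is not None else None
        return TimeCourseDataset(self.meta, self.times.copy(), self.values[:, keep], fl)

    def replicate(self, i: int) -> np.ndarray:
        return self.values[:, i]


@dataclass
class FieldSeries:
    """Time-stamped 2D grids of tumor volume fraction on a uniform grid.

    Grids are row-major with the origin at the top-left corner, x increasing
    rightward (columns), y downward (rows); pixel centers sit at
    ``(i + 1/2) * pixel_size``. Values are clamped to [0, 1] on ingest.
    """

    times: np.ndarray  # (N_f,) hours
    grids: np.ndarray  # (N_f, ny, nx) phi_T in [0, 1]
    pixel_size: float  # micrometers

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.grids = np.asarray(self.grids, dtype=float)
        if self.grids.ndim != 3 or self.grids.shape[0] != self.times.size:
            raise ValueError(
                f"grids must be (N_f, ny, nx) with N_f={self.times.size}, "
                f"got {self.grids.shape}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        np.clip(self.grids, 0.0, 1.0, out=self.grids)

    @property
    def n_frames(self) -> int:
        return self.times.size

    @property
    def shape(self) -> tuple[int, int]:
        return self.grids.shape[1:]

    @property
    def extent(self) -> tuple[float, float]:
        """Physical domain size (width, height) in micrometers."""
        ny, nx = self.shape
        return (nx * self.pixel_size, ny * self.pixel_size)


# ---------------------------------------------------------------------------
# Conversions
# ---------------------------------------------------------------------------

def seeding_density_to_volume_fraction(
    density: float,
    anchor: tuple[float, float] = DEFAULT_ANCHOR,
) -> float:
    """Initial viable volume fraction for a seeding density, by linear scaling.

    The conversion is a straight line through the origin pinned at a single
    anchor pair ``(anchor_density, anchor_fraction)``: the five seeding
    densities of the study design (5e3 to 1e5 cells/ml) are all exact
    multiples of the 5,000 cells/ml anchor, so no intercept is identifiable
    and none is used.

    Parameters
    ----------
    density : float
        Seeding density in cells/ml; must be > 0.
    anchor : (float, float)
        ``(density, fraction)`` calibration pair; fraction must lie in (0, 1).
    """
    a_density, a_fraction = anchor
    if density <= 0:
        raise ValueError(f"density must be > 0, got {density}")
    if a_density <= 0 or not (0.0 < a_fraction < 1.0):
        raise ValueError(f"invalid anchor {anchor}: need density > 0, fraction in (0,1)")
    return a_fraction * (density / a_density)


def fluorescence_to_volume_fraction(
    intensities: np.ndarray,
    day0_intensity: float,
    day0_fraction: float,
) -> np.ndarray:
    """Map fluorescence intensities to viable volume fractions.

    Metabolic dye fluorescence is proportional to the number of viable cells,
    so intensities scale linearly (through the origin) onto volume fractions,
    anchored by the day-0 intensity / day-0 volume-fraction pair.
    """
    if day0_intensity <= 0:
        raise ValueError(f"day0_intensity must be > 0, got {day0_intensity}")
    intensities = np.asarray(intensities, dtype=float)
    return day0_fraction * intensities / day0_intensity


def footprint_volume_fraction(
    cell_count: float,
    well_area: float,
    cell_diameter: float = 15.0,
) -> float:
    """Alternative conversion: total cell footprint area over well area.

    Treats each cell as a disc of the given diameter (micrometers; constant
    diameter, since nothing in the protocol alters cell size) and divides the
    summed footprint by the well area (square micrometers). Provided as an
    optional mode; the anchored linear map is the default conversion because
    it requires no diameter assumption.
    """
    if cell_count < 0 or well_area <= 0 or cell_diameter <= 0:
        raise ValueError("cell_count >= 0, well_area > 0, cell_diameter > 0 required")
    return cell_count * np.pi * (cell_diameter / 2.0) ** 2 / well_area


# ---------------------------------------------------------------------------
# Time-course CSV I/O
# ---------------------------------------------------------------------------
# Long format, one row per (scenario, day, replicate); scenario metadata in
# '# key: value' comment lines before the column header. Values printed at 17
# significant digits so the write -> read round trip is bit exact.

_META_KEYS = ("scenario_id", "seeding_density", "fbs_percent", "treatment",
              "duration", "sampling_interval")


def write_timecourse_csv(dataset: TimeCourseDataset, path: str | os.PathLike) -> None:
    """Write a time-course dataset as commented-header long-format CSV."""
    m = dataset.meta
    lines = []
    for key in _META_KEYS:
        lines.append(f"# {key}: {getattr(m, key)}")
    lines.append("scenario_id,day,replicate,value")
    for j, t in enumerate(dataset.times):
        for i in range(dataset.n_replicates):
            lines.append(f"{m.scenario_id},{t:.17g},{i},{dataset.values[j, i]:.17g}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_timecourse_csv(path: str | os.PathLike) -> TimeCourseDataset:
    """Read a time-course dataset written by :func:`write_timecourse_csv`.

    Raises :class:`FormatError` on missing columns, duplicate
    (day, replicate) rows, ragged replicate sets, or non-monotone days,
    naming the offending row where possible.
    """
    text = Path(path).read_text()
    meta_kv: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            meta_kv[key.strip()] = val.strip()
        elif line.strip():
            body_lines.append(line)
    if not body_lines:
        raise FormatError(f"{path}: empty time-course file")
    try:
        # round_trip parsing: the default tokenizer is not correctly rounded
        # and would break the bit-exact write -> read contract
        df = pd.read_csv(io.StringIO("\n".join(body_lines)),
                         float_precision="round_trip")
    except Exception as exc:  # noqa: BLE001 - surface as format error
        raise FormatError(f"{path}: unparseable CSV ({exc})") from exc
    required = {"scenario_id", "day", "replicate", "value"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: missing columns {sorted(required - set(df.columns))}")
    if df.empty:
        raise FormatError(f"{path}: no data rows")

    dup = df.duplicated(subset=["day", "replicate"])
    if dup.any():
        row = df[dup].iloc[0]
        raise FormatError(
            f"{path}: duplicate (day={row['day']}, replicate={row['replicate']}) row"
        )
    missing = [k for k in _META_KEYS if k not in meta_kv]
    if missing:
        raise FormatError(f"{path}: missing metadata keys {missing}")
    meta = ScenarioMeta(
        scenario_id=meta_kv["scenario_id"],
        seeding_density=float(meta_kv["seeding_density"]),
        fbs_percent=float(meta_kv["fbs_percent"]),
        treatment=meta_kv["treatment"],
        duration=float(meta_kv["duration"]),
        sampling_interval=float(meta_kv["sampling_interval"]),
    )

    days = np.sort(df["day"].unique())
    reps = np.sort(df["replicate"].unique())
    pivot = df.pivot(index="day", columns="replicate", values="value")
    if pivot.isna().any().any():
        day = pivot.index[pivot.isna().any(axis=1)][0]
        raise FormatError(f"{path}: ragged replicates on day {day}")
    values = pivot.loc[days, reps].to_numpy(dtype=float)
    try:
        return TimeCourseDataset(meta, days.astype(float), values)
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc


# ---------------------------------------------------------------------------
# Field-series TIFF I/O
# ---------------------------------------------------------------------------

def write_field_series(series: FieldSeries, path: str | os.PathLike) -> None:
    """Write a field series as a float32 multi-page TIFF plus a YAML sidecar.

    One page per timepoint; the sidecar ``<path>.yaml`` carries ``pixel_size``
    (micrometers), ``times`` (hours), and the value ``scaling`` ("float" here;
    16-bit stacks from other tools use scaling 1/65535 on read).
    """
    path = Path(path)
    tifffile.imwrite(path, series.grids.astype(np.float32))
    sidecar = {
        "pixel_size": float(series.pixel_size),
        "times": [float(t) for t in series.times],
        "scaling": "float",
    }
    path.with_suffix(path.suffix + ".yaml").write_text(yaml.safe_dump(sidecar))


def read_field_series(path: str | os.PathLike) -> FieldSeries:
    """Read a multi-page TIFF field series with its YAML sidecar.

    Float pages are taken as volume fractions directly; unsigned 16-bit pages
    are scaled by 1/65535 into [0, 1]. Pages must share one shape.
    """
    path = Path(path)
    sidecar_path = path.with_suffix(path.suffix + ".yaml")
    if not sidecar_path.exists():
        raise FormatError(f"{path}: missing sidecar {sidecar_path.name}")
    sidecar = yaml.safe_load(sidecar_path.read_text())
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    if not pages:
        raise FormatError(f"{path}: empty TIFF stack")
    shapes = {p.shape for p in pages}
    if len(shapes) != 1:
        raise FormatError(f"{path}: mismatched page shapes {sorted(shapes)}")
    stack = np.stack(pages)
    if stack.dtype == np.uint16:
        stack = stack.astype(float) / 65535.0
    else:
        stack = stack.astype(float)
    times = np.asarray(sidecar["times"], dtype=float)
    if times.size != stack.shape[0]:
        raise FormatError(
            f"{path}: sidecar lists {times.size} times for {stack.shape[0]} pages"
        )
    return FieldSeries(times=times, grids=stack, pixel_size=float(sidecar["pixel_size"]))
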