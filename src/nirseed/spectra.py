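"""Core data model for NIR spectra on a uniform wavenumber grid.

Spectra are stored the way an FT-NIR instrument delivers them: a descending,
evenly spaced wavenumber axis (cm^-1) and one absorbance row per scan.  The
acquisition grid used throughout this package runs from 11,536 down to
3952 cm^-1 in steps of 8 cm^-1 (949 points).  The instrument's optical
resolution is 16 cm^-1; the digital point spacing is half that, the usual
FT zero-filling convention, and 8 cm^-1 is the only spacing consistent with
both printed point counts (949 over 11,536-3952 and 632 over 9000-3952).

The canonical interchange format is a wide CSV: five metadata columns
(`bag_id,cultivar,endophyte_strain,endophyte_status,scan_index`) followed by
one numeric column per wavenumber.  Single spectra can also be read from
plain-text JCAMP-DX files (see :mod:`nirseed.jcampdx`).  Proprietary binary
instrument files are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CULTIVARS",
    "STRAINS",
    "WavenumberGrid",
    "ScanMetadata",
    "SpectraSet",
    "build_grid",
    "trim",
    "read_csv",
    "write_csv",
    "read_jcampdx",
    "wavenumber_to_nm",
    "nm_to_wavenumber",
]

#: The four perennial-ryegrass cultivars in the study design.
CULTIVARS = ("Alto", "Bronsyn", "Maxsyn", "Trojan")

#: The twelve Epichloe endophyte strains plus WE ("without endophyte").
STRAINS = (
    "AR1", "NEA2/6", "NEA10", "NEA2", "NEA3", "NEA6", "SE",
    "NEA11", "AR37", "NEA12", "NEA21", "NEA23", "WE",
)

METADATA_COLUMNS = (
    "bag_id", "cultivar", "endophyte_strain", "endophyte_status", "scan_index",
)


@dataclass(frozen=True)
class WavenumberGrid:
    """Uniform descending wavenumber axis in cm^-1."""

    high: float
    low: float
    spacing: float

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError(f"grid spacing must be positive, got {self.spacing}")
        if self.high < self.low:
            raise ValueError(
                f"grid high ({self.high}) must be >= low ({self.low})"
            )
        span = self.high - self.low
        n_steps = span / self.spacing
        if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, n_steps):
            raise ValueError(
                f"grid range {self.high}..{self.low} is not an integer multiple "
                f"of the spacing {self.spacing}"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.high - self.low) / self.spacing)) + 1

    @property
    def points(self) -> np.ndarray:
        """Wavenumbers, strictly descending from ``high`` to ``low``."""
        return self.high - self.spacing * np.arange(self.n_points)

    def __len__(self) -> int:  # pragma: no cover - convenience
        return self.n_points


def build_grid(high: float, low: float, spacing: float) -> WavenumberGrid:
    """Construct a descending inclusive grid from ``high`` to ``low``.

    ``(high - low)`` must be an exact integer multiple of ``spacing``;
    a 949-point acquisition grid is ``build_grid(11536, 3952, 8)``.
    """
    return WavenumberGrid(float(high), float(low), float(spacing))


@dataclass(frozen=True)
class ScanMetadata:
    """Identity of one sub-sample scan of a bag of seeds."""

    bag_id: str
    cultivar: str
    endophyte_strain: str
    endophyte_status: str
    scan_index: int
    harvest_date: str | None = None
    is_outlier: bool = False

    def __post_init__(self) -> None:
        if self.cultivar not in CULTIVARS:
            raise ValueError(
                f"bag {self.bag_id}: unknown cultivar {self.cultivar!r}"
            )
        if self.endophyte_strain not in STRAINS:
            raise ValueError(
                f"bag {self.bag_id}: unknown endophyte strain "
                f"{self.endophyte_strain!r}"
            )
        if self.endophyte_status not in ("E+", "E-"):
            raise ValueError(
                f"bag {self.bag_id}: endophyte status must be 'E+' or 'E-', "
                f"got {self.endophyte_status!r}"
            )
        # WE (without endophyte) and E- imply each other.
        if (self.endophyte_strain == "WE") != (self.endophyte_status == "E-"):
            raise ValueError(
                f"bag {self.bag_id}: strain {self.endophyte_strain!r} is "
                f"inconsistent with status {self.endophyte_status!r} "
                "(WE <=> E-)"
            )
        if self.scan_index < 1:
            raise ValueError(
                f"bag {self.bag_id}: scan_index must be >= 1, "
                f"got {self.scan_index}"
            )


@dataclass
class SpectraSet:
    """A batch of scans: grid, absorbance matrix and per-scan metadata."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    metadata: list[ScanMetadata] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.absorbance.ndim != 2:
            raise ValueError("absorbance must be a 2-D (n_scans x n_points) array")
        n_scans, n_points = self.absorbance.shape
        if n_scans < 1:
            raise ValueError("a SpectraSet needs at least one scan")
        if n_points != self.grid.n_points:
            raise ValueError(
                f"absorbance has {n_points} columns but the grid has "
                f"{self.grid.n_points} points"
            )
        if len(self.metadata) != n_scans:
            raise ValueError(
                f"{len(self.metadata)} metadata records for {n_scans} scans"
            )
        if not np.isfinite(self.absorbance).all():
            raise ValueError("absorbance contains non-finite values")

    @property
    def n_scans(self) -> int:
        return self.absorbance.shape[0]

    def cultivars(self) -> np.ndarray:
        return np.array([m.cultivar for m in self.metadata])

    def statuses(self) -> np.ndarray:
        return np.array([m.endophyte_status for m in self.metadata])

    def bag_ids(self) -> np.ndarray:
        return np.array([m.bag_id for m in self.metadata])

    def subset(self, indices: Sequence[int]) -> "SpectraSet":
        """New set containing the scans at ``indices`` (original order kept)."""
        idx = np.asarray(indices, dtype=int)
        return SpectraSet(
            grid=self.grid,
            absorbance=self.absorbance[idx].copy(),
            metadata=[self.metadata[i] for i in idx],
        )


def trim(s: SpectraSet, high: float, low: float) -> SpectraSet:
    """Restrict a set to the wavenumber window ``[low, high]`` (inclusive).

    Retains exactly the grid columns whose wavenumber lies in the window;
    the standard analysis window is 9000-3952 cm^-1 (632 points of the 949).
    The input set is left unmodified.
    """
    if high < low:
        high, low = low, high
    points = s.grid.points
    keep = (points <= high) & (points >= low)
    if not keep.any():
        raise ValueError(
            f"trim window [{low}, {high}] does not intersect the grid "
            f"range [{s.grid.low}, {s.grid.high}]"
        )
    kept = points[keep]
    new_grid = WavenumberGrid(float(kept[0]), float(kept[-1]), s.grid.spacing)
    return SpectraSet(
        grid=new_grid,
        absorbance=s.absorbance[:, keep].copy(),
        metadata=list(s.metadata),
    )


def wavenumber_to_nm(wavenumber: float | np.ndarray) -> float | np.ndarray:
    """Convert cm^-1 to nm (1e7 / wavenumber)."""
    return 1e7 / np.asarray(wavenumber, dtype=float)


def nm_to_wavenumber(nm: float | np.ndarray) -> float | np.ndarray:
    """Convert nm to cm^-1 (1e7 / nm)."""
    return 1e7 / np.asarray(nm, dtype=float)


# ---------------------------------------------------------------------------
# CSV interchange
# ---------------------------------------------------------------------------

def write_csv(s: SpectraSet, path) -> None:
    """Write a set as a wide CSV (metadata columns then wavenumber columns).

    Wavenumber headers are plain decimals in cm^-1; absorbances are written
    at 9 significant digits, so a write -> read round trip is lossless at
    that precision.
    """
    records = {
        "bag_id": [m.bag_id for m in s.metadata],
        "cultivar": [m.cultivar for m in s.metadata],
        "endophyte_strain": [m.endophyte_strain for m in s.metadata],
        "endophyte_status": [m.endophyte_status for m in s.metadata],
        "scan_index": [m.scan_index for m in s.metadata],
    }
    frame = pd.DataFrame(records)
    points = s.grid.points
    spectra = pd.DataFrame(
        s.absorbance, columns=[_format_wavenumber(w) for w in points]
    )
    pd.concat([frame, spectra], axis=1).to_csv(
        path, index=False, float_format="%.9g"
    )


def _format_wavenumber(w: float) -> str:
    return f"{w:g}"


def read_csv(path) -> SpectraSet:
    """Read a wide-format spectra CSV written by :func:`write_csv`.

    Rejects ragged rows, non-uniform wavenumber grids and unknown
    cultivar / strain / status labels, naming the offending row or column.
    """
    frame = pd.read_csv(path)
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"CSV is missing metadata columns: {missing}")
    wn_cols = [c for c in frame.columns if c not in METADATA_COLUMNS]
    if not wn_cols:
        raise ValueError("CSV has no wavenumber columns")
    try:
        points = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise ValueError(f"non-numeric wavenumber column header: {exc}") from exc
    if len(points) > 1:
        steps = np.diff(points)
        if (steps >= 0).any():
            raise ValueError("wavenumber columns must be strictly descending")
        if not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ValueError("wavenumber columns are not uniformly spaced")
        spacing = -steps[0]
    else:
        spacing = 1.0
    grid = WavenumberGrid(float(points[0]), float(points[-1]), float(spacing))

    absorbance = frame[wn_cols].to_numpy(dtype=float)
    if np.isnan(absorbance).any():
        bad = int(np.argwhere(np.isnan(absorbance))[0, 0])
        raise ValueError(f"row {bad}: missing or non-numeric absorbance value")

    metadata = []
    for i, row in enumerate(frame[list(METADATA_COLUMNS)].itertuples(index=False)):
        try:
            metadata.append(
                ScanMetadata(
                    bag_id=str(row.bag_id),
                    cultivar=str(row.cultivar),
                    endophyte_strain=str(row.endophyte_strain),
                    endophyte_status=str(row.endophyte_status),
                    scan_index=int(row.scan_index),
                )
            )
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    return SpectraSet(grid=grid, absorbance=absorbance, metadata=metadata)


def read_jcampdx(path, *, bag_id: str = "jcamp", cultivar: str = "Alto",
                 endophyte_strain: str = "WE",
                 endophyte_status: str = "E-") -> SpectraSet:
    """Read one plain-text JCAMP-DX spectrum as a single-scan set.

    JCAMP-DX carries no seed metadata, so placeholder labels are attached
    (overridable via keywords).  Only AFFN-encoded linear XYDATA/XYPOINTS
    blocks with units 1/CM are supported.
    """
    from .jcampdx import parse_jcampdx

    x, y = parse_jcampdx(path)
    if x[0] < x[-1]:  # store descending, acquisition order
        x, y = x[::-1], y[::-1]
    steps = np.diff(x)
    if len(x) > 1 and not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
        raise ValueError(f"{path}: JCAMP-DX abscissa is not uniformly spaced")
    spacing = float(-steps[0]) if len(x) > 1 else 1.0
    grid = WavenumberGrid(float(x[0]), float(x[-1]), spacing)
    meta = ScanMetadata(
        bag_id=bag_id, cultivar=cultivar, endophyte_strain=endophyte_strain,
        endophyte_status=endophyte_status, scan_index=1,
    )
    return SpectraSet(grid=grid, absorbance=y[np.newaxis, :], metadata=[meta])
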