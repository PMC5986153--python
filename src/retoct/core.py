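"""Core domain types shared across the pipeline.

Coordinate conventions
----------------------
All images are indexed ``[b-scan][row][column]``.  The row index increases
with depth (axial direction), the column index runs across A-scans.  A
boundary position at A-scan ``i`` is the row of the first pixel belonging to
the layer *below* the interface, so a layer band is the half-open row
interval ``[upper_boundary, lower_boundary)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional, Tuple

import numpy as np

# The twelve retinal interfaces in anatomical order, top (inner) to bottom
# (outer).  Depth order of detected positions must follow this sequence.
BOUNDARY_NAMES: Tuple[str, ...] = (
    "ILM-RNFL",
    "RNFL-GCL",
    "GCL-IPL",
    "IPL-INL",
    "INL-OPL",
    "OPL-ONL",
    "ONL-ELM",
    "ELM-MZ",
    "MZ-EZ",
    "EZ-OSL",
    "IZ-RPE",
    "RBC",
)

BOUNDARY_INDEX: Dict[str, int] = {n: i for i, n in enumerate(BOUNDARY_NAMES)}

# The order in which boundaries are searched for: high-contrast interfaces
# first so they can anchor the search regions of the low-contrast ones.
DETECTION_ORDER: Tuple[str, ...] = (
    "ILM-RNFL",
    "RBC",
    "MZ-EZ",
    "IZ-RPE",
    "OPL-ONL",
    "ONL-ELM",
    "EZ-OSL",
    "ELM-MZ",
    "INL-OPL",
    "IPL-INL",
    "RNFL-GCL",
    "GCL-IPL",
)

# Named layer bands as (upper boundary, lower boundary) pairs.
LAYER_BANDS: Dict[str, Tuple[str, str]] = {
    "RNFL": ("ILM-RNFL", "RNFL-GCL"),
    "GCL": ("RNFL-GCL", "GCL-IPL"),
    "IPL": ("GCL-IPL", "IPL-INL"),
    "INL": ("IPL-INL", "INL-OPL"),
    "OPL": ("INL-OPL", "OPL-ONL"),
    "ONL": ("OPL-ONL", "ONL-ELM"),
    "ELM": ("ONL-ELM", "ELM-MZ"),
    "MZ": ("ELM-MZ", "MZ-EZ"),
    "EZ": ("MZ-EZ", "EZ-OSL"),
    "OSL": ("EZ-OSL", "IZ-RPE"),
    "RPE": ("IZ-RPE", "RBC"),
    "retina": ("ILM-RNFL", "RBC"),
    # "complex" of the ellipsoid zone down to the RPE/Bruch's complex.
    "complex": ("MZ-EZ", "RBC"),
    # Inner-retina band searched for hyper-reflective spots.
    "his_band": ("IPL-INL", "ONL-ELM"),
}

LABELS: Tuple[str, ...] = ("normal", "AMD", "DME")

FEATURE_NAMES: Tuple[str, ...] = (
    "his_volume_mm3",
    "drusen_volume_mm3",
    "curviness_mzez",
    "curviness_oplonl",
    "retina_mean_um",
    "retina_p70_um",
    "complex_mean_um",
    "complex_p70_um",
    "rpe_mean_um",
    "rpe_p70_um",
)


class RetoctError(Exception):
    """Base class for pipeline errors."""


@dataclass(frozen=True)
class OCTVolume:
    """A 3D stack of B-scans with physical voxel dimensions.

    Parameters
    ----------
    intensities
        ``uint8`` array of shape ``(n_bscans, depth_px, width_ascans)``.
    voxel_dims
        ``(axial um/px, lateral um/px, inter-b-scan um)``.
    """

    intensities: np.ndarray
    voxel_dims: Tuple[float, float, float]

    def __post_init__(self) -> None:
        arr = np.asarray(self.intensities)
        if arr.ndim != 3:
            raise RetoctError(f"volume must be 3D, got shape {arr.shape}")
        if any(d <= 0 for d in self.voxel_dims):
            raise RetoctError(f"voxel dimensions must be positive: {self.voxel_dims}")
        object.__setattr__(self, "intensities", arr)

    @property
    def n_bscans(self) -> int:
        return self.intensities.shape[0]

    @property
    def depth_px(self) -> int:
        return self.intensities.shape[1]

    @property
    def width_ascans(self) -> int:
        return self.intensities.shape[2]

    @property
    def voxel_volume_mm3(self) -> float:
        ax, lat, sp = self.voxel_dims
        return ax * lat * sp * 1e-9  # um^3 -> mm^3


@dataclass(frozen=True)
class Boundary:
    """One interface traced across a single B-scan."""

    name: str
    positions: np.ndarray  # per-A-scan axial row, fractional after fitting
    bscan_index: int = 0

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 1:
            raise RetoctError("boundary positions must be a 1D array")
        object.__setattr__(self, "positions", pos)

    def __len__(self) -> int:
        return len(self.positions)


class BoundarySet:
    """Mapping ``(bscan_index, boundary name) -> Boundary`` for a volume."""

    def __init__(self) -> None:
        self._data: Dict[Tuple[int, str], Boundary] = {}

    def add(self, boundary: Boundary) -> None:
        self._data[(boundary.bscan_index, boundary.name)] = boundary

    def get(self, bscan: int, name: str) -> Boundary:
        try:
            return self._data[(bscan, name)]
        except KeyError:
            raise RetoctError(f"boundary {name!r} missing for B-scan {bscan}") from None

    def has(self, bscan: int, name: str) -> bool:
        return (bscan, name) in self._data

    @property
    def bscan_indices(self) -> Tuple[int, ...]:
        return tuple(sorted({b for b, _ in self._data}))

    def names(self, bscan: int) -> Tuple[str, ...]:
        return tuple(n for n in BOUNDARY_NAMES if (bscan, n) in self._data)

    def positions_grid(self, name: str) -> np.ndarray:
        """Stack one boundary across B-scans into ``(n_bscans, width)``."""
        return np.stack([self.get(b, name).positions for b in self.bscan_indices])

    def __iter__(self) -> Iterator[Boundary]:
        return iter(self._data.values())

    def __len__(self) -> int:
        return len(self._data)

    def copy(self) -> "BoundarySet":
        out = BoundarySet()
        for b in self:
            out.add(Boundary(b.name, b.positions.copy(), b.bscan_index))
        return out

    def to_dict(self) -> Dict[str, Dict[str, list]]:
        return {
            str(b): {n: self.get(b, n).positions.tolist() for n in self.names(b)}
            for b in self.bscan_indices
        }

    @classmethod
    def from_dict(cls, d: Mapping[str, Mapping[str, list]]) -> "BoundarySet":
        out = cls()
        for b, names in d.items():
            for name, pos in names.items():
                out.add(Boundary(name, np.asarray(pos, dtype=float), int(b)))
        return out

    def ordering_violation(self, tol: float = 0.5) -> Optional[Tuple[int, str, str, int]]:
        """Return the first anatomical depth-order violation, if any.

        Checks every A-scan of every B-scan; returns
        ``(bscan, upper name, lower name, column)`` or ``None``.
        """
        for b in self.bscan_indices:
            present = self.names(b)
            for upper, lower in zip(present[:-1], present[1:]):
                du = self.get(b, upper).positions
                dl = self.get(b, lower).positions
                bad = np.nonzero(du > dl + tol)[0]
                if bad.size:
                    return (b, upper, lower, int(bad[0]))
        return None


@dataclass(frozen=True)
class PathologyMask:
    """Labeled binary 3D mask (same shape as its volume)."""

    kind: str  # "drusen" | "HIS"
    mask: np.ndarray
    voxel_dims: Tuple[float, float, float]

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        if m.ndim != 3:
            raise RetoctError("mask must be 3D")
        object.__setattr__(self, "mask", m)

    @property
    def count(self) -> int:
        return int(self.mask.sum())

    @property
    def volume_mm3(self) -> float:
        ax, lat, sp = self.voxel_dims
        return self.count * ax * lat * sp * 1e-9


@dataclass(frozen=True)
class FeatureVector:
    """The ten structural/pathology features for one eye."""

    his_volume_mm3: float
    drusen_volume_mm3: float
    curviness_mzez: float
    curviness_oplonl: float
    retina_mean_um: float
    retina_p70_um: float
    complex_mean_um: float
    complex_p70_um: float
    rpe_mean_um: float
    rpe_p70_um: float

    def __post_init__(self) -> None:
        for name in FEATURE_NAMES:
            v = getattr(self, name)
            if not np.isfinite(v):
                raise RetoctError(f"feature {name} is not finite: {v}")
        for name in ("his_volume_mm3", "drusen_volume_mm3",
                     "curviness_mzez", "curviness_oplonl"):
            if getattr(self, name) < 0:
                raise RetoctError(f"feature {name} must be non-negative")

    def to_dict(self) -> Dict[str, float]:
        return {n: float(getattr(self, n)) for n in FEATURE_NAMES}

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in FEATURE_NAMES], dtype=float)
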