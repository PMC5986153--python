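"""Synthetic SD-OCT volumes with fully known layer geometry.

A phantom is a stack of piecewise-constant B-scans: twelve layer interfaces
at configurable depths, optional sub-RPE bumps (drusen), bright intra-retinal
spots (HIS), sinusoidal boundary ripples and additive Gaussian noise.  The
generator returns the exact generative surfaces and pathology masks so every
downstream stage can be tested without external data.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import features as _feat
from .core import (
    BOUNDARY_NAMES,
    Boundary,
    BoundarySet,
    FeatureVector,
    LABELS,
    OCTVolume,
    PathologyMask,
    RetoctError,
)

# How far a sub-RPE bump propagates upward: the RPE floor and roof ride the
# full bump while the inner surfaces drape over it with attenuated height.
DRUSEN_ATTENUATION: Dict[str, float] = {
    "ONL-ELM": 0.5,
    "ELM-MZ": 0.55,
    "MZ-EZ": 0.6,
    "EZ-OSL": 0.8,
    "IZ-RPE": 1.0,
    "RBC": 1.0,
}

# Default per-layer mean intensities (layer *below* each interface), chosen
# so every interface has the gradient polarity expected by the segmenter.
DEFAULT_LAYER_PROFILE: Tuple[Tuple[str, int, int], ...] = (
    ("ILM-RNFL", 50, 150),   # RNFL
    ("RNFL-GCL", 64, 105),   # GCL
    ("GCL-IPL", 76, 75),     # IPL
    ("IPL-INL", 88, 40),     # INL
    ("INL-OPL", 100, 130),   # OPL
    ("OPL-ONL", 112, 50),    # ONL
    ("ONL-ELM", 126, 20),    # ELM
    ("ELM-MZ", 134, 70),     # MZ
    ("MZ-EZ", 142, 180),     # EZ
    ("EZ-OSL", 150, 110),    # OSL + IZ
    ("IZ-RPE", 158, 200),    # RPE
    ("RBC", 168, 80),        # choroid
)

DEFAULT_VOXEL_DIMS: Tuple[float, float, float] = (3.9, 11.6, 120.0)


@dataclass(frozen=True)
class DrusenBump:
    """Semi-elliptic sub-RPE detachment."""

    bscan_start: int
    bscan_stop: int  # exclusive
    center_col: int
    radius_px: float
    height_px: float
    interior_intensity: int = 80

    def elevation(self, width: int) -> np.ndarray:
        """Per-column upward elevation of the RPE floor, in pixels."""
        c = np.arange(width, dtype=float)
        u = (c - self.center_col) / self.radius_px
        elev = np.zeros(width)
        inside = np.abs(u) < 1.0
        elev[inside] = self.height_px * np.sqrt(1.0 - u[inside] ** 2)
        return elev


@dataclass(frozen=True)
class HisSpot:
    """Bright disk inside the inner retina."""

    bscan: int
    row: int
    col: int
    radius_px: float
    intensity: int = 210


@dataclass(frozen=True)
class BoundaryRipple:
    """Sinusoidal deformation of one interface (same on every B-scan)."""

    boundary: str
    amplitude_px: float
    periods: float
    phase: float = 0.0


@dataclass(frozen=True)
class PhantomSpec:
    width_ascans: int = 128
    depth_px: int = 256
    n_bscans: int = 9
    voxel_dims: Tuple[float, float, float] = DEFAULT_VOXEL_DIMS
    layer_profile: Tuple[Tuple[str, float, int], ...] = DEFAULT_LAYER_PROFILE
    vitreous_intensity: int = 10
    drusen_bumps: Tuple[DrusenBump, ...] = ()
    his_spots: Tuple[HisSpot, ...] = ()
    ripples: Tuple[BoundaryRipple, ...] = ()
    noise_sd: float = 0.0
    seed: int = 0
    label: str = "normal"

    def __post_init__(self) -> None:
        names = tuple(n for n, _, _ in self.layer_profile)
        if names != BOUNDARY_NAMES:
            raise RetoctError(
                f"layer_profile must list the 12 boundaries in anatomical order, got {names}")
        depths = [d for _, d, _ in self.layer_profile]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise RetoctError(f"baseline depths must be strictly increasing: {depths}")
        if depths[0] < 0 or depths[-1] >= self.depth_px:
            raise RetoctError("layer_profile depths out of image bounds")
        for i, bump in enumerate(self.drusen_bumps):
            if bump.height_px < 0:
                raise RetoctError(f"drusen bump #{i}: height must be >= 0")
            if bump.radius_px <= 0:
                raise RetoctError(f"drusen bump #{i}: radius must be > 0")
            if not (0 <= bump.bscan_start < bump.bscan_stop <= self.n_bscans):
                raise RetoctError(f"drusen bump #{i}: B-scan range out of bounds")
            if not (0 <= bump.center_col - bump.radius_px
                    and bump.center_col + bump.radius_px < self.width_ascans):
                raise RetoctError(f"drusen bump #{i}: footprint outside image columns")
        for i, spot in enumerate(self.his_spots):
            if not (0 <= spot.bscan < self.n_bscans):
                raise RetoctError(f"HIS spot #{i}: B-scan index out of bounds")
            r = spot.radius_px
            if not (0 <= spot.row - r and spot.row + r < self.depth_px
                    and 0 <= spot.col - r and spot.col + r < self.width_ascans):
                raise RetoctError(f"HIS spot #{i}: disk outside image bounds")
        known = set(BOUNDARY_NAMES)
        for rip in self.ripples:
            if rip.boundary not in known:
                raise RetoctError(f"ripple on unknown boundary {rip.boundary!r}")
        if self.label not in LABELS:
            raise RetoctError(f"label must be one of {LABELS}")


@dataclass(frozen=True)
class GroundTruth:
    boundaries: BoundarySet
    drusen_mask: PathologyMask
    his_mask: PathologyMask
    true_features: FeatureVector
    label: str
    baseline_rbc: np.ndarray  # flat membrane line per (bscan, col), pre-detachment


def _surfaces_for_bscan(spec: PhantomSpec, bscan: int) -> Dict[str, np.ndarray]:
    """Exact generative surfaces (float rows) for one B-scan."""
    width = spec.width_ascans
    cols = np.arange(width, dtype=float)
    surf = {name: np.full(width, float(d)) for name, d, _ in spec.layer_profile}
    for rip in spec.ripples:
        surf[rip.boundary] = surf[rip.boundary] + rip.amplitude_px * np.sin(
            2.0 * np.pi * rip.periods * cols / width + rip.phase)
    elev = np.zeros(width)
    for bump in spec.drusen_bumps:
        if bump.bscan_start <= bscan < bump.bscan_stop:
            elev = np.maximum(elev, bump.elevation(width))
    for name, att in DRUSEN_ATTENUATION.items():
        surf[name] = surf[name] - att * elev
    return surf


def _rint(a: np.ndarray) -> np.ndarray:
    return np.rint(a).astype(int)


def generate_phantom(spec: PhantomSpec) -> Tuple[OCTVolume, GroundTruth]:
    """Render a phantom volume and its exact ground truth."""
    width, depth, nb = spec.width_ascans, spec.depth_px, spec.n_bscans
    intensities = {name: v for name, _, v in spec.layer_profile}
    rng = np.random.default_rng(spec.seed)

    volume = np.empty((nb, depth, width), dtype=float)
    boundaries = BoundarySet()
    drusen_mask = np.zeros((nb, depth, width), dtype=bool)
    his_mask = np.zeros((nb, depth, width), dtype=bool)
    baseline_rbc = np.empty((nb, width), dtype=float)
    rows = np.arange(depth)[:, None]

    for b in range(nb):
        surf = _surfaces_for_bscan(spec, b)
        flat = _surfaces_for_bscan(replace(spec, drusen_bumps=()), b)
        baseline_rbc[b] = flat["RBC"]

        # depth-order sanity of the generative surfaces themselves
        ordered = [surf[n] for n in BOUNDARY_NAMES]
        for (un, up), (ln, lo) in zip(zip(BOUNDARY_NAMES, ordered),
                                      zip(BOUNDARY_NAMES[1:], ordered[1:])):
            if np.any(up > lo):
                raise RetoctError(
                    f"B-scan {b}: surfaces {un}/{ln} cross; check bump/ripple geometry")

        img = np.full((depth, width), float(spec.vitreous_intensity))
        limits = [_rint(surf[n]) for n in BOUNDARY_NAMES] + [np.full(width, depth)]
        for k, name in enumerate(BOUNDARY_NAMES):
            band = (rows >= limits[k][None, :]) & (rows < limits[k + 1][None, :])
            img[band] = intensities[name]

        # drusen interior: between detached RPE floor and the flat membrane
        r_det = _rint(surf["RBC"])
        r_base = _rint(flat["RBC"])
        interior = (rows >= r_det[None, :]) & (rows < r_base[None, :])
        if interior.any():
            fills = np.full(width, 80.0)
            for bump in spec.drusen_bumps:
                if bump.bscan_start <= b < bump.bscan_stop:
                    e = bump.elevation(width) > 0
                    fills[e] = bump.interior_intensity
            img[interior] = np.broadcast_to(fills, (depth, width))[interior]
            drusen_mask[b] = interior

        for spot in spec.his_spots:
            if spot.bscan != b:
                continue
            rr, cc = np.ogrid[:depth, :width]
            disk = (rr - spot.row) ** 2 + (cc - spot.col) ** 2 <= spot.radius_px ** 2
            inner = (rows >= _rint(surf["IPL-INL"])[None, :]) \
                & (rows < _rint(surf["ONL-ELM"])[None, :])
            if np.any(disk & ~inner):
                raise RetoctError(
                    f"HIS spot at b={b},row={spot.row},col={spot.col} leaves the inner band")
            img[disk] = float(spot.intensity)
            his_mask[b] |= disk

        volume[b] = img
        for name in BOUNDARY_NAMES:
            boundaries.add(Boundary(name, surf[name], b))

    if np.any(drusen_mask & his_mask):
        raise RetoctError("drusen and HIS masks overlap")

    if spec.noise_sd > 0:
        volume = volume + rng.normal(0.0, spec.noise_sd, size=volume.shape)
    volume = np.clip(np.rint(volume), 0, 255).astype(np.uint8)

    oct_volume = OCTVolume(volume, spec.voxel_dims)
    d_mask = PathologyMask("drusen", drusen_mask, spec.voxel_dims)
    h_mask = PathologyMask("HIS", his_mask, spec.voxel_dims)
    truth = GroundTruth(
        boundaries=boundaries,
        drusen_mask=d_mask,
        his_mask=h_mask,
        true_features=_true_features(boundaries, d_mask, h_mask, spec),
        label=spec.label,
        baseline_rbc=baseline_rbc,
    )
    return oct_volume, truth


def _true_features(boundaries: BoundarySet, drusen: PathologyMask,
                   his: PathologyMask, spec: PhantomSpec) -> FeatureVector:
    """Analytic feature values from the generative surfaces and masks."""
    axial = spec.voxel_dims[0]
    cfg = _feat.FeatureConfig()

    def curv(name: str) -> float:
        vals = [_feat.curviness(boundaries.get(b, "RBC"), boundaries.get(b, name),
                                cfg.curviness)
                for b in boundaries.bscan_indices]
        return float(np.mean(vals))

    def stats(upper: str, lower: str) -> Tuple[float, float]:
        tmap = _feat.thickness_profile(boundaries, upper, lower,
                                       cfg.thickness_sigma, axial)
        return _feat.thickness_stats(tmap)

    retina = stats("ILM-RNFL", "RBC")
    cplx = stats(cfg.complex_upper, "RBC")
    rpe = stats("IZ-RPE", "RBC")
    return FeatureVector(
        his_volume_mm3=his.volume_mm3,
        drusen_volume_mm3=drusen.volume_mm3,
        curviness_mzez=curv("MZ-EZ"),
        curviness_oplonl=curv("OPL-ONL"),
        retina_mean_um=retina[0], retina_p70_um=retina[1],
        complex_mean_um=cplx[0], complex_p70_um=cplx[1],
        rpe_mean_um=rpe[0], rpe_p70_um=rpe[1],
    )


# ---------------------------------------------------------------------------
# cohorts


@dataclass(frozen=True)
class ClassTemplate:
    """A base spec plus uniform jitter ranges applied per generated volume.

    Supported jitter keys (all ``(low, high)`` inclusive ranges):
    ``depth_shift`` (whole-profile axial shift, px), ``bump_center``,
    ``bump_radius``, ``bump_height`` (additive, per bump), ``spot_col``,
    ``spot_row`` (additive, per spot), ``ripple_amp``, ``noise_sd``.
    """

    base: PhantomSpec
    jitter: Dict[str, Tuple[float, float]] = field(default_factory=dict)


def _jittered_spec(template: ClassTemplate, rng: np.random.Generator,
                   seed: int) -> PhantomSpec:
    spec = template.base
    j = template.jitter

    def draw(key: str, integer: bool = False) -> float:
        lo, hi = j[key]
        v = rng.uniform(lo, hi)
        return float(round(v)) if integer else float(v)

    kwargs: Dict[str, object] = {"seed": seed}
    shift = 0.0
    if "depth_shift" in j:
        shift = draw("depth_shift", integer=True)
        kwargs["layer_profile"] = tuple(
            (n, d + shift, v) for n, d, v in spec.layer_profile)
        if spec.his_spots:
            # spots ride with the retina so they stay inside the inner band
            kwargs["his_spots"] = tuple(
                replace(s, row=int(s.row + shift)) for s in spec.his_spots)
    if spec.drusen_bumps and any(k.startswith("bump_") for k in j):
        bumps = []
        for bump in spec.drusen_bumps:
            bumps.append(replace(
                bump,
                center_col=int(bump.center_col + (draw("bump_center", True) if "bump_center" in j else 0)),
                radius_px=bump.radius_px + (draw("bump_radius") if "bump_radius" in j else 0),
                height_px=bump.height_px + (draw("bump_height") if "bump_height" in j else 0),
            ))
        kwargs["drusen_bumps"] = tuple(bumps)
    if spec.his_spots and any(k.startswith("spot_") for k in j):
        spots = []
        for spot in kwargs.get("his_spots", spec.his_spots):
            spots.append(replace(
                spot,
                col=int(spot.col + (draw("spot_col", True) if "spot_col" in j else 0)),
                row=int(spot.row + (draw("spot_row", True) if "spot_row" in j else 0)),
            ))
        kwargs["his_spots"] = tuple(spots)
    if spec.ripples and "ripple_amp" in j:
        kwargs["ripples"] = tuple(
            replace(r, amplitude_px=r.amplitude_px + draw("ripple_amp"))
            for r in spec.ripples)
    if "noise_sd" in j:
        kwargs["noise_sd"] = max(0.0, draw("noise_sd"))
    if not j:
        kwargs.pop("seed")  # zero jitter reproduces the template exactly
    return replace(spec, **kwargs)


def default_class_templates(noise_sd: float = 6.0) -> Dict[str, ClassTemplate]:
    """Separable normal / AMD / DME archetypes for the default phantom size."""
    base = PhantomSpec(noise_sd=noise_sd)
    normal = ClassTemplate(
        base=replace(base, label="normal"),
        jitter={"depth_shift": (-4, 4)},
    )
    amd = ClassTemplate(
        base=replace(
            base, label="AMD",
            drusen_bumps=(
                DrusenBump(2, 7, center_col=40, radius_px=12, height_px=14),
                DrusenBump(3, 6, center_col=88, radius_px=9, height_px=12),
            )),
        jitter={"depth_shift": (-4, 4), "bump_center": (-6, 6),
                "bump_radius": (-2, 3), "bump_height": (-2, 2)},
    )
    dme_profile = tuple(
        (n, d + (15 if i >= 4 else 0), v)
        for i, (n, d, v) in enumerate(DEFAULT_LAYER_PROFILE))
    dme = ClassTemplate(
        base=replace(
            base, label="DME",
            layer_profile=dme_profile,
            ripples=(BoundaryRipple("OPL-ONL", amplitude_px=4.0, periods=3.0),),
            his_spots=tuple(
                HisSpot(bscan=bs, row=136, col=c, radius_px=2.0)
                for bs, c in ((1, 30), (3, 64), (4, 96), (6, 48), (7, 80)))),
        jitter={"depth_shift": (-4, 4), "spot_col": (-8, 8),
                "ripple_amp": (-1, 1.5)},
    )
    return {"normal": normal, "AMD": amd, "DME": dme}


def phantom_cohort(n_per_class: int,
                   class_params: Optional[Dict[str, ClassTemplate]] = None,
                   seed: int = 0) -> List[Tuple[OCTVolume, GroundTruth]]:
    """Generate ``n_per_class`` jittered volumes per class, fully seeded."""
    if n_per_class < 1:
        raise RetoctError("n_per_class must be >= 1")
    if class_params is not None and not class_params:
        raise RetoctError("class_params must not be empty")
    templates = class_params if class_params is not None else default_class_templates()
    rng = np.random.default_rng(seed)
    cohort: List[Tuple[OCTVolume, GroundTruth]] = []
    for label in sorted(templates):
        template = templates[label]
        for _ in range(n_per_class):
            vol_seed = int(rng.integers(0, 2**31 - 1))
            spec = _jittered_spec(template, rng, vol_seed)
            cohort.append(generate_phantom(spec))
    return cohort
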