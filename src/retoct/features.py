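"""The ten structural / pathology features computed per eye.

Features: hyper-reflective intra-retinal spot (HIS) volume, drusen volume,
curviness of the MZ-EZ and OPL-ONL boundaries, and mean / 70th-percentile
thickness of the retina, the EZ-to-RBC complex and the RPE band.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import List, NamedTuple, Sequence, Tuple

import numpy as np
from scipy import ndimage

from .core import (
    LAYER_BANDS,
    Boundary,
    BoundarySet,
    FeatureVector,
    OCTVolume,
    PathologyMask,
    RetoctError,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CurvinessParams:
    """Constants of the curviness score.

    ``alpha``: deviations from the first-order fit below this many pixels are
    not penalised.  ``delta``: minimum max-min difference for a peak to count.
    """

    alpha: float = 3.0
    delta: float = 5.0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise RetoctError("alpha must be >= 0")
        if self.delta <= 0:
            raise RetoctError("delta must be > 0")


@dataclass(frozen=True)
class FeatureConfig:
    curviness: CurvinessParams = field(default_factory=CurvinessParams)
    drusen_ratio_threshold: float = 1.3
    drusen_dev_threshold_px: float = 3.0
    drusen_band_px: int = 3
    drusen_merge_gap: int = 2
    drusen_min_run: int = 2
    his_min_component_px: int = 0  # 0 disables the size filter
    thickness_sigma: float = 2.0
    # Upper boundary of the "EZ to RBC" complex; the outer photoreceptor
    # complex starts at the myoid/ellipsoid interface.
    complex_upper: str = "MZ-EZ"


class Extremum(NamedTuple):
    index: int
    value: float
    kind: str  # "max" | "min"


@dataclass(frozen=True)
class ThicknessMap:
    """Per-(B-scan, A-scan) thickness in micrometres."""

    values_um: np.ndarray  # shape (n_bscans, width)
    sigma: float

    def __post_init__(self) -> None:
        v = np.asarray(self.values_um, dtype=float)
        if v.ndim != 2:
            raise RetoctError("thickness map must be 2D")
        object.__setattr__(self, "values_um", v)


# ---------------------------------------------------------------------------
# band helpers


def _band_limits(upper: np.ndarray, lower: np.ndarray, depth: int) -> Tuple[np.ndarray, np.ndarray]:
    """Integer half-open row limits of a band given fractional boundaries."""
    r0 = np.clip(np.rint(upper).astype(int), 0, depth)
    r1 = np.clip(np.rint(lower).astype(int), 0, depth)
    return r0, np.maximum(r1, r0)


def _band_mask_2d(upper: np.ndarray, lower: np.ndarray, depth: int) -> np.ndarray:
    r0, r1 = _band_limits(upper, lower, depth)
    rows = np.arange(depth)[:, None]
    return (rows >= r0[None, :]) & (rows < r1[None, :])


def _band_pixels(volume: OCTVolume, boundaries: BoundarySet, layer: str) -> np.ndarray:
    upper_name, lower_name = LAYER_BANDS[layer]
    vals: List[np.ndarray] = []
    for b in boundaries.bscan_indices:
        up = boundaries.get(b, upper_name).positions
        lo = boundaries.get(b, lower_name).positions
        m = _band_mask_2d(up, lo, volume.depth_px)
        vals.append(volume.intensities[b][m])
    return np.concatenate(vals) if vals else np.array([])


def layer_mean_intensity(volume: OCTVolume, boundaries: BoundarySet, layer: str) -> float:
    """Mean intensity over one layer band, pooled across all B-scans."""
    px = _band_pixels(volume, boundaries, layer)
    if px.size == 0:
        raise RetoctError(f"layer {layer!r} band is empty (coincident boundaries?)")
    return float(px.mean())


# ---------------------------------------------------------------------------
# pathology detection


def detect_his(volume: OCTVolume, boundaries: BoundarySet,
               min_component_px: int = 0) -> PathologyMask:
    """Hyper-reflective intra-retinal spots.

    Pixels in the inner-retina band (IPL-INL down to ONL-ELM) brighter than
    the pooled mean intensity of the RNFL and RPE bands.
    """
    rnfl_rpe = np.concatenate([
        _band_pixels(volume, boundaries, "RNFL"),
        _band_pixels(volume, boundaries, "RPE"),
    ])
    if rnfl_rpe.size == 0:
        raise RetoctError("RNFL/RPE reference bands are empty")
    threshold = float(rnfl_rpe.mean())

    upper_name, lower_name = LAYER_BANDS["his_band"]
    mask = np.zeros(volume.intensities.shape, dtype=bool)
    for b in boundaries.bscan_indices:
        up = boundaries.get(b, upper_name).positions
        lo = boundaries.get(b, lower_name).positions
        band = _band_mask_2d(up, lo, volume.depth_px)
        mask[b] = band & (volume.intensities[b] > threshold)
    if min_component_px > 0:
        lab, n = ndimage.label(mask)
        sizes = ndimage.sum_labels(mask, lab, index=np.arange(1, n + 1))
        keep = np.zeros(n + 1, dtype=bool)
        keep[1:] = sizes >= min_component_px
        mask = keep[lab]
    return PathologyMask("HIS", mask, volume.voxel_dims)


def _candidate_runs(candidates: np.ndarray, merge_gap: int, min_run: int,
                    dev: Optional[np.ndarray] = None,
                    ext_threshold: float = 0.5) -> List[Tuple[int, int]]:
    """Maximal runs (half-open column spans) of candidate columns.

    When the deviation profile ``dev`` is given, each run is grown outward
    hysteresis-style while the deviation stays above ``ext_threshold`` so the
    shallow flanks of a detachment are not clipped.
    """
    cols = np.nonzero(candidates)[0]
    if cols.size == 0:
        return []
    runs: List[Tuple[int, int]] = []
    start = prev = int(cols[0])
    for c in cols[1:]:
        if c - prev <= merge_gap + 1:
            prev = int(c)
        else:
            runs.append((start, prev + 1))
            start = prev = int(c)
    runs.append((start, prev + 1))
    runs = [(a, b) for a, b in runs if b - a >= min_run]
    if dev is None:
        return runs
    grown: List[Tuple[int, int]] = []
    n = len(dev)
    for a, b in runs:
        while a > 0 and dev[a - 1] > ext_threshold:
            a -= 1
        while b < n and dev[b] > ext_threshold:
            b += 1
        if grown and a <= grown[-1][1]:
            grown[-1] = (grown[-1][0], b)
        else:
            grown.append((a, b))
    return grown


def detect_drusen(volume: OCTVolume, boundaries: BoundarySet,
                  ratio_threshold: float = 1.3,
                  dev_threshold_px: float = 3.0,
                  band_px: int = 3,
                  merge_gap: int = 2,
                  min_run: int = 2) -> PathologyMask:
    """Sub-RPE detachments (drusen).

    Per B-scan the ELM-to-RBC span ``T`` is fitted with a first-order
    polynomial.  Where the RPE floor is detached upward the span thins, so
    candidate columns are those where the fit exceeds ``T`` by more than
    ``dev_threshold_px``.  A candidate run is confirmed when the mean
    intensity of the ``band_px`` rows above the detached RPE floor (bright
    RPE) is more than ``ratio_threshold`` times the mean of the ``band_px``
    rows above the flat membrane baseline (hypo-reflective interior).  Mask
    pixels are those between the detached floor and the baseline.
    """
    mask = np.zeros(volume.intensities.shape, dtype=bool)
    depth = volume.depth_px
    for b in boundaries.bscan_indices:
        rbc = boundaries.get(b, "RBC").positions
        onl = boundaries.get(b, "ONL-ELM").positions
        width = len(rbc)
        if width < 2:
            raise RetoctError("drusen fit needs at least 2 A-scans")
        x = np.arange(width, dtype=float)
        t = rbc - onl
        fit = np.polyval(np.polyfit(x, t, 1), x)
        dev = fit - t  # positive where the RPE floor is lifted
        candidates = dev > dev_threshold_px
        runs = _candidate_runs(candidates, merge_gap, min_run, dev=dev)
        if not runs:
            continue
        in_run = np.zeros(width, dtype=bool)
        for a, z in runs:
            in_run[a:z] = True
        # Baseline membrane: straight line through the RPE floor outside runs.
        ref = ~in_run
        if ref.sum() >= 2:
            baseline = np.polyval(np.polyfit(x[ref], rbc[ref], 1), x)
        else:
            baseline = np.polyval(np.polyfit(x, rbc, 1), x)
        img = volume.intensities[b].astype(float)
        for a, z in runs:
            upper_vals: List[float] = []
            lower_vals: List[float] = []
            for i in range(a, z):
                rd = int(round(rbc[i]))
                rb = int(round(baseline[i]))
                upper_vals.extend(img[max(rd - band_px, 0):max(rd, 0), i])
                lower_vals.extend(img[max(rb - band_px, 0):max(rb, 0), i])
            if not upper_vals or not lower_vals:
                continue
            lower_mean = float(np.mean(lower_vals))
            ratio = float(np.mean(upper_vals)) / max(lower_mean, 1e-9)
            if ratio <= ratio_threshold:
                continue
            for i in range(a, z):
                r0 = int(round(rbc[i]))
                r1 = int(round(baseline[i]))
                if r1 > r0:
                    mask[b, max(r0, 0):min(r1, depth), i] = True
    return PathologyMask("drusen", mask, volume.voxel_dims)


def mask_volume(mask: PathologyMask) -> float:
    """Physical volume of a mask in mm^3 (voxel count x voxel volume)."""
    return mask.volume_mm3


# ---------------------------------------------------------------------------
# curviness (boundary non-straightness)


def alternating_extrema(series: Sequence[float]) -> List[Extremum]:
    """Strictly alternating local maxima / minima of a series.

    A value is a local maximum if it exceeds at least one neighbour and is
    not below any; minima symmetrically.  Plateaus collapse to an extremum
    at their first index; series endpoints are eligible.  A constant series
    yields the empty sequence.
    """
    s = np.asarray(series, dtype=float)
    if s.size < 3:
        raise RetoctError("series must have length >= 3")
    # collapse plateaus
    comp: List[Tuple[int, float]] = [(0, float(s[0]))]
    for i in range(1, s.size):
        if s[i] != comp[-1][1]:
            comp.append((i, float(s[i])))
    if len(comp) == 1:
        return []
    out: List[Extremum] = []
    for j, (idx, v) in enumerate(comp):
        left = comp[j - 1][1] if j > 0 else None
        right = comp[j + 1][1] if j < len(comp) - 1 else None
        if (left is None or v > left) and (right is None or v > right):
            kind = "max"
        elif (left is None or v < left) and (right is None or v < right):
            kind = "min"
        else:
            continue
        out.append(Extremum(idx, v, kind))
    # guard: collapse any same-kind neighbours to the more extreme one
    cleaned: List[Extremum] = []
    for e in out:
        if cleaned and cleaned[-1].kind == e.kind:
            if (e.kind == "max" and e.value > cleaned[-1].value) or (
                    e.kind == "min" and e.value < cleaned[-1].value):
                cleaned[-1] = e
        else:
            cleaned.append(e)
    return cleaned


def prune_extrema(lmm: Sequence[Extremum], delta: float) -> List[Extremum]:
    """Remove adjacent max-min pairs whose difference is below ``delta``.

    While any adjacent pair differs by less than ``delta``, the pair with the
    smallest absolute difference is removed (leftmost on ties).  The result
    alternates and all surviving adjacent differences are >= ``delta``.
    """
    seq = list(lmm)
    for i in range(1, len(seq)):
        if seq[i].kind == seq[i - 1].kind:
            raise RetoctError("prune_extrema requires an alternating sequence")
    while len(seq) >= 2:
        diffs = [abs(seq[i + 1].value - seq[i].value) for i in range(len(seq) - 1)]
        small = [i for i, d in enumerate(diffs) if d < delta]
        if not small:
            break
        best = min(small, key=lambda i: (diffs[i], i))
        del seq[best:best + 2]
    return seq


def curviness(b_rbc: Boundary, b_given: Boundary,
              params: CurvinessParams = CurvinessParams()) -> float:
    """Curviness score of ``b_given`` relative to the RPE/Bruch's floor.

    The height profile ``NL`` of the boundary above the RBC floor is fitted
    with a first-order polynomial; ``C1`` sums the absolute deviations that
    exceed ``alpha``; ``C2`` counts the local maxima of ``NL`` surviving the
    delta-pruning; the score is ``C1 * C2``.
    """
    if len(b_rbc) != len(b_given):
        raise RetoctError("boundaries must have equal length")
    nl = np.asarray(b_rbc.positions, dtype=float) - np.asarray(b_given.positions, dtype=float)
    if nl.size < 3:
        raise RetoctError("boundaries must have length >= 3")
    x = np.arange(nl.size, dtype=float)
    pnl1 = np.polyval(np.polyfit(x, nl, 1), x)
    df = np.abs(nl - pnl1)
    c1 = float(df[df > params.alpha].sum())
    lmm = alternating_extrema(nl)
    lmm = prune_extrema(lmm, params.delta)
    c2 = sum(1 for e in lmm if e.kind == "max")
    return c1 * c2


# ---------------------------------------------------------------------------
# thickness features


def thickness_profile(boundaries: BoundarySet, upper: str, lower: str,
                      sigma: float, axial_um_per_px: float) -> ThicknessMap:
    """Per-A-scan thickness (um) of a band, Gaussian-smoothed on the en-face grid."""
    up = boundaries.positions_grid(upper)
    lo = boundaries.positions_grid(lower)
    diff = lo - up
    if np.any(diff < 0):
        logger.warning("crossing boundaries %s/%s clamped at 0 in %d A-scans",
                       upper, lower, int((diff < 0).sum()))
        diff = np.maximum(diff, 0.0)
    t = diff * axial_um_per_px
    if sigma > 0:
        t = ndimage.gaussian_filter(t, sigma=sigma, mode="reflect")
    return ThicknessMap(t, sigma)


def thickness_stats(tmap: ThicknessMap) -> Tuple[float, float]:
    """Pooled mean and 70th percentile (linear interpolation between ranks)."""
    v = tmap.values_um.ravel()
    if v.size == 0:
        raise RetoctError("empty thickness map")
    return float(v.mean()), float(np.percentile(v, 70))


# ---------------------------------------------------------------------------
# assembly


def extract_features(volume: OCTVolume, boundaries: BoundarySet,
                     config: FeatureConfig = FeatureConfig()) -> FeatureVector:
    """Compute the full ten-feature vector for one volume."""
    axial = volume.voxel_dims[0]

    def _wrap(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except RetoctError as exc:
            raise RetoctError(f"feature {name!r}: {exc}") from exc

    his = _wrap("his_volume", detect_his, volume, boundaries,
                config.his_min_component_px)
    drusen = _wrap("drusen_volume", detect_drusen, volume, boundaries,
                   config.drusen_ratio_threshold, config.drusen_dev_threshold_px,
                   config.drusen_band_px, config.drusen_merge_gap,
                   config.drusen_min_run)

    curvs = {}
    for feat, name in (("curviness_mzez", "MZ-EZ"), ("curviness_oplonl", "OPL-ONL")):
        vals = []
        for b in boundaries.bscan_indices:
            vals.append(_wrap(feat, curviness, boundaries.get(b, "RBC"),
                              boundaries.get(b, name), config.curviness))
        curvs[feat] = float(np.mean(vals))

    stats = {}
    for key, (upper, lower) in (
            ("retina", LAYER_BANDS["retina"]),
            ("complex", (config.complex_upper, "RBC")),
            ("rpe", LAYER_BANDS["RPE"])):
        tmap = _wrap(key, thickness_profile, boundaries, upper, lower,
                     config.thickness_sigma, axial)
        stats[key] = thickness_stats(tmap)

    return FeatureVector(
        his_volume_mm3=mask_volume(his),
        drusen_volume_mm3=mask_volume(drusen),
        curviness_mzez=curvs["curviness_mzez"],
        curviness_oplonl=curvs["curviness_oplonl"],
        retina_mean_um=stats["retina"][0],
        retina_p70_um=stats["retina"][1],
        complex_mean_um=stats["complex"][0],
        complex_p70_um=stats["complex"][1],
        rpe_mean_um=stats["rpe"][0],
        rpe_p70_um=stats["rpe"][1],
    )
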