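"""Layer-boundary segmentation by shortest-path search over edge-pixel chains.

Per B-scan, Canny edge pixels of the right gradient polarity are grouped into
8-connected chains; chain end pixels become graph nodes.  Traversing a chain
is free, jumping between chains costs a weighted sum of the Euclidean gap,
the slope mismatch against a reference line, and how poorly the entered chain
matches the expected bright/dark profile of the target interface.  The
minimum-weight path from the virtual start A-scan to the virtual end A-scan
is the boundary.  Interfaces are detected in a fixed high-to-low contrast
order so earlier boundaries can bound the search region (ROI) of later ones,
and a cross-B-scan median correction repairs per-scan failures.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import ndimage
from scipy.interpolate import make_smoothing_spline
from skimage.feature import canny
from skimage.morphology import thin

from .core import (
    BOUNDARY_NAMES,
    DETECTION_ORDER,
    Boundary,
    BoundarySet,
    OCTVolume,
    RetoctError,
)

logger = logging.getLogger(__name__)


class BoundaryGapError(RetoctError):
    """No source-to-sink path through real evidence exists."""

    def __init__(self, gap_columns: Sequence[int]):
        self.gap_columns = list(gap_columns)
        super().__init__(f"boundary path disconnected; uncovered columns: "
                         f"{self.gap_columns[:10]}{'...' if len(self.gap_columns) > 10 else ''}")


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class BoundaryParams:
    """Search parameters for one interface.

    ``polarity`` is the sign of the axial gradient at the interface (+1 for a
    dark-above/bright-below transition).  ``roi_upper``/``roi_lower`` are
    ``(anchor boundary name, margin px)`` pairs evaluated against already
    detected boundaries; ``None`` means the image border.  ``expected_above``
    / ``expected_below`` are nominal intensities a few pixels either side of
    the interface, used for the non-associativity penalty (``None`` disables
    it).  ``reference`` names the boundary whose shape serves as slope
    reference (``None`` = horizontal).
    """

    polarity: int
    expected_above: Optional[float] = None
    expected_below: Optional[float] = None
    roi_upper: Optional[Tuple[str, float]] = None
    roi_lower: Optional[Tuple[str, float]] = None
    reference: Optional[str] = None


# Defaults reconstructed from the interface intensity profile of a typical
# macular B-scan; only the MZ-EZ polarity is prescribed, everything else is
# overridable configuration.
DEFAULT_BOUNDARY_PARAMS: Dict[str, BoundaryParams] = {
    "ILM-RNFL": BoundaryParams(+1, 10, 150),
    "RBC": BoundaryParams(-1, 200, 80, roi_upper=("ILM-RNFL", 20.0),
                          reference="ILM-RNFL"),
    "MZ-EZ": BoundaryParams(+1, 70, 180, roi_upper=("ILM-RNFL", 10.0),
                            roi_lower=("RBC", -12.0), reference="RBC"),
    "IZ-RPE": BoundaryParams(+1, 110, 200, roi_upper=("MZ-EZ", 4.0),
                             roi_lower=("RBC", -3.0), reference="RBC"),
    "OPL-ONL": BoundaryParams(-1, 130, 50, roi_upper=("ILM-RNFL", 10.0),
                              roi_lower=("MZ-EZ", -8.0), reference="MZ-EZ"),
    "ONL-ELM": BoundaryParams(-1, 50, 20, roi_upper=("OPL-ONL", 4.0),
                              roi_lower=("MZ-EZ", -4.0), reference="MZ-EZ"),
    "EZ-OSL": BoundaryParams(-1, 180, 110, roi_upper=("MZ-EZ", 2.0),
                             roi_lower=("IZ-RPE", -2.0), reference="IZ-RPE"),
    "ELM-MZ": BoundaryParams(+1, 20, 70, roi_upper=("ONL-ELM", 2.0),
                             roi_lower=("MZ-EZ", -2.0), reference="MZ-EZ"),
    "INL-OPL": BoundaryParams(+1, 40, 130, roi_upper=("ILM-RNFL", 4.0),
                              roi_lower=("OPL-ONL", -2.0), reference="OPL-ONL"),
    "IPL-INL": BoundaryParams(-1, 75, 40, roi_upper=("ILM-RNFL", 4.0),
                              roi_lower=("INL-OPL", -2.0), reference="INL-OPL"),
    "RNFL-GCL": BoundaryParams(-1, 150, 105, roi_upper=("ILM-RNFL", 4.0),
                               roi_lower=("IPL-INL", -2.0), reference="ILM-RNFL"),
    "GCL-IPL": BoundaryParams(-1, 105, 75, roi_upper=("RNFL-GCL", 2.0),
                              roi_lower=("IPL-INL", -2.0), reference="RNFL-GCL"),
}


@dataclass(frozen=True)
class SegmentationConfig:
    canny_sigma: float = 1.5
    canny_low_pct: float = 70.0
    canny_high_pct: float = 90.0
    w_distance: float = 1.0
    w_slope: float = 2.0
    w_assoc: float = 5.0
    profile_offset_px: int = 3
    fit: str = "spline"  # "spline" | "linear" | "none"
    max_dev_px: float = 5.0
    refine: bool = True
    boundary_params: Dict[str, BoundaryParams] = field(
        default_factory=lambda: dict(DEFAULT_BOUNDARY_PARAMS))


# ---------------------------------------------------------------------------
# edge detection and grouping


_STEP_RESPONSE_CACHE: Dict[float, float] = {}


def _unit_step_response(sigma: float) -> float:
    """Peak gradient-magnitude ridge of a unit-height axial step edge."""
    if sigma not in _STEP_RESPONSE_CACHE:
        n = int(np.ceil(4 * sigma)) * 2 + 9
        step = np.zeros((n, n))
        step[n // 2:, :] = 1.0
        sm = ndimage.gaussian_filter(step, sigma)
        mag = np.hypot(ndimage.sobel(sm, axis=1), ndimage.sobel(sm, axis=0))
        _STEP_RESPONSE_CACHE[sigma] = float(mag.max())
    return _STEP_RESPONSE_CACHE[sigma]


def detect_candidate_edges(bscan: np.ndarray, polarity: int,
                           sigma: float = 1.5,
                           low_pct: float = 70.0,
                           high_pct: float = 90.0,
                           roi: Optional[Tuple[np.ndarray, np.ndarray]] = None,
                           expected_step: Optional[float] = None) -> np.ndarray:
    """Canny edge pixels whose axial gradient sign matches ``polarity``.

    Hysteresis thresholds are percentiles of the gradient-magnitude
    distribution, restricted to the search band when ``roi`` (per-column
    min/max row arrays) is given.  When the nominal interface contrast
    ``expected_step`` is known, the high threshold is additionally capped at
    roughly half the ridge response of a step of that height so a faint
    target interface is not masked by stronger neighbours inside the band.
    """
    img = np.asarray(bscan, dtype=float)
    if img.size == 0:
        raise RetoctError("empty B-scan")
    smoothed = ndimage.gaussian_filter(img, sigma)
    gy = ndimage.sobel(smoothed, axis=0)
    gx = ndimage.sobel(smoothed, axis=1)
    mag = np.hypot(gx, gy)
    if roi is not None:
        rows = np.arange(img.shape[0])[:, None]
        roi_mask = (rows >= np.asarray(roi[0])[None, :]) & \
            (rows <= np.asarray(roi[1])[None, :])
        pool = mag[roi_mask]
    else:
        roi_mask = None
        pool = mag.ravel()
    pool = pool[pool > 1e-9]
    if pool.size == 0:
        return np.zeros(img.shape, dtype=bool)
    high = float(np.percentile(pool, high_pct))
    low = float(np.percentile(pool, low_pct))
    if expected_step is not None:
        cap = 0.55 * abs(expected_step) * _unit_step_response(sigma)
        high = min(high, cap)
    low = min(low, 0.5 * high)
    if high <= 0:
        return np.zeros(img.shape, dtype=bool)
    edges = canny(img, sigma=sigma, low_threshold=low, high_threshold=high)
    if roi_mask is not None:
        edges &= roi_mask
    edges &= (gy > 0) if polarity > 0 else (gy < 0)
    # NMS can leave 2-px-thick ridges on symmetric steps; thin them so the
    # chain grouping sees single-pixel curves instead of junction clutter.
    return thin(edges)


@dataclass(frozen=True, eq=False)
class PixelGroup:
    """An 8-connected chain of edge pixels (identity equality)."""

    pixels: np.ndarray  # (n, 2) array of (row, col) in traced order

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=int)
        if px.ndim != 2 or px.shape[1] != 2 or px.shape[0] == 0:
            raise RetoctError("pixel group must be a non-empty (n, 2) array")
        object.__setattr__(self, "pixels", px)

    @property
    def ends(self) -> Tuple[Tuple[int, int], Tuple[int, int]]:
        return tuple(self.pixels[0]), tuple(self.pixels[-1])

    @property
    def left_end(self) -> Tuple[int, int]:
        a, b = self.ends
        return min(a, b, key=lambda p: (p[1], p[0]))

    @property
    def right_end(self) -> Tuple[int, int]:
        a, b = self.ends
        return max(a, b, key=lambda p: (p[1], p[0]))

    def __len__(self) -> int:
        return len(self.pixels)


_NEIGH = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def group_edge_pixels(edge_map: np.ndarray) -> List[PixelGroup]:
    """Partition edge pixels into 8-connected chains, splitting at junctions.

    Chains are traced from free ends; a pixel with three or more neighbours
    terminates the chain that reaches it first, so branching structures split
    into separate chains at the junction.
    """
    coords = {(int(r), int(c)) for r, c in zip(*np.nonzero(edge_map))}
    if not coords:
        return []

    def _neighbours(p):
        out = []
        for dr, dc in _NEIGH:
            q = (p[0] + dr, p[1] + dc)
            if q not in coords:
                continue
            # drop a diagonal link when an orthogonal bridge pixel exists;
            # the connection survives through the bridge and junctions stay
            # single pixels
            if dr and dc and ((p[0] + dr, p[1]) in coords
                              or (p[0], p[1] + dc) in coords):
                continue
            out.append(q)
        return sorted(out)

    neigh = {p: _neighbours(p) for p in coords}
    degree = {p: len(ns) for p, ns in neigh.items()}
    visited: set = set()
    chains: List[List[Tuple[int, int]]] = []

    def trace(start: Tuple[int, int]) -> List[Tuple[int, int]]:
        chain = [start]
        current = start
        while True:
            if degree[current] >= 3 and len(chain) > 1:
                break  # junction consumed, stop here
            nxt = None
            for q in neigh[current]:
                if q not in visited:
                    nxt = q
                    break
            if nxt is None:
                break
            visited.add(nxt)
            chain.append(nxt)
            current = nxt
        return chain

    seeds = sorted(coords, key=lambda p: (degree[p] > 1, p))
    for seed in seeds:
        if seed in visited:
            continue
        visited.add(seed)
        forward = trace(seed)
        backward = trace(seed) if degree[seed] > 1 else [seed]
        chain = backward[:0:-1] + forward
        chains.append(chain)
    return [PixelGroup(np.array(c)) for c in chains]


# ---------------------------------------------------------------------------
# graph construction and search


@dataclass
class BoundaryGraph:
    """Weighted DAG over chain end pixels plus virtual source/sink."""

    groups: List[PixelGroup]
    width: int
    edges: Dict[object, List[Tuple[object, float]]]
    node_group: Dict[object, int]
    fallback_weight: float = 1e9

    SOURCE = "S"
    SINK = "T"


def _group_nonassoc(group: PixelGroup, image: Optional[np.ndarray],
                    expected_above: Optional[float],
                    expected_below: Optional[float],
                    offset: int) -> float:
    """Mean absolute deviation of the chain's context from the expected
    bright/dark profile, normalised to [0, 1]."""
    if image is None or expected_above is None or expected_below is None:
        return 0.0
    rows = group.pixels[:, 0]
    cols = group.pixels[:, 1]
    h = image.shape[0]
    above = image[np.clip(rows - offset, 0, h - 1), cols]
    below = image[np.clip(rows + offset, 0, h - 1), cols]
    dev = (np.abs(above - expected_above) + np.abs(below - expected_below)) / 2.0
    return float(dev.mean() / 255.0)


def build_boundary_graph(groups: Sequence[PixelGroup],
                         roi: Tuple[np.ndarray, np.ndarray],
                         reference: Optional[np.ndarray],
                         width: int,
                         image: Optional[np.ndarray] = None,
                         params: Optional[BoundaryParams] = None,
                         config: SegmentationConfig = SegmentationConfig()) -> BoundaryGraph:
    """Assemble the boundary search graph.

    ``roi`` is a pair of per-column (min row, max row) arrays, inclusive;
    groups with any pixel outside are excluded.  ``reference`` is a
    per-column position array whose local slope inter-chain jumps are
    compared against (``None`` = horizontal).
    """
    roi_min = np.asarray(roi[0], dtype=float)
    roi_max = np.asarray(roi[1], dtype=float)
    if np.any(roi_min > roi_max):
        raise RetoctError("ROI min row exceeds max row")

    kept: List[PixelGroup] = []
    for g in groups:
        r, c = g.pixels[:, 0], g.pixels[:, 1]
        if np.all((r >= roi_min[c]) & (r <= roi_max[c])):
            kept.append(g)

    exp_above = params.expected_above if params else None
    exp_below = params.expected_below if params else None
    # charged once on the edge entering a chain, proportional to the chain's
    # extent so a long wrong-level chain cannot undercut a fragmented correct
    # one
    nonassoc = [
        config.w_assoc * len(g) * _group_nonassoc(g, image, exp_above, exp_below,
                                                  config.profile_offset_px)
        for g in kept
    ]

    edges: Dict[object, List[Tuple[object, float]]] = {}
    node_group: Dict[object, int] = {}

    def add_edge(u, v, w):
        edges.setdefault(u, []).append((v, w))

    def node(gi: int, end: int):
        g = kept[gi]
        if tuple(g.pixels[0]) == tuple(g.pixels[-1]):
            end = 0
        key = (gi, end)
        node_group[key] = gi
        return key

    w_d, w_s = config.w_distance, config.w_slope

    def ref_slope(c1: int, c2: int) -> float:
        if reference is None or c2 == c1:
            return 0.0
        return float(reference[c2] - reference[c1]) / float(c2 - c1)

    for gi, g in enumerate(kept):
        ln = node(gi, 0)
        rn = node(gi, 1)
        if ln != rn:
            add_edge(ln, rn, 0.0)  # chain traversal is free
        lr, lc = g.left_end
        rr, rc = g.right_end
        add_edge(BoundaryGraph.SOURCE, ln, w_d * (lc + 1) + nonassoc[gi])
        add_edge(rn, BoundaryGraph.SINK, w_d * (width - rc))
        for gj, h in enumerate(kept):
            if gj == gi:
                continue
            qr, qc = h.left_end
            if qc <= rc:
                continue
            dist = float(np.hypot(qr - rr, qc - rc))
            slope = (qr - rr) / (qc - rc)
            w = w_d * dist + w_s * abs(slope - ref_slope(rc, qc)) + nonassoc[gj]
            add_edge(rn, node(gj, 0), w)

    add_edge(BoundaryGraph.SOURCE, BoundaryGraph.SINK, 1e9)
    return BoundaryGraph(groups=kept, width=width, edges=edges,
                         node_group=node_group)


def shortest_boundary_path(graph: BoundaryGraph) -> List[PixelGroup]:
    """Minimum-weight source-to-sink path, returned as its chain sequence.

    Returns an empty list when the graph holds no evidence at all; raises
    :class:`BoundaryGapError` when chains exist but cannot be linked.
    """
    if not graph.groups:
        return []
    order = {BoundaryGraph.SOURCE: 0, BoundaryGraph.SINK: 1}
    for key in sorted(graph.node_group, key=lambda k: (k[0], k[1])):
        order[key] = len(order)

    dist: Dict[object, float] = {BoundaryGraph.SOURCE: 0.0}
    prev: Dict[object, object] = {}
    heap = [(0.0, 0, BoundaryGraph.SOURCE)]
    done: set = set()
    while heap:
        d, _, u = heapq.heappop(heap)
        if u in done:
            continue
        done.add(u)
        if u == BoundaryGraph.SINK:
            break
        for v, w in graph.edges.get(u, ()):
            nd = d + w
            if nd < dist.get(v, np.inf):
                dist[v] = nd
                prev[v] = u
                heapq.heappush(heap, (nd, order[v], v))

    if BoundaryGraph.SINK not in prev:
        raise BoundaryGapError(_uncovered_columns(graph))
    path: List[object] = [BoundaryGraph.SINK]
    while path[-1] != BoundaryGraph.SOURCE:
        path.append(prev[path[-1]])
    path.reverse()
    if len(path) == 2:  # fell through the fallback edge
        raise BoundaryGapError(_uncovered_columns(graph))
    gids: List[int] = []
    for n in path[1:-1]:
        gi = graph.node_group[n]
        if not gids or gids[-1] != gi:
            gids.append(gi)
    return [graph.groups[gi] for gi in gids]


def _uncovered_columns(graph: BoundaryGraph) -> List[int]:
    covered = np.zeros(graph.width, dtype=bool)
    for g in graph.groups:
        covered[g.pixels[:, 1]] = True
    return [int(c) for c in np.nonzero(~covered)[0]]


# ---------------------------------------------------------------------------
# boundary reconstruction


def _subpixel_rows(pixels: np.ndarray, axial_grad: np.ndarray) -> np.ndarray:
    """Parabolic sub-pixel ridge localisation along the axial gradient.

    The interface row convention (first pixel of the layer below) puts the
    true boundary half a pixel below the gradient ridge, hence the +0.5.
    """
    h = axial_grad.shape[0]
    r = pixels[:, 0]
    c = pixels[:, 1]
    rm = np.clip(r - 1, 0, h - 1)
    rp = np.clip(r + 1, 0, h - 1)
    m0 = axial_grad[rm, c]
    m1 = axial_grad[r, c]
    m2 = axial_grad[rp, c]
    denom = m0 - 2.0 * m1 + m2
    offset = np.zeros(len(r))
    ok = np.abs(denom) > 1e-12
    offset[ok] = 0.5 * (m0[ok] - m2[ok]) / denom[ok]
    offset = np.clip(offset, -1.0, 1.0)
    return r + offset + 0.5


def reconstruct_boundary(path_groups: Sequence[PixelGroup], width: int,
                         fit: str = "spline", name: str = "",
                         bscan_index: int = 0,
                         depth: Optional[int] = None,
                         axial_grad: Optional[np.ndarray] = None) -> Boundary:
    """Per-column positions from path pixels; gaps filled by the curve fit.

    ``axial_grad`` (the signed axial gradient oriented so the target ridge is
    a maximum) enables sub-pixel ridge localisation before fitting.
    """
    if not path_groups:
        raise RetoctError("empty path")
    pixels = np.concatenate([g.pixels for g in path_groups])
    if axial_grad is not None:
        subrows = _subpixel_rows(pixels, axial_grad)
    else:
        subrows = pixels[:, 0].astype(float)
    cols, inverse = np.unique(pixels[:, 1], return_inverse=True)
    rows = np.zeros(cols.size)
    counts = np.bincount(inverse)
    np.add.at(rows, inverse, subrows)
    rows /= counts

    x = np.arange(width, dtype=float)
    if fit == "spline" and cols.size >= 5:
        spl = make_smoothing_spline(cols.astype(float), rows)
        positions = np.asarray(spl(x), dtype=float)
        # constant extension outside the evidence span: spline extrapolation
        # is unreliable there
        positions[x < cols[0]] = spl(float(cols[0]))
        positions[x > cols[-1]] = spl(float(cols[-1]))
    else:
        positions = np.interp(x, cols.astype(float), rows)
    if depth is not None:
        positions = np.clip(positions, 0.0, depth - 1.0)
    return Boundary(name, positions, bscan_index)


# ---------------------------------------------------------------------------
# volume segmentation


def _roi_arrays(name: str, params: BoundaryParams,
                found: Dict[str, np.ndarray], depth: int,
                width: int) -> Tuple[np.ndarray, np.ndarray]:
    if params.roi_upper is None:
        rmin = np.zeros(width)
    else:
        anchor, margin = params.roi_upper
        rmin = found[anchor] + margin
    if params.roi_lower is None:
        rmax = np.full(width, depth - 1.0)
    else:
        anchor, margin = params.roi_lower
        rmax = found[anchor] + margin
    rmin = np.clip(rmin, 0, depth - 1)
    rmax = np.clip(rmax, 0, depth - 1)
    rmax = np.maximum(rmax, rmin)
    return rmin, rmax


def segment_bscan(bscan: np.ndarray, config: SegmentationConfig = SegmentationConfig(),
                  bscan_index: int = 0) -> Dict[str, Optional[np.ndarray]]:
    """Detect all twelve interfaces in one B-scan (``None`` where it failed)."""
    img = np.asarray(bscan, dtype=float)
    depth, width = img.shape
    gy = ndimage.sobel(ndimage.gaussian_filter(img, config.canny_sigma), axis=0)
    found: Dict[str, np.ndarray] = {}
    out: Dict[str, Optional[np.ndarray]] = {}
    for name in DETECTION_ORDER:
        params = config.boundary_params[name]
        anchors_ok = all(
            anchor in found
            for anchor in [a[0] for a in (params.roi_upper, params.roi_lower)
                           if a is not None])
        if not anchors_ok:
            out[name] = None
            continue
        rmin, rmax = _roi_arrays(name, params, found, depth, width)
        rmin, rmax = np.floor(rmin), np.ceil(rmax)
        step = None
        if params.expected_above is not None and params.expected_below is not None:
            step = params.expected_below - params.expected_above
        masked = detect_candidate_edges(
            img, params.polarity, config.canny_sigma,
            config.canny_low_pct, config.canny_high_pct,
            roi=(rmin, rmax), expected_step=step)
        groups = group_edge_pixels(masked)
        ref = found.get(params.reference) if params.reference else None
        graph = build_boundary_graph(groups, (rmin, rmax), ref, width,
                                     image=img, params=params, config=config)
        try:
            path = shortest_boundary_path(graph)
        except BoundaryGapError as exc:
            logger.warning("B-scan %d: %s unrecoverable (%s)", bscan_index, name, exc)
            out[name] = None
            continue
        if not path:
            logger.warning("B-scan %d: no edge evidence for %s", bscan_index, name)
            out[name] = None
            continue
        boundary = reconstruct_boundary(path, width, config.fit, name,
                                        bscan_index, depth,
                                        axial_grad=gy * params.polarity)
        found[name] = boundary.positions
        out[name] = boundary.positions
    return out


def _enforce_ordering(per_name: Dict[str, np.ndarray]) -> None:
    prev = None
    for name in BOUNDARY_NAMES:
        cur = per_name[name]
        if prev is not None:
            np.maximum(cur, prev, out=cur)
        prev = cur


def segment_volume(volume: OCTVolume,
                   config: SegmentationConfig = SegmentationConfig()) -> BoundarySet:
    """Detect the twelve boundaries in every B-scan of a volume.

    Boundaries that cannot be recovered in a B-scan are filled from the
    nearest B-scan where they were found (with a logged warning); the
    anatomical depth ordering is enforced per A-scan.
    """
    nb = volume.n_bscans
    raw: List[Dict[str, Optional[np.ndarray]]] = []
    for b in range(nb):
        raw.append(segment_bscan(volume.intensities[b], config, b))

    for name in BOUNDARY_NAMES:
        have = [b for b in range(nb) if raw[b][name] is not None]
        if not have:
            raise RetoctError(f"boundary {name} unrecoverable in every B-scan")
        for b in range(nb):
            if raw[b][name] is None:
                nearest = min(have, key=lambda h: abs(h - b))
                logger.warning("B-scan %d: filling %s from B-scan %d", b, name, nearest)
                raw[b][name] = raw[nearest][name].copy()

    result = BoundarySet()
    for b in range(nb):
        per_name = {name: raw[b][name].copy() for name in BOUNDARY_NAMES}
        _enforce_ordering(per_name)
        for name in BOUNDARY_NAMES:
            result.add(Boundary(name, per_name[name], b))
    if config.refine and nb >= 2:
        result = refine_across_bscans(result, config.max_dev_px)
    return result


def refine_across_bscans(raw: BoundarySet, max_dev_px: float = 5.0) -> BoundarySet:
    """Replace positions deviating from the adjacent-B-scan median.

    For every boundary and A-scan, a position farther than ``max_dev_px``
    from the median of the same boundary in the adjacent B-scans is replaced
    by that median.  Identity on single-B-scan sets; idempotent on sets that
    are already consistent.
    """
    bscans = raw.bscan_indices
    if len(bscans) < 2:
        return raw.copy()
    out = BoundarySet()
    for name in raw.names(bscans[0]):
        grid = raw.positions_grid(name)
        fixed = grid.copy()
        nb = grid.shape[0]
        for i in range(nb):
            neigh = [j for j in (i - 1, i + 1) if 0 <= j < nb]
            med = np.median(grid[neigh], axis=0)
            bad = np.abs(grid[i] - med) > max_dev_px
            fixed[i, bad] = med[bad]
        for i, b in enumerate(bscans):
            out.add(Boundary(name, fixed[i], b))
    return out
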