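import numpy as np
import pytest

from retoct import phantom


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free default phantom (3 B-scans) with ground truth."""
    spec = phantom.PhantomSpec(n_bscans=3, noise_sd=0.0, seed=1)
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def noisy_phantom():
    spec = phantom.PhantomSpec(n_bscans=3, noise_sd=8.0, seed=2)
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def drusen_phantom():
    spec = phantom.PhantomSpec(
        n_bscans=3, noise_sd=0.0, seed=3,
        drusen_bumps=(phantom.DrusenBump(0, 3, center_col=60,
                                         radius_px=14, height_px=14),))
    return phantom.generate_phantom(spec)


@pytest.fixture(scope="session")
def dme_phantom():
    base = phantom.default_class_templates()["DME"].base
    spec = phantom.PhantomSpec(**{**base.__dict__, "noise_sd": 0.0, "seed": 4})
    return phantom.generate_phantom(spec)


def brute_force_curviness(nl, alpha=3.0, delta=5.0):
    """Straight-line reimplementation of the curviness score, used as oracle.

    Least squares by normal equations, extrema by literal neighbourhood scan,
    pruning by literal repeated smallest-pair removal.
    """
    nl = [float(v) for v in nl]
    n = len(nl)
    xs = list(range(n))
    sx = sum(xs); sy = sum(nl)
    sxx = sum(x * x for x in xs); sxy = sum(x * y for x, y in zip(xs, nl))
    denom = n * sxx - sx * sx
    slope = (n * sxy - sx * sy) / denom
    intercept = (sy - slope * sx) / n
    c1 = 0.0
    for i, v in enumerate(nl):
        df = abs(v - (slope * i + intercept))
        if df > alpha:
            c1 += df

    # plateau-collapsed series with first-index bookkeeping
    comp = [(0, nl[0])]
    for i in range(1, n):
        if nl[i] != comp[-1][1]:
            comp.append((i, nl[i]))
    lmm = []
    for j, (idx, v) in enumerate(comp):
        left = comp[j - 1][1] if j > 0 else None
        right = comp[j + 1][1] if j < len(comp) - 1 else None
        if (left is None or v > left) and (right is None or v > right):
            lmm.append((idx, v, "max"))
        elif (left is None or v < left) and (right is None or v < right):
            lmm.append((idx, v, "min"))
    while len(lmm) >= 2:
        diffs = [abs(lmm[i + 1][1] - lmm[i][1]) for i in range(len(lmm) - 1)]
        candidates = [i for i, d in enumerate(diffs) if d < delta]
        if not candidates:
            break
        best = min(candidates, key=lambda i: (diffs[i], i))
        del lmm[best:best + 2]
    c2 = sum(1 for _, _, k in lmm if k == "max")
    return c1 * c2
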