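"""Shared fixtures: phantoms are expensive, so they are session-scoped."""

from fractions import Fraction

import numpy as np
import pytest

from canalvol.phantom import (PhantomSpec, calibrate_extent,
                              generate_labyrinth, generate_pair)
from canalvol.segmentation import ROIBox


def roi_box(d: dict) -> ROIBox:
    return ROIBox(tuple(d["lower"]), tuple(d["upper"]))


def dice(a: np.ndarray, b: np.ndarray) -> float:
    a = a.astype(bool)
    b = b.astype(bool)
    return 2.0 * (a & b).sum() / (a.sum() + b.sum())


def otsu_exhaustive_exact(x: np.ndarray, nbins: int = 256) -> float:
    """Independent Otsu oracle: exhaustive search over all interior bin
    edges maximizing w0*w1*(mu0-mu1)^2, scored in exact rational
    arithmetic, lowest maximizer on ties."""
    x = np.asarray(x, dtype=float).ravel()
    counts, edges = np.histogram(x, bins=nbins, range=(x.min(), x.max()))
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = int(counts.sum())
    total = sum(Fraction(int(c)) * Fraction(float(m))
                for c, m in zip(counts, centers))
    best_k, best_s = 0, Fraction(-1)
    w0 = 0
    s0 = Fraction(0)
    for k in range(nbins - 1):
        w0 += int(counts[k])
        s0 += Fraction(int(counts[k])) * Fraction(float(centers[k]))
        if w0 == 0 or w0 == n:
            s = Fraction(0)
        else:
            # w0*w1*(mu0-mu1)^2 up to the constant factor n^2
            s = ((Fraction(n) * s0 - Fraction(w0) * total) ** 2
                 / (Fraction(w0) * Fraction(n - w0)))
        if s > best_s:
            best_s, best_k = s, k
    return float(edges[best_k + 1])


@pytest.fixture(scope="session")
def noiseless_phantom():
    spec = PhantomSpec(noise_sd=0.0)
    pre, fluid = generate_labyrinth(spec)
    return spec, pre, fluid


@pytest.fixture(scope="session")
def pair_5pct():
    extent = calibrate_extent(PhantomSpec(), 5.0)
    return generate_pair(PhantomSpec(plug_extent_deg=extent, seed=7))


@pytest.fixture(scope="session")
def result_5pct(pair_5pct):
    import warnings

    from canalvol.volumetry import quantify_pre_post
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return quantify_pre_post(
            pair_5pct.pre, pair_5pct.post,
            roi_box(pair_5pct.truth["roi_operated"]),
            roi_box(pair_5pct.truth["keep_region"]))
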