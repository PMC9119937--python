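"""Monotone nonlinear retention-time alignment of a run onto the library axis.

Before tight 3D matching, the run's RT axis must be warped onto the library's
reference axis.  High-confidence anchors — features with exactly one
mass-compatible library candidate inside a coarse 10-minute window — are fit
with robust local regression (LOWESS) and then projected onto the monotone
cone by isotonic regression, giving a non-decreasing piecewise-linear map
that interpolates inside the anchor span and extrapolates linearly outside.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import isotonic_regression
from statsmodels.nonparametric.smoothers_lowess import lowess

from .feature_finder import Ms1Feature
from .tag_library import SpectralLibrary, neutral_mass

logger = logging.getLogger("tiffms")

MIN_ANCHORS = 5


class AlignmentError(RuntimeError):
    """Raised when too few or degenerate anchors make alignment infeasible."""


@dataclass(frozen=True)
class Anchor:
    """A high-confidence (feature, library entry) RT correspondence."""

    feature_id: str
    entry_key: tuple
    rt_run: float      # minutes, run axis
    rt_lib: float      # minutes, library axis
    weight: float      # log10 feature intensity

    def __post_init__(self):
        if self.weight <= 0:
            raise ValueError("anchor weight must be positive")


@dataclass
class AlignmentModel:
    """Monotone piecewise-linear map from run RT to library RT."""

    knots_run: np.ndarray
    knots_lib: np.ndarray
    residual_sd: float
    n_anchors: int

    def predict(self, rt: float | np.ndarray) -> float | np.ndarray:
        """Interpolate within the knot range; extrapolate linearly outside."""
        x, y = self.knots_run, self.knots_lib
        scalar = np.isscalar(rt)
        t = np.atleast_1d(np.asarray(rt, dtype=float))
        out = np.interp(t, x, y)
        if x.size >= 2:
            lo_slope = _edge_slope(x, y, 0)
            hi_slope = _edge_slope(x, y, -1)
            below = t < x[0]
            above = t > x[-1]
            out[below] = y[0] + lo_slope * (t[below] - x[0])
            out[above] = y[-1] + hi_slope * (t[above] - x[-1])
        return float(out[0]) if scalar else out

    def in_span(self, rt: float) -> bool:
        return self.knots_run[0] <= rt <= self.knots_run[-1]

    @classmethod
    def identity(cls) -> "AlignmentModel":
        return cls(knots_run=np.array([0.0, 1.0]), knots_lib=np.array([0.0, 1.0]),
                   residual_sd=0.0, n_anchors=0)


def _edge_slope(x: np.ndarray, y: np.ndarray, end: int) -> float:
    """Terminal slope over the outer ~10% of the knot span (>= 2 knots)."""
    span = x[-1] - x[0]
    if span <= 0:
        return 1.0
    if end == 0:
        mask = x <= x[0] + max(0.1 * span, 1e-9)
    else:
        mask = x >= x[-1] - max(0.1 * span, 1e-9)
    xs, ys = x[mask], y[mask]
    if xs.size < 2 or xs[-1] == xs[0]:
        return 1.0
    return float((ys[-1] - ys[0]) / (xs[-1] - xs[0]))


def select_anchors(features: list[Ms1Feature], library: SpectralLibrary,
                   coarse_rt_window: float = 10.0, ppm_tol: float = 6.0,
                   min_charge: int = 2) -> list[Anchor]:
    """Pick unambiguous (feature, entry) pairs for alignment fitting.

    A feature anchors iff exactly one library entry (same charge, same CV
    when both annotated) lies within ``ppm_tol`` of its neutral mass and
    within the coarse RT window of its raw apex RT.  Entries claimed by more
    than one feature are discarded (unique on both sides).
    """
    candidates: dict[str, tuple] = {}
    for f in sorted(features, key=lambda f: f.feature_id):
        if f.charge < min_charge:
            continue
        mass = neutral_mass(f.mono_mz, f.charge)
        tol = mass * ppm_tol * 1e-6
        hits = [
            e for e in library.query_mass_window(f.cv, mass - tol, mass + tol,
                                                 any_cv=f.cv is None)
            if e.charge == f.charge and abs(f.rt_apex - e.ref_rt) <= coarse_rt_window
        ]
        if len(hits) == 1:
            candidates[f.feature_id] = (f, hits[0])

    entry_claims: dict[tuple, list[str]] = {}
    for fid, (_, entry) in candidates.items():
        entry_claims.setdefault(entry.key, []).append(fid)

    anchors = []
    for fid, (f, entry) in candidates.items():
        if len(entry_claims[entry.key]) != 1:
            continue
        anchors.append(Anchor(
            feature_id=fid, entry_key=entry.key,
            rt_run=f.rt_apex, rt_lib=entry.ref_rt,
            weight=math.log10(max(f.intensity, 10.0))))
    anchors.sort(key=lambda a: (a.rt_run, a.feature_id))
    if len(anchors) < MIN_ANCHORS:
        raise AlignmentError(
            f"only {len(anchors)} anchors found (need >= {MIN_ANCHORS}); "
            "alignment infeasible — caller may fall back to identity")
    return anchors


def fit_alignment(anchors: list[Anchor], span: float = 0.3) -> AlignmentModel:
    """Robust LOWESS through the anchors, isotonized to enforce monotonicity.

    ``span`` is the LOWESS smoothing fraction.  The residual scale is the
    robust normal-consistent MAD estimate, 1.4826 * median |residual|.
    """
    if len(anchors) < MIN_ANCHORS:
        raise AlignmentError(f"need >= {MIN_ANCHORS} anchors, got {len(anchors)}")
    x = np.asarray([a.rt_run for a in anchors])
    y = np.asarray([a.rt_lib for a in anchors])
    if np.ptp(x) == 0:
        raise AlignmentError("degenerate anchors: all at the same run RT")

    smoothed = lowess(y, x, frac=span, it=2, return_sorted=True)
    xs, ys = smoothed[:, 0], smoothed[:, 1]
    # collapse duplicate abscissae (lowess keeps them) before isotonization
    ux, inverse = np.unique(xs, return_inverse=True)
    uy = np.bincount(inverse, weights=ys) / np.bincount(inverse)
    iso = isotonic_regression(uy).x

    model = AlignmentModel(knots_run=ux, knots_lib=iso,
                           residual_sd=0.0, n_anchors=len(anchors))
    resid = y - model.predict(x)
    model.residual_sd = float(1.4826 * np.median(np.abs(resid)))
    return model


def apply_alignment(model: AlignmentModel, features: list[Ms1Feature]) -> list[Ms1Feature]:
    """Set ``rt_aligned`` on each feature (original rt_apex retained).

    Features outside the anchor span are flagged ``extrapolated``.
    """
    for f in features:
        f.rt_aligned = float(model.predict(f.rt_apex))
        f.extrapolated = not model.in_span(f.rt_apex)
    return features
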