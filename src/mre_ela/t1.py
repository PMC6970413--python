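"""Saturation-recovery T1 mapping and GBCA uptake metrics.

The voxel model is the 2-parameter saturation recovery curve

    S(TR) = S0 * (1 - exp(-TR / T1))

fitted by nonlinear least squares on the magnitude signal.  A 3-parameter
variant with an offset term ``S(TR) = S0*(1 - exp(-TR/T1)) + c`` is available
behind the ``model`` flag.  Whole-brain contrast metrics:

* ``delta_t1``: mean pre-contrast T1 minus mean post-contrast T1 over
  per-slice brain masks (positive delta = contrast uptake);
* ``signal_intensity_change``: SI% = (post - pre)/pre * 100 on across-slice
  mean signal intensities.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import curve_fit

from .containers import T1Map, T1Series

__all__ = [
    "fit_t1_map",
    "delta_t1",
    "signal_intensity_change",
    "slice_masked_means",
]

T1_BOUNDS_MS = (1.0, 10000.0)


def _sr2(tr, s0, t1):
    return s0 * (1.0 - np.exp(-tr / t1))


def _sr3(tr, s0, t1, c):
    return s0 * (1.0 - np.exp(-tr / t1)) + c


def _initial_t1(tr: np.ndarray, s: np.ndarray, s0: float) -> float:
    """Log-linearised initial T1 from the first two recovery points."""
    with np.errstate(divide="ignore", invalid="ignore"):
        y = 1.0 - s[:2] / s0
    if np.all(y > 0):
        lny = np.log(y)
        denom = lny[0] - lny[1]
        if denom > 0:
            return float((tr[1] - tr[0]) / denom)
    return float(np.median(tr))


def _fit_voxel(tr: np.ndarray, s: np.ndarray, model: str) -> Tuple[float, float, bool]:
    s0_init = float(s[-1])
    if not np.isfinite(s).all() or np.ptp(s) <= 0 or s0_init <= 0:
        return np.nan, np.nan, False  # flat or degenerate recovery: T1 unidentifiable
    t1_init = np.clip(_initial_t1(tr, s, s0_init), *T1_BOUNDS_MS)
    try:
        if model == "3param":
            popt, _ = curve_fit(
                _sr3,
                tr,
                s,
                p0=(s0_init, t1_init, 0.0),
                bounds=([0.0, T1_BOUNDS_MS[0], -np.inf], [np.inf, T1_BOUNDS_MS[1], np.inf]),
                maxfev=2000,
            )
        else:
            popt, _ = curve_fit(
                _sr2,
                tr,
                s,
                p0=(s0_init, t1_init),
                bounds=([0.0, T1_BOUNDS_MS[0]], [np.inf, T1_BOUNDS_MS[1]]),
                maxfev=2000,
            )
    except (RuntimeError, ValueError):
        return np.nan, np.nan, False
    s0, t1 = float(popt[0]), float(popt[1])
    ok = T1_BOUNDS_MS[0] < t1 < T1_BOUNDS_MS[1]
    return t1, s0, ok


def fit_t1_map(series: T1Series, model: str = "2param", mask: np.ndarray | None = None) -> T1Map:
    """Voxelwise nonlinear least-squares T1 fit.

    Initialisation: ``S0`` from the longest-TR signal, T1 from the
    log-linearised first two points.  Voxels failing convergence or with T1
    outside (1, 10000) ms are flagged not-ok.  ``mask`` (per slice or shared)
    restricts the fit; unmasked voxels are flagged not-ok.
    """
    if model not in ("2param", "3param"):
        raise ValueError("model must be '2param' or '3param'")
    min_tr = 3 if model == "2param" else 4
    if series.n_tr < min_tr:
        raise ValueError(f"need at least {min_tr} TRs for a {model} fit")
    tr = series.tr_list
    shape = series.data.shape[:-1]
    if mask is None:
        fit_sel = np.ones(shape, dtype=bool)
    else:
        mask = np.asarray(mask, dtype=bool)
        fit_sel = np.broadcast_to(mask, shape)
    t1 = np.full(shape, np.nan)
    s0 = np.full(shape, np.nan)
    ok = np.zeros(shape, dtype=bool)
    flat = series.data.reshape(-1, series.n_tr)
    t1f, s0f, okf = t1.reshape(-1), s0.reshape(-1), ok.reshape(-1)
    for idx in np.flatnonzero(fit_sel.reshape(-1)):
        t1f[idx], s0f[idx], okf[idx] = _fit_voxel(tr, flat[idx], model)
    return T1Map(t1=t1, s0=s0, fit_ok=ok)


def _per_slice_masks(masks: np.ndarray, n_slices: int, shape2d) -> np.ndarray:
    m = np.asarray(masks, dtype=bool)
    if m.ndim == 2:
        m = np.broadcast_to(m, (n_slices, *shape2d))
    if m.shape != (n_slices, *shape2d):
        raise ValueError("mask shape does not match the map geometry")
    return m


def delta_t1(pre_map: T1Map, post_map: T1Map, brain_masks: np.ndarray) -> float:
    """Whole-brain delta-T1 in ms: mean pre-contrast minus mean post-contrast.

    Per slice, the mask-mean T1 over successfully fitted voxels; slice means
    are averaged unweighted (each slice counts once); the post-contrast
    across-slice mean is subtracted from the pre-contrast one.  Positive
    values indicate gadolinium uptake.
    """
    if pre_map.t1.shape != post_map.t1.shape:
        raise ValueError("pre and post T1 map geometries differ")
    n_slices = pre_map.t1.shape[0]
    masks = _per_slice_masks(brain_masks, n_slices, pre_map.t1.shape[1:])

    def _mean(m: T1Map) -> float:
        means = []
        for s in range(n_slices):
            sel = masks[s] & m.fit_ok[s]
            if not sel.any():
                raise ValueError(f"empty brain mask (or no valid fits) on slice {s}")
            means.append(float(m.t1[s][sel].mean()))
        return float(np.mean(means))

    return _mean(pre_map) - _mean(post_map)


def slice_masked_means(images: np.ndarray, masks: np.ndarray) -> np.ndarray:
    """Per-slice mask-mean signal intensity of a (slices, rows, cols) stack."""
    img = np.asarray(images, dtype=float)
    if img.ndim == 2:
        img = img[None]
    masks = _per_slice_masks(masks, img.shape[0], img.shape[1:])
    out = []
    for s in range(img.shape[0]):
        if not masks[s].any():
            raise ValueError(f"empty brain mask on slice {s}")
        out.append(float(img[s][masks[s]].mean()))
    return np.asarray(out)


def signal_intensity_change(pre_si: Sequence[float], post_si: Sequence[float]) -> float:
    """SI% = [(SI post-contrast - SI pre-contrast) / SI pre-contrast] * 100.

    Inputs are per-slice masked mean signal intensities; the formula is
    applied to the across-slice means.
    """
    pre = np.asarray(pre_si, dtype=float)
    post = np.asarray(post_si, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post slice counts differ")
    pre_mean = pre.mean()
    if pre_mean <= 0:
        raise ValueError("pre-contrast mean signal must be positive")
    return float((post.mean() - pre_mean) / pre_mean * 100.0)
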