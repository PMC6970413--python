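"""Phase-image processing: ±MSG subtraction, unwrapping, temporal harmonic
extraction, Butterworth band-pass and directional filtering.

Pipeline order (asserted by provenance): phase_difference -> unwrap_phase ->
temporal_harmonic -> butterworth_bandpass -> directional_filter.

Spectral conventions
--------------------
Spatial wavenumbers are spatial frequencies in cycles/m (``numpy.fft.fftfreq``
with the pixel spacing).  With the temporal convention
``s(t) = Re[U exp(+i omega t)]`` a wave propagating toward the unit direction
``d`` appears as ``U ∝ exp(-i 2*pi*k_r d.x)`` and therefore occupies the
spectral half-plane ``kappa . d < 0``; the directional filter keeps that
half-plane.  Image row 0 is the top of the field of view, so "bottom-to-top"
propagation means decreasing row index.
"""

from __future__ import annotations

import numpy as np
from skimage.restoration import unwrap_phase as _unwrap2d

from .containers import ComplexWaveField, PhaseImageSeries
from .synthetic import wrap_phase

__all__ = [
    "phase_difference",
    "unwrap_phase",
    "temporal_harmonic",
    "butterworth_bandpass",
    "directional_filter",
    "DIRECTIONS",
]

# propagation direction -> unit vector in (row, col) index space
DIRECTIONS = {
    "bottom_to_top": (-1.0, 0.0),
    "top_to_bottom": (1.0, 0.0),
    "left_to_right": (0.0, 1.0),
    "right_to_left": (0.0, -1.0),
}


def phase_difference(pos: PhaseImageSeries, neg: PhaseImageSeries) -> PhaseImageSeries:
    """Subtract the two MSG polarities and rewrap to ``(-pi, pi]``.

    Static phase contributions cancel; motion-encoded phase doubles.
    """
    if pos.data.shape != neg.data.shape:
        raise ValueError(f"shape mismatch: {pos.data.shape} vs {neg.data.shape}")
    if pos.drive_frequency != neg.drive_frequency:
        raise ValueError("drive frequency mismatch between MSG polarities")
    if pos.pixel_spacing != neg.pixel_spacing:
        raise ValueError("pixel spacing mismatch between MSG polarities")
    if pos.msg_sign * neg.msg_sign != -1:
        raise ValueError("series must carry opposite MSG signs")
    if pos.msg_sign < 0:
        pos, neg = neg, pos
    diff = wrap_phase(pos.data - neg.data)
    return pos.copy_with(diff, msg_sign=0, wrapped=True)


def unwrap_phase(series: PhaseImageSeries) -> PhaseImageSeries:
    """Spatial 2D unwrap of each temporal frame (reliability-sorted).

    The result differs from the true phase by one global multiple of 2*pi per
    frame; that offset is DC and is discarded by the temporal DFT.
    """
    if not series.wrapped:
        raise ValueError("series is not flagged wrapped")
    out = np.empty_like(series.data)
    for j in range(series.n_dynamics):
        out[:, :, j] = np.asarray(_unwrap2d(series.data[:, :, j]))
    return series.copy_with(out, wrapped=False)


def temporal_harmonic(series: PhaseImageSeries) -> ComplexWaveField:
    """First-harmonic complex amplitude of the temporal DFT, per pixel.

    Normalised ``2/n`` with kernel ``exp(-i omega t_j)`` so a time course
    ``A cos(omega t + theta)`` maps to ``A exp(i theta)``; the DC component
    (bin 0) is rejected.
    """
    n = series.n_dynamics
    if n < 4:
        raise ValueError("need at least 4 temporal offsets")
    coeff = (2.0 / n) * np.fft.fft(series.data, axis=2)[:, :, 1]
    return ComplexWaveField(
        data=coeff,
        drive_frequency=series.drive_frequency,
        pixel_spacing=series.pixel_spacing,
        provenance=["temporal_harmonic"],
    )


def _mirror_extend(a: np.ndarray) -> np.ndarray:
    """Even (mirror) extension along both axes, doubling the grid.

    Spectral filters are applied on this extension: it removes the value jump
    the periodic FFT would otherwise see at the image borders (the wave decays
    away from the source, so opposite borders differ strongly), whose leakage
    would contaminate the filtered field.
    """
    b = np.concatenate([a, a[::-1]], axis=0)
    return np.concatenate([b, b[:, ::-1]], axis=1)


def _apply_spectral_gain(field: ComplexWaveField, gain_fn, step: str) -> ComplexWaveField:
    u = field.data
    p = _mirror_extend(u)
    kr = np.fft.fftfreq(p.shape[0], d=field.pixel_spacing)
    kc = np.fft.fftfreq(p.shape[1], d=field.pixel_spacing)
    KR, KC = np.meshgrid(kr, kc, indexing="ij")
    out = np.fft.ifft2(np.fft.fft2(p) * gain_fn(KR, KC))[: u.shape[0], : u.shape[1]]
    return field.derive(out, step)


def butterworth_bandpass(
    field: ComplexWaveField,
    k_low: float = 0.0,
    k_high: float = 2000.0,
    order: int = 3,
) -> ComplexWaveField:
    """Radial Butterworth band-pass on the 2D spatial spectrum.

    ``H(k) = [1 - 1/(1+(k/k_low)^{2n})] * [1/(1+(k/k_high)^{2n})]`` with ``k``
    the radial spatial frequency in cycles/m; ``k_low = 0`` (the default)
    disables the high-pass factor -- the ±MSG subtraction already cancels
    static phase exactly, and in attenuating media removing low-k components
    distorts the slowly-varying decay envelope.  Never increases total
    spectral energy (|H| <= 1).  Applied on a mirror-extended grid to avoid
    periodic wrap-around leakage.
    """
    if k_low < 0 or k_low >= k_high:
        raise ValueError("need 0 <= k_low < k_high")
    if order < 1:
        raise ValueError("order must be >= 1")

    def gain(KR, KC):
        k = np.hypot(KR, KC)
        if k_low > 0:
            with np.errstate(divide="ignore"):
                ratio = np.where(k > 0, (k / k_low) ** (2 * order), 0.0)
            hp = 1.0 - 1.0 / (1.0 + ratio)
        else:
            hp = np.ones_like(k)
        return hp / (1.0 + (k / k_high) ** (2 * order))

    return _apply_spectral_gain(
        field, gain, f"butterworth_bandpass(k_low={k_low},k_high={k_high},order={order})"
    )


def directional_filter(
    field: ComplexWaveField,
    direction: str = "bottom_to_top",
    taper_width: float = 400.0,
) -> ComplexWaveField:
    """Keep waves propagating toward ``direction``, suppress the rest.

    Retains the spectral half-plane ``kappa . d < 0`` (see module docstring)
    with a raised-cosine transition of width ``taper_width`` (cycles/m) across
    the dividing line; applied on a mirror-extended grid (the mirrored copy
    counter-propagates and is suppressed together with true reflections).
    """
    if direction not in DIRECTIONS:
        raise ValueError(f"direction must be one of {sorted(DIRECTIONS)}")
    if taper_width < 0:
        raise ValueError("taper_width must be >= 0")
    dr, dc = DIRECTIONS[direction]

    def gain(KR, KC):
        s = KR * dr + KC * dc
        if taper_width == 0:
            return np.where(s < 0, 1.0, np.where(s > 0, 0.0, 0.5))
        w = taper_width
        return np.where(
            s <= -w / 2,
            1.0,
            np.where(s >= w / 2, 0.0, 0.5 * (1.0 - np.sin(np.pi * s / w))),
        )

    return _apply_spectral_gain(field, gain, f"directional_filter({direction},taper={taper_width})")
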