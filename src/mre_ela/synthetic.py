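"""Forward simulation of every input the pipeline consumes.

Three generators with ground truth attached:

* harmonic plane shear waves in a viscoelastic medium, encoded into wrapped
  MSG phase-image pairs (:func:`simulate_wave_series`,
  :func:`simulate_two_region_phantom`);
* saturation-recovery variable-TR signal series (:func:`simulate_t1_series`);
* cohort tables with a prescribed negative dependence of stiffness on the
  clinical disability score (:func:`simulate_cohort`).

Wave model
----------
For a homogeneous region with complex shear modulus ``G* = G' + iG''`` the
shear wavenumber is ``k = omega * sqrt(rho / G*)`` on the principal branch
(``Re k > 0``, ``Im k <= 0``), and a wave launched from the source edge is

    U(xi) = A * exp(-i k xi),   s(xi, t) = Re[U(xi) * exp(+i omega t)]

with ``xi`` the distance from the source edge.  ``Im k < 0`` makes the
amplitude decay away from the source (lossy medium).  A counter-propagating
reflection of relative amplitude ``reflection_coefficient`` re-enters from the
opposite edge.  Displacement is encoded into MR phase with opposite signs for
the two MSG polarities, a static low-order polynomial background phase is
added, and the result is wrapped to ``(-pi, pi]`` with optional Gaussian noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .containers import PhaseImageSeries, T1Series

__all__ = [
    "WaveSimConfig",
    "GroundTruth",
    "simulate_wave_series",
    "simulate_two_region_phantom",
    "simulate_t1_series",
    "simulate_cohort",
    "wrap_phase",
    "shear_wavenumber",
]

GENES = ("Fibronectin", "Neurocan", "Brevican", "Glypican5")


def wrap_phase(phase: np.ndarray) -> np.ndarray:
    """Wrap phase to ``(-pi, pi]``; exactly idempotent (in-range values are
    returned bit-identically)."""
    x = np.asarray(phase, dtype=float)
    in_range = (x > -np.pi) & (x <= np.pi)
    return np.where(in_range, x, np.angle(np.exp(1j * x)))


def shear_wavenumber(gstar: complex, density: float, frequency: float) -> complex:
    """Complex shear wavenumber ``k = omega*sqrt(rho/G*)``, rad/m.

    Principal square root: ``Re k > 0`` and ``Im k <= 0`` for ``Im G* >= 0``,
    so ``exp(-i k xi)`` propagates and decays toward increasing ``xi``.
    """
    omega = 2.0 * np.pi * frequency
    return omega * np.sqrt(density / np.complex128(gstar))


@dataclass
class WaveSimConfig:
    """Configuration of the shear-wave phantom.

    Defaults reproduce the acquisition geometry the pipeline targets:
    900 Hz drive, 8 temporal offsets per period, 128x128 matrix over a 25 mm
    field of view.  ``true_modulus_map`` may be a scalar (homogeneous medium)
    or a full complex map; per-line heterogeneity transverse to the
    propagation direction is supported (piecewise-constant phantoms).
    """

    true_modulus_map: np.ndarray | complex = 3000.0 + 0.0j
    density: float = 1000.0          # kg/m^3, soft-tissue convention
    drive_frequency: float = 900.0   # Hz
    matrix_size: int = 128
    fov: float = 0.025               # m
    n_dynamics: int = 8
    reflection_coefficient: float = 0.0
    noise_sd: float = 0.05           # rad, per phase image
    encoding_gain: float = 2.0       # rad of phase per unit displacement amplitude
    background_scale: float = 0.5    # rad, scale of the static polynomial background
    junction_col: Optional[int] = None  # anterior/posterior split column (two-region phantoms)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.matrix_size < 16:
            raise ValueError("matrix_size must be >= 16")
        if self.drive_frequency <= 0:
            raise ValueError("drive_frequency must be positive")
        if self.density <= 0:
            raise ValueError("density must be positive")
        if self.n_dynamics < 4:
            raise ValueError("n_dynamics must be >= 4 (Nyquist for the first harmonic)")
        if not 0.0 <= self.reflection_coefficient <= 1.0:
            raise ValueError("reflection_coefficient must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.fov <= 0:
            raise ValueError("fov must be positive")
        g = self.modulus_map()
        if np.any(g.real <= 0) or np.any(g.imag < 0):
            raise ValueError("need Re(G*) > 0 and Im(G*) >= 0 everywhere")

    def modulus_map(self) -> np.ndarray:
        n = self.matrix_size
        g = np.asarray(self.true_modulus_map, dtype=complex)
        if g.ndim == 0:
            g = np.full((n, n), complex(g))
        if g.shape != (n, n):
            raise ValueError(f"modulus map must be ({n}, {n}); got {g.shape}")
        return g

    @property
    def pixel_spacing(self) -> float:
        return self.fov / self.matrix_size


@dataclass
class GroundTruth:
    """Exact quantities behind one simulated acquisition.

    ``forward_field`` / ``total_field`` are the noise-free complex
    displacement fields (before encoding), kept for oracle comparisons in
    tests: ``total_field`` includes the reflected component.
    """

    modulus_map: np.ndarray
    regional_means: Dict[str, complex]
    forward_field: np.ndarray
    total_field: np.ndarray
    masks: Dict[str, np.ndarray] = field(default_factory=dict)


_EDGES = ("bottom", "top", "left", "right")


def _distance_from_edge(n: int, h: float, source_edge: str) -> Tuple[np.ndarray, int]:
    """Distance-from-source coordinate map (m) and the propagation axis (0=rows)."""
    r = np.arange(n, dtype=float) * h
    if source_edge == "bottom":   # propagation toward decreasing row index
        xi = (n - 1) * h - r
        axis = 0
    elif source_edge == "top":
        xi = r
        axis = 0
    elif source_edge == "left":
        xi = r
        axis = 1
    elif source_edge == "right":
        xi = (n - 1) * h - r
        axis = 1
    else:
        raise ValueError(f"source_edge must be one of {_EDGES}")
    return xi, axis


def _background_phase(n: int, scale: float, rng: np.random.Generator) -> np.ndarray:
    """Static smooth background: random low-order 2D polynomial, radians."""
    x = np.linspace(-1.0, 1.0, n)
    X, Y = np.meshgrid(x, x, indexing="xy")
    basis = [np.ones_like(X), X, Y, X * Y, X**2, Y**2]
    coeffs = rng.uniform(-scale, scale, size=len(basis))
    return sum(c * b for c, b in zip(coeffs, basis))


def complex_displacement_field(
    config: WaveSimConfig, source_edge: str = "bottom"
) -> Tuple[np.ndarray, np.ndarray]:
    """Noise-free complex displacement fields ``(forward, total)``.

    The medium must be uniform along each propagation line (each column for a
    bottom/top source, each row for a left/right source); waves are computed
    per line with unit amplitude at the source edge.  Displacement/stress
    continuity across region boundaries is intentionally not enforced.
    """
    n = config.matrix_size
    h = config.pixel_spacing
    g = config.modulus_map()
    xi, axis = _distance_from_edge(n, h, source_edge)

    # uniformity along the propagation axis (piecewise-constant transverse regions)
    if not np.allclose(g, g.take([0], axis=axis), rtol=0, atol=1e-9):
        raise ValueError(
            "modulus map must be uniform along each propagation line "
            f"(axis {axis}) for the plane-wave simulator"
        )
    g_line = g.take(0, axis=axis)  # one modulus per transverse line

    k = shear_wavenumber(g_line, config.density, config.drive_frequency)  # (n,)
    lam_min = float(np.min(2.0 * np.pi / k.real))
    if lam_min < 4.0 * h:
        raise ValueError(
            f"shear wavelength {lam_min * 1e3:.3f} mm is shorter than 4 pixels "
            f"({4 * h * 1e3:.3f} mm): aliased simulation rejected"
        )

    L = (n - 1) * h
    if axis == 0:
        phase_fwd = np.exp(-1j * np.outer(xi, k))          # (rows, cols)
        phase_ref = np.exp(-1j * np.outer(2.0 * L - xi, k))
    else:
        phase_fwd = np.exp(-1j * k[:, None] * xi[None, :])
        phase_ref = np.exp(-1j * k[:, None] * (2.0 * L - xi)[None, :])
    forward = phase_fwd
    total = forward + config.reflection_coefficient * phase_ref
    return forward, total


def simulate_wave_series(
    config: WaveSimConfig, source_edge: str = "bottom"
) -> Tuple[PhaseImageSeries, PhaseImageSeries, GroundTruth]:
    """Simulate a matched pair of +MSG / -MSG wrapped phase-image series.

    Returns the two series and the :class:`GroundTruth` used to build them.
    All randomness (background polynomial, phase noise) flows from
    ``config.seed``.
    """
    n = config.matrix_size
    g = config.modulus_map()
    forward, total = complex_displacement_field(config, source_edge)

    rng = np.random.default_rng(config.seed)
    background = _background_phase(n, config.background_scale, rng)

    t_phase = 2.0 * np.pi * np.arange(config.n_dynamics) / config.n_dynamics
    pos = np.empty((n, n, config.n_dynamics))
    neg = np.empty_like(pos)
    for j, wt in enumerate(t_phase):
        u = np.real(total * np.exp(1j * wt))  # s(t) = Re[U e^{+i omega t}]
        enc = config.encoding_gain * u
        noise_p = rng.normal(0.0, config.noise_sd, size=u.shape) if config.noise_sd else 0.0
        noise_n = rng.normal(0.0, config.noise_sd, size=u.shape) if config.noise_sd else 0.0
        pos[:, :, j] = wrap_phase(enc + background + noise_p)
        neg[:, :, j] = wrap_phase(-enc + background + noise_n)

    kwargs = dict(
        drive_frequency=config.drive_frequency,
        pixel_spacing=config.pixel_spacing,
        wrapped=True,
    )
    series_pos = PhaseImageSeries(data=pos, msg_sign=+1, **kwargs)
    series_neg = PhaseImageSeries(data=neg, msg_sign=-1, **kwargs)

    masks: Dict[str, np.ndarray] = {"whole": np.ones((n, n), dtype=bool)}
    means: Dict[str, complex] = {"whole": complex(g.mean())}
    if config.junction_col is not None:
        j = int(config.junction_col)
        ant = np.zeros((n, n), dtype=bool)
        ant[:, :j] = True
        post = ~ant
        masks["anterior"], masks["posterior"] = ant, post
        means["anterior"] = complex(g[ant].mean())
        means["posterior"] = complex(g[post].mean())

    truth = GroundTruth(
        modulus_map=g,
        regional_means=means,
        forward_field=forward,
        total_field=total,
        masks=masks,
    )
    return series_pos, series_neg, truth


def simulate_two_region_phantom(
    anterior_modulus: complex,
    posterior_modulus: complex,
    config: WaveSimConfig,
    source_edge: str = "bottom",
) -> Tuple[PhaseImageSeries, PhaseImageSeries, GroundTruth]:
    """Piecewise-constant phantom: anterior columns left of the junction,
    posterior columns right of it, mirroring a cerebrum/cerebellum split.

    ``GroundTruth.regional_means`` holds the two constants exactly.
    """
    n = config.matrix_size
    j = config.junction_col if config.junction_col is not None else n // 2
    if not 1 <= j <= n - 1:
        raise ValueError("junction_col must split the matrix into two non-empty parts")
    gmap = np.empty((n, n), dtype=complex)
    gmap[:, :j] = complex(anterior_modulus)
    gmap[:, j:] = complex(posterior_modulus)
    cfg = replace(config, true_modulus_map=gmap, junction_col=j)
    return simulate_wave_series(cfg, source_edge=source_edge)


def simulate_t1_series(
    t1_map: np.ndarray,
    s0_map: np.ndarray,
    tr_list: np.ndarray,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> T1Series:
    """Saturation-recovery series ``S(TR) = S0 (1 - exp(-TR/T1))`` plus noise.

    ``t1_map`` (ms) and ``s0_map`` may be 2D (one slice) or 3D
    ``(slices, rows, cols)``.
    """
    t1 = np.asarray(t1_map, dtype=float)
    s0 = np.asarray(s0_map, dtype=float)
    if t1.shape != s0.shape:
        raise ValueError("t1_map and s0_map shapes differ")
    if np.any(t1 <= 0):
        raise ValueError("all T1 values must be positive")
    tr = np.asarray(tr_list, dtype=float)
    if np.any(np.diff(tr) <= 0):
        raise ValueError("tr_list must be strictly increasing")
    signal = s0[..., None] * (1.0 - np.exp(-tr / t1[..., None]))
    if noise_sd:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return T1Series(data=signal, tr_list=tr)


def simulate_cohort(
    n_eae: int = 15,
    n_control: int = 7,
    score_range: Tuple[float, float] = (0.5, 3.0),
    stiffness_slope: float = -300.0,
    noise_sd: float = 150.0,
    seed: int = 0,
    baseline_gabs: float = 3200.0,
    baseline_phi: float = 0.3,
    posterior_softening: float = 1.5,
    fn_coupling: float = 0.6,
) -> pd.DataFrame:
    """Per-animal cohort table with a negative score--stiffness dependence.

    ``|G*| = baseline + stiffness_slope * score + N(0, noise_sd)`` per animal;
    controls carry score 0 and baseline stiffness.  The posterior (cerebellar)
    region softens ``posterior_softening`` times faster than the anterior one.
    Fibronectin fold change rises with softening (coupling ``fn_coupling`` on
    the log2 scale per kPa of loss); the other matrix genes are independent
    lognormal noise.  delta-T1 and SI% carry contrast uptake in the diseased
    group, independent of stiffness.

    One row per animal x region (whole / anterior / posterior), columns as the
    cohort CSV schema: ``animal_id, group, score, region, gstar_abs,
    gstar_real, gstar_imag, delta_t1, si_pct`` plus one fold-change column per
    gene.
    """
    if stiffness_slope > 0:
        raise ValueError("stiffness_slope must be <= 0 (softening with disability)")
    if n_eae < 3 or n_control < 3:
        raise ValueError("need at least 3 animals per group")
    lo, hi = score_range
    if not (0 < lo <= hi <= 5):
        raise ValueError("score_range must satisfy 0 < lo <= hi <= 5")

    rng = np.random.default_rng(seed)
    steps = np.arange(np.ceil(lo / 0.5), np.floor(hi / 0.5) + 1) * 0.5
    scores = np.concatenate([rng.choice(steps, size=n_eae), np.zeros(n_control)])
    groups = ["EAE"] * n_eae + ["control"] * n_control

    region_gain = {"whole": 1.0, "anterior": 0.75, "posterior": posterior_softening}
    rows = []
    for i, (grp, score) in enumerate(zip(groups, scores)):
        animal = f"{'eae' if grp == 'EAE' else 'ctl'}{i:03d}"
        # animal-level softening drives FN expression
        whole_gabs = (
            baseline_gabs
            + stiffness_slope * score
            + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
        )
        softening_kpa = max(baseline_gabs - whole_gabs, 0.0) / 1000.0
        log2_folds = {
            "Fibronectin": fn_coupling * softening_kpa + rng.normal(0.0, 0.15),
            "Neurocan": rng.normal(0.0, 0.3),
            "Brevican": rng.normal(0.0, 0.3),
            "Glypican5": rng.normal(0.0, 0.3),
        }
        uptake = score > 0
        delta_t1 = rng.normal(250.0, 80.0) if uptake else rng.normal(40.0, 25.0)
        si_pct = rng.normal(12.0, 4.0) if uptake else rng.normal(2.0, 1.5)
        phi = baseline_phi + rng.normal(0.0, 0.01)
        for region, gain in region_gain.items():
            gabs = (
                baseline_gabs
                + gain * stiffness_slope * score
                + (rng.normal(0.0, noise_sd) if noise_sd else 0.0)
            )
            if region == "whole":
                gabs = whole_gabs
            gabs = max(gabs, 200.0)
            row = {
                "animal_id": animal,
                "group": grp,
                "score": float(score),
                "region": region,
                "gstar_abs": gabs,
                "gstar_real": gabs * np.cos(phi),
                "gstar_imag": gabs * np.sin(phi),
                "phi": phi,
                "delta_t1": delta_t1,
                "si_pct": si_pct,
            }
            for gene in GENES:
                row[f"fold_{gene.lower()}"] = float(2.0 ** log2_folds[gene])
            rows.append(row)
    return pd.DataFrame(rows)
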