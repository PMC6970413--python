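"""In-memory containers shared across the pipeline.

All image containers are thin dataclasses around numpy arrays with the
acquisition geometry attached.  Convention used throughout the package:

* image axis 0 is the row (vertical) direction, row 0 is the **top** of the
  field of view; axis 1 is the column (horizontal) direction;
* a harmonic signal ``s(t) = A cos(omega t + theta)`` is represented by the
  complex amplitude ``U = A exp(i theta)``, i.e. ``s(t) = Re[U exp(+i omega t)]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List

import numpy as np

__all__ = [
    "PhaseImageSeries",
    "ComplexWaveField",
    "ElastogramMaps",
    "ViscoSummary",
    "ROISet",
    "T1Series",
    "T1Map",
]


@dataclass
class PhaseImageSeries:
    """A stack of phase images sampled over one vibration period.

    Parameters
    ----------
    data
        Phase in radians, shape ``(rows, cols, n_dynamics)``.
    msg_sign
        Sign of the motion-sensitizing gradient, ``+1`` or ``-1`` (``0`` for
        derived series such as phase differences).
    drive_frequency
        Mechanical vibration frequency in Hz.
    pixel_spacing
        In-plane pixel size in metres (isotropic).
    wrapped
        Whether values are confined to ``(-pi, pi]``.
    """

    data: np.ndarray
    msg_sign: int
    drive_frequency: float
    pixel_spacing: float
    wrapped: bool = True

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(
                f"phase series must be (rows, cols, n_dynamics); got shape {self.data.shape}"
            )
        if self.n_dynamics < 4:
            raise ValueError("need at least 4 temporal offsets (Nyquist for the first harmonic)")
        if self.pixel_spacing <= 0:
            raise ValueError("pixel_spacing must be positive")
        if self.drive_frequency <= 0:
            raise ValueError("drive_frequency must be positive")
        if self.msg_sign not in (-1, 0, 1):
            raise ValueError("msg_sign must be -1, 0 or +1")
        if self.wrapped:
            d = self.data
            if d.size and (d.min() <= -np.pi - 1e-9 or d.max() > np.pi + 1e-9):
                raise ValueError("series flagged wrapped but values fall outside (-pi, pi]")

    @property
    def n_dynamics(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple:
        return self.data.shape

    def copy_with(self, data: np.ndarray, **kw) -> "PhaseImageSeries":
        args = dict(
            msg_sign=self.msg_sign,
            drive_frequency=self.drive_frequency,
            pixel_spacing=self.pixel_spacing,
            wrapped=self.wrapped,
        )
        args.update(kw)
        return PhaseImageSeries(data=data, **args)


@dataclass
class ComplexWaveField:
    """Complex harmonic displacement-proportional field at the drive frequency."""

    data: np.ndarray
    drive_frequency: float
    pixel_spacing: float
    provenance: List[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        if self.data.ndim != 2:
            raise ValueError("wave field must be 2D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("wave field contains non-finite values")

    def derive(self, data: np.ndarray, step: str) -> "ComplexWaveField":
        """New field with `step` appended to the provenance (append-only)."""
        return ComplexWaveField(
            data=data,
            drive_frequency=self.drive_frequency,
            pixel_spacing=self.pixel_spacing,
            provenance=list(self.provenance) + [step],
        )


@dataclass
class ElastogramMaps:
    """Per-pixel complex shear modulus with a validity mask."""

    gstar: np.ndarray
    valid_mask: np.ndarray
    density: float
    drive_frequency: float

    def __post_init__(self) -> None:
        self.gstar = np.asarray(self.gstar, dtype=complex)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if self.gstar.shape != self.valid_mask.shape:
            raise ValueError("gstar and valid_mask shapes differ")
        if not np.all(np.isfinite(self.gstar[self.valid_mask])):
            raise ValueError("non-finite modulus inside the validity mask")

    @property
    def g_prime(self) -> np.ndarray:
        """Storage modulus map, Re(G*), Pa."""
        return self.gstar.real

    @property
    def g_doubleprime(self) -> np.ndarray:
        """Loss modulus map, Im(G*), Pa."""
        return self.gstar.imag

    @property
    def g_abs(self) -> np.ndarray:
        """Magnitude modulus map |G*|, Pa."""
        return np.abs(self.gstar)

    @property
    def phi(self) -> np.ndarray:
        """Loss-factor (phase angle) map, arctan(G''/G'), radians."""
        return np.arctan2(self.gstar.imag, self.gstar.real)


@dataclass
class ViscoSummary:
    """Regional viscoelastic summary derived from one complex modulus value."""

    g_prime: float
    g_doubleprime: float
    g_abs: float
    phi: float
    n_pixels: int

    @classmethod
    def from_complex(cls, g: complex, n_pixels: int) -> "ViscoSummary":
        g = complex(g)
        return cls(
            g_prime=g.real,
            g_doubleprime=g.imag,
            g_abs=abs(g),
            phi=float(np.arctan2(g.imag, g.real)),
            n_pixels=int(n_pixels),
        )

    def as_dict(self) -> Dict[str, float]:
        return {
            "g_prime": self.g_prime,
            "g_doubleprime": self.g_doubleprime,
            "g_abs": self.g_abs,
            "phi": self.phi,
            "n_pixels": self.n_pixels,
        }


@dataclass
class ROISet:
    """Whole-brain mask and its anterior (cerebrum) / posterior (cerebellum) split."""

    whole_brain: np.ndarray
    anterior: np.ndarray
    posterior: np.ndarray

    def __post_init__(self) -> None:
        self.whole_brain = np.asarray(self.whole_brain, dtype=bool)
        self.anterior = np.asarray(self.anterior, dtype=bool)
        self.posterior = np.asarray(self.posterior, dtype=bool)
        if np.any(self.anterior & self.posterior):
            raise ValueError("anterior and posterior masks overlap")
        if not np.array_equal(self.anterior | self.posterior, self.whole_brain):
            raise ValueError("anterior and posterior masks do not partition the whole-brain mask")

    def as_dict(self) -> Dict[str, np.ndarray]:
        return {
            "whole": self.whole_brain,
            "anterior": self.anterior,
            "posterior": self.posterior,
        }


@dataclass
class T1Series:
    """Variable-TR saturation-recovery image series.

    ``data`` has shape ``(n_slices, rows, cols, n_tr)``; single-slice input may
    be given as ``(rows, cols, n_tr)`` and is promoted.
    """

    data: np.ndarray
    tr_list: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim == 3:
            self.data = self.data[None]
        if self.data.ndim != 4:
            raise ValueError("T1 series must be (slices, rows, cols, n_tr)")
        self.tr_list = np.asarray(self.tr_list, dtype=float)
        if self.tr_list.ndim != 1 or self.tr_list.size != self.data.shape[-1]:
            raise ValueError("tr_list length must match the last data axis")
        if np.any(np.diff(self.tr_list) <= 0):
            raise ValueError("tr_list must be strictly increasing")

    @property
    def n_tr(self) -> int:
        return self.tr_list.size

    @property
    def n_slices(self) -> int:
        return self.data.shape[0]


@dataclass
class T1Map:
    """Voxelwise T1 fit result, one frame per slice."""

    t1: np.ndarray
    s0: np.ndarray
    fit_ok: np.ndarray

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=float)
        self.s0 = np.asarray(self.s0, dtype=float)
        self.fit_ok = np.asarray(self.fit_ok, dtype=bool)
        if self.t1.ndim == 2:
            self.t1, self.s0, self.fit_ok = (a[None] for a in (self.t1, self.s0, self.fit_ok))
        if not (self.t1.shape == self.s0.shape == self.fit_ok.shape):
            raise ValueError("t1, s0 and fit_ok shapes differ")
        if np.any(self.t1[self.fit_ok] <= 0):
            raise ValueError("non-positive T1 flagged as a successful fit")
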