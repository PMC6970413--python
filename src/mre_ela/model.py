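"""Model/Results interface over the reconstruction chain.

:class:`Elastography` holds one ±MSG acquisition pair and the analysis
settings; ``fit()`` runs phase difference -> unwrap -> temporal harmonic ->
Butterworth band-pass -> directional filter -> 2D Helmholtz inversion ->
regional summaries and returns an :class:`ElastographyResults`.

:class:`SaturationRecoveryT1` wraps the voxelwise variable-TR T1 fit the same
way.  Both Results objects expose ``summary()`` text tables, the fitted maps,
and convenience plotting.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import elastogram as el
from . import t1 as t1mod
from . import waves
from .config import FilterConfig, InversionConfig
from .containers import (
    ComplexWaveField,
    ElastogramMaps,
    PhaseImageSeries,
    ROISet,
    T1Map,
    T1Series,
    ViscoSummary,
)

__all__ = [
    "Elastography",
    "ElastographyResults",
    "SaturationRecoveryT1",
    "T1Results",
]


class Elastography:
    """MR elastography reconstruction model for one acquisition.

    Parameters
    ----------
    pos, neg
        The wrapped phase-image series for the two MSG polarities.
    roi
        Optional :class:`ROISet`; default is the full field of view split at
        the midline column.
    density
        Tissue density in kg/m^3.
    filters, inversion
        Analysis settings (Butterworth cutoffs, directional filter,
        validity-mask threshold, stencil correction, averaging mode).
    """

    def __init__(
        self,
        pos: PhaseImageSeries,
        neg: PhaseImageSeries,
        roi: Optional[ROISet] = None,
        density: float = 1000.0,
        filters: Optional[FilterConfig] = None,
        inversion: Optional[InversionConfig] = None,
    ) -> None:
        self.pos = pos
        self.neg = neg
        self.density = float(density)
        self.filters = filters or FilterConfig()
        self.inversion = inversion or InversionConfig()
        self.filters.validate()
        self.inversion.validate()
        if roi is None:
            shape = pos.data.shape[:2]
            whole = np.ones(shape, dtype=bool)
            roi = el.split_anterior_posterior(whole, shape[1] // 2, axis=1)
        self.roi = roi

    def fit(self) -> "ElastographyResults":
        fcfg, icfg = self.filters, self.inversion
        diff = waves.phase_difference(self.pos, self.neg)
        unwrapped = waves.unwrap_phase(diff)
        harmonic = waves.temporal_harmonic(unwrapped)
        filtered = waves.butterworth_bandpass(
            harmonic, k_low=fcfg.k_low, k_high=fcfg.k_high, order=fcfg.butter_order
        )
        if fcfg.use_directional:
            filtered = waves.directional_filter(
                filtered, direction=fcfg.direction, taper_width=fcfg.taper_width
            )
        maps = el.helmholtz_invert(
            filtered,
            density=self.density,
            laplacian_mask_threshold=icfg.laplacian_mask_threshold,
            stencil_correction=icfg.stencil_correction,
            support=self.roi.whole_brain,
        )
        summaries = {
            name: el.summarize_roi(maps, mask, averaging=icfg.averaging, erode=icfg.erode)
            for name, mask in self.roi.as_dict().items()
        }
        return ElastographyResults(
            model=self,
            wave_field=filtered,
            elastogram=maps,
            roi_summaries=summaries,
        )


@dataclass
class ElastographyResults:
    """Fitted elastogram, the filtered wave field, and regional summaries."""

    model: Elastography
    wave_field: ComplexWaveField
    elastogram: ElastogramMaps
    roi_summaries: Dict[str, ViscoSummary] = field(default_factory=dict)

    def summary_frame(self) -> pd.DataFrame:
        rows = []
        for region, s in self.roi_summaries.items():
            row = {"region": region}
            row.update(s.as_dict())
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        df = self.summary_frame()
        lines = [
            "MR elastography reconstruction",
            "==============================",
            f"drive frequency : {self.elastogram.drive_frequency:.1f} Hz",
            f"density         : {self.elastogram.density:.0f} kg/m^3",
            f"valid pixels    : {int(self.elastogram.valid_mask.sum())}",
            f"stages          : {' -> '.join(self.wave_field.provenance)}",
            "",
            df.to_string(
                index=False,
                formatters={
                    "g_prime": "{:10.1f}".format,
                    "g_doubleprime": "{:10.1f}".format,
                    "g_abs": "{:10.1f}".format,
                    "phi": "{:7.4f}".format,
                },
            ),
            "",
            "moduli in Pa; phi in radians",
        ]
        return "\n".join(lines)

    def plot(self, metric: str = "g_abs", ax=None, **imshow_kw):
        """Show one modulus map (requires matplotlib)."""
        import matplotlib.pyplot as plt

        data = getattr(self.elastogram, metric).astype(float).copy()
        data[~self.elastogram.valid_mask] = np.nan
        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(data, origin="upper", **imshow_kw)
        ax.set_title(f"{metric} ({'rad' if metric == 'phi' else 'Pa'})")
        plt.colorbar(im, ax=ax)
        return ax


class SaturationRecoveryT1:
    """Voxelwise saturation-recovery T1 model for a variable-TR series."""

    def __init__(self, series: T1Series, model: str = "2param", mask: Optional[np.ndarray] = None):
        self.series = series
        self.model = model
        self.mask = mask

    def fit(self) -> "T1Results":
        t1_map = t1mod.fit_t1_map(self.series, model=self.model, mask=self.mask)
        return T1Results(model=self, t1_map=t1_map)


@dataclass
class T1Results:
    model: SaturationRecoveryT1
    t1_map: T1Map

    def summary(self) -> str:
        ok = self.t1_map.fit_ok
        t1 = self.t1_map.t1[ok]
        lines = [
            "Saturation-recovery T1 fit",
            "==========================",
            f"model           : {self.model.model}",
            f"TR array (ms)   : {', '.join(f'{t:g}' for t in self.model.series.tr_list)}",
            f"voxels fitted   : {int(ok.sum())} / {ok.size}",
        ]
        if t1.size:
            lines += [
                f"T1 median (ms)  : {np.median(t1):.1f}",
                f"T1 IQR (ms)     : {np.percentile(t1, 25):.1f} - {np.percentile(t1, 75):.1f}",
            ]
        return "\n".join(lines)
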