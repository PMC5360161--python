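"""Voxel-wise ADC estimation from multi-b-value DWI.

The signal model is monoexponential decay, ``S(b) = S(0) * exp(-b * ADC)``,
so the two-point estimate is ``ADC = ln(S(0)/S(b)) / b`` and the multi-b
estimate is the negated ordinary-least-squares slope of ``ln S(b)`` against
``b``.  ADC values are stored in mm^2/s (display layers may rescale to
1e-3 mm^2/s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: How to treat noise-driven negative ADC estimates (S(b) > S(0)).
NEGATIVE_POLICIES = ("retain", "clip", "invalidate")


@dataclass(frozen=True)
class DWISeries:
    """Co-registered DWI signal volumes at one timepoint.

    Parameters
    ----------
    b_values : tuple of float
        Diffusion weightings in s/mm^2; at least two distinct values, all >= 0.
    volumes : tuple of ndarray
        One 3D signal array per b-value, all on the same grid.
    voxel_spacing : tuple of float
        Voxel size in mm along each axis.
    week : int
        Week index; 0 denotes the pretreatment scan.
    days_from_rt_start : int or None
        Scan day relative to the start of radiotherapy (metadata only).
    """

    b_values: tuple[float, ...]
    volumes: tuple[np.ndarray, ...]
    voxel_spacing: tuple[float, float, float]
    week: int = 0
    days_from_rt_start: int | None = None

    def __post_init__(self):
        if len(self.b_values) != len(self.volumes):
            raise ValueError("b_values and volumes must have equal length")
        if len(set(float(b) for b in self.b_values)) < 2:
            raise ValueError("need at least two distinct b-values")
        if any(b < 0 for b in self.b_values):
            raise ValueError("b-values must be >= 0")
        shapes = {v.shape for v in self.volumes}
        if len(shapes) != 1:
            raise ValueError(f"volumes are not on a single grid: {sorted(shapes)}")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.volumes[0].shape

    def volume_for(self, b: float) -> np.ndarray:
        for bv, vol in zip(self.b_values, self.volumes):
            if float(bv) == float(b):
                return vol
        raise KeyError(f"no volume at b={b}")


@dataclass
class ADCMap:
    """Voxel-wise ADC values (mm^2/s) plus a validity mask.

    Invalid voxels (undefined fit) hold NaN and must be excluded from all
    downstream statistics.
    """

    values: np.ndarray
    valid: np.ndarray
    voxel_spacing: tuple[float, float, float]
    n_negative: int = field(default=0)

    def __post_init__(self):
        if self.values.shape != self.valid.shape:
            raise ValueError("values and valid mask shapes differ")


def _apply_negative_policy(adc: np.ndarray, valid: np.ndarray, policy: str) -> int:
    if policy not in NEGATIVE_POLICIES:
        raise ValueError(f"negative_policy must be one of {NEGATIVE_POLICIES}")
    negative = valid & (adc < 0)
    n_neg = int(negative.sum())
    if n_neg:
        logger.info("%d voxels with negative ADC (policy=%s)", n_neg, policy)
        if policy == "clip":
            adc[negative] = 0.0
        elif policy == "invalidate":
            valid[negative] = False
            adc[negative] = np.nan
    return n_neg


def fit_adc_pair(series: DWISeries, negative_policy: str = "retain") -> ADCMap:
    """Two-point ADC map from a b=0 / b>0 pair.

    Voxels where either signal is non-positive or non-finite are marked
    invalid (NaN).  Negative ADC estimates are handled per
    ``negative_policy`` ({"retain", "clip", "invalidate"}, default retain);
    their count is logged and recorded on the returned map.
    """
    bs = sorted(set(float(b) for b in series.b_values))
    if len(series.b_values) != 2 or len(bs) != 2:
        raise ValueError("fit_adc_pair requires exactly two distinct b-values")
    if bs[0] != 0.0:
        raise ValueError("fit_adc_pair requires one b-value equal to 0")
    b_high = bs[1]
    s0 = np.asarray(series.volume_for(0.0), dtype=np.float64)
    sb = np.asarray(series.volume_for(b_high), dtype=np.float64)

    valid = (s0 > 0) & (sb > 0) & np.isfinite(s0) & np.isfinite(sb)
    adc = np.full(s0.shape, np.nan)
    adc[valid] = np.log(s0[valid] / sb[valid]) / b_high
    n_neg = _apply_negative_policy(adc, valid, negative_policy)
    return ADCMap(adc, valid, series.voxel_spacing, n_negative=n_neg)


def fit_adc_multib(series: DWISeries, negative_policy: str = "retain") -> ADCMap:
    """ADC map from >= 2 b-values via unweighted OLS on log-signal.

    Only voxels where every signal is strictly positive and finite are
    fitted; the rest are invalid.  For exactly two b-values (one of them 0)
    the result agrees with :func:`fit_adc_pair` to floating tolerance.
    """
    b = np.asarray([float(x) for x in series.b_values], dtype=np.float64)
    if len(np.unique(b)) < 2:
        raise ValueError("fit_adc_multib requires at least two distinct b-values")
    stack = np.stack([np.asarray(v, dtype=np.float64) for v in series.volumes])
    valid = np.all((stack > 0) & np.isfinite(stack), axis=0)

    adc = np.full(valid.shape, np.nan)
    if valid.any():
        log_s = np.log(stack[:, valid])  # (n_b, n_valid)
        bc = b - b.mean()
        denom = float(np.sum(bc * bc))
        slope = (bc @ (log_s - log_s.mean(axis=0))) / denom
        adc[valid] = -slope
    n_neg = _apply_negative_policy(adc, valid, negative_policy)
    return ADCMap(adc, valid, series.voxel_spacing, n_negative=n_neg)
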