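"""ROI algebra, volumes, ADC extraction, first-order histogram statistics,
and a two-component mixture helper for bimodal whole-lesion histograms.

Conventions pinned here (and relied on by the test oracles): standard
deviation uses the n-1 denominator, percentiles use linear interpolation
between order statistics, skewness is the (biased) Fisher-Pearson
standardized third moment, and kurtosis is excess kurtosis (normal -> 0).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps
from sklearn.mixture import GaussianMixture

from .adc import ADCMap

logger = logging.getLogger(__name__)

ROI_LABELS = ("gtv", "cystic_necrotic", "viable")


@dataclass
class ROIMask:
    """Binary region on the image grid.

    ``label`` is one of ``gtv``, ``cystic_necrotic`` or ``viable``;
    ``name`` is an optional free-form identifier (e.g. the lesion id) used
    in error messages.
    """

    mask: np.ndarray
    label: str
    voxel_spacing: tuple[float, float, float]
    name: str | None = None

    def __post_init__(self):
        if self.label not in ROI_LABELS:
            raise ValueError(f"label must be one of {ROI_LABELS}, got {self.label!r}")
        self.mask = np.asarray(self.mask, dtype=bool)
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


@dataclass
class HistogramSummary:
    """First-order statistics of ADC within one ROI.

    All ADC-valued fields are mm^2/s.  ``skewness``/``kurtosis`` are NaN
    when undefined (n < 3 or zero spread); ``shape_defined`` flags that
    case explicitly.
    """

    n_voxels: int
    mean: float
    median: float
    sd: float
    p10: float
    p25: float
    p75: float
    p90: float
    skewness: float
    kurtosis: float
    volume_cm3: float = math.nan
    shape_defined: bool = True

    def to_dict(self) -> dict:
        return {
            "n_voxels": self.n_voxels,
            "mean": self.mean,
            "median": self.median,
            "sd": self.sd,
            "p10": self.p10,
            "p25": self.p25,
            "p75": self.p75,
            "p90": self.p90,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "volume_cm3": self.volume_cm3,
        }


@dataclass
class ComponentSplit:
    """Two-component Gaussian mixture decomposition of an ADC sample.

    Component parameters are ordered by ascending mean.  ``bimodal`` is an
    advisory verdict: BIC must prefer two components over one AND the
    component means must be separated by more than the pooled sd.
    """

    means: tuple[float, float]
    sds: tuple[float, float]
    weights: tuple[float, float]
    assignments: np.ndarray
    bimodal: bool
    bic_one: float
    bic_two: float


def _check_same_grid(a_shape, b_shape, what: str) -> None:
    if tuple(a_shape) != tuple(b_shape):
        raise ValueError(f"grid mismatch in {what}: {tuple(a_shape)} vs {tuple(b_shape)}")


def subtract_rois(gtv: ROIMask, cystic: ROIMask) -> ROIMask:
    """Viable tumor mask: GTV minus the cystic/necrotic subregion.

    Cystic voxels lying outside the GTV are ignored; their count is logged
    as a warning.  An empty result is an error (the whole lesion cannot be
    cystic).
    """
    _check_same_grid(gtv.mask.shape, cystic.mask.shape, "subtract_rois")
    outside = int((cystic.mask & ~gtv.mask).sum())
    if outside:
        logger.warning(
            "%d cystic/necrotic voxels lie outside GTV %s and were ignored",
            outside,
            gtv.name or "(unnamed)",
        )
    viable = gtv.mask & ~cystic.mask
    if not viable.any():
        raise ValueError(
            f"viable mask is empty after subtraction for GTV {gtv.name or '(unnamed)'}"
        )
    return ROIMask(viable, "viable", gtv.voxel_spacing, name=gtv.name)


def compute_volume(mask: ROIMask) -> float:
    """ROI volume in cm^3: voxel count times voxel volume (mm^3) / 1000."""
    n = mask.n_voxels
    if n == 0:
        logger.warning("empty mask %s: volume 0", mask.name or mask.label)
        return 0.0
    voxel_mm3 = float(np.prod(mask.voxel_spacing))
    return n * voxel_mm3 / 1000.0


def extract_values(adc: ADCMap, roi: ROIMask) -> np.ndarray:
    """ADC values at valid ROI voxels, in lexicographic voxel-index order.

    The count of invalid (excluded) in-ROI voxels is logged.  Raises if no
    valid voxel remains.
    """
    _check_same_grid(adc.values.shape, roi.mask.shape, "extract_values")
    if roi.n_voxels == 0:
        raise ValueError("ROI is empty")
    take = roi.mask & adc.valid
    excluded = int(roi.n_voxels - take.sum())
    if excluded:
        logger.info("%d invalid voxels excluded from ROI %s", excluded, roi.name or roi.label)
    if not take.any():
        raise ValueError("no valid ADC voxels inside the ROI")
    # C-order boolean indexing == lexicographic (i, j, k) order.
    return adc.values[take]


def summarize_histogram(values, volume_cm3: float = math.nan) -> HistogramSummary:
    """First-order summary of an ADC sample.

    ``sd`` uses the n-1 denominator (0 for a single value); percentiles use
    linear interpolation.  Skewness/kurtosis require n >= 3 and positive
    spread, otherwise they are NaN with ``shape_defined=False``.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    n = x.size
    if n == 0:
        raise ValueError("cannot summarize an empty value list")
    sd = 0.0 if n == 1 else float(np.std(x, ddof=1))
    p10, p25, p75, p90 = (float(v) for v in np.percentile(x, [10, 25, 75, 90]))
    defined = n >= 3 and sd > 0
    if defined:
        skew = float(sps.skew(x, bias=True))
        kurt = float(sps.kurtosis(x, fisher=True, bias=True))
    else:
        skew = kurt = math.nan
    return HistogramSummary(
        n_voxels=n,
        mean=float(np.mean(x)),
        median=float(np.median(x)),
        sd=sd,
        p10=p10,
        p25=p25,
        p75=p75,
        p90=p90,
        skewness=skew,
        kurtosis=kurt,
        volume_cm3=volume_cm3,
        shape_defined=defined,
    )


def split_components(values, seed: int = 0) -> ComponentSplit:
    """Fit a two-component Gaussian mixture and judge bimodality.

    Advisory only: the verdict is ``bimodal`` when BIC prefers two
    components over one and the fitted means differ by more than the
    weight-pooled sd.  Deterministic for a given seed (k-means init).
    Requires n >= 50; smaller samples should be reviewed manually.
    """
    x = np.asarray(values, dtype=np.float64).ravel()
    if x.size < 50:
        raise ValueError("n < 50: too few values for mixture fitting, review manually")
    # standardize so sklearn's reg_covar floor is negligible at ADC scale
    loc, scale = float(np.mean(x)), float(np.std(x))
    if scale == 0:
        raise ValueError("constant input: no components to separate")
    X = ((x - loc) / scale).reshape(-1, 1)
    gm1 = GaussianMixture(n_components=1, random_state=seed).fit(X)
    gm2 = GaussianMixture(n_components=2, random_state=seed, init_params="kmeans").fit(X)
    bic1, bic2 = float(gm1.bic(X)), float(gm2.bic(X))

    means = gm2.means_.ravel() * scale + loc
    sds = np.sqrt(gm2.covariances_.ravel()) * scale
    weights = gm2.weights_.ravel()
    order = np.argsort(means)
    means, sds, weights = means[order], sds[order], weights[order]

    resp = gm2.predict_proba(X)[:, order]
    assignments = np.argmax(resp, axis=1)

    pooled_sd = math.sqrt(weights[0] * sds[0] ** 2 + weights[1] * sds[1] ** 2)
    separated = (means[1] - means[0]) > pooled_sd
    bimodal = (bic2 < bic1) and separated
    return ComponentSplit(
        means=(float(means[0]), float(means[1])),
        sds=(float(sds[0]), float(sds[1])),
        weights=(float(weights[0]), float(weights[1])),
        assignments=assignments,
        bimodal=bool(bimodal),
        bic_one=bic1,
        bic_two=bic2,
    )
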