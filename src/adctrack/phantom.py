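"""Seeded digital phantoms for weekly DWI response analysis.

A phantom is a nodal lesion on a regular grid: an ellipsoidal viable
compartment (low ADC, positively skewed) with an optional embedded
cystic/necrotic compartment (high ADC), imaged at >= 2 b-values with
Rician magnitude noise.  Weekly schedules scale the viable compartment's
ADC level (median multipliers), the lesion volume, and the cystic
compartment's size, so downstream trend analysis has a known ground truth.

Seed contract: the integer ``seed`` drives the noise realization only.
Tissue microstructure (the per-voxel true ADC draws) is a deterministic
function of the structural fields of the spec, so two specs differing only
in seed share identical masks and ground truth, and identical specs are
bit-identical.  Per-compartment fields are rescaled so that each week's
in-mask median equals the compartment's nominal median times that week's
multiplier exactly (before noise).
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats as sps

from .adc import DWISeries
from .roi import ROIMask

# Defaults anchored to a 3T head-and-neck protocol: b = {0, 800} s/mm^2,
# 1.7 x 1.7 x 5 mm voxels, pretreatment viable median 1.19e-3 mm^2/s.
VIABLE_MEDIAN_ADC = 1.19e-3
CYSTIC_MEDIAN_ADC = 2.4e-3
DEFAULT_B_VALUES = (0.0, 800.0)
DEFAULT_SPACING = (1.7, 1.7, 5.0)
# Weekly population medians: +14/25/41/42/45/58 % ADC, -8/10/16/22/40/42 % volume.
DEFAULT_ADC_MULTIPLIERS = (1.0, 1.14, 1.25, 1.41, 1.42, 1.45, 1.58)
DEFAULT_VOLUME_MULTIPLIERS = (1.0, 0.92, 0.90, 0.84, 0.78, 0.60, 0.58)
#: Median scan day per week index (week 0 = pretreatment).
DEFAULT_WEEK_DAYS = {0: 0, 1: 6, 2: 13, 3: 20, 4: 27, 5: 34, 6: 41}

ADC_FAMILIES = ("lognormal", "truncated_normal", "constant")


@dataclass(frozen=True)
class CompartmentSpec:
    """One tissue compartment: an ellipsoid with a parametric ADC law.

    ``median_adc`` is the nominal in-mask median (mm^2/s); ``spread``
    is the log-space sd for ``lognormal``, the sd (mm^2/s) for
    ``truncated_normal`` (truncated at 0), and ignored for ``constant``.
    Geometry is in voxel units.
    """

    label: str  # "viable" | "cystic"
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    family: str = "lognormal"
    median_adc: float = VIABLE_MEDIAN_ADC
    spread: float = 0.12

    def __post_init__(self):
        if self.label not in ("viable", "cystic"):
            raise ValueError(f"compartment label must be viable|cystic, got {self.label!r}")
        if self.family not in ADC_FAMILIES:
            raise ValueError(f"family must be one of {ADC_FAMILIES}")
        if self.median_adc <= 0:
            raise ValueError("median_adc must be positive")
        if self.spread < 0:
            raise ValueError("spread must be >= 0")
        if any(a < 1 for a in self.semi_axes):
            raise ValueError("semi-axes must be >= 1 voxel")


@dataclass(frozen=True)
class TrajectorySpec:
    """Weekly schedules applied to the lesion.

    ``adc_median_multipliers`` scale the viable compartment's ADC level,
    ``volume_multipliers`` scale lesion volume, and ``cystic_schedule``
    scales the cystic compartment's volume (0 = absent that week).  Week 0
    is pretreatment and its ADC/volume multipliers must be 1.
    """

    weeks: tuple[int, ...] = tuple(range(7))
    adc_median_multipliers: tuple[float, ...] = DEFAULT_ADC_MULTIPLIERS
    volume_multipliers: tuple[float, ...] = DEFAULT_VOLUME_MULTIPLIERS
    cystic_schedule: tuple[float, ...] = (1.0,) * 7

    def __post_init__(self):
        n = len(self.weeks)
        for name in ("adc_median_multipliers", "volume_multipliers", "cystic_schedule"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length must match weeks")
        if any(w2 <= w1 for w1, w2 in zip(self.weeks, self.weeks[1:])):
            raise ValueError("week indices must be strictly increasing")
        if any(m <= 0 for m in self.adc_median_multipliers):
            raise ValueError("adc_median_multipliers must be positive")
        if any(m <= 0 for m in self.volume_multipliers):
            raise ValueError("volume_multipliers must be positive")
        if any(c < 0 for c in self.cystic_schedule):
            raise ValueError("cystic_schedule must be >= 0")
        if self.adc_median_multipliers[0] != 1.0 or self.volume_multipliers[0] != 1.0:
            raise ValueError("week-0 ADC and volume multipliers must equal 1")


@dataclass(frozen=True)
class PhantomSpec:
    """Full phantom description; see module docstring for the seed contract."""

    grid_shape: tuple[int, int, int] = (48, 48, 16)
    voxel_spacing: tuple[float, float, float] = DEFAULT_SPACING
    b_values: tuple[float, ...] = DEFAULT_B_VALUES
    s0_tissue: float = 1000.0
    s0_background: float = 60.0
    background_adc: float = 0.8e-3
    noise_sigma: float = 0.0
    compartments: tuple[CompartmentSpec, ...] = (
        CompartmentSpec("viable", center=(24.0, 24.0, 8.0), semi_axes=(13.0, 13.0, 5.0)),
        CompartmentSpec(
            "cystic",
            center=(28.0, 24.0, 8.0),
            semi_axes=(5.0, 5.0, 2.5),
            family="truncated_normal",
            median_adc=CYSTIC_MEDIAN_ADC,
            spread=0.2e-3,
        ),
    )
    trajectory: TrajectorySpec = field(default_factory=TrajectorySpec)
    seed: int = 0
    overlap_precedence: str | None = "cystic"

    def __post_init__(self):
        if len(set(float(b) for b in self.b_values)) < 2:
            raise ValueError("need >= 2 distinct b-values")
        if 0.0 not in [float(b) for b in self.b_values]:
            raise ValueError("one b-value must be 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel spacing must be positive")
        labels = [c.label for c in self.compartments]
        if labels.count("viable") != 1:
            raise ValueError("exactly one viable compartment is required")
        if labels.count("cystic") > 1:
            raise ValueError("at most one cystic compartment is supported")
        if self.overlap_precedence not in (None, "cystic"):
            raise ValueError("overlap_precedence must be None or 'cystic'")


@dataclass
class PhantomWeek:
    week: int
    series: DWISeries
    masks: dict[str, ROIMask]  # keys: gtv, cystic_necrotic, viable
    true_adc: np.ndarray  # noiseless per-voxel ADC (mm^2/s), whole grid


@dataclass
class PhantomOutput:
    """Per-week volumes/masks plus the ground-truth table.

    ``truth`` columns: week, compartment (gtv|viable|cystic), true_median_adc,
    true_mean_adc, volume_cm3.
    """

    spec: PhantomSpec
    weeks: list[PhantomWeek]
    truth: pd.DataFrame


def rician_noise(signal: np.ndarray, sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Rician magnitude noise: sqrt((S + g1*sigma)^2 + (g2*sigma)^2).

    ``sigma = 0`` returns the input unchanged (no generator draws).
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    signal = np.asarray(signal, dtype=np.float64)
    if np.any(signal < 0):
        raise ValueError("signal must be non-negative")
    if sigma == 0:
        return signal
    g1 = rng.standard_normal(signal.shape)
    g2 = rng.standard_normal(signal.shape)
    return np.sqrt((signal + g1 * sigma) ** 2 + (g2 * sigma) ** 2)


def _structural_seed(spec: PhantomSpec) -> int:
    """Deterministic tissue seed from everything except the noise seed."""
    payload = json.dumps(
        {
            "grid": spec.grid_shape,
            "compartments": [
                (c.label, c.center, c.semi_axes, c.family, c.median_adc, c.spread)
                for c in spec.compartments
            ],
        },
        sort_keys=True,
    )
    return int.from_bytes(hashlib.sha256(payload.encode()).digest()[:8], "big")


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    idx = np.indices(shape, dtype=np.float64)
    d2 = sum(((idx[k] - center[k]) / semi_axes[k]) ** 2 for k in range(3))
    return d2 <= 1.0


#: Draws are truncated at +/- this many spread units so that, with default
#: parameters, viable and cystic supports are disjoint (bimodal by construction).
_TRUNC_Z = 3.0


def _base_field(comp: CompartmentSpec, shape, rng: np.random.Generator) -> np.ndarray:
    """Per-voxel base ADC draws for one compartment over the whole grid."""
    if comp.family == "constant" or comp.spread == 0:
        return np.full(shape, comp.median_adc)
    if comp.family == "lognormal":
        lo, hi = sps.norm.cdf(-_TRUNC_Z), sps.norm.cdf(_TRUNC_Z)
        z = sps.norm.ppf(rng.uniform(lo, hi, size=shape))
        return np.exp(np.log(comp.median_adc) + comp.spread * z)
    # normal truncated at zero and at +/- 3 sd
    a = max(-_TRUNC_Z, -comp.median_adc / comp.spread)
    return sps.truncnorm.rvs(
        a, _TRUNC_Z, loc=comp.median_adc, scale=comp.spread, size=shape, random_state=rng
    )


def _calibrated(values: np.ndarray, target_median: float) -> np.ndarray:
    """Rescale so the sample median equals target_median exactly."""
    med = float(np.median(values))
    return values * (target_median / med)


def generate_phantom(spec: PhantomSpec) -> PhantomOutput:
    """Generate weekly DWI series, ROI masks, and ground truth for one lesion.

    Where viable and cystic ellipsoids overlap, the cystic compartment wins
    (viable = GTV minus cystic), unless ``overlap_precedence`` is ``None``
    in which case an overlap raises.
    """
    shape = tuple(spec.grid_shape)
    spacing = spec.voxel_spacing
    traj = spec.trajectory
    viable_comp = next(c for c in spec.compartments if c.label == "viable")
    cystic_comp = next((c for c in spec.compartments if c.label == "cystic"), None)

    tissue_rng = np.random.default_rng(_structural_seed(spec))
    viable_base = _base_field(viable_comp, shape, tissue_rng)
    cystic_base = _base_field(cystic_comp, shape, tissue_rng) if cystic_comp else None
    noise_rng = np.random.default_rng(spec.seed)

    b_values = tuple(float(b) for b in spec.b_values)
    weeks: list[PhantomWeek] = []
    truth_rows: list[dict] = []
    voxel_cm3 = float(np.prod(spacing)) / 1000.0

    for i, week in enumerate(traj.weeks):
        vol_scale = traj.volume_multipliers[i] ** (1.0 / 3.0)
        viable_ell = _ellipsoid_mask(
            shape, viable_comp.center, tuple(a * vol_scale for a in viable_comp.semi_axes)
        )
        cyst_factor = traj.cystic_schedule[i] if cystic_comp else 0.0
        if cystic_comp is not None and cyst_factor > 0:
            cyst_scale = cyst_factor ** (1.0 / 3.0)
            cystic_ell = _ellipsoid_mask(
                shape, cystic_comp.center, tuple(a * cyst_scale for a in cystic_comp.semi_axes)
            )
        else:
            cystic_ell = np.zeros(shape, dtype=bool)

        if spec.overlap_precedence is None and (viable_ell & cystic_ell).any():
            raise ValueError(
                "viable and cystic compartments overlap and no precedence is declared"
            )
        gtv = viable_ell | cystic_ell
        viable = gtv & ~cystic_ell
        if not viable.any():
            raise ValueError(f"viable compartment is empty at week {week}")

        true_adc = np.full(shape, spec.background_adc)
        target = viable_comp.median_adc * traj.adc_median_multipliers[i]
        true_adc[viable] = _calibrated(viable_base[viable], target)
        if cystic_ell.any():
            true_adc[cystic_ell] = _calibrated(
                cystic_base[cystic_ell], cystic_comp.median_adc
            )

        s0_map = np.where(gtv, spec.s0_tissue, spec.s0_background)
        volumes = []
        for b in b_values:
            clean = s0_map * np.exp(-b * true_adc)
            volumes.append(rician_noise(clean, spec.noise_sigma, noise_rng))

        series = DWISeries(
            b_values=b_values,
            volumes=tuple(volumes),
            voxel_spacing=spacing,
            week=week,
            days_from_rt_start=DEFAULT_WEEK_DAYS.get(week),
        )
        masks = {
            "gtv": ROIMask(gtv, "gtv", spacing, name=f"week{week}"),
            "cystic_necrotic": ROIMask(cystic_ell, "cystic_necrotic", spacing, name=f"week{week}"),
            "viable": ROIMask(viable, "viable", spacing, name=f"week{week}"),
        }
        for comp_name, m in (("gtv", gtv), ("viable", viable), ("cystic", cystic_ell)):
            if not m.any():
                continue
            vals = true_adc[m]
            truth_rows.append(
                {
                    "week": week,
                    "compartment": comp_name,
                    "true_median_adc": float(np.median(vals)),
                    "true_mean_adc": float(np.mean(vals)),
                    "volume_cm3": int(m.sum()) * voxel_cm3,
                }
            )
        weeks.append(PhantomWeek(week=week, series=series, masks=masks, true_adc=true_adc))

    truth = pd.DataFrame(truth_rows, columns=[
        "week", "compartment", "true_median_adc", "true_mean_adc", "volume_cm3"
    ])
    return PhantomOutput(spec=spec, weeks=weeks, truth=truth)


def generate_cohort_specs(
    base: PhantomSpec,
    n_lesions: int,
    seed: int,
    median_adc_range: tuple[float, float] = (0.92e-3, 1.51e-3),
    multiplier_jitter: float = 0.02,
) -> list[PhantomSpec]:
    """Per-lesion spec variants for a cohort around one trajectory.

    Each lesion gets its own pretreatment viable median (uniform over
    ``median_adc_range``), multiplicatively jittered non-baseline ADC
    multipliers (lognormal with sd ``multiplier_jitter``), and its own
    noise seed.  Drawing is governed by a single cohort generator seeded
    with ``seed``.
    """
    if n_lesions < 1:
        raise ValueError("n_lesions must be >= 1")
    rng = np.random.default_rng(seed)
    specs = []
    for j in range(n_lesions):
        med = float(rng.uniform(*median_adc_range))
        jitter = np.exp(rng.normal(0.0, multiplier_jitter, size=len(base.trajectory.weeks)))
        jitter[0] = 1.0
        mults = tuple(
            m * g for m, g in zip(base.trajectory.adc_median_multipliers, jitter)
        )
        comps = tuple(
            replace(c, median_adc=med) if c.label == "viable" else c
            for c in base.compartments
        )
        traj = replace(base.trajectory, adc_median_multipliers=mults)
        specs.append(
            replace(base, compartments=comps, trajectory=traj, seed=seed + 1000 + j)
        )
    return specs


# ---------------------------------------------------------------------------
# Config plumbing (YAML/JSON mirrors PhantomSpec field-for-field)

def spec_from_dict(cfg: dict) -> PhantomSpec:
    """Build a PhantomSpec from a config mapping; missing keys use defaults."""
    kwargs: dict = {}
    simple = (
        "s0_tissue",
        "s0_background",
        "background_adc",
        "noise_sigma",
        "seed",
        "overlap_precedence",
    )
    for key in simple:
        if key in cfg:
            kwargs[key] = cfg[key]
    for key in ("grid_shape", "voxel_spacing", "b_values"):
        if key in cfg:
            kwargs[key] = tuple(cfg[key])
    if "compartments" in cfg:
        comps = []
        for c in cfg["compartments"]:
            comps.append(
                CompartmentSpec(
                    label=c["label"],
                    center=tuple(c["center"]),
                    semi_axes=tuple(c["semi_axes"]),
                    family=c.get("family", "lognormal"),
                    median_adc=c.get("median_adc", VIABLE_MEDIAN_ADC),
                    spread=c.get("spread", 0.12),
                )
            )
        kwargs["compartments"] = tuple(comps)
    if "trajectory" in cfg:
        t = cfg["trajectory"]
        traj_kwargs = {}
        for key in ("weeks", "adc_median_multipliers", "volume_multipliers", "cystic_schedule"):
            if key in t:
                traj_kwargs[key] = tuple(t[key])
        if "weeks" in traj_kwargs and "cystic_schedule" not in traj_kwargs:
            traj_kwargs["cystic_schedule"] = (1.0,) * len(traj_kwargs["weeks"])
        kwargs["trajectory"] = TrajectorySpec(**traj_kwargs)
    return PhantomSpec(**kwargs)


def write_phantom(output: PhantomOutput, out_dir) -> None:
    """Write per-week NIfTI volumes (one per b-value), uint8 masks, and the
    ground-truth CSV into ``out_dir``."""
    import os

    from . import nifti_io

    os.makedirs(out_dir, exist_ok=True)
    spacing = output.spec.voxel_spacing
    for wk in output.weeks:
        for b, vol in zip(wk.series.b_values, wk.series.volumes):
            nifti_io.save_volume(
                vol, spacing, os.path.join(out_dir, f"week{wk.week}_b{int(b)}.nii")
            )
        for key, fname in (
            ("gtv", "gtv"),
            ("cystic_necrotic", "cystic"),
            ("viable", "viable"),
        ):
            nifti_io.save_mask(
                wk.masks[key].mask,
                spacing,
                os.path.join(out_dir, f"week{wk.week}_mask_{fname}.nii"),
            )
    output.truth.to_csv(os.path.join(out_dir, "ground_truth.csv"), index=False)
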