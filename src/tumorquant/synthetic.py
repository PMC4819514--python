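"""Synthetic phantoms with known ground truth for every pipeline stage.

Three generators emulate the study's three data streams:

* :func:`make_dce_phantom` — an ellipsoidal tumor with an enhancing rim and
  a poorly-perfused core. The dynamic signal is produced by the *exact
  forward chain* the fitting pipeline inverts: extended-Kety concentration
  from the ground-truth (Ktrans, v_e, v_p) map, longitudinal relaxation via
  R1(t) = R1(0) + r1 C(t), SPGR signal at the (flip-angle-scaled) dynamic
  angle, plus the VFA and flip-angle-calibration scans from the same T1 and
  kappa maps. At zero noise the full pipeline must recover every map.
* :func:`make_section_phantom` — a 2D tumor section whose marker channels
  are painted to requested positive fractions exactly, with single-pixel
  vessels, a perfused subset, and hypoxia painted wherever the distance to
  the nearest *perfused* vessel exceeds a diffusion-limit threshold.
* :func:`make_group_cohort` — per-tumor metric draws from log-normal
  distributions with arm-wise multiplicative effects, emulating the
  three-arm (vehicle / anti-VEGFR-2 / metronomic-gemcitabine) design with
  n = 8 tumors per arm.

All generators are deterministic under their integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, model_validator

from .acquisition import AcquisitionParams, AIFModel, spgr_signal
from .errors import InvalidInputError
from .histology import SectionImageSet
from .pk_model import RELAXIVITY_R1_DEFAULT, DynamicSeries, PKParameterMap, kety_forward
from .stats import GROUP_COLUMNS

__all__ = [
    "PhantomSpec",
    "SectionPhantomSpec",
    "DCEPhantom",
    "GroundTruthMetrics",
    "make_dce_phantom",
    "make_section_phantom",
    "make_group_cohort",
    "DEFAULT_ARM_EFFECTS",
    "DEFAULT_BASELINES",
]

#: painted intensity conventions for section phantoms
_POSITIVE = 200.0
_BACKGROUND = 10.0
#: fixed positivity threshold matching the painted intensities
SECTION_THRESHOLD = 100.0


class PhantomSpec(BaseModel):
    """Geometry, kinetics and noise of the DCE tumor phantom.

    The tumor is an ellipsoid with semi-axes 0.35 x the grid extent; the
    enhancing rim is the outer ``rim_fraction`` of the normalized
    ellipsoidal radius, the core the remainder. ``noise_sd`` is the SD of
    additive Gaussian noise on the magnitude signal, in the same arbitrary
    units as ``m0`` — the default 0.0 gives the noiseless closure phantom;
    realistic runs use ~2 % of the baseline dynamic signal. ``kappa_range``
    spans a linear transmit-field gradient along the first axis, the kind of
    smooth B1 variation a surface coil produces.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    grid_shape: tuple[int, int, int] = (24, 24, 24)
    voxel_size: tuple[float, float, float] = (0.3, 0.3, 1.0)  # mm
    rim_fraction: float = 0.4
    ktrans_rim: float = 0.3  # per minute
    ktrans_core: float = 0.1
    ve: float = 0.3
    vp: float = 0.05
    t1_ms: float = 1500.0
    m0: float = 100.0
    kappa_range: tuple[float, float] = (0.9, 1.1)
    noise_sd: float = 0.0
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "PhantomSpec":
        if any(n <= 0 for n in self.grid_shape):
            raise ValueError("grid_shape must be strictly positive")
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be strictly positive")
        if not 0.0 < self.rim_fraction <= 1.0:
            raise ValueError("rim_fraction must lie in (0, 1]")
        if self.ktrans_rim < 0 or self.ktrans_core < 0:
            raise ValueError("ktrans values must be non-negative")
        if not 0.0 < self.ve <= 1.0:
            raise ValueError("ve must lie in (0, 1]")
        if not 0.0 <= self.vp <= 1.0 or self.ve + self.vp > 1.0:
            raise ValueError("vp must lie in [0, 1] with ve + vp <= 1")
        if self.t1_ms <= 0 or self.m0 <= 0:
            raise ValueError("t1_ms and m0 must be strictly positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if any(k <= 0 for k in self.kappa_range):
            raise ValueError("kappa_range must be strictly positive")
        return self


@dataclass
class DCEPhantom:
    """Everything :func:`make_dce_phantom` produced, ground truth included."""

    dynamic: DynamicSeries
    vfa_scans: np.ndarray  # (3, *grid)
    cal_scans: np.ndarray  # (3, *grid)
    truth_pk: PKParameterMap
    mask: np.ndarray
    truth_t1: np.ndarray
    truth_kappa: np.ndarray
    aif: AIFModel
    acq: AcquisitionParams
    relaxivity_r1: float


def _ellipsoid_radius(grid_shape: tuple[int, int, int]) -> np.ndarray:
    """Normalized ellipsoidal radius of every voxel (1.0 on the surface)."""
    axes = [np.arange(n, dtype=float) - (n - 1) / 2.0 for n in grid_shape]
    semi = [0.35 * n for n in grid_shape]
    zz, yy, xx = np.meshgrid(*axes, indexing="ij")
    return np.sqrt(
        (zz / semi[0]) ** 2 + (yy / semi[1]) ** 2 + (xx / semi[2]) ** 2
    )


def make_dce_phantom(
    spec: PhantomSpec,
    aif: AIFModel | None = None,
    acq: AcquisitionParams | None = None,
) -> DCEPhantom:
    """Generate the full MR acquisition for a rim/core tumor phantom.

    The bolus arrives exactly when the post-contrast block starts
    (onset = n_pre * frame_interval), so every pre-contrast frame carries
    zero contrast agent. Noise is additive Gaussian on all scans.
    """
    acq = acq or AcquisitionParams()
    if aif is None:
        aif = AIFModel(onset_time=acq.n_pre * acq.frame_interval)
    grid = spec.grid_shape

    rho = _ellipsoid_radius(grid)
    mask = rho <= 1.0
    rim = mask & (rho > 1.0 - spec.rim_fraction)
    core = mask & ~rim

    ktrans = np.zeros(grid)
    ktrans[rim] = spec.ktrans_rim
    ktrans[core] = spec.ktrans_core
    ve = np.where(mask, spec.ve, 0.0)
    vp = np.where(mask, spec.vp, 0.0)

    # smooth transmit-field gradient along axis 0
    k_lo, k_hi = spec.kappa_range
    profile = np.linspace(k_lo, k_hi, grid[0])
    kappa = np.broadcast_to(profile[:, None, None], grid).copy()
    t1 = np.full(grid, spec.t1_ms)  # uniform native T1

    times = acq.frame_times()
    # only two distinct kinetic parameter sets: evaluate two curves, broadcast
    conc = np.zeros(grid + (acq.n_frames,))
    if rim.any():
        conc[rim] = kety_forward(spec.ktrans_rim, spec.ve, spec.vp, aif, times)
    if core.any():
        conc[core] = kety_forward(spec.ktrans_core, spec.ve, spec.vp, aif, times)

    r1 = 1000.0 / t1[..., None] + RELAXIVITY_R1_DEFAULT * conc  # 1/s
    t1_t = 1000.0 / r1  # ms
    alpha_dyn = kappa * acq.flip_dyn
    signal = spgr_signal(spec.m0, t1_t, acq.tr_dyn, alpha_dyn[..., None])

    vfa = np.stack(
        [spgr_signal(spec.m0, t1, acq.tr_vfa, kappa * a) for a in acq.flip_vfa]
    )
    # long-TR calibration scans: amplitude x |sin(kappa * alpha)|; the long TR
    # makes T1 weighting second-order and the fit model ignores it by design
    cal = np.stack(
        [spec.m0 * np.abs(np.sin(np.deg2rad(kappa * a))) for a in acq.flip_cal]
    )

    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        signal = signal + rng.normal(0.0, spec.noise_sd, signal.shape)
        vfa = vfa + rng.normal(0.0, spec.noise_sd, vfa.shape)
        cal = cal + rng.normal(0.0, spec.noise_sd, cal.shape)

    truth = PKParameterMap(
        ktrans=ktrans,
        ve=ve,
        vp=vp,
        rss=np.zeros(grid),
        fit_ok=mask.copy(),
        enhancing=mask.copy(),
    )
    dyn = DynamicSeries(signal=signal, frame_times=times, acq=acq)
    return DCEPhantom(
        dynamic=dyn,
        vfa_scans=vfa,
        cal_scans=cal,
        truth_pk=truth,
        mask=mask,
        truth_t1=t1,
        truth_kappa=kappa,
        aif=aif,
        acq=acq,
        relaxivity_r1=RELAXIVITY_R1_DEFAULT,
    )


class SectionPhantomSpec(BaseModel):
    """Painted-section phantom: every histology metric has exact ground truth.

    ``hypoxia_distance_um`` is the oxygen-diffusion-limit surrogate: pixels
    farther than this from the nearest *perfused* vessel are painted
    EF5-positive. The default 120 um sits in the classic 100-150 um range.
    Pixel size defaults to 5 um — whole-section mosaics are quantified on a
    downsampled grid, so the default 200 x 200 phantom spans 1 x 1 mm.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    image_shape: tuple[int, int] = (200, 200)
    pixel_size_um: float = 5.0
    n_vessels: int = 40
    perfused_fraction_true: float = 0.6
    hypoxia_distance_um: float = 120.0
    necrosis_fraction_true: float = 0.2
    ki67_fraction_true: float = 0.3
    tunel_fraction_true: float = 0.05
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "SectionPhantomSpec":
        if any(n <= 0 for n in self.image_shape):
            raise ValueError("image_shape must be strictly positive")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be strictly positive")
        if self.n_vessels < 0:
            raise ValueError("n_vessels must be non-negative")
        for name in (
            "perfused_fraction_true",
            "necrosis_fraction_true",
            "ki67_fraction_true",
            "tunel_fraction_true",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.hypoxia_distance_um <= 0:
            raise ValueError("hypoxia_distance_um must be strictly positive")
        return self


@dataclass(frozen=True)
class GroundTruthMetrics:
    """What the painted section should measure, by construction counts."""

    ef5_fraction: float
    ki67_fraction: float
    tunel_fraction: float
    perfused_vessel_fraction: float | None
    mean_vessel_distance_um: float | None
    necrotic_fraction: float


def make_section_phantom(
    spec: SectionPhantomSpec,
) -> tuple[SectionImageSet, GroundTruthMetrics]:
    """Paint a section whose metrics equal the requested ground truth.

    The tumor mask is a centered rectangle (the cropped-to-boundary image);
    necrosis fills the first ``round(frac * N)`` tumor pixels in raster
    order (a contiguous band, as real necrotic cores are); vessels are
    single CD31+ pixels sampled uniformly from viable tissue with the first
    ``round(frac * n)`` of them Hoechst+. Marker channels paint positive
    pixels at intensity 200 on a background of 10, so the fixed threshold
    ``SECTION_THRESHOLD`` recovers the painted sets exactly.
    """
    from scipy import ndimage  # local: keeps module import light

    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    margin_y, margin_x = max(1, h // 20), max(1, w // 20)
    tumor = np.zeros((h, w), dtype=bool)
    tumor[margin_y : h - margin_y, margin_x : w - margin_x] = True
    n_tumor = int(tumor.sum())
    if n_tumor == 0:
        raise InvalidInputError("image too small for a tumor region")

    n_necro = round(spec.necrosis_fraction_true * n_tumor)
    tumor_idx = np.flatnonzero(tumor.ravel())
    necrosis = np.zeros((h, w), dtype=bool)
    necrosis.ravel()[tumor_idx[:n_necro]] = True
    artifact = np.zeros((h, w), dtype=bool)

    viable = tumor & ~necrosis
    viable_idx = np.flatnonzero(viable.ravel())
    n_viable = viable_idx.size
    if n_viable == 0 and (
        spec.n_vessels > 0 or spec.ki67_fraction_true > 0 or spec.tunel_fraction_true > 0
    ):
        raise InvalidInputError("no viable tissue left to paint markers into")
    if spec.n_vessels > n_viable:
        raise InvalidInputError(
            f"cannot place {spec.n_vessels} vessels in {n_viable} viable pixels"
        )

    def _paint_exact(n_pos: int, pool: np.ndarray) -> np.ndarray:
        chosen = rng.choice(pool, size=n_pos, replace=False) if n_pos else np.array([], int)
        m = np.zeros((h, w), dtype=bool)
        m.ravel()[chosen] = True
        return m

    vessel_px = (
        rng.choice(viable_idx, size=spec.n_vessels, replace=False)
        if spec.n_vessels
        else np.array([], dtype=int)
    )
    n_perf = round(spec.perfused_fraction_true * spec.n_vessels)
    cd31 = np.zeros((h, w), dtype=bool)
    cd31.ravel()[vessel_px] = True
    hoechst = np.zeros((h, w), dtype=bool)
    hoechst.ravel()[vessel_px[:n_perf]] = True

    # hypoxia: farther than the diffusion limit from any perfused vessel
    if n_perf > 0:
        dist_perf = ndimage.distance_transform_edt(~hoechst, sampling=spec.pixel_size_um)
        ef5 = viable & (dist_perf > spec.hypoxia_distance_um)
    else:
        ef5 = viable.copy()  # nothing perfused: everything viable is hypoxic

    ki67 = _paint_exact(round(spec.ki67_fraction_true * n_viable), viable_idx)
    tunel = _paint_exact(round(spec.tunel_fraction_true * n_viable), viable_idx)

    def _channel(mask: np.ndarray) -> np.ndarray:
        return np.where(mask, _POSITIVE, _BACKGROUND)

    # counterstain: nuclear stain across the tissue with deterministic texture
    # so that cross-correlation alignment has structure to lock onto
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, (h, w)), sigma=3.0)
    counterstain = np.where(tumor, 150.0 + 40.0 * texture, _BACKGROUND)

    channels = {
        "hoechst_perfusion": _channel(hoechst),
        "cd31": _channel(cd31),
        "ef5": _channel(ef5),
        "ki67": _channel(ki67),
        "tunel": _channel(tunel),
        "counterstain": counterstain,
    }
    image_set = SectionImageSet(
        channels=channels,
        pixel_size_um=spec.pixel_size_um,
        tumor_mask=tumor,
        necrosis_mask=necrosis,
        artifact_mask=artifact,
    )

    if spec.n_vessels > 0:
        edt = ndimage.distance_transform_edt(~cd31, sampling=spec.pixel_size_um)
        mvd = float(edt[viable].mean())
        pvf = 100.0 * n_perf / spec.n_vessels
    else:
        mvd = None
        pvf = None
    truth = GroundTruthMetrics(
        ef5_fraction=100.0 * float(ef5.sum()) / n_viable if n_viable else 0.0,
        ki67_fraction=100.0 * float(ki67.sum()) / n_viable if n_viable else 0.0,
        tunel_fraction=100.0 * float(tunel.sum()) / n_viable if n_viable else 0.0,
        perfused_vessel_fraction=pvf,
        mean_vessel_distance_um=mvd,
        necrotic_fraction=100.0 * n_necro / n_tumor,
    )
    return image_set, truth


#: arm-wise multiplicative effects emulating the PaCa13 day-7 physiology:
#: metronomic gemcitabine shrinks tumors ~10-fold, raises median Ktrans
#: ~5-fold in this line (~2-fold in PaCa8), slashes hypoxia and improves
#: perfusion; the anti-VEGFR-2 antibody prunes vessels (longer
#: nearest-vessel distance) without moving Ktrans.
DEFAULT_ARM_EFFECTS: dict[str, dict[str, float]] = {
    "volume_mm3": {"Veh-ctrl": 1.0, "DC101": 0.8, "Met-Gem": 0.1},
    "ktrans_median": {"Veh-ctrl": 1.0, "DC101": 1.0, "Met-Gem": 5.0},
    "ef5_fraction": {"Veh-ctrl": 1.0, "DC101": 1.2, "Met-Gem": 0.25},
    "vessel_distance_um": {"Veh-ctrl": 1.0, "DC101": 1.8, "Met-Gem": 0.7},
    "fdg_per_volume": {"Veh-ctrl": 1.0, "DC101": 1.2, "Met-Gem": 0.6},
}

#: per-metric baselines for the vehicle arm (units as named)
DEFAULT_BASELINES: dict[str, float] = {
    "volume_mm3": 600.0,
    "ktrans_median": 0.15,
    "ef5_fraction": 20.0,
    "vessel_distance_um": 60.0,
    "fdg_per_volume": 1.0,
}

#: log-normal shape: inter-tumor coefficient of variation ~40 %
DEFAULT_COHORT_SIGMA = 0.4


def make_group_cohort(
    n_per_arm: int = 8,
    effects: dict[str, dict[str, float]] | None = None,
    seed: int = 0,
    *,
    baselines: dict[str, float] | None = None,
    sigma: float = DEFAULT_COHORT_SIGMA,
    line: str = "PaCa13",
    day: int = 7,
) -> pd.DataFrame:
    """Draw a three-arm cohort of per-tumor metrics (long-format table).

    value = baseline * effect[arm] * exp(sigma * Z), Z ~ N(0, 1) — a
    log-normal with median at the arm effect, matching the strictly positive,
    right-skewed spread of tumor volumes and imaging metrics. ``sigma = 0``
    collapses each arm onto its effect exactly.
    """
    if n_per_arm < 2:
        raise InvalidInputError("n_per_arm must be >= 2")
    if sigma < 0:
        raise InvalidInputError("sigma must be non-negative")
    effects = effects if effects is not None else DEFAULT_ARM_EFFECTS
    baselines = baselines if baselines is not None else DEFAULT_BASELINES
    for metric, per_arm in effects.items():
        if any(e <= 0 for e in per_arm.values()):
            raise InvalidInputError(f"non-positive effect for metric {metric!r}")
        if metric not in baselines:
            raise InvalidInputError(f"no baseline for metric {metric!r}")

    rng = np.random.default_rng(seed)
    rows = []
    for metric, per_arm in effects.items():
        for arm, effect in per_arm.items():
            z = rng.normal(0.0, 1.0, n_per_arm)
            values = baselines[metric] * effect * np.exp(sigma * z)
            for i, v in enumerate(values):
                rows.append(
                    {
                        "tumor_id": f"{line}-{arm}-{i:02d}",
                        "line": line,
                        "arm": arm,
                        "day": day,
                        "metric": metric,
                        "value": float(v),
                    }
                )
    return pd.DataFrame(rows, columns=GROUP_COLUMNS)
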