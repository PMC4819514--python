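"""Flip-angle (B1) map estimation and variable-flip-angle T1 mapping.

Surface-coil transmission makes the realized flip angle differ from the
nominal one by a smooth spatial scale ``kappa`` (actual = kappa * nominal).
Three long-TR calibration scans bracketing the 180 deg signal null
(145/180/215 deg) pin down kappa per voxel: the measured magnitude signal is
modeled as A * |sin(kappa * alpha_nom)|, which nulls exactly where
kappa * alpha_nom crosses 180 deg. Long TR makes T1 weighting of these scans
second-order; the |sin| model deliberately ignores it.

Native T1 then comes from three SPGR scans at low-to-moderate angles
(10/20/50 deg) via the classical linearization: plotting S/sin(a) against
S/tan(a) (with a the *corrected* angle) gives a line of slope
E1 = exp(-TR/T1) and intercept M0 (1 - E1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .acquisition import AcquisitionParams
from .errors import InvalidInputError

__all__ = ["FlipAngleMap", "T1Map", "fit_flip_angle_map", "fit_t1_vfa"]

KAPPA_SEARCH = (0.5, 1.5)  # plausible B1 scale range for the surface coil


@dataclass
class FlipAngleMap:
    """Per-voxel multiplicative flip-angle scale (actual = kappa * nominal)."""

    kappa: np.ndarray
    fit_ok: np.ndarray  # False where the fit failed and kappa fell back to 1

    def __post_init__(self) -> None:
        self.kappa = np.asarray(self.kappa, dtype=float)
        self.fit_ok = np.asarray(self.fit_ok, dtype=bool)
        if self.kappa.shape != self.fit_ok.shape:
            raise InvalidInputError("kappa and fit_ok shapes differ")


@dataclass
class T1Map:
    """Per-voxel native T1 (ms) and equilibrium-signal scale M0 (a.u.)."""

    t1: np.ndarray
    m0: np.ndarray
    fit_ok: np.ndarray

    def __post_init__(self) -> None:
        self.t1 = np.asarray(self.t1, dtype=float)
        self.m0 = np.asarray(self.m0, dtype=float)
        self.fit_ok = np.asarray(self.fit_ok, dtype=bool)
        if not (self.t1.shape == self.m0.shape == self.fit_ok.shape):
            raise InvalidInputError("t1/m0/fit_ok shapes differ")

    def summary(self) -> dict:
        ok = int(self.fit_ok.sum())
        return {"voxels_ok": ok, "voxels_flagged": int(self.fit_ok.size - ok)}


def _kappa_sse_projected(kappa: np.ndarray, signals: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    """Residual SSE of S ~ A |sin(kappa a)| with the amplitude A projected out.

    kappa: (K,) candidate scales; signals: (V, 3); angles_rad: (3,).
    Returns (K, V). For each kappa the optimal amplitude is
    A* = sum(S |s|) / sum(s^2), s = sin(kappa a), giving
    SSE = sum(S^2) - (sum(S |s|))^2 / sum(s^2).
    """
    s = np.abs(np.sin(kappa[:, None] * angles_rad[None, :]))  # (K, 3)
    ss = (s**2).sum(axis=1)  # (K,)
    cross = signals @ s.T  # (V, K)
    sq = (signals**2).sum(axis=1)  # (V,)
    with np.errstate(divide="ignore", invalid="ignore"):
        sse = sq[None, :] - (cross.T**2) / ss[:, None]
    return sse


def fit_flip_angle_map(
    cal_scans: np.ndarray,
    acq: AcquisitionParams,
    mask: np.ndarray,
    *,
    n_grid: int = 401,
    n_golden: int = 60,
) -> FlipAngleMap:
    """Fit per-voxel kappa from the three flip-angle-calibration scans.

    Parameters
    ----------
    cal_scans
        Array of shape (3, *grid): magnitude signals at the nominal
        calibration angles ``acq.flip_cal``, in that order.
    mask
        Boolean tumor mask on the same grid; kappa is fitted inside it only.

    The 1-D least-squares problem in kappa (amplitude solved in closed form)
    is minimized by a dense grid over ``KAPPA_SEARCH`` followed by a vectorized
    golden-section refinement — derivative-free because |sin| has a kink at
    the null. Voxels with all-zero signal (no tissue) are flagged and fall
    back to kappa = 1, i.e. the nominal angle.
    """
    cal_scans = np.asarray(cal_scans, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if cal_scans.ndim < 2 or cal_scans.shape[0] != 3:
        raise InvalidInputError("cal_scans must stack exactly three scans on axis 0")
    if cal_scans.shape[1:] != mask.shape:
        raise InvalidInputError("calibration scans and mask grids differ")
    if len(acq.flip_cal) != 3:
        raise InvalidInputError("three nominal calibration angles required")

    angles = np.deg2rad(np.asarray(acq.flip_cal, dtype=float))
    sig = cal_scans.reshape(3, -1).T[mask.ravel()]  # (V, 3)
    finite = np.isfinite(sig).all(axis=1)
    nonzero = (sig > 0).any(axis=1)
    fittable = finite & nonzero

    kappa_v = np.ones(sig.shape[0])
    if fittable.any():
        s_fit = sig[fittable]
        grid = np.linspace(*KAPPA_SEARCH, n_grid)
        sse = _kappa_sse_projected(grid, s_fit, angles)  # (K, V)
        best = np.argmin(sse, axis=0)
        step = grid[1] - grid[0]
        lo = np.maximum(grid[best] - step, KAPPA_SEARCH[0])
        hi = np.minimum(grid[best] + step, KAPPA_SEARCH[1])

        # vectorized golden-section on the bracket (robust at the |sin| kink)
        invphi = (np.sqrt(5.0) - 1.0) / 2.0
        x1 = hi - invphi * (hi - lo)
        x2 = lo + invphi * (hi - lo)
        f1 = _eval_rows(x1, s_fit, angles)
        f2 = _eval_rows(x2, s_fit, angles)
        for _ in range(n_golden):
            take1 = f1 < f2
            hi = np.where(take1, x2, hi)
            lo = np.where(take1, lo, x1)
            x1 = hi - invphi * (hi - lo)
            x2 = lo + invphi * (hi - lo)
            f1 = _eval_rows(x1, s_fit, angles)
            f2 = _eval_rows(x2, s_fit, angles)
        kappa_v[fittable] = 0.5 * (lo + hi)

    kappa = np.ones(mask.shape, dtype=float)
    ok = np.zeros(mask.shape, dtype=bool)
    kappa[mask] = kappa_v
    ok_flat = np.zeros(sig.shape[0], dtype=bool)
    ok_flat[fittable] = True
    ok[mask] = ok_flat
    kappa[mask & ~ok] = 1.0
    return FlipAngleMap(kappa=kappa, fit_ok=ok)


def _eval_rows(kappa: np.ndarray, signals: np.ndarray, angles_rad: np.ndarray) -> np.ndarray:
    """Projected SSE evaluated at one kappa per voxel (both shape (V,))."""
    s = np.abs(np.sin(kappa[:, None] * angles_rad[None, :]))
    ss = (s**2).sum(axis=1)
    cross = (signals * s).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        return (signals**2).sum(axis=1) - cross**2 / ss


def fit_t1_vfa(
    vfa_scans: np.ndarray,
    fa_map: FlipAngleMap,
    acq: AcquisitionParams,
    mask: np.ndarray,
) -> T1Map:
    """Three-scan VFA T1 fit with per-voxel flip-angle correction.

    ``vfa_scans`` stacks the SPGR scans at ``acq.flip_vfa`` on axis 0. Per
    voxel the corrected angles are kappa * nominal, and (T1, M0) follow from
    the linear regression of y = S/sin(a) on x = S/tan(a): slope = E1,
    intercept = M0 (1 - E1). Voxels whose slope falls outside (0, 1) — no
    physical T1 — are flagged not-ok with t1 = NaN; non-finite input signals
    are likewise flagged, never raised.
    """
    vfa_scans = np.asarray(vfa_scans, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if vfa_scans.ndim < 2 or vfa_scans.shape[0] != len(acq.flip_vfa):
        raise InvalidInputError("vfa_scans must stack one scan per nominal VFA angle")
    if vfa_scans.shape[1:] != mask.shape:
        raise InvalidInputError("VFA scans and mask grids differ")
    if fa_map.kappa.shape != mask.shape:
        raise InvalidInputError("flip-angle map and mask grids differ")

    nominal = np.deg2rad(np.asarray(acq.flip_vfa, dtype=float))
    sig = vfa_scans.reshape(len(nominal), -1).T[mask.ravel()]  # (V, 3)
    kap = fa_map.kappa[mask][:, None]
    a = kap * nominal[None, :]

    with np.errstate(divide="ignore", invalid="ignore"):
        y = sig / np.sin(a)
        x = sig / np.tan(a)
    good = np.isfinite(x).all(axis=1) & np.isfinite(y).all(axis=1)

    n = x.shape[1]
    xm = x.mean(axis=1, keepdims=True)
    ym = y.mean(axis=1, keepdims=True)
    sxx = ((x - xm) ** 2).sum(axis=1)
    sxy = ((x - xm) * (y - ym)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        slope = sxy / sxx
    intercept = ym[:, 0] - slope * xm[:, 0]

    ok_v = good & np.isfinite(slope) & (slope > 0.0) & (slope < 1.0) & (intercept > 0)
    t1_v = np.full(sig.shape[0], np.nan)
    m0_v = np.full(sig.shape[0], np.nan)
    with np.errstate(divide="ignore", invalid="ignore"):
        t1_v[ok_v] = -acq.tr_vfa / np.log(slope[ok_v])
        m0_v[ok_v] = intercept[ok_v] / (1.0 - slope[ok_v])

    t1 = np.full(mask.shape, np.nan)
    m0 = np.full(mask.shape, np.nan)
    ok = np.zeros(mask.shape, dtype=bool)
    t1[mask] = t1_v
    m0[mask] = m0_v
    ok[mask] = ok_v
    return T1Map(t1=t1, m0=m0, fit_ok=ok)
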