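"""Acquisition constants and the spoiled-gradient-echo (SPGR) signal model.

The defaults encode the 7 T small-animal protocol the pipeline targets:

* flip-angle calibration — three long-TR scans near the 180° signal null
  (nominal 145°, 180°, 215°; TR = 460 ms);
* native T1 — three-scan variable flip angle (10°, 20°, 50°; TR = 144 ms);
* dynamic series — rapid T1-weighted SPGR (25°, TR = 9 ms) at 15.6 s per
  frame, 20 pre-contrast + 150 post-contrast frames.

All repetition/echo times are milliseconds, angles degrees, frame interval
seconds. ``spgr_signal`` is the single forward model shared by the synthetic
generator, the T1 fitter and the signal→concentration inversion, so closure
tests exercise one consistent chain.
"""

from __future__ import annotations

import numpy as np
from pydantic import BaseModel, ConfigDict, model_validator


class AcquisitionParams(BaseModel):
    """Constants of the three-part MR acquisition (times ms, angles deg)."""

    model_config = ConfigDict(extra="forbid", frozen=True)

    tr_cal: float = 460.0
    tr_vfa: float = 144.0
    tr_dyn: float = 9.0
    te_cal: float = 3.5
    te_vfa: float = 2.7
    te_dyn: float = 2.7
    flip_cal: tuple[float, float, float] = (145.0, 180.0, 215.0)
    flip_vfa: tuple[float, float, float] = (10.0, 20.0, 50.0)
    flip_dyn: float = 25.0
    frame_interval: float = 15.6  # seconds per dynamic frame
    n_pre: int = 20
    n_post: int = 150

    @model_validator(mode="after")
    def _check(self) -> "AcquisitionParams":
        for name in ("tr_cal", "tr_vfa", "tr_dyn", "flip_dyn", "frame_interval"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if any(a <= 0 for a in self.flip_cal) or any(a <= 0 for a in self.flip_vfa):
            raise ValueError("all nominal flip angles must be strictly positive")
        if self.n_pre < 2:
            raise ValueError("n_pre >= 2 required (baseline averaging)")
        if self.n_post < 1:
            raise ValueError("n_post must be positive")
        return self

    @property
    def n_frames(self) -> int:
        return self.n_pre + self.n_post

    def frame_times(self) -> np.ndarray:
        """Start-of-frame times (s); frame 0 acquired at t = 0."""
        return np.arange(self.n_frames, dtype=float) * self.frame_interval


class AIFModel(BaseModel):
    """Population bi-exponential arterial input function.

    C_p(t) = dose * (a1 * exp(-m1 * t') + a2 * exp(-m2 * t')), with
    t' = (t - onset_time)/60 in minutes and C_p = 0 before bolus arrival.
    Amplitudes are in mM per (mmol/kg) of injected dose, decay rates per
    minute. Defaults are the classic bi-exponential plasma-clearance
    parameters for gadolinium agents (a1 = 3.99, a2 = 4.78 kg/L;
    m1 = 0.144, m2 = 0.0111 /min) scaled by a 0.3 mmol/kg gadodiamide dose.
    The population curve is an explicit, swappable input: any study-specific
    AIF can be substituted by overriding these fields.
    """

    model_config = ConfigDict(extra="forbid", frozen=True)

    dose: float = 0.3  # mmol/kg
    a1: float = 3.99  # mM per unit dose
    a2: float = 4.78
    m1: float = 0.144  # per minute
    m2: float = 0.0111
    onset_time: float = 0.0  # bolus arrival, seconds from acquisition start

    @model_validator(mode="after")
    def _check(self) -> "AIFModel":
        if self.a1 < 0 or self.a2 < 0:
            raise ValueError("AIF amplitudes must be non-negative")
        if self.m1 <= 0 or self.m2 <= 0:
            raise ValueError("AIF decay rates must be strictly positive")
        if self.dose <= 0:
            raise ValueError("dose must be strictly positive")
        return self

    def plasma_concentration(self, times_s: np.ndarray) -> np.ndarray:
        """Evaluate C_p (mM) at times given in seconds."""
        t = np.asarray(times_s, dtype=float)
        tmin = (t - self.onset_time) / 60.0
        cp = self.dose * (
            self.a1 * np.exp(-self.m1 * np.maximum(tmin, 0.0))
            + self.a2 * np.exp(-self.m2 * np.maximum(tmin, 0.0))
        )
        return np.where(tmin >= 0.0, cp, 0.0)


def spgr_signal(
    m0: np.ndarray | float,
    t1_ms: np.ndarray | float,
    tr_ms: float,
    flip_deg: np.ndarray | float,
) -> np.ndarray:
    """Steady-state SPGR signal: S = M0 sin(a) (1 - E1) / (1 - E1 cos(a)).

    E1 = exp(-TR/T1). Inputs broadcast; angles in degrees.
    """
    a = np.deg2rad(flip_deg)
    e1 = np.exp(-tr_ms / np.asarray(t1_ms, dtype=float))
    return m0 * np.sin(a) * (1.0 - e1) / (1.0 - e1 * np.cos(a))


def spgr_invert_e1(
    signal: np.ndarray,
    m0_sin_a: np.ndarray,
    flip_deg: np.ndarray | float,
) -> np.ndarray:
    """Solve the SPGR equation for E1 given the signal and M0*sin(a).

    Rearranging S(1 - E1 cos a) = M0 sin(a) (1 - E1):
    E1 = (M0 sin a - S) / (M0 sin a - S cos a).
    Out-of-domain results (E1 outside (0, 1)) are returned as-is; callers
    decide validity.
    """
    cos_a = np.cos(np.deg2rad(flip_deg))
    num = m0_sin_a - signal
    den = m0_sin_a - signal * cos_a
    with np.errstate(divide="ignore", invalid="ignore"):
        return num / den
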