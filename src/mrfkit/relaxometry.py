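"""Gold-standard relaxometry fits: inversion-recovery T1 and single-echo
spin-echo T2.

These reproduce the NMR-style reference protocol: T1 from a 3-parameter
inversion-recovery model ``S(TI) = a + b*exp(-TI/T1)`` sampled at 20
logarithmically spaced inversion times, and T2 from a mono-exponential
``S(TE) = A*exp(-TE/T2)`` sampled at 51 echo times logarithmically spaced
from 2.026 to 2502 ms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "IRSample",
    "SESample",
    "FitResult",
    "log_spaced",
    "fit_ir_t1",
    "fit_se_t2",
    "DEFAULT_SE_TE_MS",
    "DEFAULT_IR_TI_RANGE_MS",
]

#: Published spin-echo sampling: 51 log-spaced echo times (ms).
DEFAULT_SE_TE_MS = (2.026, 2502.0, 51)
#: IR inversion-time range is not published; default spans the slowest
#: reference T1 (2872 ms) comfortably.
DEFAULT_IR_TI_RANGE_MS = (50.0, 15000.0)


def log_spaced(lo: float, hi: float, n: int) -> np.ndarray:
    """``n`` geometrically spaced values with exact endpoints ``lo``/``hi``."""
    if not (0 < lo < hi):
        raise ValueError("need 0 < lo < hi")
    if n < 2:
        raise ValueError("need n >= 2")
    vals = np.geomspace(lo, hi, n)
    vals[0] = lo
    vals[-1] = hi
    return vals


@dataclass(frozen=True)
class IRSample:
    """Inversion-recovery measurement: signed signal vs inversion time."""

    ti_ms: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        ti = np.asarray(self.ti_ms, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "ti_ms", ti)
        object.__setattr__(self, "signal", s)
        if ti.ndim != 1 or ti.shape != s.shape:
            raise ValueError("ti_ms and signal must be 1-D and the same length")
        if np.any(ti <= 0) or np.any(np.diff(ti) <= 0):
            raise ValueError("TIs must be positive and strictly increasing")

    @classmethod
    def default_times(cls, n: int = 20) -> np.ndarray:
        return log_spaced(*DEFAULT_IR_TI_RANGE_MS, n)


@dataclass(frozen=True)
class SESample:
    """Single-echo spin-echo measurement: echo amplitude vs echo time."""

    te_ms: np.ndarray
    signal: np.ndarray

    def __post_init__(self) -> None:
        te = np.asarray(self.te_ms, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "te_ms", te)
        object.__setattr__(self, "signal", s)
        if te.ndim != 1 or te.shape != s.shape:
            raise ValueError("te_ms and signal must be 1-D and the same length")
        if np.any(te <= 0) or np.any(np.diff(te) <= 0):
            raise ValueError("TEs must be positive and strictly increasing")

    @classmethod
    def default_times(cls) -> np.ndarray:
        return log_spaced(*DEFAULT_SE_TE_MS)


@dataclass(frozen=True)
class FitResult:
    estimate_ms: float
    amplitudes: tuple
    residual_norm: float
    converged: bool
    model: str

    def to_dict(self) -> dict:
        return {
            "estimate_ms": self.estimate_ms,
            "amplitudes": list(self.amplitudes),
            "residual_norm": self.residual_norm,
            "converged": self.converged,
            "model": self.model,
        }


def _failed(model: str) -> FitResult:
    return FitResult(float("nan"), (), float("nan"), False, model)


def fit_ir_t1(sample: IRSample, magnitude_mode: bool = False) -> FitResult:
    """Fit ``S(TI) = a + b*exp(-TI/T1)`` by nonlinear least squares.

    With ``magnitude_mode`` the model magnitude ``|a + b*exp(-TI/T1)|`` is
    fitted instead (for magnitude-reconstructed data).  Requires at least
    4 points spanning at least one decade of TI.
    """
    ti = sample.ti_ms
    s = sample.signal
    model = "ir3_magnitude" if magnitude_mode else "ir3"
    if ti.size < 4:
        raise ValueError("need at least 4 inversion times")
    if ti[-1] / ti[0] < 10.0:
        raise ValueError("TIs must span at least one decade")
    if np.ptp(s) == 0:
        return _failed(model)

    # Initialization: a from the long-TI plateau.  Signed mode gets b from
    # the earliest point and T1 from a log-linearized fit of |S - a0|;
    # magnitude mode uses the null point (|S| minimum), where TI = T1*ln2
    # for a standard inversion recovery.
    a0 = s[-1]
    if magnitude_mode:
        b0 = -2.0 * a0
        t1_0 = ti[int(np.argmin(np.abs(s)))] / np.log(2.0)
    else:
        b0 = s[0] - a0
        resid0 = s - a0
        usable = np.abs(resid0) > 1e-12 * max(np.abs(s).max(), 1.0)
        if usable.sum() >= 2:
            slope = np.polyfit(ti[usable], np.log(np.abs(resid0[usable])), 1)[0]
            t1_0 = -1.0 / slope if slope < 0 else ti[-1] / 3.0
        else:
            t1_0 = ti[-1] / 3.0
    t1_0 = min(max(t1_0, ti[0] / 10.0), ti[-1] * 10.0)

    def residuals(p):
        a, b, t1 = p
        pred = a + b * np.exp(-ti / t1)
        if magnitude_mode:
            pred = np.abs(pred)
        return pred - s

    try:
        res = least_squares(
            residuals,
            x0=[a0, b0, t1_0],
            bounds=([-np.inf, -np.inf, 1e-6], [np.inf, np.inf, np.inf]),
            method="trf",
            xtol=1e-14,
            ftol=1e-14,
            gtol=1e-14,
        )
    except Exception:
        return _failed(model)
    a, b, t1 = res.x
    converged = bool(res.success) and t1 > 0 and abs(b) > 0
    # reject degenerate optimum where the exponential term carries nothing
    if abs(b) < 1e-9 * max(abs(a), 1.0):
        converged = False
    if not converged:
        return _failed(model)
    return FitResult(float(t1), (float(a), float(b)), float(np.linalg.norm(res.fun)), True, model)


def fit_se_t2(sample: SESample, fit_offset: bool = False) -> FitResult:
    """Fit ``S(TE) = A*exp(-TE/T2)`` (optionally plus a constant offset).

    Initialized from log-linear regression of ``log(S)`` against TE.
    Requires at least 3 points with positive amplitudes.
    """
    te = sample.te_ms
    s = sample.signal
    model = "se2_offset" if fit_offset else "se2"
    if te.size < 3:
        raise ValueError("need at least 3 echo times")
    if np.any(s <= 0):
        raise ValueError("spin-echo amplitudes must be positive")
    if np.ptp(s) == 0:
        return _failed(model)

    slope, intercept = np.polyfit(te, np.log(s), 1)
    t2_0 = -1.0 / slope if slope < 0 else te[-1]
    t2_0 = min(max(t2_0, te[0] / 10.0), te[-1] * 10.0)
    a_0 = float(np.exp(intercept))

    if fit_offset:
        x0 = [a_0, t2_0, 0.0]

        def residuals(p):
            return p[0] * np.exp(-te / p[1]) + p[2] - s

        lb = [0.0, 1e-6, -np.inf]
        ub = [np.inf, np.inf, np.inf]
    else:
        x0 = [a_0, t2_0]

        def residuals(p):
            return p[0] * np.exp(-te / p[1]) - s

        lb = [0.0, 1e-6]
        ub = [np.inf, np.inf]

    try:
        res = least_squares(
            residuals, x0=x0, bounds=(lb, ub), method="trf",
            xtol=1e-14, ftol=1e-14, gtol=1e-14,
        )
    except Exception:
        return _failed(model)
    t2 = res.x[1]
    converged = bool(res.success) and t2 > 0 and res.x[0] > 0
    if not converged:
        return _failed(model)
    amps = (float(res.x[0]), float(res.x[2])) if fit_offset else (float(res.x[0]),)
    return FitResult(float(t2), amps, float(np.linalg.norm(res.fun)), True, model)
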