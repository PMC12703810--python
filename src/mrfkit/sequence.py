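"""Acquisition schedules and signal simulation for the inversion-prepared
variable-flip-angle FISP echo train.

Two simulators are provided:

``simulate_signal`` / ``simulate_signals``
    Extended-phase-graph (EPG) recursion for an unbalanced (gradient
    spoiled) sequence.  This is the production engine used to generate
    dictionary atoms.

``isochromat_signal``
    Brute-force Bloch simulation summing isochromats uniformly dephased
    across 2*pi per TR.  Slow, but algorithmically independent of the EPG
    recursion; it exists to validate the EPG engine.

Conventions
-----------
Transverse magnetization is the complex quantity ``m = Mx + 1j*My``.  An RF
pulse of flip angle ``a`` and phase ``p`` (degrees) maps equilibrium ``Mz=1``
to ``-1j*exp(1j*p)*sin(a)`` in the transverse plane; with the default phase
0 this is a right-handed rotation about the x axis.  The EPG configuration
states are stored as ``Fp[k] = F(+k)``, ``Fm[k] = conj(F(-k))``, ``Z[k]``;
the echo is the ``F(0)`` state read at TE after each pulse.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SequenceParams",
    "TissueParams",
    "default_schedule",
    "simulate_signal",
    "simulate_signals",
    "isochromat_signal",
    "load_schedule_csv",
    "save_schedule_csv",
]

TR_MIN_MS = 12.1
TR_MAX_MS = 15.0
FA_MAX_DEG = 74.0

#: Seed of the pseudo-random smooth TR series in :func:`default_schedule`.
#: Fixed so the default schedule is a reproducible, documented stand-in.
DEFAULT_TR_SEED = 20230921


@dataclass(frozen=True)
class SequenceParams:
    """Full acquisition schedule of the fingerprinting echo train."""

    tr_ms: np.ndarray
    fa_deg: np.ndarray
    ti_ms: float = 21.0
    te_ms: float = 2.0
    rf_phase_deg: float = 0.0

    def __post_init__(self) -> None:
        tr = np.asarray(self.tr_ms, dtype=float)
        fa = np.asarray(self.fa_deg, dtype=float)
        object.__setattr__(self, "tr_ms", tr)
        object.__setattr__(self, "fa_deg", fa)
        if tr.ndim != 1 or fa.ndim != 1:
            raise ValueError("tr_ms and fa_deg must be 1-D series")
        if tr.shape != fa.shape:
            raise ValueError(
                f"tr_ms ({tr.size}) and fa_deg ({fa.size}) lengths differ"
            )
        if tr.size < 1:
            raise ValueError("schedule must contain at least one time point")
        if np.any(tr < TR_MIN_MS - 1e-9) or np.any(tr > TR_MAX_MS + 1e-9):
            raise ValueError(f"all TRs must lie in [{TR_MIN_MS}, {TR_MAX_MS}] ms")
        if np.any(fa < 0.0) or np.any(fa > FA_MAX_DEG + 1e-9):
            raise ValueError(f"all flip angles must lie in [0, {FA_MAX_DEG}] deg")
        if not self.te_ms < tr.min():
            raise ValueError("te_ms must be smaller than the shortest TR")
        if self.ti_ms < 0:
            raise ValueError("ti_ms must be non-negative")

    @property
    def n_timepoints(self) -> int:
        return int(self.tr_ms.size)

    def content_hash(self) -> str:
        """Stable hex digest of the schedule (provenance for saved dictionaries)."""
        import hashlib

        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.tr_ms).tobytes())
        h.update(np.ascontiguousarray(self.fa_deg).tobytes())
        h.update(
            f"{self.ti_ms}:{self.te_ms}:{self.rf_phase_deg}".encode()
        )
        return h.hexdigest()


@dataclass(frozen=True)
class TissueParams:
    """Relaxation parameters of a single tissue/material."""

    t1_ms: float
    t2_ms: float
    b1_rel: float = 1.0
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not self.t1_ms > 0:
            raise ValueError(f"t1_ms must be positive, got {self.t1_ms}")
        if not self.t2_ms > 0:
            raise ValueError(f"t2_ms must be positive, got {self.t2_ms}")
        if self.b1_rel < 0:
            raise ValueError(f"b1_rel must be non-negative, got {self.b1_rel}")
        if self.m0 < 0:
            raise ValueError(f"m0 must be non-negative, got {self.m0}")


def default_schedule(
    n_timepoints: int = 1500,
    *,
    ti_ms: float = 21.0,
    te_ms: float = 2.0,
    lobe_len: int = 250,
) -> SequenceParams:
    """Deterministic stand-in flip-angle/TR schedule.

    The vendor's exact temporal pattern is not public; this stand-in keeps
    its published envelope: flip angles form repeated half-sinusoid lobes
    with peaks <= 74 deg and a zero between lobes, and TRs are a smooth
    pseudo-random series in [12.1, 15.0] ms drawn from the fixed seed
    ``DEFAULT_TR_SEED``.  Arbitrary measured schedules can be loaded with
    :func:`load_schedule_csv` instead.
    """
    if n_timepoints < 1:
        raise ValueError("n_timepoints must be >= 1")

    # Flip angles: half-sinusoid lobes with varying peaks, zeros at lobe
    # boundaries so the train periodically lets magnetization recover.
    peaks = np.array([74.0, 42.0, 60.0, 35.0, 68.0, 50.0])
    idx = np.arange(n_timepoints)
    lobe = idx // lobe_len
    pos = idx % lobe_len
    peak = peaks[lobe % peaks.size]
    fa = peak * np.sin(np.pi * pos / (lobe_len - 1))
    fa = np.clip(fa, 0.0, FA_MAX_DEG)

    # TRs: Gaussian-smoothed white noise rescaled exactly onto the
    # published TR range.
    rng = np.random.default_rng(DEFAULT_TR_SEED)
    w = 25
    raw = rng.standard_normal(n_timepoints + 2 * w)
    kernel = np.exp(-0.5 * (np.arange(-w, w + 1) / (w / 2.5)) ** 2)
    kernel /= kernel.sum()
    smooth = np.convolve(raw, kernel, mode="valid")[:n_timepoints]
    lo, hi = smooth.min(), smooth.max()
    if hi - lo < 1e-12:
        tr = np.full(n_timepoints, 0.5 * (TR_MIN_MS + TR_MAX_MS))
    else:
        tr = TR_MIN_MS + (smooth - lo) * (TR_MAX_MS - TR_MIN_MS) / (hi - lo)

    return SequenceParams(tr_ms=tr, fa_deg=fa, ti_ms=ti_ms, te_ms=te_ms)


def _relax(Fp, Fm, Z, e1, e2):
    Fp *= e2
    Fm *= e2
    Z *= e1
    Z[0] += 1.0 - e1


def simulate_signals(
    params: SequenceParams,
    t1_ms: np.ndarray,
    t2_ms: np.ndarray,
    b1_rel: np.ndarray | float = 1.0,
    m0: np.ndarray | float = 1.0,
    n_epg_states: int = 30,
    inversion_efficiency: float = 1.0,
) -> np.ndarray:
    """EPG simulation of the echo train for a batch of tissues.

    Parameters are broadcast against each other; the result has shape
    ``(n_tissues, n_timepoints)`` (complex).  Each repetition applies an RF
    rotation of ``b1_rel * fa_deg[i]`` about the constant-phase axis,
    relaxes to TE where the F(0) state is read out, relaxes over the
    remaining TR - TE, and applies one unit of gradient dephasing.
    """
    t1 = np.atleast_1d(np.asarray(t1_ms, dtype=float))
    t2 = np.atleast_1d(np.asarray(t2_ms, dtype=float))
    b1 = np.atleast_1d(np.asarray(b1_rel, dtype=float))
    m0a = np.atleast_1d(np.asarray(m0, dtype=float))
    t1, t2, b1, m0a = np.broadcast_arrays(t1, t2, b1, m0a)
    t1 = t1.ravel()
    t2 = t2.ravel()
    b1 = b1.ravel()
    m0a = m0a.ravel()
    if np.any(t1 <= 0) or np.any(t2 <= 0):
        raise ValueError("T1 and T2 must be positive")
    if n_epg_states < 2:
        raise ValueError("n_epg_states must be >= 2")

    n = t1.size
    nt = params.n_timepoints
    K = int(n_epg_states)

    te = params.te_ms
    ti = params.ti_ms
    e1_te = np.exp(-te / t1)
    e2_te = np.exp(-te / t2)
    e1_rem = np.exp(-(params.tr_ms[:, None] - te) / t1[None, :])
    e2_rem = np.exp(-(params.tr_ms[:, None] - te) / t2[None, :])

    phi = np.deg2rad(params.rf_phase_deg)
    eip = np.exp(1j * phi)
    e2ip = np.exp(2j * phi)
    alpha = np.deg2rad(params.fa_deg[:, None] * b1[None, :])  # (nt, n)
    ca2 = np.cos(alpha / 2.0) ** 2
    sa2 = np.sin(alpha / 2.0) ** 2
    sa = np.sin(alpha)
    ca = np.cos(alpha)

    Fp = np.zeros((K, n), dtype=complex)
    Fm = np.zeros((K, n), dtype=complex)
    Z = np.zeros((K, n), dtype=complex)
    Z[0] = 1.0

    # Adiabatic non-selective inversion, then TI recovery.
    Z[0] *= -inversion_efficiency
    _relax(Fp, Fm, Z, np.exp(-ti / t1), np.exp(-ti / t2))

    out = np.empty((n, nt), dtype=complex)
    for i in range(nt):
        # RF rotation (mixing of Fp/Fm/Z orders).
        c1, c2, c3, c4 = ca2[i], sa2[i], sa[i], ca[i]
        Fp_new = c1 * Fp + (e2ip * c2) * Fm + (-1j * eip) * c3 * Z
        Fm_new = (np.conj(e2ip) * c2) * Fp + c1 * Fm + (1j * np.conj(eip)) * c3 * Z
        Z_new = (-0.5j * np.conj(eip)) * c3 * Fp + (0.5j * eip) * c3 * Fm + c4 * Z
        Fp, Fm, Z = Fp_new, Fm_new, Z_new

        # Relax to the echo; read F(0).
        _relax(Fp, Fm, Z, e1_te, e2_te)
        out[:, i] = Fp[0]

        # Remaining TR, then one unit of gradient dephasing.
        _relax(Fp, Fm, Z, e1_rem[i], e2_rem[i])
        Fp[1:] = Fp[:-1]
        Fm[:-1] = Fm[1:]
        Fm[-1] = 0.0
        Fp[0] = np.conj(Fm[0])

    out *= m0a[:, None]
    return out


def simulate_signal(
    params: SequenceParams,
    tissue: TissueParams,
    n_epg_states: int = 30,
    inversion_efficiency: float = 1.0,
) -> np.ndarray:
    """Complex signal time course (length ``n_timepoints``) for one tissue."""
    return simulate_signals(
        params,
        tissue.t1_ms,
        tissue.t2_ms,
        tissue.b1_rel,
        tissue.m0,
        n_epg_states=n_epg_states,
        inversion_efficiency=inversion_efficiency,
    )[0]


def isochromat_signal(
    params: SequenceParams,
    tissue: TissueParams,
    n_spins: int = 1000,
    inversion_efficiency: float = 1.0,
) -> np.ndarray:
    """Brute-force Bloch simulation with ``n_spins`` uniformly dephased
    isochromats per TR.

    Independent reference for :func:`simulate_signal`; identical pulse and
    relaxation events, but transverse dephasing is modelled by explicit
    spins spread uniformly across 2*pi instead of configuration states.
    """
    if n_spins < 1:
        raise ValueError("n_spins must be >= 1")
    t1, t2 = tissue.t1_ms, tissue.t2_ms
    te, ti = params.te_ms, params.ti_ms
    theta = 2.0 * np.pi * (np.arange(n_spins) + 0.5) / n_spins
    dephase = np.exp(1j * theta)

    phi = np.deg2rad(params.rf_phase_deg)
    alpha = np.deg2rad(params.fa_deg * tissue.b1_rel)

    m = np.zeros(n_spins, dtype=complex)  # Mx + i My
    mz = np.full(n_spins, -inversion_efficiency)  # after ideal inversion

    e1_ti = np.exp(-ti / t1)
    mz = mz * e1_ti + (1.0 - e1_ti)

    e1_te = np.exp(-te / t1)
    e2_te = np.exp(-te / t2)

    out = np.empty(params.n_timepoints, dtype=complex)
    for i in range(params.n_timepoints):
        a = alpha[i]
        # Rotation about the axis at angle phi from x: m/mz update written
        # in complex form (equivalent to Rz(phi) Rx(a) Rz(-phi)).
        ca2 = np.cos(a / 2.0) ** 2
        sa2 = np.sin(a / 2.0) ** 2
        sa = np.sin(a)
        e2ip = np.exp(2j * phi)
        eip = np.exp(1j * phi)
        m_new = ca2 * m + e2ip * sa2 * np.conj(m) - 1j * eip * sa * mz
        mz_new = np.real(1j * 0.5 * (eip * np.conj(m) - np.conj(eip) * m)) * sa + np.cos(a) * mz
        m, mz = m_new, mz_new

        m = m * e2_te
        mz = mz * e1_te + (1.0 - e1_te)
        out[i] = tissue.m0 * m.mean()

        rem = params.tr_ms[i] - te
        e1 = np.exp(-rem / t1)
        e2 = np.exp(-rem / t2)
        m = m * e2
        mz = mz * e1 + (1.0 - e1)
        m = m * dephase

    return out


def save_schedule_csv(params: SequenceParams, path: str | Path) -> None:
    """Write the schedule as CSV with columns ``index,tr_ms,fa_deg``."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["index", "tr_ms", "fa_deg"])
        for i, (tr, fa) in enumerate(zip(params.tr_ms, params.fa_deg)):
            writer.writerow([i, repr(float(tr)), repr(float(fa))])


def load_schedule_csv(
    path: str | Path,
    ti_ms: float = 21.0,
    te_ms: float = 2.0,
    rf_phase_deg: float = 0.0,
) -> SequenceParams:
    """Read an ``index,tr_ms,fa_deg`` CSV into a :class:`SequenceParams`."""
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or not {"tr_ms", "fa_deg"} <= set(
            reader.fieldnames
        ):
            raise ValueError(
                f"{path}: schedule CSV must have header with tr_ms and fa_deg"
            )
        rows = [(float(r["tr_ms"]), float(r["fa_deg"])) for r in reader]
    if not rows:
        raise ValueError(f"{path}: empty schedule")
    tr, fa = (np.array(col) for col in zip(*rows))
    return SequenceParams(
        tr_ms=tr, fa_deg=fa, ti_ms=ti_ms, te_ms=te_ms, rf_phase_deg=rf_phase_deg
    )
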