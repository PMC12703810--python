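"""Per-pixel B1-informed inner-product dictionary matching.

The measured per-pixel B1 is snapped to the nearest B1 value present in the
dictionary (ties break to the lower value); the match is then an exhaustive
search over all (T1, T2) atoms at that B1 for the largest inner-product
magnitude ``|<atom, signal>|`` with the L2-normalized signal.  Because
atoms are unit norm, the complex scale ``m0 = <atom, signal>`` against the
unnormalized signal.  Compressed dictionaries score in the SVD subspace.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from mrfkit.dictionary import CompressedDictionary, Dictionary

__all__ = [
    "MatchResult",
    "ParameterMap",
    "NoMatchError",
    "match_pixel",
    "match_image",
    "apply_t1_mask",
    "snap_b1",
]

logger = logging.getLogger(__name__)

B1_CLAMP = (0.6, 1.4)


class NoMatchError(ValueError):
    """Raised when a signal cannot be matched (e.g. zero norm)."""


@dataclass(frozen=True)
class MatchResult:
    t1_ms: float
    t2_ms: float
    b1_used: float
    m0: complex
    score: float


@dataclass
class ParameterMap:
    """Voxelwise quantitative maps with a reporting mask.

    All volumes share shape ``(nx, ny, n_slices)``.  ``mask`` is True where
    a voxel is reported; masked-out voxels keep their raw values in memory
    and are written as NaN on disk.
    """

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    m0_magnitude: np.ndarray
    score: np.ndarray
    mask: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 5.0)

    def __post_init__(self) -> None:
        shape = self.t1_ms.shape
        for name in ("t2_ms", "m0_magnitude", "score", "mask"):
            vol = getattr(self, name)
            if vol.shape != shape:
                raise ValueError(f"{name} shape {vol.shape} != t1 shape {shape}")
        if self.t1_ms.ndim != 3:
            raise ValueError("parameter map volumes must be 3-D (x, y, slices)")

    @property
    def shape(self) -> tuple:
        return self.t1_ms.shape

    @property
    def n_slices(self) -> int:
        return int(self.t1_ms.shape[2])

    def copy(self) -> "ParameterMap":
        return ParameterMap(
            t1_ms=self.t1_ms.copy(),
            t2_ms=self.t2_ms.copy(),
            m0_magnitude=self.m0_magnitude.copy(),
            score=self.score.copy(),
            mask=self.mask.copy(),
            voxel_size_mm=self.voxel_size_mm,
        )

    def masked(self, volume: np.ndarray) -> np.ndarray:
        """Copy of ``volume`` with NaN at masked-out voxels."""
        out = np.array(volume, dtype=float)
        out[~self.mask] = np.nan
        return out


def snap_b1(b1_measured: float, b1_grid: np.ndarray) -> float:
    """Nearest dictionary B1 value; exact midpoints snap to the lower value."""
    b1 = float(b1_measured)
    if b1 < B1_CLAMP[0] or b1 > B1_CLAMP[1]:
        clamped = min(max(b1, B1_CLAMP[0]), B1_CLAMP[1])
        logger.warning("b1_measured %.4f outside %s; clamped to %.4f", b1, B1_CLAMP, clamped)
        b1 = clamped
    dist = np.abs(b1_grid - b1)
    # argmin returns the first (lowest) index on ties -> lower B1 wins
    return float(b1_grid[int(np.argmin(dist))])


def _atoms_at_b1(dictionary, b1_value):
    """Row indices of entries at the given B1 value."""
    idx = np.flatnonzero(np.isclose(dictionary.entries[:, 2], b1_value))
    if idx.size == 0:
        raise NoMatchError(f"dictionary has no entries at B1={b1_value}")
    return idx


def _match_batch(signals: np.ndarray, dictionary, idx: np.ndarray, chunk: int = 8192):
    """Match rows of ``signals`` against dictionary rows ``idx``.

    Returns (entry_rows, m0, score) arrays.  Signals must be nonzero.
    Processes in chunks to bound the memory of the score matrix.
    """
    n = signals.shape[0]
    rows = np.empty(n, dtype=np.intp)
    m0 = np.empty(n, dtype=complex)
    score = np.empty(n, dtype=float)
    compressed = isinstance(dictionary, CompressedDictionary)
    ref = dictionary.coords[idx] if compressed else dictionary.atoms[idx]
    ref_h = ref.conj().T
    for start in range(0, n, chunk):
        block = np.asarray(signals[start : start + chunk], dtype=complex)
        norms = np.linalg.norm(block, axis=1)
        unit = block / norms[:, None]
        if compressed:
            scores = (unit @ dictionary.basis) @ ref_h
        else:
            scores = unit @ ref_h
        best = np.argmax(np.abs(scores), axis=1)
        take = np.arange(scores.shape[0])
        rows[start : start + chunk] = idx[best]
        m0[start : start + chunk] = scores[take, best] * norms
        score[start : start + chunk] = np.abs(scores[take, best])
    return rows, m0, np.minimum(score, 1.0 + 1e-12)


def match_pixel(
    signal: np.ndarray,
    b1_measured: float,
    dictionary: Dictionary | CompressedDictionary,
) -> MatchResult:
    """Match one signal time course against the dictionary at the snapped B1."""
    signal = np.asarray(signal)
    if signal.ndim != 1:
        raise ValueError("signal must be a 1-D series")
    if np.linalg.norm(signal) == 0:
        raise NoMatchError("zero-norm signal cannot be matched")
    if dictionary.n_entries == 0:
        raise NoMatchError("empty dictionary")
    b1_used = snap_b1(b1_measured, dictionary.b1_grid)
    idx = _atoms_at_b1(dictionary, b1_used)
    rows, m0, score = _match_batch(signal[None, :], dictionary, idx)
    t1, t2, _ = dictionary.entries[rows[0]]
    return MatchResult(
        t1_ms=float(t1),
        t2_ms=float(t2),
        b1_used=b1_used,
        m0=complex(m0[0]),
        score=float(score[0]),
    )


def match_image(
    series: np.ndarray,
    b1_map: np.ndarray,
    dictionary: Dictionary | CompressedDictionary,
    voxel_size_mm: tuple = (1.0, 1.0, 5.0),
) -> ParameterMap:
    """Vectorized per-voxel matching of a 4-D series (x, y, slices, time).

    Voxels are grouped by snapped B1 value and matched in batched matrix
    products.  Zero-norm voxels are masked rather than raising.
    """
    series = np.asarray(series)
    b1_map = np.asarray(b1_map, dtype=float)
    if series.ndim != 4:
        raise ValueError("series must be 4-D (x, y, slices, time)")
    if series.shape[:3] != b1_map.shape:
        raise ValueError(
            f"series spatial shape {series.shape[:3]} != b1 map shape {b1_map.shape}"
        )
    nx, ny, nz, nt = series.shape
    flat = series.reshape(-1, nt)
    nvox = flat.shape[0]

    t1 = np.zeros(nvox)
    t2 = np.zeros(nvox)
    m0 = np.zeros(nvox)
    score = np.zeros(nvox)
    mask = np.zeros(nvox, dtype=bool)

    norms = np.linalg.norm(flat, axis=1)
    valid = norms > 0

    b1_grid = dictionary.b1_grid
    b1_flat = np.clip(b1_map.reshape(-1), *B1_CLAMP)
    # midpoints snap to the lower value: searchsorted on midpoints with
    # side='left' assigns a value equal to a midpoint to the lower cell
    if b1_grid.size > 1:
        mids = 0.5 * (b1_grid[:-1] + b1_grid[1:])
        snap_idx = np.searchsorted(mids, b1_flat, side="left")
    else:
        snap_idx = np.zeros(nvox, dtype=int)

    for gi in np.unique(snap_idx[valid]):
        sel = np.flatnonzero(valid & (snap_idx == gi))
        b1_val = float(b1_grid[gi])
        idx = _atoms_at_b1(dictionary, b1_val)
        logger.info("matching %d voxels at B1=%.2f", sel.size, b1_val)
        rows, m0_c, sc = _match_batch(flat[sel], dictionary, idx)
        t1[sel] = dictionary.entries[rows, 0]
        t2[sel] = dictionary.entries[rows, 1]
        m0[sel] = np.abs(m0_c)
        score[sel] = sc
        mask[sel] = True

    shape = (nx, ny, nz)
    return ParameterMap(
        t1_ms=t1.reshape(shape),
        t2_ms=t2.reshape(shape),
        m0_magnitude=m0.reshape(shape),
        score=score.reshape(shape),
        mask=mask.reshape(shape),
        voxel_size_mm=voxel_size_mm,
    )


def apply_t1_mask(pmap: ParameterMap, threshold_ms: float = 400.0) -> ParameterMap:
    """Mask out voxels with T1 below ``threshold_ms``; returns a new map."""
    if threshold_ms < 0:
        raise ValueError("threshold must be non-negative")
    out = pmap.copy()
    out.mask &= ~(out.t1_ms < threshold_ms)
    return out
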