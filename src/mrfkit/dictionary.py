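"""(T1, T2, B1) dictionary generation and SVD temporal compression.

The dictionary holds one unit-L2-norm simulated signal evolution ("atom")
per parameter combination.  The default grid uses increasing step sizes as
T1 or T2 increase:

- T1: 10 ms steps over 10-100 ms, 20 ms over 100-1000, 40 ms over
  1000-2000, 100 ms over 2000-4500;
- T2: 2 ms steps over 2-100 ms, 5 ms over 100-150, 10 ms over 150-300,
  50 ms over 300-800, 100 ms over 800-1600, 200 ms over 1600-3000;
- relative B1 from 0.6 to 1.4 in steps of 0.01.

Boundary values shared by adjacent segments appear exactly once.  Entries
are ordered (B1, T1, T2) lexicographically, which fixes the documented
tie-break of the matcher (lowest T1, then lowest T2).

Compression projects atoms onto the top right singular vectors of the atom
matrix.  With atoms as rows ``A`` and ``A = U S V^H``, the stored basis is
``V[:, :rank]``; signals project as ``x @ basis`` and compressed-space
inner products are ``conj(coords) . project(x)``, matching the full-space
convention ``<a, x> = sum(conj(a) * x)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

from mrfkit.sequence import (
    SequenceParams,
    load_schedule_csv,
    simulate_signals,
)

__all__ = [
    "GridSpec",
    "Dictionary",
    "CompressedDictionary",
    "build_axis",
    "build_dictionary",
    "compress",
    "save_dictionary",
    "load_dictionary",
    "DEFAULT_T1_SEGMENTS",
    "DEFAULT_T2_SEGMENTS",
    "default_b1_values",
]

FORMAT_VERSION = 1

DEFAULT_T1_SEGMENTS = (
    (10.0, 100.0, 10.0),
    (100.0, 1000.0, 20.0),
    (1000.0, 2000.0, 40.0),
    (2000.0, 4500.0, 100.0),
)
DEFAULT_T2_SEGMENTS = (
    (2.0, 100.0, 2.0),
    (100.0, 150.0, 5.0),
    (150.0, 300.0, 10.0),
    (300.0, 800.0, 50.0),
    (800.0, 1600.0, 100.0),
    (1600.0, 3000.0, 200.0),
)


def default_b1_values() -> np.ndarray:
    """Relative B1 grid 0.6 .. 1.4 in steps of 0.01 (81 values)."""
    return np.round(np.arange(60, 141) * 0.01, 2)


def build_axis(segments) -> np.ndarray:
    """Union of ``{lo, lo+step, ..., hi}`` over segments, strictly increasing.

    Shared segment boundaries are deduplicated.  Segments must be sorted
    with non-overlapping interiors.
    """
    segs = [(float(lo), float(hi), float(step)) for lo, hi, step in segments]
    if not segs:
        raise ValueError("at least one segment is required")
    for lo, hi, step in segs:
        if not lo < hi:
            raise ValueError(f"segment ({lo}, {hi}, {step}): lo must be < hi")
        if not step > 0:
            raise ValueError(f"segment ({lo}, {hi}, {step}): step must be > 0")
    for (lo0, hi0, _), (lo1, hi1, _) in zip(segs, segs[1:]):
        if lo1 < hi0:
            raise ValueError(
                f"segments ({lo0}, {hi0}) and ({lo1}, {hi1}) have overlapping interiors"
            )
    values: list[float] = []
    for lo, hi, step in segs:
        n = int(round((hi - lo) / step))
        pts = lo + step * np.arange(n + 1)
        pts[-1] = hi  # exact endpoint regardless of rounding
        values.append(pts)
    axis = np.concatenate(values)
    axis = np.unique(np.round(axis, 9))
    return axis


@dataclass(frozen=True)
class GridSpec:
    """Parameter grid of the dictionary."""

    t1_segments: tuple = DEFAULT_T1_SEGMENTS
    t2_segments: tuple = DEFAULT_T2_SEGMENTS
    b1_values: np.ndarray = field(default_factory=default_b1_values)
    exclude_t2_gt_t1: bool = False

    def __post_init__(self) -> None:
        b1 = np.asarray(self.b1_values, dtype=float)
        object.__setattr__(self, "b1_values", b1)
        object.__setattr__(self, "t1_segments", tuple(map(tuple, self.t1_segments)))
        object.__setattr__(self, "t2_segments", tuple(map(tuple, self.t2_segments)))
        if b1.ndim != 1 or b1.size == 0:
            raise ValueError("b1_values must be a non-empty 1-D array")
        if np.any(np.diff(b1) <= 0):
            raise ValueError("b1_values must be sorted strictly ascending")
        if b1[0] < 0.6 - 1e-9 or b1[-1] > 1.4 + 1e-9:
            raise ValueError("b1_values must lie within [0.6, 1.4]")
        # validate segments eagerly
        build_axis(self.t1_segments)
        build_axis(self.t2_segments)

    @property
    def t1_axis(self) -> np.ndarray:
        return build_axis(self.t1_segments)

    @property
    def t2_axis(self) -> np.ndarray:
        return build_axis(self.t2_segments)

    def to_dict(self) -> dict:
        return {
            "t1_segments": [list(s) for s in self.t1_segments],
            "t2_segments": [list(s) for s in self.t2_segments],
            "b1_values": self.b1_values.tolist(),
            "exclude_t2_gt_t1": bool(self.exclude_t2_gt_t1),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GridSpec":
        return cls(
            t1_segments=tuple(map(tuple, d["t1_segments"])),
            t2_segments=tuple(map(tuple, d["t2_segments"])),
            b1_values=np.asarray(d["b1_values"], dtype=float),
            exclude_t2_gt_t1=bool(d.get("exclude_t2_gt_t1", False)),
        )


@dataclass
class Dictionary:
    """Simulated dictionary: parameter entries and unit-norm atoms."""

    entries: np.ndarray  # (N, 3) columns t1_ms, t2_ms, b1_rel
    atoms: np.ndarray  # (N, n_timepoints) complex, unit L2 norm rows
    params: SequenceParams
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.entries.shape[0] != self.atoms.shape[0]:
            raise ValueError("entries and atoms row counts differ")

    @property
    def n_entries(self) -> int:
        return int(self.entries.shape[0])

    @property
    def n_timepoints(self) -> int:
        return int(self.atoms.shape[1])

    @property
    def b1_grid(self) -> np.ndarray:
        """Distinct B1 values present, ascending."""
        return np.unique(self.entries[:, 2])


@dataclass
class CompressedDictionary:
    """SVD-compressed view of a :class:`Dictionary`."""

    rank: int
    basis: np.ndarray  # (n_timepoints, rank) orthonormal columns
    coords: np.ndarray  # (N, rank) = atoms @ basis
    parent: Dictionary

    @property
    def entries(self) -> np.ndarray:
        return self.parent.entries

    @property
    def n_entries(self) -> int:
        return self.parent.n_entries

    @property
    def b1_grid(self) -> np.ndarray:
        return self.parent.b1_grid

    def project(self, signal: np.ndarray) -> np.ndarray:
        """Project time-domain signal(s) onto the temporal basis.

        Accepts shape ``(n_timepoints,)`` or ``(m, n_timepoints)``.
        """
        return np.asarray(signal) @ self.basis


def build_dictionary(
    grid: GridSpec,
    params: SequenceParams,
    b1_subset=None,
    n_epg_states: int = 30,
    inversion_efficiency: float = 1.0,
) -> Dictionary:
    """Simulate and L2-normalize one atom per (T1, T2, B1) grid entry.

    ``b1_subset`` restricts the B1 dimension (values must lie within the
    grid's B1 range); with ``exclude_t2_gt_t1`` set on the grid, entries
    with T2 > T1 are dropped.  Atoms with zero norm are rejected with an
    error naming the entry.
    """
    t1_axis = grid.t1_axis
    t2_axis = grid.t2_axis
    if b1_subset is None:
        b1_values = grid.b1_values
    else:
        b1_values = np.asarray(b1_subset, dtype=float)
        if b1_values.ndim != 1 or b1_values.size == 0:
            raise ValueError("b1_subset must be a non-empty 1-D sequence")
        lo, hi = grid.b1_values[0], grid.b1_values[-1]
        if np.any(b1_values < lo - 1e-9) or np.any(b1_values > hi + 1e-9):
            raise ValueError("b1_subset values must lie within the grid B1 range")
        b1_values = np.unique(b1_values)

    t1g, t2g = np.meshgrid(t1_axis, t2_axis, indexing="ij")
    t1f = t1g.ravel()
    t2f = t2g.ravel()
    if grid.exclude_t2_gt_t1:
        keep = t2f <= t1f
        t1f = t1f[keep]
        t2f = t2f[keep]
    n_tt = t1f.size

    entries = np.empty((n_tt * b1_values.size, 3), dtype=float)
    atoms = np.empty((n_tt * b1_values.size, params.n_timepoints), dtype=complex)
    for j, b1 in enumerate(b1_values):
        sl = slice(j * n_tt, (j + 1) * n_tt)
        entries[sl, 0] = t1f
        entries[sl, 1] = t2f
        entries[sl, 2] = b1
        atoms[sl] = simulate_signals(
            params,
            t1f,
            t2f,
            b1,
            1.0,
            n_epg_states=n_epg_states,
            inversion_efficiency=inversion_efficiency,
        )

    norms = np.linalg.norm(atoms, axis=1)
    bad = np.flatnonzero(norms == 0)
    if bad.size:
        t1b, t2b, b1b = entries[bad[0]]
        raise ValueError(
            f"atom with zero norm at entry (t1={t1b}, t2={t2b}, b1={b1b}); "
            "degenerate schedule?"
        )
    atoms /= norms[:, None]
    return Dictionary(entries=entries, atoms=atoms, params=params, grid=grid)


def compress(dictionary: Dictionary, rank: int = 50) -> CompressedDictionary:
    """Compress the dictionary to ``rank`` temporal components via SVD.

    The basis is the top-``rank`` right singular vectors of the atom
    matrix.  For tall matrices (more entries than time points is the
    interesting case's transpose) the singular vectors are obtained from
    the Hermitian eigendecomposition of the Gram matrix ``A^H A``, which
    avoids forming the full SVD of a very tall matrix.
    """
    A = dictionary.atoms
    n, t = A.shape
    max_rank = min(n, t)
    if not 1 <= rank <= max_rank:
        raise ValueError(f"rank must be in [1, {max_rank}], got {rank}")

    if n > t:
        gram = A.conj().T @ A  # (t, t) Hermitian PSD
        w, v = np.linalg.eigh(gram)
        order = np.argsort(w)[::-1][:rank]
        basis = v[:, order]
    else:
        _, _, vh = np.linalg.svd(A, full_matrices=False)
        basis = vh[:rank].conj().T
    coords = A @ basis
    return CompressedDictionary(rank=rank, basis=basis, coords=coords, parent=dictionary)


def save_dictionary(
    dictionary: Dictionary,
    path: str | Path,
    compressed: CompressedDictionary | None = None,
) -> None:
    """Persist the dictionary (and optional compressed form) to HDF5."""
    path = Path(path)
    meta = {
        "version": FORMAT_VERSION,
        "grid": dictionary.grid.to_dict(),
        "schedule_hash": dictionary.params.content_hash(),
        "ti_ms": dictionary.params.ti_ms,
        "te_ms": dictionary.params.te_ms,
        "rf_phase_deg": dictionary.params.rf_phase_deg,
        "rank": None if compressed is None else int(compressed.rank),
    }
    # track_times=False keeps byte-identical output for identical inputs
    with h5py.File(path, "w") as fh:
        opts = dict(track_times=False)
        fh.create_dataset("entries", data=dictionary.entries, **opts)
        fh.create_dataset("atoms", data=dictionary.atoms, **opts)
        fh.create_dataset("tr_ms", data=dictionary.params.tr_ms, **opts)
        fh.create_dataset("fa_deg", data=dictionary.params.fa_deg, **opts)
        if compressed is not None:
            fh.create_dataset("basis", data=compressed.basis, **opts)
            fh.create_dataset("coords", data=compressed.coords, **opts)
        fh.create_dataset("meta", data=json.dumps(meta, sort_keys=True), **opts)


def load_dictionary(path: str | Path):
    """Load a dictionary saved by :func:`save_dictionary`.

    Returns ``(Dictionary, CompressedDictionary | None)``.
    """
    path = Path(path)
    with h5py.File(path, "r") as fh:
        meta = json.loads(fh["meta"][()])
        if meta.get("version") != FORMAT_VERSION:
            raise ValueError(
                f"{path}: unsupported dictionary format version {meta.get('version')}"
            )
        params = SequenceParams(
            tr_ms=fh["tr_ms"][:],
            fa_deg=fh["fa_deg"][:],
            ti_ms=float(meta["ti_ms"]),
            te_ms=float(meta["te_ms"]),
            rf_phase_deg=float(meta["rf_phase_deg"]),
        )
        dictionary = Dictionary(
            entries=fh["entries"][:],
            atoms=fh["atoms"][:],
            params=params,
            grid=GridSpec.from_dict(meta["grid"]),
        )
        comp = None
        if "basis" in fh:
            comp = CompressedDictionary(
                rank=int(meta["rank"]),
                basis=fh["basis"][:],
                coords=fh["coords"][:],
                parent=dictionary,
            )
    return dictionary, comp
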