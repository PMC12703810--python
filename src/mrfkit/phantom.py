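"""Synthetic digital phantoms, brain-like volumes, B1 fields and noisy
test-retest acquisitions.

The vial phantom mimics a PVP relaxometry phantom: 16 mm-diameter vials of
0/10/25/40 % PVP (with repeats), four fat-mimic vials with T1 below the
400 ms reporting threshold, and a fibroglandular (FBG) mimic background
fill.  Geometry is cylindrical: vials run through all slices.  Voxels are
1 x 1 x 5 mm; pixel centers sit at integer millimetre coordinates and a
voxel belongs to a vial when its center falls inside the vial circle (no
partial-volume mixing).

Fat-mimic relaxation values (300/60 ms) are configurable defaults chosen
only to fall below the masking threshold; they are not reference values.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from mrfkit.sequence import SequenceParams, simulate_signals

__all__ = [
    "Material",
    "MaterialTable",
    "Vial",
    "PhantomSpec",
    "BrainRegion",
    "BrainSpec",
    "AcquisitionNoise",
    "TruthVolumes",
    "DEFAULT_MATERIALS",
    "default_phantom_spec",
    "default_brain_spec",
    "generate_phantom_truth",
    "generate_brain_truth",
    "generate_b1_field",
    "phantom_roi_specs",
    "simulate_acquisition",
    "generate_test_retest_pair",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Material:
    t1_ms: float
    t2_ms: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if not (self.t1_ms > 0 and self.t2_ms > 0):
            raise ValueError("material T1 and T2 must be positive")
        if self.m0 < 0:
            raise ValueError("material m0 must be non-negative")


#: NMR reference relaxation values of the phantom materials (20 C), plus a
#: fat mimic whose values are merely "below the 400 ms threshold".
DEFAULT_MATERIALS: dict[str, Material] = {
    "0% PVP": Material(2872.0, 1217.0),
    "10% PVP": Material(2151.0, 1245.0),
    "25% PVP": Material(1304.0, 962.0),
    "40% PVP": Material(656.0, 472.0),
    "FBG": Material(1321.0, 41.0),
    "fat": Material(300.0, 60.0),
}

MaterialTable = dict  # name -> Material


@dataclass(frozen=True)
class Vial:
    center_xy_mm: tuple
    material: str
    diameter_mm: float = 16.0


@dataclass(frozen=True)
class PhantomSpec:
    vials: tuple
    background_material: str = "FBG"
    shape: tuple = (112, 112, 7)
    voxel_size_mm: tuple = (1.0, 1.0, 5.0)
    materials: dict = field(default_factory=lambda: dict(DEFAULT_MATERIALS))

    def __post_init__(self) -> None:
        object.__setattr__(self, "vials", tuple(self.vials))
        if self.background_material not in self.materials:
            raise ValueError(f"unknown background material {self.background_material!r}")
        for v in self.vials:
            if v.material not in self.materials:
                raise ValueError(f"unknown vial material {v.material!r}")
            r = v.diameter_mm / 2.0
            x, y = v.center_xy_mm
            if not (r <= x <= self.shape[0] - 1 - r and r <= y <= self.shape[1] - 1 - r):
                raise ValueError(f"vial at {v.center_xy_mm} extends outside the field of view")
        for i, a in enumerate(self.vials):
            for b in self.vials[i + 1 :]:
                d = np.hypot(
                    a.center_xy_mm[0] - b.center_xy_mm[0],
                    a.center_xy_mm[1] - b.center_xy_mm[1],
                )
                if d < (a.diameter_mm + b.diameter_mm) / 2.0:
                    raise ValueError(
                        f"vials at {a.center_xy_mm} and {b.center_xy_mm} overlap"
                    )


def default_phantom_spec(shape: tuple = (112, 112, 7)) -> PhantomSpec:
    """Schematic vial layout: 11 vials on a grid (one 0 % PVP, two each of
    10/25/40 % PVP, four fat mimics), FBG background."""
    xs = [20.0, 44.0, 68.0, 92.0]
    ys = [24.0, 56.0, 88.0]
    slots = [(x, y) for y in ys for x in xs]
    mats = [
        "0% PVP",
        "10% PVP",
        "10% PVP",
        "25% PVP",
        "25% PVP",
        "40% PVP",
        "40% PVP",
        "fat",
        "fat",
        "fat",
        "fat",
    ]
    vials = tuple(Vial(center_xy_mm=c, material=m) for c, m in zip(slots, mats))
    return PhantomSpec(vials=vials, shape=shape)


@dataclass(frozen=True)
class BrainRegion:
    label: int
    name: str
    volume_cm3: float
    t1_ms: float
    t2_ms: float
    m0: float = 1.0

    def __post_init__(self) -> None:
        if self.volume_cm3 <= 0:
            raise ValueError("region volume must be positive")
        if not (self.t1_ms > 0 and self.t2_ms > 0):
            raise ValueError("region T1 and T2 must be positive")


@dataclass(frozen=True)
class BrainSpec:
    regions: tuple
    shape: tuple = (96, 96, 7)
    voxel_size_mm: tuple = (1.0, 1.0, 5.0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "regions", tuple(self.regions))
        labels = [r.label for r in self.regions]
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if 0 in labels:
            raise ValueError("label 0 is reserved for background")
        vox_mm3 = float(np.prod(self.voxel_size_mm))
        total_vox = sum(round(r.volume_cm3 * 1000.0 / vox_mm3) for r in self.regions)
        if total_vox > np.prod(self.shape):
            raise ValueError("total region volume exceeds the volume shape")


def default_brain_spec(shape: tuple = (96, 96, 7)) -> BrainSpec:
    """Desk-scale brain-like spec: CSF/GM/WM at in-vivo mean relaxation values.

    Region volumes are scaled down from whole-brain values so the volume
    fits a small test grid; they are configurable.
    """
    regions = (
        BrainRegion(1, "CSF", 2.0, 3383.0, 453.0),
        BrainRegion(2, "GM", 8.0, 1516.0, 68.0),
        BrainRegion(3, "WM", 12.0, 1046.0, 46.0),
    )
    return BrainSpec(regions=regions, shape=shape)


@dataclass(frozen=True)
class AcquisitionNoise:
    """Complex Gaussian image-space noise; ``sd`` is the per-channel standard
    deviation as a fraction of the nominal m0 scale (1.0)."""

    sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValueError("noise SD must be non-negative")


@dataclass
class TruthVolumes:
    """Ground-truth parameter volumes plus integer labels (0 = background)."""

    t1_ms: np.ndarray
    t2_ms: np.ndarray
    m0: np.ndarray
    labels: np.ndarray
    voxel_size_mm: tuple = (1.0, 1.0, 5.0)

    @property
    def shape(self) -> tuple:
        return self.t1_ms.shape


def generate_phantom_truth(spec: PhantomSpec) -> TruthVolumes:
    """Rasterize the vial phantom.  Labels: 0 background, 1..n per vial."""
    nx, ny, nz = spec.shape
    bg = spec.materials[spec.background_material]
    t1 = np.full(spec.shape, bg.t1_ms)
    t2 = np.full(spec.shape, bg.t2_ms)
    m0 = np.full(spec.shape, bg.m0)
    labels = np.zeros(spec.shape, dtype=np.int32)

    xg, yg = np.meshgrid(np.arange(nx, dtype=float), np.arange(ny, dtype=float), indexing="ij")
    for i, vial in enumerate(spec.vials, start=1):
        cx, cy = vial.center_xy_mm
        inside = (xg - cx) ** 2 + (yg - cy) ** 2 <= (vial.diameter_mm / 2.0) ** 2
        mat = spec.materials[vial.material]
        t1[inside, :] = mat.t1_ms
        t2[inside, :] = mat.t2_ms
        m0[inside, :] = mat.m0
        labels[inside, :] = i
    return TruthVolumes(t1, t2, m0, labels, spec.voxel_size_mm)


def generate_brain_truth(spec: BrainSpec, seed: int = 0) -> TruthVolumes:
    """Place compact (spherical, in mm units) regions without overlap.

    Each region claims exactly ``round(volume / voxel_volume)`` voxels (the
    nearest voxels to a randomly drawn center), so voxel counts match the
    target volume to within one voxel.  Background voxels have zero m0.
    """
    rng = np.random.default_rng(seed)
    nx, ny, nz = spec.shape
    vs = np.asarray(spec.voxel_size_mm, dtype=float)
    vox_mm3 = float(np.prod(vs))

    coords = np.stack(
        np.meshgrid(
            np.arange(nx) * vs[0],
            np.arange(ny) * vs[1],
            np.arange(nz) * vs[2],
            indexing="ij",
        ),
        axis=-1,
    ).reshape(-1, 3)

    labels = np.zeros(nx * ny * nz, dtype=np.int32)
    t1 = np.zeros(nx * ny * nz)
    t2 = np.zeros(nx * ny * nz)
    m0 = np.zeros(nx * ny * nz)

    extent = np.array([nx * vs[0], ny * vs[1], nz * vs[2]])
    # big regions first: easier packing
    for region in sorted(spec.regions, key=lambda r: -r.volume_cm3):
        n_vox = max(1, round(region.volume_cm3 * 1000.0 / vox_mm3))
        radius = (3.0 * region.volume_cm3 * 1000.0 / (4.0 * np.pi)) ** (1.0 / 3.0)
        placed = False
        for _ in range(500):
            margin = np.minimum(radius, extent / 2.0 - 1e-9)
            center = margin + rng.random(3) * (extent - 2 * margin)
            d2 = np.sum((coords - center) ** 2, axis=1)
            nearest = np.argpartition(d2, min(n_vox, d2.size - 1))[:n_vox]
            if np.any(labels[nearest] != 0):
                continue
            labels[nearest] = region.label
            t1[nearest] = region.t1_ms
            t2[nearest] = region.t2_ms
            m0[nearest] = region.m0
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place region {region.name!r} ({region.volume_cm3} cm3) "
                "without overlap; volume too crowded"
            )
    shape = spec.shape
    return TruthVolumes(
        t1.reshape(shape), t2.reshape(shape), m0.reshape(shape), labels.reshape(shape),
        spec.voxel_size_mm,
    )


def generate_b1_field(
    shape: tuple,
    amplitude: float = 0.1,
    seed: int = 0,
    clip: tuple = (0.6, 1.4),
) -> np.ndarray:
    """Smooth quadratic relative-B1 field centered near 1.0.

    ``amplitude`` bounds the peak deviation from 1.0 (before the safety
    clip to ``clip``); 0 gives a uniform field of exactly 1.0.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    if amplitude == 0:
        return np.ones(shape)
    rng = np.random.default_rng(seed)
    axes = [np.linspace(-1.0, 1.0, n) if n > 1 else np.zeros(1) for n in shape]
    x, y, z = np.meshgrid(*axes, indexing="ij")
    c = rng.uniform(-1.0, 1.0, size=9)
    q = (
        c[0] * x
        + c[1] * y
        + c[2] * z
        + c[3] * x * y
        + c[4] * x * z
        + c[5] * y * z
        + c[6] * x**2
        + c[7] * y**2
        + c[8] * z**2
    )
    peak = np.abs(q).max()
    if peak > 0:
        q = q / peak
    field = 1.0 + amplitude * q
    return np.clip(field, clip[0], clip[1])


def simulate_acquisition(
    truth: TruthVolumes,
    b1: np.ndarray,
    params: SequenceParams,
    noise: AcquisitionNoise = AcquisitionNoise(),
    n_epg_states: int = 30,
    b1_quantization: float = 0.01,
    dtype=np.complex64,
) -> np.ndarray:
    """Forward-simulate the 4-D image series (x, y, slices, time).

    Per voxel, the signal is ``simulate_signals`` at the truth (T1, T2, m0)
    and the local B1, plus i.i.d. complex Gaussian noise.  B1 is quantized
    to ``b1_quantization`` (the dictionary's native granularity) so that
    only unique (T1, T2, B1) combinations are simulated.
    """
    b1 = np.asarray(b1, dtype=float)
    if b1.shape != truth.shape:
        raise ValueError(f"b1 shape {b1.shape} != truth shape {truth.shape}")
    nt = params.n_timepoints
    shape = truth.shape
    nvox = int(np.prod(shape))

    t1 = truth.t1_ms.reshape(-1)
    t2 = truth.t2_ms.reshape(-1)
    m0 = truth.m0.reshape(-1)
    if b1_quantization > 0:
        b1q = np.round(b1.reshape(-1) / b1_quantization) * b1_quantization
    else:
        b1q = b1.reshape(-1)

    series = np.zeros((nvox, nt), dtype=dtype)
    active = m0 > 0
    if np.any(active):
        combos = np.column_stack([t1[active], t2[active], b1q[active]])
        uniq, inverse = np.unique(combos, axis=0, return_inverse=True)
        logger.info("simulating %d unique tissue/B1 combinations", uniq.shape[0])
        sigs = simulate_signals(
            params, uniq[:, 0], uniq[:, 1], uniq[:, 2], 1.0, n_epg_states=n_epg_states
        ).astype(dtype)
        idx = np.flatnonzero(active)
        chunk = 8192
        for start in range(0, idx.size, chunk):
            sl = idx[start : start + chunk]
            series[sl] = sigs[inverse[start : start + chunk]]
            series[sl] *= m0[sl, None].astype(np.float32)

    if noise.sd > 0:
        rng = np.random.default_rng(noise.seed)
        re = rng.standard_normal((nvox, nt), dtype=np.float32)
        im = rng.standard_normal((nvox, nt), dtype=np.float32)
        series += (noise.sd * (re + 1j * im)).astype(dtype)
    return series.reshape(*shape, nt)


def phantom_roi_specs(
    spec: PhantomSpec,
    vial_slices: tuple | None = None,
    n_fbg_rois: int = 4,
    fbg_slice: int | None = None,
    roi_diameter_mm: float = 8.0,
    clearance_mm: float = 2.0,
):
    """ROIs for the vial phantom: one central 8 mm circle per vial over six
    slices, plus ``n_fbg_rois`` same-size circles in the background fill on
    a single slice.

    Returns a list of ``(unit_name, ROISpec)``; repeated-material vials get
    distinct unit names ('40% PVP #1', '40% PVP #2', ...).
    """
    from mrfkit.qa import ROISpec

    nz = spec.shape[2]
    if vial_slices is None:
        vial_slices = tuple(range(min(6, nz)))
    if fbg_slice is None:
        fbg_slice = nz // 2

    out = []
    counts: dict[str, int] = {}
    for v in spec.vials:
        counts[v.material] = counts.get(v.material, 0) + 1
        out.append(
            (
                f"{v.material} #{counts[v.material]}",
                ROISpec(v.center_xy_mm, vial_slices, roi_diameter_mm),
            )
        )

    # Background ROIs: centers whose whole circle (plus a safety clearance)
    # lies outside every vial, chosen greedily for spatial spread.
    r = roi_diameter_mm / 2.0
    nx, ny = spec.shape[:2]
    step = 2
    cand = []
    for cx in range(int(np.ceil(r)), int(nx - r), step):
        for cy in range(int(np.ceil(r)), int(ny - r), step):
            clear = min(
                np.hypot(cx - v.center_xy_mm[0], cy - v.center_xy_mm[1])
                - v.diameter_mm / 2.0
                for v in spec.vials
            ) if spec.vials else np.inf
            if clear >= r + clearance_mm:
                cand.append((cx, cy, clear))
    if len(cand) < n_fbg_rois:
        raise ValueError("not enough clear background for the requested FBG ROIs")
    chosen: list[tuple] = []
    cand.sort(key=lambda c: -c[2])
    chosen.append(cand[0][:2])
    while len(chosen) < n_fbg_rois:
        best = max(
            cand,
            key=lambda c: min(np.hypot(c[0] - x, c[1] - y) for x, y in chosen),
        )
        chosen.append(best[:2])
    for k, (cx, cy) in enumerate(chosen, start=1):
        out.append(
            (
                f"{spec.background_material} #{k}",
                ROISpec((float(cx), float(cy)), (fbg_slice,), roi_diameter_mm),
            )
        )
    return out


def generate_test_retest_pair(
    truth: TruthVolumes,
    b1: np.ndarray,
    params: SequenceParams,
    noise: AcquisitionNoise,
    seeds: tuple,
    **kwargs,
) -> tuple:
    """Two acquisitions of identical truth/B1 with independent noise."""
    s1, s2 = seeds
    if s1 == s2 and noise.sd > 0:
        warnings.warn("equal noise seeds: test and retest noise will be correlated")
    a = simulate_acquisition(truth, b1, params, replace(noise, seed=s1), **kwargs)
    b = simulate_acquisition(truth, b1, params, replace(noise, seed=s2), **kwargs)
    return a, b
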