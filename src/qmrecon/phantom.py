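"""Synthetic multi-coil, multi-contrast phantom data.

Stands in for an acquired or downloaded dataset: a brain-like
piecewise-constant tissue phantom (nested ellipses with per-tissue PD/T1/T2),
smooth complex coil sensitivities from Biot-Savart fields of loop coils
placed outside the field of view, contrast series from the sequence signal
models, and complex Gaussian k-space noise with standard deviation equal to a
fixed fraction (default 0.01%) of the peak k-space magnitude.

Everything is deterministic for a fixed seed, so downstream reconstruction
and training tests run on reproducible cases with known ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Optional

import numpy as np

from .autodiff import _fft2c_np as fft2c_np
from .encoding import CoilSensitivitySet, MultiContrastKSpace
from .signal_models import ParameterMaps, SequenceParams, synthesize_contrasts

BACKGROUND, WM, GM, CSF, LESION = 0, 1, 2, 3, 4


@dataclass(frozen=True)
class TissueProps:
    """Quantitative values of one tissue class (PD a.u., T1/T2 ms)."""

    name: str
    pd: float
    t1: float
    t2: float

    def __post_init__(self):
        if self.pd < 0:
            raise ValueError("PD must be non-negative")
        if self.t1 <= 0 or self.t2 <= 0:
            raise ValueError("T1 and T2 must be positive")


# Artifact defaults: WM and GM fall inside both evaluation threshold regions
# (T1 <= 1000 ms, T2 <= 120 ms) while CSF violates both; the lesion class is
# pathology-like and excluded by the T2 <= 120 ms region.
DEFAULT_TISSUES: Dict[int, TissueProps] = {
    BACKGROUND: TissueProps("background", 0.0, 1.0, 1.0),
    WM: TissueProps("white matter", 0.70, 800.0, 70.0),
    GM: TissueProps("gray matter", 0.85, 950.0, 100.0),
    CSF: TissueProps("csf", 1.00, 4000.0, 1800.0),
    LESION: TissueProps("lesion", 0.90, 1400.0, 250.0),
}

# Cartilage/fluid-like values for knee-style qDESS cases (T2 within bounds).
KNEE_TISSUES: Dict[int, TissueProps] = {
    BACKGROUND: TissueProps("background", 0.0, 1.0, 1.0),
    WM: TissueProps("cartilage", 0.75, 1200.0, 40.0),
    GM: TissueProps("muscle", 0.85, 1400.0, 50.0),
    CSF: TissueProps("synovial fluid", 1.00, 3000.0, 300.0),
    LESION: TissueProps("meniscus", 0.60, 1000.0, 25.0),
}


@dataclass
class TissuePhantom:
    """Piecewise-constant labeled phantom with a per-tissue value table."""

    label_map: np.ndarray
    tissue_table: Dict[int, TissueProps]
    pixel_size: float = 1.0  # mm

    def __post_init__(self):
        self.label_map = np.asarray(self.label_map, dtype=np.int64)
        present = set(np.unique(self.label_map).tolist())
        missing = present - set(self.tissue_table)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from tissue table")
        bg = self.tissue_table.get(BACKGROUND)
        if bg is not None and bg.pd != 0.0:
            raise ValueError("background tissue must have PD = 0")

    def _lookup(self, attr: str) -> np.ndarray:
        lut = np.zeros(max(self.tissue_table) + 1, dtype=np.float64)
        for lab, t in self.tissue_table.items():
            lut[lab] = getattr(t, attr)
        return lut[self.label_map]

    @property
    def pd_map(self) -> np.ndarray:
        return self._lookup("pd")

    @property
    def t1_map(self) -> np.ndarray:
        return self._lookup("t1")

    @property
    def t2_map(self) -> np.ndarray:
        return self._lookup("t2")

    def parameter_maps(self) -> ParameterMaps:
        return ParameterMaps(pd=self.pd_map, t1=self.t1_map, t2=self.t2_map,
                             validity=self.pd_map > 0)


@dataclass
class CoilGeometry:
    """Loop-coil array: (center mm, unit normal, radius mm) per loop."""

    loops: list  # of (center: (3,), normal: (3,), radius: float)
    n_segments: int = 64

    def __post_init__(self):
        if self.n_segments < 16:
            raise ValueError("n_segments must be >= 16")
        clean = []
        for center, normal, radius in self.loops:
            center = np.asarray(center, dtype=np.float64)
            normal = np.asarray(normal, dtype=np.float64)
            if radius <= 0:
                raise ValueError("loop radius must be positive")
            nn = np.linalg.norm(normal)
            if nn == 0:
                raise ValueError("loop normal must be nonzero")
            clean.append((center, normal / nn, float(radius)))
        self.loops = clean


@dataclass
class SimConfig:
    """Synthesis settings: matrix size, coils, noise level, seed."""

    matrix_size: tuple = (64, 64)
    n_coils: int = 6
    noise_fraction: float = 1e-4  # 0.01% of peak |k|
    seed: int = 0
    fov: float = 256.0  # mm

    def __post_init__(self):
        r, c = self.matrix_size
        if r < 8 or c < 8:
            raise ValueError("matrix dimensions must be >= 8")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be non-negative")
        if self.n_coils < 1:
            raise ValueError("need at least one coil")


# -- tissue phantom --------------------------------------------------------

def _ellipse(rows: int, cols: int, cy: float, cx: float, ry: float, rx: float,
             angle: float = 0.0) -> np.ndarray:
    yy, xx = np.mgrid[0:rows, 0:cols].astype(np.float64)
    y = yy - cy
    x = xx - cx
    if angle:
        ca, sa = np.cos(angle), np.sin(angle)
        y, x = ca * y - sa * x, sa * y + ca * x
    return (y / ry) ** 2 + (x / rx) ** 2 <= 1.0


def make_tissue_phantom(rows: int, cols: int, seed: int = 0,
                        tissue_table: Optional[Dict[int, TissueProps]] = None,
                        n_lesions: Optional[int] = None,
                        pixel_size: float = 1.0) -> TissuePhantom:
    """Brain-like nested-ellipse phantom with seeded elliptical lesions.

    Outer CSF rim, GM ribbon, WM interior with CSF ventricles; lesion
    ellipses are placed inside the WM at seed-dependent positions while the
    outer anatomy is seed-independent.
    """
    if rows < 8 or cols < 8:
        raise ValueError("phantom dimensions must be >= 8")
    table = dict(DEFAULT_TISSUES if tissue_table is None else tissue_table)
    for required in (BACKGROUND, WM, GM, CSF):
        if required not in table:
            raise ValueError(f"tissue table must define label {required}")
    cy, cx = (rows - 1) / 2.0, (cols - 1) / 2.0
    labels = np.zeros((rows, cols), dtype=np.int64)
    head = _ellipse(rows, cols, cy, cx, 0.46 * rows, 0.40 * cols)
    gm_out = _ellipse(rows, cols, cy, cx, 0.41 * rows, 0.35 * cols)
    wm_out = _ellipse(rows, cols, cy, cx, 0.33 * rows, 0.27 * cols)
    labels[head] = CSF
    labels[gm_out] = GM
    labels[wm_out] = WM
    # ventricles: two small CSF ellipses inside the WM
    vr, vc = 0.10 * rows, 0.05 * cols
    labels[_ellipse(rows, cols, cy - 0.02 * rows, cx - 0.10 * cols, vr, vc, 0.3)] = CSF
    labels[_ellipse(rows, cols, cy - 0.02 * rows, cx + 0.10 * cols, vr, vc, -0.3)] = CSF
    rng = np.random.default_rng(seed)
    if n_lesions is None:
        n_lesions = int(rng.integers(2, 5))
    if n_lesions > 0 and LESION not in table:
        table[LESION] = DEFAULT_TISSUES[LESION]
    wm_idx = np.argwhere(labels == WM)
    for _ in range(n_lesions):
        if wm_idx.size == 0:
            break
        ly, lx = wm_idx[rng.integers(0, len(wm_idx))]
        r1 = 1.0 + 2.0 * rng.random()
        r2 = 1.0 + 2.0 * rng.random()
        les = _ellipse(rows, cols, ly, lx, r1, r2, float(rng.random() * np.pi))
        labels[les & (labels == WM)] = LESION
    return TissuePhantom(label_map=labels, tissue_table=table, pixel_size=pixel_size)


# -- coil simulation -------------------------------------------------------

def loop_ring_geometry(n_coils: int = 6, fov: float = 256.0,
                       radius: float = 100.0, distance: Optional[float] = None,
                       n_segments: int = 64) -> CoilGeometry:
    """Ring of loop coils in the image plane, normals pointing at the center.

    ``distance`` is the coil-center distance from the FOV center; the default
    keeps every winding clear of the FOV rectangle.
    """
    if distance is None:
        distance = 0.75 * fov
    loops = []
    for k in range(n_coils):
        ang = 2.0 * np.pi * k / n_coils
        center = np.array([distance * np.cos(ang), distance * np.sin(ang), 0.0])
        normal = -center / np.linalg.norm(center)
        loops.append((center, normal, radius))
    return CoilGeometry(loops=loops, n_segments=n_segments)


def loop_field(center, normal, radius: float, points: np.ndarray,
               n_segments: int = 64) -> np.ndarray:
    """Biot-Savart magnetic field of one current loop at ``points`` (N, 3).

    Discretized line integral ``sum dl x r / |r|^3`` over ``n_segments``
    straight segments; the constant mu0*I/4pi is omitted (normalized away).
    """
    center = np.asarray(center, dtype=np.float64)
    normal = np.asarray(normal, dtype=np.float64)
    normal = normal / np.linalg.norm(normal)
    # orthonormal frame spanning the loop plane
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    th = np.linspace(0.0, 2.0 * np.pi, n_segments + 1)
    pts = center + radius * (np.cos(th)[:, None] * u + np.sin(th)[:, None] * v)
    mid = 0.5 * (pts[:-1] + pts[1:])  # (S, 3)
    dl = np.diff(pts, axis=0)  # (S, 3)
    r = points[:, None, :] - mid[None, :, :]  # (N, S, 3)
    r3 = np.linalg.norm(r, axis=-1) ** 3  # (N, S)
    if np.any(r3 < 1e-12):
        raise ValueError("field evaluation point lies on the coil winding")
    cross = np.cross(dl[None, :, :], r)  # (N, S, 3)
    return (cross / r3[..., None]).sum(axis=1)


def biot_savart_sensitivities(geometry: CoilGeometry, rows: int, cols: int,
                              fov: float = 256.0) -> CoilSensitivitySet:
    """Complex coil sensitivities on the z=0 image plane, RSS-normalized.

    Phase comes from the transverse field components (``B_x - i B_y``
    convention, main field along z). Raises if a winding comes within a
    pixel of the image plane's FOV region or a loop center sits inside it.
    """
    if fov <= 0:
        raise ValueError("fov must be positive")
    px = fov / max(rows, cols)
    half = fov / 2.0
    ys = (np.arange(rows) - (rows - 1) / 2.0) * (fov / rows)
    xs = (np.arange(cols) - (cols - 1) / 2.0) * (fov / cols)
    xx, yy = np.meshgrid(xs, ys)
    points = np.stack([xx.ravel(), yy.ravel(), np.zeros(rows * cols)], axis=1)
    maps = np.empty((len(geometry.loops), rows, cols), dtype=np.complex128)
    for i, (center, normal, radius) in enumerate(geometry.loops):
        if abs(center[0]) <= half and abs(center[1]) <= half and abs(center[2]) < px:
            raise ValueError("loop center lies inside the field of view")
        # winding clearance check against the image region
        th = np.linspace(0.0, 2.0 * np.pi, geometry.n_segments, endpoint=False)
        ref = np.array([1.0, 0.0, 0.0])
        if abs(normal @ ref) > 0.9:
            ref = np.array([0.0, 1.0, 0.0])
        u = np.cross(normal, ref)
        u /= np.linalg.norm(u)
        v = np.cross(normal, u)
        wire = center + radius * (np.cos(th)[:, None] * u + np.sin(th)[:, None] * v)
        inside = (np.abs(wire[:, 0]) <= half) & (np.abs(wire[:, 1]) <= half) \
            & (np.abs(wire[:, 2]) < px)
        if inside.any():
            raise ValueError("coil winding intersects the image plane FOV")
        b = loop_field(center, normal, radius, points, geometry.n_segments)
        maps[i] = (b[:, 0] - 1j * b[:, 1]).reshape(rows, cols)
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    support = rss > 1e-12 * rss.max()
    maps = np.where(support, maps / np.where(support, rss, 1.0), 0.0)
    return CoilSensitivitySet(maps=maps, support=support)


# -- full case synthesis ---------------------------------------------------

def synthesize_case(phantom: TissuePhantom, seq: SequenceParams,
                    sens: CoilSensitivitySet, cfg: SimConfig
                    ) -> tuple[MultiContrastKSpace, ParameterMaps, CoilSensitivitySet]:
    """Forward-simulate fully sampled multi-coil k-space for one case.

    Per contrast, the image is the signal model evaluated on the phantom's
    PD/T1/T2; each coil image is sensitivity x contrast image; k-space is
    the centered orthonormal 2D DFT. Complex Gaussian noise with standard
    deviation ``noise_fraction * max |k|`` is added independently to the
    real and imaginary parts. Returns (k-space, ground-truth maps, the true
    sensitivities).
    """
    rows, cols = phantom.label_map.shape
    if sens.maps.shape[1:] != (rows, cols):
        raise ValueError("sensitivity maps do not match the phantom grid")
    if (rows, cols) != tuple(cfg.matrix_size):
        raise ValueError("config matrix size does not match the phantom")
    contrasts = synthesize_contrasts(phantom.pd_map, phantom.t1_map,
                                     phantom.t2_map, seq).astype(np.complex128)
    coil_imgs = contrasts[:, None, :, :] * sens.maps[None, :, :, :]
    kspace = fft2c_np(coil_imgs)
    if cfg.noise_fraction > 0:
        sigma = cfg.noise_fraction * np.abs(kspace).max()
        rng = np.random.default_rng(cfg.seed)
        noise = rng.normal(scale=sigma, size=kspace.shape) \
            + 1j * rng.normal(scale=sigma, size=kspace.shape)
        kspace = kspace + noise
    gt = phantom.parameter_maps()
    return MultiContrastKSpace(data=kspace, seq=seq), gt, sens
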