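"""Multi-coil, multi-contrast Cartesian encoding operators.

The forward model for accelerated parallel imaging is ``y = E_Omega x``: each
contrast image is weighted by every coil sensitivity, Fourier transformed, and
sampled on that contrast's k-space mask, with unmeasured points zero-filled.
All operators use the centered orthonormal 2D DFT and work on either plain
numpy arrays or autodiff :class:`~qmrecon.autodiff.Tensor` inputs, so the same
code path serves simulation, the zero-filled baseline, and the differentiable
data-consistency layer.

Array conventions: images are ``(P, H, W)`` complex (contrast, row, col),
k-space is ``(P, C, H, W)`` (contrast, coil, row, col), sensitivities are
``(C, H, W)``, masks are boolean ``(P, H, W)``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from . import autodiff as ad


@dataclass
class CoilSensitivitySet:
    """Complex per-coil sensitivity maps, RSS-normalized on their support."""

    maps: np.ndarray  # (C, H, W) complex
    support: np.ndarray  # (H, W) bool

    def __post_init__(self):
        self.maps = np.asarray(self.maps, dtype=np.complex128)
        if self.maps.ndim != 3:
            raise ValueError("sensitivity maps must be (C, H, W)")
        if self.support is None:
            self.support = np.ones(self.maps.shape[1:], dtype=bool)
        self.support = np.asarray(self.support, dtype=bool)
        if self.support.shape != self.maps.shape[1:]:
            raise ValueError("support shape must match map shape")
        rss = np.sqrt((np.abs(self.maps) ** 2).sum(axis=0))
        if self.support.any() and not np.allclose(rss[self.support], 1.0, atol=1e-6):
            raise ValueError("RSS of sensitivities must be 1 on the support")
        if (~self.support).any() and not np.all(rss[~self.support] < 1e-12):
            raise ValueError("sensitivities must vanish off the support")

    @property
    def n_coils(self) -> int:
        return self.maps.shape[0]


@dataclass
class MultiContrastKSpace:
    """Measured multi-contrast k-space with its sequence metadata."""

    data: np.ndarray  # (P, C, H, W) complex
    seq: object = None  # SequenceParams; kept loose to avoid an import cycle
    scale: float = 1.0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 4:
            raise ValueError("k-space must be (P, C, H, W)")
        if not np.isfinite(self.data).all():
            raise ValueError("k-space contains non-finite entries")

    @property
    def n_contrasts(self) -> int:
        return self.data.shape[0]


@dataclass
class ImageStack:
    """Per-contrast complex image stack (P, H, W)."""

    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.complex128)
        if self.data.ndim != 3:
            raise ValueError("image stack must be (P, H, W)")
        if not np.isfinite(self.data).all():
            raise ValueError("image stack contains non-finite entries")


def _raw(x):
    """Unwrap container types; pass Tensors and ndarrays through."""
    if isinstance(x, (CoilSensitivitySet,)):
        return x.maps
    if isinstance(x, (MultiContrastKSpace, ImageStack)):
        return x.data
    return x


def _check_shapes(p, h, w, sens, masks):
    if sens.ndim != 3 or sens.shape[1:] != (h, w):
        raise ValueError(f"sensitivities {sens.shape} do not match image ({h}, {w})")
    if masks.shape != (p, h, w):
        raise ValueError(f"masks {masks.shape} do not match (P, H, W) = ({p}, {h}, {w})")


def apply_E(x, sens, masks):
    """Forward encoding: y[p, c] = M_p * F(C_c * x_p).

    Unsampled k-space points are zero-filled. Accepts Tensor or ndarray ``x``;
    ``sens`` and ``masks`` are constants.
    """
    xd = _raw(x)
    sens = _raw(sens)
    masks = np.asarray(_raw(masks), dtype=bool)
    shape = xd.shape
    if len(shape) != 3:
        raise ValueError("x must be (P, H, W)")
    p, h, w = shape
    _check_shapes(p, h, w, sens, masks)
    xr = ad.reshape(xd, (p, 1, h, w))
    coil_imgs = ad.mul(xr, sens[None, :, :, :])
    return ad.mul(ad.fft2c(coil_imgs), masks[:, None, :, :])


def apply_EH(y, sens, masks):
    """Adjoint encoding: x_p = sum_c conj(C_c) * F^-1(M_p * y[p, c])."""
    yd = _raw(y)
    sens = _raw(sens)
    masks = np.asarray(_raw(masks), dtype=bool)
    if len(yd.shape) != 4:
        raise ValueError("y must be (P, C, H, W)")
    p, c, h, w = yd.shape
    _check_shapes(p, h, w, sens, masks)
    if sens.shape[0] != c:
        raise ValueError(f"y has {c} coils but sensitivities have {sens.shape[0]}")
    imgs = ad.ifft2c(ad.mul(yd, masks[:, None, :, :]))
    weighted = ad.mul(imgs, np.conj(sens)[None, :, :, :])
    return ad.tsum(weighted, axis=1)


def normal_op(x, sens, masks, lam: float = 0.0):
    """Q x = E^H E x + lambda x — self-adjoint, PSD; PD for lambda > 0."""
    out = apply_EH(apply_E(x, sens, masks), sens, masks)
    if lam != 0.0:
        out = ad.add(out, ad.mul(_raw(x), float(lam)))
    return out


# -- 3D readout decoupling -------------------------------------------------

def _fft1c(x: np.ndarray, axis: int) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis
    )


def _ifft1c(x: np.ndarray, axis: int) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.ifft(np.fft.ifftshift(x, axes=axis), axis=axis, norm="ortho"), axes=axis
    )


def decouple_readout(kspace3d: np.ndarray, mask3d: Optional[np.ndarray] = None) -> np.ndarray:
    """Split 3D k-space into independent 2D problems along the readout axis.

    ``kspace3d`` is ``(P, C, Nx, Ny, Nz)`` with readout along ``Nx``. A 1D
    inverse DFT along the readout turns the 3D reconstruction into ``Nx``
    independent 2D multi-contrast cases (returned stacked on axis 0 as
    ``(Nx, P, C, Ny, Nz)``). Requires a fully sampled readout: if ``mask3d``
    ``(P, Nx, Ny, Nz)`` is given it must be constant along the readout axis.
    """
    k = np.asarray(kspace3d, dtype=np.complex128)
    if k.ndim != 5:
        raise ValueError("3D k-space must be (P, C, Nx, Ny, Nz)")
    if mask3d is not None:
        m = np.asarray(mask3d, dtype=bool)
        if m.shape != (k.shape[0], k.shape[2], k.shape[3], k.shape[4]):
            raise ValueError("mask3d must be (P, Nx, Ny, Nz)")
        if not np.all(m == m[:, :1, :, :]):
            raise ValueError("readout axis is not fully sampled; cannot decouple")
    hybrid = _ifft1c(k, axis=2)  # (P, C, Nx, Ny, Nz)
    return np.moveaxis(hybrid, 2, 0)


def recombine_readout(slices: np.ndarray) -> np.ndarray:
    """Inverse of :func:`decouple_readout`: (Nx, P, C, Ny, Nz) -> 3D k-space."""
    hybrid = np.moveaxis(np.asarray(slices, dtype=np.complex128), 0, 2)
    return _fft1c(hybrid, axis=2)


def normalize_kspace(y: np.ndarray, sens, masks) -> tuple[np.ndarray, float]:
    """Scale k-space so that max |E^H y| = 1; returns (scaled y, scale)."""
    x0 = apply_EH(y, sens, masks)
    peak = float(np.abs(x0).max())
    if peak == 0.0:
        return np.asarray(y, dtype=np.complex128), 1.0
    return np.asarray(y, dtype=np.complex128) / peak, peak
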