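"""Retrospective Cartesian undersampling and self-supervision k-space splits.

Masks emulate accelerated acquisition: a fully sampled autocalibration (ACS)
center plus uniformly random phase-encode lines or points, at a target
acceleration factor AF (ratio of full to acquired samples).

For training without a fully sampled reference, the measured region Omega is
partitioned: SSDU-style self-supervision splits Omega into a network-input set
Theta and a held-out loss set Lambda (60/40 by default); the zero-shot variant
first reserves a validation set Gamma (20% of Omega), splits the remainder Xi
into Theta/Lambda, and early-stops on Gamma. All subsets are disjoint and the
ACS block always stays in the network input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

VALID_PATTERNS = ("random_lines", "random_points")


@dataclass
class MaskSpec:
    """Specification of a retrospective undersampling mask."""

    pattern: str = "random_lines"
    af: float = 4.0
    acs: int = 16
    seed: int = 0

    def __post_init__(self):
        if self.pattern not in VALID_PATTERNS:
            raise ValueError(f"unknown pattern {self.pattern!r}; expected one of {VALID_PATTERNS}")
        if self.af < 1:
            raise ValueError("acceleration factor must be >= 1")
        if self.acs < 0:
            raise ValueError("ACS size must be non-negative")


@dataclass
class SamplingPartition:
    """Omega and its self-supervision subsets, all boolean (P, H, W).

    theta/lam are the SSDU input/loss split; xi/gamma additionally appear for
    the zero-shot nesting (theta | lam == xi, xi | gamma == omega).
    """

    omega: np.ndarray
    theta: Optional[np.ndarray] = None
    lam: Optional[np.ndarray] = None
    xi: Optional[np.ndarray] = None
    gamma: Optional[np.ndarray] = None
    ratios: tuple = (0.4, 0.2)  # (loss_fraction, validation_fraction)
    seed: int = 0

    def __post_init__(self):
        self.omega = np.asarray(self.omega, dtype=bool)
        for name in ("theta", "lam", "xi", "gamma"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v, dtype=bool)
                if v.shape != self.omega.shape:
                    raise ValueError(f"{name} shape {v.shape} != omega shape {self.omega.shape}")
                setattr(self, name, v)
        self.validate()

    def validate(self):
        om, th, la, xi, ga = self.omega, self.theta, self.lam, self.xi, self.gamma
        for name, v in (("theta", th), ("lam", la), ("xi", xi), ("gamma", ga)):
            if v is not None and (v & ~om).any():
                raise ValueError(f"{name} is not a subset of omega")
        if th is not None and la is not None:
            if (th & la).any():
                raise ValueError("theta and lam overlap")
            parent = xi if xi is not None else om
            if not np.array_equal(th | la, parent):
                raise ValueError("theta | lam does not cover its parent set")
        if xi is not None and ga is not None:
            if (xi & ga).any():
                raise ValueError("xi and gamma overlap")
            if not np.array_equal(xi | ga, om):
                raise ValueError("xi | gamma != omega")


def acs_mask(rows: int, cols: int, pattern: str, acs: int) -> np.ndarray:
    """Boolean mask of the fully sampled calibration region."""
    m = np.zeros((rows, cols), dtype=bool)
    if acs == 0:
        return m
    if pattern == "random_lines":
        lo = rows // 2 - acs // 2
        m[lo:lo + acs, :] = True
    else:
        r0 = rows // 2 - acs // 2
        c0 = cols // 2 - acs // 2
        m[r0:r0 + acs, c0:c0 + acs] = True
    return m


def gen_mask(rows: int, cols: int, spec: MaskSpec) -> np.ndarray:
    """Generate one retrospective undersampling mask.

    The ACS region is always fully sampled; the remaining budget
    ``round(rows*cols/af) - |ACS|`` is drawn uniformly at random, as whole
    phase-encode lines (``random_lines``) or single points
    (``random_points``). Deterministic for a fixed ``spec.seed``.
    """
    if rows < 1 or cols < 1:
        raise ValueError("mask dimensions must be positive")
    budget = int(round(rows * cols / spec.af))
    base = acs_mask(rows, cols, spec.pattern, spec.acs)
    n_acs = int(base.sum())
    if n_acs > budget:
        raise ValueError(
            f"ACS region ({n_acs} samples) exceeds the sampling budget ({budget}) at AF {spec.af}"
        )
    rng = np.random.default_rng(spec.seed)
    mask = base.copy()
    if spec.pattern == "random_lines":
        free_rows = np.flatnonzero(~base[:, 0])
        n_lines = int(round((budget - n_acs) / cols))
        n_lines = min(n_lines, free_rows.size)
        chosen = rng.choice(free_rows, size=n_lines, replace=False)
        mask[chosen, :] = True
    else:
        free = np.flatnonzero(~base.ravel())
        n_pts = min(budget - n_acs, free.size)
        chosen = rng.choice(free, size=n_pts, replace=False)
        mask.ravel()[chosen] = True
    return mask


def gen_contrast_masks(rows: int, cols: int, spec: MaskSpec, n_contrasts: int,
                       shared: bool = False) -> np.ndarray:
    """Stack of per-contrast masks (P, H, W); independent draws by default."""
    if shared:
        m = gen_mask(rows, cols, spec)
        return np.repeat(m[None], n_contrasts, axis=0)
    out = np.empty((n_contrasts, rows, cols), dtype=bool)
    for p in range(n_contrasts):
        sub = MaskSpec(spec.pattern, spec.af, spec.acs, seed=spec.seed + 7919 * (p + 1))
        out[p] = gen_mask(rows, cols, sub)
    return out


def _select_subset(parent: np.ndarray, protected: np.ndarray, fraction: float,
                   rng: np.random.Generator, gaussian: bool = False) -> np.ndarray:
    """Uniform (or center-weighted) sample of round(fraction*|parent\\protected|) points."""
    eligible = parent & ~protected
    idx = np.flatnonzero(eligible.ravel())
    n = int(round(fraction * idx.size))
    if gaussian and idx.size:
        shape = parent.shape[-2:]
        coords = np.array(np.unravel_index(idx % (shape[0] * shape[1]), shape)).T
        center = np.array([shape[0] / 2, shape[1] / 2])
        d2 = ((coords - center) ** 2).sum(axis=1)
        w = np.exp(-d2 / (2 * (max(shape) / 4) ** 2))
        w = w / w.sum()
        chosen = rng.choice(idx, size=n, replace=False, p=w)
    else:
        chosen = rng.choice(idx, size=n, replace=False)
    out = np.zeros_like(parent)
    out.ravel()[chosen] = True
    return out


def partition_ssdu(omega: np.ndarray, loss_fraction: float = 0.4, seed: int = 0,
                   acs: Optional[np.ndarray] = None, gaussian: bool = False
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Split Omega into (Theta, Lambda) with Lambda the held-out loss set.

    Lambda receives ``round(loss_fraction * |Omega \\ ACS|)`` points drawn
    without replacement outside the ACS; Theta is the complement within
    Omega, so Theta and Lambda are disjoint and cover Omega exactly.
    """
    omega = np.asarray(omega, dtype=bool)
    if not omega.any():
        raise ValueError("omega is empty")
    if not 0.0 < loss_fraction < 1.0:
        raise ValueError("loss_fraction must be in (0, 1)")
    protected = np.zeros_like(omega) if acs is None else (np.asarray(acs, dtype=bool) & omega)
    rng = np.random.default_rng(seed)
    lam = _select_subset(omega, protected, loss_fraction, rng, gaussian)
    theta = omega & ~lam
    return theta, lam


def partition_zsssl(omega: np.ndarray, validation_fraction: float = 0.2,
                    loss_fraction: float = 0.4, seed: int = 0,
                    acs: Optional[np.ndarray] = None, gaussian: bool = False
                    ) -> SamplingPartition:
    """Nested zero-shot split: Gamma (validation) then Theta/Lambda within Xi.

    Gamma takes ``validation_fraction`` of Omega (ACS-exempt), Xi is the
    remainder, and Xi is split 60/40 into Theta/Lambda by default — so Theta
    holds 0.6 * 0.8 = 48% of Omega.
    """
    omega = np.asarray(omega, dtype=bool)
    if not omega.any():
        raise ValueError("omega is empty")
    if not 0.0 < validation_fraction < 1.0:
        raise ValueError("validation_fraction must be in (0, 1)")
    protected = np.zeros_like(omega) if acs is None else (np.asarray(acs, dtype=bool) & omega)
    rng = np.random.default_rng(seed)
    gamma = _select_subset(omega, protected, validation_fraction, rng, gaussian)
    xi = omega & ~gamma
    theta, lam = partition_ssdu(xi, loss_fraction, seed=seed + 1, acs=acs, gaussian=gaussian)
    return SamplingPartition(omega=omega, theta=theta, lam=lam, xi=xi, gamma=gamma,
                             ratios=(loss_fraction, validation_fraction), seed=seed)


def effective_af(nominal_af: float, retained_fraction: float) -> float:
    """Acceleration experienced by the network input after a split.

    Retaining a fraction of the measured points raises the acceleration:
    ``nominal_af / retained_fraction``, reported truncated to one decimal
    (e.g. AF 4 with 60% retained -> 6.6).
    """
    if retained_fraction <= 0 or retained_fraction > 1:
        raise ValueError("retained_fraction must be in (0, 1]")
    if nominal_af < 1:
        raise ValueError("nominal_af must be >= 1")
    value = nominal_af / retained_fraction
    return math.floor(value * 10.0) / 10.0
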