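"""Training regimes for the unrolled reconstructor.

Three regimes differ only in which k-space points feed the network and which
are held out for the loss:

* supervised (SL): input is the measured region Omega; the loss compares the
  fully sampled reference over all of k-space.
* self-supervised (SSL, SSDU-style): Omega is split into Theta (input) and
  Lambda (loss); no fully sampled data is ever touched.
* zero-shot self-supervised (ZSSSL): a single test case; Omega is first split
  into Xi and a validation set Gamma, then Xi into Theta/Lambda. Training
  optimizes Theta -> Lambda, validation monitors Xi -> Gamma, and early
  stopping halts when validation fails to improve for more than ``patience``
  consecutive epochs.

The loss is the sum of the normalized L1 and normalized L2 distances between
complex k-space tensors, which makes it invariant to global scaling of a
case.

The module-level ``train_*`` functions are thin wrappers over
:class:`qmrecon.estimators.UnrolledReconstructor`, which owns the loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .encoding import CoilSensitivitySet, apply_EH
from .sampling import SamplingPartition


@dataclass
class TrainConfig:
    """Hyperparameters of one training run.

    ``learning_rate=None`` selects the per-strategy default: 1e-4 for SL and
    SSL, 5e-4 for ZSSSL. ``accumulation_steps`` splits each batch into that
    many gradient-accumulation chunks (mathematically equivalent to the
    unsplit batch).
    """

    strategy: str = "ZSSSL"
    learning_rate: Optional[float] = None
    epochs: int = 100
    batch_size: int = 2
    accumulation_steps: int = 1
    patience: int = 25
    seed: int = 0

    DEFAULT_LR = {"SL": 1e-4, "SSL": 1e-4, "ZSSSL": 5e-4}

    def __post_init__(self):
        self.strategy = self.strategy.upper()
        if self.strategy not in ("SL", "SSL", "ZSSSL"):
            raise ValueError(f"unknown strategy {self.strategy!r}")
        if self.learning_rate is None:
            self.learning_rate = self.DEFAULT_LR[self.strategy]
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.strategy == "ZSSSL" and self.patience < 1:
            raise ValueError("patience must be >= 1 for ZSSSL")
        if self.epochs < 1 or self.batch_size < 1 or self.accumulation_steps < 1:
            raise ValueError("epochs, batch_size, accumulation_steps must be >= 1")


@dataclass
class TrainHistory:
    """Per-epoch losses and the stopping outcome of a run."""

    train_loss: List[float] = field(default_factory=list)
    val_loss: List[float] = field(default_factory=list)
    best_epoch: int = -1
    stop_reason: str = ""

    def validate(self):
        if len(self.train_loss) != len(self.val_loss):
            raise ValueError("train and validation loss lengths differ")
        if self.val_loss and self.best_epoch >= 0:
            if not np.isclose(self.val_loss[self.best_epoch], min(self.val_loss)):
                raise ValueError("best_epoch does not hold the minimum validation loss")


class FullySampledAccessError(RuntimeError):
    """Raised when a ground-truth-free regime touches fully sampled data."""


@dataclass
class ReconCase:
    """One training/inference case: measured k-space, coils, mask partition.

    ``y_full`` (the fully sampled reference) is present only for supervised
    training; :meth:`guarded` returns a view that raises on any access to it,
    which the self-supervised regimes use to enforce their contract.
    """

    y_omega: np.ndarray  # (P, C, H, W), zero outside omega
    sens: CoilSensitivitySet
    partition: SamplingPartition
    y_full: Optional[np.ndarray] = None
    scale: float = 1.0
    meta: dict = field(default_factory=dict)

    def guarded(self) -> "GuardedCase":
        return GuardedCase(self)


class GuardedCase:
    """Proxy over :class:`ReconCase` whose ``y_full`` access is forbidden."""

    def __init__(self, case: ReconCase):
        object.__setattr__(self, "_case", case)

    def __getattr__(self, name):
        if name == "y_full":
            raise FullySampledAccessError(
                "fully sampled data must not be read in a self-supervised regime")
        return getattr(object.__getattribute__(self, "_case"), name)


def make_case(kspace_full: np.ndarray, sens: CoilSensitivitySet,
              partition: SamplingPartition, keep_full: bool = True,
              normalize: bool = True, meta: Optional[dict] = None) -> ReconCase:
    """Build a case from fully sampled k-space and a sampling partition.

    Applies the measured mask, and normalizes so the zero-filled adjoint of
    the measured data has unit peak magnitude (recorded in ``scale`` and
    shared by ``y_full`` so the supervised loss sees consistent units).
    """
    k = np.asarray(kspace_full, dtype=np.complex128)
    om = partition.omega
    y_omega = k * om[:, None, :, :]
    scale = 1.0
    if normalize:
        x0 = apply_EH(y_omega, sens, om)
        peak = float(np.abs(x0).max())
        if peak > 0:
            scale = peak
            y_omega = y_omega / scale
            k = k / scale
    return ReconCase(y_omega=y_omega, sens=sens, partition=partition,
                     y_full=(k if keep_full else None), scale=scale,
                     meta=dict(meta or {}))


# -- loss ------------------------------------------------------------------

def recon_loss(u, v):
    """Normalized L1 + normalized L2 distance between k-space tensors.

    ``||u - v||_1 / ||u||_1 + ||u - v||_2 / ||u||_2`` over complex entries,
    with ``u`` the (constant) reference. Scale-invariant: L(cu, cv) = L(u, v).
    """
    ud = u.data if isinstance(u, Tensor) else np.asarray(u)
    vd = v.data if isinstance(v, Tensor) else np.asarray(v)
    if ud.shape != vd.shape:
        raise ValueError("loss inputs must share a shape")
    n1 = float(np.abs(ud).sum())
    n2 = float(np.sqrt((np.abs(ud) ** 2).sum()))
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("reference tensor must be nonzero")
    diff = ad.sub(v, ud)
    l1 = ad.tsum(ad.absolute(diff))
    l2 = ad.sqrt(ad.real(ad.tsum(ad.mul(ad.conj(diff), diff))))
    return ad.add(ad.mul(l1, 1.0 / n1), ad.mul(l2, 1.0 / n2))


# -- optimizer -------------------------------------------------------------

class Adam:
    """Adaptive-moment gradient descent over a list of parameter tensors."""

    def __init__(self, params: Sequence[Tensor], lr: float = 1e-4,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * (g * g)
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)


# -- thin wrappers over the estimator --------------------------------------

def train_supervised(cases, val_cases, dparams=None, unroll_cfg=None,
                     cfg: Optional[TrainConfig] = None):
    """Supervised training; returns (DenoiserParams, TrainHistory)."""
    from .estimators import UnrolledReconstructor
    cfg = cfg or TrainConfig(strategy="SL")
    est = UnrolledReconstructor.from_configs("sl", dparams, unroll_cfg, cfg)
    est.fit(cases, val_cases=val_cases)
    return est.denoiser_params_, est.history_


def train_ssl(cases, val_cases=None, dparams=None, unroll_cfg=None,
              cfg: Optional[TrainConfig] = None):
    """SSDU-style self-supervised training; never reads fully sampled data."""
    from .estimators import UnrolledReconstructor
    cfg = cfg or TrainConfig(strategy="SSL")
    est = UnrolledReconstructor.from_configs("ssl", dparams, unroll_cfg, cfg)
    est.fit(cases, val_cases=val_cases)
    return est.denoiser_params_, est.history_


def train_zsssl(case, dparams=None, unroll_cfg=None,
                cfg: Optional[TrainConfig] = None):
    """Zero-shot self-supervised training on a single case."""
    from .estimators import UnrolledReconstructor
    cfg = cfg or TrainConfig(strategy="ZSSSL")
    est = UnrolledReconstructor.from_configs("zsssl", dparams, unroll_cfg, cfg)
    est.fit([case] if isinstance(case, (ReconCase, GuardedCase)) else case)
    return est.denoiser_params_, est.history_
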