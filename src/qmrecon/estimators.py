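"""Estimator-style interfaces to the unrolled reconstructor and map fitters.

:class:`UnrolledReconstructor` follows the scikit-learn estimator protocol:
hyperparameters in ``__init__`` (so ``get_params``/``set_params``/``clone``
work), training in ``fit``, fitted state in trailing-underscore attributes,
reconstruction in ``predict``. :class:`RelaxometryMapper` is the
transform-shaped counterpart for signal-model map fitting.
"""

from __future__ import annotations

from typing import Optional, Sequence, Union

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import autodiff as ad
from .encoding import apply_E
from .network import (DenoiserParams, UnrollConfig, checkpointed_unrolled_recon,
                      unrolled_recon)
from .signal_models import SequenceParams, fit_maps
from .training import (Adam, GuardedCase, ReconCase, TrainConfig, TrainHistory,
                       recon_loss)

CaseLike = Union[ReconCase, GuardedCase]


class UnrolledReconstructor(BaseEstimator):
    """Trainable unrolled reconstruction network for multi-contrast k-space.

    Parameters mirror the network and training configuration: the denoiser
    (``n_blocks`` residual blocks of ``n_filters`` 3x3 filters, scaling
    ``alpha_scale``), the unroll (``n_unrolls`` alternations, ``cg_iters``
    conjugate-gradient steps, regularization weight ``lam``), and the
    training regime (``strategy`` in {'sl', 'ssl', 'zsssl'}). With
    ``checkpointed=True`` training uses per-unroll gradient checkpointing;
    forward results are identical either way.

    Fitted attributes: ``denoiser_params_`` (best-validation weights),
    ``history_`` (per-epoch losses and stop reason), ``unroll_config_``.
    """

    def __init__(self, strategy: str = "zsssl", n_blocks: int = 10,
                 n_filters: int = 64, alpha_scale: float = 0.1,
                 n_unrolls: int = 10, cg_iters: int = 10, lam: float = 0.05,
                 learning_rate: Optional[float] = None, epochs: int = 100,
                 batch_size: int = 2, accumulation_steps: int = 1,
                 patience: int = 25, seed: int = 0, checkpointed: bool = True,
                 share_weights: bool = True):
        self.strategy = strategy
        self.n_blocks = n_blocks
        self.n_filters = n_filters
        self.alpha_scale = alpha_scale
        self.n_unrolls = n_unrolls
        self.cg_iters = cg_iters
        self.lam = lam
        self.learning_rate = learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.accumulation_steps = accumulation_steps
        self.patience = patience
        self.seed = seed
        self.checkpointed = checkpointed
        self.share_weights = share_weights

    # -- wiring -----------------------------------------------------------
    @classmethod
    def from_configs(cls, strategy: str, dparams: Optional[DenoiserParams],
                     unroll_cfg: Optional[UnrollConfig],
                     cfg: TrainConfig) -> "UnrolledReconstructor":
        ucfg = unroll_cfg or UnrollConfig()
        kw = dict(strategy=strategy, n_unrolls=ucfg.n_unrolls,
                  cg_iters=ucfg.cg_iters, lam=ucfg.lam,
                  share_weights=ucfg.share_weights,
                  learning_rate=cfg.learning_rate, epochs=cfg.epochs,
                  batch_size=cfg.batch_size,
                  accumulation_steps=cfg.accumulation_steps,
                  patience=cfg.patience, seed=cfg.seed)
        if dparams is not None:
            kw.update(n_blocks=dparams.n_blocks, n_filters=dparams.n_filters,
                      alpha_scale=dparams.alpha_scale)
        est = cls(**kw)
        est._warm_params = dparams
        return est

    def _train_config(self) -> TrainConfig:
        return TrainConfig(strategy=self.strategy, learning_rate=self.learning_rate,
                           epochs=self.epochs, batch_size=self.batch_size,
                           accumulation_steps=self.accumulation_steps,
                           patience=self.patience, seed=self.seed)

    def _unroll_config(self) -> UnrollConfig:
        return UnrollConfig(n_unrolls=self.n_unrolls, cg_iters=self.cg_iters,
                            lam=self.lam, share_weights=self.share_weights)

    def _forward(self, y, sens, masks, params, cfg):
        fn = checkpointed_unrolled_recon if self.checkpointed else unrolled_recon
        return fn(y, sens, masks, params, cfg)

    # -- per-case loss ----------------------------------------------------
    def _case_loss(self, case: CaseLike, params, cfg, mode: str):
        """Build the loss graph for one case in the given mode.

        mode 'sl': input Omega, reference full k-space; 'train': Theta ->
        Lambda; 'val': Xi -> Gamma (zero-shot validation split).
        """
        part = case.partition
        if mode == "sl":
            in_masks = part.omega
            in_y = case.y_omega
            out_masks = np.ones_like(part.omega)
            u = case.y_full
            if u is None:
                raise ValueError("supervised training needs fully sampled data")
        elif mode == "train":
            if part.theta is None or part.lam is None:
                raise ValueError("self-supervision needs a Theta/Lambda partition")
            if not part.lam.any():
                raise ValueError("loss set Lambda is empty")
            in_masks = part.theta
            in_y = case.y_omega * part.theta[:, None]
            out_masks = part.lam
            u = case.y_omega * part.lam[:, None]
        elif mode == "val":
            if part.xi is None or part.gamma is None:
                raise ValueError("zero-shot validation needs a Xi/Gamma partition")
            in_masks = part.xi
            in_y = case.y_omega * part.xi[:, None]
            out_masks = part.gamma
            u = case.y_omega * part.gamma[:, None]
        else:
            raise ValueError(f"unknown loss mode {mode!r}")
        x = self._forward(in_y, case.sens, in_masks, params, cfg)
        v = apply_E(x, case.sens, out_masks)
        return recon_loss(u, v)

    def _val_loss(self, cases, params, cfg, mode: str) -> float:
        with ad.no_grad():
            vals = [float(_scalar(self._case_loss(c, params, cfg, mode)))
                    for c in cases]
        return float(np.mean(vals))

    # -- fit --------------------------------------------------------------
    def fit(self, cases: Sequence[CaseLike], val_cases: Optional[Sequence[CaseLike]] = None):
        """Train the network; returns self.

        ``cases`` is a sequence of :class:`~qmrecon.training.ReconCase`. For
        'zsssl' exactly one case is expected; for 'sl'/'ssl', ``val_cases``
        defaults to the training cases.
        """
        tcfg = self._train_config()
        cfg = self._unroll_config()
        strategy = tcfg.strategy
        cases = list(cases)
        if not cases:
            raise ValueError("no training cases given")
        if strategy == "ZSSSL":
            if len(cases) != 1:
                raise ValueError("zero-shot training uses exactly one case")
            part = cases[0].partition
            if part.xi is None or part.gamma is None:
                raise ValueError("zero-shot training needs a nested Xi/Gamma partition")
            part.validate()
        if strategy != "SL":
            cases = [c.guarded() if isinstance(c, ReconCase) else c for c in cases]
            if val_cases is not None:
                val_cases = [c.guarded() if isinstance(c, ReconCase) else c
                             for c in val_cases]
        val_set = list(val_cases) if val_cases else cases
        train_mode = "sl" if strategy == "SL" else "train"
        val_mode = "val" if strategy == "ZSSSL" else train_mode

        p0 = cases[0].y_omega.shape[0]
        params = getattr(self, "_warm_params", None)
        if params is None:
            params = DenoiserParams.init(p0, self.n_blocks, self.n_filters,
                                         self.alpha_scale, seed=tcfg.seed)
        opt = Adam(params.parameters(), lr=tcfg.learning_rate)
        rng = np.random.default_rng(tcfg.seed)
        history = TrainHistory()
        best_val = np.inf
        best_state = params.state_arrays()
        bad = 0
        stop_reason = "max_epochs"
        for epoch in range(tcfg.epochs):
            order = rng.permutation(len(cases))
            epoch_losses = []
            for start in range(0, len(order), tcfg.batch_size):
                batch = [cases[i] for i in order[start:start + tcfg.batch_size]]
                opt.zero_grad()
                chunks = np.array_split(np.arange(len(batch)),
                                        min(tcfg.accumulation_steps, len(batch)))
                for chunk in chunks:
                    if len(chunk) == 0:
                        continue
                    total = None
                    for i in chunk:
                        li = self._case_loss(batch[i], params, cfg, train_mode)
                        epoch_losses.append(float(_scalar(li)))
                        total = li if total is None else ad.add(total, li)
                    loss = ad.mul(total, 1.0 / len(batch))
                    loss.backward()
                opt.step()
            train_loss = float(np.mean(epoch_losses))
            val_loss = self._val_loss(val_set, params, cfg, val_mode)
            history.train_loss.append(train_loss)
            history.val_loss.append(val_loss)
            if val_loss < best_val:
                best_val = val_loss
                best_state = params.state_arrays()
                history.best_epoch = epoch
                bad = 0
            else:
                bad += 1
                # paper rule: halt once validation has failed to improve for
                # more than `patience` consecutive epochs
                if strategy == "ZSSSL" and bad > tcfg.patience:
                    stop_reason = "early_stopping"
                    break
        history.stop_reason = stop_reason
        params.load_arrays(best_state)
        history.validate()
        self.denoiser_params_ = params
        self.history_ = history
        self.unroll_config_ = cfg
        return self

    # -- inference ---------------------------------------------------------
    def predict(self, case: CaseLike) -> np.ndarray:
        """Reconstruct one case from its measured k-space (input E_Omega).

        Returns the (P, H, W) complex image stack in the case's original
        intensity units (the normalization scale is undone).
        """
        if not hasattr(self, "denoiser_params_"):
            raise RuntimeError("estimator is not fitted")
        cfg = self.unroll_config_
        with ad.no_grad():
            x = self._forward(case.y_omega, case.sens, case.partition.omega,
                              self.denoiser_params_, cfg)
        x = x.data if hasattr(x, "data") and not isinstance(x, np.ndarray) else np.asarray(x)
        return x * case.scale


def _scalar(x) -> float:
    return float(x.data) if hasattr(x, "data") and not isinstance(x, np.ndarray) else float(x)


class RelaxometryMapper(TransformerMixin, BaseEstimator):
    """Signal-model map fitting as a transform.

    ``transform`` maps a (P, H, W) contrast stack (complex or magnitude) to a
    :class:`~qmrecon.signal_models.ParameterMaps`. Stateless: ``fit`` only
    validates the sequence.
    """

    def __init__(self, seq: Optional[SequenceParams] = None,
                 t2_bounds=(1.0, 5000.0), t1_bounds=(1.0, 10000.0)):
        self.seq = seq
        self.t2_bounds = t2_bounds
        self.t1_bounds = t1_bounds

    def fit(self, X=None, y=None):
        if self.seq is None:
            raise ValueError("a SequenceParams must be provided")
        return self

    def transform(self, X):
        self.fit()
        X = np.asarray(X)
        if X.ndim != 3 or X.shape[0] != self.seq.n_contrasts:
            raise ValueError(
                f"expected ({self.seq.n_contrasts}, H, W) contrast stack, got {X.shape}")
        return fit_maps(X, self.seq, t2_bounds=self.t2_bounds, t1_bounds=self.t1_bounds)
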