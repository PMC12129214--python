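"""Forward signal models and parameter-map fitting for three qMRI sequences.

Supported sequences and the tissue parameter each one encodes:

* MSME (multi-slice multi-echo spin echo): ``S_i = I0 * exp(-TE_i / T2)`` —
  monoexponential T2 decay across echoes.
* VFA-SPGR (variable flip angle spoiled gradient echo):
  ``S_i = I0 * sin(a_i) * (1 - E1) / (1 - E1 * cos(a_i))`` with
  ``E1 = exp(-TR/T1)`` — T1 from signals at several flip angles. The
  ``include_sin`` flag selects the standard DESPOT1 form (default) or the
  variant without the ``sin`` numerator factor.
* qDESS (quantitative double-echo steady state): T2 from the echo/FID signal
  ratio, optionally corrected for T1 and diffusion effects through the
  steady-state factor ``F(alpha, T1, D)``.

Fitting inverts each model: log-linear + bounded Gauss-Newton for MSME,
the DESPOT1 linearization for VFA, and a closed form for qDESS. Each fitter
reports a validity flag that is false wherever the data cannot support the
model (non-positive signal, non-physical slope, parameter at a bound).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

SEQUENCE_KINDS = ("MSME", "VFA_SPGR", "QDESS")


@dataclass
class SequenceParams:
    """Acquisition parameters of one qMRI protocol.

    Times in ms, angles in degrees. The qDESS extras parameterize the
    Sveinsson T1/diffusion correction: ``assumed_t1`` (ms), diffusivity ``d``
    (mm^2/s), spoiler amplitude ``g`` (mT/m), spoiler duration ``tau`` (ms)
    and gyromagnetic ratio ``gamma`` (rad s^-1 mT^-1), entering through the
    dephasing per unit length ``dk = gamma * g * tau``. ``d`` defaults to 0,
    which switches the diffusion term off.
    """

    kind: str
    te_list: tuple = ()
    tr: float = 0.0
    flip_angles: tuple = ()
    assumed_t1: float = 1000.0
    d: float = 0.0
    g: float = 0.0
    tau: float = 0.0
    gamma: float = 0.0

    def __post_init__(self):
        if self.kind not in SEQUENCE_KINDS:
            raise ValueError(f"unknown sequence kind {self.kind!r}")
        self.te_list = tuple(float(t) for t in self.te_list)
        self.flip_angles = tuple(float(a) for a in self.flip_angles)
        if any(t <= 0 for t in self.te_list):
            raise ValueError("echo times must be positive")
        if any(b <= a for a, b in zip(self.te_list, self.te_list[1:])):
            raise ValueError("echo times must be strictly increasing")
        # DESS reads its second echo in the following TR (TE2 = 2 TR - TE1),
        # so the TR > TE sanity check applies only to the spin/gradient-echo
        # sequences.
        if self.kind != "QDESS" and self.te_list and self.tr <= max(self.te_list):
            raise ValueError("TR must exceed the largest echo time")
        if self.kind == "QDESS" and self.te_list and self.tr <= self.te_list[0]:
            raise ValueError("TR must exceed the FID echo time")
        if any(not 0 < a <= 90 for a in self.flip_angles):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if self.kind == "MSME" and len(self.te_list) < 2:
            raise ValueError("MSME needs at least two echoes")
        if self.kind == "VFA_SPGR" and len(self.flip_angles) < 2:
            raise ValueError("VFA needs at least two flip angles")

    @property
    def n_contrasts(self) -> int:
        if self.kind == "MSME":
            return len(self.te_list)
        if self.kind == "VFA_SPGR":
            return len(self.flip_angles)
        return 2  # qDESS: FID + echo

    @property
    def dk(self) -> float:
        return self.gamma * self.g * self.tau


def msme_params(te_list=None, tr: float = 4000.0) -> SequenceParams:
    """Default MSME protocol: 16 echoes, TE 10-160 ms every 10, TR 4000 ms."""
    if te_list is None:
        te_list = tuple(range(10, 170, 10))
    return SequenceParams("MSME", te_list=te_list, tr=tr, flip_angles=(90.0,))


def vfa_params(flip_angles=(4.0, 24.0), tr: float = 18.0, te: float = 8.0) -> SequenceParams:
    """Default VFA-SPGR protocol: flip angles 4/24 deg, TR 18 ms, TE 8 ms."""
    return SequenceParams("VFA_SPGR", te_list=(te,), tr=tr, flip_angles=flip_angles)


def qdess_params(te_list=(5.7, 30.1), tr: float = 17.9, flip: float = 20.0,
                 assumed_t1: float = 1000.0, d: float = 0.0, g: float = 30.0,
                 tau: float = 2.0, gamma: float = 267513.0) -> SequenceParams:
    """Default qDESS (knee) protocol: TE 5.7/30.1 ms, TR 17.9 ms, 20 deg."""
    return SequenceParams("QDESS", te_list=te_list, tr=tr, flip_angles=(flip,),
                          assumed_t1=assumed_t1, d=d, g=g, tau=tau, gamma=gamma)


@dataclass
class ParameterMaps:
    """PD/T1/T2 maps (ms) with a pixelwise validity mask."""

    pd: np.ndarray
    t1: np.ndarray
    t2: np.ndarray
    validity: np.ndarray

    def __post_init__(self):
        self.pd = np.asarray(self.pd, dtype=np.float64)
        self.t1 = np.asarray(self.t1, dtype=np.float64)
        self.t2 = np.asarray(self.t2, dtype=np.float64)
        self.validity = np.asarray(self.validity, dtype=bool)
        shapes = {self.pd.shape, self.t1.shape, self.t2.shape, self.validity.shape}
        if len(shapes) != 1:
            raise ValueError("all maps must share one shape")


# -- MSME ------------------------------------------------------------------

def msme_signal(i0, t2, te_list) -> np.ndarray:
    """Monoexponential spin-echo decay ``I0 * exp(-TE/T2)``.

    Broadcasts over array-valued ``i0``/``t2``; the echo axis is appended
    last.
    """
    i0 = np.asarray(i0, dtype=np.float64)
    t2 = np.asarray(t2, dtype=np.float64)
    te = np.asarray(te_list, dtype=np.float64)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be positive")
    if np.any(te <= 0):
        raise ValueError("echo times must be positive")
    return i0[..., None] * np.exp(-te / t2[..., None])


def fit_t2_msme(signals, te_list, bounds=(1.0, 5000.0)) -> tuple[float, float, bool]:
    """Fit (I0, T2) to one echo train by nonlinear least squares.

    Initialized by log-linear regression of ``log S`` on TE, refined with a
    bounded trust-region solver. ``valid`` is false when the signal is
    non-positive, the decay is non-physical, or T2 lands on a bound.
    """
    s = np.asarray(signals, dtype=np.float64)
    te = np.asarray(te_list, dtype=np.float64)
    if s.size < 2 or te.size != s.size:
        raise ValueError("need at least two echoes with matching TE list")
    lo, hi = bounds
    if np.any(s <= 0) or not np.all(np.isfinite(s)):
        return 0.0, hi, False
    # log-linear seed
    A = np.vstack([np.ones_like(te), -te]).T
    coef, *_ = np.linalg.lstsq(A, np.log(s), rcond=None)
    r2_0 = coef[1]
    if r2_0 <= 0:  # flat or growing signal
        return float(np.exp(coef[0])), hi, False
    t2_0 = float(np.clip(1.0 / r2_0, lo, hi))
    i0_0 = float(np.exp(coef[0]))

    def resid(p):
        return p[0] * np.exp(-te / p[1]) - s

    sol = least_squares(resid, x0=[i0_0, t2_0], bounds=([0.0, lo], [np.inf, hi]),
                        method="trf", xtol=1e-14, ftol=1e-14, gtol=1e-14)
    i0, t2 = float(sol.x[0]), float(sol.x[1])
    valid = sol.success and (lo + 1e-9 < t2 < hi - 1e-9)
    return i0, t2, bool(valid)


def fit_t2_msme_map(signals: np.ndarray, te_list, bounds=(1.0, 5000.0),
                    n_iter: int = 12) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized per-pixel MSME fit over a (..., n_echo) magnitude stack.

    Log-linear initialization followed by ``n_iter`` Gauss-Newton updates on
    (I0, R2 = 1/T2); equivalent to the scalar fitter on clean data but
    orders of magnitude faster on full maps. Returns (I0, T2, valid).
    """
    s = np.abs(np.asarray(signals, dtype=np.float64))
    te = np.asarray(te_list, dtype=np.float64)
    lo, hi = bounds
    pos = np.all(s > 0, axis=-1)
    safe = np.where(s > 0, s, 1.0)
    logs = np.log(safe)
    # weighted log-linear regression (weights ~ s reduce noise-floor bias)
    w = safe
    sw = w.sum(-1)
    swt = (w * te).sum(-1)
    swtt = (w * te * te).sum(-1)
    swy = (w * logs).sum(-1)
    swty = (w * te * logs).sum(-1)
    det = sw * swtt - swt * swt
    det = np.where(det == 0, 1.0, det)
    slope = (sw * swty - swt * swy) / det
    icept = (swtt * swy - swt * swty) / det
    r2 = np.clip(-slope, 1.0 / hi, 1.0 / lo)
    i0 = np.exp(icept)
    for _ in range(n_iter):
        e = np.exp(-te * r2[..., None])
        model = i0[..., None] * e
        res = model - s
        # Jacobian columns: dS/dI0 = e, dS/dR2 = -te * model
        j11 = (e * e).sum(-1)
        j12 = (-te * model * e).sum(-1)
        j22 = (te * te * model * model).sum(-1)
        g1 = (e * res).sum(-1)
        g2 = (-te * model * res).sum(-1)
        det = j11 * j22 - j12 * j12
        det = np.where(np.abs(det) < 1e-30, 1.0, det)
        di0 = (j22 * g1 - j12 * g2) / det
        dr2 = (j11 * g2 - j12 * g1) / det
        i0 = np.maximum(i0 - di0, 0.0)
        r2 = np.clip(r2 - dr2, 1.0 / hi, 1.0 / lo)
    t2 = 1.0 / r2
    valid = pos & (t2 > lo + 1e-9) & (t2 < hi - 1e-9) & np.isfinite(i0)
    return i0, t2, valid


# -- VFA-SPGR --------------------------------------------------------------

def spgr_signal(i0, t1, tr, alpha, include_sin: bool = True) -> np.ndarray:
    """Spoiled gradient echo steady-state signal at flip angle ``alpha`` (deg)."""
    i0 = np.asarray(i0, dtype=np.float64)
    t1 = np.asarray(t1, dtype=np.float64)
    a = np.deg2rad(np.asarray(alpha, dtype=np.float64))
    if np.any(t1 <= 0):
        raise ValueError("T1 must be positive")
    e1 = np.exp(-tr / t1)
    core = (1.0 - e1) / (1.0 - e1 * np.cos(a))
    if include_sin:
        core = np.sin(a) * core
    return i0 * core


def fit_t1_vfa(signals, flip_angles, tr, include_sin: bool = True,
               bounds=(1.0, 10000.0)):
    """DESPOT1 linearized T1 fit from SPGR signals at several flip angles.

    Regresses ``S/sin(a)`` on ``S/tan(a)`` (or ``S`` on ``S*cos(a)`` for the
    no-sin variant); the slope is ``E1 = exp(-TR/T1)``. Works elementwise
    over leading array dimensions. Returns (I0, T1, valid); ``valid`` is
    false for slopes outside (0, 1) or T1 at a bound.
    """
    s = np.asarray(signals, dtype=np.float64)
    a = np.deg2rad(np.asarray(flip_angles, dtype=np.float64))
    if a.size < 2 or np.unique(a).size < 2:
        raise ValueError("need at least two distinct flip angles")
    if s.shape[-1] != a.size:
        raise ValueError("signals last axis must match the number of flip angles")
    lo, hi = bounds
    if include_sin:
        yv = s / np.sin(a)
        xv = s / np.tan(a)
    else:
        yv = s
        xv = s * np.cos(a)
    n = a.size
    sx = xv.sum(-1)
    sy = yv.sum(-1)
    sxx = (xv * xv).sum(-1)
    sxy = (xv * yv).sum(-1)
    det = n * sxx - sx * sx
    det = np.where(np.abs(det) < 1e-300, np.nan, det)
    slope = (n * sxy - sx * sy) / det
    icept = (sy - slope * sx) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        t1 = -tr / np.log(slope)
        i0 = icept / (1.0 - slope)
    valid = np.isfinite(slope) & (slope > 0.0) & (slope < 1.0)
    t1 = np.where(valid, np.clip(t1, lo, hi), hi)
    i0 = np.where(valid & np.isfinite(i0), i0, 0.0)
    valid = valid & (t1 > lo + 1e-9) & (t1 < hi - 1e-9)
    if s.ndim == 1:
        return float(i0), float(t1), bool(valid)
    return i0, t1, valid


# -- qDESS -----------------------------------------------------------------

def qdess_f_factor(seq: SequenceParams) -> float:
    """Steady-state T1/diffusion factor F(alpha, T1, D) of the echo/FID ratio."""
    a = np.deg2rad(seq.flip_angles[0])
    dk2d = seq.dk ** 2 * seq.d
    e = np.exp(-seq.tr / seq.assumed_t1 - seq.tr * dk2d)
    return float(np.sin(a / 2.0) ** 2 * (1.0 + e) / (1.0 - np.cos(a) * e))


def qdess_ratio(t2, seq: SequenceParams, corrected: bool = True) -> np.ndarray:
    """Echo/FID signal ratio of a DESS acquisition.

    Uncorrected (``corrected=False``): ``exp(-2 (TR - TE) / T2)`` with TE the
    FID echo time. With the correction, multiplied by ``F(alpha, T1, D)`` and
    by the diffusion attenuation ``exp(-(TR - tau/3) dk^2 D)``.
    """
    t2 = np.asarray(t2, dtype=np.float64)
    if np.any(t2 <= 0):
        raise ValueError("T2 must be positive")
    if seq.kind != "QDESS":
        raise ValueError("sequence must be QDESS")
    te = seq.te_list[0]
    base = np.exp(-2.0 * (seq.tr - te) / t2)
    if not corrected:
        return base
    dk2d = seq.dk ** 2 * seq.d
    diff = np.exp(-(seq.tr - seq.tau / 3.0) * dk2d)
    return qdess_f_factor(seq) * base * diff


def fit_t2_qdess(fid, echo, seq: SequenceParams, bounds=(1.0, 500.0),
                 corrected: bool = True) -> tuple[np.ndarray, np.ndarray]:
    """Closed-form pixelwise T2 from the echo/FID magnitude ratio.

    Inverts :func:`qdess_ratio`: with ``r = |echo| / |fid|``,
    ``T2 = -2 (TR - TE) / (ln(r / F) + (TR - tau/3) dk^2 D)``. Pixels with
    zero FID, a non-decaying ratio (``r >= F``), or T2 outside ``bounds`` are
    flagged invalid.
    """
    fid = np.abs(np.asarray(fid, dtype=np.float64))
    echo = np.abs(np.asarray(echo, dtype=np.float64))
    if fid.shape != echo.shape:
        raise ValueError("fid and echo must share a shape")
    if seq.kind != "QDESS":
        raise ValueError("sequence must be QDESS")
    lo, hi = bounds
    f = qdess_f_factor(seq) if corrected else 1.0
    dk2d = (seq.dk ** 2 * seq.d) if corrected else 0.0
    te = seq.te_list[0]
    ok = fid > 0
    r = np.where(ok, echo / np.where(ok, fid, 1.0), 0.0)
    ok &= (r > 0) & (r < f)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = np.log(np.where(ok, r / f, 0.5)) + (seq.tr - seq.tau / 3.0) * dk2d
        t2 = -2.0 * (seq.tr - te) / denom
    ok &= np.isfinite(t2) & (t2 > lo) & (t2 <= hi)
    t2 = np.where(ok, t2, 0.0)
    return t2, ok


# -- unified forward synthesis / fitting ----------------------------------

def synthesize_contrasts(pd: np.ndarray, t1: np.ndarray, t2: np.ndarray,
                         seq: SequenceParams) -> np.ndarray:
    """Evaluate the sequence's signal model pixelwise -> (P, ...) stack."""
    pd = np.asarray(pd, dtype=np.float64)
    t1 = np.asarray(t1, dtype=np.float64)
    t2 = np.asarray(t2, dtype=np.float64)
    if seq.kind == "MSME":
        t2s = np.where(t2 > 0, t2, 1.0)
        out = msme_signal(np.where(t2 > 0, pd, 0.0), t2s, seq.te_list)
        return np.moveaxis(out, -1, 0)
    if seq.kind == "VFA_SPGR":
        t1s = np.where(t1 > 0, t1, 1.0)
        out = np.stack([
            spgr_signal(np.where(t1 > 0, pd, 0.0), t1s, seq.tr, a)
            for a in seq.flip_angles
        ])
        return out
    if seq.kind == "QDESS":
        t2s = np.where(t2 > 0, t2, 1.0)
        ratio = qdess_ratio(t2s, seq)
        fid = pd
        return np.stack([fid, np.where(t2 > 0, fid * ratio, 0.0)])
    raise ValueError(f"unsupported sequence {seq.kind!r}")


def fit_maps(contrasts: np.ndarray, seq: SequenceParams,
             t2_bounds=(1.0, 5000.0), t1_bounds=(1.0, 10000.0)) -> ParameterMaps:
    """Fit PD/T1/T2 maps from a (P, H, W) magnitude contrast stack."""
    mags = np.abs(np.asarray(contrasts))
    if seq.kind == "MSME":
        sig = np.moveaxis(mags, 0, -1)
        i0, t2, valid = fit_t2_msme_map(sig, seq.te_list, bounds=t2_bounds)
        t1 = np.zeros_like(t2)
        return ParameterMaps(pd=i0, t1=t1, t2=t2, validity=valid)
    if seq.kind == "VFA_SPGR":
        sig = np.moveaxis(mags, 0, -1)
        i0, t1, valid = fit_t1_vfa(sig, seq.flip_angles, seq.tr, bounds=t1_bounds)
        t2 = np.zeros_like(t1)
        return ParameterMaps(pd=i0, t1=t1, t2=t2, validity=valid)
    if seq.kind == "QDESS":
        t2, valid = fit_t2_qdess(mags[0], mags[1], seq,
                                 bounds=(t2_bounds[0], min(t2_bounds[1], 500.0)))
        return ParameterMaps(pd=mags[0], t1=np.full_like(t2, seq.assumed_t1),
                             t2=t2, validity=valid)
    raise ValueError(f"unsupported sequence {seq.kind!r}")
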