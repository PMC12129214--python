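"""Case container I/O, configuration schema, and checkpoint files.

A *case* is one simulated acquisition stored in an HDF5 file:

====================  =======================================================
group / dataset       contents
====================  =======================================================
``/kspace``           complex fully-or-undersampled k-space, (P, C, H, W)
``/sens``             complex coil sensitivities, (C, H, W)
``/sens_support``     boolean support of the sensitivities, (H, W)
``/masks/*``          bit-packed boolean masks (P, H, W): omega, theta,
                      lambda, xi, gamma
``/maps/{pd,t1,t2}``  ground-truth parameter maps, (H, W)
``/contrasts_gt``     ground-truth contrast images, (P, H, W) complex
``/recon_contrasts``  reconstruction output (written by the reconstruct stage)
``/maps_pred/*``      fitted maps from the reconstruction (fit stage)
====================  =======================================================

Root attributes carry the sequence parameters (kind, TE list, TR, flip
angles, qDESS extras), seeds, acceleration factor and normalization scale,
sufficient to rebuild the :class:`~qmrecon.signal_models.SequenceParams`
exactly. Run configuration is a strict-schema YAML document; unknown keys
are rejected.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
from typing import Dict, Literal, Optional, Tuple

import h5py
import nibabel as nib
import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, ValidationError

from .encoding import CoilSensitivitySet
from .sampling import SamplingPartition
from .signal_models import ParameterMaps, SequenceParams
from .network import DenoiserParams, UnrollConfig
from .training import ReconCase

log = logging.getLogger("qmrecon")

MASK_NAMES = ("omega", "theta", "lambda", "xi", "gamma")


class ConfigError(ValueError):
    """Invalid or unparsable run configuration (CLI exit code 2)."""


class DataError(ValueError):
    """Missing or inconsistent case data (CLI exit code 3)."""


# -- configuration ---------------------------------------------------------

class RunConfig(BaseModel):
    """Schema-validated pipeline configuration."""

    model_config = ConfigDict(extra="forbid")

    # simulation
    sequence: Literal["MSME", "VFA_SPGR", "QDESS"] = "MSME"
    te_list: Optional[Tuple[float, ...]] = None  # MSME echo-train override
    matrix_size: Tuple[int, int] = (64, 64)
    n_coils: int = 6
    noise_fraction: float = 1e-4
    fov: float = 256.0
    n_train: int = 10
    n_val: int = 2
    n_test: int = 2
    # sampling
    af: float = 4.0
    pattern: Literal["random_lines", "random_points"] = "random_lines"
    acs: int = 8
    shared_masks: bool = False
    loss_fraction: float = 0.4
    validation_fraction: float = 0.2
    # network
    n_blocks: int = 10
    n_filters: int = 64
    alpha_scale: float = 0.1
    n_unrolls: int = 10
    cg_iters: int = 10
    lam: float = 0.05
    # training
    strategy: Literal["sl", "ssl", "zsssl"] = "zsssl"
    learning_rate: Optional[float] = None
    epochs: int = 100
    batch_size: int = 2
    accumulation_steps: int = 1
    patience: int = 25
    seed: int = 0
    # evaluation
    regions: Tuple[str, ...] = ("whole", "t2_le_120")
    out_dir: str = "qmrecon_out"


def load_config(path) -> RunConfig:
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    except (OSError, yaml.YAMLError) as exc:
        raise ConfigError(f"cannot read config {path}: {exc}") from exc
    try:
        cfg = RunConfig(**raw)
    except (ValidationError, TypeError) as exc:
        raise ConfigError(str(exc)) from exc
    return cfg


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(cfg.model_dump_json().encode()).hexdigest()[:12]


# -- sequence attrs --------------------------------------------------------

def _seq_to_attrs(seq: SequenceParams) -> dict:
    return {
        "seq_kind": seq.kind, "te_list": list(seq.te_list), "tr": seq.tr,
        "flip_angles": list(seq.flip_angles), "assumed_t1": seq.assumed_t1,
        "d": seq.d, "g": seq.g, "tau": seq.tau, "gamma": seq.gamma,
    }


def _seq_from_attrs(attrs) -> SequenceParams:
    return SequenceParams(
        kind=str(attrs["seq_kind"]), te_list=tuple(attrs["te_list"]),
        tr=float(attrs["tr"]), flip_angles=tuple(attrs["flip_angles"]),
        assumed_t1=float(attrs["assumed_t1"]), d=float(attrs["d"]),
        g=float(attrs["g"]), tau=float(attrs["tau"]), gamma=float(attrs["gamma"]))


# -- masks (bit-packed) ----------------------------------------------------

def _write_mask(grp: h5py.Group, name: str, mask: np.ndarray) -> None:
    mask = np.asarray(mask, dtype=bool)
    ds = grp.create_dataset(name, data=np.packbits(mask.ravel()))
    ds.attrs["shape"] = mask.shape


def _read_mask(grp: h5py.Group, name: str) -> np.ndarray:
    ds = grp[name]
    shape = tuple(int(s) for s in ds.attrs["shape"])
    n = int(np.prod(shape))
    return np.unpackbits(ds[...], count=n).astype(bool).reshape(shape)


# -- case container --------------------------------------------------------

def write_case(path, kspace: np.ndarray, sens: CoilSensitivitySet,
               seq: SequenceParams, maps: Optional[ParameterMaps] = None,
               contrasts_gt: Optional[np.ndarray] = None,
               masks: Optional[Dict[str, np.ndarray]] = None,
               attrs: Optional[dict] = None) -> None:
    """Write (or create) a case container."""
    with h5py.File(path, "w") as fh:
        fh.create_dataset("kspace", data=np.asarray(kspace, dtype=np.complex128))
        fh.create_dataset("sens", data=sens.maps)
        fh.create_dataset("sens_support", data=sens.support.astype(np.uint8))
        if maps is not None:
            g = fh.create_group("maps")
            g.create_dataset("pd", data=maps.pd)
            g.create_dataset("t1", data=maps.t1)
            g.create_dataset("t2", data=maps.t2)
            g.create_dataset("validity", data=maps.validity.astype(np.uint8))
        if contrasts_gt is not None:
            fh.create_dataset("contrasts_gt",
                              data=np.asarray(contrasts_gt, dtype=np.complex128))
        if masks:
            mg = fh.create_group("masks")
            for name, m in masks.items():
                if m is not None:
                    _write_mask(mg, name, m)
        for k, v in _seq_to_attrs(seq).items():
            fh.attrs[k] = v
        for k, v in (attrs or {}).items():
            fh.attrs[k] = v


def update_case(path, **datasets) -> None:
    """Add or replace datasets in an existing container.

    Dict-valued entries become groups of datasets (e.g. ``maps_pred``).
    """
    with h5py.File(path, "a") as fh:
        for name, data in datasets.items():
            if isinstance(data, dict):
                if name in fh:
                    del fh[name]
                g = fh.create_group(name)
                for k, v in data.items():
                    g.create_dataset(k, data=np.asarray(v))
            else:
                if name in fh:
                    del fh[name]
                fh.create_dataset(name, data=np.asarray(data))


def write_partition(path, partition: SamplingPartition) -> None:
    """Store a sampling partition in a case container."""
    with h5py.File(path, "a") as fh:
        if "masks" in fh:
            del fh["masks"]
        mg = fh.create_group("masks")
        for name, attr in zip(MASK_NAMES, ("omega", "theta", "lam", "xi", "gamma")):
            m = getattr(partition, attr)
            if m is not None:
                _write_mask(mg, name, m)
        fh.attrs["partition_seed"] = partition.seed
        fh.attrs["ratios"] = list(partition.ratios)


class CaseFile:
    """Read-side view of a case container."""

    def __init__(self, path):
        self.path = Path(path)
        if not self.path.exists():
            raise DataError(f"case file {path} does not exist")

    def require(self, *names: str) -> None:
        with h5py.File(self.path, "r") as fh:
            for name in names:
                node = fh
                for part in name.split("/"):
                    if part not in node:
                        raise DataError(
                            f"case {self.path.name} lacks required group '{name}'")
                    node = node[part]

    def read(self, name: str) -> np.ndarray:
        with h5py.File(self.path, "r") as fh:
            node = fh
            for part in name.split("/"):
                if part not in node:
                    raise DataError(f"case {self.path.name} lacks '{name}'")
                node = node[part]
            return node[...]

    def sequence(self) -> SequenceParams:
        with h5py.File(self.path, "r") as fh:
            return _seq_from_attrs(fh.attrs)

    def attr(self, name, default=None):
        with h5py.File(self.path, "r") as fh:
            return fh.attrs.get(name, default)

    def partition(self) -> SamplingPartition:
        with h5py.File(self.path, "r") as fh:
            if "masks" not in fh or "omega" not in fh["masks"]:
                raise DataError(f"case {self.path.name} has no sampling masks")
            mg = fh["masks"]
            kw = {}
            for name, attr in zip(MASK_NAMES, ("omega", "theta", "lam", "xi", "gamma")):
                if name in mg:
                    kw[attr] = _read_mask(mg, name)
            seed = int(fh.attrs.get("partition_seed", 0))
            ratios = tuple(fh.attrs.get("ratios", (0.4, 0.2)))
        return SamplingPartition(seed=seed, ratios=ratios, **kw)

    def sensitivities(self) -> CoilSensitivitySet:
        with h5py.File(self.path, "r") as fh:
            maps = fh["sens"][...]
            support = fh["sens_support"][...].astype(bool) if "sens_support" in fh \
                else np.ones(maps.shape[1:], dtype=bool)
        return CoilSensitivitySet(maps=maps, support=support)

    def maps(self, group: str = "maps") -> ParameterMaps:
        with h5py.File(self.path, "r") as fh:
            if group not in fh:
                raise DataError(f"case {self.path.name} lacks '{group}'")
            g = fh[group]
            validity = g["validity"][...].astype(bool) if "validity" in g \
                else np.ones(g["t2"].shape, dtype=bool)
            return ParameterMaps(pd=g["pd"][...], t1=g["t1"][...],
                                 t2=g["t2"][...], validity=validity)

    def recon_case(self, keep_full: bool = True) -> ReconCase:
        """Assemble a training/inference :class:`ReconCase`."""
        from .training import make_case
        self.require("kspace", "sens", "masks/omega")
        kspace = self.read("kspace")
        return make_case(kspace, self.sensitivities(), self.partition(),
                         keep_full=keep_full,
                         meta={"path": str(self.path)})


# -- NIfTI export ----------------------------------------------------------

def export_nifti(case_path, group: str, out_path, magnitude: bool = False,
                 pixel_size: float = 1.0) -> Path:
    """Export a container group as NIfTI; row/col become the first two axes.

    Complex groups are refused unless ``magnitude=True``. Re-importing the
    file recovers the exported array exactly (up to float64 round-trip).
    """
    cf = CaseFile(case_path)
    arr = cf.read(group)
    if np.iscomplexobj(arr):
        if not magnitude:
            raise DataError(f"group '{group}' is complex; pass magnitude=True")
        arr = np.abs(arr)
    arr = np.asarray(arr, dtype=np.float64)
    if arr.ndim == 3:  # (P, H, W) -> (H, W, P) volume
        arr = np.moveaxis(arr, 0, -1)
    affine = np.diag([pixel_size, pixel_size, 1.0, 1.0])
    img = nib.Nifti1Image(arr, affine)
    img.header.set_zooms((pixel_size, pixel_size) + (1.0,) * (arr.ndim - 2))
    out_path = Path(out_path)
    nib.save(img, str(out_path))
    return out_path


def import_nifti(path) -> np.ndarray:
    arr = np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)
    if arr.ndim == 3:
        arr = np.moveaxis(arr, -1, 0)
    return arr


# -- checkpoints -----------------------------------------------------------

def save_checkpoint(path, params: DenoiserParams, cfg: UnrollConfig,
                    seed: int, extra: Optional[dict] = None) -> None:
    """Weights in one .npz plus a JSON sidecar with the unroll settings."""
    path = Path(path)
    np.savez(path, *[w.data for w in params.weights])
    sidecar = {
        "n_contrasts": params.n_contrasts, "n_blocks": params.n_blocks,
        "n_filters": params.n_filters, "alpha_scale": params.alpha_scale,
        "n_unrolls": cfg.n_unrolls, "cg_iters": cfg.cg_iters, "lam": cfg.lam,
        "share_weights": cfg.share_weights, "seed": seed,
    }
    sidecar.update(extra or {})
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_checkpoint(path) -> tuple[DenoiserParams, UnrollConfig, dict]:
    path = Path(path)
    sidecar_path = path.with_suffix(".json")
    if not path.exists() or not sidecar_path.exists():
        raise DataError(f"checkpoint {path} (or its JSON sidecar) is missing")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    npz = np.load(path if path.suffix == ".npz" else str(path) + ".npz")
    params = DenoiserParams.init(meta["n_contrasts"], meta["n_blocks"],
                                 meta["n_filters"], meta["alpha_scale"], seed=0)
    params.load_arrays([npz[f"arr_{i}"] for i in range(len(npz.files))])
    cfg = UnrollConfig(n_unrolls=meta["n_unrolls"], cg_iters=meta["cg_iters"],
                       lam=meta["lam"], share_weights=meta["share_weights"])
    return params, cfg, meta
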