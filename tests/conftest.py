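"""Shared fixtures: small randomized operator instances and a toy case."""

import numpy as np
import pytest

import qmrecon as q
from qmrecon.autodiff import _ifft2c_np
from qmrecon.sampling import acs_mask


def random_sensitivities(rng, n_coils, rows, cols):
    """Random smooth-ish RSS-normalized complex sensitivities."""
    raw = rng.normal(size=(n_coils, rows, cols)) + 1j * rng.normal(size=(n_coils, rows, cols))
    rss = np.sqrt((np.abs(raw) ** 2).sum(axis=0))
    return q.CoilSensitivitySet(maps=raw / rss, support=np.ones((rows, cols), bool))


@pytest.fixture(scope="session")
def toy_seq():
    return q.msme_params(te_list=(20.0, 40.0, 80.0, 160.0))


@pytest.fixture(scope="session")
def toy_sens():
    geom = q.loop_ring_geometry(n_coils=4, fov=256.0)
    return q.biot_savart_sensitivities(geom, 32, 32, fov=256.0)


def make_toy_case(seed, toy_seq, toy_sens, keep_full=True, zero_shot=True,
                  noise_fraction=1e-4, af=4.0):
    """One 32x32, 4-coil, 4-echo MSME case with masks and partitions."""
    rows = cols = 32
    phantom = q.make_tissue_phantom(rows, cols, seed=seed)
    sim = q.SimConfig(matrix_size=(rows, cols), n_coils=4,
                      noise_fraction=noise_fraction, seed=seed)
    ksp, gt_maps, _ = q.synthesize_case(phantom, toy_seq, toy_sens, sim)
    omega = q.gen_contrast_masks(rows, cols,
                                 q.MaskSpec("random_lines", af, 4, seed=seed),
                                 toy_seq.n_contrasts)
    acs = np.broadcast_to(acs_mask(rows, cols, "random_lines", 4), omega.shape)
    if zero_shot:
        part = q.partition_zsssl(omega, seed=seed, acs=acs)
    else:
        theta, lam = q.partition_ssdu(omega, seed=seed, acs=acs)
        part = q.SamplingPartition(omega=omega, theta=theta, lam=lam, seed=seed)
    case = q.make_case(ksp.data, toy_sens, part, keep_full=keep_full)
    gt_contrasts = (np.conj(toy_sens.maps)[None] * _ifft2c_np(ksp.data)).sum(axis=1)
    return case, gt_contrasts, gt_maps, phantom


@pytest.fixture(scope="session")
def toy_case(toy_seq, toy_sens):
    return make_toy_case(7, toy_seq, toy_sens)
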