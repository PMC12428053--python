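import numpy as np
import pytest

from ctperf import (
    MapConfig,
    PerfusionMaps,
    compute_perfusion_maps,
    make_phantom,
    simulate_series,
)
from ctperf.simulate import LesionSpec


@pytest.fixture(scope="session")
def small_phantom():
    """32-cubed phantom with the default lesion, 2 mm isotropic."""
    return make_phantom(shape=(32, 32, 32), lesion=LesionSpec(side="right", radius_mm=8.0), seed=7)


@pytest.fixture(scope="session")
def noise_free_run(small_phantom):
    """Noise-free series + vascular curves + estimated maps (computed once)."""
    series, vascular = simulate_series(small_phantom, noise_sd=0.0, seed=7)
    maps = compute_perfusion_maps(series, vascular, MapConfig())
    return small_phantom, series, vascular, maps


def random_maps(rng, shape=(12, 20, 20), spacing=(2.0, 2.0, 2.0)):
    """Random but structurally valid perfusion maps for property tests.

    An ellipsoidal brain mask with smooth-ish random CBF/CBV fields and a
    random Tmax/rMTT elevation blob on one side.
    """
    zz, yy, xx = np.indices(shape, dtype=float)
    center = [(s - 1) / 2 for s in shape]
    semi = [0.45 * s for s in shape]
    mask = sum(((g - c) / a) ** 2 for g, c, a in zip((zz, yy, xx), center, semi)) <= 1.0

    cbf = np.where(mask, rng.uniform(10.0, 70.0, shape), 0.0)
    mtt = np.where(mask, rng.uniform(2.0, 12.0, shape), 0.0)
    cbv = cbf * mtt / 60.0
    tmax = np.where(mask, rng.uniform(0.0, 4.0, shape), 0.0)
    # plant an elevated-Tmax blob on a random side
    side = rng.choice(["left", "right"])
    cx = shape[2] // 4 if side == "left" else 3 * shape[2] // 4
    blob = (
        (zz - center[0]) ** 2 + (yy - center[1]) ** 2 + (xx - cx) ** 2
    ) <= rng.uniform(2.0, 5.0) ** 2
    blob &= mask
    tmax = np.where(blob, rng.uniform(7.0, 12.0), tmax)
    ttp = tmax + rng.uniform(2.0, 6.0)
    ttp = np.where(mask, ttp, 0.0)
    return PerfusionMaps(
        cbf=cbf, cbv=cbv, mtt=mtt, ttp=ttp, tmax=tmax, brain_mask=mask, spacing=spacing
    )
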