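import numpy as np
import pytest

import lesionkit as lk

SPHERE_R = 10.0
SPHERE_V = 4.0 / 3.0 * np.pi * SPHERE_R**3  # 4188.790...
SPHERE_S = 4.0 * np.pi * SPHERE_R**2  # 1256.637...


@pytest.fixture(scope="session")
def sphere_phantom():
    """Noise-free uniform sphere, r = 10 mm, 1 mm isotropic spacing."""
    spec = lk.PhantomSpec(
        grid_shape=(32, 32, 32),
        spacing=(1.0, 1.0, 1.0),
        background_suv=0.5,
        noise_sd=0.0,
        lesions=[lk.LesionSpec(center=(15.0, 15.0, 15.0), shape="sphere",
                               radius=SPHERE_R, peak_suv=8.0)],
        seed=0,
    )
    return lk.make_phantom(spec)


@pytest.fixture(scope="session")
def sphere_metrics(sphere_phantom):
    vol, _ = sphere_phantom
    labels = lk.segment_lesions(vol)
    return lk.measure_lesions(labels, vol)


@pytest.fixture(scope="session")
def sphere_mesh(sphere_phantom):
    vol, _ = sphere_phantom
    labels = lk.segment_lesions(vol)
    return lk.voxels_to_mesh(labels, 1)


def random_binary_mask(rng, shape=(20, 20, 20), p=0.2, spacing=(1.0, 1.0, 1.0)):
    return lk.BinaryMask(values=rng.random(shape) < p, spacing=np.asarray(spacing))


def bfs_flood_fill(mask: np.ndarray, connectivity: int) -> np.ndarray:
    """Independent breadth-first-search component labeling oracle."""
    from collections import deque

    offsets = []
    for dx in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dz in (-1, 0, 1):
                if (dx, dy, dz) == (0, 0, 0):
                    continue
                order = abs(dx) + abs(dy) + abs(dz)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dx, dy, dz))
    labels = np.zeros(mask.shape, dtype=np.int32)
    k = 0
    for idx in np.ndindex(mask.shape):
        if mask[idx] and labels[idx] == 0:
            k += 1
            q = deque([idx])
            labels[idx] = k
            while q:
                x, y, z = q.popleft()
                for dx, dy, dz in offsets:
                    n = (x + dx, y + dy, z + dz)
                    if all(0 <= n[i] < mask.shape[i] for i in range(3)):
                        if mask[n] and labels[n] == 0:
                            labels[n] = k
                            q.append(n)
    return labels


def assert_same_partition(a: np.ndarray, b: np.ndarray):
    """Two labelings agree up to relabeling iff label pairs are in bijection."""
    assert (a > 0).sum() == (b > 0).sum()
    fg = a > 0
    assert np.array_equal(fg, b > 0)
    pairs = set(zip(a[fg].tolist(), b[fg].tolist()))
    assert len(pairs) == len({p[0] for p in pairs}) == len({p[1] for p in pairs})
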