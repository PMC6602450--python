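import numpy as np
import pytest

from gdtqa.structio import CaTrace, TargetSequence
from gdtqa.synth import make_fixture_set, make_native, make_template_bundle


def random_trace(seed: int, n: int = 8, scale: float = 4.0, name: str = "t") -> CaTrace:
    rng = np.random.default_rng(seed)
    return CaTrace(np.arange(1, n + 1), "A" * n, rng.normal(size=(n, 3)) * scale, name)


def rigid_copy(trace: CaTrace, seed: int, name: str = "copy") -> CaTrace:
    """Apply a random proper rotation + translation."""
    rng = np.random.default_rng(seed)
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    rot = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    return CaTrace(trace.positions.copy(), trace.seq,
                   trace.coords @ rot.T + rng.uniform(-10, 10, 3), name)


@pytest.fixture(scope="session")
def small_fixture_set():
    """Compact study: 24-residue target, 12 decoys, 8 template hits."""
    return make_fixture_set(length=24, sigmas=(0.0, 1.0, 4.0), decoys_per_sigma=4,
                            n_hits=8, fragment_coverage=0.7, seed=7)


@pytest.fixture(scope="session")
def native_75():
    return make_native(75, seed=1)


@pytest.fixture()
def exact_bundle_dir(tmp_path, native_75):
    """Bundle of unmutated, unperturbed full-coverage native fragments."""
    target, native = native_75
    bundle = make_template_bundle(native, target, n_hits=6, mutation_rate=0.0,
                                  fragment_coverage=1.0, seed=3, coord_sigma=0.0)
    return bundle.write(tmp_path / "bundle"), target, native
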