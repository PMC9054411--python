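import numpy as np
import pytest

from tacerad.imaging_io import PHASE_ORDER, PhaseVolume, QuantizedVOI, VOIMask, VOIStack


def make_quantized(levels, mask=None, G=None):
    """Wrap an integer level grid (3D) as a QuantizedVOI for direct testing."""
    levels = np.asarray(levels, dtype=np.int32)
    if levels.ndim == 2:
        levels = levels[:, :, None]
    if mask is None:
        mask = levels > 0
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.ndim == 2:
            mask = mask[:, :, None]
    if G is None:
        G = int(levels.max())
    edges = np.linspace(0.5, G + 0.5, G + 1)
    return QuantizedVOI(levels=np.where(mask, levels, 0), mask=mask, G=G, bin_edges=edges)


def make_stack(voxels_by_phase, mask, spacing=(1.0, 1.0, 1.0), recist="PR", case_id="case"):
    phases = {
        pid: PhaseVolume(np.asarray(v, dtype=float), spacing, pid)
        for pid, v in zip(PHASE_ORDER, voxels_by_phase)
    }
    return VOIStack(case_id=case_id, phases=phases, mask=VOIMask(mask), recist=recist)


def random_voi(rng, max_side=8, G=6):
    """A random small quantized VOI with a random (nonempty) mask."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    levels = rng.integers(1, G + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask.flat[int(rng.integers(0, mask.size))] = True
    return make_quantized(levels, mask, G=G)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture(scope="session")
def small_phantom_case():
    """One deterministic phantom case on a small grid (session-cached)."""
    from tacerad.phantom import PhantomConfig, generate_cohort

    cfg = PhantomConfig(n_per_class=2, grid=(28, 28, 28), radius_range_mm=(6.0, 9.0), seed=7)
    stacks, _ = generate_cohort(cfg)
    return stacks[0]
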