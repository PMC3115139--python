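import numpy as np
import pytest

from physnoise import (
    EpiSimConfig,
    PhysioSimConfig,
    SliceTimingModel,
    simulate_epi,
    simulate_physio,
    uniform_slice_timing,
)


def timing_at(times, n_slices: int = 1, reference_slice: int = 0) -> SliceTimingModel:
    """Timing model with explicitly given reference times (test helper)."""
    times = np.asarray(times, dtype=float)
    tr = float(np.median(np.diff(times))) if times.size > 1 else 1.0
    return SliceTimingModel(
        volume_tr=tr,
        n_slices=n_slices,
        n_volumes=times.size,
        reference_slice=reference_slice,
        reference_times=times,
    )


@pytest.fixture(scope="session")
def physio_run():
    """A 150-volume default physio recording with ground truth."""
    cfg = PhysioSimConfig(seed=11)
    rec, truth = simulate_physio(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def small_epi_run():
    """A compact single-flip-angle EPI simulation for GLM-level tests."""
    cfg = EpiSimConfig(grid=(10, 10, 6), n_volumes=60, flip_angles=(70.0,), seed=21)
    rec, truth = simulate_physio(cfg.physio_config())
    series, noise, truth = simulate_epi(cfg, rec, truth)
    timing = uniform_slice_timing(cfg.volume_tr, cfg.n_slices, cfg.n_volumes,
                                  cfg.reference_slice)
    return cfg, rec, truth, series[70.0], noise, timing
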