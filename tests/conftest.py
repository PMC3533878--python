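import numpy as np
import pytest

from gcmskit.core import RawRun, ScanRecord
from gcmskit.simulate import mix_like_design, simulate_run


@pytest.fixture
def tiny_run() -> RawRun:
    """Three scans at 0.375 s spacing with hand-written points."""
    scans = (
        ScanRecord([50.2, 75.0], [100.0, 40.0]),
        ScanRecord([100.1, 131.0], [500.0, 250.0]),
        ScanRecord([60.4], [10.0]),
    )
    return RawRun(scans, [10.0, 10.375, 10.75], source="tiny")


@pytest.fixture
def run_with_empty_scan() -> RawRun:
    scans = (
        ScanRecord([80.0], [5.0]),
        ScanRecord([], []),
        ScanRecord([81.1, 90.0], [7.0, 2.0]),
    )
    return RawRun(scans, [1.0, 2.0, 3.0])


@pytest.fixture(scope="session")
def mix_run_truth():
    """One replicate of the 15-component mix-like fixture (cached per session)."""
    return simulate_run(mix_like_design(1), 0)


def make_uniform_run(rng: np.random.Generator, n_scans: int = 40) -> RawRun:
    """Small random run: every scan has 1-8 points scattered over 50-200 Th."""
    rt = 100.0 + 0.5 * np.arange(n_scans)
    scans = []
    for _ in range(n_scans):
        k = int(rng.integers(1, 9))
        mz = np.sort(rng.uniform(50.0, 200.0, size=k))
        while np.any(np.diff(mz) <= 0):  # enforce strict ascent
            mz = np.sort(rng.uniform(50.0, 200.0, size=k))
        scans.append(ScanRecord(mz, rng.uniform(0.0, 1e4, size=k)))
    return RawRun(tuple(scans), rt)
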