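import numpy as np
import pytest

from msiquant.grid import Pixel, SpectrumGrid


def random_grid(rng, n_pixels=20, max_peaks=30, mz_range=(185.0, 650.0)):
    """Small random centroided grid for oracle-equivalence tests."""
    pixels = []
    coords = set()
    while len(coords) < n_pixels:
        coords.add((int(rng.integers(1, 8)), int(rng.integers(1, 8))))
    for x, y in sorted(coords):
        n = int(rng.integers(0, max_peaks))
        mz = np.sort(rng.uniform(*mz_range, size=n))
        mz = mz[np.concatenate(([True], np.diff(mz) > 0))] if n else mz
        inten = rng.uniform(0, 1e4, size=mz.size)
        pixels.append(Pixel(x, y, mz, inten))
    return SpectrumGrid(pixels, mz_range=mz_range)


def brute_force_ion_image(grid, target_mz, tolerance, agg="sum"):
    """Independent oracle: linear scan of every peak of every pixel."""
    x0, _, y0, _ = grid.bounds
    out = np.full(grid.shape, np.nan)
    for p in grid.pixels:
        acc = []
        for mz, inten in zip(p.mz, p.intensity):
            if abs(mz - target_mz) <= tolerance:
                acc.append(inten)
        if agg == "sum":
            out[p.y - y0, p.x - x0] = sum(acc)
        else:
            out[p.y - y0, p.x - x0] = max(acc) if acc else 0.0
    return out


@pytest.fixture(scope="session")
def cal_run():
    """One shared default calibration-slide analysis (seed 1)."""
    from msiquant.pipeline import run_calibration_experiment

    return run_calibration_experiment(seed=1)
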