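import numpy as np
import pytest

import colonyscan as cs


@pytest.fixture(scope="session")
def layout96():
    return cs.make_layout(96)


@pytest.fixture(scope="session")
def layout384():
    return cs.make_layout(384)


@pytest.fixture(scope="session")
def layout1536():
    return cs.make_layout(1536)


def exponential_curve(dt_hr=2.0, initial=100.0, t_end=12.0, interval=1.0 / 3.0):
    """Exact exponential growth sampled on a regular grid."""
    t = np.arange(0, t_end + 1e-9, interval)
    return cs.GrowthCurve(times=t, raw=initial * 2.0 ** (t / dt_hr))


@pytest.fixture
def exp_curve():
    return exponential_curve()


def brute_force_min_dt(times, smoothed, window=5):
    """Independent oracle: naive loop over every window, np.polyfit slopes.

    Returns (dt_min, t_center, slope_se) or None when no window has a
    positive slope on positive data.
    """
    best = None
    n = len(times)
    for i in range(n - window + 1):
        t = np.asarray(times[i : i + window], dtype=float)
        y = np.asarray(smoothed[i : i + window], dtype=float)
        if np.any(y <= 0):
            continue
        ly = np.log2(y)
        slope, intercept = np.polyfit(t, ly, 1)
        resid = ly - (slope * t + intercept)
        sxx = np.sum((t - t.mean()) ** 2)
        se = np.sqrt(np.sum(resid**2) / (window - 2) / sxx)
        if best is None or slope > best[0] + 1e-15:
            best = (slope, t[window // 2], se)
    if best is None or best[0] <= 0:
        return None
    return 1.0 / best[0], best[1], best[2]
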