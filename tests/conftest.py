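import numpy as np
import pytest

from rfmonitor import StaLtaConfig, KfConfig, gen_floorplan_fixture


@pytest.fixture(scope="session")
def plan():
    return gen_floorplan_fixture()


@pytest.fixture()
def stalta_config():
    return StaLtaConfig()


@pytest.fixture()
def kf_config():
    return KfConfig()


# ---------------------------------------------------------------------------
# Independent oracles shared by unit and acceptance tests

def oracle_sta_lta(values, T1, T2, eps=1e-6):
    """Brute-force forward/backward windowed means, written independently
    of the implementation: explicit per-sample window bounds."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    sta = np.full(n, np.nan)
    lta = np.full(n, np.nan)
    for t in range(n):
        lo, hi = t + 1, min(n, t + 1 + T1)
        win = values[lo:hi]
        good = win.size - np.count_nonzero(np.isnan(win))
        if good:
            sta[t] = np.nansum(win) / good
        lo, hi = max(0, t - T2 + 1), t + 1
        win = values[lo:hi]
        good = win.size - np.count_nonzero(np.isnan(win))
        if good:
            lta[t] = np.nansum(win) / good
    return sta, lta, sta / np.maximum(lta, eps)


def oracle_segment(sta, ratio, s1, s2, s3, split_gap=None):
    """Hand-traced hysteresis state machine."""
    n = len(sta)
    mask = np.zeros(n, dtype=bool)
    on = False
    run = 0
    run_start = 0
    for t in range(n):
        if np.isnan(sta[t]) or np.isnan(ratio[t]):
            if run == 0:
                run_start = t
            run += 1
            if split_gap is not None and run == split_gap and on:
                mask[run_start:t + 1] = False
                on = False
            else:
                mask[t] = on
            continue
        run = 0
        if not on:
            if sta[t] > s1 and ratio[t] > s2:
                on = True
        else:
            if sta[t] < s3 and ratio[t] < s2:
                on = False
        mask[t] = on
    return mask
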