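import numpy as np
import pandas as pd
import pytest

from breathkit.segmentation import BREATH_COLUMNS


def make_breath_table(
    n=None,
    lengths=None,
    ti=0.18,
    te=None,
    vti=0.2,
    vte=0.2,
    rate=None,
):
    """Build a synthetic breath table directly (no trace, no segmentation).

    Scalars broadcast; ``rate`` (breaths/min) overrides ``lengths``.
    ``te`` defaults to length - ti.
    """
    if rate is not None:
        rate = np.atleast_1d(np.asarray(rate, dtype=float))
        lengths = 60.0 / rate
    if lengths is None:
        lengths = np.full(n, 0.4)
    lengths = np.atleast_1d(np.asarray(lengths, dtype=float))
    m = len(lengths)
    ti = np.broadcast_to(np.asarray(ti, dtype=float), (m,)).copy()
    te_arr = lengths - ti if te is None else np.broadcast_to(np.asarray(te, dtype=float), (m,)).copy()
    onsets = np.concatenate(([0.0], np.cumsum(lengths)[:-1])) if m else np.array([])
    return pd.DataFrame(
        {
            "index": np.arange(m),
            "onset_s": onsets,
            "ti_s": ti,
            "te_s": te_arr,
            "vti_ml": np.broadcast_to(np.asarray(vti, dtype=float), (m,)).copy(),
            "vte_ml": np.broadcast_to(np.asarray(vte, dtype=float), (m,)).copy(),
            "length_s": lengths,
            "rate_bpm": 60.0 / lengths,
        }
    )[list(BREATH_COLUMNS)]


def brute_force_fast_window(rates, window_len, fast_fraction_max, fast_rate):
    """O(n*w) direct enumeration of the sliding-window rate-burst filter.

    Independent oracle for the optimised rolling-count implementation.
    """
    rates = np.asarray(rates, dtype=float)
    n = rates.size
    flagged = np.zeros(n, dtype=bool)
    if n == 0:
        return flagged
    w = min(window_len, n)
    for start in range(n - w + 1):
        window = rates[start : start + w]
        n_fast = int(np.sum(window > fast_rate))
        if n_fast > fast_fraction_max * w:
            flagged[start : start + w] = True
    return flagged


@pytest.fixture
def clean_trace_60s():
    """60 s perfectly regular trace at 150 breaths/min, with ground truth."""
    from breathkit.simulate import SimConfig, simulate_trace

    cfg = SimConfig(duration=60.0, base_rate=150.0, base_tidal_volume=0.2,
                    irregularity=0.0, seed=42)
    return simulate_trace(cfg)
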