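"""Breath segmentation from calibrated flow traces.

Positive flow is inspiration (an ``invert`` flag at ingestion flips rigs
wired the other way).  After low-pass baseline removal, breath onsets are
upward zero-crossings confirmed by a Schmitt trigger with symmetric
hysteresis: an onset is only accepted once the signal has actually swung
below ``-hysteresis`` and back above ``+hysteresis``, so small noise
wiggles around zero do not fragment breaths.  Per breath:

* ``ti``  — duration of the positive-flow segment from onset;
* ``te``  — duration of the following contiguous negative-flow segment;
* ``vti`` — trapezoidal integral of the positive phase (mL);
* ``vte`` — absolute trapezoidal integral of the negative phase (mL);
* ``length`` — onset-to-onset time (includes any end-expiratory pause);
* ``rate``   — 60 / length, breaths/min.

The final breath (no successor onset) is dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from breathkit.errors import ConfigError, InputError

logger = logging.getLogger(__name__)

#: Breath-table columns produced by :func:`segment_breaths`.
BREATH_COLUMNS = (
    "index",
    "onset_s",
    "ti_s",
    "te_s",
    "vti_ml",
    "vte_ml",
    "length_s",
    "rate_bpm",
)


@dataclass(frozen=True)
class Trace:
    """Uniformly sampled calibrated flow signal (mL/s) for one recording."""

    samples: np.ndarray
    sampling_rate: float
    animal_id: str = ""
    t0: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "samples", np.asarray(self.samples, dtype=float))
        if self.sampling_rate <= 0:
            raise InputError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.samples.ndim != 1 or self.samples.size < 2:
            raise InputError("trace needs a 1-D signal with at least 2 samples")
        if not np.all(np.isfinite(self.samples)):
            raise InputError("trace contains non-finite samples")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sampling_rate

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.sampling_rate


@dataclass(frozen=True)
class SegmentationParams:
    """Detector settings.

    ``hysteresis=None`` auto-scales to 5% of the trace's robust amplitude
    (half the central 2.5–97.5% flow range), which is unitless across volume
    calibrations.  ``min_insp_duration`` is a detector floor for rejecting
    sub-sample glitches and is deliberately far below the 0.025 s QC rule so
    that short-inspiration artifacts are still *detected* (and then flagged
    downstream rather than silently missed).  ``baseline_window`` (s) sets
    the time scale of the baseline estimate removed before detection:
    components slower than this are treated as bias-flow offset/drift.
    """

    hysteresis: float | None = None
    min_insp_duration: float = 0.002
    baseline_window: float = 60.0

    def __post_init__(self):
        if self.hysteresis is not None and self.hysteresis < 0:
            raise ConfigError(f"hysteresis must be >= 0, got {self.hysteresis}")
        if self.min_insp_duration < 0:
            raise ConfigError(
                f"min_insp_duration must be >= 0, got {self.min_insp_duration}"
            )
        if self.baseline_window < 0:
            raise ConfigError(
                f"baseline_window must be >= 0, got {self.baseline_window}"
            )


def _remove_baseline(samples: np.ndarray, fs: float, window_s: float) -> np.ndarray:
    """Subtract a slow baseline (bias-flow offset plus drift).

    The baseline is the signal zero-phase low-passed at ``1/window_s`` Hz
    (second-order Butterworth, forward-backward), which removes a constant
    offset exactly and tracks drift slower than ``window_s`` while leaving
    breath-band content (even multi-second expirations) essentially
    untouched.  A median/mean-of-window estimate is deliberately avoided:
    the median of an asymmetric flow waveform is offset from zero and
    windows holding a non-integer number of breaths bias the mean.
    """
    n = samples.size
    if window_s <= 0:  # 0 disables baseline removal (already-centred signals)
        return samples
    sos = signal.butter(2, 1.0 / window_s, btype="low", fs=fs, output="sos")
    padlen = min(n - 1, int(3 * window_s * fs))
    baseline = signal.sosfiltfilt(sos, samples, padlen=padlen)
    return samples - baseline


def _auto_hysteresis(flow: np.ndarray) -> float:
    lo, hi = np.percentile(flow, [2.5, 97.5])
    return 0.05 * (hi - lo) / 2.0


def _cross_times(flow: np.ndarray, idx: np.ndarray, fs: float, t0: float) -> np.ndarray:
    """Sub-sample zero-crossing times for crossings between idx and idx+1."""
    f0 = flow[idx]
    f1 = flow[idx + 1]
    denom = f1 - f0
    frac = np.where(denom != 0, -f0 / np.where(denom == 0, 1.0, denom), 0.0)
    frac = np.clip(frac, 0.0, 1.0)
    return t0 + (idx + frac) / fs


def segment_breaths(trace: Trace, params: SegmentationParams | None = None) -> pd.DataFrame:
    """Segment a trace into a breath table (columns :data:`BREATH_COLUMNS`).

    Returns an empty table (with a logged warning) when fewer than two
    onsets are detected.
    """
    params = params or SegmentationParams()
    fs = trace.sampling_rate
    flow = _remove_baseline(trace.samples, fs, params.baseline_window)

    h = params.hysteresis if params.hysteresis is not None else _auto_hysteresis(flow)

    empty = pd.DataFrame({c: pd.Series(dtype=float) for c in BREATH_COLUMNS})
    if h <= 0 and not np.any(flow != 0):
        logger.warning("constant-zero trace: no breaths detected")
        return empty

    # Schmitt trigger: +1 above +h, -1 below -h, else hold previous state.
    state = np.zeros(flow.size, dtype=np.int8)
    state[flow > h] = 1
    state[flow < -h] = -1
    if not np.any(state):
        logger.warning("signal never exceeds hysteresis threshold %.4g", h)
        return empty
    last = np.maximum.accumulate(np.where(state != 0, np.arange(state.size), -1))
    held = np.where(last >= 0, state[np.maximum(last, 0)], 0).astype(np.int8)
    # onset triggers: first +1 sample of each run that follows a -1 (or start)
    trig = np.flatnonzero((held == 1) & (np.concatenate(([0], held[:-1])) != 1))

    # zero-crossing catalogues on the baseline-corrected signal
    pos = flow > 0
    neg = flow < 0
    up = np.flatnonzero(~pos[:-1] & pos[1:])       # f[i] <= 0 < f[i+1]
    if pos[0]:  # signal starts mid-inspiration: treat sample 0 as an onset
        up = np.concatenate(([0], up))
    down = np.flatnonzero(pos[:-1] & ~pos[1:])     # f[i] > 0 >= f[i+1]
    neg_start = np.flatnonzero(~neg[:-1] & neg[1:])
    neg_end = np.flatnonzero(neg[:-1] & ~neg[1:])

    if up.size == 0 or trig.size == 0:
        logger.warning("fewer than 2 breath onsets detected")
        return empty

    # map each trigger to the upward zero-crossing just before it
    k = np.searchsorted(up, trig, side="right") - 1
    k = k[k >= 0]
    onset_idx = np.unique(up[k])

    # detector floor: drop onsets whose positive segment is shorter than the floor
    if params.min_insp_duration > 0 and onset_idx.size:
        d = np.searchsorted(down, onset_idx, side="right")
        ok = d < down.size
        seg_len = np.full(onset_idx.size, np.inf)
        seg_len[ok] = (down[d[ok]] - onset_idx[ok]) / fs
        onset_idx = onset_idx[seg_len >= params.min_insp_duration]

    if onset_idx.size < 2:
        logger.warning("fewer than 2 breath onsets detected")
        return empty

    onset_t = _cross_times(flow, onset_idx, fs, trace.t0)

    # cumulative integrals of the positive / negative parts (mL)
    dt = 1.0 / fs
    cpos = np.concatenate(([0.0], np.cumsum((np.maximum(flow[:-1], 0) + np.maximum(flow[1:], 0)) * dt / 2)))
    cneg = np.concatenate(([0.0], np.cumsum((np.minimum(flow[:-1], 0) + np.minimum(flow[1:], 0)) * dt / 2)))

    rows = []
    for i in range(onset_idx.size - 1):
        a, nxt = onset_idx[i], onset_idx[i + 1]
        j = np.searchsorted(down, a, side="right")
        if j >= down.size or down[j] >= nxt:
            continue  # no inspiration end before the next onset
        b = down[j]
        ti = float(_cross_times(flow, np.array([b]), fs, trace.t0)[0] - onset_t[i])
        j = np.searchsorted(neg_start, b, side="left")
        if j >= neg_start.size or neg_start[j] >= nxt:
            continue  # no expiratory phase in this breath
        c = neg_start[j]
        j = np.searchsorted(neg_end, c, side="left")
        d = neg_end[j] if j < neg_end.size else nxt
        d = min(d, nxt)
        tc = _cross_times(flow, np.array([c]), fs, trace.t0)[0]
        td = _cross_times(flow, np.array([d]), fs, trace.t0)[0]
        te = float(td - tc)
        if ti <= 0 or te <= 0:
            continue
        vti = float(cpos[b + 1] - cpos[a])
        vte = float(-(cneg[d + 1] - cneg[c]))
        length = float(onset_t[i + 1] - onset_t[i])
        rows.append((i, onset_t[i], ti, te, vti, vte, length, 60.0 / length))

    if not rows:
        logger.warning("no complete breaths detected")
        return empty
    df = pd.DataFrame(rows, columns=list(BREATH_COLUMNS))
    df["index"] = np.arange(len(df))
    return df


def attach_ground_truth(
    table: pd.DataFrame, truth, tolerance: float = 0.01
) -> dict[str, int | float]:
    """Greedy one-to-one matching of detected onsets to true onsets.

    ``tolerance`` is the maximum |onset difference| (s) for a match.
    Returns hits / misses (true breaths unmatched) / spurious (detections
    unmatched) counts and the hit rate.
    """
    det = np.sort(np.asarray(table["onset_s"], dtype=float)) if len(table) else np.array([])
    true_onsets = np.sort(truth.breaths["onset_s"].to_numpy())
    hits = 0
    i = j = 0
    while i < det.size and j < true_onsets.size:
        d = det[i] - true_onsets[j]
        if abs(d) <= tolerance:
            hits += 1
            i += 1
            j += 1
        elif d < 0:
            i += 1
        else:
            j += 1
    return {
        "hits": hits,
        "misses": int(true_onsets.size - hits),
        "spurious": int(det.size - hits),
        "n_true": int(true_onsets.size),
        "n_detected": int(det.size),
        "hit_rate": hits / true_onsets.size if true_onsets.size else float("nan"),
    }
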