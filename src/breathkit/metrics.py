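"""Per-animal respiratory summary metrics.

Frequency is the mean instantaneous rate (60/length) over reliable breaths;
tidal volume is the mean inspired volume; minute ventilation is their
product (exact by construction).  IBII for a pair of breaths n, n+1 is
|L(n+1) - L(n)| / L(n); pairs are only formed between breaths that were
consecutive in the original recording and both survived QC — exclusions
break the chain, they are never bridged.
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd

from breathkit.qc import QCReport


@dataclass
class AnimalSummary:
    animal_id: str
    n_reliable: int
    frequency: float          # breaths/min
    tidal_volume: float       # mL
    minute_ventilation: float  # mL/min
    ibii_mean: float
    ibii_n_pairs: int
    animal_excluded: bool

    def to_dict(self) -> dict:
        return asdict(self)


def ibii_series(table: pd.DataFrame) -> np.ndarray:
    """IBII values over originally-consecutive pairs of reliable breaths.

    ``table`` must carry the original breath ``index`` column (as produced
    by segmentation and preserved through QC).  Returns an empty array when
    fewer than two eligible pairs exist.
    """
    if len(table) < 2:
        return np.array([])
    idx = table["index"].to_numpy()
    lengths = table["length_s"].to_numpy(dtype=float)
    consecutive = np.diff(idx) == 1
    if not np.any(consecutive):
        return np.array([])
    return np.abs(np.diff(lengths))[consecutive] / lengths[:-1][consecutive]


def summarize_animal(
    table: pd.DataFrame,
    report: QCReport | None = None,
    frequency_method: str = "mean_instantaneous",
) -> AnimalSummary:
    """Summarise a reliable breath table into an :class:`AnimalSummary`.

    ``frequency_method``: ``"mean_instantaneous"`` (default) averages the
    per-breath rates 60/length; ``"per_time"`` divides the breath count by
    the total reliable breath time.  When the animal is excluded (too few
    reliable breaths, per the report) every metric is emitted as NaN.
    """
    animal_id = report.animal_id if report is not None else ""
    n = int(len(table))
    excluded = report.animal_excluded if report is not None else n == 0
    if excluded or n == 0:
        return AnimalSummary(
            animal_id=animal_id,
            n_reliable=n,
            frequency=math.nan,
            tidal_volume=math.nan,
            minute_ventilation=math.nan,
            ibii_mean=math.nan,
            ibii_n_pairs=0,
            animal_excluded=True,
        )
    lengths = table["length_s"].to_numpy(dtype=float)
    if frequency_method == "mean_instantaneous":
        frequency = float(np.mean(60.0 / lengths))
    elif frequency_method == "per_time":
        frequency = float(60.0 * n / lengths.sum())
    else:
        raise ValueError(f"unknown frequency_method {frequency_method!r}")
    tidal_volume = float(table["vti_ml"].mean())
    ibii = ibii_series(table)
    return AnimalSummary(
        animal_id=animal_id,
        n_reliable=n,
        frequency=frequency,
        tidal_volume=tidal_volume,
        minute_ventilation=frequency * tidal_volume,
        ibii_mean=float(np.mean(ibii)) if ibii.size else math.nan,
        ibii_n_pairs=int(ibii.size),
        animal_excluded=False,
    )
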