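"""Plain-text readers and writers.

Trace files are two-column delimited text with header ``time_s,flow_ml_s``;
breath tables, ground truth, metadata, and summaries are TSV.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from breathkit.errors import InputError
from breathkit.segmentation import Trace
from breathkit.simulate import GroundTruth, TRUTH_COLUMNS

logger = logging.getLogger(__name__)

TRACE_HEADER = ("time_s", "flow_ml_s")
METADATA_COLUMNS = ("animal_id", "genotype", "age_group", "trace_path")

#: successive time steps may deviate from the median by at most this
#: fraction before the trace is resampled onto a uniform grid
UNIFORMITY_TOL = 0.01
#: a step larger than this multiple of the median step is a hard error
GAP_FACTOR = 5.0


def write_trace(trace: Trace, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame({"time_s": trace.times, "flow_ml_s": trace.samples})
    df.to_csv(path, index=False, float_format="%.9g")
    return path


def read_trace_file(
    path: str | Path,
    invert: bool = False,
    animal_id: str | None = None,
    delimiter: str = ",",
) -> Trace:
    """Read a two-column time/flow text file into a :class:`Trace`.

    Verifies uniform sampling (mild jitter is resampled onto the median
    step with a warning; a gap larger than ``GAP_FACTOR`` times the median
    step is an error naming the offending line).  ``invert`` flips flow
    polarity for rigs where inspiration is recorded as negative flow.
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"trace file not found: {path}")
    try:
        df = pd.read_csv(path, sep=delimiter)
    except Exception as exc:
        raise InputError(f"could not parse {path}: {exc}") from exc
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected two columns (time, flow)")
    if len(df) < 2:
        raise InputError(f"{path}: fewer than 2 samples")
    try:
        t = df.iloc[:, 0].astype(float).to_numpy()
        flow = df.iloc[:, 1].astype(float).to_numpy()
    except (TypeError, ValueError) as exc:
        raise InputError(f"{path}: non-numeric data: {exc}") from exc
    if np.isnan(t).any() or np.isnan(flow).any():
        bad = int(np.flatnonzero(np.isnan(t) | np.isnan(flow))[0])
        raise InputError(f"{path}: missing value at line {bad + 2}")
    dt = np.diff(t)
    if np.any(dt <= 0):
        bad = int(np.flatnonzero(dt <= 0)[0])
        raise InputError(f"{path}: non-monotone time at line {bad + 2}")
    med = float(np.median(dt))
    if np.any(dt > GAP_FACTOR * med):
        bad = int(np.argmax(dt > GAP_FACTOR * med))
        raise InputError(
            f"{path}: sampling gap of {dt[bad]:.6g} s at line {bad + 2} "
            f"(median step {med:.6g} s)"
        )
    if np.max(np.abs(dt - med)) > UNIFORMITY_TOL * med:
        logger.warning("%s: non-uniform sampling; resampling to %.6g s step", path, med)
        grid = np.arange(t[0], t[-1] + med / 2, med)
        flow = np.interp(grid, t, flow)
        t = grid
    if invert:
        flow = -flow
    return Trace(
        samples=flow,
        sampling_rate=1.0 / med,
        animal_id=animal_id if animal_id is not None else path.stem,
        t0=float(t[0]),
    )


def write_breath_table(table: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    table.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_breath_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise InputError(f"breath table not found: {path}")
    df = pd.read_csv(path, sep="\t")
    if "index" not in df.columns:
        raise InputError(f"{path}: not a breath table (no 'index' column)")
    return df


def write_ground_truth(truth: GroundTruth, path: str | Path) -> Path:
    path = Path(path)
    truth.breaths.to_csv(path, sep="\t", index=False, float_format="%.9g")
    return path


def read_ground_truth(path: str | Path) -> GroundTruth:
    df = pd.read_csv(Path(path), sep="\t")
    df["artifact_kind"] = df["artifact_kind"].fillna("")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing ground-truth columns {sorted(missing)}")
    return GroundTruth(breaths=df)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read the cohort metadata TSV (animal_id, genotype, age_group, trace_path)."""
    path = Path(path)
    if not path.exists():
        raise InputError(f"metadata file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise InputError(f"{path}: missing metadata columns {sorted(missing)}")
    if df["animal_id"].duplicated().any():
        dup = df.loc[df["animal_id"].duplicated(), "animal_id"].iloc[0]
        raise InputError(f"{path}: duplicate animal_id {dup!r}")
    return df
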