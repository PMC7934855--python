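"""Artifact-rejection cascade and animal-level reliability rule.

Two stages, applied in order:

1. Per-breath rules (each comparison strict): inspiratory time *under*
   ``ti_min`` (default 0.025 s), expiratory time *over* ``te_max`` (default
   10 s), or expiratory tidal volume *more than* ``vte_vti_ratio_max``
   (default 2) times the inspiratory tidal volume.
2. A sliding window of ``window_len`` breaths (default 200, step 1) over
   the breaths that survived stage 1; a window is rejected when *more than*
   ``fast_fraction_max`` (default 10%) of its breaths have an instantaneous
   rate *faster than* ``fast_rate`` (default 600 breaths/min), and every
   breath covered by a rejected window is excluded.  Sequences shorter than
   one window are evaluated as a single window.

Animals with fewer than ``min_reliable_breaths`` (default 100) surviving
breaths are marked excluded at the report level.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from breathkit.errors import ConfigError

QC_FLAG_COLUMNS = (
    "artifact_ti",
    "artifact_te",
    "artifact_ratio",
    "in_fast_window",
    "reliable",
    "exclusion_reason",
)


@dataclass(frozen=True)
class QCConfig:
    """Thresholds of the rejection cascade (defaults are the published ones).

    ``window_stage`` and ``window_mode`` expose the two readings of the
    window rule that the published description leaves open: whether the
    window runs after the per-breath rules (default) or before them, and
    whether a rejected window excludes all of its breaths ("interval",
    default) or only its fast breaths ("fast_only").
    """

    ti_min: float = 0.025
    te_max: float = 10.0
    vte_vti_ratio_max: float = 2.0
    window_len: int = 200
    fast_fraction_max: float = 0.10
    fast_rate: float = 600.0
    min_reliable_breaths: int = 100
    window_stage: Literal["after_per_breath", "before_per_breath"] = "after_per_breath"
    window_mode: Literal["interval", "fast_only"] = "interval"

    def __post_init__(self):
        for name in ("ti_min", "te_max", "vte_vti_ratio_max", "fast_rate"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0, got {getattr(self, name)}")
        if not 0 < self.fast_fraction_max < 1:
            raise ConfigError(
                f"fast_fraction_max must be in (0, 1), got {self.fast_fraction_max}"
            )
        if self.window_len < 1:
            raise ConfigError(f"window_len must be >= 1, got {self.window_len}")
        if self.min_reliable_breaths < 1:
            raise ConfigError(
                f"min_reliable_breaths must be >= 1, got {self.min_reliable_breaths}"
            )
        if self.window_stage not in ("after_per_breath", "before_per_breath"):
            raise ConfigError(f"unknown window_stage {self.window_stage!r}")
        if self.window_mode not in ("interval", "fast_only"):
            raise ConfigError(f"unknown window_mode {self.window_mode!r}")


@dataclass
class QCReport:
    """Per-animal accounting of the rejection cascade."""

    animal_id: str = ""
    n_input: int = 0
    n_artifact_ti: int = 0
    n_artifact_te: int = 0
    n_artifact_ratio: int = 0
    n_fast_window: int = 0
    n_reliable: int = 0
    animal_excluded: bool = True
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def flag_artifact_breaths(table: pd.DataFrame, cfg: QCConfig | None = None) -> pd.DataFrame:
    """Set the three per-breath artifact flags; all comparisons strict.

    A breath with ``vti == 0`` but ``vte > 0`` fails the ratio rule (the
    ratio is unbounded); one with both volumes zero passes it.
    """
    cfg = cfg or QCConfig()
    out = table.copy()
    ti = out["ti_s"].to_numpy(dtype=float)
    te = out["te_s"].to_numpy(dtype=float)
    vti = out["vti_ml"].to_numpy(dtype=float)
    vte = out["vte_ml"].to_numpy(dtype=float)
    out["artifact_ti"] = ti < cfg.ti_min
    out["artifact_te"] = te > cfg.te_max
    out["artifact_ratio"] = vte > cfg.vte_vti_ratio_max * vti
    return out


def _bad_window_breaths(fast: np.ndarray, window_len: int, max_fraction: float) -> np.ndarray:
    """Boolean mask of positions covered by >= 1 rejected window.

    Rolling-sum implementation; the brute-force equivalent enumerates every
    window directly (kept in the test suite as the oracle).
    """
    n = fast.size
    flagged = np.zeros(n, dtype=bool)
    if n == 0:
        return flagged
    w = min(window_len, n)
    c = np.concatenate(([0], np.cumsum(fast.astype(np.int64))))
    counts = c[w:] - c[:-w]  # counts[k] = fast breaths in window [k, k+w)
    bad = counts > max_fraction * w
    if not np.any(bad):
        return flagged
    # mark coverage with a difference array
    diff = np.zeros(n + 1, dtype=np.int64)
    starts = np.flatnonzero(bad)
    np.add.at(diff, starts, 1)
    np.add.at(diff, starts + w, -1)
    return np.cumsum(diff[:-1]) > 0


def flag_fast_windows(table: pd.DataFrame, cfg: QCConfig | None = None) -> pd.DataFrame:
    """Apply the sliding-window rate-burst filter.

    Expects the per-breath flags to be present when
    ``window_stage == "after_per_breath"``: the window slides over the
    sub-sequence of breaths passing those rules, and only those can receive
    ``in_fast_window``.
    """
    cfg = cfg or QCConfig()
    out = table.copy()
    out["in_fast_window"] = False
    if len(out) == 0:
        return out
    if cfg.window_stage == "after_per_breath":
        flag_cols = ["artifact_ti", "artifact_te", "artifact_ratio"]
        present = [c for c in flag_cols if c in out.columns]
        eligible = ~out[present].any(axis=1) if present else pd.Series(True, index=out.index)
    else:
        eligible = pd.Series(True, index=out.index)
    sub = out.loc[eligible]
    fast = sub["rate_bpm"].to_numpy(dtype=float) > cfg.fast_rate
    covered = _bad_window_breaths(fast, cfg.window_len, cfg.fast_fraction_max)
    if cfg.window_mode == "fast_only":
        covered = covered & fast
    out.loc[sub.index[covered], "in_fast_window"] = True
    return out


def qc_annotate(table: pd.DataFrame, cfg: QCConfig | None = None) -> pd.DataFrame:
    """Run both flagging stages; returns the full table with all QC columns."""
    cfg = cfg or QCConfig()
    flagged = flag_artifact_breaths(table, cfg)
    flagged = flag_fast_windows(flagged, cfg)
    fail = flagged[["artifact_ti", "artifact_te", "artifact_ratio", "in_fast_window"]]
    flagged["reliable"] = ~fail.any(axis=1)
    reasons = np.select(
        [
            flagged["artifact_ti"],
            flagged["artifact_te"],
            flagged["artifact_ratio"],
            flagged["in_fast_window"],
        ],
        ["ti_under_min", "te_over_max", "vte_vti_ratio", "fast_window"],
        default="",
    )
    flagged["exclusion_reason"] = reasons
    return flagged


def apply_qc(
    table: pd.DataFrame, cfg: QCConfig | None = None, animal_id: str = ""
) -> tuple[pd.DataFrame, QCReport]:
    """Run both stages and split reliable breaths from excluded ones.

    Returns the reliable sub-table (positionally re-indexed, original
    ``index`` and ``onset_s`` retained) and a :class:`QCReport`.  Animal
    exclusion (fewer than ``min_reliable_breaths`` reliable breaths) is a
    report field, never an exception.
    """
    cfg = cfg or QCConfig()
    flagged = qc_annotate(table, cfg)
    reliable = flagged[flagged["reliable"]].reset_index(drop=True)
    report = QCReport(
        animal_id=animal_id,
        n_input=int(len(flagged)),
        n_artifact_ti=int(flagged["artifact_ti"].sum()),
        n_artifact_te=int(flagged["artifact_te"].sum()),
        n_artifact_ratio=int(flagged["artifact_ratio"].sum()),
        n_fast_window=int(flagged["in_fast_window"].sum()),
        n_reliable=int(len(reliable)),
        animal_excluded=bool(len(reliable) < cfg.min_reliable_breaths),
        config=asdict(cfg),
    )
    return reliable, report
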