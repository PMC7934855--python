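"""Pipeline orchestration and group comparison.

``run_pipeline`` composes segment -> qc -> summarize for one trace;
``build_cohort`` assembles per-animal summaries with genotype/age labels;
``compare_groups`` runs a one-way fixed-effects ANOVA across genotype
groups (excluded animals are retained in the table but never contribute to
statistics).  The 0.05 significance threshold is reported alongside the
p value, never used to filter data.  No multiple-testing correction is
applied across metrics.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from breathkit.errors import InputError
from breathkit.metrics import AnimalSummary, summarize_animal
from breathkit.qc import QCConfig, QCReport, apply_qc, qc_annotate
from breathkit.segmentation import SegmentationParams, Trace, segment_breaths

logger = logging.getLogger(__name__)

RESPIRATORY_METRICS = ("frequency", "tidal_volume", "minute_ventilation", "ibii_mean")

SIGNIFICANCE_LEVEL = 0.05


@dataclass
class GroupComparison:
    """One-way ANOVA of one metric across genotype groups."""

    metric: str
    groups: dict[str, dict[str, float]]  # name -> {n, mean, sem}
    f_statistic: float
    p_value: float
    alpha: float = SIGNIFICANCE_LEVEL

    @property
    def significant(self) -> bool:
        return bool(self.p_value < self.alpha)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["significant"] = self.significant
        return d


def run_pipeline(
    trace: Trace,
    seg_params: SegmentationParams | None = None,
    qc_config: QCConfig | None = None,
) -> tuple[pd.DataFrame, QCReport, AnimalSummary]:
    """segment -> qc -> summarize for a single animal.

    Returns the fully QC-annotated breath table (all breaths, with flags),
    the QC report, and the animal summary.  Deterministic for fixed inputs.
    """
    qc_config = qc_config or QCConfig()
    table = segment_breaths(trace, seg_params)
    annotated = qc_annotate(table, qc_config)
    reliable, report = apply_qc(table, qc_config, animal_id=trace.animal_id)
    summary = summarize_animal(reliable, report)
    logger.info(
        "pipeline %s: %d breaths, %d reliable, excluded=%s",
        trace.animal_id, report.n_input, report.n_reliable, report.animal_excluded,
    )
    return annotated, report, summary


def build_cohort(rows: list[tuple[str, str, str, AnimalSummary]]) -> pd.DataFrame:
    """Assemble (animal_id, genotype, age_group, summary) rows into a table."""
    records = []
    for animal_id, genotype, age_group, summary in rows:
        rec = {"animal_id": animal_id, "genotype": genotype, "age_group": age_group}
        rec.update(summary.to_dict())
        rec.pop("animal_id", None)
        rec["animal_id"] = animal_id
        records.append(rec)
    df = pd.DataFrame(records)
    if df["animal_id"].duplicated().any():
        raise InputError("duplicate animal_id in cohort")
    cols = ["animal_id", "genotype", "age_group"] + [
        c for c in df.columns if c not in ("animal_id", "genotype", "age_group")
    ]
    return df[cols]


def compare_groups(
    cohort: pd.DataFrame,
    metric: str,
    group_col: str = "genotype",
    min_group_size: int = 2,
) -> GroupComparison:
    """One-way fixed-effects ANOVA of ``metric`` across ``group_col`` groups.

    Excluded animals are dropped before computing anything.  Requires at
    least two groups with ``min_group_size`` non-excluded animals each.
    """
    if metric not in cohort.columns:
        raise InputError(f"unknown metric {metric!r}")
    usable = cohort[~cohort["animal_excluded"].astype(bool)]
    usable = usable[np.isfinite(usable[metric].astype(float))]
    samples = {
        name: grp[metric].astype(float).to_numpy()
        for name, grp in usable.groupby(group_col, sort=True)
    }
    samples = {k: v for k, v in samples.items() if v.size >= min_group_size}
    if len(samples) < 2:
        raise InputError(
            f"need >= 2 groups with >= {min_group_size} non-excluded animals "
            f"each for metric {metric!r}"
        )
    f_stat, p_value = stats.f_oneway(*samples.values())
    groups = {
        name: {
            "n": int(v.size),
            "mean": float(np.mean(v)),
            "sem": float(stats.sem(v)) if v.size > 1 else float("nan"),
        }
        for name, v in samples.items()
    }
    return GroupComparison(
        metric=metric,
        groups=groups,
        f_statistic=float(f_stat),
        p_value=float(p_value),
    )


def compare_all_metrics(
    cohort: pd.DataFrame, group_col: str = "genotype"
) -> list[GroupComparison]:
    """Run :func:`compare_groups` for every respiratory metric available."""
    out = []
    for metric in RESPIRATORY_METRICS:
        try:
            out.append(compare_groups(cohort, metric, group_col=group_col))
        except InputError as exc:
            logger.warning("skipping %s: %s", metric, exc)
    return out


def comparisons_to_frame(comparisons: list[GroupComparison]) -> pd.DataFrame:
    """Flatten GroupComparison rows into a TSV-friendly table."""
    rows = []
    for c in comparisons:
        for name, g in c.groups.items():
            rows.append(
                {
                    "metric": c.metric,
                    "group": name,
                    "n": g["n"],
                    "mean": g["mean"],
                    "sem": g["sem"],
                    "F": c.f_statistic,
                    "p": c.p_value,
                    "alpha": c.alpha,
                    "significant": c.significant,
                }
            )
    return pd.DataFrame(rows)
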