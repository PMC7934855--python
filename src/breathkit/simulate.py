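"""Synthetic plethysmography traces with known breath schedules.

Breaths are rendered as a positive half-sine (inspiration) followed by a
negative half-sine (expiration); the half-wave amplitude is set analytically
so the time-integral equals the scheduled volume.  Breath lengths carry
i.i.d. lognormal multiplicative jitter whose width is calibrated in closed
form so the clean schedule's mean interbreath-interval irregularity (IBII)
hits a requested target.  Four artifact kinds can be injected at Poisson
rates: sniff bursts (runs of fast shallow breaths), prolonged expirations,
volume-asymmetric breaths, and movement spikes (very short, large-amplitude
inspirations).  Every breath — artifact or not — is recorded in the emitted
ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import ndtr

from breathkit.errors import ConfigError

ARTIFACT_KINDS = ("sniff_burst", "long_expiration", "asymmetric_volume", "movement_spike")

#: Ground-truth table columns (one row per scheduled breath).
TRUTH_COLUMNS = (
    "onset_s",
    "ti_s",
    "te_s",
    "vti_ml",
    "vte_ml",
    "length_s",
    "is_artifact",
    "artifact_kind",
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one simulated recording session.

    Volumes are mL, flows mL/s, rates breaths/min.  ``irregularity`` is the
    target mean IBII of the clean (artifact-free) breath schedule.
    """

    duration: float = 1800.0
    sampling_rate: float = 1000.0
    base_rate: float = 180.0
    base_tidal_volume: float = 0.20
    irregularity: float = 0.10
    insp_fraction: float = 0.45
    baseline_offset: float = 0.0
    noise_sd: float = 0.0
    artifact_rates: Mapping[str, float] = field(default_factory=dict)
    artifact_params: Mapping[str, float] = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if not self.duration > 0:
            raise ConfigError(f"duration must be > 0, got {self.duration}")
        if not self.sampling_rate > 0:
            raise ConfigError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not self.base_rate > 0:
            raise ConfigError(f"base_rate must be > 0, got {self.base_rate}")
        if not self.base_tidal_volume > 0:
            raise ConfigError(
                f"base_tidal_volume must be > 0, got {self.base_tidal_volume}"
            )
        if not self.irregularity >= 0:
            raise ConfigError(f"irregularity must be >= 0, got {self.irregularity}")
        if not 0 < self.insp_fraction < 1:
            raise ConfigError(
                f"insp_fraction must be in (0, 1), got {self.insp_fraction}"
            )
        if self.noise_sd < 0:
            raise ConfigError(f"noise_sd must be >= 0, got {self.noise_sd}")
        for kind, rate in self.artifact_rates.items():
            if kind not in ARTIFACT_KINDS:
                raise ConfigError(f"unknown artifact kind {kind!r}")
            if rate < 0:
                raise ConfigError(f"artifact_rates[{kind!r}] must be >= 0, got {rate}")
        for key in self.artifact_params:
            if key not in DEFAULT_ARTIFACT_PARAMS:
                raise ConfigError(f"unknown artifact parameter {key!r}")


#: Magnitude settings for injected artifacts (overridable via
#: ``SimConfig.artifact_params``).
DEFAULT_ARTIFACT_PARAMS = {
    "sniff_rate_bpm": 700.0,   # instantaneous rate within a sniff burst
    "sniff_len_breaths": 30.0,  # breaths per burst
    "sniff_vt_scale": 0.3,     # sniff tidal volume relative to base
    "long_te_s": 15.0,         # expiratory duration of a long-expiration breath
    "long_exp_amp_rel": 0.15,  # its expiratory peak flow relative to nominal
                               # (kept small: the excess exhaled volume shifts
                               # the local baseline estimate around the event)
    "asym_vte_vti_ratio": 3.0,  # Vte/Vti of a volume-asymmetric breath
    "spike_amp_rel": 5.0,      # spike peak flow relative to nominal peak flow
    "spike_ti_s": 0.015,       # inspiratory duration of a movement spike
}


@dataclass(frozen=True)
class GroundTruth:
    """True breath schedule emitted alongside a synthetic trace."""

    breaths: pd.DataFrame  # columns TRUTH_COLUMNS, ordered by onset

    @property
    def n_breaths(self) -> int:
        return len(self.breaths)

    def clean(self) -> pd.DataFrame:
        """Rows for non-artifact breaths."""
        return self.breaths[~self.breaths["is_artifact"]]

    def mean_ibii(self, clean_only: bool = True) -> float:
        """Mean IBII of the scheduled breath-length series."""
        df = self.clean() if clean_only else self.breaths
        lengths = df["length_s"].to_numpy()
        if len(lengths) < 2:
            return float("nan")
        return float(np.mean(np.abs(np.diff(lengths)) / lengths[:-1]))

    def to_breath_table(self) -> pd.DataFrame:
        """Recast the schedule as a breath table (oracle for the analysis
        stages, bypassing waveform rendering and segmentation)."""
        df = self.breaths
        return pd.DataFrame(
            {
                "index": np.arange(len(df)),
                "onset_s": df["onset_s"].to_numpy(),
                "ti_s": df["ti_s"].to_numpy(),
                "te_s": df["te_s"].to_numpy(),
                "vti_ml": df["vti_ml"].to_numpy(),
                "vte_ml": df["vte_ml"].to_numpy(),
                "length_s": df["length_s"].to_numpy(),
                "rate_bpm": 60.0 / df["length_s"].to_numpy(),
            }
        )


@dataclass(frozen=True)
class PhenotypePreset:
    """Named partial SimConfig encoding a breathing phenotype."""

    name: str
    base_rate: float
    base_tidal_volume: float
    irregularity: float

    def apply(self, config: SimConfig) -> SimConfig:
        return replace(
            config,
            base_rate=self.base_rate,
            base_tidal_volume=self.base_tidal_volume,
            irregularity=self.irregularity,
        )


# Absolute values are implementer-chosen (no published numeric baselines);
# only the qualitative orderings are constrained: mutants breathe shallower
# than WT, early mutants compensate with faster breathing, late mutants
# cannot increase rate further, and rescued animals breathe faster than
# late mutants.
PRESETS: dict[str, PhenotypePreset] = {
    "WT": PhenotypePreset("WT", base_rate=180.0, base_tidal_volume=0.20, irregularity=0.10),
    "SCA1_6mo": PhenotypePreset("SCA1_6mo", base_rate=250.0, base_tidal_volume=0.15, irregularity=0.15),
    "SCA1_late": PhenotypePreset("SCA1_late", base_rate=250.0, base_tidal_volume=0.12, irregularity=0.20),
    "SCA1_rescued_late": PhenotypePreset("SCA1_rescued_late", base_rate=270.0, base_tidal_volume=0.14, irregularity=0.15),
}


def mean_ibii_for_sigma(sigma: float) -> float:
    """Expected mean IBII of a schedule with lognormal jitter width ``sigma``.

    With lengths L_n = T * X_n, X_n = exp(sigma * Z_n + sigma**2 / 2)
    (normalised so E[1/X] = 1, keeping the mean instantaneous rate unbiased),
    the ratio X_{n+1}/X_n is lognormal(0, sigma*sqrt(2)) and
    E|ratio - 1| = exp(sigma**2) * (2 * Phi(sigma*sqrt(2)) - 1).
    """
    return float(np.exp(sigma**2) * (2.0 * ndtr(sigma * np.sqrt(2.0)) - 1.0))


def sigma_for_mean_ibii(target: float) -> float:
    """Invert :func:`mean_ibii_for_sigma` (target >= 0)."""
    if target < 0:
        raise ConfigError(f"irregularity must be >= 0, got {target}")
    if target == 0:
        return 0.0
    hi = 0.5
    while mean_ibii_for_sigma(hi) < target:
        hi *= 2.0
        if hi > 64:  # pragma: no cover - unreachably large target
            raise ConfigError(f"irregularity target {target} out of range")
    return float(brentq(lambda s: mean_ibii_for_sigma(s) - target, 0.0, hi, xtol=1e-12))


def _artifact_param(config: SimConfig, key: str) -> float:
    return float(config.artifact_params.get(key, DEFAULT_ARTIFACT_PARAMS[key]))


def _build_schedule(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the breath-by-breath schedule (no waveform rendering)."""
    period = 60.0 / config.base_rate
    sigma = sigma_for_mean_ibii(config.irregularity)
    params = {k: _artifact_param(config, k) for k in DEFAULT_ARTIFACT_PARAMS}

    # Poisson event schedule per artifact kind, ordered by time.
    events: list[tuple[float, str]] = []
    minutes = config.duration / 60.0
    for kind in ARTIFACT_KINDS:
        rate = float(config.artifact_rates.get(kind, 0.0))
        if rate <= 0:
            continue
        n_events = rng.poisson(rate * minutes)
        for t_event in np.sort(rng.uniform(0.0, config.duration, size=n_events)):
            events.append((float(t_event), kind))
    events.sort()

    if not events:
        # vectorised fast path for clean schedules
        est = int(np.ceil(config.duration / period)) + 16
        while True:
            if sigma > 0:
                jit = np.exp(sigma * rng.standard_normal(est) + sigma**2 / 2.0)
            else:
                jit = np.ones(est)
            lengths = period * jit
            onsets = np.concatenate(([0.0], np.cumsum(lengths)[:-1]))
            keep = onsets + lengths <= config.duration
            if not keep[-1]:  # schedule long enough to cover the recording
                break
            est *= 2  # pragma: no cover - extremely unlucky jitter draw
        lengths = lengths[keep]
        onsets = onsets[keep]
        ti = config.insp_fraction * lengths
        return pd.DataFrame(
            {
                "onset_s": onsets,
                "ti_s": ti,
                "te_s": lengths - ti,
                "vti_ml": config.base_tidal_volume,
                "vte_ml": config.base_tidal_volume,
                "length_s": lengths,
                "is_artifact": False,
                "artifact_kind": "",
            }
        )

    rows: list[tuple] = []
    t = 0.0
    ev = 0

    def clean_breath_params() -> tuple[float, float, float, float, float]:
        if sigma > 0:
            jitter = float(np.exp(sigma * rng.standard_normal() + sigma**2 / 2.0))
        else:
            jitter = 1.0
        length = period * jitter
        ti = config.insp_fraction * length
        te = length - ti
        return length, ti, te, config.base_tidal_volume, config.base_tidal_volume

    while True:
        if ev < len(events) and t >= events[ev][0]:
            kind = events[ev][1]
            ev += 1
            if kind == "sniff_burst":
                burst_len = int(round(params["sniff_len_breaths"]))
                burst_period = 60.0 / params["sniff_rate_bpm"]
                vt = config.base_tidal_volume * params["sniff_vt_scale"]
                for _ in range(burst_len):
                    if t + burst_period > config.duration:
                        break
                    ti = config.insp_fraction * burst_period
                    te = burst_period - ti
                    rows.append((t, ti, te, vt, vt, burst_period, True, kind))
                    t += burst_period
            elif kind == "long_expiration":
                _, ti, te_nominal, vti, _ = clean_breath_params()
                te = params["long_te_s"]
                length = ti + te
                if t + length > config.duration:
                    continue
                # expiratory amplitude must stay detectable over the long
                # phase, so the expired volume follows from the amplitude
                nominal_amp_e = np.pi * config.base_tidal_volume / (2.0 * te_nominal)
                amp = params["long_exp_amp_rel"] * nominal_amp_e
                vte = amp * 2.0 * te / np.pi
                rows.append((t, ti, te, vti, vte, length, True, kind))
                t += length
            elif kind == "asymmetric_volume":
                length, ti, te, vti, _ = clean_breath_params()
                if t + length > config.duration:
                    continue
                vte = vti * params["asym_vte_vti_ratio"]
                rows.append((t, ti, te, vti, vte, length, True, kind))
                t += length
            else:  # movement_spike
                length, _, _, _, _ = clean_breath_params()
                if t + length > config.duration:
                    continue
                # sharp symmetric up-down transient, then a pause: steep
                # edges keep the measured ti/te robust to baseline offset
                ti = min(params["spike_ti_s"], 0.4 * length)
                te = ti
                nominal_ti = config.insp_fraction * period
                nominal_peak = np.pi * config.base_tidal_volume / (2.0 * nominal_ti)
                amp = params["spike_amp_rel"] * nominal_peak
                vti = amp * 2.0 * ti / np.pi
                rows.append((t, ti, te, vti, vti, length, True, kind))
                t += length
            continue
        length, ti, te, vti, vte = clean_breath_params()
        if t + length > config.duration:
            break
        rows.append((t, ti, te, vti, vte, length, False, ""))
        t += length

    df = pd.DataFrame(rows, columns=list(TRUTH_COLUMNS))
    return df


def _render(schedule: pd.DataFrame, config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Render the schedule into uniformly sampled flow (mL/s), vectorised."""
    n = int(round(config.duration * config.sampling_rate))
    t = np.arange(n) / config.sampling_rate
    flow = np.zeros(n)
    if len(schedule):
        onsets = schedule["onset_s"].to_numpy()
        ti = schedule["ti_s"].to_numpy()
        te = schedule["te_s"].to_numpy()
        amp_i = np.pi * schedule["vti_ml"].to_numpy() / (2.0 * ti)
        amp_e = np.pi * schedule["vte_ml"].to_numpy() / (2.0 * te)
        idx = np.searchsorted(onsets, t, side="right") - 1
        idx_c = np.clip(idx, 0, None)
        tau = t - onsets[idx_c]
        in_insp = (idx >= 0) & (tau < ti[idx_c])
        in_exp = (idx >= 0) & ~in_insp & (tau < ti[idx_c] + te[idx_c])
        flow[in_insp] = amp_i[idx_c[in_insp]] * np.sin(
            np.pi * tau[in_insp] / ti[idx_c[in_insp]]
        )
        k = idx_c[in_exp]
        flow[in_exp] = -amp_e[k] * np.sin(np.pi * (tau[in_exp] - ti[k]) / te[k])
    if config.baseline_offset:
        flow = flow + config.baseline_offset
    if config.noise_sd > 0:
        flow = flow + config.noise_sd * rng.standard_normal(n)
    return flow


def simulate_trace(config: SimConfig):
    """Simulate one recording; returns ``(Trace, GroundTruth)``.

    Deterministic: identical config (including seed) gives bit-identical
    samples and schedule.
    """
    from breathkit.segmentation import Trace  # local import avoids a cycle

    config.validate()
    rng = np.random.default_rng(config.seed)
    schedule = _build_schedule(config, rng)
    samples = _render(schedule, config, rng)
    trace = Trace(samples=samples, sampling_rate=config.sampling_rate, animal_id="sim")
    return trace, GroundTruth(breaths=schedule)


def simulate_cohort(
    preset_counts: Mapping[str, int],
    base_config: SimConfig | None = None,
    seed: int = 0,
) -> list[tuple[str, str, "object", GroundTruth]]:
    """Simulate ``n`` animals per phenotype preset.

    Per-animal seeds are derived as ``default_rng([seed, i])`` with ``i`` a
    global animal counter over the preset list in insertion order, so each
    animal's stream is independent of cohort composition changes downstream
    of it.  Returns ``[(animal_id, genotype, Trace, GroundTruth), ...]``.
    """
    if not preset_counts:
        raise ConfigError("preset_counts must name at least one preset")
    base = base_config if base_config is not None else SimConfig()
    out = []
    counter = 0
    for name, n_animals in preset_counts.items():
        if name not in PRESETS:
            raise ConfigError(f"unknown preset {name!r}; known: {sorted(PRESETS)}")
        if n_animals < 1:
            raise ConfigError(f"n_animals must be >= 1 for preset {name!r}")
        preset = PRESETS[name]
        for j in range(n_animals):
            animal_seed = int(np.random.default_rng([seed, counter]).integers(2**63))
            cfg = replace(preset.apply(base), seed=animal_seed)
            trace, truth = simulate_trace(cfg)
            animal_id = f"{name}_{j:02d}"
            trace = replace(trace, animal_id=animal_id)
            out.append((animal_id, name, trace, truth))
            counter += 1
    return out
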