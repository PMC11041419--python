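"""Synthetic CGM cohorts with known pattern structure.

Six archetypal fluctuation templates span the clinically meaningful glucose
strata — from a steady marginally-hypoglycemic/normal trace to a severely
hyperglycemic peak-and-decline — and patients are built by tiling days with
template segments drawn from per-patient mixture weights.  Four patient
archetypes (A-D) mirror typical glycemic-control profiles: A mostly
hyperglycemic fluctuation, B very poorly controlled (dominated by the
highest-glucose patterns), C and D increasingly well controlled.  Meal-surge
templates are preferentially placed around breakfast/lunch/dinner and the
steady low template overnight (02:00-06:00), giving the diurnal structure the
hourly-occurrence analysis should recover.  Gaussian sensor noise, sample
dropout and clipping to [1, 30] mmol/L emulate flash-monitor data sampled
every 15 minutes.

The generator records ground truth per emitted segment, so window-level and
patient-level recovery can be scored exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cgm_io import GlucoseSeries

#: Template mixture means per patient archetype (shares over templates 1..6).
ARCHETYPE_WEIGHTS = {
    "A": np.array([13.6, 17.0, 22.4, 23.1, 19.3, 4.7]),
    "B": np.array([2.1, 3.6, 6.8, 10.1, 26.2, 51.2]),
    "C": np.array([27.6, 27.6, 23.5, 15.6, 5.5, 0.3]),
    "D": np.array([51.9, 32.5, 10.2, 5.0, 0.4, 0.0]),
}
for _k in ARCHETYPE_WEIGHTS:       # exact simplex normalisation
    ARCHETYPE_WEIGHTS[_k] = ARCHETYPE_WEIGHTS[_k] / ARCHETYPE_WEIGHTS[_k].sum()

#: Cohort shares of the archetypes (A is the majority profile).
ARCHETYPE_SHARES = {"A": 0.587, "B": 0.032, "C": 0.278, "D": 0.103}


def pattern_templates(duration: int = 150,
                      step: int = 15) -> list[np.ndarray]:
    """Six deterministic glucose templates at 15-minute resolution.

    T1 steady 3-6 mmol/L (slightly concave up); T2 normal, slight rise 6->8;
    T3 declining ~11->6; T4 rising ~11->16; T5 hyperglycemic level 14-19
    (concave); T6 severely hyperglycemic 19-28 (peak and decline).  Template
    means increase strictly from T1 to T6.
    """
    if duration < 30:
        raise ValueError("duration must be >= 30 minutes")
    n = duration // step
    x = np.linspace(0.0, 1.0, n)
    u = 2 * x - 1
    return [
        4.2 + 0.8 * u ** 2,          # T1: steady/concave-up, within [4.2, 5.0]
        6.0 + 2.0 * x,               # T2: slight rise 6 -> 8
        11.0 - 5.0 * x,              # T3: decline 11 -> 6
        11.0 + 5.0 * x,              # T4: rise 11 -> 16
        16.5 - 2.5 * u ** 2,         # T5: concave level, within [14, 16.5]
        19.0 + 9.0 * np.sin(np.pi * x),  # T6: peak-and-decline 19 -> 28 -> 19
    ]


@dataclass
class SyntheticConfig:
    """Generator settings; the defaults emulate a 15-minute flash monitor
    cohort with mild sensor noise and 5% dropout."""

    n_patients: int = 20
    days_per_patient: int = 14
    sampling_interval: int = 15          # minutes
    segment_minutes: int = 150           # template segment length
    noise_sd: float = 0.5                # mmol/L
    dropout_rate: float = 0.05
    meal_hours: tuple = (9, 13, 19)
    overnight_hours: tuple = (2, 6)      # [start, end) of the T1-favoured span
    diurnal_boost: float = 4.0           # weight multiplier at favoured hours
    archetype_weights: dict | None = None   # override mixture per archetype
    archetype_shares: dict | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _segment_weights(base: np.ndarray, mid_hour: float,
                     cfg: SyntheticConfig) -> np.ndarray:
    """Reweight template probabilities by time of day: meal surges favour
    T2/T4, the small hours favour T1."""
    w = base.copy()
    lo, hi = cfg.overnight_hours
    if lo <= mid_hour < hi:
        w[0] *= cfg.diurnal_boost
    if any(abs(mid_hour - m) <= 1.0 for m in cfg.meal_hours):
        w[1] *= cfg.diurnal_boost
        w[3] *= cfg.diurnal_boost
    return w / w.sum()


def generate_cohort(config: SyntheticConfig
                    ) -> tuple[list[GlucoseSeries], pd.DataFrame]:
    """Generate a cohort of CGM traces plus segment-level ground truth.

    Returns ``(series_list, truth)`` where ``truth`` has one row per emitted
    template segment: patient_id, segment_start, template (1..6), archetype.
    Traces are reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    weights = config.archetype_weights or ARCHETYPE_WEIGHTS
    shares = config.archetype_shares or ARCHETYPE_SHARES
    arch_names = sorted(shares)
    arch_p = np.array([shares[a] for a in arch_names], dtype=float)
    arch_p /= arch_p.sum()

    templates = pattern_templates(config.segment_minutes,
                                  config.sampling_interval)
    t0 = pd.Timestamp("2019-01-01 00:00:00")
    per_seg = config.segment_minutes // config.sampling_interval
    total_minutes = config.days_per_patient * 1440
    n_segments = total_minutes // config.segment_minutes

    series_list, truth_rows = [], []
    for pi in range(config.n_patients):
        pid = f"P{pi:03d}"
        arch = arch_names[int(rng.choice(len(arch_names), p=arch_p))]
        base_w = np.asarray(weights[arch], dtype=float)
        times, values = [], []
        for si in range(n_segments):
            seg_start = t0 + pd.Timedelta(minutes=si * config.segment_minutes)
            mid = seg_start + pd.Timedelta(minutes=config.segment_minutes / 2)
            mid_hour = mid.hour + mid.minute / 60.0
            w = _segment_weights(base_w, mid_hour, config)
            tmpl = int(rng.choice(6, p=w))
            vals = templates[tmpl].copy()
            if config.noise_sd > 0:
                vals = vals + rng.normal(0.0, config.noise_sd, size=per_seg)
            vals = np.clip(vals, 1.0, 30.0)
            offs = np.arange(per_seg) * config.sampling_interval
            keep = np.ones(per_seg, dtype=bool)
            if config.dropout_rate > 0:
                keep = rng.random(per_seg) >= config.dropout_rate
            times.append(seg_start + pd.to_timedelta(offs[keep], unit="min"))
            values.append(vals[keep])
            truth_rows.append({"patient_id": pid,
                               "segment_start": seg_start.isoformat(),
                               "template": tmpl + 1, "archetype": arch})
        ts = pd.DatetimeIndex(np.concatenate([t.values for t in times]))
        vv = np.concatenate(values)
        if len(vv) == 0:        # pathological dropout; keep the type invariant
            ts = pd.DatetimeIndex([t0])
            vv = np.array([5.0])
        series_list.append(GlucoseSeries(pid, ts, vv))
    truth = pd.DataFrame(truth_rows)
    return series_list, truth


def generate_archetype_compositions(n_patients: int = 60,
                                    concentration: float = 100.0,
                                    seed: int = 0,
                                    shares: dict | None = None):
    """Draw per-patient time-in-patterns compositions (percent, summing to
    100) from Dirichlet distributions centred on the four archetype mixture
    means.

    ``concentration`` scales all Dirichlet parameters; the default of 100
    gives within-archetype spreads of roughly 2-4 percentage points on the
    dominant shares.  Archetype counts are deterministic (largest-remainder
    apportionment of ``shares``, equal by default) so every archetype is
    represented.  Returns (compositions, archetype_labels).
    """
    rng = np.random.default_rng(seed)
    shares = shares or {a: 0.25 for a in ARCHETYPE_WEIGHTS}
    names = sorted(shares)
    p = np.array([shares[a] for a in names], dtype=float)
    p /= p.sum()
    counts = np.floor(p * n_patients).astype(int)
    rem = np.argsort(-(p * n_patients - counts), kind="stable")
    for i in range(n_patients - counts.sum()):
        counts[rem[i % len(names)]] += 1
    comps, labels = [], []
    for arch, cnt in zip(names, counts):
        # zero mixture entries get a tiny floor so the Dirichlet is proper
        alpha = np.maximum(ARCHETYPE_WEIGHTS[arch], 1e-3) * concentration
        for _ in range(cnt):
            comps.append(100.0 * rng.dirichlet(alpha))
            labels.append(arch)
    return np.array(comps), np.array(labels)


def generate_labeled_windows(n_per_template: int = 100, duration: int = 150,
                             noise_sd: float = 0.5, seed: int = 0,
                             step: int = 15):
    """Windows drawn directly from the six templates plus Gaussian noise,
    with ground-truth template labels — the planted-structure fixture for
    clustering tests."""
    from .preprocess import Window
    rng = np.random.default_rng(seed)
    templates = pattern_templates(duration, step)
    t0 = pd.Timestamp("2019-01-01 00:00:00")
    windows, labels = [], []
    order = rng.permutation(6 * n_per_template)
    plan = np.repeat(np.arange(6), n_per_template)[order]
    for i, tmpl in enumerate(plan):
        vals = templates[tmpl] + rng.normal(0.0, noise_sd,
                                            size=len(templates[tmpl]))
        vals = np.clip(vals, 1.0, 30.0)
        windows.append(Window(
            patient_id="SYN", start=t0 + pd.Timedelta(minutes=i * duration),
            duration=duration,
            offsets=np.arange(len(vals)) * step, values=vals))
        labels.append(int(tmpl) + 1)
    return windows, np.array(labels)
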