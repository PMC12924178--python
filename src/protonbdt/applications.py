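"""Clinical applications of the delivery-time model.

Two downstream uses of predicted inter-pulse times:

* cumulative delivery-time reconstruction for volumetric-repainting plans
  (is the predicted total beam-on time close to the delivered one?);
* interplay evaluation — mapping every pulse onto the phase of a
  sinusoidal breathing trace and comparing per-phase charge deposition
  between model-predicted and logged timings, against the machine's own
  fraction-to-fraction variability.

Dose recalculation is out of scope; the pipeline stops at phase-resolved
charge maps compared by total-variation distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MachineConfig
from .features import transition_features
from .machine import plan_to_pulses

__all__ = [
    "BreathingTrace",
    "PhaseMap",
    "CumulativeComparison",
    "cumulative_bdt",
    "compare_timing_sources",
    "breathing_phase",
    "map_pulses_to_phases",
    "compare_phase_maps",
    "predict_plan_timing",
    "interplay_experiment",
]


@dataclass
class BreathingTrace:
    """Sinusoidal breathing surrogate; phases are uniform bins of the cycle."""

    period: float            # s
    amplitude: float = 1.0   # displacement units; metadata only
    phase_offset: float = 0.0  # radians
    n_phases: int = 10

    def __post_init__(self) -> None:
        if self.period <= 0:
            raise ValueError("period must be > 0")
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")


@dataclass
class PhaseMap:
    """Per-breathing-phase charge accumulation for one timing source."""

    charge_pc: np.ndarray   # (n_phases,)
    labels: np.ndarray      # per-pulse phase indices
    period: float
    n_phases: int
    source: str = ""

    @property
    def distribution(self) -> np.ndarray:
        total = self.charge_pc.sum()
        return self.charge_pc / total if total > 0 else self.charge_pc


@dataclass
class CumulativeComparison:
    """Cumulative delivery time under two timing sources, per beam."""

    per_beam: pd.DataFrame       # beam_id, pulse_index, cum_ref_ms, cum_pred_ms
    total_reference_ms: float
    total_predicted_ms: float

    @property
    def relative_deviation(self) -> float:
        """(predicted - reference) / reference of the total delivery time."""
        return (self.total_predicted_ms - self.total_reference_ms) / self.total_reference_ms


def cumulative_bdt(delta_ts) -> np.ndarray:
    """Running sum of inter-pulse times; the last value is the beam-on total."""
    dt = np.asarray(delta_ts, dtype=float)
    if np.any(dt <= 0):
        raise ValueError("inter-pulse times must be > 0")
    return np.cumsum(dt)


def compare_timing_sources(reference_dt, predicted_dt,
                           beam_ids=None, pulse_index=None) -> CumulativeComparison:
    """Compare cumulative delivery time of predicted vs reference intervals."""
    ref = np.asarray(reference_dt, dtype=float)
    pred = np.asarray(predicted_dt, dtype=float)
    if ref.shape != pred.shape:
        raise ValueError("reference and predicted interval counts differ")
    beam_ids = np.asarray(beam_ids) if beam_ids is not None else np.full(len(ref), "all")
    pulse_index = (np.asarray(pulse_index) if pulse_index is not None
                   else np.arange(2, len(ref) + 2))
    frames = []
    for beam in pd.unique(beam_ids):
        m = beam_ids == beam
        frames.append(pd.DataFrame({
            "beam_id": beam,
            "pulse_index": pulse_index[m],
            "dt_ref_ms": ref[m],
            "dt_pred_ms": pred[m],
            "cum_ref_ms": cumulative_bdt(ref[m]),
            "cum_pred_ms": cumulative_bdt(pred[m]),
        }))
    per_beam = pd.concat(frames, ignore_index=True)
    return CumulativeComparison(per_beam, float(ref.sum()), float(pred.sum()))


def breathing_phase(t_s, trace: BreathingTrace) -> np.ndarray:
    """Breathing-phase index of time(s) ``t_s`` (seconds): uniform-in-time bins.

    phase = floor(n_phases * frac(t / period + offset / 2π)); periodic in
    the trace period and independent of amplitude.
    """
    t = np.asarray(t_s, dtype=float)
    cycle = np.mod(t / trace.period + trace.phase_offset / (2.0 * np.pi), 1.0)
    phase = np.floor(trace.n_phases * cycle).astype(int)
    return np.minimum(phase, trace.n_phases - 1)  # guard the frac == 1.0 edge


def map_pulses_to_phases(timestamps_ms, charges_pc,
                         trace: BreathingTrace, source: str = "") -> PhaseMap:
    """Label each pulse with its breathing phase and accumulate charge."""
    ts = np.asarray(timestamps_ms, dtype=float)
    q = np.asarray(charges_pc, dtype=float)
    if ts.shape != q.shape:
        raise ValueError("timestamps and charges must have equal length")
    if np.any(np.diff(ts) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if np.any(q <= 0):
        raise ValueError("charges must be positive")
    labels = breathing_phase(ts / 1000.0, trace)
    charge = np.bincount(labels, weights=q, minlength=trace.n_phases)
    return PhaseMap(charge, labels, trace.period, trace.n_phases, source)


def compare_phase_maps(map_a: PhaseMap, map_b: PhaseMap) -> dict:
    """Agreement fraction of pulse phase labels and total-variation distance.

    TV = 0.5 * sum |p_a - p_b| over the normalized per-phase charge
    distributions; both quantities lie in [0, 1].
    """
    if map_a.n_phases != map_b.n_phases or len(map_a.labels) != len(map_b.labels):
        raise ValueError("phase maps must share pulse count and n_phases")
    agreement = float(np.mean(map_a.labels == map_b.labels))
    tv = float(0.5 * np.abs(map_a.distribution - map_b.distribution).sum())
    return {"agreement": agreement, "tv_distance": tv}


def predict_plan_timing(results, plan: pd.DataFrame,
                        config: MachineConfig | None = None) -> pd.DataFrame:
    """Predict per-pulse timestamps for an undelivered plan.

    Features derive from plan geometry and ordering alone; predicted
    inter-pulse times are accumulated per beam with the first pulse at 0.
    """
    config = config or MachineConfig()
    pulses = plan_to_pulses(plan, config)
    frames = []
    for beam, g in pulses.groupby("beam_id", sort=False):
        g = g.reset_index(drop=True)
        feats = transition_features(g, config)
        dt = results.predict(feats)
        g["timestamp_ms"] = np.concatenate([[0.0], np.cumsum(dt)])
        frames.append(g)
    return pd.concat(frames, ignore_index=True)


def interplay_experiment(plan: pd.DataFrame, results, fraction_logs: pd.DataFrame,
                         periods_s=(2.0, 4.0, 5.0), n_phases: int = 10,
                         phase_offset: float = 0.0,
                         config: MachineConfig | None = None) -> pd.DataFrame:
    """Phase-map comparison: model-predicted timing vs logged fractions.

    For each breathing period, builds per-phase charge maps from (a) the
    model-predicted pulse timestamps of ``plan`` and (b) each reference
    fraction's logged timestamps, and compares them by total-variation
    distance and label agreement.  The reference fractions' pairwise
    distances quantify the machine's intrinsic variability; the exported
    ``within_intrinsic`` flag records whether the mean model-vs-reference
    distance does not exceed the largest intrinsic one.

    Raises if the plan's beams appear in the model's training set (the
    experiment is only meaningful on held-out plans).
    """
    config = config or MachineConfig()
    plan_beams = set(plan["beam_id"].unique())
    train_beams = {b for (_, b) in results.training_ids}
    leaked = plan_beams & train_beams
    if leaked:
        raise ValueError(f"plan beam(s) {sorted(leaked)} were in the training set")

    predicted = predict_plan_timing(results, plan, config)
    fractions = sorted(fraction_logs["fraction_id"].unique())
    rows = []
    for period in periods_s:
        trace = BreathingTrace(period=float(period), n_phases=n_phases,
                               phase_offset=phase_offset)
        model_map = _log_phase_map(predicted, trace, source="model")
        ref_maps = {
            f: _log_phase_map(fraction_logs[fraction_logs["fraction_id"] == f],
                              trace, source=f)
            for f in fractions}
        model_tvs, model_agrees = [], []
        for f in fractions:
            c = compare_phase_maps(model_map, ref_maps[f])
            model_tvs.append(c["tv_distance"])
            model_agrees.append(c["agreement"])
        intrinsic_tvs = [
            compare_phase_maps(ref_maps[f1], ref_maps[f2])["tv_distance"]
            for i, f1 in enumerate(fractions) for f2 in fractions[i + 1:]]
        rows.append({
            "period_s": float(period),
            "model_tv_mean": float(np.mean(model_tvs)),
            "model_tv_max": float(np.max(model_tvs)),
            "model_agreement_mean": float(np.mean(model_agrees)),
            "intrinsic_tv_min": float(np.min(intrinsic_tvs)) if intrinsic_tvs else np.nan,
            "intrinsic_tv_max": float(np.max(intrinsic_tvs)) if intrinsic_tvs else np.nan,
            "within_intrinsic": bool(intrinsic_tvs
                                     and np.mean(model_tvs) <= np.max(intrinsic_tvs)),
        })
    return pd.DataFrame(rows)


def _log_phase_map(log: pd.DataFrame, trace: BreathingTrace, source: str) -> PhaseMap:
    """Phase map of a pulse table, beams concatenated in delivery order.

    Beams are delivered sequentially; each beam's clock (and the breathing
    phase underneath it) restarts at zero, so labels are computed per beam
    and concatenated.
    """
    labels_all, charge = [], np.zeros(trace.n_phases)
    for _, g in log.groupby("beam_id", sort=False):
        g = g.sort_values("pulse_index")
        pm = map_pulses_to_phases(g["timestamp_ms"].to_numpy(),
                                  g["target_charge_pC"].to_numpy(), trace, source)
        labels_all.append(pm.labels)
        charge += pm.charge_pc
    return PhaseMap(charge, np.concatenate(labels_all), trace.period,
                    trace.n_phases, source)
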