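"""Per-transition feature engineering and the stratified train/test split.

A pulse log of N pulses yields N-1 feature rows, one per transition
(pulse n-1 -> n).  Geometric change magnitudes are log1p-compressed; the
inter-pulse time target is log1p-transformed to reduce its heavy skew.

Engineered columns
------------------
log_daa        log1p of the summed aperture leaf travel (mm),
               daa = sum_l sqrt(dX_l^2 + dY_l^2) over the leaf bank
log_ds         log1p of the spot travel (Euclidean, mm)
delta_e        signed energy-level difference (level index units)
log_de         log1p of |delta_e|
charge         target charge of the destination pulse (pC)
delta_charge   signed charge difference (pC)
is_first_pulse flags the transition out of a beam-fraction's first pulse
is_tx_pulse    flags the low-charge -> treatment transition
delta_t        target: timestamp difference (ms)
log_delta_t    log1p(delta_t)
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .config import MachineConfig
from .machine import _transition_kinematics

__all__ = [
    "NUMERIC_FEATURES",
    "BOOLEAN_FEATURES",
    "MODEL_FEATURES",
    "delta_aa",
    "delta_s",
    "log1p_target",
    "inverse_log1p_target",
    "build_feature_table",
    "transition_features",
    "stratified_split",
]

NUMERIC_FEATURES = ["log_daa", "log_ds", "delta_e", "log_de", "charge", "delta_charge"]
BOOLEAN_FEATURES = ["is_first_pulse", "is_tx_pulse"]
MODEL_FEATURES = NUMERIC_FEATURES + BOOLEAN_FEATURES
ID_COLUMNS = ["fraction_id", "beam_id", "pulse_index"]


def delta_aa(prev_leaves, next_leaves) -> float:
    """Summed aperture leaf travel: sum_l sqrt(dX_l^2 + dY_l^2), in mm.

    Leaves are matched by index; inputs are (n_leaves, 2) coordinate arrays.
    """
    a = np.asarray(prev_leaves, dtype=float)
    b = np.asarray(next_leaves, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 2:
        raise ValueError("leaf sets must share the same (n_leaves, 2) shape")
    d = b - a
    return float(np.hypot(d[:, 0], d[:, 1]).sum())


def delta_s(prev_xy, next_xy) -> float:
    """Euclidean distance between consecutive spot positions, in mm."""
    a = np.asarray(prev_xy, dtype=float)
    b = np.asarray(next_xy, dtype=float)
    return float(np.hypot(*(b - a)))


def log1p_target(y):
    """Skew-reducing target transform, y_log = log(1 + y); y must be >= 0."""
    y = np.asarray(y, dtype=float)
    if np.any(y < 0):
        raise ValueError("log1p target transform requires y >= 0")
    return np.log1p(y)


def inverse_log1p_target(y_log):
    return np.expm1(np.asarray(y_log, dtype=float))


def _features_from_kinematics(kin: pd.DataFrame) -> pd.DataFrame:
    return pd.DataFrame({
        "log_daa": np.log1p(kin["daa_mm"].to_numpy()),
        "log_ds": np.log1p(kin["ds_mm"].to_numpy()),
        "delta_e": kin["de_levels"].to_numpy(dtype=float),
        "log_de": np.log1p(np.abs(kin["de_levels"].to_numpy(dtype=float))),
        "charge": kin["charge_pc"].to_numpy(),
        "delta_charge": kin["dq_pc"].to_numpy(),
        "is_first_pulse": kin["is_first_pulse"].to_numpy(),
        "is_tx_pulse": kin["is_tx_pulse"].to_numpy(),
    })


def transition_features(pulses: pd.DataFrame,
                        config: MachineConfig | None = None) -> pd.DataFrame:
    """Feature rows (no target) for one beam's ordered pulse sequence.

    Used to predict delivery times for a plan that has never been
    delivered: all features derive from geometry and ordering alone.
    """
    config = config or MachineConfig()
    kin = _transition_kinematics(pulses.reset_index(drop=True), config)
    return _features_from_kinematics(kin)


def build_feature_table(log, config: MachineConfig | None = None) -> pd.DataFrame:
    """Per-transition feature table with the delta_t target for a pulse log.

    ``log`` is a flat log frame or a list of TreatmentRecords.  One row per
    transition; identifier columns (fraction_id, beam_id, destination
    pulse_index) are kept for grouping and leakage checks but are not model
    features.
    """
    config = config or MachineConfig()
    if not isinstance(log, pd.DataFrame):
        log = pd.concat([r.pulses for r in log], ignore_index=True)
    frames = []
    for (frac, beam), pulses in log.groupby(["fraction_id", "beam_id"], sort=False):
        pulses = pulses.sort_values("pulse_index").reset_index(drop=True)
        if len(pulses) < 2:
            warnings.warn(f"{frac}/{beam}: single-pulse record yields no transitions",
                          stacklevel=2)
            continue
        kin = _transition_kinematics(pulses, config)
        feats = _features_from_kinematics(kin)
        dt = np.diff(pulses["timestamp_ms"].to_numpy(dtype=float))
        feats["delta_t"] = dt
        feats["log_delta_t"] = log1p_target(dt)
        feats.insert(0, "fraction_id", frac)
        feats.insert(1, "beam_id", beam)
        feats.insert(2, "pulse_index", pulses["pulse_index"].to_numpy()[1:])
        frames.append(feats)
    if not frames:
        return pd.DataFrame(columns=ID_COLUMNS + MODEL_FEATURES + ["delta_t", "log_delta_t"])
    return pd.concat(frames, ignore_index=True)


def stratified_split(table: pd.DataFrame, train_frac: float = 0.7,
                     n_bins: int = 10, seed: int = 0
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Quantile-stratified train/test split on the log-transformed target.

    The table is binned into ``n_bins`` quantile strata of ``log_delta_t``
    and split so each stratum contributes ``train_frac`` of its rows to the
    training set (70/30 by default).
    """
    if not 0 < train_frac < 1:
        raise ValueError("train_frac must lie in (0, 1)")
    if len(table) < n_bins:
        raise ValueError("table must have at least n_bins rows")
    bins = pd.qcut(table["log_delta_t"], q=n_bins, labels=False, duplicates="drop")
    if bins.nunique() < n_bins:
        warnings.warn(f"collapsed to {bins.nunique()} stratification bins "
                      "(duplicated target quantiles)", stacklevel=2)
    train, test = train_test_split(table, train_size=train_frac,
                                   stratify=bins, random_state=seed)
    return (train.sort_index().reset_index(drop=True),
            test.sort_index().reset_index(drop=True))
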