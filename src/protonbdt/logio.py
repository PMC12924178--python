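"""Reading, writing and validating pulse logs and spot plans.

The on-disk format is plain CSV with the documented column schemas
(:mod:`protonbdt.schema`); floats are serialized with fixed decimal
precision so write -> read -> write round trips are bit-stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .config import MachineConfig
from .schema import leaf_columns, log_columns, plan_columns

__all__ = [
    "TreatmentRecord",
    "Issue",
    "SchemaError",
    "read_log",
    "read_log_frame",
    "write_log",
    "read_plan",
    "write_plan",
    "validate",
]

_FLOAT_FORMAT = "%.4f"


class SchemaError(ValueError):
    """A file does not carry the documented column schema."""


@dataclass
class Issue:
    severity: str   # "error" | "warning"
    location: str   # e.g. "f01/b02 pulse 17"
    message: str


@dataclass
class TreatmentRecord:
    """One beam delivery within one fraction: the ordered pulse list."""

    fraction_id: str
    beam_id: str
    pulses: pd.DataFrame
    provenance: str = ""

    def __post_init__(self) -> None:
        if self.pulses.empty:
            raise ValueError("TreatmentRecord requires at least one pulse")


def _check_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} is missing column(s): {', '.join(missing)}")


def read_log_frame(path: str | Path, config: MachineConfig | None = None) -> pd.DataFrame:
    """Read a pulse-log CSV into a flat frame sorted by pulse_index."""
    config = config or MachineConfig()
    df = pd.read_csv(path, dtype={"fraction_id": str, "beam_id": str})
    _check_columns(df, log_columns(config.n_leaves), f"log file {path}")
    df = (df.sort_values(["fraction_id", "beam_id", "pulse_index"])
            .reset_index(drop=True))
    for frac, beam, pulses in _iter_groups(df):
        ts = pulses["timestamp_ms"].to_numpy()
        bad = (ts[1:] <= ts[:-1]).nonzero()[0]
        if len(bad):
            idx = int(pulses["pulse_index"].iloc[bad[0] + 1])
            raise ValueError(
                f"non-monotone timestamps in {frac}/{beam} at pulse {idx}")
        over = pulses["target_charge_pC"] > config.max_pulse_charge
        if over.any():
            warnings.warn(
                f"{frac}/{beam}: {int(over.sum())} pulse(s) exceed the "
                f"{config.max_pulse_charge} pC charge cap", stacklevel=2)
    return df


def _iter_groups(df: pd.DataFrame):
    for (frac, beam), g in df.groupby(["fraction_id", "beam_id"], sort=False):
        yield frac, beam, g


def read_log(path: str | Path, config: MachineConfig | None = None) -> list[TreatmentRecord]:
    """Read a pulse-log CSV into one TreatmentRecord per (fraction, beam)."""
    df = read_log_frame(path, config)
    return [TreatmentRecord(frac, beam, g.reset_index(drop=True), provenance=str(path))
            for frac, beam, g in _iter_groups(df)]


def write_log(records, path: str | Path,
              config: MachineConfig | None = None) -> None:
    """Write records (a flat frame or TreatmentRecord list) to CSV."""
    config = config or MachineConfig()
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = (pd.concat([r.pulses for r in records], ignore_index=True)
              if records else pd.DataFrame(columns=log_columns(config.n_leaves)))
    cols = log_columns(config.n_leaves)
    _check_columns(df, cols, "log frame") if len(df) else None
    df.reindex(columns=cols).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def read_plan(path: str | Path, config: MachineConfig | None = None) -> pd.DataFrame:
    config = config or MachineConfig()
    df = pd.read_csv(path, dtype={"beam_id": str})
    _check_columns(df, plan_columns(config.n_leaves), f"plan file {path}")
    return df


def write_plan(plan: pd.DataFrame, path: str | Path,
               config: MachineConfig | None = None) -> None:
    config = config or MachineConfig()
    cols = plan_columns(config.n_leaves)
    _check_columns(plan, cols, "plan frame")
    plan.reindex(columns=cols).to_csv(path, index=False, float_format=_FLOAT_FORMAT)


def validate(records, config: MachineConfig | None = None) -> list[Issue]:
    """Check pulse-log invariants; returns an empty list iff all hold.

    Pure reporting: never mutates or raises on content problems.
    Checks per (fraction, beam): contiguous 1-based pulse indices, strictly
    increasing timestamps, the per-pulse charge cap (warning severity), and
    low-charge-layer pulses carrying exactly the configured low charge.
    """
    config = config or MachineConfig()
    if isinstance(records, pd.DataFrame):
        groups = list(_iter_groups(records))
    else:
        groups = [(r.fraction_id, r.beam_id, r.pulses) for r in records]
    issues: list[Issue] = []
    for frac, beam, pulses in groups:
        loc = f"{frac}/{beam}"
        idx = pulses["pulse_index"].to_numpy()
        expected = range(1, len(idx) + 1)
        if list(idx) != list(expected):
            dupes = pd.Series(idx).duplicated()
            if dupes.any():
                issues.append(Issue("error", f"{loc} pulse {int(idx[dupes.idxmax()])}",
                                    "duplicated pulse_index"))
            else:
                issues.append(Issue("error", loc,
                                    "pulse_index not contiguous from 1"))
        ts = pulses["timestamp_ms"].to_numpy()
        bad = (ts[1:] <= ts[:-1]).nonzero()[0]
        for k in bad[:5]:
            issues.append(Issue("error", f"{loc} pulse {int(idx[k + 1])}",
                                "timestamp not strictly increasing"))
        over = pulses["target_charge_pC"].to_numpy() > config.max_pulse_charge
        for k in over.nonzero()[0][:5]:
            issues.append(Issue("warning", f"{loc} pulse {int(idx[k])}",
                                f"target charge {pulses['target_charge_pC'].iloc[k]} pC "
                                f"exceeds the {config.max_pulse_charge} pC cap"))
        low = pulses["is_low_charge"].to_numpy(dtype=bool)
        wrong = low & (pulses["target_charge_pC"].to_numpy() != config.low_charge)
        for k in wrong.nonzero()[0][:5]:
            issues.append(Issue("error", f"{loc} pulse {int(idx[k])}",
                                f"low-charge pulse must carry {config.low_charge} pC"))
    return issues
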