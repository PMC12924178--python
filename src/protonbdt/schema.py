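"""Column schemas shared by the plan and pulse-log tables.

Both artefacts are plain CSV: a *plan* is the ordered spot list the machine
will deliver, a *log* is the per-pulse delivery record.  The log schema is a
documented, project-defined subset of what a vendor treatment record carries
(only the fields the timing analysis needs).
"""

from __future__ import annotations

N_LEAVES_DEFAULT = 14


def leaf_columns(n_leaves: int = N_LEAVES_DEFAULT) -> list[str]:
    """Interleaved leaf coordinate columns: leaf01_x_mm, leaf01_y_mm, ..."""
    cols = []
    for i in range(1, n_leaves + 1):
        cols.append(f"leaf{i:02d}_x_mm")
        cols.append(f"leaf{i:02d}_y_mm")
    return cols


PLAN_BASE_COLUMNS = [
    "beam_id",
    "layer_index",
    "energy_level",
    "x_mm",
    "y_mm",
    "charge_pC",
    "is_low_charge",
]

LOG_BASE_COLUMNS = [
    "fraction_id",
    "beam_id",
    "pulse_index",
    "timestamp_ms",
    "target_charge_pC",
    "energy_level",
    "x_mm",
    "y_mm",
    "is_low_charge",
]


def plan_columns(n_leaves: int = N_LEAVES_DEFAULT) -> list[str]:
    return PLAN_BASE_COLUMNS + leaf_columns(n_leaves)


def log_columns(n_leaves: int = N_LEAVES_DEFAULT) -> list[str]:
    return LOG_BASE_COLUMNS + leaf_columns(n_leaves)
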