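"""Synthetic delivery-physics model and machine-log generator.

Emulates pulse-scanned proton delivery on a compact synchrocyclotron with
nozzle-mounted energy selection:

* energy levels realised by combinations of range-modulator plates
  (binary-weighted thicknesses on the first eight plates reproduce 161
  levels at 2.1 mm water-equivalent spacing; the remaining plates are
  spares);
* beams composed of energy layers, each beam opening with a low-charge
  verification layer delivered at a fixed reduced pulse charge;
* spots rastered serpentine within a layer and split into pulses capped at
  the per-pulse charge limit (fill-to-cap with a final remainder);
* a 14-leaf adaptive aperture that re-trims whenever the beam moves to a
  new raster row or energy layer, so same-row pulses see no leaf motion;
* an additive deterministic inter-pulse-time model (base period, spot
  travel, charge step, aperture latency linear in total leaf travel,
  energy-switch latency linear in plates repositioned, plus low-charge to
  treatment and beam-start surcharges) with heteroscedastic inter-fraction
  noise on top.

All randomness is driven by explicit seeds; identical (seed, plan, config)
triples produce bit-identical logs.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .config import MachineConfig
from .schema import leaf_columns, log_columns, plan_columns

__all__ = [
    "energy_table",
    "plate_configuration",
    "plates_moved",
    "generate_plan",
    "split_spot_to_pulses",
    "plan_to_pulses",
    "deterministic_delta_t",
    "simulate_fraction",
    "simulate_course",
    "make_repainted_plan",
]

_ROUND = 4  # decimals kept in generated tables; keeps CSV round trips bit-stable


def energy_table(config: MachineConfig) -> np.ndarray:
    """Water-equivalent thickness (mm) of each energy level, level 0 first."""
    return np.arange(config.n_energy_levels) * config.wet_spacing


def _plate_weights(config: MachineConfig) -> np.ndarray:
    """Plate thicknesses in wet_spacing units: binary weights, then spares."""
    n_active = max(1, math.ceil(math.log2(config.n_energy_levels))) if config.n_energy_levels > 1 else 1
    if n_active > config.n_plates:
        raise ValueError("not enough plates to realise the requested level count")
    weights = np.zeros(config.n_plates, dtype=np.int64)
    weights[:n_active] = 2 ** np.arange(n_active)
    return weights


def plate_configuration(level: int, config: MachineConfig) -> np.ndarray:
    """Plate occupancy (1 = inserted) realising ``level`` wet_spacing units.

    Binary decomposition over the active plates makes the mapping
    deterministic and injective on levels.
    """
    if not 0 <= level < config.n_energy_levels:
        raise ValueError(f"energy level {level} outside [0, {config.n_energy_levels})")
    weights = _plate_weights(config)
    occ = np.zeros(config.n_plates, dtype=np.int8)
    active = np.nonzero(weights)[0]
    occ[active] = (int(level) >> np.arange(len(active))) & 1
    return occ


def _occupancy_table(config: MachineConfig) -> np.ndarray:
    levels = np.arange(config.n_energy_levels)
    weights = _plate_weights(config)
    active = np.nonzero(weights)[0]
    table = np.zeros((config.n_energy_levels, config.n_plates), dtype=np.int8)
    table[:, active] = (levels[:, None] >> np.arange(len(active))[None, :]) & 1
    return table


def plates_moved(level_a: int, level_b: int, config: MachineConfig) -> int:
    """Number of plates repositioned between two levels (Hamming distance)."""
    a = plate_configuration(level_a, config)
    b = plate_configuration(level_b, config)
    return int(np.sum(a != b))


def split_spot_to_pulses(charge: float, config: MachineConfig) -> np.ndarray:
    """Split a spot charge into pulse charges, fill-to-cap with a remainder.

    ``ceil(charge / cap)`` pulses, all at the cap except a final remainder.
    """
    if charge <= 0:
        raise ValueError("spot charge must be > 0")
    cap = config.max_pulse_charge
    n = int(math.ceil(charge / cap - 1e-12))
    charges = np.full(n, cap)
    remainder = charge - cap * (n - 1)
    charges[-1] = remainder
    return np.round(charges, _ROUND)


def _aperture_leaves(center_x: float, center_y: float, radius: float,
                     config: MachineConfig) -> np.ndarray:
    """Leaf (x, y) positions trimming a circular opening around a row centre."""
    angles = 2.0 * np.pi * np.arange(config.n_leaves) / config.n_leaves
    xs = center_x + radius * np.cos(angles)
    ys = center_y + radius * np.sin(angles)
    return np.column_stack([xs, ys])


def generate_plan(seed: int, n_beams: int, n_layers_per_beam: int,
                  spots_per_layer: int, config: MachineConfig | None = None,
                  charge_range: tuple[float, float] = (2.0, 20.0),
                  beam_prefix: str = "b") -> pd.DataFrame:
    """Generate an ordered synthetic spot list.

    Each beam opens with a low-charge verification layer (a copy of its
    first treatment layer delivered at the fixed low charge), followed by
    ``n_layers_per_beam`` treatment layers in descending energy order.
    Spots follow a serpentine raster; aperture leaves are set once per
    raster row at a fixed margin around the active row.
    """
    if min(n_beams, n_layers_per_beam, spots_per_layer) < 1:
        raise ValueError("n_beams, n_layers_per_beam and spots_per_layer must be >= 1")
    config = config or MachineConfig()
    rng = np.random.default_rng(seed)
    half = config.field_half_extent_mm
    lcols = leaf_columns(config.n_leaves)

    rows: list[dict] = []
    for b in range(n_beams):
        beam_id = f"{beam_prefix}{b + 1:02d}"
        beam_center = rng.uniform(-20.0, 20.0, size=2)
        top = int(rng.integers(120, config.n_energy_levels))
        levels = [top]
        for _ in range(n_layers_per_beam - 1):
            step = int(rng.integers(1, 13))
            levels.append(max(levels[-1] - step, 0))

        side = math.ceil(math.sqrt(spots_per_layer))
        layer_specs = []
        for li, level in enumerate(levels):
            spacing = float(rng.uniform(3.0, 8.0))
            center = beam_center + rng.uniform(-3.0, 3.0, size=2)
            charges = rng.uniform(charge_range[0], charge_range[1], size=spots_per_layer)
            # trim opening varies with the target cross-section row by row,
            # so aperture moves span the whole 50-1000 ms latency band
            row_radii = 8.0 + 0.1 * level + rng.uniform(0.0, 25.0, size=side)
            layer_specs.append((level, spacing, center, charges, row_radii))

        # low-charge prelude mirrors the first treatment layer's geometry
        first = layer_specs[0]
        emit = [(0, first[0], first[1], first[2], None, first[4])]
        for li, spec in enumerate(layer_specs, start=1):
            level, spacing, center, charges, row_radii = spec
            emit.append((li, level, spacing, center, charges, row_radii))

        for layer_index, level, spacing, center, charges, row_radii in emit:
            positions = []
            for r in range(side):
                cols = range(side) if r % 2 == 0 else range(side - 1, -1, -1)
                for c in cols:
                    positions.append((r, c))
            positions = positions[:spots_per_layer]
            for s, (r, c) in enumerate(positions):
                x = center[0] + (c - (side - 1) / 2.0) * spacing
                y = center[1] + (r - (side - 1) / 2.0) * spacing
                x = float(np.clip(x, -half, half))
                y = float(np.clip(y, -half, half))
                row_y = center[1] + (r - (side - 1) / 2.0) * spacing
                leaves = _aperture_leaves(center[0], float(np.clip(row_y, -half, half)),
                                          float(row_radii[r]), config)
                charge = config.low_charge if charges is None else float(charges[s])
                rec = {
                    "beam_id": beam_id,
                    "layer_index": layer_index,
                    "energy_level": level,
                    "x_mm": round(x, _ROUND),
                    "y_mm": round(y, _ROUND),
                    "charge_pC": round(charge, _ROUND),
                    "is_low_charge": charges is None,
                }
                for col, val in zip(lcols, np.round(leaves.ravel(), _ROUND)):
                    rec[col] = val
                rows.append(rec)
    return pd.DataFrame(rows, columns=plan_columns(config.n_leaves))


def make_repainted_plan(plan: pd.DataFrame, n_repaints: int = 5,
                        config: MachineConfig | None = None) -> pd.DataFrame:
    """Repeat each beam's treatment layer sequence ``n_repaints`` times.

    Volumetric repainting: every pass re-delivers the same descending
    energy-layer sequence, so each repaint boundary is a large upward
    energy jump from the lowest level back to the highest.  The low-charge
    prelude is delivered once, before the first pass.
    """
    if n_repaints < 1:
        raise ValueError("n_repaints must be >= 1")
    config = config or MachineConfig()
    out = []
    for beam_id, beam in plan.groupby("beam_id", sort=False):
        prelude = beam[beam["is_low_charge"]]
        treatment = beam[~beam["is_low_charge"]]
        layer_ids = list(dict.fromkeys(treatment["layer_index"]))
        out.append(prelude)
        out.append(treatment)
        next_layer_index = (max(layer_ids) if layer_ids else 0) + 1
        for _ in range(n_repaints - 1):
            for li in layer_ids:
                layer = treatment[treatment["layer_index"] == li].copy()
                layer["layer_index"] = next_layer_index
                next_layer_index += 1
                out.append(layer)
    return pd.concat(out, ignore_index=True)


def plan_to_pulses(plan: pd.DataFrame, config: MachineConfig | None = None) -> pd.DataFrame:
    """Expand a spot plan into the ordered pulse sequence (no timestamps).

    Pulse indices are contiguous from 1 within each beam.
    """
    config = config or MachineConfig()
    lcols = leaf_columns(config.n_leaves)
    frames = []
    for beam_id, beam in plan.groupby("beam_id", sort=False):
        counts = []
        charges_all = []
        for charge in beam["charge_pC"].to_numpy():
            ch = split_spot_to_pulses(float(charge), config)
            counts.append(len(ch))
            charges_all.append(ch)
        expanded = beam.loc[beam.index.repeat(counts)].reset_index(drop=True)
        expanded["target_charge_pC"] = np.concatenate(charges_all)
        expanded["pulse_index"] = np.arange(1, len(expanded) + 1)
        frames.append(expanded[["beam_id", "pulse_index", "target_charge_pC",
                                "energy_level", "x_mm", "y_mm", "is_low_charge"] + lcols])
    return pd.concat(frames, ignore_index=True)


def _transition_kinematics(pulses: pd.DataFrame, config: MachineConfig) -> pd.DataFrame:
    """Per-transition geometric deltas for one beam's ordered pulse sequence.

    Row ``k`` describes the transition from pulse ``k`` to pulse ``k+1``
    (1-based pulse indices: source ``k``, destination ``k+1``).
    """
    lcols = leaf_columns(config.n_leaves)
    xy = pulses[["x_mm", "y_mm"]].to_numpy(dtype=float)
    leaves = pulses[lcols].to_numpy(dtype=float).reshape(len(pulses), config.n_leaves, 2)
    levels = pulses["energy_level"].to_numpy(dtype=np.int64)
    charge = pulses["target_charge_pC"].to_numpy(dtype=float)
    low = pulses["is_low_charge"].to_numpy(dtype=bool)

    ds = np.hypot(*(np.diff(xy, axis=0).T))
    dleaf = np.diff(leaves, axis=0)
    daa = np.hypot(dleaf[..., 0], dleaf[..., 1]).sum(axis=1)
    de = np.diff(levels)
    occ = _occupancy_table(config)
    plates = np.sum(occ[levels[1:]] != occ[levels[:-1]], axis=1)
    dq = np.diff(charge)
    is_tx = low[:-1] & ~low[1:]
    is_first = np.zeros(len(ds), dtype=bool)
    if len(is_first):
        is_first[0] = True
    return pd.DataFrame({
        "ds_mm": ds,
        "daa_mm": daa,
        "de_levels": de,
        "plates_moved": plates,
        "dq_pc": dq,
        "charge_pc": charge[1:],
        "is_first_pulse": is_first,
        "is_tx_pulse": is_tx,
    })


def _deterministic_dt_from_kin(kin: pd.DataFrame, config: MachineConfig) -> np.ndarray:
    t = config.timing
    daa = kin["daa_mm"].to_numpy(dtype=float)
    de = kin["de_levels"].to_numpy()
    dt = (
        t.t_base
        + t.t_spot_per_mm * kin["ds_mm"].to_numpy(dtype=float)
        + t.t_charge_per_pc * np.abs(kin["dq_pc"].to_numpy(dtype=float))
        + (daa > 0) * (t.t_aa_latency + t.t_aa_per_mm * daa)
        + (de != 0) * (t.t_energy_latency + t.t_plate * kin["plates_moved"].to_numpy(dtype=float))
        + t.t_tx_extra * kin["is_tx_pulse"].to_numpy(dtype=float)
        + t.t_first_extra * kin["is_first_pulse"].to_numpy(dtype=float)
    )
    return dt


def deterministic_delta_t(prev, next, config: MachineConfig | None = None,
                          is_first: bool = False) -> float:
    """Deterministic inter-pulse time (ms) between two pulse records.

    ``prev`` and ``next`` are mappings/Series carrying the log columns
    (position, leaf coordinates, energy level, charge, low-charge flag).
    """
    config = config or MachineConfig()
    pulses = pd.DataFrame([dict(prev), dict(next)])
    if "target_charge_pC" not in pulses:
        pulses["target_charge_pC"] = pulses["charge_pC"] if "charge_pC" in pulses else 0.0
    if "is_low_charge" not in pulses:
        pulses["is_low_charge"] = False
    kin = _transition_kinematics(pulses, config)
    kin.loc[0, "is_first_pulse"] = is_first
    return float(_deterministic_dt_from_kin(kin, config)[0])


def _noisy_delta_t(dt_det: np.ndarray, rng: np.random.Generator,
                   config: MachineConfig) -> np.ndarray:
    nz = config.noise
    sigma = nz.sigma_floor + nz.sigma_rel * dt_det
    noise = rng.normal(0.0, 1.0, size=dt_det.shape) * sigma
    outlier = rng.random(dt_det.shape) < nz.outlier_prob
    noise = noise + outlier * rng.exponential(nz.outlier_scale, size=dt_det.shape)
    return np.maximum(dt_det + noise, 0.5)


def simulate_fraction(plan: pd.DataFrame, seed: int,
                      config: MachineConfig | None = None,
                      fraction_id: str = "f01") -> pd.DataFrame:
    """Deliver ``plan`` once, returning a pulse log with noisy timestamps.

    Timestamps are cumulative sums of the deterministic inter-pulse times
    plus heteroscedastic noise, truncated so every interval stays positive;
    the first pulse of each beam is at t = 0.
    """
    if plan.empty:
        raise ValueError("plan is empty")
    config = config or MachineConfig()
    rng = np.random.default_rng(seed)
    frames = []
    for beam_id, pulses in plan_to_pulses(plan, config).groupby("beam_id", sort=False):
        pulses = pulses.reset_index(drop=True)
        kin = _transition_kinematics(pulses, config)
        dt = _noisy_delta_t(_deterministic_dt_from_kin(kin, config), rng, config)
        ts = np.concatenate([[0.0], np.cumsum(dt)])
        pulses.insert(0, "fraction_id", fraction_id)
        pulses.insert(3, "timestamp_ms", np.round(ts, _ROUND))
        frames.append(pulses)
    log = pd.concat(frames, ignore_index=True)
    return log[log_columns(config.n_leaves)]


def simulate_course(plan: pd.DataFrame, n_fractions: int, seed: int,
                    config: MachineConfig | None = None) -> pd.DataFrame:
    """Deliver ``plan`` over several fractions with independent noise.

    The pulse sequence is identical across fractions; only timestamps vary.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be >= 1")
    config = config or MachineConfig()
    frames = []
    for k in range(n_fractions):
        sub_seed = np.random.SeedSequence([seed, k]).generate_state(1)[0] % (2**31 - 1)
        frames.append(simulate_fraction(plan, int(sub_seed), config,
                                        fraction_id=f"f{k + 1:02d}"))
    return pd.concat(frames, ignore_index=True)
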