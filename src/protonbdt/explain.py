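"""Shapley-value explainability for the delivery-time forest.

Two independent routes compute the same quantity:

* :func:`exact_shapley` — brute-force enumeration of the Shapley formula
  phi_i = sum over coalitions S of |S|!(n-|S|-1)!/n! (f(S u {i}) - f(S)),
  feasible up to 15 features;
* :func:`tree_shap` — a polynomial-time tree-structure algorithm for
  random forests.

Both use the *interventional* value function: f(S) is the mean model
output over a background set, with features in S taken from the instance
being explained and the rest from each background row.  For a single tree
and a single (instance, background-row) pair, a leaf is reached by such a
hybrid input iff the features where the instance and the background row
part ways on the leaf's path (sets A: instance-side, B: background-side)
satisfy A ⊆ S and B ∩ S = ∅.  The Shapley value of that indicator game has
the closed form

    phi_i = v * (a-1)! b! / (a+b)!    for i in A,
    phi_i = -v * a! (b-1)! / (a+b)!   for i in B,

with a = |A|, b = |B| and leaf value v (features outside A ∪ B are null
players).  Summing over leaves, trees and background rows gives exact
interventional Shapley values in time polynomial in the tree size.

Attributions are reported in the model's native output space (the log1p
target), so additivity phi_0 + sum_i phi_i = prediction holds exactly.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import Pipeline

from .model import DEFAULT_BINS

__all__ = [
    "Attribution",
    "DEFAULT_GROUPS",
    "exact_shapley",
    "tree_shap",
    "group_attributions",
    "importance_summary",
    "sample_for_explanation",
]

#: Physical feature groups: aperture, spot travel, charge, energy, flags.
DEFAULT_GROUPS: dict[str, list[str]] = {
    "aa": ["log_daa"],
    "spot": ["log_ds"],
    "charge": ["charge", "delta_charge"],
    "energy": ["delta_e", "log_de"],
    "boolean": ["is_first_pulse", "is_tx_pulse"],
}

_MAX_EXACT_FEATURES = 15


@dataclass
class Attribution:
    """Per-instance additive feature attributions.

    ``base_value + phi.sum(axis=1) == prediction`` for every instance.
    """

    feature_names: list[str]
    base_value: float
    phi: np.ndarray         # (n_instances, n_features)
    prediction: np.ndarray  # (n_instances,)

    def additivity_gap(self) -> np.ndarray:
        return self.base_value + self.phi.sum(axis=1) - self.prediction


def exact_shapley(predict_fn, instance, background) -> np.ndarray:
    """Brute-force Shapley values of one instance by coalition enumeration.

    ``predict_fn`` maps an (m, d) array to (m,) outputs; ``background`` is
    the (m, d) reference set of the interventional value function.
    """
    x = np.asarray(instance, dtype=float).ravel()
    Z = np.asarray(background, dtype=float)
    if Z.ndim != 2 or Z.shape[1] != x.size:
        raise ValueError("background must be (m, d) matching the instance")
    if Z.shape[0] == 0:
        raise ValueError("background must be non-empty")
    d = x.size
    if d > _MAX_EXACT_FEATURES:
        raise ValueError(f"exact enumeration is limited to {_MAX_EXACT_FEATURES} features")

    fS = np.empty(2 ** d)
    for mask in range(2 ** d):
        hybrid = Z.copy()
        for i in range(d):
            if mask >> i & 1:
                hybrid[:, i] = x[i]
        fS[mask] = float(np.mean(predict_fn(hybrid)))

    fact = [math.factorial(k) for k in range(d + 1)]
    phi = np.zeros(d)
    full = (1 << d) - 1
    for i in range(d):
        rest = full & ~(1 << i)
        # iterate over all subsets of rest
        S = rest
        while True:
            s = bin(S).count("1")
            w = fact[s] * fact[d - s - 1] / fact[d]
            phi[i] += w * (fS[S | (1 << i)] - fS[S])
            if S == 0:
                break
            S = (S - 1) & rest
    return phi


def _as_forest(model) -> tuple[RandomForestRegressor, object | None]:
    if isinstance(model, Pipeline):
        return model.named_steps["forest"], model.named_steps["scale"]
    if isinstance(model, RandomForestRegressor):
        return model, None
    raise TypeError("tree attribution supports a RandomForestRegressor or a "
                    "(scale, forest) pipeline")


def tree_shap(model, X, background,
              feature_names: list[str] | None = None) -> Attribution:
    """Exact interventional Shapley values for a random forest.

    Accepts the fitted (scale, forest) pipeline or a bare forest.  Scaling
    is per-feature and strictly monotone, so mixing instance and background
    features commutes with it and the attributions agree with
    :func:`exact_shapley` run on the full pipeline in the original space.
    """
    forest, scaler = _as_forest(model)
    if feature_names is None:
        feature_names = (list(X.columns) if isinstance(X, pd.DataFrame)
                         else [f"x{i}" for i in range(np.asarray(X).shape[1])])
    Xs = scaler.transform(X) if scaler is not None else np.asarray(X, dtype=float)
    Zs = scaler.transform(background) if scaler is not None else np.asarray(
        background, dtype=float)
    Xs = np.asarray(Xs, dtype=float)
    Zs = np.asarray(Zs, dtype=float)
    if len(Zs) == 0:
        raise ValueError("background must be non-empty")

    nf, d = Xs.shape
    nb = Zs.shape[0]
    fact = np.array([math.factorial(k) for k in range(2 * d + 1)], dtype=float)
    # weight tables indexed by (a, b); undefined entries stay 0
    wa = np.zeros((d + 1, d + 1))
    wb = np.zeros((d + 1, d + 1))
    for a in range(d + 1):
        for b in range(d + 1):
            if a >= 1:
                wa[a, b] = fact[a - 1] * fact[b] / fact[a + b]
            if b >= 1:
                wb[a, b] = fact[a] * fact[b - 1] / fact[a + b]

    phi = np.zeros((nf, nb, d))
    for est in forest.estimators_:
        _tree_interventional(est.tree_, Xs, Zs, phi, wa, wb)
    phi /= len(forest.estimators_)

    base = float(np.mean(forest.predict(Zs)))
    prediction = forest.predict(Xs)
    return Attribution(list(feature_names), base, phi.mean(axis=1), prediction)


def _tree_interventional(tree, Xs, Zs, phi, wa, wb) -> None:
    left = tree.children_left
    right = tree.children_right
    feat = tree.feature
    thr = tree.threshold
    vals = tree.value[:, 0, 0]
    nf, nb = Xs.shape[0], Zs.shape[0]

    def rec(node: int, alive: np.ndarray, labels: dict, a: np.ndarray,
            b: np.ndarray) -> None:
        if left[node] == -1:  # leaf
            v = vals[node]
            for f, lab in labels.items():
                ma = alive & (lab == 1)
                if ma.any():
                    phi[:, :, f][ma] += v * wa[a[ma], b[ma]]
                mb = alive & (lab == 2)
                if mb.any():
                    phi[:, :, f][mb] -= v * wb[a[mb], b[mb]]
            return
        f = feat[node]
        xl = Xs[:, f] <= thr[node]
        zl = Zs[:, f] <= thr[node]
        prev = labels.get(f)
        for child, xgo, zgo in ((left[node], xl, zl),
                                (right[node], ~xl, ~zl)):
            onlyx = xgo[:, None] & ~zgo[None, :]
            onlyz = ~xgo[:, None] & zgo[None, :]
            new_alive = alive & (xgo[:, None] | zgo[None, :])
            if prev is not None:
                # a feature already pinned to one side cannot switch sides
                new_alive = new_alive & ~(onlyx & (prev == 2)) & ~(onlyz & (prev == 1))
            if not new_alive.any():
                continue
            lab = prev.copy() if prev is not None else np.zeros((nf, nb), np.int8)
            add_a = onlyx & (lab == 0) & new_alive
            add_b = onlyz & (lab == 0) & new_alive
            lab[add_a] = 1
            lab[add_b] = 2
            new_labels = dict(labels)
            new_labels[f] = lab
            rec(child, new_alive, new_labels,
                a + add_a.astype(np.int8), b + add_b.astype(np.int8))

    alive0 = np.ones((nf, nb), dtype=bool)
    zeros = np.zeros((nf, nb), dtype=np.int8)
    rec(0, alive0, {}, zeros.copy(), zeros.copy())


def group_attributions(attr: Attribution, grouping: dict[str, list[str]]
                       ) -> Attribution:
    """Sum member attributions into named groups (additivity preserved)."""
    members = [f for fs in grouping.values() for f in fs]
    if sorted(members) != sorted(attr.feature_names):
        missing = set(attr.feature_names) - set(members)
        extra = set(members) - set(attr.feature_names)
        raise ValueError("grouping must partition the feature set "
                         f"(missing: {sorted(missing)}, unknown: {sorted(extra)})")
    idx = {f: i for i, f in enumerate(attr.feature_names)}
    names = list(grouping)
    phi_g = np.column_stack([
        attr.phi[:, [idx[f] for f in grouping[g]]].sum(axis=1) for g in names])
    return Attribution(names, attr.base_value, phi_g, attr.prediction)


def importance_summary(attr: Attribution, predicted_dt_ms,
                       bins=DEFAULT_BINS) -> dict:
    """Global and per-interval importance of (grouped) attributions.

    Global importance is the mean |phi| over instances; per-interval
    importance is the max |phi| among the instances whose *predicted*
    inter-pulse time falls in each bin.
    """
    if len(attr.prediction) == 0:
        raise ValueError("attributions are empty")
    pred = np.asarray(predicted_dt_ms, dtype=float)
    absphi = np.abs(attr.phi)
    global_mean = pd.Series(absphi.mean(axis=0), index=attr.feature_names,
                            name="mean_abs_phi")
    edges = np.asarray(bins, dtype=float)
    rows = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (pred >= lo) & (pred < hi)
        row = {"bin_lo_ms": lo, "bin_hi_ms": hi, "count": int(m.sum())}
        for j, name in enumerate(attr.feature_names):
            row[name] = float(absphi[m, j].max()) if m.any() else np.nan
        rows.append(row)
    return {"global_mean_abs": global_mean,
            "per_bin_max_abs": pd.DataFrame(rows)}


def sample_for_explanation(table: pd.DataFrame, n: int = 100,
                           seed: int = 0) -> pd.DataFrame:
    """Draw an explanation set spanning the target range.

    Stratified across quantile bins of the log target so short, medium and
    long intervals are all represented.
    """
    if len(table) <= n:
        if len(table) < n:
            warnings.warn(f"table has only {len(table)} rows (< {n}); using all",
                          stacklevel=2)
        return table.copy()
    n_strata = min(10, n)
    bins = pd.qcut(table["log_delta_t"], q=n_strata, labels=False, duplicates="drop")
    rng = np.random.default_rng(seed)
    per = np.full(bins.nunique(), n // bins.nunique())
    per[:n - per.sum()] += 1
    picks = []
    for q, k in zip(sorted(bins.unique()), per):
        pool = table.index[bins == q].to_numpy()
        picks.append(rng.choice(pool, size=min(k, len(pool)), replace=False))
    idx = np.concatenate(picks)
    return table.loc[np.sort(idx)]
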