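"""Supervised sample windows for glucose-band forecasting.

Each sample anchors at a grid time t and collects, per the forecasting
model's variable sets:

* ``g0..gk``   — glucose now and k lags back: g_j = G(t - j*dt) [mmol/L]
* ``i0..ih``   — plasma insulin now and h leads ahead: i_j = I(t + j*dt)
* ``c0..ch``   — carbohydrate absorption now and h leads: c_j = C(t + j*dt)
* ``dg1..dgk`` — current-minus-past differences dg_j = G(t) - G(t - j*dt)
* ``target_glucose`` = G(t + h*dt) and its band ``target_class``

Defaults k=12, h=6 on a 5-minute grid give a 60-minute history and a
30-minute forecasting horizon.  Windows touching any missing glucose
reading (history or target) are discarded entirely — missing data is
never imputed.  The insulin/carb leads are known at prediction time
because dosing and announced meals are logged prospectively.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bands import classify
from .series import PatientSeries

DEFAULT_K = 12
DEFAULT_H = 6


def feature_columns(k: int = DEFAULT_K, h: int = DEFAULT_H) -> list[str]:
    """Ordered model-input column names for given history/horizon sizes."""
    return ([f"g{j}" for j in range(k + 1)]
            + [f"i{j}" for j in range(h + 1)]
            + [f"c{j}" for j in range(h + 1)]
            + [f"dg{j}" for j in range(1, k + 1)])


def build_samples(series: PatientSeries,
                  insulin: np.ndarray,
                  carbs: np.ndarray,
                  k: int = DEFAULT_K,
                  h: int = DEFAULT_H) -> pd.DataFrame:
    """Build the per-anchor sample table for one patient.

    ``insulin`` and ``carbs`` must be the absorption signals evaluated on
    the same grid as ``series``.  One row per anchor index a in
    [k, n-1-h] whose k+1 past glucose readings and target reading are all
    present; the ``split`` tag is inherited from the anchor timestamp.
    """
    if k <= 0 or h <= 0:
        raise ValueError("k and h must be positive")
    g = series.glucose
    n = len(g)
    insulin = np.asarray(insulin, dtype=float)
    carbs = np.asarray(carbs, dtype=float)
    if insulin.shape != g.shape or carbs.shape != g.shape:
        raise ValueError("signals must live on the series grid")
    if n < k + h + 1:
        return _empty_frame(k, h)

    anchors = np.arange(k, n - h)
    ok = np.isfinite(g[anchors + h])
    for j in range(k + 1):
        ok &= np.isfinite(g[anchors - j])
    anchors = anchors[ok]
    if len(anchors) == 0:
        return _empty_frame(k, h)

    data: dict[str, np.ndarray] = {"t": series.t[anchors]}
    for j in range(k + 1):
        data[f"g{j}"] = g[anchors - j]
    for j in range(h + 1):
        data[f"i{j}"] = insulin[anchors + j]
    for j in range(h + 1):
        data[f"c{j}"] = carbs[anchors + j]
    for j in range(1, k + 1):
        data[f"dg{j}"] = g[anchors] - g[anchors - j]
    target = g[anchors + h]
    data["target_glucose"] = target
    data["target_class"] = classify(target)
    if series.split is not None:
        data["split"] = series.split[anchors]
    else:
        data["split"] = np.array(["train"] * len(anchors), dtype=object)
    return pd.DataFrame(data)


def _empty_frame(k: int, h: int) -> pd.DataFrame:
    cols = (["t"] + feature_columns(k, h)
            + ["target_glucose", "target_class", "split"])
    return pd.DataFrame({c: [] for c in cols})


def preprocess_series(series: PatientSeries, params=None,
                      k: int = DEFAULT_K, h: int = DEFAULT_H) -> pd.DataFrame:
    """Full preprocessing for one patient: align events to the glucose
    grid, run the absorption models, and window into samples."""
    from .absorption import (AbsorptionParams, align_events, carb_signal,
                             insulin_signal)

    params = params or AbsorptionParams()
    ins = align_events(series.insulin_events, series.t)
    meals = align_events(series.meal_events, series.t)
    insulin = insulin_signal(ins, params, series.t)
    carbs = carb_signal(meals, params, series.t)
    return build_samples(series, insulin, carbs, k=k, h=h)


def train_test_split(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split a sample table on its inherited chronological split tags."""
    return (samples[samples["split"] == "train"].reset_index(drop=True),
            samples[samples["split"] == "test"].reset_index(drop=True))
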