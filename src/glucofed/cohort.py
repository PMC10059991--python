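"""Cohort input/output and the synthetic patient generator.

Three ways to obtain :class:`~glucofed.series.PatientSeries` objects:

* :func:`read_ohio_xml` — an OhioT1DM-style XML reader (``glucose_level``
  / ``bolus`` / ``basal`` / ``meal`` elements holding ``event`` children
  with ``ts``/``value`` attributes).  The real data set is
  access-restricted and is never bundled; the reader exists so the
  pipeline can run on it when a user has access.
* :func:`read_csv` / :func:`write_csv` — the package's internal
  plain-text per-patient format (one row per grid timestamp).
* :func:`simulate_patient` / :func:`simulate_cohort` — a synthetic
  generator that emulates the structure of real CGM records: 5-minute
  grid, glucose confined to [2, 25] mmol/L, meal/bolus/basal events,
  missing readings and hypo-poor class imbalance.

The synthetic glucose dynamics are a deliberately simple linear-response
model driven by the same absorption signals the forecaster sees:

    G(t+dt) = G(t) + alpha*C(t) - beta*I(t) + gamma*(G_b - G(t)) + noise

clipped to [2, 25] mmol/L.  This is not a full physiological
glucoregulatory model; it is the minimal dynamics with learnable
structure (meals push glucose up through C, insulin pulls it down
through I, and it mean-reverts to a basal level), with per-patient
coefficients drawn from configured ranges so that the patients form
distinct but related forecasting tasks.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from xml.etree import ElementTree

import numpy as np

from .absorption import AbsorptionParams, carb_signal, insulin_signal
from .bands import MGDL_PER_MMOLL
from .series import EventRecord, PatientSeries, assign_split

GLUCOSE_MIN, GLUCOSE_MAX = 2.0, 25.0


@dataclass(frozen=True)
class CohortConfig:
    """Synthetic cohort parameters.

    Ranges given as (lo, hi) tuples are drawn once per patient, giving
    the cohort its heterogeneity; scalars are shared by all patients.

    alpha : glucose rise per gram of absorbed carbohydrate
            [mmol/L per g], applied to C(t)
    beta  : glucose drop per unit plasma insulin
            [mmol/L per mU/L], applied to I(t)
    gamma : per-step mean-reversion fraction towards basal glucose
    dose_per_gram : bolus size per gram of meal carbohydrate [mU/g]
    basal_rate : background infusion [mU/min]
    """

    n_patients: int = 6
    days: float = 7.0
    seed: int = 0
    delta_t: int = 5
    basal_glucose: tuple[float, float] = (5.5, 9.5)
    meal_rate: float = 3.0                      # meals per day
    meal_carbs: tuple[float, float] = (30.0, 120.0)   # grams
    # dosing is expressed on the same arbitrary per-kg scale as the
    # insulin signal itself, chosen so I(t) spans roughly [0, 10] mU/L
    dose_per_gram: tuple[float, float] = (0.05, 0.18)  # mU per g carbohydrate
    basal_rate: tuple[float, float] = (0.002, 0.005)   # mU/min
    noise_sd: float = 0.15                      # mmol/L per step
    missing_rate: float = 0.05
    # alpha/beta are balanced so a carb-matched bolus roughly cancels its
    # meal: total rise per meal ~ alpha*Dg*A_g/dt, total drop per bolus
    # ~ beta*dose/(V_I*k_e*dt); the ranges leave each patient a little
    # over- or under-dosed, which is what creates the band excursions.
    alpha: tuple[float, float] = (0.5, 0.9)
    beta: tuple[float, float] = (0.04, 0.08)
    gamma: tuple[float, float] = (0.01, 0.02)
    absorption: AbsorptionParams = field(default_factory=AbsorptionParams)

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.days <= 0 or self.delta_t <= 0:
            raise ValueError("n_patients, days and delta_t must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.meal_rate < 0 or self.noise_sd < 0:
            raise ValueError("meal_rate and noise_sd must be non-negative")
        for name in ("basal_glucose", "meal_carbs", "dose_per_gram",
                     "basal_rate", "alpha", "beta", "gamma"):
            val = getattr(self, name)
            lo, hi = self._range(val)
            if not (np.isfinite(lo) and np.isfinite(hi) and lo <= hi):
                raise ValueError(f"invalid range for {name}: {val}")

    @staticmethod
    def _range(val) -> tuple[float, float]:
        if np.isscalar(val):
            return float(val), float(val)
        lo, hi = val
        return float(lo), float(hi)


def _draw(rng: np.random.Generator, val) -> float:
    lo, hi = CohortConfig._range(val)
    return lo if lo == hi else float(rng.uniform(lo, hi))


def integrate_glucose(g0: float, C: np.ndarray, I: np.ndarray,
                      alpha: float, beta: float, gamma: float,
                      g_basal: float, noise: np.ndarray) -> np.ndarray:
    """Step the linear-response glucose update over the grid.

    G(t+dt) = clip(G(t) + alpha*C(t) - beta*I(t) + gamma*(G_b - G(t))
                   + noise(t), 2, 25)
    """
    n = len(C)
    g = np.empty(n)
    g[0] = g0
    for i in range(n - 1):
        step = alpha * C[i] - beta * I[i] + gamma * (g_basal - g[i]) + noise[i]
        g[i + 1] = np.clip(g[i] + step, GLUCOSE_MIN, GLUCOSE_MAX)
    return g


def simulate_patient(config: CohortConfig, patient_index: int) -> PatientSeries:
    """Generate one synthetic patient, deterministic in (seed, patient_index).

    Meals follow a Poisson daily schedule with uniform carbohydrate
    sizes; each meal triggers a bolus through the patient's carb-dose
    policy; the basal infusion is constant.  Glucose then evolves by the
    linear-response update documented in the module docstring and a
    ``missing_rate`` fraction of readings is deleted (marked NaN).
    """
    rng = np.random.default_rng([config.seed, patient_index])
    dt = config.delta_t
    n = int(round(config.days * 24 * 60 / dt))
    grid = np.arange(n, dtype=np.int64) * dt

    g_b = _draw(rng, config.basal_glucose)
    dose_per_g = _draw(rng, config.dose_per_gram)
    basal = _draw(rng, config.basal_rate)
    alpha = _draw(rng, config.alpha)
    beta = _draw(rng, config.beta)
    gamma = _draw(rng, config.gamma)
    for name, v in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not np.isfinite(v):
            raise ValueError(f"non-finite dynamics coefficient {name}")

    n_meals = min(rng.poisson(config.meal_rate * config.days), n)
    meal_times = np.sort(rng.choice(n, size=n_meals, replace=False)) * dt
    lo, hi = CohortConfig._range(config.meal_carbs)
    meal_sizes = rng.uniform(lo, hi, size=n_meals)

    meal_events = [EventRecord(int(t), "meal", float(s))
                   for t, s in zip(meal_times, meal_sizes)]
    insulin_events = [EventRecord(0, "basal", basal)]
    insulin_events += [EventRecord(int(t), "bolus", float(s * dose_per_g))
                       for t, s in zip(meal_times, meal_sizes)]

    C = carb_signal(meal_events, config.absorption, grid)
    I = insulin_signal(insulin_events, config.absorption, grid)

    noise = (rng.normal(0.0, config.noise_sd, size=n)
             if config.noise_sd > 0 else np.zeros(n))
    g = integrate_glucose(g_b, C, I, alpha, beta, gamma, g_b, noise)

    if config.missing_rate > 0:
        drop = rng.random(n) < config.missing_rate
        g[drop] = np.nan

    return PatientSeries(
        patient_id=f"sim{patient_index:03d}",
        delta_t=dt,
        t=grid,
        glucose=g,
        insulin_events=insulin_events,
        meal_events=meal_events,
    )


def simulate_cohort(config: CohortConfig,
                    test_fraction: float = 0.2) -> list[PatientSeries]:
    """Generate the whole cohort with a chronological train/test split."""
    return [assign_split(simulate_patient(config, i), test_fraction)
            for i in range(config.n_patients)]


# ---------------------------------------------------------------------------
# OhioT1DM-style XML
# ---------------------------------------------------------------------------

_XML_SECTIONS = {"glucose_level": "glucose", "bolus": "bolus",
                 "basal": "basal", "meal": "meal"}


def _parse_events(root, tag: str) -> list[tuple[int, float]]:
    out = []
    for section in root.iter(tag):
        for ev in section.iter("event"):
            ts, value = ev.get("ts"), ev.get("value")
            if ts is None or value is None:
                raise ValueError(
                    f"<event> under <{tag}> is missing ts/value attributes")
            try:
                out.append((int(ts), float(value)))
            except ValueError as exc:
                raise ValueError(
                    f"malformed <event> under <{tag}>: ts={ts!r} "
                    f"value={value!r}") from exc
    return out


def read_ohio_xml(path, glucose_unit: str = "mg/dL",
                  delta_t: int = 5) -> PatientSeries:
    """Read a patient record in the OhioT1DM-style XML dialect.

    Timestamps are integer minutes; glucose is assumed mg/dL (the CGM
    convention of the source data) and converted to mmol/L on ingest
    unless ``glucose_unit="mmol/L"`` is passed.  If the file wraps its
    sections in ``<training>``/``<testing>`` elements, the split is taken
    from the file; otherwise no split is assigned.
    """
    if glucose_unit not in ("mg/dL", "mmol/L"):
        raise ValueError(f"unknown glucose unit {glucose_unit!r}")
    try:
        tree = ElementTree.parse(str(path))
    except ElementTree.ParseError as exc:
        raise ValueError(f"malformed XML in {path}: {exc}") from exc
    root = tree.getroot()
    patient_id = root.get("id", Path(str(path)).stem)

    sections = [c for c in root if c.tag in ("training", "testing")]
    scopes = sections if sections else [root]

    glucose_pairs: list[tuple[int, float]] = []
    split_tags: list[str] = []
    insulin_events: list[EventRecord] = []
    meal_events: list[EventRecord] = []
    for scope in scopes:
        tag = "test" if scope.tag == "testing" else "train"
        g_pairs = _parse_events(scope, "glucose_level")
        glucose_pairs += g_pairs
        split_tags += [tag] * len(g_pairs)
        for ts, v in _parse_events(scope, "bolus"):
            insulin_events.append(EventRecord(ts, "bolus", v))
        for ts, v in _parse_events(scope, "basal"):
            insulin_events.append(EventRecord(ts, "basal", v))
        for ts, v in _parse_events(scope, "meal"):
            meal_events.append(EventRecord(ts, "meal", v))

    if not glucose_pairs:
        raise ValueError(f"no glucose_level events found in {path}")
    t = np.array([p[0] for p in glucose_pairs], dtype=np.int64)
    g = np.array([p[1] for p in glucose_pairs], dtype=float)
    if glucose_unit == "mg/dL":
        g = g / MGDL_PER_MMOLL
    split = (np.array(split_tags, dtype=object) if sections else None)
    return PatientSeries(patient_id, delta_t, t, g,
                         insulin_events, meal_events, split)


# ---------------------------------------------------------------------------
# Internal CSV format
# ---------------------------------------------------------------------------

_CSV_HEADER = ["t", "glucose", "bolus", "basal", "meal", "split"]


def write_csv(series: PatientSeries, path) -> None:
    """Write the internal per-patient CSV: one row per grid timestamp.

    Off-grid event values would be unrepresentable; events are stored on
    their own timestamps' rows (multiple same-kind events on one
    timestamp are summed for bolus/meal; basal keeps the last rate).
    """
    by_t: dict[int, dict[str, float]] = {}
    for ev in series.insulin_events + series.meal_events:
        slot = by_t.setdefault(ev.timestamp, {})
        if ev.kind == "basal":
            slot["basal"] = ev.value
        else:
            slot[ev.kind] = slot.get(ev.kind, 0.0) + ev.value
    grid = set(int(t) for t in series.t)
    stray = [t for t in by_t if t not in grid]
    if stray:
        raise ValueError(f"events off the glucose grid at t={sorted(stray)[:5]}")

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow([f"# patient_id={series.patient_id}",
                    f"delta_t={series.delta_t}"])
        w.writerow(_CSV_HEADER)
        for i, t in enumerate(series.t):
            slot = by_t.get(int(t), {})
            g = series.glucose[i]
            w.writerow([
                int(t),
                "" if np.isnan(g) else repr(float(g)),
                _fmt(slot.get("bolus")),
                _fmt(slot.get("basal")),
                _fmt(slot.get("meal")),
                "" if series.split is None else series.split[i],
            ])


def _fmt(v) -> str:
    return "" if v is None else repr(float(v))


def read_csv(path) -> PatientSeries:
    """Read the internal CSV back into a PatientSeries (round-trip safe)."""
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    if len(rows) < 2 or not rows[0] or not rows[0][0].startswith("# patient_id="):
        raise ValueError(f"{path} is not a glucofed patient CSV")
    patient_id = rows[0][0].split("=", 1)[1]
    delta_t = int(rows[0][1].split("=", 1)[1])
    if rows[1] != _CSV_HEADER:
        raise ValueError(f"unexpected header {rows[1]} in {path}")

    t, g, split = [], [], []
    insulin_events: list[EventRecord] = []
    meal_events: list[EventRecord] = []
    for row in rows[2:]:
        if not row:
            continue
        ts = int(row[0])
        t.append(ts)
        g.append(float(row[1]) if row[1] else np.nan)
        if row[2]:
            insulin_events.append(EventRecord(ts, "bolus", float(row[2])))
        if row[3]:
            insulin_events.append(EventRecord(ts, "basal", float(row[3])))
        if row[4]:
            meal_events.append(EventRecord(ts, "meal", float(row[4])))
        split.append(row[5])
    has_split = any(s for s in split)
    return PatientSeries(
        patient_id, delta_t,
        np.array(t, dtype=np.int64), np.array(g, dtype=float),
        insulin_events, meal_events,
        np.array(split, dtype=object) if has_split else None,
    )
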