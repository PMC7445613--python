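"""Bundled per-subject respiration-rate cohorts.

Three small reference datasets of paired per-minute respiration counts ship
with the package and power the worked examples and golden tests:

* ``load_belt_accel`` — 30 adults measured simultaneously with a chest belt
  (reference) and the smartphone-accelerometer pipeline;
* ``load_placement`` — 10 subjects with the phone placed next to the left
  shoulder vs under the left foot;
* ``load_phone`` — 10 subjects measured with two different phone models.

Each loader returns an :class:`~accelresp.evalstats.RRComparison` with the
reference (or first) condition as ``rr_a``.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .evalstats import RRComparison

__all__ = ["load_belt_accel", "load_placement", "load_phone"]


def _load(name: str, col_a: str, col_b: str) -> RRComparison:
    path = resources.files("accelresp").joinpath("data", name)
    with resources.as_file(path) as fp:
        df = pd.read_csv(fp)
    return RRComparison(
        labels=df["subject"].tolist(),
        rr_a=df[col_a].to_numpy(dtype=float),
        rr_b=df[col_b].to_numpy(dtype=float),
    )


def load_belt_accel() -> RRComparison:
    """Chest belt (a) vs accelerometer pipeline (b), 30 subjects."""
    return _load("cohort_belt_accel.csv", "belt", "accel")


def load_placement() -> RRComparison:
    """Phone by the shoulder (a) vs under the foot (b), 10 subjects."""
    return _load("cohort_placement.csv", "shoulder", "foot")


def load_phone() -> RRComparison:
    """Phone model 1 (a) vs phone model 2 (b), 10 subjects."""
    return _load("cohort_phone.csv", "phone1", "phone2")
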