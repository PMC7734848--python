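"""Synthetic cohorts and virtual patients.

Real cohort tables of this kind are small (a handful of subjects per
group) with strictly positive, heavily right-skewed analyte counts —
blood IFNg-producing cells span more than an order of magnitude across
MS patients.  The generator models each analyte as an independent
log-normal within each group (moment-matched on the log scale), which
reproduces positivity and skew; it makes no attempt at inter-analyte
correlation or longitudinal structure.

Virtual patients provide ground truth for parameter-recovery tests: a
known rate-constant configuration is pushed through the deterministic
readout, multiplicative log-normal observation noise is applied, and the
result is used as a calibration target whose fitted activation constants
can be compared against the truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import calibration, rrms
from .calibration import ANALYTES, CalibrationTargets

__all__ = ["CohortGeneratorSpec", "VirtualPatientSpec", "fit_generator",
           "sample_cohort", "virtual_patient_targets"]


@dataclass
class CohortGeneratorSpec:
    """Per-group, per-analyte log-scale location and scale.

    ``location[group][analyte]`` is the mean of log(count) and
    ``scale[group][analyte]`` its standard deviation (>= 0).
    """

    location: dict
    scale: dict
    groups: tuple = ("MS", "HD")

    def __post_init__(self) -> None:
        for g in self.groups:
            for a in ANALYTES:
                if self.scale[g][a] < 0:
                    raise ValueError(f"scale[{g}][{a}] < 0")


def fit_generator(table: pd.DataFrame) -> CohortGeneratorSpec:
    """Log-scale moment matching per group and analyte.

    Raises on non-positive analyte entries (the log-normal family is
    supported on the strictly positive reals).
    """
    loc: dict = {}
    scale: dict = {}
    groups = tuple(table["group"].unique())
    for g in groups:
        rows = table[table["group"] == g]
        if len(rows) < 2:
            raise ValueError(f"group {g!r} needs >= 2 subjects")
        loc[g], scale[g] = {}, {}
        for a in ANALYTES:
            vals = rows[a].to_numpy(dtype=float)
            if np.any(vals <= 0):
                raise ValueError(f"non-positive value in {g}/{a}")
            logs = np.log(vals)
            loc[g][a] = float(np.mean(logs))
            scale[g][a] = float(np.std(logs, ddof=1))
    return CohortGeneratorSpec(location=loc, scale=scale, groups=groups)


def sample_cohort(spec: CohortGeneratorSpec, n: int, group: str,
                  seed: int = 0) -> pd.DataFrame:
    """Draw ``n`` synthetic subjects of one group (deterministic per seed)."""
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    data = {"subject_id": [f"{group}{i + 1:02d}" for i in range(n)],
            "group": [group] * n}
    for a in ANALYTES:
        draws = rng.lognormal(spec.location[group][a], spec.scale[group][a],
                              size=n)
        data[a] = np.round(draws, 2)
    return pd.DataFrame(data)


@dataclass
class VirtualPatientSpec:
    """Ground-truth configuration for one synthetic group readout.

    ``params`` is the full rate-constant table (including the group's two
    activation constants); ``sigma`` is the log-scale standard deviation
    of multiplicative observation noise on the readout.
    """

    params: rrms.ParameterSet
    sigma: float = 0.0
    seed: int = 0
    group: str = "virtual"

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


def virtual_patient_targets(spec: VirtualPatientSpec) -> CalibrationTargets:
    """Noisy (or exact, sigma=0) forward-model readout as a target set."""
    readout = calibration.simulate_readout(spec.params)
    if spec.sigma > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.lognormal(0.0, spec.sigma, size=len(ANALYTES))
        readout = {a: readout[a] * noise[i] for i, a in enumerate(ANALYTES)}
    return CalibrationTargets({a: float(readout[a]) for a in ANALYTES},
                              group=spec.group)
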