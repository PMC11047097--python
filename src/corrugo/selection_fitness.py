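"""Time-varying selection protocols and relative-fitness estimation.

A :class:`FitnessProtocol` is an ordered list of phases, each assigning a
growth multiplier per strain.  Well-level strain fractions follow, to first
approximation, a logistic replicator equation ``df/dt = s f (1 - f)`` with
``s = g (W - 1)``; :func:`fit_relative_fitness` inverts it by a linear fit
on logit-transformed fractions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .biofilm_sim import PhysicsParams, run

__all__ = [
    "FitnessProtocol",
    "FractionSeries",
    "protocol_rif_stepwise",
    "fraction_series",
    "replicator_predict",
    "fit_relative_fitness",
    "suppression_experiment",
]


@dataclass
class FitnessProtocol:
    """Ordered phases of (start time, per-strain growth multiplier)."""

    phases: list  # [(t_start, {strain: multiplier}), ...]
    description: str = ""

    def __post_init__(self):
        starts = [t for t, _ in self.phases]
        if not starts or starts[0] != 0.0:
            raise ValueError("first phase must start at t=0")
        if any(b <= a for a, b in zip(starts, starts[1:])):
            raise ValueError("phase start times must be strictly increasing")
        for _, mult in self.phases:
            if any(m <= 0 for m in mult.values()):
                raise ValueError("multipliers must be positive")

    def multipliers_at(self, t: float) -> dict:
        current = self.phases[0][1]
        for t_start, mult in self.phases:
            if t >= t_start:
                current = mult
            else:
                break
        return current

    @classmethod
    def constant(cls, multipliers: dict, description: str = "") -> "FitnessProtocol":
        return cls(phases=[(0.0, dict(multipliers))], description=description)


@dataclass
class FractionSeries:
    """Focal-strain fraction over time for one well."""

    times: np.ndarray
    fraction: np.ndarray
    well_type: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.fraction = np.asarray(self.fraction, dtype=float)
        if np.any((self.fraction < -1e-12) | (self.fraction > 1 + 1e-12)):
            raise ValueError("fractions must lie in [0, 1]")


def protocol_rif_stepwise(
    t_low: float = 41.0,
    t_high: float = 91.0,
    t_recovery: float = 141.0,
    sensitive_low: float = 0.6,
    sensitive_high: float = 0.2,
    resistant_plain: float = 0.8,
) -> FitnessProtocol:
    """Four-phase antibiotic schedule: plain -> low -> high -> plain.

    In plain medium the resistant strain carries a fitness cost
    (resistant/sensitive = 0.8); at the high antibiotic step the
    sensitive/resistant ratio is 0.2.  The low step is intermediate and
    config-overridable.
    """
    lb = {"sensitive": 1.0, "resistant": resistant_plain}
    low = {"sensitive": sensitive_low, "resistant": 1.0}
    high = {"sensitive": sensitive_high, "resistant": 1.0}
    return FitnessProtocol(
        phases=[(0.0, lb), (t_low, low), (t_high, high), (t_recovery, dict(lb))],
        description="stepwise antibiotic exposure and recovery",
    )


def fraction_series(snapshots: Sequence, focal_strain: str) -> FractionSeries:
    """Per-snapshot population fraction of the focal strain."""
    from .biofilm_sim.state import STRAIN_CODE

    code = STRAIN_CODE[focal_strain]
    times, fracs = [], []
    for s in snapshots:
        if s.n == 0:
            raise ValueError(f"empty snapshot at t={s.time}")
        times.append(s.time)
        fracs.append(float(np.mean(s.strain == code)))
    return FractionSeries(np.array(times), np.array(fracs))


def replicator_predict(f0: float, s: float, times) -> FractionSeries:
    """Closed-form logistic solution ``f(t) = f0 e^{st} / (1 - f0 + f0 e^{st})``."""
    if not 0.0 < f0 < 1.0:
        raise ValueError("f0 must lie in (0, 1)")
    t = np.asarray(times, dtype=float)
    est = np.exp(s * t)
    f = f0 * est / (1.0 - f0 + f0 * est)
    return FractionSeries(t, f)


def fit_relative_fitness(
    series: FractionSeries,
    base_growth: float,
    n_bootstrap: int = 200,
    seed: int = 0,
):
    """Estimate the selection rate and relative fitness from a fraction series.

    Least squares on ``logit(f) = logit(f0) + s t`` using the points with
    fractions strictly inside (0, 1); ``W = 1 + s / g``.  The confidence
    interval is a 95% bootstrap over time points.
    """
    ok = (series.fraction > 0.0) & (series.fraction < 1.0)
    t = series.times[ok]
    f = series.fraction[ok]
    if t.size < 3:
        raise ValueError("need at least 3 time points with fractions in (0, 1)")
    logit = np.log(f / (1.0 - f))
    s_hat, _ = np.polyfit(t, logit, 1)
    w_hat = 1.0 + s_hat / base_growth
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_bootstrap):
        idx = rng.integers(0, t.size, t.size)
        if np.unique(t[idx]).size < 2:
            continue
        sb, _ = np.polyfit(t[idx], logit[idx], 1)
        boots.append(1.0 + sb / base_growth)
    if boots:
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    else:
        ci = (w_hat, w_hat)
    return float(w_hat), ci


def suppression_experiment(
    specs: dict,
    params: PhysicsParams,
    W: float = 1.5,
    mix_ratio: float = 10.0,
    t_end: float = 72.0,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
    n_cells: int = 60,
    epsilon_max: Optional[float] = None,
) -> pd.DataFrame:
    """Final less-fit-strain fraction per well type over an ensemble of seeds.

    ``specs`` maps a well-type tag to a :class:`WellSpec`.  The population
    starts as a ``mix_ratio : 1`` mixture of a normal strain and a fitter
    strain of relative fitness ``W``; adhesion is enabled when
    ``epsilon_max`` is given.
    """
    if len(specs) < 1:
        raise ValueError("need at least one well type")
    f_lessfit = mix_ratio / (mix_ratio + 1.0)
    mix = {"neutralA": f_lessfit, "neutralB": 1.0 - f_lessfit}
    protocol = FitnessProtocol.constant({"neutralA": 1.0, "neutralB": W})
    rows = []
    for tag, spec in specs.items():
        for seed in seeds:
            p = _with_adhesion(params, epsilon_max)
            snaps = run(spec, p, t_end=t_end, snapshot_every=t_end,
                        protocol=protocol, n_cells=n_cells, strain_mix=mix,
                        seed=seed)
            final = snaps[-1]
            frac = float(np.mean(final.strain == 0))  # neutralA = less fit
            rows.append({"well": tag, "seed": seed, "lessfit_fraction": frac})
    df = pd.DataFrame(rows)
    summary = df.groupby("well")["lessfit_fraction"].agg(["mean", "sem", "count"])
    df.attrs["summary"] = summary
    return df


def _with_adhesion(params: PhysicsParams, epsilon_max: Optional[float]) -> PhysicsParams:
    import dataclasses

    if epsilon_max is None:
        return dataclasses.replace(params, adhesion_enabled=False)
    return dataclasses.replace(params, adhesion_enabled=True, epsilon_max=epsilon_max)
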