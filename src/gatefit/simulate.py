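"""Synthetic plate-reader, time-course, cytometry and calibration data.

Every input the analysis consumes can be generated here with known ground
truth, so parameter-recovery experiments close the loop: induction matrices
are drawn around the AND-gate surface, time courses around exponential
growth with linear expression accumulation, cytometry samples from
lognormal mixtures, and calibration tables from straight lines.

The default noise model is mean-preserving multiplicative lognormal with a
5% coefficient of variation, emulating plate-reader replicate scatter that
grows proportionally with signal. All generators are deterministic under a
fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .cytometry import EventSample
from .fitting import ExpressionMatrix
from .kinetics import TimeCourse
from .models import ANDGateParams, eval_and_gate

__all__ = [
    "NoiseModel",
    "default_levels",
    "simulate_matrix",
    "simulate_timecourse",
    "simulate_events",
    "simulate_calibration",
]


@dataclass(frozen=True)
class NoiseModel:
    """Replicate-scatter model applied to noiseless means.

    kind
        ``"multiplicative-lognormal"`` (default; mean-preserving),
        ``"additive-gaussian"`` (sd = cv * value), or ``"none"``.
    cv
        Fractional noise level (default 0.05).
    """

    kind: str = "multiplicative-lognormal"
    cv: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("multiplicative-lognormal", "additive-gaussian", "none"):
            raise ValueError(f"unknown noise kind {self.kind!r}")
        if self.cv < 0:
            raise ValueError("cv must be >= 0")

    def apply(self, means: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.kind == "none" or self.cv == 0:
            return np.array(means, dtype=float, copy=True)
        if self.kind == "multiplicative-lognormal":
            sigma = np.sqrt(np.log1p(self.cv**2))
            factors = rng.lognormal(mean=-(sigma**2) / 2, sigma=sigma, size=means.shape)
            return means * factors
        return means + rng.normal(0.0, self.cv * np.abs(means), size=means.shape)


def default_levels(k: float, n_nonzero: int = 8) -> np.ndarray:
    """Zero plus log-spaced levels spanning 0.01x to 100x the EC50 ``k``."""
    return np.concatenate([[0.0], np.geomspace(0.01 * k, 100.0 * k, n_nonzero)])


NONE = NoiseModel(kind="none")


def simulate_matrix(
    params: ANDGateParams,
    i_levels: Sequence[float] | None = None,
    p_levels: Sequence[float] | None = None,
    replicates: int = 3,
    noise: NoiseModel | None = None,
) -> ExpressionMatrix:
    """Bivariate induction matrix from the AND-gate model plus noise.

    Defaults to grids of zero plus 8 log-spaced levels spanning 0.01x-100x
    each half-maximal constant, 3 replicates, 5% lognormal noise.
    """
    if noise is None:
        noise = NoiseModel()
    i_levels = default_levels(params.k1) if i_levels is None else np.asarray(i_levels, float)
    p_levels = default_levels(params.k2) if p_levels is None else np.asarray(p_levels, float)
    if i_levels.size == 0 or p_levels.size == 0:
        raise ValueError("inducer level grids must be non-empty")
    if replicates < 1:
        raise ValueError("need at least one replicate")
    means = eval_and_gate(i_levels[:, None], p_levels[None, :], params)
    rng = np.random.default_rng(noise.seed)
    values = np.stack(
        [noise.apply(means, rng) for _ in range(replicates)], axis=2
    )
    return ExpressionMatrix(
        i_levels=i_levels,
        p_levels=p_levels,
        values=values,
        meta={"generator": "and-gate", "noise": noise.kind, "cv": noise.cv,
              "seed": noise.seed},
    )


def simulate_timecourse(
    rate: float,
    mu: float,
    od0: float = 0.3,
    t_grid: Sequence[float] | None = None,
    noise: NoiseModel | None = None,
    baseline_rfu_per_od: float = 0.0,
) -> TimeCourse:
    """Expression/growth time course: exponential OD, linear RFU/OD.

    ``od = od0 * exp(mu * t)`` and ``rfu/od = baseline + rate * t`` with
    noise applied to the per-cell signal; total RFU is reconstructed as
    (rfu/od) * od, as a plate reader would measure it.
    """
    if noise is None:
        noise = NoiseModel()
    t = np.linspace(0.0, 5.0, 6) if t_grid is None else np.asarray(t_grid, float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be strictly increasing")
    od = od0 * np.exp(mu * t)
    rng = np.random.default_rng(noise.seed)
    rfu_per_od = noise.apply(baseline_rfu_per_od + rate * t, rng)
    return TimeCourse(
        t=t,
        rfu=rfu_per_od * od,
        od600=od,
        condition={"rate_true": rate, "mu_true": mu, "noise": noise.kind,
                   "cv": noise.cv, "seed": noise.seed},
    )


def simulate_events(
    weights: Sequence[float],
    mu_log: Sequence[float],
    sigma_log: Sequence[float],
    n_events: int = 100_000,
    seed: int = 0,
) -> EventSample:
    """Lognormal-mixture cytometry sample (natural-log parameterization).

    ``weights`` are subpopulation fractions and must sum to 1; 100 000
    events per sample is the default acquisition scale.
    """
    weights = np.asarray(weights, dtype=float)
    mu_log = np.asarray(mu_log, dtype=float)
    sigma_log = np.asarray(sigma_log, dtype=float)
    if not (weights.size == mu_log.size == sigma_log.size):
        raise ValueError("weights, mu_log, sigma_log must have equal length")
    if abs(weights.sum() - 1.0) > 1e-9:
        raise ValueError(f"mixture weights must sum to 1, got {weights.sum()}")
    if np.any(weights < 0) or np.any(sigma_log < 0):
        raise ValueError("weights and sigma_log must be >= 0")
    rng = np.random.default_rng(seed)
    comp = rng.choice(weights.size, size=n_events, p=weights)
    fl = rng.lognormal(mean=mu_log[comp], sigma=sigma_log[comp])
    return EventSample(fl=fl, condition={"weights": tuple(weights), "seed": seed})


def simulate_calibration(
    slope1: float = 2.0,
    slope2: float = 10.0,
    n_points: int = 8,
    noise: NoiseModel | None = None,
    ng_range: tuple[float, float] = (70.0, 500.0),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Standards and sample tables for the two-stage calibration.

    Standards span ``ng_range`` (default 70-500 ng, the purified-protein
    standard range); signal = slope1 * ng, sample rfu = slope2 * ng.
    Returns ``(standards, samples)`` DataFrames with columns
    (ng, signal) and (rfu, signal).
    """
    if slope1 <= 0 or slope2 <= 0:
        raise ValueError("calibration slopes must be positive")
    if noise is None:
        noise = NONE
    rng = np.random.default_rng(noise.seed)
    ng = np.linspace(ng_range[0], ng_range[1], n_points)
    standards = pd.DataFrame({"ng": ng, "signal": noise.apply(slope1 * ng, rng)})
    sample_ng = np.linspace(ng_range[0], ng_range[1], n_points)
    samples = pd.DataFrame(
        {
            "rfu": noise.apply(slope2 * sample_ng, rng),
            "signal": noise.apply(slope1 * sample_ng, rng),
        }
    )
    return standards, samples
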