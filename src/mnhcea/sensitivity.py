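"""One-way (tornado) and probabilistic (Monte Carlo) sensitivity analysis.

Default parameter ranges and distribution families come from the parameter
registry: published 95% CIs where available, otherwise +/-25% of the base
value; beta for probabilities, log-normal for ratios, gamma for unit costs,
uniform for the discount rate.  The cost-effectiveness acceptability curve is
computed on net monetary benefit, which is robust to near-zero effect draws.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import ParameterSet

__all__ = [
    "TornadoEntry",
    "PSADraw",
    "CEACCurve",
    "default_ranges",
    "default_distributions",
    "one_way",
    "psa",
    "ceac",
    "ce_plane",
]


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    low_icer: float
    high_icer: float

    @property
    def span(self) -> float:
        return abs(self.high_icer - self.low_icer)


@dataclass(frozen=True)
class PSADraw:
    draw_index: int
    delta_cost_gov: float
    delta_cost_soc: float
    dalys_averted: float

    def net_cost(self, perspective: str) -> float:
        if perspective == "GOVERNMENT":
            return self.delta_cost_gov
        if perspective == "SOCIETAL":
            return self.delta_cost_soc
        raise ValueError(f"unknown perspective {perspective!r}")

    def icer(self, perspective: str) -> float:
        return self.net_cost(perspective) / self.dalys_averted


@dataclass(frozen=True)
class CEACCurve:
    wtp_grid: np.ndarray
    probability: np.ndarray
    perspective: str

    def __post_init__(self) -> None:
        if self.wtp_grid.size == 0:
            raise ValueError("empty WTP grid")
        if ((self.probability < 0) | (self.probability > 1)).any():
            raise ValueError("probabilities must be in [0, 1]")


def default_ranges(params: ParameterSet) -> dict[str, tuple[float, float]]:
    """Sensitivity (low, high) per parameter, from the registry."""
    out = {}
    for name in params:
        spec = params.spec(name)
        if spec.sa_range is not None:
            out[name] = spec.sa_range
    return out


def default_distributions(params: ParameterSet) -> dict[str, tuple]:
    """Sampling law per varied parameter: (family, base, low, high)."""
    out = {}
    for name in params:
        spec = params.spec(name)
        if spec.dist is not None and spec.sa_range is not None:
            out[name] = (spec.dist, params[name], *spec.sa_range)
    return out


def one_way(
    evaluate: Callable[[ParameterSet], float],
    params: ParameterSet,
    ranges: dict[str, tuple[float, float]] | None = None,
) -> list[TornadoEntry]:
    """Re-run the deterministic pipeline at each parameter's range ends.

    Entries are sorted by descending span, ties broken alphabetically.
    """
    if ranges is None:
        ranges = default_ranges(params)
    entries = []
    for name in sorted(ranges):
        low, high = ranges[name]
        if low > high:
            raise ValueError(f"{name}: range low {low} exceeds high {high}")
        v_low = evaluate(params.replace(**{name: low}))
        v_high = evaluate(params.replace(**{name: high}))
        entries.append(TornadoEntry(parameter=name, low_icer=v_low, high_icer=v_high))
    entries.sort(key=lambda e: (-e.span, e.parameter))
    return entries


def _clip(params: ParameterSet, name: str, value: float) -> float:
    """Keep a sampled value inside the parameter's hard domain."""
    kind = params.spec(name).kind
    if kind == "fraction":
        value = min(max(value, 1e-9), 1.0 - 1e-9)
    elif kind in ("ratio", "rate", "count", "usd"):
        value = max(value, 1e-12)
    if name == "rr_facility_neonatal_mortality":
        value = min(value, 1.0)  # protective by assumption
    return value


def _sample(rng: np.random.Generator, law: tuple) -> float:
    family, base = law[0], float(law[1])
    if family == "point":
        return base
    low, high = float(law[2]), float(law[3])
    if family == "uniform":
        return float(rng.uniform(low, high))
    if family == "lognormal":
        sigma = (np.log(high) - np.log(low)) / (2 * 1.959963984540054)
        return float(rng.lognormal(mean=np.log(base), sigma=sigma))
    sd = (high - low) / (2 * 1.959963984540054)
    if family == "gamma":
        if base <= 0:
            return 0.0
        shape = (base / sd) ** 2
        return float(rng.gamma(shape, sd**2 / base))
    if family == "beta":
        var = sd**2
        bound = base * (1 - base)
        if var >= bound:  # fall back to a wide-but-valid law
            var = 0.9 * bound
        nu = bound / var - 1.0
        return float(rng.beta(base * nu, (1 - base) * nu))
    raise ValueError(f"unknown distribution family {family!r}")


def psa(
    evaluate: Callable[[ParameterSet], tuple[float, float, float]],
    params: ParameterSet,
    n_draws: int = 1000,
    seed: int = 0,
    distributions: dict[str, tuple] | None = None,
) -> list[PSADraw]:
    """Joint Monte Carlo over the varied parameters.

    ``evaluate`` maps a ParameterSet to (net cost government, net cost
    societal, DALYs averted).  Deterministic given the seed; parameters are
    sampled in sorted name order.
    """
    if n_draws <= 0:
        raise ValueError("n_draws must be positive")
    if distributions is None:
        distributions = default_distributions(params)
    rng = np.random.default_rng(seed)
    draws = []
    names = sorted(distributions)
    for i in range(n_draws):
        sampled = {
            name: _clip(params, name, _sample(rng, distributions[name])) for name in names
        }
        gov, soc, dalys = evaluate(params.replace(**sampled))
        draws.append(PSADraw(draw_index=i, delta_cost_gov=gov, delta_cost_soc=soc, dalys_averted=dalys))
    return draws


def ceac(draws: list[PSADraw], wtp_grid: np.ndarray, perspective: str) -> CEACCurve:
    """Probability of cost-effectiveness across willingness-to-pay values.

    At each WTP the probability is the fraction of draws with non-negative net
    monetary benefit, NMB = WTP * DALYs - net cost.
    """
    if not draws:
        raise ValueError("no PSA draws")
    grid = np.asarray(wtp_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty WTP grid")
    costs = np.array([d.net_cost(perspective) for d in draws])
    dalys = np.array([d.dalys_averted for d in draws])
    nmb = grid[:, None] * dalys[None, :] - costs[None, :]
    prob = (nmb >= 0).mean(axis=1)
    return CEACCurve(wtp_grid=grid, probability=prob, perspective=perspective)


def ce_plane(draws: list[PSADraw], perspective: str) -> np.ndarray:
    """(delta effect, delta cost) pairs for the cost-effectiveness plane."""
    return np.array([(d.dalys_averted, d.net_cost(perspective)) for d in draws])
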