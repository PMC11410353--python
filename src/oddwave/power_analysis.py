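"""Simulation-based power analysis for the participants-by-deviants design.

Each simulated dataset draws a per-participant deviant-minus-standard effect
from Normal(mu_subj, sigma_subj); per participant, deviant and standard
condition means are those effects (deviants) or zero (standards) plus trial
noise averaged over the condition's trial count, with the standard count set
by the oddball ratio (85:15 by default).  Power is the fraction of simulated
datasets in which the deviant condition is significantly more negative than
the standard condition in a one-tailed paired t test at alpha = 0.05.

In the limit of vanishing trial noise the design collapses to a classic
paired t test with effect size d = mu_subj / sigma_subj, whose power has the
closed noncentral-t form implemented in :func:`analytic_power` -- the
benchmark the simulator is validated against.

Published power figures for this paradigm depend on trial-level variance
components that were never printed; ``sigma_trial`` is therefore an explicit
required input, and no default claims to reproduce any published percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .synthetic_eeg import SimulationParams

__all__ = [
    "PowerCell",
    "PowerGridResult",
    "effect_size_d",
    "analytic_power",
    "simulate_power_cell",
    "power_grid",
    "STANDARD_DEVIANT_RATIO",
]

STANDARD_DEVIANT_RATIO = (85, 15)
ALPHA = 0.05


@dataclass
class PowerCell:
    n_participants: int
    n_deviants: int
    power: float
    mc_se: float
    n_sims: int
    alpha: float = ALPHA
    tail: str = "negative"
    standard_deviant_ratio: tuple[int, int] = STANDARD_DEVIANT_RATIO


@dataclass
class PowerGridResult:
    cells: list[PowerCell]
    params: dict = field(default_factory=dict)
    seed: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.n_participants, c.n_deviants, c.power, c.mc_se) for c in self.cells],
            columns=["n_participants", "n_deviants", "power", "mc_se"],
        )

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def effect_size_d(mean_uv: float, sd_uv: float) -> float:
    """Cohen's d for a paired effect: mean divided by standard deviation."""
    if sd_uv <= 0:
        raise ValueError("sd must be positive")
    return mean_uv / sd_uv


def analytic_power(d: float, n: int, alpha: float = ALPHA, tail: str = "one_sided") -> float:
    """Closed-form paired-t power via the noncentral t distribution.

    One-sided power = 1 - F_nct(t_crit; df = n - 1, ncp = |d| sqrt(n)), with
    t_crit the central-t critical value at ``alpha``.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if n < 2:
        raise ValueError("need n >= 2")
    df = n - 1
    ncp = abs(d) * np.sqrt(n)
    if tail == "one_sided":
        tcrit = stats.t.ppf(1.0 - alpha, df)
        return float(stats.nct.sf(tcrit, df, ncp))
    if tail == "two_sided":
        tcrit = stats.t.ppf(1.0 - alpha / 2.0, df)
        return float(stats.nct.sf(tcrit, df, ncp) + stats.nct.cdf(-tcrit, df, ncp))
    raise ValueError(f"unknown tail {tail!r}")


def _power_from_diffs(diff: np.ndarray, alpha: float, tail: str) -> float:
    """Rejection fraction of the one-tailed paired t over (n_sims, n) diffs."""
    n = diff.shape[1]
    m = diff.mean(axis=1)
    sd = diff.std(axis=1, ddof=1)
    tvals = m / (sd / np.sqrt(n))
    df = n - 1
    if tail == "negative":
        sig = tvals < stats.t.ppf(alpha, df)
    elif tail == "positive":
        sig = tvals > stats.t.ppf(1.0 - alpha, df)
    else:
        raise ValueError(f"unknown tail {tail!r}")
    return float(sig.mean())


def _standard_count(n_deviants: int, ratio: tuple[int, int]) -> int:
    s, d = ratio
    if d <= 0 or s <= 0:
        raise ValueError(f"degenerate standard:deviant ratio {ratio}")
    return max(1, round(n_deviants * s / d))


def simulate_power_cell(
    n_participants: int,
    n_deviants: int,
    params: SimulationParams,
    n_sims: int = 1000,
    rng: np.random.Generator | None = None,
    alpha: float = ALPHA,
    ratio: tuple[int, int] = STANDARD_DEVIANT_RATIO,
    tail: str = "negative",
) -> PowerCell:
    """Monte-Carlo power for one (participants, deviants) design cell.

    Vectorized over simulations: participant-level deviant and standard
    condition means are formed from the drawn effects plus trial noise
    scaled by 1/sqrt(trial count), then compared by a one-tailed paired t.
    """
    if n_participants < 2:
        raise ValueError("need at least 2 participants")
    if n_sims < 1:
        raise ValueError("need at least one simulation")
    rng = np.random.default_rng() if rng is None else rng
    n_std = _standard_count(n_deviants, ratio)

    effects = rng.normal(params.mu_subj, params.sigma_subj, size=(n_sims, n_participants))
    dev_mean = effects + rng.normal(
        0.0, params.sigma_trial / np.sqrt(n_deviants), size=effects.shape)
    std_mean = rng.normal(0.0, params.sigma_trial / np.sqrt(n_std), size=effects.shape)
    p = _power_from_diffs(dev_mean - std_mean, alpha, tail)
    return PowerCell(
        n_participants=n_participants,
        n_deviants=n_deviants,
        power=p,
        mc_se=float(np.sqrt(p * (1.0 - p) / n_sims)),
        n_sims=n_sims,
        alpha=alpha,
        tail=tail,
        standard_deviant_ratio=ratio,
    )


def power_grid(
    n_participants_list,
    n_deviants_list,
    params: SimulationParams,
    n_sims: int = 1000,
    seed: int = 0,
    alpha: float = ALPHA,
    ratio: tuple[int, int] = STANDARD_DEVIANT_RATIO,
    tail: str = "negative",
) -> PowerGridResult:
    """Power over the cross product of participant and deviant counts.

    Each cell draws from a named substream of ``seed``; cells that share a
    participant count reuse the same substream family, giving common random
    numbers along the deviant-count axis.
    """
    if not len(n_participants_list) or not len(n_deviants_list):
        raise ValueError("grids must be nonempty")
    n_ps = [int(v) for v in n_participants_list]
    n_ds = [int(v) for v in n_deviants_list]
    n_max = max(n_ps)
    cells = []
    for n_d in n_ds:
        # common random numbers across participant counts: draw once at the
        # largest n and slice, so power is exactly non-decreasing modulo the
        # test's own discreteness rather than fresh sampling noise
        rng = substream(seed, "power", n_d)
        n_std = _standard_count(n_d, ratio)
        effects = rng.normal(params.mu_subj, params.sigma_subj, size=(n_sims, n_max))
        dev_mean = effects + rng.normal(
            0.0, params.sigma_trial / np.sqrt(n_d), size=effects.shape)
        std_mean = rng.normal(0.0, params.sigma_trial / np.sqrt(n_std), size=effects.shape)
        diff = dev_mean - std_mean
        for n_p in n_ps:
            p = _power_from_diffs(diff[:, :n_p], alpha, tail)
            cells.append(PowerCell(
                n_participants=n_p, n_deviants=n_d, power=p,
                mc_se=float(np.sqrt(p * (1.0 - p) / n_sims)),
                n_sims=n_sims, alpha=alpha, tail=tail, standard_deviant_ratio=ratio,
            ))
    return PowerGridResult(
        cells=cells,
        params={
            "mu_subj": params.mu_subj,
            "sigma_subj": params.sigma_subj,
            "sigma_trial": params.sigma_trial,
            "alpha": alpha,
            "ratio": list(ratio),
            "n_sims": n_sims,
        },
        seed=seed,
    )
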