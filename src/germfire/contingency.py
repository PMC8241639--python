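"""Bayesian comparison of fire-effect prevalence between two trait groups.

Each group's prevalence gets an independent Beta posterior under a uniform
Beta(1, 1) prior; the group difference is the paired Monte Carlo difference
of posterior draws.  Summaries are KDE modes with 95% HDIs, plus the
probability of direction P(theta_1 > theta_2).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .decision import Interval, hdi, mode_estimate

__all__ = [
    "ContingencyTable2x2",
    "PropCompareResult",
    "beta_posterior_draws",
    "bayes_prop_compare",
]


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts of species showing an effect, out of those classified, per group."""

    group_labels: tuple[str, str]
    successes: tuple[int, int]
    totals: tuple[int, int]

    def __post_init__(self):
        for s, t in zip(self.successes, self.totals):
            if t <= 0:
                raise ValueError("group totals must be positive")
            if not (0 <= s <= t):
                raise ValueError(f"successes {s} outside [0, {t}]")

    def swapped(self) -> "ContingencyTable2x2":
        return ContingencyTable2x2(
            (self.group_labels[1], self.group_labels[0]),
            (self.successes[1], self.successes[0]),
            (self.totals[1], self.totals[0]),
        )


@dataclass(frozen=True)
class PropCompareResult:
    table: ContingencyTable2x2
    freq_mode: tuple[float, float]
    freq_hdi: tuple[Interval, Interval]
    diff_mode: float                  # group1 - group2
    diff_hdi: Interval
    p_direction: float                # P(theta1 > theta2)
    n_draws: int
    seed: int


def beta_posterior_draws(
    successes: int, total: int, n_draws: int = 200_000, seed: int = 0
) -> np.ndarray:
    """Draws from the Beta(successes + 1, total - successes + 1) posterior
    of a proportion under a uniform prior."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not (0 <= successes <= total):
        raise ValueError("successes must be within [0, total]")
    if n_draws < 10_000:
        raise ValueError("use at least 10,000 draws for stable summaries")
    rng = np.random.default_rng(seed)
    return rng.beta(successes + 1, total - successes + 1, size=n_draws)


def bayes_prop_compare(
    table: ContingencyTable2x2, n_draws: int = 200_000, seed: int = 0
) -> PropCompareResult:
    """Compare effect prevalence between the table's two groups.

    Independent uniform-prior Beta posteriors per group; the difference is
    computed draw-wise, summarised by its KDE mode and 95% HDI, and the
    probability of direction is the fraction of paired draws with
    theta_1 > theta_2.
    """
    th1 = beta_posterior_draws(table.successes[0], table.totals[0], n_draws, seed)
    th2 = beta_posterior_draws(
        table.successes[1], table.totals[1], n_draws, seed + 1
    )
    diff = th1 - th2
    return PropCompareResult(
        table=table,
        freq_mode=(
            mode_estimate(th1, bounds=(0.0, 1.0)),
            mode_estimate(th2, bounds=(0.0, 1.0)),
        ),
        freq_hdi=(hdi(th1), hdi(th2)),
        diff_mode=mode_estimate(diff, bounds=(-1.0, 1.0)),
        diff_hdi=hdi(diff),
        p_direction=float(np.mean(th1 > th2)),
        n_draws=n_draws,
        seed=seed,
    )
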