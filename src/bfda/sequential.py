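"""Sequential Bayes factor design analysis with stopping boundaries.

In a sequential design, data collection starts at a minimum sample size and
observations are added (one per group per stage, keeping the groups
balanced) until the Bayes factor leaves the interval between a lower
boundary 1/b and an upper boundary b.  The design-analysis quantities are
the distribution of final sample sizes and the fraction of trajectories
that terminate at the boundary contradicting the data-generating
hypothesis (misleading evidence).

Unlike the fixed-N case, successive t statistics within a trajectory are
dependent (they share observations), so trajectories must accumulate raw
observations; running sums and sums of squares per group yield the pooled
t statistic at every stage.  The stage-wise stopping decision compares the
t statistic against precomputed critical values t*(n) solving
BF10(t; n, n) = boundary -- exactly equivalent to evaluating the Bayes
factor at every stage, because BF10 is strictly increasing in t for the
directional priors (asserted before use).  Log-BF paths are materialized
only for trajectories whose full path is requested.

Every trajectory runs on its own RNG substream spawned from the master
seed, so neither the replication count nor execution order changes any
individual trajectory.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .bayes_factor import assert_monotone_in_t, critical_t_profile, log_bf10
from .fixed_n import DesignPrior
from .priors import PriorSpec

__all__ = [
    "DecisionBoundaries",
    "SequentialConfig",
    "SequentialResult",
    "TrajectoryPath",
    "run_trajectory",
    "run_sequential",
    "misleading_rate_sequential",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DecisionBoundaries:
    """Lower (< 1) and upper (> 1) Bayes factor stopping thresholds."""

    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 < self.lower < 1 < self.upper):
            raise ValueError(
                f"boundaries must satisfy 0 < lower < 1 < upper, got "
                f"({self.lower}, {self.upper})"
            )

    @classmethod
    def symmetric(cls, b: float) -> "DecisionBoundaries":
        """Boundaries (1/b, b) from a single evidence threshold b > 1."""
        if not b > 1:
            raise ValueError(f"symmetric boundary requires b > 1, got {b}")
        return cls(1.0 / b, b)


@dataclass(frozen=True)
class SequentialConfig:
    """Sampling plan of a sequential run.

    ``n_min`` observations per group to start (default 10), ``step`` added
    per group per stage, hard censoring cap ``n_max`` per group, ``m``
    trajectories, master ``seed``.
    """

    m: int
    seed: int
    n_min: int = 10
    step: int = 1
    n_max: int = 5000

    def __post_init__(self) -> None:
        if self.m < 0:
            raise ValueError(f"m must be >= 0, got {self.m}")
        if self.n_min < 2:
            raise ValueError(f"n_min must be >= 2, got {self.n_min}")
        if self.step < 1:
            raise ValueError(f"step must be >= 1, got {self.step}")
        if self.n_max < self.n_min:
            raise ValueError(
                f"n_max ({self.n_max}) must be >= n_min ({self.n_min})"
            )

    def eval_ns(self) -> np.ndarray:
        """Per-group sizes at which the Bayes factor is evaluated."""
        ns = np.arange(self.n_min, self.n_max + 1, self.step)
        if ns[-1] != self.n_max:
            ns = np.append(ns, self.n_max)
        return ns


@dataclass(frozen=True)
class TrajectoryPath:
    """Stored sampling trajectory: per-stage n, t, and log BF10."""

    ns: np.ndarray
    ts: np.ndarray
    log_bfs: np.ndarray


@dataclass(frozen=True)
class SequentialResult:
    """Final sample sizes and terminal sides of m sequential trajectories."""

    final_n: np.ndarray
    side: np.ndarray  # labels in {"upper", "lower", "censored"}
    deltas: np.ndarray
    design: DesignPrior
    analysis_prior: PriorSpec
    bounds: DecisionBoundaries
    config: SequentialConfig
    trajectories: Optional[list] = field(default=None, repr=False)

    @property
    def censored_fraction(self) -> float:
        if self.final_n.size == 0:
            return 0.0
        return float(np.mean(self.side == "censored"))


# Critical-t profiles are expensive for large n_max; cache per
# (prior, boundary, sampling plan).  PriorSpec is frozen, hence hashable.
_THRESHOLD_CACHE: dict = {}


def _thresholds(
    analysis_prior: PriorSpec, bounds: DecisionBoundaries, config: SequentialConfig
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    key = (
        analysis_prior,
        bounds.lower,
        bounds.upper,
        config.n_min,
        config.step,
        config.n_max,
    )
    if key not in _THRESHOLD_CACHE:
        assert_monotone_in_t(analysis_prior, config.n_min, config.n_min)
        ns = config.eval_ns()
        t_up = critical_t_profile(ns, analysis_prior, bounds.upper)
        t_lo = critical_t_profile(ns, analysis_prior, bounds.lower)
        _THRESHOLD_CACHE[key] = (ns, t_lo, t_up)
    return _THRESHOLD_CACHE[key]


def _pooled_t(s1, q1, s2, q2, n):
    """Pooled-variance two-sample t from running sums / sums of squares."""
    m1 = s1 / n
    m2 = s2 / n
    var1 = (q1 - n * m1 * m1) / (n - 1)
    var2 = (q2 - n * m2 * m2) / (n - 1)
    sp = np.sqrt((var1 + var2) / 2.0)
    return (m1 - m2) / (sp * np.sqrt(2.0 / n))


def _trajectory_core(
    rng: np.random.Generator,
    delta: float,
    ns: np.ndarray,
    t_lo: np.ndarray,
    t_up: np.ndarray,
    n_max: int,
    store_path: bool,
):
    """Run one trajectory; returns (final_n, side, path-or-None).

    Observations are drawn in geometrically growing blocks from the
    trajectory's own substream (the sequence of draws depends only on the
    substream, never on other trajectories), and running sums give the t
    statistic at every evaluation size.
    """
    n_have = 0
    x1 = np.empty(0)
    x2 = np.empty(0)
    while True:
        n_new = min(n_max, max(2 * n_have, 64)) - n_have
        x1 = np.concatenate([x1, delta + rng.standard_normal(n_new)])
        x2 = np.concatenate([x2, rng.standard_normal(n_new)])
        n_have += n_new

        mask = ns <= n_have
        ns_c = ns[mask]
        idx = ns_c - 1
        s1 = np.cumsum(x1)[idx]
        q1 = np.cumsum(x1 * x1)[idx]
        s2 = np.cumsum(x2)[idx]
        q2 = np.cumsum(x2 * x2)[idx]
        t_path = _pooled_t(s1, q1, s2, q2, ns_c)

        crossed = (t_path > t_up[mask]) | (t_path < t_lo[mask])
        hit = np.flatnonzero(crossed)
        if hit.size:
            k = int(hit[0])
            side = "upper" if t_path[k] > t_up[mask][k] else "lower"
            path = (ns_c[: k + 1], t_path[: k + 1]) if store_path else None
            return int(ns_c[k]), side, path
        if n_have >= n_max:
            path = (ns_c, t_path) if store_path else None
            return int(n_max), "censored", path


def run_trajectory(
    design: DesignPrior,
    analysis_prior: PriorSpec,
    bounds: DecisionBoundaries,
    config: SequentialConfig,
    rng: np.random.Generator,
    store_path: bool = True,
):
    """One sequential trajectory using the supplied generator.

    Returns ``(final_n, side, path)`` where ``path`` is a
    :class:`TrajectoryPath` (or None).  Identical to the corresponding
    element of :func:`run_sequential` when given the same substream.
    """
    ns, t_lo, t_up = _thresholds(analysis_prior, bounds, config)
    delta = float(design.draw(1, rng)[0])
    final_n, side, raw = _trajectory_core(
        rng, delta, ns, t_lo, t_up, config.n_max, store_path
    )
    path = None
    if raw is not None:
        p_ns, p_ts = raw
        lbs = np.asarray(log_bf10(p_ts, p_ns, p_ns, analysis_prior))
        path = TrajectoryPath(p_ns, p_ts, lbs)
    return final_n, side, path


def run_sequential(
    design: DesignPrior,
    analysis_prior: PriorSpec,
    bounds: DecisionBoundaries,
    config: SequentialConfig,
    store_paths: int = 0,
) -> SequentialResult:
    """Run m independent sequential trajectories.

    ``store_paths`` keeps the full (n, t, log BF) path for the first that
    many trajectories.  The censored fraction (trajectories reaching
    ``n_max`` with the Bayes factor still between the boundaries) is logged
    prominently; censored trajectories keep ``final_n = n_max`` and the
    label ``"censored"``.
    """
    ns, t_lo, t_up = _thresholds(analysis_prior, bounds, config)
    children = np.random.SeedSequence(config.seed).spawn(config.m)
    logger.info(
        "sequential BFDA: m=%d, bounds=(%.4g, %.4g), n_min=%d, n_max=%d, "
        "step=%d, design=%s, analysis prior=%s, seed=%d",
        config.m,
        bounds.lower,
        bounds.upper,
        config.n_min,
        config.n_max,
        config.step,
        design,
        analysis_prior,
        config.seed,
    )
    final_n = np.empty(config.m, dtype=int)
    side = np.empty(config.m, dtype=object)
    deltas = np.empty(config.m)
    trajectories: list = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        store = i < store_paths
        deltas[i] = float(design.draw(1, rng)[0])
        final_n[i], side[i], raw = _trajectory_core(
            rng, deltas[i], ns, t_lo, t_up, config.n_max, store
        )
        if store and raw is not None:
            p_ns, p_ts = raw
            lbs = np.asarray(log_bf10(p_ts, p_ns, p_ns, analysis_prior))
            trajectories.append(TrajectoryPath(p_ns, p_ts, lbs))
    result = SequentialResult(
        final_n,
        side,
        deltas,
        design,
        analysis_prior,
        bounds,
        config,
        trajectories or None,
    )
    if config.m:
        cf = result.censored_fraction
        if cf > 0:
            logger.warning(
                "sequential BFDA: %.2f%% of trajectories censored at n_max=%d",
                100 * cf,
                config.n_max,
            )
        else:
            logger.info("sequential BFDA: no censored trajectories")
    return result


def misleading_rate_sequential(result: SequentialResult, truth: str) -> float:
    """Fraction of decided trajectories that hit the wrong boundary.

    With ``truth="h1"`` the wrong boundary is the lower one; with
    ``truth="h0"`` it is the upper one.  Censored trajectories are excluded
    from the denominator (reported separately via
    ``result.censored_fraction``), never counted as errors.
    """
    if truth not in ("h0", "h1"):
        raise ValueError(f"truth must be 'h0' or 'h1', got {truth!r}")
    if result.final_n.size == 0:
        raise ValueError("empty sequential result")
    decided = result.side != "censored"
    n_dec = int(np.sum(decided))
    if n_dec == 0:
        raise ValueError(
            "all trajectories censored; misleading-evidence rate undefined"
        )
    wrong = "upper" if truth == "h0" else "lower"
    return float(np.sum(result.side[decided] == wrong) / n_dec)
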