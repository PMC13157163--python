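"""Trial scoring and the statistical evaluation battery.

Per-trial performance is summarized by four normalized values in [0, 1]:
whether the target was reached, time to target (0 = straight-line time at
top speed, 1 = the 45 s cap), distance traveled (0 = straight-line
distance, 1 = the 22.5 m an agent can cover in 45 s at 0.5 m/s), and the
collision rate (fraction of trajectory samples inside an obstacle disk).
The total score gates their complements by the reached flag:

    score = reached * [(1 - time) + (1 - distance) + (1 - collisions)] / 3

Trajectory similarity between repeats of the same task uses dynamic time
warping on length-matched resampled paths; group comparisons use Welch
t-tests, paired Cohen's d with pooled within-group variance, one-way
ANOVA partial eta^2, bootstrap SE/CI, and Holm-Bonferroni correction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .arena import Environment

__all__ = [
    "Trajectory",
    "TrialResult",
    "time_to_target_norm",
    "distance_norm",
    "collision_rate",
    "total_score",
    "dtw_distance",
    "resample_trajectory",
    "power_analysis",
    "bootstrap_success",
    "cohens_d",
    "anova_eta2",
    "holm_bonferroni",
    "bootstrap_ci",
    "welch_ttest",
    "summarize_results",
]

MAX_DISTANCE = 22.5  # m, worst case: t_max * v_max = 45 s * 0.5 m/s


@dataclass
class Trajectory:
    """Time-stamped positions of one trial, with per-sample collision flags."""

    t: np.ndarray
    xy: np.ndarray  # (n, 2) positions, columns (x, z)
    collided: np.ndarray | None = None
    dt: float | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.xy = np.asarray(self.xy, dtype=float).reshape(len(self.t), 2)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.collided is None:
            self.collided = np.zeros(len(self.t), dtype=bool)

    @property
    def path_length(self) -> float:
        """Sum of consecutive-sample Euclidean steps, in meters."""
        if len(self.t) < 2:
            return 0.0
        return float(np.sum(np.linalg.norm(np.diff(self.xy, axis=0), axis=1)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "x": self.xy[:, 0],
                "z": self.xy[:, 1],
                "collision_flag": np.asarray(self.collided, dtype=int),
            }
        )


@dataclass
class TrialResult:
    """Normalized per-trial metrics; all fields in [0, 1]."""

    reached: int
    time_norm: float | None
    dist_norm: float | None
    collision_rate: float
    total_score: float = field(default=0.0)
    t_reach: float | None = None
    meta: dict = field(default_factory=dict)


def time_to_target_norm(
    t_reach: float, straight_dist: float, v_max: float = 0.5, t_max: float = 45.0
) -> float:
    """Normalized time to target: 0 at the straight-line minimum
    ``straight_dist / v_max``, 1 at the simulation cap ``t_max``.

    Only defined for reached trials (unreached trials are excluded from
    the time statistic)."""
    t_min = straight_dist / v_max
    denom = t_max - t_min
    if denom <= 0:
        return 0.0
    return float(np.clip((t_reach - t_min) / denom, 0.0, 1.0))


def distance_norm(
    path_len: float, straight_dist: float, v_max: float = 0.5, t_max: float = 45.0
) -> float:
    """Normalized distance traveled: 0 at the straight-line distance, 1 at
    the maximal possible path length ``v_max * t_max`` (22.5 m default)."""
    denom = v_max * t_max - straight_dist
    if denom <= 0:
        return 0.0
    return float(np.clip((path_len - straight_dist) / denom, 0.0, 1.0))


def collision_rate(traj: Trajectory, env: Environment) -> float:
    """Fraction of trajectory samples lying within any coral disk
    (center distance < radius)."""
    if len(traj.t) == 0:
        return 0.0
    if env.coral_centers.size == 0:
        return 0.0
    d = np.linalg.norm(
        traj.xy[:, None, :] - env.coral_centers[None, :, :], axis=2
    ).min(axis=1)
    return float(np.mean(d < env.config.coral_radius))


def total_score(r: TrialResult) -> float:
    """Reached-gated mean of the three metric complements; 0 for failed
    trials (failures fold to score 0)."""
    if not r.reached:
        return 0.0
    parts = [1.0 - r.time_norm, 1.0 - r.dist_norm, 1.0 - r.collision_rate]
    return float(np.clip(np.mean(parts), 0.0, 1.0))


# ----------------------------------------------------------------------
# Trajectory similarity


def resample_trajectory(xy: np.ndarray, n: int) -> np.ndarray:
    """Linear-interpolation resampling of a polyline to ``n`` samples,
    uniform in sample index ("stretching" to a common length)."""
    xy = np.asarray(xy, dtype=float)
    if len(xy) == n:
        return xy
    if len(xy) == 1:
        return np.repeat(xy, n, axis=0)
    old = np.linspace(0.0, 1.0, len(xy))
    new = np.linspace(0.0, 1.0, n)
    return np.column_stack([np.interp(new, old, xy[:, k]) for k in range(xy.shape[1])])


def dtw_distance(trajA: np.ndarray, trajB: np.ndarray) -> float:
    """Dynamic-time-warping alignment cost between two position series
    under Euclidean local distance.

    Inputs of unequal length are first stretched (linearly resampled) to
    the longer one's length. Standard DP recurrence
    ``D[i,j] = cost(i,j) + min(D[i-1,j], D[i,j-1], D[i-1,j-1])``.
    """
    a = np.atleast_2d(np.asarray(trajA, dtype=float))
    b = np.atleast_2d(np.asarray(trajB, dtype=float))
    if a.shape[0] != b.shape[0]:
        n = max(a.shape[0], b.shape[0])
        a = resample_trajectory(a, n)
        b = resample_trajectory(b, n)
    n, m = a.shape[0], b.shape[0]
    cost = np.linalg.norm(a[:, None, :] - b[None, :, :], axis=2)
    D = np.full(m, np.inf)
    D[0] = cost[0, 0]
    D[1:] = cost[0, 0] + np.cumsum(cost[0, 1:])
    for i in range(1, n):
        prev = D
        D = np.empty(m)
        D[0] = prev[0] + cost[i, 0]
        # vectorised over j using running minimum along the row
        best_up = np.minimum(prev[1:], prev[:-1])  # D[i-1,j], D[i-1,j-1]
        row = cost[i]
        for j in range(1, m):
            D[j] = row[j] + min(best_up[j - 1], D[j - 1])
    return float(D[-1])


def power_analysis(
    trajs: list[np.ndarray], resample_to: int | None = 200
) -> np.ndarray:
    """All unordered pairwise DTW distances among repeat trajectories.

    10 repeats yield 45 pairwise values; low values mean the strategy
    reproduces the same route. Trajectories are resampled to a common
    length first (default 200 samples) so the costs are comparable.
    """
    if resample_to is not None:
        trajs = [resample_trajectory(np.atleast_2d(t), resample_to) for t in trajs]
    return np.array(
        [dtw_distance(a, b) for a, b in combinations(trajs, 2)], dtype=float
    )


# ----------------------------------------------------------------------
# Statistics


def bootstrap_success(
    flags: np.ndarray, n_boot: int = 100, seed: int | None = None
) -> tuple[float, float]:
    """Success rate with bootstrap standard error (resampling the trial
    flags ``n_boot`` times)."""
    flags = np.asarray(flags, dtype=float)
    rng = np.random.default_rng(seed)
    boots = rng.choice(flags, size=(n_boot, len(flags)), replace=True).mean(axis=1)
    return float(flags.mean()), float(boots.std(ddof=1))


def cohens_d(groupA: np.ndarray, groupB: np.ndarray) -> float:
    """Cohen's d for paired-by-environment contrasts: mean difference over
    the pooled within-group standard deviation. 0.2/0.5/0.8 read as
    small/medium/large."""
    a = np.asarray(groupA, dtype=float)
    b = np.asarray(groupB, dtype=float)
    na, nb = len(a), len(b)
    pooled_var = (
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
        if na + nb > 2
        else 0.0
    )
    if pooled_var == 0:
        return 0.0
    return float((a.mean() - b.mean()) / np.sqrt(pooled_var))


def anova_eta2(groups: list[np.ndarray]) -> float:
    """Partial eta^2 from a one-way ANOVA: between-group sum of squares
    over (between + error)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ss_error = sum(((g - g.mean()) ** 2).sum() for g in groups)
    if ss_between + ss_error == 0:
        return 0.0
    return float(ss_between / (ss_between + ss_error))


def holm_bonferroni(pvals: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Step-down Holm-Bonferroni decisions (True = rejected) controlling
    the familywise error rate at ``alpha``."""
    pvals = np.asarray(pvals, dtype=float)
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="holm")
    return reject


def holm_adjusted(pvals: np.ndarray) -> np.ndarray:
    """Holm-adjusted p-values."""
    _, adj, _, _ = multipletests(np.asarray(pvals, dtype=float), method="holm")
    return adj


def bootstrap_ci(
    stat_fn,
    data: np.ndarray,
    n: int = 10_000,
    level: float = 0.95,
    seed: int | None = None,
) -> tuple[float, float]:
    """Percentile bootstrap confidence interval of ``stat_fn`` over
    ``data`` (default 10,000 resamples, 95%)."""
    data = np.asarray(data, dtype=float)
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(data), size=(n, len(data)))
    boots = np.array([stat_fn(data[row]) for row in idx])
    lo, hi = np.percentile(boots, [50 * (1 - level), 50 * (1 + level)])
    return float(lo), float(hi)


def welch_ttest(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Welch t-test; returns (statistic, p-value)."""
    res = sps.ttest_ind(np.asarray(a, float), np.asarray(b, float), equal_var=False)
    return float(res.statistic), float(res.pvalue)


def summarize_results(table: pd.DataFrame, by: str = "strategy") -> pd.DataFrame:
    """Per-group means/SEs of the trial metrics from a results table with
    columns (strategy, reached, time_norm, dist_norm, collision_rate,
    score). Time/distance means use reached trials only."""
    rows = []
    for key, grp in table.groupby(by):
        ok = grp[grp["reached"] == 1]
        mean_sr, se_sr = bootstrap_success(grp["reached"].to_numpy(), seed=0)
        rows.append(
            {
                by: key,
                "n": len(grp),
                "success_rate": mean_sr,
                "success_se": se_sr,
                "time_norm": ok["time_norm"].mean() if len(ok) else np.nan,
                "dist_norm": ok["dist_norm"].mean() if len(ok) else np.nan,
                "collision_rate": grp["collision_rate"].mean(),
                "score": grp["score"].mean(),
                "score_se": grp["score"].sem() if len(grp) > 1 else 0.0,
            }
        )
    return pd.DataFrame(rows)
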