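"""Sampling-effort-reduction simulations and landscape-scale regressions.

Traps are removed from a landscape one at a time, either uniformly at
random (full random permutations, many randomizations) or in a
deterministic order given by the trap-scale urbanization index.  After
each removal the percentage of the landscape's species pool lost by the
retained traps is recorded:

    loss%(k) = 100 * (1 - S_retained(k) / S_total)

with k the number of retained traps.  Percentages normalise out
richness differences among landscapes, so scenarios can be compared
across sites.  "Reduce to k traps" keeps the last k traps of the
removal sequence, i.e. drops the first T-k removed.

Policy naming is semantic — ``most_urbanized_first`` removes traps in
descending index order, ``least_urbanized_first`` in ascending order —
to avoid the ambiguity of "ascending/descending" labels.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import IncidenceMatrix, Landscape, TrapSite

ORDERED_POLICIES = ("most_urbanized_first", "least_urbanized_first")
POLICIES = ("random",) + ORDERED_POLICIES


@dataclass(frozen=True)
class RemovalScenario:
    policy: str
    n_randomizations: int = 100
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.policy not in POLICIES:
            raise ValueError(f"policy {self.policy!r} not in {POLICIES}")
        if self.n_randomizations < 1:
            raise ValueError("n_randomizations must be >= 1")
        if self.policy == "random" and self.seed is None:
            raise ValueError("random policy requires a seed")


@dataclass
class LossCurve:
    """% species lost as a function of retained trap count k = 1..T."""

    landscape_id: str
    policy: str
    k: np.ndarray
    mean_loss_pct: np.ndarray
    sd_loss_pct: np.ndarray | None = None
    n_paths: int = 1

    def at(self, k: int) -> float:
        idx = np.flatnonzero(self.k == k)
        if idx.size == 0:
            raise KeyError(f"k={k} not on the curve")
        return float(self.mean_loss_pct[idx[0]])


def removal_order(traps: Sequence[TrapSite], policy: str) -> list[str]:
    """Deterministic removal sequence for an ordered policy.

    Ties in the index are broken by lexicographic trap_id, so the order
    is stable and documented.
    """
    if policy not in ORDERED_POLICIES:
        raise ValueError(f"ordered policy expected, got {policy!r}")
    missing = [t.trap_id for t in traps if t.urbanization_index is None]
    if missing:
        raise ValueError(f"traps missing urbanization_index: {missing}")
    reverse = policy == "most_urbanized_first"
    ordered = sorted(
        traps,
        key=lambda t: ((-t.urbanization_index if reverse else t.urbanization_index), t.trap_id),
    )
    return [t.trap_id for t in ordered]


def _loss_curve_for_sequence(values: np.ndarray, col_order: np.ndarray) -> np.ndarray:
    """loss% per k (k = 1..T) when columns are removed in ``col_order``.

    Retaining k traps keeps the last k entries of the sequence; species
    counted as retained are those with >= 1 incidence among kept columns.
    """
    S_total, T = values.shape
    if S_total == 0:
        raise ValueError("empty species pool; loss undefined")
    reordered = values[:, col_order[::-1]]  # first column = removed last
    present = np.logical_or.accumulate(reordered.astype(bool), axis=1)
    richness_by_k = present.sum(axis=0)  # k = 1..T
    return 100.0 * (1.0 - richness_by_k / S_total)


def species_loss_given_order(
    matrix: IncidenceMatrix, removal_sequence: Sequence[str]
) -> LossCurve:
    """Loss curve for one explicit removal sequence (a trap permutation)."""
    if sorted(removal_sequence) != sorted(matrix.trap_ids):
        raise ValueError("removal sequence is not a permutation of the matrix traps")
    col = {tid: j for j, tid in enumerate(matrix.trap_ids)}
    order = np.array([col[tid] for tid in removal_sequence])
    loss = _loss_curve_for_sequence(matrix.values, order)
    return LossCurve(
        landscape_id="",
        policy="ordered",
        k=np.arange(1, matrix.n_traps + 1),
        mean_loss_pct=loss,
    )


def random_mean_loss(
    matrix: IncidenceMatrix,
    n_randomizations: int = 100,
    seed: int | np.random.Generator = 0,
) -> LossCurve:
    """Mean loss curve over uniformly random full removal permutations."""
    if n_randomizations < 1:
        raise ValueError("n_randomizations must be >= 1")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    T = matrix.n_traps
    losses = np.empty((n_randomizations, T))
    for r in range(n_randomizations):
        losses[r] = _loss_curve_for_sequence(matrix.values, rng.permutation(T))
    return LossCurve(
        landscape_id="",
        policy="random",
        k=np.arange(1, T + 1),
        mean_loss_pct=losses.mean(axis=0),
        sd_loss_pct=losses.std(axis=0, ddof=1) if n_randomizations > 1 else None,
        n_paths=n_randomizations,
    )


def exact_mean_loss(matrix: IncidenceMatrix) -> LossCurve:
    """Mean loss per k averaged over *all* T! removal permutations.

    Because the loss at k depends only on the retained subset, the mean
    over permutations equals the mean over all C(T, k) subsets; feasible
    for small T and used as an exhaustive oracle.
    """
    T = matrix.n_traps
    S_total = matrix.n_species
    if S_total == 0:
        raise ValueError("empty species pool; loss undefined")
    vals = matrix.values.astype(bool)
    mean_loss = np.empty(T)
    for k in range(1, T + 1):
        richness = [
            vals[:, list(subset)].any(axis=1).sum()
            for subset in itertools.combinations(range(T), k)
        ]
        mean_loss[k - 1] = 100.0 * (1.0 - np.mean(richness) / S_total)
    return LossCurve(
        landscape_id="",
        policy="random",
        k=np.arange(1, T + 1),
        mean_loss_pct=mean_loss,
        n_paths=-1,
    )


def scenario_loss_curve(
    landscape: Landscape,
    matrix: IncidenceMatrix,
    scenario: RemovalScenario,
) -> LossCurve:
    """Dispatch a scenario to its policy and tag the landscape."""
    if scenario.policy == "random":
        curve = random_mean_loss(
            matrix, n_randomizations=scenario.n_randomizations, seed=scenario.seed
        )
    else:
        seq = removal_order(landscape.traps, scenario.policy)
        curve = species_loss_given_order(matrix, seq)
    curve.landscape_id = landscape.landscape_id
    curve.policy = scenario.policy
    return curve


def scenario_table(
    items: Sequence[tuple[Landscape, IncidenceMatrix]],
    scenarios: Sequence[RemovalScenario],
    k_values: Sequence[int] = (8, 4),
) -> pd.DataFrame:
    """Tidy mean-loss table: one row per (landscape, policy, k).

    A requested k exceeding a landscape's trap count is flagged
    (``k_exceeds_T``) rather than silently dropped.
    """
    rows = []
    for landscape, matrix in items:
        curves = {s.policy: scenario_loss_curve(landscape, matrix, s) for s in scenarios}
        for policy, curve in curves.items():
            for k in k_values:
                exceeds = k > matrix.n_traps
                sd = None
                if not exceeds and curve.sd_loss_pct is not None:
                    sd = float(curve.sd_loss_pct[np.flatnonzero(curve.k == k)[0]])
                rows.append(
                    {
                        "landscape_id": landscape.landscape_id,
                        "policy": policy,
                        "k": k,
                        "mean_loss_pct": np.nan if exceeds else curve.at(k),
                        "sd_loss_pct": sd,
                        "n_randomizations": curve.n_paths,
                        "k_exceeds_T": exceeds,
                    }
                )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scenario comparison and landscape regressions


def compare_scenarios(table: pd.DataFrame, k: int) -> dict:
    """Blocked comparison of mean species loss among removal policies at one k.

    Landscape is the blocking factor (each landscape contributes one
    mean-loss value per policy).  The overall test is a likelihood-ratio
    chi-square between the linear models loss ~ landscape + policy and
    loss ~ landscape; pairwise policy contrasts are paired t-tests
    (raw p-values, no multiplicity correction).
    """
    sub = table[(table["k"] == k) & (~table["k_exceeds_T"])]
    wide = sub.pivot(index="landscape_id", columns="policy", values="mean_loss_pct")
    wide = wide.dropna()
    policies = list(wide.columns)
    n_land, n_pol = wide.shape
    if n_pol < 2:
        raise ValueError("need at least two policies to compare")
    if n_land < 2:
        raise ValueError("need at least two landscapes to compare")

    y = wide.to_numpy().ravel()  # landscape-major
    land_idx = np.repeat(np.arange(n_land), n_pol)
    pol_idx = np.tile(np.arange(n_pol), n_land)

    def rss(with_policy: bool) -> float:
        cols = [np.ones_like(y)]
        cols += [(land_idx == l).astype(float) for l in range(1, n_land)]
        if with_policy:
            cols += [(pol_idx == p).astype(float) for p in range(1, n_pol)]
        X = np.column_stack(cols)
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return float(resid @ resid)

    rss0, rss1 = rss(False), rss(True)
    n = y.size
    if rss1 <= 0:  # perfect fit; degenerate but legal (identical policies)
        chi2 = 0.0 if np.isclose(rss0, rss1) else np.inf
    else:
        chi2 = n * np.log(rss0 / rss1)
    df = n_pol - 1
    p_overall = float(stats.chi2.sf(chi2, df)) if np.isfinite(chi2) else 0.0

    contrasts = []
    for i in range(n_pol):
        for j in range(i + 1, n_pol):
            a, b = wide.iloc[:, i], wide.iloc[:, j]
            diff = float((a - b).mean())
            if np.allclose(a, b):
                t_stat, p = 0.0, 1.0
            else:
                t_stat, p = stats.ttest_rel(a, b)
            contrasts.append(
                {
                    "policy_a": policies[i],
                    "policy_b": policies[j],
                    "mean_difference": diff,
                    "t": float(t_stat),
                    "p": float(p),
                    "direction": (
                        f"{policies[i]} loses "
                        + ("more" if diff > 0 else "less" if diff < 0 else "equal")
                    ),
                }
            )
    return {
        "k": int(k),
        "n_landscapes": int(n_land),
        "policies": policies,
        "overall": {"chi2": float(chi2), "df": int(df), "p": p_overall},
        "pairwise": contrasts,
        "policy_means": {p: float(wide[p].mean()) for p in policies},
    }


@dataclass(frozen=True)
class RegressionFit:
    slope: float
    intercept: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int


def landscape_ols(x: Sequence[float], y: Sequence[float]) -> RegressionFit:
    """Simple OLS of a per-landscape response on landscape tree cover."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 landscapes")
    if np.ptp(x) == 0:
        raise ValueError("zero variance in the explanatory variable")
    res = stats.linregress(x, y)
    n = x.size
    if np.ptp(y) == 0:  # flat response: slope 0, no explained variance
        return RegressionFit(0.0, float(y[0]), 0.0, 0.0, 1.0, n)
    return RegressionFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        f_statistic=float(res.slope**2 / res.stderr**2) if res.stderr > 0 else np.inf,
        p_value=float(res.pvalue),
        n=n,
    )


def loss_covariate_regression(
    pairs: Iterable[tuple[float, float]]
) -> RegressionFit:
    """OLS of per-landscape mean species loss % on landscape tree cover %."""
    xs, ys = zip(*pairs)
    return landscape_ols(xs, ys)


def coverage_covariate_regression(
    pairs: Iterable[tuple[float, float]]
) -> RegressionFit:
    """OLS of per-landscape coverage at a fixed trap number on tree cover %."""
    xs, ys = zip(*pairs)
    return landscape_ols(xs, ys)
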