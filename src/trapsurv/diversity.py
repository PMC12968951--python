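"""Incidence-based diversity estimation and beta-diversity turnover.

All estimators operate on the incidence-frequency summary of a binary
species x trap matrix: with T sampling units (traps), each species i has
an incidence frequency Y_i (number of traps where it was detected at
least once), U = sum_i Y_i total incidences, and Q1/Q2 counts of species
seen in exactly one/two traps ("uniques"/"duplicates").

Estimators implemented, with the small-sample conventions of the
incidence-based estimation literature (Chao2 and its coverage
companion):

* Chao2 richness
    S_obs + ((T-1)/T) * Q1^2 / (2*Q2)            if Q2 > 0
    S_obs + ((T-1)/T) * Q1*(Q1-1) / 2            if Q2 = 0
* Sample completeness (order q = 0): S_obs / Chao2.
* Sample coverage (order q = 1): the probability that an additional
  sampling unit contains only already-detected species,
    C_hat = 1 - (Q1/U) * A,
    A = (T-1)Q1 / ((T-1)Q1 + 2Q2)                if Q2 > 0
    A = (T-1)(Q1-1) / ((T-1)(Q1-1) + 2)          if Q2 = 0, Q1 > 0
  and C_hat = 1 when Q1 = 0.
* Coverage rarefied to t < T sampling units (combinatorial expectation)
  and extrapolated to T + t* units via the geometric factor A^(t*+1).
* Expected rarefied richness S(t) = sum_i [1 - C(T-Y_i, t)/C(T, t)],
  the analytic mean of observed richness over all size-t trap subsets.

Beta diversity between two traps is the replacement (turnover)
component, 2*min(b, c)/(a + b + c), where a species are shared and b, c
are unique to either trap: species swaps count, pure richness
differences do not.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .data_model import IncidenceMatrix


@dataclass(frozen=True)
class IncidenceFrequencies:
    """Sufficient statistics of an incidence matrix for all estimators."""

    T: int
    Y: np.ndarray  # per-species incidence frequencies, each in 1..T

    def __post_init__(self) -> None:
        object.__setattr__(self, "Y", np.asarray(self.Y, dtype=np.int64))
        if self.T < 1:
            raise ValueError("need at least one sampling unit")
        if self.Y.size and ((self.Y < 1) | (self.Y > self.T)).any():
            raise ValueError("incidence frequencies must lie in 1..T")

    @property
    def S_obs(self) -> int:
        return int(self.Y.size)

    @property
    def U(self) -> int:
        return int(self.Y.sum())

    @property
    def Q1(self) -> int:
        return int((self.Y == 1).sum())

    @property
    def Q2(self) -> int:
        return int((self.Y == 2).sum())


def incidence_frequencies(matrix: IncidenceMatrix) -> IncidenceFrequencies:
    """Summarise a binary matrix; all-zero species rows are not expected
    (matrix construction drops them) and would be rejected here."""
    if matrix.n_traps < 1:
        raise ValueError("matrix has no traps")
    Y = matrix.values.sum(axis=1).astype(np.int64)
    if (Y == 0).any():
        raise ValueError("matrix contains species with zero incidences")
    return IncidenceFrequencies(T=matrix.n_traps, Y=Y)


def _log_comb(n: np.ndarray | int, k: int) -> np.ndarray:
    """log C(n, k) elementwise, with C(n, k) = 0 (log = -inf) when n < k."""
    n = np.asarray(n, dtype=np.float64)
    out = np.full(n.shape, -np.inf)
    ok = n >= k
    nk = n[ok]
    out[ok] = gammaln(nk + 1) - gammaln(k + 1) - gammaln(nk - k + 1)
    return out


def _comb_ratio(n_top: np.ndarray | int, n_bot: int, k: int) -> np.ndarray:
    """C(n_top, k) / C(n_bot, k), computed in log space (0 when n_top < k)."""
    log_top = _log_comb(n_top, k)
    log_bot = _log_comb(n_bot, k)
    with np.errstate(invalid="ignore"):
        return np.where(np.isneginf(log_top), 0.0, np.exp(log_top - log_bot))


def chao2_richness(freqs: IncidenceFrequencies) -> float:
    """Nonparametric lower-bound richness estimate from uniques/duplicates."""
    if freqs.T < 2:
        raise ValueError("Chao2 is undefined on a single sampling unit")
    correction = (freqs.T - 1) / freqs.T
    if freqs.Q2 > 0:
        extra = correction * freqs.Q1**2 / (2.0 * freqs.Q2)
    else:
        extra = correction * freqs.Q1 * (freqs.Q1 - 1) / 2.0
    return freqs.S_obs + extra


def sample_completeness(freqs: IncidenceFrequencies) -> float:
    """Fraction of the estimated richness that was actually observed."""
    return freqs.S_obs / chao2_richness(freqs)


def _a_hat(freqs: IncidenceFrequencies) -> float:
    """Coverage-deficit slope factor A (in [0, 1))."""
    T, Q1, Q2 = freqs.T, freqs.Q1, freqs.Q2
    if Q1 == 0:
        return 0.0
    if Q2 > 0:
        return (T - 1) * Q1 / ((T - 1) * Q1 + 2.0 * Q2)
    return (T - 1) * (Q1 - 1) / ((T - 1) * (Q1 - 1) + 2.0)


def coverage_observed(freqs: IncidenceFrequencies) -> float:
    """Estimated sample coverage at the observed number of traps."""
    if freqs.U == 0:
        raise ValueError("no incidences")
    if freqs.T < 2:
        raise ValueError("coverage estimation needs at least two sampling units")
    if freqs.Q1 == 0:
        return 1.0
    return 1.0 - (freqs.Q1 / freqs.U) * _a_hat(freqs)


def coverage_rarefied(freqs: IncidenceFrequencies, t: int) -> float:
    """Expected coverage of a random subset of t < T sampling units."""
    if not 1 <= t < freqs.T:
        raise ValueError(f"t={t} out of range 1..{freqs.T - 1}")
    if freqs.U == 0:
        raise ValueError("no incidences")
    weights = freqs.Y / freqs.U
    ratio = _comb_ratio(freqs.T - freqs.Y, freqs.T - 1, t)
    return float(1.0 - np.sum(weights * ratio))


def coverage_extrapolated(freqs: IncidenceFrequencies, t_star: int) -> float:
    """Projected coverage at T + t_star sampling units (t_star >= 0)."""
    if t_star < 0:
        raise ValueError("t_star must be >= 0")
    if freqs.U == 0:
        raise ValueError("no incidences")
    if freqs.Q1 == 0:
        return 1.0
    return 1.0 - (freqs.Q1 / freqs.U) * _a_hat(freqs) ** (t_star + 1)


def coverage_at(freqs: IncidenceFrequencies, t: int) -> float:
    """Coverage at any t: rarefied below T, observed at T, extrapolated above."""
    if t < 1:
        raise ValueError("t must be >= 1")
    if t < freqs.T:
        return coverage_rarefied(freqs, t)
    if t == freqs.T:
        return coverage_observed(freqs)
    return coverage_extrapolated(freqs, t - freqs.T)


def coverage_profile(
    freqs: IncidenceFrequencies, t_grid: Iterable[int]
) -> pd.DataFrame:
    """Stitched coverage profile over a grid of sampling-unit counts."""
    rows = []
    for t in t_grid:
        method = (
            "rarefied" if t < freqs.T else "observed" if t == freqs.T else "extrapolated"
        )
        rows.append({"t": int(t), "coverage": coverage_at(freqs, t), "method": method})
    return pd.DataFrame(rows)


def expected_rarefied_richness(freqs: IncidenceFrequencies, t: int) -> float:
    """Mean observed richness over all size-t trap subsets (exact expectation)."""
    if not 1 <= t <= freqs.T:
        raise ValueError(f"t={t} out of range 1..{freqs.T}")
    ratio = _comb_ratio(freqs.T - freqs.Y, freqs.T, t)
    return float(np.sum(1.0 - ratio))


# ---------------------------------------------------------------------------
# beta diversity (replacement / turnover component)


@dataclass(frozen=True)
class PairDecomposition:
    """Species overlap of one trap pair: a shared, b and c unique."""

    a: int
    b: int
    c: int
    beta_repl: float


def pairwise_replacement(set_a: set, set_b: set) -> PairDecomposition:
    """Replacement component 2*min(b, c)/(a+b+c) for two species sets."""
    if not set_a and not set_b:
        raise ValueError("turnover undefined for two empty species sets")
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    return PairDecomposition(a=a, b=b, c=c, beta_repl=2.0 * min(b, c) / (a + b + c))


@dataclass(frozen=True)
class TurnoverSummary:
    mean_beta_repl: float
    n_pairs_used: int
    n_pairs_skipped: int  # pairs where both traps were empty


def landscape_mean_turnover(matrix: IncidenceMatrix) -> TurnoverSummary:
    """Mean replacement turnover over all unordered trap pairs of a landscape.

    Pairs in which both traps are empty have an undefined ratio and are
    excluded from the mean (counted in ``n_pairs_skipped``).
    """
    if matrix.n_traps < 2:
        raise ValueError("turnover needs at least two traps")
    sets = matrix.column_sets()
    values = []
    skipped = 0
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            if not sets[i] and not sets[j]:
                skipped += 1
                continue
            values.append(pairwise_replacement(sets[i], sets[j]).beta_repl)
    if not values:
        raise ValueError("all trap pairs are empty; turnover undefined")
    return TurnoverSummary(
        mean_beta_repl=float(np.mean(values)),
        n_pairs_used=len(values),
        n_pairs_skipped=skipped,
    )


def landscape_summary_table(
    matrices: dict[str, IncidenceMatrix], t_grid: Sequence[int] = (4, 8, 16, 32)
) -> pd.DataFrame:
    """Per-landscape diversity summary: richness, completeness, coverage, turnover."""
    rows = []
    for lid, matrix in matrices.items():
        f = incidence_frequencies(matrix)
        row: dict[str, object] = {
            "landscape_id": lid,
            "T": f.T,
            "S_obs": f.S_obs,
            "chao2": chao2_richness(f),
            "completeness": sample_completeness(f),
            "coverage_observed": coverage_observed(f),
        }
        for t in t_grid:
            row[f"coverage_t{t}"] = coverage_at(f, t)
        row["mean_turnover"] = landscape_mean_turnover(matrix).mean_beta_repl
        rows.append(row)
    return pd.DataFrame(rows)
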