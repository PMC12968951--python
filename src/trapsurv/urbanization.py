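"""Trap-scale urbanization index.

A trap's surroundings are summarised by two percentages measured in a
250-m buffer: tree cover and the angular share of the horizon free of
artificial barriers (roads, buildings).  The urbanization index is the
Euclidean distance of the pair from the hypothetical full-natural state
(100% tree cover, 100% barrier-free), rescaled so the index itself runs
from 0 (fully natural) to 100 (fully urban).

The rescaling divides the raw distance by sqrt(2) — a global,
data-independent scaling — rather than min-max normalising within a
dataset, so indices are comparable across studies and stable on subsets.
The two deficits are weighted equally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from .data_model import Landscape, TrapSite, ValidationError

_SQRT2 = math.sqrt(2.0)


class UndefinedCorrelationError(ValueError):
    """Pearson correlation requested on a zero-variance variable."""


@dataclass(frozen=True)
class UrbanizationIndex:
    value: float
    tree_cover_250m: float
    barrier_free_angle: float


def compute_urbanization_index(
    tree_cover_250m: float, barrier_free_angle: float
) -> UrbanizationIndex:
    """Distance from the (100, 100) full-natural state, scaled to [0, 100].

    value = sqrt((100 - tree)^2 + (100 - barrier)^2) / sqrt(2)

    0 at (100, 100); 100 at (0, 0); strictly increasing in each deficit.
    """
    for name, v in (
        ("tree_cover_250m", tree_cover_250m),
        ("barrier_free_angle", barrier_free_angle),
    ):
        if not 0.0 <= v <= 100.0:
            raise ValidationError(f"{name}={v} outside [0, 100]")
    raw = math.hypot(100.0 - tree_cover_250m, 100.0 - barrier_free_angle)
    return UrbanizationIndex(
        value=raw / _SQRT2,
        tree_cover_250m=tree_cover_250m,
        barrier_free_angle=barrier_free_angle,
    )


def add_urbanization_index(traps: Sequence[TrapSite]) -> list[TrapSite]:
    """Return copies of ``traps`` with the index field filled in."""
    return [
        replace(
            t,
            urbanization_index=compute_urbanization_index(
                t.tree_cover_250m, t.barrier_free_angle
            ).value,
        )
        for t in traps
    ]


@dataclass(frozen=True)
class CorrelationReport:
    """Design-balance diagnostics for a study's covariates.

    ``trap_tree_vs_barrier``: Pearson r between trap-scale tree cover and
    barrier-free angle over all traps.  ``landscape_mean_tree_vs_cover``:
    Pearson r between the per-landscape mean of trap-scale tree cover and
    the landscape-scale (2-km) tree cover — high values indicate traps
    were deployed proportionally across the urbanization gradient.
    """

    trap_tree_vs_barrier: float
    landscape_mean_tree_vs_cover: float
    trap_tree_vs_landscape_cover: float
    n_traps: int
    n_landscapes: int


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance in a correlation variable")
    return float(np.corrcoef(x, y)[0, 1])


def covariate_correlations(
    traps: Sequence[TrapSite], landscapes: Sequence[Landscape]
) -> CorrelationReport:
    if len(traps) < 3:
        raise ValueError("need at least 3 traps")
    if len(landscapes) < 3:
        raise ValueError("need at least 3 landscapes")
    tree = np.array([t.tree_cover_250m for t in traps])
    barrier = np.array([t.barrier_free_angle for t in traps])
    mean_tree = np.array(
        [np.mean([t.tree_cover_250m for t in l.traps]) for l in landscapes]
    )
    cover = np.array([l.tree_cover_2km for l in landscapes])
    cover_by_id = {l.landscape_id: l.tree_cover_2km for l in landscapes}
    trap_cover = np.array([cover_by_id[t.landscape_id] for t in traps])
    return CorrelationReport(
        trap_tree_vs_barrier=_pearson(tree, barrier),
        landscape_mean_tree_vs_cover=_pearson(mean_tree, cover),
        trap_tree_vs_landscape_cover=_pearson(tree, trap_cover),
        n_traps=len(traps),
        n_landscapes=len(landscapes),
    )
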