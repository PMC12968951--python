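import numpy as np
import pytest

from trapsurv.data_model import IncidenceMatrix, TrapSite
from trapsurv.diversity import IncidenceFrequencies


@pytest.fixture
def m1() -> IncidenceMatrix:
    """Worked 5-species x 4-trap incidence fixture.

    Row sums (incidence frequencies) are (4, 2, 1, 1, 1), so T=4,
    S_obs=5, U=9, Q1=3, Q2=1.  Column species sets: t1={sp1,sp2,sp3},
    t2={sp1,sp2,sp4}, t3={sp1,sp5}, t4={sp1}.
    """
    return IncidenceMatrix(
        species_ids=["sp1", "sp2", "sp3", "sp4", "sp5"],
        trap_ids=["t1", "t2", "t3", "t4"],
        values=np.array(
            [
                [1, 1, 1, 1],
                [1, 1, 0, 0],
                [1, 0, 0, 0],
                [0, 1, 0, 0],
                [0, 0, 1, 0],
            ]
        ),
    )


@pytest.fixture
def m1_freqs(m1) -> IncidenceFrequencies:
    from trapsurv.diversity import incidence_frequencies

    return incidence_frequencies(m1)


def random_incidence_matrix(
    rng: np.random.Generator,
    n_species: int | None = None,
    n_traps: int | None = None,
) -> IncidenceMatrix:
    """Random fixture with every species detected at least once."""
    S = n_species or int(rng.integers(2, 15))
    T = n_traps or int(rng.integers(2, 9))
    values = (rng.random((S, T)) < rng.uniform(0.15, 0.7)).astype(np.int8)
    for i in range(S):  # guarantee no all-zero species row
        if values[i].sum() == 0:
            values[i, rng.integers(T)] = 1
    return IncidenceMatrix(
        species_ids=[f"sp{i}" for i in range(S)],
        trap_ids=[f"t{j}" for j in range(T)],
        values=values,
    )


def make_traps(indices: dict[str, float], landscape_id: str = "L1") -> list[TrapSite]:
    """Traps with prescribed urbanization indices (covariates back-solved)."""
    traps = []
    for tid, idx in indices.items():
        cover = 100.0 - idx  # diagonal identity: index(100-x, 100-x) = x
        traps.append(
            TrapSite(
                trap_id=tid,
                landscape_id=landscape_id,
                tree_cover_250m=cover,
                barrier_free_angle=cover,
                urbanization_index=idx,
            )
        )
    return traps
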