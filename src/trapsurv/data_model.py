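"""Domain types and tabular I/O for multi-landscape trap surveys.

The sampling design is a set of landscapes (sites near potential entry
points such as ports or airports), each holding a grid of baited funnel
traps.  Every trap carries two local covariates measured in a 250-m
buffer — percent tree cover and the angular percentage of the horizon
free of artificial barriers — while each landscape carries a single
tree-cover percentage measured in a 2-km buffer.  Captures are pooled
over the whole season per (species, trap); collection-interval structure
is deliberately not modelled.

Canonical CSV schemas (comma separated, UTF-8, header required):

* ``traps.csv`` — trap_id, landscape_id, tree_cover_250m,
  barrier_free_angle[, urbanization_index]
* ``landscapes.csv`` — landscape_id, tree_cover_2km
* ``captures.csv`` — trap_id, species_id, count, origin, guild
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

ORIGINS = ("native", "non_native")
GUILDS = ("longhorned", "bark", "ambrosia", "other")

TRAP_COLUMNS = ("trap_id", "landscape_id", "tree_cover_250m", "barrier_free_angle")
LANDSCAPE_COLUMNS = ("landscape_id", "tree_cover_2km")
CAPTURE_COLUMNS = ("trap_id", "species_id", "count", "origin", "guild")


class SchemaError(ValueError):
    """A table is missing a required column or has an unreadable layout."""


class ValidationError(ValueError):
    """A row violates a domain invariant (range, uniqueness, vocabulary)."""


class ReferentialIntegrityError(ValueError):
    """A capture references a trap that is not part of the trap table."""


@dataclass(frozen=True)
class TrapSite:
    """One trap with its landscape membership and 250-m-buffer covariates."""

    trap_id: str
    landscape_id: str
    tree_cover_250m: float
    barrier_free_angle: float
    urbanization_index: float | None = None

    def __post_init__(self) -> None:
        for name in ("tree_cover_250m", "barrier_free_angle"):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValidationError(
                    f"trap {self.trap_id!r}: {name}={v} outside [0, 100]"
                )


@dataclass(frozen=True)
class Landscape:
    """A site with its 2-km tree cover and its member traps."""

    landscape_id: str
    tree_cover_2km: float
    traps: tuple[TrapSite, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.tree_cover_2km <= 100.0:
            raise ValidationError(
                f"landscape {self.landscape_id!r}: tree_cover_2km="
                f"{self.tree_cover_2km} outside [0, 100]"
            )

    @property
    def n_traps(self) -> int:
        return len(self.traps)


@dataclass(frozen=True)
class CaptureRecord:
    """Season-pooled captures of one species in one trap."""

    trap_id: str
    species_id: str
    count: int
    origin: str
    guild: str

    def __post_init__(self) -> None:
        if not self.species_id:
            raise ValidationError("species_id must be nonempty")
        if self.count < 0:
            raise ValidationError(
                f"capture ({self.trap_id}, {self.species_id}): count {self.count} < 0"
            )
        if self.origin not in ORIGINS:
            raise ValidationError(
                f"origin {self.origin!r} not in allowed tokens {ORIGINS}"
            )
        if self.guild not in GUILDS:
            raise ValidationError(
                f"guild {self.guild!r} not in allowed tokens {GUILDS}"
            )


@dataclass
class AbundanceMatrix:
    """Species x trap matrix of season-total counts for one landscape.

    Rows (species) are sorted lexicographically; columns keep the trap
    table's order.  Traps with zero captures are legal all-zero columns:
    a damaged or empty trap is still a sampling unit.
    """

    species_ids: list[str]
    trap_ids: list[str]
    values: np.ndarray  # (S, T) nonnegative ints

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int64)
        if self.values.shape != (len(self.species_ids), len(self.trap_ids)):
            raise ValueError("matrix shape does not match id lists")
        if (self.values < 0).any():
            raise ValidationError("abundance cells must be nonnegative")

    def to_incidence(self) -> "IncidenceMatrix":
        return IncidenceMatrix(
            species_ids=list(self.species_ids),
            trap_ids=list(self.trap_ids),
            values=(self.values >= 1).astype(np.int8),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.trap_ids)


@dataclass
class IncidenceMatrix:
    """Binary species x trap detection matrix; the unit of all diversity work."""

    species_ids: list[str]
    trap_ids: list[str]
    values: np.ndarray  # (S, T) in {0, 1}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int8)
        if self.values.shape != (len(self.species_ids), len(self.trap_ids)):
            raise ValueError("matrix shape does not match id lists")
        if not np.isin(self.values, (0, 1)).all():
            raise ValidationError("incidence cells must be 0 or 1")

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_traps(self) -> int:
        return len(self.trap_ids)

    def column_sets(self) -> list[set[str]]:
        """Species set observed in each trap, in column order."""
        sp = np.asarray(self.species_ids, dtype=object)
        return [set(sp[self.values[:, j] == 1]) for j in range(self.n_traps)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.species_ids, columns=self.trap_ids)


# ---------------------------------------------------------------------------
# readers / writers


def _require_columns(df: pd.DataFrame, required: Sequence[str], path: object) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")


def load_trap_table(path: str | Path) -> list[TrapSite]:
    """Read ``traps.csv`` into validated :class:`TrapSite` objects.

    Percentages are checked against [0, 100] and trap ids must be unique
    within a landscape; violations report the offending data row number
    (1-based, header excluded).
    """
    df = pd.read_csv(path, dtype={"trap_id": str, "landscape_id": str})
    _require_columns(df, TRAP_COLUMNS, path)
    has_index = "urbanization_index" in df.columns
    traps: list[TrapSite] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        key = (row.landscape_id, row.trap_id)
        if key in seen:
            raise ValidationError(
                f"{path}: row {i}: duplicate trap_id {row.trap_id!r} in "
                f"landscape {row.landscape_id!r}"
            )
        seen.add(key)
        try:
            idx = getattr(row, "urbanization_index", None) if has_index else None
            if idx is not None and pd.isna(idx):
                idx = None
            traps.append(
                TrapSite(
                    trap_id=str(row.trap_id),
                    landscape_id=str(row.landscape_id),
                    tree_cover_250m=float(row.tree_cover_250m),
                    barrier_free_angle=float(row.barrier_free_angle),
                    urbanization_index=None if idx is None else float(idx),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}: row {i}: {err}") from None
    return traps


def load_landscape_table(path: str | Path) -> dict[str, float]:
    """Read ``landscapes.csv`` as a landscape_id -> tree_cover_2km map."""
    df = pd.read_csv(path, dtype={"landscape_id": str})
    _require_columns(df, LANDSCAPE_COLUMNS, path)
    if df["landscape_id"].duplicated().any():
        dup = df.loc[df["landscape_id"].duplicated(), "landscape_id"].iloc[0]
        raise ValidationError(f"{path}: duplicate landscape_id {dup!r}")
    out: dict[str, float] = {}
    for i, row in enumerate(df.itertuples(index=False), start=1):
        cover = float(row.tree_cover_2km)
        if not 0.0 <= cover <= 100.0:
            raise ValidationError(
                f"{path}: row {i}: tree_cover_2km={cover} outside [0, 100]"
            )
        out[str(row.landscape_id)] = cover
    return out


def load_capture_table(path: str | Path) -> list[CaptureRecord]:
    """Read ``captures.csv`` into validated :class:`CaptureRecord` objects."""
    df = pd.read_csv(path, dtype={"trap_id": str, "species_id": str})
    _require_columns(df, CAPTURE_COLUMNS, path)
    records: list[CaptureRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=1):
        try:
            records.append(
                CaptureRecord(
                    trap_id=str(row.trap_id),
                    species_id=str(row.species_id),
                    count=int(row.count),
                    origin=str(row.origin),
                    guild=str(row.guild),
                )
            )
        except ValidationError as err:
            raise ValidationError(f"{path}: row {i}: {err}") from None
    return records


def write_trap_table(traps: Iterable[TrapSite], path: str | Path) -> None:
    rows = [dataclasses.asdict(t) for t in traps]
    df = pd.DataFrame(rows)
    if df["urbanization_index"].isna().all():
        df = df.drop(columns=["urbanization_index"])
    df.to_csv(path, index=False)


def write_landscape_table(covers: dict[str, float], path: str | Path) -> None:
    pd.DataFrame(
        {"landscape_id": list(covers), "tree_cover_2km": list(covers.values())}
    ).to_csv(path, index=False)


def write_capture_table(records: Iterable[CaptureRecord], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(r) for r in records]).to_csv(path, index=False)


def group_landscapes(
    traps: Iterable[TrapSite], covers: dict[str, float]
) -> list[Landscape]:
    """Assemble :class:`Landscape` objects from a trap list and a cover map."""
    by_site: dict[str, list[TrapSite]] = {}
    for t in traps:
        by_site.setdefault(t.landscape_id, []).append(t)
    unknown = set(by_site) - set(covers)
    if unknown:
        raise ReferentialIntegrityError(
            f"traps reference landscapes absent from the landscape table: "
            f"{sorted(unknown)}"
        )
    return [
        Landscape(landscape_id=lid, tree_cover_2km=covers[lid], traps=tuple(members))
        for lid, members in by_site.items()
    ]


# ---------------------------------------------------------------------------
# matrix construction


def build_matrices(
    traps: Sequence[TrapSite],
    records: Iterable[CaptureRecord],
    landscape_id: str,
    origin: str | None = None,
    guild: str | None = None,
) -> tuple[AbundanceMatrix, IncidenceMatrix]:
    """Build the (abundance, incidence) matrices for one landscape.

    ``origin``/``guild`` optionally restrict the community (e.g. only
    non-native species).  Species with no capture in the landscape after
    filtering are absent from the rows; traps with no captures remain as
    all-zero columns.  Records for traps of other landscapes are ignored,
    but a record naming a trap unknown to the whole trap table is a
    referential-integrity error.
    """
    site_traps = [t for t in traps if t.landscape_id == landscape_id]
    if not site_traps:
        raise ValueError(f"landscape {landscape_id!r} has no traps")
    trap_ids = [t.trap_id for t in site_traps]
    known_ids = {t.trap_id for t in traps}
    col = {tid: j for j, tid in enumerate(trap_ids)}

    totals: dict[tuple[str, str], int] = {}
    for r in records:
        if r.trap_id not in known_ids:
            raise ReferentialIntegrityError(
                f"capture references unknown trap_id {r.trap_id!r}"
            )
        if r.trap_id not in col:
            continue
        if origin is not None and r.origin != origin:
            continue
        if guild is not None and r.guild != guild:
            continue
        key = (r.species_id, r.trap_id)
        totals[key] = totals.get(key, 0) + r.count

    species_ids = sorted({sp for (sp, _), n in totals.items() if n > 0})
    values = np.zeros((len(species_ids), len(trap_ids)), dtype=np.int64)
    row = {sp: i for i, sp in enumerate(species_ids)}
    for (sp, tid), n in totals.items():
        if n > 0:
            values[row[sp], col[tid]] += n
    abundance = AbundanceMatrix(species_ids=species_ids, trap_ids=trap_ids, values=values)
    return abundance, abundance.to_incidence()


def read_species_list_workbook(
    path: str | Path,
    sheet_name: int | str = 0,
    column_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Best-effort adapter for a deposited spreadsheet of capture records.

    The deposited workbook's internal layout is not standardised, so this
    is a convenience stub, not a guaranteed parser: it reads one sheet and
    renames columns via ``column_map`` (spreadsheet name -> canonical
    name).  The result still has to satisfy the ``captures.csv`` schema
    before it can feed :func:`build_matrices`.
    """
    df = pd.read_excel(path, sheet_name=sheet_name)
    if column_map:
        df = df.rename(columns=column_map)
    missing = [c for c in CAPTURE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{path}: after renaming, capture columns are still missing: {missing}; "
            "pass a column_map matching the workbook's headers"
        )
    return df[list(CAPTURE_COLUMNS)]
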