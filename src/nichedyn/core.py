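"""Core data model and file I/O.

The pipeline operates on two primitive containers: a :class:`ClimateGrid`
(gridded climate for one region — cell ids, coordinates, and ``k >= 2``
climate variables) and a :class:`RangeSet` (the set of grid cells occupied by
one species in one role, native or alien, within one realm).  Cell identity is
an opaque integer; coordinates are carried along for plotting only and play no
algorithmic role.  All tabular I/O is delimited text (CSV).

Missing-data policy: rows with missing climate values are dropped at load
time and counted; downstream stages assume complete cases.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("nichedyn")

__all__ = [
    "ClimateGrid",
    "RangeSet",
    "AnalysisConfig",
    "FormatError",
    "EmptyInputError",
    "ContractError",
    "read_climate_grid",
    "write_climate_grid",
    "read_presence_table",
    "write_presence_table",
    "resolve_range_overlap",
    "filter_min_presences",
]


class FormatError(ValueError):
    """A delimited input file does not match the expected schema."""


class EmptyInputError(ValueError):
    """An input file or table contains no usable rows."""


class ContractError(ValueError):
    """A function precondition was violated."""


@dataclass
class ClimateGrid:
    """Gridded climate for one region.

    Parameters
    ----------
    region_id : str
        Label for the region (e.g. a realm name).
    cell_ids : ndarray of int, shape (n,)
        Unique opaque cell identifiers.
    xy : ndarray, shape (n, 2)
        Cell coordinates (used for plotting only).
    climate : ndarray, shape (n, k)
        Climate values, ``k >= 2``, no missing values.
    variables : list of str
        Names of the ``k`` climate variables.
    n_dropped : int
        Rows dropped at load time because of missing climate values.
    """

    region_id: str
    cell_ids: np.ndarray
    xy: np.ndarray
    climate: np.ndarray
    variables: list[str]
    n_dropped: int = 0

    def __post_init__(self) -> None:
        self.cell_ids = np.asarray(self.cell_ids, dtype=np.int64)
        self.xy = np.asarray(self.xy, dtype=float)
        self.climate = np.asarray(self.climate, dtype=float)
        if self.climate.ndim != 2 or self.climate.shape[1] < 2:
            raise ContractError("climate must be 2-D with k >= 2 variables")
        if len(np.unique(self.cell_ids)) != len(self.cell_ids):
            raise ContractError("cell_ids must be unique")
        if np.isnan(self.climate).any():
            raise ContractError("climate contains missing values after load")
        if len(self.variables) != self.climate.shape[1]:
            raise ContractError("variable names do not match climate columns")
        # index from cell id to row position, used by RangeSet lookups
        self._index = {int(c): i for i, c in enumerate(self.cell_ids)}

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    def rows_for(self, cell_ids: Iterable[int]) -> np.ndarray:
        """Row positions for the given cell ids (raises on unknown ids)."""
        try:
            return np.array([self._index[int(c)] for c in cell_ids], dtype=np.intp)
        except KeyError as exc:  # pragma: no cover - defensive
            raise ContractError(f"unknown cell id {exc.args[0]}") from exc

    def climate_for(self, cell_ids: Iterable[int]) -> np.ndarray:
        """Climate matrix for the given cell ids, in the given order."""
        return self.climate[self.rows_for(cell_ids)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"cell_id": self.cell_ids, "x": self.xy[:, 0], "y": self.xy[:, 1]}
        )
        for j, v in enumerate(self.variables):
            df[v] = self.climate[:, j]
        return df


@dataclass
class RangeSet:
    """Cells occupied by one species in one role within one realm."""

    species_id: str
    role: str  # "native" | "alien"
    realm_id: str
    cell_ids: frozenset[int]

    def __post_init__(self) -> None:
        if self.role not in ("native", "alien"):
            raise ContractError(f"role must be 'native' or 'alien', got {self.role!r}")
        self.cell_ids = frozenset(int(c) for c in self.cell_ids)

    @property
    def n(self) -> int:
        return len(self.cell_ids)

    def sorted_cells(self) -> np.ndarray:
        return np.array(sorted(self.cell_ids), dtype=np.int64)


@dataclass
class AnalysisConfig:
    """Tunable settings shared across pipeline stages.

    ``grid_resolution`` is the side length R of the ordination-space density
    grid (100 cells per axis by default); ``analog_quantile`` sets the
    background-density cutoff defining shared (analog) climates (0 = strict
    positivity); ``occupancy_correction`` divides occurrence density by
    background availability before normalizing; the expansion/unfilling
    binarization threshold is 0.1; candidate models within ``delta_aicc_cutoff``
    of the best non-nested model form the confidence set.
    """

    grid_resolution: int = 100
    analog_quantile: float = 0.0
    occupancy_quantile: float = 0.05
    occupancy_correction: bool = True
    binary_threshold: float = 0.1
    delta_aicc_cutoff: float = 4.0
    min_presences: int = 5
    # SDM settings
    sdm_min_presences: int = 20
    sdm_trees: int = 200
    sdm_pa_sets: int = 5
    sdm_replicates: int = 3
    sdm_calibration_fraction: float = 0.7
    sdm_auc_cutoff: float = 0.7
    sdm_axes: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.grid_resolution < 10:
            raise ContractError("grid_resolution must be >= 10")
        for name in ("binary_threshold", "delta_aicc_cutoff", "sdm_auc_cutoff"):
            if getattr(self, name) <= 0:
                raise ContractError(f"{name} must be positive")
        if not 0.0 <= self.analog_quantile < 1.0:
            raise ContractError("analog_quantile must be in [0, 1)")

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Load from a YAML (or JSON, a YAML subset) or TOML config file."""
        path = Path(path)
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(path.read_text())
        else:
            with open(path) as fh:
                data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise FormatError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# I/O


def read_climate_grid(path: str | Path, region_id: str | None = None) -> ClimateGrid:
    """Read a climate grid from CSV.

    Required columns: ``cell_id``, ``x``, ``y``; every remaining column is a
    climate variable.  Rows with missing climate are dropped and counted.
    """
    df = pd.read_csv(path)
    required = {"cell_id", "x", "y"}
    if not required <= set(df.columns):
        raise FormatError(f"climate grid requires columns {sorted(required)}")
    variables = [c for c in df.columns if c not in required]
    if len(variables) < 2:
        raise FormatError("climate grid requires at least 2 climate variables")
    n0 = len(df)
    if n0 == 0:
        raise EmptyInputError(f"empty climate grid: {path}")
    df = df.dropna(subset=variables)
    n_dropped = n0 - len(df)
    if n_dropped:
        logger.warning("dropped %d rows with missing climate from %s", n_dropped, path)
    if region_id is None:
        region_id = Path(path).stem
    return ClimateGrid(
        region_id=region_id,
        cell_ids=df["cell_id"].to_numpy(),
        xy=df[["x", "y"]].to_numpy(),
        climate=df[variables].to_numpy(),
        variables=variables,
        n_dropped=n_dropped,
    )


def write_climate_grid(grid: ClimateGrid, path: str | Path) -> None:
    grid.to_frame().to_csv(path, index=False)


def read_presence_table(
    path: str | Path, grid: ClimateGrid | dict[str, ClimateGrid]
) -> list[RangeSet]:
    """Read presences from CSV into validated :class:`RangeSet` objects.

    Required columns: ``species_id``, ``role``, ``realm_id``, ``cell_id``.
    Cell ids not present in the corresponding grid are dropped with a logged
    count.  ``grid`` may be a single grid or a mapping keyed by role
    (``native``/``alien``) when the two roles live on different grids.
    """
    df = pd.read_csv(path)
    required = ["species_id", "role", "realm_id", "cell_id"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"presence table lacks required column(s): {missing}")
    if len(df) == 0:
        raise EmptyInputError(f"empty presence table: {path}")

    def grid_for(role: str) -> ClimateGrid:
        if isinstance(grid, dict):
            return grid[role]
        return grid

    out: list[RangeSet] = []
    for (sp, role, realm), sub in df.groupby(
        ["species_id", "role", "realm_id"], sort=True
    ):
        g = grid_for(str(role))
        known = set(int(c) for c in g.cell_ids)
        cells = [int(c) for c in sub["cell_id"]]
        valid = [c for c in cells if c in known]
        n_unknown = len(cells) - len(valid)
        if n_unknown:
            logger.warning(
                "%s/%s/%s: dropped %d presence(s) with unknown cell ids",
                sp, role, realm, n_unknown,
            )
        if valid:
            out.append(RangeSet(str(sp), str(role), str(realm), frozenset(valid)))
    return out


def write_presence_table(ranges: Sequence[RangeSet], path: str | Path) -> None:
    rows = []
    for r in ranges:
        for c in sorted(r.cell_ids):
            rows.append((r.species_id, r.role, r.realm_id, c))
    pd.DataFrame(
        rows, columns=["species_id", "role", "realm_id", "cell_id"]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Range preparation


def resolve_range_overlap(native: RangeSet, alien: RangeSet) -> RangeSet:
    """Assign cells occupied by both ranges to the alien range.

    Alien range maps are curated to contain only introduced populations,
    whereas native maps may include misclassified areas, so overlapping cells
    are removed from the native side.  Returns the reduced native range; the
    alien range is unchanged.  An empty result is legal and is caught later by
    the minimum-presence filter.
    """
    if native.species_id != alien.species_id:
        raise ContractError(
            f"species mismatch: {native.species_id!r} vs {alien.species_id!r}"
        )
    if native.role != "native" or alien.role != "alien":
        raise ContractError("expected (native, alien) roles in that order")
    return RangeSet(
        native.species_id,
        "native",
        native.realm_id,
        native.cell_ids - alien.cell_ids,
    )


def filter_min_presences(
    ranges: Sequence[RangeSet], minimum: int
) -> tuple[list[RangeSet], list[tuple[RangeSet, int]]]:
    """Split ranges into (kept, dropped) by a minimum presence count.

    Niche comparison requires at least 5 presences per range; suitability
    models require at least 20 native presences.  Dropped ranges are returned
    with their counts for logging.
    """
    if minimum < 1:
        raise ContractError("minimum must be >= 1")
    kept = [r for r in ranges if r.n >= minimum]
    dropped = [(r, r.n) for r in ranges if r.n < minimum]
    for r, n in dropped:
        logger.info(
            "dropped %s/%s/%s: %d presence(s) < minimum %d",
            r.species_id, r.role, r.realm_id, n, minimum,
        )
    return kept, dropped
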