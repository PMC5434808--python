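"""Domain types and CSV I/O for meta-analysis of 2x2 tables.

A meta-analysis dataset is an ordered collection of comparative studies,
each reporting the number of events ``x`` out of ``n`` subjects in a
treatment and a control arm.  Study order is preserved everywhere; nothing
in the package ever sorts studies.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Study2x2",
    "MetaDataset",
    "DatasetError",
    "MissingColumnError",
    "NonIntegerCountError",
    "CountBoundsError",
    "TooFewStudiesError",
    "DEFAULT_COLUMNS",
    "read_dataset",
    "write_dataset",
    "toy_fixtures",
    "pre_eclampsia",
    "pre_eclampsia_available",
]

#: canonical field -> default CSV header name
DEFAULT_COLUMNS: Mapping[str, str] = {
    "id": "study_id",
    "x1": "events_trt",
    "n1": "n_trt",
    "x2": "events_ctl",
    "n2": "n_ctl",
}


class DatasetError(ValueError):
    """Base class for dataset validation failures."""


class MissingColumnError(DatasetError):
    pass


class NonIntegerCountError(DatasetError):
    pass


class CountBoundsError(DatasetError):
    pass


class TooFewStudiesError(DatasetError):
    pass


@dataclass(frozen=True)
class Study2x2:
    """One study's 2x2 table: events/size in treatment and control arms."""

    id: str
    x1: int
    n1: int
    x2: int
    n2: int

    def __post_init__(self) -> None:
        for name in ("x1", "n1", "x2", "n2"):
            val = getattr(self, name)
            if isinstance(val, bool) or not isinstance(val, (int, np.integer)):
                raise NonIntegerCountError(
                    f"study {self.id!r}: {name}={val!r} is not an integer count"
                )
            object.__setattr__(self, name, int(val))
        if self.n1 < 1 or self.n2 < 1:
            raise CountBoundsError(f"study {self.id!r}: group sizes must be >= 1")
        if not (0 <= self.x1 <= self.n1):
            raise CountBoundsError(
                f"study {self.id!r}: x1={self.x1} outside [0, n1={self.n1}]"
            )
        if not (0 <= self.x2 <= self.n2):
            raise CountBoundsError(
                f"study {self.id!r}: x2={self.x2} outside [0, n2={self.n2}]"
            )

    @property
    def N(self) -> int:
        return self.n1 + self.n2

    def has_zero_cell(self) -> bool:
        """True if any of the four cells (x, n-x per arm) is empty."""
        return (
            self.x1 == 0
            or self.x2 == 0
            or self.x1 == self.n1
            or self.x2 == self.n2
        )


class MetaDataset:
    """Ordered collection of at least two 2x2 studies."""

    def __init__(self, studies: Iterable[Study2x2]):
        self.studies: tuple[Study2x2, ...] = tuple(studies)
        if len(self.studies) < 2:
            raise TooFewStudiesError(
                f"a meta-analysis needs K >= 2 studies, got K={len(self.studies)}"
            )

    def __len__(self) -> int:
        return len(self.studies)

    def __iter__(self):
        return iter(self.studies)

    def __getitem__(self, i):
        return self.studies[i]

    def __eq__(self, other) -> bool:
        return isinstance(other, MetaDataset) and self.studies == other.studies

    @property
    def K(self) -> int:
        return len(self.studies)

    def _arr(self, field: str) -> np.ndarray:
        return np.array([getattr(s, field) for s in self.studies], dtype=float)

    @property
    def x1(self) -> np.ndarray:
        return self._arr("x1")

    @property
    def n1(self) -> np.ndarray:
        return self._arr("n1")

    @property
    def x2(self) -> np.ndarray:
        return self._arr("x2")

    @property
    def n2(self) -> np.ndarray:
        return self._arr("n2")

    @property
    def N(self) -> np.ndarray:
        return self.n1 + self.n2

    @property
    def ids(self) -> list[str]:
        return [s.id for s in self.studies]

    def swap_arms(self) -> "MetaDataset":
        """Exchange treatment and control arms in every study."""
        return MetaDataset(
            Study2x2(s.id, s.x2, s.n2, s.x1, s.n1) for s in self.studies
        )


def _parse_count(value: str, row_label: str, col: str) -> int:
    try:
        f = float(value)
    except (TypeError, ValueError):
        raise NonIntegerCountError(
            f"row {row_label}: column {col!r} value {value!r} is not a number"
        ) from None
    if f != int(f):
        raise NonIntegerCountError(
            f"row {row_label}: column {col!r} value {value!r} is not an "
            "exact integer count (decimals are rejected, not rounded)"
        )
    return int(f)


def read_dataset(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> MetaDataset:
    """Read a meta-analysis dataset from CSV.

    Parameters
    ----------
    path
        CSV file with one row per study.
    dialect
        Optional mapping from canonical field names
        (``id, x1, n1, x2, n2``) to the file's column names; defaults to
        :data:`DEFAULT_COLUMNS`.
    """
    cols = dict(DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh)
        header = reader.fieldnames or []
        for field, col in cols.items():
            if col not in header:
                raise MissingColumnError(
                    f"{path.name}: required column {col!r} (field {field!r}) "
                    f"not found in header {header}"
                )
        studies = []
        for i, row in enumerate(reader, start=2):  # header is line 1
            label = f"{i} (study {row.get(cols['id'], '?')!r})"
            studies.append(
                Study2x2(
                    id=str(row[cols["id"]]),
                    x1=_parse_count(row[cols["x1"]], label, cols["x1"]),
                    n1=_parse_count(row[cols["n1"]], label, cols["n1"]),
                    x2=_parse_count(row[cols["x2"]], label, cols["x2"]),
                    n2=_parse_count(row[cols["n2"]], label, cols["n2"]),
                )
            )
    return MetaDataset(studies)


def write_dataset(
    data: MetaDataset,
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
) -> None:
    """Write a dataset to CSV; exact round-trip with :func:`read_dataset`."""
    cols = dict(DEFAULT_COLUMNS)
    if dialect:
        cols.update(dialect)
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow([cols[f] for f in ("id", "x1", "n1", "x2", "n2")])
        for s in data:
            writer.writerow([s.id, s.x1, s.n1, s.x2, s.n2])


def toy_fixtures() -> dict[str, MetaDataset]:
    """Small deterministic datasets used throughout the test-suite.

    ``identical``  five balanced copies of the same null table (all OR = 1);
    ``k3``         three studies small enough for hand arithmetic;
    ``zero_cell``  contains one study with an empty cell;
    ``unbalanced`` hand-sized studies with unequal allocation.
    """
    identical = MetaDataset(
        Study2x2(f"s{i}", 5, 10, 5, 10) for i in range(1, 6)
    )
    k3 = MetaDataset(
        [
            Study2x2("a", 3, 10, 6, 12),
            Study2x2("b", 5, 20, 4, 18),
            Study2x2("c", 12, 30, 7, 25),
        ]
    )
    zero_cell = MetaDataset(
        [
            Study2x2("z1", 0, 10, 2, 10),
            Study2x2("z2", 4, 12, 3, 11),
            Study2x2("z3", 6, 15, 8, 16),
        ]
    )
    unbalanced = MetaDataset(
        [
            Study2x2("u1", 4, 10, 9, 30),
            Study2x2("u2", 8, 25, 3, 14),
            Study2x2("u3", 10, 40, 11, 22),
            Study2x2("u4", 7, 18, 6, 20),
        ]
    )
    return {
        "identical": identical,
        "k3": k3,
        "zero_cell": zero_cell,
        "unbalanced": unbalanced,
    }


_PRE_ECLAMPSIA_RESOURCE = "pre_eclampsia.csv"


def _pre_eclampsia_path():
    return resources.files("bbmeta.datasets").joinpath(_PRE_ECLAMPSIA_RESOURCE)


def pre_eclampsia_available() -> bool:
    """Whether the packaged diuretics/pre-eclampsia dataset is present."""
    try:
        return _pre_eclampsia_path().is_file()
    except ModuleNotFoundError:
        return False


def pre_eclampsia() -> MetaDataset:
    """The nine-trial diuretics-for-pre-eclampsia meta-analysis (N = 6942).

    The classic Collins et al. dataset of nine randomized trials of
    diuretics for the prevention of pre-eclampsia, a standard worked
    example for odds-ratio meta-analysis methods.
    """
    res = _pre_eclampsia_path()
    if not res.is_file():
        raise FileNotFoundError(
            "packaged pre-eclampsia dataset is missing; reinstall bbmeta "
            "or supply the CSV explicitly via read_dataset()"
        )
    with resources.as_file(res) as p:
        return read_dataset(p)
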