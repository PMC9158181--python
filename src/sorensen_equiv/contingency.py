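"""Joint-enrichment contingency tables and binary enrichment profiles.

Two feature lists are compared through the 2x2 cross-tabulation of the
enriched / non-enriched status of a fixed universe of ``n`` annotation
terms: ``n11`` terms enriched in both lists, ``n10`` only in the first,
``n01`` only in the second and ``n00`` in neither.  The table, the
corresponding cell probabilities and the terms-by-lists 0/1 incidence
matrix from which tables are built all live here, together with their
plain-text (de)serialization.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EnrichmentContingencyTable",
    "JointEnrichmentProbs",
    "EnrichmentProfile",
    "build_table",
    "estimate_probs",
    "read_table",
    "write_table",
    "read_profile",
    "write_profile",
]

#: canonical CSV/JSON field order for a contingency table
CELL_NAMES = ("n11", "n10", "n01", "n00")


def _check_cell(name: str, value) -> int:
    if isinstance(value, bool) or not float(value).is_integer():
        raise ValueError(f"cell {name} must be an integer, got {value!r}")
    value = int(value)
    if value < 0:
        raise ValueError(f"cell {name} must be non-negative, got {value}")
    return value


@dataclass(frozen=True)
class EnrichmentContingencyTable:
    """Counts of jointly enriched / non-enriched terms for two lists.

    Attributes
    ----------
    n11, n10, n01, n00 : int
        Terms enriched in both lists, only in list 1, only in list 2,
        and in neither, respectively.  All non-negative; at least one
        cell must be positive so that the total ``n`` is at least 1.
    """

    n11: int
    n10: int
    n01: int
    n00: int

    def __post_init__(self) -> None:
        for name in CELL_NAMES:
            object.__setattr__(self, name, _check_cell(name, getattr(self, name)))
        if self.n < 1:
            raise ValueError("total number of terms n must be >= 1")

    @property
    def n(self) -> int:
        """Total number of terms (sum of the four cells)."""
        return self.n11 + self.n10 + self.n01 + self.n00

    def as_array(self) -> np.ndarray:
        """Cells in probability order ``(n11, n01, n10, n00)``."""
        return np.array([self.n11, self.n01, self.n10, self.n00], dtype=np.int64)

    def to_dict(self) -> dict:
        return {name: int(getattr(self, name)) for name in CELL_NAMES}

    def transpose(self) -> "EnrichmentContingencyTable":
        """Swap the roles of the two lists (exchanges n10 and n01)."""
        return EnrichmentContingencyTable(self.n11, self.n01, self.n10, self.n00)


@dataclass(frozen=True)
class JointEnrichmentProbs:
    """Cell probabilities (p11, p01, p10, p00) of the joint-enrichment law.

    ``p00`` is derived as ``1 - (p11 + p01 + p10)`` when not given, and the
    four probabilities must sum to 1 within 1e-12.
    """

    p11: float
    p01: float
    p10: float
    p00: float = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.p00 is None:
            object.__setattr__(self, "p00", 1.0 - (self.p11 + self.p01 + self.p10))
        for name in ("p11", "p01", "p10", "p00"):
            v = float(getattr(self, name))
            if not (-1e-12 <= v <= 1.0 + 1e-12):
                raise ValueError(f"probability {name}={v} outside [0, 1]")
            object.__setattr__(self, name, min(max(v, 0.0), 1.0))
        total = self.p11 + self.p01 + self.p10 + self.p00
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"cell probabilities sum to {total}, not 1")

    def as_array(self) -> np.ndarray:
        return np.array([self.p11, self.p01, self.p10, self.p00], dtype=float)

    @property
    def enrichment_probability(self) -> float:
        """Pr{term enriched in at least one list}, p11 + p01 + p10."""
        return self.p11 + self.p01 + self.p10


class EnrichmentProfile:
    """Terms-by-lists 0/1 incidence matrix (1 = term enriched in list).

    Thin wrapper around a pandas DataFrame indexed by unique term ids,
    one column per feature list.
    """

    def __init__(self, incidence: pd.DataFrame):
        if incidence.index.has_duplicates:
            dupes = incidence.index[incidence.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate term ids: {dupes}")
        values = incidence.to_numpy()
        if not np.isin(values, (0, 1)).all():
            raise ValueError("incidence matrix must contain only 0/1 values")
        self._frame = incidence.astype(np.int8)

    @classmethod
    def from_columns(
        cls, term_ids: Sequence[str], columns: Mapping[str, Iterable[int]]
    ) -> "EnrichmentProfile":
        frame = pd.DataFrame(
            {name: list(vec) for name, vec in columns.items()},
            index=pd.Index(term_ids, name="term_id"),
        )
        return cls(frame)

    @property
    def term_ids(self) -> list:
        return self._frame.index.tolist()

    @property
    def list_ids(self) -> list:
        return self._frame.columns.tolist()

    @property
    def n_terms(self) -> int:
        return len(self._frame)

    def column(self, list_id: str) -> np.ndarray:
        if list_id not in self._frame.columns:
            raise KeyError(f"unknown list identifier: {list_id!r}")
        return self._frame[list_id].to_numpy()

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"EnrichmentProfile({self.n_terms} terms x "
            f"{len(self.list_ids)} lists {self.list_ids})"
        )


def build_table(
    profile: EnrichmentProfile, list_a: str, list_b: str
) -> EnrichmentContingencyTable:
    """Cross-tabulate the enrichment status of two lists of a profile.

    ``list_a`` plays the role of "list 1" (its exclusive enrichments are
    counted in ``n10``); swapping the arguments transposes the table.
    """
    a = profile.column(list_a)
    b = profile.column(list_b)
    n11 = int(np.sum((a == 1) & (b == 1)))
    n10 = int(np.sum((a == 1) & (b == 0)))
    n01 = int(np.sum((a == 0) & (b == 1)))
    n00 = int(np.sum((a == 0) & (b == 0)))
    return EnrichmentContingencyTable(n11, n10, n01, n00)


def estimate_probs(table: EnrichmentContingencyTable) -> JointEnrichmentProbs:
    """Plug-in cell probabilities ``p_ij = n_ij / n``."""
    n = table.n
    return JointEnrichmentProbs(
        p11=table.n11 / n, p01=table.n01 / n, p10=table.n10 / n, p00=table.n00 / n
    )


def _sniff_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        return fmt
    suffix = path.suffix.lower()
    if suffix == ".json":
        return "json"
    if suffix in (".tsv", ".tab"):
        return "tsv"
    return "csv"


def read_table(path, fmt: str | None = None) -> EnrichmentContingencyTable:
    """Read a contingency table from CSV/TSV (header n11,n10,n01,n00) or JSON."""
    path = Path(path)
    fmt = _sniff_format(path, fmt)
    if fmt == "json":
        payload = json.loads(path.read_text())
        cells = {}
        for name in CELL_NAMES:
            if name not in payload:
                raise ValueError(f"{path}: missing cell {name!r}")
            cells[name] = payload[name]
    else:
        sep = "\t" if fmt == "tsv" else ","
        frame = pd.read_csv(path, sep=sep)
        missing = [name for name in CELL_NAMES if name not in frame.columns]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        if len(frame) != 1:
            raise ValueError(f"{path}: expected exactly one data row, got {len(frame)}")
        cells = {name: frame.at[0, name] for name in CELL_NAMES}
    try:
        return EnrichmentContingencyTable(**cells)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_table(table: EnrichmentContingencyTable, path, fmt: str | None = None) -> None:
    """Write a contingency table; format sniffed from the extension."""
    path = Path(path)
    fmt = _sniff_format(path, fmt)
    if fmt == "json":
        path.write_text(json.dumps(table.to_dict()) + "\n")
    else:
        sep = "\t" if fmt == "tsv" else ","
        header = sep.join(CELL_NAMES)
        row = sep.join(str(getattr(table, name)) for name in CELL_NAMES)
        path.write_text(f"{header}\n{row}\n")


def read_profile(path, fmt: str | None = None) -> EnrichmentProfile:
    """Read an incidence matrix: term-id first column, one column per list."""
    path = Path(path)
    fmt = _sniff_format(path, fmt)
    sep = "\t" if fmt == "tsv" else ","
    frame = pd.read_csv(path, sep=sep, index_col=0)
    return EnrichmentProfile(frame)


def write_profile(profile: EnrichmentProfile, path, fmt: str | None = None) -> None:
    path = Path(path)
    fmt = _sniff_format(path, fmt)
    sep = "\t" if fmt == "tsv" else ","
    profile.to_frame().to_csv(path, sep=sep, index_label="term_id")
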