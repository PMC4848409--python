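"""Binary alteration matrices, binarization of CNA call tables and frequency
summaries.

The universal input of the package is a tumors-by-events 0/1 table.  Two
dialects are read: a plain binary TSV (samples in rows) and a
GISTIC-thresholded genes-by-samples integer table, binarized by a
configurable absolute-call threshold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import MatrixFormatError, ValidationError

ROOT_LABEL = "root"

_RESERVED_EVENT_NAMES = frozenset({ROOT_LABEL, "any", "n"})


def _round_half_away(x: float) -> int:
    """Round to the nearest integer, halves away from zero (12.5 -> 13)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class BinaryAlterationMatrix:
    """Tumors-by-events 0/1 table with unique sample and event labels."""

    sample_ids: tuple[str, ...]
    event_names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.int8)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", tuple(map(str, self.sample_ids)))
        object.__setattr__(self, "event_names", tuple(map(str, self.event_names)))
        n, k = self.n, self.k
        if n < 1 or k < 1:
            raise ValidationError("matrix must have at least one sample and one event")
        if values.shape != (n, k):
            raise ValidationError(
                f"values shape {values.shape} does not match "
                f"{n} samples x {k} events"
            )
        if len(set(self.sample_ids)) != n:
            raise ValidationError("duplicate sample identifiers")
        if len(set(self.event_names)) != k:
            raise ValidationError("duplicate event names")
        bad = set(self.event_names) & _RESERVED_EVENT_NAMES
        if bad:
            raise ValidationError(f"reserved event name(s): {sorted(bad)}")
        if not np.isin(values, (0, 1)).all():
            i, j = np.argwhere(~np.isin(values, (0, 1)))[0]
            raise ValidationError(
                f"non-binary entry {values[i, j]} at sample "
                f"{self.sample_ids[i]!r}, event {self.event_names[j]!r}"
            )

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def k(self) -> int:
        return len(self.event_names)

    def column(self, event: str) -> np.ndarray:
        return self.values[:, self.event_names.index(event)]

    def select_events(self, events: list[str]) -> "BinaryAlterationMatrix":
        missing = [e for e in events if e not in self.event_names]
        if missing:
            raise ValidationError(f"unknown event(s): {missing}")
        idx = [self.event_names.index(e) for e in events]
        return BinaryAlterationMatrix(
            self.sample_ids, tuple(events), self.values[:, idx]
        )

    def resample(self, row_indices: np.ndarray) -> "BinaryAlterationMatrix":
        """Row resample with replacement; samples get fresh positional ids."""
        ids = tuple(f"b{i}" for i in range(len(row_indices)))
        return BinaryAlterationMatrix(
            ids, self.event_names, self.values[np.asarray(row_indices)]
        )

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(
            self.values, index=list(self.sample_ids), columns=list(self.event_names)
        )
        df.to_csv(path, sep="\t", index_label="sample")


@dataclass(frozen=True)
class FrequencyEstimates:
    """Clamped marginal and joint event probabilities from a cohort.

    All values are clamped into ``[floor, 1 - floor]`` with
    ``floor = 1/(2n)``; joint probabilities are re-capped at the smaller
    marginal afterwards so conditional probabilities never exceed 1.
    """

    n: int
    events: tuple[str, ...]
    marginal: dict[str, float]
    joint: dict[frozenset, float] = field(repr=False)
    pseudo_floor: float = 0.0

    def p(self, event: str) -> float:
        return self.marginal[event]

    def p2(self, a: str, b: str) -> float:
        if a == b:
            return self.marginal[a]
        return self.joint[frozenset((a, b))]


@dataclass(frozen=True)
class FrequencySummary:
    """Per-event altered-sample counts with integer percentages."""

    n: int
    counts: dict[str, int]
    percents: dict[str, int]
    any_count: int
    any_percent: int

    def to_dict(self) -> dict:
        out: dict = {
            event: {"count": self.counts[event], "percent": self.percents[event]}
            for event in self.counts
        }
        out["any"] = {"count": self.any_count, "percent": self.any_percent}
        out["n"] = self.n
        return out


def read_matrix(
    path, dialect: str = "binary_tsv", call_threshold: int = 2
) -> BinaryAlterationMatrix:
    """Read an alteration matrix.

    ``binary_tsv``: samples in rows, header of event names, entries 0/1.
    ``gistic_thresholded``: genes-by-samples integer calls in -2..2
    (transposed on read); entry x maps to 1 iff ``|x| >= call_threshold``.
    """
    if dialect not in ("binary_tsv", "gistic_thresholded"):
        raise ValueError(f"unknown dialect {dialect!r}")
    # pandas silently renames duplicate header names; check them verbatim
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    if len(set(header)) != len(header):
        dup = sorted({h for h in header if header.count(h) > 1})
        raise ValidationError(f"duplicate column name(s): {dup}")
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise MatrixFormatError(f"cannot parse {path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise MatrixFormatError(f"{path}: empty table")
    if df.isna().any().any():
        row, col = next(
            (r, c) for r in df.index for c in df.columns if pd.isna(df.at[r, c])
        )
        raise MatrixFormatError(
            f"missing value at row {row!r}, column {col!r}; "
            "missing data is rejected, not imputed"
        )
    if dialect == "gistic_thresholded":
        df = df.T  # genes-by-samples on disk -> samples-by-genes in memory
        arr = df.to_numpy()
        if not np.isin(arr, (-2, -1, 0, 1, 2)).all():
            i, j = np.argwhere(~np.isin(arr, (-2, -1, 0, 1, 2)))[0]
            raise MatrixFormatError(
                f"call {arr[i, j]!r} outside -2..2 at sample "
                f"{df.index[i]!r}, gene {df.columns[j]!r}"
            )
        values = (np.abs(arr) >= call_threshold).astype(np.int8)
    else:
        arr = df.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            i, j = np.argwhere(~np.isin(arr, (0, 1)))[0]
            raise MatrixFormatError(
                f"non-binary entry {arr[i, j]!r} at sample "
                f"{df.index[i]!r}, event {df.columns[j]!r}"
            )
        values = arr.astype(np.int8)
    try:
        return BinaryAlterationMatrix(
            tuple(map(str, df.index)), tuple(map(str, df.columns)), values
        )
    except ValidationError:
        raise


def frequency_summary(matrix: BinaryAlterationMatrix) -> FrequencySummary:
    """Altered-sample count and integer percent per event, plus any-event."""
    n = matrix.n
    counts = {
        event: int(matrix.values[:, j].sum())
        for j, event in enumerate(matrix.event_names)
    }
    percents = {e: _round_half_away(100.0 * c / n) for e, c in counts.items()}
    any_count = int((matrix.values.sum(axis=1) > 0).sum())
    return FrequencySummary(
        n=n,
        counts=counts,
        percents=percents,
        any_count=any_count,
        any_percent=_round_half_away(100.0 * any_count / n),
    )


def estimate_probabilities(
    matrix: BinaryAlterationMatrix, floor: float | None = None
) -> FrequencyEstimates:
    """Raw marginal/joint frequencies clamped into [floor, 1 - floor].

    The default floor 1/(2n) keeps every log-weight finite on resamples
    where an event is absent (or universal); joints are re-capped at
    min(p_i, p_j) after clamping.
    """
    n = matrix.n
    if n < 2:
        raise ValidationError("probability estimation requires n >= 2")
    if floor is None:
        floor = 1.0 / (2 * n)
    if not (0.0 < floor < 0.5):
        raise ValidationError("floor must be in (0, 0.5)")
    vals = matrix.values.astype(float)
    marg_raw = vals.mean(axis=0)
    marg = np.clip(marg_raw, floor, 1.0 - floor)
    marginal = dict(zip(matrix.event_names, map(float, marg)))
    joint: dict[frozenset, float] = {}
    co = (vals.T @ vals) / n
    for a in range(matrix.k):
        for b in range(a + 1, matrix.k):
            pab = float(np.clip(co[a, b], floor, 1.0 - floor))
            pab = min(pab, marg[a], marg[b])
            joint[frozenset((matrix.event_names[a], matrix.event_names[b]))] = pab
    return FrequencyEstimates(
        n=n,
        events=matrix.event_names,
        marginal=marginal,
        joint=joint,
        pseudo_floor=floor,
    )
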