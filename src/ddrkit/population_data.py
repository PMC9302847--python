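"""Labeled trial-by-neuron population responses and their CSV interchange format.

The universal input to every analysis in this package is a
:class:`ResponseSet`: a ``trials x neurons`` matrix of real-valued responses
(spike counts per analysis window) together with one condition label per
trial.  Internally everything is observation-major (rows are trials), the
conventional layout for statistical estimators; the neuroscience literature
often writes the transposed ``N x k`` response matrix, and the CSV reader /
writer are the only places where orientation matters.

The interchange format is a plain comma-delimited UTF-8 table: one header
row, first column ``condition``, remaining columns neuron identifiers, one
row per trial.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    DDRKitError,
    InsufficientDataError,
    ResponseSetParseError,
    ShapeError,
)

__all__ = [
    "ResponseSet",
    "ConditionPair",
    "ConditionStatistics",
    "read_response_set",
    "write_response_set",
    "condition_statistics",
    "condition_pairs",
]

LABEL_COLUMN = "condition"


@dataclass(frozen=True)
class ResponseSet:
    """Trial-by-neuron response matrix with per-trial condition labels.

    Parameters
    ----------
    counts
        Array of shape ``(n_trials, n_neurons)``; real-valued responses
        (e.g. spike counts in a fixed window).  Must be finite.
    condition_labels
        One categorical label per trial (length ``n_trials``).
    neuron_ids
        One identifier per neuron column (length ``n_neurons``).
    """

    counts: np.ndarray
    condition_labels: tuple[str, ...]
    neuron_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2:
            raise ShapeError(f"counts must be 2-D, got shape {counts.shape}")
        if not np.all(np.isfinite(counts)):
            raise DDRKitError("counts contain non-finite values")
        labels = tuple(str(c) for c in self.condition_labels)
        ids = tuple(str(i) for i in self.neuron_ids)
        if len(labels) != counts.shape[0]:
            raise ShapeError(
                f"{len(labels)} labels for {counts.shape[0]} trial rows"
            )
        if len(ids) != counts.shape[1]:
            raise ShapeError(
                f"{len(ids)} neuron ids for {counts.shape[1]} columns"
            )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "condition_labels", labels)
        object.__setattr__(self, "neuron_ids", ids)

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_neurons(self) -> int:
        return self.counts.shape[1]

    @property
    def conditions(self) -> tuple[str, ...]:
        """Unique condition labels, in order of first appearance."""
        seen: dict[str, None] = {}
        for lab in self.condition_labels:
            seen.setdefault(lab, None)
        return tuple(seen)

    def trial_indices(self, label: str) -> np.ndarray:
        idx = np.array(
            [i for i, lab in enumerate(self.condition_labels) if lab == label],
            dtype=int,
        )
        if idx.size == 0:
            raise DDRKitError(f"condition {label!r} not present")
        return idx

    def trials(self, label: str) -> np.ndarray:
        """Rows of ``counts`` belonging to one condition."""
        return self.counts[self.trial_indices(label)]

    def n_trials_for(self, label: str) -> int:
        return len(self.trial_indices(label))

    def subset(self, indices: Sequence[int] | np.ndarray) -> "ResponseSet":
        idx = np.asarray(indices, dtype=int)
        return ResponseSet(
            self.counts[idx],
            tuple(self.condition_labels[i] for i in idx),
            self.neuron_ids,
        )

    def select_conditions(self, labels: Iterable[str]) -> "ResponseSet":
        wanted = set(labels)
        idx = [i for i, lab in enumerate(self.condition_labels) if lab in wanted]
        missing = wanted - set(self.condition_labels)
        if missing:
            raise DDRKitError(f"conditions not present: {sorted(missing)}")
        return self.subset(idx)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.neuron_ids))
        df.insert(0, LABEL_COLUMN, list(self.condition_labels))
        return df


@dataclass(frozen=True)
class ConditionPair:
    """An ordered pair of condition labels to be decoded against each other."""

    label_a: str
    label_b: str

    def __post_init__(self) -> None:
        if self.label_a == self.label_b:
            raise DDRKitError("label_a and label_b must differ")

    def validate(self, rs: ResponseSet, min_trials: int = 2) -> None:
        for lab in (self.label_a, self.label_b):
            n = rs.n_trials_for(lab)  # raises if absent
            if n < min_trials:
                raise InsufficientDataError(
                    f"condition {lab!r} has {n} trials; need >= {min_trials}"
                )

    def swapped(self) -> "ConditionPair":
        return ConditionPair(self.label_b, self.label_a)


@dataclass(frozen=True)
class ConditionStatistics:
    """Per-condition means and the pooled noise covariance for one pair.

    ``sigma_pooled`` is the unweighted average ``(S_a + S_b) / 2`` of the two
    per-condition sample covariances (unbiased, ``k - 1`` denominator),
    regardless of whether the trial counts ``k_a`` and ``k_b`` match.
    """

    mu_a: np.ndarray
    mu_b: np.ndarray
    sigma_pooled: np.ndarray
    k_a: int
    k_b: int
    sigma_a: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]
    sigma_b: np.ndarray = field(repr=False, default=None)  # type: ignore[assignment]

    @property
    def delta_mu(self) -> np.ndarray:
        return self.mu_a - self.mu_b

    @property
    def n_neurons(self) -> int:
        return self.mu_a.shape[0]


def condition_statistics(rs: ResponseSet, pair: ConditionPair) -> ConditionStatistics:
    """Per-condition trial means and pooled covariance for a condition pair.

    Each condition needs at least two trials so that its sample covariance
    (computed from per-condition mean-centered trials with an unbiased
    ``k - 1`` denominator) is defined.
    """
    pair.validate(rs, min_trials=2)
    a = rs.trials(pair.label_a)
    b = rs.trials(pair.label_b)
    mu_a = a.mean(axis=0)
    mu_b = b.mean(axis=0)
    sigma_a = np.cov(a, rowvar=False, ddof=1)
    sigma_b = np.cov(b, rowvar=False, ddof=1)
    sigma_a = np.atleast_2d(sigma_a)
    sigma_b = np.atleast_2d(sigma_b)
    pooled = 0.5 * (sigma_a + sigma_b)
    pooled = 0.5 * (pooled + pooled.T)  # enforce exact symmetry
    return ConditionStatistics(
        mu_a=mu_a,
        mu_b=mu_b,
        sigma_pooled=pooled,
        k_a=a.shape[0],
        k_b=b.shape[0],
        sigma_a=sigma_a,
        sigma_b=sigma_b,
    )


def condition_pairs(rs: ResponseSet) -> Iterator[ConditionPair]:
    """All unordered condition pairs present in ``rs`` (decoding is pairwise)."""
    conds = rs.conditions
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            yield ConditionPair(conds[i], conds[j])


def read_response_set(
    path,
    label_column: str = LABEL_COLUMN,
    delimiter: str = ",",
) -> ResponseSet:
    """Read a ResponseSet from a delimited text table.

    The header row must name the label column (default ``condition``) and at
    least one neuron column.  Parse failures report the offending file line
    (header is line 1).
    """
    try:
        df = pd.read_csv(path, sep=delimiter, float_precision="round_trip")
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed rows, tokenizer errors
        raise ResponseSetParseError(f"{path}: {exc}") from exc
    if label_column not in df.columns:
        raise ResponseSetParseError(
            f"{path}: missing label column {label_column!r} "
            f"(columns: {list(df.columns)})"
        )
    neuron_cols = [c for c in df.columns if c != label_column]
    if not neuron_cols:
        raise ResponseSetParseError(f"{path}: no neuron columns after {label_column!r}")
    numeric = df[neuron_cols].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & ~df[neuron_cols].isna()
    bad |= df[neuron_cols].isna()
    if bad.any().any():
        row = int(np.where(bad.any(axis=1))[0][0])
        col = bad.columns[int(np.where(bad.iloc[row])[0][0])]
        raise ResponseSetParseError(
            f"{path}: non-numeric or missing value in column {col!r} "
            f"at row {row + 1} (file line {row + 2})"
        )
    return ResponseSet(
        counts=numeric.to_numpy(dtype=float),
        condition_labels=tuple(str(v) for v in df[label_column]),
        neuron_ids=tuple(neuron_cols),
    )


def write_response_set(rs: ResponseSet, path, delimiter: str = ",") -> None:
    """Write ``rs`` as a delimited text table; round-trips counts bit-exactly.

    Values are written with ``repr`` precision, which Python guarantees to
    round-trip for IEEE doubles.
    """
    df = rs.to_frame()
    df.to_csv(path, sep=delimiter, index=False,
              float_format=lambda x: repr(float(x)))
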