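"""Domain containers and file I/O for diagnostic test analysis.

The package works with four core objects: a binary Q-matrix linking test
items to the subskills they require, an item bank for the compensatory
multidimensional 3PL response model, person-by-item binary response
matrices, and person-by-subskill ability (theta) matrices.  All file
formats are plain comma-separated text with a header row.

A 30-item, 3-subskill reading-comprehension Q-matrix and its calibrated
item bank ship with the package (``load_builtin_qmatrix`` /
``load_builtin_item_bank``) and serve as the reference instrument for the
simulation study.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "QMatrix",
    "MirtItemBank",
    "ResponseMatrix",
    "AbilityMatrix",
    "FormatError",
    "read_qmatrix",
    "write_qmatrix",
    "read_item_bank",
    "write_item_bank",
    "read_responses",
    "write_responses",
    "load_builtin_qmatrix",
    "load_builtin_item_bank",
    "count_free_parameters",
]


class FormatError(ValueError):
    """Raised when an input file violates the documented CSV layout."""


@dataclass(frozen=True)
class QMatrix:
    """Binary item-by-subskill loading structure.

    Every item must require at least one subskill and every subskill must
    be required by at least one item; entries are 0/1.
    """

    entries: np.ndarray
    item_labels: tuple[str, ...] = ()
    skill_labels: tuple[str, ...] = ()

    def __post_init__(self):
        entries = np.asarray(self.entries, dtype=int)
        if entries.ndim != 2:
            raise FormatError("Q-matrix must be two-dimensional")
        if not np.isin(entries, (0, 1)).all():
            raise FormatError("Q-matrix entries must all be 0 or 1")
        object.__setattr__(self, "entries", entries)
        j, k = entries.shape
        item_labels = tuple(self.item_labels) or tuple(str(i + 1) for i in range(j))
        skill_labels = tuple(self.skill_labels) or tuple(f"skill{i + 1}" for i in range(k))
        if len(item_labels) != j or len(skill_labels) != k:
            raise ValueError("label lengths do not match Q-matrix shape")
        object.__setattr__(self, "item_labels", item_labels)
        object.__setattr__(self, "skill_labels", skill_labels)
        row_sums = entries.sum(axis=1)
        if (row_sums == 0).any():
            bad = item_labels[int(np.argmin(row_sums))]
            raise ValueError(f"item {bad} requires no subskill (all-zero Q-matrix row)")
        col_sums = entries.sum(axis=0)
        if (col_sums == 0).any():
            bad = skill_labels[int(np.argmin(col_sums))]
            raise ValueError(f"subskill {bad} is required by no item (all-zero Q-matrix column)")

    @property
    def n_items(self) -> int:
        return self.entries.shape[0]

    @property
    def n_skills(self) -> int:
        return self.entries.shape[1]

    @property
    def nnz(self) -> int:
        return int(self.entries.sum())


@dataclass(frozen=True)
class MirtItemBank:
    """Item parameters for the compensatory multidimensional 3PL model.

    ``slopes[j, k]`` is the discrimination of item ``j`` on subskill ``k``
    (zero wherever the Q-matrix is zero), ``intercepts[j]`` the easiness
    intercept d_j, and ``guessing[j]`` the lower asymptote c_j in [0, 1).
    """

    slopes: np.ndarray
    intercepts: np.ndarray
    guessing: np.ndarray

    def __post_init__(self):
        slopes = np.atleast_2d(np.asarray(self.slopes, dtype=float))
        intercepts = np.asarray(self.intercepts, dtype=float).ravel()
        guessing = np.asarray(self.guessing, dtype=float).ravel()
        if not (slopes.shape[0] == intercepts.size == guessing.size):
            raise ValueError("inconsistent item counts across slopes/intercepts/guessing")
        if (guessing < 0).any() or (guessing >= 1).any():
            raise ValueError("guessing parameters must lie in [0, 1)")
        object.__setattr__(self, "slopes", slopes)
        object.__setattr__(self, "intercepts", intercepts)
        object.__setattr__(self, "guessing", guessing)

    @property
    def n_items(self) -> int:
        return self.slopes.shape[0]

    @property
    def n_skills(self) -> int:
        return self.slopes.shape[1]

    def qmatrix_pattern(self) -> np.ndarray:
        """Binary sparsity pattern implied by the non-zero slopes."""
        return (self.slopes != 0).astype(int)

    def matches_qmatrix(self, q: QMatrix, strict: bool = True) -> bool:
        """True when no slope escapes the Q-matrix support.

        With ``strict`` the patterns must be identical (an estimated slope
        may legitimately shrink to 0.0, so engines use ``strict=False``).
        """
        pattern = self.qmatrix_pattern()
        if strict:
            return bool((pattern == q.entries).all())
        return bool((pattern <= q.entries).all())


@dataclass(frozen=True)
class ResponseMatrix:
    """Complete person-by-item binary response data."""

    values: np.ndarray
    person_ids: tuple[str, ...] = ()

    def __post_init__(self):
        values = np.atleast_2d(np.asarray(self.values))
        if values.size == 0:
            raise FormatError("response matrix is empty")
        if not np.isin(values, (0, 1)).all():
            raise FormatError("responses must all be 0 or 1 with no missing cells")
        values = values.astype(np.int8)
        object.__setattr__(self, "values", values)
        ids = tuple(self.person_ids) or tuple(str(i + 1) for i in range(values.shape[0]))
        if len(ids) != values.shape[0]:
            raise ValueError("person_ids length does not match row count")
        object.__setattr__(self, "person_ids", ids)

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class AbilityMatrix:
    """Person-by-subskill latent trait values on the standard-normal scale."""

    theta: np.ndarray

    def __post_init__(self):
        theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        if not np.isfinite(theta).all():
            raise ValueError("theta values must be finite")
        object.__setattr__(self, "theta", theta)

    @property
    def n_persons(self) -> int:
        return self.theta.shape[0]

    @property
    def n_skills(self) -> int:
        return self.theta.shape[1]


# ---------------------------------------------------------------------------
# CSV I/O (comma-separated, UTF-8, header row required)
# ---------------------------------------------------------------------------

def read_qmatrix(path: str | Path) -> QMatrix:
    """Read a Q-matrix CSV: an ``item`` label column plus one 0/1 column per subskill."""
    df = _read_csv(path)
    if df.columns[0].lower() == "item":
        item_labels = tuple(str(v) for v in df.iloc[:, 0])
        df = df.iloc[:, 1:]
    else:
        item_labels = ()
    values = df.to_numpy()
    if not np.isin(values, (0, 1)).all():
        raise FormatError(f"{path}: Q-matrix cells must be 0 or 1")
    return QMatrix(values, item_labels=item_labels, skill_labels=tuple(df.columns))


def write_qmatrix(q: QMatrix, path: str | Path) -> None:
    df = pd.DataFrame(q.entries, columns=list(q.skill_labels))
    df.insert(0, "item", list(q.item_labels))
    df.to_csv(path, index=False)


def read_item_bank(path: str | Path) -> MirtItemBank:
    """Read an item-bank CSV with columns ``item, a_1..a_K, d, c``."""
    df = _read_csv(path)
    a_cols = [c for c in df.columns if c.startswith("a_")]
    if not a_cols or "d" not in df.columns or "c" not in df.columns:
        raise FormatError(f"{path}: expected columns item, a_1..a_K, d, c")
    return MirtItemBank(
        slopes=df[a_cols].to_numpy(float),
        intercepts=df["d"].to_numpy(float),
        guessing=df["c"].to_numpy(float),
    )


def write_item_bank(bank: MirtItemBank, path: str | Path) -> None:
    cols = {f"a_{k + 1}": bank.slopes[:, k] for k in range(bank.n_skills)}
    df = pd.DataFrame({"item": np.arange(1, bank.n_items + 1), **cols,
                       "d": bank.intercepts, "c": bank.guessing})
    df.to_csv(path, index=False, float_format="%.6g")


def read_responses(path: str | Path) -> ResponseMatrix:
    """Read a response CSV: header of item labels, one 0/1 row per person."""
    df = _read_csv(path)
    if df.isna().any().any():
        raise FormatError(f"{path}: missing cells are not supported")
    return ResponseMatrix(df.to_numpy())


def write_responses(responses: ResponseMatrix, path: str | Path) -> None:
    df = pd.DataFrame(responses.values,
                      columns=[f"item{j + 1}" for j in range(responses.n_items)])
    df.to_csv(path, index=False)


def write_abilities(abilities: AbilityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(abilities.theta,
                      columns=[f"theta{k + 1}" for k in range(abilities.n_skills)])
    df.to_csv(path, index=False, float_format="%.6g")


def read_abilities(path: str | Path) -> AbilityMatrix:
    return AbilityMatrix(_read_csv(path).to_numpy(float))


def _read_csv(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: file is empty") from exc
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    if df.shape[0] == 0:
        raise FormatError(f"{path}: no data rows")
    return df


# ---------------------------------------------------------------------------
# Packaged reference instrument
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("skilldiag").joinpath("data", name)


def load_builtin_qmatrix() -> QMatrix:
    """The packaged 30-item x 3-subskill reading-comprehension Q-matrix."""
    with resources.as_file(_data_path("qmatrix.csv")) as p:
        return read_qmatrix(p)


def load_builtin_item_bank() -> MirtItemBank:
    """The packaged compensatory-3PL item parameters for the 30-item instrument."""
    with resources.as_file(_data_path("item_bank.csv")) as p:
        return read_item_bank(p)


# ---------------------------------------------------------------------------
# Analytic parameter counting
# ---------------------------------------------------------------------------

def count_free_parameters(model: str, q: QMatrix, *,
                          estimate_correlations: bool = False) -> int:
    """Number of free parameters each model spends on a given Q-matrix.

    - ``mirt``: one slope per non-zero Q entry plus an intercept and a
      guessing parameter per item; the latent prior is a fixed standard
      multinormal.  With ``estimate_correlations`` the K(K-1)/2 latent
      correlations are added.
    - ``gdina`` (saturated): ``2**K_j`` success probabilities per item
      (``K_j`` = number of required subskills) plus ``2**K - 1`` structural
      latent-class proportions.
    - ``rrum``: a baseline probability per item, one penalty per non-zero
      Q entry, plus the ``2**K - 1`` structural proportions.
    """
    j, k = q.entries.shape
    nnz = q.nnz
    name = model.strip().lower().replace("-", "")
    if name == "mirt":
        count = nnz + 2 * j
        if estimate_correlations:
            count += k * (k - 1) // 2
        return count
    if name == "gdina":
        row_sums = q.entries.sum(axis=1)
        return int((2 ** row_sums).sum()) + (2 ** k - 1)
    if name == "rrum":
        return j + nnz + (2 ** k - 1)
    raise ValueError(f"unknown model {model!r}; expected one of mirt, gdina, rrum")
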