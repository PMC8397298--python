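"""Reading, scoring and fixed-cut-off classification of Nijmegen questionnaire data.

The Nijmegen questionnaire is a 16-item symptom scale for hyperventilation
syndrome (HVS).  Each item is rated on a five-point Likert scale —
never (0), rarely (1), sometimes (2), often (3), very often (4) — so the
total score lies in [0, 64].  The conventional clinical rule classifies a
subject as HVS-positive when the total is strictly above 23; cut-off
optimisation elsewhere in this package uses the "at least c" convention.

This module owns the raw-data plumbing: validated per-subject records,
the vectorised :class:`ScoredDataset` container that the model consumes,
and CSV input/output in either item-level (16 columns) or total-score form.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "N_ITEMS",
    "ITEM_MIN",
    "ITEM_MAX",
    "TOTAL_MAX",
    "CONVENTIONAL_CUTOFF",
    "Sex",
    "SchemaError",
    "ValidationError",
    "QuestionnaireRecord",
    "ScoredDataset",
    "score_items",
    "classify_fixed_cutoff",
    "read_scores_csv",
    "write_scores_csv",
]

N_ITEMS = 16
ITEM_MIN = 0
ITEM_MAX = 4
TOTAL_MAX = N_ITEMS * ITEM_MAX  # 64
#: Conventional clinical rule: total strictly above this value is HVS-positive.
CONVENTIONAL_CUTOFF = 23


class Sex(str, enum.Enum):
    MALE = "male"
    FEMALE = "female"
    UNKNOWN = "unknown"

    @classmethod
    def parse(cls, value: object) -> "Sex":
        """Case-insensitive normalisation; unrecognised values map to UNKNOWN."""
        if isinstance(value, Sex):
            return value
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return cls.UNKNOWN
        text = str(value).strip().lower()
        if text in {"m", "male", "man", "1"}:
            return cls.MALE
        if text in {"f", "female", "woman", "2"}:
            return cls.FEMALE
        return cls.UNKNOWN


class SchemaError(ValueError):
    """The file-level structure (columns, header, emptiness) is wrong."""


class ValidationError(ValueError):
    """A value violates the questionnaire's scoring rules."""


def score_items(items: Sequence[int]) -> int:
    """Sum 16 Likert responses into the Nijmegen total score.

    Parameters
    ----------
    items
        Exactly 16 integers, each in {0, 1, 2, 3, 4}.

    Returns
    -------
    int
        The arithmetic sum, guaranteed to lie in [0, 64].

    Raises
    ------
    ValidationError
        If the count is not 16 or any response is out of range; the message
        names the offending (0-based) item index.
    """
    items = list(items)
    if len(items) != N_ITEMS:
        raise ValidationError(
            f"expected exactly {N_ITEMS} item responses, got {len(items)}"
        )
    total = 0
    for i, v in enumerate(items):
        if not float(v).is_integer() or not (ITEM_MIN <= int(v) <= ITEM_MAX):
            raise ValidationError(
                f"item index {i}: response {v!r} not an integer in "
                f"{{{ITEM_MIN},...,{ITEM_MAX}}}"
            )
        total += int(v)
    return total


def classify_fixed_cutoff(
    score: int, cutoff: int, convention: str = "at_least"
) -> int:
    """Classify a total score against a fixed cut-off.

    ``at_least`` returns 1 iff ``score >= cutoff`` (the convention used for
    cut-off optimisation, e.g. the headline "score >= 20" rule);
    ``greater_than`` returns 1 iff ``score > cutoff`` (the conventional
    "above 23" clinical rule).
    """
    if not (0 <= score <= TOTAL_MAX):
        raise ValidationError(f"score {score} outside [0, {TOTAL_MAX}]")
    if convention == "at_least":
        return int(score >= cutoff)
    if convention == "greater_than":
        return int(score > cutoff)
    raise ValueError(f"unknown convention {convention!r}")


@dataclass
class QuestionnaireRecord:
    """One subject's questionnaire response.

    Either ``items`` (16 Likert values) or ``total`` must be given; when both
    are present the total must equal the item sum.
    """

    subject_id: str
    sex: Sex = Sex.UNKNOWN
    bmi: float | None = None
    items: tuple[int, ...] | None = None
    total: int | None = None

    def __post_init__(self) -> None:
        self.sex = Sex.parse(self.sex)
        if self.bmi is not None and self.bmi < 0:
            raise ValidationError(f"subject {self.subject_id}: negative BMI")
        if self.items is not None:
            computed = score_items(self.items)
            self.items = tuple(int(v) for v in self.items)
            if self.total is None:
                self.total = computed
            elif self.total != computed:
                raise ValidationError(
                    f"subject {self.subject_id}: total {self.total} != item sum {computed}"
                )
        if self.total is None:
            raise ValidationError(
                f"subject {self.subject_id}: need items or a total score"
            )
        if not (0 <= self.total <= TOTAL_MAX):
            raise ValidationError(
                f"subject {self.subject_id}: total {self.total} outside [0, {TOTAL_MAX}]"
            )


@dataclass
class ScoredDataset:
    """Vector of integer total scores with optional strata and true labels.

    ``true_label`` (1 = diseased) exists only for synthetic data, where the
    generating class of each score is known; real questionnaire data have no
    gold standard, which is the whole point of the latent-class model.
    """

    scores: np.ndarray
    stratum: np.ndarray | None = None
    true_label: np.ndarray | None = None
    subject_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores)
        n = len(self.scores)
        if n < 1:
            raise ValidationError("dataset must contain at least one score")
        # integer scores must respect the questionnaire range; float scores
        # (continuous-mode synthetic data) are exempt
        if np.issubdtype(self.scores.dtype, np.integer) and (
            np.any(self.scores < 0) or np.any(self.scores > TOTAL_MAX)
        ):
            bad = int(np.flatnonzero((self.scores < 0) | (self.scores > TOTAL_MAX))[0])
            raise ValidationError(
                f"row {bad}: score {self.scores[bad]} outside [0, {TOTAL_MAX}]"
            )
        for name in ("stratum", "true_label", "subject_id"):
            v = getattr(self, name)
            if v is not None:
                v = np.asarray(v)
                setattr(self, name, v)
                if len(v) != n:
                    raise ValidationError(
                        f"{name} has length {len(v)}, expected {n}"
                    )
        if self.true_label is not None and not np.isin(self.true_label, (0, 1)).all():
            raise ValidationError("true_label may contain only 0/1")

    @property
    def n(self) -> int:
        return len(self.scores)

    def subset(self, mask: np.ndarray) -> "ScoredDataset":
        mask = np.asarray(mask, bool)
        return ScoredDataset(
            scores=self.scores[mask],
            stratum=None if self.stratum is None else self.stratum[mask],
            true_label=None if self.true_label is None else self.true_label[mask],
            subject_id=None if self.subject_id is None else self.subject_id[mask],
        )

    def by_stratum(self) -> dict[str, "ScoredDataset"]:
        """Split into male/female subsets (``unknown`` rows are dropped)."""
        if self.stratum is None:
            raise ValueError("dataset has no stratum labels")
        out: dict[str, ScoredDataset] = {}
        for s in (Sex.MALE.value, Sex.FEMALE.value):
            mask = self.stratum == s
            if mask.any():
                out[s] = self.subset(mask)
        return out

    def to_frame(self) -> pd.DataFrame:
        data: dict[str, np.ndarray] = {}
        if self.subject_id is not None:
            data["subject_id"] = self.subject_id
        if self.stratum is not None:
            data["sex"] = self.stratum
        data["total"] = self.scores
        if self.true_label is not None:
            data["true_label"] = self.true_label
        return pd.DataFrame(data)


#: Default column names recognised in CSV input; override via ``columns=``.
DEFAULT_COLUMNS: Mapping[str, object] = {
    "subject_id": "subject_id",
    "sex": "sex",
    "total": "total",
    "item_prefix": "item",
    "true_label": "true_label",
}


def _item_columns(header: Iterable[str], prefix: str) -> list[str]:
    cols = [c for c in header if c.startswith(prefix) and c[len(prefix):].isdigit()]
    return sorted(cols, key=lambda c: int(c[len(prefix):]))


def read_scores_csv(
    path: str | Path, columns: Mapping[str, object] | None = None
) -> ScoredDataset:
    """Read questionnaire data from a headed CSV into a :class:`ScoredDataset`.

    The file must contain either the 16 item columns (``item1``..``item16``
    by default) — which are summed per row — or a single total-score column.
    A sex column, if present, becomes the stratum labels.  Row order is
    preserved; validation errors cite the offending (0-based) data row.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if columns:
        cmap.update(columns)
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file") from exc
    if df.empty:
        raise SchemaError(f"{path}: no data rows")

    item_cols = _item_columns(df.columns, str(cmap["item_prefix"]))
    total_col = str(cmap["total"])

    if item_cols:
        if len(item_cols) != N_ITEMS:
            raise SchemaError(
                f"{path}: found {len(item_cols)} item columns, expected {N_ITEMS}"
            )
        totals = np.empty(len(df), dtype=int)
        for r, (_, row) in enumerate(df[item_cols].iterrows()):
            try:
                totals[r] = score_items(row.to_list())
            except ValidationError as exc:
                raise ValidationError(f"{path} row {r}: {exc}") from exc
    elif total_col in df.columns:
        raw = df[total_col]
        totals = np.empty(len(df), dtype=int)
        for r, v in enumerate(raw):
            fv = float(v)
            if not fv.is_integer() or not (0 <= fv <= TOTAL_MAX):
                raise ValidationError(
                    f"{path} row {r}: total {v!r} not an integer in [0, {TOTAL_MAX}]"
                )
            totals[r] = int(fv)
    else:
        raise SchemaError(
            f"{path}: need either {N_ITEMS} '{cmap['item_prefix']}N' columns "
            f"or a '{total_col}' column"
        )

    stratum = None
    sex_col = str(cmap["sex"])
    if sex_col in df.columns:
        stratum = np.array([Sex.parse(v).value for v in df[sex_col]])

    true_label = None
    tl_col = str(cmap["true_label"])
    if tl_col in df.columns:
        true_label = df[tl_col].to_numpy(dtype=int)

    subject_id = None
    id_col = str(cmap["subject_id"])
    if id_col in df.columns:
        subject_id = df[id_col].to_numpy(dtype=str)

    return ScoredDataset(
        scores=totals, stratum=stratum, true_label=true_label, subject_id=subject_id
    )


def write_scores_csv(dataset: ScoredDataset, path: str | Path) -> None:
    """Write a dataset in total-score CSV form (round-trips with the reader)."""
    dataset.to_frame().to_csv(path, index=False)
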