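"""Multi-class evaluation metrics and per-movement evaluation reports.

Three metrics summarize agreement between predicted and expert FMS scores:
accuracy (the fraction of exact matches, N_correct / N_total), macro-F1
(the unweighted mean of one-vs-rest F1 over the score classes), and
Cohen's kappa, the chance-corrected agreement (p0 − pe)/(1 − pe) with pe
computed from the two raters' marginals. Reports stratify by movement and
append an average row.

The scalar computations are delegated to scikit-learn; this module owns
the class-set policy, the degenerate-kappa convention, and the report
shape.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from sklearn.metrics import accuracy_score, cohen_kappa_score, f1_score

from .errors import ContractError

logger = logging.getLogger(__name__)

VALID_SCORES = (1, 2, 3)


@dataclass(frozen=True)
class LabelPairSet:
    """Aligned true and predicted score vectors, optionally one movement's."""

    y_true: tuple[int, ...]
    y_pred: tuple[int, ...]
    movement_id: str | None = None

    def __post_init__(self) -> None:
        y_true = tuple(int(v) for v in self.y_true)
        y_pred = tuple(int(v) for v in self.y_pred)
        if len(y_true) != len(y_pred):
            raise ContractError(
                f"length mismatch: {len(y_true)} true vs {len(y_pred)} predicted"
            )
        if not y_true:
            raise ContractError("empty label set")
        bad = sorted({v for v in y_true + y_pred} - set(VALID_SCORES))
        if bad:
            raise ContractError(f"labels outside {{1, 2, 3}}: {bad}")
        object.__setattr__(self, "y_true", y_true)
        object.__setattr__(self, "y_pred", y_pred)

    def __len__(self) -> int:
        return len(self.y_true)


def accuracy(pairs: LabelPairSet) -> float:
    """Fraction of predictions equal to the expert score."""
    return float(accuracy_score(pairs.y_true, pairs.y_pred))


def macro_f1(pairs: LabelPairSet, fixed_classes: bool = False) -> float:
    """Unweighted mean of one-vs-rest F1 over the class set.

    By default the class set is the labels observed in y_true ∪ y_pred,
    which avoids punishing strata where a class never occurs; pass
    ``fixed_classes=True`` to always average over {1, 2, 3}. Zero-division
    in precision or recall contributes 0 (logged by scikit-learn policy).
    """
    labels = list(VALID_SCORES) if fixed_classes else None
    return float(
        f1_score(
            pairs.y_true,
            pairs.y_pred,
            labels=labels,
            average="macro",
            zero_division=0,
        )
    )


def cohen_kappa(pairs: LabelPairSet) -> float:
    """Chance-corrected agreement (p0 − pe)/(1 − pe).

    When both raters are constant and identical, pe = 1 and the quotient is
    undefined; agreement is then perfect and the value is defined as 1.0
    (logged).
    """
    y_true = np.asarray(pairs.y_true)
    y_pred = np.asarray(pairs.y_pred)
    n = len(y_true)
    labels = sorted(set(pairs.y_true) | set(pairs.y_pred))
    pe = sum(
        (np.sum(y_true == c) / n) * (np.sum(y_pred == c) / n) for c in labels
    )
    if 1.0 - pe < 1e-12:
        logger.info(
            "kappa degenerate (pe = 1: both raters constant and equal); "
            "returning 1.0"
        )
        return 1.0
    return float(cohen_kappa_score(y_true, y_pred))


@dataclass(frozen=True)
class EvalReport:
    """Per-movement metric rows plus an average row, Table-shaped."""

    rows: pd.DataFrame = field(repr=False)
    average_mode: str = "unweighted"

    def to_csv(self, path) -> None:
        self.rows.to_csv(path, index=False, float_format="%.6f")

    def to_json(self, path=None) -> str:
        text = self.rows.to_json(orient="records", indent=2)
        if path is not None:
            from pathlib import Path

            Path(path).write_text(text)
        return text

    def row(self, movement_id: str) -> Mapping[str, float]:
        match = self.rows[self.rows["movement"] == movement_id]
        if match.empty:
            raise ContractError(f"no row for movement {movement_id!r}")
        return match.iloc[0].to_dict()


def evaluate_pairs(
    pairs_by_movement: Mapping[str, LabelPairSet],
    average: str = "unweighted",
    fixed_classes: bool = False,
) -> EvalReport:
    """Compute accuracy / maF1 / kappa per movement plus an average row.

    ``average="unweighted"`` (default) averages the movement rows;
    ``"pooled"`` recomputes the metrics on all pairs concatenated.
    """
    if average not in ("unweighted", "pooled"):
        raise ContractError(f"average must be unweighted|pooled, got {average!r}")
    if not pairs_by_movement:
        raise ContractError("no movement strata to evaluate")
    records = []
    for mid in sorted(pairs_by_movement):
        pairs = pairs_by_movement[mid]
        records.append(
            {
                "movement": mid,
                "n": len(pairs),
                "accuracy": accuracy(pairs),
                "maF1": macro_f1(pairs, fixed_classes=fixed_classes),
                "kappa": cohen_kappa(pairs),
            }
        )
    frame = pd.DataFrame.from_records(records)
    if average == "unweighted":
        avg = {
            "movement": "Avg.",
            "n": int(frame["n"].sum()),
            "accuracy": float(frame["accuracy"].mean()),
            "maF1": float(frame["maF1"].mean()),
            "kappa": float(frame["kappa"].mean()),
        }
    else:
        pooled = LabelPairSet(
            tuple(v for p in pairs_by_movement.values() for v in p.y_true),
            tuple(v for p in pairs_by_movement.values() for v in p.y_pred),
        )
        avg = {
            "movement": "Avg.",
            "n": len(pooled),
            "accuracy": accuracy(pooled),
            "maF1": macro_f1(pooled, fixed_classes=fixed_classes),
            "kappa": cohen_kappa(pooled),
        }
    frame = pd.concat([frame, pd.DataFrame([avg])], ignore_index=True)
    return EvalReport(rows=frame, average_mode=average)


def evaluate_dataset(
    predictions: Iterable[Mapping],
    ground_truth: Iterable[Mapping],
    average: str = "unweighted",
    fixed_classes: bool = False,
) -> EvalReport:
    """Join predictions to ground truth on (subject_id, movement_id) and
    evaluate per movement.

    Each record needs ``subject_id``, ``movement_id`` and ``score``. Every
    prediction must have exactly one matching ground-truth record;
    unmatched ids raise a contract error listing them.
    """
    def _key(r: Mapping) -> tuple[str, str]:
        return (str(r["subject_id"]), str(r["movement_id"]))

    truth = {}
    for r in ground_truth:
        k = _key(r)
        if k in truth:
            raise ContractError(f"duplicate ground-truth record for {k}")
        truth[k] = int(r["score"])
    pred_list = list(predictions)
    missing = [
        _key(r) for r in pred_list if _key(r) not in truth
    ]
    if missing:
        raise ContractError(
            f"predictions without matching ground truth: {sorted(missing)}"
        )
    if not pred_list:
        raise ContractError("no predictions to evaluate")
    by_movement: dict[str, tuple[list[int], list[int]]] = {}
    for r in pred_list:
        k = _key(r)
        yt, yp = by_movement.setdefault(k[1], ([], []))
        yt.append(truth[k])
        yp.append(int(r["score"]))
    pairs = {
        mid: LabelPairSet(tuple(yt), tuple(yp), movement_id=mid)
        for mid, (yt, yp) in by_movement.items()
    }
    return evaluate_pairs(pairs, average=average, fixed_classes=fixed_classes)
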