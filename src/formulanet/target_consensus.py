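"""Dual-model consensus thresholding of compound-target prediction scores.

Target prediction assigns every candidate (compound, target) pair two
probability-like scores, one from a random-forest model and one from a
support-vector machine. A pair is kept only when both models place it in
the positive list (score > 0.5) AND it clears the stricter per-model
cutoffs, RF > 0.7 and SVM > 0.8 — all inequalities strict. The kept list
seeds every downstream network.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "ScoredInteraction",
    "ConsensusConfig",
    "keep_interaction",
    "consensus_filter",
    "read_score_table",
    "write_score_table",
]


@dataclass(frozen=True)
class ScoredInteraction:
    compound_id: str
    target_id: str
    rf_score: float
    svm_score: float

    def __post_init__(self) -> None:
        for label, score in (("rf", self.rf_score), ("svm", self.svm_score)):
            if not 0.0 <= score <= 1.0:
                raise ValueError(
                    f"({self.compound_id}, {self.target_id}): "
                    f"{label} score {score} outside [0, 1]"
                )


@dataclass(frozen=True)
class ConsensusConfig:
    positive_min: float = 0.5
    rf_min: float = 0.7
    svm_min: float = 0.8

    def __post_init__(self) -> None:
        if self.positive_min > self.rf_min or self.positive_min > self.svm_min:
            raise ValueError(
                "positive_min must not exceed the per-model cutoffs"
            )


def keep_interaction(
    x: ScoredInteraction, config: ConsensusConfig = ConsensusConfig()
) -> bool:
    """True iff the pair clears both the positive lists and the strict
    per-model cutoffs (all comparisons strict)."""
    return (
        x.rf_score > config.positive_min
        and x.svm_score > config.positive_min
        and x.rf_score > config.rf_min
        and x.svm_score > config.svm_min
    )


def consensus_filter(
    table: Sequence[ScoredInteraction] | Iterable[ScoredInteraction],
    config: ConsensusConfig = ConsensusConfig(),
) -> list[ScoredInteraction]:
    """Row-local filter returning exactly the kept rows, order-stable."""
    rows = list(table)
    seen: set[tuple[str, str]] = set()
    for x in rows:
        key = (x.compound_id, x.target_id)
        if key in seen:
            raise ValueError(f"duplicate interaction {key}")
        seen.add(key)
    return [x for x in rows if keep_interaction(x, config)]


def read_score_table(path: str | Path) -> list[ScoredInteraction]:
    """Read a score TSV (compound, target, rf, svm)."""
    frame = pd.read_csv(path, sep="\t")
    missing = {"compound", "target", "rf", "svm"} - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [
        ScoredInteraction(
            str(row.compound), str(row.target), float(row.rf), float(row.svm)
        )
        for row in frame.itertuples(index=False)
    ]


def write_score_table(
    table: Iterable[ScoredInteraction],
    path: str | Path,
    config: ConsensusConfig | None = None,
) -> Path:
    """Write a score TSV; with *config*, adds a ``kept`` flag column."""
    rows = []
    for x in table:
        row = {
            "compound": x.compound_id,
            "target": x.target_id,
            "rf": x.rf_score,
            "svm": x.svm_score,
        }
        if config is not None:
            row["kept"] = keep_interaction(x, config)
        rows.append(row)
    columns = ["compound", "target", "rf", "svm"] + (
        ["kept"] if config is not None else []
    )
    path = Path(path)
    pd.DataFrame(rows, columns=columns).to_csv(path, sep="\t", index=False)
    return path
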