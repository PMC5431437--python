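"""ADME candidate screening: OB/DL thresholds plus whitelist rescue.

Candidate bioactive compounds are those with oral bioavailability
OB >= 30% and drug-likeness DL >= 0.18 (the DrugBank-average cutoff);
both boundaries are inclusive. Compounds failing the thresholds can be
retained through an explicit whitelist when the literature supports their
activity — the screen reports them separately as "rescued" rather than
folding them into the strict passes.

Drug-likeness here is the continuous Tanimoto similarity between a
compound's molecular-descriptor vector and the mean descriptor vector of
known drugs:

    T(a, b) = sum(a_i b_i) / (sum(a_i^2) + sum(b_i^2) - sum(a_i b_i))
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .core_data import CompoundLibrary, CompoundRecord, ValidationError

__all__ = [
    "ScreenConfig",
    "ScreenResult",
    "tanimoto_similarity",
    "drug_likeness",
    "passes_filter",
    "screen_library",
]

DEFAULT_OB_MIN = 30.0
DEFAULT_DL_MIN = 0.18


class NotEvaluableError(ValueError):
    """The compound lacks the scores the filter needs."""


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the candidate filter (inclusive by default)."""

    ob_min: float = DEFAULT_OB_MIN
    dl_min: float = DEFAULT_DL_MIN
    inclusive: bool = True

    def __post_init__(self) -> None:
        if not 0.0 <= self.ob_min <= 100.0:
            raise ValueError(f"ob_min={self.ob_min} outside [0, 100]")
        if not 0.0 <= self.dl_min <= 1.0:
            raise ValueError(f"dl_min={self.dl_min} outside [0, 1]")


@dataclass(frozen=True)
class ScreenResult:
    """Partition of a library into strict passes, rescues, and rejects."""

    strict_pass: frozenset[str]
    rescued: frozenset[str]
    rejected: frozenset[str]
    per_herb_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def retained(self) -> frozenset[str]:
        return self.strict_pass | self.rescued

    def to_frame(self, library: CompoundLibrary) -> pd.DataFrame:
        """Per-compound report (id, ob, dl, strict_pass, rescued, retained)."""
        rows = []
        for rec in library:
            rows.append(
                {
                    "id": rec.compound_id,
                    "name": rec.name,
                    "ob": rec.ob,
                    "dl": rec.dl,
                    "herbs": ",".join(sorted(rec.herbs)),
                    "strict_pass": rec.compound_id in self.strict_pass,
                    "rescued": rec.compound_id in self.rescued,
                    "retained": rec.compound_id in self.retained,
                }
            )
        return pd.DataFrame(rows)

    def per_herb_frame(self) -> pd.DataFrame:
        rows = [
            {"herb": herb, "strict_count": strict, "retained_count": retained}
            for herb, (strict, retained) in sorted(self.per_herb_counts.items())
        ]
        return pd.DataFrame(rows, columns=["herb", "strict_count", "retained_count"])


def tanimoto_similarity(a: Sequence[float], b: Sequence[float]) -> float:
    """Continuous Tanimoto coefficient of two non-negative vectors.

    Symmetric, in [0, 1], and 1.0 exactly when the vectors coincide.
    """
    va = np.asarray(a, dtype=float)
    vb = np.asarray(b, dtype=float)
    if va.shape != vb.shape or va.ndim != 1:
        raise ValueError(f"vector length mismatch: {va.shape} vs {vb.shape}")
    if np.any(va < 0) or np.any(vb < 0):
        raise ValueError("descriptor vectors must be non-negative")
    dot = float(va @ vb)
    denom = float(va @ va) + float(vb @ vb) - dot
    if denom == 0.0:
        raise ValueError("Tanimoto undefined for two all-zero vectors")
    return dot / denom


def drug_likeness(
    descriptors: Optional[Sequence[float]], reference_mean: Sequence[float]
) -> float:
    """DL score of a compound: Tanimoto similarity to the drug-space mean."""
    if descriptors is None:
        raise NotEvaluableError(
            "no descriptor vector; use the tabulated DL value instead"
        )
    return tanimoto_similarity(descriptors, reference_mean)


def passes_filter(record: CompoundRecord, config: ScreenConfig = ScreenConfig()) -> bool:
    """Strict OB/DL candidate rule for one compound."""
    if record.ob is None or record.dl is None:
        raise NotEvaluableError(
            f"compound {record.compound_id!r} has no OB/DL scores"
        )
    if config.inclusive:
        return record.ob >= config.ob_min and record.dl >= config.dl_min
    return record.ob > config.ob_min and record.dl > config.dl_min


def screen_library(
    library: CompoundLibrary,
    whitelist: Iterable[str] = (),
    config: ScreenConfig = ScreenConfig(),
) -> ScreenResult:
    """Partition *library* into strict passes, rescued, and rejected.

    *whitelist* compounds failing the thresholds are retained as rescued;
    whitelisted strict passes stay in ``strict_pass`` (the sets are
    disjoint). Per-herb counts dedupe by compound id and count every herb
    a compound is attributed to.
    """
    white = set(whitelist)
    unknown = white - set(library.ids)
    if unknown:
        raise ValidationError(f"whitelist ids absent from library: {sorted(unknown)}")

    strict: set[str] = set()
    rescued: set[str] = set()
    rejected: set[str] = set()
    for rec in library:
        if passes_filter(rec, config):
            strict.add(rec.compound_id)
        elif rec.compound_id in white:
            rescued.add(rec.compound_id)
        else:
            rejected.add(rec.compound_id)

    per_herb: dict[str, tuple[int, int]] = {}
    for herb in sorted(library.herbs()):
        members = library.by_herb(herb)
        n_strict = sum(1 for rec in members if rec.compound_id in strict)
        n_retained = sum(
            1 for rec in members if rec.compound_id in strict or rec.compound_id in rescued
        )
        per_herb[herb] = (n_strict, n_retained)

    return ScreenResult(
        strict_pass=frozenset(strict),
        rescued=frozenset(rescued),
        rejected=frozenset(rejected),
        per_herb_counts=per_herb,
    )
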