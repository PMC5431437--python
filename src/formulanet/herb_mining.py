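"""Hypergeometric co-occurrence scoring of herb-disease associations.

Literature mining for a disease yields, per herb, a quadruple of document
counts: N papers in total, K linked to the disease, n about the herb, and
k linking both. Under the null that herb and disease papers co-occur by
chance, k follows a hypergeometric distribution; the association score is
the upper-tail probability

    P = P(X >= k) = 1 - sum_{i=0}^{k-1} C(K, i) C(N-K, n-i) / C(N, n),

so heavily studied herbs are not favoured merely for their volume. A herb
is called significantly associated when P falls below a cutoff
(0.01 by default, uncorrected).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import pandas as pd
from scipy.stats import hypergeom

__all__ = [
    "CorpusCounts",
    "DEFAULT_ALPHA",
    "hypergeom_pvalue",
    "is_significant",
    "rank_herbs",
]

DEFAULT_ALPHA = 0.01


@dataclass(frozen=True)
class CorpusCounts:
    """Document counts for one herb-disease pair.

    n_total: all papers (N); n_disease: disease-linked papers (K);
    n_herb: papers about the herb (n); n_joint: papers linking both (k).
    """

    n_total: int
    n_disease: int
    n_herb: int
    n_joint: int

    def __post_init__(self) -> None:
        n, K, d, k = self.n_total, self.n_disease, self.n_herb, self.n_joint
        if min(n, K, d, k) < 0:
            raise ValueError("counts must be non-negative")
        if K > n or d > n:
            raise ValueError(
                f"disease ({K}) and herb ({d}) counts cannot exceed total ({n})"
            )
        if k > min(K, d):
            raise ValueError(
                f"joint count {k} exceeds min(disease, herb) = {min(K, d)}"
            )


def hypergeom_pvalue(counts: CorpusCounts) -> float:
    """Upper-tail probability P(X >= k) of the hypergeometric null.

    Population ``n_total``, successes ``n_disease``, draws ``n_herb``.
    Evaluated through the survival function (log-space internals), so
    corpus-scale counts (1e7 papers) do not overflow. ``k = 0`` gives 1.
    """
    p = float(
        hypergeom.sf(
            counts.n_joint - 1,
            counts.n_total,
            counts.n_disease,
            counts.n_herb,
        )
    )
    # sf can stray a few ulp outside [0, 1]; the score is a probability.
    return min(1.0, max(0.0, p))


def is_significant(p: float, alpha: float = DEFAULT_ALPHA) -> bool:
    """True iff ``p < alpha`` (strict)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p={p} outside [0, 1]")
    return p < alpha


def rank_herbs(
    batch: Iterable[tuple[str, CorpusCounts]] | Sequence[tuple[str, CorpusCounts]],
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Score a batch of herbs and return the association table.

    Sorted ascending by p-value, ties broken lexicographically by herb
    name. Columns: herb, n_total, n_disease, n_herb, n_joint, p_value,
    significant.
    """
    rows = []
    seen: set[str] = set()
    for herb, counts in batch:
        if herb in seen:
            raise ValueError(f"duplicate herb name {herb!r}")
        seen.add(herb)
        p = hypergeom_pvalue(counts)
        rows.append(
            {
                "herb": herb,
                "n_total": counts.n_total,
                "n_disease": counts.n_disease,
                "n_herb": counts.n_herb,
                "n_joint": counts.n_joint,
                "p_value": p,
                "significant": is_significant(p, alpha),
            }
        )
    frame = pd.DataFrame(
        rows,
        columns=[
            "herb",
            "n_total",
            "n_disease",
            "n_herb",
            "n_joint",
            "p_value",
            "significant",
        ],
    )
    return frame.sort_values(["p_value", "herb"], kind="stable").reset_index(drop=True)


def read_counts_table(path) -> list[tuple[str, CorpusCounts]]:
    """Read a mining-input TSV (herb, n_total, n_disease, n_herb, n_joint)."""
    frame = pd.read_csv(path, sep="\t")
    required = {"herb", "n_total", "n_disease", "n_herb", "n_joint"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    return [
        (
            str(row.herb),
            CorpusCounts(
                int(row.n_total), int(row.n_disease), int(row.n_herb), int(row.n_joint)
            ),
        )
        for row in frame.itertuples(index=False)
    ]
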