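"""The alternative-removing comparison between two formula variants.

Given the C-T network of a reduced formula (A) and of the component set
proposed for removal (B) — or of the original formula — the comparison
partitions the union of their targets into shared, A-specific and
B-specific sets. The removal verdict operationalizes the argument that a
component set is dispensable when (i) the shared targets cover at least a
threshold fraction of the union (default 0.90) and (ii) no target hit
only by the removed components is disease-associated. Targets of unknown
disease status among the B-specific set make the verdict indeterminate
rather than silently passing: removability is a safety-relevant claim.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

from .core_data import TargetAnnotation
from .ct_network import BipartiteNetwork

__all__ = [
    "ComparisonReport",
    "RemovalVerdict",
    "compare_formulae",
    "compare_original_vs_modified",
    "removal_verdict",
]

DEFAULT_SHARED_FRACTION_THRESHOLD = 0.90


@dataclass(frozen=True)
class ComparisonReport:
    """Shared/specific target partition between two formula networks."""

    a_label: str
    b_label: str
    shared_targets: frozenset[str]
    a_specific: frozenset[str]
    b_specific: frozenset[str]
    shared_fraction: float
    b_specific_disease_linked: frozenset[str]
    b_specific_unknown: frozenset[str]

    @property
    def union_size(self) -> int:
        return len(self.shared_targets) + len(self.a_specific) + len(self.b_specific)


@dataclass(frozen=True)
class RemovalVerdict:
    removable: Optional[bool]
    coverage_ok: bool
    disease_link_ok: Optional[bool]
    reasons: tuple[str, ...]
    shared_fraction_threshold: float

    @property
    def indeterminate(self) -> bool:
        return self.removable is None


def compare_formulae(
    net_a: BipartiteNetwork,
    net_b: BipartiteNetwork,
    annotations: Mapping[str, TargetAnnotation],
    a_label: str = "modified",
    b_label: str = "removed",
) -> ComparisonReport:
    """Partition the target union of two networks.

    ``shared_fraction`` is |shared| / |union of both target sets|. Targets
    missing from *annotations* (or annotated with unknown status) are
    reported separately in ``b_specific_unknown``.
    """
    targets_a = set(net_a.target_nodes)
    targets_b = set(net_b.target_nodes)
    union = targets_a | targets_b
    if not union:
        raise ValueError("both networks have empty target sets")
    shared = targets_a & targets_b
    a_only = targets_a - targets_b
    b_only = targets_b - targets_a

    disease_linked = set()
    unknown = set()
    for t in b_only:
        ann = annotations.get(t)
        if ann is None or ann.disease_associated is None:
            unknown.add(t)
        elif ann.disease_associated:
            disease_linked.add(t)

    return ComparisonReport(
        a_label=a_label,
        b_label=b_label,
        shared_targets=frozenset(shared),
        a_specific=frozenset(a_only),
        b_specific=frozenset(b_only),
        shared_fraction=len(shared) / len(union),
        b_specific_disease_linked=frozenset(disease_linked),
        b_specific_unknown=frozenset(unknown),
    )


def compare_original_vs_modified(
    net_modified: BipartiteNetwork,
    net_original: BipartiteNetwork,
    annotations: Mapping[str, TargetAnnotation],
) -> ComparisonReport:
    """Same partition with role labels modified/original."""
    return compare_formulae(
        net_modified,
        net_original,
        annotations,
        a_label="modified",
        b_label="original",
    )


def removal_verdict(
    report: ComparisonReport,
    threshold: float = DEFAULT_SHARED_FRACTION_THRESHOLD,
) -> RemovalVerdict:
    """Decide removability from a comparison report.

    Removable iff shared coverage >= *threshold* AND no B-specific target
    is disease-linked. Unknown disease status among B-specific targets
    (with coverage passing and no known disease link) yields an
    indeterminate verdict (``removable is None``).
    """
    coverage_ok = report.shared_fraction >= threshold
    reasons = [
        f"coverage rule: shared fraction {report.shared_fraction:.4f} "
        f"{'>=' if coverage_ok else '<'} threshold {threshold:.2f}"
    ]

    if report.b_specific_disease_linked:
        disease_ok: Optional[bool] = False
        reasons.append(
            "disease-link rule: disease-associated targets specific to "
            f"{report.b_label}: {sorted(report.b_specific_disease_linked)}"
        )
    elif report.b_specific_unknown:
        disease_ok = None
        reasons.append(
            "disease-link rule: unknown disease status for "
            f"{sorted(report.b_specific_unknown)}"
        )
    else:
        disease_ok = True
        reasons.append(
            f"disease-link rule: no {report.b_label}-specific target is "
            "disease-associated"
        )

    if disease_ok is None and coverage_ok:
        removable: Optional[bool] = None
    else:
        removable = coverage_ok and bool(disease_ok)
    return RemovalVerdict(
        removable=removable,
        coverage_ok=coverage_ok,
        disease_link_ok=disease_ok,
        reasons=tuple(reasons),
        shared_fraction_threshold=threshold,
    )
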