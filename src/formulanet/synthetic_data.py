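"""Synthetic inputs with known ground truth for every pipeline stage.

No edge lists or score matrices are published for the study system, so
end-to-end exercises of the screen -> consensus -> network -> comparison
chain run on generated data whose truth is planted:

* compound libraries whose OB/DL values are drawn from two-component
  normal mixtures straddling the 30% / 0.18 screening thresholds, with
  each compound's true pass/fail status recorded;
* compound-target score tables where planted true interactions score
  strictly above the RF/SVM consensus cutoffs and decoys fail at least
  one cutoff, so the consensus filter recovers the truth set exactly;
* paired formula networks with a planted shared-target fraction, a small
  set of removed-component-specific targets, and a configurable number of
  disease-linked ones among them.

The default scenario mirrors the study's headline shape: 66 compounds in
seven herb groups, 139 comparison targets of which 4 are specific to the
removed components and none of those disease-linked.

All draws are made with a single seeded ``numpy`` generator in a fixed
order, so output is fully deterministic under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import numpy as np
from scipy.stats import norm

from .core_data import CompoundLibrary, CompoundRecord, TargetAnnotation
from .ct_network import BipartiteNetwork, build_network
from .target_consensus import ScoredInteraction

__all__ = [
    "TwoComponentSpec",
    "SimulationConfig",
    "generate_library",
    "generate_scores",
    "generate_formula_pair",
    "generate_targets",
]

DEFAULT_HERBS: tuple[tuple[str, float], ...] = (
    ("Gymnadenia Conopsea", 11.0),
    ("Stigma Croci", 8.0),
    ("Myristica Semena", 11.0),
    ("Semen Strychni", 12.0),
    ("Boswellia", 9.0),
    ("Syringa Oblata", 7.0),
    ("Rhizoma Alpiniae Officinarum", 15.0),
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class TwoComponentSpec:
    """Two-component normal mixture for a score straddling a threshold.

    ``p_high`` is the weight of the high (mostly-passing) component.
    """

    p_high: float
    high_loc: float
    high_scale: float
    low_loc: float
    low_scale: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_high <= 1.0:
            raise ConfigError(f"p_high={self.p_high} outside [0, 1]")
        if self.high_scale <= 0 or self.low_scale <= 0:
            raise ConfigError("component spreads must be positive (degenerate spec)")

    def pass_probability(self, threshold: float) -> float:
        """Design probability of drawing a value >= threshold."""
        hi = norm.sf(threshold, loc=self.high_loc, scale=self.high_scale)
        lo = norm.sf(threshold, loc=self.low_loc, scale=self.low_scale)
        return float(self.p_high * hi + (1.0 - self.p_high) * lo)

    def sample(self, rng: np.random.Generator, lo: float, hi: float) -> float:
        if rng.random() < self.p_high:
            value = rng.normal(self.high_loc, self.high_scale)
        else:
            value = rng.normal(self.low_loc, self.low_scale)
        return float(min(hi, max(lo, value)))


@dataclass(frozen=True)
class SimulationConfig:
    """Ground-truth parameters of the synthetic study conditions."""

    seed: int = 0
    n_compounds: int = 66
    n_targets: int = 139
    herbs: tuple[tuple[str, float], ...] = DEFAULT_HERBS
    ob_distribution: TwoComponentSpec = field(
        default_factory=lambda: TwoComponentSpec(0.90, 45.0, 8.0, 15.0, 6.0)
    )
    dl_distribution: TwoComponentSpec = field(
        default_factory=lambda: TwoComponentSpec(0.90, 0.45, 0.15, 0.08, 0.04)
    )
    multi_herb_rate: float = 0.1
    true_interaction_rate: float = 0.05
    score_noise: float = 0.2
    planted_shared_fraction: float = 135.0 / 139.0
    n_b_specific: int = 4
    n_disease_linked_b_specific: int = 0
    pair_noise: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "multi_herb_rate",
            "true_interaction_rate",
            "planted_shared_fraction",
            "pair_noise",
        ):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigError(f"{name}={value} outside [0, 1]")
        if self.n_compounds <= 0 or self.n_targets <= 0:
            raise ConfigError("counts must be positive")
        if self.score_noise <= 0:
            raise ConfigError("score_noise must be positive")
        if self.n_b_specific < self.n_disease_linked_b_specific:
            raise ConfigError(
                "n_disease_linked_b_specific cannot exceed n_b_specific"
            )
        if not self.herbs:
            raise ConfigError("at least one herb group required")

    @property
    def strict_pass_rate(self) -> float:
        """Design probability a compound passes OB >= 30 and DL >= 0.18."""
        return self.ob_distribution.pass_probability(
            30.0
        ) * self.dl_distribution.pass_probability(0.18)


def generate_targets(config: SimulationConfig) -> list[str]:
    return [f"T{i + 1:03d}" for i in range(config.n_targets)]


def generate_library(
    config: SimulationConfig,
) -> tuple[CompoundLibrary, dict[str, bool]]:
    """Draw a compound library; returns (library, truth pass/fail labels).

    Truth labels record each compound's actual filter status (OB >= 30
    and DL >= 0.18 on the drawn values).
    """
    rng = np.random.default_rng(config.seed)
    names = [h for h, _ in config.herbs]
    weights = np.array([w for _, w in config.herbs], dtype=float)
    weights = weights / weights.sum()

    records = []
    truth: dict[str, bool] = {}
    for i in range(config.n_compounds):
        cid = f"C{i + 1:04d}"
        ob = config.ob_distribution.sample(rng, 0.0, 100.0)
        dl = config.dl_distribution.sample(rng, 0.0, 1.0)
        herb_idx = int(rng.choice(len(names), p=weights))
        herbs = {names[herb_idx]}
        if len(names) > 1 and rng.random() < config.multi_herb_rate:
            other = int(rng.choice(len(names)))
            if other != herb_idx:
                herbs.add(names[other])
        records.append(
            CompoundRecord(
                compound_id=cid,
                name=f"synthetic compound {i + 1}",
                ob=round(ob, 2),
                dl=round(dl, 2),
                herbs=frozenset(herbs),
            )
        )
        truth[cid] = records[-1].ob >= 30.0 and records[-1].dl >= 0.18
    return CompoundLibrary(records), truth


def _open_unit(rng: np.random.Generator) -> float:
    """Uniform draw in (0, 1] so threshold offsets are strictly positive."""
    return 1.0 - float(rng.random())


def generate_scores(
    library: CompoundLibrary,
    targets: list[str],
    config: SimulationConfig,
    rf_min: float = 0.7,
    svm_min: float = 0.8,
) -> tuple[list[ScoredInteraction], set[tuple[str, str]]]:
    """Score every compound-target pair; returns (table, truth pair set).

    True interactions get RF strictly above ``rf_min`` and SVM strictly
    above ``svm_min`` (within a band of width ``score_noise``); decoys
    fail at least one cutoff. By construction the consensus filter
    recovers the truth set exactly.
    """
    rng = np.random.default_rng(config.seed + 1)
    rows = []
    truth: set[tuple[str, str]] = set()
    rf_span = min(1.0 - rf_min, config.score_noise)
    svm_span = min(1.0 - svm_min, config.score_noise)
    for rec in library:
        for t in targets:
            if rng.random() < config.true_interaction_rate:
                rf = rf_min + rf_span * _open_unit(rng)
                svm = svm_min + svm_span * _open_unit(rng)
                truth.add((rec.compound_id, t))
            else:
                mode = rng.random()
                rf_fail = mode < 0.7  # rf-only 30%, both 40%, svm-only 30%
                svm_fail = mode >= 0.3
                if rf_fail:
                    rf = max(0.0, rf_min - min(rf_min, config.score_noise) * _open_unit(rng))
                else:
                    rf = rf_min + rf_span * _open_unit(rng)
                if svm_fail:
                    svm = max(0.0, svm_min - min(svm_min, config.score_noise) * _open_unit(rng))
                else:
                    svm = svm_min + svm_span * _open_unit(rng)
            rows.append(
                ScoredInteraction(rec.compound_id, t, round(rf, 6), round(svm, 6))
            )
    return rows, truth


def generate_formula_pair(
    config: SimulationConfig,
) -> tuple[BipartiteNetwork, BipartiteNetwork, dict[str, TargetAnnotation]]:
    """Build two formula networks with a planted shared-target structure.

    Of ``n_targets`` union targets, ``round(planted_shared_fraction *
    n_targets)`` are hit by both networks, ``n_b_specific`` only by the
    second (the removed components), and the remainder only by the first.
    The first ``n_disease_linked_b_specific`` removed-only targets are
    annotated disease-associated; every shared and first-network target
    is disease-associated (the disease is what the formula treats).

    With ``pair_noise`` > 0, each shared target is independently demoted
    to one-network-only with that probability, so the measured shared
    fraction fluctuates around the planted value.
    """
    n = config.n_targets
    n_shared = int(round(config.planted_shared_fraction * n))
    n_b = config.n_b_specific
    n_a = n - n_shared - n_b
    if n_a < 0:
        raise ConfigError(
            f"planted_shared_fraction {config.planted_shared_fraction} and "
            f"n_b_specific {n_b} inconsistent with n_targets {n}"
        )
    rng = np.random.default_rng(config.seed + 2)
    targets = generate_targets(config)
    shared = targets[:n_shared]
    a_only = targets[n_shared : n_shared + n_a]
    b_only = targets[n_shared + n_a :]

    if config.pair_noise > 0.0:
        kept_shared = []
        for t in shared:
            u = rng.random()
            if u < config.pair_noise / 2.0:
                a_only = a_only + [t]
            elif u < config.pair_noise:
                b_only = b_only + [t]
            else:
                kept_shared.append(t)
        shared = kept_shared

    def spread_edges(prefix: str, hit_targets: list[str]) -> list[tuple[str, str]]:
        # round-robin so every target gets >= 1 compound edge
        n_comp = max(3, len(hit_targets) // 8 + 1)
        compounds = [f"{prefix}{i + 1:03d}" for i in range(n_comp)]
        return [(compounds[j % n_comp], t) for j, t in enumerate(hit_targets)]

    edges_a = spread_edges("FA", shared + a_only)
    edges_b = spread_edges("FB", shared + b_only)
    group_a = {c: {"modified-formula"} for c, _ in edges_a}
    group_b = {c: {"removed-components"} for c, _ in edges_b}
    net_a = build_network(edges_a, group_map=group_a)
    net_b = build_network(edges_b, group_map=group_b)

    annotations: dict[str, TargetAnnotation] = {}
    for t in shared + a_only:
        annotations[t] = TargetAnnotation(target_id=t, disease_associated=True)
    for i, t in enumerate(b_only):
        annotations[t] = TargetAnnotation(
            target_id=t,
            disease_associated=i < config.n_disease_linked_b_specific,
        )
    return net_a, net_b, annotations
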