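"""Ground-truth recovery and determinism of the synthetic generators."""

import math

import pytest

from formulanet.adme_screen import screen_library
from formulanet.formula_compare import compare_formulae, removal_verdict
from formulanet.synthetic_data import (
    ConfigError,
    SimulationConfig,
    TwoComponentSpec,
    generate_formula_pair,
    generate_library,
    generate_scores,
    generate_targets,
)
from formulanet.target_consensus import consensus_filter


class TestGenerateLibrary:
    def test_deterministic_under_seed(self):
        config = SimulationConfig(seed=17)
        lib_a, truth_a = generate_library(config)
        lib_b, truth_b = generate_library(config)
        assert lib_a == lib_b and truth_a == truth_b

    def test_different_seeds_differ(self):
        lib_a, _ = generate_library(SimulationConfig(seed=1))
        lib_b, _ = generate_library(SimulationConfig(seed=2))
        assert lib_a != lib_b

    def test_all_pass_when_distributions_sit_above_thresholds(self):
        config = SimulationConfig(
            seed=0,
            n_compounds=50,
            ob_distribution=TwoComponentSpec(1.0, 70.0, 3.0, 70.0, 3.0),
            dl_distribution=TwoComponentSpec(1.0, 0.6, 0.03, 0.6, 0.03),
        )
        library, truth = generate_library(config)
        result = screen_library(library)
        assert len(result.strict_pass) == len(library)
        assert all(truth.values())

    def test_truth_labels_match_screen(self):
        config = SimulationConfig(seed=5, n_compounds=200)
        library, truth = generate_library(config)
        result = screen_library(library)
        assert {cid for cid, ok in truth.items() if ok} == set(result.strict_pass)

    def test_pass_rate_within_three_standard_errors_of_design(self):
        config = SimulationConfig(seed=11, n_compounds=10_000)
        library, truth = generate_library(config)
        p = config.strict_pass_rate
        se = math.sqrt(p * (1 - p) / config.n_compounds)
        observed = sum(truth.values()) / config.n_compounds
        assert abs(observed - p) < 3 * se

    def test_degenerate_spread_rejected(self):
        with pytest.raises(ConfigError, match="degenerate"):
            TwoComponentSpec(0.5, 45.0, 0.0, 15.0, 5.0)

    def test_herb_attribution_nonempty_and_from_config(self):
        config = SimulationConfig(seed=3, n_compounds=100)
        library, _ = generate_library(config)
        allowed = {h for h, _ in config.herbs}
        assert all(rec.herbs and rec.herbs <= allowed for rec in library)


class TestGenerateScores:
    def test_consensus_filter_recovers_truth_exactly(self):
        config = SimulationConfig(seed=23, n_compounds=20, n_targets=25)
        library, _ = generate_library(config)
        scores, truth = generate_scores(library, generate_targets(config), config)
        kept = consensus_filter(scores)
        assert {(x.compound_id, x.target_id) for x in kept} == truth

    def test_zero_interaction_rate_gives_empty_kept_set(self):
        config = SimulationConfig(
            seed=2, n_compounds=10, n_targets=10, true_interaction_rate=0.0
        )
        library, _ = generate_library(config)
        scores, truth = generate_scores(library, generate_targets(config), config)
        assert not truth
        assert consensus_filter(scores) == []

    def test_500_pairs_kept_size_matches_independent_scan(self):
        config = SimulationConfig(seed=31, n_compounds=20, n_targets=25)
        library, _ = generate_library(config)
        scores, truth = generate_scores(library, generate_targets(config), config)
        assert len(scores) == 500
        scanned = sum(
            1 for x in scores if x.rf_score > 0.7 and x.svm_score > 0.8
        )
        assert scanned == len(truth)

    def test_scores_in_unit_interval(self):
        config = SimulationConfig(seed=8, n_compounds=15, n_targets=15)
        library, _ = generate_library(config)
        scores, _ = generate_scores(library, generate_targets(config), config)
        assert all(0.0 <= x.rf_score <= 1.0 and 0.0 <= x.svm_score <= 1.0 for x in scores)


class TestGenerateFormulaPair:
    @pytest.mark.parametrize("fraction", [0.5, 0.75, 0.9, 0.97])
    def test_planted_fraction_recovered_exactly_noise_free(self, fraction):
        config = SimulationConfig(
            seed=7, n_targets=100, planted_shared_fraction=fraction, n_b_specific=2
        )
        net_a, net_b, annotations = generate_formula_pair(config)
        report = compare_formulae(net_a, net_b, annotations)
        assert report.shared_fraction == round(fraction * 100) / 100

    def test_study_shaped_scenario_is_removable(self):
        config = SimulationConfig(seed=19)  # 139 targets, 4 non-disease specifics
        net_a, net_b, annotations = generate_formula_pair(config)
        report = compare_formulae(net_a, net_b, annotations)
        verdict = removal_verdict(report, threshold=0.90)
        assert report.shared_fraction == pytest.approx(135 / 139)
        assert verdict.removable is True

    def test_full_shared_fraction_gives_identical_target_sets(self):
        config = SimulationConfig(
            seed=4, n_targets=50, planted_shared_fraction=1.0, n_b_specific=0
        )
        net_a, net_b, _ = generate_formula_pair(config)
        assert net_a.target_nodes == net_b.target_nodes

    def test_one_disease_linked_specific_blocks_removal(self):
        config = SimulationConfig(seed=6, n_disease_linked_b_specific=1)
        net_a, net_b, annotations = generate_formula_pair(config)
        report = compare_formulae(net_a, net_b, annotations)
        assert removal_verdict(report).removable is False

    def test_inconsistent_planting_rejected(self):
        with pytest.raises(ConfigError, match="inconsistent"):
            generate_formula_pair(
                SimulationConfig(
                    seed=0,
                    n_targets=10,
                    planted_shared_fraction=0.9,
                    n_b_specific=5,
                )
            )

    def test_noisy_mode_fraction_near_planted(self):
        config = SimulationConfig(
            seed=13, n_targets=400, planted_shared_fraction=0.8,
            n_b_specific=10, pair_noise=0.1,
        )
        net_a, net_b, annotations = generate_formula_pair(config)
        report = compare_formulae(net_a, net_b, annotations)
        # each shared target survives with prob 0.9; fraction shrinks ~10%
        assert abs(report.shared_fraction - 0.8 * 0.9) < 0.05

    def test_determinism(self):
        config = SimulationConfig(seed=99)
        a1, b1, ann1 = generate_formula_pair(config)
        a2, b2, ann2 = generate_formula_pair(config)
        assert a1.edges == a2.edges and b1.edges == b2.edges and ann1 == ann2
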