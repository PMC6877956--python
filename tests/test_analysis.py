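import numpy as np
import pytest

from smopsi.analysis import (aa_class_distribution, group_columns,
                             mean_decrease_accuracy, physchem_distribution,
                             tree_feature_importance)
from smopsi.features import FEATURE_GROUPS, PSSM_ALPHABET, PhysChemScales
from smopsi.model import TrainConfig, train
from smopsi.pipeline import featurize_bundle
from smopsi.synthetic_data import SynthConfig, generate_bundle


@pytest.fixture(scope="module")
def pssm_only_matrix():
    """Signal confined to the PSSM block (no composition bias)."""
    config = SynthConfig(seed=41, n_chains=20, chain_length=(60, 100),
                         signal_strength=4.0, composition_bias=0.0)
    matrix, _, _ = featurize_bundle(generate_bundle(config))
    return matrix


@pytest.fixture(scope="module")
def pssm_only_ensemble(pssm_only_matrix):
    return train(pssm_only_matrix, TrainConfig(n_downsample_repeats=2, random_seed=4))


class TestAaClassDistribution:
    def test_single_chain_direct_counts(self):
        dist = aa_class_distribution([("AAAK", [0, 0, 0, 1])])
        table = dist.table.set_index("letter")
        assert table.loc["A", "nonbinding_freq"] == 1.0
        assert table.loc["K", "binding_freq"] == 1.0
        assert table.loc["K", "nonbinding_freq"] == 0.0

    def test_frequencies_sum_to_one_per_class(self, strong_bundle):
        pairs = [(strong_bundle.sequences[c], strong_bundle.labels[c])
                 for c in strong_bundle.chain_ids()]
        table = aa_class_distribution(pairs).table
        assert table["binding_freq"].sum() == pytest.approx(1.0)
        assert table["nonbinding_freq"].sum() == pytest.approx(1.0)

    def test_counts_conserved_per_letter(self, strong_bundle):
        pairs = [(strong_bundle.sequences[c], strong_bundle.labels[c])
                 for c in strong_bundle.chain_ids()]
        table = aa_class_distribution(pairs).table
        all_letters = "".join(strong_bundle.sequences.values())
        for _, row in table.iterrows():
            assert row["binding_count"] + row["nonbinding_count"] == \
                all_letters.count(row["letter"])

    def test_composition_bias_detected(self, strong_bundle):
        # binding positions are biased toward hydrophilic/charged letters
        pairs = [(strong_bundle.sequences[c], strong_bundle.labels[c])
                 for c in strong_bundle.chain_ids()]
        table = aa_class_distribution(pairs).table.set_index("letter")
        hydrophilic = list("RKHDESTNQ")
        assert table.loc[hydrophilic, "binding_freq"].sum() > \
            table.loc[hydrophilic, "nonbinding_freq"].sum()
        assert (table["q"] <= 1).all() and (table["q"] >= 0).all()

    def test_empty_class_raises(self):
        with pytest.raises(ValueError):
            aa_class_distribution([("AAAA", [0, 0, 0, 0])])


class TestPhyschemDistribution:
    def test_hydrophilic_binding_class_has_higher_mean(self, scales):
        pairs = [("KRDEAVL", [1, 1, 1, 1, 0, 0, 0])]
        table = physchem_distribution(pairs, scales).set_index("property")
        assert table.loc["hydrophilicity", "binding_mean"] > \
            table.loc["hydrophilicity", "nonbinding_mean"]
        # Kyte-Doolittle: charged residues are strongly hydrophobic-negative
        assert table.loc["hydrophobicity", "binding_mean"] < \
            table.loc["hydrophobicity", "nonbinding_mean"]

    def test_identical_compositions_show_no_difference(self, scales):
        pairs = [("ACDK", [1, 1, 0, 0]), ("CAKD", [0, 0, 1, 1])]
        table = physchem_distribution(pairs, scales).set_index("property")
        for prop in table.index:
            assert table.loc[prop, "binding_mean"] == \
                pytest.approx(table.loc[prop, "nonbinding_mean"])
            assert table.loc[prop, "p"] > 0.9

    def test_charge_means_bounded(self, strong_bundle, scales):
        pairs = [(strong_bundle.sequences[c], strong_bundle.labels[c])
                 for c in strong_bundle.chain_ids()]
        table = physchem_distribution(pairs, scales).set_index("property")
        assert -1 <= table.loc["charge", "binding_mean"] <= 1
        assert -1 <= table.loc["charge", "nonbinding_mean"] <= 1

    def test_invariant_to_chain_ordering(self, strong_bundle, scales):
        pairs = [(strong_bundle.sequences[c], strong_bundle.labels[c])
                 for c in strong_bundle.chain_ids()]
        forward = physchem_distribution(pairs, scales)
        backward = physchem_distribution(pairs[::-1], scales)
        np.testing.assert_allclose(forward["binding_mean"], backward["binding_mean"])


class TestMeanDecreaseAccuracy:
    def test_pssm_group_ranks_first(self, pssm_only_ensemble, pssm_only_matrix):
        from smopsi.model import downsample

        held_out = downsample(pssm_only_matrix, seed=2)
        report = mean_decrease_accuracy(pssm_only_ensemble, held_out,
                                        n_repeats=5, seed=0)
        assert report.ranking()[0] == "pssm"
        assert report.scores["pssm"] > 0.2

    def test_constant_column_group_scores_zero(self, pssm_only_matrix):
        from smopsi.model import downsample

        matrix = pssm_only_matrix.subset(np.arange(len(pssm_only_matrix)))
        width = matrix.window_config.width
        matrix.rows[:, group_columns(width, "hbond")] = 0.0
        ensemble = train(matrix, TrainConfig(n_downsample_repeats=1, random_seed=1))
        report = mean_decrease_accuracy(ensemble, downsample(matrix, seed=3),
                                        n_repeats=5, seed=0, groups=["hbond"])
        assert report.scores["hbond"] == pytest.approx(0.0, abs=1e-12)

    def test_group_excluded_from_training_has_negligible_score(self, pssm_only_matrix):
        """Zeroing a group in both training and evaluation makes its MDA
        vanish (|score| < 0.01 at 20 repeats)."""
        from smopsi.model import downsample

        matrix = pssm_only_matrix.subset(np.arange(len(pssm_only_matrix)))
        width = matrix.window_config.width
        matrix.rows[:, group_columns(width, "onehot")] = 0.0
        ensemble = train(matrix, TrainConfig(n_downsample_repeats=1, random_seed=1))
        report = mean_decrease_accuracy(ensemble, downsample(matrix, seed=3),
                                        n_repeats=20, seed=0, groups=["onehot"])
        assert abs(report.scores["onehot"]) < 0.01

    def test_random_uniform_corruption_mode(self, pssm_only_ensemble, pssm_only_matrix):
        from smopsi.model import downsample

        report = mean_decrease_accuracy(pssm_only_ensemble,
                                        downsample(pssm_only_matrix, seed=2),
                                        n_repeats=3, seed=0,
                                        corrupt="random-uniform",
                                        groups=["pssm", "hbond"])
        assert report.scores["pssm"] > report.scores["hbond"]

    def test_unknown_group_rejected(self, pssm_only_ensemble, pssm_only_matrix):
        with pytest.raises(KeyError):
            mean_decrease_accuracy(pssm_only_ensemble, pssm_only_matrix,
                                   groups=["nonexistent"], n_repeats=1, seed=0)


class TestTreeImportance:
    def test_normalized_scores_sum_to_one(self, pssm_only_matrix):
        report = tree_feature_importance(pssm_only_matrix, seed=0, n_trees=50)
        assert sum(report.scores.values()) == pytest.approx(1.0)
        assert set(report.scores) == set(FEATURE_GROUPS)

    def test_pssm_share_dominates(self, pssm_only_matrix):
        from smopsi.model import downsample

        balanced = downsample(pssm_only_matrix, seed=5)
        report = tree_feature_importance(balanced, seed=0, n_trees=100)
        assert report.ranking()[0] == "pssm"
        assert report.scores["pssm"] > 0.5

    def test_deterministic_given_seed(self, pssm_only_matrix):
        a = tree_feature_importance(pssm_only_matrix, seed=7, n_trees=30)
        b = tree_feature_importance(pssm_only_matrix, seed=7, n_trees=30)
        assert a.scores == b.scores

    def test_single_class_rejected(self):
        from smopsi.windows import FeatureMatrix, WindowConfig

        matrix = FeatureMatrix(rows=np.zeros((5, 44)), labels=np.ones(5),
                               chain_ids=np.array(["a"] * 5, dtype=object),
                               positions=np.arange(1, 6),
                               window_config=WindowConfig(width=1))
        with pytest.raises(ValueError):
            tree_feature_importance(matrix, seed=0)
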