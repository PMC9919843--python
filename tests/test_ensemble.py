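"""Voting semantics, ablation bookkeeping and ensemble structure.

Structural tests run on untrained (or one-epoch) tiny models; the
accuracy-bearing end-to-end behaviour lives in the acceptance suite.
"""

from collections import Counter

import numpy as np
import pytest

from freqhar.dataio import stack_windows
from freqhar.ensemble import (
    ABLATION_CONFIGS,
    EnsembleSet,
    majority_vote,
    predict_ensemble,
    predict_single_tta,
    run_ablation,
    train_ensemble,
)
from freqhar.ensemble import _profile_for
from freqhar.importance import FrequencyBank
from freqhar.model import ActivityClassifier, ModelConfig, TrainConfig
from freqhar.spectral import SpectrumGrid
from freqhar.synthetic import generate_benchmark


class TestMajorityVote:
    def _scores(self, label, n_classes, winning=0.9):
        s = np.full(n_classes, (1 - winning) / (n_classes - 1))
        s[label] = winning
        return s

    def test_unanimity(self):
        votes = [(2, self._scores(2, 4)) for _ in range(3)]
        assert majority_vote(votes) == 2

    def test_single_vote(self):
        assert majority_vote([(1, self._scores(1, 3))]) == 1

    def test_plain_majority(self):
        votes = [(0, self._scores(0, 3)), (0, self._scores(0, 3)),
                 (1, self._scores(1, 3))]
        assert majority_vote(votes) == 0

    def test_tie_goes_to_higher_mean_winning_score(self):
        votes = [
            (0, self._scores(0, 3, winning=0.6)),
            (0, self._scores(0, 3, winning=0.8)),   # mean for 0: 0.7
            (1, self._scores(1, 3, winning=0.9)),
            (1, self._scores(1, 3, winning=0.55)),  # mean for 1: 0.725
        ]
        assert majority_vote(votes) == 1

    def test_residual_tie_goes_to_lowest_index(self):
        votes = [(2, self._scores(2, 3, 0.7)), (1, self._scores(1, 3, 0.7))]
        assert majority_vote(votes) == 1

    def test_empty_votes_rejected(self):
        with pytest.raises(ValueError):
            majority_vote([])


def test_ablation_table_flag_pattern():
    """The eight rows cover every on/off combination exactly once."""
    flags = {
        (c.use_DA, c.use_TTA, c.use_EL) for c in ABLATION_CONFIGS.values()
    }
    assert len(flags) == 8
    assert ABLATION_CONFIGS["a"].use_DA and ABLATION_CONFIGS["a"].use_TTA \
        and ABLATION_CONFIGS["a"].use_EL
    assert not (ABLATION_CONFIGS["h"].use_DA or ABLATION_CONFIGS["h"].use_TTA
                or ABLATION_CONFIGS["h"].use_EL)
    # DA-only and TTA-only rows exist
    assert (ABLATION_CONFIGS["d"].use_DA, ABLATION_CONFIGS["d"].use_TTA,
            ABLATION_CONFIGS["d"].use_EL) == (True, False, False)
    assert (ABLATION_CONFIGS["f"].use_DA, ABLATION_CONFIGS["f"].use_TTA,
            ABLATION_CONFIGS["f"].use_EL) == (False, True, False)


@pytest.fixture(scope="module")
def tiny_setup():
    split, bank = generate_benchmark(seed=21, n_subjects=6,
                                     per_split_subjects=(2, 2, 2),
                                     duration_s=4.0)
    cfg = ModelConfig(n_classes=len(split.class_set), scale="tiny",
                      padding="same")
    return split, bank, cfg


class TestEnsembleStructure:
    def test_one_member_per_class(self, tiny_setup):
        split, bank, cfg = tiny_setup
        ens = train_ensemble(split, bank, "peak", cfg,
                             TrainConfig(epochs=0, seed=0))
        assert len(ens.members) == len(split.class_set)
        assert [label for label, _, _ in ens.members] == split.class_set
        for label, profile, _ in ens.members:
            if bank.bin_of(label) > 0:
                assert profile.center_bin == bank.bin_of(label)

    def test_without_da_members_differ_only_by_seed(self, tiny_setup):
        split, bank, cfg = tiny_setup
        ens = train_ensemble(split, bank, "gaussian", cfg,
                             TrainConfig(epochs=0, seed=0), use_DA=False)
        w0 = ens.members[0][2].head.W
        w1 = ens.members[1][2].head.W
        assert not np.array_equal(w0, w1)  # distinct initialisation seeds

    def test_bank_must_cover_all_classes(self, tiny_setup):
        split, bank, cfg = tiny_setup
        partial = FrequencyBank(
            entries={split.class_set[0]: (0, 0.0)}, grid=bank.grid
        )
        with pytest.raises(ValueError, match="lacks classes"):
            train_ensemble(split, partial, "peak", cfg,
                           TrainConfig(epochs=0, seed=0))

    def test_unknown_filter_kind(self, tiny_setup):
        split, bank, cfg = tiny_setup
        with pytest.raises(ValueError, match="filter kind"):
            train_ensemble(split, bank, "hann", cfg,
                           TrainConfig(epochs=0, seed=0))

    def test_vote_record_has_one_entry_per_member(self, tiny_setup):
        split, bank, cfg = tiny_setup
        ens = train_ensemble(split, bank, "triangular", cfg,
                             TrainConfig(epochs=0, seed=0))
        X, _ = stack_windows(split.test[:5], split.class_set)
        winners, records = predict_ensemble(ens, X)
        assert winners.shape == (5,)
        assert all(len(rec) == len(split.class_set) for rec in records)
        for rec in records:
            for label, scores in rec:
                assert scores.shape == (len(split.class_set),)
                assert abs(scores.sum() - 1) < 1e-6

    def test_accuracy_recomputable_from_vote_records(self, tiny_setup):
        split, bank, cfg = tiny_setup
        ens = train_ensemble(split, bank, "peak", cfg,
                             TrainConfig(epochs=1, batch_size=32, seed=0))
        X, y = stack_windows(split.test, split.class_set)
        winners, records = predict_ensemble(ens, X)
        replayed = np.array([majority_vote(rec) for rec in records])
        np.testing.assert_array_equal(winners, replayed)

    def test_empty_ensemble_rejected(self, tiny_setup):
        split, bank, _ = tiny_setup
        with pytest.raises(ValueError):
            EnsembleSet(members=[], filter_kind="peak", bank=bank,
                        class_set=split.class_set)
        ens = EnsembleSet(members=[], filter_kind="peak", bank=bank,
                          class_set=[])
        with pytest.raises(ValueError, match="empty"):
            predict_ensemble(ens, np.zeros((1, 3, 128)))


class TestSingleModelTta:
    def test_vote_multiset_matches_ensemble_of_copies(self, tiny_setup):
        """One model + |C| filters == an ensemble of |C| copies of it."""
        split, bank, cfg = tiny_setup
        seed = 4
        model = ActivityClassifier(cfg, split.window_size, seed=seed)
        members = [
            (label,
             _profile_for(bank.grid, "gaussian", bank.bin_of(label),
                          sigma_bins=10.0, rng_seed=seed * 1009 + i),
             model)
            for i, label in enumerate(split.class_set)
        ]
        ens = EnsembleSet(members=members, filter_kind="gaussian", bank=bank,
                          class_set=split.class_set)
        X, _ = stack_windows(split.test[:6], split.class_set)
        w_single, rec_single = predict_single_tta(
            model, X, bank, "gaussian", split.class_set, rng_seed=seed
        )
        w_ens, rec_ens = predict_ensemble(ens, X, use_TTA=True)
        np.testing.assert_array_equal(w_single, w_ens)
        for a, b in zip(rec_single, rec_ens):
            assert Counter(lab for lab, _ in a) == Counter(lab for lab, _ in b)

    def test_single_class_bank_degenerates_to_one_vote(self, tiny_setup):
        split, bank, _ = tiny_setup
        cfg1 = ModelConfig(n_classes=2, scale="tiny", padding="same")
        model = ActivityClassifier(cfg1, split.window_size, seed=0)
        only = FrequencyBank(entries={"static": (0, 0.0)}, grid=bank.grid)
        X, _ = stack_windows(split.test[:3], split.class_set)
        winners, records = predict_single_tta(
            model, X, only, "peak", ["static"]
        )
        assert all(len(rec) == 1 for rec in records)
        np.testing.assert_array_equal(
            winners, [rec[0][0] for rec in records]
        )


class TestIdenticalMembersReduceToSingleModel:
    def test_no_tta_no_da_identical_seeds(self, tiny_setup):
        """|C| copies of one model without TTA vote exactly like that model."""
        split, bank, cfg = tiny_setup
        model = ActivityClassifier(cfg, split.window_size, seed=9)
        profile = _profile_for(bank.grid, "peak", 3, 10.0, None)
        members = [(label, profile, model) for label in split.class_set]
        ens = EnsembleSet(members=members, filter_kind="peak", bank=bank,
                          class_set=split.class_set)
        X, _ = stack_windows(split.test[:8], split.class_set)
        winners, _ = predict_ensemble(ens, X, use_TTA=False)
        single = model.predict_proba(X).argmax(axis=1)
        np.testing.assert_array_equal(winners, single)


def test_run_ablation_reports_and_rejects(tiny_setup):
    split, bank, cfg = tiny_setup
    table = run_ablation(split, bank, "peak", cfg,
                         TrainConfig(epochs=0, seed=0),
                         configs=("h",), seeds=(0,))
    assert list(table["config"]) == ["h"]
    assert table.loc[0, ["DA", "TTA", "EL"]].tolist() == [False, False, False]
    assert 0.0 <= table.loc[0, "mean_acc"] <= 1.0
    with pytest.raises(ValueError, match="unknown config"):
        run_ablation(split, bank, "peak", cfg, TrainConfig(epochs=0, seed=0),
                     configs=("z",), seeds=(0,))
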