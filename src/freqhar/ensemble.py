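"""Phases 2-3: per-class band-emphasis ensembles with test-time filtering.

One classifier is trained per activity class, each on training data
passed through that class's emphasis filter (frequency-domain data
augmentation, *DA*).  At prediction time each member sees the test
window filtered by its own profile (*test-time augmentation, TTA*) and
votes with its argmax label; the majority label wins (*ensemble
learning, EL*).  The ablation harness switches each of the three
ingredients on and off in the eight combinations labelled (a)-(h), and
the filter-comparison harness runs the full method with each of the
four window shapes.

Ties in the vote are resolved deterministically: among the tied labels
the one whose voters had the highest mean winning score wins, and a
residual tie falls to the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .dataio import DatasetSplit, stack_windows
from .importance import FrequencyBank
from .model import ActivityClassifier, ModelConfig, TrainConfig, train
from .spectral import GainProfile, SpectrumGrid, apply_gains, make_emphasis_profile

__all__ = [
    "EnsembleSet",
    "AblationConfig",
    "ABLATION_CONFIGS",
    "majority_vote",
    "train_ensemble",
    "predict_ensemble",
    "predict_single_tta",
    "evaluate_config",
    "run_ablation",
    "run_filter_comparison",
]

FILTER_KINDS = ("peak", "gaussian", "triangular", "random")


@dataclass(frozen=True)
class AblationConfig:
    """One row of the ablation table: which ingredients are active."""

    label: str
    use_DA: bool
    use_TTA: bool
    use_EL: bool


# The eight ablation rows: every on/off combination of DA, TTA and EL.
ABLATION_CONFIGS: dict[str, AblationConfig] = {
    "a": AblationConfig("a", True, True, True),
    "b": AblationConfig("b", True, True, False),
    "c": AblationConfig("c", True, False, True),
    "d": AblationConfig("d", True, False, False),
    "e": AblationConfig("e", False, True, True),
    "f": AblationConfig("f", False, True, False),
    "g": AblationConfig("g", False, False, True),
    "h": AblationConfig("h", False, False, False),
}


@dataclass
class EnsembleSet:
    """|C| trained members, each paired with its class's emphasis profile."""

    members: list[tuple[str, GainProfile, ActivityClassifier]]
    filter_kind: str
    bank: FrequencyBank
    class_set: list[str]

    def __post_init__(self) -> None:
        if len(self.members) != len(self.class_set):
            raise ValueError(
                f"{len(self.members)} members for {len(self.class_set)} classes"
            )


def majority_vote(votes: Sequence[tuple[int, np.ndarray]]) -> int:
    """Label voted for by the most members.

    ``votes`` holds ``(argmax_label, score_vector)`` pairs.  Ties go to
    the tied label with the highest mean winning score among its voters,
    then to the lowest label index.
    """
    if not votes:
        raise ValueError("no votes")
    counts: dict[int, int] = {}
    winning_scores: dict[int, list[float]] = {}
    for label, scores in votes:
        label = int(label)
        counts[label] = counts.get(label, 0) + 1
        winning_scores.setdefault(label, []).append(float(scores[label]))
    top = max(counts.values())
    tied = [lab for lab, n in counts.items() if n == top]
    if len(tied) == 1:
        return tied[0]
    return max(
        tied,
        key=lambda lab: (np.mean(winning_scores[lab]), -lab),
    )


def _profile_for(
    grid: SpectrumGrid,
    filter_kind: str,
    center_bin: int,
    sigma_bins: float,
    rng_seed: int | None,
) -> GainProfile:
    kwargs = {"sigma_bins": sigma_bins} if filter_kind == "gaussian" else {}
    return make_emphasis_profile(
        grid, filter_kind, center_bin, rng_seed=rng_seed, **kwargs
    )


def train_ensemble(
    split: DatasetSplit,
    bank: FrequencyBank,
    filter_kind: str,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    use_DA: bool = True,
) -> EnsembleSet:
    """Train one member per class.

    With ``use_DA`` each member trains on the whole training set passed
    through its class's emphasis profile.  Without it (the plain-ensemble
    ablations) every member trains on the original data and diversity
    comes only from seed-varied initialisation.  Random-window profiles
    are drawn once per member under a recorded seed and reused at test
    time, so DA and TTA see the same filter.
    """
    if filter_kind not in FILTER_KINDS:
        raise ValueError(f"unknown filter kind {filter_kind!r}")
    missing = set(split.class_set) - set(bank.entries)
    if missing:
        raise ValueError(f"bank lacks classes {sorted(missing)}")
    grid = bank.grid
    X, y = stack_windows(split.train, split.class_set)

    members = []
    for i, label in enumerate(split.class_set):
        profile = _profile_for(
            grid, filter_kind, bank.bin_of(label),
            sigma_bins=10.0, rng_seed=train_cfg.seed * 1009 + i,
        )
        member_cfg = TrainConfig(
            batch_size=train_cfg.batch_size,
            learning_rate=train_cfg.learning_rate,
            epochs=train_cfg.epochs,
            optimizer=train_cfg.optimizer,
            loss=train_cfg.loss,
            seed=train_cfg.seed + i,
            select=train_cfg.select,
        )
        model = ActivityClassifier(
            model_cfg, split.window_size, seed=member_cfg.seed
        )
        Xc = apply_gains(X, profile.gains) if use_DA else X
        train(model, (Xc, y), member_cfg)
        members.append((label, profile, model))
    return EnsembleSet(
        members=members, filter_kind=filter_kind, bank=bank,
        class_set=list(split.class_set),
    )


def predict_ensemble(
    ens: EnsembleSet,
    X: np.ndarray,
    use_TTA: bool = True,
) -> tuple[np.ndarray, list[list[tuple[int, np.ndarray]]]]:
    """Majority-vote prediction for a batch of windows.

    Each member votes on the input filtered by its own profile (or the
    original input when ``use_TTA`` is off).  Returns the winning label
    indices and, per window, the full vote record — one
    ``(member_label, score_vector)`` per member, in member order — from
    which every reported accuracy can be recomputed.
    """
    if not ens.members:
        raise ValueError("empty ensemble")
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    member_votes = []
    for _, profile, model in ens.members:
        Xf = apply_gains(X, profile.gains) if use_TTA else X
        probs = model.predict_proba(Xf)
        member_votes.append((probs.argmax(axis=1), probs))
    records = [
        [(int(labels[i]), probs[i]) for labels, probs in member_votes]
        for i in range(len(X))
    ]
    winners = np.array([majority_vote(rec) for rec in records])
    return winners, records


def predict_single_tta(
    model: ActivityClassifier,
    X: np.ndarray,
    bank: FrequencyBank,
    filter_kind: str,
    class_set: Sequence[str],
    sigma_bins: float = 10.0,
    rng_seed: int = 0,
) -> tuple[np.ndarray, list[list[tuple[int, np.ndarray]]]]:
    """TTA with a single model: one prediction per class filter, then vote.

    Structurally equivalent to :func:`predict_ensemble` over |C| copies
    of the same model.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 2:
        X = X[None]
    member_votes = []
    for i, label in enumerate(class_set):
        profile = _profile_for(
            bank.grid, filter_kind, bank.bin_of(label),
            sigma_bins=sigma_bins, rng_seed=rng_seed * 1009 + i,
        )
        probs = model.predict_proba(apply_gains(X, profile.gains))
        member_votes.append((probs.argmax(axis=1), probs))
    records = [
        [(int(labels[i]), probs[i]) for labels, probs in member_votes]
        for i in range(len(X))
    ]
    winners = np.array([majority_vote(rec) for rec in records])
    return winners, records


def _train_single(
    split: DatasetSplit,
    bank: FrequencyBank | None,
    filter_kind: str,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    use_DA: bool,
) -> ActivityClassifier:
    """One model; with DA it trains on the union of all filtered copies."""
    X, y = stack_windows(split.train, split.class_set)
    if use_DA:
        assert bank is not None
        copies_X, copies_y = [], []
        for i, label in enumerate(split.class_set):
            profile = _profile_for(
                bank.grid, filter_kind, bank.bin_of(label),
                sigma_bins=10.0, rng_seed=train_cfg.seed * 1009 + i,
            )
            copies_X.append(apply_gains(X, profile.gains))
            copies_y.append(y)
        X = np.concatenate(copies_X)
        y = np.concatenate(copies_y)
    model = ActivityClassifier(model_cfg, split.window_size, seed=train_cfg.seed)
    train(model, (X, y), train_cfg)
    return model


def evaluate_config(
    split: DatasetSplit,
    bank: FrequencyBank,
    filter_kind: str,
    config: AblationConfig,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
) -> float:
    """Overall test accuracy of one DA/TTA/EL combination."""
    X_test, y_test = stack_windows(split.test, split.class_set)
    if config.use_EL:
        ens = train_ensemble(
            split, bank, filter_kind, model_cfg, train_cfg, use_DA=config.use_DA
        )
        winners, _ = predict_ensemble(ens, X_test, use_TTA=config.use_TTA)
    else:
        model = _train_single(
            split, bank if config.use_DA else None, filter_kind,
            model_cfg, train_cfg, use_DA=config.use_DA,
        )
        if config.use_TTA:
            winners, _ = predict_single_tta(
                model, X_test, bank, filter_kind, split.class_set,
                rng_seed=train_cfg.seed,
            )
        else:
            winners = model.predict_proba(X_test).argmax(axis=1)
    return float((winners == y_test).mean())


def run_ablation(
    split: DatasetSplit,
    bank: FrequencyBank,
    filter_kind: str,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    configs: Sequence[str] = tuple(ABLATION_CONFIGS),
    seeds: Sequence[int] = (0, 1, 2),
) -> pd.DataFrame:
    """Accuracy table over the requested ablation rows and seeds."""
    rows = []
    for name in configs:
        try:
            config = ABLATION_CONFIGS[name]
        except KeyError:
            raise ValueError(
                f"unknown config {name!r}; expected one of "
                f"{list(ABLATION_CONFIGS)}"
            ) from None
        accs = []
        for seed in seeds:
            cfg = TrainConfig(
                batch_size=train_cfg.batch_size,
                learning_rate=train_cfg.learning_rate,
                epochs=train_cfg.epochs,
                seed=seed,
                select=train_cfg.select,
            )
            accs.append(
                evaluate_config(split, bank, filter_kind, config, model_cfg, cfg)
            )
        rows.append(
            {
                "config": name,
                "DA": config.use_DA,
                "TTA": config.use_TTA,
                "EL": config.use_EL,
                **{f"acc_seed{s}": a for s, a in zip(seeds, accs)},
                "mean_acc": float(np.mean(accs)),
                "std_acc": float(np.std(accs)),
            }
        )
    return pd.DataFrame(rows)


def run_filter_comparison(
    split: DatasetSplit,
    bank: FrequencyBank,
    model_cfg: ModelConfig,
    train_cfg: TrainConfig,
    seeds: Sequence[int] = (0, 1, 2),
    kinds: Sequence[str] = FILTER_KINDS,
) -> pd.DataFrame:
    """Full method (DA+TTA+EL) once per window shape."""
    rows = []
    for kind in kinds:
        accs = []
        for seed in seeds:
            cfg = TrainConfig(
                batch_size=train_cfg.batch_size,
                learning_rate=train_cfg.learning_rate,
                epochs=train_cfg.epochs,
                seed=seed,
                select=train_cfg.select,
            )
            accs.append(
                evaluate_config(
                    split, bank, kind, ABLATION_CONFIGS["a"], model_cfg, cfg
                )
            )
        rows.append(
            {
                "filter": kind,
                **{f"acc_seed{s}": a for s, a in zip(seeds, accs)},
                "mean_acc": float(np.mean(accs)),
                "std_acc": float(np.std(accs)),
            }
        )
    return pd.DataFrame(rows)
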