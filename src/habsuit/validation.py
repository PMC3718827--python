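"""Train/test splitting, replicate hold-out validation and AUC scoring."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from habsuit.grid import LayerStack, OccurrenceSet
from habsuit.maxent import (
    DEFAULT_BACKGROUND_N,
    DEFAULT_BETA,
    DEFAULT_BIAS_BUFFER_KM,
    FeatureMapper,
    features_at,
    fit,
    sample_background,
)

logger = logging.getLogger(__name__)


@dataclass
class SplitSpec:
    train_fraction: float = 0.75
    replicates: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ValueError(f"train_fraction must be in (0, 1), got {self.train_fraction}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def split(occ: OccurrenceSet, fraction: float, seed: int) -> tuple[OccurrenceSet, OccurrenceSet]:
    """Random disjoint train/test partition with ``|train| = round(fraction*n)``."""
    n = len(occ)
    if n < 4:
        raise ValueError(f"need at least 4 records to split, got {n}")
    n_train = int(round(fraction * n))
    if n_train == 0 or n_train == n:
        raise ValueError(f"fraction {fraction} leaves an empty train or test side for n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return occ.subset(np.sort(perm[:n_train])), occ.subset(np.sort(perm[n_train:]))


def auc(presence_scores, background_scores) -> float:
    """Mann-Whitney AUC: P(random presence outscores random background),
    ties counted 1/2."""
    p = np.asarray(presence_scores, dtype=float)
    b = np.asarray(background_scores, dtype=float)
    if p.size == 0 or b.size == 0:
        raise ValueError("both score lists must be non-empty")
    ranks = rankdata(np.concatenate([p, b]))
    u = ranks[: p.size].sum() - p.size * (p.size + 1) / 2.0
    return float(u / (p.size * b.size))


def rate(auc_value: float) -> str:
    """Performance label: >0.9 excellent; [0.7, 0.9] good; [0.5, 0.7) poor;
    <0.5 no better than random. Boundary values 0.9 and 0.7 rate 'good'."""
    if not (0.0 <= auc_value <= 1.0):
        raise ValueError(f"AUC must be in [0, 1], got {auc_value}")
    if auc_value > 0.9:
        return "excellent"
    if auc_value >= 0.7:
        return "good"
    if auc_value >= 0.5:
        return "poor"
    return "no better than random"


@dataclass
class ValidationReport:
    replicates: pd.DataFrame  # columns: replicate, mode, train_auc, test_auc
    summary: pd.DataFrame  # per mode: mean/sd train & test AUC + rating

    def to_csv(self, path) -> None:
        self.replicates.to_csv(path, index=False)


def cross_validate(
    occ: OccurrenceSet,
    stack: LayerStack,
    spec: SplitSpec,
    modes: tuple[str, ...] = ("bias", "global"),
    background_n: int = DEFAULT_BACKGROUND_N,
    buffer_km: float = DEFAULT_BIAS_BUFFER_KM,
    beta: float = DEFAULT_BETA,
) -> ValidationReport:
    """Repeated random hold-out validation per background mode.

    For every replicate and mode the model is fitted on the training split
    against that mode's background sample and scored on both splits; the
    training background is reused for test scoring.
    """
    rows = []
    for mode in modes:
        bg = sample_background(
            stack, occ, n=background_n, mode=mode, buffer_km=buffer_km,
            seed=spec.seed + 7919 * (1 + modes.index(mode)),
        )
        bg_df = features_at(stack, bg)
        continuous = stack.continuous_names()
        categorical = {
            name: sorted(int(v) for v in np.unique(bg_df[name]))
            for name in stack.categorical_names()
        }
        mapper = FeatureMapper.fit(bg_df, continuous, categorical)
        F_bg = mapper.transform(bg_df)
        for rep in range(spec.replicates):
            train, test = split(occ, spec.train_fraction, seed=spec.seed + rep)
            F_train = mapper.transform(features_at(stack, train))
            F_test = mapper.transform(features_at(stack, test))
            model = fit(F_train, F_bg, beta=beta, mapper=mapper)
            s_bg = F_bg @ model.lambdas
            rows.append(
                {
                    "replicate": rep,
                    "mode": mode,
                    "train_auc": auc(F_train @ model.lambdas, s_bg),
                    "test_auc": auc(F_test @ model.lambdas, s_bg),
                }
            )
    reps = pd.DataFrame(rows)
    summ = (
        reps.groupby("mode")
        .agg(
            train_auc_mean=("train_auc", "mean"),
            train_auc_sd=("train_auc", "std"),
            test_auc_mean=("test_auc", "mean"),
            test_auc_sd=("test_auc", "std"),
        )
        .fillna(0.0)
        .reset_index()
    )
    summ["rating"] = summ["test_auc_mean"].map(rate)
    return ValidationReport(reps, summ)
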