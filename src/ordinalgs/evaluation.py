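"""CV2 fivefold cross-validation, the PCCC metric and model comparison.

The outer scheme mimics incomplete multi-environment trials: (environment,
line) cells — not whole lines — are partitioned into k folds stratified by
environment, so a line held out in one environment usually remains observed
in others ("CV2").  Each fold is predicted by every model after tuning or
fitting on the remaining folds only; the percentage of cases correctly
classified (PCCC) is computed per trait-environment group, and fold means
with normal-approximation confidence intervals summarise each model.
"""

from __future__ import annotations

import logging
import warnings
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .kernels import KernelSet, assemble_features
from .mlp import MLPSpec, train_mlp, predict_classes, tune_mlp
from .svm import (
    DEFAULT_COST_GRID,
    DEFAULT_GAMMA_GRID,
    fit_ovo,
    predict_vote,
    tune_svm,
)
from .tgblup import TGBLUPConfig, ThresholdGBLUP
from .trial import OrdinalTrialTable

__all__ = [
    "CVPlan",
    "BenchmarkResult",
    "make_cv2_folds",
    "pccc",
    "run_benchmark",
    "summarize",
    "TGBLUPModel",
    "MLPBenchModel",
    "SVMBenchModel",
    "OracleModel",
    "ModalBaseline",
]

logger = logging.getLogger(__name__)


@dataclass
class CVPlan:
    """Fold assignment (0-based) for each row of a trial table."""

    folds: np.ndarray
    k: int
    seed: int

    def __post_init__(self):
        f = np.asarray(self.folds)
        if f.min() < 0 or f.max() >= self.k:
            raise ValueError("fold indices out of range")
        self.folds = f


def make_cv2_folds(table: OrdinalTrialTable, k: int = 5, seed: int = 0) -> CVPlan:
    """Assign each observed cell to one of k folds, stratified by environment.

    Within every (trait, environment) stratum the fold sizes differ by at
    most one.  A stratum with fewer than k cells is assigned unstratified
    (uniformly at random) with a warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    rng = np.random.default_rng(seed)
    folds = -np.ones(len(table), dtype=int)
    for (trait, env), grp in table.df.groupby(["trait", "env_id"], sort=True):
        idx = grp.index.to_numpy()
        if len(idx) < k:
            warnings.warn(
                f"stratum (trait={trait}, env={env}) has {len(idx)} < {k} "
                "cells; unstratified assignment", RuntimeWarning,
            )
            folds[idx] = rng.integers(k, size=len(idx))
        else:
            folds[idx] = rng.permutation(np.resize(np.arange(k), len(idx)))
    return CVPlan(folds=folds, k=k, seed=seed)


def pccc(observed, predicted) -> float:
    """Percentage of cases correctly classified: 100·#matches/n."""
    obs = np.asarray(observed)
    pred = np.asarray(predicted)
    if obs.shape != pred.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {pred.shape}")
    if obs.size == 0:
        raise ValueError("empty input")
    return 100.0 * float(np.mean(obs == pred))


# ---------------------------------------------------------------------------
# model adapters — a common fit-on-train / predict-test protocol


def _feature_cells(df: pd.DataFrame, env_order, line_order):
    env_pos = {e: i for i, e in enumerate(env_order)}
    line_pos = {l: j for j, l in enumerate(line_order)}
    return [(env_pos[e], line_pos[l]) for e, l in zip(df["env_id"], df["line_id"])]


class TGBLUPModel:
    """Threshold-GBLUP adapter for the benchmark loop."""

    def __init__(self, config: TGBLUPConfig | None = None):
        self.config = config or TGBLUPConfig()

    def fit_predict(self, train_table, test_df, kernels, env_order,
                    include_interaction, seed):
        cfg = TGBLUPConfig(
            n_iter=self.config.n_iter, burn_in=self.config.burn_in,
            thin=self.config.thin, prior_df=self.config.prior_df,
            prior_scale_mode=self.config.prior_scale_mode,
            include_interaction=include_interaction, seed=seed,
        )
        res = ThresholdGBLUP(train_table, kernels, config=cfg).fit()
        _, classes = res.predict(test_df["env_id"].tolist(), test_df["line_id"].tolist())
        return classes


class MLPBenchModel:
    """Feedforward-network adapter: tune (layers, units) per training fold."""

    def __init__(self, grid=None, spec: MLPSpec | None = None):
        self.grid = grid
        self.spec = spec or MLPSpec()

    def fit_predict(self, train_table, test_df, kernels, env_order,
                    include_interaction, seed):
        I = len(env_order)
        Xtr = assemble_features(
            _feature_cells(train_table.df, env_order, kernels.line_ids),
            kernels.L1, I, include_interaction,
        )
        Xte = assemble_features(
            _feature_cells(test_df, env_order, kernels.line_ids),
            kernels.L1, I, include_interaction,
        )
        y = train_table.df["category"].to_numpy()
        base = MLPSpec(
            n_layers=self.spec.n_layers, units=self.spec.units,
            dropout_rate=self.spec.dropout_rate, max_epochs=self.spec.max_epochs,
            batch_size=self.spec.batch_size, learning_rate=self.spec.learning_rate,
            seed=seed,
        )
        if self.grid is None:
            model = train_mlp(Xtr, y, base)
        else:
            _, model, _ = tune_mlp(Xtr, y, self.grid, base, full_output=True)
        return predict_classes(model, Xte)


class SVMBenchModel:
    """One-vs-one SVM adapter: tune (T, γ) by inner CV per training fold."""

    def __init__(self, cost_grid=DEFAULT_COST_GRID, gamma_grid=DEFAULT_GAMMA_GRID,
                 k_inner: int = 10):
        self.cost_grid = cost_grid
        self.gamma_grid = gamma_grid
        self.k_inner = k_inner

    def fit_predict(self, train_table, test_df, kernels, env_order,
                    include_interaction, seed):
        I = len(env_order)
        Xtr = assemble_features(
            _feature_cells(train_table.df, env_order, kernels.line_ids),
            kernels.L1, I, include_interaction,
        )
        Xte = assemble_features(
            _feature_cells(test_df, env_order, kernels.line_ids),
            kernels.L1, I, include_interaction,
        )
        y = train_table.df["category"].to_numpy()
        spec = tune_svm(
            Xtr, y, self.cost_grid, self.gamma_grid,
            k_inner=min(self.k_inner, len(Xtr)), seed=seed,
        )
        model = fit_ovo(Xtr, y, spec)
        return predict_vote(model, Xte)


class OracleModel:
    """Plug-in oracle returning the observed category (plumbing check)."""

    def fit_predict(self, train_table, test_df, kernels, env_order,
                    include_interaction, seed):
        return test_df["category"].to_numpy()


class BayesOracleModel:
    """Bayes-optimal classifier from the generator's true probabilities."""

    def __init__(self, truth):
        self.truth = truth

    def fit_predict(self, train_table, test_df, kernels, env_order,
                    include_interaction, seed):
        cfg = self.truth.config
        env_pos = {e: i for i, e in enumerate(cfg.env_ids)}
        line_pos = {l: j for j, l in enumerate(cfg.line_ids)}
        i = np.array([env_pos[e] for e in test_df["env_id"]])
        j = np.array([line_pos[l] for l in test_df["line_id"]])
        return self.truth.oracle_classes(i, j)


class ModalBaseline:
    """Predicts each environment's modal training category."""

    def fit_predict(self, train_table, test_df, kernels, env_order,
                    include_interaction, seed):
        df = train_table.df
        global_mode = int(df["category"].mode().iloc[0])
        modes = {
            env: int(grp["category"].mode().iloc[0])
            for env, grp in df.groupby("env_id")
        }
        return np.array([modes.get(e, global_mode) for e in test_df["env_id"]])


# ---------------------------------------------------------------------------
# benchmark loop


@dataclass
class BenchmarkResult:
    """Fold-level PCCC rows: (trait, environment, model, variant, fold, pccc)."""

    df: pd.DataFrame
    k: int
    seed: int


def _derive_seed(base: int, *parts) -> int:
    h = zlib.crc32("|".join(map(str, parts)).encode())
    return int((base * 2654435761 + h) % (2**31 - 1))


def run_benchmark(
    table: OrdinalTrialTable,
    kernels: KernelSet,
    models: dict,
    plan: CVPlan,
    variants=("I", "WI"),
) -> BenchmarkResult:
    """Fit/tune every model on each training fold and score the held-out fold.

    ``models`` maps a display name to an adapter with the
    ``fit_predict(train_table, test_df, kernels, env_order,
    include_interaction, seed)`` protocol.  Variants: "I" includes the G×E
    term, "WI" omits it.  Test cells in an environment absent from the
    training fold are skipped with a warning (unseen environments are never
    predicted).  PCCC is computed per (trait, environment).
    """
    env_order = table.env_ids
    rows = []
    for trait in table.traits:
        trait_mask = (table.df["trait"] == trait).to_numpy()
        for variant in variants:
            if variant not in ("I", "WI"):
                raise ValueError(f"unknown variant {variant!r}")
            include_interaction = variant == "I"
            for f in range(plan.k):
                train_mask = trait_mask & (plan.folds != f)
                test_mask = trait_mask & (plan.folds == f)
                train_df = table.df[train_mask]
                test_df = table.df[test_mask]
                if train_df.empty or test_df.empty:
                    continue
                train_envs = set(train_df["env_id"])
                unseen = ~test_df["env_id"].isin(train_envs)
                if unseen.any():
                    warnings.warn(
                        f"fold {f+1}: skipping {int(unseen.sum())} test cells in "
                        f"environment(s) unseen in training", RuntimeWarning,
                    )
                    test_df = test_df[~unseen]
                if test_df.empty:
                    continue
                train_table = table.subset(rows=train_df.index)
                for name, model in models.items():
                    seed = _derive_seed(plan.seed, trait, variant, f, name)
                    logger.info(
                        "trait=%s variant=%s fold=%d model=%s", trait, variant,
                        f + 1, name,
                    )
                    pred = np.asarray(
                        model.fit_predict(
                            train_table, test_df, kernels, env_order,
                            include_interaction, seed,
                        )
                    )
                    for env, grp in test_df.groupby("env_id", sort=True):
                        loc = test_df.index.get_indexer(grp.index)
                        rows.append(
                            {
                                "trait": trait,
                                "environment": env,
                                "model": name,
                                "variant": variant,
                                "fold": f + 1,
                                "pccc": pccc(grp["category"].to_numpy(), pred[loc]),
                                "n_cells": len(grp),
                            }
                        )
    return BenchmarkResult(df=pd.DataFrame(rows), k=plan.k, seed=plan.seed)


# ---------------------------------------------------------------------------
# summaries


@dataclass
class BenchmarkSummary:
    means: pd.DataFrame
    comparisons: pd.DataFrame


def summarize(result: BenchmarkResult, alpha: float = 0.05) -> BenchmarkSummary:
    """Fold means with normal-approximation CIs and pairwise comparisons.

    For each (trait, environment, model, variant): mean PCCC, SE = SD/√k and
    the mean ± z_{1−α/2}·SE interval.  Pairwise model comparisons within a
    (trait, environment, variant) group flag interval overlap and report the
    relative difference 100·(A−B)/B of the fold means.
    """
    z = norm.ppf(1 - alpha / 2)
    df = result.df if isinstance(result, BenchmarkResult) else result
    rows = []
    for key, grp in df.groupby(["trait", "environment", "model", "variant"], sort=True):
        vals = grp["pccc"].to_numpy()
        k = len(vals)
        mean = float(vals.mean())
        if k >= 2:
            se = float(vals.std(ddof=1) / np.sqrt(k))
            lo, hi = mean - z * se, mean + z * se
            single = False
        else:
            se, lo, hi, single = np.nan, np.nan, np.nan, True
        rows.append(
            dict(
                trait=key[0], environment=key[1], model=key[2], variant=key[3],
                n_folds=k, mean_pccc=mean, se=se, ci_low=lo, ci_high=hi,
                single_fold=single,
            )
        )
    means = pd.DataFrame(rows)

    comp_rows = []
    for key, grp in means.groupby(["trait", "environment", "variant"], sort=True):
        recs = grp.to_dict("records")
        for a in recs:
            for b in recs:
                if a["model"] >= b["model"]:
                    continue
                if np.isnan(a["ci_low"]) or np.isnan(b["ci_low"]):
                    overlap = None
                else:
                    overlap = (
                        a["ci_low"] <= b["ci_high"] and b["ci_low"] <= a["ci_high"]
                    )
                rel = (
                    100.0 * (a["mean_pccc"] - b["mean_pccc"]) / b["mean_pccc"]
                    if b["mean_pccc"] != 0 else np.nan
                )
                comp_rows.append(
                    dict(
                        trait=key[0], environment=key[1], variant=key[2],
                        model_a=a["model"], model_b=b["model"],
                        mean_a=a["mean_pccc"], mean_b=b["mean_pccc"],
                        rel_diff_pct=rel,
                        ci_flag="overlapping" if overlap else (
                            "non-overlapping" if overlap is not None else "no-ci"
                        ),
                    )
                )
    return BenchmarkSummary(means=means, comparisons=pd.DataFrame(comp_rows))
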