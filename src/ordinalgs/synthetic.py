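"""Synthetic multi-environment trial generator with known truth.

The generator draws data with exactly the statistical structure the
threshold model assumes: liabilities ``l_ij = E_i + g_j + gE_ij + ε_ij``
with genomic effects ``g ~ N(0, G1·σg²)``, genotype-by-environment effects
independent across environments with per-environment covariance ``G1·σgE²``,
standard-normal residuals, and ordered thresholds mapping each liability to
one of C categories.  Because every parameter is recorded in a
:class:`TruthRecord` (including the exact per-cell category probabilities),
downstream estimators can be validated against the Bayes oracle.

Continuous traits can additionally be discretised per environment at given
quantile levels, e.g. (1/3, 2/3) for three categories or
(0.20, 0.45, 0.70, 0.90) for five.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .trial import OrdinalTrialTable

__all__ = [
    "SyntheticConfig",
    "TruthRecord",
    "simulate_markers",
    "simulate_trial",
    "discretize_trait",
]


@dataclass
class SyntheticConfig:
    """Study-design parameters of a simulated multi-environment trial.

    Defaults describe a mid-sized wheat-nursery-like design: three managed
    environments, 300 genotyped lines, 500 biallelic markers, a 3-category
    ordinal trait with unequal class frequencies, moderate heritable signal
    (σg² = 0.6) with a weaker G×E component (σgE² = 0.2) against the unit
    residual, and 20% of (environment, line) cells unobserved, mimicking
    unbalanced trials.
    """

    I: int = 3
    J: int = 300
    m: int = 500
    maf_range: tuple[float, float] = (0.2, 0.45)
    C: int = 3
    thresholds: tuple[float, ...] = (0.0, 1.0)
    env_effects: tuple[float, ...] = (-0.5, 0.0, 0.5)
    sigma_g2: float = 0.6
    sigma_ge2: float = 0.2
    missing_cell_fraction: float = 0.2
    seed: int = 0
    trait: str = "trait"

    def __post_init__(self):
        g = np.asarray(self.thresholds, dtype=float)
        if len(g) != self.C - 1:
            raise ValueError(f"need C-1={self.C-1} thresholds, got {len(g)}")
        if len(g) > 1 and not np.all(np.diff(g) > 0):
            raise ValueError("thresholds must be strictly increasing")
        if self.sigma_g2 < 0 or self.sigma_ge2 < 0:
            raise ValueError("variances must be non-negative")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if len(self.env_effects) != self.I:
            raise ValueError(f"need {self.I} env_effects, got {len(self.env_effects)}")
        if not 0 <= self.missing_cell_fraction < 1:
            raise ValueError("missing_cell_fraction must be in [0, 1)")

    @property
    def env_ids(self) -> list:
        return [f"E{i+1}" for i in range(self.I)]

    @property
    def line_ids(self) -> list:
        return [f"L{j+1}" for j in range(self.J)]


@dataclass
class TruthRecord:
    """Generating parameters and exact per-cell category probabilities.

    ``liab_grid`` and ``probs_grid`` cover the full I×J grid; ``observed``
    marks the cells that made it into the phenotype table.  The Bayes-oracle
    class of any cell is the argmax of its row of ``probs_grid``.
    """

    config: SyntheticConfig
    g: np.ndarray                 # (J,)
    gE: np.ndarray                # (I, J)
    liab_grid: np.ndarray         # (I, J)
    probs_grid: np.ndarray        # (I, J, C)
    category_grid: np.ndarray     # (I, J)
    observed: np.ndarray          # (I, J) bool

    @property
    def liabilities(self) -> np.ndarray:
        """Liabilities of the observed cells (row-major cell order)."""
        return self.liab_grid[self.observed]

    @property
    def true_probs(self) -> np.ndarray:
        """(n_observed, C) probability vectors of the observed cells."""
        return self.probs_grid[self.observed]

    def oracle_classes(self, i: np.ndarray, j: np.ndarray) -> np.ndarray:
        """Bayes-optimal category for cells (i, j): argmax of true probs."""
        return np.argmax(self.probs_grid[i, j], axis=-1) + 1


def simulate_markers(
    J: int,
    m: int,
    maf_range=(0.2, 0.45),
    rng: np.random.Generator | int = 0,
    max_retries: int = 100,
) -> np.ndarray:
    """Draw a J×m dosage matrix, column j ~ Binomial(2, p_j), p_j ~ U(maf_range).

    Constant columns are resampled (they carry no information and cannot be
    scaled); after ``max_retries`` failed resamples the offending column is
    reported and the draw aborts.
    """
    if J < 2 or m < 1:
        raise ValueError("need J >= 2 lines and m >= 1 markers")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    lo, hi = maf_range
    p = rng.uniform(lo, hi, size=m)
    X = rng.binomial(2, p, size=(J, m)).astype(float)
    for _ in range(max_retries):
        const = np.flatnonzero(X.std(axis=0) == 0.0)
        if const.size == 0:
            return X
        X[:, const] = rng.binomial(2, p[const], size=(J, const.size))
    const = np.flatnonzero(X.std(axis=0) == 0.0)
    raise RuntimeError(
        f"marker column {const[0]} remained constant after {max_retries} "
        f"resamples (degenerate maf_range {maf_range})"
    )


def _draw_mvn_g1(eigvals, eigvecs, variance, size, rng):
    """Draws from N(0, G1·variance) via the eigendecomposition of G1."""
    sd = np.sqrt(np.clip(eigvals, 0.0, None) * variance)
    z = rng.standard_normal(size=(size, len(eigvals)))
    return (z * sd) @ eigvecs.T


def liability_probs(mu: np.ndarray, thresholds) -> np.ndarray:
    """Exact category probabilities for liability mean(s) mu, residual SD 1.

    P(y = c) is the probit difference Φ(γ_c − μ) − Φ(γ_{c−1} − μ) with
    γ_0 = −∞ and γ_C = +∞.
    """
    mu = np.asarray(mu, dtype=float)
    gam = np.asarray(thresholds, dtype=float)
    cum = ndtr(gam - mu[..., None])            # (..., C-1) cumulative probs
    ones = np.ones(mu.shape + (1,))
    zeros = np.zeros(mu.shape + (1,))
    return np.diff(np.concatenate([zeros, cum, ones], axis=-1), axis=-1)


def categorize(liab: np.ndarray, thresholds) -> np.ndarray:
    """Category 1 + #{c : l > γ_c} of each liability."""
    gam = np.asarray(thresholds, dtype=float)
    return 1 + np.sum(np.asarray(liab)[..., None] > gam, axis=-1)


def simulate_trial(
    cfg: SyntheticConfig,
    G1: np.ndarray,
    rng: np.random.Generator | None = None,
) -> tuple[OrdinalTrialTable, TruthRecord]:
    """Simulate ordinal phenotypes on an I×J grid under the threshold model.

    Parameters
    ----------
    cfg : SyntheticConfig
    G1 : ndarray (J, J)
        Genomic relationship matrix; must be symmetric PSD.
    rng : Generator, optional
        Defaults to ``default_rng(cfg.seed)``.

    Returns
    -------
    (table, truth)
        Observed cells as an :class:`OrdinalTrialTable` plus the full
        :class:`TruthRecord`.
    """
    G1 = np.asarray(G1, dtype=float)
    if G1.shape != (cfg.J, cfg.J):
        raise ValueError(f"G1 must be {cfg.J}×{cfg.J}, got {G1.shape}")
    if not np.allclose(G1, G1.T, atol=1e-8):
        raise ValueError("G1 must be symmetric")
    w, U = np.linalg.eigh((G1 + G1.T) / 2.0)
    tol = 1e-8 * max(1.0, abs(w[-1]))
    if w[0] < -tol:
        raise ValueError(f"G1 is not PSD (smallest eigenvalue {w[0]:.3e})")

    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    E = np.asarray(cfg.env_effects, dtype=float)
    g = _draw_mvn_g1(w, U, cfg.sigma_g2, 1, rng)[0]                   # (J,)
    gE = _draw_mvn_g1(w, U, cfg.sigma_ge2, cfg.I, rng)                # (I, J)
    eps = rng.standard_normal((cfg.I, cfg.J))
    mu = E[:, None] + g[None, :] + gE
    liab = mu + eps
    cat = categorize(liab, cfg.thresholds)
    probs = liability_probs(mu, cfg.thresholds)

    n_cells = cfg.I * cfg.J
    n_missing = int(round(cfg.missing_cell_fraction * n_cells))
    observed = np.ones(n_cells, dtype=bool)
    if n_missing:
        observed[rng.choice(n_cells, size=n_missing, replace=False)] = False
    observed = observed.reshape(cfg.I, cfg.J)

    ii, jj = np.nonzero(observed)
    env_ids = cfg.env_ids
    line_ids = cfg.line_ids
    df = pd.DataFrame(
        {
            "env_id": [env_ids[i] for i in ii],
            "line_id": [line_ids[j] for j in jj],
            "trait": cfg.trait,
            "category": cat[ii, jj],
        }
    )
    table = OrdinalTrialTable(df)
    truth = TruthRecord(
        config=cfg, g=g, gE=gE, liab_grid=liab,
        probs_grid=probs, category_grid=cat, observed=observed,
    )
    return table, truth


def discretize_trait(
    values_by_env: dict,
    quantile_levels,
    boundary: str = "le",
) -> dict:
    """Discretise a continuous trait per environment at given quantile levels.

    Within each environment the empirical quantiles q_k (linear interpolation
    between order statistics, numpy's default) are computed and each value v
    is assigned category ``1 + #{k : v > q_k}`` — values equal to a boundary
    fall in the lower category (``boundary='le'``); ``boundary='lt'`` uses the
    opposite convention.

    Parameters
    ----------
    values_by_env : dict
        Environment id → 1-D array of continuous values (≥ 2 per env).
    quantile_levels : sequence of float
        Strictly increasing levels in (0, 1); K levels give K+1 categories.

    Returns
    -------
    dict : environment id → integer category array in 1..K+1.
    """
    levels = np.asarray(quantile_levels, dtype=float)
    if levels.ndim != 1 or len(levels) == 0:
        raise ValueError("quantile_levels must be a non-empty 1-D sequence")
    if not np.all((levels > 0) & (levels < 1)):
        raise ValueError("quantile levels must lie strictly in (0, 1)")
    if len(levels) > 1 and not np.all(np.diff(levels) > 0):
        raise ValueError("quantile levels must be strictly increasing")
    if boundary not in ("le", "lt"):
        raise ValueError("boundary must be 'le' or 'lt'")

    out = {}
    for env, values in values_by_env.items():
        v = np.asarray(values, dtype=float)
        if v.size < 2:
            raise ValueError(f"environment {env!r} has fewer than 2 values")
        if np.ptp(v) == 0:
            raise ValueError(
                f"environment {env!r} has constant values; all quantiles tie"
            )
        q = np.quantile(v, levels)  # linear interpolation ("type 7")
        if boundary == "le":
            out[env] = (1 + np.sum(v[:, None] > q, axis=1)).astype(int)
        else:
            out[env] = (1 + np.sum(v[:, None] >= q, axis=1)).astype(int)
    return out
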