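"""One-vs-one radial-kernel SVM for ordered categories.

K classes are handled by K(K−1)/2 soft-margin binary machines, one per
unordered class pair (the lower class coded +1, the higher −1), each trained
only on that pair's rows with the radial kernel

    K(x, x′) = exp(−γ ‖x − x′‖²),

cost T bounding the total margin violation.  Prediction applies every
binary machine to the query and counts "+1" votes; the class with most
votes wins, ties broken by the larger sum of signed decision values, then
by the lower class index.  (T, γ) are tuned on the benchmark's grid
T ∈ {1, 1.2, 1.4, 1.6, 1.8, 2} × γ ∈ {1e-4, 2e-4, 2.5e-4, 3e-4} by 10-fold
inner cross-validation on the classification accuracy.

The binary quadratic subproblem is solved by scikit-learn's SMO
(:class:`sklearn.svm.SVC`); the kernel form, pairing protocol, voting,
tie-breaks and tuning loop live here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

__all__ = [
    "SVMSpec",
    "OvoModel",
    "radial_kernel",
    "fit_ovo",
    "predict_vote",
    "tune_svm",
    "DEFAULT_COST_GRID",
    "DEFAULT_GAMMA_GRID",
    "OrdinalSVM",
]

DEFAULT_COST_GRID = (1.0, 1.2, 1.4, 1.6, 1.8, 2.0)
DEFAULT_GAMMA_GRID = (1e-4, 2e-4, 2.5e-4, 3e-4)


@dataclass
class SVMSpec:
    """Soft-margin cost T and radial-kernel width γ (both > 0)."""

    cost: float = 1.0
    kernel_gamma: float = 1e-4

    def __post_init__(self):
        if self.cost <= 0 or self.kernel_gamma <= 0:
            raise ValueError("cost and kernel_gamma must be strictly positive")


def radial_kernel(x: np.ndarray, x_prime: np.ndarray, gamma: float) -> float:
    """exp(−γ Σ_j (x_j − x′_j)²) ∈ (0, 1]."""
    x = np.asarray(x, dtype=float)
    x_prime = np.asarray(x_prime, dtype=float)
    if x.shape != x_prime.shape:
        raise ValueError(f"width mismatch: {x.shape} vs {x_prime.shape}")
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    return float(np.exp(-gamma * np.sum((x - x_prime) ** 2)))


class OvoModel:
    """K(K−1)/2 fitted binary machines over the observed class labels."""

    def __init__(self, classes: np.ndarray, machines: dict, spec: SVMSpec):
        self.classes = classes
        self.machines = machines  # {(a, b): fitted binary SVC}, a < b
        self.spec = spec

    @property
    def n_machines(self) -> int:
        return len(self.machines)


def fit_ovo(features: np.ndarray, labels: np.ndarray, spec: SVMSpec) -> OvoModel:
    """Fit one binary radial-kernel SVM per unordered class pair.

    For pair (a, b) with a < b, class a is coded +1 and class b −1; only
    rows of those two classes enter the subproblem.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    counts = {c: int((y == c).sum()) for c in classes}
    empty = [c for c, n in counts.items() if n == 0]
    if empty:
        raise ValueError(f"class(es) with no training rows: {empty}")
    machines = {}
    for ia in range(classes.size):
        for ib in range(ia + 1, classes.size):
            a, b = classes[ia], classes[ib]
            sel = (y == a) | (y == b)
            y_pm = np.where(y[sel] == a, 1, -1)
            svc = SVC(C=spec.cost, kernel="rbf", gamma=spec.kernel_gamma)
            svc.fit(X[sel], y_pm)
            machines[(a, b)] = svc
    return OvoModel(classes, machines, spec)


def decision_values(model: OvoModel, X: np.ndarray) -> dict:
    """Signed decision value f(x) of each binary machine (positive → first class)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    out = {}
    for pair, svc in model.machines.items():
        f = svc.decision_function(X)
        # SVC orders classes [-1, +1]; positive decision means +1, i.e. pair[0]
        out[pair] = f
    return out


def predict_vote(model: OvoModel, X: np.ndarray) -> np.ndarray:
    """Majority vote over all binary machines.

    Each machine votes for the class on the positive side of its decision
    function.  Ties are broken by the larger sum of signed decision values
    among the tied classes, then by the lowest class index.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    K = model.classes.size
    pos = {c: k for k, c in enumerate(model.classes)}
    votes = np.zeros((len(X), K), dtype=int)
    score = np.zeros((len(X), K))
    for (a, b), f in decision_values(model, X).items():
        ka, kb = pos[a], pos[b]
        win_a = f > 0
        votes[win_a, ka] += 1
        votes[~win_a, kb] += 1
        score[:, ka] += f
        score[:, kb] -= f
    out = np.empty(len(X), dtype=model.classes.dtype)
    for r in range(len(X)):
        top = votes[r].max()
        tied = np.flatnonzero(votes[r] == top)
        if tied.size > 1:
            tied = tied[score[r, tied] == score[r, tied].max()]
        out[r] = model.classes[tied[0]]
    return out


def tune_svm(
    features: np.ndarray,
    labels: np.ndarray,
    cost_grid=DEFAULT_COST_GRID,
    gamma_grid=DEFAULT_GAMMA_GRID,
    k_inner: int = 10,
    seed: int = 0,
    full_output: bool = False,
):
    """Pick (T, γ) by mean k-fold inner-CV accuracy on the training data.

    Folds are stratified by class when every class has at least ``k_inner``
    rows; otherwise plain K-fold with a warning.  Ties prefer the smaller T,
    then the smaller γ.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if len(X) < k_inner:
        raise ValueError(f"need at least k_inner={k_inner} rows, got {len(X)}")
    _, counts = np.unique(y, return_counts=True)
    if counts.min() >= k_inner:
        splitter = StratifiedKFold(n_splits=k_inner, shuffle=True, random_state=seed)
        splits = list(splitter.split(X, y))
    else:
        warnings.warn(
            "a class has fewer rows than the fold count; using unstratified "
            "inner folds", RuntimeWarning,
        )
        splitter = KFold(n_splits=k_inner, shuffle=True, random_state=seed)
        splits = list(splitter.split(X))

    best, best_acc, trace = None, -np.inf, []
    for T in sorted(cost_grid):
        for gam in sorted(gamma_grid):
            spec = SVMSpec(cost=T, kernel_gamma=gam)
            accs = []
            for tr, te in splits:
                model = fit_ovo(X[tr], y[tr], spec)
                pred = predict_vote(model, X[te])
                accs.append(float(np.mean(pred == y[te])))
            acc = float(np.mean(accs))
            trace.append((T, gam, 100.0 * acc))
            if acc > best_acc:
                best, best_acc = spec, acc
    if full_output:
        return best, trace
    return best


class OrdinalSVM:
    """Estimator-style wrapper: tune on the grid, refit on all rows."""

    def __init__(self, features, labels, cost_grid=DEFAULT_COST_GRID,
                 gamma_grid=DEFAULT_GAMMA_GRID, k_inner: int = 10, seed: int = 0):
        self.features = np.asarray(features, dtype=float)
        self.labels = np.asarray(labels)
        self.cost_grid = cost_grid
        self.gamma_grid = gamma_grid
        self.k_inner = k_inner
        self.seed = seed

    def fit(self) -> "OrdinalSVMResults":
        spec, trace = tune_svm(
            self.features, self.labels, self.cost_grid, self.gamma_grid,
            k_inner=self.k_inner, seed=self.seed, full_output=True,
        )
        model = fit_ovo(self.features, self.labels, spec)
        return OrdinalSVMResults(spec, model, trace)


class OrdinalSVMResults:
    def __init__(self, spec: SVMSpec, model: OvoModel, trace):
        self.spec = spec
        self.model = model
        self.tuning_trace = trace

    def predict(self, X) -> np.ndarray:
        return predict_vote(self.model, X)
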