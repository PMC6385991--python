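"""Genomic relationship kernels and Cholesky-based feature construction.

The genomic relationship matrix (GRM) ``G1 = W Wᵀ / m`` is computed from
column-standardised marker dosages W (VanRaden-type).  Genotype-by-environment
covariance is the Kronecker product ``G2 = I_I ⊗ G1`` — environments are
assumed independent, so G2 is block-diagonal with one GRM block per
environment and is never materialised for model fitting; entries are served
on demand.  For the machine-learning stages each line is represented by its
row of the Cholesky factor L1 of G1, so that the Gram matrix of those rows
reproduces G1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MarkerMatrix",
    "KernelSet",
    "scale_markers",
    "compute_g1",
    "expand_g2",
    "materialize_g2",
    "cholesky_features",
    "assemble_features",
]

#: jitter ladder tried in order when G1 is numerically rank-deficient
JITTER_LADDER = (0.0, 1e-10, 1e-8, 1e-6, 1e-4)


@dataclass
class MarkerMatrix:
    """Line × marker dosage matrix with its column-standardised version.

    Attributes
    ----------
    line_ids : list of str
        Identifiers for the J lines (rows).
    raw : ndarray of shape (J, m)
        Dosages, typically minor-allele counts in {0, 1, 2}.
    scaled : ndarray of shape (J, m)
        Column-centred, column-scaled dosages (the W of the GRM).
    """

    line_ids: list
    raw: np.ndarray
    scaled: np.ndarray = field(default=None)  # type: ignore[assignment]
    marker_ids: list = None

    def __post_init__(self):
        self.raw = np.asarray(self.raw, dtype=float)
        if self.raw.ndim != 2:
            raise ValueError("marker matrix must be 2-D (lines × markers)")
        if len(self.line_ids) != self.raw.shape[0]:
            raise ValueError(
                f"{len(self.line_ids)} line ids for {self.raw.shape[0]} rows"
            )
        if self.marker_ids is None:
            self.marker_ids = [f"M{k+1}" for k in range(self.raw.shape[1])]
        if self.scaled is None:
            self.scaled = scale_markers(self.raw, marker_ids=self.marker_ids)

    @property
    def n_lines(self) -> int:
        return self.raw.shape[0]

    @property
    def n_markers(self) -> int:
        return self.raw.shape[1]


def scale_markers(raw: np.ndarray, marker_ids=None) -> np.ndarray:
    """Centre each marker column and divide by its population (1/n) SD.

    With this scaling ``W Wᵀ / m`` has unit average diagonal, so genomic
    variance is expressed per unit of relationship.

    Raises
    ------
    ValueError
        If any column is constant (zero variance), naming the marker.
    """
    raw = np.asarray(raw, dtype=float)
    mean = raw.mean(axis=0)
    sd = raw.std(axis=0)  # population SD (ddof=0)
    bad = np.flatnonzero(sd == 0.0)
    if bad.size:
        name = marker_ids[bad[0]] if marker_ids is not None else f"column {bad[0]}"
        raise ValueError(f"constant marker column cannot be scaled: {name}")
    return (raw - mean) / sd


def compute_g1(W: np.ndarray) -> np.ndarray:
    """Genomic relationship matrix ``G1 = W Wᵀ / m`` from scaled markers."""
    W = np.asarray(W, dtype=float)
    if W.ndim != 2 or W.shape[1] < 1:
        raise ValueError("W must be J×m with m ≥ 1")
    G1 = W @ W.T / W.shape[1]
    return (G1 + G1.T) / 2.0  # enforce exact symmetry


def expand_g2(I: int, G1: np.ndarray, pairs) -> np.ndarray:
    """Entries of ``I_I ⊗ G1`` for cell-index pairs, without materialising it.

    Each pair is ``((i, j), (i2, j2))`` of zero-based (environment, line)
    indices.  Environments are independent, so the entry is ``G1[j, j2]``
    when ``i == i2`` and 0 otherwise.
    """
    G1 = np.asarray(G1)
    J = G1.shape[0]
    out = np.empty(len(pairs))
    for k, ((i, j), (i2, j2)) in enumerate(pairs):
        if not (0 <= i < I and 0 <= i2 < I):
            raise IndexError(f"environment index out of range in pair {k}")
        if not (0 <= j < J and 0 <= j2 < J):
            raise IndexError(f"line index out of range in pair {k}")
        out[k] = G1[j, j2] if i == i2 else 0.0
    return out


def materialize_g2(I: int, G1: np.ndarray) -> np.ndarray:
    """Explicit ``I_I ⊗ G1`` (tests and tiny problems only)."""
    return np.kron(np.eye(I), np.asarray(G1, dtype=float))


def cholesky_features(G1: np.ndarray) -> tuple[np.ndarray, float]:
    """Lower-triangular L1 with ``L1 L1ᵀ = G1 + jitter·Id``.

    The smallest jitter from the ladder ``{0, 1e-10, 1e-8, 1e-6, 1e-4}``
    for which the factorisation succeeds is used; duplicated genotypes make
    G1 rank-deficient, so a nonzero jitter is routine.

    Returns
    -------
    (L1, jitter)
    """
    G1 = np.asarray(G1, dtype=float)
    if not np.allclose(G1, G1.T, atol=1e-8):
        raise ValueError("G1 must be symmetric")
    for jitter in JITTER_LADDER:
        try:
            L1 = np.linalg.cholesky(G1 + jitter * np.eye(G1.shape[0]))
            return L1, jitter
        except np.linalg.LinAlgError:
            continue
    raise np.linalg.LinAlgError(
        f"Cholesky failed at the largest jitter {JITTER_LADDER[-1]:g}; "
        "G1 is not positive semidefinite"
    )


def assemble_features(
    cells, L1: np.ndarray, I: int, include_interaction: bool = True
) -> np.ndarray:
    """Feature rows for (environment, line) cells.

    A cell's row concatenates a one-hot environment block (I columns), the
    line's row of the GRM Cholesky factor (J columns) and — when the G×E
    variant is requested — the one-hot(environment) ⊗ Cholesky-row block
    (I·J columns), which is the cell's row of the Cholesky factor of
    ``I_I ⊗ G1``.

    Parameters
    ----------
    cells : sequence of (i, j)
        Zero-based environment and line indices.
    include_interaction : bool
        True for the with-interaction (I) variant, False for WI.
    """
    L1 = np.asarray(L1, dtype=float)
    J = L1.shape[0]
    width = I + J + (I * J if include_interaction else 0)
    X = np.zeros((len(cells), width))
    for r, (i, j) in enumerate(cells):
        if not 0 <= i < I:
            raise IndexError(f"unknown environment index {i} in cell {r}")
        if not 0 <= j < J:
            raise IndexError(f"unknown line index {j} in cell {r}")
        X[r, i] = 1.0
        X[r, I : I + J] = L1[j]
        if include_interaction:
            off = I + J + i * J
            X[r, off : off + J] = L1[j]
    return X


@dataclass
class KernelSet:
    """G1 with its Cholesky factor; G2 = I_I ⊗ G1 kept implicit.

    ``eigvals``/``eigvecs`` hold the symmetric eigendecomposition of G1
    (eigenvalues clipped at zero), shared by the Gibbs sampler.
    """

    G1: np.ndarray
    I: int
    L1: np.ndarray = None
    jitter: float = None
    line_ids: list = None
    eigvals: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]
    eigvecs: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]

    def __post_init__(self):
        G1 = np.asarray(self.G1, dtype=float)
        if not np.allclose(G1, G1.T, atol=1e-10):
            raise ValueError("G1 must be symmetric")
        self.G1 = (G1 + G1.T) / 2.0
        if self.eigvals is None:
            w, U = np.linalg.eigh(self.G1)
            if w.min() < -1e-8:
                raise ValueError(
                    f"G1 has eigenvalue {w.min():.3e} < -1e-8: not PSD"
                )
            self.eigvals = np.clip(w, 0.0, None)
            self.eigvecs = U
        if self.L1 is None:
            self.L1, self.jitter = cholesky_features(self.G1)
        if self.line_ids is None:
            self.line_ids = [f"L{j+1}" for j in range(self.G1.shape[0])]

    @property
    def n_lines(self) -> int:
        return self.G1.shape[0]

    @classmethod
    def from_markers(cls, markers: MarkerMatrix, I: int) -> "KernelSet":
        G1 = compute_g1(markers.scaled)
        return cls(G1=G1, I=I, line_ids=list(markers.line_ids))

    def g2_entries(self, pairs) -> np.ndarray:
        return expand_g2(self.I, self.G1, pairs)
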