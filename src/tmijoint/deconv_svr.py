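"""Linear deconvolution of bulk expression into cell-type fractions via SVR.

Solves X = S·f one sample at a time with epsilon-insensitive support vector
regression under a linear kernel, after restricting both matrices to their
shared genes and z-scoring each over all entries. Raw regression coefficients
are mapped to the probability simplex by clamping negatives to zero and
renormalizing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.svm import SVR

# Converged defaults used when swarm tuning is skipped: penalty C = 3,
# tube half-width epsilon ~ 1.2e-5, kernel coefficient phi ~ 0.045 (inert
# under the linear kernel but kept for API symmetry with the tuner).
DEFAULT_C = 3.0
DEFAULT_EPSILON = 1.203564e-5
DEFAULT_PHI = 0.04545455


class DeconvolutionError(ValueError):
    pass


@dataclass(frozen=True)
class SvrParams:
    """Hyperparameters of the epsilon-SVR solver."""

    epsilon: float = DEFAULT_EPSILON
    C: float = DEFAULT_C
    phi: float = DEFAULT_PHI  # inert for k(x, y) = x.y; retained on purpose

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.C <= 0:
            raise ValueError("C must be > 0")
        if self.phi <= 0:
            raise ValueError("phi must be > 0")

    def as_vector(self) -> np.ndarray:
        return np.array([self.epsilon, self.C, self.phi])


@dataclass
class SignatureMatrix:
    """Gene x cell-type reference expression basis (non-negative)."""

    values: pd.DataFrame  # rows: genes, columns: cell types

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise DeconvolutionError("signature matrix contains non-finite entries")
        zero_cols = self.values.columns[(vals == 0).all(axis=0)]
        if len(zero_cols):
            raise DeconvolutionError(f"all-zero signature columns: {list(zero_cols)}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def cell_type_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class MixtureMatrix:
    """Gene x sample bulk expression matrix."""

    values: pd.DataFrame  # rows: genes, columns: samples

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.values.to_numpy(dtype=float))):
            raise DeconvolutionError("mixture matrix contains non-finite entries")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)


@dataclass
class CellFractionTable:
    """Sample x cell-type proportions, rows on the probability simplex."""

    values: pd.DataFrame  # rows: samples, columns: cell types
    raw_coefficients: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        vals = self.values.to_numpy(dtype=float)
        if np.any(vals < -1e-12):
            raise DeconvolutionError("fractions must be non-negative")
        if not np.allclose(vals.sum(axis=1), 1.0, atol=1e-9):
            raise DeconvolutionError("fraction rows must sum to 1")


def _zscore_global(frame: pd.DataFrame) -> pd.DataFrame:
    vals = frame.to_numpy(dtype=float)
    sd = vals.std()
    if sd == 0:
        raise DeconvolutionError("matrix is constant; cannot z-score")
    return (frame - vals.mean()) / sd


def align_and_normalize(
    X: MixtureMatrix, S: SignatureMatrix
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Restrict both matrices to shared genes (mixture order) and z-score each
    over all of its entries."""
    shared = [g for g in X.gene_ids if g in set(S.gene_ids)]
    if len(shared) < 2:
        sample_x = X.gene_ids[:5]
        sample_s = S.gene_ids[:5]
        raise DeconvolutionError(
            f"only {len(shared)} shared genes between mixture and signature "
            f"(mixture starts {sample_x}, signature starts {sample_s})"
        )
    return _zscore_global(X.values.loc[shared]), _zscore_global(S.values.loc[shared])


def svr_solve(
    x: np.ndarray, S_norm: np.ndarray, params: SvrParams | None = None,
    tol: float = 1e-4,
) -> np.ndarray:
    """Regression coefficients of epsilon-SVR fitting x ~ S_norm @ w.

    Deterministic for fixed inputs (libsvm's SMO has no random component for
    epsilon-SVR with these settings). The default stopping tolerance is loose
    enough to keep per-sample fits fast; tighten for stress tests.
    """
    params = params or SvrParams()
    x = np.asarray(x, dtype=float)
    S_norm = np.asarray(S_norm, dtype=float)
    if x.ndim != 1 or S_norm.shape[0] != x.shape[0]:
        raise DeconvolutionError(
            f"shape mismatch: x has {x.shape[0]} genes, signature {S_norm.shape[0]}"
        )
    model = SVR(kernel="linear", C=params.C, epsilon=params.epsilon, tol=tol)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model.fit(S_norm, x)
    if model.fit_status_ != 0:  # pragma: no cover - libsvm rarely reports this
        raise DeconvolutionError(f"SVR solver failed to converge with {params}")
    return model.coef_.ravel().copy()


def coefficients_to_fractions(w: np.ndarray) -> np.ndarray:
    """Clamp negatives to zero and renormalize; all-non-positive coefficient
    vectors degrade to the uniform distribution with a warning."""
    w = np.asarray(w, dtype=float)
    clamped = np.clip(w, 0.0, None)
    total = clamped.sum()
    if total <= 0:
        warnings.warn(
            "all coefficients non-positive; returning uniform fractions",
            stacklevel=2,
        )
        return np.full(w.shape, 1.0 / w.size)
    return clamped / total


def deconvolve(
    X: MixtureMatrix, S: SignatureMatrix, params: SvrParams | None = None
) -> CellFractionTable:
    """Estimate per-sample cell-type fractions for every mixture column."""
    params = params or SvrParams()
    X_norm, S_norm = align_and_normalize(X, S)
    S_arr = S_norm.to_numpy()
    coefs = {}
    fracs = {}
    for sample in X_norm.columns:
        w = svr_solve(X_norm[sample].to_numpy(), S_arr, params)
        coefs[sample] = w
        fracs[sample] = coefficients_to_fractions(w)
    cell_types = S.cell_type_ids
    return CellFractionTable(
        values=pd.DataFrame.from_dict(fracs, orient="index", columns=cell_types).loc[
            X.sample_ids
        ],
        raw_coefficients=pd.DataFrame.from_dict(
            coefs, orient="index", columns=cell_types
        ).loc[X.sample_ids],
    )


# ---------------------------------------------------------------------------
# TSV plumbing: header row = column ids, first column = row ids
# ---------------------------------------------------------------------------

def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_matrix_tsv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", float_format="%.10g")
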