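"""CCA-based spatial filtering of ERP epochs.

Spatial filters are weight vectors over electrodes that project multichannel
EEG onto virtual channels.  Here they are fitted by canonical correlation
analysis between the stacked target-class training epochs and equally many
stacked copies of their average ERP waveform: the canonical directions on the
epoch side maximize the correlation of single-trial projections with the
average evoked response, concentrating stimulus-locked energy in few
components.  The ``n_w`` directions with the highest canonical correlations
(default 4) are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import linalg

from .preprocessing import DownsampledEpoch

__all__ = [
    "TargetEpochSet",
    "AverageErp",
    "CcaProblem",
    "SpatialFilterBank",
    "average_erp",
    "build_cca_problem",
    "fit_cca_filters",
    "apply_filters",
]

#: Number of spatial filters retained by default.
DEFAULT_N_W = 4

#: Ridge added to covariance diagonals before whitening, for rank safety.
CCA_RIDGE = 1e-8


@dataclass
class TargetEpochSet:
    """Artifact-free downsampled epochs of the target class used for fitting."""

    epochs: list[DownsampledEpoch]

    def __post_init__(self) -> None:
        if len(self.epochs) < 2:
            raise ValueError("need at least two target epochs")
        shapes = {ep.Y.shape for ep in self.epochs}
        if len(shapes) != 1:
            raise ValueError(f"epochs disagree in shape: {shapes}")

    @property
    def n_target(self) -> int:
        return len(self.epochs)

    @property
    def shape(self) -> tuple[int, int]:
        return self.epochs[0].Y.shape

    def stack(self) -> np.ndarray:
        """(n_target, n_channels, n_hat_t) array of the epoch matrices."""
        return np.stack([ep.Y for ep in self.epochs])


@dataclass(frozen=True)
class AverageErp:
    """Entrywise mean of a target epoch set (n_channels x n_hat_t, uV)."""

    Ybar: np.ndarray


@dataclass(frozen=True)
class CcaProblem:
    """Stacked design matrices for the CCA fit.

    ``U`` stacks the transposed epochs, ``V`` stacks equally many transposed
    copies of the average ERP; both are (n_hat_t * n_target) x n_channels.
    """

    U: np.ndarray
    V: np.ndarray


@dataclass
class SpatialFilterBank:
    """Retained CCA spatial filters.

    ``W`` holds one unit-norm weight vector per column (n_channels x n_w),
    ordered by decreasing canonical correlation; each column's
    largest-magnitude element is positive (sign convention, the scale of a
    CCA direction being arbitrary).
    """

    W: np.ndarray
    correlations: np.ndarray
    n_w: int

    def __post_init__(self) -> None:
        if self.W.shape[1] != self.n_w or self.correlations.shape != (self.n_w,):
            raise ValueError("inconsistent filter bank shapes")
        if np.any(np.diff(self.correlations) > 1e-12):
            raise ValueError("correlations must be non-increasing")

    def to_json(self, path: str | Path, montage_hash: str | None = None) -> None:
        Path(path).write_text(json.dumps({
            "weights": self.W.tolist(),
            "correlations": self.correlations.tolist(),
            "n_w": self.n_w,
            "montage_hash": montage_hash,
        }, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "SpatialFilterBank":
        doc = json.loads(Path(path).read_text())
        return cls(W=np.asarray(doc["weights"], dtype=float),
                   correlations=np.asarray(doc["correlations"], dtype=float),
                   n_w=int(doc["n_w"]))


def average_erp(epoch_set: TargetEpochSet) -> AverageErp:
    """Arithmetic mean of the target epochs, entry by entry."""
    return AverageErp(Ybar=epoch_set.stack().mean(axis=0))


def build_cca_problem(epoch_set: TargetEpochSet) -> CcaProblem:
    """Assemble the stacked (n_hat_t * n_target) x n_channels design matrices."""
    stacked = epoch_set.stack()                       # (k, n_e, n_t)
    ybar = stacked.mean(axis=0)
    U = stacked.transpose(0, 2, 1).reshape(-1, stacked.shape[1])
    V = np.tile(ybar.T, (epoch_set.n_target, 1))
    return CcaProblem(U=U, V=V)


def _fix_sign(W: np.ndarray) -> np.ndarray:
    idx = np.argmax(np.abs(W), axis=0)
    signs = np.sign(W[idx, np.arange(W.shape[1])])
    signs[signs == 0] = 1.0
    return W * signs


def _cca_directions(U: np.ndarray, V: np.ndarray,
                    ridge: float = CCA_RIDGE) -> tuple[np.ndarray, np.ndarray]:
    """All canonical directions on the U side, by whitened cross-covariance SVD.

    Columns are mean-centered (standard CCA convention).  Returns the U-side
    directions (columns, unsorted scale) and the canonical correlations,
    both ordered by decreasing correlation.
    """
    Uc = U - U.mean(axis=0)
    Vc = V - V.mean(axis=0)
    n = Uc.shape[0]
    Cuu = Uc.T @ Uc / (n - 1)
    Cvv = Vc.T @ Vc / (n - 1)
    Cuv = Uc.T @ Vc / (n - 1)
    scale = max(np.trace(Cuu), np.trace(Cvv), 1.0)
    Cuu = Cuu + ridge * scale * np.eye(Cuu.shape[0])
    Cvv = Cvv + ridge * scale * np.eye(Cvv.shape[0])

    Lu = linalg.cholesky(Cuu, lower=True)
    Lv = linalg.cholesky(Cvv, lower=True)
    K = linalg.solve_triangular(Lu, Cuv, lower=True)
    K = linalg.solve_triangular(Lv, K.T, lower=True).T
    left, corrs, _right = linalg.svd(K)
    # Map whitened directions back to channel space.
    W = linalg.solve_triangular(Lu.T, left, lower=False)
    return W, np.clip(corrs, 0.0, 1.0)


def fit_cca_filters(epoch_set: TargetEpochSet, n_w: int = DEFAULT_N_W,
                    ridge: float = CCA_RIDGE) -> SpatialFilterBank:
    """Fit the spatial filter bank from target-class epochs.

    Raises an estimation error when the stacked epoch matrix carries no
    variance in any direction (e.g. all-zero epochs).  Warns (via the return
    path of numpy errstate nothing - callers with very few epochs get noisier
    filters; the calibration layer enforces its own minimum).
    """
    n_e = epoch_set.shape[0]
    if not 1 <= n_w <= n_e:
        raise ValueError(f"n_w must be in [1, {n_e}], got {n_w}")
    problem = build_cca_problem(epoch_set)
    Uc = problem.U - problem.U.mean(axis=0)
    if not np.any(np.abs(Uc) > 0):
        raise np.linalg.LinAlgError(
            "target epochs carry no variance; cannot estimate spatial filters")
    W_all, corrs = _cca_directions(problem.U, problem.V, ridge=ridge)
    W = W_all[:, :n_w]
    W = W / np.linalg.norm(W, axis=0, keepdims=True)
    W = _fix_sign(W)
    return SpatialFilterBank(W=W, correlations=corrs[:n_w], n_w=n_w)


def apply_filters(epoch: DownsampledEpoch | np.ndarray,
                  bank: SpatialFilterBank) -> np.ndarray:
    """Project an epoch onto the filter bank: row j = w_j' Y (n_w x n_hat_t)."""
    Y = epoch.Y if isinstance(epoch, DownsampledEpoch) else np.asarray(epoch)
    if Y.shape[0] != bank.W.shape[0]:
        raise ValueError(
            f"epoch has {Y.shape[0]} channels, bank expects {bank.W.shape[0]}")
    return bank.W.T @ Y
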