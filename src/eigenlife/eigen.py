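"""Eigenbehavior modelling of binary routine matrices.

The principal components of a behavior matrix — the eigenvectors u of the
sample covariance of its mean-centered rows, ranked by eigenvalue — are
the *eigenbehaviors* of the individual (rows = days) or group (rows =
per-subject average behaviors).  The smallest leading set explaining at
least 90% of the variability are the *primary* eigenbehaviors; the fewer
are needed, the more regular the routine.  A day Gamma is represented by
its weight vector omega_i = u_i . (Gamma - Psi) relative to the average
behavior Psi, and partially observed days can be completed by least
squares in the eigenbehavior basis.

The modelling interface follows the Model/Results convention:
``EigenBehavior(matrix).fit()`` returns an :class:`EigenBehaviorResults`
carrying Psi, the eigenvectors/eigenvalues, explained-variance fractions
and the projection/reconstruction/prediction machinery.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .behavior import BehaviorMatrix

# Components with eigenvalue below RANK_RTOL * largest are numerical noise.
RANK_RTOL = 1e-12


class EigenBehavior:
    """Eigenbehavior model of one behavior matrix.

    Parameters
    ----------
    matrix : BehaviorMatrix or array-like
        D x H matrix of daily behaviors (or N x H of average behaviors).
        At least two rows are required to define a covariance.
    """

    def __init__(self, matrix: BehaviorMatrix | np.ndarray):
        if isinstance(matrix, BehaviorMatrix):
            self.endog = matrix.values
            self.col_labels = list(matrix.col_labels)
            self.row_labels = list(matrix.row_labels)
            self.category = matrix.category
        else:
            self.endog = np.asarray(matrix, dtype=float)
            self.col_labels = [f"c{i}" for i in range(self.endog.shape[1])]
            self.row_labels = list(range(self.endog.shape[0]))
            self.category = None
        if self.endog.ndim != 2:
            raise ValueError("behavior data must be 2-D")
        if self.endog.shape[0] < 2:
            raise ValueError("need at least 2 rows to fit an eigenmodel")

    def fit(self) -> "EigenBehaviorResults":
        """Eigendecomposition of the sample covariance via thin SVD.

        The SVD of the centered data is used instead of forming the H x H
        covariance explicitly; eigenvalues are singular values squared over
        (D - 1).  Components below ``RANK_RTOL`` times the leading
        eigenvalue are dropped, and each eigenvector's sign is fixed so its
        largest-magnitude entry is positive.
        """
        X = self.endog
        psi = X.mean(axis=0)
        centered = X - psi
        _, s, vt = np.linalg.svd(centered, full_matrices=False)
        eigvals = s ** 2 / (X.shape[0] - 1)
        if eigvals.size and eigvals[0] > 0:
            keep = eigvals > RANK_RTOL * eigvals[0]
        else:
            keep = np.zeros(eigvals.shape, dtype=bool)
        eigvals = eigvals[keep]
        eigvecs = vt[keep].T  # H x r, columns orthonormal
        for i in range(eigvecs.shape[1]):
            col = eigvecs[:, i]
            if col[np.argmax(np.abs(col))] < 0:
                eigvecs[:, i] = -col
        return EigenBehaviorResults(self, psi, eigvals, eigvecs)


@dataclass
class EigenBehaviorResults:
    """Fitted eigenbehavior decomposition.

    Attributes
    ----------
    psi : ndarray, shape (H,)
        Average behavior (column means).
    eigvals : ndarray, shape (r,)
        Eigenvalues of the sample covariance, descending.
    eigvecs : ndarray, shape (H, r)
        Orthonormal eigenbehaviors as columns, signs fixed.
    """

    model: EigenBehavior
    psi: np.ndarray
    eigvals: np.ndarray
    eigvecs: np.ndarray

    @property
    def rank(self) -> int:
        return self.eigvals.size

    @property
    def evr(self) -> np.ndarray:
        """Explained-variance fractions lambda_i / sum(lambda)."""
        total = self.eigvals.sum()
        if total == 0:
            return np.zeros(0)
        return self.eigvals / total

    def primary_count(self, threshold: float = 0.9) -> int:
        """Smallest k whose leading eigenbehaviors explain >= threshold."""
        if self.rank == 0:
            raise ValueError("degenerate model: no behavior variability")
        cum = np.cumsum(self.evr)
        return int(np.searchsorted(cum, threshold - 1e-12) + 1)

    def project(self, gamma: np.ndarray, k: int | None = None) -> np.ndarray:
        """Weights omega_i = u_i . (gamma - psi), i = 1..k."""
        gamma = np.asarray(gamma, dtype=float)
        if gamma.shape != self.psi.shape:
            raise ValueError("behavior vector has wrong length")
        k = self.rank if k is None else k
        if k > self.rank:
            raise ValueError(f"k={k} exceeds model rank {self.rank}")
        return self.eigvecs[:, :k].T @ (gamma - self.psi)

    def reconstruct(self, omega: np.ndarray) -> np.ndarray:
        """psi + sum_i omega_i u_i."""
        omega = np.asarray(omega, dtype=float)
        if omega.size > self.rank:
            raise ValueError("weight vector longer than model rank")
        return self.psi + self.eigvecs[:, :omega.size] @ omega

    def residual_norm2(self, gamma: np.ndarray, k: int | None = None) -> float:
        """Squared residual of projecting gamma onto the k-dim subspace."""
        omega = self.project(gamma, k)
        phi = np.asarray(gamma, dtype=float) - self.psi
        # clamp: cancellation can drive an exact-zero residual to -1e-16
        return float(max(phi @ phi - omega @ omega, 0.0))

    def predict_remaining(self, observed: np.ndarray,
                          observed_cols: np.ndarray,
                          target_cols: np.ndarray,
                          k: int | None = None) -> np.ndarray:
        """Complete a partially observed day by least squares.

        The weights omega minimizing the squared error between psi +
        sum omega_i u_i and the day, restricted to the observed columns,
        are found by least squares on the observed rows of the
        eigenvector matrix; the fitted combination is then evaluated on
        the target columns, clipped to [0, 1] and thresholded at 0.5.
        The number of components is truncated to the number of observed
        columns to keep the system determined.
        """
        observed = np.asarray(observed, dtype=float)
        observed_cols = np.asarray(observed_cols, dtype=int)
        target_cols = np.asarray(target_cols, dtype=int)
        if observed.shape != observed_cols.shape:
            raise ValueError("observed values/columns length mismatch")
        k = self.primary_count() if (k is None and self.rank) else (k or 0)
        k = min(k, self.rank, observed_cols.size)
        if k == 0:
            continuous = self.psi[target_cols]
        else:
            u_obs = self.eigvecs[observed_cols, :k]
            rhs = observed - self.psi[observed_cols]
            omega, *_ = np.linalg.lstsq(u_obs, rhs, rcond=None)
            continuous = self.psi[target_cols] + self.eigvecs[target_cols, :k] @ omega
        return (np.clip(continuous, 0.0, 1.0) >= 0.5).astype(float)

    def summary(self) -> str:
        lines = ["Eigenbehavior decomposition",
                 "=" * 27,
                 f"rows (days/subjects): {self.model.endog.shape[0]}",
                 f"behavior columns:     {self.model.endog.shape[1]}",
                 f"rank:                 {self.rank}"]
        if self.rank:
            lines.append(f"primary eigenbehaviors (90% variability): "
                         f"{self.primary_count()}")
            lines.append("  i   eigenvalue   explained   cumulative")
            cum = 0.0
            for i, (lam, frac) in enumerate(zip(self.eigvals, self.evr), 1):
                cum += frac
                lines.append(f"{i:>3}   {lam:10.4f}   {frac:9.4f}   {cum:10.4f}")
        else:
            lines.append("all rows identical: psi-only model")
        return "\n".join(lines)


@dataclass
class PredictionResult:
    """Leave-one-day partial-day prediction accuracies for one subject."""

    category: str | None
    per_day: list[float]
    split: str

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.per_day))


def split_columns_by_period(col_labels: list[str],
                            target_periods: set[str]) -> tuple[np.ndarray, np.ndarray]:
    """Indices of observed (earlier-period) and target columns."""
    targets = [i for i, c in enumerate(col_labels)
               if c.rsplit("_", 1)[1] in target_periods]
    observed = [i for i in range(len(col_labels)) if i not in set(targets)]
    return np.asarray(observed, dtype=int), np.asarray(targets, dtype=int)


DEFAULT_TARGET_PERIODS = {"activity": {"P2"}, "diet": {"P3", "P4", "P5"}}


def cv_prediction_accuracy(matrix: BehaviorMatrix,
                           target_periods: set[str] | None = None,
                           threshold: float = 0.9) -> PredictionResult:
    """Leave-one-day cross-validated partial-day prediction accuracy.

    For each held-out day an eigenmodel is fit on the remaining days; the
    weights are estimated from the earlier-period columns of the held-out
    day and used to predict the later-period columns (activity: P0-P1
    predict P2; diet: P0-P2 predict P3-P5).  Accuracy is the fraction of
    target cells predicted correctly.  With no variability in the
    training fold the thresholded average behavior is the prediction.
    """
    if matrix.n_rows < 3:
        raise ValueError("need at least 3 days for leave-one-day CV")
    if target_periods is None:
        target_periods = DEFAULT_TARGET_PERIODS[matrix.category]
    observed_cols, target_cols = split_columns_by_period(matrix.col_labels,
                                                         target_periods)
    if target_cols.size == 0 or observed_cols.size == 0:
        raise ValueError("period split leaves no observed or target columns")
    accuracies = []
    values = matrix.values
    for i in range(matrix.n_rows):
        train = np.delete(values, i, axis=0)
        res = EigenBehavior(train).fit()
        k = res.primary_count(threshold) if res.rank else 0
        pred = res.predict_remaining(values[i, observed_cols],
                                     observed_cols, target_cols, k=k)
        accuracies.append(float(np.mean(pred == values[i, target_cols])))
    return PredictionResult(category=matrix.category, per_day=accuracies,
                            split="+".join(sorted(target_periods)))
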