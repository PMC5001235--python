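"""Distance covariance/correlation between SMG expression submatrices.

The functional similarity of two patients' SMG lists g_a, g_b is measured by
the distance correlation of their expression submatrices E^a, E^b over the
shared cohort of N samples:

    d_jk^i   = || e_j^i - e_k^i ||                     (Euclidean column distances)
    dbar_jk  = d_jk - rowmean_j - colmean_k + grandmean (double-centering)
    dCov     = (1/N^2) sum_jk dbar_jk^a * dbar_jk^b     (biased V-statistic)
    dCor     = dCov(a,b) / sqrt(dCov(a,a) * dCov(b,b))

dCor lies in [0, 1], is 1 for identical distance structure, and — unlike a
Pearson correlation of vectors — responds to nonlinear dependence between the
two gene sets' sample geometries. The biased 1/N^2 normalization is used
throughout (not the unbiased U-statistic variant).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .expression import ExpressionMatrix, ExpressionSubmatrix, UnmatchableProfileError, extract_submatrix
from .variant_io import SMGProfile

logger = logging.getLogger(__name__)

#: Relative tolerance below which a self-dCov counts as zero (degenerate
#: constant submatrix), after normalizing by the squared grand-mean distance.
DEGENERATE_RTOL = 1e-14


class CohortMismatchError(ValueError):
    """Raised when two submatrices do not share the same ordered cohort."""


@dataclass
class DistanceMatrix:
    """N x N Euclidean distances between cohort sample columns (D^i)."""

    values: np.ndarray
    cohort: list[str]


@dataclass
class CenteredDistanceMatrix:
    """Double-centered distance matrix (row and column sums zero)."""

    values: np.ndarray


@dataclass
class DistanceCorrelationMatrix:
    """Symmetric P x P matrix of pairwise patient dCor values (D_dCor)."""

    values: np.ndarray
    patient_ids: list[str]
    degenerate_flags: dict[str, bool] = field(default_factory=dict)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.patient_ids)


def _as_values(E) -> np.ndarray:
    values = E.values if isinstance(E, ExpressionSubmatrix) else np.asarray(E, dtype=float)
    values = np.atleast_2d(np.asarray(values, dtype=float))
    if not np.isfinite(values).all():
        raise ValueError("expression submatrix contains non-finite values")
    return values


def pairwise_column_distances(E) -> DistanceMatrix:
    """Euclidean distances d_jk = ||e_j - e_k|| between all column pairs."""
    values = _as_values(E)
    if values.shape[1] < 2:
        raise ValueError("need at least 2 cohort samples")
    D = squareform(pdist(values.T, metric="euclidean"))
    cohort = E.samples if isinstance(E, ExpressionSubmatrix) else [str(j) for j in range(values.shape[1])]
    return DistanceMatrix(values=D, cohort=cohort)


def double_center(D) -> CenteredDistanceMatrix:
    """Subtract row and column means, add back the grand mean."""
    M = D.values if isinstance(D, DistanceMatrix) else np.asarray(D, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("distance matrix must be square")
    row = M.mean(axis=1, keepdims=True)
    col = M.mean(axis=0, keepdims=True)
    grand = M.mean()
    return CenteredDistanceMatrix(values=M - row - col + grand)


def _centered(E) -> tuple[np.ndarray, float]:
    """Centered distance matrix and the grand-mean distance scale."""
    D = pairwise_column_distances(E).values
    return double_center(D).values, float(D.mean())


def _check_cohort(Ea, Eb) -> None:
    if isinstance(Ea, ExpressionSubmatrix) and isinstance(Eb, ExpressionSubmatrix):
        if Ea.samples != Eb.samples:
            raise CohortMismatchError("submatrices span different cohort sample lists")
    else:
        a, b = _as_values(Ea), _as_values(Eb)
        if a.shape[1] != b.shape[1]:
            raise CohortMismatchError(
                f"cohort sizes differ: {a.shape[1]} vs {b.shape[1]}"
            )


def distance_covariance(Ea, Eb) -> float:
    """Biased V-statistic dCov between two submatrices over the same cohort."""
    _check_cohort(Ea, Eb)
    A, _ = _centered(Ea)
    B, _ = _centered(Eb)
    N = A.shape[0]
    v = float(np.sum(A * B)) / (N * N)
    return v


def _self_dcov_is_zero(dcov_self: float, grand_mean: float) -> bool:
    if grand_mean == 0.0:
        return True
    return dcov_self / (grand_mean * grand_mean) < DEGENERATE_RTOL


def distance_correlation(Ea, Eb) -> float:
    """dCor in [0, 1]; degenerate (constant) submatrices give 0 by convention."""
    _check_cohort(Ea, Eb)
    A, ga = _centered(Ea)
    B, gb = _centered(Eb)
    N = A.shape[0]
    vaa = float(np.sum(A * A)) / (N * N)
    vbb = float(np.sum(B * B)) / (N * N)
    if _self_dcov_is_zero(vaa, ga) or _self_dcov_is_zero(vbb, gb):
        return 0.0
    vab = float(np.sum(A * B)) / (N * N)
    r = vab / np.sqrt(vaa * vbb)
    return float(min(max(r, 0.0), 1.0))


def dcor_matrix(
    profiles: list[SMGProfile],
    expr: ExpressionMatrix,
) -> DistanceCorrelationMatrix:
    """Pairwise dCor matrix over all matchable patients.

    Each patient's centered distance matrix is computed once and reused for
    all P-1 pairings: the centered matrices are flattened into a P x N^2
    array whose Gram matrix (scaled by 1/N^2) is the full dCov matrix, from
    which dCor follows by normalizing with the diagonal. Profiles that match
    no expression row (or are empty) are dropped with a log message.
    """
    usable: list[tuple[str, ExpressionSubmatrix]] = []
    for prof in profiles:
        try:
            usable.append((prof.patient_id, extract_submatrix(expr, prof)))
        except UnmatchableProfileError as exc:
            logger.warning("excluding patient from dCor matrix: %s", exc)
    if len(usable) < 2:
        raise ValueError(f"need >= 2 matchable profiles, got {len(usable)}")

    N = expr.n_samples
    patient_ids = [pid for pid, _ in usable]
    flat = np.empty((len(usable), N * N), dtype=float)
    grand_means = np.empty(len(usable), dtype=float)
    for i, (_, sub) in enumerate(usable):
        C, g = _centered(sub)
        flat[i] = C.ravel()
        grand_means[i] = g

    dcov = (flat @ flat.T) / (N * N)
    self_dcov = np.diag(dcov).copy()
    degenerate = np.array(
        [_self_dcov_is_zero(v, g) for v, g in zip(self_dcov, grand_means)]
    )
    if degenerate.any():
        logger.warning(
            "%d patient(s) with degenerate (constant) submatrices: dCor set to 0",
            int(degenerate.sum()),
        )

    norm = np.sqrt(self_dcov)
    norm[degenerate] = 1.0  # avoid div-by-zero; rows/cols zeroed below
    values = dcov / np.outer(norm, norm)
    values[degenerate, :] = 0.0
    values[:, degenerate] = 0.0
    values = np.clip(values, 0.0, 1.0)
    values = (values + values.T) / 2.0
    idx = np.flatnonzero(~degenerate)
    values[idx, idx] = 1.0
    flags = {pid: bool(d) for pid, d in zip(patient_ids, degenerate)}
    return DistanceCorrelationMatrix(values=values, patient_ids=patient_ids, degenerate_flags=flags)
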