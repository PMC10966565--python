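"""Orthogonalized power-envelope connectivity (PEC).

PEC quantifies amplitude synchrony between two band-limited signals
while suppressing the spurious zero-lag coupling that volume
conduction produces: before the envelope of ``y`` is computed, the
component of ``y`` in phase with ``x`` is removed (orthogonalization),

    y_perp_x(t) = imag( y(t) * conj(x(t)) / |x(t)| ),

and the Pearson correlation of the log power envelopes
``log(|y_perp_x|^2 + eps)`` vs ``log(|x|^2 + eps)`` is averaged over
the two directions.  Instantaneous mixtures of a single source leave a
residual of ~0 and return 0 by convention.

Feature-space conventions: a band's connectivity matrix over n regions
is symmetric with a zero diagonal; vectorized row-major over the upper
triangle *including* the diagonal it has n(n+1)/2 entries (6441 at
n = 113).  Self-pairs carry 0 and are excluded from inference; they
are retained in the vector only to honor that dimension convention.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin


LOG_EPS = 1e-12   # relative floor inside log(power + eps * mean power)
# residual below this fraction of the source RMS counts as collinear
COLLINEAR_TOL = 1e-6


def n_pec_features(n_regions: int, include_diagonal: bool = True) -> int:
    """Pairwise-feature count; 113 regions -> 6441 with self-pairs."""
    if include_diagonal:
        return n_regions * (n_regions + 1) // 2
    return n_regions * (n_regions - 1) // 2


def _block_mean(x: np.ndarray, k: int) -> np.ndarray:
    """Average consecutive blocks of k samples along the last axis."""
    if k <= 1:
        return x
    n = (x.shape[-1] // k) * k
    shape = x.shape[:-1] + (n // k, k)
    return x[..., :n].reshape(shape).mean(axis=-1)


def _guarded_log(power: np.ndarray) -> np.ndarray:
    """log(power + eps*mean) — the relative floor keeps PEC exactly
    invariant to rescaling either input."""
    floor = LOG_EPS * power.mean(axis=-1, keepdims=True)
    return np.log(power + np.maximum(floor, np.finfo(float).tiny))


def _log_power(z: np.ndarray) -> np.ndarray:
    return _guarded_log(np.abs(z) ** 2)


def _corr_rows(rows: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row with a reference vector."""
    rows = rows - rows.mean(axis=-1, keepdims=True)
    ref = ref - ref.mean()
    denom = np.sqrt((rows**2).sum(axis=-1) * (ref**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (rows @ ref) / denom
    return np.where(denom > 0, r, 0.0)


def orthogonalized_envelope_correlation(
    x: np.ndarray,
    y: np.ndarray,
    env_samples_per_point: int = 1,
) -> float:
    """PEC between two complex analytic/wavelet coefficient series.

    ``env_samples_per_point`` > 1 block-averages the log-power
    envelopes before correlating (decimation to reduce envelope
    autocorrelation).
    """
    x = np.asarray(x, dtype=complex)
    y = np.asarray(y, dtype=complex)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D series of equal length")
    if x.size < 20:
        raise ValueError("need at least 20 samples")
    if not x.any() or not y.any():
        raise ValueError("all-zero input")

    def one_direction(src: np.ndarray, tgt: np.ndarray) -> float:
        mag = np.abs(src)
        resid = np.imag(tgt * np.conj(src) / (mag + LOG_EPS * mag.mean()))
        if np.sqrt((resid**2).mean()) <= COLLINEAR_TOL * np.sqrt(
            (np.abs(tgt) ** 2).mean()
        ):
            return 0.0
        lp = _block_mean(_guarded_log(resid**2), env_samples_per_point)
        ls = _block_mean(_log_power(src), env_samples_per_point)
        return float(_corr_rows(lp[None, :], ls)[0])

    return 0.5 * (one_direction(x, y) + one_direction(y, x))


def pec_matrix(
    coeffs: np.ndarray,
    env_samples_per_point: int = 1,
    subsample: int = 1,
) -> np.ndarray:
    """All-pairs PEC from one band's complex coefficients (region x time).

    ``subsample`` keeps every k-th coefficient sample before
    orthogonalization (exact, since orthogonalization is pointwise);
    ``env_samples_per_point`` block-averages the log-power envelopes
    afterwards.  Returns a symmetric matrix with zero diagonal.
    """
    coeffs = np.asarray(coeffs, dtype=complex)
    if coeffs.ndim != 2:
        raise ValueError("coeffs must be (n_regions, n_samples)")
    if subsample > 1:
        coeffs = coeffs[:, ::subsample]
    n_regions, n = coeffs.shape
    if n < 20:
        raise ValueError("need at least 20 coefficient samples")
    directed = np.zeros((n_regions, n_regions))
    rms = np.sqrt((np.abs(coeffs) ** 2).mean(axis=-1))
    for i in range(n_regions):
        mag = np.abs(coeffs[i])
        unit = coeffs[i] / (mag + LOG_EPS * mag.mean())
        resid = np.imag(coeffs * np.conj(unit)[None, :])       # every y _|_ x_i
        lp = _block_mean(_guarded_log(resid**2), env_samples_per_point)
        ls = _block_mean(_log_power(coeffs[i]), env_samples_per_point)
        row = _corr_rows(lp, ls)
        collinear = np.sqrt((resid**2).mean(axis=-1)) <= COLLINEAR_TOL * rms
        row[collinear] = 0.0
        directed[i] = row
    out = 0.5 * (directed + directed.T)
    np.fill_diagonal(out, 0.0)
    return out


def vectorize_pec(mat: np.ndarray, include_diagonal: bool = True) -> np.ndarray:
    """Row-major upper-triangle feature vector of a PEC matrix."""
    n = mat.shape[0]
    iu = np.triu_indices(n, k=0 if include_diagonal else 1)
    return np.asarray(mat)[iu]


def unvectorize_pec(vec: np.ndarray, n_regions: int, include_diagonal: bool = True) -> np.ndarray:
    """Inverse of :func:`vectorize_pec` (symmetric fill)."""
    out = np.zeros((n_regions, n_regions))
    iu = np.triu_indices(n_regions, k=0 if include_diagonal else 1)
    out[iu] = vec
    out = out + out.T - np.diag(np.diag(out))
    return out


class FeatureZScorer(TransformerMixin, BaseEstimator):
    """Across-subject z-transform of a subject x feature array.

    Standardizes every feature column to mean 0 and unit sample SD
    (ddof=1); zero-variance columns are mapped to 0 with a warning.
    Fitting requires at least two subjects.
    """

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[0] < 2:
            raise ValueError("need a 2-D array with at least 2 subjects")
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=1)
        n_dead = int((sd == 0).sum())
        if n_dead:
            warnings.warn(
                f"{n_dead} zero-variance feature(s) set to 0 after z-transform",
                stacklevel=2,
            )
        self.zero_variance_ = sd == 0
        sd = np.where(sd == 0, 1.0, sd)
        self.scale_ = sd
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = (X - self.mean_) / self.scale_
        out[:, self.zero_variance_] = 0.0
        return out


def znorm_features(features: np.ndarray) -> np.ndarray:
    """Functional one-shot across-subject feature z-transform."""
    return FeatureZScorer().fit_transform(features)


@dataclass(frozen=True)
class DiscrepancyScore:
    """Sum over unique region pairs of (subject PEC - reference PEC)."""

    subject_id: str
    band: str
    value: float


def discrepancy_sum(
    subject_pec: np.ndarray,
    reference_mean: np.ndarray,
    subject_id: str = "",
    band: str = "",
) -> DiscrepancyScore:
    """Per-subject connectivity discrepancy relative to a reference mean.

    The reference is typically the arithmetic mean PEC matrix of the
    healthy-control group; the score sums the differences over the
    unique off-diagonal pairs and is linear and additive over disjoint
    pair sets.
    """
    a = np.asarray(subject_pec, dtype=float)
    b = np.asarray(reference_mean, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"region sets differ: {a.shape} vs {b.shape}")
    iu = np.triu_indices(a.shape[0], k=1)
    return DiscrepancyScore(
        subject_id=subject_id, band=band, value=float((a[iu] - b[iu]).sum())
    )
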