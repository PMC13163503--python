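"""Pixel-wise imaging reliability in PLS score space.

Pixel spectra are projected onto the calibration latent space; each score
vector's squared Mahalanobis distance to the calibration score cloud is
compared against a chi-square quantile chosen to match k-sigma normal
coverage. The reliability index is the inlier fraction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from scipy.stats import chi2

CONDITION_WARN_THRESHOLD = 1e10
CONDITION_SINGULAR_THRESHOLD = 1e15


def ksigma_coverage(k: float) -> float:
    """Two-sided standard-normal coverage probability erf(k / sqrt(2))."""
    return math.erf(k / math.sqrt(2.0))


@dataclass
class CalibrationManifold:
    """Mean, covariance and chi-square threshold of the calibration scores."""

    mu: np.ndarray       # (A,)
    sigma: np.ndarray    # (A, A)
    A: int
    k: float
    alpha: float
    tau: float
    _cho: tuple = None   # cached Cholesky factor of sigma

    def __post_init__(self) -> None:
        self.mu = np.atleast_1d(np.asarray(self.mu, dtype=float))
        self.sigma = np.atleast_2d(np.asarray(self.sigma, dtype=float))
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must lie in (0, 1)")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        cond = np.linalg.cond(self.sigma)
        if cond > CONDITION_SINGULAR_THRESHOLD:
            raise ValueError(
                f"singular score covariance (cond={cond:.3g}); "
                "try fewer latent variables"
            )
        if cond > CONDITION_WARN_THRESHOLD:
            warnings.warn(
                f"score covariance is ill-conditioned (cond={cond:.3g})",
                stacklevel=2,
            )
        try:
            self._cho = linalg.cho_factor(self.sigma, lower=True)
        except linalg.LinAlgError as exc:
            raise ValueError(
                "singular score covariance; try fewer latent variables"
            ) from exc


def project_scores(model, spectra: np.ndarray) -> np.ndarray:
    """Project preprocessed spectra onto the model's latent space.

    T = (X - x_mean) W*; spectra must have been preprocessed with the same
    pattern as the calibration set. Set ``center=False`` on the model call
    path is intentionally not offered here; uncentered projection is
    available via ``model.Wstar`` directly.
    """
    X = np.atleast_2d(np.asarray(spectra, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"band count {X.shape[1]} does not match model ({model.x_mean.size})"
        )
    return (X - model.x_mean) @ model.Wstar


def fit_manifold(Ttrain: np.ndarray, k: float = 3.0,
                 alpha: float | None = None) -> CalibrationManifold:
    """Fit mu, Sigma and the chi-square threshold to calibration scores.

    alpha defaults to the two-sided k-sigma coverage erf(k/sqrt(2)); passing
    ``alpha`` explicitly (e.g. 0.99) overrides the k parameterization.
    """
    T = np.atleast_2d(np.asarray(Ttrain, dtype=float))
    m, A = T.shape
    if m <= A:
        raise ValueError("need more calibration samples than latent variables")
    mu = T.mean(axis=0)
    sigma = np.cov(T, rowvar=False, ddof=1)
    sigma = np.atleast_2d(sigma)
    if alpha is None:
        alpha = ksigma_coverage(k)
    tau = float(chi2.ppf(alpha, df=A))
    return CalibrationManifold(mu=mu, sigma=sigma, A=A, k=k, alpha=alpha,
                               tau=tau)


def mahalanobis_sq(t: np.ndarray, manifold: CalibrationManifold) -> np.ndarray:
    """Squared Mahalanobis distance of score vector(s) to the manifold.

    Uses a Cholesky solve rather than explicit inversion. Accepts a single
    A-vector or an (n, A) matrix; returns a scalar or an n-vector.
    """
    t = np.asarray(t, dtype=float)
    single = t.ndim == 1
    T = np.atleast_2d(t)
    if T.shape[1] != manifold.mu.size:
        raise ValueError("score dimension does not match manifold")
    diff = T - manifold.mu
    z = linalg.cho_solve(manifold._cho, diff.T)
    d2 = np.einsum("ij,ji->i", diff, z)
    d2 = np.maximum(d2, 0.0)
    return float(d2[0]) if single else d2


@dataclass
class ReliabilityResult:
    d2: np.ndarray
    inlier_mask: np.ndarray
    reliability: float
    n_pixels: int


def reliability_index(d2, tau: float) -> ReliabilityResult:
    """Inlier fraction: share of squared distances at or below tau."""
    d2 = np.asarray(d2, dtype=float).ravel()
    if d2.size == 0:
        raise ValueError("empty pixel set")
    inliers = d2 <= tau
    return ReliabilityResult(
        d2=d2,
        inlier_mask=inliers,
        reliability=float(inliers.mean()),
        n_pixels=int(d2.size),
    )


def assess_map(cube, flesh, model, spec, manifold) -> ReliabilityResult:
    """Reliability of one corrected cube's flesh pixels under a manifold."""
    from .preprocess import apply_pattern

    pix = np.where(flesh.mask)
    spectra = cube.values[pix]
    finite = np.isfinite(spectra).all(axis=1)
    processed = apply_pattern(spectra[finite], spec, on_error="nan")
    ok = np.isfinite(processed).all(axis=1)
    if not ok.any():
        raise ValueError("no valid flesh spectra to assess")
    scores = project_scores(model, processed[ok])
    d2 = mahalanobis_sq(scores, manifold)
    return reliability_index(d2, manifold.tau)


def model_reliability(per_sample_results) -> float:
    """Unweighted mean of per-sample reliability values."""
    vals = [
        r.reliability if isinstance(r, ReliabilityResult) else float(r)
        for r in per_sample_results
    ]
    if not vals:
        raise ValueError("need at least one test sample")
    return float(np.mean(vals))


def threshold_sensitivity(records, k_values=(2.0, 3.0, 4.0)):
    """Re-rank sweep configurations at alternative k-sigma thresholds.

    ``records`` are SweepRecords with cached per-sample D2 arrays. Returns a
    dict with per-k reliabilities per configuration and whether the argmax
    configuration is invariant across k.
    """
    import pandas as pd

    rows = []
    winners = {}
    for k in k_values:
        alpha = ksigma_coverage(k)
        for rec in records:
            if not rec.d2_cache or rec.manifold is None:
                raise ValueError(
                    f"no cached distances for ({rec.geometry_mode}, {rec.pattern})"
                )
            tau = float(chi2.ppf(alpha, df=rec.manifold.A))
            rel = float(np.mean([np.mean(d2 <= tau) for d2 in rec.d2_cache]))
            rows.append(dict(k=k, geometry_mode=rec.geometry_mode,
                             pattern=rec.pattern, reliability=rel))
        sub = [r for r in rows if r["k"] == k]
        best = max(sub, key=lambda r: r["reliability"])
        winners[k] = (best["geometry_mode"], best["pattern"])
    return {
        "table": pd.DataFrame(rows),
        "winners": winners,
        "invariant": len(set(winners.values())) == 1,
    }
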