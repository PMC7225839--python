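"""Mixed-model machinery for genomic prediction.

The model is the standard additive genomic mixed model

    y = 1 mu + Z u + e,    u ~ N(0, I sigma_u^2),    e ~ N(0, I sigma_e^2)

with Z the column-centered marker dosage matrix (ridge-regression BLUP),
or equivalently

    y = 1 mu + g + e,      g ~ N(0, K sigma_A^2)

with K the VanRaden method-1 genomic relationship matrix.  The two
parameterizations are linked by K = Z Z' / c with c = sum_j 2 p_j (1-p_j)
(codominant; sum_j p_j (1-p_j) for dominant presence/absence markers), so
sigma_A^2 = c * sigma_u^2 and the ridge parameter is
lambda = sigma_e^2 / sigma_u^2 = c * sigma_e^2 / sigma_A^2.

Variance components are estimated by REML on a single spectral
decomposition followed by scalar (Brent) optimization of the variance
ratio, the approach used by rrBLUP's ``mixed.solve``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .geno import CODOMINANT, DOMINANT, GenotypeMatrix


class ModelError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Centering and the genomic relationship matrix
# ---------------------------------------------------------------------------

def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Observed allele (codominant) or tag-presence (dominant) frequency
    per marker, from non-missing calls."""
    d = geno.dosages
    n_obs = np.sum(~np.isnan(d), axis=0)
    if np.any(n_obs == 0):
        raise ModelError("all-missing marker; filter before modeling")
    denom = 2.0 * n_obs if geno.marker_class == CODOMINANT else n_obs
    return np.nansum(d, axis=0) / denom


def center_dosages(
    geno: GenotypeMatrix, freqs: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Center dosages to Z = M - 2p (codominant) or M - p (dominant).

    Returns ``(Z, freqs)``.  Pass training-set ``freqs`` to center a
    validation matrix consistently.  Requires imputed (no-missing) input.
    """
    if np.isnan(geno.dosages).any():
        raise ModelError("dosages contain missing values; impute first")
    if freqs is None:
        mult = 2.0 if geno.marker_class == CODOMINANT else 1.0
        freqs = geno.dosages.mean(axis=0) / mult
    mult = 2.0 if geno.marker_class == CODOMINANT else 1.0
    return geno.dosages - mult * freqs, np.asarray(freqs)


def grm_denominator(freqs: np.ndarray, marker_class: str = CODOMINANT) -> float:
    """VanRaden normalization constant c = sum 2p(1-p) (codominant) or
    sum p(1-p) (dominant)."""
    p = np.asarray(freqs, dtype=float)
    c = float(np.sum(2.0 * p * (1.0 - p))) if marker_class == CODOMINANT \
        else float(np.sum(p * (1.0 - p)))
    return c


@dataclass
class GRM:
    """Realized genomic relationship matrix with its line ids and the
    normalization constant c linking GRM- and marker-level variances."""

    matrix: np.ndarray
    line_ids: np.ndarray
    denom: float

    def __post_init__(self) -> None:
        k = np.asarray(self.matrix, dtype=float)
        if k.shape[0] != k.shape[1]:
            raise ModelError("GRM must be square")
        if not np.allclose(k, k.T, atol=1e-10):
            raise ModelError("GRM must be symmetric")
        self.matrix = k


def grm(geno: GenotypeMatrix) -> GRM:
    """VanRaden method-1 GRM: K = W W' / c with W the centered dosages."""
    W, p = center_dosages(geno)
    c = grm_denominator(p, geno.marker_class)
    if c <= 0:
        raise ModelError("all markers monomorphic; GRM undefined")
    return GRM(matrix=(W @ W.T) / c, line_ids=geno.line_ids, denom=c)


# ---------------------------------------------------------------------------
# REML by spectral decomposition
# ---------------------------------------------------------------------------

@dataclass
class VarComp:
    """REML variance components.

    ``sigma2_K`` is the raw REML parameter: genetic variance per unit of
    the supplied K (so for K = ZZ' it is the marker-effect variance
    sigma_u^2).  ``V_A`` is the additive variance on the realized scale,
    sigma2_K * tr(PKP) / (n-1) with P the intercept-projection -- the
    expected sample variance of the genetic values.  The two coincide for
    a GRM standardized to mean diagonal ~1 in an unstructured outbred
    sample, but differ by ~(1+F) for inbred lines, where the VanRaden
    matrix has diagonal near 2.  Estimation is scale-invariant: K is
    normalized internally so the variance ratio lambda_ = V_e / V_A is
    optimized on a fixed log range whatever the scaling of K.
    ``h2`` = V_A / (V_A + V_e) exactly; the ridge parameter for marker
    effects is V_e / sigma2_K (equal to lambda_ only when K is already on
    realized scale).  ``logREML`` is the restricted log-likelihood at the
    optimum (up to the usual additive constant)."""

    V_A: float
    V_e: float
    lambda_: float
    h2: float
    logREML: float
    sigma2_K: float = 0.0


_LOG_RATIO_BOUNDS = (-10.0, 10.0)


def _spectral_reml(theta: np.ndarray, eta: np.ndarray) -> tuple[float, float, float, float]:
    """Maximize the restricted likelihood of eta_i ~ N(0, Vg*theta_i + Ve).

    ``theta``/``eta`` are eigenvalues and rotated data from the fixed-
    effect-projected covariance.  Returns (Vg, Ve, ratio Ve/Vg, logREML).
    The ratio delta = Ve/Vg is profiled: given delta,
    Vg = mean(eta^2 / (theta + delta)).
    """
    q = len(eta)
    eta2 = eta**2

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        denom = theta + delta
        vg = np.mean(eta2 / denom)
        return 0.5 * (q * np.log(vg) + np.sum(np.log(denom)) + q)

    res = optimize.minimize_scalar(
        neg_restricted_ll,
        bounds=_LOG_RATIO_BOUNDS,
        method="bounded",
        options={"xatol": 1e-10},
    )
    # Guard against interior local flatness near the bounds: compare with
    # the boundary values explicitly.
    cands = [res.x, _LOG_RATIO_BOUNDS[0], _LOG_RATIO_BOUNDS[1]]
    best = min(cands, key=neg_restricted_ll)
    delta = float(np.exp(best))
    vg = float(np.mean(eta2 / (theta + delta)))
    ve = delta * vg
    return vg, ve, delta, -neg_restricted_ll(best)


def reml(y: np.ndarray, K: GRM | np.ndarray) -> VarComp:
    """REML variance components for y = 1 mu + g + e, g ~ N(0, K V_A).

    A single eigendecomposition of the projected relationship matrix is
    followed by Brent optimization of log(V_e/V_A) on [-10, 10].
    """
    y = np.asarray(y, dtype=float).ravel()
    Kmat = K.matrix if isinstance(K, GRM) else np.asarray(K, dtype=float)
    n = len(y)
    if Kmat.shape != (n, n):
        raise ModelError(f"K is {Kmat.shape}, y has length {n}")
    if not np.isfinite(y).all():
        raise ModelError("y contains non-finite values")
    if np.ptp(y) == 0:
        raise ModelError("constant phenotype vector; variance ratio undefined")

    theta, eta = _project_and_rotate(y, Kmat)
    # normalize to realized scale: tr(PKP)/(n-1) = 1, so the optimized
    # ratio is V_e/V_A directly and the log bounds are scale-free
    scale = float(np.sum(theta)) / (n - 1)
    if scale <= 0:
        raise ModelError("K has no variance after intercept projection")
    vg_norm, ve, delta, ll = _spectral_reml(theta / scale, eta)
    v_a = vg_norm  # realized-scale additive variance
    h2 = v_a / (v_a + ve) if (v_a + ve) > 0 else 0.0
    return VarComp(V_A=v_a, V_e=ve, lambda_=delta, h2=h2, logREML=ll,
                   sigma2_K=vg_norm / scale)


def _project_and_rotate(y: np.ndarray, Kmat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Project out the intercept, eigendecompose the projected K, and
    rotate y into the eigenbasis, dropping the null direction."""
    n = len(y)
    # error contrasts: orthonormal basis of the complement of the
    # intercept (Helmert rows), so the intercept is removed exactly even
    # when K is rank-deficient
    H = _helmert(n)
    B = H @ Kmat @ H.T
    theta, V = np.linalg.eigh(B)
    if theta.min() < -1e-6 * max(1.0, abs(theta.max())):
        raise ModelError(
            f"K is not positive semi-definite (min projected eig {theta.min():.3g})"
        )
    theta = np.clip(theta, 0.0, None)
    eta = V.T @ (H @ y)
    return theta, eta


def _helmert(n: int) -> np.ndarray:
    """(n-1) x n orthonormal contrast matrix with rows orthogonal to 1."""
    H = np.zeros((n - 1, n))
    for i in range(1, n):
        H[i - 1, :i] = 1.0
        H[i - 1, i] = -i
        H[i - 1] /= np.sqrt(i * (i + 1))
    return H


def reml_grid_loglik(y: np.ndarray, K: GRM | np.ndarray, log_delta: np.ndarray) -> np.ndarray:
    """Profiled restricted log-likelihood on a grid of log variance
    ratios log(V_e/V_A), on the same realized K scale :func:`reml`
    optimizes over (for diagnostics and cross-checks)."""
    y = np.asarray(y, dtype=float).ravel()
    Kmat = K.matrix if isinstance(K, GRM) else np.asarray(K, dtype=float)
    theta, eta = _project_and_rotate(y, Kmat)
    theta = theta / (float(np.sum(theta)) / (len(y) - 1))
    q = len(eta)
    eta2 = eta**2
    out = np.empty(len(log_delta))
    for i, ld in enumerate(np.asarray(log_delta, dtype=float)):
        delta = np.exp(ld)
        denom = theta + delta
        vg = np.mean(eta2 / denom)
        out[i] = -0.5 * (q * np.log(vg) + np.sum(np.log(denom)) + q)
    return out


# ---------------------------------------------------------------------------
# Ridge-regression BLUP
# ---------------------------------------------------------------------------

@dataclass
class RRFit:
    """Fitted ridge mixed model: intercept, per-marker effects, and the
    ridge parameter lambda = sigma_e^2 / sigma_u^2 actually used."""

    mu: float
    u: np.ndarray
    lambda_: float
    marker_ids: np.ndarray
    varcomp: VarComp | None = None


def fit_rrblup(
    y: np.ndarray,
    Z: np.ndarray,
    lambda_: float | None = None,
    marker_ids: np.ndarray | None = None,
) -> RRFit:
    """Fit marker effects by ridge regression (RR-BLUP).

    ``Z`` must be the column-centered training dosage matrix.  When
    ``lambda_`` is None it is set by REML on the marker covariance
    K = Z Z' / c, mapped back to the marker scale through c; the REML fit
    is kept on the result.  The solution solves

        (Z'Z + lambda I) u = Z'(y - mu 1)

    with mu the generalized-least-squares intercept (equal to mean(y)
    for exactly column-centered Z).
    """
    y = np.asarray(y, dtype=float).ravel()
    Z = np.asarray(Z, dtype=float)
    n, m = Z.shape
    if m == 0:
        raise ModelError("no markers to fit")
    if len(y) != n:
        raise ModelError(f"y has length {len(y)} but Z has {n} rows")
    if not np.isfinite(y).all():
        raise ModelError("y contains non-finite values")

    varcomp = None
    if lambda_ is None:
        # REML on the marker covariance K = ZZ': sigma2_K is the
        # marker-effect variance sigma_u^2, so the ridge parameter is
        # V_e / sigma2_K.
        vc = reml(y, Z @ Z.T)
        lambda_ = vc.V_e / vc.sigma2_K
        varcomp = vc
    if lambda_ <= 0:
        raise ModelError("lambda must be positive")

    # GLS intercept: with V = ZZ' + lambda I, mu = (1'V^-1 1)^-1 1'V^-1 y.
    # For column-centered Z, 1 is an eigenvector of V and mu = mean(y);
    # compute the general form to stay correct for nearly centered input.
    if n <= m:
        V = Z @ Z.T + lambda_ * np.eye(n)
        Vinv_1 = np.linalg.solve(V, np.ones(n))
        mu = float(Vinv_1 @ y / Vinv_1.sum())
        # u = Z' V^-1 (y - mu)
        u = Z.T @ np.linalg.solve(V, y - mu)
    else:
        # solve in marker space: (Z'Z + lambda I) u = Z'(y - mu)
        ZtZ = Z.T @ Z + lambda_ * np.eye(m)
        mu = float(np.mean(y))
        u = np.linalg.solve(ZtZ, Z.T @ (y - mu))

    if marker_ids is None:
        marker_ids = np.arange(m)
    return RRFit(mu=mu, u=u, lambda_=float(lambda_),
                 marker_ids=np.asarray(marker_ids), varcomp=varcomp)


def predict_gebv(fit: RRFit, Z_new: np.ndarray,
                 marker_ids: np.ndarray | None = None) -> np.ndarray:
    """Genomic estimated breeding values mu + Z_new u.

    ``Z_new`` must be centered with the training set's allele frequencies
    and carry the same markers in the same order; pass ``marker_ids`` to
    have this checked.
    """
    Z_new = np.asarray(Z_new, dtype=float)
    if Z_new.shape[1] != len(fit.u):
        raise ModelError(
            f"Z_new has {Z_new.shape[1]} markers, fit has {len(fit.u)}"
        )
    if marker_ids is not None:
        mismatch = np.asarray(marker_ids) != np.asarray(fit.marker_ids)
        if mismatch.any():
            bad = list(np.asarray(marker_ids)[mismatch][:5])
            raise ModelError(f"marker mismatch with training fit: {bad}")
    return fit.mu + Z_new @ fit.u


def gblup_breeding_values(y: np.ndarray, K: GRM | np.ndarray,
                          varcomp: VarComp | None = None) -> np.ndarray:
    """BLUP of genetic values g from the GRM parameterization:
    g_hat = V_A K (V_A K + V_e I)^-1 (y - mu).  Used as the dual route
    cross-checking RR-BLUP fitted genetic values."""
    y = np.asarray(y, dtype=float).ravel()
    Kmat = K.matrix if isinstance(K, GRM) else np.asarray(K, dtype=float)
    if varcomp is None:
        varcomp = reml(y, Kmat)
    n = len(y)
    V = varcomp.sigma2_K * Kmat + varcomp.V_e * np.eye(n)
    Vinv_1 = np.linalg.solve(V, np.ones(n))
    mu = float(Vinv_1 @ y / Vinv_1.sum())
    return varcomp.sigma2_K * (Kmat @ np.linalg.solve(V, y - mu))


def accuracy(pred: np.ndarray, ref: np.ndarray) -> float:
    """Prediction accuracy: Pearson correlation between predicted and
    reference values.  Returns NaN when either side has zero variance."""
    pred = np.asarray(pred, dtype=float).ravel()
    ref = np.asarray(ref, dtype=float).ravel()
    if len(pred) != len(ref):
        raise ModelError("pred and ref must have equal length")
    if len(pred) < 3:
        raise ModelError("need at least 3 pairs for a correlation")
    if np.std(pred) == 0 or np.std(ref) == 0:
        return float("nan")
    return float(stats.pearsonr(pred, ref)[0])
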