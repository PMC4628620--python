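"""Maximum-likelihood polygenic variance-component estimation.

Model: ``y = X beta + g + e`` with ``g ~ N(0, 2*Phi*sigma2_g)`` and
``e ~ N(0, I*sigma2_e)``, so ``V = 2*Phi*sigma2_g + I*sigma2_e``.  Narrow-
sense heritability is ``h2 = sigma2_g / (sigma2_g + sigma2_e)``.

The fit uses a one-time symmetric eigendecomposition of ``A = 2*Phi``:
rotating y and X into the eigenbasis diagonalizes V with eigenvalues
``lambda_i = h2*d_i + (1 - h2)`` (up to the total-variance scale), after
which beta and the total variance profile out analytically and only the
ratio h2 in [0, 1] is optimized by bounded scalar search.

For model comparison across fixed-effect sets, fits also carry
``h2_total = sigma2_g / (sigma2_g + sigma2_e + var_fixed)`` — heritability
expressed against the total phenotypic variance including the variance
captured by non-intercept fixed effects (e.g. SNP dosages).  With an
intercept-only design the two coincide; ``h2_total`` is the quantity whose
differences across nested SNP models measure "heritability explained".
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy import linalg, optimize, stats

from .pedigree import KinshipResult

__all__ = [
    "KinshipEigen",
    "VCFit",
    "IdentifiabilityError",
    "OptimizerError",
    "fit_polygenic",
    "h2_standard_error",
    "lrt_h2_zero",
    "lrt_nested",
]

_BOUNDARY_TOL = 1e-4


class IdentifiabilityError(ValueError):
    """sigma2_g and sigma2_e cannot be separated (relatedness ~ identity)."""


class OptimizerError(RuntimeError):
    """The likelihood optimizer produced an inconsistent result."""


@dataclass(frozen=True)
class KinshipEigen:
    """Eigendecomposition of the additive relationship matrix A = 2*Phi.

    Computed once per cohort and reused across traits/replicates/models.
    """

    ids: tuple[str, ...]
    d: np.ndarray  # eigenvalues of A, ascending
    U: np.ndarray  # orthonormal eigenvectors, columns

    @classmethod
    def from_kinship(cls, kin: "KinshipResult | np.ndarray", ids: Sequence[str] | None = None) -> "KinshipEigen":
        if isinstance(kin, KinshipResult):
            phi, ids = kin.phi, kin.ids
        else:
            phi = np.asarray(kin, dtype=float)
            ids = tuple(ids) if ids is not None else tuple(map(str, range(len(phi))))
        A = 2.0 * phi
        d, U = np.linalg.eigh(A)
        if d.min() < -1e-8 * max(1.0, d.max()):
            raise ValueError(
                f"2*Phi is not positive semidefinite (min eigenvalue {d.min():.3g})"
            )
        d = np.clip(d, 0.0, None)
        if np.ptp(d) < 1e-8:
            raise IdentifiabilityError(
                "relatedness matrix is a multiple of the identity; "
                "sigma2_g and sigma2_e are not separately identifiable"
            )
        return cls(tuple(ids), d, U)

    def subset(self, keep_ids: Sequence[str], phi: np.ndarray) -> "KinshipEigen":
        """Re-decompose on a subset of individuals (phi is the full matrix)."""
        idx = {iid: k for k, iid in enumerate(self.ids)}
        sel = np.array([idx[i] for i in keep_ids])
        return KinshipEigen.from_kinship(phi[np.ix_(sel, sel)], keep_ids)


@dataclass
class VCFit:
    """A fitted polygenic model."""

    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    loglik: float
    h2: float
    h2_se: float  # NaN when h2 is at a boundary
    converged: bool
    n: int
    var_fixed: float  # sample variance of the non-intercept fixed-effect predictor
    h2_total: float  # sigma2_g / (sigma2_g + sigma2_e + var_fixed)
    method: str = "ML"
    ids: tuple[str, ...] = field(default_factory=tuple)
    n_fixed: int = 1

    def to_json(self, **kwargs) -> str:
        d = asdict(self)
        d["beta"] = list(map(float, np.atleast_1d(self.beta)))
        d["ids"] = list(self.ids)
        return json.dumps(d, **kwargs)


def _design(X: np.ndarray | None, n: int) -> np.ndarray:
    if X is None:
        return np.ones((n, 1))
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != n:
        X = X.T
    # ensure an intercept column is present (a constant *nonzero* column)
    constant = np.ptp(X, axis=0) == 0
    if not np.any(constant & (X[0] != 0)):
        X = np.column_stack([np.ones(n), X])
    return X


def _profile(h2: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray, reml: bool):
    """Profile log-likelihood at a fixed heritability ratio.

    Returns (loglik, beta, sigma2_p) with sigma2_p the total variance scale:
    V = sigma2_p * diag(h2*d + 1 - h2).
    """
    n, p = Xt.shape
    lam = h2 * d + (1.0 - h2)
    if lam.min() <= 0:
        return -np.inf, np.zeros(p), np.nan
    w = 1.0 / np.sqrt(lam)
    Xw = Xt * w[:, None]
    yw = yt * w
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    rss = float(resid @ resid)
    logdet = float(np.sum(np.log(lam)))
    if reml:
        dof = n - p
        s2 = rss / dof
        _, rlogdet = np.linalg.slogdet(Xw.T @ Xw)
        ll = -0.5 * (dof * np.log(2 * np.pi * s2) + dof + logdet + rlogdet)
    else:
        s2 = rss / n
        ll = -0.5 * (n * np.log(2 * np.pi * s2) + n + logdet)
    return ll, beta, s2


def fit_polygenic(
    y: np.ndarray,
    X: np.ndarray | None,
    kin: "KinshipResult | KinshipEigen | np.ndarray",
    reml: bool = False,
    fix_h2: float | None = None,
    xatol: float = 1e-8,
    compute_se: bool = True,
    ids: Sequence[str] | None = None,
) -> VCFit:
    """Fit the polygenic model by maximum likelihood.

    Parameters
    ----------
    y, X
        Trait vector and fixed-effect design (an intercept is added if
        absent; ``X=None`` means intercept only), index-aligned with ``kin``.
    kin
        A :class:`KinshipResult`, a precomputed :class:`KinshipEigen`, or a
        raw kinship matrix Phi.
    reml
        Use residual (restricted) ML instead of ML.
    fix_h2
        Evaluate at a fixed heritability ratio instead of optimizing
        (``fix_h2=0`` gives the no-polygenic null model).
    """
    eig = kin if isinstance(kin, KinshipEigen) else KinshipEigen.from_kinship(kin, ids)
    y = np.asarray(y, dtype=float).ravel()
    n = y.size
    if n != len(eig.ids):
        raise ValueError(f"y has {n} entries but kinship has {len(eig.ids)}")
    X_full = _design(X, n)
    # reduce to a full-column-rank basis (degenerate columns, e.g. all-zero
    # dosages, would break the REML determinant and inflate the LRT df)
    rank = np.linalg.matrix_rank(X_full)
    if rank < X_full.shape[1]:
        _, _, piv = linalg.qr(X_full, mode="economic", pivoting=True)
        keep = np.sort(piv[:rank])
    else:
        keep = np.arange(X_full.shape[1])
    X = X_full[:, keep]
    p = X.shape[1]
    if n <= p + 2:
        raise ValueError("need n > number of fixed effects + 2")
    yt = eig.U.T @ y
    Xt = eig.U.T @ X

    if fix_h2 is not None:
        h2_hat = float(fix_h2)
        ll, beta, s2 = _profile(h2_hat, eig.d, yt, Xt, reml)
        converged = True
    else:
        res = optimize.minimize_scalar(
            lambda h: -_profile(h, eig.d, yt, Xt, reml)[0],
            bounds=(0.0, 1.0),
            method="bounded",
            options={"xatol": xatol},
        )
        candidates = [float(res.x), 0.0, 1.0 - 1e-12]
        lls = [_profile(h, eig.d, yt, Xt, reml)[0] for h in candidates]
        best = int(np.argmax(lls))
        h2_hat = candidates[best]
        ll, beta, s2 = _profile(h2_hat, eig.d, yt, Xt, reml)
        converged = bool(res.success) and np.isfinite(ll)
        if not converged:
            warnings.warn(f"polygenic fit did not converge: {res.message}")
    if h2_hat > 1.0 - 1e-9:
        h2_hat = 1.0
    sigma2_g = h2_hat * s2
    sigma2_e = (1.0 - h2_hat) * s2

    # variance captured by non-intercept fixed effects, on the data scale
    # (GLS coefficients are invariant under the orthonormal rotation).
    # E[var(X beta_hat)] exceeds var(X beta) by tr(Xc'Xc Cov(beta_hat))/n;
    # subtract that estimation-noise term so null covariates report ~0.
    if p > 1:
        fitted = X @ beta
        Xc = X - X.mean(axis=0)
        lam_hat = h2_hat * eig.d + (1.0 - h2_hat)
        Xw = Xt / np.sqrt(np.clip(lam_hat, 1e-12, None))[:, None]
        try:
            cov_beta = s2 * np.linalg.inv(Xw.T @ Xw)
            noise = float(np.trace((Xc.T @ Xc) @ cov_beta)) / n
        except np.linalg.LinAlgError:
            noise = 0.0
        var_fixed = max(float(np.var(fitted)) - noise, 0.0)
    else:
        var_fixed = 0.0
    denom = sigma2_g + sigma2_e + var_fixed
    h2_total = sigma2_g / denom if denom > 0 else np.nan

    beta_full = np.zeros(X_full.shape[1])
    beta_full[keep] = np.asarray(beta)
    fit = VCFit(
        sigma2_g=float(sigma2_g),
        sigma2_e=float(sigma2_e),
        beta=beta_full,
        loglik=float(ll),
        h2=float(h2_hat),
        h2_se=np.nan,
        converged=converged,
        n=n,
        var_fixed=var_fixed,
        h2_total=float(h2_total),
        method="REML" if reml else "ML",
        ids=eig.ids,
        n_fixed=p,
    )
    if compute_se and fix_h2 is None:
        fit.h2_se = h2_standard_error(fit, y, X, eig)
    return fit


def _loglik_sigmas(s2g: float, s2e: float, d: np.ndarray, yt: np.ndarray, Xt: np.ndarray) -> float:
    """ML log-likelihood at explicit (sigma2_g, sigma2_e), beta profiled."""
    lam = s2g * d + s2e
    if lam.min() <= 0:
        return -np.inf
    w = 1.0 / np.sqrt(lam)
    Xw = Xt * w[:, None]
    yw = yt * w
    beta, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    resid = yw - Xw @ beta
    n = yt.size
    return -0.5 * (n * np.log(2 * np.pi) + float(np.sum(np.log(lam))) + float(resid @ resid))


def h2_standard_error(
    fit: VCFit,
    y: np.ndarray,
    X: np.ndarray | None,
    kin: "KinshipResult | KinshipEigen | np.ndarray",
) -> float:
    """Delta-method SE of h2 from the numerically differentiated observed
    information of (sigma2_g, sigma2_e); central differences with step
    1e-5 x parameter scale.  NaN (with a warning) at a boundary estimate."""
    if fit.h2 < _BOUNDARY_TOL or fit.h2 > 1.0 - _BOUNDARY_TOL:
        warnings.warn("h2 estimate at a boundary; standard error undefined")
        return float("nan")
    eig = kin if isinstance(kin, KinshipEigen) else KinshipEigen.from_kinship(kin)
    y = np.asarray(y, dtype=float).ravel()
    X = _design(X, y.size)
    yt, Xt = eig.U.T @ y, eig.U.T @ X
    theta = np.array([fit.sigma2_g, fit.sigma2_e])
    scale = np.maximum(np.abs(theta), 1e-3 * (fit.sigma2_g + fit.sigma2_e))
    h = 1e-5 * scale
    H = np.empty((2, 2))

    def ll(t):
        return _loglik_sigmas(t[0], t[1], eig.d, yt, Xt)

    for i in range(2):
        for j in range(2):
            tpp = theta.copy(); tpp[i] += h[i]; tpp[j] += h[j]
            tpm = theta.copy(); tpm[i] += h[i]; tpm[j] -= h[j]
            tmp = theta.copy(); tmp[i] -= h[i]; tmp[j] += h[j]
            tmm = theta.copy(); tmm[i] -= h[i]; tmm[j] -= h[j]
            H[i, j] = (ll(tpp) - ll(tpm) - ll(tmp) + ll(tmm)) / (4 * h[i] * h[j])
    info = -H
    try:
        cov = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        warnings.warn("observed information is singular; SE undefined")
        return float("nan")
    s = fit.sigma2_g + fit.sigma2_e
    grad = np.array([fit.sigma2_e, -fit.sigma2_g]) / s**2
    var = float(grad @ cov @ grad)
    if var < 0:
        warnings.warn("negative delta-method variance; SE undefined")
        return float("nan")
    return float(np.sqrt(var))


def lrt_h2_zero(fit: VCFit, null_loglik: float) -> float:
    """Boundary likelihood-ratio test of h2 = 0.

    The null (sigma2_g = 0) lies on the parameter boundary, so the LRT
    statistic is asymptotically a 50:50 mixture of a point mass at zero and
    chi-square(1); ``p = 0.5 * P(chi2_1 > Lambda)``.
    """
    lam = 2.0 * (fit.loglik - null_loglik)
    if lam < -1e-6:
        raise OptimizerError(
            f"full-model log-likelihood below null by {-lam / 2:.3g}; optimizer failure"
        )
    lam = max(lam, 0.0)
    return 0.5 * float(stats.chi2.sf(lam, df=1))


def lrt_nested(fit_full: VCFit, fit_reduced: VCFit, df: int) -> float:
    """Likelihood-ratio test of nested fixed-effect sets (chi-square df)."""
    if fit_full.n != fit_reduced.n or (
        fit_full.ids and fit_reduced.ids and fit_full.ids != fit_reduced.ids
    ):
        raise ValueError("fits use different individual sets; refusing to compare")
    lam = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if lam < -1e-6:
        raise OptimizerError("full model log-likelihood below reduced model")
    return float(stats.chi2.sf(max(lam, 0.0), df=df))
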