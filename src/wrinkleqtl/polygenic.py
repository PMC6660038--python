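"""Genomic relationship matrix and polygenic variance-component fitting.

The model is the standard single-component animal model

    y = X beta + g + e,   g ~ N(0, K * VA),   e ~ N(0, I * VR)

with K the standardized GRM.  Heritability h2 = VA / (VA + VR) is estimated
by maximum likelihood (the GenABEL `polygenic` convention); REML is available
behind a flag.  The likelihood is profiled on the eigenbasis of K: for a
given h2 the GLS fixed effects and the total variance have closed forms, so
the optimization is a 1-D search over h2 in [0, 0.999].
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .genio import GenotypeMatrix

log = logging.getLogger(__name__)

H2_UPPER = 0.999  # keeps Sigma invertible

__all__ = ["Kinship", "PolygenicFit", "compute_grm", "polygenic_loglik", "fit_polygenic"]


@dataclass
class Kinship:
    matrix: np.ndarray
    method: str
    n_snps_used: int

    def write(self, path, ids) -> None:
        pd.DataFrame(self.matrix, index=ids, columns=ids).to_csv(path, sep="\t")

    @staticmethod
    def read(path) -> "Kinship":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return Kinship(df.to_numpy(), "loaded", -1)


def compute_grm(
    g: GenotypeMatrix, skip_monomorphic: bool = False, missing: str = "mean"
) -> Kinship:
    """Standardized (VanRaden-2 style) GRM: K = Z Z'/m with
    z = (g - 2p)/sqrt(2p(1-p)).

    Missing dosages are mean-substituted (zero after centering) by default;
    ``missing="pairwise"`` divides each entry by the number of SNPs observed
    in both individuals instead.  Monomorphic SNPs are an error unless
    ``skip_monomorphic`` (QC should have removed them).
    """
    if g.m < 2:
        raise ValueError("need at least 2 SNPs for a GRM")
    d = g.dosage_float()
    p = np.nanmean(d, axis=0) / 2.0
    mono = (p <= 0.0) | (p >= 1.0) | np.isnan(p)
    if mono.any():
        if not skip_monomorphic:
            raise ValueError(
                f"{mono.sum()} monomorphic SNPs reached the GRM; run QC first"
            )
        d = d[:, ~mono]
        p = p[~mono]
    z = (d - 2 * p) / np.sqrt(2 * p * (1 - p))
    obs = ~np.isnan(z)
    z = np.where(obs, z, 0.0)
    m = z.shape[1]
    if missing == "mean":
        K = z @ z.T / m
    elif missing == "pairwise":
        counts = obs.astype(float) @ obs.astype(float).T
        K = z @ z.T / np.maximum(counts, 1.0)
    else:
        raise ValueError(f"unknown missing policy {missing!r}")
    K = (K + K.T) / 2.0
    return Kinship(K, f"standardized/{missing}", m)


@dataclass
class PolygenicFit:
    """Fitted variance components with the reusable covariance factor.

    ``eigvecs``/``eigvals`` diagonalize K, so Sigma^-1 =
    U diag(1/(VA*lam + VR)) U' can be applied without refactorizing; the
    association scan reuses it.
    """

    VA: float
    VR: float
    h2: float
    beta: np.ndarray
    loglik: float
    eigvecs: np.ndarray
    eigvals: np.ndarray
    covariates: np.ndarray
    reml: bool = False

    @property
    def mu(self) -> float:
        return float(self.beta[0])

    def sigma_inv_matmul(self, M: np.ndarray) -> np.ndarray:
        """Compute Sigma^-1 @ M."""
        d = self.VA * self.eigvals + self.VR
        Mt = self.eigvecs.T @ M
        return self.eigvecs @ (Mt / d[:, None] if M.ndim == 2 else Mt / d)

    def summary(self) -> dict:
        return {
            "VA": self.VA,
            "VR": self.VR,
            "h2": self.h2,
            "loglik": self.loglik,
            "beta": list(np.asarray(self.beta, dtype=float)),
            "reml": self.reml,
        }

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.summary(), fh, indent=2)


def _design(covariates, n) -> np.ndarray:
    """Covariate matrix with a leading intercept column."""
    if covariates is None:
        return np.ones((n, 1))
    X = np.asarray(covariates, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if not np.allclose(X[:, 0], 1.0):
        X = np.column_stack([np.ones(len(X)), X])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("singular covariate design")
    return X


def _gls_on_eigenbasis(yt, Xt, d):
    """Weighted LS of rotated y on rotated X with per-row variances d."""
    w = 1.0 / d
    XtW = Xt * w[:, None]
    beta = np.linalg.solve(XtW.T @ Xt, XtW.T @ yt)
    r = yt - Xt @ beta
    return beta, r, w


def polygenic_loglik(y, covariates, K, VA: float, VR: float) -> float:
    """Gaussian log-likelihood of the polygenic model at fixed (VA, VR).

    -1/2 [ log|Sigma| + (y - X beta_hat)' Sigma^-1 (y - X beta_hat)
           + n log(2 pi) ]   with beta_hat the GLS solution.
    """
    if VR <= 0:
        raise ValueError("VR must be positive")
    y = np.asarray(y, dtype=float)
    n = len(y)
    X = _design(covariates, n)
    Kmat = K.matrix if isinstance(K, Kinship) else np.asarray(K)
    lam, U = np.linalg.eigh(Kmat)
    d = VA * np.clip(lam, 0.0, None) + VR
    yt = U.T @ y
    Xt = U.T @ X
    _, r, w = _gls_on_eigenbasis(yt, Xt, d)
    quad = float(np.sum(r * r * w))
    logdet = float(np.sum(np.log(d)))
    return -0.5 * (logdet + quad + n * np.log(2 * np.pi))


def fit_polygenic(y, covariates, K, reml: bool = False, tol: float = 1e-6) -> PolygenicFit:
    """Maximize the polygenic likelihood by profiling over h2 in [0, 0.999].

    For each h2 the per-eigenvalue variances are d_i = h2*lam_i + (1-h2);
    the scale sigma^2 and the fixed effects are solved analytically, leaving
    a 1-D concave-ish profile maximized by Brent within the best bracket of
    a coarse grid.
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite phenotype values")
    n = len(y)
    X = _design(covariates, n)
    p = X.shape[1]
    Kmat = K.matrix if isinstance(K, Kinship) else np.asarray(K)
    lam, U = np.linalg.eigh(Kmat)
    lam = np.clip(lam, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X
    dof = n - p if reml else n

    def negll(h2: float) -> float:
        d = h2 * lam + (1.0 - h2)
        beta, r, w = _gls_on_eigenbasis(yt, Xt, d)
        rss = float(np.sum(r * r * w))
        sigma2 = rss / dof
        ll = -0.5 * (dof * np.log(2 * np.pi * sigma2) + np.sum(np.log(d)) + dof)
        if reml:
            XtW = Xt * w[:, None]
            sign, logdet_x = np.linalg.slogdet(XtW.T @ Xt)
            ll -= 0.5 * logdet_x
        return -ll

    grid = np.linspace(0.0, H2_UPPER, 41)
    vals = np.array([negll(h) for h in grid])
    j = int(np.argmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": tol})
    h2 = float(res.x) if res.fun <= vals[j] else float(grid[j])

    d = h2 * lam + (1.0 - h2)
    beta, r, w = _gls_on_eigenbasis(yt, Xt, d)
    sigma2 = float(np.sum(r * r * w)) / dof
    VA = h2 * sigma2
    VR = (1.0 - h2) * sigma2
    ll = -negll(h2)
    fit = PolygenicFit(
        VA=VA, VR=VR, h2=h2, beta=beta, loglik=float(ll),
        eigvecs=U, eigvals=lam, covariates=X, reml=reml,
    )
    log.info("polygenic fit: h2=%.4f VA=%.4g VR=%.4g logL=%.3f", h2, VA, VR, ll)
    return fit
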