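"""Post-discovery characterization of modifiable-POE CpGs.

Covers the downstream stages that relate discovered CpGs to molecular and
health phenotypes: rank enrichment of interaction p-values (hotspot tests),
kinship-adjusted methylation residuals, protein / phenome-wide association
scans with Bonferroni correction, DerSimonian-Laird random-effects
meta-analysis across discovery and replication strata, and the single-cell
correlation utilities (global-scaling log-normalization, Spearman correlation
restricted to doubly-expressing cells).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .errors import ConfigurationError, DataError

SMOKING_VARIABLES = ("smoking", "pack_years", "smoking_status")


@dataclass
class MetaResult:
    """Random-effects meta-analysis of per-stratum estimates."""

    estimates: np.ndarray
    ses: np.ndarray
    Q: float
    tau2: float
    pooled: float
    pooled_se: float
    ci95: tuple[float, float]
    p: float
    notes: list


@dataclass
class AssociationRecord:
    """One CpG x variable association from a downstream scan."""

    cpg: str
    variable: str
    beta: float
    se: float
    t: float
    p: float
    n: int
    adjusted_p: float


def rank_enrichment_test(
    all_trio_p: np.ndarray, group_mask: np.ndarray
) -> tuple[float, float]:
    """Mann-Whitney U test that a group of trios ranks more significant.

    Compares -log10(p) of the masked group against the rest with the
    one-sided alternative "group ranks higher" (smaller p-values).  Exact
    enumeration is used when n1*n2 <= 400 and the data are tie-free;
    otherwise the tie-corrected normal approximation.  Returns (U, p).
    """
    p_all = np.asarray(all_trio_p, dtype=float)
    mask = np.asarray(group_mask, dtype=bool)
    if mask.all() or not mask.any():
        raise DataError("both groups must be non-empty")
    x = -np.log10(p_all[mask])
    y = -np.log10(p_all[~mask])
    n1, n2 = len(x), len(y)
    has_ties = len(np.unique(np.concatenate([x, y]))) < n1 + n2
    method = "exact" if (n1 * n2 <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="greater", method=method)
    return float(res.statistic), float(res.pvalue)


def _reml_neg_loglik(log_delta: float, lam: np.ndarray, yr: np.ndarray,
                     xr: np.ndarray) -> float:
    """Negative restricted log-likelihood in the eigenbasis of K.

    Model y = X b + g + e, g ~ N(0, s2g K), e ~ N(0, s2e I); delta = s2e/s2g.
    After rotation by K's eigenvectors the covariance is diagonal with
    weights lam + delta (up to s2g).
    """
    delta = np.exp(log_delta)
    d = lam + delta
    n, k = len(yr), xr.shape[1]
    xtdx = xr.T @ (xr / d[:, None])
    xtdy = xr.T @ (yr / d)
    beta = np.linalg.solve(xtdx, xtdy)
    r = yr - xr @ beta
    s2 = float(r @ (r / d)) / (n - k)
    _, ld_xtdx = np.linalg.slogdet(xtdx)
    return 0.5 * (
        (n - k) * np.log(s2) + np.sum(np.log(d)) + ld_xtdx + (n - k)
    )


def lmm_adjust(
    methylation: np.ndarray, relationship: np.ndarray
) -> np.ndarray:
    """Methylation residuals after removing kinship-structured variation.

    Fits the single-variance-component mixed model ``y = mu + g + e`` with
    ``g ~ N(0, s2g K)`` by REML through the spectral decomposition of the
    relationship matrix K, then subtracts the fixed mean and the BLUP of g.
    With K proportional to the identity the two components are jointly
    unidentifiable; the mean-centered y is returned with a warning.
    """
    y = np.asarray(methylation, dtype=float)
    K = np.asarray(relationship, dtype=float)
    n = len(y)
    if K.shape != (n, n):
        raise DataError("relationship matrix dimension does not match data")
    if not np.allclose(K, K.T, atol=1e-10):
        raise DataError("relationship matrix must be symmetric")
    lam, U = linalg.eigh(K)
    if lam.min() < -1e-8:
        raise DataError(f"relationship matrix is not PSD (min eigenvalue {lam.min():.3g})")
    lam = np.maximum(lam, 0.0)
    if np.ptp(lam) < 1e-10 * max(lam.max(), 1.0):
        warnings.warn(
            "relationship matrix proportional to identity: genetic and "
            "residual variances are jointly unidentifiable; returning "
            "mean-centered values", stacklevel=2,
        )
        return y - y.mean()

    yr = U.T @ y
    xr = U.T @ np.ones((n, 1))
    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(-12.0, 12.0), args=(lam, yr, xr),
        method="bounded", options={"xatol": 1e-8},
    )
    delta = np.exp(res.x)
    d = lam + delta
    xtdx = xr.T @ (xr / d[:, None])
    beta = np.linalg.solve(xtdx, xr.T @ (yr / d))
    mu = float(beta[0])
    r = yr - xr[:, 0] * mu
    # BLUP in the rotated basis: ghat_r = lam / (lam + delta) * r
    ghat = U @ ((lam / d) * r)
    return y - mu - ghat


def association_scan(
    methylation: pd.DataFrame,
    variables: pd.DataFrame,
    covariates: pd.DataFrame,
    model: str = "phenome",
    smoking_variables: Sequence[str] = SMOKING_VARIABLES,
) -> tuple[pd.DataFrame, int]:
    """Per-CpG x per-variable OLS association scan with Bonferroni correction.

    For the ``protein`` model each variable is a plasma protein regressed
    together with the supplied covariates; for the ``phenome`` model each
    variable is a phenotype.  Smoking-type covariates are dropped from the
    design when the tested variable is itself one of them.  The Bonferroni
    denominator is the full planned family, m = n_cpgs x n_variables,
    regardless of skipped (zero-variance) variables.

    Returns ``(records, m)`` where ``records`` has one row per tested pair.
    """
    if model not in ("protein", "phenome"):
        raise ConfigurationError(f"unknown association model {model!r}")
    m = methylation.shape[1] * variables.shape[1]
    records = []
    cov_np = covariates
    for var in variables.columns:
        v = variables[var].astype(float)
        cov = cov_np.drop(columns=[c for c in cov_np.columns
                                   if var in smoking_variables
                                   and c in smoking_variables])
        clash = [c for c in cov.columns
                 if np.allclose(cov[c].to_numpy(dtype=float), v.to_numpy())]
        if clash:
            raise DataError(
                f"variable {var!r} duplicates covariate column(s) {clash}"
            )
        for cpg in methylation.columns:
            y = methylation[cpg].astype(float)
            X = pd.concat([v.rename("_var"), cov], axis=1)
            X.insert(0, "const", 1.0)
            keep = np.isfinite(y.to_numpy()) & np.isfinite(
                X.to_numpy(dtype=float)
            ).all(axis=1)
            Xc, yc = X.loc[keep], y.loc[keep]
            if Xc["_var"].var(ddof=0) == 0:
                warnings.warn(f"variable {var!r} has zero variance; skipped",
                              stacklevel=2)
                break
            from .scan import _ols

            terms, _, _ = _ols(Xc.to_numpy(dtype=float), yc.to_numpy(),
                               list(Xc.columns))
            row = terms.loc["_var"]
            records.append(
                AssociationRecord(
                    cpg=cpg, variable=var,
                    beta=float(row["estimate"]), se=float(row["se"]),
                    t=float(row["t"]), p=float(row["p"]), n=int(len(yc)),
                    adjusted_p=min(1.0, float(row["p"]) * m),
                )
            )
    out = pd.DataFrame([r.__dict__ for r in records])
    return out, m


def dl_meta(estimates: Sequence[float], ses: Sequence[float]) -> MetaResult:
    """DerSimonian-Laird random-effects meta-analysis.

    Fixed-effect weights w = 1/se^2 give the heterogeneity statistic
    Q = sum w (est - fixed)^2; the moment estimator of the between-stratum
    variance is tau^2 = max(0, (Q - df) / C) with C = sum w - sum w^2 / sum
    w.  Random-effects weights 1/(se^2 + tau^2) yield the pooled estimate,
    its SE, the 95% Wald interval and a two-sided normal p-value.  A single
    stratum is passed through unchanged (tau^2 = 0, noted).
    """
    est = np.asarray(estimates, dtype=float)
    se = np.asarray(ses, dtype=float)
    if est.size < 1:
        raise DataError("need at least one stratum")
    if (se <= 0).any():
        raise DataError("standard errors must be positive")
    notes = []
    if est.size == 1:
        pooled, pooled_se, Q, tau2 = float(est[0]), float(se[0]), 0.0, 0.0
        notes.append("single stratum: pooled estimate equals the stratum")
    else:
        w = 1.0 / se**2
        fixed = float(np.sum(w * est) / np.sum(w))
        Q = float(np.sum(w * (est - fixed) ** 2))
        df = est.size - 1
        C = float(np.sum(w) - np.sum(w**2) / np.sum(w))
        tau2 = max(0.0, (Q - df) / C) if C > 0 else 0.0
        wr = 1.0 / (se**2 + tau2)
        pooled = float(np.sum(wr * est) / np.sum(wr))
        pooled_se = float(np.sqrt(1.0 / np.sum(wr)))
    z = pooled / pooled_se
    p = float(2 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * pooled_se
    return MetaResult(
        estimates=est, ses=se, Q=Q, tau2=tau2, pooled=pooled,
        pooled_se=pooled_se, ci95=(pooled - half, pooled + half), p=p,
        notes=notes,
    )


def lognormalize(counts: np.ndarray, scale: float = 10_000.0) -> np.ndarray:
    """Global-scaling log-normalization of one cell's feature counts.

    value = ln(1 + count / total_counts * scale), the standard single-cell
    'LogNormalize' transform.  An all-zero cell is an error.
    """
    c = np.asarray(counts, dtype=float)
    if (c < 0).any():
        raise DataError("counts must be non-negative")
    total = c.sum()
    if total <= 0:
        raise DataError("cell has zero total counts")
    return np.log1p(c / total * scale)


def spearman_filtered(
    x: np.ndarray, y: np.ndarray, filter: str = "none"
) -> tuple[float, float, int]:
    """Spearman correlation, optionally over doubly-positive pairs only.

    ``filter='both_positive'`` keeps pairs where both values exceed zero
    (e.g. normalized expression detected for both genes in a cell).  Returns
    (rho, p, n_retained); fewer than 4 retained pairs is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise DataError("x and y must have the same length")
    if filter == "both_positive":
        keep = (x > 0) & (y > 0)
    elif filter == "none":
        keep = np.isfinite(x) & np.isfinite(y)
    else:
        raise ConfigurationError(f"unknown filter {filter!r}")
    xk, yk = x[keep], y[keep]
    if len(xk) < 4:
        raise DataError(f"insufficient data: {len(xk)} pairs after filtering")
    rho, p = stats.spearmanr(xk, yk)
    return float(rho), float(p), int(len(xk))
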