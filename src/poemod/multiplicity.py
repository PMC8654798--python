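"""Permutation-based significance assessment and replication rules.

Two-tier multiple testing for the interaction scan:

1. a *global* permutation FDR across all mQTL-modifier-CpG trios, built from
   whole-scan permutation replicates (pooled null p-values by default, a
   min-p family-wise variant behind a switch); and
2. *trio-specific* permutation tests with a large number of draws for the
   trios surviving the global screen, Bonferroni-adjusted over the number of
   trios entering this stage.

The permutation scheme is Freedman-Lane: the reduced model (interaction
model minus the POE x Mod term) is fitted once, its residuals are permuted
and added back to the reduced fitted values, and the full model is refitted
on each permuted response.  This preserves the main-effect and covariate
structure while nulling only the tested interaction.

Replication of a discovered trio requires both FDR-significance in the
replication sample and direction-of-effect consistency for the main POE and
the POE x Mod interaction.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import permutations as _iter_permutations
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .errors import ConfigurationError, DataError
from .scan import TrioFitResult, TrioSpec, _check_rank, build_design
from .synthio import CohortDataset


@dataclass
class PermutationRecord:
    """Outcome of one trio-specific permutation test."""

    trio: TrioSpec
    observed_t: float
    n_perm: int
    n_as_extreme: int
    empirical_p: float
    adjusted_p: float
    method: str  # "global_fdr" or "trio_bonferroni"

    @property
    def resolution(self) -> float:
        """Smallest reportable p-value, 1 / (n_perm + 1)."""
        return 1.0 / (self.n_perm + 1)


def _interaction_t_machine(X: np.ndarray, names: Sequence[str], term: str):
    """Precompute the pieces needed to get one coefficient's t over many y.

    Returns a closure mapping a response matrix Y (n x B) to the t-statistics
    of ``term`` (length B), using the fixed design X.
    """
    _check_rank(X, names)
    j = list(names).index(term)
    n, p = X.shape
    xtx_inv = np.linalg.inv(X.T @ X)
    A = xtx_inv @ X.T  # (p, n): beta = A y
    ajj = xtx_inv[j, j]
    dof = n - p

    def tstats(Y: np.ndarray) -> np.ndarray:
        B = A @ Y                      # (p, B)
        resid = Y - X @ B
        sigma2 = np.einsum("ij,ij->j", resid, resid) / dof
        return B[j] / np.sqrt(sigma2 * ajj)

    return tstats


def freedman_lane_draws(
    X: pd.DataFrame,
    y: np.ndarray,
    term: str = "POE:Mod",
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    chunk: int = 512,
) -> np.ndarray:
    """Freedman-Lane null t-statistics for one term of an explicit design.

    The reduced model (``X`` minus ``term``) is fitted once; its residuals
    are permuted and added back to the reduced fitted values, and the full
    model's t-statistic for ``term`` is computed on each permuted response.
    With ``exhaustive=True`` all n! permutations are enumerated (n <= 8).
    """
    names = list(X.columns)
    Xn = X.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(y)

    reduced_cols = [c for c in names if c != term]
    Xr = X[reduced_cols].to_numpy(dtype=float)
    _check_rank(Xr, reduced_cols)
    beta_r, _, _, _ = linalg.lstsq(Xr, y, lapack_driver="gelsd")
    fitted_r = Xr @ beta_r
    resid_r = y - fitted_r

    tmachine = _interaction_t_machine(Xn, names, term)

    if exhaustive:
        if n > 8:
            raise ConfigurationError("exhaustive enumeration limited to n <= 8")
        perms = np.array(list(_iter_permutations(range(n))))
    else:
        rng = np.random.default_rng(seed)
        perms = np.array([rng.permutation(n) for _ in range(n_perm)])

    draws = np.empty(len(perms))
    for start in range(0, len(perms), chunk):
        block = perms[start:start + chunk]
        Ystar = (fitted_r[:, None] + resid_r[block].T)
        draws[start:start + len(block)] = tmachine(Ystar)
    return draws


def freedman_lane_null(
    trio: TrioSpec,
    data: CohortDataset,
    covariates: Optional[pd.DataFrame] = None,
    n_perm: int = 1000,
    seed: int = 0,
    exhaustive: bool = False,
    chunk: int = 512,
) -> np.ndarray:
    """Null draws of the POE x Mod t-statistic by Freedman-Lane permutation.

    Builds the trio's interaction design and delegates to
    :func:`freedman_lane_draws`.  Returns the array of null t-statistics.
    """
    if not exhaustive and n_perm < 100:
        raise ConfigurationError("n_perm must be at least 100")
    design = build_design(trio, data, covariates, with_interaction=True)
    return freedman_lane_draws(
        design.X, design.y.to_numpy(), term="POE:Mod", n_perm=n_perm,
        seed=seed, exhaustive=exhaustive, chunk=chunk,
    )


def empirical_p(observed_t: float, null_t: np.ndarray) -> tuple[float, int]:
    """Two-sided plus-one empirical p: (#{|t*| >= |t|} + 1) / (B + 1)."""
    n_extreme = int((np.abs(null_t) >= abs(observed_t)).sum())
    return (n_extreme + 1) / (len(null_t) + 1), n_extreme


def observed_interaction_t(
    trio: TrioSpec,
    data: CohortDataset,
    covariates: Optional[pd.DataFrame] = None,
) -> float:
    design = build_design(trio, data, covariates, with_interaction=True)
    tmachine = _interaction_t_machine(
        design.X.to_numpy(), list(design.X.columns), "POE:Mod"
    )
    return float(tmachine(design.y.to_numpy()[:, None])[0])


def trio_permutation_test(
    trio: TrioSpec,
    data: CohortDataset,
    covariates: Optional[pd.DataFrame] = None,
    n_perm: int = 100_000,
    n_trios_tested: int = 1,
    seed: int = 0,
    min_resolution: Optional[float] = None,
) -> PermutationRecord:
    """Trio-specific permutation test with Bonferroni adjustment.

    The adjusted p is ``min(1, empirical_p * n_trios_tested)`` where
    ``n_trios_tested`` is the number of trios entering the trio-specific
    stage.  A warning is raised when ``n_perm`` cannot resolve
    ``min_resolution``.
    """
    if min_resolution is not None and 1.0 / (n_perm + 1) > min_resolution:
        warnings.warn(
            f"n_perm={n_perm} cannot resolve p-values below "
            f"{1.0 / (n_perm + 1):.2e} (requested {min_resolution:.2e})",
            stacklevel=2,
        )
    t_obs = observed_interaction_t(trio, data, covariates)
    null = freedman_lane_null(trio, data, covariates, n_perm=n_perm, seed=seed)
    p_emp, n_extreme = empirical_p(t_obs, null)
    return PermutationRecord(
        trio=trio,
        observed_t=t_obs,
        n_perm=len(null),
        n_as_extreme=n_extreme,
        empirical_p=p_emp,
        adjusted_p=min(1.0, p_emp * n_trios_tested),
        method="trio_bonferroni",
    )


def global_permutation_fdr(
    observed_p: np.ndarray,
    null_p_matrix: np.ndarray,
    q: float = 0.05,
    method: str = "pooled",
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-based FDR across all scanned trios.

    ``null_p_matrix`` holds one row per whole-scan permutation replicate
    (shape B x m, m = number of trios).  With the default pooled method, the
    FDR at threshold p is the mean number of null p-values at or below p,
    divided by the number of observed p-values at or below p; estimates are
    monotonized to be nondecreasing in p.  ``method='minp'`` instead reports
    family-wise adjusted p-values: the fraction of permutations whose minimum
    p undercuts each observed p.

    Returns ``(selected_mask, per_trio_fdr)``.
    """
    observed_p = np.asarray(observed_p, dtype=float)
    null_p = np.asarray(null_p_matrix, dtype=float)
    if null_p.ndim != 2 or null_p.shape[0] < 1:
        raise DataError("need at least one complete permutation replicate")
    m = len(observed_p)

    if method == "minp":
        minp = null_p.min(axis=1)
        fdr = np.array([np.mean(minp <= p) for p in observed_p])
        return fdr <= q, fdr

    if method != "pooled":
        raise ConfigurationError(f"unknown global FDR method {method!r}")

    order = np.argsort(observed_p)
    sorted_p = observed_p[order]
    null_flat = np.sort(null_p.ravel())
    B = null_p.shape[0]
    # mean null count at or below each observed threshold
    null_counts = np.searchsorted(null_flat, sorted_p, side="right") / B
    obs_counts = np.searchsorted(sorted_p, sorted_p, side="right")
    raw = null_counts / obs_counts
    # enforce monotone nondecreasing FDR in p (running min from the right)
    fdr_sorted = np.minimum.accumulate(raw[::-1])[::-1]
    fdr_sorted = np.minimum(fdr_sorted, 1.0)
    fdr = np.empty(m)
    fdr[order] = fdr_sorted
    return fdr <= q, fdr


def adjust_pvalues(
    p: np.ndarray, method: str = "BH", m: Optional[int] = None
) -> np.ndarray:
    """Benjamini-Hochberg step-up or Bonferroni adjustment.

    ``m`` overrides the number of tests (defaults to ``len(p)``), e.g. when
    only a subset of a planned family was computable.
    """
    p = np.asarray(p, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise DataError("p-values must lie in [0, 1]")
    if m is None:
        m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    if method == "BH":
        order = np.argsort(p)
        ranked = p[order] * m / np.arange(1, len(p) + 1)
        stepped = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty_like(p)
        out[order] = np.minimum(stepped, 1.0)
        return out
    raise ConfigurationError(f"unknown adjustment method {method!r}")


def assess_replication(
    discovery: TrioFitResult,
    replication: TrioFitResult,
    fdr_adjusted_rep_p: float,
    q: float = 0.05,
) -> tuple[str, list[str]]:
    """Replication call: FDR significance plus direction-of-effect consistency.

    A trio replicates iff the FDR-adjusted replication p for POE x Mod is at
    most ``q`` and the signs of both the main POE and the POE x Mod estimates
    agree between discovery and replication.  Returns
    ``('replicated' | 'not_replicated', reasons)``.
    """
    for fit, label in ((discovery, "discovery"), (replication, "replication")):
        for term in ("POE", "POE:Mod"):
            if term not in fit.terms.index:
                raise DataError(f"{label} fit lacks required term {term!r}")
    reasons = []
    if not (fdr_adjusted_rep_p <= q):
        reasons.append(
            f"significance: replication FDR-adjusted p "
            f"{fdr_adjusted_rep_p:.3g} > {q}"
        )
    for term in ("POE", "POE:Mod"):
        s_d = math.copysign(1.0, discovery.estimate(term))
        s_r = math.copysign(1.0, replication.estimate(term))
        if s_d != s_r:
            reasons.append(f"pattern: sign of {term} flips between samples")
    status = "replicated" if not reasons else "not_replicated"
    return status, reasons
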