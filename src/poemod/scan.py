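"""Per-trio interaction model fitting and variance decomposition.

One test unit is an mQTL-modifier-CpG *trio*: a SNP with a parent-of-origin
effect on a CpG, and a candidate modifier (environmental variable or genetic
score) that may alter the methylation contrast between the SNP's reciprocal
heterozygotes.  Two ordinary-least-squares models are fitted per trio:

* non-interaction model:  M ~ Add + Dom + POE + covariates
* interaction model:      M ~ Add + Dom + POE + Mod + Add:Mod + POE:Mod
                              + covariates

with (Add, Dom, POE) the coded genotype of :mod:`poemod.encoding` and the
modifier mean-centered before products are formed (continuous modifiers), so
that main and interaction terms are decorrelated.  The Dom:Mod product is
available behind a flag for sensitivity fits but excluded by default.

Covariates follow the base-model convention: age, sex, cell proportions and
smoking (dropped when smoking itself is the tested modifier), optionally
augmented with principal components of an omics relationship matrix (ORM-PCs,
:func:`build_orm_pcs`) screened against SNP association so genetic signal is
not absorbed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .encoding import encode_add_dom_poe
from .errors import ConfigurationError, DataError, InsufficientDataError, RankDeficiencyError
from .synthio import CohortDataset

TERMS_INTERACTION = ("Mod", "Add", "Dom", "POE", "Add:Mod", "POE:Mod")
DEFAULT_BLOCK_ORDER = ("base", "Mod", "Add", "Dom", "POE", "Add:Mod", "POE:Mod")
SMOKING_COVARIATES = ("smoking", "pack_years", "smoking_status")


@dataclass(frozen=True)
class TrioSpec:
    """One (mQTL, modifier, CpG) test unit."""

    mqtl: str
    cpg: str
    modifier: str
    modifier_kind: str = "environmental"  # or "genetic"


@dataclass
class TrioFitResult:
    """Fitted coefficients and fit statistics for one trio model."""

    trio: TrioSpec
    terms: pd.DataFrame  # index = term name; columns estimate, se, t, p
    n_used: int
    r2_full: float
    r2_base: float = np.nan
    r2_by_term: Optional[dict] = None
    residuals: Optional[np.ndarray] = field(default=None, repr=False)
    fully_explained: bool = False
    notes: list[str] = field(default_factory=list)

    def estimate(self, term: str) -> float:
        return float(self.terms.loc[term, "estimate"])

    def p(self, term: str) -> float:
        return float(self.terms.loc[term, "p"])


@dataclass
class DesignMatrix:
    """Assembled regression design for one trio."""

    X: pd.DataFrame          # complete cases only; includes 'const'
    y: pd.Series
    base_columns: list[str]  # intercept + covariates
    term_columns: list[str]  # genotype/modifier terms in canonical order


def _check_rank(X: np.ndarray, names: Sequence[str]) -> None:
    _, r, pivot = linalg.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int((diag > tol).sum())
    if rank < X.shape[1]:
        raise RankDeficiencyError([names[j] for j in pivot[rank:]])


def _ols(X: np.ndarray, y: np.ndarray, names: Sequence[str]):
    """Plain OLS with per-coefficient two-sided t-tests.

    Returns (terms DataFrame, residuals, r2).  Raises
    :class:`RankDeficiencyError` naming collinear columns.
    """
    _check_rank(X, names)
    n, p = X.shape
    beta, _, _, _ = linalg.lstsq(X, y, lapack_driver="gelsd")
    resid = y - X @ beta
    dof = n - p
    sigma2 = float(resid @ resid) / dof
    xtx_inv = np.linalg.inv(X.T @ X)
    se = np.sqrt(sigma2 * np.diag(xtx_inv))
    t = beta / se
    pvals = 2 * stats.t.sf(np.abs(t), dof)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else np.nan
    terms = pd.DataFrame(
        {"estimate": beta, "se": se, "t": t, "p": pvals}, index=list(names)
    )
    return terms, resid, r2


def _modifier_series(data: CohortDataset, name: str) -> pd.Series:
    if name in data.modifiers.columns:
        return data.modifiers[name]
    if name in data.covariates.columns:
        return data.covariates[name]
    raise DataError(f"modifier {name!r} not found in modifier or covariate tables")


def build_design(
    trio: TrioSpec,
    data: CohortDataset,
    covariates: Optional[pd.DataFrame] = None,
    with_interaction: bool = True,
    include_dom_interaction: bool = False,
    center_modifier: bool = True,
    extra_terms: Optional[pd.DataFrame] = None,
    modifier_override: Optional[pd.Series] = None,
    min_excess: int = 10,
) -> DesignMatrix:
    """Assemble the regression design for one trio on complete cases.

    ``covariates`` defaults to the cohort covariate table; smoking-type
    columns are dropped when the trio's modifier is one of them.  ``extra
    terms`` (e.g. conditioning SNP columns) are appended after the canonical
    terms.  ``modifier_override`` substitutes an arbitrary series for the
    named modifier (used by the SNP-localization scan).
    """
    coding = encode_add_dom_poe(data.genotypes, trio.mqtl)
    if trio.cpg not in data.methylation.columns:
        raise DataError(f"CpG {trio.cpg!r} not found in methylation matrix")
    y = data.methylation[trio.cpg]
    mod = modifier_override if modifier_override is not None \
        else _modifier_series(data, trio.modifier)
    mod = pd.Series(np.asarray(mod, dtype=float), index=data.individuals,
                    name=trio.modifier)

    if covariates is None:
        covariates = data.covariates
        # cell proportions lie on a simplex; one column is redundant with
        # the intercept
        cells = [c for c in covariates.columns if c.startswith("cell")]
        if cells:
            covariates = covariates.drop(columns=cells[-1])
    drop = [c for c in covariates.columns
            if trio.modifier == c or (trio.modifier in SMOKING_COVARIATES
                                      and c in SMOKING_COVARIATES)]
    covariates = covariates.drop(columns=drop)

    X = pd.DataFrame(index=pd.Index(data.individuals, name="individual"))
    X["const"] = 1.0
    for c in covariates.columns:
        X[c] = covariates[c].reindex(X.index).astype(float)
    base_columns = list(X.columns)

    if mod.var(ddof=0) == 0:
        raise DataError(f"modifier {trio.modifier!r} has zero variance")
    modc = mod - mod.mean() if center_modifier else mod

    term_columns = []

    def add_term(name, values):
        X[name] = values
        term_columns.append(name)

    if with_interaction:
        add_term("Mod", modc.to_numpy())
    add_term("Add", coding.add.astype(float))
    add_term("Dom", coding.dom.astype(float))
    add_term("POE", coding.poe.astype(float))
    if with_interaction:
        add_term("Add:Mod", coding.add * modc.to_numpy())
        add_term("POE:Mod", coding.poe * modc.to_numpy())
        if include_dom_interaction:
            add_term("Dom:Mod", coding.dom * modc.to_numpy())
    if extra_terms is not None:
        for c in extra_terms.columns:
            add_term(c, extra_terms[c].reindex(X.index).to_numpy(dtype=float))

    keep = ~coding.missing & np.isfinite(y.to_numpy(dtype=float)) \
        & np.isfinite(X.to_numpy(dtype=float)).all(axis=1)
    X = X.loc[keep]
    y = y.loc[keep].astype(float)
    n, p = X.shape
    if n < p + min_excess:
        raise InsufficientDataError(
            f"{n} complete cases for {p} parameters (need >= {p + min_excess})"
        )
    return DesignMatrix(X=X, y=y, base_columns=base_columns, term_columns=term_columns)


def fit_poe_model(
    trio: TrioSpec,
    data: CohortDataset,
    covariates: Optional[pd.DataFrame] = None,
    with_interaction: bool = True,
    include_dom_interaction: bool = False,
    center_modifier: bool = True,
    extra_terms: Optional[pd.DataFrame] = None,
    modifier_override: Optional[pd.Series] = None,
) -> TrioFitResult:
    """Fit the (non-)interaction model for one trio by OLS."""
    design = build_design(
        trio, data, covariates, with_interaction, include_dom_interaction,
        center_modifier, extra_terms, modifier_override,
    )
    names = list(design.X.columns)
    terms, resid, r2 = _ols(design.X.to_numpy(), design.y.to_numpy(), names)
    base_terms, base_resid, r2_base = _ols(
        design.X[design.base_columns].to_numpy(), design.y.to_numpy(),
        design.base_columns,
    )
    return TrioFitResult(
        trio=trio, terms=terms, n_used=len(design.y),
        r2_full=r2, r2_base=r2_base, residuals=resid,
    )


def variance_decomposition(
    trio: TrioSpec,
    data: CohortDataset,
    covariates: Optional[pd.DataFrame] = None,
    block_order: Sequence[str] = DEFAULT_BLOCK_ORDER,
    include_dom_interaction: bool = False,
) -> dict:
    """Sequential incremental R-squared over ordered model blocks.

    Blocks enter in ``block_order`` (default base -> Mod -> Add -> Dom -> POE
    -> Add:Mod -> POE:Mod); each increment is the R-squared gain when the
    block joins the model, so increments sum to ``r2_full - r2_base``
    exactly.  Returns a dict with per-block increments plus ``r2_base`` and
    ``r2_full``.
    """
    design = build_design(
        trio, data, covariates, with_interaction=True,
        include_dom_interaction=include_dom_interaction,
    )
    if block_order[0] != "base":
        raise ConfigurationError("block_order must start with 'base'")
    unknown = [b for b in block_order[1:] if b not in design.term_columns]
    if unknown:
        raise ConfigurationError(f"unknown blocks in order: {unknown}")

    Xfull = design.X
    y = design.y.to_numpy()
    tss = float(((y - y.mean()) ** 2).sum())

    cols = list(design.base_columns)
    increments = {}
    prev_r2 = None
    for block in block_order:
        if block != "base":
            cols = cols + [block]
        Xb = Xfull[cols].to_numpy()
        _check_rank(Xb, cols)
        beta, _, _, _ = linalg.lstsq(Xb, y, lapack_driver="gelsd")
        rss = float(((y - Xb @ beta) ** 2).sum())
        r2 = 1.0 - rss / tss
        if block == "base":
            r2_base = r2
        else:
            increments[block] = r2 - prev_r2
        prev_r2 = r2
    return {
        "increments": increments,
        "r2_base": r2_base,
        "r2_full": prev_r2,
        "n_used": len(y),
    }


def build_orm_pcs(
    methylation: pd.DataFrame,
    genotype_dosages: Optional[pd.DataFrame] = None,
    n_pcs: int = 20,
    gwas_alpha: float = 5e-8,
) -> pd.DataFrame:
    """Principal components of the omics relationship matrix (ORM).

    Probes are standardized (mean 0, variance 1; constant probes dropped with
    a warning), the ORM is ``W W' / p``, and the top ``n_pcs`` eigenvector
    scores are returned — minus any PC significantly associated with at least
    one SNP (per-SNP simple linear regression, p < ``gwas_alpha``), so that
    genetic signal is not regressed out downstream.
    """
    if methylation.shape[1] < 2:
        raise DataError("need at least 2 probes to build an ORM")
    W = methylation.to_numpy(dtype=float)
    sd = W.std(axis=0, ddof=0)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"dropping {int(constant.sum())} constant probes before ORM",
            stacklevel=2,
        )
        W = W[:, ~constant]
        sd = sd[~constant]
    W = (W - W.mean(axis=0)) / sd
    n, p = W.shape
    orm = W @ W.T / p
    evals, evecs = np.linalg.eigh(orm)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    rank = int((evals > 1e-10 * max(evals.max(), 1.0)).sum())
    k = min(n_pcs, rank)
    scores = evecs[:, :k] * np.sqrt(np.maximum(evals[:k], 0.0))

    keep = np.ones(k, dtype=bool)
    if genotype_dosages is not None and genotype_dosages.shape[1] > 0:
        G = genotype_dosages.to_numpy(dtype=float)
        G = np.where(np.isfinite(G), G, np.nanmean(G, axis=0))
        gsd = G.std(axis=0, ddof=0)
        informative = gsd > 0
        Gs = (G[:, informative] - G[:, informative].mean(axis=0)) / gsd[informative]
        Ss = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=0)
        r = Ss.T @ Gs / n  # PC x SNP correlations
        r = np.clip(r, -1 + 1e-15, 1 - 1e-15)
        tstat = r * np.sqrt((n - 2) / (1 - r**2))
        pvals = 2 * stats.t.sf(np.abs(tstat), n - 2)
        keep = (pvals >= gwas_alpha).all(axis=1)
    pcs = pd.DataFrame(
        scores[:, keep],
        index=methylation.index,
        columns=[f"ORM_PC{i + 1}" for i in np.flatnonzero(keep)],
    )
    return pcs


def poe_by_snp_scan(
    trio: TrioSpec,
    snps: Sequence[str],
    data: CohortDataset,
    covariates: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Localize a genetic modification signal to individual SNPs.

    The interaction model is refitted with the modifier replaced by each
    SNP's additive dosage; the POE x SNP term is reported with Bonferroni
    adjustment over the SNPs actually tested.  Monomorphic SNPs are skipped
    with a warning.
    """
    rows = []
    for snp in snps:
        dosage = data.snp_dosage(snp)
        if np.nanvar(dosage) == 0:
            warnings.warn(f"SNP {snp!r} is monomorphic; skipped", stacklevel=2)
            continue
        sub = TrioSpec(mqtl=trio.mqtl, cpg=trio.cpg, modifier=snp,
                       modifier_kind="genetic")
        fit = fit_poe_model(
            sub, data, covariates,
            modifier_override=pd.Series(dosage, index=data.individuals),
        )
        row = fit.terms.loc["POE:Mod"].rename(snp)
        row["n_used"] = fit.n_used
        rows.append(row)
    if not rows:
        return pd.DataFrame(columns=["estimate", "se", "t", "p", "n_used", "p_bonferroni"])
    out = pd.DataFrame(rows)
    out["p_bonferroni"] = np.minimum(out["p"] * len(out), 1.0)
    return out


def conditional_interaction_fit(
    trio: TrioSpec,
    conditioning_snps: Sequence[str],
    data: CohortDataset,
    covariates: Optional[pd.DataFrame] = None,
) -> TrioFitResult:
    """Interaction fit conditioning on POE x SNP terms for given SNPs.

    Each conditioning SNP contributes a centered main-effect column and a
    POE x SNP product column.  If the POE x Mod column is (numerically)
    collinear with the conditioning terms — e.g. the modifier is a weighted
    score over exactly those SNPs — the fit flags it as fully explained
    instead of failing.
    """
    if trio.mqtl in conditioning_snps:
        raise ConfigurationError("conditioning SNPs must be distinct from the mQTL")
    from .encoding import encode_add_dom_poe as _enc

    poe = _enc(data.genotypes, trio.mqtl).poe.astype(float)
    extra = {}
    for snp in conditioning_snps:
        d = data.snp_dosage(snp)
        dc = d - np.nanmean(d)
        extra[f"snp_{snp}"] = dc
        extra[f"POE:snp_{snp}"] = poe * dc
    extra_df = pd.DataFrame(extra, index=data.individuals)
    try:
        return fit_poe_model(trio, data, covariates, extra_terms=extra_df)
    except RankDeficiencyError as err:
        # the modifier terms may lie in the span of the conditioning SNP
        # columns (e.g. a score built from exactly these SNPs); drop the
        # dependent modifier columns and report the interaction as fully
        # explained rather than failing
        design = build_design(trio, data, covariates, extra_terms=extra_df)
        droppable = {"POE:Mod", "Add:Mod", "Mod"}
        dropped: set[str] = set()
        cols = list(design.X.columns)
        while True:
            try:
                terms, resid, r2 = _ols(
                    design.X[cols].to_numpy(), design.y.to_numpy(), cols
                )
                break
            except RankDeficiencyError as inner:
                removable = [c for c in inner.columns if c in droppable - dropped]
                if not removable:
                    raise err from None
                dropped.update(removable)
                cols = [c for c in cols if c not in dropped]
        if "POE:Mod" not in dropped:
            raise err from None
        return TrioFitResult(
            trio=trio, terms=terms, n_used=len(design.y), r2_full=r2,
            residuals=resid, fully_explained=True,
            notes=[f"modifier columns {sorted(dropped)} collinear with "
                   "conditioning POE x SNP terms; interaction fully explained"],
        )
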