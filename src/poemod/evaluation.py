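"""Replicated simulation experiments at study scale.

These experiments quantify the statistical behaviour of the interaction scan
under the generative model: how much methylation variance the POE x modifier
term recovers when its generative share is calibrated, how biased the
coefficient estimates are, and whether the interaction test holds its
nominal type-I error.  They are used both by the test suite and by the
reproduction script, at the cohort size of the emulated discovery sample
(n = 1663) unless stated otherwise.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scan import TrioSpec, fit_poe_model, variance_decomposition
from .synthio import (
    ModifierSpec,
    SimulationConfig,
    simulate_cohort,
    simulate_methylation,
)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def _one_trio_config(
    seed: int,
    n: int = 1663,
    interaction_beta: float = 0.0,
    target_variance_fraction: float | None = None,
    maf_range: tuple[float, float] = (0.2, 0.4),
) -> SimulationConfig:
    """One mQTL, one CpG (parental pattern), one continuous modifier."""
    return SimulationConfig(
        n_families=n,
        trio_fraction=1.0,
        n_snps=1,
        maf_range=maf_range,
        n_cpgs=1,
        poe_patterns=["parental"],
        beta_add=0.3,
        beta_poe=0.5,
        modifiers=[
            ModifierSpec(
                name="mod",
                kind="continuous",
                main_beta=0.2,
                add_interaction_beta=0.1,
                interaction_beta=interaction_beta,
                target_variance_fraction=target_variance_fraction,
                target_cpg=0,
            )
        ],
        noise_sd=1.0,
        seed=seed,
    )


_TRIO = TrioSpec(mqtl="rs00000", cpg="cg00000", modifier="mod")


def interaction_r2_experiment(
    target_fraction: float,
    n: int = 1663,
    n_reps: int = 200,
    seed: int = 1,
) -> dict:
    """Mean estimated incremental R^2 (%) of the POE x Mod term.

    Each replicate simulates a cohort of ``n`` unrelated individuals with
    the interaction coefficient calibrated so the POE x Mod column's variance
    share equals ``target_fraction``, then reads the term's sequential
    incremental R^2 off :func:`variance_decomposition`.
    """
    increments = np.empty(n_reps)
    for r, s in enumerate(_child_seeds(seed, n_reps)):
        cfg = _one_trio_config(s, n=n, target_variance_fraction=target_fraction)
        data = simulate_methylation(simulate_cohort(cfg), cfg)
        dec = variance_decomposition(_TRIO, data)
        increments[r] = dec["increments"]["POE:Mod"]
    return {
        "target_fraction": target_fraction,
        "mean_percent": float(increments.mean() * 100.0),
        "sd_percent": float(increments.std(ddof=1) * 100.0),
        "n": n,
        "n_reps": n_reps,
        "increments": increments,
    }


def coefficient_bias_experiment(
    n: int = 1663, n_reps: int = 200, seed: int = 2,
    interaction_beta: float = 0.15,
) -> pd.DataFrame:
    """Relative bias of the interaction-model coefficients at study scale.

    True values: Add 0.3, POE 0.5, Mod 0.2, Add:Mod 0.1, POE:Mod
    ``interaction_beta``; Dom is generatively zero under the parental
    pattern and excluded from the relative-bias table.
    """
    truth = {"Add": 0.3, "POE": 0.5, "Mod": 0.2, "Add:Mod": 0.1,
             "POE:Mod": interaction_beta}
    est = {t: np.empty(n_reps) for t in truth}
    for r, s in enumerate(_child_seeds(seed, n_reps)):
        cfg = _one_trio_config(s, n=n, interaction_beta=interaction_beta,
                               maf_range=(0.3, 0.3))
        data = simulate_methylation(simulate_cohort(cfg), cfg)
        fit = fit_poe_model(_TRIO, data)
        for t in truth:
            est[t][r] = fit.estimate(t)
    rows = []
    for t, true_val in truth.items():
        mean = est[t].mean()
        rows.append({
            "term": t, "true": true_val, "mean_estimate": mean,
            "relative_bias": (mean - true_val) / true_val,
            "mc_se": est[t].std(ddof=1) / np.sqrt(n_reps),
        })
    return pd.DataFrame(rows).set_index("term")


def type1_error_experiment(
    n: int = 400, n_reps: int = 1000, alpha: float = 0.05, seed: int = 3,
) -> dict:
    """Rejection rate of the POE x Mod t-test when its true coefficient is 0.

    Main effects (POE, Add, modifier) stay in the generative model, so only
    the interaction is null.  Returns the empirical rejection rate and the
    95% binomial interval around ``alpha``.
    """
    rejections = 0
    for s in _child_seeds(seed, n_reps):
        cfg = _one_trio_config(s, n=n, interaction_beta=0.0)
        data = simulate_methylation(simulate_cohort(cfg), cfg)
        fit = fit_poe_model(_TRIO, data)
        rejections += fit.p("POE:Mod") < alpha
    half = 1.959963984540054 * np.sqrt(alpha * (1 - alpha) / n_reps)
    return {
        "rate": rejections / n_reps,
        "alpha": alpha,
        "n_reps": n_reps,
        "ci95": (alpha - half, alpha + half),
    }


def protein_scan_denominator(
    n_individuals: int = 940, n_cpgs: int = 3, n_proteins: int = 1092,
    seed: int = 4,
) -> dict:
    """Bonferroni denominator of a CpG x protein association scan.

    Builds a synthetic protein panel of the study's dimensions (3 CpGs by
    1092 proteins at n = 940, covariates: cell proportion, age, sex,
    dummy-coded season of sampling, smoking) and runs
    :func:`poemod.downstream.association_scan`, reporting the multiplicity
    count the scan itself used.
    """
    from .downstream import association_scan

    rng = np.random.default_rng(seed)
    idx = [f"ind{i}" for i in range(n_individuals)]
    meth = pd.DataFrame(
        rng.standard_normal((n_individuals, n_cpgs)), index=idx,
        columns=[f"cg{j}" for j in range(n_cpgs)],
    )
    prots = pd.DataFrame(
        rng.standard_normal((n_individuals, n_proteins)), index=idx,
        columns=[f"prot{j}" for j in range(n_proteins)],
    )
    season = rng.integers(0, 4, n_individuals)
    cov = pd.DataFrame(
        {
            "cell_prop": rng.dirichlet([5, 5], n_individuals)[:, 0],
            "age": rng.uniform(18, 80, n_individuals),
            "sex": rng.integers(0, 2, n_individuals),
            "season_q2": (season == 1).astype(float),
            "season_q3": (season == 2).astype(float),
            "season_q4": (season == 3).astype(float),
            "smoking": rng.choice(3, n_individuals, p=(0.5, 0.3, 0.2)),
        },
        index=idx,
    )
    records, m = association_scan(meth, prots, cov, model="protein")
    return {"m": m, "n_pairs_tested": len(records), "n": n_individuals}


def phenome_scan_denominator(
    n_individuals: int = 800, n_cpgs: int = 3, n_phenotypes: int = 79,
    seed: int = 5,
) -> dict:
    """Bonferroni denominator of a CpG x phenotype (phenome-wide) scan."""
    from .downstream import association_scan

    rng = np.random.default_rng(seed)
    idx = [f"ind{i}" for i in range(n_individuals)]
    meth = pd.DataFrame(
        rng.standard_normal((n_individuals, n_cpgs)), index=idx,
        columns=[f"cg{j}" for j in range(n_cpgs)],
    )
    phenos = pd.DataFrame(
        rng.standard_normal((n_individuals, n_phenotypes)), index=idx,
        columns=[f"pheno{j}" for j in range(n_phenotypes)],
    )
    age = rng.uniform(18, 80, n_individuals)
    cov = pd.DataFrame(
        {
            "age": age,
            "age2": age**2,
            "cell_prop": rng.dirichlet([5, 5], n_individuals)[:, 0],
            "sex": rng.integers(0, 2, n_individuals),
            "smoking": rng.choice(3, n_individuals, p=(0.5, 0.3, 0.2)),
        },
        index=idx,
    )
    records, m = association_scan(meth, phenos, cov, model="phenome")
    return {"m": m, "n_pairs_tested": len(records), "n": n_individuals}
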