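"""End-to-end orchestration: simulate -> scan -> permute -> replicate -> meta.

The pipeline mirrors a two-sample modifier-of-POE study: a synthetic family
cohort is generated and split into disjoint discovery and replication sets;
each candidate mQTL-modifier-CpG trio is fitted with the interaction model on
the discovery set; global permutation FDR plus trio-specific permutation
tests select discoveries; selected trios are refitted on the replication set
and assessed for replication (FDR + direction consistency); finally the two
strata are combined by random-effects meta-analysis.

All outputs are plain text (TSV/JSON) under the configured output directory,
and a manifest records seeds, thresholds, and SHA-256 hashes of every
artifact so a run is bit-reproducible from its config.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .errors import ConfigurationError
from .multiplicity import (
    adjust_pvalues,
    assess_replication,
    freedman_lane_null,
    global_permutation_fdr,
    trio_permutation_test,
)
from .scan import TrioSpec, build_design, fit_poe_model
from .synthio import (
    CohortDataset,
    ModifierSpec,
    SimulationConfig,
    read_cohort,
    simulate_cohort,
    simulate_methylation,
    write_cohort,
)

ALL_STAGES = ("simulate", "scan", "permute", "replicate", "downstream")


@dataclass
class RunConfig:
    """Declarative description of one pipeline run."""

    outdir: str
    seed: int = 1
    stages: Sequence[str] = ALL_STAGES
    simulate: Optional[dict] = None       # SimulationConfig kwargs
    trios: list = field(default_factory=list)  # dicts with mqtl/cpg/modifier
    cohort_dir: Optional[str] = None      # pre-existing cohort (skip simulate)
    discovery_fraction: float = 0.72
    n_global_perm: int = 20
    n_trio_perm: int = 2000
    q_global: float = 0.05
    q_replication: float = 0.05
    global_fdr_method: str = "pooled"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def validate(self) -> None:
        unknown = [s for s in self.stages if s not in ALL_STAGES]
        if unknown:
            raise ConfigurationError(f"unknown stages: {unknown}")
        for name, val in (("q_global", self.q_global),
                          ("q_replication", self.q_replication),
                          ("discovery_fraction", self.discovery_fraction)):
            if not 0 < val < 1:
                raise ConfigurationError(f"{name} must lie in (0, 1); got {val}")
        order = [ALL_STAGES.index(s) for s in self.stages]
        if order != sorted(order):
            raise ConfigurationError("stages must respect pipeline order")
        if "scan" in self.stages and "simulate" not in self.stages:
            src = self.cohort_dir or str(Path(self.outdir) / "cohort")
            if not (Path(src) / "manifest.json").exists():
                raise ConfigurationError(
                    f"scan enabled without simulate, but cohort_dir "
                    f"({src!r}) holds no cohort: set 'cohort_dir' or enable "
                    f"'simulate'"
                )
        if "simulate" in self.stages and self.simulate is None:
            raise ConfigurationError("stage 'simulate' enabled but field "
                                     "'simulate' is missing")


def _subset_cohort(data: CohortDataset, individuals: list[str]) -> CohortDataset:
    ped_keep = set(individuals)
    ped = data.pedigree
    parents = ped.loc[ped["individual"].isin(ped_keep), ["father", "mother"]]
    ped_keep |= set(parents.to_numpy().ravel()) - {"0"}
    return CohortDataset(
        pedigree=ped[ped["individual"].isin(ped_keep)].reset_index(drop=True),
        genotypes=data.genotypes.subset(individuals),
        methylation=data.methylation.loc[individuals],
        modifiers=data.modifiers.loc[individuals],
        covariates=data.covariates.loc[individuals],
        modifier_snps=data.modifier_snps.loc[individuals],
        parent_dosages=data.parent_dosages,
        truth=data.truth,
    )


def _default_trios(data: CohortDataset) -> list[TrioSpec]:
    """All (mQTL, modifier, CpG) units with a generative interaction."""
    trios = []
    for cpg, info in data.truth.get("cpgs", {}).items():
        for inter in info.get("interactions", []):
            kind = ("genetic" if inter["modifier"] in
                    data.truth.get("modifier_meta", {}) else "environmental")
            trios.append(TrioSpec(mqtl=info["mqtl"], cpg=cpg,
                                  modifier=inter["modifier"],
                                  modifier_kind=kind))
    return trios


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _simulate_stage(config: RunConfig, outdir: Path):
    sim_kwargs = dict(config.simulate or {})
    sim_kwargs.setdefault("seed", config.seed)
    if "modifiers" in sim_kwargs:
        sim_kwargs["modifiers"] = [
            m if isinstance(m, ModifierSpec) else ModifierSpec(**m)
            for m in sim_kwargs["modifiers"]
        ]
    sim = SimulationConfig(**sim_kwargs)
    data = simulate_methylation(simulate_cohort(sim), sim)
    write_cohort(data, outdir / "cohort")
    n = len(data.individuals)
    n_disc = int(round(config.discovery_fraction * n))
    split = {
        "discovery": data.individuals[:n_disc],
        "replication": data.individuals[n_disc:],
    }
    with open(outdir / "split.json", "w") as fh:
        json.dump(split, fh, indent=1)
    return data, split


def _load_cohort(config: RunConfig, outdir: Path):
    src = Path(config.cohort_dir) if config.cohort_dir else outdir / "cohort"
    data = read_cohort(src)
    split_path = outdir / "split.json"
    if split_path.exists():
        with open(split_path) as fh:
            split = json.load(fh)
    else:
        n = len(data.individuals)
        n_disc = int(round(config.discovery_fraction * n))
        split = {"discovery": data.individuals[:n_disc],
                 "replication": data.individuals[n_disc:]}
    return data, split


def _fit_table(fits: dict[TrioSpec, object]) -> pd.DataFrame:
    rows = []
    for trio, fit in fits.items():
        for term, row in fit.terms.iterrows():
            rows.append({
                "mqtl": trio.mqtl, "cpg": trio.cpg, "modifier": trio.modifier,
                "term": term, "estimate": row["estimate"], "se": row["se"],
                "t": row["t"], "p": row["p"], "n_used": fit.n_used,
                "r2_full": fit.r2_full, "r2_base": fit.r2_base,
            })
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns the run manifest."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = np.random.SeedSequence(config.seed).spawn(4)
    perm_seed = int(seeds[1].generate_state(1)[0] % 2**31)
    trio_seed = int(seeds[2].generate_state(1)[0] % 2**31)

    manifest: dict = {
        "seed": config.seed,
        "stages": list(config.stages),
        "thresholds": {"q_global": config.q_global,
                       "q_replication": config.q_replication},
        "n_perm": {"global": config.n_global_perm, "trio": config.n_trio_perm},
        "outputs": {},
    }
    summary: list[str] = []

    data = split = None
    if "simulate" in config.stages:
        data, split = _simulate_stage(config, outdir)
        summary.append(
            f"simulate: {len(data.individuals)} offspring, "
            f"{data.genotypes.n_snps} SNPs, {data.methylation.shape[1]} CpGs"
        )
    needs_data = set(config.stages) & {"scan", "permute", "replicate", "downstream"}
    if needs_data and data is None:
        data, split = _load_cohort(config, outdir)

    trios: list[TrioSpec] = [
        t if isinstance(t, TrioSpec) else TrioSpec(**t) for t in config.trios
    ] or (_default_trios(data) if data is not None else [])

    disc = repl = None
    if needs_data:
        assert not set(split["discovery"]) & set(split["replication"])
        disc = _subset_cohort(data, split["discovery"])
        repl = _subset_cohort(data, split["replication"])

    disc_fits = {}
    if {"scan", "permute", "replicate", "downstream"} & set(config.stages):
        for trio in trios:
            disc_fits[trio] = fit_poe_model(trio, disc)
        scan_tab = _fit_table(disc_fits)
        scan_tab.to_csv(outdir / "scan_discovery.tsv", sep="\t", index=False)
        summary.append(f"scan: fitted {len(trios)} trios on "
                       f"{len(disc.individuals)} discovery individuals")

    selected = list(trios)
    if "permute" in config.stages:
        obs_p = np.array([disc_fits[t].p("POE:Mod") for t in trios])
        null_p = np.empty((config.n_global_perm, len(trios)))
        for j, trio in enumerate(trios):
            design = build_design(trio, disc)
            dof = len(design.y) - design.X.shape[1]
            draws = freedman_lane_null(
                trio, disc, n_perm=max(100, config.n_global_perm),
                seed=perm_seed + j,
            )[: config.n_global_perm]
            null_p[:, j] = 2 * stats.t.sf(np.abs(draws), dof)
        mask, fdr = global_permutation_fdr(
            obs_p, null_p, q=config.q_global, method=config.global_fdr_method
        )
        selected = [t for t, keep in zip(trios, mask) if keep]
        records = []
        for k, trio in enumerate(selected):
            rec = trio_permutation_test(
                trio, disc, n_perm=config.n_trio_perm,
                n_trios_tested=len(selected), seed=trio_seed + k,
            )
            records.append({
                "mqtl": trio.mqtl, "cpg": trio.cpg, "modifier": trio.modifier,
                "observed_t": rec.observed_t, "n_perm": rec.n_perm,
                "empirical_p": rec.empirical_p, "adjusted_p": rec.adjusted_p,
            })
        perm_tab = pd.DataFrame(
            {"mqtl": [t.mqtl for t in trios], "cpg": [t.cpg for t in trios],
             "modifier": [t.modifier for t in trios],
             "p_observed": obs_p, "fdr": fdr, "selected": mask}
        )
        perm_tab.to_csv(outdir / "permutation_global.tsv", sep="\t", index=False)
        pd.DataFrame(records).to_csv(outdir / "permutation_trio.tsv",
                                     sep="\t", index=False)
        summary.append(f"permute: {len(selected)}/{len(trios)} trios pass "
                       f"global FDR<={config.q_global}")

    statuses = {}
    if "replicate" in config.stages:
        rep_fits = {t: fit_poe_model(t, repl) for t in selected}
        rep_p = np.array([rep_fits[t].p("POE:Mod") for t in selected])
        rep_fdr = adjust_pvalues(rep_p, method="BH") if len(selected) else rep_p
        rows = []
        for trio, fdr_p in zip(selected, rep_fdr):
            status, reasons = assess_replication(
                disc_fits[trio], rep_fits[trio], float(fdr_p),
                q=config.q_replication,
            )
            statuses[trio] = status
            rows.append({
                "mqtl": trio.mqtl, "cpg": trio.cpg, "modifier": trio.modifier,
                "p_replication": rep_fits[trio].p("POE:Mod"),
                "fdr_adjusted_p": float(fdr_p), "status": status,
                "reasons": "; ".join(reasons),
            })
        pd.DataFrame(rows).to_csv(outdir / "replication.tsv", sep="\t",
                                  index=False)
        n_rep = sum(1 for s in statuses.values() if s == "replicated")
        summary.append(f"replicate: {n_rep}/{len(selected)} trios replicated")
        manifest["replicated"] = {
            f"{t.mqtl}:{t.modifier}:{t.cpg}": s for t, s in statuses.items()
        }

    if "downstream" in config.stages:
        from .downstream import dl_meta

        rep_fits = {t: fit_poe_model(t, repl) for t in selected}
        rows = []
        for trio in selected:
            res = dl_meta(
                [disc_fits[trio].estimate("POE:Mod"),
                 rep_fits[trio].estimate("POE:Mod")],
                [float(disc_fits[trio].terms.loc["POE:Mod", "se"]),
                 float(rep_fits[trio].terms.loc["POE:Mod", "se"])],
            )
            rows.append({
                "mqtl": trio.mqtl, "cpg": trio.cpg, "modifier": trio.modifier,
                "pooled": res.pooled, "pooled_se": res.pooled_se,
                "tau2": res.tau2, "Q": res.Q, "p": res.p,
            })
        pd.DataFrame(rows).to_csv(outdir / "meta_analysis.tsv", sep="\t",
                                  index=False)
        summary.append(f"downstream: meta-analyzed {len(selected)} trios")

    with open(outdir / "summary.txt", "w") as fh:
        fh.write("\n".join(summary) + "\n")
    for f in sorted(outdir.rglob("*")):
        if f.is_file() and f.name != "run_manifest.json":
            manifest["outputs"][str(f.relative_to(outdir))] = _sha256(f)
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest
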