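"""Synthetic family cohorts with known parent-of-origin architecture.

The generator emulates the statistical structure of a family-based methylation
cohort: parent-offspring duos and trios, biallelic SNPs at configurable minor
allele frequencies, CpG M-values driven by mQTLs under classical imprinting
patterns (parental, bipolar dominance, polar dominance), modifier-dependent
heterozygote contrasts (POE x modifier interactions), and covariate structure
(age, sex, cell proportions, smoking).  Every generated effect is recorded in
a ``truth`` dictionary so downstream estimators can be validated against a
known answer.

Generative model per CpG, on the M-value scale::

    M = b0 + b_add*Add + b_dom*Dom + b_poe*POE
         + b_mod*Mod + b_axm*Add*Mod + b_pxm*POE*Mod
         + covariate effects + N(0, noise_sd^2)

with (Add, Dom, POE) the coded mQTL genotype of :mod:`poemod.encoding` and
Mod a mean-centered modifier.  Imprinting-pattern presets constrain the
genotype coefficients; ``target_variance_fraction`` calibrates ``b_pxm``
analytically so the interaction column contributes a chosen share of the
total M-value variance.

Non-POE CpGs receive a latent per-individual binary epigenetic state that
separates the cohort into two methylation modes (bimodal M-values), whereas
POE CpGs sit at intermediate levels — mirroring the contrast between genomic
background CpGs and imprinted-region CpGs.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .encoding import MISSING, PhasedGenotypeMatrix, encode_add_dom_poe, weighted_allele_score
from .errors import ConfigurationError, DataError

PATTERNS = ("parental", "bipolar_dominance", "polar_dominance", "none")
MODIFIER_KINDS = ("binary", "ordinal3", "continuous", "allele_score")


@dataclass
class ModifierSpec:
    """One candidate modifier variable.

    ``kind`` selects the marginal distribution: ``binary`` Bernoulli(``p``),
    ``ordinal3`` a three-level never/former/current-style code 0/1/2 with
    probabilities ``levels_p``, ``continuous`` standard normal, and
    ``allele_score`` a weighted allele score over ``n_score_snps`` unlinked
    SNPs (weights recorded in the truth table).

    ``interaction_beta`` is the POE x modifier coefficient on the target CpG;
    ``target_variance_fraction``, when set, overrides it with an analytically
    calibrated value so the interaction column explains exactly that share of
    the CpG's total variance (population calibration per realized cohort).
    """

    name: str
    kind: str = "continuous"
    main_beta: float = 0.0
    interaction_beta: float = 0.0
    add_interaction_beta: float = 0.0
    target_variance_fraction: Optional[float] = None
    target_cpg: int = 0
    p: float = 0.25
    levels_p: tuple[float, float, float] = (0.5, 0.3, 0.2)
    n_score_snps: int = 2

    def validate(self) -> None:
        if self.kind not in MODIFIER_KINDS:
            raise ConfigurationError(f"unknown modifier kind {self.kind!r}")
        if self.target_variance_fraction is not None and not (
            0 <= self.target_variance_fraction < 1
        ):
            raise ConfigurationError("target_variance_fraction must lie in [0, 1)")
        if self.kind == "ordinal3" and not math.isclose(sum(self.levels_p), 1.0):
            raise ConfigurationError("ordinal3 level probabilities must sum to 1")


@dataclass
class CovariateSpec:
    """Covariate structure: age range (years), sex ratio, cell proportions."""

    age_range: tuple[float, float] = (18.0, 58.0)
    male_fraction: float = 0.4
    n_cell_types: int = 3
    cell_concentration: float = 5.0  # Dirichlet concentration per cell type


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    ``trio_fraction`` is the fraction of families with both parents genotyped;
    the remainder are single-parent duos.  One offspring per family enters the
    analysis set.  ``poe_patterns`` assigns an imprinting pattern per CpG;
    CpG ``j`` is driven by SNP ``mqtl_of_cpg[j]`` (defaults to ``j`` modulo
    ``n_snps``).  All randomness flows from ``seed`` through per-stage child
    streams, so a config is fully reproducible.
    """

    n_families: int = 500
    trio_fraction: float = 1.0
    n_snps: int = 1
    maf_range: tuple[float, float] = (0.1, 0.5)
    n_cpgs: int = 1
    poe_patterns: Optional[Sequence[str]] = None
    mqtl_of_cpg: Optional[Sequence[Optional[int]]] = None
    beta_add: float = 0.3
    beta_dom: float = 0.2
    beta_poe: float = 0.5
    modifiers: list[ModifierSpec] = field(default_factory=list)
    covariates: CovariateSpec = field(default_factory=CovariateSpec)
    noise_sd: float = 1.0
    bimodal_offset: float = 4.0  # M-value separation of the two non-POE modes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.poe_patterns is None:
            self.poe_patterns = ["parental"] * self.n_cpgs
        if self.mqtl_of_cpg is None:
            self.mqtl_of_cpg = [
                None if p == "none" else (j % self.n_snps)
                for j, p in enumerate(self.poe_patterns)
            ]

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigurationError(
                f"maf_range must satisfy 0 < lo <= hi <= 0.5; got {self.maf_range}"
            )
        if self.noise_sd <= 0:
            raise ConfigurationError("noise_sd must be positive")
        if not 0.0 <= self.trio_fraction <= 1.0:
            raise ConfigurationError("trio_fraction must lie in [0, 1]")
        if self.n_families < 1 or self.n_snps < 1 or self.n_cpgs < 1:
            raise ConfigurationError("n_families, n_snps and n_cpgs must be positive")
        if len(self.poe_patterns) != self.n_cpgs:
            raise ConfigurationError("poe_patterns must list one pattern per CpG")
        for j, p in enumerate(self.poe_patterns):
            if p not in PATTERNS:
                raise ConfigurationError(f"unknown POE pattern {p!r}")
            if p != "none" and self.mqtl_of_cpg[j] is None:
                raise ConfigurationError(
                    f"CpG {j} requests pattern {p!r} but has no assigned mQTL"
                )
        for m in self.modifiers:
            m.validate()
            if not 0 <= m.target_cpg < self.n_cpgs:
                raise ConfigurationError(f"modifier {m.name!r} targets unknown CpG")


@dataclass
class CohortDataset:
    """One simulated cohort: pedigree, genotypes, methylation, modifiers.

    The analysis sample is the offspring generation (rows of ``methylation``,
    ``modifiers`` and ``covariates``).  ``parent_dosages`` carries the
    unphased genotypes of the genotyped parents so origin inference can be
    exercised against the recorded truth.
    """

    pedigree: pd.DataFrame
    genotypes: PhasedGenotypeMatrix
    methylation: pd.DataFrame
    modifiers: pd.DataFrame
    covariates: pd.DataFrame
    modifier_snps: pd.DataFrame
    parent_dosages: pd.DataFrame
    truth: dict

    @property
    def individuals(self) -> list[str]:
        return self.genotypes.individuals

    def snp_dosage(self, snp_id: str) -> np.ndarray:
        """Unphased dosage for an mQTL SNP or a modifier-score SNP."""
        if snp_id in self.genotypes.snps.index:
            return self.genotypes.dosage(snp_id)
        if snp_id in self.modifier_snps.columns:
            return self.modifier_snps[snp_id].to_numpy(dtype=float)
        raise DataError(f"SNP {snp_id!r} not present in cohort")

    def check_transmission(self) -> None:
        """Assert every offspring haplotype is carried by the matching parent."""
        ped = self.pedigree.set_index("individual")
        for i, ind in enumerate(self.individuals):
            row = ped.loc[ind]
            for parent, hap in (("father", self.genotypes.paternal[i]),
                                ("mother", self.genotypes.maternal[i])):
                pid = row[parent]
                if pid == "0" or pid not in self.parent_dosages.index:
                    continue
                pd_dos = self.parent_dosages.loc[pid].to_numpy()
                ok = (hap == MISSING) | (pd_dos == 1) | (pd_dos == 2 * hap)
                if not ok.all():
                    bad = self.genotypes.snps.index[~ok].tolist()
                    raise DataError(
                        f"offspring {ind}: {parent} cannot have transmitted "
                        f"haplotype at {bad}"
                    )


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(n)]


def simulate_cohort(config: SimulationConfig) -> CohortDataset:
    """Draw pedigree, phased genotypes, modifiers and covariates.

    Parental alleles are drawn at the per-SNP MAF; each offspring receives one
    allele from each parent uniformly at random, with the transmitting parent
    and allele recorded — so the offspring's phased genotype (paternal |
    maternal) is known by construction.  Methylation is added separately by
    :func:`simulate_methylation`.
    """
    config.validate()
    seeds = _child_seeds(config.seed, 6)
    rng_geno = np.random.default_rng(seeds[0])
    rng_mod = np.random.default_rng(seeds[1])
    rng_cov = np.random.default_rng(seeds[2])
    rng_ped = np.random.default_rng(seeds[3])

    n_fam, n_snp = config.n_families, config.n_snps
    lo, hi = config.maf_range
    maf = rng_geno.uniform(lo, hi, size=n_snp) if lo < hi else np.full(n_snp, lo)

    # parental allele pairs: (family, snp, 2) alternate-allele indicators
    father_al = rng_geno.random((n_fam, n_snp, 2)) < maf[None, :, None]
    mother_al = rng_geno.random((n_fam, n_snp, 2)) < maf[None, :, None]
    pick_f = rng_geno.integers(0, 2, size=(n_fam, n_snp))
    pick_m = rng_geno.integers(0, 2, size=(n_fam, n_snp))
    paternal = np.take_along_axis(father_al, pick_f[:, :, None], axis=2)[:, :, 0]
    maternal = np.take_along_axis(mother_al, pick_m[:, :, None], axis=2)[:, :, 0]

    offspring = [f"C{i:05d}" for i in range(n_fam)]
    fathers = [f"F{i:05d}" for i in range(n_fam)]
    mothers = [f"M{i:05d}" for i in range(n_fam)]
    is_trio = rng_ped.random(n_fam) < config.trio_fraction
    # duos: which single parent is genotyped
    duo_father = rng_ped.random(n_fam) < 0.5

    snp_table = pd.DataFrame(
        {
            "chrom": ["1"] * n_snp,
            "pos": np.arange(1, n_snp + 1) * 1000,
            "ref": ["A"] * n_snp,
            "alt": ["G"] * n_snp,
            "maf": maf,
        },
        index=pd.Index([f"rs{j:05d}" for j in range(n_snp)], name="snp"),
    )

    rows = []
    parent_rows = {}
    for i in range(n_fam):
        sex = "F" if rng_ped.random() < 0.5 else "M"
        f_geno = is_trio[i] or duo_father[i]
        m_geno = is_trio[i] or not duo_father[i]
        rows.append((offspring[i], fathers[i] if f_geno else "0",
                     mothers[i] if m_geno else "0", sex))
        if f_geno:
            rows.append((fathers[i], "0", "0", "M"))
            parent_rows[fathers[i]] = father_al[i].sum(axis=1)
        if m_geno:
            rows.append((mothers[i], "0", "0", "F"))
            parent_rows[mothers[i]] = mother_al[i].sum(axis=1)
    pedigree = pd.DataFrame(rows, columns=["individual", "father", "mother", "sex"])
    parent_dosages = pd.DataFrame.from_dict(
        parent_rows, orient="index", columns=snp_table.index
    ).astype(np.int8)

    genotypes = PhasedGenotypeMatrix(
        offspring, snp_table.drop(columns="maf"),
        paternal.astype(np.int8), maternal.astype(np.int8),
    )

    # covariates
    cov = config.covariates
    age = rng_cov.uniform(*cov.age_range, size=n_fam)
    sex_num = (rng_cov.random(n_fam) < cov.male_fraction).astype(int)  # 1 = male
    cells = rng_cov.dirichlet([cov.cell_concentration] * cov.n_cell_types, size=n_fam)
    smoking = rng_cov.choice(3, size=n_fam, p=(0.5, 0.3, 0.2))
    covariates = pd.DataFrame({"age": age, "sex": sex_num}, index=offspring)
    for k in range(cov.n_cell_types):
        covariates[f"cell{k + 1}"] = cells[:, k]
    covariates["smoking"] = smoking
    covariates.index.name = "individual"

    # modifiers
    mod_cols = {}
    score_snp_cols = {}
    truth_modifiers = {}
    for m in config.modifiers:
        if m.kind == "binary":
            x = rng_mod.random(n_fam) < m.p
            mod_cols[m.name] = x.astype(int)
        elif m.kind == "ordinal3":
            mod_cols[m.name] = rng_mod.choice(3, size=n_fam, p=m.levels_p)
        elif m.kind == "continuous":
            mod_cols[m.name] = rng_mod.standard_normal(n_fam)
        elif m.kind == "allele_score":
            snp_ids, weights = [], {}
            for k in range(m.n_score_snps):
                sid = f"{m.name}_snp{k}"
                p_k = rng_mod.uniform(0.1, 0.5)
                score_snp_cols[sid] = rng_mod.binomial(2, p_k, size=n_fam)
                weights[sid] = float(rng_mod.normal(0.0, 0.15))
                snp_ids.append(sid)
            dos = pd.DataFrame(
                {s: score_snp_cols[s] for s in snp_ids}, index=offspring
            )
            mod_cols[m.name] = weighted_allele_score(dos, weights).to_numpy()
            truth_modifiers[m.name] = {"weights": weights}
    modifiers = pd.DataFrame(mod_cols, index=offspring, dtype=float)
    modifiers.index.name = "individual"
    modifier_snps = pd.DataFrame(score_snp_cols, index=offspring, dtype=np.int8)
    modifier_snps.index.name = "individual"

    truth = {
        "seed": config.seed,
        "maf": maf.tolist(),
        "poe_patterns": list(config.poe_patterns),
        "mqtl_of_cpg": list(config.mqtl_of_cpg),
        "modifier_meta": truth_modifiers,
        "is_trio": is_trio.tolist(),
    }
    return CohortDataset(
        pedigree=pedigree,
        genotypes=genotypes,
        methylation=pd.DataFrame(index=offspring),
        modifiers=modifiers,
        covariates=covariates,
        modifier_snps=modifier_snps,
        parent_dosages=parent_dosages,
        truth=truth,
    )


def _pattern_betas(pattern: str, config: SimulationConfig) -> tuple[float, float, float]:
    """Map an imprinting-pattern preset to (b_add, b_dom, b_poe)."""
    if pattern == "parental":
        return config.beta_add, 0.0, config.beta_poe
    if pattern == "bipolar_dominance":
        return 0.0, 0.0, config.beta_poe
    if pattern == "polar_dominance":
        return 0.0, config.beta_dom, config.beta_poe
    return 0.0, 0.0, 0.0  # none


def _calibrate_interaction_beta(
    base_predictor: np.ndarray, interaction_col: np.ndarray,
    fraction: float, noise_sd: float,
) -> float:
    """Solve for b so Var(b*c) / Var(y) equals ``fraction``.

    With y = L0 + b*c + e:  f * [Var(L0) + b^2 Var(c) + 2 b Cov(L0, c) +
    sd^2] = b^2 Var(c).  The positive root of the quadratic is returned.
    """
    if fraction == 0:
        return 0.0
    v0 = float(np.var(base_predictor))
    vc = float(np.var(interaction_col))
    if vc <= 0:
        raise ConfigurationError("interaction column has zero variance; cannot calibrate")
    cov = float(np.cov(base_predictor, interaction_col)[0, 1])
    a = (1.0 - fraction) * vc
    disc = fraction**2 * cov**2 + a * fraction * (v0 + noise_sd**2)
    return (fraction * cov + math.sqrt(disc)) / a


def simulate_methylation(
    dataset: CohortDataset, config: SimulationConfig
) -> CohortDataset:
    """Generate CpG M-values from the coded genotypes and modifiers.

    Fills ``dataset.methylation`` in place (and returns the dataset).  Records
    every coefficient used — including analytically calibrated interaction
    coefficients — under ``dataset.truth['cpgs']``.
    """
    config.validate()
    seeds = _child_seeds(config.seed, 6)
    rng = np.random.default_rng(seeds[4])
    n = len(dataset.individuals)

    # per-CpG covariate effects, drawn once
    cov_names = list(dataset.covariates.columns)
    cov_mat = dataset.covariates.to_numpy(dtype=float)
    cov_mat_c = cov_mat - cov_mat.mean(axis=0)

    cpg_truth = {}
    meth = {}
    for j in range(config.n_cpgs):
        cpg_id = f"cg{j:05d}"
        pattern = config.poe_patterns[j]
        cov_betas = rng.normal(0.0, [0.01 if c == "age" else 0.3 for c in cov_names])
        predictor = cov_mat_c @ cov_betas

        info = {"pattern": pattern, "covariate_betas": dict(zip(cov_names, cov_betas))}
        if pattern == "none":
            state = rng.random(n) < 0.5
            predictor = predictor + np.where(state, 1.0, -1.0) * config.bimodal_offset / 2
            info["bimodal_offset"] = config.bimodal_offset
        else:
            snp_idx = config.mqtl_of_cpg[j]
            snp_id = dataset.genotypes.snps.index[snp_idx]
            coding = encode_add_dom_poe(dataset.genotypes, snp_id)
            b_add, b_dom, b_poe = _pattern_betas(pattern, config)
            predictor = predictor + (
                b_add * coding.add + b_dom * coding.dom + b_poe * coding.poe
            )
            info.update(mqtl=snp_id, beta_add=b_add, beta_dom=b_dom, beta_poe=b_poe)

            mods_here = [m for m in config.modifiers if m.target_cpg == j]
            interactions = []
            for m in mods_here:
                modc = dataset.modifiers[m.name].to_numpy() \
                    - dataset.modifiers[m.name].mean()
                predictor = predictor + m.main_beta * modc \
                    + m.add_interaction_beta * coding.add * modc
                c = coding.poe * modc
                if m.target_variance_fraction is not None:
                    b_pxm = _calibrate_interaction_beta(
                        predictor, c, m.target_variance_fraction, config.noise_sd
                    )
                else:
                    b_pxm = m.interaction_beta
                predictor = predictor + b_pxm * c
                interactions.append(
                    {
                        "modifier": m.name,
                        "beta_main": m.main_beta,
                        "beta_add_x_mod": m.add_interaction_beta,
                        "beta_poe_x_mod": b_pxm,
                        "target_variance_fraction": m.target_variance_fraction,
                    }
                )
            info["interactions"] = interactions
        meth[cpg_id] = predictor + rng.normal(0.0, config.noise_sd, size=n)
        cpg_truth[cpg_id] = info

    dataset.methylation = pd.DataFrame(meth, index=dataset.individuals)
    dataset.methylation.index.name = "individual"
    dataset.truth["cpgs"] = cpg_truth
    dataset.truth["noise_sd"] = config.noise_sd
    return dataset


def bimodality_coefficient(x: np.ndarray) -> float:
    """Sarle's bimodality coefficient (skew^2 + 1) / kurtosis-adjusted.

    Values above ~0.555 (the uniform's coefficient) indicate bimodality.
    """
    from scipy import stats

    x = np.asarray(x, dtype=float)
    n = len(x)
    g = stats.skew(x)
    k = stats.kurtosis(x)  # excess
    return (g**2 + 1) / (k + 3 * (n - 1) ** 2 / ((n - 2) * (n - 3)))


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

_FILES = {
    "genotypes": "genotypes.vcf",
    "pedigree": "pedigree.tsv",
    "methylation": "methylation.tsv",
    "modifiers": "modifiers.tsv",
    "covariates": "covariates.tsv",
    "modifier_snps": "modifier_snps.tsv",
    "parent_dosages": "parent_genotypes.tsv",
    "truth": "truth.json",
}


def _write_vcf(path: Path, geno: PhasedGenotypeMatrix) -> None:
    """Emit a minimal VCF 4.2 with phased GT, first allele paternal."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("##poemod_phase_convention=first_allele_paternal\n")
        for chrom in pd.unique(geno.snps["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(geno.individuals) + "\n"
        )
        for j, (snp_id, row) in enumerate(geno.snps.iterrows()):
            gts = []
            for i in range(geno.n_individuals):
                p, m = geno.paternal[i, j], geno.maternal[i, j]
                gts.append(".|." if p == MISSING else f"{p}|{m}")
            fh.write(
                f"{row['chrom']}\t{row['pos']}\t{snp_id}\t{row['ref']}\t"
                f"{row['alt']}\t.\tPASS\t.\tGT\t" + "\t".join(gts) + "\n"
            )


def _read_vcf(path: Path) -> PhasedGenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    ids, chroms, poss, refs, alts = [], [], [], [], []
    pat_rows, mat_rows = [], []
    for var in vcf:
        ids.append(var.ID)
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        g = np.asarray(var.genotypes)  # (n, 3): allele1, allele2, phased
        pat = g[:, 0].astype(np.int8)
        mat = g[:, 1].astype(np.int8)
        miss = (pat < 0) | (mat < 0)
        pat[miss] = MISSING
        mat[miss] = MISSING
        pat_rows.append(pat)
        mat_rows.append(mat)
    snps = pd.DataFrame(
        {"chrom": chroms, "pos": poss, "ref": refs, "alt": alts},
        index=pd.Index(ids, name="snp"),
    )
    return PhasedGenotypeMatrix(
        individuals, snps,
        np.array(pat_rows).T if pat_rows else np.empty((len(individuals), 0)),
        np.array(mat_rows).T if mat_rows else np.empty((len(individuals), 0)),
    )


def write_cohort(dataset: CohortDataset, directory: str | Path) -> dict:
    """Write the cohort as plain-text artifacts; returns a manifest dict.

    Layout: phased VCF (``p|m``), pedigree / methylation / modifier /
    covariate TSVs, truth JSON.  The manifest records file names and SHA-256
    hashes and is itself written as ``manifest.json``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_vcf(directory / _FILES["genotypes"], dataset.genotypes)
    dataset.pedigree.to_csv(directory / _FILES["pedigree"], sep="\t", index=False)
    for key in ("methylation", "modifiers", "covariates", "modifier_snps",
                "parent_dosages"):
        getattr(dataset, key).to_csv(directory / _FILES[key], sep="\t")
    with open(directory / _FILES["truth"], "w") as fh:
        json.dump(dataset.truth, fh, indent=1, default=float)

    manifest = {"files": {}}
    for key, name in _FILES.items():
        digest = hashlib.sha256((directory / name).read_bytes()).hexdigest()
        manifest["files"][key] = {"path": name, "sha256": digest}
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def read_cohort(directory: str | Path) -> CohortDataset:
    """Round-trip reader for :func:`write_cohort` output."""
    directory = Path(directory)
    genotypes = _read_vcf(directory / _FILES["genotypes"])
    pedigree = pd.read_csv(
        directory / _FILES["pedigree"], sep="\t",
        dtype={"individual": str, "father": str, "mother": str},
    )

    def _tsv(name: str) -> pd.DataFrame:
        return pd.read_csv(directory / _FILES[name], sep="\t", index_col=0)

    with open(directory / _FILES["truth"]) as fh:
        truth = json.load(fh)
    return CohortDataset(
        pedigree=pedigree,
        genotypes=genotypes,
        methylation=_tsv("methylation"),
        modifiers=_tsv("modifiers"),
        covariates=_tsv("covariates"),
        modifier_snps=_tsv("modifier_snps"),
        parent_dosages=_tsv("parent_dosages"),
        truth=truth,
    )
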