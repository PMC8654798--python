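"""Genotype coding for parent-of-origin (POE) analyses.

A POE-mQTL model distinguishes the two reciprocal heterozygotes of a biallelic
SNP by which parent transmitted the alternate allele.  This module provides

* :class:`PhasedGenotypeMatrix` — per-individual ordered allele pairs
  (paternal, maternal dosage of the alternate allele);
* :func:`encode_add_dom_poe` — the additive / dominance / parent-of-origin
  design columns used by the interaction scan;
* :func:`infer_parental_origin` — Mendelian resolution of allele origin from
  parent genotypes in duos and trios;
* :func:`weighted_allele_score` — linear allele scoring for genetic modifiers
  (predicted expression from externally supplied SNP weights).

Conventions
-----------
The first allele of a phased genotype is the *paternal* allele throughout
(VCF ``GT`` field ``p|m``).  The heterozygote with a paternal reference allele
codes POE = -1; a paternal alternate allele codes POE = +1.  Only the sign of
the POE coefficient depends on this orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, UninformativeSNPError

logger = logging.getLogger(__name__)

MISSING = -1  # sentinel for a dosage whose parental origin (or value) is unknown


@dataclass
class PhasedGenotypeMatrix:
    """Ordered allele pairs for a set of individuals and biallelic SNPs.

    Parameters
    ----------
    individuals
        Individual identifiers (rows).
    snps
        Table indexed by SNP id with columns ``chrom``, ``pos`` (1-based),
        ``ref``, ``alt``.
    paternal, maternal
        Integer matrices (individuals x SNPs) holding the dosage of the
        alternate allele on the paternal / maternal haplotype: 0, 1, or
        ``MISSING`` (-1).  Missingness is joint: a genotype whose origin is
        unknown is missing in both matrices.
    """

    individuals: list[str]
    snps: pd.DataFrame
    paternal: np.ndarray
    maternal: np.ndarray

    def __post_init__(self) -> None:
        self.paternal = np.asarray(self.paternal, dtype=np.int8)
        self.maternal = np.asarray(self.maternal, dtype=np.int8)
        n, m = len(self.individuals), len(self.snps)
        if self.paternal.shape != (n, m) or self.maternal.shape != (n, m):
            raise DataError(
                f"allele matrices must be shaped ({n}, {m}); got "
                f"{self.paternal.shape} and {self.maternal.shape}"
            )
        for mat in (self.paternal, self.maternal):
            bad = ~np.isin(mat, (0, 1, MISSING))
            if bad.any():
                raise DataError("haplotype dosages must be 0, 1 or missing (-1)")
        if ((self.paternal == MISSING) != (self.maternal == MISSING)).any():
            raise DataError("missingness must be joint across the two haplotypes")

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_position(self, snp_id: str) -> int:
        try:
            return int(self.snps.index.get_loc(snp_id))
        except KeyError:
            raise DataError(f"SNP {snp_id!r} not present") from None

    def dosage(self, snp_id: str) -> np.ndarray:
        """Unphased alternate-allele dosage (float, NaN where missing)."""
        j = self.snp_position(snp_id)
        d = (self.paternal[:, j] + self.maternal[:, j]).astype(float)
        d[self.paternal[:, j] == MISSING] = np.nan
        return d

    def subset(self, individuals: Sequence[str]) -> "PhasedGenotypeMatrix":
        pos = {ind: i for i, ind in enumerate(self.individuals)}
        try:
            rows = [pos[i] for i in individuals]
        except KeyError as exc:
            raise DataError(f"unknown individual {exc.args[0]!r}") from None
        return PhasedGenotypeMatrix(
            list(individuals), self.snps, self.paternal[rows], self.maternal[rows]
        )


@dataclass
class PoeCoding:
    """Additive / dominance / parent-of-origin design columns for one SNP.

    The coding for the four ordered genotypes (paternal allele first) is

    ==========  =====  =====  =====
    genotype    add    dom    poe
    ==========  =====  =====  =====
    AA (0|0)      0      0      0
    Aa (0|1)      1      1     -1
    aA (1|0)      1      1     +1
    aa (1|1)      2      0      0
    ==========  =====  =====  =====

    where ``A`` is the reference and ``a`` the alternate allele, and ``Aa``
    denotes a paternal reference allele.  Closed forms: ``add = dp + dm``,
    ``dom = dp XOR dm``, ``poe = dp - dm`` for haplotype dosages (dp, dm).
    """

    add: np.ndarray
    dom: np.ndarray
    poe: np.ndarray
    missing: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        ok = ~self.missing
        if not (
            np.isin(self.add[ok], (0, 1, 2)).all()
            and np.isin(self.dom[ok], (0, 1)).all()
            and np.isin(self.poe[ok], (-1, 0, 1)).all()
            and (np.abs(self.poe[ok]) == self.dom[ok]).all()
        ):
            raise DataError("inconsistent POE coding columns")


def encode_add_dom_poe(phased: PhasedGenotypeMatrix, snp_id: str) -> PoeCoding:
    """Code one SNP into (add, dom, poe) columns across all individuals.

    Raises
    ------
    UninformativeSNPError
        If every individual is missing at the SNP.
    """
    j = phased.snp_position(snp_id)
    dp = phased.paternal[:, j].astype(np.int8)
    dm = phased.maternal[:, j].astype(np.int8)
    missing = dp == MISSING
    if missing.all():
        raise UninformativeSNPError(f"SNP {snp_id!r}: all genotypes missing")
    add = np.where(missing, 0, dp + dm).astype(np.int8)
    dom = np.where(missing, 0, dp ^ dm).astype(np.int8)
    poe = np.where(missing, 0, dp - dm).astype(np.int8)
    return PoeCoding(add=add, dom=dom, poe=poe, missing=missing)


class OriginStatus(str, Enum):
    RESOLVED = "resolved"
    AMBIGUOUS = "ambiguous"
    INCONSISTENT = "inconsistent"
    NO_PARENTS = "no_parents"


def _transmissible(parent_gt: Optional[int]) -> frozenset:
    """Set of alternate-allele dosages (0/1) a parent can transmit."""
    if parent_gt is None:
        return frozenset((0, 1))
    if parent_gt == 0:
        return frozenset((0,))
    if parent_gt == 1:
        return frozenset((0, 1))
    if parent_gt == 2:
        return frozenset((1,))
    raise DataError(f"genotype must be 0, 1, 2 or None; got {parent_gt!r}")


def infer_parental_origin(
    child_gt: int,
    father_gt: Optional[int] = None,
    mother_gt: Optional[int] = None,
) -> tuple[Optional[tuple[int, int]], OriginStatus]:
    """Resolve the parental origin of a child's alleles by Mendelian logic.

    Genotypes are unphased alternate-allele counts (0/1/2); an absent parent
    is ``None``.  Origin is assigned only when uniquely forced: homozygous
    children are trivially resolved, heterozygous children only when the
    parent genotypes admit a single (paternal, maternal) assignment.

    Returns ``((paternal_dosage, maternal_dosage), status)``; the dosage pair
    is ``None`` unless ``status`` is ``RESOLVED``.  Mendelian-inconsistent
    families yield ``INCONSISTENT`` (never an exception), matching the
    complete-case handling downstream.
    """
    if child_gt not in (0, 1, 2):
        raise DataError(f"child genotype must be 0, 1 or 2; got {child_gt!r}")
    if father_gt is None and mother_gt is None:
        return None, OriginStatus.NO_PARENTS
    pat_ok = _transmissible(father_gt)
    mat_ok = _transmissible(mother_gt)
    if child_gt == 0:
        candidates = [(0, 0)]
    elif child_gt == 2:
        candidates = [(1, 1)]
    else:
        candidates = [(0, 1), (1, 0)]
    feasible = [(p, m) for p, m in candidates if p in pat_ok and m in mat_ok]
    if not feasible:
        return None, OriginStatus.INCONSISTENT
    if len(feasible) > 1:
        return None, OriginStatus.AMBIGUOUS
    return feasible[0], OriginStatus.RESOLVED


def weighted_allele_score(
    dosages: pd.DataFrame, weights: Mapping[str, float]
) -> pd.Series:
    """Linear weighted allele score per individual.

    ``score_i = sum_j w_j * dosage_ij`` over the weighted SNPs.  This is the
    scoring step of expression prediction (PrediXcan-style) or of a polygenic
    risk score, given externally supplied per-SNP weights.

    Parameters
    ----------
    dosages
        Individuals x SNPs table of alternate-allele dosages (0/1/2, NaN for
        missing).
    weights
        Mapping SNP id -> weight (on the alternate allele).

    Missing dosages are mean-imputed per SNP (logged).  A weight referencing
    a SNP absent from ``dosages`` raises :class:`DataError` listing the ids.
    """
    absent = [s for s in weights if s not in dosages.columns]
    if absent:
        raise DataError(f"weighted SNPs absent from dosage matrix: {absent}")
    snp_ids = list(weights)
    block = dosages[snp_ids].astype(float)
    n_missing = int(block.isna().sum().sum())
    if n_missing:
        logger.info("mean-imputing %d missing dosages across %d SNPs", n_missing, len(snp_ids))
        block = block.fillna(block.mean())
    w = np.array([weights[s] for s in snp_ids], dtype=float)
    return pd.Series(block.to_numpy() @ w, index=dosages.index, name="score")
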