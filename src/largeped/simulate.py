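"""Gene-dropping SNP simulation on a template pedigree.

Each replicate draws independent founder haplotypes at a fixed minor allele
frequency (loci are in linkage equilibrium, so the founder pool is fully
specified by the per-locus frequency), transmits one recombinant gamete per
parent down the pedigree — the transmitted strand starts at a random
parental chromosome and switches between adjacent loci with the Haldane
recombination fraction of their spacing — assigns affection through a
prevalence-calibrated penetrance function at a designated disease locus
(or copies the template labels verbatim under the null), and finally masks
genotypes and phenotypes to the members flagged genotyped/phenotyped in the
template, reproducing the cohort's sampling pattern.

Penetrance calibration: per-genotype risks are multiplicative in the
effect size, ``f_g = min(1, psi**m(g) * f_0)`` with multiplicity ``m``
depending on the mode (dominant: m=1 for any risk allele; recessive: m=1
only for two copies; additive: m=g), subject to the HWE-weighted mean
penetrance equalling the prevalence ``K``; ``f_0`` is found by a monotone
scalar root solve.  The nominal "odds ratio" effect size is therefore
applied as a genotype relative risk; an odds-scale parameterization would
compress the genotype risks at an appreciable prevalence and cannot
reproduce the calibration behaviour this framework targets.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property
from typing import Iterator

import numpy as np
from scipy.optimize import brentq

from .pedigree import AFFECTED, UNAFFECTED, UNKNOWN, Pedigree

__all__ = [
    "MarkerMap",
    "DiseaseModel",
    "Replicate",
    "haldane_theta",
    "calibrate_penetrance",
    "draw_founder_haplotypes",
    "gene_drop",
    "assign_affection",
    "generate_replicates",
]

# default study conditions: 124 LD-free SNPs, 0.062 cM apart, MAF 0.2,
# prevalence = affected fraction among the genotyped template members
DEFAULT_N_LOCI = 124
DEFAULT_SPACING_CM = 0.062
DEFAULT_MAF = 0.2
DEFAULT_PREVALENCE = 106 / 798

# RNG stage tags (SeedSequence words) so every simulation stage is
# independently reproducible from (master_seed, replicate_index, stage)
_STAGE_FOUNDERS = 11
_STAGE_DROP = 13
_STAGE_AFFECTION = 17


def haldane_theta(d_cM: float | np.ndarray) -> float | np.ndarray:
    """Haldane map function: ``theta = (1 - exp(-2 d)) / 2`` with d in Morgans."""
    d = np.asarray(d_cM, dtype=float)
    if np.any(d < 0):
        raise ValueError("genetic distance must be >= 0")
    theta = 0.5 * (1.0 - np.exp(-2.0 * d / 100.0))
    return float(theta) if np.isscalar(d_cM) else theta


@dataclass(frozen=True)
class MarkerMap:
    """Ordered marker loci: (chromosome, name, position in cM)."""

    loci: tuple[tuple[int, str, float], ...]
    disease_locus: int | None = None

    def __post_init__(self) -> None:
        pos = [l[2] for l in self.loci]
        chrom = [l[0] for l in self.loci]
        for k in range(1, len(self.loci)):
            if chrom[k] == chrom[k - 1] and pos[k] <= pos[k - 1]:
                raise ValueError("positions must strictly increase within a chromosome")
        if self.disease_locus is not None and not (
            0 <= self.disease_locus < len(self.loci)
        ):
            raise ValueError("disease_locus out of range")

    @classmethod
    def uniform(
        cls,
        n_loci: int = DEFAULT_N_LOCI,
        spacing_cM: float = DEFAULT_SPACING_CM,
        chromosome: int = 1,
        disease_locus: int | None = None,
    ) -> "MarkerMap":
        loci = tuple(
            (chromosome, f"SNP{k + 1:03d}", k * spacing_cM) for k in range(n_loci)
        )
        return cls(loci, disease_locus=disease_locus)

    def __len__(self) -> int:
        return len(self.loci)

    @property
    def names(self) -> list[str]:
        return [l[1] for l in self.loci]

    @cached_property
    def thetas(self) -> np.ndarray:
        """Recombination fractions between adjacent loci (0.5 across
        chromosome boundaries)."""
        th = np.empty(max(len(self.loci) - 1, 0))
        for k in range(len(self.loci) - 1):
            c0, _, p0 = self.loci[k]
            c1, _, p1 = self.loci[k + 1]
            th[k] = haldane_theta(p1 - p0) if c0 == c1 else 0.5
        return th


def calibrate_penetrance(
    mode: str, odds_ratio: float, maf: float, prevalence: float
) -> tuple[float, float, float]:
    """Per-genotype penetrances (f0, f1, f2) for a given mode and effect
    size (applied as a genotype relative risk), with HWE-weighted mean
    penetrance equal to ``prevalence``."""
    if odds_ratio <= 0:
        raise ValueError("odds ratio must be positive")
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    mult = {
        "null": (0.0, 0.0, 0.0),
        "dominant": (0.0, 1.0, 1.0),
        "recessive": (0.0, 0.0, 1.0),
        "additive": (0.0, 1.0, 2.0),
    }.get(mode)
    if mult is None:
        raise ValueError(f"unknown mode {mode!r}")
    p = maf
    hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
    rr = odds_ratio ** np.asarray(mult)

    def fs(f0: float) -> np.ndarray:
        return np.minimum(f0 * rr, 1.0)

    def gap(f0: float) -> float:
        return float(hwe @ fs(f0)) - prevalence

    lo, hi = 1e-300, 1.0
    if gap(hi) < 0:
        raise ValueError("no penetrance root in (0, 1] for these parameters")
    f0 = brentq(gap, lo, hi, xtol=1e-15, rtol=1e-12)
    f = fs(f0)
    return float(f[0]), float(f[1]), float(f[2])


@dataclass(frozen=True)
class DiseaseModel:
    """Inheritance mode, effect size, and prevalence-calibrated penetrances.

    ``penetrances_override`` bypasses the calibration (useful for toy
    models with fixed per-genotype risks)."""

    mode: str = "null"
    odds_ratio: float = 1.0
    maf: float = DEFAULT_MAF
    prevalence: float = DEFAULT_PREVALENCE
    penetrances_override: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("null", "dominant", "recessive", "additive"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0 < self.maf < 1:
            raise ValueError("maf must be in (0, 1)")

    @cached_property
    def penetrances(self) -> tuple[float, float, float]:
        if self.penetrances_override is not None:
            return self.penetrances_override
        if self.mode == "null":
            k = self.prevalence
            return (k, k, k)
        return calibrate_penetrance(
            self.mode, self.odds_ratio, self.maf, self.prevalence
        )

    @classmethod
    def null(cls, maf: float = DEFAULT_MAF, prevalence: float = DEFAULT_PREVALENCE):
        return cls("null", 1.0, maf, prevalence)


@dataclass(frozen=True)
class Replicate:
    """One simulated dataset on the template.

    ``genotypes``: (n_members, n_loci) risk-allele counts, -1 where the
    member is not genotyped; ``phenotypes``: affection codes, unknown where
    the member is not phenotyped.  Row order is the pedigree's sorted id
    order.
    """

    ids: tuple[str, ...]
    genotypes: np.ndarray
    phenotypes: np.ndarray
    replicate_index: int
    master_seed: int

    def genotyped_rows(self) -> np.ndarray:
        return np.where((self.genotypes >= 0).any(axis=1))[0]

    def phenotyped_rows(self) -> np.ndarray:
        return np.where(self.phenotypes != UNKNOWN)[0]


class _DropPlan:
    """Precomputed generation-level index arrays for vectorized gene drops."""

    def __init__(self, pedigree: Pedigree):
        idx = {i: k for k, i in enumerate(pedigree.ids)}
        self.n = len(pedigree)
        self.founder_rows = np.array(
            [idx[i] for i in pedigree.founders], dtype=np.intp
        )
        levels: dict[int, list[str]] = {}
        for i in pedigree.nonfounders:
            levels.setdefault(pedigree.generation(i), []).append(i)
        self.levels = []
        for g in sorted(levels):
            ids = sorted(levels[g])
            self.levels.append(
                (
                    np.array([idx[i] for i in ids], dtype=np.intp),
                    np.array([idx[pedigree[i].father_id] for i in ids], dtype=np.intp),
                    np.array([idx[pedigree[i].mother_id] for i in ids], dtype=np.intp),
                )
            )


def _drop_plan(pedigree: Pedigree) -> _DropPlan:
    plan = getattr(pedigree, "_drop_plan", None)
    if plan is None:
        plan = _DropPlan(pedigree)
        pedigree._drop_plan = plan
    return plan


def draw_founder_haplotypes(
    n_founders: int,
    marker_map: MarkerMap,
    maf: float,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """(n_founders, 2, n_loci) int8 haplotypes, alleles iid Bernoulli(maf)."""
    if not 0 <= maf <= 1:
        raise ValueError("maf must be in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    return (rng.random((n_founders, 2, len(marker_map))) < maf).astype(np.int8)


def _drop_haplotypes(
    pedigree: Pedigree,
    founder_haplotypes: np.ndarray,
    marker_map: MarkerMap,
    rng: np.random.Generator,
) -> np.ndarray:
    plan = _drop_plan(pedigree)
    if founder_haplotypes.shape[0] != plan.founder_rows.size:
        raise ValueError("founder haplotype count does not match pedigree founders")
    n_loci = len(marker_map)
    theta = marker_map.thetas
    H = np.zeros((plan.n, 2, n_loci), dtype=np.int8)
    H[plan.founder_rows] = founder_haplotypes
    for child_rows, father_rows, mother_rows in plan.levels:
        m = child_rows.size
        for slot, parent_rows in ((0, father_rows), (1, mother_rows)):
            start = rng.integers(0, 2, size=(m, 1))
            if n_loci > 1:
                switch = rng.random((m, n_loci - 1)) < theta
                strand = np.concatenate([start, switch], axis=1).cumsum(axis=1) % 2
            else:
                strand = start
            ph = H[parent_rows]
            H[child_rows, slot] = np.where(strand == 0, ph[:, 0, :], ph[:, 1, :])
    return H


def gene_drop(
    pedigree: Pedigree,
    founder_haplotypes: np.ndarray,
    marker_map: MarkerMap,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Drop founder haplotypes through the pedigree.

    Returns the complete (n_members, n_loci) risk-allele-count matrix in
    sorted member order; masking to genotyped members happens later.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    H = _drop_haplotypes(pedigree, founder_haplotypes, marker_map, rng)
    return H.sum(axis=1, dtype=np.int8)


def assign_affection(
    genotypes: np.ndarray,
    model: DiseaseModel,
    template: Pedigree,
    marker_map: MarkerMap,
    rng: np.random.Generator | int,
) -> np.ndarray:
    """Phenotype vector for one replicate (sorted member order).

    Null model: the template's affection labels are copied verbatim, so
    every null replicate carries exactly the template's affection profile.
    Disease models: each template-phenotyped member is independently
    affected with probability ``f_g`` given its (unmasked) genotype at the
    disease locus; unphenotyped members stay unknown.
    """
    template_aff = np.array([ind.affection for ind in template], dtype=np.int8)
    if model.mode == "null":
        return template_aff
    if marker_map.disease_locus is None:
        raise ValueError("disease_locus must be set for a non-null model")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    f = np.array(model.penetrances)
    g = genotypes[:, marker_map.disease_locus].astype(np.intp)
    draw = rng.random(len(template_aff))
    phen = np.where(draw < f[g], AFFECTED, UNAFFECTED).astype(np.int8)
    phen[template_aff == UNKNOWN] = UNKNOWN
    return phen


def generate_replicates(
    template: Pedigree,
    marker_map: MarkerMap,
    model: DiseaseModel,
    n_reps: int,
    master_seed: int,
) -> Iterator[Replicate]:
    """Stream of masked replicates; per-replicate seeds derive
    deterministically from ``(master_seed, replicate_index, stage)``."""
    ids = tuple(template.ids)
    geno_mask = np.array([ind.genotyped for ind in template], dtype=bool)
    n_founders = len(template.founders)
    for rep in range(n_reps):
        rng_f = np.random.default_rng(
            np.random.SeedSequence([master_seed, rep, _STAGE_FOUNDERS])
        )
        rng_d = np.random.default_rng(
            np.random.SeedSequence([master_seed, rep, _STAGE_DROP])
        )
        rng_a = np.random.default_rng(
            np.random.SeedSequence([master_seed, rep, _STAGE_AFFECTION])
        )
        founders = draw_founder_haplotypes(n_founders, marker_map, model.maf, rng_f)
        geno = gene_drop(template, founders, marker_map, rng_d)
        phen = assign_affection(geno, model, template, marker_map, rng_a)
        geno = geno.copy()
        geno[~geno_mask] = -1
        yield Replicate(ids, geno, phen, rep, master_seed)
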