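"""Kinship-corrected quasi-likelihood score test for association.

The statistic tests a single SNP for case-control association in a sample
of arbitrarily related (and inbred) individuals, borrowing phenotype
information from ungenotyped relatives.  Let ``N`` be the genotyped set
(size n) and ``M`` the phenotyped-but-ungenotyped set.  With

* ``Y_i`` = (risk-allele count)/2 over ``N``,
* phenotype scores ``A_i`` = 1 (affected), ``-k/(1-k)`` (unaffected with
  assumed prevalence ``k``), 0 (unknown),
* ``K`` = 2 x kinship matrix (``K_ii = 1 + h_i``),

the test enriches the genotyped phenotype vector with its ungenotyped
relatives' scores,

    a~ = A_N + K_NM K_MM^-1 A_M,

estimates the allele frequency by quasi-likelihood (GLS),

    mu^ = (1' K_NN^-1 Y) / (1' K_NN^-1 1),      sigma^2 = mu^(1 - mu^)/2,

and forms the 1-df score statistic

    W = [a~' (Y - mu^ 1)]^2
        / ( sigma^2 [a~' K_NN a~ - (a~' 1)^2 / (1' K_NN^-1 1)] ),

referred to the upper tail of chi-square with one degree of freedom.  The
denominator is the exact gene-dropping-null variance of the numerator for
*any* enrichment vector built from phenotypes and pedigree structure, which
is what makes the type-1 error calibration robust.  Monomorphic loci are
flagged not-testable and excluded from tallies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.stats import chi2

from .pedigree import AFFECTED, UNAFFECTED, KinshipMatrix
from .simulate import Replicate

__all__ = [
    "AssociationInput",
    "AssociationResult",
    "MqlsEngine",
    "phenotype_scores",
    "mqls_statistic",
    "run_mqls_scan",
]

_JITTER = 1e-10


def phenotype_scores(affection: np.ndarray, prevalence: float) -> np.ndarray:
    """Map affection codes to scores 1 / -k(1-k)^-1 / 0."""
    if not 0 < prevalence < 1:
        raise ValueError("prevalence must be in (0, 1)")
    a = np.zeros(len(affection))
    a[affection == AFFECTED] = 1.0
    a[affection == UNAFFECTED] = -prevalence / (1.0 - prevalence)
    return a


@dataclass(frozen=True)
class AssociationInput:
    """Single-locus input: genotyped scores ``y`` (allele count / 2), scores
    ``a_n`` over the genotyped and ``a_m`` over the phenotyped-ungenotyped,
    and the corresponding kinship blocks on the K = 2*phi scale."""

    y: np.ndarray
    a_n: np.ndarray
    a_m: np.ndarray
    k_nn: np.ndarray
    k_nm: np.ndarray
    k_mm: np.ndarray
    locus: str = "locus"


@dataclass(frozen=True)
class AssociationResult:
    locus: str
    W: float
    p: float
    mu_hat: float
    testable: bool
    dof: int = 1


def _spd_solve(mat: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    """Solve an SPD system with Cholesky, retrying once with a tiny diagonal
    jitter; a second failure is an error."""
    try:
        c = cho_factor(mat, lower=True)
    except np.linalg.LinAlgError:
        warnings.warn("kinship block not positive definite; adding jitter")
        c = cho_factor(mat + _JITTER * np.eye(len(mat)), lower=True)
    return cho_solve(c, rhs)


def mqls_statistic(inp: AssociationInput) -> AssociationResult:
    """Evaluate the quasi-likelihood score statistic for one locus."""
    y, a_n = np.asarray(inp.y, float), np.asarray(inp.a_n, float)
    n = y.size
    ones = np.ones(n)
    if inp.a_m.size:
        atilde = a_n + inp.k_nm @ _spd_solve(inp.k_mm, np.asarray(inp.a_m, float))
    else:
        atilde = a_n
    u = _spd_solve(inp.k_nn, ones)
    s = float(ones @ u)
    mu = float(u @ y) / s
    asum = float(atilde @ ones)
    denom_quad = float(atilde @ inp.k_nn @ atilde) - asum**2 / s
    sigma2 = mu * (1.0 - mu) / 2.0
    if np.ptp(y) == 0.0 or sigma2 <= 0.0 or denom_quad <= 0.0:
        return AssociationResult(inp.locus, np.nan, np.nan, mu, False)
    num = float(atilde @ y) - mu * asum
    W = num**2 / (sigma2 * denom_quad)
    return AssociationResult(inp.locus, W, float(chi2.sf(W, 1)), mu, True)


class MqlsEngine:
    """Per-pedigree-structure factorizations, reused across loci/replicates.

    ``kinship`` must cover the genotyped and phenotyped member ids.  The
    engine fixes the genotyped order ``n_ids`` (sorted) and the
    phenotyped-ungenotyped order ``m_ids``; :meth:`scan` then only needs the
    per-locus genotype matrix and per-replicate affection codes.
    """

    def __init__(
        self,
        kinship: KinshipMatrix,
        genotyped_ids,
        phenotyped_ids,
        prevalence: float,
    ):
        if not 0 < prevalence < 1:
            raise ValueError("prevalence must be in (0, 1)")
        self.prevalence = prevalence
        self.n_ids = tuple(sorted(genotyped_ids))
        self.m_ids = tuple(sorted(set(phenotyped_ids) - set(self.n_ids)))
        K = kinship.K()
        ni = kinship.index(self.n_ids)
        self.k_nn = K[np.ix_(ni, ni)]
        n = len(self.n_ids)
        if self.m_ids:
            mi = kinship.index(self.m_ids)
            k_nm = K[np.ix_(ni, mi)]
            k_mm = K[np.ix_(mi, mi)]
            self.enrich = _spd_solve(k_mm, k_nm.T).T  # K_NM K_MM^-1
        else:
            self.enrich = np.zeros((n, 0))
        self.u = _spd_solve(self.k_nn, np.ones(n))
        self.s = float(self.u.sum())

    def scan(
        self,
        genotype_counts: np.ndarray,
        affection_n: np.ndarray,
        affection_m: np.ndarray,
        locus_names=None,
    ) -> list[AssociationResult]:
        """Test every locus of an (n_genotyped, n_loci) count matrix."""
        Y = np.asarray(genotype_counts, float).T / 2.0  # loci x n
        L = Y.shape[0]
        names = locus_names or [f"locus{k}" for k in range(L)]
        a_n = phenotype_scores(affection_n, self.prevalence)
        a_m = phenotype_scores(affection_m, self.prevalence)
        atilde = a_n + self.enrich @ a_m
        asum = atilde.sum()
        denom_quad = float(atilde @ self.k_nn @ atilde) - asum**2 / self.s
        mu = Y @ self.u / self.s
        sigma2 = mu * (1.0 - mu) / 2.0
        num = Y @ atilde - mu * asum
        testable = (np.ptp(Y, axis=1) > 0) & (sigma2 > 0) & (denom_quad > 0)
        with np.errstate(divide="ignore", invalid="ignore"):
            W = np.where(testable, num**2 / (sigma2 * denom_quad), np.nan)
            P = np.where(testable, chi2.sf(W, 1), np.nan)
        return [
            AssociationResult(names[k], float(W[k]), float(P[k]), float(mu[k]), bool(testable[k]))
            for k in range(L)
        ]

    def scan_replicate(self, replicate: Replicate, locus_names=None) -> list[AssociationResult]:
        rows = {i: k for k, i in enumerate(replicate.ids)}
        n_rows = np.array([rows[i] for i in self.n_ids], dtype=np.intp)
        m_rows = np.array([rows[i] for i in self.m_ids], dtype=np.intp)
        geno = replicate.genotypes[n_rows]
        if (geno < 0).any():
            raise ValueError("replicate is missing genotypes for engine members")
        return self.scan(
            geno,
            replicate.phenotypes[n_rows],
            replicate.phenotypes[m_rows] if m_rows.size else np.empty(0, np.int8),
            locus_names,
        )


_ENGINE_CACHE: dict[tuple, MqlsEngine] = {}


def run_mqls_scan(
    replicate: Replicate,
    kinship: KinshipMatrix,
    prevalence: float,
    locus_names=None,
) -> list[AssociationResult]:
    """Scan every testable locus of a replicate.

    The genotyped set is read off the replicate's missingness mask and the
    phenotyped set off its affection codes; ``kinship`` must cover both.
    Engine factorizations are cached per (kinship, prevalence) so repeated
    scans over the same structure are cheap.
    """
    ids = np.asarray(replicate.ids)
    n_ids = tuple(ids[replicate.genotyped_rows()])
    m_ids = tuple(i for i in ids[replicate.phenotyped_rows()] if i not in set(n_ids))
    missing = [i for i in (*n_ids, *m_ids) if i not in set(kinship.ids)]
    if missing:
        raise ValueError(
            f"kinship matrix does not cover replicate members, e.g. {missing[0]!r}"
        )
    key = (id(kinship), n_ids, m_ids, prevalence)
    engine = _ENGINE_CACHE.get(key)
    if engine is None:
        _ENGINE_CACHE.clear()
        engine = MqlsEngine(kinship, n_ids, m_ids, prevalence)
        _ENGINE_CACHE[key] = engine
    return engine.scan_replicate(replicate, locus_names)
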