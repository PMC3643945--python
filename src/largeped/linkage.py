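"""Two-point parametric linkage by exact pedigree likelihood.

The likelihood couples a biallelic trait locus (disease allele D at
frequency ``q``) to one observed biallelic marker through a recombination
fraction ``theta``.  Each individual's latent state is an *ordered pair of
two-locus haplotypes* (paternal, maternal), 4 haplotypes x 4 = 16 states:
founders draw haplotypes at population frequencies (HWE, linkage
equilibrium), a parent transmits a gamete whose trait and marker alleles
come from the same parental strand with probability ``1 - theta``, the
trait penetrance acts on the count of D alleles, and the marker penetrance
is the indicator that the state's alleles match the observed genotype
(missing observations contribute 1).

The joint likelihood is evaluated exactly by sum-product variable
elimination over individuals (greedy min-fill order), which performs the
same constrained summation as classical peeling with duplicated loop
breakers but handles consanguineous loops natively.  All products are
accumulated with running rescaling, so the result is a log-likelihood and a
structurally impossible configuration (Mendelian-inconsistent marker data)
comes back as ``-inf`` rather than underflow.

The two-point score of a marker is the trait-at-marker convention:
``Z = log10 L(theta=0) - log10 L(theta=1/2)`` per sub-pedigree, summed into
a LOD, with the admixture HLOD ``max_alpha sum_i log10(alpha 10^{Z_i} +
1 - alpha)`` maximized on a grid plus golden-section refinement.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .pedigree import AFFECTED, UNAFFECTED, Pedigree
from .simulate import Replicate
from .split import SubpedigreeSet

__all__ = [
    "LinkageModel",
    "LinkageResult",
    "pedigree_loglik10",
    "twopoint_lod",
    "hlod",
]

_LN10 = math.log(10.0)
_MAX_STATE_EVALS = 10**8


@dataclass(frozen=True)
class LinkageModel:
    """Parametric trait model: disease allele frequency and penetrances by
    number of disease-allele copies.  The defaults are affecteds-only
    near-zero penetrances, which make unaffected phenotypes effectively
    uninformative (their likelihood factor is ``1 - f ~ 1``)."""

    mode: str
    disease_allele_freq: float = 0.01
    penetrances: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("dominant", "recessive"):
            raise ValueError(f"unknown linkage mode {self.mode!r}")
        if not 0 < self.disease_allele_freq < 1:
            raise ValueError("disease allele frequency must be in (0, 1)")
        if self.penetrances is None:
            pen = (
                (0.0, 0.0001, 0.0001)
                if self.mode == "dominant"
                else (0.0, 0.0, 0.0001)
            )
            object.__setattr__(self, "penetrances", pen)
        if any(not 0 <= f <= 1 for f in self.penetrances):
            raise ValueError("penetrances must lie in [0, 1]")

    @classmethod
    def dominant(cls, q: float = 0.01) -> "LinkageModel":
        return cls("dominant", q)

    @classmethod
    def recessive(cls, q: float = 0.01) -> "LinkageModel":
        return cls("recessive", q)


@dataclass(frozen=True)
class LinkageResult:
    marker: str
    z: tuple[float, ...]
    lod: float
    hlod: float
    alpha_hat: float


# -- state space ------------------------------------------------------------
# haplotype index h in 0..3 encodes (trait_allele << 1) | marker_allele with
# trait allele 1 = D and marker allele 1 = the counted ("2") allele; a state
# s in 0..15 is the ordered pair (paternal hap s // 4, maternal hap s % 4).

_PAT = np.arange(16) // 4
_MAT = np.arange(16) % 4
_N_DISEASE = (_PAT >> 1) + (_MAT >> 1)
_N_MARKER = (_PAT & 1) + (_MAT & 1)


def _hap_freqs(q: float, marker_freq: float) -> np.ndarray:
    return np.array(
        [
            (1 - q) * (1 - marker_freq),
            (1 - q) * marker_freq,
            q * (1 - marker_freq),
            q * marker_freq,
        ]
    )


@lru_cache(maxsize=64)
def _gamete_probs(theta: float) -> np.ndarray:
    """(16, 4) matrix: P(gamete haplotype | parent state)."""
    gam = np.zeros((16, 4))
    for s in range(16):
        hp, hm = s // 4, s % 4
        for (t_src, m_src), w in (
            ((hp, hp), (1 - theta) / 2),
            ((hp, hm), theta / 2),
            ((hm, hm), (1 - theta) / 2),
            ((hm, hp), theta / 2),
        ):
            g = (t_src & 2) | (m_src & 1)
            gam[s, g] += w
    return gam


@lru_cache(maxsize=64)
def _transmission(theta: float) -> np.ndarray:
    """(16, 16, 16) tensor: P(child state | father state, mother state)."""
    gam = _gamete_probs(theta)
    return gam[:, None, _PAT] * gam[None, :, _MAT]


def _evidence(model: LinkageModel, affection: int, marker_count: int | None) -> np.ndarray:
    """Per-individual factor over the 16 states: trait penetrance ``f`` for
    affecteds, ``1 - f`` for unaffecteds (with near-zero affecteds-only
    penetrances this is effectively uninformative), 1 for unknowns, times
    the marker observation indicator."""
    ev = np.ones(16)
    pen = np.asarray(model.penetrances)
    if affection == AFFECTED:
        ev = ev * pen[_N_DISEASE]
    elif affection == UNAFFECTED:
        ev = ev * (1.0 - pen[_N_DISEASE])
    if marker_count is not None and marker_count >= 0:
        ev = ev * (_N_MARKER == marker_count)
    return ev


# -- variable elimination ---------------------------------------------------


def _elim_order(scopes: list[tuple[int, ...]], n_vars: int) -> list[int]:
    """Greedy min-fill elimination order over the factor interaction graph."""
    neigh: dict[int, set[int]] = {v: set() for v in range(n_vars)}
    for sc in scopes:
        for v in sc:
            neigh[v].update(u for u in sc if u != v)
    order: list[int] = []
    active = set(range(n_vars))
    while active:
        best = None
        for v in sorted(active):
            nb = neigh[v] & active
            fill = sum(
                1
                for a in nb
                for b in nb
                if a < b and b not in neigh[a]
            )
            cand = (fill, len(nb), v)
            if best is None or cand < best:
                best = cand
        v = best[2]
        nb = neigh[v] & active
        for a in nb:
            neigh[a].update(b for b in nb if b != a)
        active.discard(v)
        order.append(v)
    return order


def _eliminate(factors: list[tuple[tuple[int, ...], np.ndarray]], n_vars: int, n_states: int) -> float:
    """Sum out all variables; returns log10 of the total sum (-inf if zero)."""
    order = _elim_order([sc for sc, _ in factors], n_vars)
    # cost guard before doing any heavy work
    cost = 0
    neigh: dict[int, set[int]] = {v: set() for v in range(n_vars)}
    for sc, _ in factors:
        for v in sc:
            neigh[v].update(u for u in sc if u != v)
    active = set(range(n_vars))
    for v in order:
        nb = neigh[v] & active
        cost += n_states ** (len(nb) + 1)
        for a in nb:
            neigh[a].update(b for b in nb if b != a)
        active.discard(v)
        if cost > _MAX_STATE_EVALS:
            raise ValueError(
                "pedigree too complex for exact peeling "
                f"(> {_MAX_STATE_EVALS:.0e} state evaluations)"
            )

    log10_scale = 0.0
    pool = list(factors)
    for v in order:
        group = [f for f in pool if v in f[0]]
        pool = [f for f in pool if v not in f[0]]
        scope = sorted(set().union(*(set(sc) for sc, _ in group)))
        prod = np.ones((n_states,) * len(scope))
        for sc, arr in group:
            perm = sorted(range(len(sc)), key=lambda k: scope.index(sc[k]))
            a = np.transpose(arr, perm)
            shape = [n_states if u in sc else 1 for u in scope]
            prod = prod * a.reshape(shape)
        axis = scope.index(v)
        summed = prod.sum(axis=axis)
        peak = float(summed.max()) if summed.size else float(summed)
        if peak <= 0.0:
            return -np.inf
        log10_scale += math.log10(peak)
        summed = summed / peak
        new_scope = tuple(u for u in scope if u != v)
        pool.append((new_scope, summed))
    rest = 1.0
    for _, arr in pool:
        rest *= float(arr)
    if rest <= 0.0:
        return -np.inf
    return log10_scale + math.log10(rest)


def _build_factors(
    pedigree: Pedigree,
    marker_counts: dict[str, int],
    marker_freq: float,
    model: LinkageModel,
    theta: float,
) -> tuple[list[tuple[tuple[int, ...], np.ndarray]], int]:
    idx = {i: k for k, i in enumerate(pedigree.ids)}
    hap = _hap_freqs(model.disease_allele_freq, marker_freq)
    prior = hap[_PAT] * hap[_MAT]
    T = _transmission(theta)
    factors: list[tuple[tuple[int, ...], np.ndarray]] = []
    for ind in pedigree:
        ev = _evidence(model, ind.affection, marker_counts.get(ind.id))
        v = idx[ind.id]
        if ind.is_founder:
            factors.append(((v,), prior * ev))
        else:
            f, m = idx[ind.father_id], idx[ind.mother_id]
            factors.append(((f, m, v), T * ev[None, None, :]))
    return factors, len(pedigree)


def pedigree_loglik10(
    pedigree: Pedigree,
    marker_counts: dict[str, int],
    marker_freq: float,
    model: LinkageModel,
    theta: float,
) -> float:
    """log10 joint likelihood of affection and observed marker genotypes.

    ``marker_counts`` maps member id -> risk-allele count (0/1/2); omitted
    or negative entries mean unobserved.  ``theta`` is the trait-marker
    recombination fraction in [0, 1/2].  Mendelian-inconsistent data give
    ``-inf``.
    """
    if not 0.0 <= theta <= 0.5:
        raise ValueError("theta must be in [0, 1/2]")
    if not 0.0 < marker_freq < 1.0:
        raise ValueError("marker allele frequency must be in (0, 1)")
    factors, n = _build_factors(pedigree, marker_counts, marker_freq, model, theta)
    return _eliminate(factors, n, 16)


def hlod(z_scores) -> tuple[float, float]:
    """Heterogeneity LOD: maximize ``sum log10(alpha 10^z + 1 - alpha)`` over
    the admixture proportion alpha in [0, 1] (coarse grid, then one
    golden-section refinement).  Returns (hlod, alpha_hat)."""
    z = np.asarray([s for s in z_scores if np.isfinite(s)], dtype=float)
    if z.size == 0:
        return 0.0, 0.0

    ln = z * _LN10

    def obj(alpha: float) -> float:
        if alpha <= 0.0:
            return 0.0
        if alpha >= 1.0:
            return float(z.sum())
        return float(
            np.logaddexp(math.log(alpha) + ln, math.log1p(-alpha)).sum() / _LN10
        )

    grid = np.linspace(0.0, 1.0, 101)
    vals = [obj(a) for a in grid]
    k = int(np.argmax(vals))
    lo, hi = grid[max(k - 1, 0)], grid[min(k + 1, 100)]
    invphi = (math.sqrt(5.0) - 1.0) / 2.0
    a, b = lo, hi
    c, d = b - invphi * (b - a), a + invphi * (b - a)
    fc, fd = obj(c), obj(d)
    for _ in range(60):
        if fc >= fd:
            b, d, fd = d, c, fc
            c = b - invphi * (b - a)
            fc = obj(c)
        else:
            a, c, fc = c, d, fd
            d = a + invphi * (b - a)
            fd = obj(d)
    alpha = 0.5 * (a + b)
    best, alpha_hat = max((vals[k], grid[k]), (obj(alpha), alpha))
    if best < 1e-12:  # numerical floor: HLOD is 0 at alpha = 0 by definition
        return 0.0, 0.0
    return float(best), float(alpha_hat)


# -- single-locus peels for the factorized theta = 1/2 likelihood ----------
# at theta = 1/2 the two loci segregate independently, so
# L = (trait-only likelihood) x (marker-only likelihood) on any pedigree;
# both pieces are 4-state (ordered allele pair) single-locus peels.

_SL_PAT = np.arange(4) // 2
_SL_MAT = np.arange(4) % 2
_SL_COUNT = _SL_PAT + _SL_MAT
_SL_GAM = 0.5 * (
    (_SL_PAT[:, None] == np.arange(2)[None, :]).astype(float)
    + (_SL_MAT[:, None] == np.arange(2)[None, :]).astype(float)
)
_SL_TRANS = _SL_GAM[:, None, _SL_PAT] * _SL_GAM[None, :, _SL_MAT]


def _single_locus_loglik10(
    pedigree: Pedigree, allele_freq: float, evidence: dict[str, np.ndarray]
) -> float:
    idx = {i: k for k, i in enumerate(pedigree.ids)}
    hap = np.array([1.0 - allele_freq, allele_freq])
    prior = hap[_SL_PAT] * hap[_SL_MAT]
    factors: list[tuple[tuple[int, ...], np.ndarray]] = []
    for ind in pedigree:
        ev = evidence.get(ind.id, np.ones(4))
        v = idx[ind.id]
        if ind.is_founder:
            factors.append(((v,), prior * ev))
        else:
            f, m = idx[ind.father_id], idx[ind.mother_id]
            factors.append(((f, m, v), _SL_TRANS * ev[None, None, :]))
    return _eliminate(factors, len(pedigree), 4)


_TRAIT_CACHE: dict[tuple, float] = {}


def _trait_only_loglik10(sub: Pedigree, model: LinkageModel) -> float:
    key = (id(sub), model)
    if key not in _TRAIT_CACHE:
        if len(_TRAIT_CACHE) > 4096:
            _TRAIT_CACHE.clear()
        pen = np.asarray(model.penetrances)
        evidence = {}
        for ind in sub:
            if ind.affection == AFFECTED:
                evidence[ind.id] = pen[_SL_COUNT]
            elif ind.affection == UNAFFECTED:
                evidence[ind.id] = 1.0 - pen[_SL_COUNT]
        _TRAIT_CACHE[key] = _single_locus_loglik10(
            sub, model.disease_allele_freq, evidence
        )
    return _TRAIT_CACHE[key]


def _marker_only_loglik10(
    sub: Pedigree, counts: dict[str, int], marker_freq: float
) -> float:
    evidence = {
        i: (_SL_COUNT == g).astype(float) for i, g in counts.items() if g >= 0
    }
    return _single_locus_loglik10(sub, marker_freq, evidence)


def twopoint_lod(
    subs: SubpedigreeSet,
    replicate: Replicate,
    marker: int,
    model: LinkageModel,
    marker_freq: float = 0.2,
    marker_name: str | None = None,
) -> LinkageResult:
    """Two-point score of one marker over every sub-pedigree.

    Per sub-pedigree ``Z_i = log10 L(theta=0) - log10 L(theta=1/2)``; the
    ``theta = 1/2`` term factorizes into (trait-only) x (marker-only), with
    the trait-only part cached per sub-pedigree and model.  ``LOD = sum Z_i``
    and the HLOD maximizes the admixture mixture over alpha.
    """
    rows = {i: k for k, i in enumerate(replicate.ids)}
    zs: list[float] = []
    for sub in subs.subpedigrees:
        counts = {}
        for i in sub.ids:
            g = int(replicate.genotypes[rows[i], marker]) if i in rows else -1
            if g >= 0:
                counts[i] = g
        if not counts:
            zs.append(0.0)
            continue
        ll0 = pedigree_loglik10(sub, counts, marker_freq, model, 0.0)
        ll_half = _trait_only_loglik10(sub, model) + _marker_only_loglik10(
            sub, counts, marker_freq
        )
        if not np.isfinite(ll0) or not np.isfinite(ll_half):
            raise ValueError(
                f"Mendelian-inconsistent marker data in sub-pedigree "
                f"{sub.family_id} at marker {marker}"
            )
        zs.append(ll0 - ll_half)
    h, alpha = hlod(zs)
    return LinkageResult(
        marker_name or f"locus{marker}",
        tuple(zs),
        float(sum(zs)),
        h,
        alpha,
    )
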