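"""Synthesize large, deep, consanguineous template pedigrees.

The generator emulates the sampling profile of a founder-population isolate
cohort: one connected multi-generation pedigree (default 13 generations,
~4,998 members) with cousin-marriage loops, in which a recent-generation
subset is genotyped (default 798), a subset of the genotyped is labelled
affected (default 106), and some ungenotyped relatives carry known
phenotypes.  The template carries the *sampling frame* — which members have
genotype and phenotype data and a fixed affection label pattern — while
genotypes themselves are simulated later by gene dropping.

Mechanics: founder couples seed generation 0; each later generation's size
follows a geometric growth profile solved so the expected total matches
``target_members``; children are allocated to couples with gamma-weighted
multinomial draws (negative-binomial-like family sizes, every couple gets at
least one child); and each new couple marries either a fresh founder or,
with probability ``consanguinity_rate``, a same-generation pedigree member
of kinship at most 1/8 (cousin class — sib and avuncular matings are
excluded by the kinship cap), which is what creates inbreeding loops.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .pedigree import (
    AFFECTED,
    FEMALE,
    MALE,
    UNAFFECTED,
    UNKNOWN,
    Individual,
    Pedigree,
)

__all__ = ["TemplateParams", "InfeasibleTemplateError", "generate_template"]


class InfeasibleTemplateError(ValueError):
    """The requested template profile cannot be generated."""


# probability that a non-consanguineous marriage is to an unrelated member
# of the pedigree rather than a new founder; keeps distinct founder lineages
# connected into a single pedigree.
_WITHIN_UNRELATED_RATE = 0.15


@dataclass(frozen=True)
class TemplateParams:
    """Knobs of the template profile.

    Defaults reproduce the target cohort profile: 13 generations, ~4,998
    members, 798 genotyped sampled from the last three generations, 106 of
    the genotyped affected, plus 100 ungenotyped members with known
    (unaffected) phenotypes who let the association test borrow phenotype
    information from ungenotyped relatives.
    """

    n_generations: int = 13
    n_founder_couples: int = 2
    mean_offspring: float = 3.0
    offspring_dispersion: float = 2.0
    consanguinity_rate: float = 0.2
    target_members: int = 4998
    n_genotyped: int = 798
    n_affected_template: int = 106
    n_phenotyped_ungenotyped: int = 100
    unknown_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.consanguinity_rate <= 1.0:
            raise InfeasibleTemplateError("consanguinity_rate must be in [0, 1]")
        if not (
            self.n_affected_template <= self.n_genotyped <= self.target_members
        ):
            raise InfeasibleTemplateError(
                "need n_affected_template <= n_genotyped <= target_members"
            )
        if self.n_generations < 1 or self.n_founder_couples < 1:
            raise InfeasibleTemplateError("need >=1 generation and founder couple")

    def scaled(self, factor: float, n_generations: int | None = None, seed: int | None = None) -> "TemplateParams":
        """Shrink the whole profile by ``factor`` (for desk-scale runs)."""
        return replace(
            self,
            n_generations=n_generations or self.n_generations,
            target_members=max(20, round(self.target_members * factor)),
            n_genotyped=max(8, round(self.n_genotyped * factor)),
            n_affected_template=max(2, round(self.n_affected_template * factor)),
            n_phenotyped_ungenotyped=max(2, round(self.n_phenotyped_ungenotyped * factor)),
            seed=self.seed if seed is None else seed,
        )


def _expected_total(r: float, c1: float, p: TemplateParams) -> float:
    """Expected member count for growth ratio ``r`` and first-generation
    brood size ``c1`` (children + in-marrying founder spouses + gen 0)."""
    g = p.n_generations
    children = sum(c1 * r ** (k - 1) for k in range(1, g))
    p_new_founder = (1 - p.consanguinity_rate) * (1 - _WITHIN_UNRELATED_RATE)
    couples = sum(c1 * r**k / p.mean_offspring for k in range(1, g - 1))
    return 2 * p.n_founder_couples + children + couples * p_new_founder


def _solve_growth(p: TemplateParams) -> tuple[float, float]:
    """Growth ratio (bisection) and base brood size hitting ~1.06x the
    target; the slight overshoot is trimmed from the last generation."""
    goal = 1.06 * p.target_members
    c1 = p.n_founder_couples * p.mean_offspring
    lo, hi = 0.6, 4.0
    if _expected_total(lo, c1, p) > goal:
        r = lo
    elif _expected_total(hi, c1, p) < goal:
        r = hi
    else:
        for _ in range(80):
            mid = 0.5 * (lo + hi)
            if _expected_total(mid, c1, p) < goal:
                lo = mid
            else:
                hi = mid
        r = 0.5 * (lo + hi)
    # residual scale when r alone cannot reach the target (few generations);
    # only the descendant part scales with c1, not generation 0
    gen0 = 2 * p.n_founder_couples
    scale = (goal - gen0) / max(_expected_total(r, c1, p) - gen0, 1e-9)
    if not 0.2 <= scale <= 5.0:
        raise InfeasibleTemplateError(
            "target_members unreachable with this generation count"
        )
    return r, c1 * scale


class _Builder:
    """Mutable state while growing one pedigree attempt."""

    def __init__(self, params: TemplateParams, rng: np.random.Generator):
        self.p = params
        self.rng = rng
        cap = int(1.4 * 1.06 * params.target_members) + 256
        self.phi = np.zeros((cap, cap), dtype=np.float32)
        self.sex = np.zeros(cap, dtype=np.int8)
        self.father = np.full(cap, -1, dtype=np.int64)
        self.mother = np.full(cap, -1, dtype=np.int64)
        self.generation = np.zeros(cap, dtype=np.int64)
        self.n = 0

    def _grow(self) -> None:
        cap = self.phi.shape[0]
        new = int(cap * 1.3) + 64
        phi = np.zeros((new, new), dtype=np.float32)
        phi[:cap, :cap] = self.phi
        self.phi = phi
        for name in ("sex", "father", "mother", "generation"):
            arr = getattr(self, name)
            fill = -1 if name in ("father", "mother") else 0
            ext = np.full(new, fill, dtype=arr.dtype)
            ext[:cap] = arr
            setattr(self, name, ext)

    def add(self, sex: int, gen: int, father: int = -1, mother: int = -1) -> int:
        if self.n >= self.phi.shape[0]:
            self._grow()
        k = self.n
        self.n += 1
        self.sex[k] = sex
        self.father[k] = father
        self.mother[k] = mother
        self.generation[k] = gen
        if father < 0:
            self.phi[k, k] = 0.5
        else:
            row = 0.5 * (self.phi[father, :k] + self.phi[mother, :k])
            self.phi[k, :k] = row
            self.phi[:k, k] = row
            self.phi[k, k] = 0.5 * (1.0 + self.phi[father, mother])
        return k


def _build_structure(params: TemplateParams, rng: np.random.Generator) -> _Builder:
    p = params
    r, c1 = _solve_growth(p)
    b = _Builder(p, rng)
    couples: list[tuple[int, int]] = []
    for _ in range(p.n_founder_couples):
        f = b.add(MALE, 0)
        m = b.add(FEMALE, 0)
        couples.append((f, m))
    for g in range(1, p.n_generations):
        target_children = max(len(couples), round(c1 * r ** (g - 1)))
        weights = rng.gamma(p.offspring_dispersion, size=len(couples)) + 1e-9
        extra = rng.multinomial(target_children - len(couples), weights / weights.sum())
        gen_members: list[int] = []
        for (f, m), cnt in zip(couples, 1 + extra):
            for _ in range(cnt):
                sex = MALE if rng.random() < 0.5 else FEMALE
                gen_members.append(b.add(sex, g, f, m))
        if g == p.n_generations - 1:
            break
        n_couples = max(1, round(c1 * r**g / p.mean_offspring))
        couples = _form_couples(b, gen_members, g, n_couples, rng)
    return b


def _form_couples(
    b: _Builder,
    gen_members: list[int],
    gen: int,
    n_couples: int,
    rng: np.random.Generator,
) -> list[tuple[int, int]]:
    p = b.p
    pool = list(gen_members)
    rng.shuffle(pool)
    married: set[int] = set()
    couples: list[tuple[int, int]] = []
    for x in pool:
        if len(couples) >= n_couples:
            break
        if x in married:
            continue
        partner = -1
        cands = np.array(
            [y for y in gen_members if y not in married and y != x and b.sex[y] != b.sex[x]],
            dtype=np.int64,
        )
        if cands.size:
            phis = b.phi[x, cands]
            if rng.random() < p.consanguinity_rate:
                related = cands[(phis > 0) & (phis <= 0.125 + 1e-9)]
                unrelated = cands[phis == 0]
                if related.size:
                    partner = int(rng.choice(np.sort(related)))
                elif unrelated.size:
                    partner = int(rng.choice(np.sort(unrelated)))
            elif rng.random() < _WITHIN_UNRELATED_RATE:
                unrelated = cands[phis == 0]
                if unrelated.size:
                    partner = int(rng.choice(np.sort(unrelated)))
        if partner < 0:
            partner = b.add(FEMALE if b.sex[x] == MALE else MALE, gen)
        married.update((x, partner))
        couple = (x, partner) if b.sex[x] == MALE else (partner, x)
        couples.append(couple)
    return couples


def _truncate(b: _Builder, rng: np.random.Generator) -> np.ndarray:
    """Keep member rows; drop surplus last-generation children (never the
    last child of a couple, so no spouse is orphaned).  Returns kept rows."""
    p = b.p
    keep = np.ones(b.n, dtype=bool)
    excess = b.n - p.target_members
    if excess > 0:
        last = p.n_generations - 1
        rows = np.where((b.generation[: b.n] == last) & (b.father[: b.n] >= 0))[0]
        fam_count: dict[tuple[int, int], int] = {}
        for i in rows:
            key = (int(b.father[i]), int(b.mother[i]))
            fam_count[key] = fam_count.get(key, 0) + 1
        order = rng.permutation(rows)
        removed = 0
        for i in order:
            if removed >= excess:
                break
            key = (int(b.father[i]), int(b.mother[i]))
            if fam_count[key] > 1:
                fam_count[key] -= 1
                keep[i] = False
                removed += 1
    return np.where(keep)[0]


def generate_template(params: TemplateParams) -> Pedigree:
    """Generate one connected template pedigree matching ``params``.

    The same seed always yields the identical pedigree.  Raises
    :class:`InfeasibleTemplateError` when the sampling profile cannot be
    satisfied (e.g. more genotyped members requested than the last three
    generations contain).
    """
    p = params
    for attempt in range(20):
        rng = np.random.default_rng(np.random.SeedSequence([p.seed, attempt]))
        b = _build_structure(p, rng)
        rows = _truncate(b, rng)
        ped = _assemble(b, rows, rng)
        if ped.is_connected():
            return ped
    raise InfeasibleTemplateError(
        "could not generate a connected pedigree for these parameters"
    )


def _assemble(b: _Builder, rows: np.ndarray, rng: np.random.Generator) -> Pedigree:
    p = b.p
    total = rows.size
    if total < round(0.9 * p.target_members):
        raise InfeasibleTemplateError(
            f"generated {total} members, short of target {p.target_members}"
        )
    width = max(5, len(str(b.n)))
    ids = {int(i): f"I{int(i):0{width}d}" for i in rows}

    last3 = rows[b.generation[rows] >= p.n_generations - 3]
    need = p.n_genotyped + p.n_phenotyped_ungenotyped
    if last3.size < need:
        raise InfeasibleTemplateError(
            f"last three generations hold {last3.size} members, "
            f"need {need} for genotype/phenotype sampling"
        )
    last3 = np.sort(last3)
    picked = rng.choice(last3, size=need, replace=False)
    genotyped = set(int(i) for i in picked[: p.n_genotyped])
    pheno_ungeno = set(int(i) for i in picked[p.n_genotyped :])

    geno_sorted = np.sort(np.array(list(genotyped)))
    affected = set(
        int(i) for i in rng.choice(geno_sorted, size=p.n_affected_template, replace=False)
    )
    rest = np.sort(np.array([i for i in geno_sorted if i not in affected]))
    n_unknown = round(p.unknown_fraction * rest.size)
    unknown_aff = (
        set(int(i) for i in rng.choice(rest, size=n_unknown, replace=False))
        if n_unknown
        else set()
    )

    members = []
    for i in rows:
        i = int(i)
        if i in affected:
            aff = AFFECTED
        elif (i in genotyped and i not in unknown_aff) or i in pheno_ungeno:
            aff = UNAFFECTED
        else:
            aff = UNKNOWN
        fa, mo = int(b.father[i]), int(b.mother[i])
        members.append(
            Individual(
                id=ids[i],
                father_id=ids[fa] if fa >= 0 else None,
                mother_id=ids[mo] if mo >= 0 else None,
                sex=int(b.sex[i]),
                affection=aff,
                genotyped=i in genotyped,
            )
        )
    return Pedigree(members)
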