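"""Pedigree data model, structural validation, bit size, and kinship.

A pedigree is a directed acyclic family structure.  Members without parents
in the structure are *founders*; everyone else is a *non-founder* and must
have both parents present.  Two quantities defined here drive everything
downstream:

* the **bit size** ``b = 2 * n_nonfounders - n_founders``, the standard
  complexity measure for exact linkage algorithms (each non-founder
  contributes two meiosis indicators, each founder genotype can be summed
  out), and

* the **kinship coefficient** ``phi(i, j)``, the probability that a random
  allele drawn from *i* is identical by descent to a random allele drawn
  from *j*.  The inbreeding coefficient of an individual is the kinship of
  its parents, ``h_i = phi(father_i, mother_i)``, and ``phi(i, i) =
  (1 + h_i) / 2``.

Kinship is computed by the classic recursion evaluated in topological
order (parents before children), which is exact on pedigrees with
consanguineous loops:

* founders: ``phi(i, i) = 1/2`` and ``phi(i, j) = 0`` for any earlier *j*;
* non-founder *i* with parents *(f, m)* and *j* preceding *i* in
  topological order: ``phi(i, j) = (phi(f, j) + phi(m, j)) / 2``;
* ``phi(i, i) = (1 + phi(f, m)) / 2``.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np

__all__ = [
    "MALE",
    "FEMALE",
    "UNKNOWN",
    "UNAFFECTED",
    "AFFECTED",
    "PedigreeError",
    "DuplicateIdError",
    "UnknownParentError",
    "SingleParentError",
    "SexInconsistentError",
    "CyclicAncestryError",
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "bit_size",
    "kinship",
]

# sex codes (LINKAGE convention)
MALE = 1
FEMALE = 2

# affection codes (LINKAGE convention)
UNKNOWN = 0
UNAFFECTED = 1
AFFECTED = 2


class PedigreeError(ValueError):
    """Base class for structural pedigree errors."""


class DuplicateIdError(PedigreeError):
    """Two members share the same id."""


class UnknownParentError(PedigreeError):
    """A parent id does not resolve to a member."""


class SingleParentError(PedigreeError):
    """A record lists exactly one parent."""


class SexInconsistentError(PedigreeError):
    """A father is not male or a mother is not female."""


class CyclicAncestryError(PedigreeError):
    """An individual is its own ancestor."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``father_id`` and ``mother_id`` are both ``None`` (founder) or both set.
    ``phenotyped`` defaults to ``affection != UNKNOWN``; an individual whose
    affection is unknown is never phenotyped and vice versa.  ``genotyped``
    is independent of phenotype status: a genotyped member may still have
    unknown affection.
    """

    id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: int = MALE
    affection: int = UNKNOWN
    genotyped: bool = False
    phenotyped: bool | None = None

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise SingleParentError(
                f"individual {self.id!r} lists exactly one parent"
            )
        if self.sex not in (MALE, FEMALE):
            raise PedigreeError(f"individual {self.id!r}: bad sex code {self.sex}")
        if self.affection not in (UNKNOWN, UNAFFECTED, AFFECTED):
            raise PedigreeError(
                f"individual {self.id!r}: bad affection code {self.affection}"
            )
        if self.phenotyped is None:
            object.__setattr__(self, "phenotyped", self.affection != UNKNOWN)
        elif self.phenotyped != (self.affection != UNKNOWN):
            raise PedigreeError(
                f"individual {self.id!r}: phenotyped flag inconsistent with "
                f"affection code (unknown affection <=> not phenotyped)"
            )

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


class Pedigree:
    """A validated collection of :class:`Individual` keyed by id.

    Validation performed on construction: unique ids, resolvable parent
    references with consistent sex, no single-parent records (enforced per
    individual), and acyclic ancestry.  Member order everywhere is
    lexicographic by id, which makes all downstream output deterministic.
    """

    def __init__(self, members: Iterable[Individual], family_id: str = "F1"):
        self.family_id = family_id
        self._members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self._members:
                raise DuplicateIdError(f"duplicated id {ind.id!r}")
            self._members[ind.id] = ind
        self._members = dict(sorted(self._members.items()))
        self._validate()
        self._index = {i: k for k, i in enumerate(self.ids)}
        self._generation = self._compute_generations()

    # -- construction helpers ------------------------------------------------

    def _validate(self) -> None:
        for ind in self._members.values():
            if ind.is_founder:
                continue
            for pid, want_sex, role in (
                (ind.father_id, MALE, "father"),
                (ind.mother_id, FEMALE, "mother"),
            ):
                parent = self._members.get(pid)
                if parent is None:
                    raise UnknownParentError(
                        f"{role} {pid!r} of {ind.id!r} not found"
                    )
                if parent.sex != want_sex:
                    raise SexInconsistentError(
                        f"{role} {pid!r} of {ind.id!r} has wrong sex"
                    )
        # Kahn's algorithm over parent -> child edges detects cycles.
        children: dict[str, list[str]] = {i: [] for i in self._members}
        indeg = {i: 0 for i in self._members}
        for ind in self._members.values():
            if not ind.is_founder:
                children[ind.father_id].append(ind.id)
                children[ind.mother_id].append(ind.id)
                indeg[ind.id] = 2
        queue = [i for i, d in indeg.items() if d == 0]
        seen = 0
        while queue:
            nxt: list[str] = []
            for i in queue:
                seen += 1
                for c in children[i]:
                    indeg[c] -= 1
                    if indeg[c] == 0:
                        nxt.append(c)
            queue = nxt
        if seen != len(self._members):
            raise CyclicAncestryError("pedigree contains cyclic ancestry")

    def _compute_generations(self) -> dict[str, int]:
        gen: dict[str, int] = {}
        for i in self.topological_ids():
            ind = self._members[i]
            if ind.is_founder:
                gen[i] = 0
            else:
                gen[i] = 1 + max(gen[ind.father_id], gen[ind.mother_id])
        return gen

    # -- basic access --------------------------------------------------------

    def __len__(self) -> int:
        return len(self._members)

    def __iter__(self) -> Iterator[Individual]:
        return iter(self._members.values())

    def __contains__(self, id_: str) -> bool:
        return id_ in self._members

    def __getitem__(self, id_: str) -> Individual:
        return self._members[id_]

    @property
    def members(self) -> Mapping[str, Individual]:
        return self._members

    @property
    def ids(self) -> list[str]:
        return list(self._members)

    def index(self, id_: str) -> int:
        """Row of ``id_`` in the sorted member order."""
        return self._index[id_]

    @property
    def founders(self) -> list[str]:
        return [i.id for i in self if i.is_founder]

    @property
    def nonfounders(self) -> list[str]:
        return [i.id for i in self if not i.is_founder]

    def generation(self, id_: str) -> int:
        """Generation index: founders 0, otherwise 1 + max parent generation."""
        return self._generation[id_]

    @property
    def n_generations(self) -> int:
        return 1 + max(self._generation.values()) if self._members else 0

    def topological_ids(self) -> list[str]:
        """Member ids, parents always before children (breadth-first layers,
        lexicographic within a layer)."""
        remaining = dict(self._members)
        out: list[str] = []
        placed: set[str] = set()
        while remaining:
            layer = [
                i
                for i, ind in remaining.items()
                if ind.is_founder
                or (ind.father_id in placed and ind.mother_id in placed)
            ]
            out.extend(layer)
            placed.update(layer)
            for i in layer:
                del remaining[i]
        return out

    def children_of(self) -> dict[str, list[str]]:
        """Map parent id -> list of child ids."""
        out: dict[str, list[str]] = {i: [] for i in self._members}
        for ind in self:
            if not ind.is_founder:
                out[ind.father_id].append(ind.id)
                out[ind.mother_id].append(ind.id)
        return out

    def is_connected(self) -> bool:
        """True if the undirected parent-child graph has one component."""
        if not self._members:
            return True
        adj: dict[str, list[str]] = {i: [] for i in self._members}
        for ind in self:
            if not ind.is_founder:
                adj[ind.id] += [ind.father_id, ind.mother_id]
                adj[ind.father_id].append(ind.id)
                adj[ind.mother_id].append(ind.id)
        start = next(iter(self._members))
        seen = {start}
        stack = [start]
        while stack:
            for nb in adj[stack.pop()]:
                if nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
        return len(seen) == len(self._members)

    # -- derived structure ---------------------------------------------------

    def ancestor_closure(self, ids: Iterable[str]) -> list[str]:
        """``ids`` plus all their ancestors, sorted lexicographically."""
        out: set[str] = set()
        stack = list(ids)
        while stack:
            i = stack.pop()
            if i in out:
                continue
            if i not in self._members:
                raise KeyError(f"id {i!r} not in pedigree")
            out.add(i)
            ind = self._members[i]
            if not ind.is_founder:
                stack += [ind.father_id, ind.mother_id]
        return sorted(out)

    def subpedigree(self, ids: Iterable[str], family_id: str | None = None) -> "Pedigree":
        """Restriction to ``ids``.

        A member whose parents are both absent from ``ids`` becomes a founder
        of the sub-pedigree; a member with exactly one parent present is a
        structural error (callers must complete mates first).
        """
        keep = set(ids)
        subs: list[Individual] = []
        for i in sorted(keep):
            ind = self._members[i]
            if ind.is_founder or (
                ind.father_id not in keep and ind.mother_id not in keep
            ):
                subs.append(replace(ind, father_id=None, mother_id=None))
            elif ind.father_id in keep and ind.mother_id in keep:
                subs.append(ind)
            else:
                raise SingleParentError(
                    f"member {i!r} would keep exactly one parent in sub-pedigree"
                )
        return Pedigree(subs, family_id=family_id or self.family_id)


def bit_size(pedigree: Pedigree) -> int:
    """Pedigree complexity ``2 * n_nonfounders - n_founders``."""
    n_f = sum(1 for i in pedigree if i.is_founder)
    return 2 * (len(pedigree) - n_f) - n_f


@dataclass(frozen=True)
class KinshipMatrix:
    """Pairwise kinship over an ordered id subset.

    ``phi[i, j]`` is the kinship coefficient; ``h[i]`` the inbreeding
    coefficient (kinship of i's parents), with ``phi[i, i] = (1 + h[i]) / 2``.
    The covariance-scale matrix ``K = 2 * phi`` (so ``K_ii = 1 + h_i``) is
    positive semidefinite.
    """

    ids: tuple[str, ...]
    phi: np.ndarray
    h: np.ndarray

    def __post_init__(self) -> None:
        if self.phi.shape != (len(self.ids), len(self.ids)):
            raise ValueError("phi shape inconsistent with ids")

    def K(self) -> np.ndarray:
        return 2.0 * self.phi

    def index(self, ids: Sequence[str]) -> np.ndarray:
        pos = {i: k for k, i in enumerate(self.ids)}
        try:
            return np.array([pos[i] for i in ids], dtype=np.intp)
        except KeyError as e:  # pragma: no cover - defensive
            raise KeyError(f"id {e.args[0]!r} not covered by kinship matrix")

    def subset(self, ids: Sequence[str]) -> "KinshipMatrix":
        rows = self.index(ids)
        return KinshipMatrix(
            tuple(ids), self.phi[np.ix_(rows, rows)], self.h[rows]
        )


def kinship(pedigree: Pedigree, ids: Iterable[str] | None = None) -> KinshipMatrix:
    """Kinship and inbreeding coefficients for ``ids`` (default: everyone).

    The recursion runs over the ancestor closure of ``ids`` in topological
    order, so consanguineous loops are handled exactly.
    """
    ids = sorted(ids) if ids is not None else pedigree.ids
    for i in ids:
        if i not in pedigree:
            raise KeyError(f"id {i!r} not in pedigree")
    closure = set(pedigree.ancestor_closure(ids))
    order = [i for i in pedigree.topological_ids() if i in closure]
    idx = {i: k for k, i in enumerate(order)}
    n = len(order)
    phi = np.zeros((n, n))
    for k, i in enumerate(order):
        ind = pedigree[i]
        if ind.is_founder:
            phi[k, k] = 0.5
        else:
            fi, mi = idx[ind.father_id], idx[ind.mother_id]
            row = 0.5 * (phi[fi, :k] + phi[mi, :k])
            phi[k, :k] = row
            phi[:k, k] = row
            phi[k, k] = 0.5 * (1.0 + phi[fi, mi])
    rows = np.array([idx[i] for i in ids], dtype=np.intp)
    sub = phi[np.ix_(rows, rows)]
    h = 2.0 * np.diag(sub) - 1.0
    return KinshipMatrix(tuple(ids), sub, h)
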