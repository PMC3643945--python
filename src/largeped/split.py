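"""Bit-size-limited pedigree splitting with subject-of-interest coverage.

Exact linkage algorithms only handle pedigrees up to a bit-size cap
(conventionally 24), so a large pedigree must be divided into sub-pedigrees
that each stay under the cap while covering the *subjects of interest* —
here, affected members plus their unaffected full siblings.  The heuristic
is a deterministic greedy cluster-and-grow:

1. group subjects into full sibships and seed one cluster per sibship
   (sibs plus their parents);
2. repeatedly merge the pair of clusters whose *minimal connecting
   pedigree* — the union of both member sets, the shortest undirected
   ancestral path joining them, and any mates required for validity (a
   member never keeps exactly one parent) — stays within the bit limit,
   preferring merges that add the most subjects per added bit and breaking
   ties lexicographically;
3. emit the maximal un-mergeable clusters as sub-pedigrees.

Individuals may appear in several sub-pedigrees as connectors.  For
association analyses on the split structure each genotype must be used
exactly once, so every individual carries a unique assignment: the
sub-pedigree where it is a subject of interest, otherwise the
lexicographically first sub-pedigree containing it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import AFFECTED, UNAFFECTED, KinshipMatrix, Pedigree, kinship

__all__ = [
    "SubpedigreeSet",
    "subjects_of_interest",
    "split_pedigree",
    "subpedigree_kinship",
    "split_kinship",
]


def subjects_of_interest(pedigree: Pedigree) -> set[str]:
    """Affected members plus unaffected members sharing both parents with an
    affected member (members of unknown phenotype are excluded)."""
    affected = [i for i in pedigree if i.affection == AFFECTED]
    out = {i.id for i in affected}
    aff_parents = {
        (i.father_id, i.mother_id) for i in affected if not i.is_founder
    }
    for ind in pedigree:
        if (
            ind.affection == UNAFFECTED
            and not ind.is_founder
            and (ind.father_id, ind.mother_id) in aff_parents
        ):
            out.add(ind.id)
    return out


@dataclass(frozen=True)
class SubpedigreeSet:
    """Result of a split: validated sub-pedigrees, a subject -> sub-pedigree
    assignment, a unique (use-each-genotype-once) assignment for every
    covered member, and the bit limit used."""

    subpedigrees: tuple[Pedigree, ...]
    assignment: dict[str, int]
    unique_assignment: dict[str, int]
    bit_limit: int

    def membership(self) -> dict[str, list[int]]:
        out: dict[str, list[int]] = {}
        for k, sub in enumerate(self.subpedigrees):
            for i in sub.ids:
                out.setdefault(i, []).append(k)
        return out


class _SplitState:
    """Index-based view of the full pedigree for fast path/closure work."""

    def __init__(self, pedigree: Pedigree):
        self.ped = pedigree
        self.ids = pedigree.ids
        self.idx = {i: k for k, i in enumerate(self.ids)}
        n = len(self.ids)
        self.father = np.full(n, -1, dtype=np.int64)
        self.mother = np.full(n, -1, dtype=np.int64)
        adj: list[list[int]] = [[] for _ in range(n)]
        for ind in pedigree:
            if ind.is_founder:
                continue
            c = self.idx[ind.id]
            f, m = self.idx[ind.father_id], self.idx[ind.mother_id]
            self.father[c], self.mother[c] = f, m
            adj[c] += [f, m]
            adj[f].append(c)
            adj[m].append(c)
        self.adj = adj

    def bfs(self, sources: set[int]) -> tuple[np.ndarray, np.ndarray]:
        n = len(self.ids)
        dist = np.full(n, -1, dtype=np.int64)
        pred = np.full(n, -1, dtype=np.int64)
        frontier = sorted(sources)
        for s in frontier:
            dist[s] = 0
        while frontier:
            nxt: list[int] = []
            for v in frontier:
                for w in self.adj[v]:
                    if dist[w] < 0:
                        dist[w] = dist[v] + 1
                        pred[w] = v
                        nxt.append(w)
            frontier = nxt
        return dist, pred

    def closure(self, members: set[int]) -> set[int]:
        """Complete mates: whenever a member has exactly one parent in the
        set, pull in the other, repeatedly."""
        out = set(members)
        stack = list(members)
        while stack:
            c = stack.pop()
            f, m = int(self.father[c]), int(self.mother[c])
            if f < 0:
                continue
            fin, min_ = f in out, m in out
            if fin != min_:
                other = m if fin else f
                out.add(other)
                stack.append(other)
        return out

    def bit(self, members: set[int]) -> int:
        nonf = sum(1 for c in members if int(self.father[c]) in members)
        return 2 * nonf - (len(members) - nonf)


class _Cluster:
    __slots__ = ("members", "subjects", "bit", "dist", "pred", "key")

    def __init__(self, state: _SplitState, members: set[int], subjects: set[int]):
        self.members = members
        self.subjects = subjects
        self.bit = state.bit(members)
        self.dist, self.pred = state.bfs(members)
        self.key = min(state.ids[c] for c in members)  # lexicographic tag


def _merged_members(state: _SplitState, a: _Cluster, b: _Cluster) -> set[int] | None:
    """Minimal connecting member set of two clusters, or None if the full
    pedigree does not connect them."""
    reach = (a.dist >= 0) & (b.dist >= 0)
    if not reach.any():
        return None
    total = np.where(reach, a.dist + b.dist, np.iinfo(np.int64).max)
    meet = int(total.argmin())
    path = {meet}
    for cl in (a, b):
        v = meet
        while v >= 0 and cl.dist[v] > 0:
            v = int(cl.pred[v])
            path.add(v)
    return state.closure(a.members | b.members | path)


def split_pedigree(
    pedigree: Pedigree, subjects: set[str], bit_limit: int = 24
) -> SubpedigreeSet:
    """Divide ``pedigree`` into sub-pedigrees of bit size <= ``bit_limit``
    covering every subject of interest.  Deterministic for identical input."""
    if not subjects:
        raise ValueError("subjects of interest must be nonempty")
    if bit_limit < 0:
        raise ValueError("bit_limit must be >= 0")
    missing = sorted(s for s in subjects if s not in pedigree)
    if missing:
        raise KeyError(f"subject {missing[0]!r} not in pedigree")

    state = _SplitState(pedigree)

    # 1. seed clusters: subject sibships plus their parents
    sibships: dict[tuple[str, str] | str, set[int]] = {}
    for s in sorted(subjects):
        ind = pedigree[s]
        key = s if ind.is_founder else (ind.father_id, ind.mother_id)
        sibships.setdefault(key, set()).add(state.idx[s])
    clusters: list[_Cluster] = []
    for key in sorted(sibships, key=str):
        sibs = sibships[key]
        members = set(sibs)
        if isinstance(key, tuple):
            members |= {state.idx[key[0]], state.idx[key[1]]}
        members = state.closure(members)
        cl = _Cluster(state, members, set(sibs))
        if cl.bit > bit_limit:
            names = sorted(state.ids[c] for c in sibs)
            raise ValueError(
                f"sibship {names} plus parents already exceeds bit limit "
                f"{bit_limit} (bit {cl.bit})"
            )
        clusters.append(cl)

    # 2. greedy merge: best feasible pair by subjects-per-added-bit
    def evaluate(a: _Cluster, b: _Cluster):
        members = _merged_members(state, a, b)
        if members is None:
            return None
        bit = state.bit(members)
        if bit > bit_limit:
            return None
        added = max(1, bit - max(a.bit, b.bit))
        score = (len(a.subjects) + len(b.subjects)) / added
        return score, members

    cache: dict[tuple[str, str], tuple | None] = {}
    while len(clusters) > 1:
        best = None
        for ia in range(len(clusters)):
            for ib in range(ia + 1, len(clusters)):
                a, b = clusters[ia], clusters[ib]
                ckey = (a.key, b.key) if a.key < b.key else (b.key, a.key)
                if ckey not in cache:
                    cache[ckey] = evaluate(a, b)
                ev = cache[ckey]
                if ev is None:
                    continue
                cand = (-ev[0], ckey, ia, ib, ev[1])
                if best is None or cand[:2] < best[:2]:
                    best = cand
        if best is None:
            break
        _, _, ia, ib, members = best
        a, b = clusters[ia], clusters[ib]
        merged = _Cluster(state, members, a.subjects | b.subjects)
        clusters = [c for k, c in enumerate(clusters) if k not in (ia, ib)]
        clusters.append(merged)
        cache = {
            k: v for k, v in cache.items() if a.key not in k and b.key not in k
        }

    # 3. emit deterministic, validated sub-pedigrees
    clusters.sort(key=lambda c: c.key)
    subs = tuple(
        pedigree.subpedigree(
            [state.ids[c] for c in cl.members],
            family_id=f"{pedigree.family_id}_S{k + 1}",
        )
        for k, cl in enumerate(clusters)
    )
    assignment: dict[str, int] = {}
    for k, cl in enumerate(clusters):
        for c in sorted(cl.subjects):
            assignment[state.ids[c]] = k
    unique = dict(assignment)
    for k, sub in enumerate(subs):
        for i in sub.ids:
            unique.setdefault(i, k)
    return SubpedigreeSet(subs, assignment, unique, bit_limit)


def subpedigree_kinship(subset: SubpedigreeSet) -> list[KinshipMatrix]:
    """Kinship recomputed within each sub-pedigree structure: members whose
    parents were cut away are treated as founders, so coefficients reflect
    only the retained structure."""
    return [kinship(sub) for sub in subset.subpedigrees]


def split_kinship(subset: SubpedigreeSet) -> KinshipMatrix:
    """Block-diagonal kinship over the union of sub-pedigree members.

    Each individual contributes through the single sub-pedigree of its
    unique assignment; pairs split across sub-pedigrees get kinship zero.
    """
    blocks = subpedigree_kinship(subset)
    ids = sorted(subset.unique_assignment)
    pos = {i: k for k, i in enumerate(ids)}
    n = len(ids)
    phi = np.zeros((n, n))
    h = np.zeros(n)
    phi[np.diag_indices(n)] = 0.5
    for k, km in enumerate(blocks):
        keep = [i for i in km.ids if subset.unique_assignment[i] == k]
        rows_local = km.index(keep)
        rows_global = np.array([pos[i] for i in keep], dtype=np.intp)
        phi[np.ix_(rows_global, rows_global)] = km.phi[np.ix_(rows_local, rows_local)]
        h[rows_global] = km.h[rows_local]
    return KinshipMatrix(tuple(ids), phi, h)
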