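"""Independent oracles used by the test suite.

Everything here is written from first principles (explicit enumeration,
direct matrix arithmetic, Monte-Carlo gene dropping) and deliberately does
not reuse the package's own computational paths.
"""

from __future__ import annotations

import numpy as np

from largeped.pedigree import Individual, Pedigree


# -- brute-force two-locus pedigree likelihood ------------------------------


def _gamete_prob(parent_state: int, gamete: int, theta: float) -> float:
    """P(gamete haplotype | parent's ordered two-locus state), by explicit
    enumeration of the two strand choices."""
    hp, hm = parent_state // 4, parent_state % 4
    pr = 0.0
    for t_src, m_src, w in (
        (hp, hp, (1 - theta) / 2),
        (hp, hm, theta / 2),
        (hm, hm, (1 - theta) / 2),
        (hm, hp, theta / 2),
    ):
        if ((t_src & 2) | (m_src & 1)) == gamete:
            pr += w
    return pr


def brute_force_loglik10(
    pedigree: Pedigree,
    marker_counts: dict[str, int],
    marker_freq: float,
    penetrances,
    disease_freq: float,
    theta: float,
) -> float:
    """log10 of the full joint sum over all 16^n ordered two-locus states
    (vectorized over a dense joint array; n <= 6)."""
    ids = pedigree.ids
    n = len(ids)
    assert n <= 6, "joint enumeration limited to 6 members"
    idx = {i: k for k, i in enumerate(ids)}
    q, pm = disease_freq, marker_freq
    hap = np.array([(1 - q) * (1 - pm), (1 - q) * pm, q * (1 - pm), q * pm])
    states = np.arange(16)
    pat, mat = states // 4, states % 4
    n_disease = (pat >> 1) + (mat >> 1)
    n_marker = (pat & 1) + (mat & 1)
    pen = np.asarray(penetrances)

    joint = np.ones((16,) * n)
    trans = np.zeros((16, 16, 16))
    for sf in range(16):
        for sm in range(16):
            for sc in range(16):
                trans[sf, sm, sc] = _gamete_prob(sf, sc // 4, theta) * _gamete_prob(
                    sm, sc % 4, theta
                )
    for i in ids:
        ind = pedigree[i]
        v = idx[i]
        ev = np.ones(16)
        if ind.affection == 2:
            ev = ev * pen[n_disease]
        elif ind.affection == 1:
            ev = ev * (1.0 - pen[n_disease])
        c = marker_counts.get(i)
        if c is not None and c >= 0:
            ev = ev * (n_marker == c)
        if ind.is_founder:
            fac = hap[pat] * hap[mat] * ev
            shape = [1] * n
            shape[v] = 16
            joint = joint * fac.reshape(shape)
        else:
            f, m = idx[ind.father_id], idx[ind.mother_id]
            fac = trans * ev[None, None, :]
            # place axes (f, m, v) into the joint
            order = np.argsort([f, m, v])
            src = np.transpose(fac, order)
            shape = [1] * n
            for ax, size in zip(sorted([f, m, v]), src.shape):
                shape[ax] = size
            joint = joint * src.reshape(shape)
    total = float(joint.sum())
    return np.log10(total) if total > 0 else -np.inf


# -- Monte-Carlo gene-drop IBD estimator ------------------------------------


def gene_drop_kinship(
    pedigree: Pedigree, pairs: list[tuple[str, str]], n_drops: int, seed: int
):
    """Estimate kinship for id pairs as the IBD probability of randomly
    drawn alleles across ``n_drops`` single-locus founder-labelled drops.
    Returns (estimates, standard errors)."""
    rng = np.random.default_rng(seed)
    idx = {i: k for k, i in enumerate(pedigree.ids)}
    alleles = np.zeros((len(pedigree), 2, n_drops), dtype=np.int32)
    label = 0
    for i in pedigree.topological_ids():
        ind = pedigree[i]
        k = idx[i]
        if ind.is_founder:
            alleles[k, 0] = label
            alleles[k, 1] = label + 1
            label += 2
        else:
            for slot, pid in ((0, ind.father_id), (1, ind.mother_id)):
                pick = rng.integers(0, 2, n_drops)
                parent = alleles[idx[pid]]
                alleles[k, slot] = np.where(pick == 0, parent[0], parent[1])
    est, se = [], []
    for a, b in pairs:
        ka, kb = idx[a], idx[b]
        # P(random allele of a IBD to random allele of b): average the four
        # allele-pair comparisons
        ibd = np.zeros(n_drops)
        for s in range(2):
            for t in range(2):
                ibd += (alleles[ka, s] == alleles[kb, t]) / 4.0
        est.append(ibd.mean())
        se.append(ibd.std(ddof=1) / np.sqrt(n_drops))
    return np.array(est), np.array(se)


# -- direct quadratic-form association statistic ----------------------------


def direct_mqls_W(y, a_n, a_m, k_nn, k_nm, k_mm) -> float:
    """The displayed statistic evaluated with plain matrix inverses."""
    y = np.asarray(y, float)
    n = y.size
    ones = np.ones(n)
    k_inv = np.linalg.inv(k_nn)
    atilde = np.asarray(a_n, float)
    if np.size(a_m):
        atilde = atilde + k_nm @ np.linalg.inv(k_mm) @ np.asarray(a_m, float)
    s = ones @ k_inv @ ones
    mu = (ones @ k_inv @ y) / s
    sigma2 = mu * (1 - mu) / 2
    num = atilde @ (y - mu * ones)
    den = sigma2 * (atilde @ k_nn @ atilde - (atilde @ ones) ** 2 / s)
    return num**2 / den


# -- random small pedigrees --------------------------------------------------


def random_pedigree(rng: np.random.Generator, n_members: int) -> Pedigree:
    """A random valid pedigree of exactly ``n_members``; matings between
    existing members are allowed, so consanguineous loops occur."""
    inds: list[Individual] = []
    males: list[str] = []
    females: list[str] = []
    for k in range(n_members):
        iid = f"r{k:02d}"
        sex = 1 if rng.random() < 0.5 else 2
        father = mother = None
        if males and females and rng.random() < 0.7:
            father = males[int(rng.integers(len(males)))]
            mother = females[int(rng.integers(len(females)))]
        aff = int(rng.integers(0, 3))
        inds.append(
            Individual(
                iid,
                father_id=father,
                mother_id=mother,
                sex=sex,
                affection=aff,
                genotyped=bool(rng.random() < 0.8),
            )
        )
        (males if sex == 1 else females).append(iid)
    return Pedigree(inds)
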