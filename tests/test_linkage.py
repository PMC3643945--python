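"""Two-point linkage: peeling vs enumeration, factorization, toy LOD, HLOD."""

import math

import numpy as np
import pytest

from largeped.linkage import (
    LinkageModel,
    hlod,
    pedigree_loglik10,
    twopoint_lod,
    _marker_only_loglik10,
    _trait_only_loglik10,
)
from largeped.pedigree import AFFECTED, UNAFFECTED, Individual, Pedigree
from largeped.simulate import DiseaseModel, MarkerMap, Replicate, generate_replicates
from largeped.split import split_pedigree, subjects_of_interest

from oracles import brute_force_loglik10, random_pedigree


def _phase_known_family(m: int) -> tuple[Pedigree, dict[str, int]]:
    """Fully-penetrant dominant toy with phase fixed through homozygous
    grandparents and m non-recombinant informative meioses."""
    inds = [
        Individual("gf", sex=1, affection=AFFECTED, genotyped=True),
        Individual("gm", sex=2, affection=UNAFFECTED, genotyped=True),
        Individual("pa", father_id="gf", mother_id="gm", sex=1, affection=AFFECTED, genotyped=True),
        Individual("sp", sex=2, affection=UNAFFECTED, genotyped=True),
    ]
    counts = {"gf": 2, "gm": 0, "pa": 1, "sp": 0}
    for k in range(m):
        cid = f"c{k}"
        inds.append(
            Individual(cid, father_id="pa", mother_id="sp", sex=1, affection=AFFECTED, genotyped=True)
        )
        counts[cid] = 1
    return Pedigree(inds), counts


class TestModel:
    def test_affecteds_only_defaults(self):
        assert LinkageModel.dominant().penetrances == (0.0, 0.0001, 0.0001)
        assert LinkageModel.recessive().penetrances == (0.0, 0.0, 0.0001)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            LinkageModel("additive")
        with pytest.raises(ValueError):
            LinkageModel("dominant", 0.0)


class TestLikelihood:
    def test_missing_markers_theta_independent(self, sib_mating_pedigree):
        model = LinkageModel.dominant()
        vals = [
            pedigree_loglik10(sib_mating_pedigree, {}, 0.2, model, th)
            for th in (0.0, 0.2, 0.5)
        ]
        assert max(vals) - min(vals) < 1e-12

    def test_peeling_equals_enumeration_random_pedigrees(self):
        """Exact variable elimination matches dense joint enumeration on
        random 3-6 member pedigrees (loops included), 1e-10 relative."""
        rng = np.random.default_rng(12)
        cases = 0
        while cases < 40:
            n = int(rng.integers(3, 7))
            ped = random_pedigree(rng, n)
            model = LinkageModel(
                "dominant" if rng.random() < 0.5 else "recessive",
                float(rng.uniform(0.05, 0.5)),
                tuple(rng.uniform(0, 1, 3)),
            )
            counts = {
                i.id: int(rng.integers(0, 3))
                for i in ped
                if i.genotyped and rng.random() < 0.7
            }
            theta = float(rng.choice([0.0, 0.1, 0.3, 0.5]))
            pm = float(rng.uniform(0.1, 0.9))
            got = pedigree_loglik10(ped, counts, pm, model, theta)
            want = brute_force_loglik10(
                ped, counts, pm, model.penetrances, model.disease_allele_freq, theta
            )
            if math.isinf(want):
                assert math.isinf(got)
            else:
                assert got == pytest.approx(want, rel=1e-10, abs=1e-10)
            cases += 1

    def test_half_theta_factorizes(self, sib_mating_pedigree):
        ped = Pedigree(
            [
                Individual(i.id, father_id=i.father_id, mother_id=i.mother_id,
                           sex=i.sex, affection=(AFFECTED if k % 2 else UNAFFECTED),
                           genotyped=True)
                for k, i in enumerate(sib_mating_pedigree)
            ]
        )
        model = LinkageModel("recessive", 0.2, (0.1, 0.2, 0.9))
        counts = {"a": 1, "s1": 2, "c": 1}
        lhs = pedigree_loglik10(ped, counts, 0.3, model, 0.5)
        rhs = _trait_only_loglik10(ped, model) + _marker_only_loglik10(ped, counts, 0.3)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_mendelian_inconsistency_gives_minus_inf(self, trio):
        model = LinkageModel.dominant()
        counts = {"dad": 0, "mom": 0, "kid": 2}
        assert pedigree_loglik10(trio, counts, 0.2, model, 0.0) == -np.inf

    def test_phase_known_lod_formula(self):
        """m non-recombinant informative meioses give LOD = m*log10(2)."""
        toy = LinkageModel("dominant", 0.5, (0.0, 1.0, 1.0))
        for m in (1, 2, 4):
            ped, counts = _phase_known_family(m)
            z = pedigree_loglik10(ped, counts, 0.3, toy, 0.0) - pedigree_loglik10(
                ped, counts, 0.3, toy, 0.5
            )
            assert z == pytest.approx(m * math.log10(2), rel=1e-12)

    def test_lod_grows_with_each_nonrecombinant_meiosis(self):
        toy = LinkageModel("dominant", 0.5, (0.0, 1.0, 1.0))
        zs = []
        for m in (1, 2, 3):
            ped, counts = _phase_known_family(m)
            zs.append(
                pedigree_loglik10(ped, counts, 0.3, toy, 0.0)
                - pedigree_loglik10(ped, counts, 0.3, toy, 0.5)
            )
        assert zs[0] < zs[1] < zs[2]


class TestHlod:
    def test_alpha_one_recovers_positive_lod(self):
        z = [0.8, 0.6, 0.4]
        h, a = hlod(z)
        assert h == pytest.approx(sum(z), rel=1e-9)
        assert a == pytest.approx(1.0, abs=1e-6)

    def test_all_negative_gives_zero(self):
        h, a = hlod([-0.5, -2.0])
        assert h == 0.0 and a == 0.0

    def test_mixed_z_bounds(self):
        z = [1.2, -0.9]
        h, a = hlod(z)
        assert h >= max(0.0, sum(z)) - 1e-12
        assert 0.0 <= a <= 1.0

    def test_grid_matches_dense_grid(self):
        """Coarse grid + golden refinement within 1e-6 of a 1e-4-step
        dense grid on 50 random Z vectors."""
        rng = np.random.default_rng(4)
        dense = np.linspace(0.0, 1.0, 10_001)
        for _ in range(50):
            z = rng.normal(0, 1.2, size=rng.integers(2, 10))
            h, _ = hlod(z)
            ln = z * math.log(10.0)
            with np.errstate(divide="ignore"):
                vals = (
                    np.logaddexp(
                        np.log(dense)[:, None] + ln[None, :],
                        np.log1p(-dense)[:, None],
                    ).sum(axis=1)
                    / math.log(10.0)
                )
            vals[0] = 0.0
            vals[-1] = z.sum()
            assert h == pytest.approx(vals.max(), abs=1e-6)


class TestTwopoint:
    def test_uninformative_subpedigrees_zero(self, small_template, default_map):
        rep = next(
            generate_replicates(small_template, default_map, DiseaseModel.null(), 1, 6)
        )
        subs = split_pedigree(
            small_template, subjects_of_interest(small_template), 24
        )
        blank = Replicate(
            rep.ids,
            np.full_like(rep.genotypes, -1),
            rep.phenotypes,
            0,
            0,
        )
        res = twopoint_lod(subs, blank, 0, LinkageModel.dominant())
        assert res.lod == 0.0 and res.hlod == 0.0

    def test_scan_runs_on_split_replicate(self, small_template, default_map):
        rep = next(
            generate_replicates(small_template, default_map, DiseaseModel.null(), 1, 6)
        )
        subs = split_pedigree(
            small_template, subjects_of_interest(small_template), 24
        )
        res = twopoint_lod(subs, rep, 62, LinkageModel.recessive())
        assert len(res.z) == len(subs.subpedigrees)
        assert np.isfinite(res.lod)
        assert res.hlod >= max(0.0, res.lod) - 1e-9
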