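"""Gene-dropping simulator: map function, founder draws, transmission,
penetrance calibration, affection assignment, replicate stream."""

import math

import numpy as np
import pytest

from largeped.pedigree import AFFECTED, UNKNOWN, Individual, Pedigree
from largeped.simulate import (
    DiseaseModel,
    MarkerMap,
    assign_affection,
    calibrate_penetrance,
    draw_founder_haplotypes,
    gene_drop,
    generate_replicates,
    haldane_theta,
)
from largeped.template import TemplateParams, generate_template


class TestHaldane:
    def test_limits_and_closed_form(self):
        assert haldane_theta(0.0) == 0.0
        assert haldane_theta(1e9) == pytest.approx(0.5)
        assert haldane_theta(0.062) == pytest.approx(
            0.5 * (1 - math.exp(-0.00124))
        )

    def test_negative_distance_rejected(self):
        with pytest.raises(ValueError):
            haldane_theta(-1.0)


class TestMarkerMap:
    def test_uniform_spacing_and_thetas(self):
        mmap = MarkerMap.uniform(124, 0.062)
        assert len(mmap) == 124
        assert np.allclose(mmap.thetas, haldane_theta(0.062))

    def test_nonincreasing_positions_rejected(self):
        with pytest.raises(ValueError):
            MarkerMap(((1, "a", 0.0), (1, "b", 0.0)))


class TestFounderDraws:
    def test_degenerate_frequencies(self):
        mmap = MarkerMap.uniform(5)
        assert not draw_founder_haplotypes(10, mmap, 0.0, 0).any()
        assert draw_founder_haplotypes(10, mmap, 1.0, 0).all()

    def test_pooled_frequency_matches_maf(self):
        """1,000 founders x 124 loci: pooled risk-allele frequency within
        4 binomial SE of 0.2 at every locus."""
        mmap = MarkerMap.uniform(124)
        haps = draw_founder_haplotypes(1000, mmap, 0.2, 42)
        freq = haps.mean(axis=(0, 1))
        se = math.sqrt(0.2 * 0.8 / 2000)
        assert np.all(np.abs(freq - 0.2) <= 4 * se)


class TestGeneDrop:
    def test_mendelian_forcing(self, trio):
        mmap = MarkerMap.uniform(3)
        haps = np.ones((2, 2, 3), dtype=np.int8)  # both parents homozygous risk
        geno = gene_drop(trio, haps, mmap, 0)
        assert np.all(geno == 2)

    def test_no_recombination_copies_whole_haplotypes(self, trio):
        # near-zero spacing makes theta ~ 0, so gametes copy whole
        # parental haplotypes
        mmap = MarkerMap(((1, "a", 0.0), (1, "b", 1e-9), (1, "c", 2e-9)))
        rng = np.random.default_rng(3)
        haps = rng.integers(0, 2, size=(2, 2, 3)).astype(np.int8)
        from largeped.simulate import _drop_haplotypes

        H = _drop_haplotypes(trio, haps, mmap, rng)
        kid = H[1]  # sorted order: dad, kid, mom
        dad, mom = H[0], H[2]
        assert any(np.array_equal(kid[0], dad[s]) for s in (0, 1))
        assert any(np.array_equal(kid[1], mom[s]) for s in (0, 1))

    def test_transmission_ratio_half(self, trio):
        """Heterozygous parent transmits each allele half the time
        (binomial oracle, 4 SE over 100,000 drops)."""
        mmap = MarkerMap.uniform(1)
        haps = np.zeros((2, 2, 1), dtype=np.int8)
        haps[0, 0, 0] = 1  # dad heterozygous, mom homozygous reference
        rng = np.random.default_rng(7)
        n = 100_000
        got = 0
        # vectorized equivalent of n independent drops at a single locus
        from largeped.simulate import _drop_haplotypes

        wide = MarkerMap.uniform(n, 1000.0)  # theta ~ 1/2 -> loci independent
        haps_wide = np.zeros((2, 2, n), dtype=np.int8)
        haps_wide[0, 0, :] = 1
        H = _drop_haplotypes(trio, haps_wide, wide, rng)
        share = H[1, 0, :].mean()  # fraction of paternal gametes with allele
        se = math.sqrt(0.25 / n)
        assert abs(share - 0.5) <= 4 * se

    def test_mendelian_consistency_every_locus(self, default_template, default_map):
        """Each child's genotype is compatible with its parents."""
        rep = next(
            generate_replicates(
                default_template, default_map, DiseaseModel.null(), 1, 99
            )
        )
        from largeped.simulate import _STAGE_DROP, _STAGE_FOUNDERS

        # regenerate unmasked genotypes with the replicate's seeds
        rng_f = np.random.default_rng(
            np.random.SeedSequence([99, 0, _STAGE_FOUNDERS])
        )
        rng_d = np.random.default_rng(np.random.SeedSequence([99, 0, _STAGE_DROP]))
        founders = draw_founder_haplotypes(
            len(default_template.founders), default_map, 0.2, rng_f
        )
        from largeped.simulate import _drop_haplotypes

        H = _drop_haplotypes(default_template, founders, default_map, rng_d)
        idx = {i: k for k, i in enumerate(default_template.ids)}
        rng = np.random.default_rng(1)
        for ind in default_template:
            if ind.is_founder:
                continue
            k, f, m = idx[ind.id], idx[ind.father_id], idx[ind.mother_id]
            # each gamete allele must appear in that parent's pair, per locus
            pat_ok = (H[k, 0] == H[f, 0]) | (H[k, 0] == H[f, 1])
            mat_ok = (H[k, 1] == H[m, 0]) | (H[k, 1] == H[m, 1])
            assert pat_ok.all() and mat_ok.all()


class TestPenetrance:
    def test_null_collapses_to_prevalence(self):
        f = calibrate_penetrance("dominant", 1.0, 0.2, 0.133)
        assert f == pytest.approx((0.133, 0.133, 0.133))

    @pytest.mark.parametrize("mode", ["dominant", "recessive", "additive"])
    def test_substitution_oracle(self, mode):
        """Calibrated penetrances satisfy the multiplicative-risk relation
        and the HWE-mean-prevalence constraint by direct substitution."""
        psi, p, K = 5.0, 0.2, 0.133
        f0, f1, f2 = calibrate_penetrance(mode, psi, p, K)
        hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
        assert hwe @ [f0, f1, f2] == pytest.approx(K, abs=1e-9)
        if mode == "dominant":
            assert f1 == f2
            assert f1 == pytest.approx(psi * f0)
        elif mode == "recessive":
            assert f0 == f1
            assert f2 == pytest.approx(psi * f0)
        else:
            assert f1 == pytest.approx(psi * f0)
            assert f2 == pytest.approx(min(1.0, psi**2 * f0))

    def test_infeasible_prevalence_rejected(self):
        with pytest.raises(ValueError):
            calibrate_penetrance("dominant", 2.0, 0.2, 1.5)


class TestAffection:
    def test_null_copies_template_labels(self, default_template, default_map):
        rep = next(
            generate_replicates(
                default_template, default_map, DiseaseModel.null(), 1, 5
            )
        )
        assert int((rep.phenotypes == AFFECTED).sum()) == 106

    def test_certain_penetrance_affects_everyone(self, trio):
        mmap = MarkerMap.uniform(3, disease_locus=1)
        model = DiseaseModel("dominant", 2.0, penetrances_override=(1.0, 1.0, 1.0))
        geno = np.zeros((3, 3), dtype=np.int8)
        phen = assign_affection(geno, model, trio, mmap, 0)
        assert np.all(phen == AFFECTED)

    def test_disease_mode_requires_disease_locus(self, trio):
        mmap = MarkerMap.uniform(3)
        with pytest.raises(ValueError):
            assign_affection(
                np.zeros((3, 3), dtype=np.int8),
                DiseaseModel("dominant", 2.0),
                trio,
                mmap,
                0,
            )

    def test_affected_fraction_tracks_penetrance(self, small_template, default_map):
        """Mean affected fraction among phenotyped across replicates is
        within 4 SE of the prevalence the penetrances were calibrated to."""
        model = DiseaseModel("dominant", 5.0)
        fracs = []
        for rep in generate_replicates(small_template, default_map, model, 40, 17):
            known = rep.phenotypes != UNKNOWN
            fracs.append((rep.phenotypes[known] == AFFECTED).mean())
        fracs = np.array(fracs)
        se = fracs.std(ddof=1) / math.sqrt(fracs.size)
        assert abs(fracs.mean() - model.prevalence) <= 4 * max(se, 1e-3)


class TestReplicates:
    def test_zero_reps_empty_stream(self, trio):
        assert (
            list(generate_replicates(trio, MarkerMap.uniform(2), DiseaseModel.null(), 0, 0))
            == []
        )

    def test_same_master_seed_identical(self, small_template, default_map):
        a = list(
            generate_replicates(small_template, default_map, DiseaseModel.null(), 3, 8)
        )
        b = list(
            generate_replicates(small_template, default_map, DiseaseModel.null(), 3, 8)
        )
        for ra, rb in zip(a, b):
            assert np.array_equal(ra.genotypes, rb.genotypes)
            assert np.array_equal(ra.phenotypes, rb.phenotypes)

    def test_masking_follows_template_flags(self, small_template, default_map):
        rep = next(
            generate_replicates(small_template, default_map, DiseaseModel.null(), 1, 8)
        )
        for k, ind in enumerate(small_template):
            if ind.genotyped:
                assert (rep.genotypes[k] >= 0).all()
            else:
                assert (rep.genotypes[k] == -1).all()

    def test_pooled_sample_frequency_near_maf(self, small_template, default_map):
        """Genotyped-sample allele frequency pooled over replicates stays
        near 0.2 (empirical 4 SE; pedigree correlation inflates the SE)."""
        freqs = []
        for rep in generate_replicates(
            small_template, default_map, DiseaseModel.null(), 50, 21
        ):
            g = rep.genotypes[rep.genotyped_rows()]
            freqs.append(g.mean() / 2.0)
        freqs = np.array(freqs)
        se = freqs.std(ddof=1) / math.sqrt(freqs.size)
        assert abs(freqs.mean() - 0.2) <= 4 * se
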