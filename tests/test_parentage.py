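import numpy as np
import pytest

from nestkin.parentage import (RELATIONSHIPS,
                               PaternalLineage, detect_renesting,
                               dyad_likelihoods, genotype_error_matrix,
                               genotype_pair_probs, link_cross_nest_lineages,
                               maternity_check, partition_paternal_groups,
                               paternal_allele_llr)


def simulate_family(rng, p, n_eggs, shared_father=True):
    """One hen, one or two fathers; returns (hen, father(s), eggs)."""
    mom = rng.binomial(2, p).astype(float)
    dads = [rng.binomial(2, p).astype(float)
            for _ in range(1 if shared_father else 2)]
    eggs = []
    for k in range(n_eggs):
        dad = dads[0] if shared_father or k < n_eggs - 1 else dads[1]
        eggs.append((rng.binomial(1, mom / 2)
                     + rng.binomial(1, dad / 2)).astype(float))
    return mom, dads, eggs


class TestGenotypePairProbs:
    def test_error_matrix_rows_sum_to_one(self):
        E = genotype_error_matrix(0.005)
        assert np.allclose(E.sum(axis=1), 1.0)
        assert np.allclose(genotype_error_matrix(0.0), np.eye(3))

    @pytest.mark.parametrize("rel", RELATIONSHIPS)
    @pytest.mark.parametrize("seed", range(7))
    def test_mass_sums_to_one_over_nine_pairs(self, rel, seed):
        # exhaustive enumeration oracle: the 3x3 table is a probability
        # mass function for every relationship and frequency
        rng = np.random.default_rng(seed)
        p = rng.uniform(0.01, 0.99)
        P = genotype_pair_probs(p, rel)
        assert P.shape == (3, 3)
        assert P.sum() == pytest.approx(1.0, abs=1e-12)
        assert (P >= 0).all()

    def test_marginals_are_hwe(self):
        p = 0.3
        hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        for rel in RELATIONSHIPS:
            P = genotype_pair_probs(p, rel)
            assert np.allclose(P.sum(axis=1), hwe, atol=1e-12)
            assert np.allclose(P.sum(axis=0), hwe, atol=1e-12)

    def test_unrelated_is_independence(self):
        p = 0.42
        hwe = np.array([(1 - p) ** 2, 2 * p * (1 - p), p ** 2])
        assert np.allclose(genotype_pair_probs(p, "unrelated"),
                           np.outer(hwe, hwe))


class TestDyadLikelihoods:
    def test_identical_vectors_favor_full_sib(self):
        rng = np.random.default_rng(0)
        p = np.full(120, 0.5)
        x = rng.binomial(2, p).astype(float)
        sc = dyad_likelihoods(x, x.copy(), p)
        assert sc.best == "full_sib"
        assert sc.lnl["full_sib"] > sc.lnl["half_sib"] > sc.lnl["unrelated"]

    def test_tie_breaks_toward_less_related(self):
        # no usable site -> all likelihoods 0 -> unrelated wins the tie
        p = np.array([0.0, 1.0])
        sc = dyad_likelihoods(np.array([0.0, 2.0]), np.array([0.0, 2.0]), p)
        assert sc.best == "unrelated"

    def test_full_vs_half_sib_classification_accuracy(self):
        rng = np.random.default_rng(33)
        S = 259
        p = rng.uniform(0.45, 0.55, S)
        correct = {"full_sib": 0, "half_sib": 0}
        n = 60
        for _ in range(n):
            mom, _, eggs = simulate_family(rng, p, 2, shared_father=True)
            sc = dyad_likelihoods(eggs[0], eggs[1], p)
            correct["full_sib"] += sc.best == "full_sib"
            mom, _, eggs = simulate_family(rng, p, 2, shared_father=False)
            sc = dyad_likelihoods(eggs[0], eggs[1], p)
            correct["half_sib"] += sc.best == "half_sib"
        assert correct["full_sib"] / n >= 0.9
        assert correct["half_sib"] / n >= 0.9


class TestMaternity:
    def test_true_mother_zero_opposing(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(0.2, 0.8, 300)
        mom, _, eggs = simulate_family(rng, p, 1)
        res = maternity_check(mom, eggs[0])
        assert res.accept is True
        assert res.n_opposing == 0

    def test_unrelated_pair_rejected_at_expected_rate(self):
        # closed-form expectation: P(opposing) = 2 p^2 (1-p)^2 per site
        rng = np.random.default_rng(2)
        S = 259
        p = rng.uniform(0.45, 0.55, S)
        expected_rate = float(np.mean(2 * p**2 * (1 - p) ** 2))
        assert expected_rate > 0.05  # far above the 1% allowance
        hen = rng.binomial(2, p).astype(float)
        egg = rng.binomial(2, p).astype(float)
        res = maternity_check(hen, egg)
        assert res.accept is False
        assert res.mismatch_rate == pytest.approx(expected_rate, abs=0.06)

    def test_too_few_sites_indeterminate(self):
        res = maternity_check(np.zeros(30), np.zeros(30))
        assert res.accept is None

    def test_ajk_floor_blocks_acceptance(self):
        mom = np.ones(100)
        res = maternity_check(mom, mom.copy(), ajk=0.1)
        assert res.accept is False

    def test_parasitic_eggs_rejected_in_simulation(self, default_sim):
        from nestkin.genodata import select_parentage_sites

        focal = default_sim.genotypes.subset_samples(default_sim.focal_ids)
        Mpar = select_parentage_sites(focal)
        idx = {s: j for j, s in enumerate(Mpar.sample_ids)}
        hens = default_sim.nest_table[default_sim.nest_table.role == "hen"]
        hen_of_nest = dict(zip(hens.nest_id, hens.sample_id))
        n_rej = n_tot = 0
        for r in default_sim.truth.eggs.itertuples():
            if not r.is_parasitic:
                continue
            hen = hen_of_nest[r.nest_id]
            res = maternity_check(Mpar.dosages[:, idx[hen]],
                                  Mpar.dosages[:, idx[r.sample_id]])
            n_tot += 1
            n_rej += res.accept is False
        assert n_tot > 0 and n_rej == n_tot


class TestPartition:
    def _setup(self, rng, shared_father, n_eggs=8):
        S = 259
        p = rng.uniform(0.4, 0.6, S)
        mom, dads, eggs = simulate_family(rng, p, n_eggs,
                                          shared_father=shared_father)
        genos = {f"E{k}": e for k, e in enumerate(eggs)}
        return genos, mom, p

    def test_monogamous_clutch_single_lineage(self):
        rng = np.random.default_rng(4)
        genos, mom, p = self._setup(rng, shared_father=True)
        groups, _ = partition_paternal_groups(genos, mom, p)
        assert len(groups) == 1

    def test_epc_clutch_split_seven_one(self):
        rng = np.random.default_rng(5)
        hits = 0
        n = 40
        for _ in range(n):
            genos, mom, p = self._setup(rng, shared_father=False, n_eggs=8)
            groups, _ = partition_paternal_groups(genos, mom, p)
            sizes = sorted(len(g) for g in groups)
            singleton_is_epc_egg = any(g == ["E7"] for g in groups)
            hits += sizes == [1, 7] and singleton_is_epc_egg
        assert hits / n >= 0.9

    def test_single_egg_clutch(self):
        groups, scores = partition_paternal_groups({"E0": np.ones(100)},
                                                   None, np.full(100, 0.5))
        assert groups == [["E0"]]
        assert scores == []

    def test_no_egg_in_two_lineages_and_sizes_sum(self):
        rng = np.random.default_rng(6)
        genos, mom, p = self._setup(rng, shared_father=False, n_eggs=9)
        groups, _ = partition_paternal_groups(genos, mom, p)
        all_eggs = [e for g in groups for e in g]
        assert sorted(all_eggs) == sorted(genos)

    def test_accuracy_nondecreasing_in_site_count(self):
        rng = np.random.default_rng(7)
        acc = {}
        for S in (100, 259, 1000):
            p = rng.uniform(0.4, 0.6, S)
            hits = 0
            n = 30
            for _ in range(n):
                mom, dads, eggs = simulate_family(rng, p, 6,
                                                  shared_father=False)
                genos = {f"E{k}": e for k, e in enumerate(eggs)}
                groups, _ = partition_paternal_groups(genos, mom, p)
                sizes = sorted(len(g) for g in groups)
                hits += sizes == [1, 5]
            acc[S] = hits / n
        assert acc[100] <= acc[259] + 0.1
        assert acc[259] <= acc[1000] + 0.05
        assert acc[1000] >= 0.9


class TestPaternalAlleleLLR:
    def test_same_father_positive_different_negative(self):
        rng = np.random.default_rng(8)
        S = 400
        p = rng.uniform(0.3, 0.7, S)
        mom1 = rng.binomial(2, p).astype(float)
        mom2 = rng.binomial(2, p).astype(float)
        dad = rng.binomial(2, p).astype(float)
        other = rng.binomial(2, p).astype(float)
        egg_a = (rng.binomial(1, mom1 / 2) + rng.binomial(1, dad / 2)).astype(float)
        egg_b = (rng.binomial(1, mom2 / 2) + rng.binomial(1, dad / 2)).astype(float)
        egg_c = (rng.binomial(1, mom2 / 2) + rng.binomial(1, other / 2)).astype(float)
        assert paternal_allele_llr(egg_a, egg_b, mom1, mom2, p) > 0
        assert paternal_allele_llr(egg_a, egg_c, mom1, mom2, p) < 0


class TestCrossNestLinking:
    def _lineage_setup(self, rng, shared=True):
        S = 300
        p = rng.uniform(0.35, 0.65, S)
        dadA = rng.binomial(2, p).astype(float)
        dadB = dadA if shared else rng.binomial(2, p).astype(float)
        genos, hens = {}, {}
        lineages = []
        for nest, (mom_name, dad) in enumerate(
                [("M1", dadA), ("M2", dadB)], start=1):
            mom = rng.binomial(2, p).astype(float)
            hens[mom_name] = mom
            eggs = []
            for k in range(5):
                e = f"N{nest}E{k}"
                genos[e] = (rng.binomial(1, mom / 2)
                            + rng.binomial(1, dad / 2)).astype(float)
                eggs.append(e)
            lineages.append(PaternalLineage(f"L{nest}", eggs, [f"N{nest}"],
                                            mother_id=mom_name))
        return lineages, genos, hens, p

    def test_shared_father_lineages_merge(self):
        rng = np.random.default_rng(9)
        lineages, genos, hens, p = self._lineage_setup(rng, shared=True)
        merged = link_cross_nest_lineages(lineages, genos, hens, p)
        assert merged["L1"] == merged["L2"]

    def test_unshared_fathers_stay_separate(self):
        rng = np.random.default_rng(10)
        lineages, genos, hens, p = self._lineage_setup(rng, shared=False)
        merged = link_cross_nest_lineages(lineages, genos, hens, p)
        assert merged["L1"] != merged["L2"]

    def test_renesting_same_pair_merges_full_sib_clutches(self):
        rng = np.random.default_rng(11)
        S = 300
        p = rng.uniform(0.35, 0.65, S)
        mom = rng.binomial(2, p).astype(float)
        dad = rng.binomial(2, p).astype(float)
        genos = {}
        lineages = []
        for nest in (1, 2):
            eggs = []
            for k in range(4):
                e = f"N{nest}E{k}"
                genos[e] = (rng.binomial(1, mom / 2)
                            + rng.binomial(1, dad / 2)).astype(float)
                eggs.append(e)
            lineages.append(PaternalLineage(f"L{nest}", eggs, [f"N{nest}"],
                                            mother_id="M1"))
        merged = link_cross_nest_lineages(lineages, genos, {"M1": mom}, p)
        assert merged["L1"] == merged["L2"]
        report = detect_renesting(lineages, merged)
        assert len(report) == 1
        assert bool(report.iloc[0]["shared_father"])

    def test_renest_with_different_fathers_not_shared(self):
        rng = np.random.default_rng(12)
        S = 300
        p = rng.uniform(0.35, 0.65, S)
        mom = rng.binomial(2, p).astype(float)
        genos = {}
        lineages = []
        for nest in (1, 2):
            dad = rng.binomial(2, p).astype(float)
            eggs = []
            for k in range(4):
                e = f"N{nest}E{k}"
                genos[e] = (rng.binomial(1, mom / 2)
                            + rng.binomial(1, dad / 2)).astype(float)
                eggs.append(e)
            lineages.append(PaternalLineage(f"L{nest}", eggs, [f"N{nest}"],
                                            mother_id="M1"))
        merged = link_cross_nest_lineages(lineages, genos, {"M1": mom}, p)
        report = detect_renesting(lineages, merged)
        assert not bool(report.iloc[0]["shared_father"])

    def test_single_clutch_empty_report(self):
        ln = [PaternalLineage("L1", ["E0"], ["N1"], mother_id="M1")]
        report = detect_renesting(ln, {"L1": "L1"})
        assert report.empty
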