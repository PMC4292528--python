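import numpy as np
import pytest
from scipy.stats import chi2_contingency

from famrare import (
    AscertainedFamilySampler,
    DiseaseModel,
    StratumSpec,
    VariantPanel,
    affection_prob,
    mendelian_transmit,
    sample_parents,
    simulate_controls,
    simulate_families,
    simulate_stratified,
)
from famrare.model import hwe_genotype_probs


class TestSampleParents:
    def test_hwe_frequencies_common_variant(self, rng):
        panel = VariantPanel(maf=np.array([0.5]))
        father, _ = sample_parents(panel, 100_000, rng)
        freqs = np.bincount(father[:, 0], minlength=3) / 100_000
        expected = np.array([0.25, 0.5, 0.25])
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert np.all(np.abs(freqs - expected) < 3 * se)

    def test_rare_carrier_fraction(self, rng):
        q = 0.005
        panel = VariantPanel(maf=np.array([q]))
        father, mother = sample_parents(panel, 100_000, rng)
        expected = 2 * q * (1 - q) + q**2
        for g in (father, mother):
            frac = np.mean(g[:, 0] > 0)
            se = np.sqrt(expected * (1 - expected) / 100_000)
            assert abs(frac - expected) < 3 * se


class TestMendelianTransmit:
    @pytest.mark.parametrize("gf,gm,expected", [(2, 2, 2), (0, 0, 0), (2, 0, 1)])
    def test_deterministic_parents(self, rng, gf, gm, expected):
        child, _ = mendelian_transmit(np.array([gf]), np.array([gm]), rng)
        assert child[0] == expected

    def test_het_parent_transmits_fairly(self, rng):
        n = 100_000
        father = np.ones((n, 1), dtype=np.int8)
        mother = np.zeros((n, 1), dtype=np.int8)
        child, (tf, tm) = mendelian_transmit(father, mother, rng)
        assert np.array_equal(child, tf + tm)
        frac = child.mean()
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / n)


def _family_categories(fam):
    """Encode each family's (father, mother, child) genotypes as one label."""
    parts = [fam.father_g, fam.mother_g, fam.children_g[:, 0, :]]
    code = np.zeros(fam.n_families, dtype=np.int64)
    for arr in parts:
        for j in range(arr.shape[1]):
            code = code * 3 + arr[:, j]
    return code


class TestAscertainedSampler:
    def test_matches_rejection_oracle(self, rng):
        """Tilted sampler and naive rejection give the same joint law of
        (parental genotypes, child genotype) -- chi-square homogeneity."""
        panel = VariantPanel(maf=np.array([0.05, 0.05]))
        model = DiseaseModel(c=0.05, beta=np.array([np.log(3.0), 0.0]))
        n = 100_000
        tilted = simulate_families("trio", n, panel, model, rng, method="tilted")
        reject = simulate_families(
            "trio", n, panel, model, rng, method="rejection", max_attempts=10**8
        )
        a = _family_categories(tilted)
        b = _family_categories(reject)
        cats = np.union1d(a, b)
        table = np.stack(
            [
                np.array([(a == c).sum() for c in cats]),
                np.array([(b == c).sum() for c in cats]),
            ]
        )
        # pool rare categories to keep expected counts reasonable
        keep = table.sum(axis=0) >= 10
        pooled = np.concatenate(
            [table[:, keep], table[:, ~keep].sum(axis=1, keepdims=True)], axis=1
        )
        _, p, _, _ = chi2_contingency(pooled)
        assert p > 0.01

    def test_null_transmission_rate_is_half(self, rng):
        """Under OR=1 ascertainment is genotype-independent: heterozygous
        parents transmit the minor allele to affected children half the
        time."""
        from famrare import extract_transmissions

        panel = VariantPanel(maf=np.array([0.05, 0.1]))
        model = DiseaseModel(c=0.05, beta=np.zeros(2))
        fam = simulate_families("trio", 50_000, panel, model, rng)
        tc = extract_transmissions(fam)
        b, c = tc.B.sum(), tc.C.sum()
        frac = b / (b + c)
        assert abs(frac - 0.5) < 3 * np.sqrt(0.25 / (b + c))

    def test_null_offspring_marginals_are_hwe(self, rng):
        panel = VariantPanel(maf=np.array([0.1]))
        model = DiseaseModel(c=0.02, beta=np.zeros(1))
        fam = simulate_families("trio", 50_000, panel, model, rng)
        freqs = np.bincount(fam.children_g[:, 0, 0], minlength=3) / fam.n_families
        expected = hwe_genotype_probs(0.1)
        se = np.sqrt(expected * (1 - expected) / fam.n_families)
        assert np.all(np.abs(freqs - expected) < 4 * se)

    def test_case_enrichment_matches_exact_conditional(self, rng):
        """Affected-child genotype frequencies equal the enumerated
        conditional P(g_child | affected) and exceed HWE for carriers."""
        q, c, orr = 0.05, 0.02, 4.0
        panel = VariantPanel(maf=np.array([q]))
        model = DiseaseModel(c=c, beta=np.array([np.log(orr)]))
        # exact conditional by enumeration over parental pairs and children
        hwe = hwe_genotype_probs(q)
        from famrare.simulate import _child_dist

        joint = np.zeros(3)
        for gf in range(3):
            for gm in range(3):
                sup, pr = _child_dist(gf, gm)
                for g, p in zip(sup, pr):
                    joint[g] += hwe[gf] * hwe[gm] * p * affection_prob(
                        model, np.array([g])
                    )
        cond = joint / joint.sum()
        n = 100_000
        fam = simulate_families("trio", n, panel, model, rng)
        freqs = np.bincount(fam.children_g[:, 0, 0], minlength=3) / n
        se = np.sqrt(cond * (1 - cond) / n)
        assert np.all(np.abs(freqs - cond) < 4 * se)
        carrier_pop = 1 - hwe[0]
        assert freqs[1:].sum() > carrier_pop

    def test_enriched_trio_child_matches_asp_child(self, rng, common_panel,
                                                   common_model):
        """The retained enriched-trio child has the same genotype law as the
        first child of an ASP (it is one, by construction)."""
        n = 30_000
        kw = dict(max_parent_alleles=12)  # full enumeration for 3 variants
        asp = simulate_families("asp", n, common_panel, common_model, rng, **kw)
        enr = simulate_families(
            "enriched_trio", n, common_panel, common_model, rng, **kw
        )
        a = asp.children_g[:, 0, :].sum(axis=1)
        e = enr.children_g[:, 0, :].sum(axis=1)
        top = max(a.max(), e.max()) + 1
        table = np.stack(
            [np.bincount(a, minlength=top), np.bincount(e, minlength=top)]
        )
        table = table[:, table.sum(axis=0) >= 10]
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01

    def test_asp_children_enriched_over_trio_children(self, rng, common_panel,
                                                      common_model):
        trio = simulate_families("trio", 20_000, common_panel, common_model, rng,
                                 max_parent_alleles=12)
        asp = simulate_families("asp", 20_000, common_panel, common_model, rng,
                                max_parent_alleles=12)
        assert asp.children_g[:, :, 0].mean() > trio.children_g[:, :, 0].mean()

    def test_mendelian_consistency_everywhere(self, rng, common_panel,
                                              common_model):
        from famrare import extract_transmissions

        for structure in ("trio", "asp", "enriched_trio"):
            fam = simulate_families(structure, 2000, common_panel, common_model,
                                    rng, max_parent_alleles=12)
            extract_transmissions(fam)  # raises on any inconsistency

    def test_budget_adapts_then_fails_when_intractable(self):
        # moderate panel: truncation at 4 parental alleles loses real mass,
        # and the budget grows automatically until the residual is in bound
        panel3 = VariantPanel(maf=np.full(3, 0.3))
        model3 = DiseaseModel(c=0.1, beta=np.zeros(3))
        s = AscertainedFamilySampler(panel3, model3, "trio", max_parent_alleles=2)
        assert s.max_parent_alleles > 2 and s.residual <= 1e-4
        # high-MAF panel: full enumeration is intractable -> error
        panel = VariantPanel(maf=np.full(6, 0.5))
        model = DiseaseModel(c=0.1, beta=np.zeros(6))
        with pytest.raises(ValueError, match="rejection sampler"):
            AscertainedFamilySampler(panel, model, "trio", max_parent_alleles=24)

    def test_rejection_sampler_attempt_guard(self):
        panel = VariantPanel(maf=np.array([0.005]))
        model = DiseaseModel(c=1e-6, beta=np.zeros(1))
        with pytest.raises(RuntimeError, match="attempts"):
            simulate_families(
                "asp", 100, panel, model, np.random.default_rng(0),
                method="rejection", max_attempts=10_000,
            )


class TestControls:
    def test_unscreened_matches_hwe(self, rng):
        panel = VariantPanel(maf=np.array([0.2]))
        model = DiseaseModel(c=0.05, beta=np.array([1.0]))
        cohort = simulate_controls(panel, model, 100_000, rng, screened=False)
        freqs = np.bincount(cohort.genotypes[:, 0], minlength=3) / cohort.n
        expected = hwe_genotype_probs(0.2)
        se = np.sqrt(expected * (1 - expected) / cohort.n)
        assert np.all(np.abs(freqs - expected) < 4 * se)
        assert cohort.phenotype.mean() > 0  # some affected retained

    def test_screened_controls_depleted_of_risk_alleles(self, rng):
        """Screened-control genotype frequencies match the exact law
        P(g | unaffected) = (1 - pen(g)) HWE(g) / (1 - prevalence)."""
        q, c, orr = 0.1, 0.05, 5.0
        panel = VariantPanel(maf=np.array([q]))
        model = DiseaseModel(c=c, beta=np.array([np.log(orr)]))
        hwe = hwe_genotype_probs(q)
        pen = np.array([affection_prob(model, np.array([g])) for g in range(3)])
        cond = (1 - pen) * hwe
        cond /= cond.sum()
        n = 200_000
        cohort = simulate_controls(panel, model, n, rng, screened=True)
        assert not cohort.phenotype.any()
        freqs = np.bincount(cohort.genotypes[:, 0], minlength=3) / n
        se = np.sqrt(cond * (1 - cond) / n)
        assert np.all(np.abs(freqs - cond) < 4 * se)
        assert freqs[1:].sum() < (1 - hwe[0])  # below population carrier rate

    def test_screening_guard_when_everyone_affected(self, rng):
        panel = VariantPanel(maf=np.array([0.1]))
        model = DiseaseModel(c=0.9999, beta=np.zeros(1))
        with pytest.raises(RuntimeError, match="attempts"):
            simulate_controls(panel, model, 1000, rng, max_attempts=5000)


class TestStratified:
    def _spec(self, weight, maf, orr, c=0.05):
        panel = VariantPanel(maf=np.asarray(maf))
        model = DiseaseModel(c=c, beta=np.log(np.asarray(orr)))
        return StratumSpec(weight=weight, panel=panel, model=model)

    def test_weights_must_sum_to_one(self, rng):
        strata = [self._spec(0.5, [0.05], [1.0]), self._spec(0.3, [0.1], [1.0])]
        with pytest.raises(ValueError, match="sum to 1"):
            simulate_stratified(strata, "trio", 100, 100, rng)

    def test_labels_follow_weights(self, rng):
        strata = [self._spec(0.7, [0.05], [2.0]), self._spec(0.3, [0.2], [1.0])]
        fam, cohort = simulate_stratified(strata, "trio", 20_000, 5000, rng)
        frac = np.mean(fam.stratum == 0)
        assert abs(frac - 0.7) < 3 * np.sqrt(0.21 / 20_000)
        assert cohort.stratum is not None and cohort.n == 5000

    def test_single_stratum_degenerates_to_plain_simulation(self, rng):
        strata = [self._spec(1.0, [0.1, 0.05], [2.0, 1.0])]
        fam, _ = simulate_stratified(strata, "trio", 20_000, 0, rng)
        plain = simulate_families(
            "trio", 20_000, strata[0].panel, strata[0].model, rng
        )
        a = fam.children_g[:, 0, 0]
        b = plain.children_g[:, 0, 0]
        table = np.stack(
            [np.bincount(a, minlength=3), np.bincount(b, minlength=3)]
        )
        table = table[:, table.sum(axis=0) >= 10]
        _, p, _, _ = chi2_contingency(table)
        assert p > 0.01
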