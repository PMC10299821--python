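import numpy as np
import pandas as pd
import pytest
from scipy import stats

from conftest import make_genotypes
from mungpop.quantgen import (
    VarianceComponents,
    additive_variance_within,
    estimate_inbreeding,
    inverse_normal_transform,
    mixed_anova,
    qst,
    qst_fst_compare,
    tukey_groups,
    variance_components,
)
from mungpop.simulate import TraitSimSpec, simulate_traits


class TestInverseNormal:
    def test_middle_of_three_maps_to_zero(self):
        out = inverse_normal_transform([5.0, 1.0, 9.0])
        assert out[0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone(self, rng):
        x = np.sort(rng.normal(size=50))
        out = inverse_normal_transform(x)
        assert np.all(np.diff(out) > 0)

    def test_blom_offsets_exact(self):
        # n=5 distinct values: rank r maps to Phi^-1((r - 3/8)/5.25)
        x = np.array([10.0, 20.0, 30.0, 40.0, 50.0])
        out = inverse_normal_transform(x)
        expected = stats.norm.ppf((np.arange(1, 6) - 0.375) / 5.25)
        np.testing.assert_allclose(out, expected, atol=1e-10)

    def test_all_equal_rejected(self):
        with pytest.raises(ValueError):
            inverse_normal_transform([1.0, 1.0, 1.0])


class TestInbreeding:
    def test_fully_homozygous_sample(self, rng):
        calls = rng.choice([0, 1, 2], size=(200, 10)).astype(np.int8)
        calls[:, 0] = np.where(calls[:, 0] == 1, 0, calls[:, 0])
        g = make_genotypes(calls)
        f, _ = estimate_inbreeding(g)
        assert f[0] == pytest.approx(1.0, abs=0.02)

    def test_outbred_null(self, rng):
        p = rng.uniform(0.2, 0.8, 5000)
        calls = rng.binomial(2, p[:, None], size=(5000, 30)).astype(np.int8)
        g = make_genotypes(calls)
        _, panel = estimate_inbreeding(g)
        assert panel == pytest.approx(0.0, abs=0.05)

    def test_no_polymorphic_sites_rejected(self):
        g = make_genotypes(np.zeros((10, 4), dtype=np.int8))
        with pytest.raises(ValueError):
            estimate_inbreeding(g)


def _balanced_traits(rng_seed, **spec_kw):
    defaults = dict(group_means={"g1": 0.0, "g2": 0.0, "g3": 0.0},
                    v_fam=1.0, v_resid=1.0)
    defaults.update(spec_kw)
    spec = TraitSimSpec(**defaults)
    assign = {f"g{k}_a{j}": f"g{k}" for k in (1, 2, 3) for j in range(8)}
    return simulate_traits(spec, assign, seed=rng_seed)


class TestMixedAnova:
    def test_table_shape_and_strata(self):
        t = _balanced_traits(1)
        tab = mixed_anova(t)
        assert list(tab["source"][:3]) == ["treatment", "group", "treatment:group"]
        assert tab["df"].sum() == len(t) - 1

    def test_interaction_power(self):
        hits = 0
        for seed in range(10):
            t = _balanced_traits(seed, interaction={"g1": 3.0, "g2": -3.0, "g3": 0.0},
                                 v_resid=0.5)
            tab = mixed_anova(t).set_index("source")
            fixed = tab.loc[["treatment", "group", "treatment:group"], "F"]
            hits += fixed.idxmax() == "treatment:group"
        assert hits == 10

    def test_type_i_error_calibrated(self):
        reps = 200
        hits = {"treatment": 0, "group": 0, "treatment:group": 0}
        for seed in range(reps):
            t = _balanced_traits(seed + 1000)
            tab = mixed_anova(t).set_index("source")
            for term in hits:
                hits[term] += tab.loc[term, "p"] < 0.05
        for term, h in hits.items():
            assert 0.02 <= h / reps <= 0.10, (term, h / reps)

    def test_degenerate_design_rejected(self):
        t = pd.DataFrame({
            "accession": ["a1", "a1"], "group": ["g", "g"],
            "batch": ["b1", "b1"], "treatment": ["c", "c"],
            "replicate": [1, 2], "trait": ["t", "t"], "value": [1.0, 2.0],
        })
        with pytest.raises(ValueError):
            mixed_anova(t)

    def test_tukey_separates_shifted_group(self):
        spec = TraitSimSpec(group_means={"g1": 0.0, "g2": 0.0, "g3": 4.0},
                            v_fam=0.2, v_resid=0.3, treatments=("control",))
        assign = {f"g{k}_a{j}": f"g{k}" for k in (1, 2, 3) for j in range(10)}
        t = simulate_traits(spec, assign, seed=5)
        tab = tukey_groups(t)
        sig = tab[tab.significant]
        assert {("g1", "g3"), ("g2", "g3")} <= set(zip(sig.group_a, sig.group_b))


class TestVarianceComponents:
    def test_hand_computable_toy_exact(self):
        # 2 groups x 2 accessions x 2 replicates, single batch: EMS algebra
        rows = []
        data = {
            ("g1", "a1"): [1.0, 2.0], ("g1", "a2"): [3.0, 5.0],
            ("g2", "a3"): [7.0, 8.0], ("g2", "a4"): [10.0, 13.0],
        }
        for (grp, acc), vals in data.items():
            for rep, v in enumerate(vals):
                rows.append(dict(accession=acc, group=grp, batch="b1",
                                 treatment="c", replicate=rep + 1,
                                 trait="t", value=v))
        t = pd.DataFrame(rows)
        vc = variance_components(t)
        y = np.array([[1, 2], [3, 5], [7, 8], [10, 13]], dtype=float)
        acc_means = y.mean(axis=1)
        grp_means = acc_means.reshape(2, 2).mean(axis=1)
        grand = y.mean()
        ms_e = np.sum((y - acc_means[:, None]) ** 2) / 4       # df = 4
        ms_a = 2 * np.sum((acc_means - np.repeat(grp_means, 2)) ** 2) / 2
        ms_g = 4 * np.sum((grp_means - grand) ** 2) / 1
        assert vc.v_resid == pytest.approx(ms_e)
        assert vc.v_fam == pytest.approx((ms_a - ms_e) / 2)
        assert vc.v_b == pytest.approx((ms_g - ms_a) / 4)

    def test_parameter_recovery_median(self):
        est = []
        for seed in range(10):
            spec = TraitSimSpec(
                group_means={f"g{i}": 0.0 for i in range(50)},
                v_b=2.0, v_fam=1.0, v_resid=1.0, treatments=("control",),
                n_batches=2, n_reps=3,
            )
            assign = {f"g{i}_a{j}": f"g{i}" for i in range(50) for j in range(20)}
            t = simulate_traits(spec, assign, seed=seed)
            vc = variance_components(t)
            est.append((vc.v_b, vc.v_fam))
        med = np.median(est, axis=0)
        assert med[0] == pytest.approx(2.0, rel=0.25)
        assert med[1] == pytest.approx(1.0, rel=0.25)

    def test_null_group_variance_near_zero(self):
        est = []
        for seed in range(8):
            spec = TraitSimSpec(group_means={f"g{i}": 0.0 for i in range(20)},
                                v_b=0.0, v_fam=1.0, v_resid=1.0,
                                treatments=("control",))
            assign = {f"g{i}_a{j}": f"g{i}" for i in range(20) for j in range(10)}
            vc = variance_components(simulate_traits(spec, assign, seed=seed))
            est.append(vc.v_b)
        assert np.median(est) < 0.1

    def test_multiple_treatments_rejected(self):
        t = _balanced_traits(3)
        with pytest.raises(ValueError):
            variance_components(t)


class TestAdditiveVariance:
    @staticmethod
    def _random_k(rng, n):
        a = rng.normal(size=(n, n))
        k = a @ a.T / n
        return k / np.mean(np.diag(k))

    def test_recovery_median(self):
        est = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            k = self._random_k(r, 100)
            acc = [f"a{i}" for i in range(100)]
            assign = {a: ("g1" if i < 50 else "g2") for i, a in enumerate(acc)}
            spec = TraitSimSpec(group_means={"g1": 0.0, "g2": 0.0}, v_aw=1.0,
                                v_resid=1.0, n_batches=1, n_reps=1,
                                treatments=("control",))
            t = simulate_traits(spec, assign, relationship=k, seed=seed + 30)
            v_aw, _ = additive_variance_within(t, k, accessions=acc)
            est.append(v_aw)
        assert np.median(est) == pytest.approx(1.0, rel=0.30)

    def test_identity_k_agrees_with_moments(self):
        # K = I reduces the polygenic term to an accession variance
        spec = TraitSimSpec(group_means={"g1": 0.0, "g2": 0.0}, v_fam=1.5,
                            v_resid=1.0, n_batches=2, n_reps=3,
                            treatments=("control",))
        assign = {f"a{i}": ("g1" if i < 25 else "g2") for i in range(50)}
        t = simulate_traits(spec, assign, seed=8)
        v_aw, _ = additive_variance_within(t, np.eye(50),
                                           accessions=list(assign))
        vc = variance_components(t)
        assert v_aw == pytest.approx(vc.v_fam, rel=0.25, abs=0.15)

    def test_zero_heritability_null(self):
        est = []
        for seed in range(8):
            r = np.random.default_rng(seed)
            k = self._random_k(r, 60)
            acc = [f"a{i}" for i in range(60)]
            assign = {a: ("g1" if i < 30 else "g2") for i, a in enumerate(acc)}
            spec = TraitSimSpec(group_means={"g1": 0.0, "g2": 0.0}, v_aw=0.0,
                                v_resid=1.0, n_batches=1, n_reps=1,
                                treatments=("control",))
            t = simulate_traits(spec, assign, relationship=k, seed=seed + 60)
            v_aw, _ = additive_variance_within(t, k, accessions=acc)
            est.append(v_aw)
        assert np.median(est) < 0.15

    def test_non_psd_rejected(self):
        t = _balanced_traits(9)
        n = t["accession"].nunique()
        bad = np.eye(n)
        bad[0, 1] = bad[1, 0] = 2.0
        with pytest.raises(ValueError):
            additive_variance_within(t, bad)


class TestQst:
    def test_equation1_symmetry(self):
        assert qst(v_b=1.7, v_fam=1.7, equation=1) == pytest.approx(0.5)

    def test_equation2_closed_forms(self):
        assert qst(v_b=1.0, v_aw=1.0, f=0.0, equation=2) == pytest.approx(1 / 3)
        assert qst(v_b=1.0, v_aw=1.0, f=0.8425, equation=2) == pytest.approx(
            1.8425 / 3.8425, abs=1e-12
        )

    def test_bounds_and_degenerate(self):
        assert qst(v_b=0.0, v_fam=2.0, equation=1) == 0.0
        assert qst(v_b=2.0, v_fam=0.0, equation=1) == 1.0
        assert np.isnan(qst(v_b=0.0, v_fam=0.0, equation=1))
        with pytest.raises(ValueError):
            qst(v_b=1.0, equation=2)  # missing v_aw

    def test_monotone_in_components(self):
        vb = np.linspace(0.1, 5.0, 20)
        q1 = [qst(v_b=v, v_fam=1.0, equation=1) for v in vb]
        q2 = [qst(v_b=v, v_aw=1.0, f=0.5, equation=2) for v in vb]
        assert np.all(np.diff(q1) > 0) and np.all(np.diff(q2) > 0)
        vw = np.linspace(0.1, 5.0, 20)
        q1w = [qst(v_b=1.0, v_fam=v, equation=1) for v in vw]
        q2w = [qst(v_b=1.0, v_aw=v, f=0.5, equation=2) for v in vw]
        assert np.all(np.diff(q1w) < 0) and np.all(np.diff(q2w) < 0)

    def test_from_components_object(self):
        vc = VarianceComponents(v_b=1.0, v_fam=3.0, v_batch=0.0, v_resid=1.0)
        assert qst(vc, equation=1) == pytest.approx(0.25)


class TestQstFstCompare:
    def test_threshold_flags(self, rng):
        fst_vals = rng.uniform(0.0, 0.2, 2000)
        res = qst_fst_compare({("rdw", "control"): 0.9,
                               ("sdw", "control"): 0.0}, fst_vals)
        high = next(r for r in res if r.trait == "rdw")
        low = next(r for r in res if r.trait == "sdw")
        assert high.exceeds_mean and high.exceeds_q95 and high.exceeds_q99
        assert not (low.exceeds_mean or low.exceeds_q95 or low.exceeds_q99)
        assert high.fst_mean <= high.fst_q95 <= high.fst_q99

    def test_boundary_equal_to_mean(self, rng):
        fst_vals = rng.uniform(0.0, 0.2, 1000)
        mean = fst_vals.mean()
        res = qst_fst_compare({("t", "c"): mean}, fst_vals)
        assert not res[0].exceeds_mean

    def test_empty_distribution_rejected(self):
        with pytest.raises(ValueError):
            qst_fst_compare({("t", "c"): 0.5}, np.array([np.nan]))
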