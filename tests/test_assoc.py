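import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from waverep import assoc
from waverep.assoc import (
    AssocResult,
    DosageLD,
    Hit,
    PRSProfile,
    clump,
    combine_prs,
    evaluate_prs,
    gwas,
    inverse_normal_transform,
    locus_spans,
    merge_loci,
    paired_bootstrap_compare,
    prs_from_assoc,
    residualize,
    score_prs,
    variant_qc_mask,
)
from waverep.synthetic import GenotypeMatrix, simulate_genotypes


def _toy_genotypes(dosages, positions=None, chromosome=None):
    dosages = np.asarray(dosages, dtype=float)
    m = dosages.shape[1]
    return GenotypeMatrix(
        dosages=dosages,
        variant_ids=[f"v{j}" for j in range(m)],
        chromosome=(np.asarray(chromosome) if chromosome is not None
                    else np.ones(m, dtype=np.int64)),
        position_bp=(np.asarray(positions) if positions is not None
                     else np.arange(1, m + 1) * 1000),
        maf=np.full(m, 0.3),
    )


class TestGWAS:
    def test_perfect_fit(self, small_genotypes):
        y = small_genotypes.dosages[:, 3].copy()
        res = gwas(small_genotypes, y)
        row = res.table.iloc[3]
        assert row["BETA"] == pytest.approx(1.0, abs=1e-10)
        assert row["P"] < 1e-300

    def test_null_calibration(self):
        G = simulate_genotypes(2000, 500, seed=21)
        rng = np.random.default_rng(22)
        y = rng.standard_normal(2000)
        res = gwas(G, y)
        frac = (res.table["P"] < 0.05).mean()
        # binomial 99% CI around 0.05 with m=500
        half = 2.576 * np.sqrt(0.05 * 0.95 / 500)
        assert abs(frac - 0.05) < half

    def test_frisch_waugh_lovell_equivalence(self):
        import statsmodels.api as sm

        G = simulate_genotypes(300, 10, seed=31)
        rng = np.random.default_rng(32)
        cov = pd.DataFrame({"a": rng.normal(size=300),
                            "b": rng.normal(size=300)})
        y = (G.dosages[:, 4] * 0.4 + cov["a"] * 0.7
             + rng.normal(size=300))
        res = gwas(G, y.to_numpy(), cov)
        X = sm.add_constant(np.column_stack([G.dosages[:, 4], cov]))
        fit = sm.OLS(y, X).fit()
        row = res.table.iloc[4]
        assert row["BETA"] == pytest.approx(fit.params.iloc[1], rel=1e-9)
        assert row["SE"] == pytest.approx(fit.bse.iloc[1], rel=1e-9)
        assert row["P"] == pytest.approx(fit.pvalues.iloc[1], rel=1e-6)

    def test_zero_variance_variant_skipped(self):
        d = np.random.default_rng(0).integers(0, 3, size=(100, 3)).astype(float)
        d[:, 1] = 2.0
        G = _toy_genotypes(d)
        res = gwas(G, d[:, 0] + np.random.default_rng(1).normal(size=100))
        assert res.table["CODE"].iloc[1] == "ZERO_VARIANCE"
        assert np.isnan(res.table["P"].iloc[1])

    def test_constant_phenotype_all_skipped(self, small_genotypes):
        res = gwas(small_genotypes, np.full(800, 3.0))
        assert (res.table["CODE"] == "CONSTANT_PHENOTYPE").all()

    def test_missing_rows_dropped(self, small_genotypes):
        y = small_genotypes.dosages[:, 0].copy()
        y[:10] = np.nan
        res = gwas(small_genotypes, y)
        assert res.n_used == 790

    def test_too_few_complete_cases_raises(self, small_genotypes):
        y = np.full(800, np.nan)
        y[:10] = 1.0
        with pytest.raises(ValueError):
            gwas(small_genotypes, y)


class TestVariantQC:
    def test_maf_filter(self):
        d = np.zeros((1000, 2))
        d[0, 0] = 1.0  # MAF 0.0005 < 0.001
        d[:500, 1] = 1.0
        G = _toy_genotypes(d)
        mask = variant_qc_mask(G, hwe_p_min=0.0)
        assert not mask[0] and mask[1]

    def test_hwe_filter(self):
        rng = np.random.default_rng(5)
        hwe_ok = rng.binomial(2, 0.5, size=2000).astype(float)
        all_het = np.ones(2000)  # wildly out of HWE
        G = _toy_genotypes(np.column_stack([hwe_ok, all_het]))
        mask = variant_qc_mask(G)
        assert mask[0] and not mask[1]


class TestInverseNormalTransform:
    def test_moments(self):
        rng = np.random.default_rng(9)
        z = inverse_normal_transform(rng.exponential(size=1000))
        assert abs(z.mean()) < 0.01
        assert z.std() == pytest.approx(1.0, abs=0.02)

    def test_rank_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=500)
        assert np.allclose(inverse_normal_transform(x),
                           inverse_normal_transform(np.exp(3 * x)))

    def test_symmetry(self):
        z = inverse_normal_transform(np.arange(11, dtype=float))
        assert np.allclose(z, -z[::-1])

    def test_constant_raises(self):
        with pytest.raises(ValueError):
            inverse_normal_transform(np.ones(10))


def _assoc_from_pvalues(pvals, positions=None, chromosome=None):
    m = len(pvals)
    table = pd.DataFrame({
        "CHR": chromosome if chromosome is not None else np.ones(m, int),
        "POS": positions if positions is not None else np.arange(1, m + 1) * 1000,
        "ID": [f"v{j}" for j in range(m)],
        "BETA": np.ones(m), "SE": np.ones(m), "P": pvals, "CODE": "",
    })
    return AssocResult(table=table, phenotype_id="t", n_used=100)


class _FixedLD:
    """LD source backed by an explicit r^2 matrix (for oracle tests)."""

    def __init__(self, r2):
        self.r2 = np.asarray(r2, dtype=float)

    def r2_with(self, j):
        return self.r2[j]


def _clump_oracle(assoc_res, ld, p_threshold, r2_threshold):
    """Slow reference implementation: rescan for the best p each round."""
    t = assoc_res.table
    alive = [i for i in t.index
             if t.loc[i, "CODE"] == "" and t.loc[i, "P"] <= p_threshold]
    hits = []
    while alive:
        best = min(alive, key=lambda i: (t.loc[i, "P"], t.loc[i, "POS"],
                                         t.loc[i, "ID"]))
        hits.append(best)
        r2 = ld.r2_with(best)
        alive = [i for i in alive if i != best and not (r2[i] >= r2_threshold)]
    return hits


class TestClump:
    def test_singleton(self):
        res = _assoc_from_pvalues([1e-9, 0.5, 0.2])
        ld = _FixedLD(np.eye(3))
        hits = clump(res, ld)
        assert [h.variant_id for h in hits] == ["v0"]

    def test_correlated_pair_keeps_more_significant(self):
        r2 = np.eye(3)
        r2[0, 1] = r2[1, 0] = 0.5
        res = _assoc_from_pvalues([1e-10, 1e-9, 0.9])
        hits = clump(res, _FixedLD(r2))
        assert [h.variant_id for h in hits] == ["v0"]

    def test_independent_pair_both_kept(self):
        r2 = np.eye(2)
        r2[0, 1] = r2[1, 0] = 0.05
        res = _assoc_from_pvalues([1e-10, 1e-9])
        assert len(clump(res, _FixedLD(r2))) == 2

    def test_exhaustive_oracle_random_instances(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            m = rng.integers(2, 15)
            pv = 10.0 ** rng.uniform(-12, 0, size=m)
            a = rng.uniform(0, 1, size=(m, m))
            r2 = (a + a.T) / 2
            np.fill_diagonal(r2, 1.0)
            res = _assoc_from_pvalues(pv)
            ld = _FixedLD(r2)
            fast = [h.index for h in clump(res, ld, p_threshold=1e-4)]
            slow = _clump_oracle(res, ld, 1e-4, 0.1)
            assert fast == slow


class TestMergeLoci:
    def _hits(self, positions, pvals, chrom=1):
        return [Hit(variant_id=f"v{i}", chromosome=chrom, position_bp=p,
                    p=pv, index=i)
                for i, (p, pv) in enumerate(zip(positions, pvals))]

    def test_close_hits_merge(self):
        hits = self._hits([1, 100_001], [1e-9, 1e-10])
        loci = merge_loci(hits)
        assert len(loci) == 1
        assert loci[0].lead_variant_id == "v1"

    def test_distant_hits_stay_separate(self):
        loci = merge_loci(self._hits([1, 400_001], [1e-9, 1e-10]))
        assert len(loci) == 2

    def test_different_chromosomes_never_merge(self):
        hits = [Hit("a", 1, 10, 1e-9, 0), Hit("b", 2, 20, 1e-9, 1)]
        assert len(merge_loci(hits)) == 2

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            m = rng.integers(1, 12)
            pos = np.sort(rng.integers(1, 3_000_000, size=m))
            hits = self._hits(pos.tolist(),
                              10.0 ** rng.uniform(-15, -8, size=m))
            loci1 = merge_loci(hits)
            # re-merge the merged loci as point hits at their spans
            hits2 = [Hit(loc.lead_variant_id, loc.chromosome, loc.start_bp,
                         loc.lead_p, i) for i, loc in enumerate(loci1)]
            spans2 = [(loc.start_bp, loc.end_bp) for loc in loci1]
            loci2 = merge_loci(hits2, spans2)
            assert [(l.start_bp, l.end_bp) for l in loci2] \
                == [(l.start_bp, l.end_bp) for l in loci1]

    def test_pairwise_merge_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            m = int(rng.integers(2, 13))
            pos = np.sort(rng.choice(2_000_000, size=m, replace=False)) + 1
            pv = 10.0 ** rng.uniform(-15, -8, size=m)
            hits = self._hits(pos.tolist(), pv)
            got = merge_loci(hits)
            # oracle: iterate pairwise merging to a fixed point
            spans = [(p, p) for p in pos]
            changed = True
            while changed:
                changed = False
                for i, j in itertools.combinations(range(len(spans)), 2):
                    a, b = spans[i], spans[j]
                    gap = max(a[0], b[0]) - min(a[1], b[1])
                    if gap < 250_000:
                        spans[i] = (min(a[0], b[0]), max(a[1], b[1]))
                        del spans[j]
                        changed = True
                        break
            assert sorted((l.start_bp, l.end_bp) for l in got) \
                == sorted(spans)

    def test_locus_spans_cover_ld_partners(self):
        G = simulate_genotypes(3000, 20, ld_block_size=5, ld_rho=0.7,
                               seed=41)
        ld = DosageLD(G)
        hits = [Hit(G.variant_ids[2], 1, int(G.position_bp[2]), 1e-9, 2)]
        (start, end), = locus_spans(hits, G, ld)
        assert start <= G.position_bp[2] <= end
        assert end > start  # block partners extend the span


class TestScorePRS:
    def test_zero_betas(self, small_genotypes):
        betas = pd.Series(0.0, index=small_genotypes.variant_ids[:5])
        assert np.allclose(score_prs(small_genotypes, betas), 0.0)

    def test_single_variant_arithmetic(self):
        G = _toy_genotypes([[2.0], [1.0], [0.0]])
        s = score_prs(G, {"v0": 0.3})
        assert np.allclose(s, [0.6, 0.3, 0.0])

    def test_loop_oracle(self, small_genotypes):
        rng = np.random.default_rng(55)
        ids = list(rng.choice(small_genotypes.variant_ids, 12, replace=False))
        betas = pd.Series(rng.normal(size=12), index=ids)
        fast = score_prs(small_genotypes, betas)
        col = {v: j for j, v in enumerate(small_genotypes.variant_ids)}
        slow = np.zeros(small_genotypes.n_individuals)
        for vid, b in betas.items():
            slow += small_genotypes.dosages[:, col[vid]] * b
        assert np.allclose(fast, slow)

    def test_unmatched_warns_and_partial(self, small_genotypes):
        betas = pd.Series([1.0, 1.0],
                          index=[small_genotypes.variant_ids[0], "rs_nope"])
        with pytest.warns(UserWarning):
            s = score_prs(small_genotypes, betas)
        assert np.allclose(s, small_genotypes.dosages[:, 0])

    def test_no_match_raises(self, small_genotypes):
        with pytest.raises(ValueError):
            score_prs(small_genotypes, {"nope": 1.0})


class TestCombinePRS:
    def _profile(self, n=2000, seed=0):
        rng = np.random.default_rng(seed)
        signal = rng.standard_normal(n)
        cols = {"good": signal + 0.5 * rng.standard_normal(n),
                "noise1": rng.standard_normal(n),
                "noise2": rng.standard_normal(n)}
        labels = (signal + rng.standard_normal(n) > 1.0).astype(float)
        return PRSProfile(scores=pd.DataFrame(cols)), labels

    def test_informative_column_gets_largest_weight(self):
        from sklearn.metrics import roc_auc_score

        profile, labels = self._profile()
        combined = combine_prs(profile, labels)
        w = np.abs(combined.weights)
        assert w[0] == w.max()
        auc_combined = roc_auc_score(labels, combined.scores)
        auc_solo = roc_auc_score(labels, profile.matrix[:, 0])
        assert auc_combined >= auc_solo - 0.01

    def test_null_labels_auc_near_half(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        profile = PRSProfile(scores=pd.DataFrame(
            rng.standard_normal((5000, 3)), columns=list("abc")))
        labels = (rng.uniform(size=5000) < 0.3).astype(float)
        combined = combine_prs(profile, labels)
        assert abs(roc_auc_score(labels, combined.scores) - 0.5) < 0.03

    def test_duplicated_column_predictions_unchanged(self):
        profile, labels = self._profile(seed=3)
        dup = PRSProfile(scores=profile.scores.assign(
            dup=profile.scores["good"]))
        a = combine_prs(profile, labels, family="linear")
        b = combine_prs(dup, labels, family="linear")
        assert np.allclose(a.scores, b.scores, atol=1e-6)

    def test_perfect_separation_falls_back_to_ridge(self):
        n = 200
        x = np.concatenate([np.full(100, -2.0), np.full(100, 2.0)])
        labels = (x > 0).astype(float)
        profile = PRSProfile(scores=pd.DataFrame({"x": x}))
        combined = combine_prs(profile, labels)
        assert combined.ridge_fallback

    def test_single_class_raises(self):
        profile = PRSProfile(scores=pd.DataFrame({"x": np.arange(100.0)}))
        with pytest.raises(ValueError):
            combine_prs(profile, np.zeros(100))

    def test_linear_family(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((500, 2))
        y = X @ np.array([1.0, -2.0]) + 3.0
        profile = PRSProfile(scores=pd.DataFrame(X, columns=["a", "b"]))
        combined = combine_prs(profile, y, family="linear")
        assert np.allclose(combined.weights, [1.0, -2.0], atol=1e-10)
        assert combined.intercept == pytest.approx(3.0, abs=1e-10)


class TestEvaluatePRS:
    def test_perfect_separation_strata(self):
        n = 1000
        labels = np.zeros(n)
        labels[:50] = 1  # 5% prevalence
        scores = labels * 10 + np.linspace(0, 1, n)
        out = evaluate_prs(scores, labels)
        assert out["auc_roc"] == 1.0
        assert out["top10_prevalence"] == pytest.approx(0.5)
        assert out["bottom10_prevalence"] == 0.0

    def test_random_score_top_decile_near_overall(self):
        rng = np.random.default_rng(6)
        labels = (rng.uniform(size=20_000) < 0.1).astype(float)
        scores = rng.standard_normal(20_000)
        out = evaluate_prs(scores, labels)
        assert out["top10_prevalence"] == pytest.approx(0.1, abs=0.03)

    def test_score_equals_labels(self):
        labels = np.array([0, 0, 1, 1, 0, 1], dtype=float)
        out = evaluate_prs(labels.copy(), labels)
        assert out["auc_roc"] == 1.0
        assert out["auc_pr"] == 1.0

    def test_single_class_flagged(self):
        out = evaluate_prs(np.arange(10.0), np.zeros(10))
        assert np.isnan(out["auc_roc"])
        assert "flag" in out


class TestPairedBootstrap:
    def test_identical_scores_not_significant(self):
        rng = np.random.default_rng(8)
        labels = (rng.uniform(size=500) < 0.3).astype(float)
        s = rng.standard_normal(500) + labels
        res = paired_bootstrap_compare(s, s.copy(), labels, seed=1)
        assert res.difference == 0.0
        assert res.ci_low <= 0.0 <= res.ci_high
        assert not res.significant

    def test_informative_vs_noise_significant(self):
        rng = np.random.default_rng(9)
        n = 5000
        liab = rng.standard_normal(n)
        labels = (liab > 1.0).astype(float)
        good = liab + 0.5 * rng.standard_normal(n)
        noise = rng.standard_normal(n)
        res = paired_bootstrap_compare(good, noise, labels, seed=2)
        assert res.significant
        assert res.difference > 0

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(10)
        labels = (rng.uniform(size=300) < 0.4).astype(float)
        a = rng.standard_normal(300) + labels
        b = rng.standard_normal(300)
        r1 = paired_bootstrap_compare(a, b, labels, seed=7)
        r2 = paired_bootstrap_compare(a, b, labels, seed=7)
        assert (r1.ci_low, r1.ci_high) == (r2.ci_low, r2.ci_high)

    def test_low_reps_warn(self):
        labels = np.array([0, 1] * 50, dtype=float)
        s = np.arange(100.0)
        with pytest.warns(UserWarning):
            paired_bootstrap_compare(s, s, labels, reps=10, seed=0)


class TestResidualize:
    def test_orthogonality(self):
        rng = np.random.default_rng(11)
        F = rng.standard_normal((400, 3))
        E = F @ rng.standard_normal((3, 2)) + rng.standard_normal((400, 2))
        R = residualize(E, F)
        for j in range(2):
            for k in range(3):
                assert abs(stats.pearsonr(R[:, j], F[:, k]).statistic) < 1e-10

    def test_unrelated_features_residuals_near_centered(self):
        rng = np.random.default_rng(12)
        E = rng.standard_normal((2000, 2))
        F = rng.standard_normal((2000, 3))
        R = residualize(E, F)
        assert np.allclose(R, E - E.mean(axis=0), atol=0.2)

    def test_exact_linear_dependence_gives_zero(self):
        rng = np.random.default_rng(13)
        F = rng.standard_normal((100, 3))
        E = F @ np.array([[1.0], [2.0], [-1.0]]) + 5.0
        R = residualize(E, F)
        assert np.allclose(R, 0.0, atol=1e-10)

    def test_collinear_columns_dropped_with_warning(self):
        rng = np.random.default_rng(14)
        F = rng.standard_normal((100, 2))
        F = np.column_stack([F, F[:, 0] * 2.0])
        E = rng.standard_normal((100, 1))
        with pytest.warns(UserWarning):
            R = residualize(E, F)
        assert R.shape == (100, 1)


class TestPrsFromAssoc:
    def test_end_to_end_signal(self):
        G = simulate_genotypes(3000, 50, seed=61)
        rng = np.random.default_rng(62)
        y = G.standardized()[:, 7] * 0.5 + rng.standard_normal(3000) * 0.5
        res = gwas(G, y)
        ld = DosageLD(G)
        s = prs_from_assoc(G, res, ld, p_threshold=1e-4)
        assert abs(stats.pearsonr(s, y).statistic) > 0.3

    def test_no_hits_gives_zero_scores(self, small_genotypes):
        rng = np.random.default_rng(63)
        res = gwas(small_genotypes, rng.standard_normal(800))
        ld = DosageLD(small_genotypes)
        s = prs_from_assoc(small_genotypes, res, ld, p_threshold=1e-30)
        assert np.allclose(s, 0.0)
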