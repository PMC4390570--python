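"""Family REML vs the balanced-ANOVA oracle, broad-sense heritability,
genomic relationships, G-BLUP, and the mixed-model association scan."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats

import wqscan as w
from wqscan.quantgen import FamilyVarianceModel


def balanced_anova_oracle(df, trait="y"):
    """Expected-mean-squares estimators for the balanced family x env x rep
    design with replicate-within-environment fixed effects removed.

    Independent of the REML code path: plain groupby arithmetic.
    """
    d = df.rename(columns={trait: "y"}).copy()
    F = d["family"].nunique()
    e = d["environment"].nunique()
    r = d.groupby("environment")["replicate"].nunique().iloc[0]
    d["ybar_ij"] = d.groupby(["family", "environment"])["y"].transform("mean")
    d["ybar_jk"] = d.groupby(["environment", "replicate"])["y"].transform("mean")
    d["ybar_j"] = d.groupby("environment")["y"].transform("mean")
    d["ybar_i"] = d.groupby("family")["y"].transform("mean")
    gm = d["y"].mean()
    ms_err = (((d["y"] - d["ybar_ij"] - d["ybar_jk"] + d["ybar_j"]) ** 2).sum()
              / ((F - 1) * e * (r - 1)))
    ms_int = (((d["ybar_ij"] - d["ybar_i"] - d["ybar_j"] + gm) ** 2).sum()
              / ((F - 1) * (e - 1)))
    ms_fam = e * r * ((d.groupby("family")["y"].mean() - gm) ** 2).sum() / (F - 1)
    return ((ms_fam - ms_int) / (e * r), (ms_int - ms_err) / r, ms_err)


def simulate_trial(rng, F=150, e=2, r=3, s2g=4.0, s2ge=2.0, s2e=6.0):
    fam = np.repeat(np.arange(F), e * r)
    env = np.tile(np.repeat(np.arange(e), r), F)
    rep = np.tile(np.arange(r), F * e)
    g = rng.normal(0, np.sqrt(s2g), F)
    ge = rng.normal(0, np.sqrt(s2ge), (F, e)) if s2ge > 0 else np.zeros((F, e))
    env_eff = rng.normal(0, 1, e)
    rep_eff = rng.normal(0, 0.5, (e, r))
    y = (10 + g[fam] + env_eff[env] + ge[fam, env] + rep_eff[env, rep]
         + rng.normal(0, np.sqrt(s2e), F * e * r))
    return pd.DataFrame({"family": fam, "environment": env, "replicate": rep,
                         "y": y})


class TestFamilyReml:
    def test_zero_noise_degenerate_recovery(self):
        # family values constant across plots: residual 0, family variance
        # equals the variance of the values
        F, e, r = 30, 2, 2
        vals = np.linspace(-3, 3, F)
        df = pd.DataFrame({
            "family": np.repeat(np.arange(F), e * r),
            "environment": np.tile(np.repeat([0, 1], r), F),
            "replicate": np.tile([0, 1], F * e),
            "y": np.repeat(vals, e * r),
        })
        fit = w.fit_family_varcomps(df, "y")
        assert fit.sigma2_e == pytest.approx(0.0, abs=1e-6)
        assert fit.sigma2_G == pytest.approx(np.var(vals, ddof=1), abs=1e-6)

    def test_matches_ems_oracle_on_balanced_design(self):
        rng = np.random.default_rng(42)
        df = simulate_trial(rng)
        og, oge, oe = balanced_anova_oracle(df)
        fit = w.fit_family_varcomps(df, "y")
        assert fit.sigma2_G == pytest.approx(og, abs=1e-6)
        assert fit.sigma2_GE == pytest.approx(oge, abs=1e-6)
        assert fit.sigma2_e == pytest.approx(oe, abs=1e-6)

    def test_single_environment_flags_structural_zero(self):
        rng = np.random.default_rng(1)
        df = simulate_trial(rng, e=1, s2ge=0.0)
        with pytest.warns(UserWarning, match="single environment"):
            fit = w.fit_family_varcomps(df, "y")
        assert fit.sigma2_GE == 0.0
        assert fit.single_environment

    def test_blups_shrink_toward_zero(self):
        rng = np.random.default_rng(2)
        df = simulate_trial(rng, F=60)
        fit = w.fit_family_varcomps(df, "y")
        fam_dev = df.groupby("family")["y"].mean() - df["y"].mean()
        # BLUPs are regularized family deviations: same sign pattern mostly,
        # smaller spread
        assert fit.blups.std() < fam_dev.std()
        assert np.corrcoef(fit.blups, fam_dev)[0, 1] > 0.9

    def test_summary_mentions_components(self):
        rng = np.random.default_rng(3)
        fit = w.fit_family_varcomps(simulate_trial(rng, F=40), "y")
        text = fit.summary()
        assert "sigma2_G" in text and "broad-sense H" in text


class TestBroadSenseH:
    @pytest.mark.parametrize("vc,e,r,expected", [
        ((1.0, 0.0, 0.0), 2, 2, 1.0),
        ((1.0, 1.0, 1.0), 2, 2, 1 / (1 + 0.5 + 0.25)),
        ((0.0, 1.0, 1.0), 2, 2, 0.0),
    ])
    def test_point_values(self, vc, e, r, expected):
        comp = w.VarianceComponents(*vc, e=e, r=r, blups=pd.Series(dtype=float))
        assert w.broad_sense_H(comp) == pytest.approx(expected)

    def test_monotone_in_components(self):
        base = dict(sigma2_GE=1.0, sigma2_e=1.0, e=2, r=3,
                    blups=pd.Series(dtype=float))
        hs = [w.broad_sense_H(w.VarianceComponents(sigma2_G=s, **base))
              for s in (0.5, 1.0, 2.0)]
        assert hs == sorted(hs)
        hs_ge = [w.broad_sense_H(w.VarianceComponents(
            sigma2_G=1.0, sigma2_GE=s, sigma2_e=1.0, e=2, r=3,
            blups=pd.Series(dtype=float))) for s in (0.5, 1.0, 2.0)]
        assert hs_ge == sorted(hs_ge, reverse=True)

    def test_all_zero_rejected(self):
        comp = w.VarianceComponents(0.0, 0.0, 0.0, e=2, r=2,
                                    blups=pd.Series(dtype=float))
        with pytest.raises(ValueError):
            w.broad_sense_H(comp)


class TestGenomicRelationship:
    def test_identical_samples_share_diagonal(self):
        rng = np.random.default_rng(4)
        row = rng.integers(0, 3, 100).astype(float)
        X = np.vstack([row, row, rng.integers(0, 3, 100)])
        G = w.genomic_relationship_matrix(X)
        assert G[0, 1] == pytest.approx(G[0, 0], abs=1e-12)

    def test_hwe_diagonal_near_one_and_centering(self):
        rng = np.random.default_rng(5)
        X = rng.binomial(2, rng.uniform(0.1, 0.9, 2000), size=(200, 2000)).astype(float)
        G = w.genomic_relationship_matrix(X)
        assert 0.9 <= G.diagonal().mean() <= 1.1
        assert np.abs(G.sum(axis=1)).max() < 1e-8

    def test_monomorphic_loci_dropped(self):
        rng = np.random.default_rng(6)
        X = rng.binomial(2, 0.5, size=(50, 30)).astype(float)
        X2 = np.column_stack([X, np.full(50, 2.0)])
        np.testing.assert_allclose(w.genomic_relationship_matrix(X2),
                                   w.genomic_relationship_matrix(X))

    def test_all_monomorphic_rejected(self):
        with pytest.raises(ValueError):
            w.genomic_relationship_matrix(np.full((5, 4), 2.0))


def _structured_G(rng, n_fam=60, sibs=5, L=800):
    """Relationship matrix with real family structure (groups of selfed
    sibs), where genetic and residual variance are separable."""
    p = rng.uniform(0.1, 0.9, L)
    parents = rng.binomial(2, p, size=(n_fam, L)).astype(float)
    rows = []
    for i in range(n_fam):
        for _ in range(sibs):
            d = parents[i].copy()
            het = d == 1
            u = rng.random(het.sum())
            d[het] = np.where(u < 0.25, 0, np.where(u < 0.75, 1, 2))
            rows.append(d)
    X = np.asarray(rows)
    return w.genomic_relationship_matrix(X), X


class TestGblup:
    def test_identity_G_splits_total_variance(self):
        rng = np.random.default_rng(7)
        y = rng.normal(2.0, 3.0, 500)
        fit = w.gblup_reml(y, None, np.eye(500))
        total = fit.sigma2_u + fit.sigma2_res
        assert total == pytest.approx(np.var(y, ddof=1), rel=0.05)

    def test_null_trait_recovers_zero(self):
        rng = np.random.default_rng(8)
        G, _ = _structured_G(rng)
        hs = []
        for _ in range(10):
            fit = w.gblup_reml(rng.normal(size=G.shape[0]), None, G)
            hs.append(fit.h2_g)
        assert np.mean(hs) < 0.05

    def test_noiseless_limit(self):
        rng = np.random.default_rng(9)
        hs = []
        for _ in range(5):
            G, _ = _structured_G(rng)
            s, U = np.linalg.eigh(G)
            u = U @ (np.sqrt(np.clip(s, 0, None)) * rng.normal(size=G.shape[0]))
            hs.append(w.gblup_reml(u, None, G).h2_g)
        assert np.mean(hs) > 0.95

    def test_h2_recovery_with_family_structure(self):
        rng = np.random.default_rng(10)
        ests = []
        for _ in range(10):
            G, _ = _structured_G(rng, n_fam=60, sibs=5)
            n = G.shape[0]
            s, U = np.linalg.eigh(G)
            u = U @ (np.sqrt(np.clip(s, 0, None)) * rng.normal(size=n))
            u *= np.sqrt(2.0) / u.std()
            y = u + rng.normal(0, np.sqrt(2.0), n)
            ests.append(w.gblup_reml(y, None, G).h2_g)
        assert np.mean(ests) == pytest.approx(0.5, abs=0.1)

    def test_singular_fixed_design_rejected(self):
        y = np.arange(10.0)
        X = np.ones((10, 2))
        with pytest.raises(ValueError, match="singular"):
            w.GBLUP(y, np.eye(10), X=X)

    def test_summary_text(self):
        rng = np.random.default_rng(11)
        fit = w.gblup_reml(rng.normal(size=50), None, np.eye(50))
        assert "h2_G" in fit.summary()


class TestAssociationScan:
    def test_strong_marker_detected(self):
        rng = np.random.default_rng(12)
        G, X = _structured_G(rng, n_fam=60, sibs=5)
        m = X[:, 0]
        beta = np.sqrt(0.2 / 0.8 * 4.0 / np.var(m))
        y = m * beta + rng.normal(0, 2.0, len(m))
        res = w.association_scan(y, X[:, :40], G, alpha=1e-4)
        assert res.table.loc[0, "p_value"] < 1e-4
        assert res.table.loc[0, "significant"]

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(13)
        G, X = _structured_G(rng, n_fam=60, sibs=5, L=2000)
        y = rng.normal(size=G.shape[0])
        res = w.association_scan(y, X, G, alpha=1e-4)
        pv = res.table["p_value"].dropna()
        assert stats.kstest(pv, "uniform").statistic < 0.05

    def test_monomorphic_marker_skipped(self):
        rng = np.random.default_rng(14)
        n = 40
        X = rng.binomial(2, 0.5, size=(n, 5)).astype(float)
        X[:, 2] = 2.0
        res = w.association_scan(rng.normal(size=n), X, np.eye(n))
        assert res.table.loc[2, "status"] == "monomorphic"
        assert np.isnan(res.table.loc[2, "p_value"])

    def test_collinear_marker_skipped(self):
        rng = np.random.default_rng(15)
        n = 40
        cyc = np.repeat([0.0, 1.0], n // 2)
        fixed = np.column_stack([np.ones(n), cyc])
        M = np.column_stack([2 * cyc, rng.binomial(2, 0.5, n)])
        res = w.association_scan(rng.normal(size=n), M, np.eye(n), fixed=fixed)
        assert res.table.loc[0, "status"] == "collinear"
        assert res.table.loc[1, "status"] == "ok"

    def test_exact_mode_agrees_with_p3d_on_null_markers(self):
        rng = np.random.default_rng(16)
        G, X = _structured_G(rng, n_fam=30, sibs=4, L=300)
        y = rng.normal(size=G.shape[0])
        fast = w.association_scan(y, X[:, :15], G)
        slow = w.association_scan(y, X[:, :15], G, exact=True)
        # same markers tested, p-values of similar magnitude
        ok = fast.table["status"] == "ok"
        ratio = np.log10(slow.table.loc[ok, "p_value"] /
                         fast.table.loc[ok, "p_value"]).abs()
        assert ratio.max() < 1.0
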