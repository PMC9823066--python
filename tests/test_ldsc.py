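"""LD scores and LD score regression: oracle checks on scores, null
calibration, overlap intercepts and the joint jackknife bookkeeping."""

import numpy as np
import pytest

import matcov as mc
from matcov.gwas import run_gwas
from matcov.ldsc import (
    bivariate_ldsc, build_S_V, compute_ld_scores, floor_psd, read_stack,
    univariate_ldsc, write_stack,
)
from matcov._utils import vech_indices


def test_independent_snps_score_one():
    rng = np.random.default_rng(0)
    x = rng.binomial(2, 0.3, size=(500, 300)).astype(np.int8)
    ld = compute_ld_scores(x, window_snps=10)
    l2 = ld.table["L2"]
    assert l2.mean() == pytest.approx(1.0, abs=0.03)


def test_duplicated_snps_score_block_size():
    rng = np.random.default_rng(1)
    base = rng.binomial(2, 0.4, size=(400, 1))
    x = np.repeat(base, 5, axis=1).astype(np.int8)
    ld = compute_ld_scores(x, window_snps=5)
    assert np.allclose(ld.table["L2"], 5.0, atol=0.05)


def test_monomorphic_masked():
    rng = np.random.default_rng(2)
    x = rng.binomial(2, 0.3, size=(200, 5)).astype(np.int8)
    x[:, 3] = 0
    ld = compute_ld_scores(x, window_snps=2)
    assert np.isnan(ld.table.loc[3, "L2"])
    assert ld.table["L2"].drop(3).notna().all()


def test_small_reference_rejected():
    with pytest.raises(ValueError, match="100"):
        compute_ld_scores(np.zeros((50, 10)), 5)


def test_scores_match_large_panel_oracle():
    """Bias-adjusted scores from a modest panel agree with scores computed
    on a 10x larger independent panel of the same population."""
    cfg = mc.SimConfig(n_pairs=200, n_own=0, m_snps=200, ld_block_size=10,
                       ld_rho=0.8, maf=(0.1, 0.5), overlap=False, seed=3)
    small = mc.simulate_genotypes(cfg).mother_dosages
    big = mc.simulate_reference_panel(cfg, 2000)
    l_small = compute_ld_scores(small, 10).table["L2"]
    l_big = compute_ld_scores(big, 10).table["L2"]
    assert (l_small - l_big).abs().mean() < 0.25
    assert l_small.mean() == pytest.approx(l_big.mean(), abs=0.1)


@pytest.fixture(scope="module")
def null_fit():
    """Univariate regression on a phenotype with no genetic component."""
    cfg = mc.SimConfig(n_pairs=3000, n_own=3000, m_snps=3000,
                       psi_true=np.zeros((4, 4)), seed=4)
    coh = mc.simulate_cohort(cfg)
    ss = run_gwas(coh.own_dosages, coh.own_phenotypes["bw"],
                  coh.own_phenotypes[["sex", "age", "batch"]], snp_map=coh.snp_map)
    ld = compute_ld_scores(mc.simulate_reference_panel(cfg, 1500), 20,
                           snp_map=coh.snp_map)
    return univariate_ldsc(ss, ld, n_blocks=50)


def test_null_h2_and_intercept(null_fit):
    assert abs(null_fit.est) <= 2.5 * null_fit.se
    assert null_fit.intercept == pytest.approx(1.0, abs=3 * null_fit.intercept_se)
    assert not null_fit.reliable


def _synthetic_ld(rng, m, low=1.0, high=10.0):
    from matcov.ldsc import LDScores
    import pandas as pd

    ell = rng.uniform(low, high, size=m)
    return LDScores(pd.DataFrame({"SNP": [f"rs{i + 1}" for i in range(m)],
                                  "IDX": np.arange(m), "L2": ell}), n_ref=10_000)


def _as_ss(z, n):
    import pandas as pd

    m = len(z)
    return mc.SumStats(pd.DataFrame({
        "SNP": [f"rs{i + 1}" for i in range(m)], "A1": "A", "A2": "G",
        "BETA": z / np.sqrt(n), "SE": 1 / np.sqrt(n), "Z": z, "N": n}))


def test_univariate_recovers_slope_on_synthetic_chi2():
    """z drawn per SNP with Var(z) = 1 + N h2 l / M: the regression must
    recover h2 and an intercept of 1 within jackknife uncertainty."""
    rng = np.random.default_rng(10)
    m, n, h2 = 8000, 10_000, 0.3
    ld = _synthetic_ld(rng, m)
    ell = ld.table["L2"].to_numpy()
    z = rng.standard_normal(m) * np.sqrt(1 + n * h2 * ell / m)
    fit = univariate_ldsc(_as_ss(z, n), ld, n_blocks=100, M=m)
    assert fit.est == pytest.approx(h2, abs=2.5 * fit.se)
    assert fit.intercept == pytest.approx(1.0, abs=2.5 * fit.intercept_se)
    assert fit.se < 0.05


def test_bivariate_recovers_covariance_and_overlap_intercept():
    """(z1, z2) drawn with Cov = sqrt(N1 N2) sigma_g l / M + 0.3 (overlap
    term): slope recovers sigma_g, intercept recovers 0.3."""
    rng = np.random.default_rng(11)
    m, n1, n2, h1, h2, sg, icpt = 8000, 10_000, 6_000, 0.4, 0.25, 0.1, 0.3
    ld = _synthetic_ld(rng, m)
    ell = ld.table["L2"].to_numpy()
    v1 = 1 + n1 * h1 * ell / m
    v2 = 1 + n2 * h2 * ell / m
    cv = np.sqrt(n1 * n2) * sg * ell / m + icpt
    z1 = np.empty(m)
    z2 = np.empty(m)
    for j in range(m):  # per-SNP bivariate draw
        c = cv[j] / np.sqrt(v1[j] * v2[j])
        a, b = rng.standard_normal(2)
        z1[j] = np.sqrt(v1[j]) * a
        z2[j] = np.sqrt(v2[j]) * (c * a + np.sqrt(1 - c * c) * b)
    fit = bivariate_ldsc(_as_ss(z1, n1), _as_ss(z2, n2), ld, n_blocks=100, M=m)
    assert fit.est == pytest.approx(sg, abs=2.5 * fit.se)
    assert fit.intercept == pytest.approx(icpt, abs=2.5 * fit.intercept_se)


def test_reliability_flag_is_z_gt_4():
    from matcov.ldsc import LdscFit

    assert LdscFit(0.2, 0.04, 1.0, 0.01, 1000, 1000, np.zeros((2, 2))).reliable
    assert not LdscFit(0.2, 0.06, 1.0, 0.01, 1000, 1000, np.zeros((2, 2))).reliable


def test_too_few_snps_rejected(null_fit):
    cfg = mc.SimConfig(n_pairs=200, n_own=0, m_snps=100, ld_block_size=10,
                       overlap=False, seed=5)
    coh = mc.simulate_genotypes(cfg)
    ss = run_gwas(coh.mother_dosages, np.random.default_rng(0).standard_normal(200),
                  snp_map=coh.snp_map)
    ld = compute_ld_scores(coh.mother_dosages, 10, snp_map=coh.snp_map)
    with pytest.raises(ValueError, match="need >= 200"):
        univariate_ldsc(ss, ld, n_blocks=20)


def test_bivariate_self_consistency(quartet_stack):
    ss, ld, _ = quartet_stack
    uni = univariate_ldsc(ss["BW"], ld, n_blocks=40)
    biv = bivariate_ldsc(ss["BW"], ss["BW"], ld, n_blocks=40)
    assert biv.est == pytest.approx(uni.est, abs=0.3 * uni.se)


def test_disjoint_null_traits_zero_covariance_and_intercept():
    """Genetically independent traits measured on disjoint samples: both the
    genetic covariance and the cross-intercept vanish."""
    cfg = mc.SimConfig(n_pairs=4000, n_own=4000, m_snps=2500,
                       psi_true=np.zeros((4, 4)), seed=6)
    coh = mc.simulate_cohort(cfg)
    half = 2000
    ss1 = run_gwas(coh.own_dosages[:half], coh.own_phenotypes["bw"][:half],
                   snp_map=coh.snp_map)
    ss2 = run_gwas(coh.own_dosages[half:], coh.own_phenotypes["trait"][half:],
                   snp_map=coh.snp_map)
    ld = compute_ld_scores(mc.simulate_reference_panel(cfg, 1200), 20,
                           snp_map=coh.snp_map)
    fit = bivariate_ldsc(ss1, ss2, ld, n_blocks=40)
    assert abs(fit.est) <= 3 * fit.se
    assert fit.intercept == pytest.approx(0.0, abs=3 * fit.intercept_se)


def test_overlap_intercept_equals_phenotypic_correlation():
    """Null genetics, identical samples, phenotypic correlation 0.3: the
    cross-trait intercept estimates 0.3 (overlap x correlation)."""
    cfg = mc.SimConfig(n_pairs=4000, n_own=0, m_snps=2500, overlap=False, seed=7)
    coh = mc.simulate_genotypes(cfg)
    rng = np.random.default_rng(7)
    z = rng.standard_normal((4000, 2))
    y1 = z[:, 0]
    y2 = 0.3 * z[:, 0] + np.sqrt(1 - 0.09) * z[:, 1]
    ss1 = run_gwas(coh.mother_dosages, y1, snp_map=coh.snp_map)
    ss2 = run_gwas(coh.mother_dosages, y2, snp_map=coh.snp_map)
    ld = compute_ld_scores(mc.simulate_reference_panel(cfg, 1200), 20,
                           snp_map=coh.snp_map)
    fit = bivariate_ldsc(ss1, ss2, ld, n_blocks=40)
    assert fit.intercept == pytest.approx(0.3, abs=max(3 * fit.intercept_se, 0.05))


class TestJointStack:
    def test_duplicated_gwas_perfectly_dependent(self, quartet_stack):
        ss, ld, _ = quartet_stack
        stack = build_S_V([ss["BW"], ss["BW"], ss["T"]], ld, n_blocks=40)
        assert stack.S[0, 0] == pytest.approx(stack.S[1, 1])
        assert stack.S[0, 2] == pytest.approx(stack.S[1, 2])
        # pseudovalues of the two h2 elements correlate ~1
        pv = stack.pseudovalues
        r = np.corrcoef(pv[:, 0], pv[:, 3])[0, 1]  # (0,0) and (1,1) in vech
        assert r > 0.999

    def test_diag_V_matches_separate_regressions(self, quartet_stack):
        ss, ld, stack = quartet_stack
        order = ["BW", "BW_M", "T", "T_M"]
        pairs = vech_indices(4)
        for e, (i, j) in enumerate(pairs):
            if i == j:
                sep = univariate_ldsc(ss[order[i]], ld, n_blocks=40)
            else:
                sep = bivariate_ldsc(ss[order[i]], ss[order[j]], ld, n_blocks=40)
            assert np.sqrt(stack.V[e, e]) == pytest.approx(sep.se, rel=1e-6)
            assert stack.S[i, j] == pytest.approx(sep.est, rel=1e-6)

    def test_S_invariant_to_snp_order(self, quartet_stack):
        ss, ld, stack = quartet_stack
        rng = np.random.default_rng(8)
        shuffled = []
        for key in ("BW", "BW_M", "T", "T_M"):
            t = ss[key].table.sample(frac=1, random_state=rng.integers(1 << 30))
            shuffled.append(mc.SumStats(t.reset_index(drop=True), trait=key))
        stack2 = build_S_V(shuffled, ld, n_blocks=40)
        assert np.allclose(stack2.S, stack.S, atol=1e-10)

    def test_block_count_robustness(self, quartet_stack):
        ss, ld, _ = quartet_stack
        se_40 = univariate_ldsc(ss["BW"], ld, n_blocks=40).se
        se_80 = univariate_ldsc(ss["BW"], ld, n_blocks=80).se
        assert se_80 == pytest.approx(se_40, rel=0.25)

    def test_round_trip(self, quartet_stack, tmp_path):
        _, _, stack = quartet_stack
        write_stack(stack, tmp_path / "stack")
        back = read_stack(tmp_path / "stack")
        assert np.allclose(back.S, stack.S)
        assert np.allclose(back.V, stack.V)
        assert back.labels == stack.labels
        assert back.M == stack.M


def test_floor_psd():
    v = np.diag([1.0, -0.1])
    fixed, lam = floor_psd(v)
    assert lam == pytest.approx(-0.1)
    assert np.linalg.eigvalsh(fixed).min() >= 0
    ok, lam2 = floor_psd(np.eye(2))
    assert lam2 == 1.0 and np.allclose(ok, np.eye(2))
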