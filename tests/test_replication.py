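"""Risk counting, count normalization, NB z-scores, RS, eigenvalue, CLR."""

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from cordsig import (
    SimulationConfig,
    clr_transform,
    correlate_with_risk,
    count_risk_factors,
    filter_and_normalize_counts,
    replication_score,
    rnaseq_z,
    rs_cutoff_sweep,
    signature_eigenvalue,
    simulate_rnaseq_cohort,
)


# ---------------------------------------------------------------------------
# risk-factor counting
# ---------------------------------------------------------------------------

def test_uih_preset_all_four_fire():
    cov = pd.DataFrame({"ga": [36.0], "bw": [2900.0], "ppbmi": [31.0], "sex": [1]})
    assert count_risk_factors(cov, "uih").iloc[0] == 4


def test_uih_preset_none_fire():
    cov = pd.DataFrame({"ga": [40.0], "bw": [3500.0], "ppbmi": [22.0], "sex": [0]})
    assert count_risk_factors(cov, "uih").iloc[0] == 0


def test_boundaries_are_strict():
    cov = pd.DataFrame(
        {"ga": [37.0, 36.999], "bw": [3000.0, 2999.9], "ppbmi": [30.0, 30.001],
         "sex": [0, 0]}
    )
    counts = count_risk_factors(cov, "uih")
    assert counts.tolist() == [0, 3]


def test_olin_preset_uses_cesarean():
    cov = pd.DataFrame({"ga": [40.0], "bw": [3500.0], "sex": [0], "csection": [1]})
    assert count_risk_factors(cov, "olin").iloc[0] == 1


def test_missing_covariate_named_in_error():
    cov = pd.DataFrame({"ga": [36.0], "bw": [2900.0], "sex": [1]})
    with pytest.raises(KeyError, match="ppbmi"):
        count_risk_factors(cov, "uih")


# ---------------------------------------------------------------------------
# count filtering and normalization
# ---------------------------------------------------------------------------

def test_low_median_gene_removed():
    counts = pd.DataFrame(
        {"s1": [5, 100], "s2": [5, 120], "s3": [5, 90]}, index=["low", "high"]
    )
    norm, kept = filter_and_normalize_counts(counts)
    assert kept == ["high"]


def test_equal_totals_identity():
    counts = pd.DataFrame(
        {"s1": [30, 70], "s2": [60, 40], "s3": [50, 50]}, index=["a", "b"]
    )
    norm, kept = filter_and_normalize_counts(counts)
    assert np.allclose(norm.to_numpy(), counts.to_numpy())


def test_doubling_a_sample_leaves_profile_unchanged():
    counts = pd.DataFrame(
        {"s1": [30, 70], "s2": [60, 40], "s3": [50, 50]}, index=["a", "b"]
    )
    doubled = counts.copy()
    doubled["s1"] = counts["s1"] * 2
    n1, _ = filter_and_normalize_counts(counts)
    n2, _ = filter_and_normalize_counts(doubled)
    assert np.allclose(n1["s1"], n2["s1"])


def test_zero_total_sample_errors():
    counts = pd.DataFrame({"s1": [10, 20], "s2": [0, 0]}, index=["a", "b"])
    with pytest.raises(ValueError, match="zero total"):
        filter_and_normalize_counts(counts)


# ---------------------------------------------------------------------------
# NB z-scores
# ---------------------------------------------------------------------------

def _nb_negloglik(params, y, risk, offset):
    b0, b1, log_alpha = params
    alpha = np.exp(log_alpha)
    mu = np.exp(b0 + b1 * risk + offset)
    size = 1.0 / alpha
    return -np.sum(stats.nbinom.logpmf(y, size, size / (size + mu)))


def test_nb_slope_recovery_vs_direct_likelihood(rng):
    n = 60
    risk = rng.integers(0, 5, n).astype(float)
    mu = np.exp(3.0 + 0.5 * risk)
    y = rng.poisson(mu)
    # pad with large stable genes so library size is essentially risk-independent
    stable = rng.poisson(3000.0, size=(20, n))
    counts = pd.DataFrame(
        np.vstack([y, stable]),
        index=["g1"] + [f"stable{i}" for i in range(20)],
        columns=[f"s{i}" for i in range(n)],
    )
    zt = rnaseq_z(counts, pd.Series(risk, index=counts.columns))
    # independent oracle: direct NB likelihood maximization on the instance
    offset = np.log(counts.sum(axis=0) / np.median(counts.sum(axis=0))).to_numpy()
    res = optimize.minimize(
        _nb_negloglik, x0=[3.0, 0.1, -3.0], args=(y, risk, offset),
        method="Nelder-Mead", options={"maxiter": 5000, "xatol": 1e-8, "fatol": 1e-10},
    )
    assert zt.loc["g1", "beta"] == pytest.approx(res.x[1], abs=0.02)
    assert abs(zt.loc["g1", "beta"] - 0.5) < 2 * abs(zt.loc["g1", "beta"] / zt.loc["g1", "z"])
    assert abs(zt.loc["stable0", "z"]) < 2  # null gene


def test_rnaseq_z_null_genes_standard_normal(rng):
    cfg = SimulationConfig(n_genes=400, n_signal_genes=1, signal_effect=0.0, seed=3)
    counts, cov, _ = simulate_rnaseq_cohort(cfg)
    _, kept = filter_and_normalize_counts(counts)
    zt = rnaseq_z(counts.loc[kept], cov["risk_count"])
    z = zt["z"].dropna()
    assert stats.kstest(z, "norm").pvalue > 0.01


def test_rnaseq_z_preconditions():
    counts = pd.DataFrame(np.ones((3, 5)), columns=[f"s{i}" for i in range(5)])
    with pytest.raises(ValueError, match="at least 8"):
        rnaseq_z(counts, pd.Series([1, 2, 1, 2, 1], index=counts.columns))
    counts8 = pd.DataFrame(np.ones((3, 8)), columns=[f"s{i}" for i in range(8)])
    with pytest.raises(ValueError, match="constant"):
        rnaseq_z(counts8, pd.Series([1] * 8, index=counts8.columns))


def test_planted_negative_slope_genes_get_negative_z():
    cfg = SimulationConfig(n_genes=300, n_signal_genes=20, seed=4)
    counts, cov, truth = simulate_rnaseq_cohort(cfg)
    _, kept = filter_and_normalize_counts(counts)
    zt = rnaseq_z(counts.loc[kept], cov["risk_count"])
    neg = [g for g in truth.signal_genes if truth.signs[g] == -1 and g in zt.index]
    assert np.mean(zt.loc[neg, "z"]) < -1


# ---------------------------------------------------------------------------
# replication score
# ---------------------------------------------------------------------------

def _records(zp, zr):
    genes = [f"g{i}" for i in range(len(zp))]
    return (
        pd.DataFrame({"z_pooled": zp}, index=genes),
        pd.DataFrame({"z": zr}, index=genes),
    )


def test_rs_arithmetic_and_cutoff():
    pooled, rna = _records([2.0, -2.5, 3.0], [2.0, -1.6, -3.0])
    rec = replication_score(pooled, rna)
    assert rec["rs"].tolist() == pytest.approx([4.0, 4.0, -9.0])
    assert rec["passes"].tolist() == [True, True, False]


def test_rs_symmetry_and_nested_passing_sets(rng):
    zp, zr = rng.normal(size=100) * 2, rng.normal(size=100)
    pooled, rna = _records(zp, zr)
    rec = replication_score(pooled, rna)
    swapped = replication_score(
        pd.DataFrame({"z_pooled": zr}, index=rec.index),
        pd.DataFrame({"z": zp}, index=rec.index),
    )
    assert np.allclose(rec["rs"], swapped["rs"])
    low = set(replication_score(pooled, rna, cutoff=1.0).query("passes").index)
    high = set(replication_score(pooled, rna, cutoff=4.0).query("passes").index)
    assert high <= low


def test_rs_empty_intersection_errors():
    pooled = pd.DataFrame({"z_pooled": [1.0]}, index=["a"])
    rna = pd.DataFrame({"z": [1.0]}, index=["b"])
    with pytest.raises(ValueError, match="intersection"):
        replication_score(pooled, rna)


def test_rank_variant_invariant_to_monotone_transforms(rng):
    zp, zr = rng.normal(size=50), rng.normal(size=50)
    pooled, rna = _records(zp, zr)
    rec = replication_score(pooled, rna, method="rank")
    pooled2, rna2 = _records(np.expm1(zp) + zp, zr**3)  # strictly monotone maps
    rec2 = replication_score(pooled2, rna2, method="rank")
    assert np.allclose(rec["rs"], rec2["rs"])
    with pytest.raises(ValueError, match="method"):
        replication_score(pooled, rna, method="bogus")


def test_cutoff_sweep_monotone(rng):
    zp, zr = rng.normal(size=200) * 2, rng.normal(size=200)
    pooled, rna = _records(zp, zr)
    rec = replication_score(pooled, rna)
    p_src = {"ga": pd.Series(rng.uniform(size=200), index=rec.index)}
    sweep = rs_cutoff_sweep(rec, [-np.inf, 0.0, 1.0, 3.0], p_src)
    assert sweep.loc[0, "n_genes"] == 200  # cutoff -inf: all genes pass
    assert (np.diff(sweep["n_genes"]) <= 0).all()
    with pytest.raises(ValueError, match="increasing"):
        rs_cutoff_sweep(rec, [1.0, 1.0])


# ---------------------------------------------------------------------------
# signature eigenvalue
# ---------------------------------------------------------------------------

def test_rank_one_expression_explains_all_variance(rng):
    base = rng.normal(size=10)
    expr = pd.DataFrame(
        np.outer([1.0, 2.0, -1.5], base), index=["a", "b", "c"],
        columns=[f"s{i}" for i in range(10)],
    )
    scores, var_frac = signature_eigenvalue(expr)
    assert var_frac[0] == pytest.approx(1.0)
    assert var_frac.sum() == pytest.approx(1.0)
    assert abs(scores["eigenvalue"].mean()) < 1e-9


def test_sign_flip_flips_scores(rng):
    expr = pd.DataFrame(rng.normal(size=(5, 8)),
                        index=[f"g{i}" for i in range(5)],
                        columns=[f"s{i}" for i in range(8)])
    zp = pd.Series([-1.0, -2.0, 1.0, 2.0, 0.5], index=expr.index)
    s1, _ = signature_eigenvalue(expr, zp)
    s2, _ = signature_eigenvalue(-expr, -zp)
    # flipping expression flips subject scores (orientation follows loadings)
    assert np.allclose(np.abs(s1["eigenvalue"]), np.abs(s2["eigenvalue"]))


def test_constant_rows_dropped_with_warning(rng):
    expr = pd.DataFrame(rng.normal(size=(3, 6)), index=["a", "b", "c"],
                        columns=[f"s{i}" for i in range(6)])
    expr.loc["a"] = 5.0
    with pytest.warns(UserWarning, match="constant"):
        scores, _ = signature_eigenvalue(expr)
    assert scores.shape[0] == 6


def test_eigenvalue_requires_minimum_size():
    expr = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
    with pytest.raises(ValueError):
        signature_eigenvalue(expr)


# ---------------------------------------------------------------------------
# correlations and CLR
# ---------------------------------------------------------------------------

def test_correlate_with_risk_identity_and_bonferroni():
    risk = pd.Series([0, 1, 2, 3, 4, 2], index=list("abcdef"))
    res = correlate_with_risk(risk.astype(float), risk, n_tests=1)
    assert res["r"] == pytest.approx(1.0)
    neg = correlate_with_risk(-risk.astype(float), risk)
    assert neg["r"] == pytest.approx(-1.0)
    vals = pd.Series([0.3, 1.2, 1.8, 3.4, 3.5, 2.4], index=risk.index)
    adj = correlate_with_risk(vals, risk, n_tests=21)
    assert adj["p_adjusted"] == pytest.approx(min(1.0, adj["p"] * 21))
    assert adj["ci"][0] < adj["r"] < adj["ci"][1]


def test_correlate_with_risk_zero_variance_missing():
    risk = pd.Series([0, 1, 2, 3], index=list("abcd"))
    res = correlate_with_risk(pd.Series(1.0, index=risk.index), risk)
    assert np.isnan(res["r"])


def test_clr_uniform_and_worked_instance():
    comp = pd.DataFrame([[0.25] * 4, [0.5, 0.25, 0.125, 0.125]])
    out = clr_transform(comp)
    assert np.allclose(out.iloc[0], 0.0)
    assert np.allclose(out.sum(axis=1), 0.0, atol=1e-12)
    worked = clr_transform(pd.DataFrame([[0.5, 0.25, 0.25]]))
    assert np.allclose(worked.iloc[0], [0.4621, -0.2310, -0.2310], atol=1e-4)


def test_clr_zero_handling():
    comp = pd.DataFrame([[0.5, 0.5, 0.0]])
    with pytest.raises(ValueError, match="pseudo"):
        clr_transform(comp, pseudocount=False)
    out = clr_transform(comp, pseudocount=True)
    assert np.allclose(out.sum(axis=1), 0.0, atol=1e-12)
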