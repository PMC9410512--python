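import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gfabric import (
    ExpressionSet,
    GeneSetCollection,
    collapse_and_normalize,
    compute_ave,
    compute_cor,
    compute_fabric,
    compute_prec,
    compute_rec,
    compute_rev,
    fold_increase,
    rev_interval_factor,
    value_count,
)

from conftest import es_from_log2, es_from_matrix


# ---------------------------------------------------------------------------
# collapsing and normalization
# ---------------------------------------------------------------------------

def test_collapse_averages_spots_before_scaling():
    df = pd.DataFrame(
        [[2.0, 2.0], [4.0, 4.0]], index=["s1", "s2"], columns=["r1", "r2"]
    )
    es = ExpressionSet("A", df, spot_map={"gA": [0, 1]})
    out = collapse_and_normalize(es)
    # mean of spots (2, 4) is 3; single gene, so the median scale is 3
    assert out.values.loc["gA"].tolist() == [1.0, 1.0]


def test_single_gene_normalizes_to_one():
    out = collapse_and_normalize(es_from_matrix([[5.0, 5.0, 5.0, 5.0]]))
    assert compute_ave(out).iloc[0] == 1.0


def test_median_scaling_three_genes():
    es = es_from_matrix([[1, 1], [2, 2], [8, 8]])
    ave = compute_ave(collapse_and_normalize(es))
    assert ave.tolist() == [0.5, 1.0, 4.0]


def test_ave_mean_of_replicates_after_scaling():
    # replicate means (1, 4): scale = median 2.5 -> hmm use 3 genes so the
    # middle gene fixes the scale at 2
    es = es_from_matrix([[1, 1, 1, 1], [2, 2, 2, 2], [2, 2, 6, 6]])
    ave = compute_ave(collapse_and_normalize(es))
    assert ave.iloc[1] == 1.0
    assert ave.iloc[2] == pytest.approx(2.0)


def test_median_ave_is_one_on_random_data():
    rng = np.random.default_rng(11)
    for _ in range(5):
        es = es_from_matrix(rng.lognormal(0, 1, size=(51, 4)))
        ave = compute_ave(collapse_and_normalize(es))
        assert abs(float(np.median(ave)) - 1.0) <= 1e-9


# ---------------------------------------------------------------------------
# REV
# ---------------------------------------------------------------------------

def test_rev_zero_for_identical_replicates():
    assert compute_rev(es_from_matrix([[5, 5, 5, 5]])).iloc[0] == 0.0


def test_rev_worked_example_against_chi_square_oracle():
    # replicates (8, 10, 12, 10): sample CV = sqrt(8/3)/10 = 16.33%;
    # nu = 3 quantiles chi2(0.975) = 9.3484, chi2(0.025) = 0.2158 give the
    # mid-interval factor 2.1475, hence REV ~= 35.07%
    rev = compute_rev(es_from_matrix([[8, 10, 12, 10]])).iloc[0]
    cv = np.sqrt(8 / 3) / 10
    factor = 0.5 * (np.sqrt(3 / 9.3484) + np.sqrt(3 / 0.2158))
    assert rev == pytest.approx(100 * cv * factor, abs=0.01)
    assert rev == pytest.approx(35.07, abs=0.01)


def test_rev_scale_invariant():
    a = compute_rev(es_from_matrix([[8, 10, 12, 10]]))
    b = compute_rev(es_from_matrix([[56, 70, 84, 70]]))
    assert a.iloc[0] == pytest.approx(b.iloc[0], rel=1e-12)


def test_rev_interval_factor_nu3():
    assert rev_interval_factor(3) == pytest.approx(2.1475, abs=5e-4)


def test_rev_spot_pooling_rms_and_additive_dof():
    # two spots with identical replicate pattern: pooled CV equals either
    # spot's CV, but nu doubles (6), narrowing the interval factor
    df = pd.DataFrame(
        [[8, 10, 12, 10], [8, 10, 12, 10]], index=["s1", "s2"],
        columns=list("abcd"),
    )
    es = ExpressionSet("A", df.astype(float), spot_map={"g": [0, 1]})
    rev = compute_rev(es).iloc[0]
    cv = np.sqrt(8 / 3) / 10
    assert rev == pytest.approx(100 * cv * float(rev_interval_factor(6)), rel=1e-9)
    assert rev < 35.07  # more technical replication -> tighter estimate


def test_rev_finite_sample_recovery():
    """The estimator chain recovers factor * E[sample CV] on log-normal data.

    The expected sample CV at n = 4 is estimated with an independent plain
    NumPy Monte-Carlo (the sample CV of log-normal draws), then compared
    with the mean REV that the pipeline computes on a separate draw.
    """
    c = 0.2
    rng = np.random.default_rng(21)
    sigma = np.sqrt(np.log1p(c**2))
    oracle = rng.lognormal(-sigma**2 / 2, sigma, size=(100_000, 4))
    e_cv = float((oracle.std(axis=1, ddof=1) / oracle.mean(axis=1)).mean())

    draw = rng.lognormal(np.log(50) - sigma**2 / 2, sigma, size=(2000, 4))
    rev = compute_rev(es_from_matrix(draw))
    expected = 100 * e_cv * float(rev_interval_factor(3))
    assert float(rev.mean()) == pytest.approx(expected, rel=0.03)


# ---------------------------------------------------------------------------
# COR
# ---------------------------------------------------------------------------

def test_cor_self_correlation_is_exactly_one(fixture_fabrics):
    for fab in fixture_fabrics.values():
        assert (np.diag(fab.cor.to_numpy()) == 1.0).all()


def test_cor_perfect_anticorrelation():
    es = es_from_log2([[1, 2, 3, 4], [4, 3, 2, 1]])
    assert compute_cor(es).iloc[0, 1] == pytest.approx(-1.0)


def test_cor_hand_computed_example():
    # log2 profiles (1,2,3,4) vs (1,3,2,4): covariance 4 over sqrt(5*5)
    es = es_from_log2([[1, 2, 3, 4], [1, 3, 2, 4]])
    assert compute_cor(es).iloc[0, 1] == pytest.approx(0.8)


def test_cor_matches_brute_force_pearson():
    rng = np.random.default_rng(5)
    x = rng.lognormal(0, 0.5, size=(10, 4))
    c = compute_cor(es_from_matrix(x)).to_numpy()
    lx = np.log2(x)
    for i in range(10):
        for j in range(10):
            a, b = lx[i] - lx[i].mean(), lx[j] - lx[j].mean()
            ref = (a * b).sum() / np.sqrt((a * a).sum() * (b * b).sum())
            assert abs(c[i, j] - ref) < 1e-12 or (i == j and c[i, j] == 1.0)


def test_cor_degenerate_gene_undefined_but_diag_one():
    es = es_from_matrix([[5, 5, 5, 5], [1, 2, 3, 4]])
    c = compute_cor(es)
    assert np.isnan(c.iloc[0, 1])
    assert c.iloc[0, 0] == 1.0


def test_cor_bounded_everywhere(fixture_fabrics):
    c = fixture_fabrics["NN"].cor.to_numpy()
    assert np.nanmax(np.abs(c)) <= 1.0


# ---------------------------------------------------------------------------
# control scores
# ---------------------------------------------------------------------------

def test_rec_examples():
    rev = pd.Series([10.0, 30.0, 60.0])  # median 30
    rec = compute_rec(rev)
    assert rec.tolist() == pytest.approx([2.0, 0.0, -0.5])


def test_rec_zero_rev_capped():
    rec = compute_rec(pd.Series([0.0, 30.0, 30.0]), cap=100.0)
    assert rec.iloc[0] == 100.0


@given(st.integers(0, 2**31 - 1))
@settings(max_examples=20, deadline=None)
def test_rec_monotone_decreasing_in_rev(seed):
    rng = np.random.default_rng(seed)
    rev = pd.Series(np.sort(rng.uniform(1, 80, size=9)))
    rec = compute_rec(rev)
    assert (np.diff(rec.to_numpy()) <= 0).all()


def test_prec_whole_transcriptome_is_zero():
    rev = pd.Series([10.0, 20, 30, 40], index=list("abcd"))
    prec = compute_prec(rev, GeneSetCollection({"all": list("abcd")}))
    assert prec["all"] == 0.0


def test_prec_examples_and_singleton_equals_rec():
    rev = pd.Series([10.0, 20.0, 40.0, 20.0, 20.0], index=list("abcde"))
    sets = GeneSetCollection({"tight": ["a"], "loose": ["c"], "solo": ["c"]})
    prec = compute_prec(rev, sets)
    assert prec["tight"] == pytest.approx(1.0)    # median 20 / 10 - 1
    assert prec["loose"] == pytest.approx(-0.5)   # median 20 / 40 - 1
    rec = compute_rec(rev)
    assert prec["solo"] == pytest.approx(rec["c"])


def test_prec_skips_uncovered_set(caplog):
    rev = pd.Series([10.0, 20.0, 30.0], index=list("abc"))
    with caplog.at_level("WARNING"):
        prec = compute_prec(rev, GeneSetCollection({"ghost": ["zz"]}))
    assert "ghost" not in prec


# ---------------------------------------------------------------------------
# bookkeeping
# ---------------------------------------------------------------------------

def test_value_count_identity():
    for n in (3, 100, 5417):
        vc = value_count(n)
        assert vc["total"] == 2 * n + n * (n - 1) // 2
        assert vc["cor"] == n * (n - 1) // 2


def test_fabric_profile_round_trip(tmp_path, fixture_fabrics):
    from gfabric import FabricProfile

    fab = fixture_fabrics["NN"]
    fab.write(tmp_path)
    back = FabricProfile.read(tmp_path, "NN")
    pd.testing.assert_series_equal(fab.ave, back.ave, check_names=False)
    np.testing.assert_allclose(
        fab.cor.to_numpy(), back.cor.to_numpy(), rtol=0, atol=1e-12
    )
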