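import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import optimize, stats

from gfabric import (
    ANTAGONISTIC,
    INDEPENDENT,
    SYNERGISTIC,
    UNCLASSIFIED,
    ConditionSpec,
    FabricProfile,
    SimulationSpec,
    classify_pairs,
    compute_fabric,
    critical_r,
    partner_summary,
    remodeling_diff,
    simulate_study,
)


def fabric_with_cor(cor: np.ndarray, n_replicates: int = 4,
                    condition: str = "A") -> FabricProfile:
    """Minimal fabric carrying an injected correlation matrix."""
    n = cor.shape[0]
    genes = pd.Index([f"g{i:02d}" for i in range(n)])
    ones = pd.Series(np.ones(n), index=genes)
    return FabricProfile(
        condition=condition,
        ave=ones,
        rev=ones * 10,
        cor=pd.DataFrame(cor, index=genes, columns=genes),
        n_replicates=n_replicates,
        normalized=pd.DataFrame(
            np.ones((n, n_replicates)), index=genes
        ),
    )


# ---------------------------------------------------------------------------
# critical r
# ---------------------------------------------------------------------------

def test_critical_r_n4_against_numeric_inversion():
    # independent oracle: numerically solve |r| sqrt((n-2)/(1-r^2)) = t*
    t_star = stats.t.ppf(0.975, 2)  # 4.3027
    r_ref = optimize.brentq(
        lambda r: r * np.sqrt(2 / (1 - r**2)) - t_star, 1e-9, 1 - 1e-9
    )
    assert critical_r(4, 0.05) == pytest.approx(r_ref, abs=1e-9)
    assert critical_r(4, 0.05) == pytest.approx(0.950, abs=5e-4)


def test_critical_r_decreases_with_n():
    vals = [critical_r(n) for n in (4, 6, 10, 50, 1000)]
    assert all(a > b for a, b in zip(vals, vals[1:]))
    assert vals[-1] < 0.07


def test_critical_r_degenerate_p():
    assert critical_r(4, 1.0) == pytest.approx(0.0, abs=1e-12)
    with pytest.raises(ValueError):
        critical_r(2)


def test_critical_r_consistent_with_permutation_null():
    """Averaged over random replicate vectors, the fraction of the 4!
    permutations with |r| >= r_critical matches the nominal 5% to the
    resolution a 24-point null allows."""
    rc = critical_r(4, 0.05)
    rng = np.random.default_rng(17)
    perms = list(itertools.permutations(range(4)))
    fracs = []
    for _ in range(1500):
        a = rng.standard_normal(4)
        b = rng.standard_normal(4)
        rs = [np.corrcoef(a, b[list(p)])[0, 1] for p in perms]
        fracs.append(np.mean(np.abs(rs) >= rc))
    assert np.mean(fracs) == pytest.approx(0.05, abs=0.015)


# ---------------------------------------------------------------------------
# classification
# ---------------------------------------------------------------------------

def test_classify_pairs_examples():
    c = np.eye(3)
    c[0, 1] = c[1, 0] = 0.99    # above r_crit(4) = 0.950
    c[0, 2] = c[2, 0] = -0.96
    c[1, 2] = c[2, 1] = 0.02
    prof = classify_pairs(fabric_with_cor(c))
    assert prof.label("g00", "g01") == SYNERGISTIC
    assert prof.label("g00", "g02") == ANTAGONISTIC
    assert prof.label("g01", "g02") == INDEPENDENT


def test_between_band_pairs_stay_unclassified():
    c = np.eye(2)
    c[0, 1] = c[1, 0] = 0.5
    prof = classify_pairs(fabric_with_cor(c))
    assert prof.label("g00", "g01") == UNCLASSIFIED
    assert prof.counts()[UNCLASSIFIED] == 1


def test_undefined_correlation_unclassified():
    c = np.eye(2)
    c[0, 1] = c[1, 0] = np.nan
    prof = classify_pairs(fabric_with_cor(c))
    assert prof.label("g00", "g01") == UNCLASSIFIED


def test_classification_symmetric_and_order_invariant():
    rng = np.random.default_rng(2)
    x = rng.standard_normal((8, 4))
    c = np.corrcoef(x)
    prof = classify_pairs(fabric_with_cor(c))
    perm = rng.permutation(8)
    prof_p = classify_pairs(fabric_with_cor(c[np.ix_(perm, perm)]))
    for i in range(8):
        for j in range(i + 1, 8):
            gi, gj = f"g{i:02d}", f"g{j:02d}"
            assert prof.label(gi, gj) == prof.label(gj, gi)
            pi, pj = f"g{np.where(perm == i)[0][0]:02d}", \
                f"g{np.where(perm == j)[0][0]:02d}"
            assert prof.label(gi, gj) == prof_p.label(pi, pj)


def test_null_type_one_error_within_binomial_bounds():
    """On 1,000 independent genes with n = 4 replicates, ~5% of pairs are
    (falsely) called significant; the observed fraction sits inside the
    99% binomial band around 0.05."""
    n = 1000
    spec = SimulationSpec(
        n_genes=n,
        conditions=[ConditionSpec("null", np.full(n, 10.0), np.full(n, 0.2))],
        seed=42,
    )
    fab = compute_fabric(simulate_study(spec)["null"])
    counts = classify_pairs(fab).counts()
    n_pairs = n * (n - 1) // 2
    frac = (counts[SYNERGISTIC] + counts[ANTAGONISTIC]) / n_pairs
    half = 2.576 * np.sqrt(0.05 * 0.95 / n_pairs)
    assert abs(frac - 0.05) < half


# ---------------------------------------------------------------------------
# partner summaries and remodeling
# ---------------------------------------------------------------------------

def _profile_with_hub_labels(labels, condition="A"):
    """Profile over hub g00 plus len(labels) partners with given labels."""
    n = len(labels) + 1
    c = np.zeros((n, n))
    np.fill_diagonal(c, 1.0)
    val = {SYNERGISTIC: 0.99, ANTAGONISTIC: -0.99, INDEPENDENT: 0.0,
           UNCLASSIFIED: 0.5}
    for k, lab in enumerate(labels, start=1):
        c[0, k] = c[k, 0] = val[lab]
        # partners mutually unclassified
        for k2 in range(1, n):
            if k2 != k:
                c[k, k2] = c[k2, k] = 0.5
    return classify_pairs(fabric_with_cor(c, condition=condition))


def test_partner_summary_counting():
    prof = _profile_with_hub_labels(
        [SYNERGISTIC] * 3 + [UNCLASSIFIED] * 7
    )
    s = partner_summary(prof, "g00")
    assert s.n_partners == 10
    assert s.pct_synergistic == pytest.approx(30.0)
    assert s.pct_antagonistic == 0.0


def test_partner_summary_all_independent():
    prof = _profile_with_hub_labels([INDEPENDENT] * 4)
    s = partner_summary(prof, "g00")
    assert (s.pct_synergistic, s.pct_antagonistic, s.pct_independent) == (
        0.0, 0.0, 100.0,
    )


def test_partner_summary_errors():
    prof = _profile_with_hub_labels([INDEPENDENT])
    with pytest.raises(KeyError):
        partner_summary(prof, "missing")
    solo = classify_pairs(fabric_with_cor(np.eye(1)))
    with pytest.raises(ValueError):
        partner_summary(solo, "g00")


def test_remodeling_reports_switch_and_decoupling():
    a = _profile_with_hub_labels(
        [SYNERGISTIC, SYNERGISTIC, INDEPENDENT], condition="NN")
    b = _profile_with_hub_labels(
        [ANTAGONISTIC, INDEPENDENT, INDEPENDENT], condition="IN")
    table = remodeling_diff([a, b], "g00")
    assert table.switches("NN", "IN") == ["g01"]  # Crem-like flip
    assert table.decoupled("NN", "IN") == ["g02"]
    assert list(table.labels.columns) == ["NN", "IN"]


def test_remodeling_identical_profiles_no_changes():
    a = _profile_with_hub_labels([SYNERGISTIC, INDEPENDENT], condition="NN")
    b = _profile_with_hub_labels([SYNERGISTIC, INDEPENDENT], condition="IN")
    table = remodeling_diff([a, b], "g00")
    assert table.changes[("NN", "IN")] == {}


def test_remodeling_unclassified_state_explicit():
    a = _profile_with_hub_labels([SYNERGISTIC], condition="NN")
    b = _profile_with_hub_labels([UNCLASSIFIED], condition="IN")
    table = remodeling_diff([a, b], "g00")
    assert table.changes[("NN", "IN")] == {(SYNERGISTIC, UNCLASSIFIED): ["g01"]}


def test_edge_list_round_trip(tmp_path):
    prof = _profile_with_hub_labels([SYNERGISTIC, ANTAGONISTIC, INDEPENDENT])
    p = tmp_path / "edges.tsv"
    prof.write(p)
    edges = pd.read_csv(p, sep="\t")
    assert set(edges["label"]) == {SYNERGISTIC, ANTAGONISTIC, INDEPENDENT}
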