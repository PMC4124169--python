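"""Size factors, the exact NB test, BH adjustment, glucose ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from isletkit import diffexpr
from isletkit.diffexpr import DEConfig, bh_adjust, nb_test, size_factors


def _nb_table(rng, n_genes, mu, dispersion, factors):
    r = 1.0 / dispersion
    cols = {}
    for j, f in enumerate(factors):
        m = mu * f
        cols[f"s{j}"] = rng.negative_binomial(r, r / (r + m))
    return pd.DataFrame(cols, index=[f"g{i}" for i in range(n_genes)])


def test_size_factors_identical_samples_are_one():
    counts = pd.DataFrame({"a": [10, 20, 30], "b": [10, 20, 30]})
    np.testing.assert_allclose(size_factors(counts), [1.0, 1.0])


def test_size_factors_recover_twofold_library():
    counts = pd.DataFrame({"a": [10, 20, 30], "b": [20, 40, 60]})
    f = size_factors(counts)
    assert f["b"] / f["a"] == pytest.approx(2.0)


def test_size_factors_within_5pct_on_nb_simulation(rng):
    mu = 10 ** rng.uniform(0.5, 3, 2000)
    true = np.array([0.6, 1.0, 1.5, 2.0])
    counts = _nb_table(rng, 2000, mu, 0.05, true)
    est = size_factors(counts).to_numpy()
    ratio = est / true
    ratio /= np.exp(np.mean(np.log(ratio)))
    assert np.all(np.abs(ratio - 1) < 0.05)


def test_size_factors_error_without_all_positive_gene():
    counts = pd.DataFrame({"a": [0, 5], "b": [3, 0]})
    with pytest.raises(ValueError, match="filter"):
        size_factors(counts)


@settings(derandomize=True, max_examples=100, deadline=None)
@given(st.lists(st.floats(min_value=1e-12, max_value=1.0), min_size=1, max_size=60))
def test_bh_matches_brute_force_step_up(pvals):
    p = np.array(pvals)
    q = bh_adjust(p)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    brute = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        brute[i] = running
    np.testing.assert_allclose(q, brute, rtol=1e-10)
    assert np.all(q >= p - 1e-15)


def test_swapping_groups_negates_folds_and_keeps_pvalues(rng):
    mu = 10 ** rng.uniform(1, 3, 300)
    counts = _nb_table(rng, 300, mu, 0.05, [1, 1, 1, 1])
    counts.columns = ["a1", "a2", "b1", "b2"]
    fwd = nb_test(counts, ["a1", "a2"], ["b1", "b2"])
    rev = nb_test(counts, ["b1", "b2"], ["a1", "a2"])
    np.testing.assert_allclose(fwd["log2_fold"], -rev["log2_fold"], atol=1e-12)
    np.testing.assert_allclose(fwd["p_value"], rev["p_value"], rtol=1e-12)


def test_all_zero_gene_excluded_with_ns_call():
    counts = pd.DataFrame(
        {"a1": [0, 10], "a2": [0, 12], "b1": [0, 9], "b2": [0, 11]},
        index=["dead", "alive"],
    )
    res = nb_test(counts, ["a1", "a2"], ["b1", "b2"]).set_index("gene_id")
    assert np.isnan(res.loc["dead", "p_value"])
    assert res.loc["dead", "call"] == "ns"
    assert np.isfinite(res.loc["alive", "p_value"])


def test_single_replicate_group_rejected():
    counts = pd.DataFrame({"a1": [5], "b1": [5], "b2": [6]})
    with pytest.raises(ValueError, match="replicates"):
        nb_test(counts, ["a1"], ["b1", "b2"])


def test_qvalues_never_below_pvalues(rng):
    mu = 10 ** rng.uniform(1, 3, 500)
    counts = _nb_table(rng, 500, mu, 0.05, [1, 1, 1, 1])
    counts.columns = ["a1", "a2", "b1", "b2"]
    res = nb_test(counts, ["a1", "a2"], ["b1", "b2"]).dropna(subset=["p_value"])
    assert (res["q_value"] >= res["p_value"] - 1e-15).all()


def test_null_pvalues_roughly_uniform(rng):
    mu = 10 ** rng.uniform(0.5, 3, 2000)
    counts = _nb_table(rng, 2000, mu, 0.05, [1.1, 0.8, 1.3, 0.9])
    counts.columns = ["a1", "a2", "b1", "b2"]
    res = nb_test(counts, ["a1", "a2"], ["b1", "b2"])
    p = res["p_value"].dropna()
    assert 0.02 < (p < 0.05).mean() < 0.08
    assert (res["call"] != "ns").sum() == 0


def test_exact_pvalue_is_one_for_balanced_split():
    p = diffexpr.exact_nb_pvalue(50, 50, 2.0, 2.0, 2.0, 2.0, 0.05)
    assert p == pytest.approx(1.0)


def test_glucose_identical_inputs_give_zero_folds(rng):
    counts = pd.DataFrame(
        rng.integers(10, 200, (100, 2)),
        index=[f"t{i}" for i in range(100)], columns=["r1", "r2"],
    )
    res = diffexpr.glucose_response(counts, counts)
    np.testing.assert_allclose(res["log2_fold"], 0.0, atol=1e-12)


def test_glucose_planted_up_lnc_in_top_decile(small_sim):
    glc = small_sim.glucose()
    res = diffexpr.glucose_response(
        glc.counts_control, glc.counts_glucose, lnc_ids=set(glc.lnc_ids)
    )
    rank = {g: i for i, g in enumerate(res["gene_id"])}
    truth = glc.truth
    planted = truth.index[(truth["label"] == "up") & truth["is_lnc"]]
    cutoff = len(res) // 10
    assert all(rank[t] < cutoff for t in planted)
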