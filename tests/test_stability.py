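"""Tests of the three stability algorithms against hand computations and
brute-force oracles."""

import numpy as np
import pandas as pd
import pytest

from mirnorm import bestkeeper, consensus_table, genorm, normfinder


# ---------------------------------------------------------------------------
# brute-force geNorm oracle
# ---------------------------------------------------------------------------

def genorm_m_by_hand(rq: pd.DataFrame) -> dict:
    """Double loop over gene pairs: M_j = mean_k SD(log2(x_j/x_k))."""
    genes = list(rq.index)
    out = {}
    for j in genes:
        sds = []
        for k in genes:
            if k == j:
                continue
            ratio = np.log2(rq.loc[j].to_numpy() / rq.loc[k].to_numpy())
            sds.append(np.std(ratio, ddof=1))
        out[j] = float(np.mean(sds))
    return out


def random_rq(k, n, seed):
    rng = np.random.default_rng(seed)
    return pd.DataFrame(
        2.0 ** rng.normal(0, 1, (k, n)),
        index=[f"g{i}" for i in range(k)],
        columns=[f"s{i}" for i in range(n)],
    )


# ---------------------------------------------------------------------------
# geNorm
# ---------------------------------------------------------------------------

def test_genorm_worked_example(worked_rq):
    rep = genorm(worked_rq)
    assert rep.table.loc["A", "score"] == pytest.approx(0.5)
    assert rep.table.loc["B", "score"] == pytest.approx(0.5)
    assert rep.table.loc["C", "score"] == pytest.approx(1.0)
    assert rep.extras["elimination_order"] == ["C"]
    assert rep.best_pair == ("A", "B")
    v = rep.extras["v_series"]
    assert v.loc[v["n"] == 2, "V"].iloc[0] == pytest.approx(1.0 / 3.0)


def test_genorm_identical_genes_give_zero_m():
    rq = pd.DataFrame(np.ones((4, 5)), index=list("abcd"))
    rep = genorm(rq + 1.0)
    np.testing.assert_allclose(rep.table["score"], 0.0)
    np.testing.assert_allclose(rep.extras["v_series"]["V"], 0.0)


def test_genorm_matches_brute_force_oracle():
    for seed in range(10):
        k = 3 + seed % 4
        rq = random_rq(k, 8, seed)
        rep = genorm(rq)
        expected = genorm_m_by_hand(rq)
        for g, m in expected.items():
            assert rep.table.loc[g, "score"] == pytest.approx(m, abs=1e-9)


def test_genorm_elimination_matches_from_scratch_recomputation():
    rq = random_rq(6, 10, 42)
    rep = genorm(rq)
    remaining = list(rq.index)
    for eliminated in rep.extras["elimination_order"]:
        m = genorm_m_by_hand(rq.loc[remaining])
        worst_m = max(m.values())
        worst = max(g for g in remaining if m[g] == pytest.approx(worst_m, abs=1e-12))
        assert eliminated == worst
        remaining.remove(worst)


def test_genorm_scale_invariance():
    """Per-gene and per-sample multiplicative rescaling leave M and V alone."""
    rq = random_rq(5, 9, 7)
    rep = genorm(rq)
    rng = np.random.default_rng(1)
    gene_scale = pd.Series(10.0 ** rng.uniform(-3, 3, 5), index=rq.index)
    sample_scale = pd.Series(10.0 ** rng.uniform(-3, 3, 9), index=rq.columns)
    scaled = rq.mul(gene_scale, axis=0).mul(sample_scale, axis=1)
    rep2 = genorm(scaled)
    np.testing.assert_allclose(rep.table["score"], rep2.table["score"], atol=1e-9)
    np.testing.assert_allclose(
        rep.extras["v_series"]["V"], rep2.extras["v_series"]["V"], atol=1e-9
    )


def test_genorm_rejects_degenerate_input(worked_rq):
    with pytest.raises(ValueError, match="3 candidate genes"):
        genorm(worked_rq.iloc[:2])
    with pytest.raises(ValueError, match="positive"):
        genorm(worked_rq - 1.0)


def test_genorm_gene_order_invariance(worked_rq):
    rep = genorm(worked_rq)
    rep2 = genorm(worked_rq.loc[["C", "A", "B"]])
    pd.testing.assert_frame_equal(
        rep.table.sort_index(), rep2.table.sort_index()
    )


# ---------------------------------------------------------------------------
# NormFinder
# ---------------------------------------------------------------------------

def grouped_frame(k=5, per_group=6, seed=0, shift_gene=None, shift=0.0):
    rng = np.random.default_rng(seed)
    samples = [f"s{i}" for i in range(2 * per_group)]
    groups = pd.Series(["g1"] * per_group + ["g2"] * per_group, index=samples)
    log2 = rng.normal(0, 0.3, (k, len(samples)))
    frame = pd.DataFrame(log2, index=[f"gene{i}" for i in range(k)], columns=samples)
    if shift_gene is not None:
        frame.loc[shift_gene, groups == "g2"] += shift
    return 2.0**frame, groups


def test_normfinder_constant_genes_score_zero():
    rq = pd.DataFrame(np.ones((4, 8)) * 3.0, index=list("abcd"))
    groups = pd.Series(["g1"] * 4 + ["g2"] * 4, index=rq.columns)
    rep = normfinder(rq, groups=groups)
    np.testing.assert_allclose(rep.table["score"], 0.0, atol=1e-12)


def test_planted_group_shift_gets_strictly_largest_score():
    """One gene shifted +1 log2 in one group among otherwise constant genes."""
    rq = pd.DataFrame(np.ones((5, 10)), index=[f"gene{i}" for i in range(5)])
    groups = pd.Series(["g1"] * 5 + ["g2"] * 5, index=rq.columns)
    rq.loc["gene0", groups == "g2"] = 2.0
    rep = normfinder(rq, groups=groups)
    scores = rep.table["score"]
    assert scores["gene0"] > scores.drop("gene0").max()
    # closed form at zero noise: the shift leaks -1/k into the other genes
    # after removing the sample effect, so |d| = 0.4 vs 0.1 per group at k=5
    assert scores["gene0"] == pytest.approx(0.4, abs=1e-9)
    np.testing.assert_allclose(scores.drop("gene0"), 0.1, atol=1e-9)


def test_variance_correction_algebraic_identity():
    """Before truncation, sum_i sigma2_ig = k/(k-1) * sum_i s2_ig."""
    for seed in range(5):
        rq, groups = grouped_frame(k=6, seed=seed)
        rep = normfinder(rq, groups=groups)
        raw = rep.extras["raw_s2"]
        untrunc = rep.extras["sigma2_untruncated"]
        k = rq.shape[0]
        for g in raw.columns:
            assert untrunc[g].sum() == pytest.approx(
                k / (k - 1) * raw[g].sum(), abs=1e-9
            )


def test_ungrouped_mode_ranks_by_corrected_variance():
    rng = np.random.default_rng(3)
    sds = [0.05, 0.1, 0.2, 0.4, 0.8]
    frame = pd.DataFrame(
        [rng.normal(0, sd, 60) for sd in sds], index=[f"gene{i}" for i in range(5)]
    )
    rep = normfinder(2.0**frame)
    assert rep.extras["mode"] == "ungrouped"
    order = rep.table.sort_values("rank").index.tolist()
    assert order == [f"gene{i}" for i in range(5)]


def test_normfinder_requires_three_genes():
    rq = pd.DataFrame(np.ones((2, 6)), index=list("ab"))
    with pytest.raises(ValueError, match="k - 2"):
        normfinder(rq)


def test_normfinder_gene_order_invariance():
    rq, groups = grouped_frame(seed=4)
    rep = normfinder(rq, groups=groups)
    shuffled = rq.loc[list(reversed(rq.index))]
    rep2 = normfinder(shuffled, groups=groups)
    pd.testing.assert_series_equal(
        rep.table["score"].sort_index(), rep2.table["score"].sort_index()
    )
    assert rep.best_pair == rep2.best_pair


# ---------------------------------------------------------------------------
# BestKeeper
# ---------------------------------------------------------------------------

def test_bestkeeper_worked_example():
    cq = pd.DataFrame(
        {"s1": [20.0, 24.0], "s2": [21.0, 24.0], "s3": [22.0, 24.0]},
        index=["var", "flat"],
    )
    rep = bestkeeper(cq, efficiencies=1.0)
    assert rep.table.loc["var", "arith_mean_cq"] == pytest.approx(21.0)
    assert rep.table.loc["var", "sd_mad"] == pytest.approx(2.0 / 3.0)
    assert rep.table.loc["var", "x_fold"] == pytest.approx(2.0 ** (2.0 / 3.0))


def test_bestkeeper_sd_cutoff_flags_inconsistent_genes():
    cq = pd.DataFrame(
        {"s1": [20.0, 24.0, 25.0], "s2": [22.4, 24.1, 25.1], "s3": [24.8, 24.2, 25.2]},
        index=["wild", "a", "b"],
    )  # "wild" has MAD = 1.6 cycles
    rep = bestkeeper(cq)
    assert rep.extras["excluded"] == ["wild"]
    assert np.isnan(rep.table.loc["wild", "rank"])
    # the index is built from retained genes only
    expected_index = np.sqrt(cq.loc["a"] * cq.loc["b"])
    np.testing.assert_allclose(rep.extras["index"], expected_index)


def test_gene_identical_to_index_has_unit_correlation():
    cq = pd.DataFrame(
        {"s1": [20.0, 20.0], "s2": [21.0, 21.0], "s3": [22.5, 22.5]},
        index=["a", "b"],
    )
    rep = bestkeeper(cq)
    assert rep.table.loc["a", "r_index"] == pytest.approx(1.0)
    assert rep.table.loc["b", "r_index"] == pytest.approx(1.0)


def test_duplicate_genes_get_identical_statistics():
    rng = np.random.default_rng(5)
    base = 24.0 + rng.normal(0, 0.4, 10)
    cq = pd.DataFrame([base, base, 22.0 + rng.normal(0, 0.3, 10)],
                      index=["dup1", "dup2", "other"])
    rep = bestkeeper(cq)
    cols = ["geo_mean_cq", "sd_mad", "cv_pct", "x_fold", "r_index"]
    np.testing.assert_allclose(
        rep.table.loc["dup1", cols].astype(float),
        rep.table.loc["dup2", cols].astype(float),
    )


def test_zero_variance_index_reports_missing_correlations():
    cq = pd.DataFrame(np.full((2, 4), 24.0), index=["a", "b"])
    rep = bestkeeper(cq)
    assert np.isnan(rep.table["r_index"]).all()


def test_compatibility_limit_rejects_large_panels():
    cq = pd.DataFrame(
        24.0 + np.random.default_rng(0).normal(0, 0.2, (12, 6)),
        index=[f"g{i:02d}" for i in range(12)],
    )
    with pytest.raises(ValueError, match="at most 10"):
        bestkeeper(cq, compat_limit=True)
    rep = bestkeeper(cq)  # native mode has no limit
    assert rep.table["rank"].notna().sum() == 12


# ---------------------------------------------------------------------------
# consensus
# ---------------------------------------------------------------------------

def test_consensus_merges_reports_with_blanks():
    rng = np.random.default_rng(8)
    genes = [f"g{i:02d}" for i in range(13)]
    rq = pd.DataFrame(2.0 ** rng.normal(0, 0.4, (13, 12)), index=genes)
    groups = pd.Series(["g1"] * 6 + ["g2"] * 6, index=rq.columns)
    cq = pd.DataFrame(24.0 + rng.normal(0, 0.3, (13, 12)), index=genes,
                      columns=rq.columns)
    cq.loc["g00"] += np.linspace(-2, 2, 12)  # force a BestKeeper exclusion
    reports = [genorm(rq), normfinder(rq, groups=groups), bestkeeper(cq)]
    table = consensus_table(reports)
    gene_rows = table.iloc[:-2]
    assert len(gene_rows) == 13
    assert {"genorm_score", "genorm_rank", "normfinder_score", "normfinder_rank",
            "bestkeeper_score", "bestkeeper_rank"} <= set(table.columns)
    assert pd.isna(gene_rows.loc["g00", "bestkeeper_rank"])
    # geNorm's joint top pair is displayed with distinct ranks
    shown = sorted(gene_rows["genorm_rank"].dropna().astype(int))
    assert shown == list(range(1, 14))
    assert list(table.index[-2:]) == ["Best gene", "Best combination"]


def test_consensus_of_single_report_equals_report(worked_rq):
    rep = genorm(worked_rq)
    table = consensus_table([rep])
    np.testing.assert_allclose(
        table.iloc[:-2]["genorm_score"].astype(float),
        rep.table["score"].round(4).astype(float),
    )


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

from hypothesis import given, settings, strategies as st


@settings(max_examples=25, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_genorm_m_nonnegative_and_rescale_invariant(seed):
    rng = np.random.default_rng(seed)
    k, n = int(rng.integers(3, 7)), int(rng.integers(3, 9))
    rq = random_rq(k, n, seed)
    rep = genorm(rq)
    assert (rep.table["score"] >= 0).all()
    scaled = rq * 10.0 ** rng.uniform(-3, 3)
    np.testing.assert_allclose(
        rep.table["score"], genorm(scaled).table["score"], atol=1e-9
    )
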