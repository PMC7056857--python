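"""Fisher-exact enrichment: tables, p-values, odds ratios, BH adjustment."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import fisher_exact as scipy_fisher

from somscape import (
    ContingencyTable,
    GeneSetCollection,
    fisher_exact,
    make_contingency,
    odds_ratio_ci,
    run_enrichment,
    results_to_frame,
)
from somscape.cluster import ClusterAssignment
from somscape.enrich import _pmf_support, fisher_exact_both
from somscape.synthetic import gene_ids, simulate_genesets


def enumeration_oracle(a, b, c, d):
    """Full hypergeometric enumeration via log-factorials (independent)."""
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n + K - N), min(n, K)

    def lpmf(x):
        return (
            math.lgamma(n + 1) - math.lgamma(x + 1) - math.lgamma(n - x + 1)
            + math.lgamma(N - n + 1) - math.lgamma(K - x + 1) - math.lgamma(N - n - K + x + 1)
            - (math.lgamma(N + 1) - math.lgamma(K + 1) - math.lgamma(N - K + 1))
        )

    probs = [math.exp(lpmf(x)) for x in range(lo, hi + 1)]
    p_obs = probs[a - lo]
    p1 = sum(p for x, p in zip(range(lo, hi + 1), probs) if x >= a)
    p2 = sum(p for p in probs if p <= p_obs * (1 + 1e-7))
    return min(1.0, p1), min(1.0, p2)


# -------------------------------------------------------------- tables
def test_make_contingency_counts():
    u4 = {"g1", "g2", "g3", "g4"}
    t = make_contingency({"g1", "g2"}, {"g2", "g3"}, u4)
    assert (t.a, t.b, t.c, t.d) == (1, 1, 1, 1)
    u10 = {f"g{i}" for i in range(10)}
    t = make_contingency({"g0", "g1", "g2"}, {"g5", "g6", "g7", "g8"}, u10)
    assert (t.a, t.b, t.c, t.d) == (0, 3, 4, 3)
    t = make_contingency(u10, u10, u10)
    assert (t.a, t.b, t.c, t.d) == (10, 0, 0, 0)
    with pytest.raises(ValueError, match="empty universe"):
        make_contingency({"g"}, {"g"}, set())
    # membership outside the universe never leaks into the counts
    t = make_contingency({"g1", "zz"}, {"g2", "yy"}, u4)
    assert t.n == 4


# ------------------------------------------------------------ p-values
def test_balanced_table_two_tail_is_one():
    assert fisher_exact(ContingencyTable(5, 5, 5, 5), "two") == pytest.approx(1.0)


def test_zero_margin_gives_p_one_both_tails():
    for t in (ContingencyTable(0, 0, 5, 5), ContingencyTable(0, 5, 0, 5)):
        assert fisher_exact(t, "one_greater") == 1.0
        assert fisher_exact(t, "two") == 1.0


def test_3113_matches_frozen_enumeration():
    # margins (4,4,4,4): pmf = (1,16,36,16,1)/70
    t = ContingencyTable(3, 1, 1, 3)
    assert fisher_exact(t, "one_greater") == pytest.approx(17 / 70, abs=1e-12)
    assert fisher_exact(t, "two") == pytest.approx(34 / 70, abs=1e-12)


def test_matches_enumeration_oracle_on_small_margin_grid():
    for r1 in range(9):
        for c1 in range(9):
            for a in range(min(r1, c1) + 1):
                b, c = r1 - a, c1 - a
                for d in range(9 - c):
                    if b + d > 8:
                        continue
                    t = ContingencyTable(a, b, c, d)
                    p1, p2 = fisher_exact_both(t)
                    o1, o2 = enumeration_oracle(a, b, c, d)
                    assert p1 == pytest.approx(o1, abs=1e-12)
                    assert p2 == pytest.approx(o2, abs=1e-12)


def test_agrees_with_scipy_reference():
    rng = np.random.default_rng(5)
    for _ in range(50):
        a, b, c, d = rng.integers(0, 40, size=4)
        t = ContingencyTable(int(a), int(b), int(c), int(d))
        assert fisher_exact(t, "two") == pytest.approx(
            scipy_fisher([[a, b], [c, d]], alternative="two-sided")[1], rel=1e-9
        )
        assert fisher_exact(t, "one_greater") == pytest.approx(
            scipy_fisher([[a, b], [c, d]], alternative="greater")[1], rel=1e-9
        )


@settings(derandomize=True, deadline=None, max_examples=60)
@given(cells=st.tuples(*[st.integers(0, 30)] * 4))
def test_two_tail_invariant_under_transpose_and_bounded(cells):
    a, b, c, d = cells
    t = ContingencyTable(a, b, c, d)
    tt = ContingencyTable(a, c, b, d)
    p1, p2 = fisher_exact_both(t)
    assert 0 < p1 <= 1 and 0 < p2 <= 1
    assert p2 == pytest.approx(fisher_exact_both(tt)[1], abs=1e-12)
    if min(a + b, c + d, a + c, b + d) > 0:
        support, pmf = _pmf_support(t)
        assert p2 >= pmf[a - support[0]] - 1e-12  # two-tail >= point probability


# ---------------------------------------------------------- odds ratio
def test_odds_ratio_plain_and_symmetric_ci():
    orr, lo, hi = odds_ratio_ci(ContingencyTable(5, 5, 5, 5))
    assert orr == pytest.approx(1.0)
    assert lo * hi == pytest.approx(1.0)  # symmetric about 1 on log scale
    orr, lo, hi = odds_ratio_ci(ContingencyTable(10, 5, 2, 8))
    assert orr == pytest.approx(8.0)
    assert lo <= orr <= hi


def test_zero_cell_uses_haldane_correction():
    # longhand Woolf on the +0.5-corrected cells
    a, b, c, d = 10.5, 0.5, 2.5, 8.5
    expected = (a * d) / (b * c)
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = 1.959963984540054
    orr, lo, hi = odds_ratio_ci(ContingencyTable(10, 0, 2, 8))
    assert orr == pytest.approx(expected)
    assert lo == pytest.approx(expected * math.exp(-z * se))
    assert hi == pytest.approx(expected * math.exp(z * se))


# ----------------------------------------------------------- screening
def _labelled_clusters(labels):
    ids = gene_ids(len(labels))
    node_labels = np.arange(1, max(labels) + 2)
    return ClusterAssignment(
        node_labels=node_labels,
        seeds={c + 1: c for c in range(max(labels) + 1)},
        gene_labels={g: int(l) + 1 for g, l in zip(ids, labels)},
    )


def test_single_test_bh_is_identity():
    labels = np.zeros(40, dtype=int)
    labels[:20] = 0
    ca = _labelled_clusters(labels)
    coll = GeneSetCollection({"s": set(gene_ids(40)[:10])})
    res = run_enrichment(ca, coll)
    assert len(res) == 1
    assert res[0].p_adjusted == pytest.approx(res[0].p_two)


def test_planted_set_is_top_hit_for_its_cluster():
    rng = np.random.default_rng(13)
    labels = np.arange(1000) % 4
    coll = simulate_genesets(labels, [(1, 0.8, 0.05)], n_decoys=9, seed=13)
    ca = _labelled_clusters(labels)
    res = run_enrichment(ca, coll, tails="two")
    best = min(res, key=lambda r: r.p_two)
    assert best.cluster == 2  # group 1 -> cluster id 2
    assert best.set_name.startswith("planted_g1")
    assert best.direction == "enriched"
    df = results_to_frame(res)
    assert (df.groupby("set")["a"].sum() > 0).any()


def test_bh_adjustment_matches_textbook_stepup():
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 3, size=300)
    coll = simulate_genesets(labels, [(0, 0.6, 0.1)], n_decoys=5, seed=2)
    ca = _labelled_clusters(labels)
    res = run_enrichment(ca, coll, tails="two")
    raw = np.array([r.p_two for r in res])
    adj = np.array([r.p_adjusted for r in res])
    m = len(raw)
    order = np.argsort(raw)
    stepup = raw[order] * m / np.arange(1, m + 1)
    stepup = np.minimum.accumulate(stepup[::-1])[::-1]
    np.testing.assert_allclose(adj[order], np.minimum(stepup, 1.0), atol=1e-12)
    assert (adj >= raw - 1e-15).all()
    # adjusted p monotone in raw-p rank order
    assert (np.diff(adj[order]) >= -1e-15).all()


def test_depletion_direction_and_universe_restriction():
    labels = np.arange(200) % 2
    ids = gene_ids(200)
    ca = _labelled_clusters(labels)
    # set drawn almost entirely from group 1 -> depleted in cluster 1
    coll = GeneSetCollection({"grp1ish": {g for g, l in zip(ids, labels) if l == 1}})
    res = run_enrichment(ca, coll, tails="two")
    r1 = next(r for r in res if r.cluster == 1)
    assert r1.direction == "depleted" and r1.odds_ratio < 1
    with pytest.raises(ValueError):
        run_enrichment(ca, GeneSetCollection({"out": {"zz1", "zz2"}}))
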