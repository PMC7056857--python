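"""Fisher-exact enrichment and depletion of gene clusters.

Each (cluster, gene set) pair defines a 2x2 table over a gene universe::

              in set   not in set
    cluster      a         b
    rest         c         d

Under fixed margins ``a`` follows the hypergeometric distribution; the
one-tail p-value is P(A >= a) (enrichment only), and the two-tail
p-value follows the classical point-probability convention — the sum of
probabilities of all tables, with the same margins, that are at most as
probable as the observed one (a small relative slack absorbs float
noise), capturing enrichment and depletion symmetrically.  Odds ratios
carry Woolf (log-scale normal) confidence intervals, with the
Haldane-Anscombe +0.5 correction applied only when a cell is zero and
never to the p-values.  Within a collection, p-values are adjusted by
Benjamini-Hochberg across all cluster-set pairs of the same tail family.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, norm
from statsmodels.stats.multitest import multipletests

from .cluster import ClusterAssignment

#: relative slack when comparing hypergeometric point probabilities
_TWO_TAIL_SLACK = 1e-7


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. curated disease sets, phylostrata, pathways).

    ``ordering`` optionally ranks sets for display (e.g. phylostratum
    order along evolutionary history); it never affects the statistics.
    """

    sets: dict[str, set[str]]
    collection_name: str = ""
    ordering: dict[str, float] | None = None

    def __post_init__(self):
        self.sets = {str(k): {str(g) for g in v} for k, v in self.sets.items()}

    def __len__(self) -> int:
        return len(self.sets)

    def restricted_to(self, universe: set[str]) -> "GeneSetCollection":
        """Intersect every set with ``universe``, dropping emptied sets."""
        kept = {n: s & universe for n, s in self.sets.items() if s & universe}
        return GeneSetCollection(kept, self.collection_name, self.ordering)


@dataclass(frozen=True)
class ContingencyTable:
    a: int  # cluster & set
    b: int  # cluster only
    c: int  # set only
    d: int  # neither

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("cells must be non-negative integers")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d


@dataclass
class EnrichmentResult:
    cluster: int
    set_name: str
    table: ContingencyTable
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_one: float
    p_two: float
    p_adjusted: float
    direction: str  # "enriched" | "depleted"


def make_contingency(
    cluster_genes: set[str], annotation_genes: set[str], universe: set[str]
) -> ContingencyTable:
    """2x2 counts of cluster vs annotation membership within a universe."""
    if not universe:
        raise ValueError("empty universe")
    cl = set(cluster_genes) & universe
    an = set(annotation_genes) & universe
    a = len(cl & an)
    return ContingencyTable(a=a, b=len(cl) - a, c=len(an) - a, d=len(universe) - len(cl | an))


def _pmf_support(t: ContingencyTable):
    """Hypergeometric support and pmf for tables sharing t's margins."""
    N, K, n = t.n, t.a + t.c, t.a + t.b
    lo, hi = max(0, n + K - N), min(n, K)
    support = np.arange(lo, hi + 1)
    return support, hypergeom.pmf(support, N, K, n)


def fisher_exact_both(t: ContingencyTable) -> tuple[float, float]:
    """(one-tail greater, two-tail point-probability) p-values."""
    # a zero margin leaves a single admissible table: p = 1 both tails
    if min(t.a + t.b, t.c + t.d, t.a + t.c, t.b + t.d) == 0:
        return 1.0, 1.0
    support, pmf = _pmf_support(t)
    p_obs = pmf[t.a - support[0]]
    p_one = float(min(1.0, pmf[support >= t.a].sum()))
    p_two = float(min(1.0, pmf[pmf <= p_obs * (1.0 + _TWO_TAIL_SLACK)].sum()))
    return p_one, p_two


def fisher_exact(t: ContingencyTable, tails: str = "two") -> float:
    """Exact hypergeometric p-value with fixed margins.

    ``tails="one_greater"`` tests enrichment only (P(A >= a));
    ``tails="two"`` sums all tables at most as probable as the observed
    one.  Degenerate margins give p = 1.
    """
    if tails not in ("one_greater", "two"):
        raise ValueError("tails must be 'one_greater' or 'two'")
    p_one, p_two = fisher_exact_both(t)
    return p_one if tails == "one_greater" else p_two


def odds_ratio_ci(t: ContingencyTable, alpha: float = 0.05) -> tuple[float, float, float]:
    """Odds ratio with a Woolf (log-normal) confidence interval.

    When any cell is zero, 0.5 is added to every cell (Haldane-Anscombe)
    for the ratio and interval; raw counts always feed the exact test.
    """
    cells = np.array([t.a, t.b, t.c, t.d], dtype=float)
    if (cells == 0).any():
        cells = cells + 0.5
    a, b, c, d = cells
    orr = (a * d) / (b * c)
    z = norm.ppf(1.0 - alpha / 2.0)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return float(orr), float(orr * np.exp(-z * se)), float(orr * np.exp(z * se))


def run_enrichment(
    ca: ClusterAssignment,
    coll: GeneSetCollection,
    universe: set[str] | None = None,
    tails: str = "two",
    alpha: float = 0.05,
) -> list[EnrichmentResult]:
    """Test every cluster against every set of the collection.

    The universe defaults to all genes carrying a cluster label — the
    mapped population the clusters partition.  Adjusted p-values are
    Benjamini-Hochberg across all (cluster, set) pairs of the run.
    """
    if not ca.gene_labels:
        raise ValueError("cluster assignment carries no gene labels")
    if universe is None:
        universe = set(ca.gene_labels)
    universe = {str(g) for g in universe}
    coll_u = coll.restricted_to(universe)
    if not coll_u.sets:
        raise ValueError("no gene set overlaps the universe")

    clusters = sorted(ca.seeds)
    results: list[EnrichmentResult] = []
    for cid in clusters:
        cl_genes = {g for g in ca.genes_of(cid) if g in universe}
        for name in sorted(coll_u.sets):
            t = make_contingency(cl_genes, coll_u.sets[name], universe)
            p_one, p_two = fisher_exact_both(t)
            orr, lo, hi = odds_ratio_ci(t, alpha=alpha)
            results.append(
                EnrichmentResult(
                    cluster=cid,
                    set_name=name,
                    table=t,
                    odds_ratio=orr,
                    ci_low=lo,
                    ci_high=hi,
                    p_one=p_one,
                    p_two=p_two,
                    p_adjusted=np.nan,
                    direction="enriched" if orr > 1 else "depleted",
                )
            )
    raw = [r.p_one if tails == "one_greater" else r.p_two for r in results]
    adj = multipletests(raw, method="fdr_bh")[1]
    for r, p in zip(results, adj):
        r.p_adjusted = float(p)
    return results


def results_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    """Flat table of all enrichment results (one row per cluster-set pair)."""
    return pd.DataFrame(
        {
            "cluster": [r.cluster for r in results],
            "set": [r.set_name for r in results],
            "a": [r.table.a for r in results],
            "b": [r.table.b for r in results],
            "c": [r.table.c for r in results],
            "d": [r.table.d for r in results],
            "odds_ratio": [r.odds_ratio for r in results],
            "ci_low": [r.ci_low for r in results],
            "ci_high": [r.ci_high for r in results],
            "p_one": [r.p_one for r in results],
            "p_two": [r.p_two for r in results],
            "p_adjusted": [r.p_adjusted for r in results],
            "direction": [r.direction for r in results],
        }
    )
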