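"""Hypergeometric over-representation tests for GO terms and cytology.

Categories are tested for enrichment of an interest set against a gene
universe with the hypergeometric upper tail.  Chromosomal annotation is
expanded into three nested category levels (arm, band within arm,
sub-band within band) and every level is tested; GO-style maps are
tested term by term.  The significance rule is unadjusted p < 0.05, with
a Benjamini-Hochberg column provided alongside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .anova import bh_fdr

logger = logging.getLogger(__name__)


@dataclass
class AnnotationMap:
    """Category -> gene-set mapping over a gene universe."""

    categories: dict[str, set]
    universe: set
    levels: dict[str, str] = field(default_factory=dict)  # category -> level name

    def __post_init__(self):
        for name, genes in self.categories.items():
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"category {name!r} annotates genes outside the universe: "
                    f"{sorted(extra)[:5]}"
                )


def go_annotation(go_table: pd.DataFrame, universe=None) -> AnnotationMap:
    """Build an AnnotationMap from a (gene, term) long table."""
    uni = set(universe) if universe is not None else set(go_table["gene"])
    sub = go_table[go_table["gene"].isin(uni)]
    cats = {t: set(g["gene"]) for t, g in sub.groupby("term")}
    return AnnotationMap(cats, uni, {t: "term" for t in cats})


def chromosome_annotation(chrom_table: pd.DataFrame, universe=None) -> AnnotationMap:
    """Nested arm / band / sub-band categories from a cytology table.

    Expects columns gene, arm, band, subband; categories are named
    "X", "X:12", "X:12:A" etc., so a sub-band's genes are a subset of its
    band's, which are a subset of its arm's.
    """
    uni = set(universe) if universe is not None else set(chrom_table["gene"])
    sub = chrom_table[chrom_table["gene"].isin(uni)]
    cats: dict[str, set] = {}
    levels: dict[str, str] = {}
    for _, row in sub.iterrows():
        arm = str(row["arm"])
        band = f"{arm}:{row['band']}"
        subband = f"{band}:{row['subband']}"
        for name, level in ((arm, "arm"), (band, "band"), (subband, "subband")):
            cats.setdefault(name, set()).add(row["gene"])
            levels[name] = level
    return AnnotationMap(cats, uni, levels)


def hypergeom_overrep(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail hypergeometric p: P(X >= k) drawing n from N with K marked.

    k = observed interest genes in the category, K = category size,
    n = interest-set size, N = universe size.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"impossible counts (k={k}, K={K}, n={n}, N={N})")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def test_categories(
    interest: set,
    annotation: AnnotationMap,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of the interest set per category.

    One test per category at every nesting level; the significance flag
    uses unadjusted p < alpha, with BH q values emitted alongside.
    Categories with no genes are skipped (logged).
    """
    interest = set(interest)
    extra = interest - annotation.universe
    if extra:
        raise ValueError(f"interest genes outside universe: {sorted(extra)[:5]}")
    N = len(annotation.universe)
    n = len(interest)
    rows = []
    for name, genes in sorted(annotation.categories.items()):
        K = len(genes)
        if K == 0:
            logger.info("skipping empty category %s", name)
            continue
        k = len(interest & genes)
        p = hypergeom_overrep(k, K, n, N)
        expected = n * K / N
        odds = (
            (k / max(n - k, 0.5)) / ((K - k) / max(N - K - (n - k), 0.5))
            if K > k
            else np.inf
        )
        rows.append({
            "category": name,
            "level": annotation.levels.get(name, "category"),
            "k": k, "K": K, "n": n, "N": N,
            "expected": expected,
            "odds_ratio": odds,
            "p": p,
        })
    res = pd.DataFrame(rows)
    if not res.empty:
        res["q"] = bh_fdr(res["p"].to_numpy())
        res["significant"] = res["p"] < alpha
    return res
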