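"""Tissue atlas rescaling, tissue-specificity flags and Fisher enrichment.

An atlas gives per-tissue log2 expression for every gene plus a
whole-organism column.  Tissue columns are first rescaled to the
whole-organism baseline using the genes unexpressed in the whole
organism (below an expression threshold, default 3.4): each tissue's
additive offset is the mean difference on that unexpressed set, so all
tissues share an equal signal baseline.  A transcript is tissue-specific
when its rescaled tissue expression exceeds its whole-organism value by
at least 1 log2 unit (2-fold, inclusive).  Over-representation of a gene
list among a tissue's specific transcripts is assessed with a one-tailed
Fisher exact test, Bonferroni-corrected for the number of tissues.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats.contingency import odds_ratio as _cond_odds_ratio

WHOLE_FLY = "whole_fly"
DEFAULT_THRESHOLD = 3.4
DEFAULT_N_TISSUES = 17


def _tissue_columns(atlas: pd.DataFrame, wholefly_col: str) -> list[str]:
    return [c for c in atlas.columns if c != wholefly_col]


def unexpressed_set(atlas: pd.DataFrame, threshold: float = DEFAULT_THRESHOLD,
                    wholefly_col: str = WHOLE_FLY) -> pd.Index:
    """Genes whose whole-organism expression falls below the threshold."""
    return atlas.index[atlas[wholefly_col] < threshold]


def rescale_to_baseline(
    atlas: pd.DataFrame,
    threshold: float = DEFAULT_THRESHOLD,
    wholefly_col: str = WHOLE_FLY,
) -> pd.DataFrame:
    """Subtract each tissue's unexpressed-gene offset from its column.

    offset_t = mean over unexpressed genes of (tissue - whole organism);
    the whole-organism column is unchanged.  Idempotent: a second
    application finds offsets of zero.
    """
    U = unexpressed_set(atlas, threshold, wholefly_col)
    if len(U) == 0:
        raise ValueError(
            f"no genes below the expression threshold {threshold}; "
            "raise the threshold or check the whole-organism column"
        )
    out = atlas.copy()
    base = atlas.loc[U, wholefly_col].mean()
    for t in _tissue_columns(atlas, wholefly_col):
        offset = atlas.loc[U, t].mean() - base
        out[t] = atlas[t] - offset
    return out


def flag_tissue_specific(
    rescaled: pd.DataFrame,
    fold: float = 2.0,
    wholefly_col: str = WHOLE_FLY,
) -> pd.DataFrame:
    """Boolean gene x tissue matrix of tissue-specific expression.

    specific iff rescaled_tissue - whole_organism >= log2(fold)
    (inclusive boundary).
    """
    cut = np.log2(fold)
    tissues = _tissue_columns(rescaled, wholefly_col)
    flags = {
        t: (rescaled[t] - rescaled[wholefly_col]) >= cut for t in tissues
    }
    return pd.DataFrame(flags, index=rescaled.index)


def fisher_exact_one_tailed(a: int, b: int, c: int, d: int):
    """One-tailed (enrichment) Fisher exact test on [[a, b], [c, d]].

    Returns (p, sample odds ratio, conditional-MLE odds ratio).  The p
    value is the hypergeometric upper tail P(X >= a) at the observed
    margins.  Sample OR = a*d / (b*c), with inf when b*c = 0 and a*d > 0
    and NaN for 0/0; the conditional MLE maximises the noncentral
    hypergeometric likelihood.
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("cell counts must be non-negative integers")
    a, b, c, d = int(a), int(b), int(c), int(d)
    N = a + b + c + d
    if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
        return 1.0, np.nan, np.nan
    p = float(stats.hypergeom.sf(a - 1, N, a + b, a + c))
    if b * c == 0:
        sample_or = np.inf if a * d > 0 else np.nan
    else:
        sample_or = a * d / (b * c)
    cond_or = float(_cond_odds_ratio([[a, b], [c, d]], kind="conditional").statistic)
    return p, sample_or, cond_or


def tissue_enrichment(
    flags: pd.DataFrame,
    interest_sets: dict[str, set],
    n_tissues: int | None = None,
) -> pd.DataFrame:
    """Fisher enrichment of each interest set in each tissue's specific genes.

    For every (tissue, set) pair the 2x2 table is (in set x specific in
    tissue) over the flag matrix's gene universe.  Bonferroni correction
    multiplies by the number of tissues (default: the number of tissue
    columns).  Empty interest sets yield p = 1 rows flagged ``empty_set``.
    """
    n_tissues = n_tissues or flags.shape[1]
    universe = flags.index
    rows = []
    for set_name, genes in interest_sets.items():
        genes = set(genes) & set(universe)
        in_set = universe.isin(genes)
        for tissue in flags.columns:
            spec = flags[tissue].to_numpy(bool)
            if not in_set.any():
                rows.append({
                    "tissue": tissue, "set": set_name, "a": 0, "b": 0,
                    "c": int(spec.sum()), "d": int((~spec).sum()),
                    "p": 1.0, "p_bonferroni": 1.0,
                    "odds_ratio_sample": np.nan, "odds_ratio_cmle": np.nan,
                    "empty_set": True,
                })
                continue
            a = int((in_set & spec).sum())
            b = int((in_set & ~spec).sum())
            c = int((~in_set & spec).sum())
            d = int((~in_set & ~spec).sum())
            p, or_s, or_c = fisher_exact_one_tailed(a, b, c, d)
            rows.append({
                "tissue": tissue, "set": set_name, "a": a, "b": b, "c": c, "d": d,
                "p": p, "p_bonferroni": min(1.0, p * n_tissues),
                "odds_ratio_sample": or_s, "odds_ratio_cmle": or_c,
                "empty_set": False,
            })
    return pd.DataFrame(rows)
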