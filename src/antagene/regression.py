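"""Moderated regression of expression on sex, fitness and their interaction.

Per transcript the model Y = B + S + F + S x F + e is fit by least
squares, where F is the sex-specific line fitness of each sample's own
(line, sex) cell and batch enters as fixed blocking columns.  Per-gene
residual variances are shrunk toward a global prior by empirical Bayes
(hierarchical scaled-chi-square model: moment matching on log s^2 with
digamma/trigamma corrections), yielding moderated t statistics with
d0 + d_g degrees of freedom.  Transcripts whose sex-by-fitness
interaction survives FDR control are called sexually antagonistic and
labelled male-benefit/female-detriment or the reverse by the sign of the
interaction coefficient; sex-specific models Y = B + F + e give the
per-sex fitness-associated sets and the Venn-style overlap summary.

With sex coded 0/1 (female reference), the female slope is beta_F and
the male slope is beta_F + beta_SF.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special, stats

from .anova import bh_fdr

logger = logging.getLogger(__name__)

D0_CAP = 1e6  # prior df used when variances carry no excess spread (full shrinkage)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


@dataclass
class RegressionDesign:
    """Design matrix with named columns and per-transcript residual df."""

    X: np.ndarray
    columns: list[str]
    d_g: int
    sample_ids: list[str]

    def col(self, name: str) -> int:
        return self.columns.index(name)


def build_design(
    samples: pd.DataFrame,
    fitness: pd.DataFrame,
    batch_mode: str = "fixed",
) -> RegressionDesign:
    """Assemble [intercept | batch blocks | sex | F | F x sex].

    ``fitness`` is a long (line, sex, fitness) table; every sample's F is
    its own line's fitness in its own sex.  Sex is coded 0/1 with female
    as reference.  Batch enters as fixed blocking dummies (first batch is
    the reference); with a single batch no batch columns are added.
    Raises on rank deficiency, naming the collinear columns.
    """
    if batch_mode not in ("fixed", "correlation"):
        raise ValueError(f"unknown batch_mode {batch_mode!r}")
    fit = fitness.set_index(["line", "sex"])["fitness"]
    missing = [
        (l, s) for l, s in zip(samples["line"], samples["sex"]) if (l, s) not in fit.index
    ]
    if missing:
        raise ValueError(f"no fitness value for sample cells {sorted(set(missing))[:5]}")
    F = np.array([fit[(l, s)] for l, s in zip(samples["line"], samples["sex"])])
    male = (samples["sex"] == "M").to_numpy(float)

    cols = [np.ones(len(samples))]
    names = ["intercept"]
    batches = pd.unique(samples["batch"])
    if len(batches) > 1:
        for b in batches[1:]:
            cols.append((samples["batch"] == b).to_numpy(float))
            names.append(f"batch_{b}")
    cols += [male, F, F * male]
    names += ["sex", "F", "F_sex"]
    X = np.column_stack(cols)

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a minimal set of columns involved in the deficiency
        bad = []
        for j in range(X.shape[1]):
            others = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(others) == rank:
                bad.append(names[j])
        raise ValueError(f"design is rank deficient; collinear columns: {bad}")
    return RegressionDesign(
        X=X, columns=names, d_g=X.shape[0] - X.shape[1],
        sample_ids=list(samples["sample_id"]),
    )


# ---------------------------------------------------------------------------
# per-transcript OLS
# ---------------------------------------------------------------------------


@dataclass
class OlsFits:
    """Vectorised least-squares fits for all transcripts."""

    coef: pd.DataFrame  # transcripts x design columns
    s2: np.ndarray
    d_g: int
    design: RegressionDesign
    xtx_inv: np.ndarray


def fit_per_transcript_ols(matrix: pd.DataFrame, design: RegressionDesign) -> OlsFits:
    """Least squares per transcript; s2_g = RSS / d_g."""
    Y = matrix[design.sample_ids].to_numpy(float)
    X = design.X
    xtx_inv = np.linalg.inv(X.T @ X)
    B = Y @ X @ xtx_inv.T  # transcripts x p
    resid = Y - B @ X.T
    rss = (resid**2).sum(axis=1)
    s2 = rss / design.d_g
    coef = pd.DataFrame(B, index=matrix.index, columns=design.columns)
    return OlsFits(coef=coef, s2=s2, d_g=design.d_g, design=design, xtx_inv=xtx_inv)


def estimate_intrabatch_correlation(matrix: pd.DataFrame, design: RegressionDesign,
                                    samples: pd.DataFrame) -> float:
    """Pooled common correlation of OLS residuals within batches.

    Supports the optional ``batch_mode="correlation"`` route: the
    returned rho defines an equicorrelated block covariance per batch for
    GLS refitting.
    """
    fits = fit_per_transcript_ols(matrix, design)
    Y = matrix[design.sample_ids].to_numpy(float)
    resid = Y - fits.coef.to_numpy() @ design.X.T
    resid = resid / resid.std(axis=1, keepdims=True)
    batch = samples.set_index("sample_id").loc[design.sample_ids, "batch"].to_numpy()
    num = den = 0.0
    for b in pd.unique(batch):
        idx = np.where(batch == b)[0]
        if len(idx) < 2:
            continue
        sub = resid[:, idx]
        m = len(idx)
        cross = (sub.sum(axis=1) ** 2 - (sub**2).sum(axis=1)).sum()
        num += cross
        den += resid.shape[0] * m * (m - 1)
    return float(num / den) if den else 0.0


# ---------------------------------------------------------------------------
# empirical Bayes moderation
# ---------------------------------------------------------------------------


def _trigamma_inverse(x: float) -> float:
    """Invert the monotone trigamma function by Newton iteration."""
    if x <= 0:
        return np.inf
    # start from the large-y asymptote trigamma(y) ~ 1/y + 1/(2y^2)
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def estimate_eb_hyperparameters(s2: np.ndarray, d_g: int) -> tuple[float, float]:
    """Estimate the prior df d0 and prior variance s0^2 from gene variances.

    Under the hierarchical model s2_g ~ s0^2 * chi2_{d_g}/d_g scaled by a
    chi-square prior with d0 df, log s2_g has variance
    trigamma(d0/2) + trigamma(d_g/2).  Moment matching on log s2 inverts
    the trigamma function for d0 and corrects the mean of log s2 with
    digamma terms for s0^2.  When the observed spread does not exceed the
    sampling floor, d0 is capped at ``D0_CAP`` (full shrinkage).
    """
    s2 = np.asarray(s2, float)
    if len(s2) < 2:
        raise ValueError("need at least two variances")
    if (s2 <= 0).any():
        raise ValueError("variances must be positive")
    z = np.log(s2)
    e = z - special.digamma(d_g / 2.0) + np.log(d_g / 2.0)
    evar = z.var(ddof=1) - special.polygamma(1, d_g / 2.0)
    if evar <= 0:
        logger.info("log-variance spread at/below sampling floor; full shrinkage")
        d0 = D0_CAP
        s0_2 = float(np.exp(e.mean()))
    else:
        d0 = 2.0 * _trigamma_inverse(evar)
        d0 = min(d0, D0_CAP)
        s0_2 = float(np.exp(e.mean() + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


def posterior_variances(s2: np.ndarray, d_g: int, d0: float, s0_2: float) -> np.ndarray:
    """Shrunken variances: (d0*s0^2 + d_g*s2_g) / (d0 + d_g)."""
    return (d0 * s0_2 + d_g * np.asarray(s2, float)) / (d0 + d_g)


@dataclass
class ModeratedStats:
    """Coefficients, shrunken variances and moderated t/p/q per transcript."""

    coef: pd.DataFrame
    s2: np.ndarray
    s2_post: np.ndarray
    d0: float
    s0_2: float
    d_g: int
    t: pd.DataFrame
    p: pd.DataFrame
    q: pd.DataFrame
    design: RegressionDesign


def moderated_t(fits: OlsFits, coefficients: list[str] | None = None) -> ModeratedStats:
    """Moderated t statistics and two-sided p/q values per coefficient.

    t_gk = beta_gk / sqrt(s2_post_g * (X'X)^-1_kk), referred to Student-t
    with d0 + d_g df (normal in the full-shrinkage limit d0 = cap).
    """
    d0, s0_2 = estimate_eb_hyperparameters(fits.s2, fits.d_g)
    s2_post = posterior_variances(fits.s2, fits.d_g, d0, s0_2)
    names = coefficients or fits.design.columns
    df_total = min(d0 + fits.d_g, 1e9)
    t = {}
    p = {}
    q = {}
    for name in names:
        k = fits.design.col(name)
        se = np.sqrt(s2_post * fits.xtx_inv[k, k])
        tk = fits.coef[name].to_numpy() / se
        pk = 2.0 * stats.t.sf(np.abs(tk), df_total)
        t[name], p[name] = tk, pk
        q[name] = bh_fdr(pk)
    idx = fits.coef.index
    return ModeratedStats(
        coef=fits.coef, s2=fits.s2, s2_post=s2_post, d0=d0, s0_2=s0_2,
        d_g=fits.d_g,
        t=pd.DataFrame(t, index=idx), p=pd.DataFrame(p, index=idx),
        q=pd.DataFrame(q, index=idx), design=fits.design,
    )


# ---------------------------------------------------------------------------
# antagonism calls
# ---------------------------------------------------------------------------


@dataclass
class AntagonismCalls:
    """Antagonistic transcripts with direction and slope-sign diagnostics."""

    table: pd.DataFrame
    n_male_benefit: int
    n_female_benefit: int
    frac_opposite_male_benefit: float
    frac_opposite_female_benefit: float


def call_antagonistic(stats_: ModeratedStats, alpha: float = 0.05) -> AntagonismCalls:
    """Call sexually antagonistic transcripts from the interaction term.

    Antagonistic iff q(F x sex) < alpha.  Direction: male-benefit/
    female-detriment iff the male slope exceeds the female slope
    (beta_SF > 0 under 0/1 coding); the opposite-sign indicator reports
    whether the two sex-specific slopes actually disagree in sign, the
    diagnostic summarised per direction group.
    """
    slope_f = stats_.coef["F"].to_numpy()
    slope_m = slope_f + stats_.coef["F_sex"].to_numpy()
    qv = stats_.q["F_sex"].to_numpy()
    antagonistic = qv < alpha
    direction = np.where(
        stats_.coef["F_sex"].to_numpy() > 0,
        "male_benefit_female_detriment",
        "female_benefit_male_detriment",
    )
    opposite = np.sign(slope_m) != np.sign(slope_f)
    table = pd.DataFrame(
        {
            "transcript": stats_.coef.index,
            "antagonistic": antagonistic,
            "direction": np.where(antagonistic, direction, ""),
            "slope_f": slope_f,
            "slope_m": slope_m,
            "opposite_sign": opposite,
            "q_interaction": qv,
            "q_F": stats_.q["F"].to_numpy(),
        }
    ).set_index("transcript")
    mb = table[antagonistic & (direction == "male_benefit_female_detriment")]
    fb = table[antagonistic & (direction == "female_benefit_male_detriment")]
    return AntagonismCalls(
        table=table,
        n_male_benefit=len(mb),
        n_female_benefit=len(fb),
        frac_opposite_male_benefit=float(mb["opposite_sign"].mean()) if len(mb) else np.nan,
        frac_opposite_female_benefit=float(fb["opposite_sign"].mean()) if len(fb) else np.nan,
    )


def sex_specific_association(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    fitness: pd.DataFrame,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Fit Y = B + F + e within each sex; signed significant lists.

    Returns per sex a table with the fitness slope, moderated t, p, q and
    a significance flag at the given FDR; positive/negative association
    is the slope's sign.
    """
    out = {}
    for sex in ("F", "M"):
        sub = samples[samples["sex"] == sex]
        if sub.empty:
            raise ValueError(f"no samples for sex {sex!r}")
        fit_sex = fitness[fitness["sex"] == sex]
        cols = [np.ones(len(sub))]
        names = ["intercept"]
        batches = pd.unique(sub["batch"])
        if len(batches) > 1:
            for b in batches[1:]:
                cols.append((sub["batch"] == b).to_numpy(float))
                names.append(f"batch_{b}")
        fmap = fit_sex.set_index("line")["fitness"]
        cols.append(sub["line"].map(fmap).to_numpy(float))
        names.append("F")
        X = np.column_stack(cols)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(f"rank-deficient sex-specific design for {sex!r}")
        design = RegressionDesign(X, names, X.shape[0] - X.shape[1],
                                  list(sub["sample_id"]))
        fits = fit_per_transcript_ols(matrix, design)
        mod = moderated_t(fits, coefficients=["F"])
        out[sex] = pd.DataFrame(
            {
                "slope": fits.coef["F"],
                "t": mod.t["F"],
                "p": mod.p["F"],
                "q": mod.q["F"],
                "significant": mod.q["F"] < alpha,
            },
            index=matrix.index,
        )
    return out


def overlap_summary(
    male_set: set, female_set: set, antagonistic_set: set
) -> pd.DataFrame:
    """Venn region counts for (male-assoc, female-assoc, antagonistic).

    Returns the 7 disjoint region counts plus, per sex, the fraction of
    that sex's fitness-associated set that is also antagonistic.
    """
    A, B, C = set(male_set), set(female_set), set(antagonistic_set)
    regions = {
        "male_only": len(A - B - C),
        "female_only": len(B - A - C),
        "antagonistic_only": len(C - A - B),
        "male_female": len((A & B) - C),
        "male_antagonistic": len((A & C) - B),
        "female_antagonistic": len((B & C) - A),
        "all_three": len(A & B & C),
    }
    rows = [{"region": k, "count": v} for k, v in regions.items()]
    rows.append({"region": "frac_male_assoc_antagonistic",
                 "count": len(A & C) / len(A) if A else np.nan})
    rows.append({"region": "frac_female_assoc_antagonistic",
                 "count": len(B & C) / len(B) if B else np.nan})
    return pd.DataFrame(rows)
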