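"""Quantitative genetics of sex-specific hemiclone fitness.

Relative fitness is computed per sex by dividing each replicate value by
the maximum over all lines and replicates of that sex, then averaging the
replicate relative values per line.  The bivariate genetic architecture

    y_slr = mu_s + a_sl + e_slr

with (a_f, a_m) jointly bivariate normal across lines (the among-line
genetic variance structure) and independent sex-specific residuals is
estimated by a Gibbs sampler, giving posterior means and 95% credible
intervals for the sex-specific genetic and residual variances, the
cross-sex covariance, the intersexual genetic correlation r_MF, narrow
sense heritabilities (with the hemiclonal x2 correction) and coefficients
of variation.  A deterministic ANOVA/moment estimator is provided as an
independent oracle on balanced designs, and a rank-based selector picks
hyper-dispersed lines for expression profiling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SEXES = ("F", "M")


@dataclass
class RelativeFitness:
    """Relative-fitness summaries per line and sex.

    Attributes
    ----------
    replicates : DataFrame
        line, sex, replicate, rel_value (raw value / per-sex max).
    line_means : DataFrame
        line, sex, rel_fitness, se, n_reps.
    """

    replicates: pd.DataFrame
    line_means: pd.DataFrame

    def wide(self) -> pd.DataFrame:
        """Line x sex table of mean relative fitness (columns F, M)."""
        return self.line_means.pivot(index="line", columns="sex", values="rel_fitness")

    def to_long(self) -> pd.DataFrame:
        """Long table (line, sex, fitness) for use as a covariate."""
        out = self.line_means.rename(columns={"rel_fitness": "fitness"})
        return out[["line", "sex", "fitness"]].reset_index(drop=True)


@dataclass
class GeneticArchitecture:
    """Bivariate genetic architecture of sex-specific fitness."""

    V_line_f: float
    V_line_m: float
    V_resid_f: float
    V_resid_m: float
    cov_fm: float
    r_MF: float
    h2_f: float
    h2_m: float
    CV_A_f: float
    CV_A_m: float
    CV_R_f: float
    CV_R_m: float
    mu_f: float
    mu_m: float
    ci: dict[str, tuple[float, float]] = field(default_factory=dict)
    chains: pd.DataFrame | None = None
    converged: bool = True
    ess_r_MF: float = np.nan
    # ratio-of-posterior-means variant of h2 (the posterior-mean h2 is the
    # primary report; both conventions are defensible so both are kept)
    h2_f_ratio_of_means: float = np.nan
    h2_m_ratio_of_means: float = np.nan


# ---------------------------------------------------------------------------
# relative fitness
# ---------------------------------------------------------------------------


def compute_relative_fitness(assays: pd.DataFrame) -> RelativeFitness:
    """Normalise raw assay values to relative fitness, per sex.

    Each replicate's relative value is its raw value divided by the
    maximum raw value over all lines and replicates of the same sex; the
    line's relative fitness is the mean of its replicate relative values.
    The construction guarantees the per-sex maximum replicate relative
    value is exactly 1, and is invariant to rescaling a sex's raw values.
    """
    required = {"line", "sex", "replicate", "value"}
    if not required.issubset(assays.columns):
        raise ValueError(f"assay table needs columns {sorted(required)}")
    if (assays["value"] < 0).any():
        raise ValueError("raw fitness values must be non-negative")

    reps = assays[["line", "sex", "replicate", "value"]].copy()
    rel = []
    for sex, grp in reps.groupby("sex"):
        vmax = grp["value"].max()
        if vmax <= 0:
            raise ValueError(f"all raw values are zero for sex {sex!r}")
        g = grp.copy()
        g["rel_value"] = g["value"] / vmax
        rel.append(g)
    replicates = pd.concat(rel).sort_index().drop(columns="value")

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    line_means = (
        replicates.groupby(["line", "sex"])["rel_value"]
        .agg(rel_fitness="mean", se=_sem, n_reps="size")
        .reset_index()
    )
    return RelativeFitness(replicates=replicates, line_means=line_means)


def relative_fitness_from_values(assays: pd.DataFrame) -> RelativeFitness:
    """Wrap an assay table whose values are already on the relative scale.

    No renormalisation is applied (unlike :func:`compute_relative_fitness`,
    which divides by the per-sex maximum).  Intended for data simulated
    directly on the relative-fitness scale, where renormalising would
    rescale the generating variance components by an arbitrary factor.
    """
    replicates = assays[["line", "sex", "replicate", "value"]].rename(
        columns={"value": "rel_value"}
    )

    def _sem(x):
        return x.std(ddof=1) / np.sqrt(len(x)) if len(x) > 1 else 0.0

    line_means = (
        replicates.groupby(["line", "sex"])["rel_value"]
        .agg(rel_fitness="mean", se=_sem, n_reps="size")
        .reset_index()
    )
    return RelativeFitness(replicates=replicates, line_means=line_means)


# ---------------------------------------------------------------------------
# scalar formulas
# ---------------------------------------------------------------------------


def heritability(V_line: float, V_resid: float) -> float:
    """Narrow-sense heritability from hemiclonal variance components.

    A hemiclone line shares one haplotype, so the among-line variance
    estimates half the additive genetic variance; hence the x2 correction:
    h^2 = 2 V_line / (V_line + V_resid).
    """
    if V_line < 0 or V_resid < 0:
        raise ValueError("variance components must be >= 0")
    if V_line == 0 and V_resid == 0:
        raise ValueError("h^2 undefined when both components are zero")
    h2 = 2.0 * V_line / (V_line + V_resid)
    if h2 > 1:
        warnings.warn(f"h^2 = {h2:.3f} exceeds 1", stacklevel=2)
    return h2


def coefficient_of_variation(V: float, mean: float) -> float:
    """CV (%) of a variance component: 100 * sqrt(V) / mean."""
    if mean <= 0:
        raise ValueError("mean must be positive")
    if V < 0:
        raise ValueError("variance must be >= 0")
    return 100.0 * np.sqrt(V) / mean


# ---------------------------------------------------------------------------
# Gibbs sampler
# ---------------------------------------------------------------------------


def _derive_row(mu_f, mu_m, G, vf, vm):
    cov = G[0, 1]
    r = cov / np.sqrt(G[0, 0] * G[1, 1]) if G[0, 0] > 0 and G[1, 1] > 0 else 0.0
    return {
        "mu_f": mu_f,
        "mu_m": mu_m,
        "V_line_f": G[0, 0],
        "V_line_m": G[1, 1],
        "cov_fm": cov,
        "r_MF": r,
        "V_resid_f": vf,
        "V_resid_m": vm,
        "h2_f": 2 * G[0, 0] / (G[0, 0] + vf),
        "h2_m": 2 * G[1, 1] / (G[1, 1] + vm),
        "CV_A_f": 100 * np.sqrt(G[0, 0]) / mu_f,
        "CV_A_m": 100 * np.sqrt(G[1, 1]) / mu_m,
        "CV_R_f": 100 * np.sqrt(vf) / mu_f,
        "CV_R_m": 100 * np.sqrt(vm) / mu_m,
    }


def _effective_sample_size(x: np.ndarray) -> float:
    """ESS via initial-positive-sequence autocorrelation truncation."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 10 or np.var(x) == 0:
        return float(n)
    xc = x - x.mean()
    acf = np.correlate(xc, xc, mode="full")[n - 1 :] / (np.arange(n, 0, -1) * np.var(x))
    s = 0.0
    for k in range(1, min(n // 2, 1000)):
        if acf[k] <= 0:
            break
        s += acf[k]
    return float(n / (1 + 2 * s))


def fit_bivariate_components(
    relfit: RelativeFitness,
    n_iter: int = 20_000,
    burn_in: int = 5_000,
    thin: int = 10,
    n_chains: int = 4,
    seed: int = 0,
    ess_floor: float = 100.0,
    prior_df: float = -1.5,
) -> GeneticArchitecture:
    """Gibbs sampler for the bivariate line-effects mixed model.

    Model: ``y_slr = mu_s + a_sl + e_slr`` with line effects
    ``(a_f, a_m) ~ N2(0, G)`` and sex-specific residual variances.
    Conditionals: normal for the sex means and line effects,
    inverse-Wishart for G (nu0 = 3, near-flat, implying an approximately
    uniform marginal prior on the correlation), scaled inverse-chi-square
    (weak) for the residual variances.

    Returns posterior means and central 95% credible intervals; retained
    draws from all chains are kept on ``.chains``.  A result whose r_MF
    effective sample size falls below ``ess_floor`` is flagged
    (``converged=False``), never silently returned.
    """
    wide = relfit.wide()
    if wide.isna().any().any() or wide.shape[0] < 3:
        raise ValueError("need >= 3 lines assayed in both sexes")
    lines = wide.index.to_numpy()
    L = len(lines)

    # replicate data per sex, grouped by line
    reps = relfit.replicates
    ydata = {}
    for s in SEXES:
        sub = reps[reps["sex"] == s]
        piv = sub.pivot_table(index="line", columns="replicate", values="rel_value")
        piv = piv.loc[lines]
        ydata[s] = piv.to_numpy()  # lines x max_reps, NaN-padded if unbalanced
    nrep = {s: (~np.isnan(ydata[s])).sum(axis=1) for s in SEXES}
    ysum = {s: np.nansum(ydata[s], axis=1) for s in SEXES}
    ntot = {s: int(nrep[s].sum()) for s in SEXES}
    ss_within = {
        s: float(np.nansum(ydata[s] ** 2)) for s in SEXES
    }  # sum y^2, used with sums for residual SS

    # Improper prior p(G) ∝ |G|^(-(prior_df + p + 1)/2) with zero scale: the
    # conditional for G given line effects is IW(prior_df + L, a'a).  The
    # default prior_df = 0 is the Jeffreys-type |G|^(-3/2), which keeps the
    # marginal prior on the correlation flat-ish while avoiding both the
    # singularity-seeking density of a near-zero-scale IW(3, eps*I) prior
    # (which can trap the chain at |r| = 1) and the upward bias that a fully
    # flat p(G) ∝ 1 puts on weakly identified variance components.
    nu0 = float(prior_df)
    Lam0 = np.zeros((2, 2))
    a0, b0 = 1e-3, 1e-3  # residual inverse-gamma prior

    rng_master = np.random.default_rng(seed)
    # lines sharing a replicate-count pattern share a conditional covariance
    pattern_groups: dict[tuple[int, int], np.ndarray] = {}
    for i in range(L):
        pattern_groups.setdefault((int(nrep["F"][i]), int(nrep["M"][i])), []).append(i)
    pattern_groups = {k: np.asarray(v) for k, v in pattern_groups.items()}

    keep_rows = []
    for chain in range(n_chains):
        rng = np.random.default_rng(rng_master.integers(2**31 - 1))
        mu = {s: float(np.nanmean(ydata[s])) for s in SEXES}
        vres = {s: max(float(np.nanvar(ydata[s])), 1e-6) for s in SEXES}
        G = np.eye(2) * 0.01
        a = np.zeros((L, 2))
        for it in range(n_iter):
            # line effects | rest: same posterior covariance whenever the
            # per-line replicate counts match, so solve per count-pattern
            Ginv = np.linalg.inv(G)
            rhs = np.column_stack(
                [
                    (ysum["F"] - nrep["F"] * mu["F"]) / vres["F"],
                    (ysum["M"] - nrep["M"] * mu["M"]) / vres["M"],
                ]
            )
            for (nf_i, nm_i), idx in pattern_groups.items():
                prec = Ginv + np.diag([nf_i / vres["F"], nm_i / vres["M"]])
                Sig = np.linalg.inv(prec)
                chol = np.linalg.cholesky(Sig)
                mean = rhs[idx] @ Sig.T
                a[idx] = mean + rng.standard_normal((len(idx), 2)) @ chol.T
            # sex means | rest (flat prior)
            for s, col in (("F", 0), ("M", 1)):
                resid_mean = (ysum[s].sum() - (nrep[s] * a[:, col]).sum()) / ntot[s]
                mu[s] = rng.normal(resid_mean, np.sqrt(vres[s] / ntot[s]))
            # residual variances | rest
            for s, col in (("F", 0), ("M", 1)):
                fitted = mu[s] + a[:, col]
                rss = (
                    ss_within[s]
                    - 2 * (fitted * ysum[s]).sum()
                    + (nrep[s] * fitted**2).sum()
                )
                vres[s] = 1.0 / rng.gamma(a0 + ntot[s] / 2, 1.0 / (b0 + rss / 2))
            # G | line effects: inverse-Wishart
            S = Lam0 + a.T @ a
            G = stats.invwishart.rvs(df=nu0 + L, scale=S, random_state=rng)
            # numerical floor: keep G invertible for the next sweep
            floor = 1e-12 * max(np.trace(G), 1e-30)
            w, Q = np.linalg.eigh(G)
            if w.min() < floor:
                G = (Q * np.maximum(w, floor)) @ Q.T
            if it >= burn_in and (it - burn_in) % thin == 0:
                keep_rows.append(_derive_row(mu["F"], mu["M"], G, vres["F"], vres["M"]))

    chains = pd.DataFrame(keep_rows)
    post_mean = chains.mean()
    ci = {
        c: (float(chains[c].quantile(0.025)), float(chains[c].quantile(0.975)))
        for c in chains.columns
    }
    ess = _effective_sample_size(chains["r_MF"].to_numpy())
    converged = ess >= ess_floor
    if not converged:
        logger.warning("r_MF effective sample size %.1f below floor %.1f", ess, ess_floor)

    arch = GeneticArchitecture(
        V_line_f=post_mean["V_line_f"],
        V_line_m=post_mean["V_line_m"],
        V_resid_f=post_mean["V_resid_f"],
        V_resid_m=post_mean["V_resid_m"],
        cov_fm=post_mean["cov_fm"],
        r_MF=post_mean["r_MF"],
        h2_f=post_mean["h2_f"],
        h2_m=post_mean["h2_m"],
        CV_A_f=post_mean["CV_A_f"],
        CV_A_m=post_mean["CV_A_m"],
        CV_R_f=post_mean["CV_R_f"],
        CV_R_m=post_mean["CV_R_m"],
        mu_f=post_mean["mu_f"],
        mu_m=post_mean["mu_m"],
        ci=ci,
        chains=chains,
        converged=converged,
        ess_r_MF=ess,
        h2_f_ratio_of_means=2 * post_mean["V_line_f"]
        / (post_mean["V_line_f"] + post_mean["V_resid_f"]),
        h2_m_ratio_of_means=2 * post_mean["V_line_m"]
        / (post_mean["V_line_m"] + post_mean["V_resid_m"]),
    )
    return arch


# ---------------------------------------------------------------------------
# ANOVA / moment oracle
# ---------------------------------------------------------------------------


def reml_anova_components(relfit: RelativeFitness) -> GeneticArchitecture:
    """Deterministic moment estimator on balanced designs.

    Per sex, a one-way random-effects ANOVA gives
    ``V_line = (MS_line - MS_resid) / r`` (floored at zero) and
    ``V_resid = MS_resid``; the cross-sex covariance is the sample
    covariance of the line means, which is unbiased for the genetic
    covariance because residuals are independent between sexes.
    Point estimates only; serves as an independent oracle for the
    Gibbs sampler.
    """
    counts = relfit.line_means.pivot(index="line", columns="sex", values="n_reps")
    if counts.isna().any().any():
        raise ValueError("every line must be assayed in both sexes")
    est = {}
    for s in SEXES:
        if counts[s].nunique() != 1:
            raise ValueError(
                f"unbalanced replicates for sex {s!r}; use fit_bivariate_components"
            )
        r = int(counts[s].iloc[0])
        sub = relfit.replicates[relfit.replicates["sex"] == s]
        grand = sub["rel_value"].mean()
        means = sub.groupby("line")["rel_value"].mean()
        k = len(means)
        if r > 1:
            ss_within = ((sub["rel_value"] - sub["line"].map(means)) ** 2).sum()
            ms_resid = ss_within / (k * (r - 1))
        else:
            ms_resid = 0.0
        ms_line = r * ((means - grand) ** 2).sum() / (k - 1)
        est[s] = {
            "mu": grand,
            "V_line": max((ms_line - ms_resid) / r, 0.0),
            "V_resid": ms_resid,
            "means": means,
        }
    wide = relfit.wide()
    cov_fm = float(np.cov(wide["F"], wide["M"], ddof=1)[0, 1])
    vf, vm = est["F"]["V_line"], est["M"]["V_line"]
    r_MF = cov_fm / np.sqrt(vf * vm) if vf > 0 and vm > 0 else np.nan
    return GeneticArchitecture(
        V_line_f=vf,
        V_line_m=vm,
        V_resid_f=est["F"]["V_resid"],
        V_resid_m=est["M"]["V_resid"],
        cov_fm=cov_fm,
        r_MF=r_MF,
        h2_f=2 * vf / (vf + est["F"]["V_resid"]) if vf + est["F"]["V_resid"] > 0 else np.nan,
        h2_m=2 * vm / (vm + est["M"]["V_resid"]) if vm + est["M"]["V_resid"] > 0 else np.nan,
        CV_A_f=coefficient_of_variation(vf, est["F"]["mu"]),
        CV_A_m=coefficient_of_variation(vm, est["M"]["mu"]),
        CV_R_f=coefficient_of_variation(est["F"]["V_resid"], est["F"]["mu"]),
        CV_R_m=coefficient_of_variation(est["M"]["V_resid"], est["M"]["mu"]),
        mu_f=est["F"]["mu"],
        mu_m=est["M"]["mu"],
        chains=None,
    )


# ---------------------------------------------------------------------------
# line selection
# ---------------------------------------------------------------------------


@dataclass
class LineSelection:
    """The 15 lines chosen for expression profiling."""

    high_m_low_f: list
    low_m_high_f: list
    average: list
    ranks: pd.DataFrame  # line, rank_f, rank_m, score, pooled_se, eligible

    @property
    def all_lines(self) -> list:
        return list(self.high_m_low_f) + list(self.low_m_high_f) + list(self.average)


def select_lines(
    relfit: RelativeFitness,
    k_extreme: int = 5,
    k_mid: int = 5,
    se_filter: bool = True,
) -> LineSelection:
    """Pick hyper-dispersed, low-noise lines by sex-specific fitness rank.

    Lines are ranked per sex (ascending, average ranks for ties).  The
    antagonism score is ``rank_m - rank_f``.  Lines in the top quartile of
    pooled replicate SE are excluded first (the "low variance" filter);
    among the rest the top ``k_extreme`` scores form the high-male/
    low-female group, the bottom ``k_extreme`` the low-male/high-female
    group, and the ``k_mid`` lines minimising
    ``|rank_m - median| + |rank_f - median|`` the average group.  If the
    filter leaves fewer than the required lines it is relaxed stepwise
    with a warning.
    """
    wide = relfit.wide().dropna()
    se = relfit.line_means.pivot(index="line", columns="sex", values="se").loc[wide.index]
    ranks = pd.DataFrame(
        {
            "rank_f": stats.rankdata(wide["F"]),
            "rank_m": stats.rankdata(wide["M"]),
        },
        index=wide.index,
    )
    ranks["score"] = ranks["rank_m"] - ranks["rank_f"]
    ranks["pooled_se"] = np.sqrt(se["F"] ** 2 + se["M"] ** 2)

    need = 2 * k_extreme + k_mid
    if len(ranks) < need:
        raise ValueError(f"need >= {need} lines assayed in both sexes")

    quantiles = (0.75, 0.85, 0.95, 1.01) if se_filter else (1.01,)
    for q in quantiles:
        # absolute tolerance keeps the filter inert on (near-)noiseless data
        cutoff = ranks["pooled_se"].quantile(q) + 1e-12 if q <= 1 else np.inf
        eligible = ranks[ranks["pooled_se"] <= cutoff]
        if len(eligible) >= need:
            if se_filter and q > 0.75:
                warnings.warn(
                    f"low-variance filter relaxed to quantile {q} to retain "
                    f"{need} eligible lines",
                    stacklevel=2,
                )
            break
    ranks["eligible"] = ranks.index.isin(eligible.index)

    # deterministic tie-breaking: sort by (key, line id)
    by_score = eligible.sort_values(
        ["score"], kind="mergesort"
    )
    high_m_low_f = list(by_score.index[-k_extreme:][::-1])
    low_m_high_f = list(by_score.index[:k_extreme])
    med = (len(ranks) + 1) / 2.0
    rest = eligible.drop(index=high_m_low_f + low_m_high_f)
    mid_key = (rest["rank_m"] - med).abs() + (rest["rank_f"] - med).abs()
    average = list(mid_key.sort_values(kind="mergesort").index[:k_mid])

    return LineSelection(
        high_m_low_f=high_m_low_f,
        low_m_high_f=low_m_high_f,
        average=average,
        ranks=ranks.reset_index(),
    )
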