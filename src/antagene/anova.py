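"""Per-transcript variance partitioning: Y = B + S + L + S x L + e.

Each transcript's log2 expression is decomposed with a linear mixed model
holding a fixed sex effect (S), random batch (B), random line (L) and
random sex-by-line interaction (S x L) terms.  Variance components are
estimated by REML (boundary at zero allowed) on a profiled-likelihood
surface; likelihood-ratio tests for the random terms refit by maximum
likelihood and are referred to the boundary mixture 0.5*chi2_0 +
0.5*chi2_1, and the fixed sex effect is tested by an ML likelihood ratio
against chi2_1 (a Wald variant is available).  P values are converted to
q values with the Benjamini-Hochberg step-up, and transcripts are classed
as male-/female-biased when significant and at least ``log2_threshold``
apart in mean expression.

The likelihood machinery handles arbitrary incidence matrices: with
V = sigma2_e * (I + sum_k gamma_k Z_k Z_k'), the residual variance is
profiled out and the Woodbury identity reduces every evaluation to a
q x q factorisation, q = total number of random-effect levels.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

_LOG2PI = np.log(2 * np.pi)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------


def _indicator(codes: pd.Series) -> np.ndarray:
    levels = pd.unique(codes)
    Z = np.zeros((len(codes), len(levels)))
    lut = {l: j for j, l in enumerate(levels)}
    for i, c in enumerate(codes):
        Z[i, lut[c]] = 1.0
    return Z


@dataclass
class MixedDesign:
    """Fixed-effects matrix X plus named random-effect incidence blocks."""

    X: np.ndarray
    Z_blocks: dict[str, np.ndarray]

    def __post_init__(self):
        self.n, self.p = self.X.shape
        self._logdet_XtX = np.linalg.slogdet(self.X.T @ self.X)[1]

    def drop_random(self, name: str) -> "MixedDesign":
        return MixedDesign(self.X, {k: v for k, v in self.Z_blocks.items() if k != name})

    def drop_fixed_column(self, col: int) -> "MixedDesign":
        return MixedDesign(np.delete(self.X, col, axis=1), dict(self.Z_blocks))


def expression_design(samples: pd.DataFrame) -> MixedDesign:
    """Build the S + B + L + SxL design from a sample sheet.

    X = [intercept, male indicator]; random blocks: batch, line, and the
    sex-by-line cell.  The male indicator is column 1 of X.
    """
    male = (samples["sex"] == "M").to_numpy(float)
    X = np.column_stack([np.ones(len(samples)), male])
    Z = {
        "batch": _indicator(samples["batch"]),
        "line": _indicator(samples["line"]),
        "sexline": _indicator(samples["sex"].astype(str) + ":" + samples["line"].astype(str)),
    }
    return MixedDesign(X, Z)


# ---------------------------------------------------------------------------
# profiled likelihood
# ---------------------------------------------------------------------------


@dataclass
class MixedFit:
    """One converged (or best-found) mixed-model fit."""

    loglik: float
    method: str  # "REML" or "ML"
    variances: dict[str, float]  # per random block, on the data scale
    sigma2_e: float
    beta: np.ndarray
    beta_cov: np.ndarray
    converged: bool
    gamma: dict[str, float]


class _Profile:
    """Profiled likelihood for one (design, y) pair.

    Design-level quantities (Z'Z, Z'X, X'X) are cached on the design so
    that fitting thousands of transcripts against one design only pays
    for the per-response projections.
    """

    def __init__(self, design: MixedDesign, y: np.ndarray):
        self.design = design
        cache = getattr(design, "_profile_cache", None)
        if cache is None:
            names = list(design.Z_blocks)
            sizes = [design.Z_blocks[k].shape[1] for k in names]
            Zs = [design.Z_blocks[k] for k in names]
            Z = np.hstack(Zs) if Zs else np.zeros((design.n, 0))
            cache = {
                "names": names,
                "sizes": np.asarray(sizes, dtype=int),
                "expand": np.repeat(np.arange(len(names)), sizes)
                if names else np.zeros(0, dtype=int),
                "Z": Z,
                "ZtZ": Z.T @ Z,
                "ZtX": Z.T @ design.X,
                "XtX": design.X.T @ design.X,
            }
            design._profile_cache = cache
        self.names = cache["names"]
        self.sizes = cache["sizes"]
        self._expand = cache["expand"]
        self.Z = cache["Z"]
        self.ZtZ = cache["ZtZ"]
        self.ZtX = cache["ZtX"]
        self.XtX = cache["XtX"]
        self.Zty = self.Z.T @ y
        self.Xty = design.X.T @ y
        self.yty = float(y @ y)
        self.n, self.p = design.n, design.p

    def _gamma_vec(self, gamma: np.ndarray) -> np.ndarray:
        return gamma[self._expand]

    def core(self, gamma: np.ndarray):
        """Return (logdetW, XtWiX, XtWiy, ytWiy)."""
        if self.Z.shape[1] == 0 or np.all(gamma <= 0):
            return 0.0, self.XtX.copy(), self.Xty.copy(), self.yty
        s = np.sqrt(self._gamma_vec(np.maximum(gamma, 0.0)))
        A = np.eye(len(s)) + (s[:, None] * self.ZtZ) * s[None, :]
        cF, low = np.linalg.cholesky(A), True
        logdetW = 2.0 * np.log(np.diag(cF)).sum()
        SZtX = s[:, None] * self.ZtX
        SZty = s * self.Zty
        u = np.linalg.solve(cF, np.column_stack([SZtX, SZty]))
        XtWiX = self.XtX - u[:, : self.p].T @ u[:, : self.p]
        XtWiy = self.Xty - u[:, : self.p].T @ u[:, self.p]
        ytWiy = self.yty - float(u[:, self.p] @ u[:, self.p])
        return logdetW, XtWiX, XtWiy, ytWiy

    def loglik(self, gamma: np.ndarray, method: str):
        logdetW, XtWiX, XtWiy, ytWiy = self.core(gamma)
        cX = np.linalg.cholesky(XtWiX)
        v = np.linalg.solve(cX, XtWiy)
        rss = max(ytWiy - float(v @ v), 1e-300)
        logdet_XtWiX = 2.0 * np.log(np.diag(cX)).sum()
        if method == "REML":
            df = self.n - self.p
            s2 = rss / df
            ll = -0.5 * (
                df * (_LOG2PI + np.log(s2))
                + logdetW
                + logdet_XtWiX
                - self.design._logdet_XtX
                + df
            )
        else:
            s2 = rss / self.n
            ll = -0.5 * (self.n * (_LOG2PI + np.log(s2)) + logdetW + self.n)
        return ll, s2

    def negloglik_grad(self, theta: np.ndarray, method: str):
        """-loglik and its gradient w.r.t. theta = log gamma.

        Uses the profiled REML/ML scores: with e the GLS residual,
        d rss/d gamma_k = -||Zk' W^-1 e||^2,
        d log|W|/d gamma_k = tr(Zk' W^-1 Zk), and
        d log|X'W^-1 X|/d gamma_k = -tr((X'W^-1X)^-1 (X'W^-1Zk)(Zk'W^-1X)).
        """
        from scipy.linalg import cho_solve, solve_triangular

        gamma = np.exp(theta)
        gv = self._gamma_vec(gamma)
        s = np.sqrt(gv)
        q = len(s)
        A = np.eye(q) + (s[:, None] * self.ZtZ) * s[None, :]
        cF = np.linalg.cholesky(A)
        rhs = np.column_stack([self.ZtX, self.Zty[:, None], self.ZtZ]) * s[:, None]
        U = solve_triangular(cF, rhs, lower=True)
        UX, Uy, UZ = U[:, : self.p], U[:, self.p], U[:, self.p + 1 :]
        XtWiX = self.XtX - UX.T @ UX
        XtWiy = self.Xty - UX.T @ Uy
        ytWiy = self.yty - float(Uy @ Uy)
        ZtWiZ = self.ZtZ - UZ.T @ UZ
        ZtWiX = self.ZtX - UZ.T @ UX
        ZtWiy = self.Zty - UZ.T @ Uy
        cX = np.linalg.cholesky(XtWiX)
        v = solve_triangular(cX, XtWiy, lower=True)
        rss = max(ytWiy - float(v @ v), 1e-300)
        beta = cho_solve((cX, True), XtWiy)
        ZtWie = ZtWiy - ZtWiX @ beta
        logdetW = 2.0 * np.log(np.diag(cF)).sum()
        logdet_XtWiX = 2.0 * np.log(np.diag(cX)).sum()

        # per-block reductions
        diagZ = np.diag(ZtWiZ)
        nb = len(self.names)
        tr_k = np.zeros(nb)
        q_k = np.zeros(nb)
        x_k = np.zeros(nb)
        Gx = cho_solve((cX, True), ZtWiX.T)  # p x q
        xcontrib = np.einsum("jp,pj->j", ZtWiX, Gx)
        np.add.at(tr_k, self._expand, diagZ)
        np.add.at(q_k, self._expand, ZtWie**2)
        np.add.at(x_k, self._expand, xcontrib)

        df = self.n - self.p
        if method == "REML":
            s2 = rss / df
            ll = -0.5 * (
                df * (_LOG2PI + np.log(s2)) + logdetW + logdet_XtWiX
                - self.design._logdet_XtX + df
            )
            dll = -0.5 * (tr_k - x_k - df * q_k / rss)
        else:
            s2 = rss / self.n
            ll = -0.5 * (self.n * (_LOG2PI + np.log(s2)) + logdetW + self.n)
            dll = -0.5 * (tr_k - self.n * q_k / rss)
        return -ll, -dll * gamma

    def beta(self, gamma: np.ndarray, s2: float):
        _, XtWiX, XtWiy, _ = self.core(gamma)
        cov = np.linalg.inv(XtWiX) * s2
        return np.linalg.solve(XtWiX, XtWiy), cov


def _mom_start(prof: _Profile, y: np.ndarray) -> np.ndarray:
    """Method-of-moments starting gammas from OLS residual group means."""
    X = prof.design.X
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    s2 = max(float(resid @ resid) / max(len(y) - X.shape[1], 1), 1e-12)
    out = []
    for name in prof.names:
        Z = prof.design.Z_blocks[name]
        cnt = Z.sum(axis=0)
        means = (Z.T @ resid) / np.maximum(cnt, 1)
        vb = float(np.var(means, ddof=1)) if len(means) > 1 else 0.0
        out.append(max(vb - s2 / max(cnt.mean(), 1.0), 1e-4 * s2) / s2)
    return np.asarray(out)


def fit_mixed_model(
    design: MixedDesign,
    y: np.ndarray,
    method: str = "REML",
    tol: float = 1e-14,
    start: dict[str, float] | None = None,
) -> MixedFit:
    """Estimate variance components for one response vector.

    Variance ratios gamma_k = sigma2_k / sigma2_e are optimised on a log
    scale (quasi-Newton) with the residual variance profiled out.  The
    default start is method-of-moments; ``start`` supplies warm-start
    ratios (e.g. from a related fit).  If the warm/MoM run fails to
    converge, two fallback starts are tried.  Non-convergence is flagged
    on the returned fit, which then carries the best values found.
    """
    y = np.asarray(y, float)
    prof = _Profile(design, y)
    k = len(prof.names)
    if k == 0:
        ll, s2 = prof.loglik(np.zeros(0), method)
        beta, cov = prof.beta(np.zeros(0), s2)
        return MixedFit(ll, method, {}, s2, beta, cov, True, {})

    lb, ub = -30.0, 12.0

    def neg(theta):
        return prof.negloglik_grad(theta, method)

    if start is not None:
        x0 = np.log(np.maximum(
            [start.get(name, 0.1) for name in prof.names], 1e-10))
    else:
        x0 = np.log(np.maximum(_mom_start(prof, y), 1e-8))
    def _accept(res) -> bool:
        # L-BFGS-B can stop with an "abnormal line search" flag when the
        # numeric floor is reached; a tiny projected gradient means we are
        # at the optimum regardless of the reported status
        if res.success:
            return True
        proj = np.where(
            ((res.x <= lb + 1e-9) & (res.jac > 0))
            | ((res.x >= ub - 1e-9) & (res.jac < 0)),
            0.0, res.jac,
        )
        return bool(np.max(np.abs(proj)) < 1e-5)

    # fallback starts (near-boundary, then mid-range) only run when the
    # primary start fails to reach an acceptable optimum
    best = None
    ok = False
    for x in (x0, np.full(k, -10.0), np.full(k, np.log(0.1))):
        res = optimize.minimize(
            neg,
            np.clip(x, lb, ub),
            jac=True,
            method="L-BFGS-B",
            bounds=[(lb, ub)] * k,
            options={"ftol": tol, "gtol": 1e-12, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        ok = ok or _accept(res)
        if ok:
            break
    if not ok:
        logger.warning("mixed-model optimiser did not converge; best values kept")
    gamma = np.exp(best.x)
    # snap effectively-boundary ratios to exactly zero
    gamma[gamma < 1e-10] = 0.0
    ll, s2 = prof.loglik(gamma, method)
    beta, cov = prof.beta(gamma, s2)
    variances = {name: float(g * s2) for name, g in zip(prof.names, gamma)}
    return MixedFit(float(ll), method, variances, float(s2), beta, cov, ok,
                    dict(zip(prof.names, gamma)))


def restricted_loglik(design: MixedDesign, y: np.ndarray,
                      variances: dict[str, float], sigma2_e: float) -> float:
    """Restricted log-likelihood at given components (for checks/oracles)."""
    prof = _Profile(design, np.asarray(y, float))
    gamma = np.array([variances[k] / sigma2_e for k in prof.names])
    logdetW, XtWiX, XtWiy, ytWiy = prof.core(gamma)
    cX = np.linalg.cholesky(XtWiX)
    v = np.linalg.solve(cX, XtWiy)
    rss = ytWiy - float(v @ v)
    df = prof.n - prof.p
    return -0.5 * (
        df * (_LOG2PI + np.log(sigma2_e))
        + logdetW
        + 2 * np.log(np.diag(cX)).sum()
        - design._logdet_XtX
        + rss / sigma2_e
    )


# ---------------------------------------------------------------------------
# tests and classification
# ---------------------------------------------------------------------------


def mixture_lrt_pvalue(lrt_stat):
    """Boundary-null p value: 0.5*chi2_0 + 0.5*chi2_1 mixture.

    For a variance component tested against zero the null value lies on
    the boundary of the parameter space, so the LRT statistic is a 50:50
    mixture of a point mass at zero and chi-square with 1 df.  Statistics
    <= 0 map to p = 1 (conservative convention).
    """
    stat = np.asarray(lrt_stat, float)
    p = np.where(stat > 0, 0.5 * stats.chi2.sf(stat, df=1), 1.0)
    return float(p) if np.isscalar(lrt_stat) else p


def sex_effect_test(ll_full: float, ll_nosex: float) -> tuple[float, float]:
    """ML likelihood-ratio test of the fixed sex effect against chi2_1."""
    lrt = 2.0 * (ll_full - ll_nosex)
    if lrt < 0:
        warnings.warn("reduced-model likelihood exceeded full; statistic floored at 0",
                      stacklevel=2)
        lrt = 0.0
    return lrt, float(stats.chi2.sf(lrt, df=1)) if lrt > 0 else 1.0


def classify_sex_bias(mean_m, mean_f, q_sex, alpha: float = 0.001,
                      log2_threshold: float = 1.0):
    """Label a transcript male-/female-biased or unbiased.

    Biased requires significance (q < alpha) AND an absolute log2 mean
    difference of at least ``log2_threshold`` (2-fold by default).
    """
    diff = np.asarray(mean_m, float) - np.asarray(mean_f, float)
    sig = np.asarray(q_sex, float) < alpha
    out = np.where(sig & (diff >= log2_threshold), "male_biased",
                   np.where(sig & (diff <= -log2_threshold), "female_biased",
                            "unbiased"))
    return str(out) if out.ndim == 0 else out


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q values.

    q_(i) = min_{j >= i} p_(j) * n / j, capped at 1.  NaN entries are
    propagated as NaN (with a logged count) and excluded from n.
    """
    p = np.asarray(pvalues, float)
    q = np.full_like(p, np.nan)
    valid = ~np.isnan(p)
    n_nan = int((~valid).sum())
    if n_nan:
        logger.warning("bh_fdr: %d NaN p values propagated", n_nan)
    pv = p[valid]
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p values must lie in [0, 1]")
    n = len(pv)
    if n:
        order = np.argsort(pv, kind="mergesort")
        ranked = pv[order] * n / np.arange(1, n + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        out = np.empty(n)
        out[order] = np.minimum(qv, 1.0)
        q[valid] = out
    return q


# ---------------------------------------------------------------------------
# per-study driver
# ---------------------------------------------------------------------------


def run_anova(
    matrix: pd.DataFrame,
    samples: pd.DataFrame,
    alpha: float = 0.001,
    log2_threshold: float = 1.0,
    sex_test: str = "lrt",
) -> pd.DataFrame:
    """Fit the mixed model to every transcript and assemble results.

    Returns one row per transcript: REML variance components, the sex
    fixed effect, mixture-LRT p/q for line and sex-by-line, the sex-effect
    p/q, the log2 male-female difference and the sex-bias class.
    """
    samples = samples.set_index("sample_id").loc[matrix.columns].reset_index()
    design = expression_design(samples)
    design_nosex = design.drop_fixed_column(1)
    male = samples["sex"].to_numpy() == "M"

    rows = []
    for tid, y in matrix.iterrows():
        yv = y.to_numpy(float)
        reml = fit_mixed_model(design, yv, "REML")
        full_ml = fit_mixed_model(design, yv, "ML", start=reml.gamma)
        noline = fit_mixed_model(design.drop_random("line"), yv, "ML",
                                 start=full_ml.gamma)
        nosl = fit_mixed_model(design.drop_random("sexline"), yv, "ML",
                               start=full_ml.gamma)
        lrt_line = max(2 * (full_ml.loglik - noline.loglik), 0.0)
        lrt_sl = max(2 * (full_ml.loglik - nosl.loglik), 0.0)
        if sex_test == "wald":
            z = full_ml.beta[1] / np.sqrt(full_ml.beta_cov[1, 1])
            p_sex = 2 * stats.norm.sf(abs(z))
        else:
            nosex = fit_mixed_model(design_nosex, yv, "ML", start=full_ml.gamma)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, p_sex = sex_effect_test(full_ml.loglik, nosex.loglik)
        rows.append(
            {
                "transcript": tid,
                "var_batch": reml.variances.get("batch", 0.0),
                "var_line": reml.variances.get("line", 0.0),
                "var_sexline": reml.variances.get("sexline", 0.0),
                "var_resid": reml.sigma2_e,
                "sex_effect": reml.beta[1],
                "mean_m": float(yv[male].mean()),
                "mean_f": float(yv[~male].mean()),
                "lrt_line": lrt_line,
                "lrt_sexline": lrt_sl,
                "p_line": mixture_lrt_pvalue(lrt_line),
                "p_sexline": mixture_lrt_pvalue(lrt_sl),
                "p_sex": p_sex,
                "converged": reml.converged and full_ml.converged,
            }
        )
    res = pd.DataFrame(rows)
    res["log2_diff"] = res["mean_m"] - res["mean_f"]
    for term in ("line", "sexline", "sex"):
        res[f"q_{term}"] = bh_fdr(res[f"p_{term}"].to_numpy())
    res["sex_bias_class"] = classify_sex_bias(
        res["mean_m"].to_numpy(), res["mean_f"].to_numpy(),
        res["q_sex"].to_numpy(), alpha, log2_threshold
    )
    return res
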