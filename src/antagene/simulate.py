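"""Synthetic data generators with planted, recorded ground truth.

The generators emulate the structure of a hemiclone fitness study and its
companion expression experiment: 100 hemiclonal lines assayed for adult
fitness in both sexes (6 male replicates of competitive fertilisation
success, 4 female replicates of competitive fecundity), a 2 sexes x 15
lines x 4 replicates = 120-array expression study processed in 8 batches
of 15, a 17-tissue expression atlas with a whole-organism baseline column,
and cytological-band / GO-style annotation maps.  Every planted effect is
recorded in a :class:`TruthLabels` object so downstream discoveries can be
scored as true or false positives with no unlabelled entity.

All generators are deterministic given their config and seed.
"""

from __future__ import annotations

import logging
import string
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CHROMOSOME_ARMS = ("X", "2L", "2R", "3L", "3R", "4")
SUB_BANDS = tuple(string.ascii_uppercase[:6])  # A-F


class ConfigurationError(ValueError):
    """Raised when a simulation config violates its invariants."""


# ---------------------------------------------------------------------------
# configs and truth containers
# ---------------------------------------------------------------------------


@dataclass
class FitnessSimConfig:
    """Generating parameters for a two-sex hemiclone fitness assay.

    Defaults are the components of the study design this package targets:
    100 lines, 6 male / 4 female replicates, and genetic/residual variances
    on the relative-fitness scale with an intersexual genetic correlation
    of -0.52.  Mean relative fitness defaults (0.39 female, 0.34 male) are
    back-computed from the published coefficients of variation.
    """

    n_lines: int = 100
    V_line_f: float = 0.0070
    V_line_m: float = 0.0014
    r_MF_true: float = -0.52
    V_resid_f: float = 0.0153
    V_resid_m: float = 0.0222
    mu_f: float = 0.39
    mu_m: float = 0.34
    male_reps: int = 6
    female_reps: int = 4
    obs_model: str = "gaussian"  # or "counts"
    offspring_per_female: int = 40
    females_per_vial: int = 15
    seed: int = 0

    def validate(self) -> None:
        for name in ("V_line_f", "V_line_m", "V_resid_f", "V_resid_m"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if abs(self.r_MF_true) > 1:
            raise ConfigurationError("|r_MF_true| must be <= 1")
        if self.obs_model not in ("gaussian", "counts"):
            raise ConfigurationError(f"unknown obs_model {self.obs_model!r}")
        if self.n_lines < 1 or self.male_reps < 1 or self.female_reps < 1:
            raise ConfigurationError("n_lines and replicate counts must be >= 1")
        if not (0 < self.mu_f <= 1 and 0 < self.mu_m <= 1):
            raise ConfigurationError("mean relative fitness must lie in (0, 1]")
        G = self.line_covariance()
        if np.linalg.eigvalsh(G).min() < -1e-12:
            raise ConfigurationError("implied line covariance is not PSD")

    def line_covariance(self) -> np.ndarray:
        """2x2 genetic (among-line) covariance matrix, order (female, male)."""
        cov = self.r_MF_true * np.sqrt(self.V_line_f * self.V_line_m)
        return np.array([[self.V_line_f, cov], [cov, self.V_line_m]])


@dataclass
class ExpressionSimConfig:
    """Generating parameters for the 120-array expression study.

    Scales are log2 throughout (RMA-style normalised intensities).  The
    fractions plant per-transcript effects: a sex main effect, among-line
    variance, sex-by-line interaction variance, a fitness slope shared by
    the sexes, or a sexually antagonistic pair of opposite-signed
    sex-specific fitness slopes.  Defaults mirror the fractions the target
    study reported (91.5% sex, 27.3% line, 11.3% interaction) with 10%
    antagonistic and 5% concordantly fitness-associated transcripts.
    """

    n_transcripts: int = 2000
    n_lines: int = 15
    reps: int = 4
    n_batches: int = 8
    # line-level random variation is kept small relative to residual noise
    # (variance ratio ~1.4%): the sample-level least-squares regression
    # treats arrays as exchangeable given the fixed effects, and its null
    # calibration (permutation null, FDR control) presumes line-level
    # dependence is negligible for null transcripts
    sd_batch: float = 0.10
    sd_line: float = 0.03
    sd_interaction: float = 0.03
    sd_resid: float = 0.25
    frac_sex_biased: float = 0.90
    frac_line_variable: float = 0.27
    frac_interaction: float = 0.11
    frac_fitness_assoc: float = 0.05
    frac_antagonistic: float = 0.10
    sex_effect_sd: float = 1.5
    fitness_slope_range: tuple[float, float] = (1.0, 2.0)
    antagonistic_slope_range: tuple[float, float] = (1.0, 2.0)
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return 2 * self.n_lines * self.reps

    def validate(self) -> None:
        for name in (
            "frac_sex_biased",
            "frac_line_variable",
            "frac_interaction",
            "frac_fitness_assoc",
            "frac_antagonistic",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ConfigurationError(f"{name} must lie in [0, 1]")
        if self.frac_fitness_assoc + self.frac_antagonistic > 1:
            raise ConfigurationError(
                "fitness-associated and antagonistic fractions must not overlap"
            )
        if self.n_samples % self.n_batches:
            raise ConfigurationError(
                f"{self.n_samples} samples cannot be split into "
                f"{self.n_batches} equal batches"
            )
        for name in ("sd_batch", "sd_line", "sd_interaction", "sd_resid"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")


@dataclass
class TruthLabels:
    """Planted ground truth for one simulated dataset.

    Only the fields relevant to the generator that produced the object are
    populated; the rest stay ``None``.
    """

    line_effects: pd.DataFrame | None = None  # line, a_f, a_m
    transcripts: pd.DataFrame | None = None  # per-transcript flags + coefficients
    tissue_specific: Mapping[str, set[str]] | None = None  # tissue -> genes
    unexpressed_genes: set[str] | None = None
    enriched_terms: set[str] | None = None
    interest_set: set[str] | None = None
    n_clipped: int = 0
    extras: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# fitness study
# ---------------------------------------------------------------------------


def simulate_fitness_study(cfg: FitnessSimConfig) -> tuple[pd.DataFrame, TruthLabels]:
    """Simulate a two-sex hemiclone fitness assay.

    Per-line genetic effects ``(a_f, a_m)`` are drawn from a zero-mean
    bivariate normal with the configured variances and correlation; each
    replicate observation adds sex-specific residual noise to
    ``mu_sex + a_sex``.  Under ``obs_model="counts"`` male replicate values
    become binomial sired/total offspring counts and female values integer
    progeny counts, with the underlying proportion clipped to [0.01, 0.99]
    (clip events are counted on the returned truth).

    Returns
    -------
    (assays, truth)
        ``assays`` has columns ``line, sex, replicate, value`` plus
        ``sired, total`` under the counts model; ``truth.line_effects``
        records the drawn genetic effects.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    lines = [f"L{i + 1:03d}" for i in range(cfg.n_lines)]

    G = cfg.line_covariance()
    a = rng.multivariate_normal(np.zeros(2), G, size=cfg.n_lines, method="eigh")
    truth = TruthLabels(
        line_effects=pd.DataFrame({"line": lines, "a_f": a[:, 0], "a_m": a[:, 1]})
    )

    records = []
    n_clipped = 0
    for sex, col, mu, v_res, reps in (
        ("F", 0, cfg.mu_f, cfg.V_resid_f, cfg.female_reps),
        ("M", 1, cfg.mu_m, cfg.V_resid_m, cfg.male_reps),
    ):
        latent = mu + a[:, col][:, None] + rng.normal(
            0.0, np.sqrt(v_res), size=(cfg.n_lines, reps)
        )
        for i, line in enumerate(lines):
            for r in range(reps):
                y = latent[i, r]
                if cfg.obs_model == "gaussian":
                    v = float(np.clip(y, 0.0, 1.0))
                    n_clipped += v != y
                    records.append((line, sex, r + 1, v, np.nan, np.nan))
                elif sex == "M":
                    p = float(np.clip(y, 0.01, 0.99))
                    n_clipped += p != y
                    total = cfg.offspring_per_female * cfg.females_per_vial
                    sired = int(rng.binomial(total, p))
                    records.append((line, sex, r + 1, sired / total, sired, total))
                else:
                    lam = max(y, 0.01) * cfg.offspring_per_female
                    n_clipped += lam != y * cfg.offspring_per_female
                    count = int(rng.poisson(lam))
                    records.append((line, sex, r + 1, float(count), np.nan, np.nan))

    assays = pd.DataFrame(
        records, columns=["line", "sex", "replicate", "value", "sired", "total"]
    )
    if cfg.obs_model == "gaussian":
        assays = assays.drop(columns=["sired", "total"])
    truth.n_clipped = int(n_clipped)
    if n_clipped:
        logger.warning("clipped %d replicate values to their valid support", n_clipped)
    return assays, truth


# ---------------------------------------------------------------------------
# expression study
# ---------------------------------------------------------------------------


def _assign_batches(sample_ids: Sequence[str], n_batches: int, rng) -> pd.Series:
    """Shuffle samples once, then split into consecutive equal blocks.

    This decouples batch from sex and line by construction.
    """
    order = rng.permutation(len(sample_ids))
    block = len(sample_ids) // n_batches
    batch = np.empty(len(sample_ids), dtype=int)
    for b in range(n_batches):
        batch[order[b * block : (b + 1) * block]] = b + 1
    return pd.Series(batch, index=sample_ids, name="batch")


def simulate_expression_study(
    cfg: ExpressionSimConfig, fitness: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLabels]:
    """Simulate a two-sex, multi-line expression study with fitness slopes.

    Parameters
    ----------
    cfg
        Generating parameters.
    fitness
        Long table ``line, sex, fitness`` giving the sex-specific line
        relative fitness used as the covariate F; must cover every
        (line, sex) cell of the design exactly once.

    Returns
    -------
    (matrix, samples, truth)
        ``matrix`` is transcripts x samples on log2 scale, ``samples`` the
        sample sheet (sample_id, sex, line, batch, replicate), ``truth``
        records every planted per-transcript effect.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    fit = fitness.set_index(["line", "sex"])["fitness"]
    lines = sorted(fitness["line"].unique())
    if len(lines) != cfg.n_lines:
        raise ConfigurationError(
            f"fitness covers {len(lines)} lines, config expects {cfg.n_lines}"
        )
    for line in lines:
        for sex in ("F", "M"):
            if (line, sex) not in fit.index:
                raise ConfigurationError(f"missing fitness for line {line} sex {sex}")

    samples = pd.DataFrame(
        [
            (f"{sex}_{line}_r{r + 1}", sex, line, r + 1)
            for sex in ("F", "M")
            for line in lines
            for r in range(cfg.reps)
        ],
        columns=["sample_id", "sex", "line", "replicate"],
    )
    samples["batch"] = _assign_batches(
        samples["sample_id"].tolist(), cfg.n_batches, rng
    ).to_numpy()
    samples["fitness"] = [
        fit[(line, sex)] for line, sex in zip(samples["line"], samples["sex"])
    ]

    n, g = len(samples), cfg.n_transcripts
    male = (samples["sex"] == "M").to_numpy(float)
    F = samples["fitness"].to_numpy()
    line_idx = samples["line"].map({l: i for i, l in enumerate(lines)}).to_numpy()
    batch_idx = samples["batch"].to_numpy() - 1
    cell_idx = line_idx * 2 + male.astype(int)  # sex-by-line cell

    # disjoint planting of fitness-slope classes; other flags independent
    n_ant = int(round(cfg.frac_antagonistic * g))
    n_fit = int(round(cfg.frac_fitness_assoc * g))
    perm = rng.permutation(g)
    ant_ids = np.zeros(g, bool)
    fit_ids = np.zeros(g, bool)
    ant_ids[perm[:n_ant]] = True
    fit_ids[perm[n_ant : n_ant + n_fit]] = True
    sex_ids = rng.random(g) < cfg.frac_sex_biased
    line_ids = rng.random(g) < cfg.frac_line_variable
    int_ids = rng.random(g) < cfg.frac_interaction

    baseline = rng.normal(cfg.baseline_mean, cfg.baseline_sd, g)
    sex_eff = np.where(sex_ids, rng.normal(0.0, cfg.sex_effect_sd, g), 0.0)

    lo, hi = cfg.fitness_slope_range
    sign = rng.choice([-1.0, 1.0], g)
    shared = np.where(fit_ids, sign * rng.uniform(lo, hi, g), 0.0)
    alo, ahi = cfg.antagonistic_slope_range
    asign = rng.choice([-1.0, 1.0], g)
    slope_m_ant = asign * rng.uniform(alo, ahi, g)
    slope_f_ant = -asign * rng.uniform(alo, ahi, g)
    slope_f = np.where(ant_ids, slope_f_ant, shared)
    slope_m = np.where(ant_ids, slope_m_ant, shared)
    # design coding: female reference, beta_F = female slope,
    # beta_SF = male slope - female slope
    beta_F = slope_f
    beta_SF = slope_m - slope_f

    Y = np.empty((g, n))
    batch_eff = rng.normal(0.0, cfg.sd_batch, (g, cfg.n_batches))
    line_eff = np.where(
        line_ids[:, None], rng.normal(0.0, cfg.sd_line, (g, cfg.n_lines)), 0.0
    )
    inter_eff = np.where(
        int_ids[:, None], rng.normal(0.0, cfg.sd_interaction, (g, 2 * cfg.n_lines)), 0.0
    )
    noise = rng.normal(0.0, cfg.sd_resid, (g, n))
    Y = (
        baseline[:, None]
        + batch_eff[:, batch_idx]
        + sex_eff[:, None] * male[None, :]
        + line_eff[:, line_idx]
        + inter_eff[:, cell_idx]
        + beta_F[:, None] * F[None, :]
        + beta_SF[:, None] * (F * male)[None, :]
        + noise
    )

    tids = [f"T{i + 1:05d}" for i in range(g)]
    matrix = pd.DataFrame(Y, index=pd.Index(tids, name="transcript"),
                          columns=pd.Index(samples["sample_id"].tolist()))
    truth = TruthLabels(
        transcripts=pd.DataFrame(
            {
                "transcript": tids,
                "sex_biased": sex_ids,
                "line_variable": line_ids,
                "interaction": int_ids,
                "fitness_assoc_f": (slope_f != 0),
                "fitness_assoc_m": (slope_m != 0),
                "antagonistic": ant_ids,
                "sex_effect": sex_eff,
                "slope_f": slope_f,
                "slope_m": slope_m,
                "beta_F": beta_F,
                "beta_SF": beta_SF,
            }
        )
    )
    return matrix, samples.drop(columns="fitness"), truth


# ---------------------------------------------------------------------------
# tissue atlas
# ---------------------------------------------------------------------------


def simulate_tissue_atlas(
    n_genes: int,
    n_tissues: int = 17,
    frac_specific_per_tissue: float = 0.02,
    baseline_offsets: Sequence[float] | None = None,
    unexpressed_frac: float = 0.03,
    unexpressed_threshold: float = 3.4,
    specific_elevation: tuple[float, float] = (1.5, 3.0),
    noise_sd: float = 0.05,
    seed: int = 0,
    gene_ids: Sequence[str] | None = None,
) -> tuple[pd.DataFrame, TruthLabels]:
    """Simulate a tissue expression atlas with a whole-organism column.

    The whole-fly column contains a designated unexpressed set (exactly
    ``round(unexpressed_frac * n_genes)`` genes drawn below the expression
    threshold).  Each tissue column is the whole-fly profile plus an
    additive baseline offset (to exercise rescaling), small noise, and a
    planted set of tissue-specific genes elevated by at least 1 log2 unit
    after rescaling.

    Returns the atlas (genes x tissues plus ``whole_fly``) and truth with
    the planted specific sets and the unexpressed set.
    """
    if n_tissues < 1:
        raise ConfigurationError("n_tissues must be >= 1")
    if not 0 <= frac_specific_per_tissue <= 1 or not 0 <= unexpressed_frac <= 1:
        raise ConfigurationError("fractions must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if baseline_offsets is None:
        baseline_offsets = rng.uniform(-1.0, 1.0, n_tissues)
    elif len(baseline_offsets) != n_tissues:
        raise ConfigurationError("need one baseline offset per tissue")

    if gene_ids is not None:
        genes = list(gene_ids)
        if len(genes) != n_genes:
            raise ConfigurationError("gene_ids length must equal n_genes")
    else:
        genes = [f"G{i + 1:05d}" for i in range(n_genes)]
    tissues = [f"tissue{t + 1:02d}" for t in range(n_tissues)]

    n_unexpr = int(round(unexpressed_frac * n_genes))
    unexpr = rng.choice(n_genes, size=n_unexpr, replace=False)
    wholefly = rng.uniform(unexpressed_threshold + 0.6, 12.0, n_genes)
    wholefly[unexpr] = rng.uniform(2.0, unexpressed_threshold - 0.1, n_unexpr)

    atlas = pd.DataFrame(index=pd.Index(genes, name="gene"))
    specific: dict[str, set[str]] = {}
    expressed = np.setdiff1d(np.arange(n_genes), unexpr)
    n_spec = int(round(frac_specific_per_tissue * n_genes))
    lo, hi = specific_elevation
    for t, tissue in enumerate(tissues):
        col = wholefly + baseline_offsets[t] + rng.normal(0.0, noise_sd, n_genes)
        chosen = rng.choice(expressed, size=n_spec, replace=False)
        col[chosen] += rng.uniform(lo, hi, n_spec)
        specific[tissue] = {genes[i] for i in chosen}
        atlas[tissue] = col
    atlas["whole_fly"] = wholefly

    truth = TruthLabels(
        tissue_specific=specific,
        unexpressed_genes={genes[i] for i in unexpr},
        extras={"baseline_offsets": np.asarray(baseline_offsets, float)},
    )
    return atlas, truth


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------


def simulate_annotations(
    genes: Sequence[str],
    interest_set: Sequence[str] | None = None,
    arms: Sequence[str] = CHROMOSOME_ARMS,
    bands_per_arm: int = 20,
    go_term_sizes: Sequence[int] | None = None,
    planted_enriched_terms: Mapping[str, float] | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, TruthLabels]:
    """Simulate chromosome-band and GO-style annotation tables.

    Every gene receives exactly one (arm, band, sub-band) location drawn
    uniformly.  GO-style terms draw their members uniformly from the gene
    universe, except planted terms, whose members are drawn from
    ``interest_set`` with probability inflated by the requested enrichment
    fold, producing elevated overlap with that set.

    Returns
    -------
    (chrom_table, go_table, truth)
        ``chrom_table``: gene, arm, band, subband.  ``go_table``: gene,
        term (one row per membership).  Truth records the planted terms.
    """
    genes = list(genes)
    if not genes:
        raise ConfigurationError("empty gene list")
    rng = np.random.default_rng(seed)
    if go_term_sizes is None:
        go_term_sizes = [30] * 50
    planted_enriched_terms = dict(planted_enriched_terms or {})
    interest = set(interest_set or [])
    if planted_enriched_terms and not interest:
        raise ConfigurationError("planted enrichment requires an interest set")

    chrom = pd.DataFrame(
        {
            "gene": genes,
            "arm": rng.choice(list(arms), len(genes)),
            "band": rng.integers(1, bands_per_arm + 1, len(genes)),
            "subband": rng.choice(list(SUB_BANDS), len(genes)),
        }
    )

    gene_arr = np.array(genes)
    in_interest = np.isin(gene_arr, list(interest))
    base_frac = max(in_interest.mean(), 1.0 / len(genes))
    rows = []
    planted_names = set()
    term_sizes = list(go_term_sizes)
    names = [f"GO:{i + 1:07d}" for i in range(len(term_sizes) + len(planted_enriched_terms))]
    for i, size in enumerate(term_sizes):
        members = rng.choice(gene_arr, size=min(size, len(genes)), replace=False)
        rows += [(g, names[i]) for g in members]
    for j, (term, fold) in enumerate(planted_enriched_terms.items()):
        name = names[len(term_sizes) + j] if term.startswith("_auto") else term
        size = term_sizes[0] if term_sizes else 30
        p_int = min(fold * base_frac, 0.95)
        # weighted sampling without replacement favouring the interest set
        w = np.where(in_interest, p_int / max(in_interest.sum(), 1),
                     (1 - p_int) / max((~in_interest).sum(), 1))
        members = rng.choice(gene_arr, size=min(size, len(genes)), replace=False,
                             p=w / w.sum())
        rows += [(g, name) for g in members]
        planted_names.add(name)
    go = pd.DataFrame(rows, columns=["gene", "term"])

    truth = TruthLabels(enriched_terms=planted_names, interest_set=interest)
    return chrom, go, truth
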