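"""Statistical battery for water-stress trait comparisons.

Covers two needs.  First, agreement between manual measurements and
box-derived predictions: coefficient of determination R^2 (which may be
negative for predictions worse than the mean), Pearson r, RMSE and MAE.
Second, between-treatment inference on traits whose distributional
assumptions are shaky: Shapiro-Wilk normality and Levene variance checks,
then the non-parametric Kruskal-Wallis H test across all treatments,
pairwise Mann-Whitney U comparisons (reported as a raw, unadjusted p-value
matrix), Cohen's d effect sizes, and a Wilks'-Lambda MANOVA combining
height and petiole count.

The univariate tests delegate to scipy.stats; the Wilks'-Lambda MANOVA
(within/between SSCP matrices with Rao's F approximation) is implemented
here.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigError, PhenoboxError


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_per_group: tuple[int, ...]

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise PhenoboxError(f"p-value outside [0,1]: {self.p_value}")


@dataclass(frozen=True)
class AgreementReport:
    r2: float
    pearson_r: float
    rmse: float
    mae: float


def agreement_metrics(measured: Sequence[float], predicted: Sequence[float]) -> AgreementReport:
    """R^2, Pearson r, RMSE and MAE between measured and predicted values.

    R^2 = 1 - SSres/SStot relative to the measured mean; it turns negative
    when predictions do worse than predicting that mean.
    """
    m = np.asarray(measured, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if m.shape != p.shape:
        raise ConfigError(f"length mismatch: {m.shape} vs {p.shape}")
    if m.size < 2:
        raise ConfigError("need at least 2 observations")
    resid = p - m
    ss_res = float(np.sum(resid**2))
    ss_tot = float(np.sum((m - m.mean()) ** 2))
    if ss_tot == 0:
        raise ConfigError("measured values are constant; R^2 undefined")
    r = float(sps.pearsonr(m, p).statistic) if np.std(p) > 0 else np.nan
    return AgreementReport(
        r2=1.0 - ss_res / ss_tot,
        pearson_r=r,
        rmse=float(np.sqrt(np.mean(resid**2))),
        mae=float(np.mean(np.abs(resid))),
    )


def shapiro_wilk(values: Sequence[float]) -> TestResult:
    """Shapiro-Wilk normality test (3 <= n <= 5000)."""
    x = np.asarray(values, dtype=float)
    if not (3 <= x.size <= 5000):
        raise ConfigError(f"Shapiro-Wilk requires 3 <= n <= 5000, got {x.size}")
    res = sps.shapiro(x)
    return TestResult(float(res.statistic), float(res.pvalue), "shapiro-wilk", (x.size,))


def levene(groups: Sequence[Sequence[float]], center: str = "mean") -> TestResult:
    """Levene's variance-homogeneity test (classic mean-centered by default;
    ``center='median'`` gives the Brown-Forsythe variant)."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or any(g.size < 2 for g in gs):
        raise ConfigError("Levene needs >= 2 groups with n >= 2 each")
    if all(np.ptp(g) == 0 for g in gs):
        return TestResult(0.0, 1.0, f"levene-{center}", tuple(g.size for g in gs))
    res = sps.levene(*gs, center=center)
    return TestResult(float(res.statistic), float(res.pvalue), f"levene-{center}",
                      tuple(g.size for g in gs))


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis H test with tie correction; p from chi^2 with k-1 df."""
    gs = [np.asarray(g, dtype=float) for g in groups]
    if len(gs) < 2 or sum(g.size for g in gs) < 5:
        raise ConfigError("Kruskal-Wallis needs >= 2 groups and total n >= 5")
    pooled = np.concatenate(gs)
    if np.ptp(pooled) == 0:
        return TestResult(0.0, 1.0, "kruskal-wallis", tuple(g.size for g in gs))
    res = sps.kruskal(*gs)
    return TestResult(float(res.statistic), float(res.pvalue), "kruskal-wallis",
                      tuple(g.size for g in gs))


#: exact Mann-Whitney enumeration is used up to this product of sample sizes
EXACT_MW_LIMIT = 400


def mann_whitney_u(
    a: Sequence[float], b: Sequence[float], alternative: str = "two-sided"
) -> TestResult:
    """Mann-Whitney U test.

    Small samples (n_a * n_b <= 400, no ties) use the exact null
    distribution; otherwise the normal approximation with tie and
    continuity corrections.
    """
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 1 or xb.size < 1:
        raise ConfigError("each sample needs n >= 1")
    has_ties = np.unique(np.concatenate([xa, xb])).size < xa.size + xb.size
    exact = xa.size * xb.size <= EXACT_MW_LIMIT and not has_ties
    res = sps.mannwhitneyu(
        xa, xb, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return TestResult(
        float(res.statistic),
        float(min(res.pvalue, 1.0)),
        "mann-whitney-exact" if exact else "mann-whitney-asymptotic",
        (xa.size, xb.size),
    )


@dataclass(frozen=True)
class TraitSample:
    """One treatment group's values for a single trait."""

    treatment: str
    values: tuple[float, ...]


def pairwise_matrix(samples: Sequence[TraitSample]) -> pd.DataFrame:
    """Symmetric matrix of raw pairwise Mann-Whitney p-values (diagonal 1)."""
    if len(samples) < 2:
        raise ConfigError("need >= 2 treatments")
    names = [s.treatment for s in samples]
    mat = pd.DataFrame(np.ones((len(samples), len(samples))), index=names, columns=names)
    for i, j in combinations(range(len(samples)), 2):
        p = mann_whitney_u(samples[i].values, samples[j].values).p_value
        mat.iloc[i, j] = mat.iloc[j, i] = p
    return mat


def cohens_d(a: Sequence[float], b: Sequence[float]) -> float:
    """Cohen's d: (mean_a - mean_b) / pooled SD with (n-1) weighting."""
    xa = np.asarray(a, dtype=float)
    xb = np.asarray(b, dtype=float)
    if xa.size < 2 or xb.size < 2:
        raise ConfigError("each sample needs n >= 2")
    pooled_var = (
        (xa.size - 1) * xa.var(ddof=1) + (xb.size - 1) * xb.var(ddof=1)
    ) / (xa.size + xb.size - 2)
    if pooled_var == 0:
        raise ConfigError("zero pooled SD; effect size undefined")
    return float((xa.mean() - xb.mean()) / np.sqrt(pooled_var))


def effect_size_matrix(samples: Sequence[TraitSample]) -> pd.DataFrame:
    """Antisymmetric matrix of pairwise Cohen's d (row minus column)."""
    names = [s.treatment for s in samples]
    mat = pd.DataFrame(np.zeros((len(samples), len(samples))), index=names, columns=names)
    for i, j in combinations(range(len(samples)), 2):
        d = cohens_d(samples[i].values, samples[j].values)
        mat.iloc[i, j] = d
        mat.iloc[j, i] = -d
    return mat


def manova_wilks(groups: Sequence[np.ndarray]) -> TestResult:
    """One-way MANOVA via Wilks' Lambda with Rao's F approximation.

    ``groups`` is a list of (n_i, p) trait matrices, one per treatment.
    Lambda = det(E) / det(E + H) with E the pooled within-group and H the
    between-group SSCP matrix; Lambda in (0, 1], small values indicating
    group separation.
    """
    gs = [np.atleast_2d(np.asarray(g, dtype=float)) for g in groups]
    k = len(gs)
    if k < 2:
        raise ConfigError("MANOVA needs >= 2 groups")
    p = gs[0].shape[1]
    if any(g.shape[1] != p for g in gs):
        raise ConfigError("all groups must share the trait dimension")
    if any(g.shape[0] <= p for g in gs):
        raise ConfigError("each group needs n > number of traits")
    n_total = sum(g.shape[0] for g in gs)
    grand = np.vstack(gs).mean(axis=0)

    E = np.zeros((p, p))
    H = np.zeros((p, p))
    for g in gs:
        mu = g.mean(axis=0)
        c = g - mu
        E += c.T @ c
        d = (mu - grand)[:, None]
        H += g.shape[0] * (d @ d.T)

    det_e = np.linalg.det(E)
    if det_e <= 0:
        raise ConfigError("singular within-group SSCP matrix")
    lam = float(det_e / np.linalg.det(E + H))

    # Rao's F approximation
    q = k - 1
    denom = p * p + q * q - 5
    t = np.sqrt((p * p * q * q - 4) / denom) if denom > 0 else 1.0
    df1 = p * q
    df2 = ((n_total - 1) - (p + k) / 2) * t - (p * q - 2) / 2
    lam_t = lam ** (1.0 / t)
    f_stat = (1 - lam_t) / lam_t * df2 / df1
    p_value = float(sps.f.sf(f_stat, df1, df2))
    return TestResult(lam, p_value, "manova-wilks-rao", tuple(g.shape[0] for g in gs))


def stress_report(traits: pd.DataFrame, by: str = "treatment") -> dict:
    """Full statistical summary of a traits table, grouped by treatment.

    Runs normality and variance checks, the omnibus Kruskal-Wallis test,
    the pairwise Mann-Whitney matrix and Cohen's d per trait, plus the
    combined height+petiole MANOVA.
    """
    trait_cols = ["height_cm", "petiole_count"]
    grouped = {name: g for name, g in traits.groupby(by, sort=True)}
    report: dict = {"groups": {n: len(g) for n, g in grouped.items()}, "traits": {}}
    for col in trait_cols:
        samples = [TraitSample(n, tuple(g[col])) for n, g in grouped.items()]
        gs = [np.asarray(s.values) for s in samples]
        report["traits"][col] = {
            "shapiro": {s.treatment: shapiro_wilk(s.values) for s in samples},
            "levene": levene(gs),
            "kruskal_wallis": kruskal_wallis(gs),
            "pairwise_p": pairwise_matrix(samples),
            "cohens_d": effect_size_matrix(samples),
        }
    report["manova"] = manova_wilks([g[trait_cols].to_numpy() for g in grouped.values()])
    return report
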