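"""Statistical battery for two-session group studies.

Implements the analyses a baseline / Day-2 randomized design calls for:

* two-way mixed-model ANOVA (between factor: group or responder status;
  within factor: time) from the standard split-plot sums-of-squares
  partition, with Shapiro-Wilk normality checks per cell, Mauchly's test of
  sphericity and the Greenhouse-Geisser epsilon (vacuously 1 with two
  repeated levels, but computed generically so the machinery extends);
* Sidak-adjusted post hoc p-values;
* pooled two-sample t-tests, from raw samples or published summary
  statistics, with 95% CIs on the mean difference;
* Pearson correlations with the conventional weak (< 0.3) / moderate
  (0.3-0.5) / strong (> 0.5) magnitude bands.

Unequal group sizes are handled with Type III (sum-to-zero contrast) sums of
squares; incomplete participants are dropped listwise per outcome.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaEffect",
    "AnovaResult",
    "PooledTResult",
    "CorrelationResult",
    "mixed_anova",
    "responder_stratified_anova",
    "sidak_posthoc",
    "pooled_two_sample_t",
    "pooled_t_from_samples",
    "pearson_with_band",
    "correlation_band",
    "gg_epsilon",
    "mauchly_test",
]


@dataclass(frozen=True)
class AnovaEffect:
    F: float
    df_num: float
    df_den: float
    p: float


@dataclass
class AnovaResult:
    """Mixed-ANOVA effects plus assumption diagnostics."""

    effects: dict[str, AnovaEffect]  # keys: group, time, interaction
    epsilon_gg: float
    shapiro: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    mauchly: tuple[float, float] = (1.0, 1.0)  # (W, p); trivial for 2 levels
    n_used: int = 0
    n_dropped: int = 0
    between_factor: str = "group"

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"effect": name, "F": e.F, "df_num": e.df_num, "df_den": e.df_den, "p": e.p}
            for name, e in self.effects.items()
        ]
        df = pd.DataFrame(rows)
        df["epsilon_gg"] = self.epsilon_gg
        return df


@dataclass(frozen=True)
class PooledTResult:
    t: float
    df: int
    mean_difference: float
    ci95: tuple[float, float]
    p: float


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p: float
    band: str
    n: int


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k-1) x k orthonormal contrast matrix (rows orthogonal to the mean)."""
    helmert = np.zeros((k - 1, k))
    for i in range(1, k):
        helmert[i - 1, :i] = 1.0
        helmert[i - 1, i] = -i
        helmert[i - 1] /= np.linalg.norm(helmert[i - 1])
    return helmert


def gg_epsilon(cov: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from a repeated-measures covariance matrix.

    ``epsilon = tr(M)^2 / ((k-1) tr(M^2))`` with ``M = C S C'`` for an
    orthonormal contrast matrix C; equals 1 exactly when k = 2 or the
    sphericity assumption holds, and is bounded below by ``1/(k-1)``.
    """
    cov = np.atleast_2d(np.asarray(cov, float))
    k = cov.shape[0]
    if k < 2:
        raise ValueError("need >= 2 repeated levels")
    c = _orthonormal_contrasts(k)
    m = c @ cov @ c.T
    lam = np.linalg.eigvalsh(m)
    num = lam.sum() ** 2
    den = (k - 1) * (lam**2).sum()
    return float(num / den) if den > 0 else 1.0


def mauchly_test(cov: np.ndarray, n_subjects: int) -> tuple[float, float]:
    """Mauchly's sphericity test; returns (W, p).

    With two repeated levels the test is vacuous: W = 1, p = 1.
    """
    cov = np.atleast_2d(np.asarray(cov, float))
    k = cov.shape[0]
    if k <= 2:
        return 1.0, 1.0
    c = _orthonormal_contrasts(k)
    m = c @ cov @ c.T
    lam = np.linalg.eigvalsh(m)
    if np.any(lam <= 0):
        return 0.0, 0.0
    w = float(np.prod(lam) / (lam.mean() ** (k - 1)))
    d = k - 1
    df = d * (d + 1) // 2 - 1
    f = 1 - (2 * d**2 + d + 2) / (6 * d * (n_subjects - 1))
    chi2 = -(n_subjects - 1) * f * math.log(max(w, 1e-300))
    return w, float(sps.chi2.sf(chi2, df))


def _prepare_long(
    table: pd.DataFrame,
    outcome_name: str | None,
    between: str,
    value_col: str = "value",
) -> pd.DataFrame:
    df = table.copy()
    if outcome_name is not None and "outcome" in df.columns:
        df = df[df["outcome"] == outcome_name]
    cols = {"participant", between, "time", value_col}
    missing = cols - set(df.columns)
    if missing:
        raise ValueError(f"long table missing columns: {sorted(missing)}")
    df = df[["participant", between, "time", value_col]].dropna()
    return df


def mixed_anova(
    table: pd.DataFrame,
    outcome_name: str | None = None,
    between: str = "group",
    value_col: str = "value",
) -> AnovaResult:
    """Two-way mixed ANOVA: between-subject group x within-subject time.

    ``table`` is long-format with columns ``participant``, the between factor,
    ``time`` and ``value`` (optionally filtered to ``outcome_name`` via an
    ``outcome`` column).  Participants without a value at every time level are
    dropped (listwise deletion).  Sums of squares: the between stratum is a
    one-way ANOVA of subject means; the within stratum uses sum-to-zero
    (Type III) contrasts, so unequal group sizes are handled as SPSS-style
    GLM repeated measures would.
    """
    df = _prepare_long(table, outcome_name, between, value_col)
    wide = df.pivot_table(
        index=["participant", between], columns="time", values=value_col, aggfunc="first"
    )
    n_before = wide.shape[0]
    wide = wide.dropna()
    n_dropped = n_before - wide.shape[0]

    times = list(wide.columns)
    groups = wide.index.get_level_values(between).to_numpy()
    levels = sorted(set(groups))
    if len(levels) != 2:
        raise ValueError(f"between factor must have exactly 2 levels, got {levels}")
    if len(times) < 2:
        raise ValueError("need >= 2 time levels")
    y = wide.to_numpy(float)  # subjects x times
    n_total, t = y.shape
    n_per = {g: int((groups == g).sum()) for g in levels}
    if min(n_per.values()) < 2:
        raise ValueError("each group needs >= 2 complete participants")

    # scale-aware tolerance so zero-variance strata report F = 0, not 0/0 noise
    ss_tol = 1e-10 * max(1.0, float(np.abs(y).max())) ** 2

    def _f_ratio(ss_eff, df1, sse, df2):
        if ss_eff <= ss_tol:
            return 0.0
        if sse <= ss_tol:
            return math.inf
        return (ss_eff / df1) / (sse / df2)

    # --- between-subjects stratum: one-way ANOVA on subject means, scaled by T
    m = y.mean(axis=1)
    ss_group = t * sum(
        n_per[g] * (m[groups == g].mean() - m.mean()) ** 2 for g in levels
    )
    ss_err_b = t * sum(((m[groups == g] - m[groups == g].mean()) ** 2).sum() for g in levels)
    df_b1, df_b2 = len(levels) - 1, n_total - len(levels)
    f_group = _f_ratio(ss_group, df_b1, ss_err_b, df_b2)

    # --- within-subjects stratum: Type III via sum-coded model comparison
    g_code = np.where(groups == levels[0], 1.0, -1.0)
    subj_dummies = np.eye(n_total)
    t_codes = _sum_codes(t)  # t x (t-1)
    long_y = y.ravel()
    rows_subj = np.repeat(subj_dummies, t, axis=0)
    rows_time = np.tile(t_codes, (n_total, 1))
    rows_int = rows_time * np.repeat(g_code, t)[:, None]

    def _sse(*blocks):
        x = np.hstack(blocks)
        beta = np.linalg.lstsq(x, long_y, rcond=None)[0]
        return float(((long_y - x @ beta) ** 2).sum())

    sse_full = _sse(rows_subj, rows_time, rows_int)
    ss_time = _sse(rows_subj, rows_int) - sse_full
    ss_int = _sse(rows_subj, rows_time) - sse_full
    df_w1 = t - 1
    df_w2 = (n_total - len(levels)) * (t - 1)
    f_time = _f_ratio(ss_time, df_w1, sse_full, df_w2)
    f_int = _f_ratio(ss_int, df_w1, sse_full, df_w2)

    # --- sphericity diagnostics on the pooled within-group covariance
    resid = np.vstack([y[groups == g] - y[groups == g].mean(axis=0) for g in levels])
    cov = (resid.T @ resid) / max(n_total - len(levels), 1)
    eps = gg_epsilon(cov)
    mauchly = mauchly_test(cov, n_total)

    def _p(f, d1, d2):
        if math.isinf(f):
            return 0.0
        return float(sps.f.sf(f, d1 * eps, d2 * eps))

    effects = {
        between: AnovaEffect(float(f_group), df_b1, df_b2,
                             float(sps.f.sf(f_group, df_b1, df_b2)) if math.isfinite(f_group) else 0.0),
        "time": AnovaEffect(float(f_time), df_w1, df_w2, _p(f_time, df_w1, df_w2)),
        "interaction": AnovaEffect(float(f_int), df_w1, df_w2, _p(f_int, df_w1, df_w2)),
    }

    shapiro: dict[tuple[str, str], tuple[float, float]] = {}
    for g in levels:
        for j, tp in enumerate(times):
            cell = y[groups == g][:, j]
            if len(cell) >= 3 and np.ptp(cell) > 0:
                w, p = sps.shapiro(cell)
                shapiro[(str(g), str(tp))] = (float(w), float(p))

    return AnovaResult(
        effects=effects, epsilon_gg=eps, shapiro=shapiro, mauchly=mauchly,
        n_used=n_total, n_dropped=n_dropped, between_factor=between,
    )


def _sum_codes(k: int) -> np.ndarray:
    """k x (k-1) sum-to-zero (deviation) coding matrix."""
    codes = np.vstack([np.eye(k - 1), -np.ones((1, k - 1))])
    return codes


def responder_stratified_anova(
    table: pd.DataFrame,
    labels: pd.DataFrame,
    outcome_name: str | None = None,
    metric: str = "volume",
    value_col: str = "value",
) -> AnovaResult:
    """Mixed ANOVA with responder status (facilitators vs depressors) as the
    between factor; nonresponders are excluded.

    ``labels`` holds columns ``participant``, ``metric``, ``label`` as written
    by the classification stage.
    """
    lab = labels[(labels["metric"] == metric) & labels["label"].isin(["facilitator", "depressor"])]
    keep = dict(zip(lab["participant"].astype(str), lab["label"]))
    df = table.copy()
    df["participant"] = df["participant"].astype(str)
    df = df[df["participant"].isin(keep)]
    if df.empty:
        raise ValueError("no facilitators/depressors to analyze")
    df = df.assign(response=df["participant"].map(keep))
    return mixed_anova(df, outcome_name, between="response", value_col=value_col)


def sidak_posthoc(pvalues, m: int | None = None) -> np.ndarray:
    """Sidak multiplicity adjustment: ``p_adj = 1 - (1 - p)^m``, capped at 1."""
    p = np.asarray(list(np.atleast_1d(pvalues)), dtype=float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if m is None else int(m)
    if m < 1:
        raise ValueError("m must be >= 1")
    return np.minimum(1.0, 1.0 - (1.0 - p) ** m)


def pooled_two_sample_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> PooledTResult:
    """Equal-variance two-sample t-test from summary statistics.

    Returns the t statistic, df = n1 + n2 - 2, the mean difference
    (mean1 - mean2) and its 95% CI.  A zero pooled variance with a nonzero
    mean difference yields an infinite t with a warning.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 < 0 or sd2 < 0:
        raise ValueError("standard deviations must be >= 0")
    df = n1 + n2 - 2
    md = mean1 - mean2
    sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
    se = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    if se == 0:
        if md != 0:
            warnings.warn("zero pooled variance with nonzero mean difference; t = inf")
            return PooledTResult(math.inf, df, md, (md, md), 0.0)
        return PooledTResult(0.0, df, 0.0, (0.0, 0.0), 1.0)
    t = md / se
    tcrit = float(sps.t.ppf(0.975, df))
    p = float(2 * sps.t.sf(abs(t), df))
    return PooledTResult(float(t), df, float(md), (md - tcrit * se, md + tcrit * se), p)


def pooled_t_from_samples(x, y) -> PooledTResult:
    """Pooled t-test from raw samples (delegates to the summary form)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    return pooled_two_sample_t(
        float(x.mean()), float(x.std(ddof=1)), len(x),
        float(y.mean()), float(y.std(ddof=1)), len(y),
    )


def correlation_band(r: float) -> str:
    """Interpretation band by |r|: weak < 0.3 <= moderate <= 0.5 < strong."""
    a = abs(r)
    if a < 0.3:
        return "weak"
    if a <= 0.5:
        return "moderate"
    return "strong"


def pearson_with_band(x, y) -> CorrelationResult:
    """Sample Pearson correlation with two-sided p and magnitude band."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need >= 3 paired finite observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = sps.pearsonr(x, y)
    return CorrelationResult(
        r=float(res.statistic), p=float(res.pvalue),
        band=correlation_band(res.statistic), n=len(x),
    )
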