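"""Group-level inference for the attenuation analysis.

Implements the inference layer applied to per-participant PSEs: baseline
normalization (PSE_reaching - PSE_baseline), one-way repeated-measures and
mixed ANOVAs with Greenhouse-Geisser correction and partial eta-squared,
normality-gated planned comparisons (paired/Welch t vs Wilcoxon signed-rank
/ rank-sum) with Benjamini-Hochberg FDR, matched effect sizes (Cohen's d or
rank-biserial correlation) and 95% intervals (t-based or Hodges-Lehmann),
per-participant linear slopes of normalized PSE over % reach time, and
one-sided JZS Bayes factors with a default Cauchy prior (scale 0.707).

ANOVA decompositions are delegated to pingouin; the planned-comparison
machinery, rank-biserial conventions, Hodges-Lehmann intervals and the
one-sided Bayes factor are implemented here because their exact conventions
determine the reported statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .config import REACHING_TYPES

__all__ = [
    "AnovaEffect",
    "AnovaReport",
    "ComparisonResult",
    "SlopeResult",
    "StatsError",
    "WITHIN_PLAN",
    "normalize_pses",
    "rm_anova",
    "mixed_anova",
    "planned_comparisons",
    "between_group_comparisons",
    "fit_participant_slopes",
    "one_sample_comparison",
    "two_sample_comparison",
    "bh_adjust",
    "bayes_factor_one_sided",
    "signed_rank_statistic",
    "rank_biserial_paired",
    "rank_biserial_independent",
    "hodges_lehmann_ci_paired",
    "hodges_lehmann_ci_independent",
]

#: The seven within-group planned comparisons central to the serial-time
#: hypothesis: serial dependence during reaching plus post-reach recovery.
WITHIN_PLAN: tuple[tuple[str, str], ...] = (
    ("early", "mid"),
    ("early", "late"),
    ("early", "target"),
    ("mid", "late"),
    ("mid", "target"),
    ("late", "target"),
    ("target", "post_reach"),
)

PCT_COLUMNS = {"early": "pct_early", "mid": "pct_mid", "late": "pct_late"}


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class AnovaEffect:
    source: str
    F: float
    df1: float
    df2: float
    p: float
    partial_eta_sq: float
    epsilon: float | None = None

    def to_dict(self) -> dict:
        return {
            "source": self.source,
            "F": self.F,
            "df1": self.df1,
            "df2": self.df2,
            "p": self.p,
            "partial_eta_sq": self.partial_eta_sq,
            "epsilon": self.epsilon,
        }


@dataclass
class AnovaReport:
    effects: list[AnovaEffect]

    def __getitem__(self, source: str) -> AnovaEffect:
        for e in self.effects:
            if e.source == source:
                return e
        raise KeyError(source)

    def to_dict(self) -> dict:
        return {"effects": [e.to_dict() for e in self.effects]}


@dataclass(frozen=True)
class ComparisonResult:
    name: str
    test_used: str
    statistic: float
    df: float | None
    p_raw: float
    ci95: tuple[float, float]
    effect_size: float
    effect_size_type: str
    n: int
    p_fdr: float | None = None
    estimate: float = np.nan

    def to_dict(self) -> dict:
        return {
            "name": self.name,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_fdr": self.p_fdr,
            "ci95": list(self.ci95),
            "effect_size": self.effect_size,
            "effect_size_type": self.effect_size_type,
            "n": self.n,
            "estimate": self.estimate,
        }


@dataclass
class SlopeResult:
    """Per-participant attenuation slopes (N per % reach time) and their tests."""

    slopes: pd.DataFrame  # participant, slope [, group]
    span: str
    group_tests: dict = field(default_factory=dict)
    between_test: ComparisonResult | None = None

    def to_dict(self) -> dict:
        return {
            "span": self.span,
            "slopes": self.slopes.to_dict("records"),
            "group_tests": {k: v.to_dict() for k, v in self.group_tests.items()},
            "between_test": None
            if self.between_test is None
            else self.between_test.to_dict(),
        }


# ---------------------------------------------------------------------------
# normalization


def normalize_pses(
    fits: pd.DataFrame,
    retained_trials: pd.DataFrame | None = None,
    groups: pd.Series | dict | None = None,
) -> pd.DataFrame:
    """Baseline-normalized PSE table, one row per participant.

    Subtracts each participant's baseline PSE from each reaching-type PSE.
    Participants missing the baseline fit or any reaching cell are dropped
    (complete-case analysis; the drop is visible by comparing indices).
    When ``retained_trials`` is given, per-participant mean percent reach
    times of the early/mid/late test forces are attached as the x-axis for
    the slope fits (the target is pinned at 100%).
    """
    wide = fits.pivot_table(index="participant", columns="trial_type", values="pse")
    needed = list(REACHING_TYPES) + ["baseline"]
    missing_cols = [c for c in needed if c not in wide.columns]
    if missing_cols:
        raise StatsError(f"fits table lacks trial types: {missing_cols}")
    wide = wide.dropna(subset=needed)
    out = wide[list(REACHING_TYPES)].sub(wide["baseline"], axis=0)
    if retained_trials is not None:
        pct = (
            retained_trials[retained_trials["label"].isin(PCT_COLUMNS)]
            .groupby(["participant", "label"], observed=False)["percent_time"]
            .mean()
            .unstack()
        )
        for label, col in PCT_COLUMNS.items():
            out[col] = pct[label] if label in pct.columns else np.nan
    if groups is not None:
        out["group"] = pd.Series(groups)
    return out


# ---------------------------------------------------------------------------
# ANOVA (pingouin-backed)


def _melt(wide: pd.DataFrame, levels, value_name="pse"):
    df = wide.reset_index()[["participant", *levels]]
    return df.melt(id_vars="participant", var_name="trial_type", value_name=value_name)


def rm_anova(wide: pd.DataFrame, levels=REACHING_TYPES) -> AnovaReport:
    """One-way repeated-measures ANOVA over the within factor ``levels``.

    Greenhouse-Geisser correction is applied to the degrees of freedom
    whenever the epsilon estimate is below 1; partial eta-squared is the
    effect size. Requires complete cases.
    """
    levels = list(levels)
    if wide[levels].isna().any().any():
        bad = wide[levels].isna().any(axis=1)
        raise StatsError(f"incomplete design: missing cells for {list(wide.index[bad])}")
    if len(wide) < 3 or len(levels) < 2:
        raise StatsError("need >= 3 participants and >= 2 levels")
    values = wide[levels].to_numpy(dtype=float)
    if np.allclose(values, values[:, [0]]):
        # no within-participant variation at all: zero effect sum of squares
        k = len(levels)
        n = len(wide)
        return AnovaReport(
            [AnovaEffect("trial_type", 0.0, float(k - 1),
                         float((k - 1) * (n - 1)), 1.0, 0.0, 1.0)]
        )
    import pingouin as pg

    long = _melt(wide, levels)
    res = pg.rm_anova(
        data=long, dv="pse", within="trial_type", subject="participant",
        correction=True, effsize="np2",
    ).iloc[0]
    eps_raw = res.get("eps", np.nan)
    eps = float(eps_raw) if np.isfinite(eps_raw) else 1.0
    eps = min(eps, 1.0)
    df1, df2 = float(res["ddof1"]), float(res["ddof2"])
    if eps < 1.0:
        df1, df2 = eps * df1, eps * df2
    F = float(res["F"])
    p = float(sps.f.sf(F, df1, df2))
    return AnovaReport(
        [AnovaEffect("trial_type", F, df1, df2, p, float(res["np2"]), eps)]
    )


def mixed_anova(
    wide: pd.DataFrame, levels=REACHING_TYPES, group_col: str = "group"
) -> AnovaReport:
    """Mixed ANOVA: between-subject group, within-subject trial type.

    GG correction applies to the within and interaction terms whenever the
    epsilon estimate is below 1.
    """
    levels = list(levels)
    if group_col not in wide.columns:
        raise StatsError(f"missing group column {group_col!r}")
    if wide[group_col].nunique() < 2:
        raise StatsError("mixed ANOVA needs two non-empty groups")
    import pingouin as pg

    long = _melt(wide, levels)
    long = long.merge(
        wide.reset_index()[["participant", group_col]], on="participant"
    )
    res = pg.mixed_anova(
        data=long, dv="pse", within="trial_type", subject="participant",
        between=group_col, correction=True, effsize="np2",
    ).set_index("Source")
    eps_raw = res.loc["trial_type", "eps"] if "eps" in res.columns else np.nan
    eps = float(eps_raw) if np.isfinite(eps_raw) else 1.0
    eps = min(eps, 1.0)
    effects = []
    for source, label in (
        (group_col, "group"),
        ("trial_type", "trial_type"),
        ("Interaction", "interaction"),
    ):
        row = res.loc[source]
        df1, df2 = float(row["DF1"]), float(row["DF2"])
        this_eps = None
        if label in ("trial_type", "interaction") and eps < 1.0:
            df1, df2, this_eps = eps * df1, eps * df2, eps
        elif label in ("trial_type", "interaction"):
            this_eps = eps
        F = float(row["F"])
        p = float(sps.f.sf(F, df1, df2))
        effects.append(AnovaEffect(label, F, df1, df2, p, float(row["np2"]), this_eps))
    return AnovaReport(effects)


# ---------------------------------------------------------------------------
# rank statistics and intervals


def signed_rank_statistic(diff: np.ndarray) -> tuple[float, int]:
    """Positive-rank sum W+ of the signed-rank test (mid-ranks, zeros dropped)."""
    d = np.asarray(diff, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 0.0, 0
    ranks = sps.rankdata(np.abs(d))
    return float(ranks[d > 0].sum()), n


def rank_biserial_paired(diff: np.ndarray) -> float:
    """Matched rank-biserial correlation: 2 W+ / S - 1 with S = n(n+1)/2."""
    w_plus, n = signed_rank_statistic(diff)
    if n == 0:
        return 0.0
    s = n * (n + 1) / 2.0
    return 2.0 * w_plus / s - 1.0


def rank_biserial_independent(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-biserial correlation from the Mann-Whitney U of x vs y."""
    u1 = sps.mannwhitneyu(x, y, alternative="two-sided").statistic
    return 2.0 * u1 / (len(x) * len(y)) - 1.0


def _walsh_averages(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, dtype=float)
    i, j = np.triu_indices(d.size)
    return np.sort((d[i] + d[j]) / 2.0)


def hodges_lehmann_ci_paired(
    diff: np.ndarray, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Hodges-Lehmann estimate and CI for paired differences.

    The estimate is the median of the Walsh averages; the interval uses the
    large-sample normal approximation to the signed-rank critical value.
    """
    d = np.asarray(diff, dtype=float)
    n = d.size
    walsh = _walsh_averages(d)
    est = float(np.median(walsh))
    m = walsh.size
    z = sps.norm.ppf(0.5 + conf / 2.0)
    k = int(np.floor(n * (n + 1) / 4.0 - z * np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0)))
    k = max(k, 0)
    if k >= m / 2.0:
        return est, (walsh[0], walsh[-1])
    return est, (float(walsh[k]), float(walsh[m - 1 - k]))


def hodges_lehmann_ci_independent(
    x: np.ndarray, y: np.ndarray, conf: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Hodges-Lehmann shift estimate and CI for two independent samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    diffs = np.sort((x[:, None] - y[None, :]).ravel())
    est = float(np.median(diffs))
    n1, n2 = x.size, y.size
    m = diffs.size
    z = sps.norm.ppf(0.5 + conf / 2.0)
    k = int(np.floor(n1 * n2 / 2.0 - z * np.sqrt(n1 * n2 * (n1 + n2 + 1) / 12.0)))
    k = max(k, 0)
    if k >= m / 2.0:
        return est, (diffs[0], diffs[-1])
    return est, (float(diffs[k]), float(diffs[m - 1 - k]))


# ---------------------------------------------------------------------------
# normality-gated comparisons


def one_sample_comparison(
    values: np.ndarray,
    name: str,
    mu: float = 0.0,
    normality_alpha: float = 0.05,
) -> ComparisonResult:
    """One-sample (or paired-difference) test against ``mu``.

    Shapiro-Wilk at ``normality_alpha`` gates between the one-sample t test
    (Cohen's d, t-based CI) and the Wilcoxon signed-rank test (positive-rank
    sum W+, matched rank-biserial, Hodges-Lehmann CI).
    """
    d = np.asarray(values, dtype=float) - mu
    n = d.size
    if n < 3:
        raise StatsError(f"{name}: need n >= 3")
    if np.all(d == d[0]):
        # zero-variance differences: degenerate, report the rank path
        p = 1.0 if d[0] == 0 else 0.0
        return ComparisonResult(
            name, "wilcoxon_signed_rank", signed_rank_statistic(d)[0], None, p,
            (float(d[0] + mu), float(d[0] + mu)), rank_biserial_paired(d),
            "rank_biserial", n, estimate=float(np.median(d) + mu),
        )
    normal = sps.shapiro(d).pvalue >= normality_alpha
    if normal:
        res = sps.ttest_1samp(d, 0.0)
        sd = np.std(d, ddof=1)
        se = sd / np.sqrt(n)
        tcrit = sps.t.ppf(0.975, n - 1)
        mean = float(np.mean(d))
        return ComparisonResult(
            name, "paired_t", float(res.statistic), float(n - 1),
            float(res.pvalue), (mean - tcrit * se + mu, mean + tcrit * se + mu),
            float(mean / sd), "cohens_d", n, estimate=mean + mu,
        )
    w_plus, n_eff = signed_rank_statistic(d)
    if n_eff == 0:
        p = 1.0
    else:
        p = float(sps.wilcoxon(d[d != 0]).pvalue)
    est, ci = hodges_lehmann_ci_paired(d)
    return ComparisonResult(
        name, "wilcoxon_signed_rank", w_plus, None, p,
        (ci[0] + mu, ci[1] + mu), rank_biserial_paired(d), "rank_biserial", n,
        estimate=est + mu,
    )


def two_sample_comparison(
    x: np.ndarray,
    y: np.ndarray,
    name: str,
    normality_alpha: float = 0.05,
) -> ComparisonResult:
    """Independent-samples test of x vs y (difference x - y).

    Shapiro-Wilk per group gates between the Welch t test (pooled-SD
    Cohen's d, Welch CI) and the Wilcoxon rank-sum test (Mann-Whitney U of
    x, rank-biserial, Hodges-Lehmann shift CI).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if min(n1, n2) < 3:
        raise StatsError(f"{name}: need n >= 3 per group")
    normal = (
        sps.shapiro(x).pvalue >= normality_alpha
        and sps.shapiro(y).pvalue >= normality_alpha
    )
    if normal:
        res = sps.ttest_ind(x, y, equal_var=False)
        diff = float(np.mean(x) - np.mean(y))
        se = np.sqrt(np.var(x, ddof=1) / n1 + np.var(y, ddof=1) / n2)
        df = float(res.df)
        tcrit = sps.t.ppf(0.975, df)
        sp = np.sqrt(
            ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1))
            / (n1 + n2 - 2)
        )
        return ComparisonResult(
            name, "welch_t", float(res.statistic), df, float(res.pvalue),
            (diff - tcrit * se, diff + tcrit * se), float(diff / sp), "cohens_d",
            n1 + n2, estimate=diff,
        )
    res = sps.mannwhitneyu(x, y, alternative="two-sided")
    est, ci = hodges_lehmann_ci_independent(x, y)
    return ComparisonResult(
        name, "rank_sum", float(res.statistic), None, float(res.pvalue), ci,
        rank_biserial_independent(x, y), "rank_biserial", n1 + n2, estimate=est,
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


def _attach_fdr(results: list[ComparisonResult]) -> list[ComparisonResult]:
    adj = bh_adjust([r.p_raw for r in results])
    out = []
    for r, p in zip(results, adj):
        out.append(
            ComparisonResult(
                r.name, r.test_used, r.statistic, r.df, r.p_raw, r.ci95,
                r.effect_size, r.effect_size_type, r.n, float(p), r.estimate,
            )
        )
    return out


def planned_comparisons(
    wide: pd.DataFrame,
    plan=WITHIN_PLAN,
    normality_alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Within-group planned pairwise comparisons with BH-FDR across the plan.

    For each pair (a, b) the tested quantity is b - a (so "early vs target"
    is negative when the target PSE is lower). The normality gate selects
    the paired t or the signed-rank path per contrast.
    """
    results = []
    for a, b in plan:
        diff = (wide[b] - wide[a]).to_numpy(dtype=float)
        results.append(
            one_sample_comparison(diff, f"{a}_vs_{b}", normality_alpha=normality_alpha)
        )
    return _attach_fdr(results)


def between_group_comparisons(
    wide: pd.DataFrame,
    levels=REACHING_TYPES,
    group_col: str = "group",
    normality_alpha: float = 0.05,
) -> list[ComparisonResult]:
    """Per-trial-type between-group contrasts with BH-FDR across the set."""
    groups = sorted(wide[group_col].unique())
    if len(groups) != 2:
        raise StatsError("between-group comparisons need exactly two groups")
    g1, g2 = groups
    results = []
    for level in levels:
        x = wide.loc[wide[group_col] == g1, level].to_numpy(dtype=float)
        y = wide.loc[wide[group_col] == g2, level].to_numpy(dtype=float)
        results.append(
            two_sample_comparison(
                x, y, f"{level}:{g1}_vs_{g2}", normality_alpha=normality_alpha
            )
        )
    return _attach_fdr(results)


# ---------------------------------------------------------------------------
# slopes


def fit_participant_slopes(wide: pd.DataFrame, span: str = "early_target") -> SlopeResult:
    """Per-participant OLS slope of normalized PSE over % reach time.

    ``span='early_target'`` fits early/mid/late (at their realized mean
    percent times) plus the target pinned at 100%; ``span='early_late'``
    restricts to the three within-reach phases. Participants with fewer
    than 3 finite points are dropped (logged in the result). Group tests
    (slope vs 0, and the between-group contrast when a ``group`` column is
    present) use the same normality-gated machinery as the planned
    comparisons.
    """
    if span == "early_target":
        phases = ["early", "mid", "late", "target"]
    elif span == "early_late":
        phases = ["early", "mid", "late"]
    else:
        raise StatsError(f"unknown span {span!r}")
    rows = []
    for pid, row in wide.iterrows():
        xs, ys = [], []
        for ph in phases:
            xv = 100.0 if ph == "target" else row.get(PCT_COLUMNS[ph], np.nan)
            yv = row.get(ph, np.nan)
            if np.isfinite(xv) and np.isfinite(yv):
                xs.append(xv)
                ys.append(yv)
        if len(xs) < 3:
            continue
        slope = float(np.polyfit(xs, ys, 1)[0])
        rec = {"participant": pid, "slope": slope}
        if "group" in wide.columns:
            rec["group"] = row["group"]
        rows.append(rec)
    slopes = pd.DataFrame(rows)
    result = SlopeResult(slopes=slopes, span=span)
    if slopes.empty:
        return result
    if "group" in slopes.columns:
        for g, sub in slopes.groupby("group"):
            result.group_tests[str(g)] = one_sample_comparison(
                sub["slope"].to_numpy(), f"slope_vs_zero[{g}]"
            )
        gs = sorted(slopes["group"].unique())
        if len(gs) == 2:
            result.between_test = two_sample_comparison(
                slopes.loc[slopes["group"] == gs[0], "slope"].to_numpy(),
                slopes.loc[slopes["group"] == gs[1], "slope"].to_numpy(),
                f"slope:{gs[0]}_vs_{gs[1]}",
            )
    else:
        result.group_tests["all"] = one_sample_comparison(
            slopes["slope"].to_numpy(), "slope_vs_zero"
        )
    return result


# ---------------------------------------------------------------------------
# Bayes factors


def _jzs_marginals(t: float, n: int, r: float, alternative: str):
    nu = n - 1
    m0 = sps.t.pdf(t, nu)

    sign = 1.0 if alternative == "greater" else -1.0

    def integrand(delta):
        return sps.nct.pdf(t, nu, sign * delta * np.sqrt(n)) * 2.0 * sps.cauchy.pdf(
            delta, scale=r
        )

    m1a, _ = integrate.quad(integrand, 0.0, 10 * r, points=[r, 5 * r], limit=200)
    m1b, _ = integrate.quad(integrand, 10 * r, np.inf, limit=200)
    return m0, m1a + m1b


def bayes_factor_one_sided(
    values: np.ndarray,
    mu: float = 0.0,
    alternative: str = "greater",
    cauchy_scale: float = 0.707,
) -> tuple[float, str]:
    """One-sided JZS Bayes factor BF0+ in favor of the null.

    The alternative places a half-Cauchy prior (scale 0.707 by default) on
    the standardized effect in the direction given by ``alternative``; the
    Bayes factor is the ratio of marginal likelihoods of the one-sample t
    statistic under the null and that alternative, computed by numerical
    integration. Values above 1 favor the null; the conventional evidence
    bands (1-3 anecdotal, 3-10 moderate, >10 strong) are attached as a
    label.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2:
        raise StatsError("Bayes factor needs n >= 2")
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise StatsError("zero variance sample")
    if alternative not in ("greater", "less"):
        raise StatsError(f"unknown alternative {alternative!r}")
    t = float((np.mean(x) - mu) / (sd / np.sqrt(n)))
    m0, m1 = _jzs_marginals(t, n, cauchy_scale, alternative)
    bf0 = m0 / m1
    if bf0 < 1:
        label = "supports_alternative"
    elif bf0 < 3:
        label = "anecdotal"
    elif bf0 < 10:
        label = "moderate"
    else:
        label = "strong"
    return float(bf0), label


def bayes_factor_two_sided_t(t: float, n: int, cauchy_scale: float = 0.707) -> float:
    """Two-sided JZS BF10 from a one-sample t statistic (quadrature)."""
    nu = n - 1
    m0 = sps.t.pdf(t, nu)

    def integrand(delta):
        return sps.nct.pdf(t, nu, delta * np.sqrt(n)) * sps.cauchy.pdf(
            delta, scale=cauchy_scale
        )

    m1, _ = integrate.quad(integrand, -np.inf, np.inf, limit=200)
    return m1 / m0
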