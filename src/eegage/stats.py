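"""Group statistics over brain-age predictions.

Covers the analysis layer run on prediction tables: prediction-accuracy
metrics (Pearson r, R^2, MAE), the within-group paired t-test of BA against
CA (equivalently a one-sample t-test of the gaps against zero), the
between-group comparison of gaps, a one-way repeated-measures ANOVA across
the five scalp regions with Bonferroni-adjusted paired post-hocs, and
age/sex-matched control sampling.

Conventions: all p-values two-sided; Cohen's d for the paired test is
mean(gap)/sd(gap); R^2 is the squared Pearson correlation of predicted vs
observed age (a 1 - SSE/SST variant is available); the independent-samples
test defaults to Welch's unequal-variance form.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps


@dataclass
class MetricReport:
    """Prediction accuracy for one regional model."""

    region: str
    r: float
    p: float
    r2: float
    mae_years: float
    n: int


@dataclass
class GapTestReport:
    """Paired BA-vs-CA test summarized over one region."""

    region: str
    mean_gap_years: float
    sd_gap_years: float
    t: float
    p: float
    d: float
    n: int


@dataclass
class AnovaReport:
    """One-way repeated-measures ANOVA over regions plus pairwise post-hocs."""

    f: float
    df1: int
    df2: int
    p: float
    partial_eta_sq: float
    posthoc: pd.DataFrame


def correlation_metrics(
    ba, ca, region: str = "whole", r2_definition: str = "pearson"
) -> MetricReport:
    """Pearson r (two-sided p), R^2 and MAE of predicted vs chronological age."""
    ba = np.asarray(ba, dtype=np.float64)
    ca = np.asarray(ca, dtype=np.float64)
    if ba.shape != ca.shape or ba.ndim != 1:
        raise ValueError("ba and ca must be equal-length 1-D vectors")
    if ba.size < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(ba) == 0 or np.std(ca) == 0:
        raise ValueError("zero variance in predicted or observed ages")
    res = sps.pearsonr(ba, ca)
    if r2_definition == "pearson":
        r2 = float(res.statistic**2)
    elif r2_definition == "explained_variance":
        sst = float(((ca - ca.mean()) ** 2).sum())
        r2 = 1.0 - float(((ba - ca) ** 2).sum()) / sst
    else:
        raise ValueError(f"unknown r2_definition {r2_definition!r}")
    return MetricReport(
        region=region,
        r=float(res.statistic),
        p=float(res.pvalue),
        r2=r2,
        mae_years=float(np.abs(ba - ca).mean()),
        n=ba.size,
    )


def paired_gap_test(gaps, region: str = "whole") -> GapTestReport:
    """One-sample t-test of per-subject gaps against zero (paired BA vs CA)."""
    gaps = np.asarray(gaps, dtype=np.float64)
    if gaps.size < 2:
        raise ValueError("need at least 2 gaps")
    sd = float(gaps.std(ddof=1))
    if sd == 0:
        raise ValueError("gaps have zero variance; t-statistic undefined")
    res = sps.ttest_1samp(gaps, 0.0)
    mean = float(gaps.mean())
    return GapTestReport(
        region=region,
        mean_gap_years=mean,
        sd_gap_years=sd,
        t=float(res.statistic),
        p=float(res.pvalue),
        d=mean / sd,
        n=gaps.size,
    )


def paired_gap_test_from_summary(
    mean_gap: float, sd_gap: float, n: int, region: str = "whole"
) -> GapTestReport:
    """Recompute the paired t-test from a printed (mean, SD, n) summary.

    t = mean / (sd / sqrt(n)) with df = n - 1; lets published group tables be
    checked without subject-level data.
    """
    if n < 2:
        raise ValueError("need n >= 2")
    if sd_gap <= 0:
        raise ValueError("SD must be positive")
    t = mean_gap / (sd_gap / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return GapTestReport(
        region=region,
        mean_gap_years=float(mean_gap),
        sd_gap_years=float(sd_gap),
        t=float(t),
        p=float(p),
        d=float(mean_gap / sd_gap),
        n=int(n),
    )


def independent_gap_test(gaps_a, gaps_b, equal_var: bool = False) -> tuple[float, float]:
    """Two-sample t-test of gaps between groups (Welch by default)."""
    a = np.asarray(gaps_a, dtype=np.float64)
    b = np.asarray(gaps_b, dtype=np.float64)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 values")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        raise ValueError("both groups have zero variance")
    res = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def regional_anova(gap_matrix, region_names=None) -> AnovaReport:
    """One-way within-subject ANOVA of gaps across regions.

    ``gap_matrix`` is subjects x regions, complete (no missing cells).
    df1 = k-1, df2 = (k-1)(n-1); no sphericity correction. Partial eta^2 is
    SS_effect / (SS_effect + SS_error). Post-hoc: all pairwise paired
    t-tests with Bonferroni adjustment (p times the number of comparisons,
    capped at 1).
    """
    g = np.asarray(gap_matrix, dtype=np.float64)
    if g.ndim != 2:
        raise ValueError("gap_matrix must be subjects x regions")
    if np.any(~np.isfinite(g)):
        raise ValueError("gap_matrix has missing or non-finite cells")
    n, k = g.shape
    if n < 3 or k < 2:
        raise ValueError("need >= 3 subjects and >= 2 regions")
    names = list(region_names) if region_names is not None else [f"r{i}" for i in range(k)]
    if len(names) != k:
        raise ValueError("region_names length mismatch")

    import pingouin as pg

    long = pd.DataFrame(g, columns=names)
    long["subject"] = np.arange(n)
    long = long.melt(id_vars="subject", var_name="region", value_name="gap")
    with np.errstate(divide="ignore", invalid="ignore"):
        aov = pg.rm_anova(
            data=long, dv="gap", within="region", subject="subject", detailed=True
        )
    ss_effect = float(aov.loc[0, "SS"])
    ss_error = float(aov.loc[1, "SS"])
    # zero between-region effect (up to float dust relative to the data scale)
    ss_scale = float(((g - g.mean()) ** 2).sum())
    if ss_effect <= 1e-12 * max(ss_scale, 1e-300):
        f_stat, p, ss_effect = 0.0, 1.0, 0.0
    else:
        f_stat = float(aov.loc[0, "F"])
        p = float(aov.loc[0, "p_unc" if "p_unc" in aov.columns else "p-unc"])
    df1, df2 = k - 1, (k - 1) * (n - 1)
    eta = ss_effect / (ss_effect + ss_error) if (ss_effect + ss_error) > 0 else 0.0

    n_pairs = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        res = sps.ttest_rel(g[:, i], g[:, j])
        rows.append(
            {
                "region_a": names[i],
                "region_b": names[j],
                "mean_diff": float((g[:, i] - g[:, j]).mean()),
                "t": float(res.statistic),
                "p_uncorrected": float(res.pvalue),
                "p_bonferroni": float(min(1.0, res.pvalue * n_pairs)),
            }
        )
    return AnovaReport(
        f=f_stat, df1=df1, df2=df2, p=p, partial_eta_sq=float(eta),
        posthoc=pd.DataFrame(rows),
    )


def matched_control_sample(
    healthy: pd.DataFrame,
    cases: pd.DataFrame,
    seed: int = 0,
    age_column: str = "ca_years",
    sex_column: str | None = "sex",
) -> pd.DataFrame:
    """Select one healthy control per case, matched on age within sex strata.

    Cases are visited in seeded random order; each takes the nearest-age
    remaining control of the same sex (all strata pooled when the sex column
    is absent). Sampling is without replacement, so the pool must be at least
    as large as the case list in every stratum.
    """
    if len(healthy) < len(cases):
        raise ValueError("healthy pool smaller than the case group")
    rng = np.random.default_rng(seed)
    use_sex = sex_column is not None and sex_column in healthy.columns and sex_column in cases.columns
    pool = healthy.reset_index(drop=True)
    available = np.ones(len(pool), dtype=bool)
    order = rng.permutation(len(cases))
    chosen: list[int] = []
    for case_pos in order:
        case = cases.iloc[case_pos]
        candidates = available.copy()
        if use_sex:
            candidates &= (pool[sex_column] == case[sex_column]).to_numpy()
        if not candidates.any():
            stratum = f" in sex stratum {case[sex_column]!r}" if use_sex else ""
            raise ValueError(f"control pool exhausted{stratum}")
        dist = np.abs(pool[age_column].to_numpy() - float(case[age_column]))
        dist[~candidates] = np.inf
        pick = int(np.argmin(dist))
        available[pick] = False
        chosen.append(pick)
    return pool.iloc[sorted(chosen)].reset_index(drop=True)


def metrics_report_frame(reports: list[MetricReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])


def gap_report_frame(reports: list[GapTestReport]) -> pd.DataFrame:
    return pd.DataFrame([vars(r) for r in reports])
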