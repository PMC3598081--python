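"""Replication-stage statistics on per-CpG amplicon methylation.

Candidate CpG islands from the screening stage are fine-mapped in an
independent cohort with per-CpG methylation fractions (MassARRAY-style
measurements). This module provides the replication statistics: per-sample
mean CpG methylation, two-group Student's t-tests (pooled-variance unpaired
or paired, e.g. pre/post heart transplantation), one-way ANOVA with
Dunnett's many-to-one comparison, calibration against methylation standards
(0-100%), the screening/replication direction-consistency report, and
sex-composition matched subsampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "AmpliconPanel",
    "TTestResult",
    "DunnettResult",
    "CalibrationResult",
    "mean_cpg_methylation",
    "group_ttest",
    "anova_dunnett",
    "calibration_check",
    "direction_consistency",
    "match_subsample",
]


@dataclass
class AmpliconPanel:
    """Per-CpG methylation fractions for candidate CGIs.

    ``data`` is tidy: columns (candidate, cpg_unit, sample, fraction);
    ``metadata`` has one row per sample with at least a ``group`` column
    ('case' / 'control') and optionally ``sex`` and ``timepoint``.
    """

    data: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"candidate", "cpg_unit", "sample", "fraction"}
        if not required <= set(self.data.columns):
            raise ValueError(f"panel data needs columns {sorted(required)}")
        frac = self.data["fraction"].to_numpy(dtype=float)
        valid = frac[~np.isnan(frac)]
        if ((valid < 0) | (valid > 1)).any():
            raise ValueError("fractions must lie in [0, 1]")
        meta_samples = set(self.metadata["sample"])
        missing = set(self.data["sample"]) - meta_samples
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")

    @property
    def candidates(self) -> list[str]:
        return sorted(self.data["candidate"].unique())

    def groups(self) -> pd.Series:
        return self.metadata.set_index("sample")["group"]


def mean_cpg_methylation(panel: AmpliconPanel, candidate: str) -> pd.DataFrame:
    """Per-sample mean methylation over the candidate's CpG units.

    Missing (NaN) units are skipped; the number of units contributing per
    sample is recorded. Returns a DataFrame (sample, mean_fraction, n_units).
    """
    sub = panel.data[panel.data["candidate"] == candidate]
    if sub.empty:
        raise ValueError(f"candidate {candidate!r} not in panel")
    agg = sub.groupby("sample")["fraction"].agg(
        mean_fraction="mean", n_units="count"
    )
    return agg.reset_index()


@dataclass
class TTestResult:
    t: float
    p: float
    mean_diff: float
    degenerate: bool = False


def group_ttest(
    values_case, values_control, paired: bool = False
) -> TTestResult:
    """Two-sided Student's t-test (pooled variance unpaired; paired on
    differences). Zero-variance inputs are flagged degenerate: identical
    groups (or all-zero paired differences) return t = 0, p = 1.
    """
    a = np.asarray(values_case, dtype=float)
    b = np.asarray(values_control, dtype=float)
    if paired:
        if len(a) != len(b):
            raise ValueError("paired groups must have equal length")
        if len(a) < 2:
            raise ValueError("need at least 2 pairs")
        diff = a - b
        if np.all(diff == 0):
            return TTestResult(0.0, 1.0, 0.0, degenerate=True)
        res = stats.ttest_rel(a, b)
        return TTestResult(float(res.statistic), float(res.pvalue), float(diff.mean()))
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both groups need at least 2 samples")
    md = float(a.mean() - b.mean())
    if np.all(a == a[0]) and np.all(b == b[0]):
        if a[0] == b[0]:
            return TTestResult(0.0, 1.0, 0.0, degenerate=True)
        return TTestResult(np.inf if md > 0 else -np.inf, 0.0, md, degenerate=True)
    res = stats.ttest_ind(a, b, equal_var=True)
    return TTestResult(float(res.statistic), float(res.pvalue), md)


@dataclass
class DunnettResult:
    f_statistic: float
    anova_p: float
    t_statistics: np.ndarray  # per treatment vs control
    adjusted_p: np.ndarray
    df: int
    mc_draws: int


def anova_dunnett(
    groups: list[np.ndarray],
    mc_draws: int = 100_000,
    seed: int | None = None,
) -> DunnettResult:
    """One-way ANOVA plus Dunnett many-to-one comparison against groups[0].

    Each treatment i gets t_i = (mean_i - mean_0) / (s_p sqrt(1/n_i + 1/n_0))
    with the pooled within-group standard deviation s_p on N - g degrees of
    freedom. The two-sided adjusted p-value P(max_j |T_j| >= |t_i|) under
    the joint null is estimated by seeded Monte-Carlo from the
    equicorrelated multivariate t: T_j = (sqrt(l_j) Z0 + sqrt(1-l_j) Z_j) / W
    with l_j = n_j / (n_j + n_0) and W = sqrt(chi2_df / df), which
    reproduces corr(T_i, T_j) = sqrt(l_i l_j).
    """
    if len(groups) < 2:
        raise ValueError("need a control plus at least one treatment group")
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) < 2 for g in arrs):
        raise ValueError("every group needs at least 2 values")
    N = sum(len(g) for g in arrs)
    g = len(arrs)
    df = N - g
    ss_within = sum(((x - x.mean()) ** 2).sum() for x in arrs)
    if ss_within == 0:
        f_stat, anova_p = 0.0, 1.0
        if any(x.mean() != arrs[0].mean() for x in arrs[1:]):
            f_stat, anova_p = np.inf, 0.0
    else:
        f_stat, anova_p = stats.f_oneway(*arrs)
    sp2 = ss_within / df if df > 0 else 0.0
    n0 = len(arrs[0])
    tstats = np.array(
        [
            (x.mean() - arrs[0].mean())
            / np.sqrt(sp2 * (1 / len(x) + 1 / n0))
            if sp2 > 0
            else (0.0 if x.mean() == arrs[0].mean() else np.inf)
            for x in arrs[1:]
        ]
    )
    lam = np.array([len(x) / (len(x) + n0) for x in arrs[1:]])
    rng = np.random.default_rng(seed)
    z0 = rng.standard_normal(mc_draws)
    zi = rng.standard_normal((mc_draws, len(lam)))
    w = np.sqrt(rng.chisquare(df, mc_draws) / df)
    T = (np.sqrt(lam) * z0[:, None] + np.sqrt(1 - lam) * zi) / w[:, None]
    max_abs = np.abs(T).max(axis=1)
    adj = np.array([np.mean(max_abs >= abs(t)) for t in tstats])
    adj = np.clip(adj, 1.0 / mc_draws, 1.0)
    return DunnettResult(float(f_stat), float(anova_p), tstats, adj, df, mc_draws)


@dataclass
class CalibrationResult:
    slope: float
    intercept: float
    r_squared: float
    unbiased: bool


def calibration_check(
    nominal_percent,
    measured_percent,
    slope_band: tuple[float, float] = (0.9, 1.1),
    max_abs_intercept: float = 5.0,
) -> CalibrationResult:
    """Least-squares line of measured on nominal methylation standards.

    Standards are nominally 0/20/40/60/80/100% methylated DNA; amplification
    is declared unbiased when the slope falls in ``slope_band`` and the
    intercept within ``max_abs_intercept`` percentage points.
    """
    x = np.asarray(nominal_percent, dtype=float)
    y = np.asarray(measured_percent, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 standards")
    if not np.all(np.diff(x) > 0):
        raise ValueError("nominal levels must be strictly increasing")
    fit = stats.linregress(x, y)
    unbiased = (
        slope_band[0] <= fit.slope <= slope_band[1]
        and abs(fit.intercept) <= max_abs_intercept
    )
    return CalibrationResult(
        float(fit.slope), float(fit.intercept), float(fit.rvalue**2), unbiased
    )


def direction_consistency(
    screen: pd.DataFrame,
    replication: pd.DataFrame,
    alpha: float = 0.05,
    zero_tol: float = 1e-12,
) -> dict:
    """Compare screening directions with replication effects per candidate.

    ``screen`` needs columns (gene_id, median_diff); ``replication`` needs
    (gene_id, mean_diff, p). A candidate is same-direction when both effects
    are nonzero with equal sign (a zero replication difference counts as not
    consistent; ``zero_tol`` guards against floating dust), and significant
    when additionally p < alpha. Candidates missing from either table are
    flagged and excluded from the counts.
    """
    s = screen.set_index("gene_id")
    r = replication.set_index("gene_id")
    rows = []
    for gene in r.index:
        if gene not in s.index:
            rows.append({"gene_id": gene, "missing": True, "same_direction": False,
                         "significant": False})
            continue
        sd = float(s.loc[gene, "median_diff"])
        rd = float(r.loc[gene, "mean_diff"])
        same = abs(sd) > zero_tol and abs(rd) > zero_tol and np.sign(sd) == np.sign(rd)
        sig = bool(same and float(r.loc[gene, "p"]) < alpha)
        rows.append(
            {
                "gene_id": gene,
                "missing": False,
                "screen_diff": sd,
                "replication_diff": rd,
                "replication_p": float(r.loc[gene, "p"]),
                "same_direction": bool(same),
                "significant": sig,
            }
        )
    table = pd.DataFrame(rows)
    ok = table[~table["missing"]]
    return {
        "n_candidates": int(len(ok)),
        "n_same_direction": int(ok["same_direction"].sum()),
        "n_significant": int(ok["significant"].sum()),
        "table": table,
    }


def match_subsample(
    metadata: pd.DataFrame,
    mode: str = "ratio",
    target_female_fraction: dict[str, float] | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Subsample to a requested sex composition per group.

    ``metadata`` needs columns (sample, group, sex) with sex in {'F', 'M'}.
    mode='ratio' keeps, per group, the largest subset whose female fraction
    matches ``target_female_fraction[group]`` after rounding; mode
    'one_to_one' keeps min(#F, #M) of each sex per group. Selection within a
    sex is a seeded uniform draw, so the subset is reproducible. Raises with
    the available counts when a ratio is infeasible.
    """
    if mode not in ("ratio", "one_to_one"):
        raise ValueError("mode must be 'ratio' or 'one_to_one'")
    rng = np.random.default_rng(seed)
    kept = []
    for grp, sub in metadata.groupby("group"):
        females = sub[sub["sex"] == "F"]
        males = sub[sub["sex"] == "M"]
        if mode == "one_to_one":
            n_keep = min(len(females), len(males))
            n_f = n_m = n_keep
        else:
            if target_female_fraction is None or grp not in target_female_fraction:
                raise ValueError(f"no target female fraction for group {grp!r}")
            f = target_female_fraction[grp]
            n_f = n_m = None
            for n in range(len(sub), 0, -1):
                need_f = round(n * f)
                if 0 < f < 1 and (need_f == 0 or need_f == n):
                    continue  # a mixed target must keep both sexes represented
                if need_f <= len(females) and n - need_f <= len(males):
                    n_f, n_m = need_f, n - need_f
                    break
            if n_f is None:
                raise ValueError(
                    f"infeasible ratio {f} for group {grp!r}: "
                    f"{len(females)}F / {len(males)}M available"
                )
        if n_f == len(females) and n_m == len(males):
            kept.append(sub)
            continue
        f_idx = rng.choice(len(females), size=n_f, replace=False)
        m_idx = rng.choice(len(males), size=n_m, replace=False)
        kept.append(females.iloc[np.sort(f_idx)])
        kept.append(males.iloc[np.sort(m_idx)])
    return pd.concat(kept).sort_index().reset_index(drop=True)
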