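"""Gene-level differential-methylation screen and candidate selection.

Probe-level beta values are averaged per gene (one value per sample per
gene), and each gene is tested with a two-tailed Wilcoxon rank-sum test
between cases and controls — methylation fractions are bounded and usually
far from normal, so the rank test is the appropriate screen. The per-gene
effect is the case-minus-control difference of group median betas, whose
sign classifies genes as hyper- or hypomethylated in cases.

Exactness policy for the rank-sum p-value:

* no ties, combined n <= 25 — exact, from the full null distribution of the
  rank sum (subset-sum dynamic program, cached per group-size pair);
* ties present, combined n <= 12 — exact, by enumerating all C(n, n1)
  group assignments of the observed (tied) ranks;
* otherwise — normal approximation with the standard tie correction.

Both small-cohort screens of a typical two-stage design (e.g. 9 vs 8)
therefore use exact p-values throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ScreeningResult",
    "SelectionRules",
    "aggregate_gene_beta",
    "platform_coverage",
    "rank_sum_test",
    "wilcoxon_gene_screen",
    "classify_direction",
    "select_candidates",
]

EXACT_MAX_N = 25  # combined-sample limit for the tie-free exact distribution
TIE_ENUM_MAX_N = 12  # combined-sample limit for tie-aware full enumeration


def aggregate_gene_beta(
    beta: pd.DataFrame,
    annotation: pd.DataFrame,
    restrict_heart: bool = False,
) -> pd.DataFrame:
    """Mean beta per gene per sample.

    ``annotation`` must carry one row per probe with columns ``probe_id``,
    ``gene_id`` and optionally ``heart_expressed``; every probe of ``beta``
    must be annotated. With ``restrict_heart``, probes of genes lacking the
    heart-expression flag are dropped before aggregation (a gene left with
    zero probes is simply absent from the output).
    """
    ann = annotation.set_index("probe_id")
    missing = beta.index.difference(ann.index)
    if len(missing):
        raise ValueError(f"unannotated probes: {list(missing[:5])}")
    ann = ann.loc[beta.index]
    if (ann["gene_id"].astype(str) == "").any():
        raise ValueError("empty gene ids in annotation")
    keep = np.ones(len(ann), dtype=bool)
    if restrict_heart:
        if "heart_expressed" not in ann.columns:
            raise ValueError("annotation lacks heart_expressed flag")
        keep = ann["heart_expressed"].astype(bool).to_numpy()
    sub = beta.loc[keep]
    genes = ann.loc[keep, "gene_id"]
    out = sub.groupby(genes.to_numpy()).mean()
    out.index.name = "gene_id"
    return out.sort_index()


def platform_coverage(annotated_genes: int, covered_genes: int) -> float:
    """Percentage of annotated genes covered by the assay, to one decimal."""
    if annotated_genes <= 0:
        raise ValueError("annotated gene count must be positive")
    if not 0 <= covered_genes <= annotated_genes:
        raise ValueError("covered count must lie in [0, annotated]")
    return round(100.0 * covered_genes / annotated_genes, 1)


@lru_cache(maxsize=64)
def _ranksum_counts(n1: int, n2: int) -> tuple[np.ndarray, int]:
    """Null distribution of the group-1 rank sum for tie-free ranks 1..n1+n2.

    Returns (counts indexed by rank sum 0..n1*(n1+n2), C(n, n1)). Counts are
    exact: dp over 'which ranks are in group 1' (subset-sum recurrence).
    """
    n = n1 + n2
    max_sum = n1 * n  # loose upper bound on the rank sum
    dp = np.zeros((n1 + 1, max_sum + 1), dtype=object)
    dp[0][0] = 1
    for r in range(1, n + 1):
        for h in range(min(n1, r), 0, -1):
            row = dp[h]
            src = dp[h - 1]
            for s in range(max_sum - r, -1, -1):
                if src[s]:
                    row[s + r] += src[s]
    counts = np.array([int(x) for x in dp[n1]], dtype=float)
    return counts, math.comb(n, n1)


def _exact_p_noties(w: float, n1: int, n2: int) -> float:
    counts, total = _ranksum_counts(n1, n2)
    sums = np.arange(len(counts))
    p_le = counts[sums <= w + 1e-9].sum() / total
    p_ge = counts[sums >= w - 1e-9].sum() / total
    return min(1.0, 2.0 * min(p_le, p_ge))


def _exact_p_ties(ranks: np.ndarray, w: float, n1: int) -> float:
    """Tie-aware exact two-sided p by enumerating all group assignments."""
    n = len(ranks)
    sums = np.array([sum(ranks[list(c)]) for c in combinations(range(n), n1)])
    p_le = np.mean(sums <= w + 1e-9)
    p_ge = np.mean(sums >= w - 1e-9)
    return min(1.0, 2.0 * min(p_le, p_ge))


def _normal_p(ranks: np.ndarray, w: float, n1: int) -> float:
    """Tie-corrected normal approximation (no continuity correction)."""
    n = len(ranks)
    n2 = n - n1
    mu = n1 * (n + 1) / 2.0
    _vals, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    z = (w - mu) / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


def rank_sum_test(case: np.ndarray, control: np.ndarray) -> float:
    """Two-tailed Wilcoxon rank-sum p-value with the exactness policy above."""
    case = np.asarray(case, dtype=float)
    control = np.asarray(control, dtype=float)
    n1, n2 = len(case), len(control)
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need at least 2 samples")
    pooled = np.concatenate([case, control])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = stats.rankdata(pooled)
    w = float(ranks[:n1].sum())
    n = n1 + n2
    has_ties = len(np.unique(pooled)) < n
    if not has_ties and n <= EXACT_MAX_N:
        return _exact_p_noties(w, n1, n2)
    if has_ties and n <= TIE_ENUM_MAX_N:
        return _exact_p_ties(ranks, w, n1)
    return _normal_p(ranks, w, n1)


@dataclass
class ScreeningResult:
    """Per-gene screen outcome."""

    gene_id: str
    p_value: float
    median_diff: float
    direction: str
    n_probes: int = 1
    degenerate: bool = False
    candidate_rank: int | None = None


def classify_direction(median_diff: float, epsilon: float = 0.0) -> str:
    """'hyper' above +epsilon, 'hypo' below -epsilon, else 'unchanged'."""
    if epsilon < 0:
        raise ValueError("epsilon must be nonnegative")
    if median_diff > epsilon:
        return "hyper"
    if median_diff < -epsilon:
        return "hypo"
    return "unchanged"


def wilcoxon_gene_screen(
    gene_matrix: pd.DataFrame,
    groups: pd.Series | dict,
    epsilon: float = 0.0,
    n_probes: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-gene two-tailed rank-sum screen of cases against controls.

    ``groups`` maps sample id -> 'case' | 'control'. Returns a DataFrame
    (gene_id, p_value, median_diff, direction, n_probes, degenerate) sorted
    by gene id. Constant genes are reported with p = 1 and flagged
    degenerate.
    """
    groups = pd.Series(groups)
    samples = [s for s in gene_matrix.columns if s in groups.index]
    if len(samples) < len(gene_matrix.columns):
        raise ValueError("samples without group labels")
    case_cols = [s for s in samples if groups[s] == "case"]
    ctrl_cols = [s for s in samples if groups[s] == "control"]
    if len(case_cols) < 2 or len(ctrl_cols) < 2:
        raise ValueError("both groups need at least 2 samples")
    rows = []
    case_X = gene_matrix[case_cols].to_numpy(dtype=float)
    ctrl_X = gene_matrix[ctrl_cols].to_numpy(dtype=float)
    for idx, gene in enumerate(gene_matrix.index):
        case_v, ctrl_v = case_X[idx], ctrl_X[idx]
        pooled = np.concatenate([case_v, ctrl_v])
        degenerate = bool(np.all(pooled == pooled[0]))
        p = 1.0 if degenerate else rank_sum_test(case_v, ctrl_v)
        md = float(np.median(case_v) - np.median(ctrl_v))
        rows.append(
            {
                "gene_id": gene,
                "p_value": p,
                "median_diff": md,
                "direction": classify_direction(md, epsilon),
                "n_probes": int(n_probes[gene]) if n_probes is not None else 1,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows).sort_values("gene_id").reset_index(drop=True)


@dataclass
class SelectionRules:
    """Candidate-selection rules for the replication stage.

    The selected set is the union of the ``top_n_by_p`` most significant
    genes and the ``top_n_per_direction`` largest absolute-median-difference
    genes within each direction, after the threshold/flag filters; ties are
    broken lexicographically by gene id.
    """

    p_max: float | None = None
    min_abs_diff: float | None = None
    require_cgi: bool = False
    require_heart: bool = False
    top_n_per_direction: int = 0
    top_n_by_p: int = 0


def select_candidates(
    results: pd.DataFrame,
    rules: SelectionRules,
    gene_flags: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Deterministic ordered candidate list for replication fine-mapping.

    ``gene_flags`` (optional) carries per-gene ``has_cgi`` /
    ``heart_expressed`` booleans indexed by gene id, used by the
    ``require_*`` rules. The output is ordered by (p_value, gene_id) and
    carries a 1-based ``candidate_rank``.
    """
    df = results.copy()
    if rules.p_max is not None:
        df = df[df["p_value"] <= rules.p_max]
    if rules.min_abs_diff is not None:
        df = df[df["median_diff"].abs() >= rules.min_abs_diff]
    if rules.require_cgi or rules.require_heart:
        if gene_flags is None:
            raise ValueError("flag-based rules need gene_flags")
        flags = gene_flags.reindex(df["gene_id"])
        if rules.require_cgi:
            df = df[flags["has_cgi"].fillna(False).to_numpy(dtype=bool)]
            flags = gene_flags.reindex(df["gene_id"])
        if rules.require_heart:
            df = df[flags["heart_expressed"].fillna(False).to_numpy(dtype=bool)]
    chosen: set[str] = set()
    if rules.top_n_by_p > 0:
        by_p = df.sort_values(["p_value", "gene_id"]).head(rules.top_n_by_p)
        chosen |= set(by_p["gene_id"])
    if rules.top_n_per_direction > 0:
        for direction in ("hyper", "hypo"):
            sub = df[df["direction"] == direction].copy()
            sub["absd"] = sub["median_diff"].abs()
            top = sub.sort_values(["absd", "gene_id"], ascending=[False, True]).head(
                rules.top_n_per_direction
            )
            chosen |= set(top["gene_id"])
    if rules.top_n_by_p == 0 and rules.top_n_per_direction == 0:
        chosen = set(df["gene_id"])
    out = (
        df[df["gene_id"].isin(chosen)]
        .sort_values(["p_value", "gene_id"])
        .reset_index(drop=True)
    )
    out["candidate_rank"] = np.arange(1, len(out) + 1)
    return out
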