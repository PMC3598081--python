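"""Synthetic-data generators with known ground truth for every pipeline input.

The generators emulate a two-stage cardiac methylation study: a screening
cohort of 9 cases vs 8 controls profiled genome-wide on a beta-value array
(~2000 genes, ~90 truly differential with about one-third hypermethylated),
and a replication cohort of 30 cases vs 28 controls fine-mapped with
per-CpG amplicon measurements on 20 candidates, of which 12 replicate the
screening direction. Beta values are drawn from beta distributions
parameterized by mean and precision (concentration), so all methylation
fractions are bounded in [0, 1] by construction rather than by clipping;
probe-level heterogeneity is a small Gaussian perturbation of the gene mean
(clamped into the open unit interval so beta parameters stay valid). Bead
channel intensities, bisulfite clone sequences and qPCR CT tables complete
the input surface. All generators are deterministic given their seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .seqtools import bisulfite_convert, cpg_positions
from .preprocess import SignalMatrix

__all__ = [
    "CohortDesign",
    "BetaDataset",
    "gen_beta_matrix",
    "gen_bead_signals",
    "gen_amplicon_panel",
    "gen_bisulfite_clones",
    "gen_ct_table",
]

_MEAN_MARGIN = 0.005  # probe means are kept inside (margin, 1-margin)


@dataclass(frozen=True)
class CohortDesign:
    """Screening-cohort design with planted differential genes.

    ``delta`` is the signed mean beta shift of planted genes in cases
    (hyper genes +delta, hypo genes -delta); ``precision`` is the beta
    concentration (larger = less sampling noise); ``hyper_fraction`` sets
    how many planted genes are hypermethylated in cases (default one third,
    the remainder hypomethylated). ``probes_per_gene`` is either a fixed
    count or an inclusive (low, high) range sampled uniformly per gene.
    """

    n_cases: int = 9
    n_controls: int = 8
    n_genes: int = 2000
    probes_per_gene: int | tuple[int, int] = (1, 3)
    n_planted: int = 90
    delta: float = 0.2
    precision: float = 50.0
    baseline_range: tuple[float, float] = (0.25, 0.75)
    hyper_fraction: float = 1 / 3
    probe_sd: float = 0.02
    heart_fraction: float = 0.9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cases < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 cases and 2 controls")
        if not 0 <= self.n_planted <= self.n_genes:
            raise ValueError("n_planted must lie in [0, n_genes]")
        lo, hi = self.baseline_range
        if not (0 < lo <= hi < 1):
            raise ValueError("baseline_range must lie inside (0, 1)")
        d = abs(self.delta)
        if lo - d <= 0 or hi + d >= 1:
            raise ValueError(
                f"baseline_range {self.baseline_range} with delta {self.delta} "
                "pushes planted group means outside (0, 1); narrow the range "
                "or shrink delta"
            )
        if self.precision <= 0:
            raise ValueError("precision must be positive")

    @property
    def n_samples(self) -> int:
        return self.n_cases + self.n_controls


@dataclass
class BetaDataset:
    """Beta matrix with its probe annotation and sample metadata."""

    beta: pd.DataFrame  # probes x samples
    annotation: pd.DataFrame  # probe_id, gene_id, cgi_id, heart_expressed
    metadata: pd.DataFrame  # sample, group, sex, age, LVEF

    def groups(self) -> pd.Series:
        return self.metadata.set_index("sample")["group"]


def _beta_draw(rng: np.random.Generator, mean, precision: float, size=None):
    mean = np.asarray(mean, dtype=float)
    return rng.beta(mean * precision, (1.0 - mean) * precision, size=size)


def _sample_metadata(
    rng: np.random.Generator,
    n_cases: int,
    n_controls: int,
    female_fraction: tuple[float, float] = (0.25, 0.4),
) -> pd.DataFrame:
    """Case/control sample sheet with sex, age and ejection fraction.

    Cases carry a reduced LVEF (<45%, the usual dilated-cardiomyopathy
    inclusion criterion) and skew male; controls have normal LVEF.
    """
    rows = []
    for grp, n, ffrac in (
        ("case", n_cases, female_fraction[0]),
        ("control", n_controls, female_fraction[1]),
    ):
        n_f = round(n * ffrac)
        sexes = ["F"] * n_f + ["M"] * (n - n_f)
        for i in range(n):
            lvef = rng.uniform(15, 40) if grp == "case" else rng.uniform(55, 70)
            rows.append(
                {
                    "sample": f"{grp}_{i + 1:02d}",
                    "group": grp,
                    "sex": sexes[i],
                    "age": round(float(rng.normal(52, 11)), 1),
                    "LVEF": round(float(lvef), 1),
                }
            )
    return pd.DataFrame(rows)


def gen_beta_matrix(design: CohortDesign) -> tuple[BetaDataset, pd.DataFrame]:
    """Generate a probes x samples beta matrix with planted differential genes.

    Returns the dataset plus a truth table (gene_id, is_differential,
    direction, true_delta). With delta = 0 no gene is flagged differential
    and group means are equal in expectation.
    """
    rng = np.random.default_rng(design.seed)
    genes = [f"G{i + 1:05d}" for i in range(design.n_genes)]
    meta = _sample_metadata(rng, design.n_cases, design.n_controls)
    samples = list(meta["sample"])
    is_case = (meta["group"] == "case").to_numpy()

    planted_idx = rng.choice(design.n_genes, size=design.n_planted, replace=False)
    planted = np.zeros(design.n_genes, dtype=bool)
    planted[planted_idx] = True
    n_hyper = round(design.n_planted * design.hyper_fraction)
    hyper_idx = set(planted_idx[:n_hyper])
    true_delta = np.zeros(design.n_genes)
    for gi in planted_idx:
        true_delta[gi] = design.delta if gi in hyper_idx else -design.delta

    effective = planted & (true_delta != 0)
    baselines = rng.uniform(*design.baseline_range, size=design.n_genes)
    if isinstance(design.probes_per_gene, int):
        probe_counts = np.full(design.n_genes, design.probes_per_gene)
    else:
        lo, hi = design.probes_per_gene
        probe_counts = rng.integers(lo, hi + 1, size=design.n_genes)
    heart = rng.random(design.n_genes) < design.heart_fraction
    heart[planted] = True  # planted effects live in heart-expressed genes

    probe_rows, ann_rows = [], []
    values = []
    for gi, gene in enumerate(genes):
        for pj in range(probe_counts[gi]):
            probe_id = f"{gene}_p{pj + 1}"
            offset = rng.normal(0.0, design.probe_sd)
            ctrl_mean = np.clip(
                baselines[gi] + offset, _MEAN_MARGIN, 1 - _MEAN_MARGIN
            )
            case_mean = np.clip(
                baselines[gi] + true_delta[gi] + offset,
                _MEAN_MARGIN,
                1 - _MEAN_MARGIN,
            )
            means = np.where(is_case, case_mean, ctrl_mean)
            values.append(_beta_draw(rng, means, design.precision))
            probe_rows.append(probe_id)
            ann_rows.append(
                {
                    "probe_id": probe_id,
                    "gene_id": gene,
                    "cgi_id": f"CGI_{gene}",
                    "heart_expressed": bool(heart[gi]),
                }
            )
    beta = pd.DataFrame(np.vstack(values), index=probe_rows, columns=samples)
    beta.index.name = "probe_id"
    truth = pd.DataFrame(
        {
            "gene_id": genes,
            "is_differential": effective,
            "direction": [
                "hyper" if d > 0 else "hypo" if d < 0 else "none"
                for d in true_delta
            ],
            "true_delta": true_delta,
        }
    )
    return BetaDataset(beta, pd.DataFrame(ann_rows), meta), truth


def gen_bead_signals(
    beta: pd.DataFrame,
    intensity: float = 5000.0,
    noise: float = 50.0,
    seed: int | None = None,
    outlier_samples: list[str] | None = None,
    outlier_scale: float = 0.1,
) -> SignalMatrix:
    """Two-channel bead intensities consistent with a beta matrix.

    Methylated channel ~ intensity * beta, unmethylated ~ intensity *
    (1 - beta), each plus half-normal noise of scale ``noise`` (so channels
    stay nonnegative). ``outlier_samples`` are scaled down by
    ``outlier_scale`` to emulate a failed low-intensity array for QC
    exercises. With noise = 0 the beta formula (offset 0) inverts the
    signals exactly.
    """
    if intensity <= 0:
        raise ValueError("intensity must be positive")
    if noise < 0:
        raise ValueError("noise must be nonnegative")
    B = beta.to_numpy(dtype=float)
    if ((B < 0) | (B > 1)).any():
        raise ValueError("beta values must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    M = intensity * B
    U = intensity * (1.0 - B)
    if noise > 0:
        M = M + np.abs(rng.normal(0.0, noise, size=B.shape))
        U = U + np.abs(rng.normal(0.0, noise, size=B.shape))
    Mdf = pd.DataFrame(M, index=beta.index, columns=beta.columns)
    Udf = pd.DataFrame(U, index=beta.index, columns=beta.columns)
    for s in outlier_samples or []:
        Mdf[s] *= outlier_scale
        Udf[s] *= outlier_scale
    return SignalMatrix(Mdf, Udf)


def gen_amplicon_panel(
    candidates: list[str],
    directions: dict[str, str] | None = None,
    n_cases: int = 30,
    n_controls: int = 28,
    cpgs_per_amplicon: int = 5,
    consistent_fraction: float = 12 / 20,
    delta: float = 0.10,
    precision: float | None = 60.0,
    cpg_sd: float = 0.02,
    baseline_range: tuple[float, float] = (0.2, 0.7),
    seed: int | None = None,
):
    """Replication-stage per-CpG methylation panel for candidate CGIs.

    ``directions`` maps candidate -> 'hyper' | 'hypo' (the screening-stage
    call; default 'hyper'). Exactly round(consistent_fraction * n)
    candidates — a seeded draw — carry a case-group effect of magnitude
    ``delta`` in the screening direction; the rest carry no effect. Per-CpG
    values are beta-distributed around the amplicon group mean (plus a small
    systematic per-CpG offset); ``precision=None`` switches sampling off
    entirely, yielding noise-free fractions equal to the group means.

    Returns (AmpliconPanel, truth table with the consistency flags).
    """
    from .finemap import AmpliconPanel

    if not candidates:
        raise ValueError("candidate list is empty")
    if not 0.0 <= consistent_fraction <= 1.0:
        raise ValueError("consistent_fraction must lie in [0, 1]")
    directions = directions or {}
    rng = np.random.default_rng(seed)
    meta = _sample_metadata(rng, n_cases, n_controls)
    is_case = (meta["group"] == "case").to_numpy()
    n_consistent = round(consistent_fraction * len(candidates))
    order = rng.permutation(len(candidates))
    consistent = np.zeros(len(candidates), dtype=bool)
    consistent[order[:n_consistent]] = True

    rows, truth_rows = [], []
    for ci, cand in enumerate(candidates):
        direction = directions.get(cand, "hyper")
        if direction not in ("hyper", "hypo"):
            raise ValueError(f"bad direction {direction!r} for {cand!r}")
        sign = 1.0 if direction == "hyper" else -1.0
        eff = sign * delta if consistent[ci] else 0.0
        base = rng.uniform(*baseline_range)
        for u in range(cpgs_per_amplicon):
            cpg_off = rng.normal(0.0, cpg_sd) if precision is not None else 0.0
            for si, sample in enumerate(meta["sample"]):
                mean = base + cpg_off + (eff if is_case[si] else 0.0)
                mean = float(np.clip(mean, _MEAN_MARGIN, 1 - _MEAN_MARGIN))
                frac = (
                    float(_beta_draw(rng, mean, precision))
                    if precision is not None
                    else mean
                )
                rows.append(
                    {
                        "candidate": cand,
                        "cpg_unit": f"{cand}_CpG{u + 1}",
                        "sample": sample,
                        "fraction": frac,
                    }
                )
        truth_rows.append(
            {
                "gene_id": cand,
                "is_consistent": bool(consistent[ci]),
                "direction": direction,
                "true_delta": eff,
            }
        )
    panel = AmpliconPanel(pd.DataFrame(rows), meta)
    return panel, pd.DataFrame(truth_rows)


def gen_bisulfite_clones(
    cpg_states: np.ndarray,
    ref_seq: str,
    n_clones: int = 14,
    conversion_rate: float = 1.0,
    seed: int | None = None,
) -> tuple[list[str], np.ndarray]:
    """Bisulfite clone sequences drawn from per-CpG methylation probabilities.

    ``cpg_states`` gives, per reference CpG (in sequence order), the
    probability that a clone is methylated there. Each clone draws a binary
    methylation state per CpG and is then bisulfite-converted at
    ``conversion_rate``. Returns the converted sequences plus the planted
    clone x CpG state matrix (1 = methylated).
    """
    positions = cpg_positions(ref_seq)
    if not positions:
        raise ValueError("reference sequence contains no CpG")
    probs = np.asarray(cpg_states, dtype=float)
    if len(probs) != len(positions):
        raise ValueError(
            f"{len(probs)} probabilities for {len(positions)} CpG sites"
        )
    if ((probs < 0) | (probs > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    states = (rng.random((n_clones, len(positions))) < probs).astype(int)
    clones = []
    for ci in range(n_clones):
        meth = {p for p, st in zip(positions, states[ci]) if st}
        clones.append(
            bisulfite_convert(
                ref_seq,
                meth,
                conversion_rate=conversion_rate,
                seed=int(rng.integers(2**31)),
            )
        )
    return clones, states


def gen_ct_table(
    group_sizes: dict[str, int],
    gene_effects: dict[str, dict[str, float]],
    housekeeper_ct: float = 20.0,
    baseline_delta_ct: float = 5.0,
    housekeepers=("GAPDH", "RPL13", "ACTB"),
    noise: float = 0.0,
    rin: float = 8.0,
    control_group: str = "control",
    seed: int | None = None,
) -> pd.DataFrame:
    """qPCR CT table implementing planted fold changes under the dCT model.

    For target gene g in group grp with fold f (relative to
    ``control_group``; missing groups default to 1), each sample gets
    CT = housekeeper_ct + baseline_delta_ct - log2(f) + Gaussian noise;
    housekeeper CTs scatter around ``housekeeper_ct``. With noise = 0 the
    ddCT transform recovers every planted fold exactly.
    """
    if not np.isfinite(housekeeper_ct):
        raise ValueError("housekeeper CT must be finite")
    if control_group not in group_sizes:
        raise ValueError(f"control group {control_group!r} missing from group_sizes")
    for gene, per_group in gene_effects.items():
        for grp, fold in per_group.items():
            if fold <= 0:
                raise ValueError(f"nonpositive fold {fold} for {gene}/{grp}")
    rng = np.random.default_rng(seed)
    rows = []
    for grp, n in group_sizes.items():
        for i in range(n):
            sample = f"{grp}_{i + 1:02d}"
            for hk in housekeepers:
                ct = housekeeper_ct + (rng.normal(0, noise) if noise > 0 else 0.0)
                rows.append(
                    {"sample": sample, "group": grp, "gene": hk, "CT": ct, "RIN": rin}
                )
            for gene, per_group in gene_effects.items():
                fold = per_group.get(grp, 1.0)
                ct = (
                    housekeeper_ct
                    + baseline_delta_ct
                    - np.log2(fold)
                    + (rng.normal(0, noise) if noise > 0 else 0.0)
                )
                rows.append(
                    {"sample": sample, "group": grp, "gene": gene, "CT": ct, "RIN": rin}
                )
    return pd.DataFrame(rows)
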