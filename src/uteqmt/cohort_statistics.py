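"""Cohort-level statistics for the UTE biomarker study.

Per biomarker: normality (Lilliefors-corrected Kolmogorov–Smirnov), group
comparison (Welch t-test when normal, two-sided Mann–Whitney U otherwise),
correlation with the ordinal Kellgren–Lawrence grade (Spearman for MMF/MTR,
Pearson for T2*), empirical ROC analysis with a Youden-index operating point,
inter-reader ICC, and the closed-form binormal AUC companion used to
cross-check the simulation targets.  No multiplicity correction is applied;
each biomarker is reported at α = 0.05.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score
from statsmodels.stats.diagnostic import lilliefors as _lilliefors

from .exceptions import InvalidInputError

__all__ = [
    "TestReport",
    "RocReport",
    "ks_normality",
    "compare_groups",
    "correlate",
    "roc_auc",
    "youden_threshold",
    "icc",
    "binormal_auc",
    "run_study",
    "simulate_study_aucs",
    "BIOMARKER_ANALYSIS",
    "plot_study",
]

#: Per-biomarker analysis conventions: correlation method with KL, and ROC
#: direction ("lower" = lower values indicate disease, as for MMF and MTR;
#: "higher" for T2*).
BIOMARKER_ANALYSIS = {
    "mmf_percent": {"label": "MMF (%)", "correlation": "spearman", "direction": "lower"},
    "mtr_percent": {"label": "MTR (%)", "correlation": "spearman", "direction": "lower"},
    "t2star_ms": {"label": "T2* (ms)", "correlation": "pearson", "direction": "higher"},
}

#: Group labels: the second entry is the diseased class in ROC analyses.
GROUPS = ("normal_subtle", "mild_moderate")


@dataclass
class TestReport:
    """One hypothesis test: name, statistic, p, group sizes, direction."""

    test: str
    statistic: float
    p_value: float
    n: tuple[int, ...]
    effect_direction: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise InvalidInputError("p value outside [0, 1]")


@dataclass
class RocReport:
    """ROC summary with the Youden-index operating point."""

    auc: float
    p_value: float
    threshold: float
    sensitivity_pct: float
    specificity_pct: float
    direction: str
    n: tuple[int, int] = (0, 0)


# ---------------------------------------------------------------------------
# normality, comparison, correlation
# ---------------------------------------------------------------------------


def ks_normality(values: Sequence[float], *, lilliefors: bool = True) -> TestReport:
    """One-sample KS normality test with sample mean/SD.

    Uses Lilliefors critical values by default (parameters are estimated from
    the sample); the naive KS p-value is available with ``lilliefors=False``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 5:
        raise InvalidInputError("normality test needs n >= 5")
    if np.std(x, ddof=1) == 0:
        raise InvalidInputError("normality test undefined for zero-variance input")
    if lilliefors:
        stat, p = _lilliefors(x, dist="norm")
        name = "lilliefors_ks"
    else:
        stat, p = stats.kstest(x, "norm", args=(np.mean(x), np.std(x, ddof=1)))
        name = "ks"
    return TestReport(name, float(stat), float(min(max(p, 0.0), 1.0)), (x.size,))


def compare_groups(
    a: Sequence[float], b: Sequence[float], normal: bool
) -> TestReport:
    """Two-sided group comparison: Welch t-test if ``normal``, else Mann–Whitney.

    Degenerate (zero-variance) input for the t-test falls back to
    Mann–Whitney with a warning.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if min(a.size, b.size) < 3:
        raise InvalidInputError("each group needs n >= 3")
    direction = "a_higher" if np.mean(a) > np.mean(b) else "b_higher"
    if normal:
        if np.std(a, ddof=1) == 0 or np.std(b, ddof=1) == 0:
            warnings.warn("zero variance: falling back to Mann-Whitney")
        else:
            t, p = stats.ttest_ind(a, b, equal_var=False)
            return TestReport("welch_t", float(t), float(p), (a.size, b.size), direction)
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return TestReport("mann_whitney_u", float(u), float(p), (a.size, b.size), direction)


def correlate(
    values: Sequence[float], kl_grades: Sequence[int], method: str
) -> TestReport:
    """Correlation between a biomarker and the ordinal KL grade.

    ``method`` is ``"spearman"`` (average ranks for ties) or ``"pearson"``.
    Negative sign means the biomarker falls as KL rises.
    """
    x = np.asarray(values, dtype=float)
    k = np.asarray(kl_grades, dtype=float)
    if x.size != k.size or x.size < 5:
        raise InvalidInputError("need matched samples with n >= 5")
    if np.std(x) == 0 or np.std(k) == 0:
        raise InvalidInputError("correlation undefined for constant input")
    if method == "spearman":
        r, p = stats.spearmanr(x, k)
    elif method == "pearson":
        r, p = stats.pearsonr(x, k)
    else:
        raise InvalidInputError(f"unknown correlation method {method!r}")
    direction = "negative" if r < 0 else "positive"
    return TestReport(method, float(r), float(p), (x.size,), direction)


# ---------------------------------------------------------------------------
# ROC / Youden
# ---------------------------------------------------------------------------


def _oriented_scores(scores: np.ndarray, direction: str) -> np.ndarray:
    if direction == "lower":
        return -scores
    if direction == "higher":
        return scores.copy()
    raise InvalidInputError("direction must be 'lower' or 'higher' (value in diseased)")


def roc_auc(
    scores: Sequence[float], labels: Sequence[int], direction: str = "higher"
) -> RocReport:
    """Empirical ROC AUC with a normal-approximation p-value against AUC = 0.5.

    ``labels`` are 0 (healthy) / 1 (diseased); ``direction`` states whether
    lower or higher scores indicate disease.  The empirical AUC equals the
    Mann–Whitney identity U/(n0·n1) with ties counted one half; the p-value
    uses the large-sample normal approximation to U (no tie correction).
    The Youden operating point is filled in by :func:`youden_threshold`.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n0 == 0 or n1 == 0:
        raise InvalidInputError("both classes must be present")
    auc = float(roc_auc_score(y, _oriented_scores(s, direction)))
    mu_u = n0 * n1 / 2.0
    sd_u = math.sqrt(n0 * n1 * (n0 + n1 + 1) / 12.0)
    z = (auc * n0 * n1 - mu_u) / sd_u
    p = 2.0 * stats.norm.sf(abs(z))
    rep = youden_threshold(s, y, direction)
    return RocReport(auc, float(min(p, 1.0)), rep.threshold, rep.sensitivity_pct,
                     rep.specificity_pct, direction, (n0, n1))


def youden_threshold(
    scores: Sequence[float], labels: Sequence[int], direction: str = "higher"
) -> RocReport:
    """Operating threshold maximizing Youden's J = sensitivity + specificity − 1.

    Candidate cuts are the midpoints between adjacent distinct scores plus
    ±infinity sentinels; a subject is called diseased on the diseased side of
    the cut.  Ties in J break toward the higher-specificity cut.  The
    returned threshold is on the original score scale.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if np.sum(y == 1) == 0 or np.sum(y == 0) == 0:
        raise InvalidInputError("both classes must be present")
    t = _oriented_scores(s, direction)  # higher oriented score = more diseased
    uniq = np.unique(t)
    cands = np.concatenate(([-np.inf], (uniq[:-1] + uniq[1:]) / 2.0, [np.inf]))
    pos, neg = t[y == 1], t[y == 0]
    best = None
    for c in cands:
        sens = float(np.mean(pos > c))
        spec = float(np.mean(neg <= c))
        key = (sens + spec - 1.0, spec)
        if best is None or key > best[0]:
            best = (key, c, sens, spec)
    _, cut, sens, spec = best
    threshold = -cut if direction == "lower" else cut
    return RocReport(float("nan"), float("nan"), float(threshold),
                     100.0 * sens, 100.0 * spec, direction)


# ---------------------------------------------------------------------------
# ICC and binormal AUC
# ---------------------------------------------------------------------------


def icc(readings: np.ndarray | pd.DataFrame, form: str = "icc2_1") -> float:
    """Intraclass correlation from an (n subjects × k readings) table.

    ``icc2_1``: two-way random effects, absolute agreement, single measure
    (the default for inter-reader reliability); ``icc3_1``: two-way mixed,
    consistency.  Computed from the standard ANOVA mean squares.
    """
    x = np.asarray(readings, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 5:
        raise InvalidInputError("need >= 5 subjects and >= 2 readings")
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    if msr == 0:
        raise InvalidInputError("zero between-subject variance")
    if form == "icc2_1":
        return float((msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n))
    if form == "icc3_1":
        return float((msr - mse) / (msr + (k - 1) * mse))
    raise InvalidInputError(f"unknown ICC form {form!r}")


def binormal_auc(
    mu_healthy: float, sd_healthy: float, mu_diseased: float, sd_diseased: float
) -> float:
    """Closed-form AUC of two normal score distributions.

    AUC = Φ(|μ1 − μ2| / sqrt(σ1² + σ2²)); symmetric in the group labels and
    0.5 when the means coincide.
    """
    if sd_healthy <= 0 or sd_diseased <= 0:
        raise InvalidInputError("SDs must be positive")
    d = abs(mu_healthy - mu_diseased) / math.sqrt(sd_healthy**2 + sd_diseased**2)
    return float(stats.norm.cdf(d))


# ---------------------------------------------------------------------------
# full study
# ---------------------------------------------------------------------------


def run_study(cohort: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Run the complete statistics layer on a cohort table.

    Per biomarker: group means ± SD, per-group Lilliefors normality (a
    biomarker is treated as normal iff both groups pass at ``alpha``), the
    comparison test chosen from that flag, correlation with KL (method fixed
    per biomarker), and ROC with the Youden operating point.  When
    ``<biomarker>_reader1/2`` columns exist, the inter-reader ICC(2,1) is
    added.  Deterministic given the input table.
    """
    for col in ("group", "kl_grade"):
        if col not in cohort.columns:
            raise InvalidInputError(f"cohort table lacks required column {col!r}")
    report: dict = {"n_per_group": {}, "biomarkers": {}, "alpha": alpha,
                    "notes": "No multiple-testing correction; each biomarker at alpha."}
    by_group = {g: cohort[cohort["group"] == g] for g in GROUPS}
    for g, df in by_group.items():
        if df.empty:
            raise InvalidInputError(f"cohort lacks group {g!r}")
        report["n_per_group"][g] = int(len(df))

    labels = (cohort["group"] == "mild_moderate").astype(int).to_numpy()
    for col, conv in BIOMARKER_ANALYSIS.items():
        if col not in cohort.columns:
            raise InvalidInputError(f"cohort table lacks biomarker column {col!r}")
        vals = cohort[col].to_numpy(dtype=float)
        a = by_group["normal_subtle"][col].to_numpy(dtype=float)
        b = by_group["mild_moderate"][col].to_numpy(dtype=float)
        normality = {g: ks_normality(by_group[g][col]) for g in GROUPS}
        is_normal = all(rep.p_value > alpha for rep in normality.values())
        entry = {
            "label": conv["label"],
            "group_means": {
                "normal_subtle": {"mean": float(np.mean(a)), "sd": float(np.std(a, ddof=1))},
                "mild_moderate": {"mean": float(np.mean(b)), "sd": float(np.std(b, ddof=1))},
            },
            "normality": {g: asdict(rep) for g, rep in normality.items()},
            "treated_as_normal": bool(is_normal),
            "comparison": asdict(compare_groups(a, b, normal=is_normal)),
            "correlation_kl": asdict(
                correlate(vals, cohort["kl_grade"].to_numpy(), conv["correlation"])
            ),
            "roc": asdict(roc_auc(vals, labels, conv["direction"])),
        }
        r1, r2 = f"{col}_reader1", f"{col}_reader2"
        if r1 in cohort.columns and r2 in cohort.columns:
            entry["icc_inter_reader"] = icc(cohort[[r1, r2]].to_numpy())
        report["biomarkers"][col] = entry
    return report


def simulate_study_aucs(n_cohorts: int = 1000, seed: int = 0) -> dict:
    """Simulation reproduction of the study's ROC results.

    Draws ``n_cohorts`` cohorts from the two-group population model
    (:func:`~uteqmt.synthetic_data.table1_groups`), computes the empirical
    AUC per biomarker (MMF/MTR lower-is-diseased, T2* higher) and the
    two-sided Mann–Whitney p for the MMF group comparison per cohort, and
    returns the mean AUCs, the median MMF p, and the closed-form binormal
    AUCs for cross-checking.
    """
    from .synthetic_data import draw_cohort, table1_groups

    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n_cohorts)]
    aucs: dict[str, list[float]] = {col: [] for col in BIOMARKER_ANALYSIS}
    mmf_p: list[float] = []
    for s in child_seeds:
        cohort = draw_cohort(seed=s)
        labels = (cohort["group"] == "mild_moderate").astype(int).to_numpy()
        for col, conv in BIOMARKER_ANALYSIS.items():
            aucs[col].append(roc_auc(cohort[col].to_numpy(), labels, conv["direction"]).auc)
        a = cohort.loc[cohort["group"] == "normal_subtle", "mmf_percent"]
        b = cohort.loc[cohort["group"] == "mild_moderate", "mmf_percent"]
        mmf_p.append(compare_groups(a, b, normal=False).p_value)
    grp_h, grp_d = table1_groups()
    return {
        "n_cohorts": n_cohorts,
        "mean_auc": {col: float(np.mean(v)) for col, v in aucs.items()},
        "median_mmf_p": float(np.median(mmf_p)),
        "binormal_auc": {
            col: binormal_auc(*grp_h.moments(col), *grp_d.moments(col))
            for col in BIOMARKER_ANALYSIS
        },
    }


def plot_study(cohort: pd.DataFrame, outdir) -> list[str]:
    """Box plots per biomarker and overlaid ROC curves, written as PNG files."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    fig, axes = plt.subplots(1, 3, figsize=(11, 3.6))
    for ax, (col, conv) in zip(axes, BIOMARKER_ANALYSIS.items()):
        data = [cohort.loc[cohort["group"] == g, col] for g in GROUPS]
        ax.boxplot(data, tick_labels=["Normal/Subtle", "Mild-Moderate"])
        ax.set_ylabel(conv["label"])
    fig.tight_layout()
    box_path = outdir / "group_boxplots.png"
    fig.savefig(box_path, dpi=120)
    plt.close(fig)
    written.append(str(box_path))

    labels = (cohort["group"] == "mild_moderate").astype(int).to_numpy()
    fig, ax = plt.subplots(figsize=(4.2, 4.0))
    for col, conv in BIOMARKER_ANALYSIS.items():
        s = _oriented_scores(cohort[col].to_numpy(dtype=float), conv["direction"])
        fpr, tpr, _ = roc_curve(labels, s)
        auc = roc_auc(cohort[col].to_numpy(dtype=float), labels, conv["direction"]).auc
        ax.plot(fpr, tpr, label=f"{conv['label']} (AUC={auc:.2f})")
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.legend(loc="lower right", fontsize=8)
    fig.tight_layout()
    roc_path = outdir / "roc_curves.png"
    fig.savefig(roc_path, dpi=120)
    plt.close(fig)
    written.append(str(roc_path))
    return written
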