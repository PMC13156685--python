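"""Paired differential analysis and cohort-level statistics.

Per feature: two-sided paired t-test of log10 post- vs pre-intervention
time-normalized AUCs across subjects, Benjamini-Hochberg FDR over all
features of a cohort, and volcano classification with inclusive thresholds
(|Log2FC| >= 1.5 and FDR <= 0.01 by default).  Cohort-level: hypergeometric
cross-cohort overlap, PLS-DA with cross-validated accuracy and discriminant
Q2, and the demographic comparisons of the study populations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from sklearn.cross_decomposition import PLSRegression
from sklearn.model_selection import GroupKFold, StratifiedKFold
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable, PairedAUC


# ---------------------------------------------------------------------------
# Paired differential + volcano
# ---------------------------------------------------------------------------

def paired_differential(paired: PairedAUC) -> pd.DataFrame:
    """Per-feature paired differential statistics.

    For each feature: two-sided paired t-test of log10(auc_post) vs
    log10(auc_pre) across subjects; ``mean_log2fc`` is the subject-mean of
    log2(post/pre).  P-values are BH-adjusted over all tested features.
    Features with zero-variance differences get p = 0 and ``degenerate`` =
    True (the direction is certain but the t statistic is undefined);
    features with fewer than two complete subjects are skipped.

    Returns a DataFrame indexed by feature id with columns
    ``mean_log2fc, t_stat, p_value, fdr, degenerate``.
    """
    log_pre = np.log10(paired.auc_pre.to_numpy(dtype=float))
    log_post = np.log10(paired.auc_post.to_numpy(dtype=float))
    diffs = log_post - log_pre
    n_subj = diffs.shape[0]
    if n_subj < 2:
        raise ValueError("paired t-test needs at least two subjects")

    mean_l2fc = paired.log2fc.mean(axis=0).to_numpy()
    mean_d = diffs.mean(axis=0)
    sd_d = diffs.std(axis=0, ddof=1)
    degenerate = sd_d == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t_stat = mean_d / (sd_d / np.sqrt(n_subj))
    p = 2.0 * sstats.t.sf(np.abs(t_stat), df=n_subj - 1)
    p = np.where(degenerate & (mean_d != 0), 0.0, p)
    p = np.where(degenerate & (mean_d == 0), 1.0, p)
    t_stat = np.where(degenerate, np.sign(mean_d) * np.inf, t_stat)

    fdr = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame(
        {
            "mean_log2fc": mean_l2fc,
            "t_stat": t_stat,
            "p_value": p,
            "fdr": fdr,
            "degenerate": degenerate,
        },
        index=pd.Index(paired.feature_ids, name="feature_id"),
    )


def classify_volcano(
    stats: pd.DataFrame, fc_cut: float = 1.5, fdr_cut: float = 0.01
) -> pd.DataFrame:
    """Assign volcano classes with inclusive thresholds: ``up`` iff
    mean_log2fc >= fc_cut and fdr <= fdr_cut; ``down`` iff
    mean_log2fc <= -fc_cut and fdr <= fdr_cut; otherwise ``ns``."""
    out = stats.copy()
    sig = out["fdr"] <= fdr_cut
    up = sig & (out["mean_log2fc"] >= fc_cut)
    down = sig & (out["mean_log2fc"] <= -fc_cut)
    out["volcano_class"] = np.where(up, "up", np.where(down, "down", "ns"))
    return out


def volcano_counts(stats: pd.DataFrame) -> dict[str, int]:
    vc = stats["volcano_class"].value_counts()
    return {k: int(vc.get(k, 0)) for k in ("up", "down", "ns")}


# ---------------------------------------------------------------------------
# Cross-cohort overlap
# ---------------------------------------------------------------------------

@dataclass
class OverlapResult:
    n_universe: int
    n_set_a: int
    n_set_b: int
    n_overlap: int
    hypergeom_p: float


def cross_cohort_overlap(set_a, set_b, universe: int) -> OverlapResult:
    """Exact upper-tail hypergeometric test of the overlap between two
    feature sets drawn from a common universe: P(X >= |A ∩ B|) with
    X ~ Hypergeom(N = universe, K = |A|, n = |B|)."""
    a, b = set(set_a), set(set_b)
    if len(a) > universe or len(b) > universe:
        raise ValueError("set sizes cannot exceed the universe")
    k = len(a & b)
    p = float(sstats.hypergeom.sf(k - 1, universe, len(a), len(b)))
    return OverlapResult(universe, len(a), len(b), k, p)


# ---------------------------------------------------------------------------
# PLS-DA
# ---------------------------------------------------------------------------

@dataclass
class PlsdaReport:
    n_components: int
    cv_accuracy: float
    q2: float
    scores: np.ndarray  # samples x components, full-data fit


def _prepare_plsda_matrix(table: FeatureTable) -> np.ndarray:
    x = table.intensities.to_numpy(dtype=float)
    if np.any(x <= 0):
        raise ValueError("PLS-DA expects strictly positive intensities (impute first)")
    return np.log10(x)


def plsda_crossval(
    table: FeatureTable,
    labels,
    n_components: int = 2,
    n_folds: int = 10,
    seed: int = 0,
    grouped_by_subject: bool = False,
) -> PlsdaReport:
    """Cross-validated PLS-DA of pre vs post samples.

    Components are fit by NIPALS on autoscaled (per-feature mean-centered,
    unit-variance) log10 intensities with class labels coded {0, 1}.
    Classification cuts the predicted response at 0.5.  ``cv_accuracy`` is
    the pooled out-of-fold accuracy; discriminant Q2 = 1 - PRESS/TSS over
    the out-of-fold predictions.  Folds are stratified by class, or grouped
    by subject when ``grouped_by_subject`` (each subject's four samples stay
    in one fold).
    """
    y = np.asarray([1 if v in (1, "post", True) else 0 for v in labels], dtype=float)
    x = _prepare_plsda_matrix(table)
    if len(y) != x.shape[0]:
        raise ValueError("labels must align with samples")
    for cls in (0, 1):
        if (y == cls).sum() < n_folds and not grouped_by_subject:
            raise ValueError("need at least n_folds samples per class")

    if grouped_by_subject:
        groups = table.samples["subject_id"].to_numpy()
        splitter = GroupKFold(n_splits=n_folds)
        splits = splitter.split(x, y, groups)
    else:
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(x, y)

    y_hat = np.empty_like(y)
    for train, test in splits:
        mu = x[train].mean(axis=0)
        sd = x[train].std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        pls = PLSRegression(n_components=n_components, scale=False)
        pls.fit((x[train] - mu) / sd, y[train])
        y_hat[test] = pls.predict((x[test] - mu) / sd).ravel()

    cv_accuracy = float(np.mean((y_hat >= 0.5) == (y == 1)))
    press = float(np.sum((y - y_hat) ** 2))
    tss = float(np.sum((y - y.mean()) ** 2))
    q2 = 1.0 - press / tss

    mu = x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    sd[sd == 0] = 1.0
    pls_full = PLSRegression(n_components=n_components, scale=False)
    pls_full.fit((x - mu) / sd, y)
    return PlsdaReport(n_components, cv_accuracy, q2, np.asarray(pls_full.x_scores_))


# ---------------------------------------------------------------------------
# Demographics
# ---------------------------------------------------------------------------

@dataclass
class DemographicsReport:
    u_stat: float
    u_p: float
    chi2_stat: float
    chi2_p: float
    summary: pd.DataFrame  # per-cohort mean, sd, median, iqr of ages


def _age_summary(ages: np.ndarray) -> dict[str, float]:
    """Mean/SD on full-precision ages; median/IQR on ages truncated to whole
    years with linear-interpolation quartiles (the reporting convention of
    the study populations)."""
    trunc = np.trunc(ages)
    q25, q50, q75 = np.percentile(trunc, [25, 50, 75])
    return {
        "mean": float(np.mean(ages)),
        "sd": float(np.std(ages, ddof=1)),
        "median": float(q50),
        "iqr": float(q75 - q25),
    }


def demographics(ages_a, ages_b, sex_table) -> DemographicsReport:
    """Between-cohort demographic comparison.

    Age distributions are compared with a Mann-Whitney U test (midrank ties,
    continuity-corrected normal approximation, two-sided) on ages truncated
    to whole years, reporting U = min(U1, U2); sex distributions with a
    chi-square test on the 2x2 table with Yates continuity correction.
    """
    ages_a = np.asarray(ages_a, dtype=float)
    ages_b = np.asarray(ages_b, dtype=float)
    if ages_a.size == 0 or ages_b.size == 0:
        raise ValueError("both age groups must be non-empty")
    res = sstats.mannwhitneyu(
        np.trunc(ages_a), np.trunc(ages_b),
        alternative="two-sided", method="asymptotic", use_continuity=True,
    )
    u1 = float(res.statistic)
    u = min(u1, ages_a.size * ages_b.size - u1)

    tab = np.asarray(sex_table, dtype=float)
    if tab.shape != (2, 2) or (tab < 0).any():
        raise ValueError("sex_table must be a 2x2 table of non-negative counts")
    chi = sstats.chi2_contingency(tab, correction=True)

    summary = pd.DataFrame(
        {"cohort_a": _age_summary(ages_a), "cohort_b": _age_summary(ages_b)}
    ).T
    return DemographicsReport(
        u_stat=u,
        u_p=float(res.pvalue),
        chi2_stat=float(chi.statistic),
        chi2_p=float(chi.pvalue),
        summary=summary,
    )
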