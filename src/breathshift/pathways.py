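"""Feature annotation, pathway-degree analysis, and enrichment.

Mass-spectral features are putatively annotated by matching their m/z to
compound adduct masses — protonated [M+H]+ and deprotonated [M-H]- ions and
their single-13C isotopologues — within a +-1 ppm tolerance, after
heuristic plausibility filtering of formulas.  Annotated features feed two
pathway views: a pathway-based degree analysis (per-pathway median Log2FC
and network degree per cohort plus intra-pathway cross-cohort correlations,
with hierarchical clustering of pathways) and a reduced mummichog-style
enrichment (one-sided Fisher tests against a permutation null whose -log p
values are gamma-fitted; ambiguous multi-compound features are down-weighted).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats
from scipy.cluster import hierarchy

from .chem import C13_DELTA, PROTON_MASS, golden_rules_filter  # noqa: F401  (re-export)
from .network import CorrelationNetwork
from .synthetic import CompoundLibrary

ADDUCTS = {
    "[M+H]+": lambda m: m + PROTON_MASS,
    "[M(13C)+H]+": lambda m: m + PROTON_MASS + C13_DELTA,
    "[M-H]-": lambda m: m - PROTON_MASS,
    "[M(13C)-H]-": lambda m: m - PROTON_MASS + C13_DELTA,
}


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def adduct_mz_pool(library: CompoundLibrary) -> np.ndarray:
    """All candidate ion m/z values of a library (every compound x every
    supported adduct), sorted ascending."""
    return np.sort(
        [fn(rec.monoisotopic_mass) for rec in library.records for fn in ADDUCTS.values()]
    )


def annotate_features(
    features: pd.Series | dict, library: CompoundLibrary, tol_ppm: float = 1.0
) -> pd.DataFrame:
    """Match feature m/z values to compound adduct candidates at +-tol_ppm.

    ``features`` maps feature id -> m/z.  For every compound, candidate m/z
    values are computed for the four supported ion types; a hit is recorded
    when |observed - candidate| / candidate <= tol_ppm * 1e-6.  A feature
    may hit several compounds and vice versa.

    Returns a DataFrame with columns ``feature_id, mz, compound_id, adduct,
    ppm_error``.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    if isinstance(features, dict):
        features = pd.Series(features)

    candidates = []  # (candidate_mz, compound_id, adduct)
    for rec in library.records:
        for adduct, fn in ADDUCTS.items():
            candidates.append((fn(rec.monoisotopic_mass), rec.compound_id, adduct))
    candidates.sort()
    cand_mz = np.array([c[0] for c in candidates])

    rows = []
    for fid, mz in features.items():
        lo = np.searchsorted(cand_mz, mz / (1 + tol_ppm * 1e-6), side="left")
        hi = np.searchsorted(cand_mz, mz / (1 - tol_ppm * 1e-6), side="right")
        for k in range(lo, hi):
            cmz, cid, adduct = candidates[k]
            ppm = (mz - cmz) / cmz * 1e6
            if abs(ppm) <= tol_ppm:
                rows.append((fid, float(mz), cid, adduct, float(ppm)))
    return pd.DataFrame(
        rows, columns=["feature_id", "mz", "compound_id", "adduct", "ppm_error"]
    )


def feature_pathway_map(
    annotations: pd.DataFrame, library: CompoundLibrary
) -> dict[str, set[str]]:
    """feature id -> set of pathway ids, via annotated compounds."""
    by_compound = {rec.compound_id: set(rec.pathway_ids) for rec in library.records}
    out: dict[str, set[str]] = {}
    for fid, grp in annotations.groupby("feature_id"):
        pws: set[str] = set()
        for cid in grp["compound_id"]:
            pws |= by_compound.get(cid, set())
        out[fid] = pws
    return out


# ---------------------------------------------------------------------------
# Pathway-based degree analysis
# ---------------------------------------------------------------------------

@dataclass
class PathwayDegreeResult:
    stats: pd.DataFrame      # per-pathway medians and cross-cohort correlations
    linkage: np.ndarray      # average-linkage tree over pathways
    dendrogram_order: list[str]


def pathway_degree_analysis(
    stats_a: pd.DataFrame,
    stats_b: pd.DataFrame,
    net_a: CorrelationNetwork,
    net_b: CorrelationNetwork,
    annotations: pd.DataFrame,
    library: CompoundLibrary,
    min_features: int = 5,
) -> PathwayDegreeResult:
    """Per-pathway concordance of effect sizes and network connectivity.

    For every pathway with at least ``min_features`` annotated features:
    median Log2FC and median node degree per cohort (degree from each
    cohort's network at its construction cutoff), plus the cross-cohort
    Pearson correlation of the per-feature Log2FC vectors and of the degree
    vectors within the pathway.  Pathways are then clustered (average
    linkage, Euclidean distance on the two correlation values); the
    dendrogram leaf order is returned.
    """
    fmap = feature_pathway_map(annotations, library)
    pathway_features: dict[str, list[str]] = {}
    for fid, pws in fmap.items():
        for pw in pws:
            pathway_features.setdefault(pw, []).append(fid)

    deg_a = dict(net_a.graph.degree())
    deg_b = dict(net_b.graph.degree())

    rows = []
    for pw in sorted(pathway_features):
        fids = sorted(
            f for f in pathway_features[pw]
            if f in stats_a.index and f in stats_b.index
        )
        if len(fids) < min_features:
            continue
        fc_a = stats_a.loc[fids, "mean_log2fc"].to_numpy()
        fc_b = stats_b.loc[fids, "mean_log2fc"].to_numpy()
        da = np.array([deg_a.get(f, 0) for f in fids], dtype=float)
        db = np.array([deg_b.get(f, 0) for f in fids], dtype=float)

        def _corr(u: np.ndarray, v: np.ndarray) -> float:
            if u.std() == 0 or v.std() == 0:
                return np.nan
            return float(sstats.pearsonr(u, v).statistic)

        rows.append(
            {
                "pathway_id": pw,
                "name": library.pathway_registry.get(pw, pw),
                "n_features": len(fids),
                "median_log2fc_a": float(np.median(fc_a)),
                "median_log2fc_b": float(np.median(fc_b)),
                "median_degree_a": float(np.median(da)),
                "median_degree_b": float(np.median(db)),
                "log2fc_correlation": _corr(fc_a, fc_b),
                "degree_correlation": _corr(da, db),
            }
        )
    if not rows:
        warnings.warn(f"no pathway has >= {min_features} annotated features")
        return PathwayDegreeResult(
            stats=pd.DataFrame(), linkage=np.empty((0, 4)), dendrogram_order=[]
        )
    stats = pd.DataFrame(rows).set_index("pathway_id").sort_index()

    coords = stats[["log2fc_correlation", "degree_correlation"]].fillna(0.0).to_numpy()
    if len(stats) >= 2:
        link = hierarchy.linkage(coords, method="average", metric="euclidean")
        order = [stats.index[i] for i in hierarchy.leaves_list(link)]
    else:
        link = np.empty((0, 4))
        order = list(stats.index)
    return PathwayDegreeResult(stats=stats, linkage=link, dendrogram_order=order)


# ---------------------------------------------------------------------------
# Mummichog-style enrichment
# ---------------------------------------------------------------------------

def _weighted_counts(
    feature_ids, pathway_features: dict[str, set[str]], weight: pd.Series
) -> dict[str, float]:
    out = {}
    fset = set(feature_ids)
    for pw, fids in pathway_features.items():
        out[pw] = float(sum(weight[f] for f in fids & fset))
    return out


def _fisher_p(sig_hits: int, sig_total: int, ref_hits: int, ref_total: int) -> float:
    """One-sided (enrichment) Fisher exact p for a pathway's significant
    hits against its reference hits."""
    table = [
        [sig_hits, sig_total - sig_hits],
        [ref_hits - sig_hits, (ref_total - ref_hits) - (sig_total - sig_hits)],
    ]
    return float(sstats.fisher_exact(table, alternative="greater")[1])


def mummichog_enrichment(
    significant,
    reference,
    annotations: pd.DataFrame,
    library: CompoundLibrary,
    n_perm: int = 100,
    overlap_weight: float = 0.001,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation-calibrated pathway enrichment from putative annotations.

    A reduced mummichog-style procedure: per pathway, the weighted count of
    significant annotated features (features annotated to more than one
    compound contribute ``overlap_weight`` instead of 1, down-weighting
    ambiguous matches) is tested against the reference-feature hits with a
    one-sided Fisher exact test; a null distribution is built from
    ``n_perm`` random draws of |significant| features out of the reference,
    a gamma distribution is fitted to the pooled null -log p values by the
    method of moments, and ``p_gamma`` is the upper-tail probability of each
    observed -log p under that gamma.

    Returns a DataFrame with columns ``pathway_id, hits_significant,
    hits_reference, p_fisher, p_gamma`` (pathways without reference hits are
    skipped).
    """
    significant = set(significant)
    reference = set(reference)
    if not significant <= reference:
        raise ValueError("significant features must be a subset of the reference")
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")

    fmap = feature_pathway_map(annotations, library)
    pathway_features: dict[str, set[str]] = {}
    for fid, pws in fmap.items():
        if fid not in reference:
            continue
        for pw in pws:
            pathway_features.setdefault(pw, set()).add(fid)
    pathway_features = {pw: fids for pw, fids in pathway_features.items() if fids}
    if not pathway_features:
        return pd.DataFrame(
            columns=["pathway_id", "hits_significant", "hits_reference",
                     "p_fisher", "p_gamma"]
        )

    n_compounds = annotations.groupby("feature_id")["compound_id"].nunique()
    weight = pd.Series(1.0, index=sorted(reference))
    ambiguous = n_compounds.index[n_compounds > 1]
    weight[weight.index.intersection(ambiguous)] = overlap_weight

    ref_list = sorted(reference)
    ref_counts = _weighted_counts(ref_list, pathway_features, weight)
    sig_counts = _weighted_counts(significant, pathway_features, weight)
    n_ref, n_sig = len(reference), len(significant)

    def pathway_ps(counts: dict[str, float], total: int) -> dict[str, float]:
        return {
            pw: _fisher_p(int(np.floor(counts[pw])), total,
                          int(np.floor(ref_counts[pw])), n_ref)
            for pw in pathway_features
        }

    observed_p = pathway_ps(sig_counts, n_sig)

    rng = np.random.default_rng(seed)
    null_neglogp = []
    for _ in range(n_perm):
        draw = rng.choice(ref_list, size=n_sig, replace=False)
        counts = _weighted_counts(draw, pathway_features, weight)
        for p in pathway_ps(counts, n_sig).values():
            null_neglogp.append(-np.log(max(p, 1e-300)))
    null_neglogp = np.asarray(null_neglogp)

    mean, var = null_neglogp.mean(), null_neglogp.var(ddof=1)
    if var > 0 and mean > 0:
        shape = mean**2 / var
        scale = var / mean
        gamma = sstats.gamma(a=shape, scale=scale)
        p_gamma = {
            pw: float(gamma.sf(-np.log(max(p, 1e-300))))
            for pw, p in observed_p.items()
        }
    else:  # degenerate null (all p identical): fall back to empirical tail
        p_gamma = {
            pw: float(
                (1 + np.sum(null_neglogp >= -np.log(max(p, 1e-300))))
                / (1 + len(null_neglogp))
            )
            for pw, p in observed_p.items()
        }

    rows = [
        {
            "pathway_id": pw,
            "hits_significant": sig_counts[pw],
            "hits_reference": int(np.floor(ref_counts[pw])),
            "p_fisher": observed_p[pw],
            "p_gamma": p_gamma[pw],
        }
        for pw in sorted(pathway_features)
    ]
    return pd.DataFrame(rows)
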