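"""Differential statistics and visualization matrices.

Per-feature comparison of the wild and cultivated groups: Welch t-tests
(unequal variances) on raw intensities, fold changes as ratios of group
means, two-tier significance calls, volcano selection, autoscaling
(per-variable z-scoring), PCA, deterministic heatmap ordering, and
per-marker semi-quantification summaries.

Thresholds follow standard two-tier untargeted-metabolomics practice:
significant means fold change >= 1.5 and p <= 0.05 (inclusive), highly
significant additionally p <= 0.01; volcano selection is stricter and
exclusive (fold change > 2 and p < 0.05).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.decomposition import PCA

from .features import FeatureTable, MetaboliteGroup

__all__ = [
    "welch_fold",
    "volcano_select",
    "significance_tiers",
    "autoscale",
    "pca_scores",
    "heatmap_matrix",
    "marker_summary",
]


def welch_fold(table: FeatureTable, fdr: bool = False) -> pd.DataFrame:
    """Per-feature Welch t-test and group-mean fold change.

    Returns a DataFrame indexed by feature id with group means, the
    wild/cultivated mean ratio, the symmetric fold change (always >= 1,
    direction recorded separately), two-sided Welch p-value, and the
    log2 fold change / -log10 p columns used for volcano plots.

    Zero group means are replaced by half the smallest nonzero intensity
    in the table (a pseudo-count) before forming ratios; affected rows are
    flagged in ``pseudo_count_used``. With ``fdr=True`` a Benjamini-
    Hochberg adjusted ``q_value`` column is appended.
    """
    for grp in ("wild", "cultivated"):
        if len(table.samples_in(grp)) < 2:
            raise ValueError(f"group {grp!r} needs >= 2 samples for a Welch t-test")
    wild = table.features[table.samples_in("wild")].to_numpy(dtype=float)
    cult = table.features[table.samples_in("cultivated")].to_numpy(dtype=float)

    mean_w = wild.mean(axis=1)
    mean_c = cult.mean(axis=1)
    positive = table.intensities.to_numpy(dtype=float)
    nonzero = positive[positive > 0]
    pseudo = 0.5 * nonzero.min() if nonzero.size else 1.0
    used = (mean_w == 0) | (mean_c == 0)
    mw = np.where(mean_w == 0, pseudo, mean_w)
    mc = np.where(mean_c == 0, pseudo, mean_c)

    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = sps.ttest_ind(wild, cult, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance identical rows

    ratio = mw / mc
    fc = np.maximum(ratio, 1.0 / ratio)
    direction = np.where(ratio > 1, "up-in-wild", np.where(ratio < 1, "up-in-cultivated", "ns"))

    out = pd.DataFrame(
        {
            "mean_wild": mean_w,
            "mean_cultivated": mean_c,
            "ratio_wild_over_cultivated": ratio,
            "fold_change": fc,
            "direction": direction,
            "p_value": p,
            "log2_fc": np.log2(ratio),
            "neg_log10_p": -np.log10(np.clip(p, np.finfo(float).tiny, None)),
            "pseudo_count_used": used,
        },
        index=table.features.index,
    )
    if fdr:
        out["q_value"] = sps.false_discovery_control(p)
    return out


def volcano_select(
    results: pd.DataFrame, fc_thresh: float = 2.0, p_thresh: float = 0.05
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Split results into (up-in-wild, up-in-cultivated, ns) volcano sets.

    Selection requires fold change strictly greater than ``fc_thresh`` in
    either direction AND p strictly below ``p_thresh``; boundary values
    are not selected. The three sets are disjoint and cover the input.
    """
    if results.empty:
        raise ValueError("no results to select from")
    selected = (results["fold_change"] > fc_thresh) & (results["p_value"] < p_thresh)
    up_wild = results[selected & (results["ratio_wild_over_cultivated"] > 1)]
    up_cult = results[selected & (results["ratio_wild_over_cultivated"] < 1)]
    ns = results[~results.index.isin(up_wild.index.union(up_cult.index))]
    return up_wild, up_cult, ns


def significance_tiers(
    results: pd.DataFrame,
    p_sig: float = 0.05,
    p_high: float = 0.01,
    fc_thresh: float = 1.5,
) -> pd.Series:
    """Two-tier significance labels with inclusive thresholds.

    ``significant``: fold change >= fc_thresh and p <= p_sig;
    ``highly significant``: additionally p <= p_high (a subset of the
    significant tier); everything else ``ns``.
    """
    fc_ok = results["fold_change"] >= fc_thresh
    sig = fc_ok & (results["p_value"] <= p_sig)
    high = sig & (results["p_value"] <= p_high)
    tiers = pd.Series("ns", index=results.index, name="tier")
    tiers[sig] = "significant"
    tiers[high] = "highly significant"
    return tiers


def autoscale(matrix: pd.DataFrame) -> pd.DataFrame:
    """Autoscale a variables x samples matrix: per-row mean 0, sd 1.

    Mean-centering followed by division by the per-variable standard
    deviation (population sd, ddof=0). Zero-variance rows cannot be scaled
    and are set to all zeros with a warning.
    """
    if matrix.shape[1] < 2:
        raise ValueError("autoscaling needs >= 2 samples")
    values = matrix.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    flat = (sd == 0).ravel()
    if flat.any():
        warnings.warn(
            f"{int(flat.sum())} zero-variance row(s) set to zero during autoscaling",
            stacklevel=2,
        )
    sd[sd == 0] = 1.0
    scaled = (values - mean) / sd
    scaled[flat, :] = 0.0
    return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)


def pca_scores(scaled: pd.DataFrame, n_components: int | None = None):
    """PCA of the autoscaled matrix via singular-value decomposition.

    ``scaled`` is variables x samples (as returned by :func:`autoscale`);
    observations for the PCA are the samples. Returns ``(scores,
    loadings, variance_explained)`` where scores is samples x components,
    loadings is variables x components and variance_explained is in
    percent of total variance.
    """
    X = scaled.to_numpy(dtype=float).T  # samples x variables
    if X.shape[0] < 2:
        raise ValueError("PCA needs more than one sample")
    if not np.isfinite(X).all():
        raise ValueError("non-finite entries in matrix")
    if not X.any():
        raise ValueError("degenerate all-zero matrix")
    max_rank = min(X.shape[0], X.shape[1])
    k = max_rank if n_components is None else min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    s = pca.fit_transform(X)
    scores = pd.DataFrame(
        s, index=scaled.columns, columns=[f"PC{i + 1}" for i in range(k)]
    )
    loadings = pd.DataFrame(
        pca.components_.T, index=scaled.index, columns=scores.columns
    )
    variance_explained = pd.Series(
        pca.explained_variance_ratio_ * 100.0, index=scores.columns
    )
    return scores, loadings, variance_explained


def heatmap_matrix(
    scaled: pd.DataFrame, order_by: pd.Series | None = None, ascending: bool = True
) -> pd.DataFrame:
    """Deterministically row-ordered matrix for heatmap export.

    Rows are sorted by the ``order_by`` key (typically the p-value),
    ascending by default; ties fall back to feature id so the ordering is
    stable and reproducible. The result is a permutation of the input.
    """
    if order_by is None:
        return scaled.sort_index()
    key = order_by.reindex(scaled.index)
    order = sorted(scaled.index, key=lambda fid: (key.loc[fid], str(fid)))
    if not ascending:
        order = order[::-1]
    return scaled.loc[order]


def marker_summary(
    groups: Sequence[MetaboliteGroup], table: FeatureTable
) -> pd.DataFrame:
    """Per-marker group-wise semi-quantification from representative ions.

    For each metabolite group: five-number boxplot statistics of the
    representative feature's intensities in each sample group, the
    wild/cultivated mean ratio, and the favored direction.
    """
    rows = []
    for g in groups:
        if g.representative_id not in table.features.index:
            raise KeyError(f"marker feature {g.representative_id!r} absent from table")
        intens = table.features.loc[g.representative_id]
        rec: dict = {
            "compound": g.compound,
            "compound_class": g.compound_class,
            "consensus_rt": g.consensus_rt,
            "n_features": g.n_members,
        }
        means = {}
        for grp in ("wild", "cultivated"):
            x = intens[table.samples_in(grp)].to_numpy(dtype=float)
            means[grp] = x.mean()
            q1, med, q3 = np.percentile(x, [25, 50, 75])
            rec.update(
                {
                    f"{grp}_min": x.min(),
                    f"{grp}_q1": q1,
                    f"{grp}_median": med,
                    f"{grp}_q3": q3,
                    f"{grp}_max": x.max(),
                    f"{grp}_mean": means[grp],
                }
            )
        ratio = means["wild"] / means["cultivated"] if means["cultivated"] else np.inf
        rec["ratio_wild_over_cultivated"] = ratio
        rec["fold_change"] = max(ratio, 1.0 / ratio) if ratio > 0 else np.inf
        rec["richer_in"] = "wild" if ratio > 1 else ("cultivated" if ratio < 1 else "ns")
        rows.append(rec)
    return pd.DataFrame(rows).set_index("compound")
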