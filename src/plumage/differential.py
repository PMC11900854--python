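"""Protein-level differential statistics for two-group LFQ cohorts.

The stage mirrors standard practice for detection-limited plasma proteomics:

1. *Presence/absence*: every detected protein is tested for a difference in
   detection frequency between groups with a two-sided Fisher exact test
   (missingness is informative under a detection limit, so absence itself is
   a signal).
2. *Detection filter*: abundance testing is restricted to proteins detected
   in strictly more than 70% of samples in BOTH groups, so that rank tests
   operate on mostly-observed values.
3. *Abundance*: per-protein two-sided Mann-Whitney U on the non-missing
   intensities, exact when both groups are small and tie-free, otherwise the
   tie-corrected normal approximation with continuity correction. The fold
   change is the log2 ratio of group medians (robust, consistent with the
   rank test).
4. *FDR*: Benjamini-Hochberg within each test family separately — the
   presence/absence family (all detected proteins) and the abundance family
   (filtered proteins) are adjusted independently.

Z-scoring and scaled PCA provide the standard visual summaries (heatmaps,
sample clustering).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from plumage.io import IntensityMatrix


@dataclass
class PcaResult:
    """Sample scores on the leading components plus explained-variance fractions."""

    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    n_proteins_used: int


def detection_counts(matrix: IntensityMatrix, groups: dict[str, list[str]]) -> pd.DataFrame:
    """Per-protein detected counts and group sizes for the low/high split."""
    for g, samples in groups.items():
        if not samples:
            raise ValueError(f"group {g!r} has no samples")
    detected = matrix.values.notna()
    out = pd.DataFrame(index=matrix.values.index)
    for g, samples in groups.items():
        out[f"n_detected_{g}"] = detected[samples].sum(axis=1).astype(int)
        out[f"n_{g}"] = len(samples)
    return out


def detection_filter(
    matrix: IntensityMatrix,
    groups: dict[str, list[str]],
    threshold: float = 0.70,
) -> tuple[list[str], pd.DataFrame]:
    """Keep proteins detected in strictly more than ``threshold`` of samples in BOTH groups.

    The ">" is strict: a protein seen in exactly 70% of a group fails a 0.70
    threshold. Returns (kept protein ids in matrix order, per-protein
    detection-count table covering ALL proteins with a ``passed_filter`` flag).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    table = detection_counts(matrix, groups)
    passed = np.ones(len(table), dtype=bool)
    for g, samples in groups.items():
        passed &= table[f"n_detected_{g}"].to_numpy() > threshold * len(samples)
    table["passed_filter"] = passed
    kept = table.index[passed].tolist()
    return kept, table


def fisher_detection_test(n_det_low: int, n_low: int, n_det_high: int, n_high: int) -> float:
    """Two-sided Fisher exact p for the 2x2 detected/not-detected x group table."""
    if not (0 <= n_det_low <= n_low and 0 <= n_det_high <= n_high):
        raise ValueError("detected counts must lie within group sizes")
    table = [[n_det_low, n_low - n_det_low], [n_det_high, n_high - n_det_high]]
    return float(stats.fisher_exact(table, alternative="two-sided")[1])


def benjamini_hochberg(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-invariant.

    q_(i) = min_{j >= i} m * p_(j) / j over the ascending ordering, clipped
    at 1, mapped back to input positions. NaN inputs propagate to NaN outputs
    and do not count toward the family size m.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be 1-d")
    valid = ~np.isnan(p)
    if np.any((p[valid] < 0) | (p[valid] > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    q = np.full(p.shape, np.nan)
    pv = p[valid]
    m = pv.size
    if m == 0:
        return q
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    qs = np.minimum(np.minimum.accumulate(ranked[::-1])[::-1], 1.0)
    out = np.empty(m)
    out[order] = qs
    q[valid] = out
    return q


def _mann_whitney(x: np.ndarray, y: np.ndarray, exact_max_n: int = 10) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact for small tie-free samples, else
    tie-corrected normal approximation with continuity correction."""
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    if not has_ties and x.size <= exact_max_n and y.size <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method, use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def mann_whitney_differential(
    matrix: IntensityMatrix,
    groups: dict[str, list[str]],
    kept_proteins: list[str] | None = None,
    detection_threshold: float = 0.70,
) -> pd.DataFrame:
    """Full per-protein differential table for a two-group cohort.

    Returns one row per protein in the matrix with detection counts, the
    Fisher presence/absence test (``detection_p`` / ``detection_q``, BH over
    all proteins), and — for proteins passing the detection filter — the
    Mann-Whitney statistic, raw and BH-adjusted p (``abundance_q`` over
    exactly the filtered family) and the log2 median fold change (high vs
    low). A filtered protein with fewer than 2 non-missing values in either
    group has its abundance test marked undefined (NaN) and is excluded from
    the FDR family, flagged in ``abundance_undefined``.
    """
    if kept_proteins is None:
        kept_proteins, table = detection_filter(matrix, groups, detection_threshold)
    else:
        _, table = detection_filter(matrix, groups, detection_threshold)
        table["passed_filter"] = table.index.isin(set(kept_proteins))

    n_low, n_high = len(groups["low"]), len(groups["high"])
    det_p = np.array([
        fisher_detection_test(r[f"n_detected_low"], n_low, r[f"n_detected_high"], n_high)
        for _, r in table.iterrows()
    ])
    table = table.assign(detection_p=det_p, detection_q=benjamini_hochberg(det_p))

    low_vals = matrix.values[groups["low"]]
    high_vals = matrix.values[groups["high"]]
    stat = np.full(len(table), np.nan)
    pval = np.full(len(table), np.nan)
    lfc = np.full(len(table), np.nan)
    undefined = np.zeros(len(table), dtype=bool)
    kept_set = set(kept_proteins)
    for i, prot in enumerate(table.index):
        if prot not in kept_set:
            continue
        x = low_vals.loc[prot].dropna().to_numpy(float)
        y = high_vals.loc[prot].dropna().to_numpy(float)
        if x.size >= 1 and y.size >= 1:
            lfc[i] = np.log2(np.median(y) / np.median(x))
        if x.size < 2 or y.size < 2:
            undefined[i] = True
            continue
        stat[i], pval[i] = _mann_whitney(x, y)
    table = table.assign(
        mw_statistic=stat,
        abundance_p=pval,
        abundance_q=benjamini_hochberg(pval),
        log2_fold_change=lfc,
        abundance_undefined=undefined,
    )
    table.index.name = "protein_id"
    return table


def significant_proteins(differential: pd.DataFrame, alpha: float = 0.05) -> list[str]:
    """Protein ids with abundance_q < alpha."""
    mask = differential["abundance_q"] < alpha
    return differential.index[mask.fillna(False)].tolist()


def zscore_rows(values: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Standardize each protein row to mean 0, sd 1 over its non-missing entries.

    Missing entries stay missing. Rows with zero variance cannot be scaled;
    they are emitted as zeros and their ids returned as flagged.
    """
    if (values.notna().sum(axis=1) < 2).any():
        bad = values.index[values.notna().sum(axis=1) < 2].tolist()
        raise ValueError(f"rows with <2 non-missing values cannot be z-scored: {bad[:5]}")
    mean = values.mean(axis=1)
    sd = values.std(axis=1, ddof=1)
    flagged = values.index[sd == 0].tolist()
    safe_sd = sd.replace(0.0, np.nan)
    z = values.sub(mean, axis=0).div(safe_sd, axis=0)
    z.loc[flagged] = z.loc[flagged].where(values.loc[flagged].isna(), 0.0)
    return z, flagged


def scaled_pca(
    matrix: IntensityMatrix,
    n_components: int = 2,
    impute_policy: str = "complete-proteins",
    log_transform: bool = True,
) -> PcaResult:
    """Scaled PCA of samples over proteins (each protein centred, unit variance).

    Intensities are log2 transformed first (LFQ values are multiplicative).
    Missing values are handled by ``impute_policy``: "complete-proteins"
    drops any protein with missingness; "half-minimum" imputes missing cells
    with half the protein's observed minimum — the usual stand-in for a value
    below the detection limit.
    """
    values = matrix.values
    if log_transform:
        values = np.log2(values)
    if impute_policy == "complete-proteins":
        values = values.dropna(axis=0, how="any")
    elif impute_policy == "half-minimum":
        fill = values.min(axis=1) - (1.0 if log_transform else 0.0)
        if not log_transform:
            fill = values.min(axis=1) / 2.0
        values = values.apply(lambda row: row.fillna(fill[row.name]), axis=1)
        values = values.dropna(axis=0, how="any")  # rows that were all-missing
    else:
        raise ValueError(f"unknown impute_policy {impute_policy!r}")
    sd = values.std(axis=1, ddof=1)
    values = values[sd > 0]
    x = values.to_numpy(float).T  # samples x proteins
    x = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    max_rank = min(x.shape) - 1 if min(x.shape) > 1 else 1
    k = min(n_components, max_rank)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    return PcaResult(
        scores=pd.DataFrame(scores, index=values.columns,
                            columns=[f"PC{i + 1}" for i in range(k)]),
        explained_variance_ratio=pca.explained_variance_ratio_,
        n_proteins_used=values.shape[0],
    )
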