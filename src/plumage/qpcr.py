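"""Relative gene expression by the delta-delta-Ct method, with QC gating.

Quantities, per sample and gene (classic 100%-efficiency convention):

    mean Ct   — arithmetic mean over replicate wells (triplicates typically)
    dCt       — mean Ct(gene) - mean Ct(housekeeping), same sample
    ddCt      — dCt - mean(dCt over reference-group samples)
    fold      — 2 ** (-ddCt)

Referencing against the reference-group *mean* (rather than one calibrator
sample) matches a group-comparison design. Because dCt subtracts the
housekeeping Ct within a sample, any per-sample plate or loading offset
cancels exactly. Group differences are tested on dCt with an ordinary linear
model (optionally after Box-Cox), which on the log2 scale is the natural
test for a multiplicative expression change.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from plumage.io import CtTable
from plumage.transforms import boxcox_mle

REPLICATE_SD_FLAG = 0.5  # cycles; triplicates spreading wider than this are suspect


def delta_delta_ct(
    ct: CtTable,
    housekeeping_gene: str,
    reference_group: str = "low",
    replicate_sd_flag: float = REPLICATE_SD_FLAG,
) -> pd.DataFrame:
    """Per (sample, gene) ddCt table with fold changes.

    Samples missing a housekeeping measurement are excluded (all their
    genes); replicate SDs above ``replicate_sd_flag`` cycles are flagged but
    kept. The housekeeping gene itself appears with dCt = 0 and fold 1 by
    construction. Raises if the reference group is empty after exclusions.
    """
    data = ct.data
    if housekeeping_gene not in set(data["gene"]):
        raise ValueError(f"housekeeping gene {housekeeping_gene!r} absent from Ct table")
    agg = (data.groupby(["sample_id", "gene"], sort=True)
           .agg(mean_ct=("ct", "mean"), ct_sd=("ct", "std"),
                n_replicates=("ct", "size"), group=("group", "first"))
           .reset_index())
    hk = agg[agg["gene"] == housekeeping_gene].set_index("sample_id")["mean_ct"]
    have_hk = agg["sample_id"].isin(hk.index)
    dropped = sorted(set(agg.loc[~have_hk, "sample_id"]))
    if dropped:
        import warnings

        warnings.warn(f"samples without housekeeping Ct excluded: {dropped}", stacklevel=2)
    agg = agg[have_hk].copy()
    agg["delta_ct"] = agg["mean_ct"] - agg["sample_id"].map(hk)

    ref = agg[agg["group"] == reference_group]
    if ref.empty:
        raise ValueError(f"reference group {reference_group!r} is empty")
    ref_means = ref.groupby("gene")["delta_ct"].mean()
    agg["delta_delta_ct"] = agg["delta_ct"] - agg["gene"].map(ref_means)
    agg["fold_change"] = np.exp2(-agg["delta_delta_ct"])
    agg["replicate_sd_flag"] = agg["ct_sd"].fillna(0.0) > replicate_sd_flag
    return agg


def compare_expression(
    ddct: pd.DataFrame,
    transform: str = "none",
) -> pd.DataFrame:
    """Per-gene linear-model comparison of dCt between exposure groups.

    Fits delta_ct ~ group per gene (high vs the other group) and reports the
    group coefficient on the dCt scale, its two-sided p, and the geometric
    mean fold change per group. ``transform='boxcox'`` transforms dCt first
    (with the automatic positivity shift — dCt can be negative). Genes with
    degenerate variance are flagged with p = NaN.
    """
    rows = []
    for gene, sub in ddct.groupby("gene", sort=True):
        groups = sub["group"].unique()
        if len(groups) != 2:
            continue
        y = sub["delta_ct"].to_numpy(float)
        x = (sub["group"] == "high").to_numpy(float)
        if min((x == 0).sum(), (x == 1).sum()) < 2:
            raise ValueError(f"gene {gene!r}: need >=2 samples per group")
        lam = None
        if transform == "boxcox":
            if np.ptp(y) > 0:
                y, lam, _ = boxcox_mle(y)
        elif transform != "none":
            raise ValueError(f"unknown transform {transform!r}")
        fold_high = float(np.exp2(-sub.loc[sub["group"] == "high", "delta_delta_ct"]).mean())
        fold_ref = float(np.exp2(-sub.loc[sub["group"] != "high", "delta_delta_ct"]).mean())
        if np.ptp(y) == 0:
            # identical dCt everywhere: no evidence of a group difference
            rows.append({"gene": gene, "coef": 0.0, "se": np.nan, "t": 0.0,
                         "p": 1.0, "boxcox_lambda": lam, "degenerate": True,
                         "mean_fold_high": fold_high, "mean_fold_reference": fold_ref})
            continue
        model = sm.OLS(y, sm.add_constant(x)).fit()
        rows.append({
            "gene": gene,
            "coef": float(model.params[1]),
            "se": float(model.bse[1]),
            "t": float(model.tvalues[1]),
            "p": float(model.pvalues[1]),
            "boxcox_lambda": lam,
            "degenerate": False,
            "mean_fold_high": fold_high,
            "mean_fold_reference": fold_ref,
        })
    return pd.DataFrame(rows).set_index("gene")


@dataclass(frozen=True)
class RnaQcThresholds:
    """Spectrophotometric RNA quality gates.

    The concentration gate defaults to the conventional >= 100 ng/ul
    inclusion; ``literal_low_concentration=True`` flips it to < 100 ng/ul for
    protocols written the other way around. Purity ratios: A260/280 near 2.0
    and A260/230 within [2.0, 2.2].
    """

    min_concentration: float = 100.0  # ng/ul
    a260_280_range: tuple[float, float] = (1.9, 2.1)
    a260_230_range: tuple[float, float] = (2.0, 2.2)
    literal_low_concentration: bool = False


def rna_qc_filter(
    concentration: float,
    a260_280: float,
    a260_230: float,
    thresholds: RnaQcThresholds = RnaQcThresholds(),
) -> tuple[bool, list[str]]:
    """Gate an RNA extraction on concentration and purity ratios.

    Returns (passed, reason codes); boundaries are inclusive. Reason codes
    name the failing measurement: 'concentration', 'a260_280', 'a260_230'.
    """
    if min(concentration, a260_280, a260_230) < 0:
        raise ValueError("measurements must be nonnegative")
    reasons = []
    t = thresholds
    conc_ok = (concentration < t.min_concentration if t.literal_low_concentration
               else concentration >= t.min_concentration)
    if not conc_ok:
        reasons.append("concentration")
    if not t.a260_280_range[0] <= a260_280 <= t.a260_280_range[1]:
        reasons.append("a260_280")
    if not t.a260_230_range[0] <= a260_230 <= t.a260_230_range[1]:
        reasons.append("a260_230")
    return (not reasons), reasons
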