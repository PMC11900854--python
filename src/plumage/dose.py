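"""Per-protein dose-response linear models against ingested plastic load.

The tissue arm (hippocampal brain in the motivating study design) shows more
within-group spread than plasma, so instead of a two-group contrast each
protein's abundance is regressed on the continuous plastic burden in grams:

    g(abundance_j) = beta0 + beta1 * mass_j + eps_j

with g either the identity or a Box-Cox transform chosen by profile
likelihood (abundances are positive and right-skewed). The two-sided t test
on the slope beta1 is the dose-dependence test; Benjamini-Hochberg controls
the FDR across a screened protein set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from plumage.differential import benjamini_hochberg
from plumage.io import IntensityMatrix
from plumage.transforms import boxcox_mle


@dataclass
class DoseResponseResult:
    protein_id: str
    boxcox_lambda: float | None
    slope: float
    slope_se: float
    t_statistic: float
    p_value: float
    n: int
    degenerate: bool = False


def fit_dose_response(
    abundances: np.ndarray,
    plastic_mass: np.ndarray,
    transform: str = "boxcox",
    protein_id: str = "",
) -> DoseResponseResult:
    """OLS of (optionally Box-Cox transformed) abundance on plastic mass (g).

    Samples with missing abundance are dropped; at least 3 complete pairs are
    required. Constant mass is rejected (no dose contrast); constant
    abundance yields a degenerate flag with slope 0 and p = 1.
    """
    y = np.asarray(abundances, dtype=float)
    x = np.asarray(plastic_mass, dtype=float)
    if y.shape != x.shape:
        raise ValueError("abundance and mass vectors differ in length")
    if np.any(x < 0):
        raise ValueError("plastic mass must be nonnegative")
    keep = ~np.isnan(y)
    y, x = y[keep], x[keep]
    if y.size < 3:
        raise ValueError("need >=3 samples with non-missing abundance")
    if np.ptp(x) == 0:
        raise ValueError("plastic mass is constant; no dose contrast")
    lam: float | None = None
    if transform == "boxcox":
        if np.ptp(y) > 0:
            y, lam, _ = boxcox_mle(y)
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    if np.ptp(y) == 0:
        return DoseResponseResult(protein_id, lam, 0.0, np.nan, np.nan, 1.0,
                                  n=y.size, degenerate=True)
    model = sm.OLS(y, sm.add_constant(x)).fit()
    return DoseResponseResult(
        protein_id=protein_id,
        boxcox_lambda=lam,
        slope=float(model.params[1]),
        slope_se=float(model.bse[1]),
        t_statistic=float(model.tvalues[1]),
        p_value=float(model.pvalues[1]),
        n=int(y.size),
    )


def dose_response_screen(
    matrix: IntensityMatrix,
    metadata: pd.DataFrame,
    proteins: list[str] | None = None,
    transform: str = "boxcox",
) -> pd.DataFrame:
    """Dose-response fit for each screened protein, with BH q across the screen.

    ``proteins`` defaults to every protein in the matrix. Proteins whose fit
    is impossible (too few observations) are reported with NaN statistics and
    excluded from the FDR family.
    """
    proteins = list(proteins) if proteins is not None else matrix.protein_ids
    if not proteins:
        raise ValueError("empty protein subset")
    mass = metadata.set_index("sample_id")["plastic_mass"].reindex(matrix.sample_ids)
    if mass.isna().any():
        missing = mass.index[mass.isna()].tolist()
        raise ValueError(f"samples without plastic_mass metadata: {missing[:5]}")
    rows = []
    for prot in proteins:
        y = matrix.values.loc[prot].to_numpy(float)
        try:
            res = fit_dose_response(y, mass.to_numpy(float), transform=transform,
                                    protein_id=prot)
            rows.append({
                "protein_id": prot, "boxcox_lambda": res.boxcox_lambda,
                "slope": res.slope, "slope_se": res.slope_se,
                "t": res.t_statistic, "p": res.p_value, "n": res.n,
                "degenerate": res.degenerate,
            })
        except ValueError:
            rows.append({"protein_id": prot, "boxcox_lambda": np.nan, "slope": np.nan,
                         "slope_se": np.nan, "t": np.nan, "p": np.nan, "n": 0,
                         "degenerate": True})
    table = pd.DataFrame(rows).set_index("protein_id")
    p_for_fdr = table["p"].where(~table["degenerate"])
    table["q"] = benjamini_hochberg(p_for_fdr.to_numpy(float))
    return table
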