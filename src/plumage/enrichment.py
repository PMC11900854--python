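"""Background-constrained permutation enrichment and composition summaries.

Over-representation analysis for a nonmodel organism cannot lean on
genome-wide annotation frequencies: the expected pathway composition of a
random protein set must come from an empirical background — here, the
proteins detected in the reference (low-exposure) group. For each pathway
the observed count of significant proteins ``k_sig`` is compared against a
null built by drawing ``B`` uniform random subsets of the significant-set
size ``m`` from the background (without replacement) and counting pathway
members in each draw. The permutation p-value uses the add-one convention

    p = (1 + #{draws with k >= k_sig}) / (B + 1)

so a finite number of resamples can never report p = 0. As B grows this
converges to the hypergeometric upper tail P(X >= k_sig) with parameters
(N, K_bg, m) — the permutation machinery is kept because it generalises to
statistics without closed-form nulls and mirrors resampling-based practice.

The default test is upper-tail (over-representation of significant proteins
in a pathway); a two-sided variant doubles the smaller tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from plumage.differential import benjamini_hochberg
from plumage.io import AnnotationSet


@dataclass
class BackgroundCounts:
    """Pathway membership counts restricted to an empirical background set."""

    background: list[str]  # ordered protein ids
    pathway_counts: dict[str, int]  # pathway -> K_bg
    membership: pd.DataFrame = field(repr=False)  # pathways x background bool

    @property
    def n(self) -> int:
        return len(self.background)


def build_background(background_proteins: list[str], annotations: AnnotationSet) -> BackgroundCounts:
    """Per-pathway membership counts within the background protein set.

    Proteins without any pathway annotation still count toward N (the
    background size) but appear in no pathway row. An annotation set whose
    universe is disjoint from the background yields all-zero counts.
    """
    background = list(dict.fromkeys(background_proteins))
    if not background:
        raise ValueError("background set is empty")
    bg_index = pd.Index(background)
    rows = {}
    for pid, members in annotations.pathways.items():
        rows[pid] = bg_index.isin(members)
    membership = pd.DataFrame(rows, index=bg_index).T if rows else pd.DataFrame(
        np.empty((0, len(background)), dtype=bool), columns=bg_index)
    counts = {pid: int(membership.loc[pid].sum()) for pid in membership.index}
    return BackgroundCounts(background=background, pathway_counts=counts, membership=membership)


def _random_subset_indicators(rng: np.random.Generator, n: int, m: int, b: int) -> np.ndarray:
    """(b, n) boolean matrix; each row marks a uniform m-subset of range(n)."""
    # rank trick: the m smallest of n iid uniforms form a uniform m-subset
    u = rng.random((b, n))
    idx = np.argpartition(u, m - 1, axis=1)[:, :m]
    out = np.zeros((b, n), dtype=bool)
    np.put_along_axis(out, idx, True, axis=1)
    return out


def permutation_enrichment(
    sig_set: set[str] | list[str],
    background: BackgroundCounts,
    annotations: AnnotationSet,
    differential: pd.DataFrame | None = None,
    b_resamples: int = 10_000,
    seed: int | np.random.Generator = 0,
    two_sided: bool = False,
) -> pd.DataFrame:
    """Permutation over-representation test for every pathway with background members.

    ``sig_set`` must be a subset of the background. Returns one row per
    testable pathway (K_bg > 0): counts, add-one permutation p, BH q within
    each annotation source, and the direction of change of the pathway's
    significant members (up / down / mixed by their log2 fold changes, when a
    differential table is supplied). Fully reproducible under a fixed seed.
    """
    sig = list(dict.fromkeys(sig_set))
    bg_set = set(background.background)
    stray = [p for p in sig if p not in bg_set]
    if stray:
        raise ValueError(f"significant proteins outside the background: {stray[:5]}")
    if b_resamples < 1:
        raise ValueError("b_resamples must be >= 1")
    m, n = len(sig), background.n
    if m > n:
        raise ValueError("significant set larger than background")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    pathways = [pid for pid, k in background.pathway_counts.items() if k > 0]
    if not pathways or m == 0:
        return pd.DataFrame(columns=["pathway_id", "source", "k_sig", "K_bg", "m", "N",
                                     "null_mean", "null_sd", "p_perm", "q", "direction"])
    member = background.membership.loc[pathways].to_numpy(bool)  # P x N
    sig_indicator = background.membership.columns.isin(sig)  # N
    # integer cast matters: bool @ bool is a logical any, not a count
    k_sig = member.astype(np.int64) @ sig_indicator.astype(np.int64)  # P

    # draw resamples in blocks to bound memory at ~ block * N bytes
    block = max(1, min(b_resamples, int(2e7) // max(n, 1)))
    exceed = np.zeros(len(pathways), dtype=np.int64)
    below = np.zeros(len(pathways), dtype=np.int64)
    sum_k = np.zeros(len(pathways))
    sum_k2 = np.zeros(len(pathways))
    done = 0
    while done < b_resamples:
        nb = min(block, b_resamples - done)
        draws = _random_subset_indicators(rng, n, m, nb)  # nb x N
        k_null = member.astype(np.int64) @ draws.T.astype(np.int64)  # P x nb
        exceed += (k_null >= k_sig[:, None]).sum(axis=1)
        below += (k_null <= k_sig[:, None]).sum(axis=1)
        sum_k += k_null.sum(axis=1)
        sum_k2 += (k_null.astype(float) ** 2).sum(axis=1)
        done += nb

    p_upper = (1.0 + exceed) / (b_resamples + 1.0)
    p_lower = (1.0 + below) / (b_resamples + 1.0)
    p_perm = np.minimum(2.0 * np.minimum(p_upper, p_lower), 1.0) if two_sided else p_upper

    null_mean = sum_k / b_resamples
    null_sd = np.sqrt(np.maximum(sum_k2 / b_resamples - null_mean**2, 0.0))

    directions = []
    lfc = (differential["log2_fold_change"] if differential is not None
           and "log2_fold_change" in differential.columns else None)
    for pid in pathways:
        members_sig = annotations.pathways[pid] & set(sig)
        if lfc is None or not members_sig:
            directions.append("unknown")
            continue
        signs = np.sign(lfc.reindex(sorted(members_sig)).dropna())
        if len(signs) == 0:
            directions.append("unknown")
        elif (signs > 0).all():
            directions.append("up")
        elif (signs < 0).all():
            directions.append("down")
        else:
            directions.append("up" if signs.mean() > 0 else "down" if signs.mean() < 0 else "mixed")

    result = pd.DataFrame({
        "pathway_id": pathways,
        "source": [annotations.sources.get(pid, "unknown") for pid in pathways],
        "k_sig": k_sig.astype(int),
        "K_bg": [background.pathway_counts[pid] for pid in pathways],
        "m": m,
        "N": n,
        "null_mean": null_mean,
        "null_sd": null_sd,
        "p_perm": p_perm,
        "direction": directions,
    })
    # BH within each annotation source, as separate multiplicity families
    q = np.full(len(result), np.nan)
    for src in result["source"].unique():
        mask = (result["source"] == src).to_numpy()
        q[mask] = benjamini_hochberg(result.loc[mask, "p_perm"].to_numpy())
    result["q"] = q
    result["enrichment_fraction"] = [
        f"{k}/{kb}" for k, kb in zip(result["k_sig"], result["K_bg"])
    ]
    return result.sort_values("p_perm", kind="stable").reset_index(drop=True)


def composition_summary(
    differential: pd.DataFrame,
    annotations: AnnotationSet,
    alpha: float = 0.05,
) -> dict[str, pd.DataFrame]:
    """Cross-tabulate significant proteins by secretion status and organ vs direction.

    Direction is the sign of the log2 fold change (high vs low); proteins
    without a secretion or organ annotation fall under "unknown". Counts in
    the secretion table sum to the number of significant proteins.
    """
    sig_mask = (differential["abundance_q"] < alpha).fillna(False)
    sig = differential[sig_mask]
    directions = np.where(sig["log2_fold_change"] > 0, "up",
                          np.where(sig["log2_fold_change"] < 0, "down", "unchanged"))
    secretion = [annotations.secretion_of(p) for p in sig.index]
    sec_table = pd.crosstab(pd.Series(secretion, name="secretion"),
                            pd.Series(directions, name="direction"))
    organ_rows = []
    for prot, direction in zip(sig.index, directions):
        for organ in sorted(annotations.organs.get(prot, {"unknown"})):
            organ_rows.append((organ, direction))
    if organ_rows:
        organs, dirs = zip(*organ_rows)
        organ_table = pd.crosstab(pd.Series(organs, name="organ"),
                                  pd.Series(dirs, name="direction"))
    else:
        organ_table = pd.DataFrame()
    return {"secretion": sec_table, "organ": organ_table}
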