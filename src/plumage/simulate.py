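"""Synthetic two-group cohort generator with known ground truth.

The generator emulates the signal structure of a plasma proteome responding
to chronic tissue damage: a minority of proteins is *affected* by exposure —
intracellular proteins leak into plasma and rise in the high-exposure group,
secreted proteins fall as the producing organs lose function — while the
rest are null. Missingness is missing-not-at-random: a measurement is absent
exactly when its latent log-abundance falls below a detection limit, so
low-abundance proteins go missing more often and an exposure effect shifts
detection frequency as well as abundance.

Per-protein baseline means are spread over roughly six log2 units (a typical
plasma dynamic range after search-engine normalisation); within-group
variation is lognormal. The plastic burden covariate is near zero for
low-exposure birds and heavy-tailed (lognormal) for high-exposure birds,
spanning roughly two orders of magnitude in grams, which is what drives the
dose-response arm.

All randomness flows through one ``numpy`` Generator keyed by a single
integer seed; identical designs and seeds give bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from plumage.io import AnnotationSet, CtTable, IntensityMatrix


@dataclass(frozen=True)
class CohortDesign:
    """Parameters of a simulated two-group plasma cohort.

    Defaults encode the cohort structure the pipeline is designed for:
    13 low- vs 18 high-exposure birds, ~800 quantified proteins, 30% of
    proteins affected with +/- 1 log2 effects (intracellular up, secreted
    down), and a detection limit inside the dynamic range so that MNAR
    missingness is material.
    """

    n_low: int = 13
    n_high: int = 18
    n_proteins: int = 800
    fraction_secreted: float = 0.45
    effect_up_intracellular: float = 1.0  # log2 units, high vs low
    effect_down_secreted: float = 1.0  # log2 units (magnitude of the decrease)
    fraction_affected: float = 0.30
    baseline_mean_low: float = 16.0  # log2 abundance at the bottom of the dynamic range
    baseline_mean_span: float = 6.0  # log2 units of between-protein spread
    detection_limit: float = 16.5  # log2 abundance below which a value is not detected
    noise_sd: float = 0.8  # within-group log2 SD
    pathway_count: int = 20
    pathway_size_min: int = 10
    pathway_size_max: int = 40
    fraction_pathways_enriched: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_low, self.n_high, self.n_proteins, self.pathway_count) < 1:
            raise ValueError("counts must be >= 1")
        for frac in (self.fraction_secreted, self.fraction_affected,
                     self.fraction_pathways_enriched):
            if not 0 < frac < 1:
                raise ValueError("fractions must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not self.pathway_size_min <= self.pathway_size_max:
            raise ValueError("pathway size range inverted")
        if self.n_proteins < self.pathway_size_max:
            raise ValueError("n_proteins smaller than the largest pathway")


@dataclass
class CohortTruth:
    """Ground truth behind a simulated cohort, for parameter-recovery tests."""

    protein_class: pd.Series  # protein -> {intracellular, secreted}
    true_effect: pd.Series  # protein -> log2 effect in the high group (0 for null)
    organ: pd.Series  # protein -> organ label
    pathway_enriched: dict[str, bool]  # pathway -> truly enriched in affected proteins
    plastic_mass: pd.Series = field(default_factory=pd.Series)  # sample -> g
    baseline_mean: pd.Series = field(default_factory=pd.Series)  # protein -> log2 mu_i

    def affected_proteins(self) -> list[str]:
        return self.true_effect.index[self.true_effect != 0].tolist()


_ORGANS = ("liver", "kidney", "stomach", "brain", "muscle", "immune")


def simulate_cohort(
    design: CohortDesign,
) -> tuple[IntensityMatrix, pd.DataFrame, AnnotationSet, CohortTruth]:
    """Draw one cohort: intensities, metadata, annotations and ground truth.

    Latent log2 abundance of protein i in bird j is

        z_ij = mu_i + delta_i * 1[j in high] + eps_ij,  eps ~ N(0, noise_sd^2)

    with mu_i uniform over the baseline span and delta_i the signed true
    effect (+effect_up for affected intracellular, -effect_down for affected
    secreted, 0 otherwise). The reported intensity is 2**z_ij, and the value
    is MISSING iff z_ij < detection_limit.
    """
    rng = np.random.default_rng(design.seed)
    d = design

    proteins = [f"P{i:04d}" for i in range(d.n_proteins)]
    samples = [f"bird{j:02d}" for j in range(d.n_low + d.n_high)]
    group = np.array(["low"] * d.n_low + ["high"] * d.n_high)

    is_secreted = rng.random(d.n_proteins) < d.fraction_secreted
    protein_class = pd.Series(np.where(is_secreted, "secreted", "intracellular"),
                              index=proteins, name="class")
    affected = rng.random(d.n_proteins) < d.fraction_affected
    effect = np.where(affected,
                      np.where(is_secreted, -d.effect_down_secreted,
                               d.effect_up_intracellular),
                      0.0)
    true_effect = pd.Series(effect, index=proteins, name="true_effect")
    organ = pd.Series(rng.choice(_ORGANS, size=d.n_proteins), index=proteins, name="organ")

    mu = d.baseline_mean_low + d.baseline_mean_span * rng.random(d.n_proteins)
    latent = (mu[:, None]
              + effect[:, None] * (group == "high")[None, :]
              + rng.normal(0.0, d.noise_sd, size=(d.n_proteins, len(samples))))
    intensities = np.exp2(latent)
    intensities[latent < d.detection_limit] = np.nan
    matrix = IntensityMatrix(pd.DataFrame(intensities, index=proteins, columns=samples))

    # plastic burden: low birds below both thresholds, high birds heavy-tailed
    low_count = rng.integers(0, 5, size=d.n_low)
    low_mass = np.round(np.minimum(np.abs(rng.normal(0.0, 0.08, size=d.n_low)), 0.45), 4)
    # lognormal spanning ~0.65-40 g, matching an order-of-magnitude burden spread
    high_mass = np.round(np.clip(rng.lognormal(mean=1.0, sigma=1.1, size=d.n_high),
                                 0.65, 45.0), 4)
    high_count = np.maximum(8, np.round(high_mass * rng.uniform(6.0, 12.0, size=d.n_high))
                            ).astype(int)
    metadata = pd.DataFrame({
        "sample_id": samples,
        "group": group,
        "plastic_count": np.concatenate([low_count, high_count]).astype(int),
        "plastic_mass": np.concatenate([low_mass, high_mass]),
        "weight": np.round(rng.normal(650.0, 60.0, size=len(samples)), 1),
        "wing_length": np.round(rng.normal(304.0, 9.5, size=len(samples)), 1),
        "culmen_length": np.round(rng.normal(40.0, 1.5, size=len(samples)), 2),
        "head_bill_length": np.round(rng.normal(94.0, 2.5, size=len(samples)), 2),
        "tissue": "plasma",
    })

    annotations = _simulate_annotations(rng, d, proteins, protein_class, organ, affected)
    truth = CohortTruth(
        protein_class=protein_class,
        true_effect=true_effect,
        organ=organ,
        pathway_enriched={pid: flag for pid, flag in annotations[1].items()},
        plastic_mass=pd.Series(metadata["plastic_mass"].to_numpy(),
                               index=metadata["sample_id"]),
        baseline_mean=pd.Series(mu, index=proteins, name="baseline_mean"),
    )
    return matrix, metadata, annotations[0], truth


def _simulate_annotations(
    rng: np.random.Generator,
    d: CohortDesign,
    proteins: list[str],
    protein_class: pd.Series,
    organ: pd.Series,
    affected: np.ndarray,
) -> tuple[AnnotationSet, dict[str, bool]]:
    """Pathway sets (some enriched in affected proteins), secretion and organ maps."""
    sources = ("GO", "KEGG", "WikiPathways")
    prot_arr = np.array(proteins)
    affected_ids = prot_arr[affected]
    null_ids = prot_arr[~affected]
    pathways: dict[str, set[str]] = {}
    src_map: dict[str, str] = {}
    desc: dict[str, str] = {}
    enriched_flags: dict[str, bool] = {}
    for i in range(d.pathway_count):
        pid = f"PW{i:03d}"
        size = int(rng.integers(d.pathway_size_min, d.pathway_size_max + 1))
        enriched = (rng.random() < d.fraction_pathways_enriched
                    and len(affected_ids) >= size // 2)
        if enriched:
            # half the members from affected proteins: strong compositional signal
            n_aff = min(size // 2, len(affected_ids))
            members = np.concatenate([
                rng.choice(affected_ids, size=n_aff, replace=False),
                rng.choice(null_ids, size=size - n_aff, replace=False),
            ])
        else:
            members = rng.choice(prot_arr, size=size, replace=False)
        pathways[pid] = set(members.tolist())
        src_map[pid] = sources[i % len(sources)]
        desc[pid] = f"{src_map[pid]}:simulated pathway {i}"
        enriched_flags[pid] = bool(enriched)
    annotations = AnnotationSet(
        pathways=pathways,
        sources=src_map,
        descriptions=desc,
        secretion=protein_class.to_dict(),
        organs={p: {organ[p]} for p in proteins},
    )
    return annotations, enriched_flags


def null_design(design: CohortDesign | None = None, **overrides) -> CohortDesign:
    """A copy of a design with all exposure effects set to zero (null cohort)."""
    base = design or CohortDesign()
    return replace(base, effect_up_intracellular=0.0, effect_down_secreted=0.0, **overrides)


# ---------------------------------------------------------------------------
# qPCR fixture generator
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CtDesign:
    """Design of a simulated qPCR experiment.

    ``effects`` maps gene -> true log2 expression change in the high group;
    the housekeeping gene must carry a zero effect. A gene with true log2
    effect e yields expected ddCt = -e, hence fold change 2**e.
    """

    effects: tuple[tuple[str, float], ...] = (("ALB", 0.0), ("SOD1", 1.0), ("GKN2", 0.0))
    housekeeping_gene: str = "HMBS"
    n_low: int = 13
    n_high: int = 18
    n_replicates: int = 3
    replicate_sd: float = 0.2  # cycles, within-triplicate
    sample_sd: float = 0.5  # cycles, between-bird biological variation
    seed: int = 0

    def __post_init__(self) -> None:
        if self.replicate_sd <= 0:
            raise ValueError("replicate_sd must be positive")
        if self.housekeeping_gene in dict(self.effects) and dict(self.effects)[
                self.housekeeping_gene] != 0.0:
            raise ValueError("housekeeping gene must have zero effect")


def simulate_ct(design: CtDesign) -> CtTable:
    """Simulate triplicate Ct values for target genes plus a housekeeping gene.

    Each sample carries a random plate/loading offset shared by all of its
    wells (so only housekeeping-normalised quantities are meaningful); a true
    log2 up-regulation of e lowers the target Ct by e cycles in the high
    group. The same seed returns an identical table.
    """
    rng = np.random.default_rng(design.seed)
    genes = dict(design.effects)
    all_genes = {**genes, design.housekeeping_gene: 0.0}
    base_ct = {g: rng.uniform(18.0, 26.0) for g in sorted(all_genes)}
    rows = []
    samples = ([(f"s{j:02d}", "low") for j in range(design.n_low)]
               + [(f"s{j:02d}", "high") for j in range(design.n_low,
                                                       design.n_low + design.n_high)])
    for sample_id, grp in samples:
        offset = rng.normal(0.0, 0.3)  # per-sample loading offset, cycles
        for gene in sorted(all_genes):
            effect = all_genes[gene] if grp == "high" else 0.0
            bio = rng.normal(0.0, design.sample_sd) if gene != design.housekeeping_gene else 0.0
            mean_ct = base_ct[gene] - effect + bio + offset
            for rep in range(design.n_replicates):
                rows.append({
                    "sample_id": sample_id,
                    "gene": gene,
                    "replicate": rep + 1,
                    "ct": round(mean_ct + rng.normal(0.0, design.replicate_sd), 3),
                    "group": grp,
                    "housekeeping": gene == design.housekeeping_gene,
                })
    return CtTable(pd.DataFrame(rows))
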