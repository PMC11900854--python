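"""End-to-end orchestration: one config, one seed, a run directory of outputs.

Stage order: exposure classification -> detection filter -> presence/absence
and abundance testing -> permutation enrichment -> secretion/organ
composition -> dose-response screen (when a mass covariate is present) ->
ddCt (when a Ct table is supplied) -> plot-ready report tables. A manifest
records the resolved config, seed and per-stage row counts; an identical
config and seed reproduces every table byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from plumage import differential as da
from plumage import enrichment as en
from plumage import io as pio
from plumage import qpcr, viz
from plumage.baseline import DEFAULT_RULE, ExposureRule, classify_exposure, summarize_baseline
from plumage.dose import dose_response_screen


@dataclass
class PipelineConfig:
    """Every tunable of the pipeline as an explicit, logged setting."""

    matrix_path: str = ""
    metadata_path: str = ""
    gmt_path: str = ""
    secretion_path: str = ""
    organ_path: str = ""
    ct_path: str = ""  # optional
    out_dir: str = "run"
    count_threshold: int = 5  # pieces; exposure rule
    mass_threshold: float = 0.5  # g; exposure rule
    detection_threshold: float = 0.70
    alpha: float = 0.05
    b_resamples: int = 10_000
    seed: int = 0
    pca_impute_policy: str = "complete-proteins"
    enrichment_background: str = "low-group"  # or "filtered"
    enrichment_two_sided: bool = False
    housekeeping_gene: str = "HMBS"
    reference_group: str = "low"
    run_dose_response: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.b_resamples < 1:
            raise ValueError("b_resamples must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        return cls(**kwargs, extra=extra)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        self.stage = stage
        super().__init__(f"stage {stage!r} failed: {detail}")


def _require(path: str, stage: str) -> Path:
    p = Path(path)
    if not p.exists():
        raise PipelineError(stage, f"input file not found: {p}")
    return p


def _write(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, lineterminator="\n", float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; returns the manifest (also written to the run dir)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config": {k: v for k, v in asdict(config).items()},
                      "stages": {}}

    # --- load inputs -----------------------------------------------------
    matrix = pio.read_intensity_matrix(_require(config.matrix_path, "load"))
    metadata = pio.read_metadata(_require(config.metadata_path, "load"))
    annotations = pio.read_gmt(_require(config.gmt_path, "load"))
    if config.secretion_path:
        annotations = annotations.merged_with(
            pio.read_secretion_table(_require(config.secretion_path, "load")))
    if config.organ_path:
        annotations = annotations.merged_with(
            pio.read_organ_table(_require(config.organ_path, "load")))
    missing_samples = set(matrix.sample_ids) - set(metadata["sample_id"])
    if missing_samples:
        raise PipelineError("load", f"matrix samples without metadata: {sorted(missing_samples)[:5]}")

    # --- exposure classification ----------------------------------------
    rule = ExposureRule(config.count_threshold, config.mass_threshold)
    if {"plastic_count", "plastic_mass"}.issubset(metadata.columns):
        derived = [
            classify_exposure(int(c), float(m), rule)
            for c, m in zip(metadata["plastic_count"], metadata["plastic_mass"])
        ]
        metadata = metadata.assign(group_from_rule=derived)
        mismatch = (metadata["group"] != metadata["group_from_rule"]).sum()
        manifest["stages"]["classify"] = {"n_birds": len(metadata),
                                          "rule_mismatches": int(mismatch)}
        baseline_table = summarize_baseline(metadata)
        _write(baseline_table, out / "baseline.tsv", index=False)

    groups = pio.group_samples(metadata[metadata["sample_id"].isin(matrix.sample_ids)])
    if not groups["low"] or not groups["high"]:
        raise PipelineError("classify", "both exposure groups must be non-empty")

    # --- differential abundance -----------------------------------------
    try:
        kept, _ = da.detection_filter(matrix, groups, config.detection_threshold)
        diff = da.mann_whitney_differential(matrix, groups, kept_proteins=kept,
                                            detection_threshold=config.detection_threshold)
    except ValueError as exc:
        raise PipelineError("differential", str(exc)) from exc
    _write(diff, out / "differential.tsv")
    sig = da.significant_proteins(diff, config.alpha)
    manifest["stages"]["differential"] = {
        "n_proteins_detected": int(len(diff)),
        "n_proteins_filtered": int(diff["passed_filter"].sum()),
        "n_significant": len(sig),
    }

    # --- PCA -------------------------------------------------------------
    pca = da.scaled_pca(matrix.subset(protein_ids=kept), n_components=2,
                        impute_policy=config.pca_impute_policy)
    _write(pca.scores, out / "pca_scores.tsv")
    manifest["stages"]["pca"] = {
        "explained_variance_ratio": [float(v) for v in pca.explained_variance_ratio],
        "n_proteins_used": pca.n_proteins_used,
    }

    # --- enrichment ------------------------------------------------------
    if config.enrichment_background == "low-group":
        bg_proteins = sorted(matrix.detected_in(groups["low"]))
    elif config.enrichment_background == "filtered":
        bg_proteins = list(kept)
    else:
        raise PipelineError("enrichment",
                            f"unknown background {config.enrichment_background!r}")
    background = en.build_background(bg_proteins, annotations)
    sig_in_bg = [p for p in sig if p in set(bg_proteins)]
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    enr = en.permutation_enrichment(
        sig_in_bg, background, annotations, differential=diff,
        b_resamples=config.b_resamples, seed=rng, two_sided=config.enrichment_two_sided)
    _write(enr, out / "enrichment.tsv", index=False)
    manifest["stages"]["enrichment"] = {
        "n_pathways_tested": int(len(enr)),
        "n_enriched": int((enr["q"] < config.alpha).sum()) if len(enr) else 0,
        "background_size": background.n,
        "m": len(sig_in_bg),
    }

    # --- composition -----------------------------------------------------
    comp = en.composition_summary(diff, annotations, alpha=config.alpha)
    _write(comp["secretion"], out / "composition_secretion.tsv")
    _write(comp["organ"], out / "composition_organ.tsv")
    sec = comp["secretion"]
    manifest["stages"]["composition"] = {
        "intracellular_up": int(sec.get("up", pd.Series(dtype=int)).get("intracellular", 0)),
        "secreted_down": int(sec.get("down", pd.Series(dtype=int)).get("secreted", 0)),
    }

    # --- dose-response (optional tissue arm) -----------------------------
    if config.run_dose_response:
        dose = dose_response_screen(matrix.subset(protein_ids=kept), metadata)
        _write(dose, out / "dose_response.tsv")
        manifest["stages"]["dose_response"] = {
            "n_screened": int(len(dose)),
            "n_significant": int((dose["q"] < config.alpha).sum()),
        }

    # --- qPCR (optional) -------------------------------------------------
    if config.ct_path:
        ct = pio.read_ct_table(_require(config.ct_path, "qpcr"))
        ddct = qpcr.delta_delta_ct(ct, config.housekeeping_gene, config.reference_group)
        _write(ddct, out / "ddct.tsv", index=False)
        expr = qpcr.compare_expression(ddct)
        _write(expr, out / "expression_tests.tsv")
        manifest["stages"]["qpcr"] = {"n_genes": int(len(expr))}

    # --- report tables ---------------------------------------------------
    volcano = viz.volcano_data(diff, alpha=config.alpha)
    _write(volcano, out / "volcano.tsv", index=False)
    if sig:
        z, _flagged = da.zscore_rows(np.log2(matrix.values.loc[sig]))
        zs, tracks = viz.heatmap_data(z, metadata)
        _write(zs, out / "heatmap_z.tsv")
        _write(tracks, out / "heatmap_tracks.tsv", index=False)

    manifest["seed"] = config.seed
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest
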