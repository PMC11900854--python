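"""Background-constrained permutation enrichment against exact hypergeometric oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from plumage import enrichment as en
from plumage.io import AnnotationSet


def make_annotations(pathways, sources=None):
    return AnnotationSet(
        pathways={k: set(v) for k, v in pathways.items()},
        sources=sources or {k: "GO" for k in pathways},
    )


class TestBuildBackground:
    def test_full_overlap(self):
        ann = make_annotations({"PW": [f"P{i}" for i in range(5)]})
        bg = en.build_background([f"P{i}" for i in range(5)], ann)
        assert bg.pathway_counts["PW"] == 5
        assert bg.n == 5

    def test_disjoint_pathway_zero(self):
        ann = make_annotations({"PW": ["X", "Y"]})
        bg = en.build_background(["A", "B", "C"], ann)
        assert bg.pathway_counts["PW"] == 0

    def test_unannotated_proteins_count_toward_n(self):
        ann = make_annotations({"PW": ["A"]})
        bg = en.build_background(["A", "B", "C"], ann)
        assert bg.n == 3 and bg.pathway_counts["PW"] == 1

    def test_counts_equal_brute_force_intersections(self):
        rng = np.random.default_rng(8)
        universe = [f"P{i}" for i in range(200)]
        ann = make_annotations({
            f"PW{k}": rng.choice(universe, size=rng.integers(3, 40), replace=False)
            for k in range(15)
        })
        background = list(rng.choice(universe, size=120, replace=False))
        bg = en.build_background(background, ann)
        for pid, members in ann.pathways.items():
            assert bg.pathway_counts[pid] == len(members & set(background))

    def test_empty_background_rejected(self):
        with pytest.raises(ValueError):
            en.build_background([], make_annotations({"PW": ["A"]}))


class TestPermutationEnrichment:
    def test_sig_equals_background_degenerate_identity(self):
        proteins = [f"P{i}" for i in range(12)]
        ann = make_annotations({"PW1": proteins[:4], "PW2": proteins[4:9]})
        bg = en.build_background(proteins, ann)
        res = en.permutation_enrichment(proteins, bg, ann, b_resamples=200, seed=0)
        res = res.set_index("pathway_id")
        assert (res["k_sig"] == res["K_bg"]).all()
        assert (res["p_perm"] == 1.0).all()

    def test_toy_instance_matches_hypergeometric_tail(self):
        """N=10, K=4, m=5: drawing the 4 pathway members plus one other has
        exact upper-tail probability C(4,4)C(6,1)/C(10,5) = 6/252."""
        proteins = [f"P{i}" for i in range(10)]
        ann = make_annotations({"PW": proteins[:4]})
        bg = en.build_background(proteins, ann)
        sig = proteins[:4] + [proteins[9]]  # k_sig = 4 of m = 5
        b = 10_000
        res = en.permutation_enrichment(sig, bg, ann, b_resamples=b, seed=3)
        exact = stats.hypergeom.sf(3, 10, 4, 5)  # P(X >= 4) = 6/252
        assert exact == pytest.approx(6 / 252, abs=1e-12)
        se = np.sqrt(exact * (1 - exact) / b)
        assert abs(res["p_perm"].iloc[0] - exact) < 3 * se + 2 / (b + 1)

    def test_agreement_improves_with_b(self):
        """Monte-Carlo error against the exact tail shrinks as B grows."""
        rng = np.random.default_rng(17)
        errors = {b: [] for b in (1_000, 10_000, 100_000)}
        for trial in range(5):
            n = int(rng.integers(12, 31))
            k = int(rng.integers(2, n // 2))
            m = int(rng.integers(3, n - 1))
            proteins = [f"P{i}" for i in range(n)]
            ann = make_annotations({"PW": proteins[:k]})
            bg = en.build_background(proteins, ann)
            sig = list(rng.choice(proteins, size=m, replace=False))
            k_sig = len(set(sig) & set(proteins[:k]))
            exact = stats.hypergeom.sf(k_sig - 1, n, k, m)
            for b in errors:
                res = en.permutation_enrichment(sig, bg, ann, b_resamples=b,
                                                seed=int(rng.integers(2**31)))
                errors[b].append(abs(res["p_perm"].iloc[0] - exact))
        mean_err = [np.mean(errors[b]) for b in sorted(errors)]
        assert mean_err[2] < mean_err[0]

    def test_fixed_seed_bit_identical(self):
        proteins = [f"P{i}" for i in range(20)]
        ann = make_annotations({"PW1": proteins[:6], "PW2": proteins[5:14]})
        bg = en.build_background(proteins, ann)
        r1 = en.permutation_enrichment(proteins[:7], bg, ann, b_resamples=100, seed=42)
        r2 = en.permutation_enrichment(proteins[:7], bg, ann, b_resamples=100, seed=42)
        pd.testing.assert_frame_equal(r1, r2)

    def test_add_one_bound_p_never_zero(self):
        proteins = [f"P{i}" for i in range(15)]
        ann = make_annotations({"PW": proteins[:5]})
        bg = en.build_background(proteins, ann)
        res = en.permutation_enrichment(proteins[:5], bg, ann, b_resamples=50, seed=1)
        assert (res["p_perm"] >= 1 / 51).all()

    def test_sig_outside_background_rejected(self):
        ann = make_annotations({"PW": ["A", "B"]})
        bg = en.build_background(["A", "B", "C"], ann)
        with pytest.raises(ValueError, match="outside"):
            en.permutation_enrichment(["A", "Z"], bg, ann, b_resamples=10, seed=0)

    def test_zero_background_pathway_excluded(self):
        ann = make_annotations({"PW_in": ["A", "B"], "PW_out": ["X", "Y"]})
        bg = en.build_background(["A", "B", "C"], ann)
        res = en.permutation_enrichment(["A"], bg, ann, b_resamples=50, seed=0)
        assert set(res["pathway_id"]) == {"PW_in"}

    def test_bh_within_source_families(self):
        rng = np.random.default_rng(9)
        proteins = [f"P{i}" for i in range(60)]
        pathways = {f"PW{k}": rng.choice(proteins, size=10, replace=False)
                    for k in range(6)}
        sources = {f"PW{k}": ("GO" if k < 3 else "KEGG") for k in range(6)}
        ann = make_annotations(pathways, sources)
        bg = en.build_background(proteins, ann)
        res = en.permutation_enrichment(proteins[:15], bg, ann, b_resamples=500, seed=2)
        from plumage.differential import benjamini_hochberg

        for src in ("GO", "KEGG"):
            sub = res[res["source"] == src]
            assert sub["q"].to_numpy() == pytest.approx(
                benjamini_hochberg(sub["p_perm"].to_numpy()), abs=1e-12)

    def test_truly_enriched_pathways_rank_higher(self, signal_cohort,
                                                 signal_differential):
        from plumage import differential as da
        from plumage import io as pio

        matrix, meta, ann, truth = signal_cohort
        groups = pio.group_samples(meta)
        sig = da.significant_proteins(signal_differential)
        bg = en.build_background(sorted(matrix.detected_in(groups["low"])), ann)
        sig_bg = [p for p in sig if p in set(bg.background)]
        res = en.permutation_enrichment(sig_bg, bg, ann,
                                        differential=signal_differential,
                                        b_resamples=2000, seed=6).set_index("pathway_id")
        enriched = [p for p, flag in truth.pathway_enriched.items() if flag]
        null = [p for p, flag in truth.pathway_enriched.items() if not flag]
        assert res.loc[enriched, "p_perm"].mean() < res.loc[null, "p_perm"].mean()


class TestComposition:
    def _diff_table(self, rows):
        return pd.DataFrame(rows).set_index("protein_id")

    def test_all_secreted_down_single_cell(self):
        diff = self._diff_table([
            {"protein_id": "A", "abundance_q": 0.01, "log2_fold_change": -2.0},
            {"protein_id": "B", "abundance_q": 0.02, "log2_fold_change": -1.0},
        ])
        ann = AnnotationSet(secretion={"A": "secreted", "B": "secreted"})
        comp = en.composition_summary(diff, ann)
        sec = comp["secretion"]
        assert sec.to_numpy().sum() == 2
        assert sec.loc["secreted", "down"] == 2

    def test_empty_significant_set_empty_tables(self):
        diff = self._diff_table([
            {"protein_id": "A", "abundance_q": 0.9, "log2_fold_change": 1.0}])
        comp = en.composition_summary(diff, AnnotationSet())
        assert comp["secretion"].to_numpy().sum() == 0

    def test_unannotated_fall_under_unknown(self):
        diff = self._diff_table([
            {"protein_id": "A", "abundance_q": 0.01, "log2_fold_change": 1.0}])
        comp = en.composition_summary(diff, AnnotationSet())
        assert comp["secretion"].loc["unknown", "up"] == 1

    def test_synthetic_truth_signature(self, signal_cohort, signal_differential):
        """Intracellular proteins dominate the up direction and secreted the
        down direction, matching the simulated lysis/organ-failure pattern."""
        _, _, ann, _ = signal_cohort
        comp = en.composition_summary(signal_differential, ann)
        sec = comp["secretion"]
        assert sec.loc["intracellular", "up"] > sec.loc["intracellular", "down"]
        assert sec.loc["secreted", "down"] > sec.loc["secreted", "up"]
        n_sig = int((signal_differential["abundance_q"] < 0.05).sum())
        assert sec.to_numpy().sum() == n_sig
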