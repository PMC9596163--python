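"""The screen: common regions, gene assignment, gating, end-to-end filters."""

from __future__ import annotations

import dataclasses

import pandas as pd
import pytest

from regscreen.chromatin_state import annotate_landscape
from regscreen.io_formats import ExpressionTable, GeneModel, GeneTable
from regscreen.intervals import IntervalSet
from regscreen.synthetic import SyntheticConfig, generate, score_recovery
from regscreen.target_screen import (
    ConfigError,
    ScreenConfig,
    assign_regions_to_genes,
    common_regions,
    screen,
)

from conftest import ivs, spans


def config(**kwargs) -> ScreenConfig:
    return ScreenConfig(factors=kwargs.pop("factors", ["f1", "f2"]), **kwargs)


class TestCommonRegions:
    def test_identical_sets_give_normalized_set(self):
        peaks = {"f1": ivs((0, 10), (5, 20)), "f2": ivs((0, 10), (5, 20))}
        assert spans(common_regions(peaks, config())) == [(0, 20)]

    def test_three_set_footprint(self):
        peaks = {
            "f1": ivs((0, 10), (20, 30)),
            "f2": ivs((5, 25)),
            "f3": ivs((8, 40)),
        }
        cfg = config(factors=["f1", "f2", "f3"])
        assert spans(common_regions(peaks, cfg)) == [(8, 10), (20, 25)]

    def test_anchor_mode_keeps_whole_peaks(self):
        peaks = {
            "f1": ivs((0, 100)),
            "f2": ivs((50, 60)),
            "f3": ivs((90, 95)),
        }
        cfg = config(factors=["f1", "f2", "f3"], common_mode="anchor:f1")
        assert spans(common_regions(peaks, cfg)) == [(0, 100)]
        # footprint mode on the same input is much narrower
        assert spans(common_regions(peaks, config(factors=["f1", "f2", "f3"]))) == []

    def test_missing_factor_is_config_error(self):
        with pytest.raises(ConfigError, match="f9"):
            common_regions({"f1": ivs((0, 10)), "f2": ivs((0, 10))},
                           config(factors=["f1", "f9"]))

    def test_fewer_than_two_factors_rejected(self):
        with pytest.raises(ConfigError, match=">= 2"):
            common_regions({"f1": ivs((0, 10))}, config(factors=["f1"]))


def small_world():
    """One gene with an active promoter, plus marks for an enhancer 50 kb out."""
    genes = GeneTable([GeneModel("g1", "chr1", "+", 5000, "protein_coding")])
    marks = {
        "H3K4me3": ivs((4200, 4900)),
        "H3K27ac": ivs((4200, 4900), (55000, 55400)),
    }
    elements = annotate_landscape(marks, genes)
    return genes, marks, elements


class TestAssignRegionsToGenes:
    def test_in_promoter_association(self):
        genes, _, elements = small_world()
        assocs = assign_regions_to_genes(
            ivs((4500, 4600)), elements, genes, {"g1": "high"}, config()
        )
        (a,) = assocs
        assert (a.gene_id, a.link_kind, a.distance_bp) == ("g1", "in_promoter", 0)
        assert a.element_state == "active"
        assert a.gate_passed

    def test_within_window_distance_arithmetic(self):
        # promoter window [4000, 5010), midpoint 4505
        genes, _, elements = small_world()
        assocs = assign_regions_to_genes(
            ivs((104000, 104200)), elements, genes, {"g1": "high"}, config()
        )
        (a,) = assocs
        assert a.link_kind == "within_window"
        assert a.distance_bp == 104000 - 4505 == 99495

    def test_region_just_beyond_window_not_associated(self):
        genes, _, elements = small_world()
        assocs = assign_regions_to_genes(
            ivs((105510, 105700)), elements, genes, {"g1": "high"}, config()
        )
        assert assocs == []  # distance 101005 > 100000

    def test_distal_region_takes_enhancer_state(self):
        genes, _, elements = small_world()
        assocs = assign_regions_to_genes(
            ivs((55100, 55200)), elements, genes, {"g1": "high"}, config()
        )
        (a,) = assocs
        assert a.link_kind == "within_window"
        assert a.element_state == "active"  # the H3K27ac enhancer run
        assert a.gate_passed

    def test_gate_blocks_wrong_expression_class(self):
        genes, _, elements = small_world()
        (a,) = assign_regions_to_genes(
            ivs((4500, 4600)), elements, genes, {"g1": "not"}, config()
        )
        assert a.element_state == "active" and a.expression_class == "not"
        assert not a.gate_passed

    def test_missing_expression_class_flagged_not_dropped(self):
        genes, _, elements = small_world()
        (a,) = assign_regions_to_genes(
            ivs((4500, 4600)), elements, genes, {}, config()
        )
        assert a.expression_class == "unknown"
        assert not a.gate_passed

    def test_region_in_two_gene_windows_links_to_both(self):
        genes = GeneTable(
            [GeneModel("g1", "chr1", "+", 5000, "protein_coding"),
             GeneModel("g2", "chr1", "-", 60000, "protein_coding")]
        )
        elements = annotate_landscape({}, genes)
        assocs = assign_regions_to_genes(
            ivs((30000, 30100)), elements, genes,
            {"g1": "high", "g2": "high"}, config(required_state="any"),
        )
        assert sorted(a.gene_id for a in assocs) == ["g1", "g2"]


def run_default(dataset, **overrides):
    cfg = ScreenConfig(
        factors=dataset.config.factor_labels,
        gating_celltype=dataset.config.cell_types[0],
        target_celltype=dataset.config.cell_types[0],
        **overrides,
    )
    return screen(
        dataset.peaks_by_factor,
        dataset.mark_peaks,
        dataset.genes,
        dataset.expression,
        cfg,
        replicate2=dataset.factor1_rep2,
    )


class TestScreenEndToEnd:
    def test_planted_targets_recovered_exactly(self, default_dataset):
        result = run_default(default_dataset)
        scores = score_recovery(set(result.candidate_ids()), default_dataset.truth)
        assert scores == {"precision": 1.0, "recall": 1.0, "f1": 1.0}

    def test_summary_consistency(self, default_dataset):
        s = run_default(default_dataset).summary
        assert s["n_active_promoter_regions"] <= s["n_common_regions"]
        assert s["pct_active_promoter"] == pytest.approx(
            100.0 * s["n_active_promoter_regions"] / s["n_common_regions"], abs=1e-3
        )
        assert s["n_candidate_genes"] >= 0

    def test_candidate_table_shape_and_ranks(self, default_dataset):
        result = run_default(default_dataset)
        df = result.candidates
        assert list(df.columns) == ["n_supporting_regions", "link_kinds",
                                    "specificity_score", "rank"]
        assert sorted(df["rank"]) == list(range(1, len(df) + 1))
        assert (df["n_supporting_regions"] >= 1).all()
        # planted targets are iOL-specific by construction: scores positive
        assert (df["specificity_score"] > 0).all()

    def test_relaxing_filters_is_monotone(self, default_dataset):
        base = set(run_default(default_dataset).candidate_ids())
        wider = set(run_default(default_dataset, gene_window_bp=200_000).candidate_ids())
        any_state = set(run_default(default_dataset, required_state="any",
                                    expression_gate={
                                        "active": ("not", "low", "medium", "high"),
                                        "poised": ("not", "low", "medium", "high"),
                                        "repressed": ("not", "low", "medium", "high"),
                                        "unclassified": ("not", "low", "medium", "high"),
                                    }).candidate_ids())
        assert base <= wider
        assert base <= any_state

    def test_empty_factor_set_gives_empty_valid_table(self, default_dataset):
        ds = default_dataset
        peaks = dict(ds.peaks_by_factor)
        peaks[ds.config.factor_labels[1]] = IntervalSet()
        cfg = ScreenConfig(factors=ds.config.factor_labels,
                           gating_celltype=ds.config.cell_types[0])
        result = screen(peaks, ds.mark_peaks, ds.genes, ds.expression, cfg)
        assert result.summary["n_common_regions"] == 0
        assert result.summary["n_candidate_genes"] == 0
        assert len(result.candidates) == 0

    def test_biotype_filter(self, default_dataset):
        ds = default_dataset
        # relabel half the planted targets as lncRNA: they must drop out
        planted = ds.truth.planted_targets
        drop = set(planted[:10])
        genes = GeneTable(
            [dataclasses.replace(g, biotype="lncRNA") if g.gene_id in drop else g
             for g in ds.genes]
        )
        cfg = ScreenConfig(factors=ds.config.factor_labels,
                           gating_celltype=ds.config.cell_types[0])
        result = screen(ds.peaks_by_factor, ds.mark_peaks, genes, ds.expression,
                        cfg, replicate2=ds.factor1_rep2)
        assert set(result.candidate_ids()) == set(planted) - drop

    def test_anchor_mode_recovers_targets_too(self, default_dataset):
        anchor = f"anchor:{default_dataset.config.factor_labels[0]}"
        result = run_default(default_dataset, common_mode=anchor)
        scores = score_recovery(set(result.candidate_ids()), default_dataset.truth)
        assert scores["recall"] == 1.0


class TestScreenConfigValidation:
    def test_negative_window_rejected(self):
        with pytest.raises(ConfigError):
            ScreenConfig(factors=["a", "b"], gene_window_bp=-1)

    def test_unknown_required_state_rejected(self):
        with pytest.raises(ConfigError):
            ScreenConfig(factors=["a", "b"], required_state="closed")

    def test_unknown_common_mode_rejected(self):
        with pytest.raises(ConfigError):
            ScreenConfig(factors=["a", "b"], common_mode="union")

    def test_unknown_gating_celltype_rejected(self, default_dataset):
        ds = default_dataset
        cfg = ScreenConfig(factors=ds.config.factor_labels, gating_celltype="HeLa")
        with pytest.raises(ConfigError, match="HeLa"):
            screen(ds.peaks_by_factor, ds.mark_peaks, ds.genes, ds.expression, cfg)
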