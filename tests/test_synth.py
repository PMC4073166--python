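"""The synthetic-data generators: determinism, planted truth, validity."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from ipsmut.filtering import apply_stringent_filter
from ipsmut.io import overlaps
from ipsmut.somatic import somatic_pipeline
from ipsmut.synth import (
    CohortConfig,
    RegionConfig,
    generate_cohort,
    generate_qfish,
    generate_structural_regions,
    scenario_paper,
)


class TestCohort:
    def test_same_seed_is_identical(self):
        config = CohortConfig(n_sites=40, somatic_per_line=10, seed=77)
        rec_a, truth_a = generate_cohort(config)
        rec_b, truth_b = generate_cohort(
            CohortConfig(n_sites=40, somatic_per_line=10, seed=77)
        )
        assert rec_a == rec_b
        pd.testing.assert_frame_equal(truth_a, truth_b)

    def test_different_seed_differs(self):
        rec_a, _ = generate_cohort(CohortConfig(n_sites=40, seed=1))
        rec_b, _ = generate_cohort(CohortConfig(n_sites=40, seed=2))
        assert rec_a != rec_b

    def test_no_failure_modes_keeps_all_planted_sites(self):
        config = CohortConfig(
            n_sites=30, somatic_per_line=20, seed=5,
            quality_fail_fracs=None, ad_noise=0.0,
        )
        records, truth = generate_cohort(config)
        for line in config.resolved_lines():
            kept, _ = apply_stringent_filter(records, line)
            kept_pos = {(r.chrom, r.pos) for r in kept}
            planted = {
                (row.chrom, row.pos)
                for row in truth[truth["sample"] == line].itertuples(index=False)
            }
            assert planted <= kept_pos

    def test_quality_fail_fracs_reduce_pass_rate(self):
        config = CohortConfig(
            n_sites=200, somatic_per_line=0, seed=3,
            quality_fail_fracs={"QUAL": 0.5},
        )
        records, _ = generate_cohort(config)
        kept, table = apply_stringent_filter(records, "AT1OS")
        n_fail = (~table["kept"]).sum()
        # binomial(200, 0.5) within 3 SD
        assert abs(n_fail - 100) <= 3 * np.sqrt(200 * 0.25)
        assert (
            table.loc[~table["kept"], "reasons"]
            .str.contains("QUAL_LT_400").all()
        )

    def test_invalid_probability_blocks_rejected(self):
        with pytest.raises(ValueError):
            generate_cohort(
                CohortConfig(spectrum_probs={"C>T": 0.5, "C>G": 0.6})
            )
        with pytest.raises(ValueError):
            generate_cohort(
                CohortConfig(category_probs={"not_a_category": 1.0})
            )

    def test_truth_table_scores_every_stage(self):
        config = CohortConfig(n_sites=10, somatic_per_line=5, seed=2)
        _, truth = generate_cohort(config)
        assert set(truth.columns) == {
            "chrom", "pos", "sample", "ref", "alt", "change12", "category",
            "region_label", "ambiguous", "quality_ok",
        }
        assert len(truth) == 20
        assert (truth["ref"] != truth["alt"]).all()


class TestStructuralRegions:
    def test_planted_positions_overlap_their_region(self):
        intervals, planted = generate_structural_regions(
            RegionConfig(
                regions=[(23314.0, "CNLOH", 2), (3586.0, "deletion", 37),
                         (234.0, "deletion", 1)],
                seed=4,
            )
        )
        assert [iv.event for iv in intervals] == ["CNLOH", "deletion", "deletion"]
        assert [iv.length_kb for iv in intervals] == [23314.0, 3586.0, 234.0]
        assert len(planted) == 40
        from conftest import make_record

        for chrom, pos in planted:
            rec = make_record(chrom=chrom, pos=pos)
            assert any(overlaps(rec, iv) for iv in intervals)

    def test_regions_do_not_overlap(self):
        intervals, _ = generate_structural_regions(
            RegionConfig(regions=[(100.0, "deletion", 0)] * 20, seed=1)
        )
        ordered = sorted(intervals, key=lambda iv: iv.start)
        for a, b in zip(ordered, ordered[1:]):
            assert a.end <= b.start

    def test_zero_regions_empty(self):
        intervals, planted = generate_structural_regions(
            RegionConfig(regions=[], seed=0)
        )
        assert intervals == [] and planted == []

    def test_oversized_layout_rejected(self):
        with pytest.raises(ValueError, match="exceed"):
            generate_structural_regions(
                RegionConfig(
                    regions=[(60_000.0, "deletion", 0)],
                    chrom_length=50_000_000,
                    seed=0,
                )
            )


class TestQfishGenerator:
    def test_unit_ratio_matches_control(self):
        frame = generate_qfish(sample_ratio=1.0, n_spreads=5, dispersion=0.0)
        medians = frame.groupby("sample")["intensity"].median()
        assert medians["sample"] == pytest.approx(medians["control"])

    def test_dispersion_zero_is_exact(self):
        frame = generate_qfish(
            sample_ratio=2.0, n_spreads=3, dispersion=0.0,
            control_median=5000.0,
        )
        sample_values = frame.loc[frame["sample"] == "sample", "intensity"]
        assert (sample_values == 10_000.0).all()

    def test_invalid_ratio_rejected(self):
        with pytest.raises(ValueError):
            generate_qfish(sample_ratio=0.0, n_spreads=3)


class TestPaperScenario:
    def test_full_pipeline_accounting(self, paper_scenario):
        b = paper_scenario
        per_line, acct = somatic_pipeline(
            b.records, b.parental, b.lines, b.regions, b.exclusion
        )
        assert acct.called == 212
        assert sorted(acct.removed_by_region.values()) == [1, 2, 37]
        assert acct.removed_manual == 5
        assert acct.final == 167
        assert [len(per_line[line]) for line in b.lines] == [43, 48, 35, 41]

    def test_rerun_same_seed_identical(self, paper_scenario):
        again = scenario_paper(seed=paper_scenario.seed)
        assert again.records == paper_scenario.records
        assert again.exclusion == paper_scenario.exclusion
        pd.testing.assert_frame_equal(again.truth, paper_scenario.truth)

    def test_bundle_region_structure(self, paper_scenario):
        b = paper_scenario
        by_event = sorted((iv.event, iv.length_kb) for iv in b.regions)
        assert by_event == [
            ("CNLOH", 23314.0), ("deletion", 234.0), ("deletion", 3586.0),
        ]
        assert len(b.exclusion) == 5
        assert set(b.passages.values()) == {17, 27, 25}
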