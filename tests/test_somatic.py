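"""Somatic extraction, structural/manual exclusions and the accounting."""

from __future__ import annotations

import random

import pytest

from ipsmut.io import GenomicInterval, SampleCall
from ipsmut.somatic import (
    accounting,
    apply_exclusion_list,
    call_somatic,
    exclude_structural,
    somatic_pipeline,
)
from ipsmut.synth import CohortConfig, generate_cohort
from conftest import make_record
from oracles import oracle_overlaps


def pair(parental_gt, derived_gt, pos=100, parental_ad=None, derived_ad=None):
    def ad_for(gt):
        if gt == (0, 0):
            return (50, 0)
        if gt == (1, 1):
            return (0, 50)
        return (25, 25)

    calls = {
        "P": SampleCall(genotype=parental_gt,
                        allelic_depths=parental_ad or ad_for(parental_gt),
                        gq=99),
        "D": SampleCall(genotype=derived_gt,
                        allelic_depths=derived_ad or ad_for(derived_gt),
                        gq=99),
    }
    return make_record(pos=pos, calls=calls)


class TestCallSomatic:
    def test_canonical_de_novo(self):
        assert call_somatic([pair((0, 0), (0, 1))], "P", "D")

    def test_inherited_het_is_not_somatic(self):
        assert call_somatic([pair((0, 1), (0, 1))], "P", "D") == []

    def test_parental_het_to_derived_hom_is_not_somatic(self):
        # LOH-style genotype change: handled by the structural channel
        assert call_somatic([pair((0, 1), (1, 1))], "P", "D") == []

    def test_requires_filter_pass_in_both_samples(self):
        rec = pair((0, 0), (0, 1), parental_ad=(50, 3))  # parental hom fails
        assert call_somatic([rec], "P", "D") == []
        assert call_somatic([rec], "P", "D", require_parental_pass=False)

    def test_missing_sample_raises(self):
        with pytest.raises(KeyError):
            call_somatic([pair((0, 0), (0, 1))], "P", "nope")

    def test_output_sorted_by_karyotype_order(self):
        records = [
            pair((0, 0), (0, 1), pos=5),
            pair((0, 0), (0, 1), pos=2),
        ]
        records[0].chrom = "chr10"
        records[1].chrom = "chr2"
        out = call_somatic(records, "P", "D")
        assert [(r.chrom, r.pos) for r in out] == [("chr2", 2), ("chr10", 5)]

    def test_planted_truth_recovered_exactly(self):
        config = CohortConfig(
            n_sites=60, somatic_per_line=25, depth_mean=100.0, seed=9
        )
        records, truth = generate_cohort(config)
        for line in ("ATiPS-262", "ATiPS-263", "ATiPS-264", "ATiPS-024"):
            called = call_somatic(records, "AT1OS", line)
            expected = truth[truth["sample"] == line]
            assert {(r.chrom, r.pos) for r in called} == {
                (row.chrom, row.pos)
                for row in expected.itertuples(index=False)
            }
            assert len(called) == 25


class TestExcludeStructural:
    def test_empty_region_list_is_identity(self):
        snvs = [pair((0, 0), (0, 1), pos=p) for p in (1, 2, 3)]
        kept, removed = exclude_structural(snvs, [])
        assert kept == snvs and removed == {}

    def test_partition_is_conserved_and_matches_oracle(self):
        rng = random.Random(3)
        regions = [
            GenomicInterval(f"chr{rng.randint(1, 2)}", s, s + rng.randint(1, 400),
                            label=f"r{k}")
            for k, s in enumerate(rng.randrange(0, 3000) for _ in range(15))
        ]
        snvs = []
        for k in range(300):
            rec = pair((0, 0), (0, 1), pos=rng.randint(1, 3500))
            rec.chrom = f"chr{rng.randint(1, 2)}"
            snvs.append(rec)
        kept, removed = exclude_structural(snvs, regions)
        flat_removed = [s for group in removed.values() for s in group]
        assert len(kept) + len(flat_removed) == len(snvs)
        assert {id(s) for s in kept} | {id(s) for s in flat_removed} == {
            id(s) for s in snvs
        }
        for snv in snvs:
            hit = any(oracle_overlaps(snv, iv) for iv in regions)
            assert (snv in flat_removed) == hit

    def test_grouped_by_region_label(self):
        regions = [
            GenomicInterval("chr1", 0, 100, "CNLOH", "cnloh"),
            GenomicInterval("chr1", 200, 300, "deletion", "del1"),
        ]
        snvs = [pair((0, 0), (0, 1), pos=p) for p in (50, 60, 250, 500)]
        kept, removed = exclude_structural(snvs, regions)
        assert len(kept) == 1
        assert {k: len(v) for k, v in removed.items()} == {"cnloh": 2, "del1": 1}


class TestExclusionList:
    def test_all_entries_match(self):
        snvs = [pair((0, 0), (0, 1), pos=p) for p in range(1, 11)]
        entries = [("chr1", p, "D") for p in (2, 4, 6)]
        kept, removed = apply_exclusion_list(snvs, entries, sample="D")
        assert removed == 3 and len(kept) == 7

    def test_empty_list_is_identity(self):
        snvs = [pair((0, 0), (0, 1))]
        kept, removed = apply_exclusion_list(snvs, [], sample="D")
        assert kept == snvs and removed == 0

    def test_duplicates_removed_once_with_warning(self):
        snvs = [pair((0, 0), (0, 1), pos=5)]
        entries = [("chr1", 5, "D"), ("chr1", 5, "D")]
        with pytest.warns(UserWarning, match="duplicate"):
            kept, removed = apply_exclusion_list(snvs, entries, sample="D")
        assert removed == 1 and kept == []

    def test_unmatched_entry_warns_not_errors(self):
        snvs = [pair((0, 0), (0, 1), pos=5)]
        with pytest.warns(UserWarning, match="matched no SNV"):
            kept, removed = apply_exclusion_list(
                snvs, [("chr9", 999, "D")], sample="D"
            )
        assert removed == 0 and kept == snvs

    def test_other_samples_entries_ignored(self):
        snvs = [pair((0, 0), (0, 1), pos=5)]
        kept, removed = apply_exclusion_list(
            snvs, [("chr1", 5, "OTHER")], sample="D"
        )
        assert removed == 0 and kept == snvs


class TestAccounting:
    def test_study_scale_arithmetic(self):
        acct = accounting(212, {"CNLOH": 2, "del1": 37, "del2": 1}, 5)
        assert acct.final == 167

    def test_zero_case(self):
        assert accounting(0, {}, 0).final == 0

    def test_negative_final_rejected(self):
        with pytest.raises(ValueError):
            accounting(10, {"r": 11}, 0)


def test_pipeline_conserves_counts_at_every_stage(paper_scenario):
    b = paper_scenario
    per_line, acct = somatic_pipeline(
        b.records, b.parental, b.lines, b.regions, b.exclusion
    )
    n_final = sum(len(v) for v in per_line.values())
    assert (
        acct.called
        == n_final + sum(acct.removed_by_region.values()) + acct.removed_manual
    )
    assert acct.final == n_final
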