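import numpy as np
import pandas as pd
import pytest

from clonoscope.clonotypes import (QCConfig, assemble_clonotypes,
                                   clonotype_frequencies, filter_contigs)
from conftest import contig_frame


class TestFilterContigs:
    def test_keeps_best_umi_contig_per_locus(self):
        df = contig_frame([
            dict(umis=5, raw_contig_id="c1", cdr3_nt="TGTGCA"),
            dict(umis=2, raw_contig_id="c2", cdr3_nt="TGTGGG"),
        ])
        kept, report = filter_contigs(df)
        assert list(kept["raw_contig_id"]) == ["c1"]
        assert report["multi_chain_dropped"] == 1

    def test_umi_tie_broken_by_reads_then_id(self):
        df = contig_frame([
            dict(umis=5, reads=80, raw_contig_id="c2"),
            dict(umis=5, reads=90, raw_contig_id="c3"),
            dict(umis=5, reads=90, raw_contig_id="c1"),
        ])
        kept, _ = filter_contigs(df)
        assert list(kept["raw_contig_id"]) == ["c1"]

    def test_cross_lineage_barcode_dropped_entirely(self):
        df = contig_frame([
            dict(locus="TRB"),
            dict(locus="IGH", raw_contig_id="c9", cdr3_nt="TGTAAA"),
        ])
        kept, report = filter_contigs(df)
        assert kept.empty
        assert report["cross_lineage_dropped"] == 1

    def test_flag_filters_counted_per_rule(self):
        df = contig_frame([
            dict(productive=False, barcode="S1_b1-1"),
            dict(high_confidence=False, barcode="S1_b2-1"),
            dict(is_cell=False, barcode="S1_b3-1"),
            dict(cdr3_nt=None, barcode="S1_b4-1"),
            dict(barcode="S1_b5-1"),
        ])
        kept, report = filter_contigs(df)
        assert list(kept["barcode"]) == ["S1_b5-1"]
        assert report["not_productive"] == 1
        assert report["not_high_confidence"] == 1
        assert report["not_is_cell"] == 1
        assert report["missing_cdr3_nt"] == 1

    def test_idempotent(self, noisy_sim):
        contigs, _, _ = noisy_sim
        once, _ = filter_contigs(contigs)
        twice, report = filter_contigs(once)
        pd.testing.assert_frame_equal(once, twice)
        assert report["multi_chain_dropped"] == 0

    def test_kept_barcodes_match_generator_truth(self, noisy_sim):
        contigs, _, truth = noisy_sim
        kept, _ = filter_contigs(contigs)
        assert set(kept["barcode"]) == truth.expected_kept_barcodes


class TestAssembleClonotypes:
    def test_identical_cells_collapse(self):
        df = contig_frame([
            dict(barcode="S1_b1-1", locus="TRA", cdr3_nt="TGTGCAGCA", raw_contig_id="a1"),
            dict(barcode="S1_b1-1", locus="TRB", cdr3_nt="TGCAGTAGT", raw_contig_id="a2"),
            dict(barcode="S1_b2-1", locus="TRA", cdr3_nt="TGTGCAGCA", raw_contig_id="b1"),
            dict(barcode="S1_b2-1", locus="TRB", cdr3_nt="TGCAGTAGT", raw_contig_id="b2"),
        ])
        from clonoscope.io import SampleMeta
        table = assemble_clonotypes(df, [SampleMeta("S1", "AD")])["TCR"]
        assert len(table.counts) == 1
        assert table.counts.iloc[0, 0] == 2

    def test_synonymous_nt_merge_at_aa_level(self):
        # two TRB junctions differ only by a synonymous codon (TGT vs TGC)
        from clonoscope.io import SampleMeta
        rows = []
        for bc, nt in (("S1_b1-1", "TGTGCAAGC"), ("S1_b2-1", "TGCGCAAGC")):
            rows.append(dict(barcode=bc, locus="TRB", cdr3_nt=nt,
                             cdr3_aa="CAS", raw_contig_id=bc))
        df = contig_frame(rows)
        meta = [SampleMeta("S1", "AD")]
        assert len(assemble_clonotypes(df, meta, "nt")["TCR"].counts) == 2
        assert len(assemble_clonotypes(df, meta, "aa")["TCR"].counts) == 1

    def test_mixed_receptor_barcode_raises(self):
        df = contig_frame([
            dict(locus="TRB"),
            dict(locus="IGH", raw_contig_id="c9", cdr3_nt="TGTAAA"),
        ])
        from clonoscope.io import SampleMeta
        with pytest.raises(ValueError, match="cross-lineage"):
            assemble_clonotypes(df, [SampleMeta("S1", "AD")])

    def test_noise_free_recovery_is_exact(self, clean_sim):
        """assemble ∘ simulate is the identity on the clone partition."""
        contigs, meta, truth = clean_sim
        kept, report = filter_contigs(contigs)
        assert sum(report.values()) == 0
        table = assemble_clonotypes(kept, meta)["TCR"]
        key_of = truth.clone_key("nt")
        for sid, counts in truth.sample_clone_counts.items():
            pool = truth.clone_table[
                truth.clone_table["group"] == sid.rstrip("0123456789")]
            expected = pd.Series(counts, index=key_of[pool["clone_id"]].to_numpy())
            expected = expected[expected > 0]
            got = table.sample_counts(sid)
            assert got.sort_index().equals(expected.sort_index().astype(got.dtype))

    def test_receptor_split(self):
        from clonoscope.io import SampleMeta
        df = contig_frame([
            dict(barcode="S1_t-1", locus="TRB", raw_contig_id="t"),
            dict(barcode="S1_b-1", locus="IGH", cdr3_nt="TGTAAA",
                 raw_contig_id="b"),
        ])
        tables = assemble_clonotypes(df, [SampleMeta("S1", "AD")])
        assert set(tables) == {"TCR", "BCR"}


def test_clonotype_table_tsv_round_trip(tmp_path, clean_sim):
    """A workflow may start from an exported per-clonotype table."""
    from clonoscope.clonotypes import read_clonotype_table

    contigs, meta, _ = clean_sim
    kept, _ = filter_contigs(contigs)
    table = assemble_clonotypes(kept, meta)["TCR"]
    path = tmp_path / "clonotypes.tsv"
    table.to_frame().to_csv(path, sep="\t", index=False)
    back = read_clonotype_table(path, meta)
    pd.testing.assert_frame_equal(back.counts, table.counts)
    assert back.receptor == "TCR"


class TestClonotypeFrequencies:
    def _table(self):
        from clonoscope.io import SampleMeta
        rows = []
        for key, n in (("A", 5), ("B", 3), ("C", 2)):
            for i in range(n):
                rows.append(dict(barcode=f"S1_{key}{i}-1", locus="TRB",
                                 cdr3_nt={"A": "TGTAAA", "B": "TGTCCC",
                                          "C": "TGTGGG"}[key],
                                 raw_contig_id=f"{key}{i}"))
        df = contig_frame(rows)
        return assemble_clonotypes(df, [SampleMeta("S1", "AD")])["TCR"]

    def test_hand_computed_frequencies(self):
        freqs = clonotype_frequencies(self._table(), scope="per_sample")
        assert sorted(freqs["frequency"]) == pytest.approx([0.2, 0.3, 0.5])

    def test_single_clonotype_is_one(self):
        from clonoscope.io import SampleMeta
        df = contig_frame([dict()])
        table = assemble_clonotypes(df, [SampleMeta("S1", "AD")])["TCR"]
        freqs = clonotype_frequencies(table, scope="per_sample")
        assert freqs["frequency"].tolist() == [1.0]

    def test_frequencies_sum_to_one_every_scope(self, clean_sim):
        contigs, meta, _ = clean_sim
        kept, _ = filter_contigs(contigs)
        table = assemble_clonotypes(kept, meta)["TCR"]
        for scope, unit in (("per_sample", "sample_id"), ("pooled_group", "group")):
            freqs = clonotype_frequencies(table, scope=scope)
            sums = freqs.groupby(unit)["frequency"].sum()
            assert np.allclose(sums, 1.0, atol=1e-12)

    def test_pooled_equals_cell_weighted_merge(self, clean_sim):
        contigs, meta, _ = clean_sim
        kept, _ = filter_contigs(contigs)
        table = assemble_clonotypes(kept, meta)["TCR"]
        pooled = clonotype_frequencies(table, scope="pooled_group")
        pooled = pooled[pooled["group"] == "AD"].set_index("clonotype")
        per = clonotype_frequencies(table, scope="per_sample")
        per = per[per["sample_id"].str.startswith("AD")]
        weights = table.totals[table.samples_of("AD")]
        merged = (per.assign(w=per["sample_id"].map(weights / weights.sum()))
                  .assign(wf=lambda d: d["frequency"] * d["w"])
                  .groupby("clonotype")["wf"].sum())
        assert np.allclose(pooled["frequency"].sort_index(),
                           merged.sort_index(), atol=1e-12)

    def test_empty_scope_errors(self):
        table = self._table()
        table.meta.append(type(table.meta[0])("S2", "NC"))
        table.counts["S2"] = 0
        with pytest.raises(ValueError, match="NC"):
            clonotype_frequencies(table, scope="pooled_group")
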