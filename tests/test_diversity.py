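import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from clonoscope.clonotypes import assemble_clonotypes, filter_contigs
from clonoscope.diversity import (cdr3_length_spectrum,
                                  compare_group_diversity, diversity_table,
                                  gene_usage, inv_simpson_index,
                                  shannon_index)
from clonoscope.io import SampleMeta
from clonoscope.simulate import (GroupSpec, NoiseConfig, SyntheticConfig,
                                 simulate_repertoire)
from conftest import contig_frame


class TestIndices:
    @pytest.mark.parametrize("s", range(1, 11))
    def test_uniform_closed_form(self, s):
        counts = [7] * s
        assert shannon_index(counts) == pytest.approx(math.log(s), abs=1e-12)
        assert inv_simpson_index(counts) == pytest.approx(s, rel=1e-12)

    def test_single_clone(self):
        assert shannon_index([42]) == 0.0
        assert inv_simpson_index([42]) == 1.0

    def test_hand_computed_211(self):
        assert shannon_index([2, 1, 1]) == pytest.approx(1.039721, abs=1e-6)
        assert inv_simpson_index([2, 1, 1]) == pytest.approx(2.666667, abs=1e-6)

    def test_zero_counts_ignored(self):
        assert shannon_index([2, 0, 1, 1]) == shannon_index([2, 1, 1])

    def test_all_zero_errors(self):
        with pytest.raises(ValueError):
            shannon_index([0, 0])
        with pytest.raises(ValueError):
            inv_simpson_index([])

    def test_log_base_flag(self):
        assert shannon_index([1, 1], base=2) == pytest.approx(1.0)

    def test_agrees_with_scikit_bio(self, rng):
        from skbio.diversity.alpha import enspie, shannon

        for _ in range(20):
            counts = rng.integers(1, 100, size=rng.integers(2, 50))
            assert shannon_index(counts) == pytest.approx(
                shannon(counts, base=math.e), rel=1e-10)
            assert inv_simpson_index(counts) == pytest.approx(
                enspie(counts), rel=1e-10)


@given(st.lists(st.integers(min_value=1, max_value=1000), min_size=1,
                max_size=50))
@settings(deadline=None, max_examples=200, derandomize=True)
def test_hill_ordering_property(counts):
    """1 <= D <= S, 0 <= H <= ln S, D <= exp(H) on arbitrary count vectors."""
    s = len(counts)
    h = shannon_index(counts)
    d = inv_simpson_index(counts)
    assert 1.0 - 1e-9 <= d <= s + 1e-9
    assert -1e-12 <= h <= math.log(s) + 1e-9
    assert d <= math.exp(h) + 1e-9
    if len(set(counts)) == 1:  # uniform: all equalities
        assert d == pytest.approx(s, rel=1e-9)
        assert math.exp(h) == pytest.approx(s, rel=1e-9)


@given(st.lists(st.integers(min_value=1, max_value=500), min_size=3,
                max_size=30))
@settings(deadline=None, max_examples=100, derandomize=True)
def test_merging_equal_clones_never_increases_diversity(counts):
    merged = [counts[0] + counts[1]] + counts[2:]
    if counts[0] == counts[1]:
        assert shannon_index(merged) <= shannon_index(counts) + 1e-12
        assert inv_simpson_index(merged) <= inv_simpson_index(counts) + 1e-12


class TestGroupComparison:
    def _div(self, ad, nc):
        return pd.DataFrame({
            "sample_id": [f"AD{i}" for i in range(len(ad))]
            + [f"NC{i}" for i in range(len(nc))],
            "group": ["AD"] * len(ad) + ["NC"] * len(nc),
            "shannon_H": ad + nc, "inv_simpson_D": ad + nc})

    def test_identical_groups_permutation_p_one(self):
        cmp_ = compare_group_diversity(self._div([5.0, 5.0], [5.0, 5.0]),
                                       method="permutation")
        assert cmp_.p_value == 1.0

    def test_exhaustive_enumeration_oracle(self):
        """{1,2,3} vs {10,11}: p equals enumeration over all C(5,2) splits."""
        cmp_ = compare_group_diversity(self._div([1.0, 2.0, 3.0], [10.0, 11.0]),
                                       method="permutation")
        pooled = [1.0, 2.0, 3.0, 10.0, 11.0]
        obs = abs(np.mean([1, 2, 3]) - np.mean([10, 11]))
        hits = 0
        for nc_idx in itertools.combinations(range(5), 2):
            nc = [pooled[i] for i in nc_idx]
            ad = [pooled[i] for i in range(5) if i not in nc_idx]
            hits += abs(np.mean(ad) - np.mean(nc)) >= obs - 1e-12
        assert cmp_.n_permutations == 10
        assert cmp_.p_value == pytest.approx(hits / 10)

    def test_welch_needs_two_per_group(self):
        with pytest.raises(ValueError, match="permutation"):
            compare_group_diversity(self._div([1.0, 2.0], [3.0]),
                                    method="welch_t")

    def test_welch_matches_scipy(self):
        from scipy.stats import ttest_ind

        div = self._div([1.0, 2.0, 3.0], [4.0, 6.0])
        cmp_ = compare_group_diversity(div, metric="shannon")
        expected = ttest_ind([1, 2, 3], [4, 6], equal_var=False).pvalue
        assert cmp_.p_value == pytest.approx(expected, rel=1e-12)
        assert cmp_.group_means == {"AD": 2.0, "NC": 5.0}

    def test_permutation_invariant_to_relabeling(self):
        div = self._div([1.0, 4.0, 2.0], [3.0, 5.0])
        swapped = div.assign(group=div["group"].map({"AD": "NC", "NC": "AD"}))
        a = compare_group_diversity(div, method="permutation")
        b = compare_group_diversity(swapped, method="permutation")
        assert a.p_value == pytest.approx(b.p_value)
        assert 0 < a.p_value <= 1.0

    def test_diversity_table_fields(self, clean_sim):
        contigs, meta, _ = clean_sim
        kept, _ = filter_contigs(contigs)
        table = assemble_clonotypes(kept, meta)["TCR"]
        div = diversity_table(table)
        assert set(div["group"]) == {"AD", "NC"}
        assert (div["inv_simpson_D"] <= div["richness_S"] + 1e-9).all()
        assert (div["inv_simpson_D"] <= np.exp(div["shannon_H"]) + 1e-9).all()
        assert (div["n_cells"] == table.totals.to_numpy()).all()


def two_group_meta():
    return [SampleMeta("S1", "AD"), SampleMeta("S2", "NC")]


class TestSpectratype:
    def test_hand_computed_frequencies(self):
        rows = []
        for i, (bc, length) in enumerate([("b1", 13), ("b2", 13), ("b3", 14),
                                          ("b4", 15)]):
            rows.append(dict(barcode=f"S1_{bc}-1", cdr3_aa="C" * length,
                             cdr3_nt="TGT" * length, raw_contig_id=str(i)))
        df = contig_frame(rows)
        spec = cdr3_length_spectrum(df, [SampleMeta("S1", "AD")], "TCR")
        freq = dict(zip(spec["length"], spec["freq_AD"]))
        assert freq == {13: pytest.approx(0.5), 14: pytest.approx(0.25),
                        15: pytest.approx(0.25)}

    def test_identical_groups_all_null(self):
        rows = []
        for sid in ("S1", "S2"):
            for i in range(30):
                length = 13 if i < 20 else 15
                rows.append(dict(barcode=f"{sid}_b{i}-1", sample_id=sid,
                                 cdr3_aa="C" * length, cdr3_nt="TGT" * length,
                                 raw_contig_id=f"{sid}{i}"))
        spec = cdr3_length_spectrum(contig_frame(rows), two_group_meta(), "TCR")
        assert np.allclose(spec["p_value"], 1.0)
        assert np.allclose(spec["statistic"].dropna(), 0.0, atol=1e-12)

    def test_row_order_invariance(self, clean_sim):
        contigs, meta, _ = clean_sim
        kept, _ = filter_contigs(contigs)
        a = cdr3_length_spectrum(kept, meta, "TCR")
        b = cdr3_length_spectrum(kept.sample(frac=1, random_state=0), meta, "TCR")
        pd.testing.assert_frame_equal(a, b)

    def test_modal_length_near_fourteen(self):
        """TCR defaults at 5,000 cells: modal CDR3 length in 13–15 aa,
        >= 95/100 seeds."""
        hits = 0
        for seed in range(100):
            config = SyntheticConfig(groups={"AD": GroupSpec(1, 5000)},
                                     noise=NoiseConfig(0, 0, 0), seed=seed)
            contigs, meta, _ = simulate_repertoire(config)
            spec = cdr3_length_spectrum(contigs, meta, "TCR")
            modal = int(spec.loc[spec["freq_AD"].idxmax(), "length"])
            hits += modal in (13, 14, 15)
        assert hits >= 95


class TestGeneUsage:
    def test_hand_computed(self):
        rows = [dict(barcode=f"S1_b{i}-1", v_gene=v, raw_contig_id=str(i),
                     cdr3_nt="TGT" + "GCA" * i)
                for i, v in enumerate(["TRBV9", "TRBV9", "TRBV20-1", "TRBV5-1"])]
        usage = gene_usage(contig_frame(rows), [SampleMeta("S1", "AD")], "V", "TCR")
        freq = dict(zip(usage["gene"], usage["freq_S1"]))
        assert freq["TRBV9"] == pytest.approx(0.5)
        assert freq["TRBV20-1"] == pytest.approx(0.25)

    def test_missing_calls_excluded_and_reported(self):
        rows = [dict(barcode="S1_b1-1", v_gene=None, raw_contig_id="a"),
                dict(barcode="S1_b2-1", v_gene="TRBV9", raw_contig_id="b",
                     cdr3_nt="TGTAAA")]
        usage = gene_usage(contig_frame(rows), [SampleMeta("S1", "AD")], "V", "TCR")
        assert usage.attrs["n_missing_call"] == 1
        assert usage["freq_S1"].sum() == pytest.approx(1.0)

    def test_per_sample_frequencies_sum_to_one(self, clean_sim):
        contigs, meta, _ = clean_sim
        kept, _ = filter_contigs(contigs)
        for seg in ("V", "J"):
            usage = gene_usage(kept, meta, seg, "TCR")
            for m in meta:
                assert usage[f"freq_{m.sample_id}"].sum() == pytest.approx(1.0)

    def test_one_group_only_gene_still_tested(self):
        rows = []
        for sid, v in (("S1", "TRBV9"), ("S2", "TRBV28")):
            for i in range(40):
                rows.append(dict(barcode=f"{sid}_b{i}-1", sample_id=sid,
                                 v_gene=v, raw_contig_id=f"{sid}{i}",
                                 cdr3_nt="TGTAAA"))
        usage = gene_usage(contig_frame(rows), two_group_meta(), "V", "TCR")
        assert usage["p_value"].notna().all()
        assert (usage["p_value"] < 0.001).all()

    def test_tilted_genes_detected(self):
        """tau_AD=2 vs tau_NC=1 at 5,000 cells/group: the 5 most shifted
        V genes rejected at 0.05 in >= 90/100 seeds."""
        from clonoscope.simulate import default_vj_usage

        base = default_vj_usage("TCR")
        expect = {}
        for locus in ("TRA", "TRB"):
            for gene, p in base[locus]["V"].items():
                tilted = np.array(list(base[locus]["V"].values())) ** 0.5
                p_ad = p ** 0.5 / tilted.sum()
                expect[gene] = abs(p_ad - p) / 2  # each locus is half the obs
        top5 = sorted(expect, key=expect.get, reverse=True)[:5]
        hits = dict.fromkeys(top5, 0)
        n_seeds = 100
        for seed in range(n_seeds):
            config = SyntheticConfig(
                groups={"AD": GroupSpec(1, 5000), "NC": GroupSpec(1, 5000)},
                expansion_mass=0.0, usage_tilt={"AD": 2.0, "NC": 1.0},
                n_background_clones=20000,
                noise=NoiseConfig(0, 0, 0), seed=seed)
            contigs, meta, _ = simulate_repertoire(config)
            usage = gene_usage(contigs, meta, "V", "TCR").set_index("gene")
            for gene in top5:
                if gene in usage.index and usage.loc[gene, "p_value"] < 0.05:
                    hits[gene] += 1
        assert all(h >= 90 for h in hits.values()), hits
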