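"""Elevation flags, TF-site overlap, SNV density, hot regions, exon boundaries."""

import numpy as np
import pandas as pd
import pytest

from regsnv.annotate import (
    REPRESSOR_TFS,
    elevated_samples,
    exon_boundary_flag,
    find_hot_regions,
    flag_elevated,
    snv_density,
    tf_overlap,
)
from regsnv.io_formats import GeneModel


class TestFlagElevated:
    def test_hand_median_sd_computation(self):
        row = pd.Series(np.arange(1.0, 11.0), index=[f"s{i}" for i in range(10)])
        # median 5.5, sd (n-1) ~3.028; z for value 10 = 4.5/3.028 ~ 1.486
        assert flag_elevated(row, "s9", 0.4)
        assert not flag_elevated(row, "s4", 0.4)  # value 5 below median

    def test_constant_row_flags_nobody(self):
        row = pd.Series([2.0] * 5, index=[f"s{i}" for i in range(5)])
        assert not any(flag_elevated(row, s, 0.4) for s in row.index)

    def test_sample_at_median_not_flagged(self):
        row = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        assert not flag_elevated(row, "b", 0.4)

    def test_unknown_sample_errors(self):
        row = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        with pytest.raises(KeyError):
            flag_elevated(row, "zzz")

    def test_shift_invariant_and_scale_equivariant(self, rng):
        vals = rng.normal(5, 2, 30)
        row = pd.Series(vals, index=[f"s{i}" for i in range(30)])
        flags = [flag_elevated(row, s) for s in row.index]
        shifted = [flag_elevated(row + 7.3, s) for s in row.index]
        scaled = [flag_elevated(row * 2.5, s) for s in row.index]
        assert flags == shifted == scaled

    def test_elevated_samples_consistent_with_flag(self, rng):
        row = pd.Series(rng.normal(size=25), index=[f"s{i}" for i in range(25)])
        expect = [s for s in row.index if flag_elevated(row, s)]
        assert elevated_samples(row) == expect


def _events(rows):
    return pd.DataFrame(rows, columns=["gene_id", "sample_id", "chrom", "pos"])


class TestTfOverlap:
    def test_repressor_set_is_the_twenty_tfs(self):
        assert len(REPRESSOR_TFS) == 20
        assert "CTCF" in REPRESSOR_TFS and "REST" in REPRESSOR_TFS
        assert "MYC" not in REPRESSOR_TFS

    def test_empty_site_list(self):
        ev = _events([("g1", "s1", "chr1", 100)])
        sites = pd.DataFrame(columns=["chrom", "start", "end", "tf_name"])
        assoc, per_tf, summary = tf_overlap(ev, sites)
        assert assoc.empty
        assert summary.iloc[0]["fraction_in_sites"] == 0.0

    def test_point_in_interval(self):
        ev = _events([("g1", "s1", "chr1", 100)])
        sites = pd.DataFrame([("chr1", 50, 150, "CTCF")],
                             columns=["chrom", "start", "end", "tf_name"])
        assoc, per_tf, summary = tf_overlap(ev, sites)
        assert len(assoc) == 1 and assoc.iloc[0]["tf_name"] == "CTCF"

    def test_snv_in_two_sites_yields_two_rows(self):
        ev = _events([("g1", "s1", "chr1", 100)])
        sites = pd.DataFrame([("chr1", 50, 150, "CTCF"), ("chr1", 90, 110, "REST")],
                             columns=["chrom", "start", "end", "tf_name"])
        assoc, _, summary = tf_overlap(ev, sites)
        assert sorted(assoc["tf_name"]) == ["CTCF", "REST"]
        assert summary.iloc[0]["n_in_sites"] == 1  # one event, two associations

    def test_non_repressor_sites_ignored(self):
        ev = _events([("g1", "s1", "chr1", 100)])
        sites = pd.DataFrame([("chr1", 50, 150, "MYC")],
                             columns=["chrom", "start", "end", "tf_name"])
        assoc, _, _ = tf_overlap(ev, sites)
        assert assoc.empty

    def test_matches_brute_force_double_loop(self, rng):
        tfs = sorted(REPRESSOR_TFS) + ["MAX", "JUN"]
        sites = pd.DataFrame(
            [("chr1", int(s), int(s) + int(rng.integers(10, 300)),
              tfs[int(rng.integers(len(tfs)))])
             for s in rng.integers(0, 50_000, 40)],
            columns=["chrom", "start", "end", "tf_name"],
        )
        ev = _events([
            ("g1", f"s{int(rng.integers(5))}", "chr1", int(rng.integers(0, 50_000)))
            for _ in range(200)
        ])
        assoc, _, summary = tf_overlap(ev, sites)
        brute = []
        for e in ev.itertuples(index=False):
            for st in sites.itertuples(index=False):
                if (st.tf_name in REPRESSOR_TFS and st.chrom == e.chrom
                        and st.start <= e.pos < st.end):
                    brute.append((e.gene_id, e.sample_id, e.pos, st.tf_name))
        assert len(assoc) == len(brute)
        got = sorted(zip(assoc.gene_id, assoc.sample_id, assoc.pos, assoc.tf_name))
        assert got == sorted(brute)


class TestSnvDensity:
    def test_single_and_multi_carrier_densities(self):
        ev = _events([("g1", "s1", "chr1", 1), ("g1", "s1", "chr1", 2),
                      ("g1", "s1", "chr1", 3),
                      ("g2", "s1", "chr1", 9), ("g2", "s2", "chr1", 10),
                      ("g2", "s2", "chr1", 11), ("g2", "s2", "chr1", 12)])
        ct = pd.Series({"s1": "brca", "s2": "luad"})
        out = snv_density(["g1", "g2"], ev, {"g1": ["s1"], "g2": ["s1", "s2"]}, ct)
        assert out.set_index("gene_id").loc["g1", "snvs_per_patient"] == 3.0
        assert out.set_index("gene_id").loc["g2", "snvs_per_patient"] == 2.0

    def test_zero_elevated_carriers_omits_gene(self):
        ev = _events([("g1", "s1", "chr1", 1)])
        out = snv_density(["g1"], ev, {"g1": []}, pd.Series({"s1": "brca"}))
        assert out.empty

    def test_dominant_type_tie_breaks_lexicographically(self):
        ev = _events([("g1", "s1", "chr1", 1), ("g1", "s2", "chr1", 2)])
        ct = pd.Series({"s1": "luad", "s2": "brca"})
        out = snv_density(["g1"], ev, {"g1": ["s1", "s2"]}, ct)
        assert out.iloc[0]["dominant_cancer_type"] == "brca"

    def test_hand_tabulated_fixture(self, rng):
        genes = [f"g{i}" for i in range(5)]
        samples = [f"s{i}" for i in range(8)]
        rows = [(genes[int(rng.integers(5))], samples[int(rng.integers(8))],
                 "chr1", int(rng.integers(1000))) for _ in range(60)]
        ev = _events(rows)
        elev = {g: samples[:4] for g in genes}
        ct = pd.Series({s: "t" for s in samples})
        out = snv_density(genes, ev, elev, ct).set_index("gene_id")
        for g in genes:
            sub = [r for r in rows if r[0] == g and r[1] in samples[:4]]
            pats = {r[1] for r in sub}
            if not pats:
                assert g not in out.index
            else:
                assert out.loc[g, "snvs_per_patient"] == len(sub) / len(pats)


def _hot_events(pos_sample_pairs):
    return pd.DataFrame(
        [(s, "chr1", p) for p, s in pos_sample_pairs],
        columns=["sample_id", "chrom", "pos"],
    )


class TestFindHotRegions:
    def test_nine_snvs_fails_min_snvs(self):
        ev = _hot_events([(100, f"p{i}") for i in range(9)])
        assert find_hot_regions(ev) == []

    def test_hand_chained_positive(self):
        # 12 SNVs from 6 patients at 0,10,...,110 -> one region [0,110]
        ev = _hot_events([(10 * i, f"p{i % 6}") for i in range(12)])
        regions = find_hot_regions(ev)
        assert len(regions) == 1
        r = regions[0]
        assert (r.start, r.end - 1) == (0, 110)
        assert (r.snv_count, r.patient_count) == (12, 6)

    def test_gaps_of_31_break_every_chain(self):
        ev = _hot_events([(31 * i, f"p{i % 6}") for i in range(12)])
        assert find_hot_regions(ev) == []

    def test_gap_of_exactly_30_allowed(self):
        ev = _hot_events([(30 * i, f"p{i % 5}") for i in range(10)])
        regions = find_hot_regions(ev)
        assert len(regions) == 1
        assert regions[0].snv_count == 10

    def test_too_few_patients_rejected(self):
        ev = _hot_events([(10 * i, f"p{i % 4}") for i in range(12)])  # 4 patients
        assert find_hot_regions(ev) == []

    def test_order_invariance_and_disjointness(self, rng):
        pairs = [(int(rng.integers(0, 2000)), f"p{int(rng.integers(12))}")
                 for _ in range(150)]
        ev = _hot_events(pairs)
        regions = find_hot_regions(ev)
        shuffled = ev.sample(frac=1.0, random_state=5).reset_index(drop=True)
        regions2 = find_hot_regions(shuffled)
        key = [(r.chrom, r.start, r.end, r.snv_count, r.patient_count)
               for r in regions]
        key2 = [(r.chrom, r.start, r.end, r.snv_count, r.patient_count)
                for r in regions2]
        assert key == key2
        for a, b in zip(regions, regions[1:]):
            assert a.end <= b.start            # disjoint
            assert b.start - (a.end - 1) > 30  # merging would violate max_gap


class TestExonBoundaryFlag:
    @pytest.fixture
    def gene(self):
        return GeneModel("g", "g", "chr1", "+", 0, 20_600,
                         exons=[(0, 300), (10_300, 20_600)])

    def test_one_base_into_intron(self, gene):
        assert exon_boundary_flag(300, gene, boundary_window=10)

    def test_intron_midpoint_of_10kb_intron(self, gene):
        assert not exon_boundary_flag(5_300, gene, boundary_window=10)

    def test_non_intronic_position_errors(self, gene):
        with pytest.raises(ValueError):
            exon_boundary_flag(100, gene)

    def test_matches_brute_force_distance_scan(self, rng):
        gene = GeneModel("g", "g", "chr1", "+", 0, 9_000,
                         exons=[(0, 1000), (3000, 4000), (8000, 9000)])
        introns = [(1000, 3000), (4000, 8000)]
        for _ in range(300):
            a, b = introns[int(rng.integers(2))]
            pos = int(rng.integers(a, b))
            # distance in bases to nearest junction: first intron base = 1
            brute = min(pos - a + 1, b - pos)
            w = int(rng.integers(1, 50))
            assert exon_boundary_flag(pos, gene, w) == (brute <= w)
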