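"""Depth-aware dN/dS: expectations, tests, per-sample matrix."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from selscope import omega
from selscope.catalog_io import PanelRegion
from selscope.mutrate import TrinucSpectrum

from conftest import build_panel, uniform_depth


def flat_spectrum(rate: float) -> TrinucSpectrum:
    return TrinucSpectrum(counts=np.full(96, rate), opportunity=np.ones(96))


@pytest.fixture()
def uniform_gene_panel(tmp_path):
    """Single-exon 60-codon gene at uniform depth 100 in each of 2 samples."""
    rng = np.random.default_rng(42)
    from selscope.synthetic_data import _random_cds
    cds = _random_cds(rng, 60)
    seq = "ACGTA" + cds + "TGCAT"
    regions = [PanelRegion("g", 5, 5 + len(cds), "G1", "coding", "+", 0)]
    panel = build_panel(tmp_path, {"g": seq}, regions)
    panel.attach_depth(uniform_depth(
        panel.sites, {"s1": 100, "s2": 100}))
    return panel


class TestExpectedCounts:
    def test_closed_form_uniform_rate_and_depth(self, uniform_gene_panel):
        r = 1e-5
        exp = omega.expected_counts("G1", flat_spectrum(r), uniform_gene_panel)
        sa = uniform_gene_panel.site_alts
        n_mis = int((sa["consequence"] == "missense").sum())
        # cohort depth = 200 per site
        assert exp["missense"] == pytest.approx(r * 200 * n_mis, rel=1e-9)
        n_syn = int((sa["consequence"] == "synonymous").sum())
        assert exp["synonymous"] == pytest.approx(r * 200 * n_syn, rel=1e-9)

    def test_linearity_in_depth(self, uniform_gene_panel):
        spec = flat_spectrum(2e-6)
        base = omega.expected_counts("G1", spec, uniform_gene_panel)
        doubled = uniform_gene_panel.depth * 2
        uniform_gene_panel.depth = doubled
        twice = omega.expected_counts("G1", spec, uniform_gene_panel)
        for k in base:
            assert twice[k] == pytest.approx(2 * base[k], rel=1e-12)

    def test_cohort_equals_sum_of_samples(self, default_cohort, default_spectrum):
        panel = default_cohort.panel
        cohort_e = omega.expected_counts("TP53", default_spectrum, panel)
        total = {k: 0.0 for k in cohort_e}
        for s in panel.samples:
            e = omega.expected_counts("TP53", default_spectrum, panel, scope=s)
            for k in e:
                total[k] += e[k]
        for k in cohort_e:
            assert total[k] == pytest.approx(cohort_e[k], rel=1e-9)

    def test_absent_gene_fatal(self, uniform_gene_panel):
        with pytest.raises(ValueError, match="absent"):
            omega.expected_counts("NOPE", flat_spectrum(1e-6), uniform_gene_panel)


def _fake_mutations(n, gene="G1", consequence="missense", sample="s1"):
    return pd.DataFrame({
        "sample_id": sample, "chrom": "g", "pos": range(n), "ref": "A",
        "alt": "T", "mut_type": "SNV", "vaf_duplex": 0.01,
        "vaf_all_molecules": 0.01, "gene": gene, "consequence": consequence,
        "protein_pos": 1,
    })


class TestDnds:
    def test_ratio_and_driver_arithmetic(self):
        res = omega.dnds("G1", "missense", _fake_mutations(20), {"missense": 2.0})
        assert res.dnds == pytest.approx(10.0)
        assert res.driver_excess == pytest.approx(18.0)
        assert res.driver_fraction == pytest.approx(0.9)
        assert res.ci_low <= res.dnds <= res.ci_high
        assert res.p_value < 1e-9

    def test_zero_observed_points_to_negative_selection(self):
        res = omega.dnds("G1", "missense", _fake_mutations(0), {"missense": 2.0})
        assert res.dnds == 0.0
        assert res.ci_low == 0.0

    def test_zero_expected_suppressed(self):
        assert omega.dnds("G1", "missense", _fake_mutations(3),
                          {"missense": 0.0}) is None

    def test_garwood_interval_published_values(self):
        # 95% CI for a Poisson count of 10: (4.795, 18.390)
        lo, hi = omega.poisson_ci(10)
        assert lo == pytest.approx(4.795, abs=2e-3)
        assert hi == pytest.approx(18.390, abs=2e-3)

    def test_two_sided_p_is_doubled_smaller_tail(self):
        p = omega.poisson_pvalue(8, 2.0)
        expected = 2 * stats.poisson.sf(7, 2.0)
        assert p == pytest.approx(expected)
        assert omega.poisson_pvalue(2, 2.0) == 1.0


class TestPtert:
    @pytest.fixture()
    def promoter_panel(self, tmp_path):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=320))
        regions = [PanelRegion("p", 10, 310, "TERT", "promoter", "+")]
        panel = build_panel(tmp_path, {"p": seq}, regions)
        panel.attach_depth(uniform_depth(
            panel.sites, {"s1": 1000}))
        return panel

    def test_calibration_reproduces_nonactivating_count(self, promoter_panel):
        sites = promoter_panel.sites
        sa = promoter_panel.site_alts
        wl = set()
        for i in range(20):
            wl.add((sites["chrom"].iat[i], int(sites["pos"].iat[i]),
                    sa.loc[sa["site"] == i, "alt"].iloc[0]))
        # 50 mutations at non-whitelist positions only
        rows = []
        for i in range(100, 150):
            rows.append({
                "sample_id": "s1", "chrom": sites["chrom"].iat[i],
                "pos": int(sites["pos"].iat[i]), "ref": sites["ref"].iat[i],
                "alt": sa.loc[sa["site"] == i, "alt"].iloc[0],
                "mut_type": "SNV", "vaf_duplex": 0.01,
                "vaf_all_molecules": 0.01, "gene": "TERT",
                "consequence": "noncoding", "protein_pos": None,
            })
        muts = pd.DataFrame(rows)
        res = omega.dnds_ptert(muts, wl, flat_spectrum(1e-6), promoter_panel)
        # expected activating count = 50 * (whitelist opp / other opp)
        assert res.observed == 0
        assert res.dnds == 0.0
        assert res.expected == pytest.approx(50 * 20 / (900 - 20), rel=1e-6)

    def test_empty_whitelist_fatal(self, promoter_panel):
        with pytest.raises(ValueError, match="whitelist"):
            omega.dnds_ptert(_fake_mutations(0), set(),
                             flat_spectrum(1e-6), promoter_panel)


class TestIndelEnrichment:
    def _indels(self, spec):
        rows = []
        for gene, chrom, positions in spec:
            for p in positions:
                rows.append({
                    "sample_id": "s1", "chrom": chrom, "pos": p, "ref": "AT",
                    "alt": "A", "mut_type": "deletion", "vaf_duplex": 0.01,
                    "vaf_all_molecules": 0.01, "gene": gene,
                    "consequence": "frameshift_indel", "protein_pos": None,
                })
        return pd.DataFrame(rows)

    @pytest.fixture()
    def two_gene_panel(self, tmp_path):
        rng = np.random.default_rng(5)
        from selscope.synthetic_data import _random_cds
        seqs, regions = {}, []
        for name in ("G1", "G2"):
            cds = _random_cds(rng, 40)
            seqs[name] = "ACGTA" + cds + "TGCAT"
            regions.append(PanelRegion(name, 5, 5 + len(cds), name, "coding", "+", 0))
        panel = build_panel(tmp_path, seqs, regions)
        panel.attach_depth(uniform_depth(
            panel.sites, {"s1": 500}))
        return panel

    def test_background_rate_counting_oracle(self, two_gene_panel):
        # 4 indels in G2 -> G1 background rate = 4 / (120*500); E_G1 = that * 120*500
        muts = self._indels([("G1", "G1", [10, 11]), ("G2", "G2", [10, 11, 12, 13])])
        res = omega.indel_enrichment("G1", muts, two_gene_panel)
        assert res.expected == pytest.approx(4.0)  # equal lengths and depth
        assert res.observed == 2
        assert res.dnds == pytest.approx(0.5)

    def test_leave_one_out_never_lowers_other_genes_expectation(self, two_gene_panel):
        # moving an indel from G2 into G1 raises G1's enrichment while G2's
        # leave-one-out expectation (background = everything but G2) grows
        split = self._indels([("G1", "G1", [10, 11]), ("G2", "G2", [10, 11])])
        moved = self._indels([("G1", "G1", [10, 11, 12]), ("G2", "G2", [10])])
        e_g2_split = omega.indel_enrichment("G2", split, two_gene_panel)
        e_g2_moved = omega.indel_enrichment("G2", moved, two_gene_panel)
        assert e_g2_moved.expected >= e_g2_split.expected
        r_g1_split = omega.indel_enrichment("G1", split, two_gene_panel)
        r_g1_moved = omega.indel_enrichment("G1", moved, two_gene_panel)
        assert r_g1_moved.dnds > r_g1_split.dnds

    def test_no_background_suppressed(self, two_gene_panel):
        muts = self._indels([("G1", "G1", [10])])
        assert omega.indel_enrichment("G1", muts, two_gene_panel) is None


class TestPerSampleMatrix:
    def _boundary_panel(self, tmp_path, n_with_depth, n_samples=79):
        rng = np.random.default_rng(8)
        from selscope.synthetic_data import _random_cds
        cds = _random_cds(rng, 10)
        seq = "ACGTA" + cds + "TGCAT"
        regions = [PanelRegion("g", 5, 5 + len(cds), "G1", "coding", "+", 0)]
        panel = build_panel(tmp_path, {"g": seq}, regions)
        depth = panel.sites[["chrom", "pos"]].copy()
        for i in range(n_samples):
            depth[f"s{i}"] = 100 if i < n_with_depth else 0
        panel.attach_depth(depth)
        return panel

    @pytest.mark.parametrize("n_ok,expect", [(63, False), (64, True)])
    def test_eligibility_boundary_at_80_percent_of_79(self, tmp_path, n_ok, expect):
        """The 80%-of-samples rule flips exactly between 63/79 and 64/79."""
        panel = self._boundary_panel(tmp_path, n_ok)
        muts = _fake_mutations(0)
        df = omega.per_sample_matrix(["G1"], ["missense"], muts, panel,
                                     flat_spectrum(1e-6),
                                     calibrate_per_sample=False)
        assert df["eligible"].iloc[0] == expect
        assert int((~df["missing"]).sum()) == n_ok

    def test_zero_depth_sample_is_missing(self, tmp_path):
        panel = self._boundary_panel(tmp_path, 1, n_samples=2)
        df = omega.per_sample_matrix(["G1"], ["missense"], _fake_mutations(0),
                                     panel, flat_spectrum(1e-6),
                                     calibrate_per_sample=False)
        assert df.loc[df["sample_id"] == "s1", "missing"].iloc[0]
        assert not df.loc[df["sample_id"] == "s0", "missing"].iloc[0]
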