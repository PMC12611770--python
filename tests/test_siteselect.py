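"""Site/residue/exon/domain selection scores."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from selscope import omega, siteselect


class TestSiteExpected:
    def test_partition_sums_to_gene_expectation(self, default_cohort,
                                                default_spectrum):
        panel = default_cohort.panel
        se = siteselect.site_expected("TP53", default_spectrum, panel)
        gene_e = omega.expected_counts("TP53", default_spectrum, panel)
        for mclass, members in (("missense", ["missense"]),
                                ("synonymous", ["synonymous"]),
                                ("truncating", ["nonsense", "essential_splice"])):
            got = se.loc[se["consequence"].isin(members), "expected"].sum()
            assert got == pytest.approx(gene_e[mclass], rel=1e-9)

    def test_double_depth_site_gets_double_share(self, default_cohort,
                                                 default_spectrum):
        panel = default_cohort.panel
        se1 = siteselect.site_expected("TP53", default_spectrum, panel)
        gmask = panel.gene_mask("TP53")
        site0 = int(np.flatnonzero(gmask)[30])
        panel.depth.iloc[site0] = panel.depth.iloc[site0] * 2
        try:
            se2 = siteselect.site_expected("TP53", default_spectrum, panel)
        finally:
            panel.depth.iloc[site0] = panel.depth.iloc[site0] / 2
        m1 = se1[se1["site"] == site0]
        m2 = se2[se2["site"] == site0]
        same_class = m1["consequence"].iloc[0]
        # shares are renormalised, so compare against a reference site of the
        # same consequence class whose depth did not change
        other = se1[(se1["site"] != site0) & (se1["consequence"] == same_class)]
        ref_site = int(other["site"].iloc[0])
        ratio1 = m1["expected"].iloc[0] / \
            se1[(se1["site"] == ref_site)
                & (se1["consequence"] == same_class)]["expected"].iloc[0]
        ratio2 = m2["expected"].iloc[0] / \
            se2[(se2["site"] == ref_site)
                & (se2["consequence"] == same_class)]["expected"].iloc[0]
        assert ratio2 == pytest.approx(2 * ratio1, rel=1e-9)


class TestScoreUnits:
    def _exp_table(self, default_cohort, default_spectrum, gene="TP53"):
        return siteselect.site_expected(gene, default_spectrum,
                                        default_cohort.panel)

    def test_scores_use_exact_poisson_upper_tail(self, default_cohort,
                                                 default_spectrum):
        """Reported p-values are the exact Poisson upper tail on raw counts
        and the display score is the ε-stabilised log2 ratio."""
        se = self._exp_table(default_cohort, default_spectrum)
        scores = siteselect.score_units("TP53", default_cohort.mutations, se,
                                        unit="residue")
        tab = scores.table
        for _, row in tab.sort_values("observed", ascending=False).head(5).iterrows():
            assert row["p_value"] == pytest.approx(
                stats.poisson.sf(row["observed"] - 1, row["expected"]))
            assert row["score"] == pytest.approx(
                np.log2((row["observed"] + 0.5) / (row["expected"] + 0.5)))

    def test_no_mutations_no_positive_scores(self, default_cohort,
                                             default_spectrum):
        se = self._exp_table(default_cohort, default_spectrum)
        empty = default_cohort.mutations.iloc[0:0]
        scores = siteselect.score_units("TP53", empty, se, unit="residue")
        assert (scores.table["score"] <= 0).all()
        assert not (scores.table["q_value"] < 0.1).any()

    def test_hotspot_residue_ranks_first(self, default_cohort, default_spectrum):
        se = self._exp_table(default_cohort, default_spectrum)
        muts = default_cohort.mutations
        target = 120
        sa = default_cohort.panel.site_alts
        gmask = default_cohort.panel.gene_mask("TP53")[sa["site"]]
        pick = sa[gmask & (sa["protein_pos"] == target)
                  & (sa["consequence"] == "missense")].iloc[0]
        sites = default_cohort.panel.sites
        extra = pd.DataFrame([{
            "sample_id": s, "donor_id": "dX",
            "chrom": sites["chrom"].iat[pick["site"]],
            "pos": sites["pos"].iat[pick["site"]],
            "ref": sites["ref"].iat[pick["site"]], "alt": pick["alt"],
            "mut_type": "SNV", "vaf_duplex": 0.01, "vaf_all_molecules": 0.01,
            "gene": "TP53", "consequence": "missense", "protein_pos": target,
        } for s in default_cohort.panel.samples[:30]])
        scores = siteselect.score_units(
            "TP53", pd.concat([muts, extra], ignore_index=True), se,
            unit="residue")
        best = scores.table.sort_values("q_value").iloc[0]
        assert int(best["unit_id"]) == target

    def test_domain_scores_partition_residues(self, default_cohort,
                                              default_spectrum):
        se = self._exp_table(default_cohort, default_spectrum)
        intervals = pd.DataFrame({
            "unit_id": ["Nterm", "core", "Cterm"],
            "start": [1, 101, 301], "end": [100, 300, 394],
        })
        scores = siteselect.score_units(
            "TP53", default_cohort.mutations, se, unit="domain",
            intervals=intervals, class_filter=("missense",))
        gene_e = omega.expected_counts("TP53", default_spectrum,
                                       default_cohort.panel)["missense"]
        assert scores.table["expected"].sum() == pytest.approx(gene_e, rel=1e-9)
        assert {"dnds", "ci_low", "ci_high"} <= set(scores.table.columns)

    def test_neutral_pvalues_super_uniform(self, neutral_cohort):
        """Under neutrality residue p-values are uniform or super-uniform."""
        spec = omega.fit_cohort_spectrum(neutral_cohort.mutations,
                                         neutral_cohort.panel, pseudocount=0.0)
        se = siteselect.site_expected("G1", spec, neutral_cohort.panel)
        scores = siteselect.score_units("G1", neutral_cohort.mutations, se,
                                        unit="residue")
        p = scores.table["p_value"].to_numpy()
        n = len(p)
        for x in (0.01, 0.05, 0.1, 0.25, 0.5):
            frac = (p <= x).mean()
            band = 3 * np.sqrt(x * (1 - x) / n)
            assert frac <= x + band

    def test_unknown_unit_rejected(self, default_cohort, default_spectrum):
        se = self._exp_table(default_cohort, default_spectrum)
        with pytest.raises(ValueError, match="unknown unit"):
            siteselect.score_units("TP53", default_cohort.mutations, se,
                                   unit="chromosome")
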