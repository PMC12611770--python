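"""Panel annotation, catalog loading and consequence calls."""

import numpy as np
import pandas as pd
import pytest
from Bio.Seq import Seq

from selscope import catalog_io
from selscope.catalog_io import PanelRegion
from selscope.synthetic_data import GeneSpec, SyntheticCohortConfig, generate_cohort

from conftest import build_panel


@pytest.fixture()
def toy_gene_panel(tmp_path):
    # pad(5) + ATG AAA CGA TAA + pad(5), single exon, '+' strand
    seq = "AACCA" + "ATGAAACGATAA" + "GGTTG"
    regions = [PanelRegion("chrT", 5, 17, "GENEA", "coding", "+", 0)]
    return build_panel(tmp_path, {"chrT": seq}, regions)


class TestConsequenceAnnotation:
    def test_codon_table_forced_calls(self, toy_gene_panel):
        lookup = toy_gene_panel.alt_lookup()
        # third base of ATG: G>A gives ATA (Ile) -> missense, not nonsense
        assert lookup[("chrT", 7, "A")][1] == "missense"
        # first base of AAA: A>T gives TAA stop -> nonsense
        assert lookup[("chrT", 8, "T")][1] == "nonsense"
        # third base of AAA: A>G gives AAG (Lys) -> synonymous
        assert lookup[("chrT", 10, "G")][1] == "synonymous"

    def test_protein_positions(self, toy_gene_panel):
        lookup = toy_gene_panel.alt_lookup()
        assert lookup[("chrT", 5, "C")][2] == 1   # in start codon
        assert lookup[("chrT", 11, "T")][2] == 3  # CGA codon

    def test_trinuc_strand_collapse_on_sites(self, tmp_path):
        # site ref C flanked by A,G -> ACG; ref G flanked by C,T -> ACG too
        seq = "AAACGTAAA"
        regions = [PanelRegion("c1", 2, 6, "G1", "intronic_flank", "+")]
        panel = build_panel(tmp_path, {"c1": seq}, regions)
        tri = dict(zip(panel.sites["pos"], panel.sites["trinuc"]))
        assert tri[3] == "ACG"   # ref C, flanks A,G
        assert tri[4] == "ACG"   # ref G, flanks C,T -> collapsed

    def test_site_count_equals_region_lengths(self, default_cohort):
        panel = default_cohort.panel
        assert len(panel.sites) == sum(len(r) for r in panel.regions)
        coding = panel.total_bp("coding")
        noncoding = len(panel.sites) - coding
        assert coding + noncoding == panel.total_bp()

    def test_splice_sites_flank_internal_boundaries_only(self, tmp_path):
        # two exons with a 6-bp intron; outer flanks are not splice sites
        #           0123456789...
        seq = "AAAAA" + "CCC" + "ATGAAA" + "GTCAGA" + "CGATAA" + "CCC" + "AAAAA"
        regions = [
            PanelRegion("g", 5, 8, "G1", "intronic_flank", "+"),
            PanelRegion("g", 8, 14, "G1", "coding", "+", 0),
            PanelRegion("g", 14, 20, "G1", "intronic_flank", "+"),
            PanelRegion("g", 20, 26, "G1", "coding", "+", 0),
            PanelRegion("g", 26, 29, "G1", "intronic_flank", "+"),
        ]
        panel = build_panel(tmp_path, {"g": seq}, regions)
        lookup = panel.alt_lookup()
        splice_pos = {p for (c, p, a), v in lookup.items()
                      if v[1] == "essential_splice"}
        assert splice_pos == {14, 15, 18, 19}

    def test_brute_force_translation_oracle(self, tmp_path):
        """Annotation agrees with whole-CDS re-translation for every possible
        substitution of a two-exon minus-strand gene."""
        cfg = SyntheticCohortConfig(
            seed=5, genes=[GeneSpec("GX", 120, "-")], n_donors=4)
        cohort = generate_cohort(cfg, tmp_path / "c")
        panel = cohort.panel
        fasta = {"GX": open(cohort.paths["fasta"]).read().split("\n")[1]}
        seq = fasta["GX"]
        coding = sorted([r for r in panel.regions
                         if r.gene == "GX" and r.region_class == "coding"],
                        key=lambda r: r.start)

        def cds_of(genome):
            parts = [genome[r.start:r.end] for r in coding]
            cds = "".join(parts)
            return str(Seq(cds).reverse_complement())

        prot_ref = str(Seq(cds_of(seq)).translate())
        lookup = panel.alt_lookup()
        n_checked = 0
        for r in coding:
            for pos in range(r.start, r.end):
                for alt in "ACGT":
                    if alt == seq[pos]:
                        continue
                    mutant = seq[:pos] + alt + seq[pos + 1:]
                    prot_alt = str(Seq(cds_of(mutant)).translate())
                    diffs = [k for k, (a, b) in enumerate(zip(prot_ref, prot_alt))
                             if a != b]
                    if not diffs:
                        expect = "synonymous"
                    elif prot_alt[diffs[0]] == "*":
                        expect = "nonsense"
                    else:
                        expect = "missense"
                    assert lookup[("GX", pos, alt)][1] == expect
                    n_checked += 1
        assert n_checked == 120 * 3 * 3

    def test_region_outside_contig_is_fatal(self, tmp_path):
        with pytest.raises(ValueError, match="outside contig"):
            build_panel(tmp_path, {"c": "ACGT"},
                        [PanelRegion("c", 0, 10, "G", "coding", "+")])


class TestMutationLoading:
    def _write_catalog(self, tmp_path, rows):
        df = pd.DataFrame(rows, columns=catalog_io.MUTATION_COLUMNS)
        path = tmp_path / "muts.tsv"
        df.to_csv(path, sep="\t", index=False)
        return path

    def test_out_of_panel_and_bad_vaf_rejected(self, tmp_path, toy_gene_panel):
        rows = [("s1", "d1", "chrT", 9, "A", "T", 0.01, 0.01)] * 8
        rows.append(("s1", "d1", "chrOTHER", 9, "A", "T", 0.01, 0.01))  # no panel
        rows.append(("s1", "d1", "chrT", 9, "A", "T", 1.5, 0.01))       # bad VAF
        path = self._write_catalog(tmp_path, rows)
        df = catalog_io.load_mutations(path, toy_gene_panel)
        assert len(df) == 8
        assert df.attrs["n_rejected"] == 2

    def test_indel_frame_rule(self, tmp_path, toy_gene_panel):
        rows = [
            ("s1", "d1", "chrT", 8, "GAA", "G", 0.01, 0.01),   # 2-bp del: frameshift
            ("s1", "d1", "chrT", 8, "GAAA", "G", 0.01, 0.01),  # 3-bp del: in-frame
            ("s1", "d1", "chrT", 8, "G", "GT", 0.01, 0.01),    # 1-bp ins: frameshift
        ]
        df = catalog_io.load_mutations(
            self._write_catalog(tmp_path, rows), toy_gene_panel)
        assert list(df["consequence"]) == [
            "frameshift_indel", "inframe_indel", "frameshift_indel"]
        assert list(df["mut_type"]) == ["deletion", "deletion", "insertion"]

    def test_mnv_takes_worst_constituent_consequence(self, tmp_path, toy_gene_panel):
        # AA at 8-9 -> TA: A8>T is nonsense (TAA), A9>A no change... use 8-9 ->TG
        rows = [("s1", "d1", "chrT", 9, "AA", "TG", 0.01, 0.01)]
        df = catalog_io.load_mutations(
            self._write_catalog(tmp_path, rows), toy_gene_panel)
        assert df["mut_type"].iat[0] == "MNV"
        assert df["consequence"].iat[0] == "nonsense"

    def test_unknown_sample_fatal(self, tmp_path, toy_gene_panel):
        path = self._write_catalog(
            tmp_path, [("ghost", "d1", "chrT", 9, "A", "T", 0.01, 0.01)])
        with pytest.raises(ValueError, match="unknown sample"):
            catalog_io.load_mutations(path, toy_gene_panel, samples=["s1"])

    def test_round_trip(self, tmp_path, default_cohort):
        sub = default_cohort.mutations.head(200)
        path = tmp_path / "rt.tsv"
        catalog_io.write_mutations(sub, path)
        back = catalog_io.load_mutations(path, default_cohort.panel)
        for col in ["sample_id", "chrom", "pos", "ref", "alt", "consequence"]:
            assert list(back[col]) == list(sub[col])
        np.testing.assert_allclose(back["vaf_duplex"], sub["vaf_duplex"])


class TestResidueTally:
    def test_exhaustive_catalog_hits_every_residue(self, tmp_path):
        cfg = SyntheticCohortConfig(seed=9, genes=[GeneSpec("GY", 60)], n_donors=4)
        cohort = generate_cohort(cfg, tmp_path / "c")
        panel = cohort.panel
        sa = panel.site_alts
        gene_sites = panel.gene_mask("GY")[sa["site"]]
        prot = sa[gene_sites & sa["consequence"].isin(["missense", "nonsense"])]
        picks = prot.dropna(subset=["protein_pos"]).groupby("protein_pos").head(1)
        muts = pd.DataFrame({
            "gene": "GY", "consequence": "missense",
            "protein_pos": picks["protein_pos"].astype(int),
            "sample_id": "s1",
        })
        tally = catalog_io.residue_mutation_tally(muts, "GY", panel)
        assert tally.percent_mutated == pytest.approx(100.0)

    def test_empty_catalog_gives_zero(self, default_cohort):
        empty = default_cohort.mutations.iloc[0:0]
        tally = catalog_io.residue_mutation_tally(empty, "TP53",
                                                  default_cohort.panel)
        assert tally.percent_mutated == 0.0
        assert tally.n_covered == 394


def test_covariates_scaling(tmp_path):
    cov = pd.DataFrame({
        "donor_id": ["d1", "d1", "d2"], "sample_id": ["s1", "s2", "s3"],
        "location": ["dome", "trigone", "dome"],
        "age": [62, 62, 80], "sex": ["M", "M", "F"],
        "smoking": ["ever", "ever", "never"], "alcohol": [1, 1, 0],
        "bmi": [22.0, 22.0, 30.0], "chemo": [0, 0, 1],
    })
    path = tmp_path / "cov.tsv"
    cov.to_csv(path, sep="\t", index=False)
    out = catalog_io.load_covariates(path)
    assert out["age_decades"].tolist() == [6.2, 6.2, 8.0]
    assert out["bmi_scaled"].min() == 0.0 and out["bmi_scaled"].max() == 1.0
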