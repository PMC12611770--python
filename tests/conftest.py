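import pandas as pd
import pytest

from selscope import catalog_io, omega
from selscope.synthetic_data import GeneSpec, SyntheticCohortConfig, generate_cohort


def build_panel(tmp_path, seqs: dict, regions, depth=None):
    """Write FASTA+BED for handcrafted sequences and load the panel."""
    tmp_path.mkdir(parents=True, exist_ok=True)
    fasta = tmp_path / "ref.fa"
    with open(fasta, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    bed = tmp_path / "panel.bed"
    catalog_io.write_bed(regions, bed)
    panel = catalog_io.load_panel(bed, fasta)
    if depth is not None:
        panel.attach_depth(depth)
    return panel


def uniform_depth(panel_sites: pd.DataFrame, samples: dict) -> pd.DataFrame:
    """Depth table (1-based positions handled internally) at constant depth."""
    out = panel_sites[["chrom", "pos"]].copy()
    for name, d in samples.items():
        out[name] = d
    return out


@pytest.fixture(scope="session")
def default_cohort(tmp_path_factory):
    """One default synthetic cohort (45 donors / 79 samples, full gene set)."""
    outdir = tmp_path_factory.mktemp("default_cohort")
    return generate_cohort(SyntheticCohortConfig(seed=7), outdir)


@pytest.fixture(scope="session")
def default_spectrum(default_cohort):
    return omega.fit_cohort_spectrum(
        default_cohort.mutations, default_cohort.panel,
        whitelist=default_cohort.whitelist)


def neutral_config(seed, n_genes=2, n_codons=420, n_donors=45,
                   rate_per_year=1.0e-7, **kwargs) -> SyntheticCohortConfig:
    """Cohort with no selection anywhere (promoter hotspots off)."""
    genes = [GeneSpec(f"G{i + 1}", n_codons) for i in range(n_genes)]
    return SyntheticCohortConfig(
        seed=seed, genes=genes, covariate_effects={},
        ptert_multiplier=1.0, ptert_age_smoking_beta=0.0,
        rate_per_year=rate_per_year, n_donors=n_donors, **kwargs)


@pytest.fixture(scope="session")
def neutral_cohort(tmp_path_factory):
    outdir = tmp_path_factory.mktemp("neutral_cohort")
    return generate_cohort(neutral_config(seed=101, rate_per_year=1.7e-7), outdir)
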