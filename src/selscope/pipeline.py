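"""End-to-end orchestration: simulate/annotate → selection → reports.

A single :class:`RunConfig` drives all stages; every output TSV is listed
with its SHA-256 hash in a run manifest, so a re-run with the same seed
yields identical hashes.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, associate, catalog_io, clonefrac, omega, saturation
from .siteselect import score_units, site_expected
from .synthetic_data import SyntheticCohortConfig, generate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    outdir: str = "selscope_run"
    seed: int = 0
    # input paths (filled by the simulate stage if absent)
    panel_bed: str | None = None
    reference_fasta: str | None = None
    depth_tsv: str | None = None
    mutations_tsv: str | None = None
    covariates_tsv: str | None = None
    whitelist_tsv: str | None = None
    # thresholds
    fdr: float = associate.FDR_THRESHOLD
    eligibility: float = omega.ELIGIBILITY_FRACTION
    splice_window: int = catalog_io.SPLICE_WINDOW
    pseudocount: float = 0.5
    neutral_classes: tuple = ("synonymous", "noncoding")
    saturation_reps: int = 20
    stages: tuple = ("simulate", "annotate", "omega", "sites", "saturation",
                     "clonefrac", "associate")
    simulate: dict = field(default_factory=dict)  # SyntheticCohortConfig overrides

    def validate(self) -> None:
        if not 0 < self.eligibility <= 1 or not 0 < self.fdr < 1:
            raise ValueError("thresholds out of range")
        for key in ("panel_bed", "reference_fasta", "depth_tsv",
                    "mutations_tsv", "covariates_tsv"):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key}: {path}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all configured stages; returns the manifest dictionary."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"version": __version__, "seed": cfg.seed, "stages": {},
                "outputs": {}, "parameters": {
                    "fdr": cfg.fdr, "eligibility": cfg.eligibility,
                    "splice_window": cfg.splice_window,
                    "pseudocount": cfg.pseudocount,
                }}

    def _stage(name):
        return name in cfg.stages

    t0 = time.time()
    if _stage("simulate") and cfg.mutations_tsv is None:
        sim_cfg = SyntheticCohortConfig(seed=cfg.seed, **cfg.simulate)
        cohort = generate_cohort(sim_cfg, out / "synthetic")
        cfg.panel_bed = str(cohort.paths["bed"])
        cfg.reference_fasta = str(cohort.paths["fasta"])
        cfg.depth_tsv = str(cohort.paths["depth"])
        cfg.mutations_tsv = str(cohort.paths["mutations"])
        cfg.covariates_tsv = str(cohort.paths["covariates"])
        cfg.whitelist_tsv = str(cohort.paths["whitelist"])
        manifest["stages"]["simulate"] = {"seconds": round(time.time() - t0, 2)}

    t0 = time.time()
    panel = catalog_io.load_panel(cfg.panel_bed, cfg.reference_fasta,
                                  splice_window=cfg.splice_window)
    panel.attach_depth(catalog_io.load_depth(cfg.depth_tsv))
    mutations = catalog_io.load_mutations(cfg.mutations_tsv, panel,
                                          samples=panel.samples)
    covariates = catalog_io.load_covariates(cfg.covariates_tsv)
    whitelist = (omega.load_whitelist(cfg.whitelist_tsv)
                 if cfg.whitelist_tsv else None)
    manifest["stages"]["annotate"] = {
        "seconds": round(time.time() - t0, 2),
        "n_sites": len(panel.sites), "n_mutations": len(mutations),
        "n_rejected": mutations.attrs.get("n_rejected", 0),
    }
    spectrum = omega.fit_cohort_spectrum(
        mutations, panel, whitelist=whitelist, pseudocount=cfg.pseudocount,
        neutral_classes=tuple(cfg.neutral_classes))
    spectrum.to_tsv(out / "spectrum.tsv")
    manifest["outputs"]["spectrum.tsv"] = None

    coding_genes = sorted(
        panel.sites.loc[panel.sites["region_class"] == "coding", "gene"].unique())
    promoter_gene = next(iter(
        panel.sites.loc[panel.sites["region_class"] == "promoter", "gene"].unique()),
        None)

    if _stage("omega"):
        t0 = time.time()
        table = omega.cohort_selection_table(
            coding_genes, mutations, panel, spectrum, whitelist=whitelist,
            tert_gene=promoter_gene or "TERT")
        table.to_csv(out / "selection_cohort.tsv", sep="\t", index=False)
        per_sample = omega.per_sample_matrix(
            coding_genes, ["missense", "truncating"], mutations, panel,
            spectrum, eligibility=cfg.eligibility)
        per_sample.to_csv(out / "selection_per_sample.tsv", sep="\t", index=False)
        manifest["outputs"]["selection_cohort.tsv"] = None
        manifest["outputs"]["selection_per_sample.tsv"] = None
        manifest["stages"]["omega"] = {"seconds": round(time.time() - t0, 2)}

    if _stage("sites"):
        t0 = time.time()
        frames = []
        for gene in coding_genes:
            se = site_expected(gene, spectrum, panel)
            for unit in ("snv", "residue"):
                scores = score_units(gene, mutations, se, unit=unit)
                tab = scores.table.assign(gene=gene, unit=unit)
                frames.append(tab)
        pd.concat(frames).to_csv(out / "site_selection.tsv", sep="\t", index=False)
        manifest["outputs"]["site_selection.tsv"] = None
        manifest["stages"]["sites"] = {"seconds": round(time.time() - t0, 2)}

    if _stage("saturation"):
        t0 = time.time()
        frames = []
        for gene in coding_genes:
            depth_total = panel.depth_vector("cohort")
            d_full = float(depth_total[panel.gene_mask(gene)].mean())
            grid = saturation.default_depth_grid(d_full)
            theo = saturation.theoretical_kinetic(gene, spectrum, panel, grid)
            obs = saturation.observed_kinetic(
                gene, mutations, panel, grid, n_reps=cfg.saturation_reps,
                seed=cfg.seed)
            tab = theo.to_frame()
            tab["observed_mean"] = obs.observed_mean
            tab["observed_sd"] = obs.observed_sd
            tab["gene"] = gene
            frames.append(tab)
        pd.concat(frames).to_csv(out / "saturation.tsv", sep="\t", index=False)
        manifest["outputs"]["saturation.tsv"] = None
        manifest["stages"]["saturation"] = {"seconds": round(time.time() - t0, 2)}

    if _stage("clonefrac"):
        t0 = time.time()
        rows = []
        for sample in panel.samples:
            for gene in coding_genes:
                exp = omega.expected_counts(gene, spectrum, panel, scope=sample)
                mis = omega.dnds(gene, "missense", mutations, exp, scope=sample)
                tru = omega.dnds(gene, "truncating", mutations, exp, scope=sample)
                res = clonefrac.clone_fraction(gene, sample, mutations, mis, tru)
                rows.append(res.to_dict())
        pd.DataFrame(rows).to_csv(out / "clone_fractions.tsv", sep="\t",
                                  index=False)
        manifest["outputs"]["clone_fractions.tsv"] = None
        manifest["stages"]["clonefrac"] = {"seconds": round(time.time() - t0, 2)}

    if _stage("associate") and _stage("omega"):
        t0 = time.time()
        per_sample = pd.read_csv(out / "selection_per_sample.tsv", sep="\t")
        responses = associate.dnds_response_matrix(per_sample)
        dens = associate.density_responses(mutations, panel, whitelist=whitelist)
        responses = responses.join(dens, how="outer")
        inter = tuple(c for c in responses.columns if "activating_pTERT" in c)
        results = associate.run_models(
            responses, covariates, fdr=cfg.fdr, interaction_responses=inter)
        results.to_csv(out / "associations.tsv", sep="\t", index=False)
        manifest["outputs"]["associations.tsv"] = None
        manifest["stages"]["associate"] = {"seconds": round(time.time() - t0, 2)}

    for name in list(manifest["outputs"]):
        manifest["outputs"][name] = _sha256(out / name)
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
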