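"""Synthetic duplex-sequencing cohorts with known selection coefficients.

The generator emulates the structure of an ultradeep duplex-sequencing
study of polyclonal normal tissue: tens of donors contributing one or two
bladder samples each, a capture panel of tumour-suppressor-like genes plus
a promoter block, per-sample median depth in the thousands of haploid
genomes, a trinucleotide spectrum mixing ageing-like (CpG C>T), APOBEC-like
(TpC) and flat components with age-dependent ageing load, gene-specific
selection multipliers (ω) on missense/truncating/frameshift classes,
covariate-dependent selection, promoter-hotspot activation with an
age×smoking interaction, and clone-size (VAF) draws from a truncated
power law.  Every injected parameter is recorded in a truth file, so each
downstream inference stage has a recoverable ground truth.

Neutral mutation counts per (site, alt, sample) are Poisson with mean
rate × depth; selected classes are inflated by ω times the covariate
multipliers.  The generator carries its own codon table and consequence
logic, independent of the annotation code it is used to validate.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import catalog_io
from .catalog_io import Panel, PanelRegion
from .context import COMPLEMENT, CHANNELS, N_CHANNELS, channel_index, revcomp

# standard genetic code, written out so the generator's consequence calls
# do not share a translation path with the annotator it validates
_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
_AAS = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
CODON_TABLE = dict(zip(_CODONS, _AAS))
NONSTOP_CODONS = [c for c in _CODONS if CODON_TABLE[c] != "*"]
STOP_CODONS = [c for c in _CODONS if CODON_TABLE[c] == "*"]


@dataclass
class GeneSpec:
    """One synthetic gene: artificial two-exon CDS with selection multipliers."""

    name: str
    n_codons: int = 420
    strand: str = "+"
    omega_missense: float = 1.0
    omega_truncating: float = 1.0
    omega_indel: float = 1.0


def _default_genes() -> list[GeneSpec]:
    # selection structure loosely mirroring a normal-urothelium driver panel:
    # strong truncating selection on several tumour suppressors, moderate
    # missense selection on TP53-like genes, negative selection on FGFR3
    return [
        GeneSpec("TP53", 394, "+", omega_missense=3.5, omega_truncating=8.0,
                 omega_indel=6.0),
        GeneSpec("RBM10", 420, "-", omega_truncating=12.0, omega_indel=8.0),
        GeneSpec("KDM6A", 450, "+", omega_truncating=6.0, omega_indel=5.0),
        GeneSpec("ARID1A", 450, "+", omega_truncating=5.0, omega_indel=4.0),
        GeneSpec("CDKN1A", 164, "+", omega_truncating=10.0, omega_indel=6.0),
        GeneSpec("STAG2", 420, "-", omega_truncating=8.0, omega_indel=5.0),
        GeneSpec("FGFR3", 300, "+", omega_truncating=0.1, omega_indel=0.2),
        GeneSpec("EP300", 450, "+", omega_missense=2.0),
        GeneSpec("NOTCH2", 400, "+", omega_truncating=4.0),
        GeneSpec("FOXQ1", 200, "+", omega_missense=2.0),
    ]


@dataclass
class SyntheticCohortConfig:
    """Full generative parameterisation of a synthetic cohort."""

    seed: int = 0
    n_donors: int = 45
    paired_fraction: float = 34 / 45
    genes: list[GeneSpec] = field(default_factory=_default_genes)
    flank_bp: int = 10
    intron_bp: int = 30
    promoter_bp: int = 500
    promoter_gene: str = "TERT"
    n_whitelist: int = 20
    # depth model: per-sample mean LogNormal with the study's median, site-
    # level multiplicative gamma jitter shared across samples (probe effect)
    depth_median: float = 5164.0
    depth_sigma: float = 0.35
    site_depth_shape: float = 25.0
    # mutation burden grows linearly with age; units: mutations per site
    # (summed over its three alternates) per haploid genome per year
    rate_per_year: float = 2.2e-8
    # spectrum mixture: (APOBEC-like, ageing-like, flat); the ageing-like
    # loading is additionally proportional to donor age
    mix_apobec: float = 0.35
    mix_ageing: float = 0.45
    mix_flat: float = 0.20
    ageing_age_ref: float = 65.0
    # covariate effects: (gene, mclass) -> {binary term -> multiplier on ω}
    covariate_effects: dict = field(default_factory=lambda: {
        ("RBM10", "truncating"): {"sexM": 1.65},
        ("CDKN1A", "truncating"): {"sexM": 1.65},
        ("ARID1A", "truncating"): {"sexM": 1.65},
    })
    # promoter hotspot activation and its age×smoking dependence
    ptert_multiplier: float = 15.0
    ptert_age_smoking_beta: float = 0.25
    # clone-size law: Pareto tail truncated to [1/depth, vaf_max]
    clone_alpha: float = 1.0
    vaf_max: float = 0.25
    vaf_all_molecules_sd: float = 0.05
    # indels per coding site-genome, as a fraction of the SNV rate
    indel_fraction: float = 0.05
    frameshift_fraction: float = 0.7

    def validate(self) -> None:
        if any(
            min(g.omega_missense, g.omega_truncating, g.omega_indel) <= 0
            for g in self.genes
        ):
            raise ValueError("selection multipliers must be positive")
        if self.n_whitelist > 3 * self.promoter_bp:
            raise ValueError("whitelist larger than the promoter allows")
        weights = (self.mix_apobec, self.mix_ageing, self.mix_flat)
        if abs(sum(weights) - 1.0) > 1e-9:
            raise ValueError("spectrum mixture weights must sum to 1")
        if not 0 <= self.paired_fraction <= 1:
            raise ValueError("paired_fraction must lie in [0, 1]")

    # -- YAML round trip -------------------------------------------------
    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["genes"] = [dataclasses.asdict(g) for g in self.genes]
        d["covariate_effects"] = {
            f"{g}:{m}": eff for (g, m), eff in self.covariate_effects.items()
        }
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SyntheticCohortConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["genes"] = [GeneSpec(**g) for g in d.get("genes", [])]
        d["covariate_effects"] = {
            tuple(k.split(":")): v for k, v in d.get("covariate_effects", {}).items()
        }
        return cls(**d)


# ---------------------------------------------------------------------------
# spectrum profiles


def _profile(entries: dict[tuple[str, str], float], floor: float) -> np.ndarray:
    p = np.full(N_CHANNELS, floor)
    for i, ch in enumerate(CHANNELS):
        if ch in entries:
            p[i] += entries[ch]
    return p / p.sum()


def signature_profiles() -> np.ndarray:
    """(3, 96) channel probabilities: APOBEC-like, ageing-like, flat."""
    apobec = _profile(
        {(f"T{c}{t}", a): 1.0 for c in "C" for t in "AT" for a in "GT"}, 0.02)
    ageing = _profile(
        {(f"{f}CG", "T"): 1.0 for f in "ACGT"}, 0.03)
    flat = np.full(N_CHANNELS, 1.0 / N_CHANNELS)
    return np.vstack([apobec, ageing, flat])


# ---------------------------------------------------------------------------
# gene construction


def _random_cds(rng: np.random.Generator, n_codons: int) -> str:
    body = rng.choice(NONSTOP_CODONS, size=n_codons - 2)
    stop = rng.choice(STOP_CODONS)
    return "ATG" + "".join(body) + stop


#: bases of sequence kept outside the panel at each contig end, so every
#: panel site has a defined trinucleotide context
CONTIG_PAD = 5


def _gene_layout(rng: np.random.Generator, spec: GeneSpec, cfg: SyntheticCohortConfig):
    """Sequence, regions and generator-side consequences for one gene.

    Layout (genomic): pad | flank | exon | intron | exon | flank | pad,
    with the CDS split at an arbitrary base so codons can span the
    junction.  The pad lies outside the panel.
    """
    L = 3 * spec.n_codons
    cds = _random_cds(rng, spec.n_codons)
    split = L // 2
    off = CONTIG_PAD
    flank, intron_len = cfg.flank_bp, cfg.intron_bp
    intron = "".join(rng.choice(list("ACGT"), size=intron_len))
    f5 = "".join(rng.choice(list("ACGT"), size=flank + off))
    f3 = "".join(rng.choice(list("ACGT"), size=flank + off))
    e1, e2 = cds[:split], cds[split:]
    a = off + flank  # genomic position of the first coding base block

    if spec.strand == "+":
        seq = f5 + e1 + intron + e2 + f3
        coding1 = (a, a + split, 0)
        coding2 = (a + split + intron_len, a + L + intron_len, split % 3)
        cds_to_genomic = {
            i: (a + i if i < split else a + split + intron_len + (i - split))
            for i in range(L)
        }
        intron_span = (a + split, a + split + intron_len)
    else:
        seq = f5 + revcomp(e2) + revcomp(intron) + revcomp(e1) + f3
        n2 = L - split
        coding1 = (a, a + n2, split % 3)                      # exon 2 on genome left
        coding2 = (a + n2 + intron_len, a + L + intron_len, 0)
        cds_to_genomic = {}
        for i in range(L):
            if i < split:  # exon 1: genomic right block, reversed
                cds_to_genomic[i] = a + n2 + intron_len + (split - 1 - i)
            else:          # exon 2: genomic left block, reversed
                cds_to_genomic[i] = a + (L - 1 - i)
        intron_span = (a + n2, a + n2 + intron_len)

    regions = [
        PanelRegion(spec.name, off, a, spec.name, "intronic_flank", spec.strand),
        PanelRegion(spec.name, coding1[0], coding1[1], spec.name, "coding",
                    spec.strand, coding1[2]),
        PanelRegion(spec.name, intron_span[0], intron_span[1], spec.name,
                    "intronic_flank", spec.strand),
        PanelRegion(spec.name, coding2[0], coding2[1], spec.name, "coding",
                    spec.strand, coding2[2]),
        PanelRegion(spec.name, a + L + intron_len, a + L + intron_len + flank,
                    spec.name, "intronic_flank", spec.strand),
    ]

    # generator-side consequences for every (genomic pos, genomic alt)
    cons: dict[tuple[int, str], str] = {}
    splice = {intron_span[0], intron_span[0] + 1, intron_span[1] - 2,
              intron_span[1] - 1}
    for r in regions:
        for pos in range(r.start, r.end):
            for alt in "ACGT":
                if alt == seq[pos]:
                    continue
                if r.region_class != "coding":
                    cons[(pos, alt)] = ("essential_splice" if pos in splice
                                        else "noncoding")
    for i in range(L):
        pos = cds_to_genomic[i]
        codon_i, off = divmod(i, 3)
        codon = cds[3 * codon_i: 3 * codon_i + 3]
        aa_ref = CODON_TABLE[codon]
        for alt_coding in "ACGT":
            if alt_coding == cds[i]:
                continue
            mutant = codon[:off] + alt_coding + codon[off + 1:]
            aa_alt = CODON_TABLE[mutant]
            if aa_alt == aa_ref:
                c = "synonymous"
            elif aa_alt == "*":
                c = "nonsense"
            else:
                c = "missense"
            alt_genomic = alt_coding if spec.strand == "+" else COMPLEMENT[alt_coding]
            cons[(pos, alt_genomic)] = c
    return seq, regions, cons


def _promoter_layout(rng: np.random.Generator, cfg: SyntheticCohortConfig):
    pad = 10
    seq = "".join(rng.choice(list("ACGT"), size=cfg.promoter_bp + 2 * pad))
    region = PanelRegion(cfg.promoter_gene, pad, pad + cfg.promoter_bp,
                         cfg.promoter_gene, "promoter", "+")
    cons = {
        (pos, alt): "noncoding"
        for pos in range(pad, pad + cfg.promoter_bp)
        for alt in "ACGT" if alt != seq[pos]
    }
    # tumour-recurrent hotspot positions: distinct positions, one alt each
    positions = rng.choice(
        np.arange(pad, pad + cfg.promoter_bp), size=cfg.n_whitelist, replace=False)
    whitelist = set()
    for pos in sorted(positions):
        alts = [b for b in "ACGT" if b != seq[pos]]
        whitelist.add((cfg.promoter_gene, int(pos), str(rng.choice(alts))))
    return seq, region, cons, whitelist


# ---------------------------------------------------------------------------
# cohort assembly


@dataclass
class SimulatedCohort:
    """A generated cohort, re-loaded through the standard readers."""

    config: SyntheticCohortConfig
    panel: Panel                  # annotated by catalog_io, depth attached
    mutations: pd.DataFrame       # annotated by catalog_io
    covariates: pd.DataFrame
    whitelist: set
    generator_consequences: pd.DataFrame  # chrom, pos, alt, consequence (generator side)
    paths: dict
    expected_snv_per_sample: pd.Series | None = None  # configured Σ rate×depth×ω
    truth_drivers: pd.DataFrame | None = None  # per-record injected driver flags


def _draw_covariates(rng: np.random.Generator, cfg: SyntheticCohortConfig) -> pd.DataFrame:
    n = cfg.n_donors
    ages = rng.integers(35, 91, size=n)
    sexes = rng.choice(["M", "F"], size=n)
    smoking = rng.choice(["ever", "never"], size=n, p=[0.55, 0.45])
    if n >= 10:
        smoking[rng.integers(0, n)] = "unknown"  # one donor of unknown history
    alcohol = rng.integers(0, 2, size=n)
    bmi = np.round(rng.normal(27, 4, size=n), 1)
    chemo = (rng.random(size=n) < 0.2).astype(int)
    n_paired = int(round(cfg.paired_fraction * n))
    paired = np.zeros(n, dtype=bool)
    paired[rng.choice(n, size=n_paired, replace=False)] = True

    rows = []
    for d in range(n):
        donor = f"D{d + 1:03d}"
        locations = ["dome", "trigone"] if paired[d] else ["dome"]
        for loc in locations:
            rows.append({
                "donor_id": donor, "sample_id": f"{donor}_{loc}", "location": loc,
                "age": int(ages[d]), "sex": sexes[d], "smoking": smoking[d],
                "alcohol": int(alcohol[d]), "bmi": float(bmi[d]),
                "chemo": int(chemo[d]),
            })
    return pd.DataFrame(rows)


def _truncated_pareto(rng, n, alpha, xm, vmax):
    """Inverse-CDF draws from a Pareto(alpha) tail truncated to [xm, vmax]."""
    xm = np.minimum(xm, vmax * 0.999)
    u = rng.random(n)
    tail = 1.0 - (xm / vmax) ** alpha
    return xm * (1.0 - u * tail) ** (-1.0 / alpha)


def generate_cohort(cfg: SyntheticCohortConfig, outdir) -> SimulatedCohort:
    """Generate a cohort, write its files, and reload through catalog_io.

    Outputs under ``outdir``: panel.bed, reference.fa, depth.tsv,
    mutations.tsv, covariates.tsv, whitelist.tsv, truth.yaml.  Generation
    is bit-reproducible for a fixed config (seed included).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    # ---- panel, reference, generator-side annotation
    seqs, regions, gen_cons_rows = {}, [], []
    gene_of, class_of, channel_of, pos_of, chrom_of, ref_of, alt_of = \
        [], [], [], [], [], [], []
    region_class_rows = []
    for spec in cfg.genes:
        seq, gregs, cons = _gene_layout(rng, spec, cfg)
        seqs[spec.name] = seq
        regions.extend(gregs)
        for r in sorted(gregs, key=lambda x: x.start):
            for pos in range(r.start, r.end):
                tri = seq[pos - 1: pos + 2]
                for alt in "ACGT":
                    if alt == seq[pos]:
                        continue
                    gene_of.append(spec.name)
                    class_of.append(cons[(pos, alt)])
                    channel_of.append(channel_index(tri, alt))
                    chrom_of.append(spec.name)
                    pos_of.append(pos)
                    ref_of.append(seq[pos])
                    alt_of.append(alt)
                    region_class_rows.append(r.region_class)
    pseq, pregion, pcons, whitelist = _promoter_layout(rng, cfg)
    seqs[cfg.promoter_gene] = pseq
    regions.append(pregion)
    for pos in range(pregion.start, pregion.end):
        tri = pseq[pos - 1: pos + 2]
        for alt in "ACGT":
            if alt == pseq[pos]:
                continue
            gene_of.append(cfg.promoter_gene)
            class_of.append(pcons[(pos, alt)])
            channel_of.append(channel_index(tri, alt))
            chrom_of.append(cfg.promoter_gene)
            pos_of.append(pos)
            ref_of.append(pseq[pos])
            alt_of.append(alt)
            region_class_rows.append("promoter")

    gen = pd.DataFrame({
        "chrom": chrom_of, "pos": pos_of, "ref": ref_of, "alt": alt_of,
        "gene": gene_of, "consequence": class_of,
        "channel": np.asarray(channel_of), "region_class": region_class_rows,
    })
    # site table (one row per base) in generator order
    site_key = gen[["chrom", "pos"]].drop_duplicates().reset_index(drop=True)
    site_idx_of_alt = site_key.reset_index().merge(
        gen[["chrom", "pos"]], on=["chrom", "pos"], how="right")["index"].to_numpy()
    n_sites = len(site_key)

    # ---- covariates and samples
    cov = _draw_covariates(rng, cfg)
    samples = cov["sample_id"].tolist()
    n_samp = len(samples)
    age_dec = (cov["age"] / 10.0).to_numpy()
    is_male = (cov["sex"] == "M").to_numpy(float)
    is_smoker = (cov["smoking"] == "ever").to_numpy(float)
    indicators = {
        "sexM": is_male,
        "smoking_ever": is_smoker,
        "alcohol": cov["alcohol"].to_numpy(float),
        "chemo": cov["chemo"].to_numpy(float),
    }

    # ---- depth: sample mean (lognormal, median = depth_median) × site jitter
    mean_s = rng.lognormal(np.log(cfg.depth_median), cfg.depth_sigma, size=n_samp)
    k = cfg.site_depth_shape
    site_jitter = rng.gamma(k, 1.0 / k, size=n_sites)
    depth = np.maximum(1, np.round(site_jitter[:, None] * mean_s[None, :]))

    # ---- neutral rates per (site-alt, sample)
    profiles = signature_profiles()
    w_age = cfg.mix_ageing * (cov["age"].to_numpy() / cfg.ageing_age_ref)
    w = np.vstack([np.full(n_samp, cfg.mix_apobec), w_age,
                   np.full(n_samp, cfg.mix_flat)])
    w = w / w.sum(axis=0, keepdims=True)
    p_s = w.T @ profiles                                     # (n_samp, 96)
    total_rate_s = cfg.rate_per_year * cov["age"].to_numpy()  # per site per genome
    chan = gen["channel"].to_numpy()
    p_alt = p_s[:, chan]                                      # (n_samp, n_sitealts)
    norm = p_alt.sum(axis=1) / n_sites                        # mean per-site mass
    rate = (total_rate_s / norm)[:, None] * p_alt             # per sitealt-genome

    # ---- selection multipliers
    omega = np.ones(len(gen))
    for spec in cfg.genes:
        gmask = (gen["gene"] == spec.name).to_numpy()
        cons = gen["consequence"].to_numpy()
        omega[gmask & (cons == "missense")] = spec.omega_missense
        omega[gmask & np.isin(cons, ("nonsense", "essential_splice"))] = \
            spec.omega_truncating
    mult = np.repeat(omega[None, :], n_samp, axis=0)
    for (gene_name, mclass), effects in cfg.covariate_effects.items():
        members = {"missense": ("missense",),
                   "truncating": ("nonsense", "essential_splice")}[mclass]
        mask = ((gen["gene"] == gene_name)
                & gen["consequence"].isin(members)).to_numpy()
        for term, k_eff in effects.items():
            on = indicators[term] > 0
            mult[np.ix_(on, np.flatnonzero(mask))] *= float(k_eff)
    wl_mask = np.array([
        (c, p, a) in whitelist
        for c, p, a in zip(gen["chrom"], gen["pos"], gen["alt"])
    ])
    act = cfg.ptert_multiplier * np.exp(
        cfg.ptert_age_smoking_beta * age_dec * is_smoker)
    mult[:, wl_mask] *= act[:, None]

    # ---- SNV draws
    lam = rate * depth[site_idx_of_alt, :].T * mult           # (n_samp, n_sitealts)
    counts = rng.poisson(lam)
    s_idx, a_idx = np.nonzero(counts)
    d_rec = depth[site_idx_of_alt[a_idx], s_idx]
    # clone sizes: a mutation in a class under positive selection (total
    # multiplier m) is an expanded driver clone with probability (m-1)/m
    # and gets a power-law VAF; passengers sit in single (or few) duplex
    # molecules, the regime duplex sequencing of normal tissue reports
    mult_rec = mult[s_idx, a_idx]
    p_driver = np.clip((mult_rec - 1.0) / np.maximum(mult_rec, 1e-12), 0.0, 1.0)
    is_driver = rng.random(len(s_idx)) < p_driver
    clone_vaf = _truncated_pareto(rng, len(s_idx), cfg.clone_alpha, 2.0 / d_rec,
                                  cfg.vaf_max)
    singleton_vaf = np.minimum(counts[s_idx, a_idx], d_rec) / d_rec
    vaf = np.where(is_driver, clone_vaf, singleton_vaf)
    vaf_all = np.clip(
        vaf * np.exp(rng.normal(0, cfg.vaf_all_molecules_sd, size=len(s_idx))),
        1e-9, 1.0)
    records = pd.DataFrame({
        "sample_id": [samples[i] for i in s_idx],
        "donor_id": [cov["donor_id"].iat[i] for i in s_idx],
        "chrom": gen["chrom"].to_numpy()[a_idx],
        "pos": gen["pos"].to_numpy()[a_idx],
        "ref": gen["ref"].to_numpy()[a_idx],
        "alt": gen["alt"].to_numpy()[a_idx],
        "vaf_duplex": np.round(vaf, 8),
        "vaf_all_molecules": np.round(vaf_all, 8),
        "is_driver": is_driver,
    })

    # ---- indels (deletions anchored at a base; frameshift vs in-frame)
    indel_rows = []
    coding_mask_site = np.zeros(n_sites, dtype=bool)
    first_alt_of_site = np.unique(site_idx_of_alt, return_index=True)[1]
    coding_mask_site[np.unique(
        site_idx_of_alt[np.asarray(gen["region_class"] == "coding")])] = True
    omega_indel_site = np.ones(n_sites)
    gene_of_site = gen["gene"].to_numpy()[first_alt_of_site]
    for spec in cfg.genes:
        omega_indel_site[(gene_of_site == spec.name) & coding_mask_site] = \
            spec.omega_indel
    indel_rate_s = cfg.indel_fraction * total_rate_s
    for kind, frac, lengths in (
        ("frameshift", cfg.frameshift_fraction, (1, 2)),
        ("inframe", 1 - cfg.frameshift_fraction, (3,)),
    ):
        lam_i = (indel_rate_s[None, :] * frac * depth
                 * (omega_indel_site[:, None] if kind == "frameshift" else 1.0))
        lam_i = lam_i * coding_mask_site[:, None]
        cnt = rng.poisson(lam_i.T)                            # (n_samp, n_sites)
        si, pi = np.nonzero(cnt)
        for s, p in zip(si, pi):
            chrom = site_key["chrom"].iat[p]
            pos = int(site_key["pos"].iat[p])
            seq = seqs[chrom]
            ell = int(rng.choice(lengths))
            if pos + 1 + ell >= len(seq):
                continue
            d = depth[p, s]
            m = omega_indel_site[p] if kind == "frameshift" else 1.0
            driver = rng.random() < max(0.0, (m - 1.0) / m)
            if driver:
                v = float(_truncated_pareto(rng, 1, cfg.clone_alpha, 2.0 / d,
                                            cfg.vaf_max)[0])
            else:
                v = min(cnt[s, p], d) / d
            indel_rows.append({
                "sample_id": samples[s], "donor_id": cov["donor_id"].iat[s],
                "chrom": chrom, "pos": pos,
                "ref": seq[pos: pos + 1 + ell], "alt": seq[pos],
                "vaf_duplex": round(v, 8),
                "vaf_all_molecules": round(min(1.0, v), 8),
                "is_driver": driver,
            })
    if indel_rows:
        records = pd.concat([records, pd.DataFrame(indel_rows)], ignore_index=True)
    records = records.sort_values(
        ["sample_id", "chrom", "pos", "alt"]).reset_index(drop=True)

    # ---- write standard-format outputs
    paths = {
        "bed": outdir / "panel.bed", "fasta": outdir / "reference.fa",
        "depth": outdir / "depth.tsv", "mutations": outdir / "mutations.tsv",
        "covariates": outdir / "covariates.tsv",
        "whitelist": outdir / "whitelist.tsv", "truth": outdir / "truth.yaml",
        "truth_drivers": outdir / "truth_drivers.tsv",
    }
    catalog_io.write_bed(regions, paths["bed"])
    with open(paths["fasta"], "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")
    out_rec = records.drop(columns=["is_driver"]).copy()
    out_rec["pos"] = out_rec["pos"] + 1
    out_rec.to_csv(paths["mutations"], sep="\t", index=False)
    truth_rec = records[["sample_id", "chrom", "pos", "ref", "alt",
                         "vaf_duplex", "is_driver"]].copy()
    truth_rec["pos"] = truth_rec["pos"] + 1
    truth_rec.to_csv(paths["truth_drivers"], sep="\t", index=False)
    cov.to_csv(paths["covariates"], sep="\t", index=False)
    pd.DataFrame(
        sorted((c, p + 1, a) for c, p, a in whitelist),
        columns=["chrom", "pos", "alt"],
    ).to_csv(paths["whitelist"], sep="\t", index=False)
    cfg.to_yaml(paths["truth"])

    # ---- reload through the standard readers
    panel = catalog_io.load_panel(paths["bed"], paths["fasta"])
    depth_df = site_key.copy()
    depth_df["pos"] = depth_df["pos"] + 1
    for j, s in enumerate(samples):
        depth_df[s] = depth[:, j].astype(int)
    depth_df.to_csv(paths["depth"], sep="\t", index=False)
    panel.attach_depth(catalog_io.load_depth(paths["depth"]))
    mutations = catalog_io.load_mutations(paths["mutations"], panel,
                                          samples=samples)
    covariates = catalog_io.load_covariates(paths["covariates"])
    return SimulatedCohort(
        config=cfg, panel=panel, mutations=mutations, covariates=covariates,
        whitelist=whitelist,
        generator_consequences=gen[["chrom", "pos", "alt", "consequence"]],
        paths=paths,
        expected_snv_per_sample=pd.Series(lam.sum(axis=1), index=samples),
        truth_drivers=records[["sample_id", "chrom", "pos", "ref", "alt",
                               "vaf_duplex", "vaf_all_molecules", "is_driver"]],
    )
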