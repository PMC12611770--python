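"""Depth-aware dN/dS selection inference.

For a gene and a consequence class, the expected mutation count under
neutrality is the sum over every (site, alt) pair producing that class of
the neutral channel rate times the duplex depth at the site — so sequence
composition, the cohort's substitution spectrum and per-site sequencing
depth all enter the expectation.  Selection is then the ratio of observed
to expected counts (dN/dS), with exact Poisson confidence intervals and
two-sided Poisson p-values; the excess of observed over expected counts
estimates the number of driver mutations.

Promoter selection replaces the amino-acid consequence classes with a
dichotomy of tumour-recurrent ("activating") versus other promoter
substitutions; frameshift-indel enrichment compares a gene's indel rate
per depth-weighted coding base with the rest of the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .catalog_io import Panel
from .mutrate import TrinucSpectrum, fit_neutral_spectrum

log = logging.getLogger(__name__)

#: consequence classes aggregated into each tested mutation class
CLASS_CONSEQUENCES = {
    "missense": ("missense",),
    "truncating": ("nonsense", "essential_splice"),
    "synonymous": ("synonymous",),
    "nonsense": ("nonsense",),
    "essential_splice": ("essential_splice",),
}

ELIGIBILITY_FRACTION = 0.8  # per-sample results need >= 80% of samples


def poisson_ci(observed: int, alpha: float = 0.05) -> tuple[float, float]:
    """Exact (Garwood) confidence interval for a Poisson mean."""
    lo = 0.0 if observed == 0 else stats.chi2.ppf(alpha / 2, 2 * observed) / 2
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * observed + 2) / 2
    return lo, hi


def poisson_pvalue(observed: int, expected: float) -> float:
    """Two-sided exact Poisson p-value (doubled smaller tail, capped at 1)."""
    lower = stats.poisson.cdf(observed, expected)
    upper = stats.poisson.sf(observed - 1, expected)
    return float(min(1.0, 2 * min(lower, upper)))


@dataclass
class SelectionResult:
    """Observed/expected counts and dN/dS for one (gene, class, scope)."""

    gene: str
    mclass: str
    scope: str
    observed: int
    expected: float
    dnds: float
    ci_low: float
    ci_high: float
    p_value: float

    @property
    def driver_excess(self) -> float:
        """Estimated number of selection-driven mutations (floored at 0)."""
        return max(self.observed - self.expected, 0.0)

    @property
    def driver_fraction(self) -> float:
        """Fraction of observed mutations that are drivers."""
        return self.driver_excess / self.observed if self.observed > 0 else 0.0

    @property
    def driver_excess_ci(self) -> tuple[float, float]:
        """Driver excess at the CI endpoints of the observed count."""
        lo, hi = poisson_ci(self.observed)
        return max(lo - self.expected, 0.0), max(hi - self.expected, 0.0)

    def to_dict(self) -> dict:
        return {
            "gene": self.gene, "mclass": self.mclass, "scope": self.scope,
            "observed": self.observed, "expected": self.expected,
            "dnds": self.dnds, "ci_low": self.ci_low, "ci_high": self.ci_high,
            "p_value": self.p_value, "driver_excess": self.driver_excess,
            "driver_fraction": self.driver_fraction,
        }


def _make_result(gene, mclass, scope, observed, expected) -> SelectionResult | None:
    if expected <= 0:
        log.warning("E=0 for %s/%s/%s: result suppressed", gene, mclass, scope)
        return None
    lo, hi = poisson_ci(observed)
    return SelectionResult(
        gene=gene, mclass=mclass, scope=scope,
        observed=int(observed), expected=float(expected),
        dnds=observed / expected, ci_low=lo / expected, ci_high=hi / expected,
        p_value=poisson_pvalue(observed, expected),
    )


def expected_counts(
    gene: str,
    spectrum: TrinucSpectrum,
    panel: Panel,
    scope: str = "cohort",
    rate_scale: float = 1.0,
) -> dict[str, float]:
    """Neutral expected mutation counts per class for one gene.

    ``E[class] = Σ_{site,alt: consequence∈class} rate(channel) × depth(site)``,
    with ``truncating = nonsense + essential splice``.  The synonymous
    expectation is returned alongside for calibration checks.
    """
    if gene not in set(panel.sites["gene"]):
        raise ValueError(f"gene {gene!r} absent from panel")
    sa = panel.site_alts
    gmask = panel.gene_mask(gene)[sa["site"].to_numpy()]
    depth = panel.depth_vector(scope)
    site_e = spectrum.rate[sa["channel"].to_numpy()] * depth[sa["site"].to_numpy()]
    site_e = site_e * rate_scale
    out = {}
    cons = sa["consequence"].to_numpy()
    for mclass, members in CLASS_CONSEQUENCES.items():
        mask = gmask & np.isin(cons, members)
        out[mclass] = float(site_e[mask].sum())
    return out


def observed_count(
    gene: str, mclass: str, mutations: pd.DataFrame, scope: str = "cohort"
) -> int:
    """Observed substitution count for gene × class × scope (SNVs and MNVs)."""
    members = CLASS_CONSEQUENCES[mclass]
    sub = mutations[
        (mutations["gene"] == gene)
        & mutations["consequence"].isin(members)
        & mutations["mut_type"].isin(["SNV", "MNV"])
    ]
    if scope != "cohort":
        sub = sub[sub["sample_id"] == scope]
    return int(len(sub))


def dnds(
    gene: str,
    mclass: str,
    mutations: pd.DataFrame,
    expected: dict[str, float] | float,
    scope: str = "cohort",
) -> SelectionResult | None:
    """dN/dS for one gene × class with exact Poisson CI and p-value.

    Observed counts follow Poisson(E) under neutrality; the CI is the
    Garwood interval on the observed count divided by E.  Returns ``None``
    when E = 0 (ratio undefined).
    """
    e = expected[mclass] if isinstance(expected, dict) else float(expected)
    obs = observed_count(gene, mclass, mutations, scope)
    return _make_result(gene, mclass, scope, obs, e)


def dnds_ptert(
    mutations: pd.DataFrame,
    whitelist: set[tuple[str, int, str]],
    spectrum: TrinucSpectrum,
    panel: Panel,
    gene: str = "TERT",
    scope: str = "cohort",
) -> SelectionResult | None:
    """Selection on tumour-recurrent (activating) promoter substitutions.

    Promoter SNVs are dichotomised into activating (on the whitelist of
    positions recurrently mutated across tumour genomes) versus other; the
    spectrum-and-depth expectation over whitelist (site, alt) pairs is
    calibrated so that the non-activating sites reproduce their observed
    count, and selection is tested on the activating class only.
    """
    if not whitelist:
        raise ValueError("empty activating-mutation whitelist")
    sa = panel.site_alts
    sites = panel.sites
    promoter = (sites["region_class"] == "promoter") & (sites["gene"] == gene)
    prom_mask = promoter.to_numpy()[sa["site"].to_numpy()]
    key = list(zip(
        sites["chrom"].to_numpy()[sa["site"]], sites["pos"].to_numpy()[sa["site"]],
        sa["alt"],
    ))
    in_wl = np.array([k in whitelist for k in key])
    depth = panel.depth_vector(scope)
    site_e = spectrum.rate[sa["channel"].to_numpy()] * depth[sa["site"].to_numpy()]
    e_act_raw = float(site_e[prom_mask & in_wl].sum())
    e_other_raw = float(site_e[prom_mask & ~in_wl].sum())

    muts = mutations[
        (mutations["gene"] == gene) & (mutations["mut_type"] == "SNV")
    ]
    if scope != "cohort":
        muts = muts[muts["sample_id"] == scope]
    mut_act = np.array([
        (c, p, a) in whitelist
        for c, p, a in zip(muts["chrom"], muts["pos"], muts["alt"])
    ], dtype=bool)
    obs_act = int(mut_act.sum())
    obs_other = int((~mut_act).sum())

    # calibrate the neutral rate level on the non-activating promoter sites
    if e_other_raw > 0 and obs_other > 0:
        scale = obs_other / e_other_raw
    else:
        scale = 1.0
        log.warning("pTERT calibration impossible (no non-activating signal); "
                    "using uncalibrated spectrum rates")
    e_act = e_act_raw * scale
    return _make_result(gene, "activating_pTERT", scope, obs_act, e_act)


def indel_enrichment(
    gene: str,
    mutations: pd.DataFrame,
    panel: Panel,
    scope: str = "cohort",
) -> SelectionResult | None:
    """Frameshift-indel enrichment of one gene against the panel background.

    The background rate is frameshift indels per depth-weighted coding base
    over all *other* genes (leave-one-out, so a gene's own signal cannot
    dilute its test); the gene's expectation is that rate times its own
    depth-weighted coding length.
    """
    sites = panel.sites
    coding = (sites["region_class"] == "coding") & ~sites["excluded"]
    depth = panel.depth_vector(scope)
    in_gene = sites["gene"] == gene
    opp_gene = float(depth[(coding & in_gene).to_numpy()].sum())
    opp_bg = float(depth[(coding & ~in_gene).to_numpy()].sum())

    fs = mutations[mutations["consequence"] == "frameshift_indel"]
    if scope != "cohort":
        fs = fs[fs["sample_id"] == scope]
    obs_gene = int((fs["gene"] == gene).sum())
    obs_bg = int((fs["gene"] != gene).sum())
    if obs_bg == 0 or opp_bg == 0:
        log.warning("no background frameshift indels: %s enrichment suppressed", gene)
        return None
    expected = obs_bg / opp_bg * opp_gene
    return _make_result(gene, "frameshift_indel", scope, obs_gene, expected)


def per_sample_matrix(
    genes: list[str],
    mclasses: list[str],
    mutations: pd.DataFrame,
    panel: Panel,
    spectrum: TrinucSpectrum,
    eligibility: float = ELIGIBILITY_FRACTION,
    neutral_classes: tuple[str, ...] = ("synonymous", "noncoding"),
    calibrate_per_sample: bool = True,
) -> pd.DataFrame:
    """Per-sample dN/dS for each gene × class, with the sample-eligibility rule.

    Expected counts use each sample's own depth column.  With
    ``calibrate_per_sample`` the pooled channel rates are rescaled per
    sample so the sample's panel-wide neutral mutation count is reproduced
    exactly — per-sample dN/dS then measures selection, not mutation
    burden.  A (gene, class) combination is ``eligible`` iff its dN/dS is
    computable (E > 0, marked non-missing) for at least ``eligibility``
    (default 80%) of samples.
    """
    samples = panel.samples
    sa = panel.site_alts
    neutral_mask = sa["consequence"].isin(neutral_classes).to_numpy()
    rate_per_alt = spectrum.rate[sa["channel"].to_numpy()]
    site_of_alt = sa["site"].to_numpy()

    rows = []
    for sample in samples:
        depth = panel.depth_vector(sample)
        scale = 1.0
        if calibrate_per_sample:
            e_neutral = float((rate_per_alt * depth[site_of_alt])[neutral_mask].sum())
            obs_neutral = int(len(mutations[
                (mutations["sample_id"] == sample)
                & (mutations["mut_type"] == "SNV")
                & mutations["consequence"].isin(neutral_classes)
            ]))
            if e_neutral > 0 and obs_neutral > 0:
                scale = obs_neutral / e_neutral
        for gene in genes:
            exp = expected_counts(gene, spectrum, panel, scope=sample,
                                  rate_scale=scale)
            for mclass in mclasses:
                res = dnds(gene, mclass, mutations, exp, scope=sample)
                rows.append({
                    "gene": gene, "mclass": mclass, "sample_id": sample,
                    "observed": observed_count(gene, mclass, mutations, sample),
                    "expected": exp[mclass],
                    "dnds": res.dnds if res else np.nan,
                    "missing": res is None,
                })
    df = pd.DataFrame(rows)
    elig = (
        df.groupby(["gene", "mclass"])["missing"]
        .apply(lambda m: (~m).sum() >= eligibility * len(samples))
        .rename("eligible")
    )
    df = df.merge(elig.reset_index(), on=["gene", "mclass"])
    return df


def cohort_selection_table(
    genes: list[str],
    mutations: pd.DataFrame,
    panel: Panel,
    spectrum: TrinucSpectrum,
    whitelist: set | None = None,
    tert_gene: str = "TERT",
) -> pd.DataFrame:
    """Cohort-scope selection summary: dN/dS per gene × class, promoter
    activation test and frameshift-indel enrichment."""
    rows = []
    for gene in genes:
        exp = expected_counts(gene, spectrum, panel)
        for mclass in ("missense", "truncating"):
            res = dnds(gene, mclass, mutations, exp)
            if res is not None:
                rows.append(res.to_dict())
        res = indel_enrichment(gene, mutations, panel)
        if res is not None:
            rows.append(res.to_dict())
    if whitelist:
        res = dnds_ptert(mutations, whitelist, spectrum, panel, gene=tert_gene)
        if res is not None:
            rows.append(res.to_dict())
    return pd.DataFrame(rows)


def load_whitelist(path) -> set[tuple[str, int, str]]:
    """Read an activating-mutation whitelist TSV (chrom, pos 1-based, alt)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "alt": str})
    return {(c, int(p) - 1, a) for c, p, a in zip(df["chrom"], df["pos"], df["alt"])}


def fit_cohort_spectrum(mutations, panel, whitelist=None, **kwargs) -> TrinucSpectrum:
    """Convenience: pooled neutral spectrum excluding whitelist hotspots."""
    excl = {(c, p) for c, p, _ in whitelist} if whitelist else None
    return fit_neutral_spectrum(mutations, panel, exclude_positions=excl, **kwargs)
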