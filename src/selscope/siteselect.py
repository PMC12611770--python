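"""Selection scores for sites, residues, exons and protein domains.

A gene's class-level neutral expectation is distributed across all its
possible substitutions in proportion to channel rate × site depth; the
per-unit observed counts are then compared with their share of the
expectation (Poisson upper tail, BH-corrected within the gene).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .catalog_io import Panel
from .mutrate import TrinucSpectrum
from .omega import CLASS_CONSEQUENCES, expected_counts, poisson_ci

log = logging.getLogger(__name__)

#: stabiliser in the display score log2((obs+eps)/(exp+eps)); p-values use raw counts
SCORE_EPSILON = 0.5


def site_expected(
    gene: str,
    spectrum: TrinucSpectrum,
    panel: Panel,
    scope: str = "cohort",
    rate_scale: float = 1.0,
) -> pd.DataFrame:
    """Neutral expectation for every possible substitution of a gene.

    Within each consequence-class stratum the gene-level expectation is
    split across (site, alt) pairs proportionally to rate × depth, so the
    per-site expectations sum exactly to the gene's class expectation.
    """
    sa = panel.site_alts
    gmask = panel.gene_mask(gene)[sa["site"].to_numpy()]
    sub = sa[gmask].copy()
    depth = panel.depth_vector(scope)
    weight = spectrum.rate[sub["channel"].to_numpy()] * depth[sub["site"].to_numpy()]
    gene_e = expected_counts(gene, spectrum, panel, scope, rate_scale=rate_scale)

    expected = np.zeros(len(sub))
    cons = sub["consequence"].to_numpy()
    strata = {c: (members,) for c, members in CLASS_CONSEQUENCES.items()}
    for mclass in ("missense", "synonymous", "nonsense", "essential_splice"):
        members = CLASS_CONSEQUENCES[mclass]
        mask = np.isin(cons, members)
        total_w = weight[mask].sum()
        if total_w > 0:
            expected[mask] = gene_e[mclass] * weight[mask] / total_w
    nc_mask = cons == "noncoding"
    if nc_mask.any():
        w = weight[nc_mask]
        # noncoding stratum: rate × depth is the expectation itself
        expected[nc_mask] = w * rate_scale

    sub["expected"] = expected
    sub["chrom"] = panel.sites["chrom"].to_numpy()[sub["site"]]
    sub["pos"] = panel.sites["pos"].to_numpy()[sub["site"]]
    return sub.reset_index(drop=True)


@dataclass
class UnitScores:
    """Per-unit selection scores for one gene and class set."""

    gene: str
    unit: str
    table: pd.DataFrame  # unit_id, observed, expected, score, p_value, q_value
    n_suppressed: int    # units with zero expectation


def _observed_per_key(mutations: pd.DataFrame, gene: str, members,
                      scope: str) -> pd.DataFrame:
    sub = mutations[
        (mutations["gene"] == gene)
        & (mutations["mut_type"] == "SNV")
        & mutations["consequence"].isin(members)
    ]
    if scope != "cohort":
        sub = sub[sub["sample_id"] == scope]
    return sub


def score_units(
    gene: str,
    mutations: pd.DataFrame,
    site_exp: pd.DataFrame,
    unit: str = "snv",
    class_filter: tuple[str, ...] = ("missense", "nonsense"),
    intervals: pd.DataFrame | None = None,
    scope: str = "cohort",
    epsilon: float = SCORE_EPSILON,
) -> UnitScores:
    """Score selection per unit: single change, residue, exon or domain.

    ``score = log2((obs + ε)/(exp + ε))``; significance is the exact
    Poisson upper tail on the raw counts with BH correction across the
    gene's units.  For ``exon``/``domain``, ``intervals`` maps unit ids to
    1-based residue ranges (columns unit_id, start, end).
    """
    members = tuple(c for m in class_filter for c in CLASS_CONSEQUENCES.get(m, (m,)))
    exp_sub = site_exp[site_exp["consequence"].isin(members)].copy()
    obs_sub = _observed_per_key(mutations, gene, members, scope)

    if unit == "snv":
        exp_sub["unit_id"] = [
            f"{c}:{p + 1}>{a}"
            for c, p, a in zip(exp_sub["chrom"], exp_sub["pos"], exp_sub["alt"])
        ]
        expected = exp_sub.groupby("unit_id")["expected"].sum()
        obs_keys = [f"{c}:{p + 1}>{a}" for c, p, a in
                    zip(obs_sub["chrom"], obs_sub["pos"], obs_sub["alt"])]
        observed = pd.Series(obs_keys).value_counts()
    elif unit == "residue":
        exp_sub = exp_sub[exp_sub["protein_pos"].notna()]
        expected = exp_sub.groupby(exp_sub["protein_pos"].astype(int))["expected"].sum()
        obs_pp = obs_sub[obs_sub["protein_pos"].notna()]
        observed = obs_pp["protein_pos"].astype(int).value_counts()
    elif unit in ("exon", "domain"):
        if intervals is None:
            raise ValueError(f"{unit} scoring needs an interval table")
        exp_sub = exp_sub[exp_sub["protein_pos"].notna()]
        pp_e = exp_sub["protein_pos"].astype(int).to_numpy()
        obs_pp = obs_sub[obs_sub["protein_pos"].notna()]
        pp_o = obs_pp["protein_pos"].astype(int).to_numpy()
        expected, observed = {}, {}
        for row in intervals.itertuples():
            in_e = (pp_e >= row.start) & (pp_e <= row.end)
            expected[row.unit_id] = float(exp_sub["expected"].to_numpy()[in_e].sum())
            observed[row.unit_id] = int(((pp_o >= row.start) & (pp_o <= row.end)).sum())
        expected = pd.Series(expected)
        observed = pd.Series(observed)
    else:
        raise ValueError(f"unknown unit {unit!r}")

    tab = pd.DataFrame({"expected": expected}).fillna(0.0)
    tab["observed"] = observed.reindex(tab.index).fillna(0).astype(int)
    n_suppressed = int((tab["expected"] <= 0).sum())
    if n_suppressed:
        log.info("%d %s units with zero expectation suppressed", n_suppressed, unit)
    tab = tab[tab["expected"] > 0].copy()
    tab["score"] = np.log2((tab["observed"] + epsilon) / (tab["expected"] + epsilon))
    tab["p_value"] = stats.poisson.sf(tab["observed"] - 1, tab["expected"])
    if len(tab):
        tab["q_value"] = multipletests(tab["p_value"], method="fdr_bh")[1]
    else:
        tab["q_value"] = []
    cis = [poisson_ci(int(o)) for o in tab["observed"]]
    tab["dnds"] = tab["observed"] / tab["expected"]
    tab["ci_low"] = [lo / e for (lo, _), e in zip(cis, tab["expected"])]
    tab["ci_high"] = [hi / e for (_, hi), e in zip(cis, tab["expected"])]
    tab.index.name = "unit_id"
    return UnitScores(gene=gene, unit=unit, table=tab.reset_index(),
                      n_suppressed=n_suppressed)
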