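"""Kinetics of natural saturation mutagenesis.

As cumulative duplex depth grows, independently arisen somatic mutations
accumulate across the sites of a gene, approaching exhaustive coverage of
all possible variants.  The theoretical curve assumes neutral mutagenesis:
each possible substitution m with neutral rate r_m (mutations per
site-genome) is observed at cumulative depth D (haploid genomes) with
probability 1 − exp(−r_m D), and the curve is the mean of this probability
over all possible substitutions.  The observed curve downsamples the real
catalog: each mutation's supporting molecules are re-drawn binomially at
reduced depth, respecting its VAF.  Divergence between the two curves is a
signature of selection — positive selection lifts the observed curve above
the neutral expectation, negative selection (FGFR3-like) drops it below.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog_io import Panel
from .mutrate import TrinucSpectrum

DEFAULT_GRID_POINTS = 12
DEFAULT_GRID_MIN = 1e3


@dataclass
class SaturationCurve:
    gene: str
    depth_grid: np.ndarray
    theoretical_fraction: np.ndarray | None = None
    observed_mean: np.ndarray | None = None
    observed_sd: np.ndarray | None = None
    n_possible: int = 0

    def to_frame(self) -> pd.DataFrame:
        out = {"depth": self.depth_grid}
        if self.theoretical_fraction is not None:
            out["theoretical"] = self.theoretical_fraction
        if self.observed_mean is not None:
            out["observed_mean"] = self.observed_mean
            out["observed_sd"] = self.observed_sd
        return pd.DataFrame(out)


def default_depth_grid(d_full: float, n_points: int = DEFAULT_GRID_POINTS,
                       d_min: float = DEFAULT_GRID_MIN) -> np.ndarray:
    """Log-spaced cumulative-depth grid from ``d_min`` to full cohort depth."""
    d_min = min(d_min, d_full)
    return np.geomspace(d_min, d_full, n_points)


def _gene_rates(gene: str, spectrum: TrinucSpectrum, panel: Panel,
                classes: tuple[str, ...] | None,
                weight_by_depth: bool) -> np.ndarray:
    sa = panel.site_alts
    gmask = panel.gene_mask(gene)[sa["site"].to_numpy()]
    if classes is not None:
        gmask = gmask & sa["consequence"].isin(classes).to_numpy()
    rates = spectrum.rate[sa.loc[gmask, "channel"].to_numpy()]
    if weight_by_depth and panel.depth is not None:
        depth = panel.depth_vector("cohort")[sa.loc[gmask, "site"].to_numpy()]
        if depth.mean() > 0:
            rates = rates * depth / depth.mean()
    return rates


def theoretical_kinetic(
    gene: str,
    spectrum: TrinucSpectrum,
    panel: Panel,
    depth_grid: np.ndarray,
    classes: tuple[str, ...] | None = None,
    weight_by_depth: bool = True,
) -> SaturationCurve:
    """Expected fraction of a gene's possible substitutions seen by depth D.

    ``fraction(D) = mean_m (1 − exp(−r_m D))`` over all possible
    substitutions m of the gene (optionally restricted to consequence
    classes), with r_m the neutral rate of m's trinucleotide channel.
    With ``weight_by_depth`` each substitution's rate is scaled by its
    site's share of the gene's cohort depth profile (mean 1), so uneven
    capture efficiency shapes the curve as it does the data; under uniform
    depth this reduces exactly to ``1 − exp(−r D)``.
    """
    rates = _gene_rates(gene, spectrum, panel, classes, weight_by_depth)
    grid = np.asarray(depth_grid, dtype=float)
    frac = (1.0 - np.exp(-np.outer(grid, rates))).mean(axis=1)
    return SaturationCurve(gene=gene, depth_grid=grid,
                           theoretical_fraction=frac, n_possible=len(rates))


def observed_kinetic(
    gene: str,
    mutations: pd.DataFrame,
    panel: Panel,
    depth_grid: np.ndarray,
    n_reps: int = 20,
    seed: int = 0,
    classes: tuple[str, ...] | None = None,
    thinning: str = "molecules",
) -> SaturationCurve:
    """Observed saturation curve by depth-downsampling the catalog.

    At target cumulative depth D each mutation's site depth d (duplex, in
    its own sample) is thinned by f = D/D_full.  Two thinning models are
    available:

    ``"molecules"`` (default)
        Each of the mutation's supporting duplex molecules,
        k = max(1, round(VAF·d)), survives the depth reduction
        independently with probability f; the mutation is retained iff at
        least one survives (Binomial(k, f) ≥ 1).  This reproduces the
        full-depth observed set exactly at f = 1 and, for single-molecule
        mutations, retains each with probability f — the self-consistent
        estimate of what lower-depth sequencing of the same libraries
        would have reported.
    ``"binomial"``
        The mutation is re-detected from scratch: retained iff
        Binomial(round(f·d), VAF) ≥ 1 — a fresh sequencing experiment of
        the same tissue at reduced depth.  Even at f = 1 a low-VAF
        mutation can be lost (retention 1 − (1 − VAF)^d).

    The fraction of distinct possible substitutions retained, averaged
    over replicates, traces how mutation discovery would have progressed
    at lower depth.
    """
    if thinning not in ("molecules", "binomial"):
        raise ValueError(f"unknown thinning model {thinning!r}")
    if panel.depth is None:
        raise ValueError("panel has no depth attached")
    grid = np.asarray(depth_grid, dtype=float)
    depth_cohort = panel.depth_vector("cohort")
    d_full = float(depth_cohort[panel.gene_mask(gene)].mean())
    if (grid > d_full * (1 + 1e-9)).any():
        raise ValueError("depth grid exceeds full cohort depth: no extrapolation")

    sa = panel.site_alts
    gmask = panel.gene_mask(gene)[sa["site"].to_numpy()]
    if classes is not None:
        gmask = gmask & sa["consequence"].isin(classes).to_numpy()
    n_possible = int(gmask.sum())

    muts = mutations[(mutations["gene"] == gene) & (mutations["mut_type"] == "SNV")]
    if classes is not None:
        muts = muts[muts["consequence"].isin(classes)]
    site_idx = np.array([panel.site_index(c, p)
                         for c, p in zip(muts["chrom"], muts["pos"])])
    depth_mat = panel.depth.to_numpy()
    sample_col = {s: j for j, s in enumerate(panel.samples)}
    d = np.array([
        depth_mat[i, sample_col[s]] for i, s in zip(site_idx, muts["sample_id"])
    ]) if len(muts) else np.zeros(0)
    vaf = muts["vaf_duplex"].to_numpy()
    # identity of the possible substitution each record realises
    ident = pd.factorize(
        pd.Series([f"{c}:{p}:{a}" for c, p, a in
                   zip(muts["chrom"], muts["pos"], muts["alt"])])
    )[0] if len(muts) else np.zeros(0, dtype=int)
    n_ident = ident.max() + 1 if len(muts) else 0

    rng = np.random.default_rng(seed)
    k_support = np.maximum(1, np.round(vaf * d)).astype(int)
    means, sds = [], []
    for D in grid:
        f = D / d_full
        thinned = np.round(f * d).astype(int)
        fractions = np.empty(n_reps)
        for rep in range(n_reps):
            if len(muts):
                if thinning == "molecules":
                    kept = rng.binomial(k_support, min(f, 1.0)) >= 1
                else:
                    kept = rng.binomial(thinned, vaf) >= 1
                n_seen = len(np.unique(ident[kept]))
            else:
                n_seen = 0
            fractions[rep] = n_seen / n_possible if n_possible else 0.0
        means.append(fractions.mean())
        sds.append(fractions.std(ddof=1) if n_reps > 1 else 0.0)
    return SaturationCurve(gene=gene, depth_grid=grid,
                           observed_mean=np.array(means),
                           observed_sd=np.array(sds), n_possible=n_possible)


def retention_rate(depth: int, vaf: float, f: float, n_reps: int = 1000,
                   seed: int = 0, thinning: str = "binomial") -> float:
    """Empirical per-mutation retention frequency under depth thinning.

    With the ``binomial`` (fresh re-detection) model the expectation is
    1 − (1 − VAF)^round(f·depth); with ``molecules`` it is
    1 − (1 − f)^k for k = max(1, round(VAF·depth)) supporting molecules.
    """
    rng = np.random.default_rng(seed)
    if thinning == "binomial":
        kept = rng.binomial(int(round(f * depth)), vaf, size=n_reps) >= 1
    elif thinning == "molecules":
        k = max(1, int(round(vaf * depth)))
        kept = rng.binomial(k, min(f, 1.0), size=n_reps) >= 1
    else:
        raise ValueError(f"unknown thinning model {thinning!r}")
    return float(kept.mean())


@dataclass
class KineticDivergence:
    """Signed divergence of observed from theoretical saturation."""

    gene: str
    signed_area: float        # ∫ (observed − theoretical) dD, trapezoid on the grid
    top_depth_delta: float    # observed − theoretical at the deepest grid point

    @property
    def direction(self) -> str:
        """Positive-selection direction when observed runs above theoretical."""
        if self.top_depth_delta > 0:
            return "positive"
        if self.top_depth_delta < 0:
            return "negative"
        return "neutral"


def compare_kinetics(theoretical: SaturationCurve,
                     observed: SaturationCurve) -> KineticDivergence:
    """Signed area between observed and theoretical curves on a shared grid."""
    if not np.allclose(theoretical.depth_grid, observed.depth_grid):
        raise ValueError("depth grids differ")
    delta = observed.observed_mean - theoretical.theoretical_fraction
    area = float(np.trapezoid(delta, theoretical.depth_grid))
    return KineticDivergence(
        gene=theoretical.gene, signed_area=area,
        top_depth_delta=float(delta[-1]),
    )
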