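"""Neutral trinucleotide mutation-rate model.

Rates are estimated from mutation classes assumed to evolve neutrally
(synonymous and/or non-coding changes): for each of the 96 substitution
channels the rate is the observed neutral count divided by the channel's
mutational opportunity — the duplex-depth-weighted number of (site, alt)
pairs at which a neutral change of that channel can occur, in units of
site-genomes.  A spectrum observed on a capture panel can be re-projected
onto an arbitrary genome trinucleotide composition while conserving the
total mutation count.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .context import CHANNEL_LABELS, CHANNEL_TRINUC, N_CHANNELS, TRINUCS_32
from .catalog_io import Panel

DEFAULT_NEUTRAL_CLASSES = ("synonymous", "noncoding")
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class TrinucSpectrum:
    """96-channel mutation counts, opportunities, rates and probabilities."""

    counts: np.ndarray       # neutral mutations per channel
    opportunity: np.ndarray  # site-genomes per channel
    pseudocount: float = 0.0
    scope: str = "cohort"

    rate: np.ndarray = field(init=False)
    probability: np.ndarray = field(init=False)

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        opp = np.asarray(self.opportunity, dtype=float)
        if counts.shape != (N_CHANNELS,) or opp.shape != (N_CHANNELS,):
            raise ValueError("spectrum arrays must have 96 channels")
        if (counts < 0).any() or (opp < 0).any():
            raise ValueError("negative counts or opportunity")
        eff = counts + (self.pseudocount if (counts[opp > 0] == 0).any() else 0.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            rate = np.where(opp > 0, eff / np.where(opp > 0, opp, 1.0), 0.0)
        self.rate = rate
        total = rate.sum()
        self.probability = rate / total if total > 0 else rate

    @property
    def empty_channels(self) -> np.ndarray:
        """Channels with zero opportunity, excluded from estimation."""
        return np.flatnonzero(np.asarray(self.opportunity) == 0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "channel": CHANNEL_LABELS,
            "count": self.counts,
            "opportunity": self.opportunity,
            "rate": self.rate,
            "probability": self.probability,
        })

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def fit_neutral_spectrum(
    mutations: pd.DataFrame,
    panel: Panel,
    scope: str = "cohort",
    neutral_classes: tuple[str, ...] = DEFAULT_NEUTRAL_CLASSES,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    exclude_positions: set | None = None,
) -> TrinucSpectrum:
    """Estimate per-channel neutral rates from non-selected mutation classes.

    Parameters
    ----------
    scope
        ``"cohort"`` pools depth over all samples; a sample id restricts
        counts and opportunity to that sample.
    neutral_classes
        Consequence classes treated as selection-free; opportunity counts
        depth over the (site, alt) pairs producing those classes.
    pseudocount
        Added to every channel count when any channel with opportunity is
        empty (stabilises downstream ratios); set 0 for exact tests.
    exclude_positions
        Optional ``{(chrom, pos), ...}`` removed from both counts and
        opportunity (e.g. tumour-recurrent promoter hotspots).

    Raises
    ------
    ValueError
        If no neutral mutations remain — widen ``neutral_classes``.
    """
    bad = set(neutral_classes) - {"synonymous", "noncoding", "essential_splice"}
    if bad:
        raise ValueError(f"not usable as neutral classes: {sorted(bad)}")

    sa = panel.site_alts
    sites = panel.sites
    excl_sites = sites["excluded"].to_numpy()
    if exclude_positions:
        drop = np.array([
            (c, p) in exclude_positions
            for c, p in zip(sites["chrom"], sites["pos"])
        ])
        excl_sites = excl_sites | drop

    neutral_sa = sa[
        sa["consequence"].isin(neutral_classes)
        & ~excl_sites[sa["site"].to_numpy()]
    ]
    depth = panel.depth_vector(scope)
    opportunity = np.bincount(
        neutral_sa["channel"].to_numpy(),
        weights=depth[neutral_sa["site"].to_numpy()],
        minlength=N_CHANNELS,
    )

    muts = mutations[
        (mutations["mut_type"] == "SNV")
        & mutations["consequence"].isin(neutral_classes)
    ]
    if scope != "cohort":
        muts = muts[muts["sample_id"] == scope]
    if exclude_positions:
        keep = [
            (c, p) not in exclude_positions
            for c, p in zip(muts["chrom"], muts["pos"])
        ]
        muts = muts[keep]
    if len(muts) == 0:
        raise ValueError(
            "no neutral mutations in catalog; widen neutral_classes to fit a spectrum"
        )
    chan = _mutation_channels(muts, panel)
    counts = np.bincount(chan, minlength=N_CHANNELS).astype(float)
    return TrinucSpectrum(counts=counts, opportunity=opportunity,
                          pseudocount=pseudocount, scope=scope)


def _mutation_channels(muts: pd.DataFrame, panel: Panel) -> np.ndarray:
    """Channel index of each SNV record via its panel site's context."""
    lookup = panel.alt_lookup()
    return np.array([
        lookup[(c, p, a)][0]
        for c, p, a in zip(muts["chrom"], muts["pos"], muts["alt"])
    ], dtype=int)


@dataclass
class GenomeComposition:
    """Occurrences of each of the 32 pyrimidine-central trinucleotides."""

    counts: pd.Series  # trinuc -> count

    def __post_init__(self):
        missing = set(TRINUCS_32) - set(self.counts.index)
        if missing:
            raise ValueError(f"missing trinucleotides: {sorted(missing)}")
        if (self.counts <= 0).any():
            raise ValueError("genome trinucleotide counts must be positive")

    @classmethod
    def from_tsv(cls, path) -> "GenomeComposition":
        df = pd.read_csv(path, sep="\t")
        return cls(counts=df.set_index("trinuc")["count"].astype(float))

    @classmethod
    def from_gc_content(cls, gc: float = 0.41,
                        length: float = 3.1e9) -> "GenomeComposition":
        """Synthetic stand-in composition under an i.i.d. base model.

        Expected trinucleotide counts for a genome of the given length and
        GC content, counting both strands' pyrimidine-central collapse.
        Useful when no genome table is at hand; supply a real table for
        genome-accurate correction.
        """
        p = {"A": (1 - gc) / 2, "T": (1 - gc) / 2,
             "C": gc / 2, "G": gc / 2}
        from .context import COMPLEMENT
        counts = {}
        for tri in TRINUCS_32:
            rc = "".join(COMPLEMENT[b] for b in reversed(tri))
            prob = np.prod([p[b] for b in tri]) + np.prod([p[b] for b in rc])
            counts[tri] = prob * length
        return cls(counts=pd.Series(counts))

    def channel_counts(self) -> np.ndarray:
        """Genome trinucleotide count of each 96 channel's context."""
        per_tri = self.counts.reindex(TRINUCS_32).to_numpy(dtype=float)
        return per_tri[CHANNEL_TRINUC]


def correct_to_genome(
    spectrum: TrinucSpectrum,
    genome_comp: GenomeComposition,
    total_observed: float,
) -> np.ndarray:
    """Re-project a panel spectrum onto genome trinucleotide composition.

    Each channel's rate is multiplied by the genome-wide occurrence count
    of its trinucleotide, the products are renormalised into a probability
    vector, and the vector is rescaled so the corrected counts sum exactly
    to ``total_observed`` — the panel's trinucleotide bias is removed while
    the absolute number of observed mutations is conserved.
    """
    g = genome_comp.channel_counts()
    used = np.asarray(spectrum.opportunity) > 0
    if (~used & (g > 0)).any() and spectrum.rate[~used].sum() > 0:
        raise ValueError("spectrum lacks rates for channels present in genome")
    expected_genome = spectrum.rate * g
    total = expected_genome.sum()
    if total == 0:
        return np.zeros(N_CHANNELS)
    return expected_genome / total * float(total_observed)
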