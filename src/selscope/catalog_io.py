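"""Readers, writers and consequence annotation for duplex-sequencing panels.

The panel is a set of captured genomic intervals (BED) over a reference
(FASTA).  Every base of the panel becomes a *site* with a strand-collapsed
trinucleotide context, and every possible single-base substitution at a
site is annotated with its protein consequence by codon translation on the
annotated strand.  Mutation catalogs, per-site depth matrices and donor
covariates are plain TSV tables.

Coordinates are 0-based half-open internally; TSV mutation and depth
tables use 1-based positions at the file boundary (VCF convention).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from pyfaidx import Fasta

from .context import COMPLEMENT, channel_index, collapse_trinuc

log = logging.getLogger(__name__)

REGION_CLASSES = ("coding", "intronic_flank", "promoter")
CONSEQUENCES = ("synonymous", "missense", "nonsense", "essential_splice", "noncoding")
INDEL_CONSEQUENCES = ("frameshift_indel", "inframe_indel")

#: intronic bases on each side of a coding-exon boundary treated as
#: essential splice sites (donor/acceptor dinucleotides)
SPLICE_WINDOW = 2

MUTATION_COLUMNS = [
    "sample_id", "donor_id", "chrom", "pos", "ref", "alt",
    "vaf_duplex", "vaf_all_molecules",
]


@dataclass(frozen=True)
class PanelRegion:
    """One captured interval of one gene."""

    chrom: str
    start: int  # 0-based, half-open
    end: int
    gene: str
    region_class: str
    strand: str = "+"
    frame_anchor: int = 0  # codon offset of the first transcribed base

    def __post_init__(self):
        if self.start >= self.end:
            raise ValueError(f"empty region {self.chrom}:{self.start}-{self.end}")
        if self.region_class not in REGION_CLASSES:
            raise ValueError(f"unknown region class {self.region_class!r}")
        if self.strand not in "+-":
            raise ValueError(f"bad strand {self.strand!r}")

    def __len__(self):
        return self.end - self.start


@dataclass
class Panel:
    """Annotated panel: per-site and per-(site, alt) tables plus depth.

    ``sites`` has one row per sequenced base: chrom, pos, ref, trinuc
    (pyrimidine-collapsed), gene, region_class, excluded (ambiguous
    context).  ``site_alts`` has exactly three rows per non-excluded site:
    site (row index into ``sites``), alt, channel (0-95), consequence,
    protein_pos (1-based residue, coding sites only).
    """

    regions: list[PanelRegion]
    sites: pd.DataFrame
    site_alts: pd.DataFrame
    depth: pd.DataFrame | None = None  # sites-aligned, one column per sample
    _site_lookup: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if not self._site_lookup:
            self._site_lookup = {
                (c, p): i
                for i, (c, p) in enumerate(zip(self.sites["chrom"], self.sites["pos"]))
            }

    # -- basic accessors -------------------------------------------------
    @property
    def samples(self) -> list[str]:
        if self.depth is None:
            raise ValueError("no depth attached to panel")
        return list(self.depth.columns)

    @property
    def genes(self) -> list[str]:
        return sorted(self.sites["gene"].unique())

    def site_index(self, chrom: str, pos: int) -> int | None:
        return self._site_lookup.get((chrom, pos))

    def gene_mask(self, gene: str) -> np.ndarray:
        return (self.sites["gene"] == gene).to_numpy()

    def total_bp(self, region_class: str | None = None) -> int:
        """Panel footprint in base pairs, optionally for one region class."""
        if region_class is None:
            return len(self.sites)
        return int((self.sites["region_class"] == region_class).sum())

    # -- depth -----------------------------------------------------------
    def attach_depth(self, depth: pd.DataFrame) -> None:
        """Attach a per-site depth matrix (rows: chrom, pos + sample columns)."""
        key = list(zip(depth["chrom"], depth["pos"]))
        idx = [self._site_lookup.get(k, -1) for k in key]
        if any(i < 0 for i in idx):
            raise ValueError("depth table contains positions outside the panel")
        samples = [c for c in depth.columns if c not in ("chrom", "pos")]
        mat = np.zeros((len(self.sites), len(samples)))
        mat[np.asarray(idx)] = depth[samples].to_numpy(dtype=float)
        if (mat < 0).any():
            raise ValueError("negative depth")
        self.depth = pd.DataFrame(mat, columns=samples)

    def alt_lookup(self) -> dict:
        """(chrom, pos, alt) -> (channel, consequence, protein_pos), cached."""
        if not hasattr(self, "_alt_lookup"):
            sa = self.site_alts
            chroms = self.sites["chrom"].to_numpy()[sa["site"]]
            poss = self.sites["pos"].to_numpy()[sa["site"]]
            self._alt_lookup = {
                (c, p, a): (ch, cons, pp)
                for c, p, a, ch, cons, pp in zip(
                    chroms, poss, sa["alt"], sa["channel"], sa["consequence"],
                    sa["protein_pos"])
            }
        return self._alt_lookup

    def depth_vector(self, scope: str = "cohort") -> np.ndarray:
        """Per-site duplex depth: cohort sum or a single sample's column."""
        if self.depth is None:
            raise ValueError("no depth attached to panel")
        if scope == "cohort":
            return self.depth.to_numpy().sum(axis=1)
        if scope not in self.depth.columns:
            raise KeyError(f"unknown sample {scope!r}")
        return self.depth[scope].to_numpy()


def read_bed(bed_path) -> list[PanelRegion]:
    """Read a panel BED whose name field is ``gene|region_class|strand|frame``."""
    bed = pd.read_csv(
        bed_path, sep="\t", header=None, comment="#",
        names=["chrom", "start", "end", "name"], usecols=range(4),
        dtype={"chrom": str, "name": str},
    )
    regions = []
    for row in bed.itertuples():
        gene, region_class, strand, frame = row.name.split("|")
        regions.append(
            PanelRegion(row.chrom, int(row.start), int(row.end), gene,
                        region_class, strand, int(frame))
        )
    return regions


def write_bed(regions: list[PanelRegion], bed_path) -> None:
    with open(bed_path, "w") as fh:
        for r in regions:
            name = f"{r.gene}|{r.region_class}|{r.strand}|{r.frame_anchor}"
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{name}\n")


@lru_cache(maxsize=256)
def _translate_codon(codon: str) -> str:
    return str(Seq(codon).translate())


def _coding_order(regions: list[PanelRegion]) -> list[PanelRegion]:
    """Coding regions of one gene in transcription order."""
    coding = sorted((r for r in regions if r.region_class == "coding"),
                    key=lambda r: r.start)
    if coding and coding[0].strand == "-":
        coding = coding[::-1]
    return coding


def _annotate_gene_coding(regions, seqs, rows):
    """Fill consequence/protein_pos for the coding sites of one gene.

    The coding sequence is assembled across exons in transcription order so
    that codons spanning an exon boundary translate correctly; each
    possible alternate allele is classified by re-translating its codon.
    """
    coding = _coding_order(regions)
    if not coding:
        return
    strand = coding[0].strand
    # transcription-ordered list of (chrom, genomic pos, coding base)
    cds = []
    for r in coding:
        span = range(r.start, r.end) if strand == "+" else range(r.end - 1, r.start - 1, -1)
        for pos in span:
            base = seqs[r.chrom][pos]
            cds.append((r.chrom, pos, base if strand == "+" else COMPLEMENT.get(base, "N")))
    phase = coding[0].frame_anchor
    n = len(cds)
    for i, (chrom, pos, base) in enumerate(cds):
        c = phase + i
        codon_idx, offset = divmod(c, 3)
        lo, hi = i - offset, i - offset + 3
        if lo < 0 or hi > n:
            # partial codon at a panel edge: cannot translate
            rows[(chrom, pos)] = ("noncoding", None, True)
            continue
        codon = "".join(b for _, _, b in cds[lo:hi])
        if "N" in codon:
            rows[(chrom, pos)] = ("noncoding", None, True)
            continue
        aa_ref = _translate_codon(codon)
        cons = {}
        for alt_coding in "ACGT":
            if alt_coding == base:
                continue
            mutant = codon[:offset] + alt_coding + codon[offset + 1:]
            aa_alt = _translate_codon(mutant)
            if aa_alt == aa_ref:
                cls = "synonymous"
            elif aa_alt == "*":
                cls = "nonsense"
            else:
                cls = "missense"  # includes stop-loss: protein-altering
            # report keyed by the genomic (+ strand) alt allele
            alt_genomic = alt_coding if strand == "+" else COMPLEMENT[alt_coding]
            cons[alt_genomic] = cls
        rows[(chrom, pos)] = (cons, codon_idx + 1, False)


def _splice_positions(regions: list[PanelRegion], window: int) -> set:
    """Intronic positions within ``window`` bp of internal coding boundaries.

    The outermost CDS ends (translation start/stop) are not splice sites.
    """
    coding = _coding_order(regions)
    out = set()
    for k, r in enumerate(coding):
        strand = r.strand
        first = (k == 0)
        last = (k == len(coding) - 1)
        # genomic-left boundary is the transcription start for '+', end for '-'
        left_is_terminal = first if strand == "+" else last
        right_is_terminal = last if strand == "+" else first
        if not left_is_terminal:
            out.update((r.chrom, p) for p in range(r.start - window, r.start))
        if not right_is_terminal:
            out.update((r.chrom, p) for p in range(r.end, r.end + window))
    return out


def load_panel(bed_path, fasta_path, splice_window: int = SPLICE_WINDOW) -> Panel:
    """Build an annotated :class:`Panel` from a BED definition and FASTA.

    One site per base; trinucleotide contexts from the ±1 flanking
    reference bases (pyrimidine-collapsed); per-alt consequences by codon
    translation on the annotated strand; essential splice sites are the
    ``splice_window`` intronic bases flanking internal coding boundaries.
    Sites with an ambiguous (N) context are flagged ``excluded``.
    """
    regions = read_bed(bed_path)
    fasta = Fasta(str(fasta_path))
    seqs = {name: str(fasta[name][:]).upper() for name in fasta.keys()}

    by_gene: dict[str, list[PanelRegion]] = {}
    for r in regions:
        if r.chrom not in seqs:
            raise ValueError(f"region chrom {r.chrom!r} not in FASTA")
        if r.end > len(seqs[r.chrom]):
            raise ValueError(f"region {r.chrom}:{r.start}-{r.end} outside contig")
        by_gene.setdefault(r.gene, []).append(r)

    coding_rows: dict = {}
    splice: set = set()
    for gene, gregs in by_gene.items():
        _annotate_gene_coding(gregs, seqs, coding_rows)
        splice |= _splice_positions(gregs, splice_window)

    site_rec, alt_rec = [], []
    for r in sorted(regions, key=lambda x: (x.chrom, x.start)):
        seq = seqs[r.chrom]
        for pos in range(r.start, r.end):
            ref = seq[pos]
            flank5 = seq[pos - 1] if pos > 0 else "N"
            flank3 = seq[pos + 1] if pos + 1 < len(seq) else "N"
            tri = flank5 + ref + flank3
            excluded = "N" in tri
            site_idx = len(site_rec)
            site_rec.append(
                (r.chrom, pos, ref, collapse_trinuc(tri) if not excluded else tri,
                 r.gene, r.region_class, excluded)
            )
            if excluded:
                continue
            info = coding_rows.get((r.chrom, pos))
            if info is not None and info[2]:
                # partial codon: excluded from coding classes
                cons_map, protein_pos = None, None
            elif info is not None:
                cons_map, protein_pos = info[0], info[1]
            else:
                cons_map, protein_pos = None, None
            is_splice = (r.chrom, pos) in splice and r.region_class != "coding"
            for alt in "ACGT":
                if alt == ref:
                    continue
                if cons_map is not None:
                    cls = cons_map[alt]
                elif is_splice:
                    cls = "essential_splice"
                else:
                    cls = "noncoding"
                alt_rec.append((site_idx, alt, channel_index(tri, alt), cls, protein_pos))

    sites = pd.DataFrame(
        site_rec,
        columns=["chrom", "pos", "ref", "trinuc", "gene", "region_class", "excluded"],
    )
    site_alts = pd.DataFrame(
        alt_rec, columns=["site", "alt", "channel", "consequence", "protein_pos"]
    )
    n_excl = int(sites["excluded"].sum())
    if n_excl:
        log.warning("%d panel sites with ambiguous context excluded", n_excl)
    return Panel(regions=regions, sites=sites, site_alts=site_alts)


def load_depth(path) -> pd.DataFrame:
    """Read a site × sample duplex-depth TSV (1-based ``pos`` column)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    df["pos"] = df["pos"].astype(int) - 1
    return df


def write_depth(panel: Panel, path) -> None:
    out = panel.sites[["chrom", "pos"]].copy()
    out["pos"] = out["pos"] + 1
    out = pd.concat([out, panel.depth.round(0).astype(int)], axis=1)
    out.to_csv(path, sep="\t", index=False)


def _classify_mut_type(ref: str, alt: str) -> str:
    if len(ref) == len(alt):
        return "SNV" if len(ref) == 1 else "MNV"
    return "insertion" if len(alt) > len(ref) else "deletion"


_WORST = {c: i for i, c in enumerate(
    ["noncoding", "synonymous", "missense", "essential_splice", "nonsense"])}


def load_mutations(tsv_path, panel: Panel, samples: list[str] | None = None) -> pd.DataFrame:
    """Load and annotate a mutation catalog against a panel.

    SNV consequences come from the panel's per-alt annotation; MNVs take the
    worst consequence of their constituent substitutions; indels overlapping
    coding sequence are frameshift iff their length is not a multiple of 3.
    Records with VAF outside (0, 1] or SNVs outside the panel are rejected
    and counted in ``df.attrs['n_rejected']``.  An unknown sample id (when
    ``samples`` is given) is fatal.
    """
    raw = pd.read_csv(tsv_path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    raw["pos"] = raw["pos"].astype(int) - 1
    return annotate_mutations(raw, panel, samples=samples)


def annotate_mutations(raw: pd.DataFrame, panel: Panel,
                       samples: list[str] | None = None) -> pd.DataFrame:
    """Annotate an in-memory catalog (0-based ``pos``); see :func:`load_mutations`."""
    if samples is not None:
        unknown = set(raw["sample_id"]) - set(samples)
        if unknown:
            raise ValueError(f"unknown sample ids in catalog: {sorted(unknown)}")

    cons_lookup = {k: (v[1], v[2]) for k, v in panel.alt_lookup().items()}
    coding_pos = {
        (c, p) for c, p, rc in zip(panel.sites["chrom"], panel.sites["pos"],
                                   panel.sites["region_class"]) if rc == "coding"
    }

    records, n_rejected = [], 0
    for row in raw.itertuples():
        ref, alt = row.ref.upper(), row.alt.upper()
        ok_vaf = (0 < row.vaf_duplex <= 1) and (0 < row.vaf_all_molecules <= 1)
        if not ok_vaf:
            n_rejected += 1
            continue
        mut_type = _classify_mut_type(ref, alt)
        protein_pos = None
        if mut_type == "SNV":
            hit = cons_lookup.get((row.chrom, row.pos, alt))
            if hit is None:
                n_rejected += 1
                continue
            consequence, protein_pos = hit
        elif mut_type == "MNV":
            if len(ref) > 100:
                n_rejected += 1
                continue
            parts = [cons_lookup.get((row.chrom, row.pos + i, a))
                     for i, (r0, a) in enumerate(zip(ref, alt)) if r0 != a]
            if any(p is None for p in parts) or not parts:
                n_rejected += 1
                continue
            consequence = max((p[0] for p in parts), key=_WORST.get)
            protein_pos = next((p[1] for p in parts if p[0] == consequence), None)
        else:  # indel
            length = abs(len(ref) - len(alt))
            if length > 100:
                n_rejected += 1
                continue
            span = range(row.pos, row.pos + max(len(ref), 1))
            in_coding = any((row.chrom, p) in coding_pos for p in span)
            if not in_coding:
                consequence = "noncoding"
            elif length % 3 != 0:
                consequence = "frameshift_indel"
            else:
                consequence = "inframe_indel"
        site = panel.site_index(row.chrom, row.pos)
        gene = panel.sites["gene"].iat[site] if site is not None else None
        if gene is None:
            n_rejected += 1
            continue
        records.append((
            row.sample_id, getattr(row, "donor_id", None), row.chrom, row.pos,
            ref, alt, mut_type, float(row.vaf_duplex),
            float(row.vaf_all_molecules), gene, consequence, protein_pos,
        ))

    df = pd.DataFrame(records, columns=[
        "sample_id", "donor_id", "chrom", "pos", "ref", "alt", "mut_type",
        "vaf_duplex", "vaf_all_molecules", "gene", "consequence", "protein_pos",
    ])
    df.attrs["n_rejected"] = n_rejected
    if n_rejected:
        log.info("rejected %d catalog records (out of panel or bad VAF)", n_rejected)
    return df


def write_mutations(df: pd.DataFrame, path) -> None:
    """Write a catalog TSV (1-based positions) readable by :func:`load_mutations`."""
    out = df[MUTATION_COLUMNS].copy() if set(MUTATION_COLUMNS) <= set(df.columns) \
        else df.copy()
    out["pos"] = out["pos"] + 1
    out.to_csv(path, sep="\t", index=False)


def load_covariates(path) -> pd.DataFrame:
    """Per-sample donor covariates; derives age_decades and 0-1-rescaled BMI."""
    cov = pd.read_csv(path, sep="\t")
    cov["age_decades"] = cov["age"] / 10.0
    lo, hi = cov["bmi"].min(), cov["bmi"].max()
    cov["bmi_scaled"] = 0.0 if hi == lo else (cov["bmi"] - lo) / (hi - lo)
    bad = cov.groupby("donor_id")["sample_id"].count()
    if (bad > 2).any():
        raise ValueError("more than two samples for a donor")
    return cov


@dataclass
class ResidueTally:
    """Missense/nonsense mutation counts per residue of one gene."""

    gene: str
    counts: pd.Series  # protein_pos -> mutation count, all samples pooled
    n_covered: int
    n_mutated: int

    @property
    def percent_mutated(self) -> float:
        return 100.0 * self.n_mutated / self.n_covered if self.n_covered else 0.0


def residue_mutation_tally(mutations: pd.DataFrame, gene: str, panel: Panel) -> ResidueTally:
    """Count protein-affecting SNVs (missense or nonsense) per residue.

    Residue coverage comes from the panel's translatable codons; the
    percentage of covered residues carrying at least one mutation is the
    gene's progress toward saturation of its residues.
    """
    sa = panel.site_alts
    gene_sites = set(np.flatnonzero(panel.gene_mask(gene)))
    covered = sa.loc[sa["site"].isin(gene_sites), "protein_pos"].dropna().unique()
    if len(covered) == 0:
        raise ValueError(f"gene {gene!r} has no translatable coding sites in the panel")
    sub = mutations[
        (mutations["gene"] == gene)
        & mutations["consequence"].isin(["missense", "nonsense"])
        & mutations["protein_pos"].notna()
    ]
    counts = sub.groupby("protein_pos").size()
    counts.index = counts.index.astype(int)
    return ResidueTally(
        gene=gene,
        counts=counts,
        n_covered=len(covered),
        n_mutated=int((counts > 0).sum()),
    )
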