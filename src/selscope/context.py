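"""Trinucleotide substitution channels.

Single-base substitutions are classified into 96 channels by the mutated
base and its two flanking bases, collapsed onto the pyrimidine strand
(COSMIC ordering: C>A, C>G, C>T, T>A, T>C, T>G, each over the 16 flanking
dinucleotide combinations, alphabetically by 5' then 3' flank).
"""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
PYRIMIDINES = "CT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: the six pyrimidine-central substitution types, COSMIC order
SUB_TYPES = [("C", "A"), ("C", "G"), ("C", "T"), ("T", "A"), ("T", "C"), ("T", "G")]


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq.upper()))


def _build_channels() -> list[tuple[str, str]]:
    channels = []
    for ref, alt in SUB_TYPES:
        for five in BASES:
            for three in BASES:
                channels.append((five + ref + three, alt))
    return channels


#: 96 (pyrimidine-central trinucleotide, alt) pairs in canonical order
CHANNELS: list[tuple[str, str]] = _build_channels()
CHANNEL_LABELS: list[str] = [f"{t}>{a}" for t, a in CHANNELS]
_CHANNEL_INDEX: dict[tuple[str, str], int] = {c: i for i, c in enumerate(CHANNELS)}

#: the 32 pyrimidine-central trinucleotides, in first-channel order
TRINUCS_32: list[str] = sorted({t for t, _ in CHANNELS})
_TRINUC_INDEX: dict[str, int] = {t: i for i, t in enumerate(TRINUCS_32)}

N_CHANNELS = 96


def collapse(trinuc: str, alt: str) -> tuple[str, str]:
    """Map a stranded (trinucleotide, alt) onto its pyrimidine-central channel.

    If the central base is a purine the trinucleotide and the alternate
    allele are both reverse-complemented, so each of the 192 stranded
    labels lands in exactly one of the 96 channels.
    """
    trinuc = trinuc.upper()
    alt = alt.upper()
    if trinuc[1] in PYRIMIDINES:
        return trinuc, alt
    return revcomp(trinuc), COMPLEMENT[alt]


def collapse_trinuc(trinuc: str) -> str:
    trinuc = trinuc.upper()
    if trinuc[1] in PYRIMIDINES:
        return trinuc
    return revcomp(trinuc)


def channel_index(trinuc: str, alt: str) -> int:
    """Channel index (0..95) of a stranded substitution; raises KeyError on N."""
    return _CHANNEL_INDEX[collapse(trinuc, alt)]


def trinuc_index(trinuc: str) -> int:
    """Index (0..31) of a trinucleotide after pyrimidine collapsing."""
    return _TRINUC_INDEX[collapse_trinuc(trinuc)]


#: channel index -> index of its trinucleotide among the 32
CHANNEL_TRINUC: np.ndarray = np.array([_TRINUC_INDEX[t] for t, _ in CHANNELS])
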