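"""Fraction of genomes and cells carrying a gene's driver mutations.

The estimated number of driver mutations in a sample comes from the dN/dS
excess; the most likely drivers are the highest-VAF mutations.  Assuming
independence across mutations, the fraction of sequenced genomes bearing at
least one driver is the inclusion–exclusion probability

    P(G) = 1 − Π_x (1 − p_x)

over the all-molecules VAFs p_x of the selected drivers, identical to the
alternating inclusion–exclusion sum.  Under the two-hit assumption (both
copies of a tumour-suppressor must be lost to drive an expansion) the
fraction of mutant cells equals the fraction of mutant genomes; in the
one-hit extreme it is double, capped at 1; a hemizygous X-linked gene in a
male carries one copy per cell, so cells equal genomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .omega import SelectionResult

PLOIDY_MODES = ("two_hit", "one_hit", "hemizygous_male_X")


def round_half_up(x: float) -> int:
    """Round half away from zero (no banker's rounding)."""
    return int(np.floor(x + 0.5))


def select_drivers(
    gene: str,
    sample_id: str,
    mutations: pd.DataFrame,
    missense_result: SelectionResult | None,
    truncating_result: SelectionResult | None,
) -> dict:
    """Pick the most likely driver mutations of a gene in one sample.

    The expected driver count is round(driver excess missense) +
    round(driver excess truncating); the top-n mutations of those classes
    ranked by descending all-molecules VAF are selected (ties broken by
    ascending genomic position, so selection is deterministic).  Bound sets
    are built the same way from the CI endpoints of the excess, reusing the
    mean ranking and varying only n.
    """
    n_point, lo, hi = 0, 0.0, 0.0
    for res in (missense_result, truncating_result):
        if res is None:
            continue
        n_point += round_half_up(res.driver_excess)
        b_lo, b_hi = res.driver_excess_ci
        lo += b_lo
        hi += b_hi
    n_lo, n_hi = round_half_up(lo), round_half_up(hi)

    sub = mutations[
        (mutations["gene"] == gene)
        & (mutations["sample_id"] == sample_id)
        & mutations["consequence"].isin(
            ["missense", "nonsense", "essential_splice"])
    ].sort_values(
        by=["vaf_all_molecules", "chrom", "pos"],
        ascending=[False, True, True],
        kind="mergesort",
    )
    capped = n_point > len(sub)
    take = lambda n: sub.head(min(n, len(sub)))
    return {
        "drivers": take(n_point),
        "drivers_low": take(n_lo),
        "drivers_high": take(n_hi),
        "n_requested": n_point,
        "capped": capped,
    }


def fraction_genomes(vafs) -> float:
    """P(G) = 1 − Π(1 − p_x): probability a sequenced genome carries a driver."""
    p = np.asarray(list(vafs), dtype=float)
    if p.size == 0:
        return 0.0
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("driver VAFs must lie in (0, 1]")
    return float(1.0 - np.prod(1.0 - p))


def fraction_genomes_inclusion_exclusion(vafs) -> float:
    """Explicit alternating-sum inclusion–exclusion (reference form, O(2^n))."""
    from itertools import combinations

    p = list(vafs)
    total = 0.0
    for i in range(1, len(p) + 1):
        sign = 1.0 if i % 2 == 1 else -1.0
        total += sign * sum(float(np.prod(c)) for c in combinations(p, i))
    return total


def fraction_cells(fraction_genomes_value: float, ploidy_mode: str = "two_hit") -> float:
    """Convert fraction of mutant genomes to fraction of mutant cells."""
    if ploidy_mode not in PLOIDY_MODES:
        raise ValueError(f"unknown ploidy mode {ploidy_mode!r}")
    if ploidy_mode == "one_hit":
        return min(1.0, 2.0 * fraction_genomes_value)
    return fraction_genomes_value  # two_hit and hemizygous male X: one per cell


@dataclass
class CloneFractionResult:
    gene: str
    sample_id: str
    n_drivers_selected: int
    fraction_genomes: float
    fraction_cells: float
    bounds: tuple[float, float]
    ploidy_mode: str = "two_hit"

    def to_dict(self) -> dict:
        return {
            "gene": self.gene, "sample_id": self.sample_id,
            "n_drivers": self.n_drivers_selected,
            "fraction_genomes": self.fraction_genomes,
            "fraction_cells": self.fraction_cells,
            "bound_low": self.bounds[0], "bound_high": self.bounds[1],
            "ploidy_mode": self.ploidy_mode,
        }


def clone_fraction(
    gene: str,
    sample_id: str,
    mutations: pd.DataFrame,
    missense_result: SelectionResult | None,
    truncating_result: SelectionResult | None,
    ploidy_mode: str = "two_hit",
) -> CloneFractionResult:
    """End-to-end clone-fraction estimate for one (gene, sample)."""
    sel = select_drivers(gene, sample_id, mutations, missense_result,
                         truncating_result)
    pg = fraction_genomes(sel["drivers"]["vaf_all_molecules"])
    pg_lo = fraction_genomes(sel["drivers_low"]["vaf_all_molecules"])
    pg_hi = fraction_genomes(sel["drivers_high"]["vaf_all_molecules"])
    return CloneFractionResult(
        gene=gene, sample_id=sample_id,
        n_drivers_selected=len(sel["drivers"]),
        fraction_genomes=pg,
        fraction_cells=fraction_cells(pg, ploidy_mode),
        bounds=(pg_lo, pg_hi),
        ploidy_mode=ploidy_mode,
    )
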