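"""Cluster-level mutation summaries, bulk VAF, and the heterozygosity expectation.

The headline per-cluster quantity is the mutated fraction: ALT cells over
covered (ALT + REF) cells.  In a pure tumor cluster carrying a heterozygous
driver, that fraction is expected near 50% at depth 1 and rises with depth —
a cell with d informative observations of a balanced heterozygote shows the
variant allele at least once with probability 1 - (1/2)^d.  The closed form
here generalizes that argument to an arbitrary observed depth distribution,
allelic imbalance p, a per-observation miscall-to-alt rate, and a minimum
alt-evidence threshold, so observed cluster fractions can be compared with
what heterozygosity actually predicts at the achieved coverage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .genotype import ALT, REF, UNKNOWN, CellGenotype
from .variants import ClusterAssignment

UNASSIGNED = "unassigned"


@dataclass
class ClusterMutationSummary:
    cluster: str
    n_cells: int
    n_covered: int  # ALT + REF
    n_alt_cells: int

    @property
    def covered_fraction(self) -> float:
        return self.n_covered / self.n_cells if self.n_cells else float("nan")

    @property
    def mutated_fraction(self) -> float | None:
        """ALT / (ALT + REF); None when no cell is covered."""
        if self.n_covered == 0:
            return None
        return self.n_alt_cells / self.n_covered

    @property
    def mutated_fraction_all_cells(self) -> float:
        return self.n_alt_cells / self.n_cells if self.n_cells else float("nan")


def summarize_by_cluster(
    genotypes: Iterable[CellGenotype],
    clusters: ClusterAssignment,
    include_unassigned: bool = True,
) -> list[ClusterMutationSummary]:
    """Per-cluster covered-cell counts and mutated fractions.

    Barcodes missing from the cluster table go to an "unassigned" bucket
    (dropped entirely when include_unassigned=False).  Output order follows
    first appearance of each cluster in the assignment, then unassigned.
    """
    tallies: dict[str, dict[str, int]] = {}
    order: list[str] = list(clusters.clusters)
    for label in order:
        tallies[label] = {ALT: 0, REF: 0, UNKNOWN: 0}
    for g in genotypes:
        cluster = clusters.get(g.barcode)
        if cluster is None:
            if not include_unassigned:
                continue
            cluster = UNASSIGNED
            if cluster not in tallies:
                tallies[cluster] = {ALT: 0, REF: 0, UNKNOWN: 0}
                order.append(cluster)
        tallies[cluster][g.label] += 1
    out = []
    for label in order:
        t = tallies[label]
        out.append(
            ClusterMutationSummary(
                cluster=label,
                n_cells=t[ALT] + t[REF] + t[UNKNOWN],
                n_covered=t[ALT] + t[REF],
                n_alt_cells=t[ALT],
            )
        )
    return out


def summaries_to_frame(
    summaries: Sequence[ClusterMutationSummary],
    expected: Mapping[str, float] | None = None,
    binomial_p: Mapping[str, float] | None = None,
) -> pd.DataFrame:
    """Tabulate summaries (optionally with expected fractions / test p-values)."""
    rows = []
    for s in summaries:
        row = {
            "cluster": s.cluster,
            "n_cells": s.n_cells,
            "n_covered": s.n_covered,
            "n_alt_cells": s.n_alt_cells,
            "covered_fraction": s.covered_fraction,
            "mutated_fraction": s.mutated_fraction,
            "mutated_fraction_all_cells": s.mutated_fraction_all_cells,
        }
        if expected is not None:
            row["expected_fraction"] = expected.get(s.cluster)
        if binomial_p is not None:
            row["binomial_p"] = binomial_p.get(s.cluster)
        rows.append(row)
    return pd.DataFrame(rows)


def bulk_vaf(n_alt_reads: int, n_ref_reads: int) -> float:
    """Variant allele fraction: alt / (alt + ref) from bulk read counts."""
    if n_alt_reads < 0 or n_ref_reads < 0:
        raise ValueError("read counts must be non-negative")
    total = n_alt_reads + n_ref_reads
    if total == 0:
        raise ValueError("zero total depth: VAF undefined")
    return n_alt_reads / total


def expected_het_fraction(
    depth_hist: Mapping[int, float | int],
    p: float = 0.5,
    epsilon: float = 0.0,
    min_alt_evidence: int = 1,
) -> float:
    """Expected ALT-labeled fraction among covered heterozygous cells.

    Each of a cell's d informative observations shows the variant allele with
    probability q = p + (1 - p) * epsilon (a true alt draw, or a ref draw
    miscalled to the alt base).  The cell is labeled ALT when at least
    min_alt_evidence observations show the variant, so

        E = sum_d w_d * P[Binom(d, q) >= min_alt_evidence]

    with weights w_d the (normalized) histogram of informative depth d >= 1.
    With min_alt_evidence=1, epsilon=0 this is sum_d w_d (1 - (1-p)^d): the
    familiar 50% at d=1 for a balanced heterozygote.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"p must be in [0,1], got {p}")
    if not 0.0 <= epsilon < 1.0:
        raise ValueError(f"epsilon must be in [0,1), got {epsilon}")
    if min_alt_evidence < 1:
        raise ValueError("min_alt_evidence must be >= 1")
    items = [(int(d), float(w)) for d, w in depth_hist.items() if w > 0]
    if any(d < 1 for d, _ in items):
        raise ValueError("depth histogram must cover d >= 1 only")
    total = sum(w for _, w in items)
    if total <= 0:
        raise ValueError("empty depth histogram")
    q = p + (1.0 - p) * epsilon
    e = 0.0
    for d, w in items:
        # P[X >= m], X ~ Binom(d, q)
        e += (w / total) * float(stats.binom.sf(min_alt_evidence - 1, d, q))
    return e


def false_alt_rate(depth_hist: Mapping[int, float | int], error_to_alt: float,
                   min_alt_evidence: int = 1) -> float:
    """Expected ALT rate among covered homozygous-reference cells.

    A hom-ref cell's observation shows the alt base only through a miscall
    (probability error_to_alt, i.e. e/3 under a uniform substitution model);
    this is `expected_het_fraction` with p=0.
    """
    return expected_het_fraction(
        depth_hist, p=0.0, epsilon=error_to_alt, min_alt_evidence=min_alt_evidence
    )


def depth_histogram(genotypes: Iterable[CellGenotype]) -> dict[int, int]:
    """Histogram of informative depth (n_ref + n_alt) over covered cells."""
    hist: dict[int, int] = {}
    for g in genotypes:
        d = g.n_ref + g.n_alt
        if d >= 1:
            hist[d] = hist.get(d, 0) + 1
    return hist


def het_binomial_test(n_alt_cells: int, n_covered: int, expected: float) -> float:
    """Two-sided exact binomial test of an observed mutated fraction against
    the heterozygosity expectation.  Descriptive aid, not a tumor-call."""
    if n_covered < 1:
        return float("nan")
    return float(
        stats.binomtest(n_alt_cells, n_covered, expected, alternative="two-sided").pvalue
    )
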