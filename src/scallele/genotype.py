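"""Per-cell genotype classification at known SNV sites.

A cell is labeled ALT (mutated) if at least `min_alt_evidence` observations
carry the variant allele, REF (wildtype) if it has reference-allele evidence
and no qualifying alt evidence, and UNKNOWN when nothing informative covers
the site.  Evidence for a third base (neither ref nor alt) is, by default,
treated as no information: such a cell demonstrably does not "carry the
reference allele", but it does not carry the known variant either.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .pileup import CellAlleleCounts

ALT = "ALT"
REF = "REF"
UNKNOWN = "UNKNOWN"

LABELS = (ALT, REF, UNKNOWN)


@dataclass
class CellGenotype:
    """Per-cell call at one site (or combined over a sample's sites)."""

    barcode: str
    site_id: str
    label: str
    n_ref: int
    n_alt: int
    n_other: int
    evidence: str


def classify_cell(
    counts: CellAlleleCounts,
    min_alt_evidence: int = 1,
    other_policy: str = "unknown",
) -> CellGenotype:
    """Classify one cell at one site from its allele counts.

    Priority: ALT if n_alt >= min_alt_evidence; else REF if n_ref >= 1; else
    UNKNOWN.  other_policy controls cells whose only evidence is a third
    base: "unknown" (default) or "ref".
    """
    if other_policy not in ("unknown", "ref"):
        raise ValueError(f"unknown other_policy {other_policy!r}")
    if counts.n_alt >= min_alt_evidence:
        label = ALT
    elif counts.n_ref >= 1:
        label = REF
    elif counts.n_other >= 1 and other_policy == "ref":
        label = REF
    else:
        label = UNKNOWN
    return CellGenotype(
        barcode=counts.barcode,
        site_id=counts.site_id,
        label=label,
        n_ref=counts.n_ref,
        n_alt=counts.n_alt,
        n_other=counts.n_other,
        evidence=counts.evidence,
    )


def classify_all(
    counts: Iterable[CellAlleleCounts],
    min_alt_evidence: int = 1,
    other_policy: str = "unknown",
) -> list[CellGenotype]:
    return [classify_cell(c, min_alt_evidence, other_policy) for c in counts]


def genotype_from_row(row) -> CellGenotype:
    """Rebuild a CellGenotype from a genotype-table row (itertuples or dict)."""
    get = row._asdict().get if hasattr(row, "_asdict") else row.get
    return CellGenotype(
        barcode=str(get("barcode")),
        site_id=str(get("site_id")),
        label=str(get("label")),
        n_ref=int(get("n_ref")),
        n_alt=int(get("n_alt")),
        n_other=int(get("n_other")),
        evidence=str(get("evidence")),
    )


def classify_sample(
    per_site: Sequence[CellGenotype], combined_id: str = "combined"
) -> CellGenotype:
    """Combine one cell's per-site calls into a single label.

    Any ALT site makes the cell ALT; otherwise any REF site makes it REF;
    otherwise UNKNOWN.  Counts are summed across sites.  All inputs must
    share one barcode and one evidence level.
    """
    if not per_site:
        raise ValueError("classify_sample requires at least one site genotype")
    barcodes = {g.barcode for g in per_site}
    if len(barcodes) != 1:
        raise ValueError(f"mixed barcodes in classify_sample: {sorted(barcodes)}")
    labels = {g.label for g in per_site}
    if ALT in labels:
        label = ALT
    elif REF in labels:
        label = REF
    else:
        label = UNKNOWN
    return CellGenotype(
        barcode=per_site[0].barcode,
        site_id=combined_id,
        label=label,
        n_ref=sum(g.n_ref for g in per_site),
        n_alt=sum(g.n_alt for g in per_site),
        n_other=sum(g.n_other for g in per_site),
        evidence=per_site[0].evidence,
    )
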