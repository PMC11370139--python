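"""Splice-aware base extraction at a locus and per-cell allele counting.

The central primitive is the CIGAR walk: given a read's reference start, its
CIGAR and its query sequence, find the query base aligned to a reference
position.  Reference is consumed by {M, D, N, =, X}, query by {M, I, S, =, X};
a position under a deletion (D), an intron skip (N, ubiquitous in spliced
scRNA-seq alignments), a clip, or outside the aligned span yields no base.

Counts are aggregated per cell barcode (CB tag) at either read level or
UMI-consensus level (UB tag): under consensus, reads sharing (barcode, UMI)
derive from one molecule and collapse to a single observation by majority
base; a tied vote is uninformative and the molecule is discarded.
"""

from __future__ import annotations

import os
import re
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam

from .variants import VariantSite, normalize_barcode

# pysam cigartuples operation codes
_CIGAR_OPS = "MIDNSHP=X"
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")

_CONSUMES_REF = frozenset("MDN=X")
_CONSUMES_QUERY = frozenset("MIS=X")


def _cigar_to_tuples(cigar: str) -> list[tuple[str, int]]:
    parsed = [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for op, n in parsed) != cigar:
        raise ValueError(f"malformed CIGAR string: {cigar!r}")
    return parsed


def base_at_position(
    ref_start: int,
    cigar: str | Sequence[tuple[int, int]],
    seq: str,
    quals: Sequence[int] | None,
    pos: int,
) -> tuple[str, int | None] | None:
    """Return (base, base_quality) the read reports at reference position `pos`.

    Parameters
    ----------
    ref_start
        1-based reference coordinate of the first aligned base.
    cigar
        CIGAR string, or pysam-style list of (op_code, length) tuples.
    seq
        Query sequence (as stored, soft clips included).
    quals
        Phred base qualities parallel to `seq`, or None if unavailable.
    pos
        1-based reference coordinate to interrogate.

    Returns None when the position is uncovered: under a D or N operation,
    within a clip, or outside the read's aligned reference span.
    """
    if isinstance(cigar, str):
        ops = _cigar_to_tuples(cigar)
    else:
        ops = [(_CIGAR_OPS[code], length) for code, length in cigar]

    qlen = sum(n for op, n in ops if op in _CONSUMES_QUERY)
    if qlen != len(seq):
        raise ValueError(
            f"CIGAR consumes {qlen} query bases but sequence has {len(seq)}"
        )

    ref = ref_start
    query = 0
    for op, n in ops:
        in_ref = op in _CONSUMES_REF
        in_query = op in _CONSUMES_QUERY
        if in_ref and ref <= pos < ref + n:
            if in_query:  # M, =, X
                qi = query + (pos - ref)
                qual = quals[qi] if quals is not None else None
                return seq[qi], qual
            return None  # D or N spans the site
        if in_ref:
            ref += n
        if in_query:
            query += n
    return None  # outside aligned span (or pos < ref_start)


@dataclass
class PileupFilters:
    """Read/observation filters for site pileup.

    Defaults follow common single-cell allele-counting practice: Q20 bases,
    any mapping quality, drop unmapped/secondary/supplementary/QC-fail.
    Flag-marked duplicates are NOT excluded — 10x duplicate marking is
    UMI-based and handled by umi_mode instead.
    """

    min_base_quality: int = 20
    min_mapping_quality: int = 0
    exclude_flags: int = (
        pysam.FUNMAP | pysam.FSECONDARY | pysam.FSUPPLEMENTARY | pysam.FQCFAIL
    )
    require_cb: bool = True
    strip_suffix: bool = True


@dataclass
class CellAlleleCounts:
    """Per (cell, site) tallies of ref/alt/other base evidence."""

    barcode: str
    site_id: str
    n_ref: int = 0
    n_alt: int = 0
    n_other: int = 0
    evidence: str = "read"  # "read" or "umi"

    @property
    def depth(self) -> int:
        return self.n_ref + self.n_alt + self.n_other


@dataclass
class ReadObservation:
    """One filter-passing base observation at a site."""

    barcode: str
    umi: str | None
    base: str
    base_quality: int
    mapping_quality: int


def collect_observations(
    alignments: pysam.AlignmentFile,
    site: VariantSite,
    filters: PileupFilters,
    chrom_alias: Mapping[str, str] | None = None,
) -> list[ReadObservation]:
    """Fetch reads over the site and extract filter-passing base observations."""
    chrom = site.chrom
    if chrom not in alignments.references:
        if chrom_alias and chrom_alias.get(chrom) in alignments.references:
            chrom = chrom_alias[chrom]
        else:
            raise ValueError(
                f"chromosome {site.chrom!r} not in alignment header; "
                f"available contigs: {', '.join(alignments.references)}"
            )
    obs: list[ReadObservation] = []
    for read in alignments.fetch(chrom, site.pos - 1, site.pos):
        if read.flag & filters.exclude_flags:
            continue
        if read.mapping_quality < filters.min_mapping_quality:
            continue
        if read.query_sequence is None:
            continue
        try:
            cb = read.get_tag("CB")
        except KeyError:
            if filters.require_cb:
                continue
            cb = ""
        hit = base_at_position(
            read.reference_start + 1,
            read.cigartuples,
            read.query_sequence,
            read.query_qualities,
            site.pos,
        )
        if hit is None:
            continue
        base, qual = hit
        if qual is not None and qual < filters.min_base_quality:
            continue
        try:
            umi = read.get_tag("UB")
        except KeyError:
            umi = None
        obs.append(
            ReadObservation(
                barcode=normalize_barcode(cb, filters.strip_suffix),
                umi=umi,
                base=base,
                base_quality=qual if qual is not None else -1,
                mapping_quality=read.mapping_quality,
            )
        )
    return obs


def _umi_consensus(observations: Iterable[ReadObservation]) -> dict[str, list[str]]:
    """Collapse observations sharing (barcode, UMI) to one majority base.

    Returns barcode -> list of consensus bases.  A tie in the majority vote
    discards that molecule; observations without a UMI each count as their
    own molecule.
    """
    groups: dict[tuple[str, str], list[str]] = defaultdict(list)
    singletons: dict[str, list[str]] = defaultdict(list)
    for o in observations:
        if o.umi is None:
            singletons[o.barcode].append(o.base)
        else:
            groups[(o.barcode, o.umi)].append(o.base)
    out: dict[str, list[str]] = defaultdict(list)
    for bc, bases in singletons.items():
        out[bc].extend(bases)
    for (bc, _umi), bases in sorted(groups.items()):
        counts = Counter(bases).most_common()
        if len(counts) > 1 and counts[0][1] == counts[1][1]:
            continue  # tied duplex: uninformative, drop the molecule
        out[bc].append(counts[0][0])
    return out


def tally_observations(
    observations: Sequence[ReadObservation],
    site: VariantSite,
    umi_mode: str = "auto",
) -> list[CellAlleleCounts]:
    """Aggregate base observations into per-barcode allele counts.

    umi_mode: "read" counts every observation; "consensus" collapses
    (barcode, UMI) groups by majority vote; "auto" uses consensus when any
    observation carries a UMI, read otherwise.
    """
    if umi_mode not in ("read", "consensus", "auto"):
        raise ValueError(f"unknown umi_mode {umi_mode!r}")
    if umi_mode == "auto":
        umi_mode = (
            "consensus" if any(o.umi is not None for o in observations) else "read"
        )

    if umi_mode == "consensus":
        per_barcode = _umi_consensus(observations)
    else:
        per_barcode = defaultdict(list)
        for o in observations:
            per_barcode[o.barcode].append(o.base)

    evidence = "umi" if umi_mode == "consensus" else "read"
    out: list[CellAlleleCounts] = []
    for bc in sorted(per_barcode):
        counts = CellAlleleCounts(bc, site.key, evidence=evidence)
        for base in per_barcode[bc]:
            if base == site.ref:
                counts.n_ref += 1
            elif base == site.alt:
                counts.n_alt += 1
            else:
                counts.n_other += 1
        out.append(counts)
    return out


def pileup_site(
    alignments: str | os.PathLike | pysam.AlignmentFile,
    site: VariantSite,
    filters: PileupFilters | None = None,
    umi_mode: str = "auto",
    chrom_alias: Mapping[str, str] | None = None,
) -> list[CellAlleleCounts]:
    """Per-cell allele counts at a variant site from a barcoded BAM.

    The alignment file must be coordinate-sorted and indexed.  Every retained
    observation is assigned to exactly one barcode; reads failing the filters
    contribute nothing.  Output is sorted by barcode for determinism.
    """
    filters = filters or PileupFilters()
    if isinstance(alignments, pysam.AlignmentFile):
        obs = collect_observations(alignments, site, filters, chrom_alias)
    else:
        path = os.fspath(alignments)
        with pysam.AlignmentFile(path) as bam:
            if not bam.has_index():
                raise FileNotFoundError(
                    f"alignment index not found for {path} (expected {path}.bai); "
                    "run samtools index first"
                )
            obs = collect_observations(bam, site, filters, chrom_alias)
    return tally_observations(obs, site, umi_mode)
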