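"""Variant-site lists, barcode normalization, cluster tables and genotype tables.

User-facing coordinates are 1-based throughout (VCF convention); the pileup
engine converts to 0-based internally.  Only single-nucleotide variants are
accepted: the driver mutations this tool targets (e.g. *CTNNB1* exon-3
hotspots S33/S37/T41) are point substitutions, and silently genotyping an
indel with SNV logic would produce wrong answers.
"""

from __future__ import annotations

import gzip
import io
import os
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import pysam

_BASES = frozenset("ACGT")

GENOTYPE_COLUMNS = [
    "barcode",
    "site_id",
    "label",
    "n_ref",
    "n_alt",
    "n_other",
    "evidence",
]


@dataclass(frozen=True)
class VariantSite:
    """A known SNV locus (1-based position, single-base ref/alt alleles)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref not in _BASES or self.alt not in _BASES:
            raise ValueError(
                f"indel/MNV not supported: ref={self.ref!r} alt={self.alt!r} "
                "(single uppercase A/C/G/T required)"
            )
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical ({self.ref})")

    @property
    def key(self) -> str:
        """Stable identifier: the explicit id, else chrom:pos:ref>alt."""
        return self.id or f"{self.chrom}:{self.pos}:{self.ref}>{self.alt}"


def normalize_barcode(barcode: str, strip_suffix: bool = True) -> str:
    """Strip a trailing '-<int>' GEM-well suffix (CellRanger convention).

    CellRanger barcodes.tsv and BAM CB tags carry the suffix ('AAAC...-1');
    user-supplied cluster tables often do not.  Set strip_suffix=False to
    require exact matches.
    """
    if strip_suffix:
        return re.sub(r"-\d+$", "", barcode)
    return barcode


def _open_text(path: str | os.PathLike) -> io.TextIOBase:
    path = os.fspath(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path, "rt")


def parse_variants(path: str | os.PathLike) -> list[VariantSite]:
    """Read SNV sites from a VCF (sites columns) or a 4+ column TSV.

    Files named *.vcf / *.vcf.gz are parsed as VCF; multi-allelic records are
    split into one site per ALT allele.  Anything else is read as a
    tab-delimited table with columns chrom, pos (1-based), ref, alt and an
    optional fifth id column; '#'-prefixed lines are skipped.

    Raises ValueError on indels, MNVs, symbolic alleles or malformed
    coordinates, naming the offending record.
    """
    path = os.fspath(path)
    if path.endswith((".vcf", ".vcf.gz")):
        return _parse_vcf(path)
    return _parse_tsv(path)


def _parse_vcf(path: str) -> list[VariantSite]:
    sites: list[VariantSite] = []
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            where = f"{rec.chrom}:{rec.pos}"
            if rec.alts is None:
                raise ValueError(f"record {where} has no ALT allele")
            for alt in rec.alts:
                if len(rec.ref) != 1 or len(alt) != 1 or not set(rec.ref + alt) <= _BASES:
                    raise ValueError(
                        f"indel/MNV not supported at {where} "
                        f"(REF={rec.ref} ALT={alt})"
                    )
                vid = rec.id if rec.id not in (None, ".") else None
                sites.append(VariantSite(rec.chrom, rec.pos, rec.ref, alt, id=vid))
    return sites


def _parse_tsv(path: str) -> list[VariantSite]:
    sites: list[VariantSite] = []
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 4:
                raise ValueError(
                    f"{path}:{lineno}: expected >=4 tab-delimited columns "
                    f"(chrom, pos, ref, alt), got {len(fields)}"
                )
            chrom, pos_s, ref, alt = fields[:4]
            try:
                pos = int(pos_s)
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed coordinate {pos_s!r}")
            vid = fields[4] if len(fields) > 4 and fields[4] else None
            try:
                sites.append(VariantSite(chrom, pos, ref.upper(), alt.upper(), id=vid))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return sites


def write_variants(sites: Iterable[VariantSite], path: str | os.PathLike) -> None:
    """Write sites as a 5-column TSV (chrom, pos, ref, alt, id)."""
    with open(path, "wt") as fh:
        fh.write("#chrom\tpos\tref\talt\tid\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.pos}\t{s.ref}\t{s.alt}\t{s.id or ''}\n")


@dataclass
class ClusterAssignment:
    """Mapping from normalized cell barcode to cluster label."""

    assignments: dict[str, str] = field(default_factory=dict)

    def __getitem__(self, barcode: str) -> str:
        return self.assignments[barcode]

    def get(self, barcode: str, default: str | None = None) -> str | None:
        return self.assignments.get(barcode, default)

    def __len__(self) -> int:
        return len(self.assignments)

    def __contains__(self, barcode: str) -> bool:
        return barcode in self.assignments

    @property
    def clusters(self) -> list[str]:
        seen: dict[str, None] = {}
        for label in self.assignments.values():
            seen.setdefault(label, None)
        return list(seen)


def parse_clusters(
    path: str | os.PathLike, strip_suffix: bool = True
) -> ClusterAssignment:
    """Read a two-column barcode→cluster TSV ('#' comments skipped).

    Barcodes are normalized (GEM-well suffix stripped unless
    strip_suffix=False).  Duplicate barcodes after normalization and empty
    tables are errors.
    """
    mapping: dict[str, str] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns (barcode, cluster)"
                )
            bc = normalize_barcode(fields[0], strip_suffix)
            if bc in mapping:
                raise ValueError(f"{path}:{lineno}: duplicate barcode {fields[0]!r}")
            mapping[bc] = fields[1]
    if not mapping:
        raise ValueError(f"empty cluster table: {path}")
    return ClusterAssignment(mapping)


def read_barcodes(path: str | os.PathLike, strip_suffix: bool = True) -> list[str]:
    """Read a CellRanger-style barcodes.tsv (one barcode per line, .gz ok)."""
    with _open_text(path) as fh:
        return [normalize_barcode(line.strip(), strip_suffix) for line in fh if line.strip()]


def write_genotypes(genotypes: Iterable, path: str | os.PathLike) -> None:
    """Write per-cell genotype calls as TSV.

    Columns: barcode, site_id, label, n_ref, n_alt, n_other, evidence.
    Round-trips losslessly through :func:`read_genotypes`.
    """
    rows = [
        {
            "barcode": g.barcode,
            "site_id": g.site_id,
            "label": g.label,
            "n_ref": g.n_ref,
            "n_alt": g.n_alt,
            "n_other": g.n_other,
            "evidence": g.evidence,
        }
        for g in genotypes
    ]
    df = pd.DataFrame(rows, columns=GENOTYPE_COLUMNS)
    df.to_csv(path, sep="\t", index=False)


def read_genotypes(path: str | os.PathLike) -> pd.DataFrame:
    """Read a genotype TSV written by :func:`write_genotypes`."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "barcode": str,
            "site_id": str,
            "label": str,
            "evidence": str,
            "n_ref": int,
            "n_alt": int,
            "n_other": int,
        },
    )
    missing = set(GENOTYPE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"genotype table {path} missing columns: {sorted(missing)}")
    return df


def make_chrom_alias(names: Iterable[str]) -> Mapping[str, str]:
    """Build a 'chr'-prefix aliasing map onto the given contig names.

    For each contig in `names`, both the prefixed and unprefixed spelling map
    to the spelling the alignment header actually uses.  Without such a map,
    chromosome names must match the header exactly.
    """
    alias: dict[str, str] = {}
    for name in names:
        alias[name] = name
        if name.startswith("chr"):
            alias.setdefault(name[3:], name)
        else:
            alias.setdefault("chr" + name, name)
    return alias
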