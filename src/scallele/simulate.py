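"""Seeded generators of barcoded alignments and expression matrices with truth.

`simulate_bam` emulates a 10x-style library over a single known SNV in a
droplet experiment: each cell is homozygous-reference or heterozygous for
the variant, molecules (UMIs) are sampled at Poisson depth, each molecule's
allele is drawn independently (alt with probability p for heterozygotes),
molecules are amplified into duplicate reads, bases are miscalled uniformly
to the three other bases at a per-base rate, and a configurable fraction of
reads is spliced so that an N operation skips the site — exercising the
splice-aware pileup.  A truth table consistent record-for-record with the
emitted BAM is returned alongside.

`simulate_expression` plants an active gene set: all genes follow a
negative-binomial law with lognormal gene-level means; in active cells the
set genes' means are inflated by a multiplicative effect, shifting their
expected ranks upward.  Truth labels are returned for both generators.

All randomness flows from the single seed; re-runs are bit-identical.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import pysam
import scipy.io
import scipy.sparse

from .variants import VariantSite

HOM_REF = "hom_ref"
HET = "het"

_BASES = np.array(list("ACGT"))

DEFAULT_SITE = VariantSite("chrS", 1000, "C", "T", id="sim:site1")


@dataclass
class SimConfig:
    """Study conditions for the alignment simulator.

    depth_mean is the Poisson mean number of molecules covering the site per
    cell; the zero class is kept so UNKNOWN cells occur naturally.
    error_rate is the per-base substitution rate (e/3 to each other base).
    dup_mean controls UMI duplication: reads per molecule = 1 + Poisson(dup_mean).
    spliced_fraction is the per-read probability that an N skip spans the site.
    alt_prob is the probability a heterozygous molecule carries the alt allele.
    """

    n_cells: int = 1000
    frac_het: float = 0.5  # remainder is homozygous-reference
    depth_mean: float = 2.0
    depth_max: int | None = None
    error_rate: float = 0.001
    dup_mean: float = 0.5
    spliced_fraction: float = 0.2
    alt_prob: float = 0.5
    read_length: int = 91
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.frac_het <= 1.0:
            raise ValueError("frac_het must be in [0,1]")
        if self.depth_mean <= 0:
            raise ValueError("depth_mean must be > 0")
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error_rate must be in [0,1)")


@dataclass
class TruthTable:
    """Per-cell and per-read ground truth matching the emitted alignments."""

    cells: pd.DataFrame  # barcode, genotype, n_molecules, depth_umi, depth_read
    reads: pd.DataFrame  # read name, barcode, umi, true_allele, emitted_base, spliced


def _random_strings(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """n distinct random ACGT strings of the given length."""
    out: list[str] = []
    seen: set[str] = set()
    while len(out) < n:
        s = "".join(rng.choice(_BASES, size=length))
        if s not in seen:
            seen.add(s)
            out.append(s)
    return out


def _miscall(rng: np.random.Generator, base: str, error_rate: float) -> str:
    if error_rate > 0 and rng.random() < error_rate:
        return str(rng.choice([b for b in "ACGT" if b != base]))
    return base


def simulate_bam(
    config: SimConfig,
    site: VariantSite = DEFAULT_SITE,
    out_path: str | os.PathLike | None = None,
) -> tuple[list[pysam.AlignedSegment], TruthTable, pysam.AlignmentHeader]:
    """Generate barcoded reads over `site` with known per-cell genotypes.

    When out_path is given, a coordinate-sorted, indexed BAM is written
    there (truth tables are written next to it as <out>.truth_cells.tsv and
    <out>.truth_reads.tsv).  The records, truth and header are returned
    either way.
    """
    rng = np.random.default_rng(config.seed)
    gap = 100  # intron span of spliced reads; wide enough to cover the site
    contig_len = site.pos + config.read_length + gap + 1000
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": site.chrom, "LN": contig_len}],
        }
    )

    barcodes = [b + "-1" for b in _random_strings(rng, config.n_cells, 16)]
    genotypes = np.where(
        rng.random(config.n_cells) < config.frac_het, HET, HOM_REF
    )

    records: list[pysam.AlignedSegment] = []
    cell_rows = []
    read_rows = []
    read_serial = 0
    for bc, gt in zip(barcodes, genotypes):
        n_mol = int(rng.poisson(config.depth_mean))
        if config.depth_max is not None:
            n_mol = min(n_mol, config.depth_max)
        umis = _random_strings(rng, n_mol, 12) if n_mol else []
        depth_umi = 0
        depth_read = 0
        for umi in umis:
            if gt == HET:
                allele = site.alt if rng.random() < config.alt_prob else site.ref
            else:
                allele = site.ref
            n_reads = 1 + int(rng.poisson(config.dup_mean))
            covered = False
            for _ in range(n_reads):
                spliced = bool(rng.random() < config.spliced_fraction)
                emitted = _miscall(rng, allele, config.error_rate)
                rec = _make_read(
                    rng, header, site, config.read_length, gap,
                    name=f"read{read_serial:08d}", barcode=bc, umi=umi,
                    site_base=emitted, spliced=spliced,
                )
                read_serial += 1
                records.append(rec)
                read_rows.append(
                    {
                        "read": rec.query_name,
                        "barcode": bc,
                        "umi": umi,
                        "true_allele": allele,
                        "emitted_base": emitted,
                        "spliced": spliced,
                    }
                )
                if not spliced:
                    covered = True
                    depth_read += 1
            if covered:
                depth_umi += 1
        cell_rows.append(
            {
                "barcode": bc,
                "genotype": gt,
                "n_molecules": n_mol,
                "depth_umi": depth_umi,
                "depth_read": depth_read,
            }
        )

    records.sort(key=lambda r: (r.reference_start, r.query_name))
    truth = TruthTable(
        cells=pd.DataFrame(
            cell_rows,
            columns=["barcode", "genotype", "n_molecules", "depth_umi", "depth_read"],
        ),
        reads=pd.DataFrame(
            read_rows,
            columns=["read", "barcode", "umi", "true_allele", "emitted_base", "spliced"],
        ),
    )
    if out_path is not None:
        out_path = os.fspath(out_path)
        with pysam.AlignmentFile(out_path, "wb", header=header) as bam:
            for rec in records:
                bam.write(rec)
        pysam.index(out_path)
        truth.cells.to_csv(out_path + ".truth_cells.tsv", sep="\t", index=False)
        truth.reads.to_csv(out_path + ".truth_reads.tsv", sep="\t", index=False)
    return records, truth, header


def _make_read(
    rng: np.random.Generator,
    header: pysam.AlignmentHeader,
    site: VariantSite,
    read_length: int,
    gap: int,
    name: str,
    barcode: str,
    umi: str,
    site_base: str,
    spliced: bool,
) -> pysam.AlignedSegment:
    """Build one aligned read; if spliced, an N block spans the site."""
    seq = rng.choice(_BASES, size=read_length)
    rec = pysam.AlignedSegment(header)
    rec.query_name = name
    rec.flag = 0
    rec.reference_id = 0
    rec.mapping_quality = 255
    if spliced:
        # exon1 [start, start+a) | N gap containing the site | exon2
        a = int(rng.integers(1, read_length))  # exon1 length
        j = int(rng.integers(0, gap))  # site offset into the gap
        gap_start = site.pos - j  # 1-based first skipped position
        start = gap_start - a
        if start < 1:
            a = min(a, gap_start - 1)
            start = gap_start - a
        rec.reference_start = start - 1
        rec.cigarstring = f"{a}M{gap}N{read_length - a}M"
    else:
        offset = int(rng.integers(0, read_length))  # site's offset in the read
        start = site.pos - offset
        if start < 1:
            offset = site.pos - 1
            start = 1
        seq[offset] = site_base
        rec.reference_start = start - 1
        rec.cigarstring = f"{read_length}M"
    rec.query_sequence = "".join(seq)
    rec.query_qualities = pysam.qualitystring_to_array("I" * read_length)  # Q40
    rec.set_tag("CB", barcode)
    rec.set_tag("UB", umi)
    return rec


def simulate_expression(
    n_genes: int = 2000,
    n_cells_active: int = 200,
    n_cells_inactive: int = 200,
    set_size: int = 50,
    effect: float = 3.0,
    dispersion: float = 2.0,
    mean_log_mu: float = 0.0,
    mean_log_sigma: float = 1.0,
    seed: int = 0,
) -> tuple[ad.AnnData, list[str], np.ndarray]:
    """Count matrix with a planted active gene set.

    Gene-level base means are lognormal; counts are negative-binomial with
    the given dispersion (size) parameter.  Active cells draw the set genes
    with means inflated by (1 + effect); effect=0 reduces to the null.

    Returns (AnnData cells x genes, planted gene-set member names, boolean
    truth labels with True = active).
    """
    if set_size > n_genes:
        raise ValueError("set_size cannot exceed n_genes")
    rng = np.random.default_rng(seed)
    n_cells = n_cells_active + n_cells_inactive
    genes = [f"G{i:05d}" for i in range(n_genes)]
    set_genes = [genes[i] for i in rng.choice(n_genes, size=set_size, replace=False)]
    set_mask = np.isin(np.array(genes), np.array(set_genes))

    base_mean = rng.lognormal(mean_log_mu, mean_log_sigma, size=n_genes)
    active = np.zeros(n_cells, dtype=bool)
    active[:n_cells_active] = True
    perm = rng.permutation(n_cells)
    active = active[perm]

    means = np.tile(base_mean, (n_cells, 1))
    means[np.ix_(active, set_mask)] *= 1.0 + effect
    # NB(mean m, size r): p = r / (r + m)
    r = dispersion
    p = r / (r + means)
    counts = rng.negative_binomial(r, p)

    adata = ad.AnnData(X=scipy.sparse.csr_matrix(counts.astype(np.float64)))
    adata.obs_names = [f"cell{i:05d}" for i in range(n_cells)]
    adata.var_names = genes
    adata.obs["active"] = active
    return adata, set_genes, active


def write_mtx_triplet(adata: ad.AnnData, out_dir: str | os.PathLike) -> None:
    """Write a CellRanger-layout MTX triplet (matrix genes x cells)."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    x = adata.X
    mat = x.T.tocoo() if scipy.sparse.issparse(x) else scipy.sparse.coo_matrix(np.asarray(x).T)
    scipy.io.mmwrite(os.path.join(out_dir, "matrix.mtx"), mat)
    with open(os.path.join(out_dir, "barcodes.tsv"), "wt") as fh:
        fh.writelines(b + "\n" for b in adata.obs_names)
    with open(os.path.join(out_dir, "features.tsv"), "wt") as fh:
        fh.writelines(f"{g}\t{g}\tGene Expression\n" for g in adata.var_names)
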