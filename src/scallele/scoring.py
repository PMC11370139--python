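"""Rank-based per-cell gene-set activity scoring (recovery-curve AUC).

For each cell, genes are ordered by decreasing expression; the score for a
gene set S is the area under its recovery curve H(k) = |{g in S : rank(g)
<= k}| within the top T = floor(theta * n_genes) ranks, normalized by the
maximal achievable area (all set genes occupying the top ranks):

    auc = sum_{k=1..T} H(k) / sum_{k=1..T} min(k, |S|)

so a perfectly top-ranked set scores exactly 1 regardless of |S| versus T.
The score depends only on ranks, hence is invariant under any strictly
monotone transform of a cell's expression values (raw counts, CPM and
log-normalized values all give the same answer up to tie structure).

Droplet data is zero-dominant, so tie handling matters: ties — including the
large zero block — are broken by a seeded uniform shuffle.  Average-rank
tie-breaking would let a set of entirely unexpressed genes collect
fractional recovery from the zero block and inflate its score; random
tie-break keeps unexpressed sets at chance level while staying reproducible
for a fixed seed.
"""

from __future__ import annotations

import hashlib
import logging
import math
import os
from dataclasses import dataclass
from typing import Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .variants import _open_text, normalize_barcode

logger = logging.getLogger(__name__)


@dataclass
class SignatureScore:
    barcode: str
    gene_set: str
    auc: float
    threshold_rank: int
    n_set_genes_in_universe: int


def read_gmt(path: str | os.PathLike) -> dict[str, list[str]]:
    """Read gene sets from a GMT file (name, description, members...)."""
    from gseapy.parser import read_gmt as _gseapy_read_gmt

    sets = _gseapy_read_gmt(os.fspath(path))
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(sets: Mapping[str, Sequence[str]], path: str | os.PathLike,
              description: str = "na") -> None:
    with open(path, "wt") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def read_mtx_triplet(
    mtx: str | os.PathLike,
    barcodes: str | os.PathLike,
    features: str | os.PathLike,
    strip_suffix: bool = True,
) -> ad.AnnData:
    """Load a CellRanger-style genes-x-cells MTX triplet as cells-x-genes AnnData.

    features.tsv may have 1+ columns (id, symbol, ...); the first column is
    used as the gene identifier.  Gzipped files are accepted.
    """
    mat = scipy.io.mmread(os.fspath(mtx)).tocsr().T.tocsr()  # cells x genes
    with _open_text(barcodes) as fh:
        bcs = [normalize_barcode(l.strip().split("\t")[0], strip_suffix)
               for l in fh if l.strip()]
    with _open_text(features) as fh:
        genes = [l.rstrip("\n").split("\t")[0] for l in fh if l.strip()]
    if mat.shape != (len(bcs), len(genes)):
        raise ValueError(
            f"matrix is {mat.shape[1]}x{mat.shape[0]} (genes x cells) but "
            f"features has {len(genes)} rows and barcodes {len(bcs)}"
        )
    if len(set(genes)) != len(genes):
        raise ValueError("duplicate gene identifiers in features file")
    adata = ad.AnnData(X=mat)
    adata.obs_names = bcs
    adata.var_names = genes
    return adata


def rank_genes(values: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Rank genes by decreasing value; ties broken by a seeded uniform shuffle.

    Returns ranks[i] = rank of gene i (1 = highest expression).  For a fixed
    generator state the order is deterministic; within a tied block every
    permutation is equally likely.
    """
    values = np.asarray(values)
    n = values.shape[0]
    perm = rng.permutation(n)
    # stable sort of a pre-shuffled array: uniform order within tied blocks
    order = perm[np.argsort(-values[perm], kind="stable")]
    ranks = np.empty(n, dtype=np.int64)
    ranks[order] = np.arange(1, n + 1)
    return ranks


def recovery_auc(ranks: np.ndarray, set_indices: np.ndarray, top_fraction: float = 0.05) -> float:
    """Normalized recovery-curve area for one cell and one gene set.

    Parameters
    ----------
    ranks
        rank of every gene in the universe (1 = highest), as from rank_genes.
    set_indices
        indices (into the universe) of the set's genes present in the universe.
    top_fraction
        theta; the recovery curve is integrated over ranks 1..floor(theta*n).
    """
    if not 0.0 < top_fraction <= 1.0:
        raise ValueError(f"top_fraction must be in (0,1], got {top_fraction}")
    n = ranks.shape[0]
    s = len(set_indices)
    if s == 0:
        raise ValueError("gene set has no members in the universe")
    t = math.floor(top_fraction * n)
    if t < 1:
        raise ValueError(f"threshold rank floor({top_fraction}*{n}) is zero")
    # sum_{k=1..T} H(k): a set gene at rank r <= T contributes (T - r + 1)
    set_ranks = ranks[set_indices]
    inside = set_ranks[set_ranks <= t]
    area = int(np.sum(t - inside + 1))
    # maximal area sum_{k=1..T} min(k, s) = s_eff*(s_eff+1)/2 + (T - s_eff)*s_eff
    s_eff = min(s, t)
    max_area = s_eff * (s_eff + 1) // 2 + (t - s_eff) * s_eff
    return area / max_area


def score_matrix(
    adata: ad.AnnData,
    gene_sets: Mapping[str, Sequence[str]],
    top_fraction: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Score every cell against every gene set; one row per (cell, set).

    Genes absent from the matrix are dropped from each set (count logged);
    a set with zero overlap is scored as missing (NaN) with a warning.
    Per-cell tie-break randomness derives from (seed, barcode), so a cell's
    score does not depend on where it sits in the matrix: permuting cell
    order permutes the output rows only.
    """
    var_index = {g: i for i, g in enumerate(adata.var_names)}
    n_genes = adata.n_vars
    set_idx: dict[str, np.ndarray] = {}
    for name, genes in gene_sets.items():
        idx = np.array(sorted({var_index[g] for g in genes if g in var_index}),
                       dtype=np.int64)
        dropped = len(set(genes)) - len(idx)
        if dropped:
            logger.info("gene set %s: %d/%d genes absent from matrix, dropped",
                        name, dropped, len(set(genes)))
        if len(idx) == 0:
            logger.warning("gene set %s has no genes in the matrix; scores set "
                           "to NaN", name)
        set_idx[name] = idx

    x = adata.X
    dense = x.toarray() if scipy.sparse.issparse(x) else np.asarray(x)
    t = math.floor(top_fraction * n_genes)
    rows = []
    for ci, barcode in enumerate(adata.obs_names):
        digest = hashlib.blake2b(barcode.encode(), digest_size=8).digest()
        rng = np.random.default_rng(
            np.random.SeedSequence([seed, int.from_bytes(digest, "little")])
        )
        ranks = rank_genes(dense[ci], rng)
        for name, idx in set_idx.items():
            auc = (recovery_auc(ranks, idx, top_fraction)
                   if len(idx) else float("nan"))
            rows.append(
                {"barcode": barcode, "gene_set": name, "auc": auc,
                 "threshold_rank": t, "n_set_genes_in_universe": len(idx)}
            )
    return pd.DataFrame(rows)
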