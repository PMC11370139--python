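"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately literal: per-base CIGAR expansion, full-file
recounts, step-function AUC accumulation.  None of it shares code with the
package under test.
"""

from __future__ import annotations

from collections import Counter, defaultdict

import numpy as np
import pysam

CIGAR_OPS = "MIDNSHP=X"


def expand_cigar(ref_start: int, ops: list[tuple[str, int]]) -> dict[int, int | None]:
    """Literal per-base expansion: reference position -> query index (or None
    under D/N).  ref_start is 1-based."""
    mapping: dict[int, int | None] = {}
    ref, q = ref_start, 0
    for op, n in ops:
        for _ in range(n):
            if op in "M=X":
                mapping[ref] = q
                ref += 1
                q += 1
            elif op in "DN":
                mapping[ref] = None
                ref += 1
            elif op in "IS":
                q += 1
            # H and P touch neither sequence
    return mapping


def oracle_base_at(ref_start: int, ops: list[tuple[str, int]], seq: str,
                   quals, pos: int):
    """Base/quality at pos via per-base expansion; None when uncovered."""
    mapping = expand_cigar(ref_start, ops)
    qi = mapping.get(pos)
    if qi is None:
        return None
    return seq[qi], (quals[qi] if quals is not None else None)


def random_read(rng: np.random.Generator, max_blocks: int = 6):
    """A random plausible alignment: ops from {M,I,D,N,S}, M at both ends of
    the aligned core, S only terminal.  Returns (ref_start, ops, seq, quals)."""
    ops: list[tuple[str, int]] = []
    if rng.random() < 0.3:
        ops.append(("S", int(rng.integers(1, 10))))
    n_core = int(rng.integers(1, max_blocks + 1))
    for i in range(n_core):
        ops.append(("M", int(rng.integers(1, 30))))
        if i < n_core - 1:
            ops.append((str(rng.choice(["I", "D", "N"])), int(rng.integers(1, 40))))
    if rng.random() < 0.3:
        ops.append(("S", int(rng.integers(1, 10))))
    qlen = sum(n for op, n in ops if op in "MIS")
    seq = "".join(rng.choice(list("ACGT"), size=qlen))
    quals = [int(q) for q in rng.integers(0, 42, size=qlen)]
    ref_start = int(rng.integers(1, 500))
    return ref_start, ops, seq, quals


def naive_pileup(bam_path: str, chrom: str, pos: int, ref: str, alt: str,
                 min_base_quality: int = 20, min_mapping_quality: int = 0,
                 umi_consensus: bool = True) -> dict[str, tuple[int, int, int]]:
    """Full-file recount: iterate every read, expand its CIGAR per base, and
    tally ref/alt/other per barcode.  Returns barcode -> (n_ref, n_alt, n_other)
    with the CellRanger '-<int>' suffix stripped from barcodes."""
    per_umi: dict[tuple[str, str], list[str]] = defaultdict(list)
    per_read: dict[str, list[str]] = defaultdict(list)
    with pysam.AlignmentFile(bam_path) as bam:
        for read in bam.fetch(until_eof=True):
            if read.is_unmapped or read.is_secondary or read.is_supplementary \
                    or read.is_qcfail:
                continue
            if read.reference_name != chrom:
                continue
            if read.mapping_quality < min_mapping_quality:
                continue
            if not read.has_tag("CB"):
                continue
            ops = [(CIGAR_OPS[c], n) for c, n in read.cigartuples]
            hit = oracle_base_at(read.reference_start + 1, ops,
                                 read.query_sequence, read.query_qualities, pos)
            if hit is None:
                continue
            base, qual = hit
            if qual is not None and qual < min_base_quality:
                continue
            bc = read.get_tag("CB")
            if "-" in bc and bc.rsplit("-", 1)[1].isdigit():
                bc = bc.rsplit("-", 1)[0]
            if umi_consensus and read.has_tag("UB"):
                per_umi[(bc, read.get_tag("UB"))].append(base)
            else:
                per_read[bc].append(base)

    bases_by_bc: dict[str, list[str]] = defaultdict(list)
    for bc, bases in per_read.items():
        bases_by_bc[bc].extend(bases)
    for (bc, _umi), bases in per_umi.items():
        tally = Counter(bases).most_common()
        if len(tally) > 1 and tally[0][1] == tally[1][1]:
            continue
        bases_by_bc[bc].append(tally[0][0])

    out = {}
    for bc, bases in bases_by_bc.items():
        n_ref = sum(b == ref for b in bases)
        n_alt = sum(b == alt for b in bases)
        out[bc] = (n_ref, n_alt, len(bases) - n_ref - n_alt)
    return out


def combine_labels_bruteforce(labels: list[str]) -> str:
    """Literal priority-order evaluation of the any-ALT / any-REF combine rule."""
    for want in ("ALT", "REF"):
        for lab in labels:
            if lab == want:
                return want
    return "UNKNOWN"


def step_function_auc(ranks_of_set: list[int], n_set: int, t: int) -> float:
    """Recovery-curve area by literal accumulation over k = 1..T."""
    area = 0
    max_area = 0
    hits = set(ranks_of_set)
    h = 0
    for k in range(1, t + 1):
        if k in hits:
            h += 1
        area += h
        max_area += min(k, n_set)
    return area / max_area
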