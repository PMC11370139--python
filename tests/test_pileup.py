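import numpy as np
import pytest

from _oracles import naive_pileup, oracle_base_at, random_read
from conftest import make_bam
from scallele.pileup import PileupFilters, base_at_position, pileup_site
from scallele.simulate import SimConfig, simulate_bam
from scallele.variants import VariantSite, make_chrom_alias


class TestBaseAtPosition:
    def test_pure_match_block(self):
        assert base_at_position(100, "50M", "A" * 50, [30] * 50, 120) == ("A", 30)

    def test_intron_skip_uncovered(self):
        # M covers 100-109, N covers 110-209: the site sits in the skip
        assert base_at_position(100, "10M100N40M", "G" * 50, None, 115) is None

    def test_softclip_and_deletion_offsets(self):
        # 5S10M2D10M from 100: M1 = ref 100-109 -> query 5-14; D = 110-111;
        # M2 = ref 112-121 -> query 15-24, so pos 112 reads query index 15
        seq = "ACGTA" + "CCCCCCCCCC" + "GTGTGTGTGT"
        base, qual = base_at_position(100, "5S10M2D10M", seq, list(range(25)), 112)
        assert (base, qual) == (seq[15], 15)

    def test_deletion_uncovered(self):
        assert base_at_position(100, "10M2D10M", "A" * 20, None, 110) is None
        assert base_at_position(100, "10M2D10M", "A" * 20, None, 112) == ("A", None)

    @pytest.mark.parametrize("pos", [99, 150, 1])
    def test_outside_span_uncovered(self, pos):
        assert base_at_position(100, "50M", "A" * 50, None, pos) is None

    def test_inconsistent_seq_length_rejected(self):
        with pytest.raises(ValueError, match="query bases"):
            base_at_position(100, "50M", "A" * 49, None, 120)

    def test_malformed_cigar_rejected(self):
        with pytest.raises(ValueError, match="CIGAR"):
            base_at_position(100, "50Q", "A" * 50, None, 120)

    def test_agrees_with_per_base_expander_on_random_reads(self):
        """CIGAR walk vs a literal per-base expansion over randomized
        alignments (ops from {M,I,D,N,S}) and randomized query positions."""
        rng = np.random.default_rng(20260930)
        for _ in range(400):
            ref_start, ops, seq, quals = random_read(rng)
            cigar = "".join(f"{n}{op}" for op, n in ops)
            span = sum(n for op, n in ops if op in "MDN=X")
            for _ in range(5):
                pos = int(rng.integers(max(1, ref_start - 5), ref_start + span + 5))
                got = base_at_position(ref_start, cigar, seq, quals, pos)
                assert got == oracle_base_at(ref_start, ops, seq, quals, pos)


class TestPileupSite:
    def test_read_mode_counts_every_read(self, tmp_path, site):
        reads = [
            dict(start=990, cigar="20M", seq="A" * 10 + "C" + "A" * 9, cb="X-1")
            for _ in range(3)
        ]
        bam = make_bam(tmp_path / "a.bam", reads)
        (counts,) = pileup_site(bam, site, umi_mode="read")
        assert (counts.n_ref, counts.n_alt, counts.n_other) == (3, 0, 0)
        assert counts.evidence == "read"

    def test_umi_consensus_majority_vote(self, tmp_path, site):
        # 4 reads, one UMI, bases {T,T,T,C} at a C>T site -> one alt molecule
        reads = [
            dict(start=990, cigar="20M", seq="A" * 10 + b + "A" * 9,
                 cb="Y-1", ub="UMI1")
            for b in "TTTC"
        ]
        bam = make_bam(tmp_path / "b.bam", reads)
        (counts,) = pileup_site(bam, site, umi_mode="consensus")
        assert (counts.n_ref, counts.n_alt, counts.n_other) == (0, 1, 0)
        assert counts.evidence == "umi"

    def test_umi_tie_discards_molecule(self, tmp_path, site):
        reads = [
            dict(start=990, cigar="20M", seq="A" * 10 + b + "A" * 9,
                 cb="Y-1", ub="UMI1")
            for b in "TC"
        ]
        bam = make_bam(tmp_path / "c.bam", reads)
        assert pileup_site(bam, site, umi_mode="consensus") == []

    def test_filters_drop_secondary_lowqual_and_untagged(self, tmp_path, site):
        alt_seq = "A" * 10 + "T" + "A" * 9
        reads = [
            dict(start=990, cigar="20M", seq=alt_seq, cb="Z-1"),          # kept
            dict(start=990, cigar="20M", seq=alt_seq, cb="Z-1", flag=256),  # secondary
            dict(start=990, cigar="20M", seq=alt_seq, cb="Z-1", flag=512),  # qcfail
            dict(start=990, cigar="20M", seq=alt_seq),                     # no CB
            dict(start=990, cigar="20M", seq=alt_seq, cb="Z-1",
                 qual="!" * 20),                                           # Q0 base
        ]
        bam = make_bam(tmp_path / "d.bam", reads)
        (counts,) = pileup_site(bam, site, umi_mode="read")
        assert counts.n_alt == 1

    def test_spliced_read_contributes_nothing(self, tmp_path, site):
        reads = [dict(start=900, cigar="50M200N41M", seq="G" * 91, cb="W-1")]
        bam = make_bam(tmp_path / "e.bam", reads)
        assert pileup_site(bam, site) == []

    def test_raising_base_quality_never_increases_counts(self, tmp_path, site):
        rng = np.random.default_rng(7)
        reads = []
        for i in range(40):
            qual = "".join(chr(33 + int(q)) for q in rng.integers(0, 41, 20))
            base = rng.choice(list("CTG"))
            reads.append(dict(start=990, cigar="20M",
                              seq="A" * 10 + base + "A" * 9,
                              cb=f"BC{i % 5}-1", qual=qual))
        bam = make_bam(tmp_path / "f.bam", reads)
        prev = None
        for q in (0, 10, 20, 30, 41):
            counts = {c.barcode: (c.n_ref, c.n_alt, c.n_other)
                      for c in pileup_site(bam, site, PileupFilters(min_base_quality=q),
                                           umi_mode="read")}
            if prev is not None:
                for bc, triple in counts.items():
                    assert all(a <= b for a, b in zip(triple, prev.get(bc, (0, 0, 0))))
            prev = counts

    def test_unknown_chrom_error_names_contigs(self, tmp_path, site):
        bam = make_bam(tmp_path / "g.bam",
                       [dict(start=990, cigar="20M", seq="A" * 20, cb="X-1")])
        bad = VariantSite("chr9", 1000, "C", "T")
        with pytest.raises(ValueError, match="chrS"):
            pileup_site(bam, bad)

    def test_chrom_alias_resolves_prefix_mismatch(self, tmp_path):
        bam = make_bam(tmp_path / "h.bam",
                       [dict(start=990, cigar="20M", seq="C" * 20, cb="X-1")],
                       chrom="chr3")
        unprefixed = VariantSite("3", 1000, "C", "T")
        alias = make_chrom_alias(["chr3"])
        (counts,) = pileup_site(bam, unprefixed, chrom_alias=alias)
        assert counts.n_ref == 1

    def test_missing_index_error(self, tmp_path, site):
        bam = make_bam(tmp_path / "i.bam",
                       [dict(start=990, cigar="20M", seq="A" * 20, cb="X-1")])
        (tmp_path / "i.bam.bai").unlink()
        with pytest.raises(FileNotFoundError, match="index"):
            pileup_site(bam, site)


class TestPileupAgainstNaiveRecount:
    """Pileup equals a literal full-file recount on simulated libraries."""

    @pytest.mark.parametrize("seed", range(8))
    def test_oracle_equivalence_and_conservation(self, tmp_path, seed):
        cfg = SimConfig(n_cells=40, depth_mean=2.0, error_rate=0.01,
                        dup_mean=1.0, spliced_fraction=0.3, seed=seed)
        bam = str(tmp_path / f"sim{seed}.bam")
        _, truth, _ = simulate_bam(cfg, out_path=bam)
        site = VariantSite("chrS", 1000, "C", "T")
        counts = pileup_site(bam, site, umi_mode="consensus")
        got = {c.barcode: (c.n_ref, c.n_alt, c.n_other) for c in counts}
        expect = naive_pileup(bam, "chrS", 1000, "C", "T")
        assert got == expect

    def test_conservation_against_truth_depth(self, tmp_path, site):
        """With no errors, per-cell depth equals the true number of molecules
        having at least one unspliced read."""
        cfg = SimConfig(n_cells=60, error_rate=0.0, dup_mean=1.0,
                        spliced_fraction=0.3, seed=5)
        bam = str(tmp_path / "cons.bam")
        _, truth, _ = simulate_bam(cfg, out_path=bam)
        counts = {c.barcode: c.depth for c in pileup_site(bam, site, umi_mode="consensus")}
        for row in truth.cells.itertuples(index=False):
            bc = row.barcode.rsplit("-", 1)[0]
            assert counts.get(bc, 0) == row.depth_umi

    def test_idempotent_reruns(self, tmp_path, site):
        cfg = SimConfig(n_cells=30, seed=11)
        bam = str(tmp_path / "sim.bam")
        simulate_bam(cfg, out_path=bam)
        first = pileup_site(bam, site)
        second = pileup_site(bam, site)
        assert first == second
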