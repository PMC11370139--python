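# Methods

## Per-cell genotyping at known SNV sites

### Model and rule

Each variant site is a single-base substitution at a 1-based genomic
coordinate with one reference and one alternate allele. For every cell
barcode, the pileup engine tallies the bases its reads report at the site
(`n_ref`, `n_alt`, `n_other`) and the classifier applies a trichotomy:

- **ALT** when `n_alt >= min_alt_evidence` (default 1 — a single observation
  of the variant allele suffices);
- **REF** when not ALT and `n_ref >= 1`;
- **UNKNOWN** when no informative observation covers the site.

ALT takes precedence over co-occurring reference evidence because a
heterozygous cell is expected to express both alleles. A cell whose only
evidence is a third base (neither ref nor alt) is UNKNOWN by default
(`other_policy="unknown"`): such a cell demonstrably does not carry only the
reference allele, but it carries no evidence for the known variant either,
so treating it as uninformative is the conservative choice. `other_policy="ref"`
is available for users who prefer to read "no alternate allele seen" as
wildtype. When several sites belong to one sample, per-site calls combine by
priority — any ALT site makes the cell ALT, else any REF makes it REF, else
UNKNOWN — with counts summed.

`min_alt_evidence=1` is deliberately vulnerable to sequencing error; the
false-ALT rate it implies is quantified below and the threshold is exposed
everywhere.

### Splice-aware base extraction

scRNA-seq alignments are dominated by spliced reads, so the base lookup
walks the CIGAR explicitly: `M`, `=`, `X` consume reference and query; `I`
and `S` consume query only; `D` and `N` consume reference only. A site that
falls under `D` or `N` (an intron skip), inside a clip, or outside the
aligned span yields no observation. The walk is validated against a literal
per-base CIGAR expansion over randomized alignments in the test suite.

### Filters and evidence levels

Defaults: base quality >= 20, any mapping quality, drop
unmapped/secondary/supplementary/QC-fail reads, require a `CB` tag
(a read that cannot be assigned to a cell contributes nothing).
Flag-marked duplicates are kept, because 10x duplicate marking is UMI-based
and duplication is handled by the evidence level instead:

- `read`: every filter-passing read counts;
- `consensus` (default whenever `UB` tags are present): reads sharing
  (barcode, UMI) derive from one molecule and collapse to a single
  observation by majority base. A tied vote (e.g. one T and one C read from
  the same molecule) is uninformative and the molecule is discarded —
  conservative and deterministic. Reads without a UMI each count as their
  own molecule. Overlapping mates would be merged per (barcode, UMI) under
  consensus and double-counted under `read` mode; the simulator emits
  single-end records, matching typical 10x R2-only genotyping.

Genotype tables record the evidence level (`read`/`umi`) in every row, since
observed mutated fractions shift slightly between the two conventions.

### Heterozygosity expectation

With informative depth histogram `w_d` over covered cells, allelic sampling
probability `p` (default 0.5; a parameter because allele-specific expression
can skew transcript-level sampling), miscall-to-alt rate `epsilon` and
threshold `m`, the expected ALT fraction among covered heterozygous cells is

    E = sum_d w_d * P[Binom(d, q) >= m],   q = p + (1 - p) * epsilon.

This is exact for independent observations (true at molecule level, where
each UMI samples one allele independently). The alt-to-elsewhere miscall
direction is neglected in `q`; it is second order (it matters only when
every alt observation of a cell is simultaneously miscalled). For
homozygous-reference cells the same formula with `p=0` gives the false-ALT
rate `1 - (1 - epsilon)^d` at `m=1`, with `epsilon = e/3` under a uniform
substitution error model. The per-cluster comparison of observed vs expected
fraction is descriptive; an optional exact binomial test is provided as a
single comparison per cluster, with no multiplicity correction (documented
rather than hidden, since clusters are few and the use is diagnostic).

The cluster summary reports the mutated fraction over covered cells
(`n_alt / (n_alt + n_ref cells)`) as the primary quantity and the
per-all-cells fraction as a separate column, so the two denominators are
never conflated.

## Gene-set activity scoring

Genes are ranked per cell by decreasing expression; the score of a set S is
the normalized area under its recovery curve within the top
`T = floor(theta * n_genes)` ranks:

    auc = sum_{k=1..T} H(k) / sum_{k=1..T} min(k, |S|),

`H(k)` the number of set genes at rank <= k. The denominator is the maximal
achievable area, so a perfectly top-ranked set scores exactly 1 regardless
of |S| versus T — implementations differ here, hence the explicit contract.
`theta` defaults to 0.05, the common convention for this score family; it is
a flag, not a claim about any particular study's setting.

Ties — including the dominant zero block of droplet counts — are broken by a
seeded uniform shuffle rather than average ranks: average ranks would let a
set of entirely unexpressed genes collect fractional recovery from the zero
block and inflate its score, while a random tie-break keeps such sets at
chance level. Per-cell randomness derives from (seed, barcode hash), so a
cell's score is independent of where it sits in the matrix and runs are
bit-reproducible. Because the score is rank-based it is invariant under any
strictly monotone transform of a cell's expression vector; raw counts and
log-normalized values differ only through tie structure.

Set genes absent from the matrix are dropped with a logged count; a set with
zero overlap scores NaN with a warning rather than a silent zero.

## Synthetic data

The alignment simulator emulates the genotyping-relevant features of a 10x
library over one SNV: per-cell genotype (hom-ref or het at a configurable
mix), Poisson molecule depth with an explicit zero class (so UNKNOWN cells
occur), independent per-molecule allele sampling (alt with probability `p`),
UMI duplication (reads per molecule = 1 + Poisson), uniform substitution
errors, and spliced reads whose `N` operation spans the site. Reads are
91 bp single-end with `CB`/`UB` tags, Q40 bases and MAPQ 255, emitted as a
coordinate-sorted indexed BAM plus truth tables consistent record for
record. Defaults (1000 cells, half heterozygous, depth mean 2, error rate
0.001, 20% spliced, balanced alleles) represent a realistic sparse-coverage
droplet experiment at a moderately expressed locus.

It does **not** emulate: transcriptome-wide coverage, ambient RNA, doublets,
barcode collisions/correction, paired mates, indel errors, or allele-specific
expression beyond the single `p` parameter. Passing tests therefore show the
counting, classification and summary machinery is correct under the stated
observation model — not that real libraries satisfy that model.

The expression simulator draws counts from a negative binomial (dispersion
2) with lognormal gene-level means and inflates the planted set's means by
`(1 + effect)` in active cells; `effect = 0` is an exact null. It likewise
makes no claim of transcriptome realism; it exists to verify that the scorer
separates a known signal and stays flat under the null.

## Numerical and design choices

- Coordinates are 1-based user-facing (VCF convention) and converted to the
  alignment 0-based convention in exactly one place (the pileup engine).
- Chromosome names must match the alignment header exactly unless an
  explicit aliasing map is supplied (`make_chrom_alias` handles the common
  `chr` prefix mismatch); silent cross-naming is avoided.
- Barcode normalization strips a trailing `-<int>` GEM-well suffix by
  default (CellRanger outputs carry it, user tables often do not); a flag
  disables it.
- Indels and MNVs are rejected at parse time rather than mis-genotyped.
- `recovery_auc` uses integer accumulation (a set gene at rank `r <= T`
  contributes `T - r + 1`), so results are exact — the oracle comparison in
  the tests demands agreement to 1e-12 only to accommodate the division.
- Binomial tail probabilities come from `scipy.stats.binom.sf`; no
  simulation is used where a closed form exists.
- Simulation sizes in the test and acceptance runs (up to 10,000 cells,
  100 replicate libraries, 20 null seeds) were chosen to put 3-standard-error
  bands well inside the effects being checked while keeping the whole suite
  fast on a single CPU.

## Known limitations

- Genotyping is binary per site; no genotype likelihoods, copy-number
  awareness, or tumor-purity inference. Deciding which clusters are tumor
  remains the user's judgment, informed by the expected-fraction comparison.
- A single alt observation calls ALT by default; in high-error data raise
  `min_alt_evidence` or the base-quality threshold.
- The heterozygosity expectation assumes independent observations; read-level
  evidence violates independence when duplicates of one molecule are counted
  separately, which is why consensus mode is the default with UMIs present.
- The scorer's tie-break seed changes individual scores of heavily tied
  cells; comparisons should hold the seed fixed (manifests record it).
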