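# Methods

## The library chemistry being modelled

`drpseq` models whole-transcriptome profiling by double-random priming (DRP).
Total RNA is reverse-transcribed with an oligonucleotide carrying a fixed
25-nt MALBAC adapter (`GAGTGATGGTTGAGGTAGTGTGGAG`) and a random 3′ octamer;
one round of second-strand synthesis with the same primer yields cDNA
amplicons flanked by reverse-complementary copies of the adapter. PCR with a
mix of four variable-length adapter primers amplifies these amplicons.
Because the two ends of a short amplicon are complementary, short fragments
self-anneal into panhandle structures that block primer binding, which
suppresses their amplification — the simulator therefore never emits inserts
below `fragment_min_bp`. Each random octamer pair identifies one original
priming event, so after sequencing the octamers act as molecular counters:
reads that are identical *including* the octamers are PCR duplicates of one
molecule, reads that differ only in the octamer are independent molecules.

A sequenced read is

    [0–3 random 5′ offset bases] + forward adapter + octamer5 + insert
        (+ octamer3 + reverse adapter + Illumina adapter, if they fit)

truncated to `read_length_nt`. The variable-length PCR primers are modelled
abstractly as 0–3 random offset bases: their documented function is only to
create 5′-end heterogeneity for Illumina cluster calling.

## Simulator parameters

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 500 | genes in the synthetic transcriptome (one transcript each) |
| `expression_dispersion` | 1.0 | σ of the log-normal per-gene abundance draw |
| `rrna_mass_fraction` | 0.4 | exact share of fragment mass assigned to the rRNA classes |
| `input_picograms` × `capture_molecules_per_pg` | 5000 × 2 | Poisson mean of captured molecules |
| `fragment_min_bp`–`fragment_max_bp` | 150–600 | insert size range (amplicon gel range) |
| `pcr_cycles`, `per_cycle_efficiency` | 12, 0.45 | branching PCR: each copy duplicates per cycle with prob. 0.45 |
| `read_length_nt` | 150 | single-end read length (150-cycle kit) |
| `error_rate` | 0.0 | per-base substitution probability |
| `adapter_offsets` | (0,1,2,3) | 5′ offsets of the four PCR primers |

Abundances are *fragment masses*: the expected share of amplifiable
fragments per gene. Random priming produces fragments in proportion to
transcript copies × length, so the expression level that FPKM estimates is
fragment mass divided by transcript length; tests of rank recovery compare
FPKM against that quantity. The rRNA classes (`rRNA`, `Mt_rRNA`) are
rescaled after the log-normal draw so their summed fragment mass equals
`rrna_mass_fraction` exactly; because gene lengths are drawn independently
of biotype, the FPKM share of those classes fluctuates around the same value
with a gene-level sampling spread.

PCR duplication is an independent per-cycle Bernoulli doubling per copy, the
simplest process with mean `(1+efficiency)^cycles` and a geometric-like
spread of duplicate counts. Every copy is rendered as one read (read count
equals the summed copy counts); with the protocol's 12 cycles this makes
duplicates the majority of reads, unlike a real sequencing run that samples
the amplified pool sparsely. The duplicate-fraction statistics are therefore
validated against the simulator's truth table, not against any particular
published duplicate percentage.

The error model is substitution-only: adapters are located by
windowed exact or Hamming matching, so indel handling is deferred.
Coordinates are 0-based half-open; reads are transcript-strand oriented by
default (`flip_strand_prob` enables random flipping; the chemistry is not
strand-preserving, but the toy mapper searches both strands anyway).

ERCC-style spike-ins have known copy numbers
`stock_attomol_per_µl × dilution × volume × 6.02214e5` (molecules per
attomole) and are captured as Poisson(copies × `ercc_capture_rate`). The
synthetic mix spans four orders of magnitude of stock concentration.

## Read preprocessing

Per read, in order: (1) Illumina-adapter removal — the leftmost full
occurrence is cut, otherwise the longest adapter prefix of ≥ 5 nt that is a
suffix of the read; (2) the read is discarded unless the forward MALBAC
adapter starts within `max_forward_offset` (default 6) bases of the 5′ end
(exact match by default — the motif is a gate, not an alignment);
(3) dual-mode trimming of the core (bases after the forward adapter): cut at
the leftmost reverse-MALBAC occurrence (`BOTH_ADAPTERS`), else keep the
first 120 nt (`FORWARD_ONLY`). The 120-nt window applies to the core, not
the raw read, so insert lengths do not depend on the 5′ offset. Reads whose
reverse motif leaves no room for two octamers (< 16 nt of core) are
discarded. (4) Identical reads are collapsed on (mode, core including
octamers) *before* octamer removal — the octamer is the molecular counter —
and groups from different modes never merge, even when one core is a prefix
of the other (a known limitation of per-branch collapsing). (5) Octamers
are removed and inserts of ≥ 30 nt are kept for mapping.

`duplicate_fraction` is defined as 1 − unique molecules / reads surviving
trimming, computed before the length filter; molecules dropped by the
30-nt filter are reported separately (`reads_failing_length`, counted in
molecules).

### Exactness of molecule recovery

With error-free reads, deduplication recovers the truth table exactly —
molecule counts and per-molecule duplicate counts — *provided the 120-nt
window is out of reach of Illumina-adapter stripping*. A chance suffix
match of ≥ 5 nt to the adapter prefix occurs on ~0.13% of reads; at a read
length of 150 nt such a false strip can shorten the core below 120 nt for
some PCR copies and not others, splitting a duplicate group. When
`read_length_nt ≥ max offset + 25 (forward adapter) + 120 (window) + 32
(maximum partial strip)`, i.e. ≥ 181 nt, false strips never reach the
window and true strips cut at the same amplicon position in every copy, so
recovery is provably exact. Exactness tests therefore use 250-nt reads (a
standard MiSeq kit length); a companion test bounds the inflation at 150 nt
to < 0.5% of molecules.

## Quantification

Inserts are mapped by exact (or Hamming-tolerant, via pigeonhole-seeded
lookup) substring search against the transcriptome, both strands — adequate
because simulated inserts are contiguous transcript fragments; real-data
users bring external per-gene tables (`read_cufflinks_fpkm`). An insert
matching k genes contributes 1/k to each (uniform multi-match splitting,
conserving totals to machine precision); matching one gene at several
positions counts once.

FPKM uses the annotated transcript length (no effective-length correction)
and normalises by assigned fragments only (compatible-hits-norm):
`fpkm = assigned × 1e9 / (length_bp × total_assigned)`. Genes with
FPKM ≥ 1 are called expressed, after removing spike-ins (`ERCC-` prefix).

## Analytics

- **Saturation** — distinct mapped reads are subsampled without replacement
  (seeded) at each fraction, FPKM is recomputed and expressed genes counted.
  Whether the original study subsampled with or without replacement is not
  stated; without replacement is used, and fraction 1.0 reproduces the full
  count identically.
- **Class composition** — FPKM of expressed genes summed per biotype after
  per-gene overrides (the abundant ribosomal transcript Gm26924 is
  reassigned from lincRNA to rRNA); percentages of the per-sample total sum
  to 100.
- **rRNA base fraction** — weighted insert-length tally over rRNA genes
  divided by all assigned bases.
- **Gene-body coverage** — per-transcript coverage rescaled to 100 bins,
  normalised to mean 1 per gene, averaged across genes, renormalised. With
  uniform fragment starts the terminal bins are depressed purely by
  geometry (a fragment covering position 0 must start at 0).
- **ERCC linearity** — FPKM below 0.1 is floored at 0.1 (idempotent);
  Pearson r on log10 scale over spike-ins with copies > 0.
- **Replicate concordance** — genes with FPKM ≥ 0.001 in *either* sample
  are retained (union rule, so Pearson and Spearman see the same gene set;
  configurable). Coefficients are computed on untransformed FPKM, matching
  the "absolute FPKM" labelling, with a log10 option exposed since the
  corresponding scatter plots are drawn on log axes.
- **Control subtraction** — genes significant (q < α) in the main
  compartment comparison are removed if the dilution/cycle-number control
  finds them significant in the matching arm (side_A ↔ undiluted,
  side_B ↔ diluted), mirroring the experimental pairing. q-values are
  consumed from external differential tables, never computed.
- **Clustering** — complete-linkage agglomeration on Euclidean distances of
  log2(FPKM); zeros receive a pseudo-count of half the smallest positive
  value in the matrix (the choice is not dictated by the protocol).
  Implemented in-package to guarantee deterministic tie-breaking:
  equal-height merges resolve to the lexicographically smallest active
  cluster pair, and leaf order visits the smaller subtree (ties: the one
  holding the smallest original leaf) first. scipy's implementation serves
  as an independent cross-check in the tests.
- **Probeset collapse** — per gene the highest- (or lowest-) intensity
  probeset is kept, ties broken by lexicographic probeset id.

## Problem sizes

Desk-scale defaults were chosen so that every check runs on a laptop-class
budget: 500-gene transcriptomes; ~1e4 molecules at the protocol's 12 PCR
cycles (~8.6e5 reads) for exact-recovery checks; ~2.3e5-read libraries
(25 000 molecules × 6 cycles) for saturation; two ~1.1e5-read replicates
for concordance. The acceptance script reruns these end to end in well
under a minute.

## What the simulator does not capture

Octamer priming bias (real random primers are sequence-biased; priming here
is uniform), secondary-structure effects that reduce rRNA capture in the
real protocol, quality scores (constant placeholder), indels, and spliced
genomic alignment (inserts are contiguous transcript substrings). Passing
tests therefore demonstrate the correctness of the trimming, counting,
normalisation and analytics logic under the stated generative model — not
the biological detection rates of any particular tissue, which depend on
deposited sequencing data outside this package's scope.
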