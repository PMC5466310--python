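# mitochar

Comparative characterization of circular (insect) mitochondrial genomes as a
reusable, tested pipeline:

- **genome_model** — data model for circular annotated mitogenomes (1-based
  inclusive coordinates on the majority/F strand, origin-wrapping features),
  readers/writers for annotation TSV, FASTA and GenBank, and a consistency
  report that flags printed table values disagreeing with coordinate
  arithmetic (they are reported, never corrected).
- **composition_stats** — base composition, A+T content and strand skews
  (AT skew = (A−T)/(A+T), GC skew = (G−C)/(G+C)) per region class
  (whole genome / PCG / tRNA / rRNA / A+T-rich region), with a comparison-table
  style TSV report.
- **codon_analysis** — translation under the invertebrate mitochondrial code
  (NCBI table 5), start/stop classification including incomplete T/TA stops
  completed by polyadenylation, codons-per-thousand and RSCU with the
  Leu1/Leu2 (CTN/TTR) and Ser1/Ser2 (AGN/TCN) family split.
- **gene_topology** — adjacent-pair ledger of overlaps and intergenic spacers
  (printed-column or coordinate mode, circular closure), summary statistics,
  overlap-junction extraction, and circular gene-order comparison by signed
  breakpoint counting (e.g. the derived lepidopteran trnM-trnI-trnQ block vs
  the ancestral trnI-trnQ-trnM arrangement).
- **control_region** — scanners for fixed motifs (both strands), an anchor
  motif followed by a poly-T stretch, homopolymers, and perfect
  microsatellites / tandem repeats (primitive units, maximal arrays,
  fractional final copies), validated against exhaustive enumeration.
- **phylogeny** — concatenated-PCG supermatrix, p / K2P distances with
  pairwise deletion, canonical neighbor joining with deterministic
  tie-breaking, column-bootstrap supports, outgroup rooting, Newick I/O and
  Robinson–Foulds distances.
- **synthetic_data** — seeded generators: a ~15.2 kb circular genome with 38
  features in the lepidopteran arrangement, planted junction/spacer motifs and
  control-region elements (all listed in a truth record for plant-and-recover
  tests), plus aligned clades evolved under a K2P model down a known tree.
- **cli** — `mitochar` command with `characterize`, `topology`, `codons`,
  `motifs`, `phylo` and `simulate` verbs; a two-mode pipeline (table-only vs
  sequence) with a mode firewall, MANIFEST, config provenance and structured
  logs.

The package ships the printed annotation and composition tables of the
oleander hawk moth mitogenome (15,247 bp; 13 PCGs, 22 tRNAs, 2 rRNAs, one
A+T-rich region) as TSV fixtures under `src/mitochar/data/`, so the whole
desk-scale analysis runs with zero downloads. Known quirks of the printed
tables are preserved verbatim and surfaced by the consistency report — e.g.
the cox1 start codon is stored as the table's CCA even though the source
abstract says CGA, rrnS prints size 778 while its coordinates give 779, and
the printed overlap column sums to 27 bp while the running text says 26 bp.

## CLI

```bash
# reports from the printed annotation table (table-only mode)
mitochar characterize --annotation src/mitochar/data/daphnis_nerii_annotation.tsv --out-dir out/

# overlap/spacer ledger from the printed intergenic column
mitochar topology --annotation src/mitochar/data/daphnis_nerii_annotation.tsv --source printed --out-dir out/

# generate a seeded synthetic genome, then run sequence-level stages on it
mitochar simulate --seed 1 --out-dir sim/
mitochar codons --genbank sim/genome.gb --out-dir out/
mitochar motifs --genbank sim/genome.gb --out-dir out/

# distance phylogeny with bootstrap over several GenBank genomes
mitochar phylo --genbank a.gb --genbank b.gb --genbank c.gb --genbank d.gb \
    --model K2P --reps 1000 --seed 1 --outgroup d --out-dir out/
```

Every CLI entry point that samples requires an explicit `--seed`; there is no
wall-clock seeding anywhere.

## Notes and deliberate limitations

- Gene annotation itself is an input: there is no de novo annotation, no tRNA
  cloverleaf folding, and no multiple sequence alignment (supermatrix input
  must be pre-aligned; the synthetic clade generator emits aligned genes).
- Repeat detection is perfect-repeat only (no alignment-scored imperfect
  arrays).
- The phylogeny stage is a distance method (NJ + bootstrap). It recovers the
  generating topology on synthetic clades; it is not a maximum-likelihood or
  Bayesian implementation, and distance methods cannot arbitrate
  sister-group questions on which ML and BI themselves disagree.
- The control-region poly-T threshold, microsatellite copy thresholds and the
  ≥10 bp "major spacer" cutoff are configuration, not constants.
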