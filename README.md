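# plastidkit

A toolkit for finishing and analysing quadripartite plastid (chloroplast)
genomes from draft assemblies. It covers the full desk-side workflow:

- **Contig stitching** — classify three draft contigs (LSC / IR / SSC),
  orient the inverted repeat, detect the suffix–prefix overlaps at all four
  junctions (including the circular IRb→LSC junction), and emit the finished
  circular genome `LSC + IRa + SSC + IRb`. Junctions without overlap evidence
  are reported as gaps with ≥100 nt flanking windows for primer walking.
- **Inverted-repeat detection** — seed-and-extend self-comparison that
  recovers the maximal IR pair and the LSC/IRa/SSC/IRb layout.
- **Read-mapping QC** — local alignment under assembler-style costs
  (mismatch 2, gaps 3; acceptance by length fraction ≥ 0.8 and similarity
  fraction ≥ 0.9, with a strict 0.99/0.99 preset), per-base coverage
  profiles, sub-40× screening, dual-stringency comparison, and remapping of
  the concatenated IRb-end + LSC-start segment to resolve the artifactual
  coverage drop at the circular origin.
- **Repeat scanning** — maximal dispersed repeat pairs of four kinds
  (forward, reverse, complement, palindromic) at ≥30 nt with a Hamming
  tolerance of 3, with the IRa/IRb duplication itself excluded; genomic
  context classification (intergenic / exon / intron).
- **Microsatellites** — MISA-style SSR scan (mono 10, di 6, tri 5,
  tetra/penta/hexa 3; compound merging at ≤100 nt) plus cross-genome SSR
  polymorphism pairing by flanking-sequence anchors.
- **Comparative genomics** — per-region length/GC/coding metrics, pseudogene
  scanning (internal stop codons, plastid/bacterial code), IR-boundary and
  expansion analysis against a designated boundary gene (e.g. *ycf1*),
  orientation-normalized pairwise SNP/indel counting via unique 31-mer anchor
  chaining, and mitochondrion-derived insert detection by windowed homology
  with base-resolution boundary refinement and coverage-consistency checks.
- **Synthetic fixtures** — a deterministic generator of quadripartite
  plastomes with planted SSRs, repeats, foreign inserts and boundary genes,
  contig fragmentation with per-junction overlaps (or planted gaps), and
  read simulation — the ground truth behind the whole test suite.

## Test

```bash
python -m pytest tests/
```

The property-based tests run entirely on seeded synthetic fixtures. The
benchmark tests in `tests/test_acceptance.py` additionally need the deposited
chloroplast genomes as plain FASTA under `src/plastidkit/data/genomes/` (see
the README there for accessions and a fetch snippet); without them those
tests fail with an explanatory message.

## CLI

```bash
plastidkit simulate --seed 7 --out-dir sim --depth 50        # synthetic fixture
plastidkit stitch --contigs sim/contigs.fasta --out genome.fasta --report junctions.tsv
plastidkit ir-detect --genome genome.fasta --bed regions.bed
plastidkit map-qc --reads sim/reads.fasta --genome genome.fasta --out coverage.tsv
plastidkit repeats --genome genome.fasta --out repeats.tsv
plastidkit ssr --genome genome.fasta --out ssr.misa.tsv
plastidkit metrics --genome genome.fasta --out metrics.tsv
plastidkit pseudogenes --genome genome.fasta --features ann.gb --out pseudo.tsv
plastidkit compare --genome-a a.fasta --genome-b b.fasta --out cmp.tsv
plastidkit insert-scan --genome genome.fasta --plastid-refs p.fa --mito-refs m.fa --out calls.tsv
```

Every subcommand default matches the published analysis parameters; a
`key=value` config file (`--config`) overrides defaults, explicit flags
override the config, and each run logs its parameters and input checksums.

## Layout

```
src/plastidkit/
  seqio.py         sequence/annotation model, FASTA/GenBank/BED/TSV I/O
  quadripartite.py IR detection, contig classification, stitching, orientation
  readmap.py       read alignment, acceptance, coverage, junction remapping
  repeats.py       dispersed repeats, SSR scan, summaries, SSR comparison
  compare.py       region metrics, pseudogenes, IR boundaries, pairwise, inserts
  fixtures.py      seeded synthetic plastomes, fragmentation, read simulation
  cli.py           click-based command line
tests/             pytest suite (unit + property + acceptance criteria)
scripts/acceptance.py
```
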