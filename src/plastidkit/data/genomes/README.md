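# Deposited benchmark genomes

The benchmark tests in `tests/test_acceptance.py` and the targets in
`scripts/acceptance.py` expect the deposited chloroplast genomes here as
plain single-record FASTA, named `<accession>.fasta`:

    MT299584.fasta   Amaranthus retroflexus
    MT316305.fasta   Bienertia cycloptera
    MT316306.fasta   Bassia muricata
    MT316307.fasta   Bienertia sinuspersici
    MT316308.fasta   Haloxylon ammodendron
    MT316309.fasta   Suaeda aralocaspica
    MT316310.fasta   Suaeda eltonica
    MT316311.fasta   Suaeda maritima
    KU726550.fasta   B. sinuspersici (previous version)
    KF534478.fasta   H. ammodendron (previous version)
    KX279888.fasta   Amaranthus hypochondriacus

Fetch, with network access, e.g.:

    for acc in MT299584 MT316305 MT316306 MT316307 MT316308 \
               MT316309 MT316310 MT316311 KU726550 KF534478 KX279888.1; do
      curl -s "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi?db=nuccore&id=${acc}&rettype=fasta&retmode=text" \
        -o "${acc%.1}.fasta"
    done

They could not be bundled with this repository because the build environment
had no route to GenBank.
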