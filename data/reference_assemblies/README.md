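# Reference assemblies (not shipped)

The accession-anchored ANI checks in `tests/test_acceptance.py` compare the
ANI engine against published values for three *Macrococcus* assemblies.
Genome FASTA files are multi-megabyte binaries and are therefore not
included in the repository; to run those checks, download them from NCBI
and place them here as `<accession>.fna`:

```bash
datasets download genome accession GCF_004359525.1 GCF_004359525.2 GCF_004359515.1
# unzip and rename each *_genomic.fna to GCF_00435952*.fna / GCF_004359515.1.fna
```

Without these files the two checks fail with an explanatory message; all
other tests are self-contained.
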