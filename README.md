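# anispecies

Species clustering for bacterial and archaeal genomes based on average
nucleotide identity (ANI), built for maintainers of genome-based taxonomies
and anyone who needs reproducible, accession-stable species clusters over a
growing assembly collection.

Each species is defined by a single **representative genome**: a genome
belongs to the species when its ANI to the representative reaches the
cluster's circumscription radius (95% by default) and its alignment
fraction (AF) reaches 0.65 (configurable down to 0.5 to accommodate
incomplete MAGs). The engine covers the full life cycle of such clusters:

* **Quality scoring.** Assemblies are ranked by a tiered score,

  ```
  + 1 000 000  assembled from the type strain of the species
  +   100 000  effective type strain of the species at NCBI
  +    10 000  NCBI representative of the species
  +     1 000  assembled from the type strain of a subspecies
  +       100  complete genome
  +  completeness − 5 × contamination        (CheckM estimates)
  −       100  MAG or SAG
  −  5 × (contigs / 100)
  −  5 × (undetermined bases / 10 000)
  +        10  full-length 16S rRNA gene
  ```

  so nomenclatural type material always outranks assembly polish.

* **Representative stability.** A challenger replaces the incumbent
  representative only if its *Balanced ANI Score*,
  `BAS = 0.5 × ani_score + 0.5 × quality_score` with
  `ani_score = 100 − 20 × (100 − ANI to incumbent)`, exceeds the
  incumbent's BAS by ≥ 10 — equivalently a quality gain of at least
  `20 + 20 × (100 − ANI)` points. Divergent challengers therefore need to
  be of much higher quality, which keeps representatives stable between
  releases.

* **Release updating.** New, updated and suppressed assemblies are detected
  by accession diffing; genomes of insufficient quality are removed;
  species with disagreeing type-strain genomes (pairwise ANI < 99%) are
  flagged for manual resolution; representatives are re-elected (including
  the two special cases: an updated assembly that turns out divergent from
  its predecessor, and a representative suppressed at the source archive,
  which retires singleton clusters); all remaining genomes are re-assigned
  and the rest form de novo clusters. The change accounting (representatives
  unchanged/changed with reasons, new species, same/different cluster,
  suppressed) is emitted as text and JSON.

* **Species-boundary discreteness.** For every genome, the closest genome
  in a different species of the same genus is located; a species is
  *fuzzy* when any such interspecific ANI is ≥ 95% and *discrete* when none
  exceeds 94%.

* **Synthetic fixtures.** A seeded generator produces metadata tables, ANI
  matrices with planted species structure, release pairs with ground-truth
  expectations, and FASTA sets with known divergence, so the whole engine
  is testable without downloading genomes.

File formats are the field's standard tab-separated dialects (GTDB-style
metadata, taxonomy and species-cluster tables; FastANI output), so real
release files drop in unchanged. ANI/AF values can be ingested from FastANI
output, computed by an external FastANI executable, or estimated by the
built-in fragment aligner for small inputs and tests.

## Worked example

`examples/03_release_update.py` perturbs a synthetic release — one
singleton representative suppressed, one representative assembly updated
but deeply divergent from its predecessor, one new type-strain genome —
and runs the update:

```
Release update: R01 to R01+1

Species representatives      8 to 8
  Unchanged                  5 (62.50%)
  Changed                    3 (37.50%)
New species                  1 (12.5% increase)
Genome cluster assignment    24 to 28
  Same cluster               22 (91.67%)
  Different cluster          1 (4.17%)
  Suppressed                 1 (4.17%)
Removed by quality control   0
Representative change reasons:
  assembly_updated            1
  cluster_retired             1
  type_strain_promotion       1
Retired species clusters: s__Genus001 sp001
```

Reading the output: the suppressed singleton retired its species; the
divergent updated assembly (ANI 80.6% to its predecessor) did **not**
inherit its cluster — the closest sibling (ANI 99.99%) was promoted instead
and the corrected assembly founded the one new species, which is also the
one genome counted in "Different cluster"; and the new type-strain genome
displaced a non-type representative through score dominance.

The other example scripts demonstrate quality scoring and the replacement
rule (`01`), exact recovery of a planted partition by the greedy clustering
(`02`), fuzzy/discrete species verdicts (`04`), and the built-in fragment
ANI estimator on assemblies with planted divergence (`05`). Each prints the
numbers it computes and what they mean.

A `anispecies` console command exposes the same operations
(`score`, `qc`, `ani`, `cluster`, `update`, `discreteness`, `synth`); every
output directory receives a run manifest with the tool version, config hash,
input digests and seed.

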