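# Methods

## Model

A species cluster is a star: one representative genome and the set of
genomes whose ANI to it reaches the cluster's circumscription radius with
an alignment fraction (AF) at or above the membership threshold. ANI is
treated as a symmetric pairwise quantity even though fragment-based engines
are directional; the two directions are collapsed with a max rule for both
ANI and AF, because the update logic needs a single value per pair and the
higher direction is the less truncated estimate when assemblies differ in
completeness. A pair absent from the ANI table means "below detection" and
is never interpreted as 0% — interpolating similarities would silently
merge unrelated genomes.

Assumptions worth stating explicitly: accessions are the identity of an
assembly (base compared across releases, version signalling re-assembly);
CheckM completeness/contamination, rRNA annotations and type-material
designations arrive as trusted metadata and are never recomputed; and a
genome belongs to at most one non-retired cluster per release.

## Parameters

* `ani_radius_default` = 95 (% ANI). The species boundary. Radii above 95
  occur only when another retained representative lies within 95% ANI of a
  representative, in which case the radius is raised to that pairwise ANI
  so neither species absorbs the other; a cap (`radius_cap` = 97) guards
  against near-duplicate representatives erasing clusters outright.
* `af_threshold` = 0.65 (fraction). Membership requires this alignment
  fraction besides ANI; 0.5 is the documented relaxation for collections
  rich in incomplete MAGs, whose AF is artificially low.
* `bas_replacement_margin` = 10 (BAS units). With
  `BAS = 0.5·ani_score + 0.5·quality` and
  `ani_score = 100 − 20·(100 − ANI)`, the margin translates into a quality
  gain of `20 + 20·(100 − ANI)` points: a challenger at ANI 99.5 needs +30
  quality, one at ANI 98 needs +60. The boundary is inclusive (a challenger
  exactly at +10 replaces).
* `type_conflict_ani` = 99 (%). Two genomes both claiming the type strain
  of one species are expected to be near-identical; below this the species
  is flagged and frozen until a human supplies a resolution. Resolution
  demotes the non-chosen claimants to non-type status for scoring.
* `fuzzy_ani` = 95 / `discrete_ani` = 94 (%). Species-discreteness
  verdicts. Values strictly between the two produce an explicit
  `intermediate` class, because the two headline rules do not cover the
  gap and silently folding it into either class would bias both fractions.
* `subsample_per_species` = 150 genomes. Cap on the per-species search in
  the discreteness analysis; sampling is seeded per species by hashing the
  species label into the base seed, so adding species to a release does not
  reshuffle the subsamples of existing ones.
* `full_length_ssu` = 1200 nt. Minimum annotated 16S length earning the
  quality-score bonus; the conventional near-full-length cutoff, since the
  criterion itself does not define "full length". Configurable.

QC defaults (completeness ≥ 50, contamination ≤ 10, completeness −
5×contamination ≥ 50, ≤ 1000 contigs, N50 ≥ 5000 where an N50 is given,
≤ 100 000 undetermined bases, suppressed and multi-isolate-project
assemblies excluded) are deliberately config-first so any historical gate
can be reproduced; type-strain genomes get no exemption.

## Update workflow: decisions where the design was open

* **Order of the special cases.** Within the representative-update step the
  order is: suppressed/lost representative → updated assembly → BAS
  challenger election. A suppressed representative is therefore never
  "challenged", and an updated assembly is judged by the BAS of all cluster
  members against the *previous* assembly before any ordinary challenger
  logic runs.
* **A previous representative that now fails QC** (without being suppressed
  at source) goes through the same path as a suppressed one: the member
  with the highest BAS to it is promoted, and a singleton cluster is
  retired. Only the suppressed case is documented upstream; this is the
  closest-consistent extension and keeps the invariant that representatives
  always pass QC.
* **Challenger pool.** Ordinary BAS elections consider current cluster
  members plus *new* genomes falling within the cluster's radius and AF
  threshold of the representative — otherwise a newly sequenced type strain
  could never be promoted in the release it arrives in.
* **Change accounting.** A representative counts as "changed" only when the
  accession *base* changes; retaining an updated assembly (same base, new
  version) is stability, not change. A genome present in both releases is
  in the "same cluster" when its new cluster carries the same species label
  lineage as its old one, so representative replacement alone does not
  count members as reassigned. Retirements appear both in the change list
  (reason `cluster_retired`) and in a separate retired list.
* **Frozen species.** Unresolved type-strain conflicts freeze the species:
  its representative is carried unchanged and skips elections, but its
  members are still re-assigned by the ordinary rules. Freezing rather than
  dropping preserves the release invariants while a human decides.
* **Radii are computed once per update**, among the final representative
  set, carrying forward prior radii above 95. Assignment uses the radii
  available at assignment time; a radius raised afterwards can in principle
  strand a member admitted at 95, which is accepted in this single-pass
  design and has not been observed under separable synthetic conditions.
* **Placeholder labels** for de novo clusters are deterministic
  (`s__<genus> sp<zero-padded index>`, indexed by representative accession
  order and de-duplicated against existing labels); curated names can be
  injected via the named-species mapping.

## Built-in fragment ANI estimator

The estimator cuts the query into non-overlapping 3 kb fragments and aligns
each against the reference with a banded edit-distance aligner (edlib,
infix mode) in both orientations, mapping a fragment when its best identity
reaches the 80% floor. ANI is the mean identity of mapped fragments, AF the
mapped fraction — the same contract as fragment-based external engines, but
it is an independent implementation intended as a test oracle and for small
inputs, not a high-throughput clone; expect agreement with external engines
within about ±0.5 ANI points. Identity from edit distance slightly
underestimates substitution identity when a gapped alignment is cheaper,
which is negligible at divergences below ~10%.

## Synthetic fixtures: what they do and do not show

The generator plants a species partition and samples ANI directly:
within-species values uniform in [96.5, 99.9], between-species values
within a genus from a per-species-pair mean in [78, 93] with ±0.3 jitter
(between-species divergence is a property of the species pair, which is
what makes the closest-representative search heuristic meaningful), no
edges across genera, and optional "fuzzy" species pairs whose cross values
straddle the 95% boundary ([94.2, 96.0]). Quality attributes are sampled so
every genome passes the default QC gate; one designated type strain per
species by default. Release-pair fixtures attach ground-truth expectations
(which representative must change and why) that the updater tests assert
tag by tag. Scenarios probing the ANI term of the BAS election
(divergent updated assembly, type-strain arrival, quality upgrade) generate
the base data without type strains so score dominance does not mask the
mechanism under test.

Passing on these fixtures demonstrates the correctness of the decision
logic, not performance on real collections: the generator has no
recombination, no horizontal transfer, no assembly chimerism, no
correlation between quality and phylogeny, and its separable mode places a
clean gap around the radius that real genera (the fuzzy-species cases) do
not always have. Sequence-mode fixtures use uniform point substitutions
without indels, sufficient for validating the fragment estimator's identity
arithmetic but not its behaviour on rearranged genomes.

## Numerical choices

Scores are plain floats and never rounded; the +1 000 000 type-strain term
dominates every combination of continuous terms by construction (their
magnitude is bounded by a few hundred under valid metadata). All
tie-breaks are deterministic: equal BAS or quality resolves to the
lexicographically smaller accession, equal assignment ANI to higher AF and
then smaller representative accession. Iteration orders are sorted
throughout, so identical inputs yield identical outputs regardless of row
order. Subsampling is the only stochastic step anywhere and is pinned by
the config seed.

Test and acceptance problem sizes: planted-partition recovery uses 5–45
species and up to ~1000 genomes per run; idempotence runs 12-species
fixtures; the formula/closed-form comparison uses 10 000 random triples;
the discreteness oracle uses ≤ 20-genome fixtures where brute force is
exact. These sizes exercise every code path while keeping a full suite run
in seconds.

## Known limitations

Genus assignments are taken from taxonomy strings, so the discreteness
analysis inherits any upstream genus misassignment. The closest-species
search heuristic assumes the closest species at representative level is the
closest at genome level; violations are possible in fuzzy genera (the brute
force search is provided and the tests quantify agreement). Higher-rank
taxonomy (everything above species) is carried through, never inferred.
The engine does not validate nomenclature and has no access to external
registries; type-material designations are whatever the metadata says.
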