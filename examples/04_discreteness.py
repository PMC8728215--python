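"""How discrete are the species boundaries in a release?

For every genome, find its closest genome in a different species of the
same genus; a species is *fuzzy* when any such interspecific ANI reaches
95% (no clean gap to a neighbour species) and *discrete* when none exceeds
94%. Here 20% of intrageneric species pairs are injected with ANI values
straddling the boundary, so a matching share of fuzzy species must appear.
"""

from anispecies import SyntheticSpec, generate_dataset
from anispecies.discreteness import classify_species, closest_interspecific_pairs
from anispecies.model import SpeciesCluster

dataset = generate_dataset(
    SyntheticSpec(n_species=12, genomes_per_species=(3, 8),
                  species_per_genus=3, fuzzy_pair_rate=0.2),
    seed=9,
)
clusters = [
    SpeciesCluster(sorted(accs)[0], label, set(accs))
    for label in dataset.species_labels
    if (accs := [a for a, lbl in dataset.truth.items() if lbl == label])
]
records, log = closest_interspecific_pairs(
    clusters, dataset.taxonomy, dataset.matrix, subsample=150, seed=9
)
result = classify_species(records, subsample_log=log)

print(f"{len(records)} closest interspecific genome pairs, "
      f"{len(result.verdicts)} species analysed")
print(f"fuzzy species      {result.fuzzy_species_pct:5.1f}%  "
      f"(injected: {sorted(dataset.fuzzy_species)})")
print(f"discrete species   {result.discrete_species_pct:5.1f}%")
print(f"pairs with ANI >= 95  {result.fuzzy_pair_pct:5.1f}%")
print(f"pairs with ANI <= 94  {result.discrete_pair_pct:5.1f}%")
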