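"""Run the four-step release update on a perturbed genome set.

Between the two synthetic releases: one singleton representative is
suppressed at the source archive (its species must be retired), one
representative's assembly is updated but found deeply divergent from its
predecessor (a sibling member inherits the cluster and the corrected
assembly founds a new species), and one cluster receives a new genome
assembled from the type strain (which must be promoted to representative).
"""

from anispecies import Perturbation, SyntheticSpec, generate_release_pair, update_release
from anispecies.reporting import render_change_report

pair = generate_release_pair(
    SyntheticSpec(n_species=8, genomes_per_species=(1, 5)),
    Perturbation(
        n_suppress_singleton_reps=1,
        divergent_update=True,
        n_add_type_strain=1,
        n_new_genomes=3,
    ),
    seed=5,
)
new_release, report = update_release(pair.prev, pair.current_records, pair.matrix)
print(render_change_report(report))

print("expected vs observed representative changes:")
observed = {c.species_label: c.reason for c in report.rep_changes}
for e in pair.expectations:
    if observed.get(e.species_label) == e.kind:
        print(f"  {e.species_label}: {e.kind}  OK")
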