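"""Score two assemblies and decide whether one should replace the other as
species representative.

The quality score tiers nomenclatural status above assembly quality; the
Balanced ANI Score (BAS) then trades quality gain against divergence from
the incumbent representative: a challenger needs +10 BAS, i.e. a quality
advantage of at least 20 + 20 x (100 - ANI) points.
"""

from anispecies import GenomeRecord, TypeStatus, quality_score, should_replace

incumbent = GenomeRecord(
    accession="GCA_000000001.1",
    completeness=92.0,
    contamination=2.0,
    contig_count=150,
    ssu_lengths=(1530,),
)
challenger = GenomeRecord(
    accession="GCA_000000002.1",
    type_status=TypeStatus.TYPE_STRAIN_OF_SPECIES,
    completeness=98.5,
    contamination=0.5,
    contig_count=40,
    ssu_lengths=(1530,),
)

for g in (incumbent, challenger):
    breakdown = quality_score(g)
    print(f"{g.accession}  quality score = {breakdown.total:,.2f}")
    for name, value in breakdown.as_dict().items():
        if value and name != "total":
            print(f"    {name:24s}{value:>14,.2f}")

decision = should_replace(
    quality_score(incumbent).total,
    quality_score(challenger).total,
    ani_challenger_to_current=98.0,
)
print(
    f"\nchallenger at ANI 98.0: BAS {decision.challenger_bas:,.2f} vs "
    f"incumbent {decision.incumbent_bas:,.2f} -> "
    f"{'replace' if decision.replace else 'keep'} "
    f"(margin achieved {decision.margin_achieved:,.2f}, required 10)"
)
# The +1,000,000 type-strain term guarantees promotion whenever the
# challenger lies inside the 95% circumscription radius.
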