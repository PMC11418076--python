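"""Who wants what: conflicts over the handedness phenotype, and imprinting.

Different parties value patch-mates differently, so each favours a
different incidence of left-handedness in the same individual: the
battleground of parent-offspring and intragenomic conflict.  When the two
parental-origin genomes disagree, the loudest-voice-prevails resolution
predicts which copy of a handedness locus stays expressed.
"""

from handedkin import ControlParty, Demography, GameParams, battleground
from handedkin.reporting import reproduce_fig3

demog = Demography(10, 0.3, 0.1)  # female-biased dispersal
for scenario in ("within_group", "between_group"):
    bg = battleground(GameParams(scenario), demog)
    print(f"{scenario} (female-biased dispersal):")
    for party in (
        ControlParty.INDIVIDUAL_POOLED,
        ControlParty.MOTHER,
        ControlParty.FATHER,
        ControlParty.MATERNAL_ORIGIN_GENE,
        ControlParty.PATERNAL_ORIGIN_GENE,
    ):
        res = bg.results[party]
        print(f"  {party.value:<22} x* = {res.x_star:.4f}  (r = {res.r_party:.4f})")
    print()

print("imprinting predictions (scenario x dispersal bias x locus type):")
print(reproduce_fig3(n_breeders_per_sex=10).to_string(index=False))

# Within-group combat: parents favour less left-handedness than offspring;
# under female-biased dispersal the maternal-origin gene favours more than
# the paternal-origin gene, so a left-handedness promoter is predicted to
# be maternally expressed and paternally silenced — and vice versa in the
# between-group scenario or under male-biased dispersal.
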