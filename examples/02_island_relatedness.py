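"""Island-model relatedness under sex-biased dispersal.

Patches hold N breeding pairs; offspring disperse with sex-specific
probabilities.  Lower dispersal keeps more relatives together, raising
within-patch relatedness; a sex bias in dispersal splits relatedness by
sex, by parent, and even by the parental origin of a gene.
"""

from handedkin import Demography, island_relatedness

print("symmetric dispersal, N = 10:")
for m in (0.1, 0.3, 0.7, 1.0):
    rset = island_relatedness(Demography(10, m, m))
    print(f"  m = {m:.1f}: r(groupmate) = {rset.r_individual():.4f}, "
          f"inbreeding F = {rset.inbreeding:.4f}")

print("\nfemale-biased dispersal (m_f = 0.4, m_m = 0.1), N = 10:")
rset = island_relatedness(Demography(10, 0.4, 0.1))
print(f"  female r to groupmates  = {rset.r_individual('female'):.4f}")
print(f"  male   r to groupmates  = {rset.r_individual('male'):.4f}")
print(f"  via maternal-origin genes = {rset.r_group_origin['maternal']:.4f}")
print(f"  via paternal-origin genes = {rset.r_group_origin['paternal']:.4f}")
print(f"  mother to offspring's partners = {rset.r_parent_to_group['female']:.4f}")
print(f"  father to offspring's partners = {rset.r_parent_to_group['male']:.4f}")

# The dispersing sex (here females) is less related to its patch-mates, and
# genes inherited from the mother are less locally related than genes
# inherited from the father — the raw material for sex differences,
# parental effects and genomic imprinting in the handedness analysis.
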