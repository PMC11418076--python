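"""Pedigree relatedness: the canonical coefficients of kin selection.

Builds a three-generation family and prints the relatedness between the
classic kin pairs.  These coefficients are the r in Hamilton's rule
-c + r b > 0: how strongly selection weights a relative's fitness.
"""

from handedkin import Pedigree, pedigree_relatedness

ped = Pedigree.from_records(
    [
        ("grandma", "female", None, None),
        ("grandpa", "male", None, None),
        ("grandpa2", "male", None, None),
        ("anna", "female", "grandma", "grandpa"),
        ("ben", "male", "grandma", "grandpa"),
        ("hugo", "male", "grandma", "grandpa2"),  # half-sibling via grandma
        ("spouse1", "male", None, None),
        ("spouse2", "female", None, None),
        ("carla", "female", "anna", "spouse1"),
        ("dan", "male", "spouse2", "ben"),
    ]
)

pairs = [
    ("anna", "ben", "full siblings"),
    ("anna", "hugo", "half siblings"),
    ("carla", "dan", "first cousins"),
    ("grandma", "carla", "grandparent-grandchild"),
    ("grandma", "grandpa", "unrelated founders"),
]
for i, j, label in pairs:
    r = pedigree_relatedness(ped, i, j)
    print(f"r({i}, {j}) = {r:.4f}   [{label}]")

# Expected output: 0.5, 0.25, 0.125, 0.25, 0.0 — identity-by-descent
# probabilities under autosomal diploid inheritance, doubled.
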