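"""Pedigree kinship by the recursive tabular method.

phi_ij is the probability that alleles drawn from i and j are identical by
descent: 0.5 on a non-inbred diagonal, 0.25 for parent-offspring and full
siblings, 0 across families. The mixed models use 2*phi as the random-effect
covariance.
"""

import pandas as pd

from famprs import Pedigree, kinship_from_pedigree, relationship_matrix

ped = Pedigree(pd.DataFrame(
    [
        ("F1", "father", "", "", 1),
        ("F1", "mother", "", "", 2),
        ("F1", "child1", "father", "mother", 1),
        ("F1", "child2", "father", "mother", 2),
        ("F2", "other", "", "", 1),
    ],
    columns=["fid", "iid", "father", "mother", "sex"],
))

kin = kinship_from_pedigree(ped)
print("kinship matrix phi:")
print(kin.to_frame().round(3).to_string())
print("\nparent-offspring phi =", kin.to_frame().loc["father", "child1"])
print("full siblings    phi =", kin.to_frame().loc["child1", "child2"])
print("across families  phi =", kin.to_frame().loc["child1", "other"])

a = relationship_matrix(kin)
print("\nadditive relationship matrix 2*phi has unit diagonal:", a[0, 0])
print("it is positive semidefinite and enters the mixed models as the "
      "covariance of the polygenic random effect")
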