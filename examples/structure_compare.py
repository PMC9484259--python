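"""Compare receptor-Fc complex copies: main-chain RMSD and interdomain angle.

Builds two toy complexes whose receptor arms are hinged at different
angles, then measures what the comparison stage reports: a pairwise
main-chain RMSD matrix over the shared residues and the d1/d2
interdomain angle of each receptor about its Gly89 pivot.
"""

import numpy as np

from fcgr3kit.geometry import interdomain_angle, pairwise_rmsd_matrix
from fcgr3kit.structure import assign_complex_roles
from fcgr3kit.synthetic import ToyComplexSpec, make_toy_complex

models = []
for angle in (82.7, 86.4):
    model, _ = make_toy_complex(ToyComplexSpec(angle_deg=angle))
    model.id = f"toy_{angle:g}deg"
    assign_complex_roles(model)
    models.append(model)

pairing = [("R", "R"), ("A", "A"), ("B", "B")]
matrix = pairwise_rmsd_matrix(models, chain_pairings=[pairing] * len(models))

print("pairwise main-chain RMSD (A) over N/CA/C/O of shared residues:")
print("  " + "\t".join(matrix.labels))
for label, row in zip(matrix.labels, matrix.values):
    print(f"  {label}\t" + "\t".join(f"{v:.2f}" for v in row))

for model in models:
    res = interdomain_angle(model)
    print(
        f"{model.id}: interdomain angle {res.angle_deg:.1f} deg "
        f"({res.n_residues_d1} d1 + {res.n_residues_d2} d2 Calpha)"
    )

print(
    "\nThe off-diagonal RMSD reflects the planted 3.7-degree hinge\n"
    "difference between the two receptors; the angles report each\n"
    "receptor's domain openness, the quantity averaged across crystal\n"
    "copies when comparing receptor variants."
)
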