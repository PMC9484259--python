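"""Decompose a receptor-Fc interface: BSA, contact classes, H-bonds.

Builds the default toy complex (five planted contacts, two receptor
glycans), then runs the interface stage: Shrake-Rupley buried surface
area with protein/glycan attribution, the 5 A contact network with
main-chain/side-chain and polarity classes, and distance-based
hydrogen-bond candidates.
"""

from fcgr3kit.interface import (
    buried_surface_area,
    classify_contacts,
    complex_partition,
    contact_network,
    decompose_bsa,
    detect_hbonds,
)
from fcgr3kit.structure import assign_complex_roles, detect_glycans
from fcgr3kit.synthetic import make_toy_complex

model, truth = make_toy_complex()
detect_glycans(model)
assign_complex_roles(model)

report = decompose_bsa(buried_surface_area(complex_partition(model)), model)
print(f"total buried surface area: {report.bsa_total:.1f} A^2 "
      f"(delta-ASA sum over receptor, Fc A, Fc B)")
for key, area in report.bsa_by_component.items():
    print(f"  {key:16s} {area:7.1f} A^2")
for name, (area, pct) in sorted(report.bsa_by_region.items()):
    if area > 0:
        print(f"  region {name:12s} {area:7.1f} A^2  ({pct:.0f}% of Fc side)")

net = classify_contacts(contact_network(model, cutoff=5.0), model)
print(f"\ncontacts at 5 A cutoff: {len(net.contacts)} "
      f"(planted: {truth['n_contacts']})")
for c in net.contacts:
    print(f"  {c.residue_a.label:12s} -- {c.residue_b.label:12s} "
          f"{c.min_dist:.2f} A  {c.chain_position_a}/{c.chain_position_b}  "
          f"{c.polarity_class}")

hbonds = detect_hbonds(model)
print(f"\nhydrogen-bond candidates (N/O pairs <= 3.5 A): {len(hbonds)}")

print(
    "\nEvery planted contact is recovered at its planted distance and,\n"
    "being a CB-CB pair, classified side-chain/side-chain hydrophobic;\n"
    "the glycan components are zero because both planted glycans sit\n"
    "outside the contact patch."
)
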