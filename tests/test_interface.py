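"""SASA, buried surface area, contact networks and hydrogen bonds."""

from __future__ import annotations

import numpy as np
import pytest

from fcgr3kit.interface import (
    buried_surface_area,
    classify_contacts,
    complex_partition,
    compute_sasa,
    contact_network,
    decompose_bsa,
    detect_hbonds,
)
from fcgr3kit.structure import (
    Atom,
    Chain,
    Residue,
    StructureModel,
    assign_complex_roles,
    detect_glycans,
)
from fcgr3kit.synthetic import ToyComplexSpec, make_toy_complex


def carbon_residue(chain: str, number: int, coords) -> Residue:
    return Residue(
        chain_id=chain, seq_number=number, name="ALA", kind="amino_acid",
        atoms=[Atom("C", "C", np.asarray(coords, float))],
    )


class TestSasa:
    def test_single_carbon_matches_analytic_sphere(self):
        res = carbon_residue("X", 1, [0, 0, 0])
        result = compute_sasa([res])
        exact = 4 * np.pi * (1.70 + 1.4) ** 2
        assert result.total == pytest.approx(exact, rel=1e-12)

    def test_disjoint_atoms_sum_isolated_spheres(self):
        a = carbon_residue("X", 1, [0, 0, 0])
        b = carbon_residue("X", 2, [50, 0, 0])
        result = compute_sasa([a, b])
        exact = 2 * 4 * np.pi * (1.70 + 1.4) ** 2
        assert result.total == pytest.approx(exact, rel=1e-12)

    @pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
    def test_two_sphere_overlap_matches_spherical_caps(self, d):
        """Equal spheres at distance d: exposed area has a closed form.

        Each extended sphere (radius R = r_vdw + probe) loses a cap of
        height h = R - d/2, area 2*pi*R*h.
        """
        R = 1.70 + 1.4
        a = carbon_residue("X", 1, [0, 0, 0])
        b = carbon_residue("X", 2, [d, 0, 0])
        result = compute_sasa([a, b], n_points=960)
        h = R - d / 2
        exact = 2 * (4 * np.pi * R * R - 2 * np.pi * R * h)
        assert abs(result.total - exact) / exact < 0.01

    def test_convergence_on_random_cluster(self):
        rng = np.random.default_rng(5)
        residues = [
            carbon_residue("X", i, rng.uniform(0, 10, size=3))
            for i in range(50)
        ]
        coarse = compute_sasa(residues, n_points=960).total
        fine = compute_sasa(residues, n_points=3840).total
        assert abs(coarse - fine) / fine < 0.01

    def test_per_residue_sums_equal_total(self, toy_complex):
        model, _ = toy_complex
        result = compute_sasa(model.chain("R").residues)
        assert sum(result.per_residue_area.values()) == pytest.approx(
            result.total, abs=1e-6
        )
        assert sum(result.per_atom_area.values()) == pytest.approx(
            result.total, abs=1e-6
        )

    def test_empty_selection_rejected(self):
        with pytest.raises(ValueError, match="no heavy atoms"):
            compute_sasa([])


class TestBsa:
    def test_separated_components_bury_nothing(self):
        a = [carbon_residue("A", 1, [0, 0, 0])]
        b = [carbon_residue("B", 1, [100, 0, 0])]
        report = buried_surface_area([a, b])
        assert report.bsa_total == pytest.approx(0.0, abs=1e-9)

    def test_additivity_over_residues(self, toy_complex):
        model, _ = toy_complex
        report = buried_surface_area(complex_partition(model))
        assert sum(report.per_residue_bsa.values()) == pytest.approx(
            report.bsa_total, abs=1.0
        )

    def test_half_sum_is_half_of_delta_asa_sum(self, toy_complex):
        model, _ = toy_complex
        part = complex_partition(model)
        full = buried_surface_area(part, convention="delta_asa_sum")
        half = buried_surface_area(part, convention="half_sum")
        assert half.bsa_total == pytest.approx(full.bsa_total / 2, abs=1e-6)

    def test_symmetric_under_component_relabeling(self):
        a = [carbon_residue("A", 1, [0, 0, 0])]
        b = [carbon_residue("B", 1, [3.0, 0, 0])]
        fwd = buried_surface_area([a, b]).bsa_total
        rev = buried_surface_area([b, a]).bsa_total
        assert fwd == pytest.approx(rev, abs=1e-9)
        assert fwd > 0

    def test_larger_probe_never_decreases_bsa_on_convex_pair(self):
        a = [carbon_residue("A", 1, [0, 0, 0])]
        b = [carbon_residue("B", 1, [6.5, 0, 0])]
        totals = [
            buried_surface_area([a, b], probe=p).bsa_total
            for p in (1.4, 1.8, 2.2)
        ]
        assert totals[0] <= totals[1] + 1e-9 <= totals[2] + 2e-9

    def test_matches_fine_grid_recomputation(self, toy_complex):
        model, _ = toy_complex
        part = complex_partition(model)
        coarse = buried_surface_area(part, n_points=960).bsa_total
        fine = buried_surface_area(part, n_points=10000).bsa_total
        assert coarse == pytest.approx(fine, rel=0.02)

    def test_overlapping_partition_rejected(self, toy_complex):
        model, _ = toy_complex
        part = complex_partition(model)
        with pytest.raises(ValueError, match="overlap"):
            buried_surface_area([part[0], part[0]])

    def test_independent_sasa_route_agrees(self, toy_complex):
        """Cross-check the BSA against a second SASA implementation."""
        import biotite.structure as struc

        model, _ = toy_complex
        part = complex_partition(model)
        report = buried_surface_area(part)

        def biotite_sasa(residues) -> float:
            atoms = [(r, a) for r in residues for a in r.atoms if a.is_heavy]
            arr = struc.AtomArray(len(atoms))
            arr.coord = np.array([a.coords for _, a in atoms])
            arr.chain_id = np.array([r.chain_id for r, _ in atoms])
            arr.res_id = np.array([r.seq_number for r, _ in atoms])
            arr.res_name = np.array([r.name for r, _ in atoms])
            arr.atom_name = np.array([a.name for _, a in atoms])
            arr.element = np.array([a.element for _, a in atoms])
            radii = {"C": 1.70, "N": 1.65, "O": 1.40, "S": 1.85}
            vdw = np.array([radii.get(a.element, 1.8) for _, a in atoms])
            return float(
                np.nansum(struc.sasa(arr, probe_radius=1.4, point_number=960,
                                     vdw_radii=vdw))
            )

        assembly = [r for comp in part for r in comp]
        oracle = sum(biotite_sasa(comp) for comp in part) - biotite_sasa(assembly)
        assert report.bsa_total == pytest.approx(oracle, rel=0.03, abs=2.0)


class TestDecomposition:
    def test_no_glycans_means_zero_glycan_component(self):
        model, _ = make_toy_complex(ToyComplexSpec(seed=20, glycan_sites=()))
        detect_glycans(model)
        assign_complex_roles(model)
        report = decompose_bsa(
            buried_surface_area(complex_partition(model)), model
        )
        assert report.bsa_by_component["glycan-glycan"] == 0.0
        assert report.bsa_by_component["glycan-protein"] == 0.0

    def test_components_sum_to_total(self, toy_complex):
        model, _ = toy_complex
        report = decompose_bsa(
            buried_surface_area(complex_partition(model)), model
        )
        assert sum(report.bsa_by_component.values()) == pytest.approx(
            report.bsa_total, abs=1.0
        )

    def test_region_percentages_bounded(self, toy_complex):
        model, _ = toy_complex
        report = decompose_bsa(
            buried_surface_area(complex_partition(model)), model
        )
        for name, (area, pct) in report.bsa_by_region.items():
            assert area >= 0
            assert 0 <= pct <= 100

    def test_planted_glycan_interface_attributed(self):
        """A glycan planted into the interface shows up in the glycan BSA."""
        # receptor glycan at residue 117 sits right under planted contact
        spec = ToyComplexSpec(
            seed=21,
            contacts=((120, "A", 296), (88, "B", 327)),
            glycan_sites=(("R", 45, 2),),
        )
        model, _ = make_toy_complex(spec)
        detect_glycans(model)
        assign_complex_roles(model)
        report = decompose_bsa(
            buried_surface_area(complex_partition(model)), model
        )
        assert "R/Asn45" in report.per_glycan_bsa
        # the Asn45 glycan is far from both planted contacts: buried area
        # there must be (numerically) zero
        assert report.per_glycan_bsa["R/Asn45"] == pytest.approx(0.0, abs=1.0)


class TestContacts:
    def test_cutoff_boundary(self):
        for d, expected in ((4.9, 1), (5.1, 0)):
            a = [carbon_residue("A", 1, [0, 0, 0])]
            b = [carbon_residue("B", 1, [d, 0, 0])]
            model = StructureModel(
                id="t", chains=[Chain("A", a), Chain("B", b)],
                roles={"A": "receptor", "B": "fc_chain_A"},
            )
            net = contact_network(model, 5.0, partition=[a, b])
            assert len(net.contacts) == expected

    def test_planted_contacts_found_exactly(self, toy_complex):
        model, truth = toy_complex
        net = contact_network(model)
        found = sorted(
            [c.residue_a.seq_number, c.residue_b.chain_id,
             c.residue_b.seq_number]
            for c in net.contacts
        )
        assert found == truth["contacts"]
        for c in net.contacts:
            assert c.min_dist == pytest.approx(
                truth["contact_distance"], abs=1e-6
            )

    def test_matches_brute_force_scan(self):
        """Toy lattice: KD-tree route equals the O(n^2) distance scan."""
        rng = np.random.default_rng(6)
        a = [
            carbon_residue("A", i, rng.uniform(0, 12, 3)) for i in range(30)
        ]
        b = [
            carbon_residue("B", i, rng.uniform(8, 20, 3)) for i in range(30)
        ]
        model = StructureModel(
            id="lat", chains=[Chain("A", a), Chain("B", b)],
            roles={"A": "receptor", "B": "fc_chain_A"},
        )
        net = contact_network(model, 5.0, partition=[a, b])
        brute = set()
        for ra in a:
            for rb in b:
                d = np.linalg.norm(ra.atoms[0].coords - rb.atoms[0].coords)
                if d <= 5.0:
                    brute.add((ra.seq_number, rb.seq_number))
        assert {
            (c.residue_a.seq_number, c.residue_b.seq_number)
            for c in net.contacts
        } == brute


class TestClassification:
    def _pair_model(self, atoms_a, atoms_b):
        ra = Residue("A", 1, "LEU", atoms_a, kind="amino_acid")
        rb = Residue("B", 1, "LEU", atoms_b, kind="amino_acid")
        model = StructureModel(
            id="t", chains=[Chain("A", [ra]), Chain("B", [rb])],
            roles={"A": "receptor", "B": "fc_chain_A"},
        )
        net = contact_network(model, 5.0, partition=[[ra], [rb]])
        return classify_contacts(net, model).contacts[0]

    def test_sidechain_carbon_pair_is_hydrophobic(self):
        rec = self._pair_model(
            [Atom("CD1", "C", [0, 0, 0])], [Atom("CG", "C", [4.0, 0, 0])]
        )
        assert rec.polarity_class == "hydrophobic"
        assert rec.chain_position_a == "sidechain"
        assert rec.chain_position_b == "sidechain"

    def test_backbone_n_o_pair_is_hydrophilic_mainchain(self):
        rec = self._pair_model(
            [Atom("N", "N", [0, 0, 0])], [Atom("O", "O", [3.2, 0, 0])]
        )
        assert rec.polarity_class == "hydrophilic"
        assert rec.chain_position_a == "mainchain"
        assert rec.chain_position_b == "mainchain"

    def test_mixed_pairs_are_both(self):
        rec = self._pair_model(
            [Atom("CB", "C", [0, 0, 0]), Atom("N", "N", [0, 0, 1.4])],
            [Atom("CB", "C", [4.0, 0, 0]), Atom("O", "O", [4.0, 0, 1.4])],
        )
        assert rec.polarity_class == "both"
        assert rec.chain_position_a == "both"

    def test_every_contact_gets_exactly_one_polarity(self, toy_complex):
        model, _ = toy_complex
        net = classify_contacts(contact_network(model), model)
        for c in net.contacts:
            assert c.polarity_class in ("hydrophilic", "hydrophobic", "both")


def build_ideal_helix(n_res: int = 12) -> StructureModel:
    """Polyalanine alpha-helix from ideal internal coordinates (NeRF)."""

    def place(a, b, c, bond, angle_deg, torsion_deg):
        # NeRF: place D from three predecessors, bond |CD|, angle B-C-D,
        # torsion A-B-C-D
        bc = c - b
        bc /= np.linalg.norm(bc)
        n = np.cross(b - a, bc)
        n /= np.linalg.norm(n)
        m = np.cross(n, bc)
        ang, tor = np.radians(angle_deg), np.radians(torsion_deg)
        return c + bond * (
            -np.cos(ang) * bc
            + np.sin(ang) * np.cos(tor) * m
            + np.sin(ang) * np.sin(tor) * n
        )

    phi, psi, omega = -57.0, -47.0, 180.0
    coords = {}
    coords[(1, "N")] = np.array([0.0, 0.0, 0.0])
    coords[(1, "CA")] = np.array([1.458, 0.0, 0.0])
    coords[(1, "C")] = coords[(1, "CA")] + 1.525 * np.array(
        [np.cos(np.radians(180 - 111.2)), np.sin(np.radians(180 - 111.2)), 0.0]
    )
    for i in range(1, n_res + 1):
        # next amide N always built (a pseudo-atom after the last residue)
        # so every carbonyl O can sit in its peptide plane, anti to it
        coords[(i + 1, "N")] = place(
            coords[(i, "N")], coords[(i, "CA")], coords[(i, "C")],
            1.329, 116.2, psi,
        )
        to_n = coords[(i + 1, "N")] - coords[(i, "C")]
        to_ca = coords[(i, "CA")] - coords[(i, "C")]
        bisect = -(to_n / np.linalg.norm(to_n) + to_ca / np.linalg.norm(to_ca))
        coords[(i, "O")] = coords[(i, "C")] + 1.231 * bisect / np.linalg.norm(
            bisect
        )
        if i < n_res:
            coords[(i + 1, "CA")] = place(
                coords[(i, "CA")], coords[(i, "C")], coords[(i + 1, "N")],
                1.458, 121.7, omega,
            )
            coords[(i + 1, "C")] = place(
                coords[(i, "C")], coords[(i + 1, "N")], coords[(i + 1, "CA")],
                1.525, 111.2, phi,
            )
    chain = Chain("A")
    for i in range(1, n_res + 1):
        chain.residues.append(
            Residue(
                chain_id="A", seq_number=i, name="ALA", kind="amino_acid",
                atoms=[
                    Atom("N", "N", coords[(i, "N")]),
                    Atom("CA", "C", coords[(i, "CA")]),
                    Atom("C", "C", coords[(i, "C")]),
                    Atom("O", "O", coords[(i, "O")]),
                ],
            )
        )
    return StructureModel(
        id="helix", chains=[chain], roles={"A": "fc_chain_A"}
    )


class TestHbonds:
    def _two_res_model(self, d: float) -> StructureModel:
        ra = Residue("A", 1, "ALA", [Atom("N", "N", [0, 0, 0])],
                     kind="amino_acid")
        rb = Residue("B", 1, "ALA", [Atom("O", "O", [d, 0, 0])],
                     kind="amino_acid")
        return StructureModel(
            id="t", chains=[Chain("A", [ra]), Chain("B", [rb])],
            roles={"A": "receptor", "B": "fc_chain_A"},
        )

    def test_backbone_pair_within_cutoff_reported(self):
        model = self._two_res_model(3.2)
        hbonds = detect_hbonds(
            model, partition=[[model.chains[0].residues[0]],
                              [model.chains[1].residues[0]]]
        )
        assert len(hbonds) == 1
        assert hbonds[0][2] == pytest.approx(3.2)

    def test_pair_beyond_cutoff_not_reported(self):
        model = self._two_res_model(3.8)
        hbonds = detect_hbonds(
            model, partition=[[model.chains[0].residues[0]],
                              [model.chains[1].residues[0]]]
        )
        assert hbonds == []

    def test_ideal_helix_recovers_i_to_i_minus_4_ladder(self):
        model = build_ideal_helix(12)
        residues = model.chains[0].residues
        hbonds = detect_hbonds(model, partition=[residues])
        atom_res = {
            id(a): r.seq_number for r in residues for a in r.atoms
        }
        pairs = {
            (atom_res[id(donor)], atom_res[id(acceptor)])
            for donor, acceptor, _ in hbonds
        }
        ladder = {(i, i - 4) for i in range(5, 13)}
        assert ladder <= pairs
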