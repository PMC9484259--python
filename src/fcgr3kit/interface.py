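"""Solvent accessibility, buried-surface-area decomposition and contacts.

SASA is a deterministic Shrake-Rupley estimate (golden-spiral sphere
sampling, NACCESS-like united-atom radii, 1.4 A probe).  Buried surface
area is the per-atom loss of SASA between each component alone and the
full assembly; it is decomposed by owner (protein vs glycan), by Fc/
receptor region, and per residue.  Contact networks use a 5 A heavy-atom
cutoff with main-chain/side-chain and hydrophilic/hydrophobic/both
classification; hydrogen bonds are distance-only N/O donor-acceptor
pairs (resolution-limited data, no angle term).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .structure import (
    MAINCHAIN_ATOMS,
    Atom,
    RegionScheme,
    Residue,
    StructureModel,
    default_scheme,
)

__all__ = [
    "SASAResult",
    "InterfaceReport",
    "ContactRecord",
    "ContactNetwork",
    "compute_sasa",
    "buried_surface_area",
    "decompose_bsa",
    "complex_partition",
    "contact_network",
    "classify_contacts",
    "detect_hbonds",
]

#: United-atom van der Waals radii (A), NACCESS-like values.
RADII_SETS: dict[str, dict[str, float]] = {
    "naccess_like": {
        "C": 1.70, "N": 1.65, "O": 1.40, "S": 1.85, "P": 1.80,
        "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
        "DEFAULT": 1.80,
    },
}


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + 5.0 ** 0.5) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


@dataclass
class SASAResult:
    per_atom_area: dict[int, float]       # id(Atom) -> A^2
    per_residue_area: dict[int, float]    # id(Residue) -> A^2
    total: float
    probe: float
    n_points: int
    radii_set: str


@dataclass
class InterfaceReport:
    bsa_total: float
    convention: str
    per_atom_delta: dict[int, float] = field(default_factory=dict)
    per_residue_bsa: dict[int, float] = field(default_factory=dict)
    residue_index: dict[int, Residue] = field(default_factory=dict)
    atom_index: dict[int, tuple[Residue, Atom]] = field(default_factory=dict)
    components: list[list[Residue]] = field(default_factory=list)
    component_of_atom: dict[int, int] = field(default_factory=dict)
    bsa_by_component: dict[str, float] = field(default_factory=dict)
    bsa_by_region: dict[str, tuple[float, float]] = field(default_factory=dict)
    per_glycan_bsa: dict[str, float] = field(default_factory=dict)
    params: dict = field(default_factory=dict)


@dataclass
class ContactRecord:
    residue_a: Residue
    residue_b: Residue
    min_dist: float
    chain_position_a: str = ""   # mainchain | sidechain | both
    chain_position_b: str = ""
    polarity_class: str = ""     # hydrophilic | hydrophobic | both


@dataclass
class ContactNetwork:
    contacts: list[ContactRecord]
    hbonds: list[tuple[Atom, Atom, float]] = field(default_factory=list)
    cutoff: float = 5.0


def _gather_atoms(
    residues: list[Residue], include_waters: bool = False
) -> tuple[list[tuple[Residue, Atom]], np.ndarray, np.ndarray]:
    pairs = [
        (r, a)
        for r in residues
        if include_waters or r.kind != "water"
        for a in r.atoms
        if a.is_heavy
    ]
    coords = np.array([a.coords for _, a in pairs]) if pairs else np.empty((0, 3))
    return pairs, coords, None


def compute_sasa(
    residues: list[Residue] | StructureModel,
    probe: float = 1.4,
    n_points: int = 960,
    radii_set: str = "naccess_like",
    include_waters: bool = False,
) -> SASAResult:
    """Shrake-Rupley solvent-accessible surface area.

    Deterministic for a fixed ``n_points``: the sampling points come
    from a golden-spiral construction, not a random generator.
    """
    if isinstance(residues, StructureModel):
        residues = residues.residues()
    radii_table = RADII_SETS[radii_set]
    if any(v <= 0 for v in radii_table.values()):
        raise ValueError(f"radii set {radii_set!r} contains a non-positive radius")
    pairs, coords, _ = _gather_atoms(residues, include_waters)
    if len(pairs) == 0:
        raise ValueError("no heavy atoms in selection")
    radii = np.array(
        [
            radii_table.get(a.element.upper(), radii_table["DEFAULT"])
            for _, a in pairs
        ]
    )
    ext = radii + probe
    unit = _sphere_points(n_points)
    tree = cKDTree(coords)
    max_reach = 2.0 * ext.max()
    neighbor_lists = tree.query_ball_point(coords, max_reach)

    per_atom: dict[int, float] = {}
    per_res: dict[int, float] = {}
    total = 0.0
    for i, (res, atom) in enumerate(pairs):
        pts = coords[i] + ext[i] * unit
        exposed = np.ones(n_points, dtype=bool)
        for j in neighbor_lists[i]:
            if j == i:
                continue
            d = pts - coords[j]
            exposed &= (d * d).sum(axis=1) > ext[j] ** 2
            if not exposed.any():
                break
        area = 4.0 * np.pi * ext[i] ** 2 * exposed.sum() / n_points
        per_atom[id(atom)] = area
        per_res[id(res)] = per_res.get(id(res), 0.0) + area
        total += area
    return SASAResult(
        per_atom_area=per_atom,
        per_residue_area=per_res,
        total=total,
        probe=probe,
        n_points=n_points,
        radii_set=radii_set,
    )


def complex_partition(model: StructureModel) -> list[list[Residue]]:
    """Partition a role-assigned complex into its three components.

    Each component holds the protein chain plus the glycan trees
    attached to it (a glycan belongs to the component of its attachment
    chain).  Waters and unattached heteroatoms are excluded.
    """
    if not model.roles:
        raise ValueError("roles must be assigned before partitioning")
    glycan_res = {id(r) for g in model.glycans for r in g.sugar_residues}
    parts = []
    for role in ("receptor", "fc_chain_A", "fc_chain_B"):
        chain = model.chain_by_role(role)
        comp = [r for r in chain.residues if r.kind == "amino_acid"]
        for g in model.glycans_of_chain(chain.chain_id):
            comp.extend(g.sugar_residues)
        # sugar residues deposited in separate chains: claim those whose
        # glycan attaches to this chain
        for c in model.chains:
            if c is chain:
                continue
            if model.roles.get(c.chain_id):
                continue
            for r in c.residues:
                if id(r) in glycan_res and any(
                    id(r) in {id(s) for s in g.sugar_residues}
                    for g in model.glycans_of_chain(chain.chain_id)
                ):
                    comp.append(r)
        parts.append(comp)
    return parts


def buried_surface_area(
    partition: list[list[Residue]],
    convention: str = "delta_asa_sum",
    probe: float = 1.4,
    n_points: int = 960,
    radii_set: str = "naccess_like",
) -> InterfaceReport:
    """Buried surface area of an assembly of disjoint components.

    ``delta_asa_sum`` counts the SASA loss of every component (both
    sides of each interface); ``half_sum`` halves that, matching the
    PISA "interface area" convention.  Per-atom deltas are retained for
    downstream decomposition.
    """
    if convention not in ("delta_asa_sum", "half_sum"):
        raise ValueError(f"unknown convention {convention!r}")
    seen: set[int] = set()
    for comp in partition:
        ids = {id(r) for r in comp}
        if ids & seen:
            raise ValueError("partition components overlap")
        seen |= ids
    assembly = [r for comp in partition for r in comp]
    sasa_assembly = compute_sasa(assembly, probe, n_points, radii_set)
    per_atom_delta: dict[int, float] = {}
    atom_index: dict[int, tuple[Residue, Atom]] = {}
    component_of_atom: dict[int, int] = {}
    residue_index: dict[int, Residue] = {}
    for ci, comp in enumerate(partition):
        sasa_alone = compute_sasa(comp, probe, n_points, radii_set)
        for r in comp:
            residue_index[id(r)] = r
            for a in r.atoms:
                if not a.is_heavy:
                    continue
                delta = sasa_alone.per_atom_area.get(id(a), 0.0) - \
                    sasa_assembly.per_atom_area.get(id(a), 0.0)
                per_atom_delta[id(a)] = delta
                atom_index[id(a)] = (r, a)
                component_of_atom[id(a)] = ci
    scale = 0.5 if convention == "half_sum" else 1.0
    per_residue = {}
    for aid, delta in per_atom_delta.items():
        rid = id(atom_index[aid][0])
        per_residue[rid] = per_residue.get(rid, 0.0) + scale * delta
    total = scale * sum(per_atom_delta.values())
    return InterfaceReport(
        bsa_total=total,
        convention=convention,
        per_atom_delta={k: scale * v for k, v in per_atom_delta.items()},
        per_residue_bsa=per_residue,
        residue_index=residue_index,
        atom_index=atom_index,
        components=partition,
        component_of_atom=component_of_atom,
        params={
            "probe": probe, "n_points": n_points, "radii_set": radii_set,
        },
    )


def decompose_bsa(
    report: InterfaceReport,
    model: StructureModel,
    scheme: RegionScheme | None = None,
    neighbor_cutoff: float = 5.0,
) -> InterfaceReport:
    """Fill the component-type, per-region and per-glycan BSA breakdown.

    Atom ownership: an atom is a glycan atom when its residue belongs to
    a detected glycan tree, else a protein atom.  A buried glycan atom is
    attributed glycan-glycan when its nearest cross-component neighbour
    within ``neighbor_cutoff`` is also a glycan atom, glycan-protein
    otherwise (including occluded atoms with no near neighbour).  Region
    percentages are relative to the Fc-side buried total.
    """
    scheme = scheme or default_scheme()
    if not report.per_atom_delta:
        raise ValueError("report carries no per-atom deltas")
    glycan_res_ids = {id(r) for g in model.glycans for r in g.sugar_residues}

    aids = list(report.per_atom_delta)
    coords = np.array([report.atom_index[a][1].coords for a in aids])
    comps = np.array([report.component_of_atom[a] for a in aids])
    is_glycan = np.array(
        [id(report.atom_index[a][0]) in glycan_res_ids for a in aids]
    )
    deltas = np.array([report.per_atom_delta[a] for a in aids])

    tree = cKDTree(coords)
    neighbor_lists = tree.query_ball_point(coords, neighbor_cutoff)

    by_comp = {"protein-protein": 0.0, "glycan-protein": 0.0, "glycan-glycan": 0.0}
    for i, delta in enumerate(deltas):
        if delta <= 0:
            continue
        cross = [j for j in neighbor_lists[i] if comps[j] != comps[i]]
        if cross:
            dists = np.linalg.norm(coords[cross] - coords[i], axis=1)
            nearest_is_glycan = bool(is_glycan[cross[int(np.argmin(dists))]])
        else:
            nearest_is_glycan = False
        if is_glycan[i]:
            key = "glycan-glycan" if (cross and nearest_is_glycan) else "glycan-protein"
        else:
            key = "glycan-protein" if (cross and nearest_is_glycan) else "protein-protein"
        by_comp[key] += delta
    report.bsa_by_component = by_comp

    # region decomposition over the Fc side and receptor patches
    role_of_chain = model.roles
    fc_total = sum(
        d for i, d in zip(aids, deltas)
        if role_of_chain.get(report.atom_index[i][0].chain_id, "").startswith("fc")
        or (
            id(report.atom_index[i][0]) in glycan_res_ids
            and report.component_of_atom[i] in (1, 2)
        )
    )
    regions: dict[str, tuple[float, float]] = {}
    for name in scheme.fc_regions:
        members = scheme.fc_regions[name]
        area = 0.0
        for rid, bsa in report.per_residue_bsa.items():
            res = report.residue_index[rid]
            if res.kind != "amino_acid":
                continue
            if role_of_chain.get(res.chain_id, "").startswith("fc") and \
                    res.seq_number in members:
                area += bsa
        pct = 100.0 * area / fc_total if fc_total > 0 else 0.0
        regions[name] = (area, pct)
    for name in ("patch_A", "patch_B"):
        members = scheme.receptor_regions[name]
        area = sum(
            bsa
            for rid, bsa in report.per_residue_bsa.items()
            if (res := report.residue_index[rid]).kind == "amino_acid"
            and role_of_chain.get(res.chain_id) == "receptor"
            and res.seq_number in members
        )
        regions[name] = (area, 100.0 * area / fc_total if fc_total > 0 else 0.0)
    report.bsa_by_region = regions

    per_glycan = {}
    for g in model.glycans:
        area = sum(
            report.per_residue_bsa.get(id(r), 0.0) for r in g.sugar_residues
        )
        per_glycan[f"{g.attach_chain}/Asn{g.site}"] = area
    report.per_glycan_bsa = per_glycan
    return report


def contact_network(
    model: StructureModel,
    cutoff: float = 5.0,
    partition: list[list[Residue]] | None = None,
) -> ContactNetwork:
    """All cross-component residue pairs with any heavy-atom pair <= cutoff."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    partition = partition or complex_partition(model)
    comp_pairs = []
    for ci, comp in enumerate(partition):
        pairs, coords, _ = _gather_atoms(comp)
        comp_pairs.append((pairs, coords))
    records: list[ContactRecord] = []
    for ci in range(len(partition)):
        pa, xa = comp_pairs[ci]
        if len(xa) == 0:
            continue
        tree_a = cKDTree(xa)
        for cj in range(ci + 1, len(partition)):
            pb, xb = comp_pairs[cj]
            if len(xb) == 0:
                continue
            pairs_idx = tree_a.query_ball_tree(cKDTree(xb), cutoff)
            best: dict[tuple[int, int], float] = {}
            for i, hits in enumerate(pairs_idx):
                if not hits:
                    continue
                res_i = pa[i][0]
                for j in hits:
                    res_j = pb[j][0]
                    d = float(np.linalg.norm(xa[i] - xb[j]))
                    key = (id(res_i), id(res_j))
                    if d < best.get(key, np.inf):
                        best[key] = d
            index_a = {id(r): r for r, _ in pa}
            index_b = {id(r): r for r, _ in pb}
            for (ra, rb), d in best.items():
                records.append(
                    ContactRecord(
                        residue_a=index_a[ra], residue_b=index_b[rb], min_dist=d
                    )
                )
    records.sort(
        key=lambda r: (r.residue_a.chain_id, r.residue_a.seq_number,
                       r.residue_b.chain_id, r.residue_b.seq_number)
    )
    return ContactNetwork(contacts=records, cutoff=cutoff)


def _position_class(residue: Residue, atom_names: set[str]) -> str:
    if residue.kind != "amino_acid":
        return "sidechain"
    main = atom_names & MAINCHAIN_ATOMS
    side = atom_names - MAINCHAIN_ATOMS
    if main and side:
        return "both"
    return "mainchain" if main else "sidechain"


def classify_contacts(net: ContactNetwork, model: StructureModel) -> ContactNetwork:
    """Assign chain-position and polarity classes to every contact.

    A contact is hydrophobic when every participating atom pair is
    carbon-carbon, hydrophilic when every pair involves at least one
    N/O/S atom, and 'both' otherwise.
    """
    polar = {"N", "O", "S"}
    for rec in net.contacts:
        names_a: set[str] = set()
        names_b: set[str] = set()
        any_cc = any_polar = False
        for a in rec.residue_a.atoms:
            if not a.is_heavy:
                continue
            for b in rec.residue_b.atoms:
                if not b.is_heavy:
                    continue
                d = float(np.linalg.norm(a.coords - b.coords))
                if d <= net.cutoff:
                    names_a.add(a.name)
                    names_b.add(b.name)
                    ea, eb = a.element.upper(), b.element.upper()
                    if ea == "C" and eb == "C":
                        any_cc = True
                    if ea in polar or eb in polar:
                        any_polar = True
        rec.chain_position_a = _position_class(rec.residue_a, names_a)
        rec.chain_position_b = _position_class(rec.residue_b, names_b)
        if any_cc and any_polar:
            rec.polarity_class = "both"
        elif any_cc:
            rec.polarity_class = "hydrophobic"
        else:
            rec.polarity_class = "hydrophilic"
    return net


_DONOR_O = {
    ("SER", "OG"), ("THR", "OG1"), ("TYR", "OH"),
}


def _is_donor(res: Residue, atom: Atom) -> bool:
    if atom.element.upper() == "N":
        return True
    if atom.element.upper() == "O":
        if (res.name, atom.name) in _DONOR_O:
            return True
        if res.kind == "saccharide" and atom.name.startswith("O") and \
                atom.name not in ("O5",):  # ring oxygen is no donor
            return True
    return False


def _is_acceptor(res: Residue, atom: Atom) -> bool:
    if atom.element.upper() == "O":
        return True
    if atom.element.upper() == "N" and res.name == "HIS" and \
            atom.name in ("ND1", "NE2"):
        return True
    return False


def detect_hbonds(
    model: StructureModel,
    dist_cutoff: float = 3.5,
    partition: list[list[Residue]] | None = None,
    include_intra_fc: bool = True,
    min_seq_sep: int = 2,
) -> list[tuple[Atom, Atom, float]]:
    """Distance-only candidate hydrogen bonds (donor N/O to acceptor O/N).

    Cross-component pairs always qualify; with ``include_intra_fc`` pairs
    within an Fc chain separated by at least ``min_seq_sep`` residues are
    also scanned (the intra-Fc BC/DE loop bonds).  No angle criterion is
    applied: the source data are resolution-limited X-ray models.
    """
    partition = partition or complex_partition(model)
    comp_of_res = {
        id(r): ci for ci, comp in enumerate(partition) for r in comp
    }
    fc_roles = {"fc_chain_A", "fc_chain_B"}
    entries = []  # (res, atom)
    for comp in partition:
        for r in comp:
            for a in r.atoms:
                if a.element.upper() in ("N", "O"):
                    entries.append((r, a))
    coords = np.array([a.coords for _, a in entries])
    tree = cKDTree(coords)
    out: list[tuple[Atom, Atom, float]] = []
    seen: set[tuple[int, int]] = set()
    for i, j in tree.query_pairs(dist_cutoff):
        ri, ai = entries[i]
        rj, aj = entries[j]
        if ri is rj:
            continue
        same_comp = comp_of_res[id(ri)] == comp_of_res[id(rj)]
        if same_comp:
            if not include_intra_fc:
                continue
            role = model.roles.get(ri.chain_id, "")
            if role not in fc_roles or ri.chain_id != rj.chain_id:
                continue
            if abs(ri.seq_number - rj.seq_number) < min_seq_sep:
                continue
        d = float(np.linalg.norm(ai.coords - aj.coords))
        for donor_pair, acc_pair in ((
            (ri, ai), (rj, aj)), ((rj, aj), (ri, ai)),
        ):
            if _is_donor(*donor_pair) and _is_acceptor(*acc_pair):
                key = (id(donor_pair[1]), id(acc_pair[1]))
                if key not in seen:
                    seen.add(key)
                    out.append((donor_pair[1], acc_pair[1], d))
                break
    out.sort(key=lambda t: t[2])
    return out
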