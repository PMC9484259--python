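"""Hierarchical structure model for receptor-Fc complexes.

Parses mmCIF/PDB coordinate files into a light-weight atom/residue/chain
hierarchy, detects Asn-linked glycan trees by covalent-distance criteria,
and assigns biological roles (receptor, Fc chain A, Fc chain B) to the
chains of an FcgammaRIII-Fc complex.

Conventions
-----------
* Author residue numbering is canonical throughout (the Fc uses EU-style
  numbering, residues 237-447 of the construct).
* Hydrogens are dropped on parse; the deposited structures are 1.9-3.8 A
  X-ray models with no hydrogens.
* Alternate locations: the highest-occupancy conformer is kept, ties
  resolved in favour of altloc 'A'.
* Waters are flagged and excluded from all downstream interface math by
  default.
"""

from __future__ import annotations

import json
import urllib.request
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "Chain",
    "GlycanTree",
    "StructureModel",
    "RegionScheme",
    "default_scheme",
    "parse_structure",
    "write_pdb",
    "detect_glycans",
    "assign_complex_roles",
    "split_complex_copies",
    "select_region",
    "structure_inventory",
    "fetch_structure",
    "ParseError",
    "RoleAssignmentError",
    "FetchError",
]

#: Monosaccharide residue names recognised as glycan building blocks.
SACCHARIDES = {
    "NAG", "BMA", "MAN", "FUC", "GAL", "NDG", "SIA",
    "GLC", "BGC", "NGA", "XYL", "FUL", "A2G", "GLA",
}

WATERS = {"HOH", "WAT", "DOD", "H2O"}

AMINO_ACIDS_3 = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
    "MSE", "SEC", "PYL",
}

THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "MSE": "M", "SEC": "U", "PYL": "O",
}

MAINCHAIN_ATOMS = {"N", "CA", "C", "O", "OXT"}


class ParseError(ValueError):
    """Raised when a coordinate file cannot be read."""


class RoleAssignmentError(ValueError):
    """Raised when chains cannot be matched to receptor/Fc roles."""


class FetchError(OSError):
    """Raised when an accession cannot be downloaded."""


@dataclass(eq=False)
class Atom:
    name: str
    element: str
    coords: np.ndarray
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if not np.all(np.isfinite(self.coords)):
            raise ValueError(f"non-finite coordinates for atom {self.name}")
        if not self.element:
            raise ValueError(f"empty element for atom {self.name}")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"occupancy {self.occupancy} outside [0,1]")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() not in ("H", "D")


@dataclass(eq=False)
class Residue:
    chain_id: str
    seq_number: int
    name: str
    atoms: list[Atom]
    icode: str = ""
    kind: str = "other"  # amino_acid | saccharide | water | other

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError(
                f"residue {self.name} {self.chain_id}{self.seq_number} has no atoms"
            )

    @property
    def label(self) -> str:
        return f"{self.chain_id}/{self.name}{self.seq_number}{self.icode}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def heavy_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms if a.is_heavy])


@dataclass(eq=False)
class Chain:
    chain_id: str
    residues: list[Residue] = field(default_factory=list)

    def amino_acids(self) -> list[Residue]:
        return [r for r in self.residues if r.kind == "amino_acid"]

    def residue(self, seq_number: int, icode: str = "") -> Residue | None:
        for r in self.residues:
            if r.seq_number == seq_number and r.icode == icode:
                return r
        return None

    def sequence(self) -> str:
        return "".join(
            THREE_TO_ONE.get(r.name, "X") for r in self.amino_acids()
        )


@dataclass(eq=False)
class GlycanTree:
    attach_residue: Residue
    attach_chain: str
    sugar_residues: list[Residue]
    linkage_edges: list[tuple[Residue, Residue]]
    low_confidence: bool = False

    @property
    def site(self) -> int:
        return self.attach_residue.seq_number

    def atoms(self) -> list[Atom]:
        return [a for r in self.sugar_residues for a in r.atoms]


@dataclass(eq=False)
class StructureModel:
    id: str
    chains: list[Chain]
    glycans: list[GlycanTree] = field(default_factory=list)
    roles: dict[str, str] = field(default_factory=dict)
    copy_index: int = 1
    unattached_saccharides: list[Residue] = field(default_factory=list)

    def chain(self, chain_id: str) -> Chain:
        for c in self.chains:
            if c.chain_id == chain_id:
                return c
        raise KeyError(f"no chain {chain_id!r} in structure {self.id}")

    def chain_by_role(self, role: str) -> Chain:
        for cid, r in self.roles.items():
            if r == role:
                return self.chain(cid)
        raise KeyError(f"no chain assigned role {role!r} in {self.id}")

    def residues(self) -> list[Residue]:
        return [r for c in self.chains for r in c.residues]

    def glycans_of_chain(self, chain_id: str) -> list[GlycanTree]:
        return [g for g in self.glycans if g.attach_chain == chain_id]


@dataclass
class RegionScheme:
    """Named residue ranges on the Fc and the receptor.

    Fc loop definitions follow the CH2-domain loop nomenclature (EU
    numbering); receptor patches are the monomer-A and monomer-B contact
    patches, and d1/d2 are the two Ig-like ectodomain lobes with the
    interdomain pivot at residue 89.
    """

    fc_regions: dict[str, frozenset[int]]
    receptor_regions: dict[str, frozenset[int]]
    d1: tuple[int, int] = (1, 88)
    d2: tuple[int, int] = (90, 174)
    pivot: int = 89
    ch2: tuple[int, int] = (231, 340)

    def __post_init__(self) -> None:
        for name, members in {**self.fc_regions, **self.receptor_regions}.items():
            if not members:
                raise ValueError(f"region {name!r} is empty")
        d1 = set(range(self.d1[0], self.d1[1] + 1))
        d2 = set(range(self.d2[0], self.d2[1] + 1))
        if d1 & d2 or self.pivot in d1 | d2:
            raise ValueError("d1 and d2 must be disjoint and exclude the pivot")

    def region(self, role: str, name: str) -> frozenset[int]:
        table = self.fc_regions if role.startswith("fc") else self.receptor_regions
        if name not in table:
            raise KeyError(f"unknown region {name!r} for role {role!r}")
        return table[name]


def _rng(lo: int, hi: int) -> frozenset[int]:
    return frozenset(range(lo, hi + 1))


def default_scheme() -> RegionScheme:
    return RegionScheme(
        fc_regions={
            "n_terminus": _rng(220, 230),
            "BC_loop": _rng(267, 273),
            "BC_vicinity": _rng(265, 270),
            "DE_loop": _rng(294, 299),
            "FG_loop": _rng(325, 332),
        },
        receptor_regions={
            "patch_A": frozenset({117, 119, 120, 122, 124} | set(range(128, 135))),
            "patch_B": frozenset({88, 89, 90, 113, 158, 159, 161}),
            "d1": _rng(1, 88),
            "d2": _rng(90, 174),
        },
    )


def _classify_residue(name: str) -> str:
    if name in AMINO_ACIDS_3:
        return "amino_acid"
    if name in SACCHARIDES:
        return "saccharide"
    if name in WATERS:
        return "water"
    return "other"


def _pick_altloc(atoms: list[gemmi.Atom]) -> gemmi.Atom:
    # highest occupancy wins; ties resolved by altloc letter ('A' first)
    return sorted(atoms, key=lambda a: (-a.occ, a.altloc or "~"))[0]


def parse_structure(path: str | Path, dialect: str = "auto") -> StructureModel:
    """Read a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records with positive occupancy are represented; for
    alternate locations only the highest-occupancy conformer is kept
    (ties broken in favour of 'A').  Hydrogens are dropped.  Unknown
    residue names are classified ``other`` with a warning, never silently
    discarded.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    fmt = {
        "mmcif": gemmi.CoorFormat.Mmcif,
        "pdb": gemmi.CoorFormat.Pdb,
        "auto": gemmi.CoorFormat.Detect,
    }.get(dialect)
    if fmt is None:
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        st = gemmi.read_structure(str(path), format=fmt)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path}: no models in file")
    st.setup_entities()
    model = st[0]

    chains: list[Chain] = []
    unknown: set[str] = set()
    for gchain in model:
        chain = Chain(chain_id=gchain.name)
        for gres in gchain:
            by_name: dict[str, list[gemmi.Atom]] = {}
            for ga in gres:
                if ga.element.is_hydrogen:
                    continue
                if ga.occ <= 0:
                    continue
                by_name.setdefault(ga.name, []).append(ga)
            atoms = []
            for name, cands in by_name.items():
                ga = _pick_altloc(cands)
                atoms.append(
                    Atom(
                        name=name,
                        element=ga.element.name,
                        coords=np.array([ga.pos.x, ga.pos.y, ga.pos.z]),
                        occupancy=min(ga.occ, 1.0),
                        altloc=ga.altloc or "",
                    )
                )
            if not atoms:
                continue
            kind = _classify_residue(gres.name)
            if kind == "other":
                unknown.add(gres.name)
            chain.residues.append(
                Residue(
                    chain_id=gchain.name,
                    seq_number=gres.seqid.num,
                    icode=(gres.seqid.icode or "").strip(),
                    name=gres.name,
                    atoms=atoms,
                    kind=kind,
                )
            )
        if chain.residues:
            chains.append(chain)
    if unknown:
        warnings.warn(
            f"{path.name}: residue names classified as 'other': {sorted(unknown)}",
            stacklevel=2,
        )
    return StructureModel(id=path.stem, chains=chains)


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Write the model back out in PDB format (coordinates to 3 decimals)."""
    st = gemmi.Structure()
    st.name = model.id
    gmodel = gemmi.Model("1")
    for chain in model.chains:
        gchain = gemmi.Chain(chain.chain_id)
        for res in chain.residues:
            gres = gemmi.Residue()
            gres.name = res.name
            gres.seqid = gemmi.SeqId(res.seq_number, res.icode or " ")
            gres.het_flag = "A" if res.kind == "amino_acid" else "H"
            for atom in res.atoms:
                ga = gemmi.Atom()
                ga.name = atom.name
                ga.element = gemmi.Element(atom.element)
                ga.pos = gemmi.Position(*atom.coords)
                ga.occ = atom.occupancy
                ga.altloc = "\0" if not atom.altloc else atom.altloc
                gres.add_atom(ga)
            gchain.add_residue(gres)
        gmodel.add_chain(gchain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def _min_pair_distance(
    res_a: Residue, res_b: Residue, names_a: set[str] | None = None,
    names_b: set[str] | None = None,
) -> float:
    xa = np.array([a.coords for a in res_a.atoms
                   if names_a is None or a.name in names_a])
    xb = np.array([a.coords for a in res_b.atoms
                   if names_b is None or a.name in names_b])
    if len(xa) == 0 or len(xb) == 0:
        return np.inf
    d = np.linalg.norm(xa[:, None, :] - xb[None, :, :], axis=-1)
    return float(d.min())


def detect_glycans(model: StructureModel, bond_cutoff: float = 2.0) -> list[GlycanTree]:
    """Find Asn-linked glycan trees by heavy-atom bond distances.

    A tree is rooted at any saccharide whose anomeric C1 lies within
    ``bond_cutoff`` of an Asn side-chain ND2; sugar-sugar edges are O-C
    contacts within the same cutoff.  Saccharides reachable from no Asn
    are reported in ``model.unattached_saccharides``.  A root sugar with
    no C1 atom is linked by the nearest-atom criterion and the tree is
    flagged low-confidence.
    """
    sugars = [r for c in model.chains for r in c.residues if r.kind == "saccharide"]
    asns = [
        r for c in model.chains for r in c.residues
        if r.name == "ASN" and r.atom("ND2") is not None
    ]
    if not sugars:
        model.glycans = []
        model.unattached_saccharides = []
        return []

    # adjacency between sugars: any O atom of one within cutoff of a C atom
    # of the other (glycosidic O-C link), symmetric
    n = len(sugars)
    adj: dict[int, list[int]] = {i: [] for i in range(n)}
    for i in range(n):
        o_i = {a.name for a in sugars[i].atoms if a.element == "O"}
        c_i = {a.name for a in sugars[i].atoms if a.element == "C"}
        for j in range(i + 1, n):
            o_j = {a.name for a in sugars[j].atoms if a.element == "O"}
            c_j = {a.name for a in sugars[j].atoms if a.element == "C"}
            d = min(
                _min_pair_distance(sugars[i], sugars[j], o_i, c_j),
                _min_pair_distance(sugars[i], sugars[j], c_i, o_j),
            )
            if d <= bond_cutoff:
                adj[i].append(j)
                adj[j].append(i)

    trees: list[GlycanTree] = []
    claimed: set[int] = set()
    for asn in asns:
        nd2 = asn.atom("ND2")
        root_idx, low_conf = None, False
        best = bond_cutoff
        for i, s in enumerate(sugars):
            if i in claimed:
                continue
            c1 = s.atom("C1")
            if c1 is None:
                continue
            d = float(np.linalg.norm(c1.coords - nd2.coords))
            if d <= best:
                best, root_idx = d, i
        if root_idx is None:
            # damaged ring (no C1): fall back to the nearest heavy atom
            # of any sugar, within a relaxed shell, and flag the tree
            best = 1.5 * bond_cutoff
            for i, s in enumerate(sugars):
                if i in claimed or s.atom("C1") is not None:
                    continue
                d = min(
                    float(np.linalg.norm(a.coords - nd2.coords))
                    for a in s.atoms
                )
                if d <= best:
                    best, root_idx = d, i
                    low_conf = True
        if root_idx is None:
            continue
        # BFS from the root over the sugar adjacency graph
        order = [root_idx]
        edges: list[tuple[Residue, Residue]] = []
        seen = {root_idx}
        queue = [root_idx]
        while queue:
            cur = queue.pop(0)
            for nxt in adj[cur]:
                if nxt in seen or nxt in claimed:
                    continue
                seen.add(nxt)
                order.append(nxt)
                edges.append((sugars[cur], sugars[nxt]))
                queue.append(nxt)
        claimed |= seen
        trees.append(
            GlycanTree(
                attach_residue=asn,
                attach_chain=asn.chain_id,
                sugar_residues=[sugars[i] for i in order],
                linkage_edges=edges,
                low_confidence=low_conf,
            )
        )
    model.glycans = trees
    model.unattached_saccharides = [
        sugars[i] for i in range(n) if i not in claimed
    ]
    return trees


def _heavy_contacts_to(
    residues: list[Residue], target_coords: np.ndarray, cutoff: float
) -> int:
    """Count heavy atoms of *residues* within cutoff of any target atom."""
    if len(target_coords) == 0:
        return 0
    from scipy.spatial import cKDTree

    tree = cKDTree(target_coords)
    count = 0
    for res in residues:
        xs = res.heavy_coords()
        if len(xs) == 0:
            continue
        hits = tree.query_ball_point(xs, cutoff)
        count += sum(1 for h in hits if h)
    return count


def assign_complex_roles(
    model: StructureModel,
    scheme: RegionScheme | None = None,
    contact_cutoff: float = 5.0,
) -> StructureModel:
    """Assign receptor / fc_chain_A / fc_chain_B roles for one complex copy.

    The receptor is the protein chain with the shortest ordered length
    (~170 aa ectodomain vs ~210 aa Fc monomers).  The Fc chain whose
    BC+DE loop residues place more heavy atoms within 5 A of the receptor
    becomes chain A; ties are broken lexicographically with a warning.
    """
    scheme = scheme or default_scheme()
    protein_chains = [c for c in model.chains if len(c.amino_acids()) >= 50]
    if len(protein_chains) < 3:
        raise RoleAssignmentError(
            f"{model.id}: need one receptor-like and two Fc-like protein chains, "
            f"found {len(protein_chains)}; pass roles manually to override"
        )
    ranked = sorted(protein_chains, key=lambda c: (len(c.amino_acids()), c.chain_id))
    receptor = ranked[0]
    if len(receptor.amino_acids()) > 200:
        raise RoleAssignmentError(
            f"{model.id}: no chain matches the ~170-residue receptor length "
            "profile; use a manual role override"
        )
    fc_candidates = sorted(ranked[1:3], key=lambda c: c.chain_id)

    rec_coords = np.array(
        [a.coords for r in receptor.residues for a in r.atoms if a.is_heavy]
    )
    loop = scheme.fc_regions["BC_loop"] | scheme.fc_regions["DE_loop"]
    scores = []
    for c in fc_candidates:
        loop_res = [r for r in c.amino_acids() if r.seq_number in loop]
        scores.append(_heavy_contacts_to(loop_res, rec_coords, contact_cutoff))
    if scores[0] == scores[1]:
        warnings.warn(
            f"{model.id}: equal BC+DE loop contact counts for chains "
            f"{fc_candidates[0].chain_id}/{fc_candidates[1].chain_id}; "
            "assigning A/B lexicographically",
            stacklevel=2,
        )
        a_chain, b_chain = fc_candidates
    elif scores[0] > scores[1]:
        a_chain, b_chain = fc_candidates
    else:
        a_chain, b_chain = fc_candidates[1], fc_candidates[0]

    model.roles = {
        receptor.chain_id: "receptor",
        a_chain.chain_id: "fc_chain_A",
        b_chain.chain_id: "fc_chain_B",
    }
    return model


def split_complex_copies(model: StructureModel) -> list[StructureModel]:
    """Split an asymmetric unit with N receptor-Fc complexes into copies.

    Receptor-like chains (<=200 ordered aa) seed the copies; each takes
    the two nearest unclaimed Fc-like chains by centroid distance.
    Saccharide-only chains follow the protein chain nearest to them.
    """
    protein = [c for c in model.chains if len(c.amino_acids()) >= 50]
    receptors = sorted(
        (c for c in protein if len(c.amino_acids()) <= 200),
        key=lambda c: c.chain_id,
    )
    fcs = [c for c in protein if c not in receptors]
    others = [c for c in model.chains if c not in protein]
    if not receptors:
        return [model]

    def centroid(chain: Chain) -> np.ndarray:
        xs = np.array([a.coords for r in chain.residues for a in r.atoms])
        return xs.mean(axis=0)

    copies: list[StructureModel] = []
    free = list(fcs)
    for k, rec in enumerate(receptors, start=1):
        rc = centroid(rec)
        free.sort(key=lambda c: float(np.linalg.norm(centroid(c) - rc)))
        members = [rec] + free[:2]
        free = free[2:]
        copies.append(
            StructureModel(
                id=f"{model.id}", chains=members, copy_index=k
            )
        )
    # attach remaining (saccharide/water) chains to the nearest copy
    for c in others:
        cc = centroid(c)
        best = min(
            copies,
            key=lambda cp: min(
                float(np.linalg.norm(centroid(ch) - cc)) for ch in cp.chains
            ),
        )
        best.chains.append(c)
    return copies


def select_region(
    model: StructureModel,
    role: str,
    region_name: str,
    scheme: RegionScheme | None = None,
) -> list[Residue]:
    """Residues of the role's chain whose author number lies in the region.

    Disordered (missing) residues are simply absent from the result.
    """
    scheme = scheme or default_scheme()
    members = scheme.region(role, region_name)
    chain = model.chain_by_role(role)
    return [r for r in chain.amino_acids() if r.seq_number in members]


def structure_inventory(model: StructureModel) -> dict:
    """JSON-serialisable inventory: chains, residue counts, glycans, roles."""
    return {
        "id": model.id,
        "copy_index": model.copy_index,
        "chains": [
            {
                "chain_id": c.chain_id,
                "n_residues": len(c.residues),
                "n_amino_acids": len(c.amino_acids()),
                "n_saccharides": sum(1 for r in c.residues if r.kind == "saccharide"),
                "n_waters": sum(1 for r in c.residues if r.kind == "water"),
                "role": model.roles.get(c.chain_id, "unassigned"),
            }
            for c in model.chains
        ],
        "glycans": [
            {
                "attach_chain": g.attach_chain,
                "site": g.site,
                "n_sugars": len(g.sugar_residues),
                "sugars": [r.name for r in g.sugar_residues],
                "low_confidence": g.low_confidence,
            }
            for g in model.glycans
        ],
        "unattached_saccharides": [r.label for r in model.unattached_saccharides],
    }


def save_inventory(model: StructureModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(structure_inventory(model), indent=2))


def polymer_sequences(path: str | Path) -> dict[str, str]:
    """Full polymer (SEQRES/entity) sequences keyed by first chain id.

    Identity figures refer to the expressed constructs, not just the
    crystallographically ordered residues, so the entity sequence record
    is preferred over the coordinates when present.
    """
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    st.assign_label_seq_id()
    out: dict[str, str] = {}
    for ent in st.entities:
        if ent.entity_type != gemmi.EntityType.Polymer:
            continue
        if ent.polymer_type != gemmi.PolymerType.PeptideL:
            continue
        seq = gemmi.one_letter_code(ent.full_sequence)
        if not seq:
            continue
        key = ent.subchains[0] if ent.subchains else ent.name
        # map subchain back to an author chain id where possible
        for chain in st[0]:
            sub = chain.subchains()
            if any(s.subchain_id() in ent.subchains for s in sub):
                key = chain.name
                break
        out[key] = seq.upper().replace("-", "X")
    return out


RCSB_URL = "https://files.rcsb.org/download/{acc}.cif"


def fetch_structure(
    accession: str,
    cache_dir: str | Path = "scratch/pdb",
    timeout: float = 15.0,
) -> Path:
    """Download an mmCIF by PDB accession into a local cache (opt-in).

    Never called implicitly: offline use is the default everywhere else.
    """
    cache = Path(cache_dir)
    cache.mkdir(parents=True, exist_ok=True)
    dest = cache / f"{accession.upper()}.cif"
    if dest.exists() and dest.stat().st_size > 0:
        return dest
    url = RCSB_URL.format(acc=accession.upper())
    try:
        with urllib.request.urlopen(url, timeout=timeout) as resp:
            data = resp.read()
    except OSError as exc:
        raise FetchError(
            f"cannot download {accession} from {url}: {exc}"
        ) from exc
    dest.write_bytes(data)
    return dest
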