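"""Rigid-body superposition, RMSD matrices and interdomain angles.

Kabsch least-squares superposition underlies all pairwise main-chain
RMSD comparisons between complex copies; the interdomain angle of the
two-lobed receptor ectodomain is measured between the d1 and d2 Calpha
centroids with the Gly89 Calpha as the origin.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .seqmap import CorrespondenceMap, shared_residue_sets
from .structure import (
    RegionScheme,
    Residue,
    StructureModel,
    default_scheme,
)

__all__ = [
    "RigidTransform",
    "SuperpositionResult",
    "RMSDMatrix",
    "DomainAngleResult",
    "kabsch_superpose",
    "mainchain_rmsd",
    "pairwise_rmsd_matrix",
    "interdomain_angle",
    "GeometryError",
]

MAINCHAIN_SELECTIONS = {
    "mainchain": ("N", "CA", "C", "O"),
    "CA": ("CA",),
    "NCAC": ("N", "CA", "C"),
    "all_heavy": None,
}


class GeometryError(ValueError):
    pass


@dataclass
class RigidTransform:
    rotation: np.ndarray  # 3x3, proper
    translation: np.ndarray  # 3-vector

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, float)
        if not np.allclose(R @ R.T, np.eye(3), atol=1e-6):
            raise ValueError("rotation not orthonormal")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-6):
            raise ValueError("rotation is improper (det != +1)")
        self.rotation = R
        self.translation = np.asarray(self.translation, float)

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points, float) @ self.rotation.T + self.translation


@dataclass
class SuperpositionResult:
    transform: RigidTransform
    rmsd: float
    n_atoms: int
    atom_selection: str = "mainchain"


@dataclass
class RMSDMatrix:
    labels: list[str]
    values: np.ndarray
    selection_scope: str = "full_complex"

    def pair(self, label_a: str, label_b: str) -> float:
        i, j = self.labels.index(label_a), self.labels.index(label_b)
        return float(self.values[i, j])

    def group_average(self, group_a: list[str], group_b: list[str]) -> float:
        """Mean RMSD over all unordered cross pairs of two label groups.

        With ``group_a == group_b`` this is the mean over the distinct
        unordered pairs within the group (diagonal excluded).
        """
        vals = []
        if group_a == group_b:
            for i, la in enumerate(group_a):
                for lb in group_a[i + 1:]:
                    vals.append(self.pair(la, lb))
        else:
            for la in group_a:
                for lb in group_b:
                    if la != lb:
                        vals.append(self.pair(la, lb))
        return float(np.mean(vals))


@dataclass
class DomainAngleResult:
    angle_deg: float
    pivot_label: str
    centroid_d1: np.ndarray
    centroid_d2: np.ndarray
    n_residues_d1: int
    n_residues_d2: int


def kabsch_superpose(
    mobile: np.ndarray,
    reference: np.ndarray,
    weights: np.ndarray | None = None,
) -> SuperpositionResult:
    """Globally optimal least-squares rigid superposition (Kabsch, SVD).

    Reflections are excluded: the returned rotation is always proper.
    """
    P = np.asarray(mobile, float)
    Q = np.asarray(reference, float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise GeometryError("point sets must both be (n, 3)")
    n = len(P)
    if n < 3:
        raise GeometryError("need at least 3 points")
    if weights is None:
        w = np.ones(n)
    else:
        w = np.asarray(weights, float)
        if w.shape != (n,) or np.any(w < 0) or w.sum() == 0:
            raise GeometryError("weights must be non-negative with positive sum")
    w = w / w.sum()
    cp = (w[:, None] * P).sum(axis=0)
    cq = (w[:, None] * Q).sum(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = (w[:, None] * P0).T @ Q0
    U, S, Vt = np.linalg.svd(H)
    if S[1] < 1e-12:
        raise GeometryError("degenerate (collinear) point configuration")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    transform = RigidTransform(rotation=R, translation=t)
    moved = transform.apply(P)
    rmsd = float(np.sqrt((w * ((moved - Q) ** 2).sum(axis=1)).sum()))
    return SuperpositionResult(transform=transform, rmsd=rmsd, n_atoms=n)


def _role_of(model: StructureModel, res: Residue) -> str:
    return model.roles.get(res.chain_id, "unassigned")


def _pair_atoms(
    model_a: StructureModel,
    model_b: StructureModel,
    cmap: CorrespondenceMap,
    scope: str,
    selection: str,
    scheme: RegionScheme,
) -> tuple[np.ndarray, np.ndarray, int, int]:
    names = MAINCHAIN_SELECTIONS[selection]
    ch2 = set(range(scheme.ch2[0], scheme.ch2[1] + 1))
    xa, xb = [], []
    n_mapped = n_with_atoms = 0
    for res_a, res_b in cmap.pairs:
        if scope == "fc_ch2_only":
            role = _role_of(model_a, res_a)
            if role.startswith("fc") and res_a.seq_number not in ch2:
                continue
        n_mapped += 1
        got = False
        atom_names = names or sorted(
            {a.name for a in res_a.atoms} & {a.name for a in res_b.atoms}
        )
        for name in atom_names:
            aa, ab = res_a.atom(name), res_b.atom(name)
            if aa is not None and ab is not None and aa.is_heavy:
                xa.append(aa.coords)
                xb.append(ab.coords)
                got = True
        if got:
            n_with_atoms += 1
    return np.array(xa), np.array(xb), n_mapped, n_with_atoms


def mainchain_rmsd(
    model_a: StructureModel,
    model_b: StructureModel,
    cmap: CorrespondenceMap,
    scope: str = "full_complex",
    selection: str = "mainchain",
    min_coverage: float = 0.9,
) -> SuperpositionResult:
    """Superpose on the selected atom set and report the post-fit RMSD.

    The fit and the score use the same atom set (no fit/score split).
    ``scope='fc_ch2_only'`` restricts Fc-role residues to the CH2 range.
    """
    if not cmap.pairs:
        raise GeometryError("empty correspondence map")
    scheme = default_scheme()
    xa, xb, n_mapped, n_ok = _pair_atoms(
        model_a, model_b, cmap, scope, selection, scheme
    )
    if n_mapped == 0 or n_ok / n_mapped < min_coverage:
        raise GeometryError(
            f"only {n_ok}/{n_mapped} mapped residues have the "
            f"{selection} atoms present"
        )
    result = kabsch_superpose(xa, xb)
    result.atom_selection = selection
    return result


def pairwise_rmsd_matrix(
    models: list[StructureModel],
    chain_pairings: list[list[tuple[str, str]]] | None = None,
    scope: str = "full_complex",
    selection: str = "mainchain",
) -> RMSDMatrix:
    """Full symmetric matrix of pairwise main-chain RMSDs.

    ``chain_pairings[i]`` pairs chains of ``models[0]`` with chains of
    ``models[i]`` (role-matched).  When omitted, chains are paired by
    role if roles are assigned on all models, else by chain id.
    """
    if len(models) < 2:
        raise GeometryError("need at least two models")
    from .seqmap import correspondence_map

    if chain_pairings is None:
        chain_pairings = []
        for m in models:
            if models[0].roles and m.roles:
                pairing = [
                    (models[0].chain_by_role(role).chain_id,
                     m.chain_by_role(role).chain_id)
                    for role in ("receptor", "fc_chain_A", "fc_chain_B")
                ]
            else:
                pairing = [
                    (c.chain_id, c.chain_id) for c in models[0].chains
                    if c.amino_acids()
                ]
            chain_pairings.append(pairing)

    n = len(models)
    values = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            # map model i -> model j through model 0's chain pairing
            pairing_ij = [
                (ca_i, cb_j)
                for (_, ca_i), (_, cb_j) in zip(chain_pairings[i], chain_pairings[j])
            ]
            cmap = correspondence_map(models[i], models[j], pairing_ij)
            res = mainchain_rmsd(models[i], models[j], cmap, scope, selection)
            values[i, j] = values[j, i] = res.rmsd
    labels = [f"{m.id}:{m.copy_index}" for m in models]
    return RMSDMatrix(labels=labels, values=values, selection_scope=scope)


def interdomain_angle(
    model: StructureModel,
    chain_id: str | None = None,
    scheme: RegionScheme | None = None,
    shared_residues: list[Residue] | None = None,
) -> DomainAngleResult:
    """Angle between the d1 and d2 Calpha centroids seen from the pivot.

    The receptor ectodomain folds into two Ig-like lobes (d1: residues
    1-88, d2: 90-174) hinged at Gly89; the angle between the vectors
    pivot->centroid(d1 Calpha) and pivot->centroid(d2 Calpha) measures
    the openness of the comma shape.  ``shared_residues`` optionally
    restricts the centroids to a residue set shared across structures.
    """
    scheme = scheme or default_scheme()
    if chain_id is None:
        if "receptor" in model.roles.values():
            chain = model.chain_by_role("receptor")
        elif len(model.chains) == 1:
            chain = model.chains[0]
        else:
            raise GeometryError("chain_id required for multi-chain model")
    else:
        chain = model.chain(chain_id)

    pivot_res = chain.residue(scheme.pivot)
    pivot_ca = pivot_res.atom("CA") if pivot_res else None
    if pivot_ca is None:
        raise GeometryError(
            f"pivot residue {scheme.pivot} Calpha unresolved in chain "
            f"{chain.chain_id}; re-run with a nearest-resolved fallback "
            "pivot if appropriate"
        )
    allowed = (
        {(r.chain_id, r.seq_number, r.icode) for r in shared_residues}
        if shared_residues is not None
        else None
    )

    def domain_cas(lo: int, hi: int) -> np.ndarray:
        out = []
        for r in chain.amino_acids():
            if not lo <= r.seq_number <= hi:
                continue
            if allowed is not None and (r.chain_id, r.seq_number, r.icode) not in allowed:
                continue
            ca = r.atom("CA")
            if ca is not None:
                out.append(ca.coords)
        return np.array(out)

    d1 = domain_cas(*scheme.d1)
    d2 = domain_cas(*scheme.d2)
    if len(d1) < 10 or len(d2) < 10:
        raise GeometryError(
            f"too few resolved Calpha atoms (d1: {len(d1)}, d2: {len(d2)})"
        )
    c1, c2 = d1.mean(axis=0), d2.mean(axis=0)
    v1, v2 = c1 - pivot_ca.coords, c2 - pivot_ca.coords
    cosang = float(
        np.clip(v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2)), -1.0, 1.0)
    )
    return DomainAngleResult(
        angle_deg=float(np.degrees(np.arccos(cosang))),
        pivot_label=pivot_res.label,
        centroid_d1=c1,
        centroid_d2=c2,
        n_residues_d1=len(d1),
        n_residues_d2=len(d2),
    )


def mean_interdomain_angle(
    models: list[StructureModel],
    chain_ids: list[str],
    restrict_to_shared: bool = True,
) -> tuple[float, list[DomainAngleResult]]:
    """Average the interdomain angle over several receptor copies.

    With ``restrict_to_shared`` the centroids use only residues resolved
    in every copy, so each structure is measured over the same core.
    """
    results = []
    shared = None
    if restrict_to_shared and len(models) > 1:
        shared = shared_residue_sets(models, chain_ids)
    for k, (m, cid) in enumerate(zip(models, chain_ids)):
        res = interdomain_angle(
            m, cid, shared_residues=shared[k] if shared else None
        )
        results.append(res)
    return float(np.mean([r.angle_deg for r in results])), results
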