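"""Synthetic fixtures for every pipeline stage: toy receptor-Fc
coordinate sets with planted geometry, glycopeptide spectral-count
datasets with planted per-site glycoform mixtures, and noisy 1:1
sensorgram series.

Every generator is deterministic for a fixed seed and emits a ground-
truth record alongside its output, so downstream tests recover planted
quantities instead of re-deriving them.  The defaults mirror the study
conditions of the source system: a 174-residue two-lobed receptor
ectodomain hinged at residue 89 with an ~82.7 degree interdomain angle,
Fc chains engaging via the CH2 BC/DE loops (monomer A) and FG loop
(monomer B), three receptor glycosites (Asn45/Asn64/Asn162),
predominantly complex-type site glycoforms, and the ~0.25 uM K_D
receptor-Fc kinetic regime.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .glyco import (
    GLYCAN_CLASSES,
    GlycanComposition,
    classify_glycan,
    digest,
    find_sequons,
    glycopeptide_mass,
)
from .kinetics import ConcentrationSeries, Sensorgram, simulate_sensorgram
from .structure import Atom, Chain, Residue, StructureModel

__all__ = [
    "ToyComplexSpec",
    "GlycoDatasetSpec",
    "make_toy_complex",
    "make_glyco_dataset",
    "make_sensorgram_set",
    "GenerationError",
    "TOY_PROTEIN",
]


class GenerationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# toy coordinates


@dataclass
class ToyComplexSpec:
    """Recipe for a toy receptor + two-chain Fc coordinate set.

    ``contacts`` plants cross-chain residue pairs realised at
    ``contact_distance`` A (within the 3.8-4.8 A van der Waals band);
    ``glycan_sites`` appends linear NAG/NAG/BMA/MAN... chains to Asn
    side chains.  The receptor is built as two rigid arms whose
    centroid-pivot-centroid angle equals ``angle_deg`` exactly.
    """

    receptor_len: int = 174
    fc_start: int = 220
    fc_len: int = 221
    angle_deg: float = 82.7
    contacts: tuple[tuple[int, str, int], ...] = (
        (117, "A", 268),
        (120, "A", 296),
        (131, "A", 270),
        (88, "B", 327),
        (158, "B", 329),
    )
    contact_distance: float = 4.3
    glycan_sites: tuple[tuple[str, int, int], ...] = (
        ("R", 45, 2),
        ("R", 162, 2),
    )
    separation: float = 200.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.angle_deg < 180.0:
            raise ValueError("angle must be in (0, 180)")
        for rec_res, chain, fc_res in self.contacts:
            if not 1 <= rec_res <= self.receptor_len:
                raise ValueError(f"planted receptor residue {rec_res} out of range")
            if chain not in ("A", "B"):
                raise ValueError(f"planted Fc chain {chain!r} unknown")
            if not self.fc_start <= fc_res < self.fc_start + self.fc_len:
                raise ValueError(f"planted Fc residue {fc_res} out of range")
        if not 3.8 <= self.contact_distance <= 4.8:
            raise ValueError("contact distance outside the 3.8-4.8 A band")


CA_SPACING = 3.8
CB_LENGTH = 1.53

SUGAR_CHAIN = ("NAG", "NAG", "BMA", "MAN", "MAN", "MAN", "MAN")


def _backbone_atoms(ca: np.ndarray, direction: np.ndarray) -> list[Atom]:
    # carbonyl O points -z, away from the +z side used for CB atoms and
    # planted contacts, so a planted pair touches exactly one residue
    z = np.array([0.0, 0.0, 1.0])
    n = ca - 1.2 * direction + 0.4 * z
    c = ca + 1.2 * direction + 0.4 * z
    o = c - 1.23 * z
    return [
        Atom("N", "N", n),
        Atom("CA", "C", ca),
        Atom("C", "C", c),
        Atom("O", "O", o),
    ]


def _residue(
    chain_id: str, number: int, name: str, ca: np.ndarray, direction: np.ndarray
) -> Residue:
    atoms = _backbone_atoms(ca, direction)
    z = np.array([0.0, 0.0, 1.0])
    if name != "GLY":
        atoms.append(Atom("CB", "C", ca + CB_LENGTH * z))
    if name == "ASN":
        cb = ca + CB_LENGTH * z
        atoms.append(Atom("CG", "C", cb + 0.9 * z))
        atoms.append(Atom("OD1", "O", cb + 0.9 * z + np.array([1.0, 0, 0.4])))
        atoms.append(Atom("ND2", "N", cb + 2.1 * z))
    return Residue(
        chain_id=chain_id, seq_number=number, name=name,
        atoms=atoms, kind="amino_acid",
    )


def _sugar(chain_id: str, number: int, name: str, base: np.ndarray) -> Residue:
    z = np.array([0.0, 0.0, 1.0])
    atoms = [
        Atom("C1", "C", base),
        Atom("O5", "O", base + np.array([0.9, 0.0, 0.4])),
        Atom("C2", "C", base + np.array([-0.9, 0.0, 0.6])),
        Atom("O4", "O", base + 1.35 * z),
    ]
    return Residue(
        chain_id=chain_id, seq_number=number, name=name,
        atoms=atoms, kind="saccharide",
    )


def make_toy_complex(
    spec: ToyComplexSpec | None = None,
) -> tuple[StructureModel, dict]:
    """Build a toy receptor-Fc complex and its ground-truth record.

    The receptor chain 'R' has residues 1..174 with Calpha atoms on two
    straight arms meeting at the residue-89 pivot; the planted
    interdomain angle is exact.  Fc chains 'A' and 'B' sit
    ``separation`` A above the receptor plane except for the planted
    contact residues, which are relocated so that exactly the requested
    cross-component residue pairs fall inside a 5 A contact cutoff.
    """
    spec = spec or ToyComplexSpec()
    ang = np.radians(spec.angle_deg)
    u1 = np.array([1.0, 0.0, 0.0])
    u2 = np.array([np.cos(ang), np.sin(ang), 0.0])
    pivot = np.zeros(3)
    z = np.array([0.0, 0.0, 1.0])

    glyco_sites_r = {site for ch, site, _ in spec.glycan_sites if ch == "R"}
    receptor = Chain("R")
    for i in range(1, spec.receptor_len + 1):
        if i < 89:
            ca = pivot + u1 * CA_SPACING * (89 - i)
            direction = -u1
        elif i == 89:
            ca, direction = pivot, (u2 - u1) / np.linalg.norm(u2 - u1)
        else:
            ca = pivot + u2 * CA_SPACING * (i - 89)
            direction = u2
        name = "ASN" if i in glyco_sites_r else ("GLY" if i == 89 else "ALA")
        receptor.residues.append(_residue("R", i, name, ca, direction))

    # Fc chains: straight lines along y, far above the receptor plane
    planted_by_chain: dict[str, dict[int, int]] = {"A": {}, "B": {}}
    for rec_res, ch, fc_res in spec.contacts:
        if fc_res in planted_by_chain[ch]:
            raise GenerationError(
                f"Fc residue {ch}/{fc_res} planted twice"
            )
        planted_by_chain[ch][fc_res] = rec_res

    chains = [receptor]
    for idx, cid in enumerate(("A", "B")):
        chain = Chain(cid)
        y0 = idx * 60.0
        for k in range(spec.fc_len):
            number = spec.fc_start + k
            if number in planted_by_chain[cid]:
                rec_res = planted_by_chain[cid][number]
                rec_cb = receptor.residue(rec_res).atom("CB")
                if rec_cb is None:
                    raise GenerationError(
                        f"planted receptor residue {rec_res} has no CB"
                    )
                cb = rec_cb.coords + spec.contact_distance * z
                ca = cb + CB_LENGTH * z
                res = Residue(
                    chain_id=cid, seq_number=number, name="ALA",
                    kind="amino_acid",
                    atoms=[
                        Atom("N", "N", ca + np.array([-1.2, 0.0, 0.4])),
                        Atom("CA", "C", ca),
                        Atom("C", "C", ca + np.array([1.2, 0.0, 0.4])),
                        Atom("O", "O", ca + np.array([1.2, 0.0, 1.6])),
                        Atom("CB", "C", cb),
                    ],
                )
            else:
                ca = np.array(
                    [80.0 + idx * 40.0, y0 + CA_SPACING * k, spec.separation]
                )
                res = _residue(cid, number, "ALA", ca, np.array([0.0, 1.0, 0.0]))
            chain.residues.append(res)
        chains.append(chain)

    model = StructureModel(id=f"toy_complex_seed{spec.seed}", chains=chains)

    # glycan trees as linear sugar chains growing +z from the Asn ND2
    for ch_id, site, n_sugars in spec.glycan_sites:
        asn = model.chain(ch_id).residue(site)
        if asn is None or asn.atom("ND2") is None:
            raise GenerationError(f"glycan site {ch_id}/{site} is not an Asn")
        base = asn.atom("ND2").coords + 1.45 * z
        for s in range(n_sugars):
            name = SUGAR_CHAIN[min(s, len(SUGAR_CHAIN) - 1)]
            sugar = _sugar(ch_id, 500 + site * 10 + s, name, base)
            model.chain(ch_id).residues.append(sugar)
            base = sugar.atom("O4").coords + 1.43 * z

    # verify the plant: planted contact geometry is clash-free and exact
    for rec_res, ch, fc_res in spec.contacts:
        d = np.linalg.norm(
            model.chain(ch).residue(fc_res).atom("CB").coords
            - model.chain("R").residue(rec_res).atom("CB").coords
        )
        if not 3.8 <= d <= 4.8:
            raise GenerationError(
                f"planted contact R/{rec_res}-{ch}/{fc_res} realised at "
                f"{d:.2f} A (outside 3.8-4.8); infeasible contact set"
            )
    # and that no accidental cross-chain pair slipped inside 5 A
    from scipy.spatial import cKDTree

    planted = {(r, ch, f) for r, ch, f in spec.contacts}
    chain_list = model.chains
    for i, ca_chain in enumerate(chain_list):
        atoms_i = [
            (r, a) for r in ca_chain.residues for a in r.atoms if a.is_heavy
        ]
        tree_i = cKDTree(np.array([a.coords for _, a in atoms_i]))
        for cb_chain in chain_list[i + 1:]:
            atoms_j = [
                (r, a) for r in cb_chain.residues for a in r.atoms if a.is_heavy
            ]
            hits = tree_i.query_ball_tree(
                cKDTree(np.array([a.coords for _, a in atoms_j])), 5.0
            )
            for ii, js in enumerate(hits):
                for jj in js:
                    ri, rj = atoms_i[ii][0], atoms_j[jj][0]
                    if ca_chain.chain_id == "R":
                        key = (ri.seq_number, cb_chain.chain_id, rj.seq_number)
                    else:
                        key = (rj.seq_number, ca_chain.chain_id, ri.seq_number)
                    if key not in planted:
                        raise GenerationError(
                            f"unplanned cross-chain proximity "
                            f"{ri.label} - {rj.label}; infeasible contact set"
                        )

    ground_truth = {
        "angle_deg": spec.angle_deg,
        "contacts": sorted(
            [rec, ch, fc] for rec, ch, fc in spec.contacts
        ),
        "n_contacts": len(spec.contacts),
        "glycan_sites": sorted(
            [ch, site, n] for ch, site, n in spec.glycan_sites
        ),
        "roles": {"R": "receptor", "A": "fc_chain_A", "B": "fc_chain_B"},
        "contact_distance": spec.contact_distance,
        "seed": spec.seed,
    }
    return model, ground_truth


# ---------------------------------------------------------------------------
# glycopeptide datasets

def _toy_protein() -> str:
    """Synthetic 174-residue receptor-like sequence (not a natural gene).

    A periodic scaffold rich in chymotrypsin (F) and Glu-C (E) cut sites
    carries exactly three N-X-S/T sequons, at Asn45, Asn64 and Asn162 --
    the receptor's structurally characterised glycosites.
    """
    unit = "ADGKVREGQIHF"
    seq = list((unit * 15)[:174])
    for pos, motif in ((45, "NGS"), (64, "NGT"), (162, "NAS")):
        seq[pos - 1:pos + 2] = motif
    return "".join(seq)


#: Synthetic receptor-like protein used by the glyco examples and tests.
TOY_PROTEIN = _toy_protein()

COMPOSITION_POOLS: dict[str, tuple[GlycanComposition, ...]] = {
    "oligomannose": tuple(
        GlycanComposition(2, h, 0, 0) for h in range(5, 10)
    ),
    "hybrid": (
        GlycanComposition(3, 5, 0, 0),
        GlycanComposition(3, 6, 0, 0),
        GlycanComposition(3, 5, 0, 1),
        GlycanComposition(4, 5, 0, 1),
    ),
    "complex": (
        GlycanComposition(3, 3, 1, 0),
        GlycanComposition(4, 3, 1, 0),
        GlycanComposition(4, 4, 1, 0),
        GlycanComposition(4, 4, 1, 1),
        GlycanComposition(4, 4, 1, 2),
        GlycanComposition(5, 4, 1, 1),
        GlycanComposition(4, 4, 0, 1),
    ),
    "truncated": (
        GlycanComposition(1, 0, 0, 0),
        GlycanComposition(2, 1, 0, 0),
        GlycanComposition(2, 2, 0, 0),
    ),
}


def pool_glycan_db() -> list[GlycanComposition]:
    """Targeted composition database: the union of the class pools.

    Plays the role of a curated search database for recovery studies on
    generated data; precursor-only matching against the full
    combinatorial composition space is prone to near-isobaric
    cross-peptide collisions that a real workflow resolves with MS2
    evidence, which is out of scope here.
    """
    comps = {c for pool in COMPOSITION_POOLS.values() for c in pool}
    return sorted(comps, key=lambda c: c.key())


@dataclass
class GlycoDatasetSpec:
    """Planted per-site glycoform mixtures for a precursor table.

    The default mixtures follow the observed site profiles of the
    HEK293-expressed receptor: predominantly complex-type everywhere,
    ~10% hybrid at Asn45, truncated forms at Asn64 and Asn162.
    """

    sites: tuple[int, ...] = (45, 64, 162)
    class_mixture: dict[int, dict[str, float]] = field(default_factory=lambda: {
        45: {"complex": 0.84, "hybrid": 0.10, "oligomannose": 0.06, "truncated": 0.0},
        64: {"complex": 0.85, "hybrid": 0.03, "oligomannose": 0.02, "truncated": 0.10},
        162: {"complex": 0.88, "hybrid": 0.06, "oligomannose": 0.03, "truncated": 0.03},
    })
    n_spectra: int = 500
    ppm_noise_sd: float = 2.0
    low_prob_frac: float = 0.05
    singleton_frac: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_spectra <= 0:
            raise ValueError("n_spectra must be positive")
        for site, mix in self.class_mixture.items():
            if abs(sum(mix.values()) - 1.0) > 1e-9:
                raise ValueError(f"mixture at site {site} does not sum to 1")


def _covering_peptide(peptides, site: int):
    covering = [p for p in peptides if p.start <= site <= p.end]
    if not covering:
        raise GenerationError(f"no digest peptide covers site {site}")
    return min(covering, key=lambda p: (len(p.sequence), p.start))


def make_glyco_dataset(
    spec: GlycoDatasetSpec | None = None,
    protein: str = TOY_PROTEIN,
) -> tuple[pd.DataFrame, dict]:
    """Sample an observed-precursor table with planted class mixtures.

    Compositions are drawn from class-conditional pools, attached to the
    shortest digest peptide covering each site, and emitted with
    ppm-level mass noise (Gaussian, clipped at 3 sd so every planted
    mass stays inside a 10 ppm matching window).  A ``low_prob_frac``
    share of rows receives a log probability below 1 and a
    ``singleton_frac`` share a spectral count of 1; both are removed by
    the profiling filters, and the ground truth records the post-filter
    class fractions.
    """
    spec = spec or GlycoDatasetSpec()
    sequons = set(find_sequons(protein))
    for site in spec.sites:
        if site not in sequons:
            raise GenerationError(f"site {site} is not in an N-X-S/T sequon")
    rng = np.random.default_rng(spec.seed)
    peptides = digest(protein, max_missed=2, min_length=4)

    rows = []
    truth_fracs: dict[int, dict[str, float]] = {}
    truth_counts: dict[int, dict[str, int]] = {}
    for site in spec.sites:
        pep = _covering_peptide(peptides, site)
        mix = spec.class_mixture[site]
        classes = list(mix)
        probs = np.array([mix[c] for c in classes])
        draws = rng.choice(len(classes), size=spec.n_spectra, p=probs)
        comp_draws = []
        for d in draws:
            pool = COMPOSITION_POOLS[classes[d]]
            comp_draws.append(pool[rng.integers(len(pool))])
        counts: dict[GlycanComposition, int] = {}
        for comp in comp_draws:
            counts[comp] = counts.get(comp, 0) + 1

        kept_class_counts = dict.fromkeys(GLYCAN_CLASSES, 0)

        def noisy_mass(theo: float) -> float:
            ppm = rng.normal(0.0, spec.ppm_noise_sd)
            ppm = float(
                np.clip(ppm, -3 * spec.ppm_noise_sd, 3 * spec.ppm_noise_sd)
            )
            return theo * (1.0 + ppm * 1e-6)

        for comp, count in sorted(counts.items(), key=lambda kv: kv[0].key()):
            theo = glycopeptide_mass(pep, comp)
            low_prob = rng.random() < spec.low_prob_frac
            logp = rng.uniform(0.0, 0.99) if low_prob else rng.uniform(1.5, 3.0)
            rows.append(
                {
                    "mass": noisy_mass(theo),
                    "spectral_count": count,
                    "log_probability": round(logp, 3),
                    "site_hint": site,
                }
            )
            if not low_prob and count >= 2:
                kept_class_counts[classify_glycan(comp)] += count
            # filter-plant: an extra single-spectrum row for this form,
            # removed downstream by the minimum-spectra rule
            if rng.random() < spec.singleton_frac:
                rows.append(
                    {
                        "mass": noisy_mass(theo),
                        "spectral_count": 1,
                        "log_probability": round(rng.uniform(1.5, 3.0), 3),
                        "site_hint": site,
                    }
                )
        total_kept = sum(kept_class_counts.values())
        truth_counts[site] = kept_class_counts
        truth_fracs[site] = {
            c: (n / total_kept if total_kept else 0.0)
            for c, n in kept_class_counts.items()
        }
    table = pd.DataFrame(rows)
    ground_truth = {
        "sites": list(spec.sites),
        "planted_mixture": {str(s): spec.class_mixture[s] for s in spec.sites},
        "post_filter_class_fractions": {
            str(s): truth_fracs[s] for s in spec.sites
        },
        "post_filter_class_counts": {
            str(s): truth_counts[s] for s in spec.sites
        },
        "n_rows": len(table),
        "seed": spec.seed,
    }
    return table, ground_truth


# ---------------------------------------------------------------------------
# sensorgrams


def make_sensorgram_set(
    k_on: float = 1e5,
    k_off: float = 0.025,
    R_max: float = 1.0,
    series: ConcentrationSeries | None = None,
    schedule: tuple[float, float] = (300.0, 300.0),
    noise_sd: float = 0.05,
    seed: int = 0,
) -> tuple[list[Sensorgram], dict]:
    """Simulate a multi-concentration sensorgram series with ground truth.

    Defaults plant the ~0.25 uM K_D regime (k_on 1e5 /M/s, k_off
    0.025 /s) over a 7-point 3-fold dilution series from 10 uM with a
    300 s / 300 s association/dissociation schedule and 5% (of R_max)
    additive noise.
    """
    series = series or ConcentrationSeries(top=10e-6)
    rng = np.random.default_rng(seed)
    grams = [
        simulate_sensorgram(
            k_on, k_off, R_max, conc, schedule=schedule,
            noise_sd=noise_sd, seed=rng,
        )
        for conc in series.concentrations
    ]
    ground_truth = {
        "k_on": k_on,
        "k_off": k_off,
        "K_D": k_off / k_on,
        "R_max": R_max,
        "concentrations": list(series.concentrations),
        "noise_sd": noise_sd,
        "schedule": list(schedule),
        "seed": seed,
    }
    return grams, ground_truth


def save_ground_truth(truth: dict, path: str | Path) -> None:
    """Write the sidecar ground-truth JSON next to a fixture."""
    Path(path).write_text(json.dumps(truth, indent=2, sort_keys=True))


def sensorgrams_to_frame(grams: list[Sensorgram]) -> pd.DataFrame:
    rows = []
    for g in grams:
        for t, r in zip(g.times, g.response):
            rows.append(
                {
                    "time": t, "response": r,
                    "concentration": g.concentration,
                    "phase": "association" if t <= g.t_assoc_end else "dissociation",
                }
            )
    return pd.DataFrame(rows)


def frame_to_sensorgrams(
    frame: pd.DataFrame, t_assoc_end: float | None = None
) -> list[Sensorgram]:
    out = []
    for conc, group in frame.groupby("concentration", sort=False):
        group = group.sort_values("time")
        ta = t_assoc_end
        if ta is None:
            assoc = group[group["phase"] == "association"]
            ta = float(assoc["time"].max()) if len(assoc) else float(
                group["time"].max() / 2
            )
        out.append(
            Sensorgram(
                times=group["time"].to_numpy(),
                response=group["response"].to_numpy(),
                concentration=float(conc),
                t_assoc_start=float(group["time"].min()),
                t_assoc_end=ta,
                t_end=float(group["time"].max()),
            )
        )
    out.sort(key=lambda g: -g.concentration)
    return out
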