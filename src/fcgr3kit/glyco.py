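"""Site-specific N-glycopeptide composition profiling.

In-silico chymotrypsin/Glu-C digestion, monoisotopic glycopeptide mass
calculus, precursor-mass matching against an N-glycan composition
database, glycoform classification (oligomannose / hybrid / complex /
truncated) and per-site top-N abundance tables built from spectral
counts.  Matching is precursor-mass only; the log-probability score is
an input column from the upstream search engine, not computed here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from pyteomics import mass as pt_mass

__all__ = [
    "PeptideSpec",
    "GlycanComposition",
    "GlycopeptideMatch",
    "SiteGlycoProfile",
    "digest",
    "find_sequons",
    "glycopeptide_mass",
    "default_glycan_db",
    "match_precursors",
    "classify_glycan",
    "site_profile",
]

# monoisotopic residue-mass increments (Da)
MASS_HEXNAC = 203.07937
MASS_HEX = 162.05282
MASS_DHEX = 146.05791
MASS_NEUAC = 291.09542
MASS_CARBAMIDOMETHYL = 57.02146

ENZYME_RULES = {
    # cleave C-terminal to these residues, never before Pro
    "chymotrypsin": set("FYWLM"),
    "gluc": set("E"),          # ammonium-carbonate specificity
    "gluc_ed": set("ED"),      # phosphate-buffer specificity
}

GLYCAN_CLASSES = ("oligomannose", "hybrid", "complex", "truncated")


@dataclass(frozen=True)
class GlycanComposition:
    hexnac: int = 0
    hex: int = 0
    dhex: int = 0
    neuac: int = 0

    def __post_init__(self) -> None:
        if min(self.hexnac, self.hex, self.dhex, self.neuac) < 0:
            raise ValueError("composition counts must be non-negative")

    def __add__(self, other: "GlycanComposition") -> "GlycanComposition":
        return GlycanComposition(
            self.hexnac + other.hexnac, self.hex + other.hex,
            self.dhex + other.dhex, self.neuac + other.neuac,
        )

    @property
    def mass(self) -> float:
        return (
            MASS_HEXNAC * self.hexnac + MASS_HEX * self.hex
            + MASS_DHEX * self.dhex + MASS_NEUAC * self.neuac
        )

    @property
    def total(self) -> int:
        return self.hexnac + self.hex + self.dhex + self.neuac

    def key(self) -> tuple[int, int, int, int]:
        return (self.hexnac, self.hex, self.dhex, self.neuac)

    def __str__(self) -> str:
        return f"HexNAc{self.hexnac}Hex{self.hex}dHex{self.dhex}NeuAc{self.neuac}"


@dataclass
class PeptideSpec:
    sequence: str
    start: int   # 1-based inclusive position in the parent
    end: int
    missed_cleavages: int = 0
    fixed_mods: tuple[tuple[str, float], ...] = (("C", MASS_CARBAMIDOMETHYL),)

    def __post_init__(self) -> None:
        if self.end - self.start + 1 != len(self.sequence):
            raise ValueError("peptide span inconsistent with sequence length")

    def sequons(self, parent: str) -> list[int]:
        """Asn positions of N-X-S/T sequons (X != P) inside this peptide."""
        return [
            p for p in find_sequons(parent)
            if self.start <= p <= self.end
        ]


@dataclass
class GlycopeptideMatch:
    peptide: PeptideSpec
    site: int
    composition: GlycanComposition
    theoretical_mass: float
    observed_mass: float
    ppm_error: float
    spectral_count: int
    log_probability: float
    ambiguous: bool = False


@dataclass
class SiteGlycoProfile:
    site: int
    class_fractions: dict[str, float]
    top_n: list[tuple[GlycanComposition, int]]
    total_spectra: int
    filter_audit: dict[str, int] = field(default_factory=dict)


def find_sequons(sequence: str) -> list[int]:
    """1-based Asn positions of N-X-S/T sequons with X != P."""
    seq = sequence.upper()
    return [
        i + 1
        for i in range(len(seq) - 2)
        if seq[i] == "N" and seq[i + 1] != "P" and seq[i + 2] in "ST"
    ]


def _cut_sites(sequence: str, enzymes: set[str]) -> list[int]:
    specs = set()
    for enz in enzymes:
        if enz not in ENZYME_RULES:
            raise ValueError(f"unknown enzyme {enz!r}")
        specs |= ENZYME_RULES[enz]
    seq = sequence.upper()
    return [
        i + 1
        for i in range(len(seq) - 1)
        if seq[i] in specs and seq[i + 1] != "P"
    ]


def digest(
    sequence: str,
    enzymes: set[str] | frozenset[str] = frozenset({"chymotrypsin", "gluc"}),
    max_missed: int = 2,
    min_length: int = 4,
) -> list[PeptideSpec]:
    """In-silico proteolysis with combined enzyme specificities.

    Cleavage occurs C-terminal to F/Y/W/L/M (chymotrypsin) and to E
    (Glu-C under ammonium carbonate), never before proline.  Every
    peptide with at most ``max_missed`` internal cut sites is returned;
    peptides shorter than ``min_length`` are dropped.
    """
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    sites = _cut_sites(seq, set(enzymes))
    boundaries = [0] + sites + [len(seq)]
    peptides: list[PeptideSpec] = []
    for i in range(len(boundaries) - 1):
        for j in range(i + 1, min(i + 2 + max_missed, len(boundaries))):
            start, end = boundaries[i], boundaries[j]
            pep = seq[start:end]
            if len(pep) < min_length:
                continue
            peptides.append(
                PeptideSpec(
                    sequence=pep, start=start + 1, end=end,
                    missed_cleavages=j - i - 1,
                )
            )
    return peptides


def peptide_mass(peptide: PeptideSpec) -> float:
    """Monoisotopic neutral peptide mass with fixed modifications."""
    try:
        base = pt_mass.fast_mass(peptide.sequence)
    except Exception as exc:  # pyteomics raises on unknown residues
        for pos, letter in enumerate(peptide.sequence, start=1):
            if letter not in pt_mass.std_aa_mass:
                raise ValueError(
                    f"non-standard residue {letter!r} at peptide position {pos}"
                ) from exc
        raise
    for letter, delta in peptide.fixed_mods:
        base += peptide.sequence.count(letter) * delta
    return base


def glycopeptide_mass(
    peptide: PeptideSpec, composition: GlycanComposition
) -> float:
    """Monoisotopic mass of peptide + attached glycan composition."""
    return peptide_mass(peptide) + composition.mass


def default_glycan_db() -> list[GlycanComposition]:
    """N-glycan composition space covering HEK293-type glycoforms.

    All compositions with HexNAc 1-6, Hex 0-9, dHex 0-2, NeuAc 0-4,
    requiring Hex >= 3 once HexNAc >= 2 except for explicitly truncated
    forms (HexNAc <= 2, Hex <= 3).
    """
    db = []
    for hexnac in range(1, 7):
        for hx in range(0, 10):
            for dhex in range(0, 3):
                for neuac in range(0, 5):
                    truncated_form = hexnac <= 2 and hx <= 3
                    if hexnac >= 2 and hx < 3 and not truncated_form:
                        continue
                    db.append(GlycanComposition(hexnac, hx, dhex, neuac))
    return sorted(set(db), key=lambda c: c.key())


def classify_glycan(composition: GlycanComposition) -> str:
    """Processing-class heuristic from HexNAc/Hex/dHex/NeuAc counts.

    truncated: below the Man3GlcNAc2 core; oligomannose: the unprocessed
    Man(>=4) arm on the bare core; hybrid: one processed and one
    mannose arm (HexNAc >= 3 with Hex >= 5); complex: everything else.
    These boundaries are configuration-level heuristics, not ground
    truth from any single nomenclature.
    """
    c = composition
    if c.hexnac < 2 or (c.hexnac == 2 and c.hex < 3):
        return "truncated"
    if c.hexnac == 2 and c.hex >= 4 and c.dhex == 0 and c.neuac == 0:
        return "oligomannose"
    if c.hexnac >= 3 and c.hex >= 5:
        return "hybrid"
    return "complex"


def match_precursors(
    observed: pd.DataFrame,
    peptides: list[PeptideSpec],
    glycan_db: list[GlycanComposition],
    parent_sequence: str,
    tol_ppm: float = 10.0,
    site_column: str | None = "auto",
) -> list[GlycopeptideMatch]:
    """Match observed precursor masses to theoretical glycopeptides.

    ``observed`` needs columns ``mass``, ``spectral_count`` and
    ``log_probability``.  Every (peptide, composition) pair within
    ``tol_ppm`` of an observed mass yields a match; when one observed
    mass hits several theoretical species, all are reported and flagged
    ambiguous.  Peptides without a sequon never match.

    When the table carries an optional site assignment (a ``site`` or
    ``site_hint`` column, typically propagated from upstream MS2-level
    identification), candidate matches are restricted to that sequon;
    pass ``site_column=None`` to force pure precursor-mass matching.
    """
    if not glycan_db:
        raise ValueError("empty glycan database")
    if site_column == "auto":
        site_column = next(
            (c for c in ("site", "site_hint") if c in observed.columns), None
        )
    theo: list[tuple[float, PeptideSpec, int, GlycanComposition]] = []
    for pep in peptides:
        sites = pep.sequons(parent_sequence)
        if not sites:
            continue
        base = peptide_mass(pep)
        for comp in glycan_db:
            for site in sites:
                theo.append((base + comp.mass, pep, site, comp))
    theo.sort(key=lambda t: t[0])
    masses = np.array([t[0] for t in theo])

    matches: list[GlycopeptideMatch] = []
    for row in observed.itertuples(index=False):
        obs = float(row.mass)
        site_assign = (
            int(getattr(row, site_column)) if site_column else None
        )
        tol = obs * tol_ppm * 1e-6
        lo = int(np.searchsorted(masses, obs - tol, side="left"))
        hi = int(np.searchsorted(masses, obs + tol, side="right"))
        hits = [
            t for t in theo[lo:hi]
            if site_assign is None or t[2] == site_assign
        ]
        ambiguous = len(hits) > 1
        for theoretical, pep, site, comp in hits:
            matches.append(
                GlycopeptideMatch(
                    peptide=pep,
                    site=site,
                    composition=comp,
                    theoretical_mass=theoretical,
                    observed_mass=obs,
                    ppm_error=(obs - theoretical) / theoretical * 1e6,
                    spectral_count=int(row.spectral_count),
                    log_probability=float(row.log_probability),
                    ambiguous=ambiguous,
                )
            )
    return matches


def site_profile(
    matches: list[GlycopeptideMatch],
    site: int,
    min_log_prob: float = 1.0,
    min_spectra: int = 2,
    top_n: int = 10,
) -> SiteGlycoProfile:
    """Aggregate matches at one glycosite into class fractions and a top-N.

    Filters (applied before aggregation, with an audit of exclusions):
    log probability >= ``min_log_prob`` and spectral count >=
    ``min_spectra``.  Ranking ties are broken by (HexNAc, Hex, dHex,
    NeuAc) lexicographic order, so the table is deterministic.
    """
    at_site = [m for m in matches if m.site == site]
    audit = {
        "n_matches": len(at_site),
        "excluded_low_log_prob": 0,
        "excluded_low_spectra": 0,
    }
    kept: list[GlycopeptideMatch] = []
    for m in at_site:
        if m.log_probability < min_log_prob:
            audit["excluded_low_log_prob"] += 1
        elif m.spectral_count < min_spectra:
            audit["excluded_low_spectra"] += 1
        else:
            kept.append(m)
    audit["n_kept"] = len(kept)

    counts: dict[tuple[int, int, int, int], int] = {}
    for m in kept:
        counts[m.composition.key()] = counts.get(m.composition.key(), 0) + \
            m.spectral_count
    total = sum(counts.values())
    class_totals = dict.fromkeys(GLYCAN_CLASSES, 0)
    for key, n in counts.items():
        cls = classify_glycan(GlycanComposition(*key))
        class_totals[cls] += n
    fractions = {
        cls: (n / total if total > 0 else 0.0)
        for cls, n in class_totals.items()
    }
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = [(GlycanComposition(*k), n) for k, n in ranked[:top_n]]
    return SiteGlycoProfile(
        site=site,
        class_fractions=fractions,
        top_n=top,
        total_spectra=total,
        filter_audit=audit,
    )


def profile_table(profile: SiteGlycoProfile) -> pd.DataFrame:
    """Top-N table as a tidy DataFrame (one row per glycoform)."""
    rows = [
        {
            "site": profile.site,
            "rank": rank,
            "hexnac": comp.hexnac,
            "hex": comp.hex,
            "dhex": comp.dhex,
            "neuac": comp.neuac,
            "composition": str(comp),
            "glycan_class": classify_glycan(comp),
            "spectral_count": count,
            "fraction": count / profile.total_spectra
            if profile.total_spectra else 0.0,
        }
        for rank, (comp, count) in enumerate(profile.top_n, start=1)
    ]
    return pd.DataFrame(rows)
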