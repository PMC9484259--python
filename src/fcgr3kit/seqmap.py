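"""Pairwise global alignment, percent identity and residue correspondence.

Needleman-Wunsch global alignment (BLOSUM62, gap open 10 / extend 0.5 by
default) computes the ortholog identity figures and builds one-to-one
residue correspondence maps between homologous structures for
superposition ("shared residues").
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio import Align
from Bio.Align import substitution_matrices

from .structure import Residue, StructureModel

__all__ = [
    "AlignmentParams",
    "AlignmentResult",
    "CorrespondenceMap",
    "global_align",
    "percent_identity",
    "correspondence_map",
    "shared_residue_sets",
]

STANDARD_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass(frozen=True)
class AlignmentParams:
    matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 0.5


@dataclass
class AlignmentResult:
    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    params: AlignmentParams

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")

    def columns(self):
        return zip(self.aligned_a, self.aligned_b)


@dataclass
class CorrespondenceMap:
    pairs: list[tuple[Residue, Residue]]
    source: str = "sequence_alignment"
    identity_pct: float = 100.0

    def reversed(self) -> "CorrespondenceMap":
        return CorrespondenceMap(
            pairs=[(b, a) for a, b in self.pairs],
            source=self.source,
            identity_pct=self.identity_pct,
        )


def _aligner(params: AlignmentParams) -> Align.PairwiseAligner:
    matrix = substitution_matrices.load(params.matrix)
    # tolerate X, scored 0 against everything
    if "X" in matrix.alphabet:
        for letter in matrix.alphabet:
            matrix["X", letter] = 0.0
            matrix[letter, "X"] = 0.0
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = matrix
    aligner.mode = "global"
    aligner.open_gap_score = -params.gap_open
    aligner.extend_gap_score = -params.gap_extend
    return aligner


def global_align(
    seq_a: str, seq_b: str, params: AlignmentParams | None = None
) -> AlignmentResult:
    """Optimal Needleman-Wunsch global alignment with deterministic traceback.

    A gap of length L costs ``gap_open + (L - 1) * gap_extend``.  The
    first alignment of the enumeration order is returned (high-road
    tie-break).
    """
    if not seq_a or not seq_b:
        raise ValueError("sequences must be non-empty")
    params = params or AlignmentParams()
    for seq, tag in ((seq_a, "a"), (seq_b, "b")):
        bad = set(seq.upper()) - STANDARD_AA - {"X"}
        if bad:
            raise ValueError(f"sequence {tag} has non-standard letters {sorted(bad)}")
    aligner = _aligner(params)
    alignments = aligner.align(seq_a.upper(), seq_b.upper())
    aln = alignments[0]
    a, b = str(aln[0]), str(aln[1])
    result = AlignmentResult(
        aligned_a=a, aligned_b=b, score=float(aln.score),
        identity_pct=0.0, params=params,
    )
    result.identity_pct = percent_identity(result)
    return result


def percent_identity(
    aln: AlignmentResult, denominator: str = "aligned_columns"
) -> float:
    """matches / denominator x 100.

    ``aligned_columns`` counts columns where both sequences have a
    residue (the default ortholog-identity convention); ``shorter_seq``
    and ``alignment_length`` are provided because the convention behind
    published identity figures is often unstated.
    """
    matches = sum(
        1 for x, y in aln.columns() if x == y and x != "-"
    )
    aligned_cols = sum(
        1 for x, y in aln.columns() if x != "-" and y != "-"
    )
    if denominator == "aligned_columns":
        denom = aligned_cols
    elif denominator == "shorter_seq":
        denom = min(
            len(aln.aligned_a.replace("-", "")), len(aln.aligned_b.replace("-", ""))
        )
    elif denominator == "alignment_length":
        denom = len(aln.aligned_a)
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        return 0.0
    return 100.0 * matches / denom


def correspondence_map(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_pairing: list[tuple[str, str]],
    params: AlignmentParams | None = None,
    identity_floor: float = 30.0,
) -> CorrespondenceMap:
    """One-to-one residue correspondences between two structures.

    Chains are paired explicitly (typically by role); sequences are read
    from the resolved residues, so pairs involving disordered residues
    are absent by construction.  An identity below ``identity_floor``
    raises, since it almost always indicates a wrong chain pairing.
    """
    pairs: list[tuple[Residue, Residue]] = []
    worst = 100.0
    for cid_a, cid_b in chain_pairing:
        res_a = model_a.chain(cid_a).amino_acids()
        res_b = model_b.chain(cid_b).amino_acids()
        seq_a = model_a.chain(cid_a).sequence()
        seq_b = model_b.chain(cid_b).sequence()
        aln = global_align(seq_a, seq_b, params)
        if aln.identity_pct < identity_floor:
            raise ValueError(
                f"chain pairing {cid_a}->{cid_b} aligns at only "
                f"{aln.identity_pct:.1f}% identity (< {identity_floor}%); "
                "likely a wrong pairing"
            )
        worst = min(worst, aln.identity_pct)
        i = j = 0
        for x, y in aln.columns():
            if x != "-" and y != "-":
                pairs.append((res_a[i], res_b[j]))
            if x != "-":
                i += 1
            if y != "-":
                j += 1
    return CorrespondenceMap(pairs=pairs, identity_pct=worst)


def correspondence_by_numbering(
    model_a: StructureModel,
    model_b: StructureModel,
    chain_pairing: list[tuple[str, str]],
) -> CorrespondenceMap:
    """Correspondences from identical author numbering (same construct).

    Pairs every residue number+insertion code resolved in both chains;
    appropriate when the two structures share a numbering scheme, e.g.
    copies of one complex or allelic variants of one construct.
    """
    pairs: list[tuple[Residue, Residue]] = []
    for cid_a, cid_b in chain_pairing:
        by_num = {
            (r.seq_number, r.icode): r
            for r in model_b.chain(cid_b).amino_acids()
        }
        for res_a in model_a.chain(cid_a).amino_acids():
            res_b = by_num.get((res_a.seq_number, res_a.icode))
            if res_b is not None:
                pairs.append((res_a, res_b))
    return CorrespondenceMap(pairs=pairs, source="identical_numbering")


def shared_residue_sets(
    models: list[StructureModel],
    chain_ids: list[str],
    params: AlignmentParams | None = None,
) -> list[list[Residue]]:
    """Residues shared (resolved and alignable) across *all* models.

    Returns one residue list per model, aligned index-by-index: entry k
    of each list corresponds to the same alignment position.  Used for
    multi-structure averages where the comparison must run over the
    common ordered core.
    """
    if len(models) < 2:
        raise ValueError("need at least two models")
    ref = models[0]
    maps = [
        correspondence_map(ref, m, [(chain_ids[0], cid)], params)
        for m, cid in zip(models[1:], chain_ids[1:])
    ]
    # intersect on the reference residues present in every map
    common = None
    for cmap in maps:
        keys = {id(a) for a, _ in cmap.pairs}
        common = keys if common is None else (common & keys)
    ref_residues = [
        a for a, _ in maps[0].pairs if id(a) in common
    ]
    out = [ref_residues]
    for cmap in maps:
        lookup = {id(a): b for a, b in cmap.pairs}
        out.append([lookup[id(a)] for a in ref_residues])
    return out
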