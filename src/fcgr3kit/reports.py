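"""Report assembly for the three headline analyses.

Each run writes diff-friendly TSV tables (one-line header, '#'-prefixed
metadata) and JSON summaries, together with the RunConfig that produced
them, so deterministic runs are byte-reproducible from a saved config.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .geometry import interdomain_angle, pairwise_rmsd_matrix
from .glyco import (
    default_glycan_db,
    digest,
    match_precursors,
    profile_table,
    site_profile,
)
from .interface import (
    buried_surface_area,
    classify_contacts,
    complex_partition,
    contact_network,
    decompose_bsa,
    detect_hbonds,
)
from .structure import (
    StructureModel,
    assign_complex_roles,
    detect_glycans,
    split_complex_copies,
    structure_inventory,
)

__all__ = ["RunConfig", "run_compare", "run_interface", "run_glyco"]


@dataclass
class RunConfig:
    command: str
    inputs: list[str] = field(default_factory=list)
    params: dict = field(default_factory=dict)
    seed: int | None = None
    outdir: str = "."
    version: str = __version__

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "command": self.command,
                    "inputs": self.inputs,
                    "params": self.params,
                    "seed": self.seed,
                    "outdir": self.outdir,
                    "version": self.version,
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        data = json.loads(Path(path).read_text())
        return cls(**data)


def _meta_lines(config: RunConfig) -> str:
    return (
        f"# fcgr3kit {config.version}\n"
        f"# command: {config.command}\n"
        f"# params: {json.dumps(config.params, sort_keys=True)}\n"
    )


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def _prepare(model: StructureModel) -> list[StructureModel]:
    """Detect glycans, split copies and assign roles where possible."""
    detect_glycans(model)
    copies = split_complex_copies(model)
    out = []
    for copy in copies:
        copy.glycans = [
            g for g in model.glycans
            if any(g.attach_chain == c.chain_id for c in copy.chains)
        ]
        try:
            assign_complex_roles(copy)
        except Exception:
            pass  # apo receptor or non-complex input: roles stay empty
        out.append(copy)
    return out


def run_compare(models: list[StructureModel], config: RunConfig) -> dict:
    """RMSD matrices (both scopes), per-receptor interdomain angles, summary."""
    if len(models) < 2:
        raise ValueError("need at least two parseable models")
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    copies = [c for m in models for c in _prepare(m)]
    selection = config.params.get("selection", "mainchain")

    summary: dict = {"n_models": len(models), "n_copies": len(copies)}
    complex_copies = [c for c in copies if c.roles]
    for scope in ("full_complex", "fc_ch2_only"):
        try:
            matrix = pairwise_rmsd_matrix(
                complex_copies, scope=scope, selection=selection
            )
        except Exception as exc:
            summary[f"rmsd_{scope}"] = f"unavailable: {exc}"
            continue
        lines = [_meta_lines(config) + "label\t" + "\t".join(matrix.labels)]
        for label, row in zip(matrix.labels, matrix.values):
            lines.append(label + "\t" + "\t".join(f"{v:.3f}" for v in row))
        (outdir / f"rmsd_{scope}.tsv").write_text("\n".join(lines) + "\n")
        if len(matrix.labels) > 1:
            offdiag = matrix.values[~np.eye(len(matrix.labels), dtype=bool)]
            summary[f"rmsd_{scope}_mean_offdiag"] = round(float(offdiag.mean()), 3)

    angles = []
    for copy in copies:
        try:
            if copy.roles:
                res = interdomain_angle(copy)
                cid = copy.chain_by_role("receptor").chain_id
            else:
                receptorish = min(
                    (c for c in copy.chains if c.amino_acids()),
                    key=lambda c: len(c.amino_acids()),
                )
                res = interdomain_angle(copy, receptorish.chain_id)
                cid = receptorish.chain_id
            angles.append(
                {
                    "model": copy.id,
                    "copy": copy.copy_index,
                    "chain": cid,
                    "angle_deg": round(res.angle_deg, 2),
                }
            )
        except Exception as exc:
            angles.append(
                {"model": copy.id, "copy": copy.copy_index, "error": str(exc)}
            )
    good = [a["angle_deg"] for a in angles if "angle_deg" in a]
    summary["angles"] = angles
    if good:
        summary["mean_angle_deg"] = round(sum(good) / len(good), 2)
    _write_json(outdir / "compare_summary.json", summary)
    config.save(outdir / "run_config.json")
    return summary


def run_interface(model: StructureModel, config: RunConfig) -> dict:
    """Interface report per complex copy: BSA, contacts, H-bonds, regions."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cutoff = float(config.params.get("cutoff", 5.0))
    convention = config.params.get("convention", "delta_asa_sum")
    n_points = int(config.params.get("n_points", 960))
    summary: dict = {"model": model.id, "copies": []}
    for copy in _prepare(model):
        tag = f"copy{copy.copy_index}"
        entry: dict = {"copy": copy.copy_index}
        entry["inventory"] = structure_inventory(copy)
        if not copy.roles:
            entry["interface"] = "not a complex (no roles assignable)"
            try:
                receptorish = min(
                    (c for c in copy.chains if c.amino_acids()),
                    key=lambda c: len(c.amino_acids()),
                )
                entry["angle_deg"] = round(
                    interdomain_angle(copy, receptorish.chain_id).angle_deg, 2
                )
            except Exception as exc:
                entry["angle_error"] = str(exc)
            summary["copies"].append(entry)
            continue
        part = complex_partition(copy)
        report = decompose_bsa(
            buried_surface_area(part, convention=convention, n_points=n_points),
            copy,
        )
        entry["bsa_total"] = round(report.bsa_total, 1)
        entry["bsa_by_component"] = {
            k: round(v, 1) for k, v in report.bsa_by_component.items()
        }
        entry["bsa_by_region"] = {
            k: {"area": round(a, 1), "pct_of_fc_side": round(p, 1)}
            for k, (a, p) in report.bsa_by_region.items()
        }
        entry["per_glycan_bsa"] = {
            k: round(v, 1) for k, v in report.per_glycan_bsa.items()
        }
        entry["angle_deg"] = round(interdomain_angle(copy).angle_deg, 2)

        net = classify_contacts(contact_network(copy, cutoff), copy)
        lines = [
            _meta_lines(config)
            + "chainA\tresA\tchainB\tresB\tmin_dist\tpos_A\tpos_B\tpolarity"
        ]
        for c in net.contacts:
            lines.append(
                f"{c.residue_a.chain_id}\t{c.residue_a.name}{c.residue_a.seq_number}"
                f"\t{c.residue_b.chain_id}\t{c.residue_b.name}{c.residue_b.seq_number}"
                f"\t{c.min_dist:.2f}\t{c.chain_position_a}\t{c.chain_position_b}"
                f"\t{c.polarity_class}"
            )
        (outdir / f"contacts_{tag}.tsv").write_text("\n".join(lines) + "\n")
        entry["n_contacts"] = len(net.contacts)

        hbonds = detect_hbonds(copy)
        lines = [_meta_lines(config) + "donor\tacceptor\tdistance"]
        for donor, acceptor, dist in hbonds:
            lines.append(f"{donor.name}\t{acceptor.name}\t{dist:.2f}")
        (outdir / f"hbonds_{tag}.tsv").write_text("\n".join(lines) + "\n")
        entry["n_hbonds"] = len(hbonds)
        summary["copies"].append(entry)
    _write_json(outdir / "interface_summary.json", summary)
    config.save(outdir / "run_config.json")
    return summary


def run_glyco(
    protein: str, precursors, config: RunConfig, glycan_db=None
) -> dict:
    """Per-site glycoform profiles with class fractions and a filter audit."""
    import pandas as pd

    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    db = glycan_db if glycan_db is not None else default_glycan_db()
    max_missed = int(config.params.get("max_missed", 2))
    tol_ppm = float(config.params.get("tol_ppm", 10.0))
    peptides = digest(protein, max_missed=max_missed)
    matches = match_precursors(precursors, peptides, db, protein, tol_ppm)
    from .glyco import find_sequons

    sites = config.params.get("sites") or find_sequons(protein)
    summary: dict = {"sites": {}, "n_matches": len(matches)}
    tables = []
    for site in sites:
        prof = site_profile(
            matches,
            site,
            min_log_prob=float(config.params.get("min_log_prob", 1.0)),
            min_spectra=int(config.params.get("min_spectra", 2)),
            top_n=int(config.params.get("top_n", 10)),
        )
        summary["sites"][str(site)] = {
            "class_fractions": {
                k: round(v, 4) for k, v in prof.class_fractions.items()
            },
            "total_spectra": prof.total_spectra,
            "filter_audit": prof.filter_audit,
        }
        tables.append(profile_table(prof))
    table = (
        pd.concat(tables, ignore_index=True) if tables else pd.DataFrame()
    )
    tsv_path = outdir / "site_profiles.tsv"
    with open(tsv_path, "w") as fh:
        fh.write(_meta_lines(config))
        table.to_csv(fh, sep="\t", index=False)
    _write_json(outdir / "glyco_summary.json", summary)
    config.save(outdir / "run_config.json")
    return summary
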