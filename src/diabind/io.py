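"""Readers and writers: PDB structures and multi-model trajectories,
nonbonded parameter tables, force sets, feature JSON and dataset TSV.

Conventions at the file boundary: PDB coordinates are angstroms and atom
serials 1-based; internally atoms are 0-indexed arrays. Output tables are
tab-separated with '.' decimals and a fixed column order.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.PDB import PDBParser
from Bio.PDB.PDBExceptions import PDBConstructionWarning

from .ensemble import ENTROPY_PROPERTIES, EnsembleFrames
from .exceptions import ConfigurationError, ShapeError, StructureError
from .forcefield import VDW_FORMS, ComplexSystem
from .model import MODEL_KINDS, ComplexFeatures, CVResult

#: Residue names treated as solvent or simple ions and dropped on read.
WATER_RESNAMES = {"HOH", "WAT", "H2O", "DOD", "TIP", "TIP3", "SPC"}
ION_RESNAMES = {"NA", "CL", "K", "MG", "ZN", "CA", "FE", "MN", "BR", "IOD",
                "NA+", "CL-", "SOD", "CLA"}

FEATURE_JSON_KEYS = (
    "sum_vdw", "sum_ele", "sum_ele_scaled", "sum_fluct_vdw", "sum_fluct_ele",
    "S_ASA", "S_DIH", "S_VDW", "S_ELE", "n_frames", "vdw_form",
)


@dataclass
class RunConfig:
    """Validated knobs of one analysis run."""

    vdw_form: str = "8-4"
    model_kind: str = "diav"
    property_tag: str = "ASA"
    x_grid: tuple = (0.1, 2.0, 0.1)
    probe: float = 1.4
    n_sphere_points: int = 960
    cutoff: float | None = None
    weighted_asa: bool = False
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.vdw_form not in VDW_FORMS:
            raise ConfigurationError(f"vdw_form must be one of {sorted(VDW_FORMS)}")
        if self.model_kind not in MODEL_KINDS:
            raise ConfigurationError(f"model_kind must be one of {MODEL_KINDS}")
        if self.property_tag not in ENTROPY_PROPERTIES:
            raise ConfigurationError(
                f"property_tag must be one of {ENTROPY_PROPERTIES}"
            )

    def x_values(self) -> np.ndarray:
        lo, hi, step = self.x_grid
        return np.round(np.arange(lo, hi + 1e-9, step), 10)


# ---------------------------------------------------------------------------
# parameter tables

def load_param_table(path=None) -> pd.DataFrame:
    """Load a nonbonded parameter table (TSV).

    Columns: atom_name, residue_name, charge_e, rmin_half_A, eps_kcal,
    solv_param, radius_A. Without a path, the packaged default table for
    the toy fixture atom types is returned.
    """
    if path is None:
        ref = resources.files("diabind.data").joinpath("params_default.tsv")
        table = pd.read_csv(ref.open("r"), sep="\t")
    else:
        table = pd.read_csv(path, sep="\t")
    required = {"atom_name", "residue_name", "charge_e", "rmin_half_A",
                "eps_kcal", "solv_param", "radius_A"}
    missing = required - set(table.columns)
    if missing:
        raise StructureError(f"parameter table lacks columns: {sorted(missing)}")
    return table


def write_param_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def _param_lookup(table: pd.DataFrame) -> dict:
    return {
        (str(r.residue_name), str(r.atom_name)): r
        for r in table.itertuples(index=False)
    }


# ---------------------------------------------------------------------------
# structures and trajectories

def _parse_pdb(path, structure_id="s"):
    parser = PDBParser(QUIET=True)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", PDBConstructionWarning)
            return parser.get_structure(structure_id, str(path))
    except Exception as err:
        raise StructureError(f"cannot parse PDB file {path}: {err}") from err


def _classify_residues(model, ligand: str | None):
    """Split a Bio.PDB model into protein residues and the ligand residue.

    Waters and simple ions are dropped. The ligand is the residue named by
    ``ligand`` or, by default, the largest heteroatom residue that is not
    water or an ion.
    """
    protein, hetero = [], []
    for chain in model:
        for res in chain:
            hetflag = res.id[0]
            name = res.get_resname().strip()
            if name in WATER_RESNAMES or hetflag == "W":
                continue
            if name in ION_RESNAMES:
                continue
            if hetflag != " ":
                hetero.append(res)
            else:
                protein.append(res)
    if ligand is not None:
        pool = hetero + protein
        matches = [r for r in pool if r.get_resname().strip() == ligand]
        if not matches:
            raise StructureError(f"no residue named {ligand!r} in structure")
        lig = max(matches, key=lambda r: len(r))
        protein = [r for r in protein if r is not lig]
        return protein, lig
    if not hetero:
        raise StructureError(
            "no ligand found: structure has no non-water, non-ion HETATM "
            "residue (use an explicit ligand selection)"
        )
    return protein, max(hetero, key=lambda r: len(r))


def read_structure(
    path,
    param_table: pd.DataFrame | None = None,
    ligand: str | None = None,
    rotatable_dihedrals=None,
) -> ComplexSystem:
    """Read a protein-ligand complex from a PDB file.

    Nonbonded parameters are joined from the parameter table by
    (residue_name, atom_name); waters and simple ions are excluded;
    protein residues are renumbered contiguously from 1 in file order.
    """
    table = load_param_table() if param_table is None else param_table
    lookup = _param_lookup(table)
    structure = _parse_pdb(path)
    model = next(iter(structure))
    protein, lig = _classify_residues(model, ligand)

    coords, charge, rmin, eps, solv, radius = [], [], [], [], [], []
    residx, is_lig, names, resnames = [], [], [], []
    missing = []

    def _add(res, res_number, ligand_flag):
        rname = res.get_resname().strip()
        for atom in res:
            aname = atom.get_name().strip()
            key = (rname, aname)
            row = lookup.get(key)
            if row is None:
                missing.append(key)
                continue
            coords.append(atom.coord)
            charge.append(row.charge_e)
            rmin.append(row.rmin_half_A)
            eps.append(row.eps_kcal)
            solv.append(row.solv_param)
            radius.append(row.radius_A)
            residx.append(res_number)
            is_lig.append(ligand_flag)
            names.append(aname)
            resnames.append(rname)

    _add(lig, 0, True)
    for i, res in enumerate(protein, start=1):
        _add(res, i, False)
    if missing:
        raise StructureError(
            "no parameters for atoms: "
            + ", ".join(f"{r}/{a}" for r, a in sorted(set(missing)))
        )
    return ComplexSystem(
        coordinates=np.array(coords, dtype=float),
        charge=np.array(charge),
        lj_re=np.array(rmin),
        lj_eps=np.array(eps),
        solvation_param=np.array(solv),
        radius=np.array(radius),
        residue_index=np.array(residx),
        is_ligand=np.array(is_lig),
        rotatable_dihedrals=list(rotatable_dihedrals or []),
        atom_names=names,
        residue_names=resnames,
    )


def read_trajectory(
    path,
    system: ComplexSystem,
    frame_interval: float = 1.0,
) -> EnsembleFrames:
    """Read an ordered ensemble from a multi-model PDB file.

    Atom order must match the system (same classification rules as
    :func:`read_structure`); a model with a deviating atom count raises a
    shape error naming the frame.
    """
    structure = _parse_pdb(path)
    frames = []
    for k, model in enumerate(structure):
        coords = []
        protein, lig = _classify_residues(model, None)
        for res in [lig] + protein:
            for atom in res:
                coords.append(atom.coord)
        coords = np.array(coords, dtype=float)
        if coords.shape != (system.n_atoms, 3):
            raise ShapeError(
                f"frame {k} has {coords.shape[0]} atoms; system has "
                f"{system.n_atoms}"
            )
        frames.append(coords)
    if not frames:
        raise StructureError(f"no models found in {path}")
    return EnsembleFrames(
        system=system, frames=np.stack(frames), frame_interval=frame_interval
    )


def _pdb_atom_line(serial, name, resname, chain, resseq, xyz, hetatm):
    record = "HETATM" if hetatm else "ATOM  "
    name_field = f" {name:<3s}" if len(name) < 4 else name[:4]
    return (
        f"{record}{serial:>5d} {name_field} {resname:<3s} {chain}{resseq:>4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.0:6.2f}{0.0:6.2f}"
        f"          {name[0]:>2s}\n"
    )


def _model_lines(system: ComplexSystem, coords) -> list[str]:
    lines = []
    serial = 1
    order = list(np.flatnonzero(system.is_ligand)) + list(
        np.flatnonzero(~system.is_ligand)
    )
    for i in order:
        hetatm = bool(system.is_ligand[i])
        resseq = 1 if hetatm else int(system.residue_index[i]) + 1
        chain = "L" if hetatm else "A"
        lines.append(
            _pdb_atom_line(
                serial, system.atom_names[i], system.residue_names[i],
                chain, resseq, coords[i], hetatm,
            )
        )
        serial += 1
    return lines


def write_pdb(system: ComplexSystem, path, coords=None) -> None:
    """Write the complex (reference or given conformation) as PDB."""
    coords = system.coordinates if coords is None else np.asarray(coords)
    with open(path, "w") as fh:
        fh.writelines(_model_lines(system, coords))
        fh.write("END\n")


def write_multimodel_pdb(frames: EnsembleFrames, path) -> None:
    """Write the ensemble as a multi-model PDB trajectory."""
    with open(path, "w") as fh:
        for k in range(frames.n_frames):
            fh.write(f"MODEL     {k + 1:>4d}\n")
            fh.writelines(_model_lines(frames.system, frames.frames[k]))
            fh.write("ENDMDL\n")
        fh.write("END\n")


# ---------------------------------------------------------------------------
# force sets

def write_forces_tsv(F_real, F_vac, path, atom_ids=None) -> None:
    """Write paired solvated/vacuum per-atom force sets (kcal/mol/A)."""
    F_real = np.asarray(F_real, float)
    F_vac = np.asarray(F_vac, float)
    if F_real.shape != F_vac.shape:
        raise ShapeError("force sets must have identical shapes")
    ids = np.arange(F_real.shape[0]) if atom_ids is None else np.asarray(atom_ids)
    df = pd.DataFrame({
        "atom_id": ids,
        "Fx_real": F_real[:, 0], "Fy_real": F_real[:, 1], "Fz_real": F_real[:, 2],
        "Fx_vac": F_vac[:, 0], "Fy_vac": F_vac[:, 1], "Fz_vac": F_vac[:, 2],
    })
    df.to_csv(path, sep="\t", index=False)


def read_forces_tsv(path):
    """Read a force-set TSV; returns (F_real, F_vac) ordered by atom_id."""
    df = pd.read_csv(path, sep="\t").sort_values("atom_id")
    required = {"atom_id", "Fx_real", "Fy_real", "Fz_real",
                "Fx_vac", "Fy_vac", "Fz_vac"}
    missing = required - set(df.columns)
    if missing:
        raise StructureError(f"force table lacks columns: {sorted(missing)}")
    F_real = df[["Fx_real", "Fy_real", "Fz_real"]].to_numpy(float)
    F_vac = df[["Fx_vac", "Fy_vac", "Fz_vac"]].to_numpy(float)
    return F_real, F_vac


# ---------------------------------------------------------------------------
# features, datasets, CV reports

def features_to_dict(f: ComplexFeatures) -> dict:
    d = {
        "complex_id": f.complex_id,
        "sum_vdw": f.sum_vdw,
        "sum_ele": f.sum_ele,
        "sum_ele_scaled": f.sum_ele_scaled,
        "sum_fluct_vdw": f.sum_fluct_vdw,
        "sum_fluct_ele": f.sum_fluct_ele,
        "n_frames": f.n_frames,
        "vdw_form": f.vdw_form,
        "dg_exptl": f.dg_exptl,
    }
    for tag in ENTROPY_PROPERTIES:
        d[f"S_{tag}"] = f.entropy.get(tag)
    return d


def features_from_dict(d: dict) -> ComplexFeatures:
    entropy = {
        tag: d[f"S_{tag}"]
        for tag in ENTROPY_PROPERTIES
        if d.get(f"S_{tag}") is not None
    }
    return ComplexFeatures(
        complex_id=d.get("complex_id", "complex"),
        sum_vdw=d["sum_vdw"],
        sum_ele=d["sum_ele"],
        sum_ele_scaled=d.get("sum_ele_scaled"),
        sum_fluct_vdw=d["sum_fluct_vdw"],
        sum_fluct_ele=d["sum_fluct_ele"],
        entropy=entropy,
        dg_exptl=d.get("dg_exptl"),
        vdw_form=d.get("vdw_form", "12-6"),
        n_frames=d.get("n_frames"),
    )


def write_features_json(f: ComplexFeatures, path) -> None:
    Path(path).write_text(json.dumps(features_to_dict(f), indent=2) + "\n")


def read_features_json(path) -> ComplexFeatures:
    return features_from_dict(json.loads(Path(path).read_text()))


_DATASET_COLUMNS = [
    "complex_id", "dg_exptl", "sum_vdw", "sum_ele", "sum_ele_scaled",
    "sum_fluct_vdw", "sum_fluct_ele", "S_ASA", "S_DIH", "S_VDW", "S_ELE",
]


def write_dataset_tsv(dataset, path) -> None:
    rows = [features_to_dict(f) for f in dataset]
    pd.DataFrame(rows)[_DATASET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_dataset_tsv(path) -> list[ComplexFeatures]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for rec in df.to_dict(orient="records"):
        rec = {k: (None if pd.isna(v) else v) for k, v in rec.items()}
        out.append(features_from_dict(rec))
    return out


def write_cv_report(result: CVResult, json_path, tsv_path=None) -> None:
    """Write a cross-validation report as JSON (and an optional TSV twin)."""
    payload = {
        "mae": result.mae,
        "pearson_r": result.pearson_r,
        "params": result.params.to_dict(),
        "predictions": [
            {"complex_id": cid, "dg_exptl": float(e), "dg_pred": float(p)}
            for cid, e, p in zip(
                result.complex_ids, result.dg_exptl, result.predictions
            )
        ],
    }
    Path(json_path).write_text(json.dumps(payload, indent=2) + "\n")
    if tsv_path is not None:
        pd.DataFrame(payload["predictions"]).to_csv(tsv_path, sep="\t", index=False)
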