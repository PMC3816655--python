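"""Deterministic synthetic fixtures: toy complexes, pseudo-ensembles,
fabricated force sets, feature datasets, and the packaged 34-complex
benchmark table.

The toy generator builds a ring of pseudo-residues around a small helical
ligand and perturbs the geometry with Gaussian jitter to stand in for a
sampled molecular-dynamics ensemble. It makes no attempt to emulate real
MD physics; it exists to exercise the full pipeline reproducibly.
"""

from __future__ import annotations

import hashlib
import zlib
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, GenerationError, ParameterError
from .forcefield import ComplexSystem
from .ensemble import EnsembleFrames
from .model import ComplexFeatures, ModelParams, predict_dg

_BENCHMARK_FILE = "benchmark34.tsv"
_BENCHMARK_SHA256 = "1ff9fc442ecfc51f250dca5e98d816e412096383fb8a989c320521416358ee11"

#: Protein pseudo-residue type names cycled around the ring.
_RESIDUE_TYPES = ("TOA", "TOB", "TOC")
_LIGAND_RESNAME = "LIG"

#: Generating parameters used by default for synthetic feature datasets:
#: the DIAV coefficients fitted on the 34-complex benchmark.
DEFAULT_TRUE_PARAMS = ModelParams(
    alpha=0.0378,
    alpha2=0.0093,
    beta=0.0082,
    beta2=-0.0011,
    tau=-2.4178e-4,
    vdw_form="8-4",
    property_tag="ASA",
    model_kind="diav",
)


@dataclass(frozen=True)
class ToySpec:
    """Size and noise parameters of one toy complex + pseudo-ensemble."""

    seed: int
    n_residues: int = 8
    atoms_per_residue: int = 4
    n_ligand_atoms: int = 8
    n_frames: int = 50
    positional_jitter: float = 0.15
    charge_scale: float = 0.25

    def __post_init__(self):
        counts = (self.n_residues, self.atoms_per_residue, self.n_ligand_atoms,
                  self.n_frames)
        if any(c < 1 for c in counts):
            raise ConfigurationError("all toy counts must be >= 1")
        if self.positional_jitter < 0:
            raise ConfigurationError("positional jitter must be >= 0")


def _atom_type_params(residue_name: str, atom_name: str, charge_scale: float):
    """Deterministic per-atom-type nonbonded parameters.

    Seeded by a CRC of the (residue, atom) name pair so that every atom
    slot has fixed force-field-like parameters regardless of the toy seed
    — which makes PDB + parameter-table round trips exact.
    """
    rng = np.random.default_rng(zlib.crc32(f"{residue_name}:{atom_name}".encode()))
    return {
        "charge_e": charge_scale * rng.normal(),
        "rmin_half_A": rng.uniform(1.5, 2.0),
        "eps_kcal": rng.uniform(0.05, 0.2),
        "solv_param": rng.uniform(-0.01, 0.03),
    }


def toy_param_table(spec: ToySpec) -> pd.DataFrame:
    """Parameter table covering every atom type of a toy complex."""
    rows = []
    for rname in _RESIDUE_TYPES:
        for k in range(spec.atoms_per_residue):
            aname = f"C{k + 1}"
            p = _atom_type_params(rname, aname, spec.charge_scale)
            rows.append((aname, rname, p["charge_e"], p["rmin_half_A"],
                         p["eps_kcal"], p["solv_param"], p["rmin_half_A"]))
    for k in range(spec.n_ligand_atoms):
        aname = f"L{k + 1}"
        p = _atom_type_params(_LIGAND_RESNAME, aname, spec.charge_scale)
        rows.append((aname, _LIGAND_RESNAME, p["charge_e"], p["rmin_half_A"],
                     p["eps_kcal"], p["solv_param"], p["rmin_half_A"]))
    return pd.DataFrame(
        rows,
        columns=["atom_name", "residue_name", "charge_e", "rmin_half_A",
                 "eps_kcal", "solv_param", "radius_A"],
    )


def make_toy_complex(spec: ToySpec):
    """Build a toy complex, a jittered pseudo-ensemble and a force-set pair.

    Protein pseudo-residues sit on a ring around a helical ligand at the
    origin; frame 0 is the unperturbed geometry (no atom pair closer than
    1.5 A), subsequent frames add Gaussian positional jitter. The
    fabricated electrostatic force pair satisfies ``F_vac = s * F_real``
    with a per-protein-atom screening factor s drawn uniformly in [1, 10].

    Returns ``(system, frames, (F_real, F_vac))``; everything is a pure
    function of the spec.
    """
    rng = np.random.default_rng(spec.seed)

    # ligand: short helix around the z axis, centered at the origin
    m = spec.n_ligand_atoms
    k = np.arange(m)
    lig = np.column_stack(
        (1.2 * np.cos(2.2 * k), 1.2 * np.sin(2.2 * k), 0.8 * k - 0.4 * (m - 1))
    )

    # protein: residues on a ring wide enough to keep ~5 A center spacing
    n_res = spec.n_residues
    ring_r = max(7.0, 5.0 * n_res / (2.0 * np.pi))
    apr = spec.atoms_per_residue
    jloc = np.arange(apr)
    local = np.column_stack(
        (1.7 * np.cos(2.4 * jloc), 1.7 * np.sin(2.4 * jloc),
         0.9 * jloc - 0.45 * (apr - 1))
    )
    coords, names, resnames, residx = [lig], [], [], []
    names += [f"L{i + 1}" for i in range(m)]
    resnames += [_LIGAND_RESNAME] * m
    residx += [0] * m
    for r in range(n_res):
        theta = 2.0 * np.pi * r / n_res
        center = np.array(
            [ring_r * np.cos(theta), ring_r * np.sin(theta), 1.0 if r % 2 else -1.0]
        )
        coords.append(center + local)
        rname = _RESIDUE_TYPES[r % len(_RESIDUE_TYPES)]
        names += [f"C{i + 1}" for i in range(apr)]
        resnames += [rname] * apr
        residx += [r + 1] * apr
    coords = np.vstack(coords)
    n_atoms = coords.shape[0]

    d = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    np.fill_diagonal(d, np.inf)
    if d.min() < 1.5:
        raise GenerationError(
            f"toy packing produced a {d.min():.2f} A contact (< 1.5 A)"
        )

    params = [
        _atom_type_params(rn, an, spec.charge_scale)
        for rn, an in zip(resnames, names)
    ]
    system = ComplexSystem(
        coordinates=coords,
        charge=np.array([p["charge_e"] for p in params]),
        lj_re=np.array([p["rmin_half_A"] for p in params]),
        lj_eps=np.array([p["eps_kcal"] for p in params]),
        solvation_param=np.array([p["solv_param"] for p in params]),
        radius=np.array([p["rmin_half_A"] for p in params]),
        residue_index=np.array(residx),
        is_ligand=np.array([i < m for i in range(n_atoms)]),
        rotatable_dihedrals=_toy_dihedrals(m, n_res, apr),
        atom_names=names,
        residue_names=resnames,
    )

    jitter = rng.normal(0.0, spec.positional_jitter,
                        size=(spec.n_frames, n_atoms, 3)) if spec.positional_jitter > 0 \
        else np.zeros((spec.n_frames, n_atoms, 3))
    jitter[0] = 0.0  # frame 0 is the reference geometry
    frames = EnsembleFrames(system=system, frames=coords[None, :, :] + jitter)

    n_prot = n_atoms - m
    F_real = rng.normal(0.0, 5.0, size=(n_prot, 3))
    s = rng.uniform(1.0, 10.0, size=n_prot)
    F_vac = s[:, None] * F_real
    return system, frames, (F_real, F_vac)


def _toy_dihedrals(n_lig: int, n_res: int, apr: int) -> list[tuple[int, ...]]:
    """Rotatable dihedrals: consecutive ligand quadruples plus one
    quadruple per protein residue with >= 4 atoms."""
    dihedrals = [tuple(range(j, j + 4)) for j in range(max(0, n_lig - 3))]
    if apr >= 4:
        for r in range(n_res):
            base = n_lig + r * apr
            dihedrals.append(tuple(range(base, base + 4)))
    return dihedrals


def make_feature_dataset(
    seed: int,
    true_params: ModelParams | None = None,
    n: int = 34,
    noise_sd: float = 1.0,
) -> list[ComplexFeatures]:
    """Synthetic feature rows with known generating parameters.

    Feature ranges are chosen so predicted dG spans roughly -14 to -4
    kcal/mol, the scale of the 34-complex benchmark;
    ``dg_exptl = predict_dg(features, true_params) + N(0, noise_sd)``.
    """
    p = DEFAULT_TRUE_PARAMS if true_params is None else true_params
    if noise_sd < 0:
        raise ParameterError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        sum_ele = rng.uniform(-400.0, -30.0)
        f = ComplexFeatures(
            complex_id=f"syn{i:03d}",
            sum_vdw=rng.uniform(-250.0, -80.0),
            sum_ele=sum_ele,
            sum_ele_scaled=sum_ele / rng.uniform(1.2, 3.0),
            sum_fluct_vdw=rng.uniform(5.0, 60.0),
            sum_fluct_ele=rng.uniform(10.0, 120.0),
            entropy={
                "ASA": rng.uniform(20.0, 120.0),
                "DIH": rng.uniform(0.5, 8.0),
                "VDW": rng.uniform(0.5, 5.0),
                "ELE": rng.uniform(1.0, 10.0),
            },
            vdw_form=p.vdw_form,
        )
        f.dg_exptl = predict_dg(f, p) + rng.normal(0.0, noise_sd)
        out.append(f)
    return out


def table4_fixture() -> pd.DataFrame:
    """The packaged 34-complex benchmark: experimental dG plus the
    published simple/DIAV/DIAS cross-validated predictions (kcal/mol).

    The data file is checksummed on load; the returned frame has columns
    pdb_id, protein_name, dg_exptl, dg_simple, dg_diav, dg_dias.
    """
    ref = resources.files("diabind.data").joinpath(_BENCHMARK_FILE)
    raw = ref.read_bytes()
    digest = hashlib.sha256(raw).hexdigest()
    if digest != _BENCHMARK_SHA256:
        raise GenerationError(
            f"benchmark table checksum mismatch ({digest}); file corrupted"
        )
    df = pd.read_csv(ref.open("r"), sep="\t")
    if len(df) != 34:
        raise GenerationError(f"benchmark table has {len(df)} rows, expected 34")
    return df
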