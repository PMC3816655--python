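"""Feature extraction: from a conformational ensemble to model inputs."""

from __future__ import annotations

import numpy as np
from scipy.stats import circstd

from .ensemble import (
    ENTROPY_PROPERTIES,
    DielectricMap,
    EnsembleFrames,
    asa_property,
    dihedral_angles,
)
from .exceptions import ConfigurationError, CoverageError
from .forcefield import residue_ligand_energies
from .model import ComplexFeatures


def extract_features(
    frames: EnsembleFrames,
    vdw_form: str = "8-4",
    dmap: DielectricMap | None = None,
    properties=ENTROPY_PROPERTIES,
    probe: float = 1.4,
    n_points: int = 960,
    weighted_asa: bool = False,
    cutoff: float | None = None,
    complex_id: str = "complex",
    dg_exptl: float | None = None,
) -> ComplexFeatures:
    """Reduce an ensemble to the scalar feature set of the dG models.

    Computes, in one pass over the frames, the residue-summed mean vdW and
    electrostatic interaction energies, the summed per-residue
    fluctuations, the dielectric-scaled electrostatic sum (when ``dmap``
    is given) and the requested entropy descriptors S_x.
    """
    sys_ = frames.system
    bad = [p for p in properties if p not in ENTROPY_PROPERTIES]
    if bad:
        raise ConfigurationError(f"unknown entropy properties {bad!r}")
    eps_map = None
    if dmap is not None:
        n_prot = sys_.protein_atom_ids.size
        if dmap.eps_eff.shape != (n_prot,):
            raise CoverageError(
                f"dielectric map covers {dmap.eps_eff.shape[0]} atoms; "
                f"system has {n_prot} protein atoms"
            )
        eps_map = dmap.eps_eff

    n_res = sys_.residue_count
    vdw = np.empty((frames.n_frames, n_res))
    ele = np.empty((frames.n_frames, n_res))
    ele_scaled = np.empty_like(ele) if eps_map is not None else None
    for k in range(frames.n_frames):
        vdw[k], ele[k] = residue_ligand_energies(
            sys_, frames.frames[k], form=vdw_form, cutoff=cutoff
        )
        if ele_scaled is not None:
            _, ele_scaled[k] = residue_ligand_energies(
                sys_, frames.frames[k], form=vdw_form, cutoff=cutoff, eps_map=eps_map
            )

    entropy = {}
    if "ASA" in properties:
        asa = np.array(
            [
                asa_property(f, sys_, probe=probe, n_points=n_points, weighted=weighted_asa)
                for f in frames.frames
            ]
        )
        entropy["ASA"] = float(asa.std())
    if "DIH" in properties:
        if not sys_.rotatable_dihedrals:
            raise ConfigurationError(
                "DIH descriptor requires a non-empty rotatable_dihedrals list"
            )
        ang = np.stack(
            [dihedral_angles(f, sys_.rotatable_dihedrals) for f in frames.frames]
        )
        entropy["DIH"] = float(
            sum(
                circstd(ang[:, j], high=np.pi, low=-np.pi)
                for j in range(ang.shape[1])
            )
        )
    if "VDW" in properties:
        entropy["VDW"] = float(vdw.sum(axis=1).std())
    if "ELE" in properties:
        entropy["ELE"] = float(ele.sum(axis=1).std())

    return ComplexFeatures(
        complex_id=complex_id,
        sum_vdw=float(vdw.mean(axis=0).sum()),
        sum_ele=float(ele.mean(axis=0).sum()),
        sum_fluct_vdw=float(vdw.std(axis=0).sum()),
        sum_fluct_ele=float(ele.std(axis=0).sum()),
        sum_ele_scaled=(
            None if ele_scaled is None else float(ele_scaled.mean(axis=0).sum())
        ),
        entropy=entropy,
        dg_exptl=dg_exptl,
        vdw_form=vdw_form,
        n_frames=frames.n_frames,
    )
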