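"""Ensemble statistics over conformational frames.

Mean and fluctuation profiles of the per-residue protein-ligand
interaction, accessible-surface-area (ASA) and dihedral "entropy"
descriptors, and the effective-dielectric map estimated from paired
solvated/vacuum electrostatic force sets.

The "fluctuation" of any quantity is its population standard deviation
over the frames of the ensemble, which keeps each descriptor in the
physical units of the underlying property (A^2 for ASA, radians for
dihedrals, kcal/mol for energies).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import circstd

from .exceptions import (
    ConfigurationError,
    CoverageError,
    EmptyEnsembleError,
    ParameterError,
    ShapeError,
)
from .forcefield import ComplexSystem, residue_ligand_energies

#: Recognized entropy-descriptor property tags.
ENTROPY_PROPERTIES = ("ASA", "DIH", "VDW", "ELE")


@dataclass
class EnsembleFrames:
    """Ordered conformations of one complex.

    ``frames`` is (n_frames, n_atoms, 3) in angstroms; ``frame_interval``
    is the sampling interval in picoseconds (metadata only).
    """

    system: ComplexSystem
    frames: np.ndarray
    frame_interval: float = 1.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[0] < 1:
            raise EmptyEnsembleError("ensemble needs >= 1 frame of shape (n, 3)")
        if self.frames.shape[1:] != (self.system.n_atoms, 3):
            raise ShapeError(
                f"frame shape {self.frames.shape[1:]} does not match system "
                f"({self.system.n_atoms}, 3)"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]


@dataclass
class ResidueInteractionProfile:
    """Per-residue ensemble means and fluctuations of the interaction.

    All arrays have length ``residue_count``; fluctuations are population
    standard deviations over frames (zero for a single frame).
    ``mean_ele_scaled`` is filled only when an effective-dielectric map
    was applied.
    """

    mean_vdw: np.ndarray
    mean_ele: np.ndarray
    fluct_vdw: np.ndarray
    fluct_ele: np.ndarray
    n_frames: int
    vdw_form: str
    mean_ele_scaled: np.ndarray | None = None

    def __post_init__(self):
        for name in ("fluct_vdw", "fluct_ele"):
            if np.any(getattr(self, name) < 0):
                raise ParameterError(f"{name} must be non-negative")


@dataclass(frozen=True)
class EntropyDescriptor:
    """A scalar fluctuation descriptor S_x of one ensemble property.

    ``property_tag`` is one of ASA (total complex accessible surface,
    A^2), DIH (summed circular SD of rotatable dihedrals, radians), VDW or
    ELE (total protein-ligand energy, kcal/mol).
    """

    property_tag: str
    value: float

    def __post_init__(self):
        if self.property_tag not in ENTROPY_PROPERTIES:
            raise ConfigurationError(
                f"unknown property {self.property_tag!r}; "
                f"choose one of {ENTROPY_PROPERTIES}"
            )
        if not np.isfinite(self.value) or self.value < 0:
            raise ParameterError("entropy descriptor must be finite and >= 0")


@dataclass
class DielectricMap:
    """Per-protein-atom effective dielectric constants, all >= 1."""

    eps_eff: np.ndarray
    x: float

    def __post_init__(self):
        self.eps_eff = np.asarray(self.eps_eff, dtype=float)
        if not np.all(np.isfinite(self.eps_eff)):
            raise ParameterError("eps_eff must be finite")
        if np.any(self.eps_eff < 1):
            raise ParameterError("eps_eff must satisfy eps_eff >= 1")


def ensemble_interaction_profile(
    frames: EnsembleFrames,
    form: str = "12-6",
    cutoff: float | None = None,
    eps_map: np.ndarray | None = None,
) -> ResidueInteractionProfile:
    """Mean and fluctuation of the per-residue interaction over frames.

    With ``eps_map`` given, additionally computes the dielectric-scaled
    electrostatic mean (each protein atom's Coulomb terms divided by its
    eps_eff before residue summation).
    """
    sys_ = frames.system
    n_res = sys_.residue_count
    vdw = np.empty((frames.n_frames, n_res))
    ele = np.empty((frames.n_frames, n_res))
    ele_scaled = np.empty((frames.n_frames, n_res)) if eps_map is not None else None
    for k in range(frames.n_frames):
        vdw[k], ele[k] = residue_ligand_energies(
            sys_, frames.frames[k], form=form, cutoff=cutoff
        )
        if ele_scaled is not None:
            _, ele_scaled[k] = residue_ligand_energies(
                sys_, frames.frames[k], form=form, cutoff=cutoff, eps_map=eps_map
            )
    return ResidueInteractionProfile(
        mean_vdw=vdw.mean(axis=0),
        mean_ele=ele.mean(axis=0),
        fluct_vdw=vdw.std(axis=0),
        fluct_ele=ele.std(axis=0),
        n_frames=frames.n_frames,
        vdw_form=form,
        mean_ele_scaled=None if ele_scaled is None else ele_scaled.mean(axis=0),
    )


def _sphere_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform unit-sphere points (golden-spiral)."""
    k = np.arange(n) + 0.5
    phi = np.arccos(1.0 - 2.0 * k / n)
    theta = np.pi * (1.0 + np.sqrt(5.0)) * k
    return np.column_stack(
        (np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi))
    )


def shrake_rupley_asa(
    conformation: np.ndarray,
    radii: np.ndarray,
    probe: float = 1.4,
    n_points: int = 960,
) -> np.ndarray:
    """Per-atom solvent-accessible surface area by the Shrake-Rupley method.

    Each atom's solvent-accessible sphere (radius + probe) is sampled with
    ``n_points`` quasi-uniform test points; a point is accessible if it lies
    outside every neighbour's accessible sphere. Returns areas in A^2.
    """
    coords = np.asarray(conformation, dtype=float)
    radii = np.asarray(radii, dtype=float)
    n = coords.shape[0]
    if coords.shape != (n, 3) or radii.shape != (n,):
        raise ShapeError("conformation must be (n, 3) with n radii")
    if np.any(radii <= 0):
        raise ParameterError("all radii must be > 0")
    if n_points < 60:
        raise ParameterError("n_points must be >= 60 for a usable estimate")

    ext = radii + probe
    unit = _sphere_points(n_points)
    dmat = np.sqrt(((coords[:, None, :] - coords[None, :, :]) ** 2).sum(axis=2))
    if n > 1:
        off = ~np.eye(n, dtype=bool)
        if np.any(dmat[off] == 0.0):
            warnings.warn(
                "distinct atoms share identical coordinates; ASA is degenerate",
                RuntimeWarning,
                stacklevel=2,
            )
    areas = np.empty(n)
    for i in range(n):
        # only neighbours whose accessible spheres can reach atom i's surface
        nbr = np.flatnonzero((dmat[i] < ext[i] + ext) & (np.arange(n) != i))
        pts = coords[i] + ext[i] * unit
        if nbr.size:
            d2 = ((pts[:, None, :] - coords[nbr][None, :, :]) ** 2).sum(axis=2)
            accessible = np.all(d2 > ext[nbr] ** 2, axis=1)
            frac = accessible.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * ext[i] ** 2 * frac
    return areas


def asa_property(
    conformation: np.ndarray,
    system: ComplexSystem,
    probe: float = 1.4,
    n_points: int = 960,
    weighted: bool = False,
) -> float:
    """Total complex ASA (A^2), or the solvation-weighted sum (kcal/mol).

    In weighted mode each atom's area is multiplied by its atomic
    solvation parameter before summation.
    """
    areas = shrake_rupley_asa(conformation, system.radius, probe, n_points)
    if weighted:
        return float(np.dot(system.solvation_param, areas))
    return float(areas.sum())


def dihedral_angles(coords: np.ndarray, dihedrals) -> np.ndarray:
    """Signed dihedral angles (radians, in (-pi, pi]) for 4-atom index tuples."""
    coords = np.asarray(coords, dtype=float)
    idx = np.asarray(list(dihedrals), dtype=int)
    p0, p1, p2, p3 = (coords[idx[:, k]] for k in range(4))
    b0 = p1 - p0
    b1 = p2 - p1
    b2 = p3 - p2
    n1 = np.cross(b0, b1)
    n2 = np.cross(b1, b2)
    b1u = b1 / np.linalg.norm(b1, axis=1, keepdims=True)
    m1 = np.cross(n1, b1u)
    x = (n1 * n2).sum(axis=1)
    y = (m1 * n2).sum(axis=1)
    return np.arctan2(y, x)


def entropy_descriptor(
    frames: EnsembleFrames,
    property_tag: str,
    form: str = "12-6",
    probe: float = 1.4,
    n_points: int = 960,
    weighted_asa: bool = False,
    cutoff: float | None = None,
) -> EntropyDescriptor:
    """Fluctuation descriptor S_x of one ensemble property.

    ASA: population SD over frames of the total complex ASA. DIH: sum over
    the system's rotatable dihedrals of the circular SD of the dihedral
    angle. VDW / ELE: population SD over frames of the total
    protein-ligand vdW / electrostatic energy.
    """
    if property_tag not in ENTROPY_PROPERTIES:
        raise ConfigurationError(
            f"unknown property {property_tag!r}; choose one of {ENTROPY_PROPERTIES}"
        )
    sys_ = frames.system
    if property_tag == "ASA":
        vals = np.array(
            [
                asa_property(f, sys_, probe=probe, n_points=n_points, weighted=weighted_asa)
                for f in frames.frames
            ]
        )
        value = float(vals.std())
    elif property_tag == "DIH":
        if not sys_.rotatable_dihedrals:
            raise ConfigurationError(
                "DIH descriptor requires a non-empty rotatable_dihedrals list"
            )
        angles = np.stack(
            [dihedral_angles(f, sys_.rotatable_dihedrals) for f in frames.frames]
        )  # (n_frames, n_dihedrals)
        value = float(
            sum(
                circstd(angles[:, j], high=np.pi, low=-np.pi)
                for j in range(angles.shape[1])
            )
        )
    else:  # VDW / ELE
        totals = np.empty(frames.n_frames)
        col = 0 if property_tag == "VDW" else 1
        for k in range(frames.n_frames):
            pair = residue_ligand_energies(sys_, frames.frames[k], form=form, cutoff=cutoff)
            totals[k] = pair[col].sum()
        value = float(totals.std())
    return EntropyDescriptor(property_tag=property_tag, value=value)


def effective_dielectric(
    F_real: np.ndarray,
    F_vac: np.ndarray,
    x: float = 0.6,
    mode: int = 19,
) -> DielectricMap:
    """Per-atom effective dielectric from paired force sets.

    The raw screening ratio compares the electrostatic force on each
    protein atom computed without solvent (``F_vac``) to the force
    computed in explicit solvent (``F_real``). Mode 19 (default) uses the
    ratio of vector magnitudes; mode 18 projects the vacuum force onto the
    solvated force direction first. The raw ratio diverges where the
    solvated force is nearly zero, so both numerator and denominator are
    damped by ``x`` times the mean vacuum-force magnitude and the result
    is clipped to >= 1:

        eps_eff = max(1, (a_i + x*Fbar) / (b_i + x*Fbar))

    with a_i the vacuum measure, b_i = |F_real_i| and Fbar = mean_i |F_vac_i|.
    """
    F_real = np.asarray(F_real, dtype=float)
    F_vac = np.asarray(F_vac, dtype=float)
    if F_real.shape != F_vac.shape or F_real.ndim != 2 or F_real.shape[1] != 3:
        raise ShapeError("F_real and F_vac must both be (n_atoms, 3)")
    if x < 0:
        raise ParameterError("regularizer x must be >= 0")
    if mode not in (18, 19):
        raise ConfigurationError("mode must be 18 or 19")

    mag_real = np.linalg.norm(F_real, axis=1)
    mag_vac = np.linalg.norm(F_vac, axis=1)
    if mode == 19:
        num = mag_vac
    else:  # projection of F_vac onto the unit solvated-force direction
        with np.errstate(invalid="ignore", divide="ignore"):
            num = np.abs((F_vac * F_real).sum(axis=1)) / mag_real
        num = np.where(mag_real > 0, num, mag_vac)
    fbar = mag_vac.mean()
    damp = x * fbar
    if damp == 0.0:
        with np.errstate(invalid="ignore", divide="ignore"):
            ratio = np.where(mag_real > 0, num / mag_real, np.inf)
        if not np.all(np.isfinite(ratio)):
            raise ParameterError(
                "zero solvated force with x = 0; a positive x is required"
            )
    else:
        ratio = (num + damp) / (mag_real + damp)
    return DielectricMap(eps_eff=np.maximum(1.0, ratio), x=x)


def scaled_ele_profile(
    frames: EnsembleFrames,
    dmap: DielectricMap,
    form: str = "12-6",
    cutoff: float | None = None,
) -> ResidueInteractionProfile:
    """Interaction profile with the dielectric-scaled electrostatic mean.

    Every protein-atom/ligand-atom Coulomb term is divided by the protein
    atom's eps_eff before summation into residue totals. A unit map
    reproduces the unscaled profile exactly.
    """
    n_prot = frames.system.protein_atom_ids.size
    if dmap.eps_eff.shape != (n_prot,):
        raise CoverageError(
            f"dielectric map covers {dmap.eps_eff.shape[0]} atoms; "
            f"system has {n_prot} protein atoms"
        )
    return ensemble_interaction_profile(
        frames, form=form, cutoff=cutoff, eps_map=dmap.eps_eff
    )
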