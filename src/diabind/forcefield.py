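"""Pairwise and per-residue protein-ligand interaction energies.

Nonbonded energetics between a protein and a bound ligand: a generalized
Lennard-Jones n-m van der Waals term (the 12-6, 9-6, 8-4 and 6-3 variants)
and a Coulomb electrostatic term, decomposed per protein residue. Units are
kcal/mol, angstroms and elementary charges throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    ConfigurationError,
    DomainError,
    ParameterError,
    ShapeError,
)

#: Coulomb conversion constant, kcal*A/(mol*e^2).
COULOMB_CONSTANT = 332.0637

#: Supported van der Waals functional forms, tag -> (repulsive n, attractive m).
VDW_FORMS = {
    "12-6": (12, 6),
    "9-6": (9, 6),
    "8-4": (8, 4),
    "6-3": (6, 3),
}


def _resolve_form(form: str) -> tuple[int, int]:
    try:
        return VDW_FORMS[form]
    except KeyError:
        raise ParameterError(
            f"unknown vdW form {form!r}; choose one of {sorted(VDW_FORMS)}"
        ) from None


@dataclass(frozen=True)
class AtomParams:
    """Nonbonded parameters of a single atom.

    Attributes
    ----------
    atom_id : int
        Zero-based atom index within the complex.
    residue_index : int
        1-based protein residue number; 0 marks a ligand atom.
    is_ligand : bool
        Whether the atom belongs to the ligand.
    charge : float
        Partial charge, elementary charges.
    lj_re : float
        Per-atom equilibrium-distance component (Rmin/2 convention), A.
    lj_eps : float
        Well depth, kcal/mol.
    solvation_param : float
        Atomic solvation parameter, kcal/mol/A^2.
    radius : float
        Atomic radius used for accessible-surface-area work, A.
    """

    atom_id: int
    residue_index: int
    is_ligand: bool
    charge: float
    lj_re: float
    lj_eps: float
    solvation_param: float = 0.0
    radius: float = 1.7

    def __post_init__(self):
        vals = (self.charge, self.lj_re, self.lj_eps, self.solvation_param, self.radius)
        if not all(np.isfinite(v) for v in vals):
            raise ParameterError(f"non-finite parameter for atom {self.atom_id}")
        if self.lj_re <= 0:
            raise ParameterError(f"lj_re must be > 0 (atom {self.atom_id})")
        if self.lj_eps < 0:
            raise ParameterError(f"lj_eps must be >= 0 (atom {self.atom_id})")
        if self.radius <= 0:
            raise ParameterError(f"radius must be > 0 (atom {self.atom_id})")


@dataclass
class ComplexSystem:
    """A protein-ligand complex as parallel per-atom arrays.

    ``residue_index`` is 1-based over protein residues and 0 for ligand
    atoms; protein residue indices must be contiguous from 1. The reference
    conformation lives in ``coordinates`` (N x 3, angstroms).
    """

    coordinates: np.ndarray
    charge: np.ndarray
    lj_re: np.ndarray
    lj_eps: np.ndarray
    solvation_param: np.ndarray
    radius: np.ndarray
    residue_index: np.ndarray
    is_ligand: np.ndarray
    rotatable_dihedrals: list = field(default_factory=list)
    atom_names: list = field(default_factory=list)
    residue_names: list = field(default_factory=list)

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        n = self.coordinates.shape[0]
        if self.coordinates.shape != (n, 3):
            raise ShapeError("coordinates must be (n_atoms, 3)")
        for name in ("charge", "lj_re", "lj_eps", "solvation_param", "radius"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (n,):
                raise ShapeError(f"{name} must have length {n}")
            setattr(self, name, arr)
        self.residue_index = np.asarray(self.residue_index, dtype=int)
        self.is_ligand = np.asarray(self.is_ligand, dtype=bool)
        if self.residue_index.shape != (n,) or self.is_ligand.shape != (n,):
            raise ShapeError("residue_index and is_ligand must have length n_atoms")
        if not self.is_ligand.any():
            raise ConfigurationError("complex has no ligand atoms")
        if (self.residue_index[self.is_ligand] != 0).any():
            raise ConfigurationError("ligand atoms must carry residue_index 0")
        prot = self.residue_index[~self.is_ligand]
        if prot.size:
            uniq = np.unique(prot)
            if uniq[0] != 1 or not np.array_equal(uniq, np.arange(1, uniq.size + 1)):
                raise ConfigurationError(
                    "protein residue indices must be contiguous from 1"
                )
        if not np.all(self.lj_re > 0) or not np.all(self.radius > 0):
            raise ParameterError("lj_re and radius must be positive for all atoms")
        if not np.all(self.lj_eps >= 0):
            raise ParameterError("lj_eps must be non-negative for all atoms")
        for dih in self.rotatable_dihedrals:
            if len(dih) != 4 or any(not (0 <= i < n) for i in dih):
                raise ConfigurationError(f"bad dihedral tuple {dih!r}")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]

    @property
    def residue_count(self) -> int:
        prot = self.residue_index[~self.is_ligand]
        return int(prot.max()) if prot.size else 0

    @property
    def ligand_atom_ids(self) -> np.ndarray:
        return np.flatnonzero(self.is_ligand)

    @property
    def protein_atom_ids(self) -> np.ndarray:
        return np.flatnonzero(~self.is_ligand)

    def atom(self, i: int) -> AtomParams:
        """Return a single-atom :class:`AtomParams` view."""
        return AtomParams(
            atom_id=i,
            residue_index=int(self.residue_index[i]),
            is_ligand=bool(self.is_ligand[i]),
            charge=float(self.charge[i]),
            lj_re=float(self.lj_re[i]),
            lj_eps=float(self.lj_eps[i]),
            solvation_param=float(self.solvation_param[i]),
            radius=float(self.radius[i]),
        )


def combine_pair_params(a: AtomParams, b: AtomParams) -> tuple[float, float]:
    """Lorentz-Berthelot combination of two atoms' LJ parameters.

    Returns the pair equilibrium distance ``Re_ij = Rmin/2(a) + Rmin/2(b)``
    and the geometric-mean well depth ``eps_ij = sqrt(eps_a * eps_b)``.
    """
    for atom in (a, b):
        if not (np.isfinite(atom.lj_re) and np.isfinite(atom.lj_eps)):
            raise ParameterError(f"non-finite LJ parameters for atom {atom.atom_id}")
        if atom.lj_re <= 0:
            raise ParameterError(f"lj_re must be > 0 (atom {atom.atom_id})")
    return a.lj_re + b.lj_re, float(np.sqrt(a.lj_eps * b.lj_eps))


def lj_energy(r, Re, eps, form: str = "12-6"):
    """Generalized Lennard-Jones n-m energy, kcal/mol.

    ``E(r) = eps/(n-m) * [m*(Re/r)^n - n*(Re/r)^m]`` normalized so the
    minimum is exactly ``-eps`` at ``r = Re`` for every supported (n, m).
    Accepts scalars or arrays (broadcast).
    """
    n, m = _resolve_form(form)
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DomainError("interatomic distance must be > 0")
    Re = np.asarray(Re, dtype=float)
    eps = np.asarray(eps, dtype=float)
    if np.any(Re <= 0):
        raise DomainError("equilibrium distance must be > 0")
    if np.any(eps < 0):
        raise ParameterError("well depth must be >= 0")
    q = Re / r
    out = eps / (n - m) * (m * q**n - n * q**m)
    return out if out.ndim else float(out)


def coulomb_pair_energy(q1, q2, r, eps_scale=1.0):
    """Coulomb energy of a charge pair, kcal/mol.

    ``k * q1 * q2 / (eps_scale * r)`` with k = 332.0637 kcal*A/(mol*e^2);
    ``eps_scale`` is a dimensionless effective-dielectric divisor.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise DomainError("interatomic distance must be > 0")
    eps_scale = np.asarray(eps_scale, dtype=float)
    if np.any(eps_scale <= 0):
        raise DomainError("eps_scale must be > 0")
    out = COULOMB_CONSTANT * np.asarray(q1, float) * np.asarray(q2, float) / (
        eps_scale * r
    )
    return out if out.ndim else float(out)


def residue_ligand_energies(
    system: ComplexSystem,
    conformation: np.ndarray | None = None,
    form: str = "12-6",
    cutoff: float | None = None,
    eps_map: np.ndarray | None = None,
):
    """Per-residue protein-ligand vdW and electrostatic energies.

    For each protein residue i, sums the pairwise LJ and Coulomb energies
    over all (protein atom in residue i, ligand atom) pairs of the given
    conformation (default: the reference coordinates). No distance cutoff
    is applied unless ``cutoff`` is given.

    Parameters
    ----------
    eps_map : array, optional
        Per-protein-atom effective dielectric divisors (length = number of
        protein atoms, ordered as ``system.protein_atom_ids``) applied to
        every Coulomb pair term of that atom.

    Returns
    -------
    (e_vdw, e_ele) : two arrays of length ``system.residue_count``;
        entry ``i-1`` holds residue i.
    """
    coords = system.coordinates if conformation is None else np.asarray(
        conformation, dtype=float
    )
    if coords.shape != (system.n_atoms, 3):
        raise ShapeError(
            f"conformation shape {coords.shape} does not match "
            f"({system.n_atoms}, 3)"
        )
    lig = system.ligand_atom_ids
    prot = system.protein_atom_ids
    if lig.size == 0:
        raise ConfigurationError("complex has no ligand atoms")
    n_res = system.residue_count
    e_vdw = np.zeros(n_res)
    e_ele = np.zeros(n_res)
    if n_res == 0:
        return e_vdw, e_ele

    d = coords[prot, None, :] - coords[None, lig, :]
    r = np.sqrt((d * d).sum(axis=2))
    if np.any(r <= 0):
        raise DomainError("coincident protein and ligand atoms (r = 0)")

    Re = system.lj_re[prot, None] + system.lj_re[None, lig]
    eps = np.sqrt(system.lj_eps[prot, None] * system.lj_eps[None, lig])
    n, m = _resolve_form(form)
    q = Re / r
    e_pair_vdw = eps / (n - m) * (m * q**n - n * q**m)

    qq = system.charge[prot, None] * system.charge[None, lig]
    e_pair_ele = COULOMB_CONSTANT * qq / r
    if eps_map is not None:
        eps_map = np.asarray(eps_map, dtype=float)
        if eps_map.shape != (prot.size,):
            raise ShapeError(
                f"eps_map length {eps_map.shape} does not match "
                f"{prot.size} protein atoms"
            )
        e_pair_ele = e_pair_ele / eps_map[:, None]

    if cutoff is not None:
        mask = r <= cutoff
        e_pair_vdw = np.where(mask, e_pair_vdw, 0.0)
        e_pair_ele = np.where(mask, e_pair_ele, 0.0)

    res_of_prot = system.residue_index[prot] - 1
    np.add.at(e_vdw, res_of_prot, e_pair_vdw.sum(axis=1))
    np.add.at(e_ele, res_of_prot, e_pair_ele.sum(axis=1))
    return e_vdw, e_ele
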