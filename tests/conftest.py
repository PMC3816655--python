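import numpy as np
import pytest

from diabind import ComplexSystem, EnsembleFrames, ToySpec, make_toy_complex


@pytest.fixture
def two_residue_system():
    """Hand-built 2-residue / 2-ligand-atom complex with printed values."""
    return ComplexSystem(
        coordinates=np.array([
            [0.0, 0.0, 0.0],   # ligand L1
            [1.8, 0.0, 0.0],   # ligand L2
            [4.0, 0.0, 0.0],   # residue 1 atom
            [0.0, 4.5, 0.0],   # residue 1 atom
            [0.0, 0.0, 5.0],   # residue 2 atom
        ]),
        charge=np.array([0.30, -0.20, 0.40, -0.10, 0.25]),
        lj_re=np.array([1.7, 1.5, 1.9, 1.8, 1.6]),
        lj_eps=np.array([0.09, 0.04, 0.12, 0.06, 0.10]),
        solvation_param=np.array([0.01, 0.02, -0.01, 0.015, 0.005]),
        radius=np.array([1.7, 1.5, 1.9, 1.8, 1.6]),
        residue_index=np.array([0, 0, 1, 1, 2]),
        is_ligand=np.array([True, True, False, False, False]),
    )


@pytest.fixture
def toy():
    spec = ToySpec(seed=11, n_frames=12)
    system, frames, forces = make_toy_complex(spec)
    return spec, system, frames, forces


@pytest.fixture
def rigid_toy():
    spec = ToySpec(seed=7, n_frames=6, positional_jitter=0.0)
    system, frames, forces = make_toy_complex(spec)
    return spec, system, frames, forces


def brute_force_residue_energies(system, coords, form):
    """Independent O(N^2) pure-Python oracle for per-residue energies."""
    from diabind import combine_pair_params, coulomb_pair_energy, lj_energy

    n_res = system.residue_count
    e_vdw, e_ele = [0.0] * n_res, [0.0] * n_res
    for i in range(system.n_atoms):
        if system.is_ligand[i]:
            continue
        for j in range(system.n_atoms):
            if not system.is_ligand[j]:
                continue
            r = float(np.linalg.norm(coords[i] - coords[j]))
            Re, eps = combine_pair_params(system.atom(i), system.atom(j))
            k = system.residue_index[i] - 1
            e_vdw[k] += lj_energy(r, Re, eps, form)
            e_ele[k] += coulomb_pair_energy(
                system.charge[i], system.charge[j], r
            )
    return np.array(e_vdw), np.array(e_ele)
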