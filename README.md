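# diabind

Statistical estimation of protein–ligand binding free energies (ΔG) from
the *direct* protein–ligand interaction sampled by a molecular-dynamics
ensemble — no simulation of the free ligand in solvent, no per-target
retraining.

`diabind` is aimed at structure-based drug-design work where a complex
structure and a conformational ensemble of it are available and a fast,
transferable ΔG estimate is needed, e.g. for rescoring docking poses.

## The model

For each protein residue *i*, the ensemble gives the mean van der Waals
and electrostatic interaction energies with the ligand, E<sup>vdW</sup>(i)
and E<sup>ele</sup>(i), together with their fluctuations (population
standard deviations over frames) S<sub>vdW</sub>(i) and S<sub>ele</sub>(i).
The **DIAV** (direct interaction approximation *in vacuo* electrostatics)
model is linear in five parameters:

ΔG = α Σ<sub>i</sub> E<sup>vdW</sup>(i) + α₂ Σ<sub>i</sub> S<sub>vdW</sub>(i)
   + β Σ<sub>i</sub> E<sup>ele</sup>(i) + β₂ Σ<sub>i</sub> S<sub>ele</sub>(i)
   + τ S<sub>x</sub>

where S<sub>x</sub> is a fluctuation "entropy" descriptor of a property
*x* of the complex: the total accessible surface area (x = ASA, computed
by Shrake–Rupley), the rotatable dihedral angles (x = DIH, circular
statistics), or the total vdW/electrostatic energy. The **DIAS** variant
(direct interaction approximation with solvent) replaces each Coulomb
term by a screened one: every protein atom carries an effective
dielectric constant ε<sub>eff</sub> ≥ 1 estimated from the ratio of the
electrostatic force on that atom with and without explicit solvent,
regularized by a parameter *x* so the ratio stays finite where the
solvated force vanishes. The vdW term uses a generalized Lennard-Jones
n–m function — 12-6, 9-6, 8-4 or 6-3 — normalized so the well depth is
exactly −ε at the equilibrium distance R<sub>e</sub>; the soft 8-4 form
is the default. Parameters are fitted by ordinary least squares against
experimental ΔG and assessed by leave-one-out cross-validation (mean
absolute error and Pearson r over held-out predictions).

The package ships the 34-complex benchmark table (experimental ΔG plus
the published cross-validated predictions of all three model variants)
and a deterministic synthetic-fixture generator (toy complexes,
pseudo-trajectories, fabricated solvated/vacuum force pairs, and feature
datasets with known generating parameters).

## Worked example

```sh
python examples/03_benchmark_table.py
```

```
34 complexes, e.g. 1abe, 1abf, 1apu, 1dbb, ...

simple: MAE = 1.907 kcal/mol, Pearson r = 0.730
DIAV : MAE = 1.350 kcal/mol, Pearson r = 0.807
DIAS : MAE = 1.227 kcal/mol, Pearson r = 0.811
```

Each line scores one prediction column of the benchmark against the
experimental ΔG values: adding the fluctuation terms (DIAV) cuts the
error from ~1.9 to ~1.35 kcal/mol, and screening the electrostatics with
the effective dielectric (DIAS) reaches ~1.2 kcal/mol with r ≈ 0.81.

The other examples walk the remaining capabilities end to end:
`01_toy_pipeline.py` (toy ensemble → effective dielectric → features),
`02_fit_and_crossvalidate.py` (least-squares fit + leave-one-out CV on
synthetic features, recovering the generating coefficients), and
`04_pose_ranking.py` (ΔG-based pose selection and RMSD success rates).
A thin CLI wraps the same operations:

```sh
diabind simulate --seed 5 --out-dir sim/
diabind extract --structure sim/complex.pdb --trajectory sim/trajectory.pdb \
    --params sim/params.tsv --forces sim/forces.tsv \
    --dihedrals sim/dihedrals.json --vdw-form 8-4 --out features.json
diabind benchmark-table4
```

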