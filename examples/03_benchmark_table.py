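"""Score the packaged 34-complex benchmark predictions against experiment.

The packaged table carries, for each complex, the experimental binding
free energy and the cross-validated predictions of the simple two-term
model, the DIAV model (adds fluctuation terms) and the DIAS model (adds
dielectric-scaled electrostatics). The DIAS column should give a mean
absolute error near 1.2 kcal/mol and a Pearson correlation near 0.81.
"""

from diabind import metrics, table4_fixture

df = table4_fixture()
print(f"{len(df)} complexes, e.g. {', '.join(df['pdb_id'].head(4))}, ...\n")
expt = df["dg_exptl"].to_numpy()
for col, label in (("dg_simple", "simple"), ("dg_diav", "DIAV "),
                   ("dg_dias", "DIAS ")):
    mae, r = metrics(df[col].to_numpy(), expt)
    print(f"{label}: MAE = {mae:.3f} kcal/mol, Pearson r = {r:.3f}")
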