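# pubertwin

Longitudinal twin modelling of pubertal hormone levels and voxel-wise grey
matter density.

## The problem

In a cohort of monozygotic (MZ) and dizygotic (DZ) twins assessed around
ages 9 and 12 — urinary gonadotropin/estradiol and salivary testosterone
levels plus voxel-based-morphometry grey-matter density maps — one wants to
know whether *changes* in a hormone track *changes* in grey matter density,
whether hormone and density are associated at the second occasion, and
whether any such association is transmitted by genes, by the environment
shared within a family, or by environment unique to the individual.  Twin
data answer the last question: cross-twin cross-trait correlations that are
larger in MZ than DZ pairs point to genetic overlap; correlations present
only within persons point to unique-environment overlap.

`pubertwin` is for biostatisticians and imaging-genetics researchers who
want that full pipeline — a 4-phenotype correlated-factor ACE structural
model with full-information maximum likelihood (FIML), latent-change
algebra, constrained refits and likelihood-ratio tests, run per voxel with
false-discovery-rate control — as a tested Python library with a synthetic
cohort generator providing known ground truth.

## The model

Each phenotype (hormone at 9, density at 9, hormone at 12, density at 12)
is `x_i = mu_i + a_i A_i + c_i C_i + e_i E_i` with unit-variance latent
factors; same-kind factors correlate across phenotypes within a person
(`R_g`, `R_c`, `R_e`) and across co-twins (A: 1 in MZ / 0.5 in DZ; C: 1;
E: 0).  Writing Cov(i,j) = a_i r_g(i,j) a_j + c_i r_c(i,j) c_j +
e_i r_e(i,j) e_j, the latent-change quantities are

    V_chGM = Var(2) + Var(4) − 2 Cov(2,4)
    V_chH  = Var(1) + Var(3) − 2 Cov(1,3)
    Cov_ch = Cov(3,4) + Cov(1,2) − Cov(1,4) − Cov(2,3)
    r_ch   = Cov_ch / sqrt(V_chGM V_chH) = rph_a + rph_c + rph_e

where rph-a keeps only the genetic terms of the numerator (rph-c, rph-e
likewise) — the correlation that would be observed if only that factor kind
linked the traits.  Hypotheses (`r_ch = 0`; `Cov(3,4) = 0`; single rph
components zero) are tested by refitting under the equality constraint and
referring `−2 Δ log L` to chi-square with 1 df.  See `docs/methods.md` for
estimation details.

## Worked example

```python
import numpy as np
import pubertwin as pt

# ground truth: FSH-like hormone, heritable density, and a pure
# unique-environment coupling that makes the latent changes correlate 0.5
truth = pt.plant_coupling(pt.default_path_model(), "e", r_target=0.5)

# simulate 300 MZ + 300 DZ pairs with 34% follow-up dropout and fit
rng = np.random.default_rng(1)
y = np.vstack([pt.draw_pair_phenotypes(truth, "MZ", 300, rng),
               pt.draw_pair_phenotypes(truth, "DZ", 300, rng)])
drop = rng.random((600, 2)) < 0.34
for t in range(2):
    y[drop[:, t], 4 * t + 2] = np.nan   # hormone, age 12
    y[drop[:, t], 4 * t + 3] = np.nan   # density, age 12
data = pt.FamilyData(y, np.array(["MZ"] * 300 + ["DZ"] * 300))

model = pt.TwinACEModel(data)
full = model.fit(n_starts=2, seed=0)
print(full.summary())
null = model.fit(constraint="change_corr_zero", n_starts=1, seed=0,
                 start_model=full.path_model)
print(pt.lrt(full, null))
```

prints

```
Twin ACE model (FIML)
================================================================
families: 600   observed values: 3968
log-likelihood: 875.6417   free parameters: 34
converged: True
----------------------------------------------------------------
phenotype            mean      a2      c2      e2  total var
hormone_age9       -0.769   0.572   0.016   0.412     0.3077
density_age9        0.595   0.445   0.219   0.335     0.0097
hormone_age12      -0.119   0.460   0.198   0.342     0.2948
density_age12       0.546   0.533   0.166   0.301     0.0111
----------------------------------------------------------------
change correlation r_ch = 0.4538 (rph-a -0.0914, rph-c 0.0681, rph-e 0.4771)
chi2(1) = 152.5574, p = 4.786e-35
```

The fit recovers the generating variance fractions (true a²/c²/e² are
0.5/0.1/0.4 for the hormone and 0.5/0.15/0.35 for density; the a²/c² split
is the noisiest direction at this sample size), estimates the change
correlation at 0.45 against a generating value of 0.5 and attributes
essentially all of it to the unique-environment path (rph-e ≈ 0.48), and
the likelihood-ratio test rejects a zero change correlation decisively.

The same machinery runs per voxel from the shell:

```bash
pubertwin simulate --config sim.yaml --seed 5 --out cohort/
pubertwin prep --cohort cohort/cohort.csv --out prepped.csv
pubertwin scan --cohort cohort/cohort.csv --hypothesis change_corr \
               --alpha 0.05 --seed 2 --out maps/
pubertwin report --cohort cohort/cohort.csv --seed 2 --out report.json
```

`scan` writes NIfTI maps of r_ch, chi-square, −log10 p, the rph components
and the FDR significance mask plus a JSON sidecar (number of rejections,
critical p and the corresponding critical chi-square); `report` adds the
within-significant-voxels component attribution.

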