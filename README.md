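# permweight

Proton-coupled weighted-ensemble membrane permeation at desk scale.

Weakly basic drugs (opioids such as fentanyl, morphine, isotonitazene and
naloxone have solution pKa's of 7.9–8.7) are mostly protonated and charged
at physiological pH 7.5, yet they cross lipid bilayers — they first
partition into the membrane in the charged form, deprotonate as the local
pKa drops toward the hydrophobic core, and only the neutral form crosses.
Sampling such coupled titration/permeation events in molecular dynamics
requires rare-event machinery: the weighted-ensemble (WE) method evolves
many weighted replicas ("walkers") binned along the permeant's z-position,
splitting and merging them to a per-bin target count so that unbiased
steady-state kinetics can be harvested from vanishingly improbable
crossing events.

`permweight` reimplements that methodology end-to-end at desk scale for
method development, teaching and protocol prototyping.  The all-atom
force evaluation is replaced by a titration-coupled 1-D Brownian permeant
model; everything downstream — the WE protocol, the flux-based
permeability/MFPT estimators, the z-resolved profiling and the assay
post-processing — is the real machinery.

## What's inside

| module | contents |
| --- | --- |
| `permweight.titration` | λ = sin²θ titration coordinate; thermodynamic-integration fit of the quadratic λ-PMF `U(λ) = A(λ−B)²`; generalized Henderson–Hasselbalch (Hill) fitting; state classification at the λ < 0.2 / λ > 0.8 thresholds |
| `permweight.landscape` | the synthetic permeant: state-dependent free-energy landscape `G(z, state)`, z-dependent pKa, coupled Euler–Maruyama/titration dynamics, per-walker observable generators, named presets |
| `permweight.we` | bin schemes (5 Å solvent / 0.5 Å membrane spacing, dynamic interface bins), split/merge resampling to a target count of 4, steady-state recycling at z > 55 Å / z < −25 Å, lineage tracking, HDF5 run store |
| `permweight.flux` | `Pm = f_ex→in · ld` and `MFPT = p_ext / f_ex→in` with 95% intervals (ld = 22.5 Å), Welch t-test run comparison, in-bilayer deprotonation rate |
| `permweight.profiles` | weighted free-energy profiles `F(z) = −kT ln p(z)`, symmetrization, deprotonation fraction, observable means, region-resolved orientational free energy |
| `permweight.assays` | IAM-HPLC chromatographic hydrophobicity index (CHI) calibration with the r > 0.99 validity gate and the ±5 suitability check; vehicle-corrected BRET ratios |
| `permweight.experiment` / CLI | two-trial multi-preset experiment orchestration with reports |

## Worked example

```python
import permweight as pw

land = pw.make_scaled_presets()["fentanyl"]      # 3 kcal/mol barrier, pKa 8.4
records = pw.run_weighted_ensemble(land, n_iterations=600, tau=100.0,
                                   pH=7.5, seed=1)
flux = pw.flux_series(records)                   # 1/s, per iteration
est = pw.estimate(flux, ld=22.5, p_ext=pw.p_ext_from_lineage(records),
                  window=300)
print(f"log10 Pm = {est.log10_Pm:.2f}  MFPT = {est.MFPT:.2e} s")
```

prints

```
log10 Pm = -3.43  MFPT = 6.05e-04 s
```

meaning the toy permeant crosses with an effective permeability of
~3.7×10⁻⁴ cm/s and a mean first passage time of about 0.6 ms under these
scaled-down conditions (the two numbers satisfy `Pm × MFPT = 22.5 Å`
exactly, the algebraic identity of the flux relations).  The same run
yields z-profiles:

```python
prof = pw.symmetrize(pw.weighted_pmf(records, bin_width=0.5, window=300))
dep  = pw.symmetrize(pw.deprotonation_profile(records, bin_width=0.5, window=300))
```

with the free-energy maximum at the bilayer center and the deprotonated
fraction rising from ~0.11 in bulk (the Henderson–Hasselbalch value at
pH 7.5 for pKa 8.4) to 1 before the core.

The same workflow is available from the shell:

```bash
permweight presets --list
permweight run --config cfg.yaml --out run.h5
permweight analyze --run run.h5 --ld 22.5 --window 50
permweight compare runA.h5 runB.h5
permweight profiles --run run.h5 --bin-width 0.5 --out profiles.csv
permweight experiment --config experiment.yaml --out report.json
permweight chi --calibrants cal.csv --samples samples.csv
permweight bret --trace trace.csv --vehicle vehicle.csv
```

## Scope

No atoms, force fields or trajectory files are involved: hydration,
H-bond, contact, thickness and orientation channels are generated
synthetically with the qualitative z-dependence of permeants in a
bilayer, so the profiling machinery can be exercised end-to-end.  See
`docs/methods.md` for the model, its assumptions and its limitations.
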