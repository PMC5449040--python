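# coilpress

Random-coil backbone-amide pressure-shift reference and correction
toolkit for high-pressure NMR.

Applying pressure shifts conformational equilibria in proteins, and
chemical shifts track those changes very precisely — but part of every
observed shift change is a trivial, sequence-independent "random coil"
response that occurs in unstructured peptides too. `coilpress` bundles
a validated reference of backbone amide ¹⁵N and ¹H pressure
coefficients for the 20 canonical residues (measured in model
tetrapeptides over 0.1–200 MPa at 283 K), the models needed to use
them, and a pipeline that subtracts the random-coil response from
protein data so that only structurally meaningful pressure effects
remain.

## What's inside

| Module | Contents |
| --- | --- |
| `coilpress.reference` | Embedded coefficient tables (22 ¹⁵N rows incl. His pH 4.0/8.5 and cis/trans Pro; 19 ¹H rows), validated at load, queryable, CSV/JSON import–export |
| `coilpress.model` | Quadratic pressure-shift model δ(p) = δ₀ + B₁Δp + B₂Δp²; multistate Boltzmann ensemble with pressure-dependent free energy G(p) = G⁰ + V⁰Δp + ½β⁰Δp²; analytic Taylor coefficients of the ensemble shift; fast-exchange criterion |
| `coilpress.fitting` | Closed-form quadratic least squares with standard errors; multistart two-state thermodynamic fit with non-identifiability (F-test) flagging |
| `coilpress.correction` | Per-residue track fitting, reference subtraction, z-scored flagging of anomalous pressure responses |
| `coilpress.simulate` | Seeded synthetic titration generator (quadratic or ensemble truth, Gaussian reading noise at 0.01/0.001 ppm for ¹⁵N/¹H) |
| `coilpress.cli` | `coilpress predict / fit / correct / simulate / reference` |

Units: pressures in MPa, shifts in ppm, B₁ in ppm/GPa, B₂ in ppm/GPa²,
free energies in J/mol, volumes in mL/mol, compressibility factors in
mL/(mol·MPa) — chosen so the Boltzmann exponent needs no conversion
constants (1 mL·MPa = 1 J).

## Quick start

```python
import coilpress as cp

# reference lookups
cp.get_entry("Gly", "N15").B1            # 3.79 ppm/GPa
cp.table_mean("N15", 1)                  # 2.905909... -> 2.91 at 2 d.p.

# predict the random-coil shift of Gly 15N at 200 MPa
cp.predict_shift(cp.get_entry("Gly", "N15").coefficients, 200.0)  # 109.8913 ppm

# fit a measured series
series = cp.PressureSeries(pressures=[0.1, 50, 100, 150, 200],
                           shifts=[8.40, 8.42, 8.44, 8.45, 8.46])
fit = cp.fit_quadratic(series)
fit.coefficients.B1, fit.coefficients.B1_err

# correct protein tracks against the random-coil reference
results = cp.correct_tracks(tracks, threshold=2.0)
flagged = [r for r in results if r.flagged]
```

Command line:

```sh
coilpress predict --entry Gly:N15 --pressure 200        # 109.8913 ppm
coilpress reference show Ala
coilpress reference export --format csv --out ref.csv
coilpress simulate --entry Ala:N15 --seed 7 --out series.csv
coilpress fit --series series.csv --model quadratic
coilpress correct --tracks tracks.csv --threshold 2.0 --out results.csv
```

Track files are plain CSV with columns
`residue_id,residue_type,nucleus,pressure_MPa,shift_ppm` (optional
`variant` column for His pH forms / Pro isomers); series files use
`pressure_MPa,shift_ppm`.

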