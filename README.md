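# rsmval

Response-surface optimisation and 2002/657/EC method-validation statistics
for multi-residue LC-MS/MS methods.

## The problem

When a QuEChERS clean-up for a large drug panel is optimised, the tunable
quantities are the masses of the dispersive-SPE sorbents (here C18, PSA and
Z-Sep+), and the quantity worth maximising is not a single peak area but the
**number of analytes that pass the recovery acceptance window** (80–110 %
mean recovery) at the spike level. `rsmval` implements the complete
computational chain for that workflow, aimed at analytical chemists running
design-of-experiments method development and EU 2002/657/EC validation:

1. **Design** — the three-factor Box–Behnken design (12 edge runs plus
   replicated centres) with coded ↔ actual (mg) level mapping.
2. **Model** — the full second-order surface
   `Y = b0 + Σ bᵢxᵢ + Σ bᵢⱼxᵢxⱼ + Σ bᵢᵢxᵢ²` fitted by ordinary least
   squares, with the classical DoE ANOVA: per-term Type-III sums of squares
   `βⱼ²/[(XᵀX)⁻¹]ⱼⱼ`, residual split into lack-of-fit and pure error
   (from the centre replicates), significance flags, and the adequacy family
   R², adjusted R², PRESS / predicted R², adequate precision.
3. **Optimisation** — exact maximisation of the quadratic over the coded
   cube by stationary-point analysis and recursive face restriction, plus a
   confirmation-run check (mean, RSD %, deviation from prediction).
4. **Validation** — the 2002/657/EC metrics: compliant-analyte count,
   decision limit CCα `= 0.2·VL + 1.64·SD` and detection capability
   CCβ `= CCα + 1.64·SD` from the replicate SD at the 0.2 × VL spike,
   matrix effect `ME = (S_mat/S_sol − 1)·100` with strength classification,
   LOQ at signal-to-noise 10, recovery and intra-/inter-day precision.
5. **Simulation** — a seeded generator of spiked-recovery experiments with
   known per-analyte recovery surfaces, calibration slopes and noise, so the
   whole pipeline is testable end to end; plus the construction of response
   vectors exactly consistent with a published regression equation and its
   aggregate error components.

The shipped reference data are the published summaries of a 43-drug
(quinolones + sulfonamides) bacon/ham study: the fitted count surface, its
error sums of squares and the per-compound CCα/CCβ/LOQ table.

## Worked example

Rebuild the published ANOVA and optimum from the regression equation and the
aggregate error components alone:

```python
from rsmval import ResponseSurfaceResults
from rsmval.datasets import reference_design, reference_error_ss, reference_surface

design = reference_design()                  # BBD(3) + 5 centres, 17 runs
model = reference_surface()                  # Y = 41.80 - 0.50A - ... - 2.90C^2
results = ResponseSurfaceResults.from_aggregates(model, design, *reference_error_ss())
print(results.anova().to_string())
adq = results.adequacy()
print(f"R2 = {adq.r2:.4f}   adj-R2 = {adq.adj_r2:.4f}   "
      f"Adeq precision = {adq.adeq_precision:.3f}")
opt = results.optimize()
print(f"optimum (coded) = {opt.coded.round(4)}")
print(f"predicted response = {opt.predicted_response:.2f} "
      f"-> predicted count = {opt.predicted_count}")
```

prints

```
       term     ss  df     ms      F p_value flag
      Model 737.76   9  81.97  50.78 <0.0001   **
          A   2.00   1   2.00   1.24  0.3024
          B  18.00   1  18.00  11.15  0.0124    *
          C  60.50   1  60.50  37.48  0.0005   **
         AB   1.00   1   1.00   0.62  0.4571
         AC   4.00   1   4.00   2.48  0.1595
         BC   0.00   1   0.00   0.00  1.0000
         A2 262.78   1 262.78 162.78 <0.0001   **
         B2 297.09   1 297.09 184.04 <0.0001   **
         C2  35.41   1  35.41  21.94  0.0023   **
   Residual  11.30   7   1.61
Lack of fit   8.50   3   2.83   4.05  0.1051
 Pure error   2.80   4   0.70
  Cor total 749.06  16

R2 = 0.9849   adj-R2 = 0.9655   Adeq precision = 19.293
optimum (coded) = [-0.0595 -0.0875 -0.4844]
predicted response = 42.55 -> predicted count = 42
```

Reading it: the surface is dominated by the quadratic terms (strong
curvature in all three sorbent masses), Z-Sep+ (C) is the strongest linear
effect, the lack-of-fit test is insignificant (p = 0.105, the quadratic is
adequate), and the surface peaks *inside* the design region at a predicted
42.55 compliant drugs — truncated to 42 whole drugs — slightly below the
centre level of Z-Sep+.

A full synthetic pipeline run (design → simulate → fit → ANOVA → optimise →
validate) is available from the shell:

```bash
rsmval run --config config.yaml --seed 1 --out-dir out/
```

where `config.yaml` holds the factor mass ranges, centre count, validation
level and compliance window (see `tests/test_pipeline_cli.py` for a complete
example).

## Layout

| module | contents |
| --- | --- |
| `rsmval.design` | `FactorSpec`, `DesignTable`, `generate_bbd`, coded↔actual mapping |
| `rsmval.model` | `ResponseSurfaceModel` → `ResponseSurfaceResults`: fit, ANOVA, adequacy, summary |
| `rsmval.optimize` | stationary point, exact cube maximisation, confirmation check |
| `rsmval.validation` | compliant count, CCα/CCβ, matrix effect, LOQ, precision summary |
| `rsmval.simulate` | `SyntheticTruth`, recovery/calibration simulators, consistent-response construction |
| `rsmval.pipeline` / `rsmval.cli` | delimited formats, YAML config, staged runner, `rsmval` command |
| `rsmval.datasets` | published reference surface, error components, CCα/CCβ/LOQ table |

See `docs/methods.md` for the statistical details and design choices.
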