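# fmisopk

Dynamic ¹⁸F-FMISO PET pharmacokinetics for tumor hypoxia quantification:
two-tissue compartment modeling, time-activity-curve (TAC) fitting,
Gjedde-Patlak graphical analysis, voxelwise Ki/k3 parametric mapping, and
static tumor-to-blood hypoxia scoring — plus a synthetic-data generator
(input functions, TACs, 4D digital phantoms) so every stage is testable
without scan data.

## Who this is for

Researchers analyzing dynamic PET of hypoxia tracers in small animals (or
building analysis methodology for it). ¹⁸F-FMISO is reduced and retained in
viable hypoxic cells; a single static uptake image mixes that specific
retention with blood-borne background and perfusion effects, while dynamic
imaging plus kinetic modeling separates them.

## The model

Tissue kinetics follow the two-tissue compartment model

    dC_d/dt = K1·C_p − (k2 + k3)·C_d + k4·C_a
    dC_a/dt = k3·C_d − k4·C_a            (k4 = 0: irreversible variant)

with plasma input C_p (an image-derived left-ventricle curve), diffusive
pool C_d and trapped pool C_a. The measured ROI signal is the weighted sum
C_ROI = w_p·C_p + w_d·C_d + w_a·C_a with w_p + w_d + w_a = 1. Key outputs:

* **k3** (1/min) — the hypoxia-specific trapping rate;
* **Ki = K1·k3/(k2+k3)** (mL/g/min) — net influx of trapped tracer, also
  the late-time slope of the Patlak plot y = C_t/C_p vs x = ∫C_p/C_p;
* **ε** (%) — residual-percentage goodness of fit
  (100·mean|resid|/max(TAC); fits below 5% are accepted);
* **T/B** — static tumor-to-blood uptake ratio; above 1.2 scores hypoxic.

The compartment solver is exact for piecewise-linear C_p (per-segment
exponential-convolution closed form — no ODE step size), fitting is bounded
trust-region least squares, and maps are produced per voxel with validity
masks. See `docs/methods.md` for conventions, an identifiability analysis
of the weighted model, and known estimator behavior.

## Worked example

Simulate a noisy 2 h / 52-frame tumor TAC for an intrinsically hypoxic
tumor 1 h after an oxygen-consuming therapy, then fit both model variants
(`examples/fit_two_tissue.py`):

```text
        truth   irreversible fit
  K1   0.02550    0.02451
  k2   0.00286    0.00125
  k3   0.03314    0.03191
 w_p   0.05000    0.05070

epsilon: irreversible 0.70%  reversible 0.69%  (accepted below 5%)
fitted k4 (reversible model): 1.53e-02 1/min
```

The trapping rate k3 is recovered within ~4% at whole-ROI noise levels; ε
is far below the 5% acceptance bound; and the reversible model buys
essentially no residual, its k4 sitting at the noise floor — the
irreversible model is the right description of this tracer.

The other examples each exercise one capability and print a short
interpretation:

| script | capability |
|---|---|
| `examples/macro_influx_rates.py` | Ki from micro-parameters for all tissue presets |
| `examples/patlak_analysis.py` | Patlak slope vs compartmental Ki (agreement ≤ 5%) |
| `examples/static_hypoxia_score.py` | T/B scoring of static uptake |
| `examples/phantom_parametric_maps.py` | 32³ phantom, voxelwise Ki/k3 maps, overlap and contrast |

A thin CLI wraps the same library for shell use:
`fmisopk simulate|fit|patlak|roi|map` (each run writes a JSON provenance
record; see `fmisopk --help`).

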