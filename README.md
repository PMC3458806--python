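# frapmc

Monte Carlo simulation and grid least-squares analysis of strip-FRAP
(fluorescence recovery after photobleaching) experiments on nuclear
proteins.

## The problem

FRAP on GFP-tagged transcription factors encodes protein–chromatin
binding kinetics: a narrow strip across the nucleus is photobleached and
the speed and completeness of fluorescence recovery reflect how much of
the protein diffuses freely, how much is transiently or stably bound,
and for how long. Extracting numbers from such curves requires a forward
model. `frapmc` implements the classic particle-based one: molecules
diffuse with coefficient `D` inside an ellipsoidal nucleus and exchange
with two classes of immobile binding sites, class *i* holding an
equilibrium fraction `f_i` with mean residence time `T_i` (release rate
`k_off,i = 1/T_i`, binding rate at equilibrium `(f_i/f0)/T_i`). The five
mobility parameters `(D, f1, T1, f2, T2)` are inferred by simulating a
library of normalized recovery curves over a parameter grid
(`D ∈ [0.04, 25] µm²/s`, `f1 + f2 ≤ 0.9`, `T ∈ [0.1, 300] s`) and
picking the best-fitting curve by ordinary least squares over the
post-bleach scans.

The package is for quantitative cell biologists who want to fit their
own strip-FRAP data against this model, and for methods work on what
such fits can and cannot identify: a synthetic-data generator emulates
full multi-cell acquisitions (shot and detector noise, background,
expression spread, nucleus-size jitter) with known ground truth, so the
whole pipeline is testable end to end.

## Worked example

Simulate the TEL-repressor kinetics (57% bound for 0.63 s, 20% bound
for 59 s, remainder diffusing at 3 µm²/s) through the standard protocol
— 1000 scans of 21 ms, a 3-iteration strip bleach after scan 100:

```python
from frapmc import (AcquisitionProtocol, BleachProfile, NucleusGeometry,
                    MobilityParams, simulate_frap)

curve = simulate_frap(
    NucleusGeometry(),                       # 6 x 4 x 2.5 um semi-axes
    MobilityParams(D=3.0, f1=0.57, T1=0.63, f2=0.20, T2=59.0),
    AcquisitionProtocol(),                   # 1000 x 21 ms, bleach @ 100
    BleachProfile(),                         # deep strip bleach
    n_particles=100_000, seed=101,
)
print(f"bleach depth    {curve.intensity[100]:.3f}")
print(f"final recovery  {curve.intensity[-100:].mean():.3f}")
```

```
bleach depth    0.075
final recovery  0.700
```

The curve drops to ~8% of the pre-bleach level and plateaus at ~70%:
the 20% long-lived bound pool (59 s ≫ the 19 s observation window) stays
dark, while the free and short-bound pools re-equilibrate. Fitting a
synthetic noisy experiment generated from these same kinetics recovers
them:

```python
from frapmc import ExperimentManifest, generate_experiment
from frapmc.curve_prep import average_curves, normalize_curve
from frapmc.grid_fit import reduced_library, fit_curve, fraction_summary

library, protocol = reduced_library(seed=1000)       # 4772-node grid
experiment = generate_experiment(
    ExperimentManifest.from_preset("TEL-GFP", root_seed=5001),
    protocol=protocol,
)
fit = fit_curve(
    average_curves([normalize_curve(c) for c in experiment.cells]),
    library,
)
print(fraction_summary(fit, observation_window=protocol.postbleach_window))
```

```
{'free_pct': 20.0, 'short_bound_pct': 60.0, 'long_bound_pct': 20.0,
 'short_residence_s': 0.548, 'long_residence_s': 30.0,
 'short_residence_identifiable': True, 'long_residence_identifiable': False}
```

The bound fractions come back within one 5-point grid step of the
generating truth (23/57/20), and the long residence time is correctly
reported as "at least the observation window" rather than a number —
59 s cannot be distinguished from longer times in 19 s of data.

The same pipeline is scriptable from the shell
(`frapmc simulate / normalize / build-library / fit / synth / report`;
see `docs/FORMATS.md` for the file formats).

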