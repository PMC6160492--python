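# lintflux

A quantitative model of belly button lint (navel fluff) production, for
people interested in everyday-physics transport problems: tribologists,
teachers of order-of-magnitude estimation, and anyone who has wondered why
lint keeps turning up in the navel.

## The model

A textile fiber shed by a shirt sits sandwiched between the fabric and the
bed of abdominal hair. Breathing makes the shirt slide back and forth over
the skin once per cycle (period *T* ≈ 6 s). The cuticle scales of body hair
overlap root-to-tip like roof tiles, so the hair–lint kinetic friction
coefficient is directional: μ⁻<sub>H−L</sub> ≈ 2 μ⁺<sub>H−L</sub>. Balancing
the net traction (μ<sub>S−L</sub> − μ<sub>H−L</sub>) F<sub>N</sub> against
Stokes-scale air drag η l U gives unequal phase speeds

U<sup>±</sup> = (μ<sub>S−L</sub> − μ<sup>±</sup><sub>H−L</sub>) F<sub>N</sub> / (η l),  F<sub>N</sub> = p α d l,

and a net ratchet drift toward the navel (abdominal hair points there):

ū = (U⁺ − U⁻)/2 = (μ⁻<sub>H−L</sub> − μ⁺<sub>H−L</sub>) F<sub>N</sub> / (2 η l) ≈ 2.7 × 10⁻⁵ m/s.

The skin pressure p follows from the Laplace relation p = γ/R for a garment
of tension γ on an abdomen of longitudinal radius R. The fiber number
density n(x, t) on the chest-to-navel line then obeys a 1-D advection
equation with a constant production rate A:

∂n/∂t + ū ∂n/∂x = A,  n(x, 0) = n₀(x),

solved by characteristics as n(x, t) = A t + n₀(x − ū t). The navel at
x = L absorbs fibers at rate Ṅ<sub>B</sub> = ū n(L, t), so for a constant
initial level n₀:

N<sub>B</sub>(t) = A ū t²/2 + ū n₀ t  (t < L/ū),  A ū t²/2 + n₀ L  (t ≥ L/ū),

and the lint mass is m<sub>B</sub> = m<sub>L</sub> N<sub>B</sub> with
m<sub>L</sub> = ρ π d² l / 4 per fiber. The long-time prediction,
m<sub>B</sub>(10 h) ∼ 1 mg, matches the order of the reported experimental
daily mean of 1.82 mg.

The analytic law is verified by two independent embodiments: a
finite-volume upwind solver for the general conservation law, and a
stochastic discrete-fiber simulator of the per-breath ratchet kinematics.

## Worked example

```
$ lintflux report
fabric tension gamma                  47 N/m                       exact p*R
drift velocity u_bar                  2.717e-05 m/s                order 1e-05 m/s (floor)
source rate A (one fiber/breath)      1.67 /m/s                    order 1 /m/s (nearest)
fill time L/u_bar                     3680 s = 1.02 hr             rounds to 1 hr
lint mass after 10 hr                 0.622 mg                     order 1 mg (nearest)
initial-population mass at fill time  0.353 ug                     order 0.1 ug (floor)
experimental daily mean (context)     1.82 mg                      reported measurement, not computed
```

Reading the table: a loose shirt at p = 100 Pa on a 0.47 m abdomen carries
47 N/m of tension; the ratchet drifts fibers at ~10⁻⁵ m/s, so the initial
fiber population is swept into the navel within about an hour, after which
the steady shedding of new fibers (about one per breath over the 10 cm
strip) dominates and builds ~1 mg of lint over a waking day. The fibers
present at dressing time contribute only ~0.1 µg — which is why lint color
matches the shirt worn, not the towel used after a shower.

The same numbers are available programmatically:

```python
from lintflux import default_params, mean_velocity, accreted_mass

params = default_params()
print(mean_velocity(params).u_bar)     # 2.717e-05 m/s
print(accreted_mass(36000.0, params))  # 6.227e-07 kg after 10 hours
```

Other entry points: `lintflux forces` (force balance as JSON),
`lintflux predict --t 36000` (count/mass at a time), `lintflux solve`
(finite-volume run, CSV output), `lintflux simulate --cycles 600
--replicates 50 --seed 1` (stochastic ensemble vs the closed form),
`lintflux sweep --param R_at_fixed_gamma --min 0.2 --max 1.0 --steps 9`
(the bigger-belly effect), and `lintflux fixture --kind gaussian -o n0.csv`
(synthetic initial profiles). All accept `--config file.yaml` and
`--set key=value` overrides with units (`--set p="0.2 kPa"`).

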