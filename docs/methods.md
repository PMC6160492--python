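# Methods

## Physical model and assumptions

The package models the transport of shed textile fibers across the hairy
abdominal skin toward the navel. Its chain of reasoning:

1. **Normal force.** Clothing exerts a skin pressure p (~0.1 kPa for loose
   garments). Treating the garment as a membrane of tension γ wrapped on
   the abdominal wall of longitudinal radius R, the Laplace relation
   p = γ/R links the two; γ = p·R ≈ 47 N/m at the defaults. A fiber of
   width d and length l touches the fabric over a real contact area
   A_c = α·d·l (α ≪ 1, roughness-limited), so the interfacial normal force
   is F_N = p·α·d·l ≈ 10⁻¹¹ N.

2. **Ratchet drift.** Hair cuticle scales overlap root-to-tip, making the
   hair–lint kinetic friction directional: μ⁻ (tip-to-root) ≈ 2 μ⁺
   (root-to-tip). During each half of the breathing cycle the shirt drags
   the sandwiched fiber with friction μ_SL·F_N against the hair-side
   resistance μ_HL·F_N; the net traction balances Stokes-scale air drag
   F_D = η·l·U, giving the phase speed U = (μ_SL − μ_HL)·F_N/(η·l). With
   equal phase durations the cycle-averaged drift is
   ū = (U⁺ − U⁻)/2 = (μ⁻ − μ⁺)·F_N/(2ηl). μ_SL cancels from ū but sets
   the individual phase speeds.

   All "~" scaling relations are evaluated as equalities with
   proportionality constant one. Outputs are order-of-magnitude physics:
   the slender-body logarithmic correction to Stokes drag, stick–slip
   friction dynamics, fiber rotation and bending, gravity, electrostatics
   and van der Waals adhesion are all deliberately excluded. A phase whose
   raw speed would be negative (shirt friction too weak to drag the fiber)
   is clamped to zero and logged rather than allowed to reverse.

3. **Transport and accretion.** The fiber number density n(x, t) on the
   chest-to-navel line [0, L] obeys ∂n/∂t + ū ∂n/∂x = A with a constant
   production rate A and initial profile n₀(x). By characteristics,
   n = A·t + n₀(x − ū·t). The navel at x = L absorbs at rate ū·n(L, t),
   giving N_B(t) = A·ū·t²/2 + ∫ n₀ over [L − ū·t, L] and lint mass
   m_B = m_L·N_B with m_L = ρπd²l/4 per fiber.

## The upstream-source convention

The characteristics solution keeps n(L, t) = A·t growing indefinitely,
which implicitly assumes lint production continues upstream of the modeled
strip — physically, on the rest of the hairy torso. A solver or simulator
whose source stops at x = 0 with a zero-inflow boundary reproduces the
closed form only up to the fill time L/ū; beyond it the navel flux
saturates at A·L instead of growing. The package therefore zero-extends
n₀ below x = 0 (no pre-existing fibers enter from outside — the only
convention consistent with the n₀·L plateau), while verification runs past
the fill time extend the computational domain (`solve(..., x_min=...)`) or
the source strip (`SimConfig(source_extent=...)`) upstream by at least
ū·t_end so the artificial boundary never influences the navel. The
defaults (x_min = 0, source_extent = L) reproduce the bounded-strip
behavior.

## Parameters

All internal values are SI; config files may carry unit suffixes
(kPa, cm, mm, hr, ...), converted by a small in-package table.

| name | meaning | default | basis |
|---|---|---|---|
| d | fiber width | 10⁻⁵ m | SEM of lint fibers |
| l | fiber length | 10⁻³ m | visual inspection of lint |
| ρ | fiber density | 450 kg/m³ | cotton |
| p | skin pressure | 100 Pa | loose daytime clothing |
| R | abdominal radius (longitudinal) | 0.47 m | MRI-based measurement |
| α | real-contact fraction | 10⁻⁵ | tribological estimate |
| η | air viscosity | 1.84×10⁻⁵ Pa·s | standard |
| μ_HL⁺ | hair–lint friction, root-to-tip | 0.1 | cotton-on-hair ≈ 0.3, order 0.1 |
| μ_HL⁻ | hair–lint friction, tip-to-root | 0.2 | ≈ 2 μ_HL⁺ (cuticle asymmetry) |
| μ_SL | shirt–lint friction | 0.3 | cotton-on-hair literature value |
| L | domain length (navel at x = L) | 0.1 m | chest-to-navel strip |
| T | breathing period | 6 s | resting adult |
| A | source rate | 1 fiber·m⁻¹·s⁻¹ | one fiber per breath over L gives 1/(T·L) ≈ 1.7; nominal 1 |
| n₀ | initial fiber density | 100 m⁻¹ | one fiber per hair, hair density ~100/m |

α and μ_HL⁺ are order-of-magnitude figures; the defaults use the nominal
values above. The nearest/floor power-of-ten conventions attached to each
reported estimate are printed alongside the raw values so no rounding is
hidden.

## Numerical choices

- **Profiles.** `DensityProfile` supports constant, zero, truncated-gaussian
  and tabulated (piecewise-linear) initial conditions, all zero-extended
  outside [0, L]. Integrals are closed-form for the analytic kinds; a
  tabulated profile is integrated exactly as the trapezoid rule on its own
  nodes (exact for a piecewise-linear interpolant), with a dense-grid
  trapezoid as an independent cross-check.
- **Finite-volume solver.** First-order upwind with forward-Euler source,
  Δt = CFL·Δx/max|u| recomputed each step. Chosen over higher-order schemes
  because the velocity of interest is constant and the analytic answer
  exists: the solver's job is verification, where provable positivity and
  exact discrete conservation (live + absorbed − injected = initial, to
  round-off, every step) matter more than accuracy order. Negative
  velocities are rejected, not limited. The accreted count is the
  accumulated outflow flux at the navel face. Measured L¹ convergence order
  on a smooth profile is ≈ 1.0 (128/256/512 cells).
- **Stochastic simulator.** Square-wave cycle kinematics: each fiber moves
  −U⁻T/2 then +U⁺T/2 per cycle, so a never-clamped fiber advances by
  exactly ū·T. Sinusoidal shirt motion would change nothing at cycle
  resolution, since only the per-phase displacement matters. Fibers pushed
  below the chest end during inhale are clamped there (they cannot leave
  the hairy domain against the transport direction); this touches only
  fibers within U⁻T/2 ≈ 0.16 mm of the edge and its effect on N_B is
  O(ūT/L) ≈ 0.2%. Source fibers are injected at cycle end, uniformly over
  the source strip, K ~ Poisson(A·W·T) per cycle (Poisson is the minimal
  variance model; the production process is unmeasured). Injection at cycle
  end rather than mid-cycle shifts N_B by at most one cycle's drift.
  Replicates use independent child streams of a seeded `SeedSequence`;
  all stochastic tests use 3-standard-error tolerances, never exact values.
- **Problem sizes.** Verification runs use 512 cells for the solver
  comparisons, 128–512 cells for the convergence study, and 200 replicates
  over ~1230 cycles (twice the fill time) for the simulator ensemble; each
  completes in seconds and leaves the ensemble standard error well below
  the 2–3% agreement bands being tested.

## What the synthetic profiles do and do not emulate

The built-in n₀ profiles (constant, gaussian bump, step, zero) stand in for
the fiber population deposited by toweling after a shower. They capture
total count and spatial localization but nothing about real deposition:
correlation with hair density, fiber size dispersion, or day-to-day
variability. Tests passing on them show the transport machinery is
internally consistent (all three embodiments agree), not that the model's
inputs are accurate for any individual — A, α and μ are order-of-magnitude
figures, and the headline outputs inherit that precision.

## Known limitations

- One-dimensional: lint converges on the navel from all directions in
  reality; the polar generalization is not implemented.
- No fiber–fiber interaction, entanglement, or compaction into a plug;
  N_B counts arrivals, while a real navel eventually saturates.
- The drag balance makes fiber speed independent of the shirt's own speed,
  so a fiber could nominally outrun the shirt during exhale; the model
  keeps the force balance as stated.
- Constant A and ū throughout the domain and the day; respiratory-rate
  variation, sighing and posture changes are ignored (all would enhance
  transport, making the estimates conservative).
- The hair-density threshold separating lint-producing from non-producing
  navels is qualitative only and not modeled.
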