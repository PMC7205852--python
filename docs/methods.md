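# Methods

This note records the model equations as implemented, the numerical
choices behind the simulator and optimizer, what the synthetic-data
generator does and does not emulate, and the known limitations.  Units
are ml, s and mmHg throughout; inertances are mmHg·s²/ml; flows are
positive in the direction of normal circulation (arterial in, venous out,
CSF out of the cranium).

## Circuit model

The craniospinal space is a closed, incompressible container exchanging
volume with the outside only through venous outflow and the spinal sac.
Seven states are integrated: arterial, venous and spinal-CSF volumes
`v_a, v_v, v_s`, the intracranial pressure `p_ic`, the inertial flows
`q_v` (venous outflow) and `q_s` (foramen-magnum CSF flow, positive out
of the cranium), and a compensatory brain-displacement volume `v_comp`.

Constitutive laws:

- **Arterial pressure–volume.**  `p_a − p_ic = e_a0·Δv·(1 +
  k_ea·|Δv/V_an|^n_ea)^m_ea` with `Δv = v_a − V_an`.  Zero at the
  unstressed volume, slope `e_a0` there, strongly stiffening at large
  distension (`n_ea ≈ 23` makes the bracket a sharp soft-wall).  The
  inner power uses `|Δv|` because a signed base with the fractional outer
  exponent would be complex-valued below `V_an`; the law remains odd
  about the unstressed volume in its leading factor and monotone
  everywhere.
- **Arteriovenous resistance.**  `R_av = R_av0·(V_an/v_a)^m_Rav·(1 + c)`
  with a logistic collapse factor `c = c_collapse/(1 +
  exp(n_Rav·(v_a − V_an/2)/V_an))`.  `m_Rav = 2` is Poiseuille scaling
  (R ∝ 1/A²); the collapse factor only matters when the arterial bed is
  squeezed to half its unstressed volume.
- **Venous pressure–volume.**  Split power law about `V_vn`:
  `e_v1·Δv^m_ev1` when distended, `−e_v2·(−Δv)^m_ev2` when compressed;
  continuous and monotone.
- **Venous outflow resistance (Starling behaviour).**  Rising ICP
  compresses the veins; the smaller lumen carries a higher resistance:
  `R_v = R_v0·(V_vn/v_v)^m_Rv`, capped at `r_v_cap·R_v0` in deep
  collapse.  The dependence on the venous-pressure/ICP difference is
  indirect: the transmural pressure `p_v − p_ic` fixes `v_v` through the
  pressure–volume law (the public `(p_v, p_ic)` signature inverts it in
  closed form).  An instantaneous-ratio law of the form
  `R_v0·((p_v−p_out)/(p_v−p_ic))^m_Rv` was implemented first and
  rejected: because `p_v` moves one-to-one with `p_ic`, it feeds ICP
  straight back into the resistance with gain ~`m_Rv` (ml/s)/mmHg, which
  exceeds the total compensatory admittance of the system (~2) for the
  preset `m_Rv ≈ 2.9` and destabilizes the physiological periodic orbit
  at any operating point — the model then falls into a venous-collapse
  relaxation oscillation with ~100 mmHg ICP swings.  The volume-mediated
  law keeps the same limiting behaviours (baseline `R_v0` at zero
  compression, unbounded rise under collapse, constant for `m_Rv = 0`)
  and routes the feedback through the compliance-buffered venous volume,
  which is dynamically stable.
- **Foramen-magnum channel.**  Effective resistance and inertance switch
  with flow direction: outflow into the spinal sac sees
  `R_cs·(1 + a_Rs)` and `L_cs·(1 + b_Ls)`; inflow sees the baseline
  values.  The switch is a C¹ smoothstep of half-width `eps_q = 0.05`
  ml/s so the right-hand side stays Lipschitz for adaptive integration.
  A quadratic advective loss `ρ_l·c_geo·q_s|q_s|` (`c_geo = 1e−3`
  mmHg·s²/ml² per unit `ρ_l`) adds minor-loss damping at high CSF flow.
- **Craniospinal elastance.**  `e_c = e_c0·(1 + k_ec·(p_ic − p_0)/p_0)`,
  floored at `0.1·e_c0`: the pressure–volume curve stiffens with rising
  ICP.  It drives the Monro–Kellie ICP equation
  `dp_ic/dt = e_c·(q_a − q_v − q_s − dv_comp/dt)`.
- **Compensatory displacement.**  First-order relaxation of `v_comp`
  toward `G_comp·(p_ic − p_0)` with time constant `τ_reg`, standing in
  for slow caudal brain shift.

Structural constants (never calibrated): unstressed volumes `V_an = 15`,
`V_vn = 70`, `V_sn = 30` ml, downstream venous pressure `p_out = 5`
mmHg, compensatory gain `G_comp = 0.1` ml/mmHg, plus the numerical
constants above.  They are plausible round physiological values; the
calibration workflow treats only the 24 named physiological parameters
as adjustable.

### Conservation structure

The right-hand side satisfies `d/dt[P(p_ic) − (v_a + v_v − v_s −
v_comp)] = 0` exactly, where `P′ = 1/e_c`.  The model has no CSF
production or absorption, so constant-inflow equilibria form a
one-parameter family indexed by ICP, and the periodic orbit reached
under pulsatile forcing depends on the invariant fixed by the initial
condition.  `equilibrium_state` anchors the convention `p_ic = p_0`; all
simulations start there.  Two consequences are documented behaviours,
not bugs: initial states with different stored volume (e.g. the
unstressed rest state) converge to limit cycles at different mean ICP,
and the unstressed rest state is a true equilibrium of the zero-inflow
system only when `p_0 = p_out`.

## Simulator

Dormand–Prince 5(4) with PI step control, `rtol = 1e−6`, `atol = 1e−8`,
JIT-compiled with numba (a plain-Python path exists when numba is
absent), with `scipy.integrate.solve_ivp(method="LSODA")` as a stiff
fallback if the explicit integrator stalls.  Output is resampled to 200
phase intervals per cycle.  Steady state is declared when consecutive
cycles agree to 0.01 mmHg in ICP (sup-norm), 0.01 ml/s in both flows,
and 1e−4 ml in every volume state; the volume criterion is the
ICP tolerance divided by the ~100 mmHg/ml craniospinal elastance, and
without it the slow compensatory displacement can still be drifting when
the ICP trace has settled, which shows up as a spurious volume-
conservation residual.  At the mean preset, convergence from equilibrium
takes ~10 cycles; 200 cycles is the default cap.

`conservation_residual` integrates the ICP drive term over the cycle
(trapezoid on the phase grid) and subtracts the net stored-blood-volume
change; at a periodic steady state it is zero up to quadrature error
(~1e−5 ml here).

## Synthetic data

The inflow generator is a six-harmonic Fourier truncation of a
periodized Gaussian systolic bump (centre 0.15 of the cycle, width 0.09)
plus a dicrotic-notch bump (default depth 0.3 at phase 0.45), scaled to
an exact mean flow.  Defaults — 60 bpm, 646 ml/min, pulsatility 1.0
(peak/mean = 2) — are typical of summed internal-carotid + vertebral
PC-MRI measurements in neuro-ICU patients.  Six harmonics keep the
waveform band-limited enough that sparse 30–35-point sampling is
lossless in principle.  A sharper, skewed systolic upstroke was tried
and rejected: within six harmonics it aliases into spurious inflow
maxima and rings the ~5 Hz CSF oscillator.

`pcmri_sample` takes uniform phase samples plus i.i.d. Gaussian noise —
it emulates the sparse sampling and amplitude noise of phase-contrast
MRI but none of its physics (velocity encoding, aliasing, ROI
segmentation error, beat-to-beat gating jitter).  `make_virtual_patient`
runs the forward model to steady state and samples ICP at 125 Hz (0.5
mmHg additive noise by default) and the flows at 32 points (5% of peak).
Passing tests on virtual patients therefore demonstrates correctness of
the inference machinery under the model's own assumptions, not
robustness to model misspecification, respiratory modulation, or
measurement-alignment error in real recordings.

## Preprocessing

Venous scaling multiplies the measured jugular outflow by the ratio of
arterial to venous cycle integrals (jugular veins miss part of the
drainage).  Respiratory-cycle averaging linearly resamples each cardiac
segment between user-supplied (or heuristically detected) cycle onsets
to a common phase grid and averages pointwise.  Periodic resampling uses
trigonometric (FFT) interpolation by default — exact for band-limited
curves on uniform grids and integral-preserving to round-off — with a
periodic cubic spline available as an option for non-uniform grids.

## Calibration

The objective is 1 − R² between the measured mean ICP cycle (resampled
to the simulator grid) and the simulated steady-state cycle; each
evaluation runs the model to steady state (with the looser 1e−3 ml
volume tolerance, irrelevant to the shape objective).  SCE-UA uses 4
complexes of 2d+1 points, the standard competitive simplex inner loop,
and stops after 30 shuffling loops, on <1e−4 relative improvement over 5
loops, on population collapse, or when the objective reaches 1e−10
(numerically perfect on noiseless data).  Strictly positive scale
parameters are searched in log10 of their bounds (default 0.1–10× the
mean preset, spanning two decades, where log-space mixing is far more
effective); exponents and possibly-zero coefficients are searched linearly
(exponents bounded [0, 50]).  Failed simulations score a large penalty.
Runs are exactly reproducible given the seed.

The one-at-a-time sensitivity screen perturbs each of the 24 parameters
by ±20%, re-simulates to steady state, and reports relative effects on
mean ICP, pulse amplitude and cycle-shape R²; parameters with all
effects below 1% are flagged insensitive.  The insensitive count depends
on the forcing and operating point (14/24 at the mean preset with the
default synthetic inflow).

## Known limitations

- Inflow is a prescribed forcing: no autoregulation, no CO₂ reactivity.
- No CSF production/absorption — the model addresses within-beat
  dynamics only, not infusion tests or B-waves; mean ICP is set by the
  initial condition through the conservation invariant, not by a
  production/absorption balance.
- At the mean preset the ICP maximum slightly precedes the inflow
  maximum (~50–75 ms).  Linearizing the ICP node shows why: with the
  stiff preset craniospinal elastance (~101 mmHg/ml) the node's storage
  admittance is negligible and the outflow admittance is net inductive
  at 1 Hz, so the ICP fundamental must lead the inflow fundamental; a
  lag would require an elastance some 30× smaller.  The offset is within
  the timing uncertainty that affects aligning separately recorded ICP
  and flow measurements.
- Raising `p_0` by 50% at the mean preset slightly lowers the P2:P1
  ratio (0.58 → 0.51); the clinical association between higher reference
  pressure and P2 dominance is an across-patients observation that this
  single-parameter-set model does not by itself reproduce.
- The exact constitutive forms are reconstructions consistent with the
  verbal physiology and the named parameters; where a published form was
  dynamically inconsistent with the preset parameter values, the
  stabilized variant documented above is used.
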