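# Methods

## Model

A neuron is a rooted tree of compartments: a single spherical soma
(root), chains of cylindrical shaft compartments, and one constant-size
growth-cone compartment at each tip. Free tubulin is the only dynamic
species. Its quantity `Q_i` (mol) in compartment `i` obeys a
conservative finite-volume balance,

    dQ_i/dt =  Σ_j D · A_ij · (C_j − C_i) / d_ij        diffusion
             + f · v · C_up · A_ij                      active transport
             − b · Q_i                                  decay
             − X · dL/dt   (growth cones only)          consumption,

with `C_i = Q_i / V_i` the concentration, `A_ij` the interface
cross-section, `d_ij` the centre-to-centre distance, and `C_up` the
donor (proximal) compartment's concentration — advection is anterograde
and upwind, which keeps the scheme positivity-preserving and
mass-conservative. The soma is a Dirichlet boundary: its concentration
is re-clamped to `C_soma` after every step and the injected mass is
booked as production; the soma is the system's only source.

Neurite elongation follows the growth-cone tubulin concentration,

    dL/dt = m · p · C_gc − q,

where `p` is the microtubule polymerization rate, `q` the
concentration-independent depolymerization rate, and `m` a
per-growth-cone multiplier used for perturbations (`m = 1.5` is a
"+50%" perturbation; perturbations scale `p` only). Elongation removes
`X` mol of tubulin per metre from the growth-cone compartment;
retraction releases it there (depolymerized tubulin becomes free
again). The growth cone itself keeps a fixed size; the shaft directly
proximal to it stretches, splitting into two equal halves (half the
tubulin each) above 2.5 µm and merging into its parent (sums) below
0.5 µm. Both operations conserve cable length and tubulin exactly. A
shaft whose parent is the soma or a branch point is never merged away:
a neurite can shrink to a growth cone plus one floor-length shaft but
never disappears, and branch points are never deleted.

## Parameters

SI units internally; note 1 mM ≡ 1 mol/m³, so `p` in m/(s·mM)
multiplies concentrations in mol/m³ directly.

| symbol | meaning | default | unit |
|---|---|---|---|
| D | tubulin diffusion constant | 1e-11 | m²/s |
| f | fraction bound to active transport | 6e-3 | – |
| v | active transport speed | 440e-9 | m/s |
| b | tubulin decay rate | 5.67e-7 | 1/s |
| X | tubulin consumed per unit length | 4e-14 | mol/m |
| p | polymerization rate | 1.83e-6 | m/(s·mM) |
| q | depolymerization rate | 9.17e-9 | m/s |
| C_soma | clamped soma concentration | 5.5 | µM |

`p` and `q` are calibrated so elongation is zero at ~5 µM free
tubulin and 0.033 mm/h at 10 µM. `X` corresponds to 1640 tubulin
dimers per µm in each of ~15 microtubules (≈ 4e-14 mol/m). With the
default `D` and `b`, the diffusion–decay space constant is
λ = √(D/b) ≈ 4.2 mm, so concentration profiles along 100 µm-scale
neurites are decay-flat and gradients are set by consumption.

Geometry defaults where a choice was needed: neurite diameter 1 µm;
growth-cone compartment a 1 µm-long cylinder at the neurite diameter
(small fixed volume minimizes concentration artifacts); soma a 10 µm
sphere (only its clamped concentration matters dynamically). The
interface area between unequal neighbours is the distal compartment's
cross-section (flux limited by the narrower child; `interface_area =
"mean"` is available). At a branch point the anterograde advective flux
into each child is `f·v·C_parent·A_child` — the standard
continuum-consistent upwind discretization on a branched network, in
which a symmetric bifurcation doubles total advective throughput (each
daughter carries its own full microtubule array).

## Numerics

Backward Euler on the linear transport operator (sparse,
tree-structured; LU re-factorized whenever geometry changes and reused
otherwise), which is unconditionally stable and positive, so 40-hour
simulations run with dt of seconds even at the 0.5 µm mesh floor. An
explicit-Euler mode with a negativity check is provided for
cross-validation. One full step is operator-split: transport → growth
(using the post-transport growth-cone concentration) → remesh; the
soma clamp is part of the transport solve. Per-step retraction is
capped so the elongating shaft shrinks at most to half the merge floor
(one merge per step); with the dt values used this cap never binds in
free growth.

A mass ledger (initial + produced − decayed − consumed = current
total) closes to machine precision every step; sealed systems conserve
total tubulin to relative drift < 1e-10 over 1e5 steps. Positivity
guards — a growth cone cannot consume more tubulin than it holds —
cap free growth (logged) and skip forced-replay steps (logged), rather
than raising.

Step sizes and mesh by experiment (the package's own accuracy/cost
choices; halving dt changes final lengths by < 0.5%):

* Y-tree perturbation runs and sweeps: dt = 5–10 s, mesh 0.5–2.5 µm.
* Branched-tree competition: dt = 5 s, 10 h horizon.
* Forced-growth replay and grid-search fits: dt = 60 s, split ceiling
  10 µm. The forced-mode rule (a step whose tubulin demand exceeds the
  growth-cone stock is skipped) bounds usable dt: per-step demand must
  stay below the ~0.1 µm-equivalent stock of the default growth cone.

## Experiments

**Y-tree perturbation.** Soma, trunk of length d_A, fork, two daughters
of initial length d_B (defaults 50 and 10 µm; the geometry is a
package default, not a measured one). After 10 h of free outgrowth one
growth cone gets +50% polymerization; read-out 30 h later. Sweeps:
diffusion constant (log, 1e-13–0.5e-10 m²/s), active-transport speed
(linear including zero, 0–440e-7 m/s — the only v range stated with
the model; a log grid cannot include the v = 0 endpoint), and geometry
d_A ∈ {25,50,100,200} µm × d_B ∈ {10,20,30,40} µm with the
perturbation at t = 0 and read-out at 10 000 s. Branches with less
than ~8.5 µm of retraction room saturate at the no-deletion clamp,
which inverts the d_A trend for d_B ≤ 5 µm; the default d_B grid
therefore starts at 10 µm (a documented boundary effect).

**Complex-tree competition.** A deterministic branched fixture (9
terminal tips, soma-to-tip path distances 45–180 µm, tapering
diameters) stands in for a reconstructed dendritic morphology; any SWC
file can be used instead. For each tip in turn: control run vs +100%
perturbation for 10 h; the summary statistic is the total relative
retraction — Σ over unperturbed tips of max(0, control − perturbed
length at the horizon), divided by the perturbed tip's growth in
excess of control. Both numerator and denominator are measured against
the control run at the same horizon (the consistent comparison; the
denominator convention is this package's choice). The statistic rises
with the perturbed tip's path distance to the soma (Spearman ρ ≈ 0.95
on the fixture).

**Forced-growth replay.** Selected growth cones follow recorded
path-length traces — consuming tubulin when forced forward (a step the
growth cone cannot pay for is skipped for that step), releasing it when
retracting — while a free growth cone obeys the model. The replay
error is √Σ_t (L_sim − L_obs)² over the observed sample times. An
exhaustive grid search over (D, v, b, C_soma) within the ranges above
ranks parameter sets by this error; grid points are independent and
evaluated in deterministic grid order.

## Synthetic traces

The culture-like trace generator emulates a time-lapse recording of a
developing neuron with three neurites appearing at 0, 980 and 1650
minutes: the first two grow out (to ~55 and ~40 µm) and stall, the
third grows slowly and then spurts (~12 → ~60 µm after minute 2400)
at the expense of the others; smoothed Gaussian jitter (σ = 0.35 µm)
emulates manual frame-by-frame tracking, sampled every 10 minutes over
3000 minutes, deterministic per seed. A model-generated template
instead records the simulator's own traces on a three-neurite star
morphology (no staggered onsets) for parameter-recovery tests.

What the synthetic data do not emulate: guidance cues and substrate
interactions, growth-cone branching during the recording, measurement
outliers, and any correlation between neurite appearance and resource
state. Passing the replay tests therefore shows the fitting machinery
is correct and self-consistent, not that the model explains any
particular recorded neuron.

## Known limitations and observed behaviours

* With the full default parameter set (active transport f·v =
  2.64e-9 m/s on), a +50% perturbation on the default Y-geometry
  produces a *transient* sibling retraction (minimum near 15–20 h)
  that recovers above its pre-perturbation length by ~25 h: default
  active transport sits between the low-transport regime (sibling
  retracts persistently) and the high-transport regime (no retraction
  at all). With diffusion only (v = 0) the sibling remains below its
  10 h length at 40 h. The persistence of retraction is therefore a
  function of the transport share, not a fixed model property.
* The model contains no actin dynamics, microtubule polymer transport
  or sliding, vesicle or mitochondrial transport, no growth-cone
  splitting (topology changes only through elongation/retraction), and
  no 3D geometry — SWC coordinates are used only for path lengths.
* Any soma-produced, transported, tip-consumed resource yields the
  same competition dynamics; nothing here identifies tubulin
  specifically.
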