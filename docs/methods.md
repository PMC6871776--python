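# Methods

## The model

The quadruped is reduced to the smallest mechanical system that can still
express every planar footfall sequence: two point masses — a forequarter
mass `mF'` at the shoulders and a hindquarter mass `mH' = 1 − mF'` at the
hips — joined by a rigid, massless trunk of length `lB`, walking on massless
prismatic limbs that push only along their own axis. The pitch moment of
inertia of this dumbbell is `I' = mF'·mH'` (units `m·lB²`), equivalently the
dimensionless `Î = 4·mF'·mH'`.

Lengths are normalized by `lB`, time by the stride period `T`, mass by body
mass `m`, force by body weight `mg`. One dimensionless group survives:
`T̂ = T·√(g/lB)`. Normalized time runs over one stride, `t' ∈ [0, 1]`.

Contact is *implicit*: no footfall sequence is prescribed. Three limbs carry
two potential contact positions each — a trailing foothold `f'` and a
leading foothold `f' + D'` one stride length ahead — while the left hind
limb is the reference with a single foothold, so seven nonnegative axial
force channels `F'_c(t')` describe all limb loading. Forces are *states*
whose derivatives (the force rates `Ḟ'`) are the controls, so ground
reaction forces are continuous by construction. The equations of motion are
Newton–Euler for the single rigid body:

    ẍ' = (−ŷ + Σ_c F'_c û_c)·T̂²,    θ̈ = (Σ_c r'_c × F'_c û_c)_z / I' · T̂²,

with `û_c` the unit vector from foothold to girdle attachment and `r'_c` the
trunk offset of the attachment (`+mH'` fore, `−mF'` hind, rotated by the
pitch `θ`).

Contact structure is imposed by path constraints rather than by modes:

* forces only while shorter than standing length: `(l'max − l')·F' ≥ 0`;
* trailing before leading: `F'_T·∫₀ᵗ F'_L = 0`, with the running integral
  carried as an auxiliary state `z` (ż = F'_L, z(0) = 0);
* both girdles above ground: `y' ± m·sinθ ≥ ε` with `ε = 10⁻³ lB` (a strict
  inequality is not representable in an NLP);
* ventral limb orientation: forelimb torques about the COM nose-up, hindlimb
  torques nose-down;
* periodic kinematics, force continuity `F'_L(1) = F'_T(0)`, zero endpoint
  forces for the remaining channels, `x'(0) = 0`, `x'(1) = D'`;
* equal left/right vertical and fore-aft stride impulses (a planar surrogate
  for roll/yaw balance).

## The cost

The objective is a cost of transport: positive-plus-negative limb work plus
a squared force-rate penalty, per unit weight and distance,

    J_tot = ( ∫ Σ_c |F'_c·l̇'_c| dt' + ∫ Σ_c c₁'·Ḟ'²_c dt' ) / D'.

`c₁'` is the only fitted parameter. Its reference value `c₁D' = 3·10⁻³`
belongs to the Dalmatian walking case (`T̂_D ≈ 3.289`); other tasks scale it
as `c₁'(T̂) = c₁D'·T̂_D/T̂`, keeping the rate share of cost roughly stable
across body and stride scales. In the mathematical formulation the absolute
value is decomposed through nonnegative power slacks `p − q = F·l̇` with
complementarity `p·q = 0`; the implementation (below) treats the slacks as
derived quantities, and they are reported with complementarity holding
exactly.

## Transcription and solver

The optimal-control problem is transcribed by separated Hermite–Simpson
collocation: states and controls at the N+1 mesh nodes *and* the N interval
midpoints (M = 2N+1 sample points), one Hermite-interpolation defect and one
Simpson defect per interval per state, and every path constraint enforced at
all M points. All constraint and objective derivatives are analytic and
assembled as sparse matrices from precomputed index maps.

The NLP backend is a Gauss–Newton/augmented-Lagrangian scheme built on
SciPy's trust-region least-squares machinery (TRF with LSMR inner
iterations): the residual vector stacks

* objective residuals — `√(w_P·c₁'/D')·Ḟ'` for the rate term and
  `(w_P/D')^{1/2}·((F'l̇')² + ε_w²)^{1/4}` for an ε-smoothed work term
  (`w_P` are Simpson quadrature weights);
* equality residuals `√(μ/2)·(c + λ/μ)`;
* inequality hinge residuals `√(μ/2)·max(0, η/μ − g)`,

with first-order multiplier updates (`λ ← λ + μc`, `η ← max(0, η − μg)`)
between least-squares solves and a penalty `μ` that grows only while
infeasibility stalls. Power slacks and the relaxation variables of the
mathematical formulation are not decision variables here: the ε-smoothing
plays the role of the slack complementarity, and the multiplier-penalty
treatment plays the role of the relaxation-variable penalties, which keeps
the NLP at 16 states + 7 controls per point + 4 foothold parameters.

Each random start runs through a four-stage homotopy that simultaneously
shrinks the work smoothing (`ε_w`: 3·10⁻² → 10⁻² → 10⁻³ → 2·10⁻⁴), raises
the enforcement weight (`μ₀`: 10² → 3·10² → 10³ → 3·10³) and tightens the
per-stage feasibility target (10⁻³ → 10⁻⁴ → 10⁻⁵ → 10⁻⁵). Later stages may
refine the mesh (interpolating the iterate) whenever the estimated
discretization error exceeds the mesh tolerance of 10⁻⁴; between stages the
trajectory is down-sampled onto the 16-point seeding grid. Before the first
stage, the randomly guessed trunk states are replaced by a clipped forward
simulation of the guessed force rates, which removes the enormous initial
dynamics defects without adding information beyond the guess.

Initial guesses are drawn uniformly within the variable bounds at 16 grid
points, except the fore-aft position, which ramps linearly from 0 to `D'`.
Per-guess seeds are `base_seed + guess_index`. A *screen-then-polish*
multistart runs every guess through the first two (cheap, heavily smoothed)
stages, ranks by smoothed objective plus an infeasibility penalty, and
drives only the best few through the remaining stages.

**Validation.** A solution is valid when (i) the mesh error — each interval
re-integrated from its left node with a high-accuracy RK method under the
interpolated controls, compared with the collocated right node — is at most
10⁻⁴, and (ii) the worst exact-constraint violation at the sample points
(including the ordering products and the power-slack complementarity, which
is zero by construction here) is at most 10⁻³ in normalized units. The
pseudo-global optimum of a multistart is the valid solution with the lowest
unaugmented `J_tot`; penalty terms never enter the ranking.

## Gait analysis

A limb is in contact when its total force (trailing + leading channels
merged) exceeds 10⁻³ mg; crossings are located by linear interpolation and
intervals may wrap across the stride end. Touchdowns feed the three phase
lags HL, PL, FL (left-hind → right-hind, left-hind → left-fore, left-fore →
right-fore), all modulo one stride and timed from left-hind touchdown.
Because the planar model cannot distinguish left from right, forelimb labels
are mirror-swapped into a canonical form — four-beat walks become lateral
sequence with PL ∈ (1/16, 7/16], two-beat runs become trots — and gaits are
then binned per Hildebrand: pace (PL ≤ 1/16 or > 15/16), lateral couplets
(≤ 3/16), singlefoot (≤ 5/16), diagonal couplets (≤ 7/16), trot (≤ 9/16),
with symmetry requiring |HL − 0.5| and |FL − 0.5| ≤ 0.05. Apparent leg
stiffness `k' = −ΔF'/(Δl'/l'max)` is a least-squares slope over stance
samples within 5% of `l'max` of the stance-onset length. The walk–trot
transition of a speed sweep is the lowest grid speed whose pseudo-global
gait is a two-beat run (or, for empirical frequency tables, the first speed
where the walking frequency drops below 0.5).

## Synthetic fixtures

The analysis layer is tested against constructed strides with known
structure: raised-cosine stance humps at prescribed touchdown phases and
duty factors, per-girdle force shares matching the mass split, feet placed
under the girdles at mid-stance, and stances wrapping the stride end split
between leading and trailing channels so periodicity holds by construction.
These fixtures have closed-form duty factors, lags, impulses and work; they
are *not* dynamically consistent trunk trajectories and make no claim of
energetic optimality, so passing fixture tests validates the measurement
pipeline, not the physics. Dynamic consistency is tested separately against
an independently coded Newton–Euler oracle (explicit 3-vector cross
products, high-accuracy ODE integration).

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `c1D'` | 3·10⁻³ | force-rate penalty at the Dalmatian reference scale |
| contact threshold | 10⁻³ mg | force level defining contact |
| `ε_clearance` | 10⁻³ lB | strict-inequality margin for trunk height |
| mesh tolerance | 10⁻⁴ | relative per-interval re-simulation error |
| violation tolerance | 10⁻³ | exact-constraint validity threshold |
| symmetry tolerance | 0.05 | |HL−0.5|, |FL−0.5| bound for symmetric gaits |
| `n_segments_initial` | 15 | initial mesh intervals (16 nodes) |
| `ε_w` (final) | 2·10⁻⁴ | residual work smoothing in the last stage |

Variable bounds are generous boxes (forces to 10 mg, rates to ±120 mg/T,
pitch to ±60°) that exist to make uniform random initialization meaningful
and the problem well scaled, not to shape solutions.

## Problem sizes

Multistart counts are deliberately modest: the package defaults use ~8–20
random starts per condition with 3–6 polished, and the shipped acceptance
script uses 20 starts for the Dalmatian case and 5 per speed for the slow
Malinois conditions. The original investigation behind these parameter sets
used hundreds to a thousand starts per condition; with few starts the
pseudo-global pick is a small-sample estimate, so gait-level outcomes
(which are discrete) are usually reproduced while third-decimal costs and
lags fluctuate between seeds.

## Numerical choices and degenerate inputs

* Work smoothing biases the measured stance slightly long: at `ε_w = 2·10⁻⁴`
  the bias in `J_w` is below ~10⁻³ and reported costs are always recomputed
  from the unsmoothed trajectory.
* The ordering constraint is written `F'_T·z − s_b = 0` with `s_b ≥ 0`
  absorbing the product, so a linear penalty on `s_b` penalizes the
  complementarity violation directly (the relaxed form with `+s_b` has an
  empty interior, since both terms are nonnegative).
* Limb-length rates are computed analytically from the geometry, not by
  finite differences.
* A limb that never loads has no touchdown: phase lags are then flagged
  undefined rather than guessed.
* Ties between trailing and leading contacts of a limb at the same instant
  cannot persist: once the leading channel has carried any impulse the
  ordering constraint silences the trailing one.
* Zero-length limbs (foothold exactly under a girdle at zero height) are
  excluded by the clearance margin.

## Known limitations

* Limbs are massless: swing cost is absent, which is the likely reason the
  optimal duty factor at slow speeds sits above empirical values and decays
  late with speed.
* The trunk is rigid; galloping therefore never becomes pseudo-globally
  optimal, matching the behaviour of rigid-back models generally.
* The left/right impulse constraint is a planar stand-in for 3D roll/yaw
  balance, not actual out-of-plane mechanics.
* With few random starts the multistart can miss the global basin at high
  speeds, where local optima proliferate and the cost landscape flattens.
* The Gauss–Newton/multiplier backend enforces feasibility tightly but
  terminates on budgets rather than on a stationarity certificate; validity
  is therefore defined by feasibility and mesh error, and optimality is
  always relative to the multistart sample.
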