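# Methods

## The model

Digit segmentation is modeled as a Turing-type reaction–diffusion system of
the BMP pathway on the proximal–distal axis of a digit ray. Six components
are tracked on a 1D grid: *GDF5* and *NOG* mRNA (`m_G`, `m_N`), free GDF5
and NOG protein (`G`, `N`), the inert NOG–GDF5 complex (`C`), and pSMAD
activity (`S`), the nuclear readout of BMP signaling. The kinetic
assumptions are:

1. free GDF5 activates pSMAD through a saturating (Hill) response,
   `S = S_max · G^h_S / (K_S^h_S + G^h_S)`;
2. pSMAD represses *GDF5* transcription
   (`α_G · K_G^h_G / (K_G^h_G + S^h_G)`);
3. NOG binds GDF5 by mass action (`k_on`, `k_off`) into a complex that
   cannot signal;
4. GDF5, NOG and the complex diffuse (`D_G`, `D_N`, `D_C`); the mRNAs and
   pSMAD do not;
5. in the validated topology pSMAD also represses *NOG* transcription; the
   alternative topologies (`nog_regulation` = `constant` or `activated`)
   exist only so the necessary-condition screen can interrogate them.

All species are removed by first-order turnover. pSMAD can be an
instantaneous algebraic readout (`tau_S = 0`, the reference choice — pSMAD
phosphorylation is fast relative to transcription and turnover) or a
relaxation variable with time constant `tau_S`; the linearization handles
both (the instantaneous case eliminates `S` by the chain rule, giving a
5-component Jacobian).

The destabilizing loop is local and runs through the inhibitor: a dip in
pSMAD derepresses *NOG*, more NOG sequesters free GDF5, which lowers pSMAD
further. Long-range inhibition is carried by the diffusible ligand pool:
GDF5 leaving a forming joint (partly as complex, which releases free ligand
by dissociation) raises pSMAD at a distance and represses *GDF5*/*NOG*
transcription there. Neither loop exists when *NOG* transcription is
insensitive to (or activated by) pSMAD, which is why only the repressed
topology patterns.

## Homogeneous steady state

At a homogeneous fixed point every component has a closed form given free
GDF5: `S` from the pSMAD response, the mRNAs from the transcription Hills,
`N` from its own balance (with the effective complex-channel removal
`φ = k_on·δ_C/(k_off+δ_C)`), and `C` from the binding quasi-equilibrium.
Substituting leaves one scalar equation in `G` whose residual is positive
at `G = 0` and negative above the production bound
`β_G·α_G/(δ_mG·δ_G)`, so Brent's method on that bracket finds a root
deterministically, with no iteration-failure mode. The returned state is
verified to satisfy `|rate| < 1e-10` on a normalized scale. Multiple
roots are possible in strongly switch-like parameter regimes; the
reference set was chosen to have a unique root (checked on a 400-point
residual scan).

## Linear instability analysis

The growth rate of a perturbation with wavenumber `k` is the largest real
eigenvalue part of `J − k²D`, with `J` the reaction Jacobian at the steady
state (built symbolically with sympy, lambdified once per topology and
pSMAD regime) and `D` the diagonal diffusion matrix. A central-difference
Jacobian of the numeric reaction terms serves as a permanently available
independent oracle; the two agree to better than 1e-5 relative in the test
suite and the acceptance run. A Turing verdict requires stability at
`k = 0` and positive growth at some `k > 0`; the maximizing wavenumber is
refined with a three-point parabola and predicts the wavelength
`λ = 2π/k_max`. The `k` grid starts at 0 with ≥ 200 points and its upper
end is doubled until the maximum is interior. Eigenvalue branches may
collide as `k` varies (square-root points), so `σ(k)` is continuous but
not Lipschitz; tests therefore check pointwise agreement rather than a
step bound.

The parameter-space screen draws log-uniformly (default ±1 decade around
the reference set) for the 18 kinetic parameters, holding topology and
Hill exponents fixed, and reports the Turing-unstable fraction.
Steady-state failures are counted separately and excluded from the
denominator. The screen is the testable shadow of the network's necessary
condition: at 10⁴ draws the `constant` and `activated` topologies yield
exactly zero unstable draws, while the repressed topology yields a few
percent.

## Reference parameter set

The quantities this package reproduces are phase relations, qualitative
mutant outcomes and band-count changes, not measured rate constants, so a
reference "wildtype" set had to be constructed. It was
calibrated once by a staged search (log-uniform sampling plus Nelder–Mead
refinement in log-parameter space) against the full phenotype: a unique
homogeneous steady state, Turing instability with a margin of stability to
homogeneous perturbations (`σ(0) < −0.08/h`), a simulated static pattern
whose spacing matches the linear prediction within 15% and does not
coarsen, the in-vivo phase relations (below), a strong
transcription-ceiling contrast so the signaling-null mutant reads as
uniformly high, a linearly stable binding-null mutant, and persistence of
the instability (at shorter wavelength) when NOG removal is doubled.
Diffusivities were then rescaled jointly — an exact symmetry of the
reaction–diffusion equations — to place the predicted wavelength at
~276 μm, the scale at which new phalanges are first demarcated in the
measured growth series (~250–350 μm). Units are μm, hours and an arbitrary
concentration unit; turnover rates sit in the 0.03–2.5/h range and
diffusivities between ~140 and ~6,700 μm²/h, all physiologically
plausible for extracellular proteins.

In this regime the effective ranges of GDF5 and NOG are set by binding and
turnover as much as by raw diffusivity (the complex, with the largest
diffusivity and slow removal, acts as a long-range ligand shuttle that
re-releases free GDF5 by dissociation). The phase relations and all other
observables are insensitive to which carrier dominates, and the
equal-diffusivity witness (below) shows no diffusivity ordering is
required at all. Beyond ~2.2× the reference NOG removal rate the Turing
instability is lost, so the wavelength-vs-removal sweep is run over
scale ∈ [1, 2.2], where the predicted wavelength falls monotonically.

## Simulation

Method of lines on a uniform grid (reference spacing λ/22 ≈ 12.5 μm;
grid-refinement tests use λ/30 vs λ/60) with zero-gradient boundaries — a
digit ray is a closed tissue segment — and stiff BDF integration
(rtol 1e-6, atol 1e-9) with a banded Jacobian sparsity pattern. Component
values below −1e-9 abort the run; smaller negative excursions are clipped
to zero with a logged warning. The initial condition multiplies the
homogeneous steady state by `1 + noise_amp · field`, where the field is a
seeded sum of 64 cosine modes (unit RMS). A spectral field rather than
per-grid-point noise makes the perturbation a grid-independent function of
position, so halving `dx` reproduces band counts and positions.

The growing domain models distal tip elongation by cell incorporation, not
dilation: every `dx/v` hours one grid cell is appended at the tip. New
cells enter as naive progenitors — at the homogeneous steady state with
the same relative noise as the initial condition. (The alternative of
copying the current tip state was tried and rejected: the tip pSMAD source
pushes that state into a slowly-relaxing near-fixed-point region, the wake
never reaches the unstable pre-pattern state on a developmental timescale,
and no sequential bands form.) A half-Gaussian pSMAD source of amplitude
~0.3·S_max and width 50 μm tracks the tip, standing in for the high pSMAD
of the phalanx-forming region; it also pins the pattern phase, which is
why growing-domain band positions are reproducible across seeds to a small
fraction of a wavelength. Cells farther than `d_commit` from the tip
freeze (all six components by default; a transcription-only freeze that
lets proteins keep reacting and diffusing is available as
`commit_mode="transcription"`), recording the pattern permanently.

Band initiation events are recorded when a smoothed GDF5-mRNA peak first
exceeds twice the homogeneous steady level — a "faint band" criterion that
fires long before the pattern saturates — at a position not previously
occupied by a band. Band extraction uses moving-average smoothing
(window 5) and a peak-prominence threshold of 10% of the profile's dynamic
range; classification calls a profile periodic (≥ 2 bands and spatial
CV ≥ 0.2), uniformly high (mean ≥ 1.5× the wildtype mean) or uniformly
low. All classification outcomes reported here are robust to ±50% changes
in these thresholds.

Reference growth conditions (`digitpattern.reference`): 300 μm initial
domain, 10 μm/h tip speed — the measured whole-digit elongation rate
during segmentation is ~16 μm/h, part of which is post-patterning phalanx
growth the model does not represent — a 180 h patterning window, 650 μm
commitment distance (~2.4 wavelengths; cells must remain plastic long
enough for the pattern to establish before freezing). These conditions
yield four sequentially appearing committed bands, a digit III-like count.
Calibrated single-knob routes to exactly one extra committed band
(recorded as regression values): NOG removal ×2, tip speed ×1.25, or
patterning duration ×1.25.

### Mode metastability

On the translationally symmetric static domain the selected band count is
genuinely metastable: at 1% initial noise a 5λ domain settles into 3–6
bands depending on the realization, because the dispersion maximum is flat
and nonlinear locking admits a window of mode numbers. In the weak-noise
regime (noise 1e-4) the linear stage filters sharply around `k_max` and
the count varies by at most one. Tests assert the ±1 window at weak noise
and spacing consistency at 1% noise; exact seed-independence of counts
holds on the growing domain, where the tip source breaks the symmetry.

## Profile pipeline

The in-vivo quantification is re-implemented as: per-channel min–max
scaling to [0, 1] (NFI; invariant to staining gain and baseline, which is
the property the alignment relies on), landmark detection as the two most
distal GDF5 peaks after moving-average smoothing (window 15 px, prominence
25% of the dynamic range — raw pixel noise must not masquerade as a
joint), an affine map per specimen sending the landmark pair to (0, 1)
with linear re-interpolation onto a shared grid (no extrapolation; missing
positions are NaN and excluded from cross-specimen means, with counts
reported), and phase offsets by circular cross-correlation of
mean-subtracted, variance-normalized channels over one landmark-frame
wavelength, folded into [0, 0.5]. Because the landmarks are consecutive
joints, one landmark-frame unit is one wavelength by construction.
Simulated patterns are pushed through this same pipeline when phases are
measured (a naive fixed-window correlation fails for strongly non-sinusoidal
patterns with uneven stable gaps; the landmark frame is robust to both).

With the reference set the measured offsets are: GDF5 vs NOG mRNA 0.00,
GDF5 mRNA vs pSMAD 0.50, free GDF5 protein vs pSMAD 0.00 (fractions of a
wavelength) — mRNAs in phase with each other, antiphase to pSMAD, free
ligand in phase with pSMAD.

## Growth analysis

Element length series (whole digit, unsegmented distal domain, phalanges)
are fitted by ordinary least squares within a time window; multiple
specimens per time point enter as independent observations (the analysis
this mirrors superimposes simple linear models, so no mixed effects).
Whole-digit rates are compared on the 144–184 h active-segmentation
window. Initiation of an element is the earliest time point at which its
distal GDF5 band is present (majority vote across specimens per time
point, then forced monotone); its initial length — the wavelength proxy —
is the mean measured length at that time. An element present from the
first observation is flagged left-censored; since the band can appear
between samplings, detected initiation can lag truth by up to one sampling
interval and the length comparison is made at the detected time.
Per-element "initial growth rates" default to a fit window of
[initiation, initiation + 40 h].

## Synthetic data

Two generators provide all fixtures, so every pipeline stage is tested
against known truth with no imaging input. Intensity traces are Gaussian
band trains (4 bands, 300 μm wavelength, band width 0.18λ) with per-channel
phase offsets, per-embryo affine axis distortions (scale 0.85–1.18, shift
±40 μm — the magnitude of section-to-section variation the landmark
alignment must absorb), per-channel gain (0.6–1.8) and baseline
(0.05–0.35), and additive Gaussian noise (relative σ, default 5%, closure
tests at 10%); 1 px = 1.243 μm. Growth series follow piecewise-linear
schedules from known initiation times with Gaussian length noise
(σ = 15 μm, about the section-measurement scatter) and 2–3 specimens per
8 h time point over 128–232 h. The two-digit preset builds a digit III
(four phalanges) and a digit IV (five phalanges, initial lengths 0.8×,
equal whole-digit rates over 144–184 h, diverging after). Parametric
waveforms — not simulation output — are the default truth, so pipeline
failures cannot be masked by model behavior; simulation output is pushed
through the same pipeline in the end-to-end phase tests.

What passing these tests shows — and does not show: the pipeline recovers
phases, slopes and initiation times from data with the generators' noise
structure (additive Gaussian, affine distortions, clean band trains). Real
sections add autofluorescence structure, section obliquity and
out-of-plane joints that the generators do not emulate; performance there
is not certified by this suite.

## Numerical and design choices

- Steady-state solve: bracketed scalar root (see above); deterministic,
  no damping heuristics.
- `k_max` refinement: three-point parabola; ties at the grid edge fall
  back to the grid argmax.
- Turing threshold: growth must exceed 1e-9/h to count as unstable,
  guarding against calling numerically-zero eigenvalues positive.
- Equal-diffusivity witness search: draws with `D_N = D_C = D_G` tied,
  requiring growth > 0.05/h so the witness patterns on a developmental
  timescale; failure within the budget is a reported outcome, not an
  error.
- Bead scenarios: a constant-in-time additive free-GDF5 source from t = 0
  (Gaussian, default width 40 μm); a zero-strength (BSA) bead is bitwise
  identical to wildtype for a shared seed. Bead positions are specified as
  fractions of the final domain length.
- The signaling-null mutant zeroes `S_max` (ligand made but never
  signals) rather than deleting GDF5 dynamics, so *Gdf5* expression
  remains observable, as in the experiments it mirrors.
- Band counting for element-number comparisons uses the committed region
  only: phalanx-joint elements are fated segments, and the distal
  uncommitted zone fluctuates.

## Known limitations

- 1D only; no mechanics, cell movement or chondrocyte maturation, and no
  later-stage refinement (NOG peak splitting, pSMAD asymmetry near
  maturing phalanges are outside the model's scope).
- The reference kinetics are a calibrated regime consistent with the
  observed phenotype, not measured constants; conclusions are
  qualitative/structural (topology, phases, band-count responses), and
  quantities tied to absolute rates should not be read off.
- The necessary-condition screen samples parameter space; it inherits the
  usual limitation of sampling relative to a proof.
- Static-domain band counts are metastable across noise realizations (see
  above); only growing-domain counts are exactly reproducible.
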