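# Methods

## Physical model

### Source

The Model M42 seed is modelled as nested coaxial finite cylinders: a Yb₂O₃
ceramic core (ρ = 7.1 g/cm³), a titanium inner capsule (4.51 g/cm³), a
304-stainless-steel outer capsule (7.80 g/cm³, composition 16% Cr, 10% Ni,
0.03% S, 0.75% Si, 0.08% C, 2% Mn, 0.045% P, 69.095% Fe, 2% Mo by mass), and
a short SS-304 cable stub on the θ = 180° side, which makes the assembly
rotationally symmetric but asymmetric about the transverse plane. Only the
active length (L = 0.6 cm) is a published dimension. The remaining defaults —
core radius 0.020 cm, Ti capsule r = 0.028 cm / z ± 0.34 cm, SS capsule
r = 0.040 cm / z ± 0.40 cm, cable r = 0.035 cm × 0.2 cm — are nominal
engineering values at the scale typical of HDR seeds, chosen once from a
transmission budget consistent with the benchmark air-kerma strength; every
dimension, density and material is overridable through the config mapping of
`build_default_m42`. Decays are sampled uniformly over the core volume with
isotropic emission — the standard assumption for an unstructured active
ceramic.

The ¹⁶⁹Yb emission spectrum is packaged as a 14-line table (Tm K X-rays plus
γ rays, photons per decay) compiled from evaluated nuclear decay data:
intensity-weighted mean 93.3 keV, total yield 3.286 photons/decay. Tm L
X-rays (~7 keV) are omitted; they fall below the transport cutoff and have
sub-millimetre range in water.

### Photon interactions

Per-element tables (10–400 keV, log-spaced nodes, K-edge node pairs for Mo
and Yb) are packaged as text fixtures and combined by the mass-fraction
mixture rule; interpolation is log-log and exact at nodes. The tables are a
*constructed* cross-section set, built as follows and shipped frozen:

- **incoherent**: free-electron Klein-Nishina × N_A·Z/A, multiplied by a
  smooth binding-suppression factor S̄(E, Z) = E²/(E² + (3·Z^0.4)²) calibrated
  to the standard water incoherent/KN ratios (≈0.69 at 10 keV, 0.90 at
  20 keV, 0.95 at 30 keV, →1 above 100 keV);
- **coherent**: a power-law surrogate ∝ Z^2.2/A · E^−1.7 anchored to oxygen
  at 100 keV (correct to a few tens of percent — acceptable for a partial
  that stays below ~7% of the total in these media);
- **photoelectric**: for H, C, Ti, Fe by subtraction from directly authored
  standard totals; O and N derived so that the compound water and air tables
  reproduce the standard compound values *exactly* at every node; remaining
  elements from a per-energy Z-power-law fit to the trusted elements
  (τ·A ∝ Z^4.0–4.4), with fixed above-edge slopes and K-jump ratios 6.5 (Mo)
  and 5.2 (Yb);
- **μ_en/ρ**: for water/air constituents re-derived from the standard
  compound mass energy-absorption tables (again exact for water and air at
  nodes); for metals and Yb from the transfer decomposition
  τ·(1 − K-fluorescence escape) + incoherent·f_tr(E), with f_tr the
  Klein-Nishina energy-transfer fraction computed by quadrature.

Consequences worth knowing: water and air — the media that dominate every
scored quantity — carry standard-table accuracy; source-material coefficients
are physics-scaling approximations good to ~10–20%, entering only through
capsule/core self-filtration corrections of order 15%. Yb photoelectric below
~20 keV ignores the L-edge structure (irrelevant: such photons cannot escape
the core). Compton sampling uses the exact free-electron Klein-Nishina
angular law (rejection with the forward envelope; acceptance efficiency
> 0.55 over 10–350 keV); the angle-dependent incoherent structure factor is
not sampled. Rayleigh redirection uses a Thomson (1 + cos²θ) surrogate rather
than form-factor-peaked angles; switching it to the opposite (straight-
through) limit moves g_L(10 cm) by only ~2%, bounding the sensitivity.
Optional K-fluorescence emission after photoelectric absorption in the core
exists in the kernel design space but is off by default: the seed's K X-ray
budget is already represented in the decay spectrum, and capsule fluorescence
falls below the cutoff.

### Transport and scoring

Analogue transport (no variance reduction): free paths from the local total
μ, exact ray/cylinder/sphere boundary intersections with an ε = 10⁻⁷ cm
nudge, photoelectric termination, Klein-Nishina redirection with the exact
Compton kinematic energy, Thomson redirection for coherent events, and a
10 keV cutoff (sub-10 keV photons have sub-millimetre range in water and
cannot reach the nearest scoring shell; local absorption). Electrons are not
transported: at these energies secondary electrons are absorbed within
~0.1 mm, so collision kerma equals absorbed dose at the scoring points
(charged-particle equilibrium) — the same approximation the benchmark
dataset itself invokes.

*Water phantom* (50 cm radius sphere): expected-value collision estimator —
each collision in water scores E·μ_en(E)/μ_tot(E) into the shell×cone bin
containing the collision site. The canonical grid matches the benchmark
tables: 0.5 cm-thick shells centred on r = 0.5, 1, …, 10 cm and 4°-wide
cones centred on θ = 0°, 10°, …, 180° (full caps 0–3° and 177–180°), with
analytic volumes V = (2π/3)(r₂³−r₁³)(cosθ₁−cosθ₂). An alternative
cylindrical ρ–z mesh scoring mode (0.25 cm radial × 0.05 cm axial pitch) is
re-binned onto the polar grid by mass-weighted averaging of the cells
between common virtual surfaces.

*Air-kerma geometry*: the seed in a 1 m vacuum sphere with an air ring
detector (shells 97.5/102.5 cm ∩ cones 88°/92°). Because the phantom is
vacuum, each escaping photon contributes deterministically through a
track-length estimator, E·(μ_en/ρ)_air·ℓ/V_ring; attenuation and re-scatter
over the ~5 cm air path (< 0.1%) are neglected. The volume-averaged ring
kerma is referenced to d = 100 cm with the analytic 1/r² bin-centre factor
(1.0002). S_K = K̊·d²; with the rate in cGy/h/mCi and d in cm the product is
numerically in U/mCi.

Unit conversion: one history is one emitted photon; dose rate per contained
mCi is (keV/g per history) × 1.602 177×10⁻¹⁶ J/keV × 10³ g/kg × 100 cGy/Gy ×
3.7×10⁷ decay/s/mCi × yield photons/decay × 3600 s/h.

Uncertainties are batch-means standard errors (default 20 batches); bins
with zero score report NaN uncertainty rather than a silent zero. Each batch
seeds numba's RNG with a deterministic function of the user seed and batch
index, so a fixed seed reproduces results bit-for-bit; a lost-particle
counter (step-guard overflow) must stay at zero or the run aborts.

## TG-43 extraction conventions

g_L(r) = [D(r,90°)/G_L(r,90°)] / [D(1,90°)/G_L(1,90°)] and
F(r,θ) = [D(r,θ)/G_L(r,θ)] / [D(r,90°)/G_L(r,90°)] are pure algebra on the
polar grid; g_L(1) = 1 and F(r, 90°) = 1 hold exactly by construction, and
extraction followed by reconstruction is the identity at grid nodes for any
positive table. The geometry function uses β computed from two arctangents
with the analytic on-axis limit 1/(r² − L²/4); it matches brute-force line
integration to better than 10⁻⁶ relative. Reconstruction interpolates g_L
log-linearly in r and F bilinearly in (r, θ) — the convention of
treatment-planning practice — and refuses to extrapolate (the isodose plane
helper clamps radii to the tabulated boundary, a plotting convenience). The
radial fit is ordinary least squares on the 11 tabulated radii with R²
against the mean model; Λ is reported at full precision and compared to the
2-decimal published value within ±0.01.

Re-deriving g_L and F from the *printed* dose-rate table reproduces the
printed parameter tables within ±0.005 for r ≤ 3 cm (g_L) and within ±0.01
on the well-conditioned anisotropy cells (r ≤ 2 cm, 20–160°). At larger
radii the printed dose rates carry only 2 significant figures and the
recomputation is intrinsically unreliable (e.g. g_L(10) from rounded inputs
deviates ~5% from the printed value); those cells are reported as
informational, not mandatory, in the validation report.

## Synthetic data

The generator emulates exactly the multiplicative structure the formalism
asserts: D = C·G_L·g*·F*·(1+ε) with a known Λ* (default 1.14 cGy/h/U), g*
the published fifth-order polynomial renormalised to g*(1) = 1, an
anisotropy dip F* = 1 − A(r)cos²θ with A decreasing in r (qualitatively
matching the benchmark surface without copying it), and i.i.d. relative
Gaussian cell noise. It is the oracle for the extraction pipeline: at σ = 0
extraction recovers Λ*, g*, F* to machine precision; at σ = 1% the mean
extracted Λ over 50 replicates stays within 0.5% of truth with spread equal
to the propagated single-cell noise. What it deliberately does *not* emulate:
correlated MC noise between bins, volume-averaging bias, or transport
physics — passing synthetic tests validates the algebra, not the simulator.

## Problem sizes

Default runs are desk-scale: the packaged validation uses 1.2–1.5×10⁷
water-phantom histories (per-bin uncertainty at (1 cm, 90°) ≈ 0.7%) and
2×10⁶ air-kerma histories (≈ 0.2%), a deliberate three-orders-of-magnitude
reduction from the benchmark's 3×10⁸; the corresponding statistical floors
are reported per bin and the 1/√N scaling of the batch-means error is itself
a tested property (fitted slope −0.5 ± 0.05).

## Known limitations

- **Transverse-shell volume averaging**: scoring averages kerma over
  0.5 cm-thick shells, which biases the innermost node low (analytic factor
  ≈ 0.94 on g_L(0.5) relative to a point detector). The published
  benchmark's effectively finer mesh does not share this bias, so simulated
  g_L(0.5) sits ~6% below the printed 0.965; all validated simulated
  quantities (D(1,90°), S_K, g_L(10)) carry < 2% of it.
- **Polar anisotropy**: a solid 0.6 cm Yb₂O₃ core at 7.1 g/cm³ filters the
  axial ray far more strongly than the benchmark's printed F(θ≈0°) of
  0.6–0.7 implies (simulated values reach 0.3–0.4). The benchmark seed's
  axial construction (core segmentation, end-weld geometry) is not
  published; near-axis simulated anisotropy should be treated as
  model-specific. Extraction from the *printed* table is unaffected.
- **Cross-section fidelity**: source-material coefficients are constructed
  approximations (see above); the stochastic validation bands (10%; 5% for
  the Λ ratio, where normalisation largely cancels) are sized for this
  model class.
- No electron transport, bremsstrahlung, Doppler broadening, polarisation,
  or decay-chain time evolution; single-seed geometry only.
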