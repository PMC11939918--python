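# Methods

## Film-response models

The package works throughout with baseline-referenced, overtone-normalized
observables: ΔF = F_n/n in Hz and ΔD in units of 10⁻⁶ ("dissipation
units"), time in minutes, areal mass in ng/cm², thickness in nm, density in
g/cm³, moduli in Pa. Because every trace is referenced to a baseline
recorded in the same liquid, the solvent (Kanazawa) terms of the
rigid-in-liquid and viscoelastic film equations cancel exactly and only the
film terms are implemented.

*Rigid films* follow the Sauerbrey relation m_f = −CΔF with
C = 17.8 ng/cm²/Hz for a 5 MHz crystal; the quartz areal mass is not an
independent parameter (m_q = C·F₀ = 0.89 kg/m²) and is validated as such.
*Viscoelastic films* use the thin-film limit of the Voigt model,

ΔF = −(m_f/C)·[1 − (2/ρ_f)(η_L/δ_L)² G″/(G′²+G″²)],
ΔD = (m_f/m_q)·(4/ρ_f)(η_L/δ_L)² G′/(G′²+G″²),

where the ρ_f factors sit in the denominator — the only placement that
makes both correction terms dimensionless and that agrees with the
Voigt/Voinova small-thickness expansion. The acoustic decay length is
taken in its standard form δ_L = √(η_L/(π n F₀ ρ_L)) (≈ 141 nm in water at
23 °C for n = 3), which is the only form consistent with a Kanazawa-type
solvent term; it is the sole carrier of overtone dependence, so the rigid
limit G′ → ∞ is overtone-independent by construction. Liquid properties
default to water at 23 °C (η = 9.32×10⁻⁴ Pa·s, ρ = 0.9975 g/cm³);
25 °C and 35 °C constants are provided for the off-temperature runs.

The hydration-corrected bilayer thickness subtracts a 102 ng/cm² water
layer (the literature value for the film between silica and bilayer) from
the Sauerbrey mass before converting to nm; a negative remainder clips to
zero and sets a flag rather than returning an unphysical thickness.

## Trace I/O and baseline

Traces are plain UTF-8 CSV with `#` metadata lines (units, normalization
state, baseline window, flow-schedule events `lipid_start`, `lipid_end`,
`rinse` in minutes). Values are written with full `repr` precision so
write→read round-trips are exact and re-emission is byte-identical; the
delimiter and decimal separator are deliberately not configurable. Baseline
correction subtracts each series' mean over a window that must end no later
than `lipid_start` (default: the minute preceding it) and is idempotent.
Overtone normalization (dividing raw F_n shifts by n) is guarded by a
state flag so it cannot be applied twice.

## Feature extraction

The analysis overtone defaults to the 7th (a middle overtone, far from
both the bulk-liquid-sensitive 3rd and the surface-sensitive 11th).
Smoothing is a centered moving median (default 5 samples), robust to
spikes without biasing the minimum location; t_ads is the time from
`lipid_start` to the global minimum of the smoothed ΔF, and ΔD_max is the
maximum of the smoothed ΔD, reported even when its time differs slightly
from the frequency minimum (it generally does).

The terminal plateau is the longest trailing segment in which the local
slope of smoothed ΔF stays below 0.5 Hz/min, required to span at least
2 min. The slope is estimated by windowed least squares over a ±0.5 min
window (computed with uniform filters); the trailing half-window, where a
centered window degenerates, reuses the last full-window estimate — a
plain finite difference there is noise-dominated and produces spurious
"still drifting" failures. Asymptotes are means of the raw series over the
plateau; t_rup is the time from the frequency minimum to first entry into
a ±1 Hz band around ΔF_asymp. If |ΔF_asymp − ΔF_min| < 2 Hz the trace is
labelled unruptured and t_rup = +∞ (represented as a true infinity and
serialized as the string `"inf"`). All thresholds are configurable via
`FeatureParams`.

The deformed-vesicle height fits, per overtone, a least-squares line to
ΔD/ΔF against ΔF over the adsorption window (default `lipid_start` to the
frequency minimum), excluding samples with |ΔF| < 5 Hz where the ratio
blows up, and requiring at least 10 usable points. Each line's ΔF-axis
crossing is its zero-dissipation intercept; intercepts are aggregated by
unweighted mean (no principled weighting is available for a "common
intercept"), and the per-overtone values and spread are reported so the
user can judge commonality. A fitted slope below 10⁻⁶ per Hz raises an
extrapolation error instead of returning an arbitrarily large intercept —
this is exactly the rigid-film degenerate case, where the direct Sauerbrey
thickness should be used instead.

## Rates, classification, osmotic labels

R_ads = −ΔF_min/t_ads and R_rup = −(ΔF_min − ΔF_asymp)/t_rup, with
R_rup ≡ 0 when t_rup = ∞. R_ads ≥ R_rup is *not* enforced — one of the
single-lipid runs in the packaged table violates it.

Classification uses the asymptotic state only: SLB if |ΔF_asymp| ≤ 36 Hz
and ΔD_asymp ≤ 1.0×10⁻⁶; SLV if |ΔF_asymp| ≥ 50 Hz; otherwise partial.
The 36/50/1.0 defaults are midpoints between the empirically observed
bands (≈26–30 Hz vs 42–46 Hz vs ≥55 Hz; ΔD < 0.5 vs > 1.0) and are
configurable, since the bands themselves are the only printed anchors.
Applied to the packaged 17-run summary table, the rule reproduces every
narrative outcome.

Osmolarity is ideal van't Hoff with fixed dissociation counts (NaCl 2,
CaCl₂ 3, MgCl₂ 3, Tris 1 per mM; phosphate treated as a 1:1 salt at 2 per
mM — its exact speciation is pH-dependent, but phosphate content is
identical within every compared buffer pair, so the approximation cancels).
Exterior − interior differences beyond ±10 mOsm are labelled
hyper-/hypoosmotic; the 10 mOsm dead band keeps the 2.5 mM MgCl₂
difference of the isosmotic protocol (7.5 mOsm) from being mislabelled.
The NaCl-equivalent is delta/2. Under these counts the B2→B5 step comes
out at 153.75 mM NaCl-equivalent where the experimental description
rounds to 150 mM (it ignores the small MgCl₂ contribution).

## Packaged tables

The experimental-conditions table (buffers, vesicle sizes, flow schedules)
and the per-run summary table (six features, rates, deformed heights for
all 17 runs) ship as CSV fixtures. Two transcription notes: the 11D row's
asymptotic frequency shift is printed without a minus sign in the source
and is stored as −27.9 Hz (sign typo — a positive asymptote is physically
impossible there); printed rates that are inconsistent with their own
rounded inputs (e.g. the 12A(c) row) are kept as printed but only the
arithmetic-self-consistent rows (2A, 6A, 11A) are asserted in tests.

## Synthetic-trace generator

No instrument data are deposited, so the simulator is the package's data
source. It emulates the three fingerprints with the simplest mechanism
consistent with the critical-coverage picture: Langmuir adsorption of
vesicles (rate k_ads, only while lipid flows), first-order rupture
(k_rup) gated by total coverage reaching θ_crit, vesicle coverage
transferring one-for-one to bilayer coverage, and cumulative rupture
capped at `rupture_fraction` of cumulative adsorption to produce partial
end states. Integration is explicit fixed-step at the sampling interval
with 10 internal substeps (rates are ≤ a few per minute; a stiff solver
would be overkill), with adsorption clamped so total coverage cannot
exceed 1.

The acoustic rendering composes the film models: the intact-vesicle layer
(mass θ_v·m_vesicle_sat, lipid plus intra- and inter-vesicle water,
lumped) goes through the viscoelastic model, the bilayer
(θ_b·m_bilayer) through the rigid model. Water release on rupture is
implicit in the mass drop m_vesicle_sat → m_bilayer. The effective
vesicle-layer moduli stiffen with crowding, G_eff = G₀/(1 − θ_v)
(floored at 10⁻³): sparse vesicles wobble and dissipate strongly per unit
mass, a close-packed layer approaches a rigid slab. This choice has a
deliberate consequence: during adsorption ΔD/ΔF becomes linear in ΔF with
a common zero-dissipation intercept at −m_vesicle_sat/C on every overtone,
so the generator possesses an exact ground truth for the deformed-height
extrapolation, h_true = m_vesicle_sat/ρ.

Noise is i.i.d. Gaussian per sample and overtone (defaults 0.2 Hz and
0.05×10⁻⁶, small relative to the tens-of-Hz signals), seeded and
bitwise-reproducible. Default sampling is dt = 0.02 min over 13–22 min
depending on preset — enough to hold a ≥ 2 min terminal plateau while
keeping a full pipeline run in milliseconds.

Preset parameters are calibrated so the analyzed features land on the
magnitudes of representative runs: `dopc_fig2` (single-lipid complete SLB:
t_ads ≈ 2.1 min, ΔF_min ≈ −56.5 Hz, ΔF_asymp ≈ −25.1 Hz, intercept
≈ −113 Hz), `slb` (multicomponent SLB ending ≈ −30 Hz), `partial`
(≈ −43 Hz with ΔD_asymp ≈ 2×10⁻⁶), and `slv` (no rupture, plateau
≈ −95 Hz, ΔD ≈ 17×10⁻⁶, strongly split overtones).

What the simulator does *not* emulate: spatially resolved adsorption,
diffusion-limited kinetics, osmotic mechanics inside the model (osmotic
stress enters only through preset parameter choices), baseline drift,
rinse-step artifacts, or two-stage rupture. Passing round-trip tests
therefore demonstrates that the analysis recovers what this generative
model produces at realistic magnitudes — not that it is robust to every
artifact of real instrument exports.

## Numerical and degenerate-input choices

Invalid physical parameters raise `InvalidParameterError` at construction;
G′ = G″ = 0 is rejected in the viscoelastic model (undefined loss
fraction). Non-finite rows in trace files are rejected with their indices;
non-monotone time is a parse error naming the row. The plateau detector
raising `PlateauNotFoundError` is the designed signal that a recording is
too short. The no-rupture tolerance (2 Hz), plateau criteria, and
classification boundaries are all single-sourced defaults in
`FeatureParams`/`ClassificationBoundaries`.

## Known limitations

The Voigt model is used in its thin-film, frequency-independent-moduli
limit; no inverse (Voinova multilayer) fitting of G′, G″, h from data is
attempted. The deformed-height fit assumes the adsorption-phase ΔD/ΔF
trend is linear — multi-stage adsorption would need a windowing the
package does not automate. Osmolarity is ideal (no activity coefficients),
adequate only because conditions are compared within buffer pairs sharing
their non-NaCl content. The summary-table fixtures carry the source's
printed rounding; recomputed rates can differ from printed rates in rows
where the printed inputs were rounded after the fact.
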