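# Methods

## The problem

Natural gas escaping through mud volcanoes and seeps is a mixture shaped by
its thermogenic source and by what subsurface microbes have done to it
since: anaerobic oxidation of the C2+ alkanes, and methanogenesis fed by
the oxidation products ("secondary microbial methane").  Bulk isotope
ratios alone are ambiguous — several process combinations produce similar
bulk signatures.  The package implements a position-specific route: the two
carbon positions of propane record biodegradation very differently, and
that asymmetry is close to process-specific.

## Position-specific reconstruction

On-line pyrolysis splits propane into CH4, C2H4 and C2H6 fragments.  CH4
and C2H6 derive from the terminal carbons only; C2H4 carries one terminal
and one central carbon.  With A the peak areas and δ the fragment δ¹³C:

    δ¹³C_terminal = (δ_CH4·A_CH4 + δ_C2H6·A_C2H6) / (A_CH4 + A_C2H6)
    δ¹³C_central  = 2·δ_C2H4 − δ¹³C_terminal
    Δ¹³C_central  = δ¹³C_central − δ¹³C_terminal

Weighting is by raw peak area, as the reconstruction is conventionally
written; the identity Δ = 2(δ_C2H4 − δ_terminal) makes the offset robust to
the area normalisation.  The bulk molecular value closes the 2:1 mass
balance, bulk = (2·terminal + central)/3; on the packaged tables every
reconstructed bulk agrees with the measured one to ≤ 0.1 ‰ (one rounding
unit of the printed values).  Exceedances are flagged, not fatal.

Uncertainty is propagated by Monte Carlo (default 10 000 draws, seed
mandatory): each fragment δ is resampled with its 1σ, positions are
recomputed per replicate injection and averaged (area-weighted within a
replicate, replicates combined unweighted — mirroring how 3–5 injections
are averaged in practice).  For small σ the Monte-Carlo σ agrees with
first-order propagation, var(Δ) = 4σ²_C2H4 + 4(w₁²σ²_CH4 + w₂²σ²_C2H6),
within 5%.

## Rayleigh inversion for biodegradation extent

Anaerobic propane oxidisers attack the central C–H bonds (fumarate addition
in the characterised sulfate-reducing isolate), so the central
¹³C-isotopologue reacts more slowly and the residual propane enriches at
the central position.  The pure-culture fractionation factors are
ε_central = 33 ‰ and ε_terminal = 3 ‰ (residue-enriching sign convention,
ε ≈ 1000(α − 1)).  Using the residual-substrate form

    δ(f) = (δ₀ + 1000)·f^(−ε/1000) − 1000,

and assuming unbiodegraded thermogenic propane has no central excess
(Δ₀ = 0), the measured offset inverts to the fraction remaining

    f = ((1000 + Δ₀)/(1000 + Δ))^(1000/ε_central),   extent B = 1 − f.

The inversion applies ε_central to the offset directly, treating the
terminal position (ε = 3 ‰) as a quasi-conservative internal reference.
This convention is a design choice — the offset of two Rayleigh pools is
not itself exactly a Rayleigh pool — but for these ε values the alternatives
(ε_central − ε_terminal on the offset; joint inversion of both positions)
differ by under ~2 percentage points of extent, well inside the spread
induced by the unknown field fractionation factors.  Samples whose offset
is below detection propagate to "no estimate" rather than zero.  Offsets
below Δ₀ are rejected (they would imply negative extent).  For small Δ the
exact inversion agrees with the linearisation B ≈ 1 − exp(−Δ/ε) to < 0.5
percentage points.

Archaeal propane oxidisers activate the terminal position instead and
their fractionation factors are unmeasured; no attempt is made to fit
them.  The extent estimates therefore carry the stated bacterial ε as an
explicit assumption, exposed in `RayleighParams`.

## Co-degradation, secondary methane, source fields

*Ethane*: propane and ethane mole percentages are regressed by OLS
(propane as response).  A linear co-depletion shows up as a straight
concentration-concentration trend; on the five Murono samples the slope is
0.4.  The regression orientation matters and is fixed: propane on ethane.

*Secondary methanogenesis* is scored by three signs: every δ¹³C_CO2 above
a threshold (default +15 ‰ — the observed values, +19.1 to +34.5 ‰, are
far above any primary-CO2 expectation, and the cutoff is configurable
because no canonical boundary exists); Pearson r(Δ, δ¹³C_CH4) < 0 (added
microbial methane is ¹³C-depleted relative to the thermogenic end member);
and r(Δ, %CH4) > 0.  The verdict is "consistent" only when all three hold;
missing series degrade the verdict to "indeterminate" rather than a guess.

*Source fields* (Schoell: δD vs δ¹³C of methane; Bernard: C1/(C2+C3) vs
δ¹³C) are configuration, not code: editable YAML polygons encoding the
conventional genetic fields, with first-listed-field-wins tie-breaking.
A sample in the thermogenic δ¹³C band whose Bernard ratio exceeds a
threshold (default 100) is flagged "altered" — thermogenic gas stripped of
C2+.  Two-end-member mixing uses concentration-weighted blending,
δ_mix = Σ xᵢCᵢδᵢ / Σ xᵢCᵢ, which conserves isotope-weighted concentration
exactly.

## The synthetic generator

`mudgas.synth` emulates the processes above with full ground truth, for
pipeline validation without any external data.  Per sample: draw f; evolve
the terminal position by Rayleigh with ε_terminal and the *offset* by
Rayleigh with ε_central (central = terminal + offset).  Modelling the
offset, rather than the central position, as the ε_central Rayleigh pool
makes the generator the exact forward model of the inversion, so noise-free
recovery is exact by construction; the alternative (independent Rayleigh
evolution of both positions) would fold the inversion-convention
approximation (~4 pp at these ε) into every recovery experiment and
conflate two separate questions.  Ethane co-depletes linearly in the
propane consumed, g = 1 − ρ(1 − f) with ρ = 0.4 (a first-order option
g = f^ρ exists behind a flag), with a small Rayleigh enrichment
(ε_ethane = 5 ‰, matching the narrow observed ethane δ range).  Oxidised
carbon joins the CO2 pool with exact isotope mass balance; methanogens
convert `ch4_yield` of it to CH4 (default 0.7 mol CH4 per mol C oxidised —
between hydrogenotrophic-only turnover and full methanogenic alkane
conversion, and high enough that the methane fraction visibly rises with
extent once CO2 losses to the aqueous phase are not modelled) with an
effective ε of 60 ‰, enriching the residual CO2 and depleting the added
methane.  Fragment tables are synthesised in a fixed area stoichiometry
(A_CH4 : A_C2H4 : A_C2H6 = 1 : 1 : 0.3; the reconstruction is
weighting-robust) for 3 replicate injections.

Default study conditions: 7 samples, f ∈ [0.29, 0.45] (extents 55–71%),
source gas 93% CH4 / 3.5% CO2 / 1.25% C2H6 / 0.2% C3H8 (the C3/C2 ratio of
0.16 makes the linear co-depletion slope C3₀/(ρ·C2₀) = 0.4 by
construction), terminal position −24 ‰ with zero initial offset, source
δ¹³C_CO2 = +20 ‰ (reservoir CO2 in such systems is already
methanogenesis-processed; a primary-CO2 value near 0 ‰ would need far more
per-sample turnover than the gas-phase budget provides to reach the
observed +19 to +35 ‰), δ¹³C_CH4 = −34 ‰, δD_CH4 = −170 ‰ (held constant:
the D budget of added methane is not modelled).  Noise: σ = 0.5 ‰ on bulk
deltas; the 1.5 ‰ per-injection offset repeatability is distributed over
the three fragment deltas via the linear-propagation relation.

What the generator does not emulate: reservoir mixing between distinct
end members (the mixing operation exists but is not wired into the
generator), migration/diffusion fractionation, temperature dependence of
ε, compositional measurement error, and site heterogeneity (one source per
scenario).  Passing recovery tests therefore demonstrate the pipeline's
internal consistency and noise behaviour, not robustness to
source-mixing confounds in real data.

## Guild annotation

Taxon names (bare genera or SILVA-style lineage strings) are matched
case-insensitively at a declared rank against an editable YAML lookup
covering hydrogenotrophic and acetoclastic methanogens, ANME, the
sulfate-reducer orders, Rhodocyclaceae (nitrate-coupled alkane oxidation)
and Geobacter (iron-coupled).  When rules at different ranks both match —
the genus Geobacter sits inside the sulfate-reducer order
Desulfuromonadales — the most specific rank wins; equal-rank conflicts
raise an error demanding lookup disambiguation.  The consistency report is
deliberately qualitative: secondary methanogenesis is "supported" when
methanogens co-occur with a consistent isotope indicator, C2+ oxidiser
candidates are listed when biodegradation is isotopically evident, and
near-absent ANME (< 0.9%) is noted as arguing against anaerobic methane
oxidation.

## Numerical and interface choices

- Tri-state cells (value | below-detection-limit | missing) throughout;
  bdl contributes zero only to the composition-closure check and is
  excluded from every statistic and regression.  Tables round-trip
  bit-for-bit including bdl states.
- Packaged fixtures follow the printed tables; where a narrative range
  disagrees with a table cell (e.g. a CH4 maximum of 96.66 vs a printed
  96.74), the table wins and summaries operate on table values.
- All stochastic code (Monte-Carlo propagation, the generator) takes a
  mandatory seed; identical config + seed reproduces outputs
  byte-identically.
- Report rounding: 1 decimal for ‰, whole percent for extents in the
  markdown report; CSV/JSON keep full precision.
- Problem sizes: the packaged analyses run on the 7 field samples;
  recovery experiments default to 12–200 synthetic samples and 10 000
  Monte-Carlo draws, which characterise the estimator's bias and spread
  to well under the 2-percentage-point tolerance used in the tests.

## Known limitations

- The extent inversion inherits pure-culture ε values measured in one
  condition set; field communities (archaeal activation, temperature,
  substrate limitation) may fractionate differently, and the exact ε
  convention behind any published extent range is not recoverable from
  printed values alone — the package asserts the printed 55–71% envelope
  as bounds, not as point equalities.
- Gamou and Murono likely differ in source gas; the single-source
  generator and the Δ₀ = 0 assumption are simplifications.
- Bernard/Schoell field boundaries are editable approximations of drawn,
  never tabulated, diagram fields.
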