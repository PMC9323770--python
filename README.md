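# mudgas

Hydrocarbon-cycling diagnostics for mud-volcano and seep gases: position-
specific ¹³C analysis of propane, Rayleigh inversion for the extent of
anaerobic biodegradation, conventional gas-source classification,
secondary-methanogenesis indicators, a synthetic-data generator with known
ground truth, and metabolic-guild annotation of 16S-derived abundance
tables.

It is aimed at isotope biogeochemists working on natural gas seeps: people
who have GC/IRMS gas compositions and delta values (and possibly
pyrolysis-fragment measurements of propane) and want to answer, with
explicit assumptions, *is this gas biodegraded, by how much, and is the
methane partly secondary-microbial?*

## The science in brief

Anaerobic propane oxidisers activate propane at the **central** carbon, so
the central ¹³C-isotopologue of the residual pool reacts slowly and the
central position enriches far faster than the terminals.  Pyrolysis
fragments recover the two positions:

    δ¹³C_terminal = (δ_CH4·A_CH4 + δ_C2H6·A_C2H6) / (A_CH4 + A_C2H6)
    δ¹³C_central  = 2·δ_C2H4 − δ¹³C_terminal
    Δ¹³C_central  = δ¹³C_central − δ¹³C_terminal

With pure-culture fractionation factors (ε_central = 33 ‰,
ε_terminal = 3 ‰) and an unbiodegraded starting offset Δ₀ = 0, the
residual-substrate Rayleigh law

    δ(f) = (δ₀ + 1000)·f^(−ε/1000) − 1000

inverts the measured offset for the fraction of propane remaining f and
the extent of biodegradation B = 1 − f.  Around that core sit the standard
diagnostics: the Bernard ratio C₁/(C₂+C₃) and Schoell δD–δ¹³C genetic
fields, ethane/propane co-depletion slopes, and the three-way
secondary-methanogenesis indicator (¹³C-enriched residual CO₂, methane
δ¹³C falling and methane fraction rising with Δ¹³C_central).  See
`docs/methods.md` for assumptions and conventions.

## Worked example

The package ships the seven-sample Tokamachi (Niigata, Japan) field
tables — two Gamou mud-volcano samples, five Murono samples:

```python
from mudgas import biodeg, datasets, psia

records = datasets.load_tokamachi()
g1 = {r.id: r for r in records}["G-1"]

# position mass balance: offset and 2:1 bulk closure
off = psia.central_offset(g1.isotope_value("d13c_central"),
                          g1.isotope_value("d13c_terminal"))
bulk = psia.bulk_from_positions(g1.isotope_value("d13c_terminal"),
                                g1.isotope_value("d13c_central"))
print(off, round(bulk, 1))          # 31.5  -9.8

# Rayleigh inversion, eps_central = 33, initial offset 0
for e in biodeg.extents_for_records(records):
    print(e.sample_id, round(e.extent_percent))
```

```
G-1 61
G-2 60
M-1 58
M-2 57
M-4 70
M-5 67
```

G-1's central position carries a +31.5 ‰ excess over its terminals, and
the 2:1 mass balance reproduces the measured bulk propane value of
−9.8 ‰.  The six samples with a measured offset span extents of 57–70%
propane consumed; M-3, whose offset is below detection, yields no
estimate rather than a zero.  The Murono concentration trend gives a
propane-on-ethane slope of 0.4 (ethane co-degrades at ~40% the rate of
propane), and the secondary-methane indicator returns
`consistent with secondary methanogenesis`.

The same steps are available as narrative drivers — `analysis/01_...` to
`analysis/07_...` — which print these numbers and write tables under
`results/`, and as a CLI (`mudgas ingest|psia|biodeg|classify|simulate|
guilds|run`).

## Synthetic validation

`mudgas.synth` generates seep-field scenarios with full ground truth
(Rayleigh-evolved positions, linear ethane co-depletion, secondary
methanogenesis with exact carbon bookkeeping, instrument noise) and
`recovery_experiment` pushes them through the fragment-reconstruction +
inversion pipeline: recovery is exact with noise off, and with the stated
instrument noise (0.5 ‰ bulk, 1.5 ‰ offset repeatability) the mean
recovered extent at n = 200 sits within 0.1 pp of truth
(`analysis/06_synthetic_recovery.py`).

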