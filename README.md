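# mcsdr

Design and in-silico analysis of **mismatch-closure-mediated strand
displacement** probes for single-nucleotide-variant (SNV) detection.

A toehold-mediated strand displacement reaction reads out a DNA target by
letting it invade a fluorophore/quencher reporter duplex; as an SNV probe it
discriminates poorly, because a single mismatch barely changes either the
reaction free energy or the long-time kinetics.  The mismatch-closure design
adds a *helper strand* that base-pairs over the interrogated site of the
unwanted allele.  The closure shortens that allele's effective toehold,
reassigns the first branch-migration base to the unpaired spacer, and gates
branch migration behind a rare base-breathing event — so the unwanted allele
is penalized both thermodynamically,

    ΔΔG = ΔG_rxn(MM) − ΔG_rxn(PM)   (nearest-neighbor model),

and kinetically, through the breathing-gated pathway

    A + B ⇌ I → I* → … → C + D,   k_open = ν·exp(−ΔG_open/RT),  k_close = ν,

with undocking coupled to the toehold free energy by detailed balance,
`k_undock = k_dock·C°·exp(ΔG_toehold/RT)`.  The package implements the
sequence/domain model and probe builder, the nearest-neighbor energy
landscapes, the one-step/two-step/multi-closure ODE kinetic models, apparent-
rate fitting from fluorescence traces (simplex, negative-parameter penalty),
the DF/yield/DDF figures of merit, a design-grid sweep, and a seeded
synthetic plate-reader data generator — so the whole analysis is testable
without wet-lab data.  It is aimed at nucleic-acid probe designers and
DNA-nanotechnology modellers.

## Worked example

```python
from mcsdr import thermo, kinetics, reference

system = reference.reference_system()          # 8 nt toehold, 1 closure
tp = thermo.ThermoParams()

for mode in ("tSDR", "mcSDR"):
    pm = thermo.landscape(system, "PM", mode, tp)
    mm = thermo.landscape(system, "MM", mode, tp)
    print(f"ddG {mode}: {thermo.ddG(pm, mm):.2f} kcal/mol")

t = kinetics.fit_time_grid(3600.0)
for variant in ("PM", "MM"):
    tr = kinetics.simulate_mcsdr(system, variant, A0=250e-9, B0=250e-9, t_grid=t)
    k = kinetics.apparent_second_order_rate(tr, 250e-9, 250e-9)
    print(f"{variant}: apparent k = {k:.3g} /M/s, 1 h yield = {tr.endpoint/250e-9:.3f}")
```

prints

```
ddG tSDR: 1.97 kcal/mol
ddG mcSDR: 4.92 kcal/mol
PM: apparent k = 7e+03 /M/s, 1 h yield = 0.871
MM: apparent k = 62.6 /M/s, 1 h yield = 0.053
```

Read: on the bundled reference design (a synthetic KRAS-codon-12-like
context at 250 nM strands, 37 °C), a traditional probe separates the alleles
by only 1.97 kcal/mol, while one closure raises the gap to 4.92 kcal/mol;
kinetically the matched target reacts ~110× faster, so after an hour it has
converted 87 % of the probe versus 5 % for the mismatched allele (endpoint
DF ≈ 16, and far larger at higher closure counts — see
`kinetics.sweep_grid`).

A CLI wraps the same library:

```bash
mcsdr landscape --config config.json --out out/   # landscapes + ddG summary
mcsdr sweep --out out/                            # 6x5 toehold x closure grid
mcsdr synth --config config.json --seed 7 --out out/   # synthetic VAF panel
mcsdr fit --traces out/panel_traces.csv --a0 250e-9 --b0 250e-9 --slope 1e9 --out fits.json
```

where `config.json` holds `{"design": {...}}` as written by
`strand_model.save_design`.

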