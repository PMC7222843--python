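# slurrycbc

Buffer-capacity analysis of acid/base titrations of animal slurry.

Whether slurry is acidified (to curb NH₃ and CH₄ emissions) or alkalized (to
strip and recover ammonia), the dose needed to hit a target pH is set by the
slurry's buffer systems — volatile fatty acids (VFA, pKa ≈ 4.76), the
carbonate couples (pKa 6.35 and 10.33) and ammonia (pKa 9.25) — whose
strengths drift over weeks of storage. `slurrycbc` turns raw titration logs
into **current buffer capacity** (CBC) curves,

```
CBC(pH) = | 1 / (dpH/dn) |        n = titrant amount, mol per kg slurry
```

by fitting a 6th-degree polynomial pH = p(n) over a protocol-defined pH
window, differentiating it analytically and taking the reciprocal absolute
slope. From the CBC curve it extracts per-buffer peak capacities and their
pH, and from the raw dosing data the acid/base amounts spent between pH
bounds (initial→7.0, 7.0→5.5, 5.5→3.0, 9.5→11.5) for storage-series
reporting. A closed-system multi-buffer charge-balance **simulator**
generates realistic titrations from measured slurry compositions and doubles
as an independent physico-chemical oracle (the classical buffer index
β = dC_B/dpH) for the whole pipeline. See `docs/methods.md` for the model,
its assumptions and its measured accuracy envelope.

## Worked example

Simulate a fattening-pig slurry acidification and analyse it:

```python
import slurrycbc as s

mix = s.preset_mixture("fattening_pig")          # measured week-0 composition
rec = s.simulate_titration(mix, s.acid_protocol(2.5))
fit, curve, peaks = s.analyze_record(rec)

print(f"{rec.n_steps} dosing steps, initial pH {rec.initial_ph:.2f}")
for name, pk in peaks.items():
    print(f"{name}: peak pH {pk.peak_ph:.2f}, "
          f"max CBC {pk.max_cbc:.3f} mol/kg/pH, local max: {pk.is_local_max}")
print(f"acid pH 7.0->5.5: {s.amount_between(rec, 7.0, 5.5):.3f} mol HCl/kg")
```

prints

```
63 dosing steps, initial pH 7.50
VFA: peak pH 4.50, max CBC 0.097 mol/kg/pH, local max: False
HCO3: peak pH 6.00, max CBC 0.081 mol/kg/pH, local max: False
acid pH 7.0->5.5: 0.109 mol HCl/kg
```

Reading: lowering this slurry from pH 7.0 to 5.5 (the acidification target
for emission control) costs 0.109 mol HCl per kg slurry. In both reporting
windows the capacity maximum sits on the window boundary
(`local max: False`): at this VFA level the acetic and bicarbonate shoulders
merge, so the peaks are reported as non-quantifiable suprema rather than
fabricated maxima — exactly the situation that occurs in VFA-rich stored pig
slurry.

The same pipeline runs from the shell on instrument CSV logs via a YAML
manifest:

```
slurry-cbc simulate scenario.yaml -o titration.csv
slurry-cbc qc batch.yaml -o qc.csv
slurry-cbc cbc batch.yaml -o out/
slurry-cbc segments batch.yaml -o segments.csv
slurry-cbc report samples.csv -o report/
```

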