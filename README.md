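# stcmix

Mixture-effect analysis for the zebrafish embryo **spontaneous tail coiling
(STC)** assay: concentration–response fitting, hyperactivity
standardization, concentration-addition and independent-action mixture
prediction, equitoxic and substitution mixture design, and antagonism
evaluation for mixtures whose components push coiling activity in opposite
directions. A seeded generator of synthetic embryo-level coiling counts
makes every stage testable without raw assay data.

## The scientific problem

Neuroactive chemicals co-occur in surface waters, but risk assessment is
done substance by substance. The STC assay quantifies the earliest motor
activity of zebrafish embryos (~24 hpf) as coils per minute; neuroactive
exposure shifts the rate up (hyperactivity) or down (hypoactivity). The
question the analysis answers: can mixture effects on this integrated
behavioural endpoint be predicted from single-substance curves, grouping
components by their *effect direction* rather than their molecular
mechanism — and what happens when directions oppose?

## Models

Single-substance (and mixture) concentration–response is the four-parameter
log-logistic curve

    y(x) = c + (d − c) / (1 + (e/x)^b)

with slope *b*, floor *c* = 0, ceiling *d* = 100 after standardization, and
inflection *e* = EC50. Hyperactive substances plateau at substance-specific
maxima, so raw percent changes are divided by each substance's fitted
maximum *M* to give a common 0–100 scale (the standardized EC50 equals the
raw EC at *M*/2). Confidence intervals are estimate ± 2·SE.

Mixture predictions from standardized component curves with molar
fractions *pᵢ*:

* **Concentration addition (CA, Loewe additivity):**
  `ECx_mix = ( Σᵢ pᵢ / ECxᵢ )⁻¹`; for equitoxic designs
  (*pᵢ ∝ EC50ᵢ*) this reduces to `EC50_mix = (Σᵢ EC50ᵢ)/n`.
* **Independent action (IA, Bliss independence):**
  `E_mix(C) = 1 − Πᵢ (1 − Eᵢ(pᵢ·C))`, inverted for ECx by bracketed
  root-finding.
* **Antagonism (opposing directions):** CA/IA are undefined; the observed
  mixture is compared with the CA expectation of its same-direction subset,
  and judged antagonistic when it falls below that reference by more than
  2·SE at ≥ 2 consecutive tested concentrations. The rise-then-fall
  response is summarized by a Gaussian on log₁₀ concentration with a free
  baseline.

## Worked example

```python
from stcmix import ca_ecx, ia_ecx, equitoxic_design, reference_substances

subs = reference_substances()          # six reference neuroactive substances
design = equitoxic_design(
    [(n, subs[n].crc()) for n in
     ("chlorpyrifos", "hexaconazole", "chlorpyrifos-oxon")],
    label="ternary",
)
print({c.name: round(c.fraction, 3) for c in design.components})
print(round(ca_ecx(50.0, design), 3), round(ia_ecx(50.0, design), 3))
```

prints

```
{'chlorpyrifos': 0.324, 'hexaconazole': 0.603, 'chlorpyrifos-oxon': 0.073}
2.007 2.176
```

i.e. the equitoxic ternary mixture is predicted to halve-shift coiling
activity at ~2.0 µmol/L under CA and ~2.2 µmol/L under IA — the two models
nearly coincide, and both sit within a few percent of the experimentally
observed mixture EC50 (1.95 µmol/L).

The numbered drivers under `analysis/` walk through the full story
(standardization, the five mixture predictions, substitution designs,
synthetic-data parameter recovery, antagonism) and write their tables under
`results/`:

```bash
python analysis/02_mixture_predictions.py
```

## Command line

`stcmix` exposes the stages as subcommands:

```bash
stcmix simulate  --scenario scenario.yaml --seed 1 --out records.csv
stcmix normalize --records records.csv --out normalized.csv
stcmix fit       --normalized normalized.csv --direction hyperactivity --out params.csv
stcmix predict   --model both --design design.yaml --out predictions.csv
stcmix antagonism --observed normalized.csv --reference predictions.csv --out report.csv
stcmix run       --config config.yaml
```

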