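# stereocleave

RNase H — the enzyme recruited by gapmer antisense oligonucleotides (ASOs) —
discriminates between the two stereoconfigurations (*R*p and *S*p) of the
phosphorothioate (PS) linkages on the DNA strand of an RNA–DNA heteroduplex.
`stereocleave` re-implements, as a tested analysis pipeline with a synthetic
data generator, the computational chain used to measure that discrimination
for *E. coli* RNase H:

- **chirality-by-base encoding** — degenerate libraries in which the identity
  of each base encodes the chirality of the PS linkage on its 3′ side, so PS
  stereochemistry can be read out by sequencing (four libraries, two mutually
  opposite encodings);
- **the massive-parallel screen** — limited digestion of circular 9-nt
  heteroduplex substrates, sequencing of the uncleaved-circular vs control
  fractions, window-trimer counting, exact-test differential abundance with
  Benjamini–Hochberg FDR, and cross-encoding consistency calls that cancel
  base-sequence effects;
- **kinetic competition** — mass-action ODEs for the catalytic cycle
  E + S ⇌ ES → EP → E + P (optionally with a competitive inhibitor,
  E + I ⇌ EI) explaining why the *S*p-pocket substrate is hydrolysed fastest
  in isolation yet the ranking flips in the presence of a nicked-dumbbell
  inhibitor;
- **cleavage-site mapping** — fragment sequencing where the 3′-trimmed insert
  length encodes the cleavage position affinely, recovering the rule that
  cleavage occurs two nucleotides from an *R*p-PS linkage;
- **dose–response** — four-parameter log-logistic knockdown fits
  f(x) = c + (d − c)/(1 + (x/e)^b) with d fixed at 100% of control, absolute
  IC50 in closed form, and bootstrap potency ratios.

It is written for computational biologists studying ASO design and
stereodefined backbone chemistry; every input is produced by the
`synthetic_data` module with planted, recoverable truths, so the whole chain
is verifiable end to end.

## Worked example

Fit knockdown curves for two epimers of a gapmer that differ only in the
chirality of one strategically placed PS linkage, planted at a 2.5-fold
potency difference:

```python
import numpy as np
from stereocleave.synthetic_data import simulate_dose_response
from stereocleave.dose_response import fit_4pl, absolute_ic50, potency_ratio

conc = np.geomspace(0.1, 100, 8)
planted = {"HIF1A_R": (1.0, 10.0, 100.0, 2.0),   # (b, c, d, e)
           "HIF1A_S": (1.0, 10.0, 100.0, 5.0)}
table = simulate_dose_response(planted, conc, replicates=4, noise_sd=3.0, seed=1)

fits, data = {}, {}
for name, grp in table.groupby("compound"):
    x, y = grp["concentration"].to_numpy(), grp["response_percent"].to_numpy()
    fits[name], data[name] = fit_4pl(x, y), (x, y)

for name, fit in fits.items():
    print(name, round(fit.e, 3), round(absolute_ic50(fit), 3))
pr = potency_ratio(fits["HIF1A_S"], fits["HIF1A_R"],
                   data["HIF1A_S"], data["HIF1A_R"], n_boot=1000, seed=2)
print(round(pr.ratio, 2), (round(pr.ci_low, 2), round(pr.ci_high, 2)))
```

prints

```
HIF1A_R 2.008 2.478
HIF1A_S 5.386 6.349
2.56 (2.31, 2.87)
```

i.e. the fitted inflection `e` and absolute IC50 (concentration reaching 50%
of the untreated mRNA level) per compound, and the S:R potency ratio of 2.56
with a residual-bootstrap 95% CI that covers the planted 2.5.

## Analyses

The numbered drivers under `analysis/` run each study end to end and write
tables under `results/`:

| script | what it does |
| --- | --- |
| `01_screen_chiral_motifs.py` | four-library screen → differential tables + consistency calls (SpSpSp strong-enriched in the uncleaved fraction in both encoding comparisons) |
| `02_competition_kinetics.py` | eight stereo combinations ± inhibitor → final cleaved fractions (pocket-position ranking flip; PO tracks Rp) |
| `03_chem_walk_cleavage_map.py` | chirality walk + HIF1A-style epimers → recovered sites (constant +2 offset; Sp epimer scrambles the pattern) |
| `04_dose_response.py` | epimer knockdown fits → IC50s and potency ratio |

Each takes an optional integer seed (default 1), e.g.
`python analysis/01_screen_chiral_motifs.py 7`.

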