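# Methods

## Coordinates and domain types

All positions are 1-based. A DNA strand of n bases has n − 1 internal
linkages; linkage *i* sits between bases *i* and *i + 1* and is "3′ of base
*i*". A PS linkage is annotated `Rp`, `Sp`, `PO` (unmodified phosphodiester)
or `RANDOM` (stereorandom mixture). `RANDOM` is legal only in compound
designs; decoded sequencing output is always definite, and an n-base
fully-random PS oligo represents 2^(n−1) diastereoisomers.

The four encoding libraries map bases to chirality as synthesised from 1:1:1
amidite mixes:

| library | alphabet | map | encoding class |
| --- | --- | --- | --- |
| L1 | A,G,T | A→Rp, G→Sp, T→Sp | ENC1 |
| L2 | A,C,T | A→Sp, C→Sp, T→Rp | ENC2 |
| L3 | A,G,T | A→Sp, G→Rp, T→Rp | ENC2 |
| L4 | A,C,T | A→Rp, C→Rp, T→Sp | ENC1 |

On the shared {A,T} sub-alphabet ENC1 and ENC2 are exact opposites, which is
what lets a cross-encoding comparison cancel base-sequence effects: the same
chirality motif is carried by complementary base motifs in the two classes.
The informative comparisons are the same-alphabet, opposite-encoding pairs
(L1, L3) and (L2, L4).

## Chem-walk designs and the cleavage-site rule

The walk compounds share one base sequence: a mixed-base segment carrying an
internal positive control cleavage site (IPCCS, a sequence-optimised site
that cleaves regardless of chirality), an 11-dT platform of constant base
composition, and a short 3′ flank. The segment sequences are synthetic
stand-ins (and labelled as such); only the *structure* (defined IPCCS
position, pure-dT tract) matters to any downstream computation. Compounds 1–5 place a
single Rp linkage at five distinct tract linkages; compound 6's only Rp sits
two linkages from the IPCCS; compound 7 is all-Sp.

Site prediction: each Rp linkage promotes the scissile RNA phosphate
`offset_to_scissile` positions away. The magnitude is two; the *direction* is
a drawing convention not fixed by the text, so it is explicit configuration
(`ContactWindow.offset_to_scissile ∈ {+2, −2}`, default +2) and the read
simulator and mapper simply share whichever convention is chosen. A compound
with no Rp loses positional guidance and is predicted to cleave diffusely
across the tract-opposed positions. Predictions falling outside the duplex
are dropped with a warning record rather than silently.

## Screen: planted truth model

Each library pool draws 9-mers uniformly over its 3-letter alphabet. The
default pool of 10^6 molecules keeps all 3^9 = 19,683 nonamers represented
(~50× each), emulating a synthesis-scale library; smaller pools make the
fully-Sp stratum of the ENC2 libraries (a single nonamer, poly-A or poly-T)
a shot-noise artifact.

Digestion: a molecule's cleavage rate is the maximum over the seven sliding
3-linkage contact windows of `seq_weight(window bases) × gate`, where the
gate (default 0.05) applies only when all three window linkages are Sp —
modelling an enzyme free to pick its register, for which a single Rp linkage
anywhere restores full activity. `P(cleaved) = 1 − exp(−rate × exposure)`.
`seq_weight` defaults to 1 for every motif (pure-chirality truth); a loadable
table can add base-sequence preferences. Exposure is a free parameter (real
enzyme dose and incubation time have no fixed mapping to rate units); the
default 6.0 is chosen so that the uncleaved circular band is dominated by fully-Sp
molecules, matching the strong band depletion seen after digestion. This
matters statistically: under ENC2 encodings the fully-Sp stratum is only
(1/3)^9 of the pool, and a light digestion would leave its enrichment
undetectable at desk-scale read depth.

Sequencing: each gel fraction yields a fixed 50,000 reads (gel extraction
fixes depth per band regardless of band mass), multinomial over the
fraction's molecules, zero error by default. Read layout is
5′ adapter + nonamer + 3′ adapter + constant filler with the sample index on
the title line. PCR amplification bias is deliberately not modelled.

## Screen: decoding and statistics

Demultiplexing requires exact index match. Trimming follows cutadapt
semantics: the 13-nt 5′ adapter anchored at the read start and the 13-nt 3′
adapter searched downstream, substitutions only, error rate 0.1
(⌊0.1·13⌋ = 1 mismatch each). Retained inserts must be exactly 9 nt and
conform to the library alphabet. Window trimers (insert positions 1–3 and
5–7) are tallied independently per window, keeping {A,T}-only trimers; a C/G
inside one window excludes the read from that window only. Whole-read
exclusion would be the alternative convention; per-window was chosen because
it preserves information and keeps the two windows independent ledgers.

Differential abundance is implemented from first principles rather than by
wrapping a count-based differential package such as edgeR: library size is total retained nonamers
(a closed two-sample pool; no TMM), log2 fold changes use pseudocount 0.5,
and the p-value is the two-sided conditional binomial exact test of the
motif's count split given both totals — the Poisson limit of the
negative-binomial exact test, appropriate at dispersion 0 (the default, since
the screen ran in duplicate only). An optional common dispersion
(moment-estimated across replicates) switches the reference distribution to
beta-binomial. FDR is Benjamini–Hochberg across all motifs × windows. An
independent edgeR-style analysis is *not* the oracle here; the test suite
checks the exact test against brute-force enumeration instead.

Consistency calls pair motifs across an opposite-encoding library pair in
chirality space: `strong` = same effect direction and FDR < 0.01 in both
libraries; `moderate` = same direction and FDR < 0.05 (not strong); anything
else `none`. Pairing libraries of the same encoding class is rejected as a
configuration error.

Caveat: when the uncleaved fraction contains few distinct molecules, fixed
read depth resamples each molecule many times and motif counts become
overdispersed relative to the binomial reference. The planted enrichment is
orders of magnitude above this inflation, but null calibration is only exact
at the molecule-count level — which is how the suite's 100-run null
calibration operates.

## Kinetic competition

Each stereo class of the 3-linkage contact window is one reaction (one tube)
integrating E + S ⇌ ES → EP → E + P, optionally with E + I ⇌ EI. Only the
pocket linkage (the 5′-most varied site, the one bound by the
phosphate-binding pocket) carries chirality dependence:

| parameter | default | meaning |
| --- | --- | --- |
| k_on_base | 10 /(c·t) | association to intact duplex |
| alpha | Rp 1, PO 1, Sp 0.1 | association multiplier by pocket chirality |
| k_off_substrate | 1 /t | non-productive ES dissociation (chirality-blind) |
| k_cat | 1 /t | hydrolysis |
| k_off_product | Rp 0.05, PO 0.05, Sp 5 /t | product release (enzyme recycling) |
| inhibitor k_on, k_off | 10, 0.01 | high-affinity competitive inhibitor |
| enzyme_total, substrate_conc | 0.1, 10 | limited enzyme, substrate excess |
| t_end | 30 | partial-digestion horizon |

Units are arbitrary but coherent (concentration c, time t). The defaults
encode the interpretation that Rp-in-pocket substrates associate fast but
release product slowly: without inhibitor the enzyme spends its time stuck on
Rp product (turnover ≈ 21 t vs ≈ 1.3 t for Sp), so Sp classes are cleaved
fastest; a high-affinity inhibitor penalises weak associators most, flipping
the ranking. PO shares Rp's parameters, so it tracks Rp identically in both
regimes. Mass action requires a substrate off-rate for the reversible
binding step; `k_off_substrate` is chirality-independent, since the weak Sp
association is carried entirely by `alpha`.

Numerics: LSODA with rtol 1e-8, atol 1e-12; mass balance
|S + ES + EP + P − S₀| < 1e-6 along trajectories. A Gillespie SSA
implementation with a system-size parameter serves as the stochastic oracle;
the suite checks agreement at small copy numbers within Monte-Carlo error.

## Cleavage-site mapping

The assay is length-based: after 3′-adapter trimming (22-nt adapter,
substitutions only at error rate 0.1) and the 14–33 nt retention window,
inserts that (a) match the construct's anchored per-position class pattern
and (b) equal the construct template prefix exactly are converted to
positions by `position = anchor − length + 1`. The construct layout
(template, anchor, pattern, window) is data shared between the read simulator
and the mapper, not code; the HIF1A-style default ships the class pattern
(6×any, [AT][CG][GT][AC][AT], literal GTT) and a synthetic template
consistent with it, exposing RNA positions 8–27; the geometry is a
documented stand-in. Predominant site
is the count argmax with ties broken to the lowest position; profile
comparison is total-variation distance of normalised profiles.

One known wet-lab limitation of this assay class is not modelled: capture
probes hybridise poorly to oligo-A tracts, so real chem-walk-style libraries
can fail to yield internal-site reads at all. The simulator emits chem-walk
fragment reads regardless, through its own construct layout.

## Dose–response

Model: f(x) = c + (100 − c)/(1 + (x/e)^b), the four-parameter log-logistic
with the untreated level fixed at 100%. The fit minimises squared error over
(b, c, ln e) — working in ln e makes the fit exactly scale-equivariant —
initialised at b = 1, c = min response, e = geometric median concentration,
with an analytic restart at −b; the lower optimum wins. Tolerances 1e-10 on
parameters; degenerate (flat) data or c ≥ 100 flags the fit non-converged
rather than erroring. Absolute IC50 (response = 50% of control) is the
closed form e·((100 − c)/(50 − c) − 1)^(1/b), erroring when c ≥ 50; both it
and the relative EC50 (= e) are reported because "concentration achieving
50% knockdown" most naturally reads as the absolute quantity. Potency ratios
carry percentile CIs from a residual bootstrap (default 1000 resamples;
replicates whose refit fails are dropped and counted); the residual
bootstrap assumes only i.i.d. noise around the fitted curve.

## Study conditions and problem sizes

The generator defaults are the package's study conditions: pools of 10^6
molecules, 50,000 reads per screen sample, digestion exposure 6.0, chirality
gate 0.05, zero sequencing error, quadruplicate dose-response points at 8
log-spaced concentrations with 3-percentage-point Gaussian noise, and 10^5
fragment reads per chem-walk compound. These sizes make every planted effect
recoverable while keeping any single analysis under a minute on one CPU.

## What the synthetic data does not emulate

No PCR amplification bias, no calibrated sequencing-error profile, no
quality scores beyond a constant placeholder, no duplex-formation
thermodynamics or gel-mobility modelling, and no ligation sequence bias.
Passing tests therefore demonstrate that the *computational chain* recovers
what was planted under clean sampling assumptions — not that the chain is
robust to the full error structure of real libraries, where overdispersion
(biological replicates, PCR jackpots) would demand the dispersion-inflated
test variant.
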