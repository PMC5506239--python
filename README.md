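# nanorad

Radiation dose–response survival modelling with repair saturation, and the
dosimetry and toxicity arithmetic for nanoparticle radio-enhancement studies
in radioresistant bacteria.

## The problem

*Deinococcus radiodurans* survives gamma-ray doses a thousandfold beyond what
kills mammalian cells, which makes it the natural testbed for agents meant to
defeat radioresistance — such as ultra-small high-Z metal nanoparticles that
amplify local radiation effects. Quantifying that amplification requires a
survival model that captures the characteristic *shoulder* of a radioresistant
clonogenic survival curve, a reproducible fitting procedure, and careful
bookkeeping linking administered nanoparticle doses, per-cell uptake, and
toxicity. `nanorad` packages all of this with a seeded synthetic-assay
generator so every stage is testable without lab data.

## The model

A cell carries *n* genome copies (four for *D. radiodurans*). One copy
survives dose *D* (kGy) with probability

    S(D) = exp( −α·D · exp(−β·exp(−δ·D)) )

where **α** (kGy⁻¹) is the induction rate of lethal double-strand breaks,
**β** (dimensionless) the repair capacity, and **δ** (kGy⁻¹) the rate at which
radiation inactivates the repair machinery itself. The colony-forming survival
is the multi-target composition

    S_cfu(D) = 1 − (1 − S(D))^n .

At low dose the repair term holds survival near 1 (the shoulder); once δ·D is
large, repair is switched off and the curve decays as exp(−α·D). Fitting is
staged accordingly: α is first read off the exponential tail, (β, δ) are then
estimated by nonlinear least squares over the whole curve, and (by default) a
joint refinement of all three parameters follows.

Radio-enhancement is quantified two ways: the **sensitization enhancement
ratio** SER-50% = D_ref(50%) / D_test(50%) (ratio of doses for the same CFU
reduction), and the fixed-dose **amplification** (S_ref − S_test)/S_ref.

## Worked example

Fit both packaged reference conditions (unloaded cells vs. cells loaded with
~4700 platinum nanoparticles each) and derive the enhancement metrics:

```
$ nanorad pipeline --output-dir results
reference: alpha=0.290 beta=1.90 delta=0.350
test:      alpha=0.350 beta=1.90 delta=0.450
SER at 50%: 1.227
amplification at 8 kGy: 39.7%
results written to results/results.json
```

The fitted α rises from 0.290 to 0.350 kGy⁻¹ and δ from 0.35 to 0.45 kGy⁻¹
when nanoparticles are present — more lethal damage induced and faster loss of
repair capacity — while β is unchanged: the particles do not alter the cells'
intrinsic repair capacity, they overwhelm it. The model-implied SER of 1.23
means 23% more dose is needed to halve survival in unloaded cells than in
loaded ones; the 39.7% amplification means about four in ten cells that would
have survived 8 kGy are killed when loaded.

Per-cell uptake accounting from a total platinum mass measured by ICP-MS:

```
$ nanorad uptake --total-mass 1.079 --n-cells 7e8 --administered-mass 20
total particles:        3.3e+12
particles per cell:     4.8e+03
mass per cell:          0.0015 pg
cell volume fraction:   0.0005 %
uptake of administered: 5.4 %
```

Other subcommands: `simulate` (seeded clonogenic assays), `fit`, `ser`,
`toxicity` (CFU normalization, MIC, two-way ANOVA + Tukey), `growth`
(OD600 doubling time). All accept `--help`.

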