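# cdrdesign

Structure-based rationalization and design of antibody CDR
(complementarity-determining-region) amino-acid preferences at
antibody–antigen interfaces.

## The problem

High-throughput phage display can select hundreds of antibody variants that
bind a target antigen, giving per-position amino-acid preference profiles for
the interface CDR residues. This package implements a knowledge-based
pipeline that *rationalizes* those experimental preferences from the complex
structure alone, and turns the rationalization into predictive models that
can rank amino acids at interface positions of a new antibody–antigen pair:

- **W<sub>ji</sub>** — the experimental preference of amino-acid type *i* at
  CDR position *j*: a Bayesian pseudo-counted log-odds of the observed count
  against the NNK degenerate-codon background, in half-bit units:
  `W = 2·log2(((C + √M·p) / (M + √M)) / p)`, with the binary label
  `δW = 1 ⟺ W ≥ 0 ⟺ C ≥ M·p`.
- **X<sub>ji</sub>** — an atomistic contact score from 3-D probability
  density maps (PDMs) of atom types around the antigen surface, harvested
  from contact statistics in protein interiors:
  `X = Σ_m log10(max(AVE(PDM_m), p_ref)/p_ref)` over the residue's heavy
  atoms, maximized over side-chain rotamers placed on an alanine-reduced
  scaffold (p_ref = 10⁻¹⁰ guards the log against empty map regions).
- **Y<sub>ji</sub>** — a hydration/desolvation balance from water-oxygen
  PDMs of the two sides: two desolvation sums (one side's water density
  inside the other side's molecular volume) against two water-mediated
  interaction sums over the hydration-shell overlap, minimized over rotamers.
- **Z<sub>ji</sub>** — a structural propensity from a structure-based
  sequence profile, in the same half-bit pseudo-count form.
- **pW<sub>ji</sub>** — a per-type logistic model
  `pW = σ(x·X + y·Y + z·Z + a)` trained with leave-one-out over the contact
  positions; per-type thresholds t_i maximize the Matthews correlation
  coefficient (MCC) of the pooled leave-one-out predictions, and predictions
  are assessed by accuracy, specificity, recall, precision and MCC.

A closed-form baseline gives the metrics a *random* predictor would achieve,
which is the yardstick for everything else.

## Worked example

The closed-form random baseline for 24 interface positions, 20 amino-acid
types, and 5.7 truly-positive / 5.7 predicted-positive types per position:

```console
$ cdrdesign baseline --positions 24 --types 20 --mean-pos 5.7 --pred 5.7
accuracy	0.5925
precision	0.2850
recall	0.2850
specificity	0.7150
```

Any trained predictor has to beat those four numbers. Simulate a selection
experiment (150 binders over a 5-position NNK window), then profile it:

```console
$ cdrdesign simulate --seed 5 --kind selection --positions 28,29,30,31,32 \
      --m 150 --outdir demo
$ cdrdesign profile --sequences demo/sequences.tsv \
      --positions 28,29,30,31,32 --out demo/profile.tsv
$ head -6 demo/profile.tsv
# config_hash=5202e4f0c6b6
position	aa	C	M	p	W	deltaW	I
28	A	13	150	0.0625	0.88185902989157	1	0.1083943887484529
28	C	3	150	0.03125	-1.1677255401312865	0	0.1083943887484529
28	D	2	150	0.03125	-2.1788696449691165	0	0.1083943887484529
28	E	4	150	0.03125	-0.42044253193144343	0	0.1083943887484529
```

Column `C` is the observed count of the type at the position among the
`M = 150` binders, `p` the NNK background probability, `W` the half-bit
preference (A and G are enriched above background here, so `deltaW = 1`),
and `I` the positional information content in bits. `cdrdesign train`,
`predict`, `evaluate` and `rank` then run the leave-one-out logistic pipeline
on score/preference tables; `build-pdm` and `hydrate` build atom-type and
water-oxygen density maps (OpenDX output) around a PDB structure.

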