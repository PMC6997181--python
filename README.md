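# mirloop

Mass-action modelling of mirtron-mediated synaptic homeostasis in the
*Drosophila* larva, together with the RT-qPCR quantification and statistics
pipeline used to measure it.

## The problem

The nicotinic acetylcholine receptor β2 subunit (nAcRβ2) depolarizes
central neurons and admits Ca²⁺; unchecked, activity begets more receptor
and the synaptic potential overshoots. Two coupled control loops keep it
in range:

* an **incoherent feedforward loop** — activity phosphorylates (via
  CaMKII) the transcription factor Adf-1, which de-represses the Shal K⁺
  channel and its interacting protein SKIP; SKIP favours Shal's slow
  inactivation mode, amplifying the repolarizing current; and
* a **negative feedback loop** — the mirtron miR-1010, spliced from an
  intron of its host gene SKIP, degrades nAcRβ2 mRNA and returns the
  system to rest.

`mirloop` implements this motif as an eight-species mass-action reaction
network, encodes every fly line and treatment (miR-1010 null/het, SKIP
MiMIC, binding-site mutant nAcRβ2^Δ1010, NaChBac, Kir2.1, nicotine doses)
as a parameter-level perturbation of the same model, and reduces the
simulated responses to the observables the motif is judged on: the peak of
the normalized potential, the delay Δt to return below 20% of the
wild-type peak, the sustained/delayed/homeostatic classification, and
steady-state fold changes per genotype. A companion pipeline implements
relative quantification from raw Ct values (2^−ΔΔCt with Rpl32/U27
endogenous controls, Ct < 33 expression filter) and the variance-decision
significance procedure (Bartlett test, then Student's or Welch's t test),
plus seeded synthetic Ct generators whose ground truths are the published
fold changes.

## The model

With `u(t)` the agonist drive and all species dimensionless (time in
receptor lifetimes, 1/d_P):

```
dR/dt  = k_R + a_R·V − d_R·R − k_rep·M·R        nAcRβ2 mRNA
dP/dt  = k_P·R − d_P·P                           surface receptor
dV/dt  = k_V·u(t)·P − k_leak·V − g_K·K·(1+α·Sp)·V  potential proxy
dA/dt  = k_Aon·V·(1−A) − k_Aoff·A                phospho-Adf-1 fraction
dSt/dt = a_S·A − d_St·St                         SKIP transcript
dSp/dt = k_Sp·St − d_Sp·Sp                       SKIP protein
dK/dt  = a_K·A − d_K·K                           Shal channel
dM/dt  = η·a_S·A − d_M·M                         mature miR-1010
```

Mirtron production is stoichiometrically coupled to host-gene
transcription (η·a_S, yield η ∈ [0, 1]); repression of R by M is
catalytic. Every term is one elementary mass-action reaction in
`build_default_network`.

## Worked example

```python
>>> import mirloop as ml
>>> model = ml.SynapticHomeostasisModel()           # published fold changes
>>> model.response_metrics(
...     ["wild-type", "miR-1010-null", "miR-1010-het", "SKIP-MiMIC"]
... ).round(3)
        genotype   peak  time_of_peak  t_return  delta_t  terminal_level classification
0      wild-type  1.000         1.500     4.150    0.000           0.126    homeostatic
1  miR-1010-null  1.852        50.000       NaN      NaN           1.852      sustained
2   miR-1010-het  1.084         1.675     5.575    1.425           0.179        delayed
3     SKIP-MiMIC  1.080         1.750     6.175    2.025           0.145        delayed
```

The wild type overshoots, then the two loops pull it back below 20% of its
peak by t ≈ 4 receptor lifetimes. Halving the mirtron yield or removing
functional SKIP protein raises the peak above wild-type and delays the
return (Δt ≈ 1.4 and 2.0 lifetimes); removing miR-1010 entirely leaves the
potential sustained at ~1.9× the wild-type peak — the mirtron dosage acts
as a switch between the high- and low-receptor regimes
(`ml.switch_scan` locates the threshold yield on an η grid).

Calibration and quantification:

```python
>>> results = model.fit(seed=1)      # multistart Nelder–Mead, log2 loss
>>> print(results.summary())         # estimates + per-observation residuals
>>> ct = ml.generate_ct_data(ml.get_preset("nicotine-nAcRb2"), seed=7)
>>> ml.quantify_table(ct)[["fold_change", "test_used", "p_value", "stars"]]
   fold_change test_used       p_value stars
0     2.164336   student  5.211296e-08   ***
```

The synthetic nicotine experiment (true fold change 2, nine replicates per
group, 0.2-cycle noise) is recovered by the 2^−ΔΔCt stage at 2.16-fold,
significant under the Bartlett-gated Student test.

The same stages are scriptable: `mirloop simulate|metrics|calibrate|qpcr|synth|run`
(see `mirloop --help`).

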