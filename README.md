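# rloopflank

Quantitative analysis of DNA conformation at R-loop flanks.

When an RNA strand invades duplex DNA (as in CRISPR interference complexes),
the DNA duplex flanking the R-loop can either remain stably base-paired or
fray and bend, depending on which RNA terminus abuts it. `rloopflank` is the
analysis toolkit for the three measurements that quantify this:

1. **Permanganate footprinting gels.** Permanganate oxidizes thymines in
   distorted or unpaired DNA; piperidine cleaves at oxidized thymines, and
   the labeled fragments are resolved by denaturing PAGE. From band volumes
   `v_1..v_n` (band 1 = shortest fragment, band n = full length) the package
   computes, per thymine `i`:

   - oxidation probability `p_i = v_i / Σ_{j≥i} v_j`
   - rate constant `k_i = ln(1/(1−p_i))/t` (quench time `t`)
   - cross-replicate corrected rate `k_i,corr = (μ_ref/k̄_ref)·k_i`, using a
     reference thymine to normalize out permanganate-preparation activity
   - **PRI** (Permanganate Reactivity Index) `= k_i,corr / kss_corr`, with
     `kss_corr = 0.79 min⁻¹` so a fully single-stranded thymine scores 1
   - **FO** (Fraction Oxidized) of the R-loop flank:
     `FO = 1 − Π_{a∈RLF}(1 − p_a,corr) = 1 − exp(−Σ_{a∈RLF} k_a,corr t)`

   plus a seeded synthetic-gel simulator (with exact enumeration oracles,
   chain-reaction/background/gel-runoff stress options) so every estimator
   is validated by parameter recovery without any experimental download.

2. **Envelope surface area (ESA).** For trajectory frames of an
   interhelical junction, the joint solvent-exposed surface area (Å²) of the
   RNA-terminal base and the DNA base stacked on it — low when stacked, high
   when unstacked — computed by deterministic equal-area sphere sampling,
   with 1-ns sliding-window smoothing.

3. **Melting curves.** Two-state logistic fits with linear baselines (and a
   derivative fallback) extract Tm from A260-vs-temperature refolding scans
   of dumbbell constructs, with replicate aggregation and ΔTm comparison.

It is written for bench scientists quantifying their own footprinting or
melting data and for computational users analyzing junction trajectories.
See `docs/methods.md` for models, assumptions and numerical choices.

## Worked example

Simulate a three-replicate experiment for two substrates — an R-loop flank
whose reactivity decays with distance from the R-loop edge, and a fully
single-stranded bubble control — then quantify PRI and FO:

```sh
rloopflank simulate --rates-file examples/demo_rates.yaml \
    --replicates 3 --activity-sigma 0.3 --molecules 1000000 --seed 42 \
    --out lanes.tsv
rloopflank quantify --lanes lanes.tsv \
    --substrates examples/demo_substrates.yaml --out pri.tsv
rloopflank fo --lanes lanes.tsv \
    --substrates examples/demo_substrates.yaml --out fo.tsv
```

`pri.tsv` holds one row per (lane, thymine) with `p`, `k`, `k_corr`, `pri`
and quality flags, under a metadata header recording `kss_corr 0.79` and the
fitted `mu_ref`. Averaged over the three replicate sets, the R-loop-flank
substrate comes out as:

| position | PRI mean | PRI sd |
|---------:|---------:|-------:|
|        3 |    0.714 |  0.010 |
|        4 |    0.520 |  0.008 |
|        5 |    0.324 |  0.004 |
|        6 |    0.156 |  0.002 |
|        7 |    0.078 |  0.001 |
|       10 |    0.323 |  0.003 |

i.e. the thymine at the R-loop edge (position 3) is ~70% as reactive as
unpaired DNA and reactivity decays into the duplex, while the reference
thymine (position 10) sits at its substrate-independent baseline — the
pattern of a fraying duplex terminus. The simulation's true PRIs were
0.70, 0.51, 0.32, 0.15, 0.076 and 0.32: the pipeline recovers them through
the lognormal activity variation it was asked to remove. `fo.tsv` prints

```
substrate_id	fo_mean	fo_sd	n_replicates	members
rloop3_nts	0.9410807409080405	0.002351095782909104	3	T1,T2,T3,T4,T5
bubble_ctrl	0.9992284872645244	8.674803263282962e-05	3	T1,T2,T3,T4,T5
```

— ~94% of flank molecules were oxidized on at least one of the five flank
thymines within the 2-min pulse, versus >99.9% for the open bubble.

The other subcommands follow the same pattern:
`rloopflank esa --frames traj.pdb --residues A:11,B:12 --out esa.tsv`
(per-frame and 1-ns-smoothed ESA in Å²) and
`rloopflank melt curves_rep*.csv --out tm.tsv` (per-construct Tm mean ± SD).
Everything is also available as a library (`rloopflank.reactivity`,
`.synthetic`, `.esa`, `.melt`, `.io`).

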