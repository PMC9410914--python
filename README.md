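# ribokin

Single-molecule kinetic analysis of 30S ribosomal subunit binding to
riboswitch-containing mRNAs.

## The problem

Translation initiation in bacteria starts with the 30S ribosomal subunit
binding the mRNA near its Shine-Dalgarno (SD) sequence. A preQ1-sensing
pseudoknotted riboswitch embedded in the 5′-UTR can partially sequester the
SD on ligand binding, modulating both how fast the 30S arrives and how long
it stays. In a colocalization TIRF assay, surface-tethered mRNA molecules
are visited by labelled 30S subunits, producing per-molecule two-channel
intensity traces in which binding events appear as stretches of high
acceptor signal. Two classes of events are seen: short "standby-site"
contacts and long "cleft-accommodated" complexes in which the 5′-UTR has
been unfolded into the mRNA channel.

`ribokin` implements the full analysis of such traces — and, because raw
traces of this kind are rarely deposited, a generator that simulates them
with known ground truth so every stage can be validated end to end.

## The model

Each molecule alternates between unbound and bound states. Both dwell
classes follow a two-pathway exponential mixture

    f(t) = a_f · k_f · exp(−k_f t) + a_s · k_s · exp(−k_s t)

with second-order binding rate constants `k_on = k_pseudo / [30S]`. The
pipeline:

1. **Idealization** — per-trace two-state hidden Markov model with Gaussian
   emissions (EM + Viterbi), donor-bleach detection truncating the
   analyzable window;
2. **Dwell fitting** — maximum-likelihood exponential mixtures with left
   truncation at one camera frame and survival terms for right-censored
   dwells; molecule-level bootstrap errors;
3. **Photobleach correction** — dissociation rates corrected by the
   effective bleach rate of the dual-labelled 30S (`k_eff = 2k_b/3` for two
   labels), estimated from a locked-on control cohort;
4. **Classification** — short/long events split at the equal-density point
   `t* = ln[(a_f k_f)/(a_s k_s)]/(k_f − k_s)`; molecules binned into
   low/mid/high occupancy by fractional bound time (fixed 0.10/0.20
   boundaries or crossovers of a three-Gaussian fit);
5. **Titrations** — global non-cooperative Hill fits (coefficients −1 for
   `k_on`, +1 for `k_off`) with a shared half-saturation constant;
6. **Ligand jumps** — paired before/after analysis of the same molecules;
7. **Thermodynamics** — a free-energy diagram from the rates,
   `ΔG = −RT ln(k_on·c/k_off)`, with the standby level from the fast
   pathway and the cleft-accommodation step from the slow/fast equilibrium
   ratio; the ligand-induced net unfolding penalty is the difference of the
   accommodation steps between ligand states.

The fit-shaped stages are scikit-learn style estimators
(`TwoStateIdealizer`, `ExponentialMixtureMLE`, `HillTitration` via
`fit_hill_global`, `OccupancyMixture`) with plain functions layered on top.

## Worked example

```python
from ribokin import simulate, pipeline, kinetics

p = simulate.preset("wt_minus")            # ligand-free wild type
cohort = simulate.generate_cohort(
    p.classes, 300, p.acquisition, p.photophysics,
    ligand_conc=p.ligand_conc, seed=2026, condition="wt_minus")
control = simulate.generate_bleach_control(100, p.photophysics, seed=2027)
k_bleach = pipeline.estimate_bleach_from_control(control)
result = pipeline.analyze_condition(cohort, k_bleach_eff=k_bleach)
print(f"kon_slow  = {result['rates']['kon_slow']:.3g} /M/s")
print(f"koff_slow = {result['rates']['koff_slow']:.4f} /s")
print(f"t*        = {result['t_star']:.1f} s")
```

Output from this exact run:

```
kon_slow  = 3.25e+05 /M/s
koff_slow = 0.0021 /s
t*        = 9.7 s
```

The cohort was generated with `k_on,slow = 3.3e5 /M/s` and
`k_off,slow = 0.002 /s` at 20 nM 30S, 10,000 frames of 100 ms: the
end-to-end pipeline (noisy rendering, HMM idealization, censored mixture
MLE, bleach correction) recovers both slow-pathway constants within a few
percent, and the derived short/long threshold of about ten seconds cleanly
separates standby from accommodated events.

The same stages are scriptable from the shell:

```bash
ribokin simulate --preset wt_minus --n 300 --seed 7 --out cohort/
ribokin idealize --in cohort/ --out ideal.json
ribokin fit --ideal ideal.json --conc-nm 20 --out rates.json
ribokin classify --rates rates.json --ideal ideal.json --out classes.json
ribokin reproduce --preset-pair wt --n 300 --seed 7 --out report/
```

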