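# Methods

## Kinetic model

A surface-tethered mRNA molecule alternates between an unbound and a
30S-bound state. Dwell times in each state follow a two-component
("fast"/"slow" pathway) exponential mixture: an unbound dwell is drawn
from the slow pathway with probability `a_on_slow` (pseudo-first-order
rate `k_on,slow · [30S]`) and from the fast pathway otherwise; bound
dwells analogously with `a_off_slow`. The two bound pathways map onto the
two biochemically distinct binding modes: transient standby-site contacts
(fast dissociation) and cleft-accommodated complexes (slow dissociation).

The pathways are modelled as a per-dwell mixture, not as a hidden mRNA
conformational state with its own exchange kinetics. A mixture reproduces
exactly the double-exponential dwell likelihood that the analysis fits, and
the experimental literature reports mixture amplitudes rather than
conformational exchange rates; long-term per-molecule heterogeneity is
instead injected through molecule classes (`MoleculeClassSpec`), each with
its own scheme.

### Default condition parameters

Slow-pathway rate constants per condition are the published per-condition
estimates; the wild-type pair is

| condition | k_on,slow (1/M/s) | a_on,slow | k_off,slow (1/s) | a_off,slow | ligand |
|-----------|------------------|-----------|------------------|------------|--------|
| `wt_minus` | 0.33e6 | 0.89 | 0.002 | 0.58 | 0 |
| `wt_plus`  | 0.24e6 | 0.96 | 0.006 | 0.41 | 1 µM |

Mutant presets (`i1s8` … `i4s0`, 150 ms frames), S1-depleted (`ds1`) and
initiation-factor (`ifs`) presets follow the same pattern. Where a
dissociation constant is not published for a condition (the insert/SD
mutants), the presets use 0.006 1/s — a generator knob consistent with the
qualitative observation that these mutants dissociate like the
ligand-bound wild type — and it should not be read as a measured value.
Fast-pathway defaults (`k_on,fast = 3.3e6 /M/s`, `k_off,fast = 0.5 /s`)
are likewise generator knobs: they keep standby events near two seconds,
well separated from accommodated events, but are not literature values.

### Acquisition and photophysics defaults

100 ms frames, 10,000-frame movies (150 ms for mutant presets), 20 nM
ribosome concentration. Intensities 100 (unbound) / 600 (bound) arbitrary
units with Gaussian camera noise of SD 50 (signal-to-noise 10). The 30S
carries two acceptor fluorophores, drawn fresh for every binding event
(each event is a new ribosome from solution); each bleaches independently
at `k_bleach_acceptor = 2e-4 /s`, so the mean signal-survival time of a
bound ribosome is `3/(2k_b) = 7500 s` and about 6% of slow dissociation
events are bleach-truncated — "residual" photobleaching, per the
dual-labelling design. The donor (mRNA label) bleaches at `1e-4 /s` and
ends the analyzable window (`valid_until`).

Frames straddling a state transition carry duty-cycle-weighted intensity,
which makes the one-frame dead time a real, testable feature rather than
an idealization.

## Idealization

Each trace gets its own two-state Gaussian-emission HMM (intensity levels
vary between molecules, so no global fit): means initialized at the
20th/80th intensity percentiles, sticky transition prior, 50 EM iterations
max at tolerance 1e-6, Viterbi decoding, higher mean = bound. Traces are
standardized first, making the result exactly invariant to affine
intensity rescaling. Two safeguards: (1) rare-event traces, where both
initialization quantiles fall inside the majority state, seed the second
mean from the 99.9th percentile instead; (2) fitted state means closer
than twice the within-state SD collapse to a single state, so pure noise
is never split into spurious events. Donor bleach is detected as a
trailing 50-frame median below three times a robust noise estimate.

## Dwell-time inference

Dwells are maximal constant-state runs, with duration = run length ×
frame time. The mixture likelihood is left-truncated at one frame (events
shorter than a frame are unobservable; the density is renormalized on
`[frame_time, ∞)`) and right-censored dwells enter through survival
terms — censoring is non-ignorable because the slow dissociation pathway
(mean ~500 s) is of the order of the observation window.

Left-censored dwells (the first run of each trace) are **excluded** from
rate fitting rather than given survival terms. Their observed length is
itself the quantity that defines them, so treating them as "at least this
long" is informatively coarsened data; numerically it biased the slow
binding rate ~30% low on ground-truth dwells. Exclusion is ignorable (the
first-dwell index does not depend on the dwell value).

Optimization is multistart (5 starts) L-BFGS with rates in log space and
the amplitude in logit space. An optional weak Gamma prior on the rates is
available (`prior_alpha`) but is off by default: in testing it distorted
near-empty minority components more than it helped.

Right-censored mixtures have a known boundary degeneracy: an arbitrarily
slow, small-amplitude component can absorb the censored tail. The
reporting layer therefore falls back to a single-exponential fit when the
two-component fit is degenerate — a component amplitude below 3% or a slow
component whose mean dwell exceeds the longest observation. Near
saturation the binding process is effectively single-pathway (slow
amplitude 96%), and the single-rate estimate is then within a few percent
of the slow-pathway rate, because the fast pathway contributes almost no
observation time. Closely spaced rate pairs are deliberately not flagged:
an under-resolved pair still brackets the dominant rate, whereas forcing
such fits to one component proved to bias the estimate upward by merging
the real fast pathway.

Model selection (`select_model`) uses BIC with ties resolved toward one
component.

## Photobleach correction

Observed signal loss is the earlier of dissociation and loss of the last
acceptor label, so observed dissociation rates are corrected by
subtraction: `k_off = k_obs − k_bleach_eff`, with
`k_bleach_eff = 1/mean(apparent loss time)` estimated from a locked-on
control cohort (for n independent labels the mean loss time is `H_n/k_b`;
`3/(2k_b)` for two). Binding rates are corrected only through the
donor-bleach truncation of the analyzable window. This asymmetric
convention is a package decision; it leaves a small (~2 percentage point)
downward bias in ligand-jump binding-rate contrasts because bleach-
truncated bound events inflate the following apparent unbound dwell, and
that inflation is larger in the slow-dissociating (ligand-free) condition.
The control cohort is simulated with long movies (eight times the expected
mean loss time) and donor bleaching off, so truncation bias in the mean is
negligible; if the control were shorter, censored-loss events would need
their own survival treatment.

## Classification

The short/long (standby vs accommodated) boundary is the equal-weighted-
density point of the fitted dissociation mixture,
`t* = ln[(a_f k_f)/(a_s k_s)]/(k_f − k_s)` — the Bayes-optimal decision
boundary for the mixture; with the wild-type parameters it falls near 10 s.
Censored bound events are classified long only when already longer than
`t*`, otherwise "indeterminate" and excluded from counts.

Molecule classes: L if fractional bound time < t1, M if t1 ≤ f ≤ t2, H if
f > t2 (boundaries belong to M, matching the "0.1 to 0.2" mid-class
convention). Thresholds are either fixed (0.10, 0.20) or derived as the
density crossovers of a three-Gaussian mixture fit to the occupancy
histogram; on the default synthetic parameterization both agree on ≥ 95%
of molecules. Collapsed components or missing crossovers fall back to the
fixed pair with a warning. In ligand-jump pairing, a molecule with zero
detected binding events in a segment is "inaccessible", ordered below L.

## Hill titrations

`kon(c) = kon0 − (kon0 − kon∞)·c/(K + c)` and
`koff(c) = koff0 + (koff∞ − koff0)·c/(K + c)` are fitted jointly with a
shared K by weighted least squares (inverse-variance weights when errors
are supplied). With 6 concentrations and 5% multiplicative noise the K
estimator is unbiased but has ~20% sampling SD; reported summary values
therefore average independent replicate titrations. The default
concentration grid (0, 25, 50, 150, 400, 1000 nM) log-brackets the
expected half-saturation.

## Free-energy diagram

State free energies at a reference concentration follow from
`ΔG = −RT ln(k_on·c/k_off)` with R = 1.987e-3 kcal/(mol·K) and T = 298.15 K
by default. The standby level uses the fast components; the accommodation
step is `−RT ln[(k_on,slow/k_off,slow)/(k_on,fast/k_off,fast)]`, in which
concentration cancels — so the step, and the net ligand-induced unfolding
penalty (the difference of the steps between ligand states), is invariant
to the reference concentration, while the absolute levels shift by
`−RT ln 10` per 10-fold concentration increase. The partition of the
diagram into standby = fast and accommodated = slow levels is a package
convention; since the fast-pathway constants are generator knobs rather
than measured values, the absolute standby level carries no quantitative
claim — only the accommodation arithmetic does.

## What the generator does and does not emulate

Emulated: two-pathway renewal kinetics, per-molecule occupancy
heterogeneity (via class mixtures or the occupancy-mixture sampler),
dual-acceptor and donor photobleaching, frame integration with duty-cycle
aliasing, additive Gaussian camera noise, paired ligand-jump segments with
shared molecule identities.

Not emulated: EMCCD/sCMOS noise statistics beyond additive Gaussian,
background surface binding, image-plane spot detection and colocalization
(traces are the input unit), shuttered-illumination duty cycles (treated
as continuous; a noted limitation, since shuttering would lower the
effective bleach rates), and any coupling between a molecule's occupancy
class and its event-level kinetics beyond what the class schemes encode.
Passing tests therefore validate the statistical pipeline against this
generative model, not against instrument-specific artifacts of real
movies.

## Problem sizes and numerical choices

Validation cohorts use 300 molecules × 10,000 frames for equilibrium
recovery and 200 molecules × 2 × 8,000 frames per ligand-jump replicate —
matching the scale of the emulated experiment while keeping a full run in
minutes on one CPU. Summary statistics over stochastic procedures average
10–50 independent replicates depending on the per-replicate cost.
Bootstrap intervals resample molecules (not dwells) with percentile 68%
and 95% bands; replicates with fewer than 20 complete dwells are skipped
and logged. Ties and degenerate inputs: equal mixture rates raise (no
short/long separation exists); zero-variance traces idealize to a single
state with a warning; a vanishing fast amplitude clamps the event
threshold at zero.

## Known limitations

- Sub-frame events are unrecoverable and slightly deplete the fast
  pathways; the truncation term keeps rate estimates unbiased to < 2% at
  `k · frame_time ≤ 0.2`.
- The bleach-remnant inflation of unbound dwells described above is not
  corrected; at the default residual bleach rate it costs a few percent on
  slow binding-rate estimates.
- Per-trace HMMs assume two intensity levels; multi-step photobleaching of
  the dual label within one event renders as a single loss.
- The occupancy-mixture sampler draws fractional bound times directly and
  is not coupled to the event-level kinetic schemes; it emulates the
  molecule-level histogram, not full traces.
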