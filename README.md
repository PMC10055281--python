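# damfretkit

Quantitative single-cell analysis of amyloid nucleation from DAmFRET
(Distributed Amphifluoric FRET) flow cytometry, with companion tools for
polyglutamine (polyQ) "Q-zipper" sequence rules, nucleation-kinetics
inference, and microscopy/gel quantification.

## Who this is for

DAmFRET treats each yeast cell as a femtoliter test tube: a protein of
interest fused to a photoconvertible fluorophore is expressed over a
~hundred-fold concentration range, and each cell reports its degree of
self-assembly as **AmFRET** = compensated FRET intensity / acceptor
intensity, plotted against a per-cell concentration proxy
(acceptor / side scatter). Because amyloid formation is rate-limited by a
stochastic nucleation event, cells at the same concentration split into
discrete AmFRET-negative and AmFRET-positive populations, and the fraction
of positive cells versus concentration carries kinetic information. This
package is for researchers who want that whole analysis chain — gating,
gate-statistic computation, kinetic fitting — as tested, scriptable Python,
plus a synthetic-data generator that reproduces the assay's statistical
structure so every stage can be validated without instrument files.

## What it computes

* **fgate** — the fraction of expressing cells whose AmFRET exceeds a
  negative-control-derived gate. The control's acceptor range is divided
  into 64 log-spaced bins; the per-bin upper gate is the 99th percentile of
  the control AmFRET in that bin; bins below 2×10⁶ acceptor units or above
  the control's 99th acceptor percentile are filled from the nearest valid
  bin; the profile is boxcar-smoothed (width 5) and shifted up by 0.028;
  the lower gate is −0.2. fgate ∈ [0, 1] and equals the count-weighted mean
  of per-bin positive fractions exactly.
* **Nucleation kinetics** — with concentration ramping linearly to c_T over
  induction time T, the fraction of nucleated cells is
  P(c_T) = 1 − exp(−k·c_Tⁿ·T/(n+1)). `fit_reaction_order` recovers the
  apparent reaction order n (n ≈ 1 ⇒ monomeric nucleus) by binomial maximum
  likelihood with a profile-likelihood confidence interval;
  `detect_poisoning` tests for the multiphasic ("self-poisoned") signature —
  a plateau and re-rise in fraction-positive versus concentration — by AICc
  model selection against a logistic poisoning window.
* **Q-zipper sequence rules** — β-strand side chains alternate by 180°, so a
  zipper strand face needs glutamine at every other position. The rules
  quantify *unilateral* contiguity (longest uninterrupted Q run in one
  parity frame; ≥ 5 supports a single long zipper) and *bilateral*
  contiguity (longest literal Q run; ≥ 6 supports lamellar zippers),
  classify sequences as Q_B / Q_U / none, and search for the minimal
  intramolecular four-strand nucleus layout (4×6 residues + 3 loops:
  36 residues with 4-residue loops — the clinical polyQ threshold — or
  33 with tri-glycine loops).
* **Imaging** — per-cell puncta calls from an intensity-dispersion statistic
  (sd/√mean > 30), ellipsoid cell volumes and concentrations, and SDD-AGE
  lane densitometry (rolling-ball background, 10-px lane profiles
  normalized to unit integral).

## Worked example

```python
import numpy as np
import damfretkit as dk

opt = dk.OpticsModel()
spill = dk.SpilloverModel(opt.s_donor, opt.s_acceptor)

# a nucleating sample and a monomeric negative control
sample = dk.simulate_population(
    nucleation=dk.NucleationParams(k=0.05, n=1.0), n_cells=20_000, seed=1)
control = dk.simulate_negative_control(n_cells=100_000, seed=42)

# gate (cells -> singlets -> expressing), compensate, derive AmFRET
table, report, _ = dk.process_events(sample.events, spill)
ctrl_table, _, _ = dk.process_events(control.events, spill)

gate = dk.build_negative_gate(ctrl_table)
profile = dk.fraction_positive(table, gate)
print(report.stage_counts)
print(f"fgate = {profile.fgate:.3f}")

fit = dk.fit_reaction_order(
    dk.truth_fraction_positive(sample, np.logspace(0, 2, 33)), T=16.0)
print(f"n_hat = {fit.n_hat:.2f}  CI = ({fit.n_ci[0]:.2f}, {fit.n_ci[1]:.2f})")
```

Output:

```
{'cells': 20000, 'singlets': 18962, 'expressing': 17998}
fgate = 0.844
n_hat = 1.02  CI = (0.98, 1.05)
```

The gate sequence removed doublets (forward-scatter width) and
non-expressing cells (donor vs autofluorescence polygon); 84% of the
remaining expressing cells lie above the negative gate, and the fitted
reaction order recovers the simulated n = 1 — the concentration dependence
expected when nucleation occurs within a single molecule.

Sequence rules from the command line:

```bash
$ damfretkit classify-seq --csv QQQQNQQQQNQQQQN $(damfretkit build-repeat QQQQQN 60)
name,length,uni,bi,zipper_class,de_novo_competent
seq1,15,4,4,none,False
seq2,60,30,5,Q_U,True
```

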