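# icmsim

Spatial-stochastic simulation of cell-fate proportioning in the early
mouse embryo's inner cell mass (ICM), for computational and systems
biologists studying how a noisy gene-regulatory network plus local
signaling produces reproducible tissue-level outcomes.

Between embryonic days ~2.75 and ~4.75 the bipotent ICM resolves into
epiblast (EPI, NANOG-high) and primitive endoderm (PRE, GATA6-high) at a
robust ~40:60 ratio.  `icmsim` models each cell of a static 2D tissue as a
well-mixed voxel carrying the NANOG–GATA6–FGF4 network — cooperative
promoter binding-site ladders with all-or-nothing gene switching, mutual
repression and self-activation, basal plus induced transcription,
translation and first-order decay, FGFR–FGF4 monomer/dimer kinetics, and
ERK activation with ERK-mediated NANOG phosphorylation — and couples cells
through FGF4 escape (autocrine/paracrine, flux-conserving split) and
membrane-to-membrane ligand exchange.  The whole tissue is one
continuous-time Markov chain, sampled exactly (Gillespie direct method
with per-cell propensity caching, compiled with numba), so copy-number
noise and its tissue-level consequences are represented without
approximation.

On top of the simulator the package provides:

* fate classification and tissue observables (lineage counts, first
  appearance times, protein correlations, neighborhood composition versus
  a multinomial baseline, FGF4 by neighborhood degree);
* the pattern-score objective — per-configuration score
  `S = (exp(-||Z-w||_1/||w||_1) - w*)/(1 - w*)`, joint score
  `min(S_on, S_off)`, and the spread-penalized meta score — used to rank
  parameter sets against the 40-60-0 / 100-0-0 targets;
* experiment drivers: model variants (signaling-free mutants TM-APM/TM-A/
  TM-PM, the *Fgf4* knockout TM-FGF4, the reinferred cell-autonomous
  mutant RTM), initial-condition perturbations, timed exogenous FGF4
  dosing, system-size scans, and robustness statistics (CV vs the binomial
  baseline, standardized absolute fate deviation, fate error, copies ↔
  ng/ml conversion);
* a multi-round simulation-based inference loop (SNPE-style: simulate,
  reduce to score features, train conditional density estimators,
  condition on the all-ones target, select by meta score) with a
  closed-form Gaussian-mixture backend behind a pluggable interface.

## Worked example

```python
import numpy as np
from icmsim import ParameterSet, build_lattice, run_batch
from icmsim.experiments import icd_sampler, final_fate_counts
from icmsim.observables import EPI, PRE, first_appearance

params = ParameterSet()          # frozen wild-type MAP estimate
lattice = build_lattice(5, 5)
ensemble = run_batch(params, lattice, "ITWT",
                     icd_sampler(params, 25),
                     n_reps=10, base_seed=2024, t_end=48 * 3600.0)

finals = final_fate_counts(ensemble)
print("mean EPI/PRE/UND at 48 h:", finals.mean(axis=0))
print("first EPI appearance [h]:",
      round(np.nanmean(first_appearance(ensemble, EPI)), 2))
print("first PRE appearance [h]:",
      round(np.nanmean(first_appearance(ensemble, PRE)), 2))
```

prints

```
mean EPI/PRE/UND at 48 h: [12.7 12.3  0. ]
first EPI appearance [h]: 3.95
first PRE appearance [h]: 12.48
```

i.e. from identically prepared undifferentiated tissues, EPI cells appear
first (within a few hours), PRE cells follow several hours later once FGF4
secreted by nascent EPI cells has activated ERK in their neighbors (the
delay shrinks to ~7-8 h on the 100-cell test tissue, where first-appearance
times are earlier), and by 48 h the tissue has partitioned into the two
committed lineages with only the occasional straggler.  Disabling cell–cell
signaling (`variant="TM-APM"`) collapses the outcome to near-total EPI
dominance, and adding exogenous FGF4 to the *Fgf4* knockout before ~24 h
rescues the PRE fate — the model's two defining signaling phenotypes.

A command-line interface mirrors the library
(`icmsim simulate|batch|score|experiment|infer|report`), storing
trajectories in HDF5, tidy summaries as CSV, and a JSON run manifest next
to every output.

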