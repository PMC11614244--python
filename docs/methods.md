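# Methods

## The model

`icmsim` simulates lineage proportioning in the early mouse inner cell mass
(ICM): a static 2D tissue of cells, each carrying the NANOG–GATA6–FGF4
gene-regulatory network, committing stochastically to the epiblast (EPI,
NANOG-high) or primitive-endoderm (PRE, GATA6-high) fate.  The tissue state
is a continuous-time Markov chain over integer copy numbers; every
reaction and every cell-to-cell transport step is an elementary event with
a mass-action propensity, sampled exactly with Gillespie's direct method.
This is the mesoscopic reaction–diffusion master-equation picture with one
well-mixed voxel per cell; the engine is organized like a next-subvolume
scheme with per-cell propensity caches, which changes the computational
cost but not the sampled law.

Per cell the model tracks three mRNAs (*Nanog*, *Gata6*, *Fgf4*), NANOG and
phosphorylated NANOG, GATA6, cytoplasmic FGF4, membrane FGFR–FGF4 monomer
and dimer complexes, and inactive/active ERK, plus the occupancy of eight
promoter–TF binding-site ladders (NANOG-pool and GATA6 with four sites each
on *Nanog* and *Gata6*, two each on *Fgf4*, and three active-ERK sites on
*Nanog* and *Gata6*).  Gene switching is all-or-nothing: a gene is
repressed/activated only while all sites of a repressor/activator are
occupied, and repression takes precedence.  Transcription has a basal mode
(20% of the full rate, blocked by repression, absent for *Fgf4*) and a
full-induction mode requiring activation.  Translation, degradation,
monomer dimerization, ERK (de)activation by dimer complexes and
ERK-mediated NANOG (de)phosphorylation complete the intracellular channel
set; phosphorylated NANOG decays twice as fast as NANOG, which halves the
steady NANOG pool under strong signaling.

Cell–cell communication is carried exclusively by FGF4.  Cytoplasmic FGF4
escapes at total rate `1/tau_escape`, landing as a membrane monomer complex
on the emitting cell (autocrine) or a face-adjacent neighbor (paracrine,
share `chi_para * rho_meme`, split evenly over neighbors); the autocrine
channel takes the complement so the total escape flux is conserved for
every cell regardless of neighbor count.  Membrane monomers additionally
hop between adjacent membranes at `rho_meme / tau_exchange`.  `rho_meme`
is the shared-surface fraction, `n_neighbors/6` for cuboidal monolayer
voxels (a 4-face convention is available as a flag).

## Promoter cooperativity

The one genuinely open design point is the promoter unbinding rate.  The
binding rate is diffusion-limited, `k_b = 4*pi*d*D/V ≈ 3.0e-4 /s` per free
TF copy, identical for all pairs and ladder steps.  For unbinding, the
package's default is a nucleation-type cooperative ladder: partially
occupied promoter states are unstable (unbinding at `k_coop * h_sat *
k_b`), while the complete q-copy complex is mutually stabilized and decays
at `h_sat * k_b / k_coop**(q-1)`.  The stationary probability of the
switched (fully occupied) state is then Hill-like with effective exponent
close to q and midpoint near the pair's half-saturation threshold `h_sat`,
which is precisely the regulatory semantics the thresholds carry (50% of
transcriptional control at `h_sat` copies).  Constant-rate alternatives —
the same `k_u` at every step, calibrated either to the 50% point
(`half_occupancy`) or to `h_sat*k_b/(k_coop*q)` / `h_sat*k_b/k_coop**q` —
are selectable via the `ku_rule` flag.  They were implemented first and
rejected as defaults on phenotype grounds: the constant-rate ladder's
geometric stationary law saturates too slowly (at most ~85% switching at
reachable copy numbers), which either traps every cell in a mixed
undifferentiated state (the `coop_*` calibrations) or caps GATA6 below the
PRE classification threshold (the `half_occupancy` calibration), so no
parameter set can realize the documented committed states.

Bound TF copies are sequestered from the free pool by default (binding
consumes a copy, drawn proportionally from the NANOG/P-NANOG forms for the
pooled TF; unbinding releases an unphosphorylated copy).  A flag disables
sequestration for sensitivity checks; at most 22 copies per cell can be
bound, so the effect is small.

## Parameters

All fixed constants (volumes, lifetimes, steady-state targets,
dimerization kinetics) and the 19 free parameters are carried by
`ParameterSet`, whose defaults are the frozen wild-type MAP estimate; the
same values ship as `configs/itwt_map.yaml`.  Times are seconds, counts
are copies per cell.  Derived rates follow
`k_m,s = Mbar/tau_m` (split 20/80 between basal and induced modes),
`k_m,d = 1/tau_m`, `k_p,d = 1/tau_p`, and a per-mRNA translation
propensity `Pbar/(Mbar*tau_p)` chosen so the full-induction protein steady
state equals `Pbar` (1000 copies for NANOG/GATA6); the "~4 proteins per
mRNA" burst heuristic and this steady-state anchoring cannot both hold
with the given lifetimes, and the steady state wins because the
classification thresholds are derived from it.  The monomerization rate is
taken as `1/360 /s` (its tabulated value `3e-3` is the one-digit rounding).

Fate classification compares total NANOG (free + phosphorylated) and GATA6
against constants: EPI iff NANOG > 388 and GATA6 < 329; PRE iff
GATA6 > 842 and NANOG < 329 (strict inequalities; 388 and 842 are
recomputed from `P/2 - 5*sqrt(P/2)` and `P - 5*sqrt(P)` with P = 1000, the
low threshold 329 is pinned).

The signaling-free reinferred mutant (`configs/rtm_map.yaml`) shares all
wild-type values except the four core-motif thresholds.  Their published
values are unavailable in text form, so the shipped file is a synthetic
stand-in calibrated to the mutant's documented behavior: reversed
Nanog/Gata6 self-activation relationship and a cell-autonomous 40/60
EPI/PRE split.

## Initial conditions and interventions

Each cell draws one pooled count per resource class — Poisson with twice
the configured per-gene mean (117 mRNA, 482 protein) — and splits it
fairly (Binomial(N, 1/2)) between the Nanog- and Gata6-side species; by
Poisson thinning the per-gene allocations are exactly independent Poisson
counts.  Inactive ERK starts at its abundant steady level (1000), all
other species at zero; every cell classifies as undifferentiated at t = 0.
Perturbation modes add a per-species uniform mean layer
(`uniform_variability`), or rescale the means of a randomly chosen subset
of cells in tandem (`equal_linear`) or antagonistically
(`adversarial_linear`).  Exogenous FGF4 doses are per-cell
Binomial(Poisson(2m), 1/2) draws (mean m) added atomically to the membrane
monomer pool at scheduled times (cytoplasmic entry is a flag); timed
additions truncate the pending waiting time and force a propensity
refresh, preserving exactness of the inhomogeneous process.

## Scores and inference

Lineage counts are scored against target proportions (40-60-0 with
signaling, 100-0-0 without) by an exponential transform of the l1
distance, normalized to 1 at the target and 0 at distance `2*max(w)`.
Distances beyond that bound are reachable through counts on the zero-target
(undifferentiated) component, where the raw formula would go negative; the
score is clamped to [0, 1].  The two configuration scores combine through
`((S0+S1) - |S0-S1|)/2 = min(S0, S1)`; an ensemble of joint-score series
over the last 12 h of a 48 h run (half-open window, 48 grid points at
0.25 h) is summarized by the meta score `mean(max(median - ((p95-p5)/2)^2,
0))` with linearly interpolated percentiles.

The inference loop is sequential neural-posterior-estimation shaped:
sample parameters from a proposal (round 1: the 19-dimensional uniform
prior; 4-dimensional for the signaling-free mutant), simulate, reduce to
the 48-point joint-score feature vector, train several conditional density
estimators on the same (theta, x) set with different seeds, condition each
on the all-ones target observation, and select the candidate whose MAP
point earns the highest meta score on a fresh validation ensemble; the
selected posterior, truncated to the prior box, is the next round's
proposal.  The density-estimation backend is a pluggable
train/condition/sample/MAP contract; the default backend fits a
full-covariance Gaussian mixture to the joint (theta, x) sample and
conditions it analytically, which keeps sampling, MAP extraction
(multi-start Nelder–Mead within the prior box) and further conditioning
(for the MAP-conditioned parameter-correlation analysis) in closed form.
Raw scores in [0, 1] are used as features without normalization.  Toy-scale
defaults are a 25-cell lattice, 1000 simulations per round, 3 rounds and 3
candidates; campaign-scale settings are reachable through configuration
but are not defaults.

## Verification strategy and problem sizes

The engine is validated against analytic laws and an independent
brute-force direct-method SSA on toys where both are tractable: the
isolated ERK module (exact Poisson stationary law, 10^4 stationary
replicates) and a two-cell FGF4 transport toy (moment agreement within 3
standard errors).  Event logs replay deterministically and conserve ligand
through every transport event.  Tissue-level checks run at reduced sizes:
10 replicate 48 h wild-type runs on a 5x5 lattice for fate proportions and
appearance times, 50 replicates for the mutant noise analysis, 8-replicate
batches per dosing condition for the plasticity window, and the
linear-Gaussian toy (with its exact analytic posterior as oracle) for the
inference loop.  Published campaign scales (1000-replicate batches,
13-size scans, 10^5-simulation rounds) are reachable through the same
interfaces.

What the synthetic data do not capture: real ICMs grow, divide, and
rearrange in 3D with mechanical coupling; the lattice is static and 2D by
design, so passing tests validate the stochastic chemistry and signaling
logic, not morphogenesis.

## Known limitations

* With the frozen MAP values the wild-type 48 h EPI share measures ~55%
  (published: ~40%), the PRE–EPI first-appearance delay ~8-10 h
  (published: ~7 h), and the EPI population reaches its plateau later than
  the published 4 h mark.  The committed states, fate ordering (EPI first),
  signaling-dependence (near-total EPI dominance without signaling;
  PRE rescue by exogenous FGF4 with a closing plasticity window) and
  noise behavior all reproduce.  The residual quantitative gaps trace to
  promoter-microdynamics details that the source text leaves
  under-determined; the `ku_rule`/ICD flags expose the main alternatives.
* The score clamp at 0 makes all-undifferentiated tissues indistinguishable
  from other far-off configurations, as in the published objective.
* The Gaussian-mixture posterior backend is well suited to the smooth,
  low-dimensional toy problems exercised here; multimodal 19-dimensional
  posteriors at campaign scale would warrant a neural backend behind the
  same interface.
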