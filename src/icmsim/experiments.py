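"""Initial conditions, perturbations, dosing, and robustness statistics.

The default initial-condition distribution (ICD) gives every cell a
balanced, noisy allocation of Nanog/Gata6 resources: a pooled count is
drawn from a Poisson law with twice the configured per-gene mean (117 mRNA
and 482 protein copies per gene at the reference parameter set) and split
fairly between the two genes by a Binomial(N, 1/2) draw, for the mRNA and
protein pools separately.  By the Poisson thinning property each gene's
allocation is then exactly Poisson with the configured per-gene mean, and
the two allocations are independent (the pooled construction matters only
for non-Poisson mean layers); both markers start co-expressed below the
high-expression thresholds.  Inactive ERK starts at its abundant steady
level and every other species at zero, so each cell classifies as
undifferentiated at time zero.

Perturbation modes:

* ``uniform_variability`` — the fixed per-gene mean is replaced, per cell,
  by a uniform draw from ``[mean*(1-s), mean*(1+s)]`` (clipped at zero) with
  ``s`` the intensity/100; at 100% intensity this reproduces the full
  discrete ranges [0, 2*mean] used for mRNA and protein species.
* ``equal_linear`` — a chosen subset of cells has both gene means rescaled
  in tandem by ``1 + dev/100`` for deviation ``dev`` in [-100, 100].
* ``adversarial_linear`` — the subset has anticorrelated rescaling:
  NANOG-side mean scaled by ``1 - dev/100`` and GATA6-side by
  ``1 + dev/100`` (deviation -100% means 200% NANOG / 0% GATA6).

Exogenous FGF4 doses mirror the ICD composition (binomial split of a
doubled-mean Poisson draw, i.e. per-cell Poisson with the requested mean)
and enter the membrane monomer pool by default.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .engine import GridSeries, Intervention, run_batch
from .lattice import Lattice, lattice_for_size
from .observables import EPI, FATES, PRE, UND, fate_counts
from .params import ParameterSet
from .reactions import NSTATE, S

__all__ = [
    "PerturbationSpec",
    "sample_icd",
    "icd_sampler",
    "add_exogenous_fgf4",
    "cv_from_counts",
    "cv_analysis",
    "safd",
    "fate_error",
    "concentration_conversion",
    "final_fate_counts",
]

AVOGADRO = 6.02214e23
FGF4_MASS_KDA = 25.0
ICP_MODES = ("none", "uniform_variability", "equal_linear", "adversarial_linear")
DEFAULT_ADDITION_TIMES_H = (0, 4, 8, 12, 16, 24, 32, 40)


@dataclass(frozen=True)
class PerturbationSpec:
    """Initial-condition perturbation and dosing specification."""

    icp_mode: str = "none"
    icp_intensity: float = 0.0        # percent (deviation or variability)
    n_perturbed_cells: int = 0
    exogenous_mean: float = 0.0       # mean added FGF4 copies per cell
    exogenous_time_h: float = 0.0

    def __post_init__(self) -> None:
        if self.icp_mode not in ICP_MODES:
            raise ValueError(f"unknown icp_mode {self.icp_mode!r}")
        if self.icp_mode in ("equal_linear", "adversarial_linear"):
            if not -100.0 <= self.icp_intensity <= 100.0:
                raise ValueError("linear ICP deviation must lie in [-100, 100] %")
        if self.exogenous_mean < 0:
            raise ValueError("exogenous mean must be non-negative")


def _split_pool(rng: np.random.Generator, mean_a: float, mean_b: float,
                complementary: bool) -> tuple[int, int]:
    """Poisson-pool draw split between two genes.

    The complementary split draws one pooled Poisson(mean_a+mean_b) count
    and allocates Binomial(N, mean_a/(mean_a+mean_b)) to side a.  By Poisson
    thinning this is distributionally identical to two independent Poisson
    draws; the pooled construction is kept as the generative recipe.
    """
    if complementary:
        tot = mean_a + mean_b
        if tot <= 0:
            return 0, 0
        n = rng.poisson(tot)
        a = rng.binomial(n, mean_a / tot) if n > 0 else 0
        return int(a), int(n - a)
    return int(rng.poisson(mean_a)), int(rng.poisson(mean_b))


def sample_icd(
    params: ParameterSet,
    n_cells: int,
    spec: PerturbationSpec = PerturbationSpec(),
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> np.ndarray:
    """Sample one (L, NSTATE) tissue initial state at t = 0."""
    if rng is None:
        rng = np.random.default_rng(seed)
    comp = params.icd_split == "complementary"
    m_mrna, m_prot = params.mean_init_mrna, params.mean_init_protein
    x = np.zeros((n_cells, NSTATE), dtype=np.int64)
    perturbed = np.zeros(n_cells, dtype=bool)
    if spec.icp_mode in ("equal_linear", "adversarial_linear"):
        if spec.n_perturbed_cells > n_cells:
            raise ValueError("n_perturbed_cells exceeds tissue size")
        idx = rng.choice(n_cells, size=spec.n_perturbed_cells, replace=False)
        perturbed[idx] = True
    s = spec.icp_intensity / 100.0
    for i in range(n_cells):
        mm_n = mm_g = m_mrna
        mp_n = mp_g = m_prot
        if spec.icp_mode == "uniform_variability":
            # per-species uniform mean layer, then the Poisson/fair-binomial
            # composition
            mm_n = rng.uniform(max(0.0, m_mrna * (1 - s)), m_mrna * (1 + s))
            mm_g = rng.uniform(max(0.0, m_mrna * (1 - s)), m_mrna * (1 + s))
            mp_n = rng.uniform(max(0.0, m_prot * (1 - s)), m_prot * (1 + s))
            mp_g = rng.uniform(max(0.0, m_prot * (1 - s)), m_prot * (1 + s))
        elif perturbed[i]:
            if spec.icp_mode == "equal_linear":
                fn = fg = 1.0 + s
            else:
                fn, fg = 1.0 - s, 1.0 + s
            mm_n, mm_g = m_mrna * fn, m_mrna * fg
            mp_n, mp_g = m_prot * fn, m_prot * fg
        x[i, S.Nanog_mRNA], x[i, S.Gata6_mRNA] = _split_pool(rng, mm_n, mm_g, comp)
        x[i, S.NANOG], x[i, S.GATA6] = _split_pool(rng, mp_n, mp_g, comp)
        x[i, S.I_ERK] = int(round(params.Pbar_ERK))
    return x


def icd_sampler(params: ParameterSet, n_cells: int,
                spec: PerturbationSpec = PerturbationSpec()) -> Callable:
    """Bind an ICD into the ``icd_sampler(rng)`` callable used by batches."""
    return lambda rng: sample_icd(params, n_cells, spec, rng=rng)


def add_exogenous_fgf4(
    params: ParameterSet,
    n_cells: int,
    mean_copies: float,
    time_h: float,
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
) -> Intervention:
    """Build a timed exogenous FGF4 addition for every cell.

    Each cell receives an independent Binomial(Poisson(2*mean), 1/2) draw
    (per-cell expectation = ``mean_copies``), entering the membrane monomer
    pool (or cytoplasm, per the parameter flag) at the scheduled time.
    """
    if mean_copies < 0:
        raise ValueError("mean must be non-negative")
    if rng is None:
        rng = np.random.default_rng(seed)
    counts = np.zeros(n_cells, dtype=np.int64)
    if mean_copies > 0:
        pool = rng.poisson(2.0 * mean_copies, size=n_cells)
        counts = rng.binomial(pool, 0.5)
    sp = S.M_FGFR_FGF4 if params.exogenous_target == "membrane" else S.FGF4
    return Intervention(time_h * 3600.0, counts.astype(np.int64), sp)


def final_fate_counts(ensemble: Sequence[GridSeries]) -> np.ndarray:
    """(R, 3) lineage counts at the last grid point of each replicate."""
    return np.stack([fate_counts(s)[-1] for s in ensemble])


def cv_from_counts(counts: np.ndarray, eta: int) -> pd.DataFrame:
    """CV1 (simulated) and binomial-baseline CV0 per fate from 48 h counts.

    CV1 = sd/mean of the replicate fate counts; CV0 = sqrt((1-p)/(eta*p))
    for the same mean fate fraction p.  Zero-mean fates give NaN.
    """
    rows = []
    for f, name in enumerate(FATES):
        c = counts[:, f].astype(float)
        mu = c.mean()
        if mu == 0:
            cv1 = cv0 = np.nan
        else:
            cv1 = c.std(ddof=1) / mu
            p = mu / eta
            cv0 = np.sqrt((1.0 - p) / (eta * p))
        rows.append({"fate": name, "eta": eta, "cv1": cv1, "cv0": cv0,
                     "ratio": cv0 / cv1 if cv1 and np.isfinite(cv1) else np.nan})
    return pd.DataFrame(rows)


def cv_analysis(
    params: ParameterSet,
    sizes: Sequence[int],
    n_reps: int,
    variant: str,
    base_seed: int,
    t_end: float = 48 * 3600.0,
) -> pd.DataFrame:
    """Coefficient-of-variation scan over system sizes.

    For each size eta, runs ``n_reps`` replicates to ``t_end``, classifies
    fates at the final time point and reports CV1, the binomial baseline CV0
    and their ratio per fate.
    """
    frames = []
    for k, eta in enumerate(sizes):
        lat = lattice_for_size(eta)
        ens = run_batch(params, lat, variant, icd_sampler(params, eta),
                        n_reps, base_seed + k, t_end)
        frames.append(cv_from_counts(final_fate_counts(ens), eta))
    return pd.concat(frames, ignore_index=True)


def safd(ref: np.ndarray, pert: np.ndarray) -> float:
    """Standardized absolute fate deviation |mu_ref - mu_pert| / sigma_ref.

    Inputs are per-replicate counts (or proportions) of one fate at a common
    evaluation time; NaN when the reference ensemble has zero spread.
    """
    ref = np.asarray(ref, dtype=float)
    pert = np.asarray(pert, dtype=float)
    sigma = ref.std(ddof=1)
    if sigma == 0:
        return float("nan")
    return float(abs(ref.mean() - pert.mean()) / sigma)


def fate_error(ref: np.ndarray, pert: np.ndarray) -> float:
    """Signed mean difference of cell-fate counts, perturbed minus reference."""
    return float(np.asarray(pert, dtype=float).mean()
                 - np.asarray(ref, dtype=float).mean())


def concentration_conversion(mean_copies_per_cell: float, n_cells: int) -> float:
    """Convert a mean per-cell FGF4 copy number to a medium mass
    concentration in ng/ml.

    gamma = (x_total * M) / (N_A * V_med) with M = 25 kDa and a closed
    medium of ``n_cells`` cells at 4200 um^3 each; linear in the per-cell
    mean and independent of the cell number.
    """
    if n_cells <= 0:
        raise ValueError("n_cells must be positive")
    if mean_copies_per_cell < 0:
        raise ValueError("copy number must be non-negative")
    total = mean_copies_per_cell * n_cells
    mass_g = total * FGF4_MASS_KDA * 1000.0 / AVOGADRO
    v_med_ml = n_cells * 4200.0 * 1e-12
    return mass_g * 1e9 / v_med_ml
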