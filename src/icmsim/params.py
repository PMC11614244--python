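"""Model parameters and rate derivations for the ICM fate-proportioning network.

The model tracks three genes (*Nanog*, *Gata6*, *Fgf4*) and their protein
products inside each cell of a static 2D tissue, together with the FGF4/ERK
signal-transduction branch (FGFR-FGF4 monomer/dimer complexes, inactive and
active ERK, phosphorylated NANOG).  A :class:`ParameterSet` bundles

* the fixed biophysical constants (cell volume, diffusion coefficients,
  mRNA/protein steady-state targets and lifetimes, dimerization kinetics), and
* the free parameters that were the subject of the original inference
  campaign (promoter half-saturation thresholds, signaling time scales,
  initial-condition means), frozen here at their MAP estimates,

and derives every mass-action rate constant used by the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "ParameterSet",
    "PROMOTER_PAIRS",
    "PromoterPair",
    "FREE_PARAM_NAMES",
    "FREE_PARAM_BOUNDS",
    "RTM_FREE_PARAM_NAMES",
    "VARIANTS",
    "derive_promoter_rates",
    "promoter_unbinding_rates",
    "ladder_half_occupancy_ratio",
    "derive_expression_rates",
    "classification_thresholds",
]

#: Model variants.  ITWT: inferred wild type, all channels.  RTM: reinferred
#: mutant, all cell-cell signaling channels removed.  TM-APM/TM-A/TM-PM:
#: theoretical mutants removing (autocrine+paracrine+membrane-exchange),
#: autocrine only, or (paracrine+membrane-exchange) transport.  TM-FGF4:
#: *Fgf4* transcription removed (full loss of FGF4 production).
VARIANTS = ("ITWT", "RTM", "TM-APM", "TM-A", "TM-PM", "TM-FGF4")

GENES = ("Nanog", "Gata6", "Fgf4")

HOUR = 3600.0


@dataclass(frozen=True)
class PromoterPair:
    """One gene--TF regulatory pair: ``q`` independent binding sites that the
    TF fills one copy at a time; full occupancy switches the gene."""

    name: str       # e.g. "Nanog_NANOG" (gene_TF alias)
    gene: str       # regulated gene
    tf: str         # "NANOG_pool" ({NANOG, P-NANOG}), "GATA6" or "A-ERK"
    role: str       # "activator" or "repressor"
    q: int          # number of TF binding sites (cooperativity degree)


#: Regulated gene--TF pairs.  {NANOG, P-NANOG} act as one pooled TF.
PROMOTER_PAIRS: tuple[PromoterPair, ...] = (
    PromoterPair("Nanog_NANOG", "Nanog", "NANOG_pool", "activator", 4),
    PromoterPair("Nanog_GATA6", "Nanog", "GATA6", "repressor", 4),
    PromoterPair("Gata6_NANOG", "Gata6", "NANOG_pool", "repressor", 4),
    PromoterPair("Gata6_GATA6", "Gata6", "GATA6", "activator", 4),
    PromoterPair("Fgf4_NANOG", "Fgf4", "NANOG_pool", "activator", 2),
    PromoterPair("Fgf4_GATA6", "Fgf4", "GATA6", "repressor", 2),
    PromoterPair("Nanog_AERK", "Nanog", "A-ERK", "repressor", 3),
    PromoterPair("Gata6_AERK", "Gata6", "A-ERK", "activator", 3),
)

#: Ordered free-parameter names (the 19-dimensional inference space).
FREE_PARAM_NAMES: tuple[str, ...] = (
    "Nanog_NANOG",
    "Gata6_GATA6",
    "Gata6_NANOG",
    "Nanog_GATA6",
    "Fgf4_NANOG",
    "Gata6_AERK",
    "Fgf4_GATA6",
    "Nanog_AERK",
    "tau_escape",
    "tau_exchange",
    "chi_auto",
    "tau_pho_erk",
    "tau_doh_erk",
    "tau_pho_nanog",
    "tau_doh_nanog",
    "mean_init_mrna",
    "mean_init_protein",
    "tau_d_fgf4",
    "tau_d_mfgfr",
)

#: Uniform prior bounds per free parameter (units: copies for thresholds and
#: initial-condition means, seconds for time scales, dimensionless for
#: chi_auto).
FREE_PARAM_BOUNDS: dict[str, tuple[float, float]] = {
    "Nanog_NANOG": (0.0, 1000.0),
    "Gata6_GATA6": (0.0, 1000.0),
    "Gata6_NANOG": (0.0, 1000.0),
    "Nanog_GATA6": (0.0, 1000.0),
    "Fgf4_NANOG": (0.0, 1000.0),
    "Gata6_AERK": (0.0, 1000.0),
    "Fgf4_GATA6": (0.0, 1000.0),
    "Nanog_AERK": (0.0, 1000.0),
    "tau_escape": (300.0, 4500.0),
    "tau_exchange": (30.0, 4200.0),
    "chi_auto": (0.0, 1.0),
    "tau_pho_erk": (300.0, 43200.0),
    "tau_doh_erk": (30.0, 43200.0),
    "tau_pho_nanog": (300.0, 43200.0),
    "tau_doh_nanog": (30.0, 43200.0),
    "mean_init_mrna": (0.0, 250.0),
    "mean_init_protein": (0.0, 1000.0),
    "tau_d_fgf4": (300.0, 28800.0),
    "tau_d_mfgfr": (300.0, 28800.0),
}

#: The RTM reinfers only the core GRN motif thresholds.
RTM_FREE_PARAM_NAMES: tuple[str, ...] = (
    "Nanog_NANOG",
    "Gata6_GATA6",
    "Gata6_NANOG",
    "Nanog_GATA6",
)


@dataclass(frozen=True)
class ParameterSet:
    """All fixed and free model parameters plus numerical-convention flags.

    Defaults correspond to the wild-type MAP estimate.  Times are seconds,
    lengths micrometres, counts molecule copies per cell.
    """

    # -- fixed biophysics --------------------------------------------------
    V: float = 4200.0          # cell volume [um^3]
    D: float = 10.0            # TF diffusion coefficient [um^2/s]
    d: float = 0.01            # promoter binding-site diameter [um]
    k_coop: float = 5.0        # cooperativity tuning coefficient
    c_basal: float = 0.2       # basal share of mRNA production
    c_find: float = 0.8        # full-induction share of mRNA production
    Mbar_Nanog: float = 250.0  # full-induction mean mRNA copies
    Mbar_Gata6: float = 250.0
    Mbar_Fgf4: float = 200.0
    tau_m_Nanog: float = 4.0 * HOUR   # mRNA mean lifetime
    tau_m_Gata6: float = 4.0 * HOUR
    tau_m_Fgf4: float = 4.0 * HOUR
    Pbar_NANOG: float = 1000.0        # full-induction mean protein copies
    Pbar_GATA6: float = 1000.0
    Pbar_FGF4: float = 800.0
    Pbar_ERK: float = 1000.0
    tau_p_NANOG: float = 2.0 * HOUR   # protein mean lifetime
    tau_p_GATA6: float = 2.0 * HOUR
    tau_p_ERK: float = 48.0 * HOUR
    tau_p_PNANOG: float = 1.0 * HOUR
    tau_p_DFGFR: float = 240.0 * HOUR
    k_mono: float = 1.0 / 360.0       # dimer -> 2 monomers [1/s]

    # -- free parameters (MAP defaults) ------------------------------------
    Nanog_NANOG: float = 125.0    # half-saturation, Nanog self-activation
    Gata6_GATA6: float = 275.0    # half-saturation, Gata6 self-activation
    Gata6_NANOG: float = 412.0    # half-saturation, Gata6 repression by NANOG
    Nanog_GATA6: float = 411.0    # half-saturation, Nanog repression by GATA6
    Fgf4_NANOG: float = 552.0     # half-saturation, Fgf4 activation by NANOG
    Gata6_AERK: float = 615.0     # half-saturation, Gata6 activation by A-ERK
    Fgf4_GATA6: float = 95.0      # half-saturation, Fgf4 repression by GATA6
    Nanog_AERK: float = 695.0     # half-saturation, Nanog repression by A-ERK
    tau_escape: float = 2303.0    # mean FGF4 escape time [s]
    tau_exchange: float = 1380.0  # mean FGF4 membrane-exchange time [s]
    chi_auto: float = 0.39        # autocrine share of the escape flux
    tau_pho_erk: float = 31379.0  # ERK phosphorylation half-turnover [s]
    tau_doh_erk: float = 1025.0   # ERK dephosphorylation half-turnover [s]
    tau_pho_nanog: float = 18944.0
    tau_doh_nanog: float = 21361.0
    mean_init_mrna: float = 117.0     # per-gene initial mRNA mean [copies]
    mean_init_protein: float = 482.0  # per-gene initial protein mean [copies]
    tau_d_fgf4: float = 13158.0   # cytoplasmic FGF4 lifetime [s]
    tau_d_mfgfr: float = 3456.0   # membrane monomer-complex lifetime [s]

    # -- numerical-convention flags ----------------------------------------
    #: promoter unbinding-rate rule:
    #:   "cooperative" (default) — nucleation-type cooperativity: partially
    #:     occupied promoter states are unstable (unbinding k_coop-fold
    #:     faster than h_sat*k_b) while the complete q-copy complex is
    #:     mutually stabilized, unbinding at h_sat*k_b/k_coop**(q-1).  The
    #:     stationary switched-state probability is then Hill-like with
    #:     exponent ~q and midpoint approximately at A = h_sat.
    #:   "half_occupancy" — constant k_u = h_sat*k_b/r*(q) at every step,
    #:     with r*(q) the ladder ratio at which full occupancy has
    #:     probability 1/2 (shallow, non-cooperative response);
    #:   "coop_linear"  — constant k_u = h_sat*k_b/(k_coop*q);
    #:   "coop_power"   — constant k_u = h_sat*k_b/k_coop**q.
    ku_rule: str = "cooperative"
    rho_faces: int = 6            # voxel faces used in rho_meme (6 or 4)
    sequester_bound_tf: bool = True   # promoter-bound TF copies leave free pool
    dimer_ligand_count: int = 2   # FGF4 ligands counted per dimer complex
    icd_split: str = "complementary"  # "complementary" or "independent" split
    exogenous_target: str = "membrane"  # where exogenous FGF4 enters

    def __post_init__(self) -> None:
        if not math.isclose(self.c_basal + self.c_find, 1.0, rel_tol=1e-9):
            raise ValueError("c_basal + c_find must equal 1")
        if not 0.0 <= self.chi_auto <= 1.0:
            raise ValueError("chi_auto must lie in [0, 1]")
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name.startswith(("tau_", "Mbar", "Pbar")) or f.name in "VDd":
                if not isinstance(v, bool) and v <= 0:
                    raise ValueError(f"{f.name} must be strictly positive")
        for pair in PROMOTER_PAIRS:
            if getattr(self, pair.name) < 0:
                raise ValueError(f"{pair.name} must be non-negative")
        if self.ku_rule not in ("cooperative", "half_occupancy", "coop_linear",
                                "coop_power"):
            raise ValueError(
                "ku_rule must be 'cooperative', 'half_occupancy', "
                "'coop_linear' or 'coop_power'")
        if self.rho_faces not in (4, 6):
            raise ValueError("rho_faces must be 4 or 6")
        if self.icd_split not in ("complementary", "independent"):
            raise ValueError("icd_split must be 'complementary' or 'independent'")
        if self.exogenous_target not in ("membrane", "cytoplasm"):
            raise ValueError("exogenous_target must be 'membrane' or 'cytoplasm'")

    # -- derived rates -----------------------------------------------------
    @property
    def chi_para(self) -> float:
        return 1.0 - self.chi_auto

    @property
    def k_b(self) -> float:
        """Nominal promoter binding rate, diffusion-limited: 4*pi*d*D/V."""
        return 4.0 * math.pi * self.d * self.D / self.V

    @property
    def k_dime(self) -> float:
        """Monomer-complex dimerization rate; receptor-ligand complexes are
        assumed to diffuse 30x slower than free TFs."""
        return 4.0 * math.pi * self.d * (self.D / 30.0) / self.V

    @property
    def k_escape(self) -> float:
        return 1.0 / self.tau_escape

    @property
    def k_exchange(self) -> float:
        return 1.0 / self.tau_exchange

    def mbar(self, gene: str) -> float:
        return getattr(self, f"Mbar_{gene}")

    def tau_m(self, gene: str) -> float:
        return getattr(self, f"tau_m_{gene}")

    def with_free(self, values: dict[str, float]) -> "ParameterSet":
        """Return a copy with the given free parameters replaced."""
        unknown = set(values) - set(FREE_PARAM_NAMES)
        if unknown:
            raise ValueError(f"unknown free parameters: {sorted(unknown)}")
        return replace(self, **values)

    def free_vector(self) -> list[float]:
        return [getattr(self, n) for n in FREE_PARAM_NAMES]


_PAIR_BY_NAME = {p.name: p for p in PROMOTER_PAIRS}


def ladder_half_occupancy_ratio(q: int) -> float:
    """Per-step bind/unbind ratio at which the q-step ladder's full
    occupancy has probability exactly 1/2.

    The ladder with constant up-rate ``k_b A`` and down-rate ``k_u`` has the
    geometric stationary law ``pi(Q) ~ r**Q`` with ``r = k_b A / k_u``, so
    the half-occupancy ratio is the positive root of
    ``r**q = sum_{Q<q} r**Q`` (1.618, 1.839, 1.928 for q = 2, 3, 4).
    """
    if q < 1:
        raise ValueError("q must be >= 1")
    coeffs = [1.0] + [-1.0] * q  # r**q - r**(q-1) - ... - 1 = 0
    roots = [r.real for r in np.roots(coeffs)
             if abs(r.imag) < 1e-12 and r.real > 0]
    return max(roots)


def derive_promoter_rates(params: ParameterSet, pair: str) -> tuple[float, float]:
    """Nominal binding rate and full-complex unbinding rate for a pair.

    Binding is diffusion-limited and identical for every pair and every
    ladder step: ``k_b = 4*pi*d*D/V`` (the effective propensity is ``k_b``
    times the free TF copy number).  The returned ``k_u`` is the unbinding
    rate of the fully occupied promoter; see
    :func:`promoter_unbinding_rates` for the step-resolved rates.
    """
    _, k_u_full = promoter_unbinding_rates(params, pair)
    return params.k_b, k_u_full


def promoter_unbinding_rates(params: ParameterSet, pair: str) -> tuple[float, float]:
    """Step-resolved promoter unbinding rates ``(k_u_partial, k_u_full)``.

    ``k_u_partial`` applies when leaving a partially occupied state
    (occupancy 1..q-1 after the event is still possible), ``k_u_full`` when
    leaving the complete q-copy complex.

    Under the default ``cooperative`` rule the bound TF copies stabilize
    each other only once all ``q`` sites are filled: partial complexes decay
    fast (``k_coop * h_sat * k_b``) while the full complex unbinds at
    ``h_sat * k_b / k_coop**(q-1)``.  The product of step ratios then gives
    a switched-state probability that is Hill-like with exponent ~q and
    midpoint approximately at a free TF count of ``h_sat``.  The alternative rules
    use one constant rate for every step: ``h_sat*k_b/r*(q)`` (ladder
    half-occupancy calibration), ``h_sat*k_b/(k_coop*q)`` or
    ``h_sat*k_b/k_coop**q``.
    """
    try:
        p = _PAIR_BY_NAME[pair]
    except KeyError:
        raise ValueError(f"unknown gene-TF pair {pair!r}") from None
    h_sat = getattr(params, pair)
    base = h_sat * params.k_b
    if params.ku_rule == "cooperative":
        return base * params.k_coop, base / params.k_coop ** (p.q - 1)
    if params.ku_rule == "coop_power":
        k_u = base / params.k_coop ** p.q
    elif params.ku_rule == "coop_linear":
        k_u = base / (params.k_coop * p.q)
    else:
        k_u = base / ladder_half_occupancy_ratio(p.q)
    return k_u, k_u


def derive_expression_rates(params: ParameterSet, gene: str):
    """mRNA and protein synthesis/degradation rates for one gene.

    Returns ``(k_m_s_basal, k_m_s_find, k_m_d, k_p_s, k_p_d)`` in 1/s.
    ``k_p_s`` is the per-mRNA translation propensity, chosen so that the
    full-induction steady-state protein level equals ``Pbar``:
    ``k_p_s = Pbar / (Mbar * tau_p)``.  *Fgf4* has no basal transcription.
    """
    if gene not in GENES:
        raise ValueError(f"unknown gene {gene!r}")
    mbar, tau_m = params.mbar(gene), params.tau_m(gene)
    if tau_m <= 0:
        raise ValueError("mRNA lifetime must be positive")
    k_m_total = mbar / tau_m
    if gene == "Fgf4":
        k_m_s_basal, k_m_s_find = 0.0, k_m_total
        pbar, tau_p = params.Pbar_FGF4, params.tau_d_fgf4
    else:
        k_m_s_basal = params.c_basal * k_m_total
        k_m_s_find = params.c_find * k_m_total
        pbar = getattr(params, f"Pbar_{gene.upper()}")
        tau_p = getattr(params, f"tau_p_{gene.upper()}")
    return (k_m_s_basal, k_m_s_find, 1.0 / tau_m, pbar / (mbar * tau_p), 1.0 / tau_p)


def classification_thresholds(params: ParameterSet) -> tuple[float, float, float]:
    """Fate-classification constants ``(low, high_nanog, high_gata6)``.

    Assuming Poissonian copy-number noise, the high-NANOG threshold is the
    mean full-induction level after ERK-mediated phosphorylation halves it,
    minus five standard deviations: ``P/2 - 5*sqrt(P/2)``; the high-GATA6
    threshold is ``P - 5*sqrt(P)``.  The low threshold (basal mean plus five
    standard deviations) is pinned at its published value of 329 copies.
    """
    p = params.Pbar_NANOG
    high_nanog = p / 2.0 - 5.0 * math.sqrt(p / 2.0)
    pg = params.Pbar_GATA6
    high_gata6 = pg - 5.0 * math.sqrt(pg)
    return 329.0, high_nanog, high_gata6
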