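"""Intracellular reaction channels of the NANOG--GATA6--FGF4 network.

State layout (one cell).  Indices 0..10 are molecular species copy numbers,
indices 11..18 are promoter-site occupancies, one per regulated gene--TF pair
in the order of :data:`icmsim.params.PROMOTER_PAIRS`:

====  =====================
 0    Nanog mRNA
 1    Gata6 mRNA
 2    Fgf4 mRNA
 3    NANOG
 4    P-NANOG (phosphorylated)
 5    GATA6
 6    FGF4 (cytoplasmic)
 7    M-FGFR-FGF4 (membrane monomer complex)
 8    D-FGFR-FGF4 (membrane dimer complex)
 9    I-ERK (inactive)
10    A-ERK (active)
====  =====================

Gene switching is all-or-nothing: a gene is repressed (``G_rep = 1``) when
any of its repressor pairs has all ``q`` sites occupied and activated
(``G_act = 1``) when any activator pair is fully occupied; repression takes
precedence over activation.  Basal transcription runs at ``c_basal`` of the
full rate whenever the gene is unrepressed (*Fgf4* has no basal mode);
full-induction transcription additionally requires activation.

By default promoter-bound TF copies are sequestered: binding removes one
copy from the free pool and unbinding returns it.  For the pooled
{NANOG, P-NANOG} transcription factor, the bound copy is drawn
proportionally from the two forms and unbinding releases an unphosphorylated
copy (the total NANOG pool is conserved either way).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .params import (GENES, PROMOTER_PAIRS, ParameterSet,
                     derive_expression_rates, promoter_unbinding_rates)

__all__ = [
    "SPECIES",
    "NSPECIES",
    "NSTATE",
    "S",
    "ReactionChannel",
    "build_cell_channels",
    "evaluate_propensity",
    "propensity_vector",
    "gene_regulation_state",
]

SPECIES = (
    "Nanog_mRNA",
    "Gata6_mRNA",
    "Fgf4_mRNA",
    "NANOG",
    "P_NANOG",
    "GATA6",
    "FGF4",
    "M_FGFR_FGF4",
    "D_FGFR_FGF4",
    "I_ERK",
    "A_ERK",
)
NSPECIES = len(SPECIES)
NPAIRS = len(PROMOTER_PAIRS)
NSTATE = NSPECIES + NPAIRS


class S:
    """Named state-vector indices."""

    Nanog_mRNA, Gata6_mRNA, Fgf4_mRNA = 0, 1, 2
    NANOG, P_NANOG, GATA6, FGF4 = 3, 4, 5, 6
    M_FGFR_FGF4, D_FGFR_FGF4, I_ERK, A_ERK = 7, 8, 9, 10
    OCC0 = NSPECIES  # first promoter-occupancy slot


# TF pool id per pair: 0 = {NANOG, P-NANOG}, 1 = GATA6, 2 = A-ERK
PAIR_TF_POOL = tuple(
    {"NANOG_pool": 0, "GATA6": 1, "A-ERK": 2}[p.tf] for p in PROMOTER_PAIRS
)
PAIR_Q = tuple(p.q for p in PROMOTER_PAIRS)

# per-gene (activator pair indices, repressor pair indices)
GENE_REGULATORS = {
    "Nanog": ((0,), (1, 6)),
    "Gata6": ((3, 7), (2,)),
    "Fgf4": ((4,), (5,)),
}

_POOL_SPECIES = {1: (S.GATA6,), 2: (S.A_ERK,), 0: (S.NANOG, S.P_NANOG)}


def _free_pool(x: np.ndarray, pool: int) -> float:
    return float(sum(x[i] for i in _POOL_SPECIES[pool]))


def gene_regulation_state(x: np.ndarray, gene: str) -> tuple[int, int]:
    """Return ``(G_rep, G_act)`` indicators for a gene in state ``x``."""
    acts, reps = GENE_REGULATORS[gene]
    g_rep = int(any(x[S.OCC0 + p] == PAIR_Q[p] for p in reps))
    g_act = int(any(x[S.OCC0 + p] == PAIR_Q[p] for p in acts))
    return g_rep, g_act


@dataclass(frozen=True)
class ReactionChannel:
    """Propensity rule plus stoichiometric state-change vector."""

    name: str
    label: str  # reaction-group tag
    propensity: Callable[[np.ndarray], float]
    delta: np.ndarray  # (NSTATE,) integer increments

    def apply(self, x: np.ndarray) -> np.ndarray:
        out = x + self.delta
        if (out < 0).any():
            raise RuntimeError(f"channel {self.name} produced a negative count")
        return out


def evaluate_propensity(channel: ReactionChannel, state: np.ndarray) -> float:
    """Mass-action propensity of a channel in a given cell state [1/s]."""
    return float(channel.propensity(state))


def _delta(**inc: int) -> np.ndarray:
    d = np.zeros(NSTATE, dtype=np.int64)
    for key, v in inc.items():
        d[getattr(S, key) if hasattr(S, key) else int(key)] = v
    return d


def _occ_delta(pair: int, docc: int, dspecies: dict[int, int]) -> np.ndarray:
    d = np.zeros(NSTATE, dtype=np.int64)
    d[S.OCC0 + pair] = docc
    for idx, v in dspecies.items():
        d[idx] += v
    return d


def build_cell_channels(params: ParameterSet, variant: str) -> list[ReactionChannel]:
    """All intracellular reaction channels of one cell for a model variant.

    The channel topology is identical across variants except that TM-FGF4
    removes *Fgf4* transcription; variants differ otherwise only through
    parameter values and transport channels (handled at tissue level).
    """
    if variant not in ("ITWT", "RTM", "TM-APM", "TM-A", "TM-PM", "TM-FGF4"):
        raise ValueError(f"unknown variant {variant!r}")
    seq = params.sequester_bound_tf
    ch: list[ReactionChannel] = []

    # --- promoter binding/unbinding ladders -------------------------------
    for pidx, pair in enumerate(PROMOTER_PAIRS):
        k_b = params.k_b
        k_u_part, k_u_full = promoter_unbinding_rates(params, pair.name)
        pool = PAIR_TF_POOL[pidx]
        q = pair.q
        occ = S.OCC0 + pidx

        def a_bind(x, *, occ=occ, q=q, pool=pool, k_b=k_b):
            if x[occ] >= q:
                return 0.0
            return k_b * _free_pool(x, pool)

        if seq:
            if pool == 0:
                # split by donor species so each channel has fixed stoichiometry
                def a_bind_n(x, *, occ=occ, q=q, k_b=k_b):
                    return 0.0 if x[occ] >= q else k_b * x[S.NANOG]

                def a_bind_pn(x, *, occ=occ, q=q, k_b=k_b):
                    return 0.0 if x[occ] >= q else k_b * x[S.P_NANOG]

                ch.append(ReactionChannel(f"bind:{pair.name}:NANOG", "promoter",
                                          a_bind_n, _occ_delta(pidx, +1, {S.NANOG: -1})))
                ch.append(ReactionChannel(f"bind:{pair.name}:P_NANOG", "promoter",
                                          a_bind_pn, _occ_delta(pidx, +1, {S.P_NANOG: -1})))
                unbind_delta = _occ_delta(pidx, -1, {S.NANOG: +1})
            else:
                sp = _POOL_SPECIES[pool][0]
                ch.append(ReactionChannel(f"bind:{pair.name}", "promoter",
                                          a_bind, _occ_delta(pidx, +1, {sp: -1})))
                unbind_delta = _occ_delta(pidx, -1, {sp: +1})
        else:
            ch.append(ReactionChannel(f"bind:{pair.name}", "promoter",
                                      a_bind, _occ_delta(pidx, +1, {})))
            unbind_delta = _occ_delta(pidx, -1, {})

        def a_unbind(x, *, occ=occ, q=q, kp=k_u_part, kf=k_u_full):
            if x[occ] <= 0:
                return 0.0
            return kf if x[occ] == q else kp

        ch.append(ReactionChannel(f"unbind:{pair.name}", "promoter", a_unbind, unbind_delta))

    # --- transcription, translation, degradation --------------------------
    mrna_idx = {"Nanog": S.Nanog_mRNA, "Gata6": S.Gata6_mRNA, "Fgf4": S.Fgf4_mRNA}
    prot_idx = {"Nanog": S.NANOG, "Gata6": S.GATA6, "Fgf4": S.FGF4}
    for gene in GENES:
        k_basal, k_find, k_m_d, k_p_s, k_p_d = derive_expression_rates(params, gene)
        m, p = mrna_idx[gene], prot_idx[gene]
        if gene != "Fgf4" and k_basal > 0:
            def a_basal(x, *, gene=gene, k=k_basal):
                g_rep, _ = gene_regulation_state(x, gene)
                return k * (1 - g_rep)

            ch.append(ReactionChannel(f"transcribe_basal:{gene}", "transcription",
                                      a_basal, _delta(**{str(m): +1})))
        if not (gene == "Fgf4" and variant == "TM-FGF4"):
            def a_find(x, *, gene=gene, k=k_find):
                g_rep, g_act = gene_regulation_state(x, gene)
                return k * (1 - g_rep) * g_act

            ch.append(ReactionChannel(f"transcribe_induced:{gene}", "transcription",
                                      a_find, _delta(**{str(m): +1})))
        ch.append(ReactionChannel(f"degrade_mrna:{gene}", "mrna_turnover",
                                  lambda x, m=m, k=k_m_d: k * x[m],
                                  _delta(**{str(m): -1})))
        ch.append(ReactionChannel(f"translate:{gene}", "translation",
                                  lambda x, m=m, k=k_p_s: k * x[m],
                                  _delta(**{str(p): +1})))
        ch.append(ReactionChannel(f"degrade_protein:{gene}", "protein_turnover",
                                  lambda x, p=p, k=k_p_d: k * x[p],
                                  _delta(**{str(p): -1})))

    # remaining first-order protein decays
    for name, idx, tau in (
        ("P_NANOG", S.P_NANOG, params.tau_p_PNANOG),
        ("M_FGFR_FGF4", S.M_FGFR_FGF4, params.tau_d_mfgfr),
        ("D_FGFR_FGF4", S.D_FGFR_FGF4, params.tau_p_DFGFR),
        ("I_ERK", S.I_ERK, params.tau_p_ERK),
        ("A_ERK", S.A_ERK, params.tau_p_ERK),
    ):
        k = 1.0 / tau
        ch.append(ReactionChannel(f"degrade_protein:{name}", "protein_turnover",
                                  lambda x, idx=idx, k=k: k * x[idx],
                                  _delta(**{str(idx): -1})))

    # --- FGFR dimerization / monomerization -------------------------------
    k_dime = params.k_dime
    ch.append(ReactionChannel("dimerize", "fgfr",
                              lambda x, k=k_dime: k * x[S.M_FGFR_FGF4] * (x[S.M_FGFR_FGF4] - 1) / 2.0,
                              _delta(M_FGFR_FGF4=-2, D_FGFR_FGF4=+1)))
    ch.append(ReactionChannel("monomerize", "fgfr",
                              lambda x, k=params.k_mono: k * x[S.D_FGFR_FGF4],
                              _delta(M_FGFR_FGF4=+2, D_FGFR_FGF4=-1)))

    # --- ERK activation / inactivation ------------------------------------
    k_phoE, k_dohE = 1.0 / params.tau_pho_erk, 1.0 / params.tau_doh_erk
    ch.append(ReactionChannel("erk_activate", "erk",
                              lambda x, k=k_phoE: k * x[S.D_FGFR_FGF4] * x[S.I_ERK],
                              _delta(I_ERK=-1, A_ERK=+1)))
    ch.append(ReactionChannel("erk_inactivate", "erk",
                              lambda x, k=k_dohE: k * x[S.A_ERK],
                              _delta(I_ERK=+1, A_ERK=-1)))
    k_synE = params.Pbar_ERK / params.tau_p_ERK
    ch.append(ReactionChannel("erk_synthesize", "erk",
                              lambda x, k=k_synE: k, _delta(I_ERK=+1)))

    # --- NANOG (de)phosphorylation ----------------------------------------
    k_phoN, k_dohN = 1.0 / params.tau_pho_nanog, 1.0 / params.tau_doh_nanog
    ch.append(ReactionChannel("nanog_phosphorylate", "nanog_pho",
                              lambda x, k=k_phoN: k * x[S.A_ERK] * x[S.NANOG],
                              _delta(NANOG=-1, P_NANOG=+1)))
    ch.append(ReactionChannel("nanog_dephosphorylate", "nanog_pho",
                              lambda x, k=k_dohN: k * x[S.P_NANOG],
                              _delta(NANOG=+1, P_NANOG=-1)))
    return ch


def propensity_vector(channels: list[ReactionChannel], x: np.ndarray) -> np.ndarray:
    return np.array([c.propensity(x) for c in channels], dtype=float)
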