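"""Cell-level observables, fate classification, and tissue statistics.

A cell's lineage is read from two protein totals: total NANOG (free plus
phosphorylated) and total GATA6.  A cell is epiblast (EPI) when total NANOG
exceeds the high-NANOG threshold while total GATA6 is below the low
threshold; primitive endoderm (PRE) when total GATA6 exceeds the high-GATA6
threshold while total NANOG is below the low threshold; undifferentiated
(UND) otherwise.  Comparisons are strict, so counts exactly at a threshold
do not qualify as "above"/"below".

Total FGF4 aggregates cytoplasmic ligand, membrane monomer complexes and
(by default) two ligands per dimer complex.
"""

from __future__ import annotations

from typing import Iterable, Optional, Sequence

import numpy as np

from .engine import GridSeries
from .lattice import Lattice, neighborhood
from .params import ParameterSet, classification_thresholds
from .reactions import S

__all__ = [
    "FATES",
    "EPI",
    "PRE",
    "UND",
    "cell_totals",
    "classify_fate",
    "classify_grid",
    "fate_counts",
    "first_appearance",
    "protein_correlations",
    "neighborhood_composition",
    "multinomial_baseline",
    "fgf4_by_degree",
]

EPI, PRE, UND = 0, 1, 2
FATES = ("EPI", "PRE", "UND")

_DEFAULT_THRESHOLDS = classification_thresholds(ParameterSet())


def cell_totals(data: np.ndarray, dimer_ligands: int = 2) -> np.ndarray:
    """Aggregate protein totals (..., [total_NANOG, total_GATA6, total_FGF4])
    from state arrays of shape (..., NSTATE)."""
    nanog = data[..., S.NANOG] + data[..., S.P_NANOG]
    gata6 = data[..., S.GATA6]
    fgf4 = (data[..., S.FGF4] + data[..., S.M_FGFR_FGF4]
            + dimer_ligands * data[..., S.D_FGFR_FGF4])
    return np.stack([nanog, gata6, fgf4], axis=-1)


def classify_fate(
    total_nanog: float,
    total_gata6: float,
    thresholds: tuple[float, float, float] = _DEFAULT_THRESHOLDS,
) -> int:
    """Classify one cell from its protein totals; returns EPI, PRE or UND."""
    low, high_n, high_g = thresholds
    if total_nanog > high_n and total_gata6 < low:
        return EPI
    if total_gata6 > high_g and total_nanog < low:
        return PRE
    return UND


def classify_grid(
    series: GridSeries,
    thresholds: tuple[float, float, float] = _DEFAULT_THRESHOLDS,
    dimer_ligands: int = 2,
) -> np.ndarray:
    """(T, L) fate codes for every grid point and cell."""
    totals = cell_totals(series.data, dimer_ligands)
    low, high_n, high_g = thresholds
    nanog, gata6 = totals[..., 0], totals[..., 1]
    epi = (nanog > high_n) & (gata6 < low)
    pre = (gata6 > high_g) & (nanog < low) & ~epi
    out = np.full(nanog.shape, UND, dtype=np.int8)
    out[epi] = EPI
    out[pre] = PRE
    return out


def fate_counts(
    series: GridSeries,
    thresholds: tuple[float, float, float] = _DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """(T, 3) lineage counts (EPI, PRE, UND); rows always sum to L."""
    fates = classify_grid(series, thresholds)
    return np.stack([(fates == f).sum(axis=1) for f in (EPI, PRE, UND)], axis=1)


def first_appearance(
    ensemble: Sequence[GridSeries],
    fate: int,
    thresholds: tuple[float, float, float] = _DEFAULT_THRESHOLDS,
) -> np.ndarray:
    """Per replicate, the first grid time (hours) with >= 1 cell of ``fate``;
    NaN when the fate never appears."""
    if len(ensemble) == 0:
        raise ValueError("ensemble must be non-empty")
    out = np.full(len(ensemble), np.nan)
    for r, series in enumerate(ensemble):
        counts = fate_counts(series, thresholds)[:, fate]
        hit = np.nonzero(counts >= 1)[0]
        if hit.size:
            out[r] = series.times_h[hit[0]]
    return out


def protein_correlations(
    ensemble: Sequence[GridSeries], t_index: int = -1, dimer_ligands: int = 2
) -> np.ndarray:
    """Pairwise Pearson correlations among the three protein totals across
    all cells (pooled over replicates) at one grid time point.

    Zero-variance columns give NaN entries.
    """
    rows = [cell_totals(s.data[t_index], dimer_ligands) for s in ensemble]
    pooled = np.concatenate(rows, axis=0).astype(float)
    if pooled.shape[0] < 2:
        raise ValueError("need at least 2 cells")
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(pooled, rowvar=False)
    return r


def multinomial_baseline(fates: np.ndarray) -> np.ndarray:
    """Tissue-wide fate fractions (rho_0): the neighborhood composition of a
    spatially uncoupled multinomial null model."""
    fates = np.asarray(fates).ravel()
    return np.array([(fates == f).mean() for f in (EPI, PRE, UND)])


def neighborhood_composition(
    fates: np.ndarray,
    lattice: Lattice,
    degree: int,
    mode: str = "exact",
) -> np.ndarray:
    """Mean fate composition (rho_1) of each fate's degree-``k`` neighborhood.

    Returns a (3, 3) array: row f = reference fate, column g = mean fraction
    of fate-g cells among the neighbors.  ``mode='exact'`` uses cells at
    shortest-path distance exactly ``degree``; ``mode='upto'`` pools degrees
    1..``degree``.  Rows whose reference fate is absent are NaN.
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if mode not in ("exact", "upto"):
        raise ValueError("mode must be 'exact' or 'upto'")
    fates = np.asarray(fates).ravel()
    L = lattice.n_cells
    if fates.shape[0] != L:
        raise ValueError("fates length must match lattice size")
    comp = np.full((3, 3), np.nan)
    frac_sums = np.zeros((3, 3))
    counts = np.zeros(3)
    for i in range(L):
        if mode == "exact":
            neigh = neighborhood(lattice, i, degree)
        else:
            neigh = set()
            for k in range(1, degree + 1):
                neigh |= neighborhood(lattice, i, k)
        if not neigh:
            continue
        nf = np.array([fates[j] for j in neigh])
        f = fates[i]
        counts[f] += 1
        for g in (EPI, PRE, UND):
            frac_sums[f, g] += (nf == g).mean()
    for f in (EPI, PRE, UND):
        if counts[f] > 0:
            comp[f] = frac_sums[f] / counts[f]
    return comp


def fgf4_by_degree(
    data: np.ndarray,
    fates: np.ndarray,
    lattice: Lattice,
    max_degree: int,
    dimer_ligands: int = 2,
) -> dict[str, np.ndarray]:
    """Mean and sd of total FGF4 stratified by neighborhood degree around
    each fate class.

    ``data`` is one (L, NSTATE) snapshot.  Returns ``{"mean": a, "sd": b}``
    with arrays of shape (3, max_degree+1); degree 0 is the reference cell.
    Strata with no cells are NaN.
    """
    totals = cell_totals(data, dimer_ligands)[:, 2].astype(float)
    fates = np.asarray(fates).ravel()
    mean = np.full((3, max_degree + 1), np.nan)
    sd = np.full((3, max_degree + 1), np.nan)
    for f in (EPI, PRE, UND):
        refs = np.nonzero(fates == f)[0]
        if refs.size == 0:
            continue
        for k in range(max_degree + 1):
            vals = []
            for i in refs:
                for j in neighborhood(lattice, int(i), k):
                    vals.append(totals[j])
            if vals:
                arr = np.array(vals)
                mean[f, k] = arr.mean()
                sd[f, k] = arr.std(ddof=0)
    return {"mean": mean, "sd": sd}
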