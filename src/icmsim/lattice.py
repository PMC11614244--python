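"""Static 2D cell lattice, neighborhood stratification, and FGF4 transport.

The tissue is a rectangular grid of cuboidal cells ("voxels") one cell thick.
Two cells are first-degree neighbors only when they share a complete face, so
every cell has 2, 3 or 4 first-degree neighbors (diagonal contact does not
count).  Higher-degree neighborhoods are shells of equal shortest-path length
on the face-adjacency graph.

FGF4 leaves a cell's cytoplasm at total rate ``k_escape`` and lands on a
membrane as the receptor-bound monomer complex: on the emitting cell's own
membrane (autocrine) or a neighbor's (paracrine).  The split is governed by
the autocrine fraction ``chi_auto`` and the shared-surface fraction
``rho_meme``; the total escape flux is conserved regardless of neighbor
count.  Membrane-bound monomer complexes additionally hop between adjacent
membranes at ``k_meme = rho_meme * k_exchange``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ParameterSet

__all__ = [
    "Lattice",
    "TransportChannel",
    "build_lattice",
    "lattice_for_size",
    "factorize_size",
    "neighborhood",
    "rho_meme",
    "derive_signaling_rates",
    "build_transport_channels",
]


@dataclass(frozen=True)
class Lattice:
    rows: int
    cols: int
    #: (L, 4) int array of neighbor indices, padded with -1.
    neighbors: np.ndarray
    #: (L,) int array of first-degree neighbor counts.
    n_neighbors: np.ndarray

    @property
    def n_cells(self) -> int:
        return self.rows * self.cols

    def adjacent_pairs(self) -> list[tuple[int, int]]:
        """Unordered first-degree adjacent pairs (i < j)."""
        out = []
        for i in range(self.n_cells):
            for j in self.neighbors[i, : self.n_neighbors[i]]:
                if i < j:
                    out.append((i, int(j)))
        return out


@dataclass(frozen=True)
class TransportChannel:
    """A single cell-to-cell (or cell-to-self) FGF4 relabeling channel."""

    kind: str        # "autocrine", "paracrine" or "exchange"
    source: int
    destination: int
    rate: float      # [1/s] per source molecule

    @property
    def species_from(self) -> str:
        return "FGF4" if self.kind in ("autocrine", "paracrine") else "M-FGFR-FGF4"

    species_to: str = "M-FGFR-FGF4"


def build_lattice(rows: int, cols: int) -> Lattice:
    if rows < 1 or cols < 1:
        raise ValueError("lattice dimensions must be positive")
    L = rows * cols
    neighbors = np.full((L, 4), -1, dtype=np.int64)
    counts = np.zeros(L, dtype=np.int64)
    for r in range(rows):
        for c in range(cols):
            i = r * cols + c
            for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows and 0 <= cc < cols:
                    neighbors[i, counts[i]] = rr * cols + cc
                    counts[i] += 1
    neighbors.setflags(write=False)
    counts.setflags(write=False)
    return Lattice(rows, cols, neighbors, counts)


def factorize_size(n_cells: int) -> tuple[int, int]:
    """Most-square factorization rows x cols (rows <= cols) of a cell count."""
    if n_cells < 1:
        raise ValueError("cell count must be positive")
    best = (1, n_cells)
    for r in range(1, int(np.sqrt(n_cells)) + 1):
        if n_cells % r == 0:
            best = (r, n_cells // r)
    return best


def lattice_for_size(n_cells: int) -> Lattice:
    return build_lattice(*factorize_size(n_cells))


def neighborhood(lattice: Lattice, cell: int, degree: int) -> set[int]:
    """Cells at shortest face-adjacency path length exactly ``degree``.

    Degree 0 is the cell itself; strata of different degree are disjoint and
    jointly partition the lattice up to its diameter.
    """
    if not 0 <= cell < lattice.n_cells:
        raise ValueError(f"cell {cell} outside lattice")
    if degree < 0:
        raise ValueError("degree must be >= 0")
    # BFS by shells on the face-adjacency graph.
    frontier = {cell}
    seen = {cell}
    for _ in range(degree):
        nxt = set()
        for i in frontier:
            for j in lattice.neighbors[i, : lattice.n_neighbors[i]]:
                j = int(j)
                if j not in seen:
                    nxt.add(j)
        seen |= nxt
        frontier = nxt
        if not frontier:
            break
    return frontier


def rho_meme(lattice: Lattice, cell: int, faces: int = 6) -> float:
    """Fraction of a cell's surface shared with its first-degree neighbors.

    Under the cuboidal-voxel convention a monolayer cell has ``faces`` = 6
    faces of which at most 4 can be shared; ``faces`` = 4 counts only the
    lateral faces.
    """
    if not 0 <= cell < lattice.n_cells:
        raise ValueError(f"cell {cell} outside lattice")
    return float(lattice.n_neighbors[cell]) / float(faces)


def derive_signaling_rates(
    params: ParameterSet, lattice: Lattice, cell: int
) -> tuple[float, float, float]:
    """Per-cell FGF4 transport rates ``(k_escape_auto, k_escape_para, k_meme)``.

    ``k_escape_para = chi_para * rho_meme * k_escape`` and the autocrine rate
    takes up the remainder, ``k_escape_auto = (1 - chi_para*rho_meme) *
    k_escape``, so the total escape flux is exactly ``k_escape`` for every
    cell (conservation of molecular flux).  The membrane-exchange rate is
    ``k_meme = rho_meme * k_exchange``.  Paracrine and exchange fluxes are
    split uniformly over first-degree neighbors.
    """
    if not 0.0 <= params.chi_auto <= 1.0:
        raise ValueError("chi_auto outside [0, 1]")
    rho = rho_meme(lattice, cell, params.rho_faces)
    k_escape = params.k_escape
    k_para = params.chi_para * rho * k_escape
    k_auto = (1.0 - params.chi_para * rho) * k_escape
    k_meme = rho * params.k_exchange
    return k_auto, k_para, k_meme


def build_transport_channels(
    params: ParameterSet, lattice: Lattice, variant: str
) -> list[TransportChannel]:
    """Enumerate every transport channel of the tissue for a model variant.

    Every channel relabels one ligand (cytoplasmic FGF4 or membrane monomer
    complex) without creating or destroying it, so total ligand is conserved
    by transport.  Variant masks: TM-APM and RTM remove all three families,
    TM-A removes autocrine, TM-PM removes paracrine and exchange.
    """
    if variant not in ("ITWT", "RTM", "TM-APM", "TM-A", "TM-PM", "TM-FGF4"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant in ("RTM", "TM-APM"):
        return []
    want_auto = variant != "TM-A"
    want_para = variant != "TM-PM"
    channels: list[TransportChannel] = []
    for i in range(lattice.n_cells):
        k_auto, k_para, k_meme = derive_signaling_rates(params, lattice, i)
        nn = int(lattice.n_neighbors[i])
        if want_auto:
            channels.append(TransportChannel("autocrine", i, i, k_auto))
        if want_para and nn > 0:
            for j in lattice.neighbors[i, :nn]:
                channels.append(TransportChannel("paracrine", i, int(j), k_para / nn))
                channels.append(TransportChannel("exchange", i, int(j), k_meme / nn))
    return channels
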