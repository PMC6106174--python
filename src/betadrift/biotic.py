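"""Biotic covariates: earlier-period richness and Rao Q, and the mean
binomial variance (MBV) of local occupancy.

MBV averages n*p*q over every species found in a cell's neighborhood window,
where p is the occupied fraction of the window's cells and n the realized
window size (coastal windows are smaller).  It peaks when species occupy half
the window — the configuration with the most room for local ranges to move —
and is 0 when every local species is locally ubiquitous or absent.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .atlas import OccurrenceAtlas, moore_neighbors
from .traits import DistanceMatrix, rao_q


def richness(atlas: OccurrenceAtlas, cell_id) -> int:
    return int(atlas.presence[atlas.grid.index_of(cell_id)].sum())


def rao_alpha(atlas: OccurrenceAtlas, cell_id, dmat: DistanceMatrix) -> float:
    comm = atlas.presence[atlas.grid.index_of(cell_id)]
    if comm.sum() == 0:
        return float("nan")
    return rao_q(comm, dmat)


def mean_binomial_variance(atlas: OccurrenceAtlas, cell_id,
                           include_focal: bool = False) -> float:
    """Mean of n*p*q over species found in the focal cell's window.

    The window holds the focal cell plus its surviving Moore neighbors;
    species membership uses the whole window, but by default the occupancy
    fraction p is taken over the surrounding cells only (n = their count).
    ``include_focal`` switches to counting the focal cell in p and n too.
    """
    g = atlas.grid
    i = g.index_of(cell_id)
    nbrs = moore_neighbors(g, cell_id).neighbors
    if not nbrs:
        return float("nan")
    jdx = np.array([g.index_of(c) for c in nbrs])
    sub = atlas.presence[jdx]
    member = (atlas.presence[i] > 0) | (sub.sum(axis=0) > 0)
    if not member.any():
        return float("nan")
    if include_focal:
        n = len(jdx) + 1
        k = sub[:, member].sum(axis=0) + atlas.presence[i, member]
    else:
        n = len(jdx)
        k = sub[:, member].sum(axis=0)
    p = k / n
    return float(np.mean(n * p * (1.0 - p)))


def biotic_covariates(atlas_early: OccurrenceAtlas,
                      dmat: DistanceMatrix,
                      include_focal: bool = False) -> pd.DataFrame:
    """Per-cell SR, RaoQ and MBV computed on the earlier atlas.

    Vectorized over cells; equivalent to the per-cell operations above.
    """
    g = atlas_early.grid
    P = atlas_early.presence.astype(np.float64)
    S = P.sum(axis=1)

    # Rao Q per cell
    nonempty = S > 0
    Pn = np.zeros_like(P)
    Pn[nonempty] = P[nonempty] / S[nonempty, None]
    q = np.einsum("cs,cs->c", Pn @ dmat.d, Pn)
    q[~nonempty] = np.nan

    # neighbor occupancy counts per (cell, species)
    pairs = g.adjacency_pairs()
    deg = np.zeros(g.n_cells)
    nbr_count = np.zeros_like(P)
    np.add.at(deg, pairs[:, 0], 1)
    np.add.at(nbr_count, pairs[:, 0], P[pairs[:, 1]])
    member = (P > 0) | (nbr_count > 0)
    if include_focal:
        k = nbr_count + P
        n = deg + 1
    else:
        k = nbr_count
        n = deg
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = k / n[:, None]
        npq = n[:, None] * frac * (1.0 - frac)
    counts = member.sum(axis=1)
    sums = np.where(member, np.nan_to_num(npq), 0.0).sum(axis=1)
    ok = (counts > 0) & (deg > 0)
    mbv = np.full(g.n_cells, np.nan)
    mbv[ok] = sums[ok] / counts[ok]
    return pd.DataFrame({"cell_id": list(g.cell_ids), "SR": S.astype(int),
                         "RaoQ": q, "MBV": mbv})
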