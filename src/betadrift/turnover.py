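"""Pairwise taxonomic and functional turnover and neighborhood moving-window means.

Taxonomic turnover is the Simpson-family index beta_sim = min(b, c) /
(min(b, c) + a), which isolates compositional replacement from richness
gradients and nestedness.  Functional turnover beta_rao is the gain in Rao
quadratic entropy when two communities are pooled (gamma minus mean alpha),
by default on the Jost equivalent-numbers scale.  Each focal cell's value is
the mean of the pairwise measure against its surviving Moore neighbors, so
coastal cells simply average over fewer pairs.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .atlas import Grid, OccurrenceAtlas
from .traits import DistanceMatrix

MEASURES = ("sim", "rao", "nfn", "mfd")


@dataclass(frozen=True)
class CommunityPair:
    """Shared/unique species counts for a focal-vs-neighbor comparison.

    ``a``: shared; ``b``: only in the neighbor; ``c``: only in the focal.
    """

    a: int
    b: int
    c: int

    def __post_init__(self):
        if min(self.a, self.b, self.c) < 0 or self.a + self.b + self.c < 1:
            raise ValueError("counts must be non-negative with a+b+c >= 1")


def community_pair(comm_focal, comm_neighbor) -> CommunityPair:
    f = np.asarray(comm_focal, dtype=bool)
    n = np.asarray(comm_neighbor, dtype=bool)
    return CommunityPair(int((f & n).sum()), int((n & ~f).sum()),
                         int((f & ~n).sum()))


def beta_sim(pair: CommunityPair) -> float:
    """min(b,c)/(min(b,c)+a); NaN when one community is empty."""
    m = min(pair.b, pair.c)
    if pair.a == 0 and m == 0:
        return float("nan")
    return m / (m + pair.a)


def _rao_terms(comm1, comm2, dmat: DistanceMatrix):
    c1 = np.asarray(comm1, dtype=float)
    c2 = np.asarray(comm2, dtype=float)
    s1, s2 = c1.sum(), c2.sum()
    if s1 == 0 or s2 == 0:
        return None
    p1, p2 = c1 / s1, c2 / s2
    d = dmat.d
    q1 = p1 @ d @ p1
    q2 = p2 @ d @ p2
    cross = p1 @ d @ p2
    q_gamma = (q1 + q2 + 2.0 * cross) / 4.0  # pooled with weight 1/2 each
    return q1, q2, q_gamma


def beta_rao_pair(comm1, comm2, dmat: DistanceMatrix, jost: bool = True,
                  proportional: bool = False) -> float:
    """Rao-Q beta between two presence-absence communities.

    gamma is the Rao Q of the pooled pair (each community weighted 1/2);
    alpha is the mean of the two within-community Q.  With ``jost`` both are
    mapped to equivalent numbers 1/(1-Q) before differencing, which keeps the
    decomposition non-negative.  ``proportional`` returns
    (gamma - alpha) / gamma instead of the additive difference.
    """
    terms = _rao_terms(comm1, comm2, dmat)
    if terms is None:
        return float("nan")
    q1, q2, q_gamma = terms
    q_alpha = (q1 + q2) / 2.0
    if jost:
        q_alpha = 1.0 / (1.0 - q_alpha)
        q_gamma = 1.0 / (1.0 - q_gamma)
    if proportional:
        if q_gamma == 0:
            return float("nan")
        return float((q_gamma - q_alpha) / q_gamma)
    return float(q_gamma - q_alpha)


def nfn_pair(comm1, comm2, dmat: DistanceMatrix) -> float:
    """Nearest-functional-neighbor distance, averaged over both directions."""
    i = np.flatnonzero(np.asarray(comm1))
    j = np.flatnonzero(np.asarray(comm2))
    if len(i) == 0 or len(j) == 0:
        return float("nan")
    sub = dmat.d[np.ix_(i, j)]
    return float((sub.min(axis=1).mean() + sub.min(axis=0).mean()) / 2.0)


def mfd_pair(comm1, comm2, dmat: DistanceMatrix) -> float:
    """Mean functional dissimilarity over all cross-community species pairs."""
    i = np.flatnonzero(np.asarray(comm1))
    j = np.flatnonzero(np.asarray(comm2))
    if len(i) == 0 or len(j) == 0:
        return float("nan")
    return float(dmat.d[np.ix_(i, j)].mean())


# ---------------------------------------------------------------------------
# Neighborhood moving window
# ---------------------------------------------------------------------------

@dataclass
class TurnoverField:
    """Per-focal-cell neighborhood turnover for one period, one measure."""

    grid: Grid
    period: str
    measure: str
    values: np.ndarray  # NaN where no valid neighbor pair

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_cells,):
            raise ValueError("values length must match grid")


@dataclass
class DeltaField:
    """Cellwise later-minus-earlier turnover; negative = homogenization."""

    grid: Grid
    measure: str
    delta: np.ndarray


def _pair_values(presence: np.ndarray, pairs: np.ndarray, measure: str,
                 dmat: DistanceMatrix | None, jost: bool,
                 proportional: bool) -> np.ndarray:
    """Measure for each directed (focal, neighbor) pair; NaN where invalid."""
    i, j = pairs[:, 0], pairs[:, 1]
    P = presence.astype(np.float64)
    S = P.sum(axis=1)
    if measure == "sim":
        a = np.einsum("ps,ps->p", P[i], P[j])
        b = S[j] - a
        c = S[i] - a
        m = np.minimum(b, c)
        denom = m + a
        out = np.full(len(pairs), np.nan)
        ok = denom > 0
        out[ok] = m[ok] / denom[ok]
        return out
    if dmat is None:
        raise ValueError(f"measure {measure!r} needs a distance matrix")
    d = dmat.d
    nonempty = S > 0
    Pn = np.zeros_like(P)
    Pn[nonempty] = P[nonempty] / S[nonempty, None]
    G = Pn @ d
    ok = nonempty[i] & nonempty[j]
    out = np.full(len(pairs), np.nan)
    if measure == "rao":
        q_within = np.einsum("cs,cs->c", G, Pn)
        cross = np.einsum("ps,ps->p", G[i], Pn[j])
        q_gamma = (q_within[i] + q_within[j] + 2.0 * cross) / 4.0
        q_alpha = (q_within[i] + q_within[j]) / 2.0
        if jost:
            q_alpha = 1.0 / (1.0 - q_alpha)
            q_gamma = 1.0 / (1.0 - q_gamma)
        val = (q_gamma - q_alpha) / q_gamma if proportional else q_gamma - q_alpha
        out[ok] = val[ok]
        return out
    fn = {"nfn": nfn_pair, "mfd": mfd_pair}[measure]
    for k in np.flatnonzero(ok):
        out[k] = fn(presence[i[k]], presence[j[k]], dmat)
    return out


def neighborhood_turnover(atlas: OccurrenceAtlas,
                          dmat: DistanceMatrix | None = None,
                          measure: str = "sim", jost: bool = True,
                          proportional: bool = False) -> TurnoverField:
    """Mean pairwise turnover of each focal cell against its Moore neighbors.

    Pairs where either community is empty are dropped from the mean; a cell
    with no valid pair gets NaN.
    """
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}")
    if dmat is not None and tuple(dmat.species) != tuple(atlas.species):
        raise ValueError("distance matrix species do not match the atlas")
    pairs = atlas.grid.adjacency_pairs()
    vals = _pair_values(atlas.presence, pairs, measure, dmat, jost, proportional)
    n = atlas.grid.n_cells
    ok = ~np.isnan(vals)
    total = np.zeros(n)
    count = np.zeros(n)
    np.add.at(total, pairs[ok, 0], vals[ok])
    np.add.at(count, pairs[ok, 0], 1)
    with np.errstate(invalid="ignore"):
        mean = np.where(count > 0, total / np.maximum(count, 1), np.nan)
    return TurnoverField(atlas.grid, atlas.period, measure, mean)


def delta(t1: TurnoverField, t2: TurnoverField) -> DeltaField:
    """Cellwise turnover(period 2) - turnover(period 1); NaN propagates."""
    if t1.grid.cell_ids != t2.grid.cell_ids:
        raise ValueError("turnover fields are on different grids")
    if t1.measure != t2.measure:
        raise ValueError("turnover fields use different measures")
    return DeltaField(t1.grid, t1.measure, t2.values - t1.values)
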