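"""Mixed-trait functional space: Gower distances and Rao quadratic entropy.

Traits may be continuous (range-scaled absolute difference, optionally
log-transformed first), ordinal (rank-scaled, then treated as continuous),
categorical (0/1 mismatch) or binary-set (multi-label memberships such as diet
categories, compared by Jaccard mismatch).  Per-trait contributions are
averaged with equal weight, giving pairwise distances in [0, 1].
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger("betadrift")

TRAIT_KINDS = ("continuous", "ordinal", "categorical", "binary-set")


@dataclass
class TraitTable:
    """Species x traits table with a declared kind per trait column.

    ``data`` is indexed by species id; ``kinds`` maps each column to one of
    ``continuous | ordinal | categorical | binary-set``.  Binary-set values are
    semicolon-delimited label strings ("insects;seeds").  ``log_traits`` names
    continuous columns (body-mass-like) to log-transform before range scaling.
    """

    data: pd.DataFrame
    kinds: dict
    log_traits: tuple = ()

    def __post_init__(self):
        self.log_traits = tuple(self.log_traits)
        unknown = set(self.kinds.values()) - set(TRAIT_KINDS)
        if unknown:
            raise ValueError(f"unknown trait kinds: {sorted(unknown)}")
        missing = [c for c in self.data.columns if c not in self.kinds]
        if missing:
            raise ValueError(f"traits without a declared kind: {missing}")
        if self.data.isna().any().any():
            bad = self.data.columns[self.data.isna().any()].tolist()
            raise ValueError(f"missing trait values in columns {bad}; "
                             "complete coverage is required")

    @property
    def species(self) -> tuple:
        return tuple(self.data.index)

    def reindex(self, species) -> "TraitTable":
        absent = [s for s in species if s not in self.data.index]
        if absent:
            raise KeyError(f"species without trait rows: {absent[:5]}")
        return TraitTable(self.data.loc[list(species)], dict(self.kinds),
                          self.log_traits)

    def relabel(self, permutation: np.ndarray) -> "TraitTable":
        """Reassign species labels to trait rows (rows travel intact)."""
        new = self.data.copy()
        new.index = np.asarray(self.data.index)[permutation]
        return TraitTable(new.loc[list(self.data.index)], dict(self.kinds),
                          self.log_traits)


def read_traits(path, kinds: dict | None = None,
                log_traits=()) -> TraitTable:
    """Read a trait CSV, wide (species + one column per trait) or long
    (species,trait_name,value).  Kinds are inferred when not given: numeric
    columns continuous, values containing ';' binary-set, else categorical."""
    df = pd.read_csv(path)
    if {"species", "trait_name", "value"} <= set(df.columns):
        df = df.pivot(index="species", columns="trait_name", values="value")

        def _maybe_numeric(s):
            try:
                return pd.to_numeric(s)
            except (ValueError, TypeError):
                return s

        df = df.apply(_maybe_numeric)
    else:
        df = df.set_index("species")
    if kinds is None:
        kinds = {}
        for c in df.columns:
            if pd.api.types.is_numeric_dtype(df[c]):
                kinds[c] = "continuous"
            elif df[c].astype(str).str.contains(";").any():
                kinds[c] = "binary-set"
            else:
                kinds[c] = "categorical"
    return TraitTable(df, kinds, log_traits)


# ---------------------------------------------------------------------------
# Gower distance
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise Gower distance matrix over an ordered species list."""

    species: tuple
    d: np.ndarray

    def __post_init__(self):
        d = np.asarray(self.d, dtype=float)
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "d", d)
        if d.shape != (len(self.species),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(d, d.T) or np.any(np.diag(d) != 0):
            raise ValueError("distance matrix must be symmetric with zero diagonal")
        if d.min() < 0 or d.max() > 1 + 1e-12:
            raise ValueError("Gower distances must lie in [0, 1]")

    def permuted(self, perm: np.ndarray) -> "DistanceMatrix":
        """Distances after assigning species label i the trait row perm[i]."""
        return DistanceMatrix(self.species, self.d[np.ix_(perm, perm)])


def _set_column(values) -> list:
    return [frozenset(str(v).split(";")) for v in values]


def gower(traits: TraitTable) -> DistanceMatrix:
    """Equal-weight Gower distances over the mixed trait table."""
    n = len(traits.species)
    parts = []
    for col, kind in ((c, traits.kinds[c]) for c in traits.data.columns):
        v = traits.data[col]
        if kind in ("continuous", "ordinal"):
            if kind == "ordinal":
                x = rankdata(v.to_numpy(), method="average")
            else:
                x = v.to_numpy(dtype=float)
                if col in traits.log_traits:
                    if np.any(x <= 0):
                        raise ValueError(f"log-flagged trait {col!r} must be positive")
                    x = np.log(x)
            rng = x.max() - x.min()
            if rng == 0:
                warnings.warn(f"trait {col!r} has zero range; contributes 0")
                parts.append(np.zeros((n, n)))
            else:
                parts.append(np.abs(x[:, None] - x[None, :]) / rng)
        elif kind == "categorical":
            x = v.to_numpy(dtype=object)
            parts.append((x[:, None] != x[None, :]).astype(float))
        else:  # binary-set
            sets = _set_column(v)
            m = np.zeros((n, n))
            for i in range(n):
                for j in range(i + 1, n):
                    inter = len(sets[i] & sets[j])
                    union = len(sets[i] | sets[j])
                    m[i, j] = m[j, i] = 1.0 - (inter / union if union else 1.0)
            parts.append(m)
    d = np.mean(parts, axis=0)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(traits.species, np.clip(d, 0.0, 1.0))


# ---------------------------------------------------------------------------
# Rao quadratic entropy
# ---------------------------------------------------------------------------

def rao_q(community: np.ndarray, dmat: DistanceMatrix) -> float:
    """Rao's quadratic entropy of a presence-absence community.

    With presence-only data every present species gets weight 1/S, so
    Q = sum_ij p_i p_j d_ij is the expected functional distance between two
    randomly drawn individuals.
    """
    comm = np.asarray(community, dtype=float)
    s = comm.sum()
    if s == 0:
        raise ValueError("Rao Q is undefined for an empty community")
    p = comm / s
    return float(p @ dmat.d @ p)
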