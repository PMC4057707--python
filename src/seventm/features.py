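"""Pairwise Cα-distance features over a structure ensemble, with iterative
correlation pruning.

For n residues common to every structure there are n(n−1)/2 unordered
residue pairs; each structure contributes one row of Euclidean Cα–Cα
distances.  Because whole groups of pairs move together (a displaced helix
drags hundreds of distances with it), the feature set is heavily redundant
and the redundancy is asymmetric across motions, which biases importance
ranking.  The pruning step therefore repeatedly finds the most correlated
pair of distance vectors and removes one of the two at random (seeded)
until no correlation exceeds the threshold (default Pearson r = 0.90),
which typically removes the large majority of the features.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist

from .structures import Structure

__all__ = [
    "FeatureTable",
    "PruneConfig",
    "RemovalRecord",
    "common_residues",
    "build_feature_table",
    "pearson",
    "prune_correlated",
]

logger = logging.getLogger(__name__)


@dataclass
class FeatureTable:
    """structures × residue-pair distance matrix.

    ``pairs`` lists (generic_i, generic_j) with i < j in lexicographic
    order; ``values[s, p]`` is the Cα–Cα distance in structure ``s`` for
    pair ``p``, in Å.
    """

    structure_ids: list[str]
    pairs: list[tuple[int, int]]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.structure_ids), len(self.pairs)):
            raise ValueError("values shape does not match ids x pairs")

    @property
    def n_features(self) -> int:
        return len(self.pairs)

    def pair_labels(self) -> list[str]:
        return [f"{i}-{j}" for i, j in self.pairs]

    def column(self, pair: tuple[int, int]) -> np.ndarray:
        try:
            idx = self.pairs.index(tuple(pair))
        except ValueError:
            raise KeyError(f"pair {pair} not in table") from None
        return self.values[:, idx]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.values, index=self.structure_ids, columns=self.pair_labels())

    def to_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index_label="structure_id", float_format="%.3f")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "FeatureTable":
        import pandas as pd

        df = pd.read_csv(path, sep="\t", index_col="structure_id")
        pairs = [tuple(int(x) for x in c.split("-")) for c in df.columns]
        return cls(list(df.index), pairs, df.to_numpy())


@dataclass
class PruneConfig:
    """Threshold and seed for the iterative max-correlation pruning.

    ``absolute`` prunes on |r| rather than signed r; the default follows
    the signed reading of 'correlation higher than 0.90', since distance
    vectors that co-vary negatively carry distinct information.
    """

    threshold: float = 0.90
    seed: int = 0
    absolute: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold <= 1.0:
            raise ValueError("threshold must be in (0, 1]")


@dataclass(frozen=True)
class RemovalRecord:
    kept: tuple[int, int]
    removed: tuple[int, int]
    r: float
    reason: str = "correlated"


def common_residues(structures: list[Structure]) -> list[int]:
    """Generic numbers with a Cα present in every structure, ascending."""
    if not structures:
        raise ValueError("no structures given")
    sets = []
    for st in structures:
        sets.append(
            {g for g, r in st.by_generic().items() if r.coords("CA") is not None}
        )
    shared = set.intersection(*sets)
    if not shared:
        raise ValueError("no residues are common to all structures")
    return sorted(shared)


def build_feature_table(structures: list[Structure], residues: list[int]) -> FeatureTable:
    """Distances between every unordered pair of the given residues, in
    every structure; pair order lexicographic (the pdist convention)."""
    residues = list(residues)
    n = len(residues)
    pairs = [(residues[i], residues[j]) for i in range(n) for j in range(i + 1, n)]
    rows = []
    for st in structures:
        by_g = st.by_generic()
        coords = []
        for g in residues:
            res = by_g.get(g)
            ca = None if res is None else res.coords("CA")
            if ca is None:
                raise ValueError(f"structure {st.id}: residue {g} has no Calpha")
            coords.append(ca)
        rows.append(pdist(np.array(coords)))
    return FeatureTable([st.id for st in structures], pairs, np.array(rows))


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Product-moment correlation; raises on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("need two equal-length vectors of length >= 3")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise ValueError("undefined correlation: zero variance")
    return float(np.corrcoef(x, y)[0, 1])


def prune_correlated(
    table: FeatureTable, config: PruneConfig | None = None
) -> tuple[FeatureTable, list[RemovalRecord]]:
    """Iteratively remove one member of the most correlated feature pair
    (uniformly at random, seeded) until the maximum pairwise correlation is
    at or below the threshold.

    Zero-variance features are removed up front with a log entry.  Ties for
    the maximal correlation resolve to the lowest lexicographic pair of
    column indices, so the procedure is bit-reproducible given the seed.
    The correlation matrix is held in memory: O(p²) in the feature count.
    """
    config = config or PruneConfig()
    if table.n_features < 2:
        raise ValueError("need at least 2 features to prune")
    rng = np.random.default_rng(config.seed)
    log: list[RemovalRecord] = []

    keep = np.ones(table.n_features, dtype=bool)
    variances = table.values.std(axis=0)
    for idx in np.flatnonzero(variances == 0.0):
        keep[idx] = False
        log.append(RemovalRecord(kept=(-1, -1), removed=table.pairs[idx], r=np.nan, reason="zero variance"))
        logger.info("pruning: removed zero-variance feature %s", table.pairs[idx])

    active = np.flatnonzero(keep)
    corr = np.corrcoef(table.values[:, active].T)
    np.fill_diagonal(corr, -np.inf)
    score = np.abs(corr) if config.absolute else corr.copy()
    np.fill_diagonal(score, -np.inf)
    alive = np.ones(len(active), dtype=bool)
    # Per-column maxima let each removal update in O(p) amortised.
    colmax = score.max(axis=1)
    colarg = score.argmax(axis=1)

    while alive.sum() >= 2:
        m = float(colmax.max())
        if m <= config.threshold:
            break
        # lowest lexicographic (i, j) with i < j among the tied maxima
        tied_cols = np.flatnonzero(np.isclose(colmax, m, rtol=0.0, atol=1e-12))
        cands = set()
        for c in tied_cols:
            for j in np.flatnonzero(np.isclose(score[c], m, rtol=0.0, atol=1e-12)):
                cands.add((int(min(c, j)), int(max(c, j))))
        i, j = min(cands)
        drop, kept = (i, j) if rng.random() < 0.5 else (j, i)
        r_val = float(corr[i, j])
        alive[drop] = False
        score[drop, :] = -np.inf
        score[:, drop] = -np.inf
        colmax[drop] = -np.inf
        # only columns whose maximum pointed at the dropped feature change
        for s in np.flatnonzero(alive & (colarg == drop)):
            colmax[s] = score[s].max()
            colarg[s] = score[s].argmax()
        log.append(
            RemovalRecord(
                kept=table.pairs[active[kept]],
                removed=table.pairs[active[drop]],
                r=r_val,
            )
        )
    surviving = active[alive]
    pruned = FeatureTable(
        list(table.structure_ids),
        [table.pairs[k] for k in surviving],
        table.values[:, surviving],
    )
    logger.info(
        "pruning: %d of %d features removed (threshold %.2f)",
        table.n_features - pruned.n_features, table.n_features, config.threshold,
    )
    return pruned, log
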