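"""Random-forest importance ranking of distance features between structure
classes.

The forest itself is delegated to scikit-learn's ``RandomForestClassifier``
(1000 trees, Gini impurity, by default); the contribution of this module
is the surrounding procedure: fitting on a (pruned) distance table,
ranking features by Gini importance (mean decrease in impurity),
annotating each feature with its direction of change between classes from
raw class means, and projecting the top-ranked distance vectors onto a
reference structure for visual inspection.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureTable
from .structures import Structure

__all__ = [
    "RFConfig",
    "RankedFeature",
    "ImportanceReport",
    "ActivationForest",
    "fit_importances",
    "direction_of_change",
    "export_vector_script",
]

logger = logging.getLogger(__name__)

#: Mean class differences smaller than this (Å) are flagged negligible.
NEGLIGIBLE_DIFF = 0.1


@dataclass
class RFConfig:
    """Forest settings; the defaults are 1000 trees with Gini importance."""

    n_trees: int = 1000
    compute_importance: bool = True
    seed: int = 0
    balanced_class_weights: bool = False

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass(frozen=True)
class RankedFeature:
    pair: tuple[int, int]
    importance: float
    direction: str | None  # "increases" / "decreases" (two-class only)
    mean_class_difference: float | None
    negligible: bool = False


@dataclass
class ImportanceReport:
    """Gini-ranked residue pairs with directions and the forest's OOB error."""

    ranked: list[RankedFeature]
    labels: dict[str, str]
    oob_error: float
    reference_class: str | None
    config: RFConfig

    def top(self, k: int) -> list[RankedFeature]:
        return self.ranked[:k]

    def summary(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "pair": [f"{p.pair[0]}-{p.pair[1]}" for p in self.ranked],
                "gini_importance": [p.importance for p in self.ranked],
                "direction": [p.direction for p in self.ranked],
                "mean_diff_A": [p.mean_class_difference for p in self.ranked],
                "negligible": [p.negligible for p in self.ranked],
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.summary().to_csv(path, sep="\t", index=False, float_format="%.6g")


def _check_labels(table: FeatureTable, labels: dict[str, str]) -> list[str]:
    missing = [sid for sid in table.structure_ids if sid not in labels]
    if missing:
        raise ValueError(f"unlabeled structures: {missing}")
    y = [labels[sid] for sid in table.structure_ids]
    classes = sorted(set(y))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    for cls in classes:
        if y.count(cls) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 structures")
    return y


def direction_of_change(
    table: FeatureTable,
    labels: dict[str, str],
    pair: tuple[int, int],
    reference_class: str,
) -> tuple[str, float]:
    """Mean(other) − mean(reference) for one pair; positive → 'increases'.

    An exactly-zero difference reports 'increases' by convention; consumers
    should heed the negligible flag (|diff| < 0.1 Å) instead of the sign.
    """
    y = np.array([labels[sid] for sid in table.structure_ids])
    classes = sorted(set(y))
    if len(classes) != 2:
        raise ValueError("direction of change is defined for exactly 2 classes")
    if reference_class not in classes:
        raise ValueError(f"reference class {reference_class!r} not among {classes}")
    other = next(c for c in classes if c != reference_class)
    col = table.column(pair)
    diff = float(col[y == other].mean() - col[y == reference_class].mean())
    return ("increases" if diff >= 0 else "decreases"), diff


def fit_importances(
    table: FeatureTable,
    labels: dict[str, str],
    config: RFConfig | None = None,
    reference_class: str | None = None,
) -> ImportanceReport:
    """Fit the forest and rank every feature by Gini importance.

    For two classes each feature is annotated with its direction of change
    relative to ``reference_class`` (default: 'inactive' when present,
    else the alphabetically first class).  The out-of-bag error is always
    reported so inseparable classes are visible.
    """
    config = config or RFConfig()
    y = _check_labels(table, labels)
    classes = sorted(set(y))
    two_class = len(classes) == 2
    if reference_class is None and two_class:
        reference_class = "inactive" if "inactive" in classes else classes[0]

    forest = RandomForestClassifier(
        n_estimators=config.n_trees,
        criterion="gini",
        oob_score=True,
        bootstrap=True,
        class_weight="balanced" if config.balanced_class_weights else None,
        random_state=int(config.seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(table.values, y)
    oob_error = 1.0 - float(forest.oob_score_)
    if config.compute_importance:
        importances = forest.feature_importances_
    else:
        importances = np.zeros(table.n_features)

    order = np.argsort(-importances, kind="stable")
    ranked = []
    for idx in order:
        pair = table.pairs[idx]
        if two_class:
            direction, diff = direction_of_change(table, labels, pair, reference_class)
            ranked.append(
                RankedFeature(pair, float(importances[idx]), direction, diff, abs(diff) < NEGLIGIBLE_DIFF)
            )
        else:
            ranked.append(RankedFeature(pair, float(importances[idx]), None, None))
    if oob_error >= 0.5 - 1e-9:
        logger.warning("forest OOB error %.2f is at or near chance: classes look inseparable", oob_error)
    return ImportanceReport(ranked, dict(labels), oob_error, reference_class, config)


class ActivationForest:
    """Model-style wrapper: construct from a table and labels, then fit.

    >>> report = ActivationForest(table, labels).fit(RFConfig(seed=7))
    >>> report.summary().head()
    """

    def __init__(self, table: FeatureTable, labels: dict[str, str]):
        self.table = table
        self.labels = labels

    def fit(self, config: RFConfig | None = None, reference_class: str | None = None) -> ImportanceReport:
        return fit_importances(self.table, self.labels, config, reference_class)


_COLORS = {"increases": "magenta", "decreases": "yellow"}


def export_vector_script(
    report: ImportanceReport,
    top_k: int,
    reference_structure: Structure,
    pml_path: str | Path,
    tsv_path: str | Path | None = None,
) -> int:
    """Write a PyMOL script drawing the top-k distance vectors on a
    reference structure, coloured by direction of change (magenta =
    increases, yellow = decreases), plus an optional generic line-segment
    TSV for other viewers.  Pairs whose residues are missing from the
    reference are skipped with a warning.  Returns the number of vectors
    drawn.
    """
    by_g = reference_structure.by_generic()
    lines = []
    for rank, feat in enumerate(report.top(top_k), start=1):
        g1, g2 = feat.pair
        r1, r2 = by_g.get(g1), by_g.get(g2)
        ca1 = None if r1 is None else r1.coords("CA")
        ca2 = None if r2 is None else r2.coords("CA")
        if ca1 is None or ca2 is None:
            logger.warning(
                "vector %d-%d skipped: residue missing in reference %s", g1, g2, reference_structure.id
            )
            continue
        color = _COLORS.get(feat.direction or "increases", "magenta")
        lines.append((rank, g1, g2, ca1, ca2, color))

    with open(pml_path, "w") as fh:
        fh.write("# distance vectors ranked by random-forest Gini importance\n")
        fh.write("# magenta: increases between classes; yellow: decreases\n")
        for rank, g1, g2, ca1, ca2, color in lines:
            name = f"vec{rank}_{g1}_{g2}"
            fh.write(f"pseudoatom {name}_a, pos=[{ca1[0]:.3f}, {ca1[1]:.3f}, {ca1[2]:.3f}]\n")
            fh.write(f"pseudoatom {name}_b, pos=[{ca2[0]:.3f}, {ca2[1]:.3f}, {ca2[2]:.3f}]\n")
            fh.write(f"distance {name}, {name}_a, {name}_b\n")
            fh.write(f"color {color}, {name}\nhide labels, {name}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("pair\tx1\ty1\tz1\tx2\ty2\tz2\tcolor\n")
            for rank, g1, g2, ca1, ca2, color in lines:
                fh.write(
                    f"{g1}-{g2}\t" + "\t".join(f"{v:.3f}" for v in (*ca1, *ca2)) + f"\t{color}\n"
                )
    return len(lines)
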