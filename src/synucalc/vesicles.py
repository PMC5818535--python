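"""Vesicle single/pair/cluster classification and condition comparison.

Vesicle centre coordinates from super-resolution images are linked whenever
two centres lie within a 250 nm radius; connected components of this graph
define clusters (a chain A-B-C counts as one cluster of three even if A and
C are farther apart). Percentages are reported over vesicles by default:
the share of vesicles sitting in components of size 1 (singles), 2 (pairs)
and >= 3 (multi). Component-based percentages are available as well.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from synucalc.errors import InputError
from synucalc.smlm import Rect, _components_by_distance

#: Centre-to-centre linkage radius (nm) defining vesicle proximity.
DEFAULT_RADIUS_NM = 250.0


@dataclass
class SpotTable:
    """Vesicle centre coordinates (nm) inside a rectangular field."""

    points: np.ndarray
    field: Rect

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 2)
        if len(self.points) and not self.field.contains(self.points).all():
            raise InputError("all spots must lie inside the field")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class ClusterSizeDistribution:
    pct_singles: float
    pct_pairs: float
    pct_multi: float
    n_vesicles: int
    n_components: int
    # percentages over components rather than vesicles
    comp_pct_singles: float
    comp_pct_pairs: float
    comp_pct_multi: float

    def __post_init__(self) -> None:
        total = self.pct_singles + self.pct_pairs + self.pct_multi
        if abs(total - 100.0) > 0.01:
            raise InputError("vesicle percentages must sum to 100")


def _merge_duplicates(points: np.ndarray, tol: float = 1.0) -> np.ndarray:
    labels = _components_by_distance(points, tol)
    if labels.max() + 1 == len(points):
        return points
    warnings.warn("duplicate vesicle coordinates merged (within 1 nm)")
    merged = np.array(
        [points[labels == lab].mean(axis=0) for lab in np.unique(labels)]
    )
    return merged


def classify_clusters(
    spots: SpotTable, radius: float = DEFAULT_RADIUS_NM
) -> ClusterSizeDistribution:
    """Classify vesicles into singles, pairs, and larger clusters."""
    if len(spots) == 0:
        raise InputError("spot table is empty")
    points = _merge_duplicates(spots.points)
    labels = _components_by_distance(points, radius)
    sizes = np.bincount(labels)
    n = len(points)
    n_singles = int(sizes[sizes == 1].sum())
    n_pairs = int(sizes[sizes == 2].sum())
    n_multi = int(sizes[sizes >= 3].sum())
    c_singles = int((sizes == 1).sum())
    c_pairs = int((sizes == 2).sum())
    c_multi = int((sizes >= 3).sum())
    n_comp = len(sizes)
    return ClusterSizeDistribution(
        pct_singles=100.0 * n_singles / n,
        pct_pairs=100.0 * n_pairs / n,
        pct_multi=100.0 * n_multi / n,
        n_vesicles=n,
        n_components=n_comp,
        comp_pct_singles=100.0 * c_singles / n_comp,
        comp_pct_pairs=100.0 * c_pairs / n_comp,
        comp_pct_multi=100.0 * c_multi / n_comp,
    )


_CATEGORIES = ("singles", "pairs", "multi")


def compare_conditions(
    dists: dict[str, list[ClusterSizeDistribution]],
) -> dict[str, dict]:
    """Per-size-category ANOVA with Tukey-adjusted pairwise comparisons.

    ``dists`` maps condition label -> per-field distributions (replicates).
    Returns, per category, the F test and the Tukey HSD table; degenerate
    (zero-variance) categories are flagged with all adjusted p = 1.
    """
    if len(dists) < 2:
        raise InputError("need at least 2 conditions")
    for cond, reps in dists.items():
        if len(reps) < 2:
            raise InputError(f"condition {cond!r} has fewer than 2 replicates")
    out: dict[str, dict] = {}
    for cat in _CATEGORIES:
        attr = f"pct_{cat}"
        groups = {c: np.array([getattr(d, attr) for d in reps]) for c, reps in dists.items()}
        values = np.concatenate(list(groups.values()))
        labels = np.concatenate(
            [np.full(len(v), c) for c, v in groups.items()]
        )
        conds = list(groups)
        pairs_means = {
            (a, b): float(groups[b].mean() - groups[a].mean())
            for i, a in enumerate(conds)
            for b in conds[i + 1:]
        }
        if np.ptp(values) == 0:
            out[cat] = {
                "degenerate": True,
                "F": 0.0,
                "p": 1.0,
                "pairwise": [
                    {"a": a, "b": b, "mean_diff": d, "p_adj": 1.0}
                    for (a, b), d in pairs_means.items()
                ],
            }
            continue
        if all(np.ptp(v) == 0 for v in groups.values()):
            # constant within every group but different between groups:
            # perfect separation, no within-group error term
            out[cat] = {
                "degenerate": True,
                "F": float("inf"),
                "p": 0.0,
                "pairwise": [
                    {"a": a, "b": b, "mean_diff": d, "p_adj": 0.0 if d else 1.0}
                    for (a, b), d in pairs_means.items()
                ],
            }
            continue
        F, p = stats.f_oneway(*groups.values())
        tukey = pairwise_tukeyhsd(values, labels)
        pairwise = []
        res = tukey.summary().data[1:]
        for row in res:
            pairwise.append(
                {
                    "a": str(row[0]),
                    "b": str(row[1]),
                    "mean_diff": float(row[2]),
                    "p_adj": float(row[3]),
                }
            )
        out[cat] = {"degenerate": False, "F": float(F), "p": float(p), "pairwise": pairwise}
    return out


def distribution_frame(
    dists: dict[str, list[ClusterSizeDistribution]]
) -> pd.DataFrame:
    """Flatten per-condition distributions into a tidy summary table."""
    rows = []
    for cond, reps in dists.items():
        for i, d in enumerate(reps):
            rows.append(
                {
                    "condition": cond,
                    "field": i,
                    "pct_singles": d.pct_singles,
                    "pct_pairs": d.pct_pairs,
                    "pct_multi": d.pct_multi,
                    "n_vesicles": d.n_vesicles,
                    "n_components": d.n_components,
                }
            )
    return pd.DataFrame(rows)
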