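"""Compositional-bias assessment of quality filtering.

Compares per-taxon read fractions before and after filtering, scores the
agreement against the identity line y = x, and attributes removed reads
to their pre-filter cluster of origin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from pyroqc.otu_cluster import Clustering
from pyroqc.seqio import ReadSet


@dataclass
class TaxonDistribution:
    """Per-taxon fractions of reads before and after filtering."""

    taxa: list[str]
    pre_fraction: np.ndarray
    post_fraction: np.ndarray

    def points(self) -> list[tuple[float, float]]:
        return list(zip(self.pre_fraction.tolist(), self.post_fraction.tolist()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "taxon": self.taxa,
                "pre_fraction": self.pre_fraction,
                "post_fraction": self.post_fraction,
            }
        )


def _taxon_counts(read_set: ReadSet) -> dict[str, int]:
    counts: dict[str, int] = {}
    for r in read_set:
        if r.taxon is None:
            raise ValueError(f"read {r.read_id!r} has no taxon label")
        counts[r.taxon] = counts.get(r.taxon, 0) + 1
    return counts


def taxon_fractions(pre_set: ReadSet, post_set: ReadSet) -> TaxonDistribution:
    """Taxon fractions over the unfiltered and filtered read sets.

    The taxa axis is the sorted union of both sets; a taxon absent from
    one set gets fraction 0 there. ``post_set`` must be a subset of
    ``pre_set`` by read id.
    """
    pre_ids = set(pre_set.ids())
    stray = [rid for rid in post_set.ids() if rid not in pre_ids]
    if stray:
        raise ValueError(f"post-filter read {stray[0]!r} not present pre-filter")
    pre = _taxon_counts(pre_set)
    post = _taxon_counts(post_set)
    taxa = sorted(set(pre) | set(post))
    n_pre, n_post = len(pre_set), len(post_set)
    pre_frac = np.array([pre.get(t, 0) / n_pre for t in taxa]) if n_pre else np.zeros(len(taxa))
    post_frac = np.array([post.get(t, 0) / n_post for t in taxa]) if n_post else np.zeros(len(taxa))
    return TaxonDistribution(taxa, pre_frac, post_frac)


def r_squared_identity(points: Iterable[tuple[float, float]]) -> float:
    """Goodness of fit of (x, y) points to the fixed line y = x.

    R^2 = 1 - sum (y_i - x_i)^2 / sum (y_i - mean(y))^2. May be negative
    (worse than predicting the mean); not clamped.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[0] < 2:
        raise ValueError("need at least two (x, y) points")
    x, y = pts[:, 0], pts[:, 1]
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        raise ValueError("all y values identical; R^2 undefined")
    ss_res = float(((y - x) ** 2).sum())
    return 1.0 - ss_res / ss_tot


@dataclass
class ClusterRemovalProfile:
    """Share of all removed reads attributed to each pre-filter cluster,
    ordered by descending pre-filter cluster size."""

    otu_ids: list[str]
    sizes: list[int]
    fraction_of_total_removed: list[float]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "otu_id": self.otu_ids,
                "pre_filter_size": self.sizes,
                "fraction_of_total_removed": self.fraction_of_total_removed,
            }
        )


def removal_by_cluster(
    pre_clustering: Clustering, removed_ids: Sequence[str]
) -> ClusterRemovalProfile:
    """Attribute removed reads to their pre-filter clusters.

    Returns, per cluster in descending size order, the fraction of all
    removed reads that came from that cluster. With no removals the
    profile is empty (the fractions would be undefined).
    """
    removed = set(removed_ids)
    missing = removed - set(pre_clustering.assignment)
    if missing:
        raise ValueError(f"removed read {sorted(missing)[0]!r} absent from clustering")
    if not removed:
        return ClusterRemovalProfile([], [], [])
    removed_per_otu: dict[str, int] = {}
    for rid in removed:
        otu = pre_clustering.assignment[rid]
        removed_per_otu[otu] = removed_per_otu.get(otu, 0) + 1
    order = sorted(
        pre_clustering.otu_sizes.items(), key=lambda kv: (-kv[1], kv[0])
    )
    total = len(removed)
    return ClusterRemovalProfile(
        otu_ids=[otu for otu, _ in order],
        sizes=[size for _, size in order],
        fraction_of_total_removed=[removed_per_otu.get(otu, 0) / total for otu, _ in order],
    )
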