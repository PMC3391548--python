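"""Pairwise alignment distances and complete-linkage OTU clustering.

Distances come from a global alignment: mismatches and internal gap
columns count as differences, while terminal-gap columns (length
overhangs) are excluded from both the numerator and the denominator. A
distance threshold of 0.03 corresponds to clustering at 97% similarity.

All-vs-all alignment is quadratic and intended for desk scale (up to a few
thousand reads); identical sequences are collapsed before alignment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.Align import PairwiseAligner

from pyroqc.seqio import ReadSet

DEFAULT_THRESHOLD = 0.03


def _make_aligner() -> PairwiseAligner:
    # Terminal gaps cost slightly less than internal ones: enough that a
    # terminal mismatch cannot slide into a cost-free overhang, while a
    # genuine length overhang is placed strictly at the end (not at a
    # score-tied internal position), where the distance then ignores it.
    aligner = PairwiseAligner(
        mode="global",
        match_score=1.0,
        mismatch_score=-1.0,
        open_gap_score=-2.0,
        extend_gap_score=-1.0,
    )
    aligner.open_end_gap_score = -1.9
    aligner.extend_end_gap_score = -0.95
    return aligner


_ALIGNER = _make_aligner()


def pairwise_distance(seq_a: str, seq_b: str) -> float:
    """End-free alignment distance between two nucleotide sequences.

    distance = (mismatches + internal gap columns) / aligned columns,
    where terminal-gap columns are excluded on both sides of the ratio.
    Symmetric; identical sequences give 0.0.
    """
    if not seq_a or not seq_b:
        raise ValueError("pairwise_distance requires non-empty sequences")
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if seq_a == seq_b:
        return 0.0
    aln = _ALIGNER.align(seq_a, seq_b)[0]
    row_a, row_b = str(aln[0]), str(aln[1])
    # strip terminal-gap columns: keep the span covered by both sequences
    start = max(len(row_a) - len(row_a.lstrip("-")), len(row_b) - len(row_b.lstrip("-")))
    end = min(len(row_a.rstrip("-")), len(row_b.rstrip("-")))
    if end <= start:
        return 1.0  # no overlap between the two sequences
    diffs = sum(1 for a, b in zip(row_a[start:end], row_b[start:end]) if a != b)
    return diffs / (end - start)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix over an ordered id list."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.d < 0) or np.any(self.d > 1):
            raise ValueError("distances must lie in [0, 1]")

    def subset(self, keep_ids: Sequence[str]) -> "DistanceMatrix":
        index = {rid: i for i, rid in enumerate(self.ids)}
        rows = [index[r] for r in keep_ids]
        return DistanceMatrix(list(keep_ids), self.d[np.ix_(rows, rows)])

    def to_phylip(self) -> str:
        lines = [str(len(self.ids))]
        for rid, row in zip(self.ids, self.d):
            lines.append(rid + "\t" + "\t".join(f"{v:.6g}" for v in row))
        return "\n".join(lines) + "\n"


def distance_matrix(read_set: ReadSet) -> DistanceMatrix:
    """All-vs-all :func:`pairwise_distance` over a ReadSet.

    Identical sequences are aligned once and share the resulting row.
    """
    ids = read_set.ids()
    seqs = [r.bases for r in read_set]
    uniq: dict[str, int] = {}
    rep = np.empty(len(seqs), dtype=int)
    uniq_seqs: list[str] = []
    for i, s in enumerate(seqs):
        if s not in uniq:
            uniq[s] = len(uniq_seqs)
            uniq_seqs.append(s)
        rep[i] = uniq[s]
    m = len(uniq_seqs)
    du = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            du[i, j] = du[j, i] = pairwise_distance(uniq_seqs[i], uniq_seqs[j])
    return DistanceMatrix(list(ids), du[np.ix_(rep, rep)])


@dataclass
class Clustering:
    """Read-to-OTU assignment produced at a given distance threshold."""

    assignment: dict[str, str]
    threshold: float
    otu_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        sizes: dict[str, int] = {}
        for otu in self.assignment.values():
            sizes[otu] = sizes.get(otu, 0) + 1
        if self.otu_sizes and self.otu_sizes != sizes:
            raise ValueError("otu_sizes inconsistent with assignment")
        self.otu_sizes = sizes

    def members(self) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for rid, otu in self.assignment.items():
            out.setdefault(otu, []).append(rid)
        return out

    def n_otus(self) -> int:
        return len(self.otu_sizes)


def complete_linkage(
    dist_matrix: DistanceMatrix, threshold: float = DEFAULT_THRESHOLD
) -> Clustering:
    """Agglomerative complete-linkage clustering cut at ``threshold``.

    Iteratively merges the pair of clusters with the smallest maximum
    inter-cluster distance while that distance is <= threshold. Ties are
    broken by the lexicographically smallest member id of the candidate
    pair, which makes the partition independent of input order.
    """
    ids = dist_matrix.ids
    n = len(ids)
    if n == 0:
        return Clustering({}, threshold)

    # cluster-level complete-linkage matrix, updated by elementwise max
    d = dist_matrix.d.astype(float).copy()
    members: list[Optional[list[int]]] = [[i] for i in range(n)]
    reps: list[Optional[str]] = [ids[i] for i in range(n)]  # min member id
    active = list(range(n))

    while len(active) > 1:
        act = np.asarray(active)
        sub = d[np.ix_(act, act)]
        iu, ju = np.triu_indices(len(act), k=1)
        vals = sub[iu, ju]
        min_d = vals.min()
        if min_d > threshold:
            break
        ties = np.nonzero(vals == min_d)[0]
        a, b = min(
            ((int(act[iu[t]]), int(act[ju[t]])) for t in ties),
            key=lambda p: tuple(sorted((reps[p[0]], reps[p[1]]))),
        )
        members[a] = members[a] + members[b]  # type: ignore[operator]
        reps[a] = min(reps[a], reps[b])  # type: ignore[type-var]
        d[a, :] = np.maximum(d[a, :], d[b, :])
        d[:, a] = d[a, :]
        d[a, a] = 0.0
        members[b] = None
        reps[b] = None
        active.remove(b)

    clusters = sorted(
        (m for m in members if m is not None),
        key=lambda m: (-len(m), min(ids[i] for i in m)),
    )
    assignment: dict[str, str] = {}
    width = max(4, len(str(len(clusters))))
    for k, cluster in enumerate(clusters, start=1):
        otu = f"OTU{k:0{width}d}"
        for i in cluster:
            assignment[ids[i]] = otu
    return Clustering(assignment, threshold)


def abundance_vector(clustering: Clustering) -> np.ndarray:
    """OTU sizes sorted in descending order."""
    return np.array(sorted(clustering.otu_sizes.values(), reverse=True), dtype=int)


def max_intra_distance(clustering: Clustering, dist_matrix: DistanceMatrix) -> float:
    """Largest within-cluster pairwise distance; 0.0 if all singletons."""
    index = {rid: i for i, rid in enumerate(dist_matrix.ids)}
    worst = 0.0
    for member_ids in clustering.members().values():
        rows = [index[r] for r in member_ids]
        if len(rows) > 1:
            sub = dist_matrix.d[np.ix_(rows, rows)]
            worst = max(worst, float(sub.max()))
    return worst
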