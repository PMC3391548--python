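"""Grid orchestration: refine a read set across a ladder of quality-filter
conditions, cluster each survivor set, and collect diversity, bias and
homopolymer summaries.

All conditions share the same trim length (computed once on the raw
reads), so every condition's survivors are a subset of the trimmed no-Q
baseline and the pairwise distance matrix is computed only once.
"""

from __future__ import annotations

import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from pyroqc import bias, diversity, homopoly, otu_cluster, refine, seqio
from pyroqc.otu_cluster import Clustering, DistanceMatrix
from pyroqc.refine import FilterConfig, RemovalLedger
from pyroqc.seqio import ReadSet

DEFAULT_Q_CUTOFFS = (25, 27, 30, 32)
DEFAULT_FRACTIONS = (0.15, 0.10)


@dataclass
class ConditionResult:
    """Everything the pipeline produced for one filter condition."""

    label: str
    config: FilterConfig
    ledger: RemovalLedger
    clustering: Optional[Clustering] = None
    estimate: Optional[diversity.DiversityEstimate] = None
    error: Optional[str] = None


@dataclass
class RunManifest:
    """Results of one grid run: per-condition ledgers, clusterings and
    diversity estimates, plus shared artifacts."""

    raw_count: int
    trim_length: Optional[int]
    threshold: float
    seed: Optional[int]
    conditions: list[ConditionResult] = field(default_factory=list)
    baseline_label: str = "trim_noQ"

    def condition(self, label: str) -> ConditionResult:
        for c in self.conditions:
            if c.label == label:
                return c
        raise KeyError(label)

    def labels(self) -> list[str]:
        return [c.label for c in self.conditions]


def grid_conditions(
    q_cutoffs: Sequence[int] = DEFAULT_Q_CUTOFFS,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    primer: Optional[str] = None,
    strip_primer: bool = False,
    trim_rule: str = "mean_minus_sd",
) -> list[FilterConfig]:
    """The two no-Q baselines plus the cutoff x fraction cross product."""
    configs = [
        FilterConfig(mode="none", trim_rule="none", primer=primer, strip_primer=strip_primer),
        FilterConfig(mode="none", trim_rule=trim_rule, primer=primer, strip_primer=strip_primer),
    ]
    for q in q_cutoffs:
        for f in fractions:
            configs.append(
                FilterConfig(
                    q_cutoff=q,
                    allowed_fraction=f,
                    mode="fraction",
                    primer=primer,
                    strip_primer=strip_primer,
                    trim_rule=trim_rule,
                )
            )
    return configs


def run_grid(
    read_set: ReadSet,
    q_cutoffs: Sequence[int] = DEFAULT_Q_CUTOFFS,
    fractions: Sequence[float] = DEFAULT_FRACTIONS,
    threshold: float = otu_cluster.DEFAULT_THRESHOLD,
    primer: Optional[str] = None,
    strip_primer: bool = False,
    trim_rule: str = "mean_minus_sd",
    rarefaction_step: int = 10,
    seed: Optional[int] = None,
    quiet: bool = True,
    cluster_full_length: bool = True,
) -> RunManifest:
    """Run refine -> cluster -> diversity over the condition grid.

    A condition that fails is recorded with its error message; the other
    conditions still run. ``cluster_full_length=False`` skips clustering
    of the full-length no-Q baseline (its distance matrix cannot be shared
    with the trimmed conditions, so it is the most expensive one).
    """
    if trim_rule == "mean_minus_sd" and len(read_set):
        # freeze the trim length so every condition shares it
        L: Optional[int] = refine.compute_trim_length(read_set)
        trim_rule = f"fixed:{L}"
    elif trim_rule.startswith("fixed:"):
        L = int(trim_rule.split(":", 1)[1])
    else:
        L = None

    manifest = RunManifest(
        raw_count=len(read_set), trim_length=L, threshold=threshold, seed=seed
    )
    configs = grid_conditions(q_cutoffs, fractions, primer, strip_primer, trim_rule)

    # distance matrices are shared: one for the trimmed survivors (every
    # fraction-mode condition selects a subset of them), one for full length
    trimmed_dm: Optional[DistanceMatrix] = None
    full_dm: Optional[DistanceMatrix] = None

    for config in configs:
        label = config.label()
        try:
            refined, ledger = refine.run_refinement(read_set, config)
            if config.trim_rule == "none":
                if not cluster_full_length:
                    manifest.conditions.append(ConditionResult(label, config, ledger))
                    continue
                if full_dm is None:
                    full_dm = otu_cluster.distance_matrix(refined)
                dm = full_dm.subset(refined.ids())
            else:
                if trimmed_dm is None:
                    no_q = FilterConfig(
                        mode="none",
                        trim_rule=config.trim_rule,
                        primer=primer,
                        strip_primer=strip_primer,
                    )
                    baseline, _ = refine.run_refinement(read_set, no_q)
                    trimmed_dm = otu_cluster.distance_matrix(baseline)
                dm = trimmed_dm.subset(refined.ids())
            clustering = otu_cluster.complete_linkage(dm, threshold)
            counts = otu_cluster.abundance_vector(clustering)
            estimate = (
                diversity.DiversityEstimate.from_counts(counts, step=rarefaction_step)
                if counts.size
                else None
            )
            manifest.conditions.append(
                ConditionResult(label, config, ledger, clustering, estimate)
            )
            if not quiet:
                print(
                    f"[{label}] remaining={ledger.remaining} "
                    f"otus={clustering.n_otus()}",
                    file=sys.stderr,
                )
        except Exception as exc:  # keep other conditions running
            manifest.conditions.append(
                ConditionResult(label, config, RemovalLedger(len(read_set)), error=str(exc))
            )
            if not quiet:
                print(f"[{label}] FAILED: {exc}", file=sys.stderr)
    return manifest


def ledger_table(manifest: RunManifest) -> pd.DataFrame:
    """Per-stage removal counts, one column per condition (the stage rows
    mirror the refinement order)."""
    data: dict[str, list] = {}
    stages = list(refine.STAGE_ORDER)
    for cond in manifest.conditions:
        removals = cond.ledger.as_dict()
        data[cond.label] = (
            [removals.get(s, 0) for s in stages]
            + [cond.ledger.remaining, round(100 * cond.ledger.percent_removed, 1)]
        )
    return pd.DataFrame(data, index=stages + ["remaining", "percent_removed"])


def diversity_table(manifest: RunManifest) -> pd.DataFrame:
    rows = []
    for cond in manifest.conditions:
        est = cond.estimate
        if est is None:
            continue
        rows.append(
            {
                "condition": cond.label,
                "n_reads": cond.ledger.remaining,
                "s_obs": est.s_obs,
                "chao1": est.chao1,
                "chao1_lo": est.chao1_ci[0],
                "chao1_hi": est.chao1_ci[1],
                "shannon_h": est.shannon_h,
                "evenness": est.evenness,
            }
        )
    return pd.DataFrame(rows)


def rarefaction_table(manifest: RunManifest) -> pd.DataFrame:
    rows = []
    for cond in manifest.conditions:
        if cond.estimate is None:
            continue
        for n, s in cond.estimate.rarefaction:
            rows.append({"condition": cond.label, "n": n, "expected_richness": s})
    return pd.DataFrame(rows)


def bias_tables(
    manifest: RunManifest,
    read_set: ReadSet,
    condition_label: str,
) -> tuple[pd.DataFrame, pd.DataFrame, float]:
    """Taxon pre/post fractions with R^2 against y = x, and the removal-
    by-cluster profile, both relative to the trimmed no-Q baseline."""
    baseline = manifest.condition(manifest.baseline_label)
    cond = manifest.condition(condition_label)
    if baseline.clustering is None or cond.clustering is None:
        raise ValueError("baseline or condition has no clustering")
    pre_ids = list(baseline.clustering.assignment)
    post_ids = [r for r in cond.clustering.assignment if r in set(pre_ids)]
    pre = read_set.subset(pre_ids)
    post = read_set.subset(post_ids)
    dist = bias.taxon_fractions(pre, post)
    r2 = bias.r_squared_identity(dist.points())
    removed = [r for r in pre_ids if r not in set(post_ids)]
    profile = bias.removal_by_cluster(baseline.clustering, removed)
    return dist.to_frame(), profile.to_frame(), r2


def report(
    manifest: RunManifest,
    read_set: ReadSet,
    out_dir: str | Path,
    bias_condition: Optional[str] = None,
    quiet: bool = True,
) -> dict[str, Path]:
    """Write the summary tables to ``out_dir`` as TSV; returns the paths.

    Re-running on the same manifest overwrites byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    def _write(name: str, frame: pd.DataFrame, index: bool = False) -> None:
        path = out / name
        frame.to_csv(path, sep="\t", index=index, float_format="%.6g")
        paths[name] = path

    _write("removal_ledger.tsv", ledger_table(manifest), index=True)
    _write("diversity.tsv", diversity_table(manifest))
    _write("rarefaction.tsv", rarefaction_table(manifest))
    _write("homopolymers.tsv", homopoly.tabulate(read_set), index=True)

    has_taxa = all(r.taxon is not None for r in read_set)
    if bias_condition and has_taxa:
        dist_frame, profile_frame, r2 = bias_tables(manifest, read_set, bias_condition)
        _write("taxon_fractions.tsv", dist_frame)
        _write("cluster_removal.tsv", profile_frame)
        (out / "bias_r2.json").write_text(
            json.dumps({"condition": bias_condition, "r_squared_identity": r2}) + "\n"
        )
        paths["bias_r2.json"] = out / "bias_r2.json"

    manifest_dict = {
        "raw_count": manifest.raw_count,
        "trim_length": manifest.trim_length,
        "threshold": manifest.threshold,
        "seed": manifest.seed,
        "conditions": {
            c.label: {
                "remaining": c.ledger.remaining,
                "n_otus": c.clustering.n_otus() if c.clustering else None,
                "error": c.error,
            }
            for c in manifest.conditions
        },
        "outputs": {k: str(v) for k, v in paths.items()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest_dict, indent=2) + "\n")
    paths["manifest.json"] = out / "manifest.json"
    if not quiet:
        print(f"report written to {out}", file=sys.stderr)
    return paths
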