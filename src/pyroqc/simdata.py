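"""Seeded 454-style amplicon read simulator with ground truth.

Generates a mock community of divergent templates (each carrying a
concrete realization of a degenerate primer at its 5' end) and draws
reads with:

* variable length (Gaussian jitter around the template length),
* per-base Phred scores declining along the read with Gaussian noise,
* substitution errors planted per base with probability 10^(-Q/10),
* homopolymer run-length +/-1 errors scaled with run length,
* an optional fraction of globally degraded ("bad") reads.

All randomness flows from the single seed in :class:`SimulationConfig`,
so identical configurations yield byte-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from pyroqc.otu_cluster import pairwise_distance
from pyroqc.refine import IUPAC
from pyroqc.seqio import QualifiedRead, ReadSet

DEFAULT_TAXA = (
    "Firmicutes",
    "Bacteroidetes",
    "Betaproteobacteria",
    "Gammaproteobacteria",
    "Actinobacteria",
    "Chloroflexi",
    "Thermotogae",
    "Nitrospirae",
)

_REJECTION_CAP = 2000


@dataclass
class SimulationConfig:
    """Full parameterization of the synthetic community and error model."""

    n_templates: int = 10
    template_length: int = 250
    min_template_divergence: float = 0.10
    abundance_model: str = "geometric"  # or "uniform"
    geometric_ratio: float = 0.7
    n_reads: int = 500
    primer: str = "tagtgtagatGTGCCAGCMGCNGCGG"
    q_start: float = 34.0
    q_slope: float = 0.02
    q_noise_sd: float = 2.0
    q_spike_rate: float = 0.0  # per-base chance of an isolated low-Q spike
    q_spike_q: float = 15.0  # mean Phred of spiked bases
    homopolymer_indel_rate: float = 0.01
    length_sd: float = 10.0
    frac_bad_reads: float = 0.0
    bad_q_drop: float = 12.0
    taxon_labels: Sequence[str] = DEFAULT_TAXA
    simulate_chimeras: bool = False  # reserved; chimera modeling not implemented
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_templates < 1:
            raise ValueError("n_templates must be >= 1")
        for name in (
            "min_template_divergence",
            "homopolymer_indel_rate",
            "frac_bad_reads",
            "q_spike_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.abundance_model not in ("geometric", "uniform"):
            raise ValueError(f"unknown abundance model {self.abundance_model!r}")
        if self.simulate_chimeras:
            raise NotImplementedError("chimera simulation is a reserved no-op flag")
        if self.template_length <= len(self.primer):
            raise ValueError("template_length must exceed the primer length")


@dataclass
class GroundTruth:
    """Per-read provenance and planted-error counts plus community truth."""

    template_ids: dict[str, str]
    taxa: dict[str, str]
    n_substitutions: dict[str, int]
    n_indels: dict[str, int]
    is_bad: dict[str, bool]
    true_richness: int
    true_abundance: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def to_rows(self) -> list[tuple[str, str, str, int, int]]:
        return [
            (rid, self.template_ids[rid], self.taxa[rid],
             self.n_substitutions[rid], self.n_indels[rid])
            for rid in self.template_ids
        ]


def _realize_primer(primer: str, rng: np.random.Generator) -> str:
    """Resolve degenerate IUPAC positions to concrete bases."""
    out = []
    for code in primer.upper():
        choices = IUPAC.get(code)
        if not choices:
            raise ValueError(f"invalid IUPAC code {code!r} in primer")
        out.append(choices[int(rng.integers(len(choices)))])
    return "".join(out)


def generate_templates(config: SimulationConfig) -> tuple[list[str], list[str]]:
    """Mock community templates plus round-robin taxon labels.

    Templates all start with a concrete realization of the primer; the
    remainder is uniform random sequence, rejection-sampled until every
    pair is at least ``min_template_divergence`` apart.
    """
    rng = np.random.default_rng(config.seed)
    body_len = config.template_length - len(config.primer)
    templates: list[str] = []
    alphabet = np.array(list("ACGT"))
    attempts = 0
    while len(templates) < config.n_templates:
        attempts += 1
        if attempts > _REJECTION_CAP:
            raise RuntimeError(
                "template rejection sampling exceeded "
                f"{_REJECTION_CAP} attempts; lower min_template_divergence "
                "or n_templates"
            )
        prefix = _realize_primer(config.primer, rng)
        body = "".join(alphabet[rng.integers(4, size=body_len)])
        cand = prefix + body
        if all(
            pairwise_distance(cand, t) >= config.min_template_divergence
            for t in templates
        ):
            templates.append(cand)
    labels = [
        config.taxon_labels[i % len(config.taxon_labels)]
        for i in range(config.n_templates)
    ]
    return templates, labels


def _abundance_weights(config: SimulationConfig) -> np.ndarray:
    if config.abundance_model == "uniform":
        w = np.ones(config.n_templates)
    else:
        w = config.geometric_ratio ** np.arange(config.n_templates)
    return w / w.sum()


def _apply_homopolymer_indels(
    bases: list[str], quals: list[int], rate: float, rng: np.random.Generator
) -> int:
    """Plant +/-1 length errors on homopolymer runs >= 4, in place.

    Per-run probability is rate * (run_length - 3). Inserted bases inherit
    the local quality value. Returns the number of planted indels.
    """
    if rate <= 0.0:
        return 0
    # locate maximal runs on the current sequence
    runs: list[tuple[int, int]] = []  # (start, length)
    i = 0
    n = len(bases)
    while i < n:
        j = i
        while j < n and bases[j] == bases[i]:
            j += 1
        if j - i >= 4 and bases[i] != "N":
            runs.append((i, j - i))
        i = j
    planted = 0
    # apply right-to-left so earlier run coordinates stay valid
    for start, length in reversed(runs):
        p = min(1.0, rate * (length - 3))
        if rng.random() >= p:
            continue
        if rng.random() < 0.5 and length > 1:
            del bases[start]
            del quals[start]
        else:
            bases.insert(start, bases[start])
            quals.insert(start, quals[start])
        planted += 1
    return planted


def simulate_reads(
    templates: Sequence[str],
    config: SimulationConfig,
    taxon_labels: Optional[Sequence[str]] = None,
) -> tuple[ReadSet, GroundTruth]:
    """Draw ``config.n_reads`` reads from the templates with the full
    error model; returns the reads and their ground truth."""
    if not templates:
        raise ValueError("no templates supplied")
    if taxon_labels is None:
        taxon_labels = [
            config.taxon_labels[i % len(config.taxon_labels)]
            for i in range(len(templates))
        ]
    rng = np.random.default_rng(config.seed + 1)  # distinct stream from templates
    weights = _abundance_weights(config)[: len(templates)]
    weights = weights / weights.sum()

    reads: list[QualifiedRead] = []
    gt = GroundTruth({}, {}, {}, {}, {}, true_richness=0)
    template_draws = rng.choice(len(templates), size=config.n_reads, p=weights)
    alphabet = "ACGT"

    for i, t_idx in enumerate(template_draws):
        template = templates[t_idx]
        rid = f"read{i + 1:06d}"
        length = int(round(rng.normal(len(template), config.length_sd)))
        length = max(1, min(length, len(template)))

        bad = bool(rng.random() < config.frac_bad_reads)
        q0 = config.q_start - (config.bad_q_drop if bad else 0.0)
        pos = np.arange(length)
        raw_q = q0 - config.q_slope * pos + rng.normal(0.0, config.q_noise_sd, length)
        if config.q_spike_rate > 0.0:
            # isolated low-confidence base calls, the trait that makes
            # end-trimming far harsher than fraction-based filtering
            spikes = rng.random(length) < config.q_spike_rate
            raw_q[spikes] = rng.normal(config.q_spike_q, 2.0, int(spikes.sum()))
        q = np.rint(np.clip(raw_q, 0, 40)).astype(int)

        bases = list(template[:length])
        quals = list(int(v) for v in q)
        n_indel = _apply_homopolymer_indels(
            bases, quals, config.homopolymer_indel_rate, rng
        )

        p_err = np.power(10.0, -np.asarray(quals) / 10.0)
        hits = np.nonzero(rng.random(len(bases)) < p_err)[0]
        for h in hits:
            original = bases[h]
            bases[h] = rng.choice([b for b in alphabet if b != original])
        n_sub = int(hits.size)

        reads.append(
            QualifiedRead(
                rid,
                "".join(bases),
                tuple(quals),
                taxon=taxon_labels[t_idx],
                template_id=f"template{t_idx + 1:03d}",
            )
        )
        gt.template_ids[rid] = f"template{t_idx + 1:03d}"
        gt.taxa[rid] = taxon_labels[t_idx]
        gt.n_substitutions[rid] = n_sub
        gt.n_indels[rid] = n_indel
        gt.is_bad[rid] = bad

    sampled = np.bincount(template_draws, minlength=len(templates))
    gt.true_richness = int(np.sum(sampled > 0))
    gt.true_abundance = np.sort(sampled[sampled > 0])[::-1]
    provenance = (
        f"simulate_reads(n_templates={len(templates)}, n_reads={config.n_reads}, "
        f"seed={config.seed})"
    )
    return ReadSet(reads, provenance), gt


def simulate_community(config: SimulationConfig) -> tuple[ReadSet, GroundTruth, list[str]]:
    """Convenience wrapper: generate templates then simulate reads."""
    templates, labels = generate_templates(config)
    read_set, gt = simulate_reads(templates, config, labels)
    return read_set, gt, templates
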