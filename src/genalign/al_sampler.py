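"""Active-learning training-set construction.

The AL training set has two parts. The replica part takes every scored
molecule at or above the score threshold and repeats it N times, where N is
the smallest integer bringing the total to at least ``replica_floor``
(default 5000). The sampled part converts mean cluster scores to sampling
fractions with a softmax, integerizes fraction x budget with largest-
remainder rounding, caps each cluster at its population and redistributes
any surplus proportionally among the uncapped clusters, then draws that many
molecules per cluster without replacement from the generated ensemble.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chemspace import Clustering
from .scoring import ScoredMolecule


@dataclass
class ALConfig:
    score_threshold: float
    replica_floor: int = 5000
    sampling_budget: int = 5000
    fraction_method: str = "softmax"

    def __post_init__(self) -> None:
        if self.replica_floor <= 0 or self.sampling_budget <= 0:
            raise ValueError("replica_floor and sampling_budget must be positive")
        if self.fraction_method != "softmax":
            raise ValueError("only the softmax fraction method is supported")


def replica_multiplicity(n_passing: int, floor: int) -> int:
    """Smallest N with N * n_passing >= floor."""
    if n_passing < 1:
        raise ValueError("n_passing must be >= 1")
    return math.ceil(floor / n_passing)


def cluster_fractions(mean_cluster_scores: Mapping[int, float]) -> dict[int, float]:
    """Softmax of mean cluster scores (overflow-safe via max subtraction)."""
    if not mean_cluster_scores:
        raise ValueError("need at least one cluster with a mean score")
    labels = sorted(mean_cluster_scores)
    m = np.array([mean_cluster_scores[l] for l in labels], dtype=float)
    e = np.exp(m - m.max())
    f = e / e.sum()
    return dict(zip(labels, f.tolist()))


def _largest_remainder(weights: np.ndarray, total: int) -> np.ndarray:
    """Integerize weights*total so the counts sum exactly to ``total``."""
    raw = weights * total
    base = np.floor(raw).astype(int)
    short = total - base.sum()
    if short > 0:
        order = np.argsort(-(raw - base), kind="stable")
        base[order[:short]] += 1
    return base


def allocate(
    fractions: Mapping[int, float], cluster_sizes: Mapping[int, int], budget: int
) -> dict[int, int]:
    """Integer per-cluster sample counts under capacity constraints.

    Initial counts are largest-remainder integerizations of fraction x
    budget. Clusters capped at their size return a surplus, which is
    redistributed among the remaining clusters proportionally to their
    fractions, iterating until the budget is met or every cluster is full.
    Total allocated = min(budget, total population over the given clusters).
    """
    labels = sorted(fractions)
    f = np.array([fractions[l] for l in labels], dtype=float)
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    sizes = np.array([cluster_sizes.get(l, 0) for l in labels], dtype=int)
    counts = np.zeros(len(labels), dtype=int)
    remaining = budget
    active = np.ones(len(labels), dtype=bool)
    while remaining > 0 and active.any():
        w = np.where(active, f, 0.0)
        if w.sum() == 0:
            break
        alloc = _largest_remainder(w / w.sum(), remaining)
        counts = np.minimum(counts + alloc, sizes)
        newly_full = active & (counts >= sizes)
        active &= ~newly_full
        remaining = budget - int(counts.sum())
        if alloc.sum() == 0:
            break
    return dict(zip(labels, counts.tolist()))


@dataclass
class ALTrainingSet:
    """Replica part (above-threshold molecules x N) plus cluster-sampled part."""

    replicas: list[str]  # passing molecules, each listed once
    multiplicity: int
    sampled: list[str]
    fractions: dict[int, float] = field(default_factory=dict)
    allocations: dict[int, int] = field(default_factory=dict)
    seed: int | None = None

    def molecules(self, shuffle_seed: int | None = None) -> list[str]:
        """Full training multiset (replicas expanded), optionally shuffled."""
        out = self.replicas * self.multiplicity + self.sampled
        if shuffle_seed is not None:
            rng = np.random.default_rng(shuffle_seed)
            out = [out[i] for i in rng.permutation(len(out))]
        return out

    def __len__(self) -> int:
        return len(self.replicas) * self.multiplicity + len(self.sampled)

    def save(self, smiles_path: str | Path, manifest_path: str | Path) -> None:
        Path(smiles_path).write_text("\n".join(self.molecules()) + "\n")
        manifest = {
            "multiplicity": self.multiplicity,
            "n_passing": len(self.replicas),
            "n_sampled": len(self.sampled),
            "fractions": {str(k): v for k, v in self.fractions.items()},
            "allocations": {str(k): v for k, v in self.allocations.items()},
            "seed": self.seed,
        }
        Path(manifest_path).write_text(json.dumps(manifest, indent=1))


def build_al_set(
    scored: Sequence[ScoredMolecule],
    clustering: Clustering,
    ensemble: Sequence[str],
    config: ALConfig,
    seed: int = 0,
    uniform_fractions: bool = False,
) -> ALTrainingSet:
    """Assemble the AL training set from a scored subset and the full ensemble.

    ``scored`` molecules must carry cluster labels consistent with
    ``clustering`` (whose labels index ``ensemble``). With
    ``uniform_fractions`` every cluster containing a scored molecule gets an
    equal fraction (the uniform-sampling control); otherwise fractions are
    the softmax of mean cluster scores.
    """
    if len(ensemble) != len(clustering.labels):
        raise ValueError("ensemble and clustering labels disagree in length")
    passing = [s.smiles for s in scored if s.score >= config.score_threshold]
    if passing:
        mult = replica_multiplicity(len(passing), config.replica_floor)
    else:
        warnings.warn("no molecules reach the score threshold; replica part empty")
        mult = 0

    by_cluster: dict[int, list[float]] = {}
    for s in scored:
        if s.cluster_label is None:
            raise ValueError(f"scored molecule {s.id} lacks a cluster label")
        by_cluster.setdefault(int(s.cluster_label), []).append(s.score)
    means = {label: float(np.mean(v)) for label, v in by_cluster.items()}
    if uniform_fractions:
        fractions = {label: 1.0 / len(means) for label in sorted(means)}
    else:
        fractions = cluster_fractions(means)

    sizes = {label: int(len(clustering.members(label))) for label in fractions}
    allocations = allocate(fractions, sizes, config.sampling_budget)

    rng = np.random.default_rng(seed)
    ensemble = list(ensemble)
    sampled: list[str] = []
    for label in sorted(allocations):
        take = allocations[label]
        if take == 0:
            continue
        members = clustering.members(label)
        pick = rng.choice(members, size=take, replace=False)
        sampled.extend(ensemble[i] for i in sorted(pick))
    return ALTrainingSet(
        replicas=passing,
        multiplicity=mult,
        sampled=sampled,
        fractions=fractions,
        allocations=allocations,
        seed=seed,
    )
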