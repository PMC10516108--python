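"""Iteration loop driving the full methodology.

One iteration is: generate a unique ensemble -> (optional drug-likeness
filters) -> descriptors -> project into the frozen proxy -> cluster ->
select a stratified subset -> score it -> assemble the AL training set ->
fine-tune. Three modes are supported:

``complete``
    softmax-of-mean-cluster-scores sampling fractions (the methodology);
``uniform``
    identical pipeline but every cluster gets the same fraction (control
    isolating the diffusion effect of cluster-stratified sampling);
``naive``
    no proxy/clustering: a random subset is scored and the AL set contains
    only the above-threshold molecules and their replicas.

All randomness is drawn from a seed ledger: the master seed and a
(stage, iteration) pair are hashed to a per-stage seed, so any stage can be
reproduced independently. The projection model is fitted once per run, on
the pretraining corpus, and reused for every iteration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from . import corpus as corpus_mod
from .al_sampler import ALConfig, ALTrainingSet, build_al_set, replica_multiplicity
from .chemspace import (
    Clustering,
    ProjectionModel,
    cluster,
    compute_descriptors,
    fast_descriptor_provider,
    project,
    rdkit_descriptor_provider,
    select_for_scoring,
)
from .generator import (
    GeneratorConfig,
    LanguageModel,
    TrainSchedule,
    build_model,
    fine_tune,
    generate_unique,
    load_checkpoint,
    pretrain,
    save_checkpoint,
)
from .metrics import IterationMetrics, iteration_metrics
from .molfilters import FilterSet, apply_filters
from .scoring import InteractionWeights, PoseProvider, ScoredMolecule, score_molecules
from .synthetic import SurrogateScorer, surrogate_pose_provider

MODES = ("complete", "uniform", "naive")


def derive_seed(master_seed: int, stage: str, iteration: int = 0) -> int:
    """Deterministic per-stage, per-iteration seed (< 2**31)."""
    digest = hashlib.sha256(f"{master_seed}:{stage}:{iteration}".encode()).digest()
    return int.from_bytes(digest[:4], "little") % (2**31)


@dataclass
class LoopConfig:
    """Configuration for a full run; defaults are the full-scale recipe."""

    score_threshold: float
    mode: str = "complete"
    n_iterations: int = 5
    master_seed: int = 0
    # corpus
    min_count: int = 1000
    length_coverage: float = 0.9999
    train_fraction: float = 0.95
    # model / schedules
    embed_dim: int = 256
    n_blocks: int = 8
    n_heads: int = 8
    dropout: float = 0.10
    pretrain_schedule: TrainSchedule = field(default_factory=TrainSchedule.pretrain_default)
    finetune_schedule: TrainSchedule = field(default_factory=TrainSchedule.finetune_default)
    # generation
    generation_size: int = 100_000
    generation_attempt_factor: int = 20  # max raw samples = factor * generation_size
    temperature: float = 1.0
    filters_enabled: bool = False
    # proxy / clustering / selection
    descriptor_set: str = "full"  # "full" or "fast"
    n_components: int = 120
    standardize: bool = True
    k: int = 100
    n_restarts: int = 100
    per_cluster_cap: int = 10
    scored_subset_size: int = 1000
    # AL set
    replica_floor: int = 5000
    sampling_budget: int = 5000
    # surrogate-scorer calibration (used only when no pose provider is given)
    surrogate_start_fraction: float = 0.25
    surrogate_noise: float = 0.0
    # evaluation
    references: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    def descriptor_provider(self):
        if self.descriptor_set == "fast":
            return fast_descriptor_provider()
        return rdkit_descriptor_provider()

    def al_config(self) -> ALConfig:
        return ALConfig(
            score_threshold=self.score_threshold,
            replica_floor=self.replica_floor,
            sampling_budget=self.sampling_budget,
        )

    @classmethod
    def tiny(cls, score_threshold: float = 11.0, **overrides) -> "LoopConfig":
        """Desk-scale profile preserving the full recipe's ratios.

        300-molecule corpus, 2000 generated per iteration, scored subset 100
        (5%), k=20 clusters with cap 5, replica floor and budget 250.
        """
        base = dict(
            score_threshold=score_threshold,
            min_count=2,
            length_coverage=0.995,
            embed_dim=64,
            n_blocks=2,
            n_heads=2,
            pretrain_schedule=TrainSchedule(
                batch_size=16, epochs=50, peak_lr=6e-4, final_lr=6e-5
            ),
            # fine-tune peak = pretrain peak / 10, as in the full-scale recipe
            finetune_schedule=TrainSchedule(
                batch_size=16, epochs=10, peak_lr=6e-5, final_lr=6e-6,
                warmup_token_fraction=0.0,
            ),
            generation_size=2000,
            generation_attempt_factor=5,
            descriptor_set="fast",
            n_components=10,
            k=20,
            n_restarts=20,
            per_cluster_cap=5,
            scored_subset_size=100,
            replica_floor=250,
            sampling_budget=250,
            surrogate_noise=0.5,
        )
        base.update(overrides)
        return cls(**base)


@dataclass
class RunState:
    """Mutable state threaded through the loop."""

    model: LanguageModel
    projection: ProjectionModel
    config: LoopConfig
    iteration: int = 0
    metrics: list[IterationMetrics] = field(default_factory=list)
    ensemble: list[str] = field(default_factory=list)
    scored: list[ScoredMolecule] = field(default_factory=list)
    clustering: Clustering | None = None
    al_set: ALTrainingSet | None = None
    seed_ledger: dict[str, int] = field(default_factory=dict)

    def seed(self, stage: str, iteration: int | None = None) -> int:
        it = self.iteration if iteration is None else iteration
        s = derive_seed(self.config.master_seed, stage, it)
        self.seed_ledger[f"{stage}:{it}"] = s
        return s

    def metrics_table(self) -> pd.DataFrame:
        return pd.DataFrame([m.to_row() for m in self.metrics])


PoseProviderFactory = Callable[[dict[str, np.ndarray]], PoseProvider]


def make_surrogate_factory(
    scorer: SurrogateScorer, projection: ProjectionModel, descriptor_provider
) -> PoseProviderFactory:
    """Factory wiring a surrogate scorer into the per-iteration provider."""

    def factory(coords_map: dict[str, np.ndarray]) -> PoseProvider:
        return surrogate_pose_provider(
            scorer, projection, descriptor_provider, precomputed_coords=coords_map
        )

    return factory


def evaluate_iteration(
    state: RunState,
    pose_provider_factory: PoseProviderFactory,
    weights: InteractionWeights | None = None,
) -> IterationMetrics:
    """Generate, project, cluster, select and score for the current iteration.

    Leaves the scored subset and clustering on the state so the AL set can
    be assembled afterwards.
    """
    cfg = state.config
    it = state.iteration
    gen = generate_unique(
        state.model,
        cfg.generation_size,
        temperature=cfg.temperature,
        max_attempts=cfg.generation_attempt_factor * cfg.generation_size,
        seed=state.seed("generate"),
    )
    ensemble = gen.molecules
    if cfg.filters_enabled:
        ensemble, _ = apply_filters(ensemble, FilterSet.default())
    if len(ensemble) < max(cfg.k, 2):
        raise RuntimeError(
            f"iteration {it}: only {len(ensemble)} molecules survive generation/filters"
        )
    matrix = compute_descriptors(ensemble, provider=cfg.descriptor_provider())
    ensemble = matrix.ids  # drop molecules that failed descriptor computation
    coords = project(state.projection, matrix)

    if cfg.mode == "naive":
        rng = np.random.default_rng(state.seed("select"))
        subset = [
            ensemble[i]
            for i in sorted(
                rng.choice(len(ensemble), size=min(cfg.scored_subset_size, len(ensemble)), replace=False)
            )
        ]
        state.clustering = None
        label_of = dict.fromkeys(subset, 0)
    else:
        clustering = cluster(
            coords, k=cfg.k, n_restarts=cfg.n_restarts, seed=state.seed("cluster")
        )
        state.clustering = clustering
        subset = select_for_scoring(
            clustering,
            ensemble,
            per_cluster_cap=cfg.per_cluster_cap,
            total=cfg.scored_subset_size,
            seed=state.seed("select"),
        )
        label_of = {
            smiles: int(clustering.labels[i]) for i, smiles in enumerate(ensemble)
        }

    coords_map = {s: coords[i] for i, s in enumerate(ensemble)}
    provider = pose_provider_factory(coords_map)
    scored, _failures = score_molecules(subset, provider, weights=weights)
    for s in scored:
        s.cluster_label = label_of.get(s.smiles)
    state.ensemble = ensemble
    state.scored = scored

    metrics = iteration_metrics(
        iteration=it,
        scores=[s.score for s in scored],
        threshold=cfg.score_threshold,
        n_generated=len(ensemble),
        generated=ensemble if cfg.references else None,
        references=cfg.references or None,
    )
    state.metrics.append(metrics)
    return metrics


def fine_tune_iteration(state: RunState) -> ALTrainingSet | None:
    """Build the AL training set for the current iteration and fine-tune."""
    cfg = state.config
    al_seed = state.seed("al_sample")
    if cfg.mode == "naive":
        passing = [s.smiles for s in state.scored if s.score >= cfg.score_threshold]
        if not passing:
            warnings.warn("naive mode: no molecules pass the threshold; skipping fine-tune")
            state.al_set = None
            state.iteration += 1
            return None
        al = ALTrainingSet(
            replicas=passing,
            multiplicity=replica_multiplicity(len(passing), cfg.replica_floor),
            sampled=[],
            seed=al_seed,
        )
    else:
        al = build_al_set(
            state.scored,
            state.clustering,
            state.ensemble,
            cfg.al_config(),
            seed=al_seed,
            uniform_fractions=(cfg.mode == "uniform"),
        )
    state.al_set = al
    molecules = al.molecules(shuffle_seed=al_seed)
    if molecules:
        fine_tune(
            state.model,
            molecules,
            schedule=cfg.finetune_schedule,
            seed=state.seed("finetune"),
        )
    state.iteration += 1
    return al


def run_iteration(
    state: RunState,
    pose_provider_factory: PoseProviderFactory,
    weights: InteractionWeights | None = None,
) -> tuple[RunState, IterationMetrics]:
    """One full iteration: evaluate the current model, then fine-tune."""
    metrics = evaluate_iteration(state, pose_provider_factory, weights=weights)
    fine_tune_iteration(state)
    return state, metrics


def prepare_run(
    config: LoopConfig,
    corpus_entries: Sequence[str],
    model: LanguageModel | None = None,
    projection: ProjectionModel | None = None,
) -> tuple[RunState, corpus_mod.PreprocessResult]:
    """Preprocess, fit the one-time projection, and pretrain (unless given)."""
    prep = corpus_mod.preprocess(
        corpus_entries,
        min_count=config.min_count,
        coverage=config.length_coverage,
        train_fraction=config.train_fraction,
        seed=derive_seed(config.master_seed, "split"),
    )
    if projection is None:
        matrix = compute_descriptors(prep.corpus, provider=config.descriptor_provider())
        n_comp = min(config.n_components, *matrix.values.shape)
        from .chemspace import fit_projection

        projection = fit_projection(matrix, n_components=n_comp, standardize=config.standardize)
    if model is None:
        gen_cfg = GeneratorConfig(
            context_length=prep.encoded.max_len + 2,
            embed_dim=config.embed_dim,
            n_blocks=config.n_blocks,
            n_heads=config.n_heads,
            dropout=config.dropout,
        )
        model = build_model(
            gen_cfg, prep.vocabulary, seed=derive_seed(config.master_seed, "init")
        )
        pretrain(
            model,
            prep.train,
            config.pretrain_schedule,
            seed=derive_seed(config.master_seed, "pretrain"),
            validation=prep.validation,
        )
    return RunState(model=model, projection=projection, config=config), prep


def run_loop(
    config: LoopConfig,
    corpus_entries: Sequence[str],
    pose_provider: PoseProvider | None = None,
    model: LanguageModel | None = None,
    projection: ProjectionModel | None = None,
    workdir: str | Path | None = None,
) -> RunState:
    """Pretrain (or reuse a model), then run ``n_iterations`` of the loop.

    Emits ``n_iterations + 1`` metric rows (row 0 evaluates the pretrained
    model). Without an explicit ``pose_provider`` a surrogate scorer is
    calibrated on the pretraining corpus so the run needs no docking engine.
    With a ``workdir``, per-iteration checkpoints and the metrics table are
    written, and an interrupted run resumes from the last completed iteration.
    """
    workdir = Path(workdir) if workdir is not None else None
    if workdir is not None:
        workdir.mkdir(parents=True, exist_ok=True)

    state, prep = prepare_run(config, corpus_entries, model=model, projection=projection)

    if pose_provider is None:
        ref_matrix = compute_descriptors(prep.corpus, provider=config.descriptor_provider())
        ref_coords = project(state.projection, ref_matrix)
        scorer = SurrogateScorer.from_reference(
            ref_coords,
            threshold=config.score_threshold,
            fraction=config.surrogate_start_fraction,
            noise_amplitude=config.surrogate_noise,
            seed=derive_seed(config.master_seed, "surrogate"),
        )
        factory = make_surrogate_factory(
            scorer, state.projection, config.descriptor_provider()
        )
    else:
        factory = lambda coords_map: pose_provider  # noqa: E731

    start_iteration = 0
    if workdir is not None:
        start_iteration = _try_resume(state, workdir)

    t0 = time.time()
    for it in range(start_iteration, config.n_iterations + 1):
        state.iteration = it
        evaluate_iteration(state, factory)
        if it < config.n_iterations:
            fine_tune_iteration(state)
        else:
            state.iteration += 1
        if workdir is not None:
            _save_progress(state, workdir, it)
    if workdir is not None:
        _write_manifest(state, workdir, elapsed=time.time() - t0)
    return state


def _save_progress(state: RunState, workdir: Path, it: int) -> None:
    save_checkpoint(state.model, workdir / f"checkpoint_{it}.npz")
    state.metrics_table().to_csv(workdir / "metrics.csv", index=False)


def _try_resume(state: RunState, workdir: Path) -> int:
    """Resume from the last completed iteration, if any; returns next iteration."""
    metrics_path = workdir / "metrics.csv"
    if not metrics_path.exists():
        return 0
    table = pd.read_csv(metrics_path)
    done = -1
    for it in sorted(table["iteration"].astype(int)):
        if (workdir / f"checkpoint_{it}.npz").exists():
            done = it
    if done < 0:
        return 0
    state.model = load_checkpoint(workdir / f"checkpoint_{done}.npz")
    kept = table[table["iteration"] <= done]
    state.metrics = []
    for _, row in kept.iterrows():
        state.metrics.append(
            IterationMetrics(
                iteration=int(row["iteration"]),
                fraction_above_threshold=float(row["fraction_above_threshold"]),
                mean_score=float(row["mean_score"]),
                max_score=float(row["max_score"]),
                n_scored=int(row["n_scored"]),
                n_generated=int(row["n_generated"]),
            )
        )
    return done + 1


def _write_manifest(state: RunState, workdir: Path, elapsed: float) -> None:
    import rdkit
    import sklearn

    cfg = dataclasses.asdict(state.config)
    cfg["pretrain_schedule"]["optimizer_betas"] = list(
        cfg["pretrain_schedule"]["optimizer_betas"]
    )
    cfg["finetune_schedule"]["optimizer_betas"] = list(
        cfg["finetune_schedule"]["optimizer_betas"]
    )
    manifest = {
        "config": cfg,
        "seed_ledger": state.seed_ledger,
        "optimizer": "adamw-fallback",
        "versions": {
            "rdkit": rdkit.rdBase.rdkitVersion,
            "sklearn": sklearn.__version__,
            "numpy": np.__version__,
        },
        "elapsed_seconds": elapsed,
    }
    (workdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
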