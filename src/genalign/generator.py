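"""Autoregressive SMILES generator: training schedules, sampling, fine-tuning.

The model is a GPT-style transformer decoder over the token vocabulary from
:mod:`genalign.corpus`. Defaults follow the full-scale recipe (256-d, 8 blocks,
8 heads, batch 512, 30 pretraining epochs with 3e-4 -> 3e-5 cosine decay after
a 10%-of-tokens linear warmup; fine-tuning 10 epochs, 3e-5 -> 3e-6, no warmup);
a ``tiny`` profile exercises identical code paths at desk scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .corpus import EncodedCorpus, TokenVocabulary, canonicalize, decode, encode, tokenize
from .nnet import GPT, AdamW, GPTConfig, _softmax


@dataclass
class GeneratorConfig:
    """Architecture hyperparameters (full-scale defaults)."""

    context_length: int
    embed_dim: int = 256
    n_blocks: int = 8
    n_heads: int = 8
    dropout: float = 0.10
    init_std: float = 0.02
    layernorm_init: float = 1.0
    bias_init: float = 0.0

    @classmethod
    def tiny(cls, context_length: int) -> "GeneratorConfig":
        """Desk-scale profile: 64-d, 2 blocks, 2 heads."""
        return cls(context_length=context_length, embed_dim=64, n_blocks=2, n_heads=2)


@dataclass
class TrainSchedule:
    """Optimization schedule; see :func:`lr_at_step` for the lr trajectory."""

    batch_size: int = 512
    epochs: int = 30
    peak_lr: float = 3e-4
    final_lr: float = 3e-5
    warmup_token_fraction: float = 0.10
    l2_lambda: float = 0.1
    optimizer_betas: tuple[float, float] = (0.965, 0.99)
    optimizer_rho: float = 0.04  # Sophia-specific; unused by the AdamW fallback
    grad_clip_norm: float = 1.0

    def __post_init__(self) -> None:
        if self.final_lr > self.peak_lr:
            raise ValueError("final_lr must be <= peak_lr")
        if not 0 <= self.warmup_token_fraction < 1:
            raise ValueError("warmup_token_fraction must be in [0, 1)")

    @classmethod
    def pretrain_default(cls) -> "TrainSchedule":
        return cls()

    @classmethod
    def finetune_default(cls) -> "TrainSchedule":
        return cls(
            epochs=10, peak_lr=3e-5, final_lr=3e-6, warmup_token_fraction=0.0
        )

    def tiny(self, epochs: int | None = None) -> "TrainSchedule":
        return replace(self, batch_size=16, epochs=self.epochs if epochs is None else epochs)


@dataclass
class LanguageModel:
    """Trained (or initialized) generator plus its vocabulary."""

    net: GPT
    config: GeneratorConfig
    vocabulary: TokenVocabulary

    @property
    def context_length(self) -> int:
        return self.config.context_length

    @property
    def max_smiles_tokens(self) -> int:
        return self.config.context_length - 2


def build_model(config: GeneratorConfig, vocabulary: TokenVocabulary, seed: int) -> LanguageModel:
    """Initialize a model deterministically under ``seed``."""
    net = GPT(
        GPTConfig(
            vocab_size=len(vocabulary),
            context_length=config.context_length,
            embed_dim=config.embed_dim,
            n_blocks=config.n_blocks,
            n_heads=config.n_heads,
            dropout=config.dropout,
            init_std=config.init_std,
            layernorm_init=config.layernorm_init,
            bias_init=config.bias_init,
        ),
        seed=seed,
    )
    return LanguageModel(net=net, config=config, vocabulary=vocabulary)


def lr_at_step(schedule: TrainSchedule, tokens_seen: float, tokens_total: float) -> float:
    """Learning rate after ``tokens_seen`` of ``tokens_total`` training tokens.

    Linear warmup from 0 to ``peak_lr`` over the first
    ``warmup_token_fraction`` of tokens, then cosine decay to ``final_lr``.
    """
    if not 0 <= tokens_seen <= tokens_total:
        raise ValueError("tokens_seen must lie in [0, tokens_total]")
    warm = schedule.warmup_token_fraction * tokens_total
    if warm > 0 and tokens_seen < warm:
        return schedule.peak_lr * tokens_seen / warm
    span = tokens_total - warm
    phase = 0.0 if span == 0 else (tokens_seen - warm) / span
    return schedule.final_lr + 0.5 * (schedule.peak_lr - schedule.final_lr) * (
        1.0 + np.cos(np.pi * phase)
    )


def _train(
    model: LanguageModel,
    sequences: np.ndarray,
    schedule: TrainSchedule,
    seed: int,
    validation: np.ndarray | None = None,
) -> list[dict]:
    """Shared training loop; returns one trace row per epoch."""
    net = model.net
    pad = model.vocabulary.pad_index
    rng = np.random.default_rng(seed)
    n, T = sequences.shape
    opt = AdamW(
        net.params, betas=schedule.optimizer_betas, weight_decay=schedule.l2_lambda
    )
    # effective length = start + tokens + end (pads only trail); batches are
    # length-bucketed and trimmed to their longest member to skip pad compute
    eff_len = (sequences != pad).sum(axis=1)
    tokens_total = schedule.epochs * int((eff_len - 1).sum())
    tokens_seen = 0
    trace: list[dict] = []
    for epoch in range(schedule.epochs):
        perm = rng.permutation(n)
        order = perm[np.argsort(eff_len[perm], kind="stable")]
        starts = list(range(0, n, schedule.batch_size))
        rng.shuffle(starts)
        losses = []
        for start in starts:
            rows = order[start : start + schedule.batch_size]
            t_max = int(eff_len[rows].max())
            batch = sequences[rows][:, :t_max]
            idx, targets = batch[:, :-1], batch[:, 1:]
            loss, grads = net.forward_backward(idx, targets, pad, rng=rng)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"training diverged (non-finite loss) at epoch {epoch}"
                )
            tokens_seen += int((eff_len[rows] - 1).sum())
            lr = lr_at_step(schedule, tokens_seen, tokens_total)
            opt.step(net.params, grads, lr, clip_norm=schedule.grad_clip_norm)
            losses.append(loss)
        row = {"epoch": epoch, "train_loss": float(np.mean(losses)), "lr": float(lr)}
        if validation is not None:
            row["val_loss"] = net.loss(validation[:, :-1], validation[:, 1:], pad)
        trace.append(row)
    return trace


def pretrain(
    model: LanguageModel,
    corpus: EncodedCorpus,
    schedule: TrainSchedule,
    seed: int,
    validation: EncodedCorpus | None = None,
) -> tuple[LanguageModel, list[dict]]:
    """Train in place on the encoded corpus; returns per-epoch loss trace."""
    if len(corpus) == 0:
        raise ValueError("empty corpus")
    val = validation.sequences if validation is not None else None
    trace = _train(model, corpus.sequences, schedule, seed, validation=val)
    return model, trace


def fine_tune(
    model: LanguageModel,
    smiles: list[str],
    schedule: TrainSchedule | None = None,
    seed: int = 0,
) -> tuple[LanguageModel, list[dict]]:
    """Continue training on an AL training set (replicas are distinct examples).

    Molecules with out-of-vocabulary tokens or exceeding the context length
    are dropped with a warning.
    """
    if not smiles:
        raise ValueError("empty fine-tuning set")
    schedule = schedule or TrainSchedule.finetune_default()
    vocab = model.vocabulary
    rows, dropped = [], 0
    for s in smiles:
        try:
            rows.append(encode(s, vocab, model.max_smiles_tokens))
        except (ValueError, KeyError):
            dropped += 1
    if dropped:
        warnings.warn(f"dropped {dropped} molecules not encodable under the vocabulary")
    if not rows:
        raise ValueError("no fine-tuning molecules are encodable")
    trace = _train(model, np.stack(rows), schedule, seed)
    return model, trace


@dataclass
class GenerationResult:
    """Unique canonical molecules plus bookkeeping about the attempts."""

    molecules: list[str]
    n_requested: int
    n_sampled: int
    n_invalid: int
    n_duplicate: int

    @property
    def shortfall(self) -> int:
        return self.n_requested - len(self.molecules)


def _sample_batch(model: LanguageModel, batch: int, temperature: float, rng) -> list[str]:
    """Sample ``batch`` raw strings autoregressively with a KV cache.

    Finished sequences are periodically compacted out of the batch so late
    steps only pay for still-active sequences.
    """
    net, vocab = model.net, model.vocabulary
    T = model.context_length
    end = vocab.end_index
    cache = net.init_cache(batch)
    tokens = np.full(batch, vocab.start_index, dtype=np.int64)
    seqs: list[list[int]] = [[] for _ in range(batch)]
    active = np.arange(batch)
    for _ in range(T - 1):
        logits = net.step(tokens, cache)
        if temperature <= 0:
            nxt = logits.argmax(-1)
        else:
            probs = _softmax(logits / temperature)
            u = rng.random((len(active), 1))
            nxt = (probs.cumsum(-1) > u).argmax(-1)
        for row, tok in zip(active, nxt):
            seqs[row].append(int(tok))
        alive = nxt != end
        n_alive = int(alive.sum())
        if n_alive == 0:
            break
        if n_alive <= 0.75 * len(active):
            keep = np.flatnonzero(alive)
            active = active[keep]
            tokens = nxt[keep]
            for i in range(net.config.n_blocks):
                cache["k"][i] = cache["k"][i][keep]
                cache["v"][i] = cache["v"][i][keep]
        else:
            tokens = np.where(alive, nxt, end)
    out = []
    for seq in seqs:
        if end in seq:
            seq = seq[: seq.index(end)]
        out.append("".join(vocab.tokens[t] for t in seq if t != vocab.pad_index))
    return out


def generate_unique(
    model: LanguageModel,
    n: int,
    temperature: float = 1.0,
    max_attempts: int | None = None,
    seed: int = 0,
    batch_size: int = 1024,
) -> GenerationResult:
    """Sample until ``n`` unique valid molecules (by canonical SMILES) are found.

    Invalid strings and canonical duplicates are discarded. Sampling stops
    with a warning once ``max_attempts`` raw samples (default ``20 * n``)
    have been drawn.
    """
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return GenerationResult([], 0, 0, 0, 0)
    max_attempts = max_attempts if max_attempts is not None else 20 * n
    rng = np.random.default_rng(seed)
    unique: list[str] = []
    seen: set[str] = set()
    n_sampled = n_invalid = n_duplicate = 0
    while len(unique) < n and n_sampled < max_attempts:
        batch = min(batch_size, max_attempts - n_sampled)
        for raw in _sample_batch(model, batch, temperature, rng):
            n_sampled += 1
            canon = canonicalize(raw)
            if canon is None or canon == "":
                n_invalid += 1
            elif canon in seen:
                n_duplicate += 1
            else:
                seen.add(canon)
                unique.append(canon)
                if len(unique) == n:
                    break
    if len(unique) < n:
        warnings.warn(
            f"generation shortfall: {len(unique)}/{n} unique molecules after "
            f"{n_sampled} attempts"
        )
    return GenerationResult(unique, n, n_sampled, n_invalid, n_duplicate)


def sequence_log_likelihood(model: LanguageModel, smiles: str) -> float:
    """Log-likelihood of the encoded sequence (through the end token)."""
    seq = encode(smiles, model.vocabulary, model.max_smiles_tokens)[None, :]
    idx, targets = seq[:, :-1], seq[:, 1:]
    logits = model.net.logits(idx)
    probs = _softmax(logits)
    tgt = np.take_along_axis(probs, targets[..., None], axis=-1)[..., 0]
    valid = targets != model.vocabulary.pad_index
    return float((np.log(tgt + 1e-12) * valid).sum())


def save_checkpoint(model: LanguageModel, path) -> None:
    """Persist parameters + config + vocabulary to an .npz file."""
    import json

    meta = {
        "config": model.config.__dict__,
        "tokens": list(model.vocabulary.tokens),
        "min_count": model.vocabulary.min_count,
    }
    np.savez(path, __meta__=json.dumps(meta), **model.net.params)


def load_checkpoint(path) -> LanguageModel:
    import json

    data = np.load(path, allow_pickle=False)
    meta = json.loads(str(data["__meta__"]))
    vocab = TokenVocabulary(tuple(meta["tokens"]), min_count=meta["min_count"])
    config = GeneratorConfig(**meta["config"])
    model = build_model(config, vocab, seed=0)
    for k in model.net.params:
        model.net.params[k] = data[k]
    return model
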