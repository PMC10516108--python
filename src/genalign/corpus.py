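"""SMILES corpus preprocessing: canonicalization, vocabulary pruning, encoding.

The preprocessing pipeline mirrors how large SMILES corpora are prepared for
autoregressive language modelling:

1. parse every string with RDKit, drop invalid entries, deduplicate by
   canonical form;
2. tokenize with the standard SMILES regex grammar and remove every string
   containing a token rarer than ``min_count`` in the corpus;
3. impose a token-length cutoff at a coverage quantile (e.g. the smallest
   length covering 99.99% of strings);
4. encode each string as ``! tokens ~ < < ...`` (start / end / pad specials)
   to a uniform length of ``max_len + 2``.
"""

from __future__ import annotations

import gzip
import json
import re
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from rdkit import Chem
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")

START_TOKEN = "!"
END_TOKEN = "~"
PAD_TOKEN = "<"

# Standard SMILES token grammar: bracket atoms, two-letter elements,
# aromatic atoms, bonds/branches/ring closures (incl. %nn).
_SMILES_TOKEN_RE = re.compile(
    r"(\[[^\]]+\]|Br|Cl|Si|Se|se|as|@@|%\d{2}"
    r"|[BCNOSPFIbcnosp*]|[-=#$:/\\().+@]|\d)"
)


class TokenizationError(ValueError):
    """Raised when a SMILES string contains a character outside the grammar."""


@dataclass(frozen=True)
class TokenVocabulary:
    """Ordered token <-> index map with start/end/pad specials.

    Specials occupy the first three indices (pad=0, start=1, end=2) so that
    zero-padding arrays is equivalent to pad-token filling.
    """

    tokens: tuple[str, ...]
    min_count: int = 1
    counts: dict[str, int] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.tokens)) != len(self.tokens):
            raise ValueError("vocabulary tokens must be unique")
        for special in (PAD_TOKEN, START_TOKEN, END_TOKEN):
            if special not in self.tokens:
                raise ValueError(f"special token {special!r} missing from vocabulary")

    @classmethod
    def from_corpus(
        cls, corpus: Iterable[str], min_count: int = 1, counts: dict[str, int] | None = None
    ) -> "TokenVocabulary":
        chem_tokens = sorted({t for s in corpus for t in tokenize(s)})
        return cls(
            tokens=(PAD_TOKEN, START_TOKEN, END_TOKEN, *chem_tokens),
            min_count=min_count,
            counts=dict(counts or {}),
        )

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def index(self) -> dict[str, int]:
        return {t: i for i, t in enumerate(self.tokens)}

    @property
    def pad_index(self) -> int:
        return self.tokens.index(PAD_TOKEN)

    @property
    def start_index(self) -> int:
        return self.tokens.index(START_TOKEN)

    @property
    def end_index(self) -> int:
        return self.tokens.index(END_TOKEN)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "tokens": list(self.tokens),
            "specials": {"start": START_TOKEN, "end": END_TOKEN, "pad": PAD_TOKEN},
            "min_count": self.min_count,
            "counts": self.counts,
        }
        Path(path).write_text(json.dumps(payload, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "TokenVocabulary":
        payload = json.loads(Path(path).read_text())
        return cls(
            tokens=tuple(payload["tokens"]),
            min_count=payload.get("min_count", 1),
            counts=payload.get("counts", {}),
        )


@dataclass
class EncodedCorpus:
    """Uniform-length integer sequences plus the vocabulary that produced them."""

    sequences: np.ndarray  # (n, max_len + 2) int32
    max_len: int
    vocabulary: TokenVocabulary

    def __len__(self) -> int:
        return len(self.sequences)


def canonicalize(smiles: str) -> str | None:
    """Canonical SMILES via RDKit, or None if the string does not parse."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        return None
    return Chem.MolToSmiles(mol)


def canonicalize_filter(entries: Sequence[str]) -> tuple[list[str], dict[str, int]]:
    """Drop invalid SMILES, canonicalize and deduplicate.

    Returns the sorted list of unique canonical forms (sorting makes the
    result independent of input order) and a report with entry counts.
    """
    seen: set[str] = set()
    n_invalid = 0
    for s in entries:
        canon = canonicalize(s)
        if canon is None:
            n_invalid += 1
        else:
            seen.add(canon)
    report = {
        "n_input": len(entries),
        "n_invalid": n_invalid,
        "n_unique_valid": len(seen),
    }
    return sorted(seen), report


def tokenize(smiles: str) -> list[str]:
    """Split a SMILES string into grammar tokens.

    Concatenating the returned tokens reproduces the input exactly;
    a character outside the grammar raises :class:`TokenizationError`
    naming its offset.
    """
    tokens: list[str] = []
    pos = 0
    while pos < len(smiles):
        m = _SMILES_TOKEN_RE.match(smiles, pos)
        if m is None:
            raise TokenizationError(
                f"unknown SMILES character {smiles[pos]!r} at offset {pos} in {smiles!r}"
            )
        tokens.append(m.group(0))
        pos = m.end()
    return tokens


def count_tokens(corpus: Iterable[str]) -> Counter:
    counts: Counter = Counter()
    for s in corpus:
        counts.update(tokenize(s))
    return counts


def prune_rare_tokens(
    corpus: Sequence[str], min_count: int
) -> tuple[list[str], TokenVocabulary, dict[str, int]]:
    """Remove strings containing any token rarer than ``min_count``.

    Occurrence counts are taken once over the *input* corpus and are not
    recomputed after removal. The returned vocabulary is built from the
    retained strings plus the three specials.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    counts = count_tokens(corpus)
    rare = {t for t, c in counts.items() if c < min_count}
    retained = [s for s in corpus if not (rare & set(tokenize(s)))]
    vocab = TokenVocabulary.from_corpus(retained, min_count=min_count, counts=dict(counts))
    report = {
        "n_input": len(corpus),
        "n_removed": len(corpus) - len(retained),
        "n_retained": len(retained),
        "n_rare_tokens": len(rare),
        "rare_tokens": sorted(rare),
    }
    return retained, vocab, report


def length_cutoff(corpus: Sequence[str], coverage: float) -> tuple[int, list[str]]:
    """Smallest token-length L covering >= ``coverage`` of the corpus.

    Strings longer than L (in tokens) are removed.
    """
    if not 0 < coverage <= 1:
        raise ValueError("coverage must be in (0, 1]")
    if not corpus:
        raise ValueError("empty corpus")
    lengths = np.array([len(tokenize(s)) for s in corpus])
    for cand in np.sort(np.unique(lengths)):
        if np.mean(lengths <= cand) >= coverage:
            cutoff = int(cand)
            break
    filtered = [s for s, n in zip(corpus, lengths) if n <= cutoff]
    return cutoff, filtered


def encode(smiles: str, vocabulary: TokenVocabulary, max_len: int) -> np.ndarray:
    """Encode as start + tokens + end + pads, total length ``max_len + 2``."""
    tokens = tokenize(smiles)
    if len(tokens) > max_len:
        raise ValueError(f"SMILES has {len(tokens)} tokens, exceeds max_len={max_len}")
    index = vocabulary.index
    try:
        body = [index[t] for t in tokens]
    except KeyError as exc:
        raise ValueError(f"token {exc.args[0]!r} not in vocabulary") from None
    seq = (
        [vocabulary.start_index]
        + body
        + [vocabulary.end_index]
        + [vocabulary.pad_index] * (max_len - len(tokens))
    )
    return np.asarray(seq, dtype=np.int32)


def decode(sequence: Sequence[int], vocabulary: TokenVocabulary) -> str:
    """Invert :func:`encode`; stops at the end token."""
    out: list[str] = []
    for idx in sequence:
        token = vocabulary.tokens[int(idx)]
        if token == START_TOKEN:
            continue
        if token == END_TOKEN:
            break
        if token == PAD_TOKEN:
            continue
        out.append(token)
    return "".join(out)


def encode_corpus(
    corpus: Sequence[str], vocabulary: TokenVocabulary, max_len: int
) -> EncodedCorpus:
    seqs = np.stack([encode(s, vocabulary, max_len) for s in corpus])
    return EncodedCorpus(sequences=seqs, max_len=max_len, vocabulary=vocabulary)


def split(
    corpus: Sequence[str], train_fraction: float, seed: int
) -> tuple[list[str], list[str]]:
    """Random disjoint train/validation split; train size = floor(fraction * n)."""
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must be in (0, 1)")
    n = len(corpus)
    if n < 2:
        raise ValueError("need at least 2 entries to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(train_fraction * n))
    train = [corpus[i] for i in sorted(order[:n_train])]
    val = [corpus[i] for i in sorted(order[n_train:])]
    return train, val


def read_smiles(path: str | Path, column: str = "smiles") -> list[str]:
    """Read SMILES from plain text (one per line) or CSV with a smiles column.

    Gzipped files (``.gz``) are handled transparently.
    """
    path = Path(path)
    opener = gzip.open if path.suffix == ".gz" else open
    stem = path.name[:-3] if path.suffix == ".gz" else path.name
    if stem.endswith(".csv"):
        import pandas as pd

        df = pd.read_csv(path)
        if column not in df.columns:
            raise ValueError(f"CSV file {path} has no {column!r} column")
        return df[column].astype(str).tolist()
    with opener(path, "rt") as fh:
        return [line.strip() for line in fh if line.strip()]


def write_smiles(smiles: Iterable[str], path: str | Path) -> None:
    Path(path).write_text("\n".join(smiles) + "\n")


@dataclass
class PreprocessResult:
    """Full pipeline output: corpus, vocabulary, encoding and per-stage report."""

    corpus: list[str]
    vocabulary: TokenVocabulary
    encoded: EncodedCorpus
    train: EncodedCorpus
    validation: EncodedCorpus
    report: dict


def preprocess(
    entries: Sequence[str],
    min_count: int = 1000,
    coverage: float = 0.9999,
    train_fraction: float = 0.95,
    seed: int = 0,
) -> PreprocessResult:
    """Run the full preprocessing pipeline with the standard defaults."""
    canon, canon_report = canonicalize_filter(entries)
    pruned, vocab, prune_report = prune_rare_tokens(canon, min_count)
    if not pruned:
        raise ValueError("no strings survive token pruning")
    cutoff, filtered = length_cutoff(pruned, coverage)
    vocab = TokenVocabulary.from_corpus(filtered, min_count=min_count, counts=vocab.counts)
    encoded = encode_corpus(filtered, vocab, cutoff)
    train_s, val_s = split(filtered, train_fraction, seed)
    report = {
        "canonicalize": canon_report,
        "prune": prune_report,
        "length_cutoff": cutoff,
        "n_after_cutoff": len(filtered),
        "n_train": len(train_s),
        "n_validation": len(val_s),
        "vocabulary_size": len(vocab),
        "rdkit_version": Chem.rdBase.rdkitVersion,
    }
    return PreprocessResult(
        corpus=filtered,
        vocabulary=vocab,
        encoded=encoded,
        train=encode_corpus(train_s, vocab, cutoff),
        validation=encode_corpus(val_s, vocab, cutoff),
        report=report,
    )
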