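"""Iteration-level evaluation of a generated ensemble.

Score statistics (fraction at or above the threshold — the comparison is
inclusive — mean and max) are computed on the scored subset, as in the
source methodology's per-iteration tables. Similarity profiles compare the
generated ensemble against reference ligands with Tanimoto coefficients over
either circular (ECFP4-equivalent, Morgan radius 2) or path-based RDKit
fingerprints.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from rdkit import Chem, DataStructs
from rdkit.Chem import rdFingerprintGenerator

from .corpus import canonicalize


def threshold_fraction(scores: Sequence[float], threshold: float) -> float:
    """Percentage of scores >= threshold (inclusive)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    return float(100.0 * np.mean(scores >= threshold))


def score_summary(scores: Sequence[float]) -> tuple[float, float]:
    """(mean, max) of the scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise ValueError("empty score list")
    return float(scores.mean()), float(scores.max())


_FP_GENERATORS = {
    "circular": lambda: rdFingerprintGenerator.GetMorganGenerator(radius=2, fpSize=2048),
    "path": lambda: rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=2048),
}


@dataclass
class SimilarityEntry:
    reference: str
    mean_tanimoto: float
    most_similar: str
    max_tanimoto: float


def similarity_profile(
    generated: Sequence[str],
    references: Sequence[str],
    fingerprint_kind: str = "circular",
) -> list[SimilarityEntry]:
    """Per-reference mean Tanimoto over the generated set, plus the nearest hit.

    ``fingerprint_kind`` is "circular" (Morgan radius 2, ECFP4-equivalent) or
    "path" (RDKit path-based). Unfingerprintable molecules are skipped with a
    warning.
    """
    if fingerprint_kind not in _FP_GENERATORS:
        raise ValueError(f"fingerprint_kind must be one of {sorted(_FP_GENERATORS)}")
    gen = _FP_GENERATORS[fingerprint_kind]()

    def fps(smiles_list):
        out, kept = [], []
        for s in smiles_list:
            mol = Chem.MolFromSmiles(s)
            if mol is None:
                continue
            out.append(gen.GetFingerprint(mol))
            kept.append(s)
        if len(kept) < len(smiles_list):
            warnings.warn(
                f"skipped {len(smiles_list) - len(kept)} unfingerprintable molecules"
            )
        return out, kept

    gen_fps, gen_smiles = fps(generated)
    if not gen_fps:
        raise ValueError("no fingerprintable generated molecules")
    entries = []
    for ref in references:
        mol = Chem.MolFromSmiles(ref)
        if mol is None:
            warnings.warn(f"skipped unfingerprintable reference {ref!r}")
            continue
        ref_fp = gen.GetFingerprint(mol)
        sims = np.array(DataStructs.BulkTanimotoSimilarity(ref_fp, gen_fps))
        best = int(sims.argmax())
        entries.append(
            SimilarityEntry(
                reference=ref,
                mean_tanimoto=float(sims.mean()),
                most_similar=gen_smiles[best],
                max_tanimoto=float(sims[best]),
            )
        )
    return entries


def exact_recovery(generated: Sequence[str], references: Sequence[str]) -> set[str]:
    """References recovered exactly (intersection by canonical SMILES).

    Returned entries are the references' canonical forms.
    """
    gen_canon = {canonicalize(s) for s in generated} - {None}
    out = set()
    for ref in references:
        canon = canonicalize(ref)
        if canon is not None and canon in gen_canon:
            out.add(canon)
    return out


@dataclass
class IterationMetrics:
    """One row of the per-iteration metrics table (iteration 0 = pretraining)."""

    iteration: int
    fraction_above_threshold: float
    mean_score: float
    max_score: float
    n_scored: int
    n_generated: int
    reference_similarity: dict[str, float] = field(default_factory=dict)
    recovered_references: list[str] = field(default_factory=list)

    def to_row(self) -> dict:
        row = {
            "iteration": self.iteration,
            "fraction_above_threshold": self.fraction_above_threshold,
            "mean_score": self.mean_score,
            "max_score": self.max_score,
            "n_scored": self.n_scored,
            "n_generated": self.n_generated,
        }
        for ref, sim in self.reference_similarity.items():
            row[f"tanimoto_{ref}"] = sim
        return row


def iteration_metrics(
    iteration: int,
    scores: Sequence[float],
    threshold: float,
    n_generated: int,
    generated: Sequence[str] | None = None,
    references: Sequence[str] | None = None,
    fingerprint_kind: str = "circular",
) -> IterationMetrics:
    mean, mx = score_summary(scores)
    sims: dict[str, float] = {}
    recovered: list[str] = []
    if references and generated:
        sims = {
            e.reference: e.mean_tanimoto
            for e in similarity_profile(generated, references, fingerprint_kind)
        }
        recovered = sorted(exact_recovery(generated, references))
    return IterationMetrics(
        iteration=iteration,
        fraction_above_threshold=threshold_fraction(scores, threshold),
        mean_score=mean,
        max_score=mx,
        n_scored=len(scores),
        n_generated=n_generated,
        reference_similarity=sims,
        recovered_references=recovered,
    )
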