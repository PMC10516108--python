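"""Synthetic fixtures: toy corpora, a surrogate scorer, planted complexes.

Everything the pipeline consumes can be generated here without downloads:

* :func:`make_corpus` enumerates a combinatorial family of small valid
  molecules (scaffold x substituents), spanning a range of token lengths;
* :class:`SurrogateScorer` is a stand-in for docking+scoring whose value
  decays smoothly with distance from a target point in the projected
  descriptor space — by construction it satisfies the two requirements a
  chemical-space proxy places on a scoring function (position correlates
  with score; nearby molecules score similarly);
* :func:`make_complex` emits toy 3D protein-ligand structures in which each
  requested interaction type is planted exactly the requested number of
  times, with every other atom pair outside all detection cutoffs.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from rdkit import Chem

from .chemspace import DescriptorProvider, ProjectionModel, compute_descriptors, project
from .scoring import (
    INTERACTION_TYPES,
    ComplexStructure,
    InteractionProfile,
    PoseProvider,
    score_profile,
)

# --------------------------------------------------------------------------- #
# toy corpus
# --------------------------------------------------------------------------- #

_TEMPLATES = (
    "{a}c1ccc({b})cc1",
    "{a}c1ccc({b})nc1",
    "{a}C1CCC({b})CC1",
    "{a}CC({b})C",
    "{a}CCN(C)CC{b}",
    "{a}CCOC(=O){b}",
    "{a}C(=O)N{b}",
    "{a}c1ccc2ccccc2c1",
)
_SUB_A = ("C", "CC", "CCC", "CCCC", "O", "N", "Cl", "F", "Br", "OC", "NC", "N#C")
_SUB_B = ("C", "CC", "O", "N", "Cl", "F", "OC", "C(F)(F)F", "C#N", "C(=O)O", "OCC")
_EXTRAS = tuple(
    ["C" * k for k in range(1, 26)]
    + ["O" + "C" * k for k in range(2, 12)]
    + ["c1ccccc1", "c1ccncc1", "C1CCCCC1", "C1CCOC1", "c1ccc2[nH]ccc2c1"]
)


def _enumerate_space() -> list[str]:
    """Deterministic enumeration of the valid, canonically-unique space."""
    seen: set[str] = set()
    out: list[str] = []
    candidates = list(_EXTRAS)
    for tpl in _TEMPLATES:
        for a in _SUB_A:
            if "{b}" in tpl:
                for b in _SUB_B:
                    candidates.append(tpl.format(a=a, b=b))
            else:
                candidates.append(tpl.format(a=a))
    for s in candidates:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            continue
        canon = Chem.MolToSmiles(mol)
        if canon not in seen:
            seen.add(canon)
            out.append(s)
    return out


def make_corpus(n: int, seed: int = 0) -> list[str]:
    """``n`` unique valid SMILES drawn from the combinatorial toy space."""
    if n < 1:
        raise ValueError("n must be >= 1")
    space = _enumerate_space()
    if n > len(space):
        raise ValueError(
            f"requested {n} molecules but the toy space contains only {len(space)}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(space))
    return [space[i] for i in order[:n]]


# --------------------------------------------------------------------------- #
# surrogate scorer
# --------------------------------------------------------------------------- #


@dataclass
class SurrogateScorer:
    """Gaussian bump in projected descriptor space standing in for docking.

    ``score(x) = max_score * exp(-||x - target||^2 / (2 scale^2)) + noise``.
    Noise is deterministic per molecule (hash of the SMILES mixed with the
    seed), so the scorer is order-independent and reproducible.
    """

    target: np.ndarray
    scale: float
    max_score: float
    noise_amplitude: float = 0.0
    seed: int = 0

    def score_coords(self, coords: np.ndarray) -> np.ndarray:
        coords = np.atleast_2d(coords)
        d2 = ((coords - self.target) ** 2).sum(axis=1)
        return self.max_score * np.exp(-d2 / (2.0 * self.scale**2))

    def _noise(self, smiles: str) -> float:
        if self.noise_amplitude == 0:
            return 0.0
        h = zlib.crc32(smiles.encode()) ^ (self.seed & 0x7FFFFFFF)
        rng = np.random.default_rng(h)
        return float(rng.normal(0.0, self.noise_amplitude))

    @classmethod
    def from_reference(
        cls,
        reference_coords: np.ndarray,
        threshold: float,
        fraction: float = 0.25,
        noise_amplitude: float = 0.0,
        seed: int = 0,
    ) -> "SurrogateScorer":
        """Calibrate the stated starting world on a reference corpus.

        The target is the projected point of the molecule furthest along the
        first component (an off-center but populated region, so a score
        gradient crosses the cloud); the length scale is half the RMS
        distance of the corpus from the target; ``max_score`` is set so that
        exactly ``fraction`` of the reference corpus scores at or above
        ``threshold`` before noise.
        """
        coords = np.atleast_2d(reference_coords)
        target = coords[int(np.argmax(coords[:, 0]))].copy()
        d = np.sqrt(((coords - target) ** 2).sum(axis=1))
        scale = float(np.sqrt(np.mean(d**2)) / 2.0)
        dq = float(np.quantile(d, fraction))
        max_score = threshold / float(np.exp(-(dq**2) / (2.0 * scale**2)))
        return cls(
            target=target,
            scale=scale,
            max_score=max_score,
            noise_amplitude=noise_amplitude,
            seed=seed,
        )


def pseudo_profile(score: float) -> InteractionProfile:
    """Back-fill a profile reproducing ``score`` at integer granularity.

    Van der Waals contacts carry weight 1.0, so a count of round(score)
    reproduces the score exactly up to rounding.
    """
    return InteractionProfile(van_der_waals=max(0, round(score)))


def surrogate_score(
    smiles: str,
    scorer: SurrogateScorer,
    projection_model: ProjectionModel,
    descriptor_provider: DescriptorProvider | None = None,
) -> tuple[float, InteractionProfile]:
    """Continuous surrogate score and its back-filled pseudo-profile."""
    matrix = compute_descriptors([smiles], provider=descriptor_provider)
    coords = project(projection_model, matrix)
    score = float(scorer.score_coords(coords)[0]) + scorer._noise(smiles)
    return score, pseudo_profile(score)


def surrogate_pose_provider(
    scorer: SurrogateScorer,
    projection_model: ProjectionModel,
    descriptor_provider: DescriptorProvider | None = None,
    precomputed_coords: Mapping[str, np.ndarray] | None = None,
) -> PoseProvider:
    """Pose-provider adapter around the surrogate scorer.

    ``precomputed_coords`` (SMILES -> projected coordinate) avoids
    recomputing descriptors when the caller already projected the ensemble.
    """

    def provider(smiles: str) -> InteractionProfile:
        if precomputed_coords is not None and smiles in precomputed_coords:
            score = float(scorer.score_coords(precomputed_coords[smiles])[0])
            score += scorer._noise(smiles)
            return pseudo_profile(score)
        return surrogate_score(smiles, scorer, projection_model, descriptor_provider)[1]

    return provider


# --------------------------------------------------------------------------- #
# planted complexes
# --------------------------------------------------------------------------- #


def _ring(center: np.ndarray, radius: float = 1.39, plane: str = "xy") -> np.ndarray:
    ang = np.linspace(0, 2 * np.pi, 6, endpoint=False)
    flat = np.stack([radius * np.cos(ang), radius * np.sin(ang), np.zeros(6)], axis=1)
    if plane == "xz":
        flat = flat[:, [0, 2, 1]]
    return flat + center


def _unit_builders():
    """Per-type builders: atoms = (element, offset, charge, is_ligand); rings by local index."""
    z = np.zeros(3)

    def simple(e1, e2, d, q1=0, q2=0):
        return (
            [(e1, z, q1, False), (e2, np.array([d, 0.0, 0.0]), q2, True)],
            [],
        )

    def cation_pi():
        atoms = [("C", p, 0, False) for p in _ring(z)]
        atoms.append(("N", np.array([0.0, 0.0, 4.0]), 1, True))
        return atoms, [tuple(range(6))]

    def halogen():
        atoms = [
            ("C", z, 0, True),
            ("Cl", np.array([1.77, 0.0, 0.0]), 0, True),
            ("O", np.array([4.97, 0.0, 0.0]), 0, False),
        ]
        return atoms, []

    def stack_face():
        atoms = [("C", p, 0, False) for p in _ring(z)]
        atoms += [("C", p, 0, True) for p in _ring(np.array([0.0, 0.0, 3.8]))]
        return atoms, [tuple(range(6)), tuple(range(6, 12))]

    def stack_edge():
        atoms = [("C", p, 0, False) for p in _ring(z)]
        atoms += [("C", p, 0, True) for p in _ring(np.array([0.0, 0.0, 5.0]), plane="xz")]
        return atoms, [tuple(range(6)), tuple(range(6, 12))]

    return {
        "hydrophobic": lambda: simple("C", "C", 4.0),
        "hydrogen_bond": lambda: simple("O", "N", 3.2),
        "ionic": lambda: simple("O", "N", 4.2, q1=-1, q2=+1),
        "cation_pi": cation_pi,
        "van_der_waals": lambda: simple("C", "O", 3.5),
        "halogen_bond": halogen,
        "pi_stack_face": stack_face,
        "pi_stack_edge": stack_edge,
        "metallic": lambda: simple("Zn", "O", 2.4),
    }


def make_complex(planted: Mapping[str, int], seed: int = 0) -> ComplexStructure:
    """Toy complex in which each interaction type occurs exactly as planted.

    Interaction units are placed on a 40-angstrom grid so no cross-unit atom
    pair comes near any detection cutoff. Unknown type names or negative
    counts raise ValueError.
    """
    unknown = set(planted) - set(INTERACTION_TYPES)
    if unknown:
        raise ValueError(f"unknown interaction types: {sorted(unknown)}")
    if any(v < 0 for v in planted.values()):
        raise ValueError("planted counts must be >= 0")
    builders = _unit_builders()
    elements, coords, charges, is_ligand, rings = [], [], [], [], []
    cell = 0
    for itype in INTERACTION_TYPES:
        for _ in range(int(planted.get(itype, 0))):
            offset = np.array([40.0 * (cell % 10), 40.0 * (cell // 10), 0.0])
            cell += 1
            atoms, local_rings = builders[itype]()
            base = len(elements)
            for el, pos, q, lig in atoms:
                elements.append(el)
                coords.append(np.asarray(pos, float) + offset)
                charges.append(q)
                is_ligand.append(lig)
            for ring in local_rings:
                rings.append(tuple(base + i for i in ring))
    if not elements:
        # detector requires both partitions; plant two inert far-apart atoms
        elements = ["C", "C"]
        coords = [np.zeros(3), np.array([30.0, 0.0, 0.0])]
        charges = [0, 0]
        is_ligand = [False, True]
    return ComplexStructure(
        elements=elements,
        coords=np.asarray(coords),
        formal_charges=charges,
        is_ligand=np.asarray(is_ligand, dtype=bool),
        rings=rings,
    )
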