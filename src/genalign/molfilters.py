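"""Configurable drug-likeness and functional-group filtering.

A :class:`FilterSet` is an ordered list of named rules, each either a
property bound (RDKit-computed physicochemical property within [min, max])
or a SMARTS substructure allow/deny pattern. A molecule is retained iff it
passes every rule; a rejection is attributed to the first failing rule.
The shipped defaults are Lipinski-style bounds plus a short deny-list of
reactive groups — a configurable stand-in, not a validated ADMET panel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

_PROPERTY_FNS = {
    "mol_weight": Descriptors.MolWt,
    "logp": Crippen.MolLogP,
    "tpsa": rdMolDescriptors.CalcTPSA,
    "hbd": Lipinski.NumHDonors,
    "hba": Lipinski.NumHAcceptors,
    "rotatable_bonds": Lipinski.NumRotatableBonds,
    "ring_count": rdMolDescriptors.CalcNumRings,
    "heavy_atoms": lambda m: m.GetNumHeavyAtoms(),
}


@dataclass
class PropertyRule:
    name: str
    prop: str
    min: float = float("-inf")
    max: float = float("inf")

    def __post_init__(self) -> None:
        if self.prop not in _PROPERTY_FNS:
            raise ValueError(
                f"unknown property {self.prop!r}; known: {sorted(_PROPERTY_FNS)}"
            )
        if self.min > self.max:
            raise ValueError(f"rule {self.name}: min > max")

    def passes(self, mol: Chem.Mol) -> bool:
        value = _PROPERTY_FNS[self.prop](mol)
        return self.min <= value <= self.max


@dataclass
class SmartsRule:
    name: str
    smarts: str
    deny: bool = True  # deny: reject on match; allow: reject on no-match
    _pattern: Chem.Mol = field(init=False, repr=False)

    def __post_init__(self) -> None:
        pattern = Chem.MolFromSmarts(self.smarts)
        if pattern is None:
            raise ValueError(f"rule {self.name}: malformed SMARTS {self.smarts!r}")
        self._pattern = pattern

    def passes(self, mol: Chem.Mol) -> bool:
        match = mol.HasSubstructMatch(self._pattern)
        return not match if self.deny else match


@dataclass
class FilterSet:
    """Ordered named rules; rule names must be unique."""

    rules: list  # PropertyRule | SmartsRule

    def __post_init__(self) -> None:
        names = [r.name for r in self.rules]
        if len(set(names)) != len(names):
            raise ValueError("rule names must be unique")

    @classmethod
    def default(cls) -> "FilterSet":
        """Lipinski-style bounds plus a curated deny-list of reactive groups."""
        return cls(
            rules=[
                PropertyRule("mol_weight", "mol_weight", 100, 600),
                PropertyRule("logp", "logp", -2, 6),
                PropertyRule("hbd", "hbd", 0, 5),
                PropertyRule("hba", "hba", 0, 10),
                PropertyRule("tpsa", "tpsa", 0, 160),
                PropertyRule("rotatable_bonds", "rotatable_bonds", 0, 10),
                SmartsRule("no_nitro", "[N+](=O)[O-]"),
                SmartsRule("no_acyl_halide", "[CX3](=O)[F,Cl,Br,I]"),
                SmartsRule("no_peroxide", "[OX2][OX2]"),
                SmartsRule("no_azide", "[N-]=[N+]=[N-]"),
                SmartsRule("no_aldehyde", "[CX3H1](=O)[#6]"),
            ]
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FilterSet":
        """Load rules from a YAML list of {name, kind, ...} mappings."""
        spec = yaml.safe_load(Path(path).read_text())
        rules = []
        for entry in spec:
            kind = entry.pop("kind")
            if kind == "property":
                rules.append(PropertyRule(**entry))
            elif kind == "smarts":
                rules.append(SmartsRule(**entry))
            else:
                raise ValueError(f"unknown rule kind {kind!r}")
        return cls(rules=rules)


def apply_filters(
    molecules: Sequence[str], filterset: FilterSet
) -> tuple[list[str], dict[str, int]]:
    """Retain molecules passing every rule; count rejections per first-failing rule.

    Input order is preserved; unparsable strings are counted under "_unparsable".
    """
    rejections = {r.name: 0 for r in filterset.rules}
    rejections["_unparsable"] = 0
    retained = []
    for s in molecules:
        mol = Chem.MolFromSmiles(s)
        if mol is None:
            rejections["_unparsable"] += 1
            continue
        for rule in filterset.rules:
            if not rule.passes(mol):
                rejections[rule.name] += 1
                break
        else:
            retained.append(s)
    return retained, rejections
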