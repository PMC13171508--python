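"""Desirability-based multiparameter optimization and R-group enumeration.

Each of five properties (MW, ALogP, PSA, HBA, HBD) is mapped onto [0, 1]
by a trapezoidal desirability curve with four transitions x1 < x2 < x3 < x4:
zero up to x1, a linear ramp to 1 at x2, a plateau to x3 and a linear ramp
back to zero at x4.  The aggregate MPO score is the importance-weighted
geometric mean of the five desirabilities, so a property that is fully
undesirable (score 0) annihilates the aggregate; a weighted arithmetic
mean is available via ``aggregation="arithmetic"``.

The default profile targets oral drug-likeness for this inhibitor series:
MW 300-520 Da (hard edges 300/580), ALogP 2-4, PSA 80-130 A^2, HBA 5-9 and
HBD 1-2, with very high importance on MW/ALogP/PSA and high on HBA/HBD.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml
from rdkit import Chem

from .descriptors import mpo_properties
from .errors import ConfigurationError, LibraryError, StructureError

logger = logging.getLogger(__name__)

MPO_PROPERTIES = ("MW", "ALogP", "PSA", "HBA", "HBD")

IMPORTANCE_WEIGHTS = {
    "very high": 1.0,
    "high": 0.75,
    "medium": 0.5,
    "low": 0.25,
}


@dataclass(frozen=True)
class PropertyCurve:
    """One trapezoidal desirability curve plus its importance weight."""

    x1: float
    x2: float
    x3: float
    x4: float
    importance: str = "high"

    def __post_init__(self) -> None:
        if not (self.x1 <= self.x2 <= self.x3 <= self.x4):
            raise ConfigurationError(
                f"transitions must be ordered, got {(self.x1, self.x2, self.x3, self.x4)}"
            )
        if self.importance not in IMPORTANCE_WEIGHTS:
            raise ConfigurationError(f"unknown importance {self.importance!r}")

    @property
    def weight(self) -> float:
        return IMPORTANCE_WEIGHTS[self.importance]


def desirability(value: float, curve: PropertyCurve | Sequence[float]) -> float:
    """Trapezoidal desirability of one property value, in [0, 1]."""
    if not isinstance(curve, PropertyCurve):
        curve = PropertyCurve(*curve)
    v = float(value)
    if v <= curve.x1 and v < curve.x2:
        return 0.0
    if v < curve.x2:
        return (v - curve.x1) / (curve.x2 - curve.x1)
    if v <= curve.x3:
        return 1.0
    if v < curve.x4:
        return (curve.x4 - v) / (curve.x4 - curve.x3)
    return 0.0


@dataclass(frozen=True)
class DesirabilityProfile:
    curves: Mapping[str, PropertyCurve]
    aggregation: str = "geometric"

    def __post_init__(self) -> None:
        missing = [p for p in MPO_PROPERTIES if p not in self.curves]
        if missing:
            raise ConfigurationError(f"profile missing properties: {missing}")
        if self.aggregation not in ("geometric", "arithmetic"):
            raise ConfigurationError(f"unknown aggregation {self.aggregation!r}")

    @classmethod
    def from_dict(cls, data: Mapping) -> "DesirabilityProfile":
        curves = {}
        for prop, spec in data.get("properties", data).items():
            if prop == "aggregation":
                continue
            t = spec["transitions"]
            curves[prop] = PropertyCurve(
                *[float(x) for x in t], importance=spec.get("importance", "high")
            )
        return cls(curves=curves, aggregation=data.get("aggregation", "geometric"))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DesirabilityProfile":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "aggregation": self.aggregation,
            "properties": {
                p: {
                    "transitions": [c.x1, c.x2, c.x3, c.x4],
                    "importance": c.importance,
                }
                for p, c in self.curves.items()
            },
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


#: the profile used throughout: oral drug-likeness for this series
DEFAULT_PROFILE = DesirabilityProfile(
    curves={
        "MW": PropertyCurve(300, 350, 520, 580, importance="very high"),
        "ALogP": PropertyCurve(1, 2, 4, 5, importance="very high"),
        "PSA": PropertyCurve(60, 80, 130, 150, importance="very high"),
        "HBA": PropertyCurve(4, 5, 9, 11, importance="high"),
        "HBD": PropertyCurve(0, 1, 2, 3, importance="high"),
    }
)


@dataclass
class MPOResult:
    property_desirabilities: dict[str, float]
    mpo: float


def mpo_score(
    properties: Mapping[str, float],
    profile: DesirabilityProfile = DEFAULT_PROFILE,
) -> MPOResult:
    """Aggregate desirability of a five-property vector.

    Weighted geometric mean by default (one zero desirability zeroes the
    aggregate); weighted arithmetic mean if the profile requests it.
    """
    missing = [p for p in MPO_PROPERTIES if p not in properties]
    if missing:
        raise ConfigurationError(f"missing MPO properties: {missing}")
    scores = {
        p: desirability(properties[p], profile.curves[p]) for p in MPO_PROPERTIES
    }
    weights = {p: profile.curves[p].weight for p in MPO_PROPERTIES}
    total_w = sum(weights.values())
    if profile.aggregation == "arithmetic":
        mpo = sum(weights[p] * scores[p] for p in MPO_PROPERTIES) / total_w
    else:
        if any(scores[p] == 0.0 for p in MPO_PROPERTIES):
            mpo = 0.0
        else:
            mpo = math.exp(
                sum(weights[p] * math.log(scores[p]) for p in MPO_PROPERTIES)
                / total_w
            )
    return MPOResult(property_desirabilities=scores, mpo=mpo)


def mpo_score_smiles(
    smiles: str, profile: DesirabilityProfile = DEFAULT_PROFILE
) -> MPOResult:
    return mpo_score(mpo_properties(smiles), profile)


@dataclass
class EnumerationRecord:
    analogue_smiles: str
    parent_scaffold: str
    substituents: dict[int, str]
    properties: dict[str, float]
    mpo_result: MPOResult
    rank: int = 0


def _attachment_sites(mol: Chem.Mol) -> list[int]:
    """Map numbers of wildcard attachment atoms, sorted."""
    sites = sorted(
        a.GetAtomMapNum()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
    )
    if not sites:
        raise ConfigurationError("scaffold has no labelled attachment points")
    if len(set(sites)) != len(sites):
        raise ConfigurationError("duplicate attachment-site labels on scaffold")
    return sites


def _fragment_mol(frag_smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles("".join(frag_smiles.split()))
    if mol is None:
        raise LibraryError(f"unparseable fragment {frag_smiles!r}")
    dummies = [a for a in mol.GetAtoms() if a.GetAtomicNum() == 0]
    if len(dummies) != 1:
        raise LibraryError(
            f"fragment {frag_smiles!r} must have exactly one attachment point, "
            f"found {len(dummies)}"
        )
    return mol


def strip_attachment_points(scaffold_smiles: str) -> str:
    """Canonical core with all wildcard attachment atoms replaced by H."""
    mol = Chem.MolFromSmiles("".join(scaffold_smiles.split()))
    if mol is None:
        raise StructureError(scaffold_smiles)
    edit = Chem.RWMol(mol)
    for idx in sorted(
        (a.GetIdx() for a in edit.GetAtoms() if a.GetAtomicNum() == 0),
        reverse=True,
    ):
        edit.RemoveAtom(idx)
    core = edit.GetMol()
    Chem.SanitizeMol(core)
    return Chem.MolToSmiles(core)


def attach_fragments(
    scaffold_smiles: str, assignment: Mapping[int, str | None]
) -> str:
    """Join fragments onto the labelled sites of a scaffold by single bonds.

    ``assignment`` maps site label -> fragment SMILES with one wildcard,
    or None for the null (hydrogen) substituent.  Returns the canonical
    SMILES of the product.
    """
    mol = Chem.MolFromSmiles("".join(scaffold_smiles.split()))
    if mol is None:
        raise StructureError(scaffold_smiles)
    if not any(a.GetAtomicNum() == 0 for a in mol.GetAtoms()):
        if assignment and any(v is not None for v in assignment.values()):
            raise ConfigurationError("scaffold has no labelled attachment points")
        return Chem.MolToSmiles(mol)
    sites = _attachment_sites(mol)
    unknown = set(assignment) - set(sites)
    if unknown:
        raise ConfigurationError(f"unknown attachment sites {sorted(unknown)}")

    edit = Chem.RWMol(mol)
    # drop dummies for H-substituted or unassigned sites (implicit H fills in)
    drop = [
        a.GetIdx()
        for a in edit.GetAtoms()
        if a.GetAtomicNum() == 0
        and assignment.get(a.GetAtomMapNum()) is None
    ]
    for idx in sorted(drop, reverse=True):
        edit.RemoveAtom(idx)
    combined = edit.GetMol()
    for site, frag_smiles in assignment.items():
        if frag_smiles is None:
            continue
        frag = Chem.RWMol(_fragment_mol(frag_smiles))
        for a in frag.GetAtoms():
            if a.GetAtomicNum() == 0:
                a.SetAtomMapNum(site)
        combined = Chem.CombineMols(combined, frag.GetMol())
    product = Chem.molzip(combined)
    Chem.SanitizeMol(product)
    for a in product.GetAtoms():
        a.SetAtomMapNum(0)
    return Chem.MolToSmiles(product)


def read_fragment_library(path: str | Path) -> list[str]:
    """Fragment SMILES file: one fragment per line, '#' comments allowed."""
    frags = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        frags.append(line.split()[0])
    return frags


def enumerate_analogues(
    scaffold_smiles: str,
    library: Sequence[str],
    *,
    cap: int | None = None,
    profile: DesirabilityProfile = DEFAULT_PROFILE,
    include_h: bool = True,
) -> list[EnumerationRecord]:
    """Cartesian R-group enumeration over the scaffold's attachment sites.

    Every fragment must carry exactly one wildcard atom; H is offered as
    the null substituent at every site when ``include_h`` is set.  Products
    are deduplicated by canonical SMILES (first generation order wins),
    scored, ranked by descending MPO (dense ranks, ties share a rank) and
    truncated at ``cap`` after ranking.
    """
    mol = Chem.MolFromSmiles("".join(scaffold_smiles.split()))
    if mol is None:
        raise StructureError(scaffold_smiles)
    sites = _attachment_sites(mol)
    for frag in library:
        _fragment_mol(frag)  # validate up front
    options: list[str | None] = ([None] if include_h else []) + list(library)
    parent_core = strip_attachment_points(scaffold_smiles)
    core_query = Chem.MolFromSmiles(parent_core)

    seen: dict[str, dict[int, str | None]] = {}
    for combo in itertools.product(options, repeat=len(sites)):
        assignment = dict(zip(sites, combo))
        try:
            smi = attach_fragments(scaffold_smiles, assignment)
        except Exception as err:  # unparseable product: skip, keep going
            logger.warning("skipping product %s on %s: %s", combo,
                           scaffold_smiles, err)
            continue
        if smi not in seen:
            seen[smi] = assignment

    records = []
    for smi, assignment in seen.items():
        props = mpo_properties(smi)
        result = mpo_score(props, profile)
        assert Chem.MolFromSmiles(smi).HasSubstructMatch(core_query)
        records.append(
            EnumerationRecord(
                analogue_smiles=smi,
                parent_scaffold=parent_core,
                substituents={
                    k: (v if v is not None else "[H]") for k, v in assignment.items()
                },
                properties=props,
                mpo_result=result,
            )
        )
    records.sort(key=lambda r: (-r.mpo_result.mpo, r.analogue_smiles))
    distinct = sorted({r.mpo_result.mpo for r in records}, reverse=True)
    rank_of = {m: i + 1 for i, m in enumerate(distinct)}
    for r in records:
        r.rank = rank_of[r.mpo_result.mpo]
    return records[:cap] if cap is not None else records


def enumeration_table(records: Sequence[EnumerationRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "analogue_smiles": r.analogue_smiles,
            "parent_scaffold": r.parent_scaffold,
            "substituents": repr(r.substituents),
            "rank": r.rank,
            "mpo": r.mpo_result.mpo,
        }
        row.update({k: r.properties[k] for k in MPO_PROPERTIES})
        rows.append(row)
    return pd.DataFrame(rows)


def optimization_report(
    initial_smiles: str,
    finals: Sequence[EnumerationRecord],
    profile: DesirabilityProfile = DEFAULT_PROFILE,
    top_k: int | None = None,
) -> pd.DataFrame:
    """Before/after comparison of MW, ALogP, HBD, HBA, PSA and MPO.

    The first row is the starting scaffold; subsequent rows are the top
    analogues with deltas relative to the start.
    """
    init_props = mpo_properties(initial_smiles)
    init_mpo = mpo_score(init_props, profile).mpo
    rows = [
        {"structure": initial_smiles, "role": "initial", **init_props,
         "MPO": init_mpo, "delta_MPO": 0.0}
    ]
    chosen = finals if top_k is None else finals[:top_k]
    for r in chosen:
        rows.append(
            {
                "structure": r.analogue_smiles,
                "role": "analogue",
                **{k: r.properties[k] for k in MPO_PROPERTIES},
                "MPO": r.mpo_result.mpo,
                "delta_MPO": r.mpo_result.mpo - init_mpo,
            }
        )
    return pd.DataFrame(rows)
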