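"""Bemis-Murcko scaffold extraction, diversity ratios and group profiling.

A Murcko scaffold keeps every ring system plus the linkers connecting
them and prunes exocyclic side chains (atoms double-bonded to a ring or
linker atom stay, per the standard convention).  Acyclic molecules have an
empty scaffold.  Per potency class the diversity summary reports

    N     molecules in the class,
    Ns    distinct non-empty scaffolds,
    Ncsk  ring-containing molecules (cyclic skeletons),

and the quotients Ns/N, Ncsk/N and Ncsk/Ns.  A low Ns/N means the class
concentrates on few cores; a high Ncsk/Ns means many molecules share each
cyclic core.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem.Scaffolds import MurckoScaffold

from .dataset import ActivityThresholds, CompoundRecord, DEFAULT_THRESHOLDS, classify_activity
from .errors import ConfigurationError, StructureError

#: default SMARTS patterns for functional-group profiling of scaffolds
DEFAULT_SMARTS: Mapping[str, str] = OrderedDict(
    [
        ("aromatic_ring", "[a]"),
        ("amine", "[NX3;!$(NC=O)]"),
        ("amide", "C(=O)N"),
        ("hydroxyl", "[OX2H]"),
        ("ether", "[OD2]([#6])[#6]"),
        ("carbonyl", "[CX3]=[OX1]"),
        ("nitrogen_heterocycle", "[#7;R]"),
        ("halogen", "[F,Cl,Br,I]"),
    ]
)


def _mol(smiles: str) -> Chem.Mol:
    cleaned = "".join(str(smiles).split())
    mol = Chem.MolFromSmiles(cleaned) if cleaned else None
    if mol is None:
        raise StructureError(smiles)
    return mol


def murcko_scaffold(smiles: str) -> str:
    """Canonical Murcko scaffold SMILES; empty string for acyclic input."""
    mol = _mol(smiles)
    if mol.GetRingInfo().NumRings() == 0:
        return ""
    core = MurckoScaffold.GetScaffoldForMol(mol)
    return Chem.MolToSmiles(core)


def cyclic_flag(smiles: str) -> bool:
    """True iff the molecule contains at least one ring."""
    return _mol(smiles).GetRingInfo().NumRings() > 0


@dataclass
class DiversitySummary:
    class_label: str
    n_molecules: int
    n_scaffolds: int
    n_cyclic: int
    ns_over_n: float
    ncsk_over_n: float
    ncsk_over_ns: float

    @classmethod
    def from_counts(
        cls, class_label: str, n_molecules: int, n_scaffolds: int, n_cyclic: int
    ) -> "DiversitySummary":
        """Build the summary from pre-tallied counts (exact quotients)."""
        if n_molecules <= 0:
            raise ConfigurationError("diversity ratios undefined for N = 0")
        if n_scaffolds <= 0:
            raise ConfigurationError("diversity ratios undefined for Ns = 0")
        return cls(
            class_label=class_label,
            n_molecules=n_molecules,
            n_scaffolds=n_scaffolds,
            n_cyclic=n_cyclic,
            ns_over_n=n_scaffolds / n_molecules,
            ncsk_over_n=n_cyclic / n_molecules,
            ncsk_over_ns=n_cyclic / n_scaffolds,
        )


def diversity_summary(
    records: Sequence[CompoundRecord], class_label: str
) -> DiversitySummary:
    """Diversity ratios for one potency class' records."""
    if not records:
        raise ConfigurationError("diversity ratios undefined for an empty class")
    scaffolds = [murcko_scaffold(r.smiles) for r in records]
    ns = len({s for s in scaffolds if s})
    ncsk = sum(1 for s in scaffolds if s)
    return DiversitySummary.from_counts(class_label, len(records), ns, ncsk)


def diversity_table(
    records: Sequence[CompoundRecord],
    class_order: Sequence[str] = ("active", "intermediate", "inactive"),
) -> pd.DataFrame:
    rows = []
    for label in class_order:
        members = [r for r in records if r.activity_class == label]
        if members:
            rows.append(diversity_summary(members, label).__dict__)
    return pd.DataFrame(rows)


@dataclass
class ScaffoldGroup:
    scaffold_smiles: str
    member_ids: list[str]
    count: int
    mean_pic50: float
    scaffold_class: str


def group_by_scaffold(
    records: Sequence[CompoundRecord],
    thresholds: ActivityThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[ScaffoldGroup], list[str]]:
    """Group curated records by Murcko scaffold.

    Returns the groups sorted by descending member count (ties broken by
    canonical scaffold SMILES) plus the ids of acyclic molecules, which
    have no scaffold and are reported separately.
    """
    buckets: dict[str, list[CompoundRecord]] = {}
    acyclic: list[str] = []
    for rec in records:
        scaf = murcko_scaffold(rec.smiles)
        if not scaf:
            acyclic.append(rec.compound_id)
            continue
        buckets.setdefault(scaf, []).append(rec)
    groups = []
    for scaf, members in buckets.items():
        mean = sum(m.pic50 for m in members) / len(members)
        groups.append(
            ScaffoldGroup(
                scaffold_smiles=scaf,
                member_ids=[m.compound_id for m in members],
                count=len(members),
                mean_pic50=mean,
                scaffold_class=classify_activity(mean, thresholds),
            )
        )
    groups.sort(key=lambda g: (-g.count, g.scaffold_smiles))
    return groups, acyclic


def scaffold_table(groups: Sequence[ScaffoldGroup]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "scaffold_smiles": g.scaffold_smiles,
                "mean_pic50": g.mean_pic50,
                "count": g.count,
                "scaffold_class": g.scaffold_class,
            }
            for g in groups
        ]
    )


@dataclass
class FunctionalGroupProfile:
    scaffold_smiles: str
    group_counts: dict[str, int] = field(default_factory=dict)

    def flags(self) -> dict[str, bool]:
        return {k: v > 0 for k, v in self.group_counts.items()}


def functional_groups(
    scaffold_smiles: str,
    patterns: Mapping[str, str] = DEFAULT_SMARTS,
) -> FunctionalGroupProfile:
    """Count SMARTS matches of each named functional group in a scaffold."""
    mol = _mol(scaffold_smiles)
    counts: dict[str, int] = {}
    for name, smarts in patterns.items():
        query = Chem.MolFromSmarts(smarts)
        if query is None:
            raise ConfigurationError(f"invalid SMARTS for pattern {name!r}: {smarts!r}")
        counts[name] = len(mol.GetSubstructMatches(query))
    return FunctionalGroupProfile(
        scaffold_smiles=Chem.MolToSmiles(mol), group_counts=counts
    )


def functional_group_table(
    scaffold_smiles_list: Iterable[str],
    patterns: Mapping[str, str] = DEFAULT_SMARTS,
) -> pd.DataFrame:
    rows = []
    for smi in scaffold_smiles_list:
        prof = functional_groups(smi, patterns)
        row = {"scaffold_smiles": prof.scaffold_smiles}
        row.update(prof.group_counts)
        rows.append(row)
    return pd.DataFrame(rows)


def render_scaffold_svg(smiles: str, path: str | Path, size: int = 300) -> None:
    """Write a 2D depiction of a scaffold as an SVG file."""
    from rdkit.Chem.Draw import rdMolDraw2D

    mol = _mol(smiles)
    drawer = rdMolDraw2D.MolDraw2DSVG(size, size)
    rdMolDraw2D.PrepareAndDrawMolecule(drawer, mol)
    drawer.FinishDrawing()
    Path(path).write_text(drawer.GetDrawingText())
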