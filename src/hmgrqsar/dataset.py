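"""Activity-table ingestion, cleansing and potency labelling.

The pipeline works on half-maximal inhibitory concentrations (IC50).
Internally every concentration is held in nanomolar and converted to the
logarithmic potency scale pIC50 = 9 - log10(IC50 [nM]), i.e. the negative
decadic logarithm of the molar concentration.  Compounds are binned into
three potency classes: active (pIC50 >= 8), intermediate (6 <= pIC50 < 8)
and inactive (pIC50 < 6); both cut-offs are configurable.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit import RDLogger

from .errors import ConfigurationError, StructureError

logger = logging.getLogger(__name__)

RDLogger.DisableLog("rdApp.*")

ACTIVE = "active"
INTERMEDIATE = "intermediate"
INACTIVE = "inactive"
ACTIVITY_CLASSES = (ACTIVE, INTERMEDIATE, INACTIVE)

#: multiplicative factors to nanomolar
_UNIT_TO_NM = {
    "nm": 1.0,
    "um": 1e3,
    "µm": 1e3,
    "μm": 1e3,
    "mm": 1e6,
    "m": 1e9,
    "pm": 1e-3,
}


@dataclass(frozen=True)
class ActivityThresholds:
    """Potency cut-offs on the pIC50 scale.

    ``active_min`` is inclusive (pIC50 >= active_min -> active) and
    ``inactive_max`` is exclusive from below (pIC50 < inactive_max ->
    inactive); everything in between is intermediate.
    """

    active_min: float = 8.0
    inactive_max: float = 6.0

    def __post_init__(self) -> None:
        if not self.active_min > self.inactive_max:
            raise ConfigurationError(
                f"active_min ({self.active_min}) must exceed "
                f"inactive_max ({self.inactive_max})"
            )


DEFAULT_THRESHOLDS = ActivityThresholds()


@dataclass
class CompoundRecord:
    """One curated molecule with its potency annotation."""

    compound_id: str
    smiles: str
    ic50: float
    pic50: float
    activity_class: str


@dataclass
class CurationReport:
    """Row accounting for one cleansing pass; input = retained + removed."""

    n_input: int = 0
    n_removed_no_ic50: int = 0
    n_removed_unparseable: int = 0
    n_removed_duplicates: int = 0
    n_retained: int = 0

    def balances(self) -> bool:
        return self.n_input == (
            self.n_retained
            + self.n_removed_no_ic50
            + self.n_removed_unparseable
            + self.n_removed_duplicates
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2) + "\n")


def canonical_smiles(smiles: str) -> str:
    """Canonicalize a SMILES string, stripping stray whitespace first.

    Raises :class:`StructureError` if RDKit cannot parse it.
    """
    cleaned = "".join(str(smiles).split())
    mol = Chem.MolFromSmiles(cleaned) if cleaned else None
    if mol is None:
        raise StructureError(smiles)
    return Chem.MolToSmiles(mol)


def pic50_from_ic50(ic50_nm: float) -> float:
    """Convert an IC50 in nM to pIC50 = 9 - log10(IC50 nM).

    Strictly decreasing in the concentration: 1000 nM (1 µM) -> 6.0,
    10 nM -> 8.0.
    """
    ic50_nm = float(ic50_nm)
    if not math.isfinite(ic50_nm) or ic50_nm <= 0:
        raise ValueError(
            f"IC50 must be a positive finite concentration in nM, got {ic50_nm!r}"
        )
    return 9.0 - math.log10(ic50_nm)


def ic50_from_pic50(pic50: float) -> float:
    """Inverse of :func:`pic50_from_ic50` (returns nM)."""
    return 10.0 ** (9.0 - float(pic50))


def classify_activity(
    pic50: float, thresholds: ActivityThresholds = DEFAULT_THRESHOLDS
) -> str:
    """Bin a finite pIC50 into active / intermediate / inactive.

    Total on finite inputs; the three classes partition the real line.
    """
    pic50 = float(pic50)
    if not math.isfinite(pic50):
        raise ValueError(f"pIC50 must be finite, got {pic50!r}")
    if pic50 >= thresholds.active_min:
        return ACTIVE
    if pic50 < thresholds.inactive_max:
        return INACTIVE
    return INTERMEDIATE


def _ic50_to_nm(value, unit) -> float | None:
    """Parse one IC50 cell (+ optional unit) to nM; None if missing/invalid."""
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    try:
        ic50 = float(value)
    except (TypeError, ValueError):
        return None
    if not math.isfinite(ic50) or ic50 <= 0:
        return None
    if unit is None or (isinstance(unit, float) and math.isnan(unit)):
        factor = 1.0
    else:
        key = str(unit).strip().lower()
        if not key:
            factor = 1.0
        elif key in _UNIT_TO_NM:
            factor = _UNIT_TO_NM[key]
        else:
            raise ConfigurationError(f"unknown concentration unit {unit!r}")
    return ic50 * factor


def cleanse(
    table: pd.DataFrame,
    *,
    id_col: str = "compound_id",
    smiles_col: str = "smiles",
    ic50_col: str = "ic50",
    units_col: str | None = None,
    thresholds: ActivityThresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[CompoundRecord], CurationReport]:
    """Cleanse a raw activity table into curated records.

    Rows are dropped, in this order of precedence, when the IC50 is
    missing/non-positive/non-numeric, when the SMILES does not parse, or
    when the canonical SMILES duplicates an earlier row (first occurrence
    wins; differing IC50 values on duplicates are logged, not aggregated).
    Output order is the stable order of first occurrence.
    """
    for col in (smiles_col, ic50_col):
        if col not in table.columns:
            raise ConfigurationError(f"required column {col!r} missing from input")
    if units_col is not None and units_col not in table.columns:
        raise ConfigurationError(f"units column {units_col!r} missing from input")
    has_ids = id_col in table.columns

    report = CurationReport(n_input=len(table))
    records: list[CompoundRecord] = []
    seen: dict[str, float] = {}
    for i, row in enumerate(table.to_dict(orient="records")):
        ic50 = _ic50_to_nm(
            row[ic50_col], row[units_col] if units_col else None
        )
        if ic50 is None:
            report.n_removed_no_ic50 += 1
            continue
        try:
            smi = canonical_smiles(row[smiles_col])
        except StructureError:
            report.n_removed_unparseable += 1
            continue
        if smi in seen:
            if not math.isclose(seen[smi], ic50, rel_tol=1e-9):
                logger.warning(
                    "duplicate structure %s with differing IC50 "
                    "(%.4g vs %.4g nM); keeping first occurrence",
                    smi, seen[smi], ic50,
                )
            report.n_removed_duplicates += 1
            continue
        seen[smi] = ic50
        cid = str(row[id_col]) if has_ids else f"CMP-{i:05d}"
        pic50 = pic50_from_ic50(ic50)
        records.append(
            CompoundRecord(
                compound_id=cid,
                smiles=smi,
                ic50=ic50,
                pic50=pic50,
                activity_class=classify_activity(pic50, thresholds),
            )
        )
    report.n_retained = len(records)
    assert report.balances()
    return records, report


def records_to_frame(records: Iterable[CompoundRecord]) -> pd.DataFrame:
    cols = ["compound_id", "smiles", "ic50", "pic50", "activity_class"]
    return pd.DataFrame([asdict(r) for r in records], columns=cols)


def frame_to_records(frame: pd.DataFrame) -> list[CompoundRecord]:
    return [
        CompoundRecord(
            compound_id=str(r.compound_id),
            smiles=str(r.smiles),
            ic50=float(r.ic50),
            pic50=float(r.pic50),
            activity_class=str(r.activity_class),
        )
        for r in frame.itertuples(index=False)
    ]


def write_curated_csv(records: Sequence[CompoundRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def read_curated_csv(path: str | Path) -> list[CompoundRecord]:
    return frame_to_records(pd.read_csv(path))


def read_activity_csv(path: str | Path) -> pd.DataFrame:
    """Read a raw activity table (id, smiles, ic50[, units])."""
    return pd.read_csv(path)


def read_smiles_file(path: str | Path) -> pd.DataFrame:
    """Read a whitespace-delimited SMILES file (SMILES [id]) as a frame."""
    rows = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        rows.append(
            {"compound_id": parts[1] if len(parts) > 1 else f"SMI-{i:05d}",
             "smiles": parts[0]}
        )
    return pd.DataFrame(rows, columns=["compound_id", "smiles"])
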