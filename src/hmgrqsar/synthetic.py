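"""Synthetic ChEMBL-like inhibitor datasets with known ground truth.

Molecules are built by decorating a small set of core scaffolds (four
nitrogen-heterocycle cores from the inhibitor series plus benzene) with
substituent fragments at labelled ring positions.  True potency is
additive on the log scale:

    pIC50 = scaffold base + sum of substituent effects + N(0, noise_sd)

and IC50 = 10^(9 - pIC50) nM.  The defaults produce 310 unique molecules
whose class proportions approximate a 211/56/43 active/intermediate/
inactive split, plus a configurable sprinkling of duplicate rows and
missing-IC50 rows so that curation behaviour is testable.  A ground-truth
ledger records, per molecule, the core, substituents, noiseless and noisy
potency and the injected defects, so every pipeline stage can be checked
for recovery.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from rdkit import Chem

from . import qsar
from .dataset import CompoundRecord, classify_activity
from .design import attach_fragments, strip_attachment_points
from .errors import ConfigurationError, IntegrityError
from .scaffolds import murcko_scaffold

#: core scaffolds with two labelled attachment sites each
DEFAULT_SCAFFOLDS: Mapping[str, str] = {
    "imidazole_biphenyl": "[*:1]c1ccc(-c2nc[nH]c2-c2ccc([*:2])cc2)cc1",
    "pyrrole_anilide": "O=C(Nc1ccc([*:1])cc1)c1[nH]cc(-c2ccccc2)c1-c1ccc([*:2])cc1",
    "pyrrole_benzylamide": "O=C(NCc1ccc([*:1])cc1)c1[nH]cc(-c2ccccc2)c1-c1ccc([*:2])cc1",
    "pyrrole_biphenyl": "[*:1]c1ccc(-c2cc[nH]c2-c2ccc([*:2])cc2)cc1",
    "benzene": "[*:1]c1ccc([*:2])cc1",
}

#: substituent fragments and their additive pIC50 effects
DEFAULT_EFFECTS: Mapping[str, float] = {
    "[*]O": 0.35,
    "[*]OC": 0.20,
    "[*]N": 0.30,
    "[*]C": 0.05,
    "[*]CC": -0.05,
    "[*]F": 0.10,
    "[*]Cl": -0.10,
    "[*]C#N": 0.15,
    "[*]C(N)=O": 0.40,
    "[*]CO": 0.25,
    "[*]C(F)(F)F": -0.30,
    "[*]C(C)=O": 0.10,
    "[*]N(C)C": -0.15,
    "[*][N+](=O)[O-]": -0.25,
}

#: scaffold base potencies, set so the default class split lands near
#: 211 active / 56 intermediate / 43 inactive over 310 molecules
DEFAULT_BASE_PIC50: Mapping[str, float] = {
    "imidazole_biphenyl": 8.9,
    "pyrrole_anilide": 9.2,
    "pyrrole_benzylamide": 9.1,
    "pyrrole_biphenyl": 8.8,
    "benzene": 6.0,
}

DEFAULT_N_PER_SCAFFOLD: Mapping[str, int] = {
    "imidazole_biphenyl": 60,
    "pyrrole_anilide": 55,
    "pyrrole_benzylamide": 55,
    "pyrrole_biphenyl": 50,
    "benzene": 90,
}


@dataclass(frozen=True)
class GeneratorSpec:
    seed: int = 42
    scaffold_set: Mapping[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SCAFFOLDS)
    )
    substituent_effects: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECTS)
    )
    scaffold_base_pic50: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASE_PIC50)
    )
    n_per_scaffold: Mapping[str, int] = field(
        default_factory=lambda: dict(DEFAULT_N_PER_SCAFFOLD)
    )
    noise_sd: float = 0.5
    duplicate_rate: float = 0.03
    missing_ic50_rate: float = 0.03

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        for rate in (self.duplicate_rate, self.missing_ic50_rate):
            if not 0 <= rate < 1:
                raise ConfigurationError("rates must be in [0, 1)")
        missing = set(self.n_per_scaffold) - set(self.scaffold_set)
        if missing:
            raise ConfigurationError(f"n_per_scaffold names unknown scaffolds {missing}")


def _analogue_pool(
    scaffold_smiles: str, effects: Mapping[str, float]
) -> list[tuple[str, dict[int, str | None], float]]:
    """All distinct decorated products of one scaffold, deterministic order.

    Returns (canonical SMILES, site assignment, summed effect) triples;
    symmetric duplicates collapse to their first generation (effects are
    site-independent, so the collapse is unambiguous).
    """
    mol = Chem.MolFromSmiles(scaffold_smiles)
    sites = sorted(
        a.GetAtomMapNum()
        for a in mol.GetAtoms()
        if a.GetAtomicNum() == 0 and a.GetAtomMapNum() > 0
    )
    options: list[str | None] = [None] + list(effects)
    pool: dict[str, tuple[dict[int, str | None], float]] = {}
    import itertools

    for combo in itertools.product(options, repeat=len(sites)):
        assignment = dict(zip(sites, combo))
        smi = attach_fragments(scaffold_smiles, assignment)
        if smi not in pool:
            eff = sum(effects[f] for f in combo if f is not None)
            pool[smi] = (assignment, eff)
    return [(smi, a, e) for smi, (a, e) in pool.items()]


def generate(spec: GeneratorSpec = GeneratorSpec()) -> tuple[pd.DataFrame, dict]:
    """Generate a raw activity table plus its ground-truth ledger.

    The table has columns compound_id, smiles, ic50 (nM) in a shuffled but
    seed-deterministic order; the ledger maps each compound to its true
    core, substituents, class, and lists the injected duplicate and
    missing-IC50 row ids.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[dict] = []
    truth: dict[str, dict] = {}
    leftovers: list[tuple[str, str]] = []  # (scaffold_name, smiles) unused combos

    for name, scaffold_smiles in spec.scaffold_set.items():
        n_want = int(spec.n_per_scaffold.get(name, 0))
        if n_want == 0:
            continue
        pool = _analogue_pool(scaffold_smiles, spec.substituent_effects)
        if n_want > 1 and len(pool) < n_want:
            raise ConfigurationError(
                f"scaffold {name!r} offers only {len(pool)} unique analogues, "
                f"{n_want} requested"
            )
        order = rng.permutation(len(pool))
        chosen, rest = order[:n_want], order[n_want:]
        base = float(spec.scaffold_base_pic50[name])
        core = strip_attachment_points(scaffold_smiles)
        for j in chosen:
            smi, assignment, eff = pool[j]
            true_pic50 = base + eff
            noisy = true_pic50 + rng.normal(0.0, spec.noise_sd)
            cid = f"SYN-{len(rows):04d}"
            rows.append(
                {"compound_id": cid, "smiles": smi,
                 "ic50": 10.0 ** (9.0 - noisy)}
            )
            truth[cid] = {
                "scaffold_name": name,
                "scaffold_smiles": core,
                "substituents": {
                    str(k): (v if v is not None else "[H]")
                    for k, v in assignment.items()
                },
                "effect_sum": eff,
                "pic50_noiseless": true_pic50,
                "pic50": noisy,
                "true_class": classify_activity(noisy),
            }
        for j in rest:
            leftovers.append((name, pool[j][0]))

    n_unique = len(rows)
    # shuffle the unique block first; injected rows are appended after it so
    # first-occurrence deduplication always retains the original molecule
    rows = [rows[int(i)] for i in rng.permutation(n_unique)]

    injected: list[dict] = []
    n_dup = int(round(spec.duplicate_rate * n_unique))
    dup_ids = []
    if n_dup:
        for src in rng.choice(n_unique, size=n_dup, replace=False):
            cid = f"DUP-{len(dup_ids):03d}"
            injected.append(
                {"compound_id": cid, "smiles": rows[int(src)]["smiles"],
                 "ic50": rows[int(src)]["ic50"]}
            )
            dup_ids.append(cid)
    # missing-IC50 rows use unused analogues so they are never also duplicates
    n_miss = int(round(spec.missing_ic50_rate * n_unique))
    miss_ids = []
    if n_miss:
        if len(leftovers) < n_miss:
            raise ConfigurationError("not enough unused analogues for missing rows")
        for k in rng.choice(len(leftovers), size=n_miss, replace=False):
            cid = f"MISS-{len(miss_ids):03d}"
            injected.append(
                {"compound_id": cid, "smiles": leftovers[int(k)][1],
                 "ic50": np.nan}
            )
            miss_ids.append(cid)
    injected = [injected[int(i)] for i in rng.permutation(len(injected))]

    table = pd.DataFrame(rows + injected, columns=["compound_id", "smiles", "ic50"])

    class_counts = {"active": 0, "intermediate": 0, "inactive": 0}
    for t in truth.values():
        class_counts[t["true_class"]] += 1
    ledger = {
        "seed": spec.seed,
        "noise_sd": spec.noise_sd,
        "n_unique": n_unique,
        "n_scaffolds": len(
            {t["scaffold_smiles"] for t in truth.values()}
        ),
        "class_counts": class_counts,
        "injected_duplicate_ids": dup_ids,
        "injected_missing_ids": miss_ids,
        "compounds": truth,
    }
    return table, ledger


def write_dataset(
    table: pd.DataFrame, ledger: dict, out_dir: str | Path
) -> tuple[Path, Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    csv_path = out / "activity.csv"
    ledger_path = out / "ledger.json"
    table.to_csv(csv_path, index=False)
    ledger_path.write_text(json.dumps(ledger, indent=2, sort_keys=True) + "\n")
    return csv_path, ledger_path


@dataclass
class RecoveryReport:
    n_compounds: int
    scaffold_match_rate: float
    ns_pipeline: int
    ns_ledger: int
    ns_match: bool
    cv_r2_mean: float | None = None
    passed: bool = False


def recovery_check(
    records: Sequence[CompoundRecord],
    ledger: dict,
    *,
    check_qsar: bool = False,
    split: "qsar.SplitSpec | None" = None,
) -> RecoveryReport:
    """Verify the pipeline recovers the generator's ground truth.

    Checks that extracted Murcko scaffolds equal the ledger cores for at
    least 99% of molecules and that the number of distinct scaffolds
    matches the ledger exactly; optionally fits the tree-ensemble QSAR
    models and records the best cross-validated R^2.
    """
    truth = ledger["compounds"]
    unknown = [r.compound_id for r in records if r.compound_id not in truth]
    if unknown:
        raise IntegrityError(f"records not present in ledger: {unknown[:5]}...")
    matches = 0
    pipeline_scaffolds = set()
    for rec in records:
        scaf = murcko_scaffold(rec.smiles)
        if scaf:
            pipeline_scaffolds.add(scaf)
        if scaf == truth[rec.compound_id]["scaffold_smiles"]:
            matches += 1
    rate = matches / len(records) if records else 0.0
    ns_ledger = int(ledger["n_scaffolds"])
    report = RecoveryReport(
        n_compounds=len(records),
        scaffold_match_rate=rate,
        ns_pipeline=len(pipeline_scaffolds),
        ns_ledger=ns_ledger,
        ns_match=len(pipeline_scaffolds) == ns_ledger,
    )
    if check_qsar:
        split = split or qsar.SplitSpec(seed=int(ledger.get("seed", 42)))
        X = qsar.featurize(list(records))
        y = [r.pic50 for r in records]
        best = -np.inf
        for rep in qsar.train_suite(X, y, split):
            if rep.model_name in qsar.TREE_ENSEMBLES:
                best = max(best, rep.cv_r2_mean)
        report.cv_r2_mean = float(best)
    report.passed = (
        report.scaffold_match_rate >= 0.99
        and report.ns_match
        and (report.cv_r2_mean is None or report.cv_r2_mean >= 0.5)
    )
    return report
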