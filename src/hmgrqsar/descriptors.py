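"""The eight physicochemical descriptors used throughout the analysis.

MW (average molecular weight, Da), LogP (Crippen atom-contribution
octanol/water partition estimate), hydrogen-bond donor and acceptor counts
(Lipinski definitions), rotatable-bond count, topological polar surface
area (Ertl additive contributions, A^2), heteroatom count and aromatic-ring
count.  The same Crippen LogP serves wherever the literature writes
"ALogP"; values from commercial ALogP implementations can differ slightly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, astuple
from typing import Iterable, Sequence

import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors, Lipinski, rdMolDescriptors

from .dataset import CompoundRecord
from .errors import StructureError

logger = logging.getLogger(__name__)

#: fixed column order for every descriptor table in the pipeline
DESCRIPTOR_COLUMNS = (
    "mw",
    "logp",
    "num_h_donors",
    "num_h_acceptors",
    "n_rot",
    "tpsa",
    "n_het",
    "n_aro",
)


@dataclass(frozen=True)
class DescriptorVector:
    mw: float
    logp: float
    num_h_donors: int
    num_h_acceptors: int
    n_rot: int
    tpsa: float
    n_het: int
    n_aro: int


def compute_descriptors(smiles: str) -> DescriptorVector:
    """Compute the eight-descriptor vector for one molecule.

    Deterministic for a given structure: any SMILES of the same molecule
    yields the same vector.
    """
    cleaned = "".join(str(smiles).split())
    mol = Chem.MolFromSmiles(cleaned) if cleaned else None
    if mol is None:
        raise StructureError(smiles)
    return DescriptorVector(
        mw=Descriptors.MolWt(mol),
        logp=Crippen.MolLogP(mol),
        num_h_donors=Lipinski.NumHDonors(mol),
        num_h_acceptors=Lipinski.NumHAcceptors(mol),
        n_rot=Lipinski.NumRotatableBonds(mol),
        tpsa=Descriptors.TPSA(mol),
        n_het=rdMolDescriptors.CalcNumHeteroatoms(mol),
        n_aro=rdMolDescriptors.CalcNumAromaticRings(mol),
    )


def descriptor_table(
    records: Sequence[CompoundRecord] | Iterable[CompoundRecord],
    *,
    skip_on_error: bool = False,
) -> pd.DataFrame:
    """One descriptor row per record, indexed by compound_id.

    A failing molecule aborts the run with its identifier unless
    ``skip_on_error`` is set, in which case it is logged and excluded.
    """
    ids, rows = [], []
    for rec in records:
        try:
            vec = compute_descriptors(rec.smiles)
        except StructureError as err:
            if skip_on_error:
                logger.warning("skipping %s: %s", rec.compound_id, err)
                continue
            raise StructureError(
                rec.smiles, detail=f"compound {rec.compound_id}"
            ) from err
        ids.append(rec.compound_id)
        rows.append(astuple(vec))
    frame = pd.DataFrame(rows, columns=list(DESCRIPTOR_COLUMNS))
    frame.insert(0, "compound_id", ids)
    return frame.set_index("compound_id")


def mpo_properties(smiles: str) -> dict[str, float]:
    """The five-property view (MW, ALogP, PSA, HBA, HBD) used by MPO scoring."""
    vec = compute_descriptors(smiles)
    return {
        "MW": vec.mw,
        "ALogP": vec.logp,
        "PSA": vec.tpsa,
        "HBA": float(vec.num_h_acceptors),
        "HBD": float(vec.num_h_donors),
    }
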