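"""Protein hydropathicity (GRAVY) and community lifestyle summary."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .core_io import SequenceRecord
from .triage import ContigScreenRecord

logger = logging.getLogger("icevir")

# Kyte-Doolittle hydropathy values per residue.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
}

DEFAULT_INTEGRASE_KEYWORDS = (
    "integrase",
    "recombinase xerc",
    "recombinase xerd",
    "site-specific recombinase",
)


@dataclass(frozen=True)
class GravyResult:
    protein_id: str
    gravy: float


@dataclass(frozen=True)
class LifestyleSummary:
    n_viruses: int
    n_temperate: int
    fraction: float


def gravy(protein: SequenceRecord) -> GravyResult:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue.

    ``X`` residues are skipped with a warning; a protein with no scorable
    residues raises ``ValueError``.
    """
    if protein.moltype != "protein":
        raise ValueError("gravy requires a protein record")
    values = [KYTE_DOOLITTLE[r] for r in protein.seq if r in KYTE_DOOLITTLE]
    n_skipped = len(protein.seq) - len(values)
    if n_skipped:
        logger.warning("gravy(%s): skipped %d X residues", protein.id, n_skipped)
    if not values:
        raise ValueError(f"protein {protein.id} has no scorable residues")
    return GravyResult(protein.id, sum(values) / len(values))


def lifestyle_summary(records: Sequence[ContigScreenRecord],
                      annotations: Mapping[str, Sequence[str]],
                      keywords: Sequence[str] = DEFAULT_INTEGRASE_KEYWORDS
                      ) -> LifestyleSummary:
    """Fraction of viruses that are temperate.

    A virus is temperate when it carries at least one ORF whose product
    annotation contains an integrase keyword, or it is flagged as a
    provirus; a virus meeting both counts once. ``annotations`` maps
    contig id to its list of ORF product strings.
    """
    if not records:
        raise ValueError("no viruses supplied")
    ids = [r.contig_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate contig ids in lifestyle input")
    kws = tuple(k.lower() for k in keywords)
    n_temperate = 0
    for rec in records:
        products = annotations.get(rec.contig_id, ())
        has_integrase = any(
            any(kw in str(p).lower() for kw in kws) for p in products)
        if rec.is_provirus or has_integrase:
            n_temperate += 1
    return LifestyleSummary(len(records), n_temperate, n_temperate / len(records))


def gravy_table(proteins: Iterable[SequenceRecord]) -> pd.DataFrame:
    rows = [gravy(p).__dict__ for p in proteins]
    return pd.DataFrame(rows, columns=["protein_id", "gravy"])
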