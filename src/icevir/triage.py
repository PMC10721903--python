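"""Three-round screening that promotes candidate contigs to bona fide viruses.

Round 1 is a per-class length cutoff, round 2 combines hallmark-gene and
host:viral gene-ratio rules (relaxed for proviruses), and round 3 screens
by an upstream viral-origin score.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

VIRAL_CLASSES = ("dsDNA", "ssDNA", "RNA", "NCLDV", "Lavidaviridae")

_LENGTH_CUTOFFS = {
    "dsDNA": 10_000,
    "NCLDV": 10_000,
    "Lavidaviridae": 10_000,
    "RNA": 1_500,
    "ssDNA": 2_500,
}

RULES = (
    "length_cutoff",
    "no_hallmark",
    "host_viral_ratio",
    "zero_information",
    "origin_screen",
    "pass",
)


@dataclass(frozen=True)
class ContigScreenRecord:
    """Per-contig summary of upstream screening tools."""

    contig_id: str
    length: int
    viral_class: str
    hallmark_count: int
    viral_gene_count: int
    host_gene_count: int
    is_provirus: bool
    viral_origin_score: float

    def __post_init__(self) -> None:
        if self.length < 1:
            raise ValueError(f"{self.contig_id}: length must be >= 1")
        for name in ("hallmark_count", "viral_gene_count", "host_gene_count"):
            if getattr(self, name) < 0:
                raise ValueError(f"{self.contig_id}: {name} must be >= 0")
        if self.viral_class not in VIRAL_CLASSES:
            raise ValueError(f"{self.contig_id}: unknown viral class "
                             f"{self.viral_class!r}")
        if not 0.0 <= self.viral_origin_score <= 1.0:
            raise ValueError(f"{self.contig_id}: viral_origin_score outside [0,1]")


@dataclass(frozen=True)
class TriageDecision:
    contig_id: str
    verdict: str  # {"accepted", "rejected"}
    rule_fired: str

    def __post_init__(self) -> None:
        if (self.verdict == "rejected") != (self.rule_fired != "pass"):
            raise ValueError("rejected iff rule_fired != pass")


def length_cutoff(viral_class: str) -> int:
    """Minimum contig length (bp) for a viral class."""
    try:
        return _LENGTH_CUTOFFS[viral_class]
    except KeyError:
        raise ValueError(f"unknown viral class {viral_class!r}") from None


def classify_contig(
    rec: ContigScreenRecord,
    min_origin_score: float = 0.5,
    apply_origin_screen: bool = True,
) -> TriageDecision:
    """Apply the filter chain to one contig.

    Rule order: length cutoff; zero-information (no hallmark and no host
    genes); hallmark requirement (proviruses pass on hallmark alone);
    host:viral gene ratio < 1 for non-proviruses; viral-origin score
    screen last. Hallmark genes count as viral genes when computing the
    ratio, so the denominator is ``max(viral_gene_count, hallmark_count, 1)``.
    """
    def reject(rule: str) -> TriageDecision:
        return TriageDecision(rec.contig_id, "rejected", rule)

    if rec.length < length_cutoff(rec.viral_class):
        return reject("length_cutoff")
    if rec.hallmark_count == 0 and rec.host_gene_count == 0:
        return reject("zero_information")
    if rec.hallmark_count < 1:
        return reject("no_hallmark")
    if not rec.is_provirus:
        denom = max(rec.viral_gene_count, rec.hallmark_count, 1)
        if rec.host_gene_count / denom >= 1.0:
            return reject("host_viral_ratio")
    if apply_origin_screen and rec.viral_origin_score < min_origin_score:
        return reject("origin_screen")
    return TriageDecision(rec.contig_id, "accepted", "pass")


def triage_dataset(
    records: Sequence[ContigScreenRecord],
    min_origin_score: float = 0.5,
    apply_origin_screen: bool = True,
) -> tuple[list[TriageDecision], pd.DataFrame]:
    """Classify every record and tabulate rule counts per viral class.

    Returns (decisions, summary). Summary rows are viral classes, columns
    the rule names; counts sum to the input size.
    """
    ids = [r.contig_id for r in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate contig ids: {dupes}")
    decisions = [
        classify_contig(r, min_origin_score, apply_origin_screen) for r in records
    ]
    summary = pd.DataFrame(0, index=list(VIRAL_CLASSES), columns=list(RULES))
    for rec, dec in zip(records, decisions):
        summary.loc[rec.viral_class, dec.rule_fired] += 1
    return decisions, summary


def read_screen_table(path: str | Path) -> list[ContigScreenRecord]:
    """Read a screen table TSV (columns matching ContigScreenRecord)."""
    df = pd.read_csv(path, sep="\t")
    return [
        ContigScreenRecord(
            contig_id=str(r.contig_id),
            length=int(r.length),
            viral_class=str(r.viral_class),
            hallmark_count=int(r.hallmark_count),
            viral_gene_count=int(r.viral_gene_count),
            host_gene_count=int(r.host_gene_count),
            is_provirus=bool(r.is_provirus),
            viral_origin_score=float(r.viral_origin_score),
        )
        for r in df.itertuples(index=False)
    ]


def write_screen_table(records: Iterable[ContigScreenRecord], path: str | Path) -> None:
    pd.DataFrame([r.__dict__ for r in records]).to_csv(path, sep="\t", index=False)


def write_decisions(decisions: Iterable[TriageDecision], path: str | Path) -> None:
    pd.DataFrame([d.__dict__ for d in decisions]).to_csv(path, sep="\t", index=False)
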