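"""Fragment-recruitment filtering and KPKG abundance/activity profiles.

Two retention tiers: species (identity >= 95%, query coverage >= 85%) and
genus (identity >= 70%, query coverage >= 50%). KPKG is recruited
kilobases per genome kilobase per metagenome (or metatranscriptome)
gigabase.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .core_io import AlignmentHit, query_coverage

TIERS = {
    "species": (95.0, 85.0),
    "genus": (70.0, 50.0),
}


@dataclass
class SampleMeta:
    sample_id: str
    kind: str  # {"metagenome", "metatranscriptome"}
    dataset_size_bp: int
    depth_label: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("metagenome", "metatranscriptome"):
            raise ValueError(f"unknown sample kind {self.kind!r}")
        if self.dataset_size_bp <= 0:
            raise ValueError("dataset_size_bp must be > 0")

    @property
    def measure(self) -> str:
        return "abundance" if self.kind == "metagenome" else "activity"


@dataclass
class RecruitmentProfile:
    contig_id: str
    sample_id: str
    tier: str
    recruited_bp: int
    kpkg: float


def filter_recruits(hits: Iterable[AlignmentHit], tier: str,
                    read_lengths: Optional[Mapping[str, int]] = None
                    ) -> list[AlignmentHit]:
    """Retain recruitment hits passing a tier's identity/coverage cutoffs.

    After thresholding, at most one hit per read is kept (highest
    bitscore, ties broken by lowest subject id) so no read is counted
    twice.
    """
    try:
        min_id, min_cov = TIERS[tier]
    except KeyError:
        raise ValueError(f"unknown tier {tier!r}") from None
    best: dict[str, AlignmentHit] = {}
    for h in hits:
        q_len = h.q_len if h.q_len is not None else (
            read_lengths.get(h.query_id) if read_lengths else None)
        if h.pct_identity < min_id or query_coverage(h, q_len) < min_cov:
            continue
        cur = best.get(h.query_id)
        if cur is None or (h.bitscore, _neg(h.subject_id)) > (cur.bitscore, _neg(cur.subject_id)):
            best[h.query_id] = h
    return [best[k] for k in sorted(best)]


class _neg(str):
    """Reverses string ordering so max() prefers the lowest subject id."""

    def __lt__(self, other):  # type: ignore[override]
        return str.__gt__(self, other)

    def __gt__(self, other):  # type: ignore[override]
        return str.__lt__(self, other)


def compute_kpkg(recruited_bp: float, genome_len_bp: int, dataset_size_bp: int) -> float:
    """Recruited kilobases per genome kilobase per dataset gigabase."""
    if genome_len_bp <= 0:
        raise ValueError("genome_len_bp must be > 0")
    if dataset_size_bp <= 0:
        raise ValueError("dataset_size_bp must be > 0")
    return (recruited_bp / 1e3) / (genome_len_bp / 1e3) / (dataset_size_bp / 1e9)


def profile(hits_by_sample: Mapping[str, Iterable[AlignmentHit]],
            contig_lengths: Mapping[str, int],
            samples: Sequence[SampleMeta],
            tier: str = "species",
            read_lengths: Optional[Mapping[str, int]] = None
            ) -> pd.DataFrame:
    """Per-(contig, sample) KPKG table at one tier.

    Recruited bp is the summed alignment length of retained best-hits.
    Columns: contig_id, sample_id, measure, tier, recruited_bp, kpkg.
    """
    meta = {s.sample_id: s for s in samples}
    rows = []
    for sample_id in sorted(meta):
        sample_hits = list(hits_by_sample.get(sample_id, []))
        unknown = sorted({h.subject_id for h in sample_hits}
                         - set(contig_lengths))
        if unknown:
            raise ValueError(f"hits to unknown contigs in {sample_id}: {unknown}")
        retained = filter_recruits(sample_hits, tier, read_lengths)
        recruited: dict[str, int] = {c: 0 for c in contig_lengths}
        for h in retained:
            recruited[h.subject_id] += h.aln_len
        for contig_id in sorted(contig_lengths):
            bp = recruited[contig_id]
            rows.append({
                "contig_id": contig_id,
                "sample_id": sample_id,
                "measure": meta[sample_id].measure,
                "tier": tier,
                "recruited_bp": bp,
                "kpkg": compute_kpkg(bp, contig_lengths[contig_id],
                                     meta[sample_id].dataset_size_bp),
            })
    return pd.DataFrame(rows)


def top_n(profile_df: pd.DataFrame, n: int = 3,
          kind: Optional[str] = None) -> pd.DataFrame:
    """Top-n contigs per sample by KPKG, descending, ties by contig id.

    ``kind`` restricts to one measure ("abundance" or "activity").
    """
    if profile_df.empty:
        raise ValueError("empty profile")
    df = profile_df
    if kind is not None:
        df = df[df["measure"] == kind]
    df = df.sort_values(["sample_id", "kpkg", "contig_id"],
                        ascending=[True, False, True], kind="mergesort")
    return df.groupby("sample_id", group_keys=False).head(n).reset_index(drop=True)


def fold_changes(profile_df: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Max/min KPKG fold-change per contig across samples (descriptive only).

    Contigs absent everywhere get fold_change NaN; a ``flagged`` column
    marks contigs exceeding ``threshold``.
    """
    rows = []
    for contig_id, grp in profile_df.groupby("contig_id"):
        vals = grp["kpkg"].to_numpy()
        pos = vals[vals > 0]
        fc = float(pos.max() / pos.min()) if len(pos) else float("nan")
        rows.append({"contig_id": contig_id, "fold_change": fc,
                     "flagged": bool(fc > threshold) if pos.size else False})
    return pd.DataFrame(rows)
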