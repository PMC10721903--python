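"""Sequence and alignment-table I/O, a small exact local aligner, and config.

FASTA reading/writing is delegated to Biopython; alignment tables follow
BLAST outfmt-6 column order (12 columns, optional 13th ``qlen``). The
built-in Smith-Waterman aligner is intended for short queries only
(spacers, tRNAs) and refuses queries longer than 500 residues.
"""

from __future__ import annotations

import logging
import sys
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("icevir")

_DNA_ALPHABET = set("ACGTN")
_PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYX")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def setup_logging(quiet: bool = False) -> None:
    """Route package logging to stderr; ``quiet`` silences INFO messages."""
    handler = logging.StreamHandler(sys.stderr)
    handler.setFormatter(logging.Formatter("[icevir] %(levelname)s %(message)s"))
    logger.handlers[:] = [handler]
    logger.setLevel(logging.WARNING if quiet else logging.INFO)


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N maps to N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SequenceRecord:
    """A single named sequence, DNA or protein."""

    id: str
    seq: str
    moltype: str = "dna"  # {"dna", "protein"}

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.moltype not in ("dna", "protein"):
            raise ValueError(f"unknown moltype {self.moltype!r}")
        alphabet = _DNA_ALPHABET if self.moltype == "dna" else _PROTEIN_ALPHABET
        bad = set(self.seq) - alphabet
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains characters {sorted(bad)} "
                f"outside the {self.moltype} alphabet"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class AlignmentHit:
    """One pairwise local-alignment row (BLAST outfmt-6 semantics).

    Coordinates are 1-based inclusive. ``q_len`` is the optional 13th
    column carrying the full query length; when absent it must be
    resolved from a sequence-length lookup before coverage is computed.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    aln_len: int
    mismatches: int
    gap_opens: int
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    evalue: float
    bitscore: float
    q_len: Optional[int] = None
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.q_start > self.q_end:
            raise ValueError(
                f"hit {self.query_id}->{self.subject_id}: q_start > q_end"
            )
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity outside [0, 100]")
        if self.aln_len < 1:
            raise ValueError("aln_len must be >= 1")
        if self.evalue < 0:
            raise ValueError("evalue must be >= 0")
        if self.q_len is not None and self.q_len < self.q_end:
            raise ValueError("q_len smaller than q_end")


def read_fasta(path: str | Path, moltype: str = "dna") -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Sequences are uppercased and input order is preserved. Duplicate ids
    raise ``ValueError`` naming the offending id; an empty file yields an
    empty list with a warning.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(SequenceRecord(rec.id, str(rec.seq).upper(), moltype))
    if not records:
        logger.warning("no records found in %s", path)
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, width: int = 70) -> None:
    """Write records to FASTA, wrapping lines at ``width`` characters."""
    bio = [_BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


_HIT_FIELDS = (
    ("query_id", str), ("subject_id", str), ("pct_identity", float),
    ("aln_len", int), ("mismatches", int), ("gap_opens", int),
    ("q_start", int), ("q_end", int), ("s_start", int), ("s_end", int),
    ("evalue", float), ("bitscore", float),
)


def read_hits(path: str | Path) -> list[AlignmentHit]:
    """Read a tab-separated alignment table (12 or 13 columns).

    The 13th column, when present, is interpreted as the full query
    length. Malformed rows raise ``ValueError`` citing the line number.
    """
    hits: list[AlignmentHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) not in (12, 13):
                raise ValueError(
                    f"{path}:{lineno}: expected 12 or 13 columns, got {len(parts)}"
                )
            kwargs = {}
            for (name, conv), raw in zip(_HIT_FIELDS, parts):
                try:
                    kwargs[name] = conv(raw)
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: cannot parse column {name!r} "
                        f"from {raw!r}"
                    ) from exc
            if len(parts) == 13:
                try:
                    kwargs["q_len"] = int(parts[12])
                except ValueError as exc:
                    raise ValueError(
                        f"{path}:{lineno}: cannot parse q_len from {parts[12]!r}"
                    ) from exc
            hits.append(AlignmentHit(**kwargs))
    return hits


def write_hits(hits: Iterable[AlignmentHit], path: str | Path) -> None:
    """Write hits as a 13-column tab-separated table (q_len last)."""
    with open(path, "w") as fh:
        for h in hits:
            q_len = h.q_len if h.q_len is not None else h.q_end
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.pct_identity:.2f}\t{h.aln_len}\t"
                f"{h.mismatches}\t{h.gap_opens}\t{h.q_start}\t{h.q_end}\t"
                f"{h.s_start}\t{h.s_end}\t{h.evalue:.3g}\t{h.bitscore:.1f}\t{q_len}\n"
            )


def query_coverage(hit: AlignmentHit, q_len: Optional[int] = None) -> float:
    """Percent of the full query spanned by this HSP, clamped to [0, 100].

    Coverage is per-HSP: ``100 * (q_end - q_start + 1) / q_len``.
    """
    length = q_len if q_len is not None else hit.q_len
    if length is None:
        raise ValueError(
            f"hit {hit.query_id}->{hit.subject_id}: q_len unavailable and no "
            "sequence-length lookup supplied"
        )
    if length < 1:
        raise ValueError("q_len must be >= 1")
    cov = 100.0 * (hit.q_end - hit.q_start + 1) / length
    return min(max(cov, 0.0), 100.0)


@dataclass(frozen=True)
class AlignScores:
    match: int = 1
    mismatch: int = -1
    gap: int = -2


def _sw_matrix(q: str, s: str, sc: AlignScores):
    """Plain Smith-Waterman DP with linear gaps. Returns (H, best cell).

    Ns in DNA score as mismatches. The best cell is chosen by maximal
    score, then lowest subject end, then lowest query end (deterministic).
    """
    n, m = len(q), len(s)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    best, best_i, best_j = 0, 0, 0
    for i in range(1, n + 1):
        qi = q[i - 1]
        row, prev = H[i], H[i - 1]
        for j in range(1, m + 1):
            sub = sc.match if (qi == s[j - 1] and qi != "N") else sc.mismatch
            v = prev[j - 1] + sub
            up = prev[j] + sc.gap
            if up > v:
                v = up
            left = row[j - 1] + sc.gap
            if left > v:
                v = left
            if v < 0:
                v = 0
            row[j] = v
            if v > best or (v == best and v > 0 and (j, i) < (best_j, best_i)):
                best, best_i, best_j = v, i, j
    return H, best, best_i, best_j


def _sw_traceback(q, s, sc, H, i, j):
    """Trace back from (i, j); preference diagonal > up > left."""
    matches = mismatches = gap_opens = aln_len = 0
    in_gap = False
    qi_end, sj_end = i, j
    while i > 0 and j > 0 and H[i][j] > 0:
        sub = sc.match if (q[i - 1] == s[j - 1] and q[i - 1] != "N") else sc.mismatch
        if H[i][j] == H[i - 1][j - 1] + sub:
            if sub == sc.match:
                matches += 1
            else:
                mismatches += 1
            aln_len += 1
            i, j = i - 1, j - 1
            in_gap = False
        elif H[i][j] == H[i - 1][j] + sc.gap:
            if not in_gap:
                gap_opens += 1
                in_gap = True
            aln_len += 1
            i -= 1
        else:
            if not in_gap:
                gap_opens += 1
                in_gap = True
            aln_len += 1
            j -= 1
    return {
        "q_start": i + 1, "q_end": qi_end,
        "s_start": j + 1, "s_end": sj_end,
        "matches": matches, "mismatches": mismatches,
        "gap_opens": gap_opens, "aln_len": aln_len,
    }


def smith_waterman(
    query: SequenceRecord,
    subject: SequenceRecord,
    scores: AlignScores = AlignScores(),
) -> Optional[AlignmentHit]:
    """Optimal local alignment of a short query against a subject.

    For DNA both strands are searched (the query is reverse-complemented);
    ties between strands prefer the lower subject start, then the forward
    strand. Returns ``None`` when no alignment scores above zero.
    """
    if query.moltype != subject.moltype:
        raise ValueError("query and subject moltype differ")
    if len(query) > 500:
        raise ValueError("smith_waterman is restricted to queries <= 500 residues")

    candidates = [("+", query.seq)]
    if query.moltype == "dna":
        candidates.append(("-", revcomp(query.seq)))

    results = []
    for strand, qseq in candidates:
        H, score, bi, bj = _sw_matrix(qseq, subject.seq, scores)
        if score <= 0:
            continue
        tb = _sw_traceback(qseq, subject.seq, scores, H, bi, bj)
        results.append((score, tb["s_start"], 0 if strand == "+" else 1, strand, tb))
    if not results:
        return None
    score, _, _, strand, tb = min(results, key=lambda r: (-r[0], r[1], r[2]))
    pct = 100.0 * tb["matches"] / tb["aln_len"]
    return AlignmentHit(
        query_id=query.id,
        subject_id=subject.id,
        pct_identity=pct,
        aln_len=tb["aln_len"],
        mismatches=tb["mismatches"],
        gap_opens=tb["gap_opens"],
        q_start=tb["q_start"],
        q_end=tb["q_end"],
        s_start=tb["s_start"],
        s_end=tb["s_end"],
        evalue=0.0,
        bitscore=float(score),
        q_len=len(query),
        strand=strand,
    )


@dataclass
class Config:
    """All pipeline thresholds with defaults matching the published method."""

    seed: int = 0
    # triage
    min_origin_score: float = 0.5
    apply_origin_screen: bool = True
    # protein network
    protein_max_evalue: float = 1e-5
    protein_min_bitscore: float = 50.0
    mcl_inflation: float = 2.0
    mcl_expansion: int = 2
    mcl_pruning: float = 1e-5
    mcl_max_iterations: int = 100
    mcl_tolerance: float = 1e-8
    vc_score_threshold: float = 1.0
    species_cutoff: float = 95.0
    genus_cutoff: float = 70.0
    # abundance
    species_min_identity: float = 95.0
    species_min_qcov: float = 85.0
    genus_min_identity: float = 70.0
    genus_min_qcov: float = 50.0
    # host assignment
    crispr_min_repeats: int = 3
    crispr_repeat_len: tuple = (19, 38)
    crispr_spacer_len: tuple = (19, 48)
    crispr_max_repeat_mismatch: int = 1
    spacer_max_mismatches: int = 1
    trna_min_aln_len: int = 60
    trna_min_identity: float = 97.0
    trna_max_mismatches: int = 10  # exclusive: mismatches < 10
    wish_k: int = 8
    wish_pseudocount: float = 1.0
    wish_window: tuple = (-1.30, -1.20)
    codon_distance_cutoff: float = 0.05
    amg_max_evalue: float = 5e-5
    amg_min_identity: float = 50.0
    amg_min_qcov: float = 50.0
    # features
    integrase_keywords: tuple = (
        "integrase",
        "recombinase xerc",
        "recombinase xerd",
        "site-specific recombinase",
    )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        cfg = cls(**data)
        for name in ("crispr_repeat_len", "crispr_spacer_len", "wish_window",
                     "integrase_keywords"):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        data = {f.name: getattr(self, f.name) for f in fields(self)}
        for k, v in data.items():
            if isinstance(v, tuple):
                data[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)
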