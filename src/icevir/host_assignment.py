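"""Virus-host assignment from multiple independent lines of evidence.

Strong evidence: CRISPR spacer-protospacer matches, shared tRNAs, and
host-homolog auxiliary metabolic genes (AMGs). Supporting evidence:
k-mer Markov log-likelihood (WisH-style), codon-usage distance, and
binning co-occurrence. Binning membership alone never yields an
assignment.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .core_io import AlignmentHit, SequenceRecord, query_coverage, revcomp

logger = logging.getLogger("icevir")

STRONG_TYPES = frozenset({"crispr", "trna", "amg"})
SUPPORTING_TYPES = frozenset({"wish", "codon", "binning"})


@dataclass
class CrisprArray:
    """A repeat-spacer array: >= 3 repeat copies, spacers between them."""

    host_id: str
    repeat_consensus: str
    repeat_starts: list  # 0-based start of each repeat copy
    spacers: list  # (sequence, 0-based start)
    strand: str = "+"

    def __post_init__(self) -> None:
        if len(self.repeat_starts) < 3:
            raise ValueError("a CRISPR array requires >= 3 repeat copies")
        if len(self.spacers) != len(self.repeat_starts) - 1:
            raise ValueError("spacer count must equal repeat copies - 1")

    @property
    def start(self) -> int:
        return self.repeat_starts[0]

    @property
    def end(self) -> int:
        """0-based exclusive end of the array."""
        return self.repeat_starts[-1] + len(self.repeat_consensus)


@dataclass
class HostEvidence:
    virus_id: str
    host_id: str
    etype: str  # {crispr, trna, wish, codon, amg, binning}
    score: float
    passed: bool
    detail: str = ""


@dataclass
class HostAssignment:
    virus_id: str
    host_id: Optional[str]
    tier: str  # {"strong", "supporting", "unassigned"}
    evidence: list = field(default_factory=list)
    ambiguous: bool = False


# ---------------------------------------------------------------------------
# CRISPR array detection (CRT-style re-implementation)
# ---------------------------------------------------------------------------

def _scan_arrays(seq: str, min_repeats: int, repeat_len: tuple,
                 spacer_len: tuple, max_repeat_mismatch: int) -> list[dict]:
    """Find repeat-spacer arrays on one strand of ``seq``.

    Seeds on exact k-mers (k = minimum repeat length) recurring at
    plausible periods, extends each candidate repeat outward while all
    copies agree, then validates repeat/spacer length bounds and a
    per-copy mismatch budget against the consensus.
    """
    min_rep, max_rep = repeat_len
    min_sp, max_sp = spacer_len
    k = min_rep
    n = len(seq)
    if n < min_repeats * min_rep + (min_repeats - 1) * min_sp:
        return []

    positions: dict[str, list[int]] = {}
    for i in range(n - k + 1):
        positions.setdefault(seq[i: i + k], []).append(i)

    min_gap, max_gap = min_rep + min_sp, max_rep + max_sp
    candidates = []
    for kmer, pos in positions.items():
        if len(pos) < min_repeats:
            continue
        run = [pos[0]]
        for p in pos[1:]:
            if min_gap <= p - run[-1] <= max_gap:
                run.append(p)
            else:
                if len(run) >= min_repeats:
                    candidates.append(run)
                run = [p]
        if len(run) >= min_repeats:
            candidates.append(run)

    candidates.sort(key=lambda r: r[0])
    arrays, covered = [], []
    for run in candidates:
        if any(s <= run[0] < e for s, e in covered):
            continue
        arr = _extend_candidate(seq, run, k, repeat_len, spacer_len,
                                max_repeat_mismatch)
        if arr is None:
            continue
        span = (arr["starts"][0], arr["starts"][-1] + len(arr["consensus"]))
        if any(not (span[1] <= s or span[0] >= e) for s, e in covered):
            continue
        covered.append(span)
        arrays.append(arr)
    return arrays


def _extend_candidate(seq, run, k, repeat_len, spacer_len, max_mm):
    min_rep, max_rep = repeat_len
    min_sp, max_sp = spacer_len
    gaps = [b - a for a, b in zip(run, run[1:])]
    min_gap = min(gaps)

    left, right = 0, k  # each repeat copy spans [p + left, p + right)

    def can_grow(new_left, new_right):
        rep = new_right - new_left
        if rep > max_rep or min_gap - rep < min_sp:
            return False
        return run[0] + new_left >= 0 and run[-1] + new_right <= len(seq)

    while can_grow(left, right + 1):
        if len({seq[p + right] for p in run}) != 1:
            break
        right += 1
    while can_grow(left - 1, right):
        if len({seq[p + left - 1] for p in run}) != 1:
            break
        left -= 1

    rep_len = right - left
    if not min_rep <= rep_len <= max_rep:
        return None
    starts = [p + left for p in run]
    for g in gaps:
        sp = g - rep_len
        if not min_sp <= sp <= max_sp:
            return None
    copies = [seq[s: s + rep_len] for s in starts]
    consensus = "".join(
        max(set(col), key=lambda c: (col.count(c), c)) for col in zip(*copies))
    if any(sum(a != b for a, b in zip(c, consensus)) > max_mm for c in copies):
        return None
    spacers = [(seq[s + rep_len: t], s + rep_len)
               for s, t in zip(starts, starts[1:])]
    return {"consensus": consensus, "starts": starts, "spacers": spacers}


def detect_crispr(host: SequenceRecord,
                  min_repeats: int = 3,
                  repeat_len: tuple = (19, 38),
                  spacer_len: tuple = (19, 48),
                  max_repeat_mismatch: int = 1) -> list[CrisprArray]:
    """Detect CRISPR arrays in a host genome; both strands scanned.

    Arrays found on the reverse strand are mapped back to forward
    coordinates; overlapping detections prefer the forward strand.
    """
    if host.moltype != "dna":
        raise ValueError("detect_crispr requires a DNA record")
    fwd = _scan_arrays(host.seq, min_repeats, repeat_len, spacer_len,
                       max_repeat_mismatch)
    arrays = [CrisprArray(host.id, a["consensus"], a["starts"], a["spacers"], "+")
              for a in fwd]
    n = len(host.seq)
    spans = [(a.start, a.end) for a in arrays]
    for a in _scan_arrays(revcomp(host.seq), min_repeats, repeat_len,
                          spacer_len, max_repeat_mismatch):
        rep_len = len(a["consensus"])
        starts = sorted(n - s - rep_len for s in a["starts"])
        spacers = sorted(((revcomp(s), n - p - len(s)) for s, p in a["spacers"]),
                         key=lambda t: t[1])
        arr = CrisprArray(host.id, a["consensus"], starts, spacers, "-")
        if any(not (arr.end <= s or arr.start >= e) for s, e in spans):
            continue
        spans.append((arr.start, arr.end))
        arrays.append(arr)
    arrays.sort(key=lambda a: a.start)
    return arrays


# ---------------------------------------------------------------------------
# Ungapped full-length matching (spacers, tRNAs)
# ---------------------------------------------------------------------------

def search_ungapped(query: str, subject: str, max_mismatches: int
                    ) -> Optional[tuple[int, int, str]]:
    """Best full-query-length ungapped match of ``query`` in ``subject``.

    Both strands are searched. Returns (mismatches, 0-based start on the
    forward subject, strand) for the best window (fewest mismatches, then
    lowest position, then forward strand), or ``None``. Uses pigeonhole
    seeding: one of ``max_mismatches + 1`` query chunks must match
    exactly.
    """
    m = len(query)
    best: Optional[tuple[int, int, str]] = None
    for strand, q in (("+", query), ("-", revcomp(query))):
        n_chunks = max_mismatches + 1
        bounds = [round(i * m / n_chunks) for i in range(n_chunks + 1)]
        seen: set[int] = set()
        for ci in range(n_chunks):
            chunk = q[bounds[ci]: bounds[ci + 1]]
            if not chunk:
                continue
            start = subject.find(chunk)
            while start != -1:
                w = start - bounds[ci]
                if w >= 0 and w + m <= len(subject) and w not in seen:
                    seen.add(w)
                    mm = sum(a != b for a, b in zip(q, subject[w: w + m]))
                    if mm <= max_mismatches:
                        cand = (mm, w, strand)
                        if best is None or (cand[0], cand[1],
                                            strand != "+") < (best[0], best[1],
                                                              best[2] != "+"):
                            best = cand
                start = subject.find(chunk, start + 1)
    return best


def match_spacers(arrays: Sequence[CrisprArray],
                  viruses: Sequence[SequenceRecord],
                  max_mismatches: int = 1) -> list[HostEvidence]:
    """Match host CRISPR spacers against viral genomes (protospacers).

    Evidence passes when a full-spacer-length, gap-free match has at most
    ``max_mismatches`` mismatches; near misses (up to 2 extra mismatches)
    are reported as failed evidence. Score is the mismatch count.
    """
    out = []
    slack = max_mismatches + 2
    for arr in arrays:
        for si, (spacer, _pos) in enumerate(arr.spacers):
            for virus in viruses:
                found = search_ungapped(spacer, virus.seq, slack)
                if found is None:
                    continue
                mm, pos, strand = found
                out.append(HostEvidence(
                    virus_id=virus.id,
                    host_id=arr.host_id,
                    etype="crispr",
                    score=float(mm),
                    passed=mm <= max_mismatches,
                    detail=(f"spacer {si} of array@{arr.start} matches "
                            f"{virus.id}:{pos + 1} strand {strand} "
                            f"({mm} mismatches)"),
                ))
    return out


def match_trna(viral_trnas: Mapping[str, Sequence[SequenceRecord]],
               hosts: Sequence[SequenceRecord],
               min_aln_len: int = 60,
               min_identity: float = 97.0,
               max_mismatches: int = 10) -> list[HostEvidence]:
    """Match viral tRNA sequences against host genomes.

    A pair passes when the best full-length ungapped alignment satisfies
    ``aln_len >= min_aln_len``, ``identity >= min_identity`` and
    ``mismatches < max_mismatches`` jointly.
    """
    out = []
    for virus_id in sorted(viral_trnas):
        for trna in viral_trnas[virus_id]:
            m = len(trna.seq)
            allow = min(max_mismatches - 1,
                        math.floor(m * (1 - min_identity / 100.0)))
            for host in hosts:
                found = search_ungapped(trna.seq, host.seq, max(allow + 2, 2))
                if found is None:
                    continue
                mm, pos, strand = found
                identity = 100.0 * (m - mm) / m
                passed = (m >= min_aln_len and identity >= min_identity
                          and mm < max_mismatches)
                out.append(HostEvidence(
                    virus_id=virus_id,
                    host_id=host.id,
                    etype="trna",
                    score=identity,
                    passed=passed,
                    detail=(f"tRNA {trna.id} at {host.id}:{pos + 1} strand "
                            f"{strand}, len {m}, {mm} mismatches"),
                ))
    return out


# ---------------------------------------------------------------------------
# Composition-based evidence (WisH-style Markov model, codon usage)
# ---------------------------------------------------------------------------

_BASE_CODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _encode(seq: str) -> np.ndarray:
    codes = np.full(len(seq), -1, dtype=np.int64)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    for base, code in _BASE_CODE.items():
        codes[arr == ord(base)] = code
    return codes


@dataclass
class MarkovModel:
    """Per-host k-mer transition model: log P(base | preceding (k-1)-mer)."""

    host_id: str
    k: int
    logp: np.ndarray  # shape (4**(k-1), 4), rows sum to 1 in probability
    pseudocount: float = 1.0

    @classmethod
    def uniform(cls, k: int = 1, host_id: str = "uniform") -> "MarkovModel":
        logp = np.full((4 ** (k - 1), 4), math.log(0.25))
        return cls(host_id, k, logp, 0.0)


def _context_indices(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(context index, next base, validity mask) for every k-window."""
    n = len(codes)
    if n < k:
        return (np.empty(0, dtype=np.int64),) * 2 + (np.empty(0, dtype=bool),)
    m = n - k + 1
    ctx = np.zeros(m, dtype=np.int64)
    valid = np.ones(m, dtype=bool)
    for j in range(k - 1):
        window = codes[j: j + m]
        ctx = ctx * 4 + np.maximum(window, 0)
        valid &= window >= 0
    nxt = codes[k - 1: k - 1 + m]
    valid &= nxt >= 0
    return ctx, nxt, valid


def train_markov(genome: SequenceRecord, k: int = 8,
                 pseudocount: float = 1.0) -> MarkovModel:
    """Train a k-mer transition model on both strands of a genome.

    Counts use add-``pseudocount`` smoothing; every context row is a
    proper conditional distribution over the 4 bases.
    """
    if genome.moltype != "dna":
        raise ValueError("train_markov requires a DNA record")
    if len(genome.seq) < 16 * k:
        logger.warning("genome %s is short (%d bp) for k=%d",
                       genome.id, len(genome.seq), k)
    counts = np.zeros((4 ** (k - 1), 4), dtype=np.float64)
    for seq in (genome.seq, revcomp(genome.seq)):
        ctx, nxt, valid = _context_indices(_encode(seq), k)
        np.add.at(counts, (ctx[valid], nxt[valid]), 1.0)
    counts += pseudocount
    logp = np.log(counts / counts.sum(axis=1, keepdims=True))
    return MarkovModel(genome.id, k, logp, pseudocount)


def wish_loglik(model: MarkovModel, virus: SequenceRecord,
                window: tuple = (-1.30, -1.20)) -> tuple[float, bool]:
    """Mean natural-log likelihood per nucleotide of a virus under a model.

    Positions whose context contains an ambiguous base are skipped.
    Passes when the value lies inside the (inclusive) window.
    """
    if len(virus.seq) < model.k:
        raise ValueError(f"virus {virus.id} shorter than k={model.k}")
    ctx, nxt, valid = _context_indices(_encode(virus.seq), model.k)
    vals = model.logp[ctx[valid], nxt[valid]]
    if len(vals) == 0:
        raise ValueError(f"virus {virus.id} has no unambiguous k-mers")
    value = float(vals.mean())
    passed = window[0] <= value <= window[1]
    return value, passed


_BASES = "ACGT"
CODONS = tuple(a + b + c for a in _BASES for b in _BASES for c in _BASES)


def codon_usage(cds_sequences: Sequence[str]) -> dict[str, float]:
    """Codon frequency table over a set of coding sequences.

    Trailing bases not forming a full codon are dropped with a warning;
    codons containing ambiguous bases are skipped. Frequencies sum to 1.
    """
    if not cds_sequences:
        raise ValueError("no coding sequences supplied")
    counts = dict.fromkeys(CODONS, 0)
    total = 0
    for seq in cds_sequences:
        seq = seq.upper()
        if len(seq) % 3:
            logger.warning("CDS length %d not a multiple of 3; tail dropped",
                           len(seq))
        for i in range(0, len(seq) - len(seq) % 3, 3):
            codon = seq[i: i + 3]
            if codon in counts:
                counts[codon] += 1
                total += 1
    if total == 0:
        raise ValueError("no countable codons in input")
    return {c: counts[c] / total for c in CODONS}


def codon_distance(table_v: Mapping[str, float],
                   table_h: Mapping[str, float]) -> float:
    """Euclidean distance between two 64-entry codon frequency vectors."""
    return math.sqrt(sum((table_v.get(c, 0.0) - table_h.get(c, 0.0)) ** 2
                         for c in CODONS))


# ---------------------------------------------------------------------------
# AMG detection and evidence integration
# ---------------------------------------------------------------------------

def detect_amg(hits: Iterable[AlignmentHit],
               host_of_protein: Mapping[str, str],
               virus_of_protein: Mapping[str, str],
               max_evalue: float = 5e-5,
               min_identity: float = 50.0,
               min_qcov: float = 50.0) -> tuple[list[HostEvidence], pd.DataFrame]:
    """Call putative AMGs from viral-ORF vs host-protein hits.

    A hit passes when ``evalue < max_evalue``, ``identity >= min_identity``
    and ``query coverage >= min_qcov``. Each passing (viral ORF, host
    gene) pair is recorded as an AMG and as host evidence.
    """
    evidence, rows = [], []
    for h in hits:
        passed = (h.evalue < max_evalue
                  and h.pct_identity >= min_identity
                  and query_coverage(h) >= min_qcov)
        if not passed:
            continue
        virus_id = virus_of_protein.get(h.query_id)
        host_id = host_of_protein.get(h.subject_id)
        if virus_id is None or host_id is None:
            raise ValueError(f"hit {h.query_id}->{h.subject_id} has unmapped "
                             "protein ids")
        rows.append({"viral_orf": h.query_id, "host_gene": h.subject_id,
                     "virus_id": virus_id, "host_id": host_id,
                     "pct_identity": h.pct_identity,
                     "query_coverage": query_coverage(h),
                     "evalue": h.evalue})
        evidence.append(HostEvidence(
            virus_id=virus_id, host_id=host_id, etype="amg",
            score=h.pct_identity, passed=True,
            detail=f"AMG {h.query_id} ~ {h.subject_id} "
                   f"({h.pct_identity:.1f}% id)"))
    cols = ["viral_orf", "host_gene", "virus_id", "host_id", "pct_identity",
            "query_coverage", "evalue"]
    return evidence, pd.DataFrame(rows, columns=cols)


def integrate(virus_id: str, evidence: Sequence[HostEvidence]) -> HostAssignment:
    """Combine all evidence for one virus into a final assignment.

    Per candidate host: strong when >= 1 passed evidence in {crispr,
    trna, amg}; supporting when >= 2 passed in {wish, codon, binning};
    otherwise no tier. Among hosts, the one with most passed strong
    evidence wins (tie-break: most total passed; remaining ties are
    reported unassigned with an ambiguity flag). Binning alone never
    assigns.
    """
    ev = [e for e in evidence if e.virus_id == virus_id]
    by_host: dict[str, list[HostEvidence]] = {}
    for e in ev:
        by_host.setdefault(e.host_id, []).append(e)

    candidates = []
    for host_id in sorted(by_host):
        items = by_host[host_id]
        n_strong = sum(1 for e in items if e.passed and e.etype in STRONG_TYPES)
        n_supp = sum(1 for e in items if e.passed and e.etype in SUPPORTING_TYPES)
        if n_strong >= 1:
            tier = "strong"
        elif n_supp >= 2:
            tier = "supporting"
        else:
            continue
        candidates.append((n_strong, n_strong + n_supp, host_id, tier))
    if not candidates:
        return HostAssignment(virus_id, None, "unassigned", ev)
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    best = candidates[0]
    ties = [c for c in candidates if c[0] == best[0] and c[1] == best[1]]
    if len(ties) > 1:
        return HostAssignment(virus_id, None, "unassigned", ev, ambiguous=True)
    return HostAssignment(virus_id, best[2], best[3], ev)


def integrate_all(evidence: Sequence[HostEvidence],
                  virus_ids: Sequence[str]) -> list[HostAssignment]:
    by_virus: dict[str, list[HostEvidence]] = {v: [] for v in virus_ids}
    for e in evidence:
        by_virus.setdefault(e.virus_id, []).append(e)
    return [integrate(v, by_virus[v]) for v in sorted(by_virus)]


def write_evidence(evidence: Sequence[HostEvidence], path) -> None:
    pd.DataFrame([e.__dict__ for e in evidence]).to_csv(path, sep="\t", index=False)


def write_assignments(assignments: Sequence[HostAssignment], path) -> None:
    rows = [{"virus_id": a.virus_id,
             "host_id": a.host_id if a.host_id is not None else "NA",
             "tier": a.tier,
             "n_evidence": len(a.evidence),
             "ambiguous": a.ambiguous} for a in assignments]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
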