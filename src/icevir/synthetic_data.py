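"""Synthetic host/virus communities with fully known planted ground truth.

Hosts are drawn from per-host order-2 Markov sequence models (Dirichlet-
perturbed around a target GC, with the GC of every transition row fixed
exactly so realized GC tracks the target) so that composition-based host
prediction has signal. Viruses paired with a host are sampled from that
host's model. The generator plants, with recorded truth: triage
pass/fail cases for every rule, genus/species structure in the protein
and nucleotide hit tables, CRISPR arrays carrying protospacers cut from
their target virus, shared tRNAs, AMGs as mutated host genes, lifestyles
(provirus flags / integrase annotations), and per-sample read
recruitment with known expected KPKG.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .abundance import SampleMeta, compute_kpkg
from .core_io import AlignmentHit, SequenceRecord, revcomp, write_fasta, write_hits
from .triage import ContigScreenRecord, length_cutoff, write_screen_table

_BASES = "ACGT"
_AA = "ACDEFGHIKLMNPQRSTVWY"

_PRODUCT_VOCAB = (
    "hypothetical protein", "major capsid protein", "terminase large subunit",
    "portal protein", "tail fiber protein", "DNA polymerase",
    "single-stranded DNA-binding protein", "holin", "endolysin",
)

TRIAGE_RULES = ("length_cutoff", "zero_information", "no_hallmark",
                "host_viral_ratio", "origin_screen")


@dataclass
class GeneratorParams:
    """Knobs of the synthetic community; ``seed`` is mandatory."""

    seed: int
    n_hosts: int = 20
    host_length: int = 100_000
    gc_content: float = 0.45
    markov_concentration: float = 1.0
    n_viruses: int = 200
    class_proportions: dict = field(default_factory=lambda: {
        "dsDNA": 0.60, "ssDNA": 0.20, "RNA": 0.05,
        "NCLDV": 0.10, "Lavidaviridae": 0.05})
    virus_length_ranges: dict = field(default_factory=lambda: {
        "dsDNA": (12_000, 25_000), "ssDNA": (3_000, 6_000),
        "RNA": (2_000, 4_000), "NCLDV": (15_000, 30_000),
        "Lavidaviridae": (12_000, 18_000)})
    temperate_fraction: float = 0.03
    n_crispr_pairs: int = 20
    n_trna_pairs: int = 20
    n_amg_pairs: int = 20
    n_binning_only: int = 10
    binning_cooccurrence_rate: float = 0.34
    amg_divergence: float = 0.10
    spacer_revcomp_rate: float = 0.30
    reverse_array_rate: float = 0.25
    n_multi_genera: int = 5
    genus_size: int = 4
    proteins_per_virus: int = 10
    proteins_per_host: int = 30
    protein_length: int = 150
    shared_families_per_genus: int = 8
    n_triage_fail_per_rule: int = 2
    read_length: int = 150
    mean_reads_per_virus: float = 100.0
    error_rate: float = 0.01
    genus_only_rate: float = 0.05
    sample_presence_rate: float = 0.90
    dataset_size_bp: int = 100_000_000
    repeat_length: int = 28
    spacer_length: int = 32
    min_spacers_per_array: int = 2
    max_spacers_per_array: int = 5
    trna_length: int = 72

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        total = sum(self.class_proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError("class proportions must sum to 1")
        for name in ("temperate_fraction", "amg_divergence", "error_rate",
                     "genus_only_rate", "sample_presence_rate",
                     "spacer_revcomp_rate", "reverse_array_rate",
                     "binning_cooccurrence_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        n_strong = self.n_crispr_pairs + self.n_trna_pairs + self.n_amg_pairs
        n_fail = self.n_triage_fail_per_rule * len(TRIAGE_RULES)
        if n_strong + self.n_binning_only + n_fail > self.n_viruses:
            raise ValueError("not enough viruses for the requested plantings")
        if self.n_amg_pairs > self.n_hosts * self.proteins_per_host:
            raise ValueError("more AMGs requested than host genes available")


@dataclass
class SyntheticTruth:
    """Everything the generator planted, for scoring downstream stages."""

    host_of: dict = field(default_factory=dict)           # virus -> host
    evidence_of: dict = field(default_factory=dict)       # virus -> [etype...]
    amg_pairs: list = field(default_factory=list)         # (viral_orf, host_gene)
    lifestyle: dict = field(default_factory=dict)         # virus -> temperate|lytic
    abundance: dict = field(default_factory=dict)         # virus -> {sample: kpkg}
    expected_reads: dict = field(default_factory=dict)    # virus -> {sample: lambda}
    planted_spacers: dict = field(default_factory=dict)   # host -> [(seq, virus)]
    planted_trnas: dict = field(default_factory=dict)     # virus -> {host: seq}
    genus_of: dict = field(default_factory=dict)          # virus -> genus label
    species_of: dict = field(default_factory=dict)        # virus -> species label
    triage_pass: list = field(default_factory=list)
    triage_fail: dict = field(default_factory=dict)       # virus -> rule
    binning_only: list = field(default_factory=list)
    crispr_arrays: dict = field(default_factory=dict)     # host -> [array meta]
    dominant_virus: Optional[str] = None

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


@dataclass
class SyntheticCommunity:
    params: GeneratorParams
    hosts: list
    host_proteins: dict
    viruses: list
    virus_proteins: dict
    screen_records: list
    annotations: dict          # contig -> [product, ...]
    protein_hits: list
    amg_hits: list
    nucleotide_hits: list
    viral_trnas: dict          # virus -> [SequenceRecord]
    binning: dict              # virus -> bin id
    samples: list
    recruitment: dict          # sample -> [AlignmentHit]
    truth: SyntheticTruth


# ---------------------------------------------------------------------------
# Sequence sampling
# ---------------------------------------------------------------------------

def _make_transition(rng: np.random.Generator, gc: float,
                     concentration: float) -> np.ndarray:
    """Order-2 transition table (16 contexts x ACGT), row GC fixed at ``gc``."""
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    rows = rng.dirichlet(base * 4 * concentration, size=16)
    at = rows[:, 0] + rows[:, 3]
    cg = rows[:, 1] + rows[:, 2]
    rows[:, 0] *= (1 - gc) / at
    rows[:, 3] *= (1 - gc) / at
    rows[:, 1] *= gc / cg
    rows[:, 2] *= gc / cg
    return rows


def _sample_markov(trans: np.ndarray, length: int, rand: random.Random) -> str:
    cum = trans.cumsum(axis=1)
    cum[:, -1] = 1.0
    rows = cum.tolist()
    marg = trans.mean(axis=0).cumsum()
    marg[-1] = 1.0
    marg = marg.tolist()
    out = []
    ctx = 0
    rnd = rand.random
    for t in range(length):
        r = rnd()
        row = marg if t < 2 else rows[ctx]
        b = 0
        while row[b] < r:
            b += 1
        out.append(_BASES[b])
        ctx = (ctx * 4 + b) % 16
    return "".join(out)


def _random_protein(rand: random.Random, length: int) -> str:
    return "".join(rand.choices(_AA, k=length))


def _other_base(c: str, rand: random.Random) -> str:
    return rand.choice([b for b in _BASES if b != c])


# ---------------------------------------------------------------------------
# generate_hosts
# ---------------------------------------------------------------------------

def generate_hosts(params: GeneratorParams):
    """Host genomes + protein sets + per-host transition tables.

    Deterministic for a fixed seed: two calls with equal params yield
    byte-identical output.
    """
    rng = np.random.default_rng([params.seed, 1])
    rand = random.Random(int(rng.integers(2 ** 31)))
    hosts, proteins, tables = [], {}, {}
    for i in range(params.n_hosts):
        hid = f"h{i:03d}"
        trans = _make_transition(rng, params.gc_content,
                                 params.markov_concentration)
        tables[hid] = trans
        hosts.append(SequenceRecord(
            hid, _sample_markov(trans, params.host_length, rand)))
        proteins[hid] = [
            SequenceRecord(f"{hid}_p{j:03d}",
                           _random_protein(rand, params.protein_length),
                           "protein")
            for j in range(params.proteins_per_host)]
    return hosts, proteins, tables


# ---------------------------------------------------------------------------
# generate_viruses
# ---------------------------------------------------------------------------

def _class_counts(params: GeneratorParams) -> list[str]:
    """Per-virus class labels via largest-remainder apportionment."""
    items = sorted(params.class_proportions.items())
    raw = [(name, params.n_viruses * frac) for name, frac in items]
    counts = {name: int(x) for name, x in raw}
    short = params.n_viruses - sum(counts.values())
    for name, _ in sorted(raw, key=lambda t: -(t[1] - int(t[1])))[:short]:
        counts[name] += 1
    labels = [name for name, c in sorted(counts.items()) for _ in range(c)]
    return labels


def _plant(seq_list: list, start: int, insert: str) -> None:
    """Overwrite characters of a mutable char-list in place."""
    seq_list[start: start + len(insert)] = list(insert)


def _reserve(occupied: list, start: int, end: int) -> bool:
    """Reserve [start, end) unless it overlaps an existing reservation."""
    for s, e in occupied:
        if not (end <= s or start >= e):
            return False
    occupied.append((start, end))
    return True


def generate_viruses(params: GeneratorParams, hosts, host_proteins,
                     host_tables, truth: SyntheticTruth):
    """Viral genomes, screening table, proteins, hit tables, plantings.

    Returns an (updated hosts, virus records, virus proteins, screen
    records, annotations, protein hits, amg hits, nucleotide hits,
    viral tRNAs, binning) bundle; ``truth`` is updated in place. Host
    sequences are modified by CRISPR-array and tRNA planting.
    """
    rng = np.random.default_rng([params.seed, 2])
    rand = random.Random(int(rng.integers(2 ** 31)))
    host_ids = [h.id for h in hosts]
    host_seq = {h.id: list(h.seq) for h in hosts}
    occupied: dict[str, list] = {h: [] for h in host_ids}

    classes = _class_counts(params)
    rng.shuffle(classes)
    virus_ids = [f"v{i:03d}" for i in range(params.n_viruses)]
    vclass = dict(zip(virus_ids, classes))

    # --- triage plantings: the last ids fail, one rule each -----------------
    n_fail = params.n_triage_fail_per_rule * len(TRIAGE_RULES)
    fail_ids = virus_ids[-n_fail:] if n_fail else []
    fail_rule = {vid: TRIAGE_RULES[i // params.n_triage_fail_per_rule]
                 for i, vid in enumerate(fail_ids)}
    passing = [v for v in virus_ids if v not in fail_rule]
    truth.triage_pass = list(passing)
    truth.triage_fail = dict(fail_rule)

    # --- host pairings ------------------------------------------------------
    pool = list(passing)
    rng.shuffle(pool)
    n_strong = params.n_crispr_pairs + params.n_trna_pairs + params.n_amg_pairs
    strong = pool[:n_strong]
    crispr_vs = strong[:params.n_crispr_pairs]
    trna_vs = strong[params.n_crispr_pairs:
                     params.n_crispr_pairs + params.n_trna_pairs]
    amg_vs = strong[params.n_crispr_pairs + params.n_trna_pairs:]
    binning_only = pool[n_strong: n_strong + params.n_binning_only]
    truth.binning_only = list(binning_only)
    for i, vid in enumerate(strong):
        truth.host_of[vid] = host_ids[i % len(host_ids)]
    for vid, kind in ([(v, "crispr") for v in crispr_vs]
                      + [(v, "trna") for v in trna_vs]
                      + [(v, "amg") for v in amg_vs]):
        truth.evidence_of.setdefault(vid, []).append(kind)
    truth.dominant_virus = crispr_vs[0] if crispr_vs else (
        strong[0] if strong else passing[0])

    # --- genus / species structure (dsDNA only, equal lengths per genus) ----
    ds_passing = [v for v in passing if vclass[v] == "dsDNA"]
    need = params.n_multi_genera * params.genus_size
    if len(ds_passing) < need:
        raise ValueError("not enough passing dsDNA viruses for planted genera")
    genus_members: dict[str, list] = {}
    picked = list(rng.choice(ds_passing, size=need, replace=False))
    for g in range(params.n_multi_genera):
        members = sorted(picked[g * params.genus_size:
                                (g + 1) * params.genus_size])
        label = f"genus{g:02d}"
        genus_members[label] = members
        for k, vid in enumerate(members):
            truth.genus_of[vid] = label
            truth.species_of[vid] = f"{label}_sp{k // 2:02d}"
    for vid in passing:
        if vid not in truth.genus_of:
            truth.genus_of[vid] = f"singleton_{vid}"
            truth.species_of[vid] = f"singleton_{vid}"

    # --- lengths ------------------------------------------------------------
    lengths = {}
    for vid in virus_ids:
        lo, hi = params.virus_length_ranges[vclass[vid]]
        lengths[vid] = int(rng.integers(lo, hi + 1))
    for label, members in genus_members.items():
        for vid in members:
            lengths[vid] = lengths[members[0]]
    for vid in fail_ids:
        if fail_rule[vid] == "length_cutoff":
            lengths[vid] = int(length_cutoff(vclass[vid]) * 0.8)

    # --- sequences (paired viruses follow their host's composition) ---------
    viruses = []
    for vid in virus_ids:
        if vid in truth.host_of:
            trans = host_tables[truth.host_of[vid]]
        else:
            trans = _make_transition(rng, params.gc_content,
                                     params.markov_concentration)
        viruses.append(SequenceRecord(
            vid, _sample_markov(trans, lengths[vid], rand)))
    vseq = {v.id: list(v.seq) for v in viruses}

    # --- shared tRNAs: identical copy in virus and host ----------------------
    viral_trnas: dict[str, list] = {}
    for vid in trna_vs:
        hid = truth.host_of[vid]
        t = "".join(rand.choices(_BASES, k=params.trna_length))
        vpos = rand.randrange(200, lengths[vid] - 200 - params.trna_length)
        _plant(vseq[vid], vpos, t)
        while True:
            hpos = rand.randrange(500, params.host_length - 500 - params.trna_length)
            if _reserve(occupied[hid], hpos - 1, hpos + params.trna_length + 1):
                break
        _plant(host_seq[hid], hpos, t)
        viral_trnas[vid] = [SequenceRecord(f"{vid}_trna0", t)]
        truth.planted_trnas.setdefault(vid, {})[hid] = t

    # --- CRISPR arrays: spacers cut from the paired virus --------------------
    rep_len, sp_len = params.repeat_length, params.spacer_length
    for vid in crispr_vs:
        hid = truth.host_of[vid]
        n_sp = rand.randint(params.min_spacers_per_array,
                            params.max_spacers_per_array)
        repeat = "".join(rand.choices(_BASES, k=rep_len))
        spacers = []
        for _ in range(n_sp):
            p = rand.randrange(0, lengths[vid] - sp_len)
            s = "".join(vseq[vid][p: p + sp_len])
            if rand.random() < params.spacer_revcomp_rate:
                s = revcomp(s)
            spacers.append(s)
        array = repeat + "".join(s + repeat for s in spacers)
        strand = "-" if rand.random() < params.reverse_array_rate else "+"
        planted = array if strand == "+" else revcomp(array)
        while True:
            hpos = rand.randrange(500, params.host_length - 500 - len(planted))
            if _reserve(occupied[hid], hpos - 1, hpos + len(planted) + 1):
                break
        _plant(host_seq[hid], hpos, planted)
        # flanking bases must break repeat extension at the exact boundary
        period = rep_len + sp_len
        first_fwd_spacer = planted[rep_len: period]
        host_seq[hid][hpos + len(planted)] = _other_base(first_fwd_spacer[0], rand)
        host_seq[hid][hpos - 1] = _other_base(first_fwd_spacer[-1], rand)
        truth.planted_spacers.setdefault(hid, []).extend(
            (s, vid) for s in spacers)
        truth.crispr_arrays.setdefault(hid, []).append({
            "start": hpos, "end": hpos + len(planted),
            "repeat_len": rep_len, "n_copies": n_sp + 1,
            "period": period, "strand": strand, "virus_id": vid})

    # --- proteins and the all-vs-all protein hit table ------------------------
    virus_proteins: dict[str, list] = {}
    for vid in virus_ids:
        virus_proteins[vid] = [
            SequenceRecord(f"{vid}_p{j:03d}",
                           _random_protein(rand, params.protein_length),
                           "protein")
            for j in range(params.proteins_per_virus)]

    protein_hits: list[AlignmentHit] = []
    plen = params.protein_length
    for label, members in genus_members.items():
        for fam in range(min(params.shared_families_per_genus,
                             params.proteins_per_virus)):
            prots = [f"{m}_p{fam:03d}" for m in members]
            for i in range(len(prots)):
                for j in range(i + 1, len(prots)):
                    bits = float(rng.uniform(80, 200))
                    protein_hits.append(AlignmentHit(
                        prots[i], prots[j], float(rng.uniform(40, 80)), plen,
                        0, 0, 1, plen, 1, plen, 1e-30, bits, q_len=plen))
    all_prot_ids = [p.id for v in virus_ids for p in virus_proteins[v]]
    for idx in range(0, len(all_prot_ids), 20):  # self-hits, dropped downstream
        pid = all_prot_ids[idx]
        protein_hits.append(AlignmentHit(pid, pid, 100.0, plen, 0, 0, 1, plen,
                                         1, plen, 1e-80, 300.0, q_len=plen))
    for _ in range(20):  # sub-threshold noise pairs
        a, b = rng.choice(len(all_prot_ids), size=2, replace=False)
        protein_hits.append(AlignmentHit(
            all_prot_ids[int(a)], all_prot_ids[int(b)], 25.0, 50, 30, 2,
            1, 50, 1, 50, 1e-3, 30.0, q_len=plen))

    # --- AMGs: mutated copies of host genes -----------------------------------
    amg_hits: list[AlignmentHit] = []
    used_genes: set[str] = set()
    for vid in amg_vs:
        hid = truth.host_of[vid]
        gene = next(p for p in host_proteins[hid] if p.id not in used_genes)
        used_genes.add(gene.id)
        aa = list(gene.seq)
        n_sub = 0
        for i in range(len(aa)):
            if rand.random() < params.amg_divergence:
                aa[i] = rand.choice([x for x in _AA if x != aa[i]])
                n_sub += 1
        orf_id = f"{vid}_amg0"
        virus_proteins[vid].append(
            SequenceRecord(orf_id, "".join(aa), "protein"))
        identity = 100.0 * (len(aa) - n_sub) / len(aa)
        amg_hits.append(AlignmentHit(
            orf_id, gene.id, identity, len(aa), n_sub, 0, 1, len(aa),
            1, len(aa), 1e-40, 250.0, q_len=len(aa)))
        truth.amg_pairs.append([orf_id, gene.id])
    for _ in range(5):  # decoys failing the identity/evalue cutoffs
        vid = passing[int(rng.integers(len(passing)))]
        hid = host_ids[int(rng.integers(len(host_ids)))]
        gene = host_proteins[hid][int(rng.integers(params.proteins_per_host))]
        amg_hits.append(AlignmentHit(
            f"{vid}_p000", gene.id, 30.0, plen, 90, 3, 1, plen, 1, plen,
            1e-3, 40.0, q_len=plen))

    # --- nucleotide hits encoding the genus/species similarity structure -----
    nucleotide_hits: list[AlignmentHit] = []
    for label, members in genus_members.items():
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                a, b = members[i], members[j]
                la = lengths[a]
                same_species = truth.species_of[a] == truth.species_of[b]
                if same_species:
                    frac, ident = 1.0, 97.0
                else:
                    frac, ident = 0.85, 90.0
                span = int(round(frac * la))
                nucleotide_hits.append(AlignmentHit(
                    a, b, ident, span, int(span * (1 - ident / 100)), 0,
                    1, span, 1, span, 0.0, 2.0 * span, q_len=la))

    # --- screening table, lifestyles, annotations -----------------------------
    screen_records, annotations = [], {}
    for vid in virus_ids:
        cls = vclass[vid]
        products = list(rand.choices(_PRODUCT_VOCAB,
                                     k=max(params.proteins_per_virus - 2, 1)))
        rule = fail_rule.get(vid)
        temperate = rule is None and rand.random() < params.temperate_fraction
        is_provirus = temperate and rand.random() < 0.5
        if temperate and not is_provirus:
            products.append("integrase")
        truth.lifestyle[vid] = "temperate" if temperate else "lytic"

        hallmark = rand.randint(1, 4)
        viral = hallmark + rand.randint(0, 10)
        host_genes = rand.randint(0, max(viral, hallmark) - 1)
        origin = rand.uniform(0.55, 1.0)
        if is_provirus:
            host_genes = viral + rand.randint(0, 3)  # ratio rule is waived
        if rule == "zero_information":
            hallmark, host_genes, is_provirus = 0, 0, False
        elif rule == "no_hallmark":
            hallmark, host_genes = 0, rand.randint(1, 3)
        elif rule == "host_viral_ratio":
            hallmark, is_provirus = rand.randint(1, 3), False
            viral = hallmark + rand.randint(0, 3)
            host_genes = max(viral, hallmark) + rand.randint(0, 4)
        elif rule == "origin_screen":
            origin = rand.uniform(0.15, 0.45)
        screen_records.append(ContigScreenRecord(
            contig_id=vid, length=lengths[vid], viral_class=cls,
            hallmark_count=hallmark, viral_gene_count=viral,
            host_gene_count=host_genes, is_provirus=is_provirus,
            viral_origin_score=round(origin, 3)))
        annotations[vid] = products

    # --- binning table ---------------------------------------------------------
    binning = {}
    for vid in binning_only:
        binning[vid] = host_ids[int(rng.integers(len(host_ids)))]
    for vid in strong:
        if rng.random() < params.binning_cooccurrence_rate:
            binning[vid] = truth.host_of[vid]

    new_hosts = [SequenceRecord(h.id, "".join(host_seq[h.id])) for h in hosts]
    new_viruses = [SequenceRecord(v.id, "".join(vseq[v.id])) for v in viruses]
    return (new_hosts, new_viruses, virus_proteins, screen_records,
            annotations, protein_hits, amg_hits, nucleotide_hits,
            viral_trnas, binning)


# ---------------------------------------------------------------------------
# generate_recruitment
# ---------------------------------------------------------------------------

def default_samples(params: GeneratorParams) -> list[SampleMeta]:
    out = []
    for kind, tag in (("metagenome", "mg"), ("metatranscriptome", "mt")):
        for depth in (30, 180, 330):
            out.append(SampleMeta(f"s_{tag}_{depth}", kind,
                                  params.dataset_size_bp, f"{depth} m"))
    return out


def generate_recruitment(params: GeneratorParams, viruses,
                         truth: SyntheticTruth,
                         samples: Optional[Sequence[SampleMeta]] = None):
    """Per-sample recruitment hit tables with known expected KPKG.

    Read counts are Poisson around a per-(virus, sample) expectation;
    reads carry binomial per-base errors at ``params.error_rate``. The
    planted dominant virus is boosted tenfold in metatranscriptome
    samples. Species-tier expected KPKG is recorded in the truth.
    """
    if samples is None:
        samples = default_samples(params)
    for s in samples:
        if s.dataset_size_bp <= 0:
            raise ValueError("zero dataset size")
    rng = np.random.default_rng([params.seed, 3])
    read_len = params.read_length
    recruitment: dict[str, list] = {s.sample_id: [] for s in samples}
    min_len = min(len(v.seq) for v in viruses)

    for virus in viruses:
        L = len(virus.seq)
        if L <= read_len:
            continue
        base = float(rng.uniform(0.5, 2.0)) * params.mean_reads_per_virus
        for s in samples:
            lam = base if rng.random() < params.sample_presence_rate else 0.0
            if virus.id == truth.dominant_virus and s.kind == "metatranscriptome":
                # KPKG is length-normalized: boost past any 2x-mean competitor
                lam = 3.0 * params.mean_reads_per_virus * L / min_len
            truth.expected_reads.setdefault(virus.id, {})[s.sample_id] = lam
            truth.abundance.setdefault(virus.id, {})[s.sample_id] = compute_kpkg(
                lam * read_len, L, s.dataset_size_bp)
            n = int(rng.poisson(lam)) if lam > 0 else 0
            if n == 0:
                continue
            pos = rng.integers(0, L - read_len, size=n)
            mms = rng.binomial(read_len, params.error_rate, size=n)
            n_genus = int(rng.poisson(lam * params.genus_only_rate))
            for r in range(n):
                mm = int(mms[r])
                recruitment[s.sample_id].append(AlignmentHit(
                    f"{s.sample_id}_{virus.id}_r{r:05d}", virus.id,
                    100.0 * (read_len - mm) / read_len, read_len, mm, 0,
                    1, read_len, int(pos[r]) + 1, int(pos[r]) + read_len,
                    1e-30, 2.0 * read_len - 3.0 * mm, q_len=read_len))
            # genus-tier-only extras: ~80% identity over 60% of the read
            span = int(round(0.6 * read_len))
            gpos = rng.integers(0, L - span, size=n_genus)
            gmms = rng.binomial(span, 0.2, size=n_genus)
            for r in range(n_genus):
                mm = int(gmms[r])
                recruitment[s.sample_id].append(AlignmentHit(
                    f"{s.sample_id}_{virus.id}_g{r:05d}", virus.id,
                    100.0 * (span - mm) / span, span, mm, 0,
                    1, span, int(gpos[r]) + 1, int(gpos[r]) + span,
                    1e-10, 2.0 * span - 3.0 * mm, q_len=read_len))
    return list(samples), recruitment


# ---------------------------------------------------------------------------
# Orchestration and output
# ---------------------------------------------------------------------------

def generate_community(params: GeneratorParams) -> SyntheticCommunity:
    """Run all generator stages and return the full in-memory bundle."""
    truth = SyntheticTruth()
    hosts, host_proteins, tables = generate_hosts(params)
    (hosts, viruses, virus_proteins, screen_records, annotations,
     protein_hits, amg_hits, nucleotide_hits, viral_trnas,
     binning) = generate_viruses(params, hosts, host_proteins, tables, truth)
    samples, recruitment = generate_recruitment(params, viruses, truth)
    return SyntheticCommunity(
        params=params, hosts=hosts, host_proteins=host_proteins,
        viruses=viruses, virus_proteins=virus_proteins,
        screen_records=screen_records, annotations=annotations,
        protein_hits=protein_hits, amg_hits=amg_hits,
        nucleotide_hits=nucleotide_hits, viral_trnas=viral_trnas,
        binning=binning, samples=samples, recruitment=recruitment,
        truth=truth)


def write_community(comm: SyntheticCommunity, outdir: str | Path) -> dict:
    """Write every table/FASTA of the community plus a manifest.json."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(comm.hosts, outdir / "hosts.fna")
    write_fasta(comm.viruses, outdir / "viruses.fna")
    write_fasta([p for h in sorted(comm.host_proteins)
                 for p in comm.host_proteins[h]], outdir / "proteins_host.faa")
    write_fasta([p for v in sorted(comm.virus_proteins)
                 for p in comm.virus_proteins[v]], outdir / "proteins_virus.faa")
    with open(outdir / "protein_map.tsv", "w") as fh:
        fh.write("protein_id\tgenome_id\tside\n")
        for h in sorted(comm.host_proteins):
            for p in comm.host_proteins[h]:
                fh.write(f"{p.id}\t{h}\thost\n")
        for v in sorted(comm.virus_proteins):
            for p in comm.virus_proteins[v]:
                fh.write(f"{p.id}\t{v}\tvirus\n")
    write_screen_table(comm.screen_records, outdir / "screen_table.tsv")
    with open(outdir / "annotations.tsv", "w") as fh:
        fh.write("contig_id\tproduct\n")
        for cid in sorted(comm.annotations):
            for product in comm.annotations[cid]:
                fh.write(f"{cid}\t{product}\n")
    write_hits(comm.protein_hits, outdir / "hits_protein_allvsall.tsv")
    write_hits(comm.amg_hits, outdir / "hits_amg.tsv")
    write_hits(comm.nucleotide_hits, outdir / "hits_nucleotide.tsv")
    trnas = [t for v in sorted(comm.viral_trnas) for t in comm.viral_trnas[v]]
    if trnas:
        write_fasta(trnas, outdir / "viral_trnas.fna")
    with open(outdir / "binning.tsv", "w") as fh:
        fh.write("virus_id\tbin_id\n")
        for vid in sorted(comm.binning):
            fh.write(f"{vid}\t{comm.binning[vid]}\n")
    with open(outdir / "samples.tsv", "w") as fh:
        fh.write("sample_id\tkind\tdataset_size_bp\tdepth_label\n")
        for s in comm.samples:
            fh.write(f"{s.sample_id}\t{s.kind}\t{s.dataset_size_bp}\t"
                     f"{s.depth_label}\n")
    for s in comm.samples:
        write_hits(comm.recruitment[s.sample_id],
                   outdir / f"recruitment_{s.sample_id}.tsv")
    comm.truth.to_json(outdir / "truth.json")
    manifest = {
        "seed": comm.params.seed,
        "params": asdict(comm.params),
        "files": sorted(p.name for p in outdir.iterdir()
                        if p.name != "manifest.json"),
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
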