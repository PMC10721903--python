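"""End-to-end orchestration: simulate -> triage -> network -> abundance ->
host assignment -> features, with a run manifest and truth scoring."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from itertools import combinations
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import abundance as ab
from . import features as ft
from . import host_assignment as ha
from . import network as nw
from . import triage as tr
from .core_io import Config
from .synthetic_data import (GeneratorParams, SyntheticCommunity,
                             SyntheticTruth, generate_community,
                             write_community)

logger = logging.getLogger("icevir")


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def similarity_matrix(nucleotide_hits, genome_lengths: dict) -> pd.DataFrame:
    """Pairwise intergenomic similarity over all genomes (diagonal 100)."""
    ids = sorted(genome_lengths)
    mat = pd.DataFrame(0.0, index=ids, columns=ids)
    np.fill_diagonal(mat.values, 100.0)
    by_pair: dict[tuple, list] = {}
    for h in nucleotide_hits:
        if h.query_id in genome_lengths and h.subject_id in genome_lengths:
            key = tuple(sorted((h.query_id, h.subject_id)))
            by_pair.setdefault(key, []).append(h)
    for (a, b), hits in by_pair.items():
        qa = [h for h in hits if h.query_id == a]
        use, query = (qa, a) if qa else (hits, b)
        sim = nw.intergenomic_similarity(use, genome_lengths[a],
                                         genome_lengths[b], genome_a=query)
        mat.loc[a, b] = mat.loc[b, a] = sim
    return mat


def run_network_stage(comm: SyntheticCommunity, accepted: list[str],
                      cfg: Config):
    """PCs, VCs, singletons and taxa over the accepted viruses."""
    protein_genome = {p.id: vid for vid in accepted
                      for p in comm.virus_proteins[vid]}
    hits = [h for h in comm.protein_hits
            if h.query_id in protein_genome and h.subject_id in protein_genome]
    graph = nw.filter_protein_edges(hits, cfg.protein_max_evalue,
                                    cfg.protein_min_bitscore)
    params = nw.MclParams(cfg.mcl_inflation, cfg.mcl_expansion,
                          cfg.mcl_pruning, cfg.mcl_max_iterations,
                          cfg.mcl_tolerance)
    pcs = nw.protein_clusters(graph, protein_genome, protein_genome, params)
    scores = nw.genome_pair_scores(pcs, accepted)
    vcs, singletons = nw.build_vcs(scores, accepted, cfg.vc_score_threshold,
                                   params)
    lengths = {v.id: len(v.seq) for v in comm.viruses if v.id in set(accepted)}
    simmat = similarity_matrix(comm.nucleotide_hits, lengths)
    species_of, genus_of = nw.demarcate_taxa(simmat, cfg.species_cutoff,
                                             cfg.genus_cutoff)
    return {"pcs": pcs, "scores": scores, "vcs": vcs,
            "singletons": singletons, "similarity": simmat,
            "species_of": species_of, "genus_of": genus_of}


def run_host_stage(comm: SyntheticCommunity, accepted: list[str], cfg: Config):
    """All evidence types + integrated assignments for accepted viruses."""
    acc = set(accepted)
    viruses = [v for v in comm.viruses if v.id in acc]
    evidence: list[ha.HostEvidence] = []

    arrays = []
    for host in comm.hosts:
        arrays.extend(ha.detect_crispr(
            host, cfg.crispr_min_repeats, cfg.crispr_repeat_len,
            cfg.crispr_spacer_len, cfg.crispr_max_repeat_mismatch))
    evidence += ha.match_spacers(arrays, viruses, cfg.spacer_max_mismatches)

    trnas = {v: comm.viral_trnas[v] for v in comm.viral_trnas if v in acc}
    evidence += ha.match_trna(trnas, comm.hosts, cfg.trna_min_aln_len,
                              cfg.trna_min_identity, cfg.trna_max_mismatches)

    models = [ha.train_markov(h, cfg.wish_k, cfg.wish_pseudocount)
              for h in comm.hosts]
    for virus in viruses:
        for model in models:
            value, passed = ha.wish_loglik(model, virus, cfg.wish_window)
            evidence.append(ha.HostEvidence(
                virus.id, model.host_id, "wish", value, passed,
                f"mean ln-likelihood {value:.4f}"))

    def _trim(seq: str) -> str:
        return seq[: len(seq) - len(seq) % 3]

    host_tables = {h.id: ha.codon_usage([_trim(h.seq)]) for h in comm.hosts}
    for virus in viruses:
        vt = ha.codon_usage([_trim(virus.seq)])
        for hid in sorted(host_tables):
            d = ha.codon_distance(vt, host_tables[hid])
            evidence.append(ha.HostEvidence(
                virus.id, hid, "codon", d, d <= cfg.codon_distance_cutoff,
                f"codon distance {d:.4f}"))

    host_of_protein = {p.id: hid for hid, ps in comm.host_proteins.items()
                       for p in ps}
    virus_of_protein = {p.id: vid for vid, ps in comm.virus_proteins.items()
                        for p in ps if vid in acc}
    amg_hits = [h for h in comm.amg_hits if h.query_id in virus_of_protein]
    amg_ev, amg_table = ha.detect_amg(
        amg_hits, host_of_protein, virus_of_protein, cfg.amg_max_evalue,
        cfg.amg_min_identity, cfg.amg_min_qcov)
    evidence += amg_ev

    for vid in sorted(comm.binning):
        if vid in acc:
            evidence.append(ha.HostEvidence(
                vid, comm.binning[vid], "binning", 1.0, True,
                f"binned with {comm.binning[vid]}"))

    assignments = ha.integrate_all(evidence, accepted)
    return {"arrays": arrays, "evidence": evidence,
            "assignments": assignments, "amg_table": amg_table}


def run_all(params: GeneratorParams, cfg: Optional[Config] = None,
            outdir: Optional[str | Path] = None) -> dict:
    """Full synthetic run; returns all stage results (and writes ``outdir``).

    Stage order: simulate, triage, network, abundance, hosts, features,
    report. Any stage failure aborts with the stage name; previously
    written outputs are preserved.
    """
    cfg = cfg or Config(seed=params.seed)
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "simulate"
    try:
        comm = generate_community(params)
        results["community"] = comm
        if out is not None:
            write_community(comm, out / "synthetic")

        stage = "triage"
        decisions, summary = tr.triage_dataset(
            comm.screen_records, cfg.min_origin_score, cfg.apply_origin_screen)
        accepted = [d.contig_id for d in decisions if d.verdict == "accepted"]
        results["decisions"], results["summary"] = decisions, summary
        results["accepted"] = accepted
        if out is not None:
            tr.write_decisions(decisions, out / "decisions.tsv")
            summary.to_csv(out / "summary.tsv", sep="\t")

        stage = "network"
        results["network"] = run_network_stage(comm, accepted, cfg)
        if out is not None:
            nw.write_vcs(results["network"]["vcs"],
                         results["network"]["singletons"], out)
            results["network"]["similarity"].to_csv(
                out / "similarity_matrix.tsv", sep="\t")

        stage = "abundance"
        acc = set(accepted)
        lengths = {v.id: len(v.seq) for v in comm.viruses if v.id in acc}
        recruitment = {s: [h for h in hits if h.subject_id in acc]
                       for s, hits in comm.recruitment.items()}
        profiles = {}
        for tier in ("species", "genus"):
            profiles[tier] = ab.profile(recruitment, lengths,
                                        comm.samples, tier)
        results["profiles"] = profiles
        results["top3"] = {
            kind: ab.top_n(profiles["species"], 3, kind)
            for kind in ("abundance", "activity")}
        if out is not None:
            profiles["species"].to_csv(out / "profile_species.tsv",
                                       sep="\t", index=False)
            profiles["genus"].to_csv(out / "profile_genus.tsv",
                                     sep="\t", index=False)

        stage = "hosts"
        results["hosts"] = run_host_stage(comm, accepted, cfg)
        if out is not None:
            ha.write_evidence(results["hosts"]["evidence"],
                              out / "evidence.tsv")
            ha.write_assignments(results["hosts"]["assignments"],
                                 out / "assignments.tsv")
            results["hosts"]["amg_table"].to_csv(out / "amgs.tsv", sep="\t",
                                                 index=False)

        stage = "features"
        acc_records = [r for r in comm.screen_records
                       if r.contig_id in set(accepted)]
        results["lifestyle"] = ft.lifestyle_summary(
            acc_records, comm.annotations, cfg.integrase_keywords)
        gravy_df = ft.gravy_table(
            p for vid in accepted for p in comm.virus_proteins[vid])
        results["gravy"] = gravy_df
        if out is not None:
            gravy_df.to_csv(out / "gravy.tsv", sep="\t", index=False)

        stage = "report"
        results["report"] = build_report(comm, results)
        if out is not None:
            results["report"].to_csv(out / "report.tsv", sep="\t", index=False)
            manifest = {
                "seed": params.seed,
                "config": asdict(cfg),
                "params": asdict(params),
                "stages": ["simulate", "triage", "network", "abundance",
                           "hosts", "features", "report"],
                "input_digests": {
                    p.name: _digest(p)
                    for p in sorted((out / "synthetic").glob("*.tsv"))},
            }
            (out / "manifest.json").write_text(
                json.dumps(manifest, indent=1, sort_keys=True, default=str))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return results


def build_report(comm: SyntheticCommunity, results: dict) -> pd.DataFrame:
    """One row per accepted virus joining every stage's verdicts."""
    accepted = results["accepted"]
    net = results["network"]
    vc_of = {g: vc.vc_id for vc in net["vcs"] for g in vc.members}
    assign = {a.virus_id: a for a in results["hosts"]["assignments"]}
    amg_counts = results["hosts"]["amg_table"].groupby("virus_id").size()
    screen = {r.contig_id: r for r in comm.screen_records}
    kws = tuple(k.lower() for k in ft.DEFAULT_INTEGRASE_KEYWORDS)

    species_prof = results["profiles"]["species"]
    kpkg = species_prof.pivot(index="contig_id", columns="sample_id",
                              values="kpkg")
    rows = []
    for vid in accepted:
        a = assign.get(vid)
        has_int = any(any(k in str(p).lower() for k in kws)
                      for p in comm.annotations.get(vid, ()))
        row = {
            "virus_id": vid,
            "viral_class": screen[vid].viral_class,
            "length": screen[vid].length,
            "vc": vc_of.get(vid, "singleton"),
            "species": net["species_of"].get(vid, "NA"),
            "genus": net["genus_of"].get(vid, "NA"),
            "host": a.host_id if a and a.host_id else "NA",
            "host_tier": a.tier if a else "unassigned",
            "n_amg": int(amg_counts.get(vid, 0)),
            "lifestyle": ("temperate"
                          if screen[vid].is_provirus or has_int else "lytic"),
        }
        for sample in kpkg.columns:
            row[f"kpkg_{sample}"] = float(kpkg.loc[vid, sample])
        rows.append(row)
    return pd.DataFrame(rows)


def _pairwise_prf(pred_partition: dict, true_partition: dict,
                  items: list) -> tuple[float, float]:
    """Pairwise precision/recall of co-clustering decisions."""
    tp = fp = fn = 0
    for a, b in combinations(sorted(items), 2):
        same_pred = pred_partition.get(a) is not None and \
            pred_partition.get(a) == pred_partition.get(b)
        same_true = true_partition.get(a) == true_partition.get(b)
        if same_pred and same_true:
            tp += 1
        elif same_pred:
            fp += 1
        elif same_true:
            fn += 1
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return precision, recall


def score_against_truth(results: dict, truth: SyntheticTruth) -> pd.DataFrame:
    """Per-stage precision/recall and error metrics on a synthetic run."""
    rows = []

    accepted = set(results["accepted"])
    true_pass = set(truth.triage_pass)
    tp = len(accepted & true_pass)
    rows.append({"stage": "triage", "metric": "precision",
                 "value": tp / len(accepted) if accepted else float("nan")})
    rows.append({"stage": "triage", "metric": "recall",
                 "value": tp / len(true_pass) if true_pass else float("nan")})

    net = results["network"]
    vc_of = {g: vc.vc_id for vc in net["vcs"] for g in vc.members}
    items = sorted(accepted)
    p, r = _pairwise_prf(vc_of, truth.genus_of, items)
    rows.append({"stage": "network_vc", "metric": "pair_precision", "value": p})
    rows.append({"stage": "network_vc", "metric": "pair_recall", "value": r})
    p, r = _pairwise_prf(net["genus_of"], truth.genus_of, items)
    rows.append({"stage": "taxa_genus", "metric": "pair_precision", "value": p})
    rows.append({"stage": "taxa_genus", "metric": "pair_recall", "value": r})
    sing = nw.singleton_fraction(net["vcs"], items)
    rows.append({"stage": "network", "metric": "singleton_fraction",
                 "value": sing})

    assigns = [a for a in results["hosts"]["assignments"]
               if a.host_id is not None]
    strong_true = {v: h for v, h in truth.host_of.items() if v in accepted}
    correct = sum(1 for a in assigns if strong_true.get(a.virus_id) == a.host_id)
    rows.append({"stage": "host", "metric": "precision",
                 "value": correct / len(assigns) if assigns else float("nan")})
    rows.append({"stage": "host", "metric": "recall",
                 "value": correct / len(strong_true) if strong_true
                 else float("nan")})
    binned_assigned = sum(1 for a in assigns if a.virus_id in
                          set(truth.binning_only))
    rows.append({"stage": "host", "metric": "binning_only_assigned",
                 "value": float(binned_assigned)})

    amg_pred = {(r_.viral_orf, r_.host_gene)
                for r_ in results["hosts"]["amg_table"].itertuples()}
    amg_true = {tuple(p_) for p_ in truth.amg_pairs
                if p_[0].split("_")[0] in accepted}
    tp = len(amg_pred & amg_true)
    rows.append({"stage": "amg", "metric": "precision",
                 "value": tp / len(amg_pred) if amg_pred else float("nan")})
    rows.append({"stage": "amg", "metric": "recall",
                 "value": tp / len(amg_true) if amg_true else float("nan")})

    prof = results["profiles"]["species"]
    est = prof.set_index(["contig_id", "sample_id"])["kpkg"]
    errs = []
    for vid, by_sample in truth.abundance.items():
        if vid not in accepted:
            continue
        for sample, expected in by_sample.items():
            lam = truth.expected_reads[vid][sample]
            if lam < 100:
                continue
            e = est.get((vid, sample), 0.0)
            errs.append(abs(e - expected) / expected)
    rows.append({"stage": "abundance", "metric": "mean_rel_error_kpkg",
                 "value": float(np.mean(errs)) if errs else float("nan")})

    ls = results["lifestyle"]
    rows.append({"stage": "lifestyle", "metric": "temperate_fraction",
                 "value": ls.fraction})
    true_frac = (sum(1 for v in accepted
                     if truth.lifestyle.get(v) == "temperate")
                 / max(len(accepted), 1))
    rows.append({"stage": "lifestyle", "metric": "planted_fraction",
                 "value": true_frac})
    return pd.DataFrame(rows)
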