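import math
import random

import numpy as np
import pytest

from icevir.core_io import AlignmentHit, SequenceRecord, revcomp
from icevir.host_assignment import (CrisprArray, HostEvidence, MarkovModel,
                                    codon_distance, codon_usage, detect_amg,
                                    detect_crispr, integrate, integrate_all,
                                    match_spacers, match_trna, search_ungapped,
                                    train_markov, wish_loglik)


def _rand_dna(rand, n):
    return "".join(rand.choices("ACGT", k=n))


def _plant_array(rand, n_spacers=3, background=3_000, reverse=False):
    """Background sequence with one planted repeat-spacer array.

    Returns (sequence, start, end, spacers). Flanking bases are set so
    repeat extension stops exactly at the planted boundary.
    """
    bg = list(_rand_dna(rand, background))
    repeat = _rand_dna(rand, 28)
    spacers = [_rand_dna(rand, 32) for _ in range(n_spacers)]
    array = repeat + "".join(s + repeat for s in spacers)
    if reverse:
        array = revcomp(array)
    pos = rand.randrange(100, background - 100 - len(array))
    bg[pos: pos + len(array)] = list(array)
    first_spacer = array[28: 60]
    bg[pos + len(array)] = rand.choice(
        [b for b in "ACGT" if b != first_spacer[0]])
    bg[pos - 1] = rand.choice([b for b in "ACGT" if b != first_spacer[-1]])
    return "".join(bg), pos, pos + len(array), spacers


class TestDetectCrispr:
    def test_planted_array_exact(self):
        rand = random.Random(1)
        seq, start, end, spacers = _plant_array(rand, n_spacers=3)
        arrays = detect_crispr(SequenceRecord("h", seq))
        assert len(arrays) == 1
        a = arrays[0]
        assert (a.start, a.end) == (start, end)
        assert len(a.spacers) == 3
        assert len(a.repeat_consensus) == 28
        # spacer coordinates are exact
        for s, p in a.spacers:
            assert seq[p: p + len(s)] == s

    def test_two_arrays_opposite_strands(self):
        rand = random.Random(2)
        seq1, s1, e1, _ = _plant_array(rand, n_spacers=2)
        seq2, s2, e2, _ = _plant_array(rand, n_spacers=4, reverse=True)
        seq = seq1 + seq2
        arrays = detect_crispr(SequenceRecord("h", seq))
        spans = {(a.start, a.end) for a in arrays}
        assert spans == {(s1, e1), (len(seq1) + s2, len(seq1) + e2)}

    def test_no_false_positives_random(self):
        for seed in range(5):
            rand = random.Random(100 + seed)
            rec = SequenceRecord(f"r{seed}", _rand_dna(rand, 5_000))
            assert detect_crispr(rec) == []

    def test_requires_dna(self):
        with pytest.raises(ValueError):
            detect_crispr(SequenceRecord("p", "MKV", moltype="protein"))

    def test_invariants(self):
        with pytest.raises(ValueError):
            CrisprArray("h", "A" * 28, [0, 60], [("C" * 32, 28)])
        with pytest.raises(ValueError):
            CrisprArray("h", "A" * 28, [0, 60, 120], [("C" * 32, 28)])

    def test_planted_truth_recovery(self, small_community):
        comm = small_community
        for host in comm.hosts:
            planted = comm.truth.crispr_arrays.get(host.id, [])
            found = detect_crispr(host)
            assert len(found) == len(planted)
            found_spans = {(a.start, a.end) for a in found}
            assert found_spans == {(m["start"], m["end"]) for m in planted}


class TestSearchUngapped:
    def test_exact(self):
        assert search_ungapped("ACGT", "TTACGTTT", 0) == (0, 2, "+")

    def test_reverse(self):
        assert search_ungapped("AAAA", "CCTTTTCC", 0) == (0, 2, "-")

    def test_none(self):
        assert search_ungapped("ACGT", "GGGGGGGG", 0) is None

    def test_matches_brute_force(self):
        rand = random.Random(7)
        for _ in range(40):
            subject = _rand_dna(rand, 60)
            q = _rand_dna(rand, 12)
            max_mm = rand.randint(0, 3)
            got = search_ungapped(q, subject, max_mm)
            # brute force over all windows and strands
            best = None
            for strand, qs in (("+", q), ("-", revcomp(q))):
                for w in range(len(subject) - len(q) + 1):
                    mm = sum(a != b for a, b in zip(qs, subject[w: w + len(q)]))
                    if mm <= max_mm:
                        cand = (mm, w, strand)
                        if best is None or (cand[0], cand[1],
                                            strand != "+") < (best[0], best[1],
                                                              best[2] != "+"):
                            best = cand
            assert got == best


class TestMatchSpacers:
    def _array(self, spacer):
        return CrisprArray("h1", "G" * 28, [0, 60, 120],
                           [(spacer, 28), ("T" * 32, 88)])

    def test_exact_protospacer(self):
        rand = random.Random(3)
        spacer = _rand_dna(rand, 32)
        virus = SequenceRecord("v1", _rand_dna(rand, 500) + spacer
                               + _rand_dna(rand, 500))
        evs = match_spacers([self._array(spacer)], [virus])
        hit = [e for e in evs if e.passed]
        assert hit and hit[0].score == 0 and hit[0].etype == "crispr"
        assert hit[0].virus_id == "v1" and hit[0].host_id == "h1"

    def test_two_mismatches_not_passed(self):
        rand = random.Random(4)
        spacer = _rand_dna(rand, 32)
        proto = list(spacer)
        proto[5] = {"A": "C"}.get(proto[5], "A")
        proto[20] = {"A": "C"}.get(proto[20], "A")
        virus = SequenceRecord("v1", _rand_dna(rand, 300) + "".join(proto)
                               + _rand_dna(rand, 300))
        evs = match_spacers([self._array(spacer)], [virus], max_mismatches=1)
        relevant = [e for e in evs if e.score == 2]
        assert relevant and not relevant[0].passed

    def test_reverse_complement_protospacer(self):
        rand = random.Random(5)
        spacer = _rand_dna(rand, 32)
        virus = SequenceRecord("v1", _rand_dna(rand, 300) + revcomp(spacer)
                               + _rand_dna(rand, 300))
        evs = [e for e in match_spacers([self._array(spacer)], [virus])
               if e.passed]
        assert evs and "strand -" in evs[0].detail

    def test_planted_exact_recovery_no_false_positives(self, small_community):
        comm = small_community
        arrays = [a for h in comm.hosts for a in detect_crispr(h)]
        accepted = set(comm.truth.triage_pass)
        viruses = [v for v in comm.viruses if v.id in accepted]
        evs = [e for e in match_spacers(arrays, viruses, max_mismatches=0)
               if e.passed]
        pairs = {(e.virus_id, e.host_id) for e in evs}
        planted = {(vid, hid) for vid, hid in comm.truth.host_of.items()
                   if "crispr" in comm.truth.evidence_of[vid]}
        assert pairs == planted


class TestMatchTrna:
    def _host_with(self, rand, insert):
        seq = _rand_dna(rand, 2_000) + insert + _rand_dna(rand, 2_000)
        return SequenceRecord("h1", seq)

    def test_72bp_identical_passes(self):
        rand = random.Random(6)
        t = _rand_dna(rand, 72)
        host = self._host_with(rand, t)
        evs = match_trna({"v1": [SequenceRecord("v1_t", t)]}, [host])
        assert [e.passed for e in evs] == [True]

    def test_59bp_identical_fails_length(self):
        rand = random.Random(7)
        t = _rand_dna(rand, 59)
        host = self._host_with(rand, t)
        evs = match_trna({"v1": [SequenceRecord("v1_t", t)]}, [host])
        assert evs and not evs[0].passed

    def test_below_identity_fails(self):
        rand = random.Random(8)
        t = _rand_dna(rand, 70)
        mutated = list(t)
        for i in (3, 30, 61):  # 3 mismatches -> 95.7% < 97%
            mutated[i] = {"A": "C"}.get(mutated[i], "A")
        host = self._host_with(rand, "".join(mutated))
        evs = match_trna({"v1": [SequenceRecord("v1_t", t)]}, [host])
        assert evs and not evs[0].passed
        assert evs[0].score < 97.0


class TestMarkov:
    def test_rows_sum_to_one(self):
        rand = random.Random(9)
        model = train_markov(SequenceRecord("h", _rand_dna(rand, 5_000)), k=4)
        sums = np.exp(model.logp).sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_homopolymer_limit(self):
        model = train_markov(SequenceRecord("h", "A" * 5_000), k=3)
        ctx_aa = 0  # context "AA"
        assert math.exp(model.logp[ctx_aa, 0]) > 0.99

    def test_non_dna_rejected(self):
        with pytest.raises(ValueError):
            train_markov(SequenceRecord("p", "MKV", moltype="protein"))

    def test_short_genome_warns(self, caplog):
        with caplog.at_level("WARNING", logger="icevir"):
            train_markov(SequenceRecord("h", "ACGTACGT"), k=8)
        assert "short" in caplog.text

    def test_uniform_model_exact(self):
        model = MarkovModel.uniform()
        value, passed = wish_loglik(model, SequenceRecord("v", "ACGTACGTAC"))
        assert abs(value - math.log(0.25)) < 1e-12
        assert not passed  # -1.386 lies outside [-1.30, -1.20]

    def test_window_inclusive(self):
        model = MarkovModel("m", 1, np.full((1, 4), -1.30))
        value, passed = wish_loglik(model, SequenceRecord("v", "ACGT"))
        assert value == pytest.approx(-1.30) and passed

    def test_own_beats_cross(self, small_community):
        comm = small_community
        models = {h.id: train_markov(h) for h in comm.hosts}
        rng = np.random.default_rng(0)
        for host in comm.hosts[:3]:
            p = int(rng.integers(0, len(host.seq) - 5_000))
            frag = SequenceRecord("f", host.seq[p: p + 5_000])
            own = wish_loglik(models[host.id], frag)[0]
            for other in comm.hosts:
                if other.id != host.id:
                    assert own > wish_loglik(models[other.id], frag)[0]

    def test_too_short_virus(self):
        model = MarkovModel.uniform(k=8)
        with pytest.raises(ValueError):
            wish_loglik(model, SequenceRecord("v", "ACG"))


class TestCodonUsage:
    def test_single_codon(self):
        table = codon_usage(["ATGATG"])
        assert table["ATG"] == 1.0
        assert sum(table.values()) == pytest.approx(1.0)

    def test_tail_dropped_with_warning(self, caplog):
        with caplog.at_level("WARNING", logger="icevir"):
            table = codon_usage(["ATGAT"])
        assert "dropped" in caplog.text
        assert table["ATG"] == 1.0

    def test_empty_error(self):
        with pytest.raises(ValueError):
            codon_usage([])

    def test_frequencies_sum_to_one(self):
        rand = random.Random(11)
        table = codon_usage([_rand_dna(rand, 300) for _ in range(3)])
        assert sum(table.values()) == pytest.approx(1.0)

    def test_identical_distance_zero(self):
        t = codon_usage(["ATGAAACCC"])
        assert codon_distance(t, t) == 0.0


class TestDetectAmg:
    H2H = {"h1_p1": "h1"}
    V2V = {"v1_orf": "v1"}

    def _hit(self, ident=60.0, evalue=1e-10, q_end=120, q_len=150):
        return AlignmentHit("v1_orf", "h1_p1", ident, q_end, 0, 0, 1, q_end,
                            1, q_end, evalue, 200.0, q_len=q_len)

    def test_passing_hit(self):
        evs, table = detect_amg([self._hit()], self.H2H, self.V2V)
        assert len(table) == 1 and evs[0].etype == "amg" and evs[0].passed
        assert evs[0].virus_id == "v1" and evs[0].host_id == "h1"

    def test_low_identity_rejected(self):
        evs, table = detect_amg([self._hit(ident=40.0)], self.H2H, self.V2V)
        assert len(table) == 0 and evs == []

    def test_evalue_boundary(self):
        evs, _ = detect_amg([self._hit(evalue=5e-5)], self.H2H, self.V2V)
        assert evs == []  # criterion is strictly better than 5e-5
        evs, _ = detect_amg([self._hit(evalue=4.9e-5)], self.H2H, self.V2V)
        assert len(evs) == 1

    def test_qcov_rejected(self):
        evs, _ = detect_amg([self._hit(q_end=60)], self.H2H, self.V2V)
        assert evs == []  # qcov 40 < 50

    def test_planted_amgs_recovered(self, small_community):
        comm = small_community
        h2h = {p.id: h for h, ps in comm.host_proteins.items() for p in ps}
        v2v = {p.id: v for v, ps in comm.virus_proteins.items() for p in ps}
        _, table = detect_amg(comm.amg_hits, h2h, v2v)
        got = {(r.viral_orf, r.host_gene) for r in table.itertuples()}
        assert got == {tuple(p) for p in comm.truth.amg_pairs}


def ev(virus="v1", host="h1", etype="crispr", passed=True, score=0.0):
    return HostEvidence(virus, host, etype, score, passed)


class TestIntegrate:
    def test_crispr_only_strong(self):
        a = integrate("v1", [ev()])
        assert a.tier == "strong" and a.host_id == "h1"

    def test_binning_only_unassigned(self):
        a = integrate("v1", [ev(etype="binning")])
        assert a.tier == "unassigned" and a.host_id is None

    def test_wish_plus_codon_supporting(self):
        a = integrate("v1", [ev(etype="wish"), ev(etype="codon")])
        assert a.tier == "supporting" and a.host_id == "h1"

    def test_failed_evidence_ignored(self):
        a = integrate("v1", [ev(passed=False), ev(etype="wish")])
        assert a.tier == "unassigned"

    def test_strong_beats_supporting(self):
        evidence = [ev(host="h1", etype="wish"), ev(host="h1", etype="codon"),
                    ev(host="h2", etype="trna")]
        a = integrate("v1", evidence)
        assert a.host_id == "h2" and a.tier == "strong"

    def test_ambiguous_tie(self):
        a = integrate("v1", [ev(host="h1"), ev(host="h2")])
        assert a.host_id is None and a.ambiguous

    def test_order_invariant(self):
        evidence = [ev(host="h1", etype="wish"), ev(host="h2", etype="amg"),
                    ev(host="h1", etype="codon")]
        a1 = integrate("v1", evidence)
        a2 = integrate("v1", evidence[::-1])
        assert (a1.host_id, a1.tier) == (a2.host_id, a2.tier)

    def test_integrate_all_covers_viruses(self):
        out = integrate_all([ev()], ["v1", "v2"])
        assert [a.virus_id for a in out] == ["v1", "v2"]
        assert out[1].tier == "unassigned"
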