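"""Dataset-construction tests: peak intersection, set algebra, window
extraction and subsampling, with brute-force oracles where the spec of
the operation admits one."""

import numpy as np
import pytest

from m6ahd.sites import (
    GenomicSite,
    LabeledSiteSet,
    PeakSet,
    derive_sites,
    extract_windows,
    read_fasta,
    read_peak_bed,
    read_site_bed,
    subsample_split,
    true_sites,
    write_site_tsv,
    write_window_fasta,
)


def _sites(keys, condition="c"):
    return [GenomicSite(s, p, st, condition) for s, p, st in keys]


class TestTrueSites:
    def test_containment_and_halfopen_boundary(self):
        peaks = PeakSet([("tx1", 5, 20, "+")])
        inside = GenomicSite("tx1", 10)
        at_end = GenomicSite("tx1", 20)
        at_start = GenomicSite("tx1", 5)
        kept = true_sites(peaks, [inside, at_end, at_start])
        assert kept == [inside, at_start]

    def test_strand_and_seqid_must_match(self):
        peaks = PeakSet([("tx1", 0, 100, "+")])
        assert true_sites(peaks, [GenomicSite("tx1", 50, "-")]) == []
        assert true_sites(peaks, [GenomicSite("tx2", 50, "+")]) == []

    def test_empty_inputs(self):
        assert true_sites(PeakSet([]), [GenomicSite("tx1", 1)]) == []
        assert true_sites(PeakSet([("tx1", 0, 5, "+")]), []) == []

    def test_against_quadratic_oracle(self, rng):
        peaks = PeakSet([
            (f"tx{rng.integers(5)}", int(s := rng.integers(0, 900)),
             int(s + 1 + rng.integers(100)), "+-"[rng.integers(2)])
            for _ in range(50)
        ])
        cands = [GenomicSite(f"tx{rng.integers(5)}", int(rng.integers(1000)),
                             "+-"[rng.integers(2)]) for _ in range(200)]
        expected = [
            c for c in cands
            if any(sid == c.seq_id and strand == c.strand and a <= c.pos < b
                   for sid, a, b, strand in peaks.intervals)
        ]
        assert true_sites(peaks, cands) == expected

    def test_monotone_in_peaks(self, rng):
        base = [("tx0", 10, 50, "+"), ("tx1", 5, 9, "+")]
        cands = [GenomicSite("tx0", int(p)) for p in rng.integers(0, 100, 30)]
        before = set(s.key for s in true_sites(PeakSet(base), cands))
        after = set(s.key for s in true_sites(PeakSet(base + [("tx0", 60, 90, "+")]), cands))
        assert before <= after


class TestDeriveSites:
    @pytest.fixture
    def universe(self):
        keys = [("tx", i, "+") for i in range(6)]  # a..f
        cands = _sites(keys)
        exp = cands[:3]    # {a,b,c}
        ctrl = cands[1:4]  # {b,c,d}
        return exp, ctrl, cands

    def test_up_definitional(self, universe):
        exp, ctrl, cands = universe
        out = derive_sites(exp, ctrl, cands, "up")
        assert [s.pos for s in out.positives] == [0]        # {a}
        assert [s.pos for s in out.negatives] == [1, 2]     # {b,c}

    def test_down_definitional(self, universe):
        exp, ctrl, cands = universe
        out = derive_sites(exp, ctrl, cands, "down")
        assert [s.pos for s in out.positives] == [3]        # {d}
        assert [s.pos for s in out.negatives] == [4, 5]     # {e,f}

    def test_up_unmethylated_mode(self, universe):
        exp, ctrl, cands = universe
        out = derive_sites(exp, ctrl, cands, "up", negative_mode="unmethylated")
        assert [s.pos for s in out.positives] == [0]
        assert [s.pos for s in out.negatives] == [4, 5]
        assert out.negative_mode == "unmethylated"

    def test_empty_control_degenerate(self, universe):
        exp, _, cands = universe
        out = derive_sites(exp, [], cands, "up")
        assert {s.pos for s in out.positives} == {0, 1, 2}
        assert out.negatives == []

    def test_empty_positive_set_warns(self, universe):
        _, ctrl, cands = universe
        with pytest.warns(UserWarning, match="no positive"):
            out = derive_sites([], ctrl, cands, "up")
        assert out.positives == []

    def test_partition_property(self, rng):
        # up-pos, down-pos, up-default-neg, unmethylated pool: pairwise
        # disjoint, union within candidates
        cands = _sites([("tx", int(i), "+") for i in range(50)])
        exp = [c for c in cands if rng.random() < 0.5]
        ctrl = [c for c in cands if rng.random() < 0.5]
        up = derive_sites(exp, ctrl, cands, "up")
        down = derive_sites(exp, ctrl, cands, "down")
        groups = [
            {s.key for s in up.positives},
            {s.key for s in down.positives},
            {s.key for s in up.negatives},
            {s.key for s in down.negatives},
        ]
        for i in range(4):
            for j in range(i + 1, 4):
                assert not (groups[i] & groups[j])
        assert set.union(*groups) <= {c.key for c in cands}

    def test_classes_never_overlap(self):
        with pytest.raises(ValueError, match="both classes"):
            LabeledSiteSet("c", "up", _sites([("tx", 1, "+")]),
                           _sites([("tx", 1, "+")]))


class TestExtractWindows:
    def test_exact_fit(self):
        seqs = {"tx": "G" * 15 + "A" + "G" * 15}
        [w] = extract_windows([GenomicSite("tx", 15)], seqs, 31)
        assert w.seq == "G" * 15 + "A" + "G" * 15
        assert len(w) == 31

    def test_boundary_site_dropped(self):
        seqs = {"tx": "G" * 10 + "A" + "G" * 40}
        assert extract_windows([GenomicSite("tx", 3)], seqs, 21) == []

    def test_minus_strand_reverse_complement(self):
        # hand-reversed 9-mer: + slice around pos=4 is CCGGTCAAT;
        # revcomp (RNA) = AUUGACCGG, center A
        seqs = {"tx": "CCGGTCAAT"}
        [w] = extract_windows([GenomicSite("tx", 4, "-")], seqs, 9,
                              center_check=False)
        assert w.seq == "AUUGACCGG"

    def test_center_check_drops_non_adenosine(self):
        seqs = {"tx": "C" * 21}
        assert extract_windows([GenomicSite("tx", 10)], seqs, 21) == []
        assert len(extract_windows([GenomicSite("tx", 10)], seqs, 21,
                                   center_check=False)) == 1

    def test_non_acgu_window_dropped(self):
        seqs = {"tx": "GGGGNGGGGGAGGGGGGGGGG"}
        assert extract_windows([GenomicSite("tx", 10)], seqs, 21) == []

    def test_missing_sequence_raises(self):
        with pytest.raises(KeyError, match="missing"):
            extract_windows([GenomicSite("missing", 5)], {"tx": "A" * 50}, 21)

    def test_center_is_adenosine_for_all_retained(self, small_bundle):
        _, seqs, truth = small_bundle
        sites = [GenomicSite(r.transcript, r.pos, r.strand)
                 for r in truth.head(200).itertuples()]
        ws = extract_windows(sites, seqs, 21)
        assert len(ws) == 200
        assert all(w.seq[10] == "A" for w in ws)


class TestSubsampleSplit:
    def _windows(self, n, label):
        from m6ahd.encoders import SequenceWindow
        return [SequenceWindow("GG" + "A" + "GG", site_ref=f"{label}:{i}")
                for i in range(n)]

    def _site_set(self):
        return LabeledSiteSet("c", "up", _sites([("tx", 0, "+")]),
                              _sites([("tx", 1, "+")]))

    def test_paper_counts_1000_80_20(self):
        wbc = {1: self._windows(2500, 1), 0: self._windows(2500, 0)}
        split = subsample_split(self._site_set(), wbc, 1000, 0.8, seed=3)
        tr = [l for _, l in split.train]
        te = [l for _, l in split.test]
        assert tr.count(1) == tr.count(0) == 800
        assert te.count(1) == te.count(0) == 200

    def test_clamping_warns(self):
        wbc = {1: self._windows(50, 1), 0: self._windows(500, 0)}
        with pytest.warns(UserWarning, match="only 50"):
            split = subsample_split(self._site_set(), wbc, 100, 0.8, seed=0)
        assert sum(l for _, l in split.train + split.test) == 50

    def test_deterministic_and_seed_sensitive(self):
        wbc = {1: self._windows(300, 1), 0: self._windows(300, 0)}
        def ids(split):
            return [w.site_ref for w, _ in split.train + split.test]
        a = subsample_split(self._site_set(), wbc, 100, 0.8, seed=5)
        b = subsample_split(self._site_set(), wbc, 100, 0.8, seed=5)
        c = subsample_split(self._site_set(), wbc, 100, 0.8, seed=6)
        assert ids(a) == ids(b)
        assert ids(a) != ids(c)

    def test_train_test_disjoint_by_site(self):
        wbc = {1: self._windows(300, 1), 0: self._windows(300, 0)}
        split = subsample_split(self._site_set(), wbc, 100, 0.8, seed=5)
        assert not ({w.site_ref for w, _ in split.train}
                    & {w.site_ref for w, _ in split.test})

    def test_empty_class_raises(self):
        with pytest.raises(ValueError, match="no windows"):
            subsample_split(self._site_set(), {1: [], 0: self._windows(5, 0)},
                            10, 0.8, seed=0)


class TestIO:
    def test_bed_and_fasta_round_trip(self, tmp_path, small_bundle):
        from m6ahd.simulate import emit_condition_bundle
        cfg, seqs, truth = small_bundle
        paths = emit_condition_bundle(truth, seqs, cfg, tmp_path / "bundle")
        files = paths["cond1"]
        cands = read_site_bed(files["candidates"])
        assert len(cands) == (truth["condition"] == "cond1").sum()
        peaks = read_peak_bed(files["exp_peaks"])
        assert all(a < b for _, a, b, _ in peaks.intervals)
        fa = read_fasta(files["transcripts"])
        sub = {k: v for k, v in seqs.items() if k.startswith("cond1_")}
        assert fa == sub

    def test_site_tsv_and_window_fasta_writers(self, tmp_path):
        from m6ahd.encoders import SequenceWindow
        ss = LabeledSiteSet("c", "up", _sites([("tx", 5, "+")]),
                            _sites([("tx", 9, "+")]))
        write_site_tsv(ss, tmp_path / "s.tsv")
        assert (tmp_path / "s.tsv").read_text().count("\n") == 3
        pairs = [(SequenceWindow("GGAGG", site_ref="tx:5:+"), 1)]
        write_window_fasta(pairs, tmp_path / "w.fa")
        assert read_fasta(tmp_path / "w.fa") == {"tx:5:+|1": "GGAGG"}
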