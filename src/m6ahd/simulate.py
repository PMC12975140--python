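"""Synthetic epitranscriptome generator.

Emulates the inputs of a differential-methylation study without any
sequencing data: per condition, a set of transcripts with RRACH-motif
m6A sites planted at known positions, a methylation status for each site
in the experimental and control samples, MeRIP-seq-style peak intervals
around methylated sites, and a single-base candidate list.

Generative model
----------------
Background sequence is i.i.d. with the configured GC content. Each
condition receives its own independent transcript set (drawn from the same
parameters), so conditions share the *kind* of signal but not the actual
sites — mirroring distinct disease cohorts whose differential sites obey a
common sequence grammar.

Each planted site carries a concrete instance of the degenerate motif
(default RRACH; R = A/G, H = A/C/U, anchor A methylated). Methylation
status: the control state is Bernoulli(base_methyl_rate); the experimental
sample gains a control-unmethylated site with probability ``gain_rate``
and loses a control-methylated site with probability ``loss_rate``.
Differentially methylated sites (gained or lost) additionally receive a
purine-biased flanking context within ``signal_halfwidth`` nt of the
anchor: each non-motif flank position is purine (A/G) with probability
``signal_bias`` instead of the background rate. This planted, localized
and purine-rich context is the learnable ground truth that the feature
search, window scan and importance analyses are tested against.

Sequences are written in the DNA alphabet (FASTA convention); downstream
window extraction maps T to U.
"""

from __future__ import annotations

import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["SimConfig", "generate_transcriptome", "plant_truth",
           "emit_condition_bundle", "simulate_bundle"]

_DEGENERATE = {"R": "AG", "H": "ACT", "A": "A", "C": "C", "G": "G", "T": "T", "U": "T"}


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the generator.

    Defaults define the standard benchmark bundle: 5 conditions, 250
    transcripts of 2,000 nt each, 10 sites per transcript (2,500 sites
    per condition), balanced GC, RRACH motif, base methylation 0.5 with
    gain/loss 0.3, MeRIP-style peaks of half-width 50 nt, and a purine
    bias of 0.85 within +/-8 nt of differential anchors.
    """

    n_transcripts: int = 250
    transcript_length: int = 2000
    gc_content: float = 0.5
    motif: str = "RRACH"
    site_rate: int = 10  # sites planted per transcript
    base_methyl_rate: float = 0.5
    gain_rate: float = 0.3
    loss_rate: float = 0.3
    peak_halfwidth: int = 50
    n_conditions: int = 5
    signal_bias: float = 0.85
    signal_halfwidth: int = 8
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.gc_content < 1):
            raise ValueError("gc_content must be in (0, 1)")
        for name in ("base_methyl_rate", "gain_rate", "loss_rate", "signal_bias"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.peak_halfwidth < 1:
            raise ValueError("peak_halfwidth must be >= 1")
        motif = self.motif.upper()
        if motif.count("A") != 1:
            raise ValueError("motif must contain exactly one anchor 'A'")
        if any(c not in _DEGENERATE for c in motif):
            raise ValueError(f"motif {motif!r} has unsupported codes")
        object.__setattr__(self, "motif", motif)

    @property
    def conditions(self) -> list:
        return [f"cond{i + 1}" for i in range(self.n_conditions)]


def _random_sequences(cfg: SimConfig, rng, condition: str) -> dict:
    """i.i.d. DNA background at the configured GC content."""
    p = np.array(
        [(1 - cfg.gc_content) / 2, cfg.gc_content / 2,
         cfg.gc_content / 2, (1 - cfg.gc_content) / 2]
    )
    bases = np.array(list("ACGT"))
    seqs = {}
    for i in range(cfg.n_transcripts):
        arr = rng.choice(bases, size=cfg.transcript_length, p=p)
        seqs[f"{condition}_tx{i:04d}"] = "".join(arr)
    return seqs


def generate_transcriptome(cfg: SimConfig) -> dict:
    """Background transcript sequences for every condition.

    Returns an id -> DNA string dict; ids are prefixed by their condition
    (each condition owns an independent transcript set). Deterministic for
    a fixed seed.
    """
    seqs: dict = {}
    for c, condition in enumerate(cfg.conditions):
        rng = np.random.default_rng((cfg.seed, 11, c))
        seqs.update(_random_sequences(cfg, rng, condition))
    return seqs


def _sample_motif(cfg: SimConfig, rng) -> str:
    return "".join(_DEGENERATE[c][rng.integers(len(_DEGENERATE[c]))] for c in cfg.motif)


def plant_truth(transcriptome: dict, cfg: SimConfig) -> tuple:
    """Plant motif sites and methylation states; returns (seqs, truth).

    ``seqs`` is the transcriptome with motif instances (and, for
    differential sites, biased flanks) written in; ``truth`` is a
    DataFrame with one row per site: transcript, pos (anchor, 0-based),
    strand, condition, methylated_in_exp, methylated_in_ctrl,
    differential.
    """
    motif_len = len(cfg.motif)
    anchor = cfg.motif.index("A")
    # keep full 81-nt windows extractable and peaks inside the transcript
    margin = max(41, cfg.peak_halfwidth + 1)
    pad = max(2 * cfg.signal_halfwidth + motif_len, cfg.peak_halfwidth + 1, 23) // 2 + 1
    span = cfg.transcript_length - 2 * margin
    bin_w = span // cfg.site_rate
    if bin_w < 2 * pad + 2:
        raise ValueError(
            f"cannot place {cfg.site_rate} non-overlapping sites in "
            f"{cfg.transcript_length}-nt transcripts"
        )

    seqs = {k: list(v) for k, v in transcriptome.items()}
    rows = []
    for c, condition in enumerate(cfg.conditions):
        rng = np.random.default_rng((cfg.seed, 23, c))
        tx_ids = [t for t in transcriptome if t.startswith(condition + "_")]
        for tx in tx_ids:
            arr = seqs[tx]
            for b in range(cfg.site_rate):
                lo = margin + b * bin_w + pad
                hi = margin + (b + 1) * bin_w - pad
                start = int(rng.integers(lo, hi))  # motif start
                pos = start + anchor
                inst = _sample_motif(cfg, rng)
                arr[start : start + motif_len] = list(inst)

                ctrl = rng.random() < cfg.base_methyl_rate
                if ctrl:
                    exp = not (rng.random() < cfg.loss_rate)
                else:
                    exp = rng.random() < cfg.gain_rate
                differential = exp != ctrl
                if differential and cfg.signal_halfwidth > 0:
                    for off in range(-cfg.signal_halfwidth, cfg.signal_halfwidth + 1):
                        j = pos + off
                        if start <= j < start + motif_len:
                            continue  # keep the motif instance intact
                        if rng.random() < cfg.signal_bias:
                            arr[j] = "AG"[rng.integers(2)]
                        else:
                            arr[j] = "CT"[rng.integers(2)]
                rows.append(
                    (tx, pos, "+", condition, bool(exp), bool(ctrl), differential)
                )
    truth = pd.DataFrame(
        rows,
        columns=["transcript", "pos", "strand", "condition",
                 "methylated_in_exp", "methylated_in_ctrl", "differential"],
    )
    return {k: "".join(v) for k, v in seqs.items()}, truth


def _merge_intervals(intervals):
    merged = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return merged


def _peaks_for(truth: pd.DataFrame, flag_col: str, halfwidth: int):
    """Merged site +/- halfwidth intervals per transcript for one sample."""
    out = []
    sub = truth[truth[flag_col]]
    for tx, grp in sub.groupby("transcript"):
        iv = [(max(0, p - halfwidth), p + halfwidth + 1) for p in grp["pos"]]
        out.extend((tx, s, e, "+") for s, e in _merge_intervals(iv))
    return out


def _write_bed(intervals, path):
    with open(path, "w") as fh:
        for seq_id, start, end, strand in intervals:
            fh.write(f"{seq_id}\t{start}\t{end}\t.\t0\t{strand}\n")


def _write_fasta(seqs: dict, path, width: int = 70):
    with open(path, "w") as fh:
        for name in seqs:
            fh.write(f">{name}\n")
            s = seqs[name]
            for i in range(0, len(s), width):
                fh.write(s[i : i + width] + "\n")


def emit_condition_bundle(truth: pd.DataFrame, seqs: dict, cfg: SimConfig, outdir) -> dict:
    """Write per-condition exp/ctrl peak BEDs, candidate BED, transcript
    FASTA and truth TSV; returns {condition: {name: path}}."""
    os.makedirs(outdir, exist_ok=True)
    paths = {}
    for condition in cfg.conditions:
        cdir = os.path.join(str(outdir), condition)
        os.makedirs(cdir, exist_ok=True)
        sub = truth[truth["condition"] == condition]
        files = {
            "exp_peaks": os.path.join(cdir, "exp-peaks.bed"),
            "ctrl_peaks": os.path.join(cdir, "ctrl-peaks.bed"),
            "candidates": os.path.join(cdir, "candidates.bed"),
            "transcripts": os.path.join(cdir, "transcripts.fa"),
            "truth": os.path.join(cdir, "truth.tsv"),
        }
        _write_bed(_peaks_for(sub, "methylated_in_exp", cfg.peak_halfwidth),
                   files["exp_peaks"])
        _write_bed(_peaks_for(sub, "methylated_in_ctrl", cfg.peak_halfwidth),
                   files["ctrl_peaks"])
        _write_bed([(r.transcript, r.pos, r.pos + 1, r.strand)
                    for r in sub.itertuples()], files["candidates"])
        _write_fasta(
            {k: v for k, v in seqs.items() if k.startswith(condition + "_")},
            files["transcripts"],
        )
        sub.to_csv(files["truth"], sep="\t", index=False)
        paths[condition] = files
    return paths


def simulate_bundle(cfg: SimConfig, outdir=None):
    """Full in-memory simulation; optionally also written to ``outdir``.

    Returns (seqs, truth[, paths]).
    """
    seqs, truth = plant_truth(generate_transcriptome(cfg), cfg)
    if outdir is None:
        return seqs, truth
    return seqs, truth, emit_condition_bundle(truth, seqs, cfg, outdir)
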