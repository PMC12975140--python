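"""Construction of up-/down-regulated m6A site datasets.

A *true* m6A site is a single-base candidate position (e.g. from an m6A
atlas) that falls inside a MeRIP-seq enrichment peak of the same condition,
on the same reference sequence and strand. Comparing the true-site sets of
an experimental condition and its control defines the two differential
directions:

up
    positives = sites methylated only in the experimental group.
down
    positives = sites methylated only in the control group.

Two negative-set conventions are supported via ``negative_mode``:

``definitional``(default)
    up-negatives are sites methylated in both groups; down-negatives are
    candidate sites methylated in neither.
``unmethylated``
    both directions draw negatives from candidates methylated in neither
    group.

Coordinates follow the BED convention throughout: 0-based, half-open,
strand-aware; single-base sites are 1-nt intervals (end = start + 1).
"""

from __future__ import annotations

import gzip
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .encoders import SequenceWindow

__all__ = [
    "GenomicSite",
    "PeakSet",
    "LabeledSiteSet",
    "SplitDataset",
    "true_sites",
    "derive_sites",
    "extract_windows",
    "subsample_split",
    "read_site_bed",
    "read_peak_bed",
    "read_fasta",
    "write_site_tsv",
    "write_window_fasta",
]

logger = logging.getLogger("m6ahd")


@dataclass(frozen=True, order=True)
class GenomicSite:
    """A single-nucleotide candidate m6A position."""

    seq_id: str
    pos: int
    strand: str = "+"
    condition: str = ""

    def __post_init__(self):
        if self.pos < 0:
            raise ValueError("pos must be >= 0")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be + or -, got {self.strand!r}")

    @property
    def key(self):
        """Identity used for set algebra (condition label excluded)."""
        return (self.seq_id, self.pos, self.strand)

    @property
    def site_id(self) -> str:
        return f"{self.seq_id}:{self.pos}:{self.strand}"


@dataclass
class PeakSet:
    """MeRIP-seq enrichment intervals for one sample role of a condition."""

    intervals: list  # of (seq_id, start, end, strand)
    sample_role: str = "experimental"
    condition: str = ""

    def __post_init__(self):
        for seq_id, start, end, strand in self.intervals:
            if start >= end:
                raise ValueError(f"empty interval {seq_id}:{start}-{end}")


@dataclass
class LabeledSiteSet:
    """Positives and matched negatives for one condition and direction."""

    condition: str
    direction: str
    positives: list
    negatives: list
    negative_mode: str = "definitional"

    def __post_init__(self):
        if self.direction not in ("up", "down"):
            raise ValueError("direction must be 'up' or 'down'")
        overlap = {s.key for s in self.positives} & {s.key for s in self.negatives}
        if overlap:
            raise ValueError(f"{len(overlap)} sites appear as both classes")


@dataclass
class SplitDataset:
    """Stratified train/test partition of (window, label) pairs."""

    train: list  # of (SequenceWindow, int)
    test: list
    seed: int = 0
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Core set operations
# ---------------------------------------------------------------------------

def true_sites(peaks: PeakSet, candidates) -> list:
    """Candidates whose position lies inside at least one peak interval of
    the same seq_id and strand (half-open containment start <= pos < end)."""
    trees: dict = {}
    for seq_id, start, end, strand in peaks.intervals:
        trees.setdefault((seq_id, strand), IntervalTree()).addi(start, end)
    out = []
    for s in candidates:
        tree = trees.get((s.seq_id, s.strand))
        if tree is not None and tree.overlaps_point(s.pos):
            out.append(s)
    return out


def derive_sites(
    exp_true,
    ctrl_true,
    candidates,
    direction: str,
    negative_mode: str = "definitional",
    condition: str = "",
) -> LabeledSiteSet:
    """Set-algebra derivation of positives and negatives for one direction.

    up: positives = exp-only; down: positives = ctrl-only. Negatives per
    ``negative_mode`` (see module docstring).
    """
    if negative_mode not in ("definitional", "unmethylated"):
        raise ValueError(f"unknown negative_mode {negative_mode!r}")
    by_key = {s.key: s for s in candidates}
    exp_keys = {s.key for s in exp_true}
    ctrl_keys = {s.key for s in ctrl_true}

    if direction == "up":
        pos_keys = exp_keys - ctrl_keys
    else:
        pos_keys = ctrl_keys - exp_keys

    unmeth_keys = set(by_key) - (exp_keys | ctrl_keys)
    if negative_mode == "unmethylated" or direction == "down":
        neg_keys = unmeth_keys
    else:  # up, definitional: stably methylated sites
        neg_keys = exp_keys & ctrl_keys

    if not pos_keys:
        warnings.warn(
            f"no positive sites for condition={condition!r} direction={direction}"
        )
    lookup = dict(by_key)
    for s in list(exp_true) + list(ctrl_true):
        lookup.setdefault(s.key, s)
    return LabeledSiteSet(
        condition=condition,
        direction=direction,
        positives=sorted(lookup[k] for k in pos_keys),
        negatives=sorted(lookup[k] for k in neg_keys),
        negative_mode=negative_mode,
    )


# ---------------------------------------------------------------------------
# Window extraction
# ---------------------------------------------------------------------------

def extract_windows(sites, seqs: dict, L: int, center_check: bool = True) -> list:
    """Extract the L-mer centered on each site, on the site's strand.

    Minus-strand sites yield the reverse complement of the genomic slice.
    Sites closer than (L-1)/2 to a sequence end, and windows containing
    characters outside ACGU after T->U mapping, are dropped with a logged
    count.
    """
    if L % 2 == 0:
        raise ValueError("window length must be odd")
    flank = (L - 1) // 2
    windows = []
    n_boundary = n_badchar = n_center = 0
    for s in sites:
        if s.seq_id not in seqs:
            raise KeyError(f"sequence {s.seq_id!r} not found in FASTA")
        seq = seqs[s.seq_id]
        if s.pos - flank < 0 or s.pos + flank + 1 > len(seq):
            n_boundary += 1
            continue
        sub = str(seq[s.pos - flank : s.pos + flank + 1]).upper()
        if s.strand == "-":
            sub = str(Seq(sub).reverse_complement_rna())
        sub = sub.replace("T", "U")
        if any(c not in "ACGU" for c in sub):
            n_badchar += 1
            continue
        if center_check and sub[flank] != "A":
            n_center += 1
            continue
        windows.append(SequenceWindow(sub, site_ref=s.site_id, center_check=center_check))
    if n_boundary or n_badchar or n_center:
        logger.info(
            "extract_windows dropped %d boundary, %d non-ACGU, %d non-central-A sites",
            n_boundary,
            n_badchar,
            n_center,
        )
    return windows


def subsample_split(
    site_set: LabeledSiteSet,
    windows_by_class: dict,
    n_per_class: int,
    train_frac: float = 0.8,
    seed: int = 0,
) -> SplitDataset:
    """Subsample up to ``n_per_class`` windows per class without
    replacement, then split each class independently at ``train_frac``.

    ``windows_by_class`` maps label (1 positives, 0 negatives) to the
    class's extracted windows. Deterministic for a fixed seed.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train, test = [], []
    meta = {"seed": seed, "condition": site_set.condition,
            "direction": site_set.direction, "negative_mode": site_set.negative_mode,
            "n_sampled": {}}
    for label in (1, 0):
        pool = list(windows_by_class[label])
        if not pool:
            raise ValueError(
                f"class {label} has no windows "
                f"({site_set.condition}/{site_set.direction})"
            )
        n = min(n_per_class, len(pool))
        if n < n_per_class:
            warnings.warn(
                f"class {label}: only {len(pool)} windows available "
                f"(requested {n_per_class})"
            )
        chosen = rng.choice(len(pool), size=n, replace=False)
        n_train = int(round(train_frac * n))
        for j, i in enumerate(chosen):
            (train if j < n_train else test).append((pool[i], label))
        meta["n_sampled"][label] = n
    return SplitDataset(train=train, test=test, seed=seed, metadata=meta)


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def _open_text(path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def read_site_bed(path, condition: str = "") -> list:
    """Read single-base sites from BED (1-nt intervals, strand in col 6)."""
    sites = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            start, end = int(f[1]), int(f[2])
            if end != start + 1:
                raise ValueError(f"site record is not single-base: {line!r}")
            strand = f[5] if len(f) > 5 else "+"
            sites.append(GenomicSite(f[0], start, strand, condition))
    return sites


def read_peak_bed(path, sample_role: str = "experimental", condition: str = "") -> PeakSet:
    """Read peak intervals from BED."""
    intervals = []
    with _open_text(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            strand = f[5] if len(f) > 5 else "+"
            intervals.append((f[0], int(f[1]), int(f[2]), strand))
    return PeakSet(intervals, sample_role=sample_role, condition=condition)


def read_fasta(path) -> dict:
    """Load FASTA (optionally gzipped) into an id -> sequence-string dict."""
    with _open_text(path) as fh:
        return {rec.id: str(rec.seq) for rec in SeqIO.parse(fh, "fasta")}


def write_site_tsv(site_set: LabeledSiteSet, path) -> None:
    import pandas as pd

    rows = [
        (s.seq_id, s.pos, s.strand, label, site_set.condition, site_set.direction)
        for label, group in ((1, site_set.positives), (0, site_set.negatives))
        for s in group
    ]
    pd.DataFrame(
        rows, columns=["seq_id", "pos", "strand", "label", "condition", "direction"]
    ).to_csv(path, sep="\t", index=False)


def write_window_fasta(pairs, path) -> None:
    """Write (window, label) pairs as FASTA with 'siteid|label' headers."""
    with open(path, "w") as fh:
        for w, label in pairs:
            fh.write(f">{w.site_ref}|{label}\n{w.seq}\n")
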