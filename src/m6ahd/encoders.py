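"""Sequence-window feature encodings for m6A site classification.

Six encoding schemes turn an RNA window centered on a candidate adenosine
into numeric features:

``OH``
    One-hot: each position becomes a 4-bit indicator block, lexicographic
    base order A, C, G, U (so ``U -> (0,0,0,1)``).
``NAC``
    Dinucleotide composition: relative frequencies of the 16 overlapping
    dinucleotides, ordered AA, AC, ... UU.
``CP``
    Chemical property: per position the triple (x, y, z) of ring-structure
    (purine), amino-group and hydrogen-bond indicators, so
    A=[1,1,1], C=[0,1,0], G=[1,0,0], U=[0,0,1].
``EIIP``
    Electron-ion interaction pseudopotential: one fixed scalar per
    nucleotide (A 0.1260, U 0.1335, C 0.1340, G 0.0806).
``ANF``
    Accumulated nucleotide frequency: at position i, the running frequency
    of that position's nucleotide among the first i positions.
``PseDNC``
    Pseudo dinucleotide composition: the 16 dinucleotide frequencies
    augmented with lambda sequence-order correlation terms over normalized
    physicochemical property vectors, weighted by w.

All encoders are pure functions of the input sequence (and, for PseDNC,
of its parameter set).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "RNA_ALPHABET",
    "DINUCLEOTIDES",
    "SCHEMES",
    "EIIP_VALUES",
    "SequenceWindow",
    "PseDNCParams",
    "EncoderSpec",
    "FeatureMatrix",
    "EncodingError",
    "encode_onehot",
    "encode_nac",
    "encode_cp",
    "encode_eiip",
    "encode_anf",
    "encode_psednc",
    "build_feature_matrix",
    "scheme_dims",
    "default_prop_table",
]

RNA_ALPHABET = "ACGU"

#: Lexicographic dinucleotide order AA, AC, AG, AU, CA, ... UU.
DINUCLEOTIDES = tuple(a + b for a in RNA_ALPHABET for b in RNA_ALPHABET)

#: Canonical concatenation order for combined feature matrices.
SCHEMES = ("OH", "NAC", "CP", "EIIP", "ANF", "PseDNC")

_BASE_INDEX = {b: i for i, b in enumerate(RNA_ALPHABET)}

# One-hot rows in lexicographic base order: A=e1, C=e2, G=e3, U=e4,
# matching the worked UACGC example.
_ONEHOT = np.eye(4)

# Chemical-property triples (ring/purine x, amino y, hydrogen-bond z).
_CP = {
    "A": (1, 1, 1),
    "C": (0, 1, 0),
    "G": (1, 0, 0),
    "U": (0, 0, 1),
}

#: Electron-ion interaction pseudopotential per nucleotide.
EIIP_VALUES = {"A": 0.1260, "U": 0.1335, "C": 0.1340, "G": 0.0806}


class EncodingError(ValueError):
    """Raised when a sequence cannot be encoded."""


def _clean(seq: str) -> str:
    """Uppercase and map DNA T to RNA U; no alphabet check here."""
    return seq.upper().replace("T", "U")


def _check_alphabet(seq: str) -> None:
    for i, ch in enumerate(seq):
        if ch not in _BASE_INDEX:
            raise EncodingError(
                f"character {ch!r} at position {i} is outside the ACGU alphabet"
            )


@dataclass(frozen=True)
class SequenceWindow:
    """An odd-length RNA window centered on a candidate adenosine.

    Parameters
    ----------
    seq
        Sequence over {A, C, G, U}; DNA input (T, lowercase) is normalized.
    site_ref
        Identifier of the originating genomic site.
    center_check
        When true (default) the window must have odd length with 'A' at the
        central position — the methylated adenosine.
    """

    seq: str
    site_ref: str = ""
    center_check: bool = True

    def __post_init__(self):
        object.__setattr__(self, "seq", _clean(self.seq))
        _check_alphabet(self.seq)
        if self.center_check:
            n = len(self.seq)
            if n % 2 == 0:
                raise ValueError(f"window length {n} must be odd")
            if self.seq[(n - 1) // 2] != "A":
                raise ValueError(
                    f"center nucleotide {self.seq[(n - 1) // 2]!r} is not 'A'"
                )

    def __len__(self) -> int:
        return len(self.seq)


def _as_seq(w: "SequenceWindow | str") -> str:
    if isinstance(w, SequenceWindow):
        return w.seq
    seq = _clean(w)
    _check_alphabet(seq)
    return seq


# ---------------------------------------------------------------------------
# Individual encoders
# ---------------------------------------------------------------------------

def encode_onehot(w: "SequenceWindow | str") -> np.ndarray:
    """One-hot encode a window into a 4L binary vector, 5'→3'."""
    seq = _as_seq(w)
    idx = np.fromiter((_BASE_INDEX[c] for c in seq), dtype=np.intp, count=len(seq))
    return _ONEHOT[idx].ravel()


def encode_nac(w: "SequenceWindow | str") -> np.ndarray:
    """Relative frequencies of the 16 overlapping dinucleotides."""
    seq = _as_seq(w)
    if len(seq) < 2:
        raise EncodingError("dinucleotide composition needs length >= 2")
    counts = np.zeros(16)
    for i in range(len(seq) - 1):
        counts[_BASE_INDEX[seq[i]] * 4 + _BASE_INDEX[seq[i + 1]]] += 1
    return counts / (len(seq) - 1)


def encode_cp(w: "SequenceWindow | str") -> np.ndarray:
    """Chemical-property triples (ring, amino, hydrogen bond) per position."""
    seq = _as_seq(w)
    out = np.empty(3 * len(seq))
    for i, c in enumerate(seq):
        out[3 * i : 3 * i + 3] = _CP[c]
    return out


def encode_eiip(w: "SequenceWindow | str") -> np.ndarray:
    """Per-position electron-ion interaction pseudopotential values."""
    seq = _as_seq(w)
    return np.array([EIIP_VALUES[c] for c in seq])


def encode_anf(w: "SequenceWindow | str") -> np.ndarray:
    """Accumulated nucleotide frequency: entry i is the frequency of
    seq[i] among the first i+1 positions; values lie in (0, 1]."""
    seq = _as_seq(w)
    out = np.empty(len(seq))
    for i, c in enumerate(seq):
        out[i] = seq[: i + 1].count(c) / (i + 1)
    return out


# ---------------------------------------------------------------------------
# PseDNC
# ---------------------------------------------------------------------------

# RNA dinucleotide physicochemical properties from nearest-neighbor
# thermodynamics: Watson-Crick stack free energy dG37 and enthalpy dH
# (kcal/mol); entropy dS (cal/mol/K) is derived as (dH - dG37)/T at
# T = 310.15 K. A dinucleotide 5'-XY-3' takes the value of its duplex stack.
_NN_DG37 = {
    "AA": -0.93, "UU": -0.93, "AU": -1.10, "UA": -1.33,
    "CU": -2.08, "AG": -2.08, "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24, "GA": -2.35, "UC": -2.35,
    "CG": -2.36, "GG": -3.26, "CC": -3.26, "GC": -3.42,
}
_NN_DH = {
    "AA": -6.82, "UU": -6.82, "AU": -9.38, "UA": -7.69,
    "CU": -10.48, "AG": -10.48, "CA": -10.44, "UG": -10.44,
    "GU": -11.40, "AC": -11.40, "GA": -12.44, "UC": -12.44,
    "CG": -10.64, "GG": -13.39, "CC": -13.39, "GC": -14.88,
}


def default_prop_table() -> dict[str, np.ndarray]:
    """Bundled property table: (dG37, dH, dS) per dinucleotide, each
    property z-score normalized across the 16 dinucleotides."""
    raw = np.array(
        [
            [_NN_DG37[d], _NN_DH[d], (_NN_DH[d] - _NN_DG37[d]) / 310.15 * 1000.0]
            for d in DINUCLEOTIDES
        ]
    )
    norm = (raw - raw.mean(axis=0)) / raw.std(axis=0)
    return {d: norm[i] for i, d in enumerate(DINUCLEOTIDES)}


@dataclass(frozen=True)
class PseDNCParams:
    """Parameters of the pseudo dinucleotide composition.

    lam
        Number of sequence-order correlation tiers (lags); requires
        lam <= L - 2 for every window encoded.
    w
        Weight of the correlation terms relative to the composition
        terms, in (0, 1].
    prop_table
        Normalized property vector per dinucleotide; all 16 keys required
        with equal vector lengths.
    """

    lam: int = 3
    w: float = 0.05
    prop_table: dict = field(default_factory=default_prop_table)

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if not (0 < self.w <= 1):
            raise ValueError("w must be in (0, 1]")
        missing = set(DINUCLEOTIDES) - set(self.prop_table)
        if missing:
            raise ValueError(f"prop_table missing dinucleotides: {sorted(missing)}")
        lengths = {len(np.atleast_1d(v)) for v in self.prop_table.values()}
        if len(lengths) != 1:
            raise ValueError("prop_table vectors must share one length")


def _theta(seq: str, j: int, table: dict) -> float:
    """Mean correlation factor at lag j: the average, over all dinucleotide
    pairs (i, i+j), of the mean squared property-vector difference."""
    n_pairs = len(seq) - 1 - j
    acc = 0.0
    for i in range(n_pairs):
        a = np.atleast_1d(table[seq[i : i + 2]])
        b = np.atleast_1d(table[seq[i + j : i + j + 2]])
        acc += float(np.mean((a - b) ** 2))
    return acc / n_pairs


def encode_psednc(w: "SequenceWindow | str", p: PseDNCParams | None = None) -> np.ndarray:
    """Pseudo dinucleotide composition: 16 + lam components summing to 1.

    The first 16 components are d_u = f_u / (sum f + w * sum theta); the last
    lam components are d_(16+j) = w * theta_j / (sum f + w * sum theta).
    With lam = 0 this reduces exactly to the dinucleotide composition.
    """
    if p is None:
        p = PseDNCParams()
    seq = _as_seq(w)
    if p.lam > len(seq) - 2:
        raise EncodingError(
            f"lam={p.lam} exceeds L-2={len(seq) - 2} for a length-{len(seq)} window"
        )
    f = encode_nac(seq)  # sums to 1
    thetas = np.array([_theta(seq, j, p.prop_table) for j in range(1, p.lam + 1)])
    denom = 1.0 + p.w * thetas.sum()
    return np.concatenate([f / denom, p.w * thetas / denom])


# ---------------------------------------------------------------------------
# Feature-matrix assembly
# ---------------------------------------------------------------------------

def scheme_dims(scheme: str, L: int, lam: int = 3) -> int:
    """Feature dimensionality of one scheme for window length L."""
    return {
        "OH": 4 * L,
        "NAC": 16,
        "CP": 3 * L,
        "EIIP": L,
        "ANF": L,
        "PseDNC": 16 + lam,
    }[scheme]


@dataclass(frozen=True)
class EncoderSpec:
    """A nonempty subset of schemes plus PseDNC parameters."""

    schemes: tuple = SCHEMES
    psednc: PseDNCParams | None = None

    def __post_init__(self):
        schemes = tuple(self.schemes)
        if not schemes:
            raise ValueError("at least one encoding scheme is required")
        unknown = set(schemes) - set(SCHEMES)
        if unknown:
            raise ValueError(f"unknown schemes: {sorted(unknown)}")
        if len(set(schemes)) != len(schemes):
            raise ValueError("duplicate schemes")
        # canonical order, independent of the order given
        object.__setattr__(
            self, "schemes", tuple(s for s in SCHEMES if s in schemes)
        )
        if "PseDNC" in self.schemes and self.psednc is None:
            object.__setattr__(self, "psednc", PseDNCParams())

    def column_names(self, L: int) -> list[str]:
        lam = self.psednc.lam if self.psednc is not None else 0
        names: list[str] = []
        for s in self.schemes:
            if s == "OH":
                names += [f"OH:{i}.{b}" for i in range(L) for b in RNA_ALPHABET]
            elif s == "NAC":
                names += [f"NAC:{d}" for d in DINUCLEOTIDES]
            elif s == "CP":
                names += [f"CP:{i}.{ch}" for i in range(L) for ch in "xyz"]
            elif s == "EIIP":
                names += [f"EIIP:{i}" for i in range(L)]
            elif s == "ANF":
                names += [f"ANF:{i}" for i in range(L)]
            elif s == "PseDNC":
                names += [f"PseDNC:{d}" for d in DINUCLEOTIDES]
                names += [f"PseDNC:theta{j}" for j in range(1, lam + 1)]
        return names


_ENCODER_FN = {
    "OH": encode_onehot,
    "NAC": encode_nac,
    "CP": encode_cp,
    "EIIP": encode_eiip,
    "ANF": encode_anf,
}


@dataclass
class FeatureMatrix:
    """Windows × named feature columns with binary labels."""

    values: np.ndarray
    columns: list
    labels: np.ndarray

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.shape != (len(self.labels), len(self.columns)):
            raise ValueError("values shape does not match columns/labels")

    @property
    def n_rows(self) -> int:
        return self.values.shape[0]

    @property
    def n_columns(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.columns)
        df["label"] = self.labels
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False, float_format="%.15g")

    @classmethod
    def from_tsv(cls, path) -> "FeatureMatrix":
        df = pd.read_csv(path, sep="\t")
        labels = df.pop("label").to_numpy()
        return cls(df.to_numpy(), list(df.columns), labels)


def build_feature_matrix(windows, spec: EncoderSpec, labels) -> FeatureMatrix:
    """Encode windows with the selected schemes concatenated in canonical
    order (OH, NAC, CP, EIIP, ANF, PseDNC); deterministic given inputs."""
    windows = list(windows)
    labels = np.asarray(labels, dtype=int)
    if len(windows) != len(labels):
        raise ValueError("labels must align with windows")
    if len(windows) == 0:
        raise ValueError("no windows to encode")
    lengths = {len(w) if isinstance(w, SequenceWindow) else len(w) for w in windows}
    if len(lengths) != 1:
        raise ValueError(f"mixed window lengths: {sorted(lengths)}")
    L = lengths.pop()

    rows = np.empty((len(windows), 0))
    blocks = []
    for w in windows:
        parts = []
        for s in spec.schemes:
            if s == "PseDNC":
                parts.append(encode_psednc(w, spec.psednc))
            else:
                parts.append(_ENCODER_FN[s](w))
        blocks.append(np.concatenate(parts))
    rows = np.vstack(blocks)
    return FeatureMatrix(rows, spec.column_names(L), labels)


def all_scheme_combinations() -> list[tuple]:
    """The 63 nonempty scheme subsets, in canonical order (by size, then
    lexicographically over canonical scheme positions)."""
    combos = []
    for r in range(1, len(SCHEMES) + 1):
        combos.extend(itertools.combinations(SCHEMES, r))
    return combos
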