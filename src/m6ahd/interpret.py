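"""Tree-ensemble feature importance (mean decrease in Gini impurity).

For every split on a feature, the impurity decrease from the parent node
to its children (weighted by the fraction of samples reaching the node)
is summed over all splits of a tree; the per-feature totals are averaged
over the trees of the forest. Unused features score zero. Importances are
reported raw and as a fraction of the total, ranked, and aggregatable by
encoding scheme and — within the chemical-property scheme — by channel
(ring/purine x, amino y, hydrogen-bond z).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pipeline import TrainedModel

__all__ = ["ImportanceTable", "gini_importance", "top_k", "aggregate_channels"]


def _parse_feature(name: str):
    """Split a column name into (scheme, index, channel)."""
    if ":" not in name:
        raise ValueError(f"unparseable feature name {name!r}")
    scheme, rest = name.split(":", 1)
    channel = ""
    if scheme == "CP":
        if "." not in rest:
            raise ValueError(f"unparseable CP feature name {name!r}")
        rest, channel = rest.rsplit(".", 1)
    return scheme, rest, channel


@dataclass
class ImportanceTable:
    """Ranked per-feature importances.

    ``frame`` columns: feature, scheme, channel, importance, fraction,
    rank — sorted non-increasing by importance, ties broken by the
    feature's canonical column order, ranks consecutive from 1.
    """

    frame: pd.DataFrame
    total: float

    def __len__(self) -> int:
        return len(self.frame)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def gini_importance(model: TrainedModel) -> ImportanceTable:
    """Mean-decrease-Gini table for a fitted tree-ensemble model."""
    if model.importances is None:
        raise TypeError(
            "Gini importance is specific to tree-ensemble models; "
            f"{model.config.algorithm} does not record impurity decreases"
        )
    imp = np.asarray(model.importances, dtype=float)
    total = float(imp.sum())
    parsed = [_parse_feature(n) for n in model.columns]
    df = pd.DataFrame(
        {
            "feature": model.columns,
            "scheme": [p[0] for p in parsed],
            "channel": [p[2] for p in parsed],
            "importance": imp,
            "fraction": imp / total if total > 0 else imp,
        }
    )
    # stable sort keeps canonical column order among ties
    df = df.sort_values("importance", ascending=False, kind="stable")
    df["rank"] = np.arange(1, len(df) + 1)
    return ImportanceTable(df.reset_index(drop=True), total)


def top_k(table: ImportanceTable, k: int) -> ImportanceTable:
    """First min(k, |table|) rows of the ranking."""
    if k < 1:
        raise ValueError("k must be >= 1")
    return ImportanceTable(table.frame.head(k).reset_index(drop=True), table.total)


def aggregate_channels(table: ImportanceTable) -> pd.DataFrame:
    """Importance summed by scheme, and within CP by chemical channel.

    Rows with channel "" are whole-scheme sums; CP additionally gets one
    row per channel (x, y, z) that partitions the CP total.
    """
    df = table.frame
    scheme_sums = df.groupby("scheme")["importance"].sum()
    rows = [
        {"scheme": s, "channel": "", "importance": float(v)}
        for s, v in scheme_sums.items()
    ]
    cp = df[df["scheme"] == "CP"]
    if len(cp):
        for ch, v in cp.groupby("channel")["importance"].sum().items():
            rows.append({"scheme": "CP", "channel": ch, "importance": float(v)})
    return pd.DataFrame(rows)
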