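"""Temporal change in regional importance and strategy classification.

Connectivity is projected once per time period; the change in a cell's
regional importance between two periods (ddIIC, in percentage points)
tells whether the cell is gaining or losing relevance as climate shifts
the suitable area. Combining that trend with the cell's *current*
habitat availability (its local PC numerator in the earlier period)
yields six management classes:

=====  ============  =====================  ==============================
class  availability  importance change      strategy
=====  ============  =====================  ==============================
I      below median  decrease (<= 0)        no action
II     above median  decrease (<= 0)        short-term conservation
III    above median  small increase (< Md)  low-priority restoration,
                                            long-term conservation
IV     above median  large increase (>= Md) long-term conservation
V      below median  small increase (< Md)  intermediate restoration
VI     below median  large increase (>= Md) high-priority restoration
=====  ============  =====================  ==============================

The increase threshold Md is the median of the *strictly positive*
changes only, so restoration effort is steered toward cells whose
conditions genuinely improve. Ties at either median resolve upward
(>=), favoring action over inaction. Both thresholds are recomputed per
transition.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import mapping

__all__ = [
    "CLASS_LABELS",
    "ChangeTable",
    "StrategyMap",
    "default_transitions",
    "temporal_change",
    "classify",
    "export_strategy_map",
    "read_strategy_map",
]

CLASS_LABELS = {
    "I": "No action",
    "II": "Short-term conservation",
    "III": "Low priority restoration / long-term conservation",
    "IV": "Long-term conservation",
    "V": "Intermediate priority restoration",
    "VI": "High priority restoration",
}


def default_transitions(periods: list[str]) -> list[tuple[str, str]]:
    """Consecutive period pairs plus the overall first-to-last trend."""
    if len(periods) < 2:
        raise ValueError("at least two periods are needed for a transition")
    pairs = [(periods[i], periods[i + 1]) for i in range(len(periods) - 1)]
    overall = (periods[0], periods[-1])
    if overall not in pairs:
        pairs.append(overall)
    return pairs


def _transition_label(earlier: str, later: str) -> str:
    return f"{later}-{earlier}"


@dataclass
class ChangeTable:
    """Per-cell change in regional importance plus initial availability.

    ``changes``: cell x transition, in percentage points of dIIC.
    ``availability``: cell x period, local PC numerators (used as the
    'current conditions' axis of the classifier).
    ``transitions``: the (earlier, later) period pairs, ordered.
    """

    changes: pd.DataFrame
    availability: pd.DataFrame
    transitions: list[tuple[str, str]]

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.changes.copy()
        out.index.name = "cell_id"
        out.to_csv(path)
        return path


def temporal_change(
    importance: pd.DataFrame,
    transitions: list[tuple[str, str]],
    availability: pd.DataFrame | None = None,
) -> ChangeTable:
    """ddIIC = dIIC(later period) - dIIC(earlier period), per cell.

    ``importance`` is the cell x period dIIC table. ``availability``
    (cell x period local PC numerators) is carried along for the
    classifier; it may be omitted when only the changes are wanted.
    """
    cols = {}
    for earlier, later in transitions:
        for p in (earlier, later):
            if p not in importance.columns:
                raise KeyError(f"unknown period label {p!r}")
        cols[_transition_label(earlier, later)] = (
            importance[later] - importance[earlier]
        )
    changes = pd.DataFrame(cols)
    if not np.isfinite(changes.to_numpy()).all():
        raise ValueError("non-finite importance change encountered")
    if availability is None:
        availability = pd.DataFrame(index=importance.index)
    return ChangeTable(changes=changes, availability=availability,
                       transitions=list(transitions))


@dataclass
class StrategyMap:
    """Class I-VI per cell per transition, with the thresholds used."""

    classes: pd.DataFrame  # cell x transition, values "I".."VI"
    thresholds: dict  # transition label -> {"median_availability", "median_positive_change"}

    def counts(self) -> pd.DataFrame:
        return self.classes.apply(lambda c: c.value_counts()).reindex(
            list(CLASS_LABELS)).fillna(0).astype(int)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        out = self.classes.copy()
        out.index.name = "cell_id"
        out.to_csv(path)
        return path


def _classify_one(avail: pd.Series, change: pd.Series) -> tuple[pd.Series, dict]:
    med_avail = float(np.median(avail.to_numpy()))
    positive = change[change > 0]
    if positive.empty:
        warnings.warn(
            "no cell shows an importance increase for this transition; the "
            "restoration split threshold is undefined",
            stacklevel=3,
        )
        med_pos = np.nan
    else:
        med_pos = float(np.median(positive.to_numpy()))

    high = avail >= med_avail
    decreasing = change <= 0
    # with med_pos undefined no cell has change > 0, so these stay empty
    small_inc = (change > 0) & (change < med_pos) if positive.size else change > 0
    large_inc = (change >= med_pos) if positive.size else pd.Series(False, index=change.index)

    out = pd.Series(index=change.index, dtype=object)
    out[high & decreasing] = "II"
    out[high & small_inc] = "III"
    out[high & large_inc] = "IV"
    out[~high & decreasing] = "I"
    out[~high & small_inc] = "V"
    out[~high & large_inc] = "VI"
    thresholds = {"median_availability": med_avail,
                  "median_positive_change": med_pos}
    return out, thresholds


def classify(change: ChangeTable) -> StrategyMap:
    """Assign every cell a strategy class I-VI for every transition.

    The availability axis uses the *earlier* period of each transition;
    the change axis uses that transition's ddIIC. Medians are computed
    per transition over all cells.
    """
    if change.changes.empty:
        raise ValueError("change table has no cells")
    classes = {}
    thresholds = {}
    for earlier, later in change.transitions:
        label = _transition_label(earlier, later)
        if earlier not in change.availability.columns:
            raise KeyError(
                f"availability for period {earlier!r} is missing; the "
                "classifier needs the earlier period's local PC numerator"
            )
        cls, thr = _classify_one(change.availability[earlier],
                                 change.changes[label])
        classes[label] = cls
        thresholds[label] = thr
    return StrategyMap(classes=pd.DataFrame(classes), thresholds=thresholds)


def export_strategy_map(strategy: StrategyMap, grid, path: str | Path) -> Path:
    """Write the classified cells as a GeoJSON polygon layer.

    One feature per cell with a class code and label per transition;
    the medians used as thresholds are stored in the collection's
    metadata.
    """
    cell_ids = set(grid.cells["cell_id"].astype(int))
    table_ids = set(int(i) for i in strategy.classes.index)
    if strategy.classes.shape[0] and not table_ids <= cell_ids:
        raise ValueError("strategy table contains cell ids absent from the grid")
    props = strategy.classes.copy()
    label_cols = {
        col: props[col].map(CLASS_LABELS) for col in props.columns
    }
    for col, lab in label_cols.items():
        props[f"{col}_label"] = lab
    keep = grid.cells["cell_id"].isin(strategy.classes.index).to_numpy()
    sub_cells = grid.cells[keep].reset_index(drop=True)
    sub_polys = [p for p, k in zip(grid.polygons, keep) if k]

    feats = []
    for k in range(len(sub_cells)):
        cid = int(sub_cells["cell_id"].iloc[k])
        p = {"cell_id": cid}
        for col in props.columns:
            p[str(col)] = str(props.loc[cid, col])
        feats.append({"type": "Feature", "geometry": mapping(sub_polys[k]),
                      "properties": p})
    doc = {
        "type": "FeatureCollection",
        "features": feats,
        "metadata": {
            "class_labels": CLASS_LABELS,
            "thresholds": {
                t: {k: (None if v != v else v) for k, v in thr.items()}
                for t, thr in strategy.thresholds.items()
            },
        },
    }
    path = Path(path)
    path.write_text(json.dumps(doc))
    return path


def read_strategy_map(path: str | Path) -> pd.DataFrame:
    """Read class assignments back from an exported GeoJSON layer."""
    doc = json.loads(Path(path).read_text())
    rows = {}
    for feat in doc.get("features", []):
        p = dict(feat["properties"])
        cid = int(p.pop("cell_id"))
        rows[cid] = {k: v for k, v in p.items() if not k.endswith("_label")}
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "cell_id"
    return df.sort_index()
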