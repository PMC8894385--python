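"""Well-level aggregation and screen hit calling.

The screen readout is the per-well ratio of contractile to synthetic
cell counts (con/syn).  Each treated well's ratio is normalized to the
negative-control ratio of its own replicate plate, giving a fold change
(FC); conditions are then called over replicates:

* ``strong_contractile`` — mean FC > 1.5 and FC > 1 in every replicate;
* ``weak_contractile``   — not strong, mean FC > 1.2;
* ``strong_synthetic``   — FC < 1 in every replicate and mean FC < 1/1.2;
* ``none``               — everything else.

A Haldane–Anscombe pseudocount of 0.5 on both counts keeps the ratio
finite and positive in wells with no synthetic (or no contractile)
cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WellSummary",
    "HitCall",
    "HitThresholds",
    "summarize_well",
    "fold_change",
    "call_hits",
    "screen_table",
]

RATIO_PSEUDOCOUNT = 0.5


@dataclass(frozen=True)
class WellSummary:
    well_id: str
    condition_label: str
    replicate_id: str
    n_contractile: int
    n_synthetic: int
    n_undecided: int
    n_unclassified: int
    ratio_con_syn: float
    low_information: bool

    @property
    def n_cells(self) -> int:
        return (
            self.n_contractile + self.n_synthetic
            + self.n_undecided + self.n_unclassified
        )


@dataclass(frozen=True)
class HitThresholds:
    strong_contractile_avg_fc: float = 1.5
    weak_contractile_avg_fc: float = 1.2

    @property
    def strong_synthetic_avg_fc(self) -> float:
        # mirror of the weak contractile threshold on the down side
        return 1.0 / self.weak_contractile_avg_fc


@dataclass(frozen=True)
class HitCall:
    condition_label: str
    per_replicate_fc: tuple[float, ...]
    avg_fc: float
    category: str  # strong_contractile | weak_contractile | strong_synthetic | none


def summarize_well(
    records: pd.DataFrame,
    well_id: str = "well",
    condition_label: str = "",
    replicate_id: str = "",
) -> WellSummary:
    """Count phenotype classes and form the con/syn ratio for one well.

    ``records`` must carry a ``phenotype`` column.  An empty record list
    is an error (the well failed).  A well with neither contractile nor
    synthetic cells carries no ratio information: its ratio is 1.0 by
    the pseudocount and it is flagged ``low_information``.
    """
    if len(records) == 0:
        raise ValueError(f"well {well_id}: no cell records (well failed)")
    counts = records["phenotype"].value_counts()
    nc = int(counts.get("contractile", 0))
    ns = int(counts.get("synthetic", 0))
    ratio = (nc + RATIO_PSEUDOCOUNT) / (ns + RATIO_PSEUDOCOUNT)
    return WellSummary(
        well_id=well_id,
        condition_label=condition_label,
        replicate_id=replicate_id,
        n_contractile=nc,
        n_synthetic=ns,
        n_undecided=int(counts.get("undecided", 0)),
        n_unclassified=int(counts.get("unclassified", 0)),
        ratio_con_syn=ratio,
        low_information=(nc == 0 and ns == 0),
    )


def fold_change(
    treatment: WellSummary | float, control_ratio_for_replicate: float
) -> float:
    """Fold change of a treated well's con/syn ratio over its replicate's
    negative-control ratio."""
    if not control_ratio_for_replicate > 0:
        raise ValueError("control ratio must be positive")
    ratio = (
        treatment.ratio_con_syn
        if isinstance(treatment, WellSummary)
        else float(treatment)
    )
    return ratio / control_ratio_for_replicate


def call_hits(
    per_replicate_fc,
    condition_label: str = "",
    thresholds: HitThresholds | None = None,
) -> HitCall:
    """Categorize one condition from its per-replicate fold changes."""
    t = thresholds or HitThresholds()
    fcs = np.asarray(list(per_replicate_fc), dtype=float)
    if np.isnan(fcs).any():
        warnings.warn(
            f"condition {condition_label!r}: NaN fold change(s) dropped",
            stacklevel=2,
        )
        fcs = fcs[~np.isnan(fcs)]
    if len(fcs) < 2:
        raise ValueError("need fold changes from at least 2 replicates")
    avg = float(fcs.mean())
    if avg > t.strong_contractile_avg_fc and np.all(fcs > 1.0):
        cat = "strong_contractile"
    elif avg > t.weak_contractile_avg_fc:
        cat = "weak_contractile"
    elif np.all(fcs < 1.0) and avg < t.strong_synthetic_avg_fc:
        cat = "strong_synthetic"
    else:
        cat = "none"
    return HitCall(
        condition_label=condition_label,
        per_replicate_fc=tuple(float(x) for x in fcs),
        avg_fc=avg,
        category=cat,
    )


def screen_table(
    summaries: list[WellSummary] | pd.DataFrame,
    thresholds: HitThresholds | None = None,
    control_label: str = "neg_control",
) -> pd.DataFrame:
    """Assemble the condition-level screen table from well summaries.

    The negative-control ratio of each replicate is the mean con/syn
    ratio over that replicate's control wells (per-plate normalization).
    Returns one row per non-control condition: per-replicate FCs, their
    mean, and the hit category, sorted by avg_fc descending.
    """
    if isinstance(summaries, pd.DataFrame):
        df = summaries
    else:
        df = pd.DataFrame([vars(s) for s in summaries])
    is_ctrl = df["condition_label"] == control_label
    ctrl = df[is_ctrl].groupby("replicate_id")["ratio_con_syn"].mean()
    missing = set(df["replicate_id"]) - set(ctrl.index)
    if missing:
        raise ValueError(f"replicates without a negative control: {missing}")

    rows = []
    for cond, grp in df[~is_ctrl].groupby("condition_label", sort=False):
        fcs, reps = [], []
        for _, w in grp.sort_values("replicate_id").iterrows():
            fcs.append(fold_change(w["ratio_con_syn"], ctrl[w["replicate_id"]]))
            reps.append(w["replicate_id"])
        call = call_hits(fcs, condition_label=cond, thresholds=thresholds)
        row = {"condition_label": cond}
        row.update({f"fc_{r}": f for r, f in zip(reps, call.per_replicate_fc)})
        row["avg_fc"] = call.avg_fc
        row["category"] = call.category
        rows.append(row)
    out = pd.DataFrame(rows).sort_values(
        "avg_fc", ascending=False, ignore_index=True
    )
    return out
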