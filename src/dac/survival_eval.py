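"""Survival-based evaluation of classifier output.

Classifier variants are scored by how well their assigned ABC and GCB
classes separate overall survival: a univariate Cox proportional-hazards
model with a GCB-vs-ABC indicator (ABC baseline), Efron tie handling and a
Wald p-value.  Type-III cases never enter the model.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter

from .classifier import ClassCall, ClassLabel, apply_confidence_threshold
from .io_formats import SurvivalRecord


@dataclass
class SurvivalSeparation:
    """Cox GCB-vs-ABC contrast: HR < 1 means better GCB outcome."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    n_abc: int
    n_gcb: int
    n_type_iii: int


def survival_separation(
    calls: Sequence[ClassCall], survival_records: Sequence[SurvivalRecord]
) -> SurvivalSeparation:
    """Fit the univariate Cox model on ABC/GCB cases (GCB=1, ABC=0)."""
    by_id = {r.sample_id: r for r in survival_records}
    rows = []
    n_t3 = 0
    for c in calls:
        if c.predicted == ClassLabel.TYPE_III:
            n_t3 += 1
            continue
        rec = by_id.get(c.sample_id)
        if rec is None:
            continue
        rows.append((rec.time, rec.event, 1.0 if c.predicted == ClassLabel.GCB else 0.0))
    df = pd.DataFrame(rows, columns=["time", "event", "gcb"])
    n_abc = int((df["gcb"] == 0).sum())
    n_gcb = int((df["gcb"] == 1).sum())
    if n_abc == 0 or n_gcb == 0:
        raise ValueError("one of the ABC/GCB classes is empty")
    if df["event"].sum() < 2:
        raise ValueError("fewer than 2 events among ABC/GCB cases")
    cph = CoxPHFitter()
    cph.fit(df, duration_col="time", event_col="event")  # lifelines uses Efron ties
    summ = cph.summary.loc["gcb"]
    return SurvivalSeparation(
        hazard_ratio=float(np.exp(summ["coef"])),
        ci_low=float(np.exp(summ["coef lower 95%"])),
        ci_high=float(np.exp(summ["coef upper 95%"])),
        p_value=float(summ["p"]),
        n_abc=n_abc,
        n_gcb=n_gcb,
        n_type_iii=n_t3,
    )


def rank_classifiers(
    separations_by_dataset: Mapping[str, Mapping[str, SurvivalSeparation]]
) -> pd.DataFrame:
    """Rank classifier variants by average p-value rank across data sets.

    ``separations_by_dataset[dataset][classifier]`` must cover the same
    classifier set in every data set.  Rank 1 = smallest p-value; ties are
    broken by |log HR| descending.  Returns a table ordered by average rank.
    """
    datasets = list(separations_by_dataset)
    classifiers = sorted(separations_by_dataset[datasets[0]])
    for ds in datasets:
        if sorted(separations_by_dataset[ds]) != classifiers:
            raise ValueError(f"dataset {ds!r} is missing classifier evaluations")
    ranks = pd.DataFrame(index=classifiers, columns=datasets, dtype=float)
    for ds in datasets:
        seps = separations_by_dataset[ds]
        order = sorted(
            classifiers,
            key=lambda c: (seps[c].p_value, -abs(np.log(seps[c].hazard_ratio))),
        )
        for i, c in enumerate(order, start=1):
            ranks.loc[c, ds] = float(i)
    out = pd.DataFrame({"average_rank": ranks.mean(axis=1)})
    for ds in datasets:
        out[f"rank_{ds}"] = ranks[ds]
        out[f"p_{ds}"] = [separations_by_dataset[ds][c].p_value for c in out.index]
        out[f"hr_{ds}"] = [separations_by_dataset[ds][c].hazard_ratio for c in out.index]
    return out.sort_values("average_rank")


def confidence_sweep(
    calls: Sequence[ClassCall],
    survival_records: Sequence[SurvivalRecord],
    thresholds: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9),
) -> pd.DataFrame:
    """Apply each hard confidence threshold and re-fit the survival model.

    Returns one row per threshold with the % of cases reassigned to
    Type-III (non-decreasing in tau) and the resulting separation; a
    threshold leaving too few events is flagged rather than fatal.
    """
    rows = []
    for tau in thresholds:
        thresholded = apply_confidence_threshold(calls, tau)
        pct_t3 = 100.0 * sum(
            c.predicted == ClassLabel.TYPE_III for c in thresholded
        ) / len(thresholded)
        try:
            sep = survival_separation(thresholded, survival_records)
            rows.append({
                "tau": tau, "pct_type_iii": pct_t3, "hazard_ratio": sep.hazard_ratio,
                "ci_low": sep.ci_low, "ci_high": sep.ci_high, "p_value": sep.p_value,
                "flagged": False,
            })
        except ValueError:
            rows.append({
                "tau": tau, "pct_type_iii": pct_t3, "hazard_ratio": np.nan,
                "ci_low": np.nan, "ci_high": np.nan, "p_value": np.nan,
                "flagged": True,
            })
    return pd.DataFrame(rows)
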