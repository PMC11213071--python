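"""Trial time-course endpoint statistics.

Participants in the open-label trial are sampled at baseline (B) and at 2,
8 and 16 weeks of treatment (W2, W8, W16). Endpoints (IFN scores, cytokine
scores, individual analytes, autoantibody titers) are evaluated as:

* paired Wilcoxon signed-rank tests of each post-baseline visit against
  baseline, with the median paired difference (MD) as effect size and BH
  q-values across the visits within an endpoint;
* Mann-Whitney U comparisons placing the trial cohort in the context of a
  large case-control cohort on a shared standardized scale;
* per-participant titer trajectories with upper-limit-of-normal (ULN)
  crossing flags;
* visit-level exclusion annotation (immune-trigger excursions such as a
  vaccination before a blood draw), with analyses reported both including
  and excluding flagged visits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import TrialTable
from .scores import CompositeScoreSeries
from .stats import benjamini_hochberg, mann_whitney_u, wilcoxon_signed_rank

__all__ = [
    "EndpointSummary",
    "paired_visit_tests",
    "cohort_context_comparison",
    "titer_trend",
    "exclusion_annotator",
]


@dataclass
class EndpointSummary:
    """Per-visit paired-test summaries for one endpoint.

    ``table`` rows: visit, median_difference (median of visit - baseline
    pairs), statistic, p_value, q_value (BH across visits), n_pairs,
    direction.
    """

    endpoint: str
    table: pd.DataFrame
    excluded_flagged: bool


def paired_visit_tests(
    trial: TrialTable,
    values: pd.Series,
    endpoint: str,
    visits=("W2", "W8", "W16"),
    baseline: str = "B",
    exclude_flagged: bool = False,
) -> EndpointSummary:
    """Paired Wilcoxon tests of each visit against baseline.

    ``values`` maps sample id to the endpoint value. Pairs whose visit (or
    baseline) sample is annotated as excluded are dropped when
    ``exclude_flagged``. BH correction is applied across the tested visits
    within this endpoint.
    """
    meta = trial.samples
    if exclude_flagged:
        meta = meta[~meta["excluded"]]
    wide = meta[["participant", "visit"]].copy()
    wide["value"] = values.reindex(meta.index)
    pivot = wide.pivot(index="participant", columns="visit", values="value")
    if baseline not in pivot.columns:
        raise ValueError(f"no baseline ({baseline}) samples present")
    rows = []
    for visit in visits:
        if visit not in pivot.columns:
            raise ValueError(f"no samples at visit {visit}")
        pair = pivot[[baseline, visit]].dropna()
        if len(pair) < 2:
            raise ValueError(f"fewer than 2 complete pairs at visit {visit}")
        res = wilcoxon_signed_rank(pair[baseline].values, pair[visit].values)
        md = res.effect
        rows.append(
            {
                "visit": visit,
                "median_difference": md,
                "statistic": res.statistic,
                "p_value": res.p_value,
                "n_pairs": len(pair),
                "direction": "decrease" if md < 0 else ("increase" if md > 0 else "none"),
            }
        )
    table = pd.DataFrame(rows)
    table["q_value"] = benjamini_hochberg(table["p_value"].values)
    return EndpointSummary(endpoint=endpoint, table=table, excluded_flagged=exclude_flagged)


def cohort_context_comparison(
    cohort_scores: CompositeScoreSeries,
    cohort_groups: pd.Series,
    trial_scores: CompositeScoreSeries,
    trial_meta: pd.DataFrame,
    case_group: str = "T21",
    control_group: str = "D21",
    visits=("B", "W2", "W8", "W16"),
) -> dict:
    """Place trial scores in cohort context on a shared standardized scale.

    Requires both score series to be standardized against the same
    reference population (checked via their reference labels). Returns the
    cohort case-vs-control Mann-Whitney result (with the difference of
    group medians as MD) and per-visit trial summaries.
    """
    if cohort_scores.reference_label != trial_scores.reference_label:
        raise ValueError(
            "mismatched standardization references: "
            f"{cohort_scores.reference_label!r} vs {trial_scores.reference_label!r}"
        )
    grp = cohort_groups.reindex(cohort_scores.scores.index)
    case = cohort_scores.scores[grp == case_group].dropna()
    ctrl = cohort_scores.scores[grp == control_group].dropna()
    mw = mann_whitney_u(case.values, ctrl.values)
    per_visit = []
    for visit in visits:
        ids = trial_meta.index[trial_meta["visit"] == visit]
        vals = trial_scores.scores.reindex(ids).dropna()
        per_visit.append(
            {
                "visit": visit,
                "n": len(vals),
                "median": float(np.median(vals)) if len(vals) else np.nan,
            }
        )
    return {
        "cohort_test": mw,
        "cohort_median_difference": mw.effect,
        "trial_by_visit": pd.DataFrame(per_visit),
        "reference": cohort_scores.reference_label,
    }


def titer_trend(
    trial: TrialTable,
    analyte: str = "anti-TPO",
    uln: float = 60.0,
    visits=("W8", "W16"),
    baseline: str = "B",
) -> pd.DataFrame:
    """Per-participant titer trajectories with ULN threshold flags.

    Per participant: baseline titer, whether it is strictly above the ULN,
    per-visit change from baseline, whether every available visit decreased
    (monotone_decrease), and whether the titer crossed from above to at or
    below the ULN (crossed_below_uln). Missing visits leave a partial
    trajectory, annotated in ``n_visits_available``.
    """
    t = trial.titers
    sub = t[t["analyte"] == analyte]
    if sub.empty:
        raise ValueError(f"no titer records for {analyte}")
    pivot = sub.pivot(index="participant", columns="visit", values="value")
    if baseline not in pivot.columns:
        raise ValueError("baseline titers missing")
    rows = []
    for p, row in pivot.iterrows():
        base = row.get(baseline, np.nan)
        if not np.isfinite(base):
            continue
        changes = {v: row.get(v, np.nan) - base for v in visits}
        avail = [v for v in visits if np.isfinite(row.get(v, np.nan))]
        decreased = bool(avail) and all(row[v] < base for v in avail)
        crossed = base > uln and any(row[v] <= uln for v in avail)
        rec = {
            "participant": p,
            "baseline": float(base),
            "above_uln_at_baseline": bool(base > uln),
            "monotone_decrease": decreased,
            "crossed_below_uln": bool(crossed),
            "n_visits_available": len(avail),
        }
        rec.update({f"change_{v}": float(changes[v]) for v in visits})
        rows.append(rec)
    return pd.DataFrame(rows).set_index("participant")


def exclusion_annotator(trial: TrialTable, annotations) -> TrialTable:
    """Mark visit-level exclusions (e.g. immune-trigger excursions).

    ``annotations`` is an iterable of (participant, visit) or (participant,
    visit, note). Unknown (participant, visit) references raise. Returns a
    new TrialTable; downstream tests can then be run both including and
    excluding the flagged visits.
    """
    samples = trial.samples.copy()
    key = samples["participant"] + "_" + samples["visit"]
    lookup = dict(zip(key, samples.index))
    for ann in annotations:
        p, v = ann[0], ann[1]
        note = ann[2] if len(ann) > 2 else "flagged"
        k = f"{p}_{v}"
        if k not in lookup:
            raise ValueError(f"unknown (participant, visit): ({p}, {v})")
        sid = lookup[k]
        samples.loc[sid, "excluded"] = True
        samples.loc[sid, "note"] = note
    return TrialTable(
        samples=samples,
        markers=trial.markers,
        expression=trial.expression,
        gene_annotation=trial.gene_annotation,
        titers=trial.titers,
    )
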