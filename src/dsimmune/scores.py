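"""Composite z-score series shared by the cytokine and IFN score stages.

A composite score is the per-sample sum of component z-scores, where each
component (an analyte or a gene) is standardized against the mean and SD of
a reference population — the euploid (D21) cohort for cohort-context
comparisons, or the pooled sample set itself ("self" mode) for trial
across-visit comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CompositeScoreSeries", "composite_score"]


@dataclass
class CompositeScoreSeries:
    """Per-sample composite score with its standardization provenance.

    ``reference_stats`` has one row per component with the reference mean
    and SD used; ``reference_label`` names the reference population so two
    score series can be checked for scale compatibility.
    """

    scores: pd.Series
    components: list[str]
    reference_stats: pd.DataFrame
    reference_label: str
    metadata: dict = field(default_factory=dict)

    def zscores(self, matrix: pd.DataFrame) -> pd.DataFrame:
        """Component z-scores of ``matrix`` under this series' reference."""
        sub = matrix.loc[self.components]
        mu = self.reference_stats["mean"]
        sd = self.reference_stats["sd"]
        return sub.sub(mu, axis=0).div(sd, axis=0)


def composite_score(
    matrix: pd.DataFrame,
    components,
    reference="self",
    reference_label: str | None = None,
) -> CompositeScoreSeries:
    """Sum of component z-scores against a reference population.

    ``matrix`` is component x sample on the analysis scale (log2-adjusted
    values). ``reference`` is either a list of reference sample ids or the
    string ``"self"`` to standardize within the provided samples. The
    reference-population mean score is 0 by construction.
    """
    components = list(components)
    missing = [c for c in components if c not in matrix.index]
    if missing:
        raise ValueError(f"components absent from matrix: {missing}")
    sub = matrix.loc[components]
    if isinstance(reference, str) and reference == "self":
        ref = sub
        label = reference_label or "self"
    else:
        ref_ids = [s for s in reference if s in sub.columns]
        if not ref_ids:
            raise ValueError("no reference samples present in matrix")
        ref = sub[ref_ids]
        label = reference_label or "reference"
    mu = ref.mean(axis=1)
    sd = ref.std(axis=1, ddof=1)
    if (sd == 0).any() or sd.isna().any():
        bad = list(sd.index[(sd == 0) | sd.isna()])
        raise ValueError(f"degenerate reference (zero/undefined SD): {bad}")
    z = sub.sub(mu, axis=0).div(sd, axis=0)
    scores = z.sum(axis=0, skipna=False)
    scores.name = "score"
    stats = pd.DataFrame({"mean": mu, "sd": sd})
    return CompositeScoreSeries(
        scores=scores,
        components=components,
        reference_stats=stats,
        reference_label=label,
    )
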