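"""Interferon-stimulated gene (ISG) selection and IFN score computation.

Individuals with trisomy 21 show a constitutive elevation of interferon
signaling, quantified here as a composite transcriptional score: the sum of
per-gene z-scores over a fixed ISG set. The ISG set is chosen from a
differential-expression result table (T21 vs euploid) by a pure filter —
significant (q below threshold), fold-change at least a floor, and not
encoded on chromosome 21 (chr21 genes such as IFNAR2, MX1 and MX2 are dose
responsive for trivial copy-number reasons and are excluded).

``isg_response_analysis`` evaluates a treatment time course: for a broad
ISG universe it computes per-gene fold-changes of each post-baseline visit
versus baseline and tests, per visit, whether the distribution of gene-level
log2 fold-changes is shifted from zero (one-sample location test,
implemented as the Wilcoxon signed-rank test against 0), with BH correction
across visits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .markers import adjust_covariates
from .scores import CompositeScoreSeries, composite_score
from .stats import benjamini_hochberg

__all__ = [
    "ExpressionMatrix",
    "IsgSet",
    "select_isgs",
    "ifn_score",
    "isg_response_analysis",
]


@dataclass
class ExpressionMatrix:
    """Gene x sample expression (FPKM-like, non-negative) with annotation.

    ``gene_annotation`` is indexed by gene with at least a ``chromosome``
    column.
    """

    values: pd.DataFrame
    gene_annotation: pd.DataFrame

    def __post_init__(self) -> None:
        vals = self.values.values
        if (vals[np.isfinite(vals)] < 0).any():
            raise ValueError("expression values must be non-negative")
        missing = self.values.index.difference(self.gene_annotation.index)
        if len(missing):
            raise ValueError(f"genes without annotation: {list(missing)[:5]} ...")

    def log2(self, pseudocount: float = 1.0) -> pd.DataFrame:
        return np.log2(self.values + pseudocount)


@dataclass
class IsgSet:
    """Ordered ISG list plus the selection parameters that produced it."""

    genes: list[str]
    fc_floor: float = 1.5
    q_max: float = 0.1
    exclude_chrom: str = "chr21"
    selection_record: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


def select_isgs(
    candidates,
    de: pd.DataFrame,
    fc_floor: float = 1.5,
    q_max: float = 0.1,
    exclude_chrom: str = "chr21",
) -> IsgSet:
    """Filter ISG candidates by a differential-expression result table.

    ``de`` is indexed by gene with columns ``fold_change`` (linear scale,
    T21 vs euploid), ``q_value`` and ``chromosome``. A candidate is kept if
    q < ``q_max``, fold-change >= ``fc_floor`` and it is not on
    ``exclude_chrom``. Output order: fold-change descending, gene name as
    tiebreak (deterministic).
    """
    candidates = list(candidates)
    missing = [g for g in candidates if g not in de.index]
    if missing:
        raise ValueError(f"candidates absent from DE table: {missing[:5]} ...")
    sub = de.loc[candidates]
    keep = (
        (sub["q_value"] < q_max)
        & (sub["fold_change"] >= fc_floor)
        & (sub["chromosome"] != exclude_chrom)
    )
    chosen = sub[keep].assign(_gene=lambda d: d.index).sort_values(
        ["fold_change", "_gene"], ascending=[False, True], kind="stable"
    )
    genes = list(chosen.index)
    if not genes:
        raise ValueError(
            "no candidate passes the selection rule; consider relaxing "
            f"fc_floor={fc_floor} or q_max={q_max}"
        )
    return IsgSet(
        genes=genes,
        fc_floor=fc_floor,
        q_max=q_max,
        exclude_chrom=exclude_chrom,
        selection_record={
            "n_candidates": len(candidates),
            "n_selected": len(genes),
            "n_excluded_chrom": int((sub["chromosome"] == exclude_chrom).sum()),
        },
    )


def ifn_score(
    expression: ExpressionMatrix,
    isgs: IsgSet,
    reference="self",
    participants: pd.DataFrame | None = None,
    adjustment: tuple = (),
    keep: str | None = "karyotype",
    pseudocount: float = 1.0,
    reference_label: str | None = None,
) -> CompositeScoreSeries:
    """DS IFN score: sum of per-ISG z-scores against a reference population.

    Expression is log2(FPKM + pseudocount) transformed; optional covariate
    adjustment (age, sex, sequencing batch) is applied before
    standardization. ``reference`` is a euploid sample id set or "self"
    (trial across-visit mode, pooled over visits).
    """
    absent = [g for g in isgs if g not in expression.values.index]
    if absent:
        raise ValueError(f"ISGs absent from expression matrix: {absent}")
    mat = expression.log2(pseudocount).loc[list(isgs)]
    if adjustment:
        if participants is None:
            raise ValueError("participants table required for adjustment")
        mat = adjust_covariates(
            mat, participants, covariates=adjustment, keep=keep
        ).values
    return composite_score(
        mat, list(isgs), reference=reference, reference_label=reference_label
    )


def isg_response_analysis(
    expression: pd.DataFrame,
    sample_meta: pd.DataFrame,
    isg_universe,
    visits=("W2", "W8", "W16"),
    baseline: str = "B",
    aggregate: str = "mean",
    pseudocount: float = 0.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Treatment response of an ISG universe across trial visits.

    ``expression`` is gene x sample (FPKM-like); ``sample_meta`` is indexed
    by sample id with ``participant`` and ``visit`` columns. For each gene
    and visit, the fold-change is the mean (or median) over participants of
    paired log2(expr_visit / expr_baseline); per visit, the gene-level
    fold-changes are tested against zero with a one-sample signed-rank
    location test and BH-corrected across visits.

    Participants lacking a baseline sample are excluded (with a recorded
    warning in the tests table attrs). Returns (fold_changes: gene x visit,
    tests: one row per visit).
    """
    universe = [g for g in isg_universe if g in expression.index]
    absent = [g for g in isg_universe if g not in expression.index]
    if absent:
        raise ValueError(f"universe genes absent from expression: {absent[:5]} ...")
    log2e = np.log2(expression.loc[universe] + pseudocount)

    base_ids = sample_meta[sample_meta["visit"] == baseline]
    base_by_part = dict(zip(base_ids["participant"], base_ids.index))
    skipped = sorted(
        set(sample_meta["participant"]) - set(base_by_part)
    )

    fc = {}
    for visit in visits:
        vmeta = sample_meta[sample_meta["visit"] == visit]
        diffs = []
        for sid, part in zip(vmeta.index, vmeta["participant"]):
            if part not in base_by_part:
                continue
            diffs.append(log2e[sid] - log2e[base_by_part[part]])
        if not diffs:
            raise ValueError(f"no complete baseline pairs at visit {visit}")
        stacked = pd.concat(diffs, axis=1)
        fc[visit] = stacked.median(axis=1) if aggregate == "median" else stacked.mean(
            axis=1
        )
    fold_changes = pd.DataFrame(fc)

    rows = []
    for visit in visits:
        vals = fold_changes[visit].dropna().values
        if np.all(vals == 0):
            stat, p = 0.0, 1.0
        else:
            nz = vals[vals != 0]
            res = sps.wilcoxon(nz, alternative="two-sided")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            {
                "visit": visit,
                "n_genes": int(np.isfinite(vals).sum()),
                "median_log2fc": float(np.median(vals)),
                "statistic": stat,
                "p_value": p,
            }
        )
    tests = pd.DataFrame(rows)
    tests["q_value"] = benjamini_hochberg(tests["p_value"].values)
    tests.attrs["skipped_participants"] = skipped
    tests.attrs["location_test"] = (
        "one-sample Wilcoxon signed-rank vs 0 (one-sample U-test equivalent)"
    )
    return fold_changes, tests
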