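"""Autoantibody reactivity pipeline.

Bead-array autoantigen profiling yields, per reaction, a median fluorescence
intensity (MFI) and a bead count. This module carries those raw
reactivities through the full cohort analysis:

1. technical QC on bead counts (``qc_filter``);
2. per-sample robust normalization to MAD units,
   score = (MFI - median_sample) / MAD_sample, which removes
   sample-specific background (``mad_transform``);
3. positivity calling per antigen against the 90th percentile of the
   euploid (D21) control distribution (``call_positivity``);
4. T21-vs-D21 over-representation by Fisher's exact test with BH FDR
   control, excluding antigens detected in too few samples
   (``test_overrepresentation``);
5. per-sample autoantibody burden summaries (``positivity_burden``) and
   antigen x clinical-phenotype association screens
   (``test_phenotype_associations``).

Single-analyte clinical assays are covered by ``tpo_index`` (ECL anti-TPO
index against negative/positive controls) and ``ana_call`` (ANA ELISA OD
ratio rule, positive iff ratio >= 2.1).

The MAD here is the raw median absolute deviation, with no 1.4826
consistency constant: scores are in MAD units by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats import benjamini_hochberg, fisher_exact

__all__ = [
    "AntigenReactivityMatrix",
    "ReactivityScoreMatrix",
    "PositivityCalls",
    "qc_filter",
    "mad_transform",
    "call_positivity",
    "tpo_index",
    "tpo_threshold",
    "ana_call",
    "test_overrepresentation",
    "positivity_burden",
    "test_phenotype_associations",
]


@dataclass
class AntigenReactivityMatrix:
    """Antigen x sample MFI matrix with per-reaction bead counts.

    ``mfi`` and ``bead_counts`` share index (antigens) and columns
    (samples). ``antigen_meta`` maps antigen id to protein symbol.
    """

    mfi: pd.DataFrame
    bead_counts: pd.DataFrame | None = None
    antigen_meta: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.mfi.values[np.isfinite(self.mfi.values)] < 0).any():
            raise ValueError("MFI values must be non-negative")
        if self.bead_counts is not None and (
            not self.mfi.index.equals(self.bead_counts.index)
            or not self.mfi.columns.equals(self.bead_counts.columns)
        ):
            raise ValueError("bead_counts must align with mfi")

    @property
    def antigens(self) -> pd.Index:
        return self.mfi.index

    @property
    def samples(self) -> pd.Index:
        return self.mfi.columns


@dataclass
class ReactivityScoreMatrix:
    """MAD-normalized reactivity scores (per-sample median 0, MAD 1)."""

    mad_scores: pd.DataFrame
    excluded_samples: list[str] = field(default_factory=list)


@dataclass
class PositivityCalls:
    """Boolean positivity calls with the per-antigen thresholds used."""

    calls: pd.DataFrame
    thresholds: pd.Series
    reference_group: str
    percentile: float = 90.0
    skipped_antigens: list[str] = field(default_factory=list)


def qc_filter(
    matrix: AntigenReactivityMatrix,
    min_beads: int = 20,
    max_missing_frac: float = 0.5,
) -> tuple[AntigenReactivityMatrix, dict]:
    """Mask low-bead reactions and drop antigens/samples mostly missing.

    Reactions with bead count < ``min_beads`` become missing; antigens and
    then samples whose missing fraction exceeds ``max_missing_frac`` are
    dropped. Returns the filtered matrix and an exclusion log.
    """
    if min_beads < 0:
        raise ValueError("min_beads must be >= 0")
    mfi = matrix.mfi.copy()
    beads = matrix.bead_counts
    n_masked = 0
    if beads is not None and min_beads > 0:
        low = beads.values < min_beads
        n_masked = int((low & np.isfinite(mfi.values)).sum())
        mfi.values[low] = np.nan
    antigen_missing = mfi.isna().mean(axis=1)
    dropped_antigens = list(antigen_missing.index[antigen_missing > max_missing_frac])
    mfi = mfi.drop(index=dropped_antigens)
    if mfi.shape[0] == 0:
        raise ValueError("all antigens failed QC")
    sample_missing = mfi.isna().mean(axis=0)
    dropped_samples = list(sample_missing.index[sample_missing > max_missing_frac])
    mfi = mfi.drop(columns=dropped_samples)
    if mfi.shape[1] == 0:
        raise ValueError("all samples failed QC")
    out_beads = None
    if beads is not None:
        out_beads = beads.loc[mfi.index, mfi.columns]
    meta = None
    if matrix.antigen_meta is not None:
        meta = matrix.antigen_meta.loc[matrix.antigen_meta.index.isin(mfi.index)]
    log = {
        "n_reactions_masked": n_masked,
        "dropped_antigens": dropped_antigens,
        "dropped_samples": dropped_samples,
        "min_beads": min_beads,
        "max_missing_frac": max_missing_frac,
    }
    return AntigenReactivityMatrix(mfi, out_beads, meta), log


def mad_transform(matrix: AntigenReactivityMatrix) -> ReactivityScoreMatrix:
    """Per-sample MAD normalization of MFI values.

    score = (MFI - median_sample(MFI)) / MAD_sample(MFI), with the raw MAD
    (no consistency constant). Samples with zero MAD or fewer than 3
    non-missing reactions are excluded and recorded. Missing values
    propagate.
    """
    scores = {}
    excluded = []
    for sample in matrix.mfi.columns:
        col = matrix.mfi[sample].astype(float)
        finite = col.dropna()
        if finite.size < 3:
            excluded.append(sample)
            continue
        med = float(np.median(finite))
        mad = float(np.median(np.abs(finite - med)))
        if mad == 0:
            excluded.append(sample)
            continue
        scores[sample] = (col - med) / mad
    if not scores:
        raise ValueError("no sample has a usable (non-zero) MAD")
    return ReactivityScoreMatrix(pd.DataFrame(scores), excluded_samples=excluded)


def call_positivity(
    scores: ReactivityScoreMatrix,
    control_ids,
    percentile: float = 90.0,
    min_controls: int = 5,
    reference_group: str = "D21",
) -> PositivityCalls:
    """Call positivity per antigen against a control-derived threshold.

    The threshold is the ``percentile`` (linear interpolation) of the
    control samples' scores for that antigen; a call is a score strictly
    above it. Controls are scored against their own threshold too, so
    roughly ``100 - percentile`` percent of controls come out positive per
    antigen by construction. Antigens with fewer than ``min_controls``
    non-missing control scores are skipped.
    """
    mat = scores.mad_scores
    controls = [c for c in control_ids if c in mat.columns]
    thresholds = {}
    skipped = []
    for antigen in mat.index:
        ctrl = mat.loc[antigen, controls].dropna()
        if ctrl.size < min_controls:
            skipped.append(antigen)
            continue
        thresholds[antigen] = float(np.percentile(ctrl.values, percentile))
    if not thresholds:
        raise ValueError("no antigen has enough control samples")
    thr = pd.Series(thresholds, name="threshold")
    calls = mat.loc[thr.index].gt(thr, axis=0) & mat.loc[thr.index].notna()
    return PositivityCalls(
        calls=calls,
        thresholds=thr,
        reference_group=reference_group,
        percentile=percentile,
        skipped_antigens=skipped,
    )


def tpo_index(sample_signal, negative_control: float, positive_control: float):
    """Anti-TPO index: (sample - negative) / (positive - negative)."""
    if positive_control <= negative_control:
        raise ValueError("assay failure: positive control <= negative control")
    return (np.asarray(sample_signal, dtype=float) - negative_control) / (
        positive_control - negative_control
    )


def tpo_threshold(healthy_control_values, percentile: float = 95.0) -> float:
    """Positivity threshold as a percentile of healthy control indices."""
    v = np.asarray(healthy_control_values, dtype=float)
    if v.size == 0:
        raise ValueError("need healthy control values")
    return float(np.percentile(v, percentile))


def ana_call(sample_od, negative_control_od: float):
    """ANA ELISA call: positive iff OD ratio sample/negative >= 2.1."""
    if negative_control_od <= 0:
        raise ValueError("assay failure: non-positive negative-control OD")
    return np.asarray(sample_od, dtype=float) / negative_control_od >= 2.1


def _positivity_table(pos_calls: pd.Series, case_mask: pd.Series) -> tuple:
    a = int((pos_calls & case_mask).sum())
    b = int((~pos_calls & case_mask).sum())
    c = int((pos_calls & ~case_mask).sum())
    d = int((~pos_calls & ~case_mask).sum())
    return a, b, c, d


def test_overrepresentation(
    calls: PositivityCalls,
    groups: pd.Series,
    case_group: str = "T21",
    control_group: str = "D21",
    min_detected: int = 18,
) -> pd.DataFrame:
    """Fisher's exact over-representation screen of positivity in cases.

    Antigens with fewer than ``min_detected`` positive samples in total are
    excluded from testing (low-detection filter). Remaining antigens get a
    2x2 Fisher's exact test (case/control x positive/negative) and BH
    q-values across the tested antigens; significance convention is q < 0.1.
    """
    samples = [s for s in calls.calls.columns if s in groups.index]
    grp = groups.loc[samples]
    keep = grp.isin([case_group, control_group])
    samples = list(grp.index[keep])
    if not samples:
        raise ValueError("no samples in the requested groups")
    case_mask = groups.loc[samples] == case_group
    sub = calls.calls[samples]
    rows = []
    for antigen in sub.index:
        pos = sub.loc[antigen].astype(bool)
        n_detected = int(pos.sum())
        if n_detected < min_detected:
            continue
        a, b, c, d = _positivity_table(pos, case_mask)
        res = fisher_exact([[a, b], [c, d]])
        rows.append(
            {
                "antigen": antigen,
                "odds_ratio": res.effect,
                "p_value": res.p_value,
                "n_positive": n_detected,
                "n_tested": len(samples),
                "n_case_positive": a,
                "n_control_positive": c,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "antigen",
            "odds_ratio",
            "p_value",
            "n_positive",
            "n_tested",
            "n_case_positive",
            "n_control_positive",
        ],
    )
    if len(out):
        out["q_value"] = benjamini_hochberg(out["p_value"].values)
        out["significant"] = out["q_value"] < 0.1
        out = out.sort_values("q_value", kind="stable").reset_index(drop=True)
    else:
        out["q_value"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def positivity_burden(
    calls: PositivityCalls,
    antigen_subset=None,
    bands=((0, 0), (1, 5), (6, None)),
) -> tuple[pd.Series, pd.DataFrame]:
    """Per-sample count of positive calls and banded proportions.

    ``bands`` are inclusive (low, high) count ranges; ``None`` means
    unbounded above. Returns (per-sample counts, band summary with
    proportions summing to 1).
    """
    sub = calls.calls
    if antigen_subset is not None:
        antigen_subset = [a for a in antigen_subset if a in sub.index]
        if not antigen_subset:
            raise ValueError("antigen subset is empty")
        sub = sub.loc[antigen_subset]
    counts = sub.sum(axis=0).astype(int)
    counts.name = "n_positive"
    rows = []
    for lo, hi in bands:
        label = f"{lo}" if hi == lo else (f"{lo}+" if hi is None else f"{lo}-{hi}")
        in_band = (counts >= lo) & (counts <= (np.inf if hi is None else hi))
        rows.append({"band": label, "n_samples": int(in_band.sum())})
    summary = pd.DataFrame(rows)
    summary["proportion"] = summary["n_samples"] / len(counts)
    return counts, summary


def test_phenotype_associations(
    calls: PositivityCalls,
    phenotypes: pd.DataFrame,
    min_cases: int = 5,
) -> pd.DataFrame:
    """Antigen x phenotype association screen within a cohort.

    ``phenotypes`` is sample x flag (boolean, NaN = unknown). Phenotypes
    with fewer than ``min_cases`` cases among called samples are skipped.
    BH correction is applied within each phenotype, across antigens (the
    family choice is recorded in the output).
    """
    rows = []
    for phenotype in phenotypes.columns:
        flags = phenotypes[phenotype]
        flags = flags.loc[flags.index.isin(calls.calls.columns)].dropna().astype(bool)
        if int(flags.sum()) < min_cases:
            continue
        samples = list(flags.index)
        sub = calls.calls[samples]
        case_mask = flags.loc[samples]
        for antigen in sub.index:
            pos = sub.loc[antigen].astype(bool)
            a, b, c, d = _positivity_table(pos, case_mask)
            res = fisher_exact([[a, b], [c, d]])
            rows.append(
                {
                    "phenotype": phenotype,
                    "antigen": antigen,
                    "odds_ratio": res.effect,
                    "p_value": res.p_value,
                    "n_cases": int(case_mask.sum()),
                    "n_tested": len(samples),
                }
            )
    out = pd.DataFrame(
        rows,
        columns=["phenotype", "antigen", "odds_ratio", "p_value", "n_cases", "n_tested"],
    )
    if len(out):
        out["q_value"] = np.nan
        for phenotype, idx in out.groupby("phenotype").groups.items():
            out.loc[idx, "q_value"] = benjamini_hochberg(out.loc[idx, "p_value"].values)
        out.attrs["bh_family"] = "within phenotype, across antigens"
    return out
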