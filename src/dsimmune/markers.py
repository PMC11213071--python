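"""Multiplex inflammatory-marker panel analysis.

Plasma concentrations (pg/mL) from multiplex immunoassay plates arrive as
duplicate wells per sample with plate ids and range-status flags (in range,
below or above the fit-curve range). The pipeline:

1. ``preprocess_panel`` — impute out-of-range missing values with the
   per-plate per-analyte minimum (below range) or maximum (above range) of
   the in-range concentrations, flag analytes with more than 10% of wells
   out of range, and average duplicate wells per sample;
2. ``exclude_outliers_per_group`` — mask extreme outliers (beyond 3*IQR
   outside the quartiles) per karyotype and analyte;
3. ``MarkerDifferentialAbundance`` — mixed-effects linear regression with
   log2 concentration as outcome, group (e.g. T21 status) as predictor, age
   and sex as fixed covariates and sample source as a random intercept;
   the group coefficient is the log2 fold-change, with BH q-values across
   analytes at 10% FDR;
4. ``adjust_covariates`` — residualize nuisance covariates (age, sex,
   source) out of the log2 values prior to visualization or scoring while
   preserving the group contrast;
5. ``cytokine_score`` — composite score as the sum of z-scores for TNF-a,
   IL-6, CRP and IP-10 against a euploid reference (or "self" for trial
   across-visit comparisons).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .scores import CompositeScoreSeries, composite_score
from .stats import benjamini_hochberg, extreme_outlier_mask

__all__ = [
    "MarkerPanel",
    "AdjustedMatrix",
    "preprocess_panel",
    "exclude_outliers_per_group",
    "MarkerDifferentialAbundance",
    "MarkerDAResults",
    "adjust_covariates",
    "cytokine_score",
    "CYTOKINE_SCORE_COMPONENTS",
]

CYTOKINE_SCORE_COMPONENTS = ("TNF-a", "IL-6", "CRP", "IP-10")

WELL_COLUMNS = ["sample_id", "analyte", "plate", "well", "concentration", "range_status"]
RANGE_STATUSES = {"in_range", "below_range", "above_range"}


@dataclass
class MarkerPanel:
    """Analyte x well concentration data in long format.

    ``wells`` columns: sample_id, analyte, plate, well, concentration
    (pg/mL; NaN when out of calculable range), range_status in
    {in_range, below_range, above_range}. ``analyte_flags`` marks analytes
    with an excessive out-of-range fraction (flagged, not dropped).
    """

    wells: pd.DataFrame
    analyte_flags: pd.Series | None = None
    out_of_range_fraction: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in WELL_COLUMNS if c not in self.wells.columns]
        if missing:
            raise ValueError(f"wells table missing columns: {missing}")
        bad = set(self.wells["range_status"].unique()) - RANGE_STATUSES
        if bad:
            raise ValueError(f"unknown range_status values: {sorted(bad)}")

    @property
    def analytes(self) -> list[str]:
        return sorted(self.wells["analyte"].unique())

    @property
    def samples(self) -> list[str]:
        return sorted(self.wells["sample_id"].unique())

    def to_matrix(self) -> pd.DataFrame:
        """Analyte x sample matrix, averaging any remaining duplicates."""
        return self.wells.pivot_table(
            index="analyte", columns="sample_id", values="concentration", aggfunc="mean"
        )


def preprocess_panel(panel: MarkerPanel, flag_fraction: float = 0.10) -> MarkerPanel:
    """Impute out-of-range wells, flag noisy analytes, average duplicates.

    Missing concentrations flagged below (above) the fit-curve range are
    replaced with the minimum (maximum) in-range concentration on the same
    plate for that analyte. Analytes with more than ``flag_fraction`` of
    wells out of range are flagged but retained. Duplicate wells are then
    averaged to one value per (sample, analyte). The operation is
    idempotent: a preprocessed panel passes through unchanged (flags are
    sticky).
    """
    wells = panel.wells.copy()

    frac = (
        wells.assign(oor=wells["range_status"] != "in_range")
        .groupby("analyte")["oor"]
        .mean()
    )
    flags = frac > flag_fraction
    if panel.analyte_flags is not None:
        flags = flags | panel.analyte_flags.reindex(flags.index, fill_value=False)
    if panel.out_of_range_fraction is not None:
        frac = np.maximum(
            frac, panel.out_of_range_fraction.reindex(frac.index, fill_value=0.0)
        )

    needs = wells["concentration"].isna() & (wells["range_status"] != "in_range")
    if needs.any():
        in_range = wells[wells["range_status"] == "in_range"].dropna(
            subset=["concentration"]
        )
        lo = in_range.groupby(["plate", "analyte"])["concentration"].min()
        hi = in_range.groupby(["plate", "analyte"])["concentration"].max()
        keys = pd.MultiIndex.from_frame(wells.loc[needs, ["plate", "analyte"]])
        impossible = sorted(set(keys) - set(lo.index))
        if impossible:
            raise ValueError(
                "imputation impossible, no in-range values for (plate, analyte): "
                f"{impossible}"
            )
        below = needs & (wells["range_status"] == "below_range")
        above = needs & (wells["range_status"] == "above_range")
        if below.any():
            k = pd.MultiIndex.from_frame(wells.loc[below, ["plate", "analyte"]])
            wells.loc[below, "concentration"] = lo.loc[k].values
        if above.any():
            k = pd.MultiIndex.from_frame(wells.loc[above, ["plate", "analyte"]])
            wells.loc[above, "concentration"] = hi.loc[k].values

    collapsed = (
        wells.groupby(["sample_id", "analyte"], as_index=False)
        .agg(
            plate=("plate", "first"),
            well=("well", "first"),
            concentration=("concentration", "mean"),
        )
        .assign(range_status="in_range")
    )
    return MarkerPanel(
        wells=collapsed[WELL_COLUMNS],
        analyte_flags=flags.sort_index(),
        out_of_range_fraction=frac.sort_index(),
    )


def exclude_outliers_per_group(
    matrix: pd.DataFrame, groups: pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mask extreme outliers within each (analyte, karyotype group).

    Values more than 3*IQR beyond the group quartiles are set missing.
    Returns the masked matrix and an exclusion log (analyte, sample, group,
    value).
    """
    out = matrix.copy()
    log_rows = []
    grp = groups.loc[[s for s in matrix.columns if s in groups.index]]
    for level in grp.unique():
        cols = list(grp.index[grp == level])
        block = out[cols]
        for analyte in block.index:
            mask = extreme_outlier_mask(block.loc[analyte].values)
            if mask.any():
                for s, v in zip(np.array(cols)[mask], block.loc[analyte].values[mask]):
                    log_rows.append(
                        {"analyte": analyte, "sample_id": s, "group": level, "value": v}
                    )
                out.loc[analyte, np.array(cols)[mask]] = np.nan
    log = pd.DataFrame(log_rows, columns=["analyte", "sample_id", "group", "value"])
    return out, log


class MarkerDifferentialAbundance:
    """Per-analyte mixed-effects differential abundance model.

    For each analyte fits

        log2(concentration) ~ group + age + sex  (+ random intercept: source)

    by REML. The group coefficient is the log2 fold-change of the case
    group versus the reference level. When the design has a single source
    level the model collapses to ordinary least squares, and the fallback
    is recorded per analyte.

    Parameters
    ----------
    matrix : DataFrame, analyte x sample, concentrations (pg/mL) or
        log2 values if ``log2_transform=False``.
    participants : DataFrame indexed by sample id with the group column,
        covariates and the random-effect column.
    """

    def __init__(
        self,
        matrix: pd.DataFrame,
        participants: pd.DataFrame,
        group: str = "karyotype",
        reference_level: str = "D21",
        covariates: tuple = ("age", "sex"),
        random_effect: str | None = "source",
        log2_transform: bool = True,
    ) -> None:
        self.matrix = matrix
        self.participants = participants
        self.group = group
        self.reference_level = reference_level
        self.covariates = tuple(covariates)
        self.random_effect = random_effect
        self.log2_transform = log2_transform

    def _formula(self) -> str:
        terms = [f"C(Q('{self.group}'), Treatment('{self.reference_level}'))"]
        terms += [f"Q('{c}')" for c in self.covariates]
        return "y ~ " + " + ".join(terms)

    def fit(self) -> "MarkerDAResults":
        formula = self._formula()
        rows = []
        for analyte in self.matrix.index:
            y = self.matrix.loc[analyte].astype(float)
            data = self.participants.copy()
            data = data.loc[[s for s in y.index if s in data.index]]
            data["y"] = y.loc[data.index]
            if self.log2_transform:
                data["y"] = np.log2(data["y"])
            data = data.dropna(subset=["y", self.group, *self.covariates])
            counts = data[self.group].value_counts()
            if len(counts) < 2 or counts.min() < 2:
                rows.append(self._error_row(analyte, "insufficient group sizes"))
                continue
            n_src = (
                data[self.random_effect].nunique()
                if self.random_effect is not None
                else 1
            )
            try:
                if self.random_effect is not None and n_src > 1:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        res = smf.mixedlm(
                            formula, data, groups=data[self.random_effect]
                        ).fit(reml=True)
                    method = "mixedlm"
                    converged = bool(res.converged)
                else:
                    res = smf.ols(formula, data).fit()
                    method = "ols"
                    converged = True
            except (np.linalg.LinAlgError, ValueError) as exc:
                rows.append(self._error_row(analyte, f"fit failed: {exc}"))
                continue
            coef_name = next(
                (n for n in res.params.index if n.startswith("C(Q(")), None
            )
            if coef_name is None:
                rows.append(self._error_row(analyte, "rank-deficient design"))
                continue
            rows.append(
                {
                    "analyte": analyte,
                    "log2_fc": float(res.params[coef_name]),
                    "se": float(res.bse[coef_name]),
                    "p_value": float(res.pvalues[coef_name]),
                    "method": method,
                    "converged": converged,
                    "n_used": int(len(data)),
                    "error": "",
                }
            )
        table = pd.DataFrame(rows).set_index("analyte")
        ok = table["error"] == ""
        q = np.full(len(table), np.nan)
        q[ok.values] = benjamini_hochberg(table.loc[ok, "p_value"].values)
        table["q_value"] = q
        table["significant"] = table["q_value"] < 0.1
        return MarkerDAResults(table=table, model=self)

    @staticmethod
    def _error_row(analyte, msg) -> dict:
        return {
            "analyte": analyte,
            "log2_fc": np.nan,
            "se": np.nan,
            "p_value": np.nan,
            "method": "",
            "converged": False,
            "n_used": 0,
            "error": msg,
        }


@dataclass
class MarkerDAResults:
    """Differential-abundance results, one row per analyte.

    Columns: log2_fc (group coefficient = log2 fold-change), se, p_value,
    q_value (BH across analytes), method (mixedlm / ols fallback),
    converged, n_used, significant (q < 0.1).
    """

    table: pd.DataFrame
    model: MarkerDifferentialAbundance

    @property
    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"].fillna(False)]

    def summary(self) -> str:
        m = self.model
        ok = self.table["error"] == ""
        lines = [
            "Marker differential abundance",
            f"  model: log2(conc) ~ {m.group} + " + " + ".join(m.covariates),
            f"  random intercept: {m.random_effect}",
            f"  analytes fit: {int(ok.sum())} / {len(self.table)}",
            f"  significant at q<0.1: {int(self.table['significant'].sum())}",
            "",
            self.table.loc[
                ok, ["log2_fc", "se", "p_value", "q_value", "method", "n_used"]
            ]
            .sort_values("q_value")
            .to_string(),
        ]
        return "\n".join(lines)


@dataclass
class AdjustedMatrix:
    """Covariate-adjusted log2 matrix plus a record of what was removed."""

    values: pd.DataFrame
    adjustment_record: dict = field(default_factory=dict)


def _design_columns(participants: pd.DataFrame, names) -> pd.DataFrame:
    """Numeric design block: numeric columns as-is, categoricals dummied."""
    blocks = []
    for name in names:
        col = participants[name]
        if pd.api.types.is_numeric_dtype(col):
            blocks.append(col.astype(float).to_frame(name))
        else:
            d = pd.get_dummies(col, prefix=name, drop_first=True, dtype=float)
            blocks.append(d)
    if not blocks:
        return pd.DataFrame(index=participants.index)
    return pd.concat(blocks, axis=1)


def adjust_covariates(
    matrix: pd.DataFrame,
    participants: pd.DataFrame,
    covariates=("age", "sex", "source"),
    keep: str | None = "karyotype",
) -> AdjustedMatrix:
    """Remove nuisance-covariate contributions from a log2 matrix.

    Per analyte, fits a linear model on the kept effect plus the nuisance
    covariates and subtracts the estimated nuisance contributions evaluated
    at mean-centered covariates, so the intercept and the kept group
    contrast are preserved (the removeBatchEffect idiom).
    """
    samples = [s for s in matrix.columns if s in participants.index]
    part = participants.loc[samples]
    nuis = _design_columns(part, covariates)
    # constant covariates carry no adjustable variation; their centered
    # contribution is identically zero, so drop them rather than flag
    # the design as collinear with the intercept
    nuis = nuis.loc[:, nuis.std(axis=0) > 0]
    keep_block = _design_columns(part, [keep]) if keep is not None else pd.DataFrame(
        index=part.index
    )
    X = np.column_stack(
        [np.ones(len(samples)), keep_block.values, nuis.values]
    ).astype(float)
    if nuis.shape[1]:
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError(
                f"collinear design among covariates {list(nuis.columns)}"
            )
    n_keep = keep_block.shape[1]
    nuis_centered = nuis.values - nuis.values.mean(axis=0, keepdims=True)

    Y = matrix[samples].values.astype(float)
    adjusted = Y.copy()
    if nuis.shape[1]:
        finite_rows = np.isfinite(Y).all(axis=1)
        pinv = np.linalg.pinv(X)
        if finite_rows.all():
            beta = pinv @ Y.T  # (p, n_analytes)
            beta_nuis = beta[1 + n_keep :, :]
            adjusted = Y - (nuis_centered @ beta_nuis).T
        else:
            for i in range(Y.shape[0]):
                mask = np.isfinite(Y[i])
                if mask.sum() < X.shape[1]:
                    continue
                b = np.linalg.pinv(X[mask]) @ Y[i, mask]
                adjusted[i, mask] = Y[i, mask] - nuis_centered[mask] @ b[1 + n_keep :]
    out = pd.DataFrame(adjusted, index=matrix.index, columns=samples)
    record = {"covariates_removed": list(covariates), "kept": keep}
    return AdjustedMatrix(values=out, adjustment_record=record)


def cytokine_score(
    matrix: pd.DataFrame,
    components=CYTOKINE_SCORE_COMPONENTS,
    reference="self",
    reference_label: str | None = None,
) -> CompositeScoreSeries:
    """Composite cytokine score: sum of z-scores for TNF-a, IL-6, CRP, IP-10.

    ``matrix`` must be on the analysis scale (log2, covariate-adjusted).
    ``reference`` is a set of euploid reference sample ids, or "self" to
    standardize within the provided samples (trial across-visit mode).
    """
    return composite_score(
        matrix, components, reference=reference, reference_label=reference_label
    )
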