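"""Beta regression for immune-cell cluster frequencies.

Mass-cytometry cluster proportions live in (0, 1) and are heteroskedastic
near the boundaries, so group differences are modelled with a beta
likelihood: logit mean link, constant (log-link) precision per cluster.
The group coefficient on the logit scale, exponentiated, is reported as a
"fold-change" (strictly, an odds ratio of proportions) to match the common
reporting convention for this analysis.

``BetaRegression`` is a thin model class in the statsmodels style: build
from data, ``fit()`` returns a results object with coefficients, standard
errors, Wald p-values, the precision estimate and convergence diagnostics.
``cluster_differential_frequency`` runs the full screen: per-group extreme
outlier exclusion, per-cluster fit of proportion ~ group + age + sex, BH
across clusters at 10% FDR.

Boundary proportions (exactly 0 or 1) are handled by the standard squeeze
transform y' = (y*(n-1) + 0.5)/n, toggleable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, logit
from statsmodels.othermod.betareg import BetaModel

from .markers import _design_columns
from .stats import benjamini_hochberg, extreme_outlier_mask

__all__ = [
    "BetaRegression",
    "BetaRegressionResults",
    "squeeze_proportions",
    "cluster_differential_frequency",
    "adjusted_frequencies_for_display",
]


def squeeze_proportions(y: np.ndarray) -> np.ndarray:
    """Boundary squeeze y' = (y*(n-1) + 0.5)/n for y containing 0 or 1."""
    y = np.asarray(y, dtype=float)
    n = y.size
    return (y * (n - 1) + 0.5) / n


class BetaRegression:
    """Beta regression with logit mean link and constant precision.

    Parameters
    ----------
    y : proportions strictly in (0, 1); exact 0/1 values raise unless
        ``squeeze=True`` (default), in which case the squeeze transform is
        applied and recorded.
    X : design DataFrame (no intercept column; one is added).
    """

    def __init__(self, y, X: pd.DataFrame | None = None, squeeze: bool = True):
        y = np.asarray(y, dtype=float)
        if np.any(~np.isfinite(y)):
            raise ValueError("y contains non-finite values")
        self.squeezed = False
        if np.any((y <= 0) | (y >= 1)):
            if np.any((y < 0) | (y > 1)):
                raise ValueError("proportions must lie in [0, 1]")
            if not squeeze:
                raise ValueError(
                    "proportions on the boundary {0,1}; enable squeeze or "
                    "preprocess the data"
                )
            y = squeeze_proportions(y)
            self.squeezed = True
        self.y = y
        if X is None:
            X = pd.DataFrame(index=range(y.size))
        self.feature_names = list(X.columns)
        self.exog = np.column_stack([np.ones(y.size), X.values.astype(float)])
        self.exog_names = ["intercept", *self.feature_names]
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("design matrix is rank deficient")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        predictors,
        squeeze: bool = True,
    ) -> "BetaRegression":
        X = _design_columns(data, predictors)
        return cls(data[outcome].values, X, squeeze=squeeze)

    def _start_params(self, rng=None) -> np.ndarray:
        # logit-scale OLS start for the mean; method-of-moments precision
        z = logit(np.clip(self.y, 1e-6, 1 - 1e-6))
        beta, *_ = np.linalg.lstsq(self.exog, z, rcond=None)
        mu = expit(self.exog @ beta)
        resid_var = max(np.var(self.y - mu), 1e-8)
        phi = max(np.mean(mu * (1 - mu)) / resid_var - 1.0, 1.0)
        start = np.append(beta, np.log(phi))
        if rng is not None:
            start = start + rng.normal(0, 0.2, size=start.size)
        return start

    def fit(self, maxiter: int = 200, restarts: int = 5) -> "BetaRegressionResults":
        """Maximum-likelihood fit with jittered restarts on non-convergence."""
        model = BetaModel(self.y, self.exog)
        rng = np.random.default_rng(0)
        res = None
        for attempt in range(restarts + 1):
            start = self._start_params(rng if attempt else None)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    cand = model.fit(
                        start_params=start, maxiter=maxiter, disp=False
                    )
                except (np.linalg.LinAlgError, ValueError):
                    continue
            res = cand
            if cand.mle_retvals.get("converged", False):
                break
        if res is None:
            raise RuntimeError("beta regression failed on all restarts")
        k = len(self.exog_names)
        params = pd.Series(res.params[:k], index=self.exog_names)
        bse = pd.Series(res.bse[:k], index=self.exog_names)
        pvals = pd.Series(res.pvalues[:k], index=self.exog_names)
        return BetaRegressionResults(
            params=params,
            bse=bse,
            pvalues=pvals,
            precision=float(np.exp(res.params[-1])),
            llf=float(res.llf),
            converged=bool(res.mle_retvals.get("converged", False)),
            n_obs=int(self.y.size),
            squeezed=self.squeezed,
            model=self,
            _sm_result=res,
        )

    def loglike(self, params: np.ndarray) -> float:
        """Log-likelihood at arbitrary (beta..., log precision) params."""
        return float(BetaModel(self.y, self.exog).loglike(np.asarray(params)))


@dataclass
class BetaRegressionResults:
    """Fitted beta-regression coefficients and diagnostics.

    ``params`` are on the logit scale; ``fold_change(name)`` exponentiates
    a coefficient (the reference level's fold-change is exactly 1).
    """

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    precision: float
    llf: float
    converged: bool
    n_obs: int
    squeezed: bool
    model: BetaRegression
    _sm_result: object = None

    def fold_change(self, name: str | None = None) -> float:
        if name is None:
            candidates = [n for n in self.params.index if n != "intercept"]
            if not candidates:
                return 1.0
            name = candidates[0]
        return float(np.exp(self.params[name]))

    def summary(self) -> str:
        tab = pd.DataFrame(
            {
                "coef": self.params,
                "se": self.bse,
                "p_value": self.pvalues,
                "exp(coef)": np.exp(self.params),
            }
        )
        lines = [
            "Beta regression (logit mean link, constant precision)",
            f"  n = {self.n_obs}, precision = {self.precision:.3f}, "
            f"llf = {self.llf:.3f}, converged = {self.converged}",
            tab.to_string(),
        ]
        if self.squeezed:
            lines.append("  note: boundary proportions squeezed")
        return "\n".join(lines)


def cluster_differential_frequency(
    freqs: pd.DataFrame,
    participants: pd.DataFrame,
    group: str = "karyotype",
    reference_level: str = "D21",
    covariates: tuple = ("age", "sex"),
    min_per_group: int = 10,
    squeeze: bool = True,
) -> pd.DataFrame:
    """Differential cluster-frequency screen via beta regression.

    For each cluster (row of ``freqs``, cluster x sample proportions):
    extreme outliers are excluded per group (3*IQR rule), then proportion ~
    group + covariates is fit with a logit-link beta model; the group
    coefficient is exponentiated to a fold-change. BH q-values are computed
    across clusters; clusters with fewer than ``min_per_group`` usable
    samples in either group are skipped with a warning entry.
    """
    samples = [s for s in freqs.columns if s in participants.index]
    part = participants.loc[samples]
    grp = part[group]
    rows = []
    for cluster in freqs.index:
        y = freqs.loc[cluster, samples].astype(float)
        # per-group extreme-outlier exclusion
        excluded = pd.Series(False, index=y.index)
        for level in grp.unique():
            idx = grp.index[grp == level]
            mask = extreme_outlier_mask(y.loc[idx].values)
            excluded.loc[idx[mask]] = True
        use = y.notna() & ~excluded
        counts = grp[use].value_counts()
        if len(counts) < 2 or counts.min() < min_per_group:
            rows.append(
                {
                    "cluster": cluster,
                    "coefficient": np.nan,
                    "se": np.nan,
                    "fold_change": np.nan,
                    "p_value": np.nan,
                    "precision": np.nan,
                    "n_used": int(use.sum()),
                    "n_excluded_outliers": int(excluded.sum()),
                    "converged": False,
                    "error": "insufficient samples per group",
                }
            )
            continue
        data = part.loc[use.index[use], [group, *covariates]].copy()
        data[group] = pd.Categorical(
            data[group],
            categories=[reference_level]
            + [g for g in grp.unique() if g != reference_level],
        )
        data["y"] = y.loc[data.index]
        try:
            model = BetaRegression.from_dataframe(
                data, "y", [group, *covariates], squeeze=squeeze
            )
            res = model.fit()
        except (ValueError, RuntimeError) as exc:
            rows.append(
                {
                    "cluster": cluster,
                    "coefficient": np.nan,
                    "se": np.nan,
                    "fold_change": np.nan,
                    "p_value": np.nan,
                    "precision": np.nan,
                    "n_used": int(use.sum()),
                    "n_excluded_outliers": int(excluded.sum()),
                    "converged": False,
                    "error": str(exc),
                }
            )
            continue
        coef_name = next(n for n in res.params.index if n.startswith(f"{group}_"))
        rows.append(
            {
                "cluster": cluster,
                "coefficient": float(res.params[coef_name]),
                "se": float(res.bse[coef_name]),
                "fold_change": float(np.exp(res.params[coef_name])),
                "p_value": float(res.pvalues[coef_name]),
                "precision": res.precision,
                "n_used": res.n_obs,
                "n_excluded_outliers": int(excluded.sum()),
                "converged": res.converged,
                "error": "",
            }
        )
    out = pd.DataFrame(rows).set_index("cluster")
    ok = out["error"] == ""
    q = np.full(len(out), np.nan)
    q[ok.values] = benjamini_hochberg(out.loc[ok, "p_value"].values)
    out["q_value"] = q
    out["significant"] = out["q_value"] < 0.1
    return out


def adjusted_frequencies_for_display(
    freqs: pd.DataFrame,
    participants: pd.DataFrame,
    covariates: tuple = ("age", "sex"),
    keep: str | None = "karyotype",
) -> pd.DataFrame:
    """Age/sex-adjusted proportions for visualization (sina plots).

    Residualizes the covariates on the logit scale (preserving the kept
    group contrast) and back-transforms, so values remain in (0, 1).
    """
    from .markers import adjust_covariates

    samples = [s for s in freqs.columns if s in participants.index]
    vals = freqs[samples].astype(float)
    eps = 1e-9
    z = logit(vals.clip(lower=eps, upper=1 - eps))
    adj = adjust_covariates(z, participants, covariates=covariates, keep=keep)
    return pd.DataFrame(
        expit(adj.values.values), index=vals.index, columns=adj.values.columns
    )
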