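"""Mixed-effects models over the attempt-level metrics table.

The modelling interface follows the Model/Results convention: a
:class:`MixedModel` is built from a :class:`ModelSpec` and a metrics
DataFrame, and ``fit()`` returns a :class:`MixedModelResults` carrying
coefficient estimates with Wald z-tests, the ML log-likelihood with AIC/BIC
recomputable from its parts, empirical-Bayes random-effect predictions, and
the random-effect covariance.

Families are restricted by outcome: the binary ``correct`` outcome uses a
logistic model (fitted by adaptive quadrature / Laplace ML, see
``glmm``); all continuous outcomes use Gaussian models (statsmodels
MixedLM).  ML — never REML — likelihoods are used so AIC/BIC comparisons
across fixed-effect structures are valid.

Model selection fits a ladder of candidate specifications on a harmonised
row set and picks the minimal-criterion fit, breaking ties toward fewer
parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glmm import fit_logistic_intercept, fit_logistic_vector

__all__ = [
    "ModelSpec",
    "MixedModel",
    "MixedModelResults",
    "ModelFitError",
    "fit_mixed_model",
    "model_selection",
    "default_ladder",
    "effect_reversal_analysis",
    "ReversalReport",
]

OUTCOME_FAMILIES = {
    "correct": "binomial",
    "value_fraction": "gaussian",
    "time_s": "gaussian",
    "n_moves": "gaussian",
    "sec_per_move": "gaussian",
    "productivity": "gaussian",
    "first_full_overlap": "gaussian",
}

RANDOM_STRUCTURES = ("none", "intercept", "condition")

# term names users may put in fixed_terms; "condition" expands to per-drug
# treatment contrasts against placebo
_CONDITION_TERM = "C(condition, Treatment('PLC'))"


class ModelFitError(RuntimeError):
    """A model failed to fit; carries the optimizer message."""


@dataclass(frozen=True)
class ModelSpec:
    """One model specification: outcome, fixed terms, random structure.

    ``fixed_terms`` are formula terms over metrics-table columns; the
    special term ``"condition"`` expands to per-drug treatment contrasts
    with placebo as reference, while the ``"drug"`` column is the pooled
    active-condition indicator.  ``random`` is one of ``"none"``,
    ``"intercept"`` (participant intercept) or ``"condition"`` (one
    participant intercept per condition, unstructured covariance).
    """

    outcome: str
    fixed_terms: tuple[str, ...] = ()
    random: str = "intercept"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOME_FAMILIES:
            raise ValueError(
                f"unknown outcome {self.outcome!r}; expected one of "
                f"{sorted(OUTCOME_FAMILIES)}"
            )
        if self.random not in RANDOM_STRUCTURES:
            raise ValueError(f"random must be one of {RANDOM_STRUCTURES}")

    @property
    def family(self) -> str:
        return OUTCOME_FAMILIES[self.outcome]

    @property
    def formula(self) -> str:
        terms = [_CONDITION_TERM if t == "condition" else t for t in self.fixed_terms]
        rhs = " + ".join(terms) if terms else "1"
        return f"{self.outcome} ~ {rhs}"

    def label(self) -> str:
        return f"{self.formula} | re={self.random}"

    def required_columns(self) -> set[str]:
        cols = {self.outcome, "participant_id"}
        for t in self.fixed_terms:
            if t == "condition":
                cols.add("condition")
            else:
                for piece in t.replace("*", ":").split(":"):
                    cols.add(piece.strip())
        if self.random == "condition":
            cols.add("condition")
        return cols


@dataclass
class MixedModelResults:
    """Fitted mixed model: estimates, Wald tests, information criteria,
    random-effect predictions."""

    spec: ModelSpec
    params: pd.Series
    bse: pd.Series
    llf: float
    n_params: int
    nobs: int
    n_groups: int
    random_effects: pd.DataFrame | None   # participants x RE columns
    cov_re: pd.DataFrame | None
    converged: bool = True
    singular: bool = False
    n_dropped: int = 0
    message: str = ""

    @property
    def zvalues(self) -> pd.Series:
        return self.params / self.bse

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series(2 * sps.norm.sf(np.abs(self.zvalues)), index=self.params.index)

    @property
    def aic(self) -> float:
        return -2.0 * self.llf + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return -2.0 * self.llf + np.log(self.nobs) * self.n_params

    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.params, "se": self.bse,
             "z": self.zvalues, "p": self.pvalues}
        )

    def random_effect_correlations(self) -> pd.DataFrame:
        """Pairwise correlations of the random effects with Wald-type
        z-tests (Fisher transform, n = number of participants)."""
        if self.cov_re is None or self.cov_re.shape[0] < 2:
            raise ValueError("model has no multivariate random effects")
        sd = np.sqrt(np.diag(self.cov_re.values))
        rows = []
        names = list(self.cov_re.columns)
        for i in range(len(names)):
            for j in range(i + 1, len(names)):
                r = self.cov_re.values[i, j] / (sd[i] * sd[j])
                r = float(np.clip(r, -0.999999, 0.999999))
                z = np.arctanh(r) * np.sqrt(max(self.n_groups - 3, 1))
                rows.append(
                    {"pair": f"{names[i]}~{names[j]}", "corr": r,
                     "z": z, "p": 2 * sps.norm.sf(abs(z))}
                )
        return pd.DataFrame(rows).set_index("pair")

    def summary(self) -> str:
        lines = [
            f"Model: {self.spec.label()}  [{self.spec.family}]",
            f"nobs={self.nobs} groups={self.n_groups} dropped={self.n_dropped}",
            f"logLik={self.llf:.3f}  AIC={self.aic:.2f}  BIC={self.bic:.2f}  "
            f"k={self.n_params}",
            f"converged={self.converged}" + ("  SINGULAR-RE" if self.singular else ""),
            "",
            self.coefficients().to_string(float_format=lambda v: f"{v:.4f}"),
        ]
        if self.cov_re is not None:
            lines += ["", "Random-effect covariance:",
                      self.cov_re.to_string(float_format=lambda v: f"{v:.5f}")]
        return "\n".join(lines)


def _condition_re_columns(data: pd.DataFrame) -> list[str]:
    return sorted(data["condition"].unique())


class MixedModel:
    """Mixed-effects model of one attempt-level outcome.

    Parameters
    ----------
    spec : ModelSpec
    data : DataFrame
        Attempt-level metrics table (one row per attempt).  Rows with a
        missing outcome or regressor are dropped (with a recorded count)
        before fitting.
    """

    def __init__(self, spec: ModelSpec, data: pd.DataFrame):
        missing = spec.required_columns() - set(data.columns)
        if missing:
            raise ValueError(f"metrics table lacks columns {sorted(missing)}")
        self.spec = spec
        cols = sorted(spec.required_columns())
        usable = data[cols].dropna()
        self.n_dropped = len(data) - len(usable)
        self.data = data.loc[usable.index]
        if self.data["participant_id"].nunique() < 2:
            raise ValueError("need at least 2 participants")

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, outcome: str,
                       fixed_terms: Sequence[str] = (),
                       random: str = "intercept") -> "MixedModel":
        return cls(ModelSpec(outcome, tuple(fixed_terms), random), data)

    def fit(self) -> MixedModelResults:
        if self.spec.family == "gaussian":
            return self._fit_gaussian()
        return self._fit_binomial()

    # -- gaussian ----------------------------------------------------------
    def _fit_gaussian(self) -> MixedModelResults:
        import statsmodels.formula.api as smf

        data = self.data
        spec = self.spec
        if spec.random == "none":
            fit = smf.ols(spec.formula, data=data).fit()
            k = len(fit.params) + 1  # + residual variance
            return MixedModelResults(
                spec=spec, params=fit.params, bse=fit.bse, llf=float(fit.llf),
                n_params=k, nobs=int(fit.nobs),
                n_groups=data["participant_id"].nunique(),
                random_effects=None, cov_re=None, converged=True,
                n_dropped=self.n_dropped,
            )
        re_formula = "1" if spec.random == "intercept" else "0 + C(condition)"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = smf.mixedlm(spec.formula, data=data,
                                groups=data["participant_id"],
                                re_formula=re_formula)
            try:
                fit = model.fit(reml=False)
            except Exception as exc:  # noqa: BLE001 - surfaced as fit error
                raise ModelFitError(f"{spec.label()}: {exc}") from exc
        if not fit.converged:
            # retry from the powell optimizer before giving up
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                try:
                    fit2 = model.fit(reml=False, method="powell")
                    if fit2.converged:
                        fit = fit2
                except Exception:
                    pass
        fe = fit.fe_params
        q = 1 if spec.random == "intercept" else data["condition"].nunique()
        n_cov = q * (q + 1) // 2
        k = len(fe) + n_cov + 1  # + residual variance
        cov_re = pd.DataFrame(np.atleast_2d(np.asarray(fit.cov_re)))
        if spec.random == "intercept":
            cov_re.index = cov_re.columns = ["intercept"]
            re_df = pd.DataFrame(
                {"intercept": {g: float(v.iloc[0]) for g, v in fit.random_effects.items()}}
            )
        else:
            conds = _condition_re_columns(data)
            names = list(fit.cov_re.columns)
            pretty = [n.split("[")[-1].rstrip("]").replace("T.", "") for n in names]
            cov_re.index = cov_re.columns = pretty
            re_df = pd.DataFrame(
                {g: pd.Series(np.asarray(v), index=pretty)
                 for g, v in fit.random_effects.items()}
            ).T
            re_df = re_df[sorted(re_df.columns, key=conds.index)]
        if not np.isfinite(fit.llf):
            raise ModelFitError(f"{spec.label()}: degenerate fit (non-finite log-likelihood)")
        eig = np.linalg.eigvalsh(cov_re.values)
        singular = bool(eig.min() < 1e-8 * max(eig.max(), 1e-12))
        return MixedModelResults(
            spec=spec, params=fe, bse=fit.bse_fe, llf=float(fit.llf),
            n_params=k, nobs=int(fit.nobs),
            n_groups=data["participant_id"].nunique(),
            random_effects=re_df, cov_re=cov_re,
            converged=bool(fit.converged), singular=singular,
            n_dropped=self.n_dropped,
        )

    # -- binomial ----------------------------------------------------------
    def _fit_binomial(self) -> MixedModelResults:
        import statsmodels.formula.api as smf
        from patsy import dmatrices, dmatrix

        data = self.data.copy()
        data[self.spec.outcome] = data[self.spec.outcome].astype(float)
        spec = self.spec
        if spec.random == "none":
            import statsmodels.api as sm

            fit = smf.glm(spec.formula, data=data,
                          family=sm.families.Binomial()).fit()
            return MixedModelResults(
                spec=spec, params=fit.params, bse=fit.bse, llf=float(fit.llf),
                n_params=len(fit.params), nobs=int(fit.nobs),
                n_groups=data["participant_id"].nunique(),
                random_effects=None, cov_re=None, converged=True,
                n_dropped=self.n_dropped,
            )
        ymat, X = dmatrices(spec.formula, data, return_type="dataframe")
        y = ymat.values.ravel()
        groups = data["participant_id"].values
        if spec.random == "intercept":
            res = fit_logistic_intercept(y, X.values, groups)
            cov_re = pd.DataFrame(res.cov_re, index=["intercept"],
                                  columns=["intercept"])
            re_cols = ["intercept"]
        else:
            Z = dmatrix("0 + C(condition)", data, return_type="dataframe")
            pretty = [c.split("[")[-1].rstrip("]") for c in Z.columns]
            res = fit_logistic_vector(y, X.values, Z.values, groups)
            cov_re = pd.DataFrame(res.cov_re, index=pretty, columns=pretty)
            re_cols = pretty
        if not res.converged:
            raise ModelFitError(f"{spec.label()}: {res.optimizer_message}")
        re_df = pd.DataFrame(res.ranef_modes, columns=re_cols,
                             index=np.unique(groups))
        params = pd.Series(res.beta, index=X.columns)
        bse = pd.Series(res.beta_se, index=X.columns)
        return MixedModelResults(
            spec=spec, params=params, bse=bse, llf=res.llf,
            n_params=res.n_params, nobs=res.nobs, n_groups=res.n_groups,
            random_effects=re_df, cov_re=cov_re, converged=res.converged,
            singular=res.singular, n_dropped=self.n_dropped,
        )


def fit_mixed_model(spec: ModelSpec, metrics: pd.DataFrame) -> MixedModelResults:
    """Fit one model specification to the attempt-level metrics table."""
    return MixedModel(spec, metrics).fit()


def default_ladder(outcome: str, difficulty_terms: Sequence[str] = ("sahni_k", "dp_complexity")) -> list[ModelSpec]:
    """Default candidate list for one outcome.

    Crosses nested difficulty fixed effects with pooled-drug vs per-drug
    condition coding and with the three random structures.
    """
    difficulty_sets: list[tuple[str, ...]] = []
    for k in range(1, len(difficulty_terms) + 1):
        difficulty_sets.append(tuple(difficulty_terms[:k]))
    specs = []
    for dset in difficulty_sets:
        for drug_term in ("drug", "condition"):
            for random in RANDOM_STRUCTURES:
                specs.append(ModelSpec(outcome, dset + (drug_term,), random))
    return specs


def model_selection(
    candidates: Sequence[ModelSpec],
    metrics: pd.DataFrame,
    criterion: str = "AIC",
) -> tuple[MixedModelResults, pd.DataFrame]:
    """Fit every candidate on a harmonised row set; return the best fit and
    the full ladder report.

    All candidates are fitted to the same rows (listwise deletion over the
    union of required columns) so information criteria are comparable.
    Candidates that fail to fit are marked in the ladder and skipped; ties
    on the criterion go to the model with fewer parameters.
    """
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    if len(candidates) == 0:
        raise ValueError("need at least one candidate spec")
    needed = set().union(*(s.required_columns() for s in candidates))
    missing = needed - set(metrics.columns)
    if missing:
        raise ValueError(f"metrics table lacks columns {sorted(missing)}")
    common = metrics.dropna(subset=sorted(needed))
    rows = []
    fits: list[MixedModelResults | None] = []
    for spec in candidates:
        try:
            fit = MixedModel(spec, common).fit()
            if not np.isfinite(fit.llf):
                raise ModelFitError(f"{spec.label()}: non-finite log-likelihood")
            fits.append(fit)
            rows.append(
                {"model": spec.label(), "loglik": fit.llf, "k": fit.n_params,
                 "aic": fit.aic, "bic": fit.bic,
                 "converged": fit.converged, "singular": fit.singular,
                 "failed": False}
            )
        except (ModelFitError, ValueError, np.linalg.LinAlgError) as exc:
            fits.append(None)
            rows.append(
                {"model": spec.label(), "loglik": np.nan, "k": np.nan,
                 "aic": np.nan, "bic": np.nan, "converged": False,
                 "singular": False, "failed": True, "error": str(exc)}
            )
    ladder = pd.DataFrame(rows)
    col = criterion.lower()
    ok = ladder[~ladder["failed"]]
    if ok.empty:
        raise ModelFitError("all candidate models failed to fit")
    order = ok.sort_values([col, "k"]).index
    best = fits[order[0]]
    ladder = ladder.sort_values([col, "k"], na_position="last").reset_index(drop=True)
    return best, ladder


# ---------------------------------------------------------------------------
# random-effect reversal / shrinkage analysis
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ReversalReport:
    cond_a: str
    cond_b: str
    range_a: float
    range_b: float
    range_ratio: float          # range(B) / range(A)
    ols_slope: float            # slope of B-effects regressed on A-effects
    corr: float                 # model-based correlation of the two REs
    corr_z: float
    corr_p: float


def effect_reversal_analysis(
    fit: MixedModelResults, cond_a: str, cond_b: str
) -> ReversalReport:
    """Compare participant random effects between two conditions.

    Returns the range ratio range(B)/range(A) of the empirical-Bayes
    predictions (a ratio < 1 means heterogeneity shrank under B), the OLS
    slope of B-effects on A-effects (a negative slope is a reversal), and
    the model-based correlation of the two random effects with its Wald
    z and p.
    """
    if fit.random_effects is None or fit.spec.random != "condition":
        raise ValueError("fit must have per-condition random effects")
    for c in (cond_a, cond_b):
        if c not in fit.random_effects.columns:
            raise ValueError(f"condition {c!r} not in random effects "
                             f"({list(fit.random_effects.columns)})")
    a = fit.random_effects[cond_a].values
    b = fit.random_effects[cond_b].values
    range_a = float(np.ptp(a))
    range_b = float(np.ptp(b))
    slope = float(np.polyfit(a, b, 1)[0]) if range_a > 0 else np.nan
    corr_tbl = fit.random_effect_correlations()
    key = f"{cond_a}~{cond_b}"
    key2 = f"{cond_b}~{cond_a}"
    row = corr_tbl.loc[key] if key in corr_tbl.index else corr_tbl.loc[key2]
    return ReversalReport(
        cond_a=cond_a, cond_b=cond_b, range_a=range_a, range_b=range_b,
        range_ratio=range_b / range_a if range_a > 0 else np.nan,
        ols_slope=slope, corr=float(row["corr"]), corr_z=float(row["z"]),
        corr_p=float(row["p"]),
    )
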