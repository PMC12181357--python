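"""Association models between rEZR and retinal function.

Three analysis levels are supported, mirroring how structure-function
studies of the ellipsoid zone are typically analyzed:

* **global** — ordinary least squares of a functional outcome (e.g. the
  mesopic average threshold, mesAT, in dB) on the eye-wide mean rEZR,
  adjusted for AMD stage (reference: no AMD), age, and sex (reference:
  female);
* **locally averaged** — the same fixed-effect structure with the mean rEZR
  over the 33 perimetry stimulus points as exposure;
* **spatially resolved** — a linear mixed-effects model of point-wise
  retinal sensitivity on point-local rEZR with a per-participant random
  intercept and a natural cubic spline in stimulus eccentricity, fitted by
  REML.

The public surface is statsmodels-shaped: :class:`REZRAssociation` is built
from a data frame (or via the ``from_*`` constructors from a cohort table)
and ``fit()`` returns an :class:`AssociationResult` carrying coefficient
estimates, 95% confidence intervals, p-values, and a ``summary()`` table.
Thin functional wrappers (:func:`fit_global`, :func:`fit_local_avg`,
:func:`fit_spatial`, :func:`fit_univariate`) cover the common calls.

p-values are reported without multiplicity adjustment: each functional
parameter is an independently analyzed exploratory association.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import patsy
import scipy.linalg
import statsmodels.api as sm
import statsmodels.formula.api as smf

STAGE_REFERENCE = "no AMD"
SEX_REFERENCE = "female"


class IdentifiabilityError(ValueError):
    """The design matrix is rank deficient; names the collinear terms."""


def derive_lld(bcva, llva, convention: str = "table1"):
    """Low-luminance deficit (logMAR) from BCVA and LLVA.

    Two sign conventions circulate: ``"table1"`` returns ``BCVA - LLVA``
    (consistent with published group means, where LLD is negative because
    LLVA is worse than BCVA); ``"methods_text"`` returns ``LLVA - BCVA``.
    The convention used should be recorded alongside any output.
    """
    bcva = np.asarray(bcva, dtype=float)
    llva = np.asarray(llva, dtype=float)
    if convention == "table1":
        out = bcva - llva
    elif convention == "methods_text":
        out = llva - bcva
    else:
        raise ValueError("convention must be 'table1' or 'methods_text'")
    return float(out) if out.ndim == 0 else out


def _check_identifiable(formula: str, data: pd.DataFrame) -> None:
    y, X = patsy.dmatrices(formula, data, return_type="dataframe")
    mat = X.to_numpy()
    rank = np.linalg.matrix_rank(mat)
    if rank < mat.shape[1]:
        _, _, piv = scipy.linalg.qr(mat, pivoting=True)
        dropped = sorted(X.columns[i] for i in piv[rank:])
        raise IdentifiabilityError(
            f"design matrix is rank deficient; collinear terms: {dropped}"
        )


@dataclass
class AssociationResult:
    """Fitted association model: estimates, 95% CIs, p-values, diagnostics.

    ``params`` is a data frame indexed by predictor with columns
    ``estimate``, ``ci_low``, ``ci_high``, ``p``.
    """

    params: pd.DataFrame
    n_observations: int
    n_participants: int
    converged: bool
    method: str
    outcome: str
    exposure: str
    random_effects: dict = field(default_factory=dict)
    warnings_: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        p = self.params
        if not ((p["ci_low"] <= p["estimate"] + 1e-12).all() and
                (p["estimate"] <= p["ci_high"] + 1e-12).all()):
            raise ValueError("confidence interval must bracket the estimate")

    @property
    def rezr(self) -> pd.Series:
        """The exposure (rEZR) row of the coefficient table."""
        return self.params.loc[self.exposure]

    def to_frame(self) -> pd.DataFrame:
        out = self.params.reset_index().rename(columns={"index": "predictor"})
        return out

    def summary(self) -> str:
        lines = [
            f"Association model ({self.method}); outcome: {self.outcome}",
            f"n_observations={self.n_observations}, "
            f"n_participants={self.n_participants}, converged={self.converged}",
            f"{'predictor':<32}{'CE':>12}{'95% CI':>26}{'p':>10}",
        ]
        for name, row in self.params.iterrows():
            ci = f"[{row.ci_low: .4g}, {row.ci_high: .4g}]"
            lines.append(
                f"{name:<32}{row.estimate:>12.4g}{ci:>26}{row.p:>10.4g}"
            )
        for k, v in self.random_effects.items():
            lines.append(f"{k}: {v:.4g}")
        return "\n".join(lines)


class REZRAssociation:
    """Linear association of a functional outcome with an rEZR summary.

    Parameters
    ----------
    data
        One row per analysis unit (eye, or stimulus point for the spatially
        resolved model) with the outcome, exposure and covariate columns.
    outcome, exposure
        Column names; the exposure is the rEZR summary in AU.
    univariate
        Drop all covariates and fit outcome ~ exposure only.
    random_intercept
        Fit a linear mixed model with a per-participant random intercept
        (requires ``groups`` column); otherwise OLS.
    eccentricity_spline
        Add a natural cubic spline (``spline_df`` degrees of freedom) in the
        ``ecc`` column; required alongside ``random_intercept`` for the
        point-wise outcome.
    """

    def __init__(
        self,
        data: pd.DataFrame,
        outcome: str,
        exposure: str,
        univariate: bool = False,
        random_intercept: bool = False,
        eccentricity_spline: bool = False,
        spline_df: int = 3,
        groups: str = "id",
        ecc: str = "eccentricity_deg",
        stage: str = "stage",
        age: str = "age",
        sex: str = "sex",
    ):
        self.data = data
        self.outcome = outcome
        self.exposure = exposure
        self.univariate = univariate
        self.random_intercept = random_intercept
        self.eccentricity_spline = eccentricity_spline
        self.spline_df = spline_df
        self.groups = groups
        self.ecc = ecc
        self.stage = stage
        self.age = age
        self.sex = sex
        missing = [c for c in self._required_columns() if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks columns: {missing}")
        if random_intercept and data[groups].nunique() < 2:
            raise ValueError(
                "mixed model needs at least two participants (no between-"
                "participant information in a single group)"
            )

    def _required_columns(self) -> list[str]:
        cols = [self.outcome, self.exposure]
        if not self.univariate:
            cols += [self.stage, self.age, self.sex]
        if self.random_intercept:
            cols.append(self.groups)
        if self.eccentricity_spline:
            cols.append(self.ecc)
        return cols

    @property
    def formula(self) -> str:
        terms = [f"Q('{self.exposure}')"]
        if not self.univariate:
            terms += [
                f"C(Q('{self.stage}'), Treatment('{STAGE_REFERENCE}'))",
                f"Q('{self.age}')",
                f"C(Q('{self.sex}'), Treatment('{SEX_REFERENCE}'))",
            ]
        if self.eccentricity_spline:
            terms.append(
                f"cr(Q('{self.ecc}'), df={self.spline_df}, constraints='center')"
            )
        return f"Q('{self.outcome}') ~ " + " + ".join(terms)

    def _pretty(self, name: str) -> str:
        out = name.replace(f"Q('{self.exposure}')", "rezr")
        out = out.replace(f"Q('{self.age}')", "age")
        out = out.replace(
            f"C(Q('{self.stage}'), Treatment('{STAGE_REFERENCE}'))", "stage"
        )
        out = out.replace(f"C(Q('{self.sex}'), Treatment('{SEX_REFERENCE}'))", "sex")
        out = out.replace(f"Q('{self.ecc}')", "eccentricity")
        return out

    def fit(self, reml: bool = True) -> AssociationResult:
        """Fit by OLS, or REML for the mixed model, and package the result."""
        data = self.data.dropna(subset=self._required_columns())
        _check_identifiable(self.formula, data)
        caught: list[str] = []
        if self.random_intercept:
            model = smf.mixedlm(self.formula, data, groups=data[self.groups])
            with warnings.catch_warnings(record=True) as wlist:
                warnings.simplefilter("always")
                res = model.fit(reml=reml)
            caught = [str(w.message) for w in wlist]
            converged = bool(res.converged)
            fe = res.fe_params
            ci = res.conf_int().loc[fe.index]
            pvals = res.pvalues.loc[fe.index]
            random_effects = {"random_intercept_var": float(res.cov_re.iloc[0, 0])}
            method = "LMM (REML)" if reml else "LMM (ML)"
            n_participants = int(data[self.groups].nunique())
        else:
            model = smf.ols(self.formula, data)
            res = model.fit()
            converged = True
            fe = res.params
            ci = res.conf_int(alpha=0.05)
            pvals = res.pvalues
            random_effects = {}
            method = "OLS"
            n_participants = (
                int(data[self.groups].nunique())
                if self.groups in data.columns
                else len(data)
            )
        table = pd.DataFrame(
            {
                "estimate": fe,
                "ci_low": ci.iloc[:, 0],
                "ci_high": ci.iloc[:, 1],
                "p": pvals,
            }
        )
        table.index = [self._pretty(n) for n in table.index]
        return AssociationResult(
            params=table,
            n_observations=len(data),
            n_participants=n_participants,
            converged=converged,
            method=method,
            outcome=self.outcome,
            exposure="rezr",
            random_effects=random_effects,
            warnings_=caught,
        )


# ---------------------------------------------------------------------------
# functional wrappers
# ---------------------------------------------------------------------------


def _participants(cohort) -> pd.DataFrame:
    return cohort.participants if hasattr(cohort, "participants") else cohort


def fit_global(cohort, outcome: str = "mesat_db", exposure: str = "global_rezr") -> AssociationResult:
    """Eye-level OLS: outcome on global mean rEZR + stage + age + sex."""
    return REZRAssociation(_participants(cohort), outcome, exposure).fit()


def fit_local_avg(
    cohort, outcome: str = "mesat_db", min_points: int = 20
) -> AssociationResult:
    """Locally averaged model: the mean rEZR over the 33 stimulus points per
    eye as exposure.  Eyes with fewer than ``min_points`` valid point values
    are excluded (and counted in the result's warnings)."""
    part = cohort.participants
    pts = cohort.points
    valid = pts.dropna(subset=["local_rezr"])
    counts = valid.groupby("id").size()
    keep = counts[counts >= min_points].index
    means = valid[valid["id"].isin(keep)].groupby("id")["local_rezr"].mean()
    data = part.merge(means.rename("local_mean_rezr"), on="id", how="inner")
    res = REZRAssociation(data, outcome, "local_mean_rezr").fit()
    dropped = part["id"].nunique() - len(data)
    if dropped:
        res.warnings_.append(f"{dropped} eyes excluded with < {min_points} valid points")
    return res


def fit_spatial(cohort, spline_df: int = 3, reml: bool = True) -> AssociationResult:
    """Spatially resolved LMM: point sensitivity on point-local rEZR with a
    per-participant random intercept and an eccentricity spline."""
    if hasattr(cohort, "points_with_covariates"):
        data = cohort.points_with_covariates()
    else:
        data = cohort
    per = data.groupby("id").size()
    if (per < 2).any():
        raise ValueError("each participant needs at least 2 points")
    return REZRAssociation(
        data,
        outcome="sensitivity_db",
        exposure="local_rezr",
        random_intercept=True,
        eccentricity_spline=True,
        spline_df=spline_df,
    ).fit(reml=reml)


def fit_univariate(
    table: pd.DataFrame,
    exposure: str,
    outcome: str,
    random_intercept: bool = False,
    eccentricity_spline: bool = False,
) -> AssociationResult:
    """Single-predictor regression (OLS, or LMM for point-wise outcomes)."""
    return REZRAssociation(
        table,
        outcome,
        exposure,
        univariate=True,
        random_intercept=random_intercept,
        eccentricity_spline=eccentricity_spline,
    ).fit()


# ---------------------------------------------------------------------------
# descriptive table
# ---------------------------------------------------------------------------

DESCRIBE_VARIABLES = (
    "age",
    "central_subfield_rezr",
    "global_rezr",
    "mesat_db",
    "bcva",
    "llva",
    "mat",
    "pr",
    "lld",
)


def describe(cohort, variables: Sequence[str] = DESCRIBE_VARIABLES) -> pd.DataFrame:
    """Baseline-characteristics table by AMD stage plus overall.

    Rows are (variable, statistic) pairs; per group the table reports n and
    its percentage of the overall n, male n (%), and per variable the mean
    (SD) and median [min, max].  Single-record groups report SD as missing;
    empty groups report missing markers throughout.
    """
    part = _participants(cohort)
    stages = [s for s in ("no AMD", "early", "intermediate", "late")]
    groups = {s: part[part["stage"] == s] for s in stages}
    groups["overall"] = part
    n_overall = len(part)
    rows: dict[tuple[str, str], dict[str, object]] = {}

    def put(var, stat, col, value):
        rows.setdefault((var, stat), {})[col] = value

    for name, g in groups.items():
        n = len(g)
        put("n", "count", name, n)
        put("n", "percent", name, 100.0 * n / n_overall if n_overall else np.nan)
        if n:
            male = int((g["sex"] == "male").sum())
            put("sex (male)", "count", name, male)
            put("sex (male)", "percent", name, 100.0 * male / n)
        else:
            put("sex (male)", "count", name, np.nan)
            put("sex (male)", "percent", name, np.nan)
        for var in variables:
            if n == 0 or var not in g.columns:
                for stat in ("mean", "sd", "median", "min", "max"):
                    put(var, stat, name, np.nan)
                continue
            v = g[var].astype(float)
            put(var, "mean", name, v.mean())
            put(var, "sd", name, v.std(ddof=1) if n > 1 else np.nan)
            put(var, "median", name, v.median())
            put(var, "min", name, v.min())
            put(var, "max", name, v.max())
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index = pd.MultiIndex.from_tuples(out.index, names=["variable", "stat"])
    return out[list(groups)]
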