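"""Trait transformations, covariate adjustment and multiple-testing correction.

Quantitative traits are transformed (log or rank-based inverse-normal), then
residualized on age and sex terms by ordinary least squares before the
variance-components fits; correlation scans are corrected by the
Benjamini-Hochberg step-up false-discovery-rate procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: covariate terms constructible from the ``age`` and ``sex`` columns
_BUILTIN_TERMS = ("age", "sex", "age2", "age_x_sex", "age2_x_sex")

#: SOLAR-style default covariate set ("age and sex terms")
DEFAULT_COVARIATES = ["age", "sex", "age2", "age_x_sex"]


@dataclass
class TraitSpec:
    """Declares how one trait is prepared for the genetic analyses.

    ``transform`` is applied first, then the trait is residualized on
    ``covariates`` (built-in terms ``age``, ``sex``, ``age2``, ``age_x_sex``,
    ``age2_x_sex`` or any extra column of the phenotype table, e.g. a dietary
    intake covariate).
    """

    name: str
    transform: str = "inverse_normal"  # none | log | inverse_normal
    covariates: list[str] = field(default_factory=lambda: list(DEFAULT_COVARIATES))

    def __post_init__(self):
        if self.transform not in ("none", "log", "inverse_normal"):
            raise ValueError(f"unknown transform {self.transform!r}")


@dataclass
class PreparedTrait:
    """Residualized trait values ready for the polygenic model."""

    name: str
    values: pd.Series  # indexed by individual id, complete cases only
    n_used: int
    dropped_ids: list[str]
    term_stats: pd.DataFrame | None = None


def inverse_normalize(x) -> np.ndarray:
    """Rank-based inverse-normal transform with Blom plotting positions.

    ``z_i = Phi^-1((r_i - 3/8) / (n + 1/4))`` with average ranks for ties;
    missing values stay missing. Requires >= 3 non-missing values and a
    non-constant vector.
    """
    x = np.asarray(x, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 3:
        raise ValueError("inverse_normalize needs at least 3 non-missing values")
    vals = x[mask]
    if np.all(vals == vals[0]):
        raise ValueError("inverse_normalize undefined for an all-constant vector")
    ranks = stats.rankdata(vals, method="average")
    out[mask] = stats.norm.ppf((ranks - 0.375) / (n + 0.25))
    return out


def _build_design(covariate_table: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    cols = {}
    need_age = any(t in ("age", "age2", "age_x_sex", "age2_x_sex") for t in terms)
    need_sex = any(t in ("sex", "age_x_sex", "age2_x_sex") for t in terms)
    age = sex = None
    if need_age:
        if "age" not in covariate_table:
            raise ValueError("covariate table lacks an 'age' column")
        age = covariate_table["age"].astype(float)
        age = age - age.mean()  # center before powers to tame collinearity
    if need_sex:
        if "sex" not in covariate_table:
            raise ValueError("covariate table lacks a 'sex' column")
        sex = covariate_table["sex"].astype(float)
    for term in terms:
        if term == "age":
            cols[term] = age
        elif term == "sex":
            cols[term] = sex
        elif term == "age2":
            cols[term] = age**2
        elif term == "age_x_sex":
            cols[term] = age * sex
        elif term == "age2_x_sex":
            cols[term] = age**2 * sex
        elif term in covariate_table.columns:
            cols[term] = covariate_table[term].astype(float)
        else:
            raise ValueError(f"unresolvable covariate term {term!r}")
    return pd.DataFrame(cols, index=covariate_table.index)


def adjust_covariates(
    y: pd.Series,
    covariate_table: pd.DataFrame | None = None,
    terms: list[str] | None = None,
    screen: bool = False,
    screen_alpha: float = 0.10,
    name: str = "trait",
) -> PreparedTrait:
    """OLS-residualize a (transformed) trait on an intercept plus covariate terms.

    With ``screen=True`` the covariates are first screened and only terms with
    p <= ``screen_alpha`` are retained (the intercept always stays), mirroring
    the usual variance-components workflow of keeping significant age/sex
    terms. Individuals missing the trait or any covariate are dropped and
    recorded. Residuals are returned mean-centered.
    """
    y = pd.Series(y).astype(float)
    terms = list(terms or [])
    if terms and covariate_table is None:
        raise ValueError("covariate terms requested but no covariate table given")
    if terms:
        design = _build_design(covariate_table.loc[y.index], terms)
    else:
        design = pd.DataFrame(index=y.index)

    complete = y.notna()
    for col in design.columns:
        complete &= design[col].notna()
    dropped = list(y.index[~complete])
    y_use = y[complete]
    design = design.loc[complete]
    if len(y_use) <= len(terms) + 2:
        raise ValueError("too few complete cases for covariate adjustment")

    term_stats = None
    if terms:
        X = sm.add_constant(design, has_constant="add")
        if np.linalg.matrix_rank(X.values) < X.shape[1]:
            raise ValueError(
                f"rank-deficient covariate design; collinear terms among {terms}"
            )
        fit = sm.OLS(y_use, X).fit()
        term_stats = pd.DataFrame(
            {"coef": fit.params, "p": fit.pvalues}
        ).drop(index="const")
        if screen:
            keep = [t for t in terms if fit.pvalues[t] <= screen_alpha]
            if keep != terms:
                return adjust_covariates(
                    y, covariate_table, keep, screen=False, name=name
                )
        resid = pd.Series(fit.resid, index=y_use.index)
    else:
        resid = y_use - y_use.mean()
    resid = resid - resid.mean()
    return PreparedTrait(
        name=name,
        values=resid,
        n_used=len(resid),
        dropped_ids=dropped,
        term_stats=term_stats,
    )


def prepare_trait(
    phenotypes: pd.DataFrame,
    spec: TraitSpec,
    id_col: str = "id",
    screen: bool = False,
) -> PreparedTrait:
    """Transform and covariate-adjust one trait column of a phenotype table."""
    df = phenotypes.set_index(id_col) if id_col in phenotypes.columns else phenotypes
    y = df[spec.name].astype(float)
    if spec.transform == "log":
        if (y.dropna() <= 0).any():
            raise ValueError(f"log transform of {spec.name!r}: nonpositive values")
        y = np.log(y)
    elif spec.transform == "inverse_normal":
        y = pd.Series(inverse_normalize(y.values), index=y.index)
    return adjust_covariates(
        y, df, spec.covariates, screen=screen, name=spec.name
    )


def bh_fdr(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
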