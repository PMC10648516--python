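"""Covariate-controlled inference for segregation outcomes.

Implements the study's inferential layer:

* ordinary least squares with nuisance covariates, reporting beta, 95% CI,
  t, two-sided p and the partial correlation ``r = t / sqrt(t^2 + df)``;
* linear mixed-effects models with a random intercept per subject for
  within-subject factors with two levels (system type, or within- vs
  between-system interaction type), with marginal and conditional R^2 by
  the Nakagawa-Schielzeth variance partition;
* a covariate-controlled permutation test for system-block outcomes using
  the Freedman-Lane scheme: the outcome is residualized on the nuisance
  covariates, residuals are permuted across participants, and the focal
  coefficient is refit on each permuted pseudo-outcome;
* Benjamini-Hochberg FDR and Bonferroni multiplicity corrections.

Dementia severity (CDR) is entered as a continuous predictor at its raw
values {0, 0.5, 1, 2}; a categorical recoding {0, 0.5, 1&2} is available
for post hoc group contrasts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as spstats
from statsmodels.stats.multitest import multipletests

from .errors import ConfigurationError, DesignMatrixError

DEFAULT_COVARIATES = ("gender", "mean_fd_post", "education")


@dataclass
class ModelResult:
    """Per-term estimates of a fitted linear or mixed model."""

    terms: list[str]
    coefficients: dict[str, float]
    ci95: dict[str, tuple[float, float]]
    t_values: dict[str, float]
    p_values: dict[str, float]
    partial_r: dict[str, float]
    df: float
    r2: float | None = None
    adj_r2: float | None = None
    marginal_r2: float | None = None
    conditional_r2: float | None = None
    n_obs: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "beta": [self.coefficients[t] for t in self.terms],
                "ci_low": [self.ci95[t][0] for t in self.terms],
                "ci_high": [self.ci95[t][1] for t in self.terms],
                "t": [self.t_values[t] for t in self.terms],
                "partial_r": [self.partial_r[t] for t in self.terms],
                "p": [self.p_values[t] for t in self.terms],
            }
        )


@dataclass
class PermutationResult:
    """Per-block permutation test summary."""

    blocks: list[str]
    observed_beta: dict[str, float]
    perm_p: dict[str, float]
    n_perm: int
    seed: int
    uncorrected_significant: dict[str, bool] = field(default_factory=dict)
    fdr_significant: dict[str, bool] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "block": self.blocks,
                "beta": [self.observed_beta[b] for b in self.blocks],
                "p": [self.perm_p[b] for b in self.blocks],
                "uncorrected_significant": [
                    self.uncorrected_significant[b] for b in self.blocks
                ],
                "fdr_significant": [self.fdr_significant[b] for b in self.blocks],
            }
        )


def _encode_design(data: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    """Numeric design columns for ``terms``; string/category columns are
    dummy-coded (drop-first)."""
    cols = {}
    for t in terms:
        if t not in data.columns:
            raise ConfigurationError(f"predictor {t!r} missing from data")
        col = data[t]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=t, drop_first=True, dtype=float)
            for c in dummies.columns:
                cols[c] = dummies[c].to_numpy()
        else:
            cols[t] = col.to_numpy(dtype=float)
    return pd.DataFrame(cols, index=data.index)


def partial_r_from_t(t: float, df: float) -> float:
    """Effect-size transform of a regression t statistic."""
    return float(t / np.sqrt(t * t + df))


def _check_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(arr) < arr.shape[1]:
        bad: list[str] = []
        kept: list[int] = []
        for j in range(arr.shape[1]):
            if np.linalg.matrix_rank(arr[:, kept + [j]]) == len(kept) + 1:
                kept.append(j)
            else:
                bad.append(str(X.columns[j]))
        raise DesignMatrixError(f"collinear design; offending terms: {bad}")


def fit_ols(
    data: pd.DataFrame,
    outcome: str,
    focal: list[str],
    covariates: list[str] = list(DEFAULT_COVARIATES),
) -> ModelResult:
    """OLS of ``outcome`` on focal predictors plus nuisance covariates.

    Reports beta, 95% CI, t, two-sided p and the partial correlation
    ``t / sqrt(t^2 + df)`` for every term.
    """
    X = _encode_design(data, list(focal) + list(covariates))
    y = data[outcome].to_numpy(dtype=float)
    if len(y) <= X.shape[1] + 2:
        raise ConfigurationError(
            f"need more than {X.shape[1] + 2} subjects for {X.shape[1]} terms"
        )
    X = sm.add_constant(X, prepend=True)
    _check_rank(X)
    fit = sm.OLS(y, X).fit()
    df = float(fit.df_resid)
    ci = fit.conf_int()
    terms = [c for c in X.columns if c != "const"]
    return ModelResult(
        terms=terms,
        coefficients={t: float(fit.params[t]) for t in terms},
        ci95={t: (float(ci.loc[t, 0]), float(ci.loc[t, 1])) for t in terms},
        t_values={t: float(fit.tvalues[t]) for t in terms},
        p_values={t: float(fit.pvalues[t]) for t in terms},
        partial_r={t: partial_r_from_t(float(fit.tvalues[t]), df) for t in terms},
        df=df,
        r2=float(fit.rsquared),
        adj_r2=float(fit.rsquared_adj),
        n_obs=int(fit.nobs),
    )


def _nakagawa_r2(fit) -> tuple[float, float]:
    """Marginal and conditional R^2 for a random-intercept model.

    Variance-partition formulas: fixed-effect variance is the variance of
    the fixed-effects predictions (MixedLM ``fittedvalues`` exclude random
    effects), the random-intercept variance is ``cov_re`` and the residual
    variance is ``scale``.
    """
    var_f = float(np.var(fit.fittedvalues))
    var_re = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    var_e = float(fit.scale)
    total = var_f + var_re + var_e
    return var_f / total, (var_f + var_re) / total


def fit_interaction_mixed(
    long_table: pd.DataFrame,
    outcome: str,
    condition: str,
    focal: list[str],
    covariates: list[str] = list(DEFAULT_COVARIATES),
    subject_col: str = "subject_id",
    three_way: bool = False,
) -> ModelResult:
    """Random-intercept mixed model for a two-level within-subject factor.

    Each subject contributes one row per condition level. Fixed effects are
    the condition, the focal variables and their condition interactions
    (all pairwise ``focal x condition``, plus the full three-way product
    when ``three_way`` and two focal variables are given), and the
    between-subject covariates. The random-effects structure is a random
    intercept per subject: with only two condition levels a random slope is
    not separately identifiable from the residual.
    """
    df = long_table.copy()
    levels = sorted(df[condition].unique())
    if len(levels) != 2:
        raise ConfigurationError(f"{condition!r} must have exactly 2 levels")
    counts = df.groupby(subject_col)[condition].nunique()
    if not (counts == 2).all():
        raise ConfigurationError("every subject needs one row per condition level")

    cond_num = f"{condition}_num"
    df[cond_num] = (df[condition] == levels[1]).astype(float)
    design_terms = list(focal) + list(covariates)
    enc = _encode_design(df, design_terms)
    # Scale columns (and the outcome) to unit magnitude for the optimizer;
    # pure scaling leaves t and p invariant and the estimates are rescaled
    # back below.
    scale: dict[str, float] = {}
    for c in enc.columns:
        s = float(enc[c].std())
        scale[c] = s if s > 0 else 1.0
        df[f"_enc_{c}"] = enc[c] / scale[c]
    y_scale = float(df[outcome].std()) or 1.0
    df["_outcome_scaled"] = df[outcome] / y_scale
    enc_names = {c: f"_enc_{c}" for c in enc.columns}
    focal_enc = [enc_names[c] for c in enc.columns if any(c == f or c.startswith(f"{f}_") for f in focal)]
    cov_enc = [v for v in enc_names.values() if v not in focal_enc]

    rhs = [cond_num] + focal_enc + cov_enc
    rhs += [f"{f}:{cond_num}" for f in focal_enc]
    if three_way and len(focal_enc) == 2:
        rhs.append(f"{focal_enc[0]}:{focal_enc[1]}")
        rhs.append(f"{focal_enc[0]}:{focal_enc[1]}:{cond_num}")
    formula = "_outcome_scaled ~ " + " + ".join(rhs)
    model = smf.mixedlm(formula, df, groups=df[subject_col])
    fit = model.fit(reml=True, maxiter=500)

    n_subjects = df[subject_col].nunique()
    dof = float(n_subjects - len(rhs) - 1)
    marg, cond_r2 = _nakagawa_r2(fit)

    def _clean(name: str) -> str:
        return name.replace("_enc_", "").replace(cond_num, condition)

    def _rescale(name: str) -> float:
        """Map a scaled-model coefficient back to raw units."""
        factor = y_scale
        for part in name.split(":"):
            if part.startswith("_enc_"):
                factor /= scale[part.removeprefix("_enc_")]
        return factor

    terms = [t for t in fit.params.index if t not in ("Intercept", "Group Var")]
    tvals = {t: float(fit.tvalues[t]) for t in terms}
    ci = fit.conf_int()
    return ModelResult(
        terms=[_clean(t) for t in terms],
        coefficients={_clean(t): float(fit.params[t]) * _rescale(t) for t in terms},
        ci95={
            _clean(t): tuple(sorted(
                (float(ci.loc[t, 0]) * _rescale(t), float(ci.loc[t, 1]) * _rescale(t))
            ))
            for t in terms
        },
        t_values={_clean(t): tvals[t] for t in terms},
        p_values={
            _clean(t): float(2 * spstats.t.sf(abs(tvals[t]), dof)) for t in terms
        },
        partial_r={_clean(t): partial_r_from_t(tvals[t], dof) for t in terms},
        df=dof,
        marginal_r2=marg,
        conditional_r2=cond_r2,
        n_obs=len(df),
    )


def block_permutation_test(
    outcomes: pd.DataFrame,
    data: pd.DataFrame,
    focal: str,
    covariates: list[str],
    n_perm: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> PermutationResult:
    """Freedman-Lane permutation test of ``focal`` on every outcome column.

    For each block outcome: fit the full model (focal + covariates), record
    the focal beta; residualize the outcome on the covariates alone, permute
    those residuals across participants, add back the covariate fit, and
    refit to build the null distribution. The two-sided p is
    ``(1 + #{|beta_perm| >= |beta_obs|}) / (n_perm + 1)`` so it is never 0.
    Flags are reported uncorrected and Benjamini-Hochberg FDR corrected at
    ``alpha``; all columns of ``outcomes`` form one FDR family.

    All blocks share the same permutations, preserving the dependence
    structure across blocks.
    """
    if n_perm < 100:
        raise ConfigurationError("n_perm must be >= 100")
    x = data[focal].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ConfigurationError(f"focal variable {focal!r} is constant")
    Z = sm.add_constant(_encode_design(data, list(covariates)), prepend=True)
    Zv = Z.to_numpy(dtype=float)
    _check_rank(Z)
    Y = outcomes.to_numpy(dtype=float)
    n, n_blocks = Y.shape
    if Zv.shape[0] != n or x.shape[0] != n:
        raise ConfigurationError("outcomes and covariates differ in row count")

    X_full = np.column_stack([Zv, x])
    if np.linalg.matrix_rank(X_full) < X_full.shape[1]:
        raise DesignMatrixError("focal variable is collinear with covariates")
    pinv_full = np.linalg.pinv(X_full)
    w = pinv_full[-1]                       # row extracting the focal beta
    beta_obs = Y.T @ w                      # (n_blocks,)

    # Freedman-Lane: residualize each outcome on the covariates alone.
    coef_z = np.linalg.pinv(Zv) @ Y
    E = Y - Zv @ coef_z                     # n x n_blocks residuals
    rng = np.random.default_rng(seed)
    perm_idx = np.argsort(rng.random((n_perm, n)), axis=1)
    # beta under permutation p: w . (Z g + E[perm]) = w . E[perm]  (w _|_ Z)
    W_perm = w[perm_idx]                    # n_perm x n
    beta_perm = W_perm @ E                  # n_perm x n_blocks

    exceed = (np.abs(beta_perm) >= np.abs(beta_obs)[None, :]).sum(axis=0)
    p = (1.0 + exceed) / (n_perm + 1.0)
    blocks = [str(c) for c in outcomes.columns]
    fdr_flags = fdr_correct(p, q=alpha)
    return PermutationResult(
        blocks=blocks,
        observed_beta={b: float(v) for b, v in zip(blocks, beta_obs)},
        perm_p={b: float(v) for b, v in zip(blocks, p)},
        n_perm=n_perm,
        seed=seed,
        uncorrected_significant={b: bool(v < alpha) for b, v in zip(blocks, p)},
        fdr_significant={b: bool(f) for b, f in zip(blocks, fdr_flags)},
    )


def fdr_correct(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up flags at level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ConfigurationError("p values must lie in [0, 1]")
    flags, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return flags


def bonferroni_posthoc(p_values, m: int | None = None) -> np.ndarray:
    """Bonferroni-corrected p values: ``min(1, m * p)``."""
    p = np.asarray(p_values, dtype=float)
    if m is None:
        m = p.size
    if m < 1:
        raise ConfigurationError("m must be >= 1")
    return np.minimum(1.0, m * p)


def cdr_categorical(cdr: pd.Series) -> pd.Series:
    """Categorical recoding of CDR with mild and moderate dementia combined:
    groups {0, 0.5, 1&2}."""
    def code(v: float) -> str:
        if v == 0:
            return "0"
        if v == 0.5:
            return "0.5"
        return "1&2"
    return cdr.map(code).astype("category")


def posthoc_group_ttests(
    data: pd.DataFrame, outcome: str, group: str = "cdr_group"
) -> pd.DataFrame:
    """Pairwise Welch t-tests between groups, Bonferroni corrected."""
    levels = list(data[group].cat.categories if hasattr(data[group], "cat")
                  else sorted(data[group].unique()))
    rows = []
    for i, a in enumerate(levels):
        for b in levels[i + 1:]:
            ya = data.loc[data[group] == a, outcome].to_numpy(dtype=float)
            yb = data.loc[data[group] == b, outcome].to_numpy(dtype=float)
            t, p = spstats.ttest_ind(ya, yb, equal_var=False)
            rows.append((a, b, float(t), float(p)))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "t", "p"])
    out["p_bonferroni"] = bonferroni_posthoc(out["p"].to_numpy())
    return out
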