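"""The log-linear clonotype recapture model.

For a group of clonotypes sharing a size class (and optionally other labels)
in a "pre" sample, the probability of seeing any of them again in a "post"
sample is ``P = n/N``.  Empirically ``log P`` is well described by an
ordinary linear model

    log P ~ size_group + log N_pre + log N_post + G

where ``N_pre``/``N_post`` are the unique-clonotype richness of the two
samples (the diversity covariates) and ``G`` is any set of grouping factors
of interest — transplantation protocol, cell subset, antigen specificity.
Coefficients are on the natural-log scale, so exponentiated contrasts are
fold changes in capture probability.

Uncertainty in a single cell's capture rate is summarised by the conjugate
beta posterior under a uniform prior, ``Beta(n + 1, N - n + 1)``; it is used
for visualisation and reporting only and never enters the regression.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm
import statsmodels.formula.api as smf

logger = logging.getLogger(__name__)

SIZE_TERM = "size_group"


def capture_probability(n: int, N: int) -> float:
    """Recapture probability ``P = n/N`` of a capture-record cell."""
    if N < 1:
        raise ValueError(f"N must be >= 1, got {N}")
    if not 0 <= n <= N:
        raise ValueError(f"need 0 <= n <= N, got n={n}, N={N}")
    return n / N


@dataclass(frozen=True)
class BetaPosterior:
    """Posterior of a capture probability under a uniform (Bayes) prior."""

    n: int
    N: int

    def __post_init__(self) -> None:
        if not 0 <= self.n <= self.N:
            raise ValueError(f"need 0 <= n <= N, got n={self.n}, N={self.N}")

    @property
    def alpha(self) -> float:
        return self.n + 1.0

    @property
    def beta(self) -> float:
        return self.N - self.n + 1.0

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def distribution(self) -> scipy.stats.rv_continuous:
        return scipy.stats.beta(self.alpha, self.beta)

    def pdf(self, x):
        return self.distribution.pdf(x)

    def interval(self, level: float = 0.95) -> tuple[float, float]:
        return self.distribution.interval(level)


def beta_posterior(n: int, N: int) -> BetaPosterior:
    """``Beta(n + 1, N - n + 1)`` posterior for a cell with ``n`` of ``N``
    clonotypes recaptured; ``(0, 0)`` returns the uniform prior."""
    return BetaPosterior(n, N)


def _clean_name(name: str) -> str:
    """Turn patsy coefficient names into ``term[level]`` form."""
    return re.sub(r"C\((\w+)[^\[]*", r"\1", name)


_LEVEL_RE = re.compile(r"^(?P<term>\w+)\[T\.(?P<level>.+)\]$")


@dataclass
class CaptureResults:
    """Fitted log-linear capture model.

    Wraps the underlying OLS (or WLS) results with capture-model-aware
    accessors: cleaned coefficient names, sequential ANOVA, and fold-change
    contrasts between factor levels.
    """

    model: "CaptureModel"
    _res: sm.regression.linear_model.RegressionResultsWrapper
    n_used: int
    n_dropped: int

    # -- coefficient access -------------------------------------------------

    @property
    def params(self) -> pd.Series:
        return self._res.params.rename(_clean_name)

    @property
    def bse(self) -> pd.Series:
        return self._res.bse.rename(_clean_name)

    @property
    def tvalues(self) -> pd.Series:
        return self._res.tvalues.rename(_clean_name)

    @property
    def pvalues(self) -> pd.Series:
        return self._res.pvalues.rename(_clean_name)

    @property
    def rsquared_adj(self) -> float:
        return float(self._res.rsquared_adj)

    @property
    def df_resid(self) -> float:
        return float(self._res.df_resid)

    @property
    def coefficients(self) -> pd.DataFrame:
        """Tidy coefficient table: term, level, estimate, se, t, p."""
        rows = []
        for name, est in self.params.items():
            m = _LEVEL_RE.match(name)
            term, level = (m.group("term"), m.group("level")) if m else (name, None)
            rows.append(
                {
                    "name": name,
                    "term": term,
                    "level": level,
                    "estimate": est,
                    "se": self.bse[name],
                    "t": self.tvalues[name],
                    "p": self.pvalues[name],
                }
            )
        return pd.DataFrame(rows)

    def coef(self, term: str, level: str | None = None) -> float:
        """Coefficient of ``term`` (at ``level`` for categorical terms).

        The reference level of a categorical term has coefficient 0.
        """
        name = f"{term}[T.{level}]" if level is not None else term
        if name in self.params.index:
            return float(self.params[name])
        if level is not None and level in self.model.levels_of(term):
            return 0.0  # reference level
        raise KeyError(f"no coefficient {name!r} in model")

    # -- inference ----------------------------------------------------------

    def anova(self) -> pd.DataFrame:
        """Sequential (type-I) ANOVA in declared formula term order.

        Computed by successive least-squares projections onto growing
        design blocks (patsy internally reorders categorical terms, so the
        decomposition is built directly rather than via ``anova_lm``).
        """
        res = self._res
        X = np.asarray(res.model.exog)
        y = np.asarray(res.model.endog)
        info = res.model.data.design_info
        by_clean = {_clean_name(t): (t, s) for t, s in info.term_name_slices.items()}
        order = [n for n in ["Intercept"] + self.model.term_order if n in by_clean]
        mse = res.ssr / res.df_resid if res.df_resid > 0 else np.nan
        cols: list[int] = []
        rss_prev = float(y @ y)
        rows = []
        for name in order:
            _, slc = by_clean[name]
            cols.extend(range(slc.start, slc.stop))
            rss_now = _rss(X[:, cols], y)
            if name != "Intercept":
                df = slc.stop - slc.start
                ss = max(rss_prev - rss_now, 0.0)
                F = (ss / df) / mse if mse and np.isfinite(mse) and mse > 0 else np.nan
                rows.append(
                    {
                        "term": name,
                        "df": float(df),
                        "sum_sq": ss,
                        "mean_sq": ss / df,
                        "F": F,
                        "PR(>F)": scipy.stats.f.sf(F, df, res.df_resid)
                        if np.isfinite(F)
                        else np.nan,
                    }
                )
            rss_prev = rss_now
        rows.append(
            {
                "term": "Residual",
                "df": float(res.df_resid),
                "sum_sq": float(res.ssr),
                "mean_sq": mse,
                "F": np.nan,
                "PR(>F)": np.nan,
            }
        )
        return pd.DataFrame(rows).set_index("term").rename_axis(None)

    def fold_change(
        self,
        level_a: str,
        level_b: str,
        term: str = SIZE_TERM,
        alpha: float = 0.05,
    ) -> dict:
        """Fold change in capture probability, ``exp(coef_a - coef_b)``.

        The confidence interval is delta-method on the log scale (exact for
        the log contrast) then exponentiated.
        """
        levels = self.model.levels_of(term)
        for lev in (level_a, level_b):
            if lev not in levels:
                raise KeyError(f"level {lev!r} not in term {term!r} (levels: {levels})")

        def unit(level: str) -> np.ndarray:
            v = np.zeros(len(self._res.params))
            name_clean = f"{term}[T.{level}]"
            for i, nm in enumerate(self.params.index):
                if nm == name_clean:
                    v[i] = 1.0
            return v

        contrast = unit(level_a) - unit(level_b)
        log_fc = float(contrast @ self._res.params.values)
        se = float(np.sqrt(contrast @ self._res.cov_params().values @ contrast))
        z = scipy.stats.norm.ppf(1 - alpha / 2)
        return {
            "term": term,
            "level_a": level_a,
            "level_b": level_b,
            "log_fold_change": log_fc,
            "se_log": se,
            "fold_change": float(np.exp(log_fc)),
            "ci_low": float(np.exp(log_fc - z * se)),
            "ci_high": float(np.exp(log_fc + z * se)),
        }

    def size_fold_changes(self, alpha: float = 0.05) -> pd.DataFrame:
        """Fold changes between consecutive size groups, smallest first."""
        levels = self.model.levels_of(SIZE_TERM)
        rows = [
            self.fold_change(b, a, term=SIZE_TERM, alpha=alpha)
            for a, b in zip(levels[:-1], levels[1:])
        ]
        return pd.DataFrame(rows)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        lines = [
            "Log-linear capture model",
            f"  formula: {self.model.formula}",
            f"  records used: {self.n_used} (dropped {self.n_dropped} with P = 0)",
            f"  adjusted R^2: {self.rsquared_adj:.4f}   residual df: {self.df_resid:.0f}",
            "",
            self.coefficients.drop(columns=["term", "level"]).to_string(index=False),
            "",
            "Sequential ANOVA:",
            self.anova().to_string(),
        ]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        an = self.anova().reset_index().rename(columns={"index": "term"})
        return {
            "formula": self.model.formula,
            "n_used": self.n_used,
            "n_dropped": self.n_dropped,
            "adjusted_r2": self.rsquared_adj,
            "coefficients": self.coefficients.to_dict(orient="records"),
            "anova": an.replace({np.nan: None}).to_dict(orient="records"),
        }


class CaptureModel:
    """Log-linear model of clonotype recapture probabilities.

    Parameters
    ----------
    records : DataFrame
        Capture records as produced by
        :func:`clonetrack.tracking.summarize_capture` (columns
        ``size_group, n, N, N_pre, N_post`` plus factor columns).  A ``P``
        column, if present, is used directly; otherwise ``P = n/N``.
    factors : sequence of str
        Extra grouping terms ``G`` appended to the formula, in order.
    zero_policy : {"drop", "continuity"}
        Cells with ``n = 0`` have undefined ``log P``.  ``drop`` removes
        them with a logged warning; ``continuity`` substitutes
        ``P* = (n + 0.5) / (N + 1)`` for every cell.
    weighted : bool
        If True, fit WLS with inverse delta-method variances of ``log P``,
        ``w = N P / (1 - P)``.  Default is unweighted OLS.
    size_reference : str
        Reference level of the size term (default ``singleton``).
    include_size, include_diversity : bool
        Drop the size term or the ``log N_pre + log N_post`` covariates for
        degenerate designs (e.g. single-size toy data).
    include_pair : bool
        Add ``pair_id`` as a categorical covariate (off by default; pairs
        are pooled).
    factor_references : mapping, optional
        Reference level per extra factor.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        factors: tuple[str, ...] | list[str] = (),
        zero_policy: str = "drop",
        weighted: bool = False,
        size_reference: str = "singleton",
        include_size: bool = True,
        include_diversity: bool = True,
        include_pair: bool = False,
        factor_references: dict | None = None,
    ) -> None:
        if zero_policy not in ("drop", "continuity"):
            raise ValueError(f"unknown zero_policy {zero_policy!r}")
        self.records = records.reset_index(drop=True)
        self.factors = list(factors)
        self.zero_policy = zero_policy
        self.weighted = weighted
        self.size_reference = size_reference
        self.include_size = include_size
        self.include_diversity = include_diversity
        self.include_pair = include_pair
        self.factor_references = dict(factor_references or {})
        for col in ("n", "N") if "P" not in records.columns else ():
            if col not in records.columns:
                raise ValueError(f"records need column {col!r} (or an explicit 'P')")
        for f in self.factors:
            if f not in records.columns:
                raise KeyError(f"factor {f!r} not in records")
            if records[f].nunique() < 2:
                raise ValueError(f"factor {f!r} has a single level")
        self._design = self._prepare()
        self.formula = self._build_formula()

    @classmethod
    def from_tracking(cls, results, group_by=(), **kwargs) -> "CaptureModel":
        """Build from one or several :class:`TrackingResult` objects."""
        from .tracking import concat_records, summarize_capture

        if not isinstance(results, (list, tuple)):
            results = [results]
        records = concat_records([summarize_capture(r, group_by=group_by) for r in results])
        return cls(records, factors=list(group_by), **kwargs)

    # -- design construction ------------------------------------------------

    def _prepare(self) -> pd.DataFrame:
        df = self.records.copy()
        if "P" not in df.columns:
            df["P"] = df["n"] / df["N"]
        if self.zero_policy == "continuity" and "n" in df.columns and "N" in df.columns:
            df["P"] = (df["n"] + 0.5) / (df["N"] + 1.0)
        zero = df["P"] <= 0
        self.n_dropped_ = int(zero.sum())
        if self.n_dropped_:
            logger.warning(
                "dropping %d capture record(s) with P = 0 (log undefined); "
                "use zero_policy='continuity' to retain them",
                self.n_dropped_,
            )
        df = df[~zero].copy()
        if not len(df):
            raise ValueError("all records have P = 0; nothing to fit")
        df["log_P"] = np.log(df["P"].astype(float))
        if self.include_diversity:
            for col in ("N_pre", "N_post"):
                if col not in df.columns:
                    raise ValueError(f"records need column {col!r}")
            df["log_N_pre"] = np.log(df["N_pre"].astype(float))
            df["log_N_post"] = np.log(df["N_post"].astype(float))
        if self.include_size:
            if SIZE_TERM not in df.columns:
                raise ValueError(f"records need column {SIZE_TERM!r}")
            df[SIZE_TERM] = df[SIZE_TERM].astype(str)
            present = df.loc[df["P"] > 0, SIZE_TERM].unique()
            if len(present) < 2:
                raise ValueError(
                    f"need >= 2 distinct size groups with P > 0, found {sorted(present)}"
                )
            if self.size_reference not in present:
                raise ValueError(
                    f"size reference {self.size_reference!r} absent from records "
                    f"(present: {sorted(present)})"
                )
        return df.reset_index(drop=True)

    def _build_formula(self) -> str:
        terms = []
        self.term_order: list[str] = []  # cleaned names, declared order

        def add(term: str) -> None:
            terms.append(term)
            self.term_order.append(_clean_name(term))

        if self.include_size:
            add(f'C({SIZE_TERM}, Treatment(reference="{self.size_reference}"))')
        if self.include_diversity:
            for col in ("log_N_pre", "log_N_post"):
                # a single pair makes richness constant; the covariate is then
                # confounded with the intercept and is absorbed into it
                if self._design[col].nunique() > 1:
                    add(col)
                else:
                    logger.warning(
                        "%s is constant across records; absorbed into the intercept", col
                    )
        for f in self.factors:
            if pd.api.types.is_numeric_dtype(self._design[f]):
                add(f)
            elif f in self.factor_references:
                add(f'C({f}, Treatment(reference="{self.factor_references[f]}"))')
            else:
                add(f"C({f})")
        if self.include_pair:
            add("C(pair_id)")
        if not terms:
            terms = ["1"]
        return "log_P ~ " + " + ".join(terms)

    def levels_of(self, term: str) -> list[str]:
        """Observed levels of a categorical model term, reference first."""
        if term == SIZE_TERM:
            ref = self.size_reference
        else:
            ref = self.factor_references.get(term)
        if term not in self._design.columns:
            raise KeyError(f"unknown term {term!r}")
        levels = sorted(self._design[term].astype(str).unique())
        if term == SIZE_TERM:
            # order by abundance if the records carry an ordered categorical
            col = self.records[SIZE_TERM]
            if isinstance(col.dtype, pd.CategoricalDtype):
                levels = [l for l in col.cat.categories.astype(str) if l in levels]
        if ref is not None and ref in levels:
            levels = [ref] + [l for l in levels if l != ref]
        return levels

    # -- fitting ------------------------------------------------------------

    def fit(self) -> CaptureResults:
        model = smf.ols(self.formula, data=self._design)
        exog = model.exog
        rank = np.linalg.matrix_rank(exog)
        if rank < exog.shape[1]:
            aliased = self._aliased_columns(model)
            raise ValueError(f"design matrix is rank deficient; aliased terms: {aliased}")
        if self.weighted:
            p = self._design["P"].astype(float).clip(upper=1 - 1e-12)
            w = self._design["N"].astype(float) * p / (1 - p)
            res = smf.wls(self.formula, data=self._design, weights=w).fit()
        else:
            res = model.fit()
        return CaptureResults(
            model=self,
            _res=res,
            n_used=int(exog.shape[0]),
            n_dropped=self.n_dropped_,
        )

    @staticmethod
    def _aliased_columns(model) -> list[str]:
        X = model.exog
        names = model.exog_names
        aliased = []
        kept: list[int] = []
        for j in range(X.shape[1]):
            cand = X[:, kept + [j]]
            if np.linalg.matrix_rank(cand) == len(kept) + 1:
                kept.append(j)
            else:
                aliased.append(_clean_name(names[j]))
        return aliased


def fit_loglinear(
    records: pd.DataFrame,
    extra_terms: tuple[str, ...] | list[str] = (),
    zero_handling: str = "drop",
    **kwargs,
) -> CaptureResults:
    """Fit ``log P ~ size_group + log N_pre + log N_post + G`` by OLS."""
    return CaptureModel(records, factors=extra_terms, zero_policy=zero_handling, **kwargs).fit()


@dataclass
class FactorComparison:
    """Effect of one grouping factor on log capture probability."""

    factor: str
    reference: str
    results: CaptureResults
    coefficients: pd.DataFrame = field(repr=False)
    anova_p: float
    posthoc: dict | None = None

    @property
    def estimate(self) -> float:
        """Coefficient of the first non-reference level (two-level case)."""
        return float(self.coefficients["estimate"].iloc[0])

    @property
    def se(self) -> float:
        return float(self.coefficients["se"].iloc[0])

    @property
    def pvalue(self) -> float:
        return float(self.coefficients["p"].iloc[0])


def compare_factor(
    records: pd.DataFrame,
    factor: str,
    reference: str | None = None,
    posthoc_ttest: bool = False,
    equal_var: bool = False,
    **model_kwargs,
) -> FactorComparison:
    """Add ``factor`` to the capture model and report its effect.

    Coefficients are reported with an explicit reference level (the factor's
    first sorted level unless ``reference`` is given); a positive estimate
    means the level captures better than the reference, on the log scale.
    ``posthoc_ttest=True`` additionally runs a two-sample t-test on the raw
    ``log P`` values between the two factor levels (Welch by default).
    """
    levels = sorted(pd.unique(records[factor].astype(str)))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has a single level")
    ref = reference if reference is not None else levels[0]
    model = CaptureModel(
        records,
        factors=[factor],
        factor_references={factor: ref},
        **model_kwargs,
    )
    res = model.fit()
    coefs = res.coefficients
    coefs = coefs[coefs["term"] == factor].reset_index(drop=True)
    an = res.anova()
    anova_p = float(an.loc[factor, "PR(>F)"])
    posthoc = None
    if posthoc_ttest:
        df = model._design
        if len(levels) != 2:
            raise ValueError("post-hoc t-test requires exactly two factor levels")
        other = [l for l in levels if l != ref][0]
        a = df.loc[df[factor].astype(str) == other, "log_P"]
        b = df.loc[df[factor].astype(str) == ref, "log_P"]
        t, p = scipy.stats.ttest_ind(a, b, equal_var=equal_var)
        posthoc = {"t": float(t), "p": float(p), "level_a": other, "level_b": ref}
    return FactorComparison(
        factor=factor,
        reference=ref,
        results=res,
        coefficients=coefs,
        anova_p=anova_p,
        posthoc=posthoc,
    )


def permutation_factor_pvalues(
    records: pd.DataFrame,
    factor: str,
    n_permutations: int = 500,
    seed: int = 0,
    **model_kwargs,
) -> np.ndarray:
    """Model p-values for ``factor`` under random permutation of its labels.

    Permuting the factor column across records breaks any true association,
    so the returned p-values sample the test's null distribution; the
    fraction below 0.05 estimates the empirical type-I error rate.  The
    partial F-test for the factor block is computed directly from the design
    matrix for speed and matches the sequential ANOVA p of a refit (the
    factor is the last term).
    """
    model = CaptureModel(records, factors=[factor], **model_kwargs)
    sm_model = smf.ols(model.formula, data=model._design)
    X = sm_model.exog
    y = sm_model.endog
    info = sm_model.data.design_info
    fac_cols: list[int] = []
    for term_name, slc in info.term_name_slices.items():
        if factor in term_name:
            fac_cols.extend(range(slc.start, slc.stop))
    base_cols = [j for j in range(X.shape[1]) if j not in fac_cols]
    X0, D = X[:, base_cols], X[:, fac_cols]
    n, k = X.shape[0], len(fac_cols)
    dof = n - X.shape[1]
    rss0 = _rss(X0, y)
    rng = np.random.default_rng(seed)
    pvals = np.empty(n_permutations)
    for i in range(n_permutations):
        perm = rng.permutation(n)
        rss1 = _rss(np.column_stack([X0, D[perm]]), y)
        F = ((rss0 - rss1) / k) / (rss1 / dof)
        pvals[i] = scipy.stats.f.sf(F, k, dof)
    return pvals


def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)
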