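"""Mixed-effects association and moderation analysis.

The analysis follows a two-step screen-then-model procedure on a long
participant-day table of z-scored features:

1. univariate linear mixed-effects models (random intercept per
   participant) for every speech feature, against either the daily symptom
   score (linear link, β reported) or the per-day exacerbation flag
   (logistic link, odds ratio reported), always adjusted for age, sex and
   smoking history;
2. iterative variance-inflation-factor pruning (cutoff 20) of the
   significant features and their interaction terms, then a single
   multivariate mixed model with feature×covariate two-way and
   feature×HRV×activity three-way interactions;
3. moderation analysis: the data are stratified into four intervals of the
   moderator (< mean−SD, [mean−SD, mean), [mean, mean+SD), > mean+SD) and
   the univariate model is refitted per stratum.

Model objects follow the statsmodels convention: build a
:class:`MixedAssociation` from a dataframe, call :meth:`fit`, and read
estimates, 95% CIs, p-values and a ``summary()`` table from the returned
:class:`MixedAssociationResults`.

Inference notes: linear mixed models are fitted by REML through
``statsmodels.MixedLM`` with Wald (normal-approximation) CIs and p-values;
the logistic mixed model uses ``BinomialBayesMixedGLM`` (variational
Bayes), with CIs and p-values from the Gaussian posterior approximation
and estimates reported as odds ratios.  No multiple-testing correction is
applied by default; a Benjamini–Hochberg option is available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from copdmon._naming import CONFOUNDERS, HRV_FEATURES, display_name

VIF_CUTOFF = 20.0
PHYSIO_COVARIATES = ("hrv_mean_nn", "hrv_sdnn", "hrv_pnn20", "pa_steps")
STRATA_LABELS = ("< Mean - SD", "[Mean - SD, Mean)", "[Mean, Mean + SD)",
                 "> Mean + SD")


@dataclass(frozen=True)
class ModelResult:
    """One fitted-term record on its reporting scale (β or odds ratio)."""

    term: str
    estimate: float
    ci_low: float
    ci_high: float
    p_value: float
    scale: str = "beta"  # "beta" | "or"
    converged: bool = True
    n_obs: int = 0

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)

    @property
    def display(self) -> str:
        return display_name(self.term)

    def formatted(self) -> str:
        return (f"{self.estimate:.2f} [{self.ci_low:.2f}, "
                f"{self.ci_high:.2f}]{self.stars}")


def significance_stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def zscore(table: pd.DataFrame, columns) -> pd.DataFrame:
    """Cohort-pooled z-scoring of the given columns.

    Missing entries are untouched; a zero-variance column raises, naming
    the column.
    """
    out = table.copy()
    for col in columns:
        x = out[col].astype(float)
        sd = x.std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            raise ValueError(f"column {col!r} has zero variance; cannot z-score")
        out[col] = (x - x.mean()) / sd
    return out


def _term_columns(term: str) -> list[str]:
    return term.split(":")


def _build_formula(outcome: str, terms, confounders) -> str:
    rhs = list(terms) + [
        ("C(sex)" if c == "sex" else "C(smoking)" if c == "smoking" else c)
        for c in confounders
    ]
    return f"{outcome} ~ " + " + ".join(rhs) if rhs else f"{outcome} ~ 1"


class MixedAssociation:
    """Mixed-effects association model for one outcome.

    Parameters
    ----------
    data : long participant-day table (z-scored features recommended).
    outcome : column name; ``family='gaussian'`` fits a linear mixed model,
        ``family='binomial'`` a logistic one on a 0/1 column.
    terms : fixed-effect terms of interest; interactions use the ``a:b``
        colon convention and are expanded as plain products.
    groups : random-intercept grouping column (participant).
    confounders : adjustment covariates, always included.
    """

    def __init__(self, data: pd.DataFrame, outcome: str, terms,
                 groups: str = "participant",
                 confounders=CONFOUNDERS, family: str = "gaussian"):
        if family not in ("gaussian", "binomial"):
            raise ValueError("family must be 'gaussian' or 'binomial'")
        self.outcome = outcome
        self.terms = list(terms)
        self.groups = groups
        self.confounders = tuple(confounders)
        self.family = family
        used = sorted({c for t in self.terms for c in _term_columns(t)}
                      | set(self.confounders) | {outcome, groups})
        df = data[used].dropna().copy()
        if family == "binomial":
            df[outcome] = df[outcome].astype(float)
        # canonical row order: estimates become exactly invariant to the
        # order rows arrive in (optimizer paths are order-sensitive)
        self.data = df.sort_values(used, kind="stable").reset_index(drop=True)
        self.dropped_confounders: tuple[str, ...] = ()
        self.formula = _build_formula(outcome, self.terms, self.confounders)

    @classmethod
    def from_dataframe(cls, data, outcome, terms, **kwargs) -> "MixedAssociation":
        return cls(data, outcome, terms, **kwargs)

    def _aliased(self, formula: str) -> list[str]:
        import patsy

        X = patsy.dmatrix(formula.split("~", 1)[1], self.data,
                          return_type="dataframe")
        if np.linalg.matrix_rank(X.to_numpy()) == X.shape[1]:
            return []
        aliased = []
        cols = X.to_numpy()
        for j, name in enumerate(X.columns):
            others = np.delete(cols, j, axis=1)
            resid = cols[:, j] - others @ np.linalg.lstsq(
                others, cols[:, j], rcond=None)[0]
            if np.sum(resid**2) < 1e-10 * max(np.sum(cols[:, j] ** 2), 1.0):
                aliased.append(name)
        return aliased or ["<unidentified>"]

    def _resolve_design(self) -> None:
        """Drop aliased confounders (small subsets cannot always support
        all three demographic adjustments); aliased terms of interest are
        an error."""
        confs = list(self.confounders)
        while True:
            formula = _build_formula(self.outcome, self.terms, confs)
            aliased = self._aliased(formula)
            if not aliased:
                self.formula = formula
                self.dropped_confounders = tuple(
                    c for c in self.confounders if c not in confs)
                return
            if confs:
                confs.pop()
                continue
            raise ValueError(f"rank-deficient design; aliased terms: {aliased}")

    def fit(self) -> "MixedAssociationResults":
        ngroups = self.data[self.groups].nunique()
        if ngroups < 2:
            raise ValueError("need at least 2 participants")
        self._resolve_design()
        if self.family == "gaussian":
            return self._fit_gaussian()
        return self._fit_binomial()

    def _fit_gaussian(self) -> "MixedAssociationResults":
        model = smf.mixedlm(self.formula, self.data, groups=self.groups)
        # a random-intercept variance on the boundary (singular RE
        # covariance) can defeat individual optimizers; try several and
        # keep the first converged fit, else the last usable one (flagged)
        res = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for method in (None, ["lbfgs"], ["cg"], ["powell"]):
                kwargs = {"method": method} if method else {}
                try:
                    cand = model.fit(reml=True, maxiter=2000, **kwargs)
                except (np.linalg.LinAlgError, ValueError):
                    continue
                res = cand
                if getattr(res, "converged", False):
                    break
        if res is None:
            raise ValueError(
                f"linear mixed model failed for {self.formula!r}")
        converged = bool(getattr(res, "converged", True))
        ci = res.conf_int()
        results = []
        for term in self.terms:
            est = float(res.params[term])
            results.append(ModelResult(
                term=term,
                estimate=est,
                ci_low=float(ci.loc[term, 0]),
                ci_high=float(ci.loc[term, 1]),
                p_value=float(res.pvalues[term]),
                scale="beta",
                converged=converged,
                n_obs=len(self.data),
            ))
        return MixedAssociationResults(self, results, res, converged)

    def _fit_binomial(self) -> "MixedAssociationResults":
        model = sm.BinomialBayesMixedGLM.from_formula(
            self.formula, {self.groups: f"0 + C({self.groups})"}, self.data)
        # the variational fit initializes from the legacy global RNG; pin it
        # so identical data give identical fits
        state = np.random.get_state()
        np.random.seed(1234567)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = model.fit_vb()
        finally:
            np.random.set_state(state)
        names = list(model.exog_names)
        converged = True
        z975 = 1.959963984540054
        results = []
        for term in self.terms:
            i = names.index(term)
            mean, sd = float(res.fe_mean[i]), float(res.fe_sd[i])
            z = mean / sd if sd > 0 else np.inf
            from scipy.stats import norm

            p = 2.0 * float(norm.sf(abs(z)))
            results.append(ModelResult(
                term=term,
                estimate=float(np.exp(mean)),
                ci_low=float(np.exp(mean - z975 * sd)),
                ci_high=float(np.exp(mean + z975 * sd)),
                p_value=p,
                scale="or",
                converged=converged,
                n_obs=len(self.data),
            ))
        return MixedAssociationResults(self, results, res, converged)


@dataclass
class MixedAssociationResults:
    """Per-term estimates with 95% CIs, p-values and significance tiers."""

    model: MixedAssociation
    term_results: list[ModelResult]
    raw: object
    converged: bool

    def __getitem__(self, term: str) -> ModelResult:
        for r in self.term_results:
            if r.term == term:
                return r
        raise KeyError(term)

    @property
    def params(self) -> pd.Series:
        return pd.Series({r.term: r.estimate for r in self.term_results})

    @property
    def pvalues(self) -> pd.Series:
        return pd.Series({r.term: r.p_value for r in self.term_results})

    def conf_int(self) -> pd.DataFrame:
        return pd.DataFrame(
            {0: {r.term: r.ci_low for r in self.term_results},
             1: {r.term: r.ci_high for r in self.term_results}})

    def to_frame(self) -> pd.DataFrame:
        return results_table(self.term_results)

    def summary(self) -> str:
        head = ("Mixed-effects association model "
                f"(outcome={self.model.outcome}, family={self.model.family}, "
                f"n={len(self.model.data)}, "
                f"groups={self.model.data[self.model.groups].nunique()})\n")
        scale = "OR" if self.model.family == "binomial" else "beta"
        lines = [head,
                 f"{'term':<45} {scale + ' [95% CI]':<28} {'p':>9}  sig"]
        for r in self.term_results:
            lines.append(f"{r.display:<45} {r.formatted():<28} "
                         f"{r.p_value:>9.4g}  {r.stars}")
        if not self.converged:
            lines.append("WARNING: fit did not converge")
        return "\n".join(lines)


def fit_univariate(table: pd.DataFrame, feature: str, outcome: str,
                   confounders=CONFOUNDERS,
                   groups: str = "participant") -> ModelResult:
    """Univariate screen model for one feature.

    ``outcome`` may be ``'score'``/``'daily_score'`` (linear) or
    ``'exacerbation'``/``'exacerbation_day'`` (logistic, OR scale).
    """
    outcome_col, family = _resolve_outcome(outcome)
    model = MixedAssociation(table, outcome_col, [feature], groups=groups,
                             confounders=confounders, family=family)
    return model.fit()[feature]


def _resolve_outcome(outcome: str) -> tuple[str, str]:
    if outcome in ("score", "daily_score"):
        return "daily_score", "gaussian"
    if outcome in ("exacerbation", "exacerbation_day"):
        return "exacerbation_day", "binomial"
    raise ValueError(f"unknown outcome {outcome!r}")


def univariate_screen(table: pd.DataFrame, features, outcome: str,
                      alpha: float = 0.05, bh_correct: bool = False,
                      **kwargs) -> pd.DataFrame:
    """Fit the univariate model for every feature; flag significance.

    Raw p-values by default, mirroring star-at-raw-p reporting; set
    ``bh_correct`` for Benjamini–Hochberg adjusted significance.
    """
    results = []
    for f in features:
        try:
            results.append(fit_univariate(table, f, outcome, **kwargs))
        except (ValueError, KeyError, np.linalg.LinAlgError):
            # flagged, not silently omitted
            results.append(ModelResult(f, np.nan, np.nan, np.nan, np.nan,
                                       converged=False))
    df = results_table(results)
    if bh_correct:
        from statsmodels.stats.multitest import multipletests

        df["significant"] = multipletests(df["p_value"], alpha, "fdr_bh")[0]
    else:
        df["significant"] = df["p_value"] < alpha
    return df


def vif_prune(table: pd.DataFrame, terms,
              cutoff: float = VIF_CUTOFF) -> tuple[list[str], pd.DataFrame]:
    """Iterative VIF pruning of a candidate term list.

    Builds the fixed-effects design (interaction terms as plain products of
    their z-scored components), repeatedly removes the term with the
    highest VIF while that maximum is >= ``cutoff`` (ties broken by
    removing the lexicographically last term), and returns the retained
    terms plus a removal log.
    """
    terms = list(terms)
    if len(terms) < 2:
        return terms, pd.DataFrame(columns=["removed", "vif", "iteration"])
    cols = sorted({c for t in terms for c in _term_columns(t)})
    data = table[cols].dropna()
    design = pd.DataFrame(
        {t: np.prod([data[c].to_numpy() for c in _term_columns(t)], axis=0)
         for t in terms})
    log = []
    iteration = 0
    current = list(terms)
    while len(current) >= 2:
        vifs = _vifs(design[current])
        worst = vifs.max()
        if worst < cutoff:
            break
        tied = sorted(vifs.index[vifs == worst])
        victim = tied[-1]  # lexicographically last among ties
        current.remove(victim)
        log.append({"removed": victim, "vif": float(worst),
                    "iteration": iteration})
        iteration += 1
    return current, pd.DataFrame(log, columns=["removed", "vif", "iteration"])


def _vifs(X: pd.DataFrame) -> pd.Series:
    out = {}
    A = sm.add_constant(X.to_numpy(), has_constant="add")
    for j, name in enumerate(X.columns):
        others = np.delete(A, j + 1, axis=1)
        y = A[:, j + 1]
        beta, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ beta
        ss_res = float(np.sum(resid**2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        if ss_tot <= 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def build_interaction_design(features,
                             covariates=PHYSIO_COVARIATES) -> list[str]:
    """Term list for the multivariate interaction model.

    Main effects for every feature and physiological covariate, HRV×steps
    covariate two-ways, feature×covariate two-ways, and
    feature×HRV×steps three-ways, in report order with the ``a:b:c``
    colon naming convention.
    """
    covariates = list(covariates)
    hrv = [c for c in covariates if c in HRV_FEATURES]
    steps = [c for c in covariates if c not in HRV_FEATURES]
    terms: list[str] = []
    terms += covariates
    for h in hrv:
        for s in steps:
            terms.append(f"{h}:{s}")
    for f in features:
        terms.append(f)
        for c in covariates:
            terms.append(f"{f}:{c}")
        for h in hrv:
            for s in steps:
                terms.append(f"{f}:{h}:{s}")
    return terms


def fit_multivariate(table: pd.DataFrame, terms, outcome: str,
                     confounders=CONFOUNDERS,
                     groups: str = "participant") -> MixedAssociationResults:
    """Single mixed model containing all (pruned) terms."""
    outcome_col, family = _resolve_outcome(outcome)
    model = MixedAssociation(table, outcome_col, list(terms), groups=groups,
                             confounders=confounders, family=family)
    return model.fit()


@dataclass(frozen=True)
class StratumResult:
    """Univariate refit of a feature within one moderator stratum."""

    label: str
    n_rows: int
    n_participants: int
    result: ModelResult | None  # None: empty due to a lack of data

    @property
    def empty(self) -> bool:
        return self.result is None


def moderation_stratify(table: pd.DataFrame, feature: str, moderator: str,
                        outcome: str = "score", min_rows: int = 20,
                        min_participants: int = 2,
                        **kwargs) -> list[StratumResult]:
    """Refit the univariate model within four moderator intervals.

    Boundaries come from the cohort mean and SD of the moderator; strata
    with too little data are reported as empty rather than erroring.
    """
    m = table[moderator].astype(float)
    mu, sd = float(m.mean()), float(m.std(ddof=1))
    if not np.isfinite(sd) or sd == 0:
        raise ValueError(f"moderator {moderator!r} has no variance")
    masks = [m < mu - sd,
             (m >= mu - sd) & (m < mu),
             (m >= mu) & (m < mu + sd),
             m > mu + sd]
    out = []
    for label, mask in zip(STRATA_LABELS, masks):
        sub = table[mask.fillna(False)]
        n_rows = int(sub[[feature, moderator]].dropna().shape[0])
        n_part = int(sub["participant"].nunique())
        if n_rows < min_rows or n_part < min_participants:
            out.append(StratumResult(label, n_rows, n_part, None))
            continue
        try:
            res = fit_univariate(sub, feature, outcome, **kwargs)
        except (ValueError, KeyError, np.linalg.LinAlgError):
            out.append(StratumResult(label, n_rows, n_part, None))
            continue
        out.append(StratumResult(label, n_rows, n_part, res))
    return out


def results_table(results) -> pd.DataFrame:
    """Tidy frame of ModelResults with display names and star tiers."""
    rows = []
    for r in results:
        rows.append({
            "term": r.term,
            "display": r.display,
            "scale": r.scale,
            "estimate": r.estimate,
            "ci_low": r.ci_low,
            "ci_high": r.ci_high,
            "p_value": r.p_value,
            "stars": r.stars,
            "converged": r.converged,
            "n_obs": r.n_obs,
        })
    return pd.DataFrame(rows, columns=["term", "display", "scale", "estimate",
                                       "ci_low", "ci_high", "p_value",
                                       "stars", "converged", "n_obs"])


def render_reports(results, title: str = "", csv_path=None,
                   text_path=None) -> tuple[pd.DataFrame, str]:
    """Report a result set as CSV-ready frame and formatted text.

    Rows print as ``estimate [95% CI]`` with significance stars; odds-ratio
    rows print exponentiated bounds (they already live on the OR scale).
    """
    if isinstance(results, MixedAssociationResults):
        results = results.term_results
    df = results_table(results)
    lines = [title] if title else []
    lines.append(f"{'Feature':<45} {'Estimate [95% CI]':<30} sig")
    for r in (results or []):
        lines.append(f"{r.display:<45} {r.formatted():<30}")
    lines.append("Significant model results are indicated as follows: "
                 "* p <.05, ** p <.01, *** p <.001.")
    text = "\n".join(lines)
    if csv_path is not None:
        df.to_csv(csv_path, index=False)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(text + "\n")
    return df, text
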