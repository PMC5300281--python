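"""Mixed-model analysis of volumes and overlap indices.

Responses (regional volumes, or Jaccard indices raised to the 9th power so
their errors are approximately Gaussian) are modelled with Gaussian linear
mixed models: treatment-coded fixed effects for group (G), method (M),
hemisphere (H), time-point (T) and region (R) plus chosen interactions, and
a random intercept per subject.  Models are fitted by maximum likelihood
(not REML — AIC comparisons across different fixed structures require ML),
profiling the likelihood down to the single variance ratio
sigma_subject² / sigma_residual².

Model reduction is backward elimination driven by AIC: the currently least
significant droppable term (highest p-value; a term is droppable only while
no retained higher-order term contains it) is removed and the removal kept
while the AIC does not increase.  Per-term significance uses F tests with
Satterthwaite denominator degrees of freedom (delta method on the profile
deviance in the two variance components); when the variance-parameter
Hessian is not usable the likelihood-ratio p-value is substituted, and the
method actually used is recorded in the selection trace.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "JACCARD_EXPONENT",
    "FACTOR_COLUMNS",
    "ModelSpec",
    "FitResult",
    "RandomInterceptLMM",
    "SelectionResult",
    "transform_response",
    "fit_model",
    "backward_select",
    "predict_cells",
    "term_pvalues",
    "VOLUME_FULL_TERMS",
    "WHOLE_JACCARD_TERMS",
    "REGIONAL_JACCARD_TERMS",
]

JACCARD_EXPONENT = 9

FACTOR_ORDER = ("G", "M", "H", "T", "R")
FACTOR_COLUMNS = {"G": "group", "M": "method", "H": "hemisphere", "T": "timepoint", "R": "region"}

Term = tuple[str, ...]


def transform_response(j):
    """Jaccard fractions raised to the 9th power (monotone on [0, 1])."""
    arr = np.asarray(j, dtype=float)
    if np.any((arr < 0) | (arr > 1)) or np.any(np.isnan(arr)):
        raise ValueError("Jaccard values must lie in [0, 1]")
    out = arr**JACCARD_EXPONENT
    return float(out) if np.isscalar(j) or arr.ndim == 0 else out


def _canon_term(term) -> Term:
    parts = tuple(term.split(":")) if isinstance(term, str) else tuple(term)
    bad = set(parts) - set(FACTOR_ORDER)
    if bad:
        raise ValueError(f"unknown factors {sorted(bad)}; known factors are {FACTOR_ORDER}")
    if len(set(parts)) != len(parts):
        raise ValueError(f"repeated factor in term {parts}")
    return tuple(sorted(parts, key=FACTOR_ORDER.index))


def term_name(term: Term) -> str:
    return ":".join(term)


def parse_terms(formula_terms: str) -> frozenset[Term]:
    """Parse 'G + M + G:M' style term lists into canonical term tuples."""
    return frozenset(_canon_term(t.strip()) for t in formula_terms.split("+") if t.strip())


# the three full starting models of the analysis pipeline
VOLUME_FULL_TERMS = parse_terms("M+G+H+R+T+G:M+G:R+M:R+M:H+T:G+T:R+T:G:R+G:R:M")
WHOLE_JACCARD_TERMS = parse_terms("G+M+H+T+G:M+M:H")
REGIONAL_JACCARD_TERMS = parse_terms("G+M+H+T+R+G:M+M:H+R:M+R:G")


@dataclass(frozen=True)
class ModelSpec:
    """Fixed-effect structure of one model (subject intercept always random).

    ``droppable`` lists the terms backward elimination may remove; by
    default every fixed term is eligible.  Marginality is enforced: every
    interaction's constituent main effects must be present.
    """

    response: str = "response"
    fixed_terms: frozenset = frozenset()
    droppable: frozenset | None = None

    def __post_init__(self):
        object.__setattr__(self, "fixed_terms", frozenset(_canon_term(t) for t in self.fixed_terms))
        drop = self.fixed_terms if self.droppable is None else frozenset(
            _canon_term(t) for t in self.droppable
        )
        object.__setattr__(self, "droppable", drop & self.fixed_terms)
        for t in self.fixed_terms:
            for f in t:
                if len(t) > 1 and (f,) not in self.fixed_terms:
                    raise ValueError(
                        f"marginality violated: interaction {term_name(t)} requires "
                        f"main effect {f}"
                    )

    @property
    def formula(self) -> str:
        terms = sorted(self.fixed_terms, key=lambda t: (len(t), [FACTOR_ORDER.index(f) for f in t]))
        rhs = " + ".join(term_name(t) for t in terms) or "1"
        return f"{self.response} ~ {rhs} + (1|subject)"

    @classmethod
    def from_formula(cls, formula: str) -> "ModelSpec":
        lhs, rhs = formula.split("~")
        terms = [t.strip() for t in rhs.split("+")]
        fixed = [t for t in terms if t not in ("1", "(1|subject)") and t]
        return cls(response=lhs.strip(), fixed_terms=frozenset(_canon_term(t) for t in fixed))

    def without(self, term) -> "ModelSpec":
        t = _canon_term(term)
        return ModelSpec(
            response=self.response,
            fixed_terms=self.fixed_terms - {t},
            droppable=self.droppable - {t},
        )

    def maximal_droppable(self) -> list[Term]:
        """Droppable terms not contained in any retained higher-order term."""
        out = []
        for t in self.droppable:
            if not any(set(t) < set(u) for u in self.fixed_terms):
                out.append(t)
        return sorted(out, key=lambda t: (len(t), term_name(t)))


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

def _design_matrix(df: pd.DataFrame, spec: ModelSpec):
    """Treatment-coded design matrix (alphabetically first level = reference)."""
    levels = {}
    for f in FACTOR_ORDER:
        col = FACTOR_COLUMNS[f]
        if any(f in t for t in spec.fixed_terms):
            if col not in df.columns:
                raise ValueError(f"table has no column {col!r} needed for factor {f}")
            levels[f] = sorted(df[col].astype(str).unique())
    cols = [np.ones(len(df))]
    names = ["Intercept"]
    blocks = {(): [0]}
    terms = sorted(spec.fixed_terms, key=lambda t: (len(t), [FACTOR_ORDER.index(f) for f in t]))
    for t in terms:
        idx = []
        nonref = [levels[f][1:] for f in t]
        for combo in itertools.product(*nonref):
            ind = np.ones(len(df))
            for f, lev in zip(t, combo):
                ind = ind * (df[FACTOR_COLUMNS[f]].astype(str) == lev).to_numpy(float)
            idx.append(len(cols))
            cols.append(ind)
            names.append(":".join(f"{f}[{lev}]" for f, lev in zip(t, combo)))
        blocks[t] = idx
    X = np.column_stack(cols)
    return X, names, blocks, levels


def _check_estimable(X: np.ndarray, names, blocks) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank == X.shape[1]:
        return
    # walk term blocks to name the first inestimable one
    used = [0]
    for t, idx in blocks.items():
        if t == ():
            continue
        used.extend(idx)
        r = np.linalg.matrix_rank(X[:, used])
        if r < len(used):
            raise ValueError(
                f"singular design: term {term_name(t)} is not estimable "
                "(empty factor cells); drop it or supply data covering its levels"
            )
        prev = r
    raise ValueError("singular design matrix")


# ---------------------------------------------------------------------------
# model and results
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    """Fitted random-intercept LMM: estimates, uncertainty and diagnostics."""

    spec: ModelSpec
    params: pd.Series
    cov_params: pd.DataFrame
    sigma2_subject: float
    sigma2_residual: float
    llf: float
    aic: float
    nobs: int
    n_subjects: int
    blocks: dict
    levels: dict
    model: "RandomInterceptLMM"
    df_method: str = "satterthwaite"
    _anova: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def k_params(self) -> int:
        return len(self.params) + 2

    def anova(self) -> pd.DataFrame:
        """Per-term F tests (marginal coefficient-block contrasts)."""
        if self._anova is None:
            self._anova = self.model._anova_table(self)
        return self._anova

    def pvalues(self) -> pd.Series:
        return self.anova()["p_value"]

    def predict(self, cells) -> pd.DataFrame:
        return self.model._predict_cells(self, cells)

    def summary(self) -> str:
        lines = [
            "Random-intercept linear mixed model (ML)",
            f"  formula: {self.spec.formula}",
            f"  nobs: {self.nobs}   subjects: {self.n_subjects}",
            f"  logLik: {self.llf:.4f}   AIC: {self.aic:.4f}",
            f"  sigma2_subject: {self.sigma2_subject:.6g}   "
            f"sigma2_residual: {self.sigma2_residual:.6g}",
            "",
            "Coefficients:",
        ]
        se = np.sqrt(np.diag(self.cov_params.to_numpy()))
        for name, b, s in zip(self.params.index, self.params.to_numpy(), se):
            lines.append(f"  {name:<40s} {b:>12.6f}  (se {s:.6f})")
        lines.append("")
        lines.append("Term tests (" + self.df_method + "):")
        an = self.anova()
        for t, row in an.iterrows():
            lines.append(
                f"  {t:<12s} F={row.F:>10.3f}  df=({row.df_num:.0f}, {row.df_den:.1f})"
                f"  p={row.p_value:.3e}"
            )
        return "\n".join(lines)


class RandomInterceptLMM:
    """Gaussian LMM with treatment-coded fixed effects and a subject intercept.

    Fitted by maximum likelihood via the profile deviance in the variance
    ratio theta = sigma_subject² / sigma_residual²: for fixed theta the GLS
    problem whitens each subject's rows by shrinking their subject mean,
    leaving a one-dimensional deterministic optimisation.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, subject_codes: np.ndarray,
                 names, blocks, levels, spec: ModelSpec):
        order = np.argsort(subject_codes, kind="stable")
        self.y = np.asarray(y, dtype=float)[order]
        self.X = np.asarray(X, dtype=float)[order]
        codes = np.asarray(subject_codes)[order]
        self.codes = codes
        self.starts = np.concatenate([[0], np.flatnonzero(np.diff(codes)) + 1])
        self.group_sizes = np.diff(np.concatenate([self.starts, [len(codes)]]))
        self.names = list(names)
        self.blocks = blocks
        self.levels = levels
        self.spec = spec

    @classmethod
    def from_table(cls, table: pd.DataFrame, spec: ModelSpec) -> "RandomInterceptLMM":
        df = table.copy()
        if spec.response not in df.columns:
            raise ValueError(f"table has no response column {spec.response!r}")
        if "subject" not in df.columns:
            raise ValueError("table must have a 'subject' column")
        df = df[df[spec.response].notna()].reset_index(drop=True)
        if df["subject"].nunique() < 2:
            raise ValueError("need at least 2 subjects")
        dup_cols = ["subject"] + [
            FACTOR_COLUMNS[f] for f in FACTOR_ORDER
            if FACTOR_COLUMNS[f] in df.columns
        ]
        if df.duplicated(subset=dup_cols).any():
            raise ValueError("table has duplicated factor cells within a subject")
        X, names, blocks, levels = _design_matrix(df, spec)
        _check_estimable(X, names, blocks)
        codes, _ = pd.factorize(df["subject"], sort=True)
        return cls(df[spec.response].to_numpy(float), X, codes, names, blocks, levels, spec)

    # -- likelihood machinery ---------------------------------------------
    def _whiten(self, theta: float):
        gamma = 1.0 - 1.0 / np.sqrt(1.0 + self.group_sizes * theta)
        ymean = np.add.reduceat(self.y, self.starts) / self.group_sizes
        Xmean = np.add.reduceat(self.X, self.starts, axis=0) / self.group_sizes[:, None]
        g = gamma[self.codes]
        ys = self.y - g * ymean[self.codes]
        Xs = self.X - g[:, None] * Xmean[self.codes]
        return ys, Xs

    def _gls(self, theta: float):
        ys, Xs = self._whiten(theta)
        beta, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        resid = ys - Xs @ beta
        rss = float(resid @ resid)
        return beta, rss, Xs

    def _profile_neg2ll(self, theta: float) -> float:
        n = len(self.y)
        _, rss, _ = self._gls(theta)
        s2 = max(rss / n, 1e-300)
        return n * np.log(2 * np.pi * s2) + float(np.sum(np.log1p(self.group_sizes * theta))) + n

    def fit(self) -> FitResult:
        n = len(self.y)
        res = optimize.minimize_scalar(
            lambda u: self._profile_neg2ll(np.exp(u)),
            bounds=(-25.0, 15.0), method="bounded",
            options={"xatol": 1e-10},
        )
        theta = float(np.exp(res.x))
        cands = [(self._profile_neg2ll(0.0), 0.0), (res.fun, theta)]
        n2ll, theta = min(cands, key=lambda c: c[0])
        beta, rss, Xs = self._gls(theta)
        s2 = rss / n
        xtx = Xs.T @ Xs
        cov = max(s2, 1e-300) * np.linalg.inv(xtx)
        llf = -0.5 * n2ll
        k = len(beta) + 2
        params = pd.Series(beta, index=self.names)
        return FitResult(
            spec=self.spec,
            params=params,
            cov_params=pd.DataFrame(cov, index=self.names, columns=self.names),
            sigma2_subject=theta * s2,
            sigma2_residual=s2,
            llf=llf,
            aic=2 * k - 2 * llf,
            nobs=n,
            n_subjects=len(self.group_sizes),
            blocks=self.blocks,
            levels=self.levels,
            model=self,
        )

    # -- deviance as a function of the two variance components -------------
    def _deviance_phi(self, phi) -> float:
        s_subj, s_e = max(phi[0], 0.0), max(phi[1], 1e-300)
        theta = s_subj / s_e
        _, rss, _ = self._gls(theta)
        n = len(self.y)
        return (
            n * np.log(2 * np.pi * s_e)
            + float(np.sum(np.log1p(self.group_sizes * theta)))
            + rss / s_e
        )

    def _cov_beta_phi(self, phi) -> np.ndarray:
        s_subj, s_e = max(phi[0], 0.0), max(phi[1], 1e-300)
        _, _, Xs = self._gls(s_subj / s_e)
        return s_e * np.linalg.inv(Xs.T @ Xs)

    def _satterthwaite(self, fit: FitResult):
        """Asymptotic covariance of (sigma2_subject, sigma2_residual), or None."""
        phi = np.array([fit.sigma2_subject, fit.sigma2_residual])
        if phi[1] <= 0 or not np.isfinite(fit.llf):
            return None
        h = np.maximum(np.abs(phi), phi[1]) * 1e-5
        H = np.empty((2, 2))
        f0 = self._deviance_phi(phi)
        for i in range(2):
            for j in range(i, 2):
                ei = np.zeros(2); ei[i] = h[i]
                ej = np.zeros(2); ej[j] = h[j]
                if i == j:
                    H[i, i] = (self._deviance_phi(phi + ei) - 2 * f0 + self._deviance_phi(phi - ei)) / h[i] ** 2
                else:
                    H[i, j] = H[j, i] = (
                        self._deviance_phi(phi + ei + ej)
                        - self._deviance_phi(phi + ei - ej)
                        - self._deviance_phi(phi - ei + ej)
                        + self._deviance_phi(phi - ei - ej)
                    ) / (4 * h[i] * h[j])
        try:
            evals = np.linalg.eigvalsh(H)
            if np.any(evals <= 0):
                return None
            A = 2.0 * np.linalg.inv(H)
        except np.linalg.LinAlgError:
            return None
        # perturbed fixed-effect covariances, shared by every term's gradient
        cov_pm = []
        for i in range(2):
            e = np.zeros(2); e[i] = h[i]
            cov_pm.append((self._cov_beta_phi(phi + e), self._cov_beta_phi(phi - e)))
        return A, h, cov_pm

    def _term_f(self, fit: FitResult, idx: list[int], vc) -> tuple[float, float, float]:
        """F statistic, (num df, den df) for the coefficient block ``idx``."""
        b = fit.params.to_numpy()[idx]
        C = fit.cov_params.to_numpy()[np.ix_(idx, idx)]
        q = len(idx)
        Ci = np.linalg.inv(C)
        F = float(b @ Ci @ b) / q
        if vc is None:
            return F, q, np.inf
        A, h, cov_pm = vc
        evals, P = np.linalg.eigh(C)
        dfs = []
        for d in range(q):
            u = P[:, d]
            # v(phi) = u' C_block(phi) u ; numeric gradient in phi
            grad = np.empty(2)
            for i in range(2):
                cp = cov_pm[i][0][np.ix_(idx, idx)]
                cm = cov_pm[i][1][np.ix_(idx, idx)]
                grad[i] = (u @ cp @ u - u @ cm @ u) / (2 * h[i])
            denom = float(grad @ A @ grad)
            dfs.append(2.0 * evals[d] ** 2 / denom if denom > 0 else np.inf)
        finite = [nu for nu in dfs if nu > 2]
        if not finite:
            return F, q, np.inf
        E = sum(nu / (nu - 2.0) for nu in finite)
        den_df = 2.0 * E / (E - q) if E > q else np.inf
        return F, q, den_df

    def _drop_columns_model(self, drop_idx) -> "RandomInterceptLMM":
        keep = [i for i in range(self.X.shape[1]) if i not in set(drop_idx)]
        sub = RandomInterceptLMM.__new__(RandomInterceptLMM)
        sub.y = self.y
        sub.X = self.X[:, keep]
        sub.codes = self.codes
        sub.starts = self.starts
        sub.group_sizes = self.group_sizes
        sub.names = [self.names[i] for i in keep]
        sub.blocks = {}
        sub.levels = self.levels
        sub.spec = self.spec
        return sub

    def _anova_table(self, fit: FitResult) -> pd.DataFrame:
        vc = self._satterthwaite(fit)
        method = "satterthwaite" if vc is not None else "lrt"
        rows = {}
        for t, idx in fit.blocks.items():
            if t == ():
                continue
            if method == "satterthwaite":
                F, q, den = self._term_f(fit, idx, vc)
                p = float(stats.f.sf(F, q, den)) if np.isfinite(den) else float(stats.chi2.sf(F * q, q))
                rows[term_name(t)] = {"F": F, "df_num": q, "df_den": den, "p_value": p}
            else:
                # likelihood-ratio fallback: refit with the term's columns removed
                q = len(idx)
                sub = self._drop_columns_model(idx)
                lrt = max(2.0 * (fit.llf - sub.fit().llf), 0.0)
                p = float(stats.chi2.sf(lrt, q))
                rows[term_name(t)] = {"F": lrt / q, "df_num": q, "df_den": np.inf, "p_value": p}
        fit.df_method = method
        return pd.DataFrame(rows).T

    # -- prediction --------------------------------------------------------
    def _predict_cells(self, fit: FitResult, cells) -> pd.DataFrame:
        if isinstance(cells, dict):
            cells = pd.DataFrame(cells)
        elif isinstance(cells, (list, tuple)):
            cells = pd.DataFrame(list(cells))
        cells = cells.copy().reset_index(drop=True)
        for f, levs in fit.levels.items():
            col = FACTOR_COLUMNS[f]
            if col not in cells.columns:
                raise ValueError(f"cells must provide column {col!r} for factor {f}")
            unknown = set(cells[col].astype(str)) - set(levs)
            if unknown:
                raise ValueError(f"unknown level(s) {sorted(unknown)} for factor {f}")
        pred = np.full(len(cells), fit.params.iloc[0])
        for t, idx in fit.blocks.items():
            if t == ():
                continue
            nonref = [fit.levels[f][1:] for f in t]
            for col_i, combo in zip(idx, itertools.product(*nonref)):
                match = np.ones(len(cells), dtype=bool)
                for f, lev in zip(t, combo):
                    match &= cells[FACTOR_COLUMNS[f]].astype(str).to_numpy() == lev
                pred = pred + fit.params.iloc[col_i] * match
        out = cells.copy()
        out["predicted"] = pred
        return out


# ---------------------------------------------------------------------------
# spec-surface functions
# ---------------------------------------------------------------------------

def fit_model(table: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Fit a random-intercept Gaussian LMM by ML; deterministic given data."""
    return RandomInterceptLMM.from_table(table, spec).fit()


@dataclass
class SelectionResult:
    """Outcome of backward AIC elimination."""

    selected: ModelSpec
    fit: FitResult
    trace: pd.DataFrame


def backward_select(table: pd.DataFrame, full: ModelSpec) -> SelectionResult:
    """Backward elimination: drop the least significant term while AIC does not increase.

    At each step the droppable term with the highest p-value (ties: the
    higher-order term first, then alphabetically) is refitted without; the
    drop is kept if the AIC does not increase, otherwise selection stops.
    The trace records every attempted drop.
    """
    spec = full
    fit = fit_model(table, spec)
    rows = []
    while True:
        cands = spec.maximal_droppable()
        if not cands:
            break
        an = fit.anova()
        # highest p first; ties broken by higher order, then name
        ranked = sorted(
            cands,
            key=lambda t: (-an.loc[term_name(t), "p_value"], -len(t), term_name(t)),
        )
        term = ranked[0]
        new_spec = spec.without(term)
        new_fit = fit_model(table, new_spec)
        accepted = new_fit.aic <= fit.aic
        rows.append({
            "term": term_name(term),
            "p_value": float(an.loc[term_name(term), "p_value"]),
            "df_method": fit.df_method,
            "aic_before": fit.aic,
            "aic_after": new_fit.aic,
            "accepted": accepted,
        })
        if not accepted:
            break
        spec, fit = new_spec, new_fit
    trace = pd.DataFrame(rows, columns=["term", "p_value", "df_method", "aic_before", "aic_after", "accepted"])
    return SelectionResult(selected=spec, fit=fit, trace=trace)


def predict_cells(fit: FitResult, cells) -> pd.DataFrame:
    """Model-implied mean per requested factor-level combination."""
    return fit.predict(cells)


def term_pvalues(fit: FitResult) -> pd.Series:
    """Per-term p-values (Satterthwaite F, or the recorded fallback)."""
    return fit.pvalues()
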