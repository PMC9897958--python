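"""Conditional-logistic step-selection functions with tiered AICc selection.

The step-selection function models the relative intensity of use of a
step ending at covariates ``x`` as ``w(x) = exp(b1*x1 + ... + bn*xn)``.
With each used step conditioned against its J matched available steps
(one stratum), the conditional log-likelihood is

    LL(b) = sum_s [ b'x_used(s) - log sum_{c in s} exp(b'x_c) ]

maximized here by Newton ascent with step-halving. Step length always
enters as a covariate (it corrects the sampling kernel's length bias).

Model selection follows a three-tier scheme, all by small-sample AICc
with n = number of strata:

1. per covariate, choose the functional form (linear, quadratic, or
   natural log) from single-covariate fits;
2. choose among base habitat hypotheses — Corridors {dForest, dStream},
   Human Footprint {dAg, dRoad}, Global {all four};
3. add dissimilarity terms: best grain x form for D_ALL, then for D_IND
   (demoted past candidates correlating r > 0.70 with the chosen D_ALL),
   giving the nested set {base, base + D_ALL, base + D_ALL + D_IND}
   compared by Akaike weight.

Effects are visualized as the log relative selection strength, ln(RSS):
the weighted-average log intensity ratio between a location with the
focus covariate at value v and a reference location, all other
covariates held at their means.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ModelTerm", "ModelSpec", "FitResult", "clr_fit", "aicc", "akaike_weights",
    "comparison_table", "tier1_select_forms", "tier2_select_base",
    "dissimilarity_candidates", "tier3_select_dissimilarity", "vif",
    "model_average_rss", "BASE_HYPOTHESES",
]

LN_FLOOR = 1e-12  # floor inside ln() for D^2 covariates (0 only at exact mean)


@dataclass(frozen=True)
class ModelTerm:
    """One covariate with its functional form.

    ``ln_style``: 'plus1' uses ln(z + 1) (distances in meters, which are 0
    on-feature); 'floor' uses ln(max(z, 1e-12)) (squared Mahalanobis
    distances, 0 only at exact mean equality).
    """

    name: str
    form: str = "linear"  # linear | quad | ln
    ln_style: str = "plus1"

    @property
    def n_params(self) -> int:
        return 2 if self.form == "quad" else 1

    def columns(self):
        if self.form == "linear":
            return [self.name]
        if self.form == "quad":
            return [self.name, f"{self.name}^2"]
        if self.form == "ln":
            return [f"ln({self.name})"]
        raise ValueError(f"unknown form {self.form!r}")

    def transform(self, z: np.ndarray):
        z = np.asarray(z, dtype=float)
        if self.form == "linear":
            return [z]
        if self.form == "quad":
            return [z, z**2]
        if self.ln_style == "floor":
            return [np.log(np.maximum(z, LN_FLOOR))]
        return [np.log(z + 1.0)]


@dataclass(frozen=True)
class ModelSpec:
    """A term list plus the always-present step-length covariate."""

    terms: tuple = ()
    label: str = ""
    include_step_length: bool = True

    def with_terms(self, *extra, label=None):
        return replace(self, terms=self.terms + tuple(extra),
                       label=self.label if label is None else label)

    @property
    def k(self) -> int:
        return sum(t.n_params for t in self.terms) + int(self.include_step_length)

    def column_names(self):
        names = []
        for t in self.terms:
            names.extend(t.columns())
        if self.include_step_length:
            names.append("step_length")
        return names

    def design_matrix(self, df: pd.DataFrame) -> np.ndarray:
        seen = set()
        for t in self.terms:
            if t.name in seen:
                raise ValueError(f"duplicated covariate {t.name!r}")
            seen.add(t.name)
        cols = []
        for t in self.terms:
            cols.extend(t.transform(df[t.name].to_numpy()))
        if self.include_step_length:
            cols.append(df["step_length"].to_numpy(dtype=float))
        return np.column_stack(cols) if cols else np.empty((len(df), 0))


@dataclass
class FitResult:
    spec: ModelSpec
    beta: pd.Series
    se: pd.Series
    vcov: np.ndarray
    loglik: float
    k: int
    n_strata: int
    aicc: float
    converged: bool
    n_strata_dropped: int = 0
    weight: float = np.nan
    flags: dict = field(default_factory=dict)

    def ci(self, level: float = 0.95) -> pd.DataFrame:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
        return pd.DataFrame(
            {"estimate": self.beta, "lo": self.beta - z * self.se,
             "hi": self.beta + z * self.se})


def _conditional_loglik(beta, X, strata_starts, used_pos):
    """LL, gradient, and Hessian of the stratified conditional likelihood."""
    eta = X @ beta
    n_strata = len(strata_starts) - 1
    ll = 0.0
    grad = np.zeros(X.shape[1])
    H = np.zeros((X.shape[1], X.shape[1]))
    # segment softmax via reduceat on the stratum-sorted design
    m = np.maximum.reduceat(eta, strata_starts[:-1])
    seg = np.repeat(np.arange(n_strata), np.diff(strata_starts))
    w = np.exp(eta - m[seg])
    denom = np.add.reduceat(w, strata_starts[:-1])
    p = w / denom[seg]
    ll = float(eta[used_pos].sum() - (m + np.log(denom)).sum())
    grad = X[used_pos].sum(axis=0) - X.T @ p
    mu = np.zeros((n_strata, X.shape[1]))
    np.add.at(mu, seg, p[:, None] * X)
    H = -(X.T @ (p[:, None] * X) - mu.T @ mu)
    return ll, grad, H


def clr_fit(design: pd.DataFrame, spec: ModelSpec, max_iter: int = 100,
            grad_tol: float = 1e-6) -> FitResult:
    """Fit the conditional logistic SSF by Newton ascent with step-halving.

    Strata containing any undefined covariate value are dropped (counted
    in ``n_strata_dropped``); columns without within-stratum variation are
    excluded from estimation and reported in ``flags['no_information']``
    with NaN coefficients.
    """
    df = design
    raw_cols = [t.name for t in spec.terms]
    if spec.include_step_length:
        raw_cols.append("step_length")
    bad = df[raw_cols].isna().any(axis=1) if raw_cols else pd.Series(False, index=df.index)
    bad_strata = set(df.loc[bad, "stratum"].unique())
    kept = df[~df["stratum"].isin(bad_strata)]
    kept = kept.sort_values(["stratum", "case"], ascending=[True, False],
                            kind="stable")
    n_strata = kept["stratum"].nunique()
    if n_strata < 10:
        raise ValueError("need at least 10 usable strata")
    cases = kept.groupby("stratum")["case"].sum()
    if not (cases == 1).all():
        raise ValueError("each stratum must contain exactly one used step")

    X = spec.design_matrix(kept)
    names = spec.column_names()
    codes, _ = pd.factorize(kept["stratum"].to_numpy(), sort=False)
    counts = np.bincount(codes)
    strata_starts = np.concatenate([[0], np.cumsum(counts)])
    used_pos = np.nonzero(kept["case"].to_numpy() == 1)[0]

    # within-stratum variation check per column
    no_info = []
    for j in range(X.shape[1]):
        firsts = X[strata_starts[:-1], j]
        expanded = np.repeat(firsts, counts)
        if np.allclose(X[:, j], expanded, atol=0, rtol=0):
            no_info.append(j)
    active = [j for j in range(X.shape[1]) if j not in no_info]
    Xa = X[:, active]

    beta = np.zeros(Xa.shape[1])
    converged = False
    ll, grad, H = _conditional_loglik(beta, Xa, strata_starts, used_pos)
    for _ in range(max_iter):
        if np.max(np.abs(grad)) < grad_tol:
            converged = True
            break
        try:
            step = np.linalg.solve(-H, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(-H, grad, rcond=None)[0]
        scale = 1.0
        for _ in range(40):
            cand = beta + scale * step
            ll_new, g_new, H_new = _conditional_loglik(cand, Xa, strata_starts, used_pos)
            if ll_new >= ll - 1e-12:
                beta, ll, grad, H = cand, ll_new, g_new, H_new
                break
            scale *= 0.5
        else:
            break
    else:
        ll, grad, H = _conditional_loglik(beta, Xa, strata_starts, used_pos)
        converged = bool(np.max(np.abs(grad)) < grad_tol)

    flags = {}
    if no_info:
        flags["no_information"] = [names[j] for j in no_info]
    if np.any(np.abs(beta) > 50):
        flags["separation_suspected"] = True

    info = -H
    try:
        vcov_a = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        vcov_a = np.linalg.pinv(info)
        flags["singular_information"] = True
    k_full = X.shape[1]
    beta_full = np.full(k_full, np.nan)
    se_full = np.full(k_full, np.nan)
    vcov_full = np.full((k_full, k_full), np.nan)
    for a, j in enumerate(active):
        beta_full[j] = beta[a]
        se_full[j] = np.sqrt(max(vcov_a[a, a], 0.0))
        for b, j2 in enumerate(active):
            vcov_full[j, j2] = vcov_a[a, b]
    k_eff = len(active)
    return FitResult(
        spec=spec,
        beta=pd.Series(beta_full, index=names),
        se=pd.Series(se_full, index=names),
        vcov=vcov_full,
        loglik=ll,
        k=k_eff,
        n_strata=n_strata,
        aicc=aicc(ll, k_eff, n_strata),
        converged=converged,
        n_strata_dropped=len(bad_strata),
        flags=flags,
    )


def aicc(loglik: float, k: int, n: int) -> float:
    """AICc = -2 LL + 2k + 2k(k+1)/(n-k-1), n = number of strata."""
    if n <= k + 1:
        raise ValueError("n must exceed k + 1 for the AICc correction")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


def akaike_weights(aicc_values) -> np.ndarray:
    a = np.asarray(aicc_values, dtype=float)
    delta = a - a.min()
    w = np.exp(-delta / 2.0)
    return w / w.sum()


def comparison_table(fits: dict) -> pd.DataFrame:
    """Model comparison table: k, AICc, delta AICc, Akaike weight, LL."""
    rows = pd.DataFrame(
        {
            "model": list(fits),
            "k": [f.k for f in fits.values()],
            "AICc": [f.aicc for f in fits.values()],
            "LL": [f.loglik for f in fits.values()],
        }
    )
    rows["dAICc"] = rows["AICc"] - rows["AICc"].min()
    rows["w"] = akaike_weights(rows["AICc"].to_numpy())
    for name, fit in fits.items():
        fit.weight = float(rows.loc[rows["model"] == name, "w"].iloc[0])
    return rows.sort_values("AICc").reset_index(drop=True)[
        ["model", "k", "AICc", "dAICc", "w", "LL"]]


FORMS = ("linear", "quad", "ln")


def tier1_select_forms(design: pd.DataFrame, covariates: dict,
                       ) -> dict:
    """Choose each covariate's functional form from single-covariate fits.

    ``covariates`` maps name -> ln_style ('plus1' for distances, 'floor'
    for D^2). Ties go to fewer parameters, then to linear.
    """
    chosen = {}
    for name, ln_style in covariates.items():
        fits = {}
        for form in FORMS:
            term = ModelTerm(name, form, ln_style)
            spec = ModelSpec(terms=(term,), label=f"{name}:{form}")
            try:
                fits[form] = clr_fit(design, spec)
            except (ValueError, np.linalg.LinAlgError):
                continue
        if not fits:
            raise ValueError(f"no functional form could be fit for {name!r}")
        order = sorted(
            fits,
            key=lambda f: (round(fits[f].aicc, 10),
                           ModelTerm(name, f).n_params, f != "linear"),
        )
        chosen[name] = ModelTerm(name, order[0], ln_style)
    return chosen


BASE_HYPOTHESES = {
    "corridors": ("dForest", "dStream"),
    "human_footprint": ("dAg", "dRoad"),
    "global": ("dForest", "dStream", "dAg", "dRoad"),
}


def tier2_select_base(design: pd.DataFrame, forms: dict,
                      hypotheses: dict | None = None):
    """Compare the base habitat hypotheses with tier-1 forms.

    Returns ``(best_spec, fits, table)``.
    """
    hyps = hypotheses or BASE_HYPOTHESES
    fits = {}
    for label, names in hyps.items():
        spec = ModelSpec(terms=tuple(forms[n] for n in names), label=label)
        fits[label] = clr_fit(design, spec)
    table = comparison_table(fits)
    best = table["model"].iloc[0]
    return fits[best].spec, fits, table


def dissimilarity_candidates(prefix: str, grains=(175, 250, 350, 500),
                             forms=("linear", "ln")):
    """Candidate D^2 terms over grain radii and functional forms."""
    return [ModelTerm(f"{prefix}{g}", form, ln_style="floor")
            for g in grains for form in forms]


@dataclass
class Tier3Result:
    fits: dict  # label -> FitResult for {base, base+D_ALL, base+D_ALL+D_IND}
    table: pd.DataFrame
    d_all_term: ModelTerm | None
    d_ind_term: ModelTerm | None
    d_ind_omitted: bool = False
    d_ind_rank_used: int = 0
    correlation: float = np.nan


def _term_column(design: pd.DataFrame, term: ModelTerm) -> np.ndarray:
    return term.transform(design[term.name].to_numpy())[0]


def tier3_select_dissimilarity(design: pd.DataFrame, base_spec: ModelSpec,
                               d_all_candidates, d_ind_candidates,
                               r_limit: float = 0.70,
                               fallback_depth: int = 3) -> Tier3Result:
    """Select grain x form for D_ALL then D_IND and compare the nested set.

    The best D_ALL candidate (by AICc, added to the base) is fixed first;
    D_IND candidates are then ranked by AICc added on top. If the chosen
    D_IND column's Pearson r with the chosen D_ALL column exceeds
    ``r_limit`` in absolute value, the next-best candidate is used
    (up to ``fallback_depth``); if all exceed it, D_IND is omitted.
    """
    base_fit = clr_fit(design, replace(base_spec, label="base"))

    all_fits = {}
    for term in d_all_candidates:
        spec = base_spec.with_terms(term, label=f"base+{term.columns()[0]}")
        all_fits[term] = clr_fit(design, spec)
    d_all_term = min(all_fits, key=lambda t: all_fits[t].aicc)
    d_all_fit = all_fits[d_all_term]

    ind_fits = {}
    for term in d_ind_candidates:
        spec = d_all_fit.spec.with_terms(
            term, label=d_all_fit.spec.label + f"+{term.columns()[0]}")
        ind_fits[term] = clr_fit(design, spec)
    ranked = sorted(ind_fits, key=lambda t: ind_fits[t].aicc)

    col_all = _term_column(design, d_all_term)
    d_ind_term = None
    rank_used = 0
    corr = np.nan
    for depth, term in enumerate(ranked[:fallback_depth]):
        col_ind = _term_column(design, term)
        ok = np.isfinite(col_all) & np.isfinite(col_ind)
        corr = float(np.corrcoef(col_all[ok], col_ind[ok])[0, 1])
        if abs(corr) <= r_limit:
            d_ind_term = term
            rank_used = depth
            break

    fits = {"base": base_fit, "base+D_ALL": d_all_fit}
    omitted = d_ind_term is None
    if not omitted:
        fits["base+D_ALL+D_IND"] = ind_fits[d_ind_term]
    table = comparison_table(fits)
    return Tier3Result(
        fits=fits, table=table, d_all_term=d_all_term, d_ind_term=d_ind_term,
        d_ind_omitted=omitted, d_ind_rank_used=rank_used, correlation=corr,
    )


def vif(design: pd.DataFrame, columns) -> pd.Series:
    """Variance inflation factors across design rows: 1 / (1 - R^2_j) from
    regressing each covariate on the others (with intercept)."""
    if len(columns) < 2:
        raise ValueError("need at least 2 main effects")
    X = design[list(columns)].to_numpy(dtype=float)
    X = X[np.isfinite(X).all(axis=1)]
    out = {}
    for j, name in enumerate(columns):
        y = X[:, j]
        others = np.column_stack([np.ones(len(X)), np.delete(X, j, axis=1)])
        coef, *_ = np.linalg.lstsq(others, y, rcond=None)
        resid = y - others @ coef
        ss_res = float(resid @ resid)
        ss_tot = float(((y - y.mean()) ** 2).sum())
        if ss_tot == 0:
            out[name] = np.inf
            continue
        r2 = 1.0 - ss_res / ss_tot
        out[name] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out)


def model_average_rss(fits, focus: str, ref_value: float, values,
                      n_draws: int = 2000, seed: int = 0) -> pd.DataFrame:
    """Model-averaged ln(RSS) curve for one focus covariate.

    For each model, ln RSS(v) = sum over the model's focus-covariate terms
    of beta_hat * (f(v) - f(ref_value)); other covariates sit at their
    means and contribute nothing; models without the focus covariate
    contribute zero. Curves are combined by Akaike weight and a 95% band
    comes from parametric resampling of each model's coefficient vector.
    """
    values = np.asarray(values, dtype=float)
    fits = list(fits)
    weights = np.array([f.weight for f in fits], dtype=float)
    if np.any(~np.isfinite(weights)):
        weights = akaike_weights([f.aicc for f in fits])
    weights = weights / weights.sum()

    any_focus = False
    per_model_curves = np.zeros((len(fits), len(values)))
    per_model_draws = []
    rng = np.random.default_rng(seed)
    for m, fit in enumerate(fits):
        cols = []
        deltas = []
        names = fit.spec.column_names()
        for t in fit.spec.terms:
            if t.name != focus:
                continue
            any_focus = True
            fv = np.column_stack(t.transform(values))
            fr = np.column_stack(t.transform(np.array([ref_value])))
            for ci, cname in enumerate(t.columns()):
                cols.append(names.index(cname))
                deltas.append(fv[:, ci] - fr[0, ci])
        if not cols:
            per_model_draws.append(np.zeros((n_draws, len(values))))
            continue
        D = np.column_stack(deltas)  # (n_values, n_focus_cols)
        b = fit.beta.to_numpy()[cols]
        per_model_curves[m] = D @ b
        V = fit.vcov[np.ix_(cols, cols)]
        V = np.where(np.isfinite(V), V, 0.0)
        draws = rng.multivariate_normal(b, V, size=n_draws, method="svd")
        per_model_draws.append(draws @ D.T)
    if not any_focus:
        raise ValueError(f"focus covariate {focus!r} absent from every model")

    mean_curve = weights @ per_model_curves
    stacked = np.stack(per_model_draws)  # (n_models, n_draws, n_values)
    avg_draws = np.tensordot(weights, stacked, axes=1)
    lo, hi = np.percentile(avg_draws, [2.5, 97.5], axis=0)
    return pd.DataFrame(
        {"value": values, "ln_rss": mean_curve, "lo": lo, "hi": hi})
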