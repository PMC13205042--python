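"""Inferential chain linking neural stability to autistic-trait scores.

The core analysis fits nested linear mixed-effects models to Fisher-z
stability values, long format with one row per participant × response
component and a participant random intercept:

* M0: Zr ~ component + (1 | participant)
* M1: Zr ~ component + trait + (1 | participant)
* M2: Zr ~ component × trait + (1 | participant)
* M3: Zr ~ component × trait + age + VCI + (1 | participant)

Components are sum-coded (effects coding): estimates are deviations from
the grand mean across all five components and sum to zero over the full
level set; the click level is implied as minus the sum of the four shown.
Models are fit by maximum likelihood (required for BIC/likelihood-ratio
comparability), selection is by BIC, per-coefficient t-tests use
Satterthwaite-approximated degrees of freedom, pairwise component contrasts
use Tukey's studentized-range adjustment, and variance explained follows
the marginal/conditional R² variance-partition convention for mixed models
(fixed, and fixed + random, over total variance).

The mixed-model likelihood is maximised by statsmodels' MixedLM; the
Satterthwaite machinery, effects-coded design construction, estimated
marginal means, and repeated-measures ANOVA sphericity corrections are
implemented here.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
import statsmodels.api as sm

COMPONENT_ORDER = ("click", "full_sabr", "onset", "ffr", "offset")
MODEL_IDS = ("M0", "M1", "M2", "M3")


class StatsError(ValueError):
    pass


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------

def _component_codes(components: Sequence[str], coding: str) -> tuple[list[str], dict]:
    """Column names and per-level code vectors for a categorical component.

    Effects (sum) coding drops the first level (click), whose implied
    estimate is minus the sum of the shown levels; treatment coding drops
    the first level as reference.
    """
    shown = list(components[1:])
    codes = {}
    for lev in components:
        if coding == "effects":
            codes[lev] = np.array([1.0 if lev == s else 0.0 for s in shown]) \
                if lev != components[0] else np.full(len(shown), -1.0)
        elif coding == "treatment":
            codes[lev] = np.array([1.0 if lev == s else 0.0 for s in shown])
        else:
            raise StatsError(f"unknown coding {coding!r}")
    return shown, codes


def merge_tables(stability: pd.DataFrame, traits: pd.DataFrame) -> pd.DataFrame:
    """Merge long-format stability records with per-participant traits."""
    if "Zr" not in stability.columns:
        raise StatsError("stability table must carry a Zr column")
    return stability.merge(traits, on="participant_id", how="left")


@dataclass
class ModelSpec:
    model_id: str
    trait_col: str | None
    with_interaction: bool = False
    with_covariates: bool = False
    coding: str = "effects"


def model_spec(model_id: str, trait_col: str) -> ModelSpec:
    if model_id not in MODEL_IDS:
        raise StatsError(f"unknown model id {model_id!r}")
    return ModelSpec(
        model_id=model_id,
        trait_col=None if model_id == "M0" else trait_col,
        with_interaction=model_id in ("M2", "M3"),
        with_covariates=model_id == "M3",
    )


def build_design(df: pd.DataFrame, spec: ModelSpec,
                 components: Sequence[str] = COMPONENT_ORDER) -> tuple[pd.DataFrame, list[str]]:
    """Fixed-effects design matrix (as a DataFrame with named columns)."""
    comps = [c for c in components if c in set(df["component"])]
    if not comps:
        raise StatsError("no recognised components in the stability table")
    shown, codes = _component_codes(comps, spec.coding)
    X = pd.DataFrame(index=df.index)
    X["intercept"] = 1.0
    code_rows = np.vstack([codes[c] for c in df["component"]])
    for j, name in enumerate(shown):
        X[name] = code_rows[:, j]
    if spec.trait_col is not None:
        X[spec.trait_col] = df[spec.trait_col].astype(float)
        if spec.with_interaction:
            for j, name in enumerate(shown):
                X[f"{name}:{spec.trait_col}"] = code_rows[:, j] * X[spec.trait_col]
    if spec.with_covariates:
        X["age"] = df["age"].astype(float)
        X["vci"] = df["vci"].astype(float)
    return X, comps


# ---------------------------------------------------------------------------
# random-intercept covariance algebra and Satterthwaite df
# ---------------------------------------------------------------------------

def _group_blocks(X: np.ndarray, groups: np.ndarray):
    order = np.argsort(groups, kind="stable")
    Xs, gs = X[order], groups[order]
    blocks = []
    start = 0
    for i in range(1, len(gs) + 1):
        if i == len(gs) or gs[i] != gs[start]:
            Xi = Xs[start:i]
            blocks.append((Xi.T @ Xi, Xi.sum(axis=0), i - start))
            start = i
    return blocks


def _beta_cov(blocks, sb2: float, se2: float) -> np.ndarray:
    """(X'V⁻¹X)⁻¹ for V_i = se2·I + sb2·J per participant block."""
    p = blocks[0][0].shape[0]
    M = np.zeros((p, p))
    a = 1.0 / se2
    for G, s, n in blocks:
        b = -sb2 / (se2 * (se2 + n * sb2))
        M += a * G + b * np.outer(s, s)
    return np.linalg.inv(M)


def _varcomp_information(blocks, sb2: float, se2: float) -> np.ndarray:
    """Expected ML information matrix of (σ²_b, σ²_e)."""
    I_bb = I_be = I_ee = 0.0
    for _, _, n in blocks:
        u = 1.0 / (se2 + n * sb2)
        I_bb += 0.5 * n**2 * u**2
        I_be += 0.5 * n * u**2
        I_ee += 0.5 * ((n - 1) / se2**2 + u**2)
    return np.array([[I_bb, I_be], [I_be, I_ee]])


def satterthwaite_df(contrast: np.ndarray, blocks, sb2: float, se2: float,
                     n_obs: int, n_fixed: int) -> float:
    """Satterthwaite denominator df for a single fixed-effect contrast.

    df = 2 f(θ)² / (gᵀ A g) with f(θ) = cᵀ·Cov_β(θ)·c, g its gradient in the
    variance components θ = (σ²_b, σ²_e) (central finite differences), and A
    the inverse expected ML information of θ.
    """
    c = np.asarray(contrast, dtype=float)

    def f(tb: float, te: float) -> float:
        return float(c @ _beta_cov(blocks, max(tb, 0.0), te) @ c)

    f0 = f(sb2, se2)
    hb = max(1e-10, 1e-4 * max(sb2, se2))
    he = max(1e-10, 1e-4 * se2)
    if sb2 > hb:
        g_b = (f(sb2 + hb, se2) - f(sb2 - hb, se2)) / (2 * hb)
    else:  # boundary: one-sided
        g_b = (f(sb2 + hb, se2) - f0) / hb
    g_e = (f(sb2, se2 + he) - f(sb2, se2 - he)) / (2 * he)
    g = np.array([g_b, g_e])

    info = _varcomp_information(blocks, max(sb2, 1e-12), se2)
    try:
        A = np.linalg.inv(info)
    except np.linalg.LinAlgError:
        return float(n_obs - n_fixed)
    denom = float(g @ A @ g)
    if denom <= 0:
        return float(n_obs - n_fixed)
    df = 2.0 * f0**2 / denom
    return float(np.clip(df, 1.0, n_obs - n_fixed))


# ---------------------------------------------------------------------------
# model fitting
# ---------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted random-intercept mixed model with inference bookkeeping."""

    model_id: str
    coefficients: pd.DataFrame  # term, estimate, se, df, t, p, ci_low, ci_high
    loglik: float
    bic: float
    n_params: int
    r2_marginal: float
    r2_conditional: float
    n_obs: int
    n_participants: int
    converged: bool
    sigma_b2: float
    sigma_e2: float
    components: list = field(default_factory=list)
    trait_col: str | None = None
    coding: str = "effects"
    column_names: list = field(default_factory=list)
    column_means: dict = field(default_factory=dict)
    obs_hash: str = ""
    _X: np.ndarray | None = field(default=None, repr=False)
    _groups: np.ndarray | None = field(default=None, repr=False)
    _blocks: list = field(default_factory=list, repr=False)
    _cov_beta: np.ndarray | None = field(default=None, repr=False)

    def component_effects(self) -> dict[str, float]:
        """Effects-coded component estimates for ALL levels.

        The omitted (first) level's effect is implied as minus the sum of
        the shown levels, so the full set sums to zero.
        """
        if self.coding != "effects":
            raise StatsError("component_effects requires effects coding")
        shown = [c for c in self.components[1:]]
        est = self.coefficients.set_index("term").loc[shown, "estimate"]
        out = {self.components[0]: float(-est.sum())}
        out.update({c: float(est[c]) for c in shown})
        return out


def _obs_hash(df: pd.DataFrame) -> str:
    key = "|".join(sorted(f"{p}:{c}" for p, c in zip(df["participant_id"], df["component"])))
    return hashlib.sha1(key.encode()).hexdigest()


def fit_design(y: np.ndarray, X: pd.DataFrame, groups: np.ndarray, model_id: str = "custom",
               components: Sequence[str] = (), trait_col: str | None = None,
               coding: str = "effects", obs_hash: str = "") -> ModelFit:
    """ML fit of a random-intercept LMM on an explicit design matrix."""
    Xv = X.to_numpy(dtype=float)
    if np.linalg.matrix_rank(Xv) < Xv.shape[1]:
        raise StatsError("rank-deficient fixed-effects design")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = MixedLM(np.asarray(y, dtype=float), Xv, groups=groups)
        res = model.fit(reml=False)
    converged = bool(getattr(res, "converged", True))
    se2 = float(res.scale)
    sb2 = float(np.asarray(res.cov_re)[0, 0])
    beta = np.asarray(res.fe_params, dtype=float)

    blocks = _group_blocks(Xv, np.asarray(groups))
    cov_beta = _beta_cov(blocks, sb2, se2)
    se = np.sqrt(np.diag(cov_beta))
    n_obs, p = Xv.shape
    rows = []
    for j, term in enumerate(X.columns):
        c = np.zeros(p)
        c[j] = 1.0
        dfj = satterthwaite_df(c, blocks, sb2, se2, n_obs, p)
        t = beta[j] / se[j]
        pval = 2 * stats.t.sf(abs(t), dfj)
        half = stats.t.ppf(0.975, dfj) * se[j]
        rows.append({"term": term, "estimate": beta[j], "se": se[j], "df": dfj,
                     "t": t, "p": pval, "ci_low": beta[j] - half, "ci_high": beta[j] + half})
    coef = pd.DataFrame(rows)

    n_params = p + 2  # fixed effects + random-intercept and residual variances
    llf = float(res.llf)
    bic = -2.0 * llf + n_params * np.log(n_obs)
    sigma_f2 = float(np.var(Xv @ beta))
    total = sigma_f2 + sb2 + se2
    fit = ModelFit(
        model_id=model_id,
        coefficients=coef,
        loglik=llf,
        bic=float(bic),
        n_params=n_params,
        r2_marginal=sigma_f2 / total,
        r2_conditional=(sigma_f2 + sb2) / total,
        n_obs=n_obs,
        n_participants=int(pd.unique(groups).size),
        converged=converged,
        sigma_b2=sb2,
        sigma_e2=se2,
        components=list(components),
        trait_col=trait_col,
        coding=coding,
        column_names=list(X.columns),
        column_means={c: float(X[c].mean()) for c in X.columns},
        obs_hash=obs_hash,
        _X=Xv,
        _groups=np.asarray(groups),
        _blocks=blocks,
        _cov_beta=cov_beta,
    )
    if not converged:
        warnings.warn(f"mixed model {model_id} did not converge", stacklevel=2)
    return fit


def fit_lmm(model_id: str, stability: pd.DataFrame, traits: pd.DataFrame,
            trait_col: str = "aq_total", coding: str = "effects",
            complete_covariates: bool = True) -> ModelFit:
    """Fit one of the nested candidate models M0–M3.

    Rows with missing values in any variable used by the *richest* model of
    the comparison set are dropped when ``complete_covariates`` is true, so
    that BIC comparisons across M0–M3 are on identical observations.
    """
    spec = model_spec(model_id, trait_col)
    spec.coding = coding
    df = merge_tables(stability, traits)
    needed = [trait_col] if model_id != "M0" or complete_covariates else []
    if spec.with_covariates or complete_covariates:
        needed += ["age", "vci"]
    needed = [c for c in needed if c in df.columns]
    df = df.dropna(subset=["Zr"] + needed).reset_index(drop=True)
    if df["participant_id"].nunique() < 2:
        raise StatsError("need at least two participants")
    X, comps = build_design(df, spec)
    return fit_design(df["Zr"].to_numpy(), X, df["participant_id"].to_numpy(),
                      model_id=model_id, components=comps, trait_col=spec.trait_col,
                      coding=coding, obs_hash=_obs_hash(df))


def fit_nested_models(stability: pd.DataFrame, traits: pd.DataFrame,
                      trait_col: str = "aq_total") -> dict[str, ModelFit]:
    """Fit the full M0–M3 candidate set on a common observation set."""
    return {m: fit_lmm(m, stability, traits, trait_col) for m in MODEL_IDS}


def fit_subscale_models(stability: pd.DataFrame, traits: pd.DataFrame,
                        subscale_col: str, trait_col: str = "aq_total",
                        ) -> tuple[ModelFit, ModelFit]:
    """Fits testing whether one AQ subscale adds signal beyond the rest.

    The reduced model regresses Zr on component plus the AQ total minus the
    subscale; the full model adds the subscale itself.  Compare with
    :func:`subscale_lrt`.
    """
    df = merge_tables(stability, traits)
    df = df.dropna(subset=["Zr", trait_col, subscale_col]).reset_index(drop=True)
    df["_aq_rest"] = df[trait_col].astype(float) - df[subscale_col].astype(float)
    spec = ModelSpec("subscale", trait_col="_aq_rest")
    X, comps = build_design(df, spec)
    oh = _obs_hash(df)
    groups = df["participant_id"].to_numpy()
    reduced = fit_design(df["Zr"].to_numpy(), X, groups, model_id="reduced",
                         components=comps, trait_col="_aq_rest", obs_hash=oh)
    Xf = X.copy()
    Xf[subscale_col] = df[subscale_col].astype(float)
    full = fit_design(df["Zr"].to_numpy(), Xf, groups, model_id="full",
                      components=comps, trait_col="_aq_rest", obs_hash=oh)
    return full, reduced


def select_model(fits: Mapping[str, ModelFit]) -> tuple[str, pd.DataFrame]:
    """BIC model selection: best = minimum BIC; ΔBIC relative to the best."""
    if not fits:
        raise StatsError("no fits supplied")
    hashes = {f.obs_hash for f in fits.values()}
    if len(hashes) > 1:
        raise StatsError("fits were made on differing observation sets; BIC is not comparable")
    table = pd.DataFrame(
        [{"model": k, "bic": f.bic, "loglik": f.loglik, "n_params": f.n_params}
         for k, f in fits.items()]
    ).sort_values("bic", kind="stable").reset_index(drop=True)
    table["delta_bic"] = table["bic"] - table["bic"].min()
    return str(table.loc[0, "model"]), table


# ---------------------------------------------------------------------------
# estimated marginal means and Tukey-adjusted pairwise contrasts
# ---------------------------------------------------------------------------

def _emm_row(fit: ModelFit, component: str) -> np.ndarray:
    shown, codes = _component_codes(fit.components, fit.coding)
    row = np.zeros(len(fit.column_names))
    cols = {name: i for i, name in enumerate(fit.column_names)}
    row[cols["intercept"]] = 1.0
    for j, name in enumerate(shown):
        row[cols[name]] = codes[component][j]
    if fit.trait_col is not None and fit.trait_col in cols:
        tmean = fit.column_means[fit.trait_col]
        row[cols[fit.trait_col]] = tmean
        for j, name in enumerate(shown):
            key = f"{name}:{fit.trait_col}"
            if key in cols:
                row[cols[key]] = codes[component][j] * tmean
    for cov in ("age", "vci"):
        if cov in cols:
            row[cols[cov]] = fit.column_means[cov]
    return row


def tukey_p(t_stat: float, k: int, df: float) -> float:
    """Tukey studentized-range p for a pairwise contrast among k means.

    For k = 2 the adjustment reduces exactly to the two-sided t-test, which
    is computed directly (the q and t distributions coincide up to √2).
    """
    if k < 2:
        raise StatsError("need at least two levels")
    if k == 2:
        return float(2 * stats.t.sf(abs(t_stat), df))
    return float(stats.studentized_range.sf(abs(t_stat) * np.sqrt(2.0), k, df))


def emmeans_contrasts(fit: ModelFit) -> pd.DataFrame:
    """All pairwise component contrasts with Tukey-adjusted p-values."""
    comps = fit.components
    if len(comps) < 2:
        raise StatsError("component factor absent from the fitted model")
    beta = fit.coefficients["estimate"].to_numpy()
    k = len(comps)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            c = _emm_row(fit, comps[i]) - _emm_row(fit, comps[j])
            est = float(c @ beta)
            se = float(np.sqrt(c @ fit._cov_beta @ c))
            dfc = satterthwaite_df(c, fit._blocks, fit.sigma_b2, fit.sigma_e2,
                                   fit.n_obs, len(fit.column_names))
            t = est / se
            rows.append({
                "contrast": f"{comps[i]} - {comps[j]}",
                "estimate": est, "se": se, "df": dfc, "t": t,
                "p_unadjusted": float(2 * stats.t.sf(abs(t), dfc)),
                "p_tukey": tukey_p(t, k, dfc),
            })
    out = pd.DataFrame(rows)
    out["p_tukey"] = np.maximum(out["p_tukey"], out["p_unadjusted"])
    return out


# ---------------------------------------------------------------------------
# variance explained and likelihood-ratio tests
# ---------------------------------------------------------------------------

def r2_decomposition(fit: ModelFit) -> tuple[float, float]:
    """Marginal and conditional R² (variance-partition convention)."""
    return fit.r2_marginal, fit.r2_conditional


def delta_r2(fit_with: ModelFit, fit_without: ModelFit) -> float:
    """Difference in marginal R² between two nested fits on the same data."""
    if fit_with.obs_hash != fit_without.obs_hash:
        raise StatsError("ΔR² requires fits on identical observations")
    if fit_with.n_params < fit_without.n_params:
        raise StatsError("fit_with must be the richer model")
    return fit_with.r2_marginal - fit_without.r2_marginal


def subscale_lrt(full: ModelFit, reduced: ModelFit, tol: float = 1e-6) -> tuple[float, int, float]:
    """Likelihood-ratio test of nested ML fits: χ² = 2·Δloglik."""
    if full.obs_hash != reduced.obs_hash:
        raise StatsError("LRT requires fits on identical observations")
    df = full.n_params - reduced.n_params
    if df < 0:
        raise StatsError("full model must not have fewer parameters than the reduced model")
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    if chi2 < -tol:
        raise StatsError(
            f"reduced model has higher likelihood than the full model (Δ = {chi2 / 2:.3g}); "
            "refit with better starting values"
        )
    chi2 = max(chi2, 0.0)
    if df == 0:
        return chi2, 0, 1.0
    return chi2, df, float(stats.chi2.sf(chi2, df))


# ---------------------------------------------------------------------------
# repeated-measures ANOVA with sphericity correction
# ---------------------------------------------------------------------------

@dataclass
class EffectResult:
    F: float
    df1: float
    df2: float
    p: float
    gg_epsilon: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    corrected: bool


@dataclass
class RmanovaResult:
    effects: dict  # effect name -> EffectResult
    n_subjects: int


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k−1) × k orthonormal contrast rows (orthogonal complement of 1/√k)."""
    if k < 2:
        return np.zeros((0, k))
    H = np.eye(k) - np.full((k, k), 1.0 / k)
    q, _ = np.linalg.qr(H.T)
    # drop the column aligned with the constant (QR of a rank k−1 matrix)
    basis = q[:, :k - 1]
    return basis.T


def _effect_from_scores(scores: np.ndarray, sphericity_alpha: float) -> EffectResult:
    n, d = scores.shape
    mean = scores.mean(axis=0)
    ss_effect = n * float(mean @ mean)
    resid = scores - mean
    ss_error = float((resid**2).sum())
    F = (ss_effect / d) / (ss_error / (d * (n - 1)))
    if d == 1:
        eps, W, chi2, mdf, mp = 1.0, 1.0, 0.0, 0, 1.0
    else:
        S = np.cov(scores, rowvar=False, ddof=1)
        tr, tr2 = float(np.trace(S)), float(np.trace(S @ S))
        eps = tr**2 / (d * tr2)
        eps = float(np.clip(eps, 1.0 / d, 1.0))
        det = float(np.linalg.det(S))
        geo = (tr / d) ** d
        W = det / geo if geo > 0 else 0.0
        W = min(max(W, np.finfo(float).tiny), 1.0)
        factor = (n - 1) - (2 * d**2 + d + 2) / (6.0 * d)
        chi2 = float(-factor * np.log(W))
        mdf = d * (d + 1) // 2 - 1
        mp = float(stats.chi2.sf(chi2, mdf))
    corrected = bool(d > 1 and mp < sphericity_alpha)
    df1, df2 = float(d), float(d * (n - 1))
    if corrected:
        df1, df2 = eps * df1, eps * df2
    p = float(stats.f.sf(F, df1, df2))
    return EffectResult(F=float(F), df1=df1, df2=df2, p=p, gg_epsilon=eps,
                        mauchly_chi2=chi2, mauchly_df=mdf, mauchly_p=mp, corrected=corrected)


def rmanova_gg(data: pd.DataFrame, dv: str, within: Sequence[str], subject: str,
               sphericity_alpha: float = 0.05) -> RmanovaResult:
    """Two-way (or one-way) within-subject ANOVA with Greenhouse–Geisser df.

    Requires a complete crossed design per subject.  Each effect's F is
    computed from orthonormal contrast scores of the per-subject cell means;
    Mauchly's test is run per effect and Greenhouse–Geisser corrected
    degrees of freedom are applied iff sphericity is rejected at
    ``sphericity_alpha``.
    """
    within = list(within)
    if len(within) not in (1, 2):
        raise StatsError("within must name one or two factors")
    wide = data.pivot_table(index=subject, columns=within, values=dv, aggfunc="mean")
    if wide.isna().any().any():
        raise StatsError("incomplete cells: every subject needs every factor combination")
    n = wide.shape[0]
    if n < 2:
        raise StatsError("need at least two subjects")

    if len(within) == 1:
        k = wide.shape[1]
        M = _orthonormal_contrasts(k)
        scores = wide.to_numpy() @ M.T
        return RmanovaResult({within[0]: _effect_from_scores(scores, sphericity_alpha)}, n)

    a_levels = wide.columns.get_level_values(0).unique()
    b_levels = wide.columns.get_level_values(1).unique()
    a, b = len(a_levels), len(b_levels)
    # ensure column order is the full cartesian grid
    wide = wide.reindex(columns=pd.MultiIndex.from_product([a_levels, b_levels]))
    Y = wide.to_numpy()
    Ma, Mb = _orthonormal_contrasts(a), _orthonormal_contrasts(b)
    one_a, one_b = np.full((1, a), 1 / np.sqrt(a)), np.full((1, b), 1 / np.sqrt(b))
    effects = {
        within[0]: np.kron(Ma, one_b),
        within[1]: np.kron(one_a, Mb),
        f"{within[0]}:{within[1]}": np.kron(Ma, Mb),
    }
    results = {name: _effect_from_scores(Y @ C.T, sphericity_alpha) for name, C in effects.items()}
    return RmanovaResult(results, n)


# ---------------------------------------------------------------------------
# multicollinearity and small preliminary tests
# ---------------------------------------------------------------------------

def vif(design: pd.DataFrame) -> pd.Series:
    """Variance inflation factor per predictor: 1 / (1 − R²_j).

    Each predictor is regressed (with intercept) on all others; exact
    collinearity yields ``inf``.
    """
    if design.shape[1] < 2:
        raise StatsError("VIF needs at least two predictors")
    out = {}
    for col in design.columns:
        others = sm.add_constant(design.drop(columns=[col]).to_numpy(dtype=float))
        r2 = sm.OLS(design[col].to_numpy(dtype=float), others).fit().rsquared
        out[col] = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
    return pd.Series(out, name="vif")


def welch_t(group_a: Sequence[float], group_b: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test: (t, Welch–Satterthwaite df, two-sided p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise StatsError("each group needs at least two observations")
    if np.var(a) == 0 and np.var(b) == 0:
        if np.mean(a) == np.mean(b):
            return 0.0, float(a.size + b.size - 2), 1.0
        raise StatsError("zero variance in both groups with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def corr_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Pearson correlation with two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need at least three paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise StatsError("constant input: correlation undefined")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
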