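"""Downstream statistics linking engraftment to clinical outcomes and
plasma metabolites.

Contains the metabolite preprocessing (half-minimum imputation of
below-detection values, then per-metabolite scaling so the median is 1),
the confirmatory linear mixed-effects model for the selected
(engraftment, clinical parameter) pairs, Benjamini–Hochberg FDR,
Spearman correlation links, a Procrustes concordance test with row
permutations, and the between/within (multilevel) decomposition for
repeated-measures ordination.

The mixed model is a random-intercept model per subject fitted by REML:

    value ~ engrafted + time + engrafted:time + (1 | subject)

The engrafted:time interaction is the engraftment-attributable change in
the parameter; on balanced complete data its estimate reduces to the
difference-in-differences of the four cell means. Degrees of freedom use
Satterthwaite's two-moment approximation, with the gradient of the
coefficient variance and the variance-component covariance obtained from
the REML criterion by finite differences (the construction lmerTest
uses).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .errors import NotEstimableError

# ---------------------------------------------------------------------------
# Metabolite preprocessing
# ---------------------------------------------------------------------------


def preprocess_metabolites(raw: pd.DataFrame) -> pd.DataFrame:
    """Impute below-detection values and scale each metabolite's median to 1.

    Missing cells are imputed with half of the metabolite's lowest observed
    value (distinguishing "below detection" from the lowest measured
    intensity), then the column is divided by its median. A short
    fixed-point rescale guarantees the output median is exactly 1 in
    floating point even for even-length columns. All-missing metabolites
    are dropped with a warning.
    """
    out = {}
    for name in raw.columns:
        col = raw[name].to_numpy(dtype=float)
        observed = col[~np.isnan(col)]
        if observed.size == 0:
            warnings.warn(f"metabolite {name!r} is all-missing; dropped", stacklevel=2)
            continue
        fill = observed.min() / 2.0
        col = np.where(np.isnan(col), fill, col)
        for _ in range(5):
            med = np.median(col)
            if med <= 0:
                warnings.warn(
                    f"metabolite {name!r} has non-positive median; dropped",
                    stacklevel=2,
                )
                col = None
                break
            if med == 1.0:
                break
            col = col / med
        if col is not None:
            out[name] = col
    return pd.DataFrame(out, index=raw.index)


# ---------------------------------------------------------------------------
# Random-intercept LMM with Satterthwaite degrees of freedom
# ---------------------------------------------------------------------------


@dataclass
class LmmFit:
    """REML fit of a random-intercept model."""

    params: pd.Series
    bse: pd.Series
    df: pd.Series  # Satterthwaite df per coefficient
    pvalues: pd.Series
    sigma2: float  # residual variance
    tau2: float  # random-intercept variance
    n_obs: int
    n_groups: int
    converged: bool
    singular: bool  # variance component at its floor


@dataclass
class LmmResult:
    """One (SGB, clinical parameter) confirmatory test."""

    sgb_id: str
    parameter: str
    coefficient: float  # engrafted:time interaction, in the parameter's units
    se: float
    df: float
    pvalue: float
    fdr_pvalue: float = float("nan")


class _GroupedDesign:
    """Precomputed group sums for block-diagonal V = σ²I + τ²(per-group J).

    All REML quantities use the Woodbury forms: with group sizes m_g and
    group sums S (G × p) and sy (G), X'V⁻¹X = X'X/σ² − Σ_g c_g s_g s_gᵀ
    with c_g = τ²/(σ²(σ² + m_g τ²)), and similarly for X'V⁻¹y and y'V⁻¹y.
    """

    def __init__(self, y: np.ndarray, X: np.ndarray, starts: np.ndarray,
                 sizes: np.ndarray):
        self.y, self.X = y, X
        self.sizes = sizes.astype(float)
        self.S = np.add.reduceat(X, starts, axis=0)  # G × p
        self.sy = np.add.reduceat(y, starts)  # G
        self.XtX = X.T @ X
        self.Xty = X.T @ y
        self.yty = float(y @ y)
        self.n, self.p = X.shape

    def _pieces(self, s2: float, t2: float):
        denom = s2 + self.sizes * t2
        c = t2 / (s2 * denom)
        XtVX = self.XtX / s2 - (self.S.T * c) @ self.S
        XtVy = self.Xty / s2 - self.S.T @ (c * self.sy)
        yVy = self.yty / s2 - float(c @ (self.sy**2))
        logdet = float(np.sum((self.sizes - 1) * np.log(s2) + np.log(denom)))
        return XtVX, XtVy, yVy, logdet

    def neg2_reml(self, s2: float, t2: float) -> float:
        if s2 <= 0 or t2 < 0:
            return np.inf
        XtVX, XtVy, yVy, logdet = self._pieces(s2, t2)
        sign, logdet_xtvx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        beta = np.linalg.solve(XtVX, XtVy)
        rss = yVy - beta @ XtVy
        return float(logdet + logdet_xtvx + rss)

    def profiled_neg2_reml(self, phi: float) -> tuple[float, float]:
        """Criterion profiled over σ² at variance ratio φ = τ²/σ².

        Returns (criterion, σ̂²(φ)); the profiled residual variance is
        r'W⁻¹r/(n−p) with W = I + φ·(per-group J).
        """
        XtVX, XtVy, yVy, logdetW = self._pieces(1.0, phi)
        sign, logdet_xtwx = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf, np.nan
        beta = np.linalg.solve(XtVX, XtVy)
        rss = yVy - beta @ XtVy
        dof = self.n - self.p
        if rss <= 0:
            rss = 1e-300
        s2 = rss / dof
        crit = logdetW + logdet_xtwx + dof * np.log(s2) + dof
        return float(crit), float(s2)

    def beta_cov(self, s2: float, t2: float) -> tuple[np.ndarray, np.ndarray]:
        XtVX, XtVy, _, _ = self._pieces(s2, t2)
        cov = np.linalg.inv(XtVX)
        return cov @ XtVy, cov


def fit_lmm_random_intercept(
    data: pd.DataFrame,
    response: str,
    fixed: list[str],
    group: str = "subject_id",
) -> LmmFit:
    """Fit ``response ~ 1 + fixed... + (1 | group)`` by REML.

    ``fixed`` names numeric columns of ``data``; an intercept is always
    included. Rows with missing response or predictors are dropped.
    Satterthwaite degrees of freedom are computed per coefficient.
    """
    cols = [response, group] + fixed
    df = data[cols].dropna()
    if df[group].nunique() < 2:
        raise NotEstimableError("need at least 2 subjects")
    df = df.sort_values(group, kind="stable")
    y = df[response].to_numpy(dtype=float)
    X = np.column_stack(
        [np.ones(len(df))] + [df[f].to_numpy(dtype=float) for f in fixed]
    )
    names = ["intercept"] + fixed
    codes = pd.factorize(df[group].to_numpy())[0]
    starts = np.concatenate([[0], np.flatnonzero(np.diff(codes)) + 1])
    sizes = np.diff(np.concatenate([starts, [len(codes)]]))
    design = _GroupedDesign(y, X, starts, sizes)

    # profile REML over the variance ratio φ = τ²/σ² (1-D, log scale)
    def objective(log_phi: float) -> float:
        return design.profiled_neg2_reml(np.exp(log_phi))[0]

    res = optimize.minimize_scalar(
        objective, bounds=(np.log(1e-8), np.log(1e8)), method="bounded",
        options={"xatol": 1e-10},
    )
    phi = float(np.exp(res.x))
    _, s2 = design.profiled_neg2_reml(phi)
    var_y = max(float(np.var(y, ddof=1)), 1e-300)
    floor = 1e-10 * var_y
    s2 = max(s2, floor)
    t2 = max(phi * s2, 0.0)
    singular = bool(phi <= 2e-8 or phi >= 0.5e8)
    theta = np.array([s2, t2])

    beta, cov = design.beta_cov(s2, t2)
    se = np.sqrt(np.diag(cov))

    # Satterthwaite: df_k = 2·C_k² / (gᵀ A g), with C_k = Var(β̂_k)(θ),
    # g = ∂C_k/∂θ (finite differences) and A ≈ 2·H⁻¹ of the REML criterion
    # in variance scale.
    h = np.maximum(1e-5 * theta, 1e-10 * s2)

    def crit(th: np.ndarray) -> float:
        return design.neg2_reml(max(th[0], floor), max(th[1], 0.0))

    H = np.zeros((2, 2))
    f0 = crit(theta)
    for i in range(2):
        for j in range(i, 2):
            ei = np.eye(2)[i] * h[i]
            ej = np.eye(2)[j] * h[j]
            if i == j:
                H[i, i] = (crit(theta + ei) - 2 * f0 + crit(theta - ei)) / h[i] ** 2
            else:
                H[i, j] = H[j, i] = (
                    crit(theta + ei + ej)
                    - crit(theta + ei - ej)
                    - crit(theta - ei + ej)
                    + crit(theta - ei - ej)
                ) / (4 * h[i] * h[j])
    try:
        A = 2.0 * np.linalg.inv(H)
    except np.linalg.LinAlgError:
        A = np.full((2, 2), np.nan)

    def cov_at(th: np.ndarray) -> np.ndarray:
        return design.beta_cov(max(th[0], floor), max(th[1], 0.0))[1]

    grads = []
    for i in range(2):
        ei = np.eye(2)[i] * h[i]
        grads.append((np.diag(cov_at(theta + ei)) - np.diag(cov_at(theta - ei)))
                     / (2 * h[i]))
    G = np.array(grads)  # 2 × p gradients of Var(β̂_k)

    n, p = X.shape
    fallback_df = max(n - p, 1)
    dfs = np.empty(len(names))
    for k in range(len(names)):
        g = G[:, k]
        denom = float(g @ A @ g) if np.all(np.isfinite(A)) else np.nan
        ck = float(cov[k, k])
        if not np.isfinite(denom) or denom <= 0:
            dfs[k] = fallback_df
        else:
            dfs[k] = min(2 * ck**2 / denom, 1e6)
        dfs[k] = max(dfs[k], 1.0)
    tvals = beta / se
    pvals = 2 * stats.t.sf(np.abs(tvals), dfs)
    return LmmFit(
        params=pd.Series(beta, index=names),
        bse=pd.Series(se, index=names),
        df=pd.Series(dfs, index=names),
        pvalues=pd.Series(pvals, index=names),
        sigma2=s2,
        tau2=t2,
        n_obs=n,
        n_groups=len(sizes),
        converged=bool(res.success),
        singular=singular,
    )


def fit_engraftment_lmm(
    clinical_long: pd.DataFrame,
    engraftment: pd.DataFrame,
    pairs: list[tuple[str, str]],
) -> list[LmmResult]:
    """Confirmatory mixed-model tests for selected (SGB, parameter) pairs.

    For each pair the clinical parameter's pre/post values are modeled on
    the binarized engraftment status, time (post = 1) and their
    interaction, with a random intercept per subject. The interaction
    coefficient is the engraftment-attributable change in the parameter.
    P-values of the interaction are Benjamini–Hochberg adjusted across the
    tested set.
    """
    results = []
    for sgb_id, parameter in pairs:
        sub = clinical_long[clinical_long.parameter == parameter].copy()
        sub["time_post"] = (sub["time"] == "post").astype(float)
        eng = engraftment.loc[sgb_id]
        sub["engrafted"] = sub["subject_id"].map(eng).astype(float)
        sub["engrafted_time"] = sub["engrafted"] * sub["time_post"]
        sub = sub.dropna(subset=["value", "engrafted"])
        if sub.groupby("engrafted")["subject_id"].nunique().min() < 2 or (
            sub["engrafted"].nunique() < 2
        ):
            results.append(
                LmmResult(sgb_id, parameter, np.nan, np.nan, np.nan, np.nan)
            )
            continue
        fit = fit_lmm_random_intercept(
            sub,
            response="value",
            fixed=["engrafted", "time_post", "engrafted_time"],
        )
        results.append(
            LmmResult(
                sgb_id=sgb_id,
                parameter=parameter,
                coefficient=float(fit.params["engrafted_time"]),
                se=float(fit.bse["engrafted_time"]),
                df=float(fit.df["engrafted_time"]),
                pvalue=float(fit.pvalues["engrafted_time"]),
            )
        )
    tested = [r for r in results if np.isfinite(r.pvalue)]
    if tested:
        adj = fdr_bh(np.array([r.pvalue for r in tested]))
        for r, q in zip(tested, adj):
            r.fdr_pvalue = float(q)
    return results


def lmm_results_to_frame(results: list[LmmResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sgb_id": r.sgb_id,
                "parameter": r.parameter,
                "coefficient": r.coefficient,
                "se": r.se,
                "df": r.df,
                "pvalue": r.pvalue,
                "fdr_pvalue": r.fdr_pvalue,
            }
            for r in results
        ]
    )


def fdr_bh(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values (monotone)."""
    pvals = np.asarray(pvals, dtype=float)
    return multipletests(pvals, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Correlation links
# ---------------------------------------------------------------------------


@dataclass
class CorrelationResult:
    """Spearman link between two paired quantities."""

    rho: float
    pvalue: float
    n: int
    method: str


def spearman_link(x, y, exact_below: int = 10) -> CorrelationResult:
    """Spearman correlation on pairwise-complete observations.

    For fewer than ``exact_below`` pairs the p-value is computed by exact
    permutation enumeration; otherwise the usual t approximation is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    n = x.size
    if n < 4:
        raise NotEstimableError(f"only {n} complete pairs; need at least 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise NotEstimableError("constant vector: Spearman undefined")
    rho, p_approx = stats.spearmanr(x, y)
    if n < exact_below:
        # exact permutation null: Pearson correlation of ranks over all n!
        # pairings of y with x (vectorized enumeration)
        from itertools import permutations

        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        rxc = rx - rx.mean()
        perms = np.array(list(permutations(ry)), dtype=float)
        perms -= ry.mean()
        denom = np.linalg.norm(rxc) * np.linalg.norm(perms[0])
        rho_perm = perms @ rxc / denom
        p_exact = float(np.mean(np.abs(rho_perm) >= abs(rho) - 1e-12))
        return CorrelationResult(float(rho), p_exact, n, "exact")
    return CorrelationResult(float(rho), float(p_approx), n, "t-approx")


# ---------------------------------------------------------------------------
# Procrustes concordance
# ---------------------------------------------------------------------------


@dataclass
class ProcrustesResult:
    """Concordance of two subject-level configurations."""

    m2: float
    pvalue: float
    n_permutations: int
    n_components: int


def _principal_coordinates(M: np.ndarray, n_components: int) -> np.ndarray:
    """Principal-component reduction (Euclidean principal coordinates)."""
    M = M - M.mean(axis=0)
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    k = min(n_components, (s > 1e-12 * s[0]).sum() if s.size else 0)
    if k < 1:
        raise NotEstimableError("configuration has no variance")
    return U[:, :k] * s[:k]


def _procrustes_m2(A: np.ndarray, B: np.ndarray) -> float:
    """Symmetric Procrustes statistic m² after optimal superposition.

    Both configurations are centered and scaled to unit Frobenius norm;
    m² is the residual sum of squares after the optimal rotation/scaling
    of the second onto the first (0 = identical shapes, 1 = no match).
    """
    A = A - A.mean(axis=0)
    B = B - B.mean(axis=0)
    na, nb = np.linalg.norm(A), np.linalg.norm(B)
    if na == 0 or nb == 0:
        raise NotEstimableError("degenerate configuration")
    A, B = A / na, B / nb
    s = np.linalg.svd(A.T @ B, compute_uv=False)
    return float(max(1.0 - s.sum() ** 2, 0.0))


def procrustes_test(
    A,
    B,
    n_perm: int = 999,
    seed: int = 0,
    n_components: int = 2,
) -> ProcrustesResult:
    """Procrustes concordance of two subject × feature matrices with a
    row-permutation significance test.

    Each matrix is reduced to its Euclidean principal coordinates, the
    optimal superposition is computed, and the observed m² is compared
    with its distribution under random row permutations of the second
    configuration: p = (1 + #{m²_perm ≤ m²_obs}) / (1 + n_perm).
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape[0] != B.shape[0]:
        raise ValueError("A and B must have the same subjects (rows)")
    if A.shape[0] < 4:
        raise NotEstimableError("need at least 4 subjects")
    if np.isnan(A).any() or np.isnan(B).any():
        raise ValueError("A and B must be complete (no missing values)")
    pa = _principal_coordinates(A, n_components)
    pb = _principal_coordinates(B, n_components)
    # pad to common dimension so the cross-product is defined
    k = max(pa.shape[1], pb.shape[1])
    pa = np.pad(pa, ((0, 0), (0, k - pa.shape[1])))
    pb = np.pad(pb, ((0, 0), (0, k - pb.shape[1])))
    m2_obs = _procrustes_m2(pa, pb)
    rng = np.random.default_rng(seed)
    hits = 0
    n = pa.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n)
        if _procrustes_m2(pa, pb[perm]) <= m2_obs:
            hits += 1
    p = (1 + hits) / (1 + n_perm)
    return ProcrustesResult(
        m2=m2_obs, pvalue=float(p), n_permutations=n_perm, n_components=k
    )


# ---------------------------------------------------------------------------
# Multilevel (between/within) decomposition
# ---------------------------------------------------------------------------


def multilevel_split(
    X: pd.DataFrame, subject_ids: np.ndarray | pd.Series
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """Split repeated measures into between- and within-subject parts.

    The within-subject part is each observation minus its subject mean;
    the between part is the subject mean broadcast back to the rows, so
    between + within reconstructs X exactly. PCA of the within part
    isolates the repeated-measures (pre → post) variation from stable
    between-subject differences. Subjects with a single observation have
    an all-zero within row and are reported in the flag list.
    """
    subject_ids = pd.Series(np.asarray(subject_ids), index=X.index, name="subject")
    means = X.groupby(subject_ids).transform("mean")
    within = X - means
    counts = subject_ids.map(subject_ids.value_counts())
    flagged = sorted(subject_ids[counts == 1].unique().tolist())
    return means, within, flagged
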