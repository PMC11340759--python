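"""Ridge-regularized canonical correlation analysis (rCCA) between binary
strain-engraftment profiles and baseline-corrected clinical deltas.

Classical CCA is ill-posed when the number of features approaches the
number of subjects; adding ridge penalties λ₁, λ₂ to the two covariance
blocks keeps the problem well-conditioned. The canonical directions solve
the generalized eigenproblem of

    (Cxx + λ₁ I)⁻¹ Cxy (Cyy + λ₂ I)⁻¹ Cyx

computed here through the symmetric form: the SVD of
(Cxx + λ₁ I)^(−1/2) Cxy (Cyy + λ₂ I)^(−1/2). Penalties are tuned by
leave-one-out cross-validation on a grid: for every grid point each
subject is held out once, scored on the first pair of canonical
directions fit without it, and the pooled held-out score pairs are
correlated; the grid point with the largest pooled correlation wins
(ties toward larger penalties, i.e. more shrinkage).

Features are visualized on the correlation circle: each feature's
coordinates are its correlations with the first two canonical variates of
its own dataset. Cross-dataset feature pairs are then ranked by the
absolute 2-D inner product of their circle coordinates and the top pairs
are passed on to confirmatory mixed-model testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import NotEstimableError

#: "Standard grid" for penalty tuning: 21 log-spaced values per penalty.
DEFAULT_GRID = np.logspace(-4, 0, 21)

#: Default outer-ring radius of the correlation circle.
R_OUTER_DEFAULT = 0.5


@dataclass
class RccaModel:
    """A fitted regularized CCA model."""

    x_names: list[str]
    y_names: list[str]
    x_loadings: np.ndarray  # p × k
    y_loadings: np.ndarray  # q × k
    x_scores: np.ndarray  # n × k canonical variates of X
    y_scores: np.ndarray  # n × k canonical variates of Y
    canonical_correlations: np.ndarray  # k, Pearson correlations of variates
    singular_values: np.ndarray  # k, penalized canonical correlations
    lambda1: float
    lambda2: float
    x_center: np.ndarray = field(repr=False, default=None)
    x_scale: np.ndarray = field(repr=False, default=None)
    y_center: np.ndarray = field(repr=False, default=None)
    y_scale: np.ndarray = field(repr=False, default=None)

    @property
    def n_components(self) -> int:
        return self.x_loadings.shape[1]


@dataclass
class SelectedPair:
    """One cross-dataset feature pair ranked by circle inner product."""

    x_feature: str
    y_feature: str
    inner_product: float
    rank: int


def _standardize(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    center = M.mean(axis=0)
    scale = M.std(axis=0, ddof=1)
    scale = np.where(scale > 0, scale, 1.0)
    return (M - center) / scale, center, scale


def _inv_sqrt(S: np.ndarray, floor: float = 1e-12) -> np.ndarray:
    vals, vecs = np.linalg.eigh(S)
    vals = np.maximum(vals, floor)
    return (vecs / np.sqrt(vals)) @ vecs.T


def _drop_constant(M: np.ndarray, names: list[str], label: str):
    keep = M.std(axis=0, ddof=1) > 0
    if not keep.all():
        dropped = [n for n, k in zip(names, keep) if not k]
        warnings.warn(
            f"dropping zero-variance {label} column(s): {dropped}", stacklevel=3
        )
    return M[:, keep], [n for n, k in zip(names, keep) if k]


def _as_matrix(M) -> tuple[np.ndarray, list[str]]:
    if isinstance(M, pd.DataFrame):
        return M.to_numpy(dtype=float), [str(c) for c in M.columns]
    M = np.asarray(M, dtype=float)
    return M, [f"f{i}" for i in range(M.shape[1])]


def fit_rcc(
    X,
    Y,
    lambda1: float = 0.0,
    lambda2: float = 0.0,
    n_components: int | None = None,
) -> RccaModel:
    """Fit regularized CCA on complete-case rows of X and Y.

    Columns are centered and scaled to unit variance before the covariance
    blocks are formed; zero-variance columns are dropped with a warning.
    The reported canonical correlations are the Pearson correlations of
    the canonical variates (non-increasing across components), with signs
    aligned so they are non-negative.
    """
    Xm, x_names = _as_matrix(X)
    Ym, y_names = _as_matrix(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y must have the same rows (subjects)")
    complete = ~(np.isnan(Xm).any(axis=1) | np.isnan(Ym).any(axis=1))
    Xm, Ym = Xm[complete], Ym[complete]
    n = Xm.shape[0]
    if n < 3:
        raise NotEstimableError(f"only {n} complete cases; need at least 3")
    Xm, x_names = _drop_constant(Xm, x_names, "X")
    Ym, y_names = _drop_constant(Ym, y_names, "Y")
    Xs, x_center, x_scale = _standardize(Xm)
    Ys, y_center, y_scale = _standardize(Ym)
    p, q = Xs.shape[1], Ys.shape[1]

    Cxx = Xs.T @ Xs / (n - 1) + lambda1 * np.eye(p)
    Cyy = Ys.T @ Ys / (n - 1) + lambda2 * np.eye(q)
    Cxy = Xs.T @ Ys / (n - 1)
    Wx = _inv_sqrt(Cxx)
    Wy = _inv_sqrt(Cyy)
    U, svals, Vt = np.linalg.svd(Wx @ Cxy @ Wy)
    k = min(p, q) if n_components is None else min(n_components, min(p, q))
    A = Wx @ U[:, :k]
    B = Wy @ Vt.T[:, :k]

    # deterministic sign convention: largest-|loading| entry of each X
    # direction is positive; Y direction flipped with it.
    for j in range(k):
        i = int(np.argmax(np.abs(A[:, j])))
        if A[i, j] < 0:
            A[:, j] *= -1
            B[:, j] *= -1
    xs = Xs @ A
    ys = Ys @ B
    cors = np.empty(k)
    for j in range(k):
        su, sv = xs[:, j].std(), ys[:, j].std()
        if su == 0 or sv == 0:
            cors[j] = 0.0
            continue
        c = float(np.corrcoef(xs[:, j], ys[:, j])[0, 1])
        if c < 0:
            B[:, j] *= -1
            ys[:, j] *= -1
            c = -c
        cors[j] = c
    return RccaModel(
        x_names=x_names,
        y_names=y_names,
        x_loadings=A,
        y_loadings=B,
        x_scores=xs,
        y_scores=ys,
        canonical_correlations=cors,
        singular_values=svals[:k].copy(),
        lambda1=float(lambda1),
        lambda2=float(lambda2),
        x_center=x_center,
        x_scale=x_scale,
        y_center=y_center,
        y_scale=y_scale,
    )


def tune_rcc(
    X,
    Y,
    grid1: np.ndarray | None = None,
    grid2: np.ndarray | None = None,
) -> tuple[float, float, pd.DataFrame]:
    """Leave-one-out grid search for the ridge penalties.

    For each (λ₁, λ₂) every subject is left out once; the first pair of
    canonical directions is fit on the remaining subjects and the held-out
    subject's standardized row (training-fold standardization) is scored
    on them. The pooled held-out (x-score, y-score) pairs across all folds
    are correlated, and the grid point with the largest pooled correlation
    is returned; ties break toward larger penalties. Degenerate folds mark
    the grid point as −inf.
    """
    Xm, _ = _as_matrix(X)
    Ym, _ = _as_matrix(Y)
    complete = ~(np.isnan(Xm).any(axis=1) | np.isnan(Ym).any(axis=1))
    Xm, Ym = Xm[complete], Ym[complete]
    n = Xm.shape[0]
    if n < 4:
        raise NotEstimableError("leave-one-out tuning needs at least 4 subjects")
    g1 = DEFAULT_GRID if grid1 is None else np.asarray(grid1, dtype=float)
    g2 = DEFAULT_GRID if grid2 is None else np.asarray(grid2, dtype=float)
    rows = []
    best = (-np.inf, -np.inf, -np.inf)  # (score, l1, l2) — ties to larger λ
    for l1 in g1:
        for l2 in g2:
            u = np.empty(n)
            v = np.empty(n)
            ok = True
            for i in range(n):
                mask = np.arange(n) != i
                try:
                    with warnings.catch_warnings():
                        warnings.simplefilter("ignore")
                        m = fit_rcc(Xm[mask], Ym[mask], l1, l2, n_components=1)
                except NotEstimableError:
                    ok = False
                    break
                xi = (Xm[i] - m.x_center) / m.x_scale
                yi = (Ym[i] - m.y_center) / m.y_scale
                u[i] = xi @ m.x_loadings[:, 0]
                v[i] = yi @ m.y_loadings[:, 0]
            if not ok or u.std() == 0 or v.std() == 0:
                score = -np.inf
            else:
                score = float(np.corrcoef(u, v)[0, 1])
            rows.append({"lambda1": l1, "lambda2": l2, "cv_cor": score})
            if (score, l1, l2) > best:
                best = (score, float(l1), float(l2))
    results = pd.DataFrame(rows)
    if not np.isfinite(best[0]):
        raise NotEstimableError("no grid point produced a finite pooled correlation")
    return best[1], best[2], results


def circle_coords(
    model: RccaModel,
    X,
    Y,
    r_outer: float = R_OUTER_DEFAULT,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Correlation-circle coordinates of every feature.

    Each feature's coordinates are its Pearson correlations with the first
    two canonical variates of its own dataset (computed on the centered and
    scaled feature). Features whose distance from the origin reaches
    ``r_outer`` are flagged as outer-ring (strongly represented by the
    first two variates). Constant features sit at the origin.
    """
    if model.n_components < 2:
        raise NotEstimableError("correlation circle needs at least 2 components")
    Xm, x_all = _as_matrix(X)
    Ym, y_all = _as_matrix(Y)
    complete_mask = ~(np.isnan(Xm).any(axis=1) | np.isnan(Ym).any(axis=1))
    out = []
    for Mm, all_names, names, scores, label in (
        (Xm, x_all, model.x_names, model.x_scores, "X"),
        (Ym, y_all, model.y_names, model.y_scores, "Y"),
    ):
        coords = []
        for name in names:
            col = Mm[complete_mask, all_names.index(name)]
            c = np.zeros(2)
            if np.std(col) > 0:
                for j in range(2):
                    if np.std(scores[:, j]) > 0:
                        c[j] = float(np.corrcoef(col, scores[:, j])[0, 1])
            radius = float(np.hypot(c[0], c[1]))
            coords.append(
                {
                    "feature": name,
                    "dataset": label,
                    "c1": float(c[0]),
                    "c2": float(c[1]),
                    "radius": radius,
                    "outer_ring": radius >= r_outer,
                }
            )
        out.append(pd.DataFrame(coords))
    return out[0], out[1]


def select_pairs(
    coords_x: pd.DataFrame,
    coords_y: pd.DataFrame,
    k: int = 10,
    outer_only: bool = True,
) -> list[SelectedPair]:
    """Top-k cross-dataset feature pairs by absolute circle inner product.

    The inner product of two features' circle coordinates,
    c1ˣ·c1ʸ + c2ˣ·c2ʸ (the product of the vectors' lengths and the cosine
    of their angle), flags candidate linear relations between the two
    datasets. By default only outer-ring features are considered.
    """
    cx = coords_x[coords_x.outer_ring] if outer_only else coords_x
    cy = coords_y[coords_y.outer_ring] if outer_only else coords_y
    if cx.empty or cy.empty:
        warnings.warn("no outer-ring features; returning no pairs", stacklevel=2)
        return []
    scored = []
    for rx in cx.itertuples():
        for ry in cy.itertuples():
            ip = rx.c1 * ry.c1 + rx.c2 * ry.c2
            scored.append((rx.feature, ry.feature, float(ip)))
    scored.sort(key=lambda t: (-abs(t[2]), t[0], t[1]))
    return [
        SelectedPair(x_feature=a, y_feature=b, inner_product=ip, rank=i + 1)
        for i, (a, b, ip) in enumerate(scored[:k])
    ]


def pairs_to_frame(pairs: list[SelectedPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "x_feature": p.x_feature,
                "y_feature": p.y_feature,
                "inner_product": p.inner_product,
                "rank": p.rank,
            }
            for p in pairs
        ],
        columns=["x_feature", "y_feature", "inner_product", "rank"],
    )
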