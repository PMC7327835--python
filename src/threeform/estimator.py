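"""Missing-data estimation stack: EM, multiple imputation, pooling, CFA.

The chain used by the simulation harness is

    incomplete table --EM--> MVN estimate --draws--> M completed tables
    --parcels--> parcel covariances --ULS fit--> per-scale factor solutions
    --Rubin pooling--> pooled estimates with standard errors

All of it assumes ignorable (here: MCAR-by-construction) missingness and a
multivariate-normal imputation model for the quasi-continuous items.
Imputations are drawn from the row-wise conditional normal given the EM
estimate (normal-model multiple imputation).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .exceptions import EstimationError, InvalidInputError, InvalidSpecError, UnderIdentifiedError

logger = logging.getLogger(__name__)

_LOG2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# EM for the multivariate normal with arbitrary missingness patterns


@dataclass
class MvnEstimate:
    """ML estimate of a multivariate normal from incomplete data."""

    columns: tuple[str, ...]
    mean: np.ndarray
    cov: np.ndarray
    loglik: float
    n_iter: int
    converged: bool
    loglik_path: np.ndarray = field(default_factory=lambda: np.empty(0))


def _pattern_groups(miss: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
    """Group row indices by their missingness pattern (True = missing)."""
    uniq, inverse = np.unique(miss, axis=0, return_inverse=True)
    inverse = np.asarray(inverse).ravel()
    return [(uniq[k], np.flatnonzero(inverse == k)) for k in range(len(uniq))]


def _chol_with_ridge(a: np.ndarray) -> tuple[np.ndarray, bool]:
    """Cholesky factor, adding a small ridge if the matrix is near-singular."""
    try:
        return linalg.cholesky(a, lower=True), False
    except linalg.LinAlgError:
        ridge = 1e-8 * max(np.trace(a) / max(len(a), 1), 1.0)
        logger.warning("singular conditioning block; adding ridge %.2e", ridge)
        return linalg.cholesky(a + ridge * np.eye(len(a)), lower=True), True


def em_mvn(
    data: pd.DataFrame,
    tol: float = 1e-6,
    max_iter: int = 500,
    start: tuple[np.ndarray, np.ndarray] | None = None,
) -> MvnEstimate:
    """Maximum-likelihood mean and covariance under ignorable missingness.

    The observed-data log-likelihood is nondecreasing across iterations;
    convergence is declared when either its relative change or the largest
    parameter change falls below ``tol``.  On complete data the first M-step
    already yields the closed-form moments (covariance with divisor ``n``),
    so the algorithm stops after two sweeps from any start.  ``start`` is an
    optional (mean, covariance) warm start.  Non-convergence within
    ``max_iter`` is flagged, not raised.
    """
    X = data.to_numpy(dtype=float)
    n, p = X.shape
    if n == 0 or p == 0:
        raise EstimationError("empty data table")
    miss = np.isnan(X)
    dead = np.flatnonzero(miss.all(axis=0))
    if dead.size:
        raise EstimationError(
            f"fully missing columns cannot be estimated: {[data.columns[j] for j in dead]}"
        )
    if n <= p:
        warnings.warn(
            f"n={n} rows <= p={p} columns; the covariance estimate may be singular",
            stacklevel=2,
        )

    groups = _pattern_groups(miss)
    if start is not None:
        mu = np.asarray(start[0], dtype=float).copy()
        cov = np.asarray(start[1], dtype=float).copy()
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mu = np.nanmean(X, axis=0)
            var0 = np.nanvar(X, axis=0)
        cov = np.diag(np.maximum(var0, 1e-8))

    ll_prev = -np.inf
    path: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        T1 = np.zeros(p)
        T2 = np.zeros((p, p))
        ll = 0.0
        for pat, rows in groups:
            o = np.flatnonzero(~pat)
            m = np.flatnonzero(pat)
            ng = rows.size
            if o.size == 0:
                # nothing observed: conditional = marginal
                T1[m] += ng * mu[m]
                T2[np.ix_(m, m)] += ng * (cov + np.outer(mu, mu))
                continue
            Xo = X[np.ix_(rows, o)]
            resid = Xo - mu[o]
            L, _ = _chol_with_ridge(cov[np.ix_(o, o)])
            half = linalg.solve_triangular(L, resid.T, lower=True)
            ll -= 0.5 * (
                ng * (o.size * _LOG2PI + 2.0 * np.log(np.diag(L)).sum())
                + np.einsum("ij,ij->", half, half)
            )
            T1[o] += Xo.sum(axis=0)
            T2[np.ix_(o, o)] += Xo.T @ Xo
            if m.size:
                beta = linalg.cho_solve((L, True), cov[np.ix_(o, m)])
                Xm = mu[m] + resid @ beta
                C = cov[np.ix_(m, m)] - cov[np.ix_(m, o)] @ beta
                T1[m] += Xm.sum(axis=0)
                cross = Xo.T @ Xm
                T2[np.ix_(o, m)] += cross
                T2[np.ix_(m, o)] += cross.T
                T2[np.ix_(m, m)] += Xm.T @ Xm + ng * C
        mu_new = T1 / n
        cov_new = T2 / n - np.outer(mu_new, mu_new)
        cov_new = 0.5 * (cov_new + cov_new.T)
        delta = max(
            np.abs(mu_new - mu).max(), np.abs(cov_new - cov).max()
        )
        mu, cov = mu_new, cov_new
        path.append(ll)
        scale = max(np.abs(cov).max(), 1.0)
        if (
            np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * (abs(ll_prev) + 1.0)
        ) or delta <= tol * scale:
            converged = True
            break
        ll_prev = ll

    return MvnEstimate(
        columns=tuple(data.columns),
        mean=mu,
        cov=cov,
        loglik=path[-1],
        n_iter=it,
        converged=converged,
        loglik_path=np.asarray(path),
    )


def draw_imputations(
    data: pd.DataFrame,
    est: MvnEstimate,
    M: int,
    rng: np.random.Generator | int | None = None,
) -> list[pd.DataFrame]:
    """Fill missing cells with conditional-normal draws given ``est``.

    For every row, missing cells are drawn from the normal distribution of
    the missing block conditional on that row's observed block (the marginal
    distribution when nothing is observed).  Observed cells are untouched.
    Returns ``M`` completed copies; with no missing cells these are ``M``
    identical copies of the input.
    """
    if M < 1:
        raise InvalidInputError("M must be at least 1")
    if tuple(data.columns) != est.columns:
        raise EstimationError("data columns do not match the MVN estimate")
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    X = data.to_numpy(dtype=float)
    miss = np.isnan(X)
    # per-pattern conditional parameters, computed once
    plans = []
    for pat, rows in _pattern_groups(miss):
        m = np.flatnonzero(pat)
        if m.size == 0:
            continue
        o = np.flatnonzero(~pat)
        if o.size:
            L, _ = _chol_with_ridge(est.cov[np.ix_(o, o)])
            beta = linalg.cho_solve((L, True), est.cov[np.ix_(o, m)])
            center = est.mean[m] + (X[np.ix_(rows, o)] - est.mean[o]) @ beta
            C = est.cov[np.ix_(m, m)] - est.cov[np.ix_(m, o)] @ beta
        else:
            center = np.broadcast_to(est.mean[m], (rows.size, m.size)).copy()
            C = est.cov[np.ix_(m, m)]
        C = 0.5 * (C + C.T)
        Lc, _ = _chol_with_ridge(C + 0.0)
        plans.append((rows, m, center, Lc))

    out = []
    for _ in range(M):
        Xi = X.copy()
        for rows, m, center, Lc in plans:
            z = rng.standard_normal((rows.size, m.size))
            Xi[np.ix_(rows, m)] = center + z @ Lc.T
        out.append(pd.DataFrame(Xi, index=data.index, columns=data.columns))
    return out


# ---------------------------------------------------------------------------
# Rubin pooling


@dataclass
class PooledEstimate:
    """Rubin-pooled estimate across M imputations (scalar or vector)."""

    estimate: np.ndarray
    within: np.ndarray
    between: np.ndarray
    se: np.ndarray
    df: np.ndarray
    m: int


def rubin_pool(
    estimates: Sequence[float] | np.ndarray,
    variances: Sequence[float] | np.ndarray,
) -> PooledEstimate:
    """Combine per-imputation estimates and variances.

    pooled point = mean of estimates; total variance = W + (1 + 1/M) B with
    W the mean within-imputation variance and B the between-imputation
    variance of the estimates (0 when M = 1).  Degrees of freedom follow the
    classic large-sample formula (infinite when B = 0).  Accepts shape (M,)
    for a single parameter or (M, K) for K parameters at once.
    """
    q = np.atleast_1d(np.asarray(estimates, dtype=float))
    u = np.atleast_1d(np.asarray(variances, dtype=float))
    if q.shape != u.shape:
        raise InvalidInputError("estimates and variances must have matching shapes")
    if q.ndim == 1:
        q = q[:, None]
        u = u[:, None]
    if q.shape[0] < 1:
        raise InvalidInputError("at least one imputation is required")
    if (u < 0).any():
        raise InvalidInputError("variances must be nonnegative")
    m = q.shape[0]
    qbar = q.mean(axis=0)
    W = u.mean(axis=0)
    B = q.var(axis=0, ddof=1) if m > 1 else np.zeros_like(qbar)
    T = W + (1.0 + 1.0 / m) * B
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = (1.0 + 1.0 / m) * B
        df = np.where(rel > 0, (m - 1) * (1.0 + W / np.where(rel > 0, rel, 1.0)) ** 2, np.inf)
    return PooledEstimate(
        estimate=qbar, within=W, between=B, se=np.sqrt(T), df=df, m=m
    )


# ---------------------------------------------------------------------------
# Parcels


def round_robin_parcels(items: Sequence[str], n_parcels: int = 3) -> list[list[str]]:
    """Deal items into parcels round-robin; sizes differ by at most one."""
    groups: list[list[str]] = [[] for _ in range(n_parcels)]
    for k, it in enumerate(items):
        groups[k % n_parcels].append(it)
    return groups


def build_parcels(
    data: pd.DataFrame,
    parcel_map: Mapping[str, Sequence[Sequence[str]]],
) -> pd.DataFrame:
    """Average item groups into parcel scores (three parcels per scale).

    Parcels are meant to be computed on completed (post-imputation) data, so
    the constituent items are complete; the parcel score is the plain mean of
    its items.  Columns are named ``<scale>_p1 .. _p3``.
    """
    cols: dict[str, pd.Series] = {}
    for scale_id, groups in parcel_map.items():
        if len(groups) != 3:
            raise InvalidSpecError(
                f"scale {scale_id!r} must be partitioned into exactly three parcels"
            )
        for k, group in enumerate(groups, start=1):
            if len(group) == 0:
                raise InvalidSpecError(f"scale {scale_id!r} parcel {k} has no items")
            missing = [it for it in group if it not in data.columns]
            if missing:
                raise InvalidSpecError(f"parcel items not in data: {missing}")
            cols[f"{scale_id}_p{k}"] = data[list(group)].mean(axis=1)
    return pd.DataFrame(cols, index=data.index)


# ---------------------------------------------------------------------------
# One-factor model (ULS on the covariance, fixed-factor identification)


@dataclass
class FactorSolution:
    """A fitted one-factor model with the latent variance fixed to 1.

    ``admissible`` is False for Heywood cases (a negative fitted residual
    variance); the raw negative value is retained for diagnosis.
    """

    loadings: np.ndarray
    residual_variances: np.ndarray
    latent_variance: float = 1.0
    admissible: bool = True
    converged: bool = True
    n_iter: int = 0

    @property
    def implied_cov(self) -> np.ndarray:
        return np.outer(self.loadings, self.loadings) + np.diag(self.residual_variances)


def _triad_solution(S: np.ndarray) -> tuple[np.ndarray, np.ndarray] | None:
    """Closed-form fit for three indicators (exact ULS minimizer when valid)."""
    s12, s13, s23 = S[0, 1], S[0, 2], S[1, 2]
    if abs(s23) < 1e-12:
        return None
    t = s12 * s13 / s23
    if t <= 0:
        return None
    lam1 = np.sqrt(t)
    lam = np.array([lam1, s12 / lam1, s13 / lam1])
    theta = np.diag(S) - lam**2
    return lam, theta


def fit_one_factor(
    cov: np.ndarray | pd.DataFrame,
    max_iter: int = 500,
    gtol: float = 1e-10,
) -> FactorSolution:
    """Unweighted-least-squares one-factor fit to a covariance matrix.

    Minimizes ``0.5 * || S - lambda lambda' - diag(theta) ||_F^2`` with the
    latent variance fixed to 1 and the first loading constrained nonnegative
    by sign flip.  For exactly three indicators (a just-identified model)
    the closed-form triad solution is used when its products are positive;
    otherwise L-BFGS from a principal-component start.  Residual variances
    are left unconstrained so Heywood cases surface as ``admissible=False``.
    """
    S = np.asarray(cov, dtype=float)
    if S.ndim != 2 or S.shape[0] != S.shape[1]:
        raise InvalidInputError("covariance must be square")
    p = S.shape[0]
    if p < 3:
        raise UnderIdentifiedError(
            f"a one-factor model needs at least 3 indicators, got {p}"
        )
    S = 0.5 * (S + S.T)

    if p == 3:
        triad = _triad_solution(S)
        if triad is not None:
            lam, theta = triad
            return FactorSolution(
                loadings=lam,
                residual_variances=theta,
                admissible=bool((theta >= -1e-10).all()),
                converged=True,
                n_iter=0,
            )

    evals, evecs = linalg.eigh(S)
    lam0 = evecs[:, -1] * np.sqrt(max(evals[-1], 1e-12))
    if lam0[0] < 0:
        lam0 = -lam0
    theta0 = np.maximum(np.diag(S) - lam0**2, 1e-6)

    def objective(x: np.ndarray) -> tuple[float, np.ndarray]:
        lam, theta = x[:p], x[p:]
        R = S - np.outer(lam, lam) - np.diag(theta)
        f = 0.5 * float((R**2).sum())
        grad = np.concatenate([-2.0 * R @ lam, -np.diag(R)])
        return f, grad

    res = optimize.minimize(
        objective,
        np.concatenate([lam0, theta0]),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": max_iter, "gtol": gtol, "ftol": 1e-14},
    )
    lam, theta = res.x[:p], res.x[p:]
    if lam[0] < 0:
        lam = -lam
    return FactorSolution(
        loadings=lam,
        residual_variances=theta,
        admissible=bool((theta >= -1e-10).all()),
        converged=bool(res.success),
        n_iter=int(res.nit),
    )


# ---------------------------------------------------------------------------
# Multi-scale parcel CFA with normal-theory delta-method standard errors


def vech(S: np.ndarray) -> np.ndarray:
    """Lower-triangular half-vectorization (row-major over i >= j pairs)."""
    p = S.shape[0]
    idx = np.tril_indices(p)
    return S[idx]


def unvech(v: np.ndarray, p: int) -> np.ndarray:
    S = np.zeros((p, p))
    idx = np.tril_indices(p)
    S[idx] = v
    S = S + S.T - np.diag(np.diag(S))
    return S


def _dup_pinv(p: int) -> np.ndarray:
    """Moore-Penrose inverse of the duplication matrix: vech = D+ vec."""
    rows = p * (p + 1) // 2
    Dp = np.zeros((rows, p * p))
    r = 0
    for i in range(p):
        for j in range(i + 1):
            if i == j:
                Dp[r, i * p + i] = 1.0
            else:
                Dp[r, i * p + j] = 0.5
                Dp[r, j * p + i] = 0.5
            r += 1
    return Dp


def normal_theory_acov_vech(S: np.ndarray, n: int) -> np.ndarray:
    """Asymptotic covariance of vech(sample covariance) under normality."""
    Dp = _dup_pinv(S.shape[0])
    return (2.0 / n) * Dp @ np.kron(S, S) @ Dp.T


@dataclass
class CfaFit:
    """Per-scale one-factor fits plus method-of-moments latent correlations."""

    estimates: dict[str, float]
    variances: dict[str, float]
    admissible: bool
    converged: bool


def _cfa_params(
    S: np.ndarray, scale_slices: list[tuple[str, np.ndarray]]
) -> tuple[np.ndarray, list[str], bool, bool]:
    """Loadings, residuals, and latent correlations from a parcel covariance."""
    values: list[float] = []
    names: list[str] = []
    lam_by_scale: dict[str, np.ndarray] = {}
    idx_by_scale: dict[str, np.ndarray] = {}
    admissible = True
    converged = True
    for scale_id, idx in scale_slices:
        sol = fit_one_factor(S[np.ix_(idx, idx)])
        admissible &= sol.admissible
        converged &= sol.converged
        lam_by_scale[scale_id] = sol.loadings
        idx_by_scale[scale_id] = idx
        for k in range(len(idx)):
            names.append(f"loading[{scale_id},p{k + 1}]")
            values.append(float(sol.loadings[k]))
        for k in range(len(idx)):
            names.append(f"residual[{scale_id},p{k + 1}]")
            values.append(float(sol.residual_variances[k]))
    scale_ids = [sid for sid, _ in scale_slices]
    for a in range(len(scale_ids)):
        for b in range(a + 1, len(scale_ids)):
            sa, sb = scale_ids[a], scale_ids[b]
            la, lb = lam_by_scale[sa], lam_by_scale[sb]
            cross = S[np.ix_(idx_by_scale[sa], idx_by_scale[sb])]
            denom = np.outer(la, lb)
            ok = np.abs(denom) > 1e-8
            phi = float(np.mean(cross[ok] / denom[ok])) if ok.any() else np.nan
            names.append(f"latcor[{sa},{sb}]")
            values.append(phi)
    return np.asarray(values), names, admissible, converged


def _cfa_params_batch(
    Sb: np.ndarray, scale_slices: list[tuple[str, np.ndarray]]
) -> np.ndarray | None:
    """Vectorized closed-form parameter map over a batch of covariances.

    Only valid when every scale has exactly three parcels and every triad
    product is positive throughout the batch; returns None otherwise so the
    caller can fall back to the per-matrix fit.  Output order matches
    :func:`_cfa_params`.
    """
    pieces: list[np.ndarray] = []
    lam_by_scale: dict[str, np.ndarray] = {}
    for scale_id, idx in scale_slices:
        if len(idx) != 3:
            return None
        s12 = Sb[:, idx[0], idx[1]]
        s13 = Sb[:, idx[0], idx[2]]
        s23 = Sb[:, idx[1], idx[2]]
        if (np.abs(s23) < 1e-12).any():
            return None
        t = s12 * s13 / s23
        if (t <= 0).any():
            return None
        l1 = np.sqrt(t)
        lam = np.stack([l1, s12 / l1, s13 / l1], axis=1)  # (B, 3)
        diag = Sb[:, idx, idx]
        pieces.append(lam)
        pieces.append(diag - lam**2)
        lam_by_scale[scale_id] = lam
    scale_ids = [sid for sid, _ in scale_slices]
    idx_by_scale = dict(scale_slices)
    for a in range(len(scale_ids)):
        for b in range(a + 1, len(scale_ids)):
            sa, sb = scale_ids[a], scale_ids[b]
            cross = Sb[:, idx_by_scale[sa]][:, :, idx_by_scale[sb]]  # (B, 3, 3)
            denom = lam_by_scale[sa][:, :, None] * lam_by_scale[sb][:, None, :]
            phi = (cross / denom).mean(axis=(1, 2))
            pieces.append(phi[:, None])
    return np.concatenate(pieces, axis=1)


def fit_parcel_cfa(
    parcel_cov: pd.DataFrame,
    n: int,
    parcel_cols_by_scale: Mapping[str, Sequence[str]],
) -> CfaFit:
    """Fit the analysis model to a parcel covariance matrix.

    Each scale gets a one-factor model over its three parcels (fixed-factor
    identification, ULS); latent correlations between scales are recovered
    from the cross-scale parcel covariances via
    ``phi = mean_ab s_ab / (lambda_a lambda_b)``.  Standard errors come from
    the normal-theory delta method: the asymptotic covariance of vech(S) is
    propagated through the (closed-form / ULS) parameter map by central
    finite differences (vectorized when the closed-form triad applies).
    """
    cols = list(parcel_cov.columns)
    S = parcel_cov.to_numpy(dtype=float)
    scale_slices = [
        (sid, np.asarray([cols.index(c) for c in pcols]))
        for sid, pcols in parcel_cols_by_scale.items()
    ]

    values, names, admissible, converged = _cfa_params(S, scale_slices)

    p = S.shape[0]
    s0 = vech(S)
    nv = len(s0)
    Gamma = normal_theory_acov_vech(S, n)
    steps = 1e-6 * (1.0 + np.abs(s0))

    # batch: [+h_1, -h_1, +h_2, -h_2, ...]
    Sb = np.empty((2 * nv, p, p))
    for k in range(nv):
        sp = s0.copy()
        sp[k] += steps[k]
        Sb[2 * k] = unvech(sp, p)
        sm = s0.copy()
        sm[k] -= steps[k]
        Sb[2 * k + 1] = unvech(sm, p)

    batch = _cfa_params_batch(Sb, scale_slices)
    if batch is not None:
        G = (batch[0::2] - batch[1::2]).T / (2.0 * steps)
    else:
        G = np.empty((len(values), nv))
        for k in range(nv):
            vp, _, _, _ = _cfa_params(Sb[2 * k], scale_slices)
            vm, _, _, _ = _cfa_params(Sb[2 * k + 1], scale_slices)
            G[:, k] = (vp - vm) / (2.0 * steps[k])
    var = np.einsum("ik,kl,il->i", G, Gamma, G)
    var = np.maximum(var, 0.0)

    return CfaFit(
        estimates=dict(zip(names, values.tolist())),
        variances=dict(zip(names, var.tolist())),
        admissible=admissible,
        converged=converged,
    )
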