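"""Polychoric and polyserial correlation estimation.

Two-step maximum likelihood throughout: item thresholds are fixed at their
marginal estimates (inverse normal CDF of cumulative proportions) and the
latent correlation of each pair is then estimated by maximizing the
bivariate-normal cell-probability likelihood.  The polychoric step is
vectorized over all item pairs (safeguarded Newton on the score function with
an analytic derivative of the cell probabilities); the diagonal
asymptotic-variance weights used by the DWLS fitter come from the inverse of
the per-pair observed information.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri

from ._bvn import bvn_cdf, bvn_pdf
from .datagen import SampleData

RHO_BOUND = 0.999
_PROB_FLOOR = 1e-12


class DegenerateItemError(ValueError):
    """Raised when a column shows fewer than two response categories."""


@dataclass
class MixedCorrMatrix:
    """Polychoric/polyserial correlation matrix with estimation metadata.

    ``corr`` is (k+1)x(k+1) with items first and the continuous criterion last
    (or k x k when no criterion is present).  ``asym_var`` holds the asymptotic
    variances of sqrt(n) times each non-redundant correlation, ordered as all
    item pairs (i<j, row-major) followed by the item-criterion column.
    """

    corr: np.ndarray
    thresholds_hat: np.ndarray
    asym_var: np.ndarray
    n: int
    has_criterion: bool = True
    repaired: bool = False
    nonconverged_pairs: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return self.thresholds_hat.shape[0]


def estimate_thresholds(col: np.ndarray, n_categories: int = 4) -> np.ndarray:
    """Marginal thresholds: tau_j = Phi^-1(prop of categories <= j).

    Empty boundary categories yield -inf/+inf thresholds, which downstream
    likelihoods treat as absent cells.
    """
    col = np.asarray(col, dtype=int)
    counts = np.bincount(col, minlength=n_categories + 1)[1:]
    if np.count_nonzero(counts) < 2:
        raise DegenerateItemError("item shows a single response category")
    cum = np.cumsum(counts)[:-1] / col.size
    with np.errstate(divide="ignore"):
        return ndtri(cum)


def _cell_probs_and_grad(tau_x, tau_y, rho):
    """Bivariate-normal cell probabilities and their derivative wrt rho.

    ``tau_x``/``tau_y`` are (..., 3) threshold arrays; returns (..., 4, 4)
    probability and gradient arrays.  dP/drho is the rectangle combination of
    the bivariate density at the cell corners (Plackett's identity).
    """
    big = np.full(tau_x.shape[:-1] + (1,), 9.0)
    ax = np.concatenate([-big, np.clip(tau_x, -9, 9), big], axis=-1)  # (...,5)
    by = np.concatenate([-big, np.clip(tau_y, -9, 9), big], axis=-1)
    A = ax[..., :, None]
    B = by[..., None, :]
    R = rho[..., None, None] if np.ndim(rho) else rho
    F = bvn_cdf(A, B, R)
    G = bvn_pdf(A, B, R)
    P = F[..., 1:, 1:] - F[..., :-1, 1:] - F[..., 1:, :-1] + F[..., :-1, :-1]
    dP = G[..., 1:, 1:] - G[..., :-1, 1:] - G[..., 1:, :-1] + G[..., :-1, :-1]
    return np.clip(P, 0.0, 1.0), dP


def _score(tables, tau_x, tau_y, rho):
    P, dP = _cell_probs_and_grad(tau_x, tau_y, rho)
    return np.sum(tables * dP / np.maximum(P, _PROB_FLOOR), axis=(-2, -1))


def _nll_pair(table, tau_x, tau_y, rho):
    P, _ = _cell_probs_and_grad(tau_x, tau_y, np.asarray(rho))
    return -np.sum(table * np.log(np.maximum(P, _PROB_FLOOR)))


def _start_values(tables):
    """Pearson correlation of the category scores, mildly disattenuated."""
    t = tables.astype(float)
    n = t.sum(axis=(-2, -1), keepdims=True)
    p = t / n
    c = np.arange(1.0, 5.0)
    mx = np.einsum("...ab,a->...", p, c)
    my = np.einsum("...ab,b->...", p, c)
    vx = np.einsum("...ab,a->...", p, c**2) - mx**2
    vy = np.einsum("...ab,b->...", p, c**2) - my**2
    cxy = np.einsum("...ab,a,b->...", p, c, c) - mx * my
    r = cxy / np.sqrt(np.maximum(vx * vy, 1e-12))
    return np.clip(1.15 * r, -0.9, 0.9)


def _polychoric_newton(tables, tau_x, tau_y, max_iter=50, tol=1e-8):
    """Vectorized safeguarded Newton on the score function, all pairs at once."""
    rho = _start_values(tables)
    active = np.ones(rho.shape, dtype=bool)
    delta = 5e-5
    for _ in range(max_iter):
        idx = np.flatnonzero(active)
        if idx.size == 0:
            break
        r = rho[idx]
        s0 = _score(tables[idx], tau_x[idx], tau_y[idx], r)
        sp = _score(tables[idx], tau_x[idx], tau_y[idx], np.clip(r + delta, -RHO_BOUND, RHO_BOUND))
        sm = _score(tables[idx], tau_x[idx], tau_y[idx], np.clip(r - delta, -RHO_BOUND, RHO_BOUND))
        d = (sp - sm) / (2 * delta)
        step = np.where(d < -1e-12, -s0 / np.minimum(d, -1e-12), np.sign(s0) * 0.1)
        step = np.clip(step, -0.3, 0.3)
        new = np.clip(r + step, -RHO_BOUND, RHO_BOUND)
        moved = np.abs(new - r)
        rho[idx] = new
        # boundary with outward-pointing score counts as converged (rho -> +/-1)
        at_hi = (new >= RHO_BOUND) & (s0 > 0)
        at_lo = (new <= -RHO_BOUND) & (s0 < 0)
        done = (moved < tol) | at_hi | at_lo
        active[idx[done]] = False
    return rho, active  # active==True marks non-converged pairs


def _pair_fallback(table, tau_x, tau_y):
    res = minimize_scalar(
        lambda r: _nll_pair(table, tau_x, tau_y, r),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    return float(res.x)


def _pair_info(tables, tau_x, tau_y, rho):
    """Per-observation Fisher information at the estimate (model cell probs)."""
    P, dP = _cell_probs_and_grad(tau_x, tau_y, rho)
    return np.sum(dP * dP / np.maximum(P, _PROB_FLOOR), axis=(-2, -1))


def polychoric_corr(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-step ML polychoric correlation of two ordinal vectors.

    Returns ``(rho_hat, asym_var)`` where ``asym_var`` is the asymptotic
    variance of sqrt(n) * rho_hat from the inverse observed information.
    """
    x = np.asarray(x, dtype=int)
    y = np.asarray(y, dtype=int)
    tau_x = estimate_thresholds(x)
    tau_y = estimate_thresholds(y)
    table = np.bincount(4 * (x - 1) + (y - 1), minlength=16).reshape(4, 4)
    tables = table[None].astype(float)
    txa, tya = tau_x[None], tau_y[None]
    rho, nonconv = _polychoric_newton(tables, txa, tya)
    if nonconv[0]:
        rho[0] = _pair_fallback(table, tau_x, tau_y)
    info = _pair_info(tables, txa, tya, rho)[0]
    avar = 1.0 / max(info, 1e-10)
    return float(rho[0]), float(avar)


def _polyserial_nll(rho, z, y, tau):
    s = np.sqrt(max(1.0 - rho * rho, 1e-10))
    aug = np.concatenate([[-np.inf], np.clip(tau, -9, 9), [np.inf]])
    hi = (aug[y] - rho * z) / s
    lo = (aug[y - 1] - rho * z) / s
    p = ndtr(hi) - ndtr(lo)
    return -np.sum(np.log(np.maximum(p, _PROB_FLOOR)))


def polyserial_corr(z: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-step ML polyserial correlation of a continuous and an ordinal vector."""
    z = np.asarray(z, dtype=float)
    if np.std(z) < 1e-12:
        raise DegenerateItemError("continuous variable is constant")
    z = (z - z.mean()) / z.std()
    y = np.asarray(y, dtype=int)
    tau = estimate_thresholds(y)
    res = minimize_scalar(
        lambda r: _polyserial_nll(r, z, y, tau),
        bounds=(-RHO_BOUND, RHO_BOUND),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    h = 1e-4
    d2 = (
        _polyserial_nll(min(rho + h, RHO_BOUND), z, y, tau)
        - 2 * _polyserial_nll(rho, z, y, tau)
        + _polyserial_nll(max(rho - h, -RHO_BOUND), z, y, tau)
    ) / h**2
    avar = z.size / max(d2, 1e-10)  # avar of sqrt(n) rho_hat
    return rho, float(avar)


def influence_matrix(data: SampleData, M: MixedCorrMatrix) -> np.ndarray:
    """Per-observation influence functions of the estimated correlations.

    Returns an (n x P) matrix whose column p is the influence function of
    sqrt(n) times correlation p (item pairs first, then the polyserial
    column), evaluated at the estimates: score contribution divided by the
    per-observation information.  Its empirical second-moment matrix
    estimates the asymptotic covariance of the correlation vector, which the
    robust (scaled-and-shifted) test statistic needs.
    """
    resp = data.responses
    n, k = resp.shape
    taus = M.thresholds_hat
    iu, ju = np.triu_indices(k, 1)
    rho = M.corr[iu, ju]
    P, dP = _cell_probs_and_grad(taus[iu], taus[ju], rho)
    ratio = dP / np.maximum(P, _PROB_FLOOR)
    info = np.sum(dP * dP / np.maximum(P, _PROB_FLOOR), axis=(-2, -1))
    psi_tab = ratio / np.maximum(info, 1e-10)[:, None, None]  # (P,4,4)
    npair = iu.size
    cols = [psi_tab[np.arange(npair)[None, :], resp[:, iu] - 1, resp[:, ju] - 1]]
    if M.has_criterion:
        z = data.criterion
        z = (z - z.mean()) / z.std()
        sqrt2pi = np.sqrt(2 * np.pi)
        psl = np.empty((n, k))
        for j in range(k):
            r = M.corr[j, k]
            s = np.sqrt(max(1.0 - r * r, 1e-10))
            aug = np.concatenate([[-np.inf], np.clip(taus[j], -9, 9), [np.inf]])
            y = resp[:, j]
            hi = (aug[y] - r * z) / s
            lo = (aug[y - 1] - r * z) / s
            p = np.maximum(ndtr(hi) - ndtr(lo), _PROB_FLOOR)
            fin_hi, fin_lo = np.isfinite(hi), np.isfinite(lo)
            phi_hi = np.where(fin_hi, np.exp(-np.minimum(hi, 40) ** 2 / 2) / sqrt2pi, 0.0)
            phi_lo = np.where(fin_lo, np.exp(-np.minimum(lo, 40) ** 2 / 2) / sqrt2pi, 0.0)
            dhi = (-z + r * np.where(fin_hi, hi, 0.0)) / s
            dlo = (-z + r * np.where(fin_lo, lo, 0.0)) / s
            sc = (phi_hi * dhi - phi_lo * dlo) / p
            psl[:, j] = sc / max(np.mean(sc**2), 1e-10)
        cols.append(psl)
    return np.concatenate(cols, axis=1)


def pair_index(k: int, has_criterion: bool = True):
    """Row/column indices of the non-redundant moments, in weight order."""
    iu = np.triu_indices(k, 1)
    rows, cols = list(iu[0]), list(iu[1])
    if has_criterion:
        rows += list(range(k))
        cols += [k] * k
    return np.array(rows), np.array(cols)


def nearest_pd_repair(corr: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Eigenvalue clipping followed by re-normalization to unit diagonal."""
    w, v = np.linalg.eigh(corr)
    w = np.maximum(w, eps)
    r = (v * w) @ v.T
    d = np.sqrt(np.diag(r))
    r = r / np.outer(d, d)
    np.fill_diagonal(r, 1.0)
    return r


def build_mixed_matrix(data: SampleData, include_criterion: bool = True) -> MixedCorrMatrix:
    """Assemble the full polychoric (+ polyserial) correlation matrix.

    All item pairs are estimated simultaneously by the vectorized Newton
    solver; pairs it cannot settle fall back to a bounded 1-D likelihood
    search and are recorded in ``nonconverged_pairs``.
    """
    resp = data.responses
    n, k = resp.shape
    taus = np.stack([estimate_thresholds(resp[:, j]) for j in range(k)])

    onehot = np.zeros((n, k * 4))
    onehot[np.arange(n)[:, None], np.arange(k) * 4 + (resp - 1)] = 1.0
    big = (onehot.T @ onehot).reshape(k, 4, k, 4)

    iu, ju = np.triu_indices(k, 1)
    tables = big[iu, :, ju, :]  # (P,4,4)
    tau_x, tau_y = taus[iu], taus[ju]
    rho, nonconv = _polychoric_newton(tables, tau_x, tau_y)
    bad = np.flatnonzero(nonconv)
    for b in bad:
        rho[b] = _pair_fallback(tables[b], tau_x[b], tau_y[b])
    info = _pair_info(tables, tau_x, tau_y, rho)
    avar_items = 1.0 / np.maximum(info, 1e-10)

    size = k + 1 if include_criterion else k
    corr = np.eye(size)
    corr[iu, ju] = corr[ju, iu] = rho

    avar = [avar_items]
    if include_criterion:
        ps = np.empty(k)
        ps_avar = np.empty(k)
        for j in range(k):
            ps[j], ps_avar[j] = polyserial_corr(data.criterion, resp[:, j])
        corr[:k, k] = corr[k, :k] = ps
        avar.append(ps_avar)
    avar = np.concatenate(avar)

    repaired = False
    if np.linalg.eigvalsh(corr)[0] < 1e-6:
        corr = nearest_pd_repair(corr)
        repaired = True

    return MixedCorrMatrix(
        corr=corr,
        thresholds_hat=taus,
        asym_var=avar,
        n=n,
        has_criterion=include_criterion,
        repaired=repaired,
        nonconverged_pairs=[(int(iu[b]), int(ju[b])) for b in bad],
    )
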