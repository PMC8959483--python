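"""Cox proportional-hazards fitting and per-radius interaction maps.

The solver maximises the Efron-tie-corrected partial likelihood by
Newton iteration with step halving.  It is deliberately lightweight: an
interaction map evaluates thousands of small nested model pairs, which
rules out heavier general-purpose fitters in the inner loop (those are
used as cross-checks in the test suite instead).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .curves import SummaryCurve

__all__ = [
    "CoxFit",
    "filter_covariates",
    "fit_cox",
    "lr_test",
    "InteractionMap",
    "interaction_map",
]


class CoxError(ValueError):
    """Raised for degenerate or non-converged partial-likelihood fits."""


@dataclass(frozen=True)
class CoxFit:
    """A fitted proportional-hazards model."""

    names: tuple[str, ...]
    coefs: np.ndarray
    se: np.ndarray
    cov: np.ndarray
    log_likelihood: float
    log_likelihood_null: float
    c_index: float | None
    n: int
    n_events: int
    converged: bool

    def coef(self, name: str) -> float:
        return float(self.coefs[self.names.index(name)])

    def var(self, name: str) -> float:
        i = self.names.index(name)
        return float(self.cov[i, i])

    def covariance(self, name_a: str, name_b: str) -> float:
        i, j = self.names.index(name_a), self.names.index(name_b)
        return float(self.cov[i, j])

    @property
    def summary(self) -> pd.DataFrame:
        z = np.divide(
            self.coefs, self.se, out=np.zeros_like(self.coefs), where=self.se > 0
        )
        return pd.DataFrame(
            {
                "coef": self.coefs,
                "se": self.se,
                "z": z,
                "p": 2.0 * chi2.sf(z**2, 1),
            },
            index=list(self.names),
        )


def _efron_ll_grad_hess(
    beta: np.ndarray,
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    need_grad: bool = True,
):
    """Efron partial log-likelihood with optional gradient and Hessian.

    Assumes rows sorted by ascending time.  Untied event times take a
    fully vectorised path; tied groups fall back to a per-group loop.
    """
    n, p = x.shape
    eta = x @ beta if p else np.zeros(n)
    eta = np.clip(eta, -500, 500)
    theta = np.exp(eta)

    # suffix sums over the risk set (time ascending -> risk set is a suffix)
    s0 = np.cumsum(theta[::-1])[::-1]
    if p and need_grad:
        xt = x * theta[:, None]
        s1 = np.cumsum(xt[::-1], axis=0)[::-1]
        x2t = xt[:, :, None] * x[:, None, :]
        s2 = np.cumsum(x2t[::-1], axis=0)[::-1]

    ev_idx = np.flatnonzero(event)
    if ev_idx.size == 0:
        raise CoxError("no events in the data")
    ev_times = time[ev_idx]
    starts = np.flatnonzero(np.r_[True, np.diff(ev_times) != 0])
    ends = np.r_[starts[1:], ev_times.size]
    sizes = ends - starts
    firsts = np.searchsorted(time, ev_times[starts], side="left")

    ll = 0.0
    grad = np.zeros(p)
    hess = np.zeros((p, p))

    single = sizes == 1
    if single.any():
        ds = ev_idx[starts[single]]
        f = firsts[single]
        denoms = s0[f]
        ll += float(eta[ds].sum() - np.log(denoms).sum())
        if p and need_grad:
            r1 = s1[f] / denoms[:, None]
            grad += x[ds].sum(axis=0) - r1.sum(axis=0)
            hess -= (s2[f] / denoms[:, None, None]).sum(axis=0)
            hess += np.einsum("ij,ik->jk", r1, r1)

    for gi in np.flatnonzero(~single):
        deaths = ev_idx[starts[gi] : ends[gi]]
        first = firsts[gi]
        d = int(sizes[gi])
        fracs = np.arange(d) / d
        s0_tie = theta[deaths].sum()
        denoms = s0[first] - fracs * s0_tie
        ll += float(eta[deaths].sum() - np.log(denoms).sum())
        if p and need_grad:
            s1_tie = xt[deaths].sum(axis=0)
            s2_tie = x2t[deaths].sum(axis=0)
            z1 = s1[first][None, :] - fracs[:, None] * s1_tie[None, :]
            z2 = s2[first][None, :, :] - fracs[:, None, None] * s2_tie[None, :, :]
            r1 = z1 / denoms[:, None]
            grad += x[deaths].sum(axis=0) - r1.sum(axis=0)
            hess -= (
                z2 / denoms[:, None, None] - r1[:, :, None] * r1[:, None, :]
            ).sum(axis=0)
    return ll, grad, hess


def _newton_cox(
    x: np.ndarray,
    time: np.ndarray,
    event: np.ndarray,
    max_iter: int = 60,
    tol: float = 1e-9,
):
    """Newton-Raphson maximisation with step halving; returns (beta, cov, ll, ll0)."""
    order = np.argsort(time, kind="stable")
    x = np.ascontiguousarray(x[order], dtype=float)
    time = np.asarray(time, dtype=float)[order]
    event = np.asarray(event, dtype=bool)[order]
    n, p = x.shape

    ll0, _, _ = _efron_ll_grad_hess(np.zeros(p), x, time, event)
    beta = np.zeros(p)
    if p == 0:
        return beta, np.zeros((0, 0)), ll0, ll0, True

    ll = ll0
    hess = None
    converged = False
    for _ in range(max_iter):
        _, grad, hess = _efron_ll_grad_hess(beta, x, time, event)
        info = -hess
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError as err:
            raise CoxError(f"singular information matrix: {err}") from err
        new_beta = beta + step
        new_ll, _, _ = _efron_ll_grad_hess(new_beta, x, time, event, need_grad=False)
        halvings = 0
        while (not np.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 25:
            step *= 0.5
            new_beta = beta + step
            new_ll, _, _ = _efron_ll_grad_hess(
                new_beta, x, time, event, need_grad=False
            )
            halvings += 1
        delta = abs(new_ll - ll)
        beta, ll = new_beta, new_ll
        if delta < tol * (abs(ll) + 1.0):
            converged = True
            break
    _, _, hess = _efron_ll_grad_hess(beta, x, time, event)
    try:
        cov = np.linalg.inv(-hess)
    except np.linalg.LinAlgError as err:
        raise CoxError(f"singular information matrix at optimum: {err}") from err
    if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 1e3:
        raise CoxError("fit diverged (possible monotone likelihood)")
    return beta, cov, ll, ll0, converged


def concordance_index(
    time: np.ndarray, risk: np.ndarray, event: np.ndarray
) -> float:
    """Harrell's C for higher-risk-fails-earlier (0.5 for a null model).

    Pairs are comparable when the earlier time is an event (or at a
    shared time exactly one is an event); tied risks count half.
    """
    time = np.asarray(time, dtype=float)
    risk = np.asarray(risk, dtype=float)
    event = np.asarray(event, dtype=bool)
    ti, tj = time[:, None], time[None, :]
    comparable = ((ti < tj) & event[:, None]) | (
        (ti == tj) & event[:, None] & ~event[None, :]
    )
    ri, rj = risk[:, None], risk[None, :]
    n_comp = comparable.sum()
    if n_comp == 0:
        return float("nan")
    conc = ((ri > rj) & comparable).sum()
    tied = ((ri == rj) & comparable).sum()
    return float((conc + 0.5 * tied) / n_comp)


def filter_covariates(
    table: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    availability_threshold: float = 0.90,
) -> tuple[list[str], pd.DataFrame]:
    """Availability screen then complete-case filtering.

    Covariates available for at most ``availability_threshold`` of
    patients are dropped entirely; remaining rows with any missing kept
    covariate (or missing time/event) are removed.
    """
    kept = [
        c
        for c in covariates
        if table[c].notna().mean() > availability_threshold
    ]
    cols = [duration_col, event_col, *kept]
    out = table.loc[table[cols].notna().all(axis=1)].copy()
    if len(out) == 0:
        raise ValueError("no patients remain after complete-case filtering")
    return kept, out


def fit_cox(
    table: pd.DataFrame,
    covariates: Sequence[str],
    duration_col: str = "time",
    event_col: str = "event",
    compute_c_index: bool = True,
) -> CoxFit:
    """Maximum Efron partial-likelihood fit with Harrell's C on fitted risks.

    An empty covariate list fits the null model (C-index 0.5 by
    convention).  Raises :class:`CoxError` on zero events or a singular
    design (naming the collinear terms).
    """
    time = np.asarray(table[duration_col], dtype=float)
    event = np.asarray(table[event_col], dtype=bool)
    if np.any(~np.isfinite(time)) or np.any(time <= 0):
        raise CoxError("durations must be positive and finite")
    if event.sum() == 0:
        raise CoxError("no events in the data")

    names = tuple(covariates)
    x = np.column_stack([np.asarray(table[c], dtype=float) for c in names]) if names else np.zeros((len(table), 0))
    if not np.all(np.isfinite(x)):
        raise CoxError("design matrix contains missing or non-finite values")
    if x.shape[1]:
        xc = x - x.mean(axis=0)
        rank = np.linalg.matrix_rank(xc)
        if rank < x.shape[1]:
            sd = xc.std(axis=0)
            flat = [n for n, s in zip(names, sd) if s == 0]
            detail = f" constant terms: {flat}" if flat else f" among {list(names)}"
            raise CoxError("singular design matrix;" + detail)

    beta, cov, ll, ll0, converged = _newton_cox(x, time, event)
    se = np.sqrt(np.diag(cov)) if beta.size else np.zeros(0)
    if beta.size == 0:
        c_index = 0.5 if compute_c_index else None
    elif compute_c_index:
        c_index = concordance_index(time, x @ beta, event)
    else:
        c_index = None
    return CoxFit(
        names=names,
        coefs=beta,
        se=se,
        cov=cov,
        log_likelihood=ll,
        log_likelihood_null=ll0,
        c_index=c_index,
        n=len(table),
        n_events=int(event.sum()),
        converged=converged,
    )


def lr_test(full: CoxFit, reduced: CoxFit, df: int | None = None) -> float:
    """Likelihood-ratio p-value for nested fits (chi-squared upper tail)."""
    if df is None:
        df = len(full.names) - len(reduced.names)
    if df < 1:
        raise ValueError("full model must have more parameters than reduced")
    stat = 2.0 * (full.log_likelihood - reduced.log_likelihood)
    if stat < -1e-6:
        raise CoxError("non-nested or non-converged models (ll_full < ll_reduced)")
    p = float(chi2.sf(max(stat, 0.0), df))
    return max(p, np.finfo(float).tiny)


@dataclass(frozen=True)
class InteractionMap:
    """LR-test p-values over (density annulus, dose annulus) pairs."""

    p_values: np.ndarray  # (n_density, n_dose)
    n_used: np.ndarray
    n_events_used: np.ndarray
    metric_pair: tuple[str, str]
    density_window_cm: tuple[float, float]
    dose_window_cm: tuple[float, float]

    @property
    def shape(self) -> tuple[int, int]:
        return self.p_values.shape

    @property
    def n_cells(self) -> int:
        return int(self.p_values.size)

    @property
    def density_centres_cm(self) -> np.ndarray:
        lo = self.density_window_cm[0]
        return lo + (np.arange(self.p_values.shape[0]) + 0.5) * 0.1

    @property
    def dose_centres_cm(self) -> np.ndarray:
        lo = self.dose_window_cm[0]
        return lo + (np.arange(self.p_values.shape[1]) + 0.5) * 0.1


def _curve_matrix(
    curves: Mapping[str, SummaryCurve], patients: Sequence[str]
) -> tuple[np.ndarray, tuple[float, float]]:
    first = curves[patients[0]]
    n_ann = len(first.values)
    window = (
        float(first.distances_cm[0] - 0.05),
        float(first.distances_cm[-1] + 0.05),
    )
    mat = np.full((len(patients), n_ann), np.nan)
    for i, pid in enumerate(patients):
        c = curves[pid]
        if len(c.values) != n_ann:
            raise ValueError(f"curve length mismatch for patient {pid}")
        mat[i] = np.where(c.valid, c.values, np.nan)
    return mat, window


def interaction_map(
    density_curves: Mapping[str, SummaryCurve],
    dose_curves: Mapping[str, SummaryCurve],
    clinical: pd.DataFrame,
    covariates: Sequence[str],
    metric_pair: tuple[str, str],
    duration_col: str = "time",
    event_col: str = "event",
    min_events: int = 10,
) -> InteractionMap:
    """Fit the interaction vs no-interaction model pair at every cell.

    For cell ``(i, j)`` the patients valid at density annulus ``i`` and
    dose annulus ``j`` enter two nested fits (clinical covariates +
    density + dose, with and without density*dose); the cell stores the
    LR p-value.  Cells with fewer than ``min_events`` events, or whose
    fit fails, are left missing (NaN) with a logged warning.
    """
    patients = [
        p
        for p in clinical.index
        if p in density_curves and p in dose_curves
    ]
    if not patients:
        raise ValueError("no patients with both density and dose curves")
    sub = clinical.loc[patients]
    vd, d_window = _curve_matrix(density_curves, patients)
    vz, z_window = _curve_matrix(dose_curves, patients)
    time = np.asarray(sub[duration_col], dtype=float)
    event = np.asarray(sub[event_col], dtype=bool)
    xc = (
        np.column_stack([np.asarray(sub[c], dtype=float) for c in covariates])
        if covariates
        else np.zeros((len(patients), 0))
    )

    nd, nz = vd.shape[1], vz.shape[1]
    p_map = np.full((nd, nz), np.nan)
    n_used = np.zeros((nd, nz), dtype=int)
    n_ev = np.zeros((nd, nz), dtype=int)
    n_failed = 0
    for i in range(nd):
        di = vd[:, i]
        ok_i = np.isfinite(di)
        for j in range(nz):
            zj = vz[:, j]
            rows = ok_i & np.isfinite(zj)
            ev = int(event[rows].sum())
            n_used[i, j] = int(rows.sum())
            n_ev[i, j] = ev
            if ev < min_events:
                continue
            dens = di[rows]
            dose = zj[rows]
            x_red = np.column_stack([xc[rows], dens, dose])
            x_full = np.column_stack([x_red, dens * dose])
            try:
                b_f, _, ll_f, _, _ = _newton_cox(x_full, time[rows], event[rows])
                b_r, _, ll_r, _, _ = _newton_cox(x_red, time[rows], event[rows])
                stat = 2.0 * (ll_f - ll_r)
                if stat < -1e-6:
                    raise CoxError("LR statistic negative")
                p_map[i, j] = max(
                    float(chi2.sf(max(stat, 0.0), 1)), np.finfo(float).tiny
                )
            except (CoxError, np.linalg.LinAlgError):
                n_failed += 1
    if n_failed:
        warnings.warn(
            f"{n_failed} map cells failed to fit and were left missing",
            stacklevel=2,
        )
    return InteractionMap(
        p_values=p_map,
        n_used=n_used,
        n_events_used=n_ev,
        metric_pair=tuple(metric_pair),
        density_window_cm=d_window,
        dose_window_cm=z_window,
    )
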