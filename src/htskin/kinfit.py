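"""Single-substrate kinetics: Michaelis-Menten, binding isotherm, dissociation.

Fits the three assay types used to characterize individual ptRNA constructs:

* multiple-turnover initial rates, v = kcat [E]0 [S] / (Km + [S]), fit by
  weighted nonlinear least squares with replicate-SD weights;
* equilibrium binding by gel shift, y = Bmax [E] / (Kd + [E]);
* dissociation time courses of prebound complexes, resolved into a fast
  phase (loose encounter complex, ES) and a slow phase (committed complex,
  ES*) by a two-exponential fit with AICc model selection against a single
  exponential.

Parameter standard errors come from the fit covariance. Ratios between named
constructs (leader truncations, RCCA deletions) are tabulated with
errors propagated in quadrature on the relative scale.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats


@dataclass
class MMFit:
    """Michaelis-Menten fit result. Units follow the inputs (E0, S, v)."""

    kcat: float
    Km: float
    kcat_over_Km: float
    se_kcat: float
    se_Km: float
    se_kcat_over_Km: float
    E0: float
    residuals: np.ndarray = field(repr=False, default_factory=lambda: np.array([]))
    weighted: bool = False
    Km_identifiable: bool = True


@dataclass
class BindingFit:
    Kd: float
    Bmax: float
    se_Kd: float
    se_Bmax: float
    in_range: bool = True


@dataclass
class DissociationFit:
    amp_fast: float
    amp_slow: float
    k_fast: float
    k_slow: float
    n_phases: int
    aicc_two: float
    aicc_one: float
    converged: bool = True

    @property
    def es_fraction(self) -> float:
        """Loosely bound (rapidly dissociating) fraction, interpreted as ES."""
        return self.amp_fast

    @property
    def es_star_fraction(self) -> float:
        """Stably bound fraction, interpreted as the committed ES* complex."""
        return self.amp_slow


def fit_initial_rate(
    times: Sequence[float],
    reacted_fraction: Sequence[float],
    S0: float,
    max_fraction: float = 0.1,
) -> tuple[float, float, int]:
    """Initial velocity from a progress curve: linear slope x [S]0.

    Only points with reacted fraction <= `max_fraction` enter the regression
    (the linear regime); the number of excluded points is returned. For
    substrates with several product bands the caller sums them first.
    """
    t = np.asarray(times, dtype=float)
    frac = np.asarray(reacted_fraction, dtype=float)
    keep = frac <= max_fraction
    n_excluded = int((~keep).sum())
    if keep.sum() < 3:
        raise ValueError(
            f"need >= 3 points with reacted fraction <= {max_fraction}, "
            f"have {int(keep.sum())}"
        )
    res = stats.linregress(t[keep], frac[keep])
    return float(res.slope * S0), float(res.stderr * S0), n_excluded


def _replicate_stats(df: pd.DataFrame) -> pd.DataFrame:
    g = df.groupby("x")["y"]
    out = g.agg(["mean", "std", "count"]).reset_index()
    out["std"] = out["std"].fillna(0.0)
    return out


def _mm(S, kcat, Km, E0):
    return kcat * E0 * S / (Km + S)


def fit_mm(
    data: pd.DataFrame,
    E0: float,
    weighted: bool = True,
) -> MMFit:
    """Weighted Michaelis-Menten fit of initial rates vs substrate concentration.

    `data` has columns (x, y[, replicate]) with x = [S] and y = v. When
    replicate SDs are available and `weighted`, weights are 1/SD^2 with the
    SD floored at its 10th percentile (so an accidental zero-SD point cannot
    dominate); otherwise the fit is unweighted. kcat/Km and its SE come from
    the parameter covariance by the delta method.
    """
    pts = _replicate_stats(data)
    S, v = pts["x"].to_numpy(), pts["mean"].to_numpy()
    if len(S) < 4:
        raise ValueError("need >= 4 distinct substrate concentrations")
    sigma = None
    use_weights = False
    if weighted and (pts["count"] > 1).any() and (pts["std"] > 0).any():
        sd = pts["std"].to_numpy().copy()
        floor = np.percentile(sd[sd > 0], 10)
        sigma = np.maximum(sd, floor)
        use_weights = True

    # nondimensionalize so both parameters are O(1) regardless of units
    s0, v0 = float(S.max()), float(v.max())
    Sn, vn = S / s0, v / v0
    sigma_n = None if sigma is None else sigma / v0
    Km_guess = float(Sn[np.argmin(np.abs(vn - 0.5))])
    Km_guess = max(Km_guess, Sn.min() / 10)

    popt = pcov = None
    last_err = None
    for scale in [1.0, 0.1, 10.0, 0.01, 100.0]:
        try:
            popt, pcov = optimize.curve_fit(
                lambda s, a, b: a * s / (b + s), Sn, vn,
                p0=[1.2, Km_guess * scale], sigma=sigma_n, absolute_sigma=False,
                bounds=([0, 0], [np.inf, np.inf]), maxfev=20000,
            )
            break
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    if popt is None:
        raise RuntimeError(f"Michaelis-Menten fit did not converge: {last_err}")

    # back to physical units: a = kcat*E0/v0, b = Km/s0
    J = np.diag([v0 / E0, s0])
    pcov = J @ pcov @ J
    kcat, Km = float(popt[0] * v0 / E0), float(popt[1] * s0)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    ratio = kcat / Km
    # delta method including the kcat-Km covariance
    g = np.array([1.0 / Km, -kcat / Km**2])
    se_ratio = float(np.sqrt(max(g @ pcov @ g, 0.0)))
    identifiable = bool(Km <= 10.0 * S.max())
    resid = v - _mm(S, kcat, Km, E0)
    return MMFit(
        kcat=kcat, Km=Km, kcat_over_Km=ratio,
        se_kcat=float(se[0]), se_Km=float(se[1]), se_kcat_over_Km=se_ratio,
        E0=E0, residuals=resid, weighted=use_weights,
        Km_identifiable=identifiable,
    )


def fit_binding(data: pd.DataFrame, weighted: bool = True) -> BindingFit:
    """Hyperbolic binding isotherm y = Bmax [E] / (Kd + [E]).

    [E] is total enzyme; with substrate near-trace relative to Kd the
    hyperbolic form in total enzyme is adequate (a quadratic tight-binding
    correction is deliberately not applied by default).
    """
    pts = _replicate_stats(data)
    E, y = pts["x"].to_numpy(), pts["mean"].to_numpy()
    if len(E) < 4:
        raise ValueError("need >= 4 enzyme concentrations")
    sigma = None
    if weighted and (pts["count"] > 1).any() and (pts["std"] > 0).any():
        sd = pts["std"].to_numpy().copy()
        floor = np.percentile(sd[sd > 0], 10)
        sigma = np.maximum(sd, floor)

    e0 = float(E.max())
    En = E / e0
    Kd_guess = float(En[np.argmin(np.abs(y - y.max() / 2))])
    popt = pcov = None
    last_err = None
    for scale in [1.0, 0.1, 10.0, 0.01, 100.0]:
        try:
            popt, pcov = optimize.curve_fit(
                lambda e, Bmax, Kd: Bmax * e / (Kd + e), En, y,
                p0=[min(y.max() * 1.1, 1.0), Kd_guess * scale],
                sigma=sigma, bounds=([0, 0], [1.5, np.inf]), maxfev=20000,
            )
            break
        except (RuntimeError, ValueError) as err:  # pragma: no cover - rare
            last_err = err
    if popt is None:
        raise RuntimeError(f"binding fit did not converge: {last_err}")
    Bmax, Kd = float(popt[0]), float(popt[1] * e0)
    se = np.sqrt(np.clip(np.diag(pcov), 0, None))
    se[1] *= e0
    in_range = bool(Kd <= 10 * E.max()) and bool(Kd >= E.min() / 10)
    return BindingFit(Kd=Kd, Bmax=Bmax, se_Kd=float(se[1]), se_Bmax=float(se[0]),
                      in_range=in_range)


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return np.inf
    return n * math.log(max(rss, 1e-300) / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def fit_dissociation(data: pd.DataFrame) -> DissociationFit:
    """Two-phase dissociation fit with AICc selection against one phase.

    bound(t) = A_slow exp(-k_slow t) + A_fast exp(-k_fast t), data normalized
    to the t = 0 point. The fast amplitude reports the ES (encounter) fraction
    and the slow amplitude the ES* (committed) fraction. Falls back to the
    single exponential when the two-phase fit does not converge or is not
    favored.
    """
    pts = _replicate_stats(data)
    t, y = pts["x"].to_numpy(), pts["mean"].to_numpy()
    if t.min() > 0:
        raise ValueError("dissociation data must include the t = 0 point")
    n = len(t)
    tscale = float(t.max()) if t.max() > 0 else 1.0
    t = t / tscale  # rate constants refit on unit time, rescaled on return
    t_pos = t[t > 0]
    k_guess = 1.0 / max(np.median(t_pos), 1e-9) if len(t_pos) else 1.0

    def one_exp(tt, A, k):
        return A * np.exp(-k * tt)

    popt1, _ = optimize.curve_fit(one_exp, t, y, p0=[y[0], k_guess],
                                  bounds=([0, 0], [1.5, np.inf]), maxfev=20000)
    rss1 = float(np.sum((y - one_exp(t, *popt1)) ** 2))
    aicc1 = _aicc(rss1, n, 2)

    def two_exp(tt, As, ks, Af, kf):
        return As * np.exp(-ks * tt) + Af * np.exp(-kf * tt)

    converged = True
    try:
        popt2, _ = optimize.curve_fit(
            two_exp, t, y,
            p0=[y[0] / 2, k_guess / 10, y[0] / 2, k_guess * 10],
            bounds=([0, 0, 0, 0], [1.5, np.inf, 1.5, np.inf]), maxfev=40000,
        )
        rss2 = float(np.sum((y - two_exp(t, *popt2)) ** 2))
        aicc2 = _aicc(rss2, n, 4)
    except (RuntimeError, ValueError):
        converged = False
        popt2, aicc2 = None, np.inf

    if not converged or aicc1 <= aicc2:
        A, k = float(popt1[0]), float(popt1[1]) / tscale
        return DissociationFit(amp_fast=0.0, amp_slow=A, k_fast=k, k_slow=k,
                               n_phases=1, aicc_two=float(aicc2),
                               aicc_one=float(aicc1), converged=converged)
    As, ks, Af, kf = (float(x) for x in popt2)
    ks, kf = ks / tscale, kf / tscale
    if kf < ks:  # enforce k_fast >= k_slow labelling
        As, Af = Af, As
        ks, kf = kf, ks
    return DissociationFit(amp_fast=Af, amp_slow=As, k_fast=kf, k_slow=ks,
                           n_phases=2, aicc_two=float(aicc2),
                           aicc_one=float(aicc1), converged=True)


def fold_changes(fits: Mapping[str, MMFit | BindingFit]) -> pd.DataFrame:
    """Pairwise parameter ratios between named construct fits.

    For every ordered pair of constructs, reports ratios of kcat, kcat/Km and
    Kd (whichever the fit types carry) with SEs propagated as relative errors
    in quadrature. Supports the usual construct naming (AU, AU_T5, AU_D3,
    AU_T5D3, GG, GG_D3) but accepts any labels.
    """
    if len(fits) < 2:
        raise ValueError("need at least two named fits")

    def params(fit):
        out = {}
        if isinstance(fit, MMFit):
            out["kcat"] = (fit.kcat, fit.se_kcat)
            out["kcat_over_Km"] = (fit.kcat_over_Km, fit.se_kcat_over_Km)
        if isinstance(fit, BindingFit):
            out["Kd"] = (fit.Kd, fit.se_Kd)
        return out

    rows = []
    names = list(fits)
    for a in names:
        for b in names:
            if a == b:
                continue
            pa, pb = params(fits[a]), params(fits[b])
            for key in pa.keys() & pb.keys():
                (va, sa), (vb, sb) = pa[key], pb[key]
                ratio = va / vb
                rel = math.sqrt((sa / va) ** 2 + (sb / vb) ** 2) if va and vb else np.nan
                rows.append({"numerator": a, "denominator": b, "parameter": key,
                             "fold": ratio, "se_fold": abs(ratio) * rel})
    return pd.DataFrame(rows)
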