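"""Sequence-specificity modelling of relative rate constants.

The model regresses ln(k_rel) of each leader hexamer on per-position base
indicators (a position weight matrix, PWM) plus selected pairwise interaction
terms (pairwise interaction matrix, PIM):

    ln(k_rel) ~ intercept + sum_i (a_i A_i + c_i C_i + g_i G_i + u_i U_i)
                + sum_n alpha_n I_n

where i runs over leader positions -6..-1, the capital letters are 0/1 base
indicators and each I_n is the product of two single-position indicators at
distinct positions. The four coefficients at a position are not separately
identifiable (the indicators sum to one), so a per-position identifiability
constraint is imposed; the default sum-to-zero constraint makes each
coefficient read as log-enrichment relative to the position average.

Interaction terms are admitted by iterative rounds of regression: every
not-yet-included candidate (all C(6,2)*16 = 240 position-pair x base-pair
indicators) is scored by its coefficient T-value in a refit alongside the
current model, the strongest candidate with |T| above the selection threshold
(3.5) is admitted, and rounds repeat until none clears the bar. Admission is
one term per round (forward selection): scoring candidates jointly within a
round lets a single real coupling drag correlated sibling indicators over the
threshold on leakage alone, which both biases the fit and can render the true
term collinear with the admitted set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .seqio import LEADER_LENGTH, POSITIONS, RNA_BASES, all_variants, normalize_sequence

T_THRESHOLD = 3.5

#: (position, base) column order of the 24 main-effect indicators.
MAIN_COLUMNS: list[tuple[int, str]] = [(p, b) for p in POSITIONS for b in RNA_BASES]


@dataclass(frozen=True)
class InteractionTerm:
    """A pairwise coupling indicator: base_i at position_i AND base_j at position_j."""

    positions: tuple[int, int]  # (pi, pj) with pi < pj
    bases: tuple[str, str]
    alpha: float = 0.0
    t_value: float = float("nan")
    round_admitted: int = -1
    t_at_admission: float = float("nan")

    @property
    def label(self) -> str:
        (pi, pj), (bi, bj) = self.positions, self.bases
        return f"{bi}({pi})x{bj}({pj})"

    def key(self) -> tuple:
        return (self.positions, self.bases)


def candidate_interactions() -> list[InteractionTerm]:
    """The full candidate universe: 15 position pairs x 16 base pairs = 240."""
    out = []
    for a in range(LEADER_LENGTH):
        for b in range(a + 1, LEADER_LENGTH):
            for bi in RNA_BASES:
                for bj in RNA_BASES:
                    out.append(InteractionTerm((POSITIONS[a], POSITIONS[b]), (bi, bj)))
    return out


def one_hot_design(
    variants: Sequence[str],
    interactions: Sequence[InteractionTerm] = (),
) -> pd.DataFrame:
    """Indicator design matrix: 24 main-effect columns plus requested interactions."""
    seqs = [normalize_sequence(v) for v in variants]
    n = len(seqs)
    arr = np.zeros((n, len(MAIN_COLUMNS) + len(interactions)))
    base_at = np.array([[s[k] for k in range(LEADER_LENGTH)] for s in seqs])
    for col, (pos, base) in enumerate(MAIN_COLUMNS):
        arr[:, col] = base_at[:, POSITIONS.index(pos)] == base
    for j, term in enumerate(interactions):
        (pi, pj), (bi, bj) = term.positions, term.bases
        arr[:, len(MAIN_COLUMNS) + j] = (
            (base_at[:, POSITIONS.index(pi)] == bi)
            & (base_at[:, POSITIONS.index(pj)] == bj)
        )
    cols = [f"{b}({p})" for p, b in MAIN_COLUMNS] + [t.label for t in interactions]
    return pd.DataFrame(arr, columns=cols)


def _contrast_matrix(constraint: str) -> np.ndarray:
    """Per-position 4x3 map from free parameters to the four base coefficients."""
    if constraint == "sum":
        # coefficients sum to zero within the position
        return np.array([[1.0, 0, 0], [0, 1, 0], [0, 0, 1], [-1, -1, -1]])
    if constraint == "baseline":
        # A is the reference level
        return np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]])
    raise ValueError(f"unknown identifiability constraint {constraint!r}")


def _reduced_design(X_main: np.ndarray, constraint: str) -> tuple[np.ndarray, np.ndarray]:
    """Collapse the rank-deficient 24-column main block to 18 free columns.

    Returns (X_reduced, Z) where Z is the block-diagonal 24x18 expansion such
    that full coefficients = Z @ reduced coefficients.
    """
    C = _contrast_matrix(constraint)
    Z = np.zeros((24, 18))
    for k in range(LEADER_LENGTH):
        Z[4 * k:4 * k + 4, 3 * k:3 * k + 3] = C
    return X_main @ Z, Z


@dataclass
class SpecificityModel:
    """Fitted PWM + pairwise-interaction model of ln(k_rel)."""

    intercept: float = 0.0
    main_effects: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(
            0.0, index=list(RNA_BASES), columns=list(POSITIONS)
        )
    )
    main_t_values: pd.DataFrame | None = None
    interactions: list[InteractionTerm] = field(default_factory=list)
    constraint: str = "sum"
    r_squared: float = float("nan")
    residual_df: int = 0
    n_excluded: int = 0
    selection_history: list[dict] = field(default_factory=list)

    def predict(self, variants: Sequence[str]) -> np.ndarray:
        """Evaluate the linear predictor of ln(k_rel) for each variant."""
        X = one_hot_design(variants, self.interactions).to_numpy()
        beta_main = np.concatenate(
            [self.main_effects.loc[list(RNA_BASES), p].to_numpy() for p in POSITIONS]
        )
        beta = np.concatenate([beta_main, [t.alpha for t in self.interactions]])
        return self.intercept + X @ beta

    def coefficient_table(self) -> pd.DataFrame:
        rows = [
            {"term": f"{b}({p})", "position": p, "base": b,
             "coefficient": self.main_effects.loc[b, p],
             "t_value": (self.main_t_values.loc[b, p]
                         if self.main_t_values is not None else np.nan)}
            for p in POSITIONS for b in RNA_BASES
        ]
        rows += [
            {"term": t.label, "position": None, "base": None,
             "coefficient": t.alpha, "t_value": t.t_value}
            for t in self.interactions
        ]
        return pd.DataFrame(rows)


def _prepare_response(
    ln_krel: np.ndarray, flags: Sequence[str] | None
) -> tuple[np.ndarray, int]:
    """Mask censored/non-finite observations; return (keep mask, n excluded)."""
    keep = np.isfinite(ln_krel)
    if flags is not None:
        keep &= np.array([fl in ("", "ok", None) or pd.isna(fl) for fl in flags])
    return keep, int((~keep).sum())


def fit_pwm(
    variants: Sequence[str],
    ln_krel: np.ndarray,
    weights: np.ndarray | None = None,
    flags: Sequence[str] | None = None,
    constraint: str = "sum",
    interactions: Sequence[InteractionTerm] = (),
) -> SpecificityModel:
    """Constrained least squares of ln(k_rel) on the indicator design.

    `weights` are WLS observation weights (e.g. 1 / SE^2 of ln k_rel); default
    unweighted. Censored variants (via `flags`) are excluded and counted.
    """
    ln_krel = np.asarray(ln_krel, dtype=float)
    keep, n_excluded = _prepare_response(ln_krel, flags)
    v = [variants[i] for i in np.flatnonzero(keep)]
    y = ln_krel[keep]
    X_full = one_hot_design(v, interactions).to_numpy()
    X_main, X_int = X_full[:, :24], X_full[:, 24:]
    X_red, Z = _reduced_design(X_main, constraint)
    design = sm.add_constant(np.column_stack([X_red, X_int]), has_constant="add")
    if weights is not None:
        res = sm.WLS(y, design, weights=np.asarray(weights)[keep]).fit()
    else:
        res = sm.OLS(y, design).fit()
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise np.linalg.LinAlgError("design is rank deficient after constraints")

    beta_red = res.params[1:19]
    beta_main = Z @ beta_red
    cov_red = res.cov_params()[1:19, 1:19]
    se_main = np.sqrt(np.clip(np.diag(Z @ cov_red @ Z.T), 0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        t_main = np.where(se_main > 0, beta_main / se_main, 0.0)

    model = SpecificityModel(constraint=constraint)
    model.intercept = float(res.params[0])
    for col, (p, b) in enumerate(MAIN_COLUMNS):
        model.main_effects.loc[b, p] = beta_main[col]
    model.main_t_values = pd.DataFrame(
        t_main.reshape(LEADER_LENGTH, 4).T, index=list(RNA_BASES), columns=list(POSITIONS)
    )
    fitted = []
    for j, term in enumerate(interactions):
        fitted.append(
            InteractionTerm(
                term.positions, term.bases,
                alpha=float(res.params[19 + j]),
                t_value=float(res.tvalues[19 + j]),
                round_admitted=term.round_admitted,
                t_at_admission=term.t_at_admission,
            )
        )
    model.interactions = fitted
    model.r_squared = float(res.rsquared)
    model.residual_df = int(res.df_resid)
    model.n_excluded = n_excluded
    return model


def _candidate_t_values(
    base_design: np.ndarray, y: np.ndarray, candidates_X: np.ndarray
) -> np.ndarray:
    """T-value each candidate column would get if added alone to the design.

    Frisch-Waugh: project the candidate and the response off the current
    design; the added-variable coefficient, its residual variance and hence
    its t are exact for the joint refit including that one candidate.
    """
    Q, _ = np.linalg.qr(base_design)
    y_res = y - Q @ (Q.T @ y)
    Z_res = candidates_X - Q @ (Q.T @ candidates_X)
    n, p = base_design.shape
    zz = np.einsum("ij,ij->j", Z_res, Z_res)
    zy = y_res @ Z_res
    rss0 = float(y_res @ y_res)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(zz > 1e-12, zy / np.where(zz > 0, zz, 1.0), 0.0)
        rss1 = rss0 - coef * zy
        dof = n - p - 1
        # floor the residual variance so an exact fit yields a huge finite t
        # rather than 0/0
        sigma2 = np.maximum(rss1 / dof, 1e-24)
        t = np.where(zz > 1e-12, coef / np.sqrt(sigma2 / np.where(zz > 0, zz, 1.0)), 0.0)
    return t


def select_interactions(
    variants: Sequence[str],
    ln_krel: np.ndarray,
    model: SpecificityModel | None = None,
    weights: np.ndarray | None = None,
    flags: Sequence[str] | None = None,
    threshold: float = T_THRESHOLD,
    max_rounds: int = 20,
    constraint: str = "sum",
) -> SpecificityModel:
    """Iterative forward selection of pairwise interaction terms.

    Each round scores every not-yet-included candidate by the |T| of its
    coefficient in a refit with the current model and admits the strongest
    one if its |T| is strictly above `threshold`. Stops when no candidate
    clears the bar; raises if `max_rounds` is exhausted.
    """
    if model is None:
        model = fit_pwm(variants, ln_krel, weights=weights, flags=flags,
                        constraint=constraint)
    ln_krel = np.asarray(ln_krel, dtype=float)
    keep, _ = _prepare_response(ln_krel, flags)
    v = [variants[i] for i in np.flatnonzero(keep)]
    y = ln_krel[keep]
    w = None if weights is None else np.asarray(weights)[keep]
    if w is not None:
        sw = np.sqrt(w)
        y = y * sw

    universe = candidate_interactions()
    selected: list[InteractionTerm] = []
    history: list[dict] = []

    X_main = one_hot_design(v).to_numpy()[:, :24]
    X_red, _ = _reduced_design(X_main, constraint)
    X_all_cand = one_hot_design(v, universe).to_numpy()[:, 24:]
    if w is not None:
        sw = np.sqrt(w)
        X_red = X_red * sw[:, None]
        X_all_cand = X_all_cand * sw[:, None]
        ones = sw
    else:
        ones = np.ones(len(y))

    for rnd in range(1, max_rounds + 1):
        sel_keys = {t.key() for t in selected}
        open_idx = [i for i, t in enumerate(universe) if t.key() not in sel_keys]
        if not open_idx:
            break
        X_sel = X_all_cand[:, [i for i, t in enumerate(universe) if t.key() in sel_keys]]
        base = np.column_stack([ones, X_red, X_sel])
        t_vals = _candidate_t_values(base, y, X_all_cand[:, open_idx])
        best = int(np.argmax(np.abs(t_vals)))
        best_t = float(t_vals[best])
        admit = abs(best_t) > threshold
        history.append({
            "round": rnd,
            "n_candidates": len(open_idx),
            "admitted": [universe[open_idx[best]].label] if admit else [],
            "max_abs_t": abs(best_t),
        })
        if not admit:
            final = fit_pwm(v, np.asarray(ln_krel)[keep],
                            weights=w if weights is not None else None,
                            constraint=constraint, interactions=selected)
            final.selection_history = history
            return final
        term = universe[open_idx[best]]
        selected.append(
            InteractionTerm(term.positions, term.bases,
                            round_admitted=rnd, t_at_admission=best_t)
        )
    raise RuntimeError(
        f"interaction selection did not converge in {max_rounds} rounds; "
        f"history: {history}"
    )


@dataclass
class LogoMatrix:
    """Per-position base frequencies and information content of a sequence set."""

    frequencies: pd.DataFrame  # 4 x 6, columns are positions -6..-1
    information: pd.Series  # bits per position

    def letter_heights(self) -> pd.DataFrame:
        """Frequency x IC letter heights as drawn in a sequence logo."""
        return self.frequencies * self.information

    def consensus(self) -> str:
        return "".join(self.frequencies[p].idxmax() for p in self.frequencies.columns)


def logo_from_subset(sequences: Iterable[str]) -> LogoMatrix:
    """Frequency matrix and per-position IC (uniform background, in bits).

    IC_j = 2 + sum_b p_bj log2 p_bj, so identical sequences give 2 bits and a
    uniform column gives 0.
    """
    seqs = [normalize_sequence(s) for s in sequences]
    if not seqs:
        raise ValueError("empty sequence subset")
    length = len(seqs[0])
    if any(len(s) != length for s in seqs):
        raise ValueError("sequences must be equal length")
    positions = list(POSITIONS) if length == LEADER_LENGTH else list(range(-length, 0))
    freq = pd.DataFrame(0.0, index=list(RNA_BASES), columns=positions)
    for s in seqs:
        for j, b in enumerate(s):
            freq.iloc[_BASE_ROW[b], j] += 1
    freq /= len(seqs)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freq.to_numpy() > 0, freq.to_numpy() * np.log2(freq.to_numpy()), 0.0)
    ic = pd.Series(2.0 + plogp.sum(axis=0), index=positions)
    return LogoMatrix(frequencies=freq, information=ic.clip(lower=0.0))


_BASE_ROW = {b: i for i, b in enumerate(RNA_BASES)}


def plot_logo(logo: LogoMatrix, ax=None):
    """Render a simple letter-height sequence logo with matplotlib."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 2.5))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "U": "#d62728"}
    heights = logo.letter_heights()
    for x, pos in enumerate(heights.columns):
        stack = heights[pos].sort_values()
        y = 0.0
        for base, h in stack.items():
            if h <= 0:
                continue
            ax.text(x, y + h / 2, base, ha="center", va="center",
                    fontsize=8 + 16 * min(h / 2, 1.0), color=colors[base],
                    fontweight="bold")
            y += h
    ax.set_xticks(range(len(heights.columns)))
    ax.set_xticklabels([f"N({p})" for p in heights.columns])
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    return ax


def model_to_frame(model: SpecificityModel) -> pd.DataFrame:
    """Flat serializable view of a model (round-trips with `model_from_frame`)."""
    rows = [{"kind": "intercept", "term": "const", "coefficient": model.intercept,
             "t_value": np.nan, "round": -1}]
    for p in POSITIONS:
        for b in RNA_BASES:
            rows.append({
                "kind": "main", "term": f"{b}({p})",
                "coefficient": model.main_effects.loc[b, p],
                "t_value": (model.main_t_values.loc[b, p]
                            if model.main_t_values is not None else np.nan),
                "round": -1,
            })
    for t in model.interactions:
        rows.append({"kind": "interaction", "term": t.label, "coefficient": t.alpha,
                     "t_value": t.t_value, "round": t.round_admitted})
    return pd.DataFrame(rows)


def model_from_frame(frame: pd.DataFrame, constraint: str = "sum") -> SpecificityModel:
    model = SpecificityModel(constraint=constraint)
    for _, row in frame.iterrows():
        if row["kind"] == "intercept":
            model.intercept = float(row["coefficient"])
        elif row["kind"] == "main":
            b, p = row["term"][0], int(row["term"][2:-1])
            model.main_effects.loc[b, p] = float(row["coefficient"])
        else:
            lhs, rhs = row["term"].split("x")
            bi, pi = lhs[0], int(lhs[2:-1])
            bj, pj = rhs[0], int(rhs[2:-1])
            model.interactions.append(
                InteractionTerm((pi, pj), (bi, bj), alpha=float(row["coefficient"]),
                                t_value=float(row["t_value"]),
                                round_admitted=int(row["round"]))
            )
    return model
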