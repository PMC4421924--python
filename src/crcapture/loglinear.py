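"""Hierarchical log-linear models for three-list capture-pattern tables.

A Poisson log-linear model is fitted to the 2^T - 1 observed cells; pairwise
interaction terms absorb between-list dependence, and the intercept projects
the unobserved all-zero cell x000, giving N-hat = M + x000-hat.  The family for
T = 3 runs from the saturated model (all three pairwise interactions; the
three-way term is never included, as it would leave the missing cell
unidentified) down to mutual independence - eight hierarchical models in all.
Model choice follows the classical stepwise-descending deviance (G^2)
procedure.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .capture_data import CaptureDataError, CellCounts

__all__ = [
    "LogLinearModel",
    "LogLinearFit",
    "StepwiseResult",
    "hierarchical_family",
    "fit",
    "stepwise_select",
    "saturated_closed_form",
]

Z95 = 1.959963984540054


@dataclass(frozen=True)
class LogLinearModel:
    """Main effects for every source plus a set of pairwise interactions."""

    sources: tuple[str, ...]
    interactions: tuple[tuple[str, str], ...]

    def __post_init__(self):
        srcs = tuple(self.sources)
        ints = []
        seen = set()
        for a, b in self.interactions:
            if a not in srcs or b not in srcs or a == b:
                raise CaptureDataError(f"bad interaction ({a},{b}) for sources {srcs}")
            key = tuple(sorted((a, b), key=srcs.index))
            if key in seen:
                raise CaptureDataError(f"duplicate interaction {key}")
            seen.add(key)
            ints.append(key)
        # canonical order: by position of the member sources
        ints.sort(key=lambda p: (srcs.index(p[0]), srcs.index(p[1])))
        object.__setattr__(self, "sources", srcs)
        object.__setattr__(self, "interactions", tuple(ints))

    @property
    def formula(self) -> str:
        terms = ["θ", *self.sources] + [f"{a}*{b}" for a, b in self.interactions]
        return " + ".join(terms)

    @property
    def n_params(self) -> int:
        return 1 + len(self.sources) + len(self.interactions)

    def drop(self, interaction: tuple[str, str]) -> "LogLinearModel":
        return LogLinearModel(
            self.sources, tuple(i for i in self.interactions if i != tuple(interaction))
        )


@dataclass(frozen=True)
class LogLinearFit:
    model: LogLinearModel
    coefficients: dict[str, float]
    fitted_cells: dict[str, float]
    x000_hat: float
    N_hat: float
    ci: tuple[float, float]
    G2: float
    df: int
    p_value: float
    selected: bool = False

    def with_selected(self, flag: bool) -> "LogLinearFit":
        return LogLinearFit(
            self.model, self.coefficients, self.fitted_cells, self.x000_hat,
            self.N_hat, self.ci, self.G2, self.df, self.p_value, flag,
        )


def hierarchical_family(sources: tuple[str, ...]) -> list[LogLinearModel]:
    """All hierarchical models from saturated to independence (8 for T=3)."""
    if len(sources) != 3:
        raise CaptureDataError("the implemented log-linear family requires T = 3 lists")
    pairs = list(itertools.combinations(sources, 2))
    fam = []
    for k in (3, 2, 1, 0):
        for combo in itertools.combinations(pairs, k):
            fam.append(LogLinearModel(tuple(sources), tuple(combo)))
    return fam


def _design(c: CellCounts, model: LogLinearModel) -> tuple[np.ndarray, np.ndarray, list[str]]:
    pats = c.all_patterns()
    idx = {s: i for i, s in enumerate(c.labels)}
    names = ["theta"] + list(model.sources) + [f"{a}*{b}" for a, b in model.interactions]
    rows = []
    for p in pats:
        ind = {s: int(p[idx[s]]) for s in c.labels}
        rows.append(
            [1] + [ind[s] for s in model.sources]
            + [ind[a] * ind[b] for a, b in model.interactions]
        )
    return np.array(rows, float), c.as_array(), names


def saturated_closed_form(c: CellCounts) -> float:
    """Closed-form x000 projection of the saturated (no three-way) model.

    x000 = x111*x100*x010*x001 / (x110*x101*x011) in the table's source order.
    """
    if c.T != 3:
        raise CaptureDataError("closed form defined for 3-list tables")
    g = lambda p: c.counts.get(p, 0)
    num = g("111") * g("100") * g("010") * g("001")
    den = g("110") * g("101") * g("011")
    if den == 0:
        return np.inf
    return num / den


def fit(c: CellCounts, model: LogLinearModel) -> LogLinearFit:
    """Maximum-likelihood Poisson fit to the observed cells.

    ``N_hat = M + exp(theta-hat)`` since the all-zero cell's design row is the
    intercept alone.  The 95% interval is Wald on N-hat with variance
    ``x000 + x000^2 * var(theta-hat)`` - the Poisson prediction variance of the
    unobserved cell plus the delta-method estimation variance.  G^2 is the
    deviance over observed cells with 0*log(0) = 0.
    """
    if tuple(model.sources) != tuple(c.labels):
        raise CaptureDataError(
            f"model sources {model.sources} do not match table labels {c.labels}"
        )
    X, y, names = _design(c, model)
    y_fit = y.copy()
    zero_involved = _cells_breaking_terms(c, model, X, y)
    if zero_involved:
        warnings.warn(
            f"zero observed cell(s) {sorted(zero_involved)} make a term inestimable; "
            "adding a 0.5 continuity correction to those cells",
            stacklevel=2,
        )
        pats = c.all_patterns()
        for i, p in enumerate(pats):
            if p in zero_involved:
                y_fit[i] += 0.5
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = sm.GLM(y_fit, X, family=sm.families.Poisson()).fit()
    fitted = np.asarray(res.mu)
    x000 = float(np.exp(res.params[0]))
    M = float(y.sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        g2 = float(2.0 * np.sum(np.where(y > 0, y * np.log(y / fitted), 0.0)))
    g2 = max(g2, 0.0)
    df = len(y) - model.n_params
    p = float(stats.chi2.sf(g2, df)) if df > 0 else 1.0
    var_b0 = float(res.cov_params()[0, 0])
    half = Z95 * np.sqrt(x000 + x000**2 * var_b0)
    N = M + x000
    return LogLinearFit(
        model=model,
        coefficients=dict(zip(names, map(float, res.params))),
        fitted_cells=dict(zip(c.all_patterns(), map(float, fitted))),
        x000_hat=x000,
        N_hat=N,
        ci=(N - half, N + half),
        G2=g2,
        df=df,
        p_value=p,
    )


def _cells_breaking_terms(c, model, X, y) -> set[str]:
    """Observed zero cells that zero out an entire interaction margin."""
    if not (y == 0).any():
        return set()
    pats = c.all_patterns()
    bad: set[str] = set()
    # a pairwise term is inestimable when its (1,1) margin has zero total
    for col, (a, b) in enumerate(model.interactions, start=1 + len(model.sources)):
        mask = X[:, col] == 1
        if y[mask].sum() == 0:
            bad.update(p for p, m in zip(pats, mask) if m)
    return bad


@dataclass(frozen=True)
class StepwiseResult:
    fits: tuple[LogLinearFit, ...]  # all family members, selected flag set
    selected: LogLinearFit
    path: tuple[str, ...]  # formulas visited, saturated first


def stepwise_select(c: CellCounts, alpha: float = 0.05) -> StepwiseResult:
    """Stepwise-descending selection from the saturated model.

    At each step every currently included interaction is tentatively dropped
    and the nested deviance difference G2(reduced) - G2(current) is tested
    against chi-square on the df difference.  The drop with the largest
    (non-significant) p-value is taken, ties broken by the family's fixed term
    order; descent stops when every candidate removal is significant at
    ``alpha``, retaining the most parsimonious model that still fits.
    """
    if not 0 < alpha < 1:
        raise CaptureDataError("alpha must lie in (0, 1)")
    family = hierarchical_family(tuple(c.labels))
    fits = {m.interactions: fit(c, m) for m in family}
    current = family[0]  # saturated
    path = [current.formula]
    while current.interactions:
        candidates = []
        cur_fit = fits[current.interactions]
        for term in current.interactions:
            red = current.drop(term)
            red_fit = fits[red.interactions]
            dg2 = red_fit.G2 - cur_fit.G2
            ddf = red_fit.df - cur_fit.df
            p = float(stats.chi2.sf(max(dg2, 0.0), ddf))
            candidates.append((p, term, red))
        # largest p first; ties broken by canonical term order (stable sort)
        candidates.sort(key=lambda t: -t[0])
        best_p, _, best_model = candidates[0]
        if best_p <= alpha:
            break
        current = best_model
        path.append(current.formula)
    flagged = tuple(
        f.with_selected(f.model.interactions == current.interactions)
        for f in (fits[m.interactions] for m in family)
    )
    selected = next(f for f in flagged if f.selected)
    return StepwiseResult(flagged, selected, tuple(path))
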