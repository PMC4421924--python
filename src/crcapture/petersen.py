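"""Two-source Lincoln-Petersen estimation, source pooling and independence testing.

The Lincoln-Petersen estimator N-hat = n1*n2/m crosses two lists with sizes n1,
n2 and overlap m.  With three or more lists, a dependent pair of sources is
first pooled by union (Wittes' source-pooling rule) so that the remaining
two-list cross is closer to independent; pairwise dependence is screened with
an odds-ratio test built on the third source.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .capture_data import CaptureDataError, CellCounts

__all__ = [
    "PetersenEstimate",
    "IndependenceTestResult",
    "CompletenessEstimate",
    "lincoln_petersen",
    "lincoln_petersen_pair",
    "pairwise_estimates",
    "pool_sources",
    "wittes_independence_test",
    "completeness",
    "hypergeometric_mle",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class PetersenEstimate:
    n1: int
    n2: int
    m_overlap: int
    N_hat: float
    variance: float
    ci: tuple[float, float]
    chapman: bool = False

    def __post_init__(self):
        if self.m_overlap > min(self.n1, self.n2):
            raise CaptureDataError("overlap exceeds a list size")


@dataclass(frozen=True)
class IndependenceTestResult:
    """Odds ratio between two lists with 95% Woolf (log-OR) interval.

    OR < 1 with the default convention (the 2x2 table of the pair's capture
    indicators among cases present in the stratifying source) flags negative
    association between the pair.
    """

    odds_ratio: float
    ci: tuple[float, float]
    pair: tuple[str, str]
    stratifying_source: str
    convention: str
    table: tuple[tuple[float, float], tuple[float, float]]

    @property
    def significant(self) -> bool:
        lo, hi = self.ci
        return not (lo <= 1.0 <= hi)


@dataclass(frozen=True)
class CompletenessEstimate:
    percent: float
    ci: tuple[float, float] | None


def lincoln_petersen(n1: int, n2: int, m: int, chapman: bool = False) -> PetersenEstimate:
    """Plain (default) or Chapman-corrected two-list population estimate.

    The plain estimator is N-hat = n1*n2/m with the classical variance
    n1*n2*(n1-m)*(n2-m)/m^3 and a normal-approximation 95% interval.
    """
    if min(n1, n2) < 1:
        raise CaptureDataError("both lists must be non-empty")
    if m < 1 and not chapman:
        raise CaptureDataError(
            "zero overlap: the plain Lincoln-Petersen estimate is undefined; "
            "pool sources or use the Chapman correction"
        )
    if m > min(n1, n2):
        raise CaptureDataError("overlap cannot exceed either list size")
    if chapman:
        N = (n1 + 1) * (n2 + 1) / (m + 1) - 1
        var = (n1 + 1) * (n2 + 1) * (n1 - m) * (n2 - m) / ((m + 1) ** 2 * (m + 2))
    else:
        N = n1 * n2 / m
        var = n1 * n2 * (n1 - m) * (n2 - m) / m**3
    half = Z95 * np.sqrt(var)
    return PetersenEstimate(n1, n2, m, N, var, (N - half, N + half), chapman)


def lincoln_petersen_pair(
    c: CellCounts, pair: tuple[str, str], chapman: bool = False
) -> PetersenEstimate:
    """Lincoln-Petersen estimate crossing two named lists of a cell table."""
    a, b = pair
    return lincoln_petersen(
        c.source_total(a), c.source_total(b), c.overlap(a, b), chapman=chapman
    )


def pairwise_estimates(c: CellCounts, chapman: bool = False) -> dict[tuple[str, str], PetersenEstimate]:
    out = {}
    for i, a in enumerate(c.labels):
        for b in c.labels[i + 1:]:
            out[(a, b)] = lincoln_petersen_pair(c, (a, b), chapman=chapman)
    return out


def pool_sources(c: CellCounts, pair: tuple[str, str]) -> CellCounts:
    """Merge two lists by union into a single pooled list.

    The pooled capture indicator is 1 if the case appears in either member of
    the pair; counts are re-aggregated over the reduced patterns and the total
    observed count is preserved.  Applied when a pair of sources is
    interdependent, so the remaining cross-classification is closer to
    independent.
    """
    if c.T < 3:
        raise CaptureDataError("pooling a two-list table would leave a single list")
    ia, ib = sorted((c._index(pair[0]), c._index(pair[1])))
    labels = []
    for j, lab in enumerate(c.labels):
        if j == ia:
            labels.append(f"{c.labels[ia]}+{c.labels[ib]}")
        elif j != ib:
            labels.append(lab)
    counts: dict[str, int] = {}
    for pat, cnt in c.counts.items():
        union = "1" if (pat[ia] == "1" or pat[ib] == "1") else "0"
        new = "".join(
            union if j == ia else pat[j] for j in range(c.T) if j != ib
        )
        counts[new] = counts.get(new, 0) + cnt
    return CellCounts(tuple(labels), counts)


def wittes_independence_test(
    c: CellCounts,
    pair: tuple[str, str],
    third: str,
    convention: str = "present",
) -> IndependenceTestResult:
    """Odds-ratio screen for dependence between a pair of lists.

    Cross-classifies capture by the two members of ``pair`` among observed
    cases, stratified on the ``third`` source: the default convention
    ``"present"`` restricts the 2x2 table to cases recorded by the third
    source (whose capture is then informative about both members of the
    pair); ``"absent"`` restricts to cases it missed, and ``"marginal"`` uses
    all observed cases unrestricted.  Returns the odds ratio with a 95% Woolf
    interval; zero cells get the Haldane-Anscombe 0.5 correction.
    """
    if c.T != 3:
        raise CaptureDataError("the independence screen is defined for 3-list tables")
    ia, ib, ic = c._index(pair[0]), c._index(pair[1]), c._index(third)
    if len({ia, ib, ic}) != 3:
        raise CaptureDataError("pair and third source must be three distinct lists")
    table = np.zeros((2, 2))
    for pat, cnt in c.counts.items():
        if convention == "present" and pat[ic] != "1":
            continue
        if convention == "absent" and pat[ic] != "0":
            continue
        table[1 - int(pat[ia]), 1 - int(pat[ib])] += cnt
    if convention not in ("present", "absent", "marginal"):
        raise CaptureDataError(f"unknown convention {convention!r}")
    if (table == 0).any():
        warnings.warn(
            "zero cell in the 2x2 dependence table; applying the Haldane-Anscombe "
            "0.5 correction",
            stacklevel=2,
        )
        table = table + 0.5
    orr = table[0, 0] * table[1, 1] / (table[0, 1] * table[1, 0])
    se = np.sqrt((1.0 / table).sum())
    lo, hi = np.exp(np.log(orr) - Z95 * se), np.exp(np.log(orr) + Z95 * se)
    return IndependenceTestResult(
        orr, (lo, hi), tuple(pair), third, convention,
        tuple(map(tuple, table)),
    )


def _round_half_up(x: float, digits: int = 1) -> float:
    scale = 10**digits
    return np.floor(x * scale + 0.5) / scale


def completeness(
    n_source: int, N_hat: float, ci: tuple[float, float] | None = None
) -> CompletenessEstimate:
    """Registry completeness 100*n_source/N-hat (one decimal, half-up).

    The interval inverts the bounds of the population estimate: a larger
    population bound implies lower completeness, so the lower completeness
    bound uses ``ci.high``.
    """
    if N_hat < n_source:
        raise CaptureDataError(
            f"population estimate {N_hat} below the register count {n_source}"
        )
    pct = _round_half_up(100.0 * n_source / N_hat)
    interval = None
    if ci is not None:
        lo, hi = ci
        interval = (
            _round_half_up(100.0 * n_source / hi),
            _round_half_up(100.0 * n_source / lo),
        )
    return CompletenessEstimate(pct, interval)


def hypergeometric_mle(n1: int, n2: int, m: int, n_max: int | None = None) -> int:
    """Integer MLE of N under the hypergeometric two-list model (oracle).

    Exhaustively maximizes P(overlap = m | N, n1, n2) over N; used as an
    independent cross-check of the Lincoln-Petersen closed form.
    """
    lo = n1 + n2 - m
    hi = n_max or max(n1 * n2 + 1, 100)  # the likelihood peaks at or below n1*n2
    Ns = np.arange(lo, hi + 1)
    pmf = stats.hypergeom.pmf(m, Ns, n1, n2)
    return int(Ns[np.argmax(pmf)])
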