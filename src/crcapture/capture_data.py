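"""Capture histories, capture-pattern cell counts, and covariate-to-episode expansion.

A *capture history* is the binary matrix of which observed individuals were
recorded by which list (data source / capture episode).  For T lists the
observable information collapses to the counts of the 2^T - 1 non-empty
capture patterns; both representations are provided with lossless conversion
between them.

The module also ships the two three-source cancer record-linkage tables used
throughout the test-suite and examples (breast and colorectal cancer cases
aged 50-75, lists HR = histopathological registry, MTM = multidisciplinary
team meetings, CSP = cancer screening programme), guarded by checksum
sidecars validated at load time.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CaptureHistory",
    "CellCounts",
    "CovariateTable",
    "EpisodeMap",
    "FixtureValidation",
    "read_capture_history",
    "read_cell_counts",
    "write_cell_counts",
    "to_cell_counts",
    "to_capture_history",
    "validate_fixture",
    "load_fixture",
    "fixture_checksums",
    "expand_episodes",
    "breast_episode_map",
    "colorectal_episode_map",
    "AGE_BANDS",
]


class CaptureDataError(ValueError):
    """Malformed or inconsistent capture data."""


@dataclass(frozen=True)
class CaptureHistory:
    """Binary n x T matrix of observed individuals' captures.

    Rows are observed individuals (every row must contain at least one 1:
    never-captured individuals are by construction absent from list data),
    columns are capture episodes in the order of ``episode_labels``.
    """

    matrix: np.ndarray
    episode_labels: tuple[str, ...]

    def __post_init__(self):
        m = np.asarray(self.matrix)
        if m.ndim != 2:
            raise CaptureDataError("capture matrix must be two-dimensional")
        if not np.isin(m, (0, 1)).all():
            raise CaptureDataError("capture matrix entries must be exactly 0 or 1")
        m = m.astype(np.int8)
        if m.shape[1] != len(self.episode_labels):
            raise CaptureDataError(
                f"{len(self.episode_labels)} episode labels for {m.shape[1]} columns"
            )
        zero = np.flatnonzero(m.sum(axis=1) == 0)
        if zero.size:
            raise CaptureDataError(
                f"row {zero[0]} has no captures; only observed individuals may be stored"
            )
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "episode_labels", tuple(self.episode_labels))

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def T(self) -> int:
        return self.matrix.shape[1]

    def permute_episodes(self, order: Sequence[int]) -> "CaptureHistory":
        order = list(order)
        return CaptureHistory(
            self.matrix[:, order], tuple(self.episode_labels[i] for i in order)
        )

    def write_csv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=list(self.episode_labels))
        df.insert(0, "id", np.arange(1, self.n + 1))
        df.to_csv(path, index=False)


@dataclass(frozen=True)
class CellCounts:
    """Counts of the 2^T - 1 observable capture patterns.

    Pattern keys are length-T strings over {0,1}; the leftmost digit refers to
    ``labels[0]``.  The unobservable all-zero pattern is never stored.
    """

    labels: tuple[str, ...]
    counts: Mapping[str, int]

    def __post_init__(self):
        T = len(self.labels)
        clean: dict[str, int] = {}
        for pat, cnt in self.counts.items():
            if len(pat) != T or set(pat) - {"0", "1"}:
                raise CaptureDataError(f"bad capture pattern {pat!r} for T={T}")
            if pat == "0" * T:
                raise CaptureDataError("the all-zero pattern is unobservable")
            cnt = int(cnt)
            if cnt < 0:
                raise CaptureDataError(f"negative count for pattern {pat!r}")
            clean[pat] = clean.get(pat, 0) + cnt
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts", dict(clean))

    @property
    def T(self) -> int:
        return len(self.labels)

    @property
    def total(self) -> int:
        """Number of distinct observed individuals M."""
        return sum(self.counts.values())

    def source_total(self, label: str) -> int:
        i = self._index(label)
        return sum(c for p, c in self.counts.items() if p[i] == "1")

    def overlap(self, a: str, b: str) -> int:
        ia, ib = self._index(a), self._index(b)
        return sum(c for p, c in self.counts.items() if p[ia] == "1" and p[ib] == "1")

    def count_by_breadth(self, k: int, exact: bool = False) -> int:
        """Individuals captured by >= k sources (or exactly k with ``exact``)."""
        op = (lambda s: s == k) if exact else (lambda s: s >= k)
        return sum(c for p, c in self.counts.items() if op(p.count("1")))

    def _index(self, label: str) -> int:
        try:
            return self.labels.index(label)
        except ValueError:
            raise CaptureDataError(f"unknown source {label!r}; have {self.labels}") from None

    def all_patterns(self) -> list[str]:
        """Every non-empty pattern in canonical (descending binary) order."""
        T = self.T
        return [format(i, f"0{T}b") for i in range(2**T - 1, 0, -1)]

    def as_array(self) -> np.ndarray:
        """Counts aligned with :meth:`all_patterns` (zeros filled in)."""
        return np.array([self.counts.get(p, 0) for p in self.all_patterns()], float)


def to_cell_counts(h: CaptureHistory) -> CellCounts:
    counts: dict[str, int] = {}
    for row in h.matrix:
        pat = "".join("1" if v else "0" for v in row)
        counts[pat] = counts.get(pat, 0) + 1
    return CellCounts(h.episode_labels, counts)


def to_capture_history(c: CellCounts) -> CaptureHistory:
    """Expand pattern counts into one row per individual (canonical pattern order)."""
    rows = []
    for pat in c.all_patterns():
        cnt = c.counts.get(pat, 0)
        if cnt:
            rows.append(np.tile([int(d) for d in pat], (cnt, 1)))
    if not rows:
        raise CaptureDataError("empty cell-count table")
    return CaptureHistory(np.concatenate(rows), c.labels)


def read_capture_history(path, source_columns: Sequence[str]) -> CaptureHistory:
    """Read a capture-history CSV (header ``id,<source1>,...``) into a matrix."""
    df = pd.read_csv(path)
    missing = [s for s in source_columns if s not in df.columns]
    if missing:
        raise CaptureDataError(f"missing source columns {missing} in {path}")
    sub = df[list(source_columns)]
    vals = sub.to_numpy()
    if not np.isin(vals, (0, 1)).all():
        bad = sub[~sub.isin((0, 1)).all(axis=1)].index[0]
        raise CaptureDataError(f"non-binary capture indicator on data row {bad} of {path}")
    zero = np.flatnonzero(vals.sum(axis=1) == 0)
    if zero.size:
        raise CaptureDataError(
            f"data row {zero[0]} of {path} has no captures (all-zero capture history)"
        )
    return CaptureHistory(vals, tuple(source_columns))


def read_cell_counts(path, labels: Sequence[str] | None = None) -> CellCounts:
    """Read a cell-count CSV with header ``pattern,count``.

    Source labels may be given explicitly; otherwise a ``# sources: A,B,C``
    comment on the first line is honoured, falling back to ``S1..ST``.
    """
    import io

    if hasattr(path, "read"):
        text = path.read()
    else:
        text = Path(path).read_text()
    header_labels = None
    first = text.splitlines()[0] if text else ""
    if first.startswith("#"):
        txt = first.lstrip("#").strip()
        if txt.lower().startswith("sources:"):
            header_labels = tuple(s.strip() for s in txt.split(":", 1)[1].split(","))
    df = pd.read_csv(io.StringIO(text), comment="#", dtype={"pattern": str})
    for col in ("pattern", "count"):
        if col not in df.columns:
            raise CaptureDataError(f"cell-count file {path} lacks a {col!r} column")
    T = len(df["pattern"].iloc[0])
    if labels is None:
        labels = header_labels or tuple(f"S{i+1}" for i in range(T))
    return CellCounts(tuple(labels), dict(zip(df["pattern"], df["count"])))


def write_cell_counts(c: CellCounts, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sources: {','.join(c.labels)}\n")
        fh.write("pattern,count\n")
        for pat in c.all_patterns():
            if c.counts.get(pat, 0):
                fh.write(f"{pat},{c.counts[pat]}\n")


# ---------------------------------------------------------------------------
# packaged record-linkage fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FixtureValidation:
    """Outcome of checking a cell table against its published marginal totals."""

    checks: tuple[tuple[str, int, int], ...]  # (name, expected, actual)

    @property
    def passed(self) -> bool:
        return all(exp == act for _, exp, act in self.checks)

    @property
    def failures(self) -> list[str]:
        return [
            f"{name}: expected {exp}, fixture gives {act}"
            for name, exp, act in self.checks
            if exp != act
        ]

    def __str__(self) -> str:
        lines = [
            f"{'ok ' if exp == act else 'FAIL'} {name}: expected {exp}, got {act}"
            for name, exp, act in self.checks
        ]
        return "\n".join(lines)


def validate_fixture(c: CellCounts, checksums: Mapping) -> FixtureValidation:
    """Compare a cell table against published marginal totals.

    Recognised checksum keys: ``total`` (distinct observed cases),
    ``source_totals`` (mapping label -> list size), ``two_or_more_sources``,
    ``exactly_two_sources`` and ``all_three_sources``.  A mismatch yields a
    failed report, not an exception.
    """
    checks: list[tuple[str, int, int]] = []
    if "total" in checksums:
        checks.append(("total distinct cases", int(checksums["total"]), c.total))
    for label, expected in dict(checksums.get("source_totals", {})).items():
        checks.append((f"source {label}", int(expected), c.source_total(label)))
    if "two_or_more_sources" in checksums:
        checks.append(
            ("cases in >=2 sources", int(checksums["two_or_more_sources"]),
             c.count_by_breadth(2))
        )
    if "exactly_two_sources" in checksums:
        checks.append(
            ("cases in exactly 2 sources", int(checksums["exactly_two_sources"]),
             c.count_by_breadth(2, exact=True))
        )
    if "all_three_sources" in checksums:
        checks.append(
            ("cases in all 3 sources", int(checksums["all_three_sources"]),
             c.count_by_breadth(3))
        )
    if not checks:
        raise CaptureDataError("no recognised checksum keys supplied")
    return FixtureValidation(tuple(checks))


FIXTURE_NAMES = ("breast", "colorectal")


def _fixture_dir():
    return resources.files("crcapture") / "fixtures"


def fixture_checksums(name: str) -> dict:
    if name not in FIXTURE_NAMES:
        raise CaptureDataError(f"unknown fixture {name!r}; have {FIXTURE_NAMES}")
    with (_fixture_dir() / f"{name}_checksums.json").open() as fh:
        return json.load(fh)


def load_fixture(name: str) -> CellCounts:
    """Load a packaged record-linkage table, verifying its checksum sidecar."""
    if name not in FIXTURE_NAMES:
        raise CaptureDataError(f"unknown fixture {name!r}; have {FIXTURE_NAMES}")
    with (_fixture_dir() / f"{name}_cells.csv").open() as fh:
        cells = read_cell_counts(fh)
    report = validate_fixture(cells, fixture_checksums(name))
    if not report.passed:
        raise CaptureDataError(
            f"packaged fixture {name!r} failed checksum validation:\n{report}"
        )
    return cells


# ---------------------------------------------------------------------------
# covariate tables and episode expansion
# ---------------------------------------------------------------------------

AGE_BANDS: tuple[str, ...] = ("50-54", "55-59", "60-64", "65-69", "70-75")


def age_band(age: int) -> str:
    """Five-year band over the study range 50-75 (upper band closed)."""
    if not 50 <= age <= 75:
        raise CaptureDataError(f"age {age} outside the declared range 50-75")
    return AGE_BANDS[min((int(age) - 50) // 5, 4)]


@dataclass(frozen=True)
class CovariateTable:
    """Per-individual capture indicators plus heterogeneity covariates.

    ``data`` holds one row per observed individual with binary capture columns
    (one per source) and covariate columns.  ``levels`` declares the admitted
    level set of every categorical covariate; the derived ``age_band`` column
    is added automatically when an ``age`` column is present.
    """

    data: pd.DataFrame
    sources: tuple[str, ...]
    levels: Mapping[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        df = self.data.copy()
        for s in self.sources:
            if s not in df.columns:
                raise CaptureDataError(f"missing capture column {s!r}")
            if not df[s].isin((0, 1)).all():
                raise CaptureDataError(f"non-binary capture indicator in column {s!r}")
        if df[list(self.sources)].sum(axis=1).eq(0).any():
            raise CaptureDataError("covariate table contains an uncaptured individual")
        levels = dict(self.levels)
        if "age" in df.columns and "age_band" not in df.columns:
            df["age_band"] = [age_band(a) for a in df["age"]]
            levels.setdefault("age_band", AGE_BANDS)
        for cov, lv in levels.items():
            if cov not in df.columns:
                raise CaptureDataError(f"declared covariate {cov!r} absent from table")
            bad = ~df[cov].isin(lv)
            if bad.any():
                val = df.loc[bad, cov].iloc[0]
                raise CaptureDataError(
                    f"covariate {cov!r} has value {val!r} outside declared levels {lv}"
                )
        object.__setattr__(self, "data", df)
        object.__setattr__(self, "sources", tuple(self.sources))
        object.__setattr__(self, "levels", levels)

    @property
    def n(self) -> int:
        return len(self.data)

    def capture_history(self) -> CaptureHistory:
        return CaptureHistory(self.data[list(self.sources)].to_numpy(), self.sources)


@dataclass(frozen=True)
class EpisodeMap:
    """Ordered (source, covariate, level) triples defining expanded episodes.

    ``covariate is None`` denotes a plain source episode (capture by the source
    regardless of covariates).  Each triple must be unique.
    """

    triples: tuple[tuple[str, str | None, object], ...]

    def __post_init__(self):
        trips = tuple((s, c, l) for s, c, l in self.triples)
        if len(set(trips)) != len(trips):
            raise CaptureDataError("duplicate episode in map")
        object.__setattr__(self, "triples", trips)

    @property
    def total_episodes(self) -> int:
        return len(self.triples)

    def labels(self) -> tuple[str, ...]:
        out = []
        for s, c, l in self.triples:
            out.append(s if c is None else f"{s}:{c}={l}")
        return tuple(out)


def expand_episodes(t: CovariateTable, m: EpisodeMap) -> CaptureHistory:
    """Expand per-source captures into covariate-specific capture episodes.

    Individual i scores 1 in episode (s, c, l) iff i was captured by source s
    and i's covariate c has level l.  The output feeds the Mth machinery
    unchanged, turning suspected heterogeneity covariates into extra capture
    episodes.
    """
    cols = []
    for s, cov, lvl in m.triples:
        if s not in t.sources:
            raise CaptureDataError(f"episode map names unknown source {s!r}")
        cap = t.data[s].to_numpy()
        if cov is None:
            cols.append(cap)
            continue
        if cov not in t.data.columns:
            raise CaptureDataError(f"episode map names unknown covariate {cov!r}")
        if cov in t.levels and lvl not in t.levels[cov]:
            raise CaptureDataError(
                f"episode map level {lvl!r} outside declared levels of {cov!r}"
            )
        cols.append(cap * (t.data[cov].to_numpy() == lvl))
    return CaptureHistory(np.column_stack(cols), m.labels())


def _bands_by_source(sources: Iterable[str]) -> list[tuple[str, str, object]]:
    return [(s, "age_band", b) for s in sources for b in AGE_BANDS]


def breast_episode_map(sources: Sequence[str] = ("HR", "MTM", "CSP")) -> EpisodeMap:
    """21 breast-cancer episodes: 5 age bands x 3 sources + screening history x 3 sources."""
    triples = _bands_by_source(sources)
    for s in sources:
        for lvl in (0, 1):
            triples.append((s, "screening", lvl))
    return EpisodeMap(tuple(triples))


def colorectal_episode_map(sources: Sequence[str] = ("HR", "MTM", "CSP")) -> EpisodeMap:
    """24 colorectal episodes: age bands x 3 + gender x 3 + metastasis-positive x 3."""
    triples = _bands_by_source(sources)
    for s in sources:
        for lvl in ("F", "M"):
            triples.append((s, "gender", lvl))
    for s in sources:
        triples.append((s, "metastasis", 1))
    return EpisodeMap(tuple(triples))
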