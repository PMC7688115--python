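"""From dated sherd records to presence/absence pattern matrices.

A sherd record carries a typological dating range; its evidential weight is
spread uniformly over that range (aoristic, cumulative-probability dating:
1/duration per calendar year).  Per site and ware the per-year weights of all
records are summed and capped at one, giving the probability that the ware
was in use in that year; averaging within 10-year bins and across sites
yields the two observed summaries:

* pattern A -- per bin, the share of sites at which each ware is present;
* pattern B -- per bin, the distribution of sites over the number of
  distinct wares present (0..5).

Under probabilistic presence, pattern B treats the per-ware presence
probabilities at a site as independent events and expands the distribution
of the count exactly (Poisson binomial).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .chronology import WARES

__all__ = [
    "SherdRecord",
    "TimeGrid",
    "PatternMatrix",
    "parse_records",
    "annual_weight",
    "presence_probability",
    "empirical_patterns",
    "write_patterns",
    "read_pattern",
]


@dataclass(frozen=True)
class SherdRecord:
    """One datable tableware find: site, ware, inclusive calendar-year range."""

    site_id: str
    ware: str
    year_from: int
    year_to: int

    def __post_init__(self) -> None:
        if self.year_from > self.year_to:
            raise ValueError(
                f"record dated backwards: {self.year_from} > {self.year_to}"
            )


@dataclass(frozen=True)
class TimeGrid:
    """Half-open 10-year bins covering the study period.

    ``P`` bins of ``bin_width_years`` tile ``[start_year, end_year)``; the
    default is 50 bins of 10 years over -200..300 (astronomical numbering,
    200 BC encoded as -200).
    """

    start_year: int = -200
    end_year: int = 300
    bin_width_years: int = 10

    def __post_init__(self) -> None:
        span = self.end_year - self.start_year
        if span <= 0 or span % self.bin_width_years:
            raise ValueError(
                f"bin width {self.bin_width_years} does not tile "
                f"[{self.start_year}, {self.end_year})"
            )

    @property
    def P(self) -> int:
        return (self.end_year - self.start_year) // self.bin_width_years

    @property
    def n_years(self) -> int:
        return self.end_year - self.start_year

    def bin_starts(self) -> np.ndarray:
        return self.start_year + self.bin_width_years * np.arange(self.P)


DEFAULT_GRID = TimeGrid()


@dataclass
class PatternMatrix:
    """A P x |W| matrix of proportions over time bins.

    ``kind`` is "A" (share of sites with each ware) or "B" (share of sites
    with exactly k distinct wares; rows sum to one).
    """

    kind: str
    values: np.ndarray
    categories: tuple[str, ...]
    grid: TimeGrid = field(default_factory=TimeGrid)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in ("A", "B"):
            raise ValueError(f"kind must be 'A' or 'B', got {self.kind!r}")
        if self.values.ndim != 2 or self.values.shape[1] != len(self.categories):
            raise ValueError("values must be P x |categories|")
        if np.any(self.values < -1e-12) or np.any(self.values > 1 + 1e-12):
            raise ValueError("pattern entries must lie in [0, 1]")
        if self.kind == "B":
            rows = self.values.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > 1e-9):
                raise ValueError("pattern-B rows must each sum to 1")

    @property
    def P(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.categories))
        df.insert(0, "bin_start", self.grid.bin_starts())
        return df


def annual_weight(record: SherdRecord) -> float:
    """Uniform per-year probability of a record: 1 / duration of its range.

    A find dated AD 1--10 contributes 0.10 to each of those ten years; a
    find dated AD 1--100 contributes 0.01; a single-year range contributes 1.
    """
    return 1.0 / (record.year_to - record.year_from + 1)


def _year_scores(
    records: Iterable[SherdRecord], grid: TimeGrid, cap: bool = True
) -> np.ndarray:
    """Summed per-year weights over the grid's years, optionally capped at 1."""
    scores = np.zeros(grid.n_years)
    for rec in records:
        lo = max(rec.year_from, grid.start_year)
        hi = min(rec.year_to, grid.end_year - 1)
        if lo > hi:
            continue
        scores[lo - grid.start_year : hi - grid.start_year + 1] += annual_weight(rec)
    if cap:
        np.minimum(scores, 1.0, out=scores)
    return scores


def presence_probability(
    records: Iterable[SherdRecord],
    site: str,
    ware: str,
    grid: TimeGrid = DEFAULT_GRID,
) -> np.ndarray:
    """Per-bin probability that ``ware`` was in use at ``site``.

    Per-year scores (capped at one) are averaged over the years of each bin.
    Records outside the grid simply contribute nothing.
    """
    sel = [r for r in records if r.site_id == site and r.ware == ware]
    scores = _year_scores(sel, grid)
    return scores.reshape(grid.P, grid.bin_width_years).mean(axis=1)


def parse_records(
    source: str | Path | pd.DataFrame,
    wares: Sequence[str] = WARES,
    on_error: str = "warn",
) -> list[SherdRecord]:
    """Read a sherd table (columns site, ware, year_from, year_to).

    Rows with unknown wares, unparsable years or backwards date ranges are
    rejected; with ``on_error="warn"`` each rejection raises a warning, with
    ``"raise"`` the first one aborts.  An empty table is an error.
    """
    if on_error not in ("warn", "raise"):
        raise ValueError("on_error must be 'warn' or 'raise'")
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source)
    required = {"site", "ware", "year_from", "year_to"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    if df.empty:
        raise ValueError("empty sherd table")
    known = set(wares)
    records: list[SherdRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        problem = None
        ware = str(row.ware)
        if ware not in known:
            problem = f"unknown ware {ware!r}"
        else:
            try:
                y0, y1 = int(row.year_from), int(row.year_to)
            except (TypeError, ValueError):
                problem = f"unparsable years {row.year_from!r}..{row.year_to!r}"
            else:
                if y0 > y1:
                    problem = f"backwards range {y0}..{y1}"
        if problem is not None:
            msg = f"row {idx}: {problem}; row rejected"
            if on_error == "raise":
                raise ValueError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        records.append(SherdRecord(str(row.site), ware, y0, y1))
    if not records:
        raise ValueError("no valid records in table")
    return records


def _site_ware_presence(
    records: Sequence[SherdRecord],
    sites: Sequence[str],
    wares: Sequence[str],
    grid: TimeGrid,
    presence: str,
) -> np.ndarray:
    """(n_sites, n_wares, P) presence probabilities."""
    site_idx = {s: i for i, s in enumerate(sites)}
    ware_idx = {w: i for i, w in enumerate(wares)}
    scores = np.zeros((len(sites), len(wares), grid.n_years))
    for rec in records:
        si = site_idx.get(rec.site_id)
        wi = ware_idx.get(rec.ware)
        if si is None or wi is None:
            raise ValueError(f"record outside declared registry: {rec}")
        lo = max(rec.year_from, grid.start_year)
        hi = min(rec.year_to, grid.end_year - 1)
        if lo > hi:
            continue  # dated entirely outside the grid: contributes zeros
        scores[si, wi, lo - grid.start_year : hi - grid.start_year + 1] += annual_weight(rec)
    if presence == "threshold":
        scores = (scores > 0).astype(float)
    else:
        np.minimum(scores, 1.0, out=scores)
    shape = (len(sites), len(wares), grid.P, grid.bin_width_years)
    return scores.reshape(shape).mean(axis=3)


def _poisson_binomial(probs: np.ndarray) -> np.ndarray:
    """Distribution of the count of successes from independent Bernoullis.

    ``probs`` has shape (..., n); returns shape (..., n+1) summing to one on
    the last axis.  Exact dynamic-programming convolution.
    """
    n = probs.shape[-1]
    dist = np.zeros(probs.shape[:-1] + (n + 1,))
    dist[..., 0] = 1.0
    for w in range(n):
        p = probs[..., w : w + 1]
        new = dist * (1.0 - p)
        new[..., 1:] += dist[..., :-1] * p
        dist = new
    return dist


def empirical_patterns(
    records: Sequence[SherdRecord],
    grid: TimeGrid = DEFAULT_GRID,
    wares: Sequence[str] = WARES,
    sites: Sequence[str] | None = None,
    presence: str = "probabilistic",
) -> tuple[PatternMatrix, PatternMatrix]:
    """Observed pattern matrices A and B from a sherd table.

    ``presence="probabilistic"`` (default) keeps the capped cumulative
    probabilities; ``"threshold"`` scores any positive evidence as presence 1.
    ``sites`` may be given explicitly (e.g. to include sites without records);
    otherwise the sites observed in the records are used.
    """
    if presence not in ("probabilistic", "threshold"):
        raise ValueError("presence must be 'probabilistic' or 'threshold'")
    if sites is None:
        sites = sorted({r.site_id for r in records})
    if not sites:
        raise ValueError("empty site list")
    probs = _site_ware_presence(records, sites, wares, grid, presence)
    a_vals = probs.mean(axis=0).T  # (P, n_wares)
    b_site = _poisson_binomial(np.moveaxis(probs, 1, 2))  # (n_sites, P, n_wares+1)
    b_vals = b_site.mean(axis=0)
    A = PatternMatrix("A", a_vals, tuple(wares), grid)
    B = PatternMatrix("B", b_vals, tuple(str(k) for k in range(len(wares) + 1)), grid)
    return A, B


def write_patterns(
    A: PatternMatrix,
    B: PatternMatrix,
    out_dir: str | Path,
    metadata: dict | None = None,
) -> dict[str, Path]:
    """Write pattern_A.csv, pattern_B.csv and a JSON metadata sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "A": out / "pattern_A.csv",
        "B": out / "pattern_B.csv",
        "meta": out / "patterns_meta.json",
    }
    A.to_frame().to_csv(paths["A"], index=False)
    B.to_frame().to_csv(paths["B"], index=False)
    meta = {
        "grid": {
            "start_year": A.grid.start_year,
            "end_year": A.grid.end_year,
            "bin_width_years": A.grid.bin_width_years,
        },
        "categories_A": list(A.categories),
        "categories_B": list(B.categories),
    }
    if metadata:
        meta.update(metadata)
    paths["meta"].write_text(json.dumps(meta, indent=2))
    return paths


def read_pattern(path: str | Path, kind: str) -> PatternMatrix:
    """Read a pattern CSV written by :func:`write_patterns`."""
    df = pd.read_csv(path)
    starts = df.pop("bin_start").to_numpy()
    width = int(starts[1] - starts[0]) if len(starts) > 1 else 10
    grid = TimeGrid(int(starts[0]), int(starts[-1] + width), width)
    return PatternMatrix(kind, df.to_numpy(float), tuple(df.columns), grid)
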