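"""Synthetic sherd tables and pseudo-observed patterns.

The generator emulates the statistical shape of the empirical record set:
~178 sites of very unequal richness (most contribute zero or one ware),
five wares with dated availability windows, a strong early-ware (ESA)
dominance that declines once the western import (ITS) enters the market,
and typological dating ranges of mixed width -- some decade-scale, some
spanning one to three centuries.  Record dates always fall inside the
generating ware's availability window.  No attempt is made to fit the real
database numerically; the point is that every pipeline stage can be
exercised, with known generating parameters, without any download.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .abm import SimParams, run_simulation
from .chronology import Chronology, default_chronology, windows
from .patterns import PatternMatrix, SherdRecord, TimeGrid
from .summaries import simulated_patterns

__all__ = ["SynthConfig", "gen_sherd_table", "records_to_frame", "write_sherd_table", "gen_pseudo_observed"]

# Relative record abundance per ware: qualitative early-ware dominance.
DEFAULT_WARE_WEIGHTS = {"ESA": 0.42, "ESB": 0.08, "ESC": 0.20, "ESD": 0.17, "ITS": 0.13}


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the synthetic sherd table.

    ``adoption_scale`` rescales every site/ware adoption probability (0
    disables all adoption and yields an empty table); ``width_mix`` is the
    (narrow range, broad range, P(narrow)) dating-width mixture in years.
    """

    n_sites: int = 178
    n_records: int = 8730
    ware_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WARE_WEIGHTS)
    )
    width_mix: tuple[tuple[int, int], tuple[int, int], float] = ((10, 50), (100, 300), 0.6)
    adoption_scale: float = 1.0
    site_size_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.n_sites < 1:
            raise ValueError("need at least one site")
        if self.n_records < 0 or self.adoption_scale < 0:
            raise ValueError("n_records and adoption_scale must be nonnegative")


def _clip_range(mid: float, width: float, lo: int, hi: int) -> tuple[int, int]:
    y0 = int(round(mid - width / 2.0))
    y1 = int(round(mid + width / 2.0))
    y0, y1 = max(lo, y0), min(hi, y1)
    if y0 > y1:
        y0 = y1 = min(hi, max(lo, int(round(mid))))
    return y0, y1


def gen_sherd_table(
    config: SynthConfig = SynthConfig(),
    rng: np.random.Generator | int | None = None,
    chronology: Chronology | None = None,
) -> list[SherdRecord]:
    """Generate an ICRATES-like sherd table with known structure.

    Per site and ware an adoption indicator is drawn (probability increasing
    with site size and ware popularity); the requested record count is then
    allocated across adopted site/ware pairs, and each record receives a
    mid-date inside the ware's availability window (ESA skewed early) and a
    dating width from the narrow/broad mixture, clipped to the window.
    """
    rng = np.random.default_rng(rng)
    chronology = chronology if chronology is not None else default_chronology()
    wins = windows(chronology, config.ware_weights.keys())
    sites = [f"S{i + 1:03d}" for i in range(config.n_sites)]
    if config.n_records == 0:
        return []

    ware_list = list(config.ware_weights)
    wt = np.array([config.ware_weights[w] for w in ware_list], float)
    wt = wt / wt.sum()
    site_size = rng.lognormal(0.0, config.site_size_sigma, config.n_sites)
    site_size /= site_size.mean()

    # site/ware adoption: common wares reach big sites almost surely,
    # rare wares and small sites mostly stay empty
    p_adopt = 1.0 - np.exp(-3.0 * config.adoption_scale * np.outer(site_size, wt))
    adopted = rng.random(p_adopt.shape) < p_adopt
    if not adopted.any():
        if config.adoption_scale == 0:
            return []
        raise ValueError("no site adopted any ware; infeasible configuration")

    alloc_w = np.where(adopted, np.outer(site_size, wt), 0.0).ravel()
    counts = rng.multinomial(config.n_records, alloc_w / alloc_w.sum())

    (nlo, nhi), (blo, bhi), p_narrow = config.width_mix
    records: list[SherdRecord] = []
    for flat, n in enumerate(counts):
        if n == 0:
            continue
        si, wi = divmod(flat, len(ware_list))
        ware = ware_list[wi]
        lo, hi = wins[ware]
        span = hi - lo
        for _ in range(n):
            if ware == "ESA":  # early skew: dominance before the ITS window opens
                frac = rng.beta(1.0, 1.6)
            else:
                frac = rng.random()
            mid = lo + frac * span
            if rng.random() < p_narrow:
                width = rng.uniform(nlo, nhi)
            else:
                width = rng.uniform(blo, bhi)
            y0, y1 = _clip_range(mid, width, lo, hi)
            records.append(SherdRecord(sites[si], ware, y0, y1))
    return records


def records_to_frame(records: list[SherdRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "site": [r.site_id for r in records],
            "ware": [r.ware for r in records],
            "year_from": [r.year_from for r in records],
            "year_to": [r.year_to for r in records],
        }
    )


def write_sherd_table(
    records: list[SherdRecord],
    path: str | Path,
    config: SynthConfig | None = None,
    seed: int | None = None,
) -> Path:
    """Write the table as CSV plus a JSON generation manifest alongside."""
    path = Path(path)
    records_to_frame(records).to_csv(path, index=False)
    manifest = {"n_records": len(records)}
    if config is not None:
        manifest.update(
            n_sites=config.n_sites,
            requested_records=config.n_records,
            adoption_scale=config.adoption_scale,
        )
    if seed is not None:
        manifest["seed"] = seed
    path.with_suffix(".manifest.json").write_text(json.dumps(manifest, indent=2))
    return path


def gen_pseudo_observed(
    params: SimParams,
    chronology: Chronology | None = None,
    seed: int | np.random.Generator | None = 0,
    grid: TimeGrid | None = None,
) -> tuple[PatternMatrix, PatternMatrix, SimParams]:
    """Run the market model once and return its patterns as pseudo-data.

    The returned patterns, tagged with the true generating parameters, serve
    as the "observed data" in parameter-recovery and model-selection
    experiments.
    """
    log = run_simulation(params, chronology, rng=seed)
    A, B = simulated_patterns(log, grid=grid)
    return A, B, params
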