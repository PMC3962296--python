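"""Sliding-window F_ST genome scan with a bootstrap null.

For one population pair, per-locus Weir-Cockerham theta values of
linkage-map-placed SNPs are averaged in 5-cM windows advanced in 1-cM steps
along each linkage group. Each window's mean is compared to a null built by
resampling, with replacement, as many per-locus theta values as the window
holds from the pair's complete set; windows whose mean exceeds the 95%
empirical quantile of the null are candidate selected regions. Following
standard practice the null starts at 1000 bootstrap replicates and is
refined to 5000 whenever a window exceeds the 90% quantile, so tail
quantiles are well resolved exactly where they matter.

Windows are anchored at 0 cM on each linkage group and use half-open
membership [start, start + width), so a locus belongs to exactly
width/step consecutive windows. Exceedance is strict and empirical
quantiles use the nearest-rank definition, so results are bit-reproducible
given the seed.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from radpopgen.genio import GenotypeDataset
from radpopgen import popstruct

logger = logging.getLogger(__name__)


@dataclass
class Window:
    linkage_group: int
    start_cM: float
    width_cM: float
    locus_ids: list[str]
    mean_theta: float = np.nan
    q90: float = np.nan
    q95: float = np.nan
    n_replicates: int = 0
    significant: bool = False

    @property
    def end_cM(self) -> float:
        return self.start_cM + self.width_cM

    @property
    def n_snps(self) -> int:
        return len(self.locus_ids)


@dataclass
class WindowScanResult:
    pop_i: str
    pop_j: str
    windows: list[Window]
    min_snps: int
    regions: list[tuple[int, float, float]] = field(default_factory=list)

    def tested_windows(self) -> list[Window]:
        return [w for w in self.windows if w.n_snps >= self.min_snps]

    def significant_windows(self) -> list[Window]:
        return [w for w in self.windows if w.significant]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "linkage_group": [w.linkage_group for w in self.windows],
                "start_cM": [w.start_cM for w in self.windows],
                "end_cM": [w.end_cM for w in self.windows],
                "n_snps": [w.n_snps for w in self.windows],
                "mean_theta": [w.mean_theta for w in self.windows],
                "null_q90": [w.q90 for w in self.windows],
                "null_q95": [w.q95 for w in self.windows],
                "n_replicates": [w.n_replicates for w in self.windows],
                "significant": [w.significant for w in self.windows],
            }
        )


def build_windows(
    positions: Mapping[str, tuple[int, float]],
    width: float = 5.0,
    step: float = 1.0,
    min_snps: int = 2,
) -> list[Window]:
    """Enumerate sliding windows over mapped loci.

    ``positions`` maps locus_id -> (linkage_group, cM). Windows start at
    0, step, 2*step, ... cM and are generated while start < the maximum
    mapped position on the linkage group; membership is half-open. Windows
    holding fewer than ``min_snps`` loci are recorded (so coverage is
    auditable) but are not eligible for testing.
    """
    if width <= 0 or step <= 0:
        raise ValueError("width and step must be positive")
    by_lg: dict[int, list[tuple[float, str]]] = {}
    for lid, (lg, cm) in positions.items():
        by_lg.setdefault(int(lg), []).append((float(cm), lid))
    windows: list[Window] = []
    for lg in sorted(by_lg):
        locs = sorted(by_lg[lg])
        max_pos = locs[-1][0]
        n_starts = int(math.floor(max_pos / step)) + 1 if max_pos > 0 else 1
        for k in range(n_starts):
            start = k * step
            if start >= max_pos and k > 0:
                break
            members = [lid for cm, lid in locs if start <= cm < start + width]
            windows.append(
                Window(linkage_group=lg, start_cM=start, width_cM=width, locus_ids=members)
            )
    _ = min_snps  # eligibility is decided by the scan, which stores min_snps
    return windows


def _nearest_rank_quantile(sorted_vals: np.ndarray, q: float) -> float:
    n = sorted_vals.size
    idx = max(int(math.ceil(q * n)), 1) - 1
    return float(sorted_vals[idx])


def bootstrap_null(
    n_snps: int,
    all_fst_values: np.ndarray,
    B: int,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """90% and 95% nearest-rank quantiles of bootstrap window means.

    Each replicate mean averages ``n_snps`` values drawn with replacement
    from the pair's complete per-locus theta set (negative values included).
    """
    all_fst_values = np.asarray(all_fst_values, dtype=float)
    if all_fst_values.size < 2:
        raise ValueError("need at least 2 per-locus theta values for the null")
    draws = rng.choice(all_fst_values, size=(B, n_snps), replace=True)
    means = np.sort(draws.mean(axis=1))
    return _nearest_rank_quantile(means, 0.90), _nearest_rank_quantile(means, 0.95)


def scan_pair(
    ds: GenotypeDataset,
    pop_i: str,
    pop_j: str,
    positions: Mapping[str, tuple[int, float]] | None = None,
    width: float = 5.0,
    step: float = 1.0,
    min_snps: int = 2,
    B1: int = 1000,
    B2: int = 5000,
    seed: int | None = None,
) -> WindowScanResult:
    """Sliding-window theta scan for one population pair.

    Per-locus pairwise theta is computed once; every window with at least
    ``min_snps`` member loci is tested against the bootstrap null at ``B1``
    replicates, escalating to ``B2`` exactly when the window mean exceeds
    the 90% quantile of the ``B1`` null. A window is significant when its
    mean strictly exceeds the 95% quantile at its final replicate count.
    ``positions`` defaults to the map placements carried by the dataset's
    loci.
    """
    if positions is None:
        positions = {
            l.locus_id: (l.linkage_group, l.map_position_cM)
            for l in ds.loci
            if l.mapped
        }
    fst = popstruct.wc_theta(ds, [pop_i, pop_j])
    theta = dict(zip(fst.locus_ids, fst.theta_per_locus))
    usable = {
        lid: pos
        for lid, pos in positions.items()
        if lid in theta and not np.isnan(theta[lid])
    }
    if len(usable) < min_snps:
        raise ValueError("fewer mapped loci with defined theta than min_snps")
    all_vals = np.array([theta[lid] for lid in sorted(usable)])

    windows = build_windows(usable, width=width, step=step, min_snps=min_snps)
    rng = np.random.default_rng(seed)
    for w in windows:
        if w.n_snps < min_snps:
            continue
        w.mean_theta = float(np.mean([theta[lid] for lid in w.locus_ids]))
        q90, q95 = bootstrap_null(w.n_snps, all_vals, B1, rng)
        w.n_replicates = B1
        if w.mean_theta > q90:
            q90, q95 = bootstrap_null(w.n_snps, all_vals, B2, rng)
            w.n_replicates = B2
        w.q90, w.q95 = q90, q95
        w.significant = bool(w.mean_theta > q95)
    result = WindowScanResult(pop_i=pop_i, pop_j=pop_j, windows=windows, min_snps=min_snps)
    result.regions = merge_regions(result)
    return result


def merge_regions(result: WindowScanResult) -> list[tuple[int, float, float]]:
    """Merge significant windows into regions per linkage group.

    Windows on the same linkage group whose half-open intervals overlap or
    touch coalesce into a single region [min start, max end).
    """
    sig = sorted(
        ((w.linkage_group, w.start_cM, w.end_cM) for w in result.significant_windows()),
    )
    regions: list[tuple[int, float, float]] = []
    for lg, start, end in sig:
        if regions and regions[-1][0] == lg and start <= regions[-1][2]:
            prev = regions[-1]
            regions[-1] = (lg, prev[1], max(prev[2], end))
        else:
            regions.append((lg, start, end))
    return regions


def cross_pair_summary(results: Sequence[WindowScanResult]) -> pd.DataFrame:
    """Per-cM count of population pairs with a significant region.

    For each linkage group and 1-cM bin [k, k+1), counts how many scanned
    pairs have a significant region covering the bin. Useful for a
    genome-wide shading plot of shared candidate regions.
    """
    if not results:
        raise ValueError("no scan results supplied")
    max_end: dict[int, float] = {}
    for res in results:
        for w in res.windows:
            max_end[w.linkage_group] = max(max_end.get(w.linkage_group, 0.0), w.end_cM)
    rows = []
    for lg in sorted(max_end):
        n_bins = int(math.ceil(max_end[lg]))
        counts = np.zeros(n_bins, dtype=int)
        for res in results:
            covered = np.zeros(n_bins, dtype=bool)
            for r_lg, start, end in res.regions:
                if r_lg != lg:
                    continue
                lo = int(math.floor(start))
                hi = min(int(math.ceil(end)), n_bins)
                covered[lo:hi] = True
            counts += covered
        for k in range(n_bins):
            rows.append({"linkage_group": lg, "bin_start_cM": k, "n_significant_pairs": int(counts[k])})
    return pd.DataFrame(rows)
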