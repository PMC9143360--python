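"""Recombination-congruence statistics.

Two regions of a genome alignment that share one evolutionary history
produce strongly correlated pairwise distances: each sequence pair plots
near a single regression line in a distance-vs-distance scatter (a pairwise
distance correspondence plot, PDCP). Recombination between the regions
breaks that congruence, scattering points off the line; the root mean
square error (RMSE) of the points about the fitted line quantifies it.

Tiling the alignment with sliding windows and computing the PDCP RMSE for
every window pair yields the pairwise distance deviation matrix (PDDM), a
heatmap whose red (high-RMSE) blocks mark recombination-prone region pairs
and whose quiet blocks mark regions that evolve clonally — the basis for
picking a classification region free of long-distance recombination.

A Simplot-style similarity scan (per-window identity of a query against a
panel) complements these pair statistics by localising mosaic structure in
individual genomes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .distance import DistanceMatrix, encode_msa, pairwise_matrix_from_codes, _INVALID
from .msa import Msa, Region, RegionBoundsError, extract_region

logger = logging.getLogger(__name__)


class InsufficientDataError(ValueError):
    """Fewer defined distance pairs than a regression needs."""


@dataclass
class PdcpResult:
    """A pairwise distance correspondence plot between two regions.

    One point per sequence pair whose distance is defined in both regions;
    ``slope``/``intercept`` are the OLS fit of ``d_b`` on ``d_a`` and
    ``rmse`` the root mean square residual about that line. ``degenerate``
    marks a zero-variance fit (slope forced to 0, intercept = mean d_b).
    """

    region_a: Region
    region_b: Region
    pair_ids: list[tuple[str, str]]
    d_a: np.ndarray
    d_b: np.ndarray
    slope: float
    intercept: float
    rmse: float
    n_omitted: int = 0
    degenerate: bool = False

    @property
    def n_points(self) -> int:
        return len(self.pair_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id_a": [p[0] for p in self.pair_ids],
                "id_b": [p[1] for p in self.pair_ids],
                f"d_{self.region_a}": self.d_a,
                f"d_{self.region_b}": self.d_b,
            }
        )

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")


def _ols_rmse(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float, bool]:
    """OLS of y on x; returns (slope, intercept, rmse, degenerate)."""
    if np.var(x) == 0.0:
        intercept = float(np.mean(y))
        resid = y - intercept
        return 0.0, intercept, float(np.sqrt(np.mean(resid**2))), True
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    return float(slope), float(intercept), float(np.sqrt(np.mean(resid**2))), False


def pdcp_from_matrices(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    region_a: Region,
    region_b: Region,
) -> PdcpResult:
    """PDCP from two precomputed distance matrices over the same labels."""
    if dm_a.labels != dm_b.labels:
        raise ValueError("distance matrices must share labels and order")
    da = dm_a.condensed()
    db = dm_b.condensed()
    ok = ~(np.isnan(da) | np.isnan(db))
    n_omitted = int((~ok).sum())
    if n_omitted:
        logger.warning("PDCP %s vs %s: %d pair(s) undefined, omitted",
                       region_a, region_b, n_omitted)
    if ok.sum() < 3:
        raise InsufficientDataError(
            f"PDCP {region_a} vs {region_b}: only {int(ok.sum())} defined pairs"
        )
    labels = dm_a.labels
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    pair_ids = [
        (labels[i], labels[j]) for i, j, keep in zip(iu[0], iu[1], ok) if keep
    ]
    x, y = da[ok], db[ok]
    slope, intercept, rmse, degen = _ols_rmse(x, y)
    if degen:
        logger.warning("PDCP %s vs %s: zero variance in d_a, degenerate fit",
                       region_a, region_b)
    return PdcpResult(region_a, region_b, pair_ids, x, y,
                      slope, intercept, rmse, n_omitted, degen)


def pdcp(msa: Msa, region_a: Region, region_b: Region) -> PdcpResult:
    """Pairwise distance correspondence plot between two alignment regions."""
    for r in (region_a, region_b):
        if r.end > msa.alignment_length:
            raise RegionBoundsError(f"region {r} outside alignment")
    dm_a = _region_matrix(msa, region_a)
    dm_b = _region_matrix(msa, region_b)
    return pdcp_from_matrices(dm_a, dm_b, region_a, region_b)


def _region_matrix(msa: Msa, region: Region) -> DistanceMatrix:
    return pairwise_matrix_from_codes(
        encode_msa(extract_region(msa, region)), list(msa.ids)
    )


def sliding_windows(alignment_length: int, window: int, step: int) -> list[Region]:
    """Full-length sliding windows tiling the alignment.

    Windows start at 1, 1+step, 1+2*step, ... while they fit; if the last
    regular window ends short of the alignment, one final window anchored
    at the alignment end is appended so the scan covers every column.
    Trailing partial windows are never produced.
    """
    if window > alignment_length:
        raise RegionBoundsError("window longer than alignment")
    if step < 1:
        raise ValueError("step must be >= 1")
    out: list[Region] = []
    start = 1
    while start + window - 1 <= alignment_length:
        out.append(Region(start, start + window - 1))
        start += step
    if out[-1].end < alignment_length:
        out.append(Region(alignment_length - window + 1, alignment_length))
    return out


@dataclass
class PddmGrid:
    """Pairwise distance deviation matrix over sliding windows.

    ``rmse`` is symmetric by construction: the PDCP regression is directed
    (fitting d_j on d_i and d_i on d_j give different residuals), so each
    cell stores the mean of the two directed RMSEs; the raw directed values
    are kept in ``rmse_directed`` (row = predictor window). Cells with too
    few defined pairs are NaN.
    """

    window: int
    step: int
    windows: list[Region]
    rmse: np.ndarray
    rmse_directed: np.ndarray
    degenerate: bool = False

    @property
    def n_windows(self) -> int:
        return len(self.windows)

    def window_means(self) -> np.ndarray:
        """Mean RMSE of each window against all others (NaN-aware)."""
        m = self.rmse.copy()
        np.fill_diagonal(m, np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(m, axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        names = [str(w) for w in self.windows]
        return pd.DataFrame(self.rmse, index=names, columns=names)

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", na_rep="NA", index_label="")


def pddm(msa: Msa, window: int = 500, step: int = 250) -> PddmGrid:
    """Pairwise distance deviation matrix over all sliding-window pairs.

    Per-window distance matrices are computed once, then every unordered
    window pair gets a PDCP RMSE (mean of both regression directions).
    An alignment with no distance variance anywhere (e.g. identical
    sequences) yields an all-degenerate grid, flagged via ``degenerate``.
    """
    wins = sliding_windows(msa.alignment_length, window, step)
    codes = encode_msa(msa)
    mats = [
        pairwise_matrix_from_codes(codes[:, w.slice], list(msa.ids)) for w in wins
    ]
    k = len(wins)
    directed = np.zeros((k, k))
    defined = np.ones((k, k), dtype=bool)
    any_nondegenerate = False
    for i in range(k):
        for j in range(i + 1, k):
            try:
                r_ij = pdcp_from_matrices(mats[i], mats[j], wins[i], wins[j])
                r_ji = pdcp_from_matrices(mats[j], mats[i], wins[j], wins[i])
            except InsufficientDataError:
                logger.warning("PDDM cell %s x %s: insufficient data",
                               wins[i], wins[j])
                defined[i, j] = defined[j, i] = False
                continue
            directed[i, j] = r_ij.rmse
            directed[j, i] = r_ji.rmse
            if not (r_ij.degenerate and r_ji.degenerate):
                any_nondegenerate = True
    sym = (directed + directed.T) / 2.0
    sym[~defined] = np.nan
    directed = directed.copy()
    directed[~defined] = np.nan
    np.fill_diagonal(sym, 0.0)
    np.fill_diagonal(directed, 0.0)
    grid = PddmGrid(window, step, wins, sym, directed,
                    degenerate=not any_nondegenerate)
    if grid.degenerate:
        logger.warning("PDDM: no window pair with distance variance; "
                       "grid is degenerate")
    return grid


class NoLowRecombinationSpan(ValueError):
    """No window qualifies as low-recombination at the given quantile."""


def low_recombination_span(grid: PddmGrid, quantile: float = 0.25) -> Region:
    """Longest contiguous run of quiet windows, merged into one region.

    A window qualifies when its mean RMSE against all other windows is at
    or below the given quantile of all window means. Ties between equally
    long runs break to the earliest. This is an explicit, reproducible
    stand-in for reading the low-RMSE block off a PDDM heatmap by eye.
    """
    means = grid.window_means()
    ok = np.isfinite(means)
    if ok.sum() < 2:
        raise InsufficientDataError("need >= 2 windows with defined RMSE")
    cut = np.nanquantile(means, quantile)
    low = ok & (means <= cut)
    if not low.any():
        raise NoLowRecombinationSpan(
            f"no window mean at or below quantile {quantile}"
        )
    best_start, best_len = 0, 0
    run_start = None
    for i, flag in enumerate(list(low) + [False]):
        if flag and run_start is None:
            run_start = i
        elif not flag and run_start is not None:
            if i - run_start > best_len:
                best_start, best_len = run_start, i - run_start
            run_start = None
    first = grid.windows[best_start]
    last = grid.windows[best_start + best_len - 1]
    return Region(first.start, last.end)


@dataclass
class SimilarityTrack:
    """Per-window similarity of one query against a panel of sequences.

    Similarity is 1 - windowed p-distance over the window's comparable
    sites; NaN where a window has none. ``centers`` are window midpoints in
    alignment columns.
    """

    query_id: str
    panel_ids: list[str]
    window: int
    step: int
    windows: list[Region] = field(repr=False)
    centers: np.ndarray = field(repr=False)
    similarity: np.ndarray = field(repr=False)  # (n_windows, n_panel)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.similarity, columns=self.panel_ids)
        df.insert(0, "center", self.centers)
        df.insert(0, "end", [w.end for w in self.windows])
        df.insert(0, "start", [w.start for w in self.windows])
        return df

    def to_tsv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, na_rep="NA")


def similarity_scan(
    msa: Msa, query_id: str, window: int = 1000, step: int = 40
) -> SimilarityTrack:
    """Simplot-style similarity scan of a query against the rest of an MSA.

    Windows follow the plain convention floor((L - window)/step) + 1 full
    windows starting at 1, 1+step, ...; no end-anchored extra window.
    """
    if query_id not in msa.ids:
        raise ValueError(f"query {query_id!r} not in alignment")
    if len(msa) < 2:
        raise ValueError("need at least one non-query sequence")
    if window > msa.alignment_length:
        raise RegionBoundsError("window longer than alignment")
    panel_ids = [i for i in msa.ids if i != query_id]
    codes = encode_msa(msa)
    qi = msa.ids.index(query_id)
    pidx = [msa.ids.index(i) for i in panel_ids]

    n_win = (msa.alignment_length - window) // step + 1
    wins = [Region(1 + k * step, window + k * step) for k in range(n_win)]
    sim = np.full((n_win, len(panel_ids)), np.nan)
    q = codes[qi]
    qvalid = q != _INVALID
    for k, w in enumerate(wins):
        sl = w.slice
        for c, p in enumerate(pidx):
            pv = (codes[p, sl] != _INVALID) & qvalid[sl]
            nc = int(pv.sum())
            if nc == 0:
                continue
            diff = int(((codes[p, sl] != q[sl]) & pv).sum())
            sim[k, c] = 1.0 - diff / nc
    centers = np.array([(w.start + w.end) / 2.0 for w in wins])
    return SimilarityTrack(query_id, panel_ids, window, step, wins, centers, sim)
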