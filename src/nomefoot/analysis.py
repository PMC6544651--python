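"""Molecule x site matrices, window smoothing, epiallele ordering and
per-molecule nucleosome / accessible-region calling.

The core objects are methylation matrices: rows are molecules, columns are
the top-strand coordinates of the VALID sites of one clustering variable
(CpG or GpC), values are 1 (methylated), 0 (unmethylated) or NaN (missing).
For GpC, 1 means M.CviPI-labeled, i.e. accessible; occupancy is its
complement.

Smoothing replaces each raw value by the molecule's mean state over a
centered genomic window of width W, the "clustering window": the smoothed
value at position p averages all of the molecule's called sites in
[p - W/2, p + W/2] (so a 140 nt window at 200 bp averages sites from 130 to
270 bp).  Molecules are then ordered by average-linkage hierarchical
clustering so that similar epialleles are adjacent.

Nucleosome calls use a sliding-window rule on the raw GpC states: a window
of length L (region size, default 140 bp — roughly the nucleosomal footprint
plus linker) qualifies when at least ``min_sites`` GpCs are called in it and
the protected (unmethylated) fraction reaches the stringency s; maximal
unions of overlapping qualifying windows are reported.  Accessible regions
(candidate NDRs) use the mirror rule on the methylated fraction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .reference import GenomicInterval, SiteIndex, SiteKind
from .molecules import CallState, MoleculeCall

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisParams",
    "MethylationMatrix",
    "FootprintCall",
    "build_matrix",
    "smooth_windowed",
    "cluster_molecules",
    "call_nucleosomes",
    "call_accessible_regions",
    "call_footprints",
    "export_site_csv",
    "footprints_to_bed",
]

STATE_VALUE = {
    CallState.METHYLATED: 1.0,
    CallState.UNMETHYLATED: 0.0,
    CallState.MISSING: np.nan,
}


@dataclass
class AnalysisParams:
    """Tunable analysis parameters.

    clustering_window W (bp, 20-160 useful range): width of the centered
    smoothing window; 60 works well for most amplicons.
    region_size L (bp, 100-160): minimum footprint length for a nucleosome
    call; 140 by default.
    stringency s (0.5-1): minimum fraction of window sites in the protected
    (or, for NDRs, accessible) state; 0.7 by default.
    """

    clustering_variable: SiteKind = SiteKind.GPC
    clustering_window: int = 60
    region_size: int = 140
    stringency: float = 0.7
    min_sites_per_window: int = 3

    def __post_init__(self) -> None:
        if self.clustering_window <= 0:
            raise ValueError("clustering window must be positive")
        if self.region_size <= 0:
            raise ValueError("region size must be positive")
        if not 0.5 <= self.stringency <= 1.0:
            raise ValueError(
                f"stringency must be in [0.5, 1], got {self.stringency}"
            )


@dataclass
class MethylationMatrix:
    """Molecules x sites matrix for one clustering variable.

    ``values`` is a DataFrame indexed by molecule id with site positions as
    columns (ascending); entries are 1.0 / 0.0 / NaN.  ``window`` is None for
    a raw state matrix and records W for a smoothed one.
    """

    values: pd.DataFrame
    variable: SiteKind
    spans: dict[str, GenomicInterval] = field(default_factory=dict)
    window: int | None = None

    @property
    def n_molecules(self) -> int:
        return len(self.values)

    @property
    def positions(self) -> np.ndarray:
        return self.values.columns.to_numpy(dtype=int)

    def site_counts(self) -> pd.DataFrame:
        """Per-site tallies; n_meth + n_unmeth + n_missing = n_molecules."""
        v = self.values
        return pd.DataFrame({
            "pos": v.columns.to_numpy(dtype=int),
            "n_meth": (v == 1.0).sum().to_numpy(),
            "n_unmeth": (v == 0.0).sum().to_numpy(),
            "n_missing": v.isna().sum().to_numpy(),
        })


def build_matrix(calls: list[MoleculeCall], site_index: SiteIndex,
                 variable: SiteKind) -> MethylationMatrix:
    """Raw state matrix over the VALID sites of one variable."""
    positions = site_index.positions(variable)
    data = {
        call.molecule_id: [STATE_VALUE[call.states.get(p, CallState.MISSING)]
                           for p in positions]
        for call in calls
    }
    values = pd.DataFrame.from_dict(data, orient="index", columns=positions,
                                    dtype=float)
    if not calls:
        values = pd.DataFrame(np.empty((0, len(positions))), columns=positions)
    spans = {c.molecule_id: c.span for c in calls}
    return MethylationMatrix(values=values, variable=variable, spans=spans)


def smooth_windowed(matrix: MethylationMatrix, window: int) -> MethylationMatrix:
    """Window-smoothed matrix: entry (m, p) is the mean of molecule m's
    called raw values at sites within [p - W/2, p + W/2] (inclusive bounds);
    NaN when no site of the window is called."""
    if window <= 0:
        raise ValueError("window must be positive")
    pos = matrix.positions.astype(float)
    half = window / 2.0
    raw = matrix.values.to_numpy(dtype=float)
    called = ~np.isnan(raw)
    filled = np.where(called, raw, 0.0)
    # membership[i, j]: site j inside the window centered at site i
    membership = (np.abs(pos[None, :] - pos[:, None]) <= half).astype(float)
    sums = filled @ membership.T
    counts = called.astype(float) @ membership.T
    with np.errstate(invalid="ignore", divide="ignore"):
        smoothed = np.where(counts > 0, sums / counts, np.nan)
    values = pd.DataFrame(smoothed, index=matrix.values.index,
                          columns=matrix.values.columns)
    return MethylationMatrix(values=values, variable=matrix.variable,
                             spans=dict(matrix.spans), window=window)


# ---------------------------------------------------------------------------
# Epiallele ordering
# ---------------------------------------------------------------------------

def _masked_distances(rows: np.ndarray) -> np.ndarray:
    """Condensed Euclidean distances over shared called columns, rescaled by
    sqrt(n_total / n_shared); pairs sharing no column get the matrix maximum."""
    n, n_cols = rows.shape
    called = ~np.isnan(rows)
    dists = np.zeros(n * (n - 1) // 2)
    no_share = []
    k = 0
    for i in range(n):
        for j in range(i + 1, n):
            shared = called[i] & called[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                no_share.append(k)
                dists[k] = np.nan
            else:
                diff = rows[i, shared] - rows[j, shared]
                dists[k] = np.sqrt(diff @ diff) * np.sqrt(n_cols / n_shared)
            k += 1
    if no_share:
        finite = dists[~np.isnan(dists)]
        ceiling = finite.max() if finite.size else 1.0
        dists[np.isnan(dists)] = ceiling
        logger.info("%d molecule pairs share no called site; distance set "
                    "to matrix maximum %.3f", len(no_share), ceiling)
    return dists


def _order_leaves(linkage: np.ndarray, ids: list[str],
                  rows: np.ndarray) -> list[str]:
    """Deterministic leaf order: at each internal node the subtree with the
    lower mean called value comes first; ties break on the lexicographically
    smallest molecule id in the subtree."""
    n = len(ids)
    means = [float(np.nanmean(rows[i])) if not np.all(np.isnan(rows[i]))
             else 0.5 for i in range(n)]

    def collect(node: int) -> tuple[list[int], float, str]:
        if node < n:
            return [node], means[node], ids[node]
        left, right = int(linkage[node - n, 0]), int(linkage[node - n, 1])
        l_leaves, l_mean, l_min = collect(left)
        r_leaves, r_mean, r_min = collect(right)
        if (l_mean, l_min) <= (r_mean, r_min):
            leaves = l_leaves + r_leaves
        else:
            leaves = r_leaves + l_leaves
        total = l_mean * len(l_leaves) + r_mean * len(r_leaves)
        return leaves, total / (len(l_leaves) + len(r_leaves)), min(l_min, r_min)

    order, _, _ = collect(2 * n - 2)
    return [ids[i] for i in order]


def cluster_molecules(smoothed: MethylationMatrix,
                      min_informative: int = 3) -> list[str]:
    """Order molecule ids so similar epialleles are adjacent.

    Average-linkage agglomerative clustering on masked Euclidean distances;
    molecules with fewer than ``min_informative`` called columns are appended
    after the clustered ones in id order.  The ordering is invariant to the
    row order of the input.
    """
    if smoothed.n_molecules == 0:
        raise ValueError("cannot cluster an empty matrix")
    frame = smoothed.values.sort_index()
    called_counts = frame.notna().sum(axis=1)
    informative = frame.index[called_counts >= min_informative].tolist()
    sparse = frame.index[called_counts < min_informative].tolist()
    if len(informative) <= 1:
        return informative + sparse
    rows = frame.loc[informative].to_numpy(dtype=float)
    dists = _masked_distances(rows)
    linkage = hierarchy.linkage(dists, method="average")
    ordered = _order_leaves(linkage, informative, rows)
    return ordered + sparse


# ---------------------------------------------------------------------------
# Footprint calling
# ---------------------------------------------------------------------------

@dataclass
class FootprintCall:
    """One per-molecule inferred interval: nucleosome-bound or accessible."""

    molecule_id: str
    interval: GenomicInterval
    kind: str  # "NUCLEOSOME" or "ACCESSIBLE"
    n_supporting_sites: int
    fraction: float


def _sliding_window_calls(molecule_id: str, contig: str,
                          positions: np.ndarray, states: np.ndarray,
                          span: GenomicInterval, length: int,
                          stringency: float, min_sites: int,
                          target_state: float, kind: str) -> list[FootprintCall]:
    """Merged maximal unions of qualifying length-L windows.

    A window [x, x + L) within the molecule's covered span qualifies when it
    holds >= min_sites called sites and the fraction of them in
    ``target_state`` is >= stringency.  Qualification only changes at x
    values where a called site enters or leaves the window, so those
    breakpoints are the only offsets evaluated (equivalent to scanning every
    integer x).
    """
    lo, hi = span.start, span.end - length
    if hi < lo:
        return []
    called = ~np.isnan(states)
    pos_c = positions[called]
    st_c = states[called]
    if pos_c.size == 0:
        return []
    # candidate offsets where window membership changes, clipped to the span
    cuts = {lo}
    for p in pos_c:
        for x in (p - length + 1, p + 1):
            if lo <= x <= hi:
                cuts.add(int(x))
    # runs of qualifying x as (xa, xb, best window fraction)
    qualifying: list[tuple[int, int, float]] = []
    sorted_cuts = sorted(cuts)
    for idx, x in enumerate(sorted_cuts):
        in_win = (pos_c >= x) & (pos_c < x + length)
        n = int(in_win.sum())
        if n < min_sites:
            continue
        frac = (st_c[in_win] == target_state).sum() / n
        if frac < stringency:
            continue
        x_end = sorted_cuts[idx + 1] - 1 if idx + 1 < len(sorted_cuts) else hi
        x_end = min(x_end, hi)
        if qualifying and qualifying[-1][1] + 1 >= x:
            xa, xb, f = qualifying[-1]
            qualifying[-1] = (xa, max(xb, x_end), max(f, frac))
        else:
            qualifying.append((x, x_end, frac))
    # merge runs whose window unions overlap spatially
    merged: list[tuple[int, int, float]] = []
    for xa, xb, f in qualifying:
        a, b = xa, xb + length
        if merged and a < merged[-1][1]:
            pa, pb, pf = merged[-1]
            merged[-1] = (pa, max(pb, b), max(pf, f))
        else:
            merged.append((a, b, f))
    calls = []
    for a, b, best_frac in merged:
        inside = (pos_c >= a) & (pos_c < b)
        n_support = int(((st_c == target_state) & inside).sum())
        calls.append(FootprintCall(
            molecule_id=molecule_id,
            interval=GenomicInterval(contig, a, b),
            kind=kind,
            n_supporting_sites=n_support,
            fraction=float(best_frac),
        ))
    return calls


def call_nucleosomes(molecule_id: str, positions, states,
                     span: GenomicInterval, length: int = 140,
                     stringency: float = 0.7,
                     min_sites: int = 3) -> list[FootprintCall]:
    """Nucleosome-bound intervals of one molecule from its raw GpC states.

    Protection = unmethylated GpC (state 0).  Returns maximal unions of
    overlapping qualifying windows, so a long protected run yields one call.
    """
    return _sliding_window_calls(
        molecule_id, span.contig, np.asarray(positions, dtype=float),
        np.asarray(states, dtype=float), span, length, stringency,
        min_sites, target_state=0.0, kind="NUCLEOSOME")


def call_accessible_regions(molecule_id: str, positions, states,
                            span: GenomicInterval, length: int = 140,
                            stringency: float = 0.7,
                            min_sites: int = 3) -> list[FootprintCall]:
    """Accessible (M.CviPI-labeled) intervals; mirror of the nucleosome rule
    with the methylated fraction against the stringency."""
    return _sliding_window_calls(
        molecule_id, span.contig, np.asarray(positions, dtype=float),
        np.asarray(states, dtype=float), span, length, stringency,
        min_sites, target_state=1.0, kind="ACCESSIBLE")


def call_footprints(matrix: MethylationMatrix, params: AnalysisParams,
                    accessible: bool = True) -> list[FootprintCall]:
    """Nucleosome (and optionally accessible) calls for every molecule of a
    raw GpC matrix."""
    if matrix.variable is not SiteKind.GPC:
        raise ValueError("footprints are called on the GpC matrix")
    out: list[FootprintCall] = []
    positions = matrix.positions
    for mol_id, row in matrix.values.iterrows():
        span = matrix.spans.get(mol_id)
        if span is None:
            continue
        states = row.to_numpy(dtype=float)
        out.extend(call_nucleosomes(
            mol_id, positions, states, span, params.region_size,
            params.stringency, params.min_sites_per_window))
        if accessible:
            out.extend(call_accessible_regions(
                mol_id, positions, states, span, params.region_size,
                params.stringency, params.min_sites_per_window))
    return out


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------

def export_site_csv(matrix: MethylationMatrix) -> pd.DataFrame:
    """Per-site summary: 1-based position, kind, n_meth, n_total_called and
    percent methylation (blank when the site is uncovered)."""
    counts = matrix.site_counts()
    n_total = counts.n_meth + counts.n_unmeth
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_total > 0, 100.0 * counts.n_meth / n_total, np.nan)
    return pd.DataFrame({
        "position": counts.pos + 1,
        "kind": matrix.variable.value,
        "n_meth": counts.n_meth,
        "n_total_called": n_total,
        "pct_meth": pct,
    })


def footprints_to_bed(calls: list[FootprintCall]) -> str:
    """BED6-like export: name = call type, score = round(100 * fraction)."""
    lines = []
    for c in calls:
        lines.append(
            f"{c.interval.contig}\t{c.interval.start}\t{c.interval.end}"
            f"\t{c.kind}\t{round(100 * c.fraction)}\t."
        )
    return "\n".join(lines) + ("\n" if lines else "")
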