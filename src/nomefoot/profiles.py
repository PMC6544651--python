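"""Population-averaged DNA methylation and nucleosome occupancy profiles.

Occupancy at a GpC site is the percentage of molecules whose GpC was NOT
M.CviPI-labeled (protected), i.e. 100 minus the GpC percent methylation;
DNA methylation is the percent of methylated CpGs.  Two granularities are
provided: per-site profiles for one locus (with an optional least-squares
polynomial trendline, order 6 by default) and TSS-anchored metagene
profiles where per-site counts are pooled into fixed-width bins of relative
position (default 10 bp over +/- 500 bp).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .analysis import MethylationMatrix, export_site_csv
from .reference import SiteKind

logger = logging.getLogger(__name__)

__all__ = [
    "MetageneConfig",
    "TSSAnchor",
    "locus_profile",
    "metagene_profile",
    "fit_trendline",
    "read_anchors_bed",
]


@dataclass(frozen=True)
class TSSAnchor:
    contig: str
    tss: int       # 0-based coordinate of the transcription start site
    strand: str    # "+" or "-"

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"anchor strand must be + or -, got {self.strand!r}")


@dataclass
class MetageneConfig:
    flank: int = 500
    bin_width: int = 10
    anchors: list[TSSAnchor] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.flank % self.bin_width != 0:
            raise ValueError("flank must be a multiple of bin_width")


def locus_profile(matrix_cpg: MethylationMatrix | None,
                  matrix_gpc: MethylationMatrix | None) -> pd.DataFrame:
    """Per-site population percentages for one locus.

    Columns: position (1-based), kind, n_meth, n_total_called, pct_meth and,
    for GpC rows, occupancy = 100 - pct_meth.
    """
    parts = []
    for matrix in (matrix_cpg, matrix_gpc):
        if matrix is None or matrix.values.shape[1] == 0:
            continue
        part = export_site_csv(matrix)
        if matrix.variable is SiteKind.GPC:
            part["occupancy"] = 100.0 - part["pct_meth"]
        else:
            part["occupancy"] = np.nan
        parts.append(part)
    if not parts:
        return pd.DataFrame(columns=["position", "kind", "n_meth",
                                     "n_total_called", "pct_meth", "occupancy"])
    return pd.concat(parts, ignore_index=True).sort_values(
        ["position", "kind"], kind="stable").reset_index(drop=True)


def metagene_profile(site_counts: pd.DataFrame,
                     config: MetageneConfig) -> pd.DataFrame:
    """Pool per-site methylation counts into bins of TSS-relative position.

    ``site_counts`` needs columns contig, pos (0-based), kind, n_meth,
    n_total.  Each site within +/- flank of an anchor contributes its counts
    to bin floor(rel / bin_width) where rel = pos - tss on + strand and
    tss - pos on - strand; counts are pooled over all anchors
    (count-weighted, so heavily covered sites weigh more), and sites near
    two anchors contribute to both.  Returns one row per (bin, kind) with
    bins covering [-flank, flank).
    """
    edges = np.arange(-config.flank, config.flank + config.bin_width,
                      config.bin_width)
    bin_starts = edges[:-1]
    kinds = [SiteKind.CPG.value, SiteKind.GPC.value]
    meth = {k: np.zeros(len(bin_starts), dtype=int) for k in kinds}
    total = {k: np.zeros(len(bin_starts), dtype=int) for k in kinds}
    contigs = set(site_counts["contig"].unique()) if len(site_counts) else set()
    for anchor in config.anchors:
        if anchor.contig not in contigs:
            logger.info("anchor %s:%d skipped: no site data on contig",
                        anchor.contig, anchor.tss)
            continue
        sub = site_counts[site_counts["contig"] == anchor.contig]
        rel = (sub["pos"].to_numpy() - anchor.tss if anchor.strand == "+"
               else anchor.tss - sub["pos"].to_numpy())
        inside = (rel >= -config.flank) & (rel < config.flank)
        if not inside.any():
            continue
        bins = (rel[inside] + config.flank) // config.bin_width
        for kind in kinds:
            mask = sub["kind"].to_numpy()[inside] == kind
            np.add.at(meth[kind], bins[mask].astype(int),
                      sub["n_meth"].to_numpy()[inside][mask])
            np.add.at(total[kind], bins[mask].astype(int),
                      sub["n_total"].to_numpy()[inside][mask])
    rows = []
    for kind in kinds:
        with np.errstate(invalid="ignore", divide="ignore"):
            pct = np.where(total[kind] > 0,
                           100.0 * meth[kind] / np.maximum(total[kind], 1),
                           np.nan)
        occ = 100.0 - pct if kind == SiteKind.GPC.value else np.full_like(pct, np.nan)
        for i, start in enumerate(bin_starts):
            rows.append({
                "bin_start_rel": int(start),
                "kind": kind,
                "n_meth": int(meth[kind][i]),
                "n_total": int(total[kind][i]),
                "pct": pct[i],
                "occupancy": occ[i],
            })
    return pd.DataFrame(rows, columns=["bin_start_rel", "kind", "n_meth",
                                       "n_total", "pct", "occupancy"])


def fit_trendline(xs, ys, degree: int = 6) -> tuple[np.ndarray, np.ndarray]:
    """Least-squares polynomial trendline.

    Returns (coefficients in ascending power order, fitted values at xs).
    With fewer than degree + 1 points the degree is reduced to n - 1.
    """
    xs = np.asarray(xs, dtype=float)
    ys = np.asarray(ys, dtype=float)
    keep = ~(np.isnan(xs) | np.isnan(ys))
    xs, ys = xs[keep], ys[keep]
    if xs.size == 0:
        raise ValueError("no finite points to fit")
    if xs.size < degree + 1:
        logger.info("trendline degree reduced from %d to %d (only %d points)",
                    degree, xs.size - 1, xs.size)
        degree = xs.size - 1
    poly = np.polynomial.Polynomial.fit(xs, ys, deg=degree)
    return poly.convert().coef, poly(xs)


def read_anchors_bed(path) -> list[TSSAnchor]:
    """TSS anchors from BED6: the TSS is the start for + strand features and
    end - 1 for - strand features."""
    anchors = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise ValueError(f"BED6 required for anchors, got: {line!r}")
            contig, start, end, _, _, strand = fields[:6]
            tss = int(start) if strand == "+" else int(end) - 1
            anchors.append(TSSAnchor(contig, tss, strand))
    return anchors
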