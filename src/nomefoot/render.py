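"""Publication-style outputs: lollipop SVG and occupancy heatmap.

The lollipop plot shows two stacked panels (CpG methylation above, GpC
accessibility below) with one row per molecule in clustered order and one
circle per dinucleotide site, x-scaled by genomic position.  Methylated CpGs
fill black, M.CviPI-methylated (accessible) GpCs fill blue, unmethylated
sites stay white and missing sites are not drawn.  Nucleosome footprints are
drawn as solid bars under the row; accessible regions as grey boxes.

The heatmap shows per-molecule occupancy (1 - smoothed GpC methylation) on a
red (fully occupied) to blue (fully accessible) scale, rows in clustered
order; positions with no called GpC in the window render in a distinct
missing colour.
"""

from __future__ import annotations

import xml.etree.ElementTree as ET
from dataclasses import dataclass

import numpy as np

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .analysis import FootprintCall, MethylationMatrix

__all__ = ["RenderOptions", "render_lollipop", "render_heatmap"]


@dataclass
class RenderOptions:
    cpg_color_methylated: str = "black"
    gpc_color_methylated: str = "#1f77b4"
    unmethylated_color: str = "white"
    tss: int | None = None
    show_nucleosome_bars: bool = True
    show_accessible_boxes: bool = True
    row_height: float = 14.0
    radius: float = 4.0
    width: float = 800.0
    margin: float = 40.0


def _x_scale(positions: np.ndarray, options: RenderOptions):
    lo = float(positions.min()) if positions.size else 0.0
    hi = float(positions.max()) if positions.size else 1.0
    span = max(hi - lo, 1.0)
    inner = options.width - 2 * options.margin

    def to_x(pos: float) -> float:
        return options.margin + (pos - lo) * inner / span

    return to_x


def _panel(svg: ET.Element, matrix: MethylationMatrix, ordering: list[str],
           footprints: list[FootprintCall], fill_methylated: str,
           options: RenderOptions, y0: float, label: str, to_x) -> float:
    panel = ET.SubElement(svg, "g", attrib={"class": f"panel-{label.lower()}"})
    text = ET.SubElement(panel, "text", attrib={
        "x": str(options.margin), "y": str(y0 + 4), "font-size": "12"})
    text.text = label
    y = y0 + 14
    by_molecule: dict[str, list[FootprintCall]] = {}
    for fp in footprints:
        by_molecule.setdefault(fp.molecule_id, []).append(fp)
    positions = matrix.positions
    for mol_id in ordering:
        row = ET.SubElement(panel, "g", attrib={
            "class": "molecule", "data-molecule": str(mol_id)})
        cy = y + options.row_height / 2
        if positions.size:
            ET.SubElement(row, "line", attrib={
                "x1": str(to_x(positions.min())), "x2": str(to_x(positions.max())),
                "y1": str(cy), "y2": str(cy),
                "stroke": "#999", "stroke-width": "0.5"})
        for fp in by_molecule.get(mol_id, []):
            if fp.kind == "ACCESSIBLE" and options.show_accessible_boxes:
                ET.SubElement(row, "rect", attrib={
                    "x": str(to_x(fp.interval.start)),
                    "y": str(y + 1),
                    "width": str(to_x(fp.interval.end) - to_x(fp.interval.start)),
                    "height": str(options.row_height - 2),
                    "fill": "#cccccc", "fill-opacity": "0.6",
                    "class": "accessible-box"})
            elif fp.kind == "NUCLEOSOME" and options.show_nucleosome_bars:
                ET.SubElement(row, "rect", attrib={
                    "x": str(to_x(fp.interval.start)),
                    "y": str(cy + options.radius + 1),
                    "width": str(to_x(fp.interval.end) - to_x(fp.interval.start)),
                    "height": "3",
                    "fill": "#cc0000", "class": "nucleosome-bar"})
        values = matrix.values.loc[mol_id] if mol_id in matrix.values.index else None
        if values is not None:
            for pos, value in zip(positions, values.to_numpy(dtype=float)):
                if np.isnan(value):
                    continue  # missing sites are not drawn
                fill = fill_methylated if value >= 0.5 else options.unmethylated_color
                ET.SubElement(row, "circle", attrib={
                    "cx": str(to_x(pos)), "cy": str(cy),
                    "r": str(options.radius), "fill": fill,
                    "stroke": "black", "stroke-width": "0.8"})
        y += options.row_height
    return y + 10


def render_lollipop(matrix_cpg: MethylationMatrix | None,
                    matrix_gpc: MethylationMatrix | None,
                    ordering: list[str],
                    footprints: list[FootprintCall] | None = None,
                    options: RenderOptions | None = None) -> str:
    """Render the two-panel lollipop figure and return it as an SVG string."""
    options = options or RenderOptions()
    footprints = footprints or []
    all_pos = np.concatenate([
        m.positions for m in (matrix_cpg, matrix_gpc) if m is not None
    ]) if (matrix_cpg is not None or matrix_gpc is not None) else np.array([])
    to_x = _x_scale(all_pos, options)
    n_rows = len(ordering)
    height = 2 * (24 + n_rows * options.row_height + 10) + 30
    svg = ET.Element("svg", attrib={
        "xmlns": "http://www.w3.org/2000/svg",
        "width": str(options.width), "height": str(height),
        "viewBox": f"0 0 {options.width} {height}",
    })
    y = 10.0
    if matrix_cpg is not None:
        y = _panel(svg, matrix_cpg, ordering, [], options.cpg_color_methylated,
                   options, y, "CpG", to_x)
    if matrix_gpc is not None:
        y = _panel(svg, matrix_gpc, ordering, footprints,
                   options.gpc_color_methylated, options, y, "GpC", to_x)
    if options.tss is not None and all_pos.size:
        x = to_x(options.tss)
        ET.SubElement(svg, "path", attrib={
            "d": f"M {x} {y} l -5 10 l 10 0 z", "fill": "black",
            "class": "tss-arrow"})
        lbl = ET.SubElement(svg, "text", attrib={
            "x": str(x + 8), "y": str(y + 10), "font-size": "11"})
        lbl.text = "TSS"
    return ET.tostring(svg, encoding="unicode")


def render_heatmap(smoothed_gpc: MethylationMatrix, ordering: list[str],
                   path: str | None = None, missing_color: str = "#d9d9d9"):
    """Occupancy heatmap of a smoothed GpC matrix, rows in clustered order.

    Cell value is 1 - smoothed methylation: 1 (red) = fully nucleosome
    occupied, 0 (blue) = fully accessible.  Returns the matplotlib Figure;
    writes it to ``path`` when given.
    """
    frame = smoothed_gpc.values.loc[ordering]
    occupancy = 1.0 - frame.to_numpy(dtype=float)
    masked = np.ma.masked_invalid(occupancy)
    cmap = plt.get_cmap("bwr").copy()
    cmap.set_bad(missing_color)
    positions = smoothed_gpc.positions
    fig, ax = plt.subplots(figsize=(8, max(2, 0.18 * len(ordering) + 1)))
    if positions.size >= 2:
        edges = np.empty(positions.size + 1, dtype=float)
        edges[1:-1] = (positions[1:] + positions[:-1]) / 2
        edges[0] = positions[0] - (positions[1] - positions[0]) / 2
        edges[-1] = positions[-1] + (positions[-1] - positions[-2]) / 2
    else:
        edges = np.array([0.0, 1.0])
    mesh = ax.pcolormesh(edges, np.arange(len(ordering) + 1), masked,
                         cmap=cmap, vmin=0.0, vmax=1.0)
    ax.set_ylim(len(ordering), 0)
    ax.set_xlabel("genomic position (bp)")
    ax.set_ylabel("molecule")
    fig.colorbar(mesh, ax=ax, label="nucleosome occupancy")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
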