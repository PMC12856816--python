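"""Hexagonal planning units: geometry, tenure, costs, features.

The prioritization works on a flat-top hexagonal tessellation clipped to
the region boundary.  Each planning unit (PU) carries its clipped area
as a fraction ``w`` of a full hexagon; proxy costs and feature amounts
are multiplied by ``w`` so partial edge PUs neither over- nor
under-contribute.  Tenure is assigned by majority area, with combined
"pastoral use" classes where Native Title or ILUA land is mostly under
pastoral lease.  The proxy cost blends modal median employee income
(MEI) and modal human influence index (HII), each min-max rescaled to
[0.01, 100], as cost = 0.4*MEI + 0.6*HII.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon
from shapely.strtree import STRtree

from .grids import Grid
from .simulate import BASE_TENURE_CLASSES

PU_TENURE_CLASSES = BASE_TENURE_CLASSES + (
    "Native Title pastoral use",
    "ILUA pastoral use",
)

#: conservation-status-first priority for exact ties in majority area
TENURE_TIE_PRIORITY = (
    "PA",
    "IPA",
    "Indigenous freehold",
    "Native Title pastoral use",
    "Native Title",
    "ILUA pastoral use",
    "ILUA",
    "pastoral",
    "other",
)

#: tenure eligible for selection under the voluntary-declaration objective
OBJECTIVE2_ELIGIBLE = frozenset(
    {"Native Title", "Native Title pastoral use", "Indigenous freehold"}
)
LOCKED_IN_CLASSES = frozenset({"PA", "IPA"})

COST_LO, COST_HI = 0.01, 100.0
MEI_WEIGHT, HII_WEIGHT = 0.4, 0.6


def hexagon_geometry(side_km: float) -> tuple[float, float]:
    """Perimeter (6s) and area (3*sqrt(3)/2 * s^2) of a regular hexagon."""
    if side_km <= 0:
        raise ValueError("side length must be positive")
    return 6.0 * side_km, 1.5 * np.sqrt(3.0) * side_km**2


def hexagon_polygon(cx: float, cy: float, side_km: float) -> Polygon:
    """Flat-top regular hexagon centred at (cx, cy)."""
    ang = np.deg2rad(np.arange(6) * 60.0)
    return Polygon(zip(cx + side_km * np.cos(ang), cy + side_km * np.sin(ang)))


def tessellate(
    boundary: Polygon,
    side_km: float,
    w_floor: float = 0.01,
    origin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Clip a flat-top hexagon lattice to the region boundary.

    Returns a PU table with columns ``geometry`` (clipped polygon),
    ``full_geometry``, ``w`` (clipped area / full hexagon area) and
    ``area_km2``; PUs with ``w`` below ``w_floor`` are dropped.  The
    lattice origin sits at the lower-left of the boundary's bounding
    box (or at ``origin`` if given), columns 1.5*s apart, odd columns
    shifted up half a row.
    """
    if boundary.is_empty or boundary.area == 0:
        raise ValueError("boundary polygon is empty")
    s = side_km
    _, full_area = hexagon_geometry(s)
    minx, miny, maxx, maxy = boundary.bounds
    if origin is not None:
        minx, miny = origin
    dy = np.sqrt(3.0) * s
    rows = []
    q = 0
    cx = minx
    while cx - s <= maxx:
        offset = 0.5 * dy if q % 2 else 0.0
        cy = miny - dy + offset
        while cy - dy / 2 <= maxy + dy:
            hexa = hexagon_polygon(cx, cy, s)
            clipped = hexa.intersection(boundary)
            if not clipped.is_empty and clipped.area > 0:
                w = clipped.area / full_area
                if w >= w_floor:
                    rows.append(
                        {
                            "geometry": clipped,
                            "full_geometry": hexa,
                            "w": min(w, 1.0),
                            "area_km2": clipped.area,
                        }
                    )
            cy += dy
        cx += 1.5 * s
        q += 1
    if not rows:
        raise ValueError("tessellation produced no planning units inside the boundary")
    pus = pd.DataFrame(rows)
    pus.index = pd.RangeIndex(len(pus), name="pu_id")
    return pus


def _covered_cells(grid: Grid, poly: Polygon) -> tuple[np.ndarray, np.ndarray]:
    """(rows, cols) of grid cells whose centres fall inside ``poly``."""
    xs, ys = grid.cell_centers()
    minx, miny, maxx, maxy = poly.bounds
    cs = grid.cell_size
    inside_bbox = (
        (xs >= minx - cs) & (xs <= maxx + cs) & (ys >= miny - cs) & (ys <= maxy + cs)
    )
    rr, cc = np.nonzero(inside_bbox)
    if len(rr) == 0:
        return rr, cc
    hit = shapely.contains_xy(poly, xs[rr, cc], ys[rr, cc])
    return rr[hit], cc[hit]


def classify_tenure(
    pus: pd.DataFrame,
    tenure: Grid,
    pastoral_overlay: Grid,
    tie_priority: tuple[str, ...] = TENURE_TIE_PRIORITY,
) -> pd.Series:
    """Majority-area tenure class per PU, with combined pastoral-use rule.

    The class covering the largest share of the PU wins (exact ties go
    to the earlier class in ``tie_priority``).  If the winner is Native
    Title or ILUA and the pastoral-lease overlay covers the majority of
    the PU, the combined "... pastoral use" class is assigned.  PUs
    entirely outside tenure coverage fall back to "other".
    """
    if not tenure.aligned_with(pastoral_overlay):
        raise ValueError("tenure and pastoral overlay grids are not aligned")
    code = tenure.values.astype(int)
    overlay = pastoral_overlay.values.astype(bool)
    rank = {cls: i for i, cls in enumerate(tie_priority)}
    out = []
    for _, pu in pus.iterrows():
        rr, cc = _covered_cells(tenure, pu.geometry)
        if len(rr) == 0:
            out.append("other")
            continue
        counts: dict[str, int] = {}
        for c in code[rr, cc]:
            cls = BASE_TENURE_CLASSES[c]
            counts[cls] = counts.get(cls, 0) + 1
        best = max(counts, key=lambda cls: (counts[cls], -rank.get(cls, 99)))
        if best in ("Native Title", "ILUA"):
            if 2 * int(overlay[rr, cc].sum()) > len(rr):
                best = f"{best} pastoral use"
        out.append(best)
    return pd.Series(out, index=pus.index, name="tenure")


def _modal(values: np.ndarray) -> float:
    """Most frequent value; ties resolved to the smaller value."""
    vals, counts = np.unique(values, return_counts=True)
    return float(vals[np.argmax(counts)])  # np.unique sorts, argmax takes first


def compute_cost(pus: pd.DataFrame, mei: Grid, hii: Grid) -> pd.DataFrame:
    """Proxy cost per PU: cost = (0.4*MEI' + 0.6*HII') * w.

    Modal MEI and HII are taken over the cells each PU covers (a PU too
    small to cover any cell centre uses the cell under its centroid),
    min-max normalized across PUs and rescaled to [0.01, 100] to avoid
    over-representation of near-free PUs, then blended 0.4/0.6 and
    weighted by the PU's area fraction ``w``.
    """
    if not mei.aligned_with(hii):
        raise ValueError("MEI and HII grids are not aligned")
    modes = {"mei": [], "hii": []}
    for _, pu in pus.iterrows():
        rr, cc = _covered_cells(mei, pu.geometry)
        if len(rr) == 0:
            cx, cy = pu.geometry.centroid.x, pu.geometry.centroid.y
            col = int(np.clip((cx - mei.origin[0]) / mei.cell_size, 0, mei.ncols - 1))
            row = int(np.clip(mei.nrows - 1 - (cy - mei.origin[1]) / mei.cell_size, 0, mei.nrows - 1))
            rr, cc = np.array([row]), np.array([col])
        modes["mei"].append(_modal(mei.values[rr, cc]))
        modes["hii"].append(_modal(hii.values[rr, cc]))
    out = pd.DataFrame(
        {"modal_mei": modes["mei"], "modal_hii": modes["hii"]}, index=pus.index
    )
    for col in ("modal_mei", "modal_hii"):
        v = out[col].to_numpy(dtype=float)
        if np.ptp(v) == 0:
            raise ValueError(f"{col} is constant across PUs; cost normalization degenerate")
        out[col + "_scaled"] = COST_LO + (v - v.min()) / np.ptp(v) * (COST_HI - COST_LO)
    out["cost"] = (
        MEI_WEIGHT * out["modal_mei_scaled"] + HII_WEIGHT * out["modal_hii_scaled"]
    ) * pus["w"].to_numpy(dtype=float)
    return out


def assign_cells_to_pus(template: Grid, pus: pd.DataFrame) -> np.ndarray:
    """Map each grid cell to the PU containing its centre (-1 if none).

    Cells on shared edges resolve to the lowest PU id, so the assignment
    is a deterministic partition.
    """
    xs, ys = template.cell_centers()
    pts = shapely.points(xs.ravel(), ys.ravel())
    tree = STRtree(list(pus["geometry"]))
    pt_idx, geom_idx = tree.query(pts, predicate="intersects")
    assign = np.full(len(pts), -1, dtype=int)
    # reversed iteration + overwrite keeps the smallest geometry index
    order = np.argsort(-geom_idx)
    assign[pt_idx[order]] = pus.index.to_numpy()[geom_idx[order]]
    return assign.reshape(template.shape)


def build_features(
    pus: pd.DataFrame, ranges: dict[str, np.ndarray], template: Grid
) -> pd.DataFrame:
    """Species-by-PU feature amounts a_ij (km2), weighted by w.

    a_ij = (area of species j's range cells assigned to PU i) * w_i.  A
    species with an empty range gets a zero column with a warning from
    the caller's perspective (all-zero amounts).
    """
    assign = assign_cells_to_pus(template, pus)
    pu_ids = pus.index.to_numpy()
    pos = {pid: k for k, pid in enumerate(pu_ids)}
    amounts = np.zeros((len(pu_ids), len(ranges)))
    w = pus["w"].to_numpy(dtype=float)
    for j, (sp, mask) in enumerate(ranges.items()):
        cells = assign[mask.astype(bool)]
        cells = cells[cells >= 0]
        if len(cells) == 0:
            continue
        ids, counts = np.unique(cells, return_counts=True)
        for pid, cnt in zip(ids, counts):
            k = pos[pid]
            amounts[k, j] = cnt * template.cell_area * w[k]
    return pd.DataFrame(amounts, index=pus.index, columns=list(ranges))


def build_pu_table(
    boundary: Polygon,
    side_km: float,
    tenure: Grid,
    pastoral_overlay: Grid,
    pa_mask: Grid,
    mei: Grid,
    hii: Grid,
    w_floor: float = 0.01,
) -> pd.DataFrame:
    """Assemble the full PU table: geometry, w, tenure, cost, lock flags.

    A PU is locked into every solution if its tenure class is PA or IPA
    (the existing reserve estate); ``pa_cover`` records the fraction of
    covered cells on the existing-PA mask as a diagnostic.
    """
    pus = tessellate(boundary, side_km, w_floor=w_floor)
    pus["tenure"] = classify_tenure(pus, tenure, pastoral_overlay)
    cost = compute_cost(pus, mei, hii)
    pus = pus.join(cost)
    cover = []
    for _, pu in pus.iterrows():
        rr, cc = _covered_cells(pa_mask, pu.geometry)
        cover.append(float(pa_mask.values[rr, cc].mean()) if len(rr) else 0.0)
    pus["pa_cover"] = cover
    pus["locked_in"] = pus["tenure"].isin(LOCKED_IN_CLASSES)
    pus["locked_out"] = False
    return pus
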