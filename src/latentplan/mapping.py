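"""Project species-level risk onto the analysis grid.

Total maps sum a per-species value over the species present in each
cell; mean maps average it.  For latent risk only the positive values
are aggregated, since those flag species predicted to be more threatened
than currently listed.  Cells with no qualifying species are no-data
(NaN), not zero — a mean over an empty set is undefined.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import Grid


def _check(ranges: dict[str, np.ndarray], values: pd.Series) -> None:
    missing = [sp for sp in values.index if sp not in ranges]
    if missing:
        raise ValueError(f"species without range grids: {missing}")
    if not np.isfinite(values.to_numpy(dtype=float)).all():
        raise ValueError("risk values must be finite")


def map_total(ranges: dict[str, np.ndarray], values: pd.Series) -> np.ndarray:
    """Per-cell sum of ``values`` over the species present in the cell."""
    _check(ranges, values)
    shape = next(iter(ranges.values())).shape
    out = np.zeros(shape, dtype=float)
    for sp, v in values.items():
        out += ranges[sp].astype(float) * float(v)
    return out


def map_mean(
    ranges: dict[str, np.ndarray], values: pd.Series, positive_only: bool = False
) -> np.ndarray:
    """Per-cell mean of ``values``; NaN where no qualifying species occur.

    With ``positive_only`` the mean runs over species with value > 0
    only (the positive-latent-risk convention).
    """
    _check(ranges, values)
    if positive_only:
        values = values[values > 0]
    shape = next(iter(ranges.values())).shape
    total = np.zeros(shape, dtype=float)
    count = np.zeros(shape, dtype=float)
    for sp, v in values.items():
        pres = ranges[sp].astype(float)
        total += pres * float(v)
        count += pres
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.where(count > 0, count, 1.0), np.nan)
    return out


def species_richness(ranges: dict[str, np.ndarray]) -> np.ndarray:
    shape = next(iter(ranges.values())).shape
    out = np.zeros(shape, dtype=float)
    for mask in ranges.values():
        out += mask.astype(float)
    return out


@dataclass
class RiskGrid:
    """The four risk surfaces plus species richness, on a shared grid."""

    total_current: Grid
    mean_current: Grid
    total_latent_positive: Grid
    mean_latent_positive: Grid
    richness: Grid

    def layers(self) -> dict[str, Grid]:
        return {
            "total_current": self.total_current,
            "mean_current": self.mean_current,
            "total_latent_positive": self.total_latent_positive,
            "mean_latent_positive": self.mean_latent_positive,
            "richness": self.richness,
        }


def build_risk_grids(
    ranges: dict[str, np.ndarray],
    status: pd.Series,
    latent: pd.Series,
    template: Grid,
    region_mask: np.ndarray | None = None,
) -> RiskGrid:
    """Assemble total/mean current and positive-latent risk surfaces.

    ``status`` is the ordinal current status, ``latent`` the per-species
    mean latent risk.  ``region_mask`` (boolean, True inside the study
    region) blanks everything outside the boundary to NaN.
    """
    latent_pos = latent.clip(lower=0.0)
    arrs = {
        "total_current": map_total(ranges, status),
        "mean_current": map_mean(ranges, status),
        "total_latent_positive": map_total(ranges, latent_pos),
        "mean_latent_positive": map_mean(ranges, latent, positive_only=True),
        "richness": species_richness(ranges),
    }
    if region_mask is not None:
        for k in arrs:
            arrs[k] = np.where(region_mask, arrs[k], np.nan)
    return RiskGrid(**{k: template.like(v) for k, v in arrs.items()})
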