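"""Representation targets for the minimum-set problem.

Target species are the highest-risk tail under each criterion: every
species listed endangered or critically endangered (current-risk
criterion), or every species whose mean latent risk exceeds a threshold
(latent-risk criterion, default 1.50).  For target species the
proportion of range to secure is

    P = min(0.4 * R + 0.6 * A, 0.75)

where A is the proportion of the species' distribution inside the
region and R is its risk value min-max rescaled to [0.25, 0.75] across
the target set (so P is never below 0.1 nor above 0.75).  All other
species get zero targets.  The absolute target is T = P * (in-region
range amount).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .risk import EN_ORDINAL

RISK_WEIGHT, AREA_WEIGHT = 0.4, 0.6
SCALE_LO, SCALE_HI = 0.25, 0.75
P_CAP = 0.75
DEFAULT_LATENT_THRESHOLD = 1.50


def select_targets(
    risk: pd.Series,
    criterion: str,
    latent_threshold: float = DEFAULT_LATENT_THRESHOLD,
    status_threshold: int = EN_ORDINAL,
    mode: str = "rule",
    decile: float = 0.10,
) -> pd.Index:
    """Choose the target-species set under a criterion.

    ``criterion`` is ``current_risk`` (ordinal status >=
    ``status_threshold``, i.e. EN or worse) or ``positive_latent_risk``
    (mean latent risk > ``latent_threshold``).  ``mode='decile'``
    instead takes the top ``decile`` fraction of species by the raw risk
    value.  Raises if the resulting set is empty.
    """
    if not np.isfinite(risk.to_numpy(dtype=float)).all():
        raise ValueError("risk values must be finite")
    if mode == "decile":
        n_top = max(1, int(np.ceil(decile * len(risk))))
        chosen = risk.sort_values(ascending=False).index[:n_top]
    elif criterion == "current_risk":
        chosen = risk.index[risk >= status_threshold]
    elif criterion == "positive_latent_risk":
        chosen = risk.index[risk > latent_threshold]
    else:
        raise ValueError(f"unknown criterion {criterion!r}")
    if len(chosen) == 0:
        raise ValueError(
            f"no target species under criterion {criterion!r}; "
            "lower the threshold or use decile mode"
        )
    return chosen


def scale_risk(raw: pd.Series) -> pd.Series:
    """Min-max rescale target species' raw risk onto [0.25, 0.75].

    If every raw value is equal the midpoint 0.5 is used, since the
    relative ordering carries no information.
    """
    if len(raw) == 0:
        raise ValueError("need at least one target species")
    v = raw.to_numpy(dtype=float)
    if np.ptp(v) == 0:
        return pd.Series(np.full(len(v), 0.5), index=raw.index)
    scaled = SCALE_LO + (v - v.min()) / np.ptp(v) * (SCALE_HI - SCALE_LO)
    return pd.Series(scaled, index=raw.index)


def compute_target(R: float, A: float) -> float:
    """Target proportion P = min(0.4R + 0.6A, 0.75)."""
    return min(RISK_WEIGHT * R + AREA_WEIGHT * A, P_CAP)


def build_target_table(
    risk: pd.Series,
    region_amounts: pd.Series,
    criterion: str,
    area_proportion: pd.Series | None = None,
    **select_kwargs,
) -> pd.DataFrame:
    """Full target table for one criterion.

    ``risk`` holds the per-species raw risk on the criterion's scale
    (ordinal status or mean latent risk) for every species;
    ``region_amounts`` the in-region (feature-matrix) range amount A_j
    in km2; ``area_proportion`` the fraction of the species' global
    distribution inside the region (defaults to 1, the fully in-region
    case).  Non-target species receive P = T = 0.

    Columns: ``raw_risk, is_target, R, A, P, T_km2``.
    """
    species = risk.index
    if area_proportion is None:
        area_proportion = pd.Series(1.0, index=species)
    chosen = select_targets(risk, criterion, **select_kwargs)
    R = pd.Series(0.0, index=species)
    R.loc[chosen] = scale_risk(risk.loc[chosen])
    P = pd.Series(0.0, index=species)
    for sp in chosen:
        P.loc[sp] = compute_target(float(R.loc[sp]), float(area_proportion.loc[sp]))
    T = P * region_amounts.reindex(species).fillna(0.0)
    return pd.DataFrame(
        {
            "raw_risk": risk,
            "is_target": species.isin(chosen),
            "R": R,
            "A": area_proportion,
            "P": P,
            "T_km2": T,
        }
    )
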