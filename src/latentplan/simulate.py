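"""Synthetic study systems with known ground truth.

Generates every input the downstream analysis needs — a sample of
ultrametric phylogenies, life-history traits evolved on them, spatially
autocorrelated environmental layers, connected species ranges, a
multi-tenure landscape with an existing protected-area estate, and
ordinal threat statuses drawn from a known risk model — so that model
recovery and prioritization behaviour can be tested end to end without
any external data.

The ground truth is explicit: :class:`TrueRiskModel` holds the regression
coefficients and covariance weights used to draw statuses, and a chosen
fraction of species have their observed status artificially suppressed.
Those species should later surface with positive latent risk, which is
the key recovery property the synthetic system exists to test.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from dendropy.simulate import treesim
from scipy import ndimage, stats
from shapely.geometry import Polygon

from .grids import Grid

# Base tenure classes on the raster.  Combined "pastoral use" classes are
# a planning-unit level construct (majority class + pastoral overlay) and
# do not appear on the raster itself.
BASE_TENURE_CLASSES = (
    "PA",
    "IPA",
    "Indigenous freehold",
    "Native Title",
    "ILUA",
    "pastoral",
    "other",
)

ENV_LAYERS = ("temp_wettest", "fire_total", "fire_lds", "hii", "mei")
INVADER_LAYERS = ("fox", "cane_toad")


@dataclass
class SimConfig:
    """Knobs of the synthetic study system.

    The defaults describe the desk-scale analogue of the study landscape:
    a 100 x 100 lattice of 1-km cells, about sixty mammal species, a
    modest sample of phylogenies, a tenure mosaic dominated by pastoral
    and Indigenous-held land, and ten percent of species with suppressed
    observed status.
    """

    grid_nrows: int = 100
    grid_ncols: int = 100
    cell_size: float = 1.0
    n_species: int = 60
    n_trees: int = 10
    tenure_mix: dict[str, float] | None = None
    pa_fraction: float = 0.12
    suppressed_fraction: float = 0.10
    seed: int = 0
    autocorr_sigma: float = 8.0  # Gaussian filter scale, in cells

    def __post_init__(self) -> None:
        for name in ("grid_nrows", "grid_ncols", "n_species", "n_trees"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("pa_fraction", "suppressed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")
        if self.tenure_mix is None:
            self.tenure_mix = self.default_tenure_mix(self.pa_fraction)
        unknown = set(self.tenure_mix) - set(BASE_TENURE_CLASSES)
        if unknown:
            raise ValueError(f"unknown tenure classes: {sorted(unknown)}")
        total = sum(self.tenure_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"tenure_mix must sum to 1, got {total}")

    @staticmethod
    def default_tenure_mix(pa_fraction: float) -> dict[str, float]:
        """A tenure mosaic with PA+IPA share equal to ``pa_fraction``."""
        rest = 1.0 - pa_fraction
        return {
            "PA": 0.6 * pa_fraction,
            "IPA": 0.4 * pa_fraction,
            "Indigenous freehold": 0.42 * rest,
            "Native Title": 0.32 * rest,
            "ILUA": 0.04 * rest,
            "pastoral": 0.14 * rest,
            "other": 0.08 * rest,
        }

    @property
    def n_cells(self) -> int:
        return self.grid_nrows * self.grid_ncols

    def empty_grid(self, fill: float = 0.0) -> Grid:
        return Grid(
            np.full((self.grid_nrows, self.grid_ncols), fill, dtype=float),
            cell_size=self.cell_size,
        )


@dataclass
class TrueRiskModel:
    """Ground-truth generative model for ordinal threat status.

    Latent risk is ``X @ beta_true`` plus correlated noise whose
    covariance blends phylogenetic, spatial-exponential and independent
    components with weights summing to one.  The latent values are cut at
    their deciles into a 10-point ordinal status; suppressed species have
    ``suppression_shift`` points subtracted from the observed status,
    floored at 1.
    """

    beta_true: np.ndarray
    w_phylo: float = 0.4
    w_space: float = 0.2
    w_iid: float = 0.4
    sigma2: float = 1.0
    spatial_range: float = 20.0
    suppression_shift: int = 3

    def __post_init__(self) -> None:
        self.beta_true = np.asarray(self.beta_true, dtype=float)
        ws = (self.w_phylo, self.w_space, self.w_iid)
        if any(w < 0 for w in ws):
            raise ValueError("covariance weights must be nonnegative")
        if abs(sum(ws) - 1.0) > 1e-9:
            raise ValueError("covariance weights must sum to 1")
        if self.sigma2 < 0:
            raise ValueError("sigma2 must be nonnegative")
        if self.suppression_shift < 1:
            raise ValueError("suppression_shift must be >= 1")


def species_labels(n_species: int) -> list[str]:
    return [f"sp{i + 1:04d}" for i in range(n_species)]


# ---------------------------------------------------------------------------
# Phylogenies
# ---------------------------------------------------------------------------


def simulate_phylogenies(
    n_species: int, n_trees: int, seed: int
) -> dendropy.TreeList:
    """Simulate a sample of ultrametric birth-death phylogenies.

    All trees share one taxon namespace with identical tip labels
    (``sp0001``...), mirroring a posterior sample of phylogenies for a
    fixed species set.  Pure-birth trees are grown to ``n_species``
    extant tips, so every tip sits at the present and the trees are
    ultrametric by construction.
    """
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    if n_trees < 1:
        raise ValueError("n_trees must be >= 1")
    rng = random.Random(seed)
    ns = dendropy.TaxonNamespace(species_labels(n_species))
    trees = dendropy.TreeList(taxon_namespace=ns)
    for _ in range(n_trees):
        tree = treesim.birth_death_tree(
            birth_rate=1.0, death_rate=0.0, num_extant_tips=n_species, rng=rng
        )
        # Remap the generator's own taxa onto the shared namespace in a
        # deterministic leaf-traversal order.
        tree.taxon_namespace = ns
        for taxon, leaf in zip(ns, tree.leaf_node_iter()):
            leaf.taxon = taxon
        trees.append(tree)
    return trees


def trees_to_newick(trees: dendropy.TreeList) -> str:
    return trees.as_string(schema="newick", suppress_rooting=True)


def trees_from_newick(text: str) -> dendropy.TreeList:
    return dendropy.TreeList.get(data=text, schema="newick")


# ---------------------------------------------------------------------------
# Traits
# ---------------------------------------------------------------------------

#: trait -> (root value on log scale, Brownian rate per unit branch length,
#:           variance of independent log-scale noise)
DEFAULT_TRAIT_PARAMS: dict[str, tuple[float, float, float]] = {
    "body_mass_g": (np.log(150.0), 0.8, 0.05),
    "age_first_repro_d": (np.log(365.0), 0.25, 0.02),
    "litters_per_year": (np.log(1.5), 0.10, 0.02),
    "litter_size": (np.log(3.0), 0.10, 0.02),
}


def simulate_traits(
    tree: dendropy.Tree,
    trait_params: dict[str, tuple[float, float, float]] | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Evolve life-history traits along a tree by log-scale Brownian motion.

    Each trait starts from a root value on the log scale, accumulates
    Gaussian increments with variance ``rate * branch_length`` along each
    edge, receives independent log-scale noise at the tips, and is
    exponentiated, so all values are positive and closely related species
    have more similar traits.
    """
    params = DEFAULT_TRAIT_PARAMS if trait_params is None else trait_params
    for name, (_, rate, noise) in params.items():
        if rate < 0 or noise < 0:
            raise ValueError(f"negative variance parameter for trait {name}")
    rng = np.random.default_rng(seed)
    leaves = [leaf for leaf in tree.leaf_node_iter()]
    labels = [leaf.taxon.label for leaf in leaves]
    out = {}
    for name, (root_val, rate, noise) in params.items():
        node_val: dict[int, float] = {}
        for node in tree.preorder_node_iter():
            if node.parent_node is None:
                node_val[id(node)] = root_val
            else:
                edge = node.edge.length or 0.0
                step = rng.normal(0.0, np.sqrt(rate * edge)) if rate * edge > 0 else 0.0
                node_val[id(node)] = node_val[id(node.parent_node)] + step
        tip_vals = np.array([node_val[id(leaf)] for leaf in leaves])
        if noise > 0:
            tip_vals = tip_vals + rng.normal(0.0, np.sqrt(noise), size=len(leaves))
        out[name] = np.exp(tip_vals)
    df = pd.DataFrame(out, index=pd.Index(labels, name="species"))
    return df.sort_index()


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------


def _smooth_field(shape: tuple[int, int], sigma: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian-filtered white noise, z-scored."""
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma, mode="reflect")
    return (field_ - field_.mean()) / field_.std()


def simulate_landscape(config: SimConfig, seed: int) -> dict[str, Grid]:
    """Generate environmental, cost-proxy and invader layers.

    Continuous layers are Gaussian-filtered white noise mapped through the
    normal CDF onto realistic ranges.  The human-influence index is an
    integer on the 0-61 scale and median employee income is rounded to
    $100, so that a modal (most frequent value) zonal statistic is
    well defined.  Invader layers are binary presence grids obtained by
    thresholding smoothed fields.
    """
    rng = np.random.default_rng(seed)
    shape = (config.grid_nrows, config.grid_ncols)
    s = config.autocorr_sigma

    def scaled(lo: float, hi: float, sigma: float = s) -> np.ndarray:
        u = stats.norm.cdf(_smooth_field(shape, sigma, rng))
        return lo + (hi - lo) * u

    layers: dict[str, Grid] = {}
    make = lambda arr: Grid(arr, cell_size=config.cell_size)
    layers["temp_wettest"] = make(scaled(24.0, 34.0))
    layers["fire_total"] = make(scaled(0.0, 10.0))
    layers["fire_lds"] = make(scaled(0.0, 5.0))
    layers["hii"] = make(np.round(scaled(0.0, 61.0)))
    layers["mei"] = make(np.round(scaled(20_000.0, 70_000.0) / 100.0) * 100.0)
    for name, prevalence in (("fox", 0.35), ("cane_toad", 0.45)):
        f = _smooth_field(shape, s, rng)
        thr = np.quantile(f, 1.0 - prevalence)
        layers[name] = make((f > thr).astype(float))
    return layers


# ---------------------------------------------------------------------------
# Species ranges
# ---------------------------------------------------------------------------


def _neighbors4(r: int, c: int, nrows: int, ncols: int):
    if r > 0:
        yield r - 1, c
    if r < nrows - 1:
        yield r + 1, c
    if c > 0:
        yield r, c - 1
    if c < ncols - 1:
        yield r, c + 1


def _spreading_dye(
    allowed: np.ndarray, target: int, rng: np.random.Generator, start: tuple[int, int]
) -> set[tuple[int, int]]:
    """Grow a 4-connected patch of exactly ``target`` cells from ``start``.

    Frontier ties are broken by the seeded RNG.  Raises if the connected
    component of ``start`` is smaller than ``target``.
    """
    nrows, ncols = allowed.shape
    patch = {start}
    frontier = [n for n in _neighbors4(*start, nrows, ncols) if allowed[n]]
    while len(patch) < target:
        frontier = [f for f in frontier if f not in patch]
        if not frontier:
            raise RuntimeError("spreading dye exhausted its connected component")
        idx = rng.integers(len(frontier))
        cell = frontier.pop(idx)
        patch.add(cell)
        for n in _neighbors4(*cell, nrows, ncols):
            if allowed[n] and n not in patch:
                frontier.append(n)
    return patch


def default_range_sizes(config: SimConfig, seed: int) -> np.ndarray:
    """Log-normal range sizes (cells), clipped to [5%, 40%] of the grid.

    The floor mirrors the comparative-model species pool, which excludes
    range-restricted species (criterion-B listings and species with only
    marginal overlap with the region), so in-region ranges are broad.
    """
    rng = np.random.default_rng(seed)
    sizes = rng.lognormal(mean=np.log(0.08 * config.n_cells), sigma=0.7, size=config.n_species)
    lo = max(10, int(np.ceil(0.05 * config.n_cells)))
    return np.clip(np.round(sizes), lo, int(0.4 * config.n_cells)).astype(int)


def simulate_ranges(
    config: SimConfig, target_sizes, seed: int
) -> dict[str, np.ndarray]:
    """Grow one connected binary range per species by spreading dye.

    Each range starts at a random cell and accretes uniformly random
    frontier cells (4-connectivity) until it holds exactly its target
    number of cells.
    """
    target_sizes = np.asarray(target_sizes, dtype=int)
    if len(target_sizes) != config.n_species:
        raise ValueError("one target size per species required")
    if (target_sizes < 1).any():
        raise ValueError("range target sizes must be >= 1")
    if (target_sizes > config.n_cells).any():
        raise ValueError("range target size exceeds the grid")
    rng = np.random.default_rng(seed)
    allowed = np.ones((config.grid_nrows, config.grid_ncols), dtype=bool)
    ranges: dict[str, np.ndarray] = {}
    for label, size in zip(species_labels(config.n_species), target_sizes):
        start = (int(rng.integers(config.grid_nrows)), int(rng.integers(config.grid_ncols)))
        patch = _spreading_dye(allowed, int(size), rng, start)
        mask = np.zeros_like(allowed)
        rows, cols = zip(*patch)
        mask[list(rows), list(cols)] = True
        ranges[label] = mask
    return ranges


# ---------------------------------------------------------------------------
# Tenure
# ---------------------------------------------------------------------------


def simulate_tenure(config: SimConfig, seed: int) -> tuple[Grid, Grid, Grid]:
    """Generate the tenure mosaic, existing-PA mask and pastoral overlay.

    Classes are grown one at a time by quota-limited spreading dye
    (restarting from a fresh seed cell whenever a patch is walled in), so
    realized class proportions match ``tenure_mix`` to within one cell.
    The existing-PA mask is exactly the PA and IPA cells.  A separate
    pastoral-lease overlay covers all pastoral-class cells plus a
    contiguous share of Native Title and ILUA land, so that combined
    "pastoral use" planning-unit classes occur.

    Returns ``(tenure, pa_mask, pastoral_overlay)``; tenure cell values
    are integer indices into :data:`BASE_TENURE_CLASSES`.
    """
    mix = config.tenure_mix
    total = sum(mix.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError("tenure_mix must sum to 1")
    rng = np.random.default_rng(seed)
    nrows, ncols = config.grid_nrows, config.grid_ncols
    n_cells = nrows * ncols

    # Largest-remainder quotas summing exactly to the cell count.
    classes = [c for c in BASE_TENURE_CLASSES if mix.get(c, 0.0) > 0]
    raw = np.array([mix[c] * n_cells for c in classes])
    quotas = np.floor(raw).astype(int)
    remainder = n_cells - quotas.sum()
    order = np.argsort(-(raw - np.floor(raw)))
    quotas[order[:remainder]] += 1

    code = np.full((nrows, ncols), -1, dtype=int)
    unassigned = np.ones((nrows, ncols), dtype=bool)
    # grow each class as several patches (a mosaic of holdings, not one
    # giant blob); single patches capped at ~1% of the landscape
    patch_cap = max(1, int(0.01 * n_cells))
    for cls, quota in zip(classes, quotas):
        cls_code = BASE_TENURE_CLASSES.index(cls)
        remaining = int(quota)
        while remaining > 0:
            free = np.argwhere(unassigned)
            start = tuple(free[rng.integers(len(free))])
            patch = {start}
            frontier = [n for n in _neighbors4(*start, nrows, ncols) if unassigned[n]]
            goal = min(remaining, patch_cap)
            while len(patch) < goal and frontier:
                frontier = [f for f in frontier if f not in patch]
                if not frontier:
                    break
                idx = rng.integers(len(frontier))
                cell = frontier.pop(idx)
                patch.add(cell)
                for nb in _neighbors4(*cell, nrows, ncols):
                    if unassigned[nb] and nb not in patch:
                        frontier.append(nb)
            for r, c in patch:
                code[r, c] = cls_code
                unassigned[r, c] = False
            remaining -= len(patch)

    tenure = Grid(code.astype(float), cell_size=config.cell_size)
    pa_codes = (BASE_TENURE_CLASSES.index("PA"), BASE_TENURE_CLASSES.index("IPA"))
    pa_mask = tenure.like(np.isin(code, pa_codes).astype(float))

    pastoral = code == BASE_TENURE_CLASSES.index("pastoral")
    overlay = pastoral.copy()
    indig = np.isin(
        code,
        (
            BASE_TENURE_CLASSES.index("Native Title"),
            BASE_TENURE_CLASSES.index("ILUA"),
        ),
    )
    if indig.any():
        f = _smooth_field((nrows, ncols), config.autocorr_sigma, rng)
        thr = np.quantile(f[indig], 0.6)  # ~40% of NT/ILUA land under lease
        overlay |= indig & (f > thr)
    pastoral_overlay = tenure.like(overlay.astype(float))
    return tenure, pa_mask, pastoral_overlay


def realized_tenure_mix(tenure: Grid) -> dict[str, float]:
    code = tenure.values.astype(int)
    n = code.size
    return {
        cls: float((code == i).sum()) / n
        for i, cls in enumerate(BASE_TENURE_CLASSES)
        if (code == i).any()
    }


# ---------------------------------------------------------------------------
# Threat status
# ---------------------------------------------------------------------------


def assign_threat_status(
    true_model: TrueRiskModel,
    predictors: pd.DataFrame,
    tree: dendropy.Tree,
    centroids: pd.DataFrame,
    seed: int,
    suppressed_fraction: float = 0.10,
    covariance=None,
) -> pd.DataFrame:
    """Draw ordinal threat statuses from the ground-truth risk model.

    The latent risk is ``X @ beta_true`` plus multivariate-normal noise
    with covariance ``sigma2 * (w_p V_phylo + w_s V_space + w_e I)``.
    Latent values are discretized at their empirical deciles onto the
    10-point ordinal scale (equal-probability bins, so every level is
    populated in expectation).  A random ``suppressed`` subset has
    ``suppression_shift`` subtracted from its observed status, floored at
    the scale minimum.

    Returns a frame indexed by species with columns ``latent_true``,
    ``status_true``, ``status_observed`` and ``suppressed``.
    """
    from .risk import build_covariance  # deferred: risk does not import simulate

    X = predictors.to_numpy(dtype=float)
    if X.shape[1] != len(true_model.beta_true):
        raise ValueError(
            f"predictor count {X.shape[1]} does not match beta_true "
            f"length {len(true_model.beta_true)}"
        )
    species = list(predictors.index)
    cov = covariance
    if cov is None:
        cov = build_covariance(
            tree,
            species,
            centroids,
            w_phylo=true_model.w_phylo,
            w_space=true_model.w_space,
            rho=true_model.spatial_range,
        )
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(len(species))
    if true_model.sigma2 > 0:
        L = np.linalg.cholesky(true_model.sigma2 * cov.V)
        latent = X @ true_model.beta_true + L @ noise
    else:  # degenerate noise-free limit
        latent = X @ true_model.beta_true

    cuts = np.quantile(latent, np.linspace(0.1, 0.9, 9))
    status = 1 + np.searchsorted(cuts, latent, side="left")

    return _apply_suppression(
        pd.DataFrame(
            {"latent_true": latent, "status_true": status},
            index=pd.Index(species, name="species"),
        ),
        true_model,
        rng,
        suppressed_fraction=suppressed_fraction,
    )


def _apply_suppression(
    df: pd.DataFrame, true_model: TrueRiskModel, rng: np.random.Generator,
    suppressed_fraction: float | None = None,
) -> pd.DataFrame:
    frac = 0.10 if suppressed_fraction is None else suppressed_fraction
    n = len(df)
    n_sup = int(np.floor(frac * n))
    flags = np.zeros(n, dtype=bool)
    if n_sup:
        flags[rng.choice(n, size=n_sup, replace=False)] = True
    observed = df["status_true"].to_numpy(int).copy()
    observed[flags] = np.maximum(1, observed[flags] - true_model.suppression_shift)
    out = df.copy()
    out["status_observed"] = observed
    out["suppressed"] = flags
    return out


# ---------------------------------------------------------------------------
# Region boundary
# ---------------------------------------------------------------------------


def generate_boundary(config: SimConfig, notch: bool = True) -> Polygon:
    """The study-region polygon: the grid extent, optionally minus a
    corner notch so that edge planning units really are cropped."""
    w = config.grid_ncols * config.cell_size
    h = config.grid_nrows * config.cell_size
    rect = Polygon([(0, 0), (w, 0), (w, h), (0, h)])
    if not notch:
        return rect
    tri = Polygon([(0.75 * w, h), (w, h), (w, 0.6 * h)])
    return rect.difference(tri)
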