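"""Comparative extinction-risk modelling.

The centrepiece is :class:`PhyloSpatialGLS`, a generalized least squares
model of ordinal threat status (treated on a pseudo-numeric 10-point
scale) against standardized life-history, ecological and environmental
predictors, with an error covariance that blends phylogenetic
relatedness, spatial proximity of range centroids, and independent
noise:

    V = w_p * V_phylo + w_s * V_space + w_e * I,   w_p + w_s + w_e = 1

``V_phylo`` comes from shared branch lengths scaled to unit diagonal and
``V_space`` is an exponential kernel exp(-d / rho) on Euclidean
centroid distances.  ``fit()`` returns a :class:`GLSResults` object with
coefficient estimates, standard errors, t statistics, the ML
log-likelihood and small-sample AICc, in the style of statsmodels.

Around the model sit the data-preparation and model-selection steps of a
comparative analysis: ordinal coding of threat categories, zonal
summaries of environmental layers over species ranges, skewness-guided
transformation and standardization, a VIF collinearity screen, the
AICc-guided backward/forward stepwise search for a minimum adequate
model (MAM), and latent risk — the model's fitted value minus the
observed status, averaged over a sample of phylogenies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.linalg import solve_triangular

from .grids import Grid

CATEGORIES = ("LC", "NT", "VU", "EN", "CR")
TRENDS = ("increasing", "stable", "decreasing", "unknown")
_CATEGORY_BASE = {"LC": 1, "NT": 3, "VU": 5, "EN": 7, "CR": 9}
#: encoded ordinal at or above which a species counts as EN or CR
EN_ORDINAL = _CATEGORY_BASE["EN"]


def encode_threat_ordinal(category: str, trend: str) -> int:
    """Map an IUCN-style category and population trend to a 1-10 ordinal.

    Categories carry base scores LC=1, NT=3, VU=5, EN=7, CR=9; a
    decreasing trend adds one point.  The image of the mapping is the
    full 10-point scale, monotone in category severity and worsened by
    decline.
    """
    if category not in _CATEGORY_BASE:
        raise ValueError(f"unknown category {category!r}")
    if trend not in TRENDS:
        raise ValueError(f"unknown trend {trend!r}")
    return _CATEGORY_BASE[category] + (1 if trend == "decreasing" else 0)


def filter_species(table: pd.DataFrame) -> pd.DataFrame:
    """Drop species excluded from comparative modelling.

    Removes rows flagged ``data_deficient``, ``criterion_b`` (listed for
    small range, to avoid circularity with the range-size predictor),
    ``unresolved_phylogeny`` or ``insufficient_overlap`` (<2% of the
    range inside the study region); an ``extinct`` column, if present,
    is applied too.
    """
    flags = ["data_deficient", "criterion_b", "unresolved_phylogeny", "insufficient_overlap"]
    if "extinct" in table.columns:
        flags.append("extinct")
    missing = [f for f in flags if f not in table.columns and f != "extinct"]
    if missing:
        raise ValueError(f"missing exclusion-flag columns: {missing}")
    keep = ~table[flags].any(axis=1)
    return table.loc[keep]


def filter_occurrences(occ: pd.DataFrame, max_uncertainty_km: float = 2.0) -> pd.DataFrame:
    """Clean point-occurrence records (used for invader presence layers).

    Drops records without coordinates, exact duplicate coordinates, and
    records with coordinate uncertainty above ``max_uncertainty_km``.
    """
    out = occ.dropna(subset=["lon", "lat"])
    if "uncertainty_km" in out.columns:
        out = out[out["uncertainty_km"].fillna(np.inf) <= max_uncertainty_km]
    return out.drop_duplicates(subset=["lon", "lat"])


# ---------------------------------------------------------------------------
# Predictor construction
# ---------------------------------------------------------------------------


def summarize_predictors(
    ranges: dict[str, np.ndarray],
    env: dict[str, Grid],
    traits: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Summarize spatial layers over each species' range.

    Returns ``(predictors, centroids)``: raw (untransformed) predictor
    columns — life-history traits, range size in km2, invader overlap
    proportions, and the mean of each continuous environmental layer
    over range cells — plus range-centroid coordinates (mean of occupied
    cell centres, km).
    """
    some_grid = next(iter(env.values()))
    xs, ys = some_grid.cell_centers()
    rows, cents = [], []
    for sp in traits.index:
        if sp not in ranges:
            raise ValueError(f"species {sp} has no range grid")
        mask = ranges[sp].astype(bool)
        if not mask.any():
            raise ValueError(f"species {sp} has an empty range")
        rec = {
            "body_mass_g": traits.loc[sp, "body_mass_g"],
            "age_first_repro_d": traits.loc[sp, "age_first_repro_d"],
            "litters_per_year": traits.loc[sp, "litters_per_year"],
            "litter_size": traits.loc[sp, "litter_size"],
            "range_size_km2": float(mask.sum()) * some_grid.cell_area,
            "fox_overlap": float(env["fox"].values[mask].mean()),
            "toad_overlap": float(env["cane_toad"].values[mask].mean()),
            "temp_wettest": float(env["temp_wettest"].values[mask].mean()),
            "human_influence": float(env["hii"].values[mask].mean()),
            "fire_total": float(env["fire_total"].values[mask].mean()),
            "fire_lds": float(env["fire_lds"].values[mask].mean()),
        }
        rows.append(rec)
        cents.append({"x": float(xs[mask].mean()), "y": float(ys[mask].mean())})
    idx = pd.Index(traits.index, name="species")
    return pd.DataFrame(rows, index=idx), pd.DataFrame(cents, index=idx)


def transform_standardize(
    table: pd.DataFrame,
    skew_threshold: float = 1.0,
    quadratic: tuple[str, ...] = (),
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Log-transform skewed columns, z-score everything, add quadratics.

    Columns whose absolute skewness exceeds ``skew_threshold`` (and that
    are nonnegative) are log-transformed, using log(x + eps) where zeros
    occur; every column is then standardized to mean 0, SD 1.  For each
    name in ``quadratic`` a ``<name>_sq`` column — the standardized
    square of the standardized column — is appended, giving the familiar
    centred quadratic term.  Returns the transformed table and a log of
    what was done to each column.
    """
    out = {}
    tlog: dict[str, str] = {}
    for col in table.columns:
        x = table[col].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            raise ValueError(f"column {col!r} is constant and cannot be standardized")
        if abs(stats.skew(x)) > skew_threshold and x.min() >= 0:
            eps = 0.5 * x[x > 0].min() if (x == 0).any() else 0.0
            x = np.log(x + eps)
            tlog[col] = f"log(x + {eps:g})" if eps else "log"
        else:
            tlog[col] = "identity"
        out[col] = (x - x.mean()) / x.std()
    df = pd.DataFrame(out, index=table.index)
    for col in quadratic:
        sq = df[col].to_numpy() ** 2
        df[f"{col}_sq"] = (sq - sq.mean()) / sq.std()
        tlog[f"{col}_sq"] = f"standardized square of standardized {col}"
    return df, tlog


def vif_screen(
    X: pd.DataFrame, threshold: float = 5.0
) -> tuple[list[str], pd.DataFrame]:
    """Iterative variance-inflation-factor screen for collinearity.

    Computes VIF_j = 1 / (1 - R2_j) from the regression of each column
    on the others and removes the worst offender while any VIF exceeds
    ``threshold``.  Perfectly collinear columns (infinite VIF) are
    removed with a warning rather than crashing.  Returns the retained
    column names and a per-round report of all VIF values.
    """
    if len(X) <= X.shape[1]:
        raise ValueError("need more observations than predictors for a VIF screen")
    cols = list(X.columns)
    rounds = []
    rnd = 0
    while len(cols) > 1:
        vifs = {c: _vif_one(X[cols], c) for c in cols}
        rounds.append(pd.DataFrame({"round": rnd, "predictor": list(vifs), "vif": list(vifs.values())}))
        worst = max(vifs, key=lambda c: vifs[c])
        if not np.isfinite(vifs[worst]):
            warnings.warn(f"predictor {worst!r} is perfectly collinear; removing it")
        elif vifs[worst] <= threshold:
            break
        cols.remove(worst)
        rnd += 1
    return cols, pd.concat(rounds, ignore_index=True)


def _vif_one(X: pd.DataFrame, col: str) -> float:
    y = X[col].to_numpy(dtype=float)
    others = X.drop(columns=[col]).to_numpy(dtype=float)
    A = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / tss
    if r2 >= 1.0 - 1e-12:
        return np.inf
    return 1.0 / (1.0 - r2)


# ---------------------------------------------------------------------------
# Covariance construction
# ---------------------------------------------------------------------------


@dataclass
class CovarianceModel:
    """Blended phylogenetic + spatial + independent error covariance."""

    V: np.ndarray
    V_phylo: np.ndarray
    V_space: np.ndarray
    w_phylo: float
    w_space: float
    rho: float
    species: list[str] = field(default_factory=list)

    @property
    def w_iid(self) -> float:
        return 1.0 - self.w_phylo - self.w_space


def phylo_correlation(tree: dendropy.Tree, species: list[str]) -> np.ndarray:
    """Unit-diagonal phylogenetic correlation from shared branch lengths.

    For an ultrametric tree of depth T, cov(i, j) = depth of the MRCA =
    T - d_ij / 2 with d the patristic distance; dividing by T gives a
    correlation matrix with unit diagonal.
    """
    label_to_taxon = {t.label: t for t in tree.taxon_namespace}
    missing = [s for s in species if s not in label_to_taxon]
    if missing:
        raise ValueError(f"species missing from tree: {missing}")
    pdm = tree.phylogenetic_distance_matrix()
    n = len(species)
    taxa = [label_to_taxon[s] for s in species]
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            D[i, j] = D[j, i] = d
    depth = tree.max_distance_from_root()
    if depth <= 0:
        return np.eye(n)
    C = 1.0 - D / (2.0 * depth)
    np.fill_diagonal(C, 1.0)
    return C


def spatial_correlation(centroids: pd.DataFrame, species: list[str], rho: float) -> np.ndarray:
    """Exponential-kernel correlation exp(-d/rho) on centroid distances."""
    pts = centroids.loc[species, ["x", "y"]].to_numpy(dtype=float)
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(axis=2))
    return np.exp(-d / rho)


def build_covariance(
    tree: dendropy.Tree,
    species: list[str],
    centroids: pd.DataFrame,
    w_phylo: float,
    w_space: float,
    rho: float,
) -> CovarianceModel:
    """Build the blended unit-diagonal covariance V.

    ``V = w_p V_phylo + w_s V_space + (1 - w_p - w_s) I``.  Positive
    definiteness is enforced by adding a diagonal jitter (with a
    warning) in the rare case the blend is numerically semidefinite.
    """
    if w_phylo < 0 or w_space < 0 or w_phylo + w_space > 1 + 1e-12:
        raise ValueError("need w_phylo, w_space >= 0 with w_phylo + w_space <= 1")
    if rho <= 0:
        raise ValueError("rho must be positive")
    n = len(species)
    Vp = phylo_correlation(tree, species) if w_phylo > 0 else np.eye(n)
    Vs = spatial_correlation(centroids, species, rho) if w_space > 0 else np.eye(n)
    w_e = 1.0 - w_phylo - w_space
    V = w_phylo * Vp + w_space * Vs + w_e * np.eye(n)
    V = 0.5 * (V + V.T)
    jitter = 0.0
    while True:
        try:
            np.linalg.cholesky(V + jitter * np.eye(n))
            break
        except np.linalg.LinAlgError:
            jitter = 1e-10 if jitter == 0 else jitter * 10
            if jitter > 1e-4:
                raise
    if jitter:
        warnings.warn(f"covariance required diagonal jitter {jitter:g} for positive definiteness")
        V = V + jitter * np.eye(n)
    return CovarianceModel(V=V, V_phylo=Vp, V_space=Vs, w_phylo=w_phylo, w_space=w_space, rho=rho, species=list(species))


# ---------------------------------------------------------------------------
# The GLS model
# ---------------------------------------------------------------------------


def aicc(loglik: float, k: int, n: int) -> float:
    """Akaike information criterion with small-sample correction."""
    if n <= k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k} (need n > k + 1)")
    return -2.0 * loglik + 2.0 * k + 2.0 * k * (k + 1) / (n - k - 1)


class PhyloSpatialGLS:
    """GLS regression with a known error-correlation matrix.

    Parameters
    ----------
    endog : array-like, shape (n,)
        Response (ordinal threat status on the pseudo-numeric scale).
    exog : DataFrame or ndarray, shape (n, p)
        Predictor columns, standardized; an intercept column is added
        automatically unless one named ``const`` is present.
    cov : CovarianceModel or ndarray
        Error correlation matrix V (unit diagonal).

    ``fit()`` estimates beta by feasible GLS through the Cholesky factor
    of V and returns a :class:`GLSResults`.
    """

    def __init__(self, endog, exog, cov) -> None:
        if isinstance(exog, pd.DataFrame):
            self.exog_names = list(exog.columns)
            X = exog.to_numpy(dtype=float)
            self.row_index = exog.index
        else:
            X = np.asarray(exog, dtype=float)
            if X.ndim == 1:
                X = X[:, None]
            self.exog_names = [f"x{i + 1}" for i in range(X.shape[1])]
            self.row_index = pd.RangeIndex(X.shape[0])
        y = np.asarray(endog, dtype=float)
        if "const" not in self.exog_names:
            X = np.column_stack([np.ones(len(y)), X])
            self.exog_names = ["const"] + self.exog_names
        self.endog = y
        self.exog = X
        self.cov = cov
        V = cov.V if isinstance(cov, CovarianceModel) else np.asarray(cov, dtype=float)
        if V.shape != (len(y), len(y)):
            raise ValueError("covariance matrix shape does not match the data")
        self.V = V
        if len(y) <= X.shape[1]:
            raise ValueError("need more observations than parameters")

    def fit(self) -> "GLSResults":
        y, X, V = self.endog, self.exog, self.V
        n, p = X.shape
        L = np.linalg.cholesky(V)
        Xw = solve_triangular(L, X, lower=True)
        yw = solve_triangular(L, y, lower=True)
        xtx = Xw.T @ Xw
        cond = np.linalg.cond(xtx)
        if cond > 1e12:
            raise np.linalg.LinAlgError(
                "singular design under V; collinear columns suspected among "
                + ", ".join(self.exog_names)
            )
        beta = np.linalg.solve(xtx, Xw.T @ yw)
        resid_w = yw - Xw @ beta
        rss = float(resid_w @ resid_w)
        sigma2_ml = rss / n
        logdet_V = 2.0 * float(np.log(np.diag(L)).sum())
        llf = -0.5 * (n * np.log(2.0 * np.pi * sigma2_ml) + logdet_V + n)
        df_resid = n - p
        sigma2_df = rss / df_resid
        cov_params = sigma2_df * np.linalg.inv(xtx)
        bse = np.sqrt(np.diag(cov_params))
        tvals = beta / bse
        pvals = 2.0 * stats.t.sf(np.abs(tvals), df=df_resid)
        fitted = X @ beta
        k = p + 1  # mean parameters plus the residual variance
        aicc_val = aicc(float(llf), k, n) if n > k + 1 else np.nan
        return GLSResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            bse=pd.Series(bse, index=self.exog_names),
            tvalues=pd.Series(tvals, index=self.exog_names),
            pvalues=pd.Series(pvals, index=self.exog_names),
            sigma2=sigma2_ml,
            llf=float(llf),
            df_resid=df_resid,
            k=k,
            aicc=aicc_val,
            fittedvalues=pd.Series(fitted, index=self.row_index),
            resid=pd.Series(y - fitted, index=self.row_index),
            cov_params_=pd.DataFrame(cov_params, index=self.exog_names, columns=self.exog_names),
        )


@dataclass
class GLSResults:
    """Estimates and diagnostics from a :class:`PhyloSpatialGLS` fit."""

    model: PhyloSpatialGLS
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    sigma2: float  # ML residual variance
    llf: float
    df_resid: int
    k: int
    aicc: float
    fittedvalues: pd.Series
    resid: pd.Series
    cov_params_: pd.DataFrame

    @property
    def nobs(self) -> int:
        return len(self.fittedvalues)

    def coefficient_table(self) -> pd.DataFrame:
        """Slope / SE / t / p table, one row per predictor."""
        return pd.DataFrame(
            {
                "slope": self.params,
                "se": self.bse,
                "t": self.tvalues,
                "p": self.pvalues,
            }
        )

    def rsquared(self) -> float:
        """Proportion of (V-whitened) response variation explained."""
        y = self.model.endog
        tss = float(((y - y.mean()) ** 2).sum())
        rss = float((self.resid.to_numpy() ** 2).sum())
        return 1.0 - rss / tss

    def summary(self) -> str:
        lines = [
            "Phylogenetic-spatial GLS results",
            "=" * 56,
            f"n obs: {self.nobs}    params (k): {self.k}    df resid: {self.df_resid}",
            f"log-likelihood: {self.llf:.3f}    AICc: {self.aicc:.2f}",
            f"sigma2 (ML): {self.sigma2:.4f}    R2 (raw scale): {self.rsquared():.4f}",
            "-" * 56,
            f"{'predictor':<24}{'slope':>8}{'SE':>8}{'t':>8}{'p':>8}",
        ]
        for name in self.params.index:
            lines.append(
                f"{name:<24}{self.params[name]:>8.3f}{self.bse[name]:>8.3f}"
                f"{self.tvalues[name]:>8.3f}{self.pvalues[name]:>8.4f}"
            )
        lines.append("=" * 56)
        return "\n".join(lines)


def fit_gls(X, y, cov) -> GLSResults:
    """Convenience wrapper: build and fit a :class:`PhyloSpatialGLS`."""
    return PhyloSpatialGLS(y, X, cov).fit()


def profile_covariance(
    y,
    X,
    tree: dendropy.Tree,
    centroids: pd.DataFrame,
    rho_grid=(5.0, 10.0, 20.0, 40.0, 80.0),
    weight_step: float = 0.2,
) -> tuple[CovarianceModel, GLSResults]:
    """Estimate (w_phylo, w_space, rho) by profile maximum likelihood.

    Evaluates the GLS profile log-likelihood over a simplex grid of
    covariance weights crossed with ``rho_grid`` and returns the best
    blend and its fit.  A coarse grid is adequate because the weights
    enter smoothly and downstream use only needs a reasonable blend.
    """
    species = list(X.index) if isinstance(X, pd.DataFrame) else None
    if species is None:
        raise ValueError("X must be a DataFrame indexed by species")
    best = None
    wgrid = np.arange(0.0, 1.0 + 1e-9, weight_step)
    for w_p in wgrid:
        for w_s in wgrid:
            if w_p + w_s > 1 + 1e-9:
                continue
            for rho in rho_grid if w_s > 0 else rho_grid[:1]:
                cov = build_covariance(tree, species, centroids, w_p, w_s, rho)
                try:
                    res = fit_gls(X, y, cov)
                except np.linalg.LinAlgError:
                    continue
                if best is None or res.llf > best[1].llf:
                    best = (cov, res)
    if best is None:
        raise RuntimeError("no covariance blend produced a valid fit")
    return best


# ---------------------------------------------------------------------------
# Stepwise minimum adequate model
# ---------------------------------------------------------------------------


def stepwise_mam(
    y,
    X: pd.DataFrame,
    cov,
    delta_aicc: float = 2.0,
    quadratic_pairs: dict[str, str] | None = None,
) -> tuple[GLSResults, list[dict]]:
    """Backward/forward stepwise search for the minimum adequate model.

    Backward phase: repeatedly propose deleting the highest-p predictor
    (ties by smaller absolute t, then column order); keep the deletion
    iff AICc improves by at least ``delta_aicc``; stop when the proposal
    fails.  Forward phase: try re-adding each deleted predictor in
    deletion order, keeping it iff AICc again improves by at least
    ``delta_aicc``.  A quadratic term (``quadratic_pairs`` maps it to
    its linear partner) is deleted before its linear term and never
    re-added without it.  Returns the final fit and the full decision
    trace; the degenerate case is the intercept-only model.
    """
    qpairs = {"body_mass_g_sq": "body_mass_g"} if quadratic_pairs is None else quadratic_pairs
    qpairs = {q: l for q, l in qpairs.items() if q in X.columns and l in X.columns}
    cols = list(X.columns)
    current = fit_gls(X[cols], y, cov)
    trace: list[dict] = []
    deleted: list[str] = []

    def deletable(cs: list[str]) -> list[str]:
        # a linear term is pinned while its quadratic remains
        pinned = {l for q, l in qpairs.items() if q in cs}
        return [c for c in cs if c not in pinned]

    while cols:
        cand = deletable(cols)
        if not cand:
            break
        order = sorted(
            cand,
            key=lambda c: (-current.pvalues[c], abs(current.tvalues[c]), cols.index(c)),
        )
        drop = order[0]
        new_cols = [c for c in cols if c != drop]
        new_fit = _fit_subset(y, X, new_cols, cov)
        accepted = new_fit.aicc <= current.aicc - delta_aicc
        trace.append(
            {
                "phase": "backward",
                "predictor": drop,
                "aicc_before": current.aicc,
                "aicc_after": new_fit.aicc,
                "accepted": bool(accepted),
            }
        )
        if not accepted:
            break
        cols, current = new_cols, new_fit
        deleted.append(drop)

    for cand in list(deleted):
        if cand in qpairs and qpairs[cand] not in cols:
            continue  # quadratic may not return without its linear term
        new_cols = cols + [cand]
        new_fit = _fit_subset(y, X, new_cols, cov)
        accepted = new_fit.aicc <= current.aicc - delta_aicc
        trace.append(
            {
                "phase": "forward",
                "predictor": cand,
                "aicc_before": current.aicc,
                "aicc_after": new_fit.aicc,
                "accepted": bool(accepted),
            }
        )
        if accepted:
            cols, current = new_cols, new_fit
            deleted.remove(cand)

    return current, trace


def _fit_subset(y, X: pd.DataFrame, cols: list[str], cov) -> GLSResults:
    if cols:
        return fit_gls(X[cols], y, cov)
    const = pd.DataFrame({"const": np.ones(len(X))}, index=X.index)
    return fit_gls(const, y, cov)


# ---------------------------------------------------------------------------
# Latent risk
# ---------------------------------------------------------------------------


def latent_risk(
    y: pd.Series,
    X: pd.DataFrame,
    predictors: list[str],
    trees,
    centroids: pd.DataFrame,
    w_phylo: float,
    w_space: float,
    rho: float,
    covariances: list[CovarianceModel] | None = None,
) -> pd.DataFrame:
    """Latent extinction risk averaged over a phylogeny sample.

    Refits the chosen model (columns ``predictors`` of ``X``) once per
    tree — each tree contributes its own phylogenetic covariance — and
    computes, per species and tree, the fitted status minus the observed
    status.  Prebuilt per-tree ``covariances`` may be passed to amortize
    covariance construction over repeated calls.  Returns a frame
    indexed by species with columns ``observed``, ``fitted_mean``,
    ``fitted_sd``, ``latent`` (mean over trees) and ``latent_positive``
    (its positive part).
    """
    missing = [p for p in predictors if p not in X.columns]
    if missing:
        raise ValueError(f"predictors absent from X: {missing}")
    species = list(X.index)
    if covariances is None:
        trees = list(trees)
        if not trees:
            raise ValueError("need at least one tree")
        covariances = [
            build_covariance(tree, species, centroids, w_phylo, w_space, rho)
            for tree in trees
        ]
    fitted = np.zeros((len(covariances), len(species)))
    for t_idx, cov in enumerate(covariances):
        res = _fit_subset(y.to_numpy(dtype=float), X, list(predictors), cov)
        fitted[t_idx] = res.fittedvalues.to_numpy()
    mean_fit = fitted.mean(axis=0)
    sd_fit = fitted.std(axis=0, ddof=1) if len(covariances) > 1 else np.zeros(len(species))
    latent = mean_fit - y.to_numpy(dtype=float)
    return pd.DataFrame(
        {
            "observed": y.to_numpy(dtype=float),
            "fitted_mean": mean_fit,
            "fitted_sd": sd_fit,
            "latent": latent,
            "latent_positive": np.maximum(latent, 0.0),
        },
        index=pd.Index(species, name="species"),
    )
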