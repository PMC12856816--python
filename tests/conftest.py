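import numpy as np
import pandas as pd
import pytest

from latentplan import pipeline, simulate
from latentplan.config import load_config


@pytest.fixture(scope="session")
def small_cfg() -> simulate.SimConfig:
    return simulate.SimConfig(
        grid_nrows=30, grid_ncols=30, n_species=12, n_trees=3, seed=42
    )


@pytest.fixture(scope="session")
def small_trees(small_cfg):
    return simulate.simulate_phylogenies(small_cfg.n_species, small_cfg.n_trees, seed=42)


@pytest.fixture(scope="session")
def small_system(small_cfg, small_trees):
    """A compact synthetic study system shared across test modules."""
    landscape = simulate.simulate_landscape(small_cfg, seed=43)
    sizes = simulate.default_range_sizes(small_cfg, seed=44)
    ranges = simulate.simulate_ranges(small_cfg, sizes, seed=45)
    tenure, pa_mask, pastoral = simulate.simulate_tenure(small_cfg, seed=46)
    traits = simulate.simulate_traits(small_trees[0], seed=47)
    return {
        "cfg": small_cfg,
        "trees": small_trees,
        "landscape": landscape,
        "ranges": ranges,
        "tenure": tenure,
        "pa_mask": pa_mask,
        "pastoral": pastoral,
        "traits": traits,
    }


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One full default-config pipeline run, shared where possible."""
    cfg = load_config()
    out = tmp_path_factory.mktemp("demo_run")
    return cfg, pipeline.run_all(cfg, out), out


def random_instance(rng: np.random.Generator, n_pu: int, n_sp: int, lock: bool = True):
    """A random minimum-set problem instance (feasible by construction)."""
    from latentplan.prioritize import PrioritizationProblem

    costs = pd.Series(rng.uniform(0.5, 5.0, n_pu), index=range(n_pu))
    features = pd.DataFrame(
        rng.uniform(0.0, 2.0, (n_pu, n_sp)) * (rng.random((n_pu, n_sp)) < 0.6),
        index=range(n_pu),
        columns=[f"s{j}" for j in range(n_sp)],
    )
    locked_in = pd.Series(False, index=range(n_pu))
    locked_out = pd.Series(False, index=range(n_pu))
    if lock and n_pu > 4:
        locked_in.iloc[int(rng.integers(n_pu))] = True
        j = int(rng.integers(n_pu))
        if not locked_in.iloc[j]:
            locked_out.iloc[j] = True
    supply = features.loc[~locked_out].sum(axis=0)
    targets = supply * rng.uniform(0.2, 0.8, n_sp)
    return PrioritizationProblem(
        costs=costs, features=features, targets=targets,
        locked_in=locked_in, locked_out=locked_out,
    )


def brute_force_optimum(problem) -> float:
    """Exhaustive enumeration oracle for small minimum-set instances."""
    import itertools

    n = len(problem.costs)
    c = problem.costs.to_numpy()
    A = problem.features.to_numpy()
    tgt = problem.targets.to_numpy()
    li = problem.locked_in.to_numpy()
    lo = problem.locked_out.to_numpy()
    free = [i for i in range(n) if not li[i] and not lo[i]]
    best = np.inf
    base = li.copy()
    for r in range(len(free) + 1):
        for combo in itertools.combinations(free, r):
            x = base.copy()
            x[list(combo)] = True
            if (A[x].sum(axis=0) >= tgt - 1e-9).all():
                cost = c[x].sum()
                best = min(best, cost)
    return best
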