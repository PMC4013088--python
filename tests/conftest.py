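import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import invasimap as iv

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture
def small_grid() -> iv.Grid:
    return iv.Grid(n_rows=4, n_cols=4, cell_size=250.0, origin_x=0.0, origin_y=1000.0)


@pytest.fixture
def layer_10x10() -> iv.RasterLayer:
    grid = iv.Grid(10, 10, 250.0)
    rng = np.random.default_rng(0)
    return iv.RasterLayer(grid, rng.uniform(0, 1, grid.shape), "random")


@pytest.fixture(scope="session")
def recovery_run():
    """One full synthetic-recovery experiment shared by the slower checks.

    Default scenario (three guild species on a 100x100 grid), thinning,
    10-replicate three-learner ensembles per species, future projection,
    diversity stacking. Fixed seed so results are reproducible.
    """
    from scipy.stats import spearmanr

    import invasimap.invasibility_metrics as im
    from invasimap.reporting import project_ensemble
    from invasimap.sdm_ensemble import replicate_metrics

    scenario = iv.generate_scenario(seed=0)
    occ = iv.thin_to_grid(scenario.occurrences, scenario.grid)
    ensembles_b, ensembles_f, per_species = [], [], {}
    for i, sp in enumerate(scenario.species):
        em = iv.fit_species_ensemble(
            occ, sp.species_code, scenario.baseline, n_reps=10, seed=100 + i
        )
        ensembles_b.append(em)
        ensembles_f.append(project_ensemble(em, scenario.future))
        metrics = replicate_metrics(em.replicates)
        truth = scenario.true_suitability(sp.species_code).values.ravel()
        rho = spearmanr(em.weighted_mean.values.ravel(), truth).statistic
        per_species[sp.species_code] = {
            "median_auc": float(metrics["auc"].median()),
            "median_tss": float(metrics["tss"].median()),
            "spearman_rho": float(rho),
        }
    div_b, div_f, aii = im.invasibility_analysis(ensembles_b, ensembles_f)
    return {
        "scenario": scenario,
        "occ": occ,
        "ensembles_baseline": ensembles_b,
        "ensembles_future": ensembles_f,
        "per_species": per_species,
        "diversity": (div_b, div_f),
        "aii": aii,
    }
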