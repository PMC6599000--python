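import warnings

import numpy as np
import pytest

from isoassign.raster import Grid
from isoassign.synthetic import (default_scenario, generate_bears,
                                 generate_fields, generate_subpops,
                                 three_plateau_scenario)


def make_records(scenario, cell=1.5):
    """Records + polygons + true fields for a scenario (shared helper)."""
    polygons = generate_subpops(scenario)
    grid = Grid.from_bbox(scenario.bbox, cell)
    fields = generate_fields(scenario, grid)
    return generate_bears(scenario, polygons, fields), polygons, fields


@pytest.fixture(scope="session")
def default_records():
    """Moderate-size draw from the default gradient scenario."""
    scenario = default_scenario(seed=7)
    records, polygons, fields = make_records(scenario)
    return records


@pytest.fixture(scope="session")
def plateau_run():
    """One full three-plateau end-to-end pass (shared across tests)."""
    from isoassign.assignment import cluster_stats, evaluate_accuracy
    from isoassign.clusters import build_cluster_raster
    from isoassign.isoscape import (align_rasters, ebk_surface, outlier_filter,
                                    stratified_split)

    seed = 11
    scenario = three_plateau_scenario(seed=seed)
    records, polygons, fields = make_records(scenario)
    adults = records[records.age_class == "adult"].reset_index(drop=True)
    train, test = stratified_split(adults, 0.7, seed=seed)
    isotopes = ["d13C", "d15N", "d2H"]
    surfaces = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for iso in isotopes:
            kept, _ = outlier_filter(train, iso)
            surfaces.append(ebk_surface(kept, iso, Grid.from_bbox(scenario.bbox, 1.5),
                                        n_sims=10, subset_size=100, seed=seed))
        stack = align_rasters(surfaces)
        craster = build_cluster_raster(stack, isotopes, k="auto", seed=seed, k_max=10)
        stats = cluster_stats(train, craster, isotopes)
        accuracy = evaluate_accuracy(test, stats, craster, isotopes)
    return dict(scenario=scenario, fields=fields, train=train, test=test,
                isotopes=isotopes, surfaces=surfaces, stack=stack,
                craster=craster, stats=stats, accuracy=accuracy)


def rng_of(seed):
    return np.random.default_rng(seed)
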