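"""Shared fixtures: small meshes and equilibrated synthetic sheets.

Expensive fixtures are session-scoped so the forward simulations run once.
"""

import numpy as np
import pytest

from epimorph import forces, morphometrics, spatial, synthetic
from epimorph.mesh import hexagonal_lattice
from epimorph.synthetic import DomainSpec, TensionModel


@pytest.fixture(scope="session")
def hex_lattice():
    return hexagonal_lattice(6, 6, side=1.0)


@pytest.fixture(scope="session")
def small_domain():
    return DomainSpec(width=120.0, height=120.0, notch_radius=25.0)


@pytest.fixture(scope="session")
def voronoi_sheet(small_domain):
    return synthetic.generate_voronoi_sheet(small_domain, 64, lloyd_iters=3, seed=1)


@pytest.fixture(scope="session")
def equilibrated_sheet(small_domain):
    """A plain (unpatterned mechanics) equilibrated sheet with ground truth."""
    tess = synthetic.generate_voronoi_sheet(small_domain, 100, lloyd_iters=3, seed=7)
    pattern = synthetic.dpw_pattern(small_domain)
    truth = synthetic.impose_region_pattern(tess, pattern)
    truth = synthetic.assign_mechanics(
        tess, truth,
        TensionModel(base_cv=0.2, anisotropy_gain=0.0, alignment_gain=0.0),
        seed=11,
    )
    tess, truth = synthetic.relax_to_equilibrium(tess, truth, tol=1e-6)
    return tess, truth


@pytest.fixture(scope="session")
def dpw_cohort():
    """Small patterned cohort (3 samples) run through features + inference."""
    import pandas as pd

    dom = DomainSpec(width=200.0, height=200.0, notch_radius=40.0)
    pat = synthetic.dpw_pattern(dom)
    tables, graphs, truths = [], {}, {}
    for k in range(3):
        tess, truth = synthetic.generate_sample(
            seed=500 * (k + 1), n_cells=300, domain=dom, pattern=pat,
            sample_id=f"t{k}",
        )
        feats = morphometrics.compute_features(tess)
        sol = forces.solve_bayesian(forces.build_balance_system(tess))
        feats = forces.attach_mechanics(feats, tess, sol)
        feats["region_label"] = np.asarray(truth.region_label)
        tables.append(feats)
        graphs[tess.sample_id] = spatial.build_adjacency(tess)
        truths[tess.sample_id] = truth
    return pd.concat(tables, ignore_index=True), graphs, truths
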