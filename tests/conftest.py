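import numpy as np
import pytest

from ermorph.workflows import train_default_classifier


@pytest.fixture(scope="session")
def trained_model():
    """The default ER pixel classifier, trained once per session."""
    return train_default_classifier(seed=0)


@pytest.fixture(scope="session")
def flat_edge_solutions():
    """Flat-edge (kappa = 0) solutions for both load modes and all layouts."""
    from ermorph.mechanics import ERLayout, LoadCase, MaterialSet, build_domain, solve
    mat = MaterialSet()
    out = {}
    for mode in ("protrusion", "contraction"):
        for kind in ("perpendicular", "parallel", "sheet"):
            dom = build_domain(0.0, ERLayout(kind))
            out[(mode, kind)] = solve(dom, mat, LoadCase(mode))
    return out


@pytest.fixture(scope="session")
def protrusion_sweep():
    from ermorph.mechanics import curvature_sweep
    return curvature_sweep([0.01 * i for i in range(1, 9)], loads=("protrusion",))


@pytest.fixture(scope="session")
def contraction_sweep():
    from ermorph.mechanics import curvature_sweep
    return curvature_sweep([-0.01 * i for i in range(1, 9)], loads=("contraction",))
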