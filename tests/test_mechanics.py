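"""FE kernel oracles, domain construction, layout orderings, energy split."""

import numpy as np
import pytest

from ermorph.fem import fe_solve, rect_mesh
from ermorph.mechanics import (ER, CellFrontDomain, ERLayout, FESolution,
                               LoadCase, MaterialSet, _edge_normal,
                               build_domain, curvature_sweep, energy_split,
                               ordering_report, solve, strain_energy_density)


class TestFEOracles:
    def test_patch_test_exact(self):
        # prescribed linear displacement on the boundary of a distorted mesh
        # must reproduce the uniform strain field to machine precision
        nodes, elems = rect_mesh(2.0, 1.0, 4, 3)
        rng = np.random.default_rng(0)
        interior = ((nodes[:, 0] > 1e-9) & (nodes[:, 0] < 2 - 1e-9)
                    & (nodes[:, 1] > 1e-9) & (nodes[:, 1] < 1 - 1e-9))
        nodes[interior] += rng.uniform(-0.05, 0.05, size=(interior.sum(), 2))
        A = np.array([[0.01, 0.002], [0.002, -0.005]])
        fixed = np.zeros(nodes.shape, dtype=bool)
        fixed[~interior] = True
        res = fe_solve(nodes, elems, np.full(len(elems), 5.0),
                       np.full(len(elems), 0.3), fixed=fixed,
                       prescribed=nodes @ A.T)
        assert np.abs(res.u - nodes @ A.T).max() < 1e-10
        assert np.abs(res.strain - [0.01, -0.005, 0.004]).max() < 1e-10

    def test_uniaxial_bar_energy(self):
        # free lateral contraction: U = sigma^2 / (2 E) exactly
        nodes, elems = rect_mesh(10.0, 2.0, 20, 4)
        E, sigma = 3.0, 0.2
        fixed = np.zeros(nodes.shape, dtype=bool)
        left = np.isclose(nodes[:, 0], 0.0)
        fixed[left, 0] = True
        fixed[left & np.isclose(nodes[:, 1], 0.0), 1] = True
        right = np.flatnonzero(np.isclose(nodes[:, 0], 10.0))
        right = right[np.argsort(nodes[right, 1])]
        tr = [(right[i], right[i + 1], sigma, 0.0) for i in range(len(right) - 1)]
        res = fe_solve(nodes, elems, np.full(len(elems), E),
                       np.full(len(elems), 0.45), fixed=fixed,
                       edge_tractions=tr)
        assert res.U == pytest.approx(sigma**2 / (2 * E), rel=0.005)

    def test_cantilever_vs_beam_theory(self):
        # slenderness 10: tip deflection within 2% of Euler-Bernoulli
        L, H, E, tau = 20.0, 2.0, 100.0, 0.01
        nodes, elems = rect_mesh(L, H, 60, 6)
        fixed = np.zeros(nodes.shape, dtype=bool)
        fixed[np.isclose(nodes[:, 0], 0.0)] = True
        right = np.flatnonzero(np.isclose(nodes[:, 0], L))
        right = right[np.argsort(nodes[right, 1])]
        tr = [(right[i], right[i + 1], 0.0, tau) for i in range(len(right) - 1)]
        res = fe_solve(nodes, elems, np.full(len(elems), E),
                       np.full(len(elems), 0.3), fixed=fixed,
                       edge_tractions=tr)
        P, I = tau * H, H**3 / 12
        delta_eb = P * L**3 / (3 * E * I)
        mid = np.flatnonzero(np.isclose(nodes[:, 0], L)
                             & np.isclose(nodes[:, 1], H / 2))[0]
        assert res.u[mid, 1] == pytest.approx(delta_eb, rel=0.02)

    def test_zero_load_nullity(self):
        nodes, elems = rect_mesh(5.0, 2.0, 10, 4)
        fixed = np.zeros(nodes.shape, dtype=bool)
        fixed[np.isclose(nodes[:, 1], 0.0)] = True
        res = fe_solve(nodes, elems, np.full(len(elems), 1.0),
                       np.full(len(elems), 0.45), fixed=fixed)
        assert res.U == 0.0
        assert np.abs(res.u).max() == 0.0


class TestBuildDomain:
    def test_sheet_phi_realized(self):
        dom = build_domain(0.0, ERLayout("sheet", phi=0.15))
        assert abs(dom.phi_realized - 0.15) <= 0.0015

    def test_layouts_equal_area(self):
        # the equal-ER-volume constraint across the three layouts
        for kap in (0.0, 0.05, -0.05):
            phis = [build_domain(kap, ERLayout(kind)).phi_realized
                    for kind in ("perpendicular", "parallel", "sheet")]
            assert max(phis) - min(phis) <= 0.01 * 0.15 + 0.003

    def test_perpendicular_axes_normal_to_edge(self):
        dom = build_domain(0.05, ERLayout("perpendicular"))
        normals = _edge_normal(0.05, dom.width, dom.depth, dom.tubule_anchor)
        cosang = np.sum(dom.tubule_axes * normals, axis=1)
        assert np.all(np.degrees(np.arccos(np.clip(cosang, -1, 1))) <= 2.0)

    def test_deterministic_meshing(self):
        d1 = build_domain(0.03, ERLayout("parallel"))
        d2 = build_domain(0.03, ERLayout("parallel"))
        assert np.array_equal(d1.nodes, d2.nodes)
        assert np.array_equal(d1.region, d2.region)

    def test_unresolvable_geometry(self):
        with pytest.raises(ValueError, match="coarse"):
            build_domain(0.0, ERLayout("sheet"), mesh_size=0.2)

    def test_arc_too_large(self):
        with pytest.raises(ValueError, match="2/W"):
            build_domain(0.2, ERLayout("sheet"))


class TestSolve:
    def test_quadratic_load_scaling(self):
        dom = build_domain(0.0, ERLayout("sheet"), width=10.0, depth=8.0)
        mat = MaterialSet()
        u1 = solve(dom, mat, LoadCase("protrusion", magnitude=0.1)).U
        u2 = solve(dom, mat, LoadCase("protrusion", magnitude=0.2)).U
        assert u2 / u1 == pytest.approx(4.0, rel=0.01)

    def test_energy_nonnegative_and_converged(self, flat_edge_solutions):
        for sol in flat_edge_solutions.values():
            assert sol.U >= 0
            assert sol.converged
            assert strain_energy_density(sol) == sol.U

    def test_invalid_load(self):
        with pytest.raises(ValueError):
            LoadCase("squeeze")
        with pytest.raises(ValueError):
            LoadCase("protrusion", magnitude=-1.0)

    def test_material_validation(self):
        with pytest.raises(ValueError):
            MaterialSet(E_ER=0.5)   # ER must be stiffer than cytoplasm
        with pytest.raises(ValueError):
            MaterialSet(nu=0.6)


def _bar_domain_all_er(nx=6, ny=40, L=1.2, H=8.0):
    """A single vertical ER 'tubule' bar for energy-split oracles."""
    nodes, elems = rect_mesh(L, H, nx, ny)
    n_el = len(elems)
    quad = nodes[elems]
    dom = CellFrontDomain(
        width=L, depth=H, kappa=0.0, t_cortex=0.0, thickness=1.0,
        mesh_size=H / ny, nodes=nodes, elems=elems,
        region=np.full(n_el, ER), centroids=quad.mean(axis=1),
        areas=np.full(n_el, (L / nx) * (H / ny)),
        layout=ERLayout("perpendicular"),
        er_structure_id=np.zeros(n_el, dtype=int),
        er_axis=np.tile([0.0, 1.0], (n_el, 1)),
        er_s=quad.mean(axis=1)[:, 1])
    return dom


def _fake_solution(dom, fixed, tractions, E=10.0, nu=0.3):
    res = fe_solve(dom.nodes, dom.elems, np.full(len(dom.elems), E),
                   np.full(len(dom.elems), nu), fixed=fixed,
                   edge_tractions=tractions)
    return FESolution(result=res, domain=dom,
                      load=LoadCase("protrusion"), materials=MaterialSet(),
                      tip_displacement=0.0, U=res.U)


class TestEnergySplit:
    def test_pure_extension_is_stretching(self):
        dom = _bar_domain_all_er()
        nodes = dom.nodes
        fixed = np.zeros(nodes.shape, dtype=bool)
        bottom = np.isclose(nodes[:, 1], 0.0)
        fixed[bottom, 1] = True
        fixed[bottom & np.isclose(nodes[:, 0], 0.0), 0] = True
        top = np.flatnonzero(np.isclose(nodes[:, 1], dom.depth))
        top = top[np.argsort(nodes[top, 0])]
        tr = [(top[i], top[i + 1], 0.0, 0.05) for i in range(len(top) - 1)]
        sol = _fake_solution(dom, fixed, tr)
        bend, stretch = energy_split(sol)
        assert bend <= 0.05
        assert bend + stretch == pytest.approx(1.0, abs=1e-9)

    def test_cantilever_tip_load_is_bending(self):
        dom = _bar_domain_all_er()
        nodes = dom.nodes
        fixed = np.zeros(nodes.shape, dtype=bool)
        fixed[np.isclose(nodes[:, 1], 0.0)] = True   # clamp the base
        top = np.flatnonzero(np.isclose(nodes[:, 1], dom.depth))
        top = top[np.argsort(nodes[top, 0])]
        tr = [(top[i], top[i + 1], 0.05, 0.0) for i in range(len(top) - 1)]
        sol = _fake_solution(dom, fixed, tr)
        bend, _ = energy_split(sol)
        assert bend >= 0.8

    def test_contraction_bends_more_than_protrusion(self):
        # curved-front comparison at matched |load|
        mat = MaterialSet()
        sc = solve(build_domain(-0.05, ERLayout("perpendicular")), mat,
                   LoadCase("contraction"))
        sp = solve(build_domain(0.05, ERLayout("perpendicular")), mat,
                   LoadCase("protrusion"))
        assert energy_split(sc)[0] > energy_split(sp)[0]


class TestOrderings:
    def test_flat_contraction_sheet_below_perpendicular(self, flat_edge_solutions):
        assert (flat_edge_solutions[("contraction", "sheet")].U
                < flat_edge_solutions[("contraction", "perpendicular")].U)

    def test_flat_protrusion_perpendicular_below_sheet(self, flat_edge_solutions):
        assert (flat_edge_solutions[("protrusion", "perpendicular")].U
                < flat_edge_solutions[("protrusion", "sheet")].U)

    def test_flat_contraction_parallel_between(self, flat_edge_solutions):
        u = {k: s.U for (m, k), s in flat_edge_solutions.items()
             if m == "contraction"}
        assert u["sheet"] < u["parallel"] < u["perpendicular"]


class TestSweepMachinery:
    def test_empty_kappas_rejected(self):
        with pytest.raises(ValueError):
            curvature_sweep([])

    def test_u_norm_consistent(self, protrusion_sweep):
        df = protrusion_sweep.table
        ratio = df["U"] / df["U_norm"]
        assert ratio.std() / ratio.mean() < 1e-9   # one reference per mode

    def test_ordering_report_rankings(self, contraction_sweep):
        rep = ordering_report(contraction_sweep)
        assert (rep["ranking"] == "sheet < parallel < perpendicular").all()

    def test_ordering_report_convex(self, protrusion_sweep):
        rep = ordering_report(protrusion_sweep)
        assert all(r.startswith("perpendicular") for r in rep["ranking"])

    def test_incomplete_factorial_errors(self, protrusion_sweep):
        import copy
        sw = copy.deepcopy(protrusion_sweep)
        sw.table = sw.table[sw.table["layout"] != "sheet"]
        with pytest.raises(ValueError, match="missing"):
            ordering_report(sw)


class TestMeshConvergence:
    def test_refinement_stability(self):
        # one uniform refinement: U moves < 2% and the protrusion ordering
        # (perpendicular below sheet) is unchanged
        mat = MaterialSet()
        U = {}
        for mesh in (0.1, 0.05):
            for kind in ("perpendicular", "sheet"):
                dom = build_domain(0.0, ERLayout(kind), mesh_size=mesh)
                U[(mesh, kind)] = solve(dom, mat, LoadCase("protrusion")).U
        for kind in ("perpendicular", "sheet"):
            assert abs(U[(0.05, kind)] - U[(0.1, kind)]) / U[(0.1, kind)] < 0.02
        assert U[(0.05, "perpendicular")] < U[(0.05, "sheet")]
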