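"""Geometry: circle fits, spline curvature, sign convention, inclusion filter."""

import numpy as np
import pytest
from scipy.optimize import minimize

from ermorph.geometry import (
    Contour,
    assign_sign,
    fit_circle,
    front_roi,
    perimeter_contact_fraction,
    spline_curvature,
)


def circle_points(radius, n=20, center=(0.0, 0.0), span=(0.0, 2 * np.pi)):
    t = np.linspace(*span, n)
    return np.column_stack([center[0] + radius * np.cos(t),
                            center[1] + radius * np.sin(t)])


def geometric_circle_oracle(pts):
    """Independent oracle: directly minimize sum of squared radial residuals."""
    def cost(p):
        cx, cy, r = p
        return np.sum((np.hypot(pts[:, 0] - cx, pts[:, 1] - cy) - r) ** 2)
    c0 = pts.mean(axis=0)
    r0 = np.mean(np.hypot(pts[:, 0] - c0[0], pts[:, 1] - c0[1]))
    res = minimize(cost, [c0[0], c0[1], r0], method="Nelder-Mead",
                   options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 20000})
    return res.x[2]


class TestFitCircle:
    def test_exact_circle(self):
        fit = fit_circle(circle_points(10.0))
        assert fit.kappa_magnitude == pytest.approx(0.100, abs=1e-9)
        assert not fit.degenerate

    def test_collinear_degenerate(self):
        fit = fit_circle(np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]]))
        assert fit.degenerate
        assert fit.kappa_magnitude == 0.0
        assert np.isinf(fit.radius)

    def test_noisy_circle_vs_geometric_oracle(self):
        rng = np.random.default_rng(42)
        pts = circle_points(25.0, n=50) + rng.normal(0.0, 0.2, size=(50, 2))
        fit = fit_circle(pts)
        assert abs(fit.kappa_magnitude - 0.04) / 0.04 < 0.02
        r_oracle = geometric_circle_oracle(pts)
        assert fit.radius == pytest.approx(r_oracle, rel=1e-3)

    @pytest.mark.parametrize("radius", [1.0, 10.0, 100.0, 1000.0])
    def test_noiseless_consistency(self, radius):
        fit = fit_circle(circle_points(radius, n=40, span=(0.2, 2.0)))
        assert abs(fit.kappa_magnitude - 1.0 / radius) < 1e-9

    def test_scale_covariance(self):
        pts = circle_points(12.0, n=30, span=(0.1, 2.5))
        for lam in (0.1, 3.0, 50.0):
            k1 = fit_circle(pts).kappa_magnitude
            k2 = fit_circle(lam * pts).kappa_magnitude
            assert k2 == pytest.approx(k1 / lam, rel=1e-9)


class TestSplineCurvature:
    def test_semicircular_arc(self):
        pts = circle_points(20.0, n=60, span=(0.0, np.pi))
        prof = spline_curvature(Contour(pts), smoothing=1e-6)
        assert abs(abs(prof.arc_mean()) - 0.050) < 0.001

    def test_straight_segment(self):
        x = np.linspace(0, 30, 40)
        prof = spline_curvature(Contour(np.column_stack([x, np.zeros_like(x)])),
                                smoothing=1e-9)
        assert np.max(np.abs(prof.kappa)) < 1e-6

    def test_sinusoid_crest_closed_form(self):
        # y = A sin(x/lam): curvature at a crest is A/lam^2 (y'=0 there)
        A, lam = 2.0, 5.0
        x = np.linspace(0, 4 * np.pi * lam, 800)
        prof = spline_curvature(Contour(np.column_stack([x, A * np.sin(x / lam)])),
                                smoothing=1e-8, n_samples=2000)
        crest = np.max(np.abs(prof.kappa[50:-50]))
        assert abs(crest - A / lam**2) / (A / lam**2) < 0.05

    def test_too_few_vertices(self):
        with pytest.raises(ValueError):
            spline_curvature(Contour(np.array([[0, 0], [1, 0], [2, 1], [3, 0]])))

    def test_nonpositive_smoothing(self):
        pts = circle_points(5.0, n=20, span=(0, np.pi))
        with pytest.raises(ValueError):
            spline_curvature(Contour(pts), smoothing=-1.0)

    def test_scale_covariance(self):
        pts = circle_points(8.0, n=50, span=(0.0, np.pi))
        p1 = spline_curvature(Contour(pts), smoothing=1e-8)
        p2 = spline_curvature(Contour(3.0 * pts), smoothing=1e-8)
        assert abs(p2.arc_mean()) == pytest.approx(abs(p1.arc_mean()) / 3.0, rel=1e-3)


class TestAssignSign:
    # y-down image frame; gap above the edge (smaller y), monolayer below
    def test_bump_toward_gap_positive(self):
        # arc bulging upward (toward gap at y<0): circle centre below
        pts = circle_points(10.0, n=30, center=(0, 10.0), span=(np.pi * 0.25, np.pi * 0.75))
        pts[:, 1] = 10.0 - (pts[:, 1] - 10.0)  # reflect to bulge to -y
        sc = assign_sign(0.1, Contour(pts), gap_side_probe=(0.0, -30.0))
        assert sc.kappa > 0

    def test_indent_into_monolayer_negative(self):
        # arc bowing downward into the monolayer: centre on the gap side
        pts = circle_points(10.0, n=30, center=(0, -10.0), span=(-np.pi * 0.75, -np.pi * 0.25))
        pts[:, 1] = -10.0 - (pts[:, 1] + 10.0)
        sc = assign_sign(0.1, Contour(pts), gap_side_probe=(0.0, -30.0))
        assert sc.kappa < 0

    def test_flat_edge_zero(self):
        pts = np.column_stack([np.linspace(0, 20, 10), np.zeros(10)])
        sc = assign_sign(0.0, Contour(pts), gap_side_probe=(10.0, -5.0))
        assert sc.kappa == 0.0

    def test_probe_on_edge_rejected(self):
        pts = circle_points(10.0, n=30, span=(0.2, 2.0))
        with pytest.raises(ValueError):
            assign_sign(0.1, Contour(pts), gap_side_probe=tuple(pts[5]))


class TestContactFraction:
    def square_cell(self, side=10.0):
        return Contour(np.array([[0, 0], [side, 0], [side, side], [0, side]],
                                dtype=float), closed=True)

    def test_quarter_contact(self):
        # one 10-um side of a 40-um perimeter coincides with the edge: 25%
        cell = self.square_cell()
        edge = Contour(np.array([[-20.0, 0.0], [40.0, 0.0], [40.1, 0.0]]))
        frac, include = perimeter_contact_fraction(cell, edge, tol=0.05)
        assert frac == pytest.approx(0.25, abs=0.01)
        assert include

    def test_interior_cell_excluded(self):
        cell = self.square_cell()
        edge = Contour(np.array([[-20.0, -50.0], [40.0, -50.0], [41.0, -50.0]]))
        frac, include = perimeter_contact_fraction(cell, edge, tol=1.0)
        assert frac == 0.0
        assert not include

    def test_exactly_twenty_percent_excluded(self):
        # the inclusion rule is strict: exactly 20% contact does not qualify
        from ermorph.geometry import passes_contact_filter
        assert not passes_contact_filter(0.20)
        assert passes_contact_filter(0.2000001)
        # and the measured fraction drives the decision through the same rule
        cell = Contour(np.array([[0, 0], [10, 0], [10, 15], [0, 15]], dtype=float),
                       closed=True)  # perimeter 50, bottom side 10 -> 0.20
        edge = Contour(np.array([[-20.0, 0.0], [40.0, 0.0], [40.1, 0.0]]))
        frac, include = perimeter_contact_fraction(cell, edge, tol=0.05)
        assert frac == pytest.approx(0.20, abs=0.005)
        assert include == passes_contact_filter(frac)

    def test_monotone_in_tol(self):
        cell = self.square_cell()
        edge = Contour(np.array([[-20.0, -2.0], [40.0, -2.0], [40.1, -2.0]]))
        fracs = [perimeter_contact_fraction(cell, edge, tol=t)[0]
                 for t in (0.5, 1.0, 2.5, 5.0, 20.0)]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_bad_tol(self):
        with pytest.raises(ValueError):
            perimeter_contact_fraction(self.square_cell(),
                                       self.square_cell(), tol=0.0)


class TestCellTissueCorrespondence:
    """Per-cell circle fits and the tissue-scale spline must agree in sign
    for every cell passing the perimeter-contact filter; interior cells are
    filtered out and never reported."""

    @pytest.mark.parametrize("kappa", [0.04, -0.04])
    def test_signs_agree_for_included_cells(self, kappa):
        from ermorph.geometry import spline_curvature
        R = 1.0 / abs(kappa)
        # wound edge: arc through x in [-12, 12]; gap above (y < edge)
        th = np.arcsin(12.0 / R)
        t = np.linspace(-th, th, 80)
        yc = R if kappa > 0 else -R
        sgn = 1.0 if kappa > 0 else -1.0
        edge_pts = np.column_stack([R * np.sin(t), yc - sgn * R * np.cos(t)])
        wound = Contour(edge_pts)
        probe = (0.0, -30.0)   # gap side: above the edge (y negative)
        # three edge cells, each contacting a third of the arc, one interior
        reported = []
        for lo, hi in ((-th, -th / 3), (-th / 3, th / 3), (th / 3, th)):
            tt = np.linspace(lo, hi, 30)
            contact = np.column_stack([R * np.sin(tt), yc - sgn * R * np.cos(tt)])
            rear = contact[::-1] + np.array([0.0, 12.0])
            cell = Contour(np.vstack([contact, rear]), closed=True)
            frac, include = perimeter_contact_fraction(cell, wound, tol=0.05)
            assert include
            fit = fit_circle(contact)
            cell_sign = np.sign(assign_sign(fit.kappa_magnitude, Contour(contact),
                                            probe).kappa)
            tissue_fit = fit_circle(wound.vertices)
            tissue_sign = np.sign(assign_sign(tissue_fit.kappa_magnitude, wound,
                                              probe).kappa)
            # tissue-scale spline magnitude agrees with the arc radius
            prof = spline_curvature(wound, smoothing=1e-6)
            assert abs(abs(prof.arc_mean()) - abs(kappa)) / abs(kappa) < 0.02
            assert cell_sign == tissue_sign == np.sign(kappa)
            reported.append(cell)
        interior = Contour(np.array([[-5.0, 30.0], [5.0, 30.0],
                                     [5.0, 40.0], [-5.0, 40.0]]), closed=True)
        frac, include = perimeter_contact_fraction(interior, wound, tol=0.05)
        assert not include


class TestFrontROI:
    def test_rectangle_strip(self):
        cell = Contour(np.array([[0, 0], [12.0, 0], [12.0, 20.0], [0, 20.0]]),
                       closed=True)
        edge = Contour(np.array([[-30.0, 0.0], [50.0, 0.0], [50.1, 0.0]]))
        roi = front_roi(cell, edge, d_front=5.0)
        assert roi.area == pytest.approx(5.0 * 12.0, rel=1e-6)
        assert abs(roi.edge_tangent_deg % 180.0) < 1e-6

    def test_dfront_exceeds_cell(self):
        cell = Contour(np.array([[0, 0], [12.0, 0], [12.0, 8.0], [0, 8.0]]),
                       closed=True)
        edge = Contour(np.array([[-30.0, 0.0], [50.0, 0.0], [50.1, 0.0]]))
        roi = front_roi(cell, edge, d_front=30.0)
        assert roi.area == pytest.approx(12.0 * 8.0, rel=1e-6)

    def test_annular_sector_area(self):
        # convex arc edge of radius R; cell = sector out to R + depth behind it.
        # Analytic ROI area for band depth d: theta/2 * (R^2 - (R-d)^2)
        R, d = 30.0, 5.0
        theta = np.linspace(-0.4, 0.4, 200)
        arc = np.column_stack([R * np.sin(theta), -R * np.cos(theta) + R])
        inner = np.column_stack([(R - 15.0) * np.sin(theta[::-1]),
                                 -(R - 15.0) * np.cos(theta[::-1]) + R])
        cell = Contour(np.vstack([arc, inner]), closed=True)
        edge = Contour(arc)
        roi = front_roi(cell, edge, d_front=d)
        analytic = 0.8 / 2.0 * (R**2 - (R - d) ** 2)
        assert abs(roi.area - analytic) / analytic < 0.02

    def test_cell_away_from_edge(self):
        cell = Contour(np.array([[0, 50.0], [10, 50.0], [10, 60.0], [0, 60.0]]),
                       closed=True)
        edge = Contour(np.array([[-30.0, 0.0], [50.0, 0.0], [50.1, 0.0]]))
        with pytest.raises(ValueError, match="not at edge"):
            front_roi(cell, edge, d_front=5.0)
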