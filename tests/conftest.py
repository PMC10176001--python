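"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial import Delaunay

from mapresponder.mapping import GridSpec, StimulationEvent


@pytest.fixture
def grid() -> GridSpec:
    return GridSpec()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def barycentric_interpolate(points, values, queries, fill_value=0.0):
    """Brute-force linear interpolation oracle.

    Triangulates ``points`` and, for each query, locates a containing triangle
    by testing barycentric coordinates against every simplex, then combines
    vertex values with barycentric weights.  Independent of scipy's
    interpolators (plain 2x2 linear solves only).
    """
    points = np.asarray(points, float)
    values = np.asarray(values, float)
    queries = np.asarray(queries, float)
    tri = Delaunay(points)
    out = np.full(len(queries), fill_value, dtype=float)
    done = np.zeros(len(queries), dtype=bool)
    for simplex in tri.simplices:
        a, b, c = points[simplex]
        t = np.array([[b[0] - a[0], c[0] - a[0]], [b[1] - a[1], c[1] - a[1]]])
        inv = np.linalg.inv(t)
        lam12 = (queries - a) @ inv.T
        lam0 = 1.0 - lam12.sum(axis=1)
        inside = (lam12[:, 0] >= -1e-9) & (lam12[:, 1] >= -1e-9) & (lam0 >= -1e-9)
        take = inside & ~done
        out[take] = (
            lam0[take] * values[simplex[0]]
            + lam12[take, 0] * values[simplex[1]]
            + lam12[take, 1] * values[simplex[2]]
        )
        done |= inside
    return out


def mixed_anova_closed_form(y_baseline, y_day2, groups):
    """Closed-form 2x2 mixed-ANOVA oracle via the three t^2 identities.

    * group F = squared pooled two-sample t on subject means;
    * interaction F = squared pooled two-sample t on change scores;
    * time F = squared one-sample-style t of the *unweighted* mean of the two
      group change-score means (Type III), with the pooled change-score MSE.

    Completely independent of the package's regression/SS machinery.
    """
    y1 = np.asarray(y_baseline, float)
    y2 = np.asarray(y_day2, float)
    g = np.asarray(groups)
    levels = sorted(set(g.tolist()))
    assert len(levels) == 2
    m = (y1 + y2) / 2.0
    d = y2 - y1
    n1, n2 = (g == levels[0]).sum(), (g == levels[1]).sum()
    nt = n1 + n2

    def pooled_t(x, y):
        sp2 = ((len(x) - 1) * x.var(ddof=1) + (len(y) - 1) * y.var(ddof=1)) / (
            len(x) + len(y) - 2
        )
        return (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / len(x) + 1 / len(y)))

    f_group = pooled_t(m[g == levels[0]], m[g == levels[1]]) ** 2
    f_int = pooled_t(d[g == levels[0]], d[g == levels[1]]) ** 2
    d1, d2 = d[g == levels[0]], d[g == levels[1]]
    mse_d = ((n1 - 1) * d1.var(ddof=1) + (n2 - 1) * d2.var(ddof=1)) / (nt - 2)
    tau = (d1.mean() + d2.mean()) / 2.0
    f_time = tau**2 / (mse_d * (1 / n1 + 1 / n2) / 4.0)
    return {"group": f_group, "time": f_time, "interaction": f_int}


def random_events(rng, n=10, width=7.0, height=5.0):
    """Random non-degenerate stimulation events inside the default grid."""
    pts = rng.uniform([0.3, 0.3], [width - 0.3, height - 0.3], size=(n, 2))
    amps = rng.uniform(0.05, 3.0, size=n)
    return [
        StimulationEvent(x=float(p[0]), y=float(p[1]), amplitude=float(a), trial=i)
        for i, (p, a) in enumerate(zip(pts, amps))
    ]
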