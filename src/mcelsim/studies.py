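"""Reproduction workflows: the headline quantities of the model, computed
end-to-end from the package's own geometry, flow, transport and metrics
stages.

Each function runs a self-contained numerical study at a configurable
resolution and seed and returns plain numbers.  Problem sizes default to
desk scale: coarse-but-converged meshes and reduced parameter grids chosen
so every study finishes in seconds to a few minutes on one CPU (the grids
are stated in the docstrings; the methods note discusses what the reduced
grids do and do not resolve).
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .geometry import GeometryKind, GeometrySpec, build_geometry
from .meshing import Mesh, generate_construct_mesh, generate_mesh
from .flow import solve_flow
from .metrics import (find_da_onset_fem, live_fraction, necrotic_metrics,
                      threshold_search)
from .radial1d import asymptotic_maximal, find_da_onset_1d, rn_maximal
from .transport import TransportMode, TransportProblem, solve_transport


def _spec(kind: str) -> GeometrySpec:
    return build_geometry(GeometrySpec(GeometryKind(kind)))


def _maximal(Da: float, mesh: Mesh):
    return solve_transport(
        TransportProblem(TransportMode.maximal_supply, Da=Da), mesh)


def onset_1d(shape: str = "cylinder") -> float:
    """Analytical onset of rate-induced necrosis (bisection to 1e-6)."""
    return find_da_onset_1d(shape)


def onset_fem(kind: str = "confined", resolution: str | float = "default",
              seed: int = 0, tol: float = 0.01) -> float:
    """FEM necrosis-onset Damköhler number for a chamber geometry."""
    return find_da_onset_fem(_spec(kind), resolution, tol=tol, seed=seed)


def asymptotic_accuracy(da_grid: np.ndarray | None = None) -> float:
    """Maximum relative live-fraction error (percent) of the high-Da closed
    form against the exact transcendental root, over a log grid of Da."""
    if da_grid is None:
        da_grid = np.geomspace(10.0, 100.0, 25)
    errs = []
    for da in da_grid:
        exact = rn_maximal(float(da)).phi_live
        approx = asymptotic_maximal(float(da))[1]
        errs.append(abs(approx - exact) / exact)
    return 100.0 * float(np.max(errs))


def confinement_penalty(da_values=(10.0, 20.0, 50.0),
                        resolution: str | float = "fine",
                        seed: int = 0) -> dict[str, float]:
    """Confined vs unconfined maximal-supply comparison at high Da.

    Returns the mean percentage reduction of the live fraction and the mean
    percentage increase of the effective necrotic radius
    (``sqrt(necrotic area / pi)``, symmetry-unfolded for the half-domain
    unconfined construct).
    """
    mesh_u = generate_construct_mesh(_spec("unconfined"), resolution,
                                     seed=seed)
    mesh_c = generate_construct_mesh(_spec("confined"), resolution,
                                     seed=seed)
    phi_red, rad_inc = [], []
    for da in da_values:
        m_u = necrotic_metrics(_maximal(da, mesh_u))
        m_c = necrotic_metrics(_maximal(da, mesh_c))
        phi_red.append(100.0 * (1.0 - m_c.phi_live / m_u.phi_live))
        r_u = math.sqrt(2.0 * m_u.necrotic_area / math.pi)  # unfold symmetry
        r_c = math.sqrt(m_c.necrotic_area / math.pi)
        rad_inc.append(100.0 * (r_c / r_u - 1.0))
    return {"phi_reduction_pct": float(np.mean(phi_red)),
            "radius_increase_pct": float(np.mean(rad_inc)),
            "per_da_phi": phi_red, "per_da_radius": rad_inc}


def static_sweep(kind: str, da_values, rd_values,
                 resolution: str | float = "default",
                 seed: int = 0) -> pd.DataFrame:
    """Static (no-flow) solves over a Da x Rd grid; tidy metrics table."""
    mesh = generate_mesh(_spec(kind), resolution, seed=seed)
    rows = []
    for da in da_values:
        for rd in rd_values:
            pb = TransportProblem(TransportMode.static, Da=da, Rd=rd)
            fld = solve_transport(pb, mesh)
            met = necrotic_metrics(fld)
            rows.append(dict(Da=da, Rd=rd, Sd=pb.Sd, Sc=0.0,
                             min_c=fld.min_c2(), phi_live=met.phi_live,
                             converged=fld.converged))
    return pd.DataFrame(rows)


def static_prevention_constant(kind: str = "unconfined",
                               resolution: str | float = "default",
                               seed: int = 0,
                               da_onset: float = 4.0) -> float:
    """Sufficiency constant M of ``Sd (1 - Da/Da_onset) > M`` that
    guarantees full supply in static culture.

    Reduced grid: Da in {1, 2, 3}, Rd log-spaced in [0.1, 100] at three
    points per decade — the crossing of min c through the necrosis
    threshold is log-interpolated, and a coarser grid straddles it by a
    decade, which inflates the interpolated constant (checked against a
    dense scan of the crossing).
    """
    df = static_sweep(kind, [1.0, 2.0, 3.0],
                      list(np.geomspace(0.1, 100.0, 10)), resolution, seed)
    res = threshold_search(df, "static_margin", da_onset=da_onset)
    return float(res.value)


def microfluidic_sweep(kind: str, da_values, sc_values, Rd: float,
                       resolution: str | float = "default",
                       seed: int = 0, Re: float = 0.1,
                       k_star: float = 1e-8) -> pd.DataFrame:
    """Flow + transport solves over Da x Sc (one flow solve reused: the
    steady flow is independent of Pe1)."""
    mesh = generate_mesh(_spec(kind), resolution, seed=seed)
    flow = solve_flow(mesh, Re=Re, k_star=k_star)
    rows = []
    for da in da_values:
        for sc in sc_values:
            pe1 = sc * da / (2.0 * Rd)
            pb = TransportProblem(TransportMode.microfluidic, Da=da, Rd=Rd,
                                  Pe1=pe1, flow=flow)
            fld = solve_transport(pb, mesh)
            met = necrotic_metrics(fld)
            rows.append(dict(Da=da, Rd=Rd, Sd=pb.Sd, Sc=sc, Pe1=pe1,
                             min_c=fld.min_c2(), phi_live=met.phi_live,
                             asymmetry=met.asymmetry,
                             converged=fld.converged))
    return pd.DataFrame(rows)


def microfluidic_prevention_constant(resolution: str | float = "default",
                                     seed: int = 0) -> float:
    """Simulated prevention factor X of ``Sc (1 - Da/4) > X`` in the
    unconfined chamber (Da in {2, 3}, Sc log-spaced, Rd = 1)."""
    df = microfluidic_sweep("unconfined", [2.0, 3.0],
                            list(np.geomspace(1.0, 128.0, 8)), Rd=1.0,
                            resolution=resolution, seed=seed)
    res = threshold_search(df, "convective_margin")
    return float(res.value)


def approach_product(kind: str = "unconfined",
                     resolution: str | float = "default", seed: int = 0,
                     da_values=(5.0, 10.0), Rd: float = 0.5,
                     sc_values=None) -> float:
    """Composite supply product ``Rd*Sd*Sc`` at which the microfluidic live
    fraction reaches 90% of its maximal-supply value (rate-induced cases)."""
    if sc_values is None:
        sc_values = list(np.geomspace(2.0, 2000.0, 10))
    spec = _spec(kind)
    mesh_c = generate_construct_mesh(spec, resolution, seed=seed)
    df = microfluidic_sweep(kind, list(da_values), sc_values, Rd=Rd,
                            resolution=resolution, seed=seed)
    ratios = []
    for da in da_values:
        phi_inf = live_fraction(_maximal(da, mesh_c))
        sub = df[df["Da"] == da].copy()
        sub["phi_ratio"] = sub["phi_live"] / phi_inf
        ratios.append(sub)
    res = threshold_search(pd.concat(ratios), "supply_product")
    return float(res.value)


def asymmetry_sweep(kind: str = "unconfined",
                    resolution: str | float = "default", seed: int = 0,
                    Da: float = 5.0, Rd: float = 0.5,
                    pe1_values=None) -> pd.DataFrame:
    """Necrotic-barycentre shift along a Pe1 log-sweep at fixed Da, Rd."""
    if pe1_values is None:
        pe1_values = list(np.geomspace(0.5, 2000.0, 14))
    mesh = generate_mesh(_spec(kind), resolution, seed=seed)
    flow = solve_flow(mesh, Re=0.1, k_star=1e-8)
    rows = []
    for pe1 in pe1_values:
        pb = TransportProblem(TransportMode.microfluidic, Da=Da, Rd=Rd,
                              Pe1=pe1, flow=flow)
        fld = solve_transport(pb, mesh)
        met = necrotic_metrics(fld)
        rows.append(dict(Da=Da, Rd=Rd, Sd=pb.Sd, Sc=pb.Sc, Pe1=pe1,
                         asymmetry=met.asymmetry, phi_live=met.phi_live))
    return pd.DataFrame(rows)


def asymmetry_peak_location(resolution: str | float = "default",
                            seed: int = 0) -> float:
    """Peak of the downstream barycentre shift, as ``sqrt(Da)*Sc``."""
    df = asymmetry_sweep(resolution=resolution, seed=seed)
    res = threshold_search(df, "asymmetry_peak")
    return float(res.value)


def static_confinement_excess(resolution: str | float = "default",
                              seed: int = 0,
                              da_values=(5.0, 10.0),
                              ratio_targets=(0.5, 0.7)) -> float:
    """Percentage excess of diffusive supply Sd the confined chamber needs
    to reach the same relative live fraction as the unconfined one.

    Static solves over an Sd (via Rd) log-grid at Da in {5, 10}; the Sd
    reaching each target ratio ``phi/phi_inf`` is log-interpolated per
    geometry and the mean percentage excess reported.
    """
    from .metrics import _log_crossing
    rd_values = list(np.geomspace(0.3, 30.0, 7))
    excesses = []
    mesh_ref = {k: generate_construct_mesh(_spec(k), resolution, seed=seed)
                for k in ("unconfined", "confined")}
    tables = {k: static_sweep(k, list(da_values), rd_values, resolution,
                              seed)
              for k in ("unconfined", "confined")}
    for da in da_values:
        for target in ratio_targets:
            sd_at = {}
            for kind in ("unconfined", "confined"):
                phi_inf = live_fraction(_maximal(da, mesh_ref[kind]))
                sub = tables[kind][tables[kind]["Da"] == da]
                ratio = (sub["phi_live"] / phi_inf).to_numpy()
                sd_at[kind] = _log_crossing(sub["Sd"].to_numpy(), ratio,
                                            target, increasing=True)
            if sd_at["unconfined"] and sd_at["confined"]:
                excesses.append(100.0 * (sd_at["confined"]
                                         / sd_at["unconfined"] - 1.0))
    return float(np.mean(excesses))
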