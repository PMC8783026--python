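"""Forward EIS model: defect coordinates -> complex admittance spectrum.

Physical picture
----------------
A tethered bilayer lipid membrane (tBLM) separates the bathing electrolyte
from a nanometer-thin aqueous submembrane reservoir sitting on the electrode.
An AC drive of amplitude ``U0`` is applied across the membrane.  Intact
membrane couples into the reservoir capacitively (capacitance per area
``C_m``); the reservoir couples to the electrode through the Helmholtz layer
(``C_H``); membrane defects (pores of electrochemical radius ``r_def``) short
the drive potential directly into the reservoir, from where the current
spreads laterally through the thin film of sheet conductance
``g_s = d_sub / rho_sub``.

Writing ``u`` for the phasor potential of the reservoir, charge conservation
in the thin film gives a complex modified-Helmholtz equation on the membrane
patch Omega:

    g_s * div(grad u) - i w (C_H + C_m) u = -i w C_m U0        in Omega
    u = U0                                                     on defect rims
    du/dn = 0                                                  on the outer boundary

and the area-normalised admittance collected at the electrode is

    Y(w) = (1 / (A U0)) * integral_A  i w C_H u  dA,

with ``u = U0`` over the defect disks themselves.  With no defects this
reduces to two capacitors in series, ``Y = i w C_m C_H / (C_m + C_H)``, a pure
90-degree phase.  Defects open a resistive path whose lateral spreading
produces the characteristic interior minimum of the Bode admittance-phase
curve; the minimum's coordinates ``(f_min, argY_min)`` are the spectral
features used throughout the package.

Numerics
--------
The equation is discretised with linear (P1) triangular finite elements on a
graded point cloud: geometric rings of nodes around every defect rim (element
size ~ r_def/4 at the rim) blending into a hexagonal background lattice
(element size ~ field/100 by default), triangulated with Delaunay.  One
complex sparse solve is performed per frequency.  A semi-analytic radial
solution (modified Bessel functions ``I_0, K_0`` of complex argument) for a
single centered defect in a disk domain serves as an independent oracle.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu
import scipy.special as _sp
from scipy.spatial import Delaunay, cKDTree

from .defect_sets import DefectSet
from .exceptions import (
    GeometryError,
    NoInteriorMinimumError,
    NumericalError,
    ParameterError,
)

NM_TO_CM = 1.0e-7
UF_TO_F = 1.0e-6


# ---------------------------------------------------------------------------
# parameters and spectra containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MembraneParams:
    """Electrochemical constants of the tBLM model.

    Parameters
    ----------
    r_def
        Electrochemical defect radius in nm (the conductive pore radius; not
        the 25 nm detection-box radius).
    rho_sub
        Specific resistance of the submembrane reservoir in Ohm*cm.
    c_m, c_h
        Membrane and Helmholtz capacitances per area in uF/cm^2.
    d_sub
        Submembrane reservoir thickness in nm.
    u0
        Drive amplitude in V.  The system is linear, so the admittance is
        independent of ``u0``.
    r_solution
        Optional series (bulk electrolyte) resistance in Ohm*cm^2; 0 disables
        the series element and the high-frequency phase then tends to 90 deg.
    """

    r_def: float = 2.7
    rho_sub: float = 10**4.5
    c_m: float = 0.8
    c_h: float = 9.0
    d_sub: float = 1.5
    u0: float = 1.0
    r_solution: float = 0.0

    def __post_init__(self) -> None:
        for name in ("r_def", "rho_sub", "c_m", "c_h", "d_sub", "u0"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be positive, got {getattr(self, name)}")
        if self.r_solution < 0:
            raise ParameterError("r_solution must be >= 0")

    @property
    def g_s(self) -> float:
        """Sheet conductance of the submembrane film, in S (square sheet)."""
        return self.d_sub * NM_TO_CM / self.rho_sub

    @property
    def c_total_f(self) -> float:
        """C_m + C_H in F/cm^2."""
        return (self.c_m + self.c_h) * UF_TO_F

    @property
    def c_series(self) -> float:
        """Series capacitance C_m C_H / (C_m + C_H) of the intact membrane, uF/cm^2."""
        return self.c_m * self.c_h / (self.c_m + self.c_h)


@dataclasses.dataclass(frozen=True)
class FrequencyGrid:
    """Strictly increasing, positive measurement frequencies in Hz."""

    frequencies: tuple[float, ...]

    def __post_init__(self) -> None:
        f = np.asarray(self.frequencies)
        if len(f) < 3:
            raise ParameterError("frequency grid needs at least 3 points")
        if not (np.all(f > 0) and np.all(np.diff(f) > 0)):
            raise ParameterError("frequencies must be positive and strictly increasing")

    @classmethod
    def logspaced(
        cls, f_min: float = 0.1, f_max: float = 1.0e5, points_per_decade: int = 10
    ) -> "FrequencyGrid":
        decades = np.log10(f_max / f_min)
        n = int(round(decades * points_per_decade)) + 1
        return cls(tuple(np.logspace(np.log10(f_min), np.log10(f_max), n)))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.frequencies)

    def __len__(self) -> int:
        return len(self.frequencies)


@dataclasses.dataclass(frozen=True)
class EISSpectrum:
    """Complex admittance per area (S/cm^2) versus frequency (Hz)."""

    frequencies: np.ndarray
    admittance: np.ndarray

    @property
    def phase_deg(self) -> np.ndarray:
        """arg Y in degrees (0..90 for a passive membrane with no series element)."""
        return np.degrees(np.angle(self.admittance))

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.admittance)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "y_real_s_cm2": self.admittance.real,
                "y_imag_s_cm2": self.admittance.imag,
                "phase_deg": self.phase_deg,
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def read_csv(cls, path: str | Path) -> "EISSpectrum":
        df = pd.read_csv(path)
        return cls(
            frequencies=df["frequency_hz"].to_numpy(float),
            admittance=df["y_real_s_cm2"].to_numpy(float)
            + 1j * df["y_imag_s_cm2"].to_numpy(float),
        )


@dataclasses.dataclass(frozen=True)
class SpectralFeatures:
    """Coordinates of the interior minimum of the Bode admittance-phase curve."""

    f_min: float
    arg_y_min: float


@dataclasses.dataclass(frozen=True)
class SpectrumDelta:
    """Signed feature differences, true minus predicted."""

    delta_f_log: float
    delta_arg_y: float


# ---------------------------------------------------------------------------
# mesh generation
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class MeshParams:
    """Discretisation knobs for the FEM solver.

    ``h_far`` is the far-field target element size in nm (defaults to 1/100 of
    the larger field dimension).  Rings of nodes grow geometrically from each
    defect rim by ``growth`` per ring; every ring carries at least
    ``min_ring_points`` nodes, giving rim elements of roughly ``r_def / 4``.
    ``patch_factor`` limits each defect's ring patch to that fraction of its
    nearest-neighbour distance so patches of clustered defects do not collide.
    """

    h_far: float | None = None
    growth: float = 1.2
    min_ring_points: int = 24
    patch_factor: float = 0.45

    def resolved_h_far(self, field_width: float, field_height: float) -> float:
        return self.h_far if self.h_far is not None else max(field_width, field_height) / 100.0


def _hex_lattice(width: float, height: float, spacing: float) -> np.ndarray:
    """Hexagonal lattice covering [0,w] x [0,h], boundary lines included."""
    dy = spacing * np.sqrt(3.0) / 2.0
    n_rows = max(2, int(np.ceil(height / dy)))
    rows = []
    for j in range(n_rows + 1):
        y = min(j * height / n_rows, height)
        xs = np.arange(0.0, width + 0.5 * spacing, spacing)
        if j % 2:
            xs = np.clip(xs + 0.5 * spacing, 0.0, width)
            xs = np.concatenate([[0.0], xs])
        if xs[-1] < width:
            xs = np.concatenate([xs, [width]])
        rows.append(np.column_stack([xs, np.full(len(xs), y)]))
    return np.unique(np.vstack(rows), axis=0)


def _defect_rings(
    center: np.ndarray,
    r_def: float,
    r_patch: float,
    h_far: float,
    growth: float,
    min_pts: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Geometric rings of nodes from the rim outward; returns (points, spacings)."""
    pts, spc = [], []
    r = r_def
    k = 0
    while True:
        spacing = min(r * (growth - 1.0), h_far)
        m = max(min_pts, int(np.ceil(2.0 * np.pi * r / max(spacing, 1e-9))))
        theta = 2.0 * np.pi * np.arange(m) / m + (0.5 * 2.0 * np.pi / m if k % 2 else 0.0)
        ring = center + r * np.column_stack([np.cos(theta), np.sin(theta)])
        pts.append(ring)
        spc.append(np.full(m, 2.0 * np.pi * r / m))
        nxt = r * growth
        if r * (growth - 1.0) >= h_far or nxt > r_patch:
            break
        r = nxt
        k += 1
    return np.vstack(pts), np.concatenate(spc)


def _thin_points(
    rim_pts: np.ndarray,
    candidates: np.ndarray,
    spacings: np.ndarray,
    factor: float = 0.55,
) -> np.ndarray:
    """Keep rim points; accept candidates coarse-to-fine unless they crowd kept points."""
    kept = rim_pts
    order = np.argsort(spacings)
    candidates, spacings = candidates[order], spacings[order]
    # batch by quantised spacing so the KD-tree is rebuilt only a few times
    bins = np.unique(np.round(np.log(spacings) * 8.0))
    for b in bins:
        sel = np.round(np.log(spacings) * 8.0) == b
        batch, batch_s = candidates[sel], spacings[sel]
        tree = cKDTree(kept)
        d, _ = tree.query(batch)
        ok = d > factor * batch_s
        batch, batch_s = batch[ok], batch_s[ok]
        if len(batch) > 1:
            # resolve within-batch collisions between different defects' rings
            pairs = cKDTree(batch).query_pairs(factor * batch_s.min(), output_type="ndarray")
            drop = np.zeros(len(batch), bool)
            for i, j in pairs:
                if not drop[i] and not drop[j]:
                    drop[j] = True
            batch = batch[~drop]
        if len(batch):
            kept = np.vstack([kept, batch])
    return kept


class FEMSystem:
    """Assembled FEM operator for one defect set, defect radius and mesh.

    Building the system (mesh + stiffness/mass assembly) is independent of
    ``rho_sub`` and of frequency, so one instance can be reused across the
    whole resistance axis of a fit grid.
    """

    def __init__(
        self,
        defect_set: DefectSet,
        r_def: float,
        mesh: MeshParams = MeshParams(),
        domain: str = "rectangle",
        domain_radius: float | None = None,
    ) -> None:
        if r_def <= 0:
            raise ParameterError(f"r_def must be positive, got {r_def}")
        self.defect_set = defect_set
        self.r_def = float(r_def)
        self.mesh_params = mesh
        centers = defect_set.coordinates
        w, h = defect_set.field_width, defect_set.field_height
        h_far = mesh.resolved_h_far(w, h)

        if len(centers) >= 2:
            d_nn, _ = cKDTree(centers).query(centers, k=2)
            d_nn = d_nn[:, 1]
            if np.min(d_nn) <= 2.0 * r_def:
                raise GeometryError(
                    f"defect disks overlap: min center distance {np.min(d_nn):.3g} nm "
                    f"<= 2 r_def = {2 * r_def:.3g} nm"
                )
        else:
            d_nn = np.full(len(centers), np.inf)

        rim_list, cand_list, spc_list = [], [], []
        for c, dn in zip(centers, d_nn):
            r_patch = max(1.3 * self.r_def, min(mesh.patch_factor * dn, np.inf))
            ring, spc = _defect_rings(
                c, self.r_def, r_patch, h_far, mesh.growth, mesh.min_ring_points
            )
            on_rim = np.hypot(*(ring - c).T) <= self.r_def * (1.0 + 1e-9)
            rim_list.append(ring[on_rim])
            cand_list.append(ring[~on_rim])
            spc_list.append(spc[~on_rim])

        if domain == "rectangle":
            bg = _hex_lattice(w, h, h_far)
        elif domain == "disk":
            if domain_radius is None:
                raise ParameterError("disk domain requires domain_radius")
            R = float(domain_radius)
            bg = _hex_lattice(2 * R, 2 * R, h_far) + (centers.mean(axis=0) - R)
            rel = bg - centers.mean(axis=0)
            bg = bg[np.hypot(rel[:, 0], rel[:, 1]) < R - 0.45 * h_far]
            m_b = max(16, int(np.ceil(2.0 * np.pi * R / h_far)))
            th = 2.0 * np.pi * np.arange(m_b) / m_b
            boundary = centers.mean(axis=0) + R * np.column_stack([np.cos(th), np.sin(th)])
            bg = np.vstack([bg, boundary])
        else:
            raise ParameterError(f"unknown domain {domain!r}")

        cand = np.vstack(cand_list + [bg]) if cand_list else bg
        spc = np.concatenate(spc_list + [np.full(len(bg), h_far)]) if spc_list else np.full(len(bg), h_far)
        if domain == "rectangle":
            inside = (
                (cand[:, 0] >= 0.0) & (cand[:, 0] <= w)
                & (cand[:, 1] >= 0.0) & (cand[:, 1] <= h)
            )
            cand, spc = cand[inside], spc[inside]
        rim = np.vstack(rim_list) if rim_list else np.empty((0, 2))
        if domain == "rectangle" and len(rim):
            ok = (
                (rim[:, 0] >= 0.0) & (rim[:, 0] <= w)
                & (rim[:, 1] >= 0.0) & (rim[:, 1] <= h)
            )
            rim = rim[ok]
        if len(centers) and len(cand):
            d_to_center, _ = cKDTree(centers).query(cand)
            keep = d_to_center > 1.3 * self.r_def
            cand, spc = cand[keep], spc[keep]

        if len(rim):
            points = _thin_points(rim, cand, spc)
        else:
            points = cand
        tri = Delaunay(points)
        simplices = tri.simplices
        p = points[simplices]
        det = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
            p[:, 2, 0] - p[:, 0, 0]
        ) * (p[:, 1, 1] - p[:, 0, 1])
        good = np.abs(det) > 1e-12 * max(w, h) ** 2 / len(points)
        simplices, det = simplices[good], det[good]
        if len(centers):
            centroid = points[simplices].mean(axis=1)
            d_c, _ = cKDTree(centers).query(centroid)
            hole = d_c < self.r_def * 0.999
            self._holes_area_cm2 = float(
                np.abs(det[hole]).sum() / 2.0 * NM_TO_CM**2
            )
            simplices, det = simplices[~hole], det[~hole]
            d_pt, _ = cKDTree(centers).query(points)
            self.dirichlet = d_pt <= self.r_def * (1.0 + 1e-9)
        else:
            self._holes_area_cm2 = 0.0
            self.dirichlet = np.zeros(len(points), bool)

        self.points = points
        self.simplices = simplices
        self._assemble(det)

    # -- assembly -----------------------------------------------------------
    def _assemble(self, det: np.ndarray) -> None:
        pts_cm = self.points * NM_TO_CM
        det_cm = det * NM_TO_CM**2
        tris = self.simplices
        p = pts_cm[tris]
        x, y = p[..., 0], p[..., 1]
        area = 0.5 * np.abs(det_cm)
        gx = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1) / det_cm[:, None]
        gy = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1) / det_cm[:, None]
        k_local = (gx[:, :, None] * gx[:, None, :] + gy[:, :, None] * gy[:, None, :]) * area[:, None, None]
        rows = np.repeat(tris, 3, axis=1).ravel()
        cols = np.tile(tris, (1, 3)).ravel()
        n = len(self.points)
        self.stiffness = sparse.coo_matrix(
            (k_local.ravel(), (rows, cols)), shape=(n, n)
        ).tocsr()
        lumped = np.zeros(n)
        np.add.at(lumped, tris.ravel(), np.repeat(area / 3.0, 3))
        self.mass_lumped = lumped
        self.area_cm2 = float(lumped.sum())
        free = ~self.dirichlet
        self._free = free
        self._k_ff = self.stiffness[free][:, free].tocsc()
        self._k_fd = self.stiffness[free][:, self.dirichlet].tocsc()
        self._m_f = lumped[free]

    @property
    def n_nodes(self) -> int:
        return len(self.points)

    # -- solve --------------------------------------------------------------
    def solve(self, mp: MembraneParams, fg: FrequencyGrid) -> EISSpectrum:
        """Solve one complex system per frequency and integrate the admittance."""
        if not np.isclose(mp.r_def, self.r_def):
            raise ParameterError(
                f"MembraneParams.r_def={mp.r_def} differs from meshed radius {self.r_def}"
            )
        g_s = mp.g_s
        c_tot = mp.c_total_f
        c_m = mp.c_m * UF_TO_F
        c_h = mp.c_h * UF_TO_F
        u0 = mp.u0
        n_dir = int(self.dirichlet.sum())
        dirich_u = u0 * np.ones(n_dir)
        total_area = self.area_cm2 + self._holes_area_cm2
        mass_dirich = self.mass_lumped[self.dirichlet]
        y_out = np.empty(len(fg), complex)
        for i, f in enumerate(fg.array):
            w = 2.0 * np.pi * f
            if n_dir == 0:
                u_uniform = c_m * u0 / c_tot
                integral = u_uniform * self.area_cm2
            else:
                a_ff = (g_s * self._k_ff + sparse.diags(1j * w * c_tot * self._m_f)).tocsc()
                b = 1j * w * c_m * u0 * self._m_f - g_s * (self._k_fd @ dirich_u)
                try:
                    u_free = splu(a_ff).solve(b)
                except RuntimeError as exc:  # pragma: no cover - solver failure
                    raise NumericalError(f"sparse solve failed at f={f} Hz: {exc}")
                if not np.all(np.isfinite(u_free)):
                    raise NumericalError(f"non-finite FEM solution at f={f} Hz")
                integral = (self._m_f * u_free).sum() + (mass_dirich * u0).sum()
            integral += u0 * self._holes_area_cm2
            y_out[i] = 1j * w * c_h * integral / (total_area * u0)
        if mp.r_solution > 0.0:
            y_out = y_out / (1.0 + mp.r_solution * y_out)
        return EISSpectrum(fg.array.copy(), y_out)


def model_spectrum(
    defect_set: DefectSet,
    mp: MembraneParams,
    fg: FrequencyGrid,
    mesh: MeshParams = MeshParams(),
) -> EISSpectrum:
    """Predict the admittance spectrum of a defect set by the 2D FEM model.

    With no defects the exact series-capacitor solution is returned directly.
    """
    if len(defect_set) == 0:
        w = 2.0 * np.pi * fg.array
        c_s = mp.c_series * UF_TO_F
        y = 1j * w * c_s
        if mp.r_solution > 0.0:
            y = y / (1.0 + mp.r_solution * y)
        return EISSpectrum(fg.array.copy(), y)
    system = FEMSystem(defect_set, mp.r_def, mesh)
    return system.solve(mp, fg)


# ---------------------------------------------------------------------------
# radial semi-analytic oracle
# ---------------------------------------------------------------------------

def radial_spectrum(
    mp: MembraneParams,
    domain_radius: float,
    fg: FrequencyGrid,
) -> EISSpectrum:
    """Semi-analytic spectrum of a single centered defect in a disk domain.

    Solves ``g_s (u'' + u'/r) = i w (C_H + C_m) u - i w C_m U0`` on
    ``r_def <= r <= R`` with ``u(r_def) = U0`` and ``u'(R) = 0`` using modified
    Bessel functions of complex argument, and integrates ``i w C_H u``
    analytically over the annulus (the defect disk contributes ``U0`` times
    its area).  At extreme ``|kR|`` (where ``I_v`` overflows) the outer
    boundary is irrelevant and the pure-``K_0`` decay solution is used.
    """
    r_d = mp.r_def * NM_TO_CM
    big_r = float(domain_radius) * NM_TO_CM
    if not big_r > r_d:
        raise ParameterError("domain radius must exceed r_def")
    g_s = mp.g_s
    c_tot = mp.c_total_f
    c_m = mp.c_m * UF_TO_F
    c_h = mp.c_h * UF_TO_F
    u0 = mp.u0
    y_out = np.empty(len(fg), complex)
    for i, f in enumerate(fg.array):
        w = 2.0 * np.pi * f
        k = np.sqrt(1j * w * c_tot / g_s)
        u_part = c_m * u0 / c_tot
        v0 = u0 - u_part
        with np.errstate(over="ignore", invalid="ignore"):
            i1_r = _sp.iv(1, k * big_r)
            k1_r = _sp.kv(1, k * big_r)
            denom = _sp.kv(0, k * r_d) * i1_r + _sp.iv(0, k * r_d) * k1_r
        if np.all(np.isfinite([denom.real, denom.imag, i1_r.real, i1_r.imag])) and denom != 0:
            num = _sp.kv(1, k * r_d) * i1_r - _sp.iv(1, k * r_d) * k1_r
            integral_v = v0 * (r_d / k) * num / denom
        else:
            # |kR| >> 1: outer boundary unreachable, pure K_0 decay
            integral_v = v0 * (r_d / k) * _sp.kv(1, k * r_d) / _sp.kv(0, k * r_d)
        integral = u_part * (big_r**2 - r_d**2) / 2.0 + integral_v
        y_out[i] = (
            1j * w * c_h * (2.0 * np.pi * integral + u0 * np.pi * r_d**2)
            / (np.pi * big_r**2 * u0)
        )
        if not np.isfinite(y_out[i]):
            raise NumericalError(f"radial solution non-finite at f={f} Hz")
    if mp.r_solution > 0.0:
        y_out = y_out / (1.0 + mp.r_solution * y_out)
    return EISSpectrum(fg.array.copy(), y_out)


# ---------------------------------------------------------------------------
# spectral features
# ---------------------------------------------------------------------------

def spectral_features(spectrum: EISSpectrum) -> SpectralFeatures:
    """Locate the interior minimum of the admittance-phase curve.

    The discrete argmin is refined by a three-point parabola in
    ``(log10 f, phase)``; the refined vertex position and interpolated phase
    are returned.  A minimum at either grid endpoint (e.g. the flat
    90-degree curve of a defect-free membrane) raises
    :class:`NoInteriorMinimumError`.
    """
    phase = spectrum.phase_deg
    idx = int(np.argmin(phase))
    if idx == 0 or idx == len(phase) - 1:
        raise NoInteriorMinimumError(
            "admittance-phase minimum lies at the grid boundary"
        )
    logf = np.log10(spectrum.frequencies[idx - 1 : idx + 2])
    y = phase[idx - 1 : idx + 2]
    # parabola through three points; vertex by finite differences
    d1 = (y[2] - y[0]) / (logf[2] - logf[0])
    d2 = (
        (y[2] - y[1]) / (logf[2] - logf[1]) - (y[1] - y[0]) / (logf[1] - logf[0])
    ) / (0.5 * (logf[2] - logf[0]))
    if d2 <= 0:
        return SpectralFeatures(float(spectrum.frequencies[idx]), float(y[1]))
    # d1 is the exact quadratic slope at the midpoint of the bracket, d2 = 2a
    x_v = 0.5 * (logf[0] + logf[2]) - d1 / d2  # vertex in log10 f
    # clamp into the bracketing interval for safety
    x_v = float(np.clip(x_v, logf[0], logf[2]))
    # evaluate the interpolating parabola at the vertex (Lagrange form)
    l0 = (x_v - logf[1]) * (x_v - logf[2]) / ((logf[0] - logf[1]) * (logf[0] - logf[2]))
    l1 = (x_v - logf[0]) * (x_v - logf[2]) / ((logf[1] - logf[0]) * (logf[1] - logf[2]))
    l2 = (x_v - logf[0]) * (x_v - logf[1]) / ((logf[2] - logf[0]) * (logf[2] - logf[1]))
    return SpectralFeatures(float(10.0**x_v), float(y[0] * l0 + y[1] * l1 + y[2] * l2))


def compare_spectra(true_spectrum: EISSpectrum, pred_spectrum: EISSpectrum) -> SpectrumDelta:
    """Feature differences Delta f_log and Delta argY (true minus predicted)."""
    ft = spectral_features(true_spectrum)
    fp = spectral_features(pred_spectrum)
    return SpectrumDelta(
        delta_f_log=float(np.log10(ft.f_min) - np.log10(fp.f_min)),
        delta_arg_y=float(ft.arg_y_min - fp.arg_y_min),
    )
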