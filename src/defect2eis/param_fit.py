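"""Grid-search recovery of (r_def, rho_sub) from a reference spectrum.

For every combination of defect radius and submembrane specific resistance on
a fixed grid (7 radii x 11 resistance exponents = 77 combinations by
default), the forward model predicts the spectrum of the given defect set and
its phase-minimum coordinates are compared with those of the reference
spectrum.  The discrepancy is an L1 distance in the (log10 f, arg Y) plane,

    l1 = |delta log10 f_min| + |delta argY_min| / phase_scale,

with ``phase_scale = 90`` degrees by default so both terms are O(1).  The
best grid point minimises l1; ties break toward smaller resistance exponent,
then smaller radius.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .defect_sets import DefectSet
from .eis_model import (
    EISSpectrum,
    FEMSystem,
    FrequencyGrid,
    MembraneParams,
    MeshParams,
    spectral_features,
)
from .exceptions import (
    GeometryError,
    NoInteriorMinimumError,
    NumericalError,
    ParameterError,
)

DEFAULT_R_VALUES_NM = (1.0, 3.0, 5.0, 7.0, 9.0, 11.0, 13.0)
DEFAULT_RHO_EXPONENTS = tuple(np.round(np.arange(4.0, 5.0 + 1e-9, 0.1), 10))
DEFAULT_PHASE_SCALE_DEG = 90.0


@dataclasses.dataclass(frozen=True)
class FitGrid:
    """Search grid: defect radii (nm) and base-10 exponents of rho_sub (Ohm*cm)."""

    r_values: tuple[float, ...] = DEFAULT_R_VALUES_NM
    rho_exponents: tuple[float, ...] = DEFAULT_RHO_EXPONENTS

    def __post_init__(self) -> None:
        for name, vals in (("r_values", self.r_values), ("rho_exponents", self.rho_exponents)):
            arr = np.asarray(vals)
            if arr.size == 0:
                raise ParameterError(f"{name} must be non-empty")
            if arr.size > 1 and not np.all(np.diff(arr) > 0):
                raise ParameterError(f"{name} must be strictly ascending")


def parameter_grid(grid: FitGrid = FitGrid()) -> list[tuple[float, float]]:
    """All (r_def, rho_sub) combinations, radius-major order."""
    return [
        (r, 10.0**e) for r in grid.r_values for e in grid.rho_exponents
    ]


@dataclasses.dataclass(frozen=True)
class FitResult:
    """Outcome of one grid search."""

    best_r_def: float
    best_rho_sub: float
    l1: float
    table: pd.DataFrame  # columns: r_def_nm, rho_exp, f_min_hz, arg_y_min_deg, l1

    @property
    def best_rho_exponent(self) -> float:
        return float(np.log10(self.best_rho_sub))


def fit(
    defect_set: DefectSet,
    reference: EISSpectrum,
    grid: FitGrid = FitGrid(),
    mp_base: MembraneParams = MembraneParams(),
    fg: FrequencyGrid | None = None,
    mesh: MeshParams = MeshParams(),
    phase_scale: float = DEFAULT_PHASE_SCALE_DEG,
) -> FitResult:
    """Match the modeled spectrum of ``defect_set`` to ``reference``.

    The FEM system is assembled once per radius and reused across the whole
    resistance axis (the mesh does not depend on rho_sub).  Grid points whose
    spectrum has no interior phase minimum -- or whose geometry is infeasible
    (disks overlapping at large radii) -- are scored ``l1 = inf`` and flagged
    in the table.
    """
    if fg is None:
        fg = FrequencyGrid.logspaced()
    ref_feat = spectral_features(reference)  # raises if no interior minimum
    ref_logf = np.log10(ref_feat.f_min)
    rows = []
    for r in grid.r_values:
        system: FEMSystem | None = None
        geom_error = None
        if len(defect_set) > 0:
            try:
                system = FEMSystem(defect_set, r, mesh)
            except GeometryError as exc:
                geom_error = str(exc)
        for e in grid.rho_exponents:
            mp = dataclasses.replace(mp_base, r_def=float(r), rho_sub=10.0**e)
            f_min = arg_y = np.nan
            l1 = np.inf
            flag = ""
            if geom_error is not None:
                flag = f"geometry: {geom_error}"
            else:
                try:
                    if system is None:
                        from .eis_model import model_spectrum

                        spectrum = model_spectrum(defect_set, mp, fg, mesh)
                    else:
                        spectrum = system.solve(mp, fg)
                    feat = spectral_features(spectrum)
                    f_min, arg_y = feat.f_min, feat.arg_y_min
                    l1 = abs(ref_logf - np.log10(f_min)) + abs(
                        ref_feat.arg_y_min - arg_y
                    ) / phase_scale
                except NoInteriorMinimumError:
                    flag = "no interior minimum"
                except NumericalError as exc:
                    flag = f"numerical: {exc}"
            rows.append(
                {
                    "r_def_nm": float(r),
                    "rho_exp": float(e),
                    "f_min_hz": f_min,
                    "arg_y_min_deg": arg_y,
                    "l1": l1,
                    "flag": flag,
                }
            )
    table = pd.DataFrame(rows)
    if not np.isfinite(table["l1"]).any():
        raise NumericalError("no grid point produced a comparable spectrum")
    # ties break toward smaller rho exponent, then smaller radius
    ranked = table.sort_values(["l1", "rho_exp", "r_def_nm"], kind="stable")
    best = ranked.iloc[0]
    return FitResult(
        best_r_def=float(best["r_def_nm"]),
        best_rho_sub=10.0 ** float(best["rho_exp"]),
        l1=float(best["l1"]),
        table=table,
    )
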