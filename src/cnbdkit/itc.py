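"""One-site isothermal-titration-calorimetry model and fitting.

Forward model
-------------
For a macromolecule M titrated with ligand X in a perfusion cell of volume
V0, the cumulative heat after injection i under a single-site model with
stoichiometry n, association constant Ka and molar enthalpy dH is

    Q_i = (n M_i dH V0 / 2) [ 1 + X_i/(n M_i) + 1/(n Ka M_i)
          - sqrt( (1 + X_i/(n M_i) + 1/(n Ka M_i))^2 - 4 X_i/(n M_i) ) ]

where M_i, X_i are total cell concentrations after the displacement
dilution of i injections.  The measured heat of injection i includes the
volume-displacement correction

    q_i = Q_i - Q_{i-1} + (dV_i / V0) (Q_i + Q_{i-1}) / 2.

Dilution follows the discrete perfusion rule used by VP-ITC reduction
software: with cumulative injected volume dV_tot,

    M_i = M0 (1 - dV_tot/2V0) / (1 + dV_tot/2V0)
    X_i = X_syr (dV_tot/V0) / (1 + dV_tot/2V0).

The dimensionless c = n Ka M0 governs how well Ka is determined: the
isotherm saturates into a step for c >> 1000 and flattens for c << 1.

Units: concentrations mol/L, volumes L, dH cal/mol internally; injection
heats are reported in microcalories and normalized heats in kcal per mole
of injectant, matching instrument output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import lmfit
import numpy as np
import pandas as pd

R_CAL = 1.987  # gas constant, cal/(mol K)

DEFAULT_CELL_VOLUME = 1.43e-3   # L, VP-ITC sample cell
DEFAULT_TEMPERATURE = 303.15    # K (30 C)
DEFAULT_N_INJECTIONS = 28
DEFAULT_INJECTION_VOLUME = 5e-6  # L


@dataclass
class TitrationDesign:
    cell_concentration: float            # mol/L, macromolecule
    syringe_concentration: float         # mol/L, ligand
    injection_volumes: Sequence[float]   # L
    cell_volume: float = DEFAULT_CELL_VOLUME
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        self.injection_volumes = np.asarray(self.injection_volumes, dtype=float)
        if (self.cell_concentration <= 0 or self.syringe_concentration <= 0
                or self.cell_volume <= 0 or self.temperature <= 0):
            raise ValueError("design quantities must be positive")
        if len(self.injection_volumes) < 2 or np.any(self.injection_volumes <= 0):
            raise ValueError("need >= 2 positive injection volumes")


def vp_itc_design(
    cell_concentration: float = 15e-6,
    syringe_concentration: float = 250e-6,
    n_injections: int = DEFAULT_N_INJECTIONS,
    injection_volume: float = DEFAULT_INJECTION_VOLUME,
    cell_volume: float = DEFAULT_CELL_VOLUME,
    temperature: float = DEFAULT_TEMPERATURE,
) -> TitrationDesign:
    """Standard VP-ITC design: defaults are a 15 uM cell titrated with
    250 uM ligand in 28 x 5 uL injections at 30 C."""
    return TitrationDesign(
        cell_concentration=cell_concentration,
        syringe_concentration=syringe_concentration,
        injection_volumes=[injection_volume] * n_injections,
        cell_volume=cell_volume,
        temperature=temperature,
    )


@dataclass
class OneSiteParams:
    n: float          # sites per macromolecule
    Ka: float         # 1/(mol/L)
    dH: float         # cal/mol

    def __post_init__(self) -> None:
        if self.n <= 0 or self.Ka <= 0:
            raise ValueError("n and Ka must be positive")

    @property
    def Kd(self) -> float:
        return 1.0 / self.Ka


@dataclass
class TitrationCurve:
    molar_ratio: np.ndarray        # X_t / M_t per injection
    heats: np.ndarray              # ucal per injection
    normalized: np.ndarray         # kcal per mol of injectant

    def __post_init__(self) -> None:
        self.molar_ratio = np.asarray(self.molar_ratio, dtype=float)
        self.heats = np.asarray(self.heats, dtype=float)
        self.normalized = np.asarray(self.normalized, dtype=float)
        if not (len(self.molar_ratio) == len(self.heats) == len(self.normalized)):
            raise ValueError("curve arrays must be equal length")


@dataclass
class FitResult:
    params: OneSiteParams
    stderr: dict[str, Optional[float]]
    Kd: float
    dG: float                      # cal/mol
    dS: float                      # cal/(mol K)
    residual_norm: float
    converged: bool
    c_value: float
    fitted_heats: np.ndarray = field(default_factory=lambda: np.array([]))

    def summary(self) -> dict:
        return {
            "n": self.params.n,
            "Ka_per_M": self.params.Ka,
            "Kd_M": self.Kd,
            "dH_kcal_per_mol": self.params.dH / 1000.0,
            "dG_kcal_per_mol": self.dG / 1000.0,
            "dS_cal_per_mol_K": self.dS,
            "c_value": self.c_value,
            "converged": self.converged,
            "residual_norm_ucal": self.residual_norm,
            "stderr": self.stderr,
        }


def _total_concentrations(design: TitrationDesign) -> tuple[np.ndarray, np.ndarray]:
    dv_tot = np.cumsum(design.injection_volumes)
    v0 = design.cell_volume
    half = dv_tot / (2.0 * v0)
    M = design.cell_concentration * (1.0 - half) / (1.0 + half)
    X = design.syringe_concentration * (dv_tot / v0) / (1.0 + half)
    return M, X


def _cumulative_heat(n: float, Ka: float, dH: float,
                     M: np.ndarray, X: np.ndarray, v0: float) -> np.ndarray:
    r = X / (n * M)
    inv_c = 1.0 / (n * Ka * M)
    term = 1.0 + r + inv_c
    disc = term * term - 4.0 * r
    if np.any(disc < 0):
        raise FloatingPointError("negative discriminant in one-site isotherm")
    return (n * M * dH * v0 / 2.0) * (term - np.sqrt(disc))


def simulate_titration(params: OneSiteParams, design: TitrationDesign) -> TitrationCurve:
    """Noise-free one-site titration: per-injection heats (ucal) and
    normalized heats (kcal/mol of injectant)."""
    M, X = _total_concentrations(design)
    Q = _cumulative_heat(params.n, params.Ka, params.dH, M, X, design.cell_volume)
    dv = np.asarray(design.injection_volumes)
    Qprev = np.concatenate([[0.0], Q[:-1]])
    q = Q - Qprev + (dv / design.cell_volume) * (Q + Qprev) / 2.0  # cal
    injected_mol = design.syringe_concentration * dv
    return TitrationCurve(
        molar_ratio=X / M,
        heats=q * 1e6,
        normalized=(q / injected_mol) / 1000.0,
    )


def derive_thermo(Ka: float, dH: float, T: float) -> tuple[float, float, float]:
    """(Kd, dG, dS) from Ka and dH at temperature T.

    dG = -R T ln Ka (cal/mol), dS = (dH - dG)/T (cal/mol/K), R = 1.987.
    """
    if Ka <= 0 or T <= 0:
        raise ValueError("Ka and T must be positive")
    dG = -R_CAL * T * math.log(Ka)
    dS = (dH - dG) / T
    return 1.0 / Ka, dG, dS


def _auto_init(curve: TitrationCurve, design: TitrationDesign) -> OneSiteParams:
    """Deterministic automatic initializer.

    n starts at 1; dH from the first-injection normalized heat (nearly
    full binding early in a titration); Ka by a coarse deterministic scan
    of log10 Ka against the observed heats.
    """
    dh0 = float(curve.normalized[0]) * 1000.0
    if dh0 == 0.0:
        dh0 = -1000.0
    best = (np.inf, 1e6)
    M, X = _total_concentrations(design)
    dv = np.asarray(design.injection_volumes)
    for logka in np.arange(3.0, 13.5, 0.5):
        ka = 10.0 ** logka
        Q = _cumulative_heat(1.0, ka, dh0, M, X, design.cell_volume)
        Qprev = np.concatenate([[0.0], Q[:-1]])
        q = (Q - Qprev + (dv / design.cell_volume) * (Q + Qprev) / 2.0) * 1e6
        sse = float(np.sum((q - curve.heats) ** 2))
        if sse < best[0]:
            best = (sse, ka)
    return OneSiteParams(n=1.0, Ka=best[1], dH=dh0)


def fit_one_site(
    curve: TitrationCurve,
    design: TitrationDesign,
    init: Optional[OneSiteParams] = None,
) -> FitResult:
    """Least-squares fit of (n, Ka, dH) to per-injection heats.

    Damped least squares (Levenberg–Marquardt via lmfit) on the ucal
    heats, with Ka parameterized as log10 for conditioning.  Deterministic
    for a fixed initializer; non-convergence is flagged on the result, not
    raised.
    """
    heats = np.asarray(curve.heats, dtype=float)
    if len(heats) != len(design.injection_volumes):
        raise ValueError("curve and design disagree on injection count")
    if len(heats) < 4:
        raise ValueError("fewer free data points than parameters")
    if init is None:
        init = _auto_init(curve, design)

    M, X = _total_concentrations(design)
    dv = np.asarray(design.injection_volumes)
    v0 = design.cell_volume

    def residuals(p: lmfit.Parameters) -> np.ndarray:
        n = p["n"].value
        ka = 10.0 ** p["logKa"].value
        dh = p["dH"].value
        Q = _cumulative_heat(n, ka, dh, M, X, v0)
        Qprev = np.concatenate([[0.0], Q[:-1]])
        q = (Q - Qprev + (dv / v0) * (Q + Qprev) / 2.0) * 1e6
        return q - heats

    pars = lmfit.Parameters()
    pars.add("n", value=init.n, min=1e-3, max=100.0)
    pars.add("logKa", value=math.log10(init.Ka), min=0.0, max=18.0)
    pars.add("dH", value=init.dH)
    out = lmfit.minimize(residuals, pars, method="leastsq",
                         xtol=1e-12, ftol=1e-12, max_nfev=20000)

    n_fit = out.params["n"].value
    ka_fit = 10.0 ** out.params["logKa"].value
    dh_fit = out.params["dH"].value
    kd, dg, ds = derive_thermo(ka_fit, dh_fit, design.temperature)

    # propagate log10-Ka stderr to Ka scale where available
    err: dict[str, Optional[float]] = {"n": None, "Ka": None, "dH": None}
    if out.errorbars:
        err["n"] = out.params["n"].stderr
        err["dH"] = out.params["dH"].stderr
        lerr = out.params["logKa"].stderr
        err["Ka"] = ka_fit * math.log(10.0) * lerr if lerr is not None else None

    fitted = heats + out.residual
    return FitResult(
        params=OneSiteParams(n=n_fit, Ka=ka_fit, dH=dh_fit),
        stderr=err,
        Kd=kd, dG=dg, dS=ds,
        residual_norm=float(np.linalg.norm(out.residual)),
        converged=bool(out.success),
        c_value=n_fit * ka_fit * design.cell_concentration,
        fitted_heats=fitted,
    )


def read_titration_table(path: str) -> tuple[np.ndarray, np.ndarray]:
    """Read a delimited titration table.

    Expects two numeric columns — injection volume (uL) and heat (ucal) —
    with optional header and ``#`` comment lines; whitespace, comma or tab
    delimited.  Returns (injection_volumes in L, heats in ucal).
    """
    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#")
    except Exception as exc:
        raise ValueError(f"cannot parse titration table {path!r}: {exc}") from exc
    # tolerate headerless files
    if df.shape[1] < 2:
        raise ValueError(f"titration table {path!r} needs two columns (volume_ul, heat_ucal)")
    try:
        first_row = df.columns[:2].astype(float)
        df = pd.concat(
            [pd.DataFrame([first_row.values], columns=df.columns[:2]), df.iloc[:, :2]],
            ignore_index=True,
        )
    except (TypeError, ValueError):
        pass
    vols = pd.to_numeric(df.iloc[:, 0], errors="coerce").to_numpy()
    heats = pd.to_numeric(df.iloc[:, 1], errors="coerce").to_numpy()
    if np.any(~np.isfinite(vols)) or np.any(~np.isfinite(heats)):
        raise ValueError(f"non-numeric entries in titration table {path!r}")
    return vols * 1e-6, heats
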