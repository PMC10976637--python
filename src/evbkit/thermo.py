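"""Computational Arrhenius plots and activation enthalpy/entropy analysis.

Free energies computed on a grid of temperatures are decomposed into dH and
dS by linear regression in one of two equivalent coordinate systems:

    dG/T vs 1/T   (slope = dH, intercept = -dS)  — accurate when enthalpy dominates
    dG  vs  T     (slope = -dS, intercept = dH)  — accurate when entropy dominates

``mode="auto"`` picks whichever regression has the higher R^2. Also provided:
the bimolecular standard-state translational-entropy correction -RT ln(c2/c1)
(e.g. -RT ln 55 when a solvent-concentration standard state replaces 1 M),
replicate statistics, and the decomposition of dH / T dS along the reaction
path, either on the mapping coordinate lambda or on the product-weight
coordinate c2^2 binned along the ground-state profile.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .core import R_GAS, EVBParameters
from .exceptions import InvalidInputError
from .free_energy import BinSpec, gap_profile, zwanzig_accumulate

logger = logging.getLogger("evbkit")

#: Reference temperature (K) for reporting T*dS; "room temperature".
T_REF_DEFAULT = 300.0

#: Avogadro constant (1/mol), for standard-state volume bookkeeping.
N_AVOGADRO = 6.02214076e23


@dataclass
class ArrheniusSeries:
    """Free energies on a temperature grid, with optional replicate s.e.m."""

    temperatures: np.ndarray
    dg: np.ndarray
    sem: Optional[np.ndarray] = None
    n_replicates: int = 1

    def __post_init__(self) -> None:
        self.temperatures = np.asarray(self.temperatures, dtype=float)
        self.dg = np.asarray(self.dg, dtype=float)
        if self.temperatures.shape != self.dg.shape:
            raise InvalidInputError("temperatures and dg must have equal length")
        if len(np.unique(self.temperatures)) < 3:
            raise InvalidInputError("Arrhenius analysis needs >= 3 distinct temperatures")
        if self.sem is not None:
            self.sem = np.asarray(self.sem, dtype=float)
            if np.any(self.sem < 0):
                raise InvalidInputError("s.e.m. must be >= 0")


@dataclass
class ActivationParameters:
    """dH, dS and diagnostics from one Arrhenius regression.

    ``dh`` in kcal/mol, ``ds`` in kcal/mol/K, ``tds_at`` = t_ref * ds in
    kcal/mol at the stated reference temperature; standard errors are the
    asymptotic errors of the linear regression.
    """

    dh: float
    ds: float
    tds_at: float
    t_ref: float
    se_dh: float
    se_ds: float
    r_squared: float
    mode: str

    def dg(self, temperature: float) -> float:
        """Reconstructed dG(T) = dH - T dS."""
        return self.dh - temperature * self.ds


def _fit(x, y, weights=None):
    """Linear fit returning slope, intercept, their s.e., and R^2."""
    if weights is None:
        res = stats.linregress(x, y)
        return (
            res.slope, res.intercept, res.stderr, res.intercept_stderr,
            res.rvalue ** 2,
        )
    import statsmodels.api as sm

    X = sm.add_constant(x)
    fit = sm.WLS(y, X, weights=weights).fit()
    return (
        fit.params[1], fit.params[0], fit.bse[1], fit.bse[0], fit.rsquared,
    )


def arrhenius_fit(
    series: ArrheniusSeries,
    mode: str = "auto",
    t_ref: float = T_REF_DEFAULT,
    weighted: bool = False,
) -> ActivationParameters:
    """Extract (dH, dS) from dG(T) by ordinary least squares.

    ``mode`` is ``"gOverT_vs_invT"``, ``"g_vs_T"``, or ``"auto"`` (picks the
    regression with the higher R^2). ``weighted=True`` weights points by
    1/sem^2 (requires ``series.sem``); the default is the plain unweighted
    regression on per-temperature means.
    """
    if mode not in ("gOverT_vs_invT", "g_vs_T", "auto"):
        raise InvalidInputError(f"unknown Arrhenius mode {mode!r}")
    T = series.temperatures
    g = series.dg
    w1 = w2 = None
    if weighted:
        if series.sem is None or np.any(series.sem == 0):
            raise InvalidInputError("weighted fit requires nonzero s.e.m. values")
        w1 = (T / series.sem) ** 2      # var(dG/T) = (sem/T)^2
        w2 = 1.0 / series.sem ** 2

    candidates = {}
    if mode in ("gOverT_vs_invT", "auto"):
        slope, intercept, se_s, se_i, r2 = _fit(1.0 / T, g / T, w1)
        candidates["gOverT_vs_invT"] = (slope, -intercept, se_s, se_i, r2)
    if mode in ("g_vs_T", "auto"):
        slope, intercept, se_s, se_i, r2 = _fit(T, g, w2)
        candidates["g_vs_T"] = (intercept, -slope, se_i, se_s, r2)
    chosen = mode if mode != "auto" else max(candidates, key=lambda k: candidates[k][4])
    dh, ds, se_dh, se_ds, r2 = candidates[chosen]
    return ActivationParameters(
        dh=float(dh),
        ds=float(ds),
        tds_at=float(t_ref * ds),
        t_ref=float(t_ref),
        se_dh=float(se_dh),
        se_ds=float(se_ds),
        r_squared=float(r2),
        mode=chosen,
    )


def standard_state_correction(temperature: float, conc_ratio: float) -> float:
    """Translational-entropy correction -RT ln(conc_ratio) in kcal/mol.

    ``conc_ratio`` is the ratio of the new to the old standard-state
    concentration of the diffusing partner (55 for a 1 M -> 55 M water
    standard state).
    """
    if conc_ratio <= 0:
        raise InvalidInputError("concentration ratio must be positive")
    if temperature <= 0:
        raise InvalidInputError("temperature must be positive")
    return -R_GAS * temperature * math.log(conc_ratio)


def apply_correction(dg: float, correction: float) -> float:
    """Apply a standard-state correction to a free energy (simple sum)."""
    return dg + correction


def standard_state_volume(concentration_molar: float = 1.0):
    """Free volume per molecule at the given concentration.

    Returns ``(volume_A3, radius_A)``: at 1 M each molecule moves within
    about 1661 A^3, a sphere of radius ~7.3 A.
    """
    if concentration_molar <= 0:
        raise InvalidInputError("concentration must be positive")
    volume = 1e27 / (N_AVOGADRO * concentration_molar)  # A^3 per molecule
    radius = (3.0 * volume / (4.0 * math.pi)) ** (1.0 / 3.0)
    return volume, radius


def replicate_statistics(values: Sequence[float]):
    """Mean and standard error of the mean over replicate free energies."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise InvalidInputError("replicate statistics need >= 2 replicates")
    return float(values.mean()), float(stats.sem(values, ddof=1))


@dataclass
class EntropyDecomposition:
    """dH and T dS along the reaction path, from per-bin Arrhenius fits.

    ``positions`` are lambda values or c2^2 bin centers; entries are NaN
    where a bin was absent at some temperature. All values are relative to
    the reactant reference point (first lambda, or the first c2^2 bin
    occupied at every temperature).
    """

    coordinate: str
    positions: np.ndarray
    dh: np.ndarray
    tds: np.ndarray
    r_squared: np.ndarray
    t_ref: float
    temperatures: np.ndarray


def _replicate_mean_profiles(dataset, par, temperature, bins, coordinate):
    """Per-bin dG averaged over replicates at one temperature (NaN-aware)."""
    reps = dataset.replicates
    cols = []
    for rep in reps:
        windows = dataset.select(temperature=temperature, replicate=rep)
        prof = gap_profile(windows, par, bins=bins, coordinate=coordinate)
        cols.append(prof.dg_ground)
    stacked = np.vstack(cols)
    out = np.full(stacked.shape[1], np.nan)
    complete = np.all(np.isfinite(stacked), axis=0)
    out[complete] = stacked[:, complete].mean(axis=0)
    return out, prof.bin_centers


def entropy_decomposition(
    dataset,
    par: EVBParameters,
    coordinate: str = "c2_sq",
    bins: Optional[BinSpec] = None,
    t_ref: float = T_REF_DEFAULT,
    mode: str = "auto",
) -> EntropyDecomposition:
    """Decompose the free energy along the path into dH and T dS profiles.

    For ``coordinate="lambda"``, the mapping free energies dG(lambda_m, T)
    (replicate-averaged, relative to lambda = 0) are Arrhenius-fitted per
    window. For ``coordinate="c2_sq"``, frames are binned by their product
    weight c2^2 (default 16 bins on [0.1, 0.9]), the ground-state free energy
    of each bin is reconstructed at every temperature, re-anchored at the
    first bin occupied at all temperatures, and fitted per bin. Bins missing
    at some temperature are flagged absent (NaN).
    """
    temps = dataset.temperatures
    if len(temps) < 3:
        raise InvalidInputError("entropy decomposition needs >= 3 temperatures")
    if coordinate == "lambda":
        lams = None
        values = []
        for T in temps:
            per_rep = []
            for rep in dataset.replicates:
                mapping = zwanzig_accumulate(
                    dataset.select(temperature=T, replicate=rep), par
                )
                per_rep.append(mapping.dg)
                lams = mapping.lambdas
            values.append(np.vstack(per_rep).mean(axis=0))
        values = np.vstack(values)  # (n_T, n_lambda)
        positions = lams
    elif coordinate == "c2_sq":
        if bins is None:
            bins = BinSpec(16, (0.1, 0.9))
        rows = []
        positions = None
        for T in temps:
            row, positions = _replicate_mean_profiles(
                dataset, par, T, bins, "c2_sq"
            )
            rows.append(row)
        values = np.vstack(rows)
        complete = np.all(np.isfinite(values), axis=0)
        if not complete.any():
            raise InvalidInputError("no c2^2 bin is occupied at every temperature")
        ref = int(np.flatnonzero(complete)[0])
        values = values - values[:, [ref]]
    else:
        raise InvalidInputError(f"unknown coordinate {coordinate!r}")

    n_pos = values.shape[1]
    dh = np.full(n_pos, np.nan)
    tds = np.full(n_pos, np.nan)
    r2 = np.full(n_pos, np.nan)
    t_arr = np.asarray(temps, dtype=float)
    for b in range(n_pos):
        col = values[:, b]
        ok = np.isfinite(col)
        if ok.sum() < 3:
            continue
        if np.allclose(col[ok], col[ok][0]):
            # constant dG(T): zero entropy, enthalpy equals the constant
            dh[b], tds[b], r2[b] = col[ok][0], 0.0, 1.0
            continue
        fit = arrhenius_fit(
            ArrheniusSeries(t_arr[ok], col[ok]), mode=mode, t_ref=t_ref
        )
        dh[b], tds[b], r2[b] = fit.dh, fit.tds_at, fit.r_squared
    return EntropyDecomposition(
        coordinate=coordinate,
        positions=np.asarray(positions, dtype=float),
        dh=dh,
        tds=tds,
        r_squared=r2,
        t_ref=t_ref,
        temperatures=t_arr,
    )
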