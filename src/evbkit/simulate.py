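"""One-dimensional solvent-coordinate model with harmonic diabats.

This is the synthetic-data generator of the package: it emulates the
statistical structure of MD/EVB free-energy runs (a set of lambda windows,
each sampling a Gaussian band of the energy gap, at several temperatures
and in independent replicates) using Metropolis Monte Carlo on the mapping
potential

    U_map(lambda; x) = (1 - lambda) U1(x) + lambda U2(x),
    U1 = k1 x^2 / 2,   U2 = k2 (x - d)^2 / 2 + delta_alpha.

Because the diabats are harmonic, every window free energy has a closed
form, which serves as the independent oracle for the Zwanzig/umbrella
estimators:

    G(lambda) - G(0) = U_map(x*(lambda)) + (RT/2) ln(k(lambda)/k(0)),

with k(lambda) = (1 - lambda) k1 + lambda k2 and x*(lambda) its minimum.
For k1 = k2 the system is a symmetric Marcus-type charge-transfer model
with reorganization energy lambda_reorg = k1 d^2 / 2 and diabatic crossing
lambda_reorg / 4.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize_scalar

from .core import R_GAS, DiabaticPoint, EVBParameters, ground_state_energy
from .exceptions import InvalidInputError

logger = logging.getLogger("evbkit")

_ACCEPT_BAND = (0.15, 0.7)
_TUNE_TARGET = 0.40  # burn-in step-size tuning aims at this acceptance rate


def _mc_chain_py(kappa, xcen, rt, step0, n_steps, n_burnin, normals, uniforms):
    """Metropolis chain on a harmonic potential; returns (samples, step, acc_rate)."""
    x = xcen
    step = step0
    n_prod = n_steps - n_burnin
    xs = np.empty(n_prod)
    u = 0.0
    acc_win = 0
    acc_prod = 0
    for i in range(n_steps):
        xp = x + step * normals[i]
        dxp = xp - xcen
        up = 0.5 * kappa * dxp * dxp
        accepted = False
        if up <= u or uniforms[i] < math.exp(-(up - u) / rt):
            x = xp
            u = up
            accepted = True
        if i < n_burnin:
            if accepted:
                acc_win += 1
            if (i + 1) % 200 == 0:
                rate = acc_win / 200.0
                if rate < 0.35:
                    step *= 0.85
                elif rate > 0.45:
                    step *= 1.15
                acc_win = 0
        else:
            xs[i - n_burnin] = x
            if accepted:
                acc_prod += 1
    return xs, step, acc_prod / n_prod


try:  # JIT-compile the inner loop when numba is available
    from numba import njit

    _mc_chain = njit(cache=True)(_mc_chain_py)
except ImportError:  # pragma: no cover - numba is a declared dependency
    _mc_chain = _mc_chain_py


@dataclass(frozen=True)
class HarmonicDiabatModel:
    """Harmonic two-state solvent-coordinate model.

    Parameters
    ----------
    k1, k2 : float
        Diabatic force constants (kcal/mol/A^2), > 0.
    d : float
        Displacement between the diabat minima (A), > 0.
    delta_alpha : float
        Gas-phase shift added to state 2 (kcal/mol).
    h12 : float
        Off-diagonal coupling (kcal/mol), >= 0.
    """

    k1: float
    k2: float
    d: float
    delta_alpha: float = 0.0
    h12: float = 0.0

    def __post_init__(self) -> None:
        if not (self.k1 > 0 and self.k2 > 0 and self.d > 0):
            raise InvalidInputError("k1, k2 and d must be positive")
        if self.h12 < 0:
            raise InvalidInputError("h12 must be >= 0")

    @property
    def reorganization_energy(self) -> float:
        """Marcus reorganization energy k1 d^2 / 2 (exact for k1 = k2)."""
        return 0.5 * self.k1 * self.d * self.d

    @property
    def parameters(self) -> EVBParameters:
        return EVBParameters(self.h12, self.delta_alpha)

    @classmethod
    def symmetric(
        cls,
        h12: float = 0.0,
        delta_alpha: float = 0.0,
        reorganization_energy: float = 148.0,
        d: float = 6.0,
    ) -> "HarmonicDiabatModel":
        """Symmetric charge-transfer preset (default diabatic crossing 37 kcal/mol)."""
        k = 2.0 * reorganization_energy / (d * d)
        return cls(k1=k, k2=k, d=d, delta_alpha=delta_alpha, h12=h12)

    @classmethod
    def asymmetric(
        cls, h12: float = 20.0, delta_alpha: float = 0.0
    ) -> "HarmonicDiabatModel":
        """Preset with k2/k1 = 2, giving a nonzero reaction entropy -(R/2) ln 2."""
        k1 = 2.0 * 148.0 / 36.0
        return cls(k1=k1, k2=2.0 * k1, d=6.0, delta_alpha=delta_alpha, h12=h12)


@dataclass(frozen=True)
class SamplingSpec:
    """How to sample the model: lambda schedule, temperatures, chain lengths, seed."""

    lambda_schedule: tuple = tuple(np.linspace(0.0, 1.0, 21))
    temperatures: tuple = (280.0, 290.0, 300.0, 310.0, 320.0)
    n_steps: int = 200_000
    n_burnin: int = 20_000
    step_size: float = 0.5
    seed: int = 0
    n_replicates: int = 3

    def __post_init__(self) -> None:
        # normalise to plain Python floats so configs round-trip through YAML
        object.__setattr__(
            self, "lambda_schedule", tuple(float(v) for v in self.lambda_schedule)
        )
        object.__setattr__(
            self, "temperatures", tuple(float(t) for t in self.temperatures)
        )
        lam = np.asarray(self.lambda_schedule, dtype=float)
        if lam.size < 2 or np.any(np.diff(lam) <= 0):
            raise InvalidInputError("lambda schedule must be strictly increasing")
        if lam[0] != 0.0 or lam[-1] != 1.0:
            raise InvalidInputError("lambda schedule must include endpoints 0 and 1")
        if not (self.n_steps > self.n_burnin >= 0):
            raise InvalidInputError("need n_steps > n_burnin >= 0")
        if self.step_size <= 0:
            raise InvalidInputError("step_size must be positive")
        if self.n_replicates < 1:
            raise InvalidInputError("n_replicates must be >= 1")

    def with_(self, **kwargs) -> "SamplingSpec":
        return replace(self, **kwargs)


@dataclass
class TrajectoryWindow:
    """Frames sampled at one (lambda, temperature, replicate)."""

    lambda_m: float
    temperature: float
    x: np.ndarray
    u1: np.ndarray
    u2_raw: np.ndarray
    replicate: int = 0
    acceptance_rate: Optional[float] = None
    step_size: Optional[float] = None

    @property
    def n_frames(self) -> int:
        return len(self.u1)


@dataclass
class TrajectoryDataset:
    """All windows of a run, across lambda, temperature and replicates."""

    windows: list = field(default_factory=list)

    @property
    def temperatures(self):
        return sorted({w.temperature for w in self.windows})

    @property
    def replicates(self):
        return sorted({w.replicate for w in self.windows})

    @property
    def lambdas(self):
        return sorted({w.lambda_m for w in self.windows})

    def select(self, temperature=None, replicate=None):
        """Windows matching the given temperature and/or replicate, sorted by lambda."""
        out = [
            w
            for w in self.windows
            if (temperature is None or w.temperature == temperature)
            and (replicate is None or w.replicate == replicate)
        ]
        return sorted(out, key=lambda w: w.lambda_m)

    def __len__(self) -> int:
        return len(self.windows)


def diabat_energies(model: HarmonicDiabatModel, x: float) -> DiabaticPoint:
    """Diabatic energies at coordinate x; the returned u2 includes delta_alpha."""
    if not np.all(np.isfinite(x)):
        raise InvalidInputError("coordinate must be finite")
    u1 = 0.5 * model.k1 * x * x
    u2_raw = 0.5 * model.k2 * (x - model.d) ** 2
    return DiabaticPoint(float(u1), float(u2_raw + model.delta_alpha))


def mapping_potential(model: HarmonicDiabatModel, x, lambda_m: float):
    """Mapping potential U_map = (1 - lambda) U1 + lambda U2 at coordinate x."""
    if not 0.0 <= lambda_m <= 1.0:
        raise InvalidInputError(f"lambda must be in [0, 1], got {lambda_m}")
    x = np.asarray(x, dtype=float)
    u1 = 0.5 * model.k1 * x * x
    u2 = 0.5 * model.k2 * (x - model.d) ** 2 + model.delta_alpha
    out = (1.0 - lambda_m) * u1 + lambda_m * u2
    return out if out.ndim else float(out)


def _stiffness(model: HarmonicDiabatModel, lam: float) -> float:
    return (1.0 - lam) * model.k1 + lam * model.k2


def _map_minimum(model: HarmonicDiabatModel, lam: float) -> float:
    return lam * model.k2 * model.d / _stiffness(model, lam)


def analytic_window_free_energy(
    model: HarmonicDiabatModel, lambda_m: float, temperature: float
) -> float:
    """Closed-form G(lambda) - G(0) of the harmonic mapping potential (kcal/mol)."""
    if not 0.0 <= lambda_m <= 1.0:
        raise InvalidInputError(f"lambda must be in [0, 1], got {lambda_m}")
    rt = R_GAS * temperature
    xstar = _map_minimum(model, lambda_m)
    umin = mapping_potential(model, xstar, lambda_m)
    return umin + 0.5 * rt * math.log(_stiffness(model, lambda_m) / model.k1)


def analytic_endpoint_entropy(model: HarmonicDiabatModel) -> float:
    """Closed-form reaction entropy S(1) - S(0) = -(R/2) ln(k2/k1), in kcal/mol/K."""
    return -0.5 * R_GAS * math.log(model.k2 / model.k1)


def analytic_adiabatic_extrema(model: HarmonicDiabatModel):
    """Stationary points of Eg(x): (dg_act, dg_rxn) on the adiabatic potential curve.

    Neglects the coordinate-Jacobian entropy of binning; for k1 = k2 (linear
    gap-coordinate map) the values coincide with the binned free-energy
    profile exactly, which makes this the oracle for the symmetric presets.
    """

    def eg(x):
        u1 = 0.5 * model.k1 * x * x
        u2 = 0.5 * model.k2 * (x - model.d) ** 2 + model.delta_alpha
        return ground_state_energy(u1, u2, model.h12)

    d = model.d
    rm = minimize_scalar(eg, bounds=(-d, d / 2), method="bounded")
    pm = minimize_scalar(eg, bounds=(d / 2 - 1.0, 2 * d), method="bounded")
    ts = minimize_scalar(lambda x: -eg(x), bounds=(rm.x, pm.x), method="bounded")
    return float(-ts.fun - rm.fun), float(pm.fun - rm.fun)


def simulate_window(
    model: HarmonicDiabatModel,
    lambda_m: float,
    temperature: float,
    spec: SamplingSpec,
    seed=None,
    replicate: int = 0,
) -> TrajectoryWindow:
    """Metropolis Monte Carlo on U_map(lambda) at the given temperature.

    The chain starts at the minimum of the mapping potential, tunes its
    Gaussian proposal width during burn-in toward ~40% acceptance, and
    returns the post-burn-in frames. Identical seeds give bit-identical
    trajectories.
    """
    if not 0.0 <= lambda_m <= 1.0:
        raise InvalidInputError(f"lambda must be in [0, 1], got {lambda_m}")
    if temperature <= 0:
        raise InvalidInputError("temperature must be positive")
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    normals = rng.standard_normal(spec.n_steps)
    uniforms = rng.random(spec.n_steps)
    kappa = _stiffness(model, lambda_m)
    xcen = _map_minimum(model, lambda_m)
    rt = R_GAS * temperature
    xs, step, acc = _mc_chain(
        kappa, xcen, rt, spec.step_size, spec.n_steps, spec.n_burnin, normals, uniforms
    )
    if not (_ACCEPT_BAND[0] <= acc <= _ACCEPT_BAND[1]):
        logger.warning(
            "WARN: acceptance rate %.3f outside [%.2f, %.2f] at lambda=%.3f T=%.1fK",
            acc, *_ACCEPT_BAND, lambda_m, temperature,
        )
    u1 = 0.5 * model.k1 * xs * xs
    u2_raw = 0.5 * model.k2 * (xs - model.d) ** 2
    return TrajectoryWindow(
        lambda_m=float(lambda_m),
        temperature=float(temperature),
        x=xs,
        u1=u1,
        u2_raw=u2_raw,
        replicate=replicate,
        acceptance_rate=float(acc),
        step_size=float(step),
    )


def subseed(seed: int, t_index: int, replicate: int, lambda_index: int):
    """Counter-based sub-seed for one window: SeedSequence spawn-key splitting."""
    return np.random.SeedSequence(seed, spawn_key=(t_index, replicate, lambda_index))


def generate_dataset(
    model: HarmonicDiabatModel, spec: SamplingSpec, out_dir=None
) -> TrajectoryDataset:
    """Simulate every (temperature, replicate, lambda) window of the spec.

    Sub-seeds are derived deterministically from (spec.seed, temperature
    index, replicate index, lambda index), so replicates are independent by
    construction and the full dataset is reproducible bit-for-bit. If
    ``out_dir`` is given, trajectory tables are written there (one file per
    temperature and replicate).
    """
    windows = []
    for ti, temp in enumerate(spec.temperatures):
        for ri in range(spec.n_replicates):
            for li, lam in enumerate(spec.lambda_schedule):
                windows.append(
                    simulate_window(
                        model,
                        lam,
                        temp,
                        spec,
                        seed=subseed(spec.seed, ti, ri, li),
                        replicate=ri,
                    )
                )
    dataset = TrajectoryDataset(windows)
    if out_dir is not None:
        from .io import write_trajectory_tables

        write_trajectory_tables(dataset, out_dir)
    return dataset
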