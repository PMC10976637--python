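"""Mapping free energies and energy-gap free-energy profiles.

The free energy along the lambda schedule is accumulated with Zwanzig's
exponential formula between adjacent windows,

    dG(l_{n+1}) - dG(l_n) = -RT ln < exp(-(U_map(l_{n+1}) - U_map(l_n)) / RT) >_{l_n},

and the ground-state (adiabatic) profile on the energy-gap coordinate
dU = U1 - U2 is reconstructed with the umbrella-sampling expression

    dG_g^{(m)}(X) = dG(l_m) - RT ln < exp(-(Eg - U_map(l_m)) / RT) 1[dU in bin X] >_m,

pieced together over the windows m that populate each bin with normalised
statistical weights p_m (each window's share of the bin's frames). Diabatic
profiles replace Eg by U1 or U2. All exponential averages are evaluated in
log space with a max shift.

Because h12 never enters the mapping potential and a change of delta_alpha
shifts U_map by the frame-independent constant lambda * d(delta_alpha) per
window, re-evaluating all of these quantities under new (h12, delta_alpha)
on unchanged trajectories is exactly consistent — the basis of the post-hoc
parameter-perturbation protocol implemented by :func:`reweight_profile` and
of the (h12, delta_alpha) calibration in :func:`calibrate_parameters`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.special import logsumexp

from .core import R_GAS, EVBParameters, StateWeights, ground_state_energy
from .exceptions import (
    CalibrationError,
    InvalidInputError,
    MonotoneProfileError,
    ProfileCoverageError,
)

logger = logging.getLogger("evbkit")

_ESS_WARN = 10.0


@dataclass(frozen=True)
class BinSpec:
    """Histogram specification for the reaction-coordinate profiles.

    ``gap_range=None`` uses the observed coordinate range padded by 1% of its
    span on each side. Bins receiving fewer than ``min_frames`` frames from a
    window exclude that window; bins with no contributing window are flagged
    absent (NaN), never zero.
    """

    n_bins: int = 51
    gap_range: Optional[Tuple[float, float]] = None
    min_frames: int = 10

    def __post_init__(self) -> None:
        if self.n_bins < 1:
            raise InvalidInputError("n_bins must be >= 1")
        if self.min_frames < 1:
            raise InvalidInputError("min_frames must be >= 1")
        if self.gap_range is not None and not self.gap_range[1] > self.gap_range[0]:
            raise InvalidInputError("gap_range must be increasing")


@dataclass
class MappingProfile:
    """Cumulative free energies dG(lambda_m) relative to lambda = 0."""

    lambdas: np.ndarray
    dg: np.ndarray
    n_frames: np.ndarray
    temperature: float


@dataclass
class GapProfile:
    """Binned free energies on a reaction coordinate (dU by default).

    ``dg_ground``, ``dg_state1`` and ``dg_state2`` are anchored so that the
    ground-state reactant minimum is zero; absent bins are NaN. ``window_weights``
    holds the per-bin normalised window weights p_m (rows = windows in
    ``window_lambdas`` order), and ``mean_c2_sq`` the frame-averaged product
    weight per bin.
    """

    bin_centers: np.ndarray
    bin_edges: np.ndarray
    dg_ground: np.ndarray
    dg_state1: np.ndarray
    dg_state2: np.ndarray
    counts: np.ndarray
    window_weights: np.ndarray
    window_lambdas: np.ndarray
    mean_c2_sq: np.ndarray
    temperature: float
    parameters: EVBParameters
    coordinate: str = "delta_u"
    mode: str = "direct"

    def to_frame(self):
        """Profile as a pandas DataFrame (one row per bin)."""
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_center_dU" if self.coordinate == "delta_u" else "bin_center_c2sq":
                    self.bin_centers,
                "dG_ground": self.dg_ground,
                "dG_state1": self.dg_state1,
                "dG_state2": self.dg_state2,
                "n_frames": self.counts,
            }
        )


@dataclass
class ProfileSummary:
    """Stationary points of a ground-state profile."""

    dg_act: float
    dg_rxn: float
    reactant_position: float
    ts_position: float
    product_position: float
    ts_weights: Optional[StateWeights]
    temperature: float


def _sorted_windows(windows):
    windows = list(windows)
    if not windows:
        raise InvalidInputError("no trajectory windows given")
    temps = {w.temperature for w in windows}
    if len(temps) != 1:
        raise InvalidInputError(f"windows span several temperatures: {sorted(temps)}")
    windows.sort(key=lambda w: w.lambda_m)
    lams = [w.lambda_m for w in windows]
    if len(set(lams)) != len(lams):
        raise InvalidInputError(
            "duplicate lambda windows; select a single replicate first"
        )
    for w in windows:
        if w.n_frames == 0:
            raise InvalidInputError(f"empty window at lambda={w.lambda_m}")
    return windows


def _u_map(window, par: EVBParameters):
    u2 = window.u2_raw + par.delta_alpha
    return (1.0 - window.lambda_m) * window.u1 + window.lambda_m * u2


def zwanzig_accumulate(windows, par: EVBParameters, log_weights=None) -> MappingProfile:
    """Forward Zwanzig (FEP) accumulation of dG(lambda) from lambda = 0.

    ``log_weights`` optionally supplies per-frame log importance weights for
    each window (used by the importance reweighting mode); the default is an
    unweighted ensemble average. Warns when the effective sample size of the
    exponential average drops below 10.
    """
    windows = _sorted_windows(windows)
    rt = R_GAS * windows[0].temperature
    lams = np.array([w.lambda_m for w in windows])
    steps = [0.0]
    for n in range(len(windows) - 1):
        w = windows[n]
        dlam = lams[n + 1] - lams[n]
        du = dlam * ((w.u2_raw + par.delta_alpha) - w.u1)
        arg = -du / rt
        lw = None if log_weights is None else np.asarray(log_weights[n], dtype=float)
        if lw is None:
            log_mean = logsumexp(arg) - np.log(arg.size)
            ess_arg = arg
        else:
            log_mean = logsumexp(arg + lw) - logsumexp(lw)
            ess_arg = arg + lw
        ess = np.exp(2.0 * logsumexp(ess_arg) - logsumexp(2.0 * ess_arg))
        if ess < _ESS_WARN:
            logger.warning(
                "WARN: effective sample size %.1f < %.0f for FEP step %.3f -> %.3f",
                ess, _ESS_WARN, lams[n], lams[n + 1],
            )
        steps.append(-rt * log_mean)
    return MappingProfile(
        lambdas=lams,
        dg=np.cumsum(steps),
        n_frames=np.array([w.n_frames for w in windows]),
        temperature=windows[0].temperature,
    )


def _grouped_logsumexp(arg, idx, n_bins):
    """logsumexp of ``arg`` grouped by bin index; -inf for empty bins."""
    out = np.full(n_bins, -np.inf)
    order = np.argsort(idx, kind="stable")
    sidx = idx[order]
    sarg = arg[order]
    bounds = np.searchsorted(sidx, np.arange(n_bins + 1))
    for b in range(n_bins):
        lo, hi = bounds[b], bounds[b + 1]
        if hi > lo:
            out[b] = logsumexp(sarg[lo:hi])
    return out


def _frame_c2_sq(u1, u2, h12):
    """Per-frame product weight c2^2; lower-diabat indicator when h12 = 0."""
    if h12 == 0.0:
        c2 = np.where(u2 < u1, 1.0, 0.0)
        return np.where(u1 == u2, 0.5, c2)
    delta = u2 - u1
    return 0.5 * (1.0 - delta / np.hypot(delta, 2.0 * h12))


def gap_profile(
    windows,
    par: EVBParameters,
    bins: Optional[BinSpec] = None,
    mapping: Optional[MappingProfile] = None,
    coordinate: str = "delta_u",
    log_weights=None,
    mode: str = "direct",
) -> GapProfile:
    """Reconstruct ground-state and diabatic profiles on a binned coordinate.

    ``coordinate`` is ``"delta_u"`` (the energy gap, default) or ``"c2_sq"``
    (the product state weight, used for the entropy decomposition along the
    reaction path). All three energy columns are computed in one pass; see
    :func:`ground_state_profile` and :func:`diabatic_profiles` for the
    single-purpose entry points.
    """
    if coordinate not in ("delta_u", "c2_sq"):
        raise InvalidInputError(f"unknown coordinate {coordinate!r}")
    windows = _sorted_windows(windows)
    if bins is None:
        bins = BinSpec() if coordinate == "delta_u" else BinSpec(16, (0.1, 0.9))
    rt = R_GAS * windows[0].temperature
    if mapping is None:
        mapping = zwanzig_accumulate(windows, par, log_weights=log_weights)
    if not np.allclose(mapping.lambdas, [w.lambda_m for w in windows]):
        raise InvalidInputError("mapping profile does not match the window schedule")

    n_w = len(windows)
    per = []
    for n, w in enumerate(windows):
        u2 = w.u2_raw + par.delta_alpha
        eg = ground_state_energy(w.u1, u2, par.h12)
        umap = _u_map(w, par)
        c2 = _frame_c2_sq(w.u1, u2, par.h12)
        coord = (w.u1 - u2) if coordinate == "delta_u" else c2
        lw = None if log_weights is None else np.asarray(log_weights[n], dtype=float)
        per.append((w, u2, eg, umap, c2, coord, lw))

    if bins.gap_range is not None:
        lo, hi = bins.gap_range
    else:
        lo = min(p[5].min() for p in per)
        hi = max(p[5].max() for p in per)
        pad = 0.01 * (hi - lo)
        lo, hi = lo - pad, hi + pad
    edges = np.linspace(lo, hi, bins.n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    counts = np.zeros((n_w, bins.n_bins))
    vals = np.full((3, n_w, bins.n_bins), np.nan)  # ground, state1, state2
    c2_sum = np.zeros(bins.n_bins)
    c2_cnt = np.zeros(bins.n_bins)
    for n, (w, u2, eg, umap, c2, coord, lw) in enumerate(per):
        idx = np.digitize(coord, edges) - 1
        inb = (idx >= 0) & (idx < bins.n_bins)
        idx_in = idx[inb]
        if lw is None:
            counts[n] = np.bincount(idx_in, minlength=bins.n_bins)
            log_norm = np.log(w.n_frames)
            lw_in = None
        else:
            wts = np.exp(lw - lw.max())
            counts[n] = np.bincount(idx_in, weights=wts[inb], minlength=bins.n_bins) * (
                w.n_frames / wts.sum()
            )
            log_norm = logsumexp(lw)
            lw_in = lw[inb]
            ess = np.exp(2.0 * logsumexp(lw) - logsumexp(2.0 * lw))
            if ess < _ESS_WARN:
                logger.warning(
                    "WARN: importance-weight ESS %.1f < %.0f at lambda=%.3f",
                    ess, _ESS_WARN, w.lambda_m,
                )
        for col, surf in enumerate((eg, w.u1, u2)):
            arg = -(surf[inb] - umap[inb]) / rt
            if lw_in is not None:
                arg = arg + lw_in
            lse = _grouped_logsumexp(arg, idx_in, bins.n_bins)
            vals[col, n] = mapping.dg[n] - rt * (lse - log_norm)
        c2_sum += np.bincount(idx_in, weights=c2[inb], minlength=bins.n_bins)
        c2_cnt += np.bincount(idx_in, minlength=bins.n_bins)

    # epsilon guards the threshold against float effective counts (importance mode)
    included = counts >= bins.min_frames - 1e-6
    denom = np.where(included, counts, 0.0).sum(axis=0)
    occupied = denom > 0
    if coordinate == "delta_u":
        # the schedule must tile the path between the windows' typical gaps;
        # ragged histogram tails beyond the outermost windows are fine
        medians = [float(np.median(p[5])) for p in per]
        core = (centers >= min(medians)) & (centers <= max(medians))
        run = 0
        for filled in occupied[core]:
            run = 0 if filled else run + 1
            if run >= 2:
                raise ProfileCoverageError(
                    "lambda schedule does not bridge the barrier: "
                    "interior bins of the energy-gap histogram are empty"
                )

    p = np.zeros_like(counts)
    np.divide(
        np.where(included, counts, 0.0), denom, out=p, where=occupied[None, :]
    )
    combined = np.full((3, bins.n_bins), np.nan)
    for col in range(3):
        v = np.where(included, vals[col], 0.0)
        combined[col, occupied] = (p * v).sum(axis=0)[occupied]
    mean_c2 = np.full(bins.n_bins, np.nan)
    np.divide(c2_sum, c2_cnt, out=mean_c2, where=c2_cnt > 0)

    profile = GapProfile(
        bin_centers=centers,
        bin_edges=edges,
        dg_ground=combined[0],
        dg_state1=combined[1],
        dg_state2=combined[2],
        counts=denom,
        window_weights=p,
        window_lambdas=mapping.lambdas.copy(),
        mean_c2_sq=mean_c2,
        temperature=windows[0].temperature,
        parameters=par,
        coordinate=coordinate,
        mode=mode,
    )
    _anchor_profile(profile)
    return profile


def _anchor_profile(profile: GapProfile) -> None:
    """Shift all columns so the ground-state reactant minimum sits at zero."""
    if profile.coordinate == "delta_u":
        try:
            summary = _stationary_points(
                profile.bin_centers, profile.dg_ground, profile.temperature
            )
            anchor = summary[5]  # refined reactant minimum value
        except (MonotoneProfileError, InvalidInputError):
            anchor = np.nanmin(profile.dg_ground)
    else:
        occ = np.flatnonzero(np.isfinite(profile.dg_ground))
        anchor = profile.dg_ground[occ[0]] if occ.size else 0.0
    for col in (profile.dg_ground, profile.dg_state1, profile.dg_state2):
        col -= anchor


def ground_state_profile(
    windows, par: EVBParameters, bins: Optional[BinSpec] = None,
    mapping: Optional[MappingProfile] = None,
) -> GapProfile:
    """Ground-state free energy on the energy-gap coordinate (Marcus-type profile).

    The diabatic columns are computed in the same pass and carried along.
    """
    return gap_profile(windows, par, bins=bins, mapping=mapping)


def diabatic_profiles(
    windows, par: EVBParameters, bins: Optional[BinSpec] = None,
    mapping: Optional[MappingProfile] = None,
) -> GapProfile:
    """Reactant/product diabatic free-energy curves on the energy gap.

    Identical binning and window weighting as the ground-state profile; the
    ground-state column is carried along.
    """
    return gap_profile(windows, par, bins=bins, mapping=mapping)


def _quadratic_vertex(xs, ys):
    """Vertex of the parabola through three points; falls back to the middle point."""
    a, b, c = np.polyfit(xs, ys, 2)
    if a == 0.0:
        return xs[1], ys[1]
    xv = -b / (2.0 * a)
    if not (min(xs) <= xv <= max(xs)):
        return xs[1], ys[1]
    return float(xv), float(c - b * b / (4.0 * a))


def _refine(centers, values, i):
    """3-point quadratic refinement around a discrete extremum index."""
    if 0 < i < len(values) - 1:
        return _quadratic_vertex(centers[i - 1: i + 2], values[i - 1: i + 2])
    return float(centers[i]), float(values[i])


def _stationary_points(centers, dg, temperature):
    valid = np.isfinite(dg)
    if valid.sum() < 5:
        raise InvalidInputError("need at least 5 occupied bins spanning both wells")
    c = centers[valid]
    g = dg[valid]
    # pick the interior maximum with the largest two-sided barrier, which is
    # robust to profile edges rising above the transition state
    prefix_min = np.minimum.accumulate(g)
    suffix_min = np.minimum.accumulate(g[::-1])[::-1]
    score = np.full(g.size, -np.inf)
    score[1:-1] = np.minimum(
        g[1:-1] - prefix_min[:-2], g[1:-1] - suffix_min[2:]
    )
    j = int(np.argmax(score))
    if score[j] <= 0.0:
        raise MonotoneProfileError("profile has no interior maximum between two minima")
    i_r = int(np.argmin(g[:j]))
    i_p = j + int(np.argmin(g[j:]))
    ts_x, ts_v = _refine(c, g, j)
    r_x, r_v = _refine(c, g, i_r)
    p_x, p_v = _refine(c, g, i_p)
    return ts_x, ts_v, r_x, p_x, p_v, r_v


def extract_stationary_points(profile: GapProfile) -> ProfileSummary:
    """Locate reactant/product minima and the intervening maximum on dG_ground.

    Discrete extrema are refined by a local 3-point quadratic fit; the
    activation and reaction free energies are reported relative to the
    reactant minimum, and the transition-state weights are the frame-averaged
    (c1^2, c2^2) of the bin containing the refined maximum.
    """
    ts_x, ts_v, r_x, p_x, p_v, r_v = _stationary_points(
        profile.bin_centers, profile.dg_ground, profile.temperature
    )
    ts_weights = None
    ts_bin = int(np.clip(
        np.digitize(ts_x, profile.bin_edges) - 1, 0, len(profile.bin_centers) - 1
    ))
    c2 = profile.mean_c2_sq[ts_bin]
    if np.isfinite(c2):
        ts_weights = StateWeights.from_c1_sq(float(np.clip(1.0 - c2, 0.0, 1.0)))
    return ProfileSummary(
        dg_act=float(ts_v - r_v),
        dg_rxn=float(p_v - r_v),
        reactant_position=float(r_x),
        ts_position=float(ts_x),
        product_position=float(p_x),
        ts_weights=ts_weights,
        temperature=profile.temperature,
    )


def reweight_profile(
    windows,
    par_old: EVBParameters,
    par_new: EVBParameters,
    bins: Optional[BinSpec] = None,
    mode: str = "reevaluate",
):
    """Re-analyse stored trajectories under new (h12, delta_alpha).

    ``mode="reevaluate"`` (default) re-evaluates Eg, U2, the gap and every
    mapping/umbrella quantity under ``par_new`` on the unchanged frame set —
    the "same underlying trajectories" protocol, which is exactly consistent
    for this parameter family (see module docstring). ``mode="importance"``
    additionally importance-weights each frame by
    exp(-(U_map_new - U_map_old)/RT), normalised per window.

    Returns ``(GapProfile, ProfileSummary)``; the mode is recorded on the
    profile.
    """
    if mode not in ("reevaluate", "importance"):
        raise InvalidInputError(f"unknown reweighting mode {mode!r}")
    windows = _sorted_windows(windows)
    log_weights = None
    if mode == "importance":
        rt = R_GAS * windows[0].temperature
        log_weights = [
            -(_u_map(w, par_new) - _u_map(w, par_old)) / rt for w in windows
        ]
    profile = gap_profile(
        windows, par_new, bins=bins, log_weights=log_weights, mode=mode
    )
    return profile, extract_stationary_points(profile)


def calibrate_parameters(
    windows,
    bins: Optional[BinSpec],
    targets: Tuple[float, float],
    par0: Optional[EVBParameters] = None,
    tolerance: float = 0.05,
    max_nfev: int = 200,
):
    """Fit (h12, delta_alpha) so the profile reproduces target (dG_act, dG_rxn).

    A two-dimensional bounded least-squares root find; every evaluation
    re-analyses the same trajectories under the trial parameters (post-hoc
    re-evaluation, so no resampling is needed). Returns the calibrated
    :class:`EVBParameters` and a convergence report.

    Raises
    ------
    CalibrationError
        If the residuals exceed ``tolerance`` after ``max_nfev`` evaluations.
    """
    dg_act_t, dg_rxn_t = targets
    if not (np.isfinite(dg_act_t) and np.isfinite(dg_rxn_t)):
        raise InvalidInputError("calibration targets must be finite")
    windows = _sorted_windows(windows)

    def residual(theta):
        par = EVBParameters(h12=max(theta[0], 0.0), delta_alpha=theta[1])
        prof = gap_profile(windows, par, bins=bins)
        s = extract_stationary_points(prof)
        return np.array([s.dg_act - dg_act_t, s.dg_rxn - dg_rxn_t])

    if par0 is None:
        base = extract_stationary_points(
            gap_profile(windows, EVBParameters(0.0, 0.0), bins=bins)
        )
        h12_0 = max(base.dg_act + 0.5 * (dg_rxn_t - base.dg_rxn) - dg_act_t, 0.5)
        par0 = EVBParameters(h12_0, dg_rxn_t - base.dg_rxn)
    result = least_squares(
        residual,
        x0=[par0.h12, par0.delta_alpha],
        bounds=([0.0, -np.inf], [np.inf, np.inf]),
        diff_step=1e-3,
        xtol=1e-12,
        ftol=1e-12,
        gtol=1e-12,
        max_nfev=max_nfev,
    )
    resid = residual(result.x)
    report = {
        "residual_dg_act": float(resid[0]),
        "residual_dg_rxn": float(resid[1]),
        "n_evaluations": int(result.nfev),
        "converged": bool(np.max(np.abs(resid)) <= tolerance),
    }
    if not report["converged"]:
        raise CalibrationError(
            f"calibration did not reach |residual| <= {tolerance} kcal/mol; "
            f"last residuals (dG_act, dG_rxn) = ({resid[0]:.4f}, {resid[1]:.4f})"
        )
    return EVBParameters(float(result.x[0]), float(result.x[1])), report
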