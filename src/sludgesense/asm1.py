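"""Discrete-time reduced activated-sludge (ASM1-type) plant model.

The model tracks five states in the aeration tank:

==========  =====================================================  =========
state       meaning                                                units
==========  =====================================================  =========
``X1``      readily biodegradable soluble substrate                mg COD/L
``X2``      slowly biodegradable particulate substrate             mg COD/L
``X3``      active heterotrophic biomass                           mg COD/L
``X4``      active autotrophic biomass                             mg COD/L
``X5``      dissolved oxygen                                       mg/L
==========  =====================================================  =========

The continuous balances are advanced with an explicit Euler map
``X_{k+1} = X_k + Ts * f(X_k)`` at sampling period ``Ts``.  Seven
dimensionless Monod/switching functions gate the kinetics: substrate
saturation (mu1), ammonia saturation (mu2), the aerobic/anoxic oxygen
switches (mu3/mu4), oxygen saturation for autotrophs (mu5), nitrate
saturation (mu6) and hydrolysis saturation in the particulate-to-biomass
ratio (mu7).  Nitrogen is not part of the reduced state vector, so the
ammonia/nitrate saturations are evaluated at quasi-constant surrogate
concentrations derived from the nitrogen load.

The effluent quality index is the total chemical oxygen demand
``TCOD = X1 + X2 + Is`` with ``Is`` the inert soluble material that passes
through the plant unchanged.
"""

from __future__ import annotations

import logging
import warnings
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .config import KineticParams, PlantConfig, StoichParams

__all__ = [
    "StateVector",
    "InfluentRecord",
    "STATE_COLUMNS",
    "INFLUENT_COLUMNS",
    "TRAJECTORY_COLUMNS",
    "compute_rates",
    "step",
    "simulate",
    "tcod",
    "effluent_compliance",
    "steady_state",
    "read_trajectory",
    "write_trajectory",
]

logger = logging.getLogger(__name__)

STATE_COLUMNS = ["X1", "X2", "X3", "X4", "X5"]
INFLUENT_COLUMNS = ["X1_in", "X2_in", "X3_in", "X4_in", "X5_in", "D_t", "Is"]
TRAJECTORY_COLUMNS = ["time_h"] + STATE_COLUMNS + INFLUENT_COLUMNS + ["TCOD"]


class StateVector(NamedTuple):
    """Plant state at one sampling instant (mg COD/L; mg/L for X5)."""

    X1: float
    X2: float
    X3: float
    X4: float
    X5: float


class InfluentRecord(NamedTuple):
    """Influent concentrations, dilution rate and inert COD at one step."""

    X1_in: float
    X2_in: float
    X3_in: float
    X4_in: float
    X5_in: float
    D_t: float       # 1/h instantaneous dilution rate
    Is: float        # mg COD/L inert soluble material


def _check_state(state: Sequence[float]) -> np.ndarray:
    arr = np.asarray(state, dtype=float)
    if arr.shape != (5,):
        raise ValueError(f"state must have 5 components, got shape {arr.shape}")
    for name, value in zip(STATE_COLUMNS, arr):
        if not np.isfinite(value):
            raise ValueError(f"non-finite state value: {name} = {value}")
    return arr


def compute_rates(state: Sequence[float], kin: KineticParams) -> np.ndarray:
    """Evaluate the seven saturation/switching functions at a plant state.

    Returns ``[mu1, ..., mu7]``, each in [0, 1].  The hydrolysis saturation
    mu7 works on the ratio X2/X3 and tends to 1 as the biomass vanishes with
    substrate still present.
    """
    X1, X2, X3, X4, X5 = _check_state(state)
    mu1 = X1 / (kin.K_S + X1)
    mu2 = kin.S_NH_const / (kin.K_NH + kin.S_NH_const)
    mu3 = X5 / (kin.K_OH + X5)
    mu4 = kin.K_OH / (kin.K_OH + X5)
    mu5 = X5 / (kin.K_OA + X5)
    mu6 = kin.S_NO_const / (kin.K_NO + kin.S_NO_const)
    if X3 > 0.0:
        ratio = X2 / X3
        # overflow of X2/X3 (vanishing biomass) is the saturated limit
        mu7 = ratio / (kin.K_X + ratio) if np.isfinite(ratio) else 1.0
    else:
        mu7 = 1.0 if X2 > 0.0 else 0.0
    return np.array([mu1, mu2, mu3, mu4, mu5, mu6, mu7])


def _rhs(state: np.ndarray, inf: InfluentRecord, kin: KineticParams,
         stoich: StoichParams, plant: PlantConfig) -> np.ndarray:
    """Right-hand sides of the five balance equations (per hour)."""
    X1, X2, X3, X4, X5 = state
    mu1, mu2, mu3, mu4, mu5, mu6, mu7 = compute_rates(state, kin)
    D = inf.D_t
    rb = plant.r_recycle

    aerobic_anoxic_g = mu3 + mu4 * mu6 * kin.eta_g
    aerobic_anoxic_h = mu3 + mu4 * mu6 * kin.eta_h
    growth_H = mu1 * kin.mu_max_H * aerobic_anoxic_g * X3
    hydrolysis = mu7 * kin.k_h * aerobic_anoxic_h * X3
    growth_A = mu2 * mu5 * kin.mu_max_A * X4
    decay_supply = (1.0 - stoich.f_p) * (kin.b_H * X3 + kin.b_A * X4)

    f1 = D * (inf.X1_in - X1) - growth_H / stoich.Y_H + hydrolysis
    f2 = (D * (inf.X2_in - X2) + D * (rb - 1.0) * X2
          + decay_supply - hydrolysis)
    f3 = (D * (inf.X3_in - X3) + D * (rb - 1.0) * X3
          + mu1 * mu3 * kin.mu_max_H * X3
          + mu1 * mu4 * mu6 * kin.mu_max_H * kin.eta_g * X3
          - kin.b_H * X3)
    f4 = (D * (inf.X4_in - X4) + D * (rb - 1.0) * X4
          + growth_A - kin.b_A * X4)
    f5 = (D * (inf.X5_in - X5) + plant.kLa * (plant.X5_max - X5)
          - (1.0 - stoich.Y_H) / stoich.Y_H * mu1 * mu3 * kin.mu_max_H * X3
          - (4.57 - stoich.Y_A) / stoich.Y_A * growth_A)
    return np.array([f1, f2, f3, f4, f5])


def step(state: Sequence[float], influent: InfluentRecord, kin: KineticParams,
         stoich: StoichParams, plant: PlantConfig) -> np.ndarray:
    """Advance the plant one sampling period with the explicit Euler map.

    Negative intermediate values are clipped to zero (count logged at DEBUG);
    dissolved oxygen is capped at the saturation ``X5_max``.  Non-finite
    results raise, naming the failing balance equation.
    """
    arr = _check_state(state)
    inf = InfluentRecord(*influent)
    if inf.D_t < 0:
        raise ValueError("influent dilution rate D_t must be >= 0")
    rhs = _rhs(arr, inf, kin, stoich, plant)
    nxt = arr + plant.Ts * rhs
    for i, value in enumerate(nxt):
        if not np.isfinite(value):
            raise FloatingPointError(
                f"non-finite update in balance equation for {STATE_COLUMNS[i]}")
    bound = 10.0 * max(inf.X1_in, inf.X2_in, inf.X3_in, inf.X4_in, inf.X5_in,
                       plant.X5_max, 1.0)
    if np.any(nxt > bound):
        warnings.warn("state left the stability envelope in one step; "
                      "Ts may be too large", RuntimeWarning, stacklevel=2)
    n_clipped = int(np.sum(nxt < 0.0))
    if n_clipped:
        logger.debug("clipped %d negative state value(s) to zero", n_clipped)
        nxt = np.maximum(nxt, 0.0)
    if nxt[4] > plant.X5_max:
        nxt[4] = plant.X5_max
    return nxt


def tcod(X1, X2, Is):
    """Total chemical oxygen demand of the effluent: ``X1 + X2 + Is`` (mg COD/L)."""
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    Is = np.asarray(Is, dtype=float)
    if np.any(X1 < 0) or np.any(X2 < 0) or np.any(Is < 0):
        raise ValueError("tcod inputs must be non-negative")
    out = X1 + X2 + Is
    return float(out) if out.ndim == 0 else out


def effluent_compliance(tcod_series, cod_max: float):
    """Fraction of steps with TCOD at or below the effluent limit.

    Returns ``(fraction, flags)`` where ``flags[i]`` marks compliance of
    step ``i``.
    """
    series = np.asarray(tcod_series, dtype=float)
    if series.size == 0:
        raise ValueError("effluent_compliance requires a non-empty series")
    flags = series <= cod_max
    return float(np.mean(flags)), flags


def _influent_frame(influent_series) -> pd.DataFrame:
    if isinstance(influent_series, pd.DataFrame):
        missing = set(INFLUENT_COLUMNS) - set(influent_series.columns)
        if missing:
            raise ValueError(f"influent frame lacks column(s) {sorted(missing)}")
        return influent_series[INFLUENT_COLUMNS].reset_index(drop=True)
    return pd.DataFrame([InfluentRecord(*rec) for rec in influent_series],
                        columns=INFLUENT_COLUMNS)


def simulate(init: Sequence[float], influent_series, kin: KineticParams,
             stoich: StoichParams, plant: PlantConfig) -> pd.DataFrame:
    """Simulate the plant over an influent series.

    Parameters
    ----------
    init
        Initial state (5 components).
    influent_series
        One :class:`InfluentRecord` per step (sequence or DataFrame with the
        influent columns); its length sets the number of steps.

    Returns
    -------
    pandas.DataFrame
        ``n_steps + 1`` rows with columns ``time_h, X1..X5, X1_in..X5_in,
        D_t, Is, TCOD``; row ``k`` holds the state at time ``k * Ts`` and the
        influent applied during the step that follows (the final row repeats
        the last influent record).
    """
    inf_df = _influent_frame(influent_series)
    n_steps = len(inf_df)
    states = np.empty((n_steps + 1, 5))
    states[0] = _check_state(init)
    try:
        _euler_loop(states, inf_df.to_numpy(dtype=float), kin, stoich, plant)
    except (ValueError, FloatingPointError) as exc:
        raise RuntimeError(f"simulation failed: {exc}") from exc

    if n_steps:
        inf_out = pd.concat([inf_df, inf_df.iloc[[-1]]], ignore_index=True)
    else:
        inf_out = pd.DataFrame(
            [[np.nan] * 6 + [plant.Is]], columns=INFLUENT_COLUMNS)
    out = pd.DataFrame(states, columns=STATE_COLUMNS)
    out.insert(0, "time_h", np.arange(n_steps + 1) * plant.Ts)
    out = pd.concat([out, inf_out], axis=1)
    out["TCOD"] = tcod(out["X1"].to_numpy(), out["X2"].to_numpy(),
                       np.nan_to_num(out["Is"].to_numpy(), nan=plant.Is))
    return out


def _euler_loop(states: np.ndarray, inf: np.ndarray, kin: KineticParams,
                stoich: StoichParams, plant: PlantConfig) -> None:
    """Inlined scalar Euler recursion over ``states`` (filled in place).

    Semantics are identical to iterating :func:`step`; the inlining avoids
    per-step array allocation so that calibration sweeps stay cheap.  A test
    pins the two code paths together.
    """
    Ts = plant.Ts
    rb1 = plant.r_recycle - 1.0
    kLa, X5max = plant.kLa, plant.X5_max
    YH, YA, fp = stoich.Y_H, stoich.Y_A, stoich.f_p
    mu2 = kin.S_NH_const / (kin.K_NH + kin.S_NH_const)
    mu6 = kin.S_NO_const / (kin.K_NO + kin.S_NO_const)
    oxy_H = (1.0 - YH) / YH
    oxy_A = (4.57 - YA) / YA
    X1, X2, X3, X4, X5 = states[0]
    for k in range(len(inf)):
        X1i, X2i, X3i, X4i, X5i, D, _ = inf[k]
        mu1 = X1 / (kin.K_S + X1)
        mu3 = X5 / (kin.K_OH + X5)
        mu4 = kin.K_OH / (kin.K_OH + X5)
        mu5 = X5 / (kin.K_OA + X5)
        if X3 > 0.0:
            ratio = X2 / X3
            mu7 = (ratio / (kin.K_X + ratio)
                   if ratio < 1e300 else 1.0)
        else:
            mu7 = 1.0 if X2 > 0.0 else 0.0
        growth_H = mu1 * kin.mu_max_H * (mu3 + mu4 * mu6 * kin.eta_g) * X3
        hydrolysis = mu7 * kin.k_h * (mu3 + mu4 * mu6 * kin.eta_h) * X3
        growth_A = mu2 * mu5 * kin.mu_max_A * X4
        decay_supply = (1.0 - fp) * (kin.b_H * X3 + kin.b_A * X4)
        aerobic_growth = mu1 * mu3 * kin.mu_max_H * X3
        anoxic_growth = mu1 * mu4 * mu6 * kin.mu_max_H * kin.eta_g * X3

        X1 = X1 + Ts * (D * (X1i - X1) - growth_H / YH + hydrolysis)
        X2 = X2 + Ts * (D * (X2i - X2) + D * rb1 * X2
                        + decay_supply - hydrolysis)
        X3 = X3 + Ts * (D * (X3i - X3) + D * rb1 * X3
                        + aerobic_growth + anoxic_growth - kin.b_H * X3)
        X4 = X4 + Ts * (D * (X4i - X4) + D * rb1 * X4
                        + growth_A - kin.b_A * X4)
        X5 = X5 + Ts * (D * (X5i - X5) + kLa * (X5max - X5)
                        - oxy_H * aerobic_growth - oxy_A * growth_A)
        if X1 < 0.0: X1 = 0.0
        if X2 < 0.0: X2 = 0.0
        if X3 < 0.0: X3 = 0.0
        if X4 < 0.0: X4 = 0.0
        if X5 < 0.0: X5 = 0.0
        if X5 > X5max: X5 = X5max
        if not (np.isfinite(X1) and np.isfinite(X2) and np.isfinite(X3)
                and np.isfinite(X4) and np.isfinite(X5)):
            raise FloatingPointError(f"non-finite state at step {k}")
        states[k + 1] = (X1, X2, X3, X4, X5)


def steady_state(influent: InfluentRecord, kin: KineticParams,
                 stoich: StoichParams, plant: PlantConfig,
                 init: Sequence[float] | None = None,
                 tol: float = 1e-9, max_iter: int = 2_000_000) -> np.ndarray:
    """Fixed point of the one-step map under constant influent.

    Iterates :func:`step` until the max-abs state change over one step drops
    below ``tol``.  Raises on divergence or non-convergence.
    """
    inf = InfluentRecord(*influent)
    x = _check_state(init) if init is not None else np.array(
        [inf.X1_in, inf.X2_in, max(inf.X3_in, 1.0), max(inf.X4_in, 0.1),
         min(inf.X5_in, plant.X5_max)])
    chunk = 10_000
    inf_arr = np.tile(np.asarray(inf, dtype=float), (chunk, 1))
    states = np.empty((chunk + 1, 5))
    done = 0
    while done < max_iter:
        n = min(chunk, max_iter - done)
        states[0] = x
        _euler_loop(states[: n + 1], inf_arr[:n], kin, stoich, plant)
        if np.linalg.norm(states[n]) > 1e9:
            raise RuntimeError("steady_state diverged (state norm > 1e9)")
        deltas = np.max(np.abs(np.diff(states[: n + 1], axis=0)), axis=1)
        hits = np.nonzero(deltas < tol)[0]
        if hits.size:
            return states[hits[0] + 1].copy()
        x = states[n].copy()
        done += n
    raise RuntimeError(f"steady_state did not converge in {max_iter} iterations")


def write_trajectory(traj: pd.DataFrame, path) -> None:
    """Write a trajectory to CSV with the canonical column order."""
    traj[TRAJECTORY_COLUMNS].to_csv(path, index=False)


def read_trajectory(path) -> pd.DataFrame:
    """Read a trajectory CSV written by :func:`write_trajectory`."""
    df = pd.read_csv(path)
    missing = set(TRAJECTORY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"trajectory file lacks column(s) {sorted(missing)}")
    return df
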