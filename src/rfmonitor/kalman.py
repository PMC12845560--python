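"""Partially constrained nearly-constant-velocity Kalman filter.

State X = (x, y, vx, vy) in cm and cm/s, with white-acceleration process
noise of intensity q_proc (cm^2/s^3) and position-only measurements with
isotropic noise sigma_meas (inflated by alpha_R for interpolated samples).
After each unconstrained update, the segment joining the previous and
current posterior positions is tested against the wall set; a crossing
produces a linear equality constraint C X = d on the violating position
component(s), with the target placed a small safety offset inside the
feasible side.  The constraint is enforced through a modified gain derived
by Lagrange multipliers,

    K~ = K - D' (D D')^-1 D (X^ - X~) (V' S^-1 V)^-1 V' S^-1,   D = I4,

whose posterior X- + K~ V equals the constrained target state X~ exactly;
the associated covariance is propagated in Joseph-like form so it remains
symmetric positive semidefinite.  Constraints are applied event-wise: when
no wall is crossed the standard update is kept unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import KfConfig
from .floorplan import FloorPlan, Wall, feasible_target, first_wall_crossing

logger = logging.getLogger(__name__)

MAX_CONSTRAINT_PASSES = 3  # re-test after a constraint for rare multi-wall hits


@dataclass
class KfState:
    X: np.ndarray  # (4,) state vector
    P: np.ndarray  # (4, 4) covariance

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float).reshape(4)
        self.P = np.asarray(self.P, dtype=float).reshape(4, 4)

    @property
    def position(self) -> tuple[float, float]:
        return (float(self.X[0]), float(self.X[1]))


@dataclass
class ConstraintSpec:
    """Linear equality constraint C X = d on position components."""

    C: np.ndarray  # (m, 4), m in {1, 2}; rows are unit position selectors
    d: np.ndarray  # (m,)

    def __post_init__(self) -> None:
        self.C = np.atleast_2d(np.asarray(self.C, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))


@dataclass
class FilterResult:
    states: pd.DataFrame          # t, x, y, vx, vy, constrained
    covariances: np.ndarray       # (n, 4, 4) posterior covariances
    n_constrained: int = 0


def make_model(config: KfConfig, interpolated: bool = False,
               ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """State-space matrices (A, Q, H, R) of the NCV model.

    For interpolated samples R is inflated by alpha_R (variance x4 by
    default, i.e. doubled standard deviation).
    """
    Ts = config.Ts
    A = np.array([[1, 0, Ts, 0],
                  [0, 1, 0, Ts],
                  [0, 0, 1, 0],
                  [0, 0, 0, 1]], dtype=float)
    t3, t2 = Ts ** 3 / 3.0, Ts ** 2 / 2.0
    Q = config.q_proc * np.array([[t3, 0, t2, 0],
                                  [0, t3, 0, t2],
                                  [t2, 0, Ts, 0],
                                  [0, t2, 0, Ts]], dtype=float)
    H = np.array([[1, 0, 0, 0],
                  [0, 1, 0, 0]], dtype=float)
    R = config.sigma_meas ** 2 * np.eye(2)
    if interpolated:
        R = config.alpha_R * R
    return A, Q, H, R


def predict(state: KfState, A: np.ndarray, Q: np.ndarray) -> KfState:
    """Time update: X- = A X, P- = A P A' + Q."""
    return KfState(A @ state.X, A @ state.P @ A.T + Q)


def update_unconstrained(pred: KfState, z: np.ndarray, H: np.ndarray,
                         R_k: np.ndarray,
                         ) -> tuple[KfState, np.ndarray, np.ndarray, np.ndarray]:
    """Standard measurement update; returns (posterior, K, V, S)."""
    z = np.asarray(z, dtype=float).reshape(2)
    V = z - H @ pred.X
    S = H @ pred.P @ H.T + R_k
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            f"singular innovation covariance S={S!r} "
            f"(P-={pred.P!r}, R={R_k!r})") from exc
    K = pred.P @ H.T @ S_inv
    X = pred.X + K @ V
    P = (np.eye(4) - K @ H) @ pred.P
    return KfState(X, P), K, V, S


def constrain_if_crossing(prev_state: KfState, unconstrained_state: KfState,
                          plan: FloorPlan, config: KfConfig,
                          ) -> Optional[ConstraintSpec]:
    """Build the equality constraint for a posterior-to-posterior wall
    crossing, or None when the motion stays feasible."""
    p_prev = prev_state.position
    p_new = unconstrained_state.position
    walls = first_wall_crossing(p_prev, p_new, plan)
    if not walls:
        return None
    rows, targets = [], []
    for wall in walls[:2]:
        tgt = feasible_target(p_prev, p_new, wall, config.safety_offset)
        if wall.orientation == "vertical":
            rows.append([1.0, 0.0, 0.0, 0.0])
            targets.append(tgt[0])
        else:
            rows.append([0.0, 1.0, 0.0, 0.0])
            targets.append(tgt[1])
    return ConstraintSpec(np.array(rows), np.array(targets))


def constrained_update(pred: KfState, K: np.ndarray, V: np.ndarray,
                       S: np.ndarray, R_k: np.ndarray,
                       constraint: ConstraintSpec, unconstrained: KfState,
                       config: KfConfig) -> KfState:
    """Partially constrained update via the modified gain.

    The target state X~ is the unconstrained posterior with the
    constrained position components replaced by the feasible targets
    (velocities untouched), so C X~ = d by construction.  With D = I4 the
    modified-gain posterior equals X~; when the innovation is numerically
    null (V' S^-1 V below the gate) the gain correction is singular and
    the state is set to X~ directly with the covariance propagated with
    the unmodified gain.
    """
    X_tilde = unconstrained.X.copy()
    for row, target in zip(constraint.C, constraint.d):
        idx = int(np.argmax(np.abs(row)))
        X_tilde[idx] = target
    S_inv = np.linalg.inv(S)
    gate = float(V @ S_inv @ V)
    if gate <= config.epsilon_gate:
        logger.info("null innovation with active constraint: direct "
                    "substitution fallback")
        K_mod = K
        X_new = X_tilde
    else:
        # D = I4: D'(DD')^-1 D is the identity
        correction = np.outer(unconstrained.X - X_tilde, V @ S_inv) / gate
        if np.max(np.abs(correction)) > config.gain_correction_cap:
            # a sustained constraint conflict: the modified-gain covariance
            # recursion is divergent there, so keep the nominal gain for
            # the covariance and substitute the state directly
            K_mod = K
            X_new = X_tilde
        else:
            K_mod = K - correction
            X_new = pred.X + K_mod @ V
    H = np.array([[1, 0, 0, 0], [0, 1, 0, 0]], dtype=float)
    PHt = pred.P @ H.T
    P_new = (pred.P - PHt @ K_mod.T - K_mod @ PHt.T
             + K_mod @ (H @ PHt) @ K_mod.T + K_mod @ R_k @ K_mod.T)
    P_new = 0.5 * (P_new + P_new.T)  # numerical symmetry hygiene
    return KfState(X_new, P_new)


def filter_track(track: pd.DataFrame, plan: Optional[FloorPlan],
                 config: KfConfig, gap_split: float = 60.0) -> FilterResult:
    """Run the partially constrained NCV filter over a preprocessed track.

    The track is split into continuous segments at gaps >= ``gap_split``
    seconds; each segment initializes from its first position with zero
    velocity.  A missing plan (or a plan without walls) reduces to the
    plain unconstrained NCV filter.
    """
    if track.empty:
        return FilterResult(pd.DataFrame(
            columns=["t", "x", "y", "vx", "vy", "constrained"]),
            np.zeros((0, 4, 4)))
    t = track["t"].to_numpy(dtype=float)
    xy = track[["x", "y"]].to_numpy(dtype=float)
    cov_scale = track["cov_scale"].to_numpy(dtype=float)
    splits = np.flatnonzero(np.diff(t) >= gap_split) + 1
    segments = np.split(np.arange(len(t)), splits)

    A, Q, H, R0 = make_model(config)
    rows, covs = [], []
    n_constrained = 0
    for seg in segments:
        if seg.size == 0:
            logger.info("empty segment skipped")
            continue
        i0 = seg[0]
        state = KfState(
            np.array([xy[i0, 0], xy[i0, 1], 0.0, 0.0]),
            np.diag([config.init_pos_sigma ** 2, config.init_pos_sigma ** 2,
                     config.init_vel_sigma ** 2, config.init_vel_sigma ** 2]))
        rows.append((t[i0], *state.X, False))
        covs.append(state.P)
        prev = state
        for i in seg[1:]:
            dt = t[i] - t[i - 1]
            if dt != config.Ts:
                step_cfg = config.model_copy(update={"Ts": float(dt)})
                A_k, Q_k, _, _ = make_model(step_cfg)
            else:
                A_k, Q_k = A, Q
            R_k = cov_scale[i] * R0
            pred = predict(prev, A_k, Q_k)
            post, K, V, S = update_unconstrained(pred, xy[i], H, R_k)
            constrained = False
            if plan is not None:
                # accumulate constraint rows over passes (rare multi-wall
                # geometries) and always re-apply the single modified-gain
                # update of the original unconstrained posterior
                unconstrained = post
                targets: dict[int, float] = {}
                for _ in range(MAX_CONSTRAINT_PASSES):
                    spec = constrain_if_crossing(prev, post, plan, config)
                    if spec is None:
                        break
                    for row, d_i in zip(spec.C, spec.d):
                        targets[int(np.argmax(np.abs(row)))] = float(d_i)
                    c_rows = [[1.0 * (j == ax) for j in range(4)]
                              for ax in sorted(targets)]
                    merged = ConstraintSpec(
                        np.array(c_rows),
                        np.array([targets[ax] for ax in sorted(targets)]))
                    post = constrained_update(pred, K, V, S, R_k, merged,
                                              unconstrained, config)
                    constrained = True
            if constrained:
                n_constrained += 1
            rows.append((t[i], *post.X, constrained))
            covs.append(post.P)
            prev = post
    df = pd.DataFrame(rows, columns=["t", "x", "y", "vx", "vy", "constrained"])
    return FilterResult(df, np.array(covs), n_constrained)


def write_trajectory_csv(path, result: FilterResult) -> None:
    out = pd.DataFrame({
        "timestamp": result.states["t"],
        "x_cm": result.states["x"], "y_cm": result.states["y"],
        "vx_cm_s": result.states["vx"], "vy_cm_s": result.states["vy"],
        "constrained_flag": result.states["constrained"].astype(int),
    })
    out.to_csv(path, index=False)
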