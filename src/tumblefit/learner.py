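"""Joint online training of the surrogate network and equation parameters.

The loop couples three angular-speed estimates:

* ``phi_dot_GT`` — the (processed) ground-truth speed from the stream;
* ``phi_dot_ML`` — the surrogate network's prediction;
* ``phi_dot_TH`` — the learned equation evaluated at the current
  parameters.

The two-term loss ``L = L1(GT, ML) + L2(ML, TH)`` (both mean squared
errors) is minimised with split gradient routing: L1 gradients flow to
the network weights only, L2 gradients to the equation parameters
(kappa0, lambda0, lambda1, phi0) only, with the network output treated as
a constant inside L2.  The network thus acts as a denoised, flexible
anchor between raw data and the mechanistic equation.  ``L3(GT, TH)``
evaluates the learned equation against freshly arriving data and never
produces gradients.

Training happens once every ``stride`` units of dimensionless time on a
batch drawn by the staircase sampling policy, for ``epochs`` full-batch
Adam steps per process, under a per-process exponentially decaying
learning rate with a floor.  A termination signal is raised once the mean
and standard deviation of recent total losses fall below thresholds —
the cue that the expensive simulator feeding the stream may stop.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .dynamics import (
    EquationParams,
    OblateGeometry,
    PLATELET,
    ljoe_param_gradients,
    ljoe_speed,
)
from .network import Adam, SurrogateNet
from .sampler import SamplingPolicy, TrainingBatch, draw_training_batch, training_times

logger = logging.getLogger(__name__)

__all__ = [
    "OptimizerConfig",
    "LossBreakdown",
    "TerminationConfig",
    "TerminationSignal",
    "LearnerState",
    "encode_angle",
    "biol_loss",
    "learning_rate",
    "train_process",
    "check_termination",
    "run_online_loop",
    "BIOLRegressor",
]

_PHASE_BOUND = np.pi / 2.0


@dataclass(frozen=True)
class OptimizerConfig:
    """Training-schedule settings: per-process decaying Adam learning rate
    and the epoch counts for rigid (er) and deformable (ed) bodies."""

    initial_rate: float = 0.002
    decay: float = 0.95
    floor: float = 0.0005
    epochs_rigid: int = 200
    epochs_deformable: int = 300

    def epochs(self, body_type: str) -> int:
        return self.epochs_deformable if body_type == "deformable" \
            else self.epochs_rigid


@dataclass(frozen=True)
class LossBreakdown:
    """Per-process losses: l1 = MSE(GT, ML), l2 = MSE(ML, TH),
    total = l1 + l2, and the evaluation loss l3 = MSE(GT, TH)."""

    l1: float
    l2: float
    l3: float = float("nan")

    @property
    def total(self) -> float:
        return self.l1 + self.l2


@dataclass(frozen=True)
class TerminationConfig:
    lookback: int = 10
    mean_threshold: float = 1e-3
    sd_threshold: float = 1e-3


@dataclass(frozen=True)
class TerminationSignal:
    triggered: bool
    mean: float = float("nan")
    sd: float = float("nan")


@dataclass
class LearnerState:
    """Mutable learner state carried across training processes."""

    net: SurrogateNet
    params: EquationParams
    u_phase: float = 0.0  # unconstrained reparameterisation of phi0
    step_count: int = 0
    loss_history: list = field(default_factory=list)
    parameter_trajectory: list = field(default_factory=list)
    net_optimizer: Adam | None = None
    param_optimizer: Adam | None = None

    def __post_init__(self):
        if self.net_optimizer is None:
            shapes = [w.shape for w in self.net.weights] + \
                     [b.shape for b in self.net.biases]
            self.net_optimizer = Adam(shapes)
        if self.param_optimizer is None:
            self.param_optimizer = Adam([(4,)])

    # -- checkpointing ------------------------------------------------------
    def to_checkpoint(self) -> str:
        doc = {
            "net": self.net.to_dict(),
            "params": {
                "kappa0": self.params.kappa0,
                "lambda0": self.params.lambda0,
                "lambda1": self.params.lambda1,
                "phase_offset": self.params.phase_offset,
            },
            "u_phase": self.u_phase,
            "step_count": self.step_count,
            "net_optimizer": self.net_optimizer.to_dict(),
            "param_optimizer": self.param_optimizer.to_dict(),
        }
        return json.dumps(doc)

    @classmethod
    def from_checkpoint(cls, text: str) -> "LearnerState":
        doc = json.loads(text)
        return cls(
            net=SurrogateNet.from_dict(doc["net"]),
            params=EquationParams(**doc["params"]),
            u_phase=doc["u_phase"],
            step_count=doc["step_count"],
            net_optimizer=Adam.from_dict(doc["net_optimizer"]),
            param_optimizer=Adam.from_dict(doc["param_optimizer"]),
        )

    def save(self, path):
        Path(path).write_text(self.to_checkpoint())

    @classmethod
    def load(cls, path) -> "LearnerState":
        return cls.from_checkpoint(Path(path).read_text())


def encode_angle(phi) -> np.ndarray:
    """Network input encoding (cos 2phi, sin 2phi): respects the
    pi-periodicity of the tumbling observable and matches the harmonics of
    the learned equation, with no branch discontinuities."""
    phi = np.asarray(phi, dtype=float)
    return np.column_stack([np.cos(2.0 * phi), np.sin(2.0 * phi)])


def biol_loss(phi_dot_gt, phi_dot_ml, phi_dot_th) -> LossBreakdown:
    """The two training terms plus the evaluation term, all MSE."""
    gt = np.asarray(phi_dot_gt, dtype=float)
    ml = np.asarray(phi_dot_ml, dtype=float)
    th = np.asarray(phi_dot_th, dtype=float)
    if not (gt.shape == ml.shape == th.shape):
        raise ValueError(
            f"speed vectors must share a shape, got {gt.shape}, "
            f"{ml.shape}, {th.shape}"
        )
    return LossBreakdown(
        l1=float(np.mean((gt - ml) ** 2)),
        l2=float(np.mean((ml - th) ** 2)),
        l3=float(np.mean((gt - th) ** 2)),
    )


def learning_rate(process_index: int, config: OptimizerConfig) -> float:
    """max(initial * decay^k, floor) for training process k."""
    return max(config.initial_rate * config.decay ** process_index, config.floor)


def _phase_from_u(u: float) -> float:
    return _PHASE_BOUND * np.tanh(u)


def train_process(
    state: LearnerState,
    batch: TrainingBatch,
    geometry: OblateGeometry,
    config: OptimizerConfig,
    body_type: str = "rigid",
    process_index: int | None = None,
    learn_phase: bool = True,
    joint_update: bool = False,
) -> LearnerState:
    """Run one training process (er or ed full-batch Adam epochs).

    Gradient routing: L1 -> network weights, L2 -> equation parameters
    with the network output held constant.  ``joint_update`` additionally
    lets L2 gradients flow into the network (off by default).  On a
    non-finite loss the process is aborted and the previous state kept.
    """
    frame = pd.concat(batch.series_list, ignore_index=True)
    if len(frame) == 0:
        raise ValueError("empty training batch")
    phi = frame["phi_f"].to_numpy(dtype=float)
    gt = frame["phi_dot"].to_numpy(dtype=float)
    x = encode_angle(phi)
    n = len(gt)
    k = process_index if process_index is not None else len(state.loss_history)
    lr = learning_rate(k, config)
    epochs = config.epochs(body_type)

    snapshot = state.to_checkpoint()
    theta = np.array([
        state.params.kappa0, state.params.lambda0, state.params.lambda1,
        state.u_phase,
    ])
    final = None
    for _ in range(epochs):
        p = EquationParams(
            kappa0=theta[0], lambda0=theta[1], lambda1=theta[2],
            phase_offset=_phase_from_u(theta[3]),
        )
        ml = state.net.forward(x)
        th = ljoe_speed(phi, geometry, p)
        loss = biol_loss(gt, ml, th)
        if not np.isfinite(loss.total):
            logger.warning(
                "non-finite loss in process %d; aborting and keeping the "
                "previous state", k,
            )
            restored = LearnerState.from_checkpoint(snapshot)
            restored.loss_history = state.loss_history
            restored.parameter_trajectory = state.parameter_trajectory
            return restored
        # network update (L1; optionally + L2 in joint mode)
        d_out = 2.0 * (ml - gt) / n
        if joint_update:
            d_out = d_out + 2.0 * (ml - th) / n
        w_grads, b_grads = state.net.backward(x, d_out)
        nw = len(state.net.weights)
        flat = state.net.weights + state.net.biases
        state.net_optimizer.step(flat, w_grads + b_grads, lr)
        state.net.weights, state.net.biases = flat[:nw], flat[nw:]
        # equation-parameter update (L2, ML constant)
        dk, dl0, dl1, dphi0 = ljoe_param_gradients(phi, geometry, p)
        resid = 2.0 * (th - ml) / n
        g = np.array([
            float(resid @ dk),
            float(resid @ dl0),
            float(resid @ dl1),
            float(resid @ dphi0) * _PHASE_BOUND * (1.0 - np.tanh(theta[3]) ** 2)
            if learn_phase else 0.0,
        ])
        state.param_optimizer.step([theta], [g], lr)
        state.step_count += 1
        final = loss
    state.params = EquationParams(
        kappa0=theta[0], lambda0=theta[1], lambda1=theta[2],
        phase_offset=_phase_from_u(theta[3]),
    )
    state.u_phase = float(theta[3])
    state.loss_history.append(final)
    return state


def check_termination(
    state: LearnerState, config: TerminationConfig | None = None
) -> TerminationSignal:
    """Termination signal: triggered once >= lookback processes have run
    and the mean and standard deviation of their total losses fall below
    the thresholds."""
    config = config or TerminationConfig()
    if len(state.loss_history) < config.lookback:
        return TerminationSignal(triggered=False)
    recent = np.array(
        [b.total for b in state.loss_history[-config.lookback:]]
    )
    mean, sd = float(np.mean(recent)), float(np.std(recent))
    return TerminationSignal(
        triggered=mean < config.mean_threshold and sd < config.sd_threshold,
        mean=mean,
        sd=sd,
    )


def run_online_loop(
    processed: pd.DataFrame,
    policy: SamplingPolicy | None = None,
    geometry: OblateGeometry = PLATELET,
    optimizer: OptimizerConfig | None = None,
    termination: TerminationConfig | None = None,
    stride: float = 0.25,
    body_type: str = "rigid",
    seed: int = 0,
    learn_phase: bool = True,
    joint_update: bool = False,
    stop_on_termination: bool = False,
) -> tuple[LearnerState, pd.DataFrame]:
    """Consume a processed stream and learn the equation parameters online.

    At every training time tau (tau_0 = W, advancing by ``stride``) a
    stratified batch is drawn from [tau - W, tau], one training process
    runs, and l3 is evaluated on the freshly arriving samples in
    (tau, tau + stride] (falling back to the hot window at the stream
    end).  Reproducible under the single master ``seed``.  Returns the
    final state and the parameter trajectory table.
    """
    policy = policy or SamplingPolicy()
    optimizer = optimizer or OptimizerConfig()
    termination = termination or TerminationConfig()
    times = processed["gamma_t"].to_numpy(dtype=float)
    duration = float(times[-1]) if len(times) else 0.0
    taus = training_times(duration, policy, stride)
    # edge-trimmed streams (e.g. after the moving average) may start after
    # t=0; skip training times whose window is not fully covered yet
    if len(times):
        taus = taus[taus - policy.window >= times[0]]
    master = np.random.default_rng(seed)
    net = SurrogateNet(seed=int(master.integers(2**31)))
    state = LearnerState(net=net, params=EquationParams())
    rows = []
    if len(taus) == 0:
        warnings.warn(
            f"stream duration {duration} shorter than the window "
            f"{policy.window}; no training performed"
        )
        return state, pd.DataFrame(rows)
    for k, tau in enumerate(taus):
        batch = draw_training_batch(processed, tau, policy, rng=master)
        state = train_process(
            state, batch, geometry, optimizer,
            body_type=body_type, process_index=k,
            learn_phase=learn_phase, joint_update=joint_update,
        )
        # evaluate on freshly arriving data, never on the training window
        fresh = processed[(times > tau) & (times <= tau + stride)]
        if len(fresh) == 0:
            fresh = processed[(times >= tau - policy.hot_width) & (times <= tau)]
        th = ljoe_speed(
            fresh["phi_f"].to_numpy(dtype=float), geometry, state.params
        )
        l3 = float(np.mean((fresh["phi_dot"].to_numpy(dtype=float) - th) ** 2))
        last = state.loss_history[-1]
        state.loss_history[-1] = LossBreakdown(l1=last.l1, l2=last.l2, l3=l3)
        state.parameter_trajectory.append(state.params)
        signal = check_termination(state, termination)
        rows.append({
            "process_index": k,
            "tau": float(tau),
            "kappa0": state.params.kappa0,
            "lambda0": state.params.lambda0,
            "lambda1": state.params.lambda1,
            "phi0": state.params.phase_offset,
            "l1": last.l1,
            "l2": last.l2,
            "l3": l3,
            "terminated": signal.triggered,
        })
        logger.info(
            "process %d at tau=%.2f: l1=%.3e l2=%.3e l3=%.3e params=(%.3f, "
            "%.3f, %.3f, %.3f) zeta=%s",
            k, tau, last.l1, last.l2, l3, state.params.kappa0,
            state.params.lambda0, state.params.lambda1,
            state.params.phase_offset, signal.triggered,
        )
        if signal.triggered and stop_on_termination:
            break
    return state, pd.DataFrame(rows)


class BIOLRegressor(RegressorMixin, BaseEstimator):
    """Online joint learner of a surrogate network and the corrected
    Jeffery-orbit equation parameters, with a scikit-learn interface.

    ``fit`` consumes a processed stream (an ``(n, 3)`` array of columns
    ``gamma_t, phi_f, phi_dot`` or a DataFrame with those columns) and
    runs the online training loop; ``predict`` evaluates the learned
    equation's angular speed at given rotation angles.

    Parameters mirror the online-loop defaults: an 8-unit trailing window
    with stratified staircase sampling (40 series of 10 samples, counts
    12/10/9/9), training every 0.25 units, 200 (rigid) or 300
    (deformable) Adam epochs per process at a decaying learning rate
    (0.002, decay 0.95, floor 0.0005).

    Attributes
    ----------
    params_ : EquationParams
        Learned equation parameters.
    state_ : LearnerState
        Full final learner state (network, optimisers, loss history).
    trajectory_ : pandas.DataFrame
        Per-process parameter/loss trajectory.
    terminated_ : bool
        Whether the loss-stability termination signal fired.
    """

    def __init__(
        self,
        window: float = 8.0,
        hot_width: float = 1.0,
        stride: float = 0.25,
        n_series: int = 40,
        series_length: int = 10,
        region_counts: tuple = (12, 10, 9, 9),
        region_bounds: tuple = (1.0, 2.0, 5.0, 8.0),
        epochs_rigid: int = 200,
        epochs_deformable: int = 300,
        learning_rate: float = 0.002,
        decay: float = 0.95,
        lr_floor: float = 0.0005,
        body_type: str = "rigid",
        aspect_ratio: float = 4.0,
        learn_phase: bool = True,
        joint_update: bool = False,
        lookback: int = 10,
        mean_threshold: float = 1e-3,
        sd_threshold: float = 1e-3,
        stop_on_termination: bool = False,
        random_state: int = 0,
    ):
        self.window = window
        self.hot_width = hot_width
        self.stride = stride
        self.n_series = n_series
        self.series_length = series_length
        self.region_counts = region_counts
        self.region_bounds = region_bounds
        self.epochs_rigid = epochs_rigid
        self.epochs_deformable = epochs_deformable
        self.learning_rate = learning_rate
        self.decay = decay
        self.lr_floor = lr_floor
        self.body_type = body_type
        self.aspect_ratio = aspect_ratio
        self.learn_phase = learn_phase
        self.joint_update = joint_update
        self.lookback = lookback
        self.mean_threshold = mean_threshold
        self.sd_threshold = sd_threshold
        self.stop_on_termination = stop_on_termination
        self.random_state = random_state

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            missing = {"gamma_t", "phi_f", "phi_dot"} - set(X.columns)
            if missing:
                raise ValueError(f"stream is missing columns {sorted(missing)}")
            return X
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError(
                "expected an (n, 3) array of (gamma_t, phi_f, phi_dot) rows"
            )
        return pd.DataFrame(X, columns=["gamma_t", "phi_f", "phi_dot"])

    def fit(self, X, y=None):
        frame = self._as_frame(X)
        policy = SamplingPolicy(
            window=self.window,
            hot_width=self.hot_width,
            region_bounds=tuple(self.region_bounds),
            region_counts=tuple(self.region_counts),
            n_series=self.n_series,
            series_length=self.series_length,
        )
        optimizer = OptimizerConfig(
            initial_rate=self.learning_rate,
            decay=self.decay,
            floor=self.lr_floor,
            epochs_rigid=self.epochs_rigid,
            epochs_deformable=self.epochs_deformable,
        )
        termination = TerminationConfig(
            lookback=self.lookback,
            mean_threshold=self.mean_threshold,
            sd_threshold=self.sd_threshold,
        )
        geometry = OblateGeometry.from_aspect_ratio(self.aspect_ratio)
        state, trajectory = run_online_loop(
            frame,
            policy=policy,
            geometry=geometry,
            optimizer=optimizer,
            termination=termination,
            stride=self.stride,
            body_type=self.body_type,
            seed=self.random_state,
            learn_phase=self.learn_phase,
            joint_update=self.joint_update,
            stop_on_termination=self.stop_on_termination,
        )
        self.state_ = state
        self.params_ = state.params
        self.trajectory_ = trajectory
        self.terminated_ = bool(trajectory["terminated"].iloc[-1]) \
            if len(trajectory) else False
        self.n_features_in_ = 3
        return self

    def predict(self, X):
        """Learned-equation angular speed at angles X (radians)."""
        if not hasattr(self, "params_"):
            raise RuntimeError("fit the estimator before predicting")
        phi = np.asarray(X, dtype=float).ravel()
        geometry = OblateGeometry.from_aspect_ratio(self.aspect_ratio)
        return np.asarray(ljoe_speed(phi, geometry, self.params_))
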