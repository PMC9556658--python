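"""Synthetic cohorts for the two-interval motion discrimination task.

Generates tidy per-trial behavioral tables and aligned single-trial neural
signals with the statistical structure the downstream analyses assume:

* counterbalanced stimulus sequences (each category followed equally often by
  the same or the other category),
* observers implemented as drift-diffusion agents whose drift bias carries a
  lag-resolved imprint of their own previous choices (repeaters: positive
  kernel; alternators: negative) and whose starting point is nudged by the
  previous motor action,
* scalar band-power "modulation" values per region/band/window carrying a
  previous-choice code in parietal gamma (repeaters only), an
  error-conditional previous-choice code in parietal alpha superimposed on a
  global error-related alpha suppression, and a previous-action code in motor
  beta lateralization whose raw sign depends on each observer's
  choice-to-hand mapping.

Defaults mirror the study conditions: 60 observers, 2 sessions of 600 trials
in blocks of 100, a 3 s response deadline, and a roughly 70%-correct
individual coherence threshold.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numba import njit

from .ddm.bounds import CollapsingBound
from .ddm.simulate import _sim_one

__all__ = [
    "AgentParams",
    "NeuralGenParams",
    "generate_stimulus_sequence",
    "simulate_agent",
    "generate_neural_signals",
    "generate_cohort",
    "simulate_mediation_data",
    "write_cohort",
]

DEADLINE = 3.0

SIGNAL_COLUMNS = [
    "gamma_ips23_ref", "gamma_ips23_test",
    "alpha_ips01_test", "alpha_global_test",
    "beta_motor_ref", "beta_motor_test",
]


@dataclass(frozen=True)
class AgentParams:
    """Generative parameters of one simulated observer.

    ``choice_drift_kernel`` maps the previous K choices onto additive drift
    bias (positive = repetition); ``action_start_weight`` maps the previous
    action (signed with respect to the "stronger"-reporting hand, which under
    a fixed hand map equals the previous choice) onto the starting point on
    the logit scale (negative = alternation).
    """

    v0: float = 0.0
    v_s: float = 0.6
    z0: float = 0.5
    t0: float = 0.3
    bound: CollapsingBound = field(
        default_factory=lambda: CollapsingBound(a=1.8, form="weibull",
                                                shape=3.0, scale=1.5))
    choice_drift_kernel: tuple = (0.0,) * 7
    action_start_weight: float = 0.0
    lapse_rate: float = 0.02
    subgroup: str = "neutral"
    coherence_delta: float = 6.9  # % coherence difference at threshold
    stronger_hand: str = "right"  # hand reporting "stronger"

    def __post_init__(self):
        vals = (self.v0, self.v_s, self.z0, self.t0,
                *self.choice_drift_kernel, self.action_start_weight,
                self.lapse_rate)
        if not np.all(np.isfinite(vals)):
            raise ValueError("non-finite agent parameter")
        if not 0 <= self.lapse_rate < 0.5:
            raise ValueError("lapse rate must lie in [0, 0.5)")
        if self.stronger_hand not in ("left", "right"):
            raise ValueError("stronger_hand must be 'left' or 'right'")


@dataclass(frozen=True)
class NeuralGenParams:
    """Effect sizes (power-modulation units) and noise of the neural generator."""

    gamma_prev_choice: float = 0.8     # scaled per subject by subgroup
    alpha_prev_choice_error: float = 0.6
    beta_prev_action: float = 0.8
    stim_gamma: float = 1.0
    stim_alpha: float = -0.8
    global_error_amp: float = 1.0      # alpha suppression after errors
    global_alpha_loading: float = 1.0  # loading of the global component on IPS0/1
    noise_sd: float = 15.0
    subject_intercept_sd: float = 3.0

    def __post_init__(self):
        if self.noise_sd <= 0 or self.subject_intercept_sd < 0:
            raise ValueError("noise SDs must be positive")


def generate_stimulus_sequence(n_trials: int, seed=None) -> np.ndarray:
    """Counterbalanced signed stimulus categories (-1 weaker, +1 stronger).

    Each category is followed by the same or the other category equally
    often: of the ``n_trials - 1`` transitions, repeats and switches differ
    in count by at most one (the odd transition, if any, is a switch so both
    categories always occur).
    """
    if n_trials < 2:
        raise ValueError("need at least 2 trials to counterbalance transitions")
    rng = np.random.default_rng(seed)
    n_trans = n_trials - 1
    n_switch = (n_trans + 1) // 2
    labels = np.concatenate([np.ones(n_switch, dtype=np.int64),
                             np.zeros(n_trans - n_switch, dtype=np.int64)])
    rng.shuffle(labels)
    seq = np.empty(n_trials, dtype=np.int64)
    seq[0] = rng.choice([-1, 1])
    for i, sw in enumerate(labels):
        seq[i + 1] = -seq[i] if sw else seq[i]
    return seq


@njit(cache=True)
def _agent_kernel(stim, v0, v_s, z0_logit, zw_action, t0, form, a, p1, p2,
                  kernel, lapse, dt, deadline, seed):
    np.random.seed(seed)
    n = stim.shape[0]
    K = kernel.shape[0]
    choices = np.zeros(n)
    rts = np.zeros(n)
    for t in range(n):
        vb = 0.0
        for k in range(K):
            if t - 1 - k >= 0:
                vb += kernel[k] * choices[t - 1 - k]
        zlin = z0_logit
        if t >= 1:
            zlin += zw_action * choices[t - 1]
        z = 1.0 / (1.0 + np.exp(-zlin))
        if z < 0.02:
            z = 0.02
        if z > 0.98:
            z = 0.98
        v = v0 + v_s * stim[t] + vb
        if np.random.random() < lapse:
            choices[t] = 1.0 if np.random.random() < 0.5 else -1.0
            rts[t] = t0 + np.random.random() * (deadline - t0)
            continue
        ch, fpt = _sim_one(v, z, form, a, p1, p2, dt, deadline - t0, 0)
        tries = 0
        while ch == 0 and tries < 100:
            ch, fpt = _sim_one(v, z, form, a, p1, p2, dt, deadline - t0, 0)
            tries += 1
        if ch == 0:
            ch = 1 if z >= 0.5 else -1
            fpt = deadline - t0
        choices[t] = float(ch)
        rts[t] = fpt + t0
    return choices, rts


def simulate_agent(stimuli, params: AgentParams, seed=None,
                   block_size: int | None = None, subject_id: int = 1,
                   session: int = 1, dt: float = 1e-3) -> pd.DataFrame:
    """Simulate one observer on a stimulus sequence.

    Choices and RTs come from the collapsing-bound diffusion simulator with
    trialwise drift bias from the choice-history kernel and starting point
    from the previous action; history resets at block boundaries (observers
    pause between blocks). Trials that would miss the 3 s deadline are
    regenerated.
    """
    stimuli = np.asarray(stimuli, dtype=float)
    if stimuli.size == 0:
        raise ValueError("empty stimulus sequence")
    if block_size is None:
        block_size = stimuli.size
    form, a, p1, p2 = params.bound.as_tuple()
    z0_logit = float(np.log(params.z0 / (1 - params.z0)))
    kernel = np.asarray(params.choice_drift_kernel, dtype=float)
    rng = np.random.default_rng(seed)
    frames = []
    n_blocks = int(np.ceil(stimuli.size / block_size))
    for b in range(n_blocks):
        blk = stimuli[b * block_size:(b + 1) * block_size]
        sub_seed = int(rng.integers(0, 2 ** 31 - 1))
        choices, rts = _agent_kernel(
            blk, params.v0, params.v_s, z0_logit, params.action_start_weight,
            params.t0, form, a, p1, p2, kernel, params.lapse_rate, dt,
            DEADLINE, sub_seed)
        frames.append(pd.DataFrame({
            "subject_id": subject_id,
            "session": session,
            "block": b + 1,
            "trial": np.arange(1, blk.size + 1),
            "stimulus": blk.astype(int),
            "coherence_delta": blk * params.coherence_delta,
            "choice": choices.astype(int),
            "rt": rts,
        }))
    out = pd.concat(frames, ignore_index=True)
    other = "left" if params.stronger_hand == "right" else "right"
    out["action"] = np.where(out["choice"] > 0, params.stronger_hand, other)
    out["outcome"] = np.where(out["choice"] == out["stimulus"],
                              "correct", "error")
    out["choice_hand_map"] = params.stronger_hand
    return out


def _prev_within_block(df: pd.DataFrame, col: str) -> np.ndarray:
    return df.groupby(["subject_id", "session", "block"])[col].shift(1).to_numpy()


def generate_neural_signals(trials: pd.DataFrame, params: NeuralGenParams,
                            seed=None, gamma_scale_by_subject=None) -> pd.DataFrame:
    """Trialwise band-power modulation values aligned 1:1 with ``trials``.

    Codes generated (everything plus Gaussian noise and a subject intercept):

    * ``gamma_ips23_*``: previous choice (scaled per subject, e.g. repeaters
      only) in both windows, plus current stimulus during test;
    * ``alpha_ips01_test``: previous choice conditional on a previous error,
      plus current stimulus, plus a loading on the global error component;
    * ``alpha_global_test``: spatially unspecific alpha suppression after
      error feedback;
    * ``beta_motor_*``: previous-action code, generated in the raw
      contra-minus-ipsi-of-right-hand convention so its sign flips with each
      observer's "stronger" hand; strong during reference, absent by test.
    """
    rng = np.random.default_rng(seed)
    n = len(trials)
    subjects = trials["subject_id"].to_numpy()
    uniq = np.unique(subjects)
    if gamma_scale_by_subject is None:
        gamma_scale_by_subject = {s: 1.0 for s in uniq}
    gscale = np.array([gamma_scale_by_subject.get(s, 1.0) for s in subjects])

    prev_choice = np.nan_to_num(_prev_within_block(trials, "choice"))
    prev_outcome = _prev_within_block(trials, "outcome")
    prev_error = (prev_outcome == "error").astype(float)
    stim = trials["stimulus"].to_numpy(dtype=float)
    # raw lateralization reference: contra-minus-ipsi of the right hand;
    # +1 when "stronger" maps to the right hand, else the code flips sign
    map_sign = np.where(trials["choice_hand_map"].to_numpy() == "right", 1.0, -1.0)

    intercepts = {s: rng.normal(0.0, params.subject_intercept_sd, len(SIGNAL_COLUMNS))
                  for s in uniq}
    icept = np.array([intercepts[s] for s in subjects])
    noise = rng.normal(0.0, params.noise_sd, (n, len(SIGNAL_COLUMNS)))

    global_component = -params.global_error_amp * prev_error

    sig = {}
    sig["gamma_ips23_ref"] = params.gamma_prev_choice * gscale * prev_choice
    sig["gamma_ips23_test"] = (params.gamma_prev_choice * gscale * prev_choice
                               + params.stim_gamma * stim)
    sig["alpha_ips01_test"] = (params.alpha_prev_choice_error * prev_choice * prev_error
                               + params.stim_alpha * stim
                               + params.global_alpha_loading * global_component)
    sig["alpha_global_test"] = global_component.copy()
    sig["beta_motor_ref"] = map_sign * params.beta_prev_action * prev_choice
    sig["beta_motor_test"] = np.zeros(n)

    out = pd.DataFrame({c: sig[c] + icept[:, j] + noise[:, j]
                        for j, c in enumerate(SIGNAL_COLUMNS)})
    out.index = trials.index
    return out


def _draw_agent(rng, subgroup: str) -> AgentParams:
    if subgroup == "repeater":
        w1 = max(0.03, rng.normal(0.28, 0.12))
    else:
        w1 = min(-0.03, rng.normal(-0.28, 0.12))
    decay = 0.6
    kernel = tuple(w1 * decay ** k for k in range(7))
    return AgentParams(
        v0=rng.normal(0.0, 0.05),
        v_s=max(0.3, rng.normal(0.6, 0.08)),
        z0=float(1 / (1 + np.exp(-rng.normal(0.0, 0.1)))),
        t0=float(np.clip(rng.normal(0.3, 0.03), 0.15, 0.5)),
        bound=CollapsingBound(a=float(np.clip(rng.normal(1.8, 0.15), 1.2, 2.6)),
                              form="weibull", shape=3.0, scale=1.5),
        choice_drift_kernel=kernel,
        action_start_weight=rng.normal(-0.08, 0.05),
        lapse_rate=0.02,
        subgroup=subgroup,
        coherence_delta=float(np.clip(np.exp(rng.normal(np.log(6.9), 0.3)),
                                      3.3, 13.4)),
        stronger_hand="right" if rng.random() < 0.5 else "left",
    )


def generate_cohort(n_subjects: int = 60, repeater_fraction: float = 34 / 60,
                    trials_per_session: int = 600, n_sessions: int = 2,
                    block_size: int = 100, seed=None,
                    neural_params: NeuralGenParams | None = None):
    """Simulate a full cohort: trial table, neural signals, agent parameters.

    Subgroup membership is Bernoulli(``repeater_fraction``) per subject;
    agent parameters are drawn around group means and shared across sessions,
    so individual repetition probabilities are stable across sessions by
    construction. Parietal gamma carries the previous-choice code in
    repeaters only.
    """
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    if not 0 <= repeater_fraction <= 1:
        raise ValueError("repeater_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if neural_params is None:
        neural_params = NeuralGenParams()
    agents = {}
    frames = []
    for s in range(1, n_subjects + 1):
        subgroup = "repeater" if rng.random() < repeater_fraction else "alternator"
        params = _draw_agent(rng, subgroup)
        agents[s] = params
        for sess in range(1, n_sessions + 1):
            # counterbalancing is applied within each block
            sizes = [min(block_size, trials_per_session - b * block_size)
                     for b in range(int(np.ceil(trials_per_session / block_size)))]
            stim = np.concatenate([
                generate_stimulus_sequence(sz, seed=int(rng.integers(2 ** 31 - 1)))
                for sz in sizes])
            frames.append(simulate_agent(
                stim, params, seed=int(rng.integers(2 ** 31 - 1)),
                block_size=block_size, subject_id=s, session=sess))
    trials = pd.concat(frames, ignore_index=True)
    gscale = {s: (1.0 if agents[s].subgroup == "repeater" else 0.0)
              for s in agents}
    signals = generate_neural_signals(trials, neural_params,
                                      seed=int(rng.integers(2 ** 31 - 1)),
                                      gamma_scale_by_subject=gscale)
    return trials, signals, agents


def simulate_mediation_data(n_trials: int, a_paths=(0.5, 0.0, 0.0),
                            b_paths=(0.5, 0.0, 0.0), c_prime: float = 0.0,
                            stim_paths=(0.0, 0.0), s0: float = 1.0,
                            seed=None):
    """Directly generate trials from the three-mediator system.

    Mediators are built with unit variance so ``a_paths`` are the
    standardized previous-choice -> mediator effects; ``b_paths`` and
    ``c_prime`` are standardized on the latent-response scale of the logistic
    choice model (residual variance pi^2 / 3). Returns a DataFrame with
    columns prev_choice, stimulus, m1..m3, choice.
    """
    rng = np.random.default_rng(seed)
    c_prev = rng.choice([-1.0, 1.0], n_trials)
    stim = rng.choice([-1.0, 1.0], n_trials)
    a = np.asarray(a_paths, dtype=float)
    sp = np.concatenate([np.asarray(stim_paths, dtype=float), [0.0]])
    med = np.empty((n_trials, 3))
    for k in range(3):
        expl = a[k] ** 2 + sp[k] ** 2
        noise_sd = np.sqrt(max(1.0 - expl, 0.05))
        med[:, k] = a[k] * c_prev + sp[k] * stim + rng.normal(0, noise_sd, n_trials)
    # latent-scale coefficients such that the requested values are the
    # standardized ones: beta_latent = beta_std * sd(y*) with
    # sd(y*)^2 = var(linear predictor) + pi^2/3, solved self-consistently
    b = np.asarray(b_paths, dtype=float)
    coefs_std = np.concatenate([b, [c_prime, s0]])
    X = np.column_stack([med, c_prev, stim])
    expl_var = float(np.sum(coefs_std ** 2))  # predictors ~ unit variance
    if expl_var >= 1.0:
        raise ValueError("standardized paths imply >= 100% explained variance")
    sd_latent = np.sqrt((np.pi ** 2 / 3) / (1.0 - expl_var))
    lin = X @ (coefs_std * sd_latent)
    p = 1.0 / (1.0 + np.exp(-lin))
    choice = np.where(rng.random(n_trials) < p, 1.0, -1.0)
    return pd.DataFrame({
        "prev_choice": c_prev, "stimulus": stim,
        "m1": med[:, 0], "m2": med[:, 1], "m3": med[:, 2],
        "choice": choice,
    })


def write_cohort(trials: pd.DataFrame, signals: pd.DataFrame, agents: dict,
                 out_dir, generator_config: dict | None = None) -> None:
    """Write tidy CSVs plus a JSON sidecar with all generator parameters."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    trials.to_csv(out / "trials.csv", index=False)
    signals.to_csv(out / "neural_signals.csv", index=False)
    meta = {"generator": generator_config or {},
            "agents": {str(s): _agent_to_json(a) for s, a in agents.items()}}
    (out / "generator_params.json").write_text(json.dumps(meta, indent=2))


def _agent_to_json(a: AgentParams) -> dict:
    d = asdict(a)
    d["bound"] = {"a": a.bound.a, "form": a.bound.form,
                  "shape": a.bound.shape, "scale": a.bound.scale}
    return d
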