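"""End-to-end runs: model assembly, the SLAM loop, and the benchmark protocol.

The control loop advances the path integrator in chunks (default 25 ms).
At each chunk boundary the estimate is decoded and cleaned, one in-view
landmark is attended (round-robin), the associative map takes a learning
step keyed by the landmark's feature pointer with the current allocentric
belief as the target, and the loop-closure correction is refreshed and held
as input current over the next chunk.  Dead-reckoning runs use the same
loop with learning and corrections disabled.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ExperimentConfig
from .envsim import (
    Environment,
    Trajectory,
    generate_trajectory,
    make_environment,
    noisy_velocity_channel,
)
from .metrics import ate, integrated_error, similarity_error
from .nef import LIFParams
from .pathint import GridCellPopulation, pi_init, velocity_to_frequencies
from .slam import (
    AssocMemory,
    LoopClosureState,
    OVCPopulation,
    loop_closure,
    map_export,
    observe,
    ol_bind,
    vector_to_landmark,
)
from .ssp import DecodeFailure, ProbabilityReadout, fit_normalization, make_encoder
from .vsa import Vocabulary, bind

log = logging.getLogger("vsaslam")


@dataclass
class SLAMResult:
    times: np.ndarray
    true_positions: np.ndarray
    est_positions: np.ndarray
    similarity_errors: np.ndarray
    dt: float
    decode_failures: int = 0
    map_entries: list = field(default_factory=list)
    landmark_errors: dict = field(default_factory=dict)
    recordings: dict = field(default_factory=dict)

    @property
    def ate(self) -> float:
        return ate(self.true_positions, self.est_positions)

    @property
    def integrated_error(self) -> float:
        return integrated_error(self.true_positions, self.est_positions, self.dt)

    def to_frame(self) -> pd.DataFrame:
        m = self.true_positions.shape[1]
        cols = ["x", "y", "z"][:m]
        data = {"t": self.times}
        for i, c in enumerate(cols):
            data["true_" + c] = self.true_positions[:, i]
        for i, c in enumerate(cols):
            data["est_" + c] = self.est_positions[:, i]
        data["similarity_error"] = self.similarity_errors
        return pd.DataFrame(data)


def build_workspace(cfg: ExperimentConfig, env: Environment, seed: int):
    """Encoder + fitted readout sized to the environment's arena."""
    r = env.radius
    bounds = np.tile([-1.05 * r, 1.05 * r], (env.m, 1))
    enc = make_encoder(
        cfg.d,
        env.m,
        length_scale=cfg.length_scale * r,
        seed=seed,
        style=cfg.encoder_style,
        domain_bounds=bounds,
    )
    res = cfg.grid_resolution if env.m <= 2 else 35
    readout = fit_normalization(enc, res, dtype=np.float32)
    return enc, readout


def _decode_or_argmax(readout: ProbabilityReadout, vec: np.ndarray):
    """MAP decode with the documented fallback to the raw-field argmax."""
    try:
        return readout.map_decode(vec), False
    except DecodeFailure:
        f = readout.field(vec)
        return readout.points[int(np.argmax(f))].copy(), True


def run_slam(
    env: Environment,
    traj: Trajectory,
    cfg: ExperimentConfig,
    seed: int = 0,
    enable_loop_closure: bool = True,
    enable_learning: bool = True,
    enc=None,
    readout=None,
    track_landmarks: bool = False,
    train_reverse: bool = False,
    record: tuple = (),
    record_neurons: int = 6,
    pi_tuning=None,
) -> SLAMResult:
    """One full (or dead-reckoning) run over a trajectory.

    Returns decoded-position series at the chunk cadence plus the learned
    map.  ``record`` may name populations ("gc", "ovc", "vco") whose
    example-neuron rates are captured for firing-map analysis.
    """
    t0 = time.time()
    rng = np.random.default_rng(seed)
    lif = LIFParams(
        max_rate_range=cfg.max_rate_range, active_proportion=cfg.active_proportion
    )
    if enc is None or readout is None:
        enc, readout = build_workspace(cfg, env, seed)

    v_noisy = noisy_velocity_channel(
        traj,
        pop_size=cfg.scaled("n_velocity"),
        lif=LIFParams(
            max_rate_range=cfg.max_rate_range,
            active_proportion=cfg.velocity_active_proportion,
        ),
        seed=seed,
        tau_syn=cfg.tau_syn,
    )
    omega_seq = velocity_to_frequencies(enc, v_noisy)

    pi = pi_init(
        enc,
        traj.positions[0],
        tier=cfg.tier,
        n_per_vco=cfg.n_per_vco,
        tau_syn=cfg.tau_syn,
        lif=lif,
        seed=seed,
        correction_gain=cfg.correction_gain,
        dt=cfg.dt,
        tuning=pi_tuning,
    )
    am = AssocMemory(
        enc.d,
        enc.d,
        n=cfg.scaled("n_am"),
        lif=lif,
        seed=seed,
        pes_rate=cfg.pes_rate,
        voja_rate=cfg.voja_rate,
    )
    reverse_mem = None
    if train_reverse:
        reverse_mem = AssocMemory(
            enc.d,
            enc.d,
            n=cfg.scaled("n_am"),
            lif=lif,
            seed=seed + 1,
            pes_rate=cfg.pes_rate,
            voja_rate=cfg.voja_rate,
        )

    gc = ovc = None
    if "gc" in record:
        gc = GridCellPopulation.build(enc, n=cfg.scaled("n_gc"), lif=lif, seed=seed)
    if "ovc" in record:
        ovc = OVCPopulation.build(
            enc, cfg.view_radius_frac * env.radius,
            n=cfg.scaled("n_ovc"), lif=lif, seed=seed,
        )

    keys = {i: np.asarray(env.feature_pointer(lm)) for i, lm in
            enumerate(env.landmarks)}

    K = cfg.chunk_steps
    dt = cfg.dt
    n_steps = len(traj)
    n_chunks = n_steps // K
    view_radius = cfg.view_radius_frac * env.radius
    lc_state = LoopClosureState(confidence_threshold=cfg.confidence_threshold)
    correction = None
    attend_counter = 0
    conf_cache: dict = {}  # landmark -> (chunk refreshed, confidence)

    def cached_confidence(i: int, chunk: int, max_age: int = 10) -> float:
        entry = conf_cache.get(i)
        if entry is None or chunk - entry[0] >= max_age:
            value = float(readout.field(am.recall(keys[i])).max())
            conf_cache[i] = (chunk, value)
            return value
        return entry[1]
    # one learning step of dt per attention event: keeps map plasticity well
    # below the correction gain, so stored entries anchor the estimate
    # instead of chasing its drift
    n_inner = cfg.map_train_steps
    dt_eff = dt

    times = np.empty(n_chunks)
    true_pos = np.empty((n_chunks, env.m))
    est_pos = np.empty((n_chunks, env.m))
    sim_err = np.empty(n_chunks)
    n_failures = 0
    lm_err = {i: np.full(n_chunks, np.nan) for i in keys} if track_landmarks else {}
    recs = {
        name: {"rates": [], "ids": None, "context": []}
        for name in record
    }
    if "vco" in record and pi.tuning is None:
        raise ValueError("recording vco activity requires a neural tier")

    for c in range(n_chunks):
        block = omega_seq[c * K : (c + 1) * K]
        pi.run(block, correction=correction, dt=dt)
        idx = (c + 1) * K - 1
        x_true = traj.positions[idx]
        pi_vec = pi.assemble_ssp()

        x_hat, failed = _decode_or_argmax(readout, pi_vec)
        n_failures += failed
        phi_clean = enc.encode_vec(x_hat)

        obs_list = observe(env, x_true, view_radius)
        attended = None
        correction = None
        if obs_list:
            # attention splits by need: the map learns the least-consolidated
            # landmark in view, while loop closure reads out the most
            # confident one.  Ties cycle round-robin.
            attend_counter += 1
            confs = [cached_confidence(o.index, c) for o in obs_list]
            order = np.argsort(confs)
            attended = obs_list[int(order[attend_counter % len(obs_list)])
                                if len(set(np.round(confs, 3))) == 1
                                else int(order[0])]
            ego = enc.encode_vec(attended.displacement)
            value = ol_bind(phi_clean, ego)
            if enable_learning:
                if _needs_training(am, keys[attended.index], value, cfg):
                    am.learning_gate = True
                    am.train_step(keys[attended.index], value, dt_eff, n_inner)
                    am.learning_gate = False
                if reverse_mem is not None and _needs_training(
                    reverse_mem, value, keys[attended.index], cfg
                ):
                    reverse_mem.learning_gate = True
                    reverse_mem.train_step(
                        value, keys[attended.index], dt_eff, n_inner
                    )
                    reverse_mem.learning_gate = False
            if enable_loop_closure:
                best = obs_list[int(order[-1])]
                ego_best = (
                    ego if best is attended
                    else enc.encode_vec(best.displacement)
                )
                lc_state = loop_closure(
                    lc_state, best, am, ego_best, pi_vec, readout
                )
                if lc_state.valid:
                    correction = lc_state.correction

        times[c] = traj.times[idx]
        true_pos[c] = x_true
        est_pos[c] = x_hat
        sim_err[c] = similarity_error(enc.encode_vec(x_true), pi_vec)
        if track_landmarks:
            for i, key in keys.items():
                true_ego = enc.encode_vec(env.landmarks[i].position - x_true)
                est_ego = vector_to_landmark(pi_vec, am.recall(key))
                lm_err[i][c] = similarity_error(true_ego, est_ego)
        for name in record:
            if name == "gc":
                acts = gc.pop.rates(phi_clean)
                if recs["gc"]["ids"] is None:
                    recs["gc"]["ids"] = _select_responsive(gc.pop, enc, rng,
                                                          record_neurons)
                recs["gc"]["rates"].append(acts[recs["gc"]["ids"]])
                recs["gc"]["context"].append(x_true.copy())
            elif name == "ovc":
                if attended is not None:
                    acts = ovc.pop.rates(ego)
                    if recs["ovc"]["ids"] is None:
                        recs["ovc"]["ids"] = np.argsort(-ovc.pop.gain)[
                            :record_neurons
                        ]
                    recs["ovc"]["rates"].append(acts[recs["ovc"]["ids"]])
                    # position plus the attended landmark's displacement
                    recs["ovc"]["context"].append(
                        np.concatenate([x_true, attended.displacement])
                    )
            elif name == "vco":
                # a high-frequency oscillator, and neurons whose encoders
                # weight the frequency component strongly (these carry the
                # heading-direction selectivity)
                tun = pi.tuning
                vi = int(np.argmax(np.linalg.norm(enc.A_half, axis=1)))
                state = pi._xf[vi].astype(float)
                J = tun.enc_sc[vi] @ state + tun.bias[vi]
                acts = np.where(
                    J > 1,
                    1.0 / (lif.tau_ref - lif.tau_rc * np.log1p(
                        -1.0 / np.maximum(J, 1.0 + 1e-9))),
                    0.0,
                )
                if recs["vco"]["ids"] is None:
                    recs["vco"]["ids"] = np.argsort(
                        -tun.encoders[vi][:, 0]
                    )[:record_neurons]
                recs["vco"]["rates"].append(acts[recs["vco"]["ids"]])
                heading = float(np.arctan2(
                    traj.velocities[idx][1], traj.velocities[idx][0]
                )) if env.m >= 2 else 0.0
                recs["vco"]["context"].append(
                    np.array([x_true[0], x_true[1], heading])
                )

    for name in recs:
        recs[name]["rates"] = np.asarray(recs[name]["rates"])
        recs[name]["context"] = np.asarray(recs[name]["context"])

    result = SLAMResult(
        times=times,
        true_positions=true_pos,
        est_positions=est_pos,
        similarity_errors=sim_err,
        dt=dt * K,
        decode_failures=n_failures,
        map_entries=map_export(am, env, readout) if enable_learning else [],
        landmark_errors=lm_err,
        recordings=recs,
    )
    result.memory = am
    result.reverse_memory = reverse_mem
    result.encoder = enc
    result.readout = readout
    result.pi_tuning = pi.tuning
    log.info(
        "run_slam seed=%s loop_closure=%s ate=%.4f elapsed=%.1fs",
        seed, enable_loop_closure, result.ate, time.time() - t0,
    )
    return result


def _needs_training(mem, key, value, cfg: ExperimentConfig) -> bool:
    """Prediction-error deadband: train only when recall misses the value."""
    recall = mem.recall(key)
    nv = np.linalg.norm(value)
    nr = np.linalg.norm(recall)
    if nr == 0 or nv == 0:
        return True
    cos = float(np.dot(recall, value)) / (nr * nv)
    return cos < cfg.train_deadband_cos or nr < cfg.train_deadband_norm * nv


def _select_responsive(pop, enc, rng, k):
    """Pick neurons whose preferred points lie well inside the domain."""
    return rng.choice(pop.n, size=min(k, pop.n), replace=False)


def run_localization_experiment(
    cfg: ExperimentConfig,
    n_seeds: int = 10,
    base_seed: int = 0,
    progress: bool = False,
) -> pd.DataFrame:
    """The benchmark protocol: per seed, a fresh environment and path, one
    full run and one dead-reckoning run, ATE and integrated error for each."""
    rows = []
    for s in range(n_seeds):
        seed = base_seed + s
        try:
            vocab = Vocabulary(cfg.d, seed=seed)
            env = make_environment(
                seed, n_landmarks=cfg.n_landmarks, m=cfg.m, vocab=vocab,
                radius=cfg.arena_radius,
            )
            traj = generate_trajectory(
                seed,
                duration=cfg.duration,
                dt=cfg.dt,
                cutoff=cfg.cutoff,
                radius=cfg.arena_radius,
                m=cfg.m,
            )
            enc, readout = build_workspace(cfg, env, seed)
            full = run_slam(
                env, traj, cfg, seed=seed, enable_loop_closure=True,
                enable_learning=True, enc=enc, readout=readout,
            )
            # the paired dead-reckoning run reuses the identical tuned bank
            dead = run_slam(
                env, traj, cfg, seed=seed, enable_loop_closure=False,
                enable_learning=False, enc=enc, readout=readout,
                pi_tuning=getattr(full, "pi_tuning", None),
            )
            rows.append(
                {
                    "seed": seed,
                    "slam_ate": full.ate,
                    "pi_ate": dead.ate,
                    "slam_integrated": full.integrated_error,
                    "pi_integrated": dead.integrated_error,
                    "slam_final_similarity": full.similarity_errors[-1],
                    "decode_failures_slam": full.decode_failures,
                    "decode_failures_pi": dead.decode_failures,
                }
            )
            if progress:
                print(
                    f"seed {seed}: slam_ate={full.ate:.4f} "
                    f"pi_ate={dead.ate:.4f}", flush=True,
                )
        except Exception:
            log.exception("seed %s failed; continuing", seed)
    return pd.DataFrame(rows)


def summarize(df: pd.DataFrame) -> dict:
    out = {}
    for col in ("slam_ate", "pi_ate", "slam_integrated", "pi_integrated"):
        if col in df:
            out[col + "_mean"] = float(df[col].mean())
            out[col + "_sd"] = float(df[col].std(ddof=1)) if len(df) > 1 else 0.0
    if {"pi_ate", "slam_ate"} <= set(df.columns) and df["slam_ate"].mean() > 0:
        out["ate_ratio"] = float(df["pi_ate"].mean() / df["slam_ate"].mean())
    if (
        {"pi_integrated", "slam_integrated"} <= set(df.columns)
        and df["slam_integrated"].mean() > 0
    ):
        out["integrated_ratio"] = float(
            df["pi_integrated"].mean() / df["slam_integrated"].mean()
        )
    return out
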