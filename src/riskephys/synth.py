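"""Synthetic session generator.

Emulates the statistical structure of a three-block instrumental task in
which the probability that a rewarded nose poke is followed by a foot shock
rises across blocks (P(shock|action) = 0, 0.06, 0.1; 50 trials per block).
Each session carries:

* a trial table with lognormal response times whose mean and variance rise
  with punishment risk, and pseudo-randomly chosen shock trials
  (``round(contingency x trials_per_block)`` per block, drawn without
  replacement);
* inhomogeneous-Poisson spike trains built from per-unit templates
  (baseline rate, event-locked Gaussian rate bumps with block-dependent
  gain, block-dependent baseline offsets, a shared per-trial latent gain);
* a pink-noise LFP pair with an action-locked theta burst injected into the
  VTA trace and a delayed, scaled copy of that theta component added to the
  mPFC trace (VTA-to-mPFC direction);
* von Mises spike-phase coupling to the theta oscillation, injected by
  thinning with a mean-rate-preserving acceptance function so rate and
  phase effects stay separable.

All randomness flows from one session seed through named substreams, so a
given seed always yields byte-identical sessions.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import i0

from .core import LFPChannel, Session, SpikeTrain, TrialTable, TRIAL_COLUMNS
import pandas as pd


class ConfigError(ValueError):
    """Invalid generator configuration."""


def substream(seed: int, *tags: str | int) -> np.random.Generator:
    """Independent, reproducible RNG keyed by (seed, tags).

    Tags are hashed with CRC-32 so any module can re-derive its own stream
    from the session seed without consuming another module's draws.
    """
    keys = [zlib.crc32(str(t).encode()) for t in tags]
    return np.random.default_rng(np.random.SeedSequence([int(seed)] + keys))


# ---------------------------------------------------------------------------
# configuration


@dataclass
class UnitTemplate:
    """Rate/phase recipe for one simulated unit.

    ``block_gain`` multiplies the event-locked responses per block; a
    non-constant vector makes the unit a true punishment-risk encoder.
    ``kappa`` is the von Mises concentration of spike-phase coupling per
    block (0 = no coupling); ``osc_lead`` is how far (s) the oscillation
    phase that drives spiking precedes the spike.
    """

    unit_id: str
    region: str
    baseline_rate: float  # Hz
    waveform_width: float  # ms
    # event responses: {event: (amplitude Hz, latency s, width s)}
    responses: dict = field(default_factory=dict)
    block_gain: tuple = (1.0, 1.0, 1.0)
    baseline_offset: tuple = (1.0, 1.0, 1.0)
    kappa: tuple = (0.0, 0.0, 0.0)
    preferred_phase: float = 0.0
    phase_source: str = "VTA"
    osc_lead: float = 0.0  # s, oscillation leads spikes by this much
    latent_gain: float = 0.0
    cell_class: str | None = None  # "DA" / "nonDA" for VTA templates


@dataclass
class GeneratorConfig:
    """Task, behavior, spiking and LFP parameters of one synthetic session."""

    n_blocks: int = 3
    trials_per_block: int = 50
    shock_contingency: tuple = (0.0, 0.06, 0.1)
    # shifted-lognormal RT per block: rt = rt_shift + exp(mu + sigma*eps);
    # the shift models the rat's minimum cue-to-poke latency
    rt_shift: float = 0.75
    rt_mu: tuple = (-1.39, -0.60, 0.05)     # medians ~1.0, 1.3, 1.8 s
    rt_sigma: tuple = (0.55, 0.65, 0.75)
    immobile_frac_mean: tuple = (0.25, 0.35, 0.45)
    reward_rt_shift: float = 0.5
    reward_rt_mu: float = -0.7              # median ~1 s retrieval latency
    reward_rt_sigma: float = 0.3
    iti_range: tuple = (3.0, 4.0)           # s, reward -> next cue
    first_cue: float = 5.0                  # s
    # LFP
    lfp_fs: float = 1000.0
    pink_noise_sd: tuple = (1.0, 1.0)       # (VTA, mPFC) background, a.u.
    theta_freq_range: tuple = (5.0, 15.0)   # Hz; burst frequency drawn per
                                            # trial from this band
    theta_amp_per_block: tuple = (1.6, 1.25, 0.9)
    theta_burst_duration: float = 2.5       # s, Hann envelope around action
    coupling_delay: float = 0.015           # s, VTA theta -> mPFC copy
    coupling_gain: float = 0.6
    # latent trial-to-trial state (half-normal), couples rates and log-RT
    latent_rt_gain: float = 0.15
    units: list = field(default_factory=list)  # list[UnitTemplate]
    seed: int = 0

    def __post_init__(self) -> None:
        if any(not (0.0 <= c <= 1.0) for c in self.shock_contingency):
            raise ConfigError("shock contingencies must lie in [0, 1]")
        if len(self.shock_contingency) != self.n_blocks:
            raise ConfigError("one shock contingency per block required")
        if not self.units:
            self.units = default_unit_templates()
        for u in self.units:
            if u.baseline_rate < 0 or any(k < 0 for k in u.kappa):
                raise ConfigError(f"unit {u.unit_id}: negative rate or kappa")

    def shock_counts(self) -> list[int]:
        return [int(round(c * self.trials_per_block))
                for c in self.shock_contingency]


def default_unit_templates() -> list[UnitTemplate]:
    """Default cohort: 24 mPFC and 16 VTA units.

    14/40 units are true encoders (block-modulated action-response gain,
    mixed signs); VTA splits into 8 putative-DA-like templates (slow, broad
    waveform, phasic reward response) and 8 non-DA-like templates (faster,
    narrow waveform, sustained or suppressed reward response).  Subsets are
    phase-coupled to the VTA theta oscillation with concentration declining
    over blocks.
    """
    units: list[UnitTemplate] = []
    gain_up, gain_dn = (1.0, 1.5, 2.0), (1.0, 0.5, 0.25)
    for i in range(24):
        enc = i < 8
        gain = (gain_up if i % 2 == 0 else gain_dn) if enc else (1.0, 1.0, 1.0)
        amp = 12.0 if enc else 6.0
        units.append(UnitTemplate(
            unit_id=f"m{i:02d}", region="mPFC",
            baseline_rate=3.0 + 0.25 * i, waveform_width=0.35 + 0.01 * i,
            responses={"cue": (5.0, 0.05, 0.15),
                       "action": (amp, 0.0, 0.2),
                       "reward": (5.0, 0.15, 0.2)},
            block_gain=gain,
            baseline_offset=(1.0, 1.15, 1.5) if 20 <= i < 23 else (1.0, 1.0, 1.0),
            kappa=(1.6, 1.1, 0.7) if i % 2 == 0 else (0.0, 0.0, 0.0),
            preferred_phase=0.5, phase_source="VTA", osc_lead=0.020,
            latent_gain=0.22, cell_class=None))
    for i in range(8):  # DA-like
        enc = i < 4
        units.append(UnitTemplate(
            unit_id=f"v{i:02d}", region="VTA",
            baseline_rate=4.0 + 0.4 * i, waveform_width=1.3 + 0.05 * i,
            responses={"cue": (10.0, 0.08, 0.05),
                       "action": (12.0, 0.0, 0.12),
                       "reward": (16.0, 0.1, 0.06)},
            block_gain=(1.0, 1.5, 2.0) if enc else (1.0, 1.0, 1.0),
            kappa=(1.1, 0.8, 0.5), preferred_phase=-0.4,
            phase_source="VTA", osc_lead=0.012,
            latent_gain=0.1, cell_class="DA"))
    for i in range(8):  # non-DA-like
        enc = i < 2
        suppressed = i >= 6
        amp = -6.0 if suppressed else 5.0
        units.append(UnitTemplate(
            unit_id=f"v{i + 8:02d}", region="VTA",
            baseline_rate=9.0 + 0.8 * i, waveform_width=0.5 + 0.06 * i,
            responses={"cue": (4.0, 0.1, 0.2),
                       "action": (10.0 if enc else 4.0, 0.05, 0.2),
                       "reward": (amp, 0.35, 0.35)},
            block_gain=(1.0, 1.7, 2.4) if enc else (1.0, 1.0, 1.0),
            kappa=(0.0, 0.0, 0.0),
            latent_gain=0.1, cell_class="nonDA"))
    return units


def null_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """No-shock control: every block effect switched off.

    Shock contingencies zero, flat RT distribution, flat response gains and
    baseline offsets, block-constant theta amplitude and phase coupling, no
    latent coupling — the configuration under which every downstream
    detection should fire at its nominal false-positive rate.
    """
    units = []
    for u in default_unit_templates():
        kap = (max(u.kappa),) * 3
        units.append(UnitTemplate(
            unit_id=u.unit_id, region=u.region,
            baseline_rate=u.baseline_rate, waveform_width=u.waveform_width,
            responses=dict(u.responses), block_gain=(1.0, 1.0, 1.0),
            baseline_offset=(1.0, 1.0, 1.0), kappa=kap,
            preferred_phase=u.preferred_phase, phase_source=u.phase_source,
            osc_lead=u.osc_lead, latent_gain=0.0, cell_class=u.cell_class))
    cfg = dict(shock_contingency=(0.0, 0.0, 0.0),
               rt_mu=(0.0, 0.0, 0.0), rt_sigma=(0.35, 0.35, 0.35),
               immobile_frac_mean=(0.3, 0.3, 0.3),
               theta_amp_per_block=(1.3, 1.3, 1.3),
               latent_rt_gain=0.0, units=units, seed=seed)
    cfg.update(overrides)
    return GeneratorConfig(**cfg)


# ---------------------------------------------------------------------------
# generation


def _hann_env(x: np.ndarray, duration: float) -> np.ndarray:
    """Hann window of given total duration, centered at x=0, zero outside."""
    inside = np.abs(x) <= duration / 2
    out = np.zeros_like(x)
    out[inside] = 0.5 * (1 + np.cos(2 * np.pi * x[inside] / duration))
    return out


def _make_trials(cfg: GeneratorConfig, latent: np.ndarray,
                 rng: np.random.Generator) -> pd.DataFrame:
    n = cfg.n_blocks * cfg.trials_per_block
    blocks = np.repeat(np.arange(1, cfg.n_blocks + 1), cfg.trials_per_block)
    bi = blocks - 1
    rt = cfg.rt_shift + np.exp(
        np.asarray(cfg.rt_mu)[bi]
        + np.asarray(cfg.rt_sigma)[bi] * rng.standard_normal(n)
        + cfg.latent_rt_gain * latent)
    frac = np.clip(rng.beta(4.0, 4.0, n) + np.asarray(cfg.immobile_frac_mean)[bi]
                   - 0.5, 0.0, 0.95)
    reward_rt = cfg.reward_rt_shift + np.exp(
        cfg.reward_rt_mu + cfg.reward_rt_sigma * rng.standard_normal(n))
    iti = rng.uniform(*cfg.iti_range, n)

    cue = np.empty(n)
    t = cfg.first_cue
    for k in range(n):
        cue[k] = t
        t = cue[k] + rt[k] + reward_rt[k] + iti[k]
    action = cue + rt
    reward = action + reward_rt

    shock = np.zeros(n, bool)
    for b, count in zip(range(1, cfg.n_blocks + 1), cfg.shock_counts()):
        idx = np.flatnonzero(blocks == b)
        if count > 0:
            shock[rng.choice(idx, size=count, replace=False)] = True

    return pd.DataFrame({
        "trial_id": np.arange(n), "block": blocks, "cue_time": cue,
        "action_time": action, "reward_time": reward, "shock_flag": shock,
        "rt": rt, "immobile_rt": frac * rt, "reward_rt": reward_rt,
    })[TRIAL_COLUMNS]


def _make_lfp(cfg: GeneratorConfig, trials: pd.DataFrame, duration: float,
              seed: int) -> tuple[dict, np.ndarray]:
    """Pink-noise pair plus action-locked theta bursts (VTA leads mPFC)."""
    fs = cfg.lfp_fs
    n = int(round(duration * fs))

    def pink(rng: np.random.Generator, sd: float) -> np.ndarray:
        freqs = np.fft.rfftfreq(n, 1 / fs)
        shape = np.zeros_like(freqs)
        shape[1:] = 1.0 / np.sqrt(freqs[1:])
        spec = shape * (rng.standard_normal(freqs.size)
                        + 1j * rng.standard_normal(freqs.size))
        x = np.fft.irfft(spec, n)
        return x * (sd / x.std())

    theta = np.zeros(n)
    rng_ph = substream(seed, "lfp", "phase")
    phase0 = rng_ph.uniform(-np.pi, np.pi, len(trials))
    freqs = substream(seed, "lfp", "freq").uniform(*cfg.theta_freq_range,
                                                   len(trials))
    half = cfg.theta_burst_duration / 2
    amps = np.asarray(cfg.theta_amp_per_block)
    for k, row in enumerate(trials.itertuples()):
        a = row.action_time
        i0_ = max(0, int((a - half) * fs))
        i1_ = min(n, int((a + half) * fs) + 1)
        t_rel = np.arange(i0_, i1_) / fs - a
        env = _hann_env(t_rel, cfg.theta_burst_duration)
        theta[i0_:i1_] += (amps[row.block - 1] * env
                           * np.cos(2 * np.pi * freqs[k] * t_rel + phase0[k]))

    vta = pink(substream(seed, "lfp", "VTA"), cfg.pink_noise_sd[0]) + theta
    shift = int(round(cfg.coupling_delay * cfg.lfp_fs))
    theta_delayed = np.zeros(n)
    theta_delayed[shift:] = theta[: n - shift]
    mpfc = (pink(substream(seed, "lfp", "mPFC"), cfg.pink_noise_sd[1])
            + cfg.coupling_gain * theta_delayed)

    lfp = {"VTA": LFPChannel("VTA", vta, fs),
           "mPFC": LFPChannel("mPFC", mpfc, fs)}
    return lfp, phase0, freqs


def _simulate_unit(u: UnitTemplate, cfg: GeneratorConfig, trials: pd.DataFrame,
                   latent: np.ndarray, phase0: np.ndarray,
                   theta_freqs: np.ndarray, duration: float,
                   rng: np.random.Generator) -> np.ndarray:
    """Thinned inhomogeneous Poisson spikes with von Mises phase coupling.

    Candidate spikes at a constant rate ``lam_max`` are accepted with
    probability ``lam(t) * exp(k_eff cos(phi - phi0)) / (I0(k_eff) lam_max)``
    where ``k_eff`` is the per-block concentration scaled by the theta-burst
    envelope.  Dividing by the Bessel normalization I0 keeps the expected
    rate equal to the programmed ``lam(t)`` regardless of coupling strength.
    """
    cue = trials["cue_time"].to_numpy()
    action = trials["action_time"].to_numpy()
    reward = trials["reward_time"].to_numpy()
    blocks = trials["block"].to_numpy() - 1
    bounds = np.concatenate([[0.0], (reward[:-1] + cue[1:]) / 2, [duration]])

    gains = np.asarray(u.block_gain)
    offs = np.asarray(u.baseline_offset)
    kaps = np.asarray(u.kappa)
    z_max = latent.max() if latent.size else 0.0
    pos_amp = sum(max(a, 0.0) for a, _, _ in u.responses.values())
    lam_peak = ((u.baseline_rate * offs.max() + pos_amp * gains.max())
                * np.exp(u.latent_gain * z_max))
    kmax = kaps.max()
    lam_max = lam_peak * (np.exp(kmax) / i0(kmax) if kmax > 0 else 1.0) * 1.05

    n_cand = rng.poisson(lam_max * duration)
    t = np.sort(rng.uniform(0.0, duration, n_cand))
    k = np.clip(np.searchsorted(bounds, t) - 1, 0, len(trials) - 1)
    b = blocks[k]

    lam = u.baseline_rate * offs[b]
    ev_times = {"cue": cue, "action": action, "reward": reward}
    for ev, (amp, lat, wid) in u.responses.items():
        dt = t - ev_times[ev][k] - lat
        lam = lam + amp * gains[b] * np.exp(-0.5 * (dt / wid) ** 2)
    lam = np.maximum(lam, 0.0) * np.exp(u.latent_gain * latent[k])

    accept = lam / lam_max
    if kmax > 0:
        dt_act = t - action[k]
        env = _hann_env(dt_act, cfg.theta_burst_duration)
        k_eff = kaps[b] * env
        # programmed source-theta phase at (t - osc_lead)
        phi = (2 * np.pi * theta_freqs[k] * (dt_act - u.osc_lead) + phase0[k])
        accept = accept * np.exp(k_eff * np.cos(phi - u.preferred_phase)) / i0(k_eff)
    spikes = t[rng.uniform(size=n_cand) < accept]
    return spikes


def generate_session(config: GeneratorConfig | None = None,
                     seed: int | None = None) -> Session:
    """Build a full synthetic session; deterministic in ``config.seed``."""
    cfg = config if config is not None else GeneratorConfig()
    if seed is not None:
        cfg.seed = int(seed)
    seed_ = cfg.seed

    n = cfg.n_blocks * cfg.trials_per_block
    latent = np.abs(substream(seed_, "latent").standard_normal(n))
    trials_df = _make_trials(cfg, latent, substream(seed_, "trials"))
    duration = float(trials_df["reward_time"].iloc[-1] + 5.0)

    lfp, phase0, theta_freqs = _make_lfp(cfg, trials_df, duration, seed_)

    units = []
    for u in cfg.units:
        spikes = _simulate_unit(u, cfg, trials_df, latent, phase0,
                                theta_freqs, duration,
                                substream(seed_, "unit", u.unit_id))
        units.append(SpikeTrain(u.unit_id, u.region, spikes, u.waveform_width))

    truth = {
        "units": {
            u.unit_id: {
                # any block-dependent rate (response gain or baseline offset)
                # is genuine punishment-risk encoding
                "encoder": (len(set(u.block_gain)) > 1
                            or len(set(u.baseline_offset)) > 1),
                "cell_class": u.cell_class,
                "kappa": list(u.kappa),
                "preferred_phase": u.preferred_phase,
                "phase_source": u.phase_source,
                "osc_lead": u.osc_lead,
                "latent_gain": u.latent_gain,
                "baseline_modulated": len(set(u.baseline_offset)) > 1,
                "block_gain": list(u.block_gain),
            } for u in cfg.units
        },
        "lfp_coupling": {"direction": "VTA->mPFC",
                         "delay": cfg.coupling_delay,
                         "gain": cfg.coupling_gain},
        "theta_freq_per_trial": theta_freqs.tolist(),
        "theta_amp_per_block": list(cfg.theta_amp_per_block),
        "latent": latent.tolist(),
        "latent_rt_gain": cfg.latent_rt_gain,
    }
    meta = {
        "synthetic": True,
        "seed": seed_,
        "trials_per_block": cfg.trials_per_block,
        "duration": duration,
        "config": _config_dict(cfg),
        "truth": truth,
    }
    session = Session(TrialTable(trials_df), units, lfp, meta)
    from .core import compute_baseline_rates
    compute_baseline_rates(session)
    return session


def _config_dict(cfg: GeneratorConfig) -> dict:
    d = asdict(cfg)
    d["units"] = [asdict(u) for u in cfg.units]
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    d["units"] = [UnitTemplate(**u) for u in d.get("units", [])]
    for key in ("shock_contingency", "rt_mu", "rt_sigma", "immobile_frac_mean",
                "iti_range", "pink_noise_sd", "theta_amp_per_block"):
        if key in d:
            d[key] = tuple(d[key])
    for u in d["units"]:
        u.block_gain = tuple(u.block_gain)
        u.baseline_offset = tuple(u.baseline_offset)
        u.kappa = tuple(u.kappa)
    return GeneratorConfig(**d)


def ground_truth(session: Session) -> dict:
    """Programmed effects of a synthetic session (per-unit encoder status,
    cell class, phase-coupling parameters, LFP coupling, latent series)."""
    if not session.meta.get("synthetic"):
        raise ValueError("ground truth is only defined for synthetic sessions")
    return session.meta["truth"]
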