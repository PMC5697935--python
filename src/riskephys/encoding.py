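"""Single-unit punishment-risk encoding statistics.

The central statistic is the bias-corrected percent explained variance
(omega-squared PEV) of across-trial spike counts by block,

    wPEV = (SS_blocks - df_blocks * MS_error) / (SS_total + MS_error),

computed in a 200 ms rectangular window stepped by 50 ms across the 2 s
peri-event epoch.  Its expectation is zero when block means are equal, so a
unit's encoding is judged against surrogate bands built by shuffling block
labels across trials (whole trials at a time, preserving within-trial
temporal correlation): the *pointwise* band bounds each time bin separately
and the *global* band bounds the whole trace, controlling the family-wise
false-positive rate across bins.  Both bands are found by stepping up from
the surrogate mean in increments of one-hundredth of the surrogate SD.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .core import (BASELINE_WINDOW, PeriEventTensor, SpikeTrain, TrialTable,
                   ValidationError)


# ---------------------------------------------------------------------------
# peri-event binning


def bin_peri_event(spikes: SpikeTrain | list[SpikeTrain], trials: TrialTable,
                   align: str = "action", window: tuple[float, float] = (-2.0, 2.0),
                   bin_width: float = 0.05, bin_step: float | None = None,
                   ) -> PeriEventTensor:
    """Count spikes in (possibly overlapping) bins around a task event.

    Bin *b* of trial *t* covers ``[event_t + start_b, event_t + start_b +
    bin_width)`` with starts advancing by ``bin_step`` (defaults to
    ``bin_width``: non-overlapping tiling).
    """
    if bin_step is None:
        bin_step = bin_width
    units = spikes if isinstance(spikes, list) else [spikes]
    events = trials.event_times(align)
    if np.any(~np.isfinite(events)):
        bad = int(trials.df["trial_id"].iloc[int(np.argmax(~np.isfinite(events)))])
        raise ValidationError(f"trial {bad}: missing {align} timestamp")

    n_bins = int(np.floor((window[1] - window[0] - bin_width) / bin_step + 1e-9)) + 1
    starts = window[0] + bin_step * np.arange(n_bins)
    lo_edges = events[:, None] + starts[None, :]
    hi_edges = lo_edges + bin_width

    data = np.empty((len(units), len(events), n_bins), dtype=float)
    for i, u in enumerate(units):
        t = u.spike_times
        data[i] = (np.searchsorted(t, hi_edges, "left")
                   - np.searchsorted(t, lo_edges, "left"))
    return PeriEventTensor(data=data, align_event=align, window=window,
                           bin_width=bin_width, bin_step=bin_step,
                           included_trials=trials.df["trial_id"].to_numpy(),
                           unit_ids=[u.unit_id for u in units])


def boxcar_smooth(x: np.ndarray, n_bins: int = 5, axis: int = -1) -> np.ndarray:
    """Centered boxcar mean with edge truncation and renormalization."""
    x = np.asarray(x, float)
    kernel = np.ones(n_bins)
    num = np.apply_along_axis(lambda v: np.convolve(v, kernel, "same"), axis, x)
    den = np.convolve(np.ones(x.shape[axis]), kernel, "same")
    shape = [1] * x.ndim
    shape[axis] = -1
    return num / den.reshape(shape)


def to_rates(tensor: PeriEventTensor) -> PeriEventTensor:
    if tensor.is_rate:
        return tensor
    return PeriEventTensor(tensor.data / tensor.bin_width, tensor.align_event,
                           tensor.window, tensor.bin_width, tensor.bin_step,
                           tensor.included_trials, tensor.unit_ids, is_rate=True)


def zscore_to_baseline(tensor: PeriEventTensor, baseline: PeriEventTensor,
                       ) -> tuple[np.ndarray, list[str]]:
    """Z-score rates per unit against pooled baseline mean/SD.

    Baseline statistics pool over all baseline bins and trials of the unit.
    Units with zero baseline variance cannot be normalized; their z-values
    are NaN and their ids are returned in the flagged list.
    """
    rates = to_rates(tensor).data
    base = to_rates(baseline).data
    if base.shape[1] < 2:
        raise ValidationError("baseline needs at least 2 trials")
    mu = base.mean(axis=(1, 2))
    sd = base.std(axis=(1, 2), ddof=1)
    flagged = [uid for uid, s in zip(tensor.unit_ids, sd) if s == 0]
    sd = np.where(sd == 0, np.nan, sd)
    z = (rates - mu[:, None, None]) / sd[:, None, None]
    return z, flagged


# ---------------------------------------------------------------------------
# omega-squared percent explained variance


def compute_wpev(groups: list[np.ndarray]) -> float:
    """Bias-corrected omega-squared of a one-way layout.

    ``groups`` holds per-block across-trial spike counts for one time bin.
    Returns 0 by convention when all counts are identical (SS_total +
    MS_error = 0).
    """
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >=2 blocks with >=2 trials each")
    counts = np.concatenate([np.asarray(g, float) for g in groups])
    labels = np.concatenate([np.full(len(g), i) for i, g in enumerate(groups)])
    return float(wpev_by_bin(counts[:, None], labels)[0])


def wpev_by_bin(counts: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Vectorized wPEV across time bins.

    counts: (n_trials, n_bins); labels: (n_trials,) block codes.
    """
    counts = np.asarray(counts, float)
    codes, inv = np.unique(labels, return_inverse=True)
    k = codes.size
    n = counts.shape[0]
    onehot = np.zeros((k, n))
    onehot[inv, np.arange(n)] = 1.0
    n_g = onehot.sum(1)
    grand = counts.mean(0)
    gsum = onehot @ counts
    gmean = gsum / n_g[:, None]
    ss_b = (n_g[:, None] * (gmean - grand) ** 2).sum(0)
    ss_t = ((counts - grand) ** 2).sum(0)
    ms_e = (ss_t - ss_b) / (n - k)
    denom = ss_t + ms_e
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (ss_b - (k - 1) * ms_e) / denom
    return np.where(denom == 0, 0.0, w)


def _wpev_shuffled(counts: np.ndarray, labels: np.ndarray,
                   perms: np.ndarray) -> np.ndarray:
    """wPEV traces for many label permutations at once.

    perms: (n_shuffles, n_trials) permutation index arrays applied to labels.
    Returns (n_shuffles, n_bins).
    """
    codes, inv = np.unique(labels, return_inverse=True)
    k = codes.size
    n, nb = counts.shape
    lab = inv[perms]  # (S, n)
    onehot = np.zeros((perms.shape[0], k, n))
    s_idx = np.repeat(np.arange(perms.shape[0]), n)
    onehot[s_idx, lab.ravel(), np.tile(np.arange(n), perms.shape[0])] = 1.0
    n_g = onehot.sum(2)  # (S, k)
    gsum = np.einsum("skn,nb->skb", onehot, counts)
    gmean = gsum / n_g[:, :, None]
    grand = counts.mean(0)
    ss_b = (n_g[:, :, None] * (gmean - grand) ** 2).sum(1)
    ss_t = ((counts - grand) ** 2).sum(0)
    ms_e = (ss_t - ss_b) / (n - k)
    denom = ss_t + ms_e
    with np.errstate(invalid="ignore", divide="ignore"):
        w = (ss_b - (k - 1) * ms_e) / denom
    return np.where(denom == 0, 0.0, w)


@dataclass
class SurrogateBands:
    pointwise: np.ndarray  # per bin
    global_band: float
    surrogate_mean: float
    surrogate_sd: float
    n_shuffles: int
    alpha: float


def surrogate_bands(counts: np.ndarray, labels: np.ndarray,
                    n_shuffles: int = 1000, alpha: float = 0.01,
                    rng: np.random.Generator | None = None,
                    return_traces: bool = False):
    """Pointwise and global wPEV bands from trial-shuffled surrogates.

    Block labels are permuted across trials (jointly for all bins of a
    trial); the band search steps up from the surrogate mean in increments
    of SD/100 until no more than ``alpha`` of surrogates exceed the level —
    at each bin separately (pointwise) and for whole traces in any bin
    (global).  The search is capped at max(surrogate) + SD.
    """
    if n_shuffles < 100:
        raise ValueError("need at least 100 shuffles")
    counts = np.asarray(counts, float)
    n = counts.shape[0]
    if n < np.unique(labels).size:
        raise ValueError("fewer trials than blocks")
    rng = rng if rng is not None else np.random.default_rng(0)
    perms = np.array([rng.permutation(n) for _ in range(n_shuffles)])
    surr = _wpev_shuffled(counts, labels, perms)

    mu, sd = float(surr.mean()), float(surr.std())
    cap = float(surr.max()) + sd
    # the band is the lowest level with FEWER than alpha of surrogates above
    m = max(0, int(np.ceil(alpha * n_shuffles)) - 1)

    def snap(v: float) -> float:
        """Smallest grid level mean + j*(SD/100) that is >= v (j >= 0)."""
        if sd == 0:
            return mu
        j = max(0, int(np.ceil((v - mu) / (sd / 100.0) - 1e-12)))
        return min(mu + j * (sd / 100.0), cap)

    sorted_cols = np.sort(surr, axis=0)
    pointwise = np.array([snap(sorted_cols[n_shuffles - m - 1, b])
                          for b in range(surr.shape[1])])
    maxima = np.sort(surr.max(axis=1))
    global_band = snap(maxima[n_shuffles - m - 1])
    bands = SurrogateBands(pointwise, global_band, mu, sd, n_shuffles, alpha)
    return (bands, surr) if return_traces else bands


@dataclass
class EncodingResult:
    unit_id: str
    wpev: np.ndarray
    pointwise_band: np.ndarray
    global_band: float
    encoder: bool
    crossing_bins: np.ndarray
    n_surrogates: int
    alpha: float
    bin_centers: np.ndarray | None = None


def classify_encoder(wpev_trace: np.ndarray, bands: SurrogateBands,
                     unit_id: str = "", bin_centers: np.ndarray | None = None,
                     ) -> EncodingResult:
    """A unit encodes punishment risk iff its wPEV crosses the global band."""
    crossing = np.flatnonzero(wpev_trace > bands.global_band)
    return EncodingResult(unit_id=unit_id, wpev=np.asarray(wpev_trace),
                          pointwise_band=bands.pointwise,
                          global_band=bands.global_band,
                          encoder=crossing.size > 0, crossing_bins=crossing,
                          n_surrogates=bands.n_shuffles, alpha=bands.alpha,
                          bin_centers=bin_centers)


def unit_rng(seed: int, unit_id: str) -> np.random.Generator:
    """Per-unit surrogate substream keyed by a hash of the unit id, so runs
    parallelized over units reproduce the serial result."""
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), zlib.crc32(unit_id.encode())]))


def encode_unit(spikes: SpikeTrain, trials: TrialTable, align: str = "action",
                window: tuple[float, float] = (-1.0, 1.0),
                bin_width: float = 0.2, bin_step: float = 0.05,
                n_shuffles: int = 1000, alpha: float = 0.01,
                seed: int = 0) -> EncodingResult:
    """Full wPEV-with-global-band analysis for one unit.

    Shock trials must already be excluded from ``trials``.  For onset-timing
    (fine-grid) analyses pass ``bin_width=0.05, bin_step=0.005``.
    """
    tensor = bin_peri_event(spikes, trials, align, window, bin_width, bin_step)
    counts = tensor.data[0]
    labels = trials.blocks
    trace = wpev_by_bin(counts, labels)
    bands = surrogate_bands(counts, labels, n_shuffles, alpha,
                            rng=unit_rng(seed, spikes.unit_id))
    return classify_encoder(trace, bands, spikes.unit_id, tensor.bin_centers)


# ---------------------------------------------------------------------------
# direction, baseline modulation, RT correlation


@dataclass
class SRCResult:
    unit_id: str
    src: np.ndarray          # per bin
    summary: float           # peri-event epoch pooled
    sign: str                # excitatory / inhibitory
    flagged_bins: np.ndarray = field(default_factory=lambda: np.empty(0, int))


def _pearson_vec(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Pearson r of x (n,) against each column of y (n, m); 0 where a column
    is constant."""
    xc = x - x.mean()
    yc = y - y.mean(0)
    sx = np.sqrt((xc ** 2).sum())
    sy = np.sqrt((yc ** 2).sum(0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc) / (sx * sy)
    return np.where(sy == 0, 0.0, r)


def src_direction(counts: np.ndarray, block_labels: np.ndarray,
                  unit_id: str = "") -> SRCResult:
    """Standardized regression coefficient of counts on block index.

    The simple-regression coefficient standardized by beta * (Sx/Sy) equals
    the Pearson correlation, so |SRC| <= 1; its sign classifies the unit as
    excitatory (firing rises with risk) or inhibitory.
    """
    counts = np.atleast_2d(np.asarray(counts, float))
    if counts.shape[0] == 1:
        counts = counts.T
    if counts.shape[0] < 3:
        raise ValueError("need at least 3 trials")
    x = np.asarray(block_labels, float)
    per_bin = _pearson_vec(x, counts)
    pooled = counts.sum(1)
    if pooled.std() == 0:
        summary = 0.0
        flagged = np.arange(counts.shape[1])
    else:
        summary = float(_pearson_vec(x, pooled[:, None])[0])
        flagged = np.flatnonzero(counts.std(0) == 0)
    sign = "excitatory" if summary >= 0 else "inhibitory"
    return SRCResult(unit_id, per_bin, summary, sign, flagged)


def baseline_block_modulation(spikes: SpikeTrain, trials: TrialTable,
                              window: tuple[float, float] = BASELINE_WINDOW,
                              alpha: float = 0.05) -> dict:
    """Kruskal-Wallis test for block modulation of inter-trial (baseline)
    firing, with direction from the sign of the block-index SRC."""
    tensor = bin_peri_event(spikes, trials, "baseline", window,
                            bin_width=window[1] - window[0])
    counts = tensor.data[0, :, 0]
    blocks = trials.blocks
    groups = [counts[blocks == b] for b in np.unique(blocks)]
    if any(len(g) == 0 for g in groups):
        raise ValueError("empty block in baseline modulation test")
    if all(np.all(g == groups[0][0]) for g in groups):
        p = 1.0
    else:
        p = float(stats.kruskal(*groups).pvalue)
    direction = src_direction(counts, blocks, spikes.unit_id).sign
    return {"modulated": p < alpha, "p": p, "direction": direction}


def rate_rt_correlation(counts: np.ndarray, rts: np.ndarray) -> dict:
    """Pearson correlation of per-trial peri-action rate with log RT."""
    counts = np.asarray(counts, float)
    rts = np.asarray(rts, float)
    if counts.size < 10:
        raise ValueError("need at least 10 trials")
    if counts.std() == 0 or rts.std() == 0:
        return {"r": np.nan, "p": np.nan, "flagged": True}
    r, p = stats.pearsonr(counts, np.log(rts))
    return {"r": float(r), "p": float(p), "flagged": False}
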