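"""Multitaper LFP spectra, coherence, and bivariate spectral Granger causality.

Power is estimated in 500 ms moving windows stepped by 50 ms with K = 9
Slepian (DPSS) tapers (time-bandwidth product NW = 5, so K = 2NW - 1;
half-bandwidth about 10 Hz at 500 ms), averaged over tapers and trials.
The convention is Parseval-consistent: with unit-energy tapers the
one-sided PSD integrates to the segment variance up to taper bias.

Magnitude-squared coherence pools cross- and auto-spectra over tapers and
trials per window: C_xy(f) = |S_xy|^2 / (S_x S_y), in [0, 1].

Directionality is quantified by Geweke spectral Granger causality from a
bivariate VAR fitted by pooled least squares over per-trial segments
(order chosen by AIC).  With transfer function H(f) = (I - sum_j A_j
e^(-2 pi i f j))^(-1) and residual covariance Sigma, the causality from
channel 1 to channel 2 at frequency f is

    I_{1->2}(f) = -ln(1 - (Sigma_11 - Sigma_12^2/Sigma_22) |H~_21(f)|^2
                       / S_22(f)),

where H~ is the transfer function after the standard normalization that
removes the instantaneous correlation (H~_21 = H_21 + (Sigma_12/Sigma_22)
H_22; the unnormalized form is exact when Sigma_12 = 0).  Integrated over
normalized frequency this equals the time-domain Granger causality.
Significance is assessed with a permutation bound: one channel's trial
segments are shuffled against the other's and the (1 - alpha) quantile of
the surrogate GC forms the per-frequency upper confidence bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import detrend
from scipy.signal.windows import dpss

from .core import LFPChannel, TrialTable

NW = 5.0
N_TAPERS = 9


@dataclass
class Spectrogram:
    power: np.ndarray            # time x frequency, >= 0 before normalization
    freqs: np.ndarray            # Hz
    window_centers: np.ndarray   # s relative to alignment event
    tapers: int = N_TAPERS
    normalized: bool = False
    trial_power: np.ndarray | None = None  # trials x time x freq (optional)


def _taper_fft(seg: np.ndarray, tapers: np.ndarray) -> np.ndarray:
    """Tapered rFFT of a detrended segment: (K, n_freqs) complex."""
    seg = detrend(seg, type="linear")
    return np.fft.rfft(tapers * seg[None, :], axis=1)


def _window_starts(window: tuple[float, float], win_len: float,
                   step: float) -> np.ndarray:
    n = int(np.floor((window[1] - window[0] - win_len) / step + 1e-9)) + 1
    return window[0] + step * np.arange(n)


def multitaper_spectrogram(lfp: LFPChannel, trials: TrialTable,
                           align: str = "action",
                           window: tuple[float, float] = (-2.0, 2.0),
                           win_len: float = 0.5, step: float = 0.05,
                           fmax: float = 125.0,
                           keep_trials: bool = False) -> Spectrogram:
    """Trial-averaged multitaper power, time-resolved around a task event."""
    if lfp.fs < 2 * fmax:
        raise ValueError(f"fs {lfp.fs} too low for fmax {fmax}")
    nwin = int(round(win_len * lfp.fs))
    tapers = dpss(nwin, NW, N_TAPERS)  # unit-energy rows
    freqs = np.fft.rfftfreq(nwin, 1 / lfp.fs)
    fsel = freqs <= fmax
    starts = _window_starts(window, win_len, step)
    events = trials.event_times(align)

    power = np.zeros((len(events), starts.size, int(fsel.sum())))
    for ti, ev in enumerate(events):
        for wi, s in enumerate(starts):
            seg = lfp.segment(ev + s, ev + s + win_len)[:nwin]
            X = _taper_fft(seg, tapers)[:, fsel]
            p = (np.abs(X) ** 2).mean(0) / lfp.fs
            scale = np.ones(p.size) * 2.0  # one-sided
            scale[0] = 1.0
            if freqs[fsel][-1] == lfp.fs / 2:
                scale[-1] = 1.0
            power[ti, wi] = p * scale
    spec = Spectrogram(power=power.mean(0), freqs=freqs[fsel],
                       window_centers=starts + win_len / 2,
                       trial_power=power if keep_trials else None)
    return spec


def baseline_power(lfp: LFPChannel, trials: TrialTable,
                   window: tuple[float, float] = (-2.5, -0.5),
                   win_len: float = 0.5, step: float = 0.05,
                   fmax: float = 125.0) -> np.ndarray:
    """Per-trial baseline power (trials x freq): mean over pre-cue windows."""
    spec = multitaper_spectrogram(lfp, trials, "baseline", window, win_len,
                                  step, fmax, keep_trials=True)
    return spec.trial_power.mean(1)


def normalize_spectrogram(spec: Spectrogram,
                          baseline_trials: np.ndarray) -> Spectrogram:
    """Z-score power at each (time, frequency) against the across-trial
    baseline mean and SD at that frequency.  Frequencies with zero baseline
    SD come out NaN."""
    mu = baseline_trials.mean(0)
    sd = baseline_trials.std(0, ddof=1)
    sd = np.where(sd == 0, np.nan, sd)
    z = (spec.power - mu[None, :]) / sd[None, :]
    return Spectrogram(power=z, freqs=spec.freqs,
                       window_centers=spec.window_centers,
                       tapers=spec.tapers, normalized=True)


def msc_coherence(x: LFPChannel, y: LFPChannel, trials: TrialTable,
                  align: str = "action",
                  window: tuple[float, float] = (-2.0, 2.0),
                  win_len: float = 0.5, step: float = 0.05,
                  fmax: float = 125.0) -> Spectrogram:
    """Magnitude-squared coherence, pooled over tapers and trials per window."""
    if x.fs != y.fs:
        raise ValueError("channels must share a sampling rate")
    n_eff = len(trials) * N_TAPERS
    if n_eff < 2:
        raise ValueError("MSC needs >= 2 effective samples (tapers x trials)")
    nwin = int(round(win_len * x.fs))
    tapers = dpss(nwin, NW, N_TAPERS)
    freqs = np.fft.rfftfreq(nwin, 1 / x.fs)
    fsel = freqs <= fmax
    starts = _window_starts(window, win_len, step)
    events = trials.event_times(align)

    coh = np.zeros((starts.size, int(fsel.sum())))
    for wi, s in enumerate(starts):
        sxy = np.zeros(int(fsel.sum()), complex)
        sxx = np.zeros(int(fsel.sum()))
        syy = np.zeros(int(fsel.sum()))
        for ev in events:
            X = _taper_fft(x.segment(ev + s, ev + s + win_len)[:nwin],
                           tapers)[:, fsel]
            Yf = _taper_fft(y.segment(ev + s, ev + s + win_len)[:nwin],
                            tapers)[:, fsel]
            sxy += (X * np.conj(Yf)).sum(0)
            sxx += (np.abs(X) ** 2).sum(0)
            syy += (np.abs(Yf) ** 2).sum(0)
        coh[wi] = np.abs(sxy) ** 2 / (sxx * syy)
    return Spectrogram(power=coh, freqs=freqs[fsel],
                       window_centers=starts + win_len / 2)


# ---------------------------------------------------------------------------
# VAR / Granger


@dataclass
class VARModel:
    A: np.ndarray       # order x 2 x 2 coefficient matrices
    Sigma: np.ndarray   # 2 x 2 residual covariance
    order: int
    aic: dict           # order -> AIC value
    fs: float


@dataclass
class GCResult:
    freqs: np.ndarray
    gc_xy: np.ndarray   # channel 1 -> channel 2
    gc_yx: np.ndarray
    var: VARModel
    perm_bound: np.ndarray | None = None
    alpha: float | None = None


def _segments(x, y) -> tuple[list[np.ndarray], list[np.ndarray]]:
    if isinstance(x, np.ndarray) and x.ndim == 1:
        x, y = [x], [y]
    return [np.asarray(s, float) for s in x], [np.asarray(s, float) for s in y]


def _stack_lagged(segs2: np.ndarray, order: int):
    """Design/target matrices for a VAR(order) pooled over segments.

    segs2: (n_segments, 2, n_samples), detrended per segment.
    """
    Xs, Ys = [], []
    for seg in segs2:
        n = seg.shape[1]
        if n <= order:
            continue
        Y = seg[:, order:].T                              # (n-order) x 2
        lag_cols = [seg[:, order - j: n - j].T for j in range(1, order + 1)]
        Xs.append(np.concatenate(lag_cols, axis=1))       # (n-order) x 2*order
        Ys.append(Y)
    return np.concatenate(Xs), np.concatenate(Ys)


def fit_var(x, y, order_max: int = 20, order: int | None = None,
            fs: float = 1.0) -> VARModel:
    """Least-squares bivariate VAR pooled over per-trial segments.

    Each segment is linearly detrended before stacking.  The model order is
    the AIC argmin over 1..order_max unless fixed explicitly.  Near-singular
    regressors (e.g. duplicated channels) raise with advice.
    """
    xs, ys = _segments(x, y)
    segs = np.array([detrend(np.vstack([a, b]), axis=1, type="linear")
                     for a, b in zip(xs, ys)])
    n_total = sum(s.shape[1] for s in segs)
    if n_total <= 10 * order_max:
        raise ValueError("series too short for requested order_max")

    orders = [order] if order is not None else list(range(1, order_max + 1))
    aic: dict[int, float] = {}
    best = None
    for p_ in orders:
        X, Y = _stack_lagged(segs, p_)
        gram = X.T @ X
        cond = np.linalg.cond(gram)
        if cond > 1e12:
            raise np.linalg.LinAlgError(
                f"near-singular VAR regressors at order {p_} "
                f"(cond {cond:.2g}); try a shorter order or check for "
                "duplicated channels")
        coef = np.linalg.solve(gram, X.T @ Y)             # (2p) x 2
        resid = Y - X @ coef
        n_obs = Y.shape[0]
        Sigma = resid.T @ resid / (n_obs - 2 * p_)
        sign, logdet = np.linalg.slogdet(Sigma)
        a = logdet + 2.0 * (p_ * 4) / n_obs
        aic[p_] = float(a)
        if best is None or a < aic[best[0]]:
            A = coef.T.reshape(2, p_, 2).transpose(1, 0, 2)
            best = (p_, A, Sigma)
    p_star, A, Sigma = best
    return VARModel(A=A, Sigma=Sigma, order=p_star, aic=aic, fs=fs)


def _transfer(var: VARModel, freqs: np.ndarray) -> np.ndarray:
    """H(f) = (I - sum_j A_j e^(-2 pi i f j / fs))^(-1), (n_freqs, 2, 2)."""
    omega = 2 * np.pi * freqs / var.fs
    j = np.arange(1, var.order + 1)
    phase = np.exp(-1j * omega[:, None] * j[None, :])     # F x order
    Af = np.einsum("fj,jab->fab", phase, var.A)
    eye = np.eye(2)[None]
    H = np.linalg.inv(eye - Af)
    return H


def spectral_gc(var: VARModel, freqs: np.ndarray,
                exclude_singular: bool = True) -> GCResult:
    """Geweke spectral Granger causality in both directions per frequency."""
    freqs = np.asarray(freqs, float)
    omega = 2 * np.pi * freqs / var.fs
    j = np.arange(1, var.order + 1)
    phase = np.exp(-1j * omega[:, None] * j[None, :])
    Af = np.eye(2)[None] - np.einsum("fj,jab->fab", phase, var.A)
    dets = np.abs(np.linalg.det(Af))
    bad = dets < 1e-12
    H = np.full_like(Af, np.nan)
    H[~bad] = np.linalg.inv(Af[~bad])
    S = np.einsum("fab,bc,fdc->fad", H, var.Sigma, np.conj(H))

    sig = var.Sigma
    # normalization removing instantaneous correlation
    H21t = H[:, 1, 0] + (sig[0, 1] / sig[1, 1]) * H[:, 1, 1]
    H12t = H[:, 0, 1] + (sig[0, 1] / sig[0, 0]) * H[:, 0, 0]
    s22 = np.real(S[:, 1, 1])
    s11 = np.real(S[:, 0, 0])
    with np.errstate(invalid="ignore", divide="ignore"):
        gc_xy = -np.log(1.0 - (sig[0, 0] - sig[0, 1] ** 2 / sig[1, 1])
                        * np.abs(H21t) ** 2 / s22)
        gc_yx = -np.log(1.0 - (sig[1, 1] - sig[0, 1] ** 2 / sig[0, 0])
                        * np.abs(H12t) ** 2 / s11)
    gc_xy = np.maximum(gc_xy, 0.0)
    gc_yx = np.maximum(gc_yx, 0.0)
    if exclude_singular and np.any(bad):
        gc_xy[bad] = np.nan
        gc_yx[bad] = np.nan
    return GCResult(freqs=freqs, gc_xy=gc_xy, gc_yx=gc_yx, var=var)


def granger_pair(x, y, order_max: int = 20, fs: float = 1.0,
                 freqs: np.ndarray | None = None) -> GCResult:
    """Fit a pooled VAR on (x, y) segments and return spectral GC."""
    var = fit_var(x, y, order_max=order_max, fs=fs)
    if freqs is None:
        freqs = np.arange(1.0, min(50.0, fs / 2), 1.0)
    return spectral_gc(var, freqs)


def gc_permutation_bound(x, y, order_max: int = 20, fs: float = 1.0,
                         freqs: np.ndarray | None = None,
                         n_perm: int = 1000, alpha: float = 0.001,
                         rng: np.random.Generator | None = None) -> GCResult:
    """Spectral GC with a per-frequency permutation upper confidence bound.

    Whole trial segments of the second channel are shuffled against the
    first (preserving within-segment autocorrelation); the (1 - alpha)
    quantile of the surrogate GC (both directions pooled into one null) is
    the bound.
    """
    if n_perm < 20:
        raise ValueError("need at least 20 permutations")
    xs, ys = _segments(x, y)
    if len(xs) < 3:
        raise ValueError("permutation bound needs >= 3 segments")
    rng = rng if rng is not None else np.random.default_rng(0)
    result = granger_pair(xs, ys, order_max=order_max, fs=fs, freqs=freqs)
    order = result.var.order

    surro = np.empty((n_perm, result.freqs.size))
    for i in range(n_perm):
        perm = rng.permutation(len(ys))
        if np.all(perm == np.arange(len(ys))):
            perm = np.roll(perm, 1)
        var = fit_var(xs, [ys[k] for k in perm], order=order, fs=fs)
        g = spectral_gc(var, result.freqs)
        surro[i] = g.gc_xy
    if alpha >= 1.0:
        bound = surro.min(0)
    else:
        bound = np.quantile(surro, 1.0 - alpha, axis=0)
    result.perm_bound = bound
    result.alpha = alpha
    return result


def band_mean(values: np.ndarray, freqs: np.ndarray,
              band: tuple[float, float] = (5.0, 15.0)) -> float:
    """Mean of a spectral quantity over in-band frequency bins."""
    sel = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.nanmean(np.asarray(values)[..., sel]))


def peri_event_segments(lfp: LFPChannel, trials: TrialTable,
                        align: str = "action",
                        window: tuple[float, float] = (-2.0, 2.0)) -> list:
    """Per-trial raw LFP segments around an event (inputs to fit_var)."""
    n = int(round((window[1] - window[0]) * lfp.fs))
    return [lfp.segment(ev + window[0], ev + window[1])[:n]
            for ev in trials.event_times(align)]
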