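"""Putative dopamine / non-dopamine classification of VTA units.

Two criteria are combined.  The electrophysiological criterion keeps units
with mean baseline rate below 12 Hz and waveform width above 1.2 ms (strict
inequalities).  The functional criterion compares each unit's across-trial
firing-rate distribution in 100 ms bins around reward delivery (-0.5 to
+1.0 s, 15 bins) against its across-trial baseline-rate distribution via
the area under the ROC curve, maps the resulting auROC profiles into the
top-3 principal-component space (SVD of the column-centered matrix), and
clusters them with a 2-component full-covariance Gaussian mixture fitted by
EM.  The cluster whose mean profile shows phasic post-reward elevation
(largest mean auROC within 0-300 ms after reward) is anchored as Type 1;
a unit is putative DA only if it satisfies both criteria.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.mixture import GaussianMixture

from .core import (BASELINE_WINDOW, Session, SpikeTrain, TrialTable,
                   exclude_shock_trials)
from .encoding import bin_peri_event

REWARD_WINDOW = (-0.5, 1.0)
REWARD_BIN = 0.1
PHASIC_WINDOW = (0.0, 0.3)  # s post-reward, anchors the Type1 label


@dataclass
class RewardResponseProfile:
    unit_id: str
    auroc: np.ndarray            # one value per 100 ms bin, 15 bins
    pc_scores: np.ndarray | None = None
    cluster: str | None = None   # "Type1" / "Type2"


def _auroc(event_rates: np.ndarray, baseline_rates: np.ndarray) -> float:
    """Mann-Whitney auROC: P(event > baseline) + 0.5 P(tie)."""
    u = stats.mannwhitneyu(event_rates, baseline_rates,
                           alternative="two-sided").statistic
    return float(u / (event_rates.size * baseline_rates.size))


def auroc_profile(spikes: SpikeTrain, trials: TrialTable) -> RewardResponseProfile:
    """Per-bin auROC of reward-epoch firing against baseline firing.

    0.5 means the unit's trial-by-trial rate around reward is
    indistinguishable from baseline; 1 means every event-epoch rate exceeds
    every baseline rate.  Invariant to monotone transforms of the rates.
    """
    if len(trials) < 10:
        raise ValueError("need at least 10 trials for auROC profiles")
    ev = bin_peri_event(spikes, trials, "reward", REWARD_WINDOW,
                        bin_width=REWARD_BIN)
    base = bin_peri_event(spikes, trials, "baseline", BASELINE_WINDOW,
                          bin_width=BASELINE_WINDOW[1] - BASELINE_WINDOW[0])
    base_rates = base.data[0, :, 0] / base.bin_width
    if base_rates.size == 0:
        raise ValueError("empty baseline distribution")
    ev_rates = ev.data[0] / ev.bin_width  # trials x bins
    auroc = np.array([_auroc(ev_rates[:, b], base_rates)
                      for b in range(ev_rates.shape[1])])
    return RewardResponseProfile(spikes.unit_id, auroc)


@dataclass
class ClusterResult:
    labels: list[str]            # per unit: "Type1"/"Type2"
    pc_scores: np.ndarray        # units x 3
    loadings: np.ndarray         # bins x 3
    column_means: np.ndarray
    mean_profiles: dict          # label -> mean auROC profile
    degenerate: bool = False


def pca_cluster(profiles: list[RewardResponseProfile],
                n_restarts: int = 20, seed: int = 0) -> ClusterResult:
    """Top-3 PCA of the auROC matrix followed by 2-component GMM clustering.

    The matrix (units x bins) is column-mean centered and decomposed by
    SVD; units are clustered in the top-3 PC space with full-covariance
    Gaussian mixtures (k-means-seeded EM restarts, best by likelihood).
    Component indices are arbitrary, so the phasic-reward cluster is
    re-anchored as Type1 from the mean auROC in the 0-300 ms post-reward
    bins; swapping GMM components therefore never changes final labels.
    """
    mat = np.array([p.auroc for p in profiles])
    n_units = mat.shape[0]
    if n_units < 4:
        raise ValueError("need at least 2x more units than mixture components")
    col_means = mat.mean(0)
    centered = mat - col_means
    if np.allclose(centered, 0.0):
        for p in profiles:
            p.pc_scores, p.cluster = np.zeros(3), "Type2"
        return ClusterResult(["Type2"] * n_units, np.zeros((n_units, 3)),
                             np.zeros((mat.shape[1], 3)), col_means,
                             {"Type2": col_means}, degenerate=True)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    k = min(3, s.size)
    scores = np.zeros((n_units, 3))
    scores[:, :k] = u[:, :k] * s[:k]
    loadings = np.zeros((mat.shape[1], 3))
    loadings[:, :k] = vt[:k].T

    gmm = GaussianMixture(n_components=2, covariance_type="full",
                          n_init=n_restarts, init_params="kmeans",
                          reg_covar=1e-6, tol=1e-8, max_iter=500,
                          random_state=seed)
    comp = gmm.fit_predict(scores)
    if not gmm.converged_:
        raise RuntimeError(
            f"GMM EM did not converge in {n_restarts} restarts "
            f"(lower bound {gmm.lower_bound_:.3g})")

    centers = bin_centers()
    phasic = (centers >= PHASIC_WINDOW[0]) & (centers <= PHASIC_WINDOW[1])
    phasic_mean = [mat[comp == c][:, phasic].mean() if np.any(comp == c)
                   else -np.inf for c in (0, 1)]
    type1_comp = int(np.argmax(phasic_mean))
    labels = ["Type1" if c == type1_comp else "Type2" for c in comp]
    mean_profiles = {lab: mat[[l == lab for l in labels]].mean(0)
                     for lab in set(labels)}
    for p, sc, lab in zip(profiles, scores, labels):
        p.pc_scores, p.cluster = sc, lab
    return ClusterResult(labels, scores, loadings, col_means, mean_profiles)


def bin_centers() -> np.ndarray:
    """Centers of the 15 reward-epoch auROC bins, s relative to reward."""
    n = int(round((REWARD_WINDOW[1] - REWARD_WINDOW[0]) / REWARD_BIN))
    return REWARD_WINDOW[0] + REWARD_BIN * (np.arange(n) + 0.5)


def classify_vta_unit(spikes: SpikeTrain, cluster: str) -> str:
    """Dual-criterion label: putative_DA iff baseline < 12 Hz AND width >
    1.2 ms AND reward-response cluster is Type1; otherwise putative_nonDA."""
    if spikes.baseline_rate is None:
        raise ValueError(f"unit {spikes.unit_id}: baseline_rate not computed")
    is_da = (spikes.baseline_rate < 12.0
             and spikes.waveform_width > 1.2
             and cluster == "Type1")
    return "putative_DA" if is_da else "putative_nonDA"


def classify_session(session: Session, seed: int = 0) -> dict:
    """Classify every VTA unit of a session; mPFC units are untouched
    (those with baseline > 20 Hz are only flagged as metadata)."""
    trials = exclude_shock_trials(session.trials)
    vta = session.units_in("VTA")
    if not vta:
        return {"labels": {}, "profiles": [], "fast_mpfc": []}
    profiles = [auroc_profile(u, trials) for u in vta]
    result = pca_cluster(profiles, seed=seed)
    labels = {u.unit_id: classify_vta_unit(u, p.cluster)
              for u, p in zip(vta, profiles)}
    fast_mpfc = [u.unit_id for u in session.units_in("mPFC")
                 if (u.baseline_rate or 0) > 20.0]
    return {"labels": labels, "profiles": profiles, "cluster": result,
            "fast_mpfc": fast_mpfc}
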