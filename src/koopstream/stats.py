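"""Behavior-aware statistics on extracted features.

Triplet labeling with an RT-derived neutral zone, the constrained
permutation test for the percept dependence of phi_star, KL divergence of
percept-split distributions, branch reconstructions with triplet-averaged
profiles (Pearson r, R^2), and the motor-response control analysis.
"""

from __future__ import annotations

import warnings

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA

from .datatypes import (LABEL_CODES, NEUTRAL, ONE_STREAM, TWO_STREAM,
                        BranchAssignment, KoopmanDecomposition,
                        KoopstreamError, PerceptTimeline, TripletLabels)
from .edmd import reconstruct

__all__ = ["label_triplets", "label_triplets_control",
           "n_neutral_triplets",
           "permutation_test_phi_star", "kl_divergence_percepts",
           "branch_reconstruction", "triplet_average",
           "profile_similarity", "reconstruction_r2",
           "median_ci_bootstrap", "compare_similarities",
           "motor_control_analysis", "export_embedding"]

_ONE = LABEL_CODES[ONE_STREAM]
_TWO = LABEL_CODES[TWO_STREAM]
_NEUTRAL = LABEL_CODES[NEUTRAL]


def n_neutral_triplets(rt: float, triplet_duration: float = 0.6) -> int:
    """Number of percept-neutral triplets preceding each press:
    ceil(rt / triplet_duration)."""
    return int(np.ceil(rt / triplet_duration))


def label_triplets(timeline: PerceptTimeline, rt: float | None = None,
                   triplet_duration: float | None = None) -> TripletLabels:
    """Label each triplet by the percept in force at its onset, with the
    RT-derived neutral zone immediately preceding each button press.

    The ``n_neutral = ceil(rt / triplet_duration)`` triplets that end at or
    before the press-containing triplet are set neutral — these span the
    reaction-time ambiguity between the internal switch and its report.
    """
    rt = timeline.reaction_time if rt is None else rt
    td = timeline.triplet_duration if triplet_duration is None else \
        triplet_duration
    n_triplets = int(round(timeline.block_duration / td))
    onsets = np.arange(n_triplets) * td
    labels = timeline.state_at(onsets).copy()

    presses = timeline.button_times
    if np.any((presses < 0) | (presses > timeline.block_duration)):
        raise KoopstreamError("button press outside the stimulus block")
    n_neutral = n_neutral_triplets(rt, td)
    for press in presses:
        j = int(np.floor(press / td))        # triplet containing the press
        lo = max(j - n_neutral, 0)
        labels[lo:j] = _NEUTRAL
    return TripletLabels(labels=labels, triplet_duration=td,
                         n_neutral=n_neutral, reaction_time=rt)


def label_triplets_control(timeline: PerceptTimeline,
                           stimulus_changes: np.ndarray,
                           rt: float | None = None,
                           triplet_duration: float | None = None
                           ) -> TripletLabels:
    """Control-block labeling: percept changes are driven by the stimulus.

    All triplets from each stimulus change (a df-schedule event) up to the
    subsequent button press are percept-neutral, since the listener's
    report lags the externally forced switch.
    """
    labels = label_triplets(timeline, rt, triplet_duration)
    td = labels.triplet_duration
    presses = timeline.button_times
    for change in np.sort(np.asarray(stimulus_changes, float)):
        later = presses[presses > change]
        end = later[0] if len(later) else timeline.block_duration
        lo = int(np.floor(change / td))
        hi = min(int(np.floor(end / td)), labels.n_triplets - 1)
        labels.labels[lo:hi + 1] = _NEUTRAL
    return labels


def median_ci_bootstrap(values, n_boot: int = 10_000, seed: int = 0,
                        level: float = 0.95) -> tuple[float, float, float]:
    """Percentile-bootstrap confidence interval for the median.

    Returns (median, lower, upper).
    """
    values = np.asarray(values, float)
    if len(values) < 2:
        raise KoopstreamError("need at least 2 values for a bootstrap CI")
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    meds = np.median(values[idx], axis=1)
    alpha = (1.0 - level) / 2
    lo, hi = np.quantile(meds, [alpha, 1 - alpha])
    return float(np.median(values)), float(lo), float(hi)


def compare_similarities(r_a, r_b, alternative: str = "greater"):
    """One-sided Wilcoxon rank-sum comparison of two groups of
    per-contact similarity coefficients (e.g., bistable vs control r)."""
    res = sps.ranksums(np.asarray(r_a, float), np.asarray(r_b, float),
                       alternative=alternative)
    return float(res.statistic), float(res.pvalue)


def _triplet_stats(series: np.ndarray, times: np.ndarray,
                   labels: TripletLabels) -> tuple[np.ndarray, np.ndarray]:
    """Per-triplet sum and count of series samples."""
    idx = np.floor(np.asarray(times) / labels.triplet_duration).astype(int)
    valid = (idx >= 0) & (idx < labels.n_triplets)
    sums = np.bincount(idx[valid], weights=series[valid],
                       minlength=labels.n_triplets)
    counts = np.bincount(idx[valid], minlength=labels.n_triplets)
    return sums, counts


def _mean_difference(sums, counts, labels: np.ndarray) -> float:
    """mean(two-stream) - mean(one-stream) of the underlying samples."""
    two = labels == _TWO
    one = labels == _ONE
    n_two, n_one = counts[two].sum(), counts[one].sum()
    if n_two == 0 or n_one == 0:
        return np.nan
    return sums[two].sum() / n_two - sums[one].sum() / n_one


def _place_switches(rng: np.random.Generator, n_triplets: int,
                    n_switches: int, min_run: int, first: int,
                    max_tries: int = 2000) -> np.ndarray:
    """Random switch positions honoring the minimum-run constraint.

    The first switch is pinned at triplet ``first`` (the stimulus start
    after accounting for RT); the rest are drawn uniformly over feasible
    triplet boundaries by rejection until all inter-switch runs, and the
    final run to the block end, span at least ``min_run`` triplets.
    """
    lo, hi = first + min_run, n_triplets - min_run
    n_free = n_switches - 1
    if n_free < 0:
        return np.array([], dtype=int)
    if n_free == 0:
        if n_triplets - first < min_run:
            raise KoopstreamError("block too short for the switch count")
        return np.array([first])
    if hi - lo + 1 < n_free or n_free * min_run > hi - lo + 1:
        raise KoopstreamError(
            "cannot place switches: run-length constraint infeasible")
    for _ in range(max_tries):
        pos = np.sort(rng.choice(np.arange(lo, hi + 1), size=n_free,
                                 replace=False))
        runs = np.diff(np.concatenate([[first], pos, [n_triplets]]))
        if (runs >= min_run).all():
            return np.concatenate([[first], pos])
    raise KoopstreamError(
        "switch placement rejection sampling failed; constraints too tight")


def permutation_test_phi_star(phi_star: np.ndarray, times: np.ndarray,
                              labels: TripletLabels,
                              n_perm: int = 10_000,
                              seed: int = 0) -> dict:
    """Constrained permutation test for percept dependence of phi_star.

    The observed statistic is the difference in means of phi_star over
    two-stream vs one-stream triplets.  Each permutation re-places the
    observed number of switches at random triplet boundaries such that
    every run of same-label triplets spans a time window larger than RT,
    with the first switch pinned at the start of the block after RT and the
    first percept drawn at random; neutral zones are re-applied before each
    switch.  The Monte Carlo p-value is ``(m + 1) / (n + 1)`` with m the
    number of permutations whose |mean difference| reaches the observed
    one.  Significance level alpha = 0.01 by convention.
    """
    obs_labels = labels.labels
    if not ((obs_labels == _ONE).any() and (obs_labels == _TWO).any()):
        raise KoopstreamError("both percepts must be present")
    sums, counts = _triplet_stats(np.asarray(phi_star, float),
                                  times, labels)
    mu_obs = _mean_difference(sums, counts, obs_labels)

    # observed switch count: changes between non-neutral labels
    solid = obs_labels[obs_labels != _NEUTRAL]
    n_switches = int(np.sum(np.diff(solid) != 0)) + 1
    # +1: the pinned first switch at block start mirrors the subject's
    # first report establishing the initial percept

    td = labels.triplet_duration
    # a run must span a window larger than RT *and* keep at least one
    # solid triplet once its trailing neutral zone is re-applied
    min_run = max(int(np.floor(labels.reaction_time / td)) + 1,
                  labels.n_neutral + 1)
    first = int(np.ceil(labels.reaction_time / td))
    n_triplets = labels.n_triplets

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    m = 0
    for i in range(n_perm):
        switches = _place_switches(rng, n_triplets, n_switches,
                                   min_run, first)
        perm = np.full(n_triplets, _NEUTRAL, dtype=int)
        state = _ONE if rng.random() < 0.5 else _TWO
        bounds = np.concatenate([switches, [n_triplets]])
        perm[:switches[0]] = _NEUTRAL
        for a, b in zip(bounds[:-1], bounds[1:]):
            perm[a:b] = state
            state = _TWO if state == _ONE else _ONE
        for s in switches:
            perm[max(s - labels.n_neutral, 0):s] = _NEUTRAL
        assert int(np.sum(np.diff(perm[perm != _NEUTRAL]) != 0)) + 1 \
            == n_switches, "permutation changed the switch count"
        null[i] = _mean_difference(sums, counts, perm)
        if np.abs(null[i]) >= np.abs(mu_obs):
            m += 1
    p = (m + 1) / (n_perm + 1)
    return dict(p=p, mu_obs=mu_obs, null=null, m=m, n_perm=n_perm,
                n_switches=n_switches)


def kl_divergence_percepts(phi_star: np.ndarray, times: np.ndarray,
                           labels: TripletLabels, n_bins: int = 25,
                           smoothing: float = 1e-10) -> float:
    """KL divergence between percept-split distributions of phi_star.

    Histograms use ``n_bins`` shared equal-width bins over the pooled range
    with additive smoothing; the divergence reported is
    KL(two-stream || one-stream).  Absolute values depend on this binning
    dialect.
    """
    phi_star = np.asarray(phi_star, float)
    sample_labels = labels.sample_labels(times)
    one = phi_star[sample_labels == _ONE]
    two = phi_star[sample_labels == _TWO]
    if len(one) < n_bins or len(two) < n_bins:
        raise KoopstreamError("too few samples per percept for the bins")
    lo = min(one.min(), two.min())
    hi = max(one.max(), two.max())
    edges = np.linspace(lo, hi, n_bins + 1)
    p, _ = np.histogram(two, bins=edges)
    q, _ = np.histogram(one, bins=edges)
    p = p / p.sum() + smoothing
    q = q / q.sum() + smoothing
    p, q = p / p.sum(), q / q.sum()
    return float(np.sum(p * np.log(p / q)))


def branch_reconstruction(decomp: KoopmanDecomposition,
                          branches: BranchAssignment,
                          branch: str, channel: int) -> np.ndarray:
    """Real branch-restricted reconstruction of one channel.

    ``branch`` is "J1", "J2" or "union"; the J1 and J2 series sum exactly
    to the union series.  An empty branch yields zeros with a warning.
    """
    idx = {"J1": branches.J1, "J2": branches.J2,
           "union": sorted(set(branches.J1) | set(branches.J2))}[branch]
    if len(idx) == 0:
        warnings.warn(f"branch {branch} is empty; returning zeros",
                      RuntimeWarning, stacklevel=2)
        return np.zeros(decomp.eigfuns.shape[0])
    return reconstruct(decomp, idx)[:, channel]


def triplet_average(series: np.ndarray, times: np.ndarray,
                    labels: TripletLabels, percept: str, rate: float
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Mean and SEM profile over the triplet-locked epochs of one percept."""
    series = np.asarray(series, float)
    times = np.asarray(times, float)
    td = labels.triplet_duration
    n_per = int(round(td * rate))
    code = LABEL_CODES[percept]
    epochs = []
    for j in np.flatnonzero(labels.labels == code):
        onset = j * td
        k = int(round((onset - times[0]) * rate))
        if k < 0 or k + n_per > len(series):
            continue
        epochs.append(series[k:k + n_per])
    if len(epochs) < 2:
        raise KoopstreamError(
            f"fewer than 2 {percept} epochs available for averaging")
    epochs = np.array(epochs)
    mean = epochs.mean(axis=0)
    sem = epochs.std(axis=0, ddof=1) / np.sqrt(len(epochs))
    return mean, sem


def profile_similarity(profile_a: np.ndarray,
                       profile_b: np.ndarray) -> float:
    """Pearson correlation between two triplet profiles."""
    a, b = np.asarray(profile_a, float), np.asarray(profile_b, float)
    if len(a) != len(b):
        raise KoopstreamError("profiles must have equal length")
    if a.std() == 0 or b.std() == 0:
        raise KoopstreamError("zero-variance profile")
    return float(sps.pearsonr(a, b).statistic)


def reconstruction_r2(recon_profile: np.ndarray,
                      mean_lfp_profile: np.ndarray) -> float:
    """Coefficient of determination of a reconstruction profile against the
    triplet-averaged standardized LFP profile."""
    y = np.asarray(mean_lfp_profile, float)
    yhat = np.asarray(recon_profile, float)
    if len(y) != len(yhat):
        raise KoopstreamError("profiles must have equal length")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise KoopstreamError("zero-variance target profile")
    return float(1.0 - np.sum((y - yhat) ** 2) / ss_tot)


def motor_control_analysis(phi_star: np.ndarray, times: np.ndarray,
                           matches, rate: float,
                           segment_s: float = 1.2) -> dict:
    """Test whether phase-shift predictions merely reflect the motor act.

    For each transition, the ``segment_s`` stretch of phi_star immediately
    preceding the predicted time is extracted and z-scored; segments are
    pooled per transition direction, projected on their first two principal
    components, and the pb vs bp groups compared with a two-sample rank
    test per component.  Under the null (no motor artifact) p > 0.05.

    ``matches`` is the alignment table from the predictor with an added
    ``direction`` column; rows without one are treated as one direction.
    """
    times = np.asarray(times, float)
    n_seg = int(round(segment_s * rate))
    results = {}
    table = matches[matches["outcome"].isin(["bp", "pb"])]
    directions = table["direction"].unique() if "direction" in table else \
        ["all"]
    for d in directions:
        sub = table if d == "all" else table[table["direction"] == d]
        segs, groups = [], []
        for _, row in sub.iterrows():
            k = int(round((row["predicted_time"] - times[0]) * rate))
            if k - n_seg < 0:
                continue
            seg = np.asarray(phi_star[k - n_seg:k], float)
            sd = seg.std()
            if sd == 0:
                continue
            segs.append((seg - seg.mean()) / sd)
            groups.append(row["outcome"])
        groups = np.array(groups)
        if (groups == "bp").sum() < 2 or (groups == "pb").sum() < 2:
            warnings.warn(f"direction {d}: insufficient events; skipped",
                          RuntimeWarning, stacklevel=2)
            continue
        X = np.array(segs)
        scores = PCA(n_components=2).fit_transform(X)
        pvals = []
        for comp in range(2):
            a = scores[groups == "bp", comp]
            b = scores[groups == "pb", comp]
            pvals.append(float(sps.ranksums(a, b).pvalue))
        results[d] = dict(p_pc1=pvals[0], p_pc2=pvals[1],
                          n_bp=int((groups == "bp").sum()),
                          n_pb=int((groups == "pb").sum()))
    return results


def export_embedding(decomp: KoopmanDecomposition,
                     branches: BranchAssignment,
                     labels: TripletLabels | None = None):
    """Three-dimensional embedding table (t, phi_star, Re/Im of the leading
    J2 oscillator) for manifold visualization."""
    import pandas as pd

    star = branches.phi_star_index
    if star is None:
        raise KoopstreamError("phi_star not located")
    osc = [j for j in branches.J2
           if decomp.frequencies[j] > 0]
    if not osc:
        raise KoopstreamError("no oscillatory J2 eigenfunction to export")
    lead = min(osc, key=lambda j: -decomp.exp_eigvals[j].real)
    out = pd.DataFrame({
        "time_s": decomp.times,
        "phi_star": decomp.eigfuns[:, star].real,
        "re_phi_f": decomp.eigfuns[:, lead].real,
        "im_phi_f": decomp.eigfuns[:, lead].imag,
    })
    if labels is not None:
        out["label"] = labels.sample_labels(decomp.times)
    return out
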