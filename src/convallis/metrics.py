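"""Analysis metrics and the linear spike-count readout.

Population measures of what unsupervised training did to the network:
subthreshold membrane-potential skewness (the quantity the valley objective
drives up), a circular tuning index for the ring task, the one-way ANOVA
F-statistic for per-class spike-count selectivity, CV of inter-spike
intervals and mean pairwise spike-count correlations (asynchronous-irregular
state diagnostics), and a multi-class linear readout trained on spike
counts only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.svm import LinearSVC

__all__ = [
    "CountMatrix",
    "ReadoutModel",
    "subthreshold_skewness",
    "tuning_index",
    "f_statistic",
    "cv_isi",
    "pairwise_correlation",
    "train_readout",
    "evaluate_readout",
]


@dataclass
class CountMatrix:
    """Spike counts (utterances x neurons) with class labels."""

    counts: np.ndarray
    labels: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=np.float64)
        self.labels = np.asarray(self.labels)
        if self.counts.ndim != 2 or len(self.labels) != self.counts.shape[0]:
            raise ValueError("counts must be (n_utterances, n_neurons) with one label per row")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class ReadoutModel:
    model: LinearSVC
    classes: np.ndarray


def subthreshold_skewness(
    voltage_trace,
    spike_times,
    dt: float = 0.1,
    refractory_period: float = 2.0,
    exclusion_window: float = 5.0,
) -> float:
    """Third standardized moment of the subthreshold voltage distribution.

    Samples inside ``[t_spike - 1 ms, t_spike + refractory_period +
    exclusion_window]`` are excised so the stereotyped spike shape and ADP
    transient do not contaminate the subthreshold histogram.
    """
    v = np.asarray(voltage_trace, dtype=np.float64)
    n = len(v)
    keep = np.ones(n, dtype=bool)
    for t in np.asarray(spike_times, dtype=np.float64):
        lo = max(0, int((t - 1.0) / dt))
        hi = min(n, int((t + refractory_period + exclusion_window) / dt) + 1)
        keep[lo:hi] = False
    v = v[keep]
    if len(v) < 3 or np.std(v) == 0:
        raise ValueError("constant or near-empty trace: skewness undefined")
    return float(stats.skew(v, bias=True))


def tuning_index(rates_per_angle) -> float:
    """Resultant-vector length of the rate profile over equally spaced
    angles: |sum r(theta) e^{i theta}| / sum r(theta), in [0, 1]."""
    r = np.asarray(rates_per_angle, dtype=np.float64)
    if np.any(r < 0):
        raise ValueError("rates must be non-negative")
    total = r.sum()
    if total <= 0:
        raise ValueError("tuning undefined for all-zero rates")
    theta = 2.0 * np.pi * np.arange(len(r)) / len(r)
    return float(np.abs(np.sum(r * np.exp(1j * theta))) / total)


def f_statistic(counts, labels) -> float:
    """One-way ANOVA F: between-class mean square over within-class mean
    square, for one neuron's spike counts across stimulus presentations."""
    counts = np.asarray(counts, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    n = len(counts)
    grand = counts.mean()
    ss_between = 0.0
    ss_within = 0.0
    for c in classes:
        x = counts[labels == c]
        if len(x) < 2:
            raise ValueError("need at least two presentations per class")
        ss_between += len(x) * (x.mean() - grand) ** 2
        ss_within += np.sum((x - x.mean()) ** 2)
    if ss_within == 0:
        raise ValueError("zero within-class variance: F undefined")
    df_b = len(classes) - 1
    df_w = n - len(classes)
    return float((ss_between / df_b) / (ss_within / df_w))


def cv_isi(spike_times) -> float:
    """Coefficient of variation of inter-spike intervals (sample s.d. with
    n-1 normalization over mean ISI).  Requires at least 3 spikes."""
    t = np.asarray(spike_times, dtype=np.float64)
    if len(t) < 3:
        raise ValueError("cv_isi requires at least 3 spikes")
    isi = np.diff(t)
    return float(np.std(isi, ddof=1) / np.mean(isi))


def population_cv_isi(spike_trains, min_spikes: int = 5) -> float:
    """Mean CV-ISI over neurons with at least ``min_spikes`` spikes."""
    vals = [cv_isi(t) for t in spike_trains if len(t) >= min_spikes]
    if not vals:
        raise ValueError("no neuron has enough spikes for a CV estimate")
    return float(np.mean(vals))


def pairwise_correlation(
    spike_trains,
    duration: float,
    n_pairs: int = 2000,
    bin_size: float = 5.0,
    seed=None,
    max_resample: int = 50,
) -> float:
    """Mean Pearson correlation of binned spike counts over randomly sampled
    distinct neuron pairs.  Pairs containing a zero-variance train are
    resampled."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = len(spike_trains)
    if n < 2:
        raise ValueError("need at least two neurons")
    n_bins = int(np.ceil(duration / bin_size))
    binned = np.stack(
        [
            np.bincount(
                np.minimum((np.asarray(t) / bin_size).astype(int), n_bins - 1),
                minlength=n_bins,
            )
            for t in spike_trains
        ]
    ).astype(np.float64)
    var = binned.var(axis=1)
    alive = np.nonzero(var > 0)[0]
    if len(alive) < 2:
        raise ValueError("fewer than two neurons with variable counts")
    coeffs = []
    trials = 0
    while len(coeffs) < n_pairs and trials < n_pairs * max_resample:
        i, j = rng.choice(alive, size=2, replace=False)
        trials += 1
        c = np.corrcoef(binned[i], binned[j])[0, 1]
        coeffs.append(c)
    return float(np.mean(coeffs))


def train_readout(A: CountMatrix, cost: float = 0.01, seed: int = 0) -> ReadoutModel:
    """Multi-class linear large-margin readout on spike counts.

    One-vs-rest linear SVM (cost parameter C = 0.01 by default); prediction
    is the argmax over the per-class scores.
    """
    classes = np.unique(A.labels)
    if len(classes) < 2:
        raise ValueError("single-class training set")
    model = LinearSVC(C=cost, multi_class="ovr", random_state=seed, max_iter=20000)
    model.fit(A.counts, A.labels)
    return ReadoutModel(model=model, classes=classes)


def evaluate_readout(model: ReadoutModel, A_test: CountMatrix) -> float:
    """Fraction of test utterances misclassified."""
    pred = model.model.predict(A_test.counts)
    return float(np.mean(pred != A_test.labels))
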