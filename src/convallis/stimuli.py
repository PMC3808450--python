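"""Synthetic input ensembles.

Two stimulus families drive the unsupervised-learning experiments:

* a circular-Gaussian ensemble — a ring of excitatory Poisson sources whose
  rate profile is a wrapped Gaussian bump re-centred at a random position
  every 100 ms, plus constant-rate inhibitory background sources;

* a synthetic "digit" ensemble — multi-class spatiotemporal intensity
  matrices (frequency channels x time, 1 s epochs at 500 Hz) standing in for
  a cochleogram front-end: a shared pool of spectral "notes" is drawn once
  and each class is a fixed timed sequence of two-note chords from that
  pool; each simulated "speaker" is a structured distortion of the class
  template (time warp, channel jitter, amplitude noise), and every
  utterance is normalized to equal summed activity before being encoded as
  inhomogeneous Poisson spike trains with a 5 Hz grand-mean rate.

Generators are deterministic given (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_sim import SpikeTrainSet, poisson_spike_trains

__all__ = [
    "CircularEnsembleSpec",
    "SyntheticDigitSpec",
    "Utterance",
    "IntensityEnsemble",
    "circular_gaussian_rates",
    "synthesize_digit_ensemble",
    "normalize_utterance",
    "encode_poisson_ensemble",
]


# ---------------------------------------------------------------------------
# Circular-Gaussian ensemble
# ---------------------------------------------------------------------------


@dataclass
class CircularEnsembleSpec:
    n_excitatory: int = 1000
    n_inhibitory: int = 250
    hold_duration: float = 100.0  # ms
    profile_width: float = 0.05  # fraction of the ring
    peak_rate: float = 30.0  # Hz
    inhibitory_rate: float = 10.0  # Hz
    duration: float = 1000.0  # ms

    def __post_init__(self):
        if self.n_excitatory <= 0 or self.n_inhibitory < 0:
            raise ValueError("population counts must be positive")
        if not 0.0 < self.profile_width < 0.5:
            raise ValueError("profile_width must lie in (0, 0.5)")
        if self.peak_rate < 0 or self.inhibitory_rate < 0:
            raise ValueError("rates must be non-negative")


def circular_gaussian_rates(spec: CircularEnsembleSpec, rng=None):
    """Piecewise-constant rate matrix (n_excitatory, n_holds) in Hz.

    Within each hold of ``hold_duration`` ms, source i fires at
    ``peak_rate * exp(-d(i, c)^2 / (2 sigma^2))`` where d is circular
    distance on the ring, sigma = profile_width * n_excitatory, and the
    centre c is drawn uniformly over all positions per hold.  Returns
    ``(rates, centers)``.
    """
    rng = rng if isinstance(rng, np.random.Generator) else np.random.default_rng(rng)
    n = spec.n_excitatory
    n_holds = int(round(spec.duration / spec.hold_duration))
    sigma = spec.profile_width * n
    centers = rng.integers(0, n, size=n_holds)
    idx = np.arange(n)
    rates = np.empty((n, n_holds))
    for h, c in enumerate(centers):
        d = np.abs(idx - c)
        d = np.minimum(d, n - d)
        rates[:, h] = spec.peak_rate * np.exp(-(d**2) / (2.0 * sigma**2))
    return rates, centers


# ---------------------------------------------------------------------------
# Synthetic digit ensemble
# ---------------------------------------------------------------------------


@dataclass
class SyntheticDigitSpec:
    n_classes: int = 11
    n_channels: int = 93
    epoch_length: float = 1000.0  # ms
    sample_rate: float = 500.0  # Hz
    n_speakers_train: int = 8
    n_speakers_test: int = 4
    n_utterances_per_speaker: int = 2
    time_warp: float = 0.10  # +/- fractional warp per speaker
    channel_jitter: int = 2  # +/- channels per speaker
    amplitude_noise: float = 0.20  # multiplicative, per ridge
    mean_input_rate: float = 5.0  # Hz, grand mean after encoding
    n_notes: int = 8  # shared spectral pool size; n_notes//2 chords per class

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("need at least two classes")
        if self.n_channels < 4:
            raise ValueError("need at least four channels")
        if self.mean_input_rate < 0:
            raise ValueError("mean_input_rate must be non-negative")

    @property
    def n_bins(self) -> int:
        return int(round(self.epoch_length * self.sample_rate * 1e-3))

    @property
    def bin_width(self) -> float:
        return 1000.0 / self.sample_rate  # ms


@dataclass
class Utterance:
    intensity: np.ndarray  # (n_channels, n_bins), non-negative
    label: int
    speaker: int


@dataclass
class IntensityEnsemble:
    utterances: list
    spec: SyntheticDigitSpec
    templates: np.ndarray | None = None  # (n_classes, n_channels, n_bins)

    def split(self):
        """(train, test) utterance lists with disjoint speaker sets."""
        train = [u for u in self.utterances if u.speaker < self.spec.n_speakers_train]
        test = [u for u in self.utterances if u.speaker >= self.spec.n_speakers_train]
        return train, test

    def labels(self) -> np.ndarray:
        return np.array([u.label for u in self.utterances])


def _note_pool(spec, rng):
    """Shared spectral 'notes': Gaussian channel profiles reused by every
    class, so long-run channel marginals overlap strongly across classes."""
    n_notes = spec.n_notes
    centers = rng.uniform(6, spec.n_channels - 6, size=n_notes)
    # keep notes spectrally separated so chords are distinguishable
    centers = np.sort(centers)
    span = spec.n_channels - 12
    centers = 6 + (centers - centers.min()) / max(np.ptp(centers), 1e-9) * span
    return dict(
        centers_c=centers,
        widths_c=rng.uniform(2.0, 4.0, size=n_notes),
    )


def _draw_class_params(spec, rng, pool, used_pairings):
    """A class is a timed sequence of chords (simultaneous note pairs).

    Every class uses each pool note exactly once (a disjoint pairing of the
    pool), so time-integrated channel energy is nearly class-invariant and
    class identity lives in which notes co-occur and when.  Small per-class
    amplitude variation leaves a weak marginal signature, keeping a
    counts-only classifier above chance but far from perfect.
    """
    n_notes = len(pool["centers_c"])
    k = n_notes // 2
    while True:
        perm = rng.permutation(n_notes)
        pairing = tuple(
            tuple(sorted((int(perm[2 * i]), int(perm[2 * i + 1])))) for i in range(k)
        )
        if frozenset(pairing) not in used_pairings:
            used_pairings.add(frozenset(pairing))
            break
    # chord times: random over the epoch with a minimum separation, so the
    # temporal layout itself differs between classes
    lo, hi = 0.15 * spec.epoch_length, 0.85 * spec.epoch_length
    min_gap = (hi - lo) / (2.0 * k)
    while True:
        times = np.sort(rng.uniform(lo, hi, size=k))
        if k < 2 or np.min(np.diff(times)) >= min_gap:
            break
    return dict(
        chords=[np.array(p) for p in pairing],
        centers_t=times,
        widths_t=rng.uniform(45.0, 65.0, size=k),
        amps=rng.uniform(0.9, 1.1, size=k),
    )


def _chord_matrix(spec, pool, chords, centers_t, widths_t, amps,
                  jitter=0, warp=1.0, amp_noise=None):
    ch = np.arange(spec.n_channels)[:, None]
    t = (np.arange(spec.n_bins) * spec.bin_width)[None, :]  # ms
    t_mid = 0.5 * spec.epoch_length
    m = np.zeros((spec.n_channels, spec.n_bins))
    if amp_noise is None:
        amp_noise = np.ones(len(chords))
    for chord, ct, wt, a, an in zip(chords, centers_t, widths_t, amps, amp_noise):
        env = np.exp(-((t - (t_mid + (ct - t_mid) * warp)) ** 2)
                     / (2.0 * (wt * warp) ** 2))
        prof = np.zeros((spec.n_channels, 1))
        for note in chord:
            cc = pool["centers_c"][note] + jitter
            wc = pool["widths_c"][note]
            prof += np.exp(-((ch - cc) ** 2) / (2.0 * wc**2))
        m += a * an * prof * env
    return m


def synthesize_digit_ensemble(spec: SyntheticDigitSpec, seed=None) -> IntensityEnsemble:
    """Generate the labeled intensity ensemble.

    A shared pool of spectral notes is drawn once; each class is a fixed
    timed sequence of two-note chords from that pool.  Every (class, speaker)
    realization re-evaluates the sequence under a speaker-specific time warp
    (centre-anchored), integer channel jitter, and per-chord multiplicative
    amplitude noise.  Train and test speakers are disjoint by index; each
    utterance is normalized to the same summed activity.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pool = _note_pool(spec, rng)
    used = set()
    class_params = []
    accepted = []
    for _ in range(spec.n_classes):
        # generator self-test: redraw until the new class template is only
        # weakly correlated with every accepted one
        best, best_corr = None, np.inf
        for _attempt in range(60):
            p = _draw_class_params(spec, rng, pool, used)
            m = _chord_matrix(spec, pool, **p).ravel()
            c = max(
                (abs(np.corrcoef(m, q)[0, 1]) for q in accepted), default=0.0
            )
            if c < best_corr:
                best, best_corr, best_m = p, c, m
            if c < 0.45:
                break
        class_params.append(best)
        accepted.append(best_m)
    templates = np.stack(
        [_chord_matrix(spec, pool, **p) for p in class_params]
    )
    n_speakers = spec.n_speakers_train + spec.n_speakers_test
    utterances = []
    for s in range(n_speakers):
        for c in range(spec.n_classes):
            p = class_params[c]
            warp = 1.0 + rng.uniform(-spec.time_warp, spec.time_warp)
            jit = int(rng.integers(-spec.channel_jitter, spec.channel_jitter + 1)) \
                if spec.channel_jitter else 0
            for _ in range(spec.n_utterances_per_speaker):
                amp_noise = 1.0 + rng.uniform(
                    -spec.amplitude_noise, spec.amplitude_noise, size=len(p["amps"])
                )
                m = _chord_matrix(
                    spec, pool, **p, jitter=jit, warp=warp, amp_noise=amp_noise
                )
                utterances.append(
                    Utterance(intensity=normalize_utterance(m), label=c, speaker=s)
                )
    return IntensityEnsemble(utterances=utterances, spec=spec, templates=templates)


def normalize_utterance(intensity: np.ndarray, target: float | None = None) -> np.ndarray:
    """Scale a non-negative intensity matrix so its total sum equals a global
    constant (default: one unit of intensity per matrix cell).  Idempotent
    and invariant to input scaling."""
    intensity = np.asarray(intensity, dtype=np.float64)
    if np.any(intensity < 0):
        raise ValueError("intensity must be non-negative")
    total = intensity.sum()
    if total <= 0:
        raise ValueError("cannot normalize an all-zero intensity matrix")
    if target is None:
        target = float(intensity.size)
    return intensity * (target / total)


def encode_poisson_ensemble(
    ensemble: IntensityEnsemble, mean_rate: float | None = None, seed=None
):
    """Encode every utterance as inhomogeneous Poisson spike trains.

    Per-channel rate is proportional to intensity, globally scaled so the
    grand mean rate across channels and time equals ``mean_rate`` (the
    normalization fixes each utterance's mean intensity at 1, so the scale
    factor is simply ``mean_rate``).  Returns a list of
    ``(SpikeTrainSet, label, speaker)`` triples.
    """
    spec = ensemble.spec
    if mean_rate is None:
        mean_rate = spec.mean_input_rate
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for u in ensemble.utterances:
        rates = u.intensity * mean_rate
        trains = poisson_spike_trains(rates, spec.bin_width, seed=rng)
        out.append((trains, u.label, u.speaker))
    return out


def encode_utterance(u: Utterance, spec: SyntheticDigitSpec, rng) -> SpikeTrainSet:
    """Fresh Poisson realization of a single utterance."""
    return poisson_spike_trains(
        u.intensity * spec.mean_input_rate, spec.bin_width, seed=rng
    )
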