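"""Synthetic ripple-vocalization corpora with known spectro-temporal structure.

Real song/speech corpora place song energy at high spectral and low temporal
modulation rates (fine harmonic structure, slow syllables) and speech energy
at low spectral and fast temporal rates (syllable rates of roughly 4-8 Hz).
This module builds surrogate "vocalizations" — moving ripples — whose
spectro-temporal modulation (STM) coordinates are drawn from class
distributions centred on those signatures, organised as within-speaker
song/speech pairs grouped into societies. Listener-rating tables and
multi-feature acoustic tables correlated with the STM plane are simulated on
top, so that every downstream stage (contrast maps, decoding, behaviour
linkage, PLS/VIP) can be validated against ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import DataError, ParameterError

__all__ = [
    "RippleSpec",
    "CorpusSpec",
    "Vocalization",
    "synth_ripple",
    "synth_corpus",
    "synth_ratings",
    "synth_acoustic_table",
    "make_default_loading_map",
    "injected_region",
    "RATING_LEVELS",
]

#: The five permitted rating levels: "surely speaking" (-1) to "surely
#: singing" (+1).
RATING_LEVELS = np.array([-1.0, -0.5, 0.0, 0.5, 1.0])

#: Class centres in the (spectral cyc/kHz, temporal Hz) modulation plane.
SONG_CENTER = (3.5, 0.7)
SPEECH_CENTER = (0.1, 6.0)


@dataclass(frozen=True)
class Vocalization:
    """A single mono recording plus the metadata the analyses group by."""

    samples: np.ndarray
    rate: float
    speaker_id: str
    category: str  # "song" or "speech"
    fieldsite: str = ""
    country: str = ""
    language_family: str = ""
    subregion: str = ""
    region: str = ""

    @property
    def duration_s(self) -> float:
        return len(self.samples) / self.rate

    def meta(self) -> dict:
        return {
            "speaker_id": self.speaker_id,
            "category": self.category,
            "fieldsite": self.fieldsite,
            "country": self.country,
            "language_family": self.language_family,
            "subregion": self.subregion,
            "region": self.region,
            "duration_s": self.duration_s,
        }


@dataclass(frozen=True)
class RippleSpec:
    """Parameters of one moving ripple.

    The ripple's linear-frequency spectrogram envelope is

        1 + depth * cos(2*pi*(temporal_mod * t + spectral_mod * f_kHz) + phase)

    over a harmonic carrier spanning ``carrier_lo``..``carrier_hi`` Hz.
    ``spectral_mod`` is in cycles per kHz (>= 0); ``temporal_mod`` is in Hz and
    signed (the sign sets the drift direction of the spectro-temporal grating).
    """

    spectral_mod: float
    temporal_mod: float
    depth: float = 0.9
    carrier_lo: float = 25.0
    carrier_hi: float = 7900.0
    phase: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.depth <= 1.0:
            raise ParameterError(f"depth must be in [0, 1], got {self.depth}")
        if self.spectral_mod < 0:
            raise ParameterError(
                f"spectral_mod must be >= 0 cyc/kHz, got {self.spectral_mod}"
            )
        if not self.carrier_lo < self.carrier_hi:
            raise ParameterError(
                f"carrier band empty: [{self.carrier_lo}, {self.carrier_hi}]"
            )


def _newman_phases(n: int) -> np.ndarray:
    # Deterministic low-crest-factor phases for a multi-sine carrier.
    k = np.arange(n, dtype=float)
    return np.pi * k * (k + 1.0) / n


def carrier_freqs(lo: float, hi: float, spacing_hz: float = 25.0) -> np.ndarray:
    """Component frequencies of the dense multi-sine carrier.

    Components are linearly spaced more closely than the spectrogram's
    frequency resolution, so the carrier's own spectral envelope is smooth at
    the analysis scale and the only off-origin modulation energy is the
    ripple's.
    """
    return np.arange(lo, hi + spacing_hz / 2, spacing_hz)


def synth_ripple(
    spec: RippleSpec,
    duration_s: float,
    rate: float,
    component_spacing_hz: float = 25.0,
    component_phases: np.ndarray | None = None,
    component_gains: np.ndarray | None = None,
    extra_mods: Sequence[tuple[float, float, float, float]] = (),
) -> Vocalization:
    """Synthesize a moving ripple as a dense sum of amplitude-modulated
    sinusoids.

    The deterministic multi-sine carrier (rather than noise) keeps the
    spectrogram envelope analytic, which is what makes the modulogram
    transform testable against closed-form expectations. Each modulated
    component g_k [1 + depth cos(2pi(w t + O f_k/1000) + phase)] sin(2pi f_k t
    + psi_k) is exactly a carrier line at f_k plus two AM sidebands at
    f_k +/- w, so the waveform is built by placing those spectral lines on
    the signal-length DFT grid and inverting — identical to the time-domain
    sum up to a frequency quantization of 1/duration Hz.

    ``extra_mods`` adds further envelope terms ``(spectral_mod, temporal_mod,
    depth, phase)`` on the same carrier — used by the corpus generator to give
    each vocalization a broadband modulation "texture" on top of its dominant
    ripple, the way natural vocal sounds are never single gratings.
    """
    if duration_s <= 0:
        raise ParameterError(f"duration_s must be > 0, got {duration_s}")
    if spec.temporal_mod != 0 and duration_s < 1.0 / abs(spec.temporal_mod):
        raise ParameterError(
            f"duration {duration_s:.3f} s holds less than one cycle of the "
            f"{spec.temporal_mod:.3f} Hz temporal modulation"
        )
    if rate < 2.0 * spec.carrier_hi:
        raise ParameterError(
            f"rate {rate} Hz below Nyquist for carrier_hi={spec.carrier_hi} Hz"
        )

    n = int(round(duration_s * rate))
    freqs = carrier_freqs(spec.carrier_lo, spec.carrier_hi, component_spacing_hz)
    if component_phases is None:
        component_phases = _newman_phases(len(freqs))
    if component_gains is None:
        component_gains = np.ones(len(freqs))
    psi = np.asarray(component_phases, dtype=float)
    g = np.asarray(component_gains, dtype=float)

    spectrum = np.zeros(n // 2 + 1, dtype=complex)

    def _add_lines(freq_hz: np.ndarray, amp: np.ndarray, phase: np.ndarray) -> None:
        # A*sin(2*pi*f*t + p) -> rfft bin round(f*n/rate) with (n/2)*A*e^{i(p-pi/2)}
        keep = (freq_hz > 0) & (freq_hz < rate / 2.0)
        bins = np.round(freq_hz[keep] * n / rate).astype(int)
        np.add.at(spectrum, bins, 0.5 * n * amp[keep] * np.exp(1j * (phase[keep] - np.pi / 2)))

    _add_lines(freqs, g, psi)
    mods = [(spec.spectral_mod, spec.temporal_mod, spec.depth, spec.phase), *extra_mods]
    for s_mod, t_mod, depth, phase in mods:
        # sideband phase offset per component: chi_k = 2*pi*O*f_k/1000 + phase
        chi = 2.0 * np.pi * s_mod * freqs / 1000.0 + phase
        _add_lines(freqs + t_mod, 0.5 * depth * g, psi + chi)
        _add_lines(freqs - t_mod, 0.5 * depth * g, psi - chi)
    wave = np.fft.irfft(spectrum, n)
    peak = np.abs(wave).max()
    if peak > 0:
        wave = 0.95 * wave / peak
    return Vocalization(samples=wave, rate=rate, speaker_id="", category="")


@dataclass(frozen=True)
class CorpusSpec:
    """Study-condition parameters of a synthetic paired corpus.

    Defaults emulate the desk-scale version of a 21-society paired corpus
    (15 speakers per society, the median society size of the source corpus),
    with song ripples centred at (3.5 cyc/kHz, 0.7 Hz) and speech ripples at
    (0.1 cyc/kHz, 6 Hz). ``effect_size`` scales the class separation about the
    midpoint: 0 gives a null corpus with identical class distributions,
    1 the nominal separation.

    ``clarity_sd`` controls a per-society multiplier on the class separation,
    emulating the fact that some societies' song and speech styles are
    acoustically closer than others'; this is the shared driver that makes
    machine decodability and listener separability covary across societies.
    ``speaker_clarity_sd`` adds the same kind of variation at the speaker
    level (some individuals sing in a speech-like way and vice versa), and
    ``texture_n``/``texture_depth`` give every vocalization a broadband
    modulation background so no cell of the analysis plane is noise-free.
    """

    n_groups: int = 21
    speakers_per_group: int | Sequence[int] = 15
    duration_s: tuple[float, float] = (2.5, 5.0)
    sample_rate: float = 16000.0
    effect_size: float = 1.0
    seed: int = 0
    class_params: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"song": SONG_CENTER, "speech": SPEECH_CENTER}
    )
    group_sd: tuple[float, float] = (0.3, 0.5)
    speaker_sd: tuple[float, float] = (0.35, 0.6)
    voc_sd: tuple[float, float] = (0.15, 0.25)
    clarity_sd: float = 0.5
    speaker_clarity_sd: float = 0.25
    depth_mean: float = 0.7
    depth_sd: float = 0.1
    carrier: tuple[float, float] = (25.0, 7900.0)
    component_spacing_hz: float = 25.0
    noise_db: float = -35.0
    min_temporal_hz: float = 0.6
    texture_n: int = 3
    texture_depth: float = 0.04
    texture_span: tuple[float, float, float] = (8.0, 0.5, 9.0)  # spectral max, |temporal| lo/hi

    def __post_init__(self) -> None:
        if self.n_groups < 2:
            raise ParameterError(f"n_groups must be >= 2, got {self.n_groups}")
        lo, hi = self.duration_s
        if lo <= 0 or hi < lo:
            raise ParameterError(f"invalid duration range {self.duration_s}")
        if set(self.class_params) != {"song", "speech"}:
            raise ParameterError("class_params must define 'song' and 'speech'")

    def group_sizes(self) -> list[int]:
        if isinstance(self.speakers_per_group, int):
            return [self.speakers_per_group] * self.n_groups
        sizes = list(self.speakers_per_group)
        if len(sizes) != self.n_groups:
            raise ParameterError(
                f"speakers_per_group has {len(sizes)} entries for "
                f"{self.n_groups} groups"
            )
        return sizes


def _group_labels(g: int) -> dict:
    # Nested coarser groupings: societies share countries, countries share
    # language families, etc., so every CV grouping level has >= 2 labels.
    return {
        "fieldsite": f"site{g:02d}",
        "country": f"country{g // 2:02d}",
        "language_family": f"family{g // 3:02d}",
        "subregion": f"subregion{g // 4:02d}",
        "region": f"region{g // 5:02d}",
    }


def synth_corpus(spec: CorpusSpec) -> list[Vocalization]:
    """Generate the paired corpus: one song and one speech per speaker.

    Within a speaker, the carrier component phases/gains and the (group,
    speaker) coordinate offsets are shared between the two categories — the
    synthetic analogue of voice identity — so only the class-dependent ripple
    coordinates (plus small per-vocalization jitter) distinguish song from
    speech. Deterministic given ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    song_c = np.array(spec.class_params["song"], dtype=float)
    speech_c = np.array(spec.class_params["speech"], dtype=float)
    midpoint = 0.5 * (song_c + speech_c)
    group_sd = np.asarray(spec.group_sd)
    speaker_sd = np.asarray(spec.speaker_sd)
    voc_sd = np.asarray(spec.voc_sd)
    dur_lo, dur_hi = spec.duration_s
    noise_amp = 10.0 ** (spec.noise_db / 20.0)

    corpus: list[Vocalization] = []
    for g, n_speakers in enumerate(spec.group_sizes()):
        labels = _group_labels(g)
        clarity = float(np.clip(rng.normal(1.0, spec.clarity_sd), 0.4, 1.7))
        group_offset = rng.normal(0.0, group_sd)
        freqs = carrier_freqs(spec.carrier[0], spec.carrier[1], spec.component_spacing_hz)
        for s in range(n_speakers):
            speaker_id = f"s{g:02d}_{s:02d}"
            speaker_offset = rng.normal(0.0, speaker_sd)
            spk_clarity = float(np.clip(rng.normal(1.0, spec.speaker_clarity_sd), 0.3, 1.8))
            phases = rng.uniform(0.0, 2.0 * np.pi, len(freqs))
            # smooth per-speaker spectral tilt: the "voice" colouration shared
            # by the speaker's song and speech (static, low spectral mod)
            coeffs = rng.normal(0.0, 0.15, 3)
            thetas = rng.uniform(0.0, 2.0 * np.pi, 3)
            j = np.arange(1, 4)
            gains = np.exp(
                (coeffs[None, :] * np.cos(
                    2.0 * np.pi * j[None, :] * freqs[:, None] / (2 * spec.carrier[1])
                    + thetas[None, :]
                )).sum(axis=1)
            )
            durations = rng.uniform(dur_lo, dur_hi, 2)
            for category, center, dur in zip(
                ("song", "speech"), (song_c, speech_c), durations
            ):
                shifted = midpoint + spec.effect_size * clarity * spk_clarity * (center - midpoint)
                coord = shifted + group_offset + speaker_offset + rng.normal(0.0, voc_sd)
                spectral = max(coord[0], 0.0)
                temporal = max(coord[1], spec.min_temporal_hz)
                tsign = 1.0 if rng.random() < 0.5 else -1.0
                depth = float(np.clip(rng.normal(spec.depth_mean, spec.depth_sd), 0.2, 0.8))
                # broadband modulation texture: low-depth ripples at random
                # coordinates, different for every vocalization
                s_max, t_lo, t_hi = spec.texture_span
                extra = [
                    (
                        float(rng.uniform(0.0, s_max)),
                        float(rng.uniform(t_lo, t_hi) * (1 if rng.random() < 0.5 else -1)),
                        float(np.clip(np.abs(rng.normal(0.0, 1.25 * spec.texture_depth)), 0.02, 0.3)),
                        float(rng.uniform(0.0, 2.0 * np.pi)),
                    )
                    for _ in range(spec.texture_n)
                ]
                ripple = RippleSpec(
                    spectral_mod=spectral,
                    temporal_mod=tsign * temporal,
                    depth=depth,
                    carrier_lo=spec.carrier[0],
                    carrier_hi=spec.carrier[1],
                    phase=rng.uniform(0.0, 2.0 * np.pi),
                )
                voc = synth_ripple(
                    ripple,
                    duration_s=dur,
                    rate=spec.sample_rate,
                    component_spacing_hz=spec.component_spacing_hz,
                    component_phases=phases,
                    component_gains=gains,
                    extra_mods=extra,
                )
                wave = voc.samples + noise_amp * rng.standard_normal(len(voc.samples))
                wave = wave / np.sqrt((wave**2).mean())  # constant RMS across corpus
                corpus.append(
                    Vocalization(
                        samples=wave,
                        rate=spec.sample_rate,
                        speaker_id=speaker_id,
                        category=category,
                        **labels,
                    )
                )
    return corpus


def injected_region(
    spectral_axis: np.ndarray,
    temporal_axis: np.ndarray,
    spec: CorpusSpec,
    radius_scale: float = 1.8,
    harmonics: bool = False,
) -> np.ndarray:
    """Boolean (n_spectral, n_temporal) mask of the modulation-plane region the
    corpus generator concentrates class energy in (both temporal signs).

    The region is the union of ellipses of ``radius_scale`` total jitter
    standard deviations around each class centre after applying
    ``effect_size``; with ``harmonics`` it also includes the (2*spectral,
    2*temporal) images that the magnitude spectrogram of an AM signal carries
    (the short-time magnitude of carrier + asymmetrically windowed sidebands
    is not a pure sinusoid in time). Used as ground truth for weight-map
    recovery checks.
    """
    sd = np.sqrt(
        np.asarray(spec.group_sd) ** 2
        + np.asarray(spec.speaker_sd) ** 2
        + np.asarray(spec.voc_sd) ** 2
    )
    song_c = np.array(spec.class_params["song"], dtype=float)
    speech_c = np.array(spec.class_params["speech"], dtype=float)
    midpoint = 0.5 * (song_c + speech_c)
    S, T = np.meshgrid(spectral_axis, temporal_axis, indexing="ij")
    mask = np.zeros_like(S, dtype=bool)
    for center in (song_c, speech_c):
        c = midpoint + spec.effect_size * (center - midpoint)
        centers = [(c, 1.0)]
        if harmonics:
            centers.append((2.0 * c, 2.0))
        for cc, mult in centers:
            for tsign in (1.0, -1.0):
                d2 = ((S - cc[0]) / (mult * radius_scale * sd[0])) ** 2 + (
                    (T - tsign * cc[1]) / (mult * radius_scale * sd[1])
                ) ** 2
                mask |= d2 <= 1.0
    return mask


def synth_ratings(
    stm,
    template: np.ndarray,
    noise_sd: float = 0.3,
    n_listeners: int = 24,
    gain: float = 1.2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate listeners rating each vocalization on the 5-point
    speaking(-1)..singing(+1) scale.

    Each listener's continuous judgment of a vocalization is a saturating
    (tanh) read-out of the projection of its modulogram onto ``template``
    (a weight map on the same grid, e.g. a contrast statistic map), plus
    Gaussian listener noise, quantized to the five permitted levels. Grid
    cells are standardized across the corpus before projecting — listeners
    judge deviations from what is typical, not absolute power, which keeps a
    few high-energy recordings from dominating the score scale. The
    projection itself is z-scored across the corpus before the tanh.
    Deterministic given ``seed``.
    """
    template = np.asarray(template, dtype=float)
    n_cells = stm.X.shape[1]
    if template.size != n_cells:
        raise ParameterError(
            f"template has {template.size} cells, modulogram grid has {n_cells}"
        )
    if n_listeners < 1:
        raise ParameterError("n_listeners must be >= 1")
    Z = stm.X - stm.X.mean(axis=0)
    cell_sd = stm.X.std(axis=0)
    nz = cell_sd > 0
    Z[:, nz] = Z[:, nz] / cell_sd[nz]
    score = Z @ template.ravel()
    sd = score.std()
    if sd == 0:
        raise DataError("template projection is constant across the corpus")
    z = (score - score.mean()) / sd

    rng = np.random.default_rng(seed)
    meta = stm.meta
    stim_ids = (meta["speaker_id"] + "_" + meta["category"]).to_numpy()
    rows = []
    for li in range(n_listeners):
        noise = rng.normal(0.0, noise_sd, len(z)) if noise_sd > 0 else 0.0
        cont = np.tanh(gain * z + noise)
        levels = RATING_LEVELS[np.abs(cont[:, None] - RATING_LEVELS[None, :]).argmin(axis=1)]
        rts = rng.uniform(0.8, 5.0, len(z))
        for stim, r, rt in zip(stim_ids, levels, rts):
            rows.append((f"listener{li:03d}", stim, r, rt))
    ratings = pd.DataFrame(rows, columns=["listener_id", "stimulus_id", "rating", "rt_s"])
    return ratings


#: Canonical acoustic-variable names mirroring the kinds of descriptors found
#: in conventional speech/song feature sets, with their label groups.
_NAMED_FEATURES = [
    ("pitch_f0_median", "pitch"),
    ("pitch_f0_iqr", "pitch"),
    ("pitch_space", "pitch"),
    ("first_formant_median", "formants"),
    ("second_formant_median", "formants"),
    ("vowel_space", "formants"),
    ("intensity_median", "intensity"),
    ("amplitude_space", "intensity"),
    ("vowel_rate", "rhythm"),
    ("pulse_rate", "rhythm"),
    ("temporal_modulation_rate", "rhythm"),
    ("roughness_median", "timbre"),
    ("harmonicity_median", "timbre"),
    ("spectral_centroid", "timbre"),
]


def make_default_loading_map(
    spectral_axis: np.ndarray,
    temporal_axis: np.ndarray,
    n_features: int = 98,
    seed: int = 0,
) -> dict[str, tuple[str, list[tuple[tuple[float, float], float]]]]:
    """Build a feature -> (label, [((spectral, temporal), weight), ...]) map.

    Pitch/formant-type features load on the song region (high spectral, low
    temporal modulation), rhythm-type features on the speech region (low
    spectral, ~6 Hz temporal); filler features load on random cells; the last
    ~15% of features have all-zero loadings (pure-noise negative controls).
    """
    rng = np.random.default_rng(seed)
    song_cells = [(SONG_CENTER, 1.0), ((SONG_CENTER[0], -SONG_CENTER[1]), 0.6)]
    speech_cells = [(SPEECH_CENTER, 1.0), ((SPEECH_CENTER[0], -SPEECH_CENTER[1]), 0.6)]
    loading_map: dict[str, tuple[str, list]] = {}
    for name, label in _NAMED_FEATURES[: min(len(_NAMED_FEATURES), n_features)]:
        base = speech_cells if label == "rhythm" else song_cells
        jitter = [(c, w * rng.uniform(0.7, 1.3)) for c, w in base]
        loading_map[name] = (label, jitter)
    n_controls = max(1, int(round(0.15 * n_features)))
    n_filler = n_features - len(loading_map) - n_controls
    for i in range(max(n_filler, 0)):
        s = float(rng.uniform(spectral_axis.min(), spectral_axis.max()))
        t = float(rng.uniform(temporal_axis.min(), temporal_axis.max()))
        loading_map[f"misc_feature_{i:02d}"] = ("other", [((s, t), rng.uniform(0.5, 1.5))])
    i = 0
    while len(loading_map) < n_features:
        loading_map[f"noise_control_{i:02d}"] = ("control", [])
        i += 1
    return loading_map


def synth_acoustic_table(
    stm,
    loading_map: Mapping[str, tuple[str, list]] | None = None,
    n_features: int = 98,
    noise_sd: float = 0.5,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a conventional acoustic-feature table as noisy linear reads of
    STM grid cells.

    Returns ``(features, labels)``: a samples x features table (rows aligned
    with ``stm`` rows) and a (feature, label) map. Features with empty
    loadings are pure noise.
    """
    if loading_map is None:
        loading_map = make_default_loading_map(
            stm.spectral_axis, stm.temporal_axis, n_features=n_features, seed=seed
        )
    rng = np.random.default_rng(seed)
    Z = stm.X - stm.X.mean(axis=0)
    sd = stm.X.std(axis=0)
    nz = sd > 0
    Z[:, nz] = Z[:, nz] / sd[nz]
    cols = {}
    labels = []
    for name, (label, loadings) in loading_map.items():
        value = np.zeros(stm.X.shape[0])
        for (s, t), w in loadings:
            value += w * Z[:, stm.cell_index(s, t)]
        value = value + rng.normal(0.0, noise_sd, len(value))
        cols[name] = value
        labels.append((name, label))
    features = pd.DataFrame(cols)
    label_map = pd.DataFrame(labels, columns=["feature", "label"])
    return features, label_map
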