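"""Synthetic multi-subject, two-condition EEG with known ground truth.

Generates 64-channel "recordings" for a paired sea-level vs. high-altitude
design so that every downstream quantity — aperiodic exponent, band powers,
phase-lagged coupling, condition contrasts, age dependence — can be checked
by parameter recovery.

Generative model per channel::

    x(t) = aperiodic(chi) + sum_b A_b * narrowband_b(t) + coupled sources + noise

* Aperiodic background: white Gaussian noise shaped in the frequency domain
  by f^(-chi/2) (so its population PSD is proportional to f^-chi), variance
  normalized to 1.  The exponent chi is ``exponent_base`` minus an age trend,
  plus a condition offset at altitude.
* Oscillations: Gaussian-envelope narrowband noise (white noise whose FFT is
  weighted by a Gaussian around the center frequency), giving realistic
  spectral peaks for the peak-stripping stage of the 1/f fit.
* Coupling: a shared narrowband source injected into a set of channels, with
  a constant phase rotation (frequency-domain, applied over the source's
  support) accumulating per channel; wPLI between the channels recovers the
  programmed lag structure.  Zero lag deliberately produces no wPLI.

The model contains no blinks, muscle artifacts, line noise, or volume
conduction — what passing recovery tests show is correctness of the
analysis chain, not robustness to real-world contamination.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .channels import BIOSEMI64_LABELS, default_region_map
from .preprocess import BANDS, CONDITIONS, Recording

__all__ = [
    "ConditionEffects",
    "Oscillation",
    "CouplingSpec",
    "SynthConfig",
    "GroundTruth",
    "generate_aperiodic_noise",
    "generate_narrowband_noise",
    "generate_coupled_pair",
    "generate_study",
    "save_study",
    "load_study",
]


@dataclass
class ConditionEffects:
    """Multiplicative/additive effects applied in the altitude condition.

    Defaults encode the qualitative result pattern of acute high-altitude
    hypoxia: spectral slowing (delta power up, alpha power down), a flatter
    aperiodic spectrum (exponent down), and stronger delta/theta phase
    coupling (overall FC and theta-band integration up).
    """

    exponent_delta: float = -0.3
    alpha_power_scale: float = 0.75
    delta_power_scale: float = 1.35
    theta_coupling_boost: float = 1.6
    delta_coupling_boost: float = 1.6

    def coupling_boost(self, band: str) -> float:
        if band == "theta":
            return self.theta_coupling_boost
        if band == "delta":
            return self.delta_coupling_boost
        return 1.0

    def power_scale(self, band: str) -> float:
        if band == "alpha":
            return self.alpha_power_scale
        if band == "delta":
            return self.delta_power_scale
        return 1.0


@dataclass
class Oscillation:
    """One band-limited oscillatory component (center Hz, bandwidth Hz, amplitude)."""

    band: str
    center: float
    bandwidth: float
    amplitude: float


@dataclass
class CouplingSpec:
    """A set of channels sharing one phase-lagged narrowband source.

    ``phase_lag`` accumulates along ``channels``: the k-th listed channel
    receives the source rotated by k * phase_lag.  ``boostable`` marks the
    couplings that the altitude condition scales; module-internal theta
    couplings are held fixed so the theta boost changes network *topology*
    (bridges between modules) rather than uniform strength.
    """

    channels: tuple[int, ...]
    band: str
    center: float
    phase_lag: float
    strength: float
    amplitude: float = 1.0
    boostable: bool = True


def _default_oscillations() -> list[Oscillation]:
    # Amplitudes put roughly half of broadband variance in oscillations,
    # with the usual alpha dominance at rest.
    return [
        Oscillation("delta", center=2.0, bandwidth=1.5, amplitude=0.55),
        Oscillation("theta", center=6.0, bandwidth=1.5, amplitude=0.35),
        Oscillation("alpha", center=10.0, bandwidth=1.5, amplitude=0.65),
        Oscillation("beta", center=20.0, bandwidth=4.0, amplitude=0.30),
    ]


def _default_couplings(n_channels: int) -> list[CouplingSpec]:
    """Module + bridge coupling layout for the delta and theta bands.

    Per band: four modules of eight channels each share a phase-lagged
    source (lag pi/4 per channel, so almost all within-module pairs are
    away from the wPLI-blind 0/pi lags), plus two-channel "bridge" sources
    linking adjacent modules in a ring.  In the delta band both modules
    and bridges are boostable (altitude scales overall FC strength); in
    the theta band only the bridges are boostable, so the altitude effect
    is a topological shift toward integration at matched edge density.
    """
    rng = np.random.default_rng(20240)  # fixed layout, not study randomness
    specs: list[CouplingSpec] = []
    for band, center, modules_boost in (("delta", 2.0, True), ("theta", 6.0, False)):
        order = rng.permutation(n_channels)
        modules = [tuple(int(c) for c in order[8 * m : 8 * (m + 1)]) for m in range(4)]
        for mod in modules:
            specs.append(
                CouplingSpec(
                    channels=mod,
                    band=band,
                    center=center,
                    phase_lag=np.pi / 4,
                    strength=0.55,
                    amplitude=0.8,
                    boostable=modules_boost,
                )
            )
        # Expansion links: every channel outside the modules is tied to one
        # module channel.  In the theta band these are the only boostable
        # couplings, so the altitude boost recruits the whole cap into the
        # coupled core — a topological shift toward integration that
        # survives proportional (density-matched) thresholding.
        periphery = [int(c) for c in order[32:]]
        for i, ch in enumerate(periphery):
            hub = modules[i % 4][(i // 4) % 8]
            specs.append(
                CouplingSpec(
                    channels=(hub, ch),
                    band=band,
                    center=center,
                    phase_lag=np.pi / 2,
                    strength=0.28,
                    amplitude=0.8,
                    boostable=True,
                )
            )
    return specs


@dataclass
class SynthConfig:
    """Study-level generator settings.

    Desk-scale defaults (fs=256 Hz, 300 s) keep full-study runs tractable;
    the cohort structure (16 subjects, ages 19-45, 64 channels, paired
    conditions) mirrors the high-altitude study design.
    """

    n_subjects: int = 16
    fs: float = 256.0
    duration: float = 300.0
    n_channels: int = 64
    age_range: tuple[float, float] = (19.0, 45.0)
    exponent_base: float = 1.5
    exponent_age_slope: float = 0.02
    condition_effects: ConditionEffects = field(default_factory=ConditionEffects)
    band_oscillations: list[Oscillation] = field(default_factory=_default_oscillations)
    coupling_spec: list[CouplingSpec] | None = None
    noise_sd: float = 0.05
    subject_amp_jitter_sd: float = 0.2
    subject_exponent_sd: float = 0.08
    subject_coupling_jitter_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.exponent_base <= 0:
            raise ValueError("exponent_base must be > 0")
        if not (0 < self.age_range[0] < self.age_range[1] < 120):
            raise ValueError(f"implausible age_range {self.age_range}")
        top = max(o.center for o in self.band_oscillations)
        if self.fs <= 2 * top:
            raise ValueError(
                f"fs={self.fs} violates Nyquist for oscillation at {top} Hz"
            )
        if self.coupling_spec is None:
            self.coupling_spec = _default_couplings(self.n_channels)
        for cs in self.coupling_spec:
            if not 0 <= cs.strength <= 1:
                raise ValueError(f"coupling strength {cs.strength} outside [0, 1]")
            if not -np.pi < cs.phase_lag <= np.pi:
                raise ValueError(f"phase lag {cs.phase_lag} outside (-pi, pi]")
            if max(cs.channels) >= self.n_channels:
                raise ValueError(
                    f"coupling_spec references channel {max(cs.channels)} "
                    f">= n_channels={self.n_channels}"
                )


@dataclass
class SubjectTruth:
    """Programmed ground truth for one subject-condition recording."""

    subject_id: str
    condition: str
    age: float
    exponent: float
    band_amplitudes: dict[str, float]
    relative_band_power: dict[str, float]
    couplings: list[CouplingSpec]


@dataclass
class GroundTruth:
    """Ground truth for a whole study, keyed by (subject_id, condition)."""

    entries: dict[tuple[str, str], SubjectTruth]

    def __getitem__(self, key: tuple[str, str]) -> SubjectTruth:
        return self.entries[key]


def generate_aperiodic_noise(
    n_samples: int, fs: float, exponent: float, seed: int | np.random.Generator
) -> np.ndarray:
    """1/f^chi noise by frequency-domain amplitude shaping of white noise.

    The DC bin is zeroed and the output is scaled to zero mean, unit
    variance, so the population PSD is proportional to f^-exponent.
    """
    if not np.isfinite(exponent) or exponent < 0:
        raise ValueError(f"exponent must be finite and >= 0, got {exponent}")
    if n_samples < 2 * fs:
        raise ValueError("need at least 2 s of samples for stable shaping")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    x = np.fft.irfft(spec * shape, n=n_samples)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_narrowband_noise(
    n_samples: int,
    fs: float,
    center: float,
    bandwidth: float,
    seed: int | np.random.Generator,
) -> np.ndarray:
    """Gaussian-envelope narrowband noise with unit variance.

    White noise whose FFT amplitudes are weighted by a Gaussian centered at
    ``center`` with sigma = bandwidth / 2; produces a realistic smooth
    spectral peak rather than a pure sinusoid line.
    """
    if not 0 < center < fs / 2:
        raise ValueError(f"center {center} Hz outside (0, Nyquist)")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    white = rng.standard_normal(n_samples)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / fs)
    sigma = bandwidth / 2.0
    shape = np.exp(-0.5 * ((freqs - center) / sigma) ** 2)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n_samples)
    x -= x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _phase_rotate(x: np.ndarray, phase_lag: float) -> np.ndarray:
    """Rotate every positive-frequency component of ``x`` by ``-phase_lag``.

    For a narrowband signal this is a constant phase shift across the band's
    support, i.e. a frequency-independent lag within the band.
    """
    spec = np.fft.rfft(x)
    spec[1:] *= np.exp(-1j * phase_lag)
    return np.fft.irfft(spec, n=len(x))


def generate_coupled_pair(
    fs: float,
    duration: float,
    center_freq: float,
    phase_lag: float,
    coupling: float,
    seed: int | np.random.Generator,
    bandwidth: float = 1.5,
) -> np.ndarray:
    """Two channels sharing a phase-lagged narrowband source.

    Channel 0 carries the source; channel 1 is
    ``coupling * rotate(source, phase_lag) + (1 - coupling) * noise`` with
    independent narrowband noise in the same band.  Returns a (2, n) array.
    """
    if not 0 <= coupling <= 1:
        raise ValueError(f"coupling {coupling} outside [0, 1]")
    if not 0 < center_freq < fs / 2:
        raise ValueError(f"center_freq {center_freq} outside (0, Nyquist)")
    if not -np.pi < phase_lag <= np.pi:
        import warnings

        warnings.warn("phase_lag outside (-pi, pi]; normalizing", stacklevel=2)
        phase_lag = np.angle(np.exp(1j * phase_lag))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = int(round(fs * duration))
    source = generate_narrowband_noise(n, fs, center_freq, bandwidth, rng)
    noise = generate_narrowband_noise(n, fs, center_freq, bandwidth, rng)
    ch1 = source
    ch2 = coupling * _phase_rotate(source, phase_lag) + (1.0 - coupling) * noise
    return np.vstack([ch1, ch2])


def _analytic_psd(
    exponent: float,
    band_amps: dict[str, float],
    oscillations: list[Oscillation],
    freqs: np.ndarray,
) -> np.ndarray:
    """Population PSD of the generative model on a frequency grid (unnormalized)."""
    psd = np.zeros_like(freqs)
    pos = freqs > 0
    shape = freqs[pos] ** (-exponent)
    psd[pos] = shape / np.trapezoid(shape, freqs[pos])  # unit-variance background
    for osc in oscillations:
        amp = band_amps.get(osc.band, osc.amplitude)
        sigma = osc.bandwidth / 2.0
        bump = np.exp(-0.5 * ((freqs - osc.center) / sigma) ** 2)
        area = np.trapezoid(bump, freqs)
        if area > 0:
            psd += amp**2 * bump / area  # variance amp^2 in the bump
    return psd


def _true_relative_power(
    exponent: float,
    band_amps: dict[str, float],
    oscillations: list[Oscillation],
    broadband: tuple[float, float] = (0.5, 30.0),
) -> dict[str, float]:
    freqs = np.linspace(0.01, 45.0, 9000)
    psd = _analytic_psd(exponent, band_amps, oscillations, freqs)

    def integral(lo: float, hi: float) -> float:
        m = (freqs >= lo) & (freqs <= hi)
        return float(np.trapezoid(psd[m], freqs[m]))

    total = integral(*broadband)
    return {b: integral(lo, hi) / total for b, (lo, hi) in BANDS.items()}


def generate_study(
    config: SynthConfig,
) -> tuple[list[Recording], GroundTruth, pd.DataFrame]:
    """Generate the full paired study: 2 x n_subjects recordings.

    Ages are drawn uniformly in ``age_range`` and shared across a subject's
    two conditions (within-subject design).  The altitude condition applies
    ``condition_effects`` to the exponent, band amplitudes, and coupling
    strengths.  All randomness derives from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.fs * config.duration))
    labels = (
        list(BIOSEMI64_LABELS)
        if config.n_channels == 64
        else [f"CH{i:02d}" for i in range(config.n_channels)]
    )
    region_map = (
        default_region_map()
        if config.n_channels == 64
        else {lab: "frontal" for lab in labels}
    )

    ages = rng.uniform(*config.age_range, size=config.n_subjects)
    recordings: list[Recording] = []
    truth: dict[tuple[str, str], SubjectTruth] = {}
    rows = []
    eff = config.condition_effects

    for s in range(config.n_subjects):
        sid = f"S{s + 1:02d}"
        age = float(ages[s])
        # between-subject variability, shared across the paired conditions
        exp_jitter = rng.normal(0.0, config.subject_exponent_sd)
        amp_jitter = {
            osc.band: float(np.exp(rng.normal(0.0, config.subject_amp_jitter_sd)))
            for osc in config.band_oscillations
        }
        coupling_jitter = np.exp(
            rng.normal(0.0, config.subject_coupling_jitter_sd, len(config.coupling_spec))
        )
        for cond in CONDITIONS:
            exponent = (
                config.exponent_base
                + exp_jitter
                - config.exponent_age_slope * (age - config.age_range[0])
            )
            if cond == "altitude":
                exponent += eff.exponent_delta
            exponent = max(exponent, 0.05)

            band_amps = {
                osc.band: osc.amplitude
                * amp_jitter[osc.band]
                * (eff.power_scale(osc.band) if cond == "altitude" else 1.0)
                for osc in config.band_oscillations
            }

            data = np.empty((config.n_channels, n))
            for c in range(config.n_channels):
                x = generate_aperiodic_noise(n, config.fs, exponent, rng)
                for osc in config.band_oscillations:
                    x = x + band_amps[osc.band] * generate_narrowband_noise(
                        n, config.fs, osc.center, osc.bandwidth, rng
                    )
                x += config.noise_sd * rng.standard_normal(n)
                data[c] = x

            applied: list[CouplingSpec] = []
            for ci, cs in enumerate(config.coupling_spec):
                strength = cs.strength * float(coupling_jitter[ci])
                if cond == "altitude" and cs.boostable:
                    strength = strength * eff.coupling_boost(cs.band)
                strength = min(1.0, strength)
                source = generate_narrowband_noise(
                    n, config.fs, cs.center, 1.5, rng
                )
                for k, ch in enumerate(cs.channels):
                    shifted = _phase_rotate(source, k * cs.phase_lag) if k else source
                    data[ch] += cs.amplitude * strength * shifted
                applied.append(
                    CouplingSpec(
                        channels=cs.channels,
                        band=cs.band,
                        center=cs.center,
                        phase_lag=cs.phase_lag,
                        strength=strength,
                        amplitude=cs.amplitude,
                        boostable=cs.boostable,
                    )
                )

            recordings.append(
                Recording(
                    data=data,
                    fs=config.fs,
                    channel_labels=list(labels),
                    region_map=dict(region_map),
                    subject_id=sid,
                    condition=cond,
                )
            )
            truth[(sid, cond)] = SubjectTruth(
                subject_id=sid,
                condition=cond,
                age=age,
                exponent=exponent,
                band_amplitudes=band_amps,
                relative_band_power=_true_relative_power(
                    exponent, band_amps, config.band_oscillations
                ),
                couplings=applied,
            )
            rows.append({"subject_id": sid, "age_years": age, "condition": cond})

    table = pd.DataFrame(rows)
    return recordings, GroundTruth(entries=truth), table


def save_study(
    out_dir: str | Path,
    recordings: list[Recording],
    truth: GroundTruth,
    table: pd.DataFrame,
) -> None:
    """Write recordings (.npz), ground truth (JSON), and subject table (CSV)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for rec in recordings:
        np.savez_compressed(
            out / f"{rec.subject_id}_{rec.condition}.npz",
            data=rec.data,
            fs=rec.fs,
            channel_labels=np.array(rec.channel_labels),
            regions=np.array([rec.region_map[c] for c in rec.channel_labels]),
            subject_id=rec.subject_id,
            condition=rec.condition,
        )
    gt = {
        f"{sid}|{cond}": {
            **{
                k: v
                for k, v in asdict(st).items()
                if k != "couplings"
            },
            "couplings": [asdict(cs) for cs in st.couplings],
        }
        for (sid, cond), st in truth.entries.items()
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    table.to_csv(out / "subjects.csv", index=False)


def load_study(in_dir: str | Path) -> tuple[list[Recording], pd.DataFrame]:
    """Load recordings and subject table written by :func:`save_study`."""
    src = Path(in_dir)
    table = pd.read_csv(src / "subjects.csv")
    recordings = []
    for _, row in table.iterrows():
        with np.load(src / f"{row.subject_id}_{row.condition}.npz") as z:
            labels = [str(c) for c in z["channel_labels"]]
            regions = [str(r) for r in z["regions"]]
            recordings.append(
                Recording(
                    data=z["data"],
                    fs=float(z["fs"]),
                    channel_labels=labels,
                    region_map=dict(zip(labels, regions)),
                    subject_id=str(row.subject_id),
                    condition=str(row.condition),
                )
            )
    return recordings, table
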