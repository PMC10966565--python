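"""Synthetic resting-EEG cohorts with planted group effects.

Each subject is a region x time source-space signal built as a sum of
six band-limited oscillations plus 1/f background noise.  Band
oscillations are amplitude-modulated by slowly varying positive
envelopes whose *log*-envelope correlation structure is imposed by
construction (correlated Gaussian processes mapped through exp), so
the amplitude-synchrony that power-envelope connectivity measures is
directly controllable.

Group effects are planted two ways:

- ``band_power``: a shift of the target regions' log band amplitude by
  a Cohen's d expressed in units of the between-subject SD (the log
  scale makes d scale-free);
- ``envelope_coupling``: an additive delta on the target pairs' target
  log-envelope correlation (the matrix is re-projected to the nearest
  valid correlation matrix).

Everything is a pure function of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.fft as sfft

from oscillome.bands import BandSpec, DEFAULT_BANDS
from oscillome.preprocess import Recording
from oscillome.source import ROITimeSeries, LeadField, load_parcellation_table

# Resting-EEG-flavoured relative band amplitudes (alpha-dominant,
# power falling off with frequency).
DEFAULT_BASELINE_POWER: dict[str, float] = {
    "delta": 1.0,
    "theta": 0.8,
    "alpha": 1.2,
    "beta": 0.5,
    "low_gamma": 0.25,
    "high_gamma": 0.15,
}


@dataclass(frozen=True)
class EffectSpec:
    """A planted group difference.

    ``targets`` holds region names for ``band_power`` effects and
    (region_i, region_j) name tuples for ``envelope_coupling`` effects.
    ``magnitude`` is a Cohen's d (band_power) or an additive
    correlation delta in [-1, 1] (envelope_coupling).
    """

    kind: str
    band: str
    targets: tuple
    magnitude: float
    group: str

    def __post_init__(self) -> None:
        if self.kind not in ("band_power", "envelope_coupling"):
            raise ValueError(f"unknown effect kind {self.kind!r}")
        if self.kind == "envelope_coupling" and abs(self.magnitude) > 1:
            raise ValueError("coupling delta must be in [-1, 1]")


@dataclass
class SynthCohortConfig:
    """Study conditions for a simulated cohort.

    Defaults mirror a 5-min resting recording at 500 Hz over 113
    regions; tests use shorter durations.
    """

    n_per_group: dict[str, int] = field(default_factory=lambda: {"HC": 30, "PKD": 30})
    fs: float = 500.0
    duration: float = 300.0
    n_regions: int = 113
    region_names: list[str] | None = None
    network_labels: list[str] | None = None
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS
    baseline_power: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BASELINE_POWER)
    )
    envelope_corr: float | dict[str, np.ndarray] = 0.4   # uniform off-diagonal baseline
    envelope_bandwidth: float = 1.0     # Hz, low-pass on envelopes
    log_env_sigma: float = 0.4          # SD of log envelopes within subject
    # Between-subject variance decomposition of log amplitude: a global
    # gain (electrode/skull scaling, shared by everything), a per-region
    # broadband gain, and a small band-specific residual.  The shared
    # gains are multiplicative on the whole region signal and are what
    # the per-region PSD z-transform removes.
    gain_global_sd: float = 0.25
    gain_region_sd: float = 0.20
    band_amp_sd: float = 0.12           # band-specific residual SD of log amplitude
    noise_exponent: float = 1.0         # 1/f slope of the background
    noise_scale: float = 1.0            # background RMS relative to unit-amp band
    amplitude_uv: float = 10.0          # overall scale, uV-flavoured
    effects: tuple[EffectSpec, ...] = ()
    leadfield: LeadField | None = None
    sensor_snr: float = np.inf
    paradigm: str = "eyes_closed"
    seed: int = 0

    def __post_init__(self) -> None:
        if int(round(self.duration * self.fs)) != round(self.duration * self.fs, 6):
            raise ValueError("duration * fs must be an integer sample count")
        if self.region_names is None:
            table = load_parcellation_table().preserved()
            names = list(table["region"])[: self.n_regions]
            nets = list(table["network"])[: self.n_regions]
            while len(names) < self.n_regions:
                names.append(f"R{len(names) + 1:03d}")
                nets.append("DMN")
            self.region_names, self.network_labels = names, nets
        if len(self.region_names) != self.n_regions:
            raise ValueError("region_names length != n_regions")

    def groups(self) -> list[str]:
        return list(self.n_per_group)


def _nearest_correlation(mat: np.ndarray) -> np.ndarray:
    """Clip negative eigenvalues and restore the unit diagonal."""
    sym = (mat + mat.T) / 2
    w, v = np.linalg.eigh(sym)
    w = np.clip(w, 1e-10, None)
    out = (v * w) @ v.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    np.fill_diagonal(out, 1.0)
    return out


def gen_correlated_envelopes(
    target_corr: np.ndarray,
    duration: float,
    fs: float,
    bandwidth: float = 1.0,
    seed: int | np.random.Generator | None = None,
    sigma_log: float = 0.4,
) -> np.ndarray:
    """Positive envelopes whose log-envelope correlations match a target.

    Independent Gaussian processes are low-pass filtered below
    ``bandwidth`` (zero-phase, fourth-order-Butterworth magnitude
    response applied in the frequency domain), standardized, mixed
    through a square root of the target correlation matrix, and mapped
    through exp; the log-envelope correlation matrix therefore equals
    the target by construction (up to sampling error).
    """
    n = int(round(duration * fs))
    if n <= 0:
        raise ValueError(f"duration={duration}s at fs={fs} gives no samples")
    corr = np.asarray(target_corr, dtype=float)
    if corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("target_corr must be square")
    if not np.allclose(corr, corr.T, atol=1e-10):
        raise ValueError("target_corr must be symmetric")
    w, v = np.linalg.eigh((corr + corr.T) / 2)
    if w.min() < -1e-8:
        raise ValueError(
            f"target_corr is not positive semidefinite "
            f"(smallest eigenvalue {w.min():.3e})"
        )
    factor = v * np.sqrt(np.clip(w, 0.0, None))
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # Envelopes are band-limited to ``bandwidth``; generate them on a
    # coarse internal grid (16x the bandwidth) and linearly upsample —
    # interpolation images are ~-24 dB and the log-envelope
    # correlations are untouched by the (shared) interpolation.
    fs_env = min(fs, 16.0 * bandwidth)
    n_env = max(int(round(n * fs_env / fs)), min(n, 32))
    z = rng.standard_normal((corr.shape[0], n_env))
    spec = sfft.rfft(z, axis=-1)
    f = sfft.rfftfreq(n_env, 1.0 / fs_env)
    spec *= 1.0 / np.sqrt(1.0 + (f / bandwidth) ** 8)   # |H| of a 4th-order low-pass
    z = sfft.irfft(spec, n=n_env, axis=-1)
    z -= z.mean(axis=-1, keepdims=True)
    sd = z.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    z /= sd
    mixed = factor @ z
    if n_env != n:
        pos = np.arange(n) * (n_env / n)
        lo = np.minimum(pos.astype(int), n_env - 2)
        frac = pos - lo
        mixed = mixed[:, lo] * (1.0 - frac) + mixed[:, lo + 1] * frac
    return np.exp(sigma_log * mixed)


def make_band_oscillation(
    band: BandSpec,
    envelope: np.ndarray,
    fs: float,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Band-limited carrier (FFT-masked white noise) times the envelope.

    The carrier is exactly band-limited to [f_lo, f_hi] and normalized
    to unit RMS, so the output's in-band power fraction is >= 90% up to
    envelope-modulation sidebands.
    """
    if band.f_hi >= fs / 2:
        raise ValueError(
            f"band {band.name} upper edge {band.f_hi} Hz >= Nyquist {fs / 2} Hz"
        )
    envelope = np.asarray(envelope, dtype=float)
    n = envelope.shape[-1]
    if n == 0:
        raise ValueError("empty envelope")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    # Synthesize the masked white-noise spectrum directly: complex
    # Gaussian coefficients on the in-band bins, zero elsewhere
    # (distributionally identical to FFT-masking white noise).
    freqs = sfft.rfftfreq(n, 1 / fs)
    mask = (freqs >= band.f_lo) & (freqs <= band.f_hi)
    shape = envelope.shape[:-1] + (len(freqs),)
    spec = np.zeros(shape, dtype=np.complex64)
    nb = int(mask.sum())
    spec[..., mask] = (
        rng.standard_normal(shape[:-1] + (nb,), dtype=np.float32)
        + 1j * rng.standard_normal(shape[:-1] + (nb,), dtype=np.float32)
    )
    carrier = sfft.irfft(spec, n=n, axis=-1)   # float32; upcasts with the envelope
    rms = np.sqrt((carrier**2).mean(axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    carrier /= rms
    return envelope * carrier


def one_over_f_noise(
    shape: tuple[int, ...],
    fs: float,
    exponent: float = 1.0,
    seed: int | np.random.Generator | None = None,
) -> np.ndarray:
    """Unit-RMS noise with power spectral density proportional to 1/f^exponent."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = shape[-1]
    freqs = sfft.rfftfreq(n, 1 / fs)
    scale = np.zeros_like(freqs)
    scale[1:] = freqs[1:] ** (-exponent / 2)
    nspec = len(freqs)
    spec = (
        rng.standard_normal(shape[:-1] + (nspec,), dtype=np.float32)
        + 1j * rng.standard_normal(shape[:-1] + (nspec,), dtype=np.float32)
    ) * scale.astype(np.float32)
    out = sfft.irfft(spec, n=n, axis=-1)
    rms = np.sqrt((out**2).mean(axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return out / rms


def _band_target_corr(config: SynthCohortConfig, band: BandSpec, group: str) -> np.ndarray:
    R = config.n_regions
    if isinstance(config.envelope_corr, dict):
        base = np.asarray(config.envelope_corr[band.name], dtype=float).copy()
    else:
        rho = float(config.envelope_corr)
        base = np.full((R, R), rho)
        np.fill_diagonal(base, 1.0)
    name_to_idx = {nm: i for i, nm in enumerate(config.region_names)}
    touched = False
    for eff in config.effects:
        if eff.kind != "envelope_coupling" or eff.band != band.name or eff.group != group:
            continue
        for a, b in eff.targets:
            i, j = name_to_idx[a], name_to_idx[b]
            base[i, j] = np.clip(base[i, j] + eff.magnitude, -0.999, 0.999)
            base[j, i] = base[i, j]
            touched = True
    if touched:
        base = _nearest_correlation(base)
    return base


def _total_amp_sd(config: SynthCohortConfig) -> float:
    """Between-subject SD of log band amplitude (all components)."""
    return float(
        np.sqrt(
            config.gain_global_sd**2
            + config.gain_region_sd**2
            + config.band_amp_sd**2
        )
    )


def _band_log_amplitudes(
    config: SynthCohortConfig, band: BandSpec, group: str, rng: np.random.Generator
) -> np.ndarray:
    """Per-region log amplitude: baseline + band residual + planted shift.

    The planted Cohen's d is expressed against the full between-subject
    SD of log band amplitude (shared gains included), so the realized
    raw-scale effect size equals the configured d.
    """
    amp = np.log(config.baseline_power.get(band.name, 1.0)) + rng.normal(
        0.0, config.band_amp_sd, config.n_regions
    )
    name_to_idx = {nm: i for i, nm in enumerate(config.region_names)}
    for eff in config.effects:
        if eff.kind != "band_power" or eff.band != band.name or eff.group != group:
            continue
        idx = [name_to_idx[t] for t in eff.targets]
        amp[idx] += eff.magnitude * _total_amp_sd(config)
    return amp


def gen_subject(
    config: SynthCohortConfig, group: str, subject_seed, subject_id: str = ""
) -> ROITimeSeries:
    """One subject's region x time source signal for the given group."""
    if group not in config.n_per_group:
        raise ValueError(
            f"unknown group {group!r}; configured groups: {config.groups()}"
        )
    rng = np.random.default_rng(subject_seed)
    n = int(round(config.duration * config.fs))
    gain = np.exp(
        rng.normal(0.0, config.gain_global_sd)
        + rng.normal(0.0, config.gain_region_sd, config.n_regions)
    )
    # accumulate in single precision: ample for a noise-driven simulator
    data = np.zeros((config.n_regions, n), dtype=np.float32)
    for band in config.bands:
        corr = _band_target_corr(config, band, group)
        env = gen_correlated_envelopes(
            corr,
            config.duration,
            config.fs,
            bandwidth=config.envelope_bandwidth,
            seed=rng,
            sigma_log=config.log_env_sigma,
        ).astype(np.float32)
        amp = np.exp(_band_log_amplitudes(config, band, group, rng)).astype(np.float32)
        data += amp[:, None] * make_band_oscillation(band, env, config.fs, seed=rng)
    data += np.float32(config.noise_scale) * one_over_f_noise(
        (config.n_regions, n), config.fs, config.noise_exponent, seed=rng
    )
    data *= gain[:, None] * config.amplitude_uv
    return ROITimeSeries(
        data=data,
        fs=config.fs,
        region_names=list(config.region_names),
        network_labels=list(config.network_labels),
        subject_id=subject_id,
        group=group,
    )


def gen_cohort(
    config: SynthCohortConfig,
) -> tuple[list[ROITimeSeries], pd.DataFrame]:
    """Full multi-group cohort plus its metadata table.

    Deterministic given ``config.seed``: per-subject seeds are spawned
    from a single SeedSequence.
    """
    for g, n in config.n_per_group.items():
        if n < 2:
            raise ValueError(f"group {g!r} needs n_per_group >= 2, got {n}")
    ss = np.random.SeedSequence(config.seed)
    total = sum(config.n_per_group.values())
    children = ss.spawn(total)
    subjects, meta = [], []
    k = 0
    for group, n in config.n_per_group.items():
        for j in range(n):
            sid = f"{group}_{j + 1:03d}"
            subjects.append(gen_subject(config, group, children[k], subject_id=sid))
            meta.append(
                {"subject_id": sid, "group": group, "paradigm": config.paradigm}
            )
            k += 1
    return subjects, pd.DataFrame(meta)


def project_to_sensors(
    roi: ROITimeSeries,
    leadfield: np.ndarray | LeadField,
    snr: float = np.inf,
    seed: int | np.random.Generator | None = None,
) -> Recording:
    """Mix source series to sensors and add white noise at a target SNR.

    ``leadfield`` columns map one source each (n_sensors x n_regions);
    a LeadField with 3-column orientation blocks is accepted, in which
    case each region drives a random fixed unit orientation.  ``snr``
    is the per-sensor signal-to-noise variance ratio.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    if isinstance(leadfield, LeadField):
        G3 = leadfield.matrix
        if G3.shape[1] != 3 * roi.n_regions:
            raise ValueError(
                f"lead field has {G3.shape[1] // 3} source blocks but ROI has "
                f"{roi.n_regions} regions"
            )
        ori = rng.standard_normal((roi.n_regions, 3))
        ori /= np.linalg.norm(ori, axis=1, keepdims=True)
        G = np.stack(
            [G3[:, 3 * v : 3 * v + 3] @ ori[v] for v in range(roi.n_regions)], axis=1
        )
    else:
        G = np.asarray(leadfield, dtype=float)
        if G.ndim != 2 or G.shape[1] != roi.n_regions:
            raise ValueError(
                f"lead field shape {G.shape} incompatible with {roi.n_regions} regions"
            )
    sensors = G @ roi.data
    if np.isfinite(snr):
        if snr <= 0:
            raise ValueError("snr must be > 0")
        var = sensors.var(axis=-1, keepdims=True)
        sensors = sensors + rng.standard_normal(sensors.shape) * np.sqrt(var / snr)
    return Recording(
        data=sensors,
        fs=roi.fs,
        subject_id=roi.subject_id,
        paradigm="eyes_closed",
    )
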