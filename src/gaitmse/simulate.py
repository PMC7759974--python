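"""Synthetic gait-force generator.

Emulates the morphology of force-sensitive-resistor recordings of walking:
each stance phase is a positive double-peaked pulse (heel-strike lobe then
toe-off lobe, built from two raised-cosine lobes), swing phases rest near
zero, and successive stride periods jitter with a configurable coefficient
of variation — the knob that separates "steady" from "variable" gait and
that the multiscale-entropy features pick up. The right foot runs
anti-phased to the left by a configurable offset. This imitates signal
shape only, not disease physiology; class names are arbitrary labels.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np

from gaitmse.io import CohortManifest, GaitRecord, save_manifest, write_gait_record


@dataclass
class GaitClassParams:
    """Class-level generator parameters.

    stride_period_s : mean stride duration (s); ~1.1 s for comfortable walking.
    period_cv : coefficient of variation of stride-to-stride period — the
        class-separating knob.
    amplitude : stance peak force (arbitrary force-proportional units).
    amplitude_cv : stride-to-stride amplitude CV.
    double_peak_ratio : toe-off peak height relative to heel-strike peak.
    noise_sd : additive white-noise SD, in amplitude units (sensor/ADC
        floor; ~0.5% of peak force for a clean force-sensitive resistor).
    asymmetry : right-foot phase offset as a fraction of the stride period
        (0.5 = perfectly alternating feet).
    stance_fraction : stance duration as a fraction of the stride period.
    period_amp_coupling : exponent coupling instantaneous cadence to peak
        force (impulse–momentum: a shorter stride loads harder), so stride
        timing variability also shows up as loading variability.
    lobe_sharpness : exponent (> 1 steepens) on each raised-cosine lobe;
        real heel-strike/toe-off force lobes rise faster than a plain hann.
    """

    label: str = "HC"
    stride_period_s: float = 1.1
    period_cv: float = 0.03
    amplitude: float = 1.0
    amplitude_cv: float = 0.05
    double_peak_ratio: float = 0.9
    noise_sd: float = 0.005
    asymmetry: float = 0.5
    stance_fraction: float = 0.62
    period_amp_coupling: float = 1.0
    lobe_sharpness: float = 2.0

    def __post_init__(self) -> None:
        if self.stride_period_s <= 0:
            raise ValueError("stride_period_s must be positive")
        if self.period_cv < 0 or self.amplitude_cv < 0 or self.noise_sd < 0:
            raise ValueError("period_cv, amplitude_cv and noise_sd must be >= 0")
        if not 0 < self.stance_fraction < 1:
            raise ValueError("stance_fraction must be in (0, 1)")
        if self.amplitude <= 0:
            raise ValueError("amplitude must be positive")


#: Default four-class presets, separated mainly by stride-period variability
#: and asymmetry. Morphology labels only — no clinical claim.
DEFAULT_CLASS_PARAMS: dict[str, GaitClassParams] = {
    "HC": GaitClassParams(label="HC", period_cv=0.03, asymmetry=0.50),
    "PD": GaitClassParams(label="PD", period_cv=0.10, asymmetry=0.48, amplitude_cv=0.10),
    "HD": GaitClassParams(label="HD", period_cv=0.18, asymmetry=0.45, amplitude_cv=0.15),
    "ALS": GaitClassParams(label="ALS", period_cv=0.12, asymmetry=0.42, stride_period_s=1.3),
}


def _raised_cosine(t: np.ndarray, start: float, width: float) -> np.ndarray:
    """One positive raised-cosine lobe on [start, start+width], zero outside."""
    phase = (t - start) / width
    lobe = 0.5 * (1.0 - np.cos(2.0 * np.pi * phase))
    lobe[(phase < 0) | (phase > 1)] = 0.0
    return lobe


def _add_lobe(
    signal: np.ndarray, fs: float, start: float, width: float, amp: float, sharp: float
) -> None:
    """Add one sharpened raised-cosine lobe in place, touching only the
    samples under its support."""
    i0 = max(int(np.ceil(start * fs)), 0)
    i1 = min(int(np.floor((start + width) * fs)) + 1, len(signal))
    if i1 <= i0:
        return
    t_local = np.arange(i0, i1) / fs
    lobe = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t_local - start) / width))
    signal[i0:i1] += amp * lobe**sharp


def _one_foot(
    params: GaitClassParams,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
    t_offset: float,
) -> np.ndarray:
    """Force trace of one foot: a train of double-peaked stance pulses."""
    n = int(round(duration_s * fs))
    signal = np.zeros(n)
    stride_t = t_offset
    # march stride-by-stride until the record is covered
    while stride_t < duration_s:
        if params.period_cv > 0:
            period = rng.normal(params.stride_period_s, params.period_cv * params.stride_period_s)
            period = max(period, 0.2 * params.stride_period_s)
        else:
            period = params.stride_period_s
        if params.amplitude_cv > 0:
            amp = rng.normal(params.amplitude, params.amplitude_cv * params.amplitude)
            amp = max(amp, 0.1 * params.amplitude)
        else:
            amp = params.amplitude
        # faster strides load harder (impulse-momentum coupling)
        amp *= (params.stride_period_s / period) ** params.period_amp_coupling
        stance = params.stance_fraction * period
        # heel lobe over the first 60% of stance, toe lobe over the last 60%
        _add_lobe(signal, fs, stride_t, 0.6 * stance, amp, params.lobe_sharpness)
        _add_lobe(
            signal,
            fs,
            stride_t + 0.4 * stance,
            0.6 * stance,
            amp * params.double_peak_ratio,
            params.lobe_sharpness,
        )
        stride_t += period
    return signal


def simulate_gait_record(
    params: GaitClassParams,
    duration_s: float = 300.0,
    fs: float = 300.0,
    seed: int | np.random.Generator = 0,
    subject_id: str = "sim",
) -> GaitRecord:
    """Simulate one subject's left/right gait-force record.

    Fully reproducible given the seed. Stance envelopes are non-negative by
    construction; Gaussian noise of SD ``noise_sd`` is added afterwards.
    """
    if duration_s <= 0 or fs <= 0:
        raise ValueError("duration_s and fs must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    lf = _one_foot(params, duration_s, fs, rng, t_offset=0.0)
    rf = _one_foot(params, duration_s, fs, rng, t_offset=params.asymmetry * params.stride_period_s)
    if params.noise_sd > 0:
        lf = lf + rng.normal(0.0, params.noise_sd, size=len(lf))
        rf = rf + rng.normal(0.0, params.noise_sd, size=len(rf))
    return GaitRecord(
        subject_id=subject_id, class_label=params.label, fs=fs, lf=lf, rf=rf
    )


def _jitter_params(
    params: GaitClassParams, rng: np.random.Generator, jitter: float
) -> GaitClassParams:
    """Perturb class means per subject so subjects differ within class."""
    if jitter == 0:
        return params
    scale = lambda v: v * (1.0 + rng.normal(0.0, jitter))  # noqa: E731
    return replace(
        params,
        stride_period_s=max(scale(params.stride_period_s), 0.3),
        period_cv=max(scale(params.period_cv), 0.0),
        amplitude=max(scale(params.amplitude), 0.1),
        amplitude_cv=max(scale(params.amplitude_cv), 0.0),
        double_peak_ratio=float(np.clip(scale(params.double_peak_ratio), 0.3, 1.5)),
        asymmetry=float(np.clip(scale(params.asymmetry), 0.2, 0.8)),
    )


def make_cohort(
    spec: list[tuple[GaitClassParams, int]],
    duration_s: float = 300.0,
    fs: float = 300.0,
    seed: int = 0,
    subject_jitter: float = 0.05,
    out_dir: str | Path | None = None,
) -> tuple[list[GaitRecord], CohortManifest]:
    """Simulate a labeled cohort, optionally writing records + manifest.

    ``spec`` is a list of (class parameters, subject count). Each subject
    gets a small seeded perturbation (default 5%) of the class means. When
    ``out_dir`` is given, records are written in the native delimited-text
    format alongside a ``manifest.csv``.
    """
    rng = np.random.default_rng(seed)
    records: list[GaitRecord] = []
    entries: list[tuple[str, str, str]] = []
    for params, n_subjects in spec:
        if n_subjects < 1:
            raise ValueError("each class needs at least one subject")
        for i in range(1, n_subjects + 1):
            subject_id = f"{params.label}{i:02d}"
            subject_params = _jitter_params(params, rng, subject_jitter)
            record = simulate_gait_record(
                subject_params, duration_s=duration_s, fs=fs, seed=rng, subject_id=subject_id
            )
            records.append(record)
            entries.append((f"{subject_id}.txt", subject_id, params.label))
    manifest = CohortManifest(entries=entries, base_dir=Path(out_dir or "."))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for record in records:
            write_gait_record(record, out_dir / f"{record.subject_id}.txt")
        save_manifest(manifest, out_dir / "manifest.csv")
    return records, manifest
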