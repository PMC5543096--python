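"""Split-half SNR estimation, spectral disturbance quantification, and the
technique x trial-count benchmark.

The SNR of a processed response is estimated from two equal halves of a
session.  Structure shared by the halves counts as signal, the half
difference as noise::

    power(R)  = sum |R(z)|^2
    P_noise   = power(data1 - data2) / 2
    P_total   = (power(data1) + power(data2)) / 2
    SNR       = (P_total - P_noise) / P_noise

The estimator assumes zero-mean additive noise that is independent between
halves; a negative estimate (P_noise > P_total) is reported as computed
with a flag rather than clamped.

:func:`run_benchmark` replays the full study on synthetic cohorts: per
replicate ("animal") it generates a session, splits it into halves,
processes the first N trials of each half through every technique and the
Beer-Lambert pipeline to the temporal and spatial endpoints, and
aggregates split-half SNRs across replicates with paired comparisons
against plain trial averaging.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, replace
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage, signal, stats

from .beer_lambert import BeerLambertUnmixer
from .config import AcquisitionConfig, DisturbanceConfig, ResponseConfig
from .response import locate_peak_roi, spatial_map, temporal_response
from .simulate import generate_raw_stack
from .stacks import demultiplex
from .techniques import (_SVDTechnique, TECHNIQUES, average_trials,
                         make_technique, reconstruct_components,
                         svd_components)

__all__ = [
    "power",
    "SplitHalfSNR",
    "snr_split_half",
    "SpectrumResult",
    "amplitude_spectrum",
    "dominant_peak_frequency",
    "SNRReport",
    "run_benchmark",
]


def power(R) -> float:
    """Total power: sum of squared elements."""
    R = np.asarray(R, dtype=float)
    if not np.isfinite(R).all():
        raise ValueError("power requires finite input")
    return float(np.sum(np.abs(R) ** 2))


@dataclass(frozen=True)
class SplitHalfSNR:
    p_total: float
    p_noise: float
    p_signal: float
    snr: float
    negative: bool  # assumption violation: P_noise exceeded P_total


def snr_split_half(data1, data2) -> SplitHalfSNR:
    """Split-half SNR of two equal-shape response outputs."""
    a = np.asarray(data1, dtype=float)
    b = np.asarray(data2, dtype=float)
    if a.shape != b.shape:
        raise ValueError("data1 and data2 must have identical shapes")
    p_noise = power(a - b) / 2.0
    if p_noise == 0.0:
        raise ValueError("data1 and data2 are identical; split-half noise "
                         "power is zero and the SNR is undefined")
    p_total = (power(a) + power(b)) / 2.0
    p_signal = p_total - p_noise
    return SplitHalfSNR(p_total=p_total, p_noise=p_noise, p_signal=p_signal,
                        snr=p_signal / p_noise, negative=p_signal < 0)


@dataclass
class SpectrumResult:
    frequencies: np.ndarray  # Hz, spanning [0, fs/2]
    amplitudes: np.ndarray
    peaks: pd.DataFrame      # columns: frequency_hz, magnitude


def amplitude_spectrum(trace, fs: float, detrend: str = "linear",
                       window: str = "hann", pad_factor: int = 4,
                       peak_threshold: float = 5.0,
                       neighborhood_hz: float = 1.0) -> SpectrumResult:
    """One-sided amplitude spectrum of a uniformly sampled trace.

    The trace is detrended, Hann-windowed and zero-padded to
    ``pad_factor`` times its length for peak readability.  Detected peaks
    are local maxima exceeding ``peak_threshold`` times the median spectral
    magnitude within a ``+-neighborhood_hz`` band.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    x = np.asarray(trace, dtype=float)
    if x.ndim != 1:
        raise ValueError("trace must be 1-D")
    if detrend:
        x = signal.detrend(x, type=detrend)
    win = signal.get_window(window, len(x)) if window else np.ones(len(x))
    n_fft = max(int(pad_factor), 1) * len(x)
    amp = np.abs(np.fft.rfft(x * win, n=n_fft)) * 2.0 / win.sum()
    freqs = np.fft.rfftfreq(n_fft, d=1.0 / fs)

    half_bins = max(1, int(round(neighborhood_hz / (freqs[1] - freqs[0]))))
    local_median = ndimage.median_filter(amp, size=2 * half_bins + 1,
                                         mode="nearest")
    # absolute floor keeps float rounding on featureless traces from
    # registering as peaks
    floor = 1e-12 * max(1e-300, float(np.abs(trace).max()))
    cand, _ = signal.find_peaks(amp)
    keep = cand[(amp[cand] > peak_threshold * local_median[cand])
                & (amp[cand] > floor)]
    order = np.argsort(amp[keep])[::-1]
    peaks = pd.DataFrame({
        "frequency_hz": freqs[keep][order],
        "magnitude": amp[keep][order],
    })
    return SpectrumResult(frequencies=freqs, amplitudes=amp, peaks=peaks)


def dominant_peak_frequency(spec: SpectrumResult, f_lo: float, f_hi: float,
                            exclude_dc: bool = True) -> float:
    """Frequency of the largest detected peak in ``(f_lo, f_hi]``; falls
    back to the largest-magnitude bin in the band if no peak was detected."""
    df = spec.peaks
    sel = df[(df["frequency_hz"] > f_lo) & (df["frequency_hz"] <= f_hi)]
    if exclude_dc:
        sel = sel[sel["frequency_hz"] > 0]
    if len(sel):
        return float(sel.iloc[0]["frequency_hz"])
    mask = (spec.frequencies > max(f_lo, spec.frequencies[1] if exclude_dc else f_lo)) \
        & (spec.frequencies <= f_hi)
    if not mask.any():
        raise ValueError(f"no frequencies in ({f_lo}, {f_hi}] Hz")
    idx = np.flatnonzero(mask)[np.argmax(spec.amplitudes[mask])]
    return float(spec.frequencies[idx])


# ---------------------------------------------------------------------------
# the benchmark

@dataclass
class SNRReport:
    """Benchmark output: per-replicate SNR rows, cross-replicate summary,
    and paired comparisons against trial averaging."""

    per_replicate: pd.DataFrame
    summary: pd.DataFrame
    comparisons: pd.DataFrame
    config: dict

    def mean_snr(self, technique: str, endpoint: str, n_trials: int) -> float:
        s = self.summary
        row = s[(s["technique"] == technique) & (s["endpoint"] == endpoint)
                & (s["n_trials"] == n_trials)]
        return float(row["snr_mean"].iloc[0])

    def sem_snr(self, technique: str, endpoint: str, n_trials: int) -> float:
        s = self.summary
        row = s[(s["technique"] == technique) & (s["endpoint"] == endpoint)
                & (s["n_trials"] == n_trials)]
        return float(row["snr_sem"].iloc[0])


def _apply_techniques(sub: np.ndarray, techniques: Dict[str, object],
                      fpt: int) -> Dict[str, np.ndarray]:
    """Run every technique on one per-wavelength stack, computing the SVD
    once for the PCA-family members (their outputs are bit-identical to the
    standalone transformers because the same svd/reconstruct routines run)."""
    outs = {}
    svd = None
    for name, est in techniques.items():
        if isinstance(est, _SVDTechnique):
            if svd is None:
                r, c, t = sub.shape
                C = sub.reshape(r * c, t)
                mu = C.mean(axis=1, keepdims=True)
                svd = (C, mu, *svd_components(C - mu))
            C, mu, U, s, P = svd
            try:
                idx = est._select(U, s, P, fpt)
            except ValueError:
                outs[name] = None
                continue
            rec = reconstruct_components(U, P, idx) + mu
            outs[name] = average_trials(rec.reshape(sub.shape), fpt)
        else:
            outs[name] = est.transform(sub)
    return outs


def default_benchmark_techniques(acq: AcquisitionConfig,
                                 overrides: Optional[dict] = None) -> Dict[str, object]:
    """The seven compared techniques parameterised for an acquisition
    (frames per trial, per-wavelength rate, pixel pitch)."""
    fpt = acq.frames_per_trial
    fs = acq.per_wavelength_rate_hz
    base = {
        "averaging": dict(frames_per_trial=fpt),
        "lowpass": dict(frames_per_trial=fpt, sampling_rate_hz=fs),
        "bandpass": dict(frames_per_trial=fpt, sampling_rate_hz=fs),
        "pca": dict(frames_per_trial=fpt),
        "truncdiff": dict(frames_per_trial=fpt),
        "gsr": dict(frames_per_trial=fpt),
        "gaussian": dict(frames_per_trial=fpt, pixel_pitch_um=acq.pixel_pitch_um),
    }
    for name, params in (overrides or {}).items():
        base.setdefault(name, {}).update(params)
    return {name: make_technique(name, **params) for name, params in base.items()}


def run_benchmark(
    acq: AcquisitionConfig,
    dist: DisturbanceConfig,
    resp: ResponseConfig,
    techniques: Optional[Sequence[str]] = None,
    technique_params: Optional[dict] = None,
    trial_counts: Sequence[int] = (1, 10, 25, 50),
    n_replicates: int = 19,
    seed: int = 0,
    trials_per_half: int = 50,
    roi_size: int = 50,
    frame_window: Tuple[int, int] = (41, 70),
    component: str = "hbt",
    replicate_amp_jitter_sd: float = 0.15,
    use_ground_truth_roi: bool = False,
    dtype=np.float32,
) -> SNRReport:
    """Full technique x trial-count split-half benchmark on a synthetic
    cohort.

    Each of ``n_replicates`` synthetic animals gets its own seed stream and
    mildly jittered disturbance amplitudes (lognormal,
    ``replicate_amp_jitter_sd``), so cross-replicate standard errors are
    meaningful.  One continuous session of ``2 * trials_per_half`` trials
    is generated per replicate and split in two; for each technique and
    each N in ``trial_counts`` the first N trials of each half run through
    the full pipeline to the temporal (ROI trace) and spatial (windowed
    map) endpoints; both halves share the ROI, located on the combined
    session (or the ground-truth blob centre with
    ``use_ground_truth_roi``).
    """
    if max(trial_counts) > trials_per_half:
        raise ValueError("trial_counts cannot exceed trials_per_half")
    if acq.n_trials != 1:
        acq = replace(acq, n_trials=1)
    session_acq = replace(acq, n_trials=2 * trials_per_half)
    fpt = acq.frames_per_trial
    names = list(techniques) if techniques is not None else list(TECHNIQUES)
    if "averaging" not in names:
        names = ["averaging"] + names

    unmixer = BeerLambertUnmixer(
        n_baseline_frames=acq.n_baseline_frames,
        wavelengths_nm=acq.wavelengths_nm,
    ).fit(None)

    root = np.random.SeedSequence(seed)
    rep_seeds = root.spawn(n_replicates)
    rows = []
    for rep, rep_ss in enumerate(rep_seeds):
        jit_ss, gen_ss = rep_ss.spawn(2)
        jit_rng = np.random.default_rng(jit_ss)
        factors = np.exp(replicate_amp_jitter_sd * jit_rng.standard_normal(3))
        rep_dist = replace(
            dist,
            breathing_amp=dist.breathing_amp * factors[0],
            heartbeat_amp=dist.heartbeat_amp * factors[1],
            drift_rate=dist.drift_rate * factors[2],
        )
        stack, gt = generate_raw_stack(session_acq, rep_dist, resp, gen_ss,
                                       dtype=dtype)
        wstacks = demultiplex(stack)
        half_len = fpt * trials_per_half
        halves = [
            [ws.data[:, :, :half_len] for ws in wstacks],
            [ws.data[:, :, half_len:] for ws in wstacks],
        ]

        if use_ground_truth_roi:
            center = gt.center
        else:
            combined = unmixer.transform(
                [average_trials(ws.data, fpt) for ws in wstacks]
            )
            center = locate_peak_roi(combined, roi_size=roi_size,
                                     frame_window=frame_window,
                                     component=component)

        tech_objs = default_benchmark_techniques(acq, technique_params)
        tech_objs = {n: tech_objs[n] for n in names}

        for n_trials in trial_counts:
            endpoint_outputs = {name: {"temporal": [], "spatial": []}
                                for name in names}
            ok = {name: True for name in names}
            for half in halves:
                per_wavelength = [
                    _apply_techniques(arr[:, :, :fpt * n_trials], tech_objs, fpt)
                    for arr in half
                ]
                for name in names:
                    outs = [pw[name] for pw in per_wavelength]
                    if any(o is None for o in outs):
                        ok[name] = False
                        continue
                    h = unmixer.transform(outs)
                    tr = temporal_response(h, center, roi_size=roi_size,
                                           component=component)
                    sm = spatial_map(h, frame_window=frame_window,
                                     component=component)
                    endpoint_outputs[name]["temporal"].append(tr.trace)
                    endpoint_outputs[name]["spatial"].append(sm.map)
            for name in names:
                for endpoint in ("temporal", "spatial"):
                    if not ok[name]:
                        rows.append(dict(technique=name, n_trials=n_trials,
                                         endpoint=endpoint, replicate=rep,
                                         p_total=np.nan, p_noise=np.nan,
                                         p_signal=np.nan, snr=np.nan,
                                         negative=False))
                        continue
                    d1, d2 = endpoint_outputs[name][endpoint]
                    est = snr_split_half(d1, d2)
                    rows.append(dict(technique=name, n_trials=n_trials,
                                     endpoint=endpoint, replicate=rep,
                                     p_total=est.p_total, p_noise=est.p_noise,
                                     p_signal=est.p_signal, snr=est.snr,
                                     negative=est.negative))

    per_replicate = pd.DataFrame(rows)
    summary = (
        per_replicate.groupby(["technique", "n_trials", "endpoint"], as_index=False)
        .agg(snr_mean=("snr", "mean"), snr_sem=("snr", "sem"),
             n_replicates=("snr", "count"))
    )
    comparisons = _paired_comparisons(per_replicate)
    cfg = dict(acquisition=acq.to_dict(), disturbance=dist.to_dict(),
               response=resp.to_dict(), techniques=names,
               trial_counts=list(trial_counts), n_replicates=n_replicates,
               trials_per_half=trials_per_half, seed=seed, roi_size=roi_size,
               frame_window=list(frame_window), component=component)
    return SNRReport(per_replicate=per_replicate, summary=summary,
                     comparisons=comparisons, config=cfg)


def plot_snr_curves(report: SNRReport, out_path, endpoint: str = "temporal"):
    """SNR vs trial count, one line per technique (cross-replicate mean
    with standard-error bars).  Requires matplotlib."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    s = report.summary[report.summary["endpoint"] == endpoint]
    for tech, grp in s.groupby("technique"):
        grp = grp.sort_values("n_trials")
        ax.errorbar(grp["n_trials"], grp["snr_mean"], yerr=grp["snr_sem"],
                    marker="o", capsize=3, label=tech)
    ax.set_xlabel("number of trials")
    ax.set_ylabel("split-half SNR")
    ax.set_yscale("log")
    ax.set_title(f"{endpoint} response")
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=150)
    plt.close(fig)
    return out_path


def _paired_comparisons(per_replicate: pd.DataFrame,
                        baseline: str = "averaging") -> pd.DataFrame:
    """Per-replicate SNR deltas vs the baseline technique with paired
    t-tests (reporting plumbing, not part of the estimator)."""
    rows = []
    base = per_replicate[per_replicate["technique"] == baseline]
    for (tech, n_trials, endpoint), grp in per_replicate.groupby(
            ["technique", "n_trials", "endpoint"]):
        if tech == baseline:
            continue
        b = base[(base["n_trials"] == n_trials) & (base["endpoint"] == endpoint)]
        merged = grp.merge(b, on="replicate", suffixes=("", "_base"))
        delta = merged["snr"] - merged["snr_base"]
        valid = delta.dropna()
        if len(valid) >= 2:
            t_stat, p_val = stats.ttest_rel(
                merged["snr"].loc[valid.index], merged["snr_base"].loc[valid.index]
            )
        else:
            t_stat, p_val = np.nan, np.nan
        rows.append(dict(technique=tech, n_trials=n_trials, endpoint=endpoint,
                         delta_mean=valid.mean(), delta_sem=stats.sem(valid)
                         if len(valid) >= 2 else np.nan,
                         t_statistic=t_stat, p_value=p_val, n=len(valid)))
    return pd.DataFrame(rows)
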