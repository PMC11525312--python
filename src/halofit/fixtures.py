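"""Synthetic test data with stored ground truth.

Everything the package analyses can be generated here: single-track
chromatogram peaks (clean or ring-masked), whole plate images with track
geometry, and dose series whose integrals follow a five-parameter logistic.
All outputs are reproducible from (spec, seed).

The default ideal-peak study emulates fluorescence signals of a planar
yeast estrogen screen read with an 8-bit camera: bell-shaped peaks
(Lorentzian- or Gaussian-shaped in equal parts) with amplitudes of 60-220
grey values and width parameters of 30-80 samples, riding on a background
plateau of ~50 grey values, with additive camera noise of 1-2 grey values,
8-bit quantization, and Savitzky-Golay smoothing (polyorder 2, window 111).
The analysis window spans one width parameter around the apex — the
signal-zone interval within which ring maxima delimit the unaffected
flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .errors import DataError, ParameterError
from .image import Chromatogram, GreyImage, TrackGeometry, smooth
from .models import PeakParams, eval_peak
from .peaks import PeakWindow, integrate_peak, make_baseline

MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic study.

    Defaults mirror the replicated validation design: 42 peaks, a 50/50
    Lorentzian/Gaussian shape mix, amplitude range 60-220 grey values,
    width range 30-80 samples, noise sd 1-2 grey values, and a 10-step
    1:2 dose series with five-parameter-logistic truth (top 1, bottom 0,
    inflection 320 dose units, slope -2, symmetry 1) and masking onset
    above 640 dose units.
    """

    seed: int = 0
    n_peaks: int = 42
    shape_mix: Mapping[str, float] = field(
        default_factory=lambda: {"lorentzian": 0.5, "gaussian": 0.5}
    )
    amplitude_range: tuple[float, float] = (60.0, 220.0)
    width_range: tuple[float, float] = (30.0, 80.0)
    noise_sd_range: tuple[float, float] = (1.0, 2.0)
    background: float = 50.0
    track_length: int = 601
    window_factor: float = 1.0  # window length as a multiple of the width parameter
    quantize: bool = True
    smooth_profiles: bool = True
    # dose-series truth
    doses: tuple[float, ...] = tuple(10.0 * 2**k for k in range(10))
    n_replicates: int = 4
    fivepl_truth: tuple[float, float, float, float, float] = (1.0, 0.0, 320.0, -2.0, 1.0)
    masking_onset: float = 640.0
    response_noise_sd: float = 0.05
    # dose spots are quantified over a wider window than the validation-study
    # peaks: ring flanks carry most of the area, as for real halo signals
    dose_window_factor: float = 2.0

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.shape_mix.values()), 1.0):
            raise ParameterError("shape mix fractions must sum to 1")
        for rng_pair in (self.amplitude_range, self.width_range, self.noise_sd_range):
            if rng_pair[0] < 0 or rng_pair[1] < rng_pair[0]:
                raise ParameterError("ranges must be non-negative and ordered")


@dataclass
class PeakTruth:
    """Ground truth for one generated peak."""

    index: int
    kind: str
    params: PeakParams
    amplitude: float
    width: float
    noise_sd: float
    background: float
    window: PeakWindow
    net_integral: float  # noiseless, baseline-corrected, over the window


def _rng(spec: FixtureSpec, *streams: int) -> np.random.Generator:
    return np.random.default_rng([int(spec.seed) % MAX_SEED, *streams])


def _truth_params(kind: str, amplitude: float, width: float, centre: float) -> PeakParams:
    if kind == "lorentzian":
        # width parameter is the FWHM; A scaled so the apex height is `amplitude`
        return PeakParams("lorentzian", A=amplitude * np.pi * width / 2, alpha=centre, width=width)
    if kind == "gaussian":
        return PeakParams("gaussian", A=amplitude, mu=centre, sigma=width)
    raise ParameterError(f"unsupported fixture kind {kind!r}")


def generate_ideal_peak(spec: FixtureSpec, index: int) -> tuple[Chromatogram, PeakTruth]:
    """One unimodal synthetic peak with its ground-truth record.

    The peak kind is drawn from the shape mix (deterministic per index for
    a 50/50 mix: even indices Lorentzian, odd Gaussian), amplitude, width
    and noise sd uniformly from their ranges. The returned chromatogram is
    quantized to 8 bits and Savitzky-Golay smoothed unless the spec
    disables either step.
    """
    rng = _rng(spec, 1, index)
    kinds = sorted(spec.shape_mix)
    fracs = np.array([spec.shape_mix[k] for k in kinds])
    if len(kinds) == 2 and np.allclose(fracs, 0.5):
        kind = ("lorentzian", "gaussian")[index % 2] if set(kinds) == {"lorentzian", "gaussian"} else kinds[index % 2]
    else:
        kind = rng.choice(kinds, p=fracs)
    amplitude = rng.uniform(*spec.amplitude_range)
    width = rng.uniform(*spec.width_range)
    noise_sd = rng.uniform(*spec.noise_sd_range)

    n = spec.track_length
    x = np.arange(n, dtype=float)
    centre = (n - 1) / 2.0
    params = _truth_params(kind, amplitude, width, centre)
    clean = np.asarray(eval_peak(params, x), float) + spec.background

    y = clean + (rng.normal(0.0, noise_sd, n) if noise_sd > 0 else 0.0)
    if spec.quantize:
        y = np.clip(np.round(y), 0, 255)
    chrom = Chromatogram(positions=x, intensities=y, label=f"peak-{index}")
    if spec.smooth_profiles:
        chrom = smooth(chrom)

    half = int(round(spec.window_factor * width)) // 2
    window = PeakWindow(centre - half, centre + half)
    clean_chrom = Chromatogram(positions=x, intensities=clean)
    truth_net = integrate_peak(clean_chrom, window, make_baseline(clean_chrom, window)).net_integral
    truth = PeakTruth(
        index=index,
        kind=kind,
        params=params,
        amplitude=amplitude,
        width=width,
        noise_sd=noise_sd,
        background=spec.background,
        window=window,
        net_integral=truth_net,
    )
    return chrom, truth


def generate_plate_image(
    track_specs: list[dict],
    *,
    width: int = 200,
    height: int = 300,
    background: float = 40.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[GreyImage, list[TrackGeometry]]:
    """Render a synthetic plate: 2-D Gaussian spots, optionally ring-masked.

    Each track spec is a dict with keys ``center_x``, ``spot_y``,
    ``amplitude``, ``spot_sigma`` and optional ``ring`` (bool),
    ``band_width``, ``label``. Emits the image and matching track
    geometries (application at the bottom row, front at the top row).
    """
    rng = np.random.default_rng(seed % MAX_SEED)
    yy, xx = np.mgrid[0:height, 0:width]
    img = np.full((height, width), float(background))
    geoms: list[TrackGeometry] = []
    centers = []
    for i, ts in enumerate(track_specs):
        cx, cy = float(ts["center_x"]), float(ts["spot_y"])
        amp, sig = float(ts["amplitude"]), float(ts["spot_sigma"])
        bw = float(ts.get("band_width", 6 * sig))
        for prev_cx, prev_bw in centers:
            if abs(cx - prev_cx) < (bw + prev_bw) / 2:
                raise DataError("overlapping tracks in plate layout")
        centers.append((cx, bw))
        r2 = (xx - cx) ** 2 + (yy - cy) ** 2
        spot = amp * np.exp(-r2 / (2 * sig**2))
        if ts.get("ring", False):
            # dead centre: suppress the inner area of the spot
            spot *= 1.0 - 0.9 * np.exp(-r2 / (2 * (sig / 2) ** 2))
        img += spot
        geoms.append(
            TrackGeometry(
                track_center_x=cx,
                application_band_width=bw,
                application_y=height - 1,
                front_y=0,
                label=str(ts.get("label", f"track-{i}")),
            )
        )
    if noise_sd > 0:
        img += rng.normal(0, noise_sd, img.shape)
    grey = GreyImage(pixels=np.clip(np.round(img), 0, 255).astype(np.uint8))
    return grey, geoms


def fivepl(x, a: float, d: float, w: float, b: float, f: float):
    """Five-parameter logistic: f(x) = d + (a - d) / (1 + (x/w)^b)^f."""
    x = np.asarray(x, float)
    with np.errstate(over="ignore"):
        return d + (a - d) / (1.0 + (x / w) ** b) ** f


def generate_dose_series(spec: FixtureSpec, *, with_chromatograms: bool = False):
    """Dose series whose true responses follow the spec's 5PL truth.

    One peak per (dose, replicate) is generated with its amplitude scaled
    by the noisy five-parameter-logistic response; doses above the masking
    onset additionally receive the simulated cytotoxic mask. The returned
    DataFrame has one row per (dose, replicate) with

    - ``response_true``: noiseless 5PL value,
    - ``response``: 5PL value plus seeded replicate noise (real-valued;
      baseline-corrected net integrals can be slightly negative),
    - ``integral_ideal``: net integral of the unmasked peak,
    - ``integral_unmodelled``: net integral of the (possibly masked) peak
      as plain integration would report it,
    - ``masked``: whether the masking was applied.

    With ``with_chromatograms=True`` a parallel list of records with the
    masked chromatogram, window and baseline is returned so the
    extrapolation pipeline can produce the "modelled" integrals.
    """
    import pandas as pd

    from .validation import MaskSpec, simulate_masking  # local: avoids cycle

    a, d, w, b, f = spec.fivepl_truth
    rng = _rng(spec, 2)
    base_amp = max(spec.amplitude_range)
    width = float(np.mean(spec.width_range))
    n = spec.track_length
    x = np.arange(n, dtype=float)
    centre = (n - 1) / 2.0
    half = int(round(spec.dose_window_factor * width)) // 2
    window = PeakWindow(centre - half, centre + half)

    rows, chroms = [], []
    for dose in spec.doses:
        true = float(fivepl(dose, a, d, w, b, f))
        for rep in range(spec.n_replicates):
            resp = true + rng.normal(0.0, spec.response_noise_sd)
            amp = base_amp * max(resp, 0.0)
            clean = np.full(n, float(spec.background))
            if amp > 0:
                clean = clean + np.asarray(
                    eval_peak(_truth_params("lorentzian", amp, width, centre), x), float
                )
            noise_sd = rng.uniform(*spec.noise_sd_range)
            y = np.clip(np.round(clean + rng.normal(0, noise_sd, n)), 0, 255)
            chrom = smooth(Chromatogram(positions=x, intensities=y))
            baseline = make_baseline(chrom, window)
            ideal_net = integrate_peak(chrom, window, baseline).net_integral
            masked_flag = dose > spec.masking_onset
            if masked_flag:
                idx = window.indices(chrom)
                xw, yw = chrom.positions[idx], chrom.intensities[idx]
                # a dead spot centre retains the plate background fluorescence
                masked_y = simulate_masking(
                    xw, yw, MaskSpec.from_window(xw, yw, floor=float(spec.background))
                )
                inten = chrom.intensities.copy()
                inten[idx] = masked_y
                chrom = Chromatogram(positions=x, intensities=inten, smoothed=True)
                unmod_net = integrate_peak(chrom, window, baseline).net_integral
            else:
                unmod_net = ideal_net
            rows.append(
                {
                    "dose": dose,
                    "replicate": rep,
                    "response_true": true,
                    "response": resp,
                    "integral_ideal": ideal_net,
                    "integral_unmodelled": unmod_net,
                    "masked": masked_flag,
                }
            )
            if with_chromatograms:
                chroms.append(
                    {"dose": dose, "replicate": rep, "chromatogram": chrom,
                     "window": window, "baseline": baseline, "masked": masked_flag}
                )
    df = pd.DataFrame(rows)
    return (df, chroms) if with_chromatograms else df
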