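"""Synthetic Raman spectra of oil palm fruit exocarp with known ground truth.

The original 46 field spectra are not publicly deposited, so this module
emulates them: each spectrum is a fluorescence-like baseline plus the four
major carotenoid bands (a combination band near 958 cm^-1, C-CH3 rocking
near 1000 cm^-1, C-C stretching near 1150 cm^-1, and the dominant C=C
stretching band nu1 near 1515 cm^-1), with the nu1 band built from four
overlapping Lorentzian sub-bands assigned to lycopene (nu1a), beta-carotene
(nu1b), lutein (nu1c) and neoxanthin (nu1d).

The class-conditional defaults encode the reported ripening trends exactly
at the level of class means: e.g. the beta-carotene sub-band intensity rises
by 170 % from under-ripe to ripe, the lycopene sub-band by 230.5 % from ripe
to over-ripe, and the per-class intensity orderings hold.  Every generated
spectrum records its true sub-band parameters so parameter recovery can be
tested end-to-end.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io import RipenessLabel, Spectrum

__all__ = [
    "SubBandDistribution",
    "ClassProfile",
    "GeneratorConfig",
    "default_profiles",
    "generate_spectrum",
    "generate_dataset",
    "lorentzian",
]

#: Fixed centers (cm^-1) of the three minor carotenoid bands nu4, nu3, nu2.
MINOR_BAND_POSITIONS = (958.0, 1000.0, 1150.0)
#: FWHM (cm^-1) used for each minor band.
MINOR_BAND_FWHM = 10.0

#: Fractional within-class spread of intensity and FWHM (sd = 8 % of mean).
DEFAULT_RELATIVE_SD = 0.08


def lorentzian(x: np.ndarray, position: float, intensity: float, fwhm: float) -> np.ndarray:
    """Height-parameterized Lorentzian: peak value ``intensity`` at ``position``."""
    gamma = fwhm / 2.0
    return intensity * gamma**2 / ((np.asarray(x, dtype=float) - position) ** 2 + gamma**2)


@dataclass(frozen=True)
class SubBandDistribution:
    """Class-conditional distribution of one nu1 sub-band's true parameters."""

    mean_position: float
    sd_position: float
    mean_intensity: float
    sd_intensity: float
    mean_fwhm: float
    sd_fwhm: float

    def __post_init__(self) -> None:
        if self.mean_fwhm <= 0:
            raise ValidationError("mean_fwhm must be positive")
        if self.mean_intensity < 0:
            raise ValidationError("mean_intensity must be non-negative")
        if min(self.sd_position, self.sd_intensity, self.sd_fwhm) < 0:
            raise ValidationError("sd terms must be non-negative")


@dataclass(frozen=True)
class ClassProfile:
    """All four sub-band distributions for one ripeness class.

    ``minor_band_scale`` gives the amplitudes of the nu2/nu3/nu4 bands as
    fractions of the summed nu1 sub-band amplitudes (ordered nu2, nu3, nu4,
    i.e. strongest to weakest minor band).
    """

    label: RipenessLabel
    subbands: tuple[SubBandDistribution, SubBandDistribution, SubBandDistribution, SubBandDistribution]
    minor_band_scale: tuple[float, float, float] = (0.50, 0.30, 0.12)

    def __post_init__(self) -> None:
        if len(self.subbands) != 4:
            raise ValidationError("a class profile holds exactly 4 sub-bands")
        positions = [sb.mean_position for sb in self.subbands]
        if not np.all(np.diff(positions) > 0):
            raise ValidationError("sub-band mean positions must be strictly increasing")
        if len(self.minor_band_scale) != 3:
            raise ValidationError("minor_band_scale must have 3 entries (nu2, nu3, nu4)")


@dataclass(frozen=True)
class GeneratorConfig:
    """Axis, baseline, noise and sampling plan for the generator.

    The baseline is ``slope*(x - axis_start) + intercept`` plus a broad
    Gaussian (fluorescence hump); ``offset`` is a constant zero offset the
    rubber-band correction is meant to remove.  ``n_per_class`` is ordered
    (under-ripe, ripe, over-ripe) and defaults to the field sample plan
    14/20/12.
    """

    axis_start: float = 800.0
    axis_end: float = 1800.0
    axis_step: float = 0.5
    noise_sd: float = 0.0055
    baseline_slope: float = 1e-4
    baseline_intercept: float = 0.0
    baseline_gauss_amplitude: float = 0.3
    baseline_gauss_center: float = 1300.0
    baseline_gauss_width: float = 400.0
    offset: float = 0.05
    n_per_class: tuple[int, int, int] = (14, 20, 12)
    seed: int = 20210915

    def __post_init__(self) -> None:
        if self.axis_step <= 0:
            raise ValidationError("axis_step must be positive")
        if self.axis_start > 940.0 or self.axis_end < 1540.0:
            raise ValidationError("axis must cover at least [940, 1540] cm^-1")
        if any(n < 2 for n in self.n_per_class):
            raise ValidationError("need at least 2 samples per class")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be non-negative")

    def axis(self) -> np.ndarray:
        n = int(round((self.axis_end - self.axis_start) / self.axis_step)) + 1
        return self.axis_start + self.axis_step * np.arange(n)

    def baseline(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        lin = self.baseline_slope * (x - self.axis_start) + self.baseline_intercept
        hump = self.baseline_gauss_amplitude * np.exp(
            -0.5 * ((x - self.baseline_gauss_center) / self.baseline_gauss_width) ** 2
        )
        return lin + hump


def _profile(
    label: RipenessLabel,
    positions: tuple[float, ...],
    position_sds: tuple[float, ...],
    intensities: tuple[float, ...],
    fwhms: tuple[float, ...],
    rel_sd: float = DEFAULT_RELATIVE_SD,
) -> ClassProfile:
    subbands = tuple(
        SubBandDistribution(
            mean_position=p,
            sd_position=ps,
            mean_intensity=a,
            sd_intensity=rel_sd * a,
            mean_fwhm=w,
            sd_fwhm=rel_sd * w,
        )
        for p, ps, a, w in zip(positions, position_sds, intensities, fwhms)
    )
    return ClassProfile(label=label, subbands=subbands)


def default_profiles() -> tuple[ClassProfile, ClassProfile, ClassProfile]:
    """Default class profiles encoding the reported ripening trends.

    Under-ripe base intensities (0.40, 0.55, 0.28, 0.15 a.u.) were chosen to
    satisfy all three per-class intensity orderings simultaneously; the
    class-to-class multipliers are exactly the published percent changes
    (under->ripe: +51.2/+170/+126.2/+35 %; ripe->over: +230.5/-33.8/+46/+83.3 %).
    FWHM means encode the beta-carotene +3.49 %/-20.3 % and lycopene
    -12.78 %/+48.23 % transitions.  Position variance peaks in the ripe class
    for nu1a-c (sd 1.2 vs 0.4 cm^-1); nu1d is wide (sd 1.5) in every class;
    nu1c and nu1d mean positions drop slightly from ripe to over-ripe.
    """
    under_int = (0.40, 0.55, 0.28, 0.15)
    ripe_mult = (1.512, 2.70, 2.262, 1.35)
    over_mult = (3.305, 0.662, 1.46, 1.833)
    ripe_int = tuple(a * m for a, m in zip(under_int, ripe_mult))
    over_int = tuple(a * m for a, m in zip(ripe_int, over_mult))
    under = _profile(
        RipenessLabel.UNDER_RIPE,
        positions=(1506.0, 1512.0, 1519.0, 1524.5),
        position_sds=(0.4, 0.4, 0.4, 1.5),
        intensities=under_int,
        fwhms=(9.00, 10.00, 8.00, 7.50),
    )
    ripe = _profile(
        RipenessLabel.RIPE,
        positions=(1506.0, 1512.0, 1519.0, 1524.5),
        position_sds=(1.2, 1.2, 1.2, 1.5),
        intensities=ripe_int,
        fwhms=(7.85, 10.35, 7.52, 7.05),
    )
    over = _profile(
        RipenessLabel.OVER_RIPE,
        positions=(1506.0, 1512.0, 1518.0, 1523.0),
        position_sds=(0.4, 0.4, 0.4, 1.5),
        intensities=over_int,
        fwhms=(11.64, 8.25, 9.02, 8.46),
    )
    return under, ripe, over


def fixed_position_profiles(
    positions: tuple[float, float, float, float] = (1506.0, 1512.0, 1518.0, 1524.0),
    sd_position: float = 0.4,
) -> tuple[ClassProfile, ClassProfile, ClassProfile]:
    """Default profiles with every class's mean positions pinned.

    Used for position-recovery validation: all classes share the catalog
    mean positions (default: the four sub-band means) with a common
    position sd, while intensities and FWHM keep their class structure.
    """
    out = []
    for profile in default_profiles():
        subbands = tuple(
            SubBandDistribution(
                mean_position=pos,
                sd_position=sd_position,
                mean_intensity=sb.mean_intensity,
                sd_intensity=sb.sd_intensity,
                mean_fwhm=sb.mean_fwhm,
                sd_fwhm=sb.sd_fwhm,
            )
            for pos, sb in zip(positions, profile.subbands)
        )
        out.append(
            ClassProfile(
                label=profile.label,
                subbands=subbands,
                minor_band_scale=profile.minor_band_scale,
            )
        )
    return tuple(out)


_MAX_RESAMPLE = 100


def generate_spectrum(
    profile: ClassProfile,
    config: GeneratorConfig,
    rng: np.random.Generator,
    sample_id: str = "synthetic",
) -> tuple[Spectrum, dict]:
    """Draw one spectrum from a class profile.

    Returns the spectrum and its ground-truth record: the sampled position,
    intensity and FWHM of each nu1 sub-band.  Sampled intensities are
    truncated at zero; a non-positive sampled FWHM is redrawn (bounded
    retries).
    """
    x = config.axis()
    truth: dict = {"sample_id": sample_id, "label": profile.label.name}
    signal = np.zeros_like(x)
    amplitudes = []
    for name, sb in zip(("nu1a", "nu1b", "nu1c", "nu1d"), profile.subbands):
        pos = rng.normal(sb.mean_position, sb.sd_position)
        amp = max(0.0, rng.normal(sb.mean_intensity, sb.sd_intensity))
        fwhm = rng.normal(sb.mean_fwhm, sb.sd_fwhm)
        for _ in range(_MAX_RESAMPLE):
            if fwhm > 0:
                break
            fwhm = rng.normal(sb.mean_fwhm, sb.sd_fwhm)
        else:
            raise ValidationError(f"could not sample a positive FWHM for {name}")
        signal += lorentzian(x, pos, amp, fwhm)
        amplitudes.append(amp)
        truth[f"pos_{name}"] = pos
        truth[f"int_{name}"] = amp
        truth[f"fwhm_{name}"] = fwhm
    total_amp = float(sum(amplitudes))
    # minor bands ordered nu2 (strongest) .. nu4 (weakest); positions ascend
    for pos, scale in zip(MINOR_BAND_POSITIONS, reversed(profile.minor_band_scale)):
        signal += lorentzian(x, pos, scale * total_amp, MINOR_BAND_FWHM)
    y = config.offset + config.baseline(x) + signal
    if config.noise_sd > 0:
        y = y + rng.normal(0.0, config.noise_sd, size=x.size)
    spectrum = Spectrum(
        wavenumbers=x, intensities=y, sample_id=sample_id, label=profile.label
    )
    return spectrum, truth


def generate_dataset(
    config: GeneratorConfig | None = None,
    profiles: tuple[ClassProfile, ClassProfile, ClassProfile] | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Generate a labeled dataset (default: 14 under-ripe, 20 ripe, 12 over-ripe).

    Deterministic for a fixed ``config.seed``.  Returns the spectra and a
    ground-truth table with one row per spectrum, keyed by ``sample_id``.
    """
    config = config or GeneratorConfig()
    profiles = profiles or default_profiles()
    if tuple(p.label for p in profiles) != (
        RipenessLabel.UNDER_RIPE,
        RipenessLabel.RIPE,
        RipenessLabel.OVER_RIPE,
    ):
        raise ValidationError("profiles must be ordered (under-ripe, ripe, over-ripe)")
    rng = np.random.default_rng(config.seed)
    spectra: list[Spectrum] = []
    records: list[dict] = []
    for profile, n in zip(profiles, config.n_per_class):
        for i in range(n):
            sid = f"{profile.label.short}_{i + 1:02d}"
            spec, truth = generate_spectrum(profile, config, rng, sample_id=sid)
            spectra.append(spec)
            records.append(truth)
    return spectra, pd.DataFrame.from_records(records)
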