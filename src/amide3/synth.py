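"""Synthetic GCF Amide III spectra and cohorts.

Emulates the statistical structure the downstream analysis assumes: a
17-participant cohort, ten portions (aliquots) per sample, an Amide III band
built from the fixed 12-Gaussian component model, a smooth baseline and
portion-level intensity variability.  The generator is fully seeded, so every
stage of the pipeline is testable without measured data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .library import (
    AMIDE3_LIBRARY,
    ROMAN_ORDER,
    ASSIGNMENTS,
    TABLE3_AREA_SD,
    TABLE3_PARAMS,
    ComponentLibrary,
    mean_reference_params,
)
from .spectrum import Spectrum

#: FWHM of a Gaussian equals this constant times its standard deviation.
FWHM_PER_SIGMA = 2.0 * math.sqrt(2.0 * math.log(2.0))

GENDER_LEVELS = {"F", "M"}
AGE_LEVELS = {"Y", "O"}
CARIES_LEVELS = {"H", "C", "M"}
PERIODONTAL_LEVELS = {"H", "L", "M"}
COMORBIDITY_LEVELS = {"H", "G", "C", "M"}

FACTOR_COLUMNS = ("gender", "age", "caries", "periodontal", "comorbidity")


class ConfigurationError(ValueError):
    """Invalid synthetic-data configuration."""


@dataclass(frozen=True)
class ComponentSpec:
    """One Gaussian component: position, width and integral intensity.

    `area` is the integral intensity in arbitrary units; when built from the
    reference table it equals the printed percentage share.
    """

    index: str
    assignment: str
    center: float
    fwhm: float
    area: float

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise ValueError(f"component {self.index}: fwhm must be positive, got {self.fwhm}")
        if self.area < 0:
            raise ValueError(f"component {self.index}: area must be non-negative")

    @property
    def sigma(self) -> float:
        return self.fwhm / FWHM_PER_SIGMA

    @property
    def height(self) -> float:
        """Peak amplitude at the center."""
        return self.area / (self.sigma * math.sqrt(2.0 * math.pi))


@dataclass(frozen=True)
class SampleFactors:
    """Clinical factor levels of one participant, encoded as a 5-letter code.

    Letter order: gender (F/M), age (Y/O), caries (H/C/M), periodontal
    disease (H/L/M), comorbidity (H/G/C/M).
    """

    participant_id: str
    gender: str
    age: str
    caries: str
    periodontal: str
    comorbidity: str

    def __post_init__(self) -> None:
        checks = (
            (self.gender, GENDER_LEVELS, "gender"),
            (self.age, AGE_LEVELS, "age"),
            (self.caries, CARIES_LEVELS, "caries"),
            (self.periodontal, PERIODONTAL_LEVELS, "periodontal"),
            (self.comorbidity, COMORBIDITY_LEVELS, "comorbidity"),
        )
        for value, levels, name in checks:
            if value not in levels:
                raise ValueError(f"invalid {name} level {value!r}")
        code = self.code
        if not self.participant_id.startswith(code):
            raise ValueError(
                f"participant_id {self.participant_id!r} inconsistent with factors {code}"
            )

    @property
    def code(self) -> str:
        return self.gender + self.age + self.caries + self.periodontal + self.comorbidity

    @classmethod
    def from_code(cls, code: str, participant_id: str | None = None) -> "SampleFactors":
        if len(code) < 5:
            raise ValueError(f"factor code must have 5 letters, got {code!r}")
        g, a, c, p, m = code[:5]
        return cls(participant_id or code, g, a, c, p, m)


def _default_components() -> tuple[ComponentSpec, ...]:
    base = mean_reference_params()
    return tuple(
        ComponentSpec(r, ASSIGNMENTS[r], center=base[r][0], area=base[r][1], fwhm=base[r][2])
        for r in ROMAN_ORDER
    )


@dataclass(frozen=True)
class SyntheticConfig:
    """Conditions under which synthetic spectra are generated.

    Parameters
    ----------
    components : tuple of 12 ComponentSpec
        The Amide III model; defaults to the mean of the reference samples.
    grid : (min, max, step) in cm^-1
        Wavenumber grid.  Default 1185-1330 at 0.5 cm^-1: finer than the
        nominal 4 cm^-1 instrument resolution so derivative-based peak
        initialization is stable.
    baseline_coeffs : polynomial coefficients, ascending order
        Evaluated in (nu - grid_min); default a small positive-slope line,
        present to exercise the baseline-correction stage.
    noise_sd : additive Gaussian noise SD in absorbance units
        None means 0.5% of the noiseless peak maximum.
    portion_scale_sd : SD of the per-portion multiplicative intensity factor
        Models the slight portion-to-portion intensity variation of repeated
        measurements of one sample.
    n_portions : portions per sample (the study divided each sample into ten).
    seed : base seed for all randomness.
    """

    components: tuple[ComponentSpec, ...] = field(default_factory=_default_components)
    grid: tuple[float, float, float] = (1185.0, 1330.0, 0.5)
    baseline_coeffs: tuple[float, ...] = (0.0,)
    noise_sd: float | None = None
    portion_scale_sd: float = 0.05
    n_portions: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.components) != 12:
            raise ConfigurationError(f"exactly 12 components required, got {len(self.components)}")
        lo, hi, step = self.grid
        if step <= 0 or hi <= lo:
            raise ConfigurationError("grid must satisfy min < max and step > 0")
        if self.n_portions < 1:
            raise ConfigurationError("n_portions must be >= 1")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.portion_scale_sd < 0:
            raise ConfigurationError("portion_scale_sd must be >= 0")

    def wavenumbers(self) -> np.ndarray:
        lo, hi, step = self.grid
        n = int(round((hi - lo) / step)) + 1
        return lo + step * np.arange(n)


def gaussian_profile(spec: ComponentSpec, grid: np.ndarray) -> np.ndarray:
    """Area-normalized Gaussian line shape of one component on `grid`.

    Returns area * N(center, sigma^2) density with sigma = fwhm / (2 sqrt(2 ln 2)),
    so the integral over an unbounded grid equals `area` exactly.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("empty wavenumber grid")
    if spec.fwhm <= 0:
        raise ValueError("fwhm must be positive")
    s = spec.sigma
    z = (grid - spec.center) / s
    return spec.area / (s * math.sqrt(2.0 * math.pi)) * np.exp(-0.5 * z * z)


def model_sum(components, grid: np.ndarray) -> np.ndarray:
    """Sum of all component profiles (the noiseless band model)."""
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    for c in components:
        out += gaussian_profile(c, grid)
    return out


def _noise_sd(config: SyntheticConfig, clean_peak: np.ndarray) -> float:
    if config.noise_sd is not None:
        return config.noise_sd
    return 0.005 * float(np.max(clean_peak)) if clean_peak.size else 0.0


def synthesize_spectrum(
    config: SyntheticConfig,
    portion: int = 0,
    sample_id: str | None = None,
) -> Spectrum:
    """One synthetic portion spectrum: scaled band + baseline + noise.

    The per-portion intensity factor is drawn from N(1, portion_scale_sd^2)
    and the additive noise from N(0, noise_sd^2); both depend only on
    (seed, portion), so the same call is bit-reproducible.
    """
    nu = config.wavenumbers()
    lo, hi = nu[0], nu[-1]
    for c in config.components:
        if not (lo <= c.center <= hi):
            raise ConfigurationError(
                f"grid [{lo}, {hi}] does not cover component {c.index} at {c.center} cm^-1"
            )
    peak = model_sum(config.components, nu)
    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed) % 2**31, int(portion)]))
    scale = 1.0 + config.portion_scale_sd * rng.standard_normal() if config.portion_scale_sd else 1.0
    baseline = np.polynomial.polynomial.polyval(nu - nu[0], config.baseline_coeffs)
    sd = _noise_sd(config, peak)
    noise = sd * rng.standard_normal(nu.size) if sd > 0 else 0.0
    return Spectrum(nu, scale * peak + baseline + noise, sample_id=sample_id, portion_id=portion)


def spectrum_from_table(
    sample_id: str,
    grid: np.ndarray | tuple[float, float, float] = (1185.0, 1330.0, 0.5),
) -> Spectrum:
    """Noiseless 12-Gaussian reconstruction of one reference sample.

    `sample_id` must be one of the four tabulated GCF samples (FYHHH, FOCHH,
    FOCMC, FOMLG).  Printed integral-intensity shares are used as areas in
    arbitrary units, so the total area is ~100.
    """
    if sample_id not in TABLE3_PARAMS:
        raise KeyError(
            f"unknown sample {sample_id!r}; available: {sorted(TABLE3_PARAMS)}"
        )
    if isinstance(grid, tuple) and len(grid) == 3 and np.isscalar(grid[0]):
        lo, hi, step = grid
        n = int(round((hi - lo) / step)) + 1
        nu = lo + step * np.arange(n)
    else:
        nu = np.asarray(grid, dtype=float)
    comps = table_components(sample_id)
    return Spectrum(nu, model_sum(comps, nu), sample_id=sample_id, portion_id=None)


def table_components(sample_id: str) -> tuple[ComponentSpec, ...]:
    """Reference ComponentSpec set for one of the four tabulated samples."""
    params = TABLE3_PARAMS[sample_id]
    return tuple(
        ComponentSpec(
            r, ASSIGNMENTS[r],
            center=params[r][0], area=params[r][1], fwhm=params[r][2],
        )
        for r in ROMAN_ORDER
    )


def default_cohort_factors() -> list[SampleFactors]:
    """The 17-participant cohort, ids made unique where codes repeat."""
    from .library import COHORT_CODES

    seen: dict[str, int] = {}
    out = []
    for code in COHORT_CODES:
        seen[code] = seen.get(code, 0) + 1
        pid = code if seen[code] == 1 else f"{code}-{seen[code]}"
        out.append(SampleFactors.from_code(code, pid))
    return out


def perturb_components(
    base: tuple[ComponentSpec, ...],
    rng: np.random.Generator,
    library: ComponentLibrary = AMIDE3_LIBRARY,
    center_sd: float = 0.5,
    fwhm_sd: float = 0.5,
    area_sd: dict[str, float] | None = None,
) -> tuple[ComponentSpec, ...]:
    """Draw a participant-level parameter set around `base`.

    Centers stay inside the library windows (truncation by clipping), FWHM
    inside [7, 19] cm^-1 and areas non-negative.  Area scatter defaults to
    the across-sample scatter of the reference table.
    """
    if area_sd is None:
        area_sd = {
            r: float(np.mean([TABLE3_AREA_SD[s][r] for s in TABLE3_AREA_SD]))
            for r in ROMAN_ORDER
        }
    out = []
    for spec in base:
        lo, hi = library[spec.index].window
        center = float(np.clip(spec.center + center_sd * rng.standard_normal(), lo, hi))
        fwhm = float(np.clip(spec.fwhm + fwhm_sd * rng.standard_normal(), 7.0, 19.0))
        area = float(max(spec.area + area_sd[spec.index] * rng.standard_normal(), 0.0))
        out.append(ComponentSpec(spec.index, spec.assignment, center, fwhm, area))
    return tuple(out)


def generate_cohort(
    factors: list[SampleFactors] | None = None,
    config: SyntheticConfig | None = None,
    effects: dict[tuple[str, str], dict[str, float]] | None = None,
) -> tuple[list[Spectrum], pd.DataFrame]:
    """Synthesize a whole cohort: n_portions spectra per participant.

    Per-participant component parameters are drawn by perturbing the base
    library within the component windows.  `effects` optionally adds
    structured factor effects: ``{(factor, level): {component: delta_area}}``
    shifts the named component areas (in share points) for every participant
    whose factor takes that level, before portion synthesis.

    Returns the aligned list of spectra (sample_id/portion_id set) and the
    factor table, one row per participant.
    """
    if factors is None:
        factors = default_cohort_factors()
    if config is None:
        config = SyntheticConfig()
    spectra: list[Spectrum] = []
    rows = []
    master = np.random.SeedSequence(int(config.seed) % 2**31)
    part_seeds = master.spawn(len(factors))
    for sf, ss in zip(factors, part_seeds):
        rng = np.random.default_rng(ss)
        comps = perturb_components(config.components, rng)
        if effects:
            deltas: dict[str, float] = {}
            for (factor, level), shift in effects.items():
                if getattr(sf, factor) == level:
                    for roman, d in shift.items():
                        deltas[roman] = deltas.get(roman, 0.0) + d
            if deltas:
                comps = tuple(
                    ComponentSpec(
                        c.index, c.assignment, c.center, c.fwhm,
                        max(c.area + deltas.get(c.index, 0.0), 0.0),
                    )
                    for c in comps
                )
        part_seed = int(rng.integers(0, 2**31))
        part_config = SyntheticConfig(
            components=comps,
            grid=config.grid,
            baseline_coeffs=config.baseline_coeffs,
            noise_sd=config.noise_sd,
            portion_scale_sd=config.portion_scale_sd,
            n_portions=config.n_portions,
            seed=part_seed,
        )
        for portion in range(config.n_portions):
            spectra.append(
                synthesize_spectrum(part_config, portion, sample_id=sf.participant_id)
            )
        rows.append(
            {
                "participant_id": sf.participant_id,
                **{col: getattr(sf, col) for col in FACTOR_COLUMNS},
            }
        )
    table = pd.DataFrame(rows).set_index("participant_id")
    return spectra, table
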