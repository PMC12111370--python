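import numpy as np
import pytest

import amide3 as a
from amide3.library import ROMAN_ORDER, TABLE3_AREA_SD, ASSIGNMENTS
from amide3.synth import ComponentSpec
from amide3.deconv import DeconvolutionResult, FitConstraints

SAMPLES = ("FYHHH", "FOCHH", "FOCMC", "FOMLG")


@pytest.fixture(scope="session")
def table_spectra():
    """Noiseless reconstructions of the four reference samples."""
    return {sid: a.spectrum_from_table(sid) for sid in SAMPLES}


@pytest.fixture(scope="session")
def table_fits(table_spectra):
    """Full-pipeline deconvolutions of the noiseless reference spectra."""
    out = {}
    for sid, spec in table_spectra.items():
        init = a.initialize_peaks(spec)
        out[sid] = a.fit_gaussians(spec, init)
    return out


@pytest.fixture(scope="session")
def portion_sd():
    """Across-sample mean of the printed per-component area scatter."""
    return {
        r: float(np.mean([TABLE3_AREA_SD[s][r] for s in TABLE3_AREA_SD]))
        for r in ROMAN_ORDER
    }


def make_parameter_result(areas: dict) -> DeconvolutionResult:
    """A minimal DeconvolutionResult carrying given component areas.

    Used by the statistical-stage tests, which operate on fitted parameters
    rather than on spectra.
    """
    comps = tuple(
        ComponentSpec(r, ASSIGNMENTS[r], center=1190.0 + 10 * i, fwhm=10.0,
                      area=float(max(areas[r], 0.0)))
        for i, r in enumerate(ROMAN_ORDER)
    )
    nu = np.linspace(1185, 1330, 40)
    return DeconvolutionResult(
        components=comps, init=comps, constraints=FitConstraints(),
        chi2=0.0, n_iter=0, converged=True,
        residual=np.zeros(40), wavenumbers=nu,
    )


def draw_portion_results(rng, base_areas: dict, sd: dict, n: int = 10):
    """Per-portion parameter draws around one sample's component areas."""
    out = []
    for _ in range(n):
        areas = {
            r: base_areas[r] + sd[r] * rng.standard_normal() for r in ROMAN_ORDER
        }
        out.append(make_parameter_result(areas))
    return out
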