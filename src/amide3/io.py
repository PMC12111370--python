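"""Spectrum and table I/O.

CSV is the canonical exchange format: two numeric columns (wavenumber cm^-1,
absorbance) with an optional header line.  Sample and portion identity are
taken from the filename pattern ``<sample>_<portion>.csv`` when present.
"""

from __future__ import annotations

import re
from pathlib import Path

import pandas as pd

from .spectrum import Spectrum

_FILENAME_RE = re.compile(r"^(?P<sample>.+?)(?:_(?P<portion>\d+))?$")


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed; the message names the line."""


def read_spectrum(path: str | Path, dialect: str = "csv") -> Spectrum:
    """Read one spectrum file into canonical ascending-wavenumber form."""
    if dialect == "jcamp":
        raise NotImplementedError(
            "JCAMP-DX ingestion is not available; convert to two-column CSV"
        )
    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    rows: list[tuple[float, float]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            parts = re.split(r"[,;\t]", line)
            if len(parts) < 2:
                raise SpectrumParseError(f"{path.name}:{lineno}: expected two columns")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError:
                if lineno == 1:  # header line
                    continue
                raise SpectrumParseError(
                    f"{path.name}:{lineno}: non-numeric row {line!r}"
                ) from None
    if not rows:
        raise SpectrumParseError(f"{path.name}: no data rows")
    nu = [r[0] for r in rows]
    if len(set(nu)) != len(nu):
        dup = next(v for v in nu if nu.count(v) > 1)
        raise SpectrumParseError(f"{path.name}: duplicate wavenumber {dup}")
    m = _FILENAME_RE.match(path.stem)
    sample = m.group("sample") if m else path.stem
    portion = int(m.group("portion")) if m and m.group("portion") else None
    return Spectrum(nu, [r[1] for r in rows], sample_id=sample, portion_id=portion)


def write_spectrum(spectrum: Spectrum, path: str | Path) -> Path:
    """Write a spectrum as two-column CSV with a header."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {"wavenumber_cm-1": spectrum.wavenumbers, "absorbance": spectrum.absorbance}
    )
    df.to_csv(path, index=False)
    return path


def read_spectra_dir(directory: str | Path) -> list[Spectrum]:
    """Read every ``*.csv`` spectrum in a directory, sorted by name.

    A ``factors.csv`` metadata table living next to the spectra is skipped.
    """
    directory = Path(directory)
    files = sorted(f for f in directory.glob("*.csv") if f.name != "factors.csv")
    if not files:
        raise FileNotFoundError(f"no .csv spectra in {directory}")
    return [read_spectrum(f) for f in files]


def write_factor_table(factors: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    factors.to_csv(path)
    return path


def read_factor_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, index_col=0)


def load_synthetic_config(path: str | Path):
    """Build a SyntheticConfig from a YAML (or JSON) mapping.

    Recognized keys mirror the SyntheticConfig fields; `components` entries
    are mappings with index, assignment, center, fwhm and area.
    """
    import yaml

    from .synth import ComponentSpec, SyntheticConfig

    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "components" in kwargs:
        kwargs["components"] = tuple(
            ComponentSpec(
                c["index"], c["assignment"],
                center=float(c["center"]), fwhm=float(c["fwhm"]), area=float(c["area"]),
            )
            for c in kwargs["components"]
        )
    for key in ("grid", "baseline_coeffs"):
        if key in kwargs:
            kwargs[key] = tuple(kwargs[key])
    return SyntheticConfig(**kwargs)


def dump_synthetic_config(config, path: str | Path) -> Path:
    """Write a SyntheticConfig as YAML (round-trips with load)."""
    import yaml

    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    data = {
        "components": [
            {"index": c.index, "assignment": c.assignment,
             "center": c.center, "fwhm": c.fwhm, "area": c.area}
            for c in config.components
        ],
        "grid": list(config.grid),
        "baseline_coeffs": list(config.baseline_coeffs),
        "noise_sd": config.noise_sd,
        "portion_scale_sd": config.portion_scale_sd,
        "n_portions": config.n_portions,
        "seed": config.seed,
    }
    path.write_text(yaml.safe_dump(data, allow_unicode=True, sort_keys=False))
    return path
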