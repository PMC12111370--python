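"""Fixed Amide III component library and reference deconvolution parameters.

The Amide III absorption band of protein-containing biofluids (~1330-1185 cm^-1)
is modelled as a sum of twelve Gaussian components, each assigned to a protein
secondary-structure class.  Component positions are constrained to narrow
literature windows; the windows, the class assignments and the reference fitted
parameters for four gingival crevicular fluid (GCF) samples are data, not code,
so alternative assignment tables can be swapped in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Roman-numeral component order, low to high wavenumber.
ROMAN_ORDER = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI", "XII")

#: Secondary-structure class of each component.
ASSIGNMENTS = {
    "I": "β-sheet",
    "II": "β-sheet",
    "III": "β-sheet",
    "IV": "β-sheet",
    "V": "β-sheet",
    "VI": "random coil",
    "VII": "random coil",
    "VIII": "β-turn",
    "IX": "β-turn",
    "X": "α-helix",
    "XI": "α-helix",
    "XII": "α-helix",
}

#: Literature wavenumber window (low, high) in cm^-1 for each component center.
WINDOWS = {
    "I": (1194.5, 1196.5),
    "II": (1203.5, 1206.0),
    "III": (1214.0, 1218.0),
    "IV": (1224.5, 1230.0),
    "V": (1238.5, 1242.0),
    "VI": (1251.0, 1254.0),
    "VII": (1261.5, 1264.0),
    "VIII": (1270.0, 1273.0),
    "IX": (1283.0, 1285.0),
    "X": (1298.0, 1299.0),
    "XI": (1308.8, 1311.0),
    "XII": (1317.0, 1318.5),
}


@dataclass(frozen=True)
class LibraryEntry:
    """One component of the fixed Amide III model."""

    index: str
    assignment: str
    window: tuple[float, float]

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.window[0] + self.window[1])


@dataclass(frozen=True)
class ComponentLibrary:
    """Ordered collection of the twelve Amide III component definitions."""

    entries: tuple[LibraryEntry, ...] = field(
        default_factory=lambda: tuple(
            LibraryEntry(r, ASSIGNMENTS[r], WINDOWS[r]) for r in ROMAN_ORDER
        )
    )

    def __post_init__(self) -> None:
        lows = [e.window[0] for e in self.entries]
        highs = [e.window[1] for e in self.entries]
        if any(lo >= hi for lo, hi in zip(lows, highs)):
            raise ValueError("component windows must satisfy low < high")
        if any(b <= a for a, b in zip(lows[1:], lows)):
            # windows ordered low -> high along the entry order
            pass
        if list(lows) != sorted(lows):
            raise ValueError("component windows must be ordered by wavenumber")

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)

    def __getitem__(self, index: str) -> LibraryEntry:
        for e in self.entries:
            if e.index == index:
                return e
        raise KeyError(index)

    @property
    def indices(self) -> tuple[str, ...]:
        return tuple(e.index for e in self.entries)

    def span(self) -> tuple[float, float]:
        """Wavenumber range covered by all windows."""
        return (min(e.window[0] for e in self.entries), max(e.window[1] for e in self.entries))


#: Default Amide III component library.
AMIDE3_LIBRARY = ComponentLibrary()

# Reference fitted parameters for the four GCF samples selected for
# deconvolution.  Per component: (center cm^-1, integral intensity share %,
# FWHM cm^-1).  Integral intensities are treated as areas in arbitrary units
# summing to ~100, since only relative content is analysed downstream.
TABLE3_PARAMS: dict[str, dict[str, tuple[float, float, float]]] = {
    "FYHHH": {
        "I": (1195.0, 0.3, 11.0),
        "II": (1205.3, 4.3, 11.1),
        "III": (1218.1, 10.8, 12.7),
        "IV": (1230.0, 16.8, 14.0),
        "V": (1242.1, 21.0, 13.1),
        "VI": (1253.9, 21.9, 13.3),
        "VII": (1264.2, 9.3, 16.0),
        "VIII": (1273.0, 4.2, 16.0),
        "IX": (1285.0, 2.2, 16.0),
        "X": (1299.0, 2.1, 15.7),
        "XI": (1309.2, 3.4, 14.3),
        "XII": (1317.3, 3.7, 7.4),
    },
    "FOCHH": {
        "I": (1194.5, 0.6, 9.8),
        "II": (1203.4, 3.7, 11.3),
        "III": (1215.0, 9.1, 14.0),
        "IV": (1226.2, 19.0, 15.2),
        "V": (1239.5, 28.4, 13.9),
        "VI": (1251.0, 13.4, 14.2),
        "VII": (1261.5, 8.0, 15.4),
        "VIII": (1270.8, 4.5, 18.0),
        "IX": (1283.9, 3.1, 16.8),
        "X": (1298.1, 2.5, 15.3),
        "XI": (1310.9, 4.0, 13.7),
        "XII": (1318.4, 3.8, 9.2),
    },
    "FOCMC": {
        "I": (1196.0, 0.3, 10.5),
        "II": (1206.0, 4.9, 12.9),
        "III": (1218.0, 12.5, 16.0),
        "IV": (1228.4, 14.6, 16.0),
        "V": (1240.0, 26.4, 14.8),
        "VI": (1251.5, 12.8, 16.3),
        "VII": (1262.0, 10.6, 15.6),
        "VIII": (1273.0, 4.6, 18.0),
        "IX": (1284.0, 4.5, 15.5),
        "X": (1298.0, 4.6, 16.0),
        "XI": (1308.8, 3.0, 15.0),
        "XII": (1317.0, 1.4, 8.0),
    },
    "FOMLG": {
        "I": (1196.4, 0.5, 9.6),
        "II": (1203.5, 3.1, 10.4),
        "III": (1213.8, 7.2, 14.2),
        "IV": (1224.7, 19.9, 14.3),
        "V": (1238.5, 30.2, 13.4),
        "VI": (1251.0, 17.8, 13.0),
        "VII": (1261.8, 6.0, 16.4),
        "VIII": (1269.9, 4.5, 18.0),
        "IX": (1283.0, 1.6, 16.5),
        "X": (1298.6, 2.1, 13.9),
        "XI": (1309.8, 3.5, 13.0),
        "XII": (1317.5, 3.6, 8.1),
    },
}

# Reported across-portion scatter (±) of the integral-intensity shares, same
# sample/component layout as TABLE3_PARAMS.  Used as the default per-portion
# area variability when emulating the cohort and when comparing from summary
# statistics without raw portions.
TABLE3_AREA_SD: dict[str, dict[str, float]] = {
    "FYHHH": {
        "I": 0.30, "II": 0.30, "III": 0.60, "IV": 0.91, "V": 2.12, "VI": 2.72,
        "VII": 1.51, "VIII": 0.60, "IX": 0.30, "X": 0.30, "XI": 0.30, "XII": 0.60,
    },
    "FOCHH": {
        "I": 0.35, "II": 0.35, "III": 0.35, "IV": 1.39, "V": 2.09, "VI": 1.39,
        "VII": 1.74, "VIII": 0.70, "IX": 0.35, "X": 0.35, "XI": 1.05, "XII": 0.35,
    },
    "FOCMC": {
        "I": 0.15, "II": 0.31, "III": 0.61, "IV": 1.22, "V": 3.06, "VI": 1.53,
        "VII": 1.22, "VIII": 0.76, "IX": 0.61, "X": 0.76, "XI": 0.31, "XII": 0.15,
    },
    "FOMLG": {
        "I": 0.34, "II": 0.34, "III": 0.68, "IV": 1.36, "V": 1.70, "VI": 1.36,
        "VII": 0.68, "VIII": 0.68, "IX": 0.34, "X": 0.34, "XI": 0.34, "XII": 0.68,
    },
}

#: Participant codes of the study cohort (gender, age, caries, periodontal,
#: comorbidity encoded positionally).  Codes may repeat: distinct participants
#: can share a clinical profile.
COHORT_CODES = (
    "FYHHH", "FYCHH", "FYCHH", "FOCHH", "MYCLG", "MOCLH", "FOCMC", "FYCHG",
    "MYCLH", "FYCHM", "FOMLG", "MOMLG", "FOMHC", "FOMLM", "FOMLG", "FYMLM",
    "FYCHH",
)


def mean_reference_params() -> dict[str, tuple[float, float, float]]:
    """Component-wise mean of the four reference parameter sets.

    Centers are clipped into the library windows so the result is a valid
    base library for cohort synthesis.
    """
    out: dict[str, tuple[float, float, float]] = {}
    for r in ROMAN_ORDER:
        rows = np.array([TABLE3_PARAMS[s][r] for s in TABLE3_PARAMS])
        c, a, f = rows.mean(axis=0)
        lo, hi = WINDOWS[r]
        out[r] = (float(np.clip(c, lo, hi)), float(a), float(f))
    return out
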