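"""Delta-notation arithmetic and two-point keratin normalization.

Tissue isotope ratios are reported in delta notation relative to an
international standard (VSMOW for H/O, VPDB for C, AIR for N), in per mil.
Raw instrument deltas are placed on those scales by co-analysing two
calibrated keratin reference materials and fitting the unique affine map
that sends the raw readings of the anchors to their accepted values
(comparative equilibration for hydrogen, where only the non-exchangeable
fraction is of interest; the exchange correction is folded into the same
keratin-anchored affine map).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

ISOTOPES = ("d13C", "d15N", "d2H", "d18O")

#: Keratin reference materials with accepted values (per mil) on the
#: international scales: BWBIII/PRCgel anchor the C and N scales,
#: CBS (caribou hoof) and KHS (kudu horn) anchor non-exchangeable H and O.
REFERENCE_MATERIALS: Mapping[str, Mapping[str, float]] = {
    "BWBIII": {"d13C": -20.18, "d15N": 14.31},
    "PRCgel": {"d13C": -13.64, "d15N": 5.07},
    "CBS": {"d2H": -197.0, "d18O": 2.50},
    "KHS": {"d2H": -54.1, "d18O": 21.46},
    "SPK": {"d2H": -106.0, "d18O": 10.8},  # QA/QC control keratin
}


def delta_from_ratio(r_sample, r_std):
    """Delta value in per mil from sample and standard heavy/light isotope ratios.

    delta = 1000 * (r_sample / r_std - 1).
    """
    r_sample = np.asarray(r_sample, dtype=float)
    r_std = np.asarray(r_std, dtype=float)
    if np.any(r_std <= 0):
        raise ValueError("standard ratio must be positive")
    if np.any(r_sample < 0):
        raise ValueError("sample ratio must be non-negative")
    out = 1000.0 * (r_sample / r_std - 1.0)
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class ReferenceMaterial:
    """A named reference material and its accepted per-mil values per isotope."""

    name: str
    accepted: Mapping[str, float]

    def __post_init__(self):
        if not self.accepted:
            raise ValueError("reference material needs at least one accepted value")
        if not all(np.isfinite(v) for v in self.accepted.values()):
            raise ValueError("accepted values must be finite")

    @classmethod
    def known(cls, name: str) -> "ReferenceMaterial":
        return cls(name, dict(REFERENCE_MATERIALS[name]))


@dataclass(frozen=True)
class CalibrationLine:
    """Affine normalization calibrated = slope * raw + intercept for one isotope."""

    isotope: str
    slope: float
    intercept: float
    anchors: tuple[str, str] = ("", "")

    def __post_init__(self):
        if not np.isfinite(self.slope) or self.slope == 0:
            raise ValueError("slope must be finite and nonzero")
        if not np.isfinite(self.intercept):
            raise ValueError("intercept must be finite")

    def apply(self, raw):
        raw = np.asarray(raw, dtype=float)
        out = self.slope * raw + self.intercept
        return float(out) if out.ndim == 0 else out

    def invert(self, calibrated):
        calibrated = np.asarray(calibrated, dtype=float)
        out = (calibrated - self.intercept) / self.slope
        return float(out) if out.ndim == 0 else out


def fit_two_point(raw_a, raw_b, ref_a: ReferenceMaterial, ref_b: ReferenceMaterial,
                  isotope: str) -> CalibrationLine:
    """Two-point normalization through the accepted values of two reference materials."""
    if isotope not in ref_a.accepted or isotope not in ref_b.accepted:
        raise ValueError(f"both reference materials must carry accepted {isotope} values")
    if raw_a == raw_b:
        raise ValueError("degenerate anchors: identical raw readings")
    acc_a = ref_a.accepted[isotope]
    acc_b = ref_b.accepted[isotope]
    slope = (acc_b - acc_a) / (raw_b - raw_a)
    intercept = acc_a - slope * raw_a
    return CalibrationLine(isotope, slope, intercept, (ref_a.name, ref_b.name))


def apply_calibration(raw_table: pd.DataFrame,
                      lines: Mapping[str, CalibrationLine]) -> pd.DataFrame:
    """Normalize every isotope column of a raw table; drop reference rows.

    ``raw_table`` mirrors the record schema with an optional ``role`` column
    (``sample`` | ``reference``). Missing cells stay missing. Every isotope
    column present must have a calibration line.
    """
    present = [c for c in ISOTOPES if c in raw_table.columns]
    missing = [c for c in present if c not in lines]
    if missing:
        raise ValueError(f"no calibration line for isotope(s): {', '.join(missing)}")
    out = raw_table.copy()
    for iso in present:
        out[iso] = lines[iso].apply(out[iso].to_numpy(dtype=float))
    if "role" in out.columns:
        out = out[out["role"] != "reference"].drop(columns=["role"]).reset_index(drop=True)
    return out


def read_reference_materials(path) -> dict[str, ReferenceMaterial]:
    """Read a (name, isotope, accepted_per_mil) CSV into ReferenceMaterial objects."""
    df = pd.read_csv(path)
    out: dict[str, ReferenceMaterial] = {}
    for name, grp in df.groupby("name"):
        out[str(name)] = ReferenceMaterial(
            str(name), dict(zip(grp["isotope"], grp["accepted_per_mil"].astype(float)))
        )
    return out
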