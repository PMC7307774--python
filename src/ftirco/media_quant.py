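"""Univariate glucose and phosphate estimation from ATR media spectra.

Spent-media ATR spectra are dominated by water; the glucose and phosphate
fingerprints sit on top of it in the 900-1200 cm^-1 window.  The estimation
chain is deliberately simple and calibration-free:

1. baseline shift removed by anchoring at 1799 cm^-1 (a band-free point):
   ``s1(v) = s(v) - s(1799)``;
2. normalization to the water bending band: ``s2(v) = s1(v)/s1(1637)``;
3. subtraction of a pure-water reference treated the same way.

Phosphate level ``P_FTIR`` is then read directly at 937 cm^-1.  Glucose and
phosphate both absorb at the glucose marker 1034 cm^-1, so the glucose level
subtracts the phosphate contribution estimated from a pure phosphate
solution reference:

    G_FTIR = A_GM(1034) - A_GM(937) * A_P(1034) / A_P(937)

where A_GM is the preprocessed medium and A_P the preprocessed phosphate
reference.  Values are unitless corrected absorbances, not g/L; an external
two-point calibration can be applied downstream if reference chemistry is
available.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ftirco.spectra_io import (
    SampleMeta,
    SpectraSet,
    Spectrum,
    absorbance_at,
)


class MediaQuantError(Exception):
    pass


class NormalizationError(MediaQuantError):
    pass


class ReferenceError(MediaQuantError):
    pass


@dataclass(frozen=True)
class MediaPreprocConfig:
    """Wavenumbers (cm^-1) used in preprocessing and estimation; all reads
    are nearest-grid-point."""

    baseline_wavenumber: float = 1799.0
    norm_wavenumber: float = 1637.0
    glucose_wavenumber: float = 1034.0
    phosphate_wavenumber: float = 937.0


def _baseline_normalize(
    spectrum: Spectrum, config: MediaPreprocConfig
) -> np.ndarray:
    s = spectrum.absorbance
    s1 = s - absorbance_at(spectrum, config.baseline_wavenumber)
    denom = s1[spectrum.axis.nearest_index(config.norm_wavenumber)]
    if denom <= 1e-12:
        raise NormalizationError(
            f"{spectrum.meta.sample_id}: water-band value at "
            f"{config.norm_wavenumber} cm^-1 is <= 1e-12 after baseline correction"
        )
    return s1 / denom


def preprocess_atr(
    spectrum: Spectrum,
    water_reference: Spectrum,
    config: MediaPreprocConfig = MediaPreprocConfig(),
) -> Spectrum:
    """Baseline-correct, water-peak-normalize, and subtract the identically
    treated water reference."""
    if not np.array_equal(spectrum.axis.values, water_reference.axis.values):
        raise MediaQuantError("spectrum and water reference are not on one axis")
    s2 = _baseline_normalize(spectrum, config)
    w2 = _baseline_normalize(water_reference, config)
    return Spectrum(spectrum.axis, s2 - w2, spectrum.meta)


def preprocess_reference(
    reference: Spectrum,
    water_reference: Spectrum,
    config: MediaPreprocConfig = MediaPreprocConfig(),
) -> Spectrum:
    """References (e.g. the pure phosphate solution) go through the same
    three steps as the media spectra."""
    return preprocess_atr(reference, water_reference, config)


def estimate_phosphate(
    media: Spectrum, config: MediaPreprocConfig = MediaPreprocConfig()
) -> float:
    """P_FTIR: the preprocessed absorbance at the 937 cm^-1 phosphate band."""
    return absorbance_at(media, config.phosphate_wavenumber)


def estimate_glucose(
    media: Spectrum,
    phosphate_reference: Spectrum,
    config: MediaPreprocConfig = MediaPreprocConfig(),
) -> float:
    """G_FTIR: glucose-band absorbance with the phosphate contribution at
    1034 cm^-1 removed via the pure phosphate reference."""
    a_gm_g = absorbance_at(media, config.glucose_wavenumber)
    a_gm_p = absorbance_at(media, config.phosphate_wavenumber)
    a_p_g = absorbance_at(phosphate_reference, config.glucose_wavenumber)
    a_p_p = absorbance_at(phosphate_reference, config.phosphate_wavenumber)
    if abs(a_p_p) <= 1e-12:
        raise ReferenceError(
            "phosphate reference has ~zero absorbance at the phosphate band"
        )
    return a_gm_g - a_gm_p * a_p_g / a_p_p


def _find_reference(sset: SpectraSet, name: str) -> Spectrum:
    mask = (sset.meta["kind"] == "reference") & (sset.meta["sample_id"] == name)
    idx = np.flatnonzero(mask.to_numpy())
    if idx.size == 0:
        raise ReferenceError(f"reference spectrum {name!r} not found in set")
    return sset.spectrum(int(idx[0]))


def media_consumption_report(
    sset: SpectraSet,
    water_reference: Spectrum | None = None,
    phosphate_reference: Spectrum | None = None,
    exclusions: list | None = None,
    config: MediaPreprocConfig = MediaPreprocConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-sample G_FTIR / P_FTIR table plus a grouped summary.

    References default to the rows flagged ``kind="reference"`` named
    ``water`` and ``phosphate_solution``.  Samples in ``exclusions`` are
    flagged and left out of the summary, which averages biological (and
    technical) replicates per (strain, N-source, Pi-level).
    """
    exclusions = set(exclusions or ())
    if water_reference is None:
        water_reference = _find_reference(sset, "water")
    if phosphate_reference is None:
        phosphate_reference = _find_reference(sset, "phosphate_solution")
    p_ref = preprocess_reference(phosphate_reference, water_reference, config)

    rows = []
    media_idx = np.flatnonzero((sset.meta["kind"] == "media_atr").to_numpy())
    for i in media_idx:
        spec = sset.spectrum(int(i))
        meta = spec.meta
        excluded = meta.sample_id in exclusions
        row = {
            "sample_id": meta.sample_id,
            "strain": meta.strain,
            "n_source": meta.n_source,
            "pi_level": meta.pi_level,
            "bio_rep": meta.bio_rep,
            "tech_rep": meta.tech_rep,
            "excluded": excluded,
            "reason": "listed exclusion" if excluded else "",
            "G_FTIR": np.nan,
            "P_FTIR": np.nan,
        }
        if not excluded:
            pre = preprocess_atr(spec, water_reference, config)
            row["G_FTIR"] = estimate_glucose(pre, p_ref, config)
            row["P_FTIR"] = estimate_phosphate(pre, config)
        rows.append(row)
    table = pd.DataFrame(rows)
    n_negative = int(((table["G_FTIR"] < 0) | (table["P_FTIR"] < 0)).sum())
    if n_negative:
        warnings.warn(
            f"{n_negative} sample(s) with negative nutrient estimates "
            "(noise below the detection floor); reported as-is",
            stacklevel=2,
        )

    kept = table[~table["excluded"]]
    summary = (
        kept.groupby(["strain", "n_source", "pi_level"], sort=False, dropna=False)[
            ["G_FTIR", "P_FTIR"]
        ]
        .mean()
        .reset_index()
    )
    return table, summary
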