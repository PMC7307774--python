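"""Preprocessing of HTS biomass spectra.

Two branches are supported, mirroring how region-level and overview analyses
are prepared:

* branch 1 — Savitzky-Golay second derivative (degree-2 polynomial, window
  of 11 or 61 points), then polynomial-extended EMSC, then averaging of
  technical replicates.  The narrow 11-point window emphasizes sharp lipid
  and chitin/chitosan bands; the broad 61-point window the broad
  polyphosphate bands.
* branch 2 — average technical then biological replicates, then EMSC, for a
  whole-spectrum overview.

EMSC here is the classic model extended by linear and quadratic terms: each
sample is regressed onto {reference, 1, x, x^2} (x = axis scaled to [-1,1])
and corrected as (sample - a - d*x - e*x^2)/b, which removes additive
offsets, polynomial baselines and multiplicative path-length effects in one
least-squares step.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from ftirco.spectra_io import (
    SpectraSet,
    Spectrum,
    WavenumberAxis,
    average_replicates,
)


class PreprocessError(Exception):
    pass


class AxisError(PreprocessError):
    pass


class ConditioningError(PreprocessError):
    pass


class DegenerateSampleError(PreprocessError):
    pass


@dataclass(frozen=True)
class SGConfig:
    """Savitzky-Golay derivative settings (degree-2, second derivative,
    window of 11 or 61 points in the study)."""

    window_points: int = 11
    poly_degree: int = 2
    deriv_order: int = 2

    def __post_init__(self) -> None:
        if self.window_points < 5 or self.window_points % 2 == 0:
            raise PreprocessError("window_points must be an odd integer >= 5")
        if self.poly_degree >= self.window_points:
            raise PreprocessError("poly_degree must be < window_points")
        if self.deriv_order > self.poly_degree:
            raise PreprocessError("deriv_order must be <= poly_degree")


def sg_second_derivative(sset: SpectraSet, config: SGConfig = SGConfig()) -> SpectraSet:
    """Second derivative w.r.t. wavenumber via a Savitzky-Golay filter.

    Requires a uniform axis (relative tolerance 1e-3 on the spacing).  Output
    has the same length as the input; boundary channels come from one-sided
    polynomial fits over the first/last window.  Units: absorbance * cm^2
    (index-space derivative divided by spacing**deriv).
    """
    axis = sset.axis
    if not axis.is_uniform(rtol=1e-3):
        raise AxisError("Savitzky-Golay derivative requires a uniform axis")
    if len(axis) < config.window_points:
        raise PreprocessError(
            f"axis has {len(axis)} points, smaller than window {config.window_points}"
        )
    spacing = float(np.median(np.diff(axis.values)))
    deriv = savgol_filter(
        sset.matrix,
        window_length=config.window_points,
        polyorder=config.poly_degree,
        deriv=config.deriv_order,
        delta=spacing,
        axis=1,
        mode="interp",
    )
    out = SpectraSet(axis, deriv, sset.meta.copy(), copy.deepcopy(sset.provenance))
    return out.with_stage(
        "sg_second_derivative",
        window_points=config.window_points,
        poly_degree=config.poly_degree,
        deriv_order=config.deriv_order,
    )


@dataclass
class EMSCModel:
    """Fitted EMSC: reference spectrum, per-sample coefficients and the
    corrected spectra.

    Coefficient columns: ``b`` multiplicative, ``a`` additive offset, then
    ``p1..p_degree`` for the polynomial terms in the scaled axis (``p1`` =
    linear ``d``, ``p2`` = quadratic ``e`` at the default degree 2).
    """

    reference: np.ndarray
    poly_degree: int
    coefficients: pd.DataFrame
    corrected: SpectraSet


def fit_emsc(
    sset: SpectraSet,
    reference="set_mean",
    poly_degree: int = 2,
) -> EMSCModel:
    """Fit the polynomial-extended EMSC model to every sample.

    Each sample s is regressed (ordinary least squares) onto
    {reference, 1, x, x^2, ...} and corrected as
    ``(s - a - p1*x - ... )/b``.  The reference defaults to the mean spectrum
    of the set being corrected.
    """
    axis = sset.axis
    if isinstance(reference, str):
        if reference != "set_mean":
            raise ValueError(f"unknown reference spec {reference!r}")
        ref = sset.matrix.mean(axis=0)
    elif isinstance(reference, Spectrum):
        if not np.array_equal(reference.axis.values, axis.values):
            raise PreprocessError("reference is not on the set's axis")
        ref = reference.absorbance
    else:
        ref = np.asarray(reference, dtype=float)
        if ref.shape != (len(axis),):
            raise PreprocessError("reference length does not match the axis")

    x = axis.normalized()
    poly = np.vander(x, poly_degree + 1, increasing=True).T  # rows: 1, x, x^2...
    # conditioning guard: the reference must not lie in the polynomial span
    proj, *_ = np.linalg.lstsq(poly.T, ref, rcond=None)
    resid = ref - poly.T @ proj
    ref_norm = np.linalg.norm(ref)
    if ref_norm < 1e-300 or np.linalg.norm(resid) <= 1e-8 * max(ref_norm, 1.0):
        raise ConditioningError(
            "EMSC reference is (numerically) a polynomial of the axis; "
            "the multiplicative coefficient is not identifiable"
        )

    basis = np.vstack([ref, poly])  # (2 + degree) x P
    coef, *_ = np.linalg.lstsq(basis.T, sset.matrix.T, rcond=None)
    coef = coef.T  # samples x (2 + degree): [b, a, p1, ..., p_degree]
    b = coef[:, 0]
    bad = np.abs(b) <= 1e-12
    if bad.any():
        names = sset.meta.loc[bad, "sample_id"].tolist()
        raise DegenerateSampleError(
            f"multiplicative coefficient ~ 0 for sample(s) {names}"
        )
    baseline = coef[:, 1:] @ poly  # samples x P
    corrected_matrix = (sset.matrix - baseline) / b[:, None]

    columns = ["b", "a"] + [f"p{k}" for k in range(1, poly_degree + 1)]
    coefficients = pd.DataFrame(coef, columns=columns)
    coefficients.insert(0, "sample_id", sset.meta["sample_id"].to_numpy())

    corrected = SpectraSet(
        axis, corrected_matrix, sset.meta.copy(), copy.deepcopy(sset.provenance)
    ).with_stage("emsc", poly_degree=poly_degree, reference="set_mean" if isinstance(reference, str) else "external")
    return EMSCModel(
        reference=ref,
        poly_degree=poly_degree,
        coefficients=coefficients,
        corrected=corrected,
    )


def _has_stage(sset: SpectraSet, stage: str) -> bool:
    return any(p.get("stage") == stage for p in sset.provenance)


def preprocess_branch1(sset: SpectraSet, window: int = 11) -> SpectraSet:
    """Derivative branch: SG second derivative (given window) -> EMSC against
    the mean derivative spectrum -> average technical replicates.

    On the full study design (936 measured spectra) this yields 312 spectra,
    one per biological sample.  Calling the branch on data that already
    carries a derivative stage is not an error, but the repeat is flagged in
    the provenance record.
    """
    reapplied = _has_stage(sset, "sg_second_derivative")
    deriv = sg_second_derivative(sset, SGConfig(window_points=window))
    model = fit_emsc(deriv, reference="set_mean", poly_degree=2)
    averaged = average_replicates(
        model.corrected, ["strain", "n_source", "pi_level", "bio_rep"]
    )
    out = averaged.with_stage("preprocess_branch1", window=window)
    if reapplied:
        out.provenance[-1]["reapplied_on_derivative"] = True
    return out


def preprocess_branch2(sset: SpectraSet) -> SpectraSet:
    """Overview branch: average technical replicates -> average biological
    replicates -> EMSC (set-mean reference, degree 2).

    On the full study design this yields 104 spectra, one per grown
    (strain, N-source, Pi-level) combination.
    """
    tech_avg = average_replicates(
        sset, ["strain", "n_source", "pi_level", "bio_rep"]
    )
    bio_avg = average_replicates(tech_avg, ["strain", "n_source", "pi_level"])
    model = fit_emsc(bio_avg, reference="set_mean", poly_degree=2)
    return model.corrected.with_stage("preprocess_branch2")
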