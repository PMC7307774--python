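"""Region-restricted PCA and ANOVA variance decomposition.

Two questions drive the biomass analysis:

* *what varies?* — PCA of the preprocessed spectra, run separately per
  nitrogen source and (for the metabolite views) restricted to the lipid,
  polyphosphate or chitin/chitosan band regions;
* *why does it vary?* — a fixed-effects ANOVA decomposition of each strain's
  spectra into level-mean matrices for the N-source factor (2 levels), the
  Pi factor (6 levels) and their interaction (12 cells), plus a residual.
  The sum of squares of each factor's effect matrix, normalized over the
  three factors of interest so the shares sum to 100%, quantifies how much
  of the spectral variation each design factor is responsible for.
  Biological-replicate scatter remains in the residual and is reported but
  never enters the normalization.  This is the decomposition underlying
  ANOVA-PCA/ASCA.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ftirco.spectra_io import (
    REGION_WINDOWS,
    REGIONS,
    RegionSet,
    SpectraSet,
    extract_regions,
)


class ChemometricsError(Exception):
    pass


class DegenerateFactorWarning(UserWarning):
    pass


@dataclass
class PCAResult:
    """Centered (not scaled) PCA of a spectra matrix.

    ``explained_variance_fraction`` is sigma_i^2 over the sum of *all*
    squared singular values up to the matrix rank, so the retained fractions
    need not sum to 1.  Sign convention: each loading vector is flipped so
    its largest-magnitude element is positive.
    """

    scores: np.ndarray  # samples x components
    loadings: np.ndarray  # components x wavenumbers
    explained_variance_fraction: np.ndarray
    mean_spectrum: np.ndarray
    wavenumbers: np.ndarray
    sample_ids: list
    labels: dict = field(default_factory=dict)


def pca(sset: SpectraSet, n_components: int = 2) -> PCAResult:
    """Column-mean-centered SVD PCA."""
    X = sset.matrix
    n, p = X.shape
    if n < 2:
        raise ChemometricsError("PCA needs at least 2 samples")
    if n_components > min(n - 1, p):
        raise ChemometricsError(
            f"n_components={n_components} exceeds min(samples-1, wavenumbers)"
        )
    mean = X.mean(axis=0)
    Xc = X - mean
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    total = float(np.sum(s**2))
    if total <= 0:
        raise ChemometricsError("matrix has zero variance")
    frac = (s**2 / total)[:n_components]
    scores = U[:, :n_components] * s[:n_components]
    loadings = Vt[:n_components]
    # deterministic sign: largest-|.| loading element positive
    for k in range(n_components):
        j = int(np.argmax(np.abs(loadings[k])))
        if loadings[k, j] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    return PCAResult(
        scores=scores,
        loadings=loadings,
        explained_variance_fraction=frac,
        mean_spectrum=mean,
        wavenumbers=sset.axis.values.copy(),
        sample_ids=sset.meta["sample_id"].tolist(),
        labels={},
    )


@dataclass
class EffectMatrices:
    """ANOVA decomposition X = m + A_N + A_Pi + A_int + residual (row-wise)."""

    grand_mean: np.ndarray  # P
    a_n: np.ndarray  # n x P
    a_pi: np.ndarray
    a_int: np.ndarray
    residual: np.ndarray
    warnings: list = field(default_factory=list)


def anova_effect_matrices(
    sset: SpectraSet,
    n_col: str = "n_source",
    pi_col: str = "pi_level",
) -> EffectMatrices:
    """Decompose a (single-strain) spectra matrix into design-factor
    level-mean matrices.

    Row i of each effect matrix holds the deviation of the corresponding
    level mean from the grand mean: ``A_N[i] = mean(rows with i's N) - m``;
    ``A_int[i] = mean(rows in i's (N, Pi) cell) - m - A_N[i] - A_Pi[i]``.
    Cells absent from the data (no-growth combinations) simply contribute no
    rows; all means are taken over observed rows only.  The reconstruction
    ``m + A_N + A_Pi + A_int + residual = X`` is exact by construction.
    """
    X = sset.matrix
    n = X.shape[0]
    if n == 0:
        raise ChemometricsError("empty set")
    meta = sset.meta
    for col in (n_col, pi_col):
        if meta[col].isna().any():
            raise ChemometricsError(f"missing values in factor column {col!r}")
    m = X.mean(axis=0)

    warnings_list = []

    def _level_effects(labels) -> np.ndarray:
        levels = pd.unique(labels)
        if len(levels) < 2:
            warnings_list.append(
                f"factor with single observed level {levels[0]!r}: effect set to 0"
            )
            return np.zeros_like(X)
        out = np.empty_like(X)
        for lev in levels:
            mask = (labels == lev).to_numpy()
            out[mask] = X[mask].mean(axis=0) - m
        return out

    n_labels = meta[n_col].astype(str)
    pi_labels = meta[pi_col].astype(str)
    a_n = _level_effects(n_labels)
    a_pi = _level_effects(pi_labels)

    cell_labels = n_labels + "\x1f" + pi_labels
    a_int = np.empty_like(X)
    for lev in pd.unique(cell_labels):
        mask = (cell_labels == lev).to_numpy()
        a_int[mask] = X[mask].mean(axis=0) - m
    a_int -= a_n + a_pi
    residual = X - m - a_n - a_pi - a_int
    return EffectMatrices(m, a_n, a_pi, a_int, residual, warnings_list)


def variation_contribution(
    sset: SpectraSet,
    region: RegionSet | str | None = None,
) -> dict:
    """Percent of spectral variation attributable to N, Pi, and N x Pi for
    one strain's spectra (technical replicates already averaged).

    ``SS_f`` is the sum of squared entries of factor f's effect matrix;
    shares are normalized over the three factors so they sum to 100.  The
    residual SS (biological scatter and everything else) is returned
    alongside but excluded from the normalization.
    """
    if region is not None:
        if isinstance(region, str):
            region = REGIONS[region]
        sset = extract_regions(sset, region)
    em = anova_effect_matrices(sset)
    ss = {
        "ss_n": float(np.sum(em.a_n**2)),
        "ss_pi": float(np.sum(em.a_pi**2)),
        "ss_int": float(np.sum(em.a_int**2)),
        "ss_residual": float(np.sum(em.residual**2)),
    }
    total = ss["ss_n"] + ss["ss_pi"] + ss["ss_int"]
    if total <= 0:
        raise ChemometricsError(
            "all three factor sums of squares are zero; contributions undefined"
        )
    return {
        "var_N": 100.0 * ss["ss_n"] / total,
        "var_Pi": 100.0 * ss["ss_pi"] / total,
        "var_int": 100.0 * ss["ss_int"] / total,
        **ss,
        "warnings": em.warnings,
    }


def variation_table(
    sset: SpectraSet,
    regions=("lipid", "polyphosphate", "chitin_chitosan"),
) -> pd.DataFrame:
    """Per-strain, per-region variation contributions over a preprocessed set
    (biological replicates retained, technical replicates averaged)."""
    rows = []
    for region_name in regions:
        region = REGIONS[region_name] if isinstance(region_name, str) else region_name
        for strain in pd.unique(sset.meta["strain"].dropna()):
            sub = sset.where(strain=strain)
            vc = variation_contribution(sub, region)
            rows.append(
                {
                    "strain": strain,
                    "region": region.name,
                    "var_N": vc["var_N"],
                    "var_Pi": vc["var_Pi"],
                    "var_int": vc["var_int"],
                    "ss_residual": vc["ss_residual"],
                }
            )
    return pd.DataFrame(rows)


def run_region_pca(
    sset: SpectraSet,
    region_name: str,
    n_components: int = 2,
    split_col: str = "n_source",
) -> dict:
    """PCA per nitrogen-source split over one metabolite region.

    The input should be branch-1 preprocessed with the window bound to the
    region (11 points for lipid and chitin/chitosan, 61 for polyphosphate);
    a mismatch is recorded as a label, not an error.
    """
    region = REGIONS[region_name]
    cut = extract_regions(sset, region)
    expected_window = REGION_WINDOWS.get(region.name)
    used_window = next(
        (
            p.get("window_points", p.get("window"))
            for p in reversed(sset.provenance)
            if p.get("stage") in ("sg_second_derivative", "preprocess_branch1")
        ),
        None,
    )
    results: dict[str, PCAResult] = {}
    for split in pd.unique(cut.meta[split_col].dropna()):
        sub = cut.where(**{split_col: split})
        res = pca(sub, n_components=n_components)
        res.labels = {
            "region": region.name,
            "split": str(split),
            "window_expected": expected_window,
            "window_used": used_window,
        }
        results[str(split)] = res
    return results
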