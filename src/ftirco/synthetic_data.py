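"""Synthetic FTIR spectra with known ground truth.

Generates study-shaped data so every downstream stage (derivatives, EMSC,
region PCA, ANOVA variance decomposition, media estimation) can be tested
without the original raw measurements:

* biomass transmission (HTS) spectra are path-length-scaled mixtures of
  lipid, chitin/chitosan, polyphosphate, protein and carbohydrate band
  systems, distorted by a quadratic baseline and additive noise;
* growth-media ATR spectra are water + glucose + phosphate (+ organic acid)
  mixtures with an offset and noise.

Band positions follow the standard mid-infrared assignments for fungal
biomass (ester carbonyl at 1745, acyl CH at 2925/2855, polyphosphate P=O and
P-O-P near 1265/885, chitin amide and N-H bands, carbohydrate C-O region),
and for the media the glucose (1151, 1103, 1080, 1034, 990) and phosphate
(1161, 1076, 937) fingerprints plus the water bending band at 1637.

The factorial design is 9 strains x 2 N-sources x 6 Pi levels x 3 biological
replicates, each measured in 3 technical replicates, with the two Mortierella
strains excluded at the highest phosphate level (no growth).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from ftirco.spectra_io import (
    N_SOURCES,
    PI_LEVELS,
    STRAINS,
    MetadataError,
    SampleMeta,
    SpectraSet,
    Spectrum,
    WavenumberAxis,
)

#: (strain, pi_level) combinations where no growth was observed and hence no
#: biomass spectra exist.
STUDY_EXCLUSIONS = (("MAL", "Pi8"), ("MHY", "Pi8"))

#: Pi level on a log2 scale relative to the reference recipe (Pi1).
PI_LOG2 = {"Pi0.25": -2.0, "Pi0.5": -1.0, "Pi1": 0.0, "Pi2": 1.0, "Pi4": 2.0, "Pi8": 3.0}

#: Pi level as a multiple of the reference phosphate-salt concentration.
PI_MULTIPLE = {"Pi0.25": 0.25, "Pi0.5": 0.5, "Pi1": 1.0, "Pi2": 2.0, "Pi4": 4.0, "Pi8": 8.0}

NARROW_FWHM = 20.0  # cm^-1, lipid / chitin-like sharp bands
BROAD_FWHM = 60.0  # cm^-1, polyphosphate / water-like broad bands


class SimulationError(Exception):
    pass


@dataclass(frozen=True)
class BandModel:
    """One absorption band: gaussian or lorentzian profile."""

    center: float
    fwhm: float = NARROW_FWHM
    height: float = 1.0
    shape: str = "gaussian"

    def __post_init__(self) -> None:
        if self.fwhm <= 0:
            raise SimulationError(f"band at {self.center}: fwhm must be > 0")
        if self.height < 0:
            raise SimulationError(f"band at {self.center}: height must be >= 0")
        if self.shape not in ("gaussian", "lorentzian"):
            raise SimulationError(f"unknown band shape {self.shape!r}")

    def profile(self, wavenumbers: np.ndarray) -> np.ndarray:
        d = wavenumbers - self.center
        if self.shape == "gaussian":
            return self.height * np.exp(-4.0 * math.log(2.0) * d**2 / self.fwhm**2)
        hw = self.fwhm / 2.0
        return self.height * hw**2 / (d**2 + hw**2)


@dataclass(frozen=True)
class ComponentSpectrum:
    """A named pure-component band system."""

    name: str
    bands: tuple

    def __post_init__(self) -> None:
        if not self.bands:
            raise SimulationError(f"component {self.name}: needs at least one band")
        object.__setattr__(self, "bands", tuple(self.bands))

    def evaluate(self, axis: WavenumberAxis) -> np.ndarray:
        out = np.zeros(len(axis))
        for band in self.bands:
            out += band.profile(axis.values)
        return out


def component_spectrum(component: ComponentSpectrum, axis: WavenumberAxis) -> Spectrum:
    """Pure-component spectrum on ``axis`` (sum of its band profiles)."""
    return Spectrum(
        axis,
        component.evaluate(axis),
        SampleMeta(sample_id=component.name, kind="reference"),
    )


def _g(center, height, fwhm=NARROW_FWHM):
    return BandModel(center=center, height=height, fwhm=fwhm)


#: Pure-component band library used by both simulators.
DEFAULT_LIBRARY: dict[str, ComponentSpectrum] = {
    "lipid": ComponentSpectrum(
        "lipid",
        (
            _g(3010, 0.15),
            _g(2955, 0.35),
            _g(2925, 0.9),
            _g(2855, 0.6),
            _g(1745, 1.0),
            _g(1465, 0.35),
            _g(1160, 0.3),
            _g(725, 0.15),
        ),
    ),
    "chitin_chitosan": ComponentSpectrum(
        "chitin_chitosan",
        (
            _g(3434, 0.4, BROAD_FWHM),
            _g(3275, 0.6),
            _g(3105, 0.35),
            _g(1660, 0.8),
            _g(1629, 0.7),
            _g(1550, 0.6),
            _g(1377, 0.35),
            _g(1070, 0.5, BROAD_FWHM),
            _g(952, 0.3),
        ),
    ),
    "polyphosphate": ComponentSpectrum(
        "polyphosphate",
        (_g(1265, 1.0, BROAD_FWHM), _g(885, 0.8, BROAD_FWHM)),
    ),
    "protein": ComponentSpectrum(
        "protein",
        (_g(3290, 0.5, BROAD_FWHM), _g(1655, 1.0, 40.0), _g(1545, 0.7, 40.0)),
    ),
    "carbohydrate": ComponentSpectrum(
        "carbohydrate",
        (_g(3400, 0.5, 120.0), _g(1150, 0.4, 40.0), _g(1050, 0.8, BROAD_FWHM)),
    ),
    "organic_acid": ComponentSpectrum("organic_acid", (_g(1715, 1.0, 30.0),)),
    "water": ComponentSpectrum(
        "water", (_g(3350, 1.2, 300.0), _g(1637, 1.0, 80.0))
    ),
    "glucose": ComponentSpectrum(
        "glucose",
        (
            _g(1151, 0.5),
            _g(1103, 0.6),
            _g(1080, 0.7),
            _g(1034, 1.0),
            _g(990, 0.5),
        ),
    ),
    "phosphate": ComponentSpectrum(
        "phosphate",
        (_g(1161, 0.5), _g(1076, 0.8), _g(937, 1.0)),
    ),
}

BIOMASS_COMPONENTS = (
    "lipid",
    "chitin_chitosan",
    "polyphosphate",
    "protein",
    "carbohydrate",
)


# ---------------------------------------------------------------------------
# Design construction


def build_design(
    strains: Sequence[str] = STRAINS,
    n_sources: Sequence[str] = N_SOURCES,
    pi_levels: Sequence[str] = PI_LEVELS,
    bio_reps: int = 3,
    exclusions: Iterable[tuple] = (),
) -> list[SampleMeta]:
    """Full factorial design at biological-replicate granularity.

    Excluded (strain, pi_level) combinations are kept in the design with
    ``grew=False``; they are dropped when expanding to measured spectra.
    """
    if not (strains and n_sources and pi_levels):
        raise MetadataError("strains, n_sources, pi_levels must be non-empty")
    if bio_reps < 1:
        raise MetadataError("bio_reps must be >= 1")
    excl = set()
    for strain, pi in exclusions:
        if strain not in strains:
            raise MetadataError(f"exclusion names unknown strain {strain!r}")
        if pi not in pi_levels:
            raise MetadataError(f"exclusion names unknown Pi level {pi!r}")
        excl.add((strain, pi))
    design: list[SampleMeta] = []
    for strain in strains:
        for n in n_sources:
            for pi in pi_levels:
                grew = (strain, pi) not in excl
                for rep in range(1, bio_reps + 1):
                    design.append(
                        SampleMeta(
                            sample_id=f"{strain}_{n}_{pi}_b{rep}",
                            strain=strain,
                            n_source=n,
                            pi_level=pi,
                            bio_rep=rep,
                            kind="biomass_hts",
                            grew=grew,
                        )
                    )
    return design


def expand_technical(
    design: Sequence[SampleMeta], tech_reps: int = 3, grown_only: bool = True
) -> list[SampleMeta]:
    """Expand biological samples into measured technical replicates."""
    if tech_reps < 1:
        raise MetadataError("tech_reps must be >= 1")
    out: list[SampleMeta] = []
    for s in design:
        if grown_only and not s.grew:
            continue
        for t in range(1, tech_reps + 1):
            out.append(
                SampleMeta(
                    sample_id=f"{s.sample_id}_t{t}",
                    strain=s.strain,
                    n_source=s.n_source,
                    pi_level=s.pi_level,
                    bio_rep=s.bio_rep,
                    tech_rep=t,
                    kind=s.kind,
                    grew=s.grew,
                )
            )
    return out


def study_design() -> list[SampleMeta]:
    """The screening design: 324 biological samples, 312 grown (the two
    Mortierella strains do not grow at Pi8)."""
    return build_design(exclusions=STUDY_EXCLUSIONS)


# ---------------------------------------------------------------------------
# Effect model


def _default_baselines() -> dict:
    # Strain-specific component levels (arbitrary absorbance-like units)
    # echoing the screening's qualitative picture: UVI is the strongest lipid
    # producer; MCI/ARO/RST/AGL store polyphosphates; cell-wall chitin is
    # present everywhere at moderate levels.
    rows = {
        #          lipid  chitin polyP  protein carbo
        "AGL": (0.50, 0.45, 0.40, 0.50, 0.50),
        "ARO": (0.45, 0.40, 0.55, 0.50, 0.50),
        "CBL": (0.40, 0.50, 0.30, 0.55, 0.50),
        "LCO": (0.35, 0.50, 0.25, 0.55, 0.50),
        "MAL": (0.60, 0.35, 0.20, 0.45, 0.45),
        "MHY": (0.55, 0.35, 0.15, 0.45, 0.45),
        "MCI": (0.55, 0.45, 0.55, 0.50, 0.50),
        "RST": (0.30, 0.50, 0.60, 0.55, 0.50),
        "UVI": (0.80, 0.35, 0.15, 0.40, 0.45),
    }
    return {
        strain: dict(zip(BIOMASS_COMPONENTS, vals)) for strain, vals in rows.items()
    }


@dataclass
class EffectModel:
    """How the design factors move the latent component concentrations.

    Concentration of component k in biological sample (strain, N, Pi, rep):

        c_k = max(0, base[strain][k] + n_effect[k][N]
                     + (pi_slope[k] + int_slope[k]·1[N=AS]) · log2(Pi)
                     + bio_noise)

    Defaults encode the qualitative trends seen in the screening: intracellular
    polyphosphate rises with the phosphate level (most strongly on ammonium
    sulphate, where Pi is the only phosphorus source), chitin/chitosan rises
    under phosphorus starvation on AS, and lipid storage drops at low Pi on AS.
    """

    baseline: dict = field(default_factory=_default_baselines)
    n_effect: dict = field(
        default_factory=lambda: {
            "lipid": {"YE": 0.05, "AS": 0.0},
            "chitin_chitosan": {"YE": 0.0, "AS": 0.05},
            "polyphosphate": {"YE": 0.02, "AS": 0.0},
            "protein": {"YE": 0.05, "AS": 0.0},
            "carbohydrate": {"YE": 0.0, "AS": 0.0},
        }
    )
    pi_slope: dict = field(
        default_factory=lambda: {
            "lipid": 0.0,
            "chitin_chitosan": -0.01,
            "polyphosphate": 0.04,
            "protein": 0.0,
            "carbohydrate": 0.0,
        }
    )
    int_slope: dict = field(
        default_factory=lambda: {
            "lipid": 0.03,
            "chitin_chitosan": -0.05,
            "polyphosphate": 0.08,
            "protein": 0.0,
            "carbohydrate": 0.0,
        }
    )
    bio_sd: float = 0.02
    tech_noise_sd: float = 0.003
    path_log_sd: float = 0.15
    baseline_ranges: dict = field(
        default_factory=lambda: {
            "a0": (-0.05, 0.05),
            "a1": (-0.02, 0.02),
            "a2": (-0.02, 0.02),
        }
    )

    def __post_init__(self) -> None:
        for name in ("bio_sd", "tech_noise_sd", "path_log_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be >= 0")

    def concentration(
        self, strain: str, n_source: str, pi_level: str, component: str, bio_noise: float
    ) -> float:
        base = self.baseline.get(strain, {}).get(component, 0.0)
        n_eff = self.n_effect.get(component, {}).get(n_source, 0.0)
        slope = self.pi_slope.get(component, 0.0)
        if n_source == "AS":
            slope += self.int_slope.get(component, 0.0)
        c = base + n_eff + slope * PI_LOG2[pi_level] + bio_noise
        return max(0.0, c)

    # YAML round-trip -------------------------------------------------------
    def to_yaml(self, path) -> None:
        payload = {
            "baseline": self.baseline,
            "n_effect": self.n_effect,
            "pi_slope": self.pi_slope,
            "int_slope": self.int_slope,
            "bio_sd": self.bio_sd,
            "tech_noise_sd": self.tech_noise_sd,
            "path_log_sd": self.path_log_sd,
            "baseline_ranges": {k: list(v) for k, v in self.baseline_ranges.items()},
        }
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EffectModel":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        payload["baseline_ranges"] = {
            k: tuple(v) for k, v in payload.get("baseline_ranges", {}).items()
        }
        return cls(**payload)


# ---------------------------------------------------------------------------
# Simulators


def _bio_key(meta: SampleMeta) -> tuple:
    return (meta.strain, meta.n_source, meta.pi_level, meta.bio_rep)


def simulate_biomass_set(
    design: Sequence[SampleMeta],
    effects: EffectModel | None = None,
    library: Mapping[str, ComponentSpectrum] | None = None,
    axis: WavenumberAxis | None = None,
    seed: int = 0,
) -> tuple[SpectraSet, pd.DataFrame]:
    """Simulate HTS biomass spectra for a measured design.

    Per sample: ``A(v) = b * sum_k c_k s_k(v) + a0 + a1*x + a2*x^2 + eps(v)``
    with ``x`` the axis mapped onto [-1, 1].  Technical replicates of one
    biological sample share the concentrations ``c_k`` and differ in path
    length ``b``, baseline, and noise.  Fully deterministic under
    ``(seed, design, effects)``; per-sample random streams are derived from
    the global seed and stable biological/technical counters so any subset of
    the design reproduces identically.

    Returns the spectra plus a ground-truth table (one row per measured
    spectrum: concentrations, path length, baseline coefficients, noise sd).
    """
    if not design:
        raise SimulationError("design is empty")
    effects = effects if effects is not None else EffectModel()
    library = library if library is not None else DEFAULT_LIBRARY
    axis = axis if axis is not None else WavenumberAxis.hts_default()

    comps = [k for k in BIOMASS_COMPONENTS if k in library]
    S = np.vstack([library[k].evaluate(axis) for k in comps])  # K x P
    x = axis.normalized()

    bio_index: dict[tuple, int] = {}
    bio_noise: dict[tuple, np.ndarray] = {}
    concentrations: dict[tuple, np.ndarray] = {}

    matrix = np.empty((len(design), len(axis)))
    truth_rows = []
    for i, meta in enumerate(design):
        key = _bio_key(meta)
        if key not in bio_index:
            b_idx = len(bio_index)
            bio_index[key] = b_idx
            rng_bio = np.random.default_rng([seed, 1, b_idx])
            noise = rng_bio.normal(0.0, effects.bio_sd, size=len(comps))
            bio_noise[key] = noise
            concentrations[key] = np.array(
                [
                    effects.concentration(
                        meta.strain, meta.n_source, meta.pi_level, comp, noise[j]
                    )
                    for j, comp in enumerate(comps)
                ]
            )
        c = concentrations[key]
        rng_tech = np.random.default_rng([seed, 2, i])
        b = float(np.exp(rng_tech.normal(0.0, effects.path_log_sd)))
        a0 = float(rng_tech.uniform(*effects.baseline_ranges["a0"]))
        a1 = float(rng_tech.uniform(*effects.baseline_ranges["a1"]))
        a2 = float(rng_tech.uniform(*effects.baseline_ranges["a2"]))
        eps = rng_tech.normal(0.0, effects.tech_noise_sd, size=len(axis))
        matrix[i] = b * (c @ S) + a0 + a1 * x + a2 * x**2 + eps
        row = meta.as_dict()
        row.update({f"c_{comp}": c[j] for j, comp in enumerate(comps)})
        row.update(
            {
                "path_length": b,
                "a0": a0,
                "a1": a1,
                "a2": a2,
                "noise_sd": effects.tech_noise_sd,
                "seed": seed,
            }
        )
        truth_rows.append(row)

    meta_df = pd.DataFrame([m.as_dict() for m in design])
    sset = SpectraSet(axis, matrix, meta_df).with_stage(
        "simulate_biomass", seed=seed, n_samples=len(design)
    )
    return sset, pd.DataFrame(truth_rows)


def default_consumption(
    design: Sequence[SampleMeta], seed: int = 0
) -> pd.DataFrame:
    """Plausible per-biological-sample nutrient fractions remaining.

    Glucose consumption tracks growth (grown samples consume 30-90% of the
    starting glucose; no-growth wells keep it all); the phosphate fraction
    remaining rises with the starting Pi level (uptake saturates).
    """
    rows = []
    seen = set()
    for i, meta in enumerate(design):
        key = _bio_key(meta)
        if key in seen:
            continue
        seen.add(key)
        rng = np.random.default_rng([seed, 3, len(seen) - 1])
        if meta.grew:
            g = float(np.clip(rng.uniform(0.1, 0.7), 0.0, 1.0))
            p_base = 1.0 - 0.8 / PI_MULTIPLE[meta.pi_level] ** 0.5
            p = float(np.clip(p_base + rng.normal(0.0, 0.05), 0.0, 1.0))
        else:
            g, p = 1.0, 1.0
        rows.append(
            {
                "strain": meta.strain,
                "n_source": meta.n_source,
                "pi_level": meta.pi_level,
                "bio_rep": meta.bio_rep,
                "glucose_frac": g,
                "phosphate_frac": p,
            }
        )
    return pd.DataFrame(rows)


@dataclass
class MediaModel:
    """Amplitudes and noise for the media (ATR) simulator, in the water-peak
    normalized absorbance scale of the preprocessed spectra."""

    glucose_amp: float = 0.6  # full (uncultivated) 80 g/L glucose signal
    phosphate_amp: float = 0.05  # signal per Pi1-equivalent of phosphate salts
    acid_amp: float = 0.08  # organic-acid carbonyl, strongest at low Pi on AS
    offset_sd: float = 0.01
    noise_sd: float = 0.001
    reference_phosphate_multiple: float = 4.0

    def __post_init__(self) -> None:
        if self.noise_sd < 0 or self.offset_sd < 0:
            raise SimulationError("noise settings must be >= 0")


def simulate_media_set(
    design: Sequence[SampleMeta],
    consumption: pd.DataFrame | None = None,
    library: Mapping[str, ComponentSpectrum] | None = None,
    axis: WavenumberAxis | None = None,
    seed: int = 0,
    media_model: MediaModel | None = None,
    tech_reps: int = 3,
) -> tuple[SpectraSet, pd.DataFrame]:
    """Simulate ATR spectra of spent growth media.

    ``A(v) = water(v) + g*glucose(v) + p*phosphate(v) + acid*organic_acid(v)
    + offset + eps(v)``, where ``g`` and ``p`` derive from the true fractions
    remaining (``consumption``, per biological sample) and the starting
    amounts (glucose identical everywhere; phosphate proportional to the Pi
    level).  Media exist for every biological sample — also the no-growth
    wells — each measured in ``tech_reps`` technical replicates.

    Two reference spectra (pure water and a pure phosphate solution) are
    appended with ``kind="reference"``.
    """
    if not design:
        raise SimulationError("design is empty")
    library = library if library is not None else DEFAULT_LIBRARY
    axis = axis if axis is not None else WavenumberAxis.atr_default()
    mm = media_model if media_model is not None else MediaModel()
    if consumption is None:
        consumption = default_consumption(design, seed=seed)
    cons = consumption.set_index(["strain", "n_source", "pi_level", "bio_rep"])
    if ((cons["glucose_frac"] < 0) | (cons["glucose_frac"] > 1)).any():
        raise SimulationError("glucose fractions must lie in [0, 1]")
    if ((cons["phosphate_frac"] < 0) | (cons["phosphate_frac"] > 1)).any():
        raise SimulationError("phosphate fractions must lie in [0, 1]")

    water = library["water"].evaluate(axis)
    glucose = library["glucose"].evaluate(axis)
    phosphate = library["phosphate"].evaluate(axis)
    acid = library["organic_acid"].evaluate(axis)

    measured = expand_technical(list(design), tech_reps=tech_reps, grown_only=False)
    matrix = np.empty((len(measured) + 2, len(axis)))
    metas = []
    truth_rows = []
    for i, meta in enumerate(measured):
        g_frac, p_frac = cons.loc[_bio_key(meta), ["glucose_frac", "phosphate_frac"]]
        g_amt = float(g_frac) * mm.glucose_amp
        p_amt = float(p_frac) * PI_MULTIPLE[meta.pi_level] * mm.phosphate_amp
        # acidification is strongest for grown AS cultures under Pi limitation
        if meta.grew and meta.n_source == "AS":
            acid_amt = mm.acid_amp / PI_MULTIPLE[meta.pi_level] ** 0.5
        else:
            acid_amt = 0.0
        rng = np.random.default_rng([seed, 4, i])
        offset = float(rng.normal(0.0, mm.offset_sd))
        eps = rng.normal(0.0, mm.noise_sd, size=len(axis))
        matrix[i] = (
            water + g_amt * glucose + p_amt * phosphate + acid_amt * acid + offset + eps
        )
        m = SampleMeta(
            sample_id=meta.sample_id.replace("_b", "_media_b"),
            strain=meta.strain,
            n_source=meta.n_source,
            pi_level=meta.pi_level,
            bio_rep=meta.bio_rep,
            tech_rep=meta.tech_rep,
            kind="media_atr",
            grew=meta.grew,
        )
        metas.append(m)
        truth_rows.append(
            {
                **m.as_dict(),
                "glucose_frac": float(g_frac),
                "phosphate_frac": float(p_frac),
                "glucose_amt": g_amt,
                "phosphate_amt": p_amt,
                "acid_amt": acid_amt,
                "offset": offset,
                "noise_sd": mm.noise_sd,
                "seed": seed,
            }
        )

    # reference spectra, noise-free
    matrix[len(measured)] = water
    metas.append(SampleMeta(sample_id="water", kind="reference"))
    p_ref = mm.reference_phosphate_multiple * mm.phosphate_amp
    matrix[len(measured) + 1] = water + p_ref * phosphate
    metas.append(SampleMeta(sample_id="phosphate_solution", kind="reference"))

    meta_df = pd.DataFrame([m.as_dict() for m in metas])
    sset = SpectraSet(axis, matrix, meta_df).with_stage(
        "simulate_media", seed=seed, n_samples=len(measured)
    )
    return sset, pd.DataFrame(truth_rows)
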