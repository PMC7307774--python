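"""Spectral data model and I/O.

The unit of exchange between all pipeline stages is the :class:`SpectraSet`:
a shared wavenumber axis, a samples-by-wavenumbers absorbance matrix, and a
pandas metadata table with one row per sample.  Wavenumber axes are stored
ascending (instruments typically export descending; readers canonicalize).

On-disk formats are deliberately plain:

* wide CSV — first column ``wavenumber_cm-1``, one column per sample, header
  row of sample ids; a sibling tab-separated metadata table keyed by
  ``sample_id`` carries the design factors.
* a minimal JCAMP-DX-like text format for single spectra (``##XUNITS=1/CM``,
  ``##YUNITS=ABSORBANCE``, XY pairs).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

# Design vocabulary of the screening experiment: nine Mucoromycota strains,
# two nitrogen sources (yeast extract / ammonium sulphate), six phosphate
# levels labelled as multiples of the reference KH2PO4/Na2HPO4 recipe.
STRAINS = ("AGL", "ARO", "CBL", "LCO", "MAL", "MHY", "MCI", "RST", "UVI")
N_SOURCES = ("YE", "AS")
PI_LEVELS = ("Pi0.25", "Pi0.5", "Pi1", "Pi2", "Pi4", "Pi8")
SAMPLE_KINDS = ("biomass_hts", "media_atr", "reference")

#: Nominal digital spacing of the HTS instrument grid, cm^-1.
HTS_SPACING = 1.928

META_COLUMNS = [
    "sample_id",
    "strain",
    "n_source",
    "pi_level",
    "bio_rep",
    "tech_rep",
    "kind",
    "grew",
]


class SpectraError(Exception):
    """Base class for spectra I/O and axis errors."""


class ParseError(SpectraError):
    pass


class MetadataError(SpectraError):
    pass


class RangeError(SpectraError):
    pass


class EmptyRegionError(SpectraError):
    pass


@dataclass(frozen=True)
class WavenumberAxis:
    """Strictly increasing wavenumber grid in cm^-1."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size == 0:
            raise SpectraError("axis must be a non-empty 1-D array")
        if not np.all(np.isfinite(values)):
            raise SpectraError("axis contains non-finite wavenumbers")
        if np.any(np.diff(values) == 0):
            raise SpectraError("axis contains duplicate wavenumbers")
        if values[0] > values[-1]:
            values = values[::-1]
        if np.any(np.diff(values) <= 0):
            raise SpectraError("axis is not strictly monotonic")
        object.__setattr__(self, "values", values)
        self.values.setflags(write=False)

    def __len__(self) -> int:
        return self.values.size

    @property
    def spacing(self) -> float | str:
        """Nominal step in cm^-1, or ``"irregular"``."""
        d = np.diff(self.values)
        step = float(np.median(d))
        if np.allclose(d, step, rtol=1e-3, atol=0.0):
            return step
        return "irregular"

    def is_uniform(self, rtol: float = 1e-3) -> bool:
        d = np.diff(self.values)
        return bool(np.allclose(d, np.median(d), rtol=rtol, atol=0.0))

    def nearest_index(self, target: float) -> int:
        """Index of the grid point nearest ``target``; ties go to the higher
        wavenumber.  ``target`` must lie within the axis range."""
        v = self.values
        if target < v[0] or target > v[-1]:
            raise RangeError(
                f"wavenumber {target} outside axis range [{v[0]}, {v[-1]}]"
            )
        j = int(np.searchsorted(v, target))
        if j == 0:
            return 0
        lo, hi = j - 1, j
        # closed tie -> higher wavenumber
        if abs(v[hi] - target) <= abs(target - v[lo]):
            return hi
        return lo

    def normalized(self) -> np.ndarray:
        """Axis mapped affinely onto [-1, 1]; basis for polynomial baselines."""
        v = self.values
        return 2.0 * (v - v[0]) / (v[-1] - v[0]) - 1.0

    @classmethod
    def hts_default(cls) -> "WavenumberAxis":
        """Default HTS transmission grid: 500-4000 cm^-1, step 1.928 cm^-1."""
        n = int(np.floor((4000.0 - 500.0) / HTS_SPACING)) + 1
        return cls(500.0 + HTS_SPACING * np.arange(n))

    @classmethod
    def atr_default(cls) -> "WavenumberAxis":
        """Default ATR grid: 600-4000 cm^-1 at the same digital spacing."""
        n = int(np.floor((4000.0 - 600.0) / HTS_SPACING)) + 1
        return cls(600.0 + HTS_SPACING * np.arange(n))


@dataclass
class SampleMeta:
    """Design metadata for one measured spectrum."""

    sample_id: str
    strain: str | None = None
    n_source: str | None = None
    pi_level: str | None = None
    bio_rep: int | None = None
    tech_rep: int | None = None
    kind: str = "biomass_hts"
    grew: bool = True

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise MetadataError("sample_id must be a non-empty string")
        if self.strain is not None and self.strain not in STRAINS:
            raise MetadataError(f"unknown strain code {self.strain!r}")
        if self.n_source is not None and self.n_source not in N_SOURCES:
            raise MetadataError(f"unknown N-source {self.n_source!r}")
        if self.pi_level is not None and self.pi_level not in PI_LEVELS:
            raise MetadataError(f"unknown Pi level {self.pi_level!r}")
        if self.kind not in SAMPLE_KINDS:
            raise MetadataError(f"unknown sample kind {self.kind!r}")

    def as_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "strain": self.strain,
            "n_source": self.n_source,
            "pi_level": self.pi_level,
            "bio_rep": self.bio_rep,
            "tech_rep": self.tech_rep,
            "kind": self.kind,
            "grew": self.grew,
        }


@dataclass
class Spectrum:
    """A single absorbance spectrum on a wavenumber axis."""

    axis: WavenumberAxis
    absorbance: np.ndarray
    meta: SampleMeta

    def __post_init__(self) -> None:
        ab = np.asarray(self.absorbance, dtype=float)
        if ab.shape != (len(self.axis),):
            raise SpectraError(
                f"absorbance length {ab.size} != axis length {len(self.axis)}"
            )
        if not np.all(np.isfinite(ab)):
            raise SpectraError(f"non-finite absorbance in {self.meta.sample_id}")
        self.absorbance = ab


@dataclass
class SpectraSet:
    """A batch of spectra sharing one axis.

    ``meta`` is a DataFrame with the columns of :data:`META_COLUMNS`;
    ``provenance`` records the preprocessing stages applied so far.
    """

    axis: WavenumberAxis
    matrix: np.ndarray
    meta: pd.DataFrame
    provenance: list = field(default_factory=list)

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.ndim != 2 or m.shape[1] != len(self.axis):
            raise SpectraError(
                f"matrix shape {m.shape} incompatible with axis length {len(self.axis)}"
            )
        if len(self.meta) != m.shape[0]:
            raise SpectraError(
                f"metadata rows ({len(self.meta)}) != matrix rows ({m.shape[0]})"
            )
        self.matrix = m
        self.meta = self.meta.reset_index(drop=True)

    def __len__(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_samples(self) -> int:
        return self.matrix.shape[0]

    def spectrum(self, i: int) -> Spectrum:
        row = self.meta.iloc[i]
        return Spectrum(self.axis, self.matrix[i], _meta_from_row(row))

    def select(self, mask) -> "SpectraSet":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return SpectraSet(
            self.axis,
            self.matrix[idx],
            self.meta.iloc[idx].reset_index(drop=True),
            copy.deepcopy(self.provenance),
        )

    def where(self, **conditions) -> "SpectraSet":
        """Subset by metadata equality, e.g. ``set.where(strain="MCI")``."""
        mask = np.ones(len(self), dtype=bool)
        for col, val in conditions.items():
            mask &= (self.meta[col] == val).to_numpy()
        return self.select(mask)

    def with_stage(self, stage: str, **params) -> "SpectraSet":
        out = copy.copy(self)
        out.provenance = copy.deepcopy(self.provenance) + [
            {"stage": stage, **params}
        ]
        return out

    @classmethod
    def from_spectra(cls, spectra: Sequence[Spectrum]) -> "SpectraSet":
        if not spectra:
            raise SpectraError("cannot build a SpectraSet from zero spectra")
        axis = spectra[0].axis
        for s in spectra[1:]:
            if not np.array_equal(s.axis.values, axis.values):
                raise SpectraError("spectra do not share an axis")
        matrix = np.vstack([s.absorbance for s in spectra])
        meta = pd.DataFrame([s.meta.as_dict() for s in spectra])
        return cls(axis, matrix, meta)


def _meta_from_row(row: pd.Series) -> SampleMeta:
    def _int_or_none(x):
        return None if pd.isna(x) else int(x)

    def _str_or_none(x):
        return None if (x is None or (isinstance(x, float) and np.isnan(x))) else x

    return SampleMeta(
        sample_id=str(row["sample_id"]),
        strain=_str_or_none(row.get("strain")),
        n_source=_str_or_none(row.get("n_source")),
        pi_level=_str_or_none(row.get("pi_level")),
        bio_rep=_int_or_none(row.get("bio_rep")),
        tech_rep=_int_or_none(row.get("tech_rep")),
        kind=row.get("kind", "biomass_hts"),
        grew=bool(row.get("grew", True)),
    )


@dataclass(frozen=True)
class RegionSet:
    """Named list of closed wavenumber intervals, cm^-1."""

    name: str
    intervals: tuple

    def __post_init__(self) -> None:
        ivs = tuple(tuple(map(float, iv)) for iv in self.intervals)
        for lo, hi in ivs:
            if not lo < hi:
                raise SpectraError(f"region {self.name}: invalid interval [{lo}, {hi}]")
        ivs = tuple(sorted(ivs))
        for (lo1, hi1), (lo2, hi2) in zip(ivs, ivs[1:]):
            if lo2 <= hi1:
                raise SpectraError(
                    f"region {self.name}: overlapping intervals "
                    f"[{lo1}, {hi1}] and [{lo2}, {hi2}]"
                )
        object.__setattr__(self, "intervals", ivs)

    def mask(self, axis: WavenumberAxis) -> np.ndarray:
        """Boolean mask of axis points inside any closed interval."""
        v = axis.values
        m = np.zeros(v.size, dtype=bool)
        for lo, hi in self.intervals:
            sel = (v >= lo) & (v <= hi)
            if not sel.any():
                raise EmptyRegionError(
                    f"region {self.name}: interval [{lo}, {hi}] contains no axis points"
                )
            m |= sel
        return m


#: Analysis regions for the three target metabolite band systems.
REGIONS: dict[str, RegionSet] = {
    "lipid": RegionSet(
        "lipid",
        (
            (2819.0, 3020.0),
            (1726.0, 1760.0),
            (1375.0, 1475.0),
            (1149.0, 1160.0),
            (715.0, 730.0),
        ),
    ),
    "polyphosphate": RegionSet(
        "polyphosphate",
        ((1203.0, 1301.0), (842.0, 925.0)),
    ),
    "chitin_chitosan": RegionSet(
        "chitin_chitosan",
        (
            (3417.0, 3457.0),
            (3251.0, 3293.0),
            (3081.0, 3133.0),
            (1623.0, 1639.0),
            (1346.0, 1392.0),
            (941.0, 962.0),
        ),
    ),
}

#: Savitzky-Golay window bound to each region downstream: narrow lipid and
#: chitin/chitosan bands use 11 points, broad polyphosphate bands use 61.
REGION_WINDOWS = {"lipid": 11, "chitin_chitosan": 11, "polyphosphate": 61}


# ---------------------------------------------------------------------------
# I/O


def _meta_path_for(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.tsv")


def load_spectra(
    path,
    format: str = "wide_csv",
    metadata_path=None,
) -> SpectraSet:
    """Read a :class:`SpectraSet` from disk.

    ``wide_csv``: first column is the wavenumber grid, remaining columns are
    samples; metadata comes from ``metadata_path`` (default: sibling
    ``<file>.meta.tsv``).  ``jcamp_like``: a minimal single-spectrum text
    format; returns a one-row set.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "wide_csv":
        return _load_wide_csv(path, metadata_path)
    if format == "jcamp_like":
        return _load_jcamp_like(path)
    raise ValueError(f"unknown format {format!r}")


def _load_wide_csv(path: Path, metadata_path) -> SpectraSet:
    try:
        df = pd.read_csv(path, dtype=str)
    except Exception as exc:  # pragma: no cover - pandas message passthrough
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[1] < 2:
        raise ParseError(f"{path}: wide CSV needs a wavenumber column plus samples")
    sample_ids = [str(c) for c in df.columns[1:]]
    values = np.empty((df.shape[0], df.shape[1]), dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise").to_numpy(float)
        except (ValueError, TypeError):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0]
            raise ParseError(
                f"{path}: non-numeric cell at row {row + 2}, column {col!r}: "
                f"{bad.iloc[0]!r}"
            ) from None
    wn = values[:, 0]
    matrix = values[:, 1:].T  # samples x wavenumbers

    metadata_path = (
        Path(metadata_path) if metadata_path is not None else _meta_path_for(path)
    )
    if metadata_path.exists():
        meta = _read_meta_table(metadata_path)
        missing = set(sample_ids) - set(meta["sample_id"])
        if missing:
            raise MetadataError(
                f"{path}: sample ids missing from metadata table: {sorted(missing)}"
            )
        meta = (
            meta.set_index("sample_id").loc[sample_ids].reset_index()
        )  # preserve column order
    else:
        meta = pd.DataFrame(
            [SampleMeta(sample_id=s, strain=None).as_dict() for s in sample_ids]
        )

    axis = WavenumberAxis(wn)
    if wn[0] > wn[-1]:
        matrix = matrix[:, ::-1]
    return SpectraSet(axis, matrix, meta)


def _read_meta_table(path: Path) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id"}
    if not required <= set(meta.columns):
        raise MetadataError(f"{path}: metadata table lacks sample_id column")
    for col in META_COLUMNS:
        if col not in meta.columns:
            meta[col] = None
    for col in ("bio_rep", "tech_rep"):
        meta[col] = pd.to_numeric(meta[col], errors="coerce").astype("Int64")
    meta["grew"] = (
        meta["grew"].map({"True": True, "False": False, None: True}).fillna(True)
    )
    return meta[META_COLUMNS]


def _load_jcamp_like(path: Path) -> SpectraSet:
    title = path.stem
    xs: list[float] = []
    ys: list[float] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        if line.startswith("##"):
            key, _, val = line[2:].partition("=")
            if key.upper() == "TITLE" and val:
                title = val.strip()
            continue
        parts = line.replace(",", " ").split()
        if len(parts) != 2:
            raise ParseError(f"{path}:{lineno}: expected an XY pair, got {line!r}")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric XY pair {line!r}") from None
    if not xs:
        raise ParseError(f"{path}: no XY data")
    order = np.argsort(xs)
    axis = WavenumberAxis(np.asarray(xs)[order])
    matrix = np.asarray(ys)[order][None, :]
    meta = pd.DataFrame([SampleMeta(sample_id=title).as_dict()])
    return SpectraSet(axis, matrix, meta)


def write_spectra(sset: SpectraSet, path, format: str = "wide_csv") -> None:
    """Write a :class:`SpectraSet` (wide CSV + sibling metadata TSV, or a
    one-spectrum JCAMP-DX-like file).  Lossless to >= 9 significant digits."""
    if len(sset) == 0:
        raise SpectraError("refusing to write an empty SpectraSet")
    ids = sset.meta["sample_id"].astype(str)
    if (ids == "").any() or ids.isna().any():
        raise MetadataError("empty sample_id in metadata")
    if ids.duplicated().any():
        raise MetadataError(
            f"duplicate sample ids: {sorted(ids[ids.duplicated()].unique())}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "wide_csv":
        _write_wide_csv(sset, path)
    elif format == "jcamp_like":
        _write_jcamp_like(sset, path)
    else:
        raise ValueError(f"unknown format {format!r}")


def _write_wide_csv(sset: SpectraSet, path: Path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write("wavenumber_cm-1," + ",".join(sset.meta["sample_id"]) + "\n")
        for j, wn in enumerate(sset.axis.values):
            row = ",".join(format(x, ".12g") for x in sset.matrix[:, j])
            fh.write(f"{wn:.12g},{row}\n")
    meta = sset.meta.copy()
    meta.to_csv(_meta_path_for(path), sep="\t", index=False)


def _write_jcamp_like(sset: SpectraSet, path: Path) -> None:
    if len(sset) != 1:
        raise SpectraError("jcamp_like format holds exactly one spectrum")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"##TITLE={sset.meta['sample_id'].iloc[0]}\n")
        fh.write("##XUNITS=1/CM\n##YUNITS=ABSORBANCE\n")
        for wn, ab in zip(sset.axis.values, sset.matrix[0]):
            fh.write(f"{wn:.12g} {ab:.12g}\n")
        fh.write("##END=\n")


# ---------------------------------------------------------------------------
# Axis / region / replicate utilities


def absorbance_at(spectrum: Spectrum, target: float) -> float:
    """Absorbance at the grid point nearest ``target`` (ties -> higher
    wavenumber).  This is how all single-wavenumber reads (e.g. the 937 cm^-1
    phosphate band) are taken on the digitized grid."""
    return float(spectrum.absorbance[spectrum.axis.nearest_index(target)])


def extract_regions(sset: SpectraSet, regions: RegionSet) -> SpectraSet:
    """Restrict a set to the axis points falling inside the closed intervals
    of ``regions``; point order and metadata are preserved."""
    mask = regions.mask(sset.axis)
    out = SpectraSet(
        WavenumberAxis(sset.axis.values[mask]),
        sset.matrix[:, mask],
        sset.meta.copy(),
        copy.deepcopy(sset.provenance),
    )
    return out.with_stage(
        "extract_regions", region=regions.name, intervals=list(regions.intervals)
    )


def average_replicates(sset: SpectraSet, group_keys: Iterable[str]) -> SpectraSet:
    """Average spectra over replicates.

    One output row per distinct combination of ``group_keys`` (arithmetic
    mean of member rows), in order of first appearance.  Replicate index
    columns not in the keys are dropped from the metadata (set to NA).
    """
    group_keys = list(group_keys)
    if len(sset) == 0:
        raise SpectraError("cannot average an empty SpectraSet")
    for k in group_keys:
        if k not in sset.meta.columns:
            raise MetadataError(f"unknown group key {k!r}")
        if sset.meta[k].isna().any():
            raise MetadataError(f"group key {k!r} has missing values")

    keys_df = sset.meta[group_keys].astype(object)
    key_tuples = [tuple(r) for r in keys_df.itertuples(index=False, name=None)]
    seen: dict[tuple, int] = {}
    order: list[tuple] = []
    for t in key_tuples:
        if t not in seen:
            seen[t] = len(order)
            order.append(t)
    group_index = np.array([seen[t] for t in key_tuples])

    n_groups = len(order)
    out_matrix = np.zeros((n_groups, sset.matrix.shape[1]))
    counts = np.bincount(group_index, minlength=n_groups).astype(float)
    for j in range(sset.matrix.shape[1]):
        out_matrix[:, j] = np.bincount(
            group_index, weights=sset.matrix[:, j], minlength=n_groups
        )
    out_matrix /= counts[:, None]

    first_rows = [key_tuples.index(t) for t in order]
    meta = sset.meta.iloc[first_rows].reset_index(drop=True).copy()
    for rep_col in ("tech_rep", "bio_rep"):
        if rep_col not in group_keys and rep_col in meta.columns:
            meta[rep_col] = pd.array([None] * n_groups, dtype="Int64")
    if "sample_id" not in group_keys:
        meta["sample_id"] = ["|".join(map(str, t)) for t in order]

    out = SpectraSet(sset.axis, out_matrix, meta, copy.deepcopy(sset.provenance))
    return out.with_stage("average_replicates", group_keys=group_keys)
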