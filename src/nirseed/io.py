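"""Data model and CSV readers/writers for spectra, reference values, genetic
maps, RIL genotypes, and phenotypes.

All tables are comma-separated UTF-8 with a header row.  Spectra files carry
wavenumbers (cm^-1) as column headers, written in descending order following
instrument convention; in memory the grid is always stored ascending.  The id
column is named ``sample_id`` (``line_id`` for genotype/phenotype tables).
Absorbance is stored as log(1/R); the instrument's reflectance-mode output is
assumed already converted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "WavenumberGrid",
    "SpectraSet",
    "ReferenceTable",
    "GeneticMap",
    "RILPopulation",
    "PhenotypeTable",
    "COMPONENTS",
    "FormatError",
    "ValidationError",
    "read_spectra",
    "write_spectra",
    "read_reference",
    "write_reference",
    "read_map",
    "write_map",
    "read_genotypes",
    "write_genotypes",
    "read_map_genotypes",
    "read_phenotypes",
    "write_phenotypes",
    "join_spectra_reference",
]

#: Seed storage components with calibration models.
COMPONENTS = ("oil", "protein", "carbon", "nitrogen")

GRID_MIN = 4000.0
GRID_MAX = 10000.0


class FormatError(ValueError):
    """Raised when a file cannot be parsed as the expected table kind."""


class ValidationError(ValueError):
    """Raised when a parsed table violates a domain invariant."""


@dataclass(frozen=True)
class WavenumberGrid:
    """Strictly increasing wavenumber axis in cm^-1.

    ``resolution`` is the nominal spacing; the stored values may deviate
    slightly (e.g. after derivative edge trimming the grid stays uniform, but
    window masking can leave gaps).
    """

    values: np.ndarray
    resolution: float | None = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValidationError("grid needs at least 2 wavenumbers")
        if not np.all(np.diff(v) > 0):
            raise FormatError("wavenumber grid must be strictly monotonic")
        if v[0] < GRID_MIN - 1e-9 or v[-1] > GRID_MAX + 1e-9:
            raise ValidationError(
                f"wavenumbers must lie in [{GRID_MIN:g}, {GRID_MAX:g}] cm^-1"
            )
        object.__setattr__(self, "values", v)
        if self.resolution is None:
            object.__setattr__(self, "resolution", float(np.median(np.diff(v))))

    def __len__(self) -> int:
        return self.values.size

    def __eq__(self, other) -> bool:
        return isinstance(other, WavenumberGrid) and np.array_equal(
            self.values, other.values
        )


@dataclass
class SpectraSet:
    """Sample x wavenumber absorbance matrix with per-sample annotations."""

    grid: WavenumberGrid
    absorbance: np.ndarray
    sample_ids: list[str]
    meta: pd.DataFrame | None = None

    def __post_init__(self):
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 2:
            raise ValidationError("absorbance must be 2-D (sample x wavenumber)")
        if a.shape[0] != len(self.sample_ids):
            raise ValidationError("row count must equal number of sample ids")
        if a.shape[1] != len(self.grid):
            raise ValidationError("column count must match grid length")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dup = sorted({s for s in self.sample_ids if self.sample_ids.count(s) > 1})
            raise ValidationError(f"duplicate sample ids: {dup}")
        if not np.all(np.isfinite(a)):
            raise ValidationError("missing/non-finite absorbance values not allowed")
        self.absorbance = a
        self.sample_ids = list(map(str, self.sample_ids))

    @property
    def n_samples(self) -> int:
        return self.absorbance.shape[0]

    def subset(self, ids) -> "SpectraSet":
        """Restrict to the given sample ids, in the given order."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in ids if s not in index]
        if missing:
            raise ValidationError(f"unknown sample ids: {missing}")
        rows = [index[s] for s in ids]
        meta = self.meta.iloc[rows].reset_index(drop=True) if self.meta is not None else None
        return SpectraSet(self.grid, self.absorbance[rows], list(ids), meta)


@dataclass
class ReferenceTable:
    """Long-format reference concentrations (% dry seed weight)."""

    records: pd.DataFrame  # columns: sample_id, component, value, method

    def __post_init__(self):
        df = self.records.copy()
        required = {"sample_id", "component", "value"}
        if not required.issubset(df.columns):
            raise FormatError(f"reference table needs columns {sorted(required)}")
        if "method" not in df.columns:
            df["method"] = ""
        df["method"] = df["method"].fillna("").astype(str)
        df["sample_id"] = df["sample_id"].astype(str)
        unknown = set(df["component"]) - set(COMPONENTS)
        if unknown:
            raise ValidationError(f"unknown components: {sorted(unknown)}")
        vals = df["value"].astype(float)
        if len(df) and not ((vals > 0) & (vals < 100)).all():
            bad = df.loc[~((vals > 0) & (vals < 100)), "sample_id"].tolist()
            raise ValidationError(f"values must lie in (0, 100): samples {bad}")
        if df.duplicated(["sample_id", "component"]).any():
            raise ValidationError("at most one record per (sample_id, component)")
        df["value"] = vals
        self.records = df.reset_index(drop=True)

    def values_for(self, component: str) -> pd.Series:
        """sample_id -> value for one component."""
        sub = self.records[self.records["component"] == component]
        return pd.Series(sub["value"].values, index=sub["sample_id"].values)


@dataclass
class GeneticMap:
    """Ordered chromosomes, each with named markers at non-decreasing cM."""

    chromosomes: list[str]
    markers: dict[str, list[str]]      # chromosome -> marker names in map order
    positions: dict[str, np.ndarray]   # chromosome -> positions (cM)

    def __post_init__(self):
        all_names: list[str] = []
        for chrom in self.chromosomes:
            pos = np.asarray(self.positions[chrom], dtype=float)
            if np.any(pos < 0) or np.any(np.diff(pos) < 0):
                raise ValidationError(
                    f"chromosome {chrom}: positions must be non-negative, sorted"
                )
            self.positions[chrom] = pos
            all_names.extend(self.markers[chrom])
        if len(set(all_names)) != len(all_names):
            raise ValidationError("marker names must be globally unique")

    @property
    def marker_names(self) -> list[str]:
        return [m for c in self.chromosomes for m in self.markers[c]]

    def chrom_of(self, marker: str) -> str:
        for c in self.chromosomes:
            if marker in self.markers[c]:
                return c
        raise KeyError(marker)


GENOTYPE_CODES = ("A", "B")  # A = Col-0-like, B = Ct-1-like; missing = NaN


@dataclass
class RILPopulation:
    """Genetic map plus homozygous line x marker genotype codes.

    Genotypes are stored as floats: 0.0 = A, 1.0 = B, NaN = missing; only
    homozygous classes exist because RILs are (near-)fully inbred.
    """

    map: GeneticMap
    genotypes: pd.DataFrame  # index = line ids, columns = marker names

    def __post_init__(self):
        if self.genotypes.index.duplicated().any():
            raise ValidationError("line ids must be unique")
        map_markers = self.map.marker_names
        extra = [m for m in self.genotypes.columns if m not in set(map_markers)]
        if extra:
            raise ValidationError(f"markers absent from map: {extra}")
        missing_cols = [m for m in map_markers if m not in self.genotypes.columns]
        if missing_cols:
            raise ValidationError(f"map markers missing from genotypes: {missing_cols}")
        g = self.genotypes[map_markers].astype(float)
        ok = g.isna() | g.isin([0.0, 1.0])
        if not ok.all().all():
            raise ValidationError("genotype codes must be A, B, or missing")
        self.genotypes = g

    @property
    def line_ids(self) -> list[str]:
        return [str(i) for i in self.genotypes.index]

    @property
    def n_lines(self) -> int:
        return len(self.genotypes)


@dataclass
class PhenotypeTable:
    """line_id x trait values (replicates already averaged for QTL input)."""

    records: pd.DataFrame  # columns: line_id, trait, value

    def __post_init__(self):
        df = self.records.copy()
        if not {"line_id", "trait", "value"}.issubset(df.columns):
            raise FormatError("phenotype table needs columns line_id, trait, value")
        df["line_id"] = df["line_id"].astype(str)
        df["value"] = df["value"].astype(float)
        if df.duplicated(["line_id", "trait"]).any():
            raise ValidationError("one value per line x trait required")
        self.records = df.reset_index(drop=True)

    def values_for(self, trait: str) -> pd.Series:
        sub = self.records[self.records["trait"] == trait]
        return pd.Series(sub["value"].values, index=sub["line_id"].values)


# ---------------------------------------------------------------------------
# readers / writers

def read_spectra(path) -> SpectraSet:
    """Read a samples x wavenumbers CSV (id column ``sample_id``)."""
    df = pd.read_csv(path, dtype={"sample_id": str}, float_precision="round_trip")
    if "sample_id" not in df.columns:
        raise FormatError("spectra CSV must have a 'sample_id' column")
    wn_cols = [c for c in df.columns if c != "sample_id"]
    try:
        wn = np.array([float(c) for c in wn_cols])
    except ValueError as exc:
        raise FormatError(f"non-numeric wavenumber header: {exc}") from None
    if wn.size >= 2 and np.all(np.diff(wn) < 0):  # instrument order: descending
        order = np.argsort(wn)
    elif wn.size >= 2 and np.all(np.diff(wn) > 0):
        order = np.arange(wn.size)
    else:
        raise FormatError("wavenumber headers must be strictly monotonic")
    ids = df["sample_id"].tolist()
    if len(set(ids)) != len(ids):
        raise ValidationError("duplicate sample id in spectra file")
    a = df[wn_cols].to_numpy(dtype=float)[:, order]
    return SpectraSet(WavenumberGrid(wn[order]), a, ids)


def write_spectra(spectra: SpectraSet, path) -> None:
    """Write in instrument convention: wavenumber columns descending."""
    wn = spectra.grid.values[::-1]
    df = pd.DataFrame(spectra.absorbance[:, ::-1], columns=[repr(float(v)) for v in wn])
    df.insert(0, "sample_id", spectra.sample_ids)
    df.to_csv(path, index=False)


def read_reference(path) -> ReferenceTable:
    df = pd.read_csv(path, dtype={"sample_id": str})
    return ReferenceTable(df)


def write_reference(refs: ReferenceTable, path) -> None:
    refs.records.to_csv(path, index=False)


def read_map(path) -> GeneticMap:
    df = pd.read_csv(path, dtype={"marker": str, "chr": str})
    if not {"marker", "chr", "pos_cM"}.issubset(df.columns):
        raise FormatError("map CSV needs columns marker, chr, pos_cM")
    chroms = list(dict.fromkeys(df["chr"]))
    markers = {c: df.loc[df["chr"] == c, "marker"].tolist() for c in chroms}
    positions = {
        c: df.loc[df["chr"] == c, "pos_cM"].to_numpy(float) for c in chroms
    }
    return GeneticMap(chroms, markers, positions)


def write_map(gmap: GeneticMap, path) -> None:
    rows = [
        {"marker": m, "chr": c, "pos_cM": p}
        for c in gmap.chromosomes
        for m, p in zip(gmap.markers[c], gmap.positions[c])
    ]
    pd.DataFrame(rows, columns=["marker", "chr", "pos_cM"]).to_csv(path, index=False)


_CODE_TO_FLOAT = {"A": 0.0, "B": 1.0, "NA": np.nan, "": np.nan}


def read_genotypes(path, gmap: GeneticMap) -> RILPopulation:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "line_id" not in df.columns:
        raise FormatError("genotype CSV must have a 'line_id' column")
    df = df.set_index("line_id")
    bad = set(np.unique(df.to_numpy())) - set(_CODE_TO_FLOAT)
    if bad:
        raise ValidationError(f"genotype codes must be A/B/NA, got {sorted(bad)}")
    g = df.apply(lambda col: col.map(_CODE_TO_FLOAT)).astype(float)
    return RILPopulation(gmap, g)


def write_genotypes(pop: RILPopulation, path) -> None:
    codes = np.where(
        pop.genotypes.isna(), "NA", np.where(pop.genotypes == 1.0, "B", "A")
    )
    g = pd.DataFrame(codes, index=pop.genotypes.index, columns=pop.genotypes.columns)
    g.index.name = "line_id"
    g.to_csv(path)


def read_map_genotypes(map_path, genotype_path) -> RILPopulation:
    """Convenience: read map and genotype CSVs into one population."""
    return read_genotypes(genotype_path, read_map(map_path))


def read_phenotypes(path) -> PhenotypeTable:
    df = pd.read_csv(path, dtype={"line_id": str, "trait": str})
    if df.empty and not {"line_id", "trait", "value"}.issubset(df.columns):
        df = pd.DataFrame(columns=["line_id", "trait", "value"])
    return PhenotypeTable(df)


def write_phenotypes(phen: PhenotypeTable, path) -> None:
    phen.records.to_csv(path, index=False)


def join_spectra_reference(
    spectra: SpectraSet, refs: ReferenceTable, component: str
):
    """Align spectra rows with reference values for one component.

    Returns ``(X, y, ids, dropped)`` where ``X`` is the absorbance matrix over
    the shared sample ids (in spectra order), ``y`` the reference vector, and
    ``dropped`` the ids present on only one side.
    """
    ref_vals = refs.values_for(component)
    shared = [s for s in spectra.sample_ids if s in ref_vals.index]
    if len(shared) < 2:
        raise ValidationError(
            f"need >= 2 samples shared between spectra and {component} references"
        )
    dropped = sorted(
        (set(spectra.sample_ids) | set(ref_vals.index)) - set(shared)
    )
    sub = spectra.subset(shared)
    y = ref_vals.loc[shared].to_numpy(float)
    return sub.absorbance, y, shared, dropped
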