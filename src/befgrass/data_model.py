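"""Core tabular data structures: community tables, trait tables, IVI weights.

A community is recorded as long-format rows (one row = one species in one
1 m^2 quadrat) carrying the three abundance components used throughout the
analysis: aboveground biomass (g/m^2), cover (fraction of ground area) and
density (individuals/m^2). The important value index (IVI) of a species is
the mean of its relative biomass, relative cover and relative density within
its quadrat; the resulting weight vector p sums to one and serves as the
abundance weight everywhere downstream (Shannon H, Rao's Q, weighted MPD,
the taxon-shuffle null).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "SpeciesObservation",
    "CommunityTable",
    "IVIVector",
    "TraitTable",
    "TRAIT_COLUMNS",
    "compute_ivi",
    "log_transform",
    "inverse_log_transform",
    "read_community_table",
    "read_trait_table",
    "write_results",
]

TRAIT_COLUMNS = ("SLA", "leaf_size", "height", "seed_mass")

COMMUNITY_COLUMNS = ("quadrat_id", "site_id", "species", "biomass", "cover", "density")


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass(frozen=True)
class SpeciesObservation:
    """One species record in one quadrat."""

    quadrat_id: str
    site_id: str
    species: str
    biomass: float  # g/m^2, >= 0
    cover: float  # fraction in [0, 1]
    density: float  # individuals/m^2, >= 0

    def __post_init__(self) -> None:
        for name in ("biomass", "cover", "density"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValidationError(
                    f"{name}={v!r} for {self.species} in quadrat {self.quadrat_id} "
                    "must be finite and non-negative"
                )
        if self.cover > 1:
            raise ValidationError(
                f"cover={self.cover} for {self.species} in quadrat "
                f"{self.quadrat_id} exceeds 1 (cover is stored as a fraction)"
            )


@dataclass
class CommunityTable:
    """Long-format species-by-quadrat table with an explicit quadrat index.

    ``data`` holds one row per (quadrat, species); ``quadrat_meta`` is indexed
    by quadrat_id and carries at least site_id, optionally grassland_type and
    elevation.
    """

    data: pd.DataFrame
    quadrat_meta: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        missing = [c for c in COMMUNITY_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"community table missing columns: {missing}")
        if self.data.empty:
            raise ValidationError("community table has no observations")
        dup = self.data.duplicated(subset=["quadrat_id", "species"])
        if dup.any():
            rows = self.data.loc[dup, ["quadrat_id", "species"]]
            pairs = ", ".join(f"{q}:{s}" for q, s in rows.itertuples(index=False))
            raise ValidationError(f"duplicate species within quadrat: {pairs}")
        for name in ("biomass", "cover", "density"):
            col = self.data[name].to_numpy(dtype=float)
            if not np.all(np.isfinite(col)) or (col < 0).any():
                raise ValidationError(f"column {name} has negative or non-finite values")
        if (self.data["cover"].to_numpy(dtype=float) > 1).any():
            raise ValidationError("cover values above 1; use cover_unit='percent' on load")
        if self.quadrat_meta is None:
            meta = (
                self.data.groupby("quadrat_id", sort=True)["site_id"].first().to_frame()
            )
            object.__setattr__(self, "quadrat_meta", meta)
        else:
            referenced = set(self.data["quadrat_id"])
            indexed = set(self.quadrat_meta.index)
            orphans = referenced - indexed
            if orphans:
                raise ValidationError(f"quadrats missing from index: {sorted(orphans)}")

    @property
    def quadrat_ids(self) -> list[str]:
        return list(self.quadrat_meta.index)

    @property
    def species_pool(self) -> list[str]:
        return sorted(self.data["species"].unique())

    def quadrat(self, quadrat_id: str) -> pd.DataFrame:
        sub = self.data[self.data["quadrat_id"] == quadrat_id]
        if sub.empty:
            raise KeyError(quadrat_id)
        return sub

    def observations(self, quadrat_id: str) -> list[SpeciesObservation]:
        sub = self.quadrat(quadrat_id)
        return [
            SpeciesObservation(
                quadrat_id=str(r.quadrat_id),
                site_id=str(r.site_id),
                species=str(r.species),
                biomass=float(r.biomass),
                cover=float(r.cover),
                density=float(r.density),
            )
            for r in sub.itertuples(index=False)
        ]

    def total_biomass(self) -> pd.Series:
        """Quadrat-level aboveground biomass (g/m^2)."""
        return self.data.groupby("quadrat_id", sort=True)["biomass"].sum()

    def richness(self) -> pd.Series:
        return self.data.groupby("quadrat_id", sort=True)["species"].nunique()


@dataclass(frozen=True)
class IVIVector:
    """Per-quadrat species importance weights p_i, summing to one."""

    quadrat_id: str
    weights: dict[str, float]

    def __post_init__(self) -> None:
        vals = np.array(list(self.weights.values()), dtype=float)
        if len(vals) == 0:
            raise ValidationError(f"empty IVI vector for quadrat {self.quadrat_id}")
        if (vals <= 0).any():
            raise ValidationError(f"non-positive IVI weight in quadrat {self.quadrat_id}")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValidationError(
                f"IVI weights for quadrat {self.quadrat_id} sum to {vals.sum()!r}, not 1"
            )

    @property
    def species(self) -> list[str]:
        return list(self.weights)

    def as_array(self, order: list[str] | None = None) -> np.ndarray:
        order = order if order is not None else self.species
        return np.array([self.weights[s] for s in order], dtype=float)


@dataclass
class TraitTable:
    """Species x trait table; raw values on positive measurement scales.

    Units: SLA mm^2/mg, leaf_size cm^2, height cm, seed_mass mg. Missing
    values are NaN and flagged through :meth:`missing_species`.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in TRAIT_COLUMNS if c not in self.data.columns]
        if missing:
            # tolerated: an absent trait column means that trait was not
            # measured; downstream metrics for it are skipped with a warning
            warnings.warn(f"trait table lacks columns {missing}; treated as missing",
                          stacklevel=2)
            self.data = self.data.assign(**{c: np.nan for c in missing})
        vals = self.data[list(TRAIT_COLUMNS)].to_numpy(dtype=float)
        bad = (vals <= 0) & ~np.isnan(vals)
        if bad.any():
            rows = self.data.index[bad.any(axis=1)].tolist()
            raise ValidationError(
                f"non-positive trait values (not log-transformable) for: {rows}"
            )

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    def complete_species(self, traits: tuple[str, ...] = TRAIT_COLUMNS) -> list[str]:
        sub = self.data[list(traits)]
        return list(sub.index[~sub.isna().any(axis=1)])

    def missing_species(self, community_species: list[str]) -> list[str]:
        """Community species lacking a (complete) trait row."""
        have = set(self.complete_species())
        return sorted(set(community_species) - have)


def compute_ivi(observations: list[SpeciesObservation] | pd.DataFrame) -> IVIVector:
    """Important value index for one quadrat.

    p_i is the mean, over the abundance components whose quadrat column sum is
    positive, of value_i / column-sum. A component that sums to zero across
    the quadrat (e.g. covers all unrecorded) is dropped from the average with
    a warning; if all three sum to zero the quadrat is unusable.
    """
    if isinstance(observations, pd.DataFrame):
        df = observations
        quadrat_id = str(df["quadrat_id"].iloc[0]) if len(df) else "?"
        species = [str(s) for s in df["species"]]
        comps = df[["biomass", "cover", "density"]].to_numpy(dtype=float)
    else:
        if not observations:
            raise ValidationError("compute_ivi: empty quadrat")
        quadrat_id = observations[0].quadrat_id
        species = [o.species for o in observations]
        comps = np.array(
            [[o.biomass, o.cover, o.density] for o in observations], dtype=float
        )
    if comps.shape[0] == 0:
        raise ValidationError("compute_ivi: empty quadrat")
    if len(set(species)) != len(species):
        raise ValidationError(f"duplicate species in quadrat {quadrat_id}")
    sums = comps.sum(axis=0)
    usable = sums > 0
    if not usable.any():
        raise ValidationError(
            f"quadrat {quadrat_id}: biomass, cover and density all sum to zero"
        )
    if not usable.all():
        dropped = [n for n, u in zip(("biomass", "cover", "density"), usable) if not u]
        warnings.warn(
            f"quadrat {quadrat_id}: zero-sum component(s) {dropped} dropped from IVI",
            stacklevel=2,
        )
    rel = comps[:, usable] / sums[usable]
    p = rel.mean(axis=1)
    # guard against species with zero in every usable component
    if (p <= 0).any():
        zeros = [s for s, w in zip(species, p) if w <= 0]
        raise ValidationError(
            f"quadrat {quadrat_id}: species with zero abundance in all components: {zeros}"
        )
    p = p / p.sum()
    return IVIVector(quadrat_id=quadrat_id, weights=dict(zip(species, p)))


def log_transform(x):
    """Base-10 log of a positive measurement (the scale used for traits,
    biomass and richness throughout the regressions)."""
    arr = np.asarray(x, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise ValueError("log_transform requires strictly positive finite values")
    out = np.log10(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def inverse_log_transform(x):
    """Back-transform from the log10 scale (e.g. a fitted breakpoint in
    log-richness back to species per m^2)."""
    arr = np.asarray(x, dtype=float)
    out = np.power(10.0, arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def read_community_table(
    path,
    cover_unit: str = "fraction",
    sep: str = "\t",
) -> CommunityTable:
    """Read a long-format community file.

    Required columns: quadrat_id, site_id, species, biomass_g_m2, cover,
    density_m2; optional grassland_type, elevation. ``cover_unit`` is
    'fraction' for cover in (0, 1] or 'percent' for (0, 100]; covers are
    stored internally as fractions.
    """
    if cover_unit not in ("fraction", "percent"):
        raise ValueError(f"unknown cover_unit {cover_unit!r}")
    raw = pd.read_csv(path, sep=sep)
    required = {"quadrat_id", "site_id", "species", "biomass_g_m2", "cover", "density_m2"}
    missing = required - set(raw.columns)
    if missing:
        raise ValidationError(f"community file {path}: missing columns {sorted(missing)}")
    df = pd.DataFrame(
        {
            "quadrat_id": raw["quadrat_id"].astype(str),
            "site_id": raw["site_id"].astype(str),
            "species": raw["species"].astype(str),
            "biomass": raw["biomass_g_m2"].astype(float),
            "cover": raw["cover"].astype(float),
            "density": raw["density_m2"].astype(float),
        }
    )
    if cover_unit == "percent":
        df["cover"] = df["cover"] / 100.0
    meta_cols = [c for c in ("grassland_type", "elevation") if c in raw.columns]
    meta = None
    if meta_cols:
        meta = (
            pd.concat([df[["quadrat_id", "site_id"]], raw[meta_cols]], axis=1)
            .groupby("quadrat_id", sort=True)
            .first()
        )
    return CommunityTable(data=df, quadrat_meta=meta)


def write_community_table(table: CommunityTable, path, sep: str = "\t") -> None:
    out = table.data.rename(
        columns={"biomass": "biomass_g_m2", "density": "density_m2"}
    )
    if "grassland_type" in table.quadrat_meta.columns:
        gt = table.quadrat_meta["grassland_type"]
        out = out.assign(grassland_type=out["quadrat_id"].map(gt))
    out.to_csv(path, sep=sep, index=False)


def read_trait_table(path, sep: str = "\t") -> TraitTable:
    raw = pd.read_csv(path, sep=sep)
    if "species" not in raw.columns:
        raise ValidationError(f"trait file {path}: missing 'species' column")
    raw = raw.set_index("species")
    return TraitTable(data=raw)


def write_trait_table(traits: TraitTable, path, sep: str = "\t") -> None:
    traits.data.rename_axis("species").to_csv(path, sep=sep)


def write_results(tables: dict[str, pd.DataFrame], outdir, sep: str = "\t") -> list[str]:
    """Write each named result table as <name>.tsv under outdir."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = []
    for name, df in tables.items():
        p = os.path.join(outdir, f"{name}.tsv")
        df.to_csv(p, sep=sep, index=False)
        paths.append(p)
    return paths
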