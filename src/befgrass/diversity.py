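"""Per-quadrat species, functional and phylogenetic diversity.

All indices are weighted by the important value index p (see
:mod:`befgrass.data_model`):

* Shannon-Wiener ``H = -sum_i p_i ln p_i`` (natural log).
* Rao's quadratic entropy ``FD_Q = sum_ij d_ij p_i p_j`` over a trait-space
  distance matrix (full double sum over ordered pairs; the diagonal is zero).
* Abundance-weighted mean pairwise phylogenetic distance
  ``MPD = sum_{i != j} d_ij p_i p_j / sum_{i != j} p_i p_j`` over patristic
  distances.

Trait space: each trait is log10-transformed and z-scored across the full
species pool supplied to the run (a common space keeps standardized effect
sizes comparable across quadrats); a single trait uses the absolute z
difference, several traits the Euclidean distance over z-scores divided by
sqrt(#traits) so single- and multi-trait values share a scale.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .data_model import TRAIT_COLUMNS, CommunityTable, IVIVector, TraitTable, compute_ivi
from .phylo import DistanceMatrix

__all__ = [
    "shannon",
    "trait_distance_matrix",
    "rao_q",
    "mpd_weighted",
    "diversity_table",
    "TRAIT_SETS",
]

#: the analysis' default trait sets: each single trait plus all four combined
TRAIT_SETS: dict[str, tuple[str, ...]] = {
    "SLA": ("SLA",),
    "leaf_size": ("leaf_size",),
    "height": ("height",),
    "seed_mass": ("seed_mass",),
    "multi": TRAIT_COLUMNS,
}


def shannon(p: IVIVector | np.ndarray) -> float:
    """Shannon-Wiener index H = -sum p_i ln p_i (nats) on the IVI weights."""
    w = p.as_array() if isinstance(p, IVIVector) else np.asarray(p, dtype=float)
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("weights must sum to 1")
    return float(-(w * np.log(w)).sum())


def trait_distance_matrix(
    traits: TraitTable,
    trait_set: tuple[str, ...],
    species: list[str] | None = None,
) -> DistanceMatrix:
    """Pairwise trait-space distances over z-scored log10 traits.

    ``species`` restricts the matrix rows/columns; standardization always
    uses the full pool of species with complete values for ``trait_set``.
    """
    unknown = set(trait_set) - set(TRAIT_COLUMNS)
    if unknown:
        raise ValueError(f"unknown traits: {sorted(unknown)}")
    pool = traits.complete_species(tuple(trait_set))
    sub = traits.data.loc[pool, list(trait_set)].astype(float)
    logt = np.log10(sub.to_numpy())
    mu = logt.mean(axis=0)
    sd = logt.std(axis=0, ddof=1)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"zero-variance trait(s) {list(np.array(trait_set)[zero_var])} "
            "contribute 0 to the distance",
            stacklevel=2,
        )
        sd = np.where(zero_var, 1.0, sd)
        logt[:, zero_var] = 0.0
        mu = np.where(zero_var, 0.0, mu)
    z = (logt - mu) / sd
    if species is not None:
        idx = {s: i for i, s in enumerate(pool)}
        missing = [s for s in species if s not in idx]
        if missing:
            raise KeyError(f"species without complete {trait_set} values: {missing}")
        z = z[[idx[s] for s in species]]
        labels = list(species)
    else:
        labels = pool
    diff = z[:, None, :] - z[None, :, :]
    d = np.sqrt((diff**2).sum(axis=2)) / np.sqrt(len(trait_set))
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(labels=labels, values=d)


def rao_q(d: DistanceMatrix | np.ndarray, p: IVIVector | np.ndarray) -> float:
    """Rao's quadratic entropy: full double sum sum_ij d_ij p_i p_j."""
    if isinstance(p, IVIVector):
        species = p.species
        w = p.as_array()
        mat = d.submatrix(species) if isinstance(d, DistanceMatrix) else np.asarray(d)
    else:
        w = np.asarray(p, dtype=float)
        mat = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if mat.shape != (len(w), len(w)):
        raise ValueError("distance matrix does not match weight vector")
    return float(w @ mat @ w)


def mpd_weighted(d: DistanceMatrix | np.ndarray, p: IVIVector | np.ndarray) -> float:
    """IVI-weighted mean pairwise distance over distinct species pairs.

    Returns NaN (undefined) for a single-species community, where there are
    no pairs.
    """
    if isinstance(p, IVIVector):
        w = p.as_array()
        mat = d.submatrix(p.species) if isinstance(d, DistanceMatrix) else np.asarray(d)
    else:
        w = np.asarray(p, dtype=float)
        mat = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if len(w) < 2:
        return float("nan")
    num = float(w @ mat @ w)
    s = w.sum()
    denom = s * s - float(w @ w)  # sum over distinct ordered pairs of p_i p_j
    return num / denom


def diversity_table(
    community: CommunityTable,
    traits: TraitTable | None = None,
    phylo_distances: DistanceMatrix | None = None,
    trait_sets: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """One row per quadrat: richness S, Shannon H, FD_Q per trait set, MPD.

    Species lacking trait or phylogeny data are excluded from the relevant
    metric for that quadrat (count reported in the ``n_excluded_*`` columns);
    a quadrat that degenerates to a single usable species gets FD_Q = 0 and an
    undefined (NaN) MPD. One bad quadrat never aborts the batch.
    """
    trait_sets = TRAIT_SETS if trait_sets is None else trait_sets
    trait_dms: dict[str, DistanceMatrix] = {}
    if traits is not None:
        for name, tset in trait_sets.items():
            if len(traits.complete_species(tuple(tset))) < 2:
                warnings.warn(
                    f"trait set {name!r}: fewer than two species with complete "
                    "values, skipped", stacklevel=2)
                continue
            trait_dms[name] = trait_distance_matrix(traits, tuple(tset))

    rows = []
    for qid in community.quadrat_ids:
        sub = community.quadrat(qid)
        ivi = compute_ivi(sub)
        row: dict = {
            "quadrat_id": qid,
            "site_id": str(sub["site_id"].iloc[0]),
            "richness": len(ivi.species),
            "shannon": shannon(ivi),
            "biomass": float(sub["biomass"].sum()),
        }
        for name, dm in trait_dms.items():
            kept = [s for s in ivi.species if dm.has(s)]
            row[f"n_excluded_fd_{name}"] = len(ivi.species) - len(kept)
            if len(kept) == 0:
                row[f"fd_{name}"] = float("nan")
            elif len(kept) == 1:
                row[f"fd_{name}"] = 0.0
            else:
                w = ivi.as_array(kept)
                w = w / w.sum()
                row[f"fd_{name}"] = rao_q(dm.submatrix(kept), w)
        if phylo_distances is not None:
            kept = [s for s in ivi.species if phylo_distances.has(s)]
            row["n_excluded_mpd"] = len(ivi.species) - len(kept)
            if len(kept) < 2:
                row["mpd"] = float("nan")
            else:
                w = ivi.as_array(kept)
                w = w / w.sum()
                row["mpd"] = mpd_weighted(phylo_distances.submatrix(kept), w)
        rows.append(row)
    return pd.DataFrame(rows)
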