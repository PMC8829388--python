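"""Taxon-shuffle null models and standardized effect sizes (SES).

The null keeps each quadrat's richness and IVI weight vector fixed and
redraws the species identities uniformly without replacement from a pool
(default: every species in the run with complete trait and phylogeny data).
SES = (observed - null mean) / null sd; positive values indicate functional
or phylogenetic overdispersion, negative values clustering. Communities are
classified at the run level from the t-based 95% CI of the mean SES.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import IVIVector
from .phylo import DistanceMatrix

__all__ = [
    "SESRecord",
    "DispersionSummary",
    "quadrat_rng",
    "shuffle_null",
    "ses",
    "ses_table",
    "dispersion_summary",
]

DEFAULT_N_ITER = 10_000  # iterations of the taxon-shuffle null


@dataclass(frozen=True)
class SESRecord:
    quadrat_id: str
    metric: str
    observed: float
    null_mean: float
    null_sd: float
    ses: float  # NaN when undefined (null sd == 0 or observed undefined)
    n_iterations: int
    seed: int | None

    @property
    def undefined(self) -> bool:
        return not np.isfinite(self.ses)


@dataclass(frozen=True)
class DispersionSummary:
    metric: str
    mean_ses: float
    ci_low: float
    ci_high: float
    verdict: str  # clustered | overdispersed | neutral
    n: int


def quadrat_rng(master_seed: int, quadrat_id: str) -> np.random.Generator:
    """Deterministic per-quadrat substream: independent of batch order."""
    tag = zlib.crc32(str(quadrat_id).encode())
    return np.random.default_rng(np.random.SeedSequence([int(master_seed), tag]))


def shuffle_null(
    weights: IVIVector | np.ndarray,
    pool_size: int,
    metric: str,
    d: DistanceMatrix | np.ndarray,
    n_iter: int = DEFAULT_N_ITER,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Null distribution of ``metric`` ('rao_q' or 'mpd') under taxon shuffle.

    ``d`` is the pool-level distance matrix (its row order defines the pool);
    each iteration draws S = len(weights) species uniformly without
    replacement and assigns the fixed weight vector to them in draw order.
    """
    w = weights.as_array() if isinstance(weights, IVIVector) else np.asarray(weights, float)
    dm = d.values if isinstance(d, DistanceMatrix) else np.asarray(d, dtype=float)
    if pool_size != dm.shape[0]:
        raise ValueError("pool_size must match the distance matrix")
    S = len(w)
    if pool_size < S:
        raise ValueError(f"pool ({pool_size}) smaller than quadrat richness ({S})")
    if n_iter < 2:
        raise ValueError("n_iter must be >= 2")
    if metric not in ("rao_q", "mpd"):
        raise ValueError(f"unknown metric {metric!r}")
    if metric == "mpd" and S < 2:
        return np.full(n_iter, np.nan)
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # first S columns of a uniformly random permutation, for every iteration
    u = rng.random((n_iter, pool_size))
    idx = np.argsort(u, axis=1)[:, :S]
    dsub = dm[idx[:, :, None], idx[:, None, :]]  # (n_iter, S, S)
    vals = np.einsum("nij,i,j->n", dsub, w, w)
    if metric == "mpd":
        s = w.sum()
        vals = vals / (s * s - float(w @ w))
    return vals


def ses(
    observed: float,
    null_values: np.ndarray,
    quadrat_id: str = "",
    metric: str = "",
    seed: int | None = None,
) -> SESRecord:
    """Standardized effect size of an observed metric against its null."""
    null_values = np.asarray(null_values, dtype=float)
    mean = float(np.nanmean(null_values)) if np.isfinite(null_values).any() else float("nan")
    sd = float(np.nanstd(null_values, ddof=1)) if np.isfinite(null_values).any() else float("nan")
    # sd indistinguishable from zero (e.g. every draw is a permutation of the
    # same species set) makes the SES undefined
    degenerate = not np.isfinite(sd) or sd <= 1e-12 * max(abs(mean), 1.0)
    if not np.isfinite(observed) or degenerate:
        z = float("nan")
    else:
        z = (float(observed) - mean) / sd
    return SESRecord(
        quadrat_id=quadrat_id,
        metric=metric,
        observed=float(observed),
        null_mean=mean,
        null_sd=sd,
        ses=z,
        n_iterations=len(null_values),
        seed=seed,
    )


def ses_table(
    diversity: pd.DataFrame,
    ivi_by_quadrat: dict[str, IVIVector],
    distance_matrices: dict[str, DistanceMatrix],
    n_iter: int = DEFAULT_N_ITER,
    master_seed: int = 0,
) -> pd.DataFrame:
    """Append SES columns to a diversity table.

    ``distance_matrices`` maps metric column name (e.g. 'fd_multi', 'mpd') to
    the pool-level distance matrix used both for the observed value's species
    and the shuffle pool. Per-quadrat RNG substreams derive from
    (master_seed, quadrat_id), so batch order never changes results.
    """
    out = diversity.copy()
    for col, dm in distance_matrices.items():
        kind = "mpd" if col == "mpd" else "rao_q"
        ses_col, mean_col, sd_col = f"ses_{col}", f"null_mean_{col}", f"null_sd_{col}"
        vals = {c: [] for c in (ses_col, mean_col, sd_col)}
        for _, row in out.iterrows():
            qid = str(row["quadrat_id"])
            ivi = ivi_by_quadrat[qid]
            kept = [s for s in ivi.species if dm.has(s)]
            obs = row.get(col, float("nan"))
            if len(kept) < 2 or not np.isfinite(obs):
                rec = SESRecord(qid, col, float(obs), np.nan, np.nan, np.nan, 0, master_seed)
            else:
                w = ivi.as_array(kept)
                w = w / w.sum()
                rng = quadrat_rng(master_seed, f"{qid}:{col}")
                null = shuffle_null(w, len(dm.labels), kind, dm, n_iter=n_iter, rng=rng)
                rec = ses(float(obs), null, qid, col, master_seed)
            vals[ses_col].append(rec.ses)
            vals[mean_col].append(rec.null_mean)
            vals[sd_col].append(rec.null_sd)
        for c, v in vals.items():
            out[c] = v
    return out


def dispersion_summary(ses_values: np.ndarray | pd.Series, metric: str = "") -> DispersionSummary:
    """Run-level dispersion verdict from the t-based 95% CI of mean SES.

    clustered if the CI lies entirely below 0, overdispersed entirely above,
    neutral otherwise.
    """
    vals = np.asarray(ses_values, dtype=float)
    vals = vals[np.isfinite(vals)]
    n = len(vals)
    if n < 2:
        raise ValueError("need >= 2 defined SES values")
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1))
    if sd == 0:
        lo = hi = mean
    else:
        half = stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n)
        lo, hi = mean - half, mean + half
    if hi < 0:
        verdict = "clustered"
    elif lo > 0:
        verdict = "overdispersed"
    else:
        verdict = "neutral"
    return DispersionSummary(metric=metric, mean_ses=mean, ci_low=float(lo),
                             ci_high=float(hi), verdict=verdict, n=n)
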