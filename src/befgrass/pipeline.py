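"""End-to-end orchestration: data -> diversity -> SES -> model competition
-> quantile envelope, with tabular outputs.

Orientation of every fitted relationship follows the study design and is
fixed here to avoid silent axis swaps: quadrat aboveground biomass (log10)
is always the *response* against the diversity indices, while the SES
indices are the *responses* against species richness (log10). Quantile
envelopes use richness or Shannon H as predictor and the SES columns as
responses.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as _sps

from . import __version__
from .data_model import (
    CommunityTable,
    TraitTable,
    compute_ivi,
    log_transform,
    read_community_table,
    read_trait_table,
    write_results,
)
from .diversity import TRAIT_SETS, diversity_table, trait_distance_matrix
from .null_models import DEFAULT_N_ITER, dispersion_summary, ses_table
from .phylo import DistanceMatrix, bladj_calibrate, load_tree, patristic_distances, read_node_ages
from .quantile_reg import envelope_table
from .stats_models import ModelComparison, PiecewiseFit, compare_models

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_analysis", "relationship_table", "group_summary"]


@dataclass
class RunConfig:
    community_path: str | None = None
    trait_path: str | None = None
    tree_path: str | None = None
    ages_path: str | None = None
    cover_unit: str = "fraction"
    n_iter: int = DEFAULT_N_ITER
    seed: int = 0
    delta_aic_threshold: float = 5.0
    quantiles: tuple[float, ...] = (0.05, 0.5, 0.95)
    n_boot: int = 999
    output_dir: str | None = None
    trait_sets: dict = field(default_factory=lambda: dict(TRAIT_SETS))

    def __post_init__(self) -> None:
        if self.delta_aic_threshold <= 0 or self.n_boot <= 0 or self.n_iter < 2:
            raise ValueError("thresholds and iteration counts must be positive")
        if not all(0 < q < 1 for q in self.quantiles):
            raise ValueError("quantiles must lie strictly inside (0, 1)")


def _fit_row(name: str, comp: ModelComparison) -> list[dict]:
    """Tidy rows (one per candidate model) for one relationship."""
    from .stats_models import classify_shape

    rows = []
    for model in ("linear", "quadratic", "piecewise"):
        fit = comp.fits[model]
        row = {
            "relationship": name,
            "model": model,
            "r2": fit.r2,
            "sig": fit.p_sig,
            "delta_aic": comp.delta_aic[model],
            "best": model == comp.best,
        }
        if model == "piecewise" and isinstance(fit, PiecewiseFit):
            if comp.piecewise_reportable:
                row.update(
                    shape=classify_shape(fit),
                    breakpoint=fit.breakpoint,
                    breakpoint_ci_low=fit.breakpoint_ci[0],
                    breakpoint_ci_high=fit.breakpoint_ci[1],
                    left_slope=fit.left_slope,
                    left_slope_ci_low=fit.left_slope_ci[0],
                    left_slope_ci_high=fit.left_slope_ci[1],
                    right_slope=fit.right_slope,
                    right_slope_ci_low=fit.right_slope_ci[0],
                    right_slope_ci_high=fit.right_slope_ci[1],
                    davies_p=fit.davies_p,
                )
            else:  # the dash convention: no interpretable piecewise model
                row.update(shape="-", r2=np.nan, sig=np.nan, delta_aic=np.nan,
                           davies_p=fit.davies_p)
        else:
            row["shape"] = classify_shape(fit)
        rows.append(row)
    return rows


def relationship_table(
    df: pd.DataFrame,
    pairs: list[tuple[str, str, str]],
    delta_aic_threshold: float = 5.0,
) -> pd.DataFrame:
    """Model-competition table over (x column, y column, label) pairs."""
    rows = []
    for x_col, y_col, label in pairs:
        sub = df[[x_col, y_col]].dropna()
        try:
            comp = compare_models(
                sub[x_col].to_numpy(), sub[y_col].to_numpy(),
                delta_aic_threshold=delta_aic_threshold,
            )
        except Exception as exc:
            logger.warning("relationship %s failed: %s", label, exc)
            rows.append({"relationship": label, "model": "none", "shape": "-",
                         "best": False, "error": str(exc)})
            continue
        rows.extend(_fit_row(label, comp))
    return pd.DataFrame(rows)


def run_analysis(
    config: RunConfig,
    community: CommunityTable | None = None,
    traits: TraitTable | None = None,
    tree=None,
) -> dict[str, pd.DataFrame]:
    """Run every stage and return (and optionally write) the result bundle.

    Either pass loaded objects or set paths on the config. Artifacts:
    ``diversity_ses`` (per-quadrat metrics + SES), ``dispersion_summary``,
    ``biomass_models`` (diversity -> biomass competition),
    ``richness_models`` (richness -> SES competition), ``envelope``
    (quantile slopes for richness and H as predictors), ``run_log``.
    """
    errors: list[str] = []
    if community is None:
        community = read_community_table(config.community_path, cover_unit=config.cover_unit)
    if traits is None and config.trait_path:
        traits = read_trait_table(config.trait_path)
    if tree is None and config.tree_path:
        tree = load_tree(config.tree_path)
        if config.ages_path:
            tree = bladj_calibrate(tree, read_node_ages(config.ages_path))

    missing = traits.missing_species(community.species_pool) if traits else []
    if missing:
        logger.warning("%d community species lack complete traits", len(missing))

    phylo_dm = patristic_distances(tree) if tree is not None else None
    trait_sets = {k: tuple(v) for k, v in config.trait_sets.items()}
    div = diversity_table(community, traits, phylo_dm, trait_sets=trait_sets)

    ivi_by_quadrat = {
        qid: compute_ivi(community.quadrat(qid)) for qid in community.quadrat_ids
    }
    dms: dict[str, DistanceMatrix] = {}
    if traits is not None:
        for name, tset in trait_sets.items():
            if len(traits.complete_species(tset)) >= 2:
                dms[f"fd_{name}"] = trait_distance_matrix(traits, tset)
    if phylo_dm is not None:
        # run-wide shuffle pool: every species with phylogeny data
        dms["mpd"] = phylo_dm

    div_ses = ses_table(div, ivi_by_quadrat, dms, n_iter=config.n_iter,
                        master_seed=config.seed)

    ses_cols = [c for c in div_ses.columns if c.startswith("ses_")]
    disp = pd.DataFrame(
        [asdict(dispersion_summary(div_ses[c], metric=c)) for c in ses_cols
         if np.isfinite(div_ses[c]).sum() >= 2]
    )

    work = div_ses.copy()
    work["log_biomass"] = log_transform(work["biomass"].to_numpy())
    work["log_richness"] = log_transform(work["richness"].to_numpy())

    biomass_pairs = [("log_richness", "log_biomass", "species_richness"),
                     ("shannon", "log_biomass", "shannon_h")]
    biomass_pairs += [(c, "log_biomass", c) for c in ses_cols]
    biomass_models = relationship_table(work, biomass_pairs, config.delta_aic_threshold)

    richness_pairs = [("log_richness", c, c) for c in ses_cols]
    richness_models = relationship_table(work, richness_pairs, config.delta_aic_threshold)

    env_frames = []
    for pred, pname in (("log_richness", "log_richness"), ("shannon", "shannon_h")):
        env_frames.append(
            envelope_table(
                work[pred].to_numpy(), work[ses_cols], taus=config.quantiles,
                n_boot=config.n_boot, seed=config.seed, x_name=pname,
            )
        )
    envelope = pd.concat(env_frames, ignore_index=True)

    run_log = pd.DataFrame(
        [{"version": __version__, "seed": config.seed, "n_iter": config.n_iter,
          "n_boot": config.n_boot, "n_quadrats": len(div_ses),
          "n_species_missing_traits": len(missing),
          "errors": "; ".join(errors) if errors else ""}]
    )
    results = {
        "diversity_ses": div_ses,
        "dispersion_summary": disp,
        "biomass_models": biomass_models,
        "richness_models": richness_models,
        "envelope": envelope,
        "run_log": run_log,
    }
    if config.output_dir:
        write_results(results, config.output_dir)
    return results


def group_summary(div_ses: pd.DataFrame, group_col: str) -> pd.DataFrame:
    """Per-group mean and t-based 95% CI of every numeric metric, plus
    which group attains the maximum and minimum of each metric mean."""
    if group_col not in div_ses.columns:
        raise KeyError(f"grouping column {group_col!r} not present")
    metrics = [c for c in div_ses.columns
               if c not in (group_col, "quadrat_id", "site_id")
               and pd.api.types.is_numeric_dtype(div_ses[c])]
    rows = []
    for g, sub in div_ses.groupby(group_col):
        for m in metrics:
            vals = sub[m].dropna().to_numpy(dtype=float)
            n = len(vals)
            row = {"group": g, "metric": m, "n": n,
                   "mean": float(vals.mean()) if n else np.nan}
            if n >= 2 and vals.std(ddof=1) > 0:
                half = _sps.t.ppf(0.975, n - 1) * vals.std(ddof=1) / np.sqrt(n)
                row["ci_low"], row["ci_high"] = row["mean"] - half, row["mean"] + half
                row["ci_flag"] = ""
            else:
                row["ci_low"] = row["ci_high"] = np.nan
                row["ci_flag"] = "n<2" if n < 2 else "zero-variance"
            rows.append(row)
    out = pd.DataFrame(rows)
    if out.empty:
        return out
    flags = []
    for m, sub in out.groupby("metric"):
        valid = sub.dropna(subset=["mean"])
        if valid.empty:
            continue
        flags.append({"metric": m,
                      "max_group": valid.loc[valid["mean"].idxmax(), "group"],
                      "min_group": valid.loc[valid["mean"].idxmin(), "group"]})
    extremes = pd.DataFrame(flags)
    return out.merge(extremes, on="metric", how="left")
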