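"""The study's concrete analyses on top of the PGLS engine.

Five-model suites for the full mammal data set (environment × latitude
interaction, additive, latitude-only, environment-only, null) and for the
semi-aquatic hair-density subset (latitude × log hair density and its
submodels); per-environment group summaries; the pinniped blubber-section
subanalysis; and plain per-FA OLS regressions against latitude.

Environment is a three-level factor (terrestrial, semi-aquatic,
fully-aquatic), dummy-coded against a reference level (default
fully-aquatic, so intercept contrasts read as "versus fully-aquatic").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fa import DELTA9_MUFAS, DELTA9_SFAS, FAProfile
from .pgls import (
    FitError,
    ModelComparison,
    MultiTreeResult,
    PGLSFit,
    _aggregate_fits,
    compare_models,
    fit_lambda_ml,
    effect_size,
    iteration_seed,
)
from .phylo import PhyloTree, normalize_taxon

__all__ = [
    "ENV_LEVELS",
    "ModelSpec",
    "MAIN_SUITE",
    "HAIR_SUITE",
    "SuiteResult",
    "build_design_matrix",
    "run_model_suite",
    "group_summary",
    "environment_slopes",
    "blubber_section_subanalysis",
    "fa_vs_latitude_regressions",
]

ENV_LEVELS = ("terrestrial", "semi_aquatic", "fully_aquatic")


@dataclass(frozen=True)
class ModelSpec:
    """A named regression formula over the trait table's columns."""

    name: str
    terms: tuple[str, ...]  # drawn from {latitude, environment, log_hair_density,
    #                         latitude:environment, latitude:log_hair_density}
    reference_level: str = "fully_aquatic"

    @property
    def uses_environment(self) -> bool:
        return any("environment" in t for t in self.terms)

    @property
    def uses_hair(self) -> bool:
        return any("log_hair_density" in t for t in self.terms)


def _spec(name: str, *terms: str) -> ModelSpec:
    return ModelSpec(name=name, terms=terms)


#: full-dataset suite: Δ9-DI or DBI against environment and latitude
MAIN_SUITE: tuple[ModelSpec, ...] = (
    _spec("interaction", "latitude", "environment", "latitude:environment"),
    _spec("additive", "latitude", "environment"),
    _spec("latitude_only", "latitude"),
    _spec("environment_only", "environment"),
    _spec("null"),
)

#: semi-aquatic subset suite: Δ9-DI against latitude and log hair density
HAIR_SUITE: tuple[ModelSpec, ...] = (
    _spec("latitude_x_hair", "latitude", "log_hair_density", "latitude:log_hair_density"),
    _spec("latitude_plus_hair", "latitude", "log_hair_density"),
    _spec("hair_density_only", "log_hair_density"),
    _spec("latitude_only", "latitude"),
    _spec("null"),
)


def build_design_matrix(
    records: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, list[str]]:
    """Design matrix for a model spec: intercept, then terms in order.

    Environment enters as two dummy columns against ``spec.reference_level``;
    the interaction adds the elementwise products of latitude with each dummy
    (marginal terms are always included by the suite definitions).
    """
    n = len(records)
    cols: list[np.ndarray] = [np.ones(n)]
    names: list[str] = ["intercept"]
    env_dummies: dict[str, np.ndarray] = {}
    if spec.uses_environment:
        present = set(records["environment"])
        missing_levels = [lv for lv in ENV_LEVELS if lv not in present]
        if missing_levels:
            raise FitError(
                f"environment level(s) with zero records: {', '.join(missing_levels)}"
            )
        for lv in ENV_LEVELS:
            if lv != spec.reference_level:
                env_dummies[lv] = (records["environment"] == lv).to_numpy(float)
    for term in spec.terms:
        if term == "latitude":
            cols.append(records["latitude"].to_numpy(float))
            names.append("latitude")
        elif term == "environment":
            for lv, d in env_dummies.items():
                cols.append(d)
                names.append(f"env[{lv}]")
        elif term == "log_hair_density":
            cols.append(records["log_hair_density"].to_numpy(float))
            names.append("log_hair_density")
        elif term == "latitude:environment":
            lat = records["latitude"].to_numpy(float)
            for lv, d in env_dummies.items():
                cols.append(lat * d)
                names.append(f"latitude:env[{lv}]")
        elif term == "latitude:log_hair_density":
            cols.append(
                records["latitude"].to_numpy(float)
                * records["log_hair_density"].to_numpy(float)
            )
            names.append("latitude:log_hair_density")
        else:
            raise FitError(f"unknown model term {term!r}")
    return np.column_stack(cols), names


@dataclass
class SuiteResult:
    """One response's model-selection run across polytomy resolutions."""

    response: str
    comparison: ModelComparison          # ranked by mean AICc
    comparison_median: ModelComparison   # same, median-aggregated
    fits: dict[str, MultiTreeResult] = field(default_factory=dict)
    env_slopes: pd.DataFrame | None = None  # per-environment slopes (interaction)

    def table(self) -> pd.DataFrame:
        """Comparison table shaped like the published ones."""
        df = self.comparison.table.copy()
        return df.rename(
            columns={
                "delta_aicc": "delta_AICc",
                "lambda": "PGLS_lambda",
                "r": "effect_size_r",
                "weight": "weighted_AICc",
            }
        )[["model", "delta_AICc", "PGLS_lambda", "effect_size_r", "weighted_AICc"]]


def _resolved_trees(tree: PhyloTree, n_iter: int, seed: int) -> list[PhyloTree]:
    if tree.is_binary:
        return [tree]
    return [tree.resolve_polytomies(iteration_seed(seed, it)) for it in range(n_iter)]


def run_model_suite(
    records: pd.DataFrame,
    tree: PhyloTree,
    response: str,
    suite: Sequence[ModelSpec] = MAIN_SUITE,
    n_iter: int = 1000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> SuiteResult:
    """Fit every model in the suite across random polytomy resolutions.

    All models in one run share the same resolved trees (same derived seeds),
    so per-iteration AICc differences and effect sizes compare like with
    like.  Effect size r is computed per iteration against that iteration's
    intercept-only fit, then aggregated.  Records whose species are missing
    required predictors are dropped with a log message before fitting.
    """
    needed = {"latitude"} | (
        {"log_hair_density"} if any(s.uses_hair for s in suite) else set()
    )
    use = records.dropna(subset=[response, *needed]).reset_index(drop=True)
    if len(use) < len(records):
        import logging

        logging.getLogger(__name__).info(
            "dropped %d records missing %s", len(records) - len(use), sorted(needed)
        )
    taxa = list(use["species"])
    pruned = tree.prune_to(taxa)
    trees = _resolved_trees(pruned, n_iter, seed)
    y = use[response].to_numpy(float)

    null_spec = next((s for s in suite if s.name == "null"), _spec("null"))
    specs = list(suite)
    if null_spec not in specs:
        specs.append(null_spec)

    fits_by_model: dict[str, list[PGLSFit]] = {}
    for spec in specs:
        X, names = build_design_matrix(use, spec)
        fits_by_model[spec.name] = [
            fit_lambda_ml(y, X, t, taxa=taxa, coef_names=names, ci_level=ci_level)
            for t in trees
        ]
    null_fits = fits_by_model["null"]
    for name, fits in fits_by_model.items():
        for f, f0 in zip(fits, null_fits):
            f.r = None if name == "null" else effect_size(f, f0)

    results: dict[str, MultiTreeResult] = {}
    rows_mean: dict[str, PGLSFit] = {}
    rows_median: dict[str, PGLSFit] = {}
    for spec in suite:
        fits = fits_by_model[spec.name]
        per_it = pd.DataFrame(
            {
                "iteration": range(len(fits)),
                "model": spec.name,
                "aicc": [f.aicc for f in fits],
                "lambda": [f.lambda_hat for f in fits],
                "lnl": [f.lnl for f in fits],
            }
        )
        results[spec.name] = MultiTreeResult(
            per_iteration=per_it,
            mean_fit=_aggregate_fits(fits, "mean"),
            median_fit=_aggregate_fits(fits, "median"),
        )
        rows_mean[spec.name] = results[spec.name].mean_fit
        rows_median[spec.name] = results[spec.name].median_fit

    out = SuiteResult(
        response=response,
        comparison=compare_models(rows_mean),
        comparison_median=compare_models(rows_median),
        fits=results,
    )
    if "interaction" in fits_by_model and any(s.name == "interaction" for s in suite):
        out.env_slopes = environment_slopes(
            fits_by_model["interaction"], reference_level=suite[0].reference_level,
            ci_level=ci_level,
        )
    return out


def environment_slopes(
    interaction_fits: Sequence[PGLSFit],
    reference_level: str = "fully_aquatic",
    ci_level: float = 0.95,
) -> pd.DataFrame:
    """Per-environment latitude slopes from interaction-model fits.

    The reference level's slope is β_latitude; every other level's is
    β_latitude + β_latitude:env, with variance from the coefficient
    covariance.  CIs are t-based and averaged across iterations.
    """
    rows = {lv: {"slope": [], "ci_low": [], "ci_high": []} for lv in ENV_LEVELS}
    for fit in interaction_fits:
        names = fit.coef_names
        i_lat = names.index("latitude")
        tcrit = stats.t.ppf(0.5 + ci_level / 2.0, df=fit.df_resid)
        for lv in ENV_LEVELS:
            if lv == reference_level:
                slope = fit.beta[i_lat]
                var = fit.cov_beta[i_lat, i_lat]
            else:
                i_int = names.index(f"latitude:env[{lv}]")
                slope = fit.beta[i_lat] + fit.beta[i_int]
                var = (
                    fit.cov_beta[i_lat, i_lat]
                    + fit.cov_beta[i_int, i_int]
                    + 2.0 * fit.cov_beta[i_lat, i_int]
                )
            se = np.sqrt(var)
            rows[lv]["slope"].append(slope)
            rows[lv]["ci_low"].append(slope - tcrit * se)
            rows[lv]["ci_high"].append(slope + tcrit * se)
    recs = []
    for lv in ENV_LEVELS:
        lo = float(np.mean(rows[lv]["ci_low"]))
        hi = float(np.mean(rows[lv]["ci_high"]))
        recs.append(
            {
                "environment": lv,
                "slope": float(np.mean(rows[lv]["slope"])),
                "ci_low": lo,
                "ci_high": hi,
                "significant": lo > 0 or hi < 0,
            }
        )
    return pd.DataFrame(recs)


def group_summary(records: pd.DataFrame, field: str) -> pd.DataFrame:
    """Mean, sample SD (n−1) and n of an index per environment group.

    Empty groups are omitted; single-record groups report NaN SD.
    """
    rows = []
    for lv in ENV_LEVELS:
        vals = records.loc[records["environment"] == lv, field].dropna()
        if len(vals) == 0:
            import logging

            logging.getLogger(__name__).warning("environment %s has no records", lv)
            continue
        rows.append(
            {
                "environment": lv,
                "mean": float(vals.mean()),
                "sd": float(vals.std(ddof=1)) if len(vals) > 1 else np.nan,
                "n": int(len(vals)),
            }
        )
    return pd.DataFrame(rows)


def blubber_section_subanalysis(
    records: pd.DataFrame,
    tree: PhyloTree,
    n_iter: int = 1000,
    seed: int = 0,
    response: str = "delta9_di",
) -> dict[str, pd.DataFrame]:
    """Latitude-only PGLS run separately per pinniped blubber section.

    Splits pinniped records by whether the whole blubber core or only the
    outer layer was analysed — blubber is stratified, so the section used can
    bias the desaturation index — and fits each group independently.  Groups
    with fewer than three species are refused.
    """
    pinn = records[records["pinniped"].astype(bool)]
    out: dict[str, pd.DataFrame] = {}
    for section in ("outer", "whole"):
        grp = pinn[pinn["blubber_section"] == section].reset_index(drop=True)
        if len(grp) < 3:
            raise FitError(
                f"blubber section {section!r} has only {len(grp)} pinniped records; "
                "need ≥ 3 for a latitude regression"
            )
        taxa = list(grp["species"])
        sub = tree.prune_to(taxa)
        trees = _resolved_trees(sub, n_iter, seed)
        y = grp[response].to_numpy(float)
        X, names = build_design_matrix(grp, _spec("latitude_only", "latitude"))
        fits = [fit_lambda_ml(y, X, t, taxa=taxa, coef_names=names) for t in trees]
        i_lat = names.index("latitude")
        lo = float(np.mean([f.ci_low[i_lat] for f in fits]))
        hi = float(np.mean([f.ci_high[i_lat] for f in fits]))
        out[section] = pd.DataFrame(
            [
                {
                    "section": section,
                    "n": len(grp),
                    "slope": float(np.mean([f.beta[i_lat] for f in fits])),
                    "intercept": float(np.mean([f.beta[0] for f in fits])),
                    "ci_low": lo,
                    "ci_high": hi,
                    "significant": lo > 0 or hi < 0,
                    "lambda": float(np.mean([f.lambda_hat for f in fits])),
                }
            ]
        )
    return out


def fa_vs_latitude_regressions(
    profiles: Iterable[FAProfile],
    records: pd.DataFrame,
    fas: Sequence[str] = (*DELTA9_SFAS, *DELTA9_MUFAS),
    alpha: float = 0.01,
) -> pd.DataFrame:
    """Ordinary least-squares regression of each FA's wt% on latitude.

    Deliberately non-phylogenetic: this asks which individual FAs move with
    latitude in the supplied set of species (the published analysis restricts
    to pinnipeds — filter ``records`` accordingly before calling).  A FA with
    constant wt% across species gets slope 0 and an undefined p-value, flagged
    in the ``note`` column.
    """
    lat_by_species = {
        normalize_taxon(r.species): float(r.latitude) for r in records.itertuples()
    }
    prof_list = [p for p in profiles if normalize_taxon(p.species) in lat_by_species]
    rows = []
    for fa_label in fas:
        xs, ys = [], []
        for p in prof_list:
            xs.append(lat_by_species[normalize_taxon(p.species)])
            ys.append(p.get(fa_label))
        if len(xs) < 3:
            raise FitError(f"need ≥ 3 species with latitude for {fa_label}, got {len(xs)}")
        xs_a, ys_a = np.asarray(xs), np.asarray(ys)
        if np.ptp(ys_a) == 0 or np.ptp(xs_a) == 0:
            rows.append(
                {"fa": fa_label, "slope": 0.0, "p_value": np.nan, "n": len(xs),
                 "significant": False, "note": "constant values"}
            )
            continue
        res = stats.linregress(xs_a, ys_a)
        rows.append(
            {
                "fa": fa_label,
                "slope": float(res.slope),
                "p_value": float(res.pvalue),
                "n": len(xs),
                "significant": bool(res.pvalue < alpha),
                "note": "",
            }
        )
    return pd.DataFrame(rows)
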