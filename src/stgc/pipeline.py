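"""End-to-end orchestration: simulate -> GC + DTI -> group inference.

A :class:`RunConfig` pins every analysis constant (windowing, model
orders, free-water threshold, correction levels, seed).  The pipeline
simulates a synthetic cohort, computes per-subject directed ROI GC
matrices and tract diffusion metrics, runs the between-group and
brain-behaviour statistics, and writes TSV tables plus a JSON manifest
from which every number in the report can be regenerated.

The GC and DTI halves are independent stages with their own derived
seeds, so each can be run on its own and gives results identical to the
joint run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dti import (
    estimate_rician_sigma,
    fit_tensor,
    free_water_fraction,
    tensor_scalars,
    tract_mean_metrics,
)
from .errors import ConfigurationError, StgcError
from .granger import build_edge_matrix
from .simulate import (
    CohortSpec,
    default_cohort_spec,
    default_gradient_table,
    default_network_spec,
    default_tract_geometry,
    load_defaults,
    simulate_covariates,
    simulate_dwi_cohort,
    simulate_var_series,
)
from .stats import adjusted_association, bh_fdr, bonferroni_threshold, ttest_two_sample
from .timeseries import prepare_series

__all__ = ["RunConfig", "ComponentMap", "select_dmn_component", "run_pipeline",
           "run_gc_stage", "run_dti_stage", "run_inference_stage"]


@dataclass
class RunConfig:
    """Analysis constants for one reproducible run."""

    discard_leading: int = 2
    keep_last: int = 208
    n_windows: int = 4
    order_min: int = 1
    order_max: int = 5
    fw_threshold: float = 0.7
    alpha: float = 0.05
    bonferroni_m: int | None = None  # None: number of tests actually run
    fdr_q: float = 0.1
    seed: int = 0
    n_hc: int | None = None
    n_patient: int | None = None
    roi_subset: list[str] | None = None
    voxels_per_roi: int | None = None

    def __post_init__(self) -> None:
        if self.keep_last % self.n_windows != 0:
            raise ConfigurationError(
                f"keep_last={self.keep_last} not divisible by n_windows={self.n_windows}"
            )
        if not 1 <= self.order_min <= self.order_max:
            raise ConfigurationError("need 1 <= order_min <= order_max")
        if not 0 < self.fdr_q < 1 or not 0 < self.alpha < 1:
            raise ConfigurationError("alpha and fdr_q must lie in (0, 1)")

    @property
    def order_range(self) -> tuple[int, ...]:
        return tuple(range(self.order_min, self.order_max + 1))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**payload)

    def cohort_spec(self) -> CohortSpec:
        spec = default_cohort_spec()
        if self.n_hc is not None:
            spec.n_hc = self.n_hc
        if self.n_patient is not None:
            spec.n_patient = self.n_patient
        return spec


@dataclass
class ComponentMap:
    """A spatial ICA component and its template match."""

    component_id: int
    spatial_map: np.ndarray
    template_correlation: float


def select_dmn_component(
    components: list[np.ndarray],
    template: np.ndarray,
    mask: np.ndarray | None = None,
    absolute: bool = False,
) -> ComponentMap:
    """Pick the component maximising spatial correlation with a template.

    Correlation is Pearson over in-mask voxels; by default the signed
    value is maximised (``absolute=True`` matches on magnitude).
    Zero-variance components are excluded with a warning; if all are
    excluded an error is raised.
    """
    if not components:
        raise ValueError("need at least one component")
    sel = np.ones(template.shape, dtype=bool) if mask is None else mask.astype(bool)
    t = template[sel].ravel()
    if t.std() == 0:
        raise ValueError("template has zero variance in mask")
    best: ComponentMap | None = None
    for idx, comp in enumerate(components):
        if comp.shape != template.shape:
            raise ValueError(f"component {idx} grid differs from template")
        c = comp[sel].ravel()
        if c.std() == 0:
            warnings.warn(f"component {idx} has zero variance; excluded")
            continue
        r = float(np.corrcoef(c, t)[0, 1])
        score = abs(r) if absolute else r
        if best is None or score > (abs(best.template_correlation) if absolute
                                    else best.template_correlation):
            best = ComponentMap(idx, comp, r)
    if best is None:
        raise ValueError("all components excluded (zero variance)")
    return best


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------


def _stage_seed(seed: int, stage: int, item: int = 0) -> np.random.SeedSequence:
    return np.random.SeedSequence([seed, stage, item])


def run_gc_stage(config: RunConfig) -> pd.DataFrame:
    """Per-subject directed ROI GC table (long format).

    Columns: subject_id, group, source, target, gc.
    """
    spec = config.cohort_spec()
    cfg_net = load_defaults()["network"]
    n_timepoints = int(cfg_net["n_timepoints"])
    rows = []
    for idx, (sid, group) in enumerate(zip(spec.subject_ids, spec.groups)):
        try:
            net = default_network_spec(group, cohort=spec)
            if config.voxels_per_roi is not None:
                net.voxels_per_roi = config.voxels_per_roi
            rois = simulate_var_series(
                net, n_timepoints, seed=_stage_seed(config.seed, 1, idx)
            )
            names = config.roi_subset or net.roi_names
            trimmed = {}
            scheme = None
            for name in names:
                roi = rois[name]
                data, scheme = prepare_series(
                    roi.data, config.discard_leading, config.keep_last, config.n_windows
                )
                trimmed[name] = dataclasses.replace(roi, data=data)
            edges = build_edge_matrix(
                [trimmed[n] for n in names], scheme, config.order_range
            )
            for i, src in enumerate(names):
                for j, tgt in enumerate(names):
                    if i != j:
                        rows.append(
                            {
                                "subject_id": sid,
                                "group": group,
                                "source": src,
                                "target": tgt,
                                "gc": edges.gc[i, j],
                            }
                        )
        except StgcError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StgcError(f"GC stage failed for subject {sid}: {exc}") from exc
    return pd.DataFrame(rows)


def run_dti_stage(config: RunConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject tract metrics and the covariate table.

    Returns ``(tracts, covariates)`` where ``tracts`` has columns
    subject_id, group, tract, mean_fa/md/rd/ad, n_voxels, n_masked.
    """
    spec = config.cohort_spec()
    gtab = default_gradient_table()
    geometry = default_tract_geometry()
    cohort = simulate_dwi_cohort(spec, gtab, geometry, seed=_stage_seed(config.seed, 2))
    rows = []
    for sid, group in zip(cohort.subject_ids, cohort.groups):
        try:
            for tract, geom in cohort.geometry.items():
                signals = cohort.signals[sid][tract]
                sigma = estimate_rician_sigma(signals, gtab)
                shape = tuple(geom.voxels.max(axis=0) + 1)
                maps = {m: np.zeros(shape) for m in ("fa", "md", "rd", "ad")}
                mask = np.zeros(shape, dtype=bool)
                for v, coord in enumerate(geom.voxels):
                    tv = fit_tensor(signals[v], gtab, rician_sigma=sigma)
                    f = free_water_fraction(
                        signals[v], gtab, tissue_d=0.7e-3, rician_sigma=sigma
                    )
                    fa, md, rd, ad = tensor_scalars(tv.eigenvalues)
                    c = tuple(coord)
                    maps["fa"][c], maps["md"][c] = fa, md
                    maps["rd"][c], maps["ad"][c] = rd, ad
                    mask[c] = f > config.fw_threshold
                tm = tract_mean_metrics(maps, geom.voxels, mask, tract_name=tract)
                rows.append(
                    {
                        "subject_id": sid,
                        "group": group,
                        "tract": tract,
                        "mean_fa": tm.mean_fa,
                        "mean_md": tm.mean_md,
                        "mean_rd": tm.mean_rd,
                        "mean_ad": tm.mean_ad,
                        "n_voxels": tm.n_voxels,
                        "n_masked": tm.n_masked,
                    }
                )
        except StgcError:
            raise
        except Exception as exc:  # pragma: no cover - defensive
            raise StgcError(f"DTI stage failed for subject {sid}: {exc}") from exc
    tracts = pd.DataFrame(rows)
    mem_tract = spec.memory_tract
    fa_series = (
        tracts[tracts["tract"] == mem_tract]
        .set_index("subject_id")["mean_fa"]
        .reindex(spec.subject_ids)
    )
    covariates = simulate_covariates(
        spec, fa_series.to_numpy(), seed=_stage_seed(config.seed, 3)
    )
    return tracts, covariates


def run_inference_stage(
    config: RunConfig,
    gc_table: pd.DataFrame,
    tracts: pd.DataFrame,
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group tests (edges + tract metrics) and memory associations."""
    tests = []
    if not gc_table.empty:
        for (src, tgt), grp in gc_table.groupby(["source", "target"], sort=True):
            hc = grp.loc[grp["group"] == "hc", "gc"].to_numpy()
            pt = grp.loc[grp["group"] == "amci", "gc"].to_numpy()
            res = ttest_two_sample(hc, pt)
            tests.append(
                {
                    "test": f"gc:{src}->{tgt}",
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p_two_tailed,
                }
            )
    for metric in ("mean_fa", "mean_md", "mean_rd", "mean_ad"):
        for tract, grp in tracts.groupby("tract", sort=True):
            hc = grp.loc[grp["group"] == "hc", metric].to_numpy()
            pt = grp.loc[grp["group"] == "amci", metric].to_numpy()
            res = ttest_two_sample(hc, pt)
            tests.append(
                {
                    "test": f"{metric}:{tract}",
                    "statistic": res.statistic,
                    "df": res.df,
                    "p": res.p_two_tailed,
                }
            )
    group_tests = pd.DataFrame(tests)
    m = config.bonferroni_m or len(group_tests)
    thr = bonferroni_threshold(config.alpha, m)
    group_tests["bonferroni_threshold"] = thr
    group_tests["bonferroni_significant"] = group_tests["p"] < thr
    group_tests["fdr_significant"] = bh_fdr(group_tests["p"].to_numpy(), config.fdr_q)

    spec = config.cohort_spec()
    cov = covariates.assign(gender_male=(covariates["gender"] == "M").astype(float))
    fa = (
        tracts[tracts["tract"] == spec.memory_tract]
        .set_index("subject_id")["mean_fa"]
    )
    assoc_rows = []
    for group in ("hc", "amci"):
        sub = cov[cov["group"] == group].set_index("subject_id")
        aligned_fa = fa.reindex(sub.index)
        row = {"group": group, "outcome": f"mean_fa:{spec.memory_tract}"}
        if len(sub) > 5:  # intercept + predictor + 3 covariates
            res = adjusted_association(
                aligned_fa.to_numpy(),
                sub["memory_score"].to_numpy(),
                sub[["gender_male", "age", "motion"]].reset_index(drop=True),
            )
            row.update(
                coefficient=res.coefficient, t=res.t_statistic, df=res.df, p=res.p
            )
        else:
            warnings.warn(f"group {group}: too few subjects for adjusted association")
            row.update(coefficient=np.nan, t=np.nan, df=0, p=np.nan)
        assoc_rows.append(row)
    associations = pd.DataFrame(assoc_rows)
    return group_tests, associations


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict[str, Path]:
    """Full deterministic run; writes tables and a manifest into ``out_dir``.

    All outputs are computed before anything is written, so a stage
    failure leaves the output directory untouched.
    """
    gc_table = run_gc_stage(config)
    tracts, covariates = run_dti_stage(config)
    group_tests, associations = run_inference_stage(config, gc_table, tracts, covariates)

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, frame in (
        ("edges", gc_table),
        ("tracts", tracts),
        ("covariates", covariates),
        ("group_tests", group_tests),
        ("associations", associations),
    ):
        path = out / f"{name}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        paths[name] = path

    cfg_dict = dataclasses.asdict(config)
    manifest = {
        "package": "stgc",
        "version": __version__,
        "seed": config.seed,
        "parameters": cfg_dict,
        "parameter_hash": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "tables": {k: p.name for k, p in paths.items()},
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    paths["manifest"] = manifest_path
    return paths
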