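"""Synthetic cohort generator.

Everything the analysis pipeline consumes can be generated here from an
explicit seed: multivoxel ROI "BOLD" series driven by (piecewise) vector
autoregressions with known directed couplings, diffusion-weighted
signals over synthetic thalamo-cortical tracts with planted group
differences and free-water contamination, and a per-subject covariate
table whose moments match the study cohort (26 healthy controls vs 20
amnestic-MCI patients) with a memory score coupled to tract integrity in
the patient group only.

The generator's defaults live in ``defaults.yaml`` (packaged alongside
this module) and define the study conditions: 210 timepoints at
TR = 2 s, 10 DMN/subcortical ROIs with 5 voxels each, b = 3000 s/mm^2
single-shell DWI at SNR 30.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
import yaml
from scipy.stats import gamma as gamma_dist

from .dti import FREE_WATER_DIFFUSIVITY, GradientTable, tensor_scalars
from .errors import ConfigurationError, StationarityError
from .timeseries import ROITimeSeries

__all__ = [
    "NetworkSpec",
    "CohortSpec",
    "TractGeometry",
    "CohortDWI",
    "load_defaults",
    "default_network_spec",
    "default_cohort_spec",
    "default_gradient_table",
    "default_tract_geometry",
    "simulate_var_series",
    "apply_hrf",
    "simulate_dwi_cohort",
    "simulate_covariates",
]


@lru_cache(maxsize=1)
def load_defaults() -> dict:
    """Load the versioned generator defaults shipped with the package."""
    text = (importlib.resources.files("stgc") / "defaults.yaml").read_text()
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# BOLD network simulation
# ---------------------------------------------------------------------------


@dataclass
class NetworkSpec:
    """Piecewise-stationary VAR(1) network generating ROI-level BOLD.

    ``coupling_regimes`` is an ordered list of ``(start_index, matrix)``
    pairs; ``matrix[i, j]`` couples ROI ``j`` (source, lag 1) to ROI
    ``i`` (target).  Every regime matrix must have spectral radius < 1.
    Voxel series share their ROI's latent process: with within-ROI
    correlation ``rho``, each voxel is ``sqrt(rho) * latent +
    sqrt(1 - rho) * noise`` (equal variances), so any two voxels of one
    ROI correlate at ``rho``.
    """

    roi_names: list[str]
    coupling_regimes: list[tuple[int, np.ndarray]]
    noise_sd: float = 1.0
    voxels_per_roi: int = 5
    within_roi_correlation: float = 0.7
    tr_seconds: float = 2.0

    def __post_init__(self) -> None:
        k = len(self.roi_names)
        if not 0 <= self.within_roi_correlation < 1:
            raise ConfigurationError("within_roi_correlation must lie in [0, 1)")
        if self.noise_sd <= 0 or self.voxels_per_roi < 1:
            raise ConfigurationError("noise_sd and voxels_per_roi must be positive")
        regimes = []
        last_start = -1
        for idx, (start, mat) in enumerate(self.coupling_regimes):
            mat = np.asarray(mat, dtype=float)
            if mat.shape != (k, k):
                raise ConfigurationError(f"regime {idx}: matrix must be {k}x{k}")
            if start <= last_start:
                raise ConfigurationError("regimes must be ordered, non-overlapping")
            radius = float(np.max(np.abs(np.linalg.eigvals(mat))))
            if radius >= 1.0:
                raise StationarityError(
                    f"regime {idx} (start {start}): spectral radius {radius:.3f} >= 1"
                )
            regimes.append((int(start), mat))
            last_start = start
        if not regimes or regimes[0][0] != 0:
            raise ConfigurationError("first regime must start at index 0")
        self.coupling_regimes = regimes


def _regime_matrix(spec: NetworkSpec, t: int) -> np.ndarray:
    mat = spec.coupling_regimes[0][1]
    for start, m in spec.coupling_regimes:
        if t >= start:
            mat = m
    return mat


def simulate_var_series(
    spec: NetworkSpec,
    n_timepoints: int,
    seed: int | np.random.SeedSequence,
    burn_in: int = 50,
) -> dict[str, ROITimeSeries]:
    """Simulate per-ROI voxel x time matrices from a piecewise VAR(1).

    Reproducible: identical ``(spec, n_timepoints, seed)`` yield
    bit-identical output.
    """
    rng = np.random.default_rng(seed)
    k = len(spec.roi_names)
    a0 = spec.coupling_regimes[0][1]
    z = np.zeros(k)
    for _ in range(burn_in):
        z = a0 @ z + rng.normal(0.0, spec.noise_sd, size=k)
    latent = np.empty((k, n_timepoints))
    latent[:, 0] = z
    for t in range(1, n_timepoints):
        a = _regime_matrix(spec, t)
        latent[:, t] = a @ latent[:, t - 1] + rng.normal(0.0, spec.noise_sd, size=k)

    rho = spec.within_roi_correlation
    out: dict[str, ROITimeSeries] = {}
    for i, name in enumerate(spec.roi_names):
        sd = float(latent[i].std())
        sd = sd if sd > 0 else 1.0
        eps = rng.normal(0.0, 1.0, size=(spec.voxels_per_roi, n_timepoints))
        data = np.sqrt(rho) * latent[i][None, :] + np.sqrt(1 - rho) * sd * eps
        voxel_ids = [(i, v, 0) for v in range(spec.voxels_per_roi)]
        out[name] = ROITimeSeries(
            roi_name=name, voxel_ids=voxel_ids, data=data, tr_seconds=spec.tr_seconds
        )
    return out


def hrf_kernel(tr_seconds: float, duration: float = 32.0) -> np.ndarray:
    """Canonical double-gamma HRF sampled at TR (peak ~5 s, undershoot ~15 s)."""
    if tr_seconds <= 0:
        raise ConfigurationError("tr_seconds must be positive")
    t = np.arange(0.0, duration, tr_seconds)
    kernel = gamma_dist.pdf(t, a=6.0) - gamma_dist.pdf(t, a=16.0) / 6.0
    return kernel


def apply_hrf(series: np.ndarray, tr_seconds: float) -> np.ndarray:
    """Causal convolution of neural-like series with the canonical HRF.

    Output has the same length as the input (leading edge of the full
    convolution), applied along the last axis.
    """
    series = np.asarray(series, dtype=float)
    kernel = hrf_kernel(tr_seconds)
    if series.ndim == 1:
        return np.convolve(series, kernel)[: series.size]
    return np.apply_along_axis(
        lambda row: np.convolve(row, kernel)[: row.size], -1, series
    )


def default_network_spec(group: str = "hc", cohort: "CohortSpec | None" = None) -> NetworkSpec:
    """Stationary default network for one group; patient edges attenuated."""
    cfg = load_defaults()["network"]
    names = list(cfg["roi_names"])
    k = len(names)
    mat = np.eye(k) * cfg["self_coupling"]
    effects = (cohort.edge_effects if cohort is not None
               else load_defaults()["cohort"]["edge_effects"])
    for edge, value in cfg["couplings"].items():
        src, tgt = edge.split("->")
        c = float(value)
        if group != "hc" and edge in effects:
            c *= float(effects[edge])
        mat[names.index(tgt), names.index(src)] = c
    return NetworkSpec(
        roi_names=names,
        coupling_regimes=[(0, mat)],
        noise_sd=cfg["noise_sd"],
        voxels_per_roi=cfg["voxels_per_roi"],
        within_roi_correlation=cfg["within_roi_correlation"],
        tr_seconds=cfg["tr_seconds"],
    )


# ---------------------------------------------------------------------------
# DWI cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class TractGeometry:
    """Voxel-index geometry of one synthetic tract."""

    tract_name: str
    voxels: np.ndarray  # (n, 3) int
    border_voxels: np.ndarray  # subset rows of `voxels` planted with free water

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=int)
        self.border_voxels = np.asarray(self.border_voxels, dtype=int)


@dataclass
class CohortSpec:
    """Design of the synthetic two-group cohort."""

    n_hc: int = 26
    n_patient: int = 20
    edge_effects: dict[str, float] = field(default_factory=dict)
    tract_effects: dict[str, tuple[float, float]] = field(default_factory=dict)
    memory_coupling: dict[str, float] = field(default_factory=lambda: {"hc": 0.0, "amci": -0.75})
    memory_tract: str = "L-Thalamus->L-IPL"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_hc < 2 or self.n_patient < 2:
            raise ConfigurationError("group sizes must be >= 2")
        for g, rho in self.memory_coupling.items():
            if abs(rho) >= 1:
                raise ConfigurationError(f"|memory_coupling[{g}]| must be < 1")

    @property
    def subject_ids(self) -> list[str]:
        return [f"hc{i:03d}" for i in range(self.n_hc)] + [
            f"mci{i:03d}" for i in range(self.n_patient)
        ]

    @property
    def groups(self) -> list[str]:
        return ["hc"] * self.n_hc + ["amci"] * self.n_patient


def default_cohort_spec() -> CohortSpec:
    cfg = load_defaults()
    tract_effects = {
        name: (float(eff["delta_ad"]), float(eff["delta_rd"]))
        for name, eff in cfg["dwi"]["tract_effects"].items()
    }
    return CohortSpec(
        n_hc=cfg["cohort"]["n_hc"],
        n_patient=cfg["cohort"]["n_patient"],
        edge_effects=dict(cfg["cohort"]["edge_effects"]),
        tract_effects=tract_effects,
        memory_coupling=dict(cfg["cohort"]["memory_coupling"]),
        memory_tract=cfg["cohort"]["memory_tract"],
    )


def _fibonacci_directions(n: int) -> np.ndarray:
    """Deterministic, approximately isotropic unit directions."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    vecs = np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )
    return vecs / np.linalg.norm(vecs, axis=1, keepdims=True)


def default_gradient_table() -> GradientTable:
    """61 isotropically distributed b = 3000 directions plus four b = 0."""
    cfg = load_defaults()["dwi"]
    n_dir, n_b0 = int(cfg["n_directions"]), int(cfg["n_b0"])
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dir, float(cfg["bval"]))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), _fibonacci_directions(n_dir)])
    return GradientTable(bvals=bvals, bvecs=bvecs)


def default_tract_geometry() -> dict[str, TractGeometry]:
    """Straight-line synthetic tracts with free-water border voxels."""
    cfg = load_defaults()["dwi"]
    length = int(cfg["tract_length"])
    every = int(cfg["border_every"])
    geoms: dict[str, TractGeometry] = {}
    for t_idx, name in enumerate(cfg["tract_effects"]):
        core = np.array([(x, t_idx * 4, 0) for x in range(length)])
        border = np.array([(x, t_idx * 4 + 1, 0) for x in range(0, length, every)])
        geoms[name] = TractGeometry(
            tract_name=name,
            voxels=np.vstack([core, border]),
            border_voxels=border,
        )
    return geoms


@dataclass
class CohortDWI:
    """Simulated DWI signals and bookkeeping for a cohort."""

    subject_ids: list[str]
    groups: list[str]
    signals: dict[str, dict[str, np.ndarray]]  # subject -> tract -> (n_vox, n_meas)
    geometry: dict[str, TractGeometry]
    true_fa: pd.DataFrame  # subject x tract, noise-free generating FA


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q, r = np.linalg.qr(rng.standard_normal((3, 3)))
    return q * np.sign(np.diag(r))


def simulate_dwi_cohort(
    spec: CohortSpec,
    gtab: GradientTable,
    tract_geometry: dict[str, TractGeometry] | None = None,
    seed: int = 0,
) -> CohortDWI:
    """Forward-simulate per-subject DWI signals over synthetic tracts.

    Patient-group tracts listed in ``spec.tract_effects`` have their
    generating eigenvalues perturbed by ``(delta_ad, delta_rd)`` (axial
    and radial diffusivity shifts); voxels listed as tract borders are
    planted with a high free-water fraction; signals carry Rician noise
    at the configured SNR.
    """
    cfg = load_defaults()["dwi"]
    geometry = tract_geometry if tract_geometry is not None else default_tract_geometry()
    base = np.array(cfg["tissue_eigenvalues"], dtype=float)
    snr = float(cfg["snr"])
    f_border = float(cfg["free_water_f"])
    subj_sd = float(cfg["subject_eigen_sd"])
    vox_sd = float(cfg["voxel_eigen_sd"])

    # validate perturbed tensors before any simulation
    for tract, (d_ad, d_rd) in spec.tract_effects.items():
        lam = base + np.array([d_ad, d_rd, d_rd])
        if np.any(lam <= 0) or not (lam[0] >= lam[1] >= lam[2]):
            raise ConfigurationError(
                f"tract effect on {tract!r} yields invalid eigenvalues {lam}"
            )

    rng = np.random.default_rng(seed)
    signals: dict[str, dict[str, np.ndarray]] = {}
    fa_rows = []
    for subject, group in zip(spec.subject_ids, spec.groups):
        subj_signals: dict[str, np.ndarray] = {}
        fa_row: dict[str, float] = {}
        for tract, geom in geometry.items():
            lam_group = base.copy()
            if group != "hc" and tract in spec.tract_effects:
                d_ad, d_rd = spec.tract_effects[tract]
                lam_group = lam_group + np.array([d_ad, d_rd, d_rd])
            lam_subj = lam_group * np.exp(rng.normal(0.0, subj_sd, size=3))
            lam_subj = np.sort(lam_subj)[::-1]
            n_vox = geom.voxels.shape[0]
            border_set = {tuple(v) for v in geom.border_voxels}
            vox_signals = np.empty((n_vox, gtab.bvals.size))
            fas = []
            for v in range(n_vox):
                lam_vox = np.sort(lam_subj * np.exp(rng.normal(0.0, vox_sd, size=3)))[::-1]
                rot = _random_rotation(rng)
                D = rot @ np.diag(lam_vox) @ rot.T
                f = f_border if tuple(geom.voxels[v]) in border_set else 0.0
                bg = np.einsum("ni,ij,nj->n", gtab.bvecs, D, gtab.bvecs)
                s = (1 - f) * np.exp(-gtab.bvals * bg) + f * np.exp(
                    -gtab.bvals * FREE_WATER_DIFFUSIVITY
                )
                sigma = 1.0 / snr
                noise_r = rng.normal(0.0, sigma, size=s.size)
                noise_i = rng.normal(0.0, sigma, size=s.size)
                vox_signals[v] = np.sqrt((s + noise_r) ** 2 + noise_i**2)
                if f == 0.0:
                    fas.append(tensor_scalars(lam_vox)[0])
            subj_signals[tract] = vox_signals
            fa_row[tract] = float(np.mean(fas))
        signals[subject] = subj_signals
        fa_rows.append(fa_row)
    true_fa = pd.DataFrame(fa_rows, index=spec.subject_ids)
    return CohortDWI(
        subject_ids=spec.subject_ids,
        groups=spec.groups,
        signals=signals,
        geometry=geometry,
        true_fa=true_fa,
    )


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------


def simulate_covariates(
    spec: CohortSpec,
    tract_fa_per_subject,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-subject covariate table with a group-specific FA-memory coupling.

    Demographic and neuropsychological scores are drawn from the cohort
    moments in the defaults file.  The memory score of group ``g`` is
    ``mean_g + sd * (rho_g * z(FA) + sqrt(1 - rho_g^2) * noise)`` where
    ``z(FA)`` standardises the planted tract's per-subject FA within the
    group, so ``rho_g`` is the generating FA-memory correlation.
    """
    cfg = load_defaults()
    cov_cfg = cfg["covariates"]
    mem_cfg = cfg["cohort"]
    fa = np.asarray(tract_fa_per_subject, dtype=float)
    ids = spec.subject_ids
    groups = np.array(spec.groups)
    if fa.shape != (len(ids),):
        raise ValueError("tract_fa_per_subject must align with the cohort subjects")
    rng = np.random.default_rng(seed)

    rows: dict[str, np.ndarray] = {}
    for col in ("age", "education", "mmse", "gds", "epq_e", "epq_n", "cr"):
        vals = np.empty(len(ids))
        for g in ("hc", "amci"):
            mean, sd = cov_cfg[col][g]
            sel = groups == g
            vals[sel] = rng.normal(mean, sd, size=sel.sum())
        rows[col] = vals
    rows["mmse"] = np.clip(rows["mmse"], 0, 30)
    rows["gds"] = np.clip(rows["gds"], 0, None)

    gender = np.empty(len(ids), dtype=object)
    study_n = {"hc": int(mem_cfg["n_hc"]), "amci": int(mem_cfg["n_patient"])}
    for g, n_group in (("hc", spec.n_hc), ("amci", spec.n_patient)):
        # preserve the study's male fraction for scaled-down cohorts,
        # keeping both genders represented
        frac = int(cov_cfg["male_count"][g]) / study_n[g]
        n_male = int(np.clip(round(frac * n_group), 1, n_group - 1))
        labels = np.array(["M"] * n_male + ["F"] * (n_group - n_male))
        gender[groups == g] = rng.permutation(labels)

    motion = rng.lognormal(cov_cfg["motion_log_mean"], cov_cfg["motion_log_sd"], len(ids))

    memory = np.empty(len(ids))
    sd_mem = float(mem_cfg["memory_sd"])
    for g in ("hc", "amci"):
        sel = groups == g
        rho = float(spec.memory_coupling.get(g, 0.0))
        z = fa[sel] - fa[sel].mean()
        z_sd = z.std()
        z = z / z_sd if z_sd > 0 else z
        eps = rng.standard_normal(sel.sum())
        memory[sel] = (
            float(mem_cfg["memory_mean"][g])
            + sd_mem * (rho * z + np.sqrt(1 - rho**2) * eps)
        )

    return pd.DataFrame(
        {
            "subject_id": ids,
            "group": groups,
            "age": rows["age"],
            "gender": gender,
            "education": rows["education"],
            "mmse": rows["mmse"],
            "gds": rows["gds"],
            "epq_e": rows["epq_e"],
            "epq_n": rows["epq_n"],
            "cr": rows["cr"],
            "memory_score": memory,
            "motion": motion,
        }
    )
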