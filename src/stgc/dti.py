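"""Diffusion-tensor metrics with free-water masking.

Voxelwise diffusion tensors are estimated by log-linear least squares of
``ln(S/S0) = -b g' D g``; the tensor's eigenvalues yield the standard
scalar maps

* mean diffusivity        MD = (l1 + l2 + l3) / 3
* axial diffusivity       AD = l1
* radial diffusivity      RD = (l2 + l3) / 2
* fractional anisotropy   FA = sqrt(3/2) * ||l - MD|| / ||l||

Voxels contaminated by free water (CSF-like isotropic diffusion at
~3.0e-3 mm^2/s) are identified by a shell-averaged bi-exponential
signal-fraction fit and masked above a configurable threshold before
tract-level averaging.  With a single non-zero b shell the pair
(f, tissue diffusivity) is not jointly identifiable, so the tissue
diffusivity is fixed per run (default 0.7e-3 mm^2/s).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import EmptyTractError, IdentifiabilityError, SingularDesignError

__all__ = [
    "GradientTable",
    "TensorVoxel",
    "TractMetrics",
    "FREE_WATER_DIFFUSIVITY",
    "estimate_rician_sigma",
    "fit_tensor",
    "tensor_scalars",
    "free_water_fraction",
    "tract_mean_metrics",
]

logger = logging.getLogger(__name__)

#: Diffusivity of free water at body temperature, mm^2/s.
FREE_WATER_DIFFUSIVITY = 3.0e-3


@dataclass
class GradientTable:
    """Diffusion gradient scheme: b-values (s/mm^2) and unit b-vectors."""

    bvals: np.ndarray
    bvecs: np.ndarray  # (n, 3)

    def __post_init__(self) -> None:
        self.bvals = np.asarray(self.bvals, dtype=float)
        self.bvecs = np.asarray(self.bvecs, dtype=float)
        if self.bvecs.ndim != 2 or self.bvecs.shape[1] != 3:
            raise ValueError("bvecs must have shape (n, 3)")
        if self.bvals.shape[0] != self.bvecs.shape[0]:
            raise ValueError("bvals and bvecs lengths differ")
        if np.any(self.bvals < 0):
            raise ValueError("b-values must be non-negative")
        dwi = self.bvals > 0
        norms = np.linalg.norm(self.bvecs[dwi], axis=1)
        if dwi.any() and not np.allclose(norms, 1.0, atol=1e-3):
            raise ValueError("non-b0 gradient vectors must be unit norm (1e-3)")
        if self.bvals.size < 7 or not (~dwi).any():
            raise ValueError("need >= 7 entries including >= 1 b=0 for tensor fitting")

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    def shells(self) -> list[float]:
        """Unique non-zero b-values."""
        return sorted(set(self.bvals[self.bvals > 0]))


@dataclass
class TensorVoxel:
    """Diffusion tensor summary for one voxel."""

    eigenvalues: np.ndarray  # descending, mm^2/s
    eigenvectors: np.ndarray  # columns, orthonormal
    free_water_fraction: float = float("nan")
    masked: bool = False
    n_clamped: int = 0

    def __post_init__(self) -> None:
        ev = np.asarray(self.eigenvalues, dtype=float)
        if ev.shape != (3,) or np.any(np.diff(ev) > 1e-15):
            raise ValueError("eigenvalues must be a descending triple")
        self.eigenvalues = ev


@dataclass
class TractMetrics:
    """Mean scalar metrics over a tract's unmasked voxels."""

    tract_name: str
    voxel_set: list[tuple[int, int, int]]
    mean_fa: float
    mean_md: float
    mean_rd: float
    mean_ad: float
    n_voxels: int = 0
    n_masked: int = 0


_design_cache: dict[bytes, tuple[np.ndarray, np.ndarray]] = {}


def _design_matrix(gtab: GradientTable) -> np.ndarray:
    g = gtab.bvecs
    b = gtab.bvals[:, None]
    cols = np.column_stack(
        [
            g[:, 0] ** 2,
            g[:, 1] ** 2,
            g[:, 2] ** 2,
            2 * g[:, 0] * g[:, 1],
            2 * g[:, 0] * g[:, 2],
            2 * g[:, 1] * g[:, 2],
        ]
    )
    return np.column_stack([-b * cols, np.ones(len(g))])


def _design_pinv(gtab: GradientTable) -> tuple[np.ndarray, np.ndarray]:
    """Design matrix and its pseudo-inverse, cached per gradient scheme."""
    key = gtab.bvals.tobytes() + gtab.bvecs.tobytes()
    if key not in _design_cache:
        X = _design_matrix(gtab)
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise SingularDesignError("gradient scheme yields a singular tensor design")
        if len(_design_cache) > 32:
            _design_cache.clear()
        _design_cache[key] = (X, np.linalg.pinv(X))
    return _design_cache[key]


def estimate_rician_sigma(signals: np.ndarray, gtab: GradientTable) -> float:
    """Pooled noise level from the repeated b = 0 measurements.

    ``signals`` is (n_voxels, n_measurements); the standard deviation of
    the b = 0 repeats around each voxel's own b = 0 mean is pooled over
    voxels.  At b0 SNR >> 1 the Rician noise is effectively Gaussian, so
    this estimates the per-channel sigma used by the noise-floor
    correction.
    """
    s = np.atleast_2d(np.asarray(signals, dtype=float))
    b0 = s[:, gtab.b0_mask]
    if b0.shape[1] < 2:
        raise ValueError("need >= 2 b=0 measurements to estimate sigma")
    resid = b0 - b0.mean(axis=1, keepdims=True)
    return float(np.sqrt((resid**2).sum() / (b0.size - b0.shape[0])))


def _floor_correct(s: np.ndarray, sigma: float) -> np.ndarray:
    """Second-moment Rician noise-floor correction, clipped at 0.2 sigma."""
    return np.sqrt(np.clip(s**2 - 2.0 * sigma**2, (0.2 * sigma) ** 2, None))


def fit_tensor(
    signals: np.ndarray, gtab: GradientTable, rician_sigma: float | None = None
) -> TensorVoxel:
    """Log-linear least-squares tensor fit for a single voxel.

    At high b-values the Rician noise floor dominates strongly attenuated
    measurements and biases the fitted diffusivities; passing
    ``rician_sigma`` (e.g. from :func:`estimate_rician_sigma`) applies the
    standard second-moment correction ``sqrt(M^2 - 2 sigma^2)`` before the
    log-linear fit.  Negative eigenvalues arising from noisy fits are
    clamped to zero (the clamp count is recorded and logged).
    """
    s = np.asarray(signals, dtype=float)
    if s.shape != gtab.bvals.shape:
        raise ValueError("signals must match gradient table length")
    if np.any(s <= 0):
        bad = np.flatnonzero(s <= 0)
        raise ValueError(f"non-positive signal at measurement indices {bad.tolist()}")
    if rician_sigma is not None:
        s = _floor_correct(s, rician_sigma)
    _, pinv = _design_pinv(gtab)
    beta = pinv @ np.log(s)
    dxx, dyy, dzz, dxy, dxz, dyz = beta[:6]
    D = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
    evals, evecs = np.linalg.eigh(D)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    n_clamped = int(np.sum(evals < 0))
    if n_clamped:
        logger.debug("clamped %d negative eigenvalue(s)", n_clamped)
        evals = np.clip(evals, 0.0, None)
    return TensorVoxel(eigenvalues=evals, eigenvectors=evecs, n_clamped=n_clamped)


def tensor_scalars(eigenvalues: np.ndarray) -> tuple[float, float, float, float]:
    """Return ``(fa, md, rd, ad)`` from a sorted non-negative eigenvalue triple."""
    lam = np.asarray(eigenvalues, dtype=float)
    if lam.shape != (3,):
        raise ValueError("eigenvalues must be a triple")
    if np.any(np.diff(lam) > 1e-15) or np.any(lam < 0):
        raise ValueError("eigenvalues must be sorted descending and non-negative")
    ssq = float(np.sum(lam**2))
    if ssq == 0.0:
        raise ValueError("FA undefined for the all-zero tensor")
    md = float(lam.mean())
    ad = float(lam[0])
    rd = float((lam[1] + lam[2]) / 2.0)
    fa = float(np.sqrt(1.5) * np.sqrt(np.sum((lam - md) ** 2)) / np.sqrt(ssq))
    return min(fa, 1.0), md, rd, ad


def free_water_fraction(
    signals: np.ndarray,
    gtab: GradientTable,
    tissue_d: float | None = 0.7e-3,
    water_d: float = FREE_WATER_DIFFUSIVITY,
    rician_sigma: float | None = None,
) -> float:
    """Free-water signal fraction from shell-averaged signals.

    Fits ``S(b)/S0 = (1 - f) exp(-b d_tissue) + f exp(-b d_water)`` by
    bounded least squares over the shell-averaged attenuations.  With a
    single non-zero shell ``tissue_d`` must be supplied (the pair
    (f, tissue_d) is unidentifiable); with two or more shells passing
    ``tissue_d=None`` co-estimates it.

    When ``rician_sigma`` is given, shell attenuations are computed from
    noise-floor-corrected second moments (RMS of ``M^2 - 2 sigma^2``), a
    simple heuristic for high-b data whose free-water signal sits below
    the noise floor.
    """
    s = np.asarray(signals, dtype=float)
    if s.shape != gtab.bvals.shape:
        raise ValueError("signals must match gradient table length")
    shells = gtab.shells()
    b_arr = np.array(shells)
    if rician_sigma is None:
        s0 = float(s[gtab.b0_mask].mean())
        if s0 <= 0:
            raise ValueError("non-positive mean b=0 signal")
        atten = np.array([s[gtab.bvals == b].mean() / s0 for b in shells])
    else:
        sq = np.clip(s**2 - 2.0 * rician_sigma**2, 0.0, None)
        s0 = float(np.sqrt(sq[gtab.b0_mask].mean()))
        if s0 <= 0:
            raise ValueError("non-positive corrected b=0 signal")
        atten = np.array(
            [np.sqrt(sq[gtab.bvals == b].mean()) / s0 for b in shells]
        )

    if tissue_d is None:
        if len(shells) < 2:
            raise IdentifiabilityError(
                "single-shell data: (f, tissue_d) unidentifiable; supply tissue_d"
            )

        def resid2(theta):
            f, dt = theta
            return (1 - f) * np.exp(-b_arr * dt) + f * np.exp(-b_arr * water_d) - atten

        sol = least_squares(
            resid2, x0=[0.1, 0.7e-3], bounds=([0.0, 1e-5], [1.0, water_d])
        )
        return float(np.clip(sol.x[0], 0.0, 1.0))

    # with tissue_d fixed the model is linear in f: r_b = a_b - f (a_b - c_b);
    # the bounded 1-D least-squares solution is the projected closed form
    a = np.exp(-b_arr * tissue_d)
    c = np.exp(-b_arr * water_d)
    denom = float(np.sum((a - c) ** 2))
    if denom == 0.0:
        raise IdentifiabilityError("tissue_d equals water_d; f unidentifiable")
    f = float(np.sum((a - c) * (a - atten)) / denom)
    return float(np.clip(f, 0.0, 1.0))


def tract_mean_metrics(
    scalar_maps: dict[str, np.ndarray],
    voxel_set,
    mask: np.ndarray | None = None,
    tract_name: str = "",
) -> TractMetrics:
    """Unweighted mean scalar metrics over a tract's voxel set.

    Duplicate voxels are collapsed before averaging; voxels flagged in
    ``mask`` (True = excluded, e.g. free-water contaminated) are dropped
    and counted in ``n_masked``.  ``scalar_maps`` must contain the keys
    ``fa``, ``md``, ``rd`` and ``ad``.
    """
    required = {"fa", "md", "rd", "ad"}
    if not required.issubset(scalar_maps):
        raise ValueError(f"scalar_maps must contain {sorted(required)}")
    shape = scalar_maps["fa"].shape
    unique = sorted({(int(x), int(y), int(z)) for x, y, z in voxel_set})
    for v in unique:
        if any(c < 0 or c >= s for c, s in zip(v, shape)):
            raise IndexError(f"voxel {v} outside map bounds {shape}")
    if mask is not None:
        kept = [v for v in unique if not mask[v]]
    else:
        kept = unique
    n_masked = len(unique) - len(kept)
    if not kept:
        raise EmptyTractError(
            f"tract {tract_name!r}: all {len(unique)} voxels masked"
        )
    idx = tuple(np.array(kept).T)
    return TractMetrics(
        tract_name=tract_name,
        voxel_set=kept,
        mean_fa=float(scalar_maps["fa"][idx].mean()),
        mean_md=float(scalar_maps["md"][idx].mean()),
        mean_rd=float(scalar_maps["rd"][idx].mean()),
        mean_ad=float(scalar_maps["ad"][idx].mean()),
        n_voxels=len(kept),
        n_masked=n_masked,
    )
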