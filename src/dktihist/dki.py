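"""Diffusion kurtosis signal representation: forward model, fit, metrics.

The model represents the diffusion-weighted signal along unit direction
``n`` at b-value ``b`` (s/mm^2) as

    ln S(b, n) = ln S0 - b * D_app(n) + (b^2 / 6) * MD^2 * W_app(n)

with D_app(n) = n_i n_j D_ij the apparent diffusivity of the rank-2
diffusion tensor D (mm^2/s), W_app(n) = n_i n_j n_k n_l W_ijkl the
directional projection of the dimensionless, fully symmetric rank-4
kurtosis tensor W, and MD = tr(D)/3 the mean diffusivity.  The apparent
(directional) kurtosis is K_app(n) = (MD^2 / D_app(n)^2) W_app(n).

Estimation is ordinary linear least squares on log-signals with 22
unknowns: ln S0, the 6 unique elements of D, and the 15 unique elements of
MD^2*W; W is recovered by dividing by the fitted MD^2.  The model is exactly
log-linear, so noiseless signals are recovered to numerical precision.

Scalar metrics (mean/axial/radial diffusivity and kurtosis, FA, KFA) follow
the standard definitions; axial/radial can be referred either to the
principal eigenvector of D (the convention of common kurtosis estimators)
or to a fixed anteroposterior (y) axis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .quadrature import great_circle_directions, sphere_directions

__all__ = [
    "GradientScheme",
    "DiffusionTensor",
    "KurtosisTensor",
    "DkiFit",
    "DktiMetrics",
    "SchemeError",
    "DegenerateTensorError",
    "apparent_diffusion",
    "apparent_kurtosis",
    "forward_signal",
    "design_matrix",
    "fit_dki",
    "fit_dki_array",
    "eigendecompose",
    "diffusion_metrics",
    "kurtosis_metrics",
    "kfa",
    "dkti_metrics",
    "reference_scheme",
]

AXIS_CONVENTIONS = ("principal_eigenvector", "anteroposterior")
ANTEROPOSTERIOR_AXIS = np.array([0.0, 1.0, 0.0])

# Unique-element bookkeeping for symmetric tensors.  Multiplicities count the
# index permutations of each unique element in the full expansion.
DT_INDICES: tuple[tuple[int, int], ...] = ((0, 0), (1, 1), (2, 2), (0, 1), (0, 2), (1, 2))
DT_MULT = np.array([1.0, 1.0, 1.0, 2.0, 2.0, 2.0])

KT_INDICES: tuple[tuple[int, int, int, int], ...] = (
    (0, 0, 0, 0), (1, 1, 1, 1), (2, 2, 2, 2),
    (0, 0, 0, 1), (0, 0, 0, 2), (0, 1, 1, 1), (1, 1, 1, 2), (0, 2, 2, 2), (1, 2, 2, 2),
    (0, 0, 1, 1), (0, 0, 2, 2), (1, 1, 2, 2),
    (0, 0, 1, 2), (0, 1, 1, 2), (0, 1, 2, 2),
)
KT_MULT = np.array([1.0, 1.0, 1.0, 4.0, 4.0, 4.0, 4.0, 4.0, 4.0, 6.0, 6.0, 6.0, 12.0, 12.0, 12.0])


def _build_kt_full_map() -> np.ndarray:
    from itertools import permutations

    m = np.empty((3, 3, 3, 3), dtype=int)
    for u, idx in enumerate(KT_INDICES):
        for perm in set(permutations(idx)):
            m[perm] = u
    return m


_KT_FULL_MAP = _build_kt_full_map()
_KT_I, _KT_J, _KT_K, _KT_L = (np.array(a) for a in zip(*KT_INDICES))


def kt_unique_to_full(ktu: np.ndarray) -> np.ndarray:
    """Expand (..., 15) unique kurtosis elements to the full (..., 3,3,3,3)."""
    return np.asarray(ktu, dtype=float)[..., _KT_FULL_MAP]


def kt_full_to_unique(full: np.ndarray) -> np.ndarray:
    """Extract the (..., 15) unique elements from a full (..., 3,3,3,3) tensor."""
    return np.asarray(full, dtype=float)[..., _KT_I, _KT_J, _KT_K, _KT_L]


#: fitted mean diffusivity (mm^2/s) at or below this is treated as degenerate
MD_DEGENERATE = 1e-9


class SchemeError(ValueError):
    """Gradient table cannot determine the 22 model unknowns."""


class DegenerateTensorError(ValueError):
    """Tensor is degenerate for the requested operation (e.g. D_app <= 0)."""


def _unit_check(n: np.ndarray, tol: float = 1e-6) -> np.ndarray:
    n = np.asarray(n, dtype=float)
    if n.shape != (3,):
        raise ValueError("direction must be a 3-vector")
    if abs(np.linalg.norm(n) - 1.0) > tol:
        raise ValueError(f"direction must have unit norm, got {np.linalg.norm(n):.8f}")
    return n


def quadratic_products(dirs: np.ndarray) -> np.ndarray:
    """(m, 6) products n_i n_j for the unique diffusion-tensor elements."""
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    return np.stack([dirs[:, i] * dirs[:, j] for i, j in DT_INDICES], axis=1)


def quartic_products(dirs: np.ndarray) -> np.ndarray:
    """(m, 15) products n_i n_j n_k n_l for the unique kurtosis-tensor elements."""
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    return np.stack(
        [dirs[:, i] * dirs[:, j] * dirs[:, k] * dirs[:, l] for i, j, k, l in KT_INDICES],
        axis=1,
    )


@dataclass(frozen=True)
class GradientScheme:
    """Acquisition table: one (b-value, unit direction) pair per measurement.

    b-values in s/mm^2; the direction of a b=0 measurement may be the zero
    vector.  At least two distinct nonzero shells and 15 distinct nonzero-b
    directions are required so the 22 model unknowns are identifiable.
    """

    bvalues: np.ndarray
    directions: np.ndarray

    def __post_init__(self) -> None:
        b = np.asarray(self.bvalues, dtype=float).ravel()
        d = np.asarray(self.directions, dtype=float)
        if d.shape != (b.size, 3):
            raise SchemeError("directions must be (n_measurements, 3)")
        if np.any(b < 0):
            raise SchemeError("b-values must be non-negative")
        norms = np.linalg.norm(d, axis=1)
        nonzero = b > 0
        bad = nonzero & (np.abs(norms - 1.0) > 1e-6)
        if np.any(bad):
            col = int(np.flatnonzero(bad)[0])
            raise SchemeError(
                f"direction in column {col} has norm {norms[col]:.6f}, expected 1"
            )
        if np.unique(np.round(b[nonzero], 6)).size < 2:
            raise SchemeError("at least 2 distinct nonzero b-values required")
        uniq_dirs = np.unique(np.round(d[nonzero], 6), axis=0)
        if uniq_dirs.shape[0] < 15:
            raise SchemeError("at least 15 distinct nonzero-b directions required")
        object.__setattr__(self, "bvalues", b)
        object.__setattr__(self, "directions", d)

    def __len__(self) -> int:
        return self.bvalues.size

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvalues == 0

    @property
    def shells(self) -> np.ndarray:
        """Sorted distinct nonzero b-values."""
        return np.unique(self.bvalues[self.bvalues > 0])


class DiffusionTensor:
    """Symmetric rank-2 diffusion tensor (mm^2/s)."""

    __slots__ = ("matrix",)

    def __init__(self, matrix: np.ndarray):
        m = np.asarray(matrix, dtype=float)
        if m.shape != (3, 3):
            raise ValueError("diffusion tensor must be 3x3")
        if not np.allclose(m, m.T, atol=1e-12 + 1e-8 * np.abs(m).max(initial=0.0)):
            raise ValueError("diffusion tensor must be symmetric")
        self.matrix = 0.5 * (m + m.T)

    @classmethod
    def from_unique(cls, vec6: np.ndarray) -> "DiffusionTensor":
        """Build from [D11, D22, D33, D12, D13, D23]."""
        v = np.asarray(vec6, dtype=float).ravel()
        if v.size != 6:
            raise ValueError("expected 6 unique elements")
        m = np.empty((3, 3))
        for val, (i, j) in zip(v, DT_INDICES):
            m[i, j] = m[j, i] = val
        return cls(m)

    @property
    def unique(self) -> np.ndarray:
        return np.array([self.matrix[i, j] for i, j in DT_INDICES])

    @property
    def md(self) -> float:
        """Mean diffusivity, tr(D)/3."""
        return float(np.trace(self.matrix)) / 3.0

    def rotated(self, rot: np.ndarray) -> "DiffusionTensor":
        rot = np.asarray(rot, dtype=float)
        return DiffusionTensor(rot @ self.matrix @ rot.T)

    def __repr__(self) -> str:  # pragma: no cover
        return f"DiffusionTensor(md={self.md:.3e})"


class KurtosisTensor:
    """Fully symmetric rank-4 kurtosis tensor (dimensionless)."""

    __slots__ = ("tensor",)

    def __init__(self, tensor: np.ndarray):
        t = np.asarray(tensor, dtype=float)
        if t.shape != (3, 3, 3, 3):
            raise ValueError("kurtosis tensor must be 3x3x3x3")
        if not np.all(np.isfinite(t)):
            raise ValueError("kurtosis tensor must be finite")
        scale = np.abs(t).max(initial=0.0)
        for perm in ((1, 0, 2, 3), (0, 1, 3, 2), (2, 3, 0, 1), (0, 2, 1, 3)):
            if not np.allclose(t, np.transpose(t, perm), atol=1e-12 + 1e-8 * scale):
                raise ValueError("kurtosis tensor must be symmetric under index permutation")
        self.tensor = t

    @classmethod
    def from_unique(cls, vec15: np.ndarray) -> "KurtosisTensor":
        """Build from the 15 unique elements ordered as ``KT_INDICES``."""
        v = np.asarray(vec15, dtype=float).ravel()
        if v.size != 15:
            raise ValueError("expected 15 unique elements")
        t = np.zeros((3, 3, 3, 3))
        from itertools import permutations

        for val, idx in zip(v, KT_INDICES):
            for perm in set(permutations(idx)):
                t[perm] = val
        return cls(t)

    @classmethod
    def zero(cls) -> "KurtosisTensor":
        return cls(np.zeros((3, 3, 3, 3)))

    @property
    def unique(self) -> np.ndarray:
        return np.array([self.tensor[idx] for idx in KT_INDICES])

    @property
    def frobenius_norm(self) -> float:
        return float(np.sqrt(np.sum(self.tensor**2)))

    def rotated(self, rot: np.ndarray) -> "KurtosisTensor":
        rot = np.asarray(rot, dtype=float)
        return KurtosisTensor(np.einsum("ia,jb,kc,ld,abcd->ijkl", rot, rot, rot, rot, self.tensor))

    def __repr__(self) -> str:  # pragma: no cover
        return f"KurtosisTensor(|W|={self.frobenius_norm:.3e})"


@dataclass
class DkiFit:
    """Result of a single-voxel fit."""

    s0: float
    dt: DiffusionTensor
    kt: KurtosisTensor
    residual_norm: float
    valid: bool = True

    def __post_init__(self) -> None:
        if self.valid and self.s0 <= 0:
            raise ValueError("fitted S0 must be positive")
        if self.residual_norm < 0:
            raise ValueError("residual norm must be non-negative")


@dataclass
class DktiMetrics:
    """The eight scalar metrics per voxel (diffusivities in mm^2/s)."""

    d_mean: float
    d_axial: float
    d_radial: float
    fa: float
    k_mean: float
    k_axial: float
    k_radial: float
    kfa: float
    valid: bool = True

    _NAMES = ("d_mean", "d_axial", "d_radial", "fa", "k_mean", "k_axial", "k_radial", "kfa")

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in self._NAMES}


def apparent_diffusion(dt: DiffusionTensor, n: np.ndarray) -> float:
    """Projected diffusivity D_app(n) = n_i n_j D_ij (mm^2/s)."""
    n = _unit_check(n)
    return float(n @ dt.matrix @ n)


def apparent_kurtosis(dt: DiffusionTensor, kt: KurtosisTensor, n: np.ndarray) -> float:
    """Directional kurtosis K_app(n) = (MD^2 / D_app(n)^2) W_app(n)."""
    n = _unit_check(n)
    d_app = float(n @ dt.matrix @ n)
    if d_app <= 0:
        raise DegenerateTensorError("apparent diffusivity is non-positive along n")
    w_app = float((quartic_products(n) @ (kt.unique * KT_MULT))[0])
    return dt.md**2 / d_app**2 * w_app


def forward_signal(
    s0: float, dt: DiffusionTensor, kt: KurtosisTensor, scheme: GradientScheme
) -> np.ndarray:
    """Noiseless signal for every (b, n) measurement of the scheme."""
    if s0 <= 0:
        raise ValueError("S0 must be positive")
    b = scheme.bvalues
    d_app = quadratic_products(scheme.directions) @ (dt.unique * DT_MULT)
    w_app = quartic_products(scheme.directions) @ (kt.unique * KT_MULT)
    # s0 factored out so that b = 0 returns s0 exactly
    return s0 * np.exp(-b * d_app + (b**2 / 6.0) * dt.md**2 * w_app)


def design_matrix(scheme: GradientScheme) -> np.ndarray:
    """(m, 22) log-linear design: [1, -b q_D(n), (b^2/6) q_W(n)].

    Columns 1..6 multiply the unique diffusion-tensor elements, columns
    7..21 the unique elements of MD^2 * W (multiplicities folded in).
    """
    b = scheme.bvalues[:, None]
    a_d = -b * quadratic_products(scheme.directions) * DT_MULT
    a_w = (b**2 / 6.0) * quartic_products(scheme.directions) * KT_MULT
    return np.hstack([np.ones((len(scheme), 1)), a_d, a_w])


def fit_dki_array(
    signals: np.ndarray, scheme: GradientScheme
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised unconstrained fit of many voxels at once.

    Parameters
    ----------
    signals : (m, N) array, strictly positive where valid.

    Returns
    -------
    s0 : (N,), dt_unique : (N, 6), kt_unique : (N, 15), residual : (N,),
    valid : (N,) bool.  Invalid voxels (non-positive signal or fitted
    MD <= 0) carry NaN parameters, never silent zeros.
    """
    signals = np.asarray(signals, dtype=float)
    if signals.ndim == 1:
        signals = signals[:, None]
    if signals.shape[0] != len(scheme):
        raise ValueError("signal axis length does not match the gradient scheme")
    a = design_matrix(scheme)
    rank = np.linalg.matrix_rank(a)
    if rank < a.shape[1]:
        raise SchemeError(f"design matrix rank {rank} < 22; scheme is unidentifiable")

    n_vox = signals.shape[1]
    s0 = np.full(n_vox, np.nan)
    dtu = np.full((n_vox, 6), np.nan)
    ktu = np.full((n_vox, 15), np.nan)
    resid = np.full(n_vox, np.nan)
    valid = np.all(signals > 0, axis=0) & np.all(np.isfinite(signals), axis=0)
    if np.any(valid):
        log_s = np.log(signals[:, valid])
        beta, *_ = np.linalg.lstsq(a, log_s, rcond=None)
        res = np.linalg.norm(a @ beta - log_s, axis=0)
        s0_v = np.exp(beta[0])
        dtu_v = beta[1:7].T
        md = dtu_v[:, :3].mean(axis=1)
        # MD below any physiological scale (~1e-5 mm^2/s even for solids)
        # means the voxel carries no diffusion signal; W = X / MD^2 would
        # blow up, so such voxels are flagged instead
        ok = md > MD_DEGENERATE
        ktu_v = np.full((ok.size, 15), np.nan)
        ktu_v[ok] = beta[7:, ok].T / md[ok, None] ** 2
        idx = np.flatnonzero(valid)
        s0[idx] = s0_v
        dtu[idx] = dtu_v
        resid[idx] = res
        ktu[idx] = ktu_v
        valid[idx[~ok]] = False
    return s0, dtu, ktu, resid, valid


def fit_dki(signals: np.ndarray, scheme: GradientScheme) -> DkiFit:
    """Fit a single voxel; see :func:`fit_dki_array` for the estimator."""
    signals = np.asarray(signals, dtype=float).ravel()
    if np.any(signals <= 0) or not np.all(np.isfinite(signals)):
        raise ValueError("signals must be positive and finite")
    s0, dtu, ktu, resid, valid = fit_dki_array(signals[:, None], scheme)
    if not valid[0]:
        # fitted MD <= 0: unphysical voxel, flagged rather than zero-filled
        return DkiFit(
            s0=float(s0[0]),
            dt=DiffusionTensor.from_unique(np.nan_to_num(dtu[0])),
            kt=KurtosisTensor.zero(),
            residual_norm=float(resid[0]),
            valid=False,
        )
    return DkiFit(
        s0=float(s0[0]),
        dt=DiffusionTensor.from_unique(dtu[0]),
        kt=KurtosisTensor.from_unique(ktu[0]),
        residual_norm=float(resid[0]),
        valid=True,
    )


def eigendecompose(dt: DiffusionTensor) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvalues sorted descending and matching orthonormal eigenvectors.

    Returns ``(lam, vecs)`` with ``vecs[:, i]`` the eigenvector of
    ``lam[i]`` and ``sum_i lam[i] v_i v_i^T == dt.matrix``.
    """
    lam, vecs = np.linalg.eigh(dt.matrix)
    order = np.argsort(lam)[::-1]
    return lam[order], vecs[:, order]


def _fa_from_eigenvalues(lam: np.ndarray) -> float:
    sq = float(np.sum(lam**2))
    if sq == 0:
        return 0.0  # all-zero tensor: FA defined as 0
    dev = lam - lam.mean()
    return float(np.sqrt(1.5 * np.sum(dev**2) / sq))


def diffusion_metrics(
    dt: DiffusionTensor, axis_convention: str = "principal_eigenvector"
) -> tuple[float, float, float, float]:
    """(d_mean, d_axial, d_radial, fa) under the requested axis convention.

    ``principal_eigenvector``: axial = lambda_1, radial = (lambda_2 +
    lambda_3)/2.  ``anteroposterior``: axial = D_app(y-axis), radial = mean
    of D_app over the great circle perpendicular to y.
    """
    if axis_convention not in AXIS_CONVENTIONS:
        raise ValueError(f"unknown axis convention {axis_convention!r}")
    lam, _ = eigendecompose(dt)
    d_mean = float(lam.mean())
    fa = _fa_from_eigenvalues(lam)
    if axis_convention == "principal_eigenvector":
        d_axial = float(lam[0])
        d_radial = float((lam[1] + lam[2]) / 2.0)
    else:
        axis = ANTEROPOSTERIOR_AXIS
        d_axial = float(axis @ dt.matrix @ axis)
        circ = great_circle_directions(axis, 64)
        d_radial = float(np.mean(np.einsum("ci,ij,cj->c", circ, dt.matrix, circ)))
    return d_mean, d_axial, d_radial, fa


def kurtosis_metrics(
    dt: DiffusionTensor,
    kt: KurtosisTensor,
    axis_convention: str = "principal_eigenvector",
    sphere: np.ndarray | None = None,
    n_circle: int = 64,
) -> tuple[float, float, float]:
    """(k_mean, k_axial, k_radial) by spherical / great-circle quadrature.

    k_mean averages K_app over a near-uniform sphere set (>= 60 directions
    required), k_axial evaluates K_app along the reference axis, k_radial
    averages K_app over ``n_circle`` directions on the perpendicular great
    circle.
    """
    if axis_convention not in AXIS_CONVENTIONS:
        raise ValueError(f"unknown axis convention {axis_convention!r}")
    if sphere is None:
        sphere = sphere_directions(250)
    sphere = np.asarray(sphere, dtype=float)
    if sphere.shape[0] < 60:
        raise ValueError("spherical quadrature needs at least 60 directions")

    md = dt.md
    if md <= 0:
        raise DegenerateTensorError("mean diffusivity is non-positive")

    # All quadrature directions are expressed in the eigenframe of D, which
    # makes every metric exactly equivariant under a joint rotation of
    # (D, W) — the quadrature error depends only on tensor shape, not pose.
    lam, vecs = eigendecompose(dt)
    ktf = kt.rotated(vecs.T)
    ktu_w = ktf.unique * KT_MULT

    def k_app(dirs: np.ndarray) -> np.ndarray:
        d_app = dirs**2 @ lam
        if np.any(d_app <= 0):
            raise DegenerateTensorError("apparent diffusivity non-positive on quadrature set")
        w_app = quartic_products(dirs) @ ktu_w
        return md**2 / d_app**2 * w_app

    k_mean = float(np.mean(k_app(sphere)))
    if axis_convention == "principal_eigenvector":
        axis_f = np.array([1.0, 0.0, 0.0])
        circle_f = great_circle_directions(axis_f, n_circle)
    else:
        axis_f = vecs.T @ ANTEROPOSTERIOR_AXIS
        circle_f = great_circle_directions(ANTEROPOSTERIOR_AXIS, n_circle) @ vecs
    k_axial = float(k_app(axis_f[None, :])[0])
    k_radial = float(np.mean(k_app(circle_f)))
    return k_mean, k_axial, k_radial


# unique elements of the isotropic rank-4 tensor I4_ijkl = (d_ij d_kl + d_ik d_jl + d_il d_jk)/3
_ISO4_UNIQUE = np.array([1.0, 1.0, 1.0, 0, 0, 0, 0, 0, 0, 1 / 3, 1 / 3, 1 / 3, 0, 0, 0])


def kfa(kt: KurtosisTensor) -> float:
    """Kurtosis fractional anisotropy in [0, 1].

    KFA = ||W - Wbar * I4||_F / ||W||_F where Wbar = (1/5)(W1111 + W2222 +
    W3333 + 2 W1122 + 2 W1133 + 2 W2233) is the orthogonal projection of W
    onto the isotropic rank-4 tensor I4, and the Frobenius norms run over
    the full 81-element expansion.  The zero tensor maps to 0.
    """
    u = kt.unique
    norm_sq = float(np.sum(KT_MULT * u**2))
    if norm_sq == 0:
        return 0.0
    wbar = (u[0] + u[1] + u[2] + 2.0 * (u[9] + u[10] + u[11])) / 5.0
    diff = u - wbar * _ISO4_UNIQUE
    val = np.sqrt(float(np.sum(KT_MULT * diff**2)) / norm_sq)
    return float(np.clip(val, 0.0, 1.0))


def dkti_metrics(
    fit: DkiFit,
    axis_convention: str = "principal_eigenvector",
    sphere: np.ndarray | None = None,
) -> DktiMetrics:
    """All eight scalar metrics from a voxel fit; NaNs for invalid voxels."""
    if not fit.valid:
        nan = float("nan")
        return DktiMetrics(nan, nan, nan, nan, nan, nan, nan, nan, valid=False)
    d_mean, d_axial, d_radial, fa = diffusion_metrics(fit.dt, axis_convention)
    k_mean, k_axial, k_radial = kurtosis_metrics(fit.dt, fit.kt, axis_convention, sphere)
    return DktiMetrics(d_mean, d_axial, d_radial, fa, k_mean, k_axial, k_radial, kfa(fit.kt))


def reference_scheme(
    n_directions: int = 30, shells: tuple[float, ...] = (100.0, 1000.0, 2000.0), n_b0: int = 1
) -> GradientScheme:
    """The acquisition protocol emulated throughout: 30 directions at each of
    b = 100, 1000, 2000 s/mm^2 plus a b = 0 measurement."""
    from .quadrature import hemisphere_directions as _hemi

    hemisphere = _hemi(n_directions)
    bvals = [0.0] * n_b0
    dirs = [np.zeros(3)] * n_b0
    for b in shells:
        bvals.extend([b] * n_directions)
        dirs.extend(hemisphere)
    return GradientScheme(np.array(bvals), np.array(dirs))
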