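"""Local displacement correlator, PCP eigen-spectrum, gap and MP comparison.

The correlator C = <Delta Delta^T> over frames, projected into the
non-affine subspace as PCP, carries the local soft-mode structure: its
eigenvalues lambda_mu sum to the time-averaged chi, and a large gap
Gamma = 1 - lambda_2/lambda_1 between the top eigenvalue and the rest
marks a site dominated by a single soft non-affine mode.  The empirical
spectrum is compared against the Marchenko-Pastur law, the eigenvalue
density a featureless random displacement ensemble would produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .neighborhoods import D, Neighborhood

logger = logging.getLogger(__name__)

#: eigenvalues below ZERO_TOL * lambda_max count as the annihilated affine block
ZERO_TOL = 1e-9
#: relative top-pair separation below which the dominant mode is degenerate
DEGENERACY_TOL = 1e-6


@dataclass
class DisplacementCorrelator:
    """Ensemble-averaged second moment of Delta (symmetric PSD)."""

    C: np.ndarray
    n_frames: int
    mean_subtracted: bool = False


@dataclass
class NapSpectrum:
    """Eigen-decomposition of PCP, descending, with the normalized gap."""

    eigenvalues: np.ndarray          # descending, A^2
    eigenvectors: np.ndarray         # columns match eigenvalues
    normalized_eigenvalues: np.ndarray
    gap: float                       # 1 - lambda_2/lambda_1 on the normalized scale
    gap_absolute: float              # lambda_1 - lambda_2 (A^2)
    n_zero: int                      # eigenvalues below tolerance (>= 9 for PCP)
    degenerate_top: bool = False
    affine_dim: int = 0              # structurally annihilated dimensions (9 for PCP)

    @property
    def total(self) -> float:
        """Sum of eigenvalues = time-averaged chi (trace identity)."""
        return float(self.eigenvalues.sum())


@dataclass
class MPFit:
    """Moment-matched Marchenko-Pastur fit to the non-zero spectrum."""

    sigma2: float
    q: float                         # matrix dimension / n_frames
    lambda_minus: float
    lambda_plus: float
    ks_stat: float
    outlier_indices: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    point_mass_warning: bool = False


def correlator(deltas: np.ndarray, mean_subtract: bool = False) -> DisplacementCorrelator:
    """C = (1/T) sum_t Delta_t Delta_t^T from a (T, m) displacement matrix.

    No mean subtraction by default: chi is defined about the fixed
    reference, and keeping C reference-based makes the trace identity
    sum(lambda) = <chi> exact.  ``mean_subtract=True`` is for drifted
    ensembles where the reference no longer matches the ensemble mean.
    """
    deltas = np.asarray(deltas, dtype=float)
    if deltas.ndim != 2:
        raise ValueError("deltas must be a (T, m) matrix")
    T = deltas.shape[0]
    if T < 2:
        raise ValueError(f"need at least 2 frames to form a correlator, got {T}")
    if mean_subtract:
        deltas = deltas - deltas.mean(axis=0)
    C = deltas.T @ deltas / T
    C = 0.5 * (C + C.T)
    return DisplacementCorrelator(C=C, n_frames=T, mean_subtracted=mean_subtract)


def _sorted_eigh(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    values, vectors = np.linalg.eigh(S)
    order = np.argsort(values)[::-1]
    values = values[order]
    vectors = vectors[:, order]
    # deterministic sign: largest-magnitude component of each vector positive
    for k in range(vectors.shape[1]):
        j = int(np.argmax(np.abs(vectors[:, k])))
        if vectors[j, k] < 0:
            vectors[:, k] = -vectors[:, k]
    return values, vectors


def _make_spectrum(
    values: np.ndarray, vectors: np.ndarray, affine_dim: int = 0
) -> NapSpectrum:
    lam_max = values[0] if values[0] > 0 else 0.0
    if lam_max > 0:
        normalized = values / lam_max
        gap = float(1.0 - values[1] / values[0]) if len(values) > 1 else 1.0
        gap_abs = float(values[0] - values[1]) if len(values) > 1 else float(values[0])
        degenerate = len(values) > 1 and (values[0] - values[1]) < DEGENERACY_TOL * values[0]
    else:
        normalized = np.zeros_like(values)
        gap, gap_abs, degenerate = 0.0, 0.0, True
    n_zero = int(np.sum(values < ZERO_TOL * max(lam_max, 1e-300)))
    return NapSpectrum(
        eigenvalues=values,
        eigenvectors=vectors,
        normalized_eigenvalues=normalized,
        gap=gap,
        gap_absolute=gap_abs,
        n_zero=n_zero,
        degenerate_top=degenerate,
        affine_dim=affine_dim,
    )


def pcp_spectrum(proj, corr: DisplacementCorrelator) -> NapSpectrum:
    """Full symmetric eigen-decomposition of P C P, descending.

    The 9 affine directions are annihilated exactly, so at least d^2
    eigenvalues vanish to numerical precision.
    """
    P = proj.P
    C = corr.C
    if P.shape != C.shape:
        raise ValueError(f"dimension mismatch: P is {P.shape}, C is {C.shape}")
    asym = np.max(np.abs(C - C.T))
    if asym > 1e-8 * max(1.0, float(np.max(np.abs(C)))):
        raise ValueError(f"correlator is not symmetric (max asymmetry {asym:g})")
    S = P @ C @ P
    S = 0.5 * (S + S.T)
    values, vectors = _sorted_eigh(S)
    if values[-1] < -1e-10 * max(values[0], 1.0):
        raise ValueError("PCP has a significantly negative eigenvalue; C is not PSD")
    np.clip(values, 0.0, None, out=values)
    return _make_spectrum(values, vectors, affine_dim=D * D)


def spectrum_from_matrix(C: np.ndarray) -> NapSpectrum:
    """Spectrum of a bare symmetric PSD matrix (no projection).

    Used for the random-correlation-matrix comparison, where the
    Marchenko-Pastur law is fitted to an unprojected Wishart spectrum.
    """
    C = np.asarray(C, dtype=float)
    values, vectors = _sorted_eigh(0.5 * (C + C.T))
    np.clip(values, 0.0, None, out=values)
    return _make_spectrum(values, vectors)


def dominant_mode(spec: NapSpectrum, nb: Neighborhood) -> np.ndarray:
    """Top eigenvector unstacked to a per-member (n_omega, 3) displacement field.

    The sign is fixed so the largest-magnitude component is positive.  A
    quasi-degenerate top pair makes the returned direction arbitrary within
    the degenerate plane; the spectrum's ``degenerate_top`` flag records it.
    """
    if spec.eigenvalues[0] <= 0:
        raise ValueError("top eigenvalue is zero: no dominant mode")
    if spec.degenerate_top:
        logger.warning(
            "top eigenvalue pair of atom %d is quasi-degenerate; the dominant "
            "mode is defined only up to a rotation in the degenerate plane",
            nb.center_index,
        )
    mode = spec.eigenvectors[:, 0]
    if mode.shape[0] != nb.dof:
        raise ValueError(
            f"spectrum dimension {mode.shape[0]} does not match neighborhood "
            f"dof {nb.dof}"
        )
    return mode.reshape(nb.n_members, D)


# ---------------------------------------------------------------------------
# Marchenko-Pastur comparison
# ---------------------------------------------------------------------------

def mp_support(sigma2: float, q: float) -> tuple[float, float]:
    """Support edges sigma^2 (1 -+ sqrt(q))^2 of the MP density."""
    sq = np.sqrt(q)
    return sigma2 * (1 - sq) ** 2, sigma2 * (1 + sq) ** 2


def mp_cdf(x: np.ndarray, sigma2: float, q: float, grid_size: int = 4096) -> np.ndarray:
    """CDF of the Marchenko-Pastur law (continuous part, renormalized).

    For q < 1 the law is absolutely continuous on [lambda-, lambda+]; the
    density sqrt((l+ - x)(x - l-)) / (2 pi sigma^2 q x) is integrated on a
    fine grid and normalized to remove discretization error.  For q >= 1
    the point mass at zero is included with weight 1 - 1/q.
    """
    lam_minus, lam_plus = mp_support(sigma2, q)
    grid = np.linspace(lam_minus, lam_plus, grid_size)
    with np.errstate(invalid="ignore", divide="ignore"):
        dens = np.sqrt(np.clip((lam_plus - grid) * (grid - lam_minus), 0, None)) / (
            2 * np.pi * sigma2 * q * np.maximum(grid, 1e-300)
        )
    cum = np.concatenate([[0.0], np.cumsum((dens[1:] + dens[:-1]) * 0.5 * np.diff(grid))])
    cum /= cum[-1]
    x = np.asarray(x, dtype=float)
    cont = np.interp(x, grid, cum, left=0.0, right=1.0)
    if q > 1:
        w0 = 1 - 1 / q
        return np.where(x >= 0, w0 + (1 - w0) * cont, 0.0)
    return cont


def mp_fit(spec: NapSpectrum, n_frames: int) -> MPFit:
    """Moment-matched MP fit to the non-zero eigenvalues of a spectrum.

    sigma^2 is the mean non-zero eigenvalue (the MP mean), q the ratio of
    retained dimensions to frames.  ks_stat is the Kolmogorov-Smirnov
    distance between the empirical CDF of the non-zero eigenvalues and the
    fitted MP CDF; eigenvalues outside [lambda-, lambda+] are flagged as
    outliers (structured soft modes standing out of the random background).
    """
    values = spec.eigenvalues
    nonzero_mask = values > ZERO_TOL * max(values[0], 1e-300)
    nonzero = values[nonzero_mask]
    if len(nonzero) < 10:
        raise ValueError(f"need >= 10 non-zero eigenvalues for an MP fit, got {len(nonzero)}")
    # ambient dimension: everything except the structurally annihilated
    # affine block.  With fewer frames than dimensions the sample
    # correlator is rank-deficient and the MP law (q > 1) carries a
    # matching point mass at zero.
    ambient = len(values) - spec.affine_dim
    bulk = values[:ambient]  # descending; rank-deficiency zeros included
    q = ambient / n_frames
    sigma2 = float(bulk.mean())
    lam_minus, lam_plus = mp_support(sigma2, q)
    point_mass = q >= 1
    if point_mass:
        logger.warning("q = %.3g >= 1: MP law has a point mass at zero", q)
    sorted_vals = np.sort(bulk)
    n = len(sorted_vals)
    F = mp_cdf(sorted_vals, sigma2, q)
    emp_hi = np.arange(1, n + 1) / n
    emp_lo = np.arange(0, n) / n
    ks = float(np.max(np.maximum(np.abs(emp_hi - F), np.abs(emp_lo - F))))
    tol = 1e-9 * max(lam_plus, 1.0)
    outliers = np.nonzero(
        nonzero_mask & ((values > lam_plus + tol) | (values < lam_minus - tol))
    )[0]
    return MPFit(
        sigma2=sigma2,
        q=q,
        lambda_minus=lam_minus,
        lambda_plus=lam_plus,
        ks_stat=ks,
        outlier_indices=outliers,
        point_mass_warning=point_mass,
    )
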