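"""Fiber orientation distributions by constrained spherical deconvolution.

The FOD is expanded in a real, symmetric (even-order) spherical-harmonic basis
with descoteaux-style index ordering: coefficients run over degrees
l = 0, 2, ..., L_max and orders m = -l..l, giving (L_max+1)(L_max+2)/2
coefficients (28 at the default L_max = 6).

The single-fiber response function is estimated by recursive calibration:
starting from a nearly isotropic ("fat") tensor profile, candidate voxels are
deconvolved, voxels whose second FOD peak is more than a fixed fraction of the
first are discarded, and the response is re-estimated as the zonal (m = 0)
profile of the surviving voxels' signals aligned to their principal peak,
until the selected set stabilizes.

Deconvolution follows the iterative non-negativity-constrained scheme: FOD
amplitudes are evaluated on a fixed constraint sphere and amplitudes below a
small threshold tau are penalized with weight lambda until the active set
stabilizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import sph_harm_y

from ._sphere import fibonacci_hemisphere, fibonacci_sphere
from .formats_io import BinaryMask, DWIDataset, ValidationError, VolumeGrid

logger = logging.getLogger(__name__)

DEFAULT_L_MAX = 6
#: non-negativity constraint sphere size, regularization weight, threshold factor
N_CONSTRAINT_DIRS = 300
CSD_LAMBDA = 1.0
CSD_TAU = 0.1
CSD_MAX_ITER = 50
#: recursive calibration: single-fiber peak-ratio cutoff and iteration cap
RESPONSE_RATIO_SF = 0.1
RESPONSE_MAX_ITER = 10
#: peak extraction defaults
N_SEARCH_DIRS = 724
PEAK_REFINE_STEPS = 10
DEFAULT_MIN_SEPARATION = 25.0
DEFAULT_MAX_PEAKS = 3


class CalibrationError(RuntimeError):
    """Recursive response calibration failed (no single-fiber voxels survive)."""


# ---------------------------------------------------------------------------
# spherical harmonic basis
# ---------------------------------------------------------------------------


def sh_degrees_orders(l_max: int) -> tuple[np.ndarray, np.ndarray]:
    """Degree and order of each coefficient for even-order real SH up to l_max."""
    degrees, orders = [], []
    for l in range(0, l_max + 1, 2):
        for m in range(-l, l + 1):
            degrees.append(l)
            orders.append(m)
    return np.asarray(degrees), np.asarray(orders)


def build_sh_basis(l_max: int, dirs: np.ndarray) -> np.ndarray:
    """Evaluation matrix of the real symmetric SH basis at unit directions.

    Row i holds the basis values at ``dirs[i]``. Real basis from the complex
    SH ``Y_l^m``: ``sqrt(2) (-1)^m Im(Y_l^|m|)`` for m < 0, ``Y_l^0`` for
    m = 0, ``sqrt(2) (-1)^m Re(Y_l^m)`` for m > 0. Only even degrees are used,
    so every basis function is antipodally symmetric.
    """
    if l_max < 0 or l_max % 2 != 0:
        raise ValidationError("L_max must be an even non-negative integer")
    dirs = np.atleast_2d(np.asarray(dirs, dtype=float))
    x, y, z = dirs[:, 0], dirs[:, 1], dirs[:, 2]
    theta = np.arccos(np.clip(z, -1.0, 1.0))
    phi = np.arctan2(y, x)
    degrees, orders = sh_degrees_orders(l_max)
    # sph_harm_y is a ufunc: one broadcast call over all (l, |m|) x points
    ylm = sph_harm_y(
        degrees[:, None], np.abs(orders)[:, None], theta[None, :], phi[None, :]
    )
    sign = np.where(orders % 2 == 0, 1.0, -1.0)[:, None]
    out = np.where(
        orders[:, None] < 0,
        np.sqrt(2.0) * sign * ylm.imag,
        np.where(orders[:, None] == 0, ylm.real, np.sqrt(2.0) * sign * ylm.real),
    )
    return np.ascontiguousarray(out.T)


@dataclass(frozen=True)
class SphericalHarmonicBasis:
    """Even-order real SH basis of a fixed maximum degree."""

    l_max: int = DEFAULT_L_MAX

    def __post_init__(self):
        if self.l_max < 0 or self.l_max % 2 != 0:
            raise ValidationError("L_max must be an even non-negative integer")

    @property
    def n_coeffs(self) -> int:
        return (self.l_max + 1) * (self.l_max + 2) // 2

    @property
    def degrees(self) -> np.ndarray:
        return sh_degrees_orders(self.l_max)[0]

    def matrix(self, dirs: np.ndarray) -> np.ndarray:
        return build_sh_basis(self.l_max, dirs)


# ---------------------------------------------------------------------------
# response function
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseFunction:
    """Zonal (m = 0) SH coefficients of the axis-aligned single-fiber signal."""

    zonal_coeffs: np.ndarray  # (l_max/2 + 1,), degrees 0, 2, ..., l_max
    l_max: int

    def __post_init__(self):
        zc = np.asarray(self.zonal_coeffs, dtype=float)
        if len(zc) != self.l_max // 2 + 1:
            raise ValidationError("zonal coefficient count must be l_max/2 + 1")
        if zc[0] <= 0:
            raise ValidationError("order-0 response coefficient must be positive")
        zc = zc.copy()
        zc.setflags(write=False)
        object.__setattr__(self, "zonal_coeffs", zc)

    def rotational_harmonics(self, degrees: np.ndarray) -> np.ndarray:
        """Per-coefficient convolution factors ``sqrt(4 pi / (2l+1)) r_l``.

        Spherical convolution of an FOD with an axially symmetric kernel
        multiplies each SH coefficient of degree l by this factor.
        """
        r_of_l = {2 * i: c for i, c in enumerate(self.zonal_coeffs)}
        return np.array(
            [np.sqrt(4 * np.pi / (2 * l + 1)) * r_of_l[int(l)] for l in degrees]
        )

    def signal(self, cos_theta: np.ndarray) -> np.ndarray:
        """Response signal profile at polar angles theta from the fiber axis."""
        from scipy.special import eval_legendre

        x = np.asarray(cos_theta, dtype=float)
        out = np.zeros_like(x)
        for i, c in enumerate(self.zonal_coeffs):
            l = 2 * i
            out += c * np.sqrt((2 * l + 1) / (4 * np.pi)) * eval_legendre(l, x)
        return out


def zonal_fit(cos_theta: np.ndarray, values: np.ndarray, l_max: int) -> np.ndarray:
    """Least-squares zonal SH coefficients (degrees 0..l_max even) of a profile."""
    from scipy.special import eval_legendre

    x = np.asarray(cos_theta, dtype=float)
    cols = [
        np.sqrt((2 * l + 1) / (4 * np.pi)) * eval_legendre(l, x)
        for l in range(0, l_max + 1, 2)
    ]
    design = np.column_stack(cols)
    coeffs, *_ = np.linalg.lstsq(design, np.asarray(values, dtype=float), rcond=None)
    return coeffs


def response_from_tensor(
    gradients_bvals: np.ndarray,
    lambda_parallel: float,
    lambda_perp: float,
    l_max: int = DEFAULT_L_MAX,
) -> ResponseFunction:
    """Response of an axially symmetric tensor at the acquisition's b-value.

    Evaluated on a dense set of polar angles and projected onto the zonal
    basis. Signal is S0-normalized (S0 = 1).
    """
    b = float(np.max(gradients_bvals))
    x = np.cos(np.linspace(0.0, np.pi, 512))
    prof = np.exp(-b * (lambda_perp + (lambda_parallel - lambda_perp) * x**2))
    return ResponseFunction(zonal_coeffs=zonal_fit(x, prof, l_max), l_max=l_max)


#: "fat" (nearly isotropic, FA ~ 0.1) tensor used to start recursive calibration
FAT_LAMBDA_PARALLEL = 0.78e-3
FAT_LAMBDA_PERP = 0.66e-3


# ---------------------------------------------------------------------------
# constrained spherical deconvolution
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FODField:
    """Per-voxel SH coefficients of the FOD on a grid."""

    coeffs: np.ndarray  # (X, Y, Z, n_coeffs); zero outside the mask
    basis: SphericalHarmonicBasis
    grid: VolumeGrid

    def __post_init__(self):
        if self.coeffs.shape[:3] != self.grid.dims:
            raise ValidationError("FOD coefficient volume does not match grid dims")
        if self.coeffs.shape[3] != self.basis.n_coeffs:
            raise ValidationError("FOD coefficient count does not match basis")


def _csd_single_voxel(
    signal: np.ndarray,
    forward: np.ndarray,
    b_constraint: np.ndarray,
    init_mask: np.ndarray,
    lam: float,
    tau_factor: float,
    max_iter: int,
) -> tuple[np.ndarray, bool]:
    """Iterative non-negativity-constrained deconvolution of one voxel."""
    a_init = forward[:, init_mask]
    f = np.zeros(forward.shape[1])
    f[init_mask], *_ = np.linalg.lstsq(a_init, signal, rcond=None)
    amp0 = b_constraint @ f
    tau = tau_factor * float(amp0.mean())
    prev_active = None
    converged = False
    for _ in range(max_iter):
        amp = b_constraint @ f
        active = amp < tau
        if prev_active is not None and np.array_equal(active, prev_active):
            converged = True
            break
        prev_active = active
        m = np.vstack([forward, lam * b_constraint[active]])
        rhs = np.concatenate([signal, np.zeros(int(active.sum()))])
        f, *_ = np.linalg.lstsq(m, rhs, rcond=None)
    return f, converged


def _csd_signals(
    signals: np.ndarray,
    gradients,
    response: ResponseFunction,
    basis: SphericalHarmonicBasis,
    constraint_dirs: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """CSD of S0-normalized DWI signals (n_vox, n_dwi) -> (coeffs, converged)."""
    dwi_dirs = gradients.bvecs[gradients.dwi_mask]
    b_signal = basis.matrix(dwi_dirs)
    forward = b_signal * response.rotational_harmonics(basis.degrees)[None, :]
    if constraint_dirs is None:
        constraint_dirs = fibonacci_sphere(N_CONSTRAINT_DIRS)
    b_constraint = basis.matrix(constraint_dirs)
    init_mask = basis.degrees <= min(4, basis.l_max)
    coeffs = np.zeros((len(signals), basis.n_coeffs))
    converged = np.zeros(len(signals), dtype=bool)
    for i, s in enumerate(signals):
        f, ok = _csd_single_voxel(
            s, forward, b_constraint, init_mask, CSD_LAMBDA, CSD_TAU, CSD_MAX_ITER
        )
        coeffs[i] = f
        converged[i] = ok
    return coeffs, converged


def _normalized_dwi_signals(dwi: DWIDataset, vox: np.ndarray) -> np.ndarray:
    """S0-normalized DWI signals at voxel indices (n_vox, 3) -> (n_vox, n_dwi)."""
    g = dwi.gradients
    sig = dwi.signal[vox[:, 0], vox[:, 1], vox[:, 2], :]
    s0 = sig[:, g.b0_mask].mean(axis=1)
    s0 = np.maximum(s0, 1e-8 * max(float(np.max(s0, initial=0.0)), 1.0))
    return sig[:, g.dwi_mask] / s0[:, None]


def csd_deconvolve(
    dwi: DWIDataset,
    response: ResponseFunction,
    mask: BinaryMask,
    basis: SphericalHarmonicBasis | None = None,
) -> FODField:
    """Constrained spherical deconvolution of every voxel inside ``mask``.

    Voxels whose non-negativity active set fails to stabilize within the
    iteration cap are logged and their FOD set to zero (excluded from
    tracking).
    """
    if basis is None:
        basis = SphericalHarmonicBasis(response.l_max)
    bvals = dwi.gradients.bvals[dwi.gradients.dwi_mask]
    if np.ptp(bvals) > dwi.gradients.b0_threshold:
        raise ValidationError("CSD requires single-shell data (one nonzero b-value)")
    vox = np.argwhere(mask.values > 0)
    coeffs = np.zeros(dwi.grid.dims + (basis.n_coeffs,))
    if len(vox):
        signals = _normalized_dwi_signals(dwi, vox)
        c, converged = _csd_signals(signals, dwi.gradients, response, basis)
        if not converged.all():
            n_bad = int((~converged).sum())
            logger.warning("CSD: %d voxel(s) did not converge; FOD set to zero", n_bad)
            c[~converged] = 0.0
        coeffs[vox[:, 0], vox[:, 1], vox[:, 2]] = c
    return FODField(coeffs=coeffs, basis=basis, grid=dwi.grid)


# ---------------------------------------------------------------------------
# recursive response calibration
# ---------------------------------------------------------------------------


def calibrate_response_recursive(
    dwi: DWIDataset,
    mask: BinaryMask,
    basis: SphericalHarmonicBasis | None = None,
    ratio_sf: float = RESPONSE_RATIO_SF,
    max_iter: int = RESPONSE_MAX_ITER,
    return_selection: bool = False,
) -> "ResponseFunction | tuple[ResponseFunction, np.ndarray]":
    """Recursively calibrated single-fiber response from the data themselves.

    Iterates: deconvolve all candidate voxels with the current response, keep
    voxels whose second-to-first FOD peak amplitude ratio is below ``ratio_sf``,
    and re-estimate the response as the zonal average of the selected voxels'
    signals aligned to their principal FOD peak. Starts from a nearly isotropic
    tensor profile; stops when the selected set repeats or after ``max_iter``.
    """
    if basis is None:
        basis = SphericalHarmonicBasis(DEFAULT_L_MAX)
    g = dwi.gradients
    bvals = g.bvals[g.dwi_mask]
    if np.ptp(bvals) > g.b0_threshold:
        raise ValidationError("calibration requires single-shell data")
    vox = np.argwhere(mask.values > 0)
    if len(vox) == 0:
        raise CalibrationError("empty calibration mask")
    signals = _normalized_dwi_signals(dwi, vox)
    dwi_dirs = g.bvecs[g.dwi_mask]
    search_dirs = fibonacci_hemisphere(N_SEARCH_DIRS)
    b_search = basis.matrix(search_dirs)

    response = response_from_tensor(
        g.bvals, FAT_LAMBDA_PARALLEL, FAT_LAMBDA_PERP, basis.l_max
    )
    prev_selected: set[frozenset] = set()
    selected = np.ones(len(vox), dtype=bool)
    for iteration in range(max_iter):
        coeffs, converged = _csd_signals(signals, g, response, basis)
        peaks = [
            extract_peaks(c, basis, amplitude_threshold=0.0, max_peaks=2,
                          search_matrix=(search_dirs, b_search))
            if ok
            else PeakSet.empty()
            for c, ok in zip(coeffs, converged)
        ]
        new_selected = np.array(
            [
                len(p) >= 1
                and (len(p) == 1 or p.amplitudes[1] < ratio_sf * p.amplitudes[0])
                for p in peaks
            ]
        )
        if not new_selected.any():
            raise CalibrationError(
                "no voxels pass the single-fiber selection; check the mask/data"
            )
        key = frozenset(np.flatnonzero(new_selected).tolist())
        logger.info(
            "response calibration iter %d: %d/%d voxels selected",
            iteration + 1,
            int(new_selected.sum()),
            len(vox),
        )
        # re-estimate: zonal profile of signals aligned to each principal peak
        zonal = []
        for i in np.flatnonzero(new_selected):
            axis = peaks[i].directions[0]
            cos_t = dwi_dirs @ axis
            zonal.append(zonal_fit(cos_t, signals[i], basis.l_max))
        response = ResponseFunction(
            zonal_coeffs=np.mean(zonal, axis=0), l_max=basis.l_max
        )
        selected = new_selected
        if key in prev_selected:
            break
        prev_selected.add(key)
    if return_selection:
        return response, vox[selected]
    return response


# ---------------------------------------------------------------------------
# peak extraction
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PeakSet:
    """FOD peaks: unit axes (antipodally collapsed) with amplitudes, descending."""

    directions: np.ndarray  # (k, 3)
    amplitudes: np.ndarray  # (k,)

    @staticmethod
    def empty() -> "PeakSet":
        return PeakSet(directions=np.zeros((0, 3)), amplitudes=np.zeros(0))

    def __len__(self) -> int:
        return len(self.amplitudes)


def _tangent_bases(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Orthonormal tangent pairs for an array of unit vectors (k, 3)."""
    ref = np.where(
        np.abs(d[:, :1]) < 0.9, [[1.0, 0.0, 0.0]], [[0.0, 1.0, 0.0]]
    )
    e1 = np.cross(d, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    return e1, np.cross(d, e1)


def _refine_peaks(
    coeffs: np.ndarray,
    basis: SphericalHarmonicBasis,
    dirs0: np.ndarray,
    steps: int = PEAK_REFINE_STEPS,
) -> tuple[np.ndarray, np.ndarray]:
    """Projected local ascent on the SH expansion, batched over candidates.

    Each iteration evaluates a 5-point finite-difference stencil per candidate
    and one trial step; a rejected trial halves that candidate's step size.
    """
    h = 0.01  # finite-difference angle, radians
    cur = dirs0 / np.linalg.norm(dirs0, axis=1, keepdims=True)
    amps = basis.matrix(cur) @ coeffs
    step = np.full(len(cur), 0.05)  # per-candidate step, radians
    for _ in range(steps):
        e1, e2 = _tangent_bases(cur)
        stencil = np.stack(
            [cur + h * e1, cur - h * e1, cur + h * e2, cur - h * e2], axis=1
        )
        stencil /= np.linalg.norm(stencil, axis=2, keepdims=True)
        sa = (basis.matrix(stencil.reshape(-1, 3)) @ coeffs).reshape(len(cur), 4)
        grad = ((sa[:, 0] - sa[:, 1])[:, None] * e1 + (sa[:, 2] - sa[:, 3])[:, None] * e2) / (2 * h)
        gn = np.linalg.norm(grad, axis=1, keepdims=True)
        unit = np.divide(grad, gn, out=np.zeros_like(grad), where=gn > 1e-12)
        trial = cur + step[:, None] * unit
        trial /= np.linalg.norm(trial, axis=1, keepdims=True)
        ta = basis.matrix(trial) @ coeffs
        better = ta > amps
        cur = np.where(better[:, None], trial, cur)
        amps = np.where(better, ta, amps)
        step = np.where(better, step, step * 0.5)
    return cur, amps


def extract_peaks(
    fod_coeffs: np.ndarray,
    basis: SphericalHarmonicBasis,
    amplitude_threshold: float = 0.08,
    max_peaks: int = DEFAULT_MAX_PEAKS,
    min_separation: float = DEFAULT_MIN_SEPARATION,
    search_matrix: tuple[np.ndarray, np.ndarray] | None = None,
) -> PeakSet:
    """Local maxima of the FOD above ``amplitude_threshold``.

    Initial search on a hemisphere tessellation (antipodal pairs collapse to
    one representative because the basis is even), refined by projected local
    ascent on the SH expansion; peaks closer than ``min_separation`` degrees to
    a stronger peak are discarded, at most ``max_peaks`` returned.
    """
    fod_coeffs = np.asarray(fod_coeffs, dtype=float)
    if not np.all(np.isfinite(fod_coeffs)):
        raise ValidationError("non-finite FOD coefficients")
    if search_matrix is None:
        dirs = fibonacci_hemisphere(N_SEARCH_DIRS)
        b = basis.matrix(dirs)
    else:
        dirs, b = search_matrix
    amps = b @ fod_coeffs
    order = np.argsort(amps)[::-1]
    min_sep_cos = np.cos(np.radians(min_separation))
    candidates: list[np.ndarray] = []
    for i in order:
        if amps[i] < amplitude_threshold or len(candidates) >= max_peaks:
            break
        d = dirs[i]
        if all(abs(d @ c) < min_sep_cos for c in candidates):
            candidates.append(d)
    if not candidates:
        return PeakSet.empty()
    rdirs, ramps = _refine_peaks(fod_coeffs, basis, np.asarray(candidates))
    refined: list[tuple[np.ndarray, float]] = []
    for rd, ra in zip(rdirs, ramps):
        if rd[2] < 0 or (rd[2] == 0 and (rd[1] < 0 or (rd[1] == 0 and rd[0] < 0))):
            rd = -rd  # canonical hemisphere representative
        refined.append((rd, float(ra)))
    refined.sort(key=lambda t: -t[1])
    kept: list[tuple[np.ndarray, float]] = []
    for rd, ra in refined:
        if ra < amplitude_threshold:
            continue
        if all(abs(rd @ kd) < min_sep_cos for kd, _ in kept):
            kept.append((rd, ra))
    if not kept:
        return PeakSet.empty()
    return PeakSet(
        directions=np.array([k[0] for k in kept]),
        amplitudes=np.array([k[1] for k in kept]),
    )
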