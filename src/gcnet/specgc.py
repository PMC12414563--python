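"""Frequency-domain Granger causality between ROI pairs.

For every ordered pair of regional time series a bivariate autoregressive
model of order p is fitted by ordinary least squares; Geweke's decomposition
partitions each channel's power spectrum into an intrinsic part and a causal
part attributable to the other channel, and the spectral GC is the log-ratio

    GC_{i->j}(f) = ln( S_jj(f) / (S_jj(f) - (Sigma_ii - Sigma_ij^2/Sigma_jj) |H_ji(f)|^2) )

evaluated on a uniform frequency grid from 0 to the Nyquist frequency.  Band
adjacency matrices are arithmetic means of the GC spectrum over canonical
band limits (inclusive at both ends).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthcohort import TimeSeriesSet, _pairwise_geweke

__all__ = [
    "DEFAULT_BANDS",
    "BivariateVarModel",
    "SpectralFactors",
    "GCSpectrum",
    "SpectralConnectivity",
    "BandConnectivity",
    "DegenerateInputError",
    "fit_var",
    "spectral_factors",
    "spectral_gc_pair",
    "connectivity_matrices",
    "band_average",
    "make_freq_grid",
]

#: canonical EEG band limits in Hz, inclusive at both ends
DEFAULT_BANDS: dict[str, tuple[float, float]] = {
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (14.0, 30.0),
    "gamma": (30.0, 40.0),
}


class DegenerateInputError(ValueError):
    """Raised when the lagged regressor matrix is rank deficient (for example
    a constant channel)."""


@dataclass
class BivariateVarModel:
    """Order-p bivariate AR fit for one ROI pair.

    coeff[k] is the 2x2 coefficient matrix at lag k+1 in channel order
    (x_i, x_j); noise_cov is the residual covariance (denominator T - p).
    reduced_var holds the residual variances of the two univariate AR(p)
    models (x_i on its own past, x_j on its own past), needed for
    time-domain GC.
    """

    order: int
    coeff: np.ndarray  # (p, 2, 2)
    noise_cov: np.ndarray  # (2, 2)
    fs: float
    pair: tuple[int, int] = (0, 1)
    reduced_var: tuple[float, float] = (np.nan, np.nan)

    def time_domain_gc(self) -> tuple[float, float]:
        """(GC_{i->j}, GC_{j->i}) = ln(reduced/full residual variance)."""
        gc_ij = float(np.log(self.reduced_var[1] / self.noise_cov[1, 1]))
        gc_ji = float(np.log(self.reduced_var[0] / self.noise_cov[0, 0]))
        return gc_ij, gc_ji

    def instantaneous_gc(self) -> float:
        s = self.noise_cov
        return float(np.log(s[0, 0] * s[1, 1] / np.linalg.det(s)))


@dataclass
class SpectralFactors:
    freq_grid: np.ndarray
    transfer: np.ndarray  # (F, 2, 2) complex, H(f)
    spectrum: np.ndarray  # (F, 2, 2) complex Hermitian, S(f)


@dataclass
class GCSpectrum:
    freq_grid: np.ndarray
    gc: np.ndarray  # (F,) non-negative, nats
    direction: tuple[int, int]
    n_clamped: int = 0


@dataclass
class SpectralConnectivity:
    """R x R x F tensor of pairwise spectral GC for one subject."""

    subject_id: str
    tensor: np.ndarray
    freq_grid: np.ndarray
    roi_labels: list[str]
    failed_pairs: list[tuple[int, int]] = field(default_factory=list)
    n_clamped: int = 0

    @property
    def n_rois(self) -> int:
        return self.tensor.shape[0]

    def report(self) -> dict:
        return {
            "subject_id": self.subject_id,
            "n_rois": self.n_rois,
            "n_freqs": int(self.freq_grid.size),
            "failed_pairs": [list(p) for p in self.failed_pairs],
            "n_clamped": int(self.n_clamped),
        }


@dataclass
class BandConnectivity:
    """Per-band R x R adjacency A; A[i, j] is the mean GC i->j over the band
    (nats), the weight of the directed edge i -> j."""

    subject_id: str
    adjacency: dict[str, np.ndarray]
    bands: dict[str, tuple[float, float]]
    roi_labels: list[str]


# ---------------------------------------------------------------------------
# AR fitting
# ---------------------------------------------------------------------------

def _lag_matrix(series: np.ndarray, p: int) -> np.ndarray:
    """Stack lags 1..p of each channel: shape (T - p, n_ch * p), columns
    ordered (channel, lag)."""
    n_ch, T = series.shape
    cols = np.empty((T - p, n_ch * p))
    for c in range(n_ch):
        for k in range(1, p + 1):
            cols[:, c * p + k - 1] = series[c, p - k:T - k]
    return cols


def _solve_normal(G: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Solve G B = C for B via Cholesky; raise on (near-)singular G."""
    try:
        import scipy.linalg as sla

        cf = sla.cho_factor(G, check_finite=False)
        return sla.cho_solve(cf, C, check_finite=False)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise DegenerateInputError(str(exc)) from exc
    except Exception as exc:
        raise DegenerateInputError(
            f"rank-deficient regressor matrix: {exc}") from exc


def fit_var(
    x_i: np.ndarray,
    x_j: np.ndarray,
    p: int,
    *,
    fs: float = 500.0,
    pair: tuple[int, int] = (0, 1),
) -> BivariateVarModel:
    """Least-squares bivariate AR(p) fit of the ordered channel pair.

    Coefficients minimize the one-step prediction error over samples
    p+1..T; the residual covariance uses denominator T - p.  The univariate
    reduced-model residual variances (each channel on its own past) are
    fitted alongside.
    """
    x_i = np.asarray(x_i, dtype=float).ravel()
    x_j = np.asarray(x_j, dtype=float).ravel()
    if x_i.size != x_j.size:
        raise ValueError("both series must have the same length")
    T = x_i.size
    if T <= 10 * p:
        raise ValueError("series length must exceed 10x the order")
    if np.std(x_i) == 0 or np.std(x_j) == 0:
        raise DegenerateInputError("constant input series")

    data = np.vstack([x_i, x_j])
    Z = _lag_matrix(data, p)  # (T-p, 2p)
    Y = data[:, p:].T  # (T-p, 2)
    G = Z.T @ Z
    C = Z.T @ Y
    B = _solve_normal(G, C)  # (2p, 2): column per equation
    resid_cov = (Y.T @ Y - C.T @ B) / (T - p)
    resid_cov = (resid_cov + resid_cov.T) / 2

    # univariate reduced models, same lag window and denominator
    reduced = []
    for c in range(2):
        idx = slice(c * p, (c + 1) * p)
        Gc = G[idx, idx]
        Cc = C[idx, c]
        bc = _solve_normal(Gc, Cc)
        rv = (Y[:, c] @ Y[:, c] - Cc @ bc) / (T - p)
        reduced.append(float(rv))

    # coeff[k][r, c]: equation r, regressor channel c, lag k+1
    coeff = np.empty((p, 2, 2))
    for eq in range(2):
        for ch in range(2):
            coeff[:, eq, ch] = B[ch * p:(ch + 1) * p, eq]
    return BivariateVarModel(order=p, coeff=coeff, noise_cov=resid_cov,
                             fs=fs, pair=pair, reduced_var=(reduced[0], reduced[1]))


# ---------------------------------------------------------------------------
# spectral machinery
# ---------------------------------------------------------------------------

def spectral_factors(model: BivariateVarModel, freq_grid: np.ndarray) -> SpectralFactors:
    """Transfer H(f) = (I - sum_k A_k e^{-i 2 pi f k / fs})^{-1} and spectrum
    S(f) = H(f) Sigma H(f)^H on the given grid."""
    freq_grid = np.asarray(freq_grid, dtype=float)
    if np.any(freq_grid < 0) or np.any(freq_grid > model.fs / 2 + 1e-9):
        raise ValueError("freq_grid must lie within [0, fs/2]")
    omega = 2 * np.pi * freq_grid / model.fs
    lags = np.arange(1, model.order + 1)
    phase = np.exp(-1j * omega[:, None] * lags[None, :])
    A_omega = np.tensordot(phase, model.coeff, axes=(1, 0))
    B = np.eye(2)[None] - A_omega
    det = B[:, 0, 0] * B[:, 1, 1] - B[:, 0, 1] * B[:, 1, 0]
    bad = np.abs(det) < 1e-14
    if np.any(bad):
        f_bad = freq_grid[np.argmax(bad)]
        raise ValueError(f"characteristic matrix singular at {f_bad:.4f} Hz")
    H = np.empty_like(B)
    inv_det = 1.0 / det
    H[:, 0, 0] = B[:, 1, 1] * inv_det
    H[:, 1, 1] = B[:, 0, 0] * inv_det
    H[:, 0, 1] = -B[:, 0, 1] * inv_det
    H[:, 1, 0] = -B[:, 1, 0] * inv_det
    S = H @ model.noise_cov @ np.conj(H).transpose(0, 2, 1)
    return SpectralFactors(freq_grid=freq_grid, transfer=H, spectrum=S)


def spectral_gc_pair(
    model: BivariateVarModel,
    freq_grid: np.ndarray,
) -> tuple[GCSpectrum, GCSpectrum]:
    """Spectral GC in both directions from one bivariate fit.

    Negative round-off values (argument of the log below 1) are clamped to 0
    and counted in ``n_clamped`` of each returned spectrum.
    """
    factors = spectral_factors(model, freq_grid)
    H, sigma = factors.transfer, model.noise_cov
    S = factors.spectrum
    out = []
    directions = (model.pair, (model.pair[1], model.pair[0]))
    for (a, b), direction in zip(((0, 1), (1, 0)), directions):
        s_bb = S[:, b, b].real
        causal = (sigma[a, a] - sigma[a, b] ** 2 / sigma[b, b]) * np.abs(H[:, b, a]) ** 2
        intrinsic = s_bb - causal
        floor = 1e-12 * s_bb
        clamped_den = int(np.sum(intrinsic < floor))
        gc = np.log(s_bb / np.maximum(intrinsic, floor))
        n_clamped = clamped_den + int(np.sum(gc < 0))
        out.append(GCSpectrum(freq_grid=factors.freq_grid,
                              gc=np.maximum(gc, 0.0),
                              direction=direction, n_clamped=n_clamped))
    return out[0], out[1]


def make_freq_grid(fs: float, freq_resolution: float) -> np.ndarray:
    """Uniform grid {0, df, 2 df, ..., fs/2} inclusive of 0 and Nyquist
    (fs = 500 Hz, df = 0.1 Hz gives 2501 samples)."""
    n = int(round(fs / 2 / freq_resolution)) + 1
    return np.arange(n) * freq_resolution


def connectivity_matrices(
    subject: TimeSeriesSet,
    p: int = 30,
    freq_resolution: float = 0.1,
) -> SpectralConnectivity:
    """Pairwise spectral GC for all ordered ROI pairs of one subject.

    Each of the R(R-1)/2 unordered pairs is fitted once and both directions
    stored; the diagonal is identically zero.  Pairs whose fit fails are
    recorded in ``failed_pairs`` and their entries set to NaN (missing, not
    zero).

    A single lagged Gram matrix over all channels is computed per subject and
    pair models solved from its sub-blocks, which is algebraically identical
    to fitting each pair separately.
    """
    R = subject.n_rois
    if R < 2:
        raise ValueError("need at least 2 ROIs")
    T = subject.n_samples
    if T <= 10 * p:
        raise ValueError("series length must exceed 10x the order")
    grid = make_freq_grid(subject.fs, freq_resolution)
    tensor = np.zeros((R, R, grid.size))
    failed: list[tuple[int, int]] = []
    n_clamped = 0

    data = subject.data
    Z = _lag_matrix(data, p)  # (T-p, R*p)
    Y = data[:, p:].T
    G = Z.T @ Z
    C = Z.T @ Y  # (R*p, R)
    YY = Y.T @ Y

    for i in range(R):
        for j in range(i + 1, R):
            idx = np.r_[i * p:(i + 1) * p, j * p:(j + 1) * p]
            try:
                B = _solve_normal(G[np.ix_(idx, idx)], C[np.ix_(idx, [i, j])])
                resid = (YY[np.ix_([i, j], [i, j])]
                         - C[np.ix_(idx, [i, j])].T @ B) / (T - p)
                resid = (resid + resid.T) / 2
                coeff = np.empty((p, 2, 2))
                for eq in range(2):
                    for ch in range(2):
                        coeff[:, eq, ch] = B[ch * p:(ch + 1) * p, eq]
                model = BivariateVarModel(order=p, coeff=coeff,
                                          noise_cov=resid, fs=subject.fs,
                                          pair=(i, j))
                gc_ij, gc_ji = spectral_gc_pair(model, grid)
            except (DegenerateInputError, ValueError, np.linalg.LinAlgError):
                failed.append((i, j))
                tensor[i, j] = np.nan
                tensor[j, i] = np.nan
                continue
            tensor[i, j] = gc_ij.gc
            tensor[j, i] = gc_ji.gc
            n_clamped += gc_ij.n_clamped + gc_ji.n_clamped
    return SpectralConnectivity(subject_id=subject.subject_id, tensor=tensor,
                                freq_grid=grid,
                                roi_labels=list(subject.roi_labels),
                                failed_pairs=failed, n_clamped=n_clamped)


def band_average(
    conn: SpectralConnectivity,
    bands: dict[str, tuple[float, float]] | None = None,
) -> BandConnectivity:
    """Average the spectral connectivity tensor within each named band.

    Band limits are inclusive at both ends; a band containing no grid point
    is an error.
    """
    if bands is None:
        bands = dict(DEFAULT_BANDS)
    nyq = conn.freq_grid[-1]
    adjacency = {}
    for name, (lo, hi) in bands.items():
        if not (0 <= lo <= hi <= nyq + 1e-9):
            raise ValueError(f"band {name} = ({lo}, {hi}) outside [0, {nyq}]")
        sel = (conn.freq_grid >= lo - 1e-9) & (conn.freq_grid <= hi + 1e-9)
        if not np.any(sel):
            raise ValueError(f"band {name} contains no grid point")
        A = conn.tensor[:, :, sel].mean(axis=2)
        np.fill_diagonal(A, 0.0)
        adjacency[name] = A
    return BandConnectivity(subject_id=conn.subject_id, adjacency=adjacency,
                            bands=dict(bands), roi_labels=list(conn.roi_labels))
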