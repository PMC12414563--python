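"""Synthetic VAR cohorts with band-specific directed coupling and an analytic
spectral Granger-causality oracle.

The generator emulates source-space resting-state recordings: each region of
interest (ROI) is a channel of a stable vector-autoregressive (VAR) process.
Band-specific directed influences are built as damped-oscillator pole pairs in
the source ROI (so the source carries narrow-band power at the requested
center frequency) plus a lagged cross-coefficient source -> target.  Because
the true coefficients are known, spectral Granger causality (GC) between any
ordered ROI pair can be computed analytically and used as an oracle for the
data-driven estimator.

Two groups are generated: a "low" group from the full-gain model and a "high"
group whose cross-couplings are attenuated band- and direction-specifically,
emulating reduced top-down (fronto-posterior) coupling in slow rhythms and
reduced bottom-up (posterior-frontal) coupling in fast rhythms.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BandTarget",
    "VarModelSpec",
    "TimeSeriesSet",
    "Cohort",
    "CohortConfig",
    "NonStationaryModelError",
    "make_var_model",
    "simulate_var",
    "analytic_spectral_gc",
    "analytic_band_adjacency",
    "generate_cohort",
    "demo_cohort_config",
    "write_cohort",
    "read_cohort",
]


class NonStationaryModelError(ValueError):
    """Raised when a VAR specification fails the companion stationarity gate."""


class BandTarget(NamedTuple):
    """A directed band-limited coupling: ``source`` drives ``target`` around
    ``center_hz`` with approximately ``bandwidth_hz`` (-3 dB) and strength
    ``gain`` (the lag-1 cross-coefficient, unitless)."""

    source: int
    target: int
    center_hz: float
    bandwidth_hz: float
    gain: float


@dataclass(frozen=True)
class VarModelSpec:
    """A stable VAR(p) model: x[n] = sum_k coeff[k] @ x[n-k] + e[n].

    coeff has shape (order, n_rois, n_rois); coeff[k, i, j] is the dependence
    of channel i on channel j at lag k+1.  noise_cov is the innovation
    covariance (symmetric positive definite).
    """

    coeff: np.ndarray
    noise_cov: np.ndarray
    fs: float
    band_targets: tuple[BandTarget, ...] = ()

    def __post_init__(self) -> None:
        coeff = np.asarray(self.coeff, dtype=float)
        ncov = np.asarray(self.noise_cov, dtype=float)
        object.__setattr__(self, "coeff", coeff)
        object.__setattr__(self, "noise_cov", ncov)
        if coeff.ndim != 3 or coeff.shape[1] != coeff.shape[2]:
            raise ValueError("coeff must have shape (order, n_rois, n_rois)")
        if not np.all(np.isfinite(coeff)):
            raise ValueError("non-finite VAR coefficients")
        if ncov.shape != (coeff.shape[1], coeff.shape[1]):
            raise ValueError("noise_cov shape mismatch")
        if not np.allclose(ncov, ncov.T, atol=1e-12):
            raise ValueError("noise_cov must be symmetric")
        if np.any(np.linalg.eigvalsh(ncov) <= 0):
            raise ValueError("noise_cov must be positive definite")
        rho = self.companion_spectral_radius()
        if rho >= 1.0:
            raise NonStationaryModelError(
                f"companion spectral radius {rho:.4f} >= 1: "
                "model is not stationary (reduce coupling gains)"
            )

    @property
    def n_rois(self) -> int:
        return self.coeff.shape[1]

    @property
    def order(self) -> int:
        return self.coeff.shape[0]

    def companion_spectral_radius(self) -> float:
        p, r, _ = self.coeff.shape
        comp = np.zeros((p * r, p * r))
        comp[:r] = self.coeff.transpose(1, 0, 2).reshape(r, p * r)
        if p > 1:
            comp[r:, :-r] = np.eye((p - 1) * r)
        return float(np.max(np.abs(np.linalg.eigvals(comp))))

    def transfer(self, freq_hz: np.ndarray) -> np.ndarray:
        """Transfer function H(f) = (I - sum_k A_k e^{-i 2 pi f k / fs})^{-1},
        shape (F, R, R) complex."""
        return _var_transfer(self.coeff, np.asarray(freq_hz, float), self.fs)

    def spectral_matrix(self, freq_hz: np.ndarray) -> np.ndarray:
        """Spectral density matrix S(f) = H(f) Sigma H(f)^H, shape (F, R, R)."""
        H = self.transfer(freq_hz)
        return H @ self.noise_cov @ np.conj(H).transpose(0, 2, 1)


@dataclass
class TimeSeriesSet:
    """One subject's ROI x sample activity matrix with its sampling rate."""

    subject_id: str
    fs: float
    data: np.ndarray  # (n_rois, n_samples)
    roi_labels: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (rois x samples)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")
        if len(self.roi_labels) != self.data.shape[0]:
            raise ValueError("roi_labels length must match data rows")
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("roi_labels must be unique")

    @property
    def n_rois(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def standardized(self) -> "TimeSeriesSet":
        """Return a copy with each channel z-scored (zero mean, unit SD)."""
        mu = self.data.mean(axis=1, keepdims=True)
        sd = self.data.std(axis=1, keepdims=True)
        if np.any(sd == 0):
            raise ValueError("constant channel cannot be standardized")
        return TimeSeriesSet(self.subject_id, self.fs, (self.data - mu) / sd,
                             list(self.roi_labels))


@dataclass
class Cohort:
    subjects: list[TimeSeriesSet]
    groups: list[str]  # per-subject label in {"low", "high"}
    partition: pd.DataFrame | None = None  # roi/cluster table used to build it
    true_models: dict[str, VarModelSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.subjects) != len(self.groups):
            raise ValueError("one group label per subject required")
        if set(self.groups) - {"low", "high"}:
            raise ValueError("group labels must be 'low' or 'high'")
        if "low" not in self.groups or "high" not in self.groups:
            raise ValueError("both groups must be non-empty")
        fs = {s.fs for s in self.subjects}
        labels = {tuple(s.roi_labels) for s in self.subjects}
        if len(fs) != 1 or len(labels) != 1:
            raise ValueError("all subjects must share fs and roi_labels")

    @property
    def roi_labels(self) -> list[str]:
        return list(self.subjects[0].roi_labels)

    @property
    def fs(self) -> float:
        return self.subjects[0].fs

    def split(self) -> tuple[list[TimeSeriesSet], list[TimeSeriesSet]]:
        low = [s for s, g in zip(self.subjects, self.groups) if g == "low"]
        high = [s for s, g in zip(self.subjects, self.groups) if g == "high"]
        return low, high


# ---------------------------------------------------------------------------
# model construction
# ---------------------------------------------------------------------------

def make_var_model(
    n_rois: int,
    band_targets: Sequence[BandTarget] = (),
    group_effect: float = 1.0,
    seed: int = 0,
    *,
    fs: float = 500.0,
    order: int = 2,
    base_ar: float = 0.3,
    noise_scale: Sequence[float] | None = None,
) -> VarModelSpec:
    """Construct a stationary VAR model with band-specific directed coupling.

    Each band target installs a damped-oscillator pole pair (complex-conjugate
    poles at radius r = exp(-pi * bandwidth / fs), angle 2 pi f0 / fs) in its
    source ROI and a lag-1 cross-coefficient source -> target scaled by
    ``gain * group_effect``.  Remaining ROIs follow a mildly heterogeneous
    AR(1) baseline drawn deterministically from ``seed``.
    """
    if n_rois < 2:
        raise ValueError("n_rois must be >= 2")
    if not 0.0 <= group_effect <= 1.0:
        raise ValueError("group_effect must lie in [0, 1]")
    order = max(int(order), 2 if band_targets else order)
    rng = np.random.default_rng(seed)
    coeff = np.zeros((order, n_rois, n_rois))
    # heterogeneous AR(1) baseline so channels are not i.i.d. copies
    coeff[0][np.diag_indices(n_rois)] = rng.uniform(base_ar - 0.1, base_ar + 0.1,
                                                    size=n_rois)
    noise_var = rng.uniform(0.9, 1.1, size=n_rois)
    if noise_scale is not None:
        noise_var = noise_var * np.asarray(noise_scale, dtype=float)

    for tgt in band_targets:
        s, t = int(tgt.source), int(tgt.target)
        if not (0 <= s < n_rois and 0 <= t < n_rois) or s == t:
            raise ValueError(f"invalid band target {tgt}")
        if tgt.center_hz >= fs / 2:
            raise ValueError("center frequency must be below Nyquist")
        r = np.exp(-np.pi * tgt.bandwidth_hz / fs)
        theta = 2 * np.pi * tgt.center_hz / fs
        coeff[0, s, s] = 2 * r * np.cos(theta)
        coeff[1, s, s] = -(r ** 2)
        coeff[0, t, s] += tgt.gain * group_effect

    model = VarModelSpec(
        coeff=coeff,
        noise_cov=np.diag(noise_var),
        fs=fs,
        band_targets=tuple(BandTarget(*bt) for bt in band_targets),
    )
    return model


def simulate_var(
    model: VarModelSpec,
    n_samples: int,
    seed: int,
    *,
    burn_in: int = 1000,
    subject_id: str = "sim",
    roi_labels: Sequence[str] | None = None,
) -> TimeSeriesSet:
    """Simulate ``n_samples`` samples from a stationary VAR model.

    A burn-in of ``burn_in`` samples (>= 1000 by default) is simulated and
    discarded so the emitted segment is free of initial-condition transients.
    Same (model, n_samples, seed) always yields the identical matrix.
    """
    if n_samples <= 10 * model.order:
        raise ValueError("n_samples must exceed 10x the model order")
    p, r = model.order, model.n_rois
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(model.noise_cov)
    total = n_samples + max(burn_in, 0)
    innov = rng.standard_normal((total, r)) @ L.T
    x = np.zeros((total + p, r))
    coeff = model.coeff
    for n in range(total):
        acc = innov[n]
        for k in range(p):
            acc = acc + coeff[k] @ x[n + p - 1 - k]
        x[n + p] = acc
    out = x[p + max(burn_in, 0):].T.copy()
    if roi_labels is None:
        roi_labels = [f"R{i + 1:02d}" for i in range(r)]
    return TimeSeriesSet(subject_id, model.fs, out, list(roi_labels))


# ---------------------------------------------------------------------------
# analytic spectral GC oracle
# ---------------------------------------------------------------------------

def _var_transfer(coeff: np.ndarray, freq_hz: np.ndarray, fs: float) -> np.ndarray:
    p, r, _ = coeff.shape
    omega = 2 * np.pi * freq_hz / fs  # radians per sample
    lags = np.arange(1, p + 1)
    phase = np.exp(-1j * omega[:, None] * lags[None, :])  # (F, p)
    A_omega = np.tensordot(phase, coeff, axes=(1, 0))  # (F, r, r)
    B = np.eye(r)[None] - A_omega
    return np.linalg.inv(B)


def _pairwise_geweke(H: np.ndarray, sigma: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Spectral GC in both directions from a 2-channel transfer/noise pair.

    H has shape (F, 2, 2); sigma is 2x2.  Returns (gc_0to1, gc_1to0), each a
    length-F non-negative array (nats).  Uses Geweke's partition: the causal
    power that channel a's innovations contribute to channel b's spectrum is
    (sigma_aa - sigma_ab^2 / sigma_bb) |H_ba|^2.
    """
    S = H @ sigma @ np.conj(H).transpose(0, 2, 1)
    out = []
    for a, b in ((0, 1), (1, 0)):
        s_bb = S[:, b, b].real
        causal = (sigma[a, a] - sigma[a, b] ** 2 / sigma[b, b]) * np.abs(H[:, b, a]) ** 2
        intrinsic = s_bb - causal
        floor = 1e-12 * np.maximum(s_bb, 1e-300)
        gc = np.log(s_bb / np.maximum(intrinsic, floor))
        out.append(np.maximum(gc, 0.0))
    return out[0], out[1]


def _ancestral_closure(coeff: np.ndarray, pair: tuple[int, int]) -> set[int]:
    """Smallest channel set containing ``pair`` that is causally closed
    (no member depends on a channel outside the set)."""
    dep = np.any(coeff != 0, axis=0)  # dep[i, j]: i depends on j
    closure = set(pair)
    frontier = list(pair)
    while frontier:
        i = frontier.pop()
        for j in np.nonzero(dep[i])[0]:
            if j not in closure:
                closure.add(int(j))
                frontier.append(int(j))
    return closure


def wilson_factorize(
    S_half: np.ndarray,
    *,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Wilson's spectral matrix factorization S(f) = H(f) Sigma H(f)^H.

    ``S_half`` holds the Hermitian spectral density on a uniform half grid of
    N/2+1 frequencies covering [0, pi] (as produced by an even-N full-circle
    grid).  Returns (H_half, Sigma) with H causal, minimum phase and H(0-lag)
    coefficient identity-normalized.  Convergence is checked on the
    reconstruction error max|psi psi^H - S|.
    """
    S_half = np.asarray(S_half, dtype=complex)
    nh, m, _ = S_half.shape
    N = 2 * (nh - 1)
    # two-sided extension: S[N-k] = S[k]^T (conjugate transpose = transpose
    # for Hermitian S evaluated at -omega gives S(-w) = S(w)^T conj... use
    # S(-w) = S(w).conj() elementwise on the Hermitian matrix = S(w).T
    S = np.empty((N, m, m), dtype=complex)
    S[:nh] = S_half
    S[nh:] = np.conj(S_half[-2:0:-1])
    # init: psi_k = chol of the average spectrum (constant in frequency)
    S0 = S.mean(axis=0).real
    S0 = (S0 + S0.T) / 2
    psi = np.tile(np.linalg.cholesky(S0).T, (N, 1, 1)).astype(complex)
    eye = np.eye(m)
    err = np.inf
    for _ in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ S @ np.conj(psi_inv).transpose(0, 2, 1) + eye
        gp = _plus_operator(g)
        # keep the zero-lag coefficient upper triangular (uniqueness)
        g0 = gp.mean(axis=0)
        beta = -np.tril(g0, -1)
        gp = gp + (beta - np.conj(beta).T)
        psi_new = psi @ gp
        err_new = float(np.max(np.abs(
            psi_new @ np.conj(psi_new).transpose(0, 2, 1) - S)))
        psi = psi_new
        if abs(err - err_new) < tol * max(1.0, err_new):
            err = err_new
            break
        err = err_new
    A0 = np.fft.ifft(psi, axis=0)[0].real
    sigma = A0 @ A0.T
    H = psi @ np.linalg.inv(A0)
    return H[:nh], sigma


def _plus_operator(g: np.ndarray) -> np.ndarray:
    """Causal (non-negative lag) part of g, with the zero lag halved."""
    N = g.shape[0]
    G = np.fft.ifft(g, axis=0)
    G[0] /= 2
    G[N // 2 + 1:] = 0
    if N % 2 == 0:
        G[N // 2] /= 2
    return np.fft.fft(G, axis=0)


def analytic_spectral_gc(
    model: VarModelSpec,
    freq_grid: np.ndarray,
    *,
    nfft: int = 1024,
) -> np.ndarray:
    """Pairwise spectral GC from the TRUE model coefficients (no estimation).

    Returns a tensor (R, R, F) with entry [i, j, f] = GC_{i->j}(freq_grid[f])
    in nats; the diagonal is zero.  For pairs whose ancestral closure is the
    pair itself the bivariate marginal is the exact sub-VAR and GC is computed
    in closed form; otherwise the 2x2 cross-spectrum of the full model is
    factorized with Wilson's algorithm and GC evaluated from its factors.
    """
    freq_grid = np.asarray(freq_grid, dtype=float)
    if np.any(freq_grid < 0) or np.any(freq_grid > model.fs / 2 + 1e-9):
        raise ValueError("freq_grid must lie within [0, fs/2]")
    R = model.n_rois
    F = freq_grid.size
    gc = np.zeros((R, R, F))

    half_grid = np.linspace(0.0, model.fs / 2, nfft // 2 + 1)
    S_full_half: np.ndarray | None = None

    for i in range(R):
        for j in range(i + 1, R):
            closure = _ancestral_closure(model.coeff, (i, j))
            if closure == {i, j}:
                sub = VarModelSpec(
                    coeff=model.coeff[:, [i, j]][:, :, [i, j]],
                    noise_cov=model.noise_cov[np.ix_([i, j], [i, j])],
                    fs=model.fs,
                )
                H = sub.transfer(freq_grid)
                g_ij, g_ji = _pairwise_geweke(H, sub.noise_cov)
            else:
                if S_full_half is None:
                    S_full_half = model.spectral_matrix(half_grid)
                    bad = np.abs(np.linalg.det(S_full_half)) < 1e-300
                    if np.any(bad):
                        f_bad = half_grid[np.argmax(bad)]
                        raise ValueError(
                            f"singular spectral matrix at {f_bad:.3f} Hz")
                S_pair = S_full_half[:, [i, j]][:, :, [i, j]]
                H2, sigma2 = wilson_factorize(S_pair)
                g_ij_h, g_ji_h = _pairwise_geweke(H2, sigma2)
                g_ij = np.interp(freq_grid, half_grid, g_ij_h)
                g_ji = np.interp(freq_grid, half_grid, g_ji_h)
            gc[i, j] = g_ij
            gc[j, i] = g_ji
    return gc


def analytic_band_adjacency(
    model: VarModelSpec,
    bands: dict[str, tuple[float, float]],
    *,
    freq_resolution: float = 0.1,
    nfft: int = 1024,
) -> dict[str, np.ndarray]:
    """Band-averaged analytic GC adjacency matrices (oracle counterpart of the
    estimator's band adjacencies)."""
    n = int(round(model.fs / 2 / freq_resolution)) + 1
    grid = np.arange(n) * freq_resolution
    gc = analytic_spectral_gc(model, grid, nfft=nfft)
    out = {}
    for name, (lo, hi) in bands.items():
        sel = (grid >= lo - 1e-9) & (grid <= hi + 1e-9)
        if not np.any(sel):
            raise ValueError(f"band {name} contains no grid point")
        out[name] = gc[:, :, sel].mean(axis=2)
    return out


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass
class CohortConfig:
    """Study-condition parameters for a synthetic two-group cohort.

    ``effect`` maps band name -> direction ('fp' for fronto-posterior /
    top-down, 'pf' for posterior-frontal / bottom-up) -> multiplicative gain
    retained in the high group (1.0 = no group difference).  The default
    profile attenuates theta top-down and gamma bottom-up coupling by 30%.
    """

    n_low: int = 54
    n_high: int = 55
    n_rois: int = 68
    fs: float = 500.0
    duration_s: float = 120.0
    effect: dict = field(default_factory=lambda: {
        "theta": {"fp": 0.7},
        "gamma": {"pf": 0.7},
    })
    coupling_gain: float = 0.05
    sink_noise_scale: float = 4.0
    order: int = 2
    seed: int = 0

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


#: band center/bandwidth used when placing couplings (Hz); the theta
#: oscillator is broad enough that its upper shoulder reaches into the alpha
#: band, as slow rhythms do in resting recordings
BAND_OSCILLATORS: dict[str, tuple[float, float]] = {
    "theta": (6.0, 3.0),
    "alpha": (10.0, 2.0),
    "beta": (22.0, 4.0),
    "gamma": (35.0, 4.0),
}

#: canonical coupling direction per band: slow rhythms carry top-down
#: (frontal -> posterior) influence, fast rhythms bottom-up
BAND_DIRECTION: dict[str, str] = {
    "theta": "fp",
    "alpha": "fp",
    "beta": "pf",
    "gamma": "pf",
}


def demo_cohort_config(**overrides) -> CohortConfig:
    """Desk-scale demo conditions: 25+25 subjects, 10 ROIs, 30 s at 250 Hz."""
    base = dict(n_low=25, n_high=25, n_rois=10, fs=250.0, duration_s=30.0)
    base.update(overrides)
    return CohortConfig(**base)


def default_partition_indices(n_rois: int) -> tuple[list[int], list[int], list[int]]:
    """Frontal / posterior / temporo-central index blocks for a generic
    ``n_rois``-channel cohort (roughly 35% / 35% / 30%)."""
    n_f = max(2, int(round(0.35 * n_rois)))
    n_p = max(2, int(round(0.35 * n_rois)))
    if n_f + n_p > n_rois:
        raise ValueError("n_rois too small to partition")
    frontal = list(range(n_f))
    posterior = list(range(n_f, n_f + n_p))
    excluded = list(range(n_f + n_p, n_rois))
    return frontal, posterior, excluded


def _chunks(pool: list[int], n: int) -> list[list[int]]:
    if len(pool) >= n:
        size = len(pool) // n
        out = [pool[i * size:(i + 1) * size] for i in range(n - 1)]
        out.append(pool[(n - 1) * size:])
        return out
    return [[pool[i]] if i < len(pool) else [] for i in range(n)]


def _cohort_band_targets(
    config: CohortConfig,
    frontal: list[int],
    posterior: list[int],
    excluded: list[int],
    group: str,
) -> tuple[list[BandTarget], list[int]]:
    """Band couplings in each band's canonical direction.

    Each band owns a disjoint slice of every cluster and builds triangle
    motifs src -> recv, recv -> sink, src -> sink, where src sits in the
    band's sending cluster (frontal for slow/top-down, posterior for
    fast/bottom-up), recv in the opposite cluster (relaying on the band's
    oscillator) and the sink in the temporo-central cluster.  The motif keeps
    local efficiency non-zero and responsive to the band's coupling gain.

    Nodes are never shared across bands except the sinks, which are shared
    only between band pairs with matching default attenuation (theta/gamma
    and alpha/beta), so attenuating one band cannot inflate another band's
    causal share into a common receiver.  Sources always precede receivers
    and sinks, so the coupling graph is acyclic and the model stationary by
    construction.  High-group gains are multiplied by the per-band/direction
    effect profile (all three motif edges of a band together).
    """
    order = [b for b, (f0, _) in BAND_OSCILLATORS.items() if f0 < config.fs / 2]
    f_ch = _chunks(frontal, len(order))
    p_ch = _chunks(posterior, len(order))
    x_ch = _chunks(excluded, 2) if excluded else [[], []]
    sink_group = {"theta": 0, "gamma": 0, "alpha": 1, "beta": 1}

    targets: list[BandTarget] = []
    for b_i, band in enumerate(order):
        f0, bw = BAND_OSCILLATORS[band]
        direction = BAND_DIRECTION[band]
        mult = 1.0
        if group == "high":
            mult = config.effect.get(band, {}).get(direction, 1.0)
        gain = config.coupling_gain * mult
        srcs = f_ch[b_i] if direction == "fp" else p_ch[b_i]
        recvs = p_ch[b_i] if direction == "fp" else f_ch[b_i]
        sinks = x_ch[sink_group.get(band, 0) % len(x_ch)]
        for k in range(min(len(srcs), len(recvs))):
            s, r = srcs[k], recvs[k]
            targets.append(BandTarget(s, r, f0, bw, gain))
            if sinks:
                # the relayed projection is weaker than the direct ones, as
                # secondary cortico-cortical projections are; it also keeps
                # the sink's intrinsic noise from being causally swamped
                x = sinks[k % len(sinks)]
                targets.append(BandTarget(r, x, f0, bw, 0.5 * gain))
                targets.append(BandTarget(s, x, f0, bw, gain))
    used_sinks = sorted({bt.target for bt in targets} & set(excluded))
    return targets, used_sinks


def _partition_frame(labels: list[str], frontal: list[int], posterior: list[int],
                     excluded: list[int]) -> pd.DataFrame:
    cluster = {}
    for idx in frontal:
        cluster[idx] = "frontal"
    for idx in posterior:
        cluster[idx] = "posterior"
    for idx in excluded:
        cluster[idx] = "temporo-central"
    return pd.DataFrame({
        "roi": labels,
        "label": labels,
        "hemisphere": ["-"] * len(labels),
        "cluster": [cluster[i] for i in range(len(labels))],
    })


def generate_cohort(config: CohortConfig) -> Cohort:
    """Generate a two-group cohort: low group from the full-gain model, high
    group from the attenuated model, per-subject innovations independently
    seeded from ``config.seed``."""
    if config.n_low < 2 or config.n_high < 2:
        raise ValueError("each group needs at least 2 subjects")
    if config.n_samples <= 10 * config.order:
        raise ValueError("duration_s * fs must exceed 10x the model order")

    if config.n_rois == 68:
        from .dirindex import load_default_atlas

        atlas = load_default_atlas()
        labels = list(atlas["label"])
        frontal = [i for i, c in enumerate(atlas["cluster"]) if c == "frontal"]
        posterior = [i for i, c in enumerate(atlas["cluster"]) if c == "posterior"]
        excluded = [i for i, c in enumerate(atlas["cluster"])
                    if c == "temporo-central"]
        partition = atlas[["roi", "label", "hemisphere", "cluster"]].copy()
    else:
        labels = [f"R{i + 1:02d}" for i in range(config.n_rois)]
        frontal, posterior, excluded = default_partition_indices(config.n_rois)
        partition = _partition_frame(labels, frontal, posterior, excluded)

    models = {}
    for group in ("low", "high"):
        targets, sinks = _cohort_band_targets(config, frontal, posterior,
                                              excluded, group)
        # sink regions carry higher intrinsic noise so that no channel's
        # spectrum is causally swamped (keeps pairwise GC monotone in gain)
        noise_scale = np.ones(config.n_rois)
        noise_scale[sinks] = config.sink_noise_scale
        models[group] = make_var_model(
            config.n_rois, targets, group_effect=1.0, seed=config.seed,
            fs=config.fs, order=config.order, noise_scale=noise_scale,
        )

    root = np.random.default_rng(config.seed)
    subject_seeds = root.integers(0, 2 ** 31 - 1, size=config.n_low + config.n_high)
    subjects: list[TimeSeriesSet] = []
    groups: list[str] = []
    k = 0
    for group, n in (("low", config.n_low), ("high", config.n_high)):
        for s in range(n):
            sid = f"sub-{group}{s + 1:03d}"
            ts = simulate_var(models[group], config.n_samples,
                              int(subject_seeds[k]), subject_id=sid,
                              roi_labels=labels)
            subjects.append(ts.standardized())
            groups.append(group)
            k += 1
    return Cohort(subjects, groups, partition=partition, true_models=models)


# ---------------------------------------------------------------------------
# on-disk interchange: TSV time series + CSV manifest + JSON sidecar
# ---------------------------------------------------------------------------

def write_cohort(cohort: Cohort, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for ts, group in zip(cohort.subjects, cohort.groups):
        path = out_dir / f"{ts.subject_id}.tsv"
        pd.DataFrame(ts.data.T, columns=ts.roi_labels).to_csv(
            path, sep="\t", index=False, float_format="%.6g")
        rows.append({"subject_id": ts.subject_id, "group": group,
                     "fs": ts.fs, "path": path.name})
    pd.DataFrame(rows).to_csv(out_dir / "manifest.csv", index=False)
    if cohort.partition is not None:
        cohort.partition.to_csv(out_dir / "partition.tsv", sep="\t", index=False)
    if cohort.true_models:
        sidecar = {}
        for group, model in cohort.true_models.items():
            sidecar[group] = {
                "coeff": model.coeff.tolist(),
                "noise_cov": model.noise_cov.tolist(),
                "fs": model.fs,
                "band_targets": [list(bt) for bt in model.band_targets],
            }
        (out_dir / "true_models.json").write_text(json.dumps(sidecar))
    return out_dir


def read_cohort(in_dir: str | Path) -> Cohort:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "manifest.csv")
    subjects, groups = [], []
    for row in manifest.itertuples():
        df = pd.read_csv(in_dir / row.path, sep="\t")
        subjects.append(TimeSeriesSet(row.subject_id, float(row.fs),
                                      df.to_numpy().T, list(df.columns)))
        groups.append(row.group)
    partition = None
    part_path = in_dir / "partition.tsv"
    if part_path.exists():
        partition = pd.read_csv(part_path, sep="\t")
    true_models = {}
    sidecar = in_dir / "true_models.json"
    if sidecar.exists():
        raw = json.loads(sidecar.read_text())
        for group, spec in raw.items():
            true_models[group] = VarModelSpec(
                coeff=np.asarray(spec["coeff"]),
                noise_cov=np.asarray(spec["noise_cov"]),
                fs=spec["fs"],
                band_targets=tuple(BandTarget(*bt) for bt in spec["band_targets"]),
            )
    return Cohort(subjects, groups, partition=partition, true_models=true_models)
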