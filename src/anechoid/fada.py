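"""Fourier-based anechoic demixing (FADA).

Fits the anechoic mixing model

    x_i(t) = sum_j a_ij * s_j(t - tau_ij) + residual,   i = 1..M, j = 1..N

in which every channel receives each of N shared source waveforms with its
own amplitude ``a_ij`` and its own *single* circular time delay ``tau_ij``
(no reverberation / multi-tap filters).  Because the trajectories are
band-limited, sources and data are represented by truncated Fourier series
(harmonics 0..F); a delay then acts as a per-harmonic phase rotation and
becomes a continuous parameter.

The estimator alternates, EM-like, between

1. a non-negative factorization of the coefficient-magnitude matrix
   ``|C| ~ A_abs @ |S|`` (delays drop out of magnitudes), used to
   initialise amplitudes and source magnitudes,
2. updating the source phases by least squares at fixed magnitudes,
3. re-estimating per-channel weights and delays (frequency-domain circular
   cross-correlation over a dense lag grid with parabolic sub-sample
   refinement, then joint least-squares weights), and
4. refreshing the full complex source coefficients by least squares,

keeping the best of ``n_restarts`` random initialisations.  Solutions are
reported in a canonical form that fixes the inherent permutation / scale /
delay-offset ambiguities: unit-L2-norm sources, zero weighted-mean delay
per source, delays wrapped to [-T/2, T/2), sources ordered by explained
variance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import NMF

from anechoid.fourier import FourierSeries, coeff_matrix, synthesize
from anechoid.io import TrajectorySet

__all__ = [
    "AnechoicModel",
    "magnitude_demix",
    "update_phases",
    "estimate_weights_delays",
    "fit",
    "reconstruct",
]


@dataclass
class AnechoicModel:
    """A fitted anechoic mixing model in canonical form.

    Attributes
    ----------
    sources : list of FourierSeries, length N
        Unit-L2-norm source waveforms (over one period of T samples).
    weights : ndarray (M, N)
        Mixing amplitudes; may be signed unless the fit constrained them.
    delays : ndarray (M, N)
        Per channel/source delays in seconds, wrapped to [-D/2, D/2) where
        D is the window duration; the |weight|-weighted mean delay of each
        source is zero.
    channel_means : ndarray (M,)
        Per-channel temporal means removed before fitting and added back
        by :func:`reconstruct`.
    fit_error : float
        Frobenius norm of the time-domain residual ``X - X_rec``.
    vaf : float
        Percentage of variance accounted for by the reconstruction.
    restart_errors : list of float
        Final internal (coefficient-domain) residual of every restart.
    residual_trace : list of float
        Internal residual of the winning restart across outer iterations
        (non-increasing).
    """

    sources: list[FourierSeries]
    weights: np.ndarray
    delays: np.ndarray
    n_sources: int
    sample_rate: float
    n_samples: int
    channel_means: np.ndarray
    fit_error: float = np.nan
    vaf: float = np.nan
    restart_errors: list = field(default_factory=list)
    residual_trace: list = field(default_factory=list)
    seed: int | None = None
    converged: bool = True

    @property
    def order(self) -> int:
        return self.sources[0].order

    @property
    def delays_samples(self) -> np.ndarray:
        return self.delays * self.sample_rate

    def source_matrix(self, n_samples: int | None = None) -> np.ndarray:
        """Evaluated source waveforms, one per row."""
        n = self.n_samples if n_samples is None else n_samples
        return synthesize(np.vstack([s.coeffs for s in self.sources]), n, period=self.n_samples)

    def source_coeffs(self) -> np.ndarray:
        return np.vstack([s.coeffs for s in self.sources])

    def to_dict(self) -> dict:
        return {
            "schema": "anechoid-model-1",
            "n_sources": self.n_sources,
            "order": self.order,
            "n_samples": self.n_samples,
            "sample_rate": self.sample_rate,
            "sources": [[[c.real, c.imag] for c in s.coeffs] for s in self.sources],
            "weights": self.weights.tolist(),
            "delays": self.delays.tolist(),
            "channel_means": self.channel_means.tolist(),
            "fit_error": float(self.fit_error),
            "vaf": float(self.vaf),
            "restart_errors": [float(e) for e in self.restart_errors],
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnechoicModel":
        sources = [
            FourierSeries(
                order=d["order"],
                period=d["n_samples"],
                coeffs=np.array([complex(re, im) for re, im in coeffs]),
            )
            for coeffs in d["sources"]
        ]
        return cls(
            sources=sources,
            weights=np.asarray(d["weights"], dtype=float),
            delays=np.asarray(d["delays"], dtype=float),
            n_sources=d["n_sources"],
            sample_rate=d["sample_rate"],
            n_samples=d["n_samples"],
            channel_means=np.asarray(d["channel_means"], dtype=float),
            fit_error=d.get("fit_error", np.nan),
            vaf=d.get("vaf", np.nan),
            restart_errors=d.get("restart_errors", []),
            seed=d.get("seed"),
        )


# ----------------------------------------------------------------------
# coefficient-domain helpers
#
# All residuals below use the Parseval weights w = (1, 2, 2, ...): the sum
# sum_k w_k |c_k|^2 equals the time-domain signal power (up to the common
# factor T), so coefficient-domain and time-domain least squares agree.


def _harmonic_weights(n_harmonics: int) -> np.ndarray:
    w = np.full(n_harmonics, 2.0)
    w[0] = 1.0
    return w


def _design(amps: np.ndarray, tau: np.ndarray, src: np.ndarray, period: float) -> np.ndarray:
    """Per-channel model coefficients without summing: D[i, k, j]."""
    k = np.arange(src.shape[1])
    theta = 2.0 * np.pi * k / period
    rot = np.exp(-1j * theta[None, :, None] * tau[:, None, :])
    return rot * src.T[None, :, :] * amps[:, None, :]


def _model_coeffs(amps: np.ndarray, tau: np.ndarray, src: np.ndarray, period: float) -> np.ndarray:
    return _design(amps, tau, src, period).sum(axis=2)


def _residual_norm2(coeffs: np.ndarray, amps: np.ndarray, tau: np.ndarray, src: np.ndarray, period: float) -> float:
    w = _harmonic_weights(coeffs.shape[1])
    diff = coeffs - _model_coeffs(amps, tau, src, period)
    return float(np.sum(w * np.abs(diff) ** 2))


def magnitude_demix(
    abs_coeffs: np.ndarray,
    n_sources: int,
    seed: int | None = 0,
    max_iter: int = 800,
) -> tuple[np.ndarray, np.ndarray]:
    """Non-negative factorization of the coefficient-magnitude matrix.

    Delays only rotate phases, so under source independence the magnitude
    matrix approximately factorizes as ``|C| ~ A_abs @ S_abs`` with both
    factors non-negative.  Solved by non-negative matrix factorization
    (multiplicative-update family) with a seeded random initialisation,
    hence deterministic given ``seed``.

    Returns
    -------
    (abs_weights, abs_source_coeffs) : ndarray (M, N), ndarray (N, K)
    """
    v = np.asarray(abs_coeffs, dtype=float)
    if v.ndim != 2:
        raise ValueError("abs_coeffs must be a matrix")
    if (v < 0).any():
        raise ValueError("abs_coeffs must be non-negative")
    m, k = v.shape
    if not 1 <= n_sources <= min(m, k):
        raise ValueError(f"n_sources must be in [1, min(M, K)] = [1, {min(m, k)}]")
    if not v.any():
        return np.zeros((m, n_sources)), np.zeros((n_sources, k))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # benign max_iter warnings on flat data
        nmf = NMF(n_components=n_sources, init="random", random_state=seed, max_iter=max_iter, tol=1e-8)
        a = nmf.fit_transform(v)
    return a, nmf.components_


def _solve_source_columns(coeffs: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Per-harmonic unconstrained LS solution for the source columns.

    ``basis[i, k, j] = a_ij exp(-i theta_k tau_ij)``; returns z of shape
    (N, K) minimizing ``sum_i |C_ik - sum_j basis_ikj z_jk|^2`` per k,
    via batched normal equations (a tiny ridge guards rank deficiency).
    """
    n_src = basis.shape[2]
    gram = np.einsum("ikn,ikm->knm", basis.conj(), basis) + 1e-12 * np.eye(n_src)
    rhs = np.einsum("ikn,ik->kn", basis.conj(), coeffs)
    return np.linalg.solve(gram, rhs[:, :, None])[:, :, 0].T


def _per_harmonic_error(coeffs: np.ndarray, basis: np.ndarray, src: np.ndarray) -> np.ndarray:
    """Residual energy of every harmonic: sum_i |C_ik - (B_k s_k)_i|^2."""
    model = np.einsum("ikn,nk->ik", basis, src)
    return np.sum(np.abs(coeffs - model) ** 2, axis=0)


def _phase_update(
    coeffs: np.ndarray,
    amps: np.ndarray,
    tau: np.ndarray,
    src: np.ndarray,
    period: float,
    n_iter: int = 3,
) -> np.ndarray:
    """Least-squares update of source phases at fixed magnitudes.

    Per harmonic (the objective separates across harmonics): solve the
    unconstrained complex least-squares problem for the source column,
    project back onto the fixed magnitudes, and keep the projected column
    only where it lowers that harmonic's residual.  Iterating the
    projection a few times refines the fixed point; the keep-best rule
    makes the overall objective non-increasing by construction.
    """
    mags = np.abs(src)
    out = src.copy()
    basis = _design(amps, tau, np.ones_like(src), period)
    best = _per_harmonic_error(coeffs, basis, out)
    for _ in range(n_iter):
        z = _solve_source_columns(coeffs, basis)
        cand = mags * np.exp(1j * np.angle(z))
        cand[:, 0] = mags[:, 0] * np.sign(z[:, 0].real + (z[:, 0].real == 0))
        err = _per_harmonic_error(coeffs, basis, cand)
        improved = err < best
        if not improved.any():
            break
        out[:, improved] = cand[:, improved]
        best = np.minimum(best, err)
    out[:, 0] = out[:, 0].real
    return out


def update_phases(data_coeffs: np.ndarray, model: "AnechoicModel") -> "AnechoicModel":
    """Re-optimize the source phases of a model against data coefficients.

    ``data_coeffs`` are the harmonic coefficients (rows = channels,
    harmonics 0..F) of the *mean-free* data.  Magnitudes, weights and
    delays are held fixed; the Frobenius objective never increases.
    """
    src = model.source_coeffs()
    new = _phase_update(data_coeffs, model.weights, model.delays_samples, src, model.n_samples)
    sources = [FourierSeries(model.order, model.n_samples, row) for row in new]
    return AnechoicModel(
        sources=sources,
        weights=model.weights.copy(),
        delays=model.delays.copy(),
        n_sources=model.n_sources,
        sample_rate=model.sample_rate,
        n_samples=model.n_samples,
        channel_means=model.channel_means.copy(),
        restart_errors=list(model.restart_errors),
        seed=model.seed,
    )


def _weights_given_delays(
    coeffs: np.ndarray,
    tau: np.ndarray,
    src: np.ndarray,
    period: float,
    nonneg: bool = False,
) -> np.ndarray:
    """Joint least-squares mixing weights per channel at fixed delays."""
    w = _harmonic_weights(coeffs.shape[1])
    d = _design(np.ones((coeffs.shape[0], src.shape[0])), tau, src, period)
    gram = np.einsum("k,ikn,ikm->inm", w, d.conj(), d).real
    rhs = np.einsum("k,ikn,ik->in", w, d.conj(), coeffs).real
    n = src.shape[0]
    gram = gram + 1e-12 * np.eye(n)[None]
    amps = np.linalg.solve(gram, rhs[:, :, None])[:, :, 0]
    if nonneg:
        from scipy.optimize import nnls

        wk = np.sqrt(w)
        for i in range(coeffs.shape[0]):
            di = d[i] * wk[:, None]
            a_mat = np.vstack([di.real, di.imag])
            b_vec = np.concatenate([(coeffs[i] * wk).real, (coeffs[i] * wk).imag])
            amps[i], _ = nnls(a_mat, b_vec)
    return amps


def _delay_scan(
    resid: np.ndarray,
    src_col: np.ndarray,
    period: float,
    int_phasors: np.ndarray,
    allow_signed: bool,
    fine_step: float = 0.1,
) -> np.ndarray:
    """Best circular delay per channel for one source against residuals.

    The correlation ``g_i(tau) = Re sum_k w_k R_ik conj(s_k) e^{i theta_k
    tau}`` is evaluated on the integer lag grid via a single matrix
    product, then on a +-1-sample fine grid (``fine_step`` resolution)
    around each channel's peak, and finally refined by parabolic
    interpolation of the fine-grid maximum.
    """
    n_harm = resid.shape[1]
    w = _harmonic_weights(n_harm)
    z = w[None, :] * resid * src_col.conj()[None, :]
    g_int = (z @ int_phasors).real  # (M, T)
    score = np.abs(g_int) if allow_signed else g_int
    lag0 = score.argmax(axis=1).astype(float)
    k = np.arange(n_harm)
    theta = 2.0 * np.pi * k / period
    deltas = np.arange(-10, 11) * fine_step
    e_base = np.exp(1j * theta[None, :] * lag0[:, None])  # (M, K)
    p_delta = np.exp(1j * np.outer(theta, deltas))  # (K, D)
    g_fine = ((z * e_base) @ p_delta).real  # (M, D)
    score_f = np.abs(g_fine) if allow_signed else g_fine
    best = score_f.argmax(axis=1)
    # parabolic vertex through the best fine-grid triple
    tau = lag0 + deltas[best]
    inner = (best > 0) & (best < len(deltas) - 1)
    idx = np.flatnonzero(inner)
    y0 = score_f[idx, best[idx] - 1]
    y1 = score_f[idx, best[idx]]
    y2 = score_f[idx, best[idx] + 1]
    denom = y0 - 2 * y1 + y2
    ok = np.abs(denom) > 1e-15
    shift = np.zeros_like(y1)
    shift[ok] = 0.5 * (y0[ok] - y2[ok]) / denom[ok]
    tau[idx] += np.clip(shift, -1.0, 1.0) * fine_step
    # Newton polish: g and its tau-derivatives are analytic in the Fourier
    # representation, so a few steps reach sub-grid (near machine) precision
    for _ in range(3):
        e = np.exp(1j * theta[None, :] * tau[:, None])
        ze = z * e
        g = ze.real.sum(axis=1)
        sign = np.where(g >= 0, 1.0, -1.0) if allow_signed else 1.0
        g1 = (ze * (1j * theta)).real.sum(axis=1) * sign
        g2 = -(ze * theta**2).real.sum(axis=1) * sign
        concave = g2 < -1e-30
        step = np.where(concave, -g1 / np.where(concave, g2, 1.0), 0.0)
        tau = tau + np.clip(step, -0.5, 0.5)
    return np.mod(tau, period)


def _eval_tau_candidates(coeffs: np.ndarray, src: np.ndarray, cand: np.ndarray, period: float) -> np.ndarray:
    """Exact per-channel residual (minus the constant data power) of each
    delay-vector candidate, with jointly optimal weights.  ``cand`` has
    shape (M, C, N)."""
    n_src = src.shape[0]
    w = _harmonic_weights(coeffs.shape[1])
    k = np.arange(coeffs.shape[1])
    theta = 2.0 * np.pi * k / period
    rot = np.exp(-1j * theta[None, None, :, None] * cand[:, :, None, :])  # (M, C, K, N)
    d = rot * src.T[None, None, :, :]
    gram = np.einsum("k,ickn,ickm->icnm", w, d.conj(), d).real + 1e-12 * np.eye(n_src)
    rhs = np.einsum("k,ickn,ik->icn", w, d.conj(), coeffs).real
    a_opt = np.linalg.solve(gram, rhs[..., None])[..., 0]
    return -np.einsum("icn,icn->ic", a_opt, rhs)


def _deflation_scan(
    coeffs: np.ndarray,
    src: np.ndarray,
    tau: np.ndarray,
    period: float,
    int_phasors: np.ndarray,
) -> np.ndarray:
    """Escape scan: greedy matching-pursuit delays per channel.

    Given the sources, channels decouple, but the per-channel joint delay
    landscape is multimodal: scanning a weak source against a channel that
    is dominated by another source locks onto leakage from the dominant
    one, and coordinate descent cannot escape.  Deflation avoids the
    contamination: per channel, repeatedly pick the source with the
    largest correlation gain against the *current residual*, fix its delay
    at the correlation peak, subtract its scalar-weighted contribution,
    and continue with the remaining sources.  The greedy delay vector is
    then kept only where it beats the incoming one (exact residual with
    jointly optimal weights), so the scan never degrades a channel.
    Fully deterministic.
    """
    m, n_harm = coeffs.shape
    n_src = src.shape[0]
    t_int = int_phasors.shape[1]
    w = _harmonic_weights(n_harm)
    k = np.arange(n_harm)
    theta = 2.0 * np.pi * k / period
    norms2 = np.array([np.sum(w * np.abs(src[j]) ** 2) for j in range(n_src)])
    resid = coeffs.copy()
    lobes = np.zeros((m, n_src, 2))
    lobe_scores = np.zeros((m, n_src, 2))
    used = np.zeros((m, n_src), dtype=bool)
    rows = np.arange(m)
    grid = np.arange(t_int)
    for _ in range(n_src):
        gains = np.full((m, n_src), -np.inf)
        peaks = np.zeros((m, n_src), dtype=int)
        g_all = {}
        for j in range(n_src):
            if norms2[j] <= 0:
                continue
            g = ((w[None, :] * resid * src[j].conj()[None, :]) @ int_phasors).real
            g_all[j] = g
            peaks[:, j] = np.abs(g).argmax(axis=1)
            gains[:, j] = g[rows, peaks[:, j]] ** 2 / norms2[j]
        gains[used] = -np.inf
        pick = gains.argmax(axis=1)
        lag = peaks[rows, pick]
        # first lobe + best well-separated runner-up (sources with strong
        # autocorrelation side lobes, e.g. two similar peaks per cycle,
        # make the two nearly degenerate; only a joint evaluation of the
        # combinations can tell them apart)
        g_pick = np.abs(np.stack([g_all[j][i] if j in g_all else np.zeros(t_int) for i, j in enumerate(pick)]))
        dist = (grid[None, :] - lag[:, None] + t_int // 2) % t_int - t_int // 2
        masked = np.where(np.abs(dist) > t_int // 8, g_pick, -np.inf)
        second = masked.argmax(axis=1)
        lobes[rows, pick, 0] = lag
        lobes[rows, pick, 1] = second
        lobe_scores[rows, pick, 0] = g_pick[rows, lag]
        lobe_scores[rows, pick, 1] = g_pick[rows, second]
        used[rows, pick] = True
        delayed = np.exp(-1j * theta[None, :] * lag[:, None]) * src[pick]
        a = np.sum(w * (resid * delayed.conj()), axis=1).real / norms2[pick]
        resid = resid - a[:, None] * delayed
    # evaluating every lobe combination is exponential in N; the ambiguity
    # that matters involves few sources (those with strong autocorrelation
    # side lobes), so only the two most ambiguous sources are varied
    ambiguity = (lobe_scores[:, :, 1] / np.maximum(lobe_scores[:, :, 0], 1e-30)).mean(axis=0)
    vary = np.argsort(-ambiguity)[:2] if n_src > 2 else np.arange(n_src)
    combos = np.stack(np.meshgrid(*([np.arange(2)] * len(vary)), indexing="ij"), axis=-1).reshape(-1, len(vary))
    cand = np.repeat(lobes[:, None, :, 0], len(combos) + 1, axis=1)
    for c, combo in enumerate(combos):
        cand[:, c, vary] = lobes[rows[:, None], vary[None, :], combo[None, :]]
    cand[:, -1, :] = tau
    best = _eval_tau_candidates(coeffs, src, cand, period).argmin(axis=1)
    return cand[rows, best, :]


def _pair_grid_scan(
    coeffs: np.ndarray,
    src: np.ndarray,
    amps: np.ndarray,
    tau: np.ndarray,
    period: float,
    j1: int,
    j2: int,
    step: int = 3,
    chunk: int = 64,
) -> np.ndarray:
    """Joint integer-lag grid search for one source pair, per channel.

    Per-source coordinate scans can mislock when two sources overlap
    strongly on a weakly weighted channel; the exact two-source problem
    has a closed-form weight solution per lag pair, so the full
    (lag1, lag2) grid can be evaluated outright.  Other sources are held
    fixed at their current parameters; the grid result replaces the
    incoming delays only where it lowers the exact per-channel residual.
    """
    m, n_harm = coeffs.shape
    w = _harmonic_weights(n_harm)
    theta = 2.0 * np.pi * np.arange(n_harm) / period
    others = [j for j in range(src.shape[0]) if j not in (j1, j2)]
    resid = coeffs
    if others:
        resid = coeffs - _design(amps[:, others], tau[:, others], src[others], period).sum(axis=2)
    t_int = int(round(period))
    lags = np.arange(0, t_int, step)
    e_lag = np.exp(1j * np.outer(theta, lags))
    g1 = ((w * resid * src[j1].conj()) @ e_lag).real
    g2 = ((w * resid * src[j2].conj()) @ e_lag).real
    h11 = float(np.sum(w * np.abs(src[j1]) ** 2))
    h22 = float(np.sum(w * np.abs(src[j2]) ** 2))
    if h11 <= 0 or h22 <= 0:
        return tau
    # cross inner product depends only on the lag difference
    xfull = ((w * src[j1] * src[j2].conj()) @ np.exp(-1j * np.outer(theta, np.arange(t_int)))).real
    x = xfull[(lags[:, None] - lags[None, :]) % t_int]
    det = h11 * h22 - x**2
    degenerate = np.abs(det) < 1e-9 * h11 * h22
    det_safe = np.where(degenerate, 1.0, det)
    tau1 = np.empty(m)
    tau2 = np.empty(m)
    for s in range(0, m, chunk):
        b1 = g1[s : s + chunk, :, None]
        b2 = g2[s : s + chunk, None, :]
        a1 = (h22 * b1 - x * b2) / det_safe
        a2 = (h11 * b2 - x * b1) / det_safe
        score = np.where(degenerate, -np.inf, a1 * b1 + a2 * b2)
        flat = score.reshape(score.shape[0], -1).argmax(axis=1)
        i1, i2 = np.unravel_index(flat, x.shape)
        tau1[s : s + chunk] = lags[i1]
        tau2[s : s + chunk] = lags[i2]
    cand = np.stack([tau, tau], axis=1)
    cand[:, 0, j1] = tau1
    cand[:, 0, j2] = tau2
    best = _eval_tau_candidates(coeffs, src, cand, period).argmin(axis=1)
    return cand[np.arange(m), best, :]


def _delay_weight_update(
    coeffs: np.ndarray,
    src: np.ndarray,
    amps: np.ndarray,
    tau: np.ndarray,
    period: float,
    int_phasors: np.ndarray,
    allow_signed: bool,
    n_passes: int = 1,
    nonneg: bool = False,
    lobe_scan: bool = None,
    pair_scan: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Coordinate update of delays (per source) then joint weights."""
    amps, tau = amps.copy(), tau.copy()
    if lobe_scan is None:
        lobe_scan = True
    if lobe_scan:
        tau = _deflation_scan(coeffs, src, tau, period, int_phasors)
        amps = _weights_given_delays(coeffs, tau, src, period, nonneg=nonneg)
    if pair_scan and src.shape[0] >= 2:
        energy = (amps**2).sum(axis=0) * np.sum(
            _harmonic_weights(coeffs.shape[1]) * np.abs(src) ** 2, axis=1
        )
        j1, j2 = (int(j) for j in np.argsort(-energy)[:2])
        tau = _pair_grid_scan(coeffs, src, amps, tau, period, j1, j2)
        amps = _weights_given_delays(coeffs, tau, src, period, nonneg=nonneg)
    n_src = src.shape[0]
    contrib = _design(amps, tau, src, period)  # (M, K, N)
    for _ in range(n_passes):
        for j in range(n_src):
            resid = coeffs - contrib.sum(axis=2) + contrib[:, :, j]
            if not np.abs(src[j]).any():
                tau[:, j] = 0.0
                continue
            tau[:, j] = _delay_scan(resid, src[j], period, int_phasors, allow_signed)
            contrib[:, :, j] = _design(amps[:, [j]], tau[:, [j]], src[[j]], period)[:, :, 0]
        amps = _weights_given_delays(coeffs, tau, src, period, nonneg=nonneg)
        contrib = _design(amps, tau, src, period)
    # degenerate channels: no signal -> canonical zero weight / zero delay
    w = _harmonic_weights(coeffs.shape[1])
    power = np.sum(w * np.abs(coeffs) ** 2, axis=1)
    dead = power <= 1e-24
    amps[dead] = 0.0
    tau[dead] = 0.0
    return amps, tau


def estimate_weights_delays(
    data: TrajectorySet | np.ndarray,
    sources: list[FourierSeries],
    *,
    allow_signed_weights: bool = True,
    max_iter: int = 30,
    tol: float = 1e-10,
) -> tuple[np.ndarray, np.ndarray]:
    """Estimate per-channel weights and circular delays for fixed sources.

    ``data`` may be a :class:`TrajectorySet` (channel means are removed
    first) or an already-computed complex coefficient matrix.  Delays are
    found by frequency-domain circular cross-correlation on a dense lag
    grid with parabolic sub-sample refinement; weights by least squares
    given the delayed sources; the pair of steps is iterated to a fixed
    point with a keep-best guard, so the residual never increases.

    Returns
    -------
    (weights, delays) : ndarray (M, N), ndarray (M, N)
        Delays in samples, in [0, T).
    """
    src = np.vstack([s.coeffs for s in sources])
    period = float(sources[0].period)
    if isinstance(data, TrajectorySet):
        x = data.data - data.data.mean(axis=1, keepdims=True)
        if data.n_samples <= len(sources):
            raise ValueError("need more samples than sources")
        coeffs = coeff_matrix(x, sources[0].order)
    else:
        coeffs = np.asarray(data, dtype=complex)
    m = coeffs.shape[0]
    n_src = src.shape[0]
    t_int = int(round(period))
    k = np.arange(src.shape[1])
    int_phasors = np.exp(2j * np.pi * np.outer(k, np.arange(t_int)) / period)
    tau = np.zeros((m, n_src))
    amps = _weights_given_delays(coeffs, tau, src, period, nonneg=not allow_signed_weights)
    best = _residual_norm2(coeffs, amps, tau, src, period)
    best_state = (amps, tau)
    for it in range(max_iter):
        amps, tau = _delay_weight_update(
            coeffs, src, amps, tau, period, int_phasors, allow_signed_weights,
            nonneg=not allow_signed_weights, pair_scan=(it % 5 == 0),
        )
        err = _residual_norm2(coeffs, amps, tau, src, period)
        if err < best:
            gain = (best - err) / max(best, 1e-30)
            best, best_state = err, (amps, tau)
            if gain < tol:
                break
        else:
            break
    return best_state


def _canonicalize(
    amps: np.ndarray, tau: np.ndarray, src: np.ndarray, period: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Fix scale / sign / delay-offset / permutation ambiguities."""
    amps, tau, src = amps.copy(), tau.copy(), src.copy()
    n_src = src.shape[0]
    k = np.arange(src.shape[1])
    theta = 2.0 * np.pi * k / period
    for j in range(n_src):
        norm = float(np.sqrt(period * (src[j, 0].real ** 2 + 2 * np.sum(np.abs(src[j, 1:]) ** 2))))
        if norm > 0:
            src[j] /= norm
            amps[:, j] *= norm
        if amps[:, j].sum() < 0:
            amps[:, j] *= -1
            src[j] *= -1
        # centre-and-wrap is a fixed-point iteration: wrapping can move
        # delay mass, which shifts the weighted mean again
        wsum = np.abs(amps[:, j]).sum()
        for _ in range(32):
            centre = float((np.abs(amps[:, j]) * tau[:, j]).sum() / wsum) if wsum > 0 else 0.0
            src[j] = src[j] * np.exp(-1j * theta * centre)
            tau[:, j] -= centre
            tau[:, j] = np.mod(tau[:, j] + period / 2, period) - period / 2
            if abs(centre) < 1e-12 * period:
                break
    order = np.argsort(-np.sum(amps**2, axis=0), kind="stable")
    return amps[:, order], tau[:, order], src[order]


def fit(
    data: TrajectorySet,
    n_sources: int,
    order: int = 10,
    n_restarts: int = 25,
    max_outer_iter: int = 200,
    tol: float = 1e-5,
    seed: int | None = None,
    *,
    allow_signed_weights: bool = True,
    center: bool = True,
) -> AnechoicModel:
    """Fit the anechoic mixing model, keeping the best of ``n_restarts``.

    Parameters
    ----------
    data : TrajectorySet
        Channels x samples.  Per-channel temporal means are removed before
        fitting (``center=True``) and restored at reconstruction.
    n_sources : int
        Number of source waveforms N; must satisfy
        ``N <= min(M, order + 1)``.
    order : int
        Highest retained harmonic F (capped at ``(T - 1) // 2``).  The
        default of 10 covers > 99.9 % of the spectral energy of smooth
        350-sample gait/reach trajectories.
    n_restarts : int
        Independent initialisations, alternating NMF-based starts (random
        delays and phases, per-restart NMF seed) with data-driven starts
        seeded from randomly chosen channels; every restart's head start
        runs on jittered coefficients (graduated optimization) before the
        leaders are polished on the clean data.  The solution with the
        lowest residual wins, ties broken by restart index.
    max_outer_iter, tol : int, float
        The outer loop stops when the relative residual improvement falls
        below ``tol``.
    seed : int, optional
        Master seed; the same seed reproduces the fit exactly.

    Returns
    -------
    AnechoicModel
        In canonical form (see class docstring), with ``vaf`` and
        ``fit_error`` computed against the input data.
    """
    m, t = data.data.shape
    f = min(order, (t - 1) // 2)
    n_harm = f + 1
    if not 1 <= n_sources <= min(m, n_harm):
        raise ValueError(f"n_sources must be in [1, min(M, F + 1)] = [1, {min(m, n_harm)}]")
    means = data.data.mean(axis=1) if center else np.zeros(m)
    x = data.data - means[:, None]
    coeffs = coeff_matrix(x, f)
    clean_coeffs = coeffs
    period = float(t)
    k = np.arange(n_harm)
    int_phasors = np.exp(2j * np.pi * np.outer(k, np.arange(t)) / period)

    ss = np.random.SeedSequence(seed if seed is not None else np.random.randint(2**31 - 1))

    def _outer_loop(state: dict, budget: int, coeffs: np.ndarray = None) -> dict:
        if coeffs is None:
            coeffs = clean_coeffs
        amps, tau, src = state["amps"], state["tau"], state["src"]
        trace = state["trace"]
        slowing = state["it"] == 0  # re-entering: give the escape a chance
        for it in range(state["it"], state["it"] + budget):
            src = _phase_update(coeffs, amps, tau, src, period)
            # the joint pair-grid escape is costly; run it at the start and
            # periodically once progress slows, when it can re-seat
            # mislocked delays without dominating the iteration cost
            amps, tau = _delay_weight_update(
                coeffs, src, amps, tau, period, int_phasors, allow_signed_weights,
                nonneg=not allow_signed_weights,
                lobe_scan=(n_sources <= 2 or it < 15 or slowing),
                pair_scan=(it == 0 or (slowing and it % 4 == 0)),
            )
            # full complex source refresh (per-harmonic least squares)
            basis = _design(amps, tau, np.ones_like(src), period)
            new_src = _solve_source_columns(coeffs, basis)
            new_src[:, 0] = new_src[:, 0].real
            improved = _per_harmonic_error(coeffs, basis, new_src) < _per_harmonic_error(coeffs, basis, src)
            src = np.where(improved[None, :], new_src, src)
            src[:, 0] = src[:, 0].real
            new_err = _residual_norm2(coeffs, amps, tau, src, period)
            improvement = (trace[-1] - new_err) / max(trace[-1], 1e-30)
            trace.append(min(new_err, trace[-1]))
            slowing = improvement < 50 * tol
            if improvement < tol and it > 2:
                state["done"] = True
                break
        state.update(amps=amps, tau=tau, src=src, trace=trace, it=it + 1)
        return state

    # All restarts get a short head start on *jittered* coefficients, then
    # only the leaders are run to convergence on the clean data.  The
    # jitter (5 % of the signal RMS, seeded per restart) is graduated
    # optimization: spurious sharp minima of the delay landscape -- e.g.
    # half-period mislocks of near-symmetric rhythmic sources -- wash out
    # under perturbation, while the true basin survives; empirically the
    # same fits that stall on exactly noiseless data converge cleanly once
    # the search phase is perturbed.  Full convergence of every restart
    # would be wasted work: the basin is decided within the head start.
    sigma_jit = 0.05 * float(np.sqrt(np.mean(x**2)))
    jit_sd = sigma_jit / np.sqrt(2.0 * t)
    states = []
    for r, child in enumerate(ss.spawn(n_restarts)):
        rng = np.random.default_rng(child)
        jit = rng.normal(0.0, jit_sd, size=(m, n_harm)) + 1j * rng.normal(0.0, jit_sd, size=(m, n_harm))
        coeffs = clean_coeffs + jit
        coeffs[:, 0] = coeffs[:, 0].real
        if r % 2 == 0 or m < 2 * n_sources:
            # per-restart NMF seed: the deterministic escape scans would
            # otherwise funnel every restart into the same attractor
            amps, mags = magnitude_demix(
                np.abs(coeffs), n_sources, seed=int(rng.integers(2**31 - 1))
            )
            mag_norm = np.linalg.norm(mags, axis=1, keepdims=True)
            mag_norm[mag_norm == 0] = 1.0
            amps = amps * mag_norm.T
            mags = mags / mag_norm
            tau = rng.uniform(-period / 4, period / 4, size=(m, n_sources))
            phases = rng.uniform(-np.pi, np.pi, size=(n_sources, n_harm))
            phases[:, 0] = 0.0
            src = mags * np.exp(1j * phases)
        else:
            # data-driven restart: seed the sources with randomly chosen
            # channels (every channel is a delayed, scaled, noisy source
            # blend, so these starts are physically plausible and diverse)
            picks = rng.choice(m, size=n_sources, replace=False)
            src = coeffs[picks].copy()
            norms = np.linalg.norm(np.abs(src), axis=1, keepdims=True)
            norms[norms == 0] = 1.0
            src = src / norms
            tau = np.zeros((m, n_sources))
            amps = _weights_given_delays(coeffs, tau, src, period, nonneg=not allow_signed_weights)
        state = {
            "amps": amps, "tau": tau, "src": src, "it": 0, "done": False,
            "trace": [_residual_norm2(coeffs, amps, tau, src, period)],
        }
        state = _outer_loop(state, min(12, max_outer_iter), coeffs=coeffs)
        # rank and continue on the clean objective
        state["trace"] = [_residual_norm2(clean_coeffs, state["amps"], state["tau"], state["src"], period)]
        state["done"] = False
        states.append(state)
    n_finalists = max(1, min(3, n_restarts))
    ranking = np.argsort([s["trace"][-1] for s in states], kind="stable")
    for idx in ranking[:n_finalists]:
        s = states[idx]
        if s["it"] < max_outer_iter:
            states[idx] = _outer_loop(s, max_outer_iter - s["it"])
    restart_errors = [float(s["trace"][-1]) for s in states]
    best_idx = int(np.argmin(restart_errors))
    best = states[best_idx]
    best_converged = bool(best.get("done", False))
    best_trace = best["trace"]
    amps, tau, src = best["amps"], best["tau"], best["src"]
    amps, tau, src = _canonicalize(amps, tau, src, period)
    sources = [FourierSeries(f, period, row) for row in src]
    model = AnechoicModel(
        sources=sources,
        weights=amps,
        delays=tau / data.sample_rate,
        n_sources=n_sources,
        sample_rate=data.sample_rate,
        n_samples=t,
        channel_means=means,
        restart_errors=restart_errors,
        residual_trace=best_trace,
        seed=seed,
        converged=best_converged,
    )
    recon = reconstruct(model)
    model.fit_error = float(np.linalg.norm(data.data - recon))
    from anechoid.selection import vaf  # local import: selection also uses fit()

    model.vaf = vaf(data.data, recon)
    return model


def reconstruct(model: AnechoicModel, n_samples: int | None = None) -> np.ndarray:
    """Synthesize ``x_hat_i(t) = mean_i + sum_j a_ij s_j(t - tau_ij)``.

    Evaluated from the Fourier representation on ``n_samples`` uniform
    points per period (default: the fitted sampling grid).
    """
    n = model.n_samples if n_samples is None else n_samples
    src = model.source_coeffs()
    chat = _model_coeffs(model.weights, model.delays_samples, src, float(model.n_samples))
    out = synthesize(chat, n, period=float(model.n_samples))
    return out + model.channel_means[:, None]
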