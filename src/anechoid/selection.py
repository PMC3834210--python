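"""Model selection: VAF, regression scree test, cross-validation, source alignment.

The number of movement primitives is chosen from the curve of variance
accounted for (VAF) versus model order N.  VAF compares the reconstruction
against the per-channel mean baseline:

    VAF = 100 * (1 - ||X - X_rec||_F^2 / ||X - X_bar||_F^2)

where ``X_bar`` repeats each row's temporal mean.  The scree criterion
fits ordinary least-squares lines to trailing segments of the curve
(dropping the leftmost point each round) and selects the smallest N whose
segment is statistically flat-linear: mean squared residual below a
threshold (applied on the 0-1 VAF scale) *and* slope below a saturation
bound.  Cross-validation splits by trial, freezes the training sources,
and re-estimates only weights and delays on the held-out trials.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from anechoid.fourier import FourierSeries, synthesize
from anechoid.io import TrajectorySet

__all__ = [
    "VafCurve",
    "vaf",
    "vaf_sweep",
    "scree_select",
    "cross_validate",
    "CrossValidationResult",
    "align_sources",
    "SourceAlignment",
]


@dataclass
class VafCurve:
    """VAF values indexed by the number of sources."""

    n_values: list[int]
    vaf: list[float]
    fit_refs: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.n_values) != len(self.vaf):
            raise ValueError("n_values and vaf must have the same length")
        if any(b <= a for a, b in zip(self.n_values, self.n_values[1:])):
            raise ValueError("n_values must be strictly increasing")

    def as_dict(self) -> dict:
        return {"n_values": list(self.n_values), "vaf": [float(v) for v in self.vaf]}


def vaf(x: np.ndarray, x_rec: np.ndarray) -> float:
    """Percentage of variance accounted for by a reconstruction.

    ``100 * (1 - ||X - X_rec||_F^2 / ||X - X_bar||_F^2)`` with ``X_bar``
    the row-means matrix.  100 for a perfect reconstruction, 0 for the
    mean-only reconstruction, negative when worse than the mean.
    """
    x = np.asarray(x, dtype=float)
    x_rec = np.asarray(x_rec, dtype=float)
    if x.shape != x_rec.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {x_rec.shape}")
    xbar = x.mean(axis=1, keepdims=True)
    denom = float(np.sum((x - xbar) ** 2))
    if denom == 0.0:
        raise ValueError("all rows are constant; VAF is undefined")
    return 100.0 * (1.0 - float(np.sum((x - x_rec) ** 2)) / denom)


def _sweep_seed(base: int | None, n: int) -> int | None:
    if base is None:
        return None
    return int(np.random.SeedSequence([base, n]).generate_state(1)[0] % (2**31 - 1))


def vaf_sweep(
    data: TrajectorySet,
    n_range: range | list[int] = range(1, 6),
    fit_config: dict | None = None,
) -> VafCurve:
    """Fit one best-of-restarts model per N and record its VAF.

    ``fit_config`` is forwarded to :func:`anechoid.fada.fit` (e.g.
    ``{"n_restarts": 25, "seed": 1}``); the seed is re-derived per N so the
    fits are independent but reproducible.
    """
    from anechoid.fada import fit

    cfg = dict(fit_config or {})
    base_seed = cfg.pop("seed", None)
    n_values, values, fits = [], [], []
    for n in n_range:
        model = fit(data, n, seed=_sweep_seed(base_seed, n), **cfg)
        n_values.append(int(n))
        values.append(model.vaf)
        fits.append(model)
    return VafCurve(n_values=n_values, vaf=values, fit_refs=fits)


def scree_select(
    curve: VafCurve,
    mse_threshold: float = 0.001,
    saturation_slope: float | None = 0.01,
) -> int | None:
    """Regression scree test: smallest N whose trailing segment is flat-linear.

    Starting from the full curve and dropping the leftmost point each
    round, an ordinary least-squares line is fitted to the remaining
    (N, VAF) points.  The smallest starting N whose segment has mean
    squared residual below ``mse_threshold`` is selected.  Residuals and
    slopes are computed on the 0-1 VAF scale so the documented threshold
    of 0.001 is meaningful regardless of whether the curve is stored in
    percent.

    A segment must also *saturate*: its slope (VAF fraction gained per
    added component) must stay below ``saturation_slope`` (default 0.01,
    i.e. < 1 VAF point per component).  Without this bound a steeply but
    perfectly linearly rising curve -- no elbow at all -- would pass the
    residual check trivially.  Pass ``saturation_slope=None`` to disable.

    Returns the selected N, or None when no trailing segment of at least
    three points qualifies (mirroring "the criterion did not provide a
    solution").
    """
    if len(curve.n_values) < 3:
        raise ValueError("scree test needs at least 3 points")
    n = np.asarray(curve.n_values, dtype=float)
    v = np.asarray(curve.vaf, dtype=float)
    if np.max(np.abs(v)) > 1.5:  # curve stored in percent, not fractions
        v = v / 100.0
    for start in range(len(n) - 2):
        nn, vv = n[start:], v[start:]
        slope, intercept = np.polyfit(nn, vv, 1)
        mse = float(np.mean((vv - (slope * nn + intercept)) ** 2))
        if mse < mse_threshold and (saturation_slope is None or abs(slope) < saturation_slope):
            return int(curve.n_values[start])
    return None


@dataclass
class CrossValidationResult:
    """Outcome of a by-trial train/test split."""

    test_curve: VafCurve
    train_curve: VafCurve
    models: list
    train_trials: list
    test_trials: list


def _split_trials(
    trial_ids: list, conditions: list | None, train_fraction: float, rng: np.random.Generator
) -> tuple[list, list]:
    """Split unique trials, stratified by condition when labels exist."""
    unique = list(dict.fromkeys(trial_ids))
    if conditions is not None:
        cond_of = {}
        for tid, cond in zip(trial_ids, conditions):
            cond_of.setdefault(tid, cond)
        strata: dict = {}
        for tid in unique:
            strata.setdefault(cond_of[tid], []).append(tid)
    else:
        strata = {None: unique}
    train: list = []
    for members in strata.values():
        members = list(members)
        rng.shuffle(members)
        n_train = max(1, int(round(train_fraction * len(members))))
        n_train = min(n_train, len(members) - 1) if len(members) > 1 else n_train
        train.extend(members[:n_train])
    train_set = set(train)
    test = [tid for tid in unique if tid not in train_set]
    return sorted(train, key=unique.index), sorted(test, key=unique.index)


def cross_validate(
    data: TrajectorySet,
    train_fraction: float = 0.8,
    n_range: range | list[int] = range(1, 6),
    fit_config: dict | None = None,
    seed: int | None = None,
) -> CrossValidationResult:
    """Fit sources on a train split of trials, score VAF on the held-out trials.

    The split keeps all channels of a trial together (and is stratified by
    condition label when present).  For each N the sources fitted on the
    training channels are frozen; only per-channel weights and delays are
    re-estimated on the test channels before computing the test VAF, so no
    information about the test trials enters source estimation.
    """
    from anechoid.fada import estimate_weights_delays, fit

    if data.trial_ids is None:
        raise ValueError("cross-validation requires trial_ids")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie in (0, 1)")
    unique = list(dict.fromkeys(data.trial_ids))
    if len(unique) < 5:
        raise ValueError(f"need at least 5 trials, got {len(unique)}")
    rng = np.random.default_rng(seed)
    train_ids, test_ids = _split_trials(data.trial_ids, data.conditions, train_fraction, rng)
    trial_arr = np.asarray(data.trial_ids, dtype=object)
    train_rows = np.flatnonzero(np.isin(trial_arr, np.asarray(train_ids, dtype=object)))
    test_rows = np.flatnonzero(np.isin(trial_arr, np.asarray(test_ids, dtype=object)))
    train_set, test_set = data.subset(train_rows), data.subset(test_rows)

    cfg = dict(fit_config or {})
    base_seed = cfg.pop("seed", seed)
    n_values, train_vaf, test_vaf, models = [], [], [], []
    test_means = test_set.data.mean(axis=1, keepdims=True)
    for n in n_range:
        model = fit(train_set, n, seed=_sweep_seed(base_seed, n), **cfg)
        weights, delays = estimate_weights_delays(test_set, model.sources)
        src = model.source_coeffs()
        from anechoid.fada import _model_coeffs  # noqa: PLC2701 - shared internal

        chat = _model_coeffs(weights, delays, src, float(model.n_samples))
        recon = synthesize(chat, test_set.n_samples, period=float(model.n_samples)) + test_means
        n_values.append(int(n))
        train_vaf.append(model.vaf)
        test_vaf.append(vaf(test_set.data, recon))
        models.append(model)
    return CrossValidationResult(
        test_curve=VafCurve(n_values, test_vaf),
        train_curve=VafCurve(n_values, train_vaf, fit_refs=models),
        models=models,
        train_trials=train_ids,
        test_trials=test_ids,
    )


@dataclass
class SourceAlignment:
    """Pairing of two source sets with per-pair circular shift and correlation.

    ``permutation[i]`` is the index in set B matched to source i of set A;
    ``shifts[i]`` is the circular lag (samples) by which B lags A, i.e.
    ``roll(b, -shift)`` best matches ``a``; ``correlations[i]`` is the
    signed Pearson correlation after alignment (negative when the match is
    a sign-flipped one).
    """

    permutation: np.ndarray
    shifts: np.ndarray
    correlations: np.ndarray

    @property
    def mean_abs_correlation(self) -> float:
        return float(np.mean(np.abs(self.correlations)))


def _as_matrix(sources) -> np.ndarray:
    if isinstance(sources, np.ndarray):
        return np.atleast_2d(sources)
    rows = []
    for s in sources:
        if isinstance(s, FourierSeries):
            rows.append(synthesize(s.coeffs[None, :], int(round(s.period)), period=s.period)[0])
        else:
            rows.append(np.asarray(s, dtype=float))
    return np.vstack(rows)


def _best_shift_corr(a: np.ndarray, b: np.ndarray, method: str) -> tuple[int, float]:
    """Circular lag of b w.r.t. a and the post-alignment signed correlation."""
    t = len(a)
    az = a - a.mean()
    bz = b - b.mean()
    denom = np.sqrt((az**2).sum() * (bz**2).sum())
    if denom == 0:
        return 0, 0.0
    if method == "peak":
        shift, corr = 0, 0.0
        for sgn in (1.0, -1.0):  # a sign-flipped match aligns the flipped peak
            cand = int(np.argmax(sgn * b)) - int(np.argmax(a))
            c = float(np.dot(az, np.roll(bz, -cand)) / denom)
            if abs(c) > abs(corr):
                shift, corr = cand, c
    else:  # max-|correlation| over all integer circular lags, via FFT
        # xcorr[l] = sum_t az[t] bz[t - l]; roll(bz, l) then matches az
        xcorr = np.fft.irfft(np.fft.rfft(az) * np.conj(np.fft.rfft(bz)), n=t)
        l_pos = int(np.argmax(xcorr))
        l_neg = int(np.argmin(xcorr))
        # prefer the sign-preserving alignment on near-ties (e.g. an
        # antisymmetric waveform correlates +-1 at half-period offsets)
        if xcorr[l_pos] >= -xcorr[l_neg] - 1e-9 * abs(xcorr[l_pos]):
            l_star = l_pos
        else:
            l_star = l_neg
        corr = float(np.dot(az, np.roll(bz, l_star)) / denom)
        shift = -l_star
    shift = (shift + t // 2) % t - t // 2
    return shift, corr


def align_sources(set_a, set_b, method: str = "xcorr") -> SourceAlignment:
    """Match two equally-sized source sets up to permutation, shift and sign.

    Every pair is aligned circularly (``method="xcorr"``: lag maximizing
    the absolute correlation; ``method="peak"``: lags that make the maximum
    peaks coincide -- the two coincide for clean unimodal waveforms).  The
    pairing maximizes the summed absolute post-alignment correlation:
    exhaustively over permutations for up to 4 sources, greedily by
    descending correlation otherwise.
    """
    a = _as_matrix(set_a)
    b = _as_matrix(set_b)
    if a.shape[0] != b.shape[0]:
        raise ValueError(f"source counts differ: {a.shape[0]} vs {b.shape[0]}")
    if a.shape[1] != b.shape[1]:
        raise ValueError("source sets must share the sample count")
    n = a.shape[0]
    shift_tab = np.zeros((n, n), dtype=int)
    corr_tab = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            shift_tab[i, j], corr_tab[i, j] = _best_shift_corr(a[i], b[j], method)
    score = np.abs(corr_tab)
    if n <= 4:
        best_perm, best_score = None, -np.inf
        for perm in itertools.permutations(range(n)):
            s = sum(score[i, perm[i]] for i in range(n))
            if s > best_score:
                best_perm, best_score = perm, s
        perm = np.asarray(best_perm)
    else:
        perm = np.full(n, -1)
        taken: set[int] = set()
        order = np.dstack(np.unravel_index(np.argsort(-score, axis=None), score.shape))[0]
        for i, j in order:
            if perm[i] < 0 and j not in taken:
                perm[i] = j
                taken.add(j)
    shifts = np.array([shift_tab[i, perm[i]] for i in range(n)])
    corrs = np.array([corr_tab[i, perm[i]] for i in range(n)])
    return SourceAlignment(permutation=perm, shifts=shifts, correlations=corrs)
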