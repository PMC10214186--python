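"""State-space reconstruction and multispatial convergent cross mapping.

Attractors are reconstructed from short replicated time series by pooling
lagged coordinate vectors across *segments* (countries): vectors are built
within segments only, never across a segment boundary, which is what allows
annual series of ~10 steps to be analyzed jointly.  With m the minimum
segment length, the embedding dimension obeys E <= m - 1, since one step
must remain for prediction.

Simplex projection predicts a vector's future from its E + 1 nearest
neighbors with exponential distance weights; the leave-one-out prediction
skill rho (Pearson correlation of predictions and observations) drives both
embedding-dimension selection and the nonlinearity screen (a system
dominated by stochastic noise shows no significant short-horizon skill, and
deterministic nonlinear dynamics lose skill with forecast horizon).

Convergent cross mapping (CCM) asks whether pressure X leaves a signature
in species Y: the reconstructed manifold of Y is used to cross-estimate X,
and the crossmap skill rho must both be positive and *converge* (improve as
the library of states grows).  Skill at each library size is estimated by a
bootstrap over library vectors; the significance of convergence compares
the bootstrap skill distributions at the largest and smallest library.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import linregress

__all__ = ["Embedding", "CcmResult", "NonlinearityResult", "standardize_segments",
           "build_embedding", "simplex_skill", "select_embedding_dim",
           "test_nonlinearity", "ccm", "CCMTest"]


def standardize_segments(series_by_segment):
    """z-score each segment series; error on zero within-segment variance."""
    out = []
    for i, s in enumerate(series_by_segment):
        s = np.asarray(s, dtype=float)
        sd = s.std(ddof=0)
        if sd == 0:
            raise ValueError(f"segment {i} has zero variance after standardization")
        out.append((s - s.mean()) / sd)
    return out


@dataclass
class Embedding:
    """Lagged coordinate vectors pooled across segments.

    ``coords[k, j]`` is x_{t_k - j*tau} of segment ``seg[k]``; vectors never
    span a segment boundary, so a segment of length m contributes
    m - (E - 1)*tau vectors.
    """

    E: int
    tau: int
    coords: np.ndarray          # (n, E)
    seg: np.ndarray             # (n,) segment id of each vector
    t: np.ndarray               # (n,) time index within segment (of coord 0)
    series: list                # the segment series (standardized)

    @property
    def n(self) -> int:
        return len(self.coords)

    def future_values(self, tp: int) -> np.ndarray:
        """x_{t + tp} per vector; NaN where the horizon leaves the segment."""
        out = np.full(self.n, np.nan)
        for k in range(self.n):
            s = self.series[self.seg[k]]
            idx = self.t[k] + tp
            if 0 <= idx < len(s):
                out[k] = s[idx]
        return out


def build_embedding(series_by_segment, E: int, tau: int = 1) -> Embedding:
    """Build a segment-aware delay embedding (series assumed standardized)."""
    if E < 1 or tau < 1:
        raise ValueError("E and tau must be >= 1")
    series = [np.asarray(s, dtype=float) for s in series_by_segment]
    m_min = min(len(s) for s in series)
    if E > m_min - 1:
        raise ValueError(
            f"E = {E} violates E <= m - 1 with minimum segment length m = {m_min}; "
            "one time step must be kept for prediction")
    coords, seg, tt = [], [], []
    for si, s in enumerate(series):
        for t in range((E - 1) * tau, len(s)):
            coords.append([s[t - j * tau] for j in range(E)])
            seg.append(si)
            tt.append(t)
    return Embedding(E=E, tau=tau, coords=np.asarray(coords, dtype=float),
                     seg=np.asarray(seg), t=np.asarray(tt), series=series)


def _neighbor_weights(d_sorted):
    """Exponential simplex weights from sorted neighbor distances.

    w_i = exp(-d_i / d_1); when the nearest distance is zero, the
    zero-distance neighbors share uniform weight.
    """
    d1 = d_sorted[..., 0:1]
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(d1 > 0, np.exp(-d_sorted / np.where(d1 > 0, d1, 1.0)),
                     (d_sorted == 0).astype(float))
    return w


def _simplex_predictions(emb: Embedding, tp: int):
    """Leave-one-out simplex predictions of x_{t+tp} for every valid target.

    Library vectors must themselves have a valid future value; neighbors
    within ``tau`` steps of the target in the same segment (including the
    target itself) are excluded.  Ties in distance break by vector build
    order (segment, then time), which is deterministic.
    """
    fut = emb.future_values(tp)
    valid = ~np.isnan(fut)
    tgt_idx = np.flatnonzero(valid)
    lib_idx = np.flatnonzero(valid)
    if len(lib_idx) < emb.E + 2:
        raise ValueError(
            f"too few vectors ({len(lib_idx)}) for simplex with E = {emb.E}")
    D = cdist(emb.coords[tgt_idx], emb.coords[lib_idx])
    same_seg = emb.seg[tgt_idx][:, None] == emb.seg[lib_idx][None, :]
    close = np.abs(emb.t[tgt_idx][:, None] - emb.t[lib_idx][None, :]) <= emb.tau
    D[same_seg & close] = np.inf
    k = emb.E + 1
    order = np.argsort(D, axis=1, kind="stable")[:, :k]
    d_near = np.take_along_axis(D, order, axis=1)
    usable = np.isfinite(d_near).all(axis=1)
    w = _neighbor_weights(d_near)
    vals = fut[lib_idx][order]
    pred = (w * vals).sum(axis=1) / w.sum(axis=1)
    return pred[usable], fut[tgt_idx][usable]


def _pearson(a, b) -> float:
    if len(a) < 3 or a.std() == 0 or b.std() == 0:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def simplex_skill(emb: Embedding, tp: int = 1) -> float:
    """Leave-one-out simplex forecast skill rho at horizon ``tp``."""
    pred, obs = _simplex_predictions(emb, tp)
    return _pearson(pred, obs)


def select_embedding_dim(series_by_segment, E_max: int, tau: int = 1) -> int:
    """Embedding dimension maximizing one-step simplex skill (ties -> smaller E)."""
    series = [np.asarray(s, dtype=float) for s in series_by_segment]
    m_min = min(len(s) for s in series)
    if E_max > m_min - 1:
        raise ValueError(f"E_max = {E_max} violates E <= m - 1 (m = {m_min})")
    best_E, best_rho = 1, -np.inf
    for E in range(1, E_max + 1):
        emb = build_embedding(series, E, tau)
        try:
            rho = simplex_skill(emb, tp=1)
        except ValueError:
            continue
        if rho > best_rho + 1e-12:
            best_E, best_rho = E, rho
    return best_E


@dataclass
class NonlinearityResult:
    passes: bool
    skill_by_horizon: dict       # tp -> rho
    reason: str = ""


def test_nonlinearity(series_by_segment, E: int, tau: int = 1,
                      tp_max: int = 4, n_boot: int = 300, alpha: float = 0.05,
                      seed: int = 0) -> NonlinearityResult:
    """Screen for noise-dominated series before CCM.

    Passes when (i) one-step skill is significantly positive (bootstrap over
    prediction/observation pairs) and (ii) skill declines with forecast
    horizon (negative slope of rho on tp).  A series failing (i) behaves
    like a purely stochastic system; one failing (ii) — e.g. a noise-free
    periodic signal — is flagged "no decay".
    """
    series = [np.asarray(s, dtype=float) for s in series_by_segment]
    m_min = min(len(s) for s in series)
    tp_hi = min(tp_max, m_min - 1 - (E - 1) * tau)
    if tp_hi < 2:
        return NonlinearityResult(False, {}, "insufficient horizons")
    emb = build_embedding(series, E, tau)
    skills = {}
    pred1 = obs1 = None
    for tp in range(1, tp_hi + 1):
        try:
            pred, obs = _simplex_predictions(emb, tp)
        except ValueError:
            break
        skills[tp] = _pearson(pred, obs)
        if tp == 1:
            pred1, obs1 = pred, obs
    if 1 not in skills or len(skills) < 2:
        return NonlinearityResult(False, skills, "insufficient horizons")
    rng = np.random.default_rng(seed)
    npairs = len(pred1)
    idx = rng.integers(0, npairs, size=(n_boot, npairs))
    rhos = np.array([_pearson(pred1[i], obs1[i]) for i in idx])
    sig_pos = np.quantile(rhos, alpha) > 0
    tps = np.array(sorted(skills))
    vals = np.array([skills[t] for t in tps])
    slope = linregress(tps, vals).slope
    if not sig_pos:
        return NonlinearityResult(False, skills, "no significant skill at tp=1")
    # a noise-free periodic signal decays only at float precision; demand a
    # non-trivial drop before calling it deterministic decay
    if slope >= 0 or vals[0] - vals.min() <= 1e-4:
        return NonlinearityResult(False, skills, "no decay")
    return NonlinearityResult(True, skills, "")


@dataclass
class CcmResult:
    """Crossmap skill as a function of library size, with significance."""

    source: str                 # pressure (the variable being estimated)
    target: str                 # species (whose manifold does the estimating)
    library_sizes: np.ndarray
    rho_by_L: np.ndarray        # bootstrap mean skill per library size
    sd_by_L: np.ndarray
    rho_full: float             # deterministic full-library skill
    p_value: float
    convergent: bool
    E_used: int

    def to_dict(self) -> dict:
        return {"source": self.source, "target": self.target,
                "E": self.E_used, "rho_Lmin": float(self.rho_by_L[0]),
                "rho_Lmax": float(self.rho_by_L[-1]),
                "rho_full": self.rho_full, "p_value": self.p_value,
                "convergent": self.convergent}


def _crossmap_boot(D, x_vals, lib_draws, E):
    """Bootstrap crossmap skill for one library size (vectorized).

    ``lib_draws`` is (n_boot, L) indices drawn with replacement; for every
    target vector the E + 1 nearest sampled library vectors (self excluded)
    estimate the concurrent source value.
    """
    n_boot, L = lib_draws.shape
    n = D.shape[0]
    d_sub = D[:, lib_draws]                    # (n, n_boot, L)
    d_sub = np.moveaxis(d_sub, 1, 0).copy()    # (n_boot, n, L)
    self_mask = lib_draws[:, None, :] == np.arange(n)[None, :, None]
    d_sub[self_mask] = np.inf
    k = min(E + 1, L)
    order = np.argsort(d_sub, axis=2, kind="stable")[:, :, :k]
    d_near = np.take_along_axis(d_sub, order, axis=2)
    nb = np.take_along_axis(np.broadcast_to(lib_draws[:, None, :],
                                            d_sub.shape), order, axis=2)
    w = _neighbor_weights(d_near)
    w = np.where(np.isfinite(d_near), w, 0.0)
    wsum = w.sum(axis=2)
    with np.errstate(invalid="ignore"):
        pred = (w * x_vals[nb]).sum(axis=2) / wsum   # (n_boot, n)
    rhos = np.empty(n_boot)
    for b in range(n_boot):
        ok = wsum[b] > 0
        rhos[b] = _pearson(pred[b, ok], x_vals[ok]) if ok.sum() >= 3 else 0.0
    return rhos


def ccm(y_by_segment, x_by_segment, E: int, library_sizes=None,
        n_boot: int = 100, alpha: float = 0.05, seed: int = 0, tau: int = 1,
        xmap_lag: int = -1, source: str = "X", target: str = "Y") -> CcmResult:
    """Convergent cross mapping: does X leave a signature in Y?

    The manifold of Y (the putatively *affected* series) cross-estimates the
    values of X; detection of the X -> Y influence requires the crossmap
    skill to be positive and to increase significantly from the smallest to
    the largest library.  Both inputs must share segments and be
    standardized per segment.

    ``xmap_lag`` fixes the time alignment of the cross-estimate: the Y-state
    vector at time t estimates X(t + xmap_lag).  The default of -1 reflects
    the response lag of annually sampled driven systems — a state influenced
    by X up to the previous step carries a full signature of X(t - 1) but
    only an autocorrelation-mediated one of X(t).  This is a fixed
    convention, not a lag scan.

    ``p_value`` is the bootstrap probability that skill at the largest
    library does not exceed skill at the smallest; ``convergent`` requires
    p < alpha and positive mean skill at the largest library.
    """
    ys = [np.asarray(s, dtype=float) for s in y_by_segment]
    xs = [np.asarray(s, dtype=float) for s in x_by_segment]
    if len(ys) != len(xs) or any(len(a) != len(b) for a, b in zip(ys, xs)):
        raise ValueError("X and Y must share segment structure")
    emb = build_embedding(ys, E, tau)
    usable = np.array([0 <= emb.t[k] + xmap_lag < len(xs[emb.seg[k]])
                       for k in range(emb.n)])
    x_vals = np.array([xs[emb.seg[k]][emb.t[k] + xmap_lag]
                       for k in np.flatnonzero(usable)])
    emb = Embedding(E=emb.E, tau=emb.tau, coords=emb.coords[usable],
                    seg=emb.seg[usable], t=emb.t[usable], series=emb.series)
    n = emb.n
    if library_sizes is None:
        L_min = min(E + 2, n)
        library_sizes = np.unique(np.linspace(L_min, n, 4).astype(int))
    else:
        library_sizes = np.asarray(sorted(library_sizes), dtype=int)
        if library_sizes[-1] > n:
            raise ValueError(
                f"largest library size {library_sizes[-1]} exceeds {n} vectors")
    D = cdist(emb.coords, emb.coords)
    rng = np.random.default_rng(seed)
    rho_mean, rho_sd, boot_store = [], [], {}
    for L in library_sizes:
        draws = rng.integers(0, n, size=(n_boot, int(L)))
        rhos = _crossmap_boot(D, x_vals, draws, E)
        rho_mean.append(rhos.mean()); rho_sd.append(rhos.std(ddof=1))
        boot_store[int(L)] = rhos
    a = boot_store[int(library_sizes[-1])]
    b = boot_store[int(library_sizes[0])]
    p_value = float(np.mean(a[:, None] <= b[None, :]))
    convergent = bool(p_value < alpha and np.mean(a) > 0)
    # deterministic skill with the full library (leave-one-out)
    full_draws = np.broadcast_to(np.arange(n), (1, n))
    rho_full = float(_crossmap_boot(D, x_vals, np.ascontiguousarray(full_draws), E)[0])
    return CcmResult(source=source, target=target,
                     library_sizes=np.asarray(library_sizes),
                     rho_by_L=np.asarray(rho_mean), sd_by_L=np.asarray(rho_sd),
                     rho_full=rho_full, p_value=p_value, convergent=convergent,
                     E_used=E)


class CCMTest:
    """Estimator-style wrapper: fit() runs embedding selection, the
    nonlinearity screen and CCM for one (species, pressure) direction.

    Attributes set by :meth:`fit` carry a trailing underscore following the
    scikit-learn convention (``E_``, ``nonlinearity_``, ``result_``).
    """

    def __init__(self, E_max: int = 5, tau: int = 1, n_boot: int = 100,
                 alpha: float = 0.05, seed: int = 0, screen: bool = True):
        self.E_max = E_max
        self.tau = tau
        self.n_boot = n_boot
        self.alpha = alpha
        self.seed = seed
        self.screen = screen

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in
                ("E_max", "tau", "n_boot", "alpha", "seed", "screen")}

    def set_params(self, **params):
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def fit(self, y_by_segment, x_by_segment, source="X", target="Y"):
        ys = standardize_segments(y_by_segment)
        xs = standardize_segments(x_by_segment)
        m_min = min(len(s) for s in ys)
        E_max = min(self.E_max, m_min - 1)
        self.E_ = select_embedding_dim(ys, E_max, self.tau)
        self.nonlinearity_ = test_nonlinearity(ys, self.E_, self.tau,
                                               seed=self.seed)
        if self.screen and not self.nonlinearity_.passes:
            self.result_ = None
            return self
        self.result_ = ccm(ys, xs, self.E_, n_boot=self.n_boot,
                           alpha=self.alpha, seed=self.seed, tau=self.tau,
                           source=source, target=target)
        return self
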