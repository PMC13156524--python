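"""Cluster statistics for TRF contrasts and scalar metric tests.

Mass-univariate t-maps over (lag, channel) are enhanced with threshold-free
cluster enhancement (TFCE) and assessed against a max-statistic permutation
null (label exchange for independent groups, sign flips for paired data).
Scalar per-subject metrics are compared with classical paired t-tests and
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats as sps

from .core import TRFKernel
from .errors import InvalidArgumentError, ZeroVarianceError

__all__ = [
    "StatMap",
    "smooth_trf",
    "mass_univariate_t",
    "tfce_enhance",
    "permutation_pvalues",
    "bh_adjust",
    "paired_metric_test",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))

try:  # compiled TFCE inner loop for lag-only adjacency
    from numba import njit as _njit

    @_njit(cache=True)
    def _tfce_lag_only(tmap, E, H, dh):  # pragma: no cover - compiled
        n_lags, n_ch = tmap.shape
        out = np.zeros_like(tmap)
        vmax = tmap.max()
        if vmax <= 0:
            return out
        h = dh
        while h <= vmax + 1e-12:
            weight = (h ** H) * dh
            for c in range(n_ch):
                i = 0
                while i < n_lags:
                    if tmap[i, c] >= h:
                        j = i
                        while j < n_lags and tmap[j, c] >= h:
                            j += 1
                        contrib = ((j - i) ** E) * weight
                        for p in range(i, j):
                            out[p, c] += contrib
                        i = j
                    else:
                        i += 1
            h += dh
        return out

    _HAVE_NUMBA_TFCE = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA_TFCE = False


@dataclass
class StatMap:
    """t map plus (optionally) TFCE enhancement and permutation p-values."""

    t: np.ndarray  # (n_lags, n_channels)
    tfce: Optional[np.ndarray] = None
    p: Optional[np.ndarray] = None
    alpha: float = 0.05
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.atleast_2d(np.asarray(self.t, dtype=float))
        if self.t.ndim == 1:
            self.t = self.t[:, None]

    @property
    def mask(self) -> Optional[np.ndarray]:
        if self.p is None:
            return None
        return self.p < self.alpha


def smooth_trf(trf: TRFKernel, width: float = 50.0, interpret: str = "fwhm") -> TRFKernel:
    """Gaussian smoothing along the lag axis.

    ``width`` (ms) is interpreted as the full width at half maximum by
    default (``interpret='sd'`` treats it as the Gaussian SD instead).
    Edge handling is nearest-neighbor, so constant kernels pass unchanged
    and compactly supported kernels keep their mass.
    """
    if width <= 0:
        raise InvalidArgumentError("width must be positive")
    if interpret == "fwhm":
        sigma_ms = width * FWHM_TO_SIGMA
    elif interpret == "sd":
        sigma_ms = width
    else:
        raise InvalidArgumentError(f"unknown width interpretation: {interpret!r}")
    sigma_samples = sigma_ms / 1000.0 * trf.fs
    out = trf.copy()
    out.coefs = ndimage.gaussian_filter1d(
        trf.coefs, sigma_samples, axis=0, mode="nearest"
    )
    out.weights = None
    return out


def _stack(kernels) -> np.ndarray:
    arrs = [k.coefs if isinstance(k, TRFKernel) else np.atleast_2d(np.asarray(k, float))
            for k in kernels]
    shapes = {a.shape for a in arrs}
    if len(shapes) != 1:
        raise InvalidArgumentError(f"kernel shape mismatch: {sorted(shapes)}")
    return np.stack(arrs)


def _t_independent(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    na, nb = a.shape[0], b.shape[0]
    va = a.var(axis=0, ddof=1)
    vb = b.var(axis=0, ddof=1)
    pooled = ((na - 1) * va + (nb - 1) * vb) / (na + nb - 2)
    denom = np.sqrt(pooled * (1.0 / na + 1.0 / nb))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (a.mean(axis=0) - b.mean(axis=0)) / denom
    return np.nan_to_num(t)


def _t_paired(d: np.ndarray) -> np.ndarray:
    n = d.shape[0]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = d.mean(axis=0) / (d.std(axis=0, ddof=1) / np.sqrt(n))
    return np.nan_to_num(t)


def mass_univariate_t(group_a, group_b, paired: bool = False) -> StatMap:
    """Pointwise t statistics at every (lag, channel)."""
    a = _stack(group_a)
    b = _stack(group_b)
    if a.shape[1:] != b.shape[1:]:
        raise InvalidArgumentError(
            f"kernel shape mismatch between groups: {a.shape[1:]} vs {b.shape[1:]}"
        )
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise InvalidArgumentError("need at least 2 kernels per group")
    if paired:
        if a.shape[0] != b.shape[0]:
            raise InvalidArgumentError("paired test needs equal group sizes")
        t = _t_paired(a - b)
    else:
        t = _t_independent(a, b)
    return StatMap(t=t, meta={"paired": paired, "n_a": a.shape[0], "n_b": b.shape[0]})


def _run_extents(mask_col: np.ndarray) -> np.ndarray:
    """Length of the contiguous True run covering each position (0 if False)."""
    n = mask_col.size
    out = np.zeros(n)
    if not mask_col.any():
        return out
    padded = np.concatenate([[False], mask_col, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    for s, e in zip(starts, ends):
        out[s:e] = e - s
    return out


def _tfce_signed(tmap: np.ndarray, E: float, H: float, dh: float,
                 channel_adjacency: bool) -> np.ndarray:
    """TFCE of one sign-restricted (nonnegative) map."""
    vmax = tmap.max()
    if vmax <= 0:
        return np.zeros_like(tmap)
    if not channel_adjacency and _HAVE_NUMBA_TFCE:
        return _tfce_lag_only(np.ascontiguousarray(tmap, dtype=np.float64),
                              float(E), float(H), float(dh))
    out = np.zeros_like(tmap)
    heights = np.arange(dh, vmax + dh, dh)
    # lag axis is axis 0; default connectivity is lag-neighbors within channel
    structure = np.ones((3, 3)) if channel_adjacency else np.array(
        [[0, 1, 0], [0, 1, 0], [0, 1, 0]]
    )
    for h in heights:
        mask = tmap >= h
        if not mask.any():
            break
        if channel_adjacency or tmap.shape[1] > 1:
            labels, n_lab = ndimage.label(mask, structure=structure)
            if n_lab:
                sizes = np.bincount(labels.ravel())
                ext = np.where(mask, sizes[labels], 0.0)
            else:
                ext = np.zeros_like(tmap)
        else:
            ext = _run_extents(mask[:, 0])[:, None]
        out += (ext**E) * (h**H) * dh
    return out


def tfce_enhance(
    tmap: StatMap,
    E: float = 0.5,
    H: float = 2.0,
    dh: float | None = None,
    channel_adjacency: bool = False,
) -> StatMap:
    """Threshold-free cluster enhancement of a t map.

    Positive and negative parts are enhanced separately and recombined with
    their signs.  Adjacency is along the lag axis within channel by default
    (channel adjacency requires electrode geometry).  ``dh`` defaults to
    ``max|t| / 100``.
    """
    if E <= 0 or H <= 0:
        raise InvalidArgumentError("E and H must be positive")
    t = tmap.t
    vmax = np.abs(t).max()
    if vmax == 0:
        enhanced = np.zeros_like(t)
    else:
        if dh is None:
            dh = vmax / 100.0
        if dh <= 0:
            raise InvalidArgumentError("dh must be positive")
        pos = _tfce_signed(np.maximum(t, 0.0), E, H, dh, channel_adjacency)
        neg = _tfce_signed(np.maximum(-t, 0.0), E, H, dh, channel_adjacency)
        enhanced = pos - neg
    return StatMap(t=t, tfce=enhanced, alpha=tmap.alpha,
                   meta={**tmap.meta, "E": E, "H": H, "dh": dh})


def permutation_pvalues(
    group_a,
    group_b,
    paired: bool = False,
    n_perm: int = 1000,
    seed: int = 0,
    E: float = 0.5,
    H: float = 2.0,
    alpha: float = 0.05,
    channel_adjacency: bool = False,
) -> StatMap:
    """Max-TFCE permutation p-values for an attended-vs-ignored contrast.

    The null permutes group labels (independent) or flips difference signs
    (paired); each permutation's maximum |enhanced| statistic forms the
    family-wise null, and ``p = (1 + #{null >= observed}) / (1 + n_perm)``
    pointwise.
    """
    if n_perm < 100:
        raise InvalidArgumentError("need n_perm >= 100")
    a = _stack(group_a)
    b = _stack(group_b)
    rng = np.random.default_rng(seed)

    observed = mass_univariate_t(a, b, paired=paired)
    dh = np.abs(observed.t).max() / 100.0 if np.abs(observed.t).max() > 0 else None
    obs = tfce_enhance(observed, E=E, H=H, dh=dh,
                       channel_adjacency=channel_adjacency)
    obs_abs = np.abs(obs.tfce)

    if paired:
        d = a - b
        n = d.shape[0]
        if n < 2:
            raise InvalidArgumentError("too few exchangeable units")
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            signs = rng.choice([-1.0, 1.0], size=n)
            t = _t_paired(d * signs[:, None, None])
            enh = tfce_enhance(StatMap(t=t), E=E, H=H, dh=dh,
                               channel_adjacency=channel_adjacency).tfce
            null_max[i] = np.abs(enh).max()
    else:
        pooled = np.concatenate([a, b], axis=0)
        na = a.shape[0]
        if pooled.shape[0] < 3:
            raise InvalidArgumentError("too few exchangeable units")
        null_max = np.empty(n_perm)
        for i in range(n_perm):
            perm = rng.permutation(pooled.shape[0])
            t = _t_independent(pooled[perm[:na]], pooled[perm[na:]])
            enh = tfce_enhance(StatMap(t=t), E=E, H=H, dh=dh,
                               channel_adjacency=channel_adjacency).tfce
            null_max[i] = np.abs(enh).max()

    p = (1.0 + (null_max[None, None, :] >= obs_abs[:, :, None]).sum(axis=2)) / (
        1.0 + n_perm
    )
    return StatMap(
        t=observed.t, tfce=obs.tfce, p=p, alpha=alpha,
        meta={**obs.meta, "n_perm": n_perm, "seed": seed, "paired": paired},
    )


def bh_adjust(pvals: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at FDR level ``q``."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise InvalidArgumentError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order]
    below = ranked <= (np.arange(1, m + 1) * q / m)
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = np.nonzero(below)[0].max()
        mask[order[: k + 1]] = True
    return mask


def paired_metric_test(metric_a, metric_b) -> tuple[float, float]:
    """Classical two-sided paired t-test on per-subject scalar metrics."""
    a = np.asarray(metric_a, dtype=float).ravel()
    b = np.asarray(metric_b, dtype=float).ravel()
    if a.size != b.size:
        raise InvalidArgumentError(f"length mismatch: {a.size} vs {b.size}")
    if a.size < 2:
        raise InvalidArgumentError("need at least 2 pairs")
    d = a - b
    sd = d.std(ddof=1)
    if np.allclose(a, b):
        return 0.0, 1.0
    if sd == 0:
        raise ZeroVarianceError("differences have zero variance")
    n = d.size
    t = d.mean() / (sd / np.sqrt(n))
    p = 2.0 * sps.t.sf(abs(t), df=n - 1)
    return float(t), float(p)
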