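"""Grey-relational analysis with centered-square deviations and entropy weights.

Grey relational analysis (GRA) scores the similarity of short
multivariate sequences.  For a reference sequence x0 and comparison
sequences x_i (all of length d), the variant used here measures the
deviation at entry k as the absolute difference of *centered squares*

    Delta_i(k) = | (x0(k) - mean(x0))^2 - (x_i(k) - mean(x_i))^2 |,

making the score sensitive to the fluctuation pattern of a sequence
around its own level rather than to its absolute level.  The
per-entry coefficient and the per-sequence degree are the Deng forms

    sigma_i(k) = (min min Delta + rho max max Delta) / (Delta_i(k) + rho max max Delta),
    phi_i = mean_k sigma_i(k),

with resolution coefficient rho = 0.5 and the min/max taken over the
whole reference-vs-comparisons block of the call.  When every Delta in
the block is zero the coefficients are 1 by convention.

On top of this the module builds the representative point of a sample
subset: the row most correlated with all others (initial centroid Z*),
the centroid-vs-rows coefficient matrix, entropy weights per feature
(low-entropy = high-variation features weigh more), and the weighted
centroid Z_m = w * Z* used to gate sub-models at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import BatchDataset, Scaler

__all__ = [
    "GreyConfig",
    "WeightedCentroid",
    "grey_coefficients",
    "grey_degree",
    "grey_degree_block",
    "gate_degrees",
    "sample_correlation_matrix",
    "initial_centroid",
    "coefficient_matrix",
    "entropy_weights",
    "weighted_centroid",
    "select_aux_variables",
]

_EPS = 1e-12


@dataclass(frozen=True)
class GreyConfig:
    """rho is the GRA resolution coefficient (contrast), in [0, 1]."""

    rho: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.rho <= 1.0:
            raise ValueError("rho must lie in [0, 1]")


@dataclass
class WeightedCentroid:
    """Entropy-weighted representative of a local sample subset."""

    center_row_index: int          # index of Z* within its subset
    z_star: np.ndarray             # (d,)
    weights: np.ndarray            # (d,) >= 0, sum 1
    z_weighted: np.ndarray         # (d,) = weights * z_star


def _centered_squares(rows: np.ndarray) -> np.ndarray:
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return (rows - rows.mean(axis=1, keepdims=True)) ** 2


def grey_coefficients(
    ref: np.ndarray, comps: np.ndarray, cfg: GreyConfig = GreyConfig()
) -> np.ndarray:
    """Coefficient matrix sigma (n_comps x d); min/max scoped to this block."""
    ref = np.asarray(ref, dtype=float).ravel()
    comps = np.atleast_2d(np.asarray(comps, dtype=float))
    if comps.size == 0:
        raise ValueError("comps must contain at least one row")
    if comps.shape[1] != ref.shape[0]:
        raise ValueError("ref and comps must share length d")
    c0 = _centered_squares(ref[None, :])
    ci = _centered_squares(comps)
    delta = np.abs(c0 - ci)
    dmax = delta.max()
    if dmax <= 0.0:
        return np.ones_like(delta)
    dmin = delta.min()
    return (dmin + cfg.rho * dmax) / (delta + cfg.rho * dmax)


def grey_degree(ref: np.ndarray, comp: np.ndarray, cfg: GreyConfig = GreyConfig()) -> float:
    """Correlation degree phi = mean of the coefficients of one comparison."""
    return float(grey_coefficients(ref, np.atleast_2d(comp), cfg).mean())


def grey_degree_block(
    refs: np.ndarray, comps: np.ndarray, cfg: GreyConfig = GreyConfig()
) -> np.ndarray:
    """phi of each reference row against the m comparison rows, with the
    min/max block scoped per reference over all m x d deviations.

    Returns an (n_refs, m) matrix.  This is the gating computation: each
    test sample is a reference, the m weighted centroids the comparisons.
    """
    refs = np.atleast_2d(np.asarray(refs, dtype=float))
    comps = np.atleast_2d(np.asarray(comps, dtype=float))
    c_ref = _centered_squares(refs)               # (n, d)
    c_cmp = _centered_squares(comps)              # (m, d)
    delta = np.abs(c_ref[:, None, :] - c_cmp[None, :, :])   # (n, m, d)
    dmax = delta.max(axis=(1, 2), keepdims=True)
    dmin = delta.min(axis=(1, 2), keepdims=True)
    with np.errstate(invalid="ignore"):
        sig = (dmin + cfg.rho * dmax) / (delta + cfg.rho * dmax)
    sig = np.where(dmax <= 0.0, 1.0, sig)
    return sig.mean(axis=2)


def gate_degrees(
    rows: np.ndarray,
    weights: np.ndarray,
    z_weighted: np.ndarray,
    cfg: GreyConfig = GreyConfig(),
) -> np.ndarray:
    """Weighted grey degree of each sample against each weighted centroid.

    For sub-model j both sequences live in its entropy-weighted feature
    space: the reference is w_j * x (the sample mapped into the weighted
    space) and the comparison is Z_m,j = w_j * Z*_j.  The per-feature
    coefficients are aggregated with the same entropy weights,
    omega_j = sum_k w_jk * sigma_jk, so features that carry subset
    structure dominate the degree.  The min/max block of each sample
    spans all m centroids, making its degrees mutually comparable.

    rows : (n, d); weights, z_weighted : (m, d).  Returns (n, m).
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    weights = np.atleast_2d(np.asarray(weights, dtype=float))
    z_weighted = np.atleast_2d(np.asarray(z_weighted, dtype=float))
    refs = rows[:, None, :] * weights[None, :, :]                 # (n, m, d)
    c_ref = (refs - refs.mean(axis=2, keepdims=True)) ** 2
    c_cmp = _centered_squares(z_weighted)                          # (m, d)
    delta = np.abs(c_ref - c_cmp[None, :, :])
    dmax = delta.max(axis=(1, 2), keepdims=True)
    dmin = delta.min(axis=(1, 2), keepdims=True)
    with np.errstate(invalid="ignore"):
        sig = (dmin + cfg.rho * dmax) / (delta + cfg.rho * dmax)
    sig = np.where(dmax <= 0.0, 1.0, sig)
    return np.sum(weights[None, :, :] * sig, axis=2)


def sample_correlation_matrix(rows: np.ndarray, cfg: GreyConfig = GreyConfig()) -> np.ndarray:
    """Pairwise grey-degree matrix with unit diagonal.

    Entry (i, j) is phi with row i as reference and row j as comparison;
    min/max are scoped to that single pair.
    """
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    n = rows.shape[0]
    if n < 2:
        raise ValueError("need at least 2 rows")
    c = _centered_squares(rows)                          # (n, d)
    delta = np.abs(c[:, None, :] - c[None, :, :])        # (n, n, d)
    dmax = delta.max(axis=2, keepdims=True)              # per pair
    dmin = delta.min(axis=2, keepdims=True)
    with np.errstate(invalid="ignore"):
        sig = (dmin + cfg.rho * dmax) / (delta + cfg.rho * dmax)
    sig = np.where(dmax <= 0.0, 1.0, sig)
    phi = sig.mean(axis=2)
    np.fill_diagonal(phi, 1.0)
    return phi


def initial_centroid(phi: np.ndarray) -> int:
    """Row with maximal mean off-diagonal correlation; ties -> smallest index."""
    phi = np.asarray(phi, dtype=float)
    n = phi.shape[0]
    off = (phi.sum(axis=1) - np.diag(phi)) / max(n - 1, 1)
    return int(np.argmax(off))


def coefficient_matrix(
    rows: np.ndarray, centroid_index: int, cfg: GreyConfig = GreyConfig()
) -> np.ndarray:
    """psi (n x d): coefficients of every row against the centroid row,
    with min/max scoped over all rows and features of the subset."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    return grey_coefficients(rows[centroid_index], rows, cfg)


def entropy_weights(psi: np.ndarray) -> np.ndarray:
    """Entropy weights of the feature columns of psi.

    P_ij = psi_ij / column sum; e_j = -(1/ln n) sum_i P_ij ln P_ij with
    0 ln 0 := 0; w_j = (1 - e_j) / (d - sum_j e_j).  If every column is
    uniform (denominator ~ 0) the weights fall back to 1/d.
    """
    psi = np.atleast_2d(np.asarray(psi, dtype=float))
    n, d = psi.shape
    if n < 2:
        raise ValueError("need at least 2 rows")
    col = psi.sum(axis=0, keepdims=True)
    if np.any(col <= 0):
        raise ValueError("psi columns must have positive sums")
    P = psi / col
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(P > 0, P * np.log(P), 0.0)
    e = -plogp.sum(axis=0) / np.log(n)
    denom = d - e.sum()
    if denom < _EPS:
        return np.full(d, 1.0 / d)
    w = (1.0 - e) / denom
    return w


def weighted_centroid(rows: np.ndarray, cfg: GreyConfig = GreyConfig()) -> WeightedCentroid:
    """Compose the full pipeline: correlation matrix -> initial centroid
    -> coefficient matrix -> entropy weights -> Z_m = w * Z*."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    phi = sample_correlation_matrix(rows, cfg)
    c_idx = initial_centroid(phi)
    psi = coefficient_matrix(rows, c_idx, cfg)
    w = entropy_weights(psi)
    z_star = rows[c_idx].copy()
    return WeightedCentroid(
        center_row_index=c_idx, z_star=z_star, weights=w, z_weighted=w * z_star
    )


def select_aux_variables(
    ds: BatchDataset,
    target: str,
    threshold: float = 0.7,
    cfg: GreyConfig = GreyConfig(),
) -> tuple[list[str], dict[str, float]]:
    """Keep auxiliary columns whose grey degree with the target exceeds
    the threshold (default 0.7); both are min-max scaled over rows first.

    If no column passes, the single best column is kept (with the caller
    expected to warn).  Returns (selected names, degree per name).
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    y = ds.target_vector(target)
    y_s = Scaler(mode="minmax").fit_transform(y[:, None]).ravel()
    degrees: dict[str, float] = {}
    for j, name in enumerate(ds.aux_names):
        x = ds.aux[:, j]
        x_s = Scaler(mode="minmax").fit_transform(x[:, None]).ravel()
        degrees[name] = grey_degree(y_s, x_s, cfg)
    selected = [name for name in ds.aux_names if degrees[name] > threshold]
    if not selected:
        selected = [max(degrees, key=lambda k: degrees[k])]
    return selected, degrees
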