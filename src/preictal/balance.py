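"""Minority-class oversampling and synthetic-sample fidelity checks.

Preictal windows are scarce relative to interictal ones, which biases any
classifier trained on the raw class ratio.  Two oversamplers are provided:

* **SMOTE** — each synthetic vector is ``x + u * (x_nn - x)`` with ``u``
  uniform in [0, 1], ``x`` a randomly chosen minority instance and ``x_nn``
  one of its k nearest minority neighbors (Euclidean): a coordinatewise
  convex combination of the two parents.
* **SPIDER** (prototype perturbation) — seeded k-medoids picks
  representative minority prototypes, and synthetics are prototypes plus
  Gaussian perturbations scaled per coordinate by a fraction of the
  within-class standard deviation.

Fidelity of a synthetic sample to a real one is quantified by Pearson
correlation and dynamic-time-warping distance.  Real instances are never
modified or removed; both methods are deterministic given their seed.

By default oversampling runs on feature vectors inside training folds only.
A ``balance_before_split`` switch at the pipeline level instead oversamples before
splitting (with a logged leakage warning) for faithfulness to protocols
that balance first and split afterwards.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from scipy.stats import pearsonr

__all__ = [
    "OversampleSpec",
    "smote",
    "spider",
    "oversample_to_parity",
    "fidelity",
    "dtw_distance",
]


@dataclass
class OversampleSpec:
    """Configuration shared by both oversamplers."""

    method: str = "smote"          # {"smote", "spider"}
    k_neighbors: int = 5           # SMOTE neighborhood size
    n_synthetic: int = 0           # number of synthetic vectors to generate
    perturb_scale: float = 0.1     # SPIDER: fraction of within-class std
    n_prototypes: int = 10         # SPIDER: number of k-medoids prototypes
    seed: int = 0

    def __post_init__(self) -> None:
        if self.method not in ("smote", "spider"):
            raise ValueError(f"unknown oversampling method {self.method!r}")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.n_synthetic < 0:
            raise ValueError("n_synthetic must be >= 0")
        if self.perturb_scale < 0:
            raise ValueError("perturb_scale must be >= 0")


def smote(
    minority_vectors: np.ndarray,
    spec: OversampleSpec,
    return_parents: bool = False,
):
    """Generate ``spec.n_synthetic`` SMOTE vectors from the minority class.

    Returns an ``(n_synthetic, n_features)`` array of new rows only; the
    input is untouched.  If the class is not larger than ``k_neighbors``,
    k is reduced to ``class size - 1`` with a warning.  With
    ``return_parents`` the row indices of each synthetic's two parents are
    returned as well (useful for auditing the convex-combination property).
    """
    x = np.asarray(minority_vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("minority_vectors must be (n >= 2, n_features)")
    n = x.shape[0]
    k = spec.k_neighbors
    if n <= k:
        k = n - 1
        warnings.warn(
            f"minority class of {n} <= k_neighbors={spec.k_neighbors}; using k={k}"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.n_synthetic == 0:
        empty = np.empty((0, x.shape[1]))
        return (empty, np.empty(0, int), np.empty(0, int)) if return_parents else empty
    d = cdist(x, x)
    np.fill_diagonal(d, np.inf)
    neighbors = np.argsort(d, axis=1)[:, :k]

    base = rng.integers(n, size=spec.n_synthetic)
    pick = rng.integers(k, size=spec.n_synthetic)
    u = rng.uniform(0.0, 1.0, size=spec.n_synthetic)
    nn = neighbors[base, pick]
    synth = x[base] + u[:, None] * (x[nn] - x[base])
    if return_parents:
        return synth, base, nn
    return synth


def _kmedoids(x: np.ndarray, k: int, rng: np.random.Generator,
              n_iter: int = 50) -> np.ndarray:
    """Seeded alternating-update k-medoids; returns medoid row indices."""
    n = x.shape[0]
    d = cdist(x, x)
    medoids = rng.choice(n, size=k, replace=False)
    for _ in range(n_iter):
        assign = np.argmin(d[:, medoids], axis=1)
        new = medoids.copy()
        for j in range(k):
            members = np.flatnonzero(assign == j)
            if members.size == 0:
                continue
            within = d[np.ix_(members, members)].sum(axis=1)
            new[j] = members[np.argmin(within)]
        if np.array_equal(new, medoids):
            break
        medoids = new
    return np.sort(medoids)


def spider(minority_vectors: np.ndarray, spec: OversampleSpec) -> np.ndarray:
    """Prototype-perturbation oversampling.

    Prototypes are k-medoids representatives of the minority class;
    synthetics cycle through the prototypes adding Gaussian noise with
    per-coordinate scale ``perturb_scale * within-class std``.  A class with
    zero variance yields duplicated prototypes (scale 0) with a warning.
    """
    x = np.asarray(minority_vectors, dtype=float)
    if x.ndim != 2 or x.shape[0] < 1:
        raise ValueError("minority_vectors must be (n >= 1, n_features)")
    n = x.shape[0]
    if spec.n_prototypes > n:
        raise ValueError(f"n_prototypes={spec.n_prototypes} exceeds class size {n}")
    rng = np.random.default_rng(spec.seed)
    if spec.n_prototypes == n:
        proto_idx = np.arange(n)
    else:
        proto_idx = _kmedoids(x, spec.n_prototypes, rng)
    prototypes = x[proto_idx]

    std = x.std(axis=0)  # within-class, population
    if np.all(std == 0):
        warnings.warn("degenerate minority class (zero variance); "
                      "returning unperturbed prototype duplicates")
    scale = spec.perturb_scale * std
    if spec.n_synthetic == 0:
        return np.empty((0, x.shape[1]))
    base = np.resize(np.arange(len(prototypes)), spec.n_synthetic)
    noise = rng.standard_normal((spec.n_synthetic, x.shape[1])) * scale
    return prototypes[base] + noise


def oversample_to_parity(
    x: np.ndarray, y: np.ndarray, spec: OversampleSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Append synthetic minority rows until both classes have equal counts.

    Real rows are returned unchanged (and first); only the minority class
    gains synthetic rows.  Already-balanced input is returned as-is.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y).astype(int).ravel()
    counts = np.bincount(y, minlength=2)
    deficit = int(abs(counts[1] - counts[0]))
    if deficit == 0:
        return x, y
    minority = int(np.argmin(counts))
    kwargs = {**vars(spec), "n_synthetic": deficit}
    rows = x[y == minority]
    if spec.method == "smote":
        synth = smote(rows, OversampleSpec(**kwargs))
    else:
        kwargs["n_prototypes"] = min(spec.n_prototypes, len(rows))
        synth = spider(rows, OversampleSpec(**kwargs))
    return np.vstack([x, synth]), np.r_[y, np.full(deficit, minority)]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Dynamic-time-warping distance, standard O(n*m) dynamic program.

    Local cost is the absolute (Euclidean, 1-D) difference; steps are the
    usual match/insert/delete moves.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("DTW inputs must be non-empty")
    cost = np.abs(a[:, None] - b[None, :])
    acc = np.full((n + 1, m + 1), np.inf)
    acc[0, 0] = 0.0
    for i in range(1, n + 1):
        prev_row = acc[i - 1]
        row = acc[i]
        c = cost[i - 1]
        for j in range(1, m + 1):
            row[j] = c[j - 1] + min(prev_row[j], row[j - 1], prev_row[j - 1])
    return float(acc[n, m])


def fidelity(real_signal: np.ndarray, synthetic_signal: np.ndarray) -> dict[str, float]:
    """Pearson r (equal lengths) and DTW distance between two 1-D signals."""
    a = np.asarray(real_signal, dtype=float).ravel()
    b = np.asarray(synthetic_signal, dtype=float).ravel()
    out: dict[str, float] = {"dtw_distance": dtw_distance(a, b)}
    if a.size != b.size:
        warnings.warn(
            f"Pearson correlation needs equal lengths (got {a.size}, {b.size}); "
            "reporting NaN"
        )
        out["pearson_r"] = float("nan")
    elif a.std() == 0 or b.std() == 0:
        out["pearson_r"] = float("nan")
    else:
        out["pearson_r"] = float(pearsonr(a, b).statistic)
    return out
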