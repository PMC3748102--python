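"""Colour difference between specimens and species.

The central quantity is the Earth Mover's Distance (EMD) between two pixel
distributions in 3-D Lab space: the minimum mean transport work (mass x
Euclidean Lab distance) needed to morph one distribution into the other.
Unlike the Euclidean distance between mean colours, EMD retains the full
distributional information, so two species with equal means but different
spreads still register a difference.  With both signatures normalised to
total mass 1, the EMD is a metric on distributions and is reported in Lab
units (for two point masses it reduces to their Delta E*ab).

Pixel clouds are summarised as *signatures* — weighted support-point sets —
by seeded uniform subsampling (default 500 points), which avoids the
bin-placement artefacts of 3-D histograms; binned signatures on a regular
Lab grid are available for large-scale runs.

Group comparisons of specimen-level EMDs use Tukey's HSD (studentized
range), and pairwise distance structure is visualised with non-metric
multidimensional scaling (Kruskal stress-1, SMACOF majorisation with
monotone regression).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import isotonic_regression, linear_sum_assignment, linprog
from scipy.spatial.distance import cdist, pdist, squareform

from .colorspace import PixelCloudLab

__all__ = [
    "Signature",
    "EMDResult",
    "NmdsEmbedding",
    "make_signature",
    "binned_signature",
    "emd",
    "species_emd_profile",
    "tukey_hsd",
    "pairwise_euclidean",
    "nmds",
]


@dataclass
class Signature:
    """A weighted point set summarising a Lab pixel distribution."""

    points: np.ndarray  # (K, 3)
    weights: np.ndarray  # (K,), sums to 1
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.points = np.atleast_2d(np.asarray(self.points, dtype=float))
        self.weights = np.asarray(self.weights, dtype=float)
        if self.points.shape[0] < 1 or self.points.shape[0] != self.weights.shape[0]:
            raise ValueError("points and weights must agree and be non-empty")
        if np.any(self.weights < 0):
            raise ValueError("weights must be non-negative")
        total = self.weights.sum()
        if abs(total - 1.0) > 1e-12:
            if total <= 0:
                raise ValueError("weights must have positive total mass")
            self.weights = self.weights / total

    @property
    def k(self) -> int:
        return self.points.shape[0]


@dataclass
class EMDResult:
    distance: float
    flow: np.ndarray | None = None
    status: str = "optimal"


@dataclass
class NmdsEmbedding:
    coordinates: np.ndarray  # (n, 2), column-centred
    stress: float  # Kruskal stress-1
    n_iterations: int
    seed: int | None = None
    stress_history: np.ndarray | None = None


def make_signature(cloud: PixelCloudLab, max_points: int = 500, seed=None) -> Signature:
    """Equal-weight signature; seeded uniform subsample when N > max_points."""
    if max_points < 1:
        raise ValueError("max_points must be >= 1")
    pts = cloud.points
    prov = {"n_source": pts.shape[0], "max_points": max_points}
    if pts.shape[0] > max_points:
        rng = np.random.default_rng(seed)
        idx = rng.choice(pts.shape[0], size=max_points, replace=False)
        pts = pts[np.sort(idx)]
        prov["seed"] = seed
        prov["subsampled"] = True
    k = pts.shape[0]
    return Signature(points=pts, weights=np.full(k, 1.0 / k), provenance=prov)


def binned_signature(cloud: PixelCloudLab, bins_per_axis: int = 16) -> Signature:
    """Histogram signature on a regular Lab grid (for very large clouds)."""
    edges = [
        np.linspace(0.0, 100.0, bins_per_axis + 1),
        np.linspace(-128.0, 128.0, bins_per_axis + 1),
        np.linspace(-128.0, 128.0, bins_per_axis + 1),
    ]
    hist, _ = np.histogramdd(cloud.points, bins=edges)
    occupied = np.argwhere(hist > 0)
    centers = np.column_stack(
        [(edges[d][occupied[:, d]] + edges[d][occupied[:, d] + 1]) / 2.0 for d in range(3)]
    )
    weights = hist[tuple(occupied.T)]
    return Signature(points=centers, weights=weights, provenance={"bins_per_axis": bins_per_axis})


def _emd_lp(cost: np.ndarray, wa: np.ndarray, wb: np.ndarray, return_flow: bool):
    """Balanced transportation LP (HiGHS); one redundant constraint dropped."""
    ka, kb = cost.shape
    n = ka * kb
    rows, cols, data = [], [], []
    for i in range(ka):
        rows.extend([i] * kb)
        cols.extend(range(i * kb, (i + 1) * kb))
        data.extend([1.0] * kb)
    for j in range(kb - 1):  # last column constraint is redundant
        rows.extend([ka + j] * ka)
        cols.extend(range(j, n, kb))
        data.extend([1.0] * ka)
    from scipy.sparse import csr_matrix

    A = csr_matrix((data, (rows, cols)), shape=(ka + kb - 1, n))
    b = np.concatenate([wa, wb[:-1]])
    res = linprog(cost.ravel(), A_eq=A, b_eq=b, bounds=(0, None), method="highs")
    if not res.success:
        raise RuntimeError(f"EMD transport LP failed: {res.message}")
    flow = res.x.reshape(ka, kb) if return_flow else None
    return float(res.fun), flow, res.message or "optimal"


def emd(sig_a: Signature, sig_b: Signature, return_flow: bool = False) -> EMDResult:
    """Earth Mover's Distance with Euclidean ground distance in Lab.

    Both signatures carry total mass 1, so the optimum is the mean transport
    distance (Lab units).  Equal-size uniform-weight signatures are solved
    exactly as an assignment problem (an optimal extreme point of the
    transport polytope is then a permutation); the general case solves the
    transportation LP.
    """
    cost = cdist(sig_a.points, sig_b.points)
    uniform = (
        sig_a.k == sig_b.k
        and np.allclose(sig_a.weights, 1.0 / sig_a.k, atol=1e-12)
        and np.allclose(sig_b.weights, 1.0 / sig_b.k, atol=1e-12)
    )
    if uniform:
        ri, ci = linear_sum_assignment(cost)
        distance = float(cost[ri, ci].sum() / sig_a.k)
        flow = None
        if return_flow:
            flow = np.zeros_like(cost)
            flow[ri, ci] = 1.0 / sig_a.k
        return EMDResult(distance=distance, flow=flow, status="optimal")
    distance, flow, status = _emd_lp(cost, sig_a.weights, sig_b.weights, return_flow)
    return EMDResult(distance=distance, flow=flow, status=status)


def species_emd_profile(
    target_clouds,
    other_clouds,
    max_points: int = 500,
    seed: int = 0,
    specimen_vs_specimen: bool = False,
) -> dict:
    """Mean ± SD (and 95% t CI) of EMDs from comparison specimens to a target species.

    By default each comparison specimen's signature is compared with the
    *pooled* signature of all target specimens; with
    ``specimen_vs_specimen=True`` every target-comparison specimen pair is
    computed and averaged within comparison specimens first.
    """
    target_clouds, other_clouds = list(target_clouds), list(other_clouds)
    if not target_clouds or not other_clouds:
        raise ValueError("need at least one cloud on each side")
    rng_seed = np.random.SeedSequence(seed).spawn(len(other_clouds) + len(target_clouds) + 1)
    per_specimen = []
    if specimen_vs_specimen:
        target_sigs = [
            make_signature(c, max_points, seed=int(s.generate_state(1)[0] % 2**31))
            for c, s in zip(target_clouds, rng_seed)
        ]
        for c, s in zip(other_clouds, rng_seed[len(target_clouds):]):
            sig = make_signature(c, max_points, seed=int(s.generate_state(1)[0] % 2**31))
            per_specimen.append(float(np.mean([emd(sig, t).distance for t in target_sigs])))
    else:
        pooled = PixelCloudLab(points=np.vstack([c.points for c in target_clouds]), specimen_id="pooled")
        pooled_sig = make_signature(pooled, max_points, seed=int(rng_seed[-1].generate_state(1)[0] % 2**31))
        for c, s in zip(other_clouds, rng_seed[: len(other_clouds)]):
            sig = make_signature(c, max_points, seed=int(s.generate_state(1)[0] % 2**31))
            per_specimen.append(emd(sig, pooled_sig).distance)
    arr = np.asarray(per_specimen)
    out = {"emds": arr, "mean": float(arr.mean()), "n": arr.size}
    if arr.size >= 2:
        sd = float(arr.std(ddof=1))
        half = stats.t.ppf(0.975, arr.size - 1) * sd / np.sqrt(arr.size)
        out.update({"sd": sd, "ci95": (out["mean"] - half, out["mean"] + half)})
    else:
        out.update({"sd": float("nan"), "ci95": None})
    return out


def tukey_hsd(groups: dict, alpha: float = 0.05) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons of a one-way layout.

    *groups* maps group label -> 1-D array of specimen-level values.
    Returns a table of pairwise mean differences with studentized-range
    adjusted p-values and significance flags at *alpha*.
    """
    labels = list(groups)
    arrays = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size < 2 for a in arrays):
        raise ValueError("every group needs n >= 2")
    if all(a.std(ddof=1) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group: HSD is undefined")
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        rows.append(
            {
                "group_a": labels[i],
                "group_b": labels[j],
                "mean_difference": float(arrays[i].mean() - arrays[j].mean()),
                "p_adjusted": float(res.pvalue[i, j]),
                "significant": bool(res.pvalue[i, j] < alpha),
            }
        )
    return pd.DataFrame(rows)


def pairwise_euclidean(mean_vectors, labels=None) -> pd.DataFrame:
    """Euclidean distance matrix between species mean Lab vectors."""
    X = np.atleast_2d(np.asarray(mean_vectors, dtype=float))
    if X.shape[0] < 2:
        raise ValueError("need at least 2 mean vectors")
    D = squareform(pdist(X))
    if labels is None:
        labels = [f"item_{i}" for i in range(X.shape[0])]
    return pd.DataFrame(D, index=labels, columns=labels)


def _classical_mds(D: np.ndarray, dims: int) -> np.ndarray:
    n = D.shape[0]
    J = np.eye(n) - np.ones((n, n)) / n
    B = -0.5 * J @ (D**2) @ J
    w, V = np.linalg.eigh(B)
    order = np.argsort(w)[::-1][:dims]
    lam = np.clip(w[order], 0.0, None)
    return V[:, order] * np.sqrt(lam)


def _stress1_and_disparities(delta_flat, d_flat, order):
    """Kruskal stress-1 and monotone-regressed disparities (secondary ties)."""
    fit = isotonic_regression(d_flat[order], increasing=True)
    dhat = np.empty_like(d_flat)
    dhat[order] = fit.x
    denom = float(np.sum(d_flat**2))
    if denom == 0:
        return 0.0, dhat
    return float(np.sqrt(np.sum((d_flat - dhat) ** 2) / denom)), dhat


def nmds(
    distances,
    dims: int = 2,
    n_starts: int = 4,
    seed=None,
    max_iter: int = 300,
    tol: float = 1e-7,
) -> NmdsEmbedding:
    """Non-metric MDS by SMACOF majorisation with monotone regression.

    Minimises Kruskal stress-1.  The first start is the classical
    (eigendecomposition) MDS configuration, followed by seeded random
    starts; the best final stress wins.  Within a run the recorded stress
    never increases: an update that would increase stress terminates the
    run at the previous configuration.
    """
    D = np.asarray(distances, dtype=float)
    if D.ndim != 2 or D.shape[0] != D.shape[1]:
        raise ValueError("distances must be a square matrix")
    if not np.allclose(D, D.T, atol=1e-9):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.abs(np.diag(D)) > 1e-12) or np.any(D < 0):
        raise ValueError("distances must be non-negative with a zero diagonal")
    n = D.shape[0]
    delta_flat = squareform(D, checks=False)
    order = np.argsort(delta_flat, kind="stable")
    rng = np.random.default_rng(seed)

    best = None
    for start in range(max(n_starts, 1)):
        if start == 0:
            X = _classical_mds(D, dims)
        else:
            X = rng.normal(scale=D.max() if D.max() > 0 else 1.0, size=(n, dims))
        d_flat = pdist(X)
        stress, dhat = _stress1_and_disparities(delta_flat, d_flat, order)
        history = [stress]
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            # Guttman transform with disparities dhat
            with np.errstate(divide="ignore", invalid="ignore"):
                ratio = np.where(d_flat > 0, dhat / d_flat, 0.0)
            B = -squareform(ratio)
            np.fill_diagonal(B, -B.sum(axis=1))
            X_new = (B @ X) / n
            d_new = pdist(X_new)
            stress_new, dhat_new = _stress1_and_disparities(delta_flat, d_new, order)
            if stress_new > stress + 1e-15:
                break  # keep the previous (better) configuration
            X, d_flat, dhat = X_new, d_new, dhat_new
            converged = stress - stress_new < tol
            stress = stress_new
            history.append(stress)
            if converged:
                break
        X = X - X.mean(axis=0)
        cand = NmdsEmbedding(
            coordinates=X,
            stress=stress,
            n_iterations=n_iter,
            seed=seed,
            stress_history=np.asarray(history),
        )
        if best is None or cand.stress < best.stress:
            best = cand
    return best
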