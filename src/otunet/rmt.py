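"""Signed co-occurrence network construction with random-matrix-theory
threshold selection.

The pipeline correlates log-abundance profiles of every OTU pair (Pearson
by default), then scans candidate similarity thresholds ``s_t``: entries
with ``|r| < s_t`` are zeroed and the nearest-neighbour spacing
distribution (NNSD) of the unfolded eigenvalues of the thresholded matrix
is tested against the two universal laws.  A random, fully connected
correlation structure follows the Gaussian orthogonal ensemble (GOE)
Wigner surmise ``P(d) = (pi d / 2) exp(-pi d^2 / 4)``; once thresholding
has broken the matrix into independent modular blocks the spacings follow
the Poisson law ``P(d) = exp(-d)``.  The selected threshold is the
smallest one at which the spacings are statistically Poisson — the
GOE-to-Poisson transition point — and edges of the network are exactly the
pairs with ``|r|`` at or above it, signed by the correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import interpolate, stats

logger = logging.getLogger(__name__)

#: Guimera-style NNSD histogram: equal-width bins on unfolded spacings.
NNSD_BIN_WIDTH = 0.1
NNSD_D_MAX = 3.0
MIN_EIGENVALUES = 50
MIN_SPACINGS = 30


class NetworkConstructionError(ValueError):
    """Raised when no valid network can be built."""


@dataclass
class SimilarityMatrix:
    """Symmetric signed Pearson (or Spearman) correlation matrix."""

    r: np.ndarray
    otu_ids: list[str]
    n_samples: int
    method: str = "pearson"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        n = self.r.shape[0]
        if self.r.shape != (n, n) or n != len(self.otu_ids):
            raise ValueError("similarity matrix shape mismatch")
        if not np.allclose(self.r, self.r.T, atol=1e-10):
            raise ValueError("similarity matrix not symmetric")
        if np.abs(self.r).max() > 1 + 1e-8:
            raise ValueError("|r| > 1")

    @property
    def n_otus(self) -> int:
        return self.r.shape[0]


@dataclass
class ThresholdScanPoint:
    threshold: float
    n_nodes: int          # rows with at least one off-diagonal entry
    n_eigenvalues: int    # distinct eigenvalues used for unfolding
    usable: bool
    chi2_poisson: float = np.nan
    p_poisson: float = np.nan
    chi2_goe: float = np.nan
    p_goe: float = np.nan


@dataclass
class ThresholdScan:
    """Per-threshold NNSD goodness-of-fit evidence for threshold selection."""

    points: list[ThresholdScanPoint]
    selected_threshold: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "threshold": p.threshold,
                    "n_nodes": p.n_nodes,
                    "n_eigenvalues": p.n_eigenvalues,
                    "usable": p.usable,
                    "chi2_poisson": p.chi2_poisson,
                    "p_poisson": p.p_poisson,
                    "chi2_goe": p.chi2_goe,
                    "p_goe": p.p_goe,
                }
                for p in self.points
            ]
        )


@dataclass
class CoNetwork:
    """Signed, undirected co-occurrence network at a chosen threshold.

    ``graph`` is a :class:`networkx.Graph`; every edge carries ``weight``
    (the correlation r) and ``sign`` (+1/-1), every node a ``phylum``
    attribute.  Isolated nodes are dropped at construction.
    """

    graph: nx.Graph
    threshold: float
    group: str = ""

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


def pearson_similarity(values, otu_ids=None, method: str = "pearson") -> SimilarityMatrix:
    """Pairwise correlation between OTU log-abundance profiles.

    ``values`` is OTU x sample (DataFrame or array).  Zero-variance rows
    get r = 0 off-diagonal with a warning rather than NaN, so they simply
    never form edges.
    """
    if isinstance(values, pd.DataFrame):
        otu_ids = list(values.index)
        mat = values.values.astype(float)
    else:
        mat = np.asarray(values, dtype=float)
        if otu_ids is None:
            otu_ids = [f"OTU{i}" for i in range(mat.shape[0])]
    if mat.shape[1] < 3:
        raise ValueError("need at least 3 samples for correlation")

    if method == "spearman":
        mat = np.apply_along_axis(stats.rankdata, 1, mat)
    elif method != "pearson":
        raise ValueError(f"unknown correlation method {method!r}")

    sd = mat.std(axis=1)
    flat = sd == 0
    if flat.any():
        logger.warning("%d zero-variance OTU profiles; r set to 0", flat.sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.corrcoef(mat)
    r[np.isnan(r)] = 0.0
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    return SimilarityMatrix(
        r=r, otu_ids=list(otu_ids), n_samples=mat.shape[1], method=method
    )


def _dedupe_eigenvalues(eigenvalues: np.ndarray, tol: float = 1e-8) -> np.ndarray:
    """Collapse degenerate eigenvalues (within ``tol``) to single levels."""
    lam = np.sort(np.asarray(eigenvalues, dtype=float))
    keep = [lam[0]]
    for x in lam[1:]:
        if x - keep[-1] > tol:
            keep.append(x)
    return np.asarray(keep)


def unfold_spectrum(
    eigenvalues,
    tol: float = 1e-8,
    n_knots: int = 11,
    method: str = "spline",
) -> np.ndarray:
    """Unfold an eigenvalue spectrum so the local mean spacing is one.

    Degenerate eigenvalues are removed (tolerance ``tol``), a smooth
    approximation of the cumulative spectral function is fitted — a cubic
    least-squares spline with ``n_knots`` interior knots at eigenvalue
    quantiles by default, or a degree-5 polynomial with
    ``method='polynomial'`` — and the unfolded levels are
    ``e_i = N * F_hat(lambda_i)``.  Returns the spacings
    ``d_i = e_{i+1} - e_i`` clipped at zero; their mean is ~1 by
    construction.
    """
    lam = _dedupe_eigenvalues(eigenvalues, tol=tol)
    n = lam.size
    if n < MIN_EIGENVALUES:
        raise NetworkConstructionError(
            f"only {n} distinct eigenvalues; need >= {MIN_EIGENVALUES}"
        )
    levels = np.arange(1, n + 1, dtype=float)
    if method == "polynomial":
        coeffs = np.polyfit(lam, levels, deg=5)
        smooth = np.polyval(coeffs, lam)
    elif method == "spline":
        k = min(n_knots, max(1, n // 10))
        qs = np.linspace(0, 1, k + 2)[1:-1]
        knots = np.quantile(lam, qs)
        # LSQ spline needs strictly increasing interior knots
        knots = np.unique(knots)
        knots = knots[(knots > lam[0]) & (knots < lam[-1])]
        spline = interpolate.LSQUnivariateSpline(lam, levels, knots, k=3)
        smooth = spline(lam)
    else:
        raise ValueError(f"unknown unfolding method {method!r}")
    d = np.diff(smooth)
    return np.clip(d, 0.0, None)


def _law_cdf(law: str, x: np.ndarray) -> np.ndarray:
    if law == "poisson":
        return 1.0 - np.exp(-x)
    if law == "goe":
        return 1.0 - np.exp(-np.pi * x**2 / 4.0)
    raise ValueError(f"unknown spacing law {law!r}")


def nnsd_chi2(spacings, law: str, min_expected: float = 5.0) -> tuple[float, float]:
    """Pearson chi-square of the spacing histogram against a universal law.

    Spacings are binned in widths of 0.1 up to d = 3 with the tail merged
    into the last bin; adjacent bins are merged until every expected count
    is at least ``min_expected``.  Returns ``(chi2, p)`` with
    ``df = n_bins - 1``.
    """
    d = np.asarray(spacings, dtype=float)
    if d.size < MIN_SPACINGS:
        raise ValueError(f"need >= {MIN_SPACINGS} spacings, got {d.size}")
    edges = np.arange(0.0, NNSD_D_MAX + NNSD_BIN_WIDTH / 2, NNSD_BIN_WIDTH)
    edges = np.append(edges, np.inf)
    observed, _ = np.histogram(d, bins=edges)
    cdf = _law_cdf(law, edges[:-1])
    cdf_hi = np.append(_law_cdf(law, edges[1:-1]), 1.0)
    expected = d.size * (cdf_hi - cdf)

    # merge adjacent low-expectation bins (left to right, tail absorbed)
    obs_m, exp_m = [], []
    o_acc = e_acc = 0.0
    for o, e in zip(observed, expected):
        o_acc += o
        e_acc += e
        if e_acc >= min_expected:
            obs_m.append(o_acc)
            exp_m.append(e_acc)
            o_acc = e_acc = 0.0
    if e_acc > 0 or o_acc > 0:
        if exp_m:
            obs_m[-1] += o_acc
            exp_m[-1] += e_acc
        else:
            obs_m, exp_m = [o_acc], [max(e_acc, 1e-12)]
    obs_arr = np.asarray(obs_m, dtype=float)
    exp_arr = np.asarray(exp_m, dtype=float)
    # renormalise tiny drift so Pearson statistic is well defined
    exp_arr *= obs_arr.sum() / exp_arr.sum()
    chi2 = float(((obs_arr - exp_arr) ** 2 / exp_arr).sum())
    df = max(len(obs_arr) - 1, 1)
    p = float(stats.chi2.sf(chi2, df))
    return chi2, p


def _threshold_matrix(r: np.ndarray, s_t: float) -> np.ndarray:
    """Zero |r| below the threshold (diagonal kept) and drop rows/columns
    with no remaining off-diagonal entries."""
    a = np.where(np.abs(r) >= s_t, r, 0.0)
    np.fill_diagonal(a, np.diag(r))
    off = a - np.diag(np.diag(a))
    keep = np.abs(off).sum(axis=1) > 0
    return a[np.ix_(keep, keep)]


def scan_thresholds(
    sim: SimilarityMatrix,
    s_min: float = 0.30,
    s_max: float = 0.99,
    step: float = 0.01,
    unfold_method: str = "spline",
) -> ThresholdScan:
    """Evaluate NNSD statistics over a grid of candidate thresholds.

    For each ``s_t`` the thresholded matrix is eigendecomposed, the
    spectrum unfolded and tested against the Poisson and GOE (Wigner)
    spacing laws.  Grid points with too few distinct eigenvalues or
    spacings are flagged unusable, not errors.
    """
    if sim.n_otus < 60:
        logger.warning(
            "similarity matrix has only %d OTUs; NNSD statistics unstable",
            sim.n_otus,
        )
    n_steps = int(np.floor((s_max - s_min) / step + 1e-9))
    thresholds = [round(s_min + i * step, 10) for i in range(n_steps + 1)]
    points: list[ThresholdScanPoint] = []
    for s_t in thresholds:
        a = _threshold_matrix(sim.r, s_t)
        n_nodes = a.shape[0]
        if n_nodes < MIN_EIGENVALUES:
            points.append(
                ThresholdScanPoint(s_t, n_nodes, 0, usable=False)
            )
            continue
        lam = np.linalg.eigvalsh(a)
        n_distinct = _dedupe_eigenvalues(lam).size
        if n_distinct < MIN_EIGENVALUES:
            points.append(
                ThresholdScanPoint(s_t, n_nodes, n_distinct, usable=False)
            )
            continue
        spacings = unfold_spectrum(lam, method=unfold_method)
        if spacings.size < MIN_SPACINGS:
            points.append(
                ThresholdScanPoint(s_t, n_nodes, n_distinct, usable=False)
            )
            continue
        chi2_p, p_p = nnsd_chi2(spacings, "poisson")
        chi2_g, p_g = nnsd_chi2(spacings, "goe")
        points.append(
            ThresholdScanPoint(
                s_t,
                n_nodes,
                n_distinct,
                usable=True,
                chi2_poisson=chi2_p,
                p_poisson=p_p,
                chi2_goe=chi2_g,
                p_goe=p_g,
            )
        )
    return ThresholdScan(points=points)


def select_threshold(scan: ThresholdScan, alpha: float = 0.05) -> float:
    """Pick the similarity threshold at the GOE-to-Poisson transition.

    Rule: the smallest scanned threshold whose Poisson goodness-of-fit p
    exceeds ``alpha`` *and* whose Poisson chi-square is below the GOE
    chi-square.  If no point qualifies, the usable point minimising the
    Poisson chi-square is returned with a prominent warning.
    """
    usable = [p for p in scan.points if p.usable]
    if not usable:
        raise NetworkConstructionError("no usable threshold-scan points")
    for p in usable:
        if p.p_poisson > alpha and p.chi2_poisson < p.chi2_goe:
            scan.selected_threshold = p.threshold
            return p.threshold
    best = min(usable, key=lambda p: p.chi2_poisson)
    logger.warning(
        "no Poisson-consistent threshold found; falling back to s_t=%.3f "
        "with minimal Poisson chi-square %.2f",
        best.threshold,
        best.chi2_poisson,
    )
    scan.selected_threshold = best.threshold
    return best.threshold


def build_network(
    sim: SimilarityMatrix,
    threshold: float,
    taxonomy: pd.DataFrame | None = None,
    group: str = "",
) -> CoNetwork:
    """Build the signed co-occurrence network at a similarity threshold.

    Every OTU pair with ``|r| >= threshold`` becomes an undirected edge
    with the correlation as ``weight`` and its sign as ``sign``.  Nodes
    left without any edge are dropped; each node carries its phylum (or
    ``"Unclassified"``).
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    g = nx.Graph()
    r = sim.r
    ids = sim.otu_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = np.abs(r[iu, ju]) >= threshold
    for i, j in zip(iu[mask], ju[mask]):
        w = float(r[i, j])
        g.add_edge(ids[i], ids[j], weight=w, sign=1 if w >= 0 else -1)
    if g.number_of_edges() == 0:
        raise NetworkConstructionError(
            f"no edges at threshold {threshold:g} (empty network)"
        )
    for node in g.nodes:
        phylum = "Unclassified"
        if taxonomy is not None and node in taxonomy.index:
            phylum = str(taxonomy.loc[node, "phylum"])
        g.nodes[node]["phylum"] = phylum
    # sorted node order makes downstream greedy algorithms deterministic
    ordered = nx.Graph()
    ordered.add_nodes_from(
        sorted(g.nodes(data=True), key=lambda nd: str(nd[0]))
    )
    ordered.add_edges_from(g.edges(data=True))
    return CoNetwork(graph=ordered, threshold=float(threshold), group=group)


def edge_sign_proportions(net: CoNetwork) -> tuple[float, float]:
    """Percentage of positive (co-occurrence) and negative (exclusion)
    edges; the two sum to 100."""
    signs = [d["sign"] for _, _, d in net.graph.edges(data=True)]
    if not signs:
        raise NetworkConstructionError("network has no edges")
    pos = 100.0 * sum(1 for s in signs if s > 0) / len(signs)
    return pos, 100.0 - pos
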