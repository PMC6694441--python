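"""Group covariance-network construction.

For one group of subjects, each region's uptake vector is residualized
against age, sex and whole-brain mean uptake by ordinary least squares; the
group network is the 90 x 90 Pearson correlation matrix R of the residuals.
R is binarized at a target sparsity S by keeping the K = round(S * N(N-1)/2)
edges of largest |R_ij|, so every group's graph has the same edge count
before topology is compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

log = logging.getLogger(__name__)


@dataclass
class GroupNetwork:
    """One group's inter-regional Pearson correlation matrix."""

    group: str
    R: np.ndarray
    n_subjects: int
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        R = np.asarray(self.R, dtype=float)
        if R.ndim != 2 or R.shape[0] != R.shape[1]:
            raise ValueError("R must be square")
        if not np.allclose(R, R.T, atol=1e-12):
            raise ValueError("R must be symmetric")
        if not np.allclose(np.diag(R), 1.0, atol=1e-12):
            raise ValueError("R must have unit diagonal")
        if np.any(np.abs(R) > 1 + 1e-12):
            raise ValueError("R entries must lie in [-1, 1]")
        self.R = R

    @property
    def n_regions(self) -> int:
        return self.R.shape[0]


@dataclass
class BinaryNetwork:
    """Binarized adjacency at a given sparsity; K edges, no self-loops."""

    P: np.ndarray
    sparsity: float
    K: int
    group: str = ""
    names: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        P = np.asarray(self.P)
        if not np.array_equal(P, P.T) or np.any(np.diag(P) != 0):
            raise ValueError("adjacency must be symmetric with zero diagonal")
        if not np.isin(P, (0, 1)).all():
            raise ValueError("adjacency must be 0/1")
        if int(np.triu(P, 1).sum()) != self.K:
            raise ValueError("K does not match the number of edges in P")
        self.P = P.astype(np.int8)

    @property
    def n_regions(self) -> int:
        return self.P.shape[0]


def residualize(values: np.ndarray, age: np.ndarray, sex: np.ndarray,
                global_uptake: np.ndarray) -> np.ndarray:
    """OLS-residualize every region column on intercept, age, sex, global uptake.

    Collinear or constant covariates are dropped with a warning (the
    intercept always stays). Returns the n x N residual matrix.
    """
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    covs = [("age", np.asarray(age, float)), ("sex", np.asarray(sex, float)),
            ("global_uptake", np.asarray(global_uptake, float))]
    for name, v in covs:
        if v.shape != (n,):
            raise ValueError(f"covariate {name} has shape {v.shape}, expected ({n},)")
    if n < 5:
        raise ValueError(f"need at least 5 subjects to fit 4 regression parameters, got {n}")
    X = np.ones((n, 1))
    for name, v in covs:
        cand = np.column_stack([X, v])
        if np.linalg.matrix_rank(cand, tol=1e-10) > np.linalg.matrix_rank(X, tol=1e-10):
            X = cand
        else:
            log.warning("dropping covariate %r: collinear with the design so far", name)
    beta, *_ = np.linalg.lstsq(X, values, rcond=None)
    return values - X @ beta


def correlation_matrix(residuals: np.ndarray, group: str = "",
                       names: tuple[str, ...] | None = None) -> GroupNetwork:
    """Pearson correlation matrix of region columns; diagonal set to 1."""
    residuals = np.asarray(residuals, dtype=float)
    n, N = residuals.shape
    if n < 3:
        raise ValueError(f"need at least 3 subjects for a correlation matrix, got {n}")
    sd = residuals.std(axis=0)
    if np.any(sd == 0):
        j = int(np.argmax(sd == 0))
        label = names[j] if names else f"column {j}"
        raise ValueError(f"zero-variance region {label}; correlation undefined")
    R = np.corrcoef(residuals, rowvar=False)
    R = np.clip((R + R.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(R, 1.0)
    return GroupNetwork(group=group, R=R, n_subjects=n, names=names)


def build_group_network(cohort, group: str = "") -> GroupNetwork:
    """Residualize a (single-group) cohort and correlate: the standard path.

    The whole-brain confound is the subject's mean uptake over all regions,
    computed before residualization.
    """
    resid = residualize(cohort.values, cohort.meta("age"), cohort.meta("sex"),
                        cohort.global_uptake())
    return correlation_matrix(resid, group=group or (cohort.subjects[0].group
                                                     if cohort.subjects else ""),
                              names=cohort.atlas.names)


def _edge_order(R: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle pairs sorted by decreasing |R|, ties by ascending (i, j)."""
    N = R.shape[0]
    iu, ju = np.triu_indices(N, k=1)
    # lexsort: last key is primary
    order = np.lexsort((ju, iu, -np.abs(R[iu, ju])))
    return iu[order], ju[order]


def edge_count(N: int, S: float) -> int:
    """K = round(S * N(N-1)/2), half away from zero."""
    return int(np.floor(S * N * (N - 1) / 2 + 0.5))


def binarize_at_sparsity(net: GroupNetwork, S: float) -> BinaryNetwork:
    """Keep the K = round(S * N(N-1)/2) largest-|R| edges as a 0/1 graph."""
    if not 0 < S <= 1:
        raise ValueError(f"sparsity must be in (0, 1], got {S}")
    N = net.n_regions
    K = edge_count(N, S)
    if K == 0:
        log.warning("sparsity %g yields zero edges on %d nodes", S, N)
    iu, ju = _edge_order(net.R)
    P = np.zeros((N, N), dtype=np.int8)
    P[iu[:K], ju[:K]] = 1
    P += P.T
    return BinaryNetwork(P=P, sparsity=S, K=K, group=net.group, names=net.names)


def edge_list(net: GroupNetwork):
    """Upper-triangle correlations as a (region_i, region_j, r) table,
    strongest |r| first (binarization keeps a prefix of this ordering)."""
    import pandas as pd
    iu, ju = _edge_order(net.R)
    names = net.names or tuple(str(i) for i in range(net.n_regions))
    return pd.DataFrame({"region_i": [names[i] for i in iu],
                         "region_j": [names[j] for j in ju],
                         "r": net.R[iu, ju]})


def is_connected(P: np.ndarray) -> bool:
    n_comp, _ = connected_components(csr_matrix(P), directed=False)
    return n_comp == 1


def min_connected_sparsity(net: GroupNetwork, grid_step: float = 0.01) -> float:
    """Smallest grid sparsity at which the binarized graph is one component."""
    if grid_step <= 0:
        raise ValueError("grid_step must be positive")
    grid = np.arange(grid_step, 1.0 + grid_step / 2, grid_step)
    for s in grid:
        s = float(min(s, 1.0))
        if is_connected(binarize_at_sparsity(net, s).P):
            return s
    raise RuntimeError("graph not connected at any grid sparsity up to 1.0 "
                       "(duplicate-value ties may exclude spanning edges)")
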