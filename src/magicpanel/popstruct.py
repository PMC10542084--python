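"""Genetic distance, UPGMA clustering and structure covariates.

The pairwise distance is 1 - IBS: at each site shared (non-missing in both
samples) the allele-sharing score is 1 for identical calls, 0.5 for a
homozygote vs a heterozygote, and 0 for opposite homozygotes; the distance
is one minus the mean score.  Equivalently d = mean(|g_i - g_j|)/2 over
dosage codes.

UPGMA is run with deterministic lexicographic tie-breaking and produces an
ultrametric tree (leaf depth = merge height / 2), exported as Newick via
scikit-bio TreeNode.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass

import numpy as np

from .genotype import MISSING, GenotypeMatrix


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distances in [0, 1] with zero diagonal."""

    samples: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.shape != (len(self.samples),) * 2:
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(v, v.T, equal_nan=True):
            raise ValueError("distance matrix not symmetric")
        self.values = v

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.samples.index(a), self.samples.index(b)])

    def to_tsv(self, path) -> None:
        import pandas as pd

        pd.DataFrame(self.values, index=self.samples,
                     columns=self.samples).to_csv(path, sep="\t")


def ibs_distance(matrix: GenotypeMatrix) -> DistanceMatrix:
    """1 - IBS distance over pairwise-shared non-missing sites.

    Pairs sharing no sites get NaN with a warning.
    """
    if matrix.n_samples < 2:
        raise ValueError("need at least 2 samples")
    c = matrix.calls
    # one-hot planes per genotype code; missing contributes nothing
    planes = [(c == g).astype(np.float64) for g in (0, 1, 2)]
    nonmiss = (c != MISSING).astype(np.float64)
    shared = nonmiss.T @ nonmiss
    absdiff = np.zeros_like(shared)
    for k in range(3):
        for l in range(3):
            w = abs(k - l)
            if w:
                absdiff += w * (planes[k].T @ planes[l])
    with np.errstate(divide="ignore", invalid="ignore"):
        d = absdiff / (2.0 * shared)
    if np.any(shared == 0):
        warnings.warn("sample pair(s) share no non-missing sites; distance NaN")
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(list(matrix.samples), d)


# ---------------------------------------------------------------------------
# UPGMA


def upgma(d: DistanceMatrix):
    """UPGMA tree (skbio TreeNode) with average linkage.

    Merge heights are halved into branch lengths so the tree is ultrametric;
    ties break toward the lexicographically smallest cluster-name pair.
    """
    from skbio import TreeNode

    D = d.values.copy().astype(float)
    if np.any(np.isnan(D)):
        raise ValueError("distance matrix contains NaN")
    n = len(d.samples)
    if n == 1:
        return TreeNode(name=d.samples[0])
    nodes = [TreeNode(name=s) for s in d.samples]
    heights = [0.0] * n
    sizes = [1] * n
    # cluster key for deterministic tie-breaks: smallest leaf name within
    keys = [(s,) for s in d.samples]
    active = list(range(n))
    while len(active) > 1:
        best = None
        for ii in range(len(active)):
            for jj in range(ii + 1, len(active)):
                a, b = active[ii], active[jj]
                cand = (D[a, b], min(keys[a], keys[b]), max(keys[a], keys[b]))
                if best is None or cand < best[0]:
                    best = (cand, a, b)
        _, a, b = best
        h = D[a, b] / 2.0
        parent = TreeNode(children=[nodes[a], nodes[b]])
        nodes[a].length = h - heights[a]
        nodes[b].length = h - heights[b]
        # average-linkage update into slot a
        for k in active:
            if k in (a, b):
                continue
            D[a, k] = D[k, a] = (sizes[a] * D[a, k] + sizes[b] * D[b, k]) / (
                sizes[a] + sizes[b])
        nodes[a] = parent
        heights[a] = h
        sizes[a] += sizes[b]
        keys[a] = min(keys[a], keys[b])
        active.remove(b)
    root = nodes[active[0]]
    root.length = None
    return root


def to_newick(tree) -> str:
    """Serialize a TreeNode to a Newick string."""
    buf = io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue().strip()


def from_newick(newick: str):
    """Parse a Newick string into a TreeNode."""
    from skbio import TreeNode

    return TreeNode.read(io.StringIO(newick), format="newick")


def is_ultrametric(tree, tol: float = 1e-9) -> bool:
    depths = [tree.distance(tip) for tip in tree.tips()]
    return (max(depths) - min(depths)) <= tol


# ---------------------------------------------------------------------------
# Structure covariates


def pca_covariates(matrix: GenotypeMatrix, k: int) -> np.ndarray:
    """Top-k principal components of the genotype matrix (samples x k).

    Missing dosages are imputed with the per-site mean before centering;
    returned columns are orthonormal (left singular vectors), ordered by
    non-increasing eigenvalue.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= matrix.n_samples:
        raise ValueError("k must be smaller than the number of samples")
    X = matrix.dosage(impute=True).T  # samples x sites
    X = X - X.mean(axis=0, keepdims=True)
    U, s, _ = np.linalg.svd(X, full_matrices=False)
    return U[:, :k]


def read_q_matrix(path, samples: list[str] | None = None) -> np.ndarray:
    """Read an externally produced structure covariate (Q) TSV.

    First column = sample id, remaining columns = covariates.  If
    ``samples`` is given the rows are aligned to that order.
    """
    import pandas as pd

    df = pd.read_csv(path, sep="\t", index_col=0)
    if samples is not None:
        missing = set(samples) - set(df.index)
        if missing:
            raise KeyError(f"Q matrix missing samples {sorted(missing)[:5]}")
        df = df.loc[samples]
    return df.to_numpy(float)


def write_q_matrix(path, samples: list[str], Q: np.ndarray) -> None:
    import pandas as pd

    pd.DataFrame(Q, index=samples,
                 columns=[f"Q{i + 1}" for i in range(Q.shape[1])]
                 ).to_csv(path, sep="\t", index_label="sample")
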