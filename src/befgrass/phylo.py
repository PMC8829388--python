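"""Phylogeny handling: BLADJ branch-length calibration, patristic distances,
and Blomberg's K phylogenetic signal.

Trees are :class:`dendropy.Tree` objects (rooted, tip labels = species names).
BLADJ takes a taxon-age list for named internal nodes (root age required) and
evenly spaces every undated node between its dated anchors; with tip ages
fixed at zero the calibrated tree is ultrametric by construction, and branch
lengths become time intervals (parent age minus child age).
"""

from __future__ import annotations

import random
from dataclasses import dataclass

import dendropy
import numpy as np
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "CalibrationError",
    "DistanceMatrix",
    "load_tree",
    "read_node_ages",
    "bladj_calibrate",
    "patristic_distances",
    "phylogenetic_signal",
    "is_ultrametric",
]


class CalibrationError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    """Symmetric pairwise species distances (patristic or trait-space)."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-9):
            raise ValueError("distance matrix diagonal not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        self.values = v
        self._index = {s: i for i, s in enumerate(self.labels)}

    def distance(self, a: str, b: str) -> float:
        return float(self.values[self._index[a], self._index[b]])

    def submatrix(self, species: list[str]) -> np.ndarray:
        try:
            idx = [self._index[s] for s in species]
        except KeyError as e:
            raise KeyError(f"species {e.args[0]!r} not in distance matrix") from e
        return self.values[np.ix_(idx, idx)]

    def has(self, species: str) -> bool:
        return species in self._index


def load_tree(path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def read_node_ages(path) -> dict[str, float]:
    """Plain-text ages file: one 'node_name age' pair per line."""
    ages: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, age = line.split()
            ages[name] = float(age)
    return ages


def _node_name(node: dendropy.Node) -> str | None:
    if node.is_leaf():
        return node.taxon.label if node.taxon else node.label
    return node.label


def bladj_calibrate(tree: dendropy.Tree, node_ages: dict[str, float]) -> dendropy.Tree:
    """Assign node ages by even interpolation between dated anchors (BLADJ).

    Tips are fixed at age 0. Every named internal node present in
    ``node_ages`` keeps its age; each undated node receives an age by equal
    spacing along the path between its nearest dated ancestor and a dated
    descendant reachable through undated nodes only (the path with the most
    intervening undated nodes is used; ties broken toward the older
    descendant). Branch lengths are then parent age minus child age, so the
    result is ultrametric.
    """
    tree = tree.clone(depth=1)
    root = tree.seed_node

    for node in tree.preorder_node_iter():
        name = _node_name(node)
        if node.is_leaf():
            node.age_bladj = 0.0
        elif name is not None and name in node_ages:
            node.age_bladj = float(node_ages[name])
        else:
            node.age_bladj = None

    if root.age_bladj is None:
        raise CalibrationError("root node must have a fixed age")

    # consistency on nodes dated up front
    for node in tree.preorder_node_iter():
        if node.age_bladj is None or node is root:
            continue
        anc = node.parent_node
        while anc is not None and anc.age_bladj is None:
            anc = anc.parent_node
        if anc is not None and node.age_bladj >= anc.age_bladj and not node.is_leaf():
            raise CalibrationError(
                f"age of {_node_name(node)!r} ({node.age_bladj}) is not younger than "
                f"ancestor {_node_name(anc)!r} ({anc.age_bladj})"
            )

    def dated_descendant_depth(node: dendropy.Node) -> tuple[int, float]:
        """(number of undated nodes on the deepest all-undated path from the
        parent anchor down to a dated node, age of that dated node)."""
        best_j, best_age = 1, 0.0  # at least the node itself, anchored by a tip
        stack = [(node, 1)]
        while stack:
            cur, j = stack.pop()
            for child in cur.child_nodes():
                if child.age_bladj is not None:
                    if (j, child.age_bladj) > (best_j, best_age):
                        best_j, best_age = j, child.age_bladj
                else:
                    stack.append((child, j + 1))
        return best_j, best_age

    for node in tree.preorder_node_iter():
        if node.age_bladj is not None:
            continue
        parent_age = node.parent_node.age_bladj  # preorder: parent already dated
        j, t_desc = dated_descendant_depth(node)
        node.age_bladj = parent_age - (parent_age - t_desc) / (j + 1)

    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = node.parent_node.age_bladj - node.age_bladj
            if node.edge.length < -1e-9:
                raise CalibrationError(
                    f"negative branch above {_node_name(node)!r} after calibration"
                )
    return tree


def is_ultrametric(tree: dendropy.Tree, rel_tol: float = 1e-6) -> bool:
    depths = _root_to_tip_depths(tree)
    vals = np.array(list(depths.values()))
    root_age = vals.max()
    return bool(np.ptp(vals) <= rel_tol * max(root_age, 1e-12))


def _root_to_tip_depths(tree: dendropy.Tree) -> dict[str, float]:
    depths: dict[str, float] = {}
    for node in tree.preorder_node_iter():
        d = 0.0 if node.parent_node is None else node.parent_node._depth_tmp + (
            node.edge.length or 0.0
        )
        node._depth_tmp = d
        if node.is_leaf():
            depths[node.taxon.label] = d
    return depths


def patristic_distances(tree: dendropy.Tree) -> DistanceMatrix:
    """All-pairs tip-to-tip path-length (patristic) distances."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            mat[i, j] = mat[j, i] = d
    return DistanceMatrix(labels=labels, values=mat)


def phylo_vcv(tree: dendropy.Tree) -> tuple[list[str], np.ndarray]:
    """Phylogenetic covariance matrix: V_ij = shared root-to-MRCA path length.

    Derived from depths and patristic distances: V_ij = (t_i + t_j - d_ij)/2.
    """
    dm = patristic_distances(tree)
    depths = _root_to_tip_depths(tree)
    t = np.array([depths[s] for s in dm.labels])
    V = (t[:, None] + t[None, :] - dm.values) / 2.0
    return dm.labels, V


def _blomberg_k(x: np.ndarray, Vinv_factor, V: np.ndarray, ones_Vinv_ones: float,
                Vinv_ones: np.ndarray) -> float:
    n = len(x)
    a_hat = float(Vinv_ones @ x) / ones_Vinv_ones
    r = x - a_hat
    mse0 = float(r @ r) / (n - 1)
    mse = float(r @ cho_solve(Vinv_factor, r)) / (n - 1)
    expected = (np.trace(V) - n / ones_Vinv_ones) / (n - 1)
    return (mse0 / mse) / expected


def phylogenetic_signal(
    tree: dendropy.Tree,
    trait_values: dict[str, float],
    n_shuffles: int = 999,
    seed: int | None = None,
) -> dict:
    """Blomberg's K with a tip-shuffle permutation p-value.

    K compares the observed ratio of tip variance to phylogenetically
    corrected variance against its Brownian-motion expectation; K near 1 is
    consistent with Brownian evolution, K near 0 with no signal. The p-value
    is the proportion of tip-label shuffles with K at least as large as
    observed, with the +1/(n+1) correction.
    """
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    labels, V = phylo_vcv(tree)
    missing = [s for s in labels if s not in trait_values]
    if missing:
        raise ValueError(f"tips without trait values: {missing}")
    x = np.array([float(trait_values[s]) for s in labels])
    if np.ptp(x) == 0:
        return {"K": float("nan"), "p": float("nan"), "undefined": True,
                "n_shuffles": n_shuffles}
    # short terminal branches make V numerically near-singular; ridge just
    # enough to factor
    scale = float(np.mean(np.diag(V)))
    factor = None
    for eps in (0.0, 1e-12, 1e-10, 1e-8, 1e-6):
        try:
            factor = cho_factor(V + eps * scale * np.eye(len(V)))
            break
        except np.linalg.LinAlgError:
            continue
    if factor is None:
        raise np.linalg.LinAlgError("phylogenetic covariance is not positive definite")
    ones = np.ones(len(x))
    Vinv_ones = cho_solve(factor, ones)
    denom = float(ones @ Vinv_ones)
    k_obs = _blomberg_k(x, factor, V, denom, Vinv_ones)
    rng = np.random.default_rng(seed)
    count = 0
    xs = x.copy()
    for _ in range(n_shuffles):
        rng.shuffle(xs)
        if _blomberg_k(xs, factor, V, denom, Vinv_ones) >= k_obs:
            count += 1
    p = (1 + count) / (n_shuffles + 1)
    return {"K": float(k_obs), "p": float(p), "undefined": False,
            "n_shuffles": n_shuffles}
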