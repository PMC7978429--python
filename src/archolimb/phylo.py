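"""Ancestral character estimation under Brownian motion on a time tree.

Mean normalized moment arms are continuous traits; their states at the
internal nodes of a time-calibrated phylogeny are estimated by maximum
likelihood under Brownian motion (BM).  The estimate at a node equals the
generalized-least-squares (phylogenetically weighted) mean of the tip
values with the tree re-rooted at that node,

    a_hat = (1' V^-1 1)^-1 1' V^-1 x,

where V is the BM covariance implied by the branch lengths of the re-rooted
tree (V[i,j] = shared path length from the node to tips i and j).  The
95% confidence interval around each estimate follows the convention of the
re-rooting estimator as implemented in comparative-methods software: the
node variance is (1' V^-1 1)^-1 scaled by the contrast-based rate
sum(contrasts^2)/(n-1), and the interval is estimate +/- 1.96 sd.  The
reported global rate sigma^2 is the ML estimator (1/n scaling).

Trees are Newick files with branch lengths in millions of years (Ma) and
named internal nodes (clade names); dendropy handles parsing/serialisation.
"""

from __future__ import annotations

import importlib.resources
import warnings
from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

#: ancestor sequence from the crocodile-bird split to crown birds; the
#: Dromaeosauridae node is a side branch off Eumaniraptora
MAIN_LINE_NODES = (
    "Archosauria",
    "Dinosauromorpha",
    "Dinosauria",
    "Saurischia",
    "Neotheropoda",
    "Averostra",
    "Avetheropoda",
    "Coelurosauria",
    "Eumaniraptora",
    "Avialae",
    "Phasianidae",
)
OFF_LINE_NODES = ("Dromaeosauridae",)
STUDY_NODES = MAIN_LINE_NODES[:9] + OFF_LINE_NODES + MAIN_LINE_NODES[9:]


class TreeError(ValueError):
    pass


@dataclass
class TimeTree:
    """A rooted tree with positive branch lengths (Ma) and labelled nodes."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> list[str]:
        return [t.label for t in self.tree.taxon_namespace]

    @property
    def internal_labels(self) -> list[str]:
        return [
            n.label for n in self.tree.preorder_internal_node_iter()
            if n.label is not None
        ]

    def n_edges(self) -> int:
        return sum(
            1 for e in self.tree.preorder_edge_iter() if e.head_node.parent_node
        )

    def copy(self) -> "TimeTree":
        return TimeTree(self.tree.clone(depth=1))


def _validate(tree: dendropy.Tree) -> None:
    unlabeled = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            bl = node.edge.length
            if bl is None or bl <= 0:
                raise TreeError(
                    f"zero/negative/missing branch length above "
                    f"{node.taxon.label if node.taxon else node.label or '<node>'}"
                )
        if not node.is_leaf() and node.label is None:
            unlabeled += 1
    if unlabeled:
        warnings.warn(f"{unlabeled} internal node(s) are unlabeled", stacklevel=3)


def read_tree(source: str | Path) -> TimeTree:
    """Parse a Newick tree from a file path or a Newick string."""
    if isinstance(source, Path):
        text = source.read_text()
    else:
        text = str(source)
        if "(" not in text:  # a path, not Newick data
            text = Path(text).read_text()
    tree = dendropy.Tree.get(
        data=text, schema="newick", suppress_internal_node_taxa=True,
        preserve_underscores=True,
    )
    _validate(tree)
    return TimeTree(tree)


def write_tree(timetree: TimeTree, path: str | Path | None = None) -> str:
    """Serialise to Newick (labels + branch lengths); round-trips losslessly."""
    newick = timetree.tree.as_string(
        schema="newick", suppress_rooting=True,
        unquoted_underscores=True,
    ).strip()
    if path is not None:
        Path(path).write_text(newick + "\n")
    return newick


def study_tree() -> TimeTree:
    """The packaged 13-taxon archosaur study tree (branch lengths in Ma)."""
    ref = importlib.resources.files("archolimb") / "data" / "study_tree.nwk"
    return read_tree(Path(str(ref)))


def punctuated_tree(timetree: TimeTree) -> TimeTree:
    """Sensitivity variant: identical topology, every branch length set to 1
    (a 'punctuated' model where change is per cladogenetic event)."""
    out = timetree.copy()
    for node in out.tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = 1.0
    return out


# ---------------------------------------------------------------------------
# Brownian-motion ancestral states
# ---------------------------------------------------------------------------

@dataclass
class ACEResult:
    nodes: list[str]
    estimates: np.ndarray
    variances: np.ndarray
    ci95_low: np.ndarray
    ci95_high: np.ndarray
    sigma2_ml: float
    tip_order: list[str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.nodes,
                "estimate": self.estimates,
                "variance": self.variances,
                "ci95_low": self.ci95_low,
                "ci95_high": self.ci95_high,
            }
        ).set_index("node")

    def __getitem__(self, node: str) -> float:
        return float(self.estimates[self.nodes.index(node)])


def _node_key(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label if node.label is not None else f"@{id(node)}"


def _distance_table(tree: dendropy.Tree) -> tuple[dict[str, int], np.ndarray]:
    """All pairwise path-length distances between nodes of a rooted tree.

    d(u, v) = depth(u) + depth(v) - 2 depth(mrca(u, v)), with depths
    accumulated from the root.  Returns a node-key -> index map and the
    dense distance matrix.
    """
    nodes = list(tree.preorder_node_iter())
    index = {id(n): i for i, n in enumerate(nodes)}
    depth = np.zeros(len(nodes))
    ancestors: list[list[int]] = [[] for _ in nodes]
    for n in nodes:
        i = index[id(n)]
        if n.parent_node is None:
            depth[i] = 0.0
            ancestors[i] = [i]
        else:
            p = index[id(n.parent_node)]
            depth[i] = depth[p] + n.edge.length
            ancestors[i] = ancestors[p] + [i]
    anc_sets = [set(a) for a in ancestors]
    n_nodes = len(nodes)
    dist = np.zeros((n_nodes, n_nodes))
    for i in range(n_nodes):
        for j in range(i + 1, n_nodes):
            common = anc_sets[i] & anc_sets[j]
            mrca_depth = max(depth[k] for k in common)
            dist[i, j] = dist[j, i] = depth[i] + depth[j] - 2.0 * mrca_depth
    keymap = {_node_key(n): index[id(n)] for n in nodes}
    return keymap, dist


def ace_brownian(timetree: TimeTree, trait: dict[str, float],
                 ci_z: float = 1.96) -> ACEResult:
    """ML ancestral states of one continuous trait under Brownian motion.

    ``trait`` maps every tip label to a finite value (lost muscles are
    encoded as 0 upstream).  Estimates, variances and 95% CIs are produced
    for every internal node; see the module docstring for the estimator.
    """
    tree = timetree.tree
    tips = [n for n in tree.leaf_node_iter()]
    tip_labels = [t.taxon.label for t in tips]
    if len(tips) < 2:
        raise TreeError("ancestral state estimation needs >= 2 tips")
    missing = [t for t in tip_labels if t not in trait]
    if missing:
        raise TreeError(f"trait values missing for tips: {missing}")
    x = np.array([float(trait[t]) for t in tip_labels])
    if not np.all(np.isfinite(x)):
        raise TreeError("trait values must be finite")

    keymap, dist = _distance_table(tree)
    tip_idx = np.array([keymap[t] for t in tip_labels])
    internal = [
        n for n in tree.preorder_internal_node_iter()
    ]
    n = len(tips)
    ones = np.ones(n)
    d_tt = dist[np.ix_(tip_idx, tip_idx)]

    names, est, wvar, qforms = [], [], [], []
    for node in internal:
        j = keymap[_node_key(node)]
        d_j = dist[j, tip_idx]
        # BM covariance of tips with the tree re-rooted at this node
        V = 0.5 * (d_j[:, None] + d_j[None, :] - d_tt)
        Vinv = np.linalg.inv(V)
        w = float(ones @ Vinv @ ones)
        a_hat = float(ones @ Vinv @ x) / w
        resid = x - a_hat
        q = float(resid @ Vinv @ resid)
        names.append(node.label if node.label is not None else _node_key(node))
        est.append(a_hat)
        wvar.append(1.0 / w)
        qforms.append(q)

    est = np.array(est)
    wvar = np.array(wvar)
    qforms = np.array(qforms)
    # sum of squared standardized contrasts == GLS quadratic form; it is
    # invariant to the re-rooting, so use the root's value for the rate
    q_root = qforms[0]
    sig2_contrast = q_root / (n - 1)  # scales the node variances (fastAnc)
    sigma2_ml = q_root / n  # reported ML rate
    variances = wvar * sig2_contrast
    sd = np.sqrt(variances)
    return ACEResult(
        nodes=names,
        estimates=est,
        variances=variances,
        ci95_low=est - ci_z * sd,
        ci95_high=est + ci_z * sd,
        sigma2_ml=float(sigma2_ml),
        tip_order=tip_labels,
    )


def ace_weights(timetree: TimeTree) -> tuple[list[str], list[str], np.ndarray, np.ndarray]:
    """Per-node GLS weights for fast repeated estimation on one tree.

    Returns ``(node_names, tip_order, W, wvar)`` where ``W`` is
    (nodes x tips) with rows summing to 1 (estimate = W @ x) and ``wvar``
    the per-node variance factors (1' V^-1 1)^-1.  The quadratic form for
    the rate must still be computed per trait (root V inverse is returned
    implicitly through :func:`ace_brownian`; use this helper only for
    replicate-heavy simulations).
    """
    tree = timetree.tree
    tips = list(tree.leaf_node_iter())
    tip_labels = [t.taxon.label for t in tips]
    keymap, dist = _distance_table(tree)
    tip_idx = np.array([keymap[t] for t in tip_labels])
    d_tt = dist[np.ix_(tip_idx, tip_idx)]
    n = len(tips)
    ones = np.ones(n)
    names, rows, wvar = [], [], []
    root_Vinv = None
    for node in tree.preorder_internal_node_iter():
        j = keymap[_node_key(node)]
        d_j = dist[j, tip_idx]
        V = 0.5 * (d_j[:, None] + d_j[None, :] - d_tt)
        Vinv = np.linalg.inv(V)
        if root_Vinv is None:
            root_Vinv = Vinv
        w = float(ones @ Vinv @ ones)
        rows.append((Vinv @ ones) / w)
        wvar.append(1.0 / w)
        names.append(node.label if node.label is not None else _node_key(node))
    return names, tip_labels, np.array(rows), np.array(wvar)


def ace_brownian_many(timetree: TimeTree, X: pd.DataFrame, ci_z: float = 1.96
                      ) -> dict[str, pd.DataFrame]:
    """Vectorised ancestral states for many replicate trait vectors.

    ``X``: rows = replicates, columns = tip labels.  Returns dataframes
    (replicates x nodes) of estimates, variances and CI bounds; equivalent
    to calling :func:`ace_brownian` row by row.
    """
    names, tip_labels, W, wvar = ace_weights(timetree)
    x = X[tip_labels].to_numpy(dtype=float)
    est = x @ W.T  # (reps, nodes)
    # rate from the root GLS quadratic form
    keymap, dist = _distance_table(timetree.tree)
    tip_idx = np.array([keymap[t] for t in tip_labels])
    root = timetree.tree.seed_node
    d_r = dist[keymap[_node_key(root)], tip_idx]
    V = 0.5 * (d_r[:, None] + d_r[None, :] - dist[np.ix_(tip_idx, tip_idx)])
    Vinv = np.linalg.inv(V)
    n = len(tip_labels)
    resid = x - est[:, [names.index(_node_key(root))]]
    q = np.einsum("ri,ij,rj->r", resid, Vinv, resid)
    sig2 = q / (n - 1)
    var = sig2[:, None] * wvar[None, :]
    sd = np.sqrt(var)
    return {
        "estimate": pd.DataFrame(est, columns=names),
        "variance": pd.DataFrame(var, columns=names),
        "ci95_low": pd.DataFrame(est - ci_z * sd, columns=names),
        "ci95_high": pd.DataFrame(est + ci_z * sd, columns=names),
    }


def ace_all(timetree: TimeTree, traits: pd.DataFrame,
            node_order: tuple[str, ...] | None = None) -> dict[str, pd.DataFrame]:
    """Ancestral states for a whole trait table.

    ``traits``: rows = MTUs, columns = tip taxa, values = mean normalized
    moment arms.  Returns ``{"estimate", "ci95_low", "ci95_high"}`` tables
    with rows = MTUs and columns = internal nodes (the supplementary-file
    layout).
    """
    tip_set = set(timetree.tip_labels)
    col_set = set(traits.columns)
    if tip_set != col_set:
        raise TreeError(
            f"taxon mismatch between tree and trait table: "
            f"tree-only={sorted(tip_set - col_set)}, "
            f"table-only={sorted(col_set - tip_set)}"
        )
    frames = {k: {} for k in ("estimate", "ci95_low", "ci95_high", "variance")}
    nodes = None
    for mtu, row in traits.iterrows():
        res = ace_brownian(timetree, row.to_dict())
        nodes = res.nodes
        frames["estimate"][mtu] = res.estimates
        frames["ci95_low"][mtu] = res.ci95_low
        frames["ci95_high"][mtu] = res.ci95_high
        frames["variance"][mtu] = res.variances
    order = list(node_order) if node_order else nodes
    out = {}
    for key, data in frames.items():
        df = pd.DataFrame(data, index=nodes).T
        out[key] = df[[c for c in order if c in df.columns]]
        out[key].index.name = "MTU"
    return out
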