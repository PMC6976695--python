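"""Newick phylogeny handling and generalized UniFrac.

The tree is an input (inferred upstream); here it only supplies branch
lengths.  Generalized UniFrac between two relative-abundance vectors over
the tips, with branch weight (p_A + p_B)^alpha:

    d = sum_i b_i (p_Ai + p_Bi)^a * |p_Ai - p_Bi| / (p_Ai + p_Bi)
        -----------------------------------------------------------
        sum_i b_i (p_Ai + p_Bi)^a

summing over all branches i, where p_Xi is the total proportion of
community X descending from branch i.  alpha = 1 recovers the weighted
normalised UniFrac; alpha = 0.5 (the survey's setting) damps the weight of
abundant lineages.  Branches with no descendant abundance in either
community contribute nothing.
"""

from __future__ import annotations

import io
import logging
import warnings

import pandas as pd
from skbio import TreeNode

logger = logging.getLogger(__name__)


def read_newick(source) -> TreeNode:
    """Read and validate a rooted newick tree with branch lengths.

    ``source`` is a path or a newick string.  Duplicate tip labels,
    negative branch lengths and missing branch lengths (other than at the
    root) are rejected, naming the offending node.  A tree whose root has
    more than two children is treated as unrooted and midpoint-rooted with
    a warning; internal multifurcations below the root are accepted.
    """
    text = str(source)
    if "(" not in text:
        with open(source, encoding="utf-8") as fh:
            text = fh.read()
    tree = TreeNode.read(io.StringIO(text), format="newick", convert_underscores=False)
    if len(tree.children) > 2:
        warnings.warn(
            "input tree appears unrooted (root has >2 children); midpoint-rooting",
            stacklevel=2,
        )
        tree = tree.root_at_midpoint()
    _validate_tree(tree)
    return tree


def _validate_tree(tree: TreeNode) -> None:
    seen: set[str] = set()
    for node in tree.postorder():
        if node.is_tip():
            if node.name in seen:
                raise ValueError(f"duplicate tip label {node.name!r}")
            seen.add(node.name)
        if node is tree:
            continue  # root branch length may be absent; it is never summed
        if node.length is None:
            label = node.name or f"internal node above {{{', '.join(t.name for t in node.tips())}}}"
            raise ValueError(f"missing branch length at {label}")
        if node.length < 0:
            raise ValueError(f"negative branch length at {node.name or 'internal node'}")


def write_newick(tree: TreeNode, path) -> None:
    tree.write(path, format="newick")


def _branch_proportions(tree: TreeNode, p: dict[str, float]) -> dict[int, float]:
    """Total proportion descending from each branch (post-order accumulation).

    Keys are ``id(node)`` for every non-root node.
    """
    acc: dict[int, float] = {}
    for node in tree.postorder():
        if node.is_tip():
            total = p.get(node.name, 0.0)
        else:
            total = sum(acc[id(c)] for c in node.children)
        acc[id(node)] = total
    return acc


def _as_proportion_map(vec, tree_tips: set[str], label: str) -> dict[str, float]:
    if isinstance(vec, pd.Series):
        items = vec.items()
    elif isinstance(vec, dict):
        items = vec.items()
    else:
        raise TypeError(f"{label}: expected a mapping or Series of tip -> proportion")
    p = {}
    for tip, v in items:
        if v < 0:
            raise ValueError(f"{label}: negative proportion for tip {tip!r}")
        if v > 0 and tip not in tree_tips:
            raise ValueError(f"{label}: tip {tip!r} absent from tree")
        p[str(tip)] = float(v)
    total = sum(p.values())
    if abs(total - 1.0) > 1e-6:
        raise ValueError(f"{label}: proportions sum to {total}, not 1")
    return p


def gunifrac(tree: TreeNode, pA, pB, alpha: float = 0.5) -> float:
    """Generalized UniFrac distance between two tip-proportion vectors."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    tips = {t.name for t in tree.tips()}
    a = _as_proportion_map(pA, tips, "pA")
    b = _as_proportion_map(pB, tips, "pB")
    accA = _branch_proportions(tree, a)
    accB = _branch_proportions(tree, b)
    num = 0.0
    den = 0.0
    for node in tree.postorder():
        if node is tree:
            continue
        total = accA[id(node)] + accB[id(node)]
        if total <= 0:
            continue
        w = node.length * total ** alpha
        num += w * abs(accA[id(node)] - accB[id(node)]) / total
        den += w
    if den == 0:
        raise ValueError("no branch carries abundance")
    return num / den


def layer_phylo_distances(
    tree: TreeNode,
    layer_vectors: dict[str, "pd.Series | dict[str, float]"],
    alpha: float = 0.5,
) -> pd.DataFrame:
    """Symmetric matrix of generalized UniFrac distances among layer
    abundance vectors (e.g., summed rRNA relative abundances of each
    layer's preferential OTUs, normalised to 1)."""
    layers = list(layer_vectors)
    for layer, vec in layer_vectors.items():
        total = float(pd.Series(vec).sum())
        if total <= 0:
            raise ValueError(f"empty layer set for {layer!r}")
    mat = pd.DataFrame(0.0, index=layers, columns=layers)
    for i, la in enumerate(layers):
        for lb in layers[i + 1:]:
            dval = gunifrac(tree, layer_vectors[la], layer_vectors[lb], alpha)
            mat.loc[la, lb] = dval
            mat.loc[lb, la] = dval
    return mat


def normalized_layer_vectors(
    rel_table,
    meta,
    layer_otus: dict[str, set[str]],
) -> dict[str, pd.Series]:
    """Summed relative abundances of each layer's preferential OTUs over
    that layer's samples, normalised to sum 1 (tree-ready vectors)."""
    out: dict[str, pd.Series] = {}
    info = {m.sample_id: m for m in meta}
    for layer, otus in layer_otus.items():
        if not otus:
            continue
        cols = [s for s in rel_table.sample_ids if s in info and info[s].layer == layer]
        if not cols:
            continue
        v = rel_table.data.loc[sorted(otus), cols].sum(axis=1)
        total = v.sum()
        if total > 0:
            out[layer] = v / total
    return out
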